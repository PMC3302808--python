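"""Diversity indices, frequency-spectrum neutrality tests and the
synonymous-saturation scan.

Scales follow the conventions of the population-genetics literature: Hd is
dimensionless; pi and Watterson's theta are reported per site; Tajima's D and
Fu & Li's D/F are dimensionless; Fay & Wu's H is reported per gene (the scale
on which published tables print it), with a per-site variant available.

Columns containing a gap or an 'N' in any analyzed sequence (and, for
polarized statistics, in the outgroup) are excluded from every per-site
quantity; the excluded columns are available from :func:`site_diagnostics`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .codons import count_syn_nonsyn_sites, pairwise_differences
from .seqdata import CodonAlignment, HaplotypeSet, collapse_haplotypes


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------
@dataclass
class DiversityResult:
    n: int
    h: int
    S: int
    Hd: float
    Hd_sd: float
    pi: float
    pi_sd: float
    pi_s: float
    pi_a: float
    theta_w: float
    theta_w_sd: float
    region: str = ""
    population: str = ""


@dataclass
class NeutralityResult:
    statistic: str
    value: float | None
    p_raw: float | None = None
    p_adjusted: float | None = None
    region: str = ""
    population: str = ""

    @property
    def defined(self) -> bool:
        return self.value is not None


# ---------------------------------------------------------------------------
# summaries of the alignment
# ---------------------------------------------------------------------------
def _allele_counts(m: np.ndarray) -> np.ndarray:
    """(4, L) counts of A,C,G,T per column for a coded matrix."""
    return np.stack([(m == c).sum(axis=0) for c in range(4)])


def site_diagnostics(aln: CodonAlignment, require_outgroup: bool = False) -> dict:
    mask = aln.usable_sites(require_outgroup=require_outgroup)
    return {
        "usable_sites": int(mask.sum()),
        "excluded_sites": [int(i + 1) for i in np.flatnonzero(~mask)],
    }


def segregating_sites(aln: CodonAlignment) -> int:
    m = aln.matrix()[:, aln.usable_sites()]
    counts = _allele_counts(m)
    return int(((counts > 0).sum(axis=0) > 1).sum())


def _kbar(aln: CodonAlignment) -> tuple[float, int]:
    """Mean pairwise nucleotide differences per gene and usable-site count."""
    mask = aln.usable_sites()
    m = aln.matrix()[:, mask]
    n = m.shape[0]
    counts = _allele_counts(m)
    same_pairs = (counts * (counts - 1) // 2).sum(axis=0)
    diff_pairs = n * (n - 1) // 2 - same_pairs
    return float(diff_pairs.sum() / (n * (n - 1) / 2)), int(mask.sum())


def haplotype_diversity(hs: HaplotypeSet) -> tuple[float, float]:
    """Nei's haplotype (gene) diversity with its sampling standard deviation."""
    n = hs.n
    if n < 2:
        raise ValueError("haplotype diversity needs n >= 2")
    p = hs.counts / n
    sum2 = float((p**2).sum())
    sum3 = float((p**3).sum())
    hd = n / (n - 1) * (1.0 - sum2)
    var = 2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (sum3 - sum2**2) + sum2 - sum2**2)
    return hd, float(np.sqrt(max(var, 0.0)))


def nucleotide_diversity(
    aln: CodonAlignment, site_class: str = "all", R: float = 2.0
) -> float:
    """Average pairwise difference per site, optionally restricted by class.

    ``site_class`` 'all' divides the mean pairwise Hamming distance by the
    usable-site count; 'synonymous'/'nonsynonymous' use Nei-Gojobori pathway
    difference counts divided by the modified (bias ``R``) synonymous or
    nonsynonymous site totals.  Codons overlapping an excluded column are
    dropped from the classed variants.
    """
    if aln.n < 2:
        raise ValueError("nucleotide diversity needs n >= 2")
    if site_class == "all":
        kbar, sites = _kbar(aln)
        if sites == 0:
            raise ValueError("no analyzable sites")
        return kbar / sites
    if site_class not in ("synonymous", "nonsynonymous"):
        raise ValueError(f"unknown site_class {site_class!r}")
    idx = 0 if site_class == "synonymous" else 1
    codon_cols = _clean_codon_columns(aln)
    if not codon_cols:
        raise ValueError("no analyzable codons")
    vals = []
    for sa, sb in itertools.combinations([r.seq for r in aln.sequences], 2):
        diffs = 0.0
        sites = 0.0
        for a0 in codon_cols:
            ca, cb = sa[a0 : a0 + 3], sb[a0 : a0 + 3]
            diffs += pairwise_differences(ca, cb)[idx]
            sites += (
                count_syn_nonsyn_sites(ca, R)[idx] + count_syn_nonsyn_sites(cb, R)[idx]
            ) / 2.0
        vals.append(diffs / sites if sites > 0 else 0.0)
    return float(np.mean(vals))


def _clean_codon_columns(aln: CodonAlignment) -> list[int]:
    """0-based nt start offsets of codons free of gaps/N/stops in all rows."""
    mask = aln.usable_sites()
    from .codons import STOP_CODONS

    out = []
    for i in range(aln.n_codons):
        a = aln.frame_offset + 3 * i
        if not mask[a : a + 3].all():
            continue
        if any(r.seq[a : a + 3] in STOP_CODONS for r in aln.sequences):
            continue
        out.append(a)
    return out


def _harmonics(n: int) -> tuple[float, float]:
    i = np.arange(1, n)
    return float((1.0 / i).sum()), float((1.0 / i**2).sum())


def watterson_theta(n: int, S: int, sites: int) -> tuple[float, float]:
    """Watterson's theta per site with its estimated standard deviation."""
    if n < 2:
        raise ValueError("watterson_theta needs n >= 2")
    if S < 0 or sites <= 0:
        raise ValueError("S >= 0 and sites > 0 required")
    a1, a2 = _harmonics(n)
    theta_gene = S / a1
    var_gene = S / a1**2 + a2 * S * (S - 1) / (a1**2 * (a1**2 + a2))
    return theta_gene / sites, float(np.sqrt(var_gene)) / sites


def diversity_summary(
    aln: CodonAlignment, R: float = 2.0, region: str = "", population: str = ""
) -> DiversityResult:
    hs = collapse_haplotypes(aln)
    hd, hd_sd = haplotype_diversity(hs)
    kbar, sites = _kbar(aln)
    S = segregating_sites(aln)
    theta, theta_sd = watterson_theta(aln.n, S, sites)
    # Tajima's variance of mean pairwise differences (per gene), per site below
    n = aln.n
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    var_k = b1 * kbar + b2 * kbar**2
    return DiversityResult(
        n=aln.n,
        h=hs.h,
        S=S,
        Hd=hd,
        Hd_sd=hd_sd,
        pi=kbar / sites,
        pi_sd=float(np.sqrt(max(var_k, 0.0))) / sites,
        pi_s=nucleotide_diversity(aln, "synonymous", R),
        pi_a=nucleotide_diversity(aln, "nonsynonymous", R),
        theta_w=theta,
        theta_w_sd=theta_sd,
        region=region,
        population=population,
    )


# ---------------------------------------------------------------------------
# neutrality tests
# ---------------------------------------------------------------------------
def _tajima_constants(n: int) -> dict:
    a1, a2 = _harmonics(n)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return {"a1": a1, "a2": a2, "e1": c1 / a1, "e2": c2 / (a1**2 + a2)}


def tajima_D(aln: CodonAlignment, region: str = "", population: str = "") -> NeutralityResult:
    """Tajima's D with a beta-approximation p-value.

    With no segregating site the statistic is undefined and reported as such
    (value None), never as zero.
    """
    n = aln.n
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    S = segregating_sites(aln)
    if S == 0:
        return NeutralityResult("TajimaD", None, region=region, population=population)
    kbar, _ = _kbar(aln)
    c = _tajima_constants(n)
    D = (kbar - S / c["a1"]) / np.sqrt(c["e1"] * S + c["e2"] * S * (S - 1))
    p = _tajima_beta_p(D, n, c)
    return NeutralityResult("TajimaD", float(D), p_raw=p, region=region, population=population)


def _tajima_beta_p(D: float, n: int, c: dict) -> float:
    """Two-sided p under Tajima's bounded-beta null approximation."""
    dmin = (2.0 / n - 1.0 / c["a1"]) / np.sqrt(c["e2"])
    dmax = (n / (2.0 * (n - 1.0)) - 1.0 / c["a1"]) / np.sqrt(c["e2"])
    alpha = -(1.0 + dmin * dmax) * dmax / (dmax - dmin)
    beta = (1.0 + dmin * dmax) * dmin / (dmax - dmin)
    if alpha <= 0 or beta <= 0:  # approximation breaks down at tiny n
        return float("nan")
    rv = sps.beta(beta, alpha, loc=dmin, scale=dmax - dmin)
    x = float(np.clip(D, dmin + 1e-12, dmax - 1e-12))
    return float(np.clip(2.0 * min(rv.cdf(x), rv.sf(x)), 1e-300, 1.0))


def _polarized_site_table(aln: CodonAlignment) -> dict:
    """Per-site derived-allele counts using the outgroup as ancestral state.

    Sites where the outgroup carries a gap/N or an allele absent from the
    ingroup sample (a third allele) are excluded and counted in diagnostics.
    """
    if aln.outgroup is None:
        raise ValueError("polarized statistics require an outgroup")
    m_all = aln.matrix(with_outgroup=True)
    mask = (m_all < 4).all(axis=0)
    m = m_all[:-1][:, mask]
    og = m_all[-1][mask]
    n = m.shape[0]
    counts = _allele_counts(m)
    n_alleles = (counts > 0).sum(axis=0)
    og_count = counts[og, np.arange(m.shape[1])]
    segregating = n_alleles > 1
    polarizable = segregating & (og_count > 0)
    excluded_third = int((segregating & (og_count == 0)).sum())
    # derived allele frequencies: every non-outgroup allele at a polarizable site
    sfs = np.zeros(n + 1, dtype=float)  # sfs[i] = mutations with derived count i
    eta = 0
    for j in np.flatnonzero(polarizable):
        for a in range(4):
            if a != og[j] and counts[a, j] > 0:
                sfs[counts[a, j]] += 1
                eta += 1
    kbar_pol = 0.0
    same = (counts[:, polarizable] * (counts[:, polarizable] - 1) // 2).sum(axis=0)
    kbar_pol = float(((n * (n - 1) // 2) - same).sum() / (n * (n - 1) / 2))
    return {
        "n": n,
        "sfs": sfs,
        "eta": eta,
        "eta_e": float(sfs[1]),
        "kbar": kbar_pol,
        "sites": int(mask.sum()),
        "excluded_third_allele": excluded_third,
        "n_polarized_sites": int(polarizable.sum()),
    }


def fu_li_D_F(
    aln: CodonAlignment, region: str = "", population: str = ""
) -> tuple[NeutralityResult, NeutralityResult]:
    """Fu & Li's D and F using external (derived-singleton) mutation counts.

    The outgroup allele defines the ancestral state; eta is the total number
    of polarized mutations and eta_e the number carried by exactly one
    sequence.  p-values come from the normal approximation to the
    standardized statistics (published tables mark significance levels only).
    """
    n = aln.n
    if n < 4:
        raise ValueError("Fu & Li's tests need n >= 4")
    t = _polarized_site_table(aln)
    eta, eta_e, kbar = t["eta"], t["eta_e"], t["kbar"]
    if eta == 0:
        und = NeutralityResult("FuLiD", None, region=region, population=population)
        und2 = NeutralityResult("FuLiF", None, region=region, population=population)
        return und, und2
    an, bn = _harmonics(n)
    an1 = an + 1.0 / n
    cn = 2.0 * (n * an - 2.0 * (n - 1)) / ((n - 1) * (n - 2))
    vD = 1.0 + (an**2 / (bn + an**2)) * (cn - (n + 1.0) / (n - 1.0))
    uD = an - 1.0 - vD
    D = (eta - an * eta_e) / np.sqrt(uD * eta + vD * eta**2)
    vF = (cn + 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0)) - 2.0 / (n - 1.0)) / (
        an**2 + bn
    )
    uF = (
        1.0
        + (n + 1.0) / (3.0 * (n - 1.0))
        - 4.0 * ((n + 1.0) / (n - 1.0) ** 2) * (an1 - 2.0 * n / (n + 1.0))
    ) / an - vF
    F = (kbar - eta_e) / np.sqrt(uF * eta + vF * eta**2)
    pD = float(2.0 * sps.norm.sf(abs(D)))
    pF = float(2.0 * sps.norm.sf(abs(F)))
    return (
        NeutralityResult("FuLiD", float(D), p_raw=pD, region=region, population=population),
        NeutralityResult("FuLiF", float(F), p_raw=pF, region=region, population=population),
    )


def fay_wu_H(
    aln: CodonAlignment, per_site: bool = False, region: str = "", population: str = ""
) -> NeutralityResult:
    """Fay & Wu's H = pi - theta_H from the polarized frequency spectrum.

    Reported per gene by default (the scale on which published values such as
    -34.402 are printed); ``per_site`` divides by the usable-site count.
    """
    n = aln.n
    if n < 4:
        raise ValueError("Fay & Wu's H needs n >= 4")
    t = _polarized_site_table(aln)
    if t["eta"] == 0:
        return NeutralityResult("FayWuH", None, region=region, population=population)
    i = np.arange(1, n)
    theta_H = float((2.0 * t["sfs"][1:n] * i**2).sum() / (n * (n - 1.0)))
    H = t["kbar"] - theta_H
    if per_site:
        H /= t["sites"]
    return NeutralityResult("FayWuH", float(H), region=region, population=population)


# ---------------------------------------------------------------------------
# multiple-test correction
# ---------------------------------------------------------------------------
def holm_sidak(pvals, alpha: float = 0.05) -> list[tuple[float, bool, float]]:
    """Holm step-down procedure with Dunn-Sidak thresholds.

    At step i (1-based, p-values ascending) the threshold is
    ``1 - (1 - alpha)**(1/(m - i + 1))``; rejection stops at the first
    failure.  Returns (p_raw, reject, step_threshold) in input order.
    """
    p = list(pvals)
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if any(not 0 <= x <= 1 for x in p):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    out: list[tuple[float, bool, float] | None] = [None] * m
    rejecting = True
    for step, idx in enumerate(order, start=1):
        thr = 1.0 - (1.0 - alpha) ** (1.0 / (m - step + 1))
        if p[idx] > thr:
            rejecting = False
        out[idx] = (p[idx], rejecting, thr)
    return out  # type: ignore[return-value]


def sidak_adjust(pvals) -> list[float]:
    """Holm-Sidak adjusted p-values (monotone step-down adjustment)."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 0.0
    for step, idx in enumerate(order, start=1):
        a = 1.0 - (1.0 - p[idx]) ** (m - step + 1)
        running = max(running, a)
        adj[idx] = min(1.0, running)
    return adj


# ---------------------------------------------------------------------------
# saturation scan
# ---------------------------------------------------------------------------
def saturation_scan(aln: CodonAlignment, R: float = 2.0, include_outgroup: bool = True) -> pd.DataFrame:
    """Pairwise divergence versus pS and pN (modified Nei-Gojobori, bias R).

    One row per unordered sequence pair: overall p-distance per usable site,
    proportion of synonymous differences per synonymous site and of
    nonsynonymous differences per nonsynonymous site.  Plotting pS/pN against
    divergence exposes synonymous saturation as a plateau.
    """
    names = [r.sample_id for r in aln.sequences]
    seqs = [r.seq for r in aln.sequences]
    if include_outgroup and aln.outgroup is not None:
        names.append(aln.outgroup[0])
        seqs.append(aln.outgroup[1])
    codon_cols = _clean_codon_columns(aln)
    mask = aln.usable_sites()
    rows = []
    for (ia, sa), (ib, sb) in itertools.combinations(enumerate(seqs), 2):
        nd_all = sum(
            1 for j in np.flatnonzero(mask) if sa[j] != sb[j]
        )
        sd = nd = ss = ns = 0.0
        for a0 in codon_cols:
            ca, cb = sa[a0 : a0 + 3], sb[a0 : a0 + 3]
            d = pairwise_differences(ca, cb)
            sd += d[0]
            nd += d[1]
            sA, nA = count_syn_nonsyn_sites(ca, R)
            sB, nB = count_syn_nonsyn_sites(cb, R)
            ss += (sA + sB) / 2.0
            ns += (nA + nB) / 2.0
        rows.append(
            {
                "seq_a": names[ia],
                "seq_b": names[ib],
                "divergence": nd_all / mask.sum() if mask.sum() else 0.0,
                "pS": sd / ss if ss > 0 else 0.0,
                "pN": nd / ns if ns > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)
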