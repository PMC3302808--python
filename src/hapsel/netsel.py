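"""Selection tests on the haplotype network.

Three tests, all consuming :class:`~hapsel.network.MutationRecord` lists:

* the tip/interior contingency test (two-sided Fisher exact probability on
  the 2x2 class-by-position table),
* a margin-preserving Monte-Carlo permutation test of homogeneity for larger
  (region-stratified) tables, ordered by the Pearson chi-square, and
* a rank-based "mutation survival" comparison of the numbers of haplotypes
  descending from interior synonymous versus nonsynonymous mutations, using
  an improved (Edgeworth-corrected) normal approximation to the
  Mann-Whitney U statistic, with exact enumeration for small samples.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .codons import SubstitutionClass
from .network import MutationRecord


@dataclass
class ContingencyResult:
    table: np.ndarray
    row_labels: list[str]
    col_labels: list[str]
    statistic: float
    p: float
    method: str  # "fisher_exact" | "permutation"
    n_permutations: int | None = None
    seed: int | None = None


@dataclass
class SurvivalTestResult:
    syn_counts: list[int]
    nonsyn_counts: list[int]
    medians: tuple[float, float]
    U: float
    Zc: float
    p: float
    method: str
    min_haplotypes_filter: int
    p_exact: float | None = None
    p_normal: float | None = None


class DegenerateTableError(ValueError):
    def __init__(self, msg, table):
        super().__init__(msg)
        self.table = table


# ---------------------------------------------------------------------------
# Fisher exact (point-probability two-sided convention)
# ---------------------------------------------------------------------------
def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact probability: the sum of hypergeometric point
    probabilities not exceeding that of the observed table."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    a = t[0, 0]
    r1, c1, N = t[0].sum(), t[:, 0].sum(), t.sum()
    rv = sps.hypergeom(N, r1, c1)
    lo, hi = max(0, r1 + c1 - N), min(r1, c1)
    xs = np.arange(lo, hi + 1)
    pmf = rv.pmf(xs)
    p_obs = rv.pmf(a)
    p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    return min(p, 1.0)


def tip_interior_table(records: list[MutationRecord], region: str | None = None) -> np.ndarray:
    """2x2 table [[tip syn, tip nonsyn], [interior syn, interior nonsyn]]."""
    t = np.zeros((2, 2), dtype=int)
    for r in records:
        if region is not None and r.region != region:
            continue
        if r.subst_class is SubstitutionClass.SYNONYMOUS:
            j = 0
        elif r.subst_class is SubstitutionClass.NONSYNONYMOUS:
            j = 1
        else:
            continue
        i = 0 if r.position_class == "tip" else 1
        t[i, j] += 1
    return t


def templeton_fisher(
    records: list[MutationRecord] | np.ndarray, region: str | None = None
) -> ContingencyResult:
    """Tip/interior contingency test of selection.

    Under neutrality the nonsynonymous:synonymous ratio is the same among
    tip (young) and interior (old) mutations; purifying selection depletes
    interior nonsynonymous mutations.
    """
    if isinstance(records, (list, tuple)) and records and isinstance(records[0], MutationRecord):
        table = tip_interior_table(records, region)
    else:
        table = np.asarray(records, dtype=int)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTableError("a margin of the 2x2 table is empty", table)
    p = fisher_exact_2x2(table)
    return ContingencyResult(
        table=table,
        row_labels=["tip", "interior"],
        col_labels=["synonymous", "nonsynonymous"],
        statistic=float(sps.chi2_contingency(table, correction=False)[0])
        if (table > 0).any()
        else 0.0,
        p=p,
        method="fisher_exact",
    )


# ---------------------------------------------------------------------------
# margin-preserving permutation test (Roff-Bentzen style)
# ---------------------------------------------------------------------------
def permutation_table_test(
    table, n_perm: int = 1000, seed: int = 0, chunk: int = 20000
) -> ContingencyResult:
    """Monte-Carlo homogeneity test preserving both margins.

    The N classified mutations are randomly reassigned to cells by permuting
    column labels against fixed row blocks; the Pearson chi-square orders the
    tables and p = (1 + #{perm >= obs}) / (n_perm + 1), which never returns
    zero.  Fully reproducible for a given seed.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or (t < 0).any():
        raise ValueError("need a nonnegative 2-D table")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    row_tot, col_tot = t.sum(axis=1), t.sum(axis=0)
    if (row_tot == 0).any() or (col_tot == 0).any():
        raise DegenerateTableError("degenerate margins", t)
    R, C = t.shape
    N = int(t.sum())
    E = np.outer(row_tot, col_tot) / N
    obs = float(((t - E) ** 2 / E).sum())
    if R == 1 or C == 1:
        return ContingencyResult(t, [], [], obs, 1.0, "permutation", n_perm, seed)

    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(C, dtype=np.int8), col_tot)
    row_of = np.repeat(np.arange(R), row_tot)
    hits = 0
    done = 0
    Eflat = E.ravel()
    while done < n_perm:
        m = min(chunk, n_perm - done)
        P = np.tile(labels, (m, 1))
        P = rng.permuted(P, axis=1)
        flat = (
            np.arange(m)[:, None] * (R * C) + row_of[None, :] * C + P
        ).ravel()
        counts = np.bincount(flat, minlength=m * R * C).reshape(m, R * C)
        chi2 = ((counts - Eflat) ** 2 / Eflat).sum(axis=1)
        hits += int((chi2 >= obs - 1e-9).sum())
        done += m
    p = (1.0 + hits) / (n_perm + 1.0)
    return ContingencyResult(
        table=t,
        row_labels=[f"r{i}" for i in range(R)],
        col_labels=[f"c{j}" for j in range(C)],
        statistic=obs,
        p=float(p),
        method="permutation",
        n_permutations=n_perm,
        seed=seed,
    )


def stratified_table(records: list[MutationRecord], regions: list[str]) -> np.ndarray:
    """2 x (2*len(regions)) table: rows tip/interior, columns class x region."""
    cols = [(cls, reg) for cls in ("synonymous", "nonsynonymous") for reg in regions]
    t = np.zeros((2, len(cols)), dtype=int)
    for r in records:
        if r.subst_class is SubstitutionClass.SYNONYMOUS:
            cls = "synonymous"
        elif r.subst_class is SubstitutionClass.NONSYNONYMOUS:
            cls = "nonsynonymous"
        else:
            continue
        if (cls, r.region) not in cols:
            continue
        j = cols.index((cls, r.region))
        i = 0 if r.position_class == "tip" else 1
        t[i, j] += 1
    return t


# ---------------------------------------------------------------------------
# mutation survival (Mann-Whitney with improved normal approximation)
# ---------------------------------------------------------------------------
def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def mann_whitney_exact_p(x: list[float], y: list[float]) -> float:
    """Two-sided exact p by enumeration of all rank assignments (ties via
    midranks): P(|W - E[W]| >= |obs - E[W]|) over all C(m+n, m) splits."""
    pooled = np.asarray(list(x) + list(y), dtype=float)
    ranks = _midranks(pooled)
    m = len(x)
    obs = ranks[:m].sum()
    ew = m * (len(pooled) + 1) / 2.0
    d_obs = abs(obs - ew)
    total = 0
    extreme = 0
    for combo in itertools.combinations(range(len(pooled)), m):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - ew) >= d_obs - 1e-9:
            extreme += 1
    return extreme / total


def _edgeworth_tail(z: float, m: int, n: int) -> float:
    """Upper-tail P(Z >= z) with the fourth-cumulant Edgeworth term for the
    Mann-Whitney U (the no-tie excess kurtosis; ties are handled through the
    variance)."""
    N = m + n
    g2 = -1.2 * (m * m + n * n + m * n + m + n) / (m * n * (N + 1.0))
    phi = sps.norm.pdf(z)
    tail = sps.norm.sf(z) + phi * (g2 / 24.0) * (z**3 - 3.0 * z)
    return float(np.clip(tail, 0.0, 1.0))


def rank_survival_test(
    syn_counts, nonsyn_counts, min_haplotypes: int = 1, method: str = "auto"
) -> SurvivalTestResult:
    """Compare derived-haplotype counts of synonymous vs nonsynonymous
    mutations by ranks.

    ``Zc`` is the continuity-corrected standardized U for the nonsynonymous
    group (positive when nonsynonymous mutations left more descendant
    haplotypes); the p-value uses the Edgeworth-improved normal tail, or
    exact enumeration when m + n <= 14.
    """
    xs = sorted(int(c) for c in syn_counts if c >= min_haplotypes)
    ys = sorted(int(c) for c in nonsyn_counts if c >= min_haplotypes)
    if not xs or not ys:
        raise ValueError("a group is empty after the min-haplotypes filter")
    m, n = len(xs), len(ys)
    pooled = np.asarray(xs + ys, dtype=float)
    ranks = _midranks(pooled)
    r_y = ranks[m:].sum()
    U = r_y - n * (n + 1) / 2.0  # U for the nonsynonymous group
    mu = m * n / 2.0
    N = m + n
    _, t_counts = np.unique(pooled, return_counts=True)
    tie_term = ((t_counts**3 - t_counts).sum()) / (N * (N - 1.0))
    var = m * n / 12.0 * ((N + 1.0) - tie_term)
    if var <= 0:
        zc, p_norm, p_edge = 0.0, 1.0, 1.0
    else:
        # continuity correction = half the lattice spacing of U: midranks
        # put U on a half-integer lattice whenever ties are present
        spacing = 0.5 if (t_counts > 1).any() else 1.0
        cc = spacing / 2.0 if U != mu else 0.0
        zc = (U - mu - np.sign(U - mu) * cc) / np.sqrt(var)
        p_norm = float(np.clip(2.0 * sps.norm.sf(abs(zc)), 0.0, 1.0))
        p_edge = float(np.clip(2.0 * _edgeworth_tail(abs(zc), m, n), 0.0, 1.0))
    p_exact = None
    if method == "exact" or (method == "auto" and m + n <= 14):
        p_exact = mann_whitney_exact_p(xs, ys)
        p, used = p_exact, "exact"
    elif method == "normal":
        p, used = p_norm, "normal"
    else:
        p, used = p_edge, "edgeworth"
    return SurvivalTestResult(
        syn_counts=xs,
        nonsyn_counts=ys,
        medians=(float(np.median(xs)), float(np.median(ys))),
        U=float(U),
        Zc=float(zc),
        p=float(max(p, 1e-300)),
        method=used,
        min_haplotypes_filter=min_haplotypes,
        p_exact=p_exact,
        p_normal=p_norm,
    )


def survival_mw(
    records: list[MutationRecord], min_haplotypes: int = 3, method: str = "auto"
) -> SurvivalTestResult:
    """The network form of the survival test: interior mutations only, with
    the derived-haplotype-count filter (default: present in >= 3 observed
    haplotypes)."""
    syn, nonsyn = [], []
    for r in records:
        if r.position_class != "interior":
            continue
        if r.subst_class is SubstitutionClass.SYNONYMOUS:
            syn.append(r.derived_observed_count)
        elif r.subst_class is SubstitutionClass.NONSYNONYMOUS:
            nonsyn.append(r.derived_observed_count)
    return rank_survival_test(syn, nonsyn, min_haplotypes=min_haplotypes, method=method)


# ---------------------------------------------------------------------------
# McDonald-Kreitman gate
# ---------------------------------------------------------------------------
def mcdonald_kreitman_feasible(aln, species_key=None) -> dict:
    """Report whether an MK test is possible: it requires fixed interspecific
    differences, which panmictic-looking samples without reciprocal monophyly
    lack.  Returns the fixed/polymorphic counts and a feasibility flag; no
    test statistic is computed when there are no fixed differences."""
    from .popgen import _allele_counts

    groups: dict[str, list[int]] = {}
    for i, rec in enumerate(aln.sequences):
        key = rec.species if species_key is None else species_key(rec)
        groups.setdefault(key or "?", []).append(i)
    if len(groups) < 2:
        return {"feasible": False, "reason": "fewer than two species", "fixed_differences": 0}
    m = aln.matrix()[:, aln.usable_sites()]
    fixed = 0
    names = list(groups)
    for a, b in itertools.combinations(names, 2):
        ma, mb = m[groups[a]], m[groups[b]]
        for j in range(m.shape[1]):
            sa, sb = set(ma[:, j].tolist()), set(mb[:, j].tolist())
            if len(sa) == 1 and len(sb) == 1 and sa != sb:
                fixed += 1
    return {
        "feasible": fixed > 0,
        "reason": "" if fixed > 0 else "no fixed interspecific differences",
        "fixed_differences": fixed,
    }
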