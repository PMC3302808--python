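"""Maximum Chi-square (MaxChi) recombination screen.

For each sequence pair the alignment is reduced to its polymorphic sites;
every candidate breakpoint splits them into left/right halves and the 2x2
chi-square of (match/mismatch x left/right) is computed.  The maximum over
breakpoints is compared with its permutation null (site order shuffled), the
standard unwindowed form of the method.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .seqdata import CodonAlignment


@dataclass
class MaxChiResult:
    pair: tuple[str, str]
    best_breakpoint_index: int  # split after this many polymorphic sites
    best_breakpoint_site: int  # 1-based alignment coordinate of the split
    chi2_max: float
    p: float
    n_polymorphic: int
    n_perm: int
    seed: int
    significant: bool


def _chi2_profile(mismatch: np.ndarray) -> np.ndarray:
    """Chi-square at every internal breakpoint of a 0/1 mismatch vector.

    Returns an array of length k-1 for k polymorphic sites; breakpoint b
    splits sites [0, b) from [b, k).
    """
    k = mismatch.size
    b = np.arange(1, k)
    left = np.cumsum(mismatch)[:-1].astype(float)  # mismatches left of split
    tot = float(mismatch.sum())
    right = tot - left
    nl, nr = b.astype(float), (k - b).astype(float)
    # 2x2: rows left/right, cols mismatch/match
    with np.errstate(divide="ignore", invalid="ignore"):
        p_all = tot / k
        e_l, e_r = nl * p_all, nr * p_all
        chi2 = (
            (left - e_l) ** 2 / e_l
            + (right - e_r) ** 2 / e_r
            + ((nl - left) - (nl - e_l)) ** 2 / (nl - e_l)
            + ((nr - right) - (nr - e_r)) ** 2 / (nr - e_r)
        )
    if tot == 0 or tot == k:
        return np.zeros(k - 1)
    return np.nan_to_num(chi2)


def maxchi_pair(
    mismatch: np.ndarray, n_perm: int, rng: np.random.Generator
) -> tuple[int, float, float]:
    """(best breakpoint, max chi2, permutation p) for one mismatch vector."""
    prof = _chi2_profile(mismatch)
    best = int(np.argmax(prof))
    obs = float(prof[best])
    k = mismatch.size
    perm = np.tile(mismatch, (n_perm, 1))
    perm = rng.permuted(perm, axis=1)
    # chi2 maxima of permuted vectors, vectorized over permutations
    b = np.arange(1, k, dtype=float)
    tot = float(mismatch.sum())
    p_all = tot / k
    nl, nr = b, k - b
    e_l, e_r = nl * p_all, nr * p_all
    left = np.cumsum(perm, axis=1)[:, :-1].astype(float)
    right = tot - left
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = (
            (left - e_l) ** 2 / e_l
            + (right - e_r) ** 2 / e_r
            + ((nl - left) - (nl - e_l)) ** 2 / (nl - e_l)
            + ((nr - right) - (nr - e_r)) ** 2 / (nr - e_r)
        )
    chi2 = np.nan_to_num(chi2)
    maxima = chi2.max(axis=1)
    p = (1.0 + float((maxima >= obs - 1e-9).sum())) / (n_perm + 1.0)
    return best + 1, obs, p


def maxchi(
    aln: CodonAlignment,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    min_polymorphic: int = 4,
    max_pairs: int | None = None,
) -> list[MaxChiResult]:
    """MaxChi over all sequence pairs; pairs with fewer than
    ``min_polymorphic`` informative sites are skipped."""
    names = [r.sample_id for r in aln.sequences]
    mask = aln.usable_sites()
    m = aln.matrix()[:, mask]
    site_coords = np.flatnonzero(mask) + 1
    rng = np.random.default_rng(seed)
    out: list[MaxChiResult] = []
    # mismatch vectors are laid over the sites polymorphic in the full
    # sample, so a pair can both match and mismatch along the sequence
    keep = np.flatnonzero((m != m[0]).any(axis=0))
    pairs = list(itertools.combinations(range(len(names)), 2))
    if max_pairs is not None:
        pairs = pairs[:max_pairs]
    for i, j in pairs:
        if keep.size < min_polymorphic:
            break
        mism = (m[i, keep] != m[j, keep]).astype(np.int8)
        if mism.sum() < 2 or (mism == 1).all():
            continue
        bp, chi2, p = maxchi_pair(mism, n_perm, rng)
        out.append(
            MaxChiResult(
                pair=(names[i], names[j]),
                best_breakpoint_index=bp,
                best_breakpoint_site=int(site_coords[keep[bp - 1]]),
                chi2_max=chi2,
                p=p,
                n_polymorphic=int(keep.size),
                n_perm=n_perm,
                seed=seed,
                significant=p < alpha,
            )
        )
    return out


def recombination_detected(results: list[MaxChiResult], alpha: float = 0.05) -> bool:
    """Gate used by the pipeline: any pair significant at the cutoff."""
    return any(r.p < alpha for r in results)
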