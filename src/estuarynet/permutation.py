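"""Permutation tests on distance matrices: MRPP, ANOSIM, PERMANOVA (adonis),
and simple/partial Mantel.

All five tests share the same machinery: a statistic computed on the observed
matrix, a null distribution built from seeded label (or row/column)
permutations, and the (1 + b) / (1 + n_perm) p-value estimator, so p is never
exactly zero. When the number of distinct sample permutations is at most
``n_perm`` the null is enumerated exhaustively instead of sampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations as _iter_permutations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .dissimilarity import DistanceMatrix
from .io_tables import ValidationError

__all__ = [
    "GroupTestResult",
    "MantelResult",
    "mrpp",
    "anosim",
    "adonis",
    "mantel",
    "partial_mantel",
]


@dataclass
class GroupTestResult:
    statistic_name: str
    statistic: float
    p_value: float
    n_perm: int
    seed: int
    extra: dict | None = None


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    seed: int
    partial: str | None = None


def _as_groups(d: DistanceMatrix, groups) -> np.ndarray:
    if isinstance(groups, pd.Series):
        groups = groups.loc[d.sample_ids]
    g = np.asarray(groups)
    if len(g) != len(d.sample_ids):
        raise ValidationError("group labels do not match distance matrix samples")
    labels, counts = np.unique(g, return_counts=True)
    if len(labels) < 2:
        raise ValidationError("need at least 2 groups")
    if (counts < 2).any():
        bad = labels[counts < 2][0]
        raise ValidationError(f"group {bad!r} has fewer than 2 samples")
    return g


def _permutation_indices(n: int, n_perm: int, rng: np.random.Generator):
    """Permutations of range(n): exhaustive if n! <= n_perm, else sampled.

    Returns (list of index arrays, exhaustive flag). The exhaustive list
    includes the identity, so the returned p-values are exact.
    """
    if math.factorial(n) <= n_perm:
        return [np.asarray(p) for p in _iter_permutations(range(n))], True
    return [rng.permutation(n) for _ in range(n_perm)], False


def _p_value(null: np.ndarray, observed: float, alternative: str,
             exhaustive: bool) -> float:
    if alternative == "greater":
        b = np.sum(null >= observed - 1e-12)
    elif alternative == "less":
        b = np.sum(null <= observed + 1e-12)
    else:  # two-sided on magnitude
        b = np.sum(np.abs(null) >= abs(observed) - 1e-12)
    if exhaustive:
        return float(b) / len(null)  # identity permutation is in the null set
    return (1.0 + float(b)) / (1.0 + len(null))


# ---------------------------------------------------------------------------
# group-difference tests


def _mrpp_delta(sq: np.ndarray, g: np.ndarray) -> float:
    n = len(g)
    delta = 0.0
    for label in np.unique(g):
        idx = np.flatnonzero(g == label)
        ni = len(idx)
        sub = sq[np.ix_(idx, idx)]
        xi = sub[np.triu_indices(ni, k=1)].mean()
        delta += ni / n * xi
    return delta


def mrpp(d: DistanceMatrix, groups, n_perm: int = 999,
         seed: int = 0) -> GroupTestResult:
    """Multi-response permutation procedure.

    delta = Σ (n_i/N)·(mean within-group distance); small delta means tight
    groups, so the p-value counts permuted deltas <= the observed one.
    A = 1 − delta / E[delta_perm] is the chance-corrected effect size.
    """
    g = _as_groups(d, groups)
    sq = d.values
    rng = np.random.default_rng(seed)
    observed = _mrpp_delta(sq, g)
    perms, exhaustive = _permutation_indices(len(g), n_perm, rng)
    null = np.asarray([_mrpp_delta(sq, g[p]) for p in perms])
    p = _p_value(null, observed, "less", exhaustive)
    # E[delta] under permutation is the overall mean pairwise distance
    # (each within-group pair is uniform over all pairs), so A is exact
    a = 1.0 - observed / d.condensed().mean()
    return GroupTestResult("delta", observed, p, len(perms), seed, {"A": a})


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    n_pairs = len(ranks)
    r_w = ranks[within].mean()
    r_b = ranks[~within].mean()
    # Clarke's denominator M/2 with M = n(n-1)/2 pairs, so perfect
    # separation (all between-ranks above all within-ranks) gives R = 1.
    n = int(round((1 + math.sqrt(1 + 8 * n_pairs)) / 2))
    return (r_b - r_w) / (n * (n - 1) / 4)


def _within_mask(g: np.ndarray) -> np.ndarray:
    same = g[:, None] == g[None, :]
    iu = np.triu_indices(len(g), k=1)
    return same[iu]


def anosim(d: DistanceMatrix, groups, n_perm: int = 999,
           seed: int = 0) -> GroupTestResult:
    """Analysis of similarity on average-ranked distances (Clarke's R)."""
    g = _as_groups(d, groups)
    ranks = rankdata(d.condensed())
    rng = np.random.default_rng(seed)
    observed = _anosim_r(ranks, _within_mask(g))
    perms, exhaustive = _permutation_indices(len(g), n_perm, rng)
    null = np.asarray([_anosim_r(ranks, _within_mask(g[p])) for p in perms])
    p = _p_value(null, observed, "greater", exhaustive)
    return GroupTestResult("R_anosim", observed, p, len(perms), seed)


def _adonis_f(sq2: np.ndarray, g: np.ndarray) -> tuple[float, float]:
    n = len(g)
    iu = np.triu_indices(n, k=1)
    ss_total = sq2[iu].sum() / n
    ss_within = 0.0
    labels = np.unique(g)
    for label in labels:
        idx = np.flatnonzero(g == label)
        sub = sq2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    n_groups = len(labels)
    f = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))
    return f, ss_between / ss_total


def adonis(d: DistanceMatrix, groups, n_perm: int = 999,
           seed: int = 0) -> GroupTestResult:
    """One-factor PERMANOVA (Anderson's pseudo-F from the distance matrix)."""
    g = _as_groups(d, groups)
    sq2 = d.values ** 2
    rng = np.random.default_rng(seed)
    observed, r2 = _adonis_f(sq2, g)
    perms, exhaustive = _permutation_indices(len(g), n_perm, rng)
    null = np.asarray([_adonis_f(sq2, g[p])[0] for p in perms])
    p = _p_value(null, observed, "greater", exhaustive)
    return GroupTestResult("pseudo_F", observed, p, len(perms), seed, {"R2": r2})


# ---------------------------------------------------------------------------
# matrix correlation


def _check_pair(da: DistanceMatrix, db: DistanceMatrix) -> None:
    if da.sample_ids != db.sample_ids:
        if set(da.sample_ids) != set(db.sample_ids):
            raise ValidationError("distance matrices cover different samples")
        raise ValidationError(
            "distance matrices have matching samples in different order; "
            "reorder() one of them first")


def _corr(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if method == "spearman":
        a, b = rankdata(a), rankdata(b)
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt((a @ a) * (b @ b))
    if denom == 0:
        raise ValidationError("constant distance vector; correlation undefined")
    return float(a @ b / denom)


def mantel(da: DistanceMatrix, db: DistanceMatrix, n_perm: int = 999,
           seed: int = 0, method: str = "pearson",
           alternative: str = "greater") -> MantelResult:
    """Mantel correlation between two distance matrices.

    r is the (Pearson by default) correlation of the two condensed
    off-diagonal vectors; the null permutes rows+columns of ``db`` jointly.
    """
    _check_pair(da, db)
    a = da.condensed()
    sq_b = db.values
    iu = np.triu_indices(len(da.sample_ids), k=1)
    rng = np.random.default_rng(seed)
    observed = _corr(a, sq_b[iu], method)
    perms, exhaustive = _permutation_indices(len(da.sample_ids), n_perm, rng)
    null = np.asarray([_corr(a, sq_b[np.ix_(p, p)][iu], method) for p in perms])
    p = _p_value(null, observed, alternative, exhaustive)
    return MantelResult(observed, p, len(perms), seed)


def _partial_r(r_ab: float, r_ac: float, r_bc: float) -> float:
    num = r_ab - r_ac * r_bc
    denom_sq = (1 - r_ac ** 2) * (1 - r_bc ** 2)
    if denom_sq < 1e-14:
        # b identical to c (or a to c): the 0/0 limit of full control is 0;
        # anything else is genuinely indeterminate
        if abs(num) < 1e-7:
            return 0.0
        raise ValidationError("control matrix is collinear with an input matrix")
    return num / math.sqrt(denom_sq)


def partial_mantel(da: DistanceMatrix, db: DistanceMatrix, dc: DistanceMatrix,
                   n_perm: int = 999, seed: int = 0, method: str = "pearson",
                   alternative: str = "greater") -> MantelResult:
    """Partial Mantel r_AB·C, permuting A while holding B and C fixed."""
    _check_pair(da, db)
    _check_pair(da, dc)
    iu = np.triu_indices(len(da.sample_ids), k=1)
    sq_a = da.values
    b = db.values[iu]
    c = dc.values[iu]
    r_bc = _corr(b, c, method)
    rng = np.random.default_rng(seed)

    def stat(perm_a: np.ndarray) -> float:
        return _partial_r(_corr(perm_a, b, method),
                          _corr(perm_a, c, method), r_bc)

    observed = stat(sq_a[iu])
    perms, exhaustive = _permutation_indices(len(da.sample_ids), n_perm, rng)
    null = np.asarray([stat(sq_a[np.ix_(p, p)][iu]) for p in perms])
    p = _p_value(null, observed, alternative, exhaustive)
    return MantelResult(observed, p, len(perms), seed,
                        partial=dc.metric_name or "control")
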