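"""Random-matrix-theory threshold selection for correlation networks.

The idea: as the similarity threshold rises, the nearest-neighbour spacing
distribution (NNSD) of the thresholded correlation matrix's unfolded spectrum
crosses from the Gaussian orthogonal ensemble law (Wigner surmise — level
repulsion, typical of noise-dominated matrices) to the Poisson law
(uncorrelated spacings, typical of modular/system-specific structure). The
chosen cutoff is the smallest threshold at which the NNSD is
Poisson-consistent, with a two-grid-point persistence rule to suppress
single-point flicker.

Unfolding — the monotone rescaling that gives the spectrum unit mean spacing —
uses a monotone piecewise-cubic (PCHIP) fit through a decimated empirical
spectral CDF (~n/15 knots), discarding 5% of the spectrum at each edge where
the fit is least reliable: parameter-light, and calibrated so both reference
laws are reproduced on simulated ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.stats import chi2 as chi2_dist

from .io_tables import ValidationError

__all__ = [
    "RmtScanError",
    "RmtScan",
    "nnsd",
    "poisson_spacing_cdf",
    "goe_spacing_cdf",
    "chi2_nnsd",
    "rmt_threshold_scan",
]

MIN_EIGENVALUES = 50


class RmtScanError(RuntimeError):
    """No Poisson-consistent threshold found; carries the scan table."""

    def __init__(self, message: str, scan_table: pd.DataFrame | None = None):
        super().__init__(message)
        self.scan_table = scan_table


def nnsd(eigenvalues, n_knots: int | None = None,
         edge_trim: float = 0.05) -> np.ndarray:
    """Unfolded nearest-neighbour spacings with mean exactly 1.

    Eigenvalues are sorted, the empirical spectral CDF is smoothed by a
    monotone cubic interpolant through ``n_knots`` decimated points (default
    ~n/15, at least 6), and each eigenvalue is mapped through it. A fraction
    ``edge_trim`` of the spectrum is dropped at each edge, where the density
    estimate is least reliable; spacings are the gaps of the remaining mapped
    sequence, renormalized to unit mean.
    """
    e = np.sort(np.asarray(eigenvalues, dtype=float))
    n = len(e)
    if n < MIN_EIGENVALUES:
        raise ValidationError(
            f"need at least {MIN_EIGENVALUES} eigenvalues for stable unfolding")
    if n_knots is None:
        n_knots = max(6, n // 15)
    idx = np.unique(np.linspace(0, n - 1, n_knots).round().astype(int))
    x = e[idx]
    y = (idx + 0.5) / n
    # degenerate eigenvalues collapse knots: keep the highest rank at each x
    x_u = np.unique(x)
    y_u = np.maximum.accumulate([y[x == xv].max() for xv in x_u])
    if len(x_u) < 2:
        raise ValidationError("spectrum is (numerically) a single point")
    cdf = PchipInterpolator(x_u, y_u, extrapolate=True)
    unfolded = n * np.asarray(cdf(e))
    k = int(n * edge_trim)
    if k:
        unfolded = unfolded[k:n - k]
    s = np.diff(unfolded)
    s = np.clip(s, 0.0, None)
    mean = s.mean()
    if mean == 0:
        raise ValidationError("all unfolded spacings are zero")
    return s / mean


def poisson_spacing_cdf(s: np.ndarray) -> np.ndarray:
    """CDF of the Poisson spacing law p(s) = exp(-s)."""
    return 1.0 - np.exp(-s)


def goe_spacing_cdf(s: np.ndarray) -> np.ndarray:
    """CDF of the Wigner surmise p(s) = (pi s / 2) exp(-pi s^2 / 4)."""
    return 1.0 - np.exp(-np.pi * s ** 2 / 4.0)


_LAWS = {"poisson": poisson_spacing_cdf, "goe": goe_spacing_cdf}


def chi2_nnsd(spacings, law: str = "poisson", bin_width: float = 0.1,
              s_max: float = 3.0, min_expected: float = 5.0
              ) -> tuple[float, int, float]:
    """Chi-square goodness of fit of observed spacings against a spacing law.

    Histogram bins of ``bin_width`` on [0, s_max] plus an open tail bin;
    adjacent bins are pooled until each expected count reaches
    ``min_expected`` (the textbook >= 5 rule by default — sparse-bin chi2
    otherwise inflates the type-I error); dof = n_bins - 1.
    Returns (chi2, dof, p).
    """
    s = np.asarray(spacings, dtype=float)
    if len(s) < 30:
        raise ValidationError("need at least 30 spacings for the chi-square test")
    if law not in _LAWS:
        raise ValueError(f"unknown law {law!r}")
    edges = np.arange(0.0, s_max + bin_width / 2, bin_width)
    observed = np.histogram(s, bins=np.append(edges, np.inf))[0].astype(float)
    cdf = _LAWS[law](np.append(edges, np.inf))
    expected = np.diff(cdf) * len(s)

    # pool sparse bins left-to-right; fold any undersized tail into the last bin
    obs_p, exp_p = [], []
    o_acc = e_acc = 0.0
    for o, ex in zip(observed, expected):
        o_acc += o
        e_acc += ex
        if e_acc >= min_expected:
            obs_p.append(o_acc)
            exp_p.append(e_acc)
            o_acc = e_acc = 0.0
    if e_acc > 0 or o_acc > 0:
        if obs_p:
            obs_p[-1] += o_acc
            exp_p[-1] += e_acc
        else:
            raise ValidationError("histogram is degenerate: no populated bins")
    obs_p = np.asarray(obs_p)
    exp_p = np.asarray(exp_p)
    if len(obs_p) < 2:
        raise ValidationError("too few populated bins for a chi-square test")
    stat = float(((obs_p - exp_p) ** 2 / exp_p).sum())
    dof = len(obs_p) - 1
    return stat, dof, float(chi2_dist.sf(stat, dof))


@dataclass
class RmtScan:
    """Per-threshold NNSD statistics and the selected cutoff."""

    table: pd.DataFrame  # index: threshold; cols: n_features, chi2/p per law
    chosen_cutoff: float
    p_threshold: float = 0.05
    unfolding: str = "pchip-decimated-cdf"


def _thresholded_spectrum(s_abs: np.ndarray, t: float) -> tuple[np.ndarray, int]:
    """Eigenvalues of the |r| matrix with sub-threshold entries zeroed.

    Features with no surviving off-diagonal similarity are removed first
    (their rows contribute only trivial unit eigenvalues).
    """
    m = np.where(s_abs >= t, s_abs, 0.0)
    np.fill_diagonal(m, 1.0)
    keep = (m - np.eye(len(m))).sum(axis=0) > 0
    m = m[np.ix_(keep, keep)]
    if len(m) == 0:
        return np.empty(0), 0
    return np.linalg.eigvalsh(m), int(keep.sum())


def rmt_threshold_scan(sim, t_min: float = 0.30, t_max: float = 0.99,
                       step: float = 0.01, p_threshold: float = 0.05,
                       min_dim: int = MIN_EIGENVALUES,
                       scan_all: bool = False) -> RmtScan:
    """Scan similarity thresholds for the GOE-to-Poisson NNSD transition.

    ``sim`` is a SimilarityMatrix (or a square ndarray of signed Pearson r).
    The cutoff is the smallest grid point whose NNSD is Poisson-consistent
    (p > ``p_threshold``) both there and at the next grid point. The scan
    stops early once the cutoff is confirmed unless ``scan_all`` is set.
    """
    r = sim if isinstance(sim, np.ndarray) else sim.r.to_numpy()
    s_abs = np.abs(np.asarray(r, dtype=float))
    if s_abs.shape[0] != s_abs.shape[1]:
        raise ValidationError("similarity matrix must be square")
    thresholds = np.round(np.arange(t_min, t_max + step / 2, step), 10)
    rows = []
    p_by_t: dict[float, float] = {}
    chosen = None
    for t in thresholds:
        eigs, n_kept = _thresholded_spectrum(s_abs, t)
        if n_kept < min_dim:
            rows.append({"threshold": t, "n_features": n_kept,
                         "chi2_poisson": np.nan, "p_poisson": np.nan,
                         "chi2_goe": np.nan, "p_goe": np.nan})
            break
        spacings = nnsd(eigs)
        c_p, _, p_p = chi2_nnsd(spacings, "poisson")
        c_g, _, p_g = chi2_nnsd(spacings, "goe")
        rows.append({"threshold": t, "n_features": n_kept,
                     "chi2_poisson": c_p, "p_poisson": p_p,
                     "chi2_goe": c_g, "p_goe": p_g})
        p_by_t[t] = p_p
        prev = np.round(t - step, 10)
        if chosen is None and prev in p_by_t:
            if p_by_t[prev] > p_threshold and p_p > p_threshold:
                chosen = float(prev)
                if not scan_all:
                    break
    table = pd.DataFrame(rows).set_index("threshold")
    if chosen is None:
        raise RmtScanError(
            "no Poisson-consistent threshold found in the scan range",
            scan_table=table)
    return RmtScan(table=table, chosen_cutoff=chosen, p_threshold=p_threshold)
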