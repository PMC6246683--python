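"""Feature–environment Pearson screens with BH-FDR control, and partial
correlations of keystone taxa with pollutants controlling single covariates.

Abundances are log10(relative abundance + 1e-6)-transformed before Pearson by
default; abundance data are heavy-tailed and correlation-network practice
works on log scale. The raw option is retained and the transform is recorded
on every output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_tables import AbundanceTable, EnvTable, ValidationError

__all__ = [
    "CorrelationRecord",
    "PartialCorrelationRecord",
    "transform_abundance",
    "correlation_screen",
    "bh_fdr",
    "partial_correlation",
    "keystone_partial_table",
    "significance_stars",
]

PSEUDO_COUNT = 1e-6


@dataclass
class CorrelationRecord:
    feature_id: str
    factor: str
    r: float
    p_raw: float
    p_adj: float
    significant: bool

    @property
    def sign(self) -> int:
        return 0 if np.isnan(self.r) else int(np.sign(self.r))


@dataclass
class PartialCorrelationRecord:
    feature_id: str
    pollutant: str
    control: str
    r_partial: float
    p_value: float


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "."
    return ""


def transform_abundance(tab: AbundanceTable, transform: str = "log10p"
                        ) -> pd.DataFrame:
    """Feature matrix ready for Pearson: log10(rel. abundance + 1e-6) or raw."""
    if transform == "log10p":
        return np.log10(tab.relative() + PSEUDO_COUNT)
    if transform == "raw":
        return tab.data.astype(float)
    raise ValueError(f"unknown transform {transform!r}")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def correlation_screen(tab: AbundanceTable, env: EnvTable, alpha: float = 0.05,
                       transform: str = "log10p") -> pd.DataFrame:
    """Pearson r for every (feature, factor) pair, BH-adjusted as one family.

    Zero-variance features yield NaN records that are excluded from the FDR
    family. Coordinate-role factors are not screened.
    """
    feats = transform_abundance(tab, transform)
    factors = env.factor_matrix(include_coordinates=False)
    feats = feats.loc[factors.index]
    x = feats.to_numpy()
    y = factors.to_numpy()
    n = x.shape[0]
    if n < 4:
        raise ValidationError("need at least 4 samples for the screen")
    xsd = x.std(axis=0, ddof=1)
    ysd = y.std(axis=0, ddof=1)
    xc = (x - x.mean(axis=0)) / np.where(xsd > 0, xsd, np.nan)
    yc = (y - y.mean(axis=0)) / np.where(ysd > 0, ysd, np.nan)
    r = xc.T @ yc / (n - 1)  # features × factors
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r ** 2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)

    rec = pd.DataFrame({
        "feature_id": np.repeat(feats.columns, len(factors.columns)),
        "factor": np.tile(factors.columns, len(feats.columns)),
        "r": r.ravel(),
        "p_raw": p.ravel(),
    })
    ok = rec["r"].notna()
    rec["p_adj"] = np.nan
    rec.loc[ok, "p_adj"] = bh_fdr(rec.loc[ok, "p_raw"].to_numpy())
    rec["significant"] = rec["p_adj"] < alpha
    rec.loc[~ok, "significant"] = False
    rec.attrs["transform"] = transform
    rec.attrs["alpha"] = alpha
    return rec


def partial_correlation(x, y, z) -> PartialCorrelationRecord:
    """First-order partial correlation r_xy·z with a t-test on n−3 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = len(x)
    if not (len(y) == len(z) == n):
        raise ValidationError("vectors must have equal length")
    if n < 4:
        raise ValidationError("partial correlation needs n >= 4")
    r_xy = stats.pearsonr(x, y).statistic
    r_xz = stats.pearsonr(x, z).statistic
    r_yz = stats.pearsonr(y, z).statistic
    if (1 - r_xz ** 2) < 1e-12 or (1 - r_yz ** 2) < 1e-12:
        raise ValidationError("control variable is collinear with an input")
    denom = np.sqrt((1 - r_xz ** 2) * (1 - r_yz ** 2))
    r_p = float(np.clip((r_xy - r_xz * r_yz) / denom, -1.0, 1.0))
    if np.isclose(abs(r_p), 1.0):
        p = 0.0
    else:
        t = r_p * np.sqrt((n - 3) / (1 - r_p ** 2))
        p = float(2 * stats.t.sf(abs(t), df=n - 3))
    return PartialCorrelationRecord("", "x", "z", r_p, p)


def keystone_partial_table(tab: AbundanceTable, env: EnvTable, keystone_ids,
                           pollutants=None, controls=None,
                           transform: str = "log10p") -> pd.DataFrame:
    """Keystone × pollutant × control grid of partial correlations.

    With no controls the grid reduces to plain Pearson r. Cells carry
    significance marks: '.' p<0.1, '*' p<0.05, '**' p<0.01, '***' p<0.001.
    """
    keystone_ids = list(keystone_ids)
    missing = [k for k in keystone_ids if k not in tab.data.columns]
    if missing:
        raise ValidationError(f"unknown keystone feature {missing[0]!r}")
    pollutants = list(pollutants) if pollutants is not None else env.pollutants
    controls = list(controls) if controls is not None else env.non_pollutants
    feats = transform_abundance(tab, transform).loc[env.sample_ids]

    rows = []
    for pol in pollutants:
        y = env.data[pol].to_numpy(dtype=float)
        if not controls:
            for k in keystone_ids:
                res = stats.pearsonr(feats[k].to_numpy(), y)
                rows.append({"pollutant": pol, "control": "(none)",
                             "feature_id": k, "r_partial": res.statistic,
                             "p_value": res.pvalue,
                             "stars": significance_stars(res.pvalue)})
            continue
        for ctl in controls:
            z = env.data[ctl].to_numpy(dtype=float)
            for k in keystone_ids:
                rec = partial_correlation(feats[k].to_numpy(), y, z)
                rows.append({"pollutant": pol, "control": ctl,
                             "feature_id": k, "r_partial": rec.r_partial,
                             "p_value": rec.p_value,
                             "stars": significance_stars(rec.p_value)})
    out = pd.DataFrame(rows)
    out.attrs["transform"] = transform
    return out
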