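"""Pairwise dissimilarity matrices: Bray-Curtis, Sørensen, UniFrac,
environmental Euclidean, great-circle, and single-factor distances.

Bray-Curtis works on relative abundances by default (library-size differences
are sequencing artifacts, not ecology); Sørensen is Bray-Curtis on
presence/absence. UniFrac delegates to scikit-bio; the weighted variant is
normalized so entries stay in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from scipy.spatial.distance import pdist, squareform
from skbio.diversity import beta_diversity

from .io_tables import AbundanceTable, EnvTable, ValidationError

__all__ = [
    "DistanceMatrix",
    "euclidean",
    "bray_curtis",
    "unifrac",
    "geographic_distance",
    "single_factor_distance",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class DistanceMatrix:
    """Symmetric, hollow, non-negative pairwise dissimilarities."""

    data: pd.DataFrame
    metric_name: str = ""

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if list(self.data.index) != list(self.data.columns):
            raise ValidationError("distance matrix row/column labels differ")
        if not np.allclose(vals, vals.T, atol=1e-10):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(vals), 0, atol=1e-10):
            raise ValidationError("distance matrix diagonal is not zero")
        if (vals < -1e-12).any():
            raise ValidationError("negative distances")
        np.fill_diagonal(vals, 0.0)
        self.data = pd.DataFrame((vals + vals.T) / 2,
                                 index=self.data.index, columns=self.data.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def condensed(self) -> np.ndarray:
        """Upper-triangle vector in scipy's condensed order."""
        return squareform(self.values, checks=False)

    def reorder(self, sample_ids) -> "DistanceMatrix":
        missing = set(sample_ids) - set(self.data.index)
        if missing:
            raise ValidationError(f"samples missing from matrix: {sorted(missing)}")
        return DistanceMatrix(self.data.loc[sample_ids, sample_ids],
                              self.metric_name)

    def to_skbio(self) -> skbio.DistanceMatrix:
        return skbio.DistanceMatrix(self.values, ids=self.sample_ids)


def _from_condensed(vec: np.ndarray, ids, name: str) -> DistanceMatrix:
    return DistanceMatrix(pd.DataFrame(squareform(vec), index=ids, columns=ids),
                          metric_name=name)


def euclidean(env: EnvTable, standardize: bool = True) -> DistanceMatrix:
    """Pairwise Euclidean distance over non-coordinate factors.

    With ``standardize`` each factor is z-scored first — the factors span
    incommensurate units (‰, mg/L, m), so this is the default.
    """
    mat = env.factor_matrix(include_coordinates=False)
    if mat.shape[0] < 2:
        raise ValidationError("need at least 2 samples")
    x = mat.to_numpy(dtype=float)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = mat.columns[np.argmax(sd == 0)]
            raise ValidationError(f"zero-variance factor {bad!r} cannot be z-scored")
        x = (x - x.mean(axis=0)) / sd
    name = "euclidean(z)" if standardize else "euclidean"
    return _from_condensed(pdist(x, metric="euclidean"), mat.index, name)


def bray_curtis(tab: AbundanceTable, binarize: bool = False,
                relative: bool = True) -> DistanceMatrix:
    """Bray-Curtis dissimilarity; ``binarize`` gives Sørensen."""
    x = tab.data.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValidationError("need at least 2 samples")
    if (x.sum(axis=1) == 0).any():
        bad = tab.data.index[x.sum(axis=1) == 0][0]
        raise ValidationError(f"sample {bad!r} is all zeros")
    if binarize:
        x = (x > 0).astype(float)
        name = "sorensen"
    else:
        if relative:
            x = x / x.sum(axis=1, keepdims=True)
        name = "bray_curtis"
    return _from_condensed(pdist(x, metric="braycurtis"), tab.data.index, name)


def unifrac(tab: AbundanceTable, tree: skbio.TreeNode,
            weighted: bool = False, normalized: bool = True) -> DistanceMatrix:
    """Phylogenetic beta diversity (scikit-bio unweighted/weighted UniFrac)."""
    leaves = {t.name for t in tree.tips()}
    present = tab.data.columns[(tab.data.to_numpy() > 0).any(axis=0)]
    missing = [f for f in present if f not in leaves]
    if missing:
        raise ValidationError(f"feature {missing[0]!r} is not a leaf of the tree")
    keep = [f for f in tab.data.columns if f in leaves]
    counts = tab.data[keep]
    metric = "weighted_unifrac" if weighted else "unweighted_unifrac"
    kwargs = {"normalized": normalized} if weighted else {}
    dm = beta_diversity(metric, counts.to_numpy(), ids=list(counts.index),
                        taxa=keep, tree=tree, validate=True, **kwargs)
    name = metric + ("_normalized" if weighted and normalized else "")
    return DistanceMatrix(dm.to_data_frame(), metric_name=name)


def geographic_distance(env: EnvTable) -> DistanceMatrix:
    """Great-circle (haversine) distance in km, Earth radius 6371 km."""
    for col in ("Latitude", "Longitude"):
        if col not in env.data:
            raise ValidationError(f"environment table lacks {col!r}")
    lat = np.radians(env.data["Latitude"].to_numpy(dtype=float))
    lon = np.radians(env.data["Longitude"].to_numpy(dtype=float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = (np.sin(dlat / 2) ** 2
         + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(pd.DataFrame(d, index=env.data.index,
                                       columns=env.data.index),
                          metric_name="haversine_km")


def single_factor_distance(env: EnvTable, factor: str) -> DistanceMatrix:
    """d(i, j) = |x_i − x_j| for one environmental factor."""
    if factor not in env.data:
        raise ValidationError(f"unknown factor {factor!r}")
    x = env.data[factor].to_numpy(dtype=float)
    d = np.abs(x[:, None] - x[None, :])
    return DistanceMatrix(pd.DataFrame(d, index=env.data.index,
                                       columns=env.data.index),
                          metric_name=f"factor:{factor}")
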