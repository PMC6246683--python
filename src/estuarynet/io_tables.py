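"""Tabular, tree and network I/O with strict validation.

All tables are tab-separated UTF-8 with ``.`` decimals and no quoting, the
dialect common to amplicon-table exports. Missing values are hard errors —
the downstream permutation tests assume complete 12-sample designs and silent
imputation would contaminate them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import skbio

__all__ = [
    "AbundanceTable",
    "EnvTable",
    "ValidationError",
    "read_abundance_table",
    "read_function_table",
    "read_env_table",
    "read_tree",
    "write_table",
    "export_network",
    "import_network",
    "write_manifest",
]

#: factors treated as seawater pollutants unless a role map says otherwise
DEFAULT_POLLUTANTS = ("W_Ammonia", "W_DIN", "W_TP")
#: factors that locate a sample rather than describe its chemistry
COORDINATE_FACTORS = ("Latitude", "Longitude")

VALID_ROLES = frozenset({"pollutant", "non_pollutant", "coordinate"})


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_unique(labels, kind: str) -> None:
    seen = pd.Index(labels)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()][0]
        raise ValidationError(f"duplicate {kind} ID: {dup!r}")


@dataclass
class AbundanceTable:
    """Sample × feature abundance matrix with optional feature metadata.

    ``data`` is oriented samples (rows) × features (columns). ``feature_meta``
    carries per-feature annotation: a taxonomy string for OTU tables, or the
    four-level functional category path (columns ``level1``..``level4``).
    """

    data: pd.DataFrame
    feature_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "feature")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise ValidationError("abundance table contains non-finite values")
        if values.size and (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative abundance at sample {self.data.index[i]!r}, "
                f"feature {self.data.columns[j]!r}"
            )
        if self.feature_meta is not None:
            missing = self.data.columns.difference(self.feature_meta.index)
            if len(missing):
                raise ValidationError(
                    f"feature_meta missing annotation for {missing[0]!r}"
                )
            self.feature_meta = self.feature_meta.loc[self.data.columns]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def relative(self) -> pd.DataFrame:
        """Row-normalized relative abundances."""
        totals = self.data.sum(axis=1)
        if (totals == 0).any():
            bad = totals.index[totals == 0][0]
            raise ValidationError(f"sample {bad!r} has zero total abundance")
        return self.data.div(totals, axis=0)

    def subset_features(self, keep) -> "AbundanceTable":
        keep = list(keep)
        meta = self.feature_meta.loc[keep] if self.feature_meta is not None else None
        return AbundanceTable(self.data[keep].copy(), meta)


@dataclass
class EnvTable:
    """Sample × environmental-factor matrix with factor roles and groups.

    ``roles`` maps every factor to ``pollutant`` / ``non_pollutant`` /
    ``coordinate``; ``groups`` holds the per-sample design label (e.g.
    inner/outer bay) used by the group-difference tests.
    """

    data: pd.DataFrame
    roles: dict[str, str] = field(default_factory=dict)
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "factor")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"missing/non-finite value for sample {self.data.index[i]!r}, "
                f"factor {self.data.columns[j]!r}"
            )
        for factor, role in self.roles.items():
            if role not in VALID_ROLES:
                raise ValidationError(f"unknown role {role!r} for factor {factor!r}")
        for factor in self.data.columns:
            if factor not in self.roles:
                if factor in COORDINATE_FACTORS:
                    self.roles[factor] = "coordinate"
                elif factor in DEFAULT_POLLUTANTS:
                    self.roles[factor] = "pollutant"
                else:
                    self.roles[factor] = "non_pollutant"
        if "Latitude" in self.data:
            lat = self.data["Latitude"]
            if ((lat < -90) | (lat > 90)).any():
                raise ValidationError("latitude outside [-90, 90]")
        if "Longitude" in self.data:
            lon = self.data["Longitude"]
            if ((lon < -180) | (lon > 180)).any():
                raise ValidationError("longitude outside [-180, 180]")
        if self.groups is not None:
            self.groups = self.groups.loc[self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def pollutants(self) -> list[str]:
        return [f for f, r in self.roles.items() if r == "pollutant"]

    @property
    def non_pollutants(self) -> list[str]:
        return [f for f, r in self.roles.items() if r == "non_pollutant"]

    def factor_matrix(self, include_coordinates: bool = False) -> pd.DataFrame:
        """Numeric factors, dropping coordinate columns unless requested."""
        if include_coordinates:
            return self.data
        keep = [f for f in self.data.columns if self.roles[f] != "coordinate"]
        return self.data[keep]


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    _check_unique(header, "column")  # pandas would silently mangle duplicates
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    _check_unique(df.index, "row")
    return df


def _to_numeric(df: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ValidationError(f"non-numeric cell at row {row!r}, column {col!r}")
        if converted.isna().any():
            row = df.index[converted.isna()][0]
            raise ValidationError(f"missing value at row {row!r}, column {col!r}")
        out[col] = converted
    return pd.DataFrame(out, index=df.index)


def read_abundance_table(path, orientation: str = "rows=samples") -> AbundanceTable:
    """Read a TSV count table; orientation is explicit, never guessed."""
    if orientation not in ("rows=samples", "rows=features"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _to_numeric(_read_tsv(path))
    if orientation == "rows=features":
        df = df.T
    return AbundanceTable(df)


def read_function_table(path) -> AbundanceTable:
    """Read a functional table whose first columns are level1..level4 paths."""
    raw = _read_tsv(path)
    levels = [c for c in raw.columns if c.lower().startswith("level")]
    if len(levels) != 4:
        raise ValidationError(
            f"function table needs columns level1..level4, found {levels}"
        )
    meta = raw[levels].rename(columns=str.lower)
    counts = _to_numeric(raw.drop(columns=levels)).T  # samples × features
    return AbundanceTable(counts, feature_meta=meta)


def read_env_table(path, roles: dict[str, str] | None = None,
                   group_col: str = "Group") -> EnvTable:
    """Read a TSV environment table; ``roles`` overrides the default tagging."""
    raw = _read_tsv(path)
    groups = None
    if group_col in raw.columns:
        groups = raw[group_col].astype(str)
        raw = raw.drop(columns=[group_col])
    data = _to_numeric(raw)
    return EnvTable(data, roles=dict(roles or {}), groups=groups)


def read_tree(path) -> skbio.TreeNode:
    """Read a rooted Newick tree with non-negative branch lengths."""
    tree = skbio.TreeNode.read(str(path), format="newick")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise ValidationError(f"negative branch length on {node.name!r}")
    return tree


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t")
    return path


def export_network(net: nx.Graph, path, fmt: str = "graphml") -> Path:
    """Write a network as GraphML or a 3-column signed edge list."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "graphml":
        nx.write_graphml(net, path)
    elif fmt == "edgelist":
        rows = [
            {"source": u, "target": v,
             "signed_r": d.get("sign", 1) * d.get("weight", 1.0)}
            for u, v, d in net.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "signed_r"]).to_csv(
            path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {fmt!r}")
    return path


def import_network(path) -> nx.Graph:
    return nx.read_graphml(str(path))


def write_manifest(run_dir, params: dict) -> Path:
    """Record parameters plus a checksum for every file under ``run_dir``."""
    run_dir = Path(run_dir)
    checksums = {}
    for f in sorted(run_dir.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            checksums[str(f.relative_to(run_dir))] = hashlib.sha256(
                f.read_bytes()).hexdigest()
    manifest = {"parameters": params, "checksums": checksums}
    out = run_dir / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return out
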