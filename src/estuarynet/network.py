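"""Co-occurrence network construction and analysis.

Edges connect feature pairs whose |Pearson r| meets the RMT-selected cutoff
(signs are kept as an edge attribute); modules come from fast-greedy
(Clauset–Newman–Moore) modularity optimization on the unweighted graph; each
module is summarized by its eigengene (first sample-side singular vector of
the standardized member submatrix); node roles follow the Guimerà–Amaral
Zi/Pi scheme (module hub Zi > 2.5, connector Pi > 0.62); keystones are the
hubs, connectors, and top-degree nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .association import transform_abundance
from .io_tables import AbundanceTable, EnvTable, ValidationError

__all__ = [
    "SimilarityMatrix",
    "EigengeneProfile",
    "prevalence_filter",
    "similarity_matrix",
    "build_network",
    "topological_indices",
    "random_network_null",
    "detect_modules",
    "module_eigengene",
    "eigengene_env_correlation",
    "zi_pi",
    "keystones",
]

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


@dataclass
class SimilarityMatrix:
    """Signed pairwise Pearson correlations between features."""

    r: pd.DataFrame
    transform: str = "log10p"

    @property
    def feature_ids(self) -> list[str]:
        return list(self.r.index)

    @property
    def s(self) -> pd.DataFrame:
        """|r|, the similarity actually thresholded."""
        return self.r.abs()


@dataclass
class EigengeneProfile:
    module_id: int
    eigengene: pd.Series  # unit-norm, one value per sample
    variance_explained: float
    env_correlations: dict = field(default_factory=dict)


def prevalence_filter(tab: AbundanceTable, min_present: int = 8) -> AbundanceTable:
    """Keep features detected (count > 0) in at least ``min_present`` samples."""
    if min_present > len(tab.sample_ids):
        raise ValidationError("min_present exceeds the number of samples")
    present = (tab.data > 0).sum(axis=0)
    keep = tab.data.columns[present >= min_present]
    if len(keep) == 0:
        raise ValidationError("prevalence filter removed every feature")
    return tab.subset_features(keep)


def similarity_matrix(tab: AbundanceTable, transform: str = "log10p"
                      ) -> SimilarityMatrix:
    """Pairwise Pearson r between (transformed) feature profiles."""
    if len(tab.sample_ids) < 3:
        raise ValidationError("need at least 3 samples to correlate features")
    x = transform_abundance(tab, transform).to_numpy()
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = tab.data.columns[np.argmax(sd == 0)]
        raise ValidationError(
            f"feature {bad!r} has zero variance; apply a prevalence filter first")
    xc = (x - x.mean(axis=0)) / sd
    r = xc.T @ xc / (x.shape[0] - 1)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    df = pd.DataFrame(r, index=tab.data.columns, columns=tab.data.columns)
    return SimilarityMatrix(r=df, transform=transform)


def build_network(sim: SimilarityMatrix, cutoff: float) -> nx.Graph:
    """Edges where |r| >= cutoff; isolated nodes dropped; signs preserved."""
    if not 0 < cutoff < 1:
        raise ValidationError("cutoff must lie in (0, 1)")
    r = sim.r.to_numpy()
    ids = sim.feature_ids
    iu, ju = np.where(np.triu(np.abs(r) >= cutoff, k=1))
    if len(iu) == 0:
        raise ValidationError(f"no edges survive the cutoff {cutoff}")
    g = nx.Graph(cutoff=float(cutoff))
    for i, j in zip(iu, ju):
        g.add_edge(ids[i], ids[j],
                   weight=float(abs(r[i, j])), sign=int(np.sign(r[i, j])))
    return g


def topological_indices(net: nx.Graph) -> dict[str, float]:
    """Average degree / clustering / path length and a scale-free proxy.

    The path length is computed on the largest connected component; the
    scale-free proxy is the R^2 of a log-log linear fit to the degree
    distribution (single-degree networks report NaN).
    """
    if net.number_of_edges() < 1:
        raise ValidationError("network has no edges")
    degrees = np.array([d for _, d in net.degree()])
    giant = net.subgraph(max(nx.connected_components(net), key=len))
    ks, counts = np.unique(degrees, return_counts=True)
    if len(ks) >= 2:
        fit = stats.linregress(np.log10(ks), np.log10(counts))
        r2 = float(fit.rvalue ** 2)
    else:
        r2 = float("nan")
    return {
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "avg_degree": float(degrees.mean()),
        "avg_clustering": float(nx.average_clustering(net)),
        "avg_path_length": float(nx.average_shortest_path_length(giant))
        if giant.number_of_nodes() > 1 else 0.0,
        "power_law_r2": r2,
    }


def detect_modules(net: nx.Graph) -> tuple[dict[str, int], float]:
    """Fast-greedy (CNM) modularity maximization on the unweighted graph.

    Returns a node -> module-ID map (IDs contiguous from 1, largest module
    first) and the modularity Q of the partition.
    """
    communities = list(nx.community.greedy_modularity_communities(net, weight=None))
    communities.sort(key=lambda c: (-len(c), sorted(c)[0]))
    module_of = {node: mid for mid, comm in enumerate(communities, start=1)
                 for node in comm}
    q = nx.community.modularity(net, communities, weight=None)
    return module_of, float(q)


def random_network_null(net: nx.Graph, n_random: int = 100,
                        seed: int = 0) -> pd.DataFrame:
    """Degree-preserving (Maslov–Sneppen) null distribution of the indices.

    Each null network applies 10×|E| accepted double-edge swaps; the observed
    index is reported with the null mean, sd and z-score.
    """
    if n_random < 2:
        raise ValidationError("need at least 2 random networks")
    n_edges = net.number_of_edges()
    if n_edges < 2 or net.number_of_nodes() < 4:
        raise ValidationError("graph too small to rewire")
    observed = topological_indices(net)
    _, observed["modularity_q"] = detect_modules(net)
    rows = []
    for k in range(n_random):
        g = nx.Graph(net.edges())
        nx.double_edge_swap(g, nswap=10 * n_edges, max_tries=1000 * n_edges,
                            seed=int(seed) + k)
        idx = topological_indices(g)
        _, idx["modularity_q"] = detect_modules(g)
        rows.append(idx)
    null = pd.DataFrame(rows)
    out = pd.DataFrame({
        "observed": pd.Series(observed),
        "null_mean": null.mean(),
        "null_sd": null.std(ddof=1),
    })
    out["z"] = (out["observed"] - out["null_mean"]) / out["null_sd"]
    return out


def module_eigengene(tab: AbundanceTable, module_of: dict[str, int],
                     min_size: int = 6, transform: str = "log10p"
                     ) -> list[EigengeneProfile]:
    """First sample-side singular vector of each module's standardized block.

    Modules below ``min_size`` members are skipped (mirrors reporting only
    modules with more than 5 nodes). The eigengene sign is fixed so the mean
    correlation with member profiles is non-negative; variance_explained is
    sigma_1^2 / sum(sigma^2).
    """
    x = transform_abundance(tab, transform)
    sd = x.std(axis=0, ddof=1)
    z = (x - x.mean(axis=0)) / sd.replace(0, np.nan)
    profiles = []
    for mid in sorted(set(module_of.values())):
        members = [f for f, m in module_of.items() if m == mid and f in z.columns]
        if len(members) < min_size:
            continue
        block = z[members].to_numpy()
        u, s, _ = np.linalg.svd(block, full_matrices=False)
        eig = u[:, 0]
        member_corr = np.array([stats.pearsonr(eig, block[:, j]).statistic
                                for j in range(block.shape[1])])
        if member_corr.mean() < 0:
            eig = -eig
        profiles.append(EigengeneProfile(
            module_id=mid,
            eigengene=pd.Series(eig, index=x.index, name=f"module_{mid}"),
            variance_explained=float(s[0] ** 2 / (s ** 2).sum()),
        ))
    return profiles


def eigengene_env_correlation(profiles: list[EigengeneProfile], env: EnvTable
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r (and p) of every module eigengene with every factor.

    Module rows are ordered by hierarchical clustering of their correlation
    profiles, matching the usual eigengene-heatmap display.
    """
    factors = env.factor_matrix(include_coordinates=False)
    r = pd.DataFrame(index=[p.module_id for p in profiles],
                     columns=factors.columns, dtype=float)
    p = r.copy()
    for prof in profiles:
        eig = prof.eigengene.loc[factors.index].to_numpy()
        for fac in factors.columns:
            res = stats.pearsonr(eig, factors[fac].to_numpy(dtype=float))
            r.loc[prof.module_id, fac] = res.statistic
            p.loc[prof.module_id, fac] = res.pvalue
        prof.env_correlations = {
            fac: (float(r.loc[prof.module_id, fac]),
                  float(p.loc[prof.module_id, fac]))
            for fac in factors.columns}
    if len(profiles) > 2:
        order = hierarchy.leaves_list(hierarchy.linkage(r.to_numpy(), "average"))
        r, p = r.iloc[order], p.iloc[order]
    return r, p


def zi_pi(net: nx.Graph, module_of: dict[str, int]) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    Zi is computed against the node's own module (0 where the module's
    within-degree spread is 0); Pi = 1 − Σ_s (k_is / k_i)^2 over modules s.
    Roles: module_hub (Zi > 2.5), connector (Pi > 0.62), network_hub (both),
    else peripheral.
    """
    missing = [n for n in net.nodes if n not in module_of]
    if missing:
        raise ValidationError(f"node {missing[0]!r} has no module assignment")
    within_degree = {}
    per_module_degree = {}
    for node in net.nodes:
        k = net.degree(node)
        if k == 0:
            raise ValidationError(f"isolated node {node!r} in network")
        counts: dict[int, int] = {}
        for nbr in net.neighbors(node):
            counts[module_of[nbr]] = counts.get(module_of[nbr], 0) + 1
        per_module_degree[node] = counts
        within_degree[node] = counts.get(module_of[node], 0)

    stats_by_module = {}
    for mid in set(module_of.values()):
        vals = np.array([within_degree[n] for n in net.nodes
                         if module_of[n] == mid])
        stats_by_module[mid] = (vals.mean(), vals.std(ddof=0)) if len(vals) else (0, 0)

    rows = []
    for node in net.nodes:
        k = net.degree(node)
        mean_w, sd_w = stats_by_module[module_of[node]]
        zi = (within_degree[node] - mean_w) / sd_w if sd_w > 0 else 0.0
        pi = 1.0 - sum((c / k) ** 2 for c in per_module_degree[node].values())
        if zi > ZI_THRESHOLD and pi > PI_THRESHOLD:
            role = "network_hub"
        elif zi > ZI_THRESHOLD:
            role = "module_hub"
        elif pi > PI_THRESHOLD:
            role = "connector"
        else:
            role = "peripheral"
        rows.append({"node": node, "module": module_of[node], "degree": k,
                     "Zi": zi, "Pi": pi, "role": role})
    return pd.DataFrame(rows).set_index("node")


def keystones(net: nx.Graph, topology: pd.DataFrame, top_k: int = 10
              ) -> list[str]:
    """Union of module hubs, connectors, network hubs and top-degree nodes.

    The degree cut includes every node tied with the k-th ranked degree;
    the returned list is sorted by (degree desc, node ID) for determinism.
    """
    if top_k < 1:
        raise ValidationError("top_k must be >= 1")
    special = set(topology.index[topology["role"] != "peripheral"])
    deg = topology["degree"].sort_values(ascending=False)
    if len(deg) > top_k:
        kth = deg.iloc[top_k - 1]
        top = set(deg.index[deg >= kth])
    else:
        top = set(deg.index)
    result = special | top
    return sorted(result, key=lambda n: (-topology.loc[n, "degree"], n))
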