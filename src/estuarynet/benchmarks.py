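"""Self-validation benchmarks: calibration, law discrimination and
planted-structure recovery on ground-truthed synthetic data.

These routines define the quantitative checks the package holds itself to:
type-I calibration of every permutation test under an all-effects-zero
transect, NNSD discrimination of the Poisson and GOE laws on reference
ensembles, and recovery of planted modules / the pollutant-driven eigengene
by the full RMT network pipeline. The test suite and the acceptance script
both run them.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
from scipy import stats as sp_stats
from sklearn.metrics import adjusted_rand_score

from . import dissimilarity, network, permutation, rmt
from .synthetic import (GuildSpec, ScenarioConfig, generate_community,
                        generate_env)

__all__ = [
    "null_rejection_rates",
    "binomial_ci",
    "nnsd_law_fit_rates",
    "planted_network_recovery",
    "closed_form_graph_checks",
]


def binomial_ci(alpha: float, n: int, level: float = 0.95
                ) -> tuple[float, float]:
    """Normal-approximation binomial CI for a rejection-rate estimate."""
    z = sp_stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(alpha * (1 - alpha) / n)
    return alpha - half, alpha + half


def null_rejection_rates(n_rep: int = 1000, alpha: float = 0.05,
                         n_perm: int = 99, seed: int = 0) -> dict[str, float]:
    """Type-I rates of MRPP/ANOSIM/adonis/Mantel on all-effects-zero data.

    Each replicate draws a fresh null transect (two neutral 10-OTU guilds,
    no environmental response), computes Bray-Curtis distances, and tests
    inner vs outer groups (Mantel: community vs environment distances).
    """
    hits = {k: 0 for k in ("mrpp", "anosim", "adonis", "mantel")}
    for rep in range(n_rep):
        cfg = ScenarioConfig(n_otus=40, guilds=(GuildSpec(10), GuildSpec(10)),
                            seed=seed + rep)
        env = generate_env(cfg)
        tab, _ = generate_community(cfg, env)
        d = dissimilarity.bray_curtis(tab)
        g = env.groups
        perm_seed = seed * 7919 + rep
        hits["mrpp"] += permutation.mrpp(
            d, g, n_perm=n_perm, seed=perm_seed).p_value <= alpha
        hits["anosim"] += permutation.anosim(
            d, g, n_perm=n_perm, seed=perm_seed).p_value <= alpha
        hits["adonis"] += permutation.adonis(
            d, g, n_perm=n_perm, seed=perm_seed).p_value <= alpha
        hits["mantel"] += permutation.mantel(
            d, dissimilarity.euclidean(env), n_perm=n_perm,
            seed=perm_seed).p_value <= alpha
    return {k: v / n_rep for k, v in hits.items()}


def nnsd_law_fit_rates(n_rep: int = 100, dim: int = 500,
                       seed: int = 0) -> dict[str, float]:
    """How often the NNSD machinery identifies each reference ensemble.

    GOE matrices should fit the Wigner surmise and reject the Poisson law;
    iid ("picket-fence-free") spectra should fit Poisson and reject GOE.
    """
    rng = np.random.default_rng(seed)
    wigner_fit = poisson_rejected_on_goe = 0
    poisson_fit = goe_rejected_on_iid = 0
    for _ in range(n_rep):
        x = rng.standard_normal((dim, dim))
        eigs = np.linalg.eigvalsh((x + x.T) / np.sqrt(2))
        s = rmt.nnsd(eigs)
        wigner_fit += rmt.chi2_nnsd(s, "goe")[2] > 0.05
        poisson_rejected_on_goe += rmt.chi2_nnsd(s, "poisson")[2] < 0.05
    for _ in range(n_rep):
        s = rmt.nnsd(np.sort(rng.uniform(0.0, 1.0, dim)))
        poisson_fit += rmt.chi2_nnsd(s, "poisson")[2] > 0.05
        goe_rejected_on_iid += rmt.chi2_nnsd(s, "goe")[2] < 0.05
    return {"goe_wigner_fit": wigner_fit / n_rep,
            "goe_poisson_rejected": poisson_rejected_on_goe / n_rep,
            "iid_poisson_fit": poisson_fit / n_rep,
            "iid_goe_rejected": goe_rejected_on_iid / n_rep}


def planted_network_recovery(n_seeds: int = 20, seed: int = 0) -> dict:
    """Full pipeline on the default planted scenario, scored against truth.

    For each seed: prevalence filter, Pearson similarity, RMT threshold scan,
    network, fast-greedy modules. Reports the median adjusted Rand index of
    recovered vs planted modules (over guild-member nodes), the median |r|
    between the pollutant guild's module eigengene and the planted driver
    (W_DIN), and the median chosen cutoff.
    """
    aris, eig_rs, cutoffs = [], [], []
    for k in range(n_seeds):
        cfg = ScenarioConfig(seed=seed + k)
        env = generate_env(cfg)
        tab, truth = generate_community(cfg, env)
        filt = network.prevalence_filter(tab, 8)
        sim = network.similarity_matrix(filt)
        scan = rmt.rmt_threshold_scan(sim)
        net = network.build_network(sim, scan.chosen_cutoff)
        module_of, _ = network.detect_modules(net)
        labeled = [n for n in net.nodes if truth.guild_of.get(n) is not None]
        aris.append(adjusted_rand_score(
            [truth.guild_of[n] for n in labeled],
            [module_of[n] for n in labeled]))
        cutoffs.append(scan.chosen_cutoff)
        profiles = network.module_eigengene(filt, module_of)
        pollutant_guild = set(truth.module_partition[1])
        best = max(profiles, key=lambda p: len(
            pollutant_guild
            & {n for n, m in module_of.items() if m == p.module_id}))
        driver = env.data["W_DIN"].loc[best.eigengene.index]
        eig_rs.append(abs(sp_stats.pearsonr(
            best.eigengene, driver).statistic))
    return {"median_ari": float(np.median(aris)),
            "median_eigengene_driver_r": float(np.median(eig_rs)),
            "median_cutoff": float(np.median(cutoffs)),
            "aris": aris, "eigengene_rs": eig_rs}


def closed_form_graph_checks() -> dict[str, float]:
    """Graph quantities with known closed-form values.

    Two disconnected 5-cliques: Q = 0.5 over 2 modules; K5: clustering 1,
    path length 1; P4: mean path 10/6; a balanced two-module bridge node:
    Pi = 0.5.
    """
    cliques = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
    module_of, q = network.detect_modules(cliques)
    k5 = network.topological_indices(nx.complete_graph(5))
    p4 = network.topological_indices(nx.path_graph(4))
    bridge = nx.Graph([("b", "a"), ("b", "x"), ("a", "a2"), ("x", "x2")])
    topo = network.zi_pi(bridge, {"a": 1, "a2": 1, "x": 2, "x2": 2, "b": 1})
    return {"two_clique_modularity_q": q,
            "two_clique_n_modules": float(len(set(module_of.values()))),
            "k5_avg_clustering": k5["avg_clustering"],
            "k5_avg_path_length": k5["avg_path_length"],
            "p4_avg_path_length": p4["avg_path_length"],
            "bridge_node_pi": float(topo.loc["b", "Pi"])}
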