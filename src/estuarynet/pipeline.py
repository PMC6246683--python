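"""Config-driven orchestration of the full analysis sequence.

Stage order mirrors the study design: dissimilarities → group-difference
tests → Mantel / partial-Mantel screens → feature–environment correlations →
RMT network (modules, eigengenes, Zi/Pi, keystones) → functional categories.
Every output lands under one run directory with a manifest of parameters and
file checksums.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import association, dissimilarity, functional, network, permutation, rmt
from .io_tables import (AbundanceTable, EnvTable, export_network,
                        read_abundance_table, read_env_table,
                        read_function_table, read_tree, write_manifest,
                        write_table)
from .synthetic import ScenarioConfig, generate_scenario

log = logging.getLogger("estuarynet")

__all__ = ["RunConfig", "run_pipeline", "geographic_mantel_table"]


@dataclass
class RunConfig:
    # inputs: file paths, or a synthetic scenario when scenario is set
    otu_path: str | None = None
    env_path: str | None = None
    func_path: str | None = None
    tree_path: str | None = None
    scenario: ScenarioConfig | None = None
    # stage toggles
    run_dissimilarity: bool = True
    run_group_tests: bool = True
    run_mantel: bool = True
    run_screen: bool = True
    run_network: bool = True
    run_functional: bool = True
    # parameters
    n_perm: int = 999
    alpha: float = 0.05
    transform: str = "log10p"
    min_present: int = 8
    scan_grid: tuple[float, float, float] = (0.30, 0.99, 0.01)
    n_random_networks: int = 100
    normalization_target: float = functional.DEFAULT_NORMALIZATION_TARGET
    selected_categories: tuple[str, ...] = functional.SELECTED_CATEGORIES
    seed: int = 0

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        if self.scenario is not None:
            d["scenario"] = dict(self.scenario.__dict__)
        return d


def geographic_mantel_table(env: EnvTable, n_perm: int = 999,
                            seed: int = 0) -> pd.DataFrame:
    """Mantel r of environmental distances against great-circle distance.

    First row: standardized Euclidean distance over all non-coordinate
    factors vs geographic distance; then one row per factor using the
    |x_i − x_j| single-factor distance.
    """
    d_geo = dissimilarity.geographic_distance(env)
    rows = []
    res = permutation.mantel(dissimilarity.euclidean(env, standardize=True),
                             d_geo, n_perm=n_perm, seed=seed)
    rows.append({"factor": "all_factors", "r": res.r, "p": res.p_value})
    for factor in env.factor_matrix(include_coordinates=False).columns:
        d_f = dissimilarity.single_factor_distance(env, factor)
        res = permutation.mantel(d_f, d_geo, n_perm=n_perm, seed=seed)
        rows.append({"factor": factor, "r": res.r, "p": res.p_value})
    return pd.DataFrame(rows).set_index("factor")


def _load_inputs(config: RunConfig):
    if config.scenario is not None:
        return generate_scenario(config.scenario)
    if config.otu_path is None or config.env_path is None:
        raise ValueError("provide otu/env paths or a synthetic scenario")
    otus = read_abundance_table(config.otu_path)
    env = read_env_table(config.env_path)
    func = read_function_table(config.func_path) if config.func_path else None
    tree = read_tree(config.tree_path) if config.tree_path else None
    return env, otus, func, tree, None


def _group_test_row(dist, groups, n_perm, seed):
    r_m = permutation.mrpp(dist, groups, n_perm=n_perm, seed=seed)
    r_a = permutation.anosim(dist, groups, n_perm=n_perm, seed=seed)
    r_f = permutation.adonis(dist, groups, n_perm=n_perm, seed=seed)
    return {
        "metric": dist.metric_name,
        "mrpp_delta": r_m.statistic, "mrpp_p": r_m.p_value,
        "anosim_R": r_a.statistic, "anosim_p": r_a.p_value,
        "adonis_F": r_f.statistic, "adonis_p": r_f.p_value,
        "adonis_R2": r_f.extra["R2"],
    }


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run all enabled stages; returns the in-memory result bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    env, otus, func, tree, truth = _load_inputs(config)
    groups = env.groups
    results: dict = {"env": env, "otus": otus, "truth": truth}
    stage = "inputs"
    try:
        distances: dict[str, dissimilarity.DistanceMatrix] = {}
        if config.run_dissimilarity:
            stage = "dissimilarity"
            distances["env_euclidean"] = dissimilarity.euclidean(env)
            distances["bray_curtis"] = dissimilarity.bray_curtis(otus)
            distances["sorensen"] = dissimilarity.bray_curtis(otus, binarize=True)
            distances["geographic"] = dissimilarity.geographic_distance(env)
            if tree is not None:
                distances["unweighted_unifrac"] = dissimilarity.unifrac(
                    otus, tree, weighted=False)
                distances["weighted_unifrac"] = dissimilarity.unifrac(
                    otus, tree, weighted=True)
            for name, dm in distances.items():
                write_table(dm.data, out / f"dist_{name}.tsv")
            results["distances"] = distances
            log.info("dissimilarity: %d matrices [%.1fs]",
                     len(distances), time.time() - t0)

        if config.run_group_tests and groups is not None and distances:
            stage = "group_tests"
            rows = [_group_test_row(dm, groups, config.n_perm, config.seed)
                    for dm in distances.values() if dm.metric_name != "haversine_km"]
            table1 = pd.DataFrame(rows).set_index("metric")
            write_table(table1, out / "group_tests.tsv")
            results["group_tests"] = table1

        if config.run_mantel and distances:
            stage = "mantel"
            geo = distances["geographic"]
            results["geo_mantel"] = geographic_mantel_table(
                env, n_perm=config.n_perm, seed=config.seed)
            write_table(results["geo_mantel"], out / "mantel_geography.tsv")
            community = {k: v for k, v in distances.items()
                         if k not in ("env_euclidean", "geographic")}
            rows = []
            factors = env.factor_matrix(include_coordinates=False).columns
            for factor in factors:
                d_f = dissimilarity.single_factor_distance(env, factor)
                row = {"factor": factor}
                for name, dm in community.items():
                    res = permutation.partial_mantel(
                        dm, d_f, geo, n_perm=config.n_perm, seed=config.seed)
                    row[f"{name}_r"] = res.r
                    row[f"{name}_p"] = res.p_value
                rows.append(row)
            results["partial_mantel"] = pd.DataFrame(rows).set_index("factor")
            write_table(results["partial_mantel"], out / "partial_mantel.tsv")
            log.info("mantel grids done [%.1fs]", time.time() - t0)

        if config.run_screen:
            stage = "screen"
            screen = association.correlation_screen(
                otus, env, alpha=config.alpha, transform=config.transform)
            screen.to_csv(out / "correlation_screen.tsv", sep="\t", index=False)
            results["screen"] = screen

        if config.run_network:
            stage = "network"
            filtered = network.prevalence_filter(otus, config.min_present)
            sim = network.similarity_matrix(filtered, config.transform)
            scan = rmt.rmt_threshold_scan(sim, *config.scan_grid)
            write_table(scan.table, out / "rmt_scan.tsv")
            net = network.build_network(sim, scan.chosen_cutoff)
            module_of, q = network.detect_modules(net)
            topo = network.zi_pi(net, module_of)
            keys = network.keystones(net, topo)
            profiles = network.module_eigengene(
                filtered, module_of, transform=config.transform)
            eig_r, eig_p = network.eigengene_env_correlation(profiles, env)
            null = network.random_network_null(
                net, n_random=config.n_random_networks, seed=config.seed)
            nx_attrs = {n: {"module": module_of[n],
                            "degree": int(topo.loc[n, "degree"]),
                            "Zi": float(topo.loc[n, "Zi"]),
                            "Pi": float(topo.loc[n, "Pi"]),
                            "role": topo.loc[n, "role"],
                            "keystone": n in set(keys)} for n in net.nodes}
            import networkx as nx

            nx.set_node_attributes(net, nx_attrs)
            export_network(net, out / "network.graphml")
            export_network(net, out / "network_edges.tsv", fmt="edgelist")
            write_table(topo, out / "zi_pi.tsv")
            write_table(null, out / "random_network_null.tsv")
            write_table(eig_r, out / "eigengene_env_r.tsv")
            write_table(eig_p, out / "eigengene_env_p.tsv")
            pd.Series(module_of, name="module").rename_axis("node").to_frame(
            ).to_csv(out / "modules.tsv", sep="\t")
            pd.Series(keys, name="keystone").to_csv(
                out / "keystones.tsv", sep="\t", index=False)
            partial_grid = association.keystone_partial_table(
                otus, env, keys, transform=config.transform)
            partial_grid.to_csv(out / "keystone_partial_correlations.tsv",
                                sep="\t", index=False)
            results.update(network_graph=net, modules=module_of, modularity=q,
                           cutoff=scan.chosen_cutoff, scan=scan, topology=topo,
                           keystones=keys, eigengenes=profiles,
                           eigengene_env_r=eig_r, eigengene_env_p=eig_p,
                           network_null=null, keystone_partial=partial_grid)
            log.info("network: cutoff=%.2f, %d modules, Q=%.3f [%.1fs]",
                     scan.chosen_cutoff, len(set(module_of.values())), q,
                     time.time() - t0)

        if config.run_functional and func is not None and groups is not None:
            stage = "functional"
            norm = functional.normalize_depth(func, config.normalization_target)
            lvl1 = functional.aggregate_level(norm, 1)
            compare = functional.category_group_compare(
                lvl1, groups, alpha=config.alpha)
            write_table(compare, out / "category_group_compare.tsv")
            selected = functional.select_categories(
                norm, config.selected_categories)
            d_sel = dissimilarity.bray_curtis(selected)
            write_table(d_sel.data, out / "dist_bray_selected.tsv")
            sel_tests = _group_test_row(d_sel, groups, config.n_perm, config.seed)
            results.update(category_compare=compare, selected_table=selected,
                           selected_group_tests=sel_tests)
            pd.DataFrame([sel_tests]).set_index("metric").to_csv(
                out / "group_tests_selected_categories.tsv", sep="\t")
    except Exception as exc:  # annotate the failing stage, keep partial output
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    write_manifest(out, config.to_dict())
    log.info("pipeline complete [%.1fs]", time.time() - t0)
    return results
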