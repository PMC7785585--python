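"""End-to-end orchestration: simulate -> rarefy -> diversity -> stats ->
assembly -> networks, from a single YAML config.

Every stochastic stage receives a sub-seed derived by hashing the global
seed with the stage name, so adding or disabling one stage never perturbs
another stage's random stream, and re-running an identical config
reproduces every numeric output byte for byte.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._util import derive_seed, logger
from . import community_stats as cs
from . import data_model as dm
from . import diversity as dv
from . import network as nw
from .assembly import quantify_assembly
from .synthetic import ScenarioConfig, simulate_scenario

__all__ = ["RunConfig", "validate_config", "run_pipeline", "DEFAULT_CONFIG"]

ALL_STAGES = ("simulate", "rarefy", "alpha", "beta", "stats", "assembly", "network")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "bentheco_out",
    "stages": list(ALL_STAGES),
    "scenario": {},  # ScenarioConfig fields; used when no inputs block
    "inputs": None,  # {otu_table, tree, metadata, taxonomy?} file paths
    "rarefaction_depth": None,  # default: smallest sample total
    "grouping": None,  # {group name: [site, ...]}; default: split sites in half
    "env_variables": [
        "water_depth", "bottom_temperature", "bottom_salinity",
        "As", "Cd", "Cr", "Cu", "Hg", "Pb", "Zn", "clay", "silt", "sand",
    ],
    "anosim_permutations": 999,
    "mantel_permutations": 9999,
    "n_null": 999,
    "network_min_total": 20,
    "network_r_threshold": 0.4,
    "network_p_threshold": 0.01,
    "network_bootstraps": 100,
    "network_use_adjusted_p": True,
}


@dataclass
class RunConfig:
    """Validated, fully-defaulted pipeline configuration."""

    values: dict = field(default_factory=lambda: dict(DEFAULT_CONFIG))

    def __getitem__(self, key):
        return self.values[key]


def validate_config(source) -> RunConfig:
    """Load and validate a config mapping or YAML file path.

    Unknown keys are rejected; missing required values are reported all at
    once; defaults are filled in.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source or {})
    unknown = sorted(set(raw) - set(DEFAULT_CONFIG))
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(unknown)}")
    cfg = {**DEFAULT_CONFIG, **raw}
    problems = []
    if cfg["rarefaction_depth"] is not None and cfg["rarefaction_depth"] <= 0:
        problems.append("rarefaction_depth must be positive")
    if not isinstance(cfg["seed"], int):
        problems.append("seed must be an integer")
    bad_stages = sorted(set(cfg["stages"]) - set(ALL_STAGES))
    if bad_stages:
        problems.append(f"unknown stage(s): {', '.join(bad_stages)}")
    if cfg["inputs"] is not None:
        required = {"otu_table", "tree", "metadata"}
        missing = sorted(required - set(cfg["inputs"]))
        if missing:
            problems.append(f"inputs block missing: {', '.join(missing)}")
        else:
            for key, path in cfg["inputs"].items():
                if not Path(path).exists():
                    problems.append(f"inputs.{key} does not exist: {path}")
    if cfg["scenario"]:
        try:
            ScenarioConfig(**{**cfg["scenario"], "seed": 0})
        except (TypeError, ValueError) as exc:
            problems.append(f"scenario block invalid: {exc}")
    if problems:
        raise ValueError("; ".join(problems))
    return RunConfig(cfg)


def _default_grouping(meta: pd.DataFrame) -> dict[str, list[str]]:
    sites = list(dict.fromkeys(meta["site"]))
    half = max(len(sites) // 2, 1)
    return {"nearshore": sites[:half], "offshore": sites[half:]}


def _site_groups(meta: pd.DataFrame, grouping: dict[str, list[str]]) -> pd.Series:
    site_to_group = {s: g for g, ss in grouping.items() for s in ss}
    return meta["site"].map(site_to_group)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write all artifacts.

    Returns the run summary (also written as ``run_summary.json``), holding
    per-stage status, the parameters used, and headline outputs: alpha
    diversity means, ANOSIM/Mantel statistics, the five assembly-process
    fractions and per-group network topology rows.
    """
    cfg = config.values
    seed = cfg["seed"]
    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(cfg["stages"])
    t0 = time.time()
    summary: dict = {
        "version": __version__,
        "seed": seed,
        "stages": {s: "skipped" for s in ALL_STAGES},
        "parameters": {k: v for k, v in cfg.items() if k not in ("stages",)},
        "outputs": {},
    }

    def finish(status: str = "ok") -> dict:
        summary["elapsed_seconds"] = round(time.time() - t0, 3)
        summary["status"] = status
        with open(outdir / "run_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        return summary

    try:
        # ---- acquire data -------------------------------------------------
        tax = None
        if cfg["inputs"] is not None:
            table = dm.read_otu_table(cfg["inputs"]["otu_table"])
            tree = dm.read_newick(cfg["inputs"]["tree"])
            meta = dm.read_metadata(cfg["inputs"]["metadata"])
            if "taxonomy" in cfg["inputs"]:
                tax = dm.read_taxonomy(cfg["inputs"]["taxonomy"])
            summary["stages"]["simulate"] = "skipped"
        else:
            sc = ScenarioConfig(**{**cfg["scenario"], "seed": derive_seed(seed, "simulate")})
            data = simulate_scenario(sc)
            table, tree, meta = data.table, data.tree, data.meta
            if "simulate" in stages:
                dm.write_otu_table(table, outdir / "otu_table.tsv")
                dm.write_newick(tree, str(outdir / "tree.nwk"))
                dm.write_metadata(meta, outdir / "metadata.tsv")
                data.truth.write(outdir / "ground_truth.tsv")
                summary["stages"]["simulate"] = "ok"
        table, tree, meta, tax = dm.align_datasets(table, tree, meta, tax)

        # ---- rarefy -------------------------------------------------------
        if "rarefy" in stages:
            depth = cfg["rarefaction_depth"] or int(table.sample_totals().min())
            table = dv.rarefy(table, depth, derive_seed(seed, "rarefy"))
            meta = meta[meta["sample_id"].isin(table.sample_ids)].reset_index(drop=True)
            dm.write_otu_table(table, outdir / "otu_table_rarefied.tsv")
            summary["outputs"]["rarefaction_depth"] = depth
            summary["stages"]["rarefy"] = "ok"

        groups = cfg["grouping"] or _default_grouping(meta)
        labels = _site_groups(meta, groups).astype(str).tolist()

        # ---- alpha diversity + environmental screens ----------------------
        if "alpha" in stages:
            alpha = dv.alpha_diversity(table, tree)
            alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t", index=False,
                         lineterminator="\n")
            env_vars = [v for v in cfg["env_variables"] if v in meta.columns]
            screen = cs.spearman_screen(
                alpha.set_index("sample_id")[["richness", "shannon", "pd"]], meta, env_vars
            )
            screen.to_csv(outdir / "alpha_env_spearman.tsv", sep="\t", index=False,
                          lineterminator="\n")
            summary["outputs"]["alpha_mean"] = {
                k: float(alpha[k].mean()) for k in ("richness", "shannon", "pd")
            }
            summary["stages"]["alpha"] = "ok"

        # ---- beta diversity ----------------------------------------------
        bc = dv.bray_curtis(table)
        if "beta" in stages:
            uf = dv.unweighted_unifrac(table, tree)
            dm.write_distance_matrix(bc, outdir / "bray_curtis.tsv")
            dm.write_distance_matrix(uf, outdir / "unweighted_unifrac.tsv")
            ord_bc = dv.pcoa(bc)
            ord_bc.to_csv(outdir / "pcoa_bray_curtis.tsv", sep="\t",
                          lineterminator="\n")
            ev = ord_bc.attrs["proportion_explained"]
            summary["outputs"]["pcoa_prop_explained_12"] = [float(ev[0]), float(ev[1])]
            summary["stages"]["beta"] = "ok"

        # ---- multivariate statistics --------------------------------------
        if "stats" in stages:
            env_vars = [v for v in cfg["env_variables"] if v in meta.columns]
            geo = cs.geo_distance(meta)
            env = cs.env_distance(meta, env_vars)
            r_anosim, p_anosim = cs.anosim(
                bc, labels, cfg["anosim_permutations"], derive_seed(seed, "anosim")
            )
            m_geo = cs.mantel(bc, geo, cfg["mantel_permutations"], derive_seed(seed, "mantel_geo"))
            m_env = cs.mantel(bc, env, cfg["mantel_permutations"], derive_seed(seed, "mantel_env"))
            pm_geo = cs.partial_mantel(
                bc, geo, env, cfg["mantel_permutations"], derive_seed(seed, "pmantel_geo")
            )
            slope, intercept, r_decay = cs.distance_decay(bc, geo)
            stats_rows = [
                {"test": "anosim_site_groups", "statistic": r_anosim, "p_value": p_anosim,
                 "permutations": cfg["anosim_permutations"]},
                {"test": "mantel_geographic", "statistic": m_geo.r, "p_value": m_geo.p_value,
                 "permutations": m_geo.n_permutations},
                {"test": "mantel_environment", "statistic": m_env.r, "p_value": m_env.p_value,
                 "permutations": m_env.n_permutations},
                {"test": "partial_mantel_geo_given_env", "statistic": pm_geo.r,
                 "p_value": pm_geo.p_value, "permutations": pm_geo.n_permutations},
                {"test": "distance_decay_slope", "statistic": slope, "p_value": np.nan,
                 "permutations": 0},
            ]
            pd.DataFrame(stats_rows).to_csv(outdir / "community_stats.tsv", sep="\t",
                                            index=False, lineterminator="\n")
            simper_res = cs.simper(table, labels)
            for (a, b), df_s in simper_res.items():
                df_s.head(50).to_csv(outdir / f"simper_{a}_vs_{b}.tsv", sep="\t",
                                     index=False, lineterminator="\n")
            summary["outputs"]["anosim_R"] = float(r_anosim)
            summary["outputs"]["mantel_geo_r"] = float(m_geo.r)
            summary["outputs"]["mantel_env_r"] = float(m_env.r)
            summary["outputs"]["distance_decay_slope"] = float(slope)
            summary["stages"]["stats"] = "ok"

        # ---- assembly processes -------------------------------------------
        if "assembly" in stages:
            pairs, partition = quantify_assembly(
                table, tree, n_null=cfg["n_null"], seed=derive_seed(seed, "assembly")
            )
            pairs.to_csv(outdir / "assembly_pairs.tsv", sep="\t", index=False,
                         lineterminator="\n")
            with open(outdir / "assembly_partition.json", "w") as fh:
                json.dump(
                    {"fractions": partition.fractions, "n_pairs": partition.n_pairs,
                     "n_undefined": partition.n_undefined},
                    fh, indent=2, sort_keys=True,
                )
            summary["outputs"]["assembly_fractions"] = partition.fractions
            summary["stages"]["assembly"] = "ok"

        # ---- co-occurrence networks ---------------------------------------
        if "network" in stages:
            topo_rows = []
            for gname in groups:
                samples = [s for s, lab in zip(table.sample_ids, labels) if lab == gname]
                if len(samples) < 10:
                    logger.warning("group %s has %d samples (<10); network skipped",
                                   gname, len(samples))
                    continue
                sub = table.select_samples(samples)
                sub = nw.filter_min_count(sub, cfg["network_min_total"])
                corr = nw.sparcc(sub, seed=derive_seed(seed, f"sparcc_{gname}"))
                p = nw.bootstrap_pvalues(
                    sub, corr, n_boot=cfg["network_bootstraps"],
                    seed=derive_seed(seed, f"boot_{gname}"),
                )
                p_eff = nw.fdr_bh(p) if cfg["network_use_adjusted_p"] else p
                g = nw.build_network(
                    corr, p_eff, cfg["network_r_threshold"], cfg["network_p_threshold"]
                )
                edges = pd.DataFrame(
                    [{"source": u, "target": v, "r": d["r"], "sign": d["sign"]}
                     for u, v, d in g.edges(data=True)]
                )
                edges.to_csv(outdir / f"network_edges_{gname}.tsv", sep="\t",
                             index=False, lineterminator="\n")
                if g.number_of_nodes() > 0:
                    topo = nw.topology_metrics(g, derive_seed(seed, f"mod_{gname}"))
                else:
                    topo = {"nodes": 0.0, "edges": 0.0}
                topo_rows.append({"group": gname, **topo})
            pd.DataFrame(topo_rows).to_csv(outdir / "network_topology.tsv", sep="\t",
                                           index=False, lineterminator="\n")
            summary["outputs"]["network_topology"] = topo_rows
            summary["stages"]["network"] = "ok"
    except Exception as exc:
        logger.error("pipeline failed: %s", exc)
        summary["error"] = str(exc)
        finish("failed")
        raise
    return finish("ok")
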