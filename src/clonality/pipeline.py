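"""Pipeline orchestration: compose the analysis stages into one reproducible
run driven by a single config document.

Stages (dependency order): sim -> rates -> genotype -> het -> sig -> phylo
-> scrna -> cohort.  Every stochastic stage takes its seed from the config;
re-running an identical config reproduces every numeric field of the report.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_stats, noise_rates, pigeonhole, scrna_scores, signatures
from .genotyper import MUT, build_status_matrix, mutation_burden, site_fraction_concordance
from .heterogeneity import classify_seeding_from_cells, tissue_heterogeneity, trace_origin
from .simdata import NoiseRates, read_fixture, simulate_case, simulate_expression_case

ALL_STAGES = ("sim", "rates", "genotype", "het", "sig", "phylo", "scrna", "cohort")

DEFAULTS = {
    "seed": 0,
    "stages": list(ALL_STAGES),
    "sim": {},
    "noise": {"ado": 0.103, "fp": 2.68e-6, "seq_error": 0.005},
    "genotype": {"min_depth": 5, "min_posterior": 0.95},
    "het": {"min_informative": 5, "h_tolerance": 0.1, "distance_threshold": 0.15},
    "phylo": {"tolerance": 0.1, "presence_threshold": 0.05},
    "sig": {"k_range": [1, 6], "n_resamples": 15, "n_inits": 5},
    "scrna": {"n_features": 500, "threshold": 0.7},
    "input_dir": None,
}


def _merge(config: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULTS))
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    unknown = [s for s in cfg["stages"] if s not in ALL_STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}")
    return cfg


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def run_pipeline(config: dict | None = None) -> dict:
    """Execute the selected stages and return the structured run report."""
    cfg = _merge(config)
    stages = cfg["stages"]
    seed = int(cfg["seed"])
    report: dict = {"config": cfg, "stages": {}}
    noise = NoiseRates(**cfg["noise"])

    case = None
    needs_case = [s for s in ("rates", "genotype", "het", "sig", "phylo") if s in stages]
    if "sim" in stages or cfg["input_dir"]:
        if cfg["input_dir"]:
            case = read_fixture(cfg["input_dir"])
        else:
            case = simulate_case(noise=noise, seed=seed, **cfg["sim"])
    elif needs_case:
        raise ValueError(
            f"stage '{needs_case[0]}' needs case inputs: include the 'sim' stage "
            "or set input_dir to a genotype fixture directory"
        )
    if case is not None:
        report["stages"]["sim"] = {
            "seeding_mode_truth": case.seeding.mode,
            "source_regions_truth": list(case.seeding.source_regions),
            "n_cells": int(len(case.cells)),
            "n_sites": int(case.reads.ref.shape[1]),
        }

    if "rates" in stages:
        rates = noise_rates.estimate_rates(case.controls)
        report["stages"]["rates"] = {
            "cohort_fp_mean": float(rates.loc["cohort", "fp_rate"]),
            "cohort_ado_median": float(rates.loc["cohort", "ado_rate"]),
        }

    status = None
    if any(s in stages for s in ("genotype", "het", "sig")):
        if case is None:
            raise ValueError("stage 'genotype' needs inputs; include 'sim' or input_dir")
        status = build_status_matrix(
            case.reads, case.noise, case.cells, **cfg["genotype"]
        )
    if "genotype" in stages:
        burden = mutation_burden(status, callable_mb=50.0)
        _, r = site_fraction_concordance(status, case.bulk_vaf)
        report["stages"]["genotype"] = {
            "mean_mutations_per_cell": float(burden["n_mutations"].mean()),
            "mean_rate_per_mb": float(burden["rate_per_mb"].mean()),
            "bulk_concordance_r": r,
        }

    if "het" in stages:
        het = tissue_heterogeneity(status)
        if "is_met" in status.cells.columns:
            met_mask = status.cells["is_met"].astype(bool)
            met_tissues = sorted(status.cells.loc[met_mask, "tissue"].unique())
        else:
            met_tissues = []
        met_tissues = [t for t in met_tissues if (status.cells["tissue"] == t).sum() >= 2]
        out = {
            "similarity_index": {t: h.similarity_index for t, h in het.items()},
            "H": {t: h.H for t, h in het.items()},
            "metastases": {},
        }
        for t in met_tissues:
            origin = trace_origin(status, t, min_informative=cfg["het"]["min_informative"])
            call = classify_seeding_from_cells(
                status, t,
                h_tolerance=cfg["het"]["h_tolerance"],
                distance_threshold=cfg["het"]["distance_threshold"],
            )
            out["metastases"][t] = {
                "origin_counts": origin.region_counts,
                "origin_p": origin.p_value,
                "seeding_call": call["mode"],
                "n_lineages": call["n_lineages"],
            }
        report["stages"]["het"] = _jsonable(out)

    if "sig" in stages:
        catalog = catalog_from_status(status)
        k_lo, k_hi = cfg["sig"]["k_range"]
        sols, k_sel = signatures.extract_signatures(
            catalog,
            k_range=range(k_lo, k_hi + 1),
            n_resamples=cfg["sig"]["n_resamples"],
            n_inits=cfg["sig"]["n_inits"],
            seed=seed,
        )
        report["stages"]["sig"] = {
            "selected_k": int(k_sel),
            "stability": {k: s.mean_stability for k, s in sols.items()},
            "frobenius_error": {k: s.frobenius_error for k, s in sols.items()},
        }

    if "phylo" in stages:
        if case is None:
            raise ValueError("stage 'phylo' needs bulk VAFs; include 'sim' or input_dir")
        met = [t for t in case.bulk_vaf.columns if t.startswith(("liver", "lymph"))]
        calls = {}
        regions = [c for c in case.bulk_vaf.columns if c not in met and c != "primary"]
        for t in met:
            clusters = pigeonhole.cluster_ccf(
                case.bulk_vaf["primary"],
                case.bulk_vaf[t],
                random_state=seed % (2**31),
                extra_vafs=case.bulk_vaf[regions].to_numpy(),
            )
            tree = pigeonhole.build_tree(clusters, tolerance=cfg["phylo"]["tolerance"])
            call = pigeonhole.classify_seeding(tree, cfg["phylo"]["presence_threshold"])
            calls[t] = {
                "mode": call.mode,
                "n_clusters": int(len(clusters.clusters)),
                "newick": pigeonhole.tree_to_newick(tree),
            }
        report["stages"]["phylo"] = calls

    if "scrna" in stages:
        expr = simulate_expression_case(seed=seed)
        proj = scrna_scores.project_cells(
            expr.met_expr, expr.primary_expr, expr.primary_clusters,
            n_features=cfg["scrna"]["n_features"], threshold=cfg["scrna"]["threshold"],
        )
        mc = scrna_scores.mc_score(proj, clusters=sorted(expr.primary_clusters.unique()))
        emt = scrna_scores.emt_module_score(expr.primary_expr, expr.emt_genes, seed=seed)
        cnv = scrna_scores.cnv_score(expr.cnv_matrix, expr.cnv_baseline)
        emt_by_cluster = emt.groupby(expr.primary_clusters).mean()
        reg = scrna_scores.regress_emt_mc(emt_by_cluster, mc)
        report["stages"]["scrna"] = _jsonable(
            {
                "mc_scores": mc,
                "assigned_fraction": float(proj["assigned"].notna().mean()),
                "mean_cnv_score": float(cnv.mean()),
                "regression": reg,
            }
        )

    if "cohort" in stages:
        report["stages"]["cohort"] = cohort_stats.reproduce_table1()

    return _jsonable(report)


def classify_case_seeding(case, met_tissue: str = "liver", seed: int = 0) -> dict:
    """Mono/polyclonal seeding call for one simulated or loaded case,
    combining the single-cell evidence with the pigeonhole-tree call.

    The single-cell rule (distinct metastasis lineages + heterogeneity
    comparison with the traced source region) decides the final call when
    per-cell genotypes are available; the bulk CCF-cluster tree call is
    computed and reported alongside (and would decide in its absence).
    """
    status = build_status_matrix(case.reads, case.noise, case.cells)
    cell_call = classify_seeding_from_cells(status, met_tissue)
    if "is_met" in case.cells.columns:
        met_names = set(case.cells.loc[case.cells["is_met"].astype(bool), "tissue"].unique())
    else:
        met_names = {met_tissue}
    regions = [c for c in case.bulk_vaf.columns if c != "primary" and c not in met_names]
    tree_mode = "undefined"
    try:
        clusters = pigeonhole.cluster_ccf(
            case.bulk_vaf["primary"],
            case.bulk_vaf[met_tissue],
            random_state=int(seed) % (2**31),
            extra_vafs=case.bulk_vaf[regions].to_numpy(),
        )
        tree = pigeonhole.build_tree(clusters)
        tree_mode = pigeonhole.classify_seeding(tree).mode
    except ValueError:
        pass
    return {
        "mode": cell_call["mode"],
        "cell_call": cell_call["mode"],
        "tree_call": tree_mode,
        "n_lineages": cell_call["n_lineages"],
        "h_met": cell_call["h_met"],
        "h_source": cell_call["h_source"],
    }


def catalog_from_status(status) -> pd.DataFrame:
    """96-class catalog per tissue from MUT calls: a site contributes to a
    tissue's spectrum once per cell in which it is called mutant."""
    rows = []
    sites = status.sites
    for tissue, grp in status.cells.groupby("tissue"):
        codes = status.codes[status.cells.index.isin(grp.index)]
        counts = (codes == MUT).sum(axis=0)
        for site, c in zip(sites.index, counts):
            if c > 0:
                rows.append(
                    {
                        "sample": tissue,
                        "ref": sites.loc[site, "ref"],
                        "alt": sites.loc[site, "alt"],
                        "context": sites.loc[site, "context"],
                        "count": int(c),
                    }
                )
    if not rows:
        raise ValueError("no mutant calls to build a catalog from")
    df = pd.DataFrame(rows)
    df = df.loc[df.index.repeat(df["count"])].drop(columns="count").reset_index(drop=True)
    return signatures.build_96_catalog(df)


def validate_io(paths: dict[str, str]) -> list[str]:
    """Schema/coordinate diagnostics for input files; returns messages, empty
    when everything validates."""
    diags: list[str] = []
    for kind, path in paths.items():
        p = Path(path)
        if not p.exists():
            diags.append(f"{kind}: {p} does not exist")
            continue
        if kind == "status":
            df = pd.read_csv(p, sep="\t", index_col=0, nrows=200)
            tokens = set(np.unique(df.to_numpy().astype(str)))
            bad = tokens - {"MUT", "WT", "CND"}
            for t in sorted(bad):
                lines = df.index[(df == t).any(axis=1)].tolist()[:3]
                diags.append(
                    f"status: unknown token {t!r} (e.g. rows {lines}); vocabulary is MUT/WT/CND"
                )
        elif kind == "sites":
            df = pd.read_csv(p, sep="\t", nrows=200)
            if "pos" in df and (df["pos"] < 1).any():
                diags.append("sites: positions must be 1-based (found pos < 1)")
        elif kind == "vcf":
            text = p.read_text().splitlines()
            fmt = [l for l in text if l.startswith("##FORMAT")]
            if not any("ID=AD" in l for l in fmt):
                diags.append("vcf: no AD FORMAT field; genotyping needs per-allele read counts")
    return diags
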