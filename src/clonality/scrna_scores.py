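"""Single-cell transcriptome statistics: cluster projection, metastatic
contribution (MC) score, EMT module score, quadratic CNV score, and the
EMT~MC regression.

* Projection: each metastatic cell is compared to per-cluster centroids of
  the primary tumor (per-gene median over the top variance-ranked genes) by
  cosine, Pearson and Spearman similarity, and assigned to the top centroid
  when the measures agree.
* MC score of a primary cluster: the fraction of assigned metastatic cells
  that project onto it (scores sum to 1 over clusters).
* EMT score: expression-matched module score — the mean expression of the
  EMT gene set minus the mean of bin-matched control genes, per cell.
* CNV score: the quadratic sum of deviations of copy-number region values
  from the neutral baseline, per cell (a genomic-instability proxy).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import substream

__all__ = [
    "ScoreBundle",
    "project_cells",
    "mc_score",
    "emt_module_score",
    "cnv_score",
    "regress_emt_mc",
    "qc_filter",
]


@dataclass
class ScoreBundle:
    assignments: pd.DataFrame
    mc_scores: pd.Series
    emt_scores: pd.Series
    cnv_scores: pd.Series
    regression: dict


def _rank_rows(X: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, X)


def _row_cosine(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    an = np.linalg.norm(A, axis=1, keepdims=True)
    bn = np.linalg.norm(B, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = (A @ B.T) / (an * bn.T)
    return sim


def _row_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return _row_cosine(A - A.mean(axis=1, keepdims=True), B - B.mean(axis=1, keepdims=True))


def project_cells(
    met_expr: pd.DataFrame,
    primary_expr: pd.DataFrame,
    cluster_labels: pd.Series,
    n_features: int = 500,
    threshold: float = 0.7,
    min_cluster_cells: int = 3,
) -> pd.DataFrame:
    """Centroid projection of metastatic cells onto primary clusters.

    A cell is assigned to the top centroid when at least 2 of the 3
    similarity measures (cosine, Pearson, Spearman) agree on it and the
    maximum similarity reaches ``threshold``; otherwise it is unassigned.
    Cells with undefined similarity (all-zero expression) are unassigned.
    """
    if not (0 <= threshold <= 1):
        raise ValueError("threshold must lie in [0, 1]")
    shared = primary_expr.columns.intersection(met_expr.columns)
    if shared.empty:
        raise ValueError("no shared gene universe")
    prim = primary_expr[shared]
    met = met_expr[shared]
    variances = prim.var(axis=0)
    top = variances.nlargest(min(n_features, len(shared))).index
    prim, met = prim[top], met[top]

    centroids, kept = [], []
    for k, cells in cluster_labels.groupby(cluster_labels):
        if len(cells) < min_cluster_cells:
            warnings.warn(f"cluster {k} has < {min_cluster_cells} cells; excluded")
            continue
        centroids.append(prim.loc[cells.index].median(axis=0).to_numpy())
        kept.append(k)
    if not centroids:
        raise ValueError("no cluster large enough to form a centroid")
    C = np.vstack(centroids)
    M = met.to_numpy(dtype=float)

    sims = {
        "cosine": _row_cosine(M, C),
        "pearson": _row_pearson(M, C),
        "spearman": _row_pearson(_rank_rows(M), _rank_rows(C)),
    }
    rows = []
    for i, cell in enumerate(met.index):
        per_measure = {}
        for name, S in sims.items():
            row = S[i]
            per_measure[name] = (None, np.nan) if np.isnan(row).all() else (
                kept[int(np.nanargmax(row))],
                float(np.nanmax(row)),
            )
        tops = [v[0] for v in per_measure.values() if v[0] is not None]
        assigned = None
        best_sim = np.nan
        if tops:
            vals, counts = np.unique(np.asarray(tops, dtype=object), return_counts=True)
            winner = vals[np.argmax(counts)]
            agree = int(counts.max())
            best_sim = max(
                v[1] for v in per_measure.values() if v[0] == winner
            )
            if agree >= 2 and best_sim >= threshold:
                assigned = winner
        rows.append(
            {
                "cell": cell,
                "assigned": assigned,
                "max_similarity": best_sim,
                **{f"top_{m}": per_measure[m][0] for m in sims},
            }
        )
    return pd.DataFrame(rows).set_index("cell")


def mc_score(
    assignments: pd.DataFrame,
    clusters=None,
    include_unassigned: bool = False,
) -> pd.Series:
    """Metastatic contribution score per primary cluster: the fraction of
    (assigned) metastatic cells projecting onto the cluster."""
    assigned = assignments["assigned"].dropna()
    if assigned.empty:
        warnings.warn("zero assigned cells: MC scores undefined")
        return pd.Series(dtype=float, name="mc_score")
    denom = len(assignments) if include_unassigned else len(assigned)
    counts = assigned.value_counts()
    if clusters is not None:
        counts = counts.reindex(list(clusters), fill_value=0)
    return (counts / denom).rename("mc_score")


def emt_module_score(
    expression: pd.DataFrame,
    gene_set: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Expression-matched module score per cell.

    Genes are binned into ``n_bins`` equal-frequency bins of cohort-average
    expression; for every set gene, ``n_ctrl`` control genes are drawn (with
    replacement) from its bin.  Score = mean(set genes) - mean(controls).
    """
    if len(gene_set) == 0:
        raise ValueError("gene set is empty")
    missing = set(gene_set) - set(expression.columns)
    if missing:
        raise ValueError(f"gene set members absent from matrix: {sorted(missing)[:5]}")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    rng = substream(seed, "module-score")
    avg = expression.mean(axis=0)
    # equal-frequency binning; ties broken by rank so bins stay balanced
    order = avg.rank(method="first")
    bins = pd.qcut(order, q=min(n_bins, len(order)), labels=False)
    bin_members = {b: np.array(avg.index[bins == b]) for b in np.unique(bins)}

    control_genes = []
    for g in gene_set:
        pool = bin_members[int(bins[g])]
        control_genes.append(rng.choice(pool, size=n_ctrl, replace=True))
    control_genes = np.concatenate(control_genes)
    set_mean = expression[list(gene_set)].mean(axis=1)
    ctrl_mean = expression[control_genes].to_numpy().mean(axis=1)
    return (set_mean - ctrl_mean).rename("emt_score")


def cnv_score(cnv_matrix: pd.DataFrame, baseline: float = 1.0) -> pd.Series:
    """Per-cell quadratic sum of CNV-region deviations from the neutral
    baseline: score = sum_r (value_r - baseline)^2."""
    if cnv_matrix.isna().any().any():
        raise ValueError("CNV matrix contains missing values; impute upstream")
    dev = cnv_matrix.to_numpy(dtype=float) - baseline
    return pd.Series((dev**2).sum(axis=1), index=cnv_matrix.index, name="cnv_score")


def regress_emt_mc(emt_by_cluster: pd.Series, mc_by_cluster: pd.Series) -> dict:
    """OLS of the MC score on the mean EMT score across primary clusters."""
    joined = pd.concat(
        [emt_by_cluster.rename("emt"), mc_by_cluster.rename("mc")], axis=1
    ).dropna()
    if len(joined) < 3:
        raise ValueError("need >= 3 clusters for the regression")
    if joined["emt"].std() == 0:
        raise ValueError("zero-variance EMT predictor")
    res = stats.linregress(joined["emt"], joined["mc"])
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "p_value": float(res.pvalue),
        "n_clusters": int(len(joined)),
    }


def qc_filter(
    expression: pd.DataFrame,
    min_genes: int = 200,
    max_mito_fraction: float = 0.2,
    mito_prefix: str = "MT-",
) -> pd.DataFrame:
    """Optional upstream cell filter: drop cells with fewer than
    ``min_genes`` detected genes or mitochondrial content above
    ``max_mito_fraction``."""
    detected = (expression > 0).sum(axis=1)
    mito_genes = [g for g in expression.columns if str(g).startswith(mito_prefix)]
    total = expression.sum(axis=1)
    mito = expression[mito_genes].sum(axis=1) if mito_genes else 0.0
    with np.errstate(invalid="ignore"):
        frac = np.where(total > 0, mito / total.replace(0, np.nan), 0.0) if mito_genes else np.zeros(len(expression))
    keep = (detected >= min_genes) & (pd.Series(frac, index=expression.index).fillna(0) <= max_mito_fraction)
    return expression.loc[keep]
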