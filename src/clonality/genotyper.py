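"""Bayesian diploid genotyping per cell-site under ADO and sequencing error.

At each candidate SNV site a cell is diploid with genotype g in {RR, RA, AA}.
Given n = ref + alt reads with per-read error rate eps and allele-dropout
probability ado, the likelihoods are

    L(RR) = Binom(alt | n, eps)
    L(AA) = Binom(ref | n, eps)
    L(RA) = (1 - ado) * Binom(alt | n, 1/2)
            + (ado/2) * Binom(alt | n, eps)      # alt allele dropped
            + (ado/2) * Binom(ref | n, eps)      # ref allele dropped

i.e. dropout converts a heterozygous template into one of the two homozygous
templates with equal probability.  The posterior is prior x likelihood,
normalized.  With ado = 0 this reduces to the standard diploid caller.

A consequence worth knowing: at a site whose reads are all reference, the
posterior for RR is capped near 1/(1 + ado/2) ~ 0.95 for ado = 0.103 -- the
model never fully rules out a dropped alternate allele.

Statuses: a call is CND (cannot determine) when depth or posterior
confidence is insufficient; otherwise MUT for RA/AA and WT for RR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .simdata import NoiseRates, ReadCountMatrix

__all__ = [
    "GenotypePosterior",
    "StatusMatrix",
    "genotype_posterior",
    "call_status",
    "build_status_matrix",
    "filter_snvs",
    "mutation_burden",
    "site_fraction_concordance",
    "CND",
    "WT",
    "MUT",
]

# status codes used throughout the package
CND, WT, MUT = -1, 0, 1
STATUS_STR = {CND: "CND", WT: "WT", MUT: "MUT"}
STATUS_CODE = {v: k for k, v in STATUS_STR.items()}
GENOTYPES = ("RR", "RA", "AA")


@dataclass
class GenotypePosterior:
    """Posterior over {RR, RA, AA}; arrays broadcast over input shape."""

    probs: np.ndarray  # (..., 3), rows sum to 1
    depth: np.ndarray
    map_genotype: np.ndarray  # int index into GENOTYPES
    map_probability: np.ndarray


def genotype_posterior(
    ref_count,
    alt_count,
    noise: NoiseRates,
    prior=None,
) -> GenotypePosterior:
    """Posterior genotype probabilities for (arrays of) read-count pairs.

    With n = 0 the posterior equals the prior exactly.  Computation is in
    log space; mixture terms with zero weight are dropped, so ado = 0 and
    eps = 0 are exact, not clipped.
    """
    ref = np.asarray(ref_count)
    alt = np.asarray(alt_count)
    if (ref < 0).any() or (alt < 0).any():
        raise ValueError("read counts must be non-negative")
    if prior is None:
        prior = np.full(3, 1.0 / 3.0)
    prior = np.asarray(prior, dtype=float)
    if prior.shape[-1] != 3 or not np.allclose(prior.sum(axis=-1), 1.0):
        raise ValueError("prior must be a 3-vector summing to 1")
    n = ref + alt
    eps = noise.seq_error

    with np.errstate(divide="ignore"):
        l_alt_eps = stats.binom.logpmf(alt, n, eps)  # log Binom(alt | n, eps)
        l_ref_eps = stats.binom.logpmf(ref, n, eps)
        l_half = stats.binom.logpmf(alt, n, 0.5)
    log_rr = l_alt_eps
    log_aa = l_ref_eps
    terms = np.stack([l_half, l_alt_eps, l_ref_eps], axis=-1)
    weights = np.array([1.0 - noise.ado, noise.ado / 2.0, noise.ado / 2.0])
    log_ra = logsumexp(np.broadcast_to(terms, terms.shape), axis=-1, b=weights)

    log_like = np.stack([log_rr, log_ra, log_aa], axis=-1)
    with np.errstate(divide="ignore"):
        log_post = log_like + np.log(prior)
    log_post = log_post - logsumexp(log_post, axis=-1, keepdims=True)
    probs = np.exp(log_post)
    probs = probs / probs.sum(axis=-1, keepdims=True)
    map_g = np.argmax(probs, axis=-1)
    map_p = np.max(probs, axis=-1)
    return GenotypePosterior(probs, n, map_g, map_p)


def call_status(
    posterior: GenotypePosterior,
    min_depth: int = 5,
    min_posterior: float = 0.95,
):
    """Status (MUT/WT/CND) and zygosity from a genotype posterior.

    CND iff depth < min_depth or MAP probability < min_posterior; otherwise
    WT for RR and MUT for RA/AA.  Returns (status codes, zygosity strings).
    """
    if not (0 < min_posterior <= 1) or min_depth < 0:
        raise ValueError("min_posterior in (0, 1] and min_depth >= 0 required")
    cnd = (posterior.depth < min_depth) | (posterior.map_probability < min_posterior)
    status = np.where(cnd, CND, np.where(posterior.map_genotype == 0, WT, MUT))
    zygosity = np.where(
        cnd, "unknown", np.array(GENOTYPES, dtype=object)[posterior.map_genotype]
    )
    return status.astype(np.int8), zygosity


@dataclass
class StatusMatrix:
    """Cells x sites mutation-status matrix (codes: MUT=1, WT=0, CND=-1) with
    cell metadata (tissue, region) and site metadata (gene)."""

    status: pd.DataFrame  # int8 codes, index cells, columns sites
    cells: pd.DataFrame  # index cell; at least tissue, region
    sites: pd.DataFrame  # index site; at least gene
    zygosity: pd.DataFrame | None = None

    def __post_init__(self):
        if not self.status.index.equals(self.cells.index):
            raise ValueError("status rows must match cell metadata")
        if not self.status.columns.equals(self.sites.index):
            raise ValueError("status columns must match site metadata")

    @property
    def codes(self) -> np.ndarray:
        return self.status.to_numpy(dtype=np.int8)

    def subset_cells(self, cells) -> "StatusMatrix":
        return StatusMatrix(
            self.status.loc[cells],
            self.cells.loc[cells],
            self.sites,
            None if self.zygosity is None else self.zygosity.loc[cells],
        )

    def subset_sites(self, sites) -> "StatusMatrix":
        return StatusMatrix(
            self.status[sites],
            self.cells,
            self.sites.loc[sites],
            None if self.zygosity is None else self.zygosity[sites],
        )

    def to_strings(self) -> pd.DataFrame:
        return self.status.apply(lambda col: col.map(STATUS_STR))

    def write(self, path) -> None:
        self.to_strings().to_csv(path, sep="\t")

    @classmethod
    def read(cls, path, cells: pd.DataFrame, sites: pd.DataFrame) -> "StatusMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        bad = set(np.unique(df.to_numpy().astype(str))) - set(STATUS_CODE)
        if bad:
            raise ValueError(f"unknown status tokens: {sorted(bad)}")
        codes = df.apply(lambda col: col.map(STATUS_CODE)).astype(np.int8)
        codes.columns.name = "site"
        return cls(codes, cells.loc[df.index], sites.loc[df.columns])


def build_status_matrix(
    reads: ReadCountMatrix,
    noise: NoiseRates,
    cells_meta: pd.DataFrame | None = None,
    prior=None,
    min_depth: int = 5,
    min_posterior: float = 0.95,
) -> StatusMatrix:
    """Genotype every cell-site pair and classify MUT/WT/CND."""
    post = genotype_posterior(reads.ref, reads.alt, noise, prior)
    status, zyg = call_status(post, min_depth, min_posterior)
    if cells_meta is None:
        cells_meta = pd.DataFrame(index=pd.Index(reads.cells, name="cell"))
        cells_meta["tissue"] = "unknown"
        cells_meta["region"] = "unknown"
    idx = pd.Index(reads.cells, name="cell")
    return StatusMatrix(
        pd.DataFrame(status, index=idx, columns=reads.sites.index),
        cells_meta.loc[idx],
        reads.sites,
        pd.DataFrame(zyg, index=idx, columns=reads.sites.index),
    )


def filter_snvs(
    status: StatusMatrix,
    tissue_support: pd.DataFrame | None = None,
    rule: str = "OR",
    min_tissue_reads: int = 10,
    min_cells: int = 3,
) -> pd.Index:
    """Retain candidate sites by the support filter.

    OR rule: keep a site if it has >= min_tissue_reads supporting reads in at
    least one tissue, or it is called MUT in >= min_cells single cells.
    AND rule: require both.  ``tissue_support`` is sites x tissues supporting
    read counts; it is mandatory (the tissue clause always participates).
    """
    if rule not in ("OR", "AND"):
        raise ValueError("rule must be 'OR' or 'AND'")
    if tissue_support is None:
        raise ValueError(f"rule {rule} needs a tissue support table")
    cells_ok = (status.codes == MUT).sum(axis=0) >= min_cells
    tissue_ok = (
        tissue_support.reindex(status.sites.index).fillna(0).max(axis=1)
        >= min_tissue_reads
    ).to_numpy()
    keep = (cells_ok | tissue_ok) if rule == "OR" else (cells_ok & tissue_ok)
    return status.sites.index[keep]


def mutation_burden(status: StatusMatrix, callable_mb: float) -> pd.DataFrame:
    """Per-cell mutation count and rate per megabase of callable genome."""
    if callable_mb <= 0:
        raise ValueError("callable_mb must be > 0")
    codes = status.codes
    count = (codes == MUT).sum(axis=1)
    informative = (codes != CND).sum(axis=1)
    return pd.DataFrame(
        {
            "n_mutations": count,
            "rate_per_mb": count / callable_mb,
            "n_informative": informative,
            "all_cnd": informative == 0,
        },
        index=status.status.index,
    )


def site_fraction_concordance(
    status: StatusMatrix,
    bulk_vaf: pd.DataFrame,
    tissues: list[str] | None = None,
    vaf_to_fraction: float = 2.0,
) -> tuple[pd.DataFrame, float]:
    """Per-site single-cell mutant fractions per tissue vs bulk VAFs.

    Fraction = MUT / (MUT + WT) among determinable cells of the tissue.  The
    bulk VAF is mapped to an expected cell fraction by the diploid convention
    fraction ~ 2 x VAF for heterozygous mutations (clamped to [0, 1]);
    returns (per-site table, Pearson r over all defined pairs).
    """
    tissues = tissues or sorted(status.cells["tissue"].unique())
    rows = []
    for t in tissues:
        sub = status.codes[(status.cells["tissue"] == t).to_numpy()]
        mut = (sub == MUT).sum(axis=0)
        wt = (sub == WT).sum(axis=0)
        det = mut + wt
        with np.errstate(invalid="ignore"):
            frac = np.where(det > 0, mut / np.maximum(det, 1), np.nan)
        for site, f, d in zip(status.sites.index, frac, det):
            rows.append((t, site, f, int(d)))
    table = pd.DataFrame(rows, columns=["tissue", "site", "sc_fraction", "n_determinable"])
    bulk_long = bulk_vaf.reindex(status.sites.index).reset_index(names="site").melt(
        id_vars="site", var_name="tissue", value_name="bulk_vaf"
    )
    table = table.merge(bulk_long, on=["tissue", "site"], how="left")
    table["bulk_fraction"] = np.clip(table["bulk_vaf"] * vaf_to_fraction, 0.0, 1.0)
    ok = table.dropna(subset=["sc_fraction", "bulk_fraction"])
    if len(ok) < 2:
        raise ValueError("need >= 2 sites with determinable cells for a correlation")
    if ok["sc_fraction"].std() == 0 or ok["bulk_fraction"].std() == 0:
        warnings.warn("zero variance in fractions; correlation undefined")
        return table, float("nan")
    r = float(np.corrcoef(ok["sc_fraction"], ok["bulk_fraction"])[0, 1])
    return table, r
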