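"""Synthetic single-cell exome and expression cases with fully known truth.

The generator emulates the study design this package analyses: a primary
tumor sampled in several regions, each dominated by a small set of subclones
from one clone tree, plus metastases founded either by a single subclone
(monoclonal seeding) or by a cluster of cells drawn from several distinct
branches (polyclonal seeding).  Sequencing noise follows the operational
definitions of MDA artifacts: allele dropout (ADO) removes one allele of a
heterozygous site before amplification, false positives (FP) emit spurious
variant calls at reference sites, and a per-read error rate corrupts bases.

Everything is driven by one integer seed through named substreams so every
intermediate object is bit-reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NoiseRates",
    "CloneTree",
    "SeedingTruth",
    "ReadCountMatrix",
    "ControlSites",
    "SimulatedCase",
    "ExpressionCase",
    "simulate_case",
    "simulate_controls",
    "simulate_expression_case",
    "write_fixture",
    "read_fixture",
    "substream",
]

# control-site call codes
HOMREF, HET, HOMALT, NOCALL = 0, 1, 2, 3

_BASES = "ACGT"


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, collision-resistant child RNG of a single master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(name.encode())])
    )


@dataclass(frozen=True)
class NoiseRates:
    """MDA noise parameters shared by the simulator and the genotype model.

    ado : probability that one allele of a truly heterozygous site fails to
        amplify (cohort median reported for this protocol: 0.103).
    fp : per-site probability of a spurious variant call at a true
        homozygous-reference site (cohort mean for this protocol: 2.68e-6).
    seq_error : per-read base error rate.
    """

    ado: float = 0.103
    fp: float = 2.68e-6
    seq_error: float = 0.005

    def __post_init__(self):
        for name in ("ado", "fp", "seq_error"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class CloneTree:
    """Rooted clone tree with per-clone private mutation counts and per-tissue
    prevalences (fraction of cells in the tissue descending from the clone)."""

    nodes: list[int]
    parent: dict[int, int | None]
    mutations_per_clone: dict[int, int]
    prevalence: pd.DataFrame  # tissues x clones

    @property
    def root(self) -> int:
        roots = [n for n in self.nodes if self.parent[n] is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {roots}")
        return roots[0]

    def children(self, node: int) -> list[int]:
        return [n for n in self.nodes if self.parent[n] == node]

    def ancestry(self, node: int) -> list[int]:
        """Path root -> node, inclusive."""
        path = [node]
        while self.parent[path[-1]] is not None:
            path.append(self.parent[path[-1]])
        return path[::-1]

    def is_ancestor(self, a: int, b: int) -> bool:
        """True if a is an ancestor of b (or a == b)."""
        return a in self.ancestry(b)

    def check_pigeonhole(self, tol: float = 1e-9) -> None:
        """Parent prevalence must dominate the sum of its children, per tissue."""
        for node in self.nodes:
            kids = self.children(node)
            if not kids:
                continue
            for tissue in self.prevalence.index:
                parent_p = self.prevalence.loc[tissue, node]
                child_sum = sum(self.prevalence.loc[tissue, k] for k in kids)
                if child_sum > parent_p + tol:
                    raise AssertionError(
                        f"pigeonhole violated at clone {node} in {tissue}: "
                        f"children sum {child_sum:.4f} > parent {parent_p:.4f}"
                    )


@dataclass(frozen=True)
class SeedingTruth:
    mode: str  # "monoclonal" | "polyclonal"
    source_regions: tuple[str, ...]
    seeding_clones: frozenset[int]


@dataclass
class ReadCountMatrix:
    """Per cell-site (ref, alt) read counts at candidate somatic sites."""

    cells: list[str]
    sites: pd.DataFrame  # index: site id; columns gene, context, chrom, pos, candidate
    ref: np.ndarray  # (n_cells, n_sites) int
    alt: np.ndarray

    def __post_init__(self):
        if (self.ref < 0).any() or (self.alt < 0).any():
            raise ValueError("read counts must be non-negative")
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("cell labels must be unique")
        if self.sites.index.has_duplicates:
            raise ValueError("site labels must be unique")

    @property
    def depth(self) -> np.ndarray:
        return self.ref + self.alt


@dataclass
class ControlSites:
    """Call-level control data: germline-heterozygous sites (ADO controls)
    and confident homozygous-reference sites (FP controls), disjoint from the
    somatic candidate set.  Calls are coded HOMREF/HET/HOMALT/NOCALL."""

    cells: list[str]
    het_calls: np.ndarray  # (n_cells, n_het_sites) int8
    hom_calls: np.ndarray  # (n_cells, n_hom_sites) int8


@dataclass
class SimulatedCase:
    tree: CloneTree
    seeding: SeedingTruth
    truth: pd.DataFrame  # cells x sites, 1 = carries the mutation (het)
    template: np.ndarray  # amplified-template genotype codes 0=RR,1=RA,2=AA
    reads: ReadCountMatrix
    controls: ControlSites
    bulk_vaf: pd.DataFrame  # sites x tissues (+ pooled "primary")
    cells: pd.DataFrame  # index cell; columns tissue, region, clone
    noise: NoiseRates
    params: dict = field(default_factory=dict)


@dataclass
class ExpressionCase:
    primary_expr: pd.DataFrame  # cells x genes, non-negative
    primary_clusters: pd.Series  # cell -> cluster id
    met_expr: pd.DataFrame
    emt_genes: list[str]
    cnv_matrix: pd.DataFrame  # cells x regions, centered on baseline
    cnv_baseline: float
    truth: pd.DataFrame  # met cell -> source cluster
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# clone tree / seeding construction


def _draw_tree_parents(n_clones: int, rng: np.random.Generator) -> dict[int, int | None]:
    # uniform random recursive tree: clone i attaches to a uniform earlier clone
    parent: dict[int, int | None] = {0: None}
    for i in range(1, n_clones):
        parent[i] = int(rng.integers(0, i))
    return parent


def _antichain_pairs(parent: dict[int, int | None]) -> list[tuple[int, int]]:
    def ancestry(n):
        path = {n}
        while parent[n] is not None:
            n = parent[n]
            path.add(n)
        return path

    nodes = [n for n in parent if parent[n] is not None]
    anc = {n: ancestry(n) for n in nodes}
    return [
        (a, b)
        for i, a in enumerate(nodes)
        for b in nodes[i + 1 :]
        if a not in anc[b] and b not in anc[a]
    ]


def simulate_case(
    n_regions: int = 4,
    cells_per_region: int = 10,
    n_clones: int = 6,
    n_mutations: int = 200,
    seeding_mode: str = "polyclonal",
    noise: NoiseRates | None = None,
    seed: int = 0,
    *,
    cells_per_met: int | None = None,
    met_tissues: tuple[str, ...] = ("liver", "lymph"),
    mean_depth: float = 30.0,
    depth_dispersion: float = 3.0,
    n_het_controls: int = 500,
    n_hom_controls: int = 2000,
    bulk_depth: int = 500,
    trunk_weight: float = 0.15,
    driver_genes: tuple[str, ...] = ("APC", "TP53"),
) -> SimulatedCase:
    """Generate one fully specified case: clone tree, regional primary tumor,
    seeded metastases, noisy read counts, control-site calls and bulk VAFs.

    Coverage is negative-binomial (overdispersed MDA coverage, mean 30x by
    default); ADO, FP and sequencing error follow ``noise``.  With all noise
    rates zero the observed genotype equals the truth at every covered site.
    """
    if min(n_regions, cells_per_region, n_clones, n_mutations) < 1:
        raise ValueError("all counts must be >= 1")
    if seeding_mode not in ("monoclonal", "polyclonal"):
        raise ValueError(f"unknown seeding_mode {seeding_mode!r}")
    if seeding_mode == "polyclonal" and n_clones < 3:
        raise ValueError(
            "polyclonal seeding needs n_clones >= 3 (two distinct non-nested "
            "branches are impossible otherwise)"
        )
    noise = noise or NoiseRates()
    cells_per_met = cells_per_met if cells_per_met is not None else cells_per_region

    rng_tree = substream(seed, "tree")
    rng_mut = substream(seed, "mutations")
    rng_cells = substream(seed, "cells")
    rng_reads = substream(seed, "reads")
    rng_bulk = substream(seed, "bulk")

    # --- tree
    parent = _draw_tree_parents(n_clones, rng_tree)
    if seeding_mode == "polyclonal" and not _antichain_pairs(parent):
        # pure chain: re-root the deepest clone onto the trunk to create a branch
        parent[n_clones - 1] = 0
    nodes = list(range(n_clones))

    # --- private mutation counts: multinomial over clones, every clone kept
    # identifiable with at least one private mutation
    counts = rng_mut.multinomial(n_mutations, np.full(n_clones, 1.0 / n_clones))
    while (counts == 0).any() and n_mutations >= n_clones:
        counts[np.argmax(counts)] -= 1
        counts[np.argmin(counts)] += 1
    clone_of_site = np.repeat(np.arange(n_clones), counts)

    # --- site metadata
    n_sites = len(clone_of_site)
    site_ids = [f"s{i:04d}" for i in range(n_sites)]
    refs = rng_mut.choice(list(_BASES), size=n_sites)
    alts = np.array(
        [rng_mut.choice([b for b in _BASES if b != r]) for r in refs]
    )
    contexts = np.array(
        [
            rng_mut.choice(list(_BASES)) + r + rng_mut.choice(list(_BASES))
            for r in refs
        ]
    )
    genes = np.array([f"GENE{i // 3:04d}" for i in range(n_sites)], dtype=object)
    # clonal driver mutations live on the trunk, as in a real carcinoma
    trunk_sites = np.flatnonzero(clone_of_site == 0)
    for g, s in zip(driver_genes, trunk_sites):
        genes[s] = g
    sites = pd.DataFrame(
        {
            "gene": genes,
            "ref": refs,
            "alt": alts,
            "context": contexts,
            "chrom": [str(rng_mut.integers(1, 23)) for _ in range(n_sites)],
            "pos": np.sort(rng_mut.choice(np.arange(1, 50_000_000), n_sites, replace=False)),
            "candidate": True,
            "clone": clone_of_site,
        },
        index=pd.Index(site_ids, name="site"),
    )

    # clone genotype matrix: clone k carries private mutations of its ancestry
    ancestry_sets = {k: set() for k in nodes}
    for k in nodes:
        p = k
        while p is not None:
            ancestry_sets[k].add(p)
            p = parent[p]
    G = np.zeros((n_clones, n_sites), dtype=np.int8)
    for k in nodes:
        G[k] = np.isin(clone_of_site, list(ancestry_sets[k]))

    # --- regional structure: non-root clones homed round-robin across regions
    regions = [f"region-{i + 1}" for i in range(n_regions)]
    non_root = [n for n in nodes if n != 0]
    rng_cells.shuffle(non_root)
    home = {c: regions[i % n_regions] for i, c in enumerate(non_root)}

    # --- seeding truth
    depth_of = {k: len(ancestry_sets[k]) for k in nodes}
    if seeding_mode == "monoclonal":
        deepest = max(depth_of.values())
        candidates = sorted(k for k in non_root if depth_of[k] == deepest)
        c = int(rng_cells.choice(candidates))
        seeding_clones = frozenset({c})
    else:
        pairs = _antichain_pairs(parent)
        distinct = [p for p in pairs if home[p[0]] != home[p[1]]]
        a, b = (distinct or pairs)[int(rng_cells.integers(0, len(distinct or pairs)))]
        seeding_clones = frozenset({int(a), int(b)})
    source_regions = tuple(sorted({home[c] for c in seeding_clones}))

    # --- cell composition
    region_pool = {r: [c for c in non_root if home[c] == r] for r in regions}
    cell_rows = []
    for r in regions:
        pool = region_pool[r] or [0]
        for i in range(cells_per_region):
            clone = 0 if rng_cells.random() < trunk_weight else int(rng_cells.choice(pool))
            cell_rows.append((f"{r}-c{i:02d}", r, r, clone, False))
    seed_list = sorted(seeding_clones)
    for t in met_tissues:
        for i in range(cells_per_met):
            clone = int(seed_list[int(rng_cells.integers(0, len(seed_list)))])
            cell_rows.append((f"{t}-c{i:02d}", t, t, clone, True))
    cells = pd.DataFrame(
        cell_rows, columns=["cell", "tissue", "region", "clone", "is_met"]
    ).set_index("cell")

    truth = pd.DataFrame(
        G[cells["clone"].to_numpy()], index=cells.index, columns=sites.index
    )

    # --- prevalence truth (expected mixture weights aggregated up the tree)
    tissues = regions + list(met_tissues)
    weights = pd.DataFrame(0.0, index=tissues, columns=nodes)
    for r in regions:
        pool = region_pool[r] or [0]
        weights.loc[r, 0] += trunk_weight if region_pool[r] else 1.0
        for c in pool:
            if c != 0:
                weights.loc[r, c] += (1 - trunk_weight) / len(pool)
    for t in met_tissues:
        for c in seed_list:
            weights.loc[t, c] += 1.0 / len(seed_list)
    prevalence = pd.DataFrame(0.0, index=tissues, columns=nodes)
    for k in nodes:
        subtree = [m for m in nodes if k in ancestry_sets[m]]
        prevalence[k] = weights[subtree].sum(axis=1)
    tree = CloneTree(nodes, parent, {k: int(counts[k]) for k in nodes}, prevalence)
    tree.check_pigeonhole()
    seeding = SeedingTruth(seeding_mode, source_regions, seeding_clones)

    # --- reads
    n_cells = len(cells)
    p_nb = depth_dispersion / (depth_dispersion + mean_depth)
    depth = rng_reads.negative_binomial(depth_dispersion, p_nb, size=(n_cells, n_sites))
    tr = truth.to_numpy()
    template = tr.astype(np.int8)  # 0=RR, 1=RA (het somatic), 2=AA
    # ADO: one allele of a het template drops, chosen uniformly
    het = template == 1
    drop = het & (rng_reads.random(het.shape) < noise.ado)
    to_alt = rng_reads.random(het.shape) < 0.5
    template = np.where(drop & to_alt, 2, np.where(drop, 0, template)).astype(np.int8)
    # FP: a reference site is emitted as a spurious het call
    fp_hit = (tr == 0) & (rng_reads.random(tr.shape) < noise.fp)
    template = np.where(fp_hit, 1, template).astype(np.int8)
    p_alt = np.select(
        [template == 0, template == 1], [noise.seq_error, 0.5], 1.0 - noise.seq_error
    )
    alt = rng_reads.binomial(depth, p_alt)
    reads = ReadCountMatrix(list(cells.index), sites, depth - alt, alt)

    # --- controls (call level; disjoint from candidate sites by construction)
    controls = simulate_controls(
        list(cells.index), n_het_controls, n_hom_controls, noise, seed
    )

    # --- bulk VAFs: prevalence/2 for het mutations, binomial read sampling
    true_vaf = prevalence.loc[:, clone_of_site].to_numpy().T / 2.0  # sites x tissues
    alt_bulk = rng_bulk.binomial(bulk_depth, np.clip(true_vaf, 0.0, 1.0))
    bulk = pd.DataFrame(alt_bulk / bulk_depth, index=sites.index, columns=tissues)
    pooled = prevalence.loc[regions, clone_of_site].mean(axis=0).to_numpy() / 2.0
    bulk["primary"] = rng_bulk.binomial(bulk_depth, np.clip(pooled, 0, 1)) / bulk_depth

    params = dict(
        n_regions=n_regions,
        cells_per_region=cells_per_region,
        n_clones=n_clones,
        n_mutations=n_mutations,
        seeding_mode=seeding_mode,
        seed=int(seed),
        mean_depth=mean_depth,
        depth_dispersion=depth_dispersion,
        noise=asdict(noise),
    )
    return SimulatedCase(
        tree, seeding, truth, template, reads, controls, bulk, cells, noise, params
    )


def simulate_controls(
    cells: list[str] | int,
    n_het_sites: int,
    n_hom_sites: int,
    noise: NoiseRates,
    seed: int = 0,
    no_call_rate: float = 0.02,
) -> ControlSites:
    """Call-level control sites.  Het controls suffer ADO (-> confident
    homozygous call); hom-ref controls suffer FP (-> spurious non-ref call);
    a small fraction of sites is uninformative (no confident call)."""
    if isinstance(cells, int):
        cells = [f"cell-{i:03d}" for i in range(cells)]
    rng = substream(seed, "controls")
    n = len(cells)

    u = rng.random((n, n_het_sites))
    het = np.full((n, n_het_sites), HET, dtype=np.int8)
    het[u < no_call_rate] = NOCALL
    ado_hit = (u >= no_call_rate) & (u < no_call_rate + (1 - no_call_rate) * noise.ado)
    to_alt = rng.random((n, n_het_sites)) < 0.5
    het[ado_hit & to_alt] = HOMALT
    het[ado_hit & ~to_alt] = HOMREF

    u = rng.random((n, n_hom_sites))
    hom = np.full((n, n_hom_sites), HOMREF, dtype=np.int8)
    hom[u < no_call_rate] = NOCALL
    fp_hit = (u >= no_call_rate) & (u < no_call_rate + (1 - no_call_rate) * noise.fp)
    hom[fp_hit] = HET
    return ControlSites(list(cells), het, hom)


# ---------------------------------------------------------------------------
# expression cases


def simulate_expression_case(
    n_clusters: int = 8,
    cells: int = 50,
    n_genes: int = 1000,
    emt_effect: float = 1.0,
    cnv_profile: str | dict | None = None,
    seed: int = 0,
    *,
    n_met_cells: int = 150,
    n_emt_genes: int = 50,
    n_cnv_regions: int = 20,
    marker_frac: float = 0.05,
    marker_fold: float = 4.0,
    source_weight: float = 0.8,
    cnv_baseline: float = 1.0,
) -> ExpressionCase:
    """Planted-structure expression case for the transcriptome scores.

    ``cells`` is the number of primary cells per cluster.  Two designated
    source clusters contribute ``source_weight`` of the metastatic cells and
    carry the EMT elevation (``emt_effect`` added to the expected expression
    of the EMT gene set) plus non-neutral CNV regions; the recorded truth maps
    every metastatic cell to its source cluster.
    """
    if emt_effect < 0:
        raise ValueError("emt_effect must be >= 0")
    if n_emt_genes > n_genes:
        raise ValueError("EMT gene set larger than the gene universe")
    rng = substream(seed, "expression")
    genes = [f"g{i:04d}" for i in range(n_genes)]
    emt_genes = genes[:n_emt_genes]
    clusters = list(range(n_clusters))
    high_mc = clusters[: min(2, n_clusters)]  # planted metastasizing clusters

    base_mu = rng.gamma(2.0, 1.5, size=n_genes)
    n_markers = max(1, int(marker_frac * n_genes))
    # cluster markers never overlap the EMT set, so with emt_effect = 0 the
    # EMT genes are exchangeable across clusters
    marker_pool = np.arange(n_emt_genes, n_genes)
    marker_idx = {
        k: rng.choice(marker_pool, n_markers, replace=False) for k in clusters
    }

    def _mu(cluster: int) -> np.ndarray:
        mu = base_mu.copy()
        mu[marker_idx[cluster]] *= marker_fold
        if cluster in high_mc and emt_effect > 0:
            mu[:n_emt_genes] += emt_effect
        return mu

    rows, labels = [], []
    for k in clusters:
        mu = _mu(k)
        rows.append(rng.poisson(mu, size=(cells, n_genes)))
        labels += [k] * cells
    primary = pd.DataFrame(
        np.vstack(rows),
        index=[f"prim-{i:04d}" for i in range(n_clusters * cells)],
        columns=genes,
    )
    primary_clusters = pd.Series(labels, index=primary.index, name="cluster")

    probs = np.full(n_clusters, (1 - source_weight) / max(1, n_clusters - len(high_mc)))
    probs[high_mc] = source_weight / len(high_mc)
    probs /= probs.sum()
    src = rng.choice(clusters, size=n_met_cells, p=probs)
    met = pd.DataFrame(
        np.vstack([rng.poisson(_mu(int(k)), size=(1, n_genes)) for k in src]),
        index=[f"met-{i:04d}" for i in range(n_met_cells)],
        columns=genes,
    )
    truth = pd.DataFrame({"source_cluster": src}, index=met.index)

    # CNV matrix over all cells, centered on the neutral baseline
    all_cells = list(primary.index) + list(met.index)
    cell_cluster = np.concatenate([np.asarray(labels), src])
    cnv = np.full((len(all_cells), n_cnv_regions), float(cnv_baseline))
    if cnv_profile != "neutral":
        if cnv_profile is None or cnv_profile == "default":
            cnv_profile = {k: [(2 * i, 0.5), (2 * i + 1, -0.4)] for i, k in enumerate(high_mc)}
        for k, devs in cnv_profile.items():
            mask = cell_cluster == k
            for region_idx, delta in devs:
                cnv[mask, region_idx] = cnv_baseline + delta
    cnv += rng.normal(0, 0.02, cnv.shape) if cnv_profile != "neutral" else 0.0
    cnv_matrix = pd.DataFrame(
        cnv, index=all_cells, columns=[f"cnv_region_{i:02d}" for i in range(n_cnv_regions)]
    )

    return ExpressionCase(
        primary,
        primary_clusters,
        met,
        emt_genes,
        cnv_matrix,
        float(cnv_baseline),
        truth,
        params=dict(
            n_clusters=n_clusters,
            cells=cells,
            n_genes=n_genes,
            emt_effect=emt_effect,
            seed=int(seed),
            high_mc_clusters=list(high_mc),
        ),
    )


# ---------------------------------------------------------------------------
# fixtures on disk (plain TSV/JSON, round-trip exact)


def write_fixture(case, directory, overwrite: bool = False) -> list[str]:
    """Write a simulated case to a directory of plain-text files.

    Dispatches on the case type; refuses to write into an existing non-empty
    directory unless ``overwrite`` is set.  Returns the file names written.
    """
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(f"{directory} is not empty (pass overwrite=True)")
    directory.mkdir(parents=True, exist_ok=True)
    if isinstance(case, SimulatedCase):
        return _write_genotype_fixture(case, directory)
    if isinstance(case, ExpressionCase):
        return _write_expression_fixture(case, directory)
    raise TypeError(f"cannot write fixture for {type(case).__name__}")


def _write_genotype_fixture(case: SimulatedCase, d: Path) -> list[str]:
    r = case.reads
    n_cells, n_sites = r.ref.shape
    long = pd.DataFrame(
        {
            "cell": np.repeat(r.cells, n_sites),
            "site": np.tile(r.sites.index, n_cells),
            "ref_count": r.ref.ravel(),
            "alt_count": r.alt.ravel(),
        }
    )
    long.to_csv(d / "genotypes.tsv", sep="\t", index=False)
    r.sites.to_csv(d / "sites.tsv", sep="\t")
    case.cells.to_csv(d / "cells.tsv", sep="\t")
    ctrl = pd.DataFrame(
        np.hstack([case.controls.het_calls, case.controls.hom_calls]),
        index=pd.Index(case.controls.cells, name="cell"),
        columns=[f"het{i}" for i in range(case.controls.het_calls.shape[1])]
        + [f"hom{i}" for i in range(case.controls.hom_calls.shape[1])],
    )
    ctrl.to_csv(d / "controls.tsv", sep="\t")
    case.bulk_vaf.to_csv(d / "bulk_vaf.tsv", sep="\t")
    case.truth.to_csv(d / "truth_genotypes.tsv", sep="\t")
    truth = {
        "seeding": {
            "mode": case.seeding.mode,
            "source_regions": list(case.seeding.source_regions),
            "seeding_clones": sorted(case.seeding.seeding_clones),
        },
        "tree": {
            "nodes": case.tree.nodes,
            "parent": {str(k): v for k, v in case.tree.parent.items()},
            "mutations_per_clone": {
                str(k): v for k, v in case.tree.mutations_per_clone.items()
            },
            "prevalence": json.loads(case.tree.prevalence.to_json()),
        },
        "template": case.template.tolist(),
    }
    (d / "truth.json").write_text(json.dumps(truth, indent=1))
    (d / "manifest.json").write_text(json.dumps(case.params, indent=1))
    return [
        "genotypes.tsv", "sites.tsv", "cells.tsv", "controls.tsv",
        "bulk_vaf.tsv", "truth_genotypes.tsv", "truth.json", "manifest.json",
    ]


def _write_expression_fixture(case: ExpressionCase, d: Path) -> list[str]:
    case.primary_expr.to_csv(d / "expr_primary.tsv", sep="\t")
    case.met_expr.to_csv(d / "expr_met.tsv", sep="\t")
    case.primary_clusters.to_frame().to_csv(d / "clusters_primary.tsv", sep="\t")
    case.cnv_matrix.to_csv(d / "cnv.tsv", sep="\t")
    (d / "emt_genes.txt").write_text("\n".join(case.emt_genes) + "\n")
    case.truth.to_csv(d / "truth_expression.tsv", sep="\t")
    (d / "manifest.json").write_text(
        json.dumps({**case.params, "cnv_baseline": case.cnv_baseline}, indent=1)
    )
    return [
        "expr_primary.tsv", "expr_met.tsv", "clusters_primary.tsv",
        "cnv.tsv", "emt_genes.txt", "truth_expression.tsv", "manifest.json",
    ]


def read_fixture(directory):
    """Reconstruct a case written by :func:`write_fixture`."""
    d = Path(directory)
    if (d / "genotypes.tsv").exists():
        return _read_genotype_fixture(d)
    if (d / "expr_primary.tsv").exists():
        return _read_expression_fixture(d)
    raise FileNotFoundError(f"no recognizable fixture in {d}")


def _read_genotype_fixture(d: Path) -> SimulatedCase:
    manifest = json.loads((d / "manifest.json").read_text())
    truth_meta = json.loads((d / "truth.json").read_text())
    sites = pd.read_csv(d / "sites.tsv", sep="\t", index_col=0, dtype={"chrom": str})
    cells = pd.read_csv(d / "cells.tsv", sep="\t", index_col=0)
    long = pd.read_csv(d / "genotypes.tsv", sep="\t")
    cell_order = list(cells.index)
    ref = (
        long.pivot(index="cell", columns="site", values="ref_count")
        .loc[cell_order, sites.index]
        .to_numpy()
    )
    alt = (
        long.pivot(index="cell", columns="site", values="alt_count")
        .loc[cell_order, sites.index]
        .to_numpy()
    )
    reads = ReadCountMatrix(cell_order, sites, ref, alt)
    ctrl = pd.read_csv(d / "controls.tsv", sep="\t", index_col=0)
    het_cols = [c for c in ctrl.columns if c.startswith("het")]
    hom_cols = [c for c in ctrl.columns if c.startswith("hom")]
    controls = ControlSites(
        list(ctrl.index),
        ctrl[het_cols].to_numpy(dtype=np.int8),
        ctrl[hom_cols].to_numpy(dtype=np.int8),
    )
    bulk = pd.read_csv(d / "bulk_vaf.tsv", sep="\t", index_col=0)
    truth = pd.read_csv(d / "truth_genotypes.tsv", sep="\t", index_col=0)
    truth.columns.name = "site"
    tm = truth_meta["tree"]
    prev = pd.DataFrame(tm["prevalence"])
    prev.columns = prev.columns.astype(int)
    tree = CloneTree(
        [int(n) for n in tm["nodes"]],
        {int(k): (None if v is None else int(v)) for k, v in tm["parent"].items()},
        {int(k): int(v) for k, v in tm["mutations_per_clone"].items()},
        prev,
    )
    seeding = SeedingTruth(
        truth_meta["seeding"]["mode"],
        tuple(truth_meta["seeding"]["source_regions"]),
        frozenset(truth_meta["seeding"]["seeding_clones"]),
    )
    return SimulatedCase(
        tree,
        seeding,
        truth,
        np.asarray(truth_meta["template"], dtype=np.int8),
        reads,
        controls,
        bulk,
        cells,
        NoiseRates(**manifest["noise"]),
        manifest,
    )


def _read_expression_fixture(d: Path) -> ExpressionCase:
    manifest = json.loads((d / "manifest.json").read_text())
    baseline = manifest.pop("cnv_baseline")
    return ExpressionCase(
        pd.read_csv(d / "expr_primary.tsv", sep="\t", index_col=0),
        pd.read_csv(d / "clusters_primary.tsv", sep="\t", index_col=0)["cluster"],
        pd.read_csv(d / "expr_met.tsv", sep="\t", index_col=0),
        (d / "emt_genes.txt").read_text().split(),
        pd.read_csv(d / "cnv.tsv", sep="\t", index_col=0),
        float(baseline),
        pd.read_csv(d / "truth_expression.tsv", sep="\t", index_col=0),
        manifest,
    )
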