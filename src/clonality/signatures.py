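"""Mutational-signature extraction on the 96-class trinucleotide catalog.

Single-base substitutions are folded into the pyrimidine-centric convention
(6 substitution types C>A, C>G, C>T, T>A, T>C, T>G x 16 flanking contexts);
purine-reference mutations are reverse-complemented.  Signatures are
extracted by non-negative matrix factorization with multiplicative updates
minimizing the Frobenius norm; the number of processes K is chosen by
bootstrap signature stability (mean cosine silhouette of matched bootstrap
solutions) against the Frobenius reconstruction error on the original
catalog, scanned over a K range.  Discovered signatures are matched to a
reference catalogue by cosine similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .simdata import substream

__all__ = [
    "SUB_TYPES",
    "CLASSES_96",
    "build_96_catalog",
    "extract_signatures",
    "select_k",
    "match_signatures",
    "load_reference_signatures",
    "SignatureSolution",
    "nmf_multiplicative",
]

logger = logging.getLogger(__name__)

SUB_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: pyrimidine-centric class labels, lexicographic: substitution type, then
#: 5' base, then 3' base, e.g. "A[C>A]A"
CLASSES_96 = [
    f"{five}[{sub}]{three}"
    for sub in SUB_TYPES
    for five in _BASES
    for three in _BASES
]
_CLASS_INDEX = {c: i for i, c in enumerate(CLASSES_96)}


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def mutation_class(ref: str, alt: str, context: str) -> str:
    """96-class label for one substitution; purine refs are folded onto the
    reverse complement strand.  Raises ValueError on malformed input."""
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt or ref not in _BASES or alt not in _BASES:
        raise ValueError(f"malformed substitution {ref}>{alt}")
    if len(context) != 3 or any(b not in _BASES for b in context) or context[1] != ref:
        raise ValueError(f"context {context!r} does not match reference {ref!r}")
    if ref in "AG":
        ref, alt, context = _revcomp(ref), _revcomp(alt), _revcomp(context)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def build_96_catalog(mutations: pd.DataFrame, sample_col: str = "sample") -> pd.DataFrame:
    """Samples x 96 count matrix from a mutation list with ``ref``, ``alt``
    and trinucleotide ``context`` columns.

    Malformed records are rejected per row with a log entry; the total count
    of well-formed mutations is conserved.
    """
    samples = (
        sorted(mutations[sample_col].unique()) if len(mutations) else []
    )
    catalog = pd.DataFrame(
        0, index=pd.Index(samples, name=sample_col), columns=CLASSES_96, dtype=int
    )
    for row in mutations.itertuples(index=True):
        try:
            cls = mutation_class(row.ref, row.alt, row.context)
        except ValueError as exc:
            logger.warning("rejecting mutation record %s: %s", row.Index, exc)
            continue
        catalog.loc[getattr(row, sample_col), cls] += 1
    return catalog


# ---------------------------------------------------------------------------
# NMF


def nmf_multiplicative(
    V: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int = 1000,
    tol: float = 1e-6,
    assert_monotone: bool = True,
):
    """Multiplicative-update NMF minimizing ||V - W H||_F.

    V is (m, n) non-negative; returns W (m, k), H (k, n) and the final
    Frobenius error.  The objective is asserted non-increasing per iteration
    (up to float slack).  Stops when the relative objective change < tol.
    """
    V = np.asarray(V, dtype=float)
    if (V < 0).any():
        raise ValueError("NMF input must be non-negative")
    m, n = V.shape
    scale = np.sqrt(V.mean() / k) if V.mean() > 0 else 1.0
    W = rng.random((m, k)) * scale + 1e-4
    H = rng.random((k, n)) * scale + 1e-4
    eps = 1e-12
    prev = np.linalg.norm(V - W @ H)
    for _ in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + eps)
        W *= (V @ H.T) / (W @ (H @ H.T) + eps)
        err = np.linalg.norm(V - W @ H)
        if assert_monotone and err > prev * (1 + 1e-9) + 1e-12:
            raise AssertionError(
                f"multiplicative update increased the objective ({prev} -> {err})"
            )
        if prev > 0 and (prev - err) / prev < tol:
            prev = err
            break
        prev = err
    return W, H, float(prev)


def _normalize_solution(W: np.ndarray, H: np.ndarray):
    """Column-normalize signatures to probability vectors, rescaling exposures."""
    col = W.sum(axis=0)
    col = np.where(col > 0, col, 1.0)
    return W / col, H * col[:, None]


@dataclass
class SignatureSolution:
    k: int
    signatures: pd.DataFrame  # 96 x K, columns sum to 1
    exposures: pd.DataFrame  # K x samples, non-negative
    stability: np.ndarray  # per-signature, in [-1, 1]
    frobenius_error: float
    meta: dict = field(default_factory=dict)

    @property
    def mean_stability(self) -> float:
        return float(np.mean(self.stability))


def _cosine_sim(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    an = A / np.maximum(np.linalg.norm(A, axis=0, keepdims=True), 1e-12)
    bn = B / np.maximum(np.linalg.norm(B, axis=0, keepdims=True), 1e-12)
    return an.T @ bn


def _bootstrap_catalog(V: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-sample multinomial resampling of mutation classes."""
    out = np.zeros_like(V, dtype=float)
    for i, row in enumerate(V):
        total = int(row.sum())
        if total == 0:
            continue
        out[i] = rng.multinomial(total, row / row.sum())
    return out


def _stability(ref_sigs: np.ndarray, boot_sigs: list[np.ndarray]) -> np.ndarray:
    """Mean cosine silhouette per signature: bootstrap signature vectors are
    matched to their closest best-fit signature; silhouette uses cosine
    distance between cluster members and the cluster prototypes."""
    k = ref_sigs.shape[1]
    if k == 1:
        return np.ones(1)
    members: list[list[np.ndarray]] = [[] for _ in range(k)]
    for S in boot_sigs:
        sim = _cosine_sim(S, ref_sigs)  # (k_boot, k)
        for j in range(S.shape[1]):
            members[int(np.argmax(sim[j]))].append(S[:, j])
    sil = np.full(k, -1.0)
    for c in range(k):
        if not members[c]:
            continue
        vals = []
        for v in members[c]:
            sims = _cosine_sim(v[:, None], ref_sigs).ravel()
            a = 1 - sims[c]  # distance to own prototype
            b = np.min(np.delete(1 - sims, c))  # nearest other prototype
            vals.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
        sil[c] = float(np.mean(vals))
    return sil


def extract_signatures(
    catalog: pd.DataFrame,
    k_range=range(1, 16),
    n_resamples: int = 50,
    n_inits: int = 20,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
    min_gain: float = 0.1,
    stability_min: float = 0.8,
) -> tuple[dict[int, SignatureSolution], int]:
    """Scan K over ``k_range``; per K fit the original catalog from
    ``n_inits`` random initializations (best fit kept) and assess stability
    over ``n_resamples`` bootstrap catalogs.  Returns ({K: solution},
    selected K); see :func:`select_k` for the selection rule.
    """
    k_range = list(k_range)
    if not k_range or min(k_range) < 1 or max(k_range) > 15:
        raise ValueError("k_range must lie within [1, 15]")
    if n_inits < 2:
        raise ValueError("stability assessment needs n_inits >= 2")
    V = catalog.to_numpy(dtype=float).T  # 96 x samples
    if not (V.sum(axis=0) > 0).any():
        raise ValueError("catalog has no nonzero sample")

    solutions: dict[int, SignatureSolution] = {}
    for k in k_range:
        best = None
        for i in range(n_inits):
            rng = substream(seed, f"nmf-k{k}-init{i}")
            W, H, err = nmf_multiplicative(V, k, rng, max_iter, tol)
            if best is None or err < best[2]:
                best = (W, H, err)
        W, H, err = best
        W, H = _normalize_solution(W, H)

        boot_sigs = []
        for b in range(n_resamples):
            rng = substream(seed, f"nmf-k{k}-boot{b}")
            Vb = _bootstrap_catalog(V.T, rng).T
            if not (Vb.sum(axis=0) > 0).any():
                continue
            Wb, Hb, _ = nmf_multiplicative(Vb, k, rng, max_iter, tol)
            Wb, _ = _normalize_solution(Wb, Hb)
            boot_sigs.append(Wb)
        stab = _stability(W, boot_sigs)
        sig_cols = [f"Sig{chr(ord('A') + j)}" if k <= 26 else f"Sig{j}" for j in range(k)]
        solutions[k] = SignatureSolution(
            k,
            pd.DataFrame(W, index=catalog.columns, columns=sig_cols),
            pd.DataFrame(H, index=sig_cols, columns=catalog.index),
            stab,
            err,
            meta={"n_inits": n_inits, "n_resamples": n_resamples, "seed": int(seed)},
        )
    return solutions, select_k(solutions, min_gain, stability_min)


def select_k(
    solutions: dict[int, SignatureSolution],
    min_gain: float = 0.1,
    stability_min: float = 0.8,
) -> int:
    """Largest K that still earns its keep: K is supported when adding the
    K-th signature improves the Frobenius error over K-1 by at least
    ``min_gain`` (relative) and the bootstrap stability stays >=
    ``stability_min``.  The smallest scanned K is always supported."""
    ks = sorted(solutions)
    supported = [ks[0]]
    for prev, k in zip(ks, ks[1:]):
        err_prev = solutions[prev].frobenius_error
        gain = (err_prev - solutions[k].frobenius_error) / err_prev if err_prev > 0 else 0.0
        if gain >= min_gain and solutions[k].mean_stability >= stability_min:
            supported.append(k)
        else:
            break  # diminishing returns: stop at the first unsupported K
    return supported[-1]


def match_signatures(
    discovered: pd.DataFrame, reference: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    """Cosine similarity of discovered signatures (96 x K) against a
    reference catalogue (96 x N) over the same class labels.

    Returns (similarity matrix K x N, best reference match per discovered
    signature, hierarchical co-clustering labels over the pooled columns).
    """
    if list(discovered.index) != list(reference.index):
        raise ValueError("class labels of discovered and reference matrices differ")
    sim = pd.DataFrame(
        _cosine_sim(discovered.to_numpy(), reference.to_numpy()),
        index=discovered.columns,
        columns=reference.columns,
    )
    best = sim.idxmax(axis=1)
    pooled = np.hstack([discovered.to_numpy(), reference.to_numpy()])
    cos = _cosine_sim(pooled, pooled)
    dist = np.clip(1 - cos, 0, None)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform((dist + dist.T) / 2, checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=max(2, min(len(pooled[0]), reference.shape[1])), criterion="maxclust")
    return sim, best, labels


def simulate_catalog(
    n_signatures: int = 3,
    n_samples: int = 50,
    mutations_per_sample: int = 500,
    seed: int = 0,
    concentration: float = 1.5,
):
    """Planted-signature catalog: each true signature concentrates its mass
    on a distinct substitution-type block (making the processes well
    separated), exposures are Dirichlet, and per-sample counts are
    multinomial draws.  Returns (catalog, signatures 96 x K, exposures)."""
    if not (1 <= n_signatures <= 6):
        raise ValueError("n_signatures must lie in [1, 6] (one block per process)")
    rng = substream(seed, "planted-catalog")
    sigs = np.zeros((96, n_signatures))
    for j in range(n_signatures):
        w = rng.dirichlet(np.full(16, concentration))
        v = np.full(96, 1e-3)
        v[j * 16 : (j + 1) * 16] = w * 5.0
        sigs[:, j] = v / v.sum()
    expo = rng.dirichlet(np.ones(n_signatures), size=n_samples)
    V = np.vstack(
        [rng.multinomial(mutations_per_sample, expo[i] @ sigs.T) for i in range(n_samples)]
    )
    catalog = pd.DataFrame(
        V, index=[f"sample-{i:03d}" for i in range(n_samples)], columns=CLASSES_96
    )
    return catalog, sigs, expo


def load_reference_signatures() -> pd.DataFrame:
    """Small synthetic 5-signature reference catalogue bundled for matching
    tests and demos (96 x 5; columns sum to 1).  It is a stand-in generated
    from simple spectral archetypes, not a published catalogue."""
    with resources.files("clonality.fixtures").joinpath(
        "synthetic_reference_signatures.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", index_col=0)
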