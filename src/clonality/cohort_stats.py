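"""Exact contingency-table tests for clinical cohort tables.

``fisher_exact_2x2`` and ``fisher_exact_rxc`` compute the conditional-on-
margins exact two-sided p by the minimum-likelihood rule (sum the
probabilities of all margin-consistent tables no more probable than the
observed one) -- the convention of standard statistical packages.  The r x c
version enumerates every margin-consistent table and refuses when the
enumeration would be too large.

``pearson_chi2_rxc`` is the asymptotic Pearson chi-square test without
continuity correction.  The bundled TRPS1-by-stage cohort table mixes the
two conventions as published: Fisher exact for the 2x2 M-stage block and
Pearson chi-square for the larger stage blocks; ``reproduce_table1`` applies
exactly that pairing.
"""

from __future__ import annotations

import math
import warnings
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "fisher_exact_2x2",
    "fisher_exact_rxc",
    "pearson_chi2_rxc",
    "load_table1",
    "reproduce_table1",
]

# relative tolerance when comparing table probabilities (guards against
# float noise deciding "no more probable than observed")
_REL_TOL = 1e-7


def _validate(table) -> np.ndarray:
    t = np.asarray(table)
    if t.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("table entries must be integers")
        t = np.round(t).astype(np.int64)
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    return t.astype(np.int64)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (minimum-likelihood rule)."""
    t = _validate(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    r1, r2 = t.sum(axis=1)
    c1, _c2 = t.sum(axis=0)
    n = t.sum()
    if r1 == 0 or r2 == 0 or c1 == 0 or _c2 == 0:
        warnings.warn("empty margin: p = 1 by convention")
        return 1.0
    # x = entry (0, 0); hypergeometric over its support
    lo, hi = max(0, r1 - (n - c1)), min(r1, c1)
    xs = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(xs, n, r1, c1)
    p_obs = stats.hypergeom.pmf(t[0, 0], n, r1, c1)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + _REL_TOL)].sum()))


def _log_factorial(n: int) -> float:
    return math.lgamma(n + 1)


def _enumeration_bound(row_sums, n_cols) -> float:
    # product over rows of the number of weak compositions of the row sum
    b = 1.0
    for r in row_sums:
        b *= math.comb(int(r) + n_cols - 1, n_cols - 1)
    return b


def fisher_exact_rxc(table, max_tables: float = 5e6) -> float:
    """Exact two-sided p for an r x c table by complete enumeration.

    All-zero rows and columns are dropped (with a warning).  Reduces exactly
    to :func:`fisher_exact_2x2` on 2x2 input.  Refuses tables whose
    enumeration bound exceeds ``max_tables``.
    """
    t = _validate(table)
    zero_rows = t.sum(axis=1) == 0
    zero_cols = t.sum(axis=0) == 0
    if zero_rows.any() or zero_cols.any():
        warnings.warn("dropping all-zero rows/columns before the exact test")
        t = t[~zero_rows][:, ~zero_cols]
    if t.size == 0 or t.shape[0] < 2 or t.shape[1] < 2:
        warnings.warn("fewer than 2 non-empty rows/columns: p = 1 by convention")
        return 1.0
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    n = int(t.sum())
    bound = _enumeration_bound(row_sums, t.shape[1])
    if bound > max_tables:
        raise ValueError(
            f"enumeration bound {bound:.3g} exceeds cap {max_tables:.3g}; "
            "table too large for the exact test"
        )

    log_const = (
        sum(_log_factorial(r) for r in row_sums)
        + sum(_log_factorial(c) for c in col_sums)
        - _log_factorial(n)
    )

    def log_prob(cells) -> float:
        return log_const - sum(_log_factorial(x) for x in cells)

    p_obs = math.exp(log_prob(t.ravel()))
    threshold = p_obs * (1 + _REL_TOL)
    r, c = t.shape
    total = 0.0

    # depth-first enumeration over rows; each row is a bounded composition
    def fill_row(i, remaining_cols, acc_cells):
        nonlocal total
        if i == r - 1:
            cells = acc_cells + list(remaining_cols)
            p = math.exp(log_prob(cells))
            if p <= threshold:
                total += p
            return
        row = row_sums[i]

        def fill_cell(j, remaining_row, cols, cells):
            if j == c - 1:
                if remaining_row <= cols[j]:
                    nc = list(cols)
                    nc[j] -= remaining_row
                    fill_row(i + 1, nc, cells + [remaining_row])
                return
            # leave enough for later columns of this row
            hi = min(remaining_row, cols[j])
            for x in range(hi + 1):
                nc = list(cols)
                nc[j] -= x
                fill_cell(j + 1, remaining_row - x, nc, cells + [x])

        fill_cell(0, int(row), remaining_cols, acc_cells)

    fill_row(0, list(col_sums), [])
    return float(min(1.0, total))


def pearson_chi2_rxc(table) -> float:
    """Pearson chi-square p (no continuity correction); zero rows/cols dropped."""
    t = _validate(table)
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        warnings.warn("fewer than 2 non-empty rows/columns: p = 1 by convention")
        return 1.0
    res = stats.chi2_contingency(t, correction=False)
    return float(res.pvalue)


def load_table1() -> pd.DataFrame:
    """The bundled TRPS1-status-by-pathological-stage cohort table
    (107 colorectal tumors; counts of TRPS1 wild-type vs mutated per stage)."""
    with resources.files("clonality.fixtures").joinpath("table1.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def reproduce_table1(table: pd.DataFrame | None = None) -> dict[str, float]:
    """Per stage block: Fisher exact for 2x2 blocks, Pearson chi-square for
    larger blocks (the published convention for this cohort)."""
    table = load_table1() if table is None else table
    out = {}
    for block, grp in table.groupby("block", sort=False):
        counts = grp[["wild_type", "mutation"]].to_numpy()
        nonzero = counts[counts.sum(axis=1) > 0]
        if nonzero.shape == (2, 2):
            out[str(block)] = fisher_exact_2x2(nonzero)
        else:
            out[str(block)] = pearson_chi2_rxc(counts)
    return out
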