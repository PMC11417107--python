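"""Per-cell false-positive (FP) and allele-dropout (ADO) rate estimation.

Both estimators operate on control-site calls:

* FP — at confident homozygous-reference sites, any non-reference call is a
  false positive; per-cell rate = non-ref calls / informative hom sites.
  The cohort summary is the *mean* over cells.
* ADO — at known germline-heterozygous sites, a confident homozygous call is
  a dropout event; per-cell rate = homozygous calls / het sites with a
  confident call.  The cohort summary is the *median* over cells.

Sites without a confident call (no-calls) are excluded from denominators.
Cells with zero informative sites carry NaN and are excluded from the cohort
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simdata import ControlSites, HET, HOMALT, HOMREF, NOCALL

__all__ = ["RateEstimates", "estimate_fp_rate", "estimate_ado_rate", "estimate_rates"]


@dataclass
class RateEstimates:
    per_cell: pd.DataFrame  # index cell; columns rate, n_informative, n_events
    cohort: float
    kind: str  # "fp" | "ado"


def estimate_fp_rate(controls: ControlSites, min_depth: int = 5) -> RateEstimates:
    """FP rate from homozygous-reference control sites.

    ``min_depth`` is part of the call-confidence contract: control calls are
    assumed to be confident calls at depth >= min_depth; no-calls encode the
    sites that failed it.
    """
    calls = controls.hom_calls
    informative = (calls != NOCALL).sum(axis=1)
    events = ((calls == HET) | (calls == HOMALT)).sum(axis=1)
    return _build(controls.cells, informative, events, kind="fp")


def estimate_ado_rate(controls: ControlSites, min_depth: int = 5) -> RateEstimates:
    """ADO rate from germline-heterozygous control sites (confident homozygous
    calls at such sites are dropout events)."""
    calls = controls.het_calls
    informative = (calls != NOCALL).sum(axis=1)
    events = ((calls == HOMREF) | (calls == HOMALT)).sum(axis=1)
    return _build(controls.cells, informative, events, kind="ado")


def _build(cells, informative, events, kind: str) -> RateEstimates:
    if (informative == 0).all():
        raise ValueError(f"no informative control sites in any cell ({kind} estimate)")
    with np.errstate(invalid="ignore"):
        rate = np.where(informative > 0, events / np.maximum(informative, 1), np.nan)
    per_cell = pd.DataFrame(
        {"rate": rate, "n_informative": informative, "n_events": events},
        index=pd.Index(cells, name="cell"),
    )
    valid = per_cell["rate"].dropna()
    cohort = float(valid.mean() if kind == "fp" else valid.median())
    return RateEstimates(per_cell, cohort, kind)


def estimate_rates(controls: ControlSites, min_depth: int = 5) -> pd.DataFrame:
    """Convenience: per-cell FP and ADO rates side by side, plus the cohort
    row (mean FP, median ADO)."""
    fp = estimate_fp_rate(controls, min_depth)
    ado = estimate_ado_rate(controls, min_depth)
    out = pd.DataFrame(
        {
            "fp_rate": fp.per_cell["rate"],
            "fp_n": fp.per_cell["n_informative"],
            "ado_rate": ado.per_cell["rate"],
            "ado_n": ado.per_cell["n_informative"],
        }
    )
    out.loc["cohort"] = [fp.cohort, fp.per_cell["n_informative"].sum(),
                         ado.cohort, ado.per_cell["n_informative"].sum()]
    return out
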