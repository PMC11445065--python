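"""Competitive-index and reporter arithmetic for in vivo fitness experiments.

Two strains (wild type and mutant) are co-inoculated; at each sampling the
mutant load is counted on a selective plate and the wild-type load derived
from the antibiotic-free total plate (cfu_WT = cfu_total - cfu_mutant).  The
normalized competitive index

    C.I. = (cfu_mutant / cfu_WT) / (inoc_mutant / inoc_WT)

equals 1 for a fitness-neutral mutation.  Barcoded sub-populations get their
absolute load as (qPCR relative density) x (selective-plate cfu).  Reporter
fluorescence is corrected by autofluorescence subtraction and normalized to
optical density.  Group comparisons use the two-tailed Mann-Whitney U test,
with group medians (never raw-scale means) as the summary statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregate import MWUResult, mann_whitney_u, significance_band


@dataclass
class CIResult:
    ci: float
    flags: tuple[str, ...] = ()


def wt_from_total(cfu_total: float, cfu_mutant: float) -> float:
    """Wild-type load from the antibiotic-free plate: cfu_total - cfu_mutant.

    A mutant count exceeding the total is a counting inconsistency and is an
    error, never silently clamped.
    """
    if cfu_total < 0 or cfu_mutant < 0:
        raise ValueError("cfu counts must be non-negative")
    if cfu_mutant > cfu_total:
        raise ValueError(
            f"cfu_mutant ({cfu_mutant:g}) exceeds cfu_total ({cfu_total:g}): "
            "counting inconsistency"
        )
    return cfu_total - cfu_mutant


def normalized_ci(
    cfu_mutant: float,
    cfu_wt: float,
    inoc_mutant_frac: float,
    inoc_wt_frac: float,
    pseudocount: float = 0.0,
) -> CIResult:
    """(cfu_mutant / cfu_WT) / (inoc_mutant / inoc_WT).

    A zero mutant count yields C.I. = 0 flagged ``below_detection`` (or uses
    ``pseudocount`` when one is supplied); a zero wild-type count is
    undefined and flagged.
    """
    if inoc_mutant_frac <= 0 or inoc_wt_frac <= 0:
        raise ValueError("inoculum fractions must be positive")
    if cfu_mutant < 0 or cfu_wt < 0:
        raise ValueError("cfu counts must be non-negative")
    inoc_ratio = inoc_mutant_frac / inoc_wt_frac
    if cfu_wt == 0:
        return CIResult(float("nan"), flags=("wt_below_detection",))
    if cfu_mutant == 0:
        if pseudocount > 0:
            return CIResult(
                (pseudocount / cfu_wt) / inoc_ratio, flags=("pseudocounted",)
            )
        return CIResult(0.0, flags=("below_detection",))
    return CIResult((cfu_mutant / cfu_wt) / inoc_ratio)


def barcode_load(rel_density: float, cfu_plate: float) -> float:
    """Absolute load of one barcoded strain: qPCR fraction x plate cfu."""
    if rel_density < 0 or cfu_plate < 0:
        raise ValueError("inputs must be non-negative")
    if rel_density > 1:
        raise ValueError(f"rel_density {rel_density} exceeds 1")
    return rel_density * cfu_plate


@dataclass
class ReporterMeasurement:
    fluorescence: float
    od: float
    autofluorescence: float


def reporter_normalize(m: ReporterMeasurement) -> tuple[float, tuple[str, ...]]:
    """(fluorescence - autofluorescence) / OD, floored at 0 with a flag when
    the autofluorescence control exceeds the signal."""
    if m.od <= 0:
        raise ValueError("optical density must be positive")
    v = (m.fluorescence - m.autofluorescence) / m.od
    if v < 0:
        return 0.0, ("negative_floored",)
    return v, ()


def ci_table(plating: pd.DataFrame, pseudocount: float = 0.0) -> pd.DataFrame:
    """Per-observation C.I. from a plating table with columns subject_id,
    day, cfu_total, cfu_mutant, inoc_mutant_frac, inoc_wt_frac."""
    rows = []
    for r in plating.itertuples():
        wt = wt_from_total(r.cfu_total, r.cfu_mutant)
        res = normalized_ci(
            r.cfu_mutant, wt, r.inoc_mutant_frac, r.inoc_wt_frac,
            pseudocount=pseudocount,
        )
        rows.append(
            dict(
                subject_id=r.subject_id,
                day=r.day,
                cfu_mutant=r.cfu_mutant,
                cfu_wt=wt,
                ci=res.ci,
                flags=",".join(res.flags),
            )
        )
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    median_a: float
    median_b: float
    n_a: int
    n_b: int
    u: float
    p: float
    band: str


def compare_ci_groups(ci_a, ci_b) -> GroupComparison:
    """Two-tailed Mann-Whitney comparison of two C.I. groups, with the
    significance bands used in figure legends (NS / * / ** / ***)."""
    a, b = list(ci_a), list(ci_b)
    r: MWUResult = mann_whitney_u(a, b)
    return GroupComparison(
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        n_a=len(a),
        n_b=len(b),
        u=r.u,
        p=r.p,
        band=significance_band(r.p),
    )
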