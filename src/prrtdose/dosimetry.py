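"""MIRD-schema dose engine.

dose(target) = sum over sources of TIAC(source) * S(target <- source)

with S-values (mGy per MBq h) tabulated for a phantom geometry.  S-value
tables are an *input*: the engine is phantom-agnostic and ships only a small
synthetic toy matrix for testing.  The remainder-of-body source uses the
standard mass-weighted adjustment of the total-body S-value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SMatrix",
    "DoseCoefficientReport",
    "CohortSummary",
    "ToxicityResult",
    "remainder_s_value",
    "dose_coefficients",
    "scale_to_administered",
    "round_dose_gy",
    "cohort_mean_sd",
    "toxicity_check",
    "DEFAULT_DOSE_LIMITS_GY",
]

TOTAL_BODY = "total_body"

#: Critical-organ cumulative dose limits in Gy (kidneys: 23 Gy).
DEFAULT_DOSE_LIMITS_GY: dict[str, float] = {"kidneys": 23.0}


@dataclass(frozen=True)
class SMatrix:
    """Target x source dose-factor table with phantom organ masses.

    ``values`` is indexed by target region (rows) with source regions as
    columns, in mGy per MBq h; ``masses_kg`` maps every source region plus
    ``total_body`` to its phantom mass.
    """

    phantom: str
    values: pd.DataFrame
    masses_kg: dict[str, float]

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("S-values must be >= 0")
        missing = [c for c in self.values.columns if c not in self.masses_kg]
        if missing:
            raise ValueError(f"S-matrix source columns without a mass: {missing}")
        if TOTAL_BODY not in self.masses_kg:
            raise ValueError("masses must include total_body")
        for region, s in self.values.iterrows():
            if region in self.values.columns:
                cross = s.drop(region)
                if len(cross) and s[region] < cross.max():
                    warnings.warn(
                        f"self-dose S({region}<-{region}) below a cross-dose term; "
                        "unusual for a beta-dominated nuclide", stacklevel=2,
                    )

    @property
    def targets(self) -> list[str]:
        return list(self.values.index)

    @property
    def sources(self) -> list[str]:
        return list(self.values.columns)

    def s(self, target: str, source: str) -> float:
        return float(self.values.at[target, source])

    @classmethod
    def from_csv(cls, values_path: str | Path, masses_path: str | Path, phantom: str = "") -> "SMatrix":
        """Load from the canonical CSV layout.

        ``values_path``: first column is the target region, remaining
        columns are sources (units mGy per MBq h, declared in a ``#`` header
        comment).  ``masses_path``: two columns, region and mass_kg.
        """
        values = pd.read_csv(values_path, comment="#", index_col=0)
        masses = pd.read_csv(masses_path, comment="#")
        masses_kg = dict(zip(masses.iloc[:, 0], masses.iloc[:, 1].astype(float)))
        return cls(phantom or Path(values_path).stem, values, masses_kg)


@dataclass(frozen=True)
class DoseCoefficientReport:
    """Per-target absorbed dose coefficients (mGy/MBq) for one subject."""

    subject_id: str
    coefficients_mgy_per_mbq: dict[str, float]
    s_matrix: str = ""
    tiac_set: str = ""

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.coefficients_mgy_per_mbq.items() if v < 0}
        if bad:
            raise ValueError(f"dose coefficients must be >= 0: {bad}")


@dataclass(frozen=True)
class CohortSummary:
    """Cohort mean and sample SD (n-1 denominator) per target region."""

    mean: dict[str, float]
    sd: dict[str, float]
    n: int
    excluded: tuple[str, ...] = ()


@dataclass(frozen=True)
class ToxicityResult:
    organ: str
    dose_gy: float
    limit_gy: float | None
    passed: bool | None  # None = no limit on record
    margin_gy: float | None


def remainder_s_value(
    s_matrix: SMatrix, target: str, explicit_sources: Sequence[str]
) -> float:
    """S(target <- remainder of body) by mass-weighted subtraction.

    S(t<-RoB) = [S(t<-TB) m_TB - sum_k S(t<-k) m_k] / m_RoB,
    m_RoB = m_TB - sum_k m_k.  Negative results are floored at zero with a
    warning (can occur when the explicit organs receive most of the
    total-body dose).
    """
    m_tb = s_matrix.masses_kg[TOTAL_BODY]
    m_sources = sum(s_matrix.masses_kg[k] for k in explicit_sources)
    m_rob = m_tb - m_sources
    if m_rob <= 0:
        raise ValueError(f"remainder mass must be > 0, got {m_rob} kg")
    numerator = s_matrix.s(target, TOTAL_BODY) * m_tb - sum(
        s_matrix.s(target, k) * s_matrix.masses_kg[k] for k in explicit_sources
    )
    s_rob = numerator / m_rob
    if s_rob < 0:
        warnings.warn(f"negative remainder S-value for target {target} floored at 0", stacklevel=2)
        s_rob = 0.0
    return s_rob


def dose_coefficients(
    tiacs: Mapping[str, float] | "object",
    s_matrix: SMatrix,
    subject_id: str = "",
) -> DoseCoefficientReport:
    """Fold source-organ TIACs with the S-matrix into target dose coefficients.

    ``tiacs`` maps source region to TIAC in hours (a
    :class:`~prrtdose.organs.SourceOrganSet` is accepted too).  The
    ``whole_body`` entry is bookkeeping, not a source; ``remainder`` uses
    the adjusted remainder S-value.
    """
    if hasattr(tiacs, "tiacs"):  # SourceOrganSet
        subject_id = subject_id or tiacs.subject_id
        tiacs = {k: v.value_h for k, v in tiacs.tiacs.items()}
    sources = {k: v for k, v in tiacs.items() if k != "whole_body"}
    explicit = [k for k in sources if k != "remainder"]
    unmapped = [k for k in explicit if k not in s_matrix.sources]
    if unmapped:
        raise ValueError(f"TIAC source regions not in the S-matrix: {unmapped}")
    coeffs: dict[str, float] = {}
    for target in s_matrix.targets:
        d = sum(sources[k] * s_matrix.s(target, k) for k in explicit)
        if "remainder" in sources:
            d += sources["remainder"] * remainder_s_value(s_matrix, target, explicit)
        coeffs[target] = d
    return DoseCoefficientReport(subject_id, coeffs, s_matrix.phantom)


def scale_to_administered(
    report: DoseCoefficientReport | Mapping[str, float], activity_mbq: float
) -> dict[str, float]:
    """Absorbed dose in Gy per target for an administered activity in MBq.

    dose_Gy = coefficient_mGy_per_MBq * activity_MBq / 1000.
    """
    if activity_mbq <= 0:
        raise ValueError(f"administered activity must be > 0 MBq, got {activity_mbq}")
    coeffs = (
        report.coefficients_mgy_per_mbq if isinstance(report, DoseCoefficientReport) else report
    )
    return {organ: c * activity_mbq / 1000.0 for organ, c in coeffs.items()}


def round_dose_gy(dose_gy: float) -> float:
    """Reporting precision for human doses: 3 significant figures at or
    above 10 Gy, 2 below (so 13.65 -> 13.7 and 3.945 -> 3.9)."""
    if dose_gy == 0:
        return 0.0
    sig = 3 if abs(dose_gy) >= 10 else 2
    return float(f"{dose_gy:.{sig}g}")


def cohort_mean_sd(
    values: Mapping[str, float], exclude: Iterable[str] = ()
) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n-1) over subjects, with exclusions.

    Returns ``(mean, sd)``; requires at least two subjects after exclusion.
    """
    excl = set(exclude)
    kept = [v for k, v in values.items() if k not in excl]
    if len(kept) < 2:
        raise ValueError(f"cohort SD needs n >= 2 after exclusions, got n = {len(kept)}")
    arr = np.asarray(kept, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1))


def summarize_cohort(
    reports: Sequence[DoseCoefficientReport], exclude: Iterable[str] = ()
) -> CohortSummary:
    """Per-target cohort mean +- sample SD over subject dose reports."""
    excl = tuple(exclude)
    kept = [r for r in reports if r.subject_id not in excl]
    if len(kept) < 2:
        raise ValueError("cohort summary needs n >= 2 after exclusions")
    targets = kept[0].coefficients_mgy_per_mbq.keys()
    mean, sd = {}, {}
    for t in targets:
        vals = {r.subject_id: r.coefficients_mgy_per_mbq[t] for r in kept}
        mean[t], sd[t] = cohort_mean_sd(vals)
    return CohortSummary(mean, sd, len(kept), excluded=excl)


def toxicity_check(
    doses_gy: Mapping[str, float],
    limits_gy: Mapping[str, float] | None = None,
) -> dict[str, ToxicityResult]:
    """Compare cumulative organ doses against critical-organ limits.

    Boundary inclusive: a dose equal to the limit fails.  Organs without a
    limit on record are reported as unchecked (``passed is None``).
    """
    limits = DEFAULT_DOSE_LIMITS_GY if limits_gy is None else dict(limits_gy)
    if not limits:
        raise ValueError("limits table must be non-empty")
    out: dict[str, ToxicityResult] = {}
    for organ, dose in doses_gy.items():
        if dose < 0:
            raise ValueError(f"negative dose for {organ}: {dose}")
        limit = limits.get(organ)
        if limit is None:
            out[organ] = ToxicityResult(organ, dose, None, None, None)
        else:
            out[organ] = ToxicityResult(organ, dose, limit, dose < limit, limit - dose)
    return out
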