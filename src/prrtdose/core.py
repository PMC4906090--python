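"""Domain types, radionuclide physics and decay/unit conventions.

All times are hours post-injection internally; all activities are fractions
of the injected activity (blood concentrations are fractions per litre).
Readers accept minutes/days and percent units and convert on ingest.

Measured activities come in two decay conventions: *uncorrected* values
include physical radioactive decay (what a gamma counter reads, corrected
only to the time of sampling), while *decay-corrected* values are referred
back to the time of injection and describe biology alone.  Every time series
carries an explicit flag so the two are never mixed silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RadionuclidePhysics",
    "LU177",
    "ActivitySample",
    "OrganTAC",
    "Subject",
    "REGIONS",
    "ACTIVITY_UNITS",
    "decay_factor",
    "convert_decay_convention",
    "read_tac_csv",
    "write_tac_csv",
]

#: Controlled vocabulary of source-region labels.
REGIONS = frozenset(
    {
        "whole_body",
        "remainder",
        "liver",
        "kidney_left",
        "kidney_right",
        "kidneys",
        "heart",
        "bladder_contents",
        "spine",
        "bone",
        "red_marrow",
        "blood",
    }
)

ACTIVITY_UNITS = frozenset({"fraction_IA", "percent_IA", "percent_IA_per_L", "fraction_IA_per_L"})

_TIME_TO_HOURS = {"h": 1.0, "hours": 1.0, "min": 1.0 / 60.0, "minutes": 1.0 / 60.0, "d": 24.0, "days": 24.0}


@dataclass(frozen=True)
class RadionuclidePhysics:
    """Physical decay data for one radionuclide.

    Parameters
    ----------
    name : str
        Nuclide label, e.g. ``"Lu-177"``.
    half_life_h : float
        Physical half-life in hours.
    photon_emissions : tuple of (float, float)
        ``(energy_keV, probability_per_decay)`` pairs for the photons
        relevant to quantitative imaging.
    """

    name: str
    half_life_h: float
    photon_emissions: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if not self.half_life_h > 0:
            raise ValueError(f"half_life_h must be positive, got {self.half_life_h}")
        for energy, prob in self.photon_emissions:
            if not (0 < prob <= 1):
                raise ValueError(f"emission probability must be in (0, 1], got {prob}")
            if energy <= 0:
                raise ValueError(f"photon energy must be positive, got {energy}")

    @property
    def decay_constant(self) -> float:
        """Physical decay constant lambda = ln(2) / T_half, per hour."""
        return math.log(2.0) / self.half_life_h


#: Lu-177: beta emitter, 6.647 d half-life, gammas at 208.3 keV (10.38%)
#: and 112.9 keV (6.2%) used for SPECT quantification.
LU177 = RadionuclidePhysics(
    name="Lu-177",
    half_life_h=6.647 * 24.0,
    photon_emissions=((208.3, 0.1038), (112.9, 0.062)),
)


@dataclass(frozen=True)
class ActivitySample:
    """One measurement: fractional activity at a time post-injection."""

    time_h: float
    value: float
    decay_corrected: bool = True

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValueError(f"sample time must be >= 0, got {self.time_h}")
        if self.value < 0:
            raise ValueError(f"sample value must be >= 0, got {self.value}")


@dataclass(frozen=True)
class OrganTAC:
    """Time-activity curve for one source region of one subject."""

    subject_id: str
    organ: str
    samples: tuple[ActivitySample, ...]
    unit: str = "fraction_IA"

    def __post_init__(self) -> None:
        if self.organ not in REGIONS:
            raise ValueError(
                f"unknown region {self.organ!r}; accepted labels: {sorted(REGIONS)}"
            )
        if self.unit not in ACTIVITY_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; accepted: {sorted(ACTIVITY_UNITS)}")
        times = [s.time_h for s in self.samples]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"samples must be strictly increasing in time, got {times}")
        flags = {s.decay_corrected for s in self.samples}
        if len(flags) > 1:
            raise ValueError("all samples in a TAC must share one decay-correction convention")

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time_h for s in self.samples], dtype=float)

    @property
    def values(self) -> np.ndarray:
        return np.array([s.value for s in self.samples], dtype=float)

    @property
    def decay_corrected(self) -> bool:
        if not self.samples:
            raise ValueError("empty TAC has no decay convention")
        return self.samples[0].decay_corrected

    def as_fraction(self) -> "OrganTAC":
        """Return a copy with percent units converted to fractional units."""
        if self.unit in ("fraction_IA", "fraction_IA_per_L"):
            return self
        new_unit = "fraction_IA" if self.unit == "percent_IA" else "fraction_IA_per_L"
        samples = tuple(replace(s, value=s.value / 100.0) for s in self.samples)
        return replace(self, samples=samples, unit=new_unit)

    def with_values(self, values: Iterable[float], decay_corrected: bool | None = None) -> "OrganTAC":
        dc = self.decay_corrected if decay_corrected is None else decay_corrected
        samples = tuple(
            ActivitySample(s.time_h, v, dc) for s, v in zip(self.samples, values, strict=True)
        )
        return replace(self, samples=samples)


def tac_from_arrays(
    subject_id: str,
    organ: str,
    times_h: Sequence[float],
    values: Sequence[float],
    *,
    unit: str = "fraction_IA",
    decay_corrected: bool = True,
) -> OrganTAC:
    """Build an :class:`OrganTAC` from parallel time/value sequences."""
    samples = tuple(
        ActivitySample(float(t), float(v), decay_corrected)
        for t, v in zip(times_h, values, strict=True)
    )
    return OrganTAC(subject_id=subject_id, organ=organ, samples=samples, unit=unit)


@dataclass(frozen=True)
class Subject:
    """Study subject: injection and anthropometric data plus schedules."""

    subject_id: str
    injected_activity_mbq: float
    body_mass_kg: float
    amino_acid_infusion: bool = True
    blood_times_h: tuple[float, ...] = ()
    imaging_times_h: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.injected_activity_mbq > 0:
            raise ValueError("injected_activity_mbq must be > 0")
        if not self.body_mass_kg > 0:
            raise ValueError("body_mass_kg must be > 0")


def decay_factor(physics: RadionuclidePhysics, t_h: float | np.ndarray) -> float | np.ndarray:
    """Fraction of atoms surviving after ``t_h`` hours: exp(-lambda t), in (0, 1].

    Raises
    ------
    ValueError
        If any time is negative.
    """
    t = np.asarray(t_h, dtype=float)
    if np.any(t < 0):
        raise ValueError(f"time must be >= 0, got {t_h}")
    out = np.exp(-physics.decay_constant * t)
    return float(out) if np.isscalar(t_h) or t.ndim == 0 else out


def convert_decay_convention(
    tac: OrganTAC, physics: RadionuclidePhysics, target_convention: str
) -> OrganTAC:
    """Convert a TAC between the two decay conventions.

    ``target_convention`` is ``"corrected"`` (referred to injection time,
    physical decay removed) or ``"uncorrected"`` (decay left in).  The
    conversion is exact: uncorrected(t) = corrected(t) * exp(-lambda t).
    """
    if target_convention not in ("corrected", "uncorrected"):
        raise ValueError(
            f"unknown convention {target_convention!r}; use 'corrected' or 'uncorrected'"
        )
    want_corrected = target_convention == "corrected"
    if tac.decay_corrected == want_corrected:
        return tac
    f = decay_factor(physics, tac.times)
    values = tac.values * f if not want_corrected else tac.values / f
    return tac.with_values(values, decay_corrected=want_corrected)


# ---------------------------------------------------------------------------
# TAC table I/O
#
# CSV layout: one row per sample with columns
#   subject_id, organ, time, time_unit, value, value_unit, decay_corrected

def read_tac_csv(path: str | Path) -> list[OrganTAC]:
    """Read a TAC table; times converted to hours, percent values to fractions."""
    df = pd.read_csv(path, comment="#")
    required = {"subject_id", "organ", "time", "time_unit", "value", "value_unit", "decay_corrected"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"TAC CSV missing columns: {sorted(missing)}")
    df = df.assign(_time_h=[t * _lookup_time_unit(u) for t, u in zip(df["time"], df["time_unit"])])
    tacs: list[OrganTAC] = []
    for (sid, organ), grp in df.groupby(["subject_id", "organ"], sort=False):
        grp = grp.sort_values("_time_h")
        times = grp["_time_h"].to_list()
        units = set(grp["value_unit"])
        if len(units) > 1:
            raise ValueError(f"mixed value units for {sid}/{organ}: {sorted(units)}")
        (unit,) = units
        flags = set(grp["decay_corrected"].astype(bool))
        if len(flags) > 1:
            raise ValueError(f"mixed decay conventions for {sid}/{organ}")
        tac = tac_from_arrays(
            str(sid), str(organ), times, grp["value"].to_list(),
            unit=str(unit), decay_corrected=flags.pop(),
        )
        tacs.append(tac.as_fraction())
    return tacs


def _lookup_time_unit(unit: str) -> float:
    try:
        return _TIME_TO_HOURS[unit]
    except KeyError:
        raise ValueError(f"unknown time unit {unit!r}; accepted: {sorted(_TIME_TO_HOURS)}") from None


def write_tac_csv(tacs: Iterable[OrganTAC], path: str | Path) -> None:
    """Write TACs in the canonical CSV layout (hours, declared units)."""
    rows = [
        {
            "subject_id": tac.subject_id,
            "organ": tac.organ,
            "time": s.time_h,
            "time_unit": "h",
            "value": s.value,
            "value_unit": tac.unit,
            "decay_corrected": s.decay_corrected,
        }
        for tac in tacs
        for s in tac.samples
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
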