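"""Transcribed measurements from the five-pig Lu-177-OPS201 study.

The per-subject TIACs and absorbed-dose coefficients reported by the study
are shipped as CSV fixtures for regression checks of the arithmetic layers
(kidney summation, spine-to-bone scaling, remainder reconstruction, cohort
statistics, human-dose extrapolation).  The subjects are labelled
``pig1``..``pig5``; ``pig4`` received no amino-acid infusion and roughly
doubled its kidney uptake.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "PIGS",
    "PIG_NO_AMINO_ACID",
    "load_study_tiacs",
    "load_study_dose_coefficients",
    "load_toy_s_matrix",
]

PIGS = ("pig1", "pig2", "pig3", "pig4", "pig5")
PIG_NO_AMINO_ACID = "pig4"


def _read(name: str, index_col: str) -> pd.DataFrame:
    with resources.files("prrtdose.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, comment="#", index_col=index_col)


def load_study_tiacs() -> pd.DataFrame:
    """Per-subject organ TIACs in hours (rows: organs, columns: subjects)."""
    return _read("study_tiacs.csv", "organ")


def load_study_dose_coefficients() -> pd.DataFrame:
    """Per-subject dose coefficients in mGy/MBq (rows: target organs)."""
    return _read("study_dose_coefficients.csv", "target")


def load_toy_s_matrix():
    """The synthetic toy phantom S-matrix shipped for testing."""
    from .dosimetry import SMatrix

    data = resources.files("prrtdose.data")
    with resources.as_file(data.joinpath("toy_s_matrix.csv")) as v, resources.as_file(
        data.joinpath("toy_masses.csv")
    ) as m:
        return SMatrix.from_csv(v, m, phantom="toy")
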