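"""Packaged study fixtures.

The package ships the published study data as small CSV files:

``study_compounds.csv``
    42 basic compounds (23 model, 4 verification, 15 sample) with
    literature logP and pKa.  One reconciliation: for compound 20
    (2-amino-6-methylpyridine) the published pKa cell (6.95) contradicts
    the compound's own published logD column, which is reproduced to ±0.01
    at all four pH values only by pKa ≈ 7.41 — the literature pKa of this
    compound (compare its 4-methyl isomer, 7.38).  The fixture therefore
    carries 7.41.
``study_logkw.csv``
    Extrapolated logk_w per compound at pH 7–10, as published.
``study_logd_model.csv``
    Published logD of the 23 model compounds (2-decimal presentation).
    The published logD columns of the three weakly basic verification
    compounds are a cyclic permutation of the values their own logP/pKa
    imply and are not shipped; the validation table below is authoritative
    for verification compounds.
``study_validation.csv``
    External-validation table: literature vs. chromatographically
    determined logD with signed percent errors.
``study_sample_logd.csv``
    Published logD predictions for the 15 sample compounds (comparison
    fixture only; the descriptor values behind them are not public).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from . import io as cio
from .ionization import Compound

__all__ = [
    "fixture_path",
    "load_compounds",
    "load_logkw",
    "load_logd",
    "load_validation_table",
    "load_sample_predictions",
]


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture CSV."""
    return Path(resources.files("chromlogd") / "data" / name)


def load_compounds() -> list[Compound]:
    """The 42-compound study table."""
    return cio.read_compounds(fixture_path("study_compounds.csv"))


def load_logkw() -> pd.DataFrame:
    """Published logk_w matrix (42 compounds × pH 7–10)."""
    return cio.read_logkw_matrix(fixture_path("study_logkw.csv"))


def load_logd() -> pd.DataFrame:
    """Published logD of the 23 model compounds (2-decimal values)."""
    return cio.read_logkw_matrix(fixture_path("study_logd_model.csv"))


def load_validation_table() -> pd.DataFrame:
    """Published external-validation table (literature vs. determined logD)."""
    return pd.read_csv(fixture_path("study_validation.csv"))


def load_sample_predictions() -> pd.DataFrame:
    """Published sample-compound logD predictions (comparison fixture)."""
    return pd.read_csv(fixture_path("study_sample_logd.csv"))
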