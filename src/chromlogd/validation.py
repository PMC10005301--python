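"""External validation and sample prediction.

A fitted QSRR model is validated on compounds withheld from fitting: the
literature logD (from published logP/pKa via the ionization correction) is
compared with the chromatographically determined logD (the model applied to
the compound's measured logk_w and descriptors), as a signed,
literature-referenced percent error

    error% = 100 · (determined − literature) / literature.

An absolute error within 20% is the conventional acceptance band; it is a
report-level flag, not an abort.  Prediction applies the same model to
sample compounds whose logD is unknown.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .ionization import Compound, default_ne, logd_base
from .qsrr import QsrrModel

__all__ = [
    "ACCEPT_THRESHOLD_PCT",
    "ValidationRecord",
    "relative_error",
    "descriptor_row",
    "validate",
    "predict",
]

logger = logging.getLogger(__name__)

ACCEPT_THRESHOLD_PCT = 20.0

DESCRIPTOR_POLICIES = ("supplied", "fallback_ne", "fail")


@dataclass(frozen=True)
class ValidationRecord:
    """Literature vs. determined logD for one compound at one pH."""

    compound_id: str
    ph: float
    literature_logd: float
    determined_logd: float
    error_pct: float

    @property
    def passed(self) -> bool:
        return abs(self.error_pct) <= ACCEPT_THRESHOLD_PCT


def relative_error(determined: float, literature: float) -> float:
    """Signed percent error of ``determined`` relative to ``literature``."""
    if literature == 0:
        raise InvalidArgumentError(
            "literature logD is zero; relative error undefined"
        )
    return 100.0 * (determined - literature) / literature


def descriptor_row(
    compound: Compound,
    ph: float,
    subset: Sequence[str],
    policy: str = "fallback_ne",
) -> Optional[dict[str, float]]:
    """Descriptor values a model needs for one compound at one pH.

    Values come from the compound table when supplied.  Under the
    ``fallback_ne`` policy a missing n_e is replaced by the expected charge
    computed from pKa (logged, since it is a substitution); A and B have no
    fallback.  Returns None — meaning "skip this cell" — when a required
    descriptor is unavailable; under the ``fail`` policy that raises.
    """
    if policy not in DESCRIPTOR_POLICIES:
        raise InvalidArgumentError(f"unknown descriptor policy {policy!r}")
    row: dict[str, float] = {}
    for term in subset:
        value: Optional[float]
        if term == "n_e":
            value = compound.ne.get(ph)
            if value is None and policy == "fallback_ne" and compound.pka1 is not None:
                value = default_ne(compound.pka1, ph, compound.pka2)
                logger.info(
                    "n_e fallback for %s at pH %s: charge from pKa = %.4f",
                    compound.id,
                    ph,
                    value,
                )
        else:
            value = getattr(compound, term, None)
        if value is None:
            message = f"descriptor {term} unavailable for {compound.id} at pH {ph}"
            if policy == "fail":
                raise InvalidArgumentError(message)
            logger.info("%s; cell skipped", message)
            return None
        row[term] = float(value)
    return row


def _determined_logd(
    model: QsrrModel,
    compound: Compound,
    logkw: float,
    ph: float,
    policy: str,
) -> Optional[float]:
    descriptors = descriptor_row(compound, ph, model.subset, policy)
    if descriptors is None:
        return None
    return float(model.predict(logkw, descriptors))


def validate(
    models: Mapping[float, QsrrModel],
    compounds: Iterable[Compound],
    logkw_matrix: pd.DataFrame,
    *,
    descriptor_policy: str = "fallback_ne",
) -> list[ValidationRecord]:
    """External validation records for every (compound, pH) cell.

    The literature logD is computed from the compound's published logP/pKa;
    the determined logD applies the pH's selected model to its logk_w.
    All records are emitted regardless of the 20% flag; cells without a
    logk_w value are skipped with a log entry.
    """
    records: list[ValidationRecord] = []
    for compound in compounds:
        for ph, model in sorted(models.items()):
            if compound.id not in logkw_matrix.index or pd.isna(
                logkw_matrix.at[compound.id, ph]
            ):
                logger.info("no logk_w for %s at pH %s; record skipped", compound.id, ph)
                continue
            literature = logd_base(compound.logp, compound.pka1, ph, compound.pka2)
            determined = _determined_logd(
                model, compound, float(logkw_matrix.at[compound.id, ph]), ph,
                descriptor_policy,
            )
            if determined is None:
                continue
            records.append(
                ValidationRecord(
                    compound_id=compound.id,
                    ph=ph,
                    literature_logd=literature,
                    determined_logd=determined,
                    error_pct=relative_error(determined, literature),
                )
            )
    return records


def predict(
    models: Mapping[float, QsrrModel],
    compounds: Iterable[Compound],
    logkw_matrix: pd.DataFrame,
    *,
    descriptor_policy: str = "fallback_ne",
) -> pd.DataFrame:
    """Model logD for each compound at each pH with an available logk_w.

    Returns a compound × pH DataFrame at full precision (round to two
    decimals only when rendering); unavailable cells are NaN.
    """
    phs = sorted(models)
    rows: dict[str, list[float]] = {}
    for compound in compounds:
        values = []
        for ph in phs:
            if compound.id not in logkw_matrix.index or pd.isna(
                logkw_matrix.at[compound.id, ph]
            ):
                logger.info("no logk_w for %s at pH %s; cell skipped", compound.id, ph)
                values.append(np.nan)
                continue
            determined = _determined_logd(
                models[ph], compound, float(logkw_matrix.at[compound.id, ph]), ph,
                descriptor_policy,
            )
            values.append(np.nan if determined is None else determined)
        rows[compound.id] = values
    return pd.DataFrame.from_dict(rows, orient="index", columns=phs).astype(float)
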