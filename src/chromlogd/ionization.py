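"""Ionization corrections for basic solutes.

The apparent octanol/water distribution coefficient logD of a base depends
on mobile-phase pH through the Henderson–Hasselbalch equilibrium of its
conjugate acid.  For a monoprotic base,

    logD(pH) = logP − log10(1 + 10^(pKa − pH)),

where pKa refers to the conjugate acid of the basic site.  For a diprotic
base with a second, less basic site (pKa2 < pKa1) the denominator gains the
doubly protonated species:

    logD(pH) = logP − log10(1 + 10^(pKa1 − pH) + 10^(pKa1 + pKa2 − 2·pH)).

Dissociation is effectively suppressed at pH ≥ pKa + 2 and logD → logP as
pH → ∞.  Acidic ionization is out of scope: the package is written for
basic solutes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, NotComputableError

__all__ = [
    "Compound",
    "ROLES",
    "as_ph_grid",
    "ionized_fraction",
    "logd_base",
    "logd_table",
    "default_ne",
]

logger = logging.getLogger(__name__)

ROLES = ("model", "verification", "sample")


@dataclass(frozen=True)
class Compound:
    """One solute with its literature physicochemical data.

    Parameters
    ----------
    id : str
        Short unique label.
    name : str
        Free-text compound name.
    role : str
        One of ``model`` (used to fit QSRR models), ``verification``
        (external validation) or ``sample`` (logD unknown, to be predicted).
    logp : float, optional
        Literature log10 octanol/water partition coefficient of the neutral
        species.  May be absent only for samples.
    pka1 : float, optional
        pKa of the conjugate acid of the most basic site.
    pka2 : float, optional
        Second basic site; must satisfy ``pka2 < pka1``.
    A, B : float, optional
        Abraham-type hydrogen-bond acidity / basicity descriptors (≥ 0).
    ne : mapping of float to float
        Supplied per-pH electrostatic charge descriptor n_e.  When a pH is
        absent the pipeline may fall back to :func:`default_ne`.
    """

    id: str
    name: str
    role: str
    logp: Optional[float] = None
    pka1: Optional[float] = None
    pka2: Optional[float] = None
    A: Optional[float] = None
    B: Optional[float] = None
    ne: Mapping[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise InvalidArgumentError(
                f"compound {self.id!r}: role must be one of {ROLES}, got {self.role!r}"
            )
        if self.role in ("model", "verification"):
            if self.logp is None or self.pka1 is None:
                raise InvalidArgumentError(
                    f"compound {self.id!r}: role {self.role!r} requires logP and pKa1"
                )
        if self.pka2 is not None:
            if self.pka1 is None or not self.pka2 < self.pka1:
                raise InvalidArgumentError(
                    f"compound {self.id!r}: pKa2 must be < pKa1 "
                    f"(got pKa1={self.pka1}, pKa2={self.pka2})"
                )
        for label, value in (("A", self.A), ("B", self.B)):
            if value is not None and value < 0:
                raise InvalidArgumentError(
                    f"compound {self.id!r}: descriptor {label} must be >= 0, got {value}"
                )


def as_ph_grid(values: Iterable[float]) -> tuple[float, ...]:
    """Validate and freeze a mobile-phase pH grid.

    The grid must be strictly increasing with every value in [0, 14].
    """
    grid = tuple(float(v) for v in values)
    if any(not (0.0 <= v <= 14.0) for v in grid):
        raise InvalidArgumentError(f"pH values must lie in [0, 14]: {grid}")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise InvalidArgumentError(f"pH grid must be strictly increasing: {grid}")
    return grid


def _require_finite(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value is None or not math.isfinite(value):
            raise InvalidArgumentError(f"{name} must be finite, got {value!r}")


def ionized_fraction(pka: float, ph: float) -> float:
    """Fraction of a basic site carrying a positive charge at ``ph``.

    Equals ``1 / (1 + 10**(ph - pka))``: 0.5 at pH = pKa, monotonically
    decreasing in pH.
    """
    _require_finite(pka=pka, ph=ph)
    return 1.0 / (1.0 + 10.0 ** (ph - pka))


def logd_base(
    logp: float,
    pka1: float,
    ph: float,
    pka2: Optional[float] = None,
) -> float:
    """Apparent distribution coefficient of a (mono- or diprotic) base.

    Raises
    ------
    NotComputableError
        If ``logp`` is missing (sample compounds without literature data).
    InvalidArgumentError
        On non-finite arguments.
    """
    if logp is None:
        raise NotComputableError("logP is missing; logD cannot be computed")
    _require_finite(logp=logp, pka1=pka1, ph=ph)
    denom = 1.0 + 10.0 ** (pka1 - ph)
    if pka2 is not None and math.isfinite(pka2):
        denom += 10.0 ** (pka1 + pka2 - 2.0 * ph)
    return logp - math.log10(denom)


def logd_table(
    compounds: Sequence[Compound],
    ph_values: Iterable[float],
) -> pd.DataFrame:
    """logD for every compound at every pH of the grid.

    Returns a DataFrame indexed by compound id with one float column per pH,
    at full floating precision (rounding is a presentation concern).  Sample
    compounds without a literature logP are skipped with a log notice.
    """
    grid = as_ph_grid(ph_values)
    rows: dict[str, list[float]] = {}
    for compound in compounds:
        if compound.logp is None or compound.pka1 is None:
            logger.info(
                "logd_table: skipping %s (%s) — no literature logP/pKa",
                compound.id,
                compound.name,
            )
            continue
        rows[compound.id] = [
            logd_base(compound.logp, compound.pka1, ph, compound.pka2) for ph in grid
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(grid)).astype(float)


def default_ne(pka1: float, ph: float, pka2: Optional[float] = None) -> float:
    """Expected positive charge number of a base at ``ph``.

    Fallback for the electrostatic-charge descriptor n_e when no supplied
    value is available: the sum of the ionized fractions of the one or two
    basic sites.
    """
    value = ionized_fraction(pka1, ph)
    if pka2 is not None and np.isfinite(pka2):
        value += ionized_fraction(pka2, ph)
    return value
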