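"""From raw isocratic retention times to extrapolated logk_w.

Under the linear solvent strength (LSS) model, the isocratic retention
factor k of a solute depends on the organic-modifier volume fraction φ as

    log10 k = logk_w − S·φ,

so an ordinary least-squares line through (φ, log10 k) measurements yields
logk_w (the retention factor extrapolated to a purely aqueous mobile phase)
as the intercept and the solvent-strength S as minus the slope.  Retention
times are first aligned run-to-run by a dual-point correction anchored on
two reference compounds, then converted to retention factors with
k = (t_R − t_0)/t_0 using the measured dead time t_0.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateAnchorError,
    DegenerateDesignError,
    InsufficientDataError,
    InvalidArgumentError,
    NonRetainedSoluteError,
)

__all__ = [
    "RetentionSeries",
    "LSSFit",
    "correct_time",
    "retention_factor",
    "fit_lss",
    "build_logkw_matrix",
]

logger = logging.getLogger(__name__)

#: minimum number of distinct φ levels required for an LSS fit
MIN_PHI_LEVELS = 4

#: an LSS fit below this R² is flagged (not rejected)
R2_WARN_THRESHOLD = 0.99

AnchorPair = Tuple[float, float]  # (reference_tR, observed_tR)


@dataclass(frozen=True)
class RetentionSeries:
    """Isocratic retention measurements of one compound at one pH.

    ``points`` holds (φ, t_R) pairs in minutes; repeated φ values are
    treated as replicate injections and averaged before fitting.
    ``anchors``, when present, are two (reference_tR, observed_tR) pairs
    from the anchor compounds of the run; ``anchor_ids`` is metadata only.
    """

    compound_id: str
    ph: float
    t0: float
    points: Tuple[Tuple[float, float], ...]
    anchors: Optional[Tuple[AnchorPair, AnchorPair]] = None
    anchor_ids: Optional[Tuple[str, str]] = None

    def __post_init__(self) -> None:
        if not self.t0 > 0:
            raise InvalidArgumentError(
                f"{self.compound_id}: dead time must be positive, got {self.t0}"
            )
        for phi, tr in self.points:
            if not 0.0 < phi < 1.0:
                raise InvalidArgumentError(
                    f"{self.compound_id}: φ must lie strictly in (0, 1), got {phi}"
                )
            if not tr > self.t0:
                raise NonRetainedSoluteError(
                    f"{self.compound_id}: tR={tr} min does not exceed t0={self.t0} min"
                )

    def averaged_points(self) -> list[tuple[float, float]]:
        """Replicate-averaged (φ, mean t_R) pairs, sorted by φ."""
        groups: dict[float, list[float]] = defaultdict(list)
        for phi, tr in self.points:
            groups[phi].append(tr)
        return sorted((phi, float(np.mean(trs))) for phi, trs in groups.items())


@dataclass(frozen=True)
class LSSFit:
    """Result of fitting the LSS line to one retention series."""

    compound_id: str
    ph: float
    logkw: float
    S: float
    r2: float
    n_points: int
    se_logkw: float
    se_S: float

    @property
    def low_r2(self) -> bool:
        """True when the linearity falls below the expected R² ≥ 0.99."""
        return self.r2 < R2_WARN_THRESHOLD


def correct_time(tr: float, anchors: Sequence[AnchorPair]) -> float:
    """Dual-point retention-time correction.

    ``anchors`` are two (reference_tR, observed_tR) pairs.  The affine map
    sending each observed anchor time to its reference time is applied to
    ``tr``; by construction the map is exact at both anchors.
    """
    (ref1, obs1), (ref2, obs2) = anchors
    if obs1 == obs2:
        raise DegenerateAnchorError(
            f"observed anchor times coincide ({obs1} min); correction undefined"
        )
    slope = (ref2 - ref1) / (obs2 - obs1)
    return ref1 + slope * (tr - obs1)


def retention_factor(tr: float, t0: float) -> float:
    """Dimensionless retention factor k = (t_R − t_0)/t_0."""
    if not t0 > 0:
        raise InvalidArgumentError(f"dead time must be positive, got {t0}")
    if not tr > t0:
        raise NonRetainedSoluteError(
            f"tR={tr} min does not exceed the dead time t0={t0} min"
        )
    return (tr - t0) / t0


def fit_lss(series: RetentionSeries) -> LSSFit:
    """Ordinary least-squares fit of log10 k against φ.

    Replicates at the same φ are averaged first; when the series carries
    anchor pairs the dual-point correction is applied to each averaged
    retention time before the retention factor is formed.  Returns the
    intercept as ``logkw`` and minus the slope as ``S`` with their classical
    standard errors.  A fit with R² < 0.99 is logged as a warning and
    flagged on the result, mirroring how such series are reported rather
    than discarded.
    """
    pts = series.averaged_points()
    if series.anchors is not None:
        pts = [(phi, correct_time(tr, series.anchors)) for phi, tr in pts]
    if len(pts) < MIN_PHI_LEVELS:
        raise InsufficientDataError(
            f"{series.compound_id} pH {series.ph}: {len(pts)} distinct φ levels; "
            f"at least {MIN_PHI_LEVELS} required"
        )
    phi = np.array([p for p, _ in pts])
    logk = np.log10([retention_factor(tr, series.t0) for _, tr in pts])
    if np.ptp(phi) == 0.0:
        raise DegenerateDesignError("zero variance in φ")
    res = stats.linregress(phi, logk)
    r2 = float(res.rvalue**2)
    fit = LSSFit(
        compound_id=series.compound_id,
        ph=series.ph,
        logkw=float(res.intercept),
        S=float(-res.slope),
        r2=r2,
        n_points=len(pts),
        se_logkw=float(res.intercept_stderr),
        se_S=float(res.stderr),
    )
    if fit.low_r2:
        logger.warning(
            "LSS fit for %s at pH %s has R²=%.4f < %.2f",
            series.compound_id,
            series.ph,
            r2,
            R2_WARN_THRESHOLD,
        )
    return fit


def build_logkw_matrix(
    series: Iterable[RetentionSeries],
    ph_values: Iterable[float],
) -> pd.DataFrame:
    """Fit every series and assemble a compound × pH table of logk_w.

    Each (compound, pH) pair may carry at most one series.  Cells without a
    series are left as NaN and logged.
    """
    from .ionization import as_ph_grid

    grid = as_ph_grid(ph_values)
    fits: dict[str, dict[float, float]] = defaultdict(dict)
    for s in series:
        if s.ph in fits[s.compound_id]:
            raise InvalidArgumentError(
                f"duplicate retention series for {s.compound_id} at pH {s.ph}"
            )
        if s.ph in grid:
            fits[s.compound_id][s.ph] = fit_lss(s).logkw
    table = pd.DataFrame.from_dict(fits, orient="index").reindex(columns=list(grid))
    table = table.astype(float)
    for cid in table.index:
        for ph in table.columns:
            if pd.isna(table.at[cid, ph]):
                logger.info("no retention series for %s at pH %s", cid, ph)
    return table
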