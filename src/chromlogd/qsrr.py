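"""QSRR models linking logD to chromatographic and molecular descriptors.

The core relation is the univariate calibration logD = a·logk_w + b fitted
over the model compounds at one mobile-phase pH.  When solutes are partly
ionized this relation degrades, and it is repaired by adding molecular
structure descriptors: the electrostatic charge n_e and the Abraham
hydrogen-bond acidity/basicity A and B, giving multi-parameter models

    logD = a·logk_w + c1·n_e + c2·A + c3·B + b

fitted by ordinary least squares.  All 2³ descriptor subsets (logk_w and
the intercept are always present) are fitted and ranked by R²; subsets
whose R² is indistinguishable at a small tolerance are treated as tied and
the most parsimonious wins.

Both the raw coefficient of determination and the adjusted R² are carried
on every fitted model: regression software commonly prints the adjusted
value, so comparisons against published calibration tables should use
``r2_adj`` while model ranking uses the raw ``r2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import CollinearityError, InsufficientDataError, InvalidArgumentError

__all__ = ["DESCRIPTORS", "QsrrModel", "fit_mlr", "select_model", "model_report"]

logger = logging.getLogger(__name__)

#: candidate molecular descriptors, in canonical reporting order
DESCRIPTORS = ("n_e", "A", "B")

INTERCEPT = "intercept"


@dataclass(frozen=True)
class QsrrModel:
    """A fitted (multi-parameter) QSRR model at one pH.

    ``coef`` and ``se`` map each term — ``logkw``, the descriptors in
    ``subset`` and ``intercept`` — to its OLS estimate and classical
    standard error.
    """

    ph: float
    subset: tuple[str, ...]
    coef: Mapping[str, float]
    se: Mapping[str, float]
    r2: float
    r2_adj: float
    n: int
    compound_ids: tuple[str, ...]

    @property
    def terms(self) -> tuple[str, ...]:
        return ("logkw", *self.subset)

    def predict(self, logkw, descriptors: Optional[Mapping[str, float]] = None):
        """Model logD for a given logk_w and descriptor values.

        ``descriptors`` must supply every name in ``subset``; it may be
        omitted for a univariate model.  Accepts scalars or arrays.
        """
        value = self.coef[INTERCEPT] + self.coef["logkw"] * np.asarray(logkw, float)
        for term in self.subset:
            if descriptors is None or term not in descriptors:
                raise InvalidArgumentError(f"descriptor {term!r} required by the model")
            value = value + self.coef[term] * np.asarray(descriptors[term], float)
        return float(value) if np.ndim(value) == 0 else value


def _find_collinear(X: pd.DataFrame) -> list[str]:
    """Columns whose removal does not reduce the design rank."""
    mat = X.to_numpy(float)
    full_rank = np.linalg.matrix_rank(mat)
    offending = []
    for j, name in enumerate(X.columns):
        reduced = np.delete(mat, j, axis=1)
        if np.linalg.matrix_rank(reduced) == full_rank:
            offending.append(str(name))
    return offending or [str(c) for c in X.columns]


def fit_mlr(
    y: Sequence[float],
    X: pd.DataFrame,
    *,
    ph: float = float("nan"),
    subset: Optional[Sequence[str]] = None,
    compound_ids: Optional[Sequence[str]] = None,
) -> QsrrModel:
    """Ordinary least squares of logD on logk_w plus chosen descriptors.

    Parameters
    ----------
    y : array-like
        logD values of the model compounds.
    X : DataFrame
        Design matrix containing a ``logkw`` column plus descriptor columns.
        The descriptor subset defaults to every non-logkw column of ``X``.
    ph : float
        Mobile-phase pH the model belongs to (metadata).
    subset : sequence of str, optional
        Descriptor columns to use, in reporting order.

    Raises
    ------
    InsufficientDataError
        If N is not greater than the number of fitted terms.
    CollinearityError
        If the design (with intercept) is rank deficient; the error names
        the offending terms.
    """
    if "logkw" not in X.columns:
        raise InvalidArgumentError("design matrix must contain a 'logkw' column")
    chosen = tuple(subset) if subset is not None else tuple(
        c for c in X.columns if c != "logkw"
    )
    cols = ["logkw", *chosen]
    design = X[cols].astype(float)
    yv = np.asarray(y, float)
    if design.isna().any().any() or np.isnan(yv).any():
        raise InvalidArgumentError("missing values in regression inputs")
    n, p = design.shape
    if n < p + 1:  # p slopes plus the intercept; exact interpolation allowed
        raise InsufficientDataError(
            f"N={n} compounds cannot identify {p + 1} regression terms"
        )
    exog = sm.add_constant(design, prepend=False, has_constant="raise")
    if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
        raise CollinearityError(_find_collinear(design))
    res = sm.OLS(yv, exog).fit()
    names = [*cols, INTERCEPT]
    params = dict(zip(names, (float(v) for v in res.params)))
    bse = dict(zip(names, (float(v) for v in res.bse)))
    return QsrrModel(
        ph=ph,
        subset=chosen,
        coef=params,
        se=bse,
        r2=float(res.rsquared),
        r2_adj=float(res.rsquared_adj),
        n=n,
        compound_ids=tuple(compound_ids) if compound_ids is not None else tuple(),
    )


def select_model(
    y: Sequence[float],
    X: pd.DataFrame,
    candidates: Iterable[str] = DESCRIPTORS,
    *,
    ph: float = float("nan"),
    compound_ids: Optional[Sequence[str]] = None,
    r2_tol: float = 0.002,
) -> tuple[QsrrModel, pd.DataFrame]:
    """Fit every descriptor subset and return the best model plus a ranking.

    All subsets of ``candidates`` (logk_w and intercept always included)
    are fitted.  Subsets within ``r2_tol`` of the highest R² are considered
    tied — R² never decreases under nesting, so without a tolerance the full
    model would always win — and among tied subsets the one with the fewest
    terms (then the higher R²) is selected.  A subset failing the
    collinearity check is excluded with a log entry.
    """
    cand = tuple(candidates)
    fitted: list[QsrrModel] = []
    rows = []
    for size in range(len(cand) + 1):
        for subset in combinations(cand, size):
            try:
                model = fit_mlr(y, X, ph=ph, subset=subset, compound_ids=compound_ids)
            except CollinearityError as err:
                logger.warning(
                    "subset %s excluded at pH %s: %s", subset or ("—",), ph, err
                )
                continue
            fitted.append(model)
            rows.append(
                {
                    "subset": "+".join(subset) if subset else "(none)",
                    "n_terms": len(subset),
                    "r2": model.r2,
                    "r2_adj": model.r2_adj,
                }
            )
    if not fitted:
        raise InsufficientDataError("no descriptor subset could be fitted")
    best_r2 = max(m.r2 for m in fitted)
    tied = [m for m in fitted if best_r2 - m.r2 <= r2_tol]
    best = min(tied, key=lambda m: (len(m.subset), -m.r2))
    ranking = pd.DataFrame(rows).sort_values(
        ["r2", "n_terms"], ascending=[False, True], ignore_index=True
    )
    ranking["selected"] = [
        row.subset == ("+".join(best.subset) if best.subset else "(none)")
        for row in ranking.itertuples()
    ]
    return best, ranking


def _fmt_term(est: float, se: float, name: str, first: bool) -> str:
    body = f"({abs(est):.2f} ± {se:.2f})" + (f" {name}" if name else "")
    if first:
        return ("-" if est < 0 else "") + body
    return (" - " if est < 0 else " + ") + body


def model_report(model: QsrrModel) -> str:
    """Render a fitted model as an ``(estimate ± se)`` equation string.

    Estimates and standard errors are rounded to two decimals; terms appear
    in canonical order (logk_w, descriptors, intercept) with sign-aware
    joining, e.g. ``logD = (1.02 ± 0.07) logkw - (0.21 ± 0.12)``.
    """
    parts = [_fmt_term(model.coef["logkw"], model.se["logkw"], "logkw", True)]
    for term in model.subset:
        parts.append(_fmt_term(model.coef[term], model.se[term], term, False))
    parts.append(_fmt_term(model.coef[INTERCEPT], model.se[INTERCEPT], "", False))
    return "logD = " + "".join(parts)
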