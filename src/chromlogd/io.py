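"""CSV readers/writers and the end-to-end pipeline.

File dialects
-------------
Compound CSV: columns ``id,name,logP,pKa1,pKa2,role,A,B`` plus optional
per-pH descriptor columns ``ne_<pH>`` (e.g. ``ne_7.0``).  Empty cell means
missing.  Retention CSV (long format): ``compound_id,pH,phi,tR,t0`` plus
optional anchor columns ``anchor1_ref,anchor1_obs,anchor2_ref,anchor2_obs``;
repeated (compound, pH, φ) rows are replicate injections.  A precomputed
logk_w matrix CSV (``compound_id`` × pH columns) is accepted in place of
raw retention data.  All files are UTF-8 with '.' decimal separator; the
Unicode minus sign (U+2212), common in typeset tables, is accepted
anywhere a number is read.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import qsrr, validation
from .errors import DuplicateRecordError, InvalidConfigError, ParseError
from .ionization import Compound, as_ph_grid, logd_table
from .retention import RetentionSeries, build_logkw_matrix
from .qsrr import QsrrModel

__all__ = [
    "read_compounds",
    "write_compounds",
    "read_retention",
    "write_retention",
    "read_logkw_matrix",
    "write_logkw_matrix",
    "models_to_json",
    "StudyConfig",
    "PipelineResult",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

MINUS_SIGN = "−"

COMPOUND_COLUMNS = ["id", "name", "logP", "pKa1", "pKa2", "role", "A", "B"]


def _to_float(cell, row: int, column: str) -> Optional[float]:
    """Parse a CSV cell to float, accepting the Unicode minus; '' → None."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return None
    text = str(cell).strip().replace(MINUS_SIGN, "-")
    if not text:
        return None
    try:
        return float(text)
    except ValueError as err:
        raise ParseError(
            f"row {row}, column {column!r}: cannot parse {cell!r} as a number"
        ) from err


def read_compounds(path: str | Path) -> list[Compound]:
    """Read a compound table CSV into validated :class:`Compound` records."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ("id", "name", "role") if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    ne_columns = {
        col: float(col[3:]) for col in frame.columns if col.startswith("ne_")
    }
    compounds: list[Compound] = []
    seen: set[str] = set()
    for i, rec in enumerate(frame.to_dict("records")):
        row = i + 2  # header is row 1
        cid = rec["id"].strip()
        if cid in seen:
            raise DuplicateRecordError(f"row {row}: duplicate compound id {cid!r}")
        seen.add(cid)
        ne = {}
        for col, ph in ne_columns.items():
            value = _to_float(rec.get(col), row, col)
            if value is not None:
                ne[ph] = value
        compounds.append(
            Compound(
                id=cid,
                name=rec["name"].strip(),
                role=rec["role"].strip(),
                logp=_to_float(rec.get("logP"), row, "logP"),
                pka1=_to_float(rec.get("pKa1"), row, "pKa1"),
                pka2=_to_float(rec.get("pKa2"), row, "pKa2"),
                A=_to_float(rec.get("A"), row, "A"),
                B=_to_float(rec.get("B"), row, "B"),
                ne=ne,
            )
        )
    return compounds


def write_compounds(
    path: str | Path,
    compounds: Sequence[Compound],
    ph_values: Sequence[float] = (),
) -> None:
    """Write compounds back to the CSV dialect read_compounds accepts."""
    ne_cols = [f"ne_{ph}" for ph in ph_values]
    rows = []
    for c in compounds:
        row = {
            "id": c.id,
            "name": c.name,
            "logP": c.logp,
            "pKa1": c.pka1,
            "pKa2": c.pka2,
            "role": c.role,
            "A": c.A,
            "B": c.B,
        }
        for ph, col in zip(ph_values, ne_cols):
            row[col] = c.ne.get(ph)
        rows.append(row)
    pd.DataFrame(rows, columns=COMPOUND_COLUMNS + ne_cols).to_csv(path, index=False)


def read_retention(path: str | Path) -> list[RetentionSeries]:
    """Read a long-format retention CSV into per-(compound, pH) series."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["compound_id", "pH", "phi", "tR", "t0"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    has_anchors = all(
        c in frame.columns
        for c in ("anchor1_ref", "anchor1_obs", "anchor2_ref", "anchor2_obs")
    )
    grouped: dict[tuple[str, float], dict] = {}
    for i, rec in enumerate(frame.to_dict("records")):
        row = i + 2
        key = (rec["compound_id"].strip(), _to_float(rec["pH"], row, "pH"))
        entry = grouped.setdefault(key, {"points": [], "t0": None, "anchors": None})
        entry["t0"] = _to_float(rec["t0"], row, "t0")
        entry["points"].append(
            (_to_float(rec["phi"], row, "phi"), _to_float(rec["tR"], row, "tR"))
        )
        if has_anchors and str(rec["anchor1_ref"]).strip():
            entry["anchors"] = (
                (_to_float(rec["anchor1_ref"], row, "anchor1_ref"),
                 _to_float(rec["anchor1_obs"], row, "anchor1_obs")),
                (_to_float(rec["anchor2_ref"], row, "anchor2_ref"),
                 _to_float(rec["anchor2_obs"], row, "anchor2_obs")),
            )
    return [
        RetentionSeries(
            compound_id=cid,
            ph=ph,
            t0=entry["t0"],
            points=tuple(entry["points"]),
            anchors=entry["anchors"],
        )
        for (cid, ph), entry in grouped.items()
    ]


def write_retention(path: str | Path, series: Iterable[RetentionSeries]) -> None:
    rows = []
    for s in series:
        for phi, tr in s.points:
            row = {
                "compound_id": s.compound_id,
                "pH": s.ph,
                "phi": phi,
                "tR": repr(tr),
                "t0": s.t0,
            }
            if s.anchors is not None:
                (r1, o1), (r2, o2) = s.anchors
                row.update(
                    anchor1_ref=r1, anchor1_obs=o1, anchor2_ref=r2, anchor2_obs=o2
                )
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_logkw_matrix(path: str | Path) -> pd.DataFrame:
    """Read a precomputed compound × pH logk_w matrix CSV."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    first = frame.columns[0]
    if frame[first].duplicated().any():
        dupes = frame[first][frame[first].duplicated()].tolist()
        raise DuplicateRecordError(f"{path}: duplicate compound ids {dupes}")
    out = {}
    for col in frame.columns[1:]:
        out[float(col)] = [
            _to_float(v, i + 2, col) for i, v in enumerate(frame[col])
        ]
    matrix = pd.DataFrame(out, index=frame[first].str.strip()).astype(float)
    matrix.index.name = first
    return matrix


def write_logkw_matrix(path: str | Path, matrix: pd.DataFrame) -> None:
    out = matrix.copy()
    out.index.name = out.index.name or "compound_id"
    out.to_csv(path)


def models_to_json(models: dict[float, QsrrModel]) -> str:
    """Serialize fitted models (full precision) to the model JSON dialect."""
    payload = {
        str(ph): {
            "pH": m.ph,
            "subset": list(m.subset),
            "coef": dict(m.coef),
            "se": dict(m.se),
            "r2": m.r2,
            "r2_adj": m.r2_adj,
            "N": m.n,
            "compound_ids": list(m.compound_ids),
        }
        for ph, m in sorted(models.items())
    }
    return json.dumps(payload, indent=1)


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one pipeline run over measured inputs."""

    compounds: Path
    retention: Optional[Path] = None
    logkw_matrix: Optional[Path] = None
    ph_values: tuple[float, ...] = (7.0, 8.0, 9.0, 10.0)
    descriptor_policy: str = "fallback_ne"
    candidates: Optional[tuple[str, ...]] = None  # None = auto-detect
    r2_tol: float = 0.002
    out_dir: Optional[Path] = None

    def __post_init__(self) -> None:
        if not self.ph_values:
            raise InvalidConfigError("pH list must be non-empty")
        as_ph_grid(self.ph_values)
        if (self.retention is None) == (self.logkw_matrix is None):
            raise InvalidConfigError(
                "exactly one of retention CSV or logk_w matrix CSV is required"
            )


@dataclass
class PipelineResult:
    """Everything a pipeline run produced, in memory plus written paths."""

    logkw: pd.DataFrame
    models: dict[float, QsrrModel]
    rankings: dict[float, pd.DataFrame]
    validation: list
    predictions: pd.DataFrame
    paths: dict[str, Path] = field(default_factory=dict)


def _available_candidates(
    compounds: Sequence[Compound], policy: str
) -> tuple[str, ...]:
    """Descriptors usable for every model compound under the policy."""
    model = [c for c in compounds if c.role == "model"]
    usable = []
    if all(c.ne or (policy == "fallback_ne" and c.pka1 is not None) for c in model):
        usable.append("n_e")
    for term in ("A", "B"):
        if all(getattr(c, term) is not None for c in model):
            usable.append(term)
    return tuple(usable)


def run_pipeline(config: StudyConfig) -> PipelineResult:
    """Run the full study: logk_w → model selection → validation → prediction.

    Deterministic given fixed inputs.  Stage-by-stage compound counts and
    every descriptor fallback are logged; hard errors propagate with their
    stage-specific exception types.
    """
    compounds = read_compounds(config.compounds)
    logger.info("read %d compounds from %s", len(compounds), config.compounds)
    by_role = {
        role: [c for c in compounds if c.role == role]
        for role in ("model", "verification", "sample")
    }
    logger.info(
        "roles: %d model / %d verification / %d sample",
        *(len(by_role[r]) for r in ("model", "verification", "sample")),
    )

    if config.retention is not None:
        series = read_retention(config.retention)
        logger.info("fitting LSS lines for %d retention series", len(series))
        logkw = build_logkw_matrix(series, config.ph_values)
    else:
        logkw = read_logkw_matrix(config.logkw_matrix)
        logkw = logkw[[ph for ph in config.ph_values if ph in logkw.columns]]

    model_compounds = by_role["model"]
    logd = logd_table(model_compounds, config.ph_values)
    candidates = (
        config.candidates
        if config.candidates is not None
        else _available_candidates(compounds, config.descriptor_policy)
    )
    logger.info("candidate descriptors: %s", candidates or "(none)")

    models: dict[float, QsrrModel] = {}
    rankings: dict[float, pd.DataFrame] = {}
    for ph in config.ph_values:
        ids = [c.id for c in model_compounds if c.id in logkw.index
               and not pd.isna(logkw.at[c.id, ph])]
        dropped = [c.id for c in model_compounds if c.id not in ids]
        if dropped:
            logger.info("pH %s: %d model compounds without logk_w: %s",
                        ph, len(dropped), dropped)
        design = {"logkw": [float(logkw.at[i, ph]) for i in ids]}
        for term in candidates:
            column = []
            for c in model_compounds:
                if c.id not in ids:
                    continue
                row = validation.descriptor_row(
                    c, ph, (term,), config.descriptor_policy
                )
                column.append(np.nan if row is None else row[term])
            design[term] = column
        X = pd.DataFrame(design, index=ids)
        y = logd.loc[ids, ph]
        model, ranking = qsrr.select_model(
            y, X, candidates, ph=ph, compound_ids=ids, r2_tol=config.r2_tol
        )
        logger.info(
            "pH %s: selected subset %s (R²=%.4f, adj %.4f, N=%d)",
            ph, model.subset or ("none",), model.r2, model.r2_adj, model.n,
        )
        models[ph] = model
        rankings[ph] = ranking

    records = validation.validate(
        models, by_role["verification"], logkw,
        descriptor_policy=config.descriptor_policy,
    )
    predictions = validation.predict(
        models, by_role["sample"], logkw,
        descriptor_policy=config.descriptor_policy,
    )

    result = PipelineResult(
        logkw=logkw, models=models, rankings=rankings,
        validation=records, predictions=predictions,
    )
    if config.out_dir is not None:
        result.paths = _write_outputs(result, config)
    return result


def _write_outputs(result: PipelineResult, config: StudyConfig) -> dict[str, Path]:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "models": out / "models.json",
        "ranking": out / "ranking.csv",
        "validation": out / "validation.csv",
        "predictions": out / "predictions.csv",
        "logkw": out / "logkw.csv",
    }
    paths["models"].write_text(models_to_json(result.models))
    ranking = pd.concat(
        {ph: r for ph, r in sorted(result.rankings.items())}, names=["pH", None]
    ).reset_index(level=0)
    ranking.to_csv(paths["ranking"], index=False)
    pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "pH": r.ph,
                "literature_logD": round(r.literature_logd, 2),
                "determined_logD": round(r.determined_logd, 2),
                "error_pct": round(r.error_pct, 2),
                "pass": r.passed,
            }
            for r in result.validation
        ]
    ).to_csv(paths["validation"], index=False)
    result.predictions.round(2).rename_axis("compound_id").to_csv(
        paths["predictions"]
    )
    write_logkw_matrix(paths["logkw"], result.logkw)
    for name, path in paths.items():
        logger.info("wrote %s -> %s", name, path)
    return paths
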