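"""Synthetic IS-RPLC studies with known ground truth.

The generator emulates the statistical structure of a chromatographic logD
study of basic compounds so that every pipeline stage — retention fitting,
ionization correction, QSRR model selection, external validation and sample
prediction — can be exercised end to end against a known truth:

* each compound gets a literature-style logP and pKa (optionally a second,
  weaker basic site), Abraham-type descriptors A and B, and a per-pH
  electrostatic charge n_e equal to its expected protonation;
* its true logD at each pH follows exactly from logP/pKa via the
  Henderson–Hasselbalch correction;
* its true logk_w at each pH is obtained by inverting the pH's true QSRR
  model, logk_w = (logD − descriptor terms − intercept − ε)/a, where
  ε ~ N(0, logd_noise_sd) is the scatter of the retention–partition
  relation expressed on the logD scale ("literature-logD channel");
* isocratic retention times follow the LSS law,
  t_R = t_0·(1 + 10^(logk_w − S·φ)) plus Gaussian noise in minutes, with
  the solvent strength S coupled linearly to logk_w (more hydrophobic
  solutes need steeper extrapolation, as on real reversed-phase columns).

All randomness flows from the config seed; outputs are bit-reproducible.

The default true models mirror the qualitative finding of the study design
this emulates: at pH 7–8 retention is governed by hydrophobicity plus the
electrostatic term n_e; at pH 9 hydrogen bonding (A, B) also matters; at
pH 10 dissociation is essentially suppressed, n_e has no variance left to
identify, and only A and B carry signal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import InvalidConfigError
from .ionization import Compound, as_ph_grid, default_ne, logd_base
from .retention import RetentionSeries

__all__ = [
    "TrueModel",
    "GeneratorConfig",
    "CompoundTruth",
    "StudyBundle",
    "generate_compounds",
    "simulate_retention",
    "generate_study",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrueModel:
    """Generating QSRR model at one pH: subset plus full coefficient map."""

    subset: tuple[str, ...]
    coef: Mapping[str, float]  # keys: logkw, the subset terms, intercept

    def value(self, logkw: float, descriptors: Mapping[str, float]) -> float:
        out = self.coef["intercept"] + self.coef["logkw"] * logkw
        for term in self.subset:
            out += self.coef[term] * descriptors[term]
        return out

    def invert_logkw(self, logd: float, descriptors: Mapping[str, float]) -> float:
        rest = self.coef["intercept"] + sum(
            self.coef[t] * descriptors[t] for t in self.subset
        )
        return (logd - rest) / self.coef["logkw"]


def _default_true_models() -> dict[float, TrueModel]:
    ne_model = TrueModel(
        subset=("n_e",), coef={"logkw": 1.0, "n_e": -0.8, "intercept": -0.1}
    )
    full_model = TrueModel(
        subset=("n_e", "A", "B"),
        coef={"logkw": 0.95, "n_e": -0.5, "A": 0.5, "B": -0.6, "intercept": 0.2},
    )
    ab_model = TrueModel(
        subset=("A", "B"), coef={"logkw": 0.95, "A": 0.5, "B": -0.6, "intercept": 0.2}
    )
    return {7.0: ne_model, 8.0: ne_model, 9.0: full_model, 10.0: ab_model}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic generator.

    Defaults reproduce the scale of the emulated study: 23 model, 4
    verification and 15 sample compounds at pH 7–10, five methanol
    fractions per series, pKa spanning ≈3–9.4 and logk_w spanning ≈−0.5
    to 4.6, retention noise of 0.01 min and a retention–partition scatter
    of 0.1 logD units.
    """

    n_model: int = 23
    n_verification: int = 4
    n_sample: int = 15
    ph_values: tuple[float, ...] = (7.0, 8.0, 9.0, 10.0)
    phi_values: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5)
    true_models: Mapping[float, TrueModel] = field(
        default_factory=_default_true_models
    )
    logkw_range: tuple[float, float] = (-0.5, 4.6)
    verification_logkw_range: tuple[float, float] = (1.5, 3.5)
    pka_range: tuple[float, float] = (2.97, 9.35)
    verification_pka_range: tuple[float, float] = (3.0, 6.5)
    p_diprotic: float = 0.15
    a_range: tuple[float, float] = (0.0, 0.7)
    b_range: tuple[float, float] = (0.2, 1.0)
    t0: float = 1.6
    s_coupling: tuple[float, float, float] = (2.5, 0.9, 0.3)  # (s0, slope, jitter sd)
    retention_noise_sd: float = 0.01  # minutes
    logd_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_model < 1:
            raise InvalidConfigError(f"n_compounds must be >= 1, got {self.n_model}")
        if min(self.n_verification, self.n_sample) < 0:
            raise InvalidConfigError("compound counts must be non-negative")
        if self.retention_noise_sd < 0 or self.logd_noise_sd < 0:
            raise InvalidConfigError("noise standard deviations must be >= 0")
        if len(self.phi_values) < 4 or not all(0 < p < 1 for p in self.phi_values):
            raise InvalidConfigError("φ grid must hold >= 4 levels strictly in (0, 1)")
        as_ph_grid(self.ph_values)
        missing = [ph for ph in self.ph_values if ph not in self.true_models]
        if missing:
            raise InvalidConfigError(f"no true model for pH values {missing}")

    @property
    def n_compounds(self) -> int:
        return self.n_model + self.n_verification + self.n_sample


@dataclass(frozen=True)
class CompoundTruth:
    """Ground truth behind one generated compound."""

    compound_id: str
    logp: float
    pka1: float
    pka2: Optional[float]
    A: float
    B: float
    logkw: Mapping[float, float]  # per pH, after relation scatter
    S: Mapping[float, float]  # per pH

    def logd(self, ph: float) -> float:
        return logd_base(self.logp, self.pka1, ph, self.pka2)


def _roles(config: GeneratorConfig) -> list[str]:
    return (
        ["model"] * config.n_model
        + ["verification"] * config.n_verification
        + ["sample"] * config.n_sample
    )


def _generate_truths(
    config: GeneratorConfig, rng: np.random.Generator
) -> list[CompoundTruth]:
    ph_ref = max(config.ph_values)
    ref_model = config.true_models[ph_ref]
    truths = []
    for i, role in enumerate(_roles(config)):
        if role == "verification":
            lo, hi = config.verification_pka_range
            kw_lo, kw_hi = config.verification_logkw_range
        else:
            lo, hi = config.pka_range
            kw_lo, kw_hi = config.logkw_range
        pka1 = rng.uniform(lo, hi)
        pka2 = None
        if role != "verification" and rng.random() < config.p_diprotic:
            pka2 = pka1 - rng.uniform(2.5, 4.5)
        A = rng.uniform(*config.a_range)
        B = rng.uniform(*config.b_range)
        logkw_ref = rng.uniform(kw_lo, kw_hi)

        # Anchor logP so that the ionization law and the reference-pH QSRR
        # relation agree exactly at the most alkaline pH of the grid.
        desc_ref = {"n_e": default_ne(pka1, ph_ref, pka2), "A": A, "B": B}
        logd_ref = ref_model.value(logkw_ref, desc_ref)
        denom = 1.0 + 10.0 ** (pka1 - ph_ref)
        if pka2 is not None:
            denom += 10.0 ** (pka1 + pka2 - 2.0 * ph_ref)
        logp = logd_ref + np.log10(denom)

        logkw: dict[float, float] = {}
        s_values: dict[float, float] = {}
        s0, s1, s_jitter = config.s_coupling
        for ph in config.ph_values:
            desc = {"n_e": default_ne(pka1, ph, pka2), "A": A, "B": B}
            logd_ph = logd_base(logp, pka1, ph, pka2)
            eps = rng.normal(0.0, config.logd_noise_sd) if config.logd_noise_sd else 0.0
            kw = config.true_models[ph].invert_logkw(logd_ph - eps, desc)
            logkw[ph] = kw
            s_raw = s0 + s1 * kw + (rng.normal(0.0, s_jitter) if s_jitter else 0.0)
            s_values[ph] = max(s_raw, 0.3)
        truths.append(
            CompoundTruth(
                compound_id=f"syn{i + 1:02d}",
                logp=float(logp),
                pka1=float(pka1),
                pka2=None if pka2 is None else float(pka2),
                A=float(A),
                B=float(B),
                logkw=logkw,
                S=s_values,
            )
        )
    return truths


def _to_compound(truth: CompoundTruth, role: str, config: GeneratorConfig) -> Compound:
    ne = {
        ph: default_ne(truth.pka1, ph, truth.pka2) for ph in config.ph_values
    }
    return Compound(
        id=truth.compound_id,
        name=f"synthetic {role} compound {truth.compound_id}",
        role=role,
        logp=None if role == "sample" else truth.logp,
        pka1=truth.pka1,
        pka2=truth.pka2,
        A=truth.A,
        B=truth.B,
        ne=ne,
    )


def generate_compounds(config: GeneratorConfig) -> list[Compound]:
    """Generate the compound table alone (deterministic under the seed).

    Sample compounds are emitted without a logP, as in a real study where
    their partition coefficients are the unknowns; the full truth is
    available through :func:`generate_study`.
    """
    rng = np.random.default_rng(config.seed)
    truths = _generate_truths(config, rng)
    return [_to_compound(t, role, config) for t, role in zip(truths, _roles(config))]


def simulate_retention(
    truth: CompoundTruth,
    config: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
    max_retries: int = 100,
) -> list[RetentionSeries]:
    """One retention series per pH for a compound with assigned truth.

    Retention times follow t_R = t_0·(1 + 10^(logk_w − S·φ)) plus Gaussian
    noise; a draw that would put t_R at or below the dead time is re-drawn
    (bounded retries, logged) and the point is dropped if the retries are
    exhausted.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    series = []
    for ph in config.ph_values:
        kw, s = truth.logkw[ph], truth.S[ph]
        points = []
        for phi in config.phi_values:
            clean = config.t0 * (1.0 + 10.0 ** (kw - s * phi))
            tr = clean
            if config.retention_noise_sd:
                tr = clean + rng.normal(0.0, config.retention_noise_sd)
                retries = 0
                while tr <= config.t0 and retries < max_retries:
                    tr = clean + rng.normal(0.0, config.retention_noise_sd)
                    retries += 1
                if retries:
                    logger.info(
                        "%s pH %s φ=%.2f: %d noise re-draws near the dead time",
                        truth.compound_id, ph, phi, retries,
                    )
                if tr <= config.t0:
                    logger.warning(
                        "%s pH %s φ=%.2f: dropped (t_R pinned at the dead time)",
                        truth.compound_id, ph, phi,
                    )
                    continue
            points.append((phi, float(tr)))
        series.append(
            RetentionSeries(
                compound_id=truth.compound_id,
                ph=ph,
                t0=config.t0,
                points=tuple(points),
            )
        )
    return series


@dataclass(frozen=True)
class StudyBundle:
    """A complete synthetic study: inputs plus the truth that made them."""

    config: GeneratorConfig
    compounds: list[Compound]
    truths: list[CompoundTruth]
    series: list[RetentionSeries]

    @property
    def true_models(self) -> Mapping[float, TrueModel]:
        return self.config.true_models

    def truth_for(self, compound_id: str) -> CompoundTruth:
        for t in self.truths:
            if t.compound_id == compound_id:
                return t
        raise KeyError(compound_id)

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Emit compounds.csv, retention.csv and truth.json into a directory."""
        from . import io as cio

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "compounds": directory / "compounds.csv",
            "retention": directory / "retention.csv",
            "truth": directory / "truth.json",
        }
        cio.write_compounds(paths["compounds"], self.compounds, self.config.ph_values)
        cio.write_retention(paths["retention"], self.series)
        truth = {
            "true_models": {
                str(ph): {"subset": list(m.subset), "coef": dict(m.coef)}
                for ph, m in sorted(self.true_models.items())
            },
            "compounds": [
                {
                    "compound_id": t.compound_id,
                    "logp": t.logp,
                    "pka1": t.pka1,
                    "pka2": t.pka2,
                    "A": t.A,
                    "B": t.B,
                    "logkw": {str(ph): v for ph, v in t.logkw.items()},
                    "S": {str(ph): v for ph, v in t.S.items()},
                }
                for t in self.truths
            ],
        }
        paths["truth"].write_text(json.dumps(truth, indent=1))
        return paths


def generate_study(config: Optional[GeneratorConfig] = None, **overrides) -> StudyBundle:
    """Generate a full study bundle under the configured conditions.

    Keyword overrides are applied to the default config, so
    ``generate_study(seed=7, logd_noise_sd=0.0)`` is a convenient spelling
    for small variations.
    """
    if config is None:
        config = GeneratorConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    rng = np.random.default_rng(config.seed)
    truths = _generate_truths(config, rng)
    compounds = [_to_compound(t, role, config) for t, role in zip(truths, _roles(config))]
    series: list[RetentionSeries] = []
    for truth in truths:
        series.extend(simulate_retention(truth, config, rng))
    return StudyBundle(config=config, compounds=compounds, truths=truths, series=series)
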