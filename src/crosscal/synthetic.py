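"""Synthetic paired-assay cohorts for testing the cross-calibration pipeline.

The generator emulates the structure of a middle-aged cardiometabolic cohort
in which four inflammation biomarkers (CRP, SAA, sICAM-1, sVCAM-1) were each
measured by two channels: a single-biomarker reference assay (method A) and
a multiplex platform (method B) whose expected reading is a linear
recalibration of the true level.  Concentrations are right-skewed and are
modeled log-normally; ordered risk-factor groups (e.g. glucose-metabolism
status) shift the true level on the log scale, so biomarker gradients are
multiplicative, matching the skewed marginals.  Measurement noise is
multiplicative Gaussian with a constant CV per method - the proportional-
error model that weighted Deming regression assumes.

Generative model per subject i and analyte:

    log t_i   = log_mean + sum_g shift_g[group_i] + log_sd * z_i
    method A  = t_i * (1 + cv_a * e_i)
    method B  = (alpha + beta * t_i) * (1 + cv_b * f_i)

with z, e, f independent standard normal and all measured values floored at
a small positive constant.  Each analyte draws from its own deterministic
substream of the master seed, so adding an analyte leaves the others'
values unchanged.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .deming import PairedMeasurements
from .errors import ConfigurationError
from .realign import CalibrationEquation

__all__ = [
    "AnalyteSpec",
    "GroupSpec",
    "CovariateModel",
    "SyntheticCohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "default_codam_config",
    "lognormal_params_from_median_iqr",
    "lognormal_params_from_mean_sd",
]

_VALUE_FLOOR = 1e-6


def _stream(seed: int, *key: str) -> np.random.Generator:
    """Deterministic substream keyed by (seed, *key); order-independent."""
    digest = hashlib.sha256(("::".join(key)).encode()).digest()
    spawn_key = tuple(int.from_bytes(digest[i : i + 4], "big") for i in range(0, 16, 4))
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(seed, spawn_key=spawn_key))
    )


def lognormal_params_from_median_iqr(
    median: float, q1: float, q3: float
) -> tuple[float, float]:
    """(log_mean, log_sd) of the log-normal with the given median and IQR."""
    if not (0 < q1 < median < q3):
        raise ConfigurationError("need 0 < q1 < median < q3")
    z75 = stats.norm.ppf(0.75)
    return math.log(median), (math.log(q3) - math.log(q1)) / (2 * z75)


def lognormal_params_from_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    """(log_mean, log_sd) of the log-normal with the given arithmetic mean/SD."""
    if mean <= 0 or sd < 0:
        raise ConfigurationError("need mean > 0 and sd >= 0")
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


@dataclass(frozen=True)
class AnalyteSpec:
    """Distribution, noise and calibration parameters of one analyte.

    ``log_mean``/``log_sd`` describe the log-normal true level (method-A
    scale); ``cv_method_*`` are fractional constant CVs of the multiplicative
    noise; ``calibration`` maps the true level to the expected method-B value.
    """

    name: str
    log_mean: float
    log_sd: float
    cv_method_a: float
    cv_method_b: float
    calibration: CalibrationEquation

    def __post_init__(self) -> None:
        if self.log_sd < 0:
            raise ConfigurationError(f"{self.name}: log_sd must be >= 0")
        for cv in (self.cv_method_a, self.cv_method_b):
            if not (0 <= cv < 1):
                raise ConfigurationError(f"{self.name}: CVs must lie in [0, 1)")
        if self.calibration.slope <= 0:
            raise ConfigurationError(
                f"{self.name}: calibration slope must be positive "
                "(methods are positively related)"
            )


@dataclass(frozen=True)
class GroupSpec:
    """One ordered risk-factor grouping and its log-scale level shifts.

    ``level_shifts`` is either a single per-level sequence applied to every
    analyte or a mapping analyte name -> per-level sequence.
    """

    factor_name: str
    ordered_levels: tuple[str, ...]
    level_shifts: Mapping[str, tuple[float, ...]] | tuple[float, ...]
    level_proportions: tuple[float, ...]

    def __post_init__(self) -> None:
        levels = tuple(self.ordered_levels)
        props = tuple(float(p) for p in self.level_proportions)
        object.__setattr__(self, "ordered_levels", levels)
        object.__setattr__(self, "level_proportions", props)
        if len(props) != len(levels):
            raise ConfigurationError("one proportion per level required")
        if any(p < 0 for p in props) or abs(sum(props) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"{self.factor_name}: proportions must be >= 0 and sum to 1"
            )
        if isinstance(self.level_shifts, Mapping):
            shifts = {k: tuple(map(float, v)) for k, v in self.level_shifts.items()}
            for k, v in shifts.items():
                if len(v) != len(levels):
                    raise ConfigurationError(f"{self.factor_name}/{k}: one shift per level")
            object.__setattr__(self, "level_shifts", shifts)
        else:
            shifts_t = tuple(float(s) for s in self.level_shifts)
            if len(shifts_t) != len(levels):
                raise ConfigurationError(f"{self.factor_name}: one shift per level")
            object.__setattr__(self, "level_shifts", shifts_t)

    def shifts_for(self, analyte: str) -> np.ndarray:
        if isinstance(self.level_shifts, Mapping):
            if analyte not in self.level_shifts:
                return np.zeros(len(self.ordered_levels))
            return np.asarray(self.level_shifts[analyte], dtype=float)
        return np.asarray(self.level_shifts, dtype=float)


@dataclass(frozen=True)
class CovariateModel:
    """Marginal distributions of the clinical covariates.

    Covariates are drawn independently of the biomarkers: the joint
    distribution of covariates and inflammation levels is not part of the
    emulated structure.
    """

    age_mean: float = 59.6
    age_sd: float = 7.0
    female_fraction: float = 0.387
    egfr_mean: float = 95.7
    egfr_sd: float = 19.0
    prior_cvd_fraction: float = 0.276


@dataclass(frozen=True)
class SyntheticCohortConfig:
    n_subjects: int
    analytes: tuple[AnalyteSpec, ...]
    groups: tuple[GroupSpec, ...] = ()
    covariates: CovariateModel = field(default_factory=CovariateModel)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "analytes", tuple(self.analytes))
        object.__setattr__(self, "groups", tuple(self.groups))
        if self.n_subjects < 3:
            raise ConfigurationError("n_subjects must be >= 3")

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=str, sort_keys=True)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)


@dataclass
class SyntheticCohort:
    """Realized cohort: one row per subject, one column group per analyte."""

    data: pd.DataFrame
    config: SyntheticCohortConfig

    def pairs(self, analyte: str) -> PairedMeasurements:
        return PairedMeasurements.from_dataframe(
            self.data, f"{analyte}_methodA", f"{analyte}_methodB", id_col="id"
        )

    def true_levels(self, analyte: str) -> np.ndarray:
        return self.data[f"{analyte}_true"].to_numpy()

    def to_csv(self, path, include_true: bool = False) -> None:
        frame = self.data
        if not include_true:
            frame = frame[[c for c in frame.columns if not c.endswith("_true")]]
        frame.to_csv(path, index=False)


def generate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Draw a cohort from the generative model; same config+seed => same data."""
    n = config.n_subjects
    cov = config.covariates
    rng_cov = _stream(config.seed, "covariates")
    frame = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "age": rng_cov.normal(cov.age_mean, cov.age_sd, n).round(1),
            "female": (rng_cov.random(n) < cov.female_fraction).astype(int),
            "egfr": rng_cov.normal(cov.egfr_mean, cov.egfr_sd, n).round(1),
            "prior_cvd": (rng_cov.random(n) < cov.prior_cvd_fraction).astype(int),
        }
    )

    group_codes: dict[str, np.ndarray] = {}
    for g in config.groups:
        rng_g = _stream(config.seed, "group", g.factor_name)
        codes = rng_g.choice(len(g.ordered_levels), size=n, p=g.level_proportions)
        group_codes[g.factor_name] = codes
        frame[g.factor_name] = pd.Categorical.from_codes(
            codes, categories=list(g.ordered_levels), ordered=True
        )

    for spec in config.analytes:
        rng_a = _stream(config.seed, "analyte", spec.name)
        z = rng_a.standard_normal(n)
        e = rng_a.standard_normal(n)
        f = rng_a.standard_normal(n)
        log_true = spec.log_mean + spec.log_sd * z
        for g in config.groups:
            shifts = g.shifts_for(spec.name)
            log_true = log_true + shifts[group_codes[g.factor_name]]
        true = np.exp(log_true)
        a = np.maximum(true * (1.0 + spec.cv_method_a * e), _VALUE_FLOOR)
        expected_b = spec.calibration.intercept + spec.calibration.slope * true
        b = np.maximum(expected_b * (1.0 + spec.cv_method_b * f), _VALUE_FLOOR)
        frame[f"{spec.name}_true"] = true
        frame[f"{spec.name}_methodA"] = a
        frame[f"{spec.name}_methodB"] = b

    return SyntheticCohort(data=frame, config=config)


# -- default cohort configuration -------------------------------------------
#
# Defaults reproduce the published structure of the emulated cohort:
# n = 550 subjects with complete paired data; log-normal marginals matched to
# the reported total-population median [IQR] (CRP, SAA) or mean +/- SD
# (sICAM-1, sVCAM-1) on the single-biomarker channel; method-B calibrations
# equal to the published Deming equations (single-biomarker -> multiplex);
# noise CVs equal to the printed intra-assay CVs of each channel; one ordered
# group factor (glucose metabolism NGM/IGM/DM2) whose log-scale shifts are
# derived from the per-group location estimates, centered to leave the
# population marginal in place.

_TOTAL_STATS = {
    # name: (kind, params on the single-biomarker channel)
    "CRP": ("median_iqr", (2.6, 1.4, 4.5)),
    "SAA": ("median_iqr", (7.0, 4.0, 13.8)),
    "sICAM1": ("mean_sd", (350.0, 91.0)),
    "sVCAM1": ("mean_sd", (476.0, 121.0)),
}

_INTRA_ASSAY_CV = {
    # name: (single-biomarker channel, multiplex channel)
    "CRP": (0.006, 0.030),
    "SAA": (0.061, 0.025),
    "sICAM1": (0.056, 0.025),
    "sVCAM1": (0.031, 0.026),
}

_CALIBRATIONS = {
    # single-biomarker -> multiplex: (intercept, slope)
    "CRP": (-0.33, 0.93),
    "SAA": (0.47, 0.14),
    "sICAM1": (36.01, 0.53),
    "sVCAM1": (77.83, 0.55),
}

# per-group location of the single-biomarker channel (same kind as above):
# glucose metabolism NGM / IGM / DM2
_GLUCOSE_GROUP_STATS = {
    "CRP": (2.2, 2.8, 3.2),
    "SAA": (6.2, 8.0, 8.1),
    "sICAM1": (338.0, 354.0, 373.0),
    "sVCAM1": (463.0, 467.0, 510.0),
}
_GLUCOSE_LEVELS = ("NGM", "IGM", "DM2")
_GLUCOSE_COUNTS = (291, 122, 137)  # of 550 complete-case subjects


def _total_lognormal(name: str) -> tuple[float, float]:
    kind, params = _TOTAL_STATS[name]
    if kind == "median_iqr":
        return lognormal_params_from_median_iqr(*params)
    return lognormal_params_from_mean_sd(*params)


def default_codam_config(seed: int = 0) -> SyntheticCohortConfig:
    """Default cohort configuration mirroring the emulated study structure.

    Two calls differing only in ``seed`` return configs identical in every
    other field.
    """
    analytes = []
    for name in _TOTAL_STATS:
        log_mean, log_sd = _total_lognormal(name)
        cv_a, cv_b = _INTRA_ASSAY_CV[name]
        alpha, beta = _CALIBRATIONS[name]
        analytes.append(
            AnalyteSpec(
                name=name,
                log_mean=log_mean,
                log_sd=log_sd,
                cv_method_a=cv_a,
                cv_method_b=cv_b,
                calibration=CalibrationEquation(
                    intercept=alpha,
                    slope=beta,
                    source_method="single",
                    target_method="multiplex",
                ),
            )
        )

    props = np.asarray(_GLUCOSE_COUNTS, dtype=float)
    props /= props.sum()
    shifts: dict[str, tuple[float, ...]] = {}
    for name, stats_by_group in _GLUCOSE_GROUP_STATS.items():
        kind, total_params = _TOTAL_STATS[name]
        total_loc = total_params[0]
        raw = np.log(np.asarray(stats_by_group) / total_loc)
        raw -= float(props @ raw)  # center: population marginal unchanged
        shifts[name] = tuple(raw)
    group = GroupSpec(
        factor_name="glucose_metabolism",
        ordered_levels=_GLUCOSE_LEVELS,
        level_shifts=shifts,
        level_proportions=tuple(props),
    )

    return SyntheticCohortConfig(
        n_subjects=550,
        analytes=tuple(analytes),
        groups=(group,),
        covariates=CovariateModel(),
        seed=seed,
    )


def with_seed(config: SyntheticCohortConfig, seed: int) -> SyntheticCohortConfig:
    return replace(config, seed=seed)
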