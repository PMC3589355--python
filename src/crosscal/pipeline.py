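"""End-to-end cross-validation workflow between two measurement methods.

Per analyte: Pearson correlation -> weighted Deming fit (both directions,
with jackknife CIs) -> realignment of method A onto method B's scale (and
vice versa) -> Bland-Altman agreement before/after realignment -> ICC of the
realigned-vs-target matrix -> for analytes with a risk-band scheme (CRP),
the 3x3 reclassification table with Cohen's kappa and concordance before and
after realignment in both directions.  Optionally, Z-score gradients across
ordered risk groups with the group-by-method interaction check.

The method-A -> method-B direction is reported as the primary realignment
(the direction in which an incoming platform replaces a legacy assay); both
directions are always computed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agreement, categorical, deming, groups, realign, synthetic
from .errors import ConfigurationError, CrossCalError

__all__ = ["StudyConfig", "run_cross_validation", "filter_acute_crp"]

logger = logging.getLogger("crosscal")


@dataclass
class StudyConfig:
    """Everything needed to run the workflow on one cohort.

    Exactly one of ``input_csv`` or ``synthetic`` must be given.  The
    ``analytes`` mapping names each analyte's (method-A, method-B) columns;
    for a synthetic cohort it defaults to the generated column layout.
    """

    input_csv: str | Path | None = None
    synthetic: synthetic.SyntheticCohortConfig | None = None
    analytes: dict[str, tuple[str, str]] | None = None
    lambda_ratio: float = 1.0
    outlier_threshold: float = 4.0
    ba_scale: str = "auto"
    quantitation_floor: float = 1e-6
    risk_schemes: dict[str, categorical.RiskCategoryScheme] = field(
        default_factory=lambda: {"CRP": categorical.CRP_RISK_SCHEME}
    )
    group_column: str | None = None
    group_levels: list[str] | None = None
    covariate_columns: list[str] = field(default_factory=list)
    log_first: dict[str, bool] = field(
        default_factory=lambda: {"CRP": True, "SAA": True}
    )
    crp_exclude_above: float | None = None  # mg/l; acute-inflammation filter
    compute_ci: bool = True
    out_dir: str | Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.synthetic is None):
            raise ConfigurationError("give exactly one of input_csv or synthetic")
        if self.outlier_threshold is not None and self.outlier_threshold <= 0:
            raise ConfigurationError("outlier_threshold must be positive")
        if self.crp_exclude_above is not None and self.crp_exclude_above <= 0:
            raise ConfigurationError("crp_exclude_above must be positive")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if "risk_schemes" in payload:
            payload["risk_schemes"] = {
                k: categorical.RiskCategoryScheme(**v)
                for k, v in payload["risk_schemes"].items()
            }
        if "analytes" in payload and payload["analytes"] is not None:
            payload["analytes"] = {
                k: tuple(v) for k, v in payload["analytes"].items()
            }
        return cls(**payload)


def filter_acute_crp(
    frame: pd.DataFrame, threshold: float, crp_column: str
) -> pd.DataFrame:
    """Drop subjects whose reference-method CRP exceeds ``threshold`` (mg/l).

    High CRP more likely reflects acute inflammation or infection than the
    low-grade inflammation of interest; exclusion is complete-case (the
    subject leaves every analyte's table).
    """
    if threshold <= 0:
        raise ConfigurationError("threshold must be positive")
    return frame.loc[frame[crp_column] <= threshold].reset_index(drop=True)


def _load_cohort(config: StudyConfig) -> tuple[pd.DataFrame, dict[str, tuple[str, str]]]:
    if config.synthetic is not None:
        cohort = synthetic.generate_cohort(config.synthetic)
        frame = cohort.data
        analytes = config.analytes or {
            spec.name: (f"{spec.name}_methodA", f"{spec.name}_methodB")
            for spec in config.synthetic.analytes
        }
    else:
        frame = pd.read_csv(config.input_csv)
        if not config.analytes:
            raise ConfigurationError("analytes column mapping required for CSV input")
        analytes = config.analytes
    missing = [
        c for cols in analytes.values() for c in cols if c not in frame.columns
    ]
    missing += [
        c
        for c in (config.covariate_columns or [])
        + ([config.group_column] if config.group_column else [])
        if c not in frame.columns
    ]
    if missing:
        raise ConfigurationError(f"columns not found in cohort: {missing}")
    return frame, analytes


def _ba_payload(res: agreement.BlandAltmanResult) -> dict:
    payload = {
        "scale": res.scale,
        "mean_difference": res.mean_difference,
        "sd_difference": res.sd_difference,
        "loa_low": res.loa_low,
        "loa_high": res.loa_high,
        "n": res.n,
    }
    if res.multiplicative_loa is not None:
        payload["multiplicative_loa"] = list(res.multiplicative_loa)
        payload["multiplicative_mean"] = res.multiplicative_mean
    return payload


def _fit_payload(fit: deming.DemingFit) -> dict:
    payload = {
        "intercept": fit.intercept,
        "slope": fit.slope,
        "sylx": fit.sylx,
        "lambda_ratio": fit.lambda_ratio,
        "n_pairs": fit.n_pairs,
        "converged": fit.converged,
        "n_iterations": fit.n_iterations,
    }
    if fit.intercept_ci is not None:
        payload["intercept_ci"] = list(fit.intercept_ci)
        payload["slope_ci"] = list(fit.slope_ci)
    return payload


def _reclassification(
    values_a: np.ndarray,
    values_b: np.ndarray,
    eq_ab: realign.CalibrationEquation,
    eq_ba: realign.CalibrationEquation,
    scheme: categorical.RiskCategoryScheme,
) -> dict:
    """Kappa/concordance before realignment and after, in both directions."""
    out = {}
    cat_a = categorical.categorize(values_a, scheme)
    cat_b = categorical.categorize(values_b, scheme)
    blocks = {
        "unaligned": (cat_a, cat_b),
        "a_realigned_to_b": (
            categorical.categorize(realign.realign(values_a, eq_ab), scheme),
            cat_b,
        ),
        "b_realigned_to_a": (
            cat_a,
            categorical.categorize(realign.realign(values_b, eq_ba), scheme),
        ),
    }
    for key, (ra, rb) in blocks.items():
        table = categorical.crosstab(ra, rb, scheme)
        kap = categorical.cohens_kappa(table)
        out[key] = {
            "kappa": kap.kappa,
            "observed_agreement": kap.observed_agreement,
            "expected_agreement": kap.expected_agreement,
            "concordance": categorical.concordance(table),
            "table_counts": table.table.to_numpy().astype(int).tolist(),
            "labels": list(scheme.labels),
        }
    return out


def run_cross_validation(config: StudyConfig) -> dict:
    """Run the full workflow; returns (and optionally writes) the report.

    Per-analyte failures are isolated: the error is recorded under that
    analyte and the remaining analytes still run.
    """
    frame, analytes = _load_cohort(config)
    n_loaded = len(frame)
    if config.crp_exclude_above is not None and "CRP" in analytes:
        frame = filter_acute_crp(
            frame, config.crp_exclude_above, analytes["CRP"][0]
        )
        logger.info(
            "acute-CRP filter >%s: %d of %d subjects retained",
            config.crp_exclude_above,
            len(frame),
            n_loaded,
        )

    report: dict = {
        "config": {
            "lambda_ratio": config.lambda_ratio,
            "outlier_threshold": config.outlier_threshold,
            "ba_scale": config.ba_scale,
            "crp_exclude_above": config.crp_exclude_above,
            "seed": config.seed,
            "n_subjects_loaded": n_loaded,
            "n_subjects_analyzed": len(frame),
            "synthetic": config.synthetic.to_json() if config.synthetic else None,
        },
        "analytes": {},
    }

    for name, (col_a, col_b) in analytes.items():
        try:
            report["analytes"][name] = _analyze_one(frame, name, col_a, col_b, config)
        except CrossCalError as exc:
            logger.error("analyte %s failed: %s", name, exc)
            report["analytes"][name] = {"error": str(exc)}

    if config.group_column:
        table = groups.gradient_table(
            frame.dropna(subset=[c for cols in analytes.values() for c in cols]),
            analytes,
            config.group_column,
            config.group_levels
            or list(pd.unique(frame[config.group_column])),
            config.covariate_columns or None,
            config.log_first,
        )
        report["group_gradients"] = table.to_dict(orient="records")

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        rows = []
        for name, block in report["analytes"].items():
            if "error" in block:
                continue
            rows.append(
                {
                    "analyte": name,
                    "n_pairs": block["n_pairs"],
                    "pearson_r": block["pearson_r"],
                    "icc_realigned": block["icc_realigned"],
                    "slope_a_to_b": block["fit_a_to_b"]["slope"],
                    "intercept_a_to_b": block["fit_a_to_b"]["intercept"],
                    "ba_mean_diff_realigned": block["bland_altman_realigned"][
                        "mean_difference"
                    ],
                }
            )
        pd.DataFrame(rows).to_csv(out / "summary.csv", index=False)
    return report


def _analyze_one(
    frame: pd.DataFrame, name: str, col_a: str, col_b: str, config: StudyConfig
) -> dict:
    pairs = deming.PairedMeasurements.from_dataframe(frame, col_a, col_b, id_col="id" if "id" in frame.columns else None)
    pairs = deming.exclude_below_quantitation(pairs, config.quantitation_floor)
    if config.outlier_threshold is not None:
        pairs = deming.flag_outliers(
            pairs, config.outlier_threshold, config.lambda_ratio
        )
    x, y = pairs.retained()

    fit_ab = deming.weighted_deming_fit(pairs, config.lambda_ratio)
    pairs_ba = deming.PairedMeasurements(pairs.y, pairs.x, pairs.ids, pairs.excluded)
    fit_ba = deming.weighted_deming_fit(pairs_ba, config.lambda_ratio)
    if config.compute_ci:
        fit_ab = deming.jackknife_ci(
            pairs, lambda p: deming.weighted_deming_fit(p, config.lambda_ratio)
        )
        fit_ba = deming.jackknife_ci(
            pairs_ba, lambda p: deming.weighted_deming_fit(p, config.lambda_ratio)
        )

    eq_ab = realign.CalibrationEquation.from_fit(fit_ab, col_a, col_b)
    eq_ba = realign.CalibrationEquation.from_fit(fit_ba, col_b, col_a)
    x_on_b = realign.realign(x, eq_ab)

    block = {
        "n_pairs": int(x.size),
        "n_excluded_outliers": int(
            (pairs.reasons == "outlier").sum()
        ),
        "pearson_r": agreement.pearson_r(x, y),
        "fit_a_to_b": _fit_payload(fit_ab),
        "fit_b_to_a": _fit_payload(fit_ba),
        "realignment_a_to_b": {"intercept": eq_ab.intercept, "slope": eq_ab.slope},
        "realignment_b_to_a": {"intercept": eq_ba.intercept, "slope": eq_ba.slope},
        "bland_altman_unaligned": _ba_payload(
            agreement.bland_altman(x, y, scale=config.ba_scale)
        ),
        "bland_altman_realigned": _ba_payload(
            agreement.bland_altman(
                x_on_b,
                y,
                scale="raw" if (x_on_b <= 0).any() else config.ba_scale,
            )
        ),
        "icc_realigned": agreement.icc_absolute_agreement(
            np.column_stack([x_on_b, y])
        ).icc,
    }
    scheme = config.risk_schemes.get(name)
    if scheme is not None:
        block["reclassification"] = _reclassification(x, y, eq_ab, eq_ba, scheme)
    return block
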