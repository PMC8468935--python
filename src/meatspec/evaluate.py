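"""Model performance statistics, RPD grading and experiment-grid reports.

Conventions: RMSE uses the ``n`` divisor; R-squared is ``1 - SSE/SST``
about the observed mean (a squared-Pearson variant is available via a
flag); RPD divides the ``n-1`` standard deviation of the prediction-set
reference values by RMSEP.  These are the conventions under which the
grading bands below are interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._defaults import PROPERTIES
from .generate import SyntheticDataset
from .pls import fit_plsr, predict, select_components
from .preprocess import PreprocessingChain, apply_chain, get_preset
from .split import SplitAssignment, carcass_split, concentration_gradient_split
from .spectra import SpectraSet

__all__ = [
    "rmse",
    "r_squared",
    "rpd",
    "rpd_from_sd",
    "rpd_grade",
    "RPD_GRADE_BANDS",
    "ModelReport",
    "run_experiment_grid",
    "report_to_frame",
    "format_report_text",
    "descriptive_table",
    "correlation_table",
]


def rmse(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Root-mean-square error with the ``n`` divisor."""
    observed = np.asarray(observed, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if observed.size != predicted.size:
        raise ValueError("observed and predicted must have equal length")
    if observed.size == 0:
        raise ValueError("need at least one observation")
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


def r_squared(
    observed: np.ndarray, predicted: np.ndarray, method: str = "sse"
) -> float:
    """Coefficient of determination.

    ``method='sse'`` (default): 1 - SSE/SST with SST about the observed
    mean.  ``method='pearson'``: squared Pearson correlation between
    observed and predicted.
    """
    observed = np.asarray(observed, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if observed.size != predicted.size:
        raise ValueError("observed and predicted must have equal length")
    sst = float(np.sum((observed - observed.mean()) ** 2))
    if sst <= 0:
        raise ValueError("observed values are constant; R^2 undefined")
    if method == "sse":
        sse = float(np.sum((observed - predicted) ** 2))
        return 1.0 - sse / sst
    if method == "pearson":
        r = np.corrcoef(observed, predicted)[0, 1]
        return float(r * r)
    raise ValueError(f"unknown R^2 method {method!r}")


def rpd(prediction_references: np.ndarray, rmsep: float) -> float:
    """SD (n-1) of the prediction-set reference values divided by RMSEP."""
    values = np.asarray(prediction_references, dtype=float).ravel()
    if values.size < 2:
        raise ValueError("RPD needs at least two prediction samples")
    return rpd_from_sd(float(values.std(ddof=1)), rmsep)


def rpd_from_sd(sd: float, rmsep: float) -> float:
    """RPD from a pre-computed reference SD and an RMSEP."""
    if rmsep <= 0:
        raise ValueError("RMSEP must be positive for RPD")
    if sd < 0:
        raise ValueError("SD must be non-negative")
    return sd / rmsep


#: (lower bound inclusive, grade label), descending.
RPD_GRADE_BANDS: tuple[tuple[float, str], ...] = (
    (4.0, "excellent"),
    (3.5, "process control"),
    (3.0, "quality control"),
    (2.5, "screening"),
    (2.0, "rough screening"),
    (0.0, "not recommended"),
)


def rpd_grade(rpd_value: float) -> str:
    """Ordinal model-quality grade for an RPD value."""
    if rpd_value < 0:
        raise ValueError("RPD must be >= 0")
    for bound, label in RPD_GRADE_BANDS:
        if rpd_value >= bound:
            return label
    return RPD_GRADE_BANDS[-1][1]  # pragma: no cover


# ----------------------------------------------------------------------
# Experiment grid


@dataclass
class ModelReport:
    """One evaluated (property, preprocessing chain) cell of the grid."""

    property_name: str
    chain_label: str
    chain_name: str
    n_components: int
    r2_calibration: float
    rmsec: float
    r2_prediction: float
    rmsep: float
    rpd: float
    grade: str
    n_calibration: int
    n_prediction: int
    prediction_sd: float
    is_best: bool = False
    error: str | None = None
    model: object = field(default=None, repr=False)
    chain_state: dict | None = field(default=None, repr=False)
    chain: PreprocessingChain | None = field(default=None, repr=False)


def _resolve_chain(chain: str | PreprocessingChain) -> tuple[str, PreprocessingChain]:
    if isinstance(chain, PreprocessingChain):
        return chain.label, chain
    return chain, get_preset(chain)


def _evaluate_cell(
    spectra: SpectraSet,
    y: pd.Series,
    chain_name: str,
    chain: PreprocessingChain,
    split: SplitAssignment,
    max_components: int,
    r2_method: str,
) -> ModelReport:
    cal = spectra.subset(split.calibration_ids)
    pred = spectra.subset(split.prediction_ids)
    cal_t, state = apply_chain(cal, chain)
    pred_t, _ = apply_chain(pred, chain, fitted_state=state)

    y_cal = y.loc[split.calibration_ids].to_numpy(dtype=float)
    y_pred = y.loc[split.prediction_ids].to_numpy(dtype=float)

    cv = select_components(cal_t.reflectance, y_cal, max_components=max_components)
    model = fit_plsr(
        cal_t.reflectance, y_cal, cv.n_components, property_name=str(y.name)
    )
    yhat_cal = predict(model, cal_t.reflectance)
    yhat_pred = predict(model, pred_t.reflectance)

    rmsep = rmse(y_pred, yhat_pred)
    report = ModelReport(
        property_name=str(y.name),
        chain_label=chain.label,
        chain_name=chain_name,
        n_components=model.n_components,
        r2_calibration=r_squared(y_cal, yhat_cal, method=r2_method),
        rmsec=rmse(y_cal, yhat_cal),
        r2_prediction=r_squared(y_pred, yhat_pred, method=r2_method),
        rmsep=rmsep,
        rpd=rpd(y_pred, rmsep),
        grade="",
        n_calibration=len(y_cal),
        n_prediction=len(y_pred),
        prediction_sd=float(y_pred.std(ddof=1)),
        model=model,
        chain_state=state,
        chain=chain,
    )
    report.grade = rpd_grade(report.rpd)
    return report


def run_experiment_grid(
    dataset: SyntheticDataset | tuple[SpectraSet, pd.DataFrame],
    chains: list[str | PreprocessingChain] | None = None,
    properties: list[str] | None = None,
    split_method: str = "gradient",
    seed: int = 0,
    max_components: int = 15,
    r2_method: str = "sse",
) -> list[ModelReport]:
    """Evaluate every property x preprocessing-chain combination.

    Per property the sample set is divided (per-property gradient splits,
    or one shared carcass split), each chain is fitted on the calibration
    subset and replayed frozen on the prediction subset, the latent-variable
    count is chosen by LOOCV on the calibration subset, and the final model
    is evaluated.  The best chain per property (max RPD, ties to fewer
    components) is flagged.  A failing cell yields a report row carrying
    the error message; the grid continues.
    """
    if isinstance(dataset, SyntheticDataset):
        spectra, references = dataset.spectra, dataset.references
    else:
        spectra, references = dataset
    chains = chains if chains is not None else list(
        ("original", "msc", "snv", "sg", "sg_1der", "sg_2der",
         "sg_detrend_msc", "sg_detrend_snv")
    )
    properties = properties or [p for p in PROPERTIES if p in references.columns]

    shared_split = None
    if split_method == "carcass":
        shared_split = carcass_split(spectra.metadata)
    elif split_method != "gradient":
        raise ValueError(f"unknown split method {split_method!r}")

    reports: list[ModelReport] = []
    for prop in properties:
        y = references[prop]
        if shared_split is not None:
            split = shared_split
        else:
            split = concentration_gradient_split(y, seed=seed, property_name=prop)
        prop_reports: list[ModelReport] = []
        for chain_spec in chains:
            chain_name, chain = _resolve_chain(chain_spec)
            try:
                report = _evaluate_cell(
                    spectra, y, chain_name, chain, split, max_components, r2_method
                )
            except Exception as exc:  # record and continue
                report = ModelReport(
                    property_name=prop, chain_label=chain.label, chain_name=chain_name,
                    n_components=0, r2_calibration=np.nan, rmsec=np.nan,
                    r2_prediction=np.nan, rmsep=np.nan, rpd=np.nan, grade="failed",
                    n_calibration=split.n_calibration, n_prediction=split.n_prediction,
                    prediction_sd=np.nan, error=str(exc),
                )
            prop_reports.append(report)
        ok = [r for r in prop_reports if r.error is None]
        if ok:
            best = max(ok, key=lambda r: (r.rpd, -r.n_components))
            best.is_best = True
        reports.extend(prop_reports)
    return reports


def report_to_frame(reports: list[ModelReport], round_decimals: int | None = 2) -> pd.DataFrame:
    """Tabulate grid reports; statistics rounded to 2 decimals by default."""
    rows = []
    for r in reports:
        rows.append(
            {
                "property": r.property_name,
                "preprocessing": r.chain_label,
                "chain": r.chain_name,
                "n_LV": r.n_components,
                "R2_c": r.r2_calibration,
                "RMSEC": r.rmsec,
                "R2_p": r.r2_prediction,
                "RMSEP": r.rmsep,
                "RPD": r.rpd,
                "grade": r.grade,
                "n_cal": r.n_calibration,
                "n_pred": r.n_prediction,
                "best": r.is_best,
                "error": r.error or "",
            }
        )
    frame = pd.DataFrame(rows)
    if round_decimals is not None:
        for col in ("R2_c", "RMSEC", "R2_p", "RMSEP", "RPD"):
            frame[col] = frame[col].round(round_decimals)
    return frame


def format_report_text(reports: list[ModelReport]) -> str:
    """Aligned plain-text report (one block per property)."""
    frame = report_to_frame(reports)
    lines = []
    header = f"{'Preprocessing':<24}{'LVs':>4}{'R2c':>7}{'RMSEC':>8}{'R2p':>7}{'RMSEP':>8}{'RPD':>7}  grade"
    for prop, block in frame.groupby("property", sort=False):
        lines.append(prop)
        lines.append(header)
        for _, row in block.iterrows():
            mark = "*" if row["best"] else " "
            if row["error"]:
                lines.append(f"{mark}{row['preprocessing']:<23} FAILED: {row['error']}")
                continue
            lines.append(
                f"{mark}{row['preprocessing']:<23}{row['n_LV']:>4}"
                f"{row['R2_c']:>7.2f}{row['RMSEC']:>8.2f}"
                f"{row['R2_p']:>7.2f}{row['RMSEP']:>8.2f}{row['RPD']:>7.2f}  {row['grade']}"
            )
        lines.append("")
    return "\n".join(lines)


# ----------------------------------------------------------------------
# Descriptive statistics


def descriptive_table(references: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-cut (plus pooled 'all cuts') max/min/mean/SD/CV% of each property."""
    if "cut_type" not in metadata.columns:
        raise ValueError("metadata must carry a cut_type column")
    cuts = list(dict.fromkeys(metadata["cut_type"]))
    rows = []
    for prop in references.columns:
        groups = [(cut, references.loc[metadata["cut_type"] == cut, prop]) for cut in cuts]
        groups.append(("all cuts", references[prop]))
        for cut, vals in groups:
            v = vals.to_numpy(dtype=float)
            mean = float(v.mean())
            sd = float(v.std(ddof=1)) if v.size > 1 else np.nan
            rows.append(
                {
                    "property": prop,
                    "cut_type": cut,
                    "n": v.size,
                    "max": float(v.max()),
                    "min": float(v.min()),
                    "mean": mean,
                    "sd": sd,
                    "cv_percent": 100.0 * sd / mean if v.size > 1 and mean != 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def correlation_table(references: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation matrix with two-sided p-values.

    p-values use the t transform ``t = r sqrt((n-2)/(1-r^2))`` with n-2
    degrees of freedom.  Constant properties yield NaN entries.
    """
    n = len(references)
    if n < 3:
        raise ValueError("need at least 3 samples for correlation p-values")
    cols = list(references.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    x = references.to_numpy(dtype=float)
    sds = x.std(axis=0, ddof=1)
    for i in range(k):
        for j in range(k):
            if sds[i] < 1e-15 or sds[j] < 1e-15:
                continue
            if i == j:
                r[i, j], p[i, j] = 1.0, 0.0
                continue
            rij = float(np.corrcoef(x[:, i], x[:, j])[0, 1])
            rij = min(1.0, max(-1.0, rij))
            r[i, j] = rij
            if abs(rij) >= 1.0:
                p[i, j] = 0.0
            else:
                t = rij * np.sqrt((n - 2) / (1.0 - rij**2))
                p[i, j] = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )
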