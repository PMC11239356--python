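"""Statistical readouts: count correlations, agreement, survival.

Predicted vs ground-truth cell counts are compared with Pearson's r and
a Huber robust regression line (reporting its R^2).  Ordinal agreement
uses Spearman's rho; inter-observer agreement uses Cohen's kappa.
Patients are stratified by above/below-mean predicted CD3+ T-cell
density, compared with Kaplan-Meier curves, a log-rank test within a
five-year window, and a single-covariate Cox proportional-hazards
ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from sklearn.linear_model import HuberRegressor
from sklearn.metrics import cohen_kappa_score

ABOVE, BELOW = "above_mean", "below_mean"
FIVE_YEARS_MONTHS = 60.0


@dataclass
class EvalSummary:
    pearson_r: float
    pearson_p: float
    huber_slope: float
    huber_intercept: float
    r2: float
    mean_accuracy: float | None
    n: int


def correlate_counts(
    pred, truth, mean_accuracy: float | None = None, epsilon: float = 1.35
) -> EvalSummary:
    """Pearson correlation plus a Huber robust fit of pred on truth.

    R^2 is the coefficient of determination of the Huber line,
    1 - SS_res / SS_tot, evaluated on the data themselves.
    """
    pred = np.asarray(pred, float)
    truth = np.asarray(truth, float)
    if pred.shape != truth.shape or pred.ndim != 1 or len(pred) < 3:
        raise ValueError("pred and truth must be equal-length vectors of length >= 3")
    if pred.std() == 0 or truth.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(truth, pred)
    huber = HuberRegressor(epsilon=epsilon).fit(truth[:, None], pred)
    r2 = huber.score(truth[:, None], pred)
    return EvalSummary(
        pearson_r=float(r),
        pearson_p=float(p),
        huber_slope=float(huber.coef_[0]),
        huber_intercept=float(huber.intercept_),
        r2=float(r2),
        mean_accuracy=mean_accuracy,
        n=len(pred),
    )


def spearman_ordinal(scores_a, scores_b) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties."""
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("inputs must be equal-length vectors of length >= 3")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("rank correlation undefined for constant input")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)


def cohen_kappa(labels_a, labels_b) -> float:
    """Cohen's kappa with marginal-product expected agreement."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    if len(set(a) | set(b)) < 2:
        raise ValueError("kappa undefined when both raters use a single category")
    return float(cohen_kappa_score(a, b))


def stratify_by_mean(densities: pd.DataFrame | dict) -> pd.DataFrame:
    """Assign patients to above/below-mean predicted CD3+ density groups.

    ``densities`` maps patient id to one or more per-image densities
    (or is a DataFrame with columns patient_id, density).  Per-patient
    density is the mean over that patient's images; a patient is
    ``above_mean`` iff strictly above the cohort mean of per-patient
    densities (ties go below).  Groups may be unbalanced.
    """
    if isinstance(densities, dict):
        rows = [(pid, v) for pid, vals in densities.items() for v in np.atleast_1d(vals)]
        densities = pd.DataFrame(rows, columns=["patient_id", "density"])
    if len(densities) == 0:
        raise ValueError("no densities given")
    per_patient = densities.groupby("patient_id", sort=True)["density"].mean()
    cohort_mean = per_patient.mean()
    return pd.DataFrame(
        {
            "patient_id": per_patient.index,
            "density": per_patient.to_numpy(),
            "group": np.where(per_patient.to_numpy() > cohort_mean, ABOVE, BELOW),
        }
    )


def truncate_five_years(records: pd.DataFrame, horizon: float = FIVE_YEARS_MONTHS) -> pd.DataFrame:
    """Censor events beyond the five-year (60-month) window at 60."""
    out = records.copy()
    late = out["time"] > horizon
    out.loc[late, "event"] = 0
    out.loc[late, "time"] = horizon
    return out


def survival_compare(records: pd.DataFrame, truncate: bool = True) -> dict:
    """Two-group survival comparison.

    ``records`` needs columns time (months), event (1 died / 0
    censored), group (above_mean / below_mean).  Returns the log-rank p
    within five years, the Cox hazard ratio of above vs below (with CI),
    and per-group Kaplan-Meier fitters.
    """
    for col in ("time", "event", "group"):
        if col not in records:
            raise ValueError(f"records missing column {col!r}")
    df = truncate_five_years(records) if truncate else records.copy()
    above = df[df["group"] == ABOVE]
    below = df[df["group"] == BELOW]
    if len(above) == 0 or len(below) == 0:
        raise ValueError("both groups must be nonempty")

    lr = logrank_test(above["time"], below["time"], above["event"], below["event"])
    out = {"logrank_p": float(lr.p_value), "n_above": len(above), "n_below": len(below)}

    km = {}
    for name, grp in (("above", above), ("below", below)):
        fitter = KaplanMeierFitter(label=name)
        fitter.fit(grp["time"], grp["event"])
        km[name] = fitter
    out["km"] = km

    if above["event"].sum() == 0 or below["event"].sum() == 0:
        import warnings

        warnings.warn("a group has zero events; hazard ratio undefined")
        out["hazard_ratio"] = float("nan")
    else:
        cox_df = df[["time", "event"]].copy()
        cox_df["above"] = (df["group"] == ABOVE).astype(float)
        cph = CoxPHFitter()
        cph.fit(cox_df, duration_col="time", event_col="event")
        out["hazard_ratio"] = float(np.exp(cph.params_["above"]))
        out["hr_se_log"] = float(cph.standard_errors_["above"])
        ci = cph.confidence_intervals_.loc["above"].to_numpy()
        out["hr_ci"] = (float(np.exp(ci[0])), float(np.exp(ci[1])))
    return out


def plot_km(result: dict, path) -> None:
    """Save Kaplan-Meier curves from a survival_compare result."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, fitter in result["km"].items():
        fitter.plot_survival_function(ax=ax)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_title(f"log-rank p = {result['logrank_p']:.3g}, HR = {result.get('hazard_ratio', float('nan')):.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_scatter_fit(pred, truth, summary: EvalSummary, path) -> None:
    """Scatter of predicted vs truth counts with the Huber fit line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(truth, pred, s=14, alpha=0.7)
    xs = np.linspace(min(truth), max(truth), 50)
    ax.plot(xs, summary.huber_slope * xs + summary.huber_intercept, "k--")
    ax.set_xlabel("ground-truth count")
    ax.set_ylabel("predicted count")
    ax.set_title(f"r = {summary.pearson_r:.3f}, R$^2$ = {summary.r2:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def simulate_exponential_survival(
    n: int = 200, hazard_ratio: float = 2.0, base_hazard: float = 1.0 / 40.0,
    censor_time: float = 60.0, seed: int = 0,
) -> pd.DataFrame:
    """Two equal arms of exponential survival with a known hazard ratio.

    The above-mean arm has hazard ``base_hazard``; the below-mean arm
    ``base_hazard * hazard_ratio`` (low predicted CD3+ density confers
    worse survival).  Administrative censoring at ``censor_time``.
    """
    rng = np.random.default_rng(seed)
    n_above = n // 2
    groups = np.array([ABOVE] * n_above + [BELOW] * (n - n_above))
    hazards = np.where(groups == ABOVE, base_hazard, base_hazard * hazard_ratio)
    t = rng.exponential(1.0 / hazards)
    event = (t <= censor_time).astype(int)
    time = np.minimum(t, censor_time)
    return pd.DataFrame(
        {"patient_id": np.arange(n), "time": time, "event": event, "group": groups}
    )
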