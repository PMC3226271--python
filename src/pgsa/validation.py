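"""Model-checking toolkit: cross-validation, collinearity screening and
observed-vs-simulated distribution comparison.

Three checks mirror how the placebo-group simulation models are validated:

* subject-level k-fold cross-validation, reporting the root-mean-square
  prediction error on the model's working scale (sqrt-ADAScog for the
  endpoint model, z-units for the trajectory model) — for a well-specified
  model this converges to the residual SD;
* variance inflation factors of the quantitative predictors;
* seven-number descriptive comparison of two score samples plus paired
  quantiles for a QQ plot and a Kolmogorov-Smirnov distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data_model import CodingConfig, LongitudinalDataset, design_matrix, sqrt_transform

__all__ = [
    "kfold_cv",
    "vif",
    "compare_distributions",
    "ComparisonReport",
    "qq_plot",
    "profile_plot",
    "DEFAULT_VIF_PREDICTORS",
]

#: Quantitative predictors screened for collinearity by default: continuous
#: covariates plus the numeric allele count; binary dummies excluded.
DEFAULT_VIF_PREDICTORS = (
    "age", "education", "bmi", "apoe4", "hachinski", "faq", "mmse",
    "adascog_bl", "npbatt_bl",
)


# --------------------------------------------------------------------------
# Cross-validation
# --------------------------------------------------------------------------

def kfold_cv(
    data: LongitudinalDataset,
    kind: str,
    terms: Sequence[str],
    k: int = 5,
    seed: int | None = None,
    error: str = "rmse",
    coding: CodingConfig | None = None,
) -> float:
    """Subject-level k-fold cross-validated prediction error.

    The dataset is split into ``k`` near-equal subject folds (a subject's
    visits never straddle folds); each fold's responses are predicted by a
    model with the given fixed term set estimated from the other folds.

    Parameters
    ----------
    kind:
        ``"endpoint"`` (sqrt-ADAScog at visit 4, OLS) or ``"trajectory"``
        (NP-Batt follow-up visits, mixed model; held-out subjects are
        predicted by the fixed effects alone).
    error:
        ``"rmse"`` (default; directly comparable to a residual SD) or
        ``"mae"``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if kind not in ("endpoint", "trajectory"):
        raise ValueError("kind must be 'endpoint' or 'trajectory'")
    if error not in ("rmse", "mae"):
        raise ValueError("error must be 'rmse' or 'mae'")
    coding = coding or CodingConfig()

    if kind == "endpoint":
        frame = data.merged_frame(coding)
        frame = frame[(frame["visit"] == 4) & frame["adascog"].notna()].copy()
        frame["_y"] = sqrt_transform(frame["adascog"].to_numpy(float))
    else:
        frame = data.merged_frame(coding)
        frame = frame[(frame["visit"] > 0) & frame["npbatt"].notna()].copy()
        frame["_y"] = frame["npbatt"].astype(float)
    if frame.empty:
        raise ValueError("no usable responses for the requested model kind")

    subjects = np.array(sorted(frame["subject_id"].unique()))
    if len(subjects) < k:
        raise ValueError(f"fold-size error: {len(subjects)} subjects for k={k}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(subjects))
    fold_of = {s: i % k for i, s in enumerate(subjects[perm])}
    folds = frame["subject_id"].map(fold_of).to_numpy()

    errs: list[np.ndarray] = []
    for fold in range(k):
        train = frame[folds != fold]
        test = frame[folds == fold]
        if test.empty:
            continue
        if len(train["subject_id"].unique()) <= len(terms) + 1:
            raise ValueError("fold-size error: too few training subjects to fit")
        if kind == "endpoint":
            Xtr = design_matrix(train, terms)
            res = sm.OLS(train["_y"].to_numpy(), Xtr).fit()
            pred = design_matrix(test, terms) @ res.params
        else:
            from .trajectory_model import fit_lmm

            Xtr = design_matrix(train, terms)
            res = fit_lmm(
                train["_y"].to_numpy(), Xtr,
                train["subject_id"].to_numpy(), train["visit"].to_numpy(float),
                terms=list(terms),
            )
            pred = design_matrix(test, terms) @ res.beta
        errs.append(test["_y"].to_numpy() - pred)
    pooled = np.concatenate(errs)
    if error == "rmse":
        return float(np.sqrt(np.mean(pooled**2)))
    return float(np.mean(np.abs(pooled)))


# --------------------------------------------------------------------------
# Variance inflation factors
# --------------------------------------------------------------------------

def vif(
    data: LongitudinalDataset | pd.DataFrame,
    predictors: Sequence[str] = DEFAULT_VIF_PREDICTORS,
) -> dict[str, float]:
    """Variance inflation factor per quantitative predictor.

    VIF_j = 1 / (1 - R^2_j) from regressing predictor j on the others (with
    intercept).  Perfect collinearity yields ``inf`` for the terms involved.
    """
    predictors = list(predictors)
    if len(predictors) < 2:
        raise ValueError("need at least 2 predictors")
    if isinstance(data, LongitudinalDataset):
        frame = data.baseline_frame()
        # raw bmi is not an encoded column; recover it when requested
        if "bmi" in predictors and "bmi" not in frame.columns:
            frame = frame.copy()
            frame["bmi"] = [b.bmi for b in data.baselines]
    else:
        frame = data
    X = frame[predictors].to_numpy(dtype=float)
    if np.isnan(X).any():
        X = X[~np.isnan(X).any(axis=1)]
    out: dict[str, float] = {}
    for j, name in enumerate(predictors):
        yj = X[:, j]
        if np.var(yj) == 0:
            raise ValueError(f"predictor {name!r} has zero variance")
        others = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        r2 = 1.0 - resid @ resid / ((yj - yj.mean()) @ (yj - yj.mean()))
        if r2 >= 1.0 - 1e-12:
            warnings.warn(
                f"predictor {name!r} is perfectly collinear with the others",
                stacklevel=2,
            )
            out[name] = float("inf")
        else:
            out[name] = float(1.0 / (1.0 - r2))
    return out


# --------------------------------------------------------------------------
# Distribution comparison
# --------------------------------------------------------------------------

_STAT_NAMES = ["minimum", "first_quartile", "median", "mean",
               "third_quartile", "maximum", "sd"]


def _seven(x: np.ndarray) -> list[float]:
    return [
        float(np.min(x)),
        float(np.percentile(x, 25)),
        float(np.median(x)),
        float(np.mean(x)),
        float(np.percentile(x, 75)),
        float(np.max(x)),
        float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
    ]


@dataclass
class ComparisonReport:
    """Observed-vs-simulated comparison: descriptives, QQ pairs, KS distance."""

    table: pd.DataFrame
    qq_observed: np.ndarray
    qq_simulated: np.ndarray
    ks_distance: float

    def to_csv(self, dest) -> None:
        self.table.to_csv(dest)


def compare_distributions(
    observed: Sequence[float],
    simulated: Sequence[float],
) -> ComparisonReport:
    """Compare two score samples (any sizes).

    The table holds minimum, quartiles, median, mean, maximum and SD for
    each sample plus their (simulated - observed) differences.  QQ pairs use
    plotting positions (i - 0.5)/n of the smaller sample, with linear
    interpolation in the larger one.
    """
    obs = np.asarray(observed, dtype=float)
    simd = np.asarray(simulated, dtype=float)
    if obs.size == 0 or simd.size == 0:
        raise ValueError("both samples must be nonempty")
    table = pd.DataFrame(
        {"observed": _seven(obs), "simulated": _seven(simd)}, index=_STAT_NAMES
    )
    table["difference"] = table["simulated"] - table["observed"]
    n = min(len(obs), len(simd))
    pos = (np.arange(1, n + 1) - 0.5) / n
    qq_obs = np.quantile(obs, pos, method="linear")
    qq_sim = np.quantile(simd, pos, method="linear")
    ks = float(stats.ks_2samp(obs, simd).statistic)
    return ComparisonReport(table=table, qq_observed=qq_obs,
                            qq_simulated=qq_sim, ks_distance=ks)


# --------------------------------------------------------------------------
# Plots
# --------------------------------------------------------------------------

def qq_plot(report: ComparisonReport, path: str, label_x: str = "observed",
            label_y: str = "simulated") -> None:
    """Write a quantile-quantile plot of a comparison report to ``path``."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(report.qq_observed, report.qq_simulated, "o", ms=3)
    lims = [
        min(report.qq_observed.min(), report.qq_simulated.min()),
        max(report.qq_observed.max(), report.qq_simulated.max()),
    ]
    ax.plot(lims, lims, "k--", lw=1)
    ax.set_xlabel(f"{label_x} quantiles")
    ax.set_ylabel(f"{label_y} quantiles")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def profile_plot(
    fit,
    baselines,
    focal: str,
    moderator: str,
    path: str,
    quantiles: Sequence[float] = (0.25, 0.5, 0.75),
    n_points: int = 40,
) -> None:
    """Plot the predicted outcome against a focal covariate at fixed
    quantiles of a moderator, all other covariates held at cohort means.

    Works for an endpoint fit (sqrt-scale prediction vs a baseline
    covariate) or a trajectory fit with ``focal="visit"`` (predicted NP-Batt
    vs time).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    from .endpoint_model import EndpointFit, _as_baseline_frame

    frame = _as_baseline_frame(baselines, fit.coding)
    means = frame.mean(numeric_only=True)
    mod_values = frame[moderator].quantile(list(quantiles)).to_numpy()
    if focal == "visit":
        xs = np.linspace(0, 6, n_points)
    else:
        xs = np.linspace(frame[focal].min(), frame[focal].max(), n_points)

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for q, mv in zip(quantiles, mod_values):
        grid = pd.DataFrame([means] * n_points).reset_index(drop=True)
        grid[moderator] = mv
        if focal == "visit":
            grid["visit"] = xs
        else:
            grid[focal] = xs
        y = design_matrix(grid, fit.terms) @ fit.coef
        ax.plot(xs, y, label=f"{moderator} @ q{int(q * 100)} = {mv:.2f}")
    ax.set_xlabel(focal)
    scale = "sqrt ADAScog(24m)" if isinstance(fit, EndpointFit) else "NP-Batt"
    ax.set_ylabel(f"predicted {scale}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
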