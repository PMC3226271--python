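"""Univariate (endpoint-related) placebo-group simulation model.

Forecasts the modified ADAScog total at month 24 (visit 4) from baseline
covariates.  The outcome is square-root transformed (the raw score is heavily
right-skewed); model selection is backward stepwise by AIC over main effects,
followed by single-term screening of all pairwise interactions of the
retained main effects and a final AIC-based pruning pass.

A fitted model supports:

* plug-in prediction of the sqrt-scale endpoint per subject,
* parametric simulation of virtual-placebo endpoint distributions — per
  simulated trial one coefficient vector is drawn from the multivariate
  normal of the estimated parameters, applied to every subject's covariates,
  and residual noise is added per subject before back-transforming,
* analytic two-sample power for a sqrt-scale treatment effect, and
* back-transformation arithmetic (points difference implied by a sqrt-scale
  effect; confidence interval of a sample mean on the original scale).
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data_model import (
    ADASCOG_MAX,
    CodingConfig,
    LongitudinalDataset,
    SubjectBaseline,
    design_matrix,
    inverse_sqrt_transform,
    sqrt_transform,
)

__all__ = [
    "EndpointFit",
    "fit_endpoint",
    "predict_endpoint",
    "simulate_control_endpoints",
    "analytic_power",
    "effect_on_original_scale",
    "mean_ci_original_scale",
    "mci_endpoint_fixture",
    "DEFAULT_ENDPOINT_CANDIDATES",
    "SampleSizeError",
    "CollinearityError",
]

#: Default candidate main effects: demographics, ApoE4 allele count, the
#: obesity flag (BMI class >= 30), modified Hachinski, and baseline FAQ,
#: MMSE, ADAScog and NP-Batt.
DEFAULT_ENDPOINT_CANDIDATES = (
    "age", "gender", "education", "obesity", "apoe4", "hachinski",
    "faq", "mmse", "adascog_bl", "npbatt_bl",
)

ENDPOINT_VISIT = 4  # month 24


class SampleSizeError(ValueError):
    """Too few complete cases for the requested candidate set."""


class CollinearityError(ValueError):
    """Rank-deficient design; names the aliased terms."""


# --------------------------------------------------------------------------
# Fit container
# --------------------------------------------------------------------------

@dataclass
class EndpointFit:
    """Fitted endpoint model on the sqrt-ADAScog scale.

    ``cov`` is the parameter covariance used for simulation draws; ``sigma``
    the residual SD, both on the sqrt scale.
    """

    terms: list[str]
    coef: np.ndarray
    cov: np.ndarray
    sigma: float
    n: int
    transform: str = "sqrt"
    coding: CodingConfig = field(default_factory=CodingConfig)
    selection_trace: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        k = len(self.terms)
        if self.coef.shape != (k,) or self.cov.shape != (k, k):
            raise ValueError("terms, coef and cov dimensions disagree")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("parameter covariance must be symmetric")
        if np.linalg.eigvalsh(self.cov).min() < -1e-8:
            raise ValueError("parameter covariance must be PSD")
        if not self.sigma > 0:
            raise ValueError("residual SD must be > 0")

    @property
    def coef_named(self) -> dict[str, float]:
        return dict(zip(self.terms, self.coef.tolist()))

    def to_dict(self) -> dict:
        return {
            "kind": "endpoint",
            "terms": list(self.terms),
            "coefficients": self.coef.tolist(),
            "covariance": self.cov.tolist(),
            "residual_sd": self.sigma,
            "n": self.n,
            "transform": self.transform,
            "coding": self.coding.to_dict(),
            "provenance": dict(self.provenance),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "EndpointFit":
        return cls(
            terms=list(doc["terms"]),
            coef=np.asarray(doc["coefficients"], dtype=float),
            cov=np.asarray(doc["covariance"], dtype=float),
            sigma=float(doc["residual_sd"]),
            n=int(doc["n"]),
            transform=doc.get("transform", "sqrt"),
            coding=CodingConfig.from_dict(doc.get("coding", {})),
            provenance=dict(doc.get("provenance", {})),
        )


def mci_endpoint_fixture() -> EndpointFit:
    """The packaged reference ADNI-MCI endpoint model artifact.

    Carries the published coefficient values and residual SD; the parameter
    covariance is a diagonal approximation built from the printed standard
    errors (off-diagonals were not published), which slightly changes
    replicate-level dispersion relative to the full covariance.
    """
    text = (
        importlib.resources.files("pgsa.artifacts")
        .joinpath("endpoint_mci.json")
        .read_text()
    )
    return EndpointFit.from_dict(json.loads(text))


# --------------------------------------------------------------------------
# Stepwise AIC selection
# --------------------------------------------------------------------------

def _ols(y: np.ndarray, frame: pd.DataFrame, terms: Sequence[str]):
    X = design_matrix(frame, terms)
    return sm.OLS(y, X).fit()


def _parents(term: str) -> set[str]:
    return set(term.split(":")) if ":" in term else set()


def _removable(terms: Sequence[str]) -> list[str]:
    """Terms deletable without violating marginality (never the intercept,
    never a main effect contained in a retained interaction)."""
    protected = {"intercept"}
    for t in terms:
        protected |= _parents(t)
    return [t for t in terms if t not in protected]


def _backward_aic(y, frame, terms: list[str], trace: list[str]) -> list[str]:
    current = list(terms)
    aic = _ols(y, frame, current).aic
    trace.append(f"start AIC={aic:.2f} terms={current}")
    while True:
        best_drop, best_aic = None, aic
        for t in sorted(_removable(current)):
            cand = [u for u in current if u != t]
            a = _ols(y, frame, cand).aic
            if a < best_aic - 1e-10:
                best_drop, best_aic = t, a
        if best_drop is None:
            return current
        current.remove(best_drop)
        aic = best_aic
        trace.append(f"drop {best_drop} -> AIC={aic:.2f}")


def fit_endpoint(
    data: LongitudinalDataset,
    candidates: Sequence[str] | None = None,
    coding: CodingConfig | None = None,
) -> EndpointFit:
    """Fit the sqrt-ADAScog month-24 regression with stepwise AIC selection.

    Procedure: (1) outcome is sqrt(ADAScog at visit 4); (2) backward
    elimination over candidate main effects to a local AIC minimum;
    (3) each pairwise interaction of the retained main effects is tested
    singly for AIC improvement; (4) accepted interactions are pooled and the
    AIC elimination re-run (main effects protected while a retained
    interaction contains them).
    """
    coding = coding or CodingConfig()
    candidates = list(candidates or DEFAULT_ENDPOINT_CANDIDATES)

    bf = data.baseline_frame(coding)
    vf = data.visit_frame()
    end = vf[(vf["visit"] == ENDPOINT_VISIT) & vf["adascog"].notna()]
    if end.empty:
        raise SampleSizeError("no month-24 (visit 4) ADAScog outcomes in data")
    frame = bf.loc[end["subject_id"].to_numpy()]
    used_cols = sorted({p for t in candidates for p in (t.split(":"))})
    complete = frame[used_cols].notna().all(axis=1).to_numpy()
    frame = frame[complete]
    y = sqrt_transform(end["adascog"].to_numpy(dtype=float)[complete])

    if len(y) < len(candidates) + 2:
        raise SampleSizeError(
            f"{len(y)} complete cases for {len(candidates)} candidate terms"
        )
    full_terms = ["intercept"] + candidates
    X_full = design_matrix(frame, full_terms)
    rank = np.linalg.matrix_rank(X_full)
    if rank < X_full.shape[1]:
        aliased = _aliased_terms(X_full, full_terms)
        raise CollinearityError(f"rank-deficient design; aliased terms: {aliased}")

    trace: list[str] = []
    mains = _backward_aic(y, frame, full_terms, trace)

    base_aic = _ols(y, frame, mains).aic
    retained_mains = [t for t in mains if t != "intercept"]
    accepted = []
    for i, a in enumerate(sorted(retained_mains)):
        for b in sorted(retained_mains)[i + 1:]:
            inter = f"{a}:{b}"
            col = design_matrix(frame, [inter])[:, 0]
            if np.var(col) < 1e-12:  # degenerate product column
                continue
            aic_i = _ols(y, frame, mains + [inter]).aic
            if aic_i < base_aic - 1e-10:
                accepted.append(inter)
                trace.append(f"screen {inter}: AIC {aic_i:.2f} < {base_aic:.2f}, accept")
    if accepted:
        final_terms = _backward_aic(y, frame, mains + accepted, trace)
    else:
        final_terms = mains

    res = _ols(y, frame, final_terms)
    return EndpointFit(
        terms=final_terms,
        coef=res.params,
        cov=res.cov_params(),
        sigma=float(np.sqrt(res.scale)),
        n=int(len(y)),
        coding=coding,
        selection_trace=trace,
        provenance={"n_candidates": len(candidates), "fit": "OLS sqrt scale"},
    )


def _aliased_terms(X: np.ndarray, terms: Sequence[str]) -> list[str]:
    """Name terms involved in exact collinearity via QR pivot magnitudes."""
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    thresh = diag.max() * 1e-10
    return [t for t, d in zip(terms, diag) if d < thresh]


# --------------------------------------------------------------------------
# Prediction and simulation
# --------------------------------------------------------------------------

def _as_baseline_frame(
    baselines: LongitudinalDataset | Iterable[SubjectBaseline],
    coding: CodingConfig,
) -> pd.DataFrame:
    if isinstance(baselines, LongitudinalDataset):
        return baselines.baseline_frame(coding)
    from .data_model import encode_covariates

    blist = list(baselines)
    return pd.DataFrame(
        [encode_covariates(b, coding) for b in blist],
        index=[b.subject_id for b in blist],
    )


def predict_endpoint(fit: EndpointFit, baselines) -> np.ndarray:
    """Per-subject expected month-24 score on the sqrt scale (the linear
    predictor X@beta).  Square the result for a plug-in original-scale value;
    note that back-transform is biased low for the mean by Jensen's
    inequality — simulation-based summaries avoid that bias."""
    frame = _as_baseline_frame(baselines, fit.coding)
    try:
        X = design_matrix(frame, fit.terms)
    except (KeyError, ValueError) as exc:
        raise ValueError(f"prediction input missing covariates: {exc}") from exc
    return X @ fit.coef


def simulate_control_endpoints(
    fit: EndpointFit,
    baselines,
    n_replicates: int = 1,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    param_uncertainty: bool = True,
) -> np.ndarray:
    """Simulate virtual-placebo month-24 ADAScog scores, original scale.

    Per replicate, one coefficient vector is drawn from MVN(beta, cov) and
    shared by all subjects (parameter uncertainty acts at the trial level);
    per subject, sqrt-scale residual noise N(0, sigma^2) is added.  Values
    are floored at 0 on the sqrt scale, squared, and clipped to [0, 85].

    Returns an ``(n_replicates, n_subjects)`` array.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    frame = _as_baseline_frame(baselines, fit.coding)
    X = design_matrix(frame, fit.terms)
    n_sub = X.shape[0]
    if param_uncertainty:
        L = _psd_sqrt(fit.cov)
        thetas = (fit.coef[None, :]
                  + rng.standard_normal((n_replicates, len(fit.coef))) @ L.T)
    else:
        thetas = np.repeat(fit.coef[None, :], n_replicates, axis=0)
    mu = thetas @ X.T  # (reps, subjects)
    eps = rng.normal(0.0, fit.sigma, size=mu.shape)
    return inverse_sqrt_transform(mu + eps)


def _psd_sqrt(cov: np.ndarray) -> np.ndarray:
    """Matrix square root tolerant of semidefinite (incl. zero) covariance."""
    w, V = np.linalg.eigh(np.asarray(cov, dtype=float))
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


# --------------------------------------------------------------------------
# Power and back-transform arithmetic
# --------------------------------------------------------------------------

def analytic_power(
    effect: float,
    sd: float,
    n_per_group: int,
    alpha: float = 0.05,
    sided: int = 2,
) -> float:
    """Normal-approximation power for a two-sample comparison of means.

    ``effect`` and ``sd`` are on the model's working (sqrt) scale.  Because a
    randomized treatment is uncorrelated with the baseline covariates, the
    general regression-parameter power procedure reduces to this standard
    two-mean formula.
    """
    if effect < 0:
        raise ValueError("effect must be >= 0")
    if not sd > 0:
        raise ValueError("sd must be > 0")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if sided not in (1, 2):
        raise ValueError("sided must be 1 or 2")
    se = sd * np.sqrt(2.0 / n_per_group)
    z_crit = stats.norm.ppf(1 - alpha / sided)
    delta = effect / se
    power = stats.norm.cdf(delta - z_crit)
    if sided == 2:
        power += stats.norm.cdf(-delta - z_crit)  # opposite-tail rejections
    return float(power)


def effect_on_original_scale(effect: float, reference_score: float) -> float:
    """ADAScog points difference implied by a sqrt-scale effect at a given
    untreated score: (sqrt(ref) + effect)^2 - ref."""
    if not 0 <= reference_score <= ADASCOG_MAX:
        raise ValueError("reference_score must be in [0, 85]")
    return float((np.sqrt(reference_score) + effect) ** 2 - reference_score)


def mean_ci_original_scale(
    mean_original: float,
    sd: float,
    n: int,
    level: float = 0.95,
) -> tuple[float, float]:
    """Confidence interval for a sample mean, mapped to the original scale.

    The standard error ``sd/sqrt(n)`` lives on the sqrt scale; the normal
    interval around sqrt(mean) is squared endpoint-wise.
    """
    if mean_original < 0:
        raise ValueError("mean_original must be >= 0")
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    se = sd / np.sqrt(n)
    z = stats.norm.ppf(0.5 + level / 2)
    root = np.sqrt(mean_original)
    lo = max(root - z * se, 0.0)
    hi = root + z * se
    return float(lo**2), float(hi**2)
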