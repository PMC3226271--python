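"""Multivariate (trajectory-related) placebo-group simulation model.

A linear mixed model for the NP-Batt composite over 36 months with random
intercepts and random slopes versus time (time = visit number in 6-month
units).  Selection starts from a model saturated with all candidate main
effects and their interactions with time: the random-slope structure is
tested by likelihood-ratio test, fixed time-interactions and then main
effects are eliminated backward by Wald tests honoring marginality, and
pairwise interactions of the surviving main effects are screened for
inclusion.

Virtual-placebo trajectories are simulated by drawing one fixed-effect
vector per replicate from the multivariate normal of the estimates, per
subject an (intercept, slope) deviation from the bivariate normal with
covariance G, and independent within-subject noise per visit.  Power for a
slope-improving treatment is obtained by Monte-Carlo simulation of paired
control/treated arms, refitting an arm-by-time mixed model per replicate.

Implementation note: fits use an exact profiled REML/ML solver written for
this model class (random intercept + slope, iid residuals).  Subjects are
grouped by visit pattern, so each pattern shares one small marginal
covariance matrix; the likelihood then costs a handful of k x k solves per
evaluation, which keeps thousand-replicate power simulations and large
parameter-recovery fits fast.  statsmodels MixedLM fits the same model and
is used as an independent cross-check in the test suite.
"""

from __future__ import annotations

import importlib.resources
import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data_model import (
    CodingConfig,
    LEGAL_VISIT_NUMBERS,
    LongitudinalDataset,
    SubjectBaseline,
    VisitRecord,
    design_matrix,
)

__all__ = [
    "TrajectoryFit",
    "PowerResult",
    "LmmResult",
    "fit_lmm",
    "fit_trajectory",
    "predict_trajectory",
    "simulate_control_trajectories",
    "simulate_trajectory_matrix",
    "marginal_sd",
    "marginal_cov",
    "simulate_power_trajectory",
    "mci_trajectory_fixture",
    "csf_trajectory_fixture",
    "DEFAULT_TRAJECTORY_CANDIDATES",
    "ScheduleError",
    "FittingError",
]

#: Default candidate main effects (BMI enters as the two class dummies).
DEFAULT_TRAJECTORY_CANDIDATES = (
    "age", "gender", "education", "bmi2", "bmi3", "apoe4", "hachinski",
    "faq", "mmse", "adascog_bl", "npbatt_bl",
)

FULL_SCHEDULE = (0, 1, 2, 3, 4, 6)


class ScheduleError(ValueError):
    """A requested visit number is not on the legal 6-month schedule."""


class FittingError(RuntimeError):
    """The mixed-model optimizer failed to converge."""


# --------------------------------------------------------------------------
# Fit containers
# --------------------------------------------------------------------------

@dataclass
class TrajectoryFit:
    """Fitted mixed model: fixed effects plus (G, sigma_w) variance components.

    G is parameterized as (sd_intercept, sd_slope, corr); ``within_sd`` is
    the SD of the independent within-subject noise.
    """

    terms: list[str]
    coef: np.ndarray
    cov: np.ndarray
    sd_intercept: float
    sd_slope: float
    corr: float
    within_sd: float
    n: int
    n_obs: int = 0
    time_coding: str = "visit_6mo"
    random_slopes: bool = True
    boundary: bool = False
    coding: CodingConfig = field(default_factory=CodingConfig)
    selection_trace: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        k = len(self.terms)
        if self.coef.shape != (k,) or self.cov.shape != (k, k):
            raise ValueError("terms, coef and cov dimensions disagree")
        if not (self.sd_intercept >= 0 and self.sd_slope >= 0 and self.within_sd > 0):
            raise ValueError("variance components must be nonnegative, within_sd > 0")
        if not -1.0 <= self.corr <= 1.0:
            raise ValueError("corr must be in [-1, 1]")

    @property
    def G(self) -> np.ndarray:
        """Random-effects covariance matrix [[int],[slope]]."""
        c = self.corr * self.sd_intercept * self.sd_slope
        return np.array([[self.sd_intercept**2, c], [c, self.sd_slope**2]])

    @property
    def coef_named(self) -> dict[str, float]:
        return dict(zip(self.terms, self.coef.tolist()))

    def to_dict(self) -> dict:
        return {
            "kind": "trajectory",
            "terms": list(self.terms),
            "coefficients": self.coef.tolist(),
            "covariance": self.cov.tolist(),
            "random_effects": {
                "sd_intercept": self.sd_intercept,
                "sd_slope": self.sd_slope,
                "corr": self.corr,
            },
            "within_sd": self.within_sd,
            "n": self.n,
            "n_obs": self.n_obs,
            "time_coding": self.time_coding,
            "random_slopes": self.random_slopes,
            "boundary": self.boundary,
            "coding": self.coding.to_dict(),
            "provenance": dict(self.provenance),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "TrajectoryFit":
        re_ = doc["random_effects"]
        return cls(
            terms=list(doc["terms"]),
            coef=np.asarray(doc["coefficients"], dtype=float),
            cov=np.asarray(doc["covariance"], dtype=float),
            sd_intercept=float(re_["sd_intercept"]),
            sd_slope=float(re_["sd_slope"]),
            corr=float(re_["corr"]),
            within_sd=float(doc["within_sd"]),
            n=int(doc["n"]),
            n_obs=int(doc.get("n_obs", 0)),
            time_coding=doc.get("time_coding", "visit_6mo"),
            random_slopes=bool(doc.get("random_slopes", True)),
            boundary=bool(doc.get("boundary", False)),
            coding=CodingConfig.from_dict(doc.get("coding", {})),
            provenance=dict(doc.get("provenance", {})),
        )


@dataclass
class PowerResult:
    """Power estimate plus the design that produced it."""

    power: float
    method: str
    alpha: float
    effect: float
    n_per_group: int
    n_sims: int | None = None
    n_converged: int | None = None
    mc_se: float | None = None
    design: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def _load_fixture(name: str) -> TrajectoryFit:
    text = (
        importlib.resources.files("pgsa.artifacts").joinpath(name).read_text()
    )
    return TrajectoryFit.from_dict(json.loads(text))


def mci_trajectory_fixture() -> TrajectoryFit:
    """Packaged reference ADNI-MCI trajectory model (375 subjects).

    Published fixed effects and variance components; the fixed-effect
    covariance is a diagonal approximation from the printed standard errors.
    """
    return _load_fixture("trajectory_mci.json")


def csf_trajectory_fixture() -> TrajectoryFit:
    """Packaged reference trajectory model including the CSF Abeta42/T-tau
    ratio (lumbar-puncture subsample, 189 subjects)."""
    return _load_fixture("trajectory_csf.json")


# --------------------------------------------------------------------------
# Core mixed-model solver (profiled REML/ML, pattern-grouped)
# --------------------------------------------------------------------------

@dataclass
class LmmResult:
    """Raw solver output for a random-intercept(+slope) linear mixed model."""

    terms: list[str]
    beta: np.ndarray
    cov_beta: np.ndarray
    sd_intercept: float
    sd_slope: float
    corr: float
    sigma_w: float
    loglik: float
    reml: bool
    converged: bool
    boundary: bool
    n_subjects: int
    n_obs: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))

    @property
    def pvalues(self) -> np.ndarray:
        z = self.beta / self.se
        return 2 * stats.norm.sf(np.abs(z))


class _PatternData:
    """Rows regrouped by visit pattern: subjects sharing a pattern share the
    marginal covariance V = Z G Z' + sigma^2 I."""

    def __init__(self, y, X, subjects, tvals):
        y = np.asarray(y, float)
        X = np.asarray(X, float)
        subjects = np.asarray(subjects)
        tvals = np.asarray(tvals, float)
        order = np.lexsort((tvals, subjects))
        y, X, subjects, tvals = y[order], X[order], subjects[order], tvals[order]
        self.n_obs = len(y)
        # split rows per subject
        uniq, start = np.unique(subjects, return_index=True)
        self.n_subjects = len(uniq)
        bounds = np.append(start, len(y))
        groups: dict[tuple, list[tuple[np.ndarray, np.ndarray]]] = {}
        for i in range(self.n_subjects):
            sl = slice(bounds[i], bounds[i + 1])
            key = tuple(np.round(tvals[sl], 9))
            groups.setdefault(key, []).append((y[sl], X[sl]))
        self.patterns = []
        for key, items in groups.items():
            t = np.array(key)
            Y = np.stack([it[0] for it in items])          # (m, k)
            Xs = np.stack([it[1] for it in items])         # (m, k, q)
            self.patterns.append((t, Y, Xs))
        self.q = X.shape[1]

    def profile(self, G: np.ndarray, sigma2: float):
        """Return (sum log|V|, XtVX, XtVy, ytVy) over all subjects."""
        q = self.q
        XtVX = np.zeros((q, q))
        XtVy = np.zeros(q)
        ytVy = 0.0
        sum_logdet = 0.0
        for t, Y, Xs in self.patterns:
            k = len(t)
            Z = np.column_stack([np.ones(k), t])
            V = Z @ G @ Z.T + sigma2 * np.eye(k)
            sign, logdet = np.linalg.slogdet(V)
            if sign <= 0:
                return None
            Vi = np.linalg.inv(V)
            m = Y.shape[0]
            sum_logdet += m * logdet
            XtVX += np.einsum("aki,kl,alj->ij", Xs, Vi, Xs)
            XtVy += np.einsum("aki,kl,al->i", Xs, Vi, Y)
            ytVy += float(np.einsum("ak,kl,al->", Y, Vi, Y))
        return sum_logdet, XtVX, XtVy, ytVy


def _unpack(phi: np.ndarray, random_slopes: bool) -> tuple[np.ndarray, float]:
    if random_slopes:
        si, ss, rho, sw = np.exp(phi[0]), np.exp(phi[1]), np.tanh(phi[2]), np.exp(phi[3])
        c = rho * si * ss
        G = np.array([[si**2, c], [c, ss**2]])
    else:
        si, sw = np.exp(phi[0]), np.exp(phi[1])
        G = np.array([[si**2, 0.0], [0.0, 0.0]])
    return G, sw**2


def _criterion(phi, data: _PatternData, random_slopes: bool, reml: bool):
    G, s2 = _unpack(np.asarray(phi, float), random_slopes)
    prof = data.profile(G, s2)
    if prof is None:
        return 1e12
    sum_logdet, XtVX, XtVy, ytVy = prof
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        return 1e12
    rss = ytVy - beta @ XtVy
    if rss <= 0:
        rss = 1e-12
    crit = sum_logdet + rss
    if reml:
        sign, ld = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return 1e12
        crit += ld
    return 0.5 * crit


def _start_values(data: _PatternData, random_slopes: bool) -> np.ndarray:
    """Moment starts from per-subject OLS lines (falls back to crude values
    for short series)."""
    ints, slopes, resid_ss, resid_df = [], [], 0.0, 0
    for t, Y, Xs in data.patterns:
        k = len(t)
        if k >= 2 and np.ptp(t) > 0:
            Z = np.column_stack([np.ones(k), t])
            coef, *_ = np.linalg.lstsq(Z, Y.T, rcond=None)
            ints.extend(coef[0])
            slopes.extend(coef[1])
            if k > 2:
                R = Y.T - Z @ coef
                resid_ss += float(np.sum(R**2))
                resid_df += Y.shape[0] * (k - 2)
    sw = math.sqrt(resid_ss / resid_df) if resid_df > 0 else float(np.std(
        np.concatenate([Y.ravel() for _, Y, _ in data.patterns])) / 2 + 1e-3)
    si = float(np.std(ints)) if len(ints) > 3 else 1.0
    ss = float(np.std(slopes)) if len(slopes) > 3 else 0.1
    si, ss, sw = max(si, 1e-3), max(ss * 0.5, 1e-3), max(sw, 1e-3)
    if random_slopes:
        return np.array([math.log(si), math.log(ss), 0.0, math.log(sw)])
    return np.array([math.log(si), math.log(sw)])


def fit_lmm(
    y: np.ndarray,
    X: np.ndarray,
    subjects: np.ndarray,
    tvals: np.ndarray,
    terms: Sequence[str] | None = None,
    random_slopes: bool = True,
    reml: bool = True,
) -> LmmResult:
    """Fit a linear mixed model with random intercept (and slope on ``tvals``)
    plus iid within-subject noise, by profiled REML (default) or ML.

    Exact for this model class; equivalent to statsmodels MixedLM with
    ``exog_re = [1, t]`` but orders of magnitude faster on balanced panels.
    """
    data = _PatternData(y, X, subjects, tvals)
    terms = list(terms) if terms is not None else [f"x{i}" for i in range(data.q)]
    phi0 = _start_values(data, random_slopes)
    if random_slopes:
        bounds = [(-12, 6), (-12, 6), (-6, 6), (-12, 6)]
    else:
        bounds = [(-12, 6), (-12, 6)]
    res = optimize.minimize(
        _criterion, phi0, args=(data, random_slopes, reml),
        method="L-BFGS-B", bounds=bounds,
    )
    if not res.success:  # one retry from a gradient-free polish
        res2 = optimize.minimize(
            _criterion, res.x, args=(data, random_slopes, reml),
            method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
        )
        if res2.fun <= res.fun:
            res = res2
    G, s2 = _unpack(res.x, random_slopes)
    prof = data.profile(G, s2)
    if prof is None:
        raise FittingError("variance profile degenerate at the optimum")
    sum_logdet, XtVX, XtVy, ytVy = prof
    try:
        beta = np.linalg.solve(XtVX, XtVy)
        cov_beta = np.linalg.inv(XtVX)
    except np.linalg.LinAlgError as exc:
        raise FittingError(f"singular fixed-effect design: {exc}") from exc
    rss = max(ytVy - beta @ XtVy, 1e-12)
    n, q = data.n_obs, data.q
    ll = -(res.fun) - 0.5 * (n - (q if reml else 0)) * math.log(2 * math.pi)
    si = math.sqrt(G[0, 0])
    ss = math.sqrt(G[1, 1])
    rho = float(G[0, 1] / (si * ss)) if si > 0 and ss > 0 else 0.0
    boundary = bool(
        random_slopes and (ss < 1e-4 or abs(rho) > 0.995) or si < 1e-4
    )
    return LmmResult(
        terms=terms,
        beta=beta,
        cov_beta=cov_beta,
        sd_intercept=si,
        sd_slope=ss if random_slopes else 0.0,
        corr=rho if random_slopes else 0.0,
        sigma_w=math.sqrt(s2),
        loglik=float(ll),
        reml=reml,
        converged=bool(res.success or res.fun < 1e11),
        boundary=boundary,
        n_subjects=data.n_subjects,
        n_obs=data.n_obs,
    )


# --------------------------------------------------------------------------
# Model selection
# --------------------------------------------------------------------------

def _trajectory_frame(
    data: LongitudinalDataset,
    coding: CodingConfig,
    include_csf: bool,
) -> pd.DataFrame:
    """Follow-up NP-Batt rows (visit > 0) joined with encoded covariates."""
    frame = data.merged_frame(coding)
    frame = frame[(frame["visit"] > 0) & frame["npbatt"].notna()].copy()
    if include_csf:
        frame = frame[frame["csf_ratio"].notna()]
    else:
        frame = frame.drop(columns=["csf_ratio"])
    return frame.reset_index(drop=True)


def _fit_terms(frame: pd.DataFrame, terms: Sequence[str], random_slopes=True,
               reml=True) -> LmmResult:
    X = design_matrix(frame, terms)
    return fit_lmm(
        frame["npbatt"].to_numpy(float), X,
        frame["subject_id"].to_numpy(), frame["visit"].to_numpy(float),
        terms=terms, random_slopes=random_slopes, reml=reml,
    )


def _parents(term: str) -> set[str]:
    return set(term.split(":")) if ":" in term else set()


def fit_trajectory(
    data: LongitudinalDataset,
    candidates: Sequence[str] | None = None,
    include_csf: bool = False,
    coding: CodingConfig | None = None,
    alpha: float = 0.05,
    scan_baseline_interactions: bool = True,
) -> TrajectoryFit:
    """Fit the NP-Batt mixed model with stepwise selection.

    Procedure: (1) fit the saturated model (all candidate main effects, all
    their interactions with time, random intercepts and slopes, REML);
    (2) likelihood-ratio test of random slopes against the intercept-only
    random structure (chi-square, 2 df; conservative at the boundary), slopes
    retained if p < 0.05; (3) backward Wald elimination, time-interactions
    first and then main effects, largest p first, never removing a main
    effect contained in a retained interaction; (4) pairwise interactions of
    the surviving baseline main effects screened singly for inclusion, the
    accepted ones pooled and Wald-pruned.
    """
    coding = coding or CodingConfig()
    candidates = list(candidates or DEFAULT_TRAJECTORY_CANDIDATES)
    if include_csf and "csf_ratio" not in candidates:
        candidates = candidates + ["csf_ratio"]
    frame = _trajectory_frame(data, coding, include_csf)
    n_subjects = frame["subject_id"].nunique()
    if n_subjects < len(candidates) * 2 + 4:
        raise FittingError(
            f"only {n_subjects} subjects with follow-up outcomes for "
            f"{len(candidates)} candidates"
        )
    trace: list[str] = []

    saturated = (
        ["intercept", "visit"] + candidates + [f"visit:{c}" for c in candidates]
    )
    res_full = _fit_terms(frame, saturated, random_slopes=True)
    res_int = _fit_terms(frame, saturated, random_slopes=False)
    lrt = 2.0 * (res_full.loglik - res_int.loglik)
    p_lrt = float(stats.chi2.sf(max(lrt, 0.0), df=2))
    random_slopes = p_lrt < 0.05
    trace.append(f"random slopes LRT stat={lrt:.2f} p={p_lrt:.2g} -> "
                 f"{'retained' if random_slopes else 'dropped'}")

    def time_inter_eligible(t: str, terms: list[str]) -> bool:
        return ":" in t and "visit" in _parents(t)

    def main_eligible(t: str, terms: list[str]) -> bool:
        if t == "intercept" or ":" in t:
            return False
        protected = set()
        for u in terms:
            protected |= _parents(u)
        return t not in protected

    def wald_prune(terms, eligible):
        res = _fit_terms(frame, terms, random_slopes=random_slopes)
        while True:
            pvals = dict(zip(terms, res.pvalues))
            cand = [t for t in terms if eligible(t, terms)]
            worst = max(sorted(cand), key=lambda t: pvals[t]) if cand else None
            if worst is None or pvals[worst] <= alpha:
                return terms, res
            terms = [t for t in terms if t != worst]
            trace.append(f"drop {worst} (p={pvals[worst]:.3f})")
            res = _fit_terms(frame, terms, random_slopes=random_slopes)

    terms, res = wald_prune(list(saturated), time_inter_eligible)
    terms, res = wald_prune(terms, main_eligible)

    if scan_baseline_interactions:
        mains = [t for t in terms if ":" not in t and t not in ("intercept", "visit")]
        accepted = []
        for i, a in enumerate(sorted(mains)):
            for b in sorted(mains)[i + 1:]:
                inter = f"{a}:{b}"
                col = design_matrix(frame, [inter])[:, 0]
                if np.var(col) < 1e-12:  # e.g. mutually exclusive dummies
                    continue
                try:
                    r = _fit_terms(frame, terms + [inter],
                                   random_slopes=random_slopes)
                except FittingError:
                    trace.append(f"screen {inter}: degenerate design, skipped")
                    continue
                p_new = dict(zip(terms + [inter], r.pvalues))[inter]
                if p_new < alpha:
                    accepted.append(inter)
                    trace.append(f"screen {inter}: p={p_new:.3f}, accept")
        if accepted:
            def pooled_eligible(t: str, ts: list[str]) -> bool:
                return t in accepted
            terms, res = wald_prune(terms + accepted, pooled_eligible)

    if not res.converged:
        raise FittingError("final mixed-model fit did not converge")
    return TrajectoryFit(
        terms=terms,
        coef=res.beta,
        cov=res.cov_beta,
        sd_intercept=res.sd_intercept,
        sd_slope=res.sd_slope,
        corr=res.corr,
        within_sd=res.sigma_w,
        n=res.n_subjects,
        n_obs=res.n_obs,
        random_slopes=random_slopes,
        boundary=res.boundary,
        coding=coding,
        selection_trace=trace,
        provenance={"selection": "LRT slopes + Wald backward", "reml": True},
    )


# --------------------------------------------------------------------------
# Prediction and simulation
# --------------------------------------------------------------------------

def _check_visits(visits: Sequence[int]) -> np.ndarray:
    visits = np.asarray(list(visits))
    bad = sorted(set(visits.tolist()) - LEGAL_VISIT_NUMBERS)
    if bad:
        raise ScheduleError(f"illegal visit numbers {bad}; legal: "
                            f"{sorted(LEGAL_VISIT_NUMBERS)}")
    return visits.astype(float)


def _expanded_design(
    fit: TrajectoryFit,
    baselines,
    visits: Sequence[int],
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Subject x visit design rows for the fit's terms."""
    from .endpoint_model import _as_baseline_frame

    tv = _check_visits(visits)
    bf = _as_baseline_frame(baselines, fit.coding)
    n_sub = len(bf)
    rows = bf.loc[np.repeat(bf.index.to_numpy(), len(tv))].reset_index()
    rows = rows.rename(columns={"index": "subject_id"})
    rows["visit"] = np.tile(tv, n_sub)
    X = design_matrix(rows, fit.terms)
    return rows, X, list(bf.index)


def predict_trajectory(fit: TrajectoryFit, baselines, visits: Sequence[int]):
    """Fixed-effects mean NP-Batt per subject and visit.

    Returns an ``(n_subjects, n_visits)`` array (squeezed to 1-D for a single
    subject).
    """
    rows, X, ids = _expanded_design(fit, baselines, visits)
    mu = (X @ fit.coef).reshape(len(ids), len(list(visits)))
    return mu[0] if len(ids) == 1 else mu


def simulate_trajectory_matrix(
    fit: TrajectoryFit,
    baselines,
    visits: Sequence[int],
    n_replicates: int = 1,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    param_uncertainty: bool = True,
) -> np.ndarray:
    """Simulated NP-Batt values, shape ``(n_replicates, n_subjects, n_visits)``.

    Per replicate one fixed-effect vector is drawn from MVN(beta, cov) and
    shared across subjects; per subject an (intercept, slope) pair from
    N(0, G); per visit independent N(0, within_sd^2) noise.
    """
    from .endpoint_model import _psd_sqrt

    rng = rng if rng is not None else np.random.default_rng(seed)
    tv = _check_visits(visits)
    rows, X, ids = _expanded_design(fit, baselines, visits)
    n_sub, n_vis = len(ids), len(tv)
    if param_uncertainty:
        L = _psd_sqrt(fit.cov)
        thetas = fit.coef[None, :] + rng.standard_normal(
            (n_replicates, len(fit.coef))) @ L.T
    else:
        thetas = np.repeat(fit.coef[None, :], n_replicates, axis=0)
    mu = (thetas @ X.T).reshape(n_replicates, n_sub, n_vis)
    Lg = _psd_sqrt(fit.G)
    b = rng.standard_normal((n_replicates, n_sub, 2)) @ Lg.T
    mu += b[:, :, [0]] + b[:, :, [1]] * tv[None, None, :]
    mu += rng.normal(0.0, fit.within_sd, size=mu.shape)
    return mu


def simulate_control_trajectories(
    fit: TrajectoryFit,
    baselines,
    visits: Sequence[int] = FULL_SCHEDULE,
    n_replicates: int = 1,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    param_uncertainty: bool = True,
) -> list[LongitudinalDataset]:
    """Virtual-placebo trajectory datasets, one per replicate."""
    from .endpoint_model import _as_baseline_frame

    if isinstance(baselines, LongitudinalDataset):
        blist = baselines.baselines
    else:
        blist = list(baselines)
    vals = simulate_trajectory_matrix(
        fit, blist, visits, n_replicates, rng=rng, seed=seed,
        param_uncertainty=param_uncertainty,
    )
    out = []
    vlist = list(visits)
    for r in range(n_replicates):
        recs = [
            VisitRecord(b.subject_id, v, npbatt=float(vals[r, i, j]))
            for i, b in enumerate(blist)
            for j, v in enumerate(vlist)
        ]
        out.append(LongitudinalDataset(baselines=list(blist), visits=recs))
    return out


def marginal_cov(fit: TrajectoryFit, s: float, t: float) -> float:
    """Model covariance of observations at visits s and t for one subject."""
    si, ss, rho, sw = fit.sd_intercept, fit.sd_slope, fit.corr, fit.within_sd
    c = si**2 + s * t * ss**2 + (s + t) * rho * si * ss
    if s == t:
        c += sw**2
    return float(c)


def marginal_sd(fit: TrajectoryFit, visit: float) -> float:
    """SD of a single observation at a visit: random-effect plus
    within-subject variability combined."""
    if visit < 0:
        raise ValueError("visit must be >= 0")
    return math.sqrt(marginal_cov(fit, visit, visit))


# --------------------------------------------------------------------------
# Simulation-based power for slope effects
# --------------------------------------------------------------------------

def simulate_power_trajectory(
    fit: TrajectoryFit,
    cohort_generator: Callable[[int, np.random.Generator], list[SubjectBaseline]] | None = None,
    n_per_arm: int = 400,
    slope_delta: float = 0.02,
    n_sims: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    visits: Sequence[int] = FULL_SCHEDULE,
) -> PowerResult:
    """Monte-Carlo power of the arm-by-time Wald test for a treatment that
    improves the NP-Batt slope by ``slope_delta`` z-units per visit.

    Per simulation a control arm and a treated arm are generated from the
    fitted model over fresh synthetic cohorts, the treated arm's slope
    improved by ``slope_delta``; a random-intercept/slope model with arm and
    arm-by-time fixed effects is refit and the arm-by-time Wald p-value
    recorded.  A fixed-effect parameter draw shared by both arms would shift
    them identically and cancel in the arm-by-time contrast, so the plug-in
    coefficients are used directly.  Non-converged inner fits are excluded;
    above 5% non-convergence a reliability warning is attached to the result.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    if slope_delta < 0:
        raise ValueError("slope_delta must be >= 0")
    rng = np.random.default_rng(seed)
    if cohort_generator is None:
        from .synthetic_cohort import generate_baseline

        def cohort_generator(n, r):
            return generate_baseline(n, rng=r)

    tv = _check_visits(visits)
    nv = len(tv)
    t_row = np.tile(tv, 2 * n_per_arm)
    arm_row = np.repeat(np.array([0.0, 1.0]), n_per_arm * nv)
    X = np.column_stack([np.ones_like(t_row), arm_row, t_row, arm_row * t_row])
    subj = np.repeat(np.arange(2 * n_per_arm), nv)
    terms = ["intercept", "arm", "visit", "arm:visit"]

    rejections = 0
    n_converged = 0
    for _ in range(n_sims):
        control = cohort_generator(n_per_arm, rng)
        treated = cohort_generator(n_per_arm, rng)
        yc = simulate_trajectory_matrix(
            fit, control, tv.astype(int), 1, rng=rng, param_uncertainty=False,
        )[0]
        yt = simulate_trajectory_matrix(
            fit, treated, tv.astype(int), 1, rng=rng, param_uncertainty=False,
        )[0]
        yt = yt + slope_delta * tv[None, :]
        y = np.concatenate([yc.ravel(), yt.ravel()])
        res = fit_lmm(y, X, subj, t_row, terms=terms, random_slopes=True)
        if not res.converged:
            continue
        n_converged += 1
        if res.pvalues[3] < alpha:
            rejections += 1
    power = rejections / n_converged if n_converged else float("nan")
    mc_se = (
        math.sqrt(power * (1 - power) / n_converged) if n_converged else float("nan")
    )
    warnings = []
    if n_converged < 0.95 * n_sims:
        warnings.append(
            f"only {n_converged}/{n_sims} inner fits converged; power "
            "estimate may be unreliable"
        )
    return PowerResult(
        power=float(power),
        method="monte_carlo",
        alpha=alpha,
        effect=slope_delta,
        n_per_group=n_per_arm,
        n_sims=n_sims,
        n_converged=n_converged,
        mc_se=float(mc_se),
        design={"visits": [int(v) for v in tv], "model": "arm + visit + arm:visit"},
        warnings=warnings,
    )
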