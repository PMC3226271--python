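"""Synthetic ADNI-MCI-like cohorts and model-driven outcome simulation.

Real MCI cohort data are not redistributable, so every downstream stage of
the placebo-group simulation workflow is exercised on synthetic cohorts.
Baseline covariates are drawn from configurable marginal distributions whose
defaults match the published MCI cohort descriptives (n=397): age
N(74.2, 7.4), 36% women, education N(15.7, 3.0), BMI N(26.1, 4.0), ApoE4
allele counts (47%, 42%, 12%), MMSE N(27.0, 1.8) truncated to the 24-30
inclusion window, modified ADAScog N(18.6, 6.3) on [0, 85], NP-Batt
N(-1.02, 0.66), right-skewed discrete Hachinski (median 1, range 0-4) and
FAQ (median 2, range 0-21), and a log-normal CSF Abeta42/T-tau ratio
(median 1.564) present for roughly half the cohort (the lumbar-puncture
subsample).

Dependence between the continuous/ordinal covariates is induced by a
Gaussian copula.  The reference cohort's covariate correlations were never
published, so the default copula is an assumption: worse baseline cognition
covaries (ADAScog vs NP-Batt -0.6, ADAScog vs MMSE -0.4) and functional
impairment tracks poorer cognition (FAQ vs NP-Batt -0.3); all other pairs
are independent.  The generator is a statistical stand-in for the real
cohort, not a re-identification of it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data_model import (
    LEGAL_VISIT_NUMBERS,
    LongitudinalDataset,
    SubjectBaseline,
    VisitRecord,
)

__all__ = [
    "Marginal",
    "MarginalSpec",
    "DependenceSpec",
    "DependenceError",
    "generate_baseline",
    "generate_outcomes",
    "apply_dropout",
    "DEFAULT_RETENTION",
]


class DependenceError(ValueError):
    """The copula correlation matrix is not a valid correlation matrix."""


# --------------------------------------------------------------------------
# Marginal specifications
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Marginal:
    """One covariate's distribution family plus parameters.

    Families: ``truncnorm`` (mean, sd, lo, hi), ``normal`` (mean, sd),
    ``bernoulli`` (p), ``categorical`` (probs), ``nbinom_trunc`` (mean,
    shape, lo, hi; negative-binomial shape, right-skewed, integer) and
    ``lognormal`` (median, sigma).
    """

    family: str
    params: tuple = ()

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Inverse CDF used to push copula uniforms through the marginal."""
        if self.family == "truncnorm":
            mean, sd, lo, hi = self.params
            a, b = (lo - mean) / sd, (hi - mean) / sd
            return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)
        if self.family == "normal":
            mean, sd = self.params
            return stats.norm.ppf(u, loc=mean, scale=sd)
        if self.family == "nbinom_trunc":
            mean, shape, lo, hi = self.params
            p = shape / (shape + mean)
            dist = stats.nbinom(shape, p)
            clo = dist.cdf(lo - 1)
            chi = dist.cdf(hi)
            return dist.ppf(clo + u * (chi - clo))
        if self.family == "lognormal":
            median, sigma = self.params
            return stats.lognorm.ppf(u, sigma, scale=median)
        raise ValueError(f"family {self.family!r} has no quantile transform")


#: Order of the copula-driven covariates.
COPULA_FIELDS = (
    "age", "education", "bmi", "mmse", "adascog", "npbatt", "faq",
    "hachinski", "csf_ratio",
)


def _default_marginals() -> dict[str, Marginal]:
    return {
        "age": Marginal("truncnorm", (74.2, 7.4, 55.0, 95.0)),
        "education": Marginal("truncnorm", (15.7, 3.0, 4.0, 22.0)),
        "bmi": Marginal("truncnorm", (26.1, 4.0, 16.0, 45.0)),
        "mmse": Marginal("truncnorm", (27.0, 1.8, 24.0, 30.0)),
        "adascog": Marginal("truncnorm", (18.6, 6.3, 0.0, 85.0)),
        "npbatt": Marginal("normal", (-1.02, 0.66)),
        "faq": Marginal("nbinom_trunc", (3.2, 0.9, 0, 21)),
        "hachinski": Marginal("nbinom_trunc", (1.2, 1.5, 0, 4)),
        "csf_ratio": Marginal("lognormal", (1.564, 0.6)),
        # independently drawn categoricals
        "gender": Marginal("bernoulli", (141 / 397,)),          # p(female)
        "apoe4": Marginal("categorical", (185 / 397, 165 / 397, 47 / 397)),
        "medication": Marginal("bernoulli", (0.60,)),
    }


@dataclass
class MarginalSpec:
    """Per-covariate marginal distributions (defaults above) plus the
    fraction of subjects with a CSF measurement."""

    marginals: dict[str, Marginal] = field(default_factory=_default_marginals)
    csf_fraction: float = 199 / 397

    def __post_init__(self) -> None:
        probs = self.marginals["apoe4"].params
        if abs(sum(probs) - 1.0) > 1e-6:
            raise ValueError("apoe4 categorical probabilities must sum to 1")
        if not 0.0 <= self.csf_fraction <= 1.0:
            raise ValueError("csf_fraction must be in [0, 1]")
        for name in ("mmse", "adascog"):
            fam = self.marginals[name]
            if fam.family == "truncnorm":
                lo, hi = fam.params[2], fam.params[3]
                if lo < 0:
                    raise ValueError(f"{name} truncation below 0 violates score bounds")

    def replace(self, **updates: Marginal) -> "MarginalSpec":
        m = dict(self.marginals)
        m.update(updates)
        return MarginalSpec(marginals=m, csf_fraction=self.csf_fraction)


@dataclass
class DependenceSpec:
    """Gaussian-copula correlation matrix over :data:`COPULA_FIELDS`."""

    matrix: np.ndarray = field(default_factory=lambda: _default_dependence())

    def __post_init__(self) -> None:
        R = np.asarray(self.matrix, dtype=float)
        k = len(COPULA_FIELDS)
        if R.shape != (k, k):
            raise DependenceError(f"correlation matrix must be {k}x{k}")
        if not np.allclose(R, R.T, atol=1e-10):
            raise DependenceError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-10):
            raise DependenceError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise DependenceError("correlation matrix must be positive semidefinite")
        self.matrix = R


def _default_dependence() -> np.ndarray:
    R = np.eye(len(COPULA_FIELDS))
    idx = {f: i for i, f in enumerate(COPULA_FIELDS)}

    def set_(a: str, b: str, r: float) -> None:
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = r

    # strengths chosen so the encoded predictors keep the weak collinearity
    # profile reported for the reference cohort (all VIFs below 1.70)
    set_("adascog", "npbatt", -0.5)
    set_("adascog", "mmse", -0.3)
    set_("faq", "npbatt", -0.3)
    return R


# --------------------------------------------------------------------------
# Baseline generation
# --------------------------------------------------------------------------

def generate_baseline(
    n: int,
    marginals: MarginalSpec | None = None,
    dependence: DependenceSpec | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    id_prefix: str = "S",
) -> list[SubjectBaseline]:
    """Draw ``n`` synthetic MCI baseline records.

    Continuous/ordinal covariates come from a Gaussian copula pushed through
    the marginal inverse CDFs; gender, ApoE4 count, medication use and CSF
    availability are drawn independently.  Same seed (or generator state)
    plus same specs gives bit-identical cohorts.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = marginals or MarginalSpec()
    dep = dependence or DependenceSpec()
    rng = rng if rng is not None else np.random.default_rng(seed)

    z = rng.multivariate_normal(
        np.zeros(len(COPULA_FIELDS)), dep.matrix, size=n, method="eigh"
    )
    u = stats.norm.cdf(z)
    u = np.clip(u, 1e-12, 1 - 1e-12)
    cols = {
        f: spec.marginals[f].ppf(u[:, i]) for i, f in enumerate(COPULA_FIELDS)
    }
    p_female = spec.marginals["gender"].params[0]
    female = rng.random(n) < p_female
    apoe = rng.choice(3, size=n, p=np.asarray(spec.marginals["apoe4"].params))
    medicated = rng.random(n) < spec.marginals["medication"].params[0]
    has_csf = rng.random(n) < spec.csf_fraction

    width = max(4, len(str(n)))
    out = []
    for i in range(n):
        out.append(
            SubjectBaseline(
                subject_id=f"{id_prefix}{i + 1:0{width}d}",
                age=float(cols["age"][i]),
                gender="female" if female[i] else "male",
                education=float(cols["education"][i]),
                bmi=float(cols["bmi"][i]),
                apoe4_count=int(apoe[i]),
                hachinski=int(cols["hachinski"][i]),
                faq=int(cols["faq"][i]),
                mmse=int(round(cols["mmse"][i])),
                adascog_bl=float(cols["adascog"][i]),
                npbatt_bl=float(cols["npbatt"][i]),
                csf_ratio=float(cols["csf_ratio"][i]) if has_csf[i] else None,
                on_medication=bool(medicated[i]),
            ).validate()
        )
    return out


# --------------------------------------------------------------------------
# Outcome generation and dropout
# --------------------------------------------------------------------------

def generate_outcomes(
    cohort: Sequence[SubjectBaseline] | LongitudinalDataset,
    endpoint=None,
    trajectory=None,
    schedule: Sequence[int] = (1, 2, 3, 4, 6),
    treatment_slope_delta: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    param_uncertainty: bool = True,
) -> LongitudinalDataset:
    """Simulate outcome records for a cohort from fitted model artifacts.

    With a trajectory fit, NP-Batt values are generated at every scheduled
    visit (follow-up visits by default; baseline scores are covariates, not
    responses) (per-subject random intercept/slope, within-visit noise, and
    ``treatment_slope_delta`` z-units per visit added for a course-altering
    treatment).  With an endpoint fit, month-24 (visit 4) ADAScog values are
    generated by the virtual-placebo endpoint simulator.  At least one fit
    must be given.
    """
    if endpoint is None and trajectory is None:
        raise ValueError("provide an endpoint and/or a trajectory fit")
    bad = sorted(set(int(v) for v in schedule) - LEGAL_VISIT_NUMBERS)
    if bad:
        from .trajectory_model import ScheduleError

        raise ScheduleError(f"illegal visit numbers in schedule: {bad}")
    blist = (
        cohort.baselines if isinstance(cohort, LongitudinalDataset) else list(cohort)
    )
    rng = rng if rng is not None else np.random.default_rng(seed)
    visits: dict[tuple[str, int], VisitRecord] = {}

    if trajectory is not None:
        from .trajectory_model import simulate_trajectory_matrix

        vals = simulate_trajectory_matrix(
            trajectory, blist, list(schedule), 1, rng=rng,
            param_uncertainty=param_uncertainty,
        )[0]
        vals = vals + treatment_slope_delta * np.asarray(schedule, float)[None, :]
        for i, b in enumerate(blist):
            for j, v in enumerate(schedule):
                visits[(b.subject_id, int(v))] = VisitRecord(
                    b.subject_id, int(v), npbatt=float(vals[i, j])
                )

    if endpoint is not None:
        from .endpoint_model import simulate_control_endpoints

        # slope deltas are a trajectory concept; endpoint treatment effects
        # are applied by callers on the sqrt scale
        scores = simulate_control_endpoints(
            endpoint, blist, 1, rng=rng, param_uncertainty=param_uncertainty
        )[0]
        for i, b in enumerate(blist):
            key = (b.subject_id, 4)
            if key in visits:
                visits[key] = dataclasses.replace(
                    visits[key], adascog=float(scores[i])
                )
            else:
                visits[key] = VisitRecord(b.subject_id, 4, adascog=float(scores[i]))

    return LongitudinalDataset(baselines=list(blist), visits=list(visits.values()))


#: Default per-visit retention loosely matching the reference cohort's
#: follow-up (286/397 with a month-24 evaluation).
DEFAULT_RETENTION = {0: 1.0, 1: 0.95, 2: 0.90, 3: 0.82, 4: 0.72, 6: 0.55}


def apply_dropout(
    data: LongitudinalDataset,
    retention: Mapping[int, float] | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> LongitudinalDataset:
    """Thin visits missing-completely-at-random with per-visit retention.

    ``retention`` maps visit number to the probability of keeping a record;
    probabilities must be in (0, 1] and non-increasing over the schedule.
    Baselines are always retained.
    """
    retention = dict(retention or DEFAULT_RETENTION)
    last = 1.0 + 1e-12
    for v in sorted(retention):
        p = retention[v]
        if not 0 < p <= 1:
            raise ValueError(f"retention for visit {v} must be in (0, 1]")
        if p > last + 1e-12:
            raise ValueError("retention must be non-increasing over visits")
        last = p
    rng = rng if rng is not None else np.random.default_rng(seed)
    kept = [
        v for v in data.visits
        if rng.random() < retention.get(v.visit_number, 1.0)
    ]
    return LongitudinalDataset(baselines=list(data.baselines), visits=kept)
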