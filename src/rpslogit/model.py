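"""Model formulations for binary crash-fatality severity.

Three nested families are supported, in increasing order of complexity:

* ``logistic`` — a plain binary logit.  A latent utility
  ``U_i = beta0 + sum_j beta_j x_ij + eps_i`` with logistic residual ``eps``
  generates a fatal outcome when ``U_i > 0``; equivalently
  ``Y_i ~ Bernoulli(p_i1)`` with ``p_i1 = expit(beta0 + sum_j beta_j x_ij)``.
* ``spatial_logistic`` — adds a section-level effect ``phi_m`` with a Leroux
  CAR prior to the utility, capturing correlation between crashes in adjacent
  freeway sections.
* ``rp_spatial_logistic`` — additionally lets selected coefficients vary
  across crashes (unobserved heterogeneity):
  ``beta_ij = beta_bar_j + mu_ij`` with ``mu_ij ~ N(0, sigma_j^2)``.

The latent-utility view is used generatively and for documentation; all
estimation works through the equivalent Bernoulli-logistic likelihood.  The
fatality odds are ``p_i1 / p_i0 = exp(eta_i)`` and a coefficient's odds ratio
is ``exp(beta_j)`` — the multiplicative change in fatality odds per unit
increase of covariate j.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .spatial import LerouxParams, SectionNetwork

__all__ = [
    "FAMILIES",
    "INDICATOR_GROUPS",
    "DEFAULT_COVARIATES",
    "CrashDataset",
    "ModelSpec",
    "ParameterState",
    "linear_predictor",
    "fatality_probability",
    "odds_ratio",
    "log_likelihood",
    "expand_random_coefficients",
]

FAMILIES = ("logistic", "spatial_logistic", "rp_spatial_logistic")

#: Mutually exclusive indicator groups with their (all-zeros) reference level.
INDICATOR_GROUPS: dict[str, dict] = {
    "vehicle_type": {
        "members": ("coach", "truck", "other_vehicle"),
        "reference": "car",
    },
    "time_of_day": {
        "members": ("morning", "afternoon", "evening"),
        "reference": "before_dawn",
    },
    "crash_type": {
        "members": ("rear_end_crash", "angle_crash"),
        "reference": "single_vehicle",
    },
}

#: Covariates retained in the reference analysis (in minutes, 0.1/km, %, mm
#: or {0,1} as appropriate); any subset of the dataset's columns may be used.
DEFAULT_COVARIATES = (
    "ems_response_time",
    "truck",
    "other_vehicle",
    "non_local_vehicle",
    "curvature",
    "grade",
    "afternoon",
    "rear_end_crash",
    "angle_crash",
    "precipitation",
)

_BINARY_COLUMNS = frozenset(
    {
        "weekend",
        "coach",
        "truck",
        "other_vehicle",
        "non_local_vehicle",
        "morning",
        "afternoon",
        "evening",
        "rear_end_crash",
        "angle_crash",
        "bridge",
        "ramp",
    }
)


@dataclass
class CrashDataset:
    """Crash-level observations: outcome, covariates and section assignment.

    ``outcome`` is 1 for a fatal crash, 0 for non-fatal.  ``covariates`` holds
    one column per covariate (EMS response time in minutes, indicators in
    {0, 1}, curvature in 0.1/km, grade in %, precipitation in mm, ...).
    ``section_id`` gives the freeway section containing each crash.
    """

    outcome: np.ndarray
    covariates: pd.DataFrame
    section_id: np.ndarray  # array of section labels (str)

    def __post_init__(self) -> None:
        y = np.asarray(self.outcome)
        if not np.isin(y, (0, 1)).all():
            bad = np.flatnonzero(~np.isin(y, (0, 1)))[0]
            raise ValueError(
                f"outcome must be binary (0/1); row {bad} has value {y[bad]!r}"
            )
        self.outcome = y.astype(np.int8)
        self.section_id = np.asarray(self.section_id, dtype=object)
        if len(self.covariates) != self.N or len(self.section_id) != self.N:
            raise ValueError("outcome, covariates and section_id lengths differ")
        self._validate_covariates()

    def _validate_covariates(self) -> None:
        X = self.covariates
        if "ems_response_time" in X.columns:
            t = X["ems_response_time"].to_numpy(float)
            if np.any(t <= 0):
                row = int(np.flatnonzero(t <= 0)[0])
                raise ValueError(
                    f"ems_response_time must be positive minutes; row {row} has {t[row]}"
                )
        for col in X.columns:
            if col in _BINARY_COLUMNS and not np.isin(X[col].to_numpy(), (0, 1)).all():
                raise ValueError(f"indicator column {col!r} must contain only 0/1")
        for group in INDICATOR_GROUPS.values():
            present = [c for c in group["members"] if c in X.columns]
            if len(present) == len(group["members"]):
                active = X[present].to_numpy(float).sum(axis=1)
                if np.any(active > 1):
                    row = int(np.flatnonzero(active > 1)[0])
                    raise ValueError(
                        f"row {row}: more than one active indicator among {present} "
                        f"(reference category {group['reference']!r} is the all-zeros row)"
                    )

    @property
    def N(self) -> int:
        return len(self.outcome)

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariates.columns)

    def design_matrix(self, covariates: Sequence[str]) -> np.ndarray:
        missing = [c for c in covariates if c not in self.covariates.columns]
        if missing:
            raise ValueError(f"unknown covariate names: {missing}")
        return self.covariates[list(covariates)].to_numpy(np.float64)

    def section_index(self, network: SectionNetwork) -> np.ndarray:
        """Integer section index per crash; errors on unknown section ids."""
        return network.index_of(list(self.section_id))


@dataclass(frozen=True)
class ModelSpec:
    """Which family to fit, on which covariates, with which coefficients random."""

    family: str = "rp_spatial_logistic"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    random_set: frozenset[str] = frozenset({"truck"})

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(self, "random_set", frozenset(self.random_set))
        if self.family != "rp_spatial_logistic" and self.random_set:
            raise ValueError("random_set must be empty unless family is rp_spatial_logistic")
        extra = self.random_set - set(self.covariates)
        if extra:
            raise ValueError(f"random_set not contained in covariates: {sorted(extra)}")

    @property
    def spatial(self) -> bool:
        return self.family in ("spatial_logistic", "rp_spatial_logistic")

    @property
    def fixed_covariates(self) -> tuple[str, ...]:
        return tuple(c for c in self.covariates if c not in self.random_set)

    @property
    def random_covariates(self) -> tuple[str, ...]:
        return tuple(c for c in self.covariates if c in self.random_set)


@dataclass
class ParameterState:
    """One complete parameter configuration of a model family.

    ``beta`` maps fixed-effect covariates to coefficients; ``beta_bar`` and
    ``sigma`` give the mean and SD of each random coefficient, and ``mu`` its
    crash-level deviations (length N), so that ``beta_ij = beta_bar_j + mu_ij``.
    ``phi`` (length M) and ``leroux`` are present for the spatial families.
    """

    beta0: float = 0.0
    beta: dict[str, float] = field(default_factory=dict)
    beta_bar: dict[str, float] = field(default_factory=dict)
    sigma: dict[str, float] = field(default_factory=dict)
    mu: dict[str, np.ndarray] = field(default_factory=dict)
    phi: np.ndarray | None = None
    leroux: LerouxParams | None = None

    def __post_init__(self) -> None:
        for name, s in self.sigma.items():
            if not s >= 0.0:
                raise ValueError(f"sigma[{name!r}] must be positive, got {s}")


def expand_random_coefficients(
    beta_bar: float,
    sigma: float,
    draws_or_mu: int | np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-crash coefficients ``beta_i = beta_bar + mu_i``.

    Pass an integer to draw that many ``mu_i ~ N(0, sigma^2)`` generatively
    (requires ``rng``), or an array of deviations to expand deterministically.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if isinstance(draws_or_mu, (int, np.integer)):
        if rng is None:
            rng = np.random.default_rng()
        mu = rng.normal(0.0, sigma, size=int(draws_or_mu))
    else:
        mu = np.asarray(draws_or_mu, dtype=np.float64)
    return beta_bar + mu


def linear_predictor(
    dataset: CrashDataset,
    state: ParameterState,
    spec: ModelSpec,
    network: SectionNetwork | None = None,
) -> np.ndarray:
    """Systematic part ``eta_i`` of the latent utility.

    eta_i = beta0 + sum_j beta_(i,)j x_ij (+ phi_{m(i)} for spatial families),
    with beta_ij = beta_bar_j + mu_ij for covariates in the random set.
    """
    eta = np.full(dataset.N, state.beta0, dtype=np.float64)
    for name in spec.fixed_covariates:
        if name not in state.beta:
            raise ValueError(f"state.beta missing coefficient for {name!r}")
        eta += state.beta[name] * dataset.covariates[name].to_numpy(np.float64)
    for name in spec.random_covariates:
        if name not in state.beta_bar:
            raise ValueError(f"state.beta_bar missing mean for random covariate {name!r}")
        mu = state.mu.get(name)
        if mu is None:
            raise ValueError(f"state.mu missing deviations for random covariate {name!r}")
        mu = np.asarray(mu, dtype=np.float64)
        if mu.shape != (dataset.N,):
            raise ValueError(
                f"mu[{name!r}] has shape {mu.shape}, expected ({dataset.N},)"
            )
        eta += (state.beta_bar[name] + mu) * dataset.covariates[name].to_numpy(np.float64)
    if spec.spatial:
        if state.phi is None:
            raise ValueError(f"family {spec.family!r} requires section effects phi")
        if network is None:
            raise ValueError("spatial families need the section network to map crashes")
        eta += np.asarray(state.phi, dtype=np.float64)[dataset.section_index(network)]
    elif state.phi is not None and np.any(state.phi):
        raise ValueError("non-spatial family given nonzero phi")
    return eta


def fatality_probability(eta: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
    """Fatality / non-fatality probabilities ``(p1, p0)`` from the predictor.

    p1 = exp(eta) / (1 + exp(eta)) evaluated overflow-safely; p0 = 1 - p1.
    """
    eta = np.asarray(eta, dtype=np.float64)
    p1 = expit(eta)
    return p1, expit(-eta)


def odds_ratio(beta_j: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Odds ratio ``exp(beta_j)`` and percent odds change ``100 (exp(beta_j) - 1)``."""
    beta_j = np.asarray(beta_j, dtype=np.float64)
    or_ = np.exp(beta_j)
    return or_, 100.0 * (or_ - 1.0)


def bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    """Sum of Bernoulli log-terms, stable for large |eta|.

    log p1 = -log(1 + e^-eta) and log p0 = -log(1 + e^eta).
    """
    y = np.asarray(y)
    eta = np.asarray(eta, dtype=np.float64)
    sgn = np.where(y == 1, 1.0, -1.0)
    return float(-np.logaddexp(0.0, -sgn * eta).sum())


def log_likelihood(
    dataset: CrashDataset,
    state: ParameterState,
    spec: ModelSpec,
    network: SectionNetwork | None = None,
) -> float:
    """Bernoulli log-likelihood of the outcomes at the given parameter state."""
    eta = linear_predictor(dataset, state, spec, network)
    return bernoulli_loglik(dataset.outcome, eta)
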