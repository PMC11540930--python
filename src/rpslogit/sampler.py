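"""Metropolis-within-Gibbs estimation of the three crash-severity families.

Priors follow the reference analysis: diffuse normals N(0, 1e4) on all
regression coefficients and random-coefficient means, Uniform(0, 1) on the
spatial-correlation strength rho, and Uniform(0.01, 10) on the scale
hyper-parameters delta and sigma_j.  The default run length is 100,000
iterations with a 50,000-iteration burn-in on a single chain, and convergence
is judged by the Monte-Carlo-error rule: a parameter's chain is accepted when
its MC standard error is below 5% of its posterior SD.

Update kernels
--------------
* regression coefficients (beta0, beta_j, beta_bar_j): scalar adaptive
  random-walk Metropolis with the cached linear predictor updated in place;
* crash-level deviations mu_ij: one vectorized independent-Metropolis sweep
  per random covariate (each crash's deviation touches only its own Bernoulli
  term).  Deviations are instantiated only for crashes with x_ij != 0; for
  x_ij = 0 the product mu_ij * x_ij vanishes, so those latents integrate out
  exactly;
* sigma_j and delta: random-walk on the log scale inside (0.01, 10), followed
  by an ancillarity-sufficiency interweaving (non-centered rescale) move that
  proposes a joint rescaling of the scale and its latents — an extra kernel
  with the same invariant distribution that breaks the slow mixing of a scale
  conditioned on many latents;
* section effects phi_m: vectorized random-walk Metropolis over graph-color
  classes (no two adjacent sections update simultaneously), with the Leroux
  conditional law as prior and the section's Bernoulli contribution as
  likelihood;
* rho: random-walk on the logit scale with Jacobian, using the joint Leroux
  log-density through the precomputed Laplacian eigenvalues.

Proposal scales adapt by Robbins-Monro during burn-in only, so the post
burn-in chain is a fixed-kernel Markov chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .model import CrashDataset, ModelSpec, ParameterState
from .spatial import LerouxParams, SectionNetwork

__all__ = [
    "PriorConfig",
    "McmcConfig",
    "PosteriorSamples",
    "run_mcmc",
    "update_phi",
    "convergence_check",
    "classify_random_parameter",
    "fit_model",
]


@dataclass(frozen=True)
class PriorConfig:
    """Hyper-prior settings (defaults are the reference analysis' priors)."""

    beta_mean: float = 0.0
    beta_var: float = 1.0e4  # variance, i.e. SD 100 — the diffuse-normal prior
    rho_bounds: tuple[float, float] = (0.0, 1.0)
    scale_bounds: tuple[float, float] = (0.01, 10.0)  # for delta and sigma_j

    def __post_init__(self) -> None:
        lo, hi = self.scale_bounds
        if not (0.0 < lo < hi):
            raise ValueError("scale_bounds must be positive and ordered")
        if self.beta_var <= 0:
            raise ValueError("beta_var must be positive")


@dataclass(frozen=True)
class McmcConfig:
    """Chain-length, seeding and tuning settings."""

    n_iter: int = 100_000
    n_burnin: int = 50_000
    n_chains: int = 1
    thin: int = 1
    seed: int = 0
    target_accept: float = 0.44
    adapt: bool = True
    prior_only: bool = False  # switch the likelihood off (prior recovery checks)
    fixed: tuple[str, ...] = ()  # parameter names held at their initial values
    store_phi: bool = True
    max_mu_draws: int = 500  # ceiling on stored crash-level deviation draws
    progress_every: int = 0  # log acceptance every k iterations (0 = silent)

    def __post_init__(self) -> None:
        if not 0 < self.n_burnin < self.n_iter:
            raise ValueError("need 0 < n_burnin < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PosteriorSamples:
    """Post burn-in draws plus bookkeeping needed for reporting and DIC."""

    draws: dict[str, np.ndarray]  # scalar parameters, each (n_kept,)
    deviance: np.ndarray  # -2 log-likelihood per kept draw
    phi: np.ndarray | None  # (n_kept, M) when stored
    mu_mean: dict[str, np.ndarray]  # posterior mean deviations (full length N)
    mu_draws: dict[str, np.ndarray]  # thinned deviation draws, (n_mu_draws, n_active)
    mu_active: dict[str, np.ndarray]  # crash indices the deviation draws refer to
    mu_draw_index: np.ndarray  # kept-draw indices of the stored deviation draws
    eta_mean: np.ndarray  # posterior mean linear predictor per crash
    acceptance: dict[str, float]
    spec: ModelSpec
    priors: PriorConfig
    config: McmcConfig
    section_ids: list[str]

    @property
    def n_kept(self) -> int:
        return len(self.deviance)

    @property
    def parameter_names(self) -> list[str]:
        return list(self.draws)

    def posterior_mean(self) -> dict[str, float]:
        return {k: float(v.mean()) for k, v in self.draws.items()}

    def mean_state(self) -> ParameterState:
        """Posterior-mean :class:`ParameterState` (focus parameters)."""
        means = self.posterior_mean()
        beta = {}
        beta_bar = {}
        sigma = {}
        for key, val in means.items():
            if key.startswith("beta["):
                beta[key[5:-1]] = val
            elif key.startswith("beta_bar["):
                beta_bar[key[9:-1]] = val
            elif key.startswith("sigma["):
                sigma[key[6:-1]] = val
        phi = self.phi.mean(axis=0) if self.phi is not None else None
        leroux = None
        if "rho" in means and "delta" in means:
            leroux = LerouxParams(rho=means["rho"], delta=means["delta"])
        return ParameterState(
            beta0=means.get("beta0", 0.0),
            beta=beta,
            beta_bar=beta_bar,
            sigma=sigma,
            mu={k: v.copy() for k, v in self.mu_mean.items()},
            phi=phi,
            leroux=leroux,
        )


# ---------------------------------------------------------------------------
# internal sampler machinery


def _loglik_terms(sgn: np.ndarray, eta: np.ndarray) -> np.ndarray:
    # per-crash Bernoulli log-probability, stable for large |eta|
    return -np.logaddexp(0.0, -sgn * eta)


class _AdaptiveScale:
    """Robbins-Monro step-size adaptation toward a target acceptance rate."""

    def __init__(self, scale: float, target: float, enabled: bool):
        self.scale = scale
        self.target = target
        self.enabled = enabled
        self.t = 0
        self.n_prop = 0
        self.n_acc = 0.0

    def update(self, acc_rate: float, in_burnin: bool) -> None:
        self.n_prop += 1
        self.n_acc += acc_rate
        if self.enabled and in_burnin:
            self.t += 1
            gamma = (self.t + 10.0) ** -0.6
            self.scale *= math.exp(gamma * (acc_rate - self.target))
            self.scale = min(max(self.scale, 1e-8), 1e4)

    @property
    def acceptance(self) -> float:
        return self.n_acc / self.n_prop if self.n_prop else math.nan


class _Sampler:
    def __init__(
        self,
        dataset: CrashDataset,
        network: SectionNetwork | None,
        spec: ModelSpec,
        priors: PriorConfig,
        config: McmcConfig,
        init: ParameterState | None = None,
    ):
        if spec.spatial and network is None:
            raise ValueError("spatial families require a section network")
        self.dataset = dataset
        self.network = network
        self.spec = spec
        self.priors = priors
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.N = dataset.N

        # linear-coefficient block: intercept + fixed betas + random means
        self.coef_names = (
            ["beta0"]
            + [f"beta[{c}]" for c in spec.fixed_covariates]
            + [f"beta_bar[{c}]" for c in spec.random_covariates]
        )
        cols = [np.ones(self.N)]
        cols += [dataset.covariates[c].to_numpy(np.float64) for c in spec.fixed_covariates]
        cols += [dataset.covariates[c].to_numpy(np.float64) for c in spec.random_covariates]
        self.Xl = np.column_stack(cols) if self.N else np.zeros((0, len(self.coef_names)))
        self.coef = np.zeros(len(self.coef_names))

        self.sgn = np.where(dataset.outcome == 1, 1.0, -1.0)

        # random-coefficient latents, only where the covariate is active
        self.mu: dict[str, np.ndarray] = {}
        self.mu_idx: dict[str, np.ndarray] = {}
        self.mu_x: dict[str, np.ndarray] = {}
        self.sigma: dict[str, float] = {}
        for c in spec.random_covariates:
            x = dataset.covariates[c].to_numpy(np.float64)
            idx = np.flatnonzero(x != 0.0)
            self.mu_idx[c] = idx
            self.mu_x[c] = x[idx]
            self.mu[c] = np.zeros(len(idx))
            self.sigma[c] = 1.0

        if spec.spatial:
            self.M = network.M
            self.sec_idx = dataset.section_index(network) if self.N else np.zeros(0, np.int64)
            self.phi = np.zeros(self.M)
            self.rho = 0.5
            self.delta = 1.0
            self.W = network.sparse_w()
            self.nbr = network.neighbor_counts.astype(np.float64)
            self.colors = network.coloring()
            lap = np.diag(self.nbr) - network.adjacency.astype(np.float64)
            self.lap_eigs = np.linalg.eigvalsh(lap)
            self.lap_sp = sp.csr_matrix(lap)

        if init is not None:
            self._apply_init(init)

        self.eta = self._full_eta()
        self.ll = self._loglik(self.eta)
        if not np.isfinite(self.ll):
            raise RuntimeError("non-finite log-likelihood at initialization")

        t = config.target_accept
        ad = config.adapt
        self.scales: dict[str, _AdaptiveScale] = {
            n: _AdaptiveScale(0.5, t, ad) for n in self.coef_names
        }
        for c in spec.random_covariates:
            self.scales[f"mu[{c}]"] = _AdaptiveScale(1.0, t, ad)
            self.scales[f"sigma[{c}]"] = _AdaptiveScale(0.5, t, ad)
            self.scales[f"sigma_nc[{c}]"] = _AdaptiveScale(0.3, t, ad)
        if spec.spatial:
            self.scales["phi"] = _AdaptiveScale(0.5, t, ad)
            self.scales["rho"] = _AdaptiveScale(1.0, t, ad)
            self.scales["delta"] = _AdaptiveScale(0.5, t, ad)
            self.scales["delta_nc"] = _AdaptiveScale(0.3, t, ad)

    # -- state plumbing ----------------------------------------------------

    def _apply_init(self, init: ParameterState) -> None:
        for k, name in enumerate(self.coef_names):
            if name == "beta0":
                self.coef[k] = init.beta0
            elif name.startswith("beta["):
                self.coef[k] = init.beta.get(name[5:-1], 0.0)
            else:
                self.coef[k] = init.beta_bar.get(name[9:-1], 0.0)
        for c in self.spec.random_covariates:
            if c in init.sigma:
                self.sigma[c] = float(init.sigma[c])
            if c in init.mu:
                self.mu[c] = np.asarray(init.mu[c], dtype=np.float64)[self.mu_idx[c]].copy()
        if self.spec.spatial:
            if init.phi is not None:
                self.phi = np.asarray(init.phi, dtype=np.float64).copy()
            if init.leroux is not None:
                self.rho = float(init.leroux.rho)
                self.delta = float(init.leroux.delta)

    def _full_eta(self) -> np.ndarray:
        eta = self.Xl @ self.coef
        for c in self.spec.random_covariates:
            eta[self.mu_idx[c]] += self.mu[c] * self.mu_x[c]
        if self.spec.spatial:
            eta += self.phi[self.sec_idx]
        return eta

    def _loglik(self, eta: np.ndarray) -> float:
        if self.config.prior_only or self.N == 0:
            return 0.0
        return float(_loglik_terms(self.sgn, eta).sum())

    def state(self) -> ParameterState:
        beta = {}
        beta_bar = {}
        for k, name in enumerate(self.coef_names):
            if name.startswith("beta["):
                beta[name[5:-1]] = float(self.coef[k])
            elif name.startswith("beta_bar["):
                beta_bar[name[9:-1]] = float(self.coef[k])
        mu_full = {}
        for c in self.spec.random_covariates:
            m = np.zeros(self.N)
            m[self.mu_idx[c]] = self.mu[c]
            mu_full[c] = m
        return ParameterState(
            beta0=float(self.coef[0]),
            beta=beta,
            beta_bar=beta_bar,
            sigma=dict(self.sigma),
            mu=mu_full,
            phi=self.phi.copy() if self.spec.spatial else None,
            leroux=LerouxParams(self.rho, self.delta) if self.spec.spatial else None,
        )

    # -- kernels -----------------------------------------------------------

    def _update_coefs(self, in_burnin: bool) -> None:
        var0 = self.priors.beta_var
        m0 = self.priors.beta_mean
        for k, name in enumerate(self.coef_names):
            if name in self.config.fixed:
                continue
            sc = self.scales[name]
            b = self.coef[k]
            b_new = b + sc.scale * self.rng.standard_normal()
            d_eta = (b_new - b) * self.Xl[:, k]
            ll_new = self._loglik(self.eta + d_eta)
            log_a = (ll_new - self.ll) + ((b - m0) ** 2 - (b_new - m0) ** 2) / (2 * var0)
            acc = 0.0
            if math.log(self.rng.random()) < log_a:
                self.coef[k] = b_new
                self.eta += d_eta
                self.ll = ll_new
                acc = 1.0
            sc.update(acc, in_burnin)

    def _update_mu(self, in_burnin: bool) -> None:
        for c in self.spec.random_covariates:
            if f"mu[{c}]" in self.config.fixed:
                continue
            idx = self.mu_idx[c]
            if len(idx) == 0:
                continue
            sc = self.scales[f"mu[{c}]"]
            mu = self.mu[c]
            sig2 = self.sigma[c] ** 2
            step = sc.scale * self.rng.standard_normal(len(idx))
            mu_new = mu + step
            if self.config.prior_only or self.N == 0:
                d_ll = np.zeros(len(idx))
            else:
                eta_a = self.eta[idx]
                d_eta = step * self.mu_x[c]
                d_ll = _loglik_terms(self.sgn[idx], eta_a + d_eta) - _loglik_terms(
                    self.sgn[idx], eta_a
                )
            log_a = d_ll + (mu**2 - mu_new**2) / (2 * sig2)
            accept = np.log(self.rng.random(len(idx))) < log_a
            if accept.any():
                mu[accept] = mu_new[accept]
                if not (self.config.prior_only or self.N == 0):
                    upd = idx[accept]
                    self.eta[upd] += step[accept] * self.mu_x[c][accept]
                    self.ll += float(d_ll[accept].sum())
            sc.update(float(accept.mean()), in_burnin)

    def _update_sigma(self, in_burnin: bool) -> None:
        lo, hi = self.priors.scale_bounds
        for c in self.spec.random_covariates:
            if f"sigma[{c}]" in self.config.fixed:
                continue
            mu = self.mu[c]
            n = len(mu)
            ssq = float(mu @ mu)
            # centered move: sigma | mu (likelihood untouched)
            sc = self.scales[f"sigma[{c}]"]
            s = self.sigma[c]
            s_new = s * math.exp(sc.scale * self.rng.standard_normal())
            acc = 0.0
            if lo < s_new < hi:
                # N(mu; 0, s) terms + log-Jacobian of the log-scale walk
                log_a = (
                    -n * (math.log(s_new) - math.log(s))
                    - ssq / 2 * (1 / s_new**2 - 1 / s**2)
                    + (math.log(s_new) - math.log(s))
                )
                if math.log(self.rng.random()) < log_a:
                    self.sigma[c] = s_new
                    acc = 1.0
            sc.update(acc, in_burnin)

            # non-centered rescale: mu = s * z with z fixed
            sc2 = self.scales[f"sigma_nc[{c}]"]
            s = self.sigma[c]
            s_new = s * math.exp(sc2.scale * self.rng.standard_normal())
            acc = 0.0
            if lo < s_new < hi:
                ratio = s_new / s
                idx = self.mu_idx[c]
                if self.config.prior_only or self.N == 0:
                    ll_new = self.ll
                    d_eta = None
                else:
                    d_eta = (ratio - 1.0) * self.mu[c] * self.mu_x[c]
                    eta_new = self.eta.copy()
                    eta_new[idx] += d_eta
                    ll_new = self._loglik(eta_new)
                log_a = (ll_new - self.ll) + math.log(ratio)  # uniform prior on s
                if math.log(self.rng.random()) < log_a:
                    self.sigma[c] = s_new
                    self.mu[c] = self.mu[c] * ratio
                    if d_eta is not None:
                        self.eta = eta_new
                        self.ll = ll_new
                    acc = 1.0
            sc2.update(acc, in_burnin)

    def _phi_color_sweep(self, in_burnin: bool) -> None:
        if "phi" in self.config.fixed:
            return
        sc = self.scales["phi"]
        cond_denom = 1.0 - self.rho + self.rho * self.nbr
        cond_denom = np.maximum(cond_denom, 1e-12)
        acc_total = 0.0
        for cls in self.colors:
            step = sc.scale * self.rng.standard_normal(len(cls))
            phi_new_c = self.phi[cls] + step
            wphi = self.W @ self.phi
            mean_c = self.rho * wphi[cls] / cond_denom[cls]
            var_c = self.delta**2 / cond_denom[cls]
            d_prior = ((self.phi[cls] - mean_c) ** 2 - (phi_new_c - mean_c) ** 2) / (2 * var_c)
            if self.config.prior_only or self.N == 0:
                d_ll_sec = np.zeros(len(cls))
            else:
                d_phi = np.zeros(self.M)
                d_phi[cls] = step
                d_eta = d_phi[self.sec_idx]
                d_ll = _loglik_terms(self.sgn, self.eta + d_eta) - _loglik_terms(
                    self.sgn, self.eta
                )
                d_ll_sec = np.bincount(self.sec_idx, weights=d_ll, minlength=self.M)[cls]
            log_a = d_ll_sec + d_prior
            accept = np.log(self.rng.random(len(cls))) < log_a
            if accept.any():
                self.phi[cls[accept]] += step[accept]
                if not (self.config.prior_only or self.N == 0):
                    d_phi_acc = np.zeros(self.M)
                    d_phi_acc[cls[accept]] = step[accept]
                    self.eta += d_phi_acc[self.sec_idx]
                    self.ll += float(d_ll_sec[accept].sum())
            acc_total += float(accept.mean()) * len(cls)
        sc.update(acc_total / self.M, in_burnin)

    def _car_logprior(self, rho: float, delta: float, quad_lap: float, quad_id: float) -> float:
        # log p(phi | rho, delta) up to constants, proper for rho < 1
        eigs = rho * self.lap_eigs + (1.0 - rho)
        logdet = float(np.log(np.maximum(eigs, 1e-300)).sum()) - 2 * self.M * math.log(delta)
        quad = (rho * quad_lap + (1.0 - rho) * quad_id) / delta**2
        return 0.5 * logdet - 0.5 * quad

    def _update_rho_delta(self, in_burnin: bool) -> None:
        quad_lap = float(self.phi @ (self.lap_sp @ self.phi))
        quad_id = float(self.phi @ self.phi)
        lo, hi = self.priors.scale_bounds

        if "rho" not in self.config.fixed:
            sc = self.scales["rho"]
            r = min(max(self.rho, 1e-12), 1 - 1e-12)
            z = math.log(r / (1 - r))
            z_new = z + sc.scale * self.rng.standard_normal()
            r_new = 1.0 / (1.0 + math.exp(-z_new))
            log_a = (
                self._car_logprior(r_new, self.delta, quad_lap, quad_id)
                - self._car_logprior(r, self.delta, quad_lap, quad_id)
                + math.log(r_new * (1 - r_new))
                - math.log(r * (1 - r))
            )
            acc = 0.0
            if math.log(self.rng.random()) < log_a:
                self.rho = r_new
                acc = 1.0
            sc.update(acc, in_burnin)

        if "delta" not in self.config.fixed:
            # centered move on log delta
            sc = self.scales["delta"]
            d = self.delta
            d_new = d * math.exp(sc.scale * self.rng.standard_normal())
            acc = 0.0
            if lo < d_new < hi:
                log_a = (
                    self._car_logprior(self.rho, d_new, quad_lap, quad_id)
                    - self._car_logprior(self.rho, d, quad_lap, quad_id)
                    + math.log(d_new / d)
                )
                if math.log(self.rng.random()) < log_a:
                    self.delta = d_new
                    acc = 1.0
            sc.update(acc, in_burnin)

            # non-centered rescale: phi = delta * psi with psi fixed
            sc2 = self.scales["delta_nc"]
            d = self.delta
            d_new = d * math.exp(sc2.scale * self.rng.standard_normal())
            acc = 0.0
            if lo < d_new < hi:
                ratio = d_new / d
                if self.config.prior_only or self.N == 0:
                    ll_new = self.ll
                    eta_new = None
                else:
                    eta_new = self.eta + (ratio - 1.0) * self.phi[self.sec_idx]
                    ll_new = self._loglik(eta_new)
                log_a = (ll_new - self.ll) + math.log(ratio)
                if math.log(self.rng.random()) < log_a:
                    self.delta = d_new
                    self.phi = self.phi * ratio
                    if eta_new is not None:
                        self.eta = eta_new
                        self.ll = ll_new
                    acc = 1.0
            sc2.update(acc, in_burnin)

    def step(self, in_burnin: bool) -> None:
        self._update_coefs(in_burnin)
        if self.spec.random_covariates:
            self._update_mu(in_burnin)
            self._update_sigma(in_burnin)
        if self.spec.spatial:
            self._phi_color_sweep(in_burnin)
            self._update_rho_delta(in_burnin)

    # -- driver ------------------------------------------------------------

    def run(self, progress: Callable[[str], None] | None = None) -> PosteriorSamples:
        cfg = self.config
        n_kept = -(-(cfg.n_iter - cfg.n_burnin) // cfg.thin)
        scalar_names = list(self.coef_names)
        for c in self.spec.random_covariates:
            scalar_names.append(f"sigma[{c}]")
        if self.spec.spatial:
            scalar_names += ["rho", "delta"]
        draws = {n: np.empty(n_kept) for n in scalar_names}
        deviance = np.empty(n_kept)
        phi_store = (
            np.empty((n_kept, self.M)) if (self.spec.spatial and cfg.store_phi) else None
        )
        mu_sum = {c: np.zeros(len(self.mu_idx[c])) for c in self.spec.random_covariates}
        eta_sum = np.zeros(self.N)
        mu_every = max(1, -(-n_kept // max(cfg.max_mu_draws, 1)))
        n_mu = len(range(0, n_kept, mu_every))
        mu_store = {
            c: np.empty((n_mu, len(self.mu_idx[c]))) for c in self.spec.random_covariates
        }
        mu_draw_index = np.arange(0, n_kept, mu_every)

        kept = 0
        for it in range(cfg.n_iter):
            in_burnin = it < cfg.n_burnin
            self.step(in_burnin)
            if not in_burnin and (it - cfg.n_burnin) % cfg.thin == 0:
                k = 0
                for name in self.coef_names:
                    draws[name][kept] = self.coef[k]
                    k += 1
                for c in self.spec.random_covariates:
                    draws[f"sigma[{c}]"][kept] = self.sigma[c]
                if self.spec.spatial:
                    draws["rho"][kept] = self.rho
                    draws["delta"][kept] = self.delta
                    if phi_store is not None:
                        phi_store[kept] = self.phi
                deviance[kept] = -2.0 * self.ll
                for c in self.spec.random_covariates:
                    mu_sum[c] += self.mu[c]
                    if kept % mu_every == 0:
                        mu_store[c][kept // mu_every] = self.mu[c]
                eta_sum += self.eta
                kept += 1
            if cfg.progress_every and (it + 1) % cfg.progress_every == 0 and progress:
                rates = ", ".join(
                    f"{n}={s.acceptance:.2f}" for n, s in self.scales.items()
                )
                progress(f"iter {it + 1}/{cfg.n_iter}: acceptance {rates}")

        if not cfg.prior_only and self.N > 0 and cfg.adapt:
            dead = [
                n
                for n, s in self.scales.items()
                if s.n_prop > 0 and s.n_acc == 0.0 and n not in cfg.fixed
            ]
            if dead:
                raise RuntimeError(
                    f"zero acceptance after adaptation for blocks {dead}; "
                    "check the data/model for degeneracy"
                )

        mu_mean = {}
        for c in self.spec.random_covariates:
            full = np.zeros(self.N)
            full[self.mu_idx[c]] = mu_sum[c] / max(kept, 1)
            mu_mean[c] = full
        return PosteriorSamples(
            draws=draws,
            deviance=deviance[:kept],
            phi=phi_store[:kept] if phi_store is not None else None,
            mu_mean=mu_mean,
            mu_draws=mu_store,
            mu_active={c: self.mu_idx[c].copy() for c in self.spec.random_covariates},
            mu_draw_index=mu_draw_index,
            eta_mean=eta_sum / max(kept, 1),
            acceptance={n: s.acceptance for n, s in self.scales.items()},
            spec=self.spec,
            priors=self.priors,
            config=cfg,
            section_ids=list(self.network.section_ids) if self.spec.spatial else [],
        )


def run_mcmc(
    dataset: CrashDataset,
    network: SectionNetwork | None,
    spec: ModelSpec,
    priors: PriorConfig | None = None,
    config: McmcConfig | None = None,
    init: ParameterState | None = None,
    progress: Callable[[str], None] | None = None,
) -> PosteriorSamples:
    """Run one Metropolis-within-Gibbs chain and return post burn-in draws.

    Deterministic given ``config.seed``.  ``init`` overrides the default
    initialization (coefficients 0, phi 0, rho 0.5, delta and sigma 1).
    """
    sampler = _Sampler(
        dataset, network, spec, priors or PriorConfig(), config or McmcConfig(), init
    )
    return sampler.run(progress)


def update_phi(
    state: ParameterState,
    dataset: CrashDataset,
    network: SectionNetwork,
    spec: ModelSpec | None = None,
    priors: PriorConfig | None = None,
    rng_seed: int = 0,
    n_sweeps: int = 1,
    scales: tuple[float, float, float] = (0.5, 1.0, 0.3),
) -> ParameterState:
    """Standalone spatial-block update: ``n_sweeps`` Metropolis sweeps over
    (phi, rho, delta) holding all regression parameters fixed.

    Each phi_m sees the Leroux conditional as its prior and its section's
    Bernoulli likelihood contribution; sections without crashes reduce to a
    prior-conditional draw target.  Returns a new state; the input is untouched.
    """
    if spec is None:
        covs = tuple(state.beta) + tuple(state.beta_bar)
        random = frozenset(state.sigma) if state.sigma else frozenset()
        family = "rp_spatial_logistic" if random else "spatial_logistic"
        spec = ModelSpec(family=family, covariates=covs, random_set=random)
    fixed = tuple(
        ["beta0"]
        + [f"beta[{c}]" for c in spec.fixed_covariates]
        + [f"beta_bar[{c}]" for c in spec.random_covariates]
        + [f"mu[{c}]" for c in spec.random_covariates]
        + [f"sigma[{c}]" for c in spec.random_covariates]
    )
    cfg = McmcConfig(
        n_iter=max(n_sweeps, 2),
        n_burnin=1,
        seed=rng_seed,
        adapt=False,
        fixed=fixed,
        store_phi=False,
    )
    s = _Sampler(dataset, network, spec, priors or PriorConfig(), cfg, init=state)
    s.scales["phi"].scale = scales[0]
    s.scales["rho"].scale = scales[1]
    s.scales["delta"].scale = scales[2]
    for _ in range(n_sweeps):
        s._phi_color_sweep(in_burnin=False)
        s._update_rho_delta(in_burnin=False)
    return s.state()


def convergence_check(
    samples: PosteriorSamples | Mapping[str, np.ndarray],
    threshold: float = 0.05,
    n_batches: int = 50,
) -> dict[str, dict]:
    """Per-parameter Monte-Carlo-error convergence rule.

    The MC standard error of each posterior mean is estimated by batch means
    (default 50 batches); a parameter passes when MC error / posterior SD is
    strictly below the threshold (default 5%).  A constant chain has 0/0 and
    is flagged ``indeterminate`` rather than passed.
    """
    draws = samples.draws if isinstance(samples, PosteriorSamples) else dict(samples)
    out: dict[str, dict] = {}
    for name, x in draws.items():
        x = np.asarray(x, dtype=np.float64)
        if len(x) < 2 * n_batches:
            raise ValueError(
                f"{name}: need at least {2 * n_batches} draws for {n_batches} batches"
            )
        sd = float(x.std(ddof=1))
        b = len(x) // n_batches
        bm = x[: b * n_batches].reshape(n_batches, b).mean(axis=1)
        mc_error = float(bm.std(ddof=1) / math.sqrt(n_batches))
        if sd <= 1e-12 * max(1.0, abs(float(x.mean()))):  # constant chain: 0/0
            out[name] = {"status": "indeterminate", "mc_error": mc_error, "sd": sd,
                         "ratio": math.nan}
            continue
        ratio = mc_error / sd
        out[name] = {
            "status": "pass" if ratio < threshold else "fail",
            "mc_error": mc_error,
            "sd": sd,
            "ratio": ratio,
        }
    return out


def classify_random_parameter(
    sigma_samples: np.ndarray,
    level: float = 0.95,
    prior_lower: float = 0.01,
    boundary_factor: float = 2.0,
) -> str:
    """Decide whether a random coefficient's spread is supported by the data.

    A positive-support SD can never have a credible interval bracketing zero,
    so "posterior variance not significant at the ``level`` credibility" is
    operationalized as: the lower (1-level)/2 posterior quantile of sigma sits
    at the prior's lower boundary (below ``boundary_factor * prior_lower``).
    Returns ``"collapse_to_fixed"`` in that case, else ``"random"``.
    """
    x = np.asarray(sigma_samples, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty sigma sample array")
    q = float(np.quantile(x, (1.0 - level) / 2.0))
    return "collapse_to_fixed" if q < boundary_factor * prior_lower else "random"


def fit_model(
    dataset: CrashDataset,
    network: SectionNetwork | None,
    spec: ModelSpec,
    priors: PriorConfig | None = None,
    config: McmcConfig | None = None,
    collapse: bool = True,
    progress: Callable[[str], None] | None = None,
) -> tuple[PosteriorSamples, ModelSpec, list[str]]:
    """Fit a family, applying the random-to-fixed collapse rule.

    After a random-parameters fit, any sigma_j classified as unsupported is
    moved out of the random set and the model is refit; if the random set
    empties, the family degrades to the spatial logistic.  Returns the final
    samples, the final spec, and the covariates that were collapsed.
    """
    collapsed: list[str] = []
    while True:
        samples = run_mcmc(dataset, network, spec, priors, config, progress=progress)
        if not (collapse and spec.random_covariates):
            return samples, spec, collapsed
        to_collapse = [
            c
            for c in spec.random_covariates
            if classify_random_parameter(samples.draws[f"sigma[{c}]"]) == "collapse_to_fixed"
        ]
        if not to_collapse:
            return samples, spec, collapsed
        collapsed += to_collapse
        new_random = spec.random_set - set(to_collapse)
        if new_random:
            spec = replace(spec, random_set=frozenset(new_random))
        else:
            spec = ModelSpec(
                family="spatial_logistic",
                covariates=spec.covariates,
                random_set=frozenset(),
            )
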