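"""Posterior summaries, effect quantification and model comparison.

This module turns raw MCMC draws into the quantities an injury-severity
analysis reports: posterior means and SDs, equal-tailed credible intervals
with 90/95% significance flags, odds ratios and percent odds changes,
the share of crashes with a positive heterogeneous effect, average marginal
effects on the fatality probability, and DIC-based model comparison.

DIC here is the conditional (focused) form matching common MCMC practice for
hierarchical models: the deviance conditions on the sampled section effects
and crash-level coefficients, ``pD = Dbar - D(theta_hat)`` with
``D(theta_hat)`` evaluated at the posterior means of all focus parameters.
Because the linear predictor is linear in those parameters, the predictor at
the posterior mean equals the posterior mean predictor, which the sampler
tracks exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

from .model import CrashDataset, ModelSpec, ParameterState, linear_predictor, odds_ratio
from .model import bernoulli_loglik
from .sampler import PosteriorSamples, convergence_check
from .spatial import SectionNetwork

__all__ = [
    "DicReport",
    "FitReport",
    "summarize_posterior",
    "heterogeneity_share",
    "average_marginal_effect",
    "compute_dic",
    "compare_models",
    "build_report",
    "plot_traces",
]


@dataclass(frozen=True)
class DicReport:
    """Deviance information criterion components: DIC = Dbar + pD."""

    dbar: float
    pd: float
    dataset_label: str | None = None

    @property
    def dic(self) -> float:
        return self.dbar + self.pd


def summarize_posterior(
    samples: PosteriorSamples | Mapping[str, np.ndarray],
    levels: tuple[float, ...] = (0.90, 0.95),
) -> pd.DataFrame:
    """Posterior mean, SD, equal-tailed intervals and significance flags.

    A parameter is "significant at level L" when its equal-tailed L-interval
    excludes zero.  Rows are parameters; interval and flag columns appear per
    level.
    """
    draws = samples.draws if isinstance(samples, PosteriorSamples) else dict(samples)
    rows = {}
    for name, x in draws.items():
        x = np.asarray(x, dtype=np.float64)
        if x.size == 0:
            raise ValueError(f"no draws for parameter {name!r}")
        row = {"mean": float(x.mean()), "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0}
        for lv in levels:
            a = (1.0 - lv) / 2.0
            lo, hi = np.quantile(x, [a, 1.0 - a])
            pct = int(round(lv * 100))
            row[f"lower_{pct}"] = float(lo)
            row[f"upper_{pct}"] = float(hi)
            row[f"significant_{pct}"] = bool(lo > 0.0 or hi < 0.0)
        rows[name] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def heterogeneity_share(beta_bar: float, sigma: float) -> float:
    """Percent of crashes with a positive coefficient, ``100 * Phi(beta_bar/sigma)``.

    Under the normal mixing law beta_i ~ N(beta_bar, sigma^2), this is the
    share of observations for which the heterogeneous effect increases the
    fatality odds.
    """
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return float(100.0 * ndtr(beta_bar / sigma))


def _is_indicator(dataset: CrashDataset, covariate: str) -> bool:
    vals = dataset.covariates[covariate].to_numpy()
    return bool(np.isin(vals, (0, 1)).all())


def average_marginal_effect(
    dataset: CrashDataset,
    samples: PosteriorSamples | ParameterState,
    covariate: str,
    delta_x: float,
    spec: ModelSpec | None = None,
    network: SectionNetwork | None = None,
    plug_in: bool = False,
) -> float:
    """Average marginal effect of a ``delta_x`` change in a continuous covariate.

    The AME is the mean over crashes (and, by default, over posterior draws)
    of ``p1(x_j + delta_x) - p1(x_j)`` with every other covariate held at its
    observed value.  With ``plug_in=True`` (or when a single
    :class:`ParameterState` is given) the effect is evaluated at one
    parameter configuration only.  Posterior averaging over crash-level
    deviations uses the sampler's stored (evenly thinned) deviation draws.
    """
    if covariate not in dataset.covariates.columns:
        raise ValueError(f"unknown covariate {covariate!r}")
    if _is_indicator(dataset, covariate):
        raise ValueError(
            f"{covariate!r} is an indicator; report its odds ratio instead of an AME"
        )

    def _ame_from_eta(eta: np.ndarray, slope: float | np.ndarray) -> float:
        return float(np.mean(expit(eta + slope * delta_x) - expit(eta)))

    if isinstance(samples, ParameterState):
        if spec is None:
            raise ValueError("evaluating at a ParameterState requires the model spec")
        eta = linear_predictor(dataset, samples, spec, network)
        if covariate in spec.random_covariates:
            slope = samples.beta_bar[covariate] + np.asarray(samples.mu[covariate])
        else:
            slope = samples.beta[covariate]
        return _ame_from_eta(eta, slope)

    spec = samples.spec
    if plug_in:
        return average_marginal_effect(
            dataset, samples.mean_state(), covariate, delta_x, spec, network
        )

    # posterior-averaged path: rebuild eta per stored draw
    x_cols = {
        c: dataset.covariates[c].to_numpy(np.float64)
        for c in spec.covariates
    }
    sec = dataset.section_index(network) if spec.spatial else None
    if spec.spatial and network is None:
        raise ValueError("spatial fits need the network for posterior-averaged AMEs")
    idx = samples.mu_draw_index if spec.random_covariates else np.arange(
        0, samples.n_kept, max(1, samples.n_kept // samples.config.max_mu_draws)
    )
    total = 0.0
    for j, t in enumerate(idx):
        eta = np.full(dataset.N, samples.draws["beta0"][t])
        for c in spec.fixed_covariates:
            eta += samples.draws[f"beta[{c}]"][t] * x_cols[c]
        dev: dict[str, np.ndarray] = {}
        for c in spec.random_covariates:
            coefs = np.zeros(dataset.N)
            coefs[samples.mu_active[c]] = samples.mu_draws[c][j]
            dev[c] = coefs
            eta += (samples.draws[f"beta_bar[{c}]"][t] + coefs) * x_cols[c]
        if spec.spatial:
            if samples.phi is None:
                raise ValueError("phi draws were not stored; rerun with store_phi=True")
            eta += samples.phi[t][sec]
        if covariate in spec.random_covariates:
            slope = samples.draws[f"beta_bar[{covariate}]"][t] + dev[covariate]
        else:
            slope = samples.draws[f"beta[{covariate}]"][t]
        total += _ame_from_eta(eta, slope)
    return total / len(idx)


def compute_dic(
    samples: PosteriorSamples,
    dataset: CrashDataset,
    spec: ModelSpec | None = None,
    dataset_label: str | None = None,
) -> DicReport:
    """Conditional DIC from the stored deviance draws and mean predictor.

    Dbar is the posterior mean of -2 log-likelihood; D(theta_hat) evaluates
    the deviance at the posterior mean of the focus parameters (equivalently,
    at the posterior-mean linear predictor); pD = Dbar - D(theta_hat).
    """
    dev = np.asarray(samples.deviance, dtype=np.float64)
    if not np.isfinite(dev).all():
        raise ValueError("non-finite deviance draws")
    dbar = float(dev.mean())
    d_hat = -2.0 * bernoulli_loglik(dataset.outcome, samples.eta_mean)
    return DicReport(dbar=dbar, pd=dbar - d_hat, dataset_label=dataset_label)


def compare_models(
    reports: Mapping[str, DicReport],
    threshold: float = 10.0,
) -> pd.DataFrame:
    """Rank models by DIC with pairwise decisive-superiority verdicts.

    A model is flagged "considerably superior" to another when its DIC is
    lower by strictly more than ``threshold`` (default 10).  All reports must
    come from the same dataset.
    """
    if len(reports) < 2:
        raise ValueError("need at least two DIC reports to compare")
    labels = {r.dataset_label for r in reports.values() if r.dataset_label is not None}
    if len(labels) > 1:
        raise ValueError(f"DIC reports come from different datasets: {sorted(labels)}")
    order = sorted(reports, key=lambda k: reports[k].dic)
    rows = []
    best = order[0]
    for name in order:
        r = reports[name]
        beats = [
            other
            for other in reports
            if other != name and reports[other].dic - r.dic > threshold
        ]
        rows.append(
            {
                "model": name,
                "dbar": r.dbar,
                "pd": r.pd,
                "dic": r.dic,
                "delta_dic_vs_best": r.dic - reports[best].dic,
                "considerably_superior_to": ",".join(sorted(beats)),
            }
        )
    return pd.DataFrame(rows).set_index("model")


@dataclass
class FitReport:
    """The full reporting bundle for one fitted model."""

    spec: ModelSpec
    summary: pd.DataFrame  # summarize_posterior output
    odds_ratios: pd.DataFrame  # OR and percent change per covariate coefficient
    heterogeneity: pd.DataFrame  # share of positive effects per random covariate
    dic: DicReport
    convergence: pd.DataFrame  # MC-error rule per parameter
    acceptance: dict[str, float]

    def to_csv(self, path) -> None:
        self.summary.join(self.odds_ratios, how="left").to_csv(path)

    def format_text(self) -> str:
        """Mean (SD) table with 90/95% significance stars and a DIC footer."""
        lines = [f"model family: {self.spec.family}", ""]
        width = max(len(i) for i in self.summary.index) + 2
        for name, row in self.summary.iterrows():
            stars = "**" if row["significant_95"] else ("*" if row["significant_90"] else "")
            lines.append(f"{name:<{width}s} {row['mean']:8.3f} ({row['sd']:.3f}){stars}")
        for name, row in self.heterogeneity.iterrows():
            lines.append(
                f"{name + ' share positive':<{width}s} {row['percent_positive']:8.1f}%"
            )
        lines += [
            "",
            f"{'Dbar':<{width}s} {self.dic.dbar:8.1f}",
            f"{'pD':<{width}s} {self.dic.pd:8.1f}",
            f"{'DIC':<{width}s} {self.dic.dic:8.1f}",
            "",
            "*  significant at the 90% credibility level",
            "** significant at the 95% credibility level",
        ]
        return "\n".join(lines)


def build_report(
    samples: PosteriorSamples,
    dataset: CrashDataset,
    dataset_label: str | None = None,
) -> FitReport:
    """Assemble the posterior summary, odds ratios, heterogeneity shares,
    DIC and convergence flags for one fit."""
    spec = samples.spec
    summary = summarize_posterior(samples)

    or_rows = {}
    for name in summary.index:
        if name.startswith(("beta[", "beta_bar[")):
            orv, pct = odds_ratio(summary.loc[name, "mean"])
            or_rows[name] = {"odds_ratio": float(orv), "percent_change": float(pct)}
    odds = pd.DataFrame.from_dict(or_rows, orient="index")

    het_rows = {}
    for c in spec.random_covariates:
        bb = float(samples.draws[f"beta_bar[{c}]"].mean())
        sg = float(samples.draws[f"sigma[{c}]"].mean())
        het_rows[c] = {
            "beta_bar": bb,
            "sigma": sg,
            "percent_positive": heterogeneity_share(bb, sg),
        }
    het = pd.DataFrame.from_dict(het_rows, orient="index")

    dic = compute_dic(samples, dataset, spec, dataset_label=dataset_label)
    conv = pd.DataFrame.from_dict(convergence_check(samples), orient="index")
    return FitReport(
        spec=spec,
        summary=summary,
        odds_ratios=odds,
        heterogeneity=het,
        dic=dic,
        convergence=conv,
        acceptance=dict(samples.acceptance),
    )


def plot_traces(
    samples: PosteriorSamples,
    parameters: Sequence[str] | None = None,
    path=None,
):
    """History (trace) plots of the post burn-in chains, one panel per parameter."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(parameters) if parameters is not None else samples.parameter_names
    fig, axes = plt.subplots(len(names), 1, figsize=(8, 2.2 * len(names)), squeeze=False)
    for ax, name in zip(axes[:, 0], names):
        ax.plot(samples.draws[name], lw=0.3)
        ax.set_ylabel(name)
    axes[-1, 0].set_xlabel("kept iteration")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
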