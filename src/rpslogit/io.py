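"""File plumbing: crash-table CSV, adjacency text files, configs, manifests.

All tabular artifacts are plain CSV with documented headers; adjacency is a
whitespace-delimited edge list (one ``m n`` pair per line) or a ``chain: M``
shorthand.  Every run directory gets a JSON manifest with the seed, config
and package version so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import CrashDataset, ModelSpec
from .sampler import McmcConfig, PosteriorSamples, PriorConfig
from .spatial import SectionNetwork, build_adjacency, chain_network

__all__ = [
    "read_crash_csv",
    "write_crash_csv",
    "read_adjacency",
    "write_adjacency",
    "load_config",
    "write_manifest",
    "write_draws_csv",
]

OUTCOME_COLUMN = "outcome"
SECTION_COLUMN = "section_id"


def read_crash_csv(path, covariates: list[str] | None = None) -> CrashDataset:
    """Load a crash-level table.

    Required columns: ``outcome`` (0/1 fatality flag) and ``section_id``;
    all remaining columns (or the explicit ``covariates`` subset) become
    covariates.  Validation (binary outcome, positive EMS minutes, one-hot
    indicator groups) happens in :class:`CrashDataset`.
    """
    df = pd.read_csv(path)
    for col in (OUTCOME_COLUMN, SECTION_COLUMN):
        if col not in df.columns:
            raise ValueError(f"crash CSV {path} is missing required column {col!r}")
    if covariates is None:
        covariates = [c for c in df.columns if c not in (OUTCOME_COLUMN, SECTION_COLUMN)]
    else:
        missing = [c for c in covariates if c not in df.columns]
        if missing:
            raise ValueError(f"crash CSV {path} is missing covariate columns {missing}")
    return CrashDataset(
        outcome=df[OUTCOME_COLUMN].to_numpy(),
        covariates=df[covariates].copy(),
        section_id=df[SECTION_COLUMN].astype(str).to_numpy(dtype=object),
    )


def write_crash_csv(dataset: CrashDataset, path) -> None:
    df = dataset.covariates.copy()
    df.insert(0, OUTCOME_COLUMN, dataset.outcome)
    df.insert(1, SECTION_COLUMN, dataset.section_id)
    df.to_csv(path, index=False)


def read_adjacency(path) -> SectionNetwork:
    """Read a section network from an edge-list file or ``chain: M`` line.

    Edge-list format: one whitespace-delimited ``m n`` label pair per line
    ('#' comments allowed); every label that appears becomes a section.  A
    single line ``chain: M`` declares a linear freeway of M sections.
    """
    text = Path(path).read_text()
    lines = [ln.strip() for ln in text.splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if len(lines) == 1 and lines[0].lower().replace(" ", "").startswith("chain:"):
        m = int(lines[0].split(":", 1)[1])
        return chain_network(m)
    labels: list[str] = []
    seen = set()
    edges = []
    for ln in lines:
        parts = ln.split()
        if len(parts) != 2:
            raise ValueError(f"malformed adjacency line {ln!r}: expected 'm n'")
        for p in parts:
            if p not in seen:
                seen.add(p)
                labels.append(p)
        edges.append((parts[0], parts[1]))
    return build_adjacency((labels, edges))


def write_adjacency(network: SectionNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("# section adjacency edge list: one 'm n' pair per line\n")
        ids = network.section_ids
        w = np.asarray(network.adjacency)
        for i in range(network.M):
            for j in range(i + 1, network.M):
                if w[i, j]:
                    fh.write(f"{ids[i]} {ids[j]}\n")


def load_config(path) -> dict[str, Any]:
    """Load a YAML/JSON run config with prior/mcmc/model blocks.

    Recognized blocks (all optional): ``model`` (family, covariates,
    random_set), ``priors`` (PriorConfig fields), ``mcmc`` (McmcConfig
    fields).  Returns parsed objects under those keys.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out: dict[str, Any] = {}
    if "model" in raw:
        m = dict(raw["model"])
        if "random_set" in m:
            m["random_set"] = frozenset(m["random_set"])
        if "covariates" in m:
            m["covariates"] = tuple(m["covariates"])
        out["model"] = ModelSpec(**m)
    if "priors" in raw:
        p = dict(raw["priors"])
        for key in ("rho_bounds", "scale_bounds"):
            if key in p:
                p[key] = tuple(p[key])
        out["priors"] = PriorConfig(**p)
    if "mcmc" in raw:
        m = dict(raw["mcmc"])
        if "fixed" in m:
            m["fixed"] = tuple(m["fixed"])
        out["mcmc"] = McmcConfig(**m)
    for key in raw:
        if key not in ("model", "priors", "mcmc"):
            out[key] = raw[key]
    return out


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (frozenset, set, tuple)):
        return [_jsonable(v) for v in sorted(obj) if True] if isinstance(obj, (frozenset, set)) else [
            _jsonable(v) for v in obj
        ]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    return obj


def write_manifest(path, *, seed: int, config: Mapping[str, Any],
                   extra: Mapping[str, Any] | None = None) -> None:
    """Write the reproducibility manifest: seed, config hash, full config,
    package version, plus any run diagnostics passed in ``extra``."""
    payload = {
        "package": "rpslogit",
        "version": __version__,
        "seed": int(seed),
        "config": _jsonable(dict(config)),
    }
    payload["config_hash"] = hashlib.sha256(
        json.dumps(payload["config"], sort_keys=True).encode()
    ).hexdigest()[:16]
    if extra:
        payload.update(_jsonable(dict(extra)))
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_draws_csv(samples: PosteriorSamples, path) -> None:
    """Export scalar-parameter draws as CSV, one column per parameter."""
    pd.DataFrame(samples.draws).to_csv(path, index=False)
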