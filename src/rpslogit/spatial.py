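"""Areal support for the spatial crash-severity models.

A freeway is cut into homogeneous sections; crashes in nearby sections share
unobserved conditions (pavement, enforcement, weather exposure), which the
models absorb through a section-level Gaussian effect ``phi`` with a Leroux
conditional-autoregressive (CAR) prior.  This module builds and validates the
section adjacency structure, evaluates the Leroux prior (both its per-section
conditional law and the joint log-density), and segments raw roadway geometry
into homogeneous sections.

The Leroux CAR prior for section ``m`` given all other sections is

    phi_m | phi_-m ~ N( rho * sum_n w_mn phi_n / (1 - rho + rho * sum_n w_mn),
                        delta^2 / (1 - rho + rho * sum_n w_mn) )

with ``w_mn = 1`` when sections m and n share a common end and 0 otherwise.
``rho`` in [0, 1] interpolates between independent effects (rho = 0) and the
intrinsic CAR (rho = 1); ``delta`` scales the conditional spread.  For
``rho < 1`` the implied joint distribution is a proper multivariate normal
with precision ``Q = (rho * (D - W) + (1 - rho) * I) / delta^2`` where ``D``
is the diagonal matrix of neighbor counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "SectionNetwork",
    "LerouxParams",
    "GeometrySegment",
    "build_adjacency",
    "chain_network",
    "leroux_conditional",
    "leroux_precision",
    "leroux_joint_logdensity",
    "segment_by_homogeneity",
    "assign_sections",
]


@dataclass(frozen=True)
class LerouxParams:
    """Hyper-parameters of the Leroux CAR prior.

    rho measures the strength of spatial correlation (0 = none, 1 = intrinsic
    CAR); delta (> 0) sets the conditional standard deviation scale.
    """

    rho: float
    delta: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must lie in [0, 1], got {self.rho}")
        if not self.delta > 0.0:
            raise ValueError(f"delta must be positive, got {self.delta}")


@dataclass
class SectionNetwork:
    """Symmetric binary first-order adjacency over freeway sections."""

    section_ids: list[str]
    adjacency: np.ndarray  # dense (M, M) uint8; M stays small (hundreds)

    def __post_init__(self) -> None:
        W = np.asarray(self.adjacency)
        M = len(self.section_ids)
        if len(set(self.section_ids)) != M:
            raise ValueError("duplicate section labels")
        if W.shape != (M, M):
            raise ValueError(f"adjacency shape {W.shape} does not match {M} sections")
        if not np.array_equal(W, W.T):
            raise ValueError("adjacency matrix must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("adjacency diagonal must be zero (no self-edges)")
        if not np.isin(W, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = W.astype(np.uint8)
        self._index = {s: i for i, s in enumerate(self.section_ids)}

    @property
    def M(self) -> int:
        return len(self.section_ids)

    @property
    def neighbor_counts(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def index_of(self, section_id: str | Sequence[str]) -> np.ndarray | int:
        if isinstance(section_id, str):
            return self._index[section_id]
        try:
            return np.array([self._index[s] for s in section_id], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"unknown section id {exc.args[0]!r}") from exc

    def sparse_w(self) -> sp.csr_matrix:
        return sp.csr_matrix(self.adjacency.astype(np.float64))

    def coloring(self) -> list[np.ndarray]:
        """Partition sections into classes with no within-class edges.

        Sections in the same class are conditionally independent given the
        rest, so a Metropolis sweep can update each class as one vectorized
        block.  A chain yields the even/odd two-coloring.
        """
        import networkx as nx

        g = nx.from_numpy_array(self.adjacency)
        colors = nx.coloring.greedy_color(g, strategy="largest_first")
        n_colors = max(colors.values(), default=0) + 1
        return [
            np.array([v for v, c in colors.items() if c == k], dtype=np.int64)
            for k in range(n_colors)
        ]


def chain_network(M: int, prefix: str = "S") -> SectionNetwork:
    """Chain of ``M`` sections: section k adjacent to k-1 and k+1 only."""
    labels = [f"{prefix}{k + 1}" for k in range(M)]
    return build_adjacency(labels)


def build_adjacency(
    section_order_or_edges: Sequence[str] | tuple[Sequence[str], Iterable[tuple[str, str]]],
) -> SectionNetwork:
    """Build a :class:`SectionNetwork` from a chain order or an edge list.

    Parameters
    ----------
    section_order_or_edges
        Either an ordered sequence of section labels — interpreted as a linear
        freeway where consecutive sections share a common end (a chain, M-1
        edges) — or a ``(labels, edges)`` tuple with an explicit list of
        undirected ``(m, n)`` label pairs for non-linear networks.
    """
    if (
        isinstance(section_order_or_edges, tuple)
        and len(section_order_or_edges) == 2
        and not isinstance(section_order_or_edges[0], str)
        and not isinstance(section_order_or_edges[1], str)
        and all(isinstance(e, (tuple, list)) for e in section_order_or_edges[1])
    ):
        labels, edges = section_order_or_edges
        labels = [str(s) for s in labels]
    else:
        labels = [str(s) for s in section_order_or_edges]
        edges = list(zip(labels[:-1], labels[1:]))

    if len(set(labels)) != len(labels):
        dupes = sorted({s for s in labels if labels.count(s) > 1})
        raise ValueError(f"duplicate section labels: {dupes}")
    index = {s: i for i, s in enumerate(labels)}
    M = len(labels)
    W = np.zeros((M, M), dtype=np.uint8)
    for m, n in edges:
        m, n = str(m), str(n)
        if m not in index or n not in index:
            missing = m if m not in index else n
            raise ValueError(f"edge references unknown section label {missing!r}")
        if m == n:
            raise ValueError(f"self-edge on section {m!r} is not allowed")
        W[index[m], index[n]] = 1
        W[index[n], index[m]] = 1
    return SectionNetwork(section_ids=labels, adjacency=W)


def _conditional_factor(params: LerouxParams, n_neighbors: np.ndarray | float) -> np.ndarray:
    # 1 - rho + rho * sum_n w_mn: shared denominator of the conditional mean/variance
    return 1.0 - params.rho + params.rho * np.asarray(n_neighbors, dtype=np.float64)


def leroux_conditional(
    m: int,
    phi_others: np.ndarray,
    params: LerouxParams,
    network: SectionNetwork,
) -> tuple[float, float]:
    """Conditional law of ``phi_m`` given every other section's effect.

    ``phi_others`` is the full length-M vector of effects; the m-th entry is
    ignored.  Returns ``(mean, variance)`` of the Gaussian full conditional:
    mean = rho * S / (1 - rho + rho * d_m), variance = delta^2 / (same), with
    S the sum of neighbor effects and d_m the neighbor count.
    """
    phi = np.asarray(phi_others, dtype=np.float64)
    if phi.shape != (network.M,):
        raise ValueError(f"phi_others must have length M={network.M}")
    w_m = network.adjacency[m].astype(np.float64)
    denom = float(_conditional_factor(params, w_m.sum()))
    mean = params.rho * float(w_m @ phi) / denom
    variance = params.delta**2 / denom
    return mean, variance


def leroux_precision(params: LerouxParams, network: SectionNetwork) -> np.ndarray:
    """Joint precision Q = (rho (D - W) + (1 - rho) I) / delta^2 (dense)."""
    W = network.adjacency.astype(np.float64)
    D = np.diag(network.neighbor_counts.astype(np.float64))
    M = network.M
    return (params.rho * (D - W) + (1.0 - params.rho) * np.eye(M)) / params.delta**2


def leroux_joint_logdensity(
    phi_vector: np.ndarray,
    params: LerouxParams,
    network: SectionNetwork,
) -> float:
    """Log-density of the joint (proper, rho < 1) Leroux CAR distribution.

    Equals the zero-mean multivariate normal log-density with precision Q.
    rho = 1 gives an improper joint (the intrinsic CAR) and is rejected here;
    the sampler handles that boundary through the conditional law only.
    """
    if params.rho >= 1.0:
        raise ValueError(
            "rho = 1 yields an improper joint (intrinsic CAR); "
            "the joint log-density requires rho < 1"
        )
    phi = np.asarray(phi_vector, dtype=np.float64)
    M = network.M
    if phi.shape != (M,):
        raise ValueError(f"phi must have length M={M}")
    d = network.neighbor_counts.astype(np.float64)
    # eigenvalues of rho (D - W) + (1 - rho) I are rho * lam_k + (1 - rho)
    # with lam_k the (nonnegative) graph-Laplacian eigenvalues
    lam = np.linalg.eigvalsh(np.diag(d) - network.adjacency.astype(np.float64))
    logdet_q = float(np.sum(np.log(params.rho * lam + (1.0 - params.rho)))) - 2.0 * M * np.log(
        params.delta
    )
    Q = leroux_precision(params, network)
    quad = float(phi @ Q @ phi)
    return -0.5 * M * np.log(2.0 * np.pi) + 0.5 * logdet_q - 0.5 * quad


@dataclass(frozen=True)
class GeometrySegment:
    """A homogeneous stretch of freeway.

    curvature is in units of 0.1/km (inverse curve radius); grade in percent.
    """

    start_km: float
    end_km: float
    curvature: float
    grade: float

    def __post_init__(self) -> None:
        if not self.end_km > self.start_km:
            raise ValueError("segment must have end_km > start_km")

    @property
    def length_km(self) -> float:
        return self.end_km - self.start_km


def segment_by_homogeneity(
    geometry_table: pd.DataFrame,
    curvature_tol: float = 0.0,
    grade_tol: float = 0.0,
) -> list[GeometrySegment]:
    """Merge consecutive geometry intervals into homogeneous sections.

    The input table has one row per raw interval with columns ``start_km``,
    ``end_km``, ``curvature``, ``grade``, ordered along the freeway and tiling
    it without gaps or overlap.  Consecutive intervals are merged while both
    the curvature and grade changes stay within the given tolerances
    (default 0: exact homogeneity).  Merged segment attributes are
    length-weighted means of their member intervals.
    """
    required = {"start_km", "end_km", "curvature", "grade"}
    missing = required - set(geometry_table.columns)
    if missing:
        raise ValueError(f"geometry table missing columns {sorted(missing)}")
    g = geometry_table.reset_index(drop=True)
    start = g["start_km"].to_numpy(float)
    end = g["end_km"].to_numpy(float)
    if np.any(end <= start):
        raise ValueError("each geometry interval needs end_km > start_km")
    if np.any(np.diff(start) <= 0) or not np.allclose(start[1:], end[:-1]):
        raise ValueError("geometry intervals must be ordered and tile without gaps/overlap")

    curv = g["curvature"].to_numpy(float)
    grade = g["grade"].to_numpy(float)
    segments: list[GeometrySegment] = []
    i = 0
    n = len(g)
    while i < n:
        j = i
        while (
            j + 1 < n
            and abs(curv[j + 1] - curv[j]) <= curvature_tol
            and abs(grade[j + 1] - grade[j]) <= grade_tol
        ):
            j += 1
        length = end[i : j + 1] - start[i : j + 1]
        segments.append(
            GeometrySegment(
                start_km=float(start[i]),
                end_km=float(end[j]),
                curvature=float(np.average(curv[i : j + 1], weights=length)),
                grade=float(np.average(grade[i : j + 1], weights=length)),
            )
        )
        i = j + 1
    return segments


def assign_sections(km_markers: np.ndarray, segments: Sequence[GeometrySegment]) -> np.ndarray:
    """Map crash km markers to section indices via half-open [start, end) tiling.

    The final segment's end is treated as closed so the last km of the freeway
    is assignable.
    """
    starts = np.array([s.start_km for s in segments])
    ends = np.array([s.end_km for s in segments])
    km = np.asarray(km_markers, dtype=np.float64)
    idx = np.searchsorted(starts, km, side="right") - 1
    bad = (km < starts[0]) | (km > ends[-1])
    if np.any(bad):
        raise ValueError(f"{int(bad.sum())} km markers fall outside the segmented range")
    idx = np.clip(idx, 0, len(segments) - 1)
    return idx.astype(np.int64)
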