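"""Section network construction and the Leroux CAR prior.

The key oracle here is brute-force Gaussian conditioning: the per-section
conditional law returned by ``leroux_conditional`` must coincide with the
conditional derived by partitioning the joint precision
Q = (rho (D - W) + (1 - rho) I) / delta^2.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rpslogit.spatial import (
    GeometrySegment,
    LerouxParams,
    SectionNetwork,
    assign_sections,
    build_adjacency,
    chain_network,
    leroux_conditional,
    leroux_joint_logdensity,
    leroux_precision,
    segment_by_homogeneity,
)


class TestBuildAdjacency:
    def test_single_section_has_no_neighbors(self):
        net = build_adjacency(["only"])
        assert net.M == 1
        assert net.n_edges == 0
        assert net.adjacency.sum() == 0

    def test_chain_of_three(self):
        net = build_adjacency(["a", "b", "c"])
        w = net.adjacency
        assert w[0, 1] == w[1, 2] == 1
        assert w[0, 2] == 0
        assert np.array_equal(w, w.T)

    def test_study_scale_chain(self):
        # a single freeway segmented into 154 homogeneous sections forms a
        # chain: 153 shared ends, interior sections with exactly 2 neighbors
        net = chain_network(154)
        assert net.M == 154
        assert net.n_edges == 153
        assert net.neighbor_counts.max() == 2
        assert (net.neighbor_counts == 1).sum() == 2  # the two termini

    def test_explicit_edge_list(self):
        net = build_adjacency((["a", "b", "c"], [("a", "c")]))
        assert net.n_edges == 1
        assert net.adjacency[0, 2] == 1 and net.adjacency[0, 1] == 0

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_adjacency(["a", "b", "a"])

    def test_self_edge_rejected(self):
        with pytest.raises(ValueError, match="self-edge"):
            build_adjacency((["a", "b"], [("a", "a")]))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown section label"):
            build_adjacency((["a", "b"], [("a", "zzz")]))

    def test_asymmetric_matrix_rejected(self):
        w = np.zeros((2, 2), dtype=np.uint8)
        w[0, 1] = 1
        with pytest.raises(ValueError, match="symmetric"):
            SectionNetwork(section_ids=["a", "b"], adjacency=w)


def _brute_force_conditional(m, phi, params, network):
    """Oracle: condition the joint Gaussian N(0, Q^{-1}) on phi_{-m}."""
    Q = leroux_precision(params, network)
    others = [i for i in range(network.M) if i != m]
    var = 1.0 / Q[m, m]
    mean = -var * float(Q[m, others] @ phi[others])
    return mean, var


class TestLerouxConditional:
    def test_independence_limit(self, chain3):
        params = LerouxParams(rho=0.0, delta=0.7)
        mean, var = leroux_conditional(1, np.array([3.0, 0.0, -2.0]), params, chain3)
        assert mean == 0.0
        assert var == pytest.approx(0.49)

    def test_intrinsic_limit_averages_neighbors(self, chain3):
        params = LerouxParams(rho=1.0, delta=0.9)
        a, b = 1.4, -0.6
        mean, var = leroux_conditional(1, np.array([a, 0.0, b]), params, chain3)
        assert mean == pytest.approx((a + b) / 2.0)
        assert var == pytest.approx(0.81 / 2.0)

    def test_middle_section_matches_partitioned_joint(self, chain3):
        # hyper-parameters at the published spatial-model posterior means
        params = LerouxParams(rho=0.62, delta=0.74)
        phi = np.array([0.8, 0.1, -1.1])
        mean, var = leroux_conditional(1, phi, params, chain3)
        bmean, bvar = _brute_force_conditional(1, phi, params, chain3)
        assert mean == pytest.approx(bmean, rel=1e-12)
        assert var == pytest.approx(bvar, rel=1e-12)

    def test_matches_partitioned_joint_on_random_chains(self):
        # oracle equivalence across all chain sizes up to 6 and 100 random
        # hyper-parameter/effect configurations
        rng = np.random.default_rng(42)
        worst = 0.0
        for trial in range(100):
            m_sections = int(rng.integers(2, 7))
            net = chain_network(m_sections)
            params = LerouxParams(
                rho=float(rng.uniform(0, 0.999)), delta=float(rng.uniform(0.05, 3.0))
            )
            phi = rng.normal(0, 2, m_sections)
            m = int(rng.integers(0, m_sections))
            mean, var = leroux_conditional(m, phi, params, net)
            bmean, bvar = _brute_force_conditional(m, phi, params, net)
            worst = max(
                worst,
                abs(mean - bmean) / max(abs(bmean), 1e-12),
                abs(var - bvar) / bvar,
            )
        assert worst <= 1e-10

    def test_variance_nonincreasing_in_neighbor_count(self):
        params = LerouxParams(rho=0.7, delta=1.3)
        variances = []
        for n_nbr in range(5):
            denom = 1 - params.rho + params.rho * n_nbr
            variances.append(params.delta**2 / denom)
        assert all(a >= b for a, b in zip(variances, variances[1:]))

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            LerouxParams(rho=1.2, delta=1.0)
        with pytest.raises(ValueError):
            LerouxParams(rho=0.5, delta=0.0)


class TestLerouxJoint:
    def test_rho_zero_is_iid_normal(self, chain3):
        params = LerouxParams(rho=0.0, delta=0.8)
        phi = np.array([0.3, -0.9, 1.7])
        expected = stats.norm.logpdf(phi, scale=0.8).sum()
        assert leroux_joint_logdensity(phi, params, chain3) == pytest.approx(expected)

    def test_zero_vector_value(self, chain3):
        params = LerouxParams(rho=0.4, delta=1.1)
        Q = leroux_precision(params, chain3)
        expected = -1.5 * np.log(2 * np.pi) + 0.5 * np.linalg.slogdet(Q)[1]
        assert leroux_joint_logdensity(np.zeros(3), params, chain3) == pytest.approx(expected)

    def test_matches_dense_multivariate_normal(self):
        net = chain_network(4)
        params = LerouxParams(rho=0.5, delta=1.0)
        rng = np.random.default_rng(7)
        phi = rng.normal(size=4)
        cov = np.linalg.inv(leroux_precision(params, net))
        expected = stats.multivariate_normal(mean=np.zeros(4), cov=cov).logpdf(phi)
        assert leroux_joint_logdensity(phi, params, net) == pytest.approx(expected, rel=1e-10)

    def test_intrinsic_limit_rejected(self, chain3):
        with pytest.raises(ValueError, match="improper"):
            leroux_joint_logdensity(np.zeros(3), LerouxParams(rho=1.0, delta=1.0), chain3)

    def test_precision_positive_definite(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            net = chain_network(int(rng.integers(2, 7)))
            params = LerouxParams(
                rho=float(rng.uniform(0, 0.9999)), delta=float(rng.uniform(0.05, 5))
            )
            Q = leroux_precision(params, net)
            assert np.allclose(Q, Q.T)
            assert np.linalg.eigvalsh(Q).min() > 0


class TestSegmentation:
    @staticmethod
    def _table(curv, grade, width=0.5):
        n = len(curv)
        start = np.arange(n) * width
        return pd.DataFrame(
            {"start_km": start, "end_km": start + width, "curvature": curv, "grade": grade}
        )

    def test_homogeneous_geometry_is_one_segment(self):
        t = self._table([1.5] * 8, [0.7] * 8)
        segs = segment_by_homogeneity(t)
        assert len(segs) == 1
        assert segs[0].start_km == 0.0 and segs[0].end_km == 4.0

    def test_single_grade_step_splits_at_change_point(self):
        t = self._table([1.0] * 6, [0.5] * 3 + [2.0] * 3)
        segs = segment_by_homogeneity(t)
        assert len(segs) == 2
        assert segs[0].end_km == pytest.approx(1.5)
        assert segs[1].start_km == pytest.approx(1.5)

    def test_recovers_planted_sections_at_study_scale(self):
        # 60 km of synthetic geometry with 153 planted change points; zero
        # tolerance must recover exactly the 154 planted sections
        rng = np.random.default_rng(9)
        n_sections = 154
        lengths = rng.uniform(0.2, 0.6, n_sections)
        curv = rng.uniform(0, 4.35, n_sections)
        grade = rng.uniform(0, 2.91, n_sections)
        # ensure consecutive sections genuinely differ
        for k in range(1, n_sections):
            if curv[k] == curv[k - 1] and grade[k] == grade[k - 1]:
                grade[k] += 0.1
        rows = []
        pos = 0.0
        for k in range(n_sections):
            n_sub = int(rng.integers(1, 4))
            for s in range(n_sub):
                w = lengths[k] / n_sub
                rows.append((pos, pos + w, curv[k], grade[k]))
                pos += w
        t = pd.DataFrame(rows, columns=["start_km", "end_km", "curvature", "grade"])
        segs = segment_by_homogeneity(t)
        assert len(segs) == n_sections
        assert segs[0].start_km == 0.0
        assert segs[-1].end_km == pytest.approx(pos)
        # output tiles the input range
        for a, b in zip(segs, segs[1:]):
            assert a.end_km == pytest.approx(b.start_km)

    def test_unordered_input_rejected(self):
        t = pd.DataFrame(
            {
                "start_km": [1.0, 0.0],
                "end_km": [2.0, 1.0],
                "curvature": [1, 1],
                "grade": [1, 1],
            }
        )
        with pytest.raises(ValueError, match="ordered"):
            segment_by_homogeneity(t)

    def test_half_open_assignment(self):
        segs = [
            GeometrySegment(0.0, 1.0, 1.0, 0.5),
            GeometrySegment(1.0, 2.5, 2.0, 0.5),
        ]
        idx = assign_sections(np.array([0.0, 0.99, 1.0, 2.5]), segs)
        assert idx.tolist() == [0, 0, 1, 1]
        with pytest.raises(ValueError, match="outside"):
            assign_sections(np.array([3.0]), segs)
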