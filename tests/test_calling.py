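"""Coverage filtering, DMC thresholds, chain rules and caller invariants."""

import numpy as np
import pytest
from scipy.stats import poisson

from dmrscape.calling import (
    CallerConfig,
    MethylMatrix,
    NoAnalyzableCpGsError,
    build_matrix,
    call_dmcs,
    call_dmrs,
    group_means,
)
from dmrscape.io import CpGRecord
from dmrscape.simulate import SimulationConfig, generate_truth, simulate_study


def _records(sample, triplets):
    return [CpGRecord("chr1", pos, m, u, sample) for pos, m, u in triplets]


def _matrix(positions, fractions, sample_ids, coverage=20):
    """Direct matrix with exact fractions (coverage uniform)."""
    fractions = np.asarray(fractions, dtype=float)
    return MethylMatrix(
        chroms=np.array(["chr1"] * len(positions), dtype=object),
        positions=np.asarray(positions, dtype=np.int64),
        sample_ids=list(sample_ids),
        fractions=fractions,
        coverages=np.full(fractions.shape, coverage, dtype=np.int64),
    )


class TestBuildMatrix:
    def test_all_sample_coverage_filter(self):
        samples = {
            "a": _records("a", [(100, 5, 5), (200, 5, 5)]),
            "b": _records("b", [(100, 5, 5), (200, 2, 2)]),  # 4x at 200
        }
        m = build_matrix(samples, CallerConfig(min_coverage=5))
        assert list(m.positions) == [100]  # 10x/10x kept, 10x/4x dropped

    def test_empty_intersection_raises(self):
        samples = {
            "a": _records("a", [(100, 10, 10)]),
            "b": _records("b", [(200, 10, 10)]),
        }
        with pytest.raises(NoAnalyzableCpGsError):
            build_matrix(samples)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            build_matrix({"a": _records("a", [(100, 5, 5)])})

    def test_retention_matches_poisson_product(self):
        """With independent Poisson coverage, the retained fraction equals
        the product of per-sample P(cov >= 5) to within 1%."""
        config = SimulationConfig(
            n_cpgs=20_000, coverage_lambda=8.0, genotypes=(("control", 2), ("tumor", 2)),
            seed=5,
        )
        truth = generate_truth(config)
        study = simulate_study(truth)
        samples = {**study["control"], **study["tumor"]}
        m = build_matrix(samples, CallerConfig())
        expected = poisson.sf(4, 8.0) ** 4
        assert m.n_cpgs / len(truth.positions) == pytest.approx(expected, abs=0.01)


class TestGroupMeans:
    def test_mean_and_single_sample_identity(self):
        m = _matrix([10, 20], [[0.4, 0.6, 0.1], [0.2, 0.8, 0.9]], ["s1", "s2", "s3"])
        mean_a, mean_b = group_means(m, ["s1", "s2"], ["s3"])
        assert mean_a == pytest.approx([0.5, 0.5])
        assert mean_b == pytest.approx([0.1, 0.9])  # equals the lone sample

    def test_matches_brute_force_row_means(self):
        rng = np.random.default_rng(6)
        frac = rng.random((100, 4))
        m = _matrix(range(0, 1000, 10), frac, ["a1", "a2", "b1", "b2"])
        mean_a, mean_b = group_means(m, ["a1", "a2"], ["b1", "b2"])
        for i in range(100):
            assert mean_a[i] == pytest.approx((frac[i, 0] + frac[i, 1]) / 2)
            assert mean_b[i] == pytest.approx((frac[i, 2] + frac[i, 3]) / 2)

    def test_unknown_sample_and_overlap_rejected(self):
        m = _matrix([10], [[0.1, 0.2]], ["s1", "s2"])
        with pytest.raises(KeyError):
            group_means(m, ["s1"], ["nope"])
        with pytest.raises(ValueError):
            group_means(m, ["s1"], ["s1"])


class TestCallDmcs:
    @pytest.mark.parametrize(
        "mean_a, mean_b, expected_dir",
        [
            (0.80, 0.45, "hypo"),   # diff -0.35
            (0.80, 0.55, None),     # |diff| 0.25 below threshold
            (0.80, 0.50, "hypo"),   # exactly -0.30: inclusive threshold
            (0.10, 0.40, "hyper"),  # exactly +0.30
        ],
    )
    def test_threshold_is_inclusive(self, mean_a, mean_b, expected_dir):
        m = _matrix([10], [[mean_a, mean_b]], ["a", "b"])
        dmcs = call_dmcs(m, ["a"], ["b"])
        if expected_dir is None:
            assert dmcs == []
        else:
            assert dmcs[0].direction == expected_dir
            assert dmcs[0].diff == pytest.approx(mean_b - mean_a)

    def test_lowering_threshold_never_loses_dmcs(self):
        rng = np.random.default_rng(7)
        m = _matrix(range(0, 5000, 10), rng.random((500, 4)), ["a1", "a2", "b1", "b2"])
        counts = [
            len(call_dmcs(m, ["a1", "a2"], ["b1", "b2"], CallerConfig(delta_threshold=t)))
            for t in (0.5, 0.4, 0.3, 0.2, 0.1)
        ]
        assert counts == sorted(counts)


def _separable_matrix(positions, direction="hypo"):
    """Per-CpG fractions with a clean 0.4 group shift at every position."""
    n = len(positions)
    rng = np.random.default_rng(8)
    level = 0.85 if direction == "hypo" else 0.15  # headroom for the shift
    base = level + rng.uniform(-0.03, 0.03, size=(n, 2))
    shift = -0.4 if direction == "hypo" else 0.4
    tumor = base + shift + rng.uniform(-0.02, 0.02, size=(n, 2))
    frac = np.clip(np.hstack([base, tumor]), 0, 1)
    return _matrix(positions, frac, ["a1", "a2", "b1", "b2"])


class TestCallDmrs:
    GROUPS = (["a1", "a2"], ["b1", "b2"])

    def test_three_dmcs_within_gap_chain(self):
        m = _separable_matrix([100, 130, 170])
        dmcs = call_dmcs(m, *self.GROUPS)
        dmrs = call_dmrs(dmcs, m, *self.GROUPS)
        assert len(dmrs) == 1
        d = dmrs[0]
        assert (d.interval.start, d.interval.end, d.n_cpgs) == (100, 171, 3)
        assert d.direction == "hypo" and d.p_mwu < 0.05

    def test_gap_over_fifty_breaks_chain(self):
        m = _separable_matrix([100, 130, 195])  # gap 65
        dmcs = call_dmcs(m, *self.GROUPS)
        assert len(dmcs) == 3
        assert call_dmrs(dmcs, m, *self.GROUPS) == []

    def test_direction_change_breaks_chain(self):
        hypo = _separable_matrix([100, 130], "hypo")
        hyper = _separable_matrix([160, 190], "hyper")
        frac = np.vstack([hypo.fractions, hyper.fractions])
        m = _matrix([100, 130, 160, 190], frac, ["a1", "a2", "b1", "b2"])
        dmcs = call_dmcs(m, *self.GROUPS)
        assert {d.direction for d in dmcs} == {"hypo", "hyper"}
        assert call_dmrs(dmcs, m, *self.GROUPS) == []  # two runs of 2 CpGs

    def test_intervening_non_dmc_does_not_break_by_default(self):
        m = _separable_matrix([100, 120, 140, 160])
        # flatten CpG at 140 to a non-DMC while keeping it retained
        m.fractions[2] = [0.85, 0.85, 0.84, 0.86]
        dmcs = call_dmcs(m, *self.GROUPS)
        assert len(dmcs) == 3
        relaxed = call_dmrs(dmcs, m, *self.GROUPS)
        assert len(relaxed) == 1 and relaxed[0].n_cpgs == 3
        strict = call_dmrs(
            dmcs, m, *self.GROUPS, CallerConfig(strict_consecutive=True)
        )
        assert strict == []  # retained CpG at 140 splits the run

    def test_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(9)
        m = _matrix(range(0, 3000, 15), rng.random((200, 4)), ["a1", "a2", "b1", "b2"])
        fwd_dmcs = call_dmcs(m, ["a1", "a2"], ["b1", "b2"])
        rev_dmcs = call_dmcs(m, ["b1", "b2"], ["a1", "a2"])
        assert len(fwd_dmcs) == len(rev_dmcs)
        for f, r in zip(fwd_dmcs, rev_dmcs):
            assert f.pos == r.pos
            assert f.diff == pytest.approx(-r.diff)
            assert {f.direction, r.direction} in ({"hypo", "hyper"}, set())
        fwd = call_dmrs(fwd_dmcs, m, ["a1", "a2"], ["b1", "b2"])
        rev = call_dmrs(rev_dmcs, m, ["b1", "b2"], ["a1", "a2"])
        for df, dr in zip(fwd, rev):
            assert df.interval == dr.interval
            assert df.mean_diff == pytest.approx(-dr.mean_diff)
            assert df.p_mwu == pytest.approx(dr.p_mwu, abs=1e-12)
            assert df.direction != dr.direction

    def test_null_data_false_positive_rate_below_one_per_mb(self):
        """Without planted regions, fewer than one DMR per Mb at defaults."""
        config = SimulationConfig(
            n_cpgs=30_000, coverage_lambda=30.0,
            genotypes=(("control", 2), ("tumor", 2)), seed=13,
        )
        truth = generate_truth(config)
        study = simulate_study(truth)
        samples = {**study["control"], **study["tumor"]}
        m = build_matrix(samples)
        dmcs = call_dmcs(m, list(study["control"]), list(study["tumor"]))
        dmrs = call_dmrs(dmcs, m, list(study["control"]), list(study["tumor"]))
        span_mb = (truth.positions[-1] - truth.positions[0]) / 1e6
        assert len(dmrs) / span_mb < 1.0
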