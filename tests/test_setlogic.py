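"""Cross-comparison DMR matching, partition, transformation filter and
catalytic/accessory target classification."""

import numpy as np
import pytest

from dmrscape.calling import DMR
from dmrscape.intervals import GenomicInterval
from dmrscape.setlogic import (
    ComparisonResult,
    classify_ca_af,
    cross_reference,
    match_dmrs,
    partition_specific_overlapping,
    transformation_filter,
)


def _dmr(start, end, direction="hypo", chrom="chr1"):
    return DMR(GenomicInterval(chrom, start, end), 3, direction, -0.4, 0.01)


def _cmp(name, dmrs):
    return ComparisonResult(name, list(dmrs))


class TestMatchDmrs:
    def test_one_bp_overlap_matches(self):
        assert match_dmrs([_dmr(100, 200)], [_dmr(150, 250)]) == [(0, 0)]

    def test_half_open_abutment_does_not_match(self):
        assert match_dmrs([_dmr(100, 200)], [_dmr(200, 300)]) == []

    def test_direction_flag(self):
        a, b = [_dmr(100, 200, "hypo")], [_dmr(150, 250, "hyper")]
        assert match_dmrs(a, b, require_same_direction=True) == []
        assert match_dmrs(a, b, require_same_direction=False) == [(0, 0)]

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(30)

        def rand_set(n):
            return [
                _dmr(int(s), int(s) + int(rng.integers(20, 200)),
                     str(rng.choice(["hypo", "hyper"])))
                for s in rng.integers(0, 20_000, n)
            ]

        set_a, set_b = rand_set(60), rand_set(60)
        got = set(match_dmrs(set_a, set_b))
        expected = {
            (i, j)
            for i, a in enumerate(set_a)
            for j, b in enumerate(set_b)
            if a.interval.overlaps(b.interval) and a.direction == b.direction
        }
        assert got == expected


class TestPartition:
    def test_disjoint_sets_are_all_specific(self):
        labeled, counts = partition_specific_overlapping(
            _cmp("A", [_dmr(100, 200)]), _cmp("B", [_dmr(500, 600)])
        )
        assert {c.partition_label for c in labeled} == {"specific_A", "specific_B"}
        assert counts.loc["hypo", "overlapping"] == 0

    def test_identical_sets_are_all_overlapping(self):
        dmrs = [_dmr(100, 200), _dmr(500, 600)]
        labeled, counts = partition_specific_overlapping(_cmp("A", dmrs), _cmp("B", dmrs))
        assert all(c.partition_label == "overlapping" for c in labeled)
        assert counts.loc["hypo", "overlapping"] == 2  # counted on A's units

    def test_recovers_planted_pattern(self, study_truth, study_results):
        """Treating ko and ci as the two tumor types, each planted region's
        specific/overlapping label is recovered."""
        from dmrscape.simulate import expected_partition_label

        labeled, _ = partition_specific_overlapping(
            study_results["ko"], study_results["ci"]
        )
        total = hit = 0
        for region in study_truth.config.planted_regions:
            want = expected_partition_label(region, "ko", "ci")
            if want is None:
                continue
            total += 1
            for c in labeled:
                d = c.dmr
                if (
                    d.interval.overlaps(region.interval)
                    and (d.direction == "hypo") == (region.delta < 0)
                    and c.partition_label == want
                ):
                    hit += 1
                    break
        assert total > 20
        assert hit / total >= 0.90


class TestTransformationFilter:
    def test_shared_dmr_removed_everywhere(self):
        shared = _dmr(100, 200)
        results = {
            "wt": _cmp("wt", [shared, _dmr(1000, 1100)]),
            "ko": _cmp("ko", [_dmr(120, 180), _dmr(3000, 3100)]),
            "ci": _cmp("ci", [_dmr(90, 150)]),
        }
        filtered, removed = transformation_filter(results)
        assert len(removed) == 3  # one copy per genotype list
        assert all(c.mechanism_label == "transformation" for c in removed)
        assert [d.interval.start for d in filtered["wt"].dmrs] == [1000]
        assert [d.interval.start for d in filtered["ko"].dmrs] == [3000]
        assert filtered["ci"].dmrs == []

    def test_single_genotype_dmr_retained(self):
        results = {
            "wt": _cmp("wt", []),
            "ko": _cmp("ko", [_dmr(100, 200)]),
            "ci": _cmp("ci", []),
        }
        filtered, removed = transformation_filter(results)
        assert removed == [] and len(filtered["ko"].dmrs) == 1

    def test_missing_genotype_rejected(self):
        with pytest.raises(ValueError):
            transformation_filter({"ko": _cmp("ko", [])})


class TestClassifyCaAf:
    def _classify(self, wt, ko, ci):
        filtered = {"wt": _cmp("wt", wt), "ko": _cmp("ko", ko), "ci": _cmp("ci", ci)}
        return classify_ca_af(filtered)

    def test_hypo_in_ko_only_is_accessory_target(self):
        labels, counts = self._classify([], [_dmr(100, 200)], [])
        assert labels[0].mechanism_label == "af_target"
        assert counts.loc["hypo", "af_target"] == 1

    def test_hypo_in_ko_and_ci_is_catalytic_target(self):
        labels, _ = self._classify([], [_dmr(100, 200)], [_dmr(150, 250)])
        by_source = {c.source: c.mechanism_label for c in labels}
        assert by_source["ko"] == "ca_target"

    def test_hyper_in_ci_not_ko_is_accessory_target(self):
        labels, _ = self._classify([], [], [_dmr(100, 200, "hyper")])
        assert labels[0].mechanism_label == "af_target"

    def test_hyper_in_wt_only_is_catalytic_target(self):
        labels, _ = self._classify([_dmr(100, 200, "hyper")], [], [])
        assert labels[0].mechanism_label == "ca_target"

    def test_labeling_is_exhaustive_and_disjoint(self):
        rng = np.random.default_rng(31)

        def rand(n):
            return [
                _dmr(int(s), int(s) + 50, str(rng.choice(["hypo", "hyper"])))
                for s in rng.integers(0, 100_000, n)
            ]

        wt, ko, ci = rand(30), rand(30), rand(30)
        labels, counts = self._classify(wt, ko, ci)
        assert len(labels) == 90  # every DMR entering gets exactly one label
        assert int(counts.to_numpy().sum()) == 90

    def test_labels_invariant_under_input_order(self):
        rng = np.random.default_rng(32)
        ko = [_dmr(int(s), int(s) + 50) for s in rng.integers(0, 50_000, 20)]
        ci = [_dmr(int(s), int(s) + 50) for s in rng.integers(0, 50_000, 20)]
        l1, _ = self._classify([], ko, ci)
        l2, _ = self._classify([], ko[::-1], ci[::-1])
        key = lambda c: (c.source, c.dmr.interval.start)
        assert sorted([(key(c), c.mechanism_label) for c in l1]) == sorted(
            [(key(c), c.mechanism_label) for c in l2]
        )

    def test_ko_ci_relabel_metamorphic(self):
        """Swapping which genotype is called 'ko' moves the hypo
        accessory-target label to the other list, symmetrically."""
        only_one = [_dmr(100, 200)]
        labels_fwd, _ = self._classify([], only_one, [])
        filtered = {"wt": _cmp("wt", []), "ko": _cmp("ci", []), "ci": _cmp("ko", only_one)}
        labels_rev, _ = classify_ca_af(filtered, wt="wt", ko="ci", ci="ko")
        assert labels_fwd[0].mechanism_label == "af_target"
        assert labels_rev[0].mechanism_label == "af_target"


class TestCrossReference:
    def test_empty_external_gives_zeros(self):
        labels, _ = classify_ca_af(
            {"wt": _cmp("wt", []), "ko": _cmp("ko", [_dmr(100, 200)]), "ci": _cmp("ci", [])}
        )
        counts = cross_reference(labels, _cmp("ext", []))
        assert (counts.to_numpy() == 0).all()

    def test_external_equal_to_af_set_counts_all(self):
        ko = [_dmr(100, 200), _dmr(1000, 1100)]
        labels, counts = classify_ca_af(
            {"wt": _cmp("wt", []), "ko": _cmp("ko", ko), "ci": _cmp("ci", [])}
        )
        ext = cross_reference(labels, _cmp("ext", ko))
        assert ext.loc["hypo", "af_target"] == counts.loc["hypo", "af_target"] == 2

    def test_matches_brute_force_counts(self):
        rng = np.random.default_rng(33)
        ko = [_dmr(int(s), int(s) + 60) for s in rng.integers(0, 30_000, 25)]
        external = [_dmr(int(s), int(s) + 60) for s in rng.integers(0, 30_000, 25)]
        labels, _ = classify_ca_af(
            {"wt": _cmp("wt", []), "ko": _cmp("ko", ko), "ci": _cmp("ci", [])}
        )
        got = cross_reference(labels, _cmp("ext", external))
        expected = sum(
            1
            for c in labels
            if c.mechanism_label == "af_target"
            and any(c.dmr.interval.overlaps(e.interval) for e in external)
        )
        assert got.loc["hypo", "af_target"] == expected
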