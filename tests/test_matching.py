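import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smapkit.genotype_inference import InferredGenotypeMatrix
from smapkit.io_formats import AA, AB, BB, MISSING, GenotypeMatrix, MatchReport, SampleMatch
from smapkit.matching import (
    ScoreConfig,
    classify_swaps,
    cscore,
    cscore_matrix,
    delta_cscore,
    match_samples,
)

LOOSE = ScoreConfig(min_compared=1)


def brute_force_cscore(a, b, mode="fraction", weights=(1.0, 2.0, 3.0)):
    """Independent position-by-position counting oracle."""
    matched_weight = 0.0
    matched = 0
    compared = 0
    for x, y in zip(a, b):
        if x == MISSING or y == MISSING:
            continue
        compared += 1
        if x == y:
            matched += 1
            matched_weight += weights[x]
    if compared == 0:
        return float("nan")
    return matched / compared if mode == "fraction" else matched_weight / compared


class TestCscore:
    def test_three_of_four_matched(self):
        a = [AA, AB, BB, AA]
        b = [AA, AB, BB, BB]
        assert cscore(a, b, LOOSE) == pytest.approx(0.75)

    def test_identity_is_one(self):
        v = [AA, AB, BB, AA, AB]
        assert cscore(v, v, LOOSE) == 1.0

    def test_weighted_mode_uses_class_weights(self):
        cfg = ScoreConfig(mode="weighted", min_compared=1)
        v = [AA, AB, BB]
        assert cscore(v, v, cfg) == pytest.approx(2.0)

    def test_missing_positions_excluded(self):
        a = [AA, MISSING, BB]
        b = [AA, AB, MISSING]
        assert cscore(a, b, LOOSE) == 1.0

    def test_below_min_compared_is_nan(self):
        assert np.isnan(cscore([AA] * 5, [AA] * 5, ScoreConfig(min_compared=20)))

    @settings(deadline=None, max_examples=100)
    @given(
        data=st.lists(
            st.tuples(
                st.sampled_from([AA, AB, BB, MISSING]),
                st.sampled_from([AA, AB, BB, MISSING]),
            ),
            min_size=1,
            max_size=20,
        ),
        mode=st.sampled_from(["fraction", "weighted"]),
    )
    def test_matches_brute_force_oracle(self, data, mode):
        a = [x for x, _ in data]
        b = [y for _, y in data]
        cfg = ScoreConfig(mode=mode, min_compared=1)
        expected = brute_force_cscore(a, b, mode)
        got = cscore(a, b, cfg)
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(expected)

    def test_matrix_form_agrees_with_scalar(self, small_panel):
        rng = np.random.default_rng(0)
        vec = rng.choice([AA, AB, BB], small_panel.n_snps).astype(np.int8)
        mat = cscore_matrix(vec, small_panel.calls, LOOSE)
        for i in range(small_panel.n_samples):
            assert mat[i] == pytest.approx(
                cscore(vec, small_panel.calls[i], LOOSE)
            )


class TestDeltaCscore:
    def test_basic(self):
        assert delta_cscore([0.9, 0.72, 0.5]) == pytest.approx(0.2)

    def test_tie_is_zero(self):
        assert delta_cscore([0.5, 0.5]) == 0.0

    def test_single_candidate_is_one(self):
        assert delta_cscore([0.8]) == 1.0

    def test_zero_best_is_nan(self):
        assert np.isnan(delta_cscore([0.0, 0.0]))

    @settings(deadline=None, max_examples=50)
    @given(
        scores=st.lists(
            st.floats(min_value=0.01, max_value=1.0), min_size=2, max_size=10
        ),
        c=st.floats(min_value=0.1, max_value=50),
    )
    def test_scale_invariance(self, scores, c):
        base = delta_cscore(scores)
        scaled = delta_cscore([c * s for s in scores])
        assert scaled == pytest.approx(base, abs=1e-9)


def as_inferred(calls, channels, batch="b1", snps=None):
    calls = np.asarray(calls, dtype=np.int8)
    snps = snps or [f"chr1:{100 + i}:A:G" for i in range(calls.shape[1])]
    return InferredGenotypeMatrix(batch, channels, snps, calls)


class TestMatchSamples:
    @staticmethod
    def _permuted_fixture(seed=0, n_samples=5, n_snps=50):
        rng = np.random.default_rng(seed)
        calls = rng.choice([AA, AB, BB], (n_samples, n_snps)).astype(np.int8)
        snps = [f"chr1:{100 + i}:A:G" for i in range(n_snps)]
        panel = GenotypeMatrix([f"S{i}" for i in range(n_samples)], snps, calls)
        perm = rng.permutation(n_samples)
        inferred = as_inferred(calls[perm], [f"ch{i}" for i in range(n_samples)], snps=snps)
        manifest = {f"ch{i}": f"S{i}" for i in range(n_samples)}
        return panel, inferred, perm, manifest

    def test_recovers_known_permutation(self):
        panel, inferred, perm, manifest = self._permuted_fixture()
        cfg = ScoreConfig(cscore_min=0.8, min_compared=10)
        report = match_samples(inferred, panel, cfg, manifest=manifest)
        for i, m in enumerate(sorted(report.matches, key=lambda m: m.channel)):
            assert m.best_candidate == f"S{perm[i]}"
            assert m.cscore == 1.0
            # delta computed against the true second-best by brute force
            scores = sorted(
                (
                    brute_force_cscore(inferred.calls[i], panel.calls[j])
                    for j in range(panel.n_samples)
                ),
                reverse=True,
            )
            assert m.delta_cscore == pytest.approx(
                (scores[0] - scores[1]) / scores[0]
            )

    def test_identity_fixture_all_matched(self):
        rng = np.random.default_rng(1)
        calls = rng.choice([AA, AB, BB], (5, 60)).astype(np.int8)
        snps = [f"chr1:{i}:A:G" for i in range(60)]
        panel = GenotypeMatrix([f"S{i}" for i in range(5)], snps, calls)
        inferred = as_inferred(calls, [f"S{i}" for i in range(5)], snps=snps)
        report = match_samples(inferred, panel, ScoreConfig(cscore_min=0.8))
        assert all(m.status == "matched" for m in report.matches)

    def test_low_cscore_unassignable(self):
        panel, inferred, perm, manifest = self._permuted_fixture()
        cfg = ScoreConfig(cscore_min=1.01, min_compared=10)  # unreachable
        report = match_samples(inferred, panel, cfg, manifest=manifest)
        assert all(m.status == "unassignable" for m in report.matches)

    def test_duplicated_reference_sample_unassignable(self):
        rng = np.random.default_rng(2)
        calls = rng.choice([AA, AB, BB], (3, 40)).astype(np.int8)
        dup = np.vstack([calls, calls[0]])  # S3 duplicates S0
        snps = [f"chr1:{i}:A:G" for i in range(40)]
        panel = GenotypeMatrix(["S0", "S1", "S2", "S3"], snps, dup)
        inferred = as_inferred(calls[:1], ["S0"], snps=snps)
        report = match_samples(inferred, panel, ScoreConfig(cscore_min=0.5))
        (m,) = report.matches
        assert m.delta_cscore == 0.0
        assert m.status == "unassignable"

    def test_control_channel_never_assigned(self):
        panel, inferred, perm, manifest = self._permuted_fixture()
        manifest["ch0"] = "CONTROL"
        report = match_samples(
            inferred, panel, ScoreConfig(cscore_min=0.8, min_compared=10),
            manifest=manifest,
        )
        m = [x for x in report.matches if x.channel == "ch0"][0]
        assert m.status == "control" and m.best_match is None

    def test_control_calibration_sets_threshold_to_control_mean(self):
        panel, inferred, perm, manifest = self._permuted_fixture(n_snps=60)
        manifest["ch0"] = "CONTROL"
        cfg = ScoreConfig(min_compared=10)  # cscore_min None -> calibrate
        report = match_samples(inferred, panel, cfg, manifest=manifest)
        ctrl = [m for m in report.matches if m.status == "control"][0]
        assert report.cscore_min == pytest.approx(ctrl.cscore)

    def test_single_candidate_pool_rejected(self):
        snps = ["chr1:1:A:G"]
        panel = GenotypeMatrix(["S0"], snps, np.array([[AA]], dtype=np.int8))
        inferred = as_inferred([[AA]], ["S0"], snps=snps)
        with pytest.raises(ValueError, match="2 candidate"):
            match_samples(inferred, panel)


def report_with_corrections(pairs):
    matches = [
        SampleMatch("b1", f"ch{i}", orig, dest, 0.9, 0.5, 0.4, "corrected")
        for i, (orig, dest) in enumerate(pairs)
    ]
    return MatchReport(matches)


class TestClassifySwaps:
    def test_reciprocal_pair(self):
        graph = classify_swaps(report_with_corrections([("A", "B"), ("B", "A")]))
        assert [c.kind for c in graph.components] == ["reciprocal"]

    def test_one_way(self):
        graph = classify_swaps(report_with_corrections([("A", "B")]))
        assert [c.kind for c in graph.components] == ["one-way"]

    def test_cyclic_of_length_three(self):
        graph = classify_swaps(
            report_with_corrections([("A", "B"), ("B", "C"), ("C", "A")])
        )
        assert [c.kind for c in graph.components] == ["cyclic"]

    def test_mixed_topologies_counted(self):
        graph = classify_swaps(
            report_with_corrections(
                [("A", "B"), ("B", "A"), ("C", "D"), ("E", "F"), ("F", "G"), ("G", "E")]
            )
        )
        assert graph.counts() == {"reciprocal": 1, "one-way": 1, "cyclic": 1}

    def test_component_sizes_sum_to_corrected_nodes(self):
        pairs = [("A", "B"), ("B", "A"), ("C", "D")]
        graph = classify_swaps(report_with_corrections(pairs))
        total = sum(len(c.samples) for c in graph.components)
        assert total == 4  # A, B, C, D
        rec = [c for c in graph.components if c.kind == "reciprocal"]
        assert all(len(c.samples) == 2 for c in rec)

    def test_empty_report_has_no_components(self):
        assert classify_swaps(MatchReport([])).components == []
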