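"""Batch metrics, recovery statistics, analogue coverage and run tracking."""

import numpy as np
import pytest

from conftest import naive_tanimoto, random_fp_set
from denovoeval.diversity import SphereConfig
from denovoeval.fingerprints import fingerprint_matrix
from denovoeval.genmetrics import (
    MetricReport,
    RecoveryReport,
    analogue_coverage,
    batch_metrics,
    recovery_probability,
    reports_to_dataframe,
    track_run,
)
from denovoeval.standardize import canonicalize
from denovoeval.synthetic import LibrarySpec, generate_run_stream


class TestBatchMetrics:
    def test_mixed_batch(self):
        m = batch_metrics(["CCO", "OCC", "C1CC"], set())
        assert m.validity == pytest.approx(2 / 3)
        assert m.uniqueness == pytest.approx(1 / 2)  # CCO == OCC canonically
        assert m.novelty == 1.0

    def test_batch_inside_training_set(self):
        train = {canonicalize(s) for s in ["CCO", "CCN"]}
        m = batch_metrics(["CCO", "OCC", "NCC"], train)
        assert m.novelty == 0.0

    def test_counts_are_nested(self, design_library):
        rng = np.random.default_rng(8)
        pool = [s for _, s in design_library]
        batch = [pool[i] for i in rng.integers(0, len(pool), size=460)]
        batch += ["C1CC("] * 25 + [pool[0]] * 15  # planted invalids + dups
        train = {canonicalize(pool[i]) for i in range(50)}
        m = batch_metrics(batch, train)
        # set-arithmetic oracle
        canon = [canonicalize(s) for s in batch]
        valid = [c for c in canon if c is not None]
        unique = set(valid)
        assert (m.n_total, m.n_valid) == (500, len(valid))
        assert m.n_unique == len(unique)
        assert m.n_novel == len(unique - train)
        assert m.n_total >= m.n_valid >= m.n_unique >= m.n_novel

    def test_empty_batch_raises(self):
        with pytest.raises(ValueError):
            batch_metrics([], set())


class TestRecovery:
    def test_planted_matches_arithmetic(self, design_library):
        pool = [canonicalize(s) for _, s in design_library]
        sample = pool[:400]
        actives = set(pool[:2])  # 2 planted active matches
        inactives = set(pool[2:22])  # 20 planted inactive matches
        rep = recovery_probability([sample], actives, inactives)
        assert rep.p_active_mean == pytest.approx(2 / 400)
        assert rep.p_inactive_mean == pytest.approx(20 / 400)
        assert rep.bias == pytest.approx(0.1)

    def test_published_all_row_arithmetic(self):
        # recovery probabilities 63e-6 / 917e-6 give a 0.069 active bias
        rep = RecoveryReport.from_probabilities(63e-6, 917e-6)
        assert round(rep.bias, 3) == 0.069

    def test_fold_change_against_baseline(self):
        baseline = RecoveryReport.from_probabilities(10e-6, 5957e-6)
        rep = RecoveryReport.from_probabilities(79e-6, 486e-6, baseline=baseline)
        assert rep.fold_change == pytest.approx(rep.bias / baseline.bias)

    def test_zero_active_matches(self):
        rep = RecoveryReport.from_probabilities(
            0.0, 0.01, baseline=RecoveryReport.from_probabilities(0.001, 0.01)
        )
        assert rep.bias == 0.0 and rep.fold_change == 0.0

    def test_zero_inactive_probability_flags_infinite(self):
        rep = RecoveryReport.from_probabilities(0.001, 0.0)
        assert rep.infinite_bias and np.isinf(rep.bias)

    def test_disjoint_reference_probabilities_bounded(self, design_library):
        pool = [canonicalize(s) for _, s in design_library]
        rep = recovery_probability([pool], set(pool[:100]), set(pool[100:300]))
        assert rep.p_active_mean + rep.p_inactive_mean <= 1.0

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            recovery_probability([["C1CC"]], set(), set())


class TestAnalogueCoverage:
    def test_identical_sets(self):
        F = fingerprint_matrix(["CCO", "c1ccccc1", "CCNCC"])
        cov = analogue_coverage(F, F)
        assert cov == analogue_coverage(F, F)
        assert cov.gen_fraction == 1.0 and cov.ref_fraction == 1.0

    def test_no_pair_reaches_threshold(self):
        gen = np.eye(64, dtype=bool)[:3]
        ref = np.eye(64, dtype=bool)[10:13]
        cov = analogue_coverage(gen, ref)
        assert cov.gen_fraction == 0.0 and cov.ref_fraction == 0.0

    def test_matches_brute_force_pairwise_scan(self):
        rng = np.random.default_rng(13)
        gen = random_fp_set(rng, 30, nbits=64)
        ref = random_fp_set(rng, 20, nbits=64)
        cov = analogue_coverage(gen, ref, threshold=0.4)
        sims = [[naive_tanimoto(g, r) for r in ref] for g in gen]
        gen_frac = np.mean([max(row) >= 0.4 for row in sims])
        ref_frac = np.mean([max(col) >= 0.4 for col in zip(*sims)])
        assert cov.gen_fraction == pytest.approx(gen_frac)
        assert cov.ref_fraction == pytest.approx(ref_frac)

    def test_gen_fraction_monotone_in_threshold(self):
        rng = np.random.default_rng(19)
        gen = random_fp_set(rng, 25, nbits=64)
        ref = random_fp_set(rng, 25, nbits=64)
        fracs = [
            analogue_coverage(gen, ref, threshold=t).gen_fraction
            for t in (0.6, 0.5, 0.4, 0.3, 0.2)
        ]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            analogue_coverage(np.zeros((0, 8), dtype=bool), np.ones((1, 8), dtype=bool))


SMALL_SPHERE = SphereConfig(subsample_k=200, seed=0)


class TestTrackRun:
    def test_identical_batches_give_constant_series(self, design_library):
        batch = [s for _, s in design_library[:40]]
        stream = [(i, batch) for i in range(1, 201)]
        reports = list(track_run(stream, set(), every=100, sphere_config=SMALL_SPHERE))
        assert len(reports) == 2
        assert reports[0].metrics == reports[1].metrics

    def test_row_count(self, design_library):
        batch = [s for _, s in design_library[:10]]
        stream = [(i, batch) for i in range(1, 301)]
        reports = list(track_run(stream, set(), every=100, sphere_config=SMALL_SPHERE))
        assert len(reports) == 3
        assert [r.label for r in reports] == ["step_100", "step_200", "step_300"]

    def test_streaming_equals_concatenation(self, design_library):
        pool = [s for _, s in design_library]
        rng = np.random.default_rng(2)
        batches = [
            [pool[i] for i in rng.integers(0, len(pool), size=16)] for _ in range(40)
        ]
        stream = list(enumerate(batches, start=1))
        whole = list(track_run(stream, set(), every=20, sphere_config=SMALL_SPHERE))
        part1 = list(track_run(stream[:20], set(), every=20, sphere_config=SMALL_SPHERE))
        part2 = list(track_run(stream[20:], set(), every=20, sphere_config=SMALL_SPHERE))
        assert [r.metrics for r in whole] == [r.metrics for r in part1 + part2]

    def test_unordered_steps_raise(self):
        stream = [(1, ["CCO"]), (1, ["CCN"])]
        with pytest.raises(ValueError):
            list(track_run(stream, set(), every=1))

    def test_collapsing_stream_dynamics(self):
        """Uniqueness and SEDiv decline across intervals on the collapsing
        profile — the overfitting signature of a reward-hacking agent."""
        stream = generate_run_stream(150, batch_size=32, profile="collapsing", seed=5)
        reports = list(track_run(stream, set(), every=50, sphere_config=SMALL_SPHERE))
        uniq = [r.metrics["uniqueness"] for r in reports]
        sed = [r.metrics["sediv"] for r in reports]
        tol = 0.05
        assert all(b <= a + tol for a, b in zip(uniq, uniq[1:]))
        assert all(b <= a + tol for a, b in zip(sed, sed[1:]))
        assert uniq[-1] < uniq[0]

    def test_report_json_roundtrip(self):
        rep = MetricReport("step_100", {"validity": 0.9, "novelty": None}, {"n_total": 10}, 3)
        assert MetricReport.from_json(rep.to_json()) == rep

    def test_reports_dataframe_columns(self, design_library):
        batch = [s for _, s in design_library[:10]]
        reports = list(
            track_run([(1, batch)], set(), every=1, sphere_config=SMALL_SPHERE)
        )
        df = reports_to_dataframe(reports)
        for col in ("validity", "uniqueness", "novelty", "sediv", "intdiv"):
            assert col in df.columns
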