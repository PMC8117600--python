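"""Sphere-exclusion picking, SEDiv, internal diversity and clustering."""

import numpy as np
import pytest

from conftest import naive_leader_pick, naive_tanimoto, random_fp_set
from denovoeval.diversity import (
    SphereConfig,
    cluster_assign,
    internal_diversity,
    scaffold_metrics,
    sediv,
    sphere_exclusion_pick,
)
from denovoeval.fingerprints import fingerprint_matrix, tanimoto
from denovoeval.standardize import bemis_murcko_scaffold

NO_SUBSAMPLE = SphereConfig(subsample_k=None)


class TestSphereExclusionPick:
    def test_identical_set_yields_one_pick(self):
        F = np.tile(random_fp_set(np.random.default_rng(0), 1, 64), (10, 1))
        assert sphere_exclusion_pick(F, 0.65) == [0]

    def test_mutually_distant_set_picks_all(self):
        F = np.eye(32, dtype=bool)[:8]  # disjoint bit sets, distance 1
        assert sphere_exclusion_pick(F, 0.65) == list(range(8))

    @pytest.mark.parametrize("radius", [0.2, 0.65])
    def test_matches_naive_leader_oracle(self, radius):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(1, 31))
            F = random_fp_set(rng, n, nbits=64, density=rng.uniform(0.1, 0.6))
            assert sphere_exclusion_pick(F, radius) == naive_leader_pick(F, radius)

    def test_boundary_distance_excludes(self):
        # distance exactly equal to the radius must not qualify as a pick
        a = np.zeros(8, dtype=bool)
        b = np.zeros(8, dtype=bool)
        a[:2] = True
        b[[0, 2]] = True  # similarity 1/3, distance 2/3
        assert sphere_exclusion_pick(np.vstack([a, b]), 2 / 3) == [0]
        assert sphere_exclusion_pick(np.vstack([a, b]), 0.66) == [0, 1]

    def test_centroid_separation_and_coverage(self):
        rng = np.random.default_rng(17)
        F = random_fp_set(rng, 60, nbits=64, density=0.25)
        radius = 0.65
        picked = sphere_exclusion_pick(F, radius)
        for i, a in enumerate(picked):
            for b in picked[:i]:
                assert 1.0 - tanimoto(F[a], F[b]) > radius
        for i in range(len(F)):
            assert i in picked or any(
                1.0 - tanimoto(F[i], F[c]) <= radius for c in picked
            )

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            sphere_exclusion_pick(np.zeros((0, 8), dtype=bool), 0.65)


class TestSediv:
    def test_identical_molecules_give_one_over_n(self):
        F = np.tile(fingerprint_matrix(["CCO"]), (10, 1))
        assert sediv(F, NO_SUBSAMPLE).value == pytest.approx(0.1)

    def test_mutually_distant_set_gives_one(self):
        F = np.eye(64, dtype=bool)[:10]
        assert sediv(F, NO_SUBSAMPLE).value == 1.0

    def test_design_library_recovery(self, design_library_fps):
        # 5 mutually distant tight series x 100 analogues -> 5/500 exactly
        result = sediv(design_library_fps, NO_SUBSAMPLE)
        assert result.value == 5 / 500
        # cross-checked against the naive leader oracle
        assert result.n_picked == len(naive_leader_pick(design_library_fps, 0.65))

    def test_bounds_invariant(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            n = int(rng.integers(1, 40))
            F = random_fp_set(rng, n, nbits=64, density=rng.uniform(0.1, 0.6))
            v = sediv(F, NO_SUBSAMPLE).value
            assert 1 / n <= v <= 1.0

    def test_subsampling_is_seeded_and_recorded(self):
        rng = np.random.default_rng(4)
        F = random_fp_set(rng, 50, nbits=64)
        config = SphereConfig(subsample_k=20, seed=99)
        r1, r2 = sediv(F, config), sediv(F, config)
        assert r1 == r2
        assert r1.subsampled and r1.n_evaluated == 20 and r1.seed == 99

    def test_heavy_atom_confound(self):
        """IntDiv drops for systematically larger molecules; SEDiv holds.

        Two libraries share the same 5-series design, but in one every
        substituent is extended by a hexyl chain (~6 extra heavy atoms per
        molecule).  Internal diversity falls with the larger molecules
        while sphere-exclusion diversity stays at the k/n design value.
        """
        from denovoeval.synthetic import LibrarySpec, generate_scaffold_library

        small = LibrarySpec(n_scaffolds=5, n_decorations_per_scaffold=60, seed=2)
        big_pool = tuple(
            "CCCCCC" + d if d != "[H]" else "CCCCCC" for d in small.decoration_pool
        )
        big = LibrarySpec(
            n_scaffolds=5, n_decorations_per_scaffold=60, seed=2, decoration_pool=big_pool
        )
        values = {}
        for name, spec in [("small", small), ("big", big)]:
            F = fingerprint_matrix([s for _, s in generate_scaffold_library(spec)])
            values[name] = (sediv(F, NO_SUBSAMPLE).value, internal_diversity(F))
        assert values["big"][1] < values["small"][1]  # the confound
        assert values["small"][0] == values["big"][0] == 5 / 300  # SEDiv robust


class TestInternalDiversity:
    def test_identical_set_is_zero(self):
        F = np.tile(fingerprint_matrix(["CCO"]), (5, 1))
        assert internal_diversity(F) == pytest.approx(0.0)

    def test_two_molecule_closed_form(self):
        # pairwise similarity s -> 1 - (1 + 1 + s + s) / 4
        a = np.zeros(16, dtype=bool)
        b = np.zeros(16, dtype=bool)
        a[[0, 1, 2]] = True
        b[[1, 2, 3]] = True  # s = 0.5 -> intdiv 0.25
        assert internal_diversity(np.vstack([a, b])) == pytest.approx(
            1 - (1 + 1 + 0.5 + 0.5) / 4
        )

    def test_matches_full_matrix_brute_force(self):
        rng = np.random.default_rng(31)
        F = random_fp_set(rng, 25, nbits=64)
        n = len(F)
        mean = np.mean(
            [[naive_tanimoto(F[i], F[j]) for j in range(n)] for i in range(n)]
        )
        assert internal_diversity(F) == pytest.approx(1 - mean, abs=1e-12)


class TestClusterAssign:
    def test_identical_set_single_cluster(self):
        F = np.tile(fingerprint_matrix(["CCO"]), (6, 1))
        res = cluster_assign(F)
        assert res.centroid_indices == (0,)
        assert res.cluster_sizes.tolist() == [6]

    def test_mutually_distant_singletons(self):
        F = np.eye(32, dtype=bool)[:7]
        res = cluster_assign(F)
        assert len(res.centroid_indices) == 7
        assert res.cluster_sizes.tolist() == [1] * 7

    def test_nearest_centroid_verified_by_brute_force(self, design_library_fps):
        F = design_library_fps[::10]
        res = cluster_assign(F, NO_SUBSAMPLE)
        centroids = list(res.centroid_indices)
        for i in range(len(F)):
            sims = [naive_tanimoto(F[i], F[c]) for c in centroids]
            assert res.membership[i] == int(np.argmax(sims))
        assert res.cluster_sizes.sum() == len(F)


class TestScaffoldMetrics:
    def test_shared_scaffold_uniqueness(self):
        scaffolds = ["c1ccccc1"] * 20
        m = scaffold_metrics(scaffolds)
        assert m.uniqueness == pytest.approx(0.05)

    def test_distinct_distant_scaffolds(self, design_library):
        leaders = [s for mol_id, s in design_library if mol_id.split("_")[1] == "D0"]
        scaffolds = [bemis_murcko_scaffold(s) for _, s in design_library]
        m = scaffold_metrics(scaffolds)
        assert m.n_unique_scaffolds == 5
        # the 5 series scaffolds are mutually distant even at radius 0.2
        assert m.diversity == 1.0

    def test_mixed_library_matches_set_arithmetic(self, design_library):
        scaffolds = [bemis_murcko_scaffold(s) for _, s in design_library[:150]]
        m = scaffold_metrics(scaffolds)
        assert m.uniqueness == pytest.approx(len(set(scaffolds)) / 150)
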