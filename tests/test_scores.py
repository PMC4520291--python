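"""Goodness-of-fit scores: identities, ranges and brute-force equivalence."""

import numpy as np
import pytest

from emscore import (
    DensityMap,
    SegmentSelection,
    apply_transform,
    ccc,
    chamfer_distance,
    envelope_score,
    generate_local_ensemble,
    joint_histogram,
    lap_ccc,
    laplacian_filter,
    make_toy_structure,
    mutual_information,
    normal_vector_score,
    sccc,
    score_ensemble,
    simulate_map,
    smi,
    volume_threshold,
)
from emscore.scores import VOLUME_PER_DALTON
from emscore.structure_core import FitTransform

from oracles import naive_chamfer, naive_mi, naive_pearson


class TestCcc:
    def test_self_correlation_is_one(self, rng):
        m = DensityMap(rng.random((8, 8, 8)), apix=1.0)
        assert ccc(m, m) == pytest.approx(1.0, abs=1e-12)

    def test_positive_affine_invariance(self, rng):
        m = DensityMap(rng.random((8, 8, 8)), apix=1.0)
        scaled = m.copy(grid=3.7 * m.grid + 11.0)
        assert ccc(scaled, m) == pytest.approx(1.0, abs=1e-12)

    def test_matches_naive_pearson(self, random_map_pair):
        a, b = random_map_pair
        assert ccc(a, b) == pytest.approx(naive_pearson(a.grid, b.grid), abs=1e-12)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(20):
            a = DensityMap(rng.random((6, 6, 6)), apix=1.0)
            b = DensityMap(rng.random((6, 6, 6)), apix=1.0)
            v = ccc(a, b)
            assert -1.0 <= v <= 1.0
            assert v == pytest.approx(ccc(b, a), abs=1e-15)

    def test_zero_variance_rejected(self, rng):
        flat = DensityMap(np.full((6, 6, 6), 2.0), apix=1.0)
        other = DensityMap(rng.random((6, 6, 6)), apix=1.0)
        with pytest.raises(ValueError, match="undefined CCC"):
            ccc(flat, other)

    def test_masked_ccc_uses_only_masked_voxels(self, random_map_pair):
        a, b = random_map_pair
        mask = np.zeros(a.shape, dtype=bool)
        mask[2:6, 2:6, 2:6] = True
        expected = naive_pearson(a.grid[mask], b.grid[mask])
        assert ccc(a, b, mask=mask) == pytest.approx(expected, abs=1e-12)


class TestLapCcc:
    def test_self_is_one(self, rng):
        m = DensityMap(rng.random((8, 8, 8)), apix=1.0)
        assert lap_ccc(m, m) == pytest.approx(1.0, abs=1e-12)

    def test_constant_offset_invisible(self, rng):
        m = DensityMap(rng.random((8, 8, 8)), apix=1.0)
        shifted = m.copy(grid=m.grid + 5.0)
        assert lap_ccc(shifted, m) == pytest.approx(1.0, abs=1e-9)

    def test_is_ccc_of_laplacians(self, random_map_pair):
        a, b = random_map_pair
        assert lap_ccc(a, b) == ccc(laplacian_filter(a), laplacian_filter(b))


class TestMutualInformation:
    def test_two_equal_bins_give_one_bit(self):
        grid = np.zeros((4, 4, 4))
        grid.ravel()[: grid.size // 2] = 1.0
        m = DensityMap(grid, apix=1.0)
        assert mutual_information(m, m, bins=2) == pytest.approx(1.0, abs=1e-12)

    def test_independent_maps_near_zero(self, rng):
        a = DensityMap(rng.random((20, 20, 20)), apix=1.0)
        b = DensityMap(rng.random((20, 20, 20)), apix=1.0)
        assert mutual_information(a, b, bins=5) < 0.01

    def test_matches_naive_histogram_oracle(self, random_map_pair):
        a, b = random_map_pair
        expected = naive_mi(a.grid, b.grid, bins=5)
        assert mutual_information(a, b, bins=5) == pytest.approx(expected, abs=1e-12)

    def test_self_mi_equals_binned_entropy(self, rng):
        m = DensityMap(rng.random((8, 8, 8)), apix=1.0)
        h = joint_histogram(m, m, bins=20)
        p = h.marginal_x[h.marginal_x > 0]
        entropy = -(p * np.log2(p)).sum()
        assert mutual_information(m, m, bins=20) == pytest.approx(entropy, abs=1e-12)

    def test_nonnegative_on_random_pairs(self, rng):
        for _ in range(100):
            a = DensityMap(rng.random((5, 5, 5)), apix=1.0)
            b = DensityMap(rng.random((5, 5, 5)), apix=1.0)
            assert mutual_information(a, b) >= 0.0

    def test_constant_map_gives_zero(self, rng):
        flat = DensityMap(np.full((6, 6, 6), 1.0), apix=1.0)
        other = DensityMap(rng.random((6, 6, 6)), apix=1.0)
        assert mutual_information(flat, other) == 0.0

    def test_joint_histogram_invariants(self, random_map_pair):
        a, b = random_map_pair
        h = joint_histogram(a, b, bins=7)
        assert h.joint.sum() == pytest.approx(1.0, abs=1e-9)
        assert (h.joint >= 0).all()
        assert np.allclose(h.marginal_x, h.joint.sum(axis=1))
        assert np.allclose(h.marginal_y, h.joint.sum(axis=0))


class TestEnvelopeScore:
    def test_perfect_occupancy_equals_atom_count(self):
        # 2x2x2 block of density, 8 atoms exactly at those voxel centers
        grid = np.zeros((6, 6, 6))
        grid[2:4, 2:4, 2:4] = 1.0
        m = DensityMap(grid, apix=1.0)
        helix = make_toy_structure(3, "helix")
        coords = [(i, j, k) for k in (2.0, 3.0) for j in (2.0, 3.0) for i in (2.0, 3.0)]
        from emscore.structure_core import AtomicStructure, AtomRecord
        atoms = [
            AtomRecord(serial=n + 1, name="CA", element="C", res_name="ALA",
                       chain="A", res_seq=n + 1, coord=c, mass=12.0)
            for n, c in enumerate(coords)
        ]
        s = AtomicStructure(atoms)
        assert envelope_score(s, m, threshold=0.5) == len(atoms)

    def test_single_atom_in_empty_map_is_pure_protrusion(self):
        m = DensityMap(np.zeros((5, 5, 5)), apix=1.0)
        s = make_toy_structure(3, "helix")
        one = type(s)([s.atoms[0]])
        assert envelope_score(one, m, threshold=0.5) == -2

    def test_hand_computed_toy_configuration(self):
        # envelope: 5 voxels along x at z=y=2; atoms at 3 of them
        grid = np.zeros((5, 5, 7))
        grid[2, 2, 1:6] = 1.0
        m = DensityMap(grid, apix=1.0)
        from emscore.structure_core import AtomicStructure, AtomRecord
        coords = [(1.0, 2.0, 2.0), (2.0, 2.0, 2.0), (6.0, 2.0, 0.0)]
        atoms = [
            AtomRecord(serial=n + 1, name="CA", element="C", res_name="ALA",
                       chain="A", res_seq=n + 1, coord=c, mass=12.0)
            for n, c in enumerate(coords)
        ]
        s = AtomicStructure(atoms)
        # atoms 1,2 inside (+1 each); atom 3 at (6,2,0): voxel below threshold (-2)
        # envelope voxels x in {1..5}; within one voxel of an atom: x in {1,2,3}
        # (atom at x=2 covers 1-3); x=4,5 empty (-1 each) => 1+1-2-1-1 = -2
        assert envelope_score(s, m, threshold=0.5) == -2

    def test_monotone_under_atom_exit(self):
        grid = np.zeros((6, 6, 6))
        grid[1:5, 1:5, 1:5] = 1.0
        m = DensityMap(grid, apix=1.0)
        from emscore.structure_core import AtomicStructure, AtomRecord

        def structure_with_k_outside(k):
            coords = [(2.0, 2.0, 2.0)] * (4 - k) + [(20.0, 20.0, 20.0)] * k
            atoms = [
                AtomRecord(serial=n + 1, name="CA", element="C", res_name="ALA",
                           chain="A", res_seq=n + 1, coord=c, mass=12.0)
                for n, c in enumerate(coords)
            ]
            return AtomicStructure(atoms)

        scores = [envelope_score(structure_with_k_outside(k), m, 0.5) for k in range(5)]
        assert all(a > b for a, b in zip(scores, scores[1:]))


class TestNormalVectorScore:
    def test_self_fit_is_zero(self, helix):
        m = simulate_map(helix, 10.0, apix=2.5)
        thr = volume_threshold(m, VOLUME_PER_DALTON * helix.total_mass)
        assert normal_vector_score(m, m, thr, thr) == pytest.approx(0.0, abs=1e-6)
        assert normal_vector_score(m, m, thr, thr, use_sobel=True) == pytest.approx(
            0.0, abs=1e-6
        )

    def test_opposed_ramps_give_pi(self):
        zz, yy, xx = np.mgrid[0:8, 0:8, 0:8]
        target = DensityMap((7 - xx).astype(float), apix=1.0)
        probe = DensityMap(xx.astype(float), apix=1.0)
        # surfaces coincide; normals are exactly +x vs -x
        v = normal_vector_score(probe, target, threshold_t=4.0, threshold_p=4.0)
        assert v == pytest.approx(np.pi, abs=1e-12)

    def test_range_on_random_envelopes(self, rng):
        for _ in range(10):
            a = DensityMap(rng.random((7, 7, 7)), apix=1.0)
            b = DensityMap(rng.random((7, 7, 7)), apix=1.0)
            v = normal_vector_score(a, b, 0.6, 0.6)
            assert 0.0 <= v <= np.pi

    def test_offset_cubes_match_naive_reimplementation(self):
        def blob(center):
            zz, yy, xx = np.mgrid[0:10, 0:10, 0:10]
            d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
            return np.exp(-d2 / 6.0)

        target = DensityMap(blob((4.5, 4.5, 4.5)), apix=1.0)
        probe = DensityMap(blob((5.5, 4.5, 3.5)), apix=1.0)
        got = normal_vector_score(probe, target, 0.3, 0.3)

        # independent: brute-force surfaces, central-difference normals,
        # per-point nearest probe voxel by linear scan
        def naive_surface_normals(grid, thr):
            from oracles import brute_surface_scan

            pts = sorted(brute_surface_scan(grid, thr))
            out = []
            g = np.gradient(grid)
            for (z, y, x) in pts:
                vec = -np.array([g[2][z, y, x], g[1][z, y, x], g[0][z, y, x]])
                n = np.linalg.norm(vec)
                if n > 0:
                    out.append(((z, y, x), vec / n))
            return out

        ts = naive_surface_normals(target.grid, 0.3)
        ps = naive_surface_normals(probe.grid, 0.3)
        angles = []
        for (tp, tn) in ts:
            best, best_d = None, np.inf
            for (pp, pn) in ps:
                d = sum((a - b) ** 2 for a, b in zip(tp, pp))
                if d < best_d:
                    best_d, best = d, pn
            angles.append(np.arccos(np.clip(np.dot(tn, best), -1, 1)))
        assert got == pytest.approx(float(np.mean(angles)), abs=1e-9)


class TestChamferDistance:
    def test_identical_maps_zero(self, helix):
        m = simulate_map(helix, 10.0, apix=2.5)
        thr = volume_threshold(m, VOLUME_PER_DALTON * helix.total_mass)
        assert chamfer_distance(m, m, thr, thr) == 0.0

    def test_single_voxel_three_four_five(self):
        a = np.zeros((6, 6, 6))
        a[0, 0, 0] = 1.0
        b = np.zeros((6, 6, 6))
        b[0, 4, 3] = 1.0  # (x=3, y=4, z=0): distance 5 from origin voxel
        probe = DensityMap(a, apix=1.0)
        target = DensityMap(b, apix=1.0)
        assert chamfer_distance(probe, target, 0.5, 0.5) == pytest.approx(5.0)

    def test_matches_quadratic_brute_force(self, rng):
        a = DensityMap(rng.random((7, 7, 7)), apix=1.2)
        b = DensityMap(rng.random((7, 7, 7)), apix=1.2)
        got = chamfer_distance(a, b, 0.7, 0.7)
        from emscore import extract_surface

        x = extract_surface(a, 0.7, with_normals=False).coordinates()
        y = extract_surface(b, 0.7, with_normals=False).coordinates()
        assert len(x) <= 200 and len(y) <= 200
        assert got == pytest.approx(naive_chamfer(x, y), abs=1e-12)

    def test_asymmetric(self, rng):
        a = np.zeros((6, 6, 6))
        a[2, 2, 2] = 1.0
        b = np.zeros((6, 6, 6))
        b[2, 2, 2] = 1.0
        b[4, 4, 4] = 1.0
        pa, pb = DensityMap(a, apix=1.0), DensityMap(b, apix=1.0)
        assert chamfer_distance(pa, pb, 0.5, 0.5) != chamfer_distance(pb, pa, 0.5, 0.5)


class TestSegmentScores:
    @pytest.fixture
    def two_domain_case(self):
        model = make_toy_structure(30, "two-domain", hinge_angle=25.0)
        target = simulate_map(model, 8.0, apix=2.0)
        seg1 = SegmentSelection((("A", 1, 15),), label="d1")
        seg2 = SegmentSelection((("A", 16, 30),), label="d2")
        return model, target, seg1, seg2

    def test_whole_structure_segment_equals_masked_ccc(self, two_domain_case):
        model, target, _, _ = two_domain_case
        whole = SegmentSelection((("A", 1, 30),), label="all")
        from emscore import simulate_on_grid
        from emscore.scores import segment_mask

        probe = simulate_on_grid(model, 8.0, target)
        mask = segment_mask(model, whole, target, 8.0)
        assert sccc(model, whole, target, 8.0) == pytest.approx(
            ccc(probe, target, mask=mask), abs=1e-15
        )

    def test_perfect_fit_scores_one_everywhere(self, two_domain_case):
        model, target, seg1, seg2 = two_domain_case
        assert sccc(model, seg1, target, 8.0) == pytest.approx(1.0, abs=1e-9)
        assert sccc(model, seg2, target, 8.0) == pytest.approx(1.0, abs=1e-9)

    def test_displaced_domain_drops_most(self, two_domain_case):
        model, target, seg1, seg2 = two_domain_case
        # displace only domain 2 atoms by 6 Å
        coords = model.coords.copy()
        d2_idx = [i for i, a in enumerate(model.atoms) if a.res_seq >= 16]
        coords[d2_idx] += np.array([6.0, 0.0, 0.0])
        displaced = model.with_coords(coords)
        drop_moved = sccc(model, seg2, target, 8.0) - sccc(displaced, seg2, target, 8.0)
        drop_fixed = abs(sccc(model, seg1, target, 8.0) - sccc(displaced, seg1, target, 8.0))
        assert drop_moved > 0
        assert drop_fixed < drop_moved

    def test_smi_whole_structure_consistency(self, two_domain_case):
        model, target, _, _ = two_domain_case
        whole = SegmentSelection((("A", 1, 30),), label="all")
        from emscore import simulate_on_grid
        from emscore.scores import segment_mask

        probe = simulate_on_grid(model, 8.0, target)
        mask = segment_mask(model, whole, target, 8.0)
        assert smi(model, whole, target, 8.0) == pytest.approx(
            mutual_information(probe, target, mask=mask), abs=1e-15
        )

    def test_misplaced_segment_scores_lower_smi(self, two_domain_case):
        model, target, seg1, seg2 = two_domain_case
        coords = model.coords.copy()
        d2_idx = [i for i, a in enumerate(model.atoms) if a.res_seq >= 16]
        coords[d2_idx] += np.array([6.0, 0.0, 0.0])
        displaced = model.with_coords(coords)
        assert smi(displaced, seg2, target, 8.0) < smi(model, seg2, target, 8.0)


class TestScoreEnsemble:
    def test_identity_ranks_first_for_self_simulated_map(self, helix40):
        target = simulate_map(helix40, 10.0, apix=3.0)
        fits = generate_local_ensemble(helix40, 8, seed=3)
        table = score_ensemble(fits, helix40, target, 10.0, ["ccc"])
        assert table.rank_of("ccc", "model_0") == 1.0

    def test_single_fit_all_ranks_one(self, helix40):
        target = simulate_map(helix40, 10.0, apix=3.0)
        fits = [FitTransform.identity(fit_id="only")]
        table = score_ensemble(fits, helix40, target, 10.0, ["ccc", "mi", "cd"])
        assert all(table.ranks[n][0] == 1.0 for n in table.scores)

    def test_ranks_match_independent_sort(self, helix40):
        target = simulate_map(helix40, 10.0, apix=3.0)
        fits = generate_local_ensemble(helix40, 9, seed=7)
        table = score_ensemble(fits, helix40, target, 10.0, ["ccc", "cd"])
        ccc_vals = table.scores["CCC"]
        order = np.argsort(-ccc_vals)  # descending polarity
        expected = np.empty(len(ccc_vals))
        expected[order] = np.arange(1, len(ccc_vals) + 1)
        assert np.allclose(table.ranks["CCC"], expected)
        cd_vals = table.scores["CD"]
        order = np.argsort(cd_vals)  # ascending polarity
        expected[order] = np.arange(1, len(cd_vals) + 1)
        assert np.allclose(table.ranks["CD"], expected)

    def test_unknown_score_name_rejected(self, helix40):
        target = simulate_map(helix40, 10.0, apix=3.0)
        with pytest.raises(ValueError, match="unknown score"):
            score_ensemble([FitTransform.identity(fit_id="f")], helix40, target,
                           10.0, ["bogus"])

    def test_deterministic(self, helix40):
        target = simulate_map(helix40, 10.0, apix=3.0)
        fits = generate_local_ensemble(helix40, 5, seed=11)
        t1 = score_ensemble(fits, helix40, target, 10.0, ["ccc", "mi", "nv_s"])
        t2 = score_ensemble(fits, helix40, target, 10.0, ["ccc", "mi", "nv_s"])
        for name in t1.scores:
            assert np.array_equal(t1.scores[name], t2.scores[name])

    def test_tsv_round_trip(self, helix40, tmp_path):
        target = simulate_map(helix40, 10.0, apix=3.0)
        fits = generate_local_ensemble(helix40, 4, seed=5)
        table = score_ensemble(fits, helix40, target, 10.0, ["ccc", "mi"])
        p = tmp_path / "scores.tsv"
        table.to_tsv(p)
        from emscore import ScoreTable

        back = ScoreTable.from_tsv(p)
        assert back.fit_ids == table.fit_ids
        assert np.allclose(back.scores["CCC"], table.scores["CCC"], atol=1e-6)
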