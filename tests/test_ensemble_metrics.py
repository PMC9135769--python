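"""Homogeneity S_h, RDF/ruggedness, epitope RMSD, ensemble deviation,
hydropathy."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from topofold import (
    EpitopeDefinition,
    RDFProfile,
    StructureError,
    conformational_homogeneity,
    ensemble_average_deviation,
    epitope_rmsd,
    hydropathy_profile,
    radial_distribution,
    rdf_ruggedness,
    select_core_sidechains,
)


def _frames_with_pairwise_rmsd(d):
    """Two 4-point frames at plain (and superposed) RMSD exactly d."""
    base = np.array(
        [[0.0, 0, 0], [3.8, 0, 0], [0, 3.8, 0], [0, 0, 3.8]]
    )
    other = base.copy()
    # symmetric stretch: move two opposite points apart along x
    other[0, 0] -= d
    other[1, 0] += d
    # plain rmsd = sqrt((d^2 + d^2)/4) = d/sqrt(2); rescale to hit d
    scale = d / np.sqrt(np.mean(np.sum((other - base) ** 2, axis=1)))
    other = base + (other - base) * scale
    return np.stack([base, other])


class TestConformationalHomogeneity:
    def test_identical_frames_give_zero(self):
        frames = np.tile(np.random.default_rng(0).normal(size=(6, 3)), (4, 1, 1))
        report = conformational_homogeneity(frames)
        assert report.S_h == 0.0
        assert np.all(report.pairwise_rmsd == 0)

    def test_two_frames_at_unit_rmsd_give_half(self):
        frames = _frames_with_pairwise_rmsd(1.0)
        superposed = conformational_homogeneity(frames)
        # S_h sums both ordered pairs over N^2 = 4: 2 * rmsd / 4
        d = superposed.pairwise_rmsd[0, 1]
        assert superposed.S_h == pytest.approx(2 * d / 4)
        assert superposed.S_h <= 0.5 + 1e-9  # superposition cannot increase it

    def test_three_frames_all_pairs_equal_one(self, monkeypatch):
        # hand evaluation of the formula: 6 ordered pairs / 9
        import topofold.ensemble_metrics as em

        monkeypatch.setattr(em, "rmsd", lambda a, b, superpose=False: 1.0)
        frames = np.zeros((3, 5, 3))
        report = em.conformational_homogeneity(frames)
        assert report.S_h == pytest.approx(6.0 / 9.0)

    def test_matches_nested_loop_oracle_for_small_ensembles(self, rng):
        from scipy.spatial.transform import Rotation as Rot

        for n in (2, 3, 4, 5, 6):
            frames = rng.normal(size=(n, 7, 3)) * 2.0
            report = conformational_homogeneity(frames)
            total = 0.0
            for i in range(n):
                for j in range(n):
                    if i == j:
                        continue
                    a = frames[i] - frames[i].mean(axis=0)
                    b = frames[j] - frames[j].mean(axis=0)
                    _, rssd = Rot.align_vectors(b, a)
                    total += rssd / np.sqrt(len(a))
            assert report.S_h == pytest.approx(total / n**2, rel=1e-9)

    def test_rigid_motion_of_one_frame_leaves_S_h_unchanged(self, rng):
        frames = rng.normal(size=(3, 8, 3))
        moved = frames.copy()
        rot = Rotation.from_euler("xyz", [0.5, 1.0, -0.3]).as_matrix()
        moved[1] = moved[1] @ rot.T + np.array([4.0, 4.0, 4.0])
        a = conformational_homogeneity(frames).S_h
        b = conformational_homogeneity(moved).S_h
        assert a == pytest.approx(b, rel=1e-9)

    def test_scales_linearly_with_coordinates(self, rng):
        frames = rng.normal(size=(4, 6, 3))
        s1 = conformational_homogeneity(frames).S_h
        s3 = conformational_homogeneity(frames * 3.0).S_h
        assert s3 == pytest.approx(3.0 * s1, rel=1e-9)

    def test_pairs_denominator_option(self):
        frames = _frames_with_pairwise_rmsd(1.0)
        n2 = conformational_homogeneity(frames, denominator="n_squared")
        pairs = conformational_homogeneity(frames, denominator="pairs")
        assert pairs.S_h == pytest.approx(n2.S_h * 4 / 2)

    def test_works_on_perturbed_structure_ensemble(self, small_ensemble):
        report = conformational_homogeneity(small_ensemble)
        assert report.n_frames == 5
        assert report.S_h > 0
        np.testing.assert_allclose(report.pairwise_rmsd, report.pairwise_rmsd.T)


class TestRadialDistribution:
    def test_two_atoms_single_nonzero_bin(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        profile = radial_distribution(coords, r_max=4.0, bin_width=0.1)
        nonzero = np.nonzero(profile.g)[0]
        assert len(nonzero) == 1
        assert profile.r[nonzero[0]] == pytest.approx(2.05, abs=0.051)

    def test_uniform_cloud_is_flat_near_one(self):
        gen = np.random.default_rng(42)
        pts = gen.uniform(0, 10, size=(1000, 3))
        profile = radial_distribution(pts, r_max=4.0, bin_width=0.1, volume=1000.0)
        mid = (profile.r >= 1.0) & (profile.r <= 3.5)
        assert np.all(np.abs(profile.g[mid] - 1.0) < 0.1)

    def test_rigid_rotation_leaves_profile_unchanged(self, rng):
        pts = rng.normal(size=(200, 3)) * 4.0
        rot = Rotation.from_euler("zxz", [0.4, 1.2, -0.8]).as_matrix()
        p1 = radial_distribution(pts, r_max=4.0, bin_width=0.1)
        p2 = radial_distribution(pts @ rot.T + 3.0, r_max=4.0, bin_width=0.1)
        np.testing.assert_allclose(p1.g, p2.g, atol=1e-8)

    def test_single_atom_errors(self):
        with pytest.raises(StructureError):
            radial_distribution(np.zeros((1, 3)))


class TestRuggedness:
    def _profile(self, g):
        g = np.asarray(g, dtype=float)
        r = np.arange(len(g)) * 0.1 + 0.05
        return RDFProfile(r=r, g=g, bin_width=0.1)

    def test_constant_profile_is_zero(self):
        assert rdf_ruggedness(self._profile(np.ones(40))) == 0.0

    def test_single_step_equals_its_height(self):
        h = 2.5
        g = np.concatenate([np.zeros(20), np.full(20, h)])
        assert rdf_ruggedness(self._profile(g)) == pytest.approx(h)

    def test_linear_ramp_equals_total_rise(self):
        m = 0.7
        r = np.arange(40) * 0.1 + 0.05
        assert rdf_ruggedness(self._profile(m * r)) == pytest.approx(m * (r[-1] - r[0]))

    def test_profile_not_covering_range_errors(self):
        short = self._profile(np.ones(10))  # covers only [0, 1]
        with pytest.raises(ValueError, match="does not cover"):
            rdf_ruggedness(short)


class TestEpitopeRmsd:
    def _epitope(self, mode="backbone"):
        return EpitopeDefinition(
            residues=tuple(("A", i) for i in (2, 5, 8, 11, 30, 40, 50, 60)), mode=mode
        )

    def test_self_and_translated_copy_are_zero(self, bundle):
        assert epitope_rmsd(bundle, bundle, self._epitope()) == pytest.approx(0.0, abs=1e-12)
        moved = bundle.copy()
        moved.set_all_coords(bundle.all_coords() + np.array([3.0, -2.0, 9.0]))
        assert epitope_rmsd(moved, bundle, self._epitope()) == pytest.approx(0.0, abs=1e-9)

    def test_one_displaced_residue_against_alignment_oracle(self, bundle):
        from scipy.spatial.transform import Rotation as Rot

        from topofold import coords_for
        from topofold.ensemble_metrics import _epitope_coords

        epitope = self._epitope()
        moved = bundle.copy()
        for atom in moved.chains["A"][1].atoms:  # residue number 2
            atom.coords = atom.coords + np.array([0.0, 0.0, 1.0])
        value = epitope_rmsd(moved, bundle, epitope)

        model_coords, selection = _epitope_coords(moved, epitope)
        ref_coords = coords_for(bundle, selection)
        # before superposition: 3 of 24 atoms displaced by exactly 1 A
        plain = np.sqrt(np.mean(np.sum((model_coords - ref_coords) ** 2, axis=1)))
        assert plain == pytest.approx(np.sqrt(3 * 1.0**2 / 24), rel=1e-12)
        # optimal local alignment can only shrink it; independent oracle agrees
        a = model_coords - model_coords.mean(axis=0)
        b = ref_coords - ref_coords.mean(axis=0)
        _, rssd = Rot.align_vectors(b, a)
        assert value == pytest.approx(rssd / np.sqrt(len(a)), rel=1e-9)
        assert value <= plain

    def test_all_atom_mode_requires_matching_residue_names(self, bundle):
        renamed = bundle.copy()
        renamed.chains["A"][1].name = "ALA"
        with pytest.raises(StructureError, match="differs"):
            epitope_rmsd(renamed, bundle, self._epitope("all-atom"))

    def test_missing_epitope_residue_errors(self, bundle):
        bad = EpitopeDefinition(residues=(("A", 999),))
        with pytest.raises(StructureError):
            epitope_rmsd(bundle, bundle, bad)


class TestEnsembleAverageDeviation:
    def test_identical_frames_deviate_zero(self):
        frames = np.tile(np.random.default_rng(3).normal(size=(6, 3)), (3, 1, 1))
        mean_dev, per_frame = ensemble_average_deviation(frames)
        assert mean_dev == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(per_frame, 0.0)

    def test_two_frames_each_deviate_half_their_mutual_rmsd(self):
        base = np.array([[0.0, 0, 0], [3.8, 0, 0], [0, 3.8, 0], [0, 0, 3.8]])
        other = base.copy()
        other[0, 0] -= 1.0
        other[1, 0] += 1.0  # symmetric: centroid and orientation unchanged
        frames = np.stack([base, other])
        d = np.sqrt(np.mean(np.sum((base - other) ** 2, axis=1)))
        mean_dev, per_frame = ensemble_average_deviation(frames)
        np.testing.assert_allclose(per_frame, d / 2, rtol=1e-9)
        assert mean_dev == pytest.approx(d / 2, rel=1e-9)

    def test_mean_bounded_by_max_frame_deviation(self, small_ensemble):
        mean_dev, per_frame = ensemble_average_deviation(small_ensemble)
        assert mean_dev <= per_frame.max() + 1e-12

    def test_single_frame_errors(self):
        with pytest.raises(StructureError):
            ensemble_average_deviation(np.zeros((1, 5, 3)))


class TestHydropathy:
    def test_poly_ile_is_the_scale_constant_everywhere(self):
        centres, values = hydropathy_profile("I" * 15, window=9)
        np.testing.assert_allclose(values, 4.5)
        assert centres[0] == 5 and centres[-1] == 11

    def test_window_one_returns_per_residue_constants(self):
        _, values = hydropathy_profile("R", window=1)
        assert values[0] == pytest.approx(-4.5)

    def test_window_mean_against_hand_average(self):
        # KD constants: G -0.4, I 4.5, R -4.5
        _, values = hydropathy_profile("GIR", window=3)
        assert values[0] == pytest.approx((-0.4 + 4.5 - 4.5) / 3)

    @pytest.mark.parametrize(
        "seq,window,err",
        [("GG", 3, "exceeds"), ("GGGG", 2, "odd"), ("GXG", 3, "unknown")],
    )
    def test_invalid_inputs(self, seq, window, err):
        with pytest.raises(ValueError, match=err):
            hydropathy_profile(seq, window)


def test_core_selection_finds_buried_sidechains():
    from topofold import Atom, Residue, Structure

    gen = np.random.default_rng(5)
    residues = []
    # a tight cluster of 30 residues (buried) plus 4 distant ones (exposed)
    for i in range(34):
        centre = gen.normal(size=3) * 2.0 if i < 30 else np.array([80.0 + i, 0, 0])
        residues.append(
            Residue(
                number=i + 1,
                name="LEU",
                atoms=[
                    Atom("CA", "C", centre),
                    Atom("CB", "C", centre + [1.0, 0, 0]),
                    Atom("CG", "C", centre + [2.0, 0, 0]),
                ],
            )
        )
    s = Structure(chains={"A": residues})
    selection = select_core_sidechains(s, neighbor_radius=10.0, min_neighbors=16)
    chosen = {num for _, num, _, _ in selection}
    assert chosen == set(range(1, 31))
    assert all(name in ("CB", "CG") for *_, name in selection)
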