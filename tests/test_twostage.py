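import numpy as np
import pytest
from scipy.spatial.distance import cdist, pdist

from hicstitch import (
    AlphaEstimate,
    ChromReconstruction,
    Configuration3D,
    ContactMap,
    SimilarityTransform,
    bin_genome,
    build_hybrid,
    build_plan,
    procrustes_fit,
    procrustes_rmsd,
    radius_of_gyration,
    reconstruct_chromosomes,
    reconstruct_genome,
    sample_aggregate,
    sample_equispaced,
    sample_pc1,
    simulate_contacts,
    simulate_structure,
    thin_to_resolution,
)


def rotation_z(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])


class TestSampleEquispaced:
    def test_half_fraction(self):
        assert sample_equispaced(10, 0.5, 0).tolist() == [0, 2, 4, 6, 8]

    def test_full_fraction(self):
        assert sample_equispaced(10, 1.0).tolist() == list(range(10))

    def test_tenth_with_offset(self):
        # oracle: arithmetic progression 3, 13, ..., 93
        idx = sample_equispaced(95, 0.1, 3)
        assert idx.tolist() == list(range(3, 95, 10))
        assert len(idx) == 10

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="larger fraction"):
            sample_equispaced(5, 0.1)

    def test_offset_out_of_range(self):
        with pytest.raises(ValueError):
            sample_equispaced(10, 0.5, 2)


class TestSampleAggregate:
    def test_collinear_centroids(self):
        # oracle: centroid arithmetic on x = 0,1,2,3 grouped in pairs
        coords = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        reps, groups = sample_aggregate(coords, 0.5)
        assert np.allclose(reps[:, 0], [0.5, 2.5])
        assert [g.tolist() for g in groups] == [[0, 1], [2, 3]]

    def test_identity_at_full_fraction(self, rng):
        coords = rng.normal(size=(6, 3))
        reps, groups = sample_aggregate(coords, 1.0)
        assert np.array_equal(reps, coords)
        assert all(len(g) == 1 for g in groups)

    def test_trailing_short_group(self):
        coords = np.zeros((5, 3))
        _, groups = sample_aggregate(coords, 0.5)
        assert [len(g) for g in groups] == [2, 2, 1]


class TestSamplePC1:
    def test_line_ordering(self):
        t = np.linspace(0, 1, 8)
        coords = np.column_stack([t, 2 * t, -t])
        idx = sample_pc1(coords, 1.0)
        assert idx.tolist() == list(range(8))

    def test_helix_rank_selection(self):
        # oracle: projection + rank selection on a 10-point helix
        t = np.linspace(0, 4 * np.pi, 10)
        coords = np.column_stack([np.cos(t), np.sin(t), t])
        idx = sample_pc1(coords, 0.3)
        proj = (coords - coords.mean(0)) @ np.linalg.svd(coords - coords.mean(0))[2][0]
        order = np.argsort(proj)
        # selected points are ~ the 1st, middle, and last order statistics
        assert order[0] in idx or order[1] in idx
        assert order[4] in idx or order[5] in idx
        assert order[-1] in idx or order[-2] in idx
        assert len(idx) == 3

    def test_degenerate_falls_back(self):
        coords = np.ones((6, 3))
        with pytest.warns(RuntimeWarning, match="degenerate"):
            idx = sample_pc1(coords, 0.5)
        assert idx.tolist() == [0, 2, 4]

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            sample_pc1(np.zeros((2, 3)), 1.0)


def make_recs_and_map(alpha1=1.0, alpha2=1.0, cross_value=2.0):
    """Two chromosomes with 3 sampled points each and one known cross pair."""
    bins = bin_genome({"c1": 30, "c2": 30}, 10)
    coords1 = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
    coords2 = np.array([[0.0, 0, 1], [2, 0, 1], [0, 2, 1]])
    recs = {
        "c1": ChromReconstruction(
            "c1",
            Configuration3D(coords1, np.arange(3)),
            AlphaEstimate(alpha1, (alpha1, alpha1), 0.0, 1),
            0.0,
        ),
        "c2": ChromReconstruction(
            "c2",
            Configuration3D(coords2, np.arange(3, 6)),
            AlphaEstimate(alpha2, (alpha2, alpha2), 0.0, 1),
            0.0,
        ),
    }
    entries = [(0, 3, cross_value), (1, 4, 1.0), (2, 5, 1.0), (0, 4, 1.0), (1, 5, 1.0)]
    i, j, v = zip(*entries)
    cmap = ContactMap(bins, i, j, v)
    plan = build_plan(recs, scheme="equispaced", fraction=1.0)
    return recs, cmap, plan


class TestBuildHybrid:
    def test_cross_term_equal_alphas(self):
        recs, cmap, plan = make_recs_and_map(1.0, 1.0, cross_value=2.0)
        hd = build_hybrid(recs, plan, cmap, zero_mode="pseudocount")
        assert hd.matrix[0, 3] == pytest.approx(0.5)  # 2 ** -sqrt(1)

    def test_cross_term_mixed_alphas(self):
        # oracle: exponent sqrt(1*4) = 2, so 2 ** -2 = 0.25
        recs, cmap, plan = make_recs_and_map(1.0, 4.0, cross_value=2.0)
        hd = build_hybrid(recs, plan, cmap, zero_mode="pseudocount")
        assert hd.matrix[0, 3] == pytest.approx(0.25)

    def test_intra_block_euclidean_not_powerlaw(self):
        recs, cmap, plan = make_recs_and_map()
        hd = build_hybrid(recs, plan, cmap)
        want = cdist(recs["c1"].config.coords, recs["c1"].config.coords)
        assert np.array_equal(hd.matrix[:3, :3], want)

    def test_symmetric_zero_diagonal(self):
        recs, cmap, plan = make_recs_and_map(1.0, 2.0)
        hd = build_hybrid(recs, plan, cmap)
        assert np.array_equal(hd.matrix, hd.matrix.T)
        assert np.all(np.diag(hd.matrix) == 0)

    def test_penalty_mode_infinite_zeros(self):
        recs, cmap, plan = make_recs_and_map()
        hd = build_hybrid(recs, plan, cmap, zero_mode="infinite")
        # cross pair (2, 3) has no recorded contact
        assert np.isinf(hd.matrix[2, 3])

    def test_nonhybrid_intra_uses_power_law(self):
        recs, cmap, plan = make_recs_and_map()
        hd = build_hybrid(recs, plan, cmap, hybrid=False)
        # no intra contacts recorded -> pseudocount distances, not Euclidean
        euclid = cdist(recs["c1"].config.coords, recs["c1"].config.coords)
        assert not np.allclose(hd.matrix[:3, :3], euclid)


class TestProcrustesFit:
    def test_identity(self, rng):
        pts = rng.normal(size=(5, 3))
        tr = procrustes_fit(pts, pts)
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-9)
        assert tr.scale == pytest.approx(1.0)
        assert np.allclose(tr.translation, 0.0, atol=1e-9)

    def test_recovers_constructed_transform(self, rng):
        # oracle: build transform, apply, recover
        pts = rng.normal(size=(7, 3))
        R = rotation_z(np.pi / 2)
        target = 2.0 * pts @ R.T + np.array([1.0, 2.0, 3.0])
        tr = procrustes_fit(pts, target)
        assert np.allclose(tr.rotation, R, atol=1e-9)
        assert tr.scale == pytest.approx(2.0)
        assert np.allclose(tr.translation, [1, 2, 3], atol=1e-9)
        assert np.allclose(tr.apply(pts), target, atol=1e-10)

    def test_reflection_toggle(self, rng):
        pts = rng.normal(size=(6, 3))
        reflected = pts * np.array([1.0, 1.0, -1.0])
        tr = procrustes_fit(pts, reflected, allow_reflection=True)
        assert np.allclose(tr.apply(pts), reflected, atol=1e-10)
        tr_no = procrustes_fit(pts, reflected, allow_reflection=False)
        residual = np.abs(tr_no.apply(pts) - reflected).max()
        assert residual > 1e-3

    def test_cardinality_mismatch(self, rng):
        with pytest.raises(ValueError):
            procrustes_fit(rng.normal(size=(4, 3)), rng.normal(size=(5, 3)))

    def test_too_few_points(self, rng):
        with pytest.raises(ValueError):
            procrustes_fit(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))

    def test_collinear_warns(self):
        pts = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
        with pytest.warns(RuntimeWarning, match="collinear"):
            procrustes_fit(pts, pts * 2.0)

    def test_orthogonality_invariant(self, rng):
        src, dst = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
        tr = procrustes_fit(src, dst)
        assert np.allclose(tr.rotation.T @ tr.rotation, np.eye(3), atol=1e-9)


class TestSimilarityTransform:
    def test_validates_orthogonality(self):
        with pytest.raises(ValueError):
            SimilarityTransform(np.eye(3) * 2, 1.0, np.zeros(3))

    def test_validates_scale(self):
        with pytest.raises(ValueError):
            SimilarityTransform(np.eye(3), -1.0, np.zeros(3))


class TestReconstructGenome:
    def test_single_chromosome_identity(self):
        g = simulate_structure(1, 12, territory_spacing=5.0, chain_step=1.0, seed=3)
        cmap = simulate_contacts(g, alpha_true=1.0, count_scale=1.0)
        recon = reconstruct_genome(cmap, seed=5)
        assert recon.coarse is None
        tr = recon.transforms["chr1"]
        assert np.array_equal(tr.rotation, np.eye(3))
        assert tr.scale == 1.0
        stage1 = recon.stage1["chr1"].config.coords
        assert np.array_equal(recon.chrom_configs["chr1"].coords, stage1)

    def test_noise_free_full_fraction_recovery(
        self, small_genome, small_noisefree_map
    ):
        recon = reconstruct_genome(small_noisefree_map, fraction=1.0, seed=2)
        truth = small_genome.truth_configuration()
        rmsd = procrustes_rmsd(truth, recon.configuration())
        assert rmsd <= 0.05 * radius_of_gyration(truth)

    def test_sampling_closer_than_replicate(self, small_genome):
        # fractions 0.5 vs 1.0 differ less than either differs from a
        # re-noised replicate reconstruction
        cm = simulate_contacts(
            small_genome, alpha_true=1.0, count_scale=100.0, noise="poisson", seed=10
        )
        r_half = reconstruct_genome(cm, fraction=0.5, seed=1)
        r_full = reconstruct_genome(cm, fraction=1.0, seed=1)
        cm_rep = simulate_contacts(
            small_genome, alpha_true=1.0, count_scale=100.0, noise="poisson", seed=77
        )
        r_rep = reconstruct_genome(cm_rep, fraction=1.0, seed=1)
        d_sampling = procrustes_rmsd(r_half.configuration(), r_full.configuration())
        d_rep = procrustes_rmsd(r_full.configuration(), r_rep.configuration())
        assert d_sampling < d_rep

    def test_coverage_and_geometry_preservation(self, small_noisefree_map):
        recon = reconstruct_genome(small_noisefree_map, fraction=0.5, seed=4)
        coords = recon.coords()
        assert coords.shape == (small_noisefree_map.bins.n_bins, 3)
        assert np.all(np.isfinite(coords))
        # similarity transform preserves all pairwise distance ratios
        for chrom, rec in recon.stage1.items():
            before = pdist(rec.config.coords)
            after = pdist(recon.chrom_configs[chrom].coords)
            ratio = after / before
            assert np.allclose(ratio, ratio[0], rtol=1e-9)

    def test_stitch_residual_is_procrustes_minimum(self, small_noisefree_map):
        from hicstitch.twostage import _sampled_points

        recon = reconstruct_genome(small_noisefree_map, fraction=0.5, seed=4)
        for chrom in recon.bins.chrom_names:
            rec = recon.stage1[chrom]
            src = _sampled_points(rec, recon.plan)
            offset = 0
            for c in recon.plan.chroms:
                if c == chrom:
                    break
                offset += recon.plan.m_k(c)
            sl = slice(offset, offset + recon.plan.m_k(chrom))
            target = recon.coarse.coords[sl]
            stored = recon.transforms[chrom]
            res_stored = ((stored.apply(src) - target) ** 2).sum()
            refit = procrustes_fit(src, target)
            res_refit = ((refit.apply(src) - target) ** 2).sum()
            assert res_stored <= res_refit + 1e-12

    def test_hybrid_intra_blocks_bit_exact(self, small_noisefree_map):
        recs = reconstruct_chromosomes(small_noisefree_map, seed=0)
        plan = build_plan(recs, scheme="equispaced", fraction=0.5)
        hd = build_hybrid(recs, plan, small_noisefree_map)
        from hicstitch.twostage import _sampled_points

        for chrom, rec in recs.items():
            pts = _sampled_points(rec, plan)
            sl = hd.block_slices[chrom]
            assert np.array_equal(hd.matrix[sl, sl], cdist(pts, pts))

    @pytest.mark.parametrize("scheme", ["equispaced", "aggregate", "pc1"])
    def test_all_schemes_run(self, small_genome, small_noisefree_map, scheme):
        recon = reconstruct_genome(
            small_noisefree_map, scheme=scheme, fraction=0.5, seed=6
        )
        truth = small_genome.truth_configuration()
        rmsd = procrustes_rmsd(truth, recon.configuration())
        # noise-free: every scheme should land very close to the truth
        assert rmsd <= 0.05 * radius_of_gyration(truth)

    def test_fraction_too_small_rejected(self, small_noisefree_map):
        with pytest.raises(ValueError):
            reconstruct_genome(small_noisefree_map, fraction=0.05, seed=0)


class TestThinToResolution:
    def _fine_recon(self):
        g = simulate_structure(
            2, [12, 8], territory_spacing=15.0, chain_step=1.0, seed=9,
            resolution=500_000,
        )
        cm = simulate_contacts(g, alpha_true=1.0, count_scale=1.0)
        return reconstruct_genome(cm, fraction=1.0, seed=1)

    def test_every_other_point(self):
        recon = self._fine_recon()
        coarse_bins = bin_genome(
            {c: recon.bins.chrom_length(c) for c in recon.bins.chrom_names}, 1_000_000
        )
        thinned, idx = thin_to_resolution(recon, coarse_bins)
        # 500 kb -> 1 Mb selects every other fine bin within each chromosome
        assert idx.tolist() == [0, 2, 4, 6, 8, 10, 12, 14, 16, 18]
        assert thinned.n_points == coarse_bins.n_bins

    def test_equal_resolution_identity(self):
        recon = self._fine_recon()
        thinned, idx = thin_to_resolution(recon, recon.bins)
        assert idx.tolist() == list(range(recon.bins.n_bins))
        assert np.array_equal(thinned.coords, recon.coords())

    def test_non_divisible_rejected(self):
        recon = self._fine_recon()
        coarse_bins = bin_genome(
            {c: recon.bins.chrom_length(c) for c in recon.bins.chrom_names}, 750_000
        )
        with pytest.raises(ValueError, match="divide"):
            thin_to_resolution(recon, coarse_bins)


class TestWriteRead:
    def test_write_outputs(self, tmp_path, small_noisefree_map):
        recon = reconstruct_genome(small_noisefree_map, fraction=0.5, seed=0)
        recon.write(tmp_path / "run")
        assert (tmp_path / "run" / "genome.tsv").exists()
        assert (tmp_path / "run" / "coarse.tsv").exists()
        assert (tmp_path / "run" / "meta.json").exists()
        import json

        meta = json.loads((tmp_path / "run" / "meta.json").read_text())
        assert set(meta["alphas"]) == set(small_noisefree_map.bins.chrom_names)
        from hicstitch import read_configuration

        cfg = read_configuration(tmp_path / "run" / "genome.tsv")
        assert np.allclose(cfg.coords, recon.coords())
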