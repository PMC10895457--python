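"""Distance-fluctuation statistic, coarse views and difference maps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from allofluct import synthetic
from allofluct.dfa import (
    DFMatrix,
    block_average,
    compute_df,
    df_difference,
    per_residue_profile,
    quantize,
)
from allofluct.ensemble import Ensemble, select, superpose
from conftest import brute_force_df, make_chain_model, random_rotation


def _ensemble_from_frames(frames):
    struct = synthetic.make_ca_structure(frames[0])
    f = frames.shape[0]
    return Ensemble(struct, frames, np.array(["r1"] * f), np.arange(1.0, f + 1))


@pytest.fixture(scope="module")
def harmonic_ensemble():
    model = make_chain_model(8, seed=7)
    return synthetic.sample_harmonic_ensemble(model, 300, 1)


class TestComputeDF:
    def test_rigid_ensemble_is_all_zero(self):
        frame = np.random.default_rng(0).normal(0, 5, size=(6, 3))
        ens = _ensemble_from_frames(np.repeat(frame[None], 10, axis=0))
        df = compute_df(ens, select(ens.reference, "calpha"))
        assert np.all(df.values == 0.0)

    def test_two_site_analytic_variance(self):
        # separation 1 A in half the frames, 3 A in the other half
        frames = np.zeros((10, 2, 3))
        frames[:5, 1, 0] = 1.0
        frames[5:, 1, 0] = 3.0
        ens = _ensemble_from_frames(frames)
        df = compute_df(ens, select(ens.reference, "calpha"))
        assert df.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_matches_bruteforce_oracle(self, harmonic_ensemble):
        sel = select(harmonic_ensemble.reference, "calpha")
        df = compute_df(harmonic_ensemble, sel)
        oracle = brute_force_df(harmonic_ensemble.frames)
        np.testing.assert_allclose(df.values, oracle, atol=1e-10)

    def test_invariant_to_rigid_body_motion(self, harmonic_ensemble):
        sel = select(harmonic_ensemble.reference, "calpha")
        base = compute_df(harmonic_ensemble, sel)
        rng = np.random.default_rng(5)
        moved = np.array(
            [f @ random_rotation(rng).T + rng.normal(0, 30, 3)
             for f in harmonic_ensemble.frames]
        )
        ens2 = Ensemble(harmonic_ensemble.reference, moved,
                        harmonic_ensemble.replicas, harmonic_ensemble.times)
        np.testing.assert_allclose(compute_df(ens2, sel).values, base.values,
                                   atol=1e-9)

    def test_invariant_under_superposition(self, harmonic_ensemble):
        sel = select(harmonic_ensemble.reference, "calpha")
        base = compute_df(harmonic_ensemble, sel)
        fitted = superpose(harmonic_ensemble, sel)
        np.testing.assert_allclose(compute_df(fitted, sel).values, base.values,
                                   atol=1e-9)

    def test_permutation_equivariance(self, harmonic_ensemble):
        sel = select(harmonic_ensemble.reference, "calpha")
        base = compute_df(harmonic_ensemble, sel)
        perm = np.array([3, 1, 4, 0, 7, 5, 2, 6])
        ref = harmonic_ensemble.reference
        struct2 = synthetic.make_ca_structure(ref.coords[perm])
        struct2.resids = ref.resids[perm]  # keep author numbering attached
        ens2 = Ensemble(struct2, harmonic_ensemble.frames[:, perm, :],
                        harmonic_ensemble.replicas, harmonic_ensemble.times)
        df2 = compute_df(ens2, select(struct2, "calpha"))
        np.testing.assert_allclose(df2.values, base.values[np.ix_(perm, perm)],
                                   atol=1e-12)

    def test_monotone_coordination_in_stiffness(self):
        dfs = []
        for k in (0.1, 1.0, 10.0):
            model = synthetic.HarmonicModel(
                np.array([[0.0, 0, 0], [5.0, 0, 0]]), [(0, 1, k)],
                sigma=0.5, seed=3,
            )
            ens = synthetic.sample_harmonic_ensemble(model, 20_000, 1)
            df = compute_df(ens, select(ens.reference, "calpha"))
            dfs.append(df.values[0, 1])
        assert dfs[0] > dfs[1] > dfs[2]

    def test_metatrajectory_equals_pooled_replica_variance(self):
        model = make_chain_model(6, seed=17)
        ens = synthetic.sample_harmonic_ensemble(model, 100, 3)
        sel = select(ens.reference, "calpha")
        pooled = compute_df(ens, sel).values
        # pooled variance from per-replica sufficient statistics
        f_tot = 0
        stats = []
        for rep in ens.replica_names:
            sub = Ensemble(ens.reference, ens.replica_frames(rep),
                           np.array([rep] * 100), np.arange(1.0, 101))
            d = compute_df(sub, sel)
            mu = _pair_means(sub, sel)
            stats.append((100, mu, d.values))
            f_tot += 100
        grand = sum(f * mu for f, mu, _ in stats) / f_tot
        recon = sum(f * (v + (mu - grand) ** 2) for f, mu, v in stats) / f_tot
        np.testing.assert_allclose(recon, pooled, atol=1e-9)

    def test_single_frame_rejected(self):
        frame = np.random.default_rng(1).normal(size=(4, 3))
        ens = _ensemble_from_frames(frame[None])
        with pytest.raises(ValueError, match="2 frames"):
            compute_df(ens, select(ens.reference, "calpha"))

    def test_std_convention_is_square_root(self, harmonic_ensemble):
        sel = select(harmonic_ensemble.reference, "calpha")
        var = compute_df(harmonic_ensemble, sel)
        std = compute_df(harmonic_ensemble, sel, convention="std")
        np.testing.assert_allclose(std.values, np.sqrt(var.values), atol=1e-12)

    def test_tsv_roundtrip(self, harmonic_ensemble, tmp_path):
        sel = select(harmonic_ensemble.reference, "calpha")
        df = compute_df(harmonic_ensemble, sel)
        df.to_tsv(tmp_path / "df.tsv")
        back = DFMatrix.from_tsv(tmp_path / "df.tsv")
        np.testing.assert_allclose(back.values, df.values, rtol=1e-9)
        assert back.labels == df.labels


def _pair_means(ensemble, sel):
    from scipy.spatial.distance import pdist, squareform

    d = np.mean([squareform(pdist(f)) for f in ensemble.frames[:, sel.indices]],
                axis=0)
    return d


def _random_df(n, seed=0):
    rng = np.random.default_rng(seed)
    v = np.abs(rng.normal(1.0, 0.5, size=(n, n)))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return DFMatrix(v, [("A", i + 1) for i in range(n)], n_frames=10)


class TestBlockAverage:
    def test_constant_matrix_gives_constant_blocks(self):
        df = _random_df(80)
        df.values[:] = 3.5
        np.fill_diagonal(df.values, 3.5)  # constant including diagonal
        blk = block_average(df, 40)
        assert blk.values.shape == (2, 2)
        np.testing.assert_allclose(blk.values, 3.5)

    def test_80_residues_block_40(self):
        df = _random_df(80, seed=2)
        blk = block_average(df, 40)
        np.testing.assert_allclose(
            blk.values[0, 1], df.values[0:40, 40:80].mean(), atol=0
        )

    @pytest.mark.parametrize("n,bs", [(100, 40), (17, 5), (7, 10)])
    def test_partial_edge_blocks_match_naive_loop(self, n, bs):
        df = _random_df(n, seed=n)
        blk = block_average(df, bs)
        b = -(-n // bs)
        assert blk.values.shape == (b, b)
        for p in range(b):
            for q in range(b):
                sub = df.values[p * bs:(p + 1) * bs, q * bs:(q + 1) * bs]
                assert blk.values[p, q] == np.sum(sub) / sub.size

    def test_oversized_block_collapses_to_single_value(self):
        df = _random_df(7)
        blk = block_average(df, 10)
        assert blk.values.shape == (1, 1)


class TestQuantize:
    def test_equal_width_identity(self):
        from allofluct.dfa import BlockDFMatrix

        blk = BlockDFMatrix(
            values=np.add.outer(np.arange(5.0), np.zeros(5)),
            block_size=1,
            block_labels=[str(i) for i in range(5)],
        )
        q = quantize(blk, 5)
        np.testing.assert_array_equal(q.quantized[:, 0], [0, 1, 2, 3, 4])

    def test_constant_matrix_all_level_zero(self):
        df = _random_df(6)
        df.values[:] = 2.0
        q = quantize(block_average(df, 2), 5)
        assert np.all(q.quantized == 0)

    @given(st.integers(0, 2**31 - 1), st.integers(2, 8))
    @settings(max_examples=25, deadline=None)
    def test_every_value_lies_inside_its_bin(self, seed, levels):
        df = _random_df(12, seed=seed)
        blk = block_average(df, 4)
        q = quantize(blk, levels)
        vmin, vmax = blk.values.min(), blk.values.max()
        width = (vmax - vmin) / levels
        for v, lev in zip(blk.values.ravel(), q.quantized.ravel()):
            assert 0 <= lev < levels
            assert vmin + lev * width <= v + 1e-12
            assert v <= vmin + (lev + 1) * width + 1e-12


class TestDifferenceAndProfile:
    def test_self_difference_is_zero_and_swap_antisymmetric(self):
        a, b = _random_df(10, 1), _random_df(10, 2)
        assert np.all(df_difference(a, a) == 0.0)
        np.testing.assert_array_equal(df_difference(a, b), -df_difference(b, a))

    def test_label_mismatch_reports_first_disagreement(self):
        a = _random_df(5)
        b = _random_df(5)
        b.labels[2] = ("B", 99)
        with pytest.raises(ValueError, match="position 2"):
            df_difference(a, b)

    def test_planted_decoupled_block_dominates_difference(self):
        """State lacking a block of springs shows its largest positive DF
        differences concentrated in that block."""
        n = 40
        base = (
            [(i, i + 1, 4.0) for i in range(n - 1)]
            + [(i, i + 2, 2.0) for i in range(n - 2)]
            + [(i, i + 20, 3.0) for i in range(4, 10)]  # persistent anchors
        )
        planted = [(i, j, 3.0) for i in range(12, 18) for j in range(32, 38)]
        coords = synthetic.helical_coords(n)
        coupled = synthetic.HarmonicModel(coords, base + planted, sigma=0.6,
                                          seed=31)
        uncoupled = synthetic.HarmonicModel(coords, base, sigma=0.6, seed=32)
        dfs = []
        for model in (uncoupled, coupled):
            ens = synthetic.sample_harmonic_ensemble(model, 1000, 1)
            sel = select(ens.reference, "calpha")
            dfs.append(compute_df(ens, sel))
        diff = df_difference(dfs[0], dfs[1])
        mask = np.zeros((n, n), bool)
        mask[12:18, 32:38] = True
        iu = np.triu_indices(n, 1)
        vals, m = diff[iu], mask[iu]
        top = vals >= np.quantile(vals, 0.9)
        enrichment = m[top].mean() / m.mean()
        assert enrichment >= 5.0

    def test_profile_trivial_cases(self):
        df = _random_df(3)
        df.values = np.full((3, 3), 2.0)
        np.fill_diagonal(df.values, 0.0)
        np.testing.assert_allclose(per_residue_profile(df), [2.0, 2.0, 2.0])
        df.values[:] = 0.0
        np.testing.assert_allclose(per_residue_profile(df), 0.0)

    def test_subset_profile_matches_masked_mean(self):
        df = _random_df(12, seed=9)
        partners = [2, 5, 7]
        prof = per_residue_profile(df, partners=partners)
        for i in range(12):
            cols = [j for j in partners if j != i]
            assert prof[i] == df.values[i, cols].mean()

    def test_empty_partner_subset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            per_residue_profile(_random_df(4), partners=[])
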