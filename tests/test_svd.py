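"""Spectra-matrix construction, SVD identities, RMS ranking, reconstruction."""

import numpy as np
import pytest

from ramanzlsr import (
    HyperStack,
    SpectraMatrix,
    build_matrix,
    decompose,
    eigenspectra_to_csv,
    rank_components,
    reconstruct,
    s_rmsd,
    unflatten,
)
from ramanzlsr.synthetic import (
    FullField,
    GaussianPeak,
    PhantomSpec,
    Rectangle,
    Region,
    generate_phantom,
)


def _decompose_random(rng, w=20, p=30):
    A = rng.normal(size=(w, p))
    return A, decompose(SpectraMatrix(A.copy(), x_extent=p, y_extent=1))


class TestBuildMatrix:
    def test_single_pixel_stack_is_column(self, rng):
        s = rng.normal(size=7)
        stack = HyperStack(s.reshape(1, 1, 7), wavenumbers=np.arange(7.0))
        m = build_matrix(stack)
        assert m.data.shape == (7, 1)
        np.testing.assert_array_equal(m.data[:, 0], s)

    def test_column_order_x_fastest(self, rng):
        stack = HyperStack(rng.normal(size=(3, 2, 4)), wavenumbers=np.arange(4.0))
        m = build_matrix(stack)
        for x in range(3):
            for y in range(2):
                j = y * 3 + x
                np.testing.assert_array_equal(m.data[:, j], stack.data[x, y])

    def test_round_trip_bit_identical(self, random_stack):
        m = build_matrix(random_stack)
        back = unflatten(m.data, m.x_extent, m.y_extent, m.wavenumbers)
        np.testing.assert_array_equal(back.data, random_stack.data)

    def test_inconsistent_extents_rejected(self):
        with pytest.raises(ValueError):
            SpectraMatrix(np.zeros((5, 6)), x_extent=2, y_extent=2)


class TestDecompose:
    def test_rank_one_matrix(self, rng):
        u = rng.uniform(0.5, 2.0, 12)
        v = rng.uniform(0.5, 2.0, 20)
        A = np.outer(u, v)
        decomp = decompose(SpectraMatrix(A, x_extent=20, y_extent=1))
        s = decomp.singular_values
        assert (s[1:] <= 1e-10 * s[0]).all()
        recon = reconstruct(decomp, [0], 20, 1)
        flat = build_matrix(recon).data
        np.testing.assert_allclose(flat, A, rtol=1e-10, atol=1e-10 * s[0])

    def test_diagonal_matrix_singular_values(self):
        A = np.diag([3.0, 1.0])
        decomp = decompose(SpectraMatrix(A, x_extent=2, y_extent=1))
        np.testing.assert_allclose(decomp.singular_values, [3.0, 1.0], atol=1e-12)

    def test_orthonormality_and_reconstruction(self, rng):
        A, decomp = _decompose_random(rng)
        K = decomp.n_components
        np.testing.assert_allclose(decomp.U.T @ decomp.U, np.eye(K), atol=1e-8)
        np.testing.assert_allclose(decomp.V.T @ decomp.V, np.eye(K), atol=1e-8)
        full = (decomp.U * decomp.singular_values) @ decomp.V.T
        assert np.linalg.norm(full - A) / np.linalg.norm(A) <= 1e-8

    def test_singular_values_non_increasing_and_nonnegative(self, rng):
        _, decomp = _decompose_random(rng)
        s = decomp.singular_values
        assert (np.diff(s) <= 0).all() and (s >= 0).all()

    def test_frobenius_conservation(self, rng):
        A, decomp = _decompose_random(rng)
        assert np.sum(A**2) == pytest.approx(
            np.sum(decomp.singular_values**2), rel=1e-8
        )

    def test_sign_convention(self, rng):
        _, decomp = _decompose_random(rng)
        lead = np.argmax(np.abs(decomp.U), axis=0)
        assert (decomp.U[lead, np.arange(decomp.n_components)] > 0).all()

    def test_non_finite_rejected(self):
        A = np.zeros((3, 4))
        A[1, 2] = np.nan
        with pytest.raises(ValueError):
            decompose(SpectraMatrix(A, x_extent=4, y_extent=1))


class TestSRmsd:
    def test_printed_formula(self):
        assert s_rmsd([3.0, 4.0]) == pytest.approx(np.sqrt(25.0 / 2.0))

    def test_zero_vector(self):
        assert s_rmsd(np.zeros(10)) == 0.0


def _two_component_phantom(seed=7):
    spec = PhantomSpec(
        x_extent=32, y_extent=32, w_extent=200,
        wavenumber_range=(2500.0, 3100.0),
        regions=[
            Region("background", FullField(), [], baseline=0.0),
            Region("A", Rectangle(2, 2, 14, 30),
                   [GaussianPeak(2850.0, 40.0, 8.0)]),
            Region("B", Rectangle(18, 2, 30, 30),
                   [GaussianPeak(2950.0, 40.0, 8.0)]),
        ],
        noise_sigma=1.0, seed=seed,
    )
    return generate_phantom(spec), spec


class TestRanking:
    def test_signal_components_in_top3(self):
        # nearly equal singular values let the SVD rotate the two signal
        # eigenspectra within their 2-D subspace, so the check is that the
        # span of the top-3 ranked eigenspectra captures each true profile
        (stack, _), spec = _two_component_phantom()
        decomp = decompose(build_matrix(stack))
        Q = decomp.U[:, rank_components(decomp).top(3)]
        for region in spec.regions[1:]:
            profile = region.profile(spec.wavenumbers)
            captured = np.linalg.norm(Q.T @ profile) / np.linalg.norm(profile)
            assert captured >= 0.95, f"{region.name} not represented in top 3"

    def test_order_sorts_scores_descending(self, rng):
        _, decomp = _decompose_random(rng)
        ranking = rank_components(decomp)
        sorted_scores = ranking.scores[ranking.order]
        assert (np.diff(sorted_scores) <= 1e-15).all()

    def test_raw_eigenvector_mode_is_degenerate(self, rng):
        # unit-norm eigenspectra make the literal RMS score constant 1/sqrt(W)
        _, decomp = _decompose_random(rng, w=25, p=40)
        ranking = rank_components(decomp, mode="raw_eigenvector")
        np.testing.assert_allclose(ranking.scores, 1.0 / np.sqrt(25), atol=1e-8)

    def test_ranking_invariant_to_sign_flips(self, rng):
        _, decomp = _decompose_random(rng)
        flipped = type(decomp)(
            U=-decomp.U, singular_values=decomp.singular_values, V=-decomp.V,
            x_extent=decomp.x_extent, y_extent=decomp.y_extent,
        )
        r1 = rank_components(decomp)
        r2 = rank_components(flipped)
        np.testing.assert_allclose(r1.scores, r2.scores, atol=1e-12)

    def test_unknown_mode_rejected(self, rng):
        _, decomp = _decompose_random(rng)
        with pytest.raises(ValueError):
            rank_components(decomp, mode="bogus")


class TestReconstruct:
    def test_all_components_reproduce_stack(self, random_stack):
        decomp = decompose(build_matrix(random_stack))
        recon = reconstruct(decomp, range(decomp.n_components))
        err = (np.linalg.norm(recon.data - random_stack.data)
               / np.linalg.norm(random_stack.data))
        assert err <= 1e-8

    def test_disjoint_sets_sum_to_full(self, random_stack):
        decomp = decompose(build_matrix(random_stack))
        K = decomp.n_components
        a = reconstruct(decomp, range(0, K // 2))
        b = reconstruct(decomp, range(K // 2, K))
        full = reconstruct(decomp, range(K))
        np.testing.assert_allclose(a.data + b.data, full.data, atol=1e-10)

    def test_empty_component_set_rejected(self, random_stack):
        decomp = decompose(build_matrix(random_stack))
        with pytest.raises(ValueError):
            reconstruct(decomp, [])

    def test_out_of_range_component_rejected(self, random_stack):
        decomp = decompose(build_matrix(random_stack))
        with pytest.raises(IndexError):
            reconstruct(decomp, [decomp.n_components])

    def test_top_ranked_reconstruction_denoises(self):
        (stack, truth), _ = _two_component_phantom()
        decomp = decompose(build_matrix(stack))
        ranking = rank_components(decomp)
        recon = reconstruct(decomp, ranking.top(2))
        clean = truth.clean.data
        err_recon = np.linalg.norm(recon.data - clean) / np.linalg.norm(clean)
        err_raw = np.linalg.norm(stack.data - clean) / np.linalg.norm(clean)
        assert err_recon < err_raw


def test_eigenspectra_csv_export(random_stack, tmp_path):
    import pandas as pd

    decomp = decompose(build_matrix(random_stack))
    path = eigenspectra_to_csv(decomp, tmp_path / "eig.csv", components=[0, 2])
    df = pd.read_csv(path)
    assert list(df.columns) == ["wavenumber", "component_0", "component_2"]
    np.testing.assert_allclose(df["component_0"], decomp.U[:, 0], atol=1e-12)
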