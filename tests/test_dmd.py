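import numpy as np
import pytest
from sklearn.base import clone

from stackdmd import (
    DMD,
    ImageStack,
    RankPolicy,
    SeriesSpec,
    compute_amplitudes,
    continuous_eigenvalues,
    eigendecompose,
    fit_dmd,
    make_series,
    optimal_hard_threshold_coefficient,
    psnr,
    reduced_operator,
    to_snapshot_matrix,
    truncated_svd,
)


def linear_system_stack(M, x0, m, frame_shape):
    """Stack generated by x_{k+1} = M x_k from x0."""
    cols = [x0]
    for _ in range(m - 1):
        cols.append(M @ cols[-1])
    X = np.column_stack(cols)
    return ImageStack(data=X.reshape(*frame_shape, m))


class TestTruncatedSVD:
    def test_fixed_rank_on_constructed_spectrum(self, rng):
        U = np.linalg.qr(rng.standard_normal((50, 2)))[0]
        V = np.linalg.qr(rng.standard_normal((20, 2)))[0]
        X = U @ np.diag([10.0, 8.0]) @ V.T
        f = truncated_svd(X, RankPolicy(mode="fixed", fixed_rank=2))
        assert f.retained_rank == 2
        assert np.allclose(f.S, [10.0, 8.0])

    def test_rank1_outer_product_hard_threshold(self, rng):
        X = np.outer(rng.uniform(1, 2, 30), rng.uniform(1, 2, 10))
        assert truncated_svd(X).retained_rank == 1

    def test_hard_threshold_matches_direct_formula(self, rng):
        # rank-3 signal + iid noise; oracle = direct evaluation of the
        # threshold omega(beta) * median(sigma) on the computed spectrum
        n, m, r = 200, 40, 3
        U = np.linalg.qr(rng.standard_normal((n, r)))[0]
        V = np.linalg.qr(rng.standard_normal((m, r)))[0]
        X = U @ np.diag([80.0, 60.0, 45.0]) @ V.T + 0.5 * rng.standard_normal((n, m))
        f = truncated_svd(X)
        s = np.linalg.svd(X, compute_uv=False)
        tau = optimal_hard_threshold_coefficient(m / n) * np.median(s)
        assert f.retained_rank == int(np.sum(s > tau)) == r

    def test_energy_policy(self):
        X = np.diag([3.0, 1.0, 0.1])
        f = truncated_svd(X, RankPolicy(mode="energy", energy_fraction=0.9))
        assert f.retained_rank == 2  # 9/10.01 < 0.9 <= 10/10.01

    def test_zero_matrix_is_no_signal(self):
        with pytest.raises(ValueError, match="no signal"):
            truncated_svd(np.zeros((5, 4)))

    def test_orthonormal_factors_and_descending_spectrum(self, rng):
        X = rng.standard_normal((40, 12))
        f = truncated_svd(X, RankPolicy(mode="fixed", fixed_rank=5))
        assert np.allclose(f.U.T @ f.U, np.eye(5), atol=1e-10)
        assert np.allclose(f.V.T @ f.V, np.eye(5), atol=1e-10)
        assert np.all(np.diff(f.full_spectrum) <= 1e-12)

    def test_policy_field_validation(self):
        with pytest.raises(ValueError):
            RankPolicy(mode="fixed")
        with pytest.raises(ValueError):
            RankPolicy(mode="energy", energy_fraction=1.5)
        with pytest.raises(ValueError):
            RankPolicy(mode="hard_threshold", fixed_rank=2)


class TestReducedOperator:
    def test_scaled_identity_when_X2_proportional(self, rng):
        X1 = rng.standard_normal((30, 8))
        f = truncated_svd(X1, RankPolicy(mode="fixed", fixed_rank=4))
        op = reduced_operator(f, 2.5 * X1)
        assert np.allclose(op.Atilde, 2.5 * np.eye(4), atol=1e-10)

    def test_scalar_decay_series(self):
        x = np.array([[1.0, 0.9, 0.81, 0.729]])
        X1, X2 = x[:, :-1], x[:, 1:]
        f = truncated_svd(X1, RankPolicy(mode="fixed", fixed_rank=1))
        op = reduced_operator(f, X2)
        assert op.Atilde.shape == (1, 1)
        assert op.Atilde[0, 0] == pytest.approx(0.9, abs=1e-12)

    def test_recovers_spectrum_of_known_operator(self, rng):
        # oracle: direct eigendecomposition of the generating 3x3 matrix
        M = rng.standard_normal((3, 3)) * 0.4
        x0 = rng.standard_normal(3)
        cols = [x0]
        for _ in range(9):
            cols.append(M @ cols[-1])
        X = np.column_stack(cols)
        f = truncated_svd(X[:, :-1], RankPolicy(mode="fixed", fixed_rank=3))
        op = reduced_operator(f, X[:, 1:])
        got = np.sort_complex(np.linalg.eigvals(op.Atilde))
        want = np.sort_complex(np.linalg.eigvals(M))
        assert np.allclose(got, want, atol=1e-8)


class TestEigendecompose:
    def test_diagonal_operator(self, rng):
        X1 = rng.standard_normal((20, 6))
        f = truncated_svd(X1, RankPolicy(mode="fixed", fixed_rank=2))
        from stackdmd.dmd import ReducedOperator

        vals, modes = eigendecompose(
            ReducedOperator(Atilde=np.diag([0.9, 0.5])), f, rng.standard_normal((20, 6))
        )
        assert np.allclose(sorted(vals.real, reverse=True), [0.9, 0.5])
        assert np.allclose(np.linalg.norm(modes, axis=0), 1.0)

    def test_rotation_gives_unit_circle_pair(self, rng):
        from stackdmd.dmd import ReducedOperator

        a = 0.7
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        X1 = rng.standard_normal((20, 6))
        f = truncated_svd(X1, RankPolicy(mode="fixed", fixed_rank=2))
        vals, _ = eigendecompose(ReducedOperator(Atilde=R), f, rng.standard_normal((20, 6)))
        assert np.allclose(np.sort(np.angle(vals)), [-a, a], atol=1e-12)
        assert np.allclose(np.abs(vals), 1.0, atol=1e-12)

    def test_two_pattern_eigenvalue_recovery(self, rank2_stack):
        stack, mus = rank2_stack
        model = DMD(rank=2).fit(stack)
        assert np.allclose(np.sort(model.eigenvalues_.real), np.sort(mus), atol=1e-8)
        assert np.max(np.abs(model.eigenvalues_.imag)) < 1e-10


class TestAmplitudes:
    def test_single_mode_scalar_identification(self):
        v = np.ones(16) / 4.0  # unit norm
        X = 3.0 * np.outer(v, 0.9 ** np.arange(10))
        b = compute_amplitudes(v[:, None].astype(complex), np.array([0.9 + 0j]), X)
        assert b[0] == pytest.approx(3.0, abs=1e-10)

    def test_first_frame_agrees_on_consistent_data(self, rank2_stack):
        stack, _ = rank2_stack
        m_all = DMD(rank=2, amplitude_method="all_frames").fit(stack)
        m_ff = DMD(rank=2, amplitude_method="first_frame").fit(stack)
        assert np.allclose(
            np.sort(np.abs(m_all.amplitudes_)), np.sort(np.abs(m_ff.amplitudes_)),
            atol=1e-8,
        )

    def test_all_frames_has_lower_residual_under_noise(self, rank2_stack, rng):
        stack, _ = rank2_stack
        noisy = ImageStack(data=stack.data + 0.1 * rng.standard_normal(stack.data.shape))
        snap = to_snapshot_matrix(noisy).matrix
        resid = {}
        for method in ("all_frames", "first_frame"):
            m = DMD(rank=2, amplitude_method=method).fit(noisy)
            resid[method] = np.linalg.norm(m.reconstruct_matrix().real - snap)
        assert resid["all_frames"] <= resid["first_frame"]


class TestContinuousEigenvalues:
    @pytest.mark.parametrize(
        "lam, step, want",
        [
            (1.0, 0.5, 0.0),
            (np.exp(-0.1), 1.0, -0.1),
            (1j, 1.0, 1j * np.pi / 2),
        ],
    )
    def test_closed_forms(self, lam, step, want):
        out = continuous_eigenvalues(np.array([lam], dtype=complex), step)
        assert out[0] == pytest.approx(want, abs=1e-12)

    def test_zero_eigenvalue_flagged_nan(self):
        out = continuous_eigenvalues(np.array([0.0 + 0j, 0.5 + 0j]), 1.0)
        assert np.isnan(out[0]) and np.isfinite(out[1])


class TestFitDMD:
    def test_noiseless_reconstruction_and_idempotence(self, rank2_stack):
        stack, _ = rank2_stack
        model = DMD(rank=2).fit(stack)
        rec = model.reconstruct()
        rel = np.linalg.norm(rec.data - stack.data) / np.linalg.norm(stack.data)
        assert rel < 1e-8
        rec2 = DMD(rank=2).fit(rec).reconstruct()
        assert np.linalg.norm(rec2.data - rec.data) / np.linalg.norm(rec.data) < 1e-8

    @pytest.mark.parametrize("r", [1, 2, 3])
    def test_eigenvalue_recovery_across_ranks(self, r, rng):
        n, m = 120, 20
        mus = np.array([0.97, 0.85, 0.6])[:r]
        V = np.linalg.qr(rng.standard_normal((n, r)))[0]
        X = (V * rng.uniform(1, 3, r)) @ np.vander(mus, N=m, increasing=True)
        model = DMD(rank=r).fit(ImageStack(data=X.reshape(12, 10, m)))
        assert np.allclose(np.sort(model.eigenvalues_.real), np.sort(mus), atol=1e-6)

    def test_conjugate_closure_for_real_input(self, rng):
        stack = ImageStack(data=rng.uniform(0, 10, size=(8, 8, 15)))
        model = DMD(rank=8).fit(stack)
        lam = model.eigenvalues_
        # every eigenvalue's conjugate is present
        for v in lam:
            assert np.min(np.abs(lam - np.conj(v))) < 1e-8

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError, match="two snapshots"):
            DMD().fit(ImageStack(data=np.ones((4, 4, 1))))

    def test_bleaching_series_single_real_mode(self, bleach_pair):
        noisy, _ = bleach_pair
        model = fit_dmd(noisy, "auto")
        assert model.rank_ == 1
        lam = model.eigenvalues_[0]
        assert abs(lam.imag) < 1e-12 and 0 < lam.real < 1

    def test_denoising_gain_on_poisson_series(self, bleach_pair):
        noisy, truth = bleach_pair
        rec = fit_dmd(noisy, "auto").reconstruct()
        dr = float(truth.data.max())
        for k in range(1, truth.n_frames + 1):
            assert psnr(truth.frame(k), rec.frame(k), dr) > psnr(
                truth.frame(k), noisy.frame(k), dr
            )

    def test_dft_equivalence_on_mean_subtracted_periodic_data(self, rng):
        # periodic data with independent spatial patterns on every DFT bin,
        # so the centered snapshots are linearly independent (rank m-1)
        m = 12
        k = np.arange(m)
        data = np.zeros((8, 8, m))
        for q in range(1, m // 2 + 1):
            cosq = np.cos(2 * np.pi * q * k / m)
            sinq = np.sin(2 * np.pi * q * k / m)
            data += rng.uniform(0.5, 2, (8, 8))[:, :, None] * cosq[None, None, :]
            data += rng.uniform(0.5, 2, (8, 8))[:, :, None] * sinq[None, None, :]
        data += 20.0
        stack = ImageStack(data=data)
        centered = stack.with_data(stack.data - stack.data.mean(axis=2, keepdims=True))
        model = DMD(rank=m - 1).fit(centered)
        lam = model.eigenvalues_
        assert np.allclose(np.abs(lam), 1.0, atol=1e-6)
        dft_angles = np.angle(np.exp(2j * np.pi * np.arange(1, m) / m))
        for ang in np.angle(lam):
            assert np.min(np.abs(np.angle(np.exp(1j * (ang - dft_angles))))) < 1e-6

    def test_sklearn_params_and_clone(self):
        model = DMD(rank=3, amplitude_method="first_frame")
        params = model.get_params()
        assert params["rank"] == 3
        cloned = clone(model)
        assert cloned.get_params() == params
        cloned.set_params(rank="auto")
        assert cloned.rank == "auto"

    def test_transform_gives_mode_coordinates(self, rank2_stack):
        stack, _ = rank2_stack
        model = DMD(rank=2).fit(stack)
        coords = model.transform(stack)
        assert coords.shape == (stack.n_frames, 2)
        approx = (model.modes_ @ coords.T).real
        assert np.allclose(approx, to_snapshot_matrix(stack).matrix, atol=1e-8)
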