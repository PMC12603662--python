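"""Multi-shell NLS and single-shell regularized free-water fits."""

import numpy as np
import pytest
from sklearn.base import clone

from freewater.acquisition import DWIDataset, subsample_single_shell
from freewater.fit import (
    MultiShellFreeWaterModel,
    SingleShellFreeWaterModel,
    fit_multishell,
    fit_singleshell,
    fit_tensor_lls,
    initialize_fit,
)
from freewater.model import D_ISO, predict_signal, tensor_to_matrix
from freewater.simulate import _prolate_tensor, simulate_phantom, simulate_voxel


def _voxels_dataset(scheme, f_values, snr=np.inf, seed0=0, s0=100.0):
    rng = np.random.default_rng(seed0)
    n = len(f_values)
    data = np.zeros((n, 1, 1, len(scheme)))
    tensors = []
    for i, f in enumerate(f_values):
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        q6 = _prolate_tensor(axis=axis)
        tensors.append(q6)
        data[i, 0, 0] = simulate_voxel(
            [(1.0 - f, q6)], f, s0, scheme, snr=snr, seed=seed0 * 100003 + i
        )
    ds = DWIDataset(data=data, scheme=scheme, mask=np.ones((n, 1, 1), bool))
    return ds, np.asarray(tensors)


class TestMultiShell:
    def test_noiseless_recovery(self, scheme):
        f_true = np.array([0.3, 0.0, 0.55, 0.8])
        ds, tensors = _voxels_dataset(scheme, f_true)
        est = MultiShellFreeWaterModel().fit(ds)
        f_hat = est.field_.f[:, 0, 0]
        np.testing.assert_allclose(f_hat, f_true, atol=1e-3)
        q_hat = est.field_.q[:, 0, 0]
        assert np.abs(q_hat - tensors).max() < 1e-5
        assert est.converged_.all()

    def test_zero_fraction_matches_lls_oracle(self, scheme):
        # with no free water, the bi-tensor fit must collapse to the plain
        # log-linear tensor fit
        ds, tensors = _voxels_dataset(scheme, [0.0])
        est = MultiShellFreeWaterModel().fit(ds)
        assert est.field_.f[0, 0, 0] <= 0.01
        q_lls, _ = fit_tensor_lls(ds.data, scheme)
        assert np.abs(est.field_.q[0, 0, 0] - q_lls[0, 0, 0]).max() < 1e-6

    def test_noisy_recovery_rmse(self, scheme):
        rng = np.random.default_rng(21)
        f_true = rng.uniform(0.0, 0.7, 200)
        ds, _ = _voxels_dataset(scheme, f_true, snr=40.0, seed0=2)
        f_hat = fit_multishell(ds).f[:, 0, 0]
        rmse = np.sqrt(np.mean((f_hat - f_true) ** 2))
        assert rmse <= 0.05

    def test_field_invariants_under_noise(self, scheme):
        rng = np.random.default_rng(5)
        ds, _ = _voxels_dataset(scheme, rng.uniform(0, 0.9, 30), snr=15.0, seed0=7)
        field = fit_multishell(ds)
        assert np.all(field.f >= 0) and np.all(field.f <= 1)
        evals = np.linalg.eigvalsh(tensor_to_matrix(field.q))
        assert evals.min() >= -1e-12

    def test_voxel_separability(self, scheme):
        ds, _ = _voxels_dataset(scheme, [0.1, 0.4, 0.7], snr=30.0, seed0=3)
        f_fwd = fit_multishell(ds).f.ravel()
        perm = [2, 0, 1]
        ds_perm = DWIDataset(
            data=ds.data[perm], scheme=scheme, mask=ds.mask
        )
        f_perm = fit_multishell(ds_perm).f.ravel()
        np.testing.assert_allclose(f_perm, f_fwd[perm], rtol=1e-8)

    def test_single_shell_input_redirected(self, scheme, single_voxel_ds):
        ds = single_voxel_ds(np.full(len(scheme), 50.0))
        sub = subsample_single_shell(ds, 1000.0)
        with pytest.raises(ValueError, match="[Ss]ingle[Ss]hell"):
            MultiShellFreeWaterModel().fit(sub)

    def test_roundtrip_signal_identity(self, scheme):
        # simulate -> fit -> predict reproduces the input signal
        ds, _ = _voxels_dataset(scheme, [0.25])
        field = fit_multishell(ds)
        predicted = predict_signal(field, scheme)
        np.testing.assert_allclose(predicted, ds.data, rtol=1e-6)

    def test_sklearn_protocol(self):
        est = MultiShellFreeWaterModel(d_iso=2.9e-3)
        params = est.get_params()
        assert params["d_iso"] == 2.9e-3
        cloned = clone(est)
        assert cloned.get_params() == params
        cloned.set_params(d_iso=D_ISO)
        assert cloned.d_iso == D_ISO


class TestInitialize:
    def test_pure_free_water_clamps_high(self, scheme, single_voxel_ds):
        sig = 100.0 * np.exp(-scheme.bvals * D_ISO)
        init = initialize_fit(single_voxel_ds(sig))
        assert init.f[0, 0, 0] == pytest.approx(0.99)

    def test_no_free_water_near_lower_clamp(self, scheme, single_voxel_ds):
        sig = simulate_voxel([(1.0, _prolate_tensor())], 0.0, 100.0, scheme)
        init = initialize_fit(single_voxel_ds(sig))
        assert init.f[0, 0, 0] <= 0.05

    def test_randomized_voxels_yield_valid_field(self, scheme):
        rng = np.random.default_rng(13)
        ds, _ = _voxels_dataset(scheme, rng.uniform(0, 1, 25), snr=10.0, seed0=9)
        init = initialize_fit(ds)  # constructor enforces the invariants
        assert np.all((init.f >= 0) & (init.f <= 1))
        assert np.all(init.s0[init.mask] > 0)

    def test_nonpositive_b0_flagged(self, scheme):
        data = np.zeros((2, 1, 1, len(scheme)))
        data[1] = 50.0
        ds = DWIDataset(data=data, scheme=scheme, mask=np.ones((2, 1, 1), bool))
        init = initialize_fit(ds)
        assert not init.mask[0, 0, 0]
        assert init.mask[1, 0, 0]


@pytest.fixture(scope="module")
def small_phantom():
    ds, truth, labels = simulate_phantom(shape=(10, 10, 4), snr=np.inf, seed=5)
    return subsample_single_shell(ds, 1000.0), truth, labels


class TestSingleShell:
    def test_noiseless_phantom_recovery(self, small_phantom):
        ss, truth, labels = small_phantom
        est = SingleShellFreeWaterModel().fit(ss)
        err = np.abs(est.field_.f - truth.f)[labels != 3]
        assert err.mean() <= 0.05

    def test_cost_history_non_increasing(self, small_phantom):
        ss, _, _ = small_phantom
        est = SingleShellFreeWaterModel(max_iter=40).fit(ss)
        hist = np.asarray(est.cost_history_)
        assert len(hist) >= 2
        assert np.all(np.diff(hist) <= 1e-12)

    def test_noisy_phantom_recovery(self):
        ds, truth, labels = simulate_phantom(shape=(10, 10, 4), snr=40.0, seed=6)
        ss = subsample_single_shell(ds, 1000.0)
        field = fit_singleshell(ss)
        err = np.abs(field.f - truth.f)[labels != 3]
        assert err.mean() <= 0.1

    def test_zero_reg_weight_reaches_per_voxel_minimum(self, small_phantom):
        # noiseless, constant-parameter region: without regularization the
        # data cost must approach zero (the per-voxel optimum)
        ss, _, _ = small_phantom
        est = SingleShellFreeWaterModel(reg_weight=0.0).fit(ss)
        n_samples = ss.mask.sum() * (~ss.scheme.b0_mask).sum()
        assert est.cost_history_[-1] / n_samples < 1e-6

    def test_multishell_input_rejected(self, phantom_noiseless):
        ds, _, _ = phantom_noiseless
        with pytest.raises(ValueError, match="exactly one"):
            SingleShellFreeWaterModel().fit(ds)

    def test_field_invariants(self, small_phantom):
        ss, _, _ = small_phantom
        field = SingleShellFreeWaterModel(max_iter=20).fit(ss).field_
        assert np.all((field.f >= 0) & (field.f <= 1))
        evals = np.linalg.eigvalsh(tensor_to_matrix(field.q[field.mask]))
        assert evals.min() >= -1e-12

    def test_feasibility_interval_brackets_truth(self, small_phantom):
        ss, truth, labels = small_phantom
        est = SingleShellFreeWaterModel(max_iter=1).fit(ss)
        f_lo, f_hi = est.f_bounds_
        f_true = truth.f.ravel()[est.field_.mask.ravel()]
        inside = (f_true >= f_lo - 0.02) & (f_true <= f_hi + 0.02)
        assert inside.mean() > 0.95
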