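"""fGn generator: closed-form autocovariance, exact-covariance sampling,
stream independence and the validation report."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from fbdsim import fgn
from fbdsim.errors import (AlgorithmFailureError, HurstRangeWarning,
                           InvalidParameterError, MemoryBudgetError)

GAMMA1_H035 = 0.5 * (2.0 ** 0.7 - 2.0)  # = -0.18774760364376453

hursts = st.floats(min_value=0.01, max_value=0.99)


@pytest.mark.parametrize("k,hurst,expected", [
    (0, 0.42, 1.0),
    (0, 0.5, 1.0),
    (1, 0.5, 0.0),
    (7, 0.5, 0.0),
    (1, 0.35, GAMMA1_H035),
])
def test_autocovariance_closed_form(k, hurst, expected):
    assert fgn.autocovariance(k, hurst) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("hurst", [0.0, 1.0, -0.2, 1.7, float("nan")])
def test_autocovariance_rejects_invalid_hurst(hurst):
    with pytest.raises(InvalidParameterError):
        fgn.autocovariance(1, hurst)


@given(hurst=hursts, k=st.integers(min_value=1, max_value=200))
def test_autocovariance_symmetry_and_sign(hurst, k):
    g = fgn.autocovariance(k, hurst)
    assert fgn.autocovariance(-k, hurst) == g
    assert fgn.autocovariance(0, hurst) == pytest.approx(1.0)
    if hurst < 0.5:
        assert g < 0.0  # anticorrelated increments
    elif hurst > 0.5:
        assert g > 0.0  # persistent increments
    else:
        assert g == 0.0


@pytest.mark.parametrize("hurst", [0.2, 0.35, 0.5, 0.62, 0.8])
@pytest.mark.parametrize("n", [2, 7, 33, 64])
def test_partial_sum_variance_identity(hurst, n):
    # Var[B_H(n)] = n^{2H} pins down the whole covariance sequence
    k = np.arange(-(n - 1), n)
    total = np.sum((n - np.abs(k)) * fgn.autocovariance(k, hurst))
    assert total == pytest.approx(n ** (2 * hurst), rel=1e-10)


def test_spec_validation():
    with pytest.raises(InvalidParameterError):
        fgn.FgnSpec(hurst=1.2, length=10)
    with pytest.raises(InvalidParameterError):
        fgn.FgnSpec(hurst=0.5, length=0)


def _lag_cov(x, k):
    xc = x - x.mean()
    return float(np.dot(xc[:-k], xc[k:]) / x.size)


def test_white_noise_reduction_at_half():
    n = 100_000
    x = fgn.generate_fgn(fgn.FgnSpec(0.5, n, seed=10))
    assert abs(_lag_cov(x, 1)) < 3.0 / np.sqrt(n)


def test_lag1_autocovariance_matches_theory():
    n = 100_000
    x = fgn.generate_fgn(fgn.FgnSpec(0.35, n, seed=11))
    se = np.sqrt((1 + 2 * np.sum(
        fgn.autocovariance(np.arange(1, 200), 0.35) ** 2)) / n)
    assert abs(_lag_cov(x, 1) - GAMMA1_H035) < 3 * se


def test_seeded_determinism():
    spec = fgn.FgnSpec(0.6, 2 ** 14, seed=7)
    assert np.array_equal(fgn.generate_fgn(spec), fgn.generate_fgn(spec))


def test_embedding_failure_handling(monkeypatch):
    def boom(n, hurst):
        raise AlgorithmFailureError("synthetic embedding failure")

    monkeypatch.setattr(fgn, "_dh_spectrum", boom)
    with pytest.raises(AlgorithmFailureError):
        fgn.generate_fgn(fgn.FgnSpec(0.4, 256, seed=1),
                         method="davies-harte")
    # auto mode falls back to the recursion and still delivers
    x = fgn.generate_fgn(fgn.FgnSpec(0.4, 4096, seed=1), method="auto")
    assert abs(_lag_cov(x, 1) - fgn.autocovariance(1, 0.4)) < 0.05


def test_hosking_matches_davies_harte_statistically():
    """Same empirical covariance from both exact samplers."""
    n, reps, hurst = 2048, 40, 0.4
    g1 = {"davies-harte": [], "hosking": []}
    g2 = {"davies-harte": [], "hosking": []}
    for method in g1:
        for r in range(reps):
            x = fgn.generate_fgn(fgn.FgnSpec(hurst, n, seed=1000 + r),
                                 method=method)
            g1[method].append(_lag_cov(x, 1))
            g2[method].append(_lag_cov(x, 2))
    for emp in (g1, g2):
        t = stats.ttest_ind(emp["davies-harte"], emp["hosking"])
        assert t.pvalue > 1e-3


def test_noise_tensor_streams_uncorrelated():
    nt = fgn.generate_noise_tensor(2, 1000, 0.45, seed=3)
    flat = nt.values.reshape(6, -1)
    n = flat.shape[1]
    for a in range(6):
        for b in range(a + 1, 6):
            r = np.corrcoef(flat[a], flat[b])[0, 1]
            assert abs(r) < 3.0 / np.sqrt(n)


def test_noise_tensor_unit_variance():
    nt = fgn.generate_noise_tensor(1, 100_000, 0.5, seed=4)
    se = np.sqrt(2.0 / nt.n_steps)
    for a in range(3):
        assert abs(nt.values[0, a].var() - 1.0) < 3 * se


def test_noise_tensor_partial_sums_are_brownian_at_half():
    nt = fgn.generate_noise_tensor(100, 2000, 0.5, seed=5)
    var = nt.values.sum(axis=2).var()
    n_samp = 300
    assert abs(var - 2000) < 4 * 2000 * np.sqrt(2.0 / n_samp)


def test_noise_tensor_stream_reproducible_in_isolation():
    big = fgn.generate_noise_tensor(5, 512, 0.6, seed=8)
    # regenerating a single stream via its (seed, bead, axis) key matches
    ss = np.random.SeedSequence(8, spawn_key=(3, 1))
    rng = np.random.default_rng(ss)
    lam, m = fgn._dh_spectrum(512, 0.6)
    x = fgn._dh_sample_batch([rng], np.sqrt(lam), 512, m)[0]
    np.testing.assert_allclose(big.values[3, 1], x, rtol=0, atol=1e-12)


def test_memory_budget_guard():
    with pytest.raises(MemoryBudgetError):
        fgn.generate_noise_tensor(10_000, 1_000_000, 0.5, seed=0,
                                  memory_budget=10 ** 6)


def test_chunked_blocks_cover_run():
    policy = fgn.ChunkPolicy(block_length=300)
    starts, total = [], 0
    for start, block in fgn.iter_noise_blocks(2, 1000, 0.4, 9, policy):
        starts.append(start)
        total += block.n_steps
        assert block.values.shape[0] == 2
    assert starts == [0, 300, 600, 900]
    assert total == 1000


def test_hurst_range_warning():
    with pytest.warns(HurstRangeWarning):
        fgn.generate_fgn(fgn.FgnSpec(0.2, 64, seed=0))


class TestValidator:
    def test_generator_self_consistency(self):
        x = fgn.generate_fgn(fgn.FgnSpec(0.4, 100_000, seed=21))
        assert fgn.validate_fgn(x, 0.4).passed

    def test_zeros_fail_variance(self):
        rep = fgn.validate_fgn(np.zeros(5000), 0.4)
        assert not rep.passed
        assert not rep.flags["variance"]

    def test_white_noise_fails_as_h035(self):
        x = np.random.default_rng(2).standard_normal(100_000)
        rep = fgn.validate_fgn(x, 0.35)
        assert not rep.flags["autocovariance"]

    def test_short_stream_warns_not_fails(self):
        x = fgn.generate_fgn(fgn.FgnSpec(0.5, 200, seed=1))
        rep = fgn.validate_fgn(x, 0.5)
        assert rep.short_stream_warning
        assert not rep.passed


def test_noise_store_roundtrip(tmp_path):
    nt = fgn.generate_noise_tensor(3, 256, 0.55, seed=12)
    path = tmp_path / "noise.h5"
    fgn.save_noise_tensor(path, nt, master_seed=12)
    back = fgn.load_noise_tensor(path)
    np.testing.assert_array_equal(back.values, nt.values)
    np.testing.assert_array_equal(back.seeds, nt.seeds)
    assert back.hurst == nt.hurst
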