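"""Analysis estimators against closed forms and synthetic inputs."""

import numpy as np
import pytest

from fbdsim import analysis, fgn, presets
from fbdsim.errors import InvalidParameterError, TooShortError
from fbdsim.integrator import SimulationConfig, Trajectory


def _make_trajectory(frames=None, dt=0.01, frame_interval=100,
                     energies=None, energy_steps=None, tracked=None,
                     tracked_beads=(), n_steps=None, geometry=None):
    """Minimal synthetic Trajectory for estimator tests."""
    if frames is None:
        frames = np.zeros((2, 1, 3))
    n_frames = frames.shape[0]
    frame_steps = np.arange(n_frames) * frame_interval
    if n_steps is None:
        n_steps = max(int(frame_steps[-1]),
                      0 if tracked is None else tracked.shape[0] - 1, 1)
    if energies is None:
        energies = np.zeros(2)
        energy_steps = np.array([0, n_steps])
    cfg = SimulationConfig(n_steps=n_steps, dt=dt,
                           frame_record_interval=frame_interval,
                           track_beads=tracked_beads)
    return Trajectory(frames=frames, frame_steps=frame_steps,
                      energies=np.asarray(energies, dtype=float),
                      energy_steps=np.asarray(energy_steps),
                      config=cfg, tracked_beads=tracked_beads,
                      tracked=tracked, geometry=geometry)


# ---------------------------------------------------------------------------
# MSD + power-law fit
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("d,alpha", [(0.01, 0.8), (0.005, 1.0),
                                     (0.2, 0.35), (1.0, 1.6)])
def test_fit_power_law_exact_roundtrip(d, alpha):
    t = np.geomspace(0.1, 100, 60)
    curve = analysis.MsdCurve(lags_time=t, msd=4 * d * t ** alpha,
                              n_origins=np.full(t.size, 1000),
                              dt_sample=0.01, dt_sim=0.01,
                              series_time=1000.0)
    fit = analysis.fit_power_law(curve)
    assert fit.alpha == pytest.approx(alpha, abs=1e-6)
    assert fit.d_xz == pytest.approx(d, rel=1e-6)


def test_fit_power_law_noisy_constant_has_flat_slope(rng):
    t = np.geomspace(0.1, 100, 50)
    m = 1.0 + rng.normal(0, 0.01, t.size)
    curve = analysis.MsdCurve(lags_time=t, msd=m,
                              n_origins=np.full(t.size, 1000),
                              dt_sample=0.01, dt_sim=0.01,
                              series_time=1000.0)
    fit = analysis.fit_power_law(curve)
    assert abs(fit.alpha) < 3 * fit.stderr_alpha + 1e-3


def test_fit_power_law_rejects_nonpositive_msd():
    t = np.geomspace(0.1, 100, 30)
    curve = analysis.MsdCurve(lags_time=t, msd=np.zeros(t.size),
                              n_origins=np.full(t.size, 10),
                              dt_sample=0.01, dt_sim=0.01,
                              series_time=1000.0)
    with pytest.raises(InvalidParameterError):
        analysis.fit_power_law(curve)


def test_fit_power_law_needs_enough_points():
    t = np.geomspace(0.1, 100, 30)
    curve = analysis.MsdCurve(lags_time=t, msd=t.copy(),
                              n_origins=np.full(t.size, 10),
                              dt_sample=0.01, dt_sim=0.01,
                              series_time=1000.0)
    with pytest.raises(TooShortError):
        analysis.fit_power_law(curve, fit_window=(50.0, 60.0))


def test_static_trajectory_msd_is_zero():
    pos = np.ones((500, 3))
    curve = analysis.msd_from_positions(pos, 0.01)
    np.testing.assert_array_equal(curve.msd, 0.0)


def test_free_bead_msd_matches_normal_diffusion():
    tr = presets.run_free_beads(0.5, 50_000, seed=13, n_beads=10)
    curve = analysis.msd_from_positions(tr.tracked, 0.01)
    # 2D projection: MSD = 4 D t with D = 0.005
    mask = (curve.lags_time >= 1.0) & (curve.lags_time <= 50.0)
    expected = 4 * 0.005 * curve.lags_time[mask]
    np.testing.assert_allclose(curve.msd[mask], expected, rtol=0.2)
    fit = analysis.fit_power_law(curve, fit_window=(0.1, 50.0))
    assert fit.alpha == pytest.approx(1.0, abs=0.05)
    assert fit.d_xz == pytest.approx(0.005, rel=0.15)


def test_free_bead_msd_matches_fbm_closed_form():
    tr = presets.run_free_beads(0.35, 100_000, seed=14, n_beads=5)
    curve = analysis.msd_from_positions(tr.tracked, 0.01)
    lag_steps = np.round(curve.lags_time / 0.01).astype(int)
    expected = 4 * 0.005 * 0.01 * lag_steps ** 0.7
    mask = (lag_steps >= 10) & (lag_steps <= 10_000)
    np.testing.assert_allclose(curve.msd[mask], expected[mask], rtol=0.25)


@pytest.mark.parametrize("hurst", [0.35, 0.45, 0.5, 0.6, 0.65])
def test_free_bead_exponent_recovery(hurst):
    """msd + fit_power_law recovers alpha = 2H (averaged over independent
    beads; a single fBm track has long-range-correlated MSD errors)."""
    tr = presets.run_free_beads(hurst, 100_000,
                                seed=100 + int(hurst * 100), n_beads=20)
    curve = analysis.msd_from_positions(tr.tracked, 0.01)
    fit = analysis.fit_power_law(curve, fit_window=(0.1, 100.0))
    assert fit.alpha == pytest.approx(2 * hurst, abs=0.05)


def test_msd_requires_enough_frames():
    tr = _make_trajectory(frames=np.zeros((10, 2, 3)))
    with pytest.raises(TooShortError):
        analysis.msd_2d(tr, "all", window=False)


# ---------------------------------------------------------------------------
# VACF
# ---------------------------------------------------------------------------

def test_vacf_lag_zero_is_one(rng):
    pos = np.cumsum(rng.normal(0, 0.01, (5000, 3)), axis=0)
    v = analysis.vacf_from_positions(pos, 0.01, max_lag=10)
    assert v.c_v_normalized[0] == 1.0


def test_vacf_free_bead_matches_autocovariance():
    tr = presets.run_free_beads(0.35, 100_000, seed=15)
    v = analysis.vacf_from_positions(tr.tracked_positions(0), 0.01,
                                     max_lag=20)
    gam = fgn.autocovariance(np.arange(21), 0.35)
    assert np.all(np.abs(v.c_v_normalized[1:] - gam[1:])
                  < 3 * v.c_v_se[1:] + 0.01)


def test_vacf_white_noise_vanishes_beyond_lag_zero():
    tr = presets.run_free_beads(0.5, 100_000, seed=16)
    v = analysis.vacf_from_positions(tr.tracked_positions(0), 0.01,
                                     max_lag=50)
    assert np.abs(v.c_v_normalized[1:]).max() < 0.02


def test_vacf_requires_tracked_bead():
    tr = _make_trajectory(frames=np.zeros((200, 1, 3)))
    with pytest.raises(InvalidParameterError):
        analysis.vacf(tr, 0)


# ---------------------------------------------------------------------------
# Displacement distributions
# ---------------------------------------------------------------------------

def test_free_bead_displacements_gaussian():
    tr = presets.run_free_beads(0.45, 50_000, seed=17)
    hists = analysis.displacement_distribution(tr, 0, lags=(0.1, 1.0, 10.0),
                                               window=False)
    for h in hists:
        assert h.passed, f"lag {h.lag_time}: ks={h.ks_distance}"
        # histogram integrates to one
        width = h.bin_centers[1] - h.bin_centers[0]
        assert h.densities.sum() * width == pytest.approx(1.0, abs=0.05)


def test_two_point_displacements_fail_normality():
    z = np.zeros(20_001)
    z[1::2] = 1.0  # displacements are exactly +/-1
    tracked = np.zeros((20_001, 1, 3))
    tracked[:, 0, 2] = z
    tr = _make_trajectory(frames=np.zeros((2, 1, 3)), tracked=tracked,
                          tracked_beads=(0,), n_steps=20_000)
    hists = analysis.displacement_distribution(tr, 0, lags=(0.01,),
                                               window=False)
    assert not hists[0].passed


def test_degenerate_displacement_errors():
    tracked = np.zeros((5_000, 1, 3))
    tr = _make_trajectory(frames=np.zeros((2, 1, 3)), tracked=tracked,
                          tracked_beads=(0,), n_steps=4_999)
    with pytest.raises(InvalidParameterError):
        analysis.displacement_distribution(tr, 0, lags=(0.1,), window=False)


# ---------------------------------------------------------------------------
# Projected density / energy trace
# ---------------------------------------------------------------------------

def test_projected_density_uniform_is_flat(rng):
    from fbdsim.forcefield import CylinderGeometry

    geom = CylinderGeometry(radius=10.0, length_z=20.0)
    n_frames, n_beads = 50, 400
    rho = 10.0 * np.sqrt(rng.uniform(0, 1, (n_frames, n_beads)))
    phi = rng.uniform(0, 2 * np.pi, (n_frames, n_beads))
    frames = np.stack([rho * np.cos(phi), rho * np.sin(phi),
                       rng.uniform(-10, 10, (n_frames, n_beads))], axis=-1)
    tr = _make_trajectory(frames=frames, geometry=geom)
    dm = analysis.projected_density(tr, bin_size=5.0, window=False)
    assert dm.counts.sum() == n_frames * n_beads
    # central columns (full cylinder depth) should be uniform in z
    inner = dm.counts[1:3, :]
    expect = inner.mean()
    assert np.all(np.abs(inner - expect) < 5 * np.sqrt(expect))
    assert abs(dm.com_z_offset.mean()) < 0.5


def test_projected_density_point_mass():
    frames = np.zeros((10, 7, 3))
    tr = _make_trajectory(frames=frames)
    dm = analysis.projected_density(tr, bin_size=1.0, window=False)
    assert dm.counts.max() == 70
    assert (dm.counts > 0).sum() == 1


def test_energy_trace_detects_plateau_on_decay(rng):
    steps = np.arange(0, 20_000, 100)
    e = 500.0 + 400 * np.exp(-steps / 800.0) + rng.normal(0, 2.0, steps.size)
    tr = _make_trajectory(frames=np.zeros((2, 1, 3)), energies=e,
                          energy_steps=steps, n_steps=int(steps[-1]))
    et = analysis.energy_trace(tr)
    assert et.plateau_detected
    assert et.plateau_mean == pytest.approx(500.0, rel=0.02)
    assert et.equilibration_step_estimate > 0


def test_energy_trace_rejects_linear_ramp(rng):
    steps = np.arange(0, 20_000, 100)
    e = steps * 0.05 + rng.normal(0, 0.5, steps.size)
    tr = _make_trajectory(frames=np.zeros((2, 1, 3)), energies=e,
                          energy_steps=steps, n_steps=int(steps[-1]))
    et = analysis.energy_trace(tr)
    assert not et.plateau_detected
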