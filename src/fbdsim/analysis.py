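"""Observables characterizing anomalous diffusion in trajectories.

The central quantities are

* the 2D mean-squared displacement in the xz plane, fitted as
  MSD_2d(t) = 4 D_xz t^alpha (least squares in log-log); alpha < 1 is
  subdiffusion, and for a free fractional Brownian bead alpha = 2H;
* the velocity autocorrelation function (VACF) from finite displacement
  differences over one time step,
  C_v(tau) = <[r(t+dt) - r(t)] . [r(t+tau+dt) - r(t+tau)]> / dt^2,
  averaged over time origins (stationarity assumed); for a free bead the
  normalized VACF *is* the fGn autocovariance;
* standardized one-axis displacement distributions Delta z / delta over a
  set of time lags, with a Kolmogorov-Smirnov distance to N(0, 1);
* the projected number density of beads on the xz plane and the
  center-of-mass axial offset;
* potential-energy traces with plateau diagnostics.

Ensemble averages follow the single-polymer convention: time-origin
averaging, plus bead averaging for the all-bead curve; per-bead
quantities average over independent replicate runs upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InvalidParameterError, TooShortError
from .integrator import Trajectory

__all__ = [
    "MsdCurve", "MsdFit", "VacfCurve", "DisplacementHistogram", "DensityMap",
    "EnergyTrace", "msd_2d", "msd_from_positions", "fit_power_law", "vacf",
    "vacf_from_positions", "displacement_distribution", "projected_density",
    "energy_trace",
]

_MIN_FRAMES = 100

_PLANES = {"xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}


# ---------------------------------------------------------------------------
# MSD
# ---------------------------------------------------------------------------

@dataclass
class MsdCurve:
    """Time-origin (and optionally bead) averaged MSD at log-spaced lags."""

    lags_time: np.ndarray
    msd: np.ndarray
    n_origins: np.ndarray
    dt_sample: float        # spacing of the underlying series
    dt_sim: float           # integrator time step (sets the default window)
    series_time: float      # total time span of the series used
    plane: str = "xz"

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"lag_time": self.lags_time, "msd": self.msd,
                             "n_origins": self.n_origins})


@dataclass
class MsdFit:
    """Power-law fit MSD_2d = 4 D_xz t^alpha over a lag window."""

    alpha: float
    d_xz: float
    stderr_alpha: float
    fit_window: tuple
    lags_time: np.ndarray
    msd: np.ndarray

    def __post_init__(self):
        if not np.isfinite(self.alpha):
            raise InvalidParameterError("power-law fit failed")


def _log_lags(n_samples: int, n_lags: int, lag_min: int = 1,
              lag_max: int | None = None) -> np.ndarray:
    hi = lag_max if lag_max is not None else n_samples - 1
    hi = min(hi, n_samples - 1)
    lags = np.unique(np.round(np.geomspace(lag_min, hi, n_lags))
                     .astype(np.int64))
    return lags[lags >= 1]


def msd_from_positions(positions: np.ndarray, dt_sample: float,
                       axes=(0, 2), n_lags: int = 40,
                       lags_steps: np.ndarray | None = None,
                       dt_sim: float | None = None) -> MsdCurve:
    """Time-origin-averaged MSD of a (T, 3) or (T, n, 3) position series.

    ``axes`` selects the projection (default xz plane).  Multi-bead input
    is additionally averaged over beads.
    """
    pos = np.asarray(positions, dtype=np.float64)
    if pos.ndim == 2:
        pos = pos[:, None, :]
    T = pos.shape[0]
    if T < 3:
        raise TooShortError("need at least 3 samples for an MSD")
    sel = pos[:, :, list(axes)]
    if lags_steps is None:
        lags_steps = _log_lags(T, n_lags)
    lags_steps = np.asarray(lags_steps, dtype=np.int64)
    msd = np.empty(lags_steps.size)
    n_origins = np.empty(lags_steps.size, dtype=np.int64)
    for k, lag in enumerate(lags_steps):
        diff = sel[lag:] - sel[:-lag]
        msd[k] = np.mean(np.sum(diff * diff, axis=-1))
        n_origins[k] = diff.shape[0] * diff.shape[1]
    return MsdCurve(lags_time=lags_steps * dt_sample, msd=msd,
                    n_origins=n_origins, dt_sample=dt_sample,
                    dt_sim=(dt_sim if dt_sim is not None else dt_sample),
                    series_time=(T - 1) * dt_sample)


def msd_2d(trajectory: Trajectory, bead_selection="all", plane: str = "xz",
           n_lags: int = 40, use_tracked: bool = False,
           window: bool = True) -> MsdCurve:
    """2D MSD from a trajectory.

    ``bead_selection`` is "all" (bead- and origin-averaged) or a single
    bead index.  ``use_tracked=True`` reads the per-step record of a
    tracked bead instead of the subsampled frames.  ``window`` restricts
    frames to the analysis-eligible part of production.
    """
    if plane not in _PLANES:
        raise InvalidParameterError(f"unknown plane {plane!r}")
    axes = _PLANES[plane]
    dt_sim = trajectory.config.dt
    if use_tracked:
        if bead_selection == "all":
            raise InvalidParameterError(
                "use_tracked requires a single bead index")
        pos = trajectory.tracked_positions(int(bead_selection))
        if window:
            pos = pos[trajectory.analysis_start_step:]
        if pos.shape[0] < _MIN_FRAMES:
            raise TooShortError(
                f"need >= {_MIN_FRAMES} samples, have {pos.shape[0]}")
        curve = msd_from_positions(pos, dt_sim, axes=axes, n_lags=n_lags,
                                   dt_sim=dt_sim)
    else:
        frames = (trajectory.analysis_frames() if window
                  else trajectory.frames)
        if frames.shape[0] < _MIN_FRAMES:
            raise TooShortError(
                f"need >= {_MIN_FRAMES} usable frames, "
                f"have {frames.shape[0]}")
        if bead_selection != "all":
            frames = frames[:, [int(bead_selection)], :]
        curve = msd_from_positions(frames, trajectory.frame_dt, axes=axes,
                                   n_lags=n_lags, dt_sim=dt_sim)
    curve.plane = plane
    return curve


def fit_power_law(curve: MsdCurve, fit_window: tuple | None = None) -> MsdFit:
    """Least-squares line in log(MSD) vs log(t); alpha is the slope.

    The default window is [10 sampling intervals, T/10]: the first ten
    lags of any series are dominated by sampling discreteness and the
    fastest local relaxations, and lags beyond a tenth of the series have
    too few independent origins.  For a per-step series this is
    [10 dt, T/10]; for frame-subsampled curves the lower edge scales with
    the frame interval.  Pass ``fit_window`` to override.
    """
    if fit_window is None:
        fit_window = (max(10.0 * curve.dt_sample,
                          curve.lags_time[0] * 0.999),
                      curve.series_time / 10.0)
    lo, hi = fit_window
    mask = (curve.lags_time >= lo) & (curve.lags_time <= hi)
    if mask.sum() < 8:
        raise TooShortError(
            f"need >= 8 lag points inside the window {fit_window}, "
            f"have {int(mask.sum())}")
    t = curve.lags_time[mask]
    m = curve.msd[mask]
    if np.any(m <= 0):
        raise InvalidParameterError(
            "non-positive MSD values inside the fit window")
    res = stats.linregress(np.log(t), np.log(m))
    return MsdFit(alpha=float(res.slope),
                  d_xz=float(np.exp(res.intercept) / 4.0),
                  stderr_alpha=float(res.stderr),
                  fit_window=(float(lo), float(hi)),
                  lags_time=t, msd=m)


# ---------------------------------------------------------------------------
# VACF
# ---------------------------------------------------------------------------

@dataclass
class VacfCurve:
    """Velocity autocovariance from single-step displacement differences."""

    lags_time: np.ndarray
    c_v: np.ndarray
    c_v_normalized: np.ndarray
    c_v_se: np.ndarray          # block standard errors of the normalized VACF
    dt: float

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"lag_time": self.lags_time, "c_v": self.c_v,
                             "c_v_normalized": self.c_v_normalized,
                             "se": self.c_v_se})


def vacf_from_positions(positions: np.ndarray, dt: float,
                        max_lag: int = 100, n_blocks: int = 20) -> VacfCurve:
    """VACF of one bead from per-step (T, 3) positions.

    C_v(k dt) = <v(t + k dt) . v(t)> with v the single-step displacement
    divided by dt, averaged over all origins.  Standard errors come from
    ``n_blocks`` non-overlapping block means.
    """
    pos = np.asarray(positions, dtype=np.float64)
    T = pos.shape[0]
    if T < max_lag + 10:
        raise TooShortError(
            f"need at least {max_lag + 10} per-step samples, have {T}")
    v = np.diff(pos, axis=0) / dt
    nv = v.shape[0]
    c = np.empty(max_lag + 1)
    se = np.empty(max_lag + 1)
    c0 = np.mean(np.sum(v * v, axis=1))
    for k in range(max_lag + 1):
        prod = np.sum(v[k:] * v[:nv - k], axis=1)
        c[k] = prod.mean()
        nb = min(n_blocks, prod.size)
        blocks = np.array_split(prod, nb)
        bm = np.array([b.mean() for b in blocks])
        se[k] = bm.std(ddof=1) / np.sqrt(nb) / c0
    return VacfCurve(lags_time=np.arange(max_lag + 1) * dt, c_v=c,
                     c_v_normalized=c / c0, c_v_se=se, dt=dt)


def vacf(trajectory: Trajectory, bead_index: int, max_lag: int = 100,
         window: bool = True) -> VacfCurve:
    """VACF of a per-step-tracked bead (lag resolution = one time step)."""
    pos = trajectory.tracked_positions(int(bead_index))
    if window:
        pos = pos[trajectory.analysis_start_step:]
    return vacf_from_positions(pos, trajectory.config.dt, max_lag=max_lag)


# ---------------------------------------------------------------------------
# Displacement distributions
# ---------------------------------------------------------------------------

@dataclass
class DisplacementHistogram:
    """Standardized one-axis displacement distribution at one lag."""

    lag_time: float
    lag_steps: int
    delta: float                    # std of the raw displacements
    bin_centers: np.ndarray
    densities: np.ndarray
    ks_distance: float
    ks_threshold: float
    n_samples: int
    n_effective: int
    passed: bool

    def reference_density(self) -> np.ndarray:
        return stats.norm.pdf(self.bin_centers)


def displacement_distribution(trajectory: Trajectory, bead_index: int,
                              axis: str = "z",
                              lags=(1.0, 10.0, 100.0, 1000.0),
                              bins: int = 41, hist_range=(-5.0, 5.0),
                              window: bool = True,
                              ) -> list[DisplacementHistogram]:
    """Standardized displacement histograms Delta z / delta per time lag.

    Lags are in simulation-time units and are converted to steps with the
    per-step record of the tracked bead.  The KS distance to N(0, 1) is
    compared against the 1% critical value at the number of
    *non-overlapping* displacement windows (overlapping origins are
    correlated and do not add information at this scale).
    """
    ax = {"x": 0, "y": 1, "z": 2}[axis]
    pos = trajectory.tracked_positions(int(bead_index))[:, ax]
    if window:
        pos = pos[trajectory.analysis_start_step:]
    dt = trajectory.config.dt
    out = []
    for lag_time in lags:
        lag_steps = max(1, int(round(lag_time / dt)))
        if lag_steps >= pos.size:
            raise TooShortError(
                f"lag {lag_time} exceeds the tracked series length")
        disp = pos[lag_steps:] - pos[:-lag_steps]
        delta = disp.std()
        if delta == 0.0:
            raise InvalidParameterError(
                f"degenerate displacement distribution at lag {lag_time} "
                "(zero standard deviation)")
        z = disp / delta
        dens, edges = np.histogram(z, bins=bins, range=hist_range,
                                   density=True)
        ks = float(stats.kstest(z, "norm").statistic)
        n_eff = max(2, disp.size // lag_steps)
        thresh = 1.63 / np.sqrt(n_eff)
        out.append(DisplacementHistogram(
            lag_time=float(lag_time), lag_steps=lag_steps,
            delta=float(delta),
            bin_centers=0.5 * (edges[1:] + edges[:-1]), densities=dens,
            ks_distance=ks, ks_threshold=float(thresh),
            n_samples=disp.size, n_effective=n_eff,
            passed=bool(ks <= thresh)))
    return out


# ---------------------------------------------------------------------------
# Projected density & energy
# ---------------------------------------------------------------------------

@dataclass
class DensityMap:
    """Projected number density of beads on the xz plane."""

    counts: np.ndarray          # (nx, nz); sums to beads x frames
    density: np.ndarray         # per-frame areal number density
    x_edges: np.ndarray
    z_edges: np.ndarray
    com_z_offset: np.ndarray    # per-frame center-of-mass z offset
    n_frames: int


def projected_density(trajectory: Trajectory, bin_size: float = 0.5,
                      window: bool = True) -> DensityMap:
    frames = trajectory.analysis_frames() if window else trajectory.frames
    if frames.shape[0] == 0:
        raise TooShortError("no frames in the analysis window")
    x = frames[:, :, 0].ravel()
    z = frames[:, :, 2].ravel()
    geom = trajectory.geometry
    if geom is not None:
        x_lim, z_lim = geom.radius, geom.half_length
    else:
        x_lim = float(np.abs(x).max()) + 1e-9
        z_lim = float(np.abs(z).max()) + 1e-9
    nx = max(1, int(np.ceil(2 * x_lim / bin_size)))
    nz = max(1, int(np.ceil(2 * z_lim / bin_size)))
    counts, x_edges, z_edges = np.histogram2d(
        x, z, bins=[nx, nz], range=[[-x_lim, x_lim], [-z_lim, z_lim]])
    n_frames = frames.shape[0]
    area = (x_edges[1] - x_edges[0]) * (z_edges[1] - z_edges[0])
    return DensityMap(counts=counts, density=counts / (n_frames * area),
                      x_edges=x_edges, z_edges=z_edges,
                      com_z_offset=frames[:, :, 2].mean(axis=1),
                      n_frames=n_frames)


@dataclass
class EnergyTrace:
    """Potential-energy series with plateau diagnostics.

    The plateau test fits a line to block means of the last half of the
    series; a plateau is declared when the 95% confidence interval of the
    slope contains zero.
    """

    steps: np.ndarray
    energies: np.ndarray
    plateau_mean: float
    plateau_std: float
    slope: float
    slope_ci: tuple
    plateau_detected: bool
    equilibration_step_estimate: int


def energy_trace(trajectory: Trajectory, last_fraction: float = 0.5,
                 n_blocks: int = 8) -> EnergyTrace:
    steps = trajectory.energy_steps
    e = trajectory.energies
    if e.size < 2 * n_blocks:
        raise TooShortError(
            f"need at least {2 * n_blocks} energy records, have {e.size}")
    n_tail = max(n_blocks, int(round(last_fraction * e.size)))
    tail_e = e[-n_tail:]
    tail_t = steps[-n_tail:].astype(np.float64) * trajectory.config.dt
    blocks_e = np.array([b.mean() for b in np.array_split(tail_e, n_blocks)])
    blocks_t = np.array([b.mean() for b in np.array_split(tail_t, n_blocks)])
    res = stats.linregress(blocks_t, blocks_e)
    tcrit = stats.t.ppf(0.975, n_blocks - 2)
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    plateau_mean = float(tail_e.mean())
    plateau_std = float(tail_e.std())
    # first record whose energy stays within 3 plateau-sigma of the mean
    tol = 3.0 * max(plateau_std, 1e-12)
    inside = np.abs(e - plateau_mean) <= tol
    eq_idx = 0
    for i in range(e.size):
        if inside[i:].all():
            eq_idx = i
            break
    return EnergyTrace(steps=steps, energies=e, plateau_mean=plateau_mean,
                       plateau_std=plateau_std, slope=float(res.slope),
                       slope_ci=(float(ci[0]), float(ci[1])),
                       plateau_detected=bool(ci[0] <= 0.0 <= ci[1]),
                       equilibration_step_estimate=int(steps[eq_idx]))
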