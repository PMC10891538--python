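"""Fractional Gaussian noise (fGn) generation and validation.

fGn is the increment process of fractional Brownian motion B_H.  For
standardized increments X(n) = B_H(n+1) - B_H(n) the autocovariance at
integer lag k is

    gamma(k) = 1/2 ( |k-1|^{2H} - 2|k|^{2H} + |k+1|^{2H} ),

with Hurst parameter H in (0, 1).  H = 1/2 gives uncorrelated white noise
(ordinary Brownian motion), H < 1/2 anticorrelated (subdiffusive) and
H > 1/2 positively correlated (superdiffusive) increments.

The primary sampler is the Davies-Harte circulant-embedding method: the
n x n Toeplitz covariance is embedded in an M x M circulant matrix
(M a power of two >= 2n) whose eigenvalues are the FFT of its first row;
an exact stationary Gaussian sample is then one inverse real FFT of a
spectrally weighted white-noise vector, O(M log M).  If the embedding has
negative eigenvalues the exact-but-O(n^2) Hosking (Durbin-Levinson)
recursion is used instead.  Covariance exactness is this module's
contract: negative eigenvalues are never clamped to zero.

Per-(bead, axis) streams are seeded with a counter-based scheme,
``SeedSequence(seed, spawn_key=(bead, axis))``, so every stream is
reproducible in isolation and independent of all others.
"""

from __future__ import annotations

import functools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .errors import (AlgorithmFailureError, HurstRangeWarning,
                     InvalidParameterError, MemoryBudgetError, TooShortError)
from ._kernels import hosking_sample

__all__ = [
    "FgnSpec", "NoiseTensor", "ChunkPolicy", "FgnValidationReport",
    "autocovariance", "generate_fgn", "generate_noise_tensor",
    "iter_noise_blocks", "validate_fgn", "save_noise_tensor",
    "load_noise_tensor",
]

#: practical Hurst range; outside it generation is slow/marginal, warn only
HURST_PRACTICAL_RANGE = (0.35, 0.65)

#: eigenvalues below -RELATIVE_EIG_TOL * max(eig) count as genuinely negative
_RELATIVE_EIG_TOL = 1e-8

_DEFAULT_MEMORY_BUDGET = 6 * 1024**3  # bytes


def _check_hurst(hurst: float) -> float:
    hurst = float(hurst)
    if not (0.0 < hurst < 1.0) or not math.isfinite(hurst):
        raise InvalidParameterError(
            f"Hurst parameter must lie in the open interval (0, 1), got {hurst}")
    return hurst


def _warn_hurst_range(hurst: float) -> None:
    lo, hi = HURST_PRACTICAL_RANGE
    if not (lo <= hurst <= hi):
        warnings.warn(
            f"H={hurst} is outside the practical range [{lo}, {hi}]; "
            "generation may be slow and statistics heavy-tailed in lag",
            HurstRangeWarning, stacklevel=3)


@dataclass(frozen=True)
class FgnSpec:
    """Specification of one standardized fGn stream.

    Parameters
    ----------
    hurst : float
        Hurst parameter, in (0, 1).
    length : int
        Number of increments, >= 1.
    seed : int
        Seed for the stream's random state.
    """

    hurst: float
    length: int
    seed: int = 0

    def __post_init__(self):
        _check_hurst(self.hurst)
        if int(self.length) < 1:
            raise InvalidParameterError(
                f"stream length must be >= 1, got {self.length}")
        object.__setattr__(self, "length", int(self.length))
        object.__setattr__(self, "seed", int(self.seed))


@dataclass
class NoiseTensor:
    """Pre-generated noise for a whole simulation.

    ``values[bead, axis, step]`` are standardized fGn increments; the
    3 * n_beads streams are mutually independent (the model treats the
    viscoelastic medium seen by each bead, and each Cartesian axis, as an
    independent realization).  ``seeds[bead, axis]`` is a stable integer
    fingerprint of each stream's seed sequence.
    """

    values: np.ndarray
    hurst: float
    seeds: np.ndarray
    algorithm: str = "davies-harte"

    @property
    def n_beads(self) -> int:
        return self.values.shape[0]

    @property
    def n_steps(self) -> int:
        return self.values.shape[2]


@dataclass(frozen=True)
class ChunkPolicy:
    """Chunked noise delivery for runs too long to pre-generate in memory.

    Blocks of ``block_length`` steps are generated independently per
    stream; covariance is exact within a block but long-range correlation
    *across* block boundaries is truncated.  A documented approximation,
    off by default.
    """

    block_length: int

    def __post_init__(self):
        if int(self.block_length) < 2:
            raise InvalidParameterError("block_length must be >= 2")
        object.__setattr__(self, "block_length", int(self.block_length))


def autocovariance(k, hurst: float):
    """Autocovariance gamma(k) of standardized fGn at integer lag(s) ``k``.

    Even in k; gamma(0) = 1 for every H.  Accepts scalars or arrays.
    """
    hurst = _check_hurst(hurst)
    k_arr = np.abs(np.asarray(k, dtype=np.float64))
    h2 = 2.0 * hurst
    out = 0.5 * (np.abs(k_arr - 1.0) ** h2 - 2.0 * k_arr ** h2
                 + (k_arr + 1.0) ** h2)
    if np.isscalar(k) or np.ndim(k) == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Davies-Harte circulant embedding
# ---------------------------------------------------------------------------

def _embedding_size(n: int) -> int:
    """Smallest even FFT-friendly M >= 2n (padding uses true covariances
    at the extra lags, which only enlarges the embedded Toeplitz block)."""
    from scipy.fft import next_fast_len

    m = next_fast_len(max(4, 2 * n))
    while m % 2:
        m = next_fast_len(m + 1)
    return m


@functools.lru_cache(maxsize=8)
def _dh_spectrum(n: int, hurst: float) -> tuple[np.ndarray, int]:
    """Eigenvalues of the circulant embedding (half spectrum, length M/2+1).

    Raises
    ------
    AlgorithmFailureError
        If any eigenvalue is genuinely negative (embedding invalid).
    """
    m = _embedding_size(n)
    g = autocovariance(np.arange(m // 2 + 1), hurst)
    first_row = np.concatenate([g, g[-2:0:-1]])  # symmetric, length m
    lam = np.fft.rfft(first_row).real
    lam_max = lam.max()
    if lam.min() < -_RELATIVE_EIG_TOL * lam_max:
        raise AlgorithmFailureError(
            f"circulant embedding not nonnegative definite for H={hurst}, "
            f"n={n} (min eigenvalue {lam.min():.3e})")
    # remaining tiny negatives are floating-point zeros of the spectrum
    np.clip(lam, 0.0, None, out=lam)
    return lam, m


def _dh_sample_batch(rngs, lam_sqrt: np.ndarray, n: int, m: int,
                     out=None) -> np.ndarray:
    """Draw one exact fGn sample of length n per rng via the embedding.

    The spectrum is assembled through a zero-copy complex view of the
    normal draws; all arithmetic is double precision (``out`` may be a
    lower-precision buffer, in which case values are rounded on store).
    """
    from scipy import fft as sfft

    half = m // 2
    n_streams = len(rngs)
    z = np.empty((n_streams, m))
    for i, rng in enumerate(rngs):
        z[i] = rng.standard_normal(m)
    w = np.empty((n_streams, half + 1), dtype=np.complex128)
    w[:, 0] = lam_sqrt[0] * z[:, 0]
    w[:, half] = lam_sqrt[half] * z[:, 1]
    # interleaved (re, im) pairs are exactly the complex memory layout
    w[:, 1:half] = z[:, 2:].view(np.complex128)
    w[:, 1:half] *= lam_sqrt[1:half] * math.sqrt(0.5)
    x = sfft.irfft(w, n=m, axis=-1)
    if out is None:
        out = np.empty((n_streams, n))
    np.multiply(x[:, :n], math.sqrt(m), out=out, casting="unsafe")
    return out


def _hosking_gamma(n: int, hurst: float) -> np.ndarray:
    return autocovariance(np.arange(n), hurst)


def generate_fgn(spec: FgnSpec, method: str = "auto") -> np.ndarray:
    """Generate one standardized fGn stream.

    Parameters
    ----------
    spec : FgnSpec
    method : {"auto", "davies-harte", "hosking"}
        "auto" tries circulant embedding and falls back to the Hosking
        recursion; "davies-harte" raises :class:`AlgorithmFailureError` on
        embedding failure instead of falling back.
    """
    _warn_hurst_range(spec.hurst)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    if method not in ("auto", "davies-harte", "hosking"):
        raise InvalidParameterError(f"unknown method {method!r}")
    if method in ("auto", "davies-harte"):
        try:
            lam, m = _dh_spectrum(spec.length, spec.hurst)
        except AlgorithmFailureError:
            if method == "davies-harte":
                raise
        else:
            return _dh_sample_batch([rng], np.sqrt(lam), spec.length, m)[0]
    gamma = _hosking_gamma(spec.length, spec.hurst)
    z = rng.standard_normal(spec.length)
    return hosking_sample(gamma, z)


def _stream_seedseq(seed: int, bead: int, axis: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(int(seed), spawn_key=(int(bead), int(axis)))


def generate_noise_tensor(n_beads: int, n_steps: int, hurst: float,
                          seed: int, chunk_policy: ChunkPolicy | None = None,
                          memory_budget: int = _DEFAULT_MEMORY_BUDGET,
                          batch_size: int = 128,
                          dtype=np.float64) -> NoiseTensor:
    """Pre-generate 3 independent standardized fGn streams per bead.

    Stream (bead, axis) depends only on ``(seed, bead, axis)``, so any
    subset of streams is reproducible without generating the rest.

    Raises
    ------
    MemoryBudgetError
        If the full tensor would exceed ``memory_budget`` bytes and no
        chunk policy was supplied (chunked delivery goes through
        :func:`iter_noise_blocks` instead).
    """
    hurst = _check_hurst(hurst)
    n_beads, n_steps = int(n_beads), int(n_steps)
    if n_beads < 1 or n_steps < 1:
        raise InvalidParameterError("n_beads and n_steps must be >= 1")
    _warn_hurst_range(hurst)
    dtype = np.dtype(dtype).type
    nbytes = n_beads * 3 * n_steps * np.dtype(dtype).itemsize
    if nbytes > memory_budget:
        if chunk_policy is None:
            raise MemoryBudgetError(
                f"full noise tensor needs {nbytes/1e9:.1f} GB "
                f"(> budget {memory_budget/1e9:.1f} GB); enable chunked "
                "generation via iter_noise_blocks / a ChunkPolicy")
        raise MemoryBudgetError(
            "chunked runs should consume iter_noise_blocks(), not a full "
            "NoiseTensor")

    algorithm = "davies-harte"
    try:
        lam, m = _dh_spectrum(n_steps, hurst)
        lam_sqrt = np.sqrt(lam)
    except AlgorithmFailureError:
        algorithm = "hosking"
        gamma = _hosking_gamma(n_steps, hurst)

    values = np.empty((n_beads, 3, n_steps), dtype=dtype)
    seeds = np.empty((n_beads, 3), dtype=np.uint64)
    streams = [(b, a) for b in range(n_beads) for a in range(3)]
    for i0 in range(0, len(streams), batch_size):
        chunk = streams[i0:i0 + batch_size]
        rngs = []
        for (b, a) in chunk:
            ss = _stream_seedseq(seed, b, a)
            seeds[b, a] = ss.generate_state(1, dtype=np.uint64)[0]
            rngs.append(np.random.default_rng(ss))
        if algorithm == "davies-harte":
            block = _dh_sample_batch(rngs, lam_sqrt, n_steps, m,
                                     out=np.empty((len(chunk), n_steps),
                                                  dtype=dtype))
            for (b, a), row in zip(chunk, block):
                values[b, a] = row
        else:
            for (b, a), rng in zip(chunk, rngs):
                values[b, a] = hosking_sample(
                    gamma, rng.standard_normal(n_steps)).astype(dtype)
    return NoiseTensor(values=values, hurst=hurst, seeds=seeds,
                       algorithm=algorithm)


def iter_noise_blocks(n_beads: int, n_steps: int, hurst: float, seed: int,
                      policy: ChunkPolicy, dtype=np.float64,
                      ) -> Iterator[tuple[int, NoiseTensor]]:
    """Yield ``(start_step, NoiseTensor)`` blocks of independent fGn.

    Covariance is exact within each block; correlation across block
    boundaries is truncated (the documented chunked-mode approximation).
    Block b of stream (bead, axis) is seeded from (seed, bead, axis, b).
    """
    hurst = _check_hurst(hurst)
    start = 0
    block_index = 0
    while start < n_steps:
        length = min(policy.block_length, n_steps - start)
        block_seed = np.random.SeedSequence(
            int(seed), spawn_key=(int(block_index),))
        sub_seed = int(block_seed.generate_state(1)[0] & 0x7FFFFFFF)
        yield start, generate_noise_tensor(n_beads, length, hurst, sub_seed,
                                           dtype=dtype)
        start += length
        block_index += 1


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class FgnValidationReport:
    """Empirical moments of a stream against fGn theory, with pass flags.

    Bands: the sample mean of fGn has exact standard deviation n^{H-1}
    (from Var[B_H(n)] = n^{2H}); the variance and lag bands use the
    Bartlett large-sample approximation with the theoretical covariance.
    The normality band accounts for long-range dependence: the empirical
    CDF of fGn fluctuates at scale ~ n^{H-1}, not n^{-1/2}.
    """

    n: int
    hurst: float
    mean: float
    mean_band: float
    variance: float
    variance_band: float
    lags: np.ndarray
    acov_empirical: np.ndarray
    acov_theory: np.ndarray
    acov_band: np.ndarray
    normality_stat: float
    normality_band: float
    flags: dict = field(default_factory=dict)
    passed: bool = False
    short_stream_warning: bool = False

    def summary(self) -> str:
        lines = [
            f"fGn validation (n={self.n}, H={self.hurst})",
            f"  mean     {self.mean:+.5f}  (band +/-{self.mean_band:.5f})"
            f"  -> {'ok' if self.flags['mean'] else 'FAIL'}",
            f"  variance {self.variance:.5f}  "
            f"(band 1 +/- {self.variance_band:.5f})"
            f"  -> {'ok' if self.flags['variance'] else 'FAIL'}",
            f"  autocovariance lags 1..{self.lags[-1]} "
            f"-> {'ok' if self.flags['autocovariance'] else 'FAIL'}",
            f"  normality KS={self.normality_stat:.5f} "
            f"(band {self.normality_band:.5f})"
            f"  -> {'ok' if self.flags['normality'] else 'FAIL'}",
            f"  overall: {'PASS' if self.passed else 'FAIL'}",
        ]
        if self.short_stream_warning:
            lines.append("  warning: stream shorter than 10^3; "
                         "bands are unreliable")
        return "\n".join(lines)


def _empirical_acov(x: np.ndarray, max_lag: int) -> np.ndarray:
    n = x.size
    xc = x - x.mean()
    out = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        out[k] = np.dot(xc[:n - k], xc[k:]) / n
    return out


def validate_fgn(stream: np.ndarray, hurst: float,
                 max_lag: int = 20, n_sigma: float = 4.0,
                 ) -> FgnValidationReport:
    """Check a stream's moments against standardized-fGn theory.

    Flags pass when the empirical mean, variance, autocovariances at lags
    1..max_lag and the Kolmogorov-Smirnov distance to N(0,1) all fall
    inside ``n_sigma`` theoretical bands.  Streams shorter than 10^3 get a
    warning-level report (bands too wide to be meaningful), never a hard
    failure.
    """
    from scipy import stats

    hurst = _check_hurst(hurst)
    x = np.asarray(stream, dtype=np.float64).ravel()
    n = x.size
    if n < 2:
        raise TooShortError(f"need at least 2 samples, got {n}")
    short = n < 1000
    max_lag = int(min(max_lag, n - 1))

    theory = autocovariance(np.arange(max_lag + 1), hurst)
    emp = _empirical_acov(x, max_lag)

    # Bartlett-style standard errors with the theoretical covariance
    gsq = np.sum(autocovariance(np.arange(1, min(n, 2000)), hurst) ** 2)
    se_acov = math.sqrt((1.0 + 2.0 * gsq) / n)
    mean_band = n_sigma * n ** (hurst - 1.0)          # exact sd of the mean
    var_band = n_sigma * math.sqrt(2.0 * (1.0 + 2.0 * gsq) / n)
    acov_band = np.full(max_lag, n_sigma * se_acov)

    sd = x.std()
    if sd == 0.0:
        ks_stat = 1.0
    else:
        ks_stat = float(stats.kstest(x, "norm").statistic)
    # empirical-CDF scale for long-range-dependent Gaussian sequences
    norm_band = max(n_sigma * 0.41 * n ** (hurst - 1.0),
                    1.63 / math.sqrt(n))

    flags = {
        "mean": bool(abs(x.mean()) <= mean_band),
        "variance": bool(abs(emp[0] - 1.0) <= var_band),
        "autocovariance": bool(
            np.all(np.abs(emp[1:] - theory[1:]) <= acov_band)),
        "normality": bool(ks_stat <= norm_band),
    }
    return FgnValidationReport(
        n=n, hurst=hurst, mean=float(x.mean()), mean_band=mean_band,
        variance=float(emp[0]), variance_band=var_band,
        lags=np.arange(1, max_lag + 1), acov_empirical=emp[1:],
        acov_theory=theory[1:], acov_band=acov_band,
        normality_stat=ks_stat, normality_band=norm_band,
        flags=flags, passed=all(flags.values()) and not short,
        short_stream_warning=short)


# ---------------------------------------------------------------------------
# Optional persisted noise store
# ---------------------------------------------------------------------------

def save_noise_tensor(path, tensor: NoiseTensor, master_seed: int | None = None
                      ) -> None:
    """Persist a noise tensor, one HDF5 dataset per (bead, axis) stream."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["hurst"] = tensor.hurst
        f.attrs["algorithm"] = tensor.algorithm
        f.attrs["n_beads"] = tensor.n_beads
        f.attrs["n_steps"] = tensor.n_steps
        if master_seed is not None:
            f.attrs["master_seed"] = int(master_seed)
        grp = f.create_group("streams")
        for b in range(tensor.n_beads):
            for a in range(3):
                ds = grp.create_dataset(f"bead{b:05d}_axis{a}",
                                        data=tensor.values[b, a])
                ds.attrs["hurst"] = tensor.hurst
                ds.attrs["seed_fingerprint"] = int(tensor.seeds[b, a])
                ds.attrs["algorithm"] = tensor.algorithm


def load_noise_tensor(path) -> NoiseTensor:
    import h5py

    with h5py.File(path, "r") as f:
        nb = int(f.attrs["n_beads"])
        ns = int(f.attrs["n_steps"])
        values = np.empty((nb, 3, ns))
        seeds = np.empty((nb, 3), dtype=np.uint64)
        grp = f["streams"]
        for b in range(nb):
            for a in range(3):
                ds = grp[f"bead{b:05d}_axis{a}"]
                values[b, a] = ds[...]
                seeds[b, a] = int(ds.attrs["seed_fingerprint"])
        return NoiseTensor(values=values, hurst=float(f.attrs["hurst"]),
                           seeds=seeds, algorithm=str(f.attrs["algorithm"]))
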