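# fbdsim — fractional Brownian dynamics of confined bottle-brush polymers

Chromosomal loci and cytoplasmic particles in bacteria subdiffuse: their
mean-squared displacement grows as MSD ∝ t^α with α ≈ 0.4, and their
velocities are *anticorrelated* at short lags — the signature of a
viscoelastic medium rather than of obstruction or trapping.  `fbdsim`
models this by replacing the white thermal noise of overdamped Brownian
dynamics with **fractional Gaussian noise (fGn)**, the increment process
of fractional Brownian motion B_H.  Each bead of a coarse-grained polymer
is advanced by

    r(n+1) = r(n) + (Δt/ζ) F(n) + sqrt(2 k_BT Δt/ζ) ξ(n),   ζ = 6πη a,

where the components of ξ(n) are independent standardized fGn streams
with autocovariance

    γ(k) = ½ ( |k−1|^{2H} − 2|k|^{2H} + |k+1|^{2H} ),   H ∈ (0, 1).

H = ½ recovers ordinary Brownian dynamics; H < ½ gives anticorrelated,
subdiffusive motion (a force-free bead has MSD exponent α = 2H).  The
polymer is a minimal bacterial-nucleoid model: a bottle brush of 200
backbone beads, each carrying a 40-bead side loop (8,200 beads), confined
to a cylinder of radius 14.75 σ and length 50.75 σ, with FENE or harmonic
bonds, WCA excluded volume and a 10–4 wall potential.  The analysis suite
measures what tracking experiments measure: the 2D MSD power law
MSD₂d = 4 D_xz t^α, the velocity autocorrelation function, standardized
displacement distributions Δz/δ, projected bead densities and
potential-energy traces.

The package is aimed at people studying anomalous diffusion in
coarse-grained models — the fGn generator (exact Davies–Harte circulant
embedding with a Hosking-recursion fallback, per-stream counter-based
seeding) and the estimators are usable on their own.

## Worked example

```python
import numpy as np
from fbdsim import analysis, fgn, presets

# 1. the noise is exactly what it claims to be
spec = fgn.FgnSpec(hurst=0.4, length=100_000, seed=1)
print(fgn.validate_fgn(fgn.generate_fgn(spec), hurst=0.4).summary())

# 2. a force-free bead driven by fGn subdiffuses with alpha = 2H
traj = presets.run_free_beads(hurst=0.45, n_steps=100_000, seed=1,
                              n_beads=20)
curve = analysis.msd_from_positions(traj.tracked, dt_sample=0.01)
fit = analysis.fit_power_law(curve, fit_window=(0.1, 100.0))
print(f"alpha = {fit.alpha:.3f}  (theory 2H = 0.90)")

# 3. its increments are the fGn: normalized VACF equals gamma(k)
v = analysis.vacf_from_positions(traj.tracked_positions(0), dt=0.01,
                                 max_lag=3)
print(np.round(v.c_v_normalized[:4], 4))
print(np.round(fgn.autocovariance(np.arange(4), 0.45), 4))
```

prints

```
fGn validation (n=100000, H=0.4)
  mean     +0.00098  (band +/-0.00400)  -> ok
  variance 0.99193  (band 1 +/- 0.01823)  -> ok
  autocovariance lags 1..20 -> ok
  normality KS=0.00218 (band 0.00515)  -> ok
  overall: PASS
alpha = 0.908  (theory 2H = 0.90)
[ 1.     -0.064  -0.023  -0.0124]
[ 1.     -0.067  -0.0221 -0.0137]
```

The validation bands are theoretical (the sample mean of fGn has exact
standard deviation n^{H−1}); α = 0.908 against 2H = 0.90 is parameter
recovery from simulated data, and the last two lines show the measured
velocity autocorrelation of the bead sitting on top of the analytic noise
autocovariance.

Confined-polymer runs go through the same machinery, e.g.

```bash
fbdsim run --n-backbone 30 --loop-size 40 --cylinder-radius 14.75 \
           --cylinder-length 7.6125 --bond-type harmonic --hurst 0.45 \
           --equil-steps 20000 --steps 100000 --track-bead 15 \
           --seed 1 --out brush.h5
fbdsim analyze --traj brush.h5 --out brush_analysis
fbdsim demo --out demo_dir        # end-to-end scaled reproduction
fbdsim validate-fgn --hurst 0.35 -n 100000
```

On such runs a bead in the middle of the backbone fits to α ≈ 0.30–0.35
for H ≤ 0.5 while a bead on the side loop at the backbone end fits to
α ≈ 0.5, both subdiffusive yet with Gaussian displacement distributions —
the position-dependent, "non-Brownian yet Gaussian" motion seen for
chromosomal loci.

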