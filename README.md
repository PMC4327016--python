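# lpmp — Lorentzian peak matching pursuit

Greedy reconstruction of non-uniformly sampled, exponentially decaying
signals whose spectra are sums of Lorentzian peaks — the situation of the
indirect dimension of multidimensional NMR experiments, where each time
point costs seconds of spectrometer time and non-uniform sampling (NUS) is
the standard remedy.

Classical compressed-sensing solvers such as orthogonal matching pursuit
(OMP) assume the spectrum is *strictly* sparse, but a Lorentzian peak of
half-width γ is never a handful of frequency impulses.  LPMP keeps OMP's
greedy structure while replacing its impulse dictionary with a family of
discrete Lorentzian atoms

&nbsp;&nbsp;&nbsp;&nbsp;`L_l^j = T · C^j · S_l` ,&nbsp;&nbsp; l ∈ [−N, N],&nbsp; j ∈ [0, J],

where `S`/`T` are the synthesis/analysis transforms of the 2N+1-point grid
and `C` damps time sample k by `exp(−2π k Γ/Ω)`.  Each iteration

1. picks the peak **center** `l = argmax |(A* r)_l|` (matched filter on the
   residual, A = transform rows restricted to the sampling schedule K),
2. searches the **width index** j ∈ [0, J] exhaustively, refitting all
   amplitudes jointly by least squares for every candidate,
3. commits the width permanently (amplitudes stay free forever after).

Stopping is by residual threshold ε, by relative improvement factor
α (default 0.98), or by noise amplitude σ; a *mask* of admissible peak
centers — prior knowledge from related experiments — restricts step 1.
A plain OMP baseline, a synthetic FID generator, and a schedule-averaged
benchmark harness are included.  See `docs/methods.md` for the model,
conventions, and known limitations.

## Worked example

Reconstruct the packaged six-peak scenario (257-point grid, ~20× dynamic
range, overlapping pair, off-grid centers and widths, 5 % noise) from 120
randomly sampled points, with a ±5-point mask around the known centers:

```python
import numpy as np
from lpmp import (Mask, StoppingRule, lpmp_reconstruct, measurement_operator,
                  omp_reconstruct, recovery_error, time_to_spectrum)
from lpmp.simulate import (add_noise, default_benchmark_grid, random_schedule,
                           sample_measurement, synthesize_continuous_fid,
                           table1_scenario)

grid = default_benchmark_grid()                       # 2N+1 = 257, J = 20
peaks = table1_scenario(grid)                         # six Lorentzians
noisy = add_noise(synthesize_continuous_fid(grid, peaks), 0.05, seed=1)
schedule = random_schedule(grid, 120, seed=1)
meas = sample_measurement(noisy, schedule)

mask = Mask.around_centers(grid, [p.frequency for p in peaks], halfwidth=5)
rec = lpmp_reconstruct(meas, grid, StoppingRule.relative_rule(0.98), mask=mask)
print("stop:", rec.stop_reason, "after", rec.n_iterations, "peaks")
for p in rec.peaks:
    print(f"  center {p.center:4d}  width {p.width_index:2d}  |b| {abs(p.amplitude):6.2f}")

ref = time_to_spectrum(grid, noisy)                   # full-sampling spectrum
print(f"masked LPMP error: {recovery_error(ref, rec.spectrum):.3f}")
rec_omp = omp_reconstruct(measurement_operator(schedule), meas.y,
                          StoppingRule.relative_rule(0.98))
print(f"OMP error, same data: {recovery_error(ref, rec_omp.spectrum):.3f}")
```

prints

```
stop: relative after 5 peaks
  center    3  width  5  |b|  29.25
  center   74  width  3  |b|  15.44
  center  -61  width  1  |b|   2.95
  center   23  width  2  |b|   4.26
  center  -60  width  0  |b|   0.48
masked LPMP error: 4.026
OMP error, same data: 4.833
```

The five matched atoms sit at or next to the true (aliased) centers 5.6,
70.4, −62.5 and 22.7 with widths near the true 5.2, 2.8, 4 and 5.4
line-width units (off-grid centers shift the best-fitting on-grid atom and
its width); the smallest true peak is below the noise floor.  The recovery
error is the Euclidean distance to the spectrum that *full* sampling of the
same noisy signal would have delivered — masked LPMP beats the OMP baseline
on identical data.

The same pipeline is scriptable from the shell:

```sh
lpmp simulate --table1 --samples 120 --seed 1 --out sim/
lpmp reconstruct --signal sim/measurement.tsv --method lpmp --alpha 0.98 --out rec/
lpmp benchmark --levels 90,120,150 --replicates 10 --seed 1 --out bench/
```

All files are tab-separated text (signals, spectra, peak lists, nuslist
schedules, masks); every run logs its resolved configuration and seed to
stderr and is bit-reproducible from them.

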