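# Methods

## Signal model

The package reconstructs one-dimensional free induction decays (FIDs): sums
of exponentially damped complex oscillations

    f(t) = sum_p a_p · exp(-2π γ_p t) · exp(2πi ω_p t),   t ≥ 0,

whose spectra are sums of complex Lorentzian peaks of half-width γ_p at
frequency ω_p.  In NMR the indirect dimension of a multidimensional
experiment is sampled point-by-point and is therefore expensive;
non-uniform sampling (NUS) measures only a subset K ⊂ {0, …, 2N} of the
regular time grid and reconstructs the rest.

All computations use grid units: the time unit 1/Ω and the frequency unit
ΔΩ = Ω/(2N+1) on a grid of M = 2N+1 points, time indices k ∈ [0, 2N] and
signed frequency indices l ∈ [−N, N].

### Transform pair

Two square transforms connect the domains:

* synthesis `S` (frequency → time), kernel `exp(+2πi·k·l/M)`;
* analysis `T = S⁻¹` (time → frequency), kernel `exp(−2πi·k·l/M)/M`.

The signs are fixed so that the on-grid impulse at l synthesises exactly
the continuous oscillation `exp(2πi ω t)` evaluated at `t_k = k/Ω` with
ω = l grid units.  The analysis kernel is then the familiar DFT sum for the
peak intensities.  Only the round-trip identity `S T = I` is normative; the
1/M factor lives on the analysis side, so a peak's spectral coefficient
equals its time-domain amplitude at t = 0.  The classical Fourier matrix
`F[k,l] = exp(−2πi·k·l/M)` and its inverse `(1/M)F*` are also exposed
(`build_fourier_matrix`, `fourier_inverse`) for reference; the solvers use
the synthesis/analysis pair.

### Lorentzian atoms

A damping matrix `C` multiplies time sample k by `exp(−2π·k·Γ/Ω)`, where
the width unit Γ is `gamma_unit` grid frequency steps (default 1).  The
dictionary atom with center l and width index j ∈ [0, J],

    L_l^j = T · C^j · S_l ,

is the spectrum of the damped oscillation `C^j S_l`; its closed form is the
geometric series `(1/M)(1 − ρ^M)/(1 − ρ·exp(2πi(l−l')/M))` with
`ρ = exp(−2π j·gamma_unit/M)` — a discrete complex Lorentzian with maximum
modulus at l.  `j = 0` atoms are exactly the standard basis, so the widest
dictionary always contains the plain Fourier dictionary.  Atom banks are
cached per (grid, j); memory is M² complex entries per width, a deliberate
desk-scale trade (≈1 MB per width at M = 257).

Defaults: `gamma_unit = 1` (width index = grid line-width units) and
`J = 20`, covering the packaged scenario's largest width (5.4) with
ample margin.  `J = 0` is allowed and degenerates LPMP to OMP.

## Solvers

### OMP

Orthogonal matching pursuit over the restricted Fourier dictionary
`A = S[K, :]`: per iteration the frequency index maximising the
matched-filter correlation `|(A* r)_l|` joins the support, then all
coefficients are refitted jointly by least squares.  Already-selected
columns are excluded from the argmax (a refit makes the residual orthogonal
to them anyway; exclusion also removes floating-point ties).

### LPMP

Lorentzian peak matching pursuit matches one Lorentzian peak per iteration:

1. **Center**: same matched-filter argmax as OMP, over admissible centers
   (the mask, if given) minus the centers already matched.  Ties break to
   the smallest index.
2. **Width**: every candidate j ∈ [0, J] is tried; for each, *all*
   amplitudes (committed peaks + candidate) are refitted jointly and the
   residual norm evaluated; the smallest-residual j wins, ties to the
   smallest j.
3. The width is committed permanently; amplitudes of every peak remain free
   in later refits.

The same center is never matched twice (duplicate columns would make the
joint system singular).  The masked variant differs only in the admissible
set, and runs through the identical code path, so a full mask reproduces
the unmasked run bit for bit.

### Stopping rules

* `epsilon`: stop when ‖y − A f̂‖₂ < ε.
* `relative` (default, α = 0.98): continue only while the newest iteration
  shrank the residual to ≤ α × the previous one; the first iteration always
  runs.
* `noise` (σ): stop once the newest peak's spectral height — |amplitude| ×
  the atom's modulus at its own center — is ≤ σ.  The height is the peak's
  own spectral contribution, not the superposed spectrum value, which keeps
  the criterion independent of neighbouring tails.

An iteration cap of `min(max_iter, m, M)` is always enforced: beyond m
peaks the joint least-squares system cannot be overdetermined.  Two
numerical guards apply to every rule: a residual at or below 1e−12·‖y‖₂ is
treated as exact zero and stops the loop (otherwise exactly-representable
noiseless data would trigger one spurious extra iteration and feed
rank-deficient refits), and a least-squares system with condition number
above 1e12 (or rank below its column count) stops the solver cleanly with
reason `singular`, returning the last valid iterate.  Stop reasons:
`threshold`, `relative`, `noise`, `max_iter`, `singular`, `exhausted` (no
admissible center left).

## Synthetic data

`synthesize_continuous_fid` evaluates the continuous model at the grid
times, with frequencies and dampings in grid units; both may be off-grid.
Frequencies must lie in the Nyquist band |ω| ≤ N — out-of-band peaks are
refused rather than aliased silently.  On-grid parameters reproduce the
dictionary atoms exactly, which ties the two signal models together in the
cross-module tests.

The packaged benchmark scenario (`table1_scenario`) has six peaks at
centers 5.6, 22.7, 67.8, 70.4, 194.5, 239.25 (printed on an unsigned
0…255 axis and stored aliased into the signed band — an exact relabelling,
since the sampled signal is periodic in the frequency index) with widths
5.2, 5.4, 2.6, 2.8, 4, 1.5 line-width units, on the 257-point grid
(N = 128, the closest odd conforming size to a 256-point grid).  It
combines per-peak width variation, an overlapping pair 2.6 points apart,
and off-grid centers and widths.  The intensities are a tool convention
(the benchmark's source prints none): (20, 4, 8, 6, 12, 1), a ~20× dynamic
range with the overlapping pair at comparable heights and a single
dominating peak, NOESY-style.

"5 % noise" is implemented as circular complex Gaussian noise with
per-sample standard deviation 0.05 × the maximum time-domain modulus
(`normalization="max"`); an RMS-relative alternative is selectable.
Schedules are uniform without replacement, sorted, and seed-reproducible.
Defaults follow the study conditions: 120 of 257 samples, 50 schedules per
sampling level (reducible; the packaged tests use 10 for speed).

What the generator does *not* emulate: spectrometer artefacts (phase
errors, baseline, solvent signals), t₁-noise, temperature drift, Gaussian
or Voigt line shapes, and multidimensional coupling.  Passing tests
therefore demonstrate correctness of the reconstruction machinery under
the idealised damped-oscillation model, not performance on real
spectrometer data.

## Benchmark harness

For each sampling level m, `run_benchmark` draws schedules with derived
seeds `master + m·10⁴ + replicate`, reconstructs the noisy signal with each
method, and records the Euclidean error against the analysis transform of
the *noisy* fully sampled signal (what full sampling would actually
deliver); the error against the noiseless ground-truth spectrum is kept as
a secondary column.  One noise realisation per master seed is shared by all
schedules.  Errors are complex-vector norms, not magnitude-spectrum norms.
The mask for the masked variant admits ±5 grid points (configurable)
around the rounded true centers.

## Numerical and design choices

* All least squares go through a rank-revealing SVD solve
  (`numpy.linalg.lstsq`); the condition threshold 1e12 defines
  "singular".
* Tie-breaks everywhere are "smallest index wins", making every run
  deterministic.
* Schedules must be duplicate-free and in-range; file order is preserved on
  read (generated schedules are ascending).
* The exact-recovery test fixture uses six well-separated peaks of width
  index ≤ 1 with descending amplitudes: greedy width selection is only
  unambiguous when Lorentzian tail interference at the selected center is
  small against the residual difference between adjacent widths, and wide
  tails decay only as 1/Δl (see limitations).

## Known limitations

* **Greedy width bias.**  The width argmin evaluates candidate fits while
  later peaks are still unexplained, and committed widths are never
  revisited; neighbouring peaks' tails can therefore shift the chosen width
  by one or two units even in noiseless data.  Narrow, well-separated,
  amplitude-ordered peak sets are recovered exactly; broad overlapping
  ones are approximated by several near-lying atoms, CLEAN-style.
* **Relative rule at harsh undersampling.**  With α = 0.98, every greedy
  iteration at m ≲ 100 of 257 on the packaged scenario improves the
  residual by more than 2 %, so the rule never fires and the pursuit runs
  to the iteration cap m — exact interpolation of the samples.  In that
  regime wide-atom columns at nearby centers are strongly correlated and
  the square joint fit can assign large cancelling amplitudes whose
  off-sample extrapolation inflates the spectral error, occasionally far
  beyond the plain-OMP interpolation error.  The masked variant is far
  more robust there (it forbids the spurious centers), which is exactly
  the regime where masking is most valuable.  At m ≳ 150 the rule
  terminates before interpolation and LPMP is clearly superior to OMP.
* **Matched-filter flatness for broad peaks.**  A width-5 Lorentzian
  decays within ~8 of 257 time points, so its correlation landscape under
  sparse schedules is nearly flat and the first selected center can be far
  from any true peak at low m.
* Off-grid peak centers are represented by on-grid atoms; the residual
  off-grid mismatch is absorbed by widened atoms and neighbouring centers,
  not by sub-grid fitting (out of scope).
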