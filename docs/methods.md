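# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `spinxes`. Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`.

## Kinetic model

The photocycle is a linear first-order chain

    Q  →(τ_Q)  T(S=1)  →(τ_T)  HS(S=2)  →(recombination)  domed ligated HS
    →(τ_domed)  LS ground

* `τ_Q = 100 fs` — lifetime of the photoexcited porphyrin Q-state. It is an
  external constraint (known from fluorescence up-conversion work on
  haems), so it is **never a free fit parameter**.
* `τ_T` — the intermediate triplet lifetime, the main short-time unknown;
  default ground truth 500 fs.
* Recombination: the unligated HS pool splits into three parallel
  first-order channels feeding the ligated domed HS state — fast geminate
  (default 10 ps, branch 0.4, ligand from the distal pocket), slow geminate
  (200 ps, branch 0.3, ligand from a remote internal pocket), and
  non-geminate return of escaped ligands (1.5 ns, branch 0.3). The domed
  species relaxes to the LS planar ground state with `τ_domed = 30 ps`
  (the reverse spin cross-over). Branch fractions must sum to one.

The three-level populations use the closed-form Bateman solutions, with the
exact `t·e^(−t/τ)` limit when the two rates coincide (relative difference
below 1e-9). The seven-state recombination chain is propagated through the
eigendecomposition of its rate matrix — exact for distinct rates; coincident
rates are split by a 1e-7 relative nudge, which keeps the decomposition well
conditioned at far better than the 1e-9 conservation tolerance the tests
enforce. Columns of the rate matrix sum to zero, so total population is
conserved to machine precision.

## Instrument response

The pump/probe cross-correlation (~150 fs) is read as the **FWHM** of a
Gaussian IRF, giving σ = 150/2√(2 ln 2) ≈ 63.7 fs; functions accept any
σ directly for users who prefer to treat 150 fs as a σ. Convolution with
every exponential term is analytic (exponentially-modified Gaussian). Where
the naive prefactor `exp(σ²/2τ² − x/τ)` would overflow, the identity
`erfc(a) = erfcx(a)·e^(−a²)` reduces the expression to
`½·erfcx(a)·e^(−x²/2σ²)`, finite for all |x| ≤ 10 ns and σ ≥ 1 fs (tested).

The "rising component × biexponential decay" observable is implemented in
product form, `(1 − e^(−x/τ_rise))(A₁e^(−x/τ₁) + A₂e^(−x/τ₂))`, because it
expands exactly into four pure exponentials compatible with the analytic
IRF convolution; a sum form (`−(A₁+A₂)e^(−x/τ_rise)` added to the decays)
is available behind the `form` flag for sensitivity checks. Both rise from
zero at t₀.

## Spectral model

Each spin state's Kβ (Kβ₁,₃ + Kβ′) and Kα (Kα₁ + Kα₂) emission is a sum of
pseudo-Voigt lines (50% Lorentzian fraction by default — core-hole
lifetimes make pure Gaussians unphysical, while the analysis only needs
symmetric peaks). The instrument resolution is applied as a Gaussian blur
of FWHM 0.5 eV (Kβ) / 0.6 eV (Kα). The default energy grids are
7030–7080 eV and 6378–6416 eV at 0.1 eV spacing.

Calibration anchors: Kβ₁,₃ LS centroid 7058.0 eV, Kβ′ near 7045 eV, Kα₁ at
6404 eV, Kα₂ at 6391 eV. The Kα₁ FWHM follows the linear spin-marker
relation `FWHM = intercept + slope·n_unpaired` with calibration defaults
intercept 2.5 eV, slope 0.2 eV/electron (no published values exist for this
protein, so these are explicit calibration choices). `n_unpaired` is fixed
at 1/2/4 for S = 1/2, 1, 2. Relative amplitudes (Kβ₁,₃ decreasing 1.0 →
0.96 → 0.92 LS→T→HS; Kβ′ increasing 0.06 → 0.12 → 0.20) realize the
qualitative marker trends; their absolute values are calibration choices.

**The 0.45 eV calibration.** The HS Kβ₁,₃ centroid is not set by hand: it
is solved (Brent bracketing on the forward model, tolerance 1e-6 eV) so
that a Gaussian fit in the 7056–7062 eV window of the *maximum-conversion*
laser-on spectrum — the photoexcited fraction (default 0.4) entirely in the
quintet state — is shifted by 0.45 eV from the laser-off fit. The solution
is an LS→HS offset of ≈1.24 eV, with the intermediate-state centroid
midway. The maximum conversion is defined at the photoexcitation fraction,
not at excitation × quantum yield (0.22): every photoexcited haem
transiently dissociates, and the ~55% photolysis quantum yield governs how
many remain dissociated — numerically, a 22% quintet admixture cannot pull
a window-restricted Gaussian fit by more than ~0.29 eV whatever the line
parameters, because the dominant LS component anchors the fit. The
steady-state observable amplitude in the simulator is still set by
excitation × QY = 0.22, which yields a maximum *observed* centroid shift of
≈0.22 eV in simulated experiments.

## Peak fitting

Markers are extracted by nonlinear least-squares fits of a single Gaussian
plus constant baseline inside a fixed window (Kβ₁,₃: 7056–7062 eV; Kα₁:
centroid ± 2×FWHM; the transient-amplitude marker instead averages the
area-normalized difference spectrum over 7050–7055 eV, the region that best
separates the intermediate state). Numerical choices that matter:

* Peak orientation (positive/negative) is decided against the window-edge
  baseline, not the median — the median misclassifies peaks sitting
  asymmetrically in the window.
* The start point is moment-based and the fit is bounded (amplitude sign
  fixed, centroid inside the window), which removes a spurious
  inverted-Gaussian local minimum that plain Levenberg–Marquardt finds on
  composite (two-component) peaks.
* 1σ uncertainties are the covariance diagonal scaled by the reduced χ²
  (`absolute_sigma=False` convention). Consequence: when photon statistics
  are very high, the residual is dominated by the systematic mismatch
  between the Gaussian model and the blurred pseudo-Voigt line, and errors
  saturate at that floor instead of shrinking as 1/√N. The 1/√N scaling
  properties therefore hold — and are tested — in the photon-counting
  regime (≲10⁴ photons per spectrum), which is also the realistic FEL
  regime.
* A window without an interior turning point triggers a
  `DegenerateFitWarning`; non-convergence raises `FitError` carrying the
  last iterate.

The Kα₁ width marker is reported as the pump-induced *change* of the fitted
σ (laser-on minus the pooled laser-off reference), in raw eV. A "normalized
σ" has no agreed convention, so normalization is left to the caller and no
acceptance number depends on it.

## Synthetic data generator

Emulates, per shot: Gaussian arrival-time jitter (σ = 150 fs), a
timing-tool estimate equal to the true jitter plus 10 fs Gaussian
measurement noise (the tool noise is small relative to the jitter; 10 fs is
a typical modern value), 1:1 laser-on/off interleaving, and Poisson counts
scaled to a per-spectrum photon budget. Laser-on spectra mix the per-state
lineshapes at the populations of the *effective* (nominal + jitter) delay;
the Q-state and recovered ground state are spectrally low spin, and the
ligated domed species is spectrally high spin (K emission does not
distinguish ligated from unligated HS). The default delay schedule mirrors
the measurement: 50 fs steps from −0.5 to +2 ps, then 25 log-spaced points
to 750 ps. Shots per delay is experiment-dependent and deliberately varied
across the recovery tests (16–1600).

What the generator does **not** emulate: SASE spectral jitter, beam
pointing, detector geometry (the von Hamos dispersion is abstracted to the
energy grid), read noise correlations, sample damage, or drifts. Passing
recovery tests therefore demonstrate the correctness and statistical
calibration of the analysis chain under the stated noise model, not
robustness to every systematic of a real beamline.

## Fitting machinery

Weighted least squares with the per-point 1σ errors from marker extraction;
time constants are parameterized as ln τ (positivity without hard
constraints) with generous bounds that also impose the rise < fast < slow
ordering (τ_rise ≤ 20 ps, τ₁ ∈ [2 ps, 500 ps], τ₂ ∈ [0.4 ns, 100 ns]; a
post-fit ordering check flags violations). Five multi-starts with
deterministic log-space jitter (seeds 1000+i) guard against the
biexponential's local minima; ties break by lower χ², then smaller
τ_rise. Parameters at bounds are flagged in the result. Natural-space
errors come from the delta method (numeric Jacobian of the transform).

The joint fit shares t₀, the three time constants and the amplitude
fraction f₁ = A₁/(A₁+A₂) across marker traces, with one free scale per
trace — mirroring the plotting of both spin markers on a single fit curve.
Joint fitting is the default in the workflow; per-trace fits remain
available. In the end-to-end workflow t₀ is fixed to the generator's truth
(a self-consistency setting); `fit_trace` leaves it free by default within
±1 ps. Points whose errors exceed 5× the median are logged and retained —
weighted least squares already down-weights them; nothing is silently
removed.

## Problem sizes

The default workflow simulates 76 delays × 60 shots × two line families;
the test suite uses 30–40 shots per delay and 33–46 delays for the
end-to-end checks, and ten noise realizations for every ensemble statement.
These sizes were chosen so each statistical check retains a comfortable
margin over its Monte-Carlo error.

## Known limitations

* The biexponential fit of the full workflow returns *effective* decay
  constants: the simulated decay has four timescales, so the fitted pair
  (≈75 ps / ≈1 ns at the default fixture) summarizes, rather than equals,
  the generator's channel lifetimes. The trace-level recovery experiments
  (where the ground truth *is* a rise × biexponential) are the
  parameter-recovery statements.
* The fitted workflow risetime (~280 fs) is shorter than the ~800 fs
  cascade-completion time because the intermediate state already carries
  roughly half of the spectral shift; the single-τ rise model averages the
  two steps. The cascade-completion question is answered by the three-level
  fit, which recovers τ_T directly.
* Degenerate recombination rates are handled by a relative nudge rather
  than exact limit forms (only the three-level cascade has the exact
  degenerate limit).
* Uncertainty propagation through area normalization treats the area as a
  constant (count-noise-dominant limit); the induced correlation between
  energy bins is neglected.
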