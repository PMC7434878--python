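# spinxes

Spin-state kinetics from femtosecond Fe Kα/Kβ X-ray emission spectroscopy.

## The problem

When a small ligand (NO, CO, O₂) detaches from a ferrous haem, the iron
switches from a low-spin (LS) planar configuration to a high-spin (HS,
S = 2) domed one — a spin cross-over (SCO) that is the first event of the
respiratory function; ligand rebinding drives the reverse SCO. Femtosecond
X-ray emission spectroscopy (XES) at free-electron lasers tracks this
because the Fe Kβ₁,₃/Kβ′ lines (3p→1s) and the Kα₁ width (2p→1s) are
markers of the number of unpaired 3d electrons: LS→HS conversion blue-shifts
and weakens Kβ₁,₃, strengthens Kβ′, and broadens Kα₁ linearly with the
unpaired-electron count.

`spinxes` is for practitioners of time-resolved X-ray spectroscopy who want
a tested, reusable implementation of the full analysis chain for such
measurements — and a statistically faithful synthetic-data generator to
validate it: per-shot arrival-time jitter (σ ≈ 150 fs) with a timing-tool
estimate, 1:1 laser-on/off interleaving, photolysis quantum yield, and
Poisson photon counting.

## The models

**Sequential spin cascade (Bateman kinetics).** The photoexcited porphyrin
Q-state decays to an intermediate triplet (S = 1) haem which decays to the
HS quintet:

    P_Q(t)  = e^(−t/τ_Q)
    P_T(t)  = [k_Q/(k_T − k_Q)] (e^(−k_Q t) − e^(−k_T t)),   k = 1/τ
    P_HS(t) = 1 − P_Q − P_T

with τ_Q fixed at 100 fs. The HS pool then recombines through parallel
first-order channels (fast/slow geminate plus a nanosecond non-geminate
branch) into a ligated HS domed species that relaxes back to the LS ground
state (reverse SCO, ~30 ps).

**IRF-convolved observables.** Every exponential term is convolved with the
Gaussian instrument response analytically (exponentially-modified Gaussian,
evaluated with the overflow-safe `erfcx` identity):

    (exp ⊗ G)(t) = ½ exp(σ²/2τ² − x/τ) erfc(σ/√2τ − x/√2σ),  x = t − t₀

Two fit models are provided: the phenomenological
`θ(x)(1 − e^(−x/τ_rise))(A₁e^(−x/τ₁) + A₂e^(−x/τ₂))` (rise ×
biexponential, product form; a sum form is available), and the three-level
amplitude model `c_T P_T(t) + c_HS P_HS(t)` with τ_Q held fixed. Fitting is
weighted nonlinear least squares in log-time coordinates with five
deterministic multi-starts; 1σ errors are the covariance diagonal scaled by
the reduced χ².

## Worked example

```python
import spinxes as sx

report = sx.run_workflow(seed=1, shots_per_delay=40)
print(sx.format_report_text(report))
```

prints (exactly reproducible for `seed=1`):

```
spinxes workflow report
seed: 1  config: ad3fb75d6175b5bb

rise x biexponential (joint fit of K-beta 1,3 shift and K-alpha1 width):
  risetime          279 ± 6.5 fs
  tau1 (fast decay) 75.6 ± 8.5 ps   A1 = 0.598 ± 0.051
  tau2 (slow decay) 0.936 ± 0.25 ns   A2 = 0.402 ± 0.051

three-level cascade (7053 eV amplitude, Q lifetime fixed):
  intermediate-state lifetime 542 ± 81 fs

reduced chi2: rise_biexp 1.36, three_level 1.35
```

Reading the numbers: the workflow simulated a full two-colour experiment
(Kβ and Kα shot streams), sorted the shots by timing-tool-corrected delay,
extracted the Kβ₁,₃ centroid-shift, Kα₁ width-change and 7053 eV
transient-amplitude traces, and fit them. The three-level fit recovers the
generator's intermediate-state lifetime (truth 500 fs) within its 1σ error.
The biexponential constants are *effective* values: the simulated decay is
genuinely multi-exponential (10/200 ps geminate, 30 ps domed→planar, ns
non-geminate), so the two fitted constants summarize it, and the fitted
risetime reflects the stepwise cascade (τ_Q = 100 fs to the triplet, then
τ_T = 500 fs to the quintet), which completes in under a picosecond.

The same stages are available from the shell:

```sh
spinxes workflow --seed 1 --shots-per-delay 40 --outdir out/
spinxes reduce --seed 1 --marker kbeta13_centroid_shift --outdir out/
spinxes fit --trace out/kbeta13_centroid_shift.tsv --out out/fit.json
```

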