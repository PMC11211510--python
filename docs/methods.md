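# Methods

## The two-state bending model

A bound DNA–protein complex interconverts between a partially bent (P)
and a fully bent (F) conformation with first-order rates `k_P→F` and
`k_F→P` (s⁻¹). Dwell times in each state are exponential with means
`⟨T_P⟩ = 1/k_P→F`, `⟨T_F⟩ = 1/k_F→P`, and the bending equilibrium
constant is `K_F/P = k_P→F/k_F→P = ⟨T_F⟩/⟨T_P⟩`. The two states are
read out through FRET between dyes at the DNA ends: bending shortens the
end-to-end distance, so P is the low-FRET and F the high-FRET state
(`TwoStateBendingModel` orders its labels by FRET and rejects anything
else).

Binding couples to bending through the linear scheme

    D + A ⇌[k₁, k̃₋₁] (DA)_P ⇌[k₂, k₋₂] (DA)_F

in which only the P-state exchanges with free DNA and protein. Exact
consequences implemented in `kinetic_core`:

- **Occupancy.** At totals D₀, A₀ the bound fraction follows the
  one-site curve with the composite constant `K_d = K̃_d/(1+K₂)`; the
  free-ligand concentration solves a quadratic in the complex
  concentration, taken exactly (no weak-depletion approximation). The
  bound complex splits P:F as 1:K₂ (detailed balance).
- **Dissociation after a trap.** With rebinding blocked, populations
  obey a 2×2 linear ODE whose eigenvalue magnitudes are
  `r± = (s ± √(s² − 4 k̃₋₁ k₋₂))/2`, `s = k̃₋₁+k₂+k₋₂`. `r₋` is
  computed from the Vieta product `r₊r₋ = k̃₋₁k₋₂` to avoid the
  catastrophic cancellation of the subtractive root when `r₊ ≫ r₋`.
  The closed-form eigen-expansion (not a general eigensolver) gives
  `N_P(t), N_F(t)`; the general solver and a Runge–Kutta integrator are
  used only as test oracles. In the rapid-equilibrium limit
  `k₂+k₋₂ ≫ k̃₋₁` the slow rate reduces to `k̃₋₁/(1+K₂)` — the apparent
  off rate. The degenerate case `k₂ = k₋₂ = 0` is accepted and reduces
  to single-state binding.
- **Units.** The closed forms are unit-agnostic (any consistent time
  unit). `BindingKineticModel` stores the per-minute/nM convention used
  by the ensemble assays, with per-second accessors; the
  single-molecule layer works in seconds throughout.

## Substrate presets (study conditions)

The generators default to the measured conditions of the three 30-bp
substrates:

| preset | ⟨T_P⟩ (s) | ⟨T_F⟩ (s) | FRET P/F | K_F/P | pure k̃₋₁ (min⁻¹) | K̃_d (nM) |
|--------|-----------|-----------|----------|-------|--------------------|-----------|
| LSP    | 1/24      | 1.0       | 0.22/0.65| 24.6  | 12.8               | 230.4     |
| HSP    | 0.05      | 0.07      | 0.27/0.51| 1.7   | 18.09              | 116.1     |
| NS     | 0.12      | 0.07      | 0.21/0.48| 0.6   | 12.0               | 70.4      |

Bending equilibrium constants in the binding presets use the unrounded
dwell-ratio values (24.6/1.7/0.6) rather than ratios of the rounded
dwell times; pure off rates and dissociation constants are
back-computed from the measured apparent values via the `1/(1+K_F/P)`
reduction. State FRET SDs default to 0.05; the LSP PIFE factors are
3.7 (P) and 1.5 (F), matching the −12-labelled donor construct.

## What the synthetic data emulate — and what they do not

`simulate_state_path` draws exponential waiting times with the preset
rates, starting from the stationary distribution. `bin_to_frames`
averages the state values over each frame's **exposure window**
(default 15 ms of the 15.38 ms frame at 65 frames/s) rather than
point-sampling; this reproduces the mid-FRET blur a real integrating
camera produces whenever a transition falls inside a frame.
`render_counts` pushes the ideal per-frame (FRET f, donor enhancement
q_D) through the two-channel forward detection model (below), adds
Gaussian state noise via the per-state FRET SD, camera noise with
variance `read_sd² + excess² · scale · signal` (a signal-proportional
Gaussian proxy for EMCCD excess noise, `excess ≈ √2`; adequate at the
≳100-count signals simulated here and unbiased under the inversion),
and exponential photobleaching first-passage times (bleached dye:
q = 0; a bleached acceptor also removes the FRET pathway).

Not emulated: the full EM-gain stochastic cascade, dye blinking,
spectral fluctuations, diffusing background. Passing recovery tests
therefore shows the *analysis chain* is correct and quantifies the
*frame-integration* biases; it does not certify performance under
photophysics the generator omits.

Default baselines place donor counts for protein-free DNA in the
1200–2000 camera-count range (offsets 400, full-scale 1600 counts). The
plain FRET dye-pair calibration is crosstalk-free and balanced, so the
offset-subtracted proximity ratio `a/(a+d)` equals the FRET efficiency;
no gamma correction is applied anywhere (efficiencies are reported as
uncorrected proximity ratios).

## Segmentation and dwell analysis

`fit_hmm` fits a two-state Gaussian-emission HMM by Baum–Welch EM
(log-domain forward–backward via hmmlearn) initialized at the interior
data quantiles — a deterministic split, so fits are bit-reproducible.
Variances are floored at 1e−4 (FRET² units) and flagged if hit. States
are reported in ascending mean order. `viterbi_path` decodes the MAP
path; `detect_valid_region` cuts traces at donor bleach (two-level step
model on the summed intensity) and acceptor bleach (trailing near-zero
FRET segment after distinctly higher FRET), with reason codes. The
number of states is fixed at 2 for the P/F analysis; bleached/unbound
stretches are handled by the validity cut, not extra HMM states.

`extract_dwells` tabulates maximal constant-state segments; the first
and last segment of each region are censor-flagged and **dropped by
default** (a right-censored likelihood is available for sensitivity
analysis). `fit_exponential` provides two estimators:

- **MLE** (`method="mle"`): closed form for one component (rate =
  1/sample mean); numerical mixture fit for two, with a
  likelihood-ratio diagnostic. The mean of a double exponential is
  reported amplitude-weighted, `Σ wᵢ/rateᵢ`.
- **Histogram least squares** (`method="histogram"`): exponential decay
  curves fitted to the dwell histogram binned at the frame interval,
  excluding the first bin. This is the pipeline's reporting route.

The distinction matters because of **missed events**: at 65 frames/s a
state with a 0.04 s lifetime (2.6 frames) loses its sub-frame visits
entirely. The sample mean of the *detected* dwells is then biased
upward by roughly half a frame plus the detection cutoff (measured:
0.042 s true → ~0.055 s MLE), whereas the histogram's decay constant —
a slope, invariant to losing the first bin — recovers ~0.040 s. No
explicit missed-event correction is applied; the residual biases that
survive the histogram estimator are dwell **merging** (a missed
sub-frame visit of the opposite state concatenates two dwells), which
inflates both states' fitted means by 10–20% under the NS/HSP
conditions, and F-state inflation for LSP (~1.2 s fitted vs 1.0 s
generated). These are quantified in the test suite and are shared by
any analysis of real data at this frame rate.

The TDP emits, per decoded transition, the mean observed FRET of the
departing and arriving segments; its point count equals the transition
count and the diagonal is empty by construction. A 2-component 2-D
Gaussian mixture summarizes the two clusters, ordered by the first
coordinate; per-state FRET means/variances pool the matching
coordinates of the two clusters, weighted by cluster weight. For
short-lived states the *observed* segment FRET exceeds the
instantaneous state value because most of their frames straddle a
transition under full-frame exposure: with a 2.6-frame lifetime the
LSP P-state reads ~0.28–0.29 rather than 0.22 no matter how the frames
are selected (ground-truth labels, edge trimming, medians and
posterior filtering were all measured at ≥0.27). Longer-lived states
(≥4 frames) are essentially unaffected.

## PIFE–FRET decoupling

Measured counts per frame follow

    d = u·q_D·[d̄_DD(1−f) + d̄_AD·f] + u·q_A·d̄_AA + c_D
    a = u·q_D·[ā_DD(1−f) + ā_AD·f] + u·q_A·ā_AA + c_A

with normalized excitation power u, donor/acceptor quantum-yield
factors q_D/q_A, FRET efficiency f, composite detection parameters
(d̄, ā) and camera offsets c. With the donor pass band blocking
acceptor emission, `d̄_AD = d̄_AA = 0` and six parameters remain. They
are solved, together with the two reference FRET values (f_H, f_L) and
the mount-to-mount power factor u_L, from the photobleaching-event
clusters of two calibration constructs (internally vs. end-labelled
donor), located by a 2-D Gaussian mixture and labelled by geometry.
The 16 cluster-mean coordinates over-determine the 9 unknowns; a
damped least-squares solve from closed-form initial guesses is exact
(residual < 1e−8) on noiseless cluster means and degrades gracefully
(<5% at 2% mean noise).

Per-frame inversion fixes **u = 1** for measurement traces: each frame
supplies two observables (d, a), so at most two of (u, q_D, f) are
identifiable; u only varied between calibration mounts. q_A is binary
(1 alive / 0 bleached, from the validity segmentation). The inversion
is the exact algebraic solution of the 2×2 system; FRET outside
[−0.1, 1.1] or a dark donor flags the frame invalid. State-averaged
PIFE values are computed over the **interior frames** of decoded
segments (boundary frames mix states within the exposure window and
pull the short-lived P-state average from 3.7 toward 3.4); reported
PIFE can be normalized to a reference condition's mean q_D.

## Ensemble analysis

`(ratio)_A = (F_DA − N·F_D)/F_A` maps linearly to the FRET efficiency,
`E = ((ratio)_A − 0.066)/0.65`, with the default extinction-coefficient
ratios of the Atto565/Atto647N pair; inputs are scalar band-integrated
intensities (full-spectrum integration is out of scope). Titrations are
fitted by nonlinear least squares either hyperbolically or through the
exact-depletion occupancy; **exact depletion is the default** because
the 5 nM DNA used in the titrations is not negligible against the
weaker-substrate K_d ≈ 43–44 nM, where the hyperbolic fit is biased
upward (asserted as a documented warning path). Decay curves are fitted
with 1 or 2 exponentials on the normalized signal with a floating
offset; for two components the faster rate is the off-rate estimate
(the slower one reflects system re-equilibration, e.g. rebinding of
labelled DNA, which the trap scheme does not model) and an F-test
against the single exponential is reported.

## Image pipeline

Coordinates are 0-based (x, y) with the pixel-center convention; the
affine registration maps acceptor onto donor coordinates. Detection
averages an evenly spaced 10% frame subset, LoG-filters (σ = 1.2 px,
matched to the fixture PSF), thresholds local maxima at 8× the robust
(MAD) background SD of the filtered image, and fits symmetric 2-D
Gaussians with shot-noise weights on 11×11 crops; candidates outside
median ± 3 MAD in fitted σ or amplitude are discarded. Drift is
tracked on 10-frame block averages of anchor spots (median across
anchors), linearly interpolated and extrapolated to every frame.
Traces are aperture sums over a radius-3 px disc minus the median of a
4–6 px annulus times the disc area (standard practice; captures ~96%
of a σ = 1.2 px spot, a constant factor that cancels in FRET). Frames
whose aperture leaves the field truncate the trace with a flag.

## Pipeline, formats, reproducibility

`PipelineConfig` (pydantic, unknown keys rejected) holds every stage
parameter and a single seed; the full config and package version are
serialized into each results bundle. All generators accept either a
seed or a shared `numpy.random.Generator`; the driver derives one
generator per run, so reruns are bit-identical. Trace tables are CSV
(written with 17-significant-digit floats and read with round-trip
float parsing, so the CSV and HDF5 dialects load identically) or HDF5.
The frame interval is stored explicitly (1/65 s default) rather than
inferred from times. FRET values are stored unclamped with validity
flags; clamping happens only at presentation.

Problem sizes used by the shipped recovery runs: 300 traces × 4000
frames for LSP (chosen large because its F-state dwell is ~5-fold
longer than the others), 100–250 × 4000 for HSP/NS, 40 × 4000 for the
PIFE chain, 200 × 1000 for the static-DNA control. A full recovery run
(`scripts/acceptance.py`) completes in about a minute on one CPU.

## Known limitations

- No missed-event (frame-time) correction; biases quantified above.
- The observed FRET level of states living ≲3 frames is blur-shifted;
  TDP cluster means for such states read high by up to ~0.07.
- Gaussian camera noise, binary bleaching, no blinking; q_A is binary.
- No >2-state HMMs or Bayesian model selection (BIC only as a
  diagnostic); no ≥3-component dwell mixtures.
- The hyperbolic titration mode exists for parity with common practice
  but is knowingly biased at D₀ ≈ K_d.
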