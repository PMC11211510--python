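# tfambend

Single-molecule FRET/PIFE analysis of dynamic DNA bending by the
mitochondrial transcription factor A (TFAM).

TFAM packages mitochondrial DNA and recruits the mitochondrial RNA
polymerase at the light- and heavy-strand promoters (LSP, HSP) by bending
a ~30 bp site into a U-turn. In surface-immobilized smFRET experiments
the DNA–TFAM complex is not static: it hops between a **partially bent
(P, low FRET)** and a **fully bent (F, high FRET)** conformation,

```
            k_P→F
   (DA)_P  ⇌  (DA)_F ,     K_F/P = k_P→F / k_F→P = ⟨T_F⟩ / ⟨T_P⟩ ,
            k_F→P
```

and the stability of the F-state (K_F/P) is strongly DNA-sequence
dependent. Because only the P-state can dissociate,

```
   D + A  ⇌[k₁, k̃₋₁]  (DA)_P  ⇌[k₂, k₋₂]  (DA)_F ,
```

the observed (apparent) dissociation constant and off rate are reduced
from the pure P-state values by the F-state occupancy:

```
   K_d = K̃_d / (1 + K₂) ,      k_off ≈ k̃₋₁ / (1 + K₂) ,
```

which links the bending equilibrium measured one molecule at a time to
the ensemble affinity and dissociation kinetics. This package implements
the full measurement chain for that model, for anyone analyzing
two-state conformational dynamics in camera-based single-molecule
fluorescence data:

- `kinetic_core` — exact algebra of the two-conformational-state scheme:
  dwell/rate conversions, apparent constants, the double-exponential
  dissociation decay (eigenvalues `r±` from the quadratic formula), and
  equilibrium occupancy with exact ligand depletion.
- `synthetic_data` — seeded generators for every input: continuous-time
  two-state trajectories, exposure-window frame binning (65 frames/s,
  15 ms), EMCCD-like camera counts, two-channel image stacks with drift,
  titration curves, stopped-flow decays. Presets encode the LSP, HSP and
  non-specific (NS) substrate conditions.
- `trace_extraction` — TIRF image pipeline: bead-based affine channel
  registration, LoG spot detection with 11×11 Gaussian sub-pixel
  localization, fiducial drift tracking, aperture trace extraction.
- `hmm_segmentation` — two-state Gaussian-emission HMM (Baum–Welch,
  Viterbi) with deterministic quantile initialization, plus
  photobleach/validity segmentation.
- `dwell_kinetics` — dwell tables with censor flags, exponential fits
  (closed-form MLE and histogram least squares), FRET transition density
  plots (TDP) with 2-D Gaussian-mixture summaries, kinetic summary.
- `pife_fret` — hybrid PIFE–FRET decoupling: two-channel forward
  detection model, five-cluster calibration solve, per-frame inversion
  of counts into (FRET, donor enhancement q_D).
- `ensemble_fret` — (ratio)_A ensemble FRET, anisotropy titration fits
  (hyperbolic and exact-depletion), stopped-flow decay fits.
- `cli_io` — validated pipeline configuration, trace-table CSV/HDF5
  formats, the `simulate → segment → dwell → report` driver, and the
  `tfambend` command-line interface.

## Worked example

Simulate 50 LSP-like traces (4000 frames at 65 frames/s), segment them
with the two-state HMM, and fit the dwell-time histograms:

```sh
cat > lsp.json <<'EOF'
{"preset": "LSP", "n_traces": 50, "n_frames": 4000, "seed": 7}
EOF
tfambend report --config lsp.json --out lsp_results
```

prints

```json
{
 "preset": "LSP",
 "mean_dwell_P_s": 0.04581882852352159,
 "mean_dwell_F_s": 1.1912582944844519,
 "rate_bend_per_s": 21.825088772984213,
 "rate_unbend_per_s": 0.839448509722886,
 "K_FP": 25.99931802867693,
 "se_K_FP": 0.7616820285117691,
 "fret_mean_P": 0.2896850929771094,
 "fret_mean_F": 0.648354261095428,
 "fret_var_P": 0.00430294859527146,
 "fret_var_F": 0.00013184880493666894,
 "n_dwells_P": 2341,
 "n_dwells_F": 2293,
 "mle_mean_dwell_P_s": 0.057726809713140335,
 "mle_mean_dwell_F_s": 1.2313596564795866
}
```

Reading the numbers: the partially bent state lives ~0.046 s and the
fully bent state ~1.2 s, so the bending equilibrium constant K_F/P ≈ 26
— the LSP complex spends ~96% of its time fully bent. The TDP mixture
puts the high-FRET state at 0.648. `mean_dwell_*` are the histogram-fit
(decay-slope) estimates; the `mle_*` values are the raw sample means of
detected dwells, which for the short-lived P-state are biased upward by
the one-frame detection limit (see `docs/methods.md`). The same driver
runs the HSP and NS presets (`--preset HSP`), whose F-state is 14-fold
less stable.

The same steps are available from Python
(`tfambend.run_pipeline(PipelineConfig(...))`) and as individual CLI
stages (`simulate`, `extract`, `segment`, `dwell`, `pife`, `titrate`,
`dissoc`).

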