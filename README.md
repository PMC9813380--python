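# semgmap

Segmentation-bias analysis for high-density surface-EMG (HD-sEMG)
activation maps.

## The problem

Physiologists and biomechanists summarize 64-channel grid recordings of
muscle activity as *instantaneous activation maps*: the signal of each
electrode is cut into windows of length `N` samples taken every `R`
samples (overlap = 1 − R/N), and each window yields one 8 × 8 image whose
pixel intensity is the windowed RMS

```
I[i,j,t] = sqrt( 1/(N−1) · Σ_{n=s}^{s+N−1} x²[n] )
```

for the electrode at grid position (i, j). Window length and overlap are
chosen inconsistently across studies (50–1,000 ms, 0–90 %), and that
choice itself distorts the maps — short non-overlapped rectangular
windows introduce truncation (Gibbs) artifacts, long windows blur the
spatial pattern. `semgmap` quantifies this bias with a reproducible
pipeline:

1. **synthetic generator** — motor-unit–pool simulator (size-principle
   recruitment, Gamma-renewal firing, biphasic MUAP kernels, exponential
   spatial decay on an 8 × 8 grid at 10 mm IED, 2,048 Hz) producing
   trapezoid-contraction recordings with known ground truth;
2. **preprocessing** — mean-centering, plateau segmentation, zero-lag
   second-order Butterworth band-pass (20–400 Hz), Z-score outlier-channel
   detection and radius-1 neighborhood repair;
3. **map generation** — windowed-RMS stacks over the factorial design of
   6 window lengths × 5 overlaps (30 conditions), normalized to the
   plateau maximum;
4. **image features** per map — barycenter (LoC, mm), Shannon entropy of
   the squared-intensity distribution (bits, `p_k ∝ I_k²`,
   `E = −Σ p_k log₂ p_k`), and histogram moments 1–4;
5. **embedding geometry** — pooled 3-D embedding of all maps (UMAP, or a
   deterministic PCA backend), per-condition convex-hull ("polyhedron")
   volume normalized across conditions, and voxel-occupancy entropy;
6. **bias statistics** — two-way ANOVA with η² effect sizes
   (small < 0.04 < medium < 0.64 < large), Tukey–Kramer post-hoc,
   K-medoids clustering with elbow selection, and cubic trend fits with
   zero-crossings.

## Worked example

```python
import semgmap as sm

rec = sm.simulate_recording(n_units=60, active_center=(3.5, 3.5),
                            level=0.6, noise_rms=0.05, seed=42)
rec = sm.mean_center(rec)
rec = sm.segment_plateau(rec)          # 10,240-sample hold phase
rec = sm.bandpass_zero_lag(rec)        # zero-lag 20-400 Hz Butterworth

stacks = sm.grid_search(rec)           # 6 windows x 5 overlaps = 30 stacks
table = sm.feature_table(stacks)
print(f"{len(stacks)} conditions, {len(table)} maps")
print(table.groupby("window_ms")[["entropy_bits", "m2", "m4"]].mean().round(3))

anova = sm.two_way_anova(table, "entropy_bits")
eff = anova.effects["window_ms"]
print(f"window effect on map entropy: F={eff.F:.1f}, eta^2={eff.eta_sq:.3f} "
      f"({sm.classify_eta(eff.eta_sq)})")
```

prints

```
30 conditions, 3940 maps
           entropy_bits     m2     m4
window_ms
50.0              4.152  0.019  6.738
100.0             4.190  0.026  6.355
150.0             4.200  0.031  6.254
250.0             4.208  0.036  6.162
500.0             4.212  0.042  6.099
1000.0            4.214  0.048  6.079
window effect on map entropy: F=30.6, eta^2=0.038 (small)
```

Short windows yield noisier RMS estimates, hence lower map entropy and
heavier-tailed pixel histograms (larger kurtosis `m4`); the two-way ANOVA
attributes a small but highly significant share of the feature variance
to window length. `semgmap run` executes the same pipeline from a YAML
config and writes every intermediate artifact plus a checksummed run
manifest; `semgmap simulate | preprocess | maps | features | embed |
stats` expose the individual stages.

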