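# widefc

Cortical activation and functional connectivity (FC) during
externally-driven versus internally-driven locomotion, from
dual-wavelength widefield Ca²⁺ imaging.

Head-fixed mice either walk because a motorized treadmill moves under
them (externally driven) or choose to walk on a free disk (internally
driven). Widefield imaging of a GCaMP-expressing dorsal cortex captures
a calcium-dependent (blue, 470 nm) and a calcium-independent (violet,
405 nm) channel on alternating frames at 20 fps per channel. `widefc`
turns such recordings — or fully synthetic stand-ins with known ground
truth — into statistical statements about how cortical activation and
between-region correlations change across locomotion states, for
researchers analyzing mesoscale imaging with rich behavior.

The pipeline:

1. **Behavior**: motorized task logs are segmented into the period
   taxonomy (rest, walk, starting/stopping/accelerating/decelerating
   ramps, 3 s post-transition windows, 3 s pre-transition delay windows
   after cue handling); disk traces are segmented by thresholding.
   Pupil diameter comes from a Pratt circle fit of 8 tracked landmarks,
   normalized to the daily maximum.
2. **Preprocessing**: subpixel phase-correlation registration within
   session (violet inherits blue's transforms), affine registration
   across sessions, brain masking, zero-phase 5th-order Butterworth
   low-pass at 7 Hz, then per-pixel regression of blue on violet; the
   residuals are the hemodynamic-corrected signal.
3. **Parcellation**: randomized SVD to 500 components, spatial JADE ICA
   to 100 components, the three-branch z-threshold rule (3.5 → 2.5
   fallback → re-z-score at 1.0 for oversize domains, 150–5000 px),
   vessel-pixel removal, Dice-optimal node assignment against a
   reference layout with a rescue path for sub-threshold ICs.
4. **Connectivity**: weighted-mean node series → ΔF/F% → 1.0 s sliding
   windows stepped by 0.25 s → Pearson r per node pair (496 edges for
   32 nodes) → Fisher z → homolog-edge averaging.
5. **Inference**: SIMPLS partial least squares. Within each period, the
   behavior parameters (speed, |acceleration|, duration, pupil — with
   TSR imputation of missing pupil) are regressed against the edges,
   Y₀ = X₀·B_PLS + E, with the component count chosen by BIC-adjusted
   10-fold contiguous cross-validation. Loadings convert to
   original-unit slopes, Δr = XL·YLᵀ/(n−1)·σ_X/σ_Y — the expected
   change in correlation per unit of each parameter. The
   parameter-removed residuals feed dummy-coded period-vs-period
   regressions; significance comes from a 1000-permutation null
   (circular shifts, averaged across mice), a two-tailed z-test, and
   Benjamini–Hochberg FDR at α = 0.05.

The synthetic generator (`widefc.synth`) emulates the full study: 16
mirror-paired cortical nodes, a vessel mask, the treadmill state
machine (3–25 s stages, speeds 0/2.25/2.77/3.33/3.88 cm/s, cues 5 s
before transitions), spontaneous bouts near 7 cm/s, planted activation
offsets and edge-correlation effects, a shared 0.2 Hz hemodynamic
artifact in both channels, and pupil traces with missing stretches.

## Worked example

Plant a rest→walk correlation shift of z = 0.3 on one edge and a +5
ΔF/F% activation offset on one node, then recover both through the
window + PLSR + permutation stack:

```python
import numpy as np
from widefc import experiments as ex

cohort = ex.simulate_window_cohort(
    n_mice=7, n_pairs=4, windows_per_period=500,
    edge_shift_r=np.tanh(0.3), activation_offset=5.0, seed=0)

sig = ex.rest_walk_significance(cohort, on="fc", n_perm=200, seed=0)
e = ex.planted_edge_index(4)
print(f"planted edge: shift = {sig.observed[e] / 2:.3f} z, "
      f"significant = {bool(sig.fdr_mask[e])}")
print(f"other edges flagged: {int(sig.fdr_mask.sum()) - 1} of {len(sig.observed) - 1}")
```

```
planted edge: shift = 0.311 z, significant = True
other edges flagged: 0 of 27
```

The planted shift is recovered at its true size (0.311 vs 0.3) and
flagged significant; no null edge is flagged. (The PLSR slope matrix is
low-rank, so a strong effect can also spread onto edges sharing a node
with it; the permutation null accounts for chance, and on truly null
cohorts the flagged fraction stays below α — see the type-I test.)

Run the full image-level pipeline from the shell:

```bash
widefc run-all --seed 1 -o out/          # simulate → ... → report
widefc parcellate -c config.yaml          # stop after parcellation
```

Each stage writes CSV/JSON (and PNG matrices in `report/`) under the
output directory, next to the resolved config and a manifest.

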