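# Methods

This note documents the models, conventions and numerical choices behind
`eegstates`, in the order data flows through the pipeline.

## Synthetic EEG generator

The generator produces multichannel recordings whose microstate structure
is known exactly, emulating a 64-channel, 5-minute, 1000 Hz resting-state
acquisition on a 10/20-extended cap. The signal model is

    x(t) = p(t) · e(t) · m_{L(t)} + ε(t)

with

- **Templates** `m_k`: smooth random potential fields on the electrode
  sphere (random linear gradient plus 1–3 von Mises–Fisher bumps,
  κ ∈ [2, 6]), average-referenced and unit-normalised. Sets are rejection-
  sampled until every pair satisfies |corr| ≤ 1 − `min_separation`
  (default 0.3) *and* every electrode's RMS across the set is ≥ 60% of the
  median electrode's — real microstate classes jointly activate the whole
  scalp, and a set leaving an electrode silent in all states would make
  any spatial-consistency check on clean data ill-posed.
- **Label process** `L(t)`: segment lengths geometric at sample
  resolution (memoryless, matching the Markov assumptions of backfitting)
  with per-state mean 80 ms by default; successors drawn from a
  row-stochastic zero-diagonal transition matrix (uniform by default).
- **Polarity** `p(t)`: flips between segments with probability 0.5 —
  microstates are polarity-invariant, and the analysis must not care.
- **Envelope** `e(t) = |sin(2π·10 Hz·t)|` scaled to mean 1: GFP waxes and
  wanes as in alpha-dominated rest, guaranteeing GFP peaks exist. Note the
  envelope has exact zeros; the backfit conventions below handle them.
- **Noise** `ε(t)`: spatially white Gaussian, SD = `noise_sigma` × the
  (unit) map norm; default 0.1. Spatially correlated noise is not
  modelled (config hook reserved).

Artifact injection plants flatline spans, fully decorrelated channels and
high-amplitude 0.5-s bursts, with provenance logging.

What the generator does **not** emulate: volume-conduction-correlated
sensor noise, ocular/cardiac/muscle artifact morphology, non-stationary
spectra, and biophysical forward modelling. Passing tests therefore show
the *pipeline* is correct and well-calibrated, not that real-data SNR
conditions are met.

Demo cohorts use 22 "patient" vs 46 "control" subjects with severity
scores ≥ 17 in the patient group (the questionnaire screening threshold)
and a lognormal 10% between-subject jitter on mean segment durations.
Planted group effects: `duration_scale` multiplies per-class mean segment
durations (default A×0.92, D×0.85), `transition_bias` multiplies
transition probabilities *into* a class with row renormalisation (default
B×1.3, C×1.15), raising that class's occurrence and coverage without
touching its segment-length law — jointly mirroring the shorter-A/D,
higher-B/C pattern such studies report. Cohorts for statistical tests are
generated at the label-sequence level (the parameters and transition
tables being functions of the label sequence alone); full-EEG cohorts are
written as BrainVision triplets by `make_demo_cohort`.

## Preprocessing

Fixed order: resample → band-pass + notch → bad-channel detection →
spherical-spline interpolation → average reference → window rejection →
epoching. Defaults: 250 Hz, 1–40 Hz, 50 Hz notch, 5 s / 4 SD / 0.8
criteria, 0.5-s / 20-SD windows, 2-s epochs.

- **Resampling**: polyphase (scipy `resample_poly`), output length
  floor(n·target/original).
- **Filters**: zero-phase Hamming-windowed-sinc FIR band-pass (transition
  width 1 Hz, so a ~3.3 s kernel at 250 Hz) applied forward-backward, plus
  an IIR notch of 2 Hz width; channel means are removed first. A 50 Hz
  sine is attenuated below 5% RMS; 10 Hz passes above 90%.
- **Bad channels**, three criteria with per-channel reasons:
  *flatline* — any constant run (successive |Δ| < 1e-10 µV) ≥ 5 s;
  *noise* — MAD-scaled SD of the first difference more than 4 robust SDs
  above the cross-channel median, with the spread floored at 5% of the
  median so that near-identical channel noise cannot inflate z-scores;
  *correlation* — over 1-s windows, the channel's Pearson correlation
  with its leave-one-out spherical-spline prediction from all other good
  channels falls below 0.8 in the majority of windows. Correlations are
  computed on a 1–20 Hz band-limited copy and *disattenuated* by the
  channel's sensor-noise floor estimated from the > 50 Hz band (white-noise
  assumption); windows with in-band SNR < 1 count as failing. The
  disattenuation removes the systematic penalty on low-amplitude but
  spatially consistent channels; a genuinely decorrelated channel still
  scores near zero. Within the full chain, detection inspects the
  resampled *unfiltered* data — the FIR kernel smears flat spans and the
  filter empties the noise-estimation band — while repair is applied to
  the filtered data.
- **Interpolation**: spherical splines (stiffness m = 4, 50 Legendre
  terms, Tikhonov regularisation 1e-5, constant term via a bordered
  system). Each bad channel becomes a fixed linear combination of good
  channels; good channels are untouched. Cross-checked in tests against
  mne's implementation and an analytic linear field.
- **Window rejection**: non-overlapping 0.5-s windows; per-channel
  calibration RMS = mean over that channel's cleanest quartile of
  windows; a window is excised when any channel exceeds 20× its
  calibration level. Cut points are recorded and epoching restarts at
  every cut, so no epoch spans a discontinuity. Rejection (not subspace
  reconstruction) is used deliberately: it is conservative, testable, and
  preserves the artifact-exclusion intent; a hook allows plugging an
  external cleaner before epoching.

## Template derivation

- **GFP peaks**: strict local maxima per epoch, thinned to ≥ 10 ms
  spacing (higher peak wins; on exact ties the earlier sample). Epoch
  boundary samples are never peaks. All peaks are used (no subsampling
  cap) at the problem sizes this package targets; a cap is configurable.
- **AAHC** operates on unit-normalised peak maps, making the partition
  invariant to per-map scaling and sign — an amplitude-weighted
  atomization criterion would not be. The implementation maintains
  per-cluster scatter matrices with rank-1 updates; the cluster template
  and its explained variance are the top eigenpair. Exact quality ties
  atomize the lowest-index cluster. Reported GEV diagnostics are
  GFP-weighted over the final partition. Equivalence with a naive
  from-scratch AAHC is asserted over 50 random instances.
- **Group templates**: subjects' template sets are aligned to an evolving
  group mean by exhaustive search over the K! = 24 permutations and
  per-map signs (maximizing summed squared correlation), iterated to a
  1e-6 fixed point (≤ 100 iterations; the objective is non-decreasing);
  the polarity-reconciled mean is renormalised. A second-level clustering
  over pooled subject maps is a reasonable alternative; the aligned-mean
  route was chosen because it is deterministic and exhaustively testable.
- **Canonical labels**: four built-in archetypes on the montage (A:
  left-posterior/right-anterior diagonal; B: the mirrored diagonal; C:
  anterior–posterior; D: fronto-central focal bump), assigned one-to-one
  by exhaustive permutation maximizing total |corr|. On synthetic cohorts
  the generating maps are arbitrary, so labels are consistent but not
  anatomically meaningful.

## Backfitting and parameters

- Label = argmax |corr| per sample; ties to the lowest class index.
  Samples with GFP < 1e-12 (envelope zeros) inherit the previous label,
  and leading dead samples take the first live label — otherwise envelope
  zeros at epoch starts fabricate one-sample segments and inflate
  occurrence.
- No temporal smoothing by default; an iterative shortest-segment
  absorption (re-assigning samples to the better-correlated neighbouring
  segment) is available via `min_segment_ms`.
- **Duration** averages interior runs only (boundary-truncated runs bias
  downward); classes with no interior run report NaN, not zero.
  **Occurrence** counts all runs per retained second. **Coverage** is the
  per-class sample share (sums to 100 exactly). Transitions are counted
  between consecutive segments within epochs only.
- **Expected transitions**: independence null
  `E(i→j) = 100·q_i q_j / Σ_{a≠b} q_a q_b` over segment-count fractions
  q. A coverage-weighted alternative is deliberately not the default: the
  null concerns segment order, not time share.

## Statistics

- Normality gate: Shapiro–Wilk on both groups; both must pass at α for
  the pooled-variance t-test, otherwise asymptotic Mann–Whitney U
  (no continuity correction). Constant samples skip the gate and are
  flagged. Welch's t is available behind a flag.
- Observed-vs-expected transition tests default to the *unpaired* t-test
  (the conventional reporting), but note: observed and expected values
  are computed from the same segmentation and are positively correlated
  within subject, which makes the unpaired test structurally conservative
  (measured type-I rate ≈ 0.008 at nominal 0.05). The paired variant
  (`paired=True`) is correctly calibrated (measured ≈ 0.05) and is what
  the calibration tests assert; the conservatism of the default is
  asserted as `rate ≤ α`.
- Multiplicity: Holm step-down by default over the 12 transition cells;
  Bonferroni and Benjamini–Hochberg selectable.
- ANCOVA: `y ~ group + x + group:x`, reporting the interaction F (type-II
  table; identical to R's sequential table for the last term).
- All statistics are cross-validated in the test suite against R
  (`t.test`, `wilcox.test(correct=FALSE)`, `shapiro.test`, `cor.test`,
  `lm`/`anova`) to 1e-6 on 50 seeded datasets; Shapiro–Wilk *p*-values
  agree to 1e-4 only, because both implementations share an analytic
  approximation whose tail behaviour differs slightly from platform to
  platform.

## Problem sizes

Validation and the acceptance script run at desk scale, chosen so the
full suite completes in minutes on one CPU: template-recovery cohorts of
6 subjects × 120 s × 32 channels at 250 Hz and noise 0.1; noise-free
parameter recovery on 120-s subjects; 200-seed null-calibration runs and
20-cohort planted-effect runs at the label-sequence level; 100-seed
bad-channel screens at 60 s × 32 channels. The full-EEG demo pipeline
(`eegstates run`) defaults to 60-s subjects for the same reason; all
durations scale up by configuration.

## Known limitations

- The simulator's white sensor noise flatters spatial-consistency checks
  relative to real recordings, where noise is spatially correlated.
- The synthetic signal is not band-limited, so the 1–40 Hz zero-phase
  filter necessarily blends neighbouring segments near transitions;
  per-sample map correlations after filtering have a lower tail even
  noise-free (the GFP²-weighted explained variance of the true labelling
  stays ≥ 0.85, and group-template recovery is unaffected).
- ICA-based artifact removal is out of scope; the window-rejection stage
  plus the plug-in hook stand in its place.
- Canonical archetypes are idealized geometric fields, not normative
  templates from a reference population; on real data, label assignments
  should be visually confirmed.
- Microstate class D's clinical interpretation (and any anatomical claim)
  is outside the package's remit; it computes the parameters, not their
  meaning.
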