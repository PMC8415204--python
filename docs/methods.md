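# Methods

## Signal model of the synthetic study

Each recording is a node × time array built as

    x_j(t) = e_j(t) · c_j(t) + ν · w_j(t)

- **Carrier** c_j: white noise band-pass filtered into the carrier band
  (default alpha, 8–13 Hz; zero-phase 4th-order Butterworth),
  standardised to unit variance. Carriers are independent across nodes,
  so the raw signals carry essentially no zero-lag correlation — the
  coupling lives entirely in the envelopes, which is what the AEC metric
  is meant to measure and what survives orthogonalization.
- **Envelope** e_j = exp(σ·d_j·g_j): the exponential of a slow Gaussian
  process (white noise low-passed at 0.3 Hz, sampled at 4 Hz, linearly
  upsampled). Envelopes are therefore positive, smooth and log-normal.
  The g_j are mixed across nodes by the Cholesky factor of a prescribed
  **latent correlation matrix**; σ = 0.5 is the baseline log-envelope SD
  (giving envelope CoV ≈ 0.5, in the range seen for band-limited MEG
  envelopes) and d_j is the per-node **dispersion factor** the activity
  effects act on.
- **Noise floor** ν = 0.05 of broadband white noise keeps every band's
  envelope non-degenerate.

The measured 1-s envelope correlation is an increasing but shrunken
function of the latent correlation (the exp transform and the carrier's
own Rayleigh-like envelope both attenuate it): latent
{0, 0.2, 0.4, 0.6, 0.8} map to roughly {0, 0.10, 0.25, 0.41, 0.58}
measured. All targets are therefore specified in the latent domain and
tests assert monotonicity plus ground-truth recovery rather than naive
equality.

**Design**: 15 subjects × drugs {active, placebo} × sessions {pre,
post1, post2, post3}; one recording per cell; 90 nodes in six contiguous
blocks (latent correlation 0.5 within block, 0.15 between — a coarse
modular resting-network topology); 300-s recordings in 2-s epochs.
Between-subject variability: a symmetric Gaussian perturbation
(SD 0.05) of the latent matrix per subject, PSD-projected (eigenvalue
clipping at 0, diagonal renormalised).

**Planted effects** (active drug, post sessions only): the latent
correlation of 20 within-block posterior edges is multiplied by 0.5
(then PSD-projected); envelope dispersion is multiplied by 1.3 on the 15
"frontal" nodes and 0.75 on the 15 "posterior" nodes. The paper-style
qualitative pattern (posterior connectivity reductions, frontal activity
increases, posterior activity decreases, active arm only) is thus
encoded with effect sizes chosen once, at design time, to be clearly
recoverable at the study's size; no empirical effect sizes exist to
match. The **receptor template** is ρ·z(|effect|) + √(1−ρ²)·z(noise),
affinely shifted nonnegative, with ρ = 0.25 — the planted spatial
correlation between receptor density and effect magnitude.

Determinism: every cell's generator seed derives from the study seed via
`SeedSequence` spawn keys, so identical seeds reproduce identical arrays
and recordings are regenerated on demand rather than held in memory.

## Analysis chain and its numerical choices

Pipeline order is fixed: region reduction (when starting from voxels:
the maximum-temporal-SD voxel represents each region, ties to the lowest
index) → per-epoch band-pass → concatenation → symmetric
orthogonalization (connectivity path only) → Hilbert envelope → 1-s
window means (trailing partial window dropped) → median filter (k = 3)
→ Pearson AEC.

- **Band-pass before concatenation, per epoch** mirrors per-band
  processing of epoched data; the Hilbert transform runs on the
  concatenated series. First/last windows are kept, not trimmed — a
  deliberate simplification.
- **Symmetric orthogonalization** solves min‖D − diag(ρ)U‖_F over
  orthonormal-row U and free row scales ρ, by alternating a Procrustes
  (polar) step with the closed-form scale update, run in the n × n
  space of an economy factorisation (an eigendecomposition of DDᵀ), so
  the cost is two n²T products regardless of iteration count.
  Convergence tolerance 1e-12 on the objective; rank-deficient input
  (Gram eigenvalue < 1e-12 of the largest) is an error.
- **Surrogate normalisation**: null per edge from K circular shifts of
  one member (offsets uniform in [5, T−5]); observed z divided by the
  null SD. The null mean (≈0 for shift surrogates) is not subtracted by
  default (configurable). K defaults to 100; calibration studies use
  K = 500 so the check measures calibration rather than the χ-noise of
  the SD estimate itself. Observed r is clipped to ±(1−1e-12) before
  atanh so perfectly coupled envelopes give a huge finite z.
- **Noise-peak fit**: window = median ± 1.4826·MAD, Freedman–Diaconis
  histogram, bounded least-squares Gaussian (amplitude, μ, σ; σ
  constrained to [width/20, 5·width]), then one refit with the window
  recentred at the fitted μ ± σ. Single-fit σ noise is ≈ 0.06 at
  n = 10⁴; robustness claims are therefore made on means over
  replicates. Failure raises an error carrying the robust estimates.
- **Mean-rank pruning** retains ceil(f·E) edges (f = 0.2); average ranks
  with average-tie handling; ties at the cutoff break lexicographically
  by (i, j). The mask is computed jointly across all subjects and
  sessions of both arms.
- **Activity path** shares the envelope code but skips
  orthogonalization: leakage correction redistributes variance across
  nodes, which would distort a per-node variability measure (a flag
  re-enables it). CoV uses the sample (n−1) SD.

## Statistics

- **RM-ANOVA**: standard two-way fully-within partitioning, each effect
  tested against its subject-by-effect interaction; for 2 × 4 with n
  subjects df are (1, n−1), (3, 3(n−1)), (3, 3(n−1)). No sphericity
  correction. Sums of squares below 1e-12 of the total are treated as
  roundoff zeros. (Reports of interaction F with df (1, 14) for such
  designs exist in the applied literature; they are not reproducible
  from the standard partition and are not replicated here.)
- **Post-hoc permutation**: subject-level sign flipping of difference
  vectors (exact under exchangeability of difference signs), flips
  applied jointly across features to preserve spatial correlation.
  p = (1 + #exceedances)/(1 + n_perm). The pipeline corrects over the
  **full comparison family**: one flip per subject × drug, shared across
  that drug's post sessions, omnibus statistic = max |t| over every
  feature and contrast. Family-wide control is what licenses study-level
  claims such as "no placebo changes anywhere"; correcting each contrast
  separately would leave the whole-arm false-positive rate near
  1−(1−α)^(#contrasts) ≈ 14 %. A single-contrast variant exists and is
  what the FWER calibration checks.
- **Gate**: edge post-hocs run on edges with interaction p < α
  (uncorrected), node post-hocs on nodes surviving interaction FDR —
  mirroring the convention of testing post-hocs only where the ANOVA
  shows an interaction. Configurable to "none". Note that gating is a
  selection step: with small gated families its circularity can inflate
  placebo-arm hits, which the family-wide correction keeps in check.
- **Template correlation**: Pearson r between |t| activity maps and the
  template; null by permuting the template's node assignment, one
  permutation shared per draw across the session family, omnibus by
  max |r|. The node-shuffle null assumes exchangeable nodes; on
  spatially smooth maps it is **anti-conservative** (measured
  false-positive rate 0.51 vs nominal 0.05 at Gaussian smoothing σ = 5
  nodes over a 1-D node ordering — `analysis/05_smoothness_inflation.py`).
  No spin/variogram-matched null is implemented; the caveat is
  demonstrated, not fixed.

## Parameters

| parameter | default | meaning |
|---|---|---|
| bands | 7 canonical | delta…gamma3 band edges (Hz) |
| fs / epoch | 600 Hz / 2 s | recording rate and epoch length |
| median_k | 3 | envelope median-filter window (1-s samples) |
| n_surrogates | 100 | circular-shift surrogates per recording |
| retain_fraction | 0.2 | mean-rank edge retention |
| n_perm | 5000 | permutations (post-hoc and spatial tests) |
| alpha / fdr_q | 0.05 | significance levels |
| log_env_sd | 0.5 | baseline log-envelope SD |
| subject_corr_sd | 0.05 | between-subject latent-correlation SD |
| template_rho | 0.25 | planted template spatial correlation |

## Evaluation scales

Routine evaluation uses the **CI profile**: the full default design
(15 × 2 × 4, 90 nodes, 300 s, 2-s epochs, all effects and the template
unchanged) with the carrier sampled at 150 Hz instead of 600 Hz and
n_perm = 2000. All downstream measures are computed from 1-s envelope
samples, whose statistics do not depend on the carrier rate, so this
changes cost (~110 s per study on one CPU) but not the scientific
content; the alpha band alone is analysed since the generator
concentrates oscillatory power there. Repeated-seed specificity checks
use the **mini profile** (10 subjects, 24 nodes, 180 s, 150 Hz,
n_perm = 1000). Template-correlation recovery averages over 20
independent template redraws against one study's |t| maps: a single
template realisation at 90 nodes carries sampling noise of SD ≈ 0.1, and
redrawing removes exactly that term (E[r] = ρ·corr(|t|, truth)) without
re-simulating recordings.

## What passing tests do and do not show

The generator produces band-limited signals with log-normal envelopes,
independent carriers, homogeneous block topology and complete balanced
designs. It does not emulate sensor noise structure, head motion,
beamformer leakage patterns (orthogonalization is exercised on
envelope-coupled but carrier-independent signals), 1/f background,
between-session amplitude nonstationarity, missing cells, or spatially
smooth effect/template maps (nodes are exchangeable — deliberately, so
the permutation nulls are exact and calibration is measurable; the
smoothness demonstration shows what breaks when they are not).
Recovery results therefore validate the pipeline's statistical
machinery, not its behaviour on any particular real dataset.

## Known limitations

- Whether the reference workflow band-passed before or after epoch
  concatenation, and whether orthogonalization was per band or
  broadband, is not fully determined; this implementation filters per
  epoch and orthogonalizes per band.
- "Cross-correlation" of envelopes is taken at zero lag (a single scalar
  per edge is required downstream); lagged coupling is out of scope.
- The gamma bands of the default generator contain only the noise floor;
  analysing them yields calibrated nulls rather than planted effects.
- The activity measure is computed on whatever node set is supplied; the
  voxel-level use case is represented by configurable node counts, not
  an actual volumetric grid (a NIfTI writer exists for node→voxel
  index maps, but no registration or resampling machinery).
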