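# Methods

`reliacase` implements a reliability-aware analysis chain for detecting
atypical task activation in *individual* subjects — the single-case setting
that matters clinically, where one child is compared against a small
normative sample rather than group against group. The pipeline was designed
around a two-group child fMRI paradigm (16 patients with developmental
dyscalculia, DD; 16 typically developing controls, TD; two numerical tasks;
test and retest sessions), but every stage is generic.

## Pipeline model

**First-level GLM (`glm`).** Each run is modeled as
`y = X b + e`, with `X = [task, motion(6), cosine drifts, 1]`. The task
regressor is a boxcar over the (self-paced, subject-specific) blocks
convolved with a canonical double-gamma HRF (gamma shapes 7/17, scale 1 s:
response peak at 6 s, undershoot trough near 16 s, peak:undershoot 6:1),
scaled to unit peak so the task beta is in data units. High-pass filtering
is expressed inside the model as two discrete-cosine drift columns (2
cycles per run) rather than by pre-filtering the data — an equivalent
nuisance-projection formulation that keeps the data untouched. Serial
correlation is handled by single-pass Cochrane–Orcutt: OLS fit, a single
pooled lag-1 autocorrelation estimate per run (per-voxel estimates are too
noisy at the ~100-volume runs children produce), one AR(1) prewhitening
pass, refit. The rest periods are the implicit baseline, so the task
coefficient is the "activation minus baseline" contrast. Session betas are
averaged voxelwise to reduce measurement error; the averaged beta is the
native currency of everything downstream.

**Reliability masking (`reliability`).** Test–retest reproducibility is
quantified per voxel by the Shrout–Fleiss two-way random-effects,
single-measure intraclass correlation,

    ICC(2,1) = (MSR − MSE) / (MSR + (k−1) MSE + k (MSC − MSE)/n),

estimated over all n subjects' k = 2 sessions (absolute agreement;
negative estimates are kept as computed). Per-task ICC maps are combined
with Fisher's z' transform (equal task weights; values clipped to
±(1 − 1e−7) before atanh), and the analysis mask keeps voxels with
combined ICC strictly greater than 0.33 — a deliberately strict floor for
child data, where reliability is typically poor. All inference, feature
extraction and clustering are restricted to this mask.

**Group statistics (`group`).** One-sample (per group, against zero) and
pooled-variance two-sample t maps on the session-averaged betas, two-sided
voxel threshold p < 0.01. Familywise error is controlled by a Monte-Carlo
cluster-extent threshold: Gaussian null fields are smoothed to the
smoothness estimated from the group-residual maps, renormalized inside the
mask, thresholded at the voxel p (two-sided, clusters formed per sign),
and the minimum extent k* is the smallest cluster size whose null
exceedance probability is ≤ α = 0.05. Smoothness uses the
variance-of-spatial-derivatives estimator
`FWHM = Δx sqrt(−2 ln 2 / ln(1 − vard/(2 var)))`, floored at one voxel
size because sampled fields cannot exhibit smoothness below the sampling
resolution (the floor is what the white-noise limit returns).

**Single-case maps (`singlecase`).** One patient against the control
sample uses the Crawford–Howell test for a deficit,

    t = (x_case − mean(controls)) / (sd(controls) · sqrt((n+1)/n)),  df = n − 1,

which treats the control sample as data, keeping the type-I rate nominal
at n = 16 where a z-score would be anticonservative. Applied voxelwise to
averaged betas it yields a signed deviation map; significant voxels
(two-sided p < 0.01) are split by sign and cluster-filtered at the same k*
as the group maps. The percentage of patients whose directional mask
covers a voxel gives the over-/under-activation frequency-of-deviation
maps. Imaging comparisons always use df = n_controls − 1 (the Crawford
definition).

**Classification (`classify`).** Features are the session-averaged betas
at voxels inside (ROI ∪) ∩ reliability mask, in documented C-order per ROI
block (an ROI-mean mode exists behind a flag); the concatenated mode
stacks both tasks' vectors. A linear SVM (C = 1, no kernel, no tuning) is
evaluated by leave-one-out with training-fold-only standardization — no
leakage of the left-out subject into the scaling. The power-set search
evaluates all 2^R − 1 nonempty ROI subsets, reporting best CCR per subset
size, all argmax subsets, and an overall winner (ties broken toward
smaller subsets, then lexicographic name order). The full 17-ROI search is
131,071 subsets and hours of fits; the runtime guard refuses R above a cap
(default 17 in the library, 10 in the CLI) without an explicit force.
CCR, sensitivity and specificity satisfy
`CCR = (sens · n_DD + spec · n_TD)/(n_DD + n_TD)` exactly by construction.

**Clustering (`cluster`).** Subjects are compared by Spearman rank
correlation over the masked voxels (average ranks over the full —
possibly concatenated — vector, so equal-length task blocks are equally
weighted), with dissimilarity d = 1 − ρ: rank-based to resist outlying
voxels, and anticorrelated patterns maximally distant (d = 2, rather than
|ρ| variants which would conflate them with correlated ones).
Agglomeration is complete linkage — a strict criterion that produces
well-separated clusters when they exist. k is an explicit input; a
largest-merge-gap suggestion is reported, never silently applied. Per
cluster, one-sample baseline-contrast maps are available; *direct*
between-cluster contrasts are refused by default because contrasting
groups formed from the same data is circular (an override flag exists for
the knowing user).

## The synthetic world

The generator (`simulate`) emulates the study the pipeline was built for,
at two levels.

*Time series* (for validating the GLM only): self-paced block designs —
comparison task 4 blocks × 6 trials, calculation 6 blocks × 4 trials,
per-trial RTs lognormal (medians 1.2 s and 4.1 s, log-sd 0.35, matching
the behavioral summary statistics of the target population), 0.5 s ISI,
14 s rest before the first and after every block, TR 1.6 s — with
unit-peak HRF signal, slow random-walk motion parameters coupled into the
data, and stationary AR(1) noise.

*Beta maps* (the pipeline's native input): per voxel v, subject s,
session k,

    beta(s,v,k) = mu_group(v) + deviant_s(v) + b_s(v) + e_{s,k}(v),

with stable between-subject field b ~ N(0, σb²) (inside the brain mask
only) and session noise e ~ N(0, σe²), so the expected ICC is
σb²/(σb² + σe²) wherever group offsets are shared — a directly
controllable reliability field (default σb = σe = 1, planted ICC 0.5, the
"fair" regime typical of child data). The default grid is 30×36×30 at
3 mm with an inscribed ellipsoidal brain mask (~15.4k voxels) carrying 17
disjoint 5×5×5 box ROIs named after fronto-parietal number-processing
regions (THA, v/h/aIPS, PCL, aPCL, aFOP, CINS, CING, vPMC with hemisphere
codes).

The default effect topography, fixed a priori from the qualitative
findings the pipeline is meant to detect: task-positive activation +1.0
in hIPS-L/R for everyone; a patient-only upregulation +2.0 in vIPS-R (the
designated discriminative ROI) and +1.5 in vPMC-L/R; a control-only
default-network deactivation −2.0 in CING-L/R. Patient heterogeneity —
the clinical observation that individual deviation loci overlap little —
is modeled by each DD subject drawing 1–3 deviant ROIs from a pool
(PCL-B, aPCL-B, aFOP-L/R, disjoint from the group-effect ROIs) with a
subject-specific shift of ±5 control-SDs.

What the generator does **not** emulate: realistic anatomy, spatially
correlated noise (betas are spatially white, so estimated smoothness
floors at one voxel), physiological noise, registration error, or
session-order effects. A green planted-recovery test therefore
establishes that the statistics find what was planted under the stated
noise model — not that they would behave identically on scanner data.

Two consequences of the stated world are worth knowing. First, the
per-voxel ICC estimate at n = 32, k = 2 has intrinsic sampling MAE ≈ 0.11
at true ICC 0.5; recovery of the planted reliability field is therefore
assessed on the voxel-averaged estimate (bias ≈ 0.01), not per voxel.
Second, with heterogeneity enabled the k = 2 clustering does *not*
recover the DD/TD partition — the deviant blobs decorrelate patients from
their own group, exactly as the mixed clusters observed clinically — so
the planted-partition recovery check runs on the same world with
heterogeneity disabled.

## Numerical choices

- Cluster connectivity: 6-face adjacency by default (26 by flag);
  suprathreshold clusters are formed within sign.
- Monte-Carlo calibration: 1000 iterations by default, seeded; a warning
  is emitted when α × iterations < 5 (unstable tail).
- Zero-variance voxels: second-level t is capped at ±1e6 and QC-flagged;
  constant time series get beta 0 and a QC flag; a zero-variance control
  sample makes the Crawford t an error, not a number.
- Mask inclusion is strict (combined ICC > threshold); ICC of a
  zero-variance voxel is NaN and never included.
- Powerset ties: all argmax subsets are reported; the single "winner" is
  the smallest, then lexicographically first.
- Complete-linkage tie-breaking follows the deterministic order of the
  linkage implementation (smallest cluster indices first).
- Seeds: every stochastic routine takes an explicit seed or Generator;
  identical config + seed reproduces outputs byte-identically.

## Limitations

- The AR(1) pooled-ρ estimate is biased downward on short runs (residual
  autocorrelation of OLS); the reported SE is accordingly mildly
  optimistic. The validation suite checks the estimator's actual sampling
  variance against its closed-form GLS value instead.
- Cluster-extent correction assumes stationary smoothness; the estimator
  is global, not local.
- LOO at n = 32 has high variance per evaluated subset; power-set winners
  should be read as candidate sets, not inference.
- No behavioral-imaging integration beyond the shared Crawford machinery;
  psychometric modeling is out of scope.
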