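# Methods

This note documents the models and procedures implemented in `pharmconn`,
the parameters that matter, the design choices made where the design was
genuinely open, and the limits of what the synthetic validation shows.

## Study design and data model

The package targets a double-blind, within-subject, two-session design:
each subject is scanned once on drug and once on placebo (TR 3 s, 124
volumes per resting scan by default, i.e. 372 s), with subjective and
cardiovascular ratings collected pre-dose and at 15, 30, 75, 115 and
200 min post-dose. The in-memory unit is a `BoldSession` (4D array, brain
mask, TR, motion parameters); sessions travel the pipeline as NIfTI-1
files on disk.

## Synthetic studies

`synthdata` is the test bed: it generates paired studies in which every
quantity the pipeline estimates has a known target.

**Spatial networks.** K compact anisotropic Gaussian blobs, truncated at
5% of peak, placed on an ellipsoidal mask with every pairwise spatial
correlation below 0.15 (the generator enforces < 0.3 as a hard invariant;
the default is stricter because anatomically distinct networks overlap
little, and overlap directly confounds source separation). Blob scales are
drawn from a narrow range (sigma 1.3–2.0 voxels, scaled with mask size) so
all planted networks sit at comparable SNR — a deliberately favourable
regime: the recovery criteria are about the pipeline, not about rescuing
vanishing sources. The mask carries anatomical stand-ins: the boundary
shell acts as "CSF" and a central core as "white matter"; networks have no
support there, mirroring gray-matter sources.

**Sessions.** Network time courses are drawn from a K×K correlation matrix
(condition-dependent), mixed linearly into voxel space — the generative
converse of dual regression — plus white Gaussian noise (`noise_sd`,
default 0.5 in map-weight units; "high SNR" scenarios use 0.10–0.15). A
shared physiological fluctuation (amplitude 2 × `noise_sd` in the tissue
stand-ins, 30% of that in gray matter) gives the CompCor-style tissue
regression something real to remove; it scales with `noise_sd` so a
noiseless session is exactly noiseless and the closed-form round-trip
checks stay valid. An optional AR(1) switch for temporal autocorrelation
is off by default for the same reason.

**Motion spikes.** With probability `spike_prob` per volume (default 0.05;
resting-state cohorts commonly flag on the order of 10% of volumes, and
0.1 is used for denoising stress tests), a volume receives (a) a recorded 1 mm translation
excursion, (b) a global-signal offset of 8 SD of the global mean, and
(c) spatially white disruption of SD 5 map-weight units. The spatial part
matters: a purely global offset is absorbed by the intercept of any
spatial regression and would leave network time courses untouched, which
no real motion artifact does.

**Subject structure.** Each subject gets one random symmetric edge
perturbation (SD `subject_sd` = 0.05) added to both sessions' correlation
targets — this shared deviation is what the paired contrasts exploit. Any
target that is not a valid correlation matrix is projected to the nearest
one (eigenvalue clipping), and the realized matrix is recorded as ground
truth. All randomness descends from a single study seed.

**Hub scenario.** The planted between-network effect used throughout
validation: under placebo two "cortical" networks correlate at 0.45 and a
"hub" correlates with each at 0.10; drug adds +`effect` to both
hub–cortical edges and −`effect` to the cortical–cortical edge. The
magnitude of a realistic drug effect on between-network correlation is
not well established (published analyses of such designs report test
statistics rather than effect sizes); the package's default is 0.2
correlation units, and "large effect" in the acceptance scenarios means
0.35.

**Ratings.** Placebo sessions fluctuate around a measure baseline; drug
sessions add a rise-and-fall bump peaking midway between the 2nd and 3rd
post-dose timepoints (≈52 min, matching the expected oral
pharmacokinetics), scaled by a per-subject lognormal sensitivity (log-SD
0.25). Defaults: amplitude 3.0 on the stimulant scale against 1.0
within-subject noise.

## Denoising

Order of operations: outlier detection → confound regression (with one
spike regressor per flagged volume) → bandpass → smoothing. Framewise
displacement is the Power-style composite (sum of |Δtranslations| plus
rotations converted to arc length at a 50 mm head radius); volume t is
flagged iff FD > 0.5 mm or the z-scored global-signal change exceeds 3 SD.
Subjects are excluded when either session has mean FD > 0.5 mm or more
than half its volumes above 0.5 mm (strict inequalities). The nuisance
design is intercept, linear and quadratic drift, 6 motion parameters and
their backward differences, white-matter and CSF mean signals, and the
spike indicators; near-collinear columns are dropped greedily with a log
record. The bandpass is an ideal zero-phase frequency mask (0.008–0.09 Hz
default), chosen over a Butterworth so pass/stop examples are exact; a
high cutoff above Nyquist is clamped to 0.99 × Nyquist with a warning
(at TR 3 s Nyquist is 0.167 Hz, so a 0.9 Hz specification cannot be taken
literally and is read as 0.09 Hz). Smoothing (FWHM 6 mm at 3 mm voxels)
is mask-restricted: volumes are convolved as data × mask and renormalised
by the smoothed mask, so out-of-mask values are neither read nor written.

Confound regression and the frequency mask are each orthogonal
projections — idempotent individually — but their composition is not
(filtering re-introduces energy along the spike columns), so "denoise
twice equals denoise once" holds stage-wise, not jointly; a joint
regression-plus-filter projection is intentionally out of scope.

## Consensus group ICA

Each run: per-session temporal PCA (1.5 × the model order retained),
seeded random concatenation order, group PCA, fixed-point spatial ICA
(logcosh nonlinearity). Component maps are z-scored within the mask and
sign-oriented to nonnegative skewness. The model order per run maximizes
Minka's Laplace approximation to the PPCA evidence over the eigenvalue
spectrum of the reduced concatenated matrix (the estimate is computed on
the concatenated group data, not per subject). Because the per-session
reduction is order-invariant, all runs of one study estimate the same
order — the run-to-run variability that matters downstream comes from the
ICA itself.

FastICA's tolerance-based convergence test routinely keeps failing on
pure-noise components even when the signal components are stable, so a
fit is accepted when it converges, or when two independent restarts agree
component-wise (greedy |r| ≥ 0.95), or — with a warning — when restarts
are exhausted but the decomposition is finite and non-degenerate. The
cross-run consensus is precisely the machinery that absorbs residual
run-to-run variability. Network identification runs on unsmoothed
denoised data: heavy smoothing violates the independent-voxel assumption
behind the Laplace order estimate and drives it to the ceiling; smoothing
is applied afterwards to the sessions entering the voxelwise contrast.

Matching uses |Pearson r| over the mask (ICA sign is arbitrary) with the
0.7 threshold; candidate consensus sets are cliques with one component per
run, grown greedily by mean internal |r| with single-use components — no
canonical rule exists for resolving overlapping candidate sets, and the
greedy rule is deterministic and maximizes within-set coherence. Members are sign-aligned to the member with the strongest mean
match, averaged, and re-z-scored; each consensus map's re-correlation with
every member is recorded. The relaxed pass repeats the extraction at
support ≥ 4 on the remaining components (the "weak subcortical network"
case). Artifact screening — a visual step in practice — is heuristic
here: boundary-shell concentration (> 50% of top-decile voxels on the
shell), spatial near-whiteness (mean neighbour correlation < 0.2, the
signature of a motion-spike component), optional high-frequency power in
a member time course, and a manual override list that always wins.

## Within-network inference

Dual regression: stage 1 regresses all K consensus maps (plus intercept)
on every volume, giving K time courses normalised to unit variance;
stage 2 regresses those courses (plus intercept) on every voxel series,
giving K spatial fit maps. Stage-1 normalisation is the implemented
reading of "normalised to unit variance"; a switch covers the stage-2
alternative. Nearly collinear consensus maps (condition number > 1e8) are
an error naming the worst pair.

The paired contrast is a one-sample t on the N subject difference maps
(df = N−1), enhanced with TFCE: for each voxel, Σ e(h)^E · h^H · dh over
thresholds h = dh, 2dh, … ≤ max(stat), with E = 0.5, H = 2,
dh = max/100, 26-connectivity — the cited method's standard defaults. The
production TFCE is a single-pass union-find kernel (numba) that is
bit-identical to a brute-force per-threshold relabeling oracle; the
oracle lives in the tests. Inference is by sign-flip permutation of the
difference maps — the exact exchangeability of a within-subject
two-condition design — with permutation 0 the identity and full
enumeration when 2^N ≤ n_perm; p_fwe(v) = (1 + #{permutation max ≥
observed TFCE(v)}) / (1 + n_perm). Both directions are always evaluated,
and the Bonferroni gate uses per-test alpha = 0.05 / (networks × 2).

## Between-network inference

Network time courses are the stage-1 dual-regression courses (the
weighted extraction consistent with the within-network stage; a
map-weighted mean is available behind a flag). Edges are Fisher-z
transformed Pearson correlations, |r| clipped at 1 − 1e-12. The paired
edge t (df = N−1) supplies the NBS gate at uncorrected P < 0.01 per
direction; connected components of the suprathreshold graph are scored by
mass (Σ|t|; extent is a config option) and compared against a sign-flip
null of the maximum component mass. One subtlety: testing increases and
decreases each at alpha 0.05 against separate nulls would double the
familywise rate, so the null is the per-permutation maximum over **both**
directions — alpha is not split, and the familywise rate over the two
directions together is controlled at 0.05 (verified by the type-I
calibration test). Sign flips are whole-matrix (one sign per subject per
permutation), never per-edge.

## Behavioral analysis

MAP = (SBP + 2·DBP)/3, the standard clinical weighting (diastole
occupies roughly two thirds of the cardiac cycle).
The repeated-measures ANOVA is an explicit two-way fully-within
sum-of-squares decomposition, each effect tested against its own
subject-interaction error term with uncorrected df (Greenhouse–Geisser is
available but off by default, matching the uncorrected df convention);
`pingouin` serves as an independent cross-check in the tests, never as
the implementation. PCS = max over post-dose timepoints of (value −
same-session baseline); the drug−placebo PCS delta feeds Pearson
correlations against per-subject connectivity change scores (cluster-mean
stage-2 coefficients for within-network results, per-subject edge z for
significant pairs), Bonferroni-corrected over the number of connectivity
measures.

## Numerical choices and degenerate inputs

Zero-variance voxels/edges get t = 0 with a log record; constant time
courses raise with the offending network named; permutation p-values
count ties conservatively (≥ with 1e-12 slack); correlation-matrix
repairs are logged; all seeds derive from a single master seed through
`numpy` SeedSequence spawning, and every stochastic routine takes an
explicit seed.

## Validation scale and limitations

The acceptance suite runs at desk scale, chosen to keep the full suite
within tens of minutes on one core: type-I calibration uses 200 null
studies (12 subjects, ~10³-voxel grids, 500 permutations per test);
consensus recovery and the hub scenario use 16×16×12 grids with 6
networks (hub scenario: 22 subjects, 50 seeds, effect 0.35); the null
brain-behavior analysis uses 500 time-course-level studies. The
acceptance script runs one full 22-subject study end to end.

What passing these tests does **not** show: the generator's linear mixing
with white (or AR(1)) noise omits hemodynamic response shape,
physiological cardiac/respiratory cycles, scanner drift beyond the
polynomial the denoiser removes, spatially varying noise, and real head
displacement (spikes are signal-level surrogates, so realignment is out
of scope). Networks are compact blobs rather than distributed multinodal
systems, and their separation (< 0.15 spatial correlation) is cleaner
than cortical reality. Type-I calibration conditions on the planted
network set rather than re-running ICA inside each null study (network
estimation uses placebo data only and is condition-independent, so it
does not participate in the null of the drug–placebo contrast). Results
on real scans additionally depend on registration, segmentation and
acquisition quality, none of which the synthetic studies exercise.
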