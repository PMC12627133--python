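# Methods

## Stimulus spaces and category structures

Both modalities use a two-dimensional stimulus space with hard physical
ranges: auditory ripples vary in temporal modulation (2.0–14.8 Hz) and
spectral modulation (−0.38–2.67 cycles/octave); visual Gabor patches vary
in spatial frequency (0.04–0.072 cycles/degree) and orientation (10–104
degrees). Only these two-parameter coordinates are modeled; waveform and
bitmap synthesis is out of scope.

Each space is mapped affinely onto a normalized unit square [0, 1]², the
modalities' common currency: decision bounds, noise parameters and all model
fitting operate in normalized coordinates, so a single noise scale σ is
comparable across modalities. The map and its inverse round-trip to 1e−12.

Each category is a bivariate normal in physical units (per-category means,
SDs and covariances are packaged constants). Rule-based (RB) pairs share the
irrelevant-dimension mean and have covariances of equal magnitude and
opposite sign, so the pooled covariance is diagonal and the ideal observer
is a unidimensional criterion at the midpoint of the means on the relevant
dimension (auditory: temporal modulation; visual: spatial frequency).
Information-integration (II) pairs differ on both dimensions; the ideal
observer is the pooled-covariance Fisher linear discriminant through the
midpoint of the means. The per-category covariances differ slightly for II
pairs, which strictly implies a quadratic bound; the quadratic term is
negligible at these parameter values and the optimal II strategy is treated
as linear throughout.

Sampling is truncated to the physical ranges (out-of-range draws rejected
and redrawn, since the ranges are hard). Training sets contain 100 stimuli
per category and are *repaired* to an exact overlap: while the count of
stimuli on the wrong side of the optimal bound differs from the target
(default 10 of 200, i.e. a 95% accuracy ceiling), one mismatched stimulus is
redrawn from its own category, with a 10⁵-redraw cap. The design fixes the
overlap count of the stimulus roster but not how to achieve it; iterative
repair is this package's construction. Repair
slightly shifts sample means away from the wrong side of the bound
(≈ +0.03 Hz for auditory RB Category A), well inside sampling error.

Points exactly on a bound are labeled "A" — a measure-zero event needing a
deterministic rule. The generalization grid is an 8×8 lattice evenly spaced
in normalized coordinates spanning the full ranges (corner-inclusive; only
the grid's size is fixed by the design, so even spacing over the full range
is this package's choice), labeled by the task's optimal bound.

## Synthetic learners

The generator emulates group-structured strategy use, not trial-level
learning dynamics: each simulated participant has, per task, an explicit
per-block strategy schedule. From a drawn onset block onward the learner
applies the task-optimal strategy (unidimensional criterion for RB, the
optimal linear-integration bound for II) with participant-specific noise σ;
earlier blocks use fixed guessing or a suboptimal unidimensional rule
(equal probability per block). The test block reuses the block-8 strategy.

The shared response rule is P(A) = (1 − lapse)·Φ(h/σ) + lapse/2 with h the
signed perpendicular distance toward the A side; this is the standard
decision-bound formulation, with perceptual and criterial noise absorbed
into the single parameter σ. Default lapse is 0.

Default cohort parameters (all overridable): control onset ~ uniform{1..4},
ADHD onset ~ uniform{2..7}; σ = 0.08 (control) vs 0.12 (ADHD) normalized
units with jitter SD 0.015 and floor 0.02; ASRS symptom scores
~ Normal(35, 6.4) truncated below the screening cutoff 51 for controls and
~ Normal(60, 11.4) truncated above it for the ADHD-like group, reproducing
the studied groups' symptom spreads; ages ~ Normal(24.2, 2.2) and
Normal(26.2, 3.4) clipped to 20–35. Training blocks hold 50 trials
(25 per category); each half of training (blocks 1–4 and 5–8) exhausts the
200-stimulus roster exactly once via a shuffled deal, so the whole space has
been presented after four blocks. A session is 400 training trials plus 64
feedback-free test trials.

What the generator does *not* emulate: within-block strategy switching,
reinforcement-driven strategy change, reaction times, key counterbalancing,
sequential effects, or any direct ASRS→noise coupling within group (the
negative symptom–accuracy correlation arises from the group structure).
Passing tests therefore show that the analysis machinery recovers scheduled
strategies and group contrasts; they do not certify behavior on real data,
where strategies are latent and nonstationary within block.

## Model fitting and selection

Nine models per block: unidimensional criteria on x and y (two free
parameters: criterion, σ) with both response-region assignments; the
General Linear Classifier (three: bound + σ) with both assignments; fixed
guessing (p = .5); and two biased-guess variants with p(A) constrained to
[0.5, 1] and [0, 0.5] (one free parameter each). The fixed guesser is
charged zero free parameters — conventions differ here, so the count is
configurable via `default_inventory(r_guess_fixed=...)`.

The GLC is parameterized for fitting as a bound angle θ plus signed offset
with a unit normal, avoiding the infinite-slope singularity of
slope/intercept form; reported parameters are converted back to slope and
intercept where finite. Guessing fits are closed-form. Boundary fits
minimize the negative log likelihood by multi-start local optimization: a
dense fixed start grid (114 points for unidimensional models, 448 for the
GLC) plus 10 seeded random starts is evaluated in one vectorized pass, and
the best start is refined by Nelder-Mead (σ constrained to [1e−4, 2] by
penalty; xatol 1e−5, fatol 1e−8, maxfev 400). Refining only the top start
after a dense vectorized screen is this package's efficiency choice; the
fits match a 400×400 dense-grid oracle within far less than 0.5 in −2lnL,
and the number of refined starts is configurable. GLC fits additionally
receive the converted best unidimensional solutions as extra starts, so the
GLC log-likelihood never falls below the best nested unidimensional one.

Likelihood contributions are clamped to [1e−10, 1 − 1e−10]; the clamp is
part of the model and is applied identically in simulation and fitting.
Selection minimizes BIC = r·ln N − 2·ln L; ΔBIC below 1e−6 counts as a tie,
broken toward fewer parameters and then a fixed family order (guessing,
unidimensional, GLC). Blocks with fewer than 10 trials are skipped with a
warning. Per-block fit seeds derive deterministically from one dataset seed.

Known limitation: with near-deterministic responders (σ ≲ 0.03) a 50-trial
block is often linearly separable after one or two noise-flipped trials, and
the GLC then attains a log likelihood near zero (σ at its floor). Its gain
over the true unidimensional model can exceed the BIC penalty, so roughly
one unidimensional block in ten is labeled procedural at that noise level.
This is a property of BIC selection over this model family at N = 50, not
an optimizer artifact (the unidimensional fits match a dense grid oracle on
such blocks). A mirror-image confusion affects biased guessers: the four
unidimensional variants jointly harvest chance spatial correlation worth
roughly two effective free parameters, so a unidimensional model narrowly
out-BICs the one-parameter biased guesser in about one block in seven. At
the noise levels of the default cohort (σ ≥ 0.08) both confusions are much
rarer and the group contrasts are unaffected.

## Strategy metrics and reporting

Families collapse to strategy labels: GLC → procedural, unidimensional →
uni_x / uni_y (assignment ignored), all guessing → random. Optimal labels
are uni_x for RB and procedural for II; uni_y on an RB task is reported
separately but never counted optimal. First-optimal-block is the smallest
training block (1–8) with the optimal label, coded 9 when the strategy
never appears during training (a censoring convention; the alternative of
excluding such participants from means is left to the consumer, since the
metrics table exposes the raw value). Total-optimal-blocks counts optimal
training blocks (0–8). Test-block labels stay in the trajectory for
proportion summaries but never enter the onset/total counts, which are
defined over training. Conditional final-block accuracy is reported only
for participants whose final-block strategy was optimal.

Learning curves aggregate per-participant block accuracies to stratum mean,
SD (ddof = 1) and SEM. Transfer is test-block minus final-training-block
accuracy per participant-task; note that grid stimuli are evenly spaced and
hence sit closer to the bound on average than Gaussian training stimuli, so
transfer carries a small negative offset even for a stationary strategy —
the no-shift null is exact only at matched stimulus difficulty. The symptom
correlation is the Pearson r between ASRS score and the unweighted mean of
a participant's training-block accuracies across blocks, tasks and
modalities (32 values in the full design), with a Fisher-z 95% CI.
Inferential mixed models over these outputs are deliberately out of scope;
the tidy CSVs are shaped for external statistics environments.

The pipeline driver chains generate → simulate → fit → metrics → report,
writing per-stage CSVs and a manifest (package version, seeds, a config
hash that excludes the output location, and SHA-256 hashes of every output
file); reruns with the same configuration are byte-identical. Heavy checks
in the test suite use deliberately scaled problem sizes — cohorts of 15 per
group over 20 seeds for group contrasts, 100 replicates for recovery
studies — chosen as the smallest sizes at which the qualitative contrasts
are stable.
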