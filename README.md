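# catstrat

Decision-bound modeling of auditory and visual category learning, built for
studying *how* learners categorize — not just how accurately. The package
targets designs that cross rule-based (RB) and information-integration (II)
category structures with auditory and visual modalities in two groups (an
ADHD-like group and a neurotypical control group), and provides everything
needed to run the analysis end to end on synthetic cohorts: stimulus-space
construction, trial-level simulation, per-block observer-model fitting, and
strategy-use metrics.

## The model

Stimuli live in a two-dimensional space (auditory: temporal × spectral
modulation of nonspeech ripples; visual: spatial frequency × orientation of
Gabor patches), mapped affinely onto a normalized unit square. Each category
is a bivariate normal; RB pairs differ on one dimension (optimal rule: a
unidimensional criterion), II pairs on both (optimal rule: a diagonal linear
bound requiring integration of the dimensions). Training sets are repaired so
exactly 10 of 200 stimuli fall on the wrong side of the optimal bound,
capping ideal-observer accuracy at 95%.

Responses are modeled with decision-bound observer models sharing the rule

    P(A | x) = Φ(h(x) / σ)

where `h` is the signed perpendicular distance from a linear bound and `σ`
absorbs perceptual and criterial noise. Per 50-trial block, nine models are
fitted by maximum likelihood: unidimensional criteria on either dimension
(r = 2 free parameters, both response assignments), the General Linear
Classifier with a free slope and intercept (r = 3, both assignments), and
guessing models (fixed p = .5, and biased variants with r = 1). The
best-fitting model per block minimizes

    BIC = r·ln N − 2·ln L,

and model families collapse to strategy labels (procedural / uni_x / uni_y /
random) from which onset and persistence of optimal-strategy use are derived
(uni_x is optimal for RB, procedural for II).

## Worked example

```python
from catstrat import (simulate_cohort, fit_dataset, compute_metrics,
                      symptom_correlation, task_distributions, optimal_boundary,
                      sample_category_set, classify_with_bound,
                      normalized_to_physical, auditory_space)

distA, distB = task_distributions("auditory", "RB")
bound = optimal_boundary(distA, distB)
crit_hz, _ = normalized_to_physical(auditory_space(), bound.criterion_x, 0.0)
stimuli = sample_category_set(distA, distB, seed=20250925)
_, ceiling = classify_with_bound(bound, stimuli)
print(f"auditory RB optimal criterion: {crit_hz:.3f} Hz; ideal-observer accuracy: {ceiling:.2f}")

trials, participants = simulate_cohort(n_per_group=4, seed=7)
fits = fit_dataset(trials, seed=8)
metrics = compute_metrics(fits, trials, participants)
print(metrics.groupby("group")[["first_optimal_block", "total_optimal_blocks"]].mean().round(2))
corr = symptom_correlation(participants, trials)
print(f"ASRS-accuracy correlation: r = {corr.r:.2f}, 95% CI [{corr.ci_low:.2f}, {corr.ci_high:.2f}]")
```

prints

```
auditory RB optimal criterion: 8.005 Hz; ideal-observer accuracy: 0.95
         first_optimal_block  total_optimal_blocks
group
ADHD                    4.44                  4.38
control                 2.56                  6.19
ASRS-accuracy correlation: r = -0.76, 95% CI [-0.95, -0.12]
```

The optimal auditory RB criterion sits at the midpoint of the category means
on temporal modulation (8.005 Hz) and classifies 95% of the fixture set
correctly — the designed ceiling. In the simulated cohort the ADHD-like
group adopts the optimal strategy about two blocks later than controls, uses
it in fewer training blocks, and ADHD-symptom (ASRS) scores correlate
negatively with overall learning accuracy.

The same stages are available from the shell:

```
catstrat generate --modality auditory --task rb --seed 20250925 --out stimuli.csv
catstrat simulate --n-per-group 15 --seed 1 --out-dir run/
catstrat fit --trials run/trials.csv --out run/fits.csv --seed 2
catstrat metrics --fits run/fits.csv --trials run/trials.csv \
    --participants run/participants.csv --out run/metrics.csv
catstrat run --out-dir run_full/        # full pipeline with manifest
```

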