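# ymaze

Analytics for Y-maze spatial-navigation experiments in immersive virtual
reality: maze geometry and gaze ray casting, trajectory metrics,
egocentric/allocentric strategy classification, gaze dwell-time analysis,
the statistical layer, and a seeded cohort simulator that makes the whole
pipeline testable against known ground truth.

## The scientific problem

In a Y-maze, a navigator learns to walk from a departure arm **A** to a
rewarded goal arm **C**. Probe trials that silently start from the third
arm **B** dissociate two wayfinding strategies: an *egocentric* navigator
repeats the learned body turn and ends in arm A, while an *allocentric*
navigator re-orients from world-anchored cues and still reaches C. Two
maze versions manipulate which cues are available:

- **landmark condition** — an equiangular maze (120°/120°/120° arm
  separations, corridors 0.66 × 1.90 m) polarized only by three distal
  landmarks (star, square, circle) hanging 8 m above the walls at 20 m;
- **geometry condition** — a landmark-free maze whose anisotropic layout
  (50°/155°/155°, corridors 0.66 × 2.30 m) itself polarizes space.

Head pose (30 Hz) and binocular gaze (120 Hz, with validity flags) are
recorded while children, young and older adults navigate. The analysis
asks where people look while they re-orient (walls, floor, or the sky
region — a 6 m sphere around the maze, split into landmark-centered
sectors), and whether age-group differences in allocentric behavior
depend on the cue type.

The central model is a binomial GLM (logit link) of each subject's
majority-allocentric outcome on age group × condition. Interactions are
summarized as probability-scale **second differences**

Δ(g₁, g₂) = [P(g₁, geometry) − P(g₁, landmark)] − [P(g₂, geometry) − P(g₂, landmark)],

with delta-method standard errors. Supporting statistics follow the
field's conventions: Fisher's exact test with conditional-MLE odds
ratios, φ and Cohen's w, Mann–Whitney / Wilcoxon rank tests with
r = z/√N, two-way ANOVA with Bonferroni simple effects, and a noncentral
chi-square power analysis. A single-predictor logistic classifier
predicts a subject's strategy (or condition) from the mean elevation of
their gaze during the orientation period of probe trials, validated by
repeated 25 % hold-out (1000 repetitions; the reported p-value is the
probability that fewer than half of held-out subjects are classified
correctly) and by leave-one-out.

Because the deposited experimental data are not bundled here, the
package ships a first-class simulator (`ymaze.simulate`) that generates
cohorts with known latent strategies, group-dependent allocentric-choice
probabilities, state-dependent gaze-elevation profiles and realistic
gaze drop-out, so every stage of the pipeline is verifiable end to end.

## Worked example

```python
from ymaze import chisq_power_n
from ymaze.simulate import default_config, simulate_cohort
from ymaze.io import specs_for
from ymaze.metrics import cohort_table
from ymaze.gaze import altitude_features
from ymaze.stats import (fit_strategy_glm, second_difference,
                         holdout_validate, loo_validate)

sim = simulate_cohort(default_config(seed=42))     # 79 simulated subjects
specs = specs_for(sim.trials)
ct = cohort_table(sim.trials, specs)
fit = fit_strategy_glm(ct)
for (age, cond), p in sorted(fit.cell_probabilities.items()):
    print(f"  {age:9s} {cond:9s} {p:.2f}")
est = second_difference(fit, ("children", "young"))
print(f"second difference children vs young: {est.delta:+.2f} "
      f"(SE {est.se:.2f}, p={est.p_value:.3g})")
print("power analysis (w=0.356, df=2):", chisq_power_n(0.356, 2), "subjects")

feats = altitude_features(sim.trials, specs).merge(ct, on="subject_id")
lm = feats[(feats.condition_x == "landmark") & feats.classifiable]
hv = holdout_validate(lm.mean_orientation_altitude, lm.strategy, seed=0)
lv = loo_validate(lm.mean_orientation_altitude, lm.strategy)
print(f"strategy from gaze altitude: hold-out {hv.overall_correct:.0%} "
      f"(p={hv.p_value:.3g}), leave-one-out {lv.overall_correct:.0%}")
```

prints

```
  children  geometry  0.79
  children  landmark  0.40
  older     geometry  0.67
  older     landmark  0.19
  young     geometry  1.00
  young     landmark  0.91
second difference children vs young: +0.29 (SE 0.19, p=0.118)
power analysis (w=0.356, df=2): 77 subjects
strategy from gaze altitude: hold-out 100% (p=0), leave-one-out 100%
```

Each cell probability is the fraction of simulated subjects in that
age × condition cell who made a majority of allocentric choices over the
three B-start probes; the second difference says how much more the
geometric polarization helps children than young adults in this
particular 79-subject draw (cohorts this small are noisy — the recovery
tests run 200 subjects per cell). The classifier separates simulated
allocentric navigators (who scan the sky sector of the facing landmark
while re-orienting) from egocentric ones (who keep wall-level gaze)
perfectly, because the simulator's gaze-elevation profiles are cleanly
separated at these defaults.

The same pipeline is scriptable from the shell:

```sh
ymaze run --config configs/demo.yaml
ymaze simulate --seed 1 --out run/ && ymaze metrics --trials run/trials.csv
```

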