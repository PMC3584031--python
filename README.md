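# distapp — distributional learning of word appearance

Children learn which things are called what far faster than direct
word–object pairing can explain, and adults can often pick the *adze*
out of a line-up of unfamiliar tools on the name alone.  One candidate
mechanism is cross-modal transfer through language statistics: words
that occur in similar linguistic contexts tend to name things of
similar visual appearance, so a learner who knows what *apples* and
*oranges* look like, and knows from text that *pear* keeps similar
company, can guess which unfamiliar object is the pear.

`distapp` is a computational test bed for that hypothesis, aimed at
computational cognitive scientists and anyone working on zero-shot
category identification.  It implements, as a library with a thin CLI:

* **Distributional word distances** — COALS-style correlation-
  transformed co-occurrence vectors: for target a and context b,
  `r = (T·n(a,b) − n(a)n(b)) / √(n(a)(T−n(a))·n(b)(T−n(b)))`, clipped
  at zero and square-rooted; word distance is `1 − Pearson(u, v)`.
  Plus an orthographic (Needleman–Wunsch) baseline.
* **Appearance distances** — each image encoded as an 11-bin Basic-
  Colour histogram and a 529-bin two-scale oriented-Basic-Image-
  Feature (oBIF) texton histogram; images compared by the
  Bhattacharyya distance `1 − Σ√(u_i v_i)`; category appearances
  (bags of 50 images) compared by a symmetrised best-match mean.
* **Decision rules** — MIRRORING (choose the word–appearance pairing
  whose pattern of distributional distances to known words best
  correlates with its pattern of appearance distances to known
  appearances), and the PROXY(k)/FOIL(k) rules that use only the k
  most/least similar known items.  Colour and texton channels are
  combined by following whichever gives the more unequivocal answer
  (larger top-minus-runner-up margin).
* **A synthetic world generator** — categories whose context-word
  profiles and colour/texture statistics are coupled through a shared
  latent variable with tunable correlation ρ, rendered as small colour
  images and embedded in filler text, so the full pipeline is testable
  end to end: at ρ = 1 the system should learn, at ρ = 0 it must fall
  to chance.
* **An experiment harness** — performance curves over known-set sizes,
  permutation baselines, bootstrap confidence intervals (words,
  images, trials), per-word and category/depth stratification,
  multi-rival curves, best-quadruple search.

See `docs/methods.md` for the full model description, parameter
conventions, and what the synthetic generator does and does not
emulate.

## Worked example

Build a coupled world, train the pipeline on its corpus and images,
and measure identification/naming as the number of already-known
appearances grows:

```python
import numpy as np
from distapp import WorldConfig, make_world
from distapp.experiment_harness import (
    ExperimentConfig, build_models, performance_curve, permutation_baseline,
)

world = make_world(WorldConfig(n_categories=24, images_per_category=30,
                               rho=1.0, seed=0))
models, sets = build_models(world, np.random.default_rng(0), n_occurrences=200)

cfg = ExperimentConfig(grid=(2, 4, 8, 16), trials_per_point=2000)
curve = performance_curve(models, cfg, np.random.default_rng(1))
print(curve[["n_known", "task", "rate"]].to_string(index=False))

mean, sd, _ = permutation_baseline(models, 10, 500, 8, np.random.default_rng(2))
print(f"permuted baseline: {100*mean:.1f}% (sd {100*sd:.1f}%)")
```

Output:

```
 n_known           task   rate
       2 identification 0.6115
       2         naming 0.6125
       4 identification 0.7650
       4         naming 0.7255
       8 identification 0.8215
       8         naming 0.7945
      16 identification 0.8415
      16         naming 0.7995
permuted baseline: 48.7% (sd 4.2%)
```

With the modalities fully coupled (ρ = 1), MIRRORING starts just above
the 50% chance line with only two known appearances and climbs as more
become available — the qualitative signature of distributional
learning of appearance.  Destroying the word-to-appearance pairing by
permutation drops the same system back to chance (48.7% here is within
Monte-Carlo error of 50% given the 4.2% spread over 10 permutations).

The same stages are scriptable from a shell:

```sh
distapp synth-world --categories 20 --rho 1.0 --seed 0 --out world/
distapp build-coals --corpus world/corpus.txt --vocab-size 64 --out model.tsv
distapp encode-images --dir world/images --out encodings.tsv
distapp run-experiment --config exp.yaml --out results/
distapp report --results results/performance_curve.tsv
```

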