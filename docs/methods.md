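# Methods

`distapp` is a computational test bed for a simple question in
cross-modal distributional learning: are the similarity structures of
*language* (which words occur in similar contexts) and of *appearance*
(which categories look alike) correlated strongly enough that a learner
could attach never-seen categories to their names using language alone?
The package implements the three measurement layers — distributional
word distances, histogram-based appearance distances, and forced-choice
decision rules — together with a synthetic world generator that makes
the whole pipeline testable without licensed corpora or downloaded
image collections.

## Distributional word distances

Each target word is represented by a vector over a context vocabulary
(the most frequent non-stoplist tokens; configurable, conventionally
14K for a full natural-language corpus, far smaller for synthetic
worlds).  A context is any token within `window = 4` positions before
or after an occurrence of the target; windows truncate at document
boundaries.  Raw windowed counts n(a,b) are converted to binary
correlation coefficients,

    r(a,b) = (T n(a,b) − n(a) n(b)) / sqrt(n(a)(T−n(a)) n(b)(T−n(b))),

where T is the grand total of window-slot pairings and n(a), n(b) the
marginals over all targets/contexts.  Negative r is treated as noise
and clipped to zero; the square root of the clipped value is stored
(a decelerating non-linearity that tempers high-frequency pairs).  The
distance between two words is `1 − Pearson(u, v)` of their vectors:
non-negative, smaller = more similar, in [0, 2].

Numerical conventions: a degenerate marginal (n = 0 or n = T) yields a
vector entry of 0; a zero-variance vector has undefined correlation and
gets the neutral distance 1 (logged).  Window weighting defaults to
flat (every in-window slot counts 1); a ramped option
(`window − d + 1`) is provided, as correlation-based co-occurrence
models in the literature differ on this point.  No dimensionality
reduction is applied.

The ORT orthographic baseline scores the optimal Needleman–Wunsch
global alignment of the two letter sequences (match +1, mismatch −1,
gap −1 by default), negated so that smaller = more similar.  It is a
deliberately non-semantic control.

## Appearance distances

An appearance — the visual model of one category — is a bag of encoded
example images (50 per category by default, mirroring the convention of
modelling a category with a set of 50 photographs).  Each image yields
two unit-sum histograms:

* **Colour (11 bins).**  Every pixel is assigned to one of the eleven
  Basic Colour terms (black, grey, white, red, orange, yellow, green,
  blue, purple, pink, brown) by nearest prototype in CIELAB, so each
  bin is a connected region of the RGB cube.  The prototype table is
  editable configuration (`read_prototype_table`), not a fitted model.
* **Textons (529 bins).**  Every pixel is classified into one of 23
  oriented Basic Image Feature (oBIF) classes at a fine scale
  (`sigma_fine = 1.0` px) and a coarse scale (`scale_ratio = 4`, so
  4.0 px); the texton is the ordered (fine, coarse) pair, indexed
  fine-major as `23·fine + coarse`.

oBIF classification takes the Gaussian 2-jet (value, first and second
derivatives, computed by derivative-of-Gaussian filtering with reflect
padding; luminance = Rec. 601 weights on [0, 1]) and picks the largest
of seven scale-normalised scores: flat `ε·s` (ε = 0.1 by default),
slope `2σ√(s_x²+s_y²)`, dark/light blob `±λ`, dark/light line
`(γ±λ)/√2`, saddle `γ`, with `λ = σ²(s_xx+s_yy)` and
`γ = σ²√((s_xx−s_yy)² + 4s_xy²)`.  The `1/√2` line normalisation is
the standard oBIF form; it makes a pure line profile (λ = γ) win as a
line rather than tying three ways with blob and saddle.  Slopes carry
8 orientation bins (45° sectors of the gradient direction centred on
0°), lines and saddles 4 bins over [0°, 180°) labelled by the
direction *along* the feature; interior sector boundaries go to the
lower bin.  All three filter parameters are configuration and are
recorded in run logs; the values above are package defaults chosen at
the conventional scale for small thumbnails, not calibrated constants.

Two images are compared by the Bhattacharyya distance
`1 − Σ√(u_i v_i)` — a cosine distance on square-rooted histograms,
which makes bin variances approximately homoscedastic so heavily
populated bins do not dominate.  Two appearances A, B are compared by
the symmetrised best-match mean

    d(A,B) = ( Σ_{a∈A} min_b d(a,b) + Σ_{b∈B} min_a d(a,b) ) / (|A|+|B|),

i.e. each image is matched to the most similar image of the other set
and matched distances are averaged over both directions.  A
one-directional reading of the definition is also defensible; the
symmetrised form was chosen so the measure is a symmetric function of
its arguments.  Note one consequence: duplicating an image in B leaves
each *directional* component unchanged but can shift the symmetrised
value slightly through reweighting (by at most `|t−d|/(n+1)` where t
is the duplicate's best-match distance).

## Trials and decision rules

A trial presents a correct word C, m rivals, and a disjoint set of
known categories with both words and appearances available.
Identification pairs the word C with each candidate appearance; naming
pairs each candidate word with the one probe appearance.  Candidate 0
is the correct pairing by bookkeeping convention only — decision rules
see scores, never labels.

* **MIRRORING** scores a pairing (w, a) by the Pearson correlation,
  across known items x, between d_word(w, x) and d_app(a, A_x).  A
  correct pairing makes the two distance patterns mirror each other.
  At least two known items are required; zero variance in either
  pattern scores 0, so degenerate trials fall to the tie-break.
* **PROXY(k)** keeps only the k known items most similar to the probe
  (distributionally similar to C for identification, appearance-similar
  to the probe appearance for naming) and picks the candidate with the
  smallest mean distance to them.
* **FOIL(k)** keeps the k *least* similar known items and picks the
  candidate with the largest mean distance to them — "whatever looks
  least like the foils".  The source description of FOIL is brief;
  this largest-mean-distance reading is the simplest consistent one.

With both channels in play, colour and texton answers are computed
separately and the channel with the larger margin — best minus
second-best candidate score, the natural multi-candidate extension of
the two-candidate rule — is followed; exactly equal margins defer to
the texton channel, and exact score ties are broken uniformly at
random by the trial's own seeded RNG.  All decisions are deterministic
given the trial spec.

## The synthetic world generator

Real experiments of this kind use a ~10^8-token corpus and ~33,000
downloaded photographs; neither is reproducible in a package.  The
generator replaces them with a latent-variable world whose two
modalities are coupled with known strength ρ ∈ [0, 1]:

* each category c draws a latent z_c ~ N(0, I_d) (d = 3 by default);
* its context profile is `softmax(κ W_lang (ρ z_c + √(1−ρ²) ε_lang))`;
* its appearance parameters — an 11-way Basic-Colour mixture plus
  stripe orientation/period/contrast and blob density — come from a
  second map of `ρ z_c + √(1−ρ²) ε_app`.

At ρ = 1 both modalities are deterministic functions of z_c; at ρ = 0
they are independent and every decision rule must collapse to chance.
The softmax concentration κ (default 2.5) sets how peaky and therefore
how separable category profiles are; defaults were chosen once so that
profiles overlap substantially (realistically noisy) while remaining
statistically distinguishable from 50 images and a few hundred word
occurrences.

Corpora embed each category word in an 8-slot window (4 before, 4
after); each slot is a context-profile draw with probability
`context_rate = 0.7`, otherwise uniform filler, and each occurrence is
emitted as its own document padded with 5 filler tokens per side.
Windows therefore never overlap and never touch the padding, so
brute-force co-occurrence counting equals windowed counting — a
deliberate simplification that makes oracle tests exact.

Images (64×64 px) are an 8-px block mosaic of prototype colours
sampled from the category's colour mixture, modulated by a sinusoidal
stripe pattern at the category's orientation (jittered per image) and
period, with Poisson-scattered dark/light blobs and a per-image
multiplicative lighting gain in [0.75, 1.25], clipped to [0, 255].
Geometry is axis-aligned in pixel coordinates, origin top-left,
row-major.

What the generator does *not* emulate: natural token frequency spectra
(no Zipfian tail, no polysemy), morphology, photographic content
(objects, viewpoint, occlusion, background clutter), or correlations
between colour and texture beyond the shared latent.  Passing tests
therefore show that the pipeline's machinery is correct and that the
decision rules extract exactly the cross-modal signal that is present
— they do not certify performance numbers on natural data.

## Statistical protocol

Performance curves draw, per trial, a fresh random known set and
probe/rival pair; rates are exact ratios of logged correct flags.
Trials per grid point default to 10^3 (the original protocol used
10^5; the count is configuration).  The permutation baseline shuffles
the word-to-appearance assignment and re-runs the full evaluation,
reporting mean and sd of the rate across permutations.  Bootstrap
intervals are percentile-based (default 500 replicates) over any
subset of three axes — words (category identities), images (each
appearance set resampled with replacement, distances recomputed,
trials replayed), trials (rows) — applied in that fixed order so the
interval is independent of how the axes are listed.  Per-word scores
sweep every rival for each word in both tasks with the maximal known
set; category means carry t-intervals and a two-sided one-sample
t-test against the grand mean (α = 0.05, no multiplicity correction);
the depth effect is an OLS fit of word rate on semantic depth with the
usual t-interval.  The best-quadruple search evaluates each sampled
4-subset under a seed derived from the run seed and the subset itself,
so sampled and exhaustive enumeration are directly comparable.

One subtlety surfaced by testing: a *fixed* finite ρ = 0 world retains
accidental correlations between its language and appearance draws, so
its conditional correct rate deviates from exactly 50% (by a few
percent at 66 categories) even though the expectation over worlds is
exactly 50%.  A pure binomial band around 50% is therefore the wrong
null for a single world.  The chance tests estimate the world-level
variance from the permutation distribution — relabelling appearances
is distribution-preserving when the modalities are independent — and
add it to the binomial term.

## Problem sizes

The shipped tests and the acceptance script run at desk scale, chosen
to keep the statistical checks well-powered: worlds of 12–66
categories with 10–50 images each, corpora of ~256 occurrences per
word, 10 permutations × 10^3 trials per task for baselines, 2×10^3 to
10^4 trials per curve point.  All sizes are configuration and scale up
directly.

## Known limitations

* The Basic-Colour partition is nearest-prototype CIELAB with a
  hand-specified prototype table, not the original published RGB-cube
  partition; bin boundaries differ in detail.
* oBIF filter scales and ε are package defaults, not values recovered
  from prior work.
* PROXY/FOIL scoring uses mean distance to the reference set; the
  source description names only the reference-set construction, so
  other aggregations (min, median) are conceivable.
* The generator's rendering is schematic; texton histograms of
  synthetic images occupy a small part of the 529-bin space compared
  with photographs.
* Bootstrap resampling over words treats per-word trial sets as
  independent, ignoring the overlap of known sets between trials.
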