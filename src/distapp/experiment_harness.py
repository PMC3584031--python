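"""Experimental protocol: curves, baselines, bootstraps, stratifications.

Runs batches of forced-choice trials against a ``ModelBundle`` and
summarises them the way the underlying study design does:

* performance curves over a grid of known-appearance-set sizes, with a
  fresh random known set and probe/rival pair per trial;
* a permutation baseline (word-to-appearance assignment shuffled and
  the whole evaluation re-run) verifying the chance level;
* percentile-bootstrap confidence intervals resampling words, images
  within appearance sets, and trials;
* per-word scores from exhaustive rival sweeps, stratified by category
  and by semantic depth (OLS slope with t-interval);
* multi-rival curves against the 1/(m+1) chance line, and a search for
  the best small set of known appearances.

Trial counts default to desk scale (10^3 per grid point); all counts
are configuration.  Every stochastic step takes an explicit RNG, and a
single run seed fans out to per-stage child seeds.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from distapp.corpus_distributional import (
    coals_transform,
    count_cooccurrence,
    distance_matrix,
    select_context_vocab,
)
from distapp.image_encoding import ObifConfig
from distapp.similarity_core import (
    SINGLE_MODALITIES,
    AppearanceSet,
    Modality,
    appearance_distance_matrix,
)
from distapp.synthetic_data import World, generate_appearance_sets, generate_corpus
from distapp.trial_engine import ModelBundle, Strategy, Task, TrialSpec, run_trial

logger = logging.getLogger(__name__)

MAX_SEED = 2**31 - 1
TASKS = (Task.IDENTIFICATION, Task.NAMING)


def child_seeds(seed: int, n: int) -> list[int]:
    """Fan a run seed out to n independent child seeds (logged)."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) % MAX_SEED for s in ss.generate_state(n)]
    logger.info("seed %d fanned out to %s", seed, seeds)
    return seeds


@dataclass(frozen=True)
class Lexicon:
    """Word metadata: category label and semantic (hypernymy) depth."""

    table: pd.DataFrame  # columns: word, category, depth

    def __post_init__(self) -> None:
        required = {"word", "category", "depth"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"lexicon needs columns {sorted(required)}")
        if self.table["word"].duplicated().any():
            raise ValueError("lexicon words must be unique")
        if (self.table["depth"] < 1).any():
            raise ValueError("semantic depth must be >= 1")


def read_lexicon(path: str | Path) -> Lexicon:
    return Lexicon(pd.read_csv(path, sep="\t"))


@dataclass(frozen=True)
class ExperimentConfig:
    """Scale and settings of one experiment run."""

    grid: tuple[int, ...] = (2, 4, 8, 16, 32, 64)
    trials_per_point: int = 1000
    strategies: tuple[Strategy, ...] = (Strategy.MIRRORING,)
    modality: Modality = Modality.BOTH
    rival_counts: tuple[int, ...] = (1,)
    k: int = 2
    n_bootstrap: int = 500
    n_permutations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if any(g < 2 for g in self.grid):
            raise ValueError("known-set sizes must be >= 2")
        for name in ("trials_per_point", "k", "n_bootstrap", "n_permutations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def default_grid(vocab_size: int) -> tuple[int, ...]:
    """Powers of two 2, 4, ... up to 512, then the maximum V - 2."""
    grid = [g for g in (2, 4, 8, 16, 32, 64, 128, 256, 512) if g <= vocab_size - 2]
    if grid and grid[-1] < vocab_size - 2:
        grid.append(vocab_size - 2)
    return tuple(grid)


def build_models(
    world: World,
    rng: np.random.Generator,
    n_occurrences: int = 256,
    window: int = 4,
    weighting: str = "flat",
    obif_config: ObifConfig | None = None,
) -> tuple[ModelBundle, dict[str, AppearanceSet]]:
    """Full pipeline from a synthetic world to trial-ready distances.

    Generates a corpus and appearance sets, fits the distributional
    model (context vocabulary = the world's most frequent non-category
    tokens), and precomputes the category-level distance matrices.
    """
    corpus = generate_corpus(world, n_occurrences, rng)
    vocab = select_context_vocab(
        corpus, world.config.context_vocab_size, stoplist=world.words
    )
    table = count_cooccurrence(corpus, vocab, window=window, weighting=weighting,
                               targets=world.words)
    model = coals_transform(table, targets=world.words)
    dist = distance_matrix(model)

    sets = generate_appearance_sets(world, rng, obif_config)
    app = {m: appearance_distance_matrix(sets, m) for m in SINGLE_MODALITIES}
    return ModelBundle.from_frames(dist, app), sets


def sample_trial_spec(
    words: Sequence[str],
    n_known: int,
    rng: np.random.Generator,
    task: Task,
    strategy: Strategy = Strategy.MIRRORING,
    modality: Modality = Modality.BOTH,
    m_rivals: int = 1,
    k: int | None = None,
) -> TrialSpec:
    """Fresh random known set and probe/rival words for one trial."""
    if n_known + m_rivals + 1 > len(words):
        raise ValueError(
            f"need {n_known + m_rivals + 1} categories, have {len(words)}"
        )
    picked = rng.choice(len(words), size=n_known + m_rivals + 1, replace=False)
    known = tuple(words[i] for i in picked[:n_known])
    correct = words[picked[n_known]]
    rivals = tuple(words[i] for i in picked[n_known + 1 :])
    if strategy in (Strategy.PROXY, Strategy.FOIL):
        k = min(k if k is not None else 2, n_known)
    else:
        k = None
    return TrialSpec(
        task=task,
        correct=correct,
        rivals=rivals,
        known=known,
        strategy=strategy,
        k=k,
        modality=modality,
        seed=int(rng.integers(MAX_SEED)),
    )


def _log_row(spec: TrialSpec, outcome) -> dict:
    return {
        "task": spec.task.value,
        "strategy": spec.strategy.value,
        "modality": spec.modality.value,
        "n_known": len(spec.known),
        "n_rivals": len(spec.rivals),
        "correct_word": spec.correct,
        "rivals": ",".join(spec.rivals),
        "chosen": outcome.chosen,
        "correct": int(outcome.correct),
        "tie": int(outcome.tie),
        "modality_used": outcome.modality_used.value,
        "seed": spec.seed,
    }


def run_trials(
    models: ModelBundle,
    n_trials: int,
    n_known: int,
    rng: np.random.Generator,
    task: Task,
    strategy: Strategy = Strategy.MIRRORING,
    modality: Modality = Modality.BOTH,
    m_rivals: int = 1,
    k: int | None = None,
) -> pd.DataFrame:
    """A batch of independently sampled trials, logged one row each."""
    rows = []
    for _ in range(n_trials):
        spec = sample_trial_spec(
            models.words, n_known, rng, task, strategy, modality, m_rivals, k
        )
        rows.append(_log_row(spec, run_trial(spec, models)))
    return pd.DataFrame(rows)


def trial_log_from_specs(specs: Sequence[TrialSpec], models: ModelBundle) -> pd.DataFrame:
    """Re-run a fixed list of trial specs (used by bootstrap replays)."""
    return pd.DataFrame([_log_row(s, run_trial(s, models)) for s in specs])


def performance_curve(
    models: ModelBundle,
    config: ExperimentConfig,
    rng: np.random.Generator,
    tasks: Sequence[Task] = TASKS,
) -> pd.DataFrame:
    """Correct rate per (n_known, task, strategy) grid point."""
    V = len(models.words)
    if max(config.grid) > V - 2:
        raise ValueError(f"grid point {max(config.grid)} too large for {V} categories")
    rows = []
    for n_known, task, strategy in itertools.product(config.grid, tasks, config.strategies):
        log = run_trials(
            models, config.trials_per_point, n_known, rng, task,
            strategy, config.modality, k=config.k,
        )
        rows.append(
            {
                "n_known": n_known,
                "task": task.value,
                "strategy": strategy.value,
                "modality": config.modality.value,
                "n_trials": len(log),
                "rate": float(log["correct"].mean()),
            }
        )
    return pd.DataFrame(rows)


def permutation_baseline(
    models: ModelBundle,
    n_perm: int,
    trials_per_perm: int,
    n_known: int,
    rng: np.random.Generator,
    tasks: Sequence[Task] = TASKS,
    strategy: Strategy = Strategy.MIRRORING,
    modality: Modality = Modality.BOTH,
    k: int | None = None,
    shuffle: bool = True,
) -> tuple[float, float, np.ndarray]:
    """Chance check: shuffle the word-to-appearance assignment and re-run.

    Each permutation relabels which appearance set belongs to which
    word, then the full trial evaluation is repeated
    (``trials_per_perm`` per task).  Returns the mean and standard
    deviation of the correct rate across permutations, plus the
    per-permutation rates.  ``shuffle=False`` keeps the identity
    assignment and recovers the unpermuted rate.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    V = len(models.words)
    rates = []
    for _ in range(n_perm):
        perm = rng.permutation(V) if shuffle else np.arange(V)
        permuted = models.permuted(perm)
        logs = [
            run_trials(permuted, trials_per_perm, n_known, rng, task, strategy, modality, k=k)
            for task in tasks
        ]
        rates.append(float(pd.concat(logs)["correct"].mean()))
    rates = np.array(rates)
    return float(rates.mean()), float(rates.std(ddof=1)), rates


def bootstrap_ci(
    log: pd.DataFrame,
    axes: Sequence[str] = ("trials",),
    n_boot: int = 500,
    level: float = 0.95,
    rng: np.random.Generator | None = None,
    image_resampler: Callable[[np.random.Generator], pd.DataFrame] | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap interval of the correct rate.

    ``axes`` is a subset of {"words", "images", "trials"}, applied in
    the fixed order images -> words -> trials regardless of how they
    are listed (so the interval does not depend on axis order):

    * images: each replicate resamples every appearance set with
      replacement and replays the logged trials — supplied by
      ``image_resampler`` (see :func:`make_image_resampler`);
    * words: category identities (the word in role C) are resampled
      with replacement and their trials pooled;
    * trials: trial rows are resampled with replacement.
    """
    if len(log) == 0:
        raise ValueError("empty trial log")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    axes_set = set(axes)
    unknown = axes_set - {"words", "images", "trials"}
    if unknown:
        raise ValueError(f"unknown bootstrap axes {sorted(unknown)}")
    if "images" in axes_set and image_resampler is None:
        raise ValueError("images axis requires an image_resampler")
    rng = rng if rng is not None else np.random.default_rng(0)

    stats_ = np.empty(n_boot)
    for b in range(n_boot):
        df = image_resampler(rng) if "images" in axes_set else log
        if "words" in axes_set:
            groups = {w: g["correct"].to_numpy() for w, g in df.groupby("correct_word")}
            names = list(groups)
            chosen = rng.choice(len(names), size=len(names), replace=True)
            values = np.concatenate([groups[names[i]] for i in chosen])
        else:
            values = df["correct"].to_numpy()
        if "trials" in axes_set:
            values = values[rng.integers(len(values), size=len(values))]
        stats_[b] = values.mean()
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats_, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def make_image_resampler(
    sets: Mapping[str, AppearanceSet],
    dist_frame: pd.DataFrame,
    specs: Sequence[TrialSpec],
) -> Callable[[np.random.Generator], pd.DataFrame]:
    """Closure for the bootstrap images axis.

    Each call resamples every appearance set with replacement,
    recomputes the appearance distance matrices, and replays the given
    trial specs against the perturbed models.
    """

    def resample(rng: np.random.Generator) -> pd.DataFrame:
        new_sets = {
            w: AppearanceSet(
                word=w,
                encodings=[s.encodings[i] for i in rng.integers(len(s), size=len(s))],
            )
            for w, s in sets.items()
        }
        app = {m: appearance_distance_matrix(new_sets, m) for m in SINGLE_MODALITIES}
        models = ModelBundle.from_frames(dist_frame, app)
        return trial_log_from_specs(specs, models)

    return resample


def per_word_scores(
    models: ModelBundle,
    rng: np.random.Generator,
    tasks: Sequence[Task] = TASKS,
    strategy: Strategy = Strategy.MIRRORING,
    modality: Modality = Modality.BOTH,
) -> pd.DataFrame:
    """Word-specific rates from exhaustive rival sweeps.

    Every word takes the role C against every other word as R, for
    both tasks, with the maximal known set (all remaining words); the
    identification and naming rates are averaged into one score per
    word.
    """
    words = models.words
    rows = []
    for c in words:
        correct_flags = []
        for task, r in itertools.product(tasks, words):
            if r == c:
                continue
            known = tuple(w for w in words if w not in (c, r))
            spec = TrialSpec(
                task=task, correct=c, rivals=(r,), known=known,
                strategy=strategy, modality=modality,
                k=None, seed=int(rng.integers(MAX_SEED)),
            )
            correct_flags.append(run_trial(spec, models).correct)
        rows.append({"word": c, "rate": float(np.mean(correct_flags))})
    return pd.DataFrame(rows)


def stratified_summary(
    per_word: pd.DataFrame, lexicon: Lexicon, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict]:
    """Category means with 95% t-intervals, plus the depth regression.

    Categories are flagged significantly above/below the grand mean by
    a two-sided one-sample t-test of their word rates against it (no
    multiplicity correction).  The depth effect is an OLS fit of
    word rate on semantic depth; the slope confidence interval is the
    usual t-interval.  Categories with fewer than two words get a mean
    but an undefined (NaN) interval, flagged ``n<2``.
    """
    df = per_word.merge(lexicon.table, on="word", how="left")
    if df["category"].isna().any():
        missing = df.loc[df["category"].isna(), "word"].tolist()
        raise ValueError(f"lexicon does not cover words: {missing[:5]}")
    grand_mean = float(df["rate"].mean())

    rows = []
    for cat, g in df.groupby("category", sort=True):
        r = g["rate"].to_numpy()
        row = {"category": cat, "n_words": len(r), "mean": float(r.mean())}
        if len(r) >= 2 and np.isclose(r.std(ddof=1), 0.0):
            # identical rates: a zero-width interval, nothing to test
            row["ci_low"] = row["ci_high"] = float(r.mean())
            row["flag"] = "ns"
        elif len(r) >= 2:
            sem = r.std(ddof=1) / np.sqrt(len(r))
            tcrit = stats.t.ppf(0.975, len(r) - 1)
            row["ci_low"] = float(r.mean() - tcrit * sem)
            row["ci_high"] = float(r.mean() + tcrit * sem)
            p = stats.ttest_1samp(r, grand_mean).pvalue
            if p < alpha:
                row["flag"] = "above" if r.mean() > grand_mean else "below"
            else:
                row["flag"] = "ns"
        else:
            row["ci_low"] = np.nan
            row["ci_high"] = np.nan
            row["flag"] = "n<2"
        rows.append(row)
    categories = pd.DataFrame(rows)

    X = sm.add_constant(df["depth"].to_numpy(dtype=float))
    fit = sm.OLS(df["rate"].to_numpy(), X).fit()
    ci = fit.conf_int(alpha=0.05)
    depth_fit = {
        "slope": float(fit.params[1]),
        "slope_ci_low": float(ci[1][0]),
        "slope_ci_high": float(ci[1][1]),
        "intercept": float(fit.params[0]),
        "grand_mean": grand_mean,
    }
    return categories, depth_fit


def multi_rival_curve(
    models: ModelBundle,
    rival_counts: Sequence[int],
    n_known: int,
    trials_per_point: int,
    rng: np.random.Generator,
    task: Task = Task.IDENTIFICATION,
    strategy: Strategy = Strategy.MIRRORING,
    modality: Modality = Modality.BOTH,
    k: int | None = None,
) -> pd.DataFrame:
    """Correct rate versus number of rivals, with the 1/(m+1) chance line."""
    rows = []
    for m in rival_counts:
        log = run_trials(
            models, trials_per_point, n_known, rng, task, strategy, modality,
            m_rivals=m, k=k,
        )
        rows.append(
            {
                "n_rivals": m,
                "rate": float(log["correct"].mean()),
                "chance": 1.0 / (m + 1),
                "n_trials": len(log),
            }
        )
    return pd.DataFrame(rows)


def quadruple_search(
    models: ModelBundle,
    n_candidates: int,
    trials_per_candidate: int,
    rng: np.random.Generator,
    modality: Modality = Modality.BOTH,
) -> tuple[tuple[str, ...], float, float]:
    """Best known-appearance quadruple among random candidates.

    Samples ``n_candidates`` distinct 4-word subsets, scores each by
    its identification rate with probe/rival pairs drawn from the
    remaining words, and returns the best quadruple, its rate, and the
    mean rate over the sampled quadruples (the random-choice baseline).

    Each quadruple is evaluated under a seed derived from the run seed
    and the quadruple itself, so a given quadruple scores identically
    whether it is reached by sampling or by exhaustive enumeration.
    """
    words = models.words
    if len(words) < 6:
        raise ValueError("need at least 6 categories")
    word_index = {w: i for i, w in enumerate(words)}
    base_seed = int(rng.integers(MAX_SEED))
    n_candidates = min(n_candidates, _n_choose_4(len(words)))

    best_quad: tuple[str, ...] = ()
    best_rate = -1.0
    rates = []
    seen: set[tuple[str, ...]] = set()
    for _ in range(n_candidates):
        while True:
            quad = tuple(sorted(words[i] for i in rng.choice(len(words), 4, replace=False)))
            if quad not in seen:
                seen.add(quad)
                break
        rate = _quadruple_rate(models, quad, trials_per_candidate, base_seed,
                               word_index, modality)
        rates.append(rate)
        if rate > best_rate:
            best_rate, best_quad = rate, quad
    return best_quad, float(best_rate), float(np.mean(rates))


def _quadruple_rate(
    models: ModelBundle,
    quad: tuple[str, ...],
    n_trials: int,
    base_seed: int,
    word_index: dict[str, int],
    modality: Modality,
) -> float:
    """Identification rate of one known-quadruple (quad-deterministic)."""
    eval_rng = np.random.default_rng([base_seed, *(word_index[w] for w in quad)])
    pool = [w for w in models.words if w not in quad]
    correct = 0
    for _ in range(n_trials):
        c, r = (pool[i] for i in eval_rng.choice(len(pool), 2, replace=False))
        spec = TrialSpec(
            task=Task.IDENTIFICATION, correct=c, rivals=(r,), known=quad,
            strategy=Strategy.MIRRORING, modality=modality,
            seed=int(eval_rng.integers(MAX_SEED)),
        )
        correct += run_trial(spec, models).correct
    return correct / n_trials


def _n_choose_4(n: int) -> int:
    return n * (n - 1) * (n - 2) * (n - 3) // 24


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic TSV export (fixed float format, no index)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
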