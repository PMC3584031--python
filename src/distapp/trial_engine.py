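"""Forced-choice identification and naming trials.

A trial presents a correct word C and m rival words or appearances,
plus a disjoint set of *known* categories whose words and appearances
are both available.  Candidate pairings are formed (identification:
word C against each candidate appearance; naming: each candidate word
against the one appearance), and a decision rule scores each pairing:

* **MIRRORING** — the Pearson correlation, across the known items x,
  between the distributional distance of the candidate word to x and
  the appearance distance of the candidate appearance to x.  A correct
  pairing makes the two distance patterns mirror each other, so its
  correlation tends to be more positive.
* **PROXY(k)** — use only the k known items most similar to the probe
  (distributionally similar to C for identification, appearance
  similar to the probe appearance for naming); candidates are scored
  by mean distance to those proxies, smallest wins ("anything that
  looks enough like the proxies is it").
* **FOIL(k)** — use the k *least* similar known items; largest mean
  distance to the foils wins ("anything very unlike the foils is it").

Colour and texton channels are scored separately; when both are in
play the channel with the more unequivocal answer — the larger margin
between its best and second-best candidate — is followed.

Candidate 0 is by convention the correct pairing; decision functions
only ever see scores, never labels, so the convention carries no
information into the decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from distapp.similarity_core import SINGLE_MODALITIES, Modality


class Task(str, Enum):
    IDENTIFICATION = "identification"
    NAMING = "naming"


class Strategy(str, Enum):
    MIRRORING = "mirroring"
    PROXY = "proxy"
    FOIL = "foil"


@dataclass
class ModelBundle:
    """Precomputed category-level distances the trial rules consume.

    ``dist`` holds distributional distances between category words;
    ``app[modality]`` holds appearance distances between the
    categories' appearance sets.  Appearance matrices are indexed by
    *appearance label*; :meth:`permuted` relabels appearances to build
    permutation baselines.
    """

    words: tuple[str, ...]
    dist: np.ndarray  # (V, V)
    app: dict[Modality, np.ndarray]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        V = len(self.words)
        if self.dist.shape != (V, V):
            raise ValueError("dist matrix shape mismatch")
        for m, a in self.app.items():
            if m not in SINGLE_MODALITIES:
                raise ValueError("appearance matrices must be single-channel")
            if a.shape != (V, V):
                raise ValueError(f"appearance matrix shape mismatch for {m}")
        self._index = {w: i for i, w in enumerate(self.words)}

    def idx(self, word: str) -> int:
        try:
            return self._index[word]
        except KeyError:
            raise KeyError(f"unknown category {word!r}") from None

    def modalities(self, modality: Modality) -> tuple[Modality, ...]:
        if modality == Modality.BOTH:
            return SINGLE_MODALITIES
        return (modality,)

    def permuted(self, perm: np.ndarray) -> "ModelBundle":
        """Reassign appearances: word i gets the appearance of perm[i]."""
        perm = np.asarray(perm)
        app = {m: a[np.ix_(perm, perm)] for m, a in self.app.items()}
        return ModelBundle(words=self.words, dist=self.dist, app=app)

    @classmethod
    def from_frames(
        cls, dist: pd.DataFrame, app: Mapping[Modality, pd.DataFrame]
    ) -> "ModelBundle":
        words = tuple(dist.index)
        return cls(
            words=words,
            dist=dist.to_numpy(),
            app={m: a.loc[list(words), list(words)].to_numpy() for m, a in app.items()},
        )


@dataclass(frozen=True)
class TrialSpec:
    """One forced-choice trial.

    ``rivals`` are the incorrect alternatives; ``known`` the categories
    whose word–appearance pairing the system already has, disjoint from
    the probe and rivals.  ``k`` applies to PROXY/FOIL only.
    """

    task: Task
    correct: str
    rivals: tuple[str, ...]
    known: tuple[str, ...]
    strategy: Strategy = Strategy.MIRRORING
    k: int | None = None
    modality: Modality = Modality.BOTH
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.rivals) < 1:
            raise ValueError("at least one rival required")
        pool = {self.correct, *self.rivals}
        if len(pool) != 1 + len(self.rivals):
            raise ValueError("correct word and rivals must be distinct")
        if pool & set(self.known):
            raise ValueError("known categories must be disjoint from the trial words")
        if self.strategy in (Strategy.PROXY, Strategy.FOIL):
            if self.k is None or self.k < 1:
                raise ValueError("PROXY/FOIL require k >= 1")
            if self.k > len(self.known):
                raise ValueError(f"k={self.k} exceeds |known|={len(self.known)}")


@dataclass(frozen=True)
class TrialOutcome:
    chosen: int
    correct: bool
    scores: dict[Modality, np.ndarray]
    modality_used: Modality
    tie: bool


def candidate_pairings(spec: TrialSpec) -> list[tuple[str, str]]:
    """(word, appearance-label) pairings, candidate 0 correct.

    Identification fixes the word and varies the appearance; naming
    fixes the appearance and varies the word.
    """
    if spec.task == Task.IDENTIFICATION:
        return [(spec.correct, spec.correct)] + [(spec.correct, r) for r in spec.rivals]
    return [(spec.correct, spec.correct)] + [(r, spec.correct) for r in spec.rivals]


def _pearson_or_zero(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    nx = float(np.sqrt(x @ x))
    ny = float(np.sqrt(y @ y))
    if nx == 0.0 or ny == 0.0:
        # degenerate pattern: no mirroring evidence either way
        return 0.0
    return float((x @ y) / (nx * ny))


def mirroring_score(
    pairing: tuple[str, str],
    known: Sequence[str],
    models: ModelBundle,
    modality: Modality,
) -> float:
    """Correlation between word-distance and appearance-distance patterns.

    Across known items x, correlates d_word(w, x) with d_app(a, A_x)
    for the candidate pairing (w, a).  Requires at least two known
    items; zero variance in either pattern scores 0.
    """
    if len(known) < 2:
        raise ValueError("mirroring requires at least 2 known categories")
    if modality == Modality.BOTH:
        raise ValueError("mirroring_score takes a single channel")
    w, a = pairing
    ki = np.array([models.idx(x) for x in known])
    dw = models.dist[models.idx(w), ki]
    da = models.app[modality][models.idx(a), ki]
    return _pearson_or_zero(dw, da)


def _strategy_scores(
    spec: TrialSpec, models: ModelBundle, modality: Modality
) -> np.ndarray:
    """Per-candidate preference scores (larger = preferred) on one channel."""
    cands = candidate_pairings(spec)
    ki = np.array([models.idx(x) for x in spec.known])
    app = models.app[modality]

    if spec.strategy == Strategy.MIRRORING:
        return np.array([mirroring_score(p, spec.known, models, modality) for p in cands])

    k = spec.k
    if spec.task == Task.IDENTIFICATION:
        # reference set from distributional similarity to the probe word
        d_ref = models.dist[models.idx(spec.correct), ki]
        order = np.argsort(d_ref, kind="stable")
        ref = ki[order[:k]] if spec.strategy == Strategy.PROXY else ki[order[-k:]]
        means = np.array([app[models.idx(a), ref].mean() for _, a in cands])
    else:
        # reference set from appearance similarity to the probe appearance
        probe_app = cands[0][1]
        d_ref = app[models.idx(probe_app), ki]
        order = np.argsort(d_ref, kind="stable")
        ref = ki[order[:k]] if spec.strategy == Strategy.PROXY else ki[order[-k:]]
        means = np.array([models.dist[models.idx(w), ref].mean() for w, _ in cands])

    # PROXY: closest to the proxies wins; FOIL: farthest from the foils wins
    return -means if spec.strategy == Strategy.PROXY else means


def decide(scores: np.ndarray, rng: np.random.Generator) -> tuple[int, bool]:
    """Argmax with exact ties broken uniformly at random."""
    scores = np.asarray(scores, dtype=float)
    best = scores.max()
    winners = np.flatnonzero(scores == best)
    if len(winners) == 1:
        return int(winners[0]), False
    return int(rng.choice(winners)), True


def decide_mirroring(
    spec: TrialSpec, scores: Sequence[float], rng: np.random.Generator | None = None
) -> int:
    """Choose the pairing with the most positive mirroring correlation."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    chosen, _ = decide(np.asarray(scores, dtype=float), rng)
    return chosen


def decide_proxy(
    spec: TrialSpec,
    models: ModelBundle,
    modality: Modality,
    rng: np.random.Generator | None = None,
) -> int:
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    spec = _with_strategy(spec, Strategy.PROXY)
    chosen, _ = decide(_strategy_scores(spec, models, modality), rng)
    return chosen


def decide_foil(
    spec: TrialSpec,
    models: ModelBundle,
    modality: Modality,
    rng: np.random.Generator | None = None,
) -> int:
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    spec = _with_strategy(spec, Strategy.FOIL)
    chosen, _ = decide(_strategy_scores(spec, models, modality), rng)
    return chosen


def _with_strategy(spec: TrialSpec, strategy: Strategy) -> TrialSpec:
    if spec.strategy == strategy:
        return spec
    return TrialSpec(
        task=spec.task,
        correct=spec.correct,
        rivals=spec.rivals,
        known=spec.known,
        strategy=strategy,
        k=spec.k,
        modality=spec.modality,
        seed=spec.seed,
    )


def combine_modalities(
    colour_scores: Sequence[float],
    texton_scores: Sequence[float],
    rng: np.random.Generator,
) -> tuple[int, Modality, bool]:
    """Follow the channel with the more unequivocal answer.

    The margin of a channel is its best score minus its second-best;
    the channel with the larger margin decides.  Equal margins fall
    back to the texton channel (the richer encoding), and any exact
    score tie within the followed channel is broken at random.
    """
    colour_scores = np.asarray(colour_scores, dtype=float)
    texton_scores = np.asarray(texton_scores, dtype=float)
    if colour_scores.shape != texton_scores.shape:
        raise ValueError("candidate counts differ between channels")

    def margin(s: np.ndarray) -> float:
        top2 = np.sort(s)[-2:]
        return float(top2[1] - top2[0])

    if margin(colour_scores) > margin(texton_scores):
        used = Modality.COLOUR
        chosen, tie = decide(colour_scores, rng)
    else:
        used = Modality.TEXTON
        chosen, tie = decide(texton_scores, rng)
    return chosen, used, tie


def run_trial(spec: TrialSpec, models: ModelBundle) -> TrialOutcome:
    """Score all candidate pairings and decide one trial.

    Deterministic given the spec (the spec seed drives tie-breaking).
    """
    rng = np.random.default_rng(spec.seed)
    scores = {m: _strategy_scores(spec, models, m) for m in models.modalities(spec.modality)}
    if spec.modality == Modality.BOTH:
        chosen, used, tie = combine_modalities(
            scores[Modality.COLOUR], scores[Modality.TEXTON], rng
        )
    else:
        used = spec.modality
        chosen, tie = decide(scores[used], rng)
    return TrialOutcome(
        chosen=chosen, correct=(chosen == 0), scores=scores, modality_used=used, tie=tie
    )
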