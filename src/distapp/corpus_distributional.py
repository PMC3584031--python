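"""COALS-style distributional word vectors and distances.

Each target word is represented by a vector over a context vocabulary
(the most frequent non-stoplist words).  A context is any token within
``window`` (default four) positions before or after an occurrence of
the target, truncated at document boundaries.  Raw windowed
co-occurrence counts are converted to binary correlation coefficients
— which compare the observed co-occurrence of a word pair with what
their independent frequencies predict — clipped at zero (negative
values are treated as noise) and square-rooted.  The distributional
distance between two words is one minus the Pearson correlation of
their vectors: non-negative, smaller = more distributionally similar.

Also provides the ORT orthographic baseline: a negated Needleman-Wunsch
global alignment score on the letter sequences of two words.
"""

from __future__ import annotations

import logging
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align

logger = logging.getLogger(__name__)

#: A corpus is a list of documents, each an ordered list of tokens.
#: Co-occurrence windows never cross document boundaries.
TokenStream = list[list[str]]

_PAREN_RE = re.compile(r"\([^()]*\)")
_TOKEN_RE = re.compile(r"[a-z0-9]+(?:['-][a-z0-9]+)*")


def normalize_tokens(
    raw_text: str,
    remove_parentheticals: bool = True,
    standardize: Callable[[str], str] | None = None,
) -> TokenStream:
    """Lowercase, strip punctuation and tokenize; one document per line.

    Parenthesised spans (stage directions, unclear utterances) are
    dropped before tokenization when ``remove_parentheticals`` is set.
    ``standardize`` is a pluggable per-token hook for morphological
    standardization (e.g. mapping plural to singular); the default is
    the identity, since synthetic corpora are pre-normalized.
    Word-internal apostrophes and hyphens survive ("jack-in-the-box").
    """
    docs: TokenStream = []
    for line in raw_text.splitlines():
        if remove_parentheticals:
            prev = None
            while prev != line:  # nested parentheses
                prev = line
                line = _PAREN_RE.sub(" ", line)
        tokens = _TOKEN_RE.findall(line.lower())
        if standardize is not None:
            tokens = [standardize(t) for t in tokens]
        if tokens:
            docs.append(tokens)
    return docs


@dataclass(frozen=True)
class ContextVocab:
    """Ordered context vocabulary with its stoplist."""

    words: tuple[str, ...]
    stoplist: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(set(self.words)) != len(self.words):
            raise ValueError("context vocabulary contains duplicates")
        overlap = set(self.words) & self.stoplist
        if overlap:
            raise ValueError(f"stoplist words in vocabulary: {sorted(overlap)[:5]}")

    def __len__(self) -> int:
        return len(self.words)

    def index(self) -> dict[str, int]:
        return {w: i for i, w in enumerate(self.words)}


def select_context_vocab(
    stream: TokenStream, size: int, stoplist: Iterable[str] = ()
) -> ContextVocab:
    """The ``size`` most frequent non-stoplist tokens.

    Frequency ties are broken lexicographically.  If fewer eligible
    tokens exist, all are returned with a warning.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    stopset = frozenset(stoplist)
    counts = Counter(t for doc in stream for t in doc if t not in stopset)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) < size:
        warnings.warn(
            f"only {len(ranked)} eligible tokens for a context vocabulary "
            f"of {size}; using all of them",
            stacklevel=2,
        )
    return ContextVocab(words=tuple(w for w, _ in ranked[:size]), stoplist=stopset)


@dataclass
class CooccurrenceTable:
    """Sparse windowed co-occurrence counts with marginals.

    ``counts[a][b]`` is the accumulated window weight of context word
    ``b`` around target ``a``.  Marginals are taken over *all* tokens
    acting as targets (``row_totals`` restricted to tracked targets),
    and ``total`` is the grand sum of window-slot pairings, as the
    correlation transform requires.
    """

    counts: dict[str, dict[str, float]]
    row_totals: dict[str, float]
    col_totals: dict[str, float]
    total: float
    vocab: ContextVocab
    window: int
    weighting: str

    def n(self, a: str, b: str) -> float:
        return self.counts.get(a, {}).get(b, 0.0)

    def n_target(self, a: str) -> float:
        return self.row_totals.get(a, 0.0)

    def n_context(self, b: str) -> float:
        return self.col_totals.get(b, 0.0)


def count_cooccurrence(
    stream: TokenStream,
    vocab: ContextVocab,
    window: int = 4,
    weighting: str = "flat",
    targets: Sequence[str] | None = None,
) -> CooccurrenceTable:
    """Windowed co-occurrence counts of context-vocab tokens around targets.

    Every token occurrence acts as a target for the marginal totals;
    per-pair rows are stored for ``targets`` (default: all words).
    ``weighting`` is ``"flat"`` (each in-window slot counts 1) or
    ``"ramped"`` (a slot at distance d counts ``window - d + 1``, so 4
    at distance 1 down to 1 at distance ``window``).  Windows truncate
    at document boundaries.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if weighting not in ("flat", "ramped"):
        raise ValueError(f"unknown weighting {weighting!r}")
    in_vocab = set(vocab.words)
    tracked = None if targets is None else set(targets)

    counts: dict[str, dict[str, float]] = {}
    row_totals: dict[str, float] = {}
    col_totals: dict[str, float] = {}
    total = 0.0

    def add(a: str, b: str, w: float) -> None:
        nonlocal total
        if b not in in_vocab:
            return
        total += w
        col_totals[b] = col_totals.get(b, 0.0) + w
        row_totals[a] = row_totals.get(a, 0.0) + w
        if tracked is None or a in tracked:
            counts.setdefault(a, {})
            counts[a][b] = counts[a].get(b, 0.0) + w

    for doc in stream:
        n = len(doc)
        for i, a in enumerate(doc):
            for d in range(1, window + 1):
                w = 1.0 if weighting == "flat" else float(window - d + 1)
                if i - d >= 0:
                    add(a, doc[i - d], w)
                if i + d < n:
                    add(a, doc[i + d], w)
    return CooccurrenceTable(
        counts=counts,
        row_totals=row_totals,
        col_totals=col_totals,
        total=total,
        vocab=vocab,
        window=window,
        weighting=weighting,
    )


@dataclass
class DistributionalModel:
    """Per-word transformed context vectors over a context vocabulary."""

    words: tuple[str, ...]
    vocab: ContextVocab
    matrix: np.ndarray  # (n_words, |vocab|), entries >= 0
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.words), len(self.vocab)):
            raise ValueError("matrix shape does not match words × vocab")
        self._index = {w: i for i, w in enumerate(self.words)}

    def vector(self, word: str) -> np.ndarray:
        try:
            return self.matrix[self._index[word]]
        except KeyError:
            raise KeyError(f"word {word!r} not in distributional model") from None


def coals_transform(
    table: CooccurrenceTable, targets: Sequence[str] | None = None
) -> DistributionalModel:
    """Correlation-transform co-occurrence counts into context vectors.

    For target a and context b with pair count n(a,b), marginals n(a),
    n(b) and grand total T::

        r = (T n(a,b) - n(a) n(b)) / sqrt(n(a) (T-n(a)) n(b) (T-n(b)))
        value = sqrt(max(r, 0))

    Degenerate marginals (n = 0 or n = T) give value 0.
    """
    T = table.total
    if T <= 0:
        raise ValueError("co-occurrence table is empty (total = 0)")
    words = tuple(targets) if targets is not None else tuple(sorted(table.counts))
    V = len(table.vocab)
    vocab_index = table.vocab.index()

    nb = np.array([table.n_context(b) for b in table.vocab.words])
    col_var = nb * (T - nb)  # zero for degenerate columns

    matrix = np.zeros((len(words), V))
    for i, a in enumerate(words):
        na = table.n_target(a)
        row_var = na * (T - na)
        if row_var <= 0:
            continue
        row = np.zeros(V)
        for b, nab in table.counts.get(a, {}).items():
            row[vocab_index[b]] = nab
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (T * row - na * nb) / np.sqrt(row_var * col_var)
        r[~np.isfinite(r)] = 0.0
        matrix[i] = np.sqrt(np.clip(r, 0.0, None))
    return DistributionalModel(words=words, vocab=table.vocab, matrix=matrix)


def _pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    """Pearson correlation, or None if either side has zero variance."""
    x = x - x.mean()
    y = y - y.mean()
    nx = float(np.sqrt(x @ x))
    ny = float(np.sqrt(y @ y))
    if nx == 0.0 or ny == 0.0:
        return None
    return float((x @ y) / (nx * ny))


def distributional_distance(model: DistributionalModel, w1: str, w2: str) -> float:
    """One minus the Pearson correlation of two context vectors (in [0, 2]).

    If either vector has zero variance the correlation is undefined and
    the distance is defined as the neutral value 1 (logged).
    """
    r = _pearson(model.vector(w1), model.vector(w2))
    if r is None:
        logger.debug("zero-variance context vector for %r or %r; distance := 1", w1, w2)
        return 1.0
    return 1.0 - r


def distance_matrix(model: DistributionalModel, words: Sequence[str] | None = None) -> pd.DataFrame:
    """Pairwise distributional distances as a labelled DataFrame."""
    words = list(words) if words is not None else list(model.words)
    X = np.stack([model.vector(w) for w in words])
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc**2).sum(axis=1))
    ok = norms > 0
    safe = np.where(ok, norms, 1.0)
    corr = (Xc / safe[:, None]) @ (Xc / safe[:, None]).T
    dist = 1.0 - corr
    # zero-variance rows: neutral distance 1 off-diagonal, 0 to self
    bad = ~ok
    if bad.any():
        dist[bad, :] = 1.0
        dist[:, bad] = 1.0
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=words, columns=words)


def orthographic_distance(
    w1: str,
    w2: str,
    match_score: float = 1.0,
    mismatch_penalty: float = -1.0,
    gap_penalty: float = -1.0,
) -> float:
    """ORT baseline: negated optimal global alignment score of two words.

    The score counts matches against mismatches, insertions and
    deletions (Needleman-Wunsch); it is negated so that smaller values
    mean more similar, matching the distance orientation of the
    distributional measure.
    """
    if not w1 or not w2:
        # optimal alignment of a word against nothing is all gaps
        return -gap_penalty * (len(w1) + len(w2))
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=match_score,
        mismatch_score=mismatch_penalty,
        open_gap_score=gap_penalty,
        extend_gap_score=gap_penalty,
    )
    return -float(aligner.score(w1, w2))


def write_model_tsv(model: DistributionalModel, path: str | Path) -> None:
    """Long-format TSV (word, context word, value), non-zero entries only."""
    with open(path, "w") as fh:
        fh.write("word\tcontext\tvalue\n")
        for i, w in enumerate(model.words):
            row = model.matrix[i]
            for j in np.nonzero(row)[0]:
                fh.write(f"{w}\t{model.vocab.words[j]}\t{row[j]:.10g}\n")


def save_model(model: DistributionalModel, path: str | Path) -> None:
    """Compact binary cache of a distributional model (.npz)."""
    np.savez_compressed(
        path,
        words=np.array(model.words),
        vocab=np.array(model.vocab.words),
        stoplist=np.array(sorted(model.vocab.stoplist)),
        matrix=model.matrix,
    )


def load_model(path: str | Path) -> DistributionalModel:
    data = np.load(path, allow_pickle=False)
    vocab = ContextVocab(
        words=tuple(str(w) for w in data["vocab"]),
        stoplist=frozenset(str(w) for w in data["stoplist"]),
    )
    return DistributionalModel(
        words=tuple(str(w) for w in data["words"]),
        vocab=vocab,
        matrix=data["matrix"],
    )
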