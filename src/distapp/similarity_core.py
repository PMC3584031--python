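"""Distances between histograms, images, and appearance sets.

Everything here is oriented as a *distance*: smaller means more
similar.  Image comparison is the Bhattacharyya distance — a cosine
distance on square-rooted unit-sum histograms, which makes bin
variances approximately homoscedastic so well-populated bins do not
dominate.  An appearance (a category's visual model) is a bag of
encoded example images; the distance between two appearances is the
symmetrised best-match mean: each image is matched to the most similar
image of the other set, and the matched distances are averaged over
both directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from distapp.image_encoding import ImageEncoding


class Modality(str, Enum):
    """Which histogram channel a comparison uses.

    ``BOTH`` is never a pairwise-distance modality: colour and texton
    answers are combined at the trial level (see
    :func:`distapp.trial_engine.combine_modalities`).
    """

    COLOUR = "colour"
    TEXTON = "texton"
    BOTH = "both"


SINGLE_MODALITIES = (Modality.COLOUR, Modality.TEXTON)


@dataclass
class AppearanceSet:
    """A category's bag of encoded example images."""

    word: str
    encodings: list[ImageEncoding]
    _sqrt_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.encodings) == 0:
            raise ValueError(f"appearance set for {self.word!r} is empty")

    def __len__(self) -> int:
        return len(self.encodings)

    def sqrt_matrix(self, modality: Modality) -> np.ndarray:
        """Stacked square-rooted histograms (n_images × n_bins), memoized.

        The cache is value-identical to recomputation; it only avoids
        repeating the square roots inside trial loops.
        """
        if modality not in self._sqrt_cache:
            if modality not in SINGLE_MODALITIES:
                raise ValueError("sqrt_matrix needs a single-channel modality")
            stack = np.stack([getattr(e, modality.value) for e in self.encodings])
            self._sqrt_cache[modality] = np.sqrt(stack)
        return self._sqrt_cache[modality]


def bhattacharyya_distance(u: np.ndarray, v: np.ndarray) -> float:
    """``1 - sum_i sqrt(u_i v_i)`` for unit-sum histograms u, v.

    Symmetric, in [0, 1], zero iff u == v, and 1 exactly when the
    supports are disjoint.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"histogram bin counts differ: {u.shape} vs {v.shape}")
    if (u < 0).any() or (v < 0).any():
        raise ValueError("histograms must be non-negative")
    d = 1.0 - float(np.sqrt(u * v).sum())
    return float(min(max(d, 0.0), 1.0))


def image_distance(enc_a: ImageEncoding, enc_b: ImageEncoding, modality: Modality) -> float:
    """Bhattacharyya distance between two images on one channel."""
    if modality == Modality.BOTH:
        raise ValueError(
            "image_distance takes a single channel; colour and texton answers "
            "are combined at the trial level (trial_engine.combine_modalities)"
        )
    return bhattacharyya_distance(
        getattr(enc_a, modality.value), getattr(enc_b, modality.value)
    )


def _cross_distances(set_a: AppearanceSet, set_b: AppearanceSet, modality: Modality) -> np.ndarray:
    """|A|×|B| matrix of pairwise image distances (one matmul)."""
    sa = set_a.sqrt_matrix(modality)
    sb = set_b.sqrt_matrix(modality)
    return np.clip(1.0 - sa @ sb.T, 0.0, 1.0)


def appearance_distance(set_a: AppearanceSet, set_b: AppearanceSet, modality: Modality) -> float:
    """Symmetrised best-match mean distance between two appearance sets.

    ``( sum_a min_b d(a,b) + sum_b min_a d(a,b) ) / (|A| + |B|)``:
    each image is matched to its most similar image in the other set
    and the matched distances averaged over both directions, so the
    measure is symmetric by construction.
    """
    if modality == Modality.BOTH:
        raise ValueError("appearance_distance takes a single channel")
    d = _cross_distances(set_a, set_b, modality)
    total = d.min(axis=1).sum() + d.min(axis=0).sum()
    return float(total / (len(set_a) + len(set_b)))


def appearance_distance_matrix(
    sets: Mapping[str, AppearanceSet] | Sequence[AppearanceSet],
    modality: Modality,
) -> pd.DataFrame:
    """Symmetric matrix of appearance distances, labelled by word."""
    if isinstance(sets, Mapping):
        items = list(sets.values())
    else:
        items = list(sets)
    words = [s.word for s in items]
    n = len(items)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = appearance_distance(items[i], items[j], modality)
    return pd.DataFrame(out, index=words, columns=words)


def write_distance_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """TSV export with row/column labels; fixed format for determinism."""
    matrix.to_csv(path, sep="\t", float_format="%.10g")


def read_distance_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
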