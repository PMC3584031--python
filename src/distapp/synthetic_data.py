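"""Synthetic worlds coupling language statistics and appearance.

Real studies of cross-modal distributional learning use a large text
corpus and downloaded photographs; neither ships with this package.
Instead a *world* of categories is drawn from a latent-variable model
in which each category c has a latent vector z_c, and

* its context-word profile phi_c is a softmax of a linear map of
  ``rho * z_c + sqrt(1 - rho^2) * (language noise)``;
* its appearance parameters theta_c — a mixture over the 11 Basic
  Colours plus stripe orientation/period/contrast and blob density —
  come from a second linear map of
  ``rho * z_c + sqrt(1 - rho^2) * (appearance noise)``.

At ``rho = 1`` both modalities are deterministic functions of z_c and
distributional similarity mirrors appearance similarity; at
``rho = 0`` they are independent and every downstream decision rule
must collapse to chance.  Corpora embed each category word in windows
of context-profile draws surrounded by filler runs (windows never
overlap, so brute-force co-occurrence counting equals windowed
counting); images are small RGB renders of colour patches, oriented
stripes and blobs with per-image jitter in phase, position and
lighting gain.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from distapp.image_encoding import (
    DEFAULT_COLOUR_PROTOTYPES,
    N_COLOUR_BINS,
    ObifConfig,
    encode_image,
)
from distapp.similarity_core import AppearanceSet


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of the latent world generator.

    ``rho`` in [0, 1] is the coupling between the language and
    appearance latents.  ``context_rate`` is the probability that a
    window slot around a category word is a context-profile draw
    rather than uniform filler.  ``concentration`` scales the softmax
    logits of both profile maps: larger values give peakier, more
    separable category profiles.  50 images per category at 64×64 px
    mirrors the convention of modelling an appearance with a set of 50
    small photographs.
    """

    n_categories: int
    latent_dim: int = 3
    rho: float = 1.0
    context_vocab_size: int = 64
    filler_vocab_size: int = 64
    context_rate: float = 0.7
    images_per_category: int = 50
    image_size: int = 64
    concentration: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        numeric = [
            self.n_categories, self.latent_dim, self.rho,
            self.context_vocab_size, self.filler_vocab_size,
            self.context_rate, self.images_per_category, self.image_size,
            self.concentration,
        ]
        if not np.isfinite(numeric).all():
            raise ValueError("WorldConfig values must be finite")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [0, 1], got {self.rho}")
        if not 0.0 <= self.context_rate <= 1.0:
            raise ValueError(f"context_rate must be in [0, 1], got {self.context_rate}")
        for name in (
            "n_categories", "latent_dim", "context_vocab_size",
            "filler_vocab_size", "images_per_category", "image_size",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")


@dataclass(frozen=True)
class Theta:
    """Appearance parameters of one category."""

    colour_mix: np.ndarray  # (11,), sums to 1
    stripe_theta: float  # orientation in [0, pi)
    stripe_period: float  # pixels
    stripe_contrast: float  # in [0, 1); 0 disables stripes
    blob_density: float  # expected blobs per pixel


@dataclass(frozen=True)
class World:
    """Latent category parameters plus the three token vocabularies."""

    config: WorldConfig
    words: tuple[str, ...]  # category words
    context_words: tuple[str, ...]
    filler_words: tuple[str, ...]
    z: np.ndarray  # (n, latent_dim) shared latents
    phi: np.ndarray  # (n, context_vocab_size), rows sum to 1
    thetas: tuple[Theta, ...]

    def index(self, category: str) -> int:
        try:
            return self.words.index(category)
        except ValueError:
            raise KeyError(f"unknown category {category!r}") from None


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def make_world(config: WorldConfig) -> World:
    """Draw a world: shared latents, context profiles, appearance params.

    Deterministic given the config (the config seed drives all draws).
    """
    rng = np.random.default_rng(config.seed)
    n, d, rho = config.n_categories, config.latent_dim, config.rho
    noise = float(np.sqrt(max(0.0, 1.0 - rho**2)))

    z = rng.standard_normal((n, d))
    # fixed random linear maps from latent space to profile logits
    w_lang = rng.standard_normal((config.context_vocab_size, d)) / np.sqrt(d)
    w_col = rng.standard_normal((N_COLOUR_BINS, d)) / np.sqrt(d)
    w_tex = rng.standard_normal((4, d)) / np.sqrt(d)

    lang_latent = rho * z + noise * rng.standard_normal((n, d))
    app_latent = rho * z + noise * rng.standard_normal((n, d))

    phi = _softmax(config.concentration * (lang_latent @ w_lang.T))
    colour_mix = _softmax(config.concentration * (app_latent @ w_col.T))

    tex = app_latent @ w_tex.T  # (n, 4)
    thetas = tuple(
        Theta(
            colour_mix=colour_mix[c],
            stripe_theta=float(np.mod(tex[c, 0] * 1.3, np.pi)),
            stripe_period=float(4.0 + 10.0 * _sigmoid(tex[c, 1])),
            stripe_contrast=float(0.6 * _sigmoid(2.0 * tex[c, 2])),
            blob_density=float(0.004 * _sigmoid(2.0 * tex[c, 3])),
        )
        for c in range(n)
    )

    width = max(3, len(str(n - 1)))
    words = tuple(f"cat{c:0{width}d}" for c in range(n))
    context_words = tuple(f"ctx{j:04d}" for j in range(config.context_vocab_size))
    filler_words = tuple(f"fil{j:04d}" for j in range(config.filler_vocab_size))
    return World(
        config=config,
        words=words,
        context_words=context_words,
        filler_words=filler_words,
        z=z,
        phi=phi,
        thetas=thetas,
    )


def generate_corpus(
    world: World, n_occurrences_per_word: int, rng: np.random.Generator
) -> list[list[str]]:
    """Token documents: one per category-word occurrence.

    Each document is ``filler*5  slot*4  word  slot*4  filler*5``; a
    slot is a draw from the category's context profile with probability
    ``context_rate``, otherwise uniform filler.  Padding keeps filler
    runs outside the ±4 window, and the per-occurrence documents mean
    co-occurrence windows cannot overlap by construction.  Document
    order is shuffled.  ``n_occurrences_per_word = 0`` yields an empty
    stream.
    """
    cfg = world.config
    docs: list[list[str]] = []
    ctx = np.asarray(world.context_words, dtype=object)
    fil = np.asarray(world.filler_words, dtype=object)
    for c, word in enumerate(world.words):
        for _ in range(n_occurrences_per_word):
            slots = []
            for _ in range(8):
                if rng.random() < cfg.context_rate:
                    slots.append(ctx[rng.choice(len(ctx), p=world.phi[c])])
                else:
                    slots.append(fil[rng.integers(len(fil))])
            pad_a = list(fil[rng.integers(len(fil), size=5)])
            pad_b = list(fil[rng.integers(len(fil), size=5)])
            docs.append(pad_a + slots[:4] + [word] + slots[4:] + pad_b)
    order = rng.permutation(len(docs))
    return [docs[i] for i in order]


def corpus_to_text(docs: list[list[str]]) -> str:
    """One document per line, whitespace-separated tokens."""
    return "\n".join(" ".join(doc) for doc in docs) + ("\n" if docs else "")


def render_image(world: World, category: str, rng: np.random.Generator) -> np.ndarray:
    """Render one RGB example image of a category.

    Background: an 8-px block mosaic of Basic-Colour prototype colours
    sampled from the category's colour mixture (blocks give the texton
    channel real structure).  Foreground: a sinusoidal stripe pattern
    at the category orientation (jittered per image) and period, and
    Poisson-scattered dark/light Gaussian blobs.  A multiplicative
    lighting gain is drawn per image and the result clipped to
    [0, 255] uint8.
    """
    c = world.index(category)
    theta = world.thetas[c]
    size = world.config.image_size
    block = 8
    nb = (size + block - 1) // block

    idx = rng.choice(N_COLOUR_BINS, size=(nb, nb), p=theta.colour_mix)
    mosaic = DEFAULT_COLOUR_PROTOTYPES[idx].astype(float)
    img = np.repeat(np.repeat(mosaic, block, axis=0), block, axis=1)[:size, :size]

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    if theta.stripe_contrast > 0:
        ang = theta.stripe_theta + rng.normal(0.0, 0.06)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        wave = np.sin(
            2.0 * np.pi * (xx * np.cos(ang) + yy * np.sin(ang)) / theta.stripe_period
            + phase
        )
        img *= (1.0 + theta.stripe_contrast * wave)[..., None]

    n_blobs = rng.poisson(theta.blob_density * size * size)
    for _ in range(n_blobs):
        cx, cy = rng.uniform(0, size, size=2)
        radius = rng.uniform(2.0, 5.0)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        bump = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * radius**2))
        img *= (1.0 + sign * 0.7 * bump)[..., None]

    gain = rng.uniform(0.75, 1.25)
    return np.clip(img * gain, 0.0, 255.0).astype(np.uint8)


def generate_appearance_sets(
    world: World,
    rng: np.random.Generator,
    obif_config: ObifConfig | None = None,
) -> dict[str, AppearanceSet]:
    """Render and encode ``images_per_category`` images per category."""
    obif_config = obif_config or ObifConfig()
    sets: dict[str, AppearanceSet] = {}
    for word in world.words:
        encodings = [
            encode_image(render_image(world, word, rng), obif_config)
            for _ in range(world.config.images_per_category)
        ]
        sets[word] = AppearanceSet(word=word, encodings=encodings)
    return sets


def save_world(world: World, directory: str | Path) -> None:
    """TSV bundle (one row per category) plus a YAML config."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = world.config
    with open(directory / "config.yaml", "w") as fh:
        yaml.safe_dump(
            {k: getattr(cfg, k) for k in cfg.__dataclass_fields__}, fh, sort_keys=True
        )
    with open(directory / "world.tsv", "w") as fh:
        z_cols = "\t".join(f"z{j}" for j in range(cfg.latent_dim))
        phi_cols = "\t".join(f"phi{j}" for j in range(cfg.context_vocab_size))
        col_cols = "\t".join(f"colour{j}" for j in range(N_COLOUR_BINS))
        fh.write(
            f"word\t{z_cols}\t{phi_cols}\t{col_cols}\t"
            "stripe_theta\tstripe_period\tstripe_contrast\tblob_density\n"
        )
        for c, word in enumerate(world.words):
            th = world.thetas[c]
            vals = (
                list(world.z[c]) + list(world.phi[c]) + list(th.colour_mix)
                + [th.stripe_theta, th.stripe_period, th.stripe_contrast, th.blob_density]
            )
            fh.write(word + "\t" + "\t".join(f"{v:.10g}" for v in vals) + "\n")


def with_seed(config: WorldConfig, seed: int) -> WorldConfig:
    """Convenience: the same world family under a different seed."""
    return replace(config, seed=seed)
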