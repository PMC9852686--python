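"""Tile classification: contract, mock test double, and a trainable model.

Three things live here.  First, the classification contract: every
classifier maps a 512x512 RGB tile to a full probability vector over the
ten diagnostic classes, with the argmax as the label and the maximum
probability as the score.  Second, a deterministic *mock* classifier that
reads the class-distinctive texture statistics of synthetic tiles to
recover their true class, and injects labelling errors at a controlled,
reproducible rate — the primary test double for the pipeline.  Third, a
compact trainable neural network (a feed-forward net over texture/pixel
features) following the study's training recipe: 25% random validation
split, random horizontal/vertical flip augmentation, early stopping on
validation loss, convergence within 50 epochs.

The active-learning loop is modelled by a :class:`TrainingStore` to which a
pathologist's corrections are appended; a retrain is due once enough
corrections accumulate.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from functools import lru_cache

import joblib
import numpy as np
from PIL import Image
from scipy import ndimage

from .hierarchy import CLASSES, DiagnosticClass
from .tiling import Tile

N_CLASSES = len(CLASSES)
#: Pixels darker than this (gray, 0-255) count as tissue for statistics.
TISSUE_GRAY_MAX = 235.0


# ---------------------------------------------------------------------------
# Texture statistics and the class signature table
# ---------------------------------------------------------------------------

def texture_statistics(image: np.ndarray, largest_component_only: bool = False) -> np.ndarray:
    """Seven summary statistics of the tissue pixels of an RGB image.

    Mean R/G/B, red-blue chroma, gray-level standard deviation, horizontal
    gradient energy, and dark-nucleus fraction, computed over non-background pixels
    (gray < 235) so the values are independent of how much empty slide the
    crop contains.  With ``largest_component_only`` the statistics are
    restricted to the largest connected tissue blob, which makes a tile
    that straddles two sections report the dominant one.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB image")
    gray = img.mean(axis=2)
    tissue = gray < TISSUE_GRAY_MAX
    if largest_component_only and tissue.any():
        labels, n = ndimage.label(tissue)
        if n > 1:
            sizes = ndimage.sum_labels(tissue, labels, index=np.arange(1, n + 1))
            tissue = labels == (int(np.argmax(sizes)) + 1)
    if tissue.mean() < 0.005:  # effectively blank
        return np.array([246.0, 246.0, 246.0, 0.0, 0.0, 0.0, 0.0])
    r = img[..., 0][tissue].mean()
    g = img[..., 1][tissue].mean()
    b = img[..., 2][tissue].mean()
    chroma = np.abs(img[..., 0] - img[..., 2])[tissue].mean()
    sd = gray[tissue].std()
    grad = np.abs(np.diff(gray, axis=1))
    grad_energy = grad[tissue[:, 1:]].mean()
    dark_fraction = 100.0 * (gray[tissue] < 120.0).mean()
    return np.array([r, g, b, chroma, sd, grad_energy, dark_fraction])


@lru_cache(maxsize=1)
def class_signatures() -> dict[DiagnosticClass, np.ndarray]:
    """Reference texture-statistic vector per class (fixed internal seed)."""
    from .synthetic import generate_class_tile

    sigs = {}
    for cls in CLASSES:
        tile = generate_class_tile(cls, size=192, seed=987_000 + cls.rank)
        sigs[cls] = texture_statistics(tile)
    return sigs


def nearest_class(stats: np.ndarray) -> DiagnosticClass:
    """Class whose signature is nearest (Euclidean) to the given statistics."""
    sigs = class_signatures()
    return min(sigs, key=lambda c: float(np.linalg.norm(stats - sigs[c])))


# ---------------------------------------------------------------------------
# Classification contract
# ---------------------------------------------------------------------------

@dataclass
class TileClassification:
    """One tile's probability vector over the ten classes.

    ``probabilities`` is ordered by hierarchy rank (see
    :data:`histotriage.hierarchy.CLASSES`); label and score are derived
    from it and validated on construction.
    """

    slide_id: str
    row0: int
    col0: int
    probabilities: np.ndarray
    label: DiagnosticClass
    score: float

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (N_CLASSES,):
            raise ValueError(f"expected {N_CLASSES} probabilities")
        if (p < -1e-12).any() or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("probabilities must be non-negative and sum to 1")
        am = CLASSES[int(np.argmax(p))]
        if am is not self.label or abs(p.max() - self.score) > 1e-9:
            raise ValueError("label/score inconsistent with probabilities")

    @classmethod
    def from_probabilities(
        cls, slide_id: str, row0: int, col0: int, probabilities: np.ndarray
    ) -> "TileClassification":
        p = np.asarray(probabilities, dtype=float)
        return cls(
            slide_id=slide_id,
            row0=row0,
            col0=col0,
            probabilities=p,
            label=CLASSES[int(np.argmax(p))],
            score=float(p.max()),
        )


def classify(tile: Tile, model) -> TileClassification:
    """Apply a classifier handle (mock or trained) to one tile."""
    px = tile.pixels
    if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] != px.shape[1]:
        raise ValueError(f"expected a square RGB tile, got shape {px.shape}")
    return model.classify(tile)


# ---------------------------------------------------------------------------
# Mock classifier
# ---------------------------------------------------------------------------

def _one_hot_probs(label: DiagnosticClass, score: float) -> np.ndarray:
    p = np.full(N_CLASSES, (1.0 - score) / (N_CLASSES - 1))
    p[CLASSES.index(label)] = score
    return p


@dataclass
class MockClassifier:
    """Deterministic test double for the trained network.

    Recovers a synthetic tile's true class from its texture statistics,
    then with probability ``error_rate`` substitutes a wrong label drawn
    from ``confusion_profile`` (default: uniform over the other classes).
    The per-tile randomness is seeded by (seed, slide_id, coordinates) so a
    given tile always receives the same classification.
    """

    error_rate: float = 0.0
    confusion_profile: dict | None = None
    seed: int = 0
    score_range: tuple[float, float] = (0.80, 0.99)

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")

    def _tile_rng(self, tile: Tile) -> np.random.Generator:
        crc = zlib.crc32(tile.slide_id.encode())
        return np.random.default_rng(
            [self.seed, tile.row0, tile.col0, crc]
        )

    def _wrong_label(
        self, true: DiagnosticClass, rng: np.random.Generator
    ) -> DiagnosticClass:
        others = [c for c in CLASSES if c is not true]
        if self.confusion_profile is None:
            return others[int(rng.integers(len(others)))]
        row = self.confusion_profile[true]
        probs = np.array([row.get(c, 0.0) for c in others], dtype=float)
        probs /= probs.sum()
        return others[int(rng.choice(len(others), p=probs))]

    def classify(self, tile: Tile) -> TileClassification:
        stats = texture_statistics(tile.pixels, largest_component_only=True)
        label = nearest_class(stats)
        rng = self._tile_rng(tile)
        if rng.random() < self.error_rate:
            label = self._wrong_label(label, rng)
        score = float(rng.uniform(*self.score_range))
        return TileClassification.from_probabilities(
            tile.slide_id, tile.row0, tile.col0, _one_hot_probs(label, score)
        )


def mock_classify(
    tile: Tile,
    error_rate: float = 0.0,
    confusion_profile: dict | None = None,
    seed: int = 0,
    score_range: tuple[float, float] = (0.80, 0.99),
) -> TileClassification:
    """Functional form of :class:`MockClassifier`."""
    return MockClassifier(error_rate, confusion_profile, seed, score_range).classify(tile)


# ---------------------------------------------------------------------------
# Training store (active-learning loop)
# ---------------------------------------------------------------------------

@dataclass
class TrainingEntry:
    image: np.ndarray
    label: DiagnosticClass
    origin: str = "initial"  # "initial" | "correction"


@dataclass
class TrainingStore:
    """The growing labelled tile set, including pathologist corrections."""

    entries: list[TrainingEntry] = field(default_factory=list)
    corrections_since_retrain: int = 0

    def add(self, image: np.ndarray, label: DiagnosticClass, origin: str = "initial") -> None:
        if origin not in ("initial", "correction"):
            raise ValueError(f"unknown origin {origin!r}")
        self.entries.append(TrainingEntry(image=image, label=label, origin=origin))
        if origin == "correction":
            self.corrections_since_retrain += 1

    def class_counts(self) -> dict[DiagnosticClass, int]:
        counts: dict[DiagnosticClass, int] = {}
        for e in self.entries:
            counts[e.label] = counts.get(e.label, 0) + 1
        return counts

    def mark_retrained(self) -> None:
        self.corrections_since_retrain = 0

    def __len__(self) -> int:
        return len(self.entries)


def record_correction(
    store: TrainingStore, tile: Tile, corrected_label: DiagnosticClass
) -> TrainingStore:
    """Append a pathologist's relabel of a misclassified tile."""
    if not isinstance(corrected_label, DiagnosticClass):
        raise ValueError(f"invalid label {corrected_label!r}")
    store.add(tile.pixels, corrected_label, origin="correction")
    return store


def retrain_due(store: TrainingStore, threshold: int) -> bool:
    """True once enough corrections have accumulated since the last retrain."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    return store.corrections_since_retrain >= threshold


DEFAULT_RETRAIN_THRESHOLD = 200


# ---------------------------------------------------------------------------
# Validation split and augmentation
# ---------------------------------------------------------------------------

def split_validation(
    store: TrainingStore, fraction: float = 0.25, seed: int = 0
) -> tuple[list[TrainingEntry], list[TrainingEntry]]:
    """Random disjoint train/validation split; |validation| = round(fraction*N)."""
    if not store.entries:
        raise ValueError("training store is empty")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n = len(store.entries)
    n_val = int(np.floor(fraction * n + 0.5))
    order = np.random.default_rng(seed).permutation(n)
    val_idx = set(order[:n_val].tolist())
    train = [store.entries[i] for i in range(n) if i not in val_idx]
    val = [store.entries[i] for i in range(n) if i in val_idx]
    return train, val


#: Flip variants: (flip vertical axis?, flip horizontal axis?)
_FLIP_VARIANTS = ((False, False), (False, True), (True, False), (True, True))


def apply_flip(image: np.ndarray, variant: int) -> np.ndarray:
    """Apply flip variant 0-3: identity, horizontal, vertical, both."""
    fv, fh = _FLIP_VARIANTS[variant]
    out = image
    if fh:
        out = out[:, ::-1]
    if fv:
        out = out[::-1, :]
    return out


def augment(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A uniformly random flip variant of a square image (label-preserving)."""
    if image.shape[0] != image.shape[1]:
        raise ValueError("expected a square image")
    return apply_flip(image, int(rng.integers(4)))


# ---------------------------------------------------------------------------
# Trainable classifier
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    validation_fraction: float = 0.25
    max_epochs: int = 50
    augmentation: frozenset[str] = frozenset({"horizontal_flip", "vertical_flip"})
    early_stopping_patience: int = 5
    min_loss_improvement: float = 1e-3
    hidden_units: int = 64
    learning_rate: float = 3e-3
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


_PIXEL_GRID = 8  # downsampled RGB map appended to the statistics


def tile_features(image: np.ndarray) -> np.ndarray:
    """Feature vector for the trainable net: texture statistics plus an
    8x8 area-averaged RGB map (flips of the image permute the map)."""
    stats = texture_statistics(image)
    small = np.asarray(
        Image.fromarray(np.asarray(image, dtype=np.uint8)).resize(
            (_PIXEL_GRID, _PIXEL_GRID), resample=Image.Resampling.BOX
        ),
        dtype=np.float64,
    )
    return np.concatenate([stats, small.ravel()])


def _allowed_variants(augmentation: frozenset[str]) -> list[int]:
    variants = [0]
    if "horizontal_flip" in augmentation:
        variants.append(1)
    if "vertical_flip" in augmentation:
        variants.append(2)
    if {"horizontal_flip", "vertical_flip"} <= augmentation:
        variants.append(3)
    return variants


@dataclass
class TrainedClassifier:
    """Handle around the fitted network; implements the classify contract."""

    mlp: object
    scaler: object
    class_ranks: np.ndarray  # model output order, as hierarchy ranks

    def predict_proba_image(self, image: np.ndarray) -> np.ndarray:
        x = self.scaler.transform(tile_features(image)[None, :])
        raw = self.mlp.predict_proba(x)[0]
        full = np.zeros(N_CLASSES)
        for j, rank in enumerate(self.class_ranks):
            full[int(rank) - 1] = raw[j]
        total = full.sum()
        return full / total if total > 0 else np.full(N_CLASSES, 1.0 / N_CLASSES)

    def classify(self, tile: Tile) -> TileClassification:
        return TileClassification.from_probabilities(
            tile.slide_id, tile.row0, tile.col0, self.predict_proba_image(tile.pixels)
        )

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "TrainedClassifier":
        return joblib.load(path)


def train(
    store: TrainingStore, config: TrainConfig | None = None
) -> tuple[TrainedClassifier, float, int]:
    """Fit the compact network with augmentation and early stopping.

    Returns ``(model, validation_accuracy, epochs_run)``.  Classes with
    fewer than 10 tiles raise a warning but are retained — rare classes are
    clinically important even when training data is thin.  Early stopping
    watches the validation log-loss with a patience window; the best
    weights seen are restored.
    """
    from sklearn.metrics import log_loss
    from sklearn.neural_network import MLPClassifier
    from sklearn.preprocessing import StandardScaler

    config = config or TrainConfig()
    counts = store.class_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 classes to train")
    for cls, n in counts.items():
        if n < 10:
            warnings.warn(
                f"class {cls.name} has only {n} tiles; retained", stacklevel=2
            )

    train_entries, val_entries = split_validation(
        store, config.validation_fraction, config.seed
    )
    if not train_entries or not val_entries:
        raise ValueError("split produced an empty partition")

    variants = _allowed_variants(config.augmentation)
    # Features of every flip variant, computed once; the per-epoch
    # augmentation then just indexes into this table.
    feats = np.stack(
        [
            np.stack([tile_features(apply_flip(e.image, v)) for v in variants])
            for e in train_entries
        ]
    )  # (n, n_variants, d)
    y = np.array([e.label.rank for e in train_entries])
    x_val = np.stack([tile_features(e.image) for e in val_entries])
    y_val = np.array([e.label.rank for e in val_entries])

    scaler = StandardScaler().fit(feats[:, 0, :])
    x_val_s = scaler.transform(x_val)
    class_ranks = np.unique(np.concatenate([y, y_val]))

    mlp = MLPClassifier(
        hidden_layer_sizes=(config.hidden_units,),
        learning_rate_init=config.learning_rate,
        random_state=config.seed,
    )
    rng = np.random.default_rng(config.seed)
    n = len(train_entries)
    best_loss = np.inf
    best_state = None
    wait = 0
    epochs_run = 0
    for epoch in range(1, config.max_epochs + 1):
        epochs_run = epoch
        choice = rng.integers(len(variants), size=n)
        x_epoch = scaler.transform(feats[np.arange(n), choice, :])
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            mlp.partial_fit(x_epoch[idx], y[idx], classes=class_ranks)
        val_loss = log_loss(y_val, mlp.predict_proba(x_val_s), labels=class_ranks)
        if val_loss < best_loss - config.min_loss_improvement:
            best_loss = val_loss
            best_state = (
                [w.copy() for w in mlp.coefs_],
                [b.copy() for b in mlp.intercepts_],
            )
            wait = 0
        else:
            wait += 1
            if wait >= config.early_stopping_patience:
                break
    if best_state is not None:
        mlp.coefs_, mlp.intercepts_ = best_state

    model = TrainedClassifier(mlp=mlp, scaler=scaler, class_ranks=class_ranks)
    val_acc = float(np.mean(mlp.predict(x_val_s) == y_val))
    store.mark_retrained()
    return model, val_acc, epochs_run
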