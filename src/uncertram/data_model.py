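"""Core records for multi-annotator ordinal image labels.

A record is one grayscale image (e.g. a chest radiograph) reviewed by a small
panel subset: each reviewer assigns an ordinal score on a 1..8 scale where 1
means high confidence the finding (ARDS) is absent, 8 high confidence it is
present, and 4/5 are equivocal.  This module holds the containers, the
annotation-table reader/writer, mean-label aggregation at the 4.5 midpoint,
per-review binarization, and pairwise inter-rater agreement (Cohen's kappa).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from sklearn.metrics import cohen_kappa_score

SCORE_LEVELS = 8
BINARY_THRESHOLD = 4.5  # midpoint of the 1..8 scale

__all__ = [
    "Annotation",
    "AnnotationSet",
    "ImageRecord",
    "LabelInfo",
    "Dataset",
    "aggregate_label",
    "ordinal_target",
    "binarize_review",
    "read_annotation_table",
    "write_annotation_table",
    "pairwise_kappa",
    "write_kappa_csv",
    "load_image",
    "preprocess_image",
]


@dataclass(frozen=True)
class Annotation:
    """One reviewer's ordinal score for one image."""

    reviewer_id: int
    score: int

    def __post_init__(self):
        if not 1 <= self.score <= SCORE_LEVELS:
            raise ValueError(f"score must be in 1..{SCORE_LEVELS}, "
                             f"got {self.score}")
        if self.reviewer_id < 1:
            raise ValueError(f"reviewer_id must be >= 1, got {self.reviewer_id}")


@dataclass
class AnnotationSet:
    """The ordered collection of reviews attached to one image."""

    image_id: str
    annotations: list[Annotation]

    def __post_init__(self):
        ids = [a.reviewer_id for a in self.annotations]
        if len(ids) != len(set(ids)):
            dup = next(r for r in ids if ids.count(r) > 1)
            raise ValueError(
                f"duplicate review by reviewer {dup} on image "
                f"{self.image_id!r}")

    @property
    def k(self) -> int:
        return len(self.annotations)

    @property
    def scores(self) -> np.ndarray:
        return np.array([a.score for a in self.annotations], dtype=float)

    @property
    def reviewer_ids(self) -> list[int]:
        return [a.reviewer_id for a in self.annotations]


@dataclass
class LabelInfo:
    """Quantities derived from an image's annotation set."""

    y: int                 # binary class, 1 = finding present (ARDS)
    mu_S: float            # mean annotation score
    ordinal_target: int    # mu_S rounded to the nearest rank in 1..8
    D: float               # image-level uncertainty (see encoding module)


@dataclass
class ImageRecord:
    image_id: str
    patient_id: str
    pixels: np.ndarray | None
    annotation_set: AnnotationSet
    label: LabelInfo | None = None


@dataclass
class Dataset:
    records: list[ImageRecord] = field(default_factory=list)
    panel_size: int = 14
    score_levels: int = SCORE_LEVELS

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def patient_ids(self) -> list[str]:
        return sorted({r.patient_id for r in self.records})


# ---------------------------------------------------------------------------
# Label aggregation
# ---------------------------------------------------------------------------

def aggregate_label(annotation_set: AnnotationSet) -> tuple[int, float]:
    """Mean-aggregate an annotation set into ``(y, mu_S)``.

    The binary label is 0 when the mean score falls below 4.5 and 1
    otherwise (a mean of exactly 4.5 is labelled positive).
    """
    if annotation_set.k == 0:
        raise ValueError("cannot aggregate an empty annotation set")
    mu = float(annotation_set.scores.mean())
    return (0 if mu < BINARY_THRESHOLD else 1), mu


def ordinal_target(annotation_set: AnnotationSet,
                   tie_break: str = "half_up") -> int:
    """Nearest-rank target for ordinal regression: round(mu_S) clamped to 1..8.

    ``tie_break`` selects behaviour at half-values: ``"half_up"`` (default,
    e.g. mean 4.5 -> 5) or ``"half_even"`` (banker's rounding).
    """
    _, mu = aggregate_label(annotation_set)
    if tie_break == "half_up":
        r = math.floor(mu + 0.5)
    elif tie_break == "half_even":
        r = round(mu)
    else:
        raise ValueError(f"unknown tie_break {tie_break!r}")
    return int(min(max(r, 1), SCORE_LEVELS))


def binarize_review(score: int) -> int:
    """Binarize one review at the 4.5 scale midpoint (<=4 -> 0, >=5 -> 1)."""
    if not 1 <= score <= SCORE_LEVELS:
        raise ValueError(f"score must be in 1..{SCORE_LEVELS}, got {score}")
    return 0 if score < BINARY_THRESHOLD else 1


# ---------------------------------------------------------------------------
# Annotation table and image IO
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ["image_id", "patient_id", "reviewer_id", "score"]


def load_image(path: Path) -> np.ndarray:
    """Load a single-channel image: 8/16-bit grayscale PNG or a .npy array."""
    path = Path(path)
    if path.suffix == ".npy":
        arr = np.load(path)
    else:
        arr = np.asarray(Image.open(path))
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a single-channel image at {path}, got "
                         f"shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite pixel values in {path}")
    return arr


def preprocess_image(pixels: np.ndarray, size: int = 512) -> np.ndarray:
    """Resize to ``size`` x ``size`` and affinely rescale to [-1024, 1024].

    This is the input contract of the pretrained chest-radiograph encoders;
    synthetic desk-scale images bypass it.
    """
    img = Image.fromarray(pixels.astype(np.float32), mode="F")
    img = img.resize((size, size), Image.BILINEAR)
    arr = np.asarray(img, dtype=np.float64)
    lo, hi = arr.min(), arr.max()
    if hi > lo:
        arr = (arr - lo) / (hi - lo)
    else:
        arr = np.zeros_like(arr)
    return arr * 2048.0 - 1024.0


def _find_image_file(image_dir: Path, image_id: str) -> Path:
    for suffix in (".png", ".npy"):
        candidate = image_dir / f"{image_id}{suffix}"
        if candidate.exists():
            return candidate
    raise FileNotFoundError(
        f"no image file for image_id {image_id!r} under {image_dir}")


def read_annotation_table(path: Path, image_dir: Path | None = None,
                          panel_size: int = 14,
                          load_pixels: bool = True) -> Dataset:
    """Read the annotation CSV and assemble one record per image.

    The CSV must have columns ``image_id,patient_id,reviewer_id,score`` with
    two-to-four rows per image in typical panels (any k >= 1 is accepted).
    When ``image_dir`` is given, every image_id must resolve to
    ``<image_id>.png`` or ``<image_id>.npy`` there.
    """
    df = pd.read_csv(path, dtype={"image_id": str, "patient_id": str})
    if df.empty and set(REQUIRED_COLUMNS).issubset(df.columns):
        return Dataset(records=[], panel_size=panel_size)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    dup = df.duplicated(subset=["image_id", "reviewer_id"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate (image_id, reviewer_id) pair: "
            f"({row['image_id']!r}, {int(row['reviewer_id'])})")
    bad = df[(df["score"] < 1) | (df["score"] > SCORE_LEVELS)]
    if len(bad):
        raise ValueError(
            f"score outside 1..{SCORE_LEVELS} for image "
            f"{bad.iloc[0]['image_id']!r}: {int(bad.iloc[0]['score'])}")
    over = df[df["reviewer_id"] > panel_size]
    if len(over):
        raise ValueError(
            f"reviewer_id {int(over.iloc[0]['reviewer_id'])} exceeds panel "
            f"size {panel_size}")

    records = []
    for image_id, group in df.groupby("image_id", sort=True):
        patients = group["patient_id"].unique()
        if len(patients) > 1:
            raise ValueError(
                f"image {image_id!r} assigned to multiple patients: "
                f"{sorted(patients)}")
        ann = AnnotationSet(image_id=str(image_id), annotations=[
            Annotation(int(r.reviewer_id), int(r.score))
            for r in group.itertuples()])
        pixels = None
        if image_dir is not None:
            file = _find_image_file(Path(image_dir), str(image_id))
            if load_pixels:
                pixels = load_image(file)
        records.append(ImageRecord(image_id=str(image_id),
                                   patient_id=str(patients[0]),
                                   pixels=pixels, annotation_set=ann))
    return Dataset(records=records, panel_size=panel_size)


def write_annotation_table(dataset: Dataset, path: Path) -> None:
    rows = [
        {"image_id": r.image_id, "patient_id": r.patient_id,
         "reviewer_id": a.reviewer_id, "score": a.score}
        for r in dataset.records for a in r.annotation_set.annotations
    ]
    pd.DataFrame(rows, columns=REQUIRED_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Inter-rater agreement
# ---------------------------------------------------------------------------

def pairwise_kappa(dataset: Dataset) -> pd.DataFrame:
    """Pairwise Cohen's kappa between reviewers on their binarized reviews.

    Entry (i, j) is computed over the images both reviewers scored; pairs
    with no shared images are NaN.  The diagonal is 1 for any reviewer with
    at least one review (self-agreement; exclude it from mean summaries).
    """
    if len(dataset) == 0:
        raise ValueError("cannot compute agreement on an empty dataset")
    m = dataset.panel_size
    by_reviewer: dict[int, dict[str, int]] = {t: {} for t in range(1, m + 1)}
    for record in dataset.records:
        for a in record.annotation_set.annotations:
            by_reviewer[a.reviewer_id][record.image_id] = binarize_review(a.score)
    kappa = np.full((m, m), np.nan)
    for i in range(1, m + 1):
        if by_reviewer[i]:
            kappa[i - 1, i - 1] = 1.0
        for j in range(i + 1, m + 1):
            shared = sorted(set(by_reviewer[i]) & set(by_reviewer[j]))
            if not shared:
                continue
            yi = [by_reviewer[i][s] for s in shared]
            yj = [by_reviewer[j][s] for s in shared]
            if yi == yj:
                k = 1.0  # perfect agreement, incl. the degenerate constant case
            else:
                k = cohen_kappa_score(yi, yj)
            kappa[i - 1, j - 1] = kappa[j - 1, i - 1] = k
    labels = list(range(1, m + 1))
    return pd.DataFrame(kappa, index=labels, columns=labels)


def write_kappa_csv(kappa: pd.DataFrame, path: Path) -> None:
    """Write the agreement matrix with reviewer-id labels, blanks for NaN."""
    kappa.to_csv(path, index_label="reviewer", na_rep="")
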