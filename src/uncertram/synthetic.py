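"""Synthetic multi-annotator image datasets with latent severity.

The generator emulates the statistical structure the method assumes without
claiming radiological realism: each patient carries a latent severity centre
in [0, 10]; each of their images jitters around it; the image itself is
background Gaussian noise plus Gaussian "opacity" blobs in two lateral lung
field regions whose intensity — and bilaterality — grow with severity (below
the class threshold blobs are mostly unilateral, above it bilateral, echoing
the bilateral-opacity hallmark of the target finding).  A panel of M
simulated reviewers scores each image on the 1..8 scale through a linear
severity-to-score map with per-reviewer bias and per-review noise, so
disagreement (and hence the uncertainty D) concentrates on ambiguous
mid-severity cases.  The severity-to-score slope spans the scale over the
severity range and aligns the class threshold u0 with the 4.5 scale midpoint,
so the binary label boundary coincides with maximal per-score ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .data_model import (Annotation, AnnotationSet, Dataset, ImageRecord,
                         aggregate_label)

__all__ = [
    "SynthConfig",
    "LatentRecord",
    "generate_dataset",
    "generate_split",
    "label_noise_rate",
    "write_dataset",
]


@dataclass
class SynthConfig:
    n_patients: int = 100
    images_per_patient: tuple[int, int] = (4, 8)
    image_size: int = 32
    panel_size: int = 14
    k_range: tuple[int, ...] = (2, 3, 4)
    severity_range: tuple[float, float] = (0.0, 10.0)
    class_threshold: float = 5.0          # u0
    patient_jitter_sd: float = 0.75
    annotator_bias_sd: float = 0.3
    annotator_noise_sd: float = 0.5
    blob_intensity_scale: float = 1.0
    background_noise_sd: float = 0.08
    seed: int = 0

    def __post_init__(self):
        if min(self.annotator_bias_sd, self.annotator_noise_sd,
               self.background_noise_sd, self.patient_jitter_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if self.panel_size < max(self.k_range):
            raise ValueError("panel_size must cover the largest k in k_range")

    @property
    def score_slope(self) -> float:
        lo, hi = self.severity_range
        return 7.0 / (hi - lo)

    def score_mean(self, u: float) -> float:
        """Noise-free severity-to-score map; u0 lands on the 4.5 midpoint."""
        lo, _ = self.severity_range
        return 1.0 + self.score_slope * (u - lo) \
            + (4.5 - (1.0 + self.score_slope * (self.class_threshold - lo)))


@dataclass
class LatentRecord:
    image_id: str
    patient_id: str
    u: float
    true_class: int


def _render_image(rng: np.random.Generator, u: float,
                  config: SynthConfig) -> np.ndarray:
    """Background noise + lateral lung-field blobs scaled by severity."""
    size = config.image_size
    img = rng.normal(0.0, config.background_noise_sd, size=(size, size))
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    lo, hi = config.severity_range
    severity = (u - lo) / (hi - lo)
    intensity = config.blob_intensity_scale * severity
    bilateral = u > config.class_threshold
    centers = [(0.5, 0.30), (0.5, 0.70)]   # left / right lung fields
    if not bilateral and rng.random() < 0.8:
        centers = [centers[rng.integers(0, 2)]]  # mostly unilateral below u0
    for cy, cx in centers:
        cy_px = cy * size + rng.normal(0, 0.05 * size)
        cx_px = cx * size + rng.normal(0, 0.05 * size)
        sigma = size * (0.10 + 0.08 * severity)
        img += intensity * np.exp(-((yy - cy_px) ** 2 + (xx - cx_px) ** 2)
                                  / (2 * sigma ** 2))
    return np.clip(img, 0.0, 2.0)


def generate_dataset(config: SynthConfig,
                     ) -> tuple[Dataset, list[LatentRecord]]:
    """Generate a dataset plus its latent-truth table, deterministically from
    ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.severity_range
    biases = rng.normal(0.0, config.annotator_bias_sd,
                        size=config.panel_size)
    records: list[ImageRecord] = []
    latent: list[LatentRecord] = []
    image_counter = 0
    for p in range(config.n_patients):
        patient_id = f"p{p:04d}"
        center = rng.uniform(lo, hi)
        n_images = int(rng.integers(config.images_per_patient[0],
                                    config.images_per_patient[1] + 1))
        for _ in range(n_images):
            u = float(np.clip(center + rng.normal(0, config.patient_jitter_sd),
                              lo, hi))
            image_id = f"img{image_counter:05d}"
            image_counter += 1
            pixels = _render_image(rng, u, config)
            k = int(rng.choice(config.k_range))
            reviewers = rng.choice(config.panel_size, size=k,
                                   replace=False) + 1
            annotations = []
            for t in sorted(int(t) for t in reviewers):
                noise = rng.normal(0, config.annotator_noise_sd)
                raw = config.score_mean(u) + biases[t - 1] + noise
                score = int(np.clip(np.floor(raw + 0.5), 1, 8))
                annotations.append(Annotation(reviewer_id=t, score=score))
            ann_set = AnnotationSet(image_id=image_id,
                                    annotations=annotations)
            records.append(ImageRecord(image_id=image_id,
                                       patient_id=patient_id,
                                       pixels=pixels,
                                       annotation_set=ann_set))
            latent.append(LatentRecord(image_id=image_id,
                                       patient_id=patient_id, u=u,
                                       true_class=int(u > config.class_threshold)))
    return (Dataset(records=records, panel_size=config.panel_size), latent)


def generate_split(config: SynthConfig, holdout_patients: int,
                   ) -> tuple[Dataset, list[LatentRecord],
                              Dataset, list[LatentRecord]]:
    """Generate patient-disjoint training and holdout datasets.

    The holdout reuses the panel (same reviewer biases) but entirely new
    patients, mirroring a temporally split cohort.
    """
    train_cfg = config
    holdout_cfg = SynthConfig(**{**config.__dict__,
                                 "n_patients": holdout_patients,
                                 "seed": config.seed + 100_003})
    train_ds, train_latent = generate_dataset(train_cfg)
    holdout_ds, holdout_latent = generate_dataset(holdout_cfg)
    for r, l in zip(holdout_ds.records, holdout_latent):
        r.patient_id = "h" + r.patient_id
        l.patient_id = "h" + l.patient_id
        r.image_id = "h" + r.image_id
        l.image_id = "h" + l.image_id
        r.annotation_set.image_id = r.image_id
    return train_ds, train_latent, holdout_ds, holdout_latent


def label_noise_rate(dataset: Dataset, latent: list[LatentRecord],
                     tau: float = 2.0) -> dict[str, float]:
    """Fraction of records whose mean-aggregated label differs from the
    latent truth, overall and per uncertainty stratum (D < tau vs D >= tau)."""
    from .encoding import uncertainty

    truth = {l.image_id: l.true_class for l in latent}
    flips, d_vals = [], []
    for r in dataset.records:
        y, _ = aggregate_label(r.annotation_set)
        flips.append(int(y != truth[r.image_id]))
        d_vals.append(uncertainty(r.annotation_set))
    flips = np.array(flips)
    d_vals = np.array(d_vals)
    clean = d_vals < tau
    out = {"overall": float(flips.mean())}
    out["clean"] = float(flips[clean].mean()) if clean.any() else float("nan")
    out["equivocal"] = (float(flips[~clean].mean()) if (~clean).any()
                        else float("nan"))
    return out


def write_dataset(dataset: Dataset, latent: list[LatentRecord],
                  out_dir: Path, image_format: str = "png") -> None:
    """Write images (16-bit grayscale PNG or .npy), annotations.csv and
    latent_truth.csv under ``out_dir``."""
    from .data_model import write_annotation_table

    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    for r in dataset.records:
        if image_format == "npy":
            np.save(img_dir / f"{r.image_id}.npy", r.pixels)
        else:
            arr = np.clip(r.pixels / 2.0, 0.0, 1.0)
            Image.fromarray((arr * 65535).astype(np.uint16)).save(
                img_dir / f"{r.image_id}.png")
    write_annotation_table(dataset, out_dir / "annotations.csv")
    pd.DataFrame([{"image_id": l.image_id, "patient_id": l.patient_id,
                   "u": l.u, "true_class": l.true_class}
                  for l in latent]).to_csv(out_dir / "latent_truth.csv",
                                           index=False)
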