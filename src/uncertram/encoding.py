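"""Privileged-information encodings and the image-level uncertainty measure.

Three protocols turn the reviews ``{(S_1, T_1), ..., (S_k, T_k)}`` attached to
an image into a fixed-length vector supplied to the privileged branch during
training only:

* **score** — the histogram of scores over the 1..8 alphabet (length 8);
* **separate** — the score histogram concatenated with a binary indicator of
  which panel members reviewed the image (length 8 + M, 22 for M = 14);
* **combine** — one slot per panel member holding that reviewer's score, 0 if
  they did not review (length M; unambiguous since scores are >= 1).

Uncertainty is ``D = mean_i g(S_i) + sigma(S_1..S_k)`` where
``g(s) = -|s - 4.5| + 3.5`` scores each rating's ambiguity (0 at the confident
extremes 1 and 8, 3 at the equivocal ratings 4 and 5) and sigma is the
population standard deviation of the scores, capturing reviewer disagreement.
The gate substitutes an all-zero vector whenever D does not exceed the
threshold tau, so confident records train the encoder on the image alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .data_model import SCORE_LEVELS, AnnotationSet, Dataset

__all__ = [
    "PrivilegedVector",
    "GateConfig",
    "encode_score",
    "encode_separate",
    "encode_combine",
    "encode",
    "encoding_length",
    "g",
    "uncertainty",
    "gate",
    "max_uncertainty",
    "enumerate_uncertainties",
]

ENCODING_METHODS = ("score", "separate", "combine")


@dataclass
class PrivilegedVector:
    values: np.ndarray
    method: str

    @property
    def length(self) -> int:
        return int(self.values.size)

    def zero_like(self) -> "PrivilegedVector":
        return PrivilegedVector(np.zeros_like(self.values), self.method)


@dataclass
class GateConfig:
    """Uncertainty threshold for supplying privileged information."""

    tau: float = 2.0

    def __post_init__(self):
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")


def _check_nonempty(annotation_set: AnnotationSet) -> None:
    if annotation_set.k == 0:
        raise ValueError(
            "cannot encode an empty annotation set (an all-zero vector is "
            "the gate's substitution, not an encoding)")


def encode_score(annotation_set: AnnotationSet) -> PrivilegedVector:
    """Score histogram: entry s counts annotations with score s."""
    _check_nonempty(annotation_set)
    values = np.zeros(SCORE_LEVELS)
    for a in annotation_set.annotations:
        values[a.score - 1] += 1
    return PrivilegedVector(values, "score")


def encode_separate(annotation_set: AnnotationSet, M: int) -> PrivilegedVector:
    """Score histogram concatenated with the reviewer-participation indicator."""
    _check_nonempty(annotation_set)
    indicator = np.zeros(M)
    for a in annotation_set.annotations:
        if a.reviewer_id > M:
            raise ValueError(f"reviewer_id {a.reviewer_id} exceeds panel "
                             f"size {M}")
        indicator[a.reviewer_id - 1] = 1.0
    values = np.concatenate([encode_score(annotation_set).values, indicator])
    return PrivilegedVector(values, "separate")


def encode_combine(annotation_set: AnnotationSet, M: int) -> PrivilegedVector:
    """Per-reviewer score slots: entry t is reviewer t's score, 0 otherwise."""
    _check_nonempty(annotation_set)
    values = np.zeros(M)
    for a in annotation_set.annotations:
        if a.reviewer_id > M:
            raise ValueError(f"reviewer_id {a.reviewer_id} exceeds panel "
                             f"size {M}")
        values[a.reviewer_id - 1] = float(a.score)
    return PrivilegedVector(values, "combine")


def encode(annotation_set: AnnotationSet, method: str,
           M: int = 14) -> PrivilegedVector:
    if method == "score":
        return encode_score(annotation_set)
    if method == "separate":
        return encode_separate(annotation_set, M)
    if method == "combine":
        return encode_combine(annotation_set, M)
    raise ValueError(f"unknown encoding method {method!r}; "
                     f"choose from {ENCODING_METHODS}")


def encoding_length(method: str, M: int = 14) -> int:
    if method == "score":
        return SCORE_LEVELS
    if method == "separate":
        return SCORE_LEVELS + M
    if method == "combine":
        return M
    raise ValueError(f"unknown encoding method {method!r}")


# ---------------------------------------------------------------------------
# Uncertainty
# ---------------------------------------------------------------------------

def g(score: int) -> float:
    """Per-score ambiguity, ``-|s - 4.5| + 3.5`` on the 1..8 scale."""
    if not 1 <= score <= SCORE_LEVELS:
        raise ValueError(f"score must be in 1..{SCORE_LEVELS}, got {score}")
    return -abs(score - 4.5) + 3.5


def uncertainty(annotation_set: AnnotationSet, ddof: int = 0) -> float:
    """Image-level uncertainty ``D = mean g(S_i) + sigma(S_1..S_k)``.

    ``ddof=0`` (default) uses the population standard deviation, which keeps
    D within roughly [0, 4] for panels of up to four reviewers; ``ddof=1``
    selects the sample convention.  D = 0 exactly when the reviews are
    unanimous at score 1 or 8.
    """
    if annotation_set.k == 0:
        raise ValueError("cannot measure uncertainty of an empty annotation set")
    scores = annotation_set.scores
    mean_g = float(np.mean([g(int(s)) for s in scores]))
    if annotation_set.k == 1:
        sigma = 0.0
    else:
        sigma = float(np.std(scores, ddof=ddof))
    return mean_g + sigma


def gate(privileged: PrivilegedVector, D: float,
         config: GateConfig) -> PrivilegedVector:
    """Pass the vector when D exceeds tau; substitute all-zeros otherwise."""
    if D < 0:
        raise ValueError(f"uncertainty must be >= 0, got {D}")
    if D > config.tau:
        return privileged
    return privileged.zero_like()


# ---------------------------------------------------------------------------
# Enumeration over the finite configuration space
# ---------------------------------------------------------------------------

def enumerate_uncertainties(k_values: tuple[int, ...] = (2, 3, 4),
                            ddof: int = 0) -> list[tuple[tuple[int, ...], float]]:
    """D for every ordered score tuple with k in ``k_values``.

    For k in {2, 3, 4} this spans the full 8^2 + 8^3 + 8^4 = 4,672
    configurations (D itself is permutation-invariant).
    """
    from .data_model import Annotation

    out = []
    for k in k_values:
        for scores in product(range(1, SCORE_LEVELS + 1), repeat=k):
            ann = AnnotationSet("enum", [Annotation(i + 1, s)
                                         for i, s in enumerate(scores)])
            out.append((scores, uncertainty(ann, ddof=ddof)))
    return out


def max_uncertainty(k_values: tuple[int, ...] = (2, 3, 4),
                    ddof: int = 0) -> float:
    """Exact maximum of D over all configurations with the given panel sizes."""
    return max(d for _, d in enumerate_uncertainties(k_values, ddof=ddof))
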