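"""Binary and continuous evaluation of segmentations against ground truth.

Positives are foreground ("cell") pixels.  With micrograph cell images the
background dominates (|TP| << |TN|), so accuracy sits close to 1 while the
Dice coefficient — blind to true negatives — is the more demanding overlap
measure.

Binary metrics from confusion counts:

    ACC = (TP + TN) / (TP + FP + TN + FN)
    DC  = 2 TP / (2 TP + FP + FN)

Continuous counterparts accept probability-valued predictions b_i against
ground truth a_i (both in [0, 1], N pixels):

    cDC  = sum(a_i b_i) / sum(a_i)                        (foreground-weighted)
    cACC = [sum(a_i b_i) + sum((1-a_i)(1-b_i))] / N

cACC reduces exactly to ACC when both inputs are binary.  A sign-corrupted
difference form of cACC circulates in print; it is available via
``literal=True`` for audit but is not a bounded agreement measure.

Note a pooling subtlety the test suite exercises: when every image
contributes the same number of evaluated pixels, the mean of per-image ACCs
equals the ACC of the pooled (summed) counts exactly; the analogous identity
does NOT hold for Dice, so a pooled DC generally differs from a per-image
averaged DC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aggregation import BinaryMask

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "accuracy",
    "dice",
    "continuous_dice",
    "continuous_accuracy",
    "per_image_summary",
    "residual_image",
    "round_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel counts TP/TN/FP/FN; foreground ("cell") is the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


@dataclass
class MetricReport:
    """Per-image metric values with their across-image mean and sample std."""

    per_image: dict[str, list[float]] = field(default_factory=dict)

    def summary(self) -> dict[str, tuple[float, float]]:
        return {k: per_image_summary(v) for k, v in self.per_image.items()}


def _as_binary_array(m) -> np.ndarray:
    a = m.values if isinstance(m, BinaryMask) else np.asarray(m)
    if not np.isin(a, (0, 1)).all():
        raise ValueError("mask must be strictly binary")
    return a.astype(np.int64)


def confusion_counts(pred, truth) -> ConfusionCounts:
    """Tally TP/TN/FP/FN between a binary prediction and binary ground truth."""
    p = _as_binary_array(pred)
    t = _as_binary_array(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    tp = int(np.sum((p == 1) & (t == 1)))
    tn = int(np.sum((p == 0) & (t == 0)))
    fp = int(np.sum((p == 1) & (t == 0)))
    fn = int(np.sum((p == 0) & (t == 1)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def accuracy(c: ConfusionCounts) -> float:
    """ACC = (TP + TN) / (TP + FP + TN + FN)."""
    if c.total == 0:
        raise ValueError("accuracy undefined: zero evaluated pixels")
    return (c.tp + c.tn) / c.total


def dice(c: ConfusionCounts) -> float:
    """DC = 2 TP / (2 TP + FP + FN); undefined with no foreground anywhere."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        raise ValueError("Dice undefined: no foreground pixels in prediction or truth")
    return 2 * c.tp / denom


def _check_unit_interval(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: truth {a.shape} vs pred {b.shape}")
    for name, x in (("truth", a), ("pred", b)):
        if not np.all(np.isfinite(x)) or x.min() < 0.0 or x.max() > 1.0:
            raise ValueError(f"{name} values must be finite and in [0, 1]")


def continuous_dice(truth, pred, variant: str = "as_printed") -> float:
    """Continuous Dice between ground truth a and probability prediction b.

    ``as_printed``: sum(a*b) / sum(a) — foreground-weighted (equals recall for
    binary inputs).  ``symmetric``: 2*sum(a*b) / (sum(a) + sum(b)), the soft
    Dice commonly used as a differentiable loss.
    """
    a = np.asarray(truth, dtype=float)
    b = np.asarray(pred, dtype=float)
    _check_unit_interval(a, b)
    sa = a.sum()
    if sa == 0:
        raise ValueError("continuous Dice undefined: ground truth has no foreground mass")
    if variant == "as_printed":
        return float((a * b).sum() / sa)
    if variant == "symmetric":
        return float(2.0 * (a * b).sum() / (sa + b.sum()))
    raise ValueError(f"unknown cDC variant {variant!r}; use 'as_printed' or 'symmetric'")


def continuous_accuracy(truth, pred, literal: bool = False) -> float:
    """Continuous accuracy between ground truth a and prediction b.

    Default: [sum(a*b) + sum((1-a)(1-b))] / N, in [0, 1], reducing exactly to
    ACC for binary inputs.  ``literal=True`` evaluates the uncorrected
    difference form [sum(a*b) - sum((1-a)(1-b))] / N, which simplifies to
    (sum(a) + sum(b) - N) / N and can be negative; kept for audit only.
    """
    a = np.asarray(truth, dtype=float)
    b = np.asarray(pred, dtype=float)
    _check_unit_interval(a, b)
    n = a.size
    if n == 0:
        raise ValueError("empty input")
    agree_fg = (a * b).sum()
    agree_bg = ((1.0 - a) * (1.0 - b)).sum()
    if literal:
        return float((agree_fg - agree_bg) / n)
    return float((agree_fg + agree_bg) / n)


def per_image_summary(per_image_values) -> tuple[float, float]:
    """Across-image mean and sample standard deviation (std 0 for one image)."""
    v = np.asarray(list(per_image_values), dtype=float)
    if v.size == 0:
        raise ValueError("no per-image values")
    if v.size == 1 or np.ptp(v) == 0.0:
        return float(v.mean()), 0.0
    return float(v.mean()), float(v.std(ddof=1))


def residual_image(pred, truth) -> np.ndarray:
    """Tri-level uint8 residual: gray = correct (TP/TN), black = FN, white = FP."""
    p = _as_binary_array(pred)
    t = _as_binary_array(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    out = np.full(p.shape, 127, dtype=np.uint8)
    out[(p == 0) & (t == 1)] = 0    # false negatives
    out[(p == 1) & (t == 0)] = 255  # false positives
    return out


def round_report(x: float, ndigits: int = 3) -> float:
    """Report-table rounding: fixed decimals, round-half-to-even."""
    return float(np.round(x, ndigits))
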