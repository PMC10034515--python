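"""Fusing per-pixel ensembles of class-membership probabilities.

An ensemble of M patch classifiers produces, for every pixel, M class
membership probabilities (CMPs) p_1..p_M that the pixel is foreground
("cell").  This module fuses them into one consensus map by four rules:

* ``mean``     - per-pixel sample mean (1/M) * sum(p_i)
* ``median``   - per-pixel sample median (robust to skewed CMP histograms)
* ``majority`` - per-pixel vote: 1 iff more members say p_i > 0.5 than p_i <= 0.5
* ``alpha``    - location parameter mu of an alpha-stable law fit to the M
  CMPs of each pixel (see :mod:`cmpens.alpha_stable`)

Probability-valued outputs are binarized at a threshold (default 0.5, with
values exactly at the threshold mapping to background).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import alpha_stable

__all__ = [
    "CMPStack",
    "ProbabilityMap",
    "BinaryMask",
    "aggregate_mean",
    "aggregate_median",
    "aggregate_majority",
    "aggregate_alpha_location",
    "binarize",
    "aggregate",
    "AGGREGATION_METHODS",
]

logger = logging.getLogger(__name__)

AGGREGATION_METHODS = ("mean", "median", "majority", "alpha")


@dataclass
class CMPStack:
    """H x W x M stack of per-pixel class-membership probabilities.

    ``values[h, w, i]`` is member i's probability that pixel (h, w) is
    foreground.  ``clip_fraction`` (optional, H x W) records the fraction of
    members whose raw value was clipped into [0, 1] by a generator.
    """

    values: np.ndarray
    member_ids: list[str] | None = None
    image_id: str = ""
    clip_fraction: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"CMPStack values must be H x W x M, got shape {self.values.shape}")
        h, w, m = self.values.shape
        if h < 1 or w < 1 or m < 1:
            raise ValueError("no members" if m < 1 else "empty image")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("CMP values must be finite")
        if self.values.min() < 0.0 or self.values.max() > 1.0:
            raise ValueError("CMP values must lie in [0, 1]")
        if self.member_ids is None:
            self.member_ids = [f"m{i:03d}" for i in range(m)]
        if len(self.member_ids) != m:
            raise ValueError("member_ids length must equal member count")

    @property
    def n_members(self) -> int:
        return self.values.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[:2]

    def subset(self, member_indices) -> "CMPStack":
        """Stack restricted to the given members (order preserved as given)."""
        idx = np.asarray(member_indices, dtype=int)
        if idx.size == 0:
            raise ValueError("no members")
        return CMPStack(
            values=self.values[:, :, idx],
            member_ids=[self.member_ids[i] for i in idx],
            image_id=self.image_id,
        )


@dataclass
class ProbabilityMap:
    """H x W consensus probability map with the method that produced it."""

    values: np.ndarray
    method: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("ProbabilityMap must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("probabilities must be finite")
        if self.values.min() < 0.0 or self.values.max() > 1.0:
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class BinaryMask:
    """H x W strictly binary mask, remembering the binarization threshold."""

    values: np.ndarray
    threshold_used: float = 0.5

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("BinaryMask must be 2-D")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("mask values must be strictly 0 or 1")
        self.values = self.values.astype(np.uint8)


def aggregate_mean(stack: CMPStack) -> ProbabilityMap:
    """Per-pixel sample mean of the member CMPs."""
    return ProbabilityMap(values=stack.values.mean(axis=2), method="mean")


def aggregate_median(stack: CMPStack) -> ProbabilityMap:
    """Per-pixel sample median (even M: midpoint of the central order statistics)."""
    return ProbabilityMap(values=np.median(stack.values, axis=2), method="median")


def aggregate_majority(stack: CMPStack) -> BinaryMask:
    """Per-pixel majority vote.

    A pixel is foreground iff strictly more members report p_i > 0.5 than
    p_i <= 0.5; exact ties vote background, and a unanimous p_i > 0.5 (the
    zero-denominator corner of the vote ratio) votes foreground.
    """
    above = (stack.values > 0.5).sum(axis=2)
    below_eq = stack.n_members - above
    return BinaryMask(values=(above > below_eq).astype(np.uint8), threshold_used=0.5)


def aggregate_alpha_location(
    stack: CMPStack,
    config: alpha_stable.FitConfig | None = None,
    min_members: int = 20,
) -> ProbabilityMap:
    """Location parameter mu of a per-pixel alpha-stable fit, clipped to [0, 1].

    Pixels whose fit fails (non-finite mu) fall back to the sample median
    with a logged warning; constant pixels return their common value.
    """
    if stack.n_members < min_members:
        raise ValueError(
            f"alpha-stable aggregation needs at least {min_members} members, "
            f"got {stack.n_members}"
        )
    cfg = config or alpha_stable.FitConfig(min_samples=min(min_members, 20))
    h, w = stack.shape
    flat = stack.values.reshape(h * w, stack.n_members)
    res = alpha_stable.fit_many(flat, cfg)
    mu = res["mu"]
    # Stable laws are continuous with full support: a fitted location outside
    # the observed sample range, or a dominant repeated value (the point mass
    # left by clipping saturated members), marks the fit as inapplicable.
    srt = np.sort(flat, axis=1)
    runs = np.diff(srt, axis=1) == 0.0
    atom_frac = (runs.sum(axis=1) + 1) / flat.shape[1]
    bad = (
        ~np.isfinite(mu)
        | (mu < srt[:, 0])
        | (mu > srt[:, -1])
        | (atom_frac > 0.4)
    )
    if bad.any():
        logger.warning(
            "alpha-stable fit failed at %d/%d pixels; falling back to median",
            int(bad.sum()), mu.size,
        )
        mu = np.where(bad, np.median(flat, axis=1), mu)
    return ProbabilityMap(values=np.clip(mu.reshape(h, w), 0.0, 1.0), method="alpha")


def binarize(prob_map: ProbabilityMap, threshold: float = 0.5) -> BinaryMask:
    """Threshold a probability map: 1 where value > threshold, else 0."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    return BinaryMask(
        values=(prob_map.values > threshold).astype(np.uint8), threshold_used=threshold
    )


def aggregate(stack: CMPStack, method: str, threshold: float = 0.5, **kwargs) -> BinaryMask:
    """Dispatch: fuse a stack by ``method`` and return the binary consensus mask."""
    if method == "mean":
        return binarize(aggregate_mean(stack), threshold)
    if method == "median":
        return binarize(aggregate_median(stack), threshold)
    if method == "alpha":
        return binarize(aggregate_alpha_location(stack, **kwargs), threshold)
    if method == "majority":
        return aggregate_majority(stack)
    raise ValueError(
        f"unknown aggregation method {method!r}; valid methods: {', '.join(AGGREGATION_METHODS)}"
    )
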