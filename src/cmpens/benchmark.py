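"""Published benchmark contingency counts for ensemble aggregation methods.

Pooled TP/TN/FP/FN pixel counts reported for eight 100-member ensembles of
patch classifiers evaluated on seven H&E micrograph test images (stride-4
grid: 62 500 evaluated pixels per 1000 x 1000 image, 437 500 in total), one
row per (ensemble recipe, aggregation method) pair.  These serve as fixture
inputs for cross-checking the metric formulas: because every test image
contributes the same pixel count, the accuracy of the pooled counts equals
the across-image mean accuracy, which is how the reported ACC column is
reproduced from the counts alone (the same identity does not hold for Dice).

Recipe keys follow :data:`cmpens.ensemble_builders.RECIPES`; method keys are
the :data:`cmpens.aggregation.AGGREGATION_METHODS` names.
"""

from __future__ import annotations

from .metrics import ConfusionCounts

__all__ = ["BENCHMARK_COUNTS", "PIXELS_PER_IMAGE", "N_TEST_IMAGES", "benchmark_counts"]

PIXELS_PER_IMAGE = 62_500  # 250 x 250 stride-4 grid per 1000 x 1000 image
N_TEST_IMAGES = 7

# (tp, tn, fp, fn), pooled over the 7 test images
_RAW: dict[tuple[str, str], tuple[int, int, int, int]] = {
    ("E_0.1pct", "mean"): (53070, 345006, 13060, 26364),
    ("E_0.1pct", "median"): (54688, 343419, 14647, 24746),
    ("E_0.1pct", "alpha"): (51328, 346449, 11617, 28106),
    ("E_0.1pct", "majority"): (54813, 343261, 14805, 24621),
    ("E_1pct", "mean"): (64352, 340931, 17135, 15082),
    ("E_1pct", "median"): (65002, 340030, 18036, 14432),
    ("E_1pct", "alpha"): (63186, 342245, 15821, 16248),
    ("E_1pct", "majority"): (65121, 339891, 18175, 14313),
    ("E_10pct", "mean"): (65777, 340942, 17124, 13657),
    ("E_10pct", "median"): (66038, 340651, 17415, 13396),
    ("E_10pct", "alpha"): (65059, 341723, 16343, 14375),
    ("E_10pct", "majority"): (66107, 340553, 17513, 13327),
    ("E_0.1pct_pru", "mean"): (53502, 344567, 13499, 25932),
    ("E_0.1pct_pru", "median"): (55126, 343027, 15039, 24308),
    ("E_0.1pct_pru", "alpha"): (51774, 346081, 11985, 27660),
    ("E_0.1pct_pru", "majority"): (55126, 343027, 15039, 24308),
    ("E_1pct_pru", "mean"): (64737, 340934, 17132, 14697),
    ("E_1pct_pru", "median"): (65307, 339963, 18103, 14127),
    ("E_1pct_pru", "alpha"): (63536, 342242, 15824, 15898),
    ("E_1pct_pru", "majority"): (65307, 339963, 18103, 14127),
    ("E_10pct_pru", "mean"): (65718, 341135, 16931, 13716),
    ("E_10pct_pru", "median"): (65961, 340781, 17285, 13473),
    ("E_10pct_pru", "alpha"): (64963, 341967, 16099, 14471),
    ("E_10pct_pru", "majority"): (65961, 340781, 17285, 13473),
    ("E_Ntr", "mean"): (65421, 342518, 15548, 14013),
    ("E_Ntr", "median"): (66012, 341807, 16259, 13422),
    ("E_Ntr", "alpha"): (63896, 343992, 14074, 15538),
    ("E_Ntr", "majority"): (66111, 341669, 16397, 13323),
    ("E_Ntr_80pru", "mean"): (65371, 342453, 15613, 14063),
    ("E_Ntr_80pru", "median"): (65937, 341805, 16261, 13497),
    ("E_Ntr_80pru", "alpha"): (63611, 344017, 14049, 15823),
    ("E_Ntr_80pru", "majority"): (66029, 341700, 16366, 13405),
}

BENCHMARK_COUNTS: dict[tuple[str, str], ConfusionCounts] = {
    key: ConfusionCounts(*vals) for key, vals in _RAW.items()
}


def benchmark_counts(recipe: str, method: str) -> ConfusionCounts:
    """Pooled counts for one (recipe, aggregation method) pair."""
    try:
        return BENCHMARK_COUNTS[(recipe, method)]
    except KeyError:
        raise KeyError(
            f"no benchmark counts for ({recipe!r}, {method!r}); recipes: "
            f"{sorted({k for k, _ in BENCHMARK_COUNTS})}, methods: "
            f"{sorted({m for _, m in BENCHMARK_COUNTS})}"
        ) from None
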