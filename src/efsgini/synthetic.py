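"""Synthetic fixture datasets with planted structure.

:func:`make_synthetic` emulates the regime the pipeline targets — many
features, few samples — by planting three kinds of features:

* *informative*: per class c, values ~ Normal(mu_{c,f}, 1) where the class
  means are a seeded permutation of equally spaced levels scaled by
  ``effect_size`` (the permutation decorrelates informative features from
  one another so only genuine copies trip the redundancy filter);
* *redundant*: an affine transform of an informative source (slope may be
  negative) plus tiny Gaussian noise, so Spearman correlation with the
  source is ~1 in magnitude;
* *noise*: i.i.d. Normal(0, noise_sd), independent of the class.

:func:`make_worked_example` returns a fixed tiny 12 x 8 two-class dataset
together with expected intermediate values precomputed with independent
oracle code, serving as a regression anchor for every pipeline stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .data import DataError, Dataset

__all__ = ["GroundTruth", "make_synthetic", "make_worked_example"]


@dataclass
class GroundTruth:
    """What was planted: ids by kind plus the class-mean matrix."""

    informative_ids: list[str]
    redundant_map: dict[str, tuple[str, float, float]]  # id -> (source, slope, intercept)
    noise_ids: list[str]
    class_means: dict[str, list[float]]  # informative id -> per-class mean

    @property
    def redundant_ids(self) -> list[str]:
        return list(self.redundant_map)

    def to_json_dict(self) -> dict:
        return {
            "informative_ids": self.informative_ids,
            "redundant_map": {
                k: {"source": s, "slope": a, "intercept": b}
                for k, (s, a, b) in self.redundant_map.items()
            },
            "noise_ids": self.noise_ids,
            "class_means": self.class_means,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)


def make_synthetic(
    n_samples: int = 200,
    n_features: int = 2000,
    n_informative: int = 10,
    n_redundant_per_informative: int = 1,
    n_classes: int = 4,
    effect_size: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[Dataset, GroundTruth]:
    """Generate a labeled matrix with planted informative/redundant/noise features.

    Classes are balanced up to remainder (samples are assigned round-robin).
    Redundant copies use a random slope in +-[0.5, 2], a random intercept,
    and additive Normal(0, 0.1) noise — small against the source's spread so
    |Spearman| with the source stays >= 0.99.  Deterministic per seed.
    """
    n_planted = n_informative * (1 + n_redundant_per_informative)
    if n_planted > n_features:
        raise DataError(
            f"{n_planted} planted features exceed n_features={n_features}"
        )
    if n_classes < 2:
        raise DataError("need at least 2 classes")
    if n_samples < 2 * n_classes:
        raise DataError("need at least 2 samples per class")
    rng = np.random.default_rng(seed)

    labels = [f"c{i}" for i in range(n_classes)]
    y = np.array([labels[i % n_classes] for i in range(n_samples)], dtype=object)
    class_idx = np.array([i % n_classes for i in range(n_samples)])

    inf_ids = [f"inf{j:03d}" for j in range(n_informative)]
    red_ids, red_map = [], {}
    class_means: dict[str, list[float]] = {}

    cols = []
    centered = np.arange(n_classes) - (n_classes - 1) / 2.0
    for j, fid in enumerate(inf_ids):
        perm = rng.permutation(n_classes)
        levels = centered[perm] * effect_size
        col = levels[class_idx] + rng.normal(0.0, 1.0, n_samples)
        cols.append(col)
        class_means[fid] = [float(v) for v in levels]
    for j, src_id in enumerate(inf_ids):
        src = cols[j]
        for r in range(n_redundant_per_informative):
            slope = float(rng.uniform(0.5, 2.0) * rng.choice([-1.0, 1.0]))
            intercept = float(rng.normal(0.0, 1.0))
            rid = f"red{j:03d}_{r}"
            red_ids.append(rid)
            red_map[rid] = (src_id, slope, intercept)
            cols.append(slope * src + intercept + rng.normal(0.0, 0.1, n_samples))
    n_noise = n_features - n_planted
    noise_ids = [f"noise{j:04d}" for j in range(n_noise)]
    if n_noise:
        cols.append(rng.normal(0.0, noise_sd, size=(n_samples, n_noise)))
        X = np.column_stack(cols)
    else:
        X = np.column_stack(cols)

    feature_ids = inf_ids + red_ids + noise_ids
    sample_ids = [f"s{i:04d}" for i in range(n_samples)]
    ds = Dataset(X, y, feature_ids, sample_ids)
    ds.require_min_class_size(2)
    truth = GroundTruth(inf_ids, red_map, noise_ids, class_means)
    return ds, truth


# ---------------------------------------------------------------------------
# Fixed worked example
# ---------------------------------------------------------------------------

# 12 samples (A/B alternating), 8 features:
#   g1 strong separator, g2 = 2*g1 + 1 (redundant copy), g3 moderate signal,
#   g4..g8 class-independent noise (fixed draws, frozen below).
_WE_Y = ["A", "B"] * 6
_WE_COLUMNS = {
    "g1": [0.8, 2.9, 1.1, 3.2, 0.9, 3.1, 1.2, 2.8, 1.0, 3.0, 0.7, 3.3],
    "g2": [2.6, 6.8, 3.2, 7.4, 2.8, 7.2, 3.4, 6.6, 3.0, 7.0, 2.4, 7.6],
    "g3": [1.4, 2.2, 0.6, 1.3, 1.9, 2.5, 1.1, 1.8, 0.8, 2.0, 1.6, 1.0],
    "g4": [-0.8, 1.32, 0.32, 0.6, -0.26, -0.01, 1.09, -1.26, -0.25, 1.02, -0.16, 0.06],
    "g5": [1.26, 1.17, 0.65, 0.21, -0.12, 0.35, 0.62, 0.38, 0.88, 0.71, 0.14, 0.52],
    "g6": [-1.09, 0.27, -2.09, 0.49, -0.4, -1.3, -0.72, 0.24, -0.35, 0.95, -0.78, -1.62],
    "g7": [-2.04, -0.94, 1.53, -1.22, -0.22, 0.9, 1.03, -1.47, -0.7, -0.96, -0.24, -0.33],
    "g8": [-0.15, 0.15, -0.84, -0.05, -1.0, 0.55, 0.42, -0.35, -0.19, -0.28, -0.71, 1.31],
}

# Expected intermediates, precomputed with independent oracle code
# (rank-correlation and one-way ANOVA from scipy, plug-in MI from a
# contingency table, exhaustive split enumeration for the tree) and frozen.
_WE_EXPECTED: dict = {}


def _worked_example_expected() -> dict:
    from ._worked_expected import EXPECTED

    return EXPECTED


def make_worked_example() -> tuple[Dataset, dict]:
    """A fixed tiny dataset plus oracle-computed expected intermediates.

    The expected dict holds: the Spearman correlation matrix, per-feature F
    statistics and MI scores, the CART tree structure and Gini importances on
    the toy candidate pool, and the GINI-Select outcome for fixed subsets
    S1..S4 with k=3.  Byte-stable across runs.
    """
    fids = list(_WE_COLUMNS)
    X = np.column_stack([_WE_COLUMNS[f] for f in fids])
    ds = Dataset(X, np.array(_WE_Y, dtype=object), fids,
                 [f"s{i:02d}" for i in range(len(_WE_Y))])
    return ds, _worked_example_expected()
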