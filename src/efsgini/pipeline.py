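"""End-to-end orchestration of the three-stage EFS-GINI flow.

Order of operations (leakage-safe default):

1. stratified 60:40 train/test split;
2. Spearman redundancy filter (|rho| >= threshold, default 0.9) fitted on the
   training partition, applied to both;
3. standardization fitted on train, applied to both;
4. stage 1 — ANOVA F-test shortlists ``stage1_pool`` features;
5. stage 2 — MI, ReliefF, SURF and SURF* each pick their top ``k_final``
   features from the shortlist, giving subsets S1..S4;
6. stage 3 — GINI-Select reconciles the subsets into exactly ``k_final``
   features;
7. the soft-voting ensemble is fitted on the selected features and scored on
   the held-out partition.

``whole_data_prep=True`` instead runs the Spearman filter and standardizer on the
whole matrix before splitting, mirroring the original whole-dataset
preprocessing protocol.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .combine import SelectionResult, gini_select
from .data import DataError, Dataset, stratified_split
from .ensemble import EnsembleConfig, EvalReport, evaluate, fit_predict_ensemble
from .filters import (
    FeatureRanking,
    f_test_scores,
    mutual_information_scores,
    relieff_scores,
    select_top,
    surf_scores,
    surfstar_scores,
)
from .preprocess import (
    RedundancyReport,
    apply_standardizer,
    fit_standardizer,
    spearman_redundancy_filter,
)

__all__ = ["PipelineConfig", "run_efs_gini", "run_single_filter", "SINGLE_FILTER_METHODS"]

logger = logging.getLogger("efsgini")

SINGLE_FILTER_METHODS = ("f_test", "mi", "relieff", "surf", "surfstar")


@dataclass
class PipelineConfig:
    """All tunable pipeline settings.

    ``k_final`` may be an integer count, a fraction in (0, 1) of the original
    feature count, or None for the default top-1% rule (ceil of 1% of the
    feature count before any filtering).  ``stage1_pool`` defaults to
    ``min(surviving features, 10 * k_final)``.
    """

    spearman_threshold: float = 0.9
    k_final: int | float | None = None
    stage1_pool: int | None = None
    n_bins: int = 8
    n_neighbors: int = 20
    test_fraction: float = 0.4
    seed: int = 0
    whole_data_prep: bool = False
    unweighted_gain: bool = False
    min_samples_split: int = 2
    knn_neighbors: int = 5
    svm_kernel: str = "rbf"
    svm_c: float = 1.0
    rf_estimators: int = 100

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        return cls(**payload)

    def to_dict(self) -> dict:
        return asdict(self)

    # -- derived quantities -------------------------------------------------

    def resolve_k_final(self, n_original_features: int) -> int:
        if self.k_final is None:
            return max(1, math.ceil(0.01 * n_original_features))
        if isinstance(self.k_final, float) and 0.0 < self.k_final < 1.0:
            return max(1, math.ceil(self.k_final * n_original_features))
        k = int(self.k_final)
        if k < 1:
            raise DataError(f"k_final must be positive, got {self.k_final}")
        return k

    def resolve_stage1_pool(self, n_surviving: int, k_final: int) -> int:
        pool = self.stage1_pool if self.stage1_pool is not None else 10 * k_final
        pool = min(pool, n_surviving)
        if pool < k_final:
            raise DataError(
                f"stage1_pool={pool} smaller than k_final={k_final}"
            )
        return pool

    def derived_seeds(self) -> tuple[int, int]:
        """(split_seed, ensemble_seed), both deterministic in ``seed``."""
        ss = np.random.SeedSequence(self.seed)
        a, b = ss.generate_state(2)
        return int(a) % 2**31, int(b) % 2**31

    def ensemble_config(self) -> EnsembleConfig:
        _, ens_seed = self.derived_seeds()
        return EnsembleConfig(
            seed=ens_seed,
            knn_neighbors=self.knn_neighbors,
            svm_kernel=self.svm_kernel,
            svm_c=self.svm_c,
            rf_estimators=self.rf_estimators,
        )


@dataclass
class PreparedData:
    """Split, redundancy-filtered, standardized data ready for scoring."""

    train: Dataset
    test: Dataset
    redundancy: RedundancyReport
    k_final: int
    stage1_pool: int


def prepare(ds: Dataset, config: PipelineConfig) -> PreparedData:
    """Split + Spearman filter + standardize, honoring ``whole_data_prep``."""
    split_seed, _ = config.derived_seeds()
    k_final = config.resolve_k_final(ds.n_features)
    if config.whole_data_prep:
        filtered, report = spearman_redundancy_filter(ds, config.spearman_threshold)
        params = fit_standardizer(filtered)
        whole = apply_standardizer(filtered, params)
        pair = stratified_split(whole, config.test_fraction, split_seed)
        train, test = pair.train, pair.test
    else:
        pair = stratified_split(ds, config.test_fraction, split_seed)
        train_f, report = spearman_redundancy_filter(
            pair.train, config.spearman_threshold
        )
        test_f = pair.test.select_features(train_f.feature_ids)
        params = fit_standardizer(train_f)
        train = apply_standardizer(train_f, params)
        test = apply_standardizer(test_f, params)
    if k_final > train.n_features:
        raise DataError(
            f"k_final={k_final} exceeds the {train.n_features} features "
            "surviving the Spearman filter"
        )
    stage1_pool = config.resolve_stage1_pool(train.n_features, k_final)
    logger.info(
        "prepared: %d train / %d test samples, %d features kept, %d dropped "
        "(threshold %.2f), k_final=%d, stage1_pool=%d",
        train.n_samples, test.n_samples, train.n_features,
        len(report.dropped), config.spearman_threshold, k_final, stage1_pool,
    )
    return PreparedData(train, test, report, k_final, stage1_pool)


def stage2_rankings(
    train_pool: Dataset, config: PipelineConfig
) -> dict[str, FeatureRanking]:
    """The four parallel stage-2 rankings on the stage-1 shortlist.

    The scorers are pure functions of the training data and configuration,
    so running them concurrently or sequentially gives identical results.
    """
    return {
        "mi": mutual_information_scores(train_pool, n_bins=config.n_bins),
        "relieff": relieff_scores(train_pool, n_neighbors=config.n_neighbors),
        "surf": surf_scores(train_pool),
        "surfstar": surfstar_scores(train_pool),
    }


def _run_stages(
    train: Dataset, config: PipelineConfig, k_final: int, stage1_pool: int
) -> tuple[SelectionResult, FeatureRanking, dict[str, FeatureRanking]]:
    """Stages 1-3; also returns the stage-1 and stage-2 rankings."""
    t0 = time.perf_counter()
    f_rank = f_test_scores(train)
    pool_ids = select_top(f_rank, stage1_pool)
    pos = {f: i for i, f in enumerate(train.feature_ids)}
    pool_ids = sorted(pool_ids, key=lambda f: pos[f])  # original column order
    train_pool = train.select_features(pool_ids)
    logger.info("stage 1 (F-test): %d -> %d features in %.2fs",
                train.n_features, len(pool_ids), time.perf_counter() - t0)

    t1 = time.perf_counter()
    rankings = stage2_rankings(train_pool, config)
    subsets = {m: select_top(r, k_final) for m, r in rankings.items()}
    logger.info("stage 2 (MI/ReliefF/SURF/SURF*): 4 x top %d in %.2fs",
                k_final, time.perf_counter() - t1)

    t2 = time.perf_counter()
    result = gini_select(
        subsets["mi"], subsets["relieff"], subsets["surf"], subsets["surfstar"],
        train_pool, k_final,
        rankings=list(rankings.values()),
        weighted_gain=not config.unweighted_gain,
        min_samples_split=config.min_samples_split,
    )
    if not result.gini_added_features:
        logger.info("stage 3: subsets coincide, CART skipped")
    logger.info("stage 3 (GINI-Select): |intersection|=%d, %d added in %.2fs",
                len(result.intersection_features),
                len(result.gini_added_features), time.perf_counter() - t2)

    result.stage1_pool = pool_ids
    result.stage2_scores = {m: r.scores() for m, r in rankings.items()}
    return result, f_rank, rankings


def select_features_efs(
    train: Dataset, config: PipelineConfig, k_final: int, stage1_pool: int
) -> SelectionResult:
    """Stages 1-3 on a prepared (standardized) training set."""
    result, _, _ = _run_stages(train, config, k_final, stage1_pool)
    return result


def evaluate_selected(
    train: Dataset, test: Dataset, features: list[str], config: PipelineConfig
) -> EvalReport:
    """Fit the soft-voting ensemble on the chosen features; score held-out data."""
    t0 = time.perf_counter()
    probs, preds = fit_predict_ensemble(
        train.select_features(features),
        test.select_features(features),
        config.ensemble_config(),
    )
    report = evaluate(test.y, preds, train.classes)
    report.runtime_seconds = time.perf_counter() - t0
    return report


def run_efs_gini(
    ds: Dataset, config: PipelineConfig | None = None
) -> tuple[SelectionResult, EvalReport]:
    """Full three-stage selection plus soft-voting evaluation.

    Returns the selection (with per-stage provenance) and the evaluation
    report on the held-out partition.  Fully reproducible for a fixed seed.
    """
    config = config or PipelineConfig()
    prep = prepare(ds, config)
    result = select_features_efs(prep.train, config, prep.k_final, prep.stage1_pool)
    result.spearman_dropped = list(prep.redundancy.dropped)
    report = evaluate_selected(prep.train, prep.test, result.final_features, config)
    logger.info("evaluation: accuracy=%.4f macro_f1=%.4f (%.2fs)",
                report.accuracy, report.macro_f1, report.runtime_seconds)
    return result, report


def rank_single_filter(
    train: Dataset, method: str, config: PipelineConfig
) -> FeatureRanking:
    if method == "f_test":
        return f_test_scores(train)
    if method == "mi":
        return mutual_information_scores(train, n_bins=config.n_bins)
    if method == "relieff":
        return relieff_scores(train, n_neighbors=config.n_neighbors)
    if method == "surf":
        return surf_scores(train)
    if method == "surfstar":
        return surfstar_scores(train)
    raise DataError(
        f"unknown method {method!r}; valid methods: {', '.join(SINGLE_FILTER_METHODS)}"
    )


def run_single_filter(
    ds: Dataset, method: str, config: PipelineConfig | None = None
) -> tuple[list[str], EvalReport]:
    """Baseline protocol: one scorer replaces stages 1-3.

    The same split/Spearman/standardization preprocessing is applied, the
    named scorer ranks all surviving features, and its top ``k_final``
    features feed the same soft-voting evaluation.
    """
    config = config or PipelineConfig()
    prep = prepare(ds, config)
    ranking = rank_single_filter(prep.train, method, config)
    features = select_top(ranking, prep.k_final)
    report = evaluate_selected(prep.train, prep.test, features, config)
    return features, report
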