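"""Planted-structure recovery study on the synthetic generator's defaults.

One seeded replicate = generate the default synthetic dataset (200 samples x
2000 features, 10 informative with one redundant copy each, 4 balanced
classes, effect size 2.0), run the shared preprocessing once, then:

* count how many planted redundant copies the Spearman stage removed;
* record the median rank of informative vs noise features for every scorer
  in the context where the pipeline runs it — the F-test over all surviving
  features, the four stage-2 scorers over the stage-1 shortlist (relief
  weighting with a distance threshold loses main-effect resolution when
  thousands of class-independent features dominate the distance metric,
  which is precisely why the staged design shortlists first);
* run the full EFS-GINI selection and the five single-filter baselines
  through the identical soft-voting evaluation on the held-out 40%.

Summaries are medians over replicates.  Used by the acceptance checks and
by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from .filters import select_top
from .pipeline import (
    PipelineConfig,
    SINGLE_FILTER_METHODS,
    _run_stages,
    evaluate_selected,
    prepare,
    rank_single_filter,
)
from .synthetic import make_synthetic

__all__ = ["planted_recovery_study"]


def _separation(ranking, truth) -> float:
    """Median noise rank minus median informative rank within one ranking."""
    pos = {f: i + 1 for i, (f, _) in enumerate(ranking.entries)}
    inf = [pos[f] for f in truth.informative_ids if f in pos]
    noise = [pos[f] for f in truth.noise_ids if f in pos]
    return float(np.median(noise) - np.median(inf))


def _replicate(gen_seed: int, pipe_seed: int, generator_kwargs: dict) -> dict:
    ds, truth = make_synthetic(seed=gen_seed, **generator_kwargs)
    config = PipelineConfig(seed=pipe_seed)
    prep = prepare(ds, config)
    rec: dict = {"gen_seed": gen_seed, "pipe_seed": pipe_seed}

    dropped = set(prep.redundancy.dropped_ids)
    rec["redundant_removed"] = len(dropped & set(truth.redundant_ids))
    rec["informative_dropped"] = len(dropped & set(truth.informative_ids))

    rec["baseline_macro_f1"] = {}
    rec["baseline_accuracy"] = {}
    for method in SINGLE_FILTER_METHODS:
        ranking = rank_single_filter(prep.train, method, config)
        feats = select_top(ranking, prep.k_final)
        report = evaluate_selected(prep.train, prep.test, feats, config)
        rec["baseline_macro_f1"][method] = report.macro_f1
        rec["baseline_accuracy"][method] = report.accuracy

    result, f_rank, rankings = _run_stages(
        prep.train, config, prep.k_final, prep.stage1_pool
    )
    rec["separation"] = {
        "f_test": _separation(f_rank, truth),
        **{m: _separation(r, truth) for m, r in rankings.items()},
    }
    report = evaluate_selected(prep.train, prep.test, result.final_features, config)
    rec["informative_recovered"] = len(
        set(result.final_features) & set(truth.informative_ids)
    )
    rec["efs_macro_f1"] = report.macro_f1
    rec["efs_accuracy"] = report.accuracy
    rec["k_final"] = prep.k_final
    return rec


def planted_recovery_study(
    n_seeds: int = 20, base_seed: int = 0, **generator_kwargs
) -> dict:
    """Run ``n_seeds`` replicates and summarize by medians.

    Generator keyword arguments override the study's default conditions
    (the :func:`efsgini.synthetic.make_synthetic` defaults).
    """
    ss = np.random.SeedSequence(base_seed)
    seeds = [int(s) % 2**31 for s in ss.generate_state(2 * n_seeds)]
    records = [
        _replicate(seeds[2 * i], seeds[2 * i + 1], generator_kwargs)
        for i in range(n_seeds)
    ]
    methods = list(SINGLE_FILTER_METHODS)
    summary = {
        "n_seeds": n_seeds,
        "redundant_removed_median": float(
            np.median([r["redundant_removed"] for r in records])
        ),
        "informative_recovered_median": float(
            np.median([r["informative_recovered"] for r in records])
        ),
        "efs_macro_f1_median": float(np.median([r["efs_macro_f1"] for r in records])),
        "efs_accuracy_median": float(np.median([r["efs_accuracy"] for r in records])),
        "separation_median": {
            m: float(np.median([r["separation"][m] for r in records]))
            for m in methods
        },
        "baseline_macro_f1_median": {
            m: float(np.median([r["baseline_macro_f1"][m] for r in records]))
            for m in methods
        },
        "efs_minus_best_baseline_f1_median": float(
            np.median(
                [
                    r["efs_macro_f1"] - max(r["baseline_macro_f1"].values())
                    for r in records
                ]
            )
        ),
    }
    return {"records": records, "summary": summary}
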