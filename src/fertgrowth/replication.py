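"""Optional full-data replication workflow.

The original study deposited an anonymized woman-level CSV in a public OSF
archive.  Given a local copy of that file (plus a population metadata CSV),
:func:`run_replication` refits every per-predictor model and the two
group-level models and writes the pooled and per-population ΔCF~ tables.
This is a long MCMC run on real data, deliberately outside the default test
suite; the same entry point runs end to end on synthetic data, which is how
it is exercised in tests.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .data_model import PredictorSpec, build_model_subset, read_records, standardize
from .fertility_model import ModelSpec
from .inference import fit
from .contrasts import contrast_1sd, group_cf_contrast, predict_cf, report

#: the per-predictor models of the main analysis: column -> transform
REPLICATION_PREDICTORS = [
    PredictorSpec("foraging_activities", "zscore", "expected negative"),
    PredictorSpec("farming_activities", "zscore", "expected positive"),
    PredictorSpec("diet_farmed", "zscore", "expected positive"),
    PredictorSpec("livestock", "log1p_then_zscore", "expected positive"),
    PredictorSpec("land_acres", "log1p_then_zscore", "expected positive"),
    PredictorSpec("wage_labor_activities", "zscore", "expected negative"),
    PredictorSpec("diet_market", "zscore", "expected negative"),
    PredictorSpec("occupation_waged", "binary", "expected negative"),
    PredictorSpec("residence_urban", "binary", "expected negative"),
    PredictorSpec("education_years", "log1p_then_zscore", "expected negative"),
    PredictorSpec("income", "log1p_then_zscore", "direction unclear"),
]

GROUPINGS = ("subsistence_type", "market_integration")


def run_replication(
    data_csv,
    meta_csv,
    out_dir,
    predictors=None,
    groupings=GROUPINGS,
    column_map=None,
    chains: int = 2,
    warmup: int = 1000,
    samples: int = 1000,
    seed: int = 1,
    woman_effect: bool = True,
) -> pd.DataFrame:
    """Fit every model of the main analysis to a deposited-style CSV.

    Skips predictors whose column is absent from the file (availability
    varies by site).  Returns the combined contrast table; per-model tables,
    forest plots and diagnostics land under ``out_dir``.
    """
    data_csv = Path(data_csv)
    if not data_csv.exists():
        raise FileNotFoundError(
            f"{data_csv} not found — place the deposited anonymized CSV there "
            "(it is not redistributed with this package)"
        )
    predictors = REPLICATION_PREDICTORS if predictors is None else predictors
    records, meta = read_records(data_csv, meta_csv, predictors, column_map)
    out_dir = Path(out_dir)
    tables = []

    for pspec in predictors:
        if pspec.name not in records.columns:
            continue
        std = standardize(records, pspec)
        dataset = build_model_subset(std, meta, pspec)
        mspec = ModelSpec(
            predictor=pspec, chains=chains, warmup=warmup, samples=samples,
            seed=seed, woman_effect=woman_effect,
        )
        post = fit(dataset, mspec)
        results = [contrast_1sd(post, "pooled")] + [
            contrast_1sd(post, "population", j) for j in range(dataset.n_populations)
        ]
        preds = [predict_cf(post, "pooled")]
        sub = report(results, meta, out_dir / pspec.name, predictions=preds)
        post.diagnostics().to_csv(out_dir / pspec.name / "diagnostics.csv", index=False)
        tables.append(sub)

    for grouping in groupings:
        dataset = build_model_subset(records, meta, None)
        mspec = ModelSpec(
            group_by=grouping, chains=chains, warmup=warmup, samples=samples,
            seed=seed, woman_effect=woman_effect,
        )
        post = fit(dataset, mspec)
        preds, contrasts = group_cf_contrast(post, grouping)
        sub = report(contrasts, meta, out_dir / grouping, predictions=preds)
        tables.append(sub)

    combined = pd.concat(tables, ignore_index=True)
    combined.to_csv(out_dir / "replication_contrasts.csv", index=False, float_format="%.6g")
    return combined
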