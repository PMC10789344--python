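"""End-to-end analysis pipeline: sessions -> report bundle.

Stages: feature extraction per rater, clinical-vs-ASR reliability,
effect-size ranking, diagnostic classification (model family), and the
correlation heatmap.  Every stage logs counts in/out; all tabular
outputs are UTF-8 CSV, figures are optional, and a run-metadata JSON
records the seed, configuration and package versions so a rerun with
the same config reproduces identical CSVs.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classification import run_model_family
from .features import SerialRegions, build_feature_table, feature_catalog, feature_dictionary
from .group_stats import correlation_heatmap, effect_size_ranking
from .reliability import reliability_report
from .scoring import Session

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

AUX_COLUMNS = (
    "mmse", "cdr_sob", "dad_total", "gds15",
    "z_svf", "z_stroop3", "z_tmtb", "z_rbmt_immediate", "z_rbmt_delayed",
)

TOP10_FEATURES = (
    "delayed_recall",
    "immediate_midlist_items_trial_3",
    "delayed_recall_midlist_items",
    "late_learning_slope",
    "immediate_total_midlist_items",
    "immediate_count_trial_5",
    "total_immediate_recall",
    "immediate_count_trial_4",
    "delayed_recall_recency_items",
    "immediate_count_trial_3",
)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; seed is mandatory for stochastic steps."""

    out_dir: Path
    seed: int
    rater: str = "asr"
    regions: SerialRegions = field(default_factory=SerialRegions)
    n_estimators: int = 500
    classifier_seed: int = 1234
    f1_threshold: float = 0.5
    diff_thresholds: dict = field(
        default_factory=lambda: {"total_immediate_recall": 14.0, "delayed_recall": 4.0}
    )
    make_figures: bool = True
    run_classification: bool = True


def run_pipeline(
    sessions: Sequence[Session],
    metadata: pd.DataFrame,
    config: RunConfig,
) -> dict[str, object]:
    """Run the full analysis and write the report bundle to ``config.out_dir``.

    ``metadata`` must be indexed by participant_id with at least
    ``label`` (0/1) and ``age`` columns; ``group`` enables subgroup
    reliability and the dementia-excluded sensitivity rerun; the
    auxiliary cognitive columns enable the heatmap.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline start: %d sessions", len(sessions))

    # --- features per rater -------------------------------------------------
    tables: dict[str, pd.DataFrame] = {}
    for rater in ("clinical", "asr"):
        present = [s for s in sessions if s.variant(rater) is not None]
        if present:
            tables[rater] = build_feature_table(present, rater, config.regions)
            tables[rater].to_csv(out / f"features_{rater}.csv")
            logger.info("features[%s]: %d participants x %d features",
                        rater, *tables[rater].shape)
    (out / "feature_dictionary.json").write_text(
        json.dumps(feature_dictionary(), indent=1), encoding="utf-8"
    )

    # --- reliability --------------------------------------------------------
    rel_df = pd.DataFrame()
    if "clinical" in tables and "asr" in tables:
        measures = {}
        for m in ("total_immediate_recall", "delayed_recall", *[
            f"immediate_count_trial_{i}" for i in range(1, 6)
        ]):
            df = pd.DataFrame(
                {
                    "value_clinical": tables["clinical"][m],
                    "value_asr": tables["asr"][m],
                }
            )
            if "group" in metadata.columns:
                df["group"] = metadata["group"]
                df["diagnosis_pair"] = np.where(metadata["label"] == 1, "MCI/dementia", "SCD")
            measures[m] = df
        rel_df = reliability_report(
            measures,
            thresholds=config.diff_thresholds,
            group_col="diagnosis_pair" if "group" in metadata.columns else None,
        )
        rel_df.to_csv(out / "reliability.csv", index=False)
        if config.make_figures:
            from .plots import agreement_scatter

            for m in ("total_immediate_recall", "delayed_recall"):
                agreement_scatter(
                    tables["clinical"][m], tables["asr"][m], m, out / f"scatter_{m}.png"
                )

    # --- effect sizes -------------------------------------------------------
    main = tables.get(config.rater)
    if main is None:
        raise ValueError(f"no sessions carry the designated rater {config.rater!r}")
    main = main.loc[metadata.index.intersection(main.index)]
    meta = metadata.loc[main.index]
    ranking = effect_size_ranking(main, meta["label"].to_numpy(), 1)
    ranking.to_csv(out / "effect_sizes.csv", index=False)
    logger.info("effect sizes: %d features ranked", len(ranking))

    # --- classification -----------------------------------------------------
    results = {}
    class_df = pd.DataFrame()
    if config.run_classification:
        table = main.join(meta[["age"]])
        exclude = (
            (meta["group"] == "dementia").to_numpy()
            if "group" in meta.columns
            else None
        )
        results, class_df = run_model_family(
            table,
            meta["label"].to_numpy(),
            feature_columns=list(feature_catalog()),
            n_estimators=config.n_estimators,
            random_seed=config.classifier_seed,
            threshold=config.f1_threshold,
            exclude_mask=exclude,
        )
        class_df.to_csv(out / "classification.csv", index=False)
        if config.make_figures:
            from .plots import roc_figure

            for subtest in ("immediate", "delayed", "recognition", "full"):
                fam = {
                    f"model {t}": results[f"{subtest}_model{t}"] for t in (1, 2, 3)
                }
                roc_figure(fam, subtest, out / f"roc_{subtest}.png")

    # --- correlation heatmap ------------------------------------------------
    aux = [c for c in AUX_COLUMNS if c in meta.columns]
    corr = None
    if aux:
        joined = main[list(TOP10_FEATURES)].join(meta[aux])
        corr = correlation_heatmap(joined)
        corr.r.to_csv(out / "correlations.csv")
        logger.info("heatmap: %d complete cases", corr.n_complete)
        if config.make_figures:
            from .plots import heatmap_figure

            heatmap_figure(corr, out / "heatmap.png")

    # --- run metadata -------------------------------------------------------
    run_meta = {
        "vltkit_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "rater": config.rater,
        "n_sessions": len(sessions),
        "classifier": {
            "n_estimators": config.n_estimators,
            "random_seed": config.classifier_seed,
            "f1_threshold": config.f1_threshold,
            "imputation": "median (within training folds)",
        },
    }
    (out / "run_metadata.json").write_text(json.dumps(run_meta, indent=1), encoding="utf-8")
    return {
        "features": tables,
        "reliability": rel_df,
        "effect_sizes": ranking,
        "classification": class_df,
        "classification_results": results,
        "correlations": corr,
    }
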