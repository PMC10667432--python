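"""End-to-end orchestration: ingest -> drop deleted -> dedup -> cohort ->
descriptives / signal screening / time-to-onset, with per-stage counts."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

from . import descriptives, ingest, preprocess, signals, tto

log = logging.getLogger("faerspv")


@dataclasses.dataclass
class PipelineConfig:
    input_dirs: tuple[str, ...]
    drug_patterns: tuple[str, ...]
    meddra_path: str | None = None
    deleted_path: str | None = None
    soc_exclusions: tuple[str, ...] = ()
    thresholds: signals.Thresholds = dataclasses.field(
        default_factory=signals.Thresholds)
    priors: signals.BcpnnPriors = dataclasses.field(
        default_factory=signals.BcpnnPriors)
    top_k: int = 5
    out_dir: str = "."


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write table2.tsv, signals_soc.tsv, signals_pt.tsv,
    tto.tsv and run_log.json into ``out_dir``. Returns the stage-count log.

    Stage counts are monotone: raw reports >= after deleted-removal >=
    after dedup >= target cohort.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict = {"thresholds": dataclasses.asdict(config.thresholds),
                    "patterns": list(config.drug_patterns)}

    parts = [ingest.read_quarter(d, deleted_path=config.deleted_path)
             for d in config.input_dirs]
    raw = ingest.concat_tables(parts)
    counts["raw_reports"] = raw.n_reports
    log.info("ingest: %d report rows", raw.n_reports)

    raw = preprocess.drop_deleted(raw)
    counts["after_deleted"] = raw.n_reports
    raw = preprocess.deduplicate(raw)
    counts["after_dedup"] = raw.n_reports
    log.info("dedup: %d unique cases", raw.n_reports)

    records = preprocess.build_cohort(raw, list(config.drug_patterns))
    cohort = preprocess.target_cohort(records)
    counts["cohort"] = len(cohort)
    log.info("cohort: %d primary-suspect target reports", len(cohort))
    if not cohort:
        raise ValueError("stage cohort: no target reports matched "
                         f"{config.drug_patterns} (counts so far: {counts})")

    summary = descriptives.summarize_cohort(cohort, k=config.top_k)
    summary.to_frame().to_csv(out_dir / "table2.tsv", sep="\t", index=False)

    meddra = (ingest.load_meddra_map(config.meddra_path)
              if config.meddra_path else None)
    for level, fname in ((signals.SOC_LEVEL, "signals_soc.tsv"),
                         (signals.PT_LEVEL, "signals_pt.tsv")):
        if level == signals.SOC_LEVEL and meddra is None:
            counts["signals_soc"] = None
            continue
        metrics = signals.screen(
            records, level=level, meddra=meddra,
            soc_exclusions=config.soc_exclusions,
            priors=config.priors, thresholds=config.thresholds)
        signals.metrics_frame(metrics).to_csv(out_dir / fname, sep="\t",
                                              index=False)
        counts[f"signals_{level.lower()}"] = len(metrics)
        counts[f"consensus_{level.lower()}"] = len(
            signals.consensus_signals(metrics))

    tto_df = tto.summarize_by_pt(cohort, min_n=1)
    tto_df.to_csv(out_dir / "tto.tsv", sep="\t", index=False)
    overall = tto.summarize_tto(tto.onset_observations(cohort))
    counts["tto_reports_with_onset"] = overall.n_with_onset
    counts["tto_median"] = overall.median

    counts["ingest_counters"] = dict(raw.counters)
    (out_dir / "run_log.json").write_text(json.dumps(counts, indent=2,
                                                     default=str) + "\n")
    return counts
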