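"""End-to-end pipeline: simulate -> preprocess -> coherence -> statistics.

Thin orchestration over the library modules, with every stage's output
written as delimited tables plus a JSON manifest (seed, configuration
hash, package version) so any number in any table can be regenerated.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .corrcoh import (
    dyad_correlation_matrices,
    familiarity_contrast,
    group_median_significant,
    ks_condition_compare,
)
from .coupling import (
    art_anova_table,
    corpus_condition_records,
    surrogate_comparison_table,
    surrogate_pair_ensemble,
)
from .preproc import synchronize_and_segment
from .registry import BAND_ORDER, CONDITIONS
from .synthetic import GeneratorConfig, generate_corpus, save_session
from .wtc import dyad_wtc_set

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on."""

    n_dyads: int = 24
    n_familiar: int | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    n_surrogates: int = 2400
    alpha: float = 0.05
    decimate: int = 1
    seed: int = 0
    outdir: str = "spafnirs_out"
    save_sessions: bool = False
    signal_types: tuple[str, ...] | None = None

    def validate(self) -> None:
        if self.n_dyads < 2:
            raise ValueError("need >= 2 dyads")
        if self.n_surrogates < 0 or self.alpha <= 0 or self.decimate < 1:
            raise ValueError("invalid statistics options")

    def config_hash(self) -> str:
        blob = json.dumps(
            dataclasses.asdict(self), default=lambda o: repr(o), sort_keys=True
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the in-memory result bundle.

    Writes, under ``config.outdir``: condition_records.csv,
    art_anova.csv, surrogate_comparison.csv, per-band group-median
    correlation matrices and KS tables, the familiarity contrast, and
    manifest.json. Deterministic given ``config.seed``.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    timings = {}

    def stage(name):
        logger.info("stage %s", name)
        timings[name] = _time.perf_counter()

    def done(name):
        timings[name] = _time.perf_counter() - timings[name]
        logger.info("stage %s finished in %.1f s", name, timings[name])

    stage("simulate")
    gen = dataclasses.replace(config.generator)
    sessions = generate_corpus(
        config.n_dyads, gen, n_familiar=config.n_familiar, seed=config.seed
    )
    if config.save_sessions:
        for s in sessions:
            save_session(s, out / "sessions")
    done("simulate")

    stage("preprocess")
    corpora = [synchronize_and_segment(s) for s in sessions]
    done("preprocess")

    stage("coherence")
    wtc_sets = {
        pre.dyad_id: dyad_wtc_set(pre, signal_types=config.signal_types)
        for pre in corpora
    }
    records = corpus_condition_records(
        corpora, signal_types=config.signal_types, wtc_sets=wtc_sets
    )
    records.to_csv(out / "condition_records.csv", index=False)
    done("coherence")

    stage("stats")
    art = art_anova_table(records)
    art.to_csv(out / "art_anova.csv", index=False)
    surrogate_records = pd.DataFrame()
    surrogate_table = pd.DataFrame()
    if config.n_surrogates > 0:
        surrogate_records = surrogate_pair_ensemble(
            corpora,
            n_surrogates=config.n_surrogates,
            seed=np.random.SeedSequence([config.seed, 1]),
            signal_types=config.signal_types,
        )
        surrogate_table = surrogate_comparison_table(records, surrogate_records)
        surrogate_table.to_csv(out / "surrogate_comparison.csv", index=False)
    done("stats")

    stage("correlated_coherence")
    matrices_by_dyad = {}
    familiarity = {}
    for pre in corpora:
        matrices_by_dyad[pre.dyad_id] = dyad_correlation_matrices(
            wtc_sets[pre.dyad_id], pre.segments, pre.dyad_id, decimate=config.decimate
        )
        familiarity[pre.dyad_id] = pre.familiarity
    corr_results = {}
    for band in BAND_ORDER:
        per_cond = {
            cond: [
                m[(band, cond)]
                for m in matrices_by_dyad.values()
                if (band, cond) in m
            ]
            for cond in CONDITIONS
        }
        if not all(per_cond.values()):
            continue
        medians = {
            cond: group_median_significant(mats, config.alpha, label=cond)
            for cond, mats in per_cond.items()
        }
        ks = ks_condition_compare(per_cond[CONDITIONS[0]], per_cond[CONDITIONS[1]])
        per_dyad = {
            d: {cond: m[(band, cond)] for cond in CONDITIONS}
            for d, m in matrices_by_dyad.items()
            if all((band, cond) in m for cond in CONDITIONS)
        }
        fam_medians, fam_ks = None, pd.DataFrame()
        if len(set(familiarity.values())) == 2:
            fam_medians, fam_ks = familiarity_contrast(per_dyad, familiarity)
        corr_results[band] = {
            "medians": medians,
            "ks": ks,
            "familiarity_medians": fam_medians,
            "familiarity_ks": fam_ks,
        }
        for cond, gm in medians.items():
            pd.DataFrame(gm.median, index=gm.names, columns=gm.names).to_csv(
                out / f"median_matrix_{band}_{cond}.csv"
            )
        if not ks.empty:
            ks.to_csv(out / f"ks_condition_{band}.csv", index=False)
        if not fam_ks.empty:
            fam_ks.to_csv(out / f"ks_familiarity_{band}.csv", index=False)
    done("correlated_coherence")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_dyads": config.n_dyads,
        "n_surrogates": config.n_surrogates,
        "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
        "n_band_series_per_dyad": len(wtc_sets[corpora[0].dyad_id]),
        "outputs": sorted(p.name for p in out.glob("*.csv")),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {
        "sessions": sessions,
        "corpora": corpora,
        "records": records,
        "art": art,
        "surrogate_records": surrogate_records,
        "surrogate_table": surrogate_table,
        "correlated": corr_results,
        "manifest": manifest,
    }


def write_reports(bundle: dict, outdir: str | Path) -> list[Path]:
    """Human-oriented summary tables from a completed bundle."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    art = bundle["art"]
    path = out / "report_condition_effects.csv"
    if art.empty:
        path.write_text("note\nno significant cells\n")
    else:
        sig = art[art["p_adj"] < 0.05].sort_values("p_adj")
        if sig.empty:
            path.write_text("note\nno significant cells\n")
        else:
            sig.to_csv(path, index=False)
    written.append(path)
    surr = bundle["surrogate_table"]
    if not surr.empty:
        path = out / "report_true_vs_surrogate.csv"
        surr.sort_values("p_adj").to_csv(path, index=False)
        written.append(path)
    return written
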