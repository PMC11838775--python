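"""End-to-end pipeline driver.

Reproduces the full analysis sequence on a synthetic paired experiment
(or user-supplied files): behavior -> tagging epochs -> event extraction ->
group detection (both methods) -> pairwise overlaps -> cross-session
reactivation -> correlations.  Every written artifact carries a provenance
header; excluded cells are reported with reasons, never silently dropped.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional

import pandas as pd
import yaml

from . import behavior, correlations, cross_session, ensembles, events, io, synthetic
from .overlap import overlap_test

log = logging.getLogger("engramkit")


@dataclass
class PipelineConfig:
    """Seeds, thresholds, and paths for one pipeline run."""

    seed: int = 0
    out_dir: str = "engram_out"
    synthetic: bool = True
    immobility_cms: float = behavior.ONLINE_IMMOBILITY_CMS
    min_immobile_parts: int = behavior.FREEZING_TAG_MIN_PARTS
    z_cut_sd: float = events.Z_CUT_SD
    rank_n_sd: float = 1.0
    n_shifts: int = 1000
    n_resamples: int = 1000
    overlap_denominator: str = "union"
    pixel_to_cm: float = 1.0
    methods: tuple = ("rank", "statistical")
    group_size: int = 16

    def to_dict(self) -> dict:
        d = asdict(self)
        d["methods"] = list(self.methods)
        return d

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "methods" in d:
            d["methods"] = tuple(d["methods"])
        return cls(**d)


@dataclass
class ResultBundle:
    config: PipelineConfig
    membership: Dict[str, Dict[str, set]]          # method -> group -> cells
    overlaps: pd.DataFrame
    reactivation: pd.DataFrame
    composition: Dict[str, Optional[float]]
    correlation_summary: pd.DataFrame
    agreement: Optional[pd.DataFrame] = None
    experiment: Optional[synthetic.Experiment] = None


def _membership_agreement(m1: Dict[str, set], m2: Dict[str, set], n_cells: int) -> pd.DataFrame:
    rows = []
    for g in sorted(set(m1) | set(m2)):
        a, b = m1.get(g, set()), m2.get(g, set())
        agree = n_cells - len(a ^ b)
        rows.append((g, len(a), len(b), len(a & b), agree / n_cells))
    return pd.DataFrame(rows, columns=["group", "n_rank", "n_statistical",
                                       "n_both", "agreement"])


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """Run the full analysis on a seeded synthetic paired experiment."""
    if not config.synthetic:
        raise NotImplementedError(
            "file-based runs: use the stage CLIs / library functions on your own "
            "tables; the driver currently orchestrates the synthetic experiment")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config_hash": io.config_hash(config.to_dict())}

    exp = synthetic.generate_experiment(config.seed, group_size=config.group_size)
    fc, rec = exp.fc, exp.recall
    log.info("synthetic experiment: %d FC cells, %d tracked to recall",
             fc.spec.n_cells, len(exp.registration))

    # behavior: classify freezing from the pose track with the online rule
    speeds = behavior.compute_speeds(fc.track)
    labels_fc = behavior.classify_freezing_online(
        speeds, config.immobility_cms, config.min_immobile_parts)
    io.write_labels(out / "fc_freezing.tsv", labels_fc, {**meta, "stage": "behavior"})

    # tagging epochs per condition (already scheduled inside the generator)
    for cond, eps in fc.condition_epochs.items():
        io.write_epochs(out / f"tagging_{cond}.tsv", eps, {**meta, "stage": "tagging"})

    # events
    raster_fc = events.extract_events(fc.traces, config.z_cut_sd)
    raster_rec = events.extract_events(rec.traces, config.z_cut_sd)
    io.write_raster(out / "fc_events.tsv", raster_fc, {**meta, "stage": "events"})
    log.info("event extraction: %d cells, %d bins", raster_fc.n_cells, raster_fc.n_bins)

    # group detection, both methods
    membership: Dict[str, Dict[str, set]] = {}
    for i, method in enumerate(config.methods):
        kwargs = {"n_sd": config.rank_n_sd} if method == "rank" else \
            {"n_shifts": config.n_shifts, "seed": config.seed * 1000 + 17 + i}
        det = ensembles.detect_groups(fc.traces, fc.condition_epochs, method, **kwargs)
        membership[method] = {g: d.members for g, d in det.items()}
        io.write_membership(out / f"membership_{method}.tsv", membership[method],
                            method, {**meta, "stage": "detect"})
    primary = membership[config.methods[0]]
    agreement = None
    if len(config.methods) == 2:
        agreement = _membership_agreement(membership[config.methods[0]],
                                          membership[config.methods[1]],
                                          fc.spec.n_cells)
        io.write_table(out / "method_agreement.tsv", agreement, {**meta, "stage": "detect"})

    # overlaps: all unordered group pairs of the primary method
    ov_rows = []
    for i, (ga, gb) in enumerate(itertools.combinations(sorted(primary), 2)):
        res = overlap_test(primary[ga], primary[gb], fc.spec.n_cells,
                                   (ga, gb), config.n_resamples,
                                   seed=config.seed * 1000 + 100 + i,
                                   denominator=config.overlap_denominator)
        ov_rows.append((ga, gb, res.observed, res.p5, res.p95, res.verdict, res.seed))
    overlaps = pd.DataFrame(ov_rows, columns=["group_a", "group_b", "observed",
                                              "p5", "p95", "verdict", "seed"])
    io.write_table(out / "overlaps.tsv", overlaps, {**meta, "stage": "overlap"})

    # cross-session reactivation
    rows = cross_session.recall_activity(exp.registration, primary, raster_rec,
                                         rec.labels, n_cells_fc=fc.spec.n_cells)
    react = pd.DataFrame([vars(r) for r in rows])
    io.write_table(out / "reactivation.tsv", react, {**meta, "stage": "react"})
    frz_recall = ensembles.recall_groups(rec.traces, rec.labels,
                                         method="rank")["frz-recall"].members
    composition = cross_session.recall_group_composition(exp.registration, primary,
                                                         frz_recall)

    # correlations: intra-group slices of FC against the circular-shift null
    table = correlations.pairwise_correlations(raster_fc, primary, session="FC")
    null = correlations.null_correlations(raster_fc, table, config.n_resamples,
                                          seed=config.seed * 1000 + 7)
    corr_rows = []
    for g in sorted(primary):
        if primary[g] and table.pair_mask(g, g).any():
            cmp_ = correlations.compare_group_to_null(table, null, (g, g))
            corr_rows.append((g, g, cmp_.n_pairs, cmp_.observed_mean, cmp_.p95,
                              cmp_.significant))
    corr_summary = pd.DataFrame(corr_rows, columns=["group_a", "group_b", "n_pairs",
                                                    "observed_mean", "p95", "significant"])
    io.write_table(out / "correlation_summary.tsv", corr_summary,
                   {**meta, "stage": "corr"})
    excl = pd.DataFrame(table.excluded, columns=["cell", "reason"])
    io.write_table(out / "excluded_cells.tsv", excl, {**meta, "stage": "corr"})
    log.info("pipeline complete: %d overlap verdicts, %d correlation slices",
             len(overlaps), len(corr_summary))

    return ResultBundle(config=config, membership=membership, overlaps=overlaps,
                        reactivation=react, composition=composition,
                        correlation_summary=corr_summary, agreement=agreement,
                        experiment=exp)
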