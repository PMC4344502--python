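"""End-to-end orchestration: simulate/load -> quantify -> kinetics -> features.

A single :class:`PipelineConfig` (YAML-loadable) drives every stage; all
stage outputs are TSVs under the run directory plus a JSON summary with
the headline tallies (detectable entities, turnover classes split by
strand role, kinetic shapes, the sequence-feature panel) and, for
simulated runs, a truth-vs-called confusion matrix. Re-running with the
same config and seed reproduces the outputs bit for bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .config import ConfigError, SimConfig, ThresholdConfig, dataclass_from_mapping
from .kinetics import FAST_CLASSES, turnover_calls
from .quantify import annotate_star, compute_frequencies, quantify_reads
from .reference import load_reference, read_sequences
from .seqfeatures import FeatureError, feature_report, sets_from_calls
from .synthdata import (add_spikein_counts, generate_reference,
                        simulate_timecourse_reads, write_simulation)

log = logging.getLogger("mirturn")


@dataclass
class PipelineConfig:
    out_dir: str = "mirturn_run"
    seed: int = 0
    sim: SimConfig | None = None
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    # real-data inputs (used when sim is None)
    hairpin_fasta: str | None = None
    annotation_tsv: str | None = None
    samples_tsv: str | None = None
    counts_tsv: str | None = None        # pre-collapsed sequence x sample counts
    reads_dir: str | None = None         # else FASTA/FASTQ per sample
    nta: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key, value in raw.items():
            if key == "sim":
                kwargs["sim"] = dataclass_from_mapping(SimConfig, value or {})
            elif key == "thresholds":
                kwargs["thresholds"] = dataclass_from_mapping(ThresholdConfig,
                                                              value or {})
            elif hasattr(cls, key) or key in cls.__dataclass_fields__:
                kwargs[key] = value
            else:
                raise ConfigError(f"unknown pipeline config key: {key!r}")
        return cls(**kwargs)

    def validate(self) -> None:
        self.thresholds.validate()
        if self.sim is None:
            missing = [n for n in ("hairpin_fasta", "annotation_tsv", "samples_tsv")
                       if getattr(self, n) is None]
            if missing:
                raise ConfigError(f"real-data run needs: {missing}")
            if self.counts_tsv is None and self.reads_dir is None:
                raise ConfigError("provide counts_tsv or reads_dir")


def _stage(name):
    log.info("stage: %s", name)
    return name


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages; returns the report directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stage = "setup"
    try:
        log.info("config: %s", config)
        truth = None
        if config.sim is not None:
            stage = _stage("simulate")
            sim_cfg = config.sim
            reference, spikeins, truth = generate_reference(sim_cfg)
            sim = simulate_timecourse_reads(reference, truth, sim_cfg)
            sim = add_spikein_counts(sim, spikeins, sim_cfg)
            write_simulation(reference, spikeins, truth, sim, out / "sim")
            counts_in = sim.counts
            sample_sheet = sim.samples
        else:
            stage = _stage("load")
            reference = load_reference(config.hairpin_fasta, config.annotation_tsv)
            sample_sheet = pd.read_csv(config.samples_tsv, sep="\t")
            if config.counts_tsv:
                counts_in = pd.read_csv(config.counts_tsv, sep="\t", index_col=0)
            else:
                reads_dir = Path(config.reads_dir)
                counts_in = {}
                for row in sample_sheet.itertuples(index=False):
                    matches = sorted(reads_dir.glob(f"{row.sample_id}.*"))
                    if not matches:
                        raise ConfigError(
                            f"no reads file for sample {row.sample_id!r}")
                    counts_in[row.sample_id] = read_sequences(matches[0])

        stage = _stage("quantify")
        counts = quantify_reads(counts_in, reference, config.thresholds,
                                nta=config.nta)
        counts.table.to_csv(out / "isoform_counts.tsv", sep="\t", index=False)
        counts.mature_mapped_total.rename("mature_mapped_total").to_csv(
            out / "sample_totals.tsv", sep="\t")

        stage = _stage("frequencies")
        fm = compute_frequencies(counts, sample_sheet, config.thresholds)
        fm.entity.to_csv(out / "entity_frequencies.tsv", sep="\t")
        fm.isoform.to_csv(out / "isoform_frequencies.tsv", sep="\t")
        fm.isoform_meta.to_csv(out / "isoform_meta.tsv", sep="\t",
                               index_label="isoform_id")
        star = annotate_star(fm, reference)
        star.to_csv(out / "strand_roles.tsv", sep="\t", index=False)

        stage = _stage("kinetics")
        calls = turnover_calls(fm, config.thresholds, level="entity", fit=True)
        calls.to_csv(out / "turnover_calls.tsv", sep="\t")
        iso_calls = turnover_calls(fm, config.thresholds, level="isoform",
                                   fit=False)
        iso_calls.to_csv(out / "isoform_turnover_calls.tsv", sep="\t")

        stage = _stage("features")
        features = None
        try:
            sets = sets_from_calls(iso_calls, fm.isoform_meta)
            features = feature_report(sets, config.thresholds, seed=config.seed)
            features["first_last"].to_csv(out / "feature_first_last.tsv",
                                          sep="\t", index=False)
            features["total_composition"].to_csv(
                out / "feature_total_composition.tsv", sep="\t", index=False)
            features["a_motif"].rename("value").to_csv(
                out / "feature_a_motif.tsv", sep="\t")
            features["a_by_position"].to_csv(out / "feature_a_positions.tsv",
                                             sep="\t", index=False)
            features["lengths"].to_csv(out / "feature_lengths.tsv",
                                       sep="\t", index=False)
        except FeatureError as exc:
            log.warning("feature stage skipped: %s", exc)

        stage = _stage("report")
        summary = build_summary(fm, star, calls, iso_calls, features, truth)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        log.info("done: %s", out)
        return out
    except Exception as exc:
        log.error("pipeline failed at stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()


def build_summary(fm, star, calls, iso_calls, features, truth=None) -> dict:
    """Headline tallies of a finished run (the pie-chart numbers)."""
    role_of = dict(zip(star["group_id"], star["role"]))
    det = calls[calls["detected"]]
    det_mature = det[~det.index.str.contains(":")]
    by_class = {}
    for cls in ("fast_lt25", "fast_lt50", "slow", "intermediate"):
        sub = det_mature[det_mature["turnover_class"] == cls]
        by_class[cls] = {
            "total": int(len(sub)),
            "star": int(sum(role_of.get(e) == "star" for e in sub.index)),
            "non_star": int(sum(role_of.get(e) == "non_star" for e in sub.index)),
        }
    # the <25% set is a subset of the <50% set by construction
    fast50_any = det_mature["turnover_class"].isin(FAST_CLASSES)
    fast25 = det_mature["turnover_class"] == "fast_lt25"
    summary = {
        "detectable_mirnas": int(len(det_mature)),
        "detectable_isoforms": int(iso_calls["detected"].sum()),
        "turnover_classes": by_class,
        "fast_lt50_total": int(fast50_any.sum()),
        "fast_lt50_star": int(sum(role_of.get(e) == "star"
                                  for e in det_mature.index[fast50_any])),
        "fast_lt25_total": int(fast25.sum()),
        "fast_lt25_star": int(sum(role_of.get(e) == "star"
                                  for e in det_mature.index[fast25])),
        "shape_classes": {k: int(v) for k, v in
                          det["shape_class"].value_counts().items()}
        if "shape_class" in det else {},
    }
    if features is not None:
        fl = features["first_last"]
        summary["features"] = {
            "first_base": fl[fl["position"] == 1][
                ["nucleotide", "freq_fast", "freq_slow", "fisher_p", "perm_p",
                 "direction"]].to_dict("records"),
            "last_base": fl[fl["position"] == "last"][
                ["nucleotide", "freq_fast", "freq_slow", "fisher_p", "perm_p",
                 "direction"]].to_dict("records"),
            "a_motif_13_16": {k: (float(v) if isinstance(v, (int, float)) else v)
                              for k, v in features["a_motif"].items()},
            "mode_length_fast": int(features["lengths"].attrs["mode_fast"]),
            "mode_length_slow": int(features["lengths"].attrs["mode_slow"]),
        }
    if truth is not None and len(truth):
        t = truth.set_index("mature_id")["true_class"]
        common = det_mature.index.intersection(t.index)
        called_fast = det_mature.loc[common, "turnover_class"].isin(FAST_CLASSES)
        true_fast = t.loc[common] == "fast"
        summary["confusion_fast_lt50"] = {
            "tp": int((called_fast & true_fast).sum()),
            "fp": int((called_fast & ~true_fast).sum()),
            "fn": int((~called_fast & true_fast).sum()),
            "tn": int((~called_fast & ~true_fast).sum()),
        }
        cm = summary["confusion_fast_lt50"]
        sens_den = cm["tp"] + cm["fn"]
        spec_den = cm["tn"] + cm["fp"]
        summary["sensitivity_fast_lt50"] = (cm["tp"] / sens_den) if sens_den else None
        summary["specificity_fast_lt50"] = (cm["tn"] / spec_den) if spec_den else None
    return summary
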