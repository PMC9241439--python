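"""End-to-end orchestration: simulate -> call -> analyse, with a manifest.

A run is driven by one structured configuration (YAML on disk) with
per-module sections; unknown keys are rejected so every threshold lives in
one auditable place. The run emits tidy TSV tables plus a JSON manifest
recording the tool version, a configuration hash, checksums of the files
written, per-stage record counts and accumulated warnings — rerunning with
identical inputs reproduces identical record counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as tio
from . import stats as tstats
from .caller import call_sample, calls_to_table
from .errors import ConfigurationError
from .simulate import (FusionSimConfig, SimGenomeConfig, SimPanelConfig,
                       distribution_from_dict, render_amplicon_reads,
                       simulate_cohort, simulate_null_junction_positions)

log = logging.getLogger("telofuseq")

_DIST_KEYS = {"mh_length_distribution", "ins_length_distribution",
              "deletion_kb_distribution"}


def _build_section(cls, params: dict, what: str):
    known = set(cls.__dataclass_fields__)
    unknown = set(params) - known
    if unknown:
        raise ConfigurationError(f"unknown {what} keys: {sorted(unknown)}")
    params = dict(params)
    for key in _DIST_KEYS & set(params):
        if isinstance(params[key], dict):
            params[key] = distribution_from_dict(params[key])
    if "families" in params:
        params["families"] = [(f, list(ms)) for f, ms in params["families"]]
    return cls(**params)


@dataclass
class RunConfig:
    """Validated configuration for an end-to-end run."""

    panel: SimPanelConfig = field(default_factory=SimPanelConfig)
    genome: SimGenomeConfig = field(default_factory=SimGenomeConfig)
    fusions: FusionSimConfig = field(default_factory=FusionSimConfig)
    n_samples: int = 10
    read_len: int = 150
    error_rate: float = 0.0
    pairs_per_event: int = 1
    k: int = 15
    min_arm_bp: int = 30
    max_mh_bp: int = 25
    template_window_bp: int = 50
    pg_per_diploid_genome: float = 6.6
    null_positions: int = 10_000
    seed: int = 0
    out_dir: str = "telofuseq_run"
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sections = {
            "panel": (SimPanelConfig, d.pop("panel", {})),
            "genome": (SimGenomeConfig, d.pop("genome", {})),
            "fusions": (FusionSimConfig, d.pop("fusions", {})),
        }
        known = set(cls.__dataclass_fields__) - {"panel", "genome", "fusions"}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {name: _build_section(sec_cls, params, name)
                  for name, (sec_cls, params) in sections.items()}
        kwargs.update(d)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        import yaml

        with open(path, "rt", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError("config file must hold a mapping")
        return cls.from_dict(data)

    def validate(self) -> None:
        self.panel.validate()
        self.genome.validate()
        self.fusions.validate()
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be positive")
        if not 50 <= self.read_len <= 1000:
            raise ConfigurationError("read_len must lie in [50, 1000]")
        if not 0 <= self.error_rate <= 0.05:
            raise ConfigurationError("error_rate must lie in [0, 0.05]")
        if not 8 <= self.k <= 31:
            raise ConfigurationError("k must lie in [8, 31]")
        if self.min_arm_bp < self.k:
            raise ConfigurationError("min_arm_bp must be >= k")
        if not 1 <= self.max_mh_bp <= 100:
            raise ConfigurationError("max_mh_bp must lie in [1, 100]")
        if self.pg_per_diploid_genome <= 0:
            raise ConfigurationError("pg_per_diploid_genome must be positive")

    def config_hash(self) -> str:
        def enc(o):
            if hasattr(o, "__dataclass_fields__"):
                return {k: enc(getattr(o, k)) for k in o.__dataclass_fields__}
            if isinstance(o, dict):
                return {k: enc(v) for k, v in sorted(o.items())}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            return o
        blob = json.dumps(enc(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_end_to_end(config: RunConfig) -> dict:
    """Execute simulate -> call -> stats and return the manifest."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    caught: list[str] = []
    manifest: dict = {"tool": "telofuseq", "version": _version(),
                      "config_hash": config.config_hash(), "counts": {},
                      "inputs": {}, "warnings": caught}

    all_truth, all_calls, all_fail = [], [], []
    genome_for_tracks = None
    with warnings.catch_warnings(record=True) as caught_w:
        warnings.simplefilter("always")
        for sid, panel, genome, events in simulate_cohort(
                config.n_samples, config.fusions, config.panel, config.genome,
                seed=config.seed):
            genome_for_tracks = genome
            r1, r2, truth = render_amplicon_reads(
                events, panel, genome, read_len=config.read_len,
                error_rate=config.error_rate, seed=config.seed,
                pairs_per_event=config.pairs_per_event)
            tt = pd.DataFrame([{
                "sample": sid, "event_id": e.event_id,
                "fusion_class": e.fusion_class,
                "ref_a": e.arm_a[0], "breakpoint_a": e.arm_a[1],
                "ref_b": e.arm_b[0], "breakpoint_b": e.arm_b[1],
                "mh_len": e.mh_len, "ins_seq": e.ins_seq or ".",
                "ins_templated": e.ins_templated,
                "deletion_a_kb": e.deletion_a_kb,
                "deletion_b_kb": e.deletion_b_kb} for e in events])
            all_truth.append(tt)
            panel.genome = genome
            calls, failures = call_sample(
                r1, r2, panel, k=config.k, min_arm_bp=config.min_arm_bp,
                max_mh_bp=config.max_mh_bp,
                template_window_bp=config.template_window_bp)
            log.info("%s: %d events, %d read pairs, %d calls, %d failures",
                     sid, len(events), len(r1), len(calls), len(failures))
            ct = calls_to_table(calls)
            ct.insert(0, "sample", sid)
            all_calls.append(ct)
            all_fail.extend((sid, f.read_id, f.reason) for f in failures)
        caught.extend(str(w.message) for w in caught_w)

    truth_df = pd.concat(all_truth, ignore_index=True)
    calls_df = pd.concat(all_calls, ignore_index=True)
    fail_df = pd.DataFrame(all_fail, columns=["sample", "read_id", "reason"])
    tio.write_table(truth_df, out / "truth.tsv")
    tio.write_table(calls_df, out / "calls.tsv")
    tio.write_table(fail_df, out / "failures.tsv")

    resolved = calls_df[calls_df["fusion_class"].isin(["intra", "inter", "genomic"])]
    props = tstats.class_proportions(calls_df)
    tio.write_table(props, out / "class_proportions.tsv")
    summary = tstats.summarize_junctions(calls_df)
    tio.write_table(summary, out / "junction_summary.tsv")

    genomic = calls_df[calls_df["fusion_class"] == "genomic"]
    chrom_lengths = genome_for_tracks.chrom_lengths
    positions = [(r.ref_b, int(r.breakpoint_b))
                 for r in genomic.itertuples(index=False)]
    if positions:
        enrich = tstats.chromosome_enrichment(positions, chrom_lengths)
        tio.write_table(enrich, out / "chromosome_enrichment.tsv")
        null = simulate_null_junction_positions(
            config.null_positions, chrom_lengths, seed=config.seed)
        rows = []
        for tname, track in genome_for_tracks.tracks.items():
            obs = tstats.feature_coincidence(positions, track)
            sim = tstats.feature_coincidence(null, track)
            cmpr = tstats.compare_coincidence(
                int(obs.loc[obs.label == "any", "coincident"].iloc[0]), len(positions),
                int(sim.loc[sim.label == "any", "coincident"].iloc[0]), len(null))
            rows.append({"track": tname,
                         "observed_prop": float(obs.loc[obs.label == "any",
                                                        "proportion"].iloc[0]),
                         "null_prop": float(sim.loc[sim.label == "any",
                                                    "proportion"].iloc[0]),
                         **cmpr})
        tio.write_table(pd.DataFrame(rows), out / "feature_coincidence.tsv")

    manifest["counts"] = {
        "samples": config.n_samples,
        "truth_events": int(len(truth_df)),
        "read_pairs": int((~truth_df_skipped(truth_df)).sum())
        if "skipped" in truth_df.columns else int(len(truth_df)),
        "calls": int(len(calls_df)),
        "resolved_calls": int(len(resolved)),
        "failures": int(len(fail_df)),
        "genomic_junctions": int(len(genomic)),
    }
    for p in sorted(out.glob("*.tsv")):
        manifest["inputs"][p.name] = _checksum(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def truth_df_skipped(truth_df: pd.DataFrame) -> pd.Series:
    if "skipped" in truth_df.columns:
        return truth_df["skipped"].astype(bool)
    return pd.Series(False, index=truth_df.index)


def _version() -> str:
    from . import __version__
    return __version__
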