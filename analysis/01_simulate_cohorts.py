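#!/usr/bin/env python
"""Simulate wild-type-like and POLQ-null-like fusion cohorts.

Two cohorts of clones transiting telomere crisis are emulated with the
class balances and junction chemistry the two genotypes display: the
mutant cohort halves the intra-chromosomal proportion, raises the
inter-chromosomal share, and shifts genomic junctions toward blunt ends
with slightly shorter microhomology. Reads and truth tables land in
scratch/sim/ (bulky, regenerated on demand); a per-sample truth summary
goes to results/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from telofuseq import io as tio
from telofuseq.simulate import (FusionSimConfig, ShiftedPoisson,
                                render_amplicon_reads, simulate_cohort)

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"

GROUPS = {
    # class mixture and junction chemistry per genotype
    "wt": FusionSimConfig(
        n_events=40,
        class_mixture={"intra": 0.30, "inter": 0.10, "genomic": 0.60},
        mh_length_distribution=ShiftedPoisson(4.5),
        ins_fraction=0.25, blunt_fraction=0.12),
    "polq_null": FusionSimConfig(
        n_events=40,
        class_mixture={"intra": 0.15, "inter": 0.35, "genomic": 0.50},
        mh_length_distribution=ShiftedPoisson(3.5),
        ins_fraction=0.25, blunt_fraction=0.20),
}
N_SAMPLES = 9
SEED = {"wt": 11, "polq_null": 13}


def main() -> None:
    rows = []
    for group, fcfg in GROUPS.items():
        for sid, panel, genome, events in simulate_cohort(
                N_SAMPLES, fcfg, seed=SEED[group]):
            sample_dir = SCRATCH / group / sid
            sample_dir.mkdir(parents=True, exist_ok=True)
            r1, r2, truth = render_amplicon_reads(events, panel, genome,
                                                  seed=SEED[group])
            tio.write_panel(panel, sample_dir / "panel.fa", sample_dir / "panel.tsv")
            tio.write_fasta(genome.sequences, sample_dir / "genome.fa")
            for name, track in genome.tracks.items():
                tio.write_features(track, sample_dir / f"{name}.bed")
            tio.write_fastq(r1, sample_dir / "R1.fastq")
            tio.write_fastq(r2, sample_dir / "R2.fastq")
            pd.DataFrame([{
                "group": group, "sample": sid, "event_id": e.event_id,
                "fusion_class": e.fusion_class, "ref_a": e.arm_a[0],
                "breakpoint_a": e.arm_a[1], "ref_b": e.arm_b[0],
                "breakpoint_b": e.arm_b[1], "mh_len": e.mh_len,
                "ins_seq": e.ins_seq or ".", "ins_templated": e.ins_templated,
                "deletion_a_kb": e.deletion_a_kb,
                "deletion_b_kb": e.deletion_b_kb,
            } for e in events]).to_csv(sample_dir / "truth.tsv", sep="\t",
                                       index=False)
            counts = pd.Series([e.fusion_class for e in events]).value_counts()
            rows.append({"group": group, "sample": sid,
                         "n_events": len(events),
                         **{f"n_{c}": int(counts.get(c, 0))
                            for c in ("intra", "inter", "genomic")}})
    RESULTS.mkdir(exist_ok=True)
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "01_cohort_summary.tsv", sep="\t", index=False)
    print(summary.groupby("group")[["n_intra", "n_inter", "n_genomic"]].sum())
    print(f"fixtures under {SCRATCH}")


if __name__ == "__main__":
    main()
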