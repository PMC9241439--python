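"""Format readers and writers shared by every stage.

FASTA/FASTQ go through Biopython; BED and the tabular formats are parsed
with explicit per-line validation so malformed records are reported with
their line number. All intervals are 0-based half-open on disk and in
memory; TSVs are UTF-8 with a header row and ``.`` for missing values.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import FeatureTrack, PanelEntry, ReferencePanel, SimGenome
from .errors import ParseError

MISSING = "."


# ---------------------------------------------------------------- FASTA/FASTQ

def write_fasta(sequences: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    """Write ``(read_id, sequence)`` pairs as Phred+33 FASTQ (quality 'I')."""
    records = []
    for read_id, seq in reads:
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


# ------------------------------------------------------------------------ BED

def read_features(path: str | os.PathLike, name: str | None = None) -> FeatureTrack:
    """Parse a BED file (>= 3 columns; 4th column, when present, is the label)."""
    intervals: list[tuple[str, int, int, str]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start:
                raise ParseError(f"{path}:{lineno}: end ({end}) must exceed start ({start})")
            label = fields[3] if len(fields) > 3 and fields[3] != MISSING else MISSING
            intervals.append((chrom, start, end, label))
    return FeatureTrack(name=name or os.path.basename(str(path)), intervals=intervals)


def write_features(track: FeatureTrack, path: str | os.PathLike) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for chrom, start, end, label in track.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")


# ---------------------------------------------------------------------- depth

def read_depth(path: str | os.PathLike) -> pd.DataFrame:
    """Read a bedGraph-like depth table (chrom, start, end, depth)."""
    rows = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 fields (chrom start end depth)")
            try:
                rows.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed depth record") from exc
            if rows[-1][2] <= rows[-1][1]:
                raise ParseError(f"{path}:{lineno}: end must exceed start")
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "depth"])


def write_depth(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[["chrom", "start", "end", "depth"]].to_csv(path, sep="\t", header=False, index=False)


# ----------------------------------------------------------------------- TSVs

def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[MISSING], keep_default_na=True)


# ---------------------------------------------------------------------- panel

def write_panel(panel: ReferencePanel, fasta_path: str | os.PathLike,
                meta_path: str | os.PathLike) -> None:
    write_fasta({e.name: e.sequence for e in panel.entries}, fasta_path)
    meta = pd.DataFrame(
        [(e.name, e.family, e.telomere_origin) for e in panel.entries],
        columns=["member", "family", "telomere_origin"],
    )
    write_table(meta, meta_path)


def read_panel(fasta_path: str | os.PathLike, meta_path: str | os.PathLike,
               genome: SimGenome | None = None) -> ReferencePanel:
    seqs = read_fasta(fasta_path)
    meta = read_table(meta_path)
    entries = []
    for row in meta.itertuples(index=False):
        if row.member not in seqs:
            raise ParseError(f"panel metadata names {row.member} absent from {fasta_path}")
        entries.append(PanelEntry(row.member, row.family, seqs[row.member],
                                  int(row.telomere_origin)))
    return ReferencePanel(entries=entries, genome=genome)


def read_genome(fasta_path: str | os.PathLike,
                track_paths: dict[str, str | os.PathLike] | None = None) -> SimGenome:
    genome = SimGenome(sequences=read_fasta(fasta_path))
    for name, p in (track_paths or {}).items():
        genome.tracks[name] = read_features(p, name=name)
    genome.validate()
    return genome
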