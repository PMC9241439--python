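"""Shared containers: reference panels, toy genomes and feature tracks.

Coordinates are 0-based half-open throughout; BED is the native interchange
format for intervals. Subtelomere panel entries are stored 5'->3' reading
telomere -> centromere, with ``telomere_origin`` marking the first
subtelomeric base (everything telomere-distal of it is telomere repeat
array). Chromatid deletion for a fusion arm is the distance from that origin
to the arm breakpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from intervaltree import IntervalTree

from .errors import ConfigurationError, DataError

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


@dataclass
class PanelEntry:
    """One subtelomere reference with its family label and telomere origin."""

    name: str
    family: str
    sequence: str
    telomere_origin: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.telomere_origin < len(self.sequence):
            raise DataError(
                f"telomere_origin {self.telomere_origin} outside sequence of "
                f"length {len(self.sequence)} for {self.name}"
            )


@dataclass
class ReferencePanel:
    """Subtelomere panel, optionally accompanied by a toy genome."""

    entries: list[PanelEntry]
    genome: "SimGenome | None" = None

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise DataError("panel entry names must be unique")

    def __iter__(self) -> Iterator[PanelEntry]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, name: str) -> PanelEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def families(self) -> dict[str, list[str]]:
        fams: dict[str, list[str]] = {}
        for e in self.entries:
            fams.setdefault(e.family, []).append(e.name)
        return fams

    def family_of(self, name: str) -> str:
        return self.get(name).family


@dataclass
class FeatureTrack:
    """Labelled genomic intervals (genes, fragile sites, repeat classes).

    ``intervals`` holds ``(chrom, start, end, label)`` tuples, 0-based
    half-open. Interval trees are built lazily per chromosome for point
    queries.
    """

    name: str
    intervals: list[tuple[str, int, int, str]] = field(default_factory=list)
    _trees: dict[str, IntervalTree] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        for chrom, start, end, _ in self.intervals:
            if end <= start:
                raise DataError(f"empty interval {chrom}:{start}-{end} in track {self.name}")

    def __len__(self) -> int:
        return len(self.intervals)

    def trees(self) -> dict[str, IntervalTree]:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for chrom, start, end, label in self.intervals:
                trees.setdefault(chrom, IntervalTree()).addi(start, end, label)
            self._trees = trees
        return self._trees

    def labels_at(self, chrom: str, pos: int) -> list[str]:
        tree = self.trees().get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.at(pos)]

    def covers(self, chrom: str, pos: int) -> bool:
        tree = self.trees().get(chrom)
        return tree is not None and bool(tree.at(pos))

    def coverage_bp(self, chrom_lengths: dict[str, int] | None = None) -> int:
        """Total covered bases after merging overlaps."""
        total = 0
        for chrom, tree in self.trees().items():
            merged = IntervalTree(tree)
            merged.merge_overlaps()
            for iv in merged:
                total += iv.end - iv.begin
        return total

    def validate_bounds(self, chrom_lengths: dict[str, int]) -> None:
        for chrom, start, end, _ in self.intervals:
            if chrom not in chrom_lengths:
                raise DataError(f"track {self.name}: unknown chromosome {chrom}")
            if start < 0 or end > chrom_lengths[chrom]:
                raise DataError(
                    f"track {self.name}: {chrom}:{start}-{end} outside chromosome bounds"
                )


@dataclass
class SimGenome:
    """Toy genome: chromosome sequences plus named feature tracks."""

    sequences: dict[str, str]
    tracks: dict[str, FeatureTrack] = field(default_factory=dict)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def validate(self) -> None:
        lengths = self.chrom_lengths
        for track in self.tracks.values():
            track.validate_bounds(lengths)


def validate_proportions(props: Iterable[float], what: str, tol: float = 1e-9) -> None:
    vals = list(props)
    if any(p < -tol or p > 1 + tol for p in vals):
        raise ConfigurationError(f"{what}: proportions must lie in [0,1]")
    if abs(sum(vals) - 1.0) > tol:
        raise ConfigurationError(f"{what}: proportions must sum to 1 (got {sum(vals)!r})")
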