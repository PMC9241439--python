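"""Seeded generators for every fixture the pipeline consumes.

The generators emulate the study design of a telomere-driven-crisis fusion
experiment: a small panel of subtelomere references (a unique 17p-like end, a
homologous 16p/21q-like family, and an XpYp-like end), fusion amplicons of
three classes (intra-chromosomal sister-chromatid fold-backs,
inter-chromosomal end-to-end fusions, and genomic fusions between a telomere
and a distant locus), paired amplicon reads, a toy genome with gene /
fragile-site / repeat tracks, uniform null junction positions, variant
allele frequency tables for clonality analysis, and satellite region depth
tables with class-specific expansion or contraction factors.

Junction chemistry is controlled by *planting*: the microhomology shared by
the two fusion partners, the stop bases that bound it, and the guard bases
that prevent accidental homology are written into the deleted-side margins
of the panel (and toy genome) sequences before amplicons are rendered, so
the emitted reads, the final references and the ground-truth records are
mutually consistent. The supplied panel/genome objects are updated in
place. Each event owns a disjoint "critical window" around each of its
breakpoints; windows never overlap between events, so one event's plants
cannot perturb another's chemistry.

Ground-truth breakpoints are stored in the canonical representation used by
the caller (junction placed leftmost on arm A's reference), because under
microhomology the physical placement is unidentifiable from sequence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (FeatureTrack, PanelEntry, ReferencePanel, SimGenome,
                   complement_base, revcomp, validate_proportions)
from .errors import ConfigurationError, InfeasibleError
from .rng import stream

BASES = "ACGT"
FUSION_CLASSES = ("intra", "inter", "genomic")

REPEAT_CLASS_WEIGHTS = {
    "LINE": 0.35, "SINE": 0.25, "LTR": 0.12, "DNA": 0.08, "STR": 0.06,
    "satellite": 0.05, "ALR": 0.04, "TAR": 0.02, "HSAT2": 0.015,
    "HSAT3": 0.015, "rDNA": 0.01,
}

SATELLITE_CLASSES = ("monomer", "HOR", "dHOR", "HSAT1", "HSAT2", "HSAT3",
                     "HSAT4", "HSAT5", "bSAT", "gSAT", "censat", "CT", "rDNA")


# ------------------------------------------------------------- distributions

@dataclass
class UniformInt:
    """Uniform integer on the closed interval [lo, hi]."""
    lo: int
    hi: int

    def __post_init__(self):
        if self.hi < self.lo:
            raise ConfigurationError("UniformInt requires hi >= lo")

    def sample(self, rng: np.random.Generator) -> int:
        return int(rng.integers(self.lo, self.hi + 1))

    @property
    def mean(self) -> float:
        return (self.lo + self.hi) / 2


@dataclass
class ShiftedPoisson:
    """shift + Poisson(mean - shift); a discrete distribution with a hard
    lower bound, used for microhomology lengths (>= 1 bp)."""
    mean: float
    shift: int = 1

    def __post_init__(self):
        if self.mean < self.shift:
            raise ConfigurationError("ShiftedPoisson mean must be >= shift")

    def sample(self, rng: np.random.Generator) -> int:
        return self.shift + int(rng.poisson(self.mean - self.shift))


@dataclass
class TruncExponential:
    """Exponential with the given mean, rejection-truncated to [lo, hi]."""
    mean: float
    lo: float = 0.0
    hi: float | None = None

    def sample(self, rng: np.random.Generator) -> float:
        for _ in range(1000):
            x = float(rng.exponential(self.mean))
            if x >= self.lo and (self.hi is None or x <= self.hi):
                return x
        raise InfeasibleError("truncated exponential rejection failed; check bounds")


def distribution_from_dict(d: dict) -> UniformInt | ShiftedPoisson | TruncExponential:
    kinds = {"uniform_int": UniformInt, "shifted_poisson": ShiftedPoisson,
             "trunc_exponential": TruncExponential}
    d = dict(d)
    kind = d.pop("kind", None)
    if kind not in kinds:
        raise ConfigurationError(f"unknown distribution kind {kind!r}")
    return kinds[kind](**d)


# ----------------------------------------------------------- panel generator

@dataclass
class SimPanelConfig:
    """Layout of the simulated subtelomere panel.

    Defaults emulate the chromosome ends used in crisis fusion assays: a
    unique 17p-like subtelomere, a homologous two-member 16p/21q-like family
    (>= 90% identity over the telomere-proximal 2 kb, so family-level
    ambiguity is a real feature of the data) and a unique XpYp-like end.
    """

    n_subtelomeres: int = 4
    subtelomere_length_bp: int = 12000
    families: list[tuple[str, list[str]]] = field(default_factory=lambda: [
        ("17p", ["17p"]),
        ("16p21q", ["16p", "21q"]),
        ("XpYp", ["XpYp"]),
    ])
    telomere_repeat: str = "TTAGGG"
    telomere_array_bp: int = 0
    homology_span_bp: int = 2000
    family_divergence: float = 0.025  # per-member substitution rate vs ancestor
    seed: int = 0

    def validate(self) -> None:
        if self.n_subtelomeres < 1 or self.subtelomere_length_bp < 1000:
            raise ConfigurationError("need >=1 subtelomere of >=1000 bp")
        members = [m for _, ms in self.families for m in ms]
        if len(members) != len(set(members)):
            raise ConfigurationError("member names must be unique")
        if len(members) != self.n_subtelomeres:
            raise ConfigurationError(
                f"families name {len(members)} members but n_subtelomeres="
                f"{self.n_subtelomeres}")
        if self.telomere_array_bp < 0:
            raise ConfigurationError("telomere_array_bp must be non-negative")
        if not self.telomere_repeat or set(self.telomere_repeat) - set(BASES):
            raise ConfigurationError("telomere_repeat must be a non-empty ACGT string")
        if not 0 <= self.family_divergence < 0.5:
            raise ConfigurationError("family_divergence must be in [0, 0.5)")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=n)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        out[i] = BASES[(BASES.index(out[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def build_subtelomere_panel(config: SimPanelConfig) -> ReferencePanel:
    """Generate the subtelomere reference panel.

    Members of one family are copies of a common ancestor over the
    telomere-proximal homology span (with a small per-member substitution
    rate) and are independent random sequence beyond it; different families
    are fully independent. Every entry is stored telomere -> centromere with
    ``telomere_origin`` at the subtelomere start (after any telomere array).
    """
    config.validate()
    rng = stream(config.seed, "panel")
    tel = (config.telomere_repeat * (config.telomere_array_bp //
           len(config.telomere_repeat) + 1))[: config.telomere_array_bp]
    span = min(config.homology_span_bp, config.subtelomere_length_bp)
    entries = []
    for family, members in config.families:
        ancestor = _random_seq(rng, span)
        for member in members:
            shared = (_mutate(rng, ancestor, config.family_divergence)
                      if len(members) > 1 else ancestor)
            private = _random_seq(rng, config.subtelomere_length_bp - span)
            entries.append(PanelEntry(
                name=member, family=family, sequence=tel + shared + private,
                telomere_origin=config.telomere_array_bp))
    return ReferencePanel(entries=entries)


# ---------------------------------------------------------- genome generator

@dataclass
class SimGenomeConfig:
    """Toy genome with human-like length variety and feature tracks."""

    chrom_lengths: dict[str, int] = field(default_factory=lambda: {
        "chr1": 100_000, "chr2": 80_000, "chr3": 60_000,
        "chr4": 40_000, "chr5": 20_000,
    })
    gene_coverage: float = 0.30
    fragile_site_coverage: float = 0.05
    repeat_coverage: float = 0.15
    repeat_class_weights: dict[str, float] = field(
        default_factory=lambda: dict(REPEAT_CLASS_WEIGHTS))
    seed: int = 0

    def validate(self) -> None:
        if not self.chrom_lengths or min(self.chrom_lengths.values()) < 1000:
            raise ConfigurationError("chromosomes must be >=1000 bp")
        for frac in (self.gene_coverage, self.fragile_site_coverage, self.repeat_coverage):
            if not 0 < frac < 1:
                raise ConfigurationError("track coverages must be in (0,1)")


def _random_track(rng, name, chrom_lengths, coverage, labels, weights,
                  len_lo=500, len_hi=3000) -> FeatureTrack:
    mean_len = (len_lo + len_hi) / 2
    mean_gap = mean_len * (1 - coverage) / coverage
    intervals = []
    for chrom, L in chrom_lengths.items():
        pos = 0
        while True:
            pos += int(rng.exponential(mean_gap))
            length = int(rng.integers(len_lo, len_hi + 1))
            if pos + length > L:
                break
            label = labels[int(rng.choice(len(labels), p=weights))] if labels else "."
            intervals.append((chrom, pos, pos + length, label))
            pos += length
    return FeatureTrack(name=name, intervals=intervals)


def build_toy_genome(config: SimGenomeConfig | None = None) -> SimGenome:
    """Generate a toy genome with gene, fragile-site and repeat tracks."""
    config = config or SimGenomeConfig()
    config.validate()
    rng = stream(config.seed, "genome")
    sequences = {c: _random_seq(rng, L) for c, L in config.chrom_lengths.items()}
    classes = list(config.repeat_class_weights)
    weights = np.array([config.repeat_class_weights[c] for c in classes], dtype=float)
    weights = weights / weights.sum()
    genome = SimGenome(sequences=sequences, tracks={
        "genes": _random_track(rng, "genes", config.chrom_lengths,
                               config.gene_coverage, None, None, 2000, 10000),
        "fragile_sites": _random_track(rng, "fragile_sites", config.chrom_lengths,
                                       config.fragile_site_coverage, None, None,
                                       800, 2500),
        "repeats": _random_track(rng, "repeats", config.chrom_lengths,
                                 config.repeat_coverage, classes, weights,
                                 300, 2000),
    })
    genome.validate()
    return genome


# --------------------------------------------------------- fusion simulation

@dataclass
class FusionSimConfig:
    """Controls for one simulated fusion-amplicon sample.

    Junction chemistry is exclusive per event: microhomology (MH, length
    drawn from ``mh_length_distribution``), insertion (INS, fraction
    ``ins_fraction``; templated from within ``template_window_bp`` of a
    breakpoint with probability ``ins_templated_fraction``) or blunt.
    The MH fraction is the remainder ``1 - ins_fraction - blunt_fraction``.
    """

    n_events: int = 40
    class_mixture: dict[str, float] = field(default_factory=lambda: {
        "intra": 0.25, "inter": 0.25, "genomic": 0.50})
    mh_length_distribution: ShiftedPoisson | UniformInt = field(
        default_factory=lambda: ShiftedPoisson(4.0))
    ins_fraction: float = 0.25
    ins_templated_fraction: float = 0.70
    ins_length_distribution: UniformInt | ShiftedPoisson = field(
        default_factory=lambda: UniformInt(5, 20))
    blunt_fraction: float = 0.15
    deletion_kb_distribution: TruncExponential = field(
        default_factory=lambda: TruncExponential(3.0, lo=0.1))
    template_window_bp: int = 50
    arm_length_bp: int = 200
    max_mh_bp: int = 25
    seed: int = 0

    @property
    def mh_fraction(self) -> float:
        return 1.0 - self.ins_fraction - self.blunt_fraction

    def validate(self) -> None:
        if self.n_events < 1:
            raise ConfigurationError("n_events must be positive")
        if set(self.class_mixture) - set(FUSION_CLASSES):
            raise ConfigurationError(f"classes must be among {FUSION_CLASSES}")
        validate_proportions(self.class_mixture.values(), "class_mixture")
        for frac in (self.ins_fraction, self.ins_templated_fraction, self.blunt_fraction):
            if not 0 <= frac <= 1:
                raise ConfigurationError("fractions must lie in [0,1]")
        if self.mh_fraction < -1e-9:
            raise ConfigurationError("ins_fraction + blunt_fraction exceed 1")
        if self.arm_length_bp < 100:
            raise ConfigurationError("arm_length_bp must be >= 100")
        if self.template_window_bp < 1:
            raise ConfigurationError("template_window_bp must be positive")


@dataclass
class GroundTruthJunction:
    """Simulator record pairing an amplicon with its true junction call.

    ``arm_a``/``arm_b`` are ``(reference_name, breakpoint, orientation)``
    with the breakpoint already in the caller's canonical (leftmost on arm
    A) representation. ``amplicon`` is the simulated fusion molecule in the
    canonical orientation's complement-free reading (arm B reversed on the
    left, arm A forward on the right).
    """

    event_id: str
    fusion_class: str
    arm_a: tuple[str, int, str]
    arm_b: tuple[str, int, str]
    mh_len: int
    ins_seq: str
    ins_templated: bool | None
    deletion_a_kb: float | None
    deletion_b_kb: float | None
    amplicon: str = ""

    def __post_init__(self):
        if self.mh_len > 0 and self.ins_seq:
            raise ValueError("an event cannot carry both MH and insertion")


class _Editor:
    """Mutable view of panel + genome sequences with disjoint critical
    windows: each fusion event reserves a window around each breakpoint and
    only ever writes inside its own windows."""

    def __init__(self, panel: ReferencePanel, genome: SimGenome | None):
        self.seqs: dict[str, bytearray] = {
            e.name: bytearray(e.sequence, "ascii") for e in panel.entries}
        if genome is not None:
            for c, s in genome.sequences.items():
                self.seqs[c] = bytearray(s, "ascii")
        self.windows: dict[str, list[tuple[int, int]]] = {}
        self.panel = panel
        self.genome = genome

    def reserve(self, ref: str, start: int, end: int) -> bool:
        taken = self.windows.setdefault(ref, [])
        if any(s < end and start < e for s, e in taken):
            return False
        taken.append((start, end))
        return True

    def release_last(self, ref: str, n: int) -> None:
        del self.windows[ref][-n:]

    def base(self, ref: str, pos: int) -> str:
        return chr(self.seqs[ref][pos])

    def fetch(self, ref: str, start: int, end: int) -> str:
        return self.seqs[ref][max(0, start):end].decode("ascii")

    def set_base(self, ref: str, pos: int, value: str) -> None:
        self.seqs[ref][pos] = ord(value)

    def set_avoiding(self, rng, ref: str, pos: int, forbidden: set[str]) -> None:
        allowed = [b for b in BASES if b not in forbidden]
        self.set_base(ref, pos, allowed[int(rng.integers(len(allowed)))])

    def writeback(self) -> None:
        for e in self.panel.entries:
            e.sequence = self.seqs[e.name].decode("ascii")
        if self.genome is not None:
            for c in self.genome.sequences:
                self.genome.sequences[c] = self.seqs[c].decode("ascii")


def _canonical_labels(name_r: str, bp_r: int, name_l: str, bp_l: int,
                      left_kind: str, mh: int, left_is_panel: bool,
                      right_is_panel: bool):
    """Resolve the canonical arm labelling for a junction.

    The amplicon is rendered with the "right" arm forward and the "left"
    arm reversed. Two labellings describe the same molecule; arm A is the
    panel arm (genomic fusions), else the panel arm with the smaller
    reference name, with intra ties broken by the smaller breakpoint tuple.
    Under labelling 1 (right arm is A) the junction sits leftmost on the
    right arm's reference: A bp = bp_r - mh and the left arm gives up its
    mh bases; under labelling 2 (left arm is A, read flipped) A bp = bp_l
    and B bp = bp_r. Returns (arm_a, arm_b, flipped).
    """
    def retract_left(bp: int, t: int) -> int:
        # left arm retracted by t bases away from the junction
        if left_kind == "panel_rev":
            return bp + t
        if left_kind == "gen_fwd":
            return bp - t
        return bp + t  # gen_rev

    # orientation labels are reference-strand-faithful in the reported frame:
    # flipping the read (opt2) inverts both arms' orientations
    left_ori = "forward" if left_kind == "gen_fwd" else "reverse"
    flip = {"forward": "reverse", "reverse": "forward"}
    opt1 = ((name_r, bp_r - mh, "forward"), (name_l, retract_left(bp_l, mh), left_ori))
    opt2 = ((name_l, bp_l, flip[left_ori]), (name_r, bp_r, "reverse"))
    if right_is_panel and not left_is_panel:
        return opt1 + (False,)
    if left_is_panel and not right_is_panel:
        return opt2 + (True,)
    if name_r < name_l:
        return opt1 + (False,)
    if name_l < name_r:
        return opt2 + (True,)
    # intra: same member; deterministic tie-break on breakpoint tuples
    key1 = (opt1[0][1], opt1[1][1])
    key2 = (opt2[0][1], opt2[1][1])
    return (opt1 + (False,)) if key1 <= key2 else (opt2 + (True,))


def simulate_fusion_events(panel: ReferencePanel, genome: SimGenome | None,
                           config: FusionSimConfig) -> list[GroundTruthJunction]:
    """Simulate one sample's fusion events with controlled junction chemistry.

    Plants microhomology / guard bases into the deleted-side margins of the
    supplied panel (and genome) sequences — the panel and genome are updated
    in place so that rendered amplicons, references and truth records stay
    mutually consistent. Returns one ground-truth record per event.
    """
    config.validate()
    if not panel.entries:
        raise ConfigurationError("panel must be non-empty")
    if config.class_mixture.get("genomic", 0) > 0 and genome is None:
        raise ConfigurationError("genomic events requested but no genome supplied")

    rng = stream(config.seed, "fusion-events")
    editor = _Editor(panel, genome)
    arm = config.arm_length_bp
    # protected zone around each junction: covers planted margins, guard and
    # stop bases, seed anchors, and the templating flank windows; arm
    # interiors outside the zone may overlap other events' zones because
    # amplicons are rendered only after every edit is in place
    wpad = max(80, config.template_window_bp + config.max_mh_bp + 5)

    classes = [c for c in FUSION_CLASSES if config.class_mixture.get(c, 0) > 0]
    probs = np.array([config.class_mixture[c] for c in classes])
    probs = probs / probs.sum()
    chem_p = np.array([config.mh_fraction, config.ins_fraction, config.blunt_fraction])
    chem_p = np.clip(chem_p, 0, None) / np.clip(chem_p, 0, None).sum()

    members = [e.name for e in panel.entries]
    fam_of = {e.name: e.family for e in panel.entries}
    origin = {e.name: e.telomere_origin for e in panel.entries}
    chroms = list(genome.sequences) if genome is not None else []
    chrom_w = (np.array([len(genome.sequences[c]) for c in chroms], dtype=float)
               if genome is not None else None)

    def draw_panel_breakpoint(member: str) -> int | None:
        length = len(editor.seqs[member])
        lo = max(origin[member] + 100, wpad)
        hi = length - arm - wpad
        if hi <= lo:
            raise ConfigurationError(
                f"subtelomere {member} too short for arm_length_bp={arm}")
        for _ in range(200):
            dkb = config.deletion_kb_distribution.sample(rng)
            b = origin[member] + int(round(dkb * 1000))
            if not lo <= b <= hi:
                continue
            if editor.reserve(member, b - wpad, b + wpad):
                return b
        return None

    def draw_genomic_arm() -> tuple[str, int, str] | None:
        for _ in range(200):
            chrom = chroms[int(rng.choice(len(chroms), p=chrom_w / chrom_w.sum()))]
            L = len(editor.seqs[chrom])
            strand = "gen_fwd" if rng.random() < 0.5 else "gen_rev"
            if strand == "gen_fwd":
                g = int(rng.integers(arm + wpad, L - wpad))
            else:
                g = int(rng.integers(wpad, L - arm - wpad))
            if editor.reserve(chrom, g - wpad, g + wpad):
                return chrom, g, strand
        return None

    specs: list[dict] = []
    for idx in range(config.n_events):
        fclass = classes[int(rng.choice(len(classes), p=probs))]
        placed = False
        for _attempt in range(50):
            # --- geometry ----------------------------------------------------
            if fclass == "intra":
                m = members[int(rng.integers(len(members)))]
                name_r, name_l = m, m
            elif fclass == "inter":
                fams = {}
                for mm in members:
                    fams.setdefault(fam_of[mm], []).append(mm)
                if len(fams) < 2:
                    raise ConfigurationError("inter events need >=2 families")
                f1, f2 = rng.choice(len(fams), size=2, replace=False)
                fam_names = list(fams)
                name_r = str(rng.choice(fams[fam_names[f1]]))
                name_l = str(rng.choice(fams[fam_names[f2]]))
            else:
                name_r = members[int(rng.integers(len(members)))]
                name_l = None  # genomic arm drawn below

            bp_r = draw_panel_breakpoint(name_r)
            if bp_r is None:
                continue
            if fclass == "genomic":
                ga = draw_genomic_arm()
                if ga is None:
                    editor.release_last(name_r, 1)
                    continue
                name_l, bp_l, left_kind = ga
            else:
                bp_l = draw_panel_breakpoint(name_l)
                if bp_l is None:
                    editor.release_last(name_r, 1)
                    continue
                left_kind = "panel_rev"
            placed = True
            break
        if not placed:
            raise InfeasibleError(
                "could not place fusion event; reduce n_events or enlarge references")

        # --- chemistry: all reads and writes stay inside this event's
        # protected zones, so earlier/later events cannot perturb it --------
        def left_tail(n: int) -> str:
            # last n bases of the left segment (junction-proximal)
            if left_kind == "gen_fwd":
                return editor.fetch(name_l, bp_l - n, bp_l)
            return revcomp(editor.fetch(name_l, bp_l, bp_l + n))

        chem = ("mh", "ins", "blunt")[int(rng.choice(3, p=chem_p))]
        mh = 0
        ins = ""
        templated: bool | None = None

        if chem == "mh":
            mh = min(config.mh_length_distribution.sample(rng), config.max_mh_bp)
            tail = left_tail(mh + 1)
            # plant: the last mh bases of the left segment become the
            # deleted-side margin of the right arm, so they extend both arms
            for i, b in enumerate(tail[1:]):
                editor.set_base(name_r, bp_r - mh + i, b)
            # stop base bounds the shared run at exactly mh
            editor.set_avoiding(rng, name_r, bp_r - mh - 1, {tail[0]})
            _guard_left(editor, rng, name_l, bp_l, left_kind,
                        next_base=editor.base(name_r, bp_r))
        elif chem == "blunt":
            editor.set_avoiding(rng, name_r, bp_r - 1, {left_tail(1)})
            _guard_left(editor, rng, name_l, bp_l, left_kind,
                        next_base=editor.base(name_r, bp_r))
        else:
            ins, templated = _sample_insertion(
                editor, rng, config, name_r, bp_r, name_l, bp_l, left_kind)

        specs.append(dict(idx=idx, fclass=fclass, name_r=name_r, bp_r=bp_r,
                          name_l=name_l, bp_l=bp_l, left_kind=left_kind,
                          mh=mh, ins=ins, templated=templated))

    # --- pass B: render amplicons and canonical truth from final sequences -
    events: list[GroundTruthJunction] = []
    for sp in specs:
        name_r, bp_r = sp["name_r"], sp["bp_r"]
        name_l, bp_l, left_kind = sp["name_l"], sp["bp_l"], sp["left_kind"]
        mh, ins = sp["mh"], sp["ins"]
        if left_kind == "gen_fwd":
            lseg = editor.fetch(name_l, bp_l - arm, bp_l)
        else:
            lseg = revcomp(editor.fetch(name_l, bp_l, bp_l + arm))
        amplicon = lseg + ins + editor.fetch(name_r, bp_r, bp_r + arm)

        arm_a, arm_b, flipped = _canonical_labels(
            name_r, bp_r, name_l, bp_l, left_kind, mh,
            left_is_panel=(left_kind == "panel_rev"), right_is_panel=True)
        truth_ins = revcomp(ins) if flipped else ins

        def deletion(arm_ref: str, bp: int) -> float | None:
            if arm_ref in origin:
                return (bp - origin[arm_ref]) / 1000.0
            return None

        events.append(GroundTruthJunction(
            event_id=f"ev{sp['idx']:06d}", fusion_class=sp["fclass"],
            arm_a=arm_a, arm_b=arm_b, mh_len=mh, ins_seq=truth_ins,
            ins_templated=sp["templated"],
            deletion_a_kb=deletion(arm_a[0], arm_a[1]),
            deletion_b_kb=deletion(arm_b[0], arm_b[1]),
            amplicon=amplicon))

    editor.writeback()
    return events


def _guard_left(editor: _Editor, rng, name_l: str, bp_l: int, left_kind: str,
                next_base: str) -> None:
    """Prevent the left arm's reference continuation from matching the first
    amplicon base after the junction (which would add spurious MH)."""
    if left_kind == "gen_fwd":
        editor.set_avoiding(rng, name_l, bp_l, {next_base})
    elif left_kind == "gen_rev":
        editor.set_avoiding(rng, name_l, bp_l - 1, {complement_base(next_base)})
    else:
        editor.set_avoiding(rng, name_l, bp_l - 1, {complement_base(next_base)})


def _flank_windows(editor: _Editor, config: FusionSimConfig, name_r, bp_r,
                   name_l, bp_l) -> list[str]:
    w = config.template_window_bp
    return [editor.fetch(name_r, bp_r - w, bp_r + w),
            editor.fetch(name_l, bp_l - w, bp_l + w)]


def _sample_insertion(editor, rng, config: FusionSimConfig, name_r, bp_r,
                      name_l, bp_l, left_kind) -> tuple[str, bool]:
    """Draw an insertion (templated from a surviving-side window, or random
    and verifiably absent from both flanks) and apply the guard bases that
    keep it unassignable to either arm."""
    w = config.template_window_bp
    for _ in range(100):
        length = max(1, config.ins_length_distribution.sample(rng))
        templated = bool(rng.random() < config.ins_templated_fraction)
        if templated:
            # copy from the surviving side of either breakpoint, either strand
            if rng.random() < 0.5:
                window = editor.fetch(name_r, bp_r, bp_r + w)
            elif left_kind == "gen_fwd":
                window = editor.fetch(name_l, bp_l - w, bp_l)
            else:
                window = editor.fetch(name_l, bp_l, bp_l + w)
            if len(window) <= length:
                continue
            start = int(rng.integers(0, len(window) - length))
            ins = window[start:start + length]
            if rng.random() < 0.5:
                ins = revcomp(ins)
        else:
            ins = _random_seq(rng, length)
        # guards: the insertion must extend neither arm
        editor.set_avoiding(rng, name_r, bp_r - 1, {ins[-1]})
        _guard_left(editor, rng, name_l, bp_l, left_kind, next_base=ins[0])
        flanks = _flank_windows(editor, config, name_r, bp_r, name_l, bp_l)
        present = any(ins in f or revcomp(ins) in f for f in flanks)
        if templated and present:
            return ins, True
        if not templated and not present:
            return ins, False
        # templated copy lost to a guard edit, or random insert found by
        # chance: resample
    raise InfeasibleError("could not sample a consistent insertion sequence")


# ------------------------------------------------------------ read rendering

def render_amplicon_reads(events: Sequence[GroundTruthJunction],
                          panel: ReferencePanel, genome: SimGenome | None,
                          read_len: int = 150, error_rate: float = 0.0,
                          seed: int = 0, pairs_per_event: int = 1
                          ) -> tuple[list[tuple[str, str]], list[tuple[str, str]], pd.DataFrame]:
    """Render paired junction-spanning reads for each event.

    Returns ``(r1_records, r2_records, truth_table)`` where the records are
    ``(read_id, sequence)`` and the truth table links every read pair to its
    event (with a ``skipped`` flag for events whose amplicon is shorter than
    the read length).
    """
    if read_len < 50:
        raise ConfigurationError("read_len must be >= 50")
    if not 0 <= error_rate <= 0.05:
        raise ConfigurationError("error_rate must lie in [0, 0.05]")
    rng = stream(seed, "reads")
    r1, r2, rows = [], [], []
    for ev in events:
        amp = ev.amplicon
        if len(amp) < read_len:
            rows.append((ev.event_id, ".", True))
            continue
        # arms have equal length, so the junction (plus half the insertion)
        # sits at the amplicon midpoint
        jmid = len(amp) // 2
        frag = min(int(1.2 * read_len) + len(ev.ins_seq), len(amp))
        start = min(max(jmid - frag // 2, 0), len(amp) - frag)
        for p in range(pairs_per_event):
            rid = f"{ev.event_id}/p{p}"
            s1 = _with_errors(rng, amp[start:start + read_len], error_rate)
            s2 = _with_errors(rng, revcomp(amp[start + frag - read_len:start + frag]),
                              error_rate)
            r1.append((rid, s1))
            r2.append((rid, s2))
            rows.append((ev.event_id, rid, False))
    truth = pd.DataFrame(rows, columns=["event_id", "read_id", "skipped"])
    return r1, r2, truth


def _with_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i in np.nonzero(rng.random(len(seq)) < rate)[0]:
        out[i] = BASES[(BASES.index(out[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


# ------------------------------------------------------------ null positions

def simulate_null_junction_positions(n: int, chrom_lengths: dict[str, int],
                                     excluded: FeatureTrack | None = None,
                                     seed: int = 0) -> list[tuple[str, int]]:
    """Draw junction positions uniformly over all non-excluded bases."""
    if n < 1:
        raise ConfigurationError("n must be positive")
    rng = stream(seed, "null-junctions")
    usable: list[tuple[str, np.ndarray, np.ndarray]] = []
    weights = []
    for chrom, L in chrom_lengths.items():
        mask_ivs = []
        if excluded is not None:
            tree = excluded.trees().get(chrom)
            if tree is not None:
                merged = tree.copy()
                merged.merge_overlaps()
                mask_ivs = sorted((iv.begin, iv.end) for iv in merged)
        starts, ends, pos = [], [], 0
        for s, e in mask_ivs:
            s, e = max(0, s), min(L, e)
            if s > pos:
                starts.append(pos)
                ends.append(s)
            pos = max(pos, e)
        if pos < L:
            starts.append(pos)
            ends.append(L)
        lengths = np.array(ends) - np.array(starts) if starts else np.array([])
        usable.append((chrom, np.array(starts), lengths))
        weights.append(lengths.sum() if len(lengths) else 0)
    total = float(sum(weights))
    if total <= 0:
        raise InfeasibleError("exclusion mask covers the whole genome")
    p = np.array(weights, dtype=float) / total
    counts = rng.multinomial(n, p)
    out: list[tuple[str, int]] = []
    for (chrom, starts, lengths), k in zip(usable, counts):
        if k == 0:
            continue
        cum = np.concatenate([[0], np.cumsum(lengths)])
        offs = rng.integers(0, cum[-1], size=k)
        idx = np.searchsorted(cum, offs, side="right") - 1
        for o, i in zip(offs, idx):
            out.append((chrom, int(starts[i] + (o - cum[i]))))
    return out


# ---------------------------------------------------------------- VAF tables

def simulate_vaf_table(n_variants: int, subclone_fractions: Sequence[float],
                       depth: int, seed: int = 0,
                       sample_id: str = "sim") -> pd.DataFrame:
    """Simulate unique-variant allele frequencies for clonality analysis.

    Each variant is private to one subclone (heterozygous within it), so its
    expected VAF is half the subclone's population fraction; read support is
    binomial at the stated depth. A single fraction of 1.0 yields the
    monoclonal case (VAF centred on 0.5).
    """
    if depth < 1:
        raise ConfigurationError("depth must be positive")
    if n_variants < 1:
        raise ConfigurationError("n_variants must be positive")
    fracs = np.asarray(list(subclone_fractions), dtype=float)
    if len(fracs) == 0 or np.any(fracs <= 0) or fracs.sum() > 1 + 1e-9:
        raise ConfigurationError("subclone fractions must be positive and sum to <= 1")
    rng = stream(seed, "vaf")
    assign = rng.integers(0, len(fracs), size=n_variants)
    expected = fracs[assign] / 2.0
    alt = rng.binomial(depth, expected)
    ref = depth - alt
    return pd.DataFrame({
        "sample": sample_id,
        "chrom": "chr1",
        "pos": np.arange(n_variants) * 100 + 50,
        "ref_count": ref,
        "alt_count": alt,
        "vaf": alt / depth,
    })


# --------------------------------------------------------------- depth table

def build_satellite_regions(classes: Sequence[str] = SATELLITE_CLASSES,
                            n_per_class: int = 200,
                            region_bp: int = 1000) -> FeatureTrack:
    """Lay out labelled satellite regions back-to-back on one contig per
    class (a stand-in for a satellite mini-reference)."""
    intervals = []
    for cls in classes:
        for i in range(n_per_class):
            intervals.append((f"sat_{cls}", i * region_bp, (i + 1) * region_bp, cls))
    return FeatureTrack(name="satellite_regions", intervals=intervals)


def simulate_region_depths(regions: FeatureTrack,
                           class_scalings: dict[str, float] | None,
                           base_depth: float, dispersion: float,
                           seed: int = 0, sample_id: str = "sim") -> "pd.DataFrame":
    """Simulate per-region mean read depths.

    Depth for a region of class c is ``base_depth * scaling(c)`` times a
    mean-one log-normal factor with log-scale dispersion ``dispersion``
    (dispersion 0 gives exact depths). Classes without an explicit scaling
    default to 1.0.
    """
    scalings = dict(class_scalings or {})
    for v in scalings.values():
        if v <= 0:
            raise ConfigurationError("class scalings must be positive")
    if base_depth <= 0:
        raise ConfigurationError("base_depth must be positive")
    if dispersion < 0:
        raise ConfigurationError("dispersion must be non-negative")
    rng = stream(seed, f"depth-{sample_id}")
    rows = []
    for i, (chrom, start, end, label) in enumerate(regions.intervals):
        scale = scalings.get(label, 1.0)
        noise = (float(rng.lognormal(-dispersion ** 2 / 2, dispersion))
                 if dispersion > 0 else 1.0)
        rows.append((f"r{i:05d}", chrom, start, end, label,
                     base_depth * scale * noise))
    df = pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end",
                                     "class", "mean_depth"])
    df.insert(0, "sample", sample_id)
    return df


# ------------------------------------------------------------- cohort helper

def simulate_cohort(n_samples: int, fusion_config: FusionSimConfig,
                    panel_config: SimPanelConfig | None = None,
                    genome_config: SimGenomeConfig | None = None,
                    seed: int = 0):
    """Yield ``(sample_id, panel, genome, events)`` for independent samples.

    Each sample receives its own fresh panel/genome realisation (same
    configuration, sample-specific seed), mirroring a cohort of clones each
    sequenced from its own pool of fusion PCR amplicons.
    """
    panel_config = panel_config or SimPanelConfig()
    genome_config = genome_config or SimGenomeConfig()
    for s in range(n_samples):
        pcfg = SimPanelConfig(**{**panel_config.__dict__})
        gcfg = SimGenomeConfig(**{**genome_config.__dict__})
        fcfg = FusionSimConfig(**{**fusion_config.__dict__})
        pcfg.seed = seed * 10007 + s
        gcfg.seed = seed * 10007 + s
        fcfg.seed = seed * 10007 + s
        panel = build_subtelomere_panel(pcfg)
        genome = build_toy_genome(gcfg)
        events = simulate_fusion_events(panel, genome, fcfg)
        yield f"clone{s:02d}", panel, genome, events
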