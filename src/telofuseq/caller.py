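"""Resolve fusion amplicon read pairs into junction calls.

Each read pair is decomposed into two *arms* — maximal ungapped matches to
the subtelomere panel or the toy genome found by k-mer seeding on both
strands and base-wise extension. The junction between the arms is then
characterised: microhomology (MH) is the overlap of the two arms' maximal
exact extensions across the junction (bases compatible with both
references), an insertion (INS) is the run of read bases assignable to
neither arm, and a junction with neither is blunt.

Because the physical junction placement is unidentifiable under MH, calls
are canonicalised: the junction is placed leftmost on arm A's reference,
where arm A is the panel arm (genomic fusions) or the panel arm with the
smaller reference name (ties on intra fusions broken by the smaller
breakpoint tuple). Fusion classes follow the assay's definitions: intra
(both arms on one panel member, or on members of one homologous family,
flagged as family-ambiguous), inter (panel arms of different families) and
genomic (exactly one arm on the panel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import ReferencePanel, SimGenome, complement_base, revcomp
from .errors import ConfigurationError, InputError

DEFAULT_K = 15
DEFAULT_MIN_ARM = 30
DEFAULT_MAX_MH = 25
DEFAULT_TEMPLATE_WINDOW = 50


# ----------------------------------------------------------------- seed index

class SeedIndex:
    """Exact k-mer index over the panel entries and the toy genome.

    Forward k-mers are stored; lookups query both the k-mer and its reverse
    complement so hits on both strands are returned. Repeated k-mers retain
    every position.
    """

    def __init__(self, panel: ReferencePanel, k: int = DEFAULT_K):
        if not 8 <= k <= 31:
            raise ConfigurationError("k must lie in [8, 31]")
        self.k = k
        self.panel = panel
        self.refs: dict[str, str] = {e.name: e.sequence for e in panel.entries}
        self.panel_names = set(self.refs)
        genome = panel.genome
        if genome is not None:
            self.refs.update(genome.sequences)
        shortest = min(len(s) for s in self.refs.values())
        if k > shortest:
            raise ConfigurationError(
                f"k={k} exceeds the shortest reference ({shortest} bp)")
        index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.refs.items():
            for i in range(len(seq) - k + 1):
                index.setdefault(seq[i:i + k], []).append((name, i))
        self._index = index

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        """All (reference, offset, strand) occurrences of ``kmer``."""
        hits = [(n, p, "+") for n, p in self._index.get(kmer, ())]
        hits += [(n, p, "-") for n, p in self._index.get(revcomp(kmer), ())]
        return hits

    def is_panel(self, name: str) -> bool:
        return name in self.panel_names


def index_panel(panel: ReferencePanel, k: int = DEFAULT_K) -> SeedIndex:
    return SeedIndex(panel, k)


# ------------------------------------------------------------------ alignment

@dataclass
class ArmAlignment:
    reference_name: str
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    orientation: str  # 'forward' | 'reverse'
    match_score: int
    family_ambiguous: bool = False


@dataclass
class FailureRecord:
    read_id: str
    reason: str  # 'no-seed' | 'single-arm' | 'ambiguous' | 'excessive-overlap' | ...


@dataclass
class JunctionCall:
    read_id: str
    arm_a: ArmAlignment
    arm_b: ArmAlignment
    fusion_class: str  # 'intra' | 'inter' | 'genomic' | 'unresolved'
    mh_len: int
    ins_seq: str
    ins_templated: bool | None
    blunt: bool
    deletion_a_kb: float | None
    deletion_b_kb: float | None
    asymmetry_kb: float | None
    breakpoint_a: int
    breakpoint_b: int
    flags: list[str] = field(default_factory=list)


class _Chain:
    """Seeds sharing one (reference, strand, diagonal)."""

    __slots__ = ("name", "strand", "diag", "seeds", "cover_start", "cover_end",
                 "score", "in_lo", "in_hi", "out_lo", "out_hi", "ambiguous")

    def __init__(self, name, strand, diag, seeds, k):
        self.name, self.strand, self.diag = name, strand, diag
        self.seeds = sorted(seeds)
        self.cover_start = self.seeds[0]
        self.cover_end = self.seeds[-1] + k
        # merged seed coverage
        cov, last = 0, -1
        for i in self.seeds:
            s, e = max(i, last), i + k
            if e > s:
                cov += e - s
            last = max(last, e)
        self.score = cov

    def ref_coord(self, read_pos: int) -> int:
        return self.diag + read_pos if self.strand == "+" else self.diag - read_pos


def _collect_chains(seq: str, index: SeedIndex) -> list[_Chain]:
    k = index.k
    groups: dict[tuple[str, str, int], list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if "N" in kmer:
            continue
        for name, p, strand in index.lookup(kmer):
            diag = p - i if strand == "+" else p + k - 1 + i
            groups.setdefault((name, strand, diag), []).append(i)
    return [_Chain(name, strand, diag, seeds, k)
            for (name, strand, diag), seeds in groups.items()]


def _ref_base(index: SeedIndex, name: str, strand: str, coord: int) -> str | None:
    seq = index.refs[name]
    if not 0 <= coord < len(seq):
        return None
    b = seq[coord]
    return b if strand == "+" else complement_base(b)


def _extend_exact(seq, index, chain, read_pos, direction) -> int:
    """Extend base-by-base from ``read_pos`` (first unchecked position);
    returns the exclusive boundary reached in ``direction`` (+1/-1)."""
    x = read_pos
    while 0 <= x < len(seq):
        rb = _ref_base(index, chain.name, chain.strand, chain.ref_coord(x))
        if rb is None or seq[x] != rb or seq[x] == "N":
            break
        x += direction
    return x


def _refine(seq, index, chain) -> None:
    """Attach exact extension boundaries: inner (junction-facing both ways)
    and outer limits from the outermost seeds."""
    first, last = chain.seeds[0], chain.seeds[-1]
    chain.out_lo = _extend_exact(seq, index, chain, first - 1, -1) + 1
    chain.in_hi = _extend_exact(seq, index, chain, last + index.k, +1)  # exclusive
    chain.in_lo = _extend_exact(seq, index, chain, first - 1, -1) + 1
    chain.out_hi = chain.in_hi


def align_arms(read_pair, index: SeedIndex,
               min_arm_bp: int = DEFAULT_MIN_ARM,
               max_mh_bp: int = DEFAULT_MAX_MH):
    """Find the two junction arms of a read pair.

    Tries each mate in turn and returns ``(left_chain, right_chain, mate_seq)``
    for the first mate that yields a valid arm pair, else a
    :class:`FailureRecord` reason string. Arms may therefore come from either
    mate; both mates observe the same junction in our amplicon geometry.
    """
    reads = [read_pair] if isinstance(read_pair, str) else list(read_pair)
    if not reads or any(not r for r in reads):
        raise InputError("empty read")
    reason = "no-seed"
    for seq in reads:
        chains = _collect_chains(seq, index)
        if not chains:
            continue
        chains.sort(key=lambda c: (-c.score, c.name, c.strand, c.diag))
        chains = chains[:40]
        for c in chains:
            _refine(seq, index, c)
        strong = [c for c in chains if c.score >= min_arm_bp]
        if not strong:
            reason = "no-seed" if reason == "no-seed" else reason
            continue
        best, best_total, tie_with = None, -1, None
        for x in strong:
            for y in strong:
                if x is y or x.cover_start > y.cover_start:
                    continue
                if x is not y and x.cover_start == y.cover_start and \
                        (x.name, x.strand, x.diag) >= (y.name, y.strand, y.diag):
                    continue
                overlap = x.cover_end - y.cover_start
                if overlap > max_mh_bp + 2:
                    continue
                total = x.score + y.score - max(0, overlap)
                if total > best_total:
                    best, best_total, tie_with = (x, y), total, None
                elif total == best_total and best is not None and \
                        {x.name, y.name} != {best[0].name, best[1].name}:
                    tie_with = (x, y)
        if best is None:
            reason = "single-arm"
            continue
        left, right = best
        if tie_with is not None:
            tl, tr = tie_with
            fams = index.panel.families
            same_family = all(
                _same_family(index, a.name, b.name)
                for a, b in ((left, tl), (right, tr)))
            if not same_family:
                reason = "ambiguous"
                continue
        _flag_family_ties(index, strong, left)
        _flag_family_ties(index, strong, right)
        return left, right, seq
    return FailureRecord(read_id="", reason=reason)


def _same_family(index: SeedIndex, a: str, b: str) -> bool:
    if not (index.is_panel(a) and index.is_panel(b)):
        return a == b
    fams = index.panel.families
    fam = {m: f for f, ms in fams.items() for m in ms}
    return fam[a] == fam[b]


def _flag_family_ties(index: SeedIndex, chains, chosen) -> None:
    """Mark an arm ambiguous when a same-family homolog matches nearly as
    well (within one seed length): over the homology span the true member is
    not reliably distinguishable, and a homolog can even outscore it by
    absorbing a junction base, so near-ties are surfaced rather than
    silently resolved."""
    chosen.ambiguous = False
    if not index.is_panel(chosen.name):
        return
    for c in chains:
        if c is chosen or c.name == chosen.name:
            continue
        if not index.is_panel(c.name) or not _same_family(index, c.name, chosen.name):
            continue
        ol = min(c.cover_end, chosen.cover_end) - max(c.cover_start, chosen.cover_start)
        span = chosen.cover_end - chosen.cover_start
        if ol >= 0.8 * span and c.score >= chosen.score - (index.k + 5):
            chosen.ambiguous = True
            return


# ----------------------------------------------------------------- resolution

def _arm_alignment(chain) -> ArmAlignment:
    lo, hi = chain.in_lo, chain.in_hi
    if chain.strand == "+":
        ref_lo, ref_hi = chain.ref_coord(lo), chain.ref_coord(hi - 1) + 1
        orientation = "forward"
    else:
        ref_lo, ref_hi = chain.ref_coord(hi - 1), chain.ref_coord(lo) + 1
        orientation = "reverse"
    return ArmAlignment(chain.name, ref_lo, ref_hi, lo, hi, orientation,
                        chain.score, getattr(chain, "ambiguous", False))


def resolve_junction(left, right, read: str, panel: ReferencePanel,
                     index: SeedIndex, read_id: str = "",
                     max_mh_bp: int = DEFAULT_MAX_MH,
                     template_window_bp: int = DEFAULT_TEMPLATE_WINDOW):
    """Characterise the junction between two aligned arms and emit the
    canonical :class:`JunctionCall` (or a :class:`FailureRecord`)."""
    e_left = left.in_hi      # left arm's maximal exact boundary (exclusive)
    s_right = right.in_lo    # right arm's maximal exact start
    mh = max(0, e_left - s_right)
    if mh > max_mh_bp:
        return FailureRecord(read_id=read_id, reason="excessive-overlap")
    ins = read[e_left:s_right] if s_right > e_left else ""
    if "N" in ins:
        return FailureRecord(read_id=read_id, reason="insertion-contains-N")

    # junction-proximal reference boundaries (strand-aware: a breakpoint is
    # the boundary of the arm's maximal extension, retracted towards its own
    # side when the ambiguous MH bases are assigned to the other arm)
    left_panel = index.is_panel(left.name)
    right_panel = index.is_panel(right.name)
    if not left_panel and not right_panel:
        return FailureRecord(read_id=read_id, reason="no-panel-arm")

    def right_bp(retract: int) -> int:
        r0 = right.ref_coord(s_right)
        return r0 + retract if right.strand == "+" else r0 + 1 - retract

    def left_bp(retract: int) -> int:
        l_jp = left.ref_coord(e_left - 1)
        return l_jp + retract if left.strand == "-" else l_jp + 1 - retract

    opt1 = ((right.name, right_bp(0), "forward"), (left.name, left_bp(mh), "reverse"))
    opt2 = ((left.name, left_bp(0), "forward"), (right.name, right_bp(mh), "reverse"))

    if right_panel and not left_panel:
        arm_a_t, arm_b_t, a_is_right = opt1[0], opt1[1], True
    elif left_panel and not right_panel:
        arm_a_t, arm_b_t, a_is_right = opt2[0], opt2[1], False
    elif right.name < left.name:
        arm_a_t, arm_b_t, a_is_right = opt1[0], opt1[1], True
    elif left.name < right.name:
        arm_a_t, arm_b_t, a_is_right = opt2[0], opt2[1], False
    else:
        k1 = (opt1[0][1], opt1[1][1])
        k2 = (opt2[0][1], opt2[1][1])
        if k1 <= k2:
            arm_a_t, arm_b_t, a_is_right = opt1[0], opt1[1], True
        else:
            arm_a_t, arm_b_t, a_is_right = opt2[0], opt2[1], False

    ins_canonical = ins if a_is_right else revcomp(ins)
    a_chain, b_chain = (right, left) if a_is_right else (left, right)
    arm_a = _arm_alignment(a_chain)
    arm_b = _arm_alignment(b_chain)
    if not a_is_right:  # reported frame is the flipped read
        flip = {"forward": "reverse", "reverse": "forward"}
        arm_a.orientation = flip[arm_a.orientation]
        arm_b.orientation = flip[arm_b.orientation]
    bp_a, bp_b = arm_a_t[1], arm_b_t[1]

    call = JunctionCall(
        read_id=read_id, arm_a=arm_a, arm_b=arm_b, fusion_class="unresolved",
        mh_len=mh, ins_seq=ins_canonical,
        ins_templated=None, blunt=(mh == 0 and not ins),
        deletion_a_kb=None, deletion_b_kb=None, asymmetry_kb=None,
        breakpoint_a=bp_a, breakpoint_b=bp_b)
    if arm_a.family_ambiguous or arm_b.family_ambiguous:
        call.flags.append("family-ambiguous")
    call.fusion_class = classify_fusion(call, panel)
    if ins_canonical:
        call.ins_templated = detect_local_template(
            ins_canonical,
            _flank(index, arm_a.reference_name, bp_a, template_window_bp),
            _flank(index, arm_b.reference_name, bp_b, template_window_bp),
            template_window_bp)
    deletion_a, deletion_b, asym = chromatid_deletions(call, panel)
    call.deletion_a_kb, call.deletion_b_kb, call.asymmetry_kb = deletion_a, deletion_b, asym
    return call


def _flank(index: SeedIndex, name: str, bp: int, window: int) -> str:
    seq = index.refs[name]
    return seq[max(0, bp - window):bp + window]


def classify_fusion(call: JunctionCall, panel: ReferencePanel) -> str:
    """Apply the assay's class definitions to a resolved call."""
    names = {e.name for e in panel.entries}
    fam = {e.name: e.family for e in panel.entries}
    a, b = call.arm_a.reference_name, call.arm_b.reference_name
    a_on, b_on = a in names, b in names
    if a_on and b_on:
        if a == b or fam[a] == fam[b]:
            if a != b and "family-ambiguous" not in call.flags:
                call.flags.append("family-ambiguous")
            return "intra"
        return "inter"
    if a_on != b_on:
        return "genomic"
    return "unresolved"


def detect_local_template(ins_seq: str, flank_a: str, flank_b: str,
                          window_bp: int = DEFAULT_TEMPLATE_WINDOW):
    """True iff the insertion occurs exactly, on either strand, within either
    breakpoint's flank window; ``None`` (not applicable) for empty insertions."""
    if not ins_seq:
        return None
    rc = revcomp(ins_seq)
    for flank in (flank_a, flank_b):
        if ins_seq in flank or rc in flank:
            return True
    return False


def chromatid_deletions(call: JunctionCall, panel: ReferencePanel):
    """Deletion (kb) of each fused chromatid: distance from the panel entry's
    telomere origin to the arm breakpoint. Undefined (None) for genomic arms;
    asymmetry is the absolute difference when both are defined."""
    from .errors import DataError

    names = {e.name: e for e in panel.entries}

    def one(ref: str, bp: int) -> float | None:
        entry = names.get(ref)
        if entry is None:
            return None
        if bp < entry.telomere_origin:
            raise DataError(
                f"breakpoint {bp} telomere-distal of origin "
                f"{entry.telomere_origin} on {ref}")
        return (bp - entry.telomere_origin) / 1000.0

    da = one(call.arm_a.reference_name, call.breakpoint_a)
    db = one(call.arm_b.reference_name, call.breakpoint_b)
    asym = abs(da - db) if da is not None and db is not None else None
    return da, db, asym


# -------------------------------------------------------------- sample-level

def call_read_pair(read_id: str, mate1: str, mate2: str | None,
                   index: SeedIndex, panel: ReferencePanel,
                   min_arm_bp: int = DEFAULT_MIN_ARM,
                   max_mh_bp: int = DEFAULT_MAX_MH,
                   template_window_bp: int = DEFAULT_TEMPLATE_WINDOW):
    pair = (mate1,) if mate2 is None else (mate1, mate2)
    res = align_arms(pair, index, max_mh_bp=max_mh_bp)
    if isinstance(res, FailureRecord):
        res.read_id = read_id
        return res
    left, right, seq = res
    if left.score < min_arm_bp or right.score < min_arm_bp:
        return FailureRecord(read_id=read_id, reason="single-arm")
    return resolve_junction(left, right, seq, panel, index, read_id=read_id,
                            max_mh_bp=max_mh_bp,
                            template_window_bp=template_window_bp)


def call_sample(r1, r2, panel: ReferencePanel, k: int = DEFAULT_K,
                min_arm_bp: int = DEFAULT_MIN_ARM,
                max_mh_bp: int = DEFAULT_MAX_MH,
                template_window_bp: int = DEFAULT_TEMPLATE_WINDOW):
    """Call every read pair of a sample.

    ``r1``/``r2`` are lists of ``(read_id, sequence)``; returns
    ``(calls, failures)``.
    """
    index = index_panel(panel, k)
    by_id = {rid: [seq, None] for rid, seq in r1}
    for rid, seq in (r2 or []):
        by_id.setdefault(rid, [None, None])[1] = seq
    calls, failures = [], []
    for rid, (m1, m2) in by_id.items():
        if m1 is None:
            m1, m2 = m2, None
        out = call_read_pair(rid, m1, m2, index, panel, min_arm_bp,
                             max_mh_bp, template_window_bp)
        (calls if isinstance(out, JunctionCall) else failures).append(out)
    return calls, failures


def calls_to_table(calls: list[JunctionCall]):
    """Tidy TSV-ready table of junction calls."""
    import pandas as pd

    rows = []
    for c in calls:
        rows.append({
            "read_id": c.read_id, "fusion_class": c.fusion_class,
            "ref_a": c.arm_a.reference_name, "breakpoint_a": c.breakpoint_a,
            "ref_b": c.arm_b.reference_name, "breakpoint_b": c.breakpoint_b,
            "arm_a_ref_start": c.arm_a.ref_start, "arm_a_ref_end": c.arm_a.ref_end,
            "arm_b_ref_start": c.arm_b.ref_start, "arm_b_ref_end": c.arm_b.ref_end,
            "mh_len": c.mh_len, "ins_seq": c.ins_seq or ".",
            "ins_templated": c.ins_templated,
            "blunt": c.blunt, "deletion_a_kb": c.deletion_a_kb,
            "deletion_b_kb": c.deletion_b_kb, "asymmetry_kb": c.asymmetry_kb,
            "flags": ";".join(c.flags) or ".",
        })
    return pd.DataFrame(rows)
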