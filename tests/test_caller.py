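"""Caller correctness: indexing, arm finding, junction chemistry, classes."""

import numpy as np
import pytest

from telofuseq import caller
from telofuseq.caller import (FailureRecord, JunctionCall, SeedIndex,
                              call_read_pair, call_sample, chromatid_deletions,
                              classify_fusion, detect_local_template, index_panel)
from telofuseq.core import PanelEntry, ReferencePanel, revcomp, complement_base
from telofuseq.errors import ConfigurationError


def _rand_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _mini_panel(seed=0, n=2, length=400, families=None):
    rng = np.random.default_rng(seed)
    names = [f"P{i}" for i in range(n)]
    families = families or names
    return ReferencePanel(entries=[
        PanelEntry(nm, fam, _rand_seq(rng, length), 0)
        for nm, fam in zip(names, families)])


class TestSeedIndex:
    def test_every_kmer_retrievable_at_true_offset(self):
        panel = _mini_panel(seed=1, n=1, length=1000)
        idx = index_panel(panel, k=15)
        seq = panel.entries[0].sequence
        for i in range(0, len(seq) - 15 + 1, 7):
            hits = idx.lookup(seq[i:i + 15])
            assert ("P0", i, "+") in hits

    def test_duplicated_kmer_returns_all_hits(self):
        rng = np.random.default_rng(2)
        core = _rand_seq(rng, 20)
        a = _rand_seq(rng, 100) + core + _rand_seq(rng, 100)
        b = _rand_seq(rng, 50) + core + _rand_seq(rng, 150)
        panel = ReferencePanel(entries=[PanelEntry("A", "fa", a, 0),
                                        PanelEntry("B", "fb", b, 0)])
        idx = index_panel(panel, k=20)
        # independent oracle: enumerate occurrences by scanning
        expected = {(nm, s.find(core), "+") for nm, s in (("A", a), ("B", b))}
        assert expected <= set(idx.lookup(core))

    def test_reverse_strand_hits(self):
        panel = _mini_panel(seed=3, n=1, length=200)
        idx = index_panel(panel, k=15)
        kmer = panel.entries[0].sequence[50:65]
        assert ("P0", 50, "-") in idx.lookup(revcomp(kmer))

    def test_k_exceeding_reference_rejected(self):
        panel = ReferencePanel(entries=[PanelEntry("S", "f", "ACGT" * 5, 0)])
        with pytest.raises(ConfigurationError):
            index_panel(panel, k=31)  # reference shorter than k
        with pytest.raises(ConfigurationError):
            index_panel(panel, k=51)  # k outside the supported range


class TestAlignArms:
    def test_two_arm_read_found_at_true_offsets(self):
        panel = _mini_panel(seed=4, n=2, length=400)
        idx = index_panel(panel, k=15)
        a, b = panel.entries[0].sequence, panel.entries[1].sequence
        read = revcomp(b[100:170]) + a[200:270]
        left, right, seq = caller.align_arms(read, idx)
        assert right.name == "P0" and right.strand == "+"
        assert right.ref_coord(right.in_lo) == 200
        assert left.name == "P1" and left.strand == "-"

    def test_single_reference_read_fails(self):
        panel = _mini_panel(seed=5, n=2, length=400)
        idx = index_panel(panel, k=15)
        res = caller.align_arms(panel.entries[0].sequence[50:190], idx)
        assert isinstance(res, FailureRecord)
        assert res.reason == "single-arm"

    def test_all_N_read_fails_no_seed(self):
        panel = _mini_panel(seed=6)
        idx = index_panel(panel, k=15)
        res = caller.align_arms("N" * 120, idx)
        assert isinstance(res, FailureRecord)
        assert res.reason == "no-seed"

    def test_empty_read_rejected(self):
        panel = _mini_panel(seed=7)
        idx = index_panel(panel, k=15)
        with pytest.raises(Exception):
            caller.align_arms("", idx)


def _build_junction_panel(left_tail: str, right_head: str, seed=0,
                          left_next: str = None, right_prev: str = None):
    """Two references whose junction-adjacent sequence is hand-specified:
    P1 carries ``left_tail`` ending at position 200; P2 carries
    ``right_head`` starting at position 200."""
    rng = np.random.default_rng(seed)
    p1 = _rand_seq(rng, 400)
    p2 = _rand_seq(rng, 400)
    p1 = p1[:200 - len(left_tail)] + left_tail + (left_next or p1[200]) + p1[201:]
    p2 = p2[:199] + (right_prev or p2[199]) + right_head + p2[200 + len(right_head):]
    return ReferencePanel(entries=[PanelEntry("P1", "f1", p1, 0),
                                   PanelEntry("P2", "f2", p2, 0)])


class TestResolveJunction:
    def test_blunt_junction(self):
        panel = _mini_panel(seed=8, n=2, length=400)
        a, b = panel.entries[0].sequence, panel.entries[1].sequence
        # abutting arms; guard both continuations so no chance MH
        read = a[120:200] + b[200:280]
        if a[200] == b[200]:  # avoid accidental extension of the left arm
            read = a[120:200] + b[201:281]
        idx = index_panel(panel, k=15)
        call = call_read_pair("r", read, None, idx, panel)
        if isinstance(call, JunctionCall):
            assert call.mh_len + len(call.ins_seq) <= 2  # chance homology only

    def test_planted_microhomology_of_four(self):
        """Flank ending ...ACGTAC meeting a flank starting GTACGG with read
        ...ACGTACGG... resolves to mh_len = 4 ('GTAC')."""
        panel = _build_junction_panel("ACGTAC", "GTACGG", seed=9,
                                      left_next="T", right_prev="G")
        p1, p2 = panel.entries[0].sequence, panel.entries[1].sequence
        # amplicon orientation: left arm = P1 forward is not a telomere
        # geometry; instead present P1's segment reversed on the left
        read = revcomp(p1[60:200]) if False else p1[60:200] + p2[202:340]
        # left arm P1 forward ends ...ACGTAC at 200; right arm P2 from 202
        # skips its first two bases 'GT' which the read shares via 'GTAC'?
        # Use the direct construction: read carries ACGTAC then GG
        read = p1[60:200] + p2[204:340]
        # read around junction: ...ACGTAC | GG...  (GTAC shared)
        idx = index_panel(panel, k=15)
        res = caller.align_arms(read, idx)
        left, right, seq = res
        call = caller.resolve_junction(left, right, seq, panel, idx, "r")
        assert isinstance(call, JunctionCall)
        assert call.mh_len == 4
        assert call.ins_seq == ""

    def test_untemplated_insertion_called(self):
        """Read bases between the arm matches, absent from both flanks
        (verified by exhaustive string search), are called as an insertion
        with mh_len 0 and ins_templated False."""
        ins = "TGTGCAAGGA"
        for attempt in range(20):
            panel = _mini_panel(seed=100 + attempt, n=2, length=400)
            a, b = panel.entries[0].sequence, panel.entries[1].sequence
            window = a[150:250] + "|" + b[150:250]
            if (ins in window or revcomp(ins) in window
                    or a[199] == ins[-1] or b[199] == ins[-1]
                    or a[200] == ins[0] or b[200] == ins[0]):
                continue
            read = a[120:200] + ins + b[200:280]
            idx = index_panel(panel, k=15)
            call = call_read_pair("r", read, None, idx, panel)
            assert isinstance(call, JunctionCall)
            assert call.mh_len == 0
            assert call.ins_seq in (ins, revcomp(ins))
            assert call.ins_templated is False
            return
        pytest.fail("no conflict-free fixture found")

    def test_mh_matches_bruteforce_oracle_on_sample(self, called_sample):
        """Reported mh_len equals an independent brute-force scan over all
        junction placements for every resolved call of a simulated sample."""
        panel, genome, events, r1, r2, calls, failures = called_sample
        refs = {e.name: e.sequence for e in panel.entries} | genome.sequences
        amp = {e.event_id: e.amplicon for e in events}
        truth = {e.event_id: e for e in events}
        for c in calls:
            if "family-ambiguous" in c.flags:
                continue
            ev = truth[c.read_id.split("/")[0]]
            a = amp[ev.event_id]
            mh = _bruteforce_mh(a, refs, ev)
            assert c.mh_len == mh, (c.read_id, c.mh_len, mh)

    def test_exclusivity_invariant(self, called_sample):
        *_, calls, _ = called_sample
        for c in calls:
            states = [c.mh_len > 0, len(c.ins_seq) > 0, c.blunt]
            assert sum(states) == 1


def _bruteforce_mh(amplicon: str, refs: dict, ev) -> int:
    """Independent oracle: slide a split point across the molecule and count
    placements where the prefix is explainable by arm B's reference (in its
    reported orientation) and the suffix by arm A's forward sequence. The
    molecule is tried in both frames because truth records are stored in the
    canonical frame, which may be the reverse complement of the rendered
    amplicon."""
    (ref_a, bp_a, _), (ref_b, bp_b, ori_b) = ev.arm_a, ev.arm_b
    if ev.ins_seq:
        return 0

    def splits(mol: str) -> list[int]:
        a_ref, b_ref = refs[ref_a], refs[ref_b]
        valid = []
        for s in range(len(mol) + 1):
            suf, pre = mol[s:], mol[:s]
            ok_a = any(a_ref[t:t + len(suf)] == suf
                       for t in range(max(0, bp_a - 30), bp_a + 31))
            if not ok_a:
                continue
            if ori_b == "reverse":
                ok_b = any(revcomp(b_ref[t:t + len(pre)]) == pre
                           for t in range(max(0, bp_b - 30), bp_b + 31))
            else:
                ok_b = any(b_ref[t - len(pre):t] == pre
                           for t in range(max(0, bp_b - 30), bp_b + 31)
                           if t - len(pre) >= 0)
            if ok_b:
                valid.append(s)
        return valid

    for mol in (amplicon, revcomp(amplicon)):
        v = splits(mol)
        if v:
            return max(v) - min(v)
    return 0


class TestClassification:
    def test_same_member_is_intra(self, called_sample):
        panel, _, events, *_ , calls, _ = called_sample
        for c in calls:
            if (c.arm_a.reference_name == c.arm_b.reference_name
                    and c.arm_a.reference_name in {e.name for e in panel.entries}):
                assert c.fusion_class == "intra"

    def test_distinct_families_are_inter_and_single_arm_is_genomic(self):
        panel = _mini_panel(seed=11, n=2, length=400)

        def mkcall(ref_a, ref_b):
            arm = caller.ArmAlignment(ref_a, 0, 10, 0, 10, "forward", 10)
            armb = caller.ArmAlignment(ref_b, 0, 10, 10, 20, "reverse", 10)
            return JunctionCall("r", arm, armb, "unresolved", 0, "", None,
                                True, None, None, None, 5, 5)

        assert classify_fusion(mkcall("P0", "P1"), panel) == "inter"
        assert classify_fusion(mkcall("P0", "chrZ"), panel) == "genomic"
        assert classify_fusion(mkcall("chrY", "chrZ"), panel) == "unresolved"

    def test_family_members_classified_intra_with_flag(self):
        panel = _mini_panel(seed=12, n=2, length=400, families=["fam", "fam"])
        arm = caller.ArmAlignment("P0", 0, 10, 0, 10, "forward", 10)
        armb = caller.ArmAlignment("P1", 0, 10, 10, 20, "reverse", 10)
        call = JunctionCall("r", arm, armb, "unresolved", 0, "", None, True,
                            None, None, None, 5, 5)
        assert classify_fusion(call, panel) == "intra"
        assert "family-ambiguous" in call.flags


class TestLocalTemplate:
    def test_planted_template_found(self):
        rng = np.random.default_rng(13)
        ins = "GGCTA"
        flank_a = _rand_seq(rng, 33) + ins + _rand_seq(rng, 12)  # 12 bp upstream
        flank_b = _rand_seq(rng, 50)
        assert detect_local_template(ins, flank_a, flank_b, 50) is True

    def test_absent_insert_is_untemplated(self):
        flank = "GC" * 50  # no run of A's anywhere
        assert detect_local_template("AAAAA", flank, flank, 50) is False

    def test_empty_insert_not_applicable(self):
        assert detect_local_template("", "ACGT", "ACGT", 50) is None

    def test_reverse_strand_template_found(self):
        rng = np.random.default_rng(14)
        ins = "GGCTAAC"
        flank = _rand_seq(rng, 20) + revcomp(ins) + _rand_seq(rng, 20)
        assert detect_local_template(ins, flank, "", 50) is True


class TestChromatidDeletions:
    def _call(self, panel, ref_a, bp_a, ref_b, bp_b):
        arm = caller.ArmAlignment(ref_a, 0, 10, 0, 10, "forward", 10)
        armb = caller.ArmAlignment(ref_b, 0, 10, 10, 20, "reverse", 10)
        return JunctionCall("r", arm, armb, "intra", 0, "", None, True,
                            None, None, None, bp_a, bp_b)

    def test_simple_arithmetic(self):
        panel = _mini_panel(seed=15, n=2, length=6000)
        da, db, asym = chromatid_deletions(
            self._call(panel, "P0", 3500, "P0", 5000), panel)
        assert da == 3.5 and db == 5.0 and asym == 1.5

    def test_genomic_arm_undefined(self):
        panel = _mini_panel(seed=16, n=2, length=6000)
        da, db, asym = chromatid_deletions(
            self._call(panel, "P0", 3500, "chr1", 999), panel)
        assert da == 3.5 and db is None and asym is None

    def test_breakpoint_before_origin_is_data_error(self):
        from telofuseq.errors import DataError
        panel = ReferencePanel(entries=[
            PanelEntry("P0", "f", "ACGT" * 1000, telomere_origin=300)])
        with pytest.raises(DataError):
            chromatid_deletions(self._call(panel, "P0", 100, "P0", 400), panel)


class TestGroundTruthRecovery:
    def test_recovery_and_palindrome_rates(self):
        """Error-free recovery of class/MH/insertion/deletions across a
        cohort; intra fold-back reads resolve at the same rate as inter."""
        from telofuseq.simulate import (FusionSimConfig, render_amplicon_reads,
                                        simulate_cohort)

        resolved = {"intra": 0, "inter": 0}
        total = {"intra": 0, "inter": 0}
        bad = unflagged = n = 0
        fcfg = FusionSimConfig(n_events=40,
                               class_mixture={"intra": 1 / 3, "inter": 1 / 3,
                                              "genomic": 1 / 3})
        for sid, panel, genome, events in simulate_cohort(10, fcfg, seed=31):
            r1, r2, _ = render_amplicon_reads(events, panel, genome, seed=31)
            panel.genome = genome
            calls, failures = call_sample(r1, r2, panel)
            truth = {e.event_id: e for e in events}
            for f in failures:
                ev = truth[f.read_id.split("/")[0]]
                if ev.fusion_class in total:
                    total[ev.fusion_class] += 1
            for c in calls:
                n += 1
                ev = truth[c.read_id.split("/")[0]]
                if ev.fusion_class in total:
                    total[ev.fusion_class] += 1
                    resolved[ev.fusion_class] += 1
                ok = (c.fusion_class == ev.fusion_class
                      and c.mh_len == ev.mh_len and c.ins_seq == ev.ins_seq
                      and c.deletion_a_kb == ev.deletion_a_kb
                      and c.deletion_b_kb == ev.deletion_b_kb)
                if not ok:
                    bad += 1
                    if "family-ambiguous" not in c.flags:
                        unflagged += 1
        assert n >= 390
        assert bad / n <= 0.01
        assert unflagged == 0
        assert resolved["intra"] / total["intra"] == resolved["inter"] / total["inter"] == 1.0
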