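"""Alignment, variant tallying, structural masks and support filters."""

import numpy as np
import pytest

from ampliclone.calling import (
    align_read,
    apply_structural_masks,
    call_variants,
    calls_table,
    report_variants,
    tally_variants,
)
from ampliclone.panel import AmpliconDef, revcomp
from ampliclone.reads import FORWARD, REVERSE, ProcessedRead
from ampliclone.variant import (
    DEL,
    HOMOPOLYMER,
    INS,
    PRIMER_ADJACENT,
    SUB,
    CallingParams,
    VariantCall,
    VariantKey,
)

MATCH, MISMATCH, OPEN, EXTEND = 1, -2, -4, -1


def toy_amplicon(insert, amplicon_id="TOY"):
    fwd, tail = "GGCACT", "AGTCCG"
    return AmpliconDef(
        amplicon_id=amplicon_id,
        gene="TOY",
        exon="1",
        reference_seq=fwd + insert + tail,
        primer_fwd=fwd,
        primer_rev=revcomp(tail),
        coding_offset=len(fwd),
        codon_start_number=1,
    )


def gotoh_score(a, b):
    """Independent affine-gap global alignment score (open = first gap base)."""
    neg = float("-inf")
    n, m = len(a), len(b)
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (deletion from a)
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (insertion)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = OPEN + (i - 1) * EXTEND
    for j in range(1, m + 1):
        Y[0][j] = OPEN + (j - 1) * EXTEND
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + OPEN, X[i - 1][j] + EXTEND, Y[i - 1][j] + OPEN)
            Y[i][j] = max(M[i][j - 1] + OPEN, Y[i][j - 1] + EXTEND, X[i][j - 1] + OPEN)
    return max(M[n][m], X[n][m], Y[n][m])


def ops_score(insert_len, ops):
    subs = sum(1 for o in ops if o[0] == SUB)
    score = 0
    del_bases = 0
    for var_type, _, ref, alt in ops:
        if var_type == DEL:
            del_bases += len(ref)
            score += OPEN + (len(ref) - 1) * EXTEND
        elif var_type == INS:
            score += OPEN + (len(alt) - 1) * EXTEND
    score += (insert_len - del_bases - subs) * MATCH + subs * MISMATCH
    return score


def apply_ops(ref, ops, shift=0):
    """Reconstruct the payload implied by ops (positions on reference coords)."""
    seq = list(ref)
    for var_type, pos, r, a in sorted(ops, key=lambda o: -o[1]):
        p = pos - shift
        if var_type == SUB:
            seq[p] = a
        elif var_type == DEL:
            del seq[p : p + len(r)]
        else:
            seq[p + 1 : p + 1] = list(a)
    return "".join(seq)


def make_read(amp, payload, orientation=FORWARD, read_id="r"):
    return ProcessedRead(read_id, "s", amp.amplicon_id, orientation, payload, (33,) * len(payload), 33.0)


class TestAlignRead:
    def test_identity(self, amp):
        assert align_read(amp.insert, amp) == []

    def test_single_substitution_position(self, amp):
        insert = amp.insert
        payload = insert[:24] + ("A" if insert[24] != "A" else "C") + insert[25:]
        ops = align_read(payload, amp)
        shift = amp.insert_span[0]
        assert ops == [(SUB, 24 + shift, insert[24], payload[24])]

    def test_deletion_left_aligned_in_run(self, amp):
        # KRAS exon-2 insert has an AAAA run at insert offset 58
        insert = amp.insert
        run_start = insert.find("AAAA")
        payload = insert[: run_start + 2] + insert[run_start + 3 :]  # delete 3rd A
        ops = align_read(payload, amp)
        assert len(ops) == 1
        var_type, pos, ref, alt = ops[0]
        assert var_type == DEL and ref == "A"
        assert pos == run_start + amp.insert_span[0]  # leftmost placement

    def test_insertion_left_aligned_and_anchored(self, amp):
        insert = amp.insert
        run_start = insert.find("AAAA")
        payload = insert[: run_start + 2] + "A" + insert[run_start + 2 :]
        ops = align_read(payload, amp)
        assert len(ops) == 1
        var_type, pos, ref, alt = ops[0]
        assert var_type == INS and alt == "A"
        assert pos == run_start + amp.insert_span[0] - 1  # anchor just before the run

    @pytest.mark.parametrize("seed", range(8))
    def test_optimality_against_gotoh_oracle(self, seed):
        """Extracted ops reconstruct the payload and achieve the optimal
        affine-gap score computed by an independent dynamic program."""
        rng = np.random.default_rng(seed)
        insert = "".join(rng.choice(list("ACGT"), 20))
        amp = toy_amplicon(insert)
        payload = list(insert)
        for _ in range(rng.integers(1, 4)):
            kind = rng.integers(3)
            p = int(rng.integers(len(payload)))
            if kind == 0:
                payload[p] = "ACGT"[rng.integers(4)]
            elif kind == 1 and len(payload) > 5:
                del payload[p]
            else:
                payload.insert(p, "ACGT"[rng.integers(4)])
        payload = "".join(payload)
        ops = align_read(payload, amp)
        # ops are equivalent on the full reference (indels at the insert edge
        # may left-normalise into the primer)
        lo, hi = amp.insert_span
        expected_full = amp.reference_seq[:lo] + payload + amp.reference_seq[hi:]
        assert apply_ops(amp.reference_seq, ops) == expected_full
        assert ops_score(len(insert), ops) == gotoh_score(insert, payload)

    def test_empty_payload_errors(self, amp):
        with pytest.raises(Exception):
            align_read("", amp)


class TestTally:
    def test_wild_type_reads_only_depth(self, amp):
        reads = [make_read(amp, amp.insert, FORWARD, f"r{i}") for i in range(60)] + [
            make_read(amp, amp.insert, REVERSE, f"q{i}") for i in range(40)
        ]
        counts, df, dr = tally_variants(reads, amp)
        assert counts == {} and (df, dr) == (60, 40)

    def test_substitution_counts_and_depth(self, amp):
        insert = amp.insert
        mut = insert[:10] + ("T" if insert[10] != "T" else "G") + insert[11:]
        reads = [make_read(amp, insert, FORWARD, f"r{i}") for i in range(95)]
        reads += [make_read(amp, mut, FORWARD if i < 3 else REVERSE, f"m{i}") for i in range(5)]
        counts, df, dr = tally_variants(reads, amp)
        key = VariantKey(amp.amplicon_id, 10 + amp.insert_span[0], insert[10], mut[10], SUB)
        assert counts[key] == [3, 2]
        assert df + dr == 100

    def test_two_alt_alleles_are_two_clones(self, amp):
        insert = amp.insert
        base = insert[15]
        alts = [b for b in "ACGT" if b != base][:2]
        reads = [make_read(amp, insert, FORWARD, f"r{i}") for i in range(10)]
        for j, alt in enumerate(alts):
            mut = insert[:15] + alt + insert[16:]
            reads += [make_read(amp, mut, FORWARD, f"m{j}{i}") for i in range(3)]
        counts, _, _ = tally_variants(reads, amp)
        assert len(counts) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_bruteforce_diff_oracle_on_toy_amplicon(self, seed):
        """Tallies on a 24-bp toy amplicon match per-read expected edits."""
        rng = np.random.default_rng(100 + seed)
        insert = "".join(rng.choice(list("ACGT"), 24))
        amp = toy_amplicon(insert)
        shift = amp.insert_span[0]
        expected: dict[VariantKey, list[int]] = {}
        reads = []
        for i in range(50):
            if rng.random() < 0.5:
                reads.append(make_read(amp, insert, FORWARD, f"wt{i}"))
                continue
            p = int(rng.integers(2, len(insert) - 2))
            base = insert[p]
            alt = "ACGT"[(("ACGT".index(base)) + 1) % 4]
            payload = insert[:p] + alt + insert[p + 1 :]
            orient = FORWARD if rng.random() < 0.5 else REVERSE
            reads.append(make_read(amp, payload, orient, f"m{i}"))
            key = VariantKey(amp.amplicon_id, p + shift, base, alt, SUB)
            expected.setdefault(key, [0, 0])[0 if orient == FORWARD else 1] += 1
        counts, _, _ = tally_variants(reads, amp)
        assert counts == expected


class TestMasks:
    def test_primer_adjacent_margin(self, amp):
        params = CallingParams()
        lo = amp.insert_span[0]
        keys = [
            VariantKey(amp.amplicon_id, lo, amp.reference_seq[lo], "A", SUB),       # 1 base in
            VariantKey(amp.amplicon_id, lo + 5, amp.reference_seq[lo + 5], "A", SUB),
        ]
        masks = apply_structural_masks(keys, amp, params)
        assert PRIMER_ADJACENT in masks[keys[0]]
        assert masks[keys[1]] == frozenset()

    def test_homopolymer_indel_masked(self, panel):
        amp = next(a for a in panel if a.amplicon_id == "KRAS_EX3")  # TTTTT run
        run_start = amp.reference_seq.find("TTTTT")
        params = CallingParams()
        dele = VariantKey(amp.amplicon_id, run_start + 1, "T", "", DEL)
        ins = VariantKey(amp.amplicon_id, run_start - 1, "", "T", INS)  # left-normalised anchor
        sub_in = VariantKey(amp.amplicon_id, run_start + 2, "T", "A", SUB)
        masks = apply_structural_masks([dele, ins, sub_in], amp, params)
        assert all(HOMOPOLYMER in masks[k] for k in (dele, ins, sub_in))

    def test_dinucleotide_repeat_not_masked(self, amp):
        # GGTGGC around the hotspot: no mononucleotide run of length >= 4
        key = VariantKey(amp.amplicon_id, 39, amp.reference_seq[39], "A", SUB)
        masks = apply_structural_masks([key], amp, CallingParams())
        assert masks[key] == frozenset()


class TestCallAndReport:
    def build_sample(self, amp, n_fwd_alt, n_rev_alt, n_fwd=800, n_rev=700, pos=15):
        insert = amp.insert
        base = insert[pos]
        alt = "ACGT"[("ACGT".index(base) + 1) % 4]
        mut = insert[:pos] + alt + insert[pos + 1 :]
        reads = [make_read(amp, insert, FORWARD, f"f{i}") for i in range(n_fwd - n_fwd_alt)]
        reads += [make_read(amp, insert, REVERSE, f"r{i}") for i in range(n_rev - n_rev_alt)]
        reads += [make_read(amp, mut, FORWARD, f"mf{i}") for i in range(n_fwd_alt)]
        reads += [make_read(amp, mut, REVERSE, f"mr{i}") for i in range(n_rev_alt)]
        return reads

    def test_vaf_formula_and_inclusive_boundary(self, panel, amp):
        reads = self.build_sample(amp, 8, 7)
        calls = call_variants(reads, panel)
        assert len(calls) == 1
        assert calls[0].vaf_pct == pytest.approx(1.0)
        assert calls[0].vaf == 15 / 1500
        assert report_variants(calls) == calls  # 1.00% reported, inclusive

    def test_bidirectional_rule_drops_one_sided(self, panel, amp):
        calls = call_variants(self.build_sample(amp, 5, 0), panel)
        assert calls == []

    def test_sub_threshold_kept_in_full_output_only(self, panel, amp):
        reads = self.build_sample(amp, 5, 4, 800, 700)  # 9/1500 = 0.6%
        calls = call_variants(reads, panel)
        assert len(calls) == 1
        assert report_variants(calls) == []

    def test_reporting_threshold_monotonicity(self, panel, amp):
        reads = self.build_sample(amp, 30, 25)
        calls = call_variants(reads, panel)
        prev = None
        for thr in (0.01, 0.5, 1.0, 5.0, 10.0):
            cur = {c.key for c in report_variants(calls, CallingParams(reporting_vaf_threshold=thr))}
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_conservation_at_position(self, panel, amp):
        reads = self.build_sample(amp, 8, 7)
        counts, df, dr = tally_variants(reads, amp)
        (key, (cf, cr)), = counts.items()
        wt_fwd = df - cf
        wt_rev = dr - cr
        assert wt_fwd + cf == df and wt_rev + cr == dr

    def test_calls_table_includes_masked_rows(self, panel):
        amp = next(a for a in panel if a.amplicon_id == "KRAS_EX3")
        run_start = amp.reference_seq.find("TTTTT")
        insert = amp.insert
        shift = amp.insert_span[0]
        mut = insert[: run_start - shift] + insert[run_start - shift + 1 :]  # del inside run
        reads = [make_read(amp, insert, FORWARD, f"f{i}") for i in range(20)]
        reads += [make_read(amp, insert, REVERSE, f"r{i}") for i in range(20)]
        reads += [make_read(amp, mut, FORWARD, "d1"), make_read(amp, mut, REVERSE, "d2")]
        table = calls_table(reads, panel)
        masked = table[table.masks.str.contains(HOMOPOLYMER, na=False)]
        assert len(masked) == 1 and not masked.iloc[0].passed
        assert call_variants(reads, panel) == []
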