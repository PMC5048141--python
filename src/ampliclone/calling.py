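"""Alignment of processed reads and per-position variant calling.

Reads that survived structural filtering are globally aligned to the
inter-primer insert of their amplicon (match +1, mismatch -2, gap open -4,
gap extend -1), differences are extracted as per-position operations, and
indels are left-normalised on the reference.  Variants are tallied per
orientation; the spanning depth of a position is the number of reads whose
end-to-end alignment covers it with an aligned base or a deletion (for
globally aligned full-length reads this is every kept read of the amplicon,
per orientation).

Support filters mirror amplicon-resequencing consensus parameters: a
variant is kept iff it is structurally unmasked (not primer-adjacent, not a
homopolymer-tract artifact), is seen on both strands, and reaches both the
minimum read count and the minimum read percentage *per orientation*.  The
VAF of variant *i* is the number of reads carrying *i* divided by the number
of reads spanning its position, both orientations pooled.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align

from .errors import AmplicloneError
from .panel import AmpliconDef, homopolymer_runs
from .reads import FORWARD, ProcessedRead
from .variant import (
    DEL,
    HOMOPOLYMER,
    INS,
    PRIMER_ADJACENT,
    SUB,
    CallingParams,
    VariantCall,
    VariantKey,
    left_normalise_deletion,
    left_normalise_insertion,
)

logger = logging.getLogger(__name__)

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -2
_aligner.open_gap_score = -4
_aligner.extend_gap_score = -1

# a substitution-only interpretation of an equal-length payload is optimal
# whenever there are at most this many mismatches (a gap pair costs >= 8,
# three mismatches cost 9 but sacrifice no matches; ties prefer mismatches)
_MAX_FAST_SUBS = 3


def _ops_from_alignment(insert: str, payload: str) -> list[tuple[str, int, str, str]]:
    """Extract (var_type, insert_pos, ref, alt) ops from the optimal global alignment."""
    aln = _aligner.align(insert, payload)[0]
    ref_blocks, q_blocks = aln.aligned
    ops: list[tuple[str, int, str, str]] = []
    pr, pq = 0, 0
    blocks = list(zip(ref_blocks, q_blocks)) + [((len(insert), len(insert)), (len(payload), len(payload)))]
    for (rs, re_), (qs, qe) in blocks:
        rs, re_, qs, qe = int(rs), int(re_), int(qs), int(qe)
        if rs > pr:
            ops.append((DEL, pr, insert[pr:rs], ""))
        if qs > pq:
            ops.append((INS, rs - 1, "", payload[pq:qs]))
        for k in range(re_ - rs):
            if insert[rs + k] != payload[qs + k]:
                ops.append((SUB, rs + k, insert[rs + k], payload[qs + k]))
        pr, pq = re_, qe
    return ops


def align_read(payload: str, amplicon: AmpliconDef) -> list[tuple[str, int, str, str]]:
    """Align a payload to its amplicon and return left-normalised variant ops.

    Ops are ``(var_type, position, ref, alt)`` on full amplicon-reference
    coordinates (insertion position = 0-based anchor base to the left).
    """
    if not payload:
        raise AmplicloneError("empty payload")
    insert = amplicon.insert
    if payload == insert:
        return []
    if len(payload) == len(insert):
        mism = [i for i, (a, b) in enumerate(zip(insert, payload)) if a != b]
        if len(mism) <= _MAX_FAST_SUBS:
            ops = [(SUB, i, insert[i], payload[i]) for i in mism]
        else:
            ops = _ops_from_alignment(insert, payload)
    else:
        ops = _ops_from_alignment(insert, payload)
    # shift to reference coordinates, then left-normalise indels there so that
    # events at the insert edge can normalise into the primer (and be masked)
    shift = amplicon.insert_span[0]
    ref = amplicon.reference_seq
    out = []
    for var_type, pos, r, a in ops:
        pos += shift
        if var_type == DEL:
            pos = left_normalise_deletion(ref, pos, len(r))
            r = ref[pos : pos + len(r)]
        elif var_type == INS:
            pos, a = left_normalise_insertion(ref, pos, a)
        out.append((var_type, pos, r, a))
    return out


def tally_variants(
    reads: Sequence[ProcessedRead], amplicon: AmpliconDef
) -> tuple[dict[VariantKey, list[int]], int, int]:
    """Tally per-orientation variant counts and spanning depths for one amplicon.

    Returns ``(counts, depth_fwd, depth_rev)`` where ``counts`` maps each
    :class:`VariantKey` to ``[count_fwd, count_rev]``.  Every non-matching
    alignment op contributes to exactly one key.
    """
    counts: dict[VariantKey, list[int]] = defaultdict(lambda: [0, 0])
    depth_fwd = depth_rev = 0
    cache: dict[str, list] = {}
    for read in reads:
        if read.amplicon_id != amplicon.amplicon_id:
            raise AmplicloneError("read/amplicon mismatch in tally_variants")
        fwd = read.orientation == FORWARD
        if fwd:
            depth_fwd += 1
        else:
            depth_rev += 1
        ops = cache.get(read.payload_seq)
        if ops is None:
            ops = align_read(read.payload_seq, amplicon)
            cache[read.payload_seq] = ops
        for var_type, pos, r, a in ops:
            key = VariantKey(amplicon.amplicon_id, pos, r, a, var_type)
            counts[key][0 if fwd else 1] += 1
    return dict(counts), depth_fwd, depth_rev


def apply_structural_masks(
    keys: Iterable[VariantKey], amplicon: AmpliconDef, params: CallingParams
) -> dict[VariantKey, frozenset]:
    """Mask variants overlapping/adjacent to primers or inside homopolymeric tracts.

    ``primer_adjacent``: the variant footprint intersects either primer span
    extended by ``primer_adjacency_margin`` bases.  ``homopolymer``: an indel
    whose footprint lies within a reference mononucleotide run of length
    ``>= homopolymer_min_run``, or a substitution of a base inside such a run.
    """
    margin = params.primer_adjacency_margin
    f0, f1 = amplicon.primer_fwd_span
    r0, r1 = amplicon.primer_rev_span
    fwd_zone = (f0, f1 + margin)
    rev_zone = (r0 - margin, r1)
    runs = [
        (s, e, b)
        for s, e, b in homopolymer_runs(amplicon.reference_seq, params.homopolymer_min_run)
    ]
    masks: dict[VariantKey, frozenset] = {}
    for key in keys:
        m = set()
        a, b = key.ref_span()
        if a < fwd_zone[1] and b > fwd_zone[0]:
            m.add(PRIMER_ADJACENT)
        if a < rev_zone[1] and b > rev_zone[0]:
            m.add(PRIMER_ADJACENT)
        for s, e, _ in runs:
            if key.var_type == SUB:
                if s <= key.position < e:
                    m.add(HOMOPOLYMER)
            elif key.var_type == DEL:
                if s <= a and b <= e:
                    m.add(HOMOPOLYMER)
            else:
                # insertion: masked when the insertion point touches the run
                # (left-normalisation anchors run-extending insertions one
                # base before the run start)
                if s - 1 <= key.position < e:
                    m.add(HOMOPOLYMER)
        masks[key] = frozenset(m)
    return masks


def call_variants(
    reads: Sequence[ProcessedRead],
    panel: Sequence[AmpliconDef],
    params: CallingParams | None = None,
) -> list[VariantCall]:
    """Produce the full (pre-reporting-threshold) call set for one sample.

    A variant is kept iff unmasked, supported by at least
    ``min_count_per_orientation`` reads and ``min_read_pct_per_direction``
    percent of the spanning depth in *each* orientation (when
    ``require_bidirectional``), thresholds inclusive.
    """
    params = params or CallingParams()
    by_amp: dict[str, list[ProcessedRead]] = defaultdict(list)
    for r in reads:
        by_amp[r.amplicon_id].append(r)
    min_frac = params.min_read_pct_per_direction / 100.0
    calls: list[VariantCall] = []
    for amp in panel:
        group = by_amp.get(amp.amplicon_id)
        if not group:
            continue
        counts, depth_fwd, depth_rev = tally_variants(group, amp)
        masks = apply_structural_masks(counts.keys(), amp, params)
        for key, (cf, cr) in counts.items():
            if masks[key]:
                continue
            if depth_fwd == 0 or depth_rev == 0:
                logger.warning("zero spanning depth for %s; variant dropped", key)
                continue
            if params.require_bidirectional:
                ok = (
                    cf >= params.min_count_per_orientation
                    and cr >= params.min_count_per_orientation
                    and cf / depth_fwd >= min_frac
                    and cr / depth_rev >= min_frac
                )
            else:
                ok = (cf + cr) >= params.min_count_per_orientation and (cf + cr) / (
                    depth_fwd + depth_rev
                ) >= min_frac
            if ok:
                calls.append(
                    VariantCall(
                        amplicon_id=key.amplicon_id,
                        position=key.position,
                        ref=key.ref,
                        alt=key.alt,
                        var_type=key.var_type,
                        count_fwd=cf,
                        count_rev=cr,
                        depth_fwd=depth_fwd,
                        depth_rev=depth_rev,
                        masks=frozenset(),
                    )
                )
    calls.sort(key=lambda c: (c.amplicon_id, c.position, c.alt, c.ref))
    return calls


def report_variants(calls: Sequence[VariantCall], params: CallingParams | None = None) -> list[VariantCall]:
    """Reported set: calls with VAF at or above the reporting threshold (inclusive)."""
    params = params or CallingParams()
    thr = params.reporting_vaf_threshold / 100.0
    return [c for c in calls if c.vaf >= thr]


def calls_table(
    reads: Sequence[ProcessedRead],
    panel: Sequence[AmpliconDef],
    params: CallingParams | None = None,
) -> pd.DataFrame:
    """Diagnostic table of *all* tallied variants, including masked and
    filter-failing ones, with per-orientation counts and pre-threshold VAFs."""
    params = params or CallingParams()
    by_amp: dict[str, list[ProcessedRead]] = defaultdict(list)
    for r in reads:
        by_amp[r.amplicon_id].append(r)
    passed_keys = {c.key for c in call_variants(reads, panel, params)}
    rows = []
    for amp in panel:
        group = by_amp.get(amp.amplicon_id)
        if not group:
            continue
        counts, depth_fwd, depth_rev = tally_variants(group, amp)
        masks = apply_structural_masks(counts.keys(), amp, params)
        for key, (cf, cr) in sorted(counts.items()):
            depth = depth_fwd + depth_rev
            rows.append(
                {
                    "amplicon_id": key.amplicon_id,
                    "position": key.position,
                    "ref": key.ref,
                    "alt": key.alt,
                    "var_type": key.var_type,
                    "count_fwd": cf,
                    "count_rev": cr,
                    "depth_fwd": depth_fwd,
                    "depth_rev": depth_rev,
                    "vaf_pct": 100.0 * (cf + cr) / depth if depth else 0.0,
                    "masks": ";".join(sorted(masks[key])),
                    "passed": key in passed_keys,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "amplicon_id", "position", "ref", "alt", "var_type", "count_fwd",
            "count_rev", "depth_fwd", "depth_rev", "vaf_pct", "masks", "passed",
        ],
    )
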