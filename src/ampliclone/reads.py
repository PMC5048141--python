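"""Read demultiplexing, orientation, quality filtering and structural validation.

The read-conservation rules are deliberately strict, mirroring amplicon
pyrosequencing practice:

* MIDs must match exactly at *both* read ends (the 3' end carries the
  reverse complement of the 5' MID); a single mismatch rejects the read;
* gene-specific primers must be complete and mismatch-free at both ends;
* the arithmetic mean phred quality of the whole raw read must exceed Q20
  (strict inequality, computed before any trimming);
* the remaining payload must align end-to-end to the inter-primer insert
  with a bounded total indel length (no truncated reads).

Every rejection is tallied in a :class:`FilterReport`, whose counts always
balance the number of input reads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import edlib
import numpy as np
from Bio import SeqIO

from .errors import AmplicloneError
from .panel import AmpliconDef, MidTag, revcomp

FORWARD = "forward"
REVERSE = "reverse"

MID_MISMATCH = "mid_mismatch"
PRIMER_MISMATCH = "primer_mismatch"
LOW_QUALITY = "low_quality"
NOT_FULL_LENGTH = "not_full_length"


@dataclass
class ProcessedRead:
    """A kept read with MIDs and primers trimmed.

    ``payload_seq`` is stored in *reference* orientation (reverse reads are
    reverse-complemented on the way in); ``orientation`` records the original
    strand for the bidirectional support filter.
    """

    read_id: str
    sample_id: str
    amplicon_id: str
    orientation: str
    payload_seq: str
    payload_qual: tuple[int, ...]
    mean_q: float


@dataclass
class FilterReport:
    """Per-reason discard tallies plus kept counts per (sample, amplicon, orientation)."""

    n_input: int = 0
    discarded: Counter = field(default_factory=Counter)
    kept: Counter = field(default_factory=Counter)

    @property
    def n_kept(self) -> int:
        return sum(self.kept.values())

    @property
    def balanced(self) -> bool:
        return self.n_input == self.n_kept + sum(self.discarded.values())

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "discarded": dict(self.discarded),
            "kept": {"|".join(k): v for k, v in sorted(self.kept.items())},
        }


# ---------------------------------------------------------------------------
# Individual predicates
# ---------------------------------------------------------------------------

def demultiplex(seq: str, mids: Sequence[MidTag]) -> MidTag | None:
    """Assign a read to a MID iff one MID matches exactly at the 5' end and
    the reverse complement of the *same* MID matches exactly at the 3' end."""
    for mid in mids:
        if seq.startswith(mid.sequence) and seq.endswith(revcomp(mid.sequence)):
            if len(seq) >= 2 * len(mid.sequence):
                return mid
    return None


def match_primer_and_orient(
    trimmed: str, panel: Sequence[AmpliconDef]
) -> tuple[str, str] | None:
    """Resolve amplicon and orientation from exact, complete primer matches.

    Forward reads start with ``primer_fwd`` and end with the reference tail
    (reverse complement of ``primer_rev``); reverse reads are the reverse
    complement of that structure.  A read matching more than one amplicon, or
    with discordant primers (chimera-like), is rejected.
    """
    hits = []
    for amp in panel:
        tail = revcomp(amp.primer_rev)
        if trimmed.startswith(amp.primer_fwd) and trimmed.endswith(tail):
            hits.append((amp.amplicon_id, FORWARD))
        if trimmed.startswith(amp.primer_rev) and trimmed.endswith(revcomp(amp.primer_fwd)):
            hits.append((amp.amplicon_id, REVERSE))
    if len(hits) != 1:
        return None
    return hits[0]


def mean_quality(quals: Sequence[int]) -> float:
    if len(quals) == 0:
        raise AmplicloneError("read has no quality values")
    return float(np.mean(quals))


def quality_filter(quals: Sequence[int], min_mean_q: float = 20.0) -> bool:
    """Keep iff the arithmetic mean phred over the whole read is strictly above Q20."""
    return mean_quality(quals) > min_mean_q


def full_length_check(payload: str, amplicon: AmpliconDef, max_indel_slack: int = 10) -> bool:
    """Keep iff the payload aligns end-to-end to the inter-primer insert with
    total inserted+deleted length ``<= max_indel_slack``.

    Uses a global (Needleman-Wunsch) edit-distance alignment; truncated or
    grossly rearranged reads fail.
    """
    if not payload:
        return False
    res = edlib.align(payload, amplicon.insert, mode="NW", task="path")
    cigar = res["cigar"] or ""
    indel = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch in "ID":
                indel += int(num)
            num = ""
    return indel <= max_indel_slack


# ---------------------------------------------------------------------------
# Full per-read pipeline
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> Iterator[tuple[str, str, list[int]]]:
    """Yield ``(read_id, sequence, phred_qualities)`` from a FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"]


def process_reads(
    reads: Iterable[tuple[str, str, Sequence[int]]],
    panel: Sequence[AmpliconDef],
    mids: Sequence[MidTag],
    sample_id: str,
    expected_mid: str | None = None,
    min_mean_q: float = 20.0,
    max_indel_slack: int = 10,
) -> tuple[list[ProcessedRead], FilterReport]:
    """Apply MID -> primer -> quality -> full-length filtering to raw reads.

    Each predicate is independent of the others, so the kept set does not
    depend on this order; the :class:`FilterReport` attributes each discard
    to the first failing rule in the canonical order above.
    """
    amp_by_id = {a.amplicon_id: a for a in panel}
    kept: list[ProcessedRead] = []
    report = FilterReport()
    for read_id, seq, quals in reads:
        report.n_input += 1
        if len(seq) != len(quals):
            raise AmplicloneError(f"read {read_id}: sequence/quality length mismatch")
        mid = demultiplex(seq, mids)
        if mid is None or (expected_mid is not None and mid.mid_id != expected_mid):
            report.discarded[MID_MISMATCH] += 1
            continue
        n = len(mid.sequence)
        trimmed = seq[n:-n]
        hit = match_primer_and_orient(trimmed, panel)
        if hit is None:
            report.discarded[PRIMER_MISMATCH] += 1
            continue
        # mean quality is computed on the entire raw read, before trimming
        mq = mean_quality(quals)
        if not mq > min_mean_q:
            report.discarded[LOW_QUALITY] += 1
            continue
        amp_id, orientation = hit
        amp = amp_by_id[amp_id]
        np_, nr = len(amp.primer_fwd), len(amp.primer_rev)
        payload = trimmed[np_:-nr] if orientation == FORWARD else trimmed[nr:-np_]
        payload_qual = list(quals[n + (np_ if orientation == FORWARD else nr):][: len(payload)])
        if orientation == REVERSE:
            payload = revcomp(payload)
            payload_qual = payload_qual[::-1]
        if not full_length_check(payload, amp, max_indel_slack):
            report.discarded[NOT_FULL_LENGTH] += 1
            continue
        kept.append(
            ProcessedRead(
                read_id=read_id,
                sample_id=sample_id,
                amplicon_id=amp_id,
                orientation=orientation,
                payload_seq=payload,
                payload_qual=tuple(payload_qual),
                mean_q=mq,
            )
        )
        report.kept[(sample_id, amp_id, orientation)] += 1
    return kept, report
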