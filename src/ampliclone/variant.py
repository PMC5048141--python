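"""Variant identity, per-orientation counts and calling parameters.

A variant is identified by ``(amplicon_id, position, ref, alt, var_type)``
on 0-based amplicon-reference coordinates:

* ``sub`` — ``position`` is the substituted base, ``ref``/``alt`` one base each;
* ``del`` — ``position`` is the first deleted base, ``ref`` the deleted
  bases, ``alt`` empty;
* ``ins`` — ``position`` is the anchor base to the *left* of the insertion,
  ``ref`` empty, ``alt`` the inserted bases.

Indels are left-normalised, so two reads expressing the same physical event
inside a repeat always produce the same key.  Distinct alternative alleles at
one position are distinct keys, i.e. distinct clones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

SUB = "sub"
INS = "ins"
DEL = "del"


@dataclass(frozen=True, order=True)
class VariantKey:
    amplicon_id: str
    position: int
    ref: str
    alt: str
    var_type: str

    def __str__(self) -> str:  # compact clone label, e.g. KRAS_EX2:39G>A
        if self.var_type == SUB:
            return f"{self.amplicon_id}:{self.position}{self.ref}>{self.alt}"
        if self.var_type == DEL:
            return f"{self.amplicon_id}:{self.position}del{self.ref}"
        return f"{self.amplicon_id}:{self.position}ins{self.alt}"

    def ref_span(self) -> tuple[int, int]:
        """Reference footprint used by structural masks (insertions cover both flanks)."""
        if self.var_type == SUB:
            return (self.position, self.position + 1)
        if self.var_type == DEL:
            return (self.position, self.position + len(self.ref))
        return (self.position, self.position + 2)


def left_normalise_deletion(ref_seq: str, pos: int, length: int) -> int:
    """Shift a deletion of ``ref_seq[pos:pos+length]`` to its leftmost equivalent start."""
    while pos > 0 and ref_seq[pos - 1] == ref_seq[pos + length - 1]:
        pos -= 1
    return pos

def left_normalise_insertion(ref_seq: str, anchor: int, seq: str) -> tuple[int, str]:
    """Shift an insertion (between ``anchor`` and ``anchor+1``) leftmost; rotates ``seq``."""
    while anchor > 0 and seq[-1] == ref_seq[anchor]:
        seq = ref_seq[anchor] + seq[:-1]
        anchor -= 1
    return anchor, seq


PRIMER_ADJACENT = "primer_adjacent"
HOMOPOLYMER = "homopolymer"


@dataclass
class VariantCall:
    """One candidate variant with per-orientation support and spanning depths."""

    amplicon_id: str
    position: int
    ref: str
    alt: str
    var_type: str
    count_fwd: int
    count_rev: int
    depth_fwd: int
    depth_rev: int
    masks: frozenset = field(default_factory=frozenset)

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.amplicon_id, self.position, self.ref, self.alt, self.var_type)

    @property
    def vaf(self) -> float:
        """Reads carrying the variant over all reads spanning its position."""
        depth = self.depth_fwd + self.depth_rev
        return (self.count_fwd + self.count_rev) / depth if depth else 0.0

    @property
    def vaf_pct(self) -> float:
        return 100.0 * self.vaf


@dataclass
class CallingParams:
    """Variant/consensus parameters of the calling stage.

    ``min_read_pct_per_direction`` and ``reporting_vaf_threshold`` are in
    percent; all comparisons are inclusive (``>=``).
    """

    min_read_pct_per_direction: float = 0.01
    min_count_per_orientation: int = 1
    require_bidirectional: bool = True
    homopolymer_min_run: int = 4
    primer_adjacency_margin: int = 1
    reporting_vaf_threshold: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "min_read_pct_per_direction",
            "min_count_per_orientation",
            "homopolymer_min_run",
            "primer_adjacency_margin",
            "reporting_vaf_threshold",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
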