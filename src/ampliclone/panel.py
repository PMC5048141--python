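"""Amplicon panel model and file-format readers/writers.

An amplicon panel bundles, for every PCR amplicon, the full reference
sequence (gene-specific primers included), the primer pair, the codon frame
of the coding region inside the insert and the hotspot windows.  Sample
multiplexing uses MID barcodes (multiplex identifiers) ligated to both ends
of each fusion-primer amplicon, so every read carries
``MID + primer + insert + primer' + MID'``.

Coordinates are 0-based half-open on the amplicon reference throughout the
package; only VCF output (:mod:`ampliclone.vcfio`) is 1-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import PanelError

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

TIME_POINTS = ("diagnosis", "relapse1", "relapse2", "control", "xeno_p1", "xeno_p2")

MANIFEST_COLUMNS = ("sample_id", "patient_id", "time_point", "replicate", "mid_id", "fastq_path")


def revcomp(seq: str) -> str:
    """Reverse-complement a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def homopolymer_runs(seq: str, min_len: int = 1) -> list[tuple[int, int, str]]:
    """Maximal mononucleotide runs of ``seq`` as ``(start, end, base)``, 0-based half-open."""
    return [
        (m.start(), m.end(), m.group(0)[0])
        for m in re.finditer(r"(.)\1*", seq)
        if m.end() - m.start() >= min_len
    ]


@dataclass(frozen=True)
class MidTag:
    """A multiplex identifier barcode."""

    mid_id: str
    sequence: str


@dataclass(frozen=True)
class AmpliconDef:
    """One amplicon of the panel.

    ``reference_seq`` is the full amplified sequence: forward primer, insert,
    then the reverse-complement of the reverse primer.  ``coding_offset`` is
    the 0-based reference position of the first base of the first complete
    codon and ``codon_start_number`` the codon number at that position.
    """

    amplicon_id: str
    gene: str
    exon: str
    reference_seq: str
    primer_fwd: str
    primer_rev: str
    coding_offset: int
    codon_start_number: int
    strand_of_cds: int = 1
    hotspot_spans: tuple[tuple[int, int], ...] = ()
    accession: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # -- derived geometry -------------------------------------------------
    @property
    def length(self) -> int:
        return len(self.reference_seq)

    @property
    def primer_fwd_span(self) -> tuple[int, int]:
        return (0, len(self.primer_fwd))

    @property
    def primer_rev_span(self) -> tuple[int, int]:
        return (self.length - len(self.primer_rev), self.length)

    @property
    def insert_span(self) -> tuple[int, int]:
        return (len(self.primer_fwd), self.length - len(self.primer_rev))

    @property
    def insert(self) -> str:
        a, b = self.insert_span
        return self.reference_seq[a:b]

    @property
    def coding_span(self) -> tuple[int, int]:
        """Reference span holding complete codons, from ``coding_offset`` to insert end."""
        a, b = self.insert_span
        n_codons = (b - self.coding_offset) // 3
        return (self.coding_offset, self.coding_offset + 3 * n_codons)

    def validate(self) -> None:
        seq = self.reference_seq
        if not seq or set(seq) - set("ACGT"):
            raise PanelError(f"{self.amplicon_id}: reference must be uppercase ACGT")
        if not seq.startswith(self.primer_fwd):
            raise PanelError(f"{self.amplicon_id}: forward primer is not a reference prefix")
        if not seq.endswith(revcomp(self.primer_rev)):
            raise PanelError(
                f"{self.amplicon_id}: reverse-complemented reverse primer is not a reference suffix"
            )
        if len(seq) <= len(self.primer_fwd) + len(self.primer_rev):
            raise PanelError(f"{self.amplicon_id}: no insert between primers")
        a, b = self.insert_span
        if not a <= self.coding_offset < b:
            raise PanelError(f"{self.amplicon_id}: coding_offset outside inter-primer insert")
        if self.strand_of_cds not in (1, -1):
            raise PanelError(f"{self.amplicon_id}: strand_of_cds must be +1 or -1")


@dataclass(frozen=True)
class SampleManifestEntry:
    """One sequenced library: a (sample, replicate) pair with its MID and FASTQ."""

    sample_id: str
    patient_id: str
    time_point: str
    replicate: int
    mid_id: str
    fastq_path: str

    def __post_init__(self) -> None:
        if self.time_point not in TIME_POINTS:
            raise PanelError(f"unknown time point {self.time_point!r}")
        if self.replicate < 1:
            raise PanelError("replicate numbers start at 1")


def validate_mids(mids: Sequence[MidTag]) -> None:
    """MID sets must be pairwise distinct and prefix-free (exact demultiplexing)."""
    seqs = [m.sequence for m in mids]
    if len(set(m.mid_id for m in mids)) != len(mids):
        raise PanelError("duplicate MID ids")
    for i, a in enumerate(seqs):
        for j, b in enumerate(seqs):
            if i != j and b.startswith(a):
                raise PanelError(f"MID {seqs[i]!r} is a prefix of {seqs[j]!r}")


def validate_panel(amplicons: Sequence[AmpliconDef], mids: Sequence[MidTag]) -> None:
    if len(set(a.amplicon_id for a in amplicons)) != len(amplicons):
        raise PanelError("duplicate amplicon ids")
    for a in amplicons:
        a.validate()
    validate_mids(mids)


# ---------------------------------------------------------------------------
# Panel config + FASTA round-trip
# ---------------------------------------------------------------------------

def load_panel(
    panel_config: str | Path, reference_fasta: str | Path
) -> tuple[list[AmpliconDef], list[MidTag]]:
    """Load and validate a panel from a YAML config plus a reference FASTA.

    FASTA records are named by ``amplicon_id``; the config lists primers,
    codon frame and hotspot windows per amplicon, and the MID set.
    Amplicons are returned sorted by ``amplicon_id`` (deterministic order).
    """
    with open(panel_config) as fh:
        cfg = yaml.safe_load(fh)
    refs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(reference_fasta), "fasta")}
    amplicons = []
    for entry in cfg.get("amplicons", []):
        amp_id = entry["amplicon_id"]
        if amp_id not in refs:
            raise PanelError(f"FASTA record missing for amplicon {amp_id!r}")
        amplicons.append(
            AmpliconDef(
                amplicon_id=amp_id,
                gene=entry["gene"],
                exon=str(entry["exon"]),
                reference_seq=refs[amp_id],
                primer_fwd=entry["primer_fwd"].upper(),
                primer_rev=entry["primer_rev"].upper(),
                coding_offset=int(entry["coding_offset"]),
                codon_start_number=int(entry["codon_start_number"]),
                strand_of_cds=int(entry.get("strand_of_cds", 1)),
                hotspot_spans=tuple(tuple(s) for s in entry.get("hotspot_spans", [])),
                accession=entry.get("accession", ""),
            )
        )
    amplicons.sort(key=lambda a: a.amplicon_id)
    mids = [MidTag(m["mid_id"], m["sequence"].upper()) for m in cfg.get("mids", [])]
    validate_panel(amplicons, mids)
    return amplicons, mids


def write_panel(
    amplicons: Sequence[AmpliconDef],
    mids: Sequence[MidTag],
    panel_config: str | Path,
    reference_fasta: str | Path,
) -> None:
    """Write a panel back to YAML + FASTA so that :func:`load_panel` round-trips."""
    cfg = {
        "amplicons": [
            {
                "amplicon_id": a.amplicon_id,
                "gene": a.gene,
                "exon": a.exon,
                "primer_fwd": a.primer_fwd,
                "primer_rev": a.primer_rev,
                "coding_offset": a.coding_offset,
                "codon_start_number": a.codon_start_number,
                "strand_of_cds": a.strand_of_cds,
                "hotspot_spans": [list(s) for s in a.hotspot_spans],
                "accession": a.accession,
            }
            for a in sorted(amplicons, key=lambda a: a.amplicon_id)
        ],
        "mids": [{"mid_id": m.mid_id, "sequence": m.sequence} for m in mids],
    }
    with open(panel_config, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    records = [
        SeqRecord(Seq(a.reference_seq), id=a.amplicon_id, description="")
        for a in sorted(amplicons, key=lambda a: a.amplicon_id)
    ]
    SeqIO.write(records, str(reference_fasta), "fasta")


# ---------------------------------------------------------------------------
# Sample manifest
# ---------------------------------------------------------------------------

def load_manifest(path: str | Path, mids: Sequence[MidTag] | None = None) -> list[SampleManifestEntry]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise PanelError(f"manifest missing columns: {sorted(missing)}")
    entries = [
        SampleManifestEntry(
            sample_id=row.sample_id,
            patient_id=row.patient_id,
            time_point=row.time_point,
            replicate=int(row.replicate),
            mid_id=row.mid_id,
            fastq_path=row.fastq_path,
        )
        for row in df.itertuples()
    ]
    seen = set()
    for e in entries:
        if (e.sample_id, e.replicate) in seen:
            raise PanelError(f"duplicate (sample_id, replicate): {(e.sample_id, e.replicate)}")
        seen.add((e.sample_id, e.replicate))
    if mids is not None:
        known = {m.mid_id for m in mids}
        for e in entries:
            if e.mid_id not in known:
                raise PanelError(f"manifest MID {e.mid_id!r} not in panel")
    return entries


def write_manifest(entries: Iterable[SampleManifestEntry], path: str | Path) -> None:
    df = pd.DataFrame([e.__dict__ for e in entries], columns=list(MANIFEST_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Bundled synthetic fixture panel
# ---------------------------------------------------------------------------
# Four synthetic amplicons modelling the KRAS/NRAS exon 2/3 hotspot windows
# (codons 12/13 and 61).  The inserts encode the canonical RAS protein
# segments (codons 6-35 and 54-83) with hotspot codons GGT/GGC (G12/G13) and
# CAA (Q61) in frame, plus designed mononucleotide runs: runs of length 3
# (pyrosequencing indel-noise sources that stay unmasked) and runs of
# length >=4 (masked as homopolymeric tracts).  Primer and flanking sequences
# are synthetic; the panel is a test fixture, not the RefSeq loci.

_FIXTURE = {
    # amplicon_id: (gene, exon, primer_fwd, insert, ref_tail, codon_start, hotspot codons)
    "KRAS_EX2": (
        "KRAS", "2", "GACCAATTAAGTGGGCATAA",
        "CTAGTGGTAGTTGGAGCTGGTGGCGTAGGAAAGAGCGCACTGACGATTCAACTTATCCAAAATCATTTCGTCGACGAATATGATCCAACT",
        "GTGAGGACTTACAACATCGC", 6, (12, 13),
    ),
    "KRAS_EX3": (
        "KRAS", "3", "TCCAGTCCACATCGATTGTC",
        "GATATCCTGGACACAGCCGGTCAAGAGGAATATAGTGCAATGCGTGACCAGTACATGCGAACCGGAGAGGGCTTTTTATGCGTCTTCGCT",
        "GAGGTACTTAACTAGCCGTT", 54, (61,),
    ),
    "NRAS_EX2": (
        "NRAS", "2", "TTATGCCGATCTACATGGCA",
        "CTTGTTGTGGTCGGTGCCGGTGGTGTTGGCAAAAGCGCTCTCACAATCCAGCTAATACAGAACCACTTTGTAGATGAGTACGACCCGACA",
        "TGGCGCCCATAGAATGCCTA", 6, (12, 13),
    ),
    "NRAS_EX3": (
        "NRAS", "3", "GTATTGGATCTGAGAAGCCG",
        "GACATTCTCGATACCGCTGGACAAGAAGAGTACTCTGCCATGAGAGATCAATATATGAGGACTGGGGAAGGGTTCCTGTGTGTGTTTGCC",
        "AGGAGCACTCATCTGACGAA", 54, (61,),
    ),
}

_DEFAULT_MIDS = (
    ("MID1", "ACGAGTGCGT"),
    ("MID2", "ACGCTCGACA"),
    ("MID3", "AGACGCACTC"),
    ("MID4", "AGCACTGTAG"),
    ("MID5", "ATCAGACACG"),
    ("MID6", "ATATCGCGAG"),
)


def default_panel() -> tuple[list[AmpliconDef], list[MidTag]]:
    """The bundled synthetic 4-amplicon panel and its 6-MID barcode set."""
    amplicons = []
    for amp_id, (gene, exon, fwd, insert, tail, codon_start, hs_codons) in _FIXTURE.items():
        coding_offset = len(fwd)
        spans = tuple(
            (coding_offset + 3 * (c - codon_start), coding_offset + 3 * (c - codon_start) + 3)
            for c in hs_codons
        )
        amplicons.append(
            AmpliconDef(
                amplicon_id=amp_id,
                gene=gene,
                exon=exon,
                reference_seq=fwd + insert + tail,
                primer_fwd=fwd,
                primer_rev=revcomp(tail),
                coding_offset=coding_offset,
                codon_start_number=codon_start,
                hotspot_spans=spans,
                accession="synthetic",
            )
        )
    amplicons.sort(key=lambda a: a.amplicon_id)
    mids = [MidTag(i, s) for i, s in _DEFAULT_MIDS]
    validate_panel(amplicons, mids)
    return amplicons, mids
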