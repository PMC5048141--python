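"""VCF 4.2 output/input for amplicon-local variant calls.

Positions are 1-based on the amplicon reference contig; indels are written
left-normalised with the standard anchor base.  Per-orientation support is
stored in INFO (DP = pooled spanning depth, DPF/DPR per orientation,
ADF/ADR per-orientation alt counts, AF = VAF as a fraction), so a written
call set round-trips exactly from the integer counts.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pysam

from .errors import AmplicloneError
from .panel import AmpliconDef
from .variant import DEL, INS, SUB, VariantCall


def _header(panel: Sequence[AmpliconDef]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##source=ampliclone')
    for amp in sorted(panel, key=lambda a: a.amplicon_id):
        header.contigs.add(amp.amplicon_id, length=amp.length)
    header.add_meta(
        "INFO", items=[("ID", "DP"), ("Number", 1), ("Type", "Integer"),
                       ("Description", "Reads spanning the position, both orientations")]
    )
    header.add_meta(
        "INFO", items=[("ID", "DPF"), ("Number", 1), ("Type", "Integer"),
                       ("Description", "Spanning depth, forward reads")]
    )
    header.add_meta(
        "INFO", items=[("ID", "DPR"), ("Number", 1), ("Type", "Integer"),
                       ("Description", "Spanning depth, reverse reads")]
    )
    header.add_meta(
        "INFO", items=[("ID", "ADF"), ("Number", 1), ("Type", "Integer"),
                       ("Description", "Variant reads, forward orientation")]
    )
    header.add_meta(
        "INFO", items=[("ID", "ADR"), ("Number", 1), ("Type", "Integer"),
                       ("Description", "Variant reads, reverse orientation")]
    )
    header.add_meta(
        "INFO", items=[("ID", "AF"), ("Number", 1), ("Type", "Float"),
                       ("Description", "Variant allele frequency (fraction)")]
    )
    return header


def write_variants_vcf(
    calls: Sequence[VariantCall], panel: Sequence[AmpliconDef], out: str | Path
) -> None:
    """Write calls as uncompressed VCF 4.2; an empty call list yields a
    parseable header-only file."""
    amps = {a.amplicon_id: a for a in panel}
    for c in calls:
        if c.amplicon_id not in amps:
            raise AmplicloneError(f"call on unknown amplicon {c.amplicon_id!r}")
    header = _header(panel)
    with pysam.VariantFile(str(out), "w", header=header) as vcf:
        for c in sorted(calls, key=lambda c: (c.amplicon_id, c.position, c.alt)):
            ref_seq = amps[c.amplicon_id].reference_seq
            if c.var_type == SUB:
                start, ref, alts = c.position, c.ref, (c.alt,)
            elif c.var_type == DEL:
                if c.position == 0:
                    raise AmplicloneError("deletion at contig start cannot be anchored")
                start = c.position - 1
                ref = ref_seq[start : c.position + len(c.ref)]
                alts = (ref_seq[start],)
            else:  # insertion: anchor base to the left
                start = c.position
                ref = ref_seq[start]
                alts = (ref + c.alt,)
            rec = vcf.new_record(
                contig=c.amplicon_id, start=start, alleles=(ref, *alts)
            )
            rec.info["DP"] = c.depth_fwd + c.depth_rev
            rec.info["DPF"] = c.depth_fwd
            rec.info["DPR"] = c.depth_rev
            rec.info["ADF"] = c.count_fwd
            rec.info["ADR"] = c.count_rev
            rec.info["AF"] = c.vaf
            vcf.write(rec)


def read_variants_vcf(path: str | Path, panel: Sequence[AmpliconDef]) -> list[VariantCall]:
    """Parse a VCF written by :func:`write_variants_vcf` back into calls."""
    amps = {a.amplicon_id: a for a in panel}
    calls = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.chrom not in amps:
                raise AmplicloneError(f"VCF contig {rec.chrom!r} not in panel")
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) == 1 and len(alt) == 1:
                var_type, pos, r, a = SUB, rec.start, ref, alt
            elif len(ref) > len(alt):
                var_type, pos, r, a = DEL, rec.start + 1, ref[1:], ""
            else:
                var_type, pos, r, a = INS, rec.start, "", alt[1:]
            calls.append(
                VariantCall(
                    amplicon_id=rec.chrom,
                    position=pos,
                    ref=r,
                    alt=a,
                    var_type=var_type,
                    count_fwd=int(rec.info["ADF"]),
                    count_rev=int(rec.info["ADR"]),
                    depth_fwd=int(rec.info["DPF"]),
                    depth_rev=int(rec.info["DPR"]),
                )
            )
    return calls
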