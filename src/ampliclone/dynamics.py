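"""Protein-level clone annotation, per-sample clone sets and longitudinal
clone-dynamics classification.

A *clone* is one distinct variant key within an amplicon; different
alternative alleles at the same hotspot position are different clones.  The
per-sample *VAF index* is the sum of the VAFs of all reported clones, a
scalar mutation burden used to stratify patients.

Across a diagnosis -> relapse pair each clone present in the reported set of
either time point falls in exactly one cluster: cluster 1 (diagnosis only,
behaviour ``disappearing``), cluster 2 (present at both; ``stable`` when the
relapse VAF is within the relative tolerance of the diagnosis VAF or below
it, ``evolving`` when expanded beyond it) or cluster 3 (relapse only,
``de_novo``).  Backtracking bypasses the reporting threshold and traces a
clone's raw VAF through every available time point, flagging sub-threshold
observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from Bio.Seq import Seq

from .errors import AmplicloneError
from .panel import AmpliconDef, revcomp
from .variant import SUB, CallingParams, VariantCall, VariantKey


@dataclass(frozen=True)
class Clone:
    """A reported (or sub-threshold) mutated clone of one sample."""

    key: VariantKey
    protein_label: str
    vaf_pct: float

    @property
    def gene_label(self) -> str:
        return f"{self.key.amplicon_id}:{self.protein_label}"


@dataclass
class SampleResult:
    """All surviving clones of one sample plus its VAF index (percent)."""

    sample_id: str
    time_point: str
    patient_id: str = ""
    clones: list[Clone] = field(default_factory=list)
    sub_threshold_clones: list[Clone] = field(default_factory=list)

    @property
    def vaf_index(self) -> float:
        return sum(c.vaf_pct for c in self.clones)

    @property
    def is_mutated(self) -> bool:
        return bool(self.clones)

    def find(self, key: VariantKey) -> Clone | None:
        for c in [*self.clones, *self.sub_threshold_clones]:
            if c.key == key:
                return c
        return None


@dataclass(frozen=True)
class DynamicsCall:
    """One clone's diagnosis -> relapse classification."""

    patient_id: str
    key: VariantKey
    protein_label: str
    vaf_diagnosis_pct: float  # 0 if absent from the reported set
    vaf_relapse_pct: float
    cluster: int  # 1: diagnosis only; 2: both; 3: relapse only
    behaviour: str  # disappearing / stable / evolving / de_novo
    shrunk: bool = False  # cluster-2 clone whose VAF dropped beyond tolerance


# ---------------------------------------------------------------------------
# Protein annotation
# ---------------------------------------------------------------------------

def annotate_protein(key: VariantKey, amplicon: AmpliconDef) -> str:
    """Protein-level label of a variant given the amplicon codon frame.

    Substitutions in the coding span translate the reference and alternate
    codons with the standard genetic code (``G12D``-style; silent changes
    repeat the reference amino acid, e.g. ``A66A``).  Indels are labelled
    ``p.?`` and variants outside the coding span ``noncoding``.
    """
    if key.var_type != SUB:
        a, b = key.ref_span()
        c0, c1 = amplicon.coding_span
        return "p.?" if a < c1 and b > c0 else "noncoding"
    pos = key.position
    c0, c1 = amplicon.coding_span
    if not c0 <= pos < c1:
        return "noncoding"
    ref_seq = amplicon.reference_seq
    if amplicon.strand_of_cds == 1:
        codon_idx = (pos - c0) // 3
        start = c0 + 3 * codon_idx
        ref_codon = ref_seq[start : start + 3]
        off = pos - start
        alt_codon = ref_codon[:off] + key.alt + ref_codon[off + 1 :]
    else:
        # coding strand is the reverse complement; codons count from the 3' end
        n_codons = (c1 - c0) // 3
        codon_idx = (c1 - 1 - pos) // 3
        end = c1 - 3 * codon_idx
        ref_codon = revcomp(ref_seq[end - 3 : end])
        alt_fwd = ref_seq[end - 3 : end]
        off = pos - (end - 3)
        alt_fwd = alt_fwd[:off] + key.alt + alt_fwd[off + 1 :]
        alt_codon = revcomp(alt_fwd)
    codon_number = amplicon.codon_start_number + codon_idx
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    return f"{ref_aa}{codon_number}{alt_aa}"


# ---------------------------------------------------------------------------
# Sample assembly and classification
# ---------------------------------------------------------------------------

def build_sample_result(
    full_calls: Sequence[VariantCall],
    panel: Sequence[AmpliconDef],
    sample_id: str,
    time_point: str,
    params: CallingParams | None = None,
    patient_id: str = "",
) -> SampleResult:
    """Split a sample's full call set into reported clones (VAF at or above
    the reporting threshold) and the sub-threshold backtracking store."""
    params = params or CallingParams()
    amps = {a.amplicon_id: a for a in panel}
    thr = params.reporting_vaf_threshold / 100.0
    res = SampleResult(sample_id=sample_id, time_point=time_point, patient_id=patient_id)
    for call in full_calls:
        amp = amps.get(call.amplicon_id)
        if amp is None:
            raise AmplicloneError(f"call on unknown amplicon {call.amplicon_id!r}")
        clone = Clone(call.key, annotate_protein(call.key, amp), call.vaf_pct)
        if call.vaf >= thr:
            res.clones.append(clone)
        else:
            res.sub_threshold_clones.append(clone)
    return res


def classify_dynamics(
    diagnosis: SampleResult,
    relapse: SampleResult,
    patient_id: str,
    rel_tolerance: float = 0.5,
) -> list[DynamicsCall]:
    """Classify every clone reported at either time point into clusters 1/2/3.

    Presence means membership of the *reported* set.  Cluster 2 covers every
    clone present at both time points; within it, a relapse VAF above
    ``diagnosis * (1 + rel_tolerance)`` is ``evolving``, anything else
    ``stable`` (a drop below ``diagnosis * (1 - rel_tolerance)`` keeps the
    stable label but sets the shrink flag).
    """
    if diagnosis.patient_id and relapse.patient_id and diagnosis.patient_id != relapse.patient_id:
        raise AmplicloneError(
            f"samples from different patients: {diagnosis.patient_id!r} vs {relapse.patient_id!r}"
        )
    calls: list[DynamicsCall] = []
    d_keys = {c.key: c for c in diagnosis.clones}
    r_keys = {c.key: c for c in relapse.clones}
    for key in sorted(set(d_keys) | set(r_keys)):
        d, r = d_keys.get(key), r_keys.get(key)
        label = (d or r).protein_label
        vd = d.vaf_pct if d else 0.0
        vr = r.vaf_pct if r else 0.0
        if d and not r:
            cluster, behaviour, shrunk = 1, "disappearing", False
        elif r and not d:
            cluster, behaviour, shrunk = 3, "de_novo", False
        else:
            cluster = 2
            if vr > vd * (1.0 + rel_tolerance):
                behaviour, shrunk = "evolving", False
            else:
                behaviour, shrunk = "stable", vr < vd * (1.0 - rel_tolerance)
        calls.append(
            DynamicsCall(
                patient_id=patient_id,
                key=key,
                protein_label=label,
                vaf_diagnosis_pct=vd,
                vaf_relapse_pct=vr,
                cluster=cluster,
                behaviour=behaviour,
                shrunk=shrunk,
            )
        )
    return calls


def backtrack_clone(
    timeline: Sequence[SampleResult],
    key: VariantKey,
    params: CallingParams | None = None,
) -> list[tuple[str, float, bool]]:
    """Raw VAF trace of one clone across an ordered timeline.

    Returns ``(time_point, vaf_pct, sub_threshold)`` per time point; a clone
    absent even from the full call set traces as 0 (flagged sub-threshold).
    """
    params = params or CallingParams()
    thr = params.reporting_vaf_threshold
    trace = []
    seen_anywhere = False
    for sample in timeline:
        clone = sample.find(key)
        v = clone.vaf_pct if clone else 0.0
        seen_anywhere = seen_anywhere or clone is not None
        trace.append((sample.time_point, v, v < thr))
    if not seen_anywhere:
        import logging

        logging.getLogger(__name__).warning("clone %s never observed in timeline", key)
    return trace


def stratify_by_vaf_index(
    diagnosis_results: dict[str, SampleResult], cutoff_pct: float = 10.0
) -> dict[str, list[str]]:
    """Partition patients into low (< cutoff) and high (>= cutoff) VAF-index
    groups at diagnosis; exactly-at-cutoff goes to ``high``."""
    groups: dict[str, list[str]] = {"low": [], "high": []}
    for patient_id, res in sorted(diagnosis_results.items()):
        groups["low" if res.vaf_index < cutoff_pct else "high"].append(patient_id)
    return groups
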