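"""Synthetic pyrosequencing-style amplicon read generator.

Reads are built haplotype-first: each read draws a haplotype (wild type or
one of the spiked subclones, multinomially by true VAF), the full fusion
construct ``MID + reference-with-variant + revcomp(MID)`` is assembled, and
sequencing noise is applied afterwards.  The noise model has three layers:

* iid per-base substitutions (``sub_rate``);
* homopolymer-length-dependent single-base indels: each maximal
  mononucleotide run of length L gains an indel with probability
  ``min(hp_indel_base * hp_indel_growth**(L-1), hp_indel_max)`` — the
  signature error mode of pyrosequencing chemistry;
* replicate-level "jackpot" artifacts: per generated library a few random
  loci carry a recurrent substitution at sub-percent per-read rate,
  emulating early-PCR-cycle errors that are amplified within one library
  but do not recur across independent replicate amplifications.  These are
  the artifacts that technical-replicate concordance filtering is designed
  to remove.

Per-base qualities are drawn independently of the simulated errors (the
downstream pipeline only uses a mean-quality gate).  Generation is a pure
function of the sample seed; replicates derive sub-seeds by stable hashing.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SimulationError
from .panel import AmpliconDef, MidTag, SampleManifestEntry, homopolymer_runs, revcomp
from .variant import DEL, INS, SUB, VariantKey

_BASES = "ACGT"
# run length at and above which the default calling parameters mask indels;
# jackpot loci avoid these tracts so that replicate-specific artifacts are
# not removed by the structural mask before calibration ever sees them
_MASKED_RUN_LEN = 4


def derive_seed(master: int, *parts: object) -> int:
    """Stable sub-seed from a master seed and arbitrary string-able tokens."""
    token = "|".join([str(master), *map(str, parts)])
    digest = hashlib.blake2b(token.encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class ErrorModel:
    """Platform noise parameters (per read). All probabilities in [0, 1]."""

    sub_rate: float = 0.002
    hp_indel_base: float = 0.001
    hp_indel_growth: float = 1.8
    hp_indel_max: float = 0.5
    q_mean: float = 33.0
    q_sd: float = 2.5
    jackpots_per_replicate: int = 8
    jackpot_rate: float = 0.0046

    def __post_init__(self) -> None:
        for name in ("sub_rate", "hp_indel_base", "hp_indel_max", "jackpot_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1]")
        if self.hp_indel_max > 0.5:
            raise SimulationError("capped homopolymer indel probability must be <= 0.5")
        if self.jackpots_per_replicate < 0:
            raise SimulationError("jackpots_per_replicate must be >= 0")

    @classmethod
    def error_free(cls) -> "ErrorModel":
        return cls(sub_rate=0.0, hp_indel_base=0.0, hp_indel_growth=1.0,
                   jackpots_per_replicate=0, jackpot_rate=0.0)

    def hp_rate(self, run_len: int) -> float:
        if self.hp_indel_base == 0.0:
            return 0.0
        return min(self.hp_indel_base * self.hp_indel_growth ** (run_len - 1), self.hp_indel_max)


@dataclass(frozen=True)
class CloneSpec:
    """A spiked subclone: one variant at a stated true VAF."""

    amplicon_id: str
    position: int
    ref: str
    alt: str
    var_type: str
    true_vaf: float
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_vaf <= 1.0:
            raise SimulationError("true_vaf must be in [0, 1]")
        if self.var_type not in (SUB, INS, DEL):
            raise SimulationError(f"unknown variant type {self.var_type!r}")

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.amplicon_id, self.position, self.ref, self.alt, self.var_type)

    def validate_against(self, amplicon: AmpliconDef) -> None:
        ref = amplicon.reference_seq
        if self.var_type in (SUB, DEL):
            if ref[self.position : self.position + len(self.ref)] != self.ref:
                raise SimulationError(f"clone {self.key} inconsistent with reference")
        if self.var_type == INS and not (0 <= self.position < len(ref)):
            raise SimulationError(f"clone {self.key} anchor outside reference")


@dataclass
class SampleSpec:
    """One library to simulate: clones, coverage, orientation mix and seed."""

    sample_id: str
    clone_specs: list[CloneSpec] = field(default_factory=list)
    coverage_per_amplicon: int = 1500
    fwd_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage_per_amplicon < 1:
            raise SimulationError("coverage must be >= 1")
        totals: dict[str, float] = {}
        seen: set[tuple[str, int, str]] = set()
        for c in self.clone_specs:
            totals[c.amplicon_id] = totals.get(c.amplicon_id, 0.0) + c.true_vaf
            ident = (c.amplicon_id, c.position, c.alt)
            if ident in seen:
                raise SimulationError("same-position clones must have distinct alt alleles")
            seen.add(ident)
        for amp, tot in totals.items():
            if tot > 1.0 + 1e-12:
                raise SimulationError(f"clone VAFs on {amp} sum to more than 1")


def _apply_variant(seq: str, clone: CloneSpec) -> str:
    p = clone.position
    if clone.var_type == SUB:
        return seq[:p] + clone.alt + seq[p + 1 :]
    if clone.var_type == DEL:
        return seq[:p] + seq[p + len(clone.ref) :]
    return seq[: p + 1] + clone.alt + seq[p + 1 :]


def _map_ref_pos(clone: CloneSpec | None, pos: int) -> int | None:
    """Map a reference position onto a clone haplotype (None if deleted)."""
    if clone is None or clone.var_type == SUB or pos <= clone.position:
        return pos
    if clone.var_type == DEL:
        if pos < clone.position + len(clone.ref):
            return None
        return pos - len(clone.ref)
    return pos + len(clone.alt)


def _jackpot_loci(
    panel: Sequence[AmpliconDef], model: ErrorModel, rng: np.random.Generator
) -> list[tuple[str, int, str]]:
    """Draw this replicate's jackpot artifact loci: (amplicon_id, ref position, alt)."""
    if model.jackpots_per_replicate == 0 or model.jackpot_rate == 0.0:
        return []
    eligible: list[tuple[str, int]] = []
    for amp in panel:
        a, b = amp.insert_span
        masked = [
            (s, e) for s, e, _ in homopolymer_runs(amp.reference_seq, _MASKED_RUN_LEN)
        ]
        for p in range(a + 2, b - 2):
            if any(s <= p < e for s, e in masked):
                continue
            if any(s <= p < e for s, e in amp.hotspot_spans):
                continue
            eligible.append((amp.amplicon_id, p))
    refs = {amp.amplicon_id: amp.reference_seq for amp in panel}
    loci = []
    idx = rng.choice(len(eligible), size=model.jackpots_per_replicate, replace=False)
    for i in idx:
        amp_id, p = eligible[i]
        alts = [b for b in _BASES if b != refs[amp_id][p]]
        loci.append((amp_id, p, alts[rng.integers(len(alts))]))
    return loci


def simulate_reads(
    spec: SampleSpec,
    panel: Sequence[AmpliconDef],
    mid: MidTag,
    error_model: ErrorModel | None = None,
) -> tuple[list[tuple[str, str, list[int]]], pd.DataFrame]:
    """Simulate one library; returns (reads, truth table).

    Reads are ``(read_id, sequence, phred_qualities)``.  The truth table has
    one row per emitted read: read_id, amplicon_id, haplotype (clone key or
    ``wt``), orientation, and a compact description of the applied noise in
    reference coordinates (MID bases are at negative offsets).
    """
    model = error_model or ErrorModel()
    rng = np.random.default_rng(spec.seed)
    panel = sorted(panel, key=lambda a: a.amplicon_id)
    amp_by_id = {a.amplicon_id: a for a in panel}
    for c in spec.clone_specs:
        if c.amplicon_id not in amp_by_id:
            raise SimulationError(f"clone references unknown amplicon {c.amplicon_id!r}")
        c.validate_against(amp_by_id[c.amplicon_id])

    jackpots = _jackpot_loci(panel, model, rng)
    mid_len = len(mid.sequence)
    reads: list[tuple[str, str, list[int]]] = []
    truth_rows = []

    for amp in panel:
        clones = [c for c in spec.clone_specs if c.amplicon_id == amp.amplicon_id]
        haplotypes: list[tuple[str, CloneSpec | None, str]] = [("wt", None, amp.reference_seq)]
        probs = [1.0 - sum(c.true_vaf for c in clones)]
        for c in clones:
            haplotypes.append((str(c.key), c, _apply_variant(amp.reference_seq, c)))
            probs.append(c.true_vaf)
        # full fusion constructs and their homopolymer runs, cached per haplotype
        constructs = []
        for name, clone, hap in haplotypes:
            full = mid.sequence + hap + revcomp(mid.sequence)
            runs = homopolymer_runs(full)
            rates = np.array([model.hp_rate(e - s) for s, e, _ in runs])
            jp = []
            for amp_id, p, alt in jackpots:
                if amp_id != amp.amplicon_id:
                    continue
                hp = _map_ref_pos(clone, p)
                if hp is not None:
                    jp.append((mid_len + hp, alt))
            constructs.append((name, full, runs, rates, jp))

        n = spec.coverage_per_amplicon
        hap_idx = rng.choice(len(haplotypes), size=n, p=np.asarray(probs))
        is_fwd = rng.random(n) < spec.fwd_fraction
        for i in range(n):
            name, full, runs, rates, jp = constructs[hap_idx[i]]
            edits: list[tuple[int, str, str]] = []  # (pos, kind, payload)
            noise_tags: list[str] = []
            if model.sub_rate > 0.0:
                hits = np.nonzero(rng.random(len(full)) < model.sub_rate)[0]
                for p in hits:
                    alt = _BASES[rng.integers(3)]
                    base = full[p]
                    if alt == base:
                        alt = _BASES[3]
                    edits.append((int(p), "sub", alt))
                    noise_tags.append(f"sub@{int(p) - mid_len}")
            if len(rates) and rates.max() > 0.0:
                run_hits = np.nonzero(rng.random(len(runs)) < rates)[0]
                for ri in run_hits:
                    s, e, b = runs[ri]
                    if rng.random() < 0.5:
                        edits.append((s, "del", ""))
                        noise_tags.append(f"del@{s - mid_len}")
                    else:
                        edits.append((s, "ins", b))
                        noise_tags.append(f"ins@{s - mid_len}")
            for p, alt in jp:
                if rng.random() < model.jackpot_rate:
                    edits.append((p, "sub", alt))
                    noise_tags.append(f"jackpot@{p - mid_len}")
            seq = full
            for p, kind, payload in sorted(edits, key=lambda t: -t[0]):
                if kind == "sub":
                    seq = seq[:p] + payload + seq[p + 1 :]
                elif kind == "del":
                    seq = seq[:p] + seq[p + 1 :]
                else:
                    seq = seq[: p + 1] + payload + seq[p + 1 :]
            orientation = "forward" if is_fwd[i] else "reverse"
            if orientation == "reverse":
                seq = revcomp(seq)
            quals = np.clip(np.rint(rng.normal(model.q_mean, model.q_sd, len(seq))), 2, 40)
            read_id = f"{spec.sample_id}.{amp.amplicon_id}.{i:05d}"
            reads.append((read_id, seq, [int(q) for q in quals]))
            truth_rows.append(
                {
                    "read_id": read_id,
                    "amplicon_id": amp.amplicon_id,
                    "haplotype": name,
                    "orientation": orientation,
                    "noise": ";".join(noise_tags),
                }
            )
    truth = pd.DataFrame(truth_rows, columns=["read_id", "amplicon_id", "haplotype", "orientation", "noise"])
    return reads, truth


def simulate_triplicates(
    spec: SampleSpec,
    panel: Sequence[AmpliconDef],
    mid: MidTag,
    error_model: ErrorModel | None = None,
    n_rep: int = 3,
) -> list[tuple[list[tuple[str, str, list[int]]], pd.DataFrame]]:
    """Simulate ``n_rep`` technical replicates differing only by derived sub-seeds."""
    if n_rep < 1:
        raise SimulationError("n_rep must be >= 1")
    out = []
    for rep in range(1, n_rep + 1):
        rep_spec = replace(spec, seed=derive_seed(spec.seed, spec.sample_id, f"rep{rep}"))
        out.append(simulate_reads(rep_spec, panel, mid, error_model))
    return out


def write_fastq(reads: Sequence[tuple[str, str, Sequence[int]]], path: str | Path) -> None:
    """Write 4-line FASTQ records (phred+33)."""
    with open(path, "w") as fh:
        for read_id, seq, quals in reads:
            qstr = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{read_id}\n{seq}\n+\n{qstr}\n")


# ---------------------------------------------------------------------------
# Cohorts: paired diagnosis/relapse patients with scenario-driven dynamics
# ---------------------------------------------------------------------------

BEHAVIOURS = ("disappearing", "stable", "de_novo", "evolving")

# catalogue of plausible hotspot subclone variants on the bundled panel
# (codon 12/13 first/second positions, codon 61 first/second positions)
HOTSPOT_CATALOGUE: tuple[tuple[str, int, str, str, str], ...] = (
    ("KRAS_EX2", 39, "G", "A", "G12D"),
    ("KRAS_EX2", 38, "G", "A", "G12S"),
    ("KRAS_EX2", 39, "G", "T", "G12V"),
    ("KRAS_EX2", 42, "G", "A", "G13D"),
    ("KRAS_EX3", 42, "A", "G", "Q61R"),
    ("KRAS_EX3", 41, "C", "A", "Q61K"),
    ("NRAS_EX2", 39, "G", "A", "G12D"),
    ("NRAS_EX2", 38, "G", "A", "G12S"),
    ("NRAS_EX2", 42, "G", "A", "G13D"),
    ("NRAS_EX3", 42, "A", "G", "Q61R"),
    ("NRAS_EX3", 41, "C", "A", "Q61K"),
    ("NRAS_EX3", 43, "A", "T", "Q61L"),
)


@dataclass
class CohortConfig:
    """Study design of a simulated diagnosis/relapse cohort."""

    n_patients: int = 17
    scenario_mix: dict = field(
        default_factory=lambda: {"disappearing": 0.3, "stable": 0.3, "de_novo": 0.2, "evolving": 0.2}
    )
    mutation_prevalence: float = 0.64
    coverage_per_amplicon: int = 1500
    fwd_fraction: float = 0.5
    error_model: ErrorModel = field(default_factory=ErrorModel)
    clones_min: int = 1
    clones_max: int = 3
    diag_vaf_pct_range: tuple[float, float] = (2.5, 30.0)
    include_patient35: bool = False
    # the backtracking/xenograft template is a dedicated few-sample
    # re-sequencing experiment, so its libraries are much deeper than the
    # routine multiplexed patient runs; depth is what separates its 1.2%
    # diagnosis clone from the 1% reporting boundary
    patient35_coverage: int = 15000
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.scenario_mix) - set(BEHAVIOURS):
            raise SimulationError(f"unknown behaviours in scenario mix: {self.scenario_mix}")
        if abs(sum(self.scenario_mix.values()) - 1.0) > 1e-9:
            raise SimulationError("scenario mix must sum to 1")
        if not 0.0 <= self.mutation_prevalence <= 1.0:
            raise SimulationError("mutation_prevalence must be in [0, 1]")


@dataclass
class CohortSim:
    """In-memory result of :func:`simulate_cohort`."""

    manifest: list[SampleManifestEntry]
    sample_specs: dict[str, SampleSpec]
    sample_mids: dict[str, str]
    clone_truth: pd.DataFrame  # patient, time_point, behaviour, clone key, label, true VAF (%)
    covariates: pd.DataFrame  # patient-level clinical covariates + true RAS status


def simulate_cohort(
    config: CohortConfig,
    panel: Sequence[AmpliconDef],
    mids: Sequence[MidTag],
    out_dir: str | Path | None = None,
) -> CohortSim:
    """Build per-patient diagnosis/relapse sample specs realising the assigned
    clone behaviours; optionally write FASTQ + truth + manifest files.

    Behaviours: ``disappearing`` (clone >=1% at diagnosis, absent at relapse),
    ``stable`` (both time points, similar VAF), ``evolving`` (expanded at
    relapse), ``de_novo`` (relapse only).  The optional patient-35 template
    adds a four-time-point patient (diagnosis, control, xenograft passages)
    with a diagnosis-only clone and a clone below the 1% cut-off at all
    patient time points that sweeps to high VAF in the xenograft.
    """
    rng = np.random.default_rng(config.seed)
    behaviours = sorted(config.scenario_mix)
    probs = np.array([config.scenario_mix[b] for b in behaviours])
    lo, hi = config.diag_vaf_pct_range

    manifest: list[SampleManifestEntry] = []
    sample_specs: dict[str, SampleSpec] = {}
    sample_mids: dict[str, str] = {}
    truth_rows = []
    cov_rows = []
    mid_cycle = [m.mid_id for m in mids]

    def add_sample(patient_id: str, time_point: str, clones: list[CloneSpec],
                   coverage: int | None = None) -> None:
        sample_id = f"{patient_id}_{time_point}"
        spec = SampleSpec(
            sample_id=sample_id,
            clone_specs=clones,
            coverage_per_amplicon=coverage or config.coverage_per_amplicon,
            fwd_fraction=config.fwd_fraction,
            seed=derive_seed(config.seed, sample_id),
        )
        sample_specs[sample_id] = spec
        mid_id = mid_cycle[len(manifest) % len(mid_cycle)]
        sample_mids[sample_id] = mid_id
        manifest.append(
            SampleManifestEntry(
                sample_id=sample_id,
                patient_id=patient_id,
                time_point=time_point,
                replicate=1,
                mid_id=mid_id,
                fastq_path=f"{sample_id}.fastq",
            )
        )

    for i in range(config.n_patients):
        patient_id = f"P{i + 1:02d}"
        mutated = rng.random() < config.mutation_prevalence
        behaviour = behaviours[rng.choice(len(behaviours), p=probs)] if mutated else ""
        diag_clones: list[CloneSpec] = []
        rel_clones: list[CloneSpec] = []
        if mutated:
            n_clones = int(rng.integers(config.clones_min, config.clones_max + 1))
            # one clone per amplicon, so per-amplicon clone fractions can
            # never exceed the haplotype budget even after relapse expansion
            picks = []
            used_amps: set[str] = set()
            for j in rng.permutation(len(HOTSPOT_CATALOGUE)):
                if HOTSPOT_CATALOGUE[j][0] not in used_amps:
                    picks.append(int(j))
                    used_amps.add(HOTSPOT_CATALOGUE[j][0])
                if len(picks) == n_clones:
                    break
            for j in picks:
                amp_id, pos, ref, alt, label = HOTSPOT_CATALOGUE[j]
                diag_vaf = float(np.exp(rng.uniform(np.log(lo), np.log(hi)))) / 100.0
                if behaviour == "disappearing":
                    vd, vr = diag_vaf, 0.0
                elif behaviour == "stable":
                    vd, vr = diag_vaf, diag_vaf * float(rng.uniform(0.85, 1.15))
                elif behaviour == "evolving":
                    vd, vr = diag_vaf, min(diag_vaf * float(rng.uniform(2.0, 3.5)), 0.6)
                else:  # de_novo
                    vd, vr = 0.0, diag_vaf
                if vd > 0.0:
                    diag_clones.append(CloneSpec(amp_id, pos, ref, alt, SUB, vd, label))
                if vr > 0.0:
                    rel_clones.append(CloneSpec(amp_id, pos, ref, alt, SUB, vr, label))
                truth_rows.append(
                    {
                        "patient_id": patient_id,
                        "behaviour": behaviour,
                        "clone": str(VariantKey(amp_id, pos, ref, alt, SUB)),
                        "label": label,
                        "vaf_diagnosis_pct": 100.0 * vd,
                        "vaf_relapse_pct": 100.0 * vr,
                    }
                )
        add_sample(patient_id, "diagnosis", diag_clones)
        add_sample(patient_id, "relapse1", rel_clones)
        cov_rows.append(
            {
                "patient_id": patient_id,
                "ras_truth": "pos" if mutated else "neg",
                "sex": str(rng.choice(["M", "F"])),
                "age_group": str(rng.choice(["infant", "child"], p=[0.65, 0.35])),
                "wbc_group": str(rng.choice(["lt100", "100to300", "ge300"], p=[0.15, 0.27, 0.58])),
                "pdn_response": str(rng.choice(["PPR", "PGR"], p=[0.28, 0.72])),
            }
        )

    if config.include_patient35:
        patient_id = "P35T"
        g12s = ("KRAS_EX2", 38, "G", "A", "G12S")
        q61r = ("NRAS_EX3", 42, "A", "G", "Q61R")
        plan = {
            "diagnosis": [(g12s, 0.012), (q61r, 0.005)],
            "control": [(q61r, 0.004)],
            "xeno_p1": [(q61r, 0.006)],
            "xeno_p2": [(q61r, 0.30)],
        }
        for tp, clone_plan in plan.items():
            clones = [
                CloneSpec(a, p, r, alt, SUB, vaf, label)
                for (a, p, r, alt, label), vaf in clone_plan
            ]
            add_sample(patient_id, tp, clones, coverage=config.patient35_coverage)
            for (a, p, r, alt, label), vaf in clone_plan:
                truth_rows.append(
                    {
                        "patient_id": patient_id,
                        "behaviour": "patient35_template",
                        "clone": str(VariantKey(a, p, r, alt, SUB)),
                        "label": label,
                        "vaf_diagnosis_pct": float("nan"),
                        "vaf_relapse_pct": float("nan"),
                    }
                )

    clone_truth = pd.DataFrame(
        truth_rows,
        columns=["patient_id", "behaviour", "clone", "label", "vaf_diagnosis_pct", "vaf_relapse_pct"],
    )
    covariates = pd.DataFrame(
        cov_rows, columns=["patient_id", "ras_truth", "sex", "age_group", "wbc_group", "pdn_response"]
    )
    sim = CohortSim(manifest, sample_specs, sample_mids, clone_truth, covariates)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        mid_by_id = {m.mid_id: m for m in mids}
        entries = []
        for entry in manifest:
            spec = sample_specs[entry.sample_id]
            reads, truth = simulate_reads(spec, panel, mid_by_id[entry.mid_id], config.error_model)
            fastq = out / f"{entry.sample_id}.fastq"
            write_fastq(reads, fastq)
            truth.to_csv(out / f"{entry.sample_id}.truth.tsv", sep="\t", index=False)
            entries.append(replace(entry, fastq_path=str(fastq)))
        sim.manifest = entries
        from .panel import write_manifest

        write_manifest(entries, out / "manifest.tsv")
        clone_truth.to_csv(out / "clone_truth.tsv", sep="\t", index=False)
        covariates.to_csv(out / "covariates.tsv", sep="\t", index=False)
    return sim
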