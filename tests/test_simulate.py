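"""Read generator: determinism, truth tables, noise model, cohorts."""

import re

import numpy as np
import pytest

from ampliclone.errors import SimulationError
from ampliclone.panel import homopolymer_runs, revcomp
from ampliclone.pipeline import call_sample
from ampliclone.simulate import (
    CloneSpec,
    CohortConfig,
    ErrorModel,
    SampleSpec,
    derive_seed,
    simulate_cohort,
    simulate_reads,
    simulate_triplicates,
    write_fastq,
)

G12D = CloneSpec("KRAS_EX2", 39, "G", "A", "sub", 0.05, "G12D")


class TestSimulateReads:
    def test_error_free_no_clones_reads_equal_reference(self, panel, mids, error_free):
        spec = SampleSpec("s", [], coverage_per_amplicon=30, seed=5)
        reads, truth = simulate_reads(spec, panel, mids[0], error_free)
        amp_by_id = {a.amplicon_id: a for a in panel}
        orient = dict(zip(truth.read_id, truth.orientation))
        for read_id, seq, _ in reads:
            amp = amp_by_id[read_id.split(".")[1]]
            expected = mids[0].sequence + amp.reference_seq + revcomp(mids[0].sequence)
            if orient[read_id] == "reverse":
                expected = revcomp(expected)
            assert seq == expected
        assert (truth.haplotype == "wt").all()

    def test_truth_table_multinomial_oracle(self, panel, mids, error_free):
        """The called VAF equals the alt fraction recomputed from the truth table."""
        spec = SampleSpec("s", [G12D], coverage_per_amplicon=1000, seed=11)
        reads, truth = simulate_reads(spec, panel, mids[0], error_free)
        k2 = truth[truth.amplicon_id == "KRAS_EX2"]
        n_alt = (k2.haplotype == str(G12D.key)).sum()
        calls, _ = call_sample(reads, panel, mids, "s")
        (call,) = calls
        assert call.count_fwd + call.count_rev == n_alt
        assert call.vaf == n_alt / len(k2)

    def test_same_seed_byte_identical_fastq(self, panel, mids, tmp_path):
        spec = SampleSpec("s", [G12D], coverage_per_amplicon=50, seed=9)
        for name in ("a.fastq", "b.fastq"):
            reads, _ = simulate_reads(spec, panel, mids[0], ErrorModel())
            write_fastq(reads, tmp_path / name)
        assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()

    def test_invalid_clone_rejected(self, panel, mids):
        bad = CloneSpec("KRAS_EX2", 39, "T", "A", "sub", 0.05)  # ref base is G
        with pytest.raises(SimulationError, match="inconsistent"):
            simulate_reads(SampleSpec("s", [bad], 10, seed=1), panel, mids[0])

    def test_same_position_distinct_alts_required(self):
        with pytest.raises(SimulationError, match="distinct alt"):
            SampleSpec("s", [G12D, G12D], 10, seed=1)

    def test_vaf_budget_per_amplicon(self):
        a = CloneSpec("KRAS_EX2", 39, "G", "A", "sub", 0.6)
        b = CloneSpec("KRAS_EX2", 42, "G", "A", "sub", 0.6)
        with pytest.raises(SimulationError, match="sum"):
            SampleSpec("s", [a, b], 10, seed=1)


class TestNoiseModel:
    def test_homopolymer_enrichment(self, panel, mids):
        """Indel noise per run grows with run length when hp_indel_growth > 1,
        verified against the truth-table noise annotations."""
        em = ErrorModel(sub_rate=0.0, hp_indel_base=0.002, hp_indel_growth=1.8,
                        jackpots_per_replicate=0)
        spec = SampleSpec("s", [], coverage_per_amplicon=4000, seed=21)
        _, truth = simulate_reads(spec, panel, mids[0], em)
        amp = {a.amplicon_id: a for a in panel}
        hits = {1: 0, 3: 0}
        opportunities = {1: 0, 3: 0}
        run_len_by_pos = {}
        for a in panel:
            full = mids[0].sequence + a.reference_seq + revcomp(mids[0].sequence)
            for s, e, _ in homopolymer_runs(full):
                run_len_by_pos[(a.amplicon_id, s - len(mids[0].sequence))] = e - s
        n_reads = truth.groupby("amplicon_id").size()
        for (amp_id, pos), L in run_len_by_pos.items():
            if L in opportunities:
                opportunities[L] += int(n_reads[amp_id])
        for row in truth.itertuples():
            for tag in filter(None, row.noise.split(";")):
                kind, pos = tag.split("@")
                L = run_len_by_pos.get((row.amplicon_id, int(pos)))
                if L in hits:
                    hits[L] += 1
        rate1 = hits[1] / opportunities[1]
        rate3 = hits[3] / opportunities[3]
        assert rate3 > 2 * rate1 > 0

    def test_binomial_vaf_recovery(self, panel, mids, error_free):
        """Spiked VAF v at coverage N is recovered within 4*sqrt(v(1-v)/N)
        in at least 95% of seeded runs."""
        v, N = 0.05, 1500
        bound = 4 * np.sqrt(v * (1 - v) / N)
        ok = 0
        n_runs = 24
        for seed in range(n_runs):
            spec = SampleSpec(f"s{seed}", [CloneSpec("KRAS_EX2", 39, "G", "A", "sub", v)],
                              coverage_per_amplicon=N, seed=seed)
            _, truth = simulate_reads(spec, panel, mids[0], error_free)
            k2 = truth[truth.amplicon_id == "KRAS_EX2"]
            obs = (k2.haplotype != "wt").mean()
            ok += abs(obs - v) <= bound
        assert ok >= 0.95 * n_runs

    def test_error_model_validation(self):
        with pytest.raises(SimulationError):
            ErrorModel(sub_rate=1.5)
        with pytest.raises(SimulationError):
            ErrorModel(hp_indel_max=0.9)


class TestTriplicates:
    def test_replicates_differ_but_share_clones(self, panel, mids):
        spec = SampleSpec("s", [G12D], coverage_per_amplicon=200, seed=3)
        reps = simulate_triplicates(spec, panel, mids[0], ErrorModel(), n_rep=3)
        assert len(reps) == 3
        seqs = ["".join(s for _, s, _ in reads) for reads, _ in reps]
        assert len(set(seqs)) == 3  # different sub-seeds, different reads
        for _, truth in reps:
            assert (truth.haplotype == str(G12D.key)).any()

    def test_single_replicate_allowed(self, panel, mids, error_free):
        assert len(simulate_triplicates(SampleSpec("s", [], 10, seed=1), panel, mids[0],
                                        error_free, n_rep=1)) == 1

    def test_zero_replicates_error(self, panel, mids):
        with pytest.raises(SimulationError):
            simulate_triplicates(SampleSpec("s", [], 10, seed=1), panel, mids[0], n_rep=0)

    def test_derive_seed_stable_and_bounded(self):
        assert derive_seed(1, "a", 2) == derive_seed(1, "a", 2)
        assert derive_seed(1, "a") != derive_seed(1, "b")
        assert 0 <= derive_seed(2**40, "x") < 2**31


class TestCohort:
    def test_bad_scenario_mix(self):
        with pytest.raises(SimulationError, match="sum"):
            CohortConfig(scenario_mix={"stable": 0.5, "de_novo": 0.2})

    def test_empty_cohort(self, panel, mids):
        sim = simulate_cohort(CohortConfig(n_patients=0), panel, mids)
        assert sim.manifest == [] and sim.sample_specs == {}

    def test_manifest_structure_and_determinism(self, panel, mids):
        cfg = CohortConfig(n_patients=4, coverage_per_amplicon=10, seed=5)
        a = simulate_cohort(cfg, panel, mids)
        b = simulate_cohort(cfg, panel, mids)
        assert a.manifest == b.manifest
        assert a.clone_truth.equals(b.clone_truth)
        assert len(a.manifest) == 8  # diagnosis + relapse per patient
        assert {e.time_point for e in a.manifest} == {"diagnosis", "relapse1"}

    def test_scenarios_encoded_in_specs(self, panel, mids):
        cfg = CohortConfig(n_patients=12, mutation_prevalence=1.0, seed=8,
                           scenario_mix={"disappearing": 1.0, "stable": 0, "de_novo": 0, "evolving": 0})
        sim = simulate_cohort(cfg, panel, mids)
        for pid in {e.patient_id for e in sim.manifest}:
            assert sim.sample_specs[f"{pid}_diagnosis"].clone_specs
            assert sim.sample_specs[f"{pid}_relapse1"].clone_specs == []

    def test_patient35_template(self, panel, mids):
        sim = simulate_cohort(CohortConfig(n_patients=0, include_patient35=True), panel, mids)
        tps = [e.time_point for e in sim.manifest]
        assert tps == ["diagnosis", "control", "xeno_p1", "xeno_p2"]
        diag = sim.sample_specs["P35T_diagnosis"]
        assert {c.label for c in diag.clone_specs} == {"G12S", "Q61R"}
        q61r_vafs = {
            e.time_point: next(c.true_vaf for c in sim.sample_specs[e.sample_id].clone_specs if c.label == "Q61R")
            for e in sim.manifest
        }
        assert q61r_vafs["diagnosis"] < 0.01 and q61r_vafs["xeno_p2"] >= 0.01

    def test_cohort_files_written(self, panel, mids, tmp_path, error_free):
        cfg = CohortConfig(n_patients=1, coverage_per_amplicon=15, seed=2, error_model=error_free)
        sim = simulate_cohort(cfg, panel, mids, out_dir=tmp_path)
        assert (tmp_path / "manifest.tsv").exists()
        for e in sim.manifest:
            assert (tmp_path / f"{e.sample_id}.fastq").exists()
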