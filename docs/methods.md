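# Methods

`ampliclone` models the analysis of ultra-deep amplicon pyrosequencing of
*KRAS*/*NRAS* hotspot regions (exon 2 codons 12/13, exon 3 codon 61) in
leukaemia samples: strict read conservation, alignment-based variant
tallying with structural masks, a technical-replicate procedure that
calibrates the reporting VAF threshold, longitudinal clone-dynamics
classification, and exact association tests on patient characteristics.
This note records the model, its assumptions, the defaults, and the design
choices made where the procedure is genuinely open.

## Read structure and conservation rules

Each fusion-primer read is `MID + primer_fwd + insert + primer_rev' + MID'`
(primes are reverse complements); a reverse-orientation read is the reverse
complement of the whole construct, so the same MID appears at the 5' end in
both orientations. Four read filters apply, all strict:

* **MID match** — the 5' MID and the reverse complement of the *same* MID at
  the 3' end must match exactly; barcode sets are validated to be
  pairwise-distinct and prefix-free, so exact matching is unambiguous.
* **Primer match** — both gene-specific primers must be complete and
  mismatch-free; a read whose two primers belong to different amplicons
  (chimera-like) is rejected, as is any ambiguous match.
* **Mean quality** — the arithmetic mean phred score of the whole raw read
  (before any trimming) must be strictly above Q20. Computing it pre-trim is
  a choice: the rule is stated for raw "sequences", and the simulated
  quality model makes the boundary case vanishingly rare either way.
* **Full length** — the trimmed payload must align end-to-end to the
  inter-primer insert with a total inserted + deleted length of at most
  `max_indel_slack` (default 10 bases, a bound on tolerated pyrosequencing
  indel noise; "full-length" is otherwise unquantified). The check uses a
  global edit-distance alignment (edlib).

The four predicates are mutually independent, so the kept set does not
depend on filter order; discard counts are attributed to the first failing
rule in the order above and always balance the input count.

## Alignment and variant tallying

Kept payloads are aligned globally to the insert with match +1, mismatch
−2, gap open −4, gap extend −1 (the open score prices the first gap base;
a length-k gap costs 4 + (k−1)). These scores, and the tie-breaks —
left-normalised indel placement, substitutions preferred at score ties —
are fixed and documented because the original vendor software does not
expose its internals; tests verify score-optimality against an independent
Gotoh dynamic program and payload reconstruction from the extracted
operations. Indels are left-normalised on the *full* reference, so an event
at the insert edge can normalise into the primer region (where the primer
mask then removes it), and a run-extending insertion anchors one base
before the run.

Every non-matching alignment operation contributes to exactly one variant
key `(amplicon, position, ref, alt, type)`; distinct alternative alleles at
one position are distinct clones. The spanning depth of a position counts
reads covering it with an aligned base *or a deletion* — with full-length
global alignments this is every kept read of the amplicon, per orientation.
VAF = variant reads / spanning reads, orientations pooled.

### Structural masks

* **Primer-adjacent**: the variant footprint intersects either primer span
  extended by 1 base (configurable margin).
* **Homopolymer**: an indel whose footprint lies within, or whose insertion
  point touches, a reference mononucleotide run of length ≥ 4, or a
  substitution inside such a run. The vendor's proprietary "dynamic N-mer
  thresholding" is deliberately replaced by this declared static rule:
  reproducibility is preferred over fidelity to an undocumented algorithm.
  The minimum run length (4) is configurable.

### Support filters

A variant is kept in the *full call set* iff it is unmasked, observed on
both strands, and reaches ≥ 1 read and ≥ 0.01% of the per-orientation
spanning depth in each orientation (inclusive thresholds; the per-direction
percentage uses the per-orientation depth as its denominator). The
*reported set* additionally requires VAF ≥ the reporting threshold
(default 1%, inclusive — a VAF of exactly 1.00% is reported). Sub-threshold
calls remain in the full set for backtracking.

## Synthetic data generator

The generator is haplotype-first: each read draws wild type or one spiked
subclone (multinomial by true VAF), the full fusion construct is assembled,
and noise is applied afterwards. There is no PCR-lineage or flowgram
simulation; the downstream filters act on read-level noise only. Qualities
are drawn independently of errors (only a mean-Q gate consumes them),
Normal(33, 2.5) rounded and clipped to [2, 40].

Noise layers and defaults:

* `sub_rate = 0.2%` — iid per-base substitutions.
* `hp_indel_base = 0.1%`, `hp_indel_growth = 1.8`, capped at 0.5 — each
  maximal mononucleotide run of length L gains a single-base indel with
  probability `base·growth^(L−1)`, the signature pyrosequencing error mode.
  The bundled panel's references carry designed runs of length 3 (noise
  sources that stay unmasked) and length ≥ 4 (masked tracts) per amplicon.
* `jackpots_per_replicate = 8`, `jackpot_rate = 0.46%` — per generated
  library, eight random unmasked non-hotspot loci carry a recurrent
  substitution at sub-percent per-read rate, emulating early-PCR-cycle
  errors amplified within one library. This layer exists because iid
  per-read noise cannot produce *replicate-discordant* artifacts in the
  0.5–1% VAF stratum: any iid artifact frequent enough to reach that
  stratum at ~10³-fold coverage appears in every replicate and would be
  scored concordant, which would make replicate concordance useless exactly
  where the threshold decision is made. Replicate-specific amplification
  jackpots are the real-world mechanism that concordance filtering targets.

No platform error rates were available to copy; these values are declared
assumptions, chosen once so that the sub-1% VAF strata contain artifacts
while the 1–5% stratum is clean, and are configurable.

Sub-seeds for replicates and cohort samples derive from the master seed by
stable hashing (blake2b), so generation is a pure function of the seed and
regeneration is byte-identical.

### Cohorts

A cohort configuration assigns each patient mutated status (default
prevalence 64%), a clone behaviour — `disappearing`, `stable`, `de_novo`,
`evolving` — and 1–3 hotspot clones drawn from a catalogue of codon
12/13/61 variants, at most one clone per amplicon so relapse expansion can
never overflow an amplicon's haplotype budget. Diagnosis VAFs are
log-uniform on 2.5–30%: the floor keeps nominal clones clearly away from
the 1% reporting boundary, so error-free closure is not confounded by
multinomial sampling of the clone fraction itself; the ceiling matches the
upper range of observed VAF indexes. Stable clones relapse at ×U(0.85,
1.15), evolving at ×U(2.0, 3.5) capped at 60%. The optional patient-35
template adds a four-time-point patient (diagnosis, control, two xenograft
passages) carrying a diagnosis-only clone at 1.2% and a second clone at
0.4–0.6% — below the reporting cut-off — at all patient time points,
sweeping to 30% at the second xenograft passage. Template libraries are
sequenced at 15000× (a dedicated few-sample re-sequencing experiment, not
a routine multiplexed run): at 1500× the 1.2% clone sits less than one
standard deviation of multinomial sampling away from the 1% boundary,
whereas at 15000× its reported status is stable across seeds — depth is
precisely what makes backtracking below the threshold meaningful.

What the generator does *not* emulate: PCR duplicates and chimeras,
flowgram-space (SFF) artifacts, context-dependent substitution spectra,
sample cross-talk, and coverage heterogeneity along the amplicon. Passing
closure tests therefore demonstrates internal consistency of the pipeline
under the declared noise model, not performance on real 454 data.

## Threshold calibration by technical replicates

Full call sets of ≥ 2 replicates are intersected by variant key: keys in
every replicate are concordant ("true"), the rest discordant. Keys are
binned by their mean VAF across the replicates containing them (a
discordant variant still needs one well-defined bin) into
`[0.01, 0.1), [0.1, 0.3), [0.3, 0.5), [0.5, 1), [1, 5), [5, ∞)` percent;
variants below 0.01% are outside the calibration universe. The selected
threshold is the lower edge of the lowest bin from which upward every bin
has discordant fraction ≤ 5% (empty bins count as clean). The 5% tolerance
formalises "minor false-positive calls"; it is a parameter, reported with
every calibration. A `hotspot_only` switch restricts the variant universe
to the panel's hotspot windows.

The calibration study design simulates triplicates at 4000× per amplicon
(deeper than routine 1500× patient libraries, as a dedicated calibration
experiment with few multiplexed samples would be): at ~10³-fold coverage
the 0.5–1% bin is only a few read counts wide and Poisson fluctuation
across its upper edge would make the selected threshold unstable, while at
4000× the strata separate cleanly. With the default error model this
procedure selects the 1% threshold in ≥ 18 of 20 independent runs.

## Clone dynamics

A sample's reported clones form its clone set; the VAF index is the sum of
their VAFs. Across a diagnosis → relapse pair, each clone reported at
either time point falls in exactly one cluster: 1 (diagnosis only), 2
(both), 3 (relapse only). Within cluster 2 the behaviour is `evolving` when
the relapse VAF exceeds diagnosis × (1 + tolerance) and `stable` otherwise;
the tolerance (default ±50%) is a formalisation — the source analyses show
the stable/evolving distinction only graphically — and a clone that shrinks
below diagnosis × (1 − tolerance) stays in cluster 2 ("similar or
increased" subsumes persistence) with a shrink flag. Presence means
membership of the *reported* set; backtracking deliberately bypasses the
threshold and traces raw VAFs through any ordered timeline, flagging
sub-threshold observations. Xenograft passages and control samples are
ordinary time points, so multi-point analyses need no special-casing.
Patients stratify by diagnosis VAF index at 10% (exactly 10% goes to the
high group; the source states only strict `<`/`>` wording).

Protein annotation translates reference and alternate codons with the
standard genetic code on the recorded frame (`G12D`, silent `A66A`);
indels are `p.?`, variants outside the coding span `noncoding`. Reverse-
strand frames are supported.

## Association statistics

Both the 2×2 Fisher test and the Freeman–Halton r×c generalisation use the
probability method — with margins fixed, the two-sided p is the sum of
probabilities of all tables at most as probable as the observed one — with
exact rational arithmetic, so knife-edge ties need no floating-point slack
and the r×c test restricted to 2×2 coincides with the 2×2 test to machine
precision. Tables too large to enumerate can use a seeded Monte-Carlo
permutation mode that reports a standard error. The patient-characteristics
report cross-tabulates RAS status against sex, age (infants, ≤ 1 year,
vs older children), WBC count and prednisone response, excluding unknown
values per comparison only. The WBC comparison dichotomises the three
printed strata at 300×10⁹/L (< 300 vs ≥ 300): this reproduces the published
p-value exactly, whereas a 2×3 Freeman–Halton test on the printed strata
does not, so the dichotomy is evidently what the published analysis did.

## Numerical and degenerate-input conventions

* Thresholds are inclusive (≥) everywhere; the reporting comparison is done
  on fractions (`vaf >= threshold_pct / 100`) to avoid scale-conversion
  round-off at the exact boundary.
* Empty calibration bins have discordant fraction 0; degenerate contingency
  margins give p = 1; a clone never observed in a timeline backtracks as an
  all-zero trace with a warning; zero spanning depth drops a candidate with
  a warning.
* Equal-length payloads with ≤ 3 mismatches take a substitution-only fast
  path (provably optimal under the scoring above; ties prefer mismatches);
  alignments are cached per distinct payload within a sample.
* The VAF index equals the sum of its clones' VAFs to 1e−9 (percent scale).

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the full pipeline at the study
scale the package documents: a 36-patient error-free cohort at 1500× per
amplicon (plus the patient-35 template), twenty 3-replicate calibration
runs at 4000×, 24-seed binomial recovery, and 500-replicate null
simulations for the test's size. These sizes keep every check exact or
well-powered while completing in minutes on one CPU.

## Known limitations

* The error model is declared, not fitted; absolute artifact rates on real
  GS Junior data will differ, and the calibrated threshold with them.
* The homopolymer mask is static; a genuine dynamic N-mer model could
  rescue true indels inside short tracts that this rule discards.
* Multi-nucleotide variants are tallied per position (no phasing), and
  adjacent substitutions are separate clones.
* The Freeman–Halton enumeration is exponential in table size; beyond
  N ≈ 100 only the Monte-Carlo mode is practical.
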