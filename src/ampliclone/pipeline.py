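"""High-level orchestration helpers tying the stages together in memory."""

from __future__ import annotations

from typing import Sequence

from .calling import CallingParams, call_variants
from .calibration import CalibrationResult, calibrate
from .dynamics import SampleResult, build_sample_result
from .panel import AmpliconDef, MidTag
from .reads import FilterReport, process_reads
from .simulate import ErrorModel, SampleSpec, simulate_reads, simulate_triplicates
from .variant import VariantCall


def call_sample(
    reads,
    panel: Sequence[AmpliconDef],
    mids: Sequence[MidTag],
    sample_id: str,
    expected_mid: str | None = None,
    params: CallingParams | None = None,
    max_indel_slack: int = 10,
) -> tuple[list[VariantCall], FilterReport]:
    """Filter raw reads and produce the sample's full call set."""
    processed, report = process_reads(
        reads, panel, mids, sample_id, expected_mid=expected_mid, max_indel_slack=max_indel_slack
    )
    calls = call_variants(processed, panel, params)
    return calls, report


def simulate_and_call(
    spec: SampleSpec,
    panel: Sequence[AmpliconDef],
    mid: MidTag,
    error_model: ErrorModel | None = None,
    params: CallingParams | None = None,
) -> list[VariantCall]:
    """Simulate one library and call its variants (truth table discarded)."""
    reads, _ = simulate_reads(spec, panel, mid, error_model)
    calls, _ = call_sample(reads, panel, [mid], spec.sample_id, expected_mid=mid.mid_id, params=params)
    return calls


def simulate_sample_result(
    spec: SampleSpec,
    panel: Sequence[AmpliconDef],
    mid: MidTag,
    time_point: str,
    error_model: ErrorModel | None = None,
    params: CallingParams | None = None,
) -> SampleResult:
    """Simulate, call and assemble one sample's clone set."""
    calls = simulate_and_call(spec, panel, mid, error_model, params)
    return build_sample_result(calls, panel, spec.sample_id, time_point, params)


def calibrate_triplicates(
    spec: SampleSpec,
    panel: Sequence[AmpliconDef],
    mid: MidTag,
    error_model: ErrorModel | None = None,
    params: CallingParams | None = None,
    n_rep: int = 3,
    max_discordant_fraction: float = 0.05,
    hotspot_only: bool = False,
) -> CalibrationResult:
    """Simulate technical replicates of one sample and run the concordance
    calibration on their full call sets."""
    call_sets = []
    for reads, _ in simulate_triplicates(spec, panel, mid, error_model, n_rep):
        calls, _ = call_sample(reads, panel, [mid], spec.sample_id, expected_mid=mid.mid_id, params=params)
        call_sets.append(calls)
    return calibrate(
        call_sets,
        max_discordant_fraction=max_discordant_fraction,
        hotspot_only=hotspot_only,
        panel=panel,
    )
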