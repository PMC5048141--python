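"""Technical-replicate concordance calibration of the reporting VAF threshold.

A variant observed in *all* replicates of a triplicate experiment (by
identity key; VAFs may differ) is treated as a true positive; anything seen
in only a subset is replicate noise.  Variants are binned by their mean VAF
across the replicates containing them into the intervals
``[0.01, 0.1), [0.1, 0.3), [0.3, 0.5), [0.5, 1), [1, 5), [5, inf)`` percent,
and the per-bin discordant fraction estimates the false-positive burden of
that VAF stratum.  The reporting threshold is the lower edge of the lowest
bin from which upward every bin is sufficiently clean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import CalibrationError
from .panel import AmpliconDef
from .variant import VariantCall, VariantKey

DEFAULT_BIN_EDGES_PCT = (0.01, 0.1, 0.3, 0.5, 1.0, 5.0)
CALIBRATION_FLOOR_PCT = 0.01


@dataclass(frozen=True)
class VafBins:
    """Ascending VAF bin lower edges in percent; the last bin is open-ended."""

    edges_pct: tuple[float, ...] = DEFAULT_BIN_EDGES_PCT

    def __post_init__(self) -> None:
        if list(self.edges_pct) != sorted(set(self.edges_pct)):
            raise CalibrationError("bin edges must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.edges_pct)

    def assign(self, vaf_pct: float) -> int | None:
        """Index of the bin containing ``vaf_pct``; None below the first edge."""
        idx = int(np.searchsorted(self.edges_pct, vaf_pct, side="right")) - 1
        return idx if idx >= 0 else None

    def label(self, i: int) -> str:
        if i == self.n - 1:
            return f">={self.edges_pct[i]}"
        return f"[{self.edges_pct[i]},{self.edges_pct[i + 1]})"


@dataclass
class CalibrationResult:
    """Per-bin concordance tallies and the selected reporting threshold."""

    bins: VafBins
    n_concordant: list[int]
    n_discordant: list[int]
    selected_threshold_pct: float | None = None
    hotspot_only: bool = False

    @property
    def discordant_fraction(self) -> list[float]:
        out = []
        for c, d in zip(self.n_concordant, self.n_discordant):
            out.append(d / (c + d) if c + d else 0.0)
        return out

    def as_dict(self) -> dict:
        return {
            "bins": [self.bins.label(i) for i in range(self.bins.n)],
            "n_concordant": self.n_concordant,
            "n_discordant": self.n_discordant,
            "discordant_fraction": self.discordant_fraction,
            "selected_threshold_pct": self.selected_threshold_pct,
            "hotspot_only": self.hotspot_only,
        }


def concordant_variants(
    replicate_call_sets: Sequence[Sequence[VariantCall]],
) -> tuple[set[VariantKey], set[VariantKey]]:
    """Split the union of replicate calls into concordant (present in every
    replicate) and discordant (present in a strict subset) key sets."""
    if len(replicate_call_sets) < 2:
        raise CalibrationError("concordance needs at least 2 replicates")
    key_sets = [set(c.key for c in calls) for calls in replicate_call_sets]
    concordant = set.intersection(*key_sets)
    discordant = set.union(*key_sets) - concordant
    return concordant, discordant


def _mean_vafs(
    replicate_call_sets: Sequence[Sequence[VariantCall]],
) -> dict[VariantKey, float]:
    """Mean VAF (percent) of every key across the replicates containing it."""
    acc: dict[VariantKey, list[float]] = {}
    for calls in replicate_call_sets:
        for c in calls:
            acc.setdefault(c.key, []).append(c.vaf_pct)
    return {k: float(np.mean(v)) for k, v in acc.items()}


def _in_hotspot(key: VariantKey, amplicons: dict[str, AmpliconDef]) -> bool:
    amp = amplicons.get(key.amplicon_id)
    if amp is None:
        return False
    a, b = key.ref_span()
    return any(a < e and b > s for s, e in amp.hotspot_spans)


def bin_and_score(
    replicate_call_sets: Sequence[Sequence[VariantCall]],
    bins: VafBins | None = None,
    hotspot_only: bool = False,
    panel: Sequence[AmpliconDef] | None = None,
) -> CalibrationResult:
    """Bin concordant/discordant variants by mean VAF across replicates.

    Variants below the calibration floor (0.01%) are excluded, mirroring the
    lowest reportable frequency of the calling stage.  With ``hotspot_only``
    the variant universe is restricted to the panel's hotspot windows.
    """
    bins = bins or VafBins()
    conc, disc = concordant_variants(replicate_call_sets)
    vafs = _mean_vafs(replicate_call_sets)
    if hotspot_only:
        if panel is None:
            raise CalibrationError("hotspot_only requires the panel")
        amps = {a.amplicon_id: a for a in panel}
        conc = {k for k in conc if _in_hotspot(k, amps)}
        disc = {k for k in disc if _in_hotspot(k, amps)}
    n_conc = [0] * bins.n
    n_disc = [0] * bins.n
    for keyset, tally in ((conc, n_conc), (disc, n_disc)):
        for key in keyset:
            v = vafs[key]
            if v < CALIBRATION_FLOOR_PCT:
                continue
            idx = bins.assign(v)
            if idx is not None:
                tally[idx] += 1
    return CalibrationResult(bins=bins, n_concordant=n_conc, n_discordant=n_disc,
                             hotspot_only=hotspot_only)


def select_threshold(
    result: CalibrationResult, max_discordant_fraction: float = 0.05
) -> float:
    """Lower edge (percent) of the lowest bin such that it and every higher
    bin have a discordant fraction at or below ``max_discordant_fraction``."""
    fractions = result.discordant_fraction
    chosen = None
    for i in range(result.bins.n - 1, -1, -1):
        if fractions[i] <= max_discordant_fraction:
            chosen = i
        else:
            break
    if chosen is None:
        raise CalibrationError(
            "no VAF stratum is clean at the requested tolerance; "
            "deeper replication is needed to calibrate a reporting threshold"
        )
    threshold = result.bins.edges_pct[chosen]
    result.selected_threshold_pct = threshold
    return threshold


def calibrate(
    replicate_call_sets: Sequence[Sequence[VariantCall]],
    bins: VafBins | None = None,
    max_discordant_fraction: float = 0.05,
    hotspot_only: bool = False,
    panel: Sequence[AmpliconDef] | None = None,
) -> CalibrationResult:
    """End-to-end triplicate calibration: bin, score and select the threshold."""
    result = bin_and_score(replicate_call_sets, bins, hotspot_only, panel)
    select_threshold(result, max_discordant_fraction)
    return result
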