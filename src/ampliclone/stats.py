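"""Exact association tests between RAS mutation status and clinical covariates.

Both the 2x2 Fisher test and its Freeman-Halton r x c generalisation use the
*probability method*: with all margins fixed, the two-sided p-value is the
sum of the (generalised) hypergeometric probabilities of every table whose
probability does not exceed that of the observed table.  Probabilities are
computed with exact rational arithmetic, so ties are handled exactly and the
r x c test restricted to a 2x2 table coincides with the 2x2 test to machine
precision.  Tables too large to enumerate can be tested by Monte-Carlo
permutation with a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import factorial
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import StatsError

_MAX_ENUM_N = 100
_MAX_ENUM_TABLES = 2_000_000


@dataclass(frozen=True)
class CohortRecord:
    """Per-patient RAS status and clinical covariates (None = not known)."""

    patient_id: str
    ras_status: str  # "pos" | "neg"
    sex: str | None = None  # "M" | "F"
    age_group: str | None = None  # "infant" (<= 1 year) | "child"
    wbc_group: str | None = None  # "lt100" | "100to300" | "ge300"
    pdn_response: str | None = None  # "PPR" | "PGR"

    def __post_init__(self) -> None:
        if self.ras_status not in ("pos", "neg"):
            raise StatsError("ras_status must be 'pos' or 'neg'")


def _clean(table) -> np.ndarray:
    """Validate counts and drop all-zero rows/columns."""
    t = np.asarray(table)
    if t.ndim != 2:
        raise StatsError("contingency table must be 2-dimensional")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.rint(t)):
            raise StatsError("contingency table must hold integers")
        t = np.rint(t).astype(int)
    if (t < 0).any():
        raise StatsError("contingency table must be non-negative")
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    return t


def _enumerate_pvalue(t: np.ndarray) -> float:
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = int(t.sum())
    if n > _MAX_ENUM_N:
        raise StatsError(
            f"table total {n} too large for exact enumeration; "
            "use fisher_exact_rxc_mc for a Monte-Carlo p-value"
        )
    # rough bound on the enumeration lattice size
    bound = 1
    for r in rows[:-1]:
        for c in cols[:-1]:
            bound *= min(int(r), int(c)) + 1
            if bound > _MAX_ENUM_TABLES:
                raise StatsError(
                    "enumeration lattice too large; use fisher_exact_rxc_mc"
                )

    const = Fraction(int(np.prod([factorial(int(r)) for r in rows], dtype=object))
                     * int(np.prod([factorial(int(c)) for c in cols], dtype=object)),
                     factorial(n))

    def prob(cells: list[int]) -> Fraction:
        denom = 1
        for x in cells:
            denom *= factorial(x)
        return const / denom

    p_obs = prob([int(x) for x in t.ravel()])
    r, c = t.shape
    total = Fraction(0)

    def rec(row: int, col: int, row_left: int, col_left: list[int], cells: list[int]):
        nonlocal total
        if row == r - 1:
            # last row forced by column margins
            forced = cells + col_left
            p = prob(forced)
            if p <= p_obs:
                total += p
            return
        if col == c - 1:
            if row_left > col_left[col]:
                return
            cells.append(row_left)
            col_left[col] -= row_left
            rec(row + 1, 0, int(rows[row + 1]), col_left, cells)
            col_left[col] += row_left
            cells.pop()
            return
        hi = min(row_left, col_left[col])
        for x in range(hi + 1):
            cells.append(x)
            col_left[col] -= x
            rec(row, col + 1, row_left - x, col_left, cells)
            col_left[col] += x
            cells.pop()

    rec(0, 0, int(rows[0]), [int(x) for x in cols], [])
    return float(total)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table (probability method,
    no continuity correction).  Degenerate margins give p = 1."""
    t = _clean(table)
    if t.shape != (2, 2):
        return 1.0
    return _enumerate_pvalue(t)


def fisher_exact_rxc(table) -> float:
    """Two-sided Freeman-Halton exact p-value for an r x c table by full
    enumeration of the margin-constrained lattice.  Degenerate margins give
    p = 1; on a 2x2 input this equals :func:`fisher_exact_2x2`."""
    t = _clean(table)
    if t.shape[0] < 2 or t.shape[1] < 2:
        return 1.0
    return _enumerate_pvalue(t)


def fisher_exact_rxc_mc(
    table, n_draws: int = 100_000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo estimate of the Freeman-Halton p-value with standard error.

    Permutes column labels against row labels under fixed margins and counts
    tables at most as probable as the observed one.
    """
    t = _clean(table)
    if t.shape[0] < 2 or t.shape[1] < 2:
        return 1.0, 0.0
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)

    def logprob(m: np.ndarray) -> float:
        return float(
            gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
            - gammaln(t.sum() + 1) - gammaln(m + 1).sum()
        )

    lp_obs = logprob(t)
    labels = np.repeat(np.arange(len(cols)), cols)
    rng = np.random.default_rng(seed)
    row_idx = np.repeat(np.arange(len(rows)), rows)
    hits = 0
    for _ in range(n_draws):
        perm = rng.permutation(labels)
        m = np.zeros_like(t)
        np.add.at(m, (row_idx, perm), 1)
        if logprob(m) <= lp_obs + 1e-9:
            hits += 1
    p = hits / n_draws
    se = float(np.sqrt(p * (1.0 - p) / n_draws))
    return p, se


# ---------------------------------------------------------------------------
# Patient-characteristics association report
# ---------------------------------------------------------------------------

_COMPARISONS = {
    # covariate: (attribute, row order, dichotomisation map or None)
    "sex": ("sex", ["M", "F"], None),
    "age": ("age_group", ["infant", "child"], None),
    "wbc": ("wbc_group", ["lt300", "ge300"], {"lt100": "lt300", "100to300": "lt300", "ge300": "ge300"}),
    "pdn": ("pdn_response", ["PPR", "PGR"], None),
}


def build_table1(records: Sequence[CohortRecord]) -> dict[str, dict]:
    """Cross-tabulate RAS status against sex, age group (infants vs older
    children), WBC count (dichotomised below/at-or-above 300e9/L) and
    prednisone response, with an exact test per comparison.

    Patients with an unknown value are excluded from that comparison only.
    """
    if not records:
        raise StatsError("empty cohort")
    out: dict[str, dict] = {}
    for name, (attr, row_order, remap) in _COMPARISONS.items():
        counts = pd.DataFrame(0, index=row_order, columns=["pos", "neg"])
        for rec in records:
            v = getattr(rec, attr)
            if v is None:
                continue
            if remap is not None:
                v = remap.get(v)
            if v not in row_order:
                raise StatsError(f"unknown {attr} value {v!r}")
            counts.loc[v, rec.ras_status] += 1
        out[name] = {
            "table": counts,
            "p": fisher_exact_2x2(counts.to_numpy()),
            "n": int(counts.to_numpy().sum()),
        }
    return out


def demo_cohort() -> list[CohortRecord]:
    """A 34-patient demonstration cohort of MLL-rearranged infant/paediatric
    ALL with the marginal covariate distributions of a real diagnostic
    series: 21 RAS-mutated and 13 wild-type patients; per-covariate margins
    (sex, infant/child, WBC stratum, prednisone response, with two unknown
    PDN and one unknown WBC entries) match the published series this package
    is modelled on.  Covariates are assigned independently within each RAS
    group, which leaves every marginal 2xk comparison unchanged.
    """

    def expand(ras: str, n: int, sex, age, wbc, pdn) -> list[CohortRecord]:
        def seq(pairs):
            vals = []
            for value, k in pairs:
                vals.extend([value] * k)
            assert len(vals) == n
            return vals

        return [
            CohortRecord(
                patient_id=f"{ras}{i + 1:02d}",
                ras_status=ras,
                sex=s, age_group=a, wbc_group=w, pdn_response=p,
            )
            for i, (s, a, w, p) in enumerate(zip(seq(sex), seq(age), seq(wbc), seq(pdn)))
        ]

    pos = expand(
        "pos", 21,
        sex=[("M", 10), ("F", 11)],
        age=[("infant", 17), ("child", 4)],
        wbc=[("lt100", 2), ("100to300", 5), ("ge300", 13), (None, 1)],
        pdn=[("PPR", 7), ("PGR", 12), (None, 2)],
    )
    neg = expand(
        "neg", 13,
        sex=[("M", 5), ("F", 8)],
        age=[("infant", 5), ("child", 8)],
        wbc=[("lt100", 3), ("100to300", 4), ("ge300", 6)],
        pdn=[("PPR", 2), ("PGR", 11)],
    )
    return pos + neg
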