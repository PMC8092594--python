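"""Gene-set overlap testing with a two-tailed Fisher's exact test.

Two target-gene sets drawn from a common gene universe are compared with
the exact hypergeometric test on the 2x2 membership table.  The two-tailed
p-value follows the probability-mass rule: the total probability of all
tables with the observed margins that are at most as probable as the
observed one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = ["OverlapTable", "OverlapResult", "contingency", "fisher_exact_two_tailed"]


@dataclass(frozen=True)
class OverlapTable:
    """2x2 membership counts of two gene sets over a universe."""

    n_both: int
    n_a_only: int
    n_b_only: int
    n_neither: int

    def __post_init__(self) -> None:
        if min(self.n_both, self.n_a_only, self.n_b_only, self.n_neither) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def universe_size(self) -> int:
        return self.n_both + self.n_a_only + self.n_b_only + self.n_neither

    @property
    def n_a(self) -> int:
        return self.n_both + self.n_a_only

    @property
    def n_b(self) -> int:
        return self.n_both + self.n_b_only


@dataclass(frozen=True)
class OverlapResult:
    table: OverlapTable
    odds_ratio: float
    p_two_tailed: float
    fold_enrichment: float


def contingency(
    set_a: set[str],
    set_b: set[str],
    universe: set[str],
    strict: bool = True,
) -> OverlapTable:
    """Membership table of two gene sets over a universe.

    With ``strict`` (default) a set member missing from the universe is an
    error; otherwise sets are silently intersected with the universe.
    """
    if strict:
        stray = (set_a | set_b) - universe
        if stray:
            raise ValueError(
                f"{len(stray)} gene(s) outside the universe, e.g. "
                f"{sorted(stray)[:5]}"
            )
    else:
        set_a = set_a & universe
        set_b = set_b & universe
    n_both = len(set_a & set_b)
    return OverlapTable(
        n_both=n_both,
        n_a_only=len(set_a) - n_both,
        n_b_only=len(set_b) - n_both,
        n_neither=len(universe) - len(set_a | set_b),
    )


def fisher_exact_two_tailed(table: OverlapTable) -> OverlapResult:
    """Two-tailed Fisher's exact test on an overlap table.

    The odds ratio is the sample (n_both x n_neither)/(n_a_only x n_b_only),
    infinite when the denominator vanishes with a non-zero numerator; fold
    enrichment compares the observed overlap with its hypergeometric
    expectation n_a x n_b / N.  Degenerate margins give p = 1.
    """
    _, p = stats.fisher_exact(
        [[table.n_both, table.n_a_only], [table.n_b_only, table.n_neither]],
        alternative="two-sided",
    )
    num = table.n_both * table.n_neither
    den = table.n_a_only * table.n_b_only
    if den > 0:
        odds = num / den
    else:
        odds = math.inf if num > 0 else math.nan
    expected = (
        table.n_a * table.n_b / table.universe_size if table.universe_size else 0.0
    )
    fold = table.n_both / expected if expected > 0 else math.nan
    return OverlapResult(
        table=table,
        odds_ratio=odds,
        p_two_tailed=float(min(p, 1.0)),
        fold_enrichment=fold,
    )
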