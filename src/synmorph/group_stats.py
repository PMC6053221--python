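"""Group comparisons: Fisher's exact contingency tests and Kruskal-Wallis/Dunn.

Near-membrane vesicle counts pooled per condition are compared between two
stimulation conditions with a two-sided Fisher's exact test on the 2x2
table (within 50 nm vs beyond). The two-sided p-value follows the
"sum of small p-values" convention used by mainstream scientific software:
the probabilities of all tables with the observed margins that are no more
likely than the observed one are summed, with a 1e-7 relative slack
absorbing floating-point ties. Probabilities come from the hypergeometric
log-pmf via log-gamma, so tables with tens of thousands of vesicles are
handled at full double precision.

Per-terminal metrics (vesicle counts, perimeter and active-zone lengths,
coverage, apposition gaps) are compared across the three conditions with a
tie-corrected Kruskal-Wallis test followed by Dunn's pairwise z tests with
Bonferroni adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2, norm, rankdata

from .pools import NearMembraneCount


@dataclass
class ContingencyTable2x2:
    """Counts with rows = conditions and columns = (within 50 nm, beyond)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("counts must be non-negative integers")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class FisherResult:
    p_two_sided: float
    odds_ratio: float
    degenerate: bool = False  # a zero margin: association untestable, p = 1


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    z: float
    p_unadjusted: float
    p_adjusted: float


@dataclass
class GroupComparison:
    metric: str
    groups: list[str]
    n_per_group: list[int]
    H: float
    p_value: float
    pairwise: list[PairwiseComparison] = field(default_factory=list)


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_2x2(table: ContingencyTable2x2) -> FisherResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed the observed table's
    (to within a 1e-7 relative slack). A zero margin makes the table
    untestable: p = 1 by convention, flagged via ``degenerate``.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = table.total

    def _odds() -> float:
        num, den = a * d, b * c
        if den == 0:
            return float("nan") if num == 0 else float("inf")
        return num / den

    if min(r1, r2, c1, c2) == 0:
        return FisherResult(p_two_sided=1.0, odds_ratio=_odds(), degenerate=True)

    lo, hi = max(0, c1 - r2), min(c1, r1)
    support = np.arange(lo, hi + 1)
    logp = (
        _log_binom(r1, support)
        + _log_binom(r2, c1 - support)
        - _log_binom(n, c1)
    )
    log_obs = logp[a - lo]
    keep = logp <= log_obs + np.log1p(1e-7)
    p = float(np.exp(logp[keep]).sum())
    return FisherResult(p_two_sided=min(p, 1.0), odds_ratio=_odds())


def build_condition_contingency(
    counts: Sequence[NearMembraneCount],
    pair: tuple[str, str],
    compartment: str,
) -> ContingencyTable2x2:
    """Assemble the (within, beyond) x condition-pair table from pooled counts."""
    by_condition = {
        c.condition: c for c in counts if c.compartment == compartment
    }
    rows = []
    for cond in pair:
        if cond not in by_condition:
            raise ValueError(f"no {compartment} counts for condition {cond!r}")
        c = by_condition[cond]
        if c.n_total == 0:
            raise ValueError(f"condition {cond!r} has zero total vesicles")
        rows.append((c.n_within, c.n_total - c.n_within))
    return ContingencyTable2x2(rows[0][0], rows[0][1], rows[1][0], rows[1][1])


def kruskal_wallis_dunn(
    groups: Mapping[str, Sequence[float]],
    n_comparisons: int | None = None,
    metric: str = "",
    adjust: bool = True,
) -> GroupComparison:
    """Tie-corrected Kruskal-Wallis H plus Dunn's pairwise post hoc tests.

    H is computed on midranks with the standard tie correction; its p-value
    uses the chi-square approximation with k-1 degrees of freedom. Dunn's z
    compares rank means with tie-corrected variance; each two-sided p is
    multiplied by the number of pairwise comparisons (Bonferroni-style
    Dunn, capped at 1) unless ``adjust`` is false.
    """
    names = list(groups)
    samples = [np.asarray(groups[g], dtype=float) for g in names]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    sizes = [len(s) for s in samples]
    if min(sizes) < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate(samples)
    N = len(pooled)
    ranks = rankdata(pooled)
    bounds = np.cumsum([0] + sizes)
    rank_means = np.array(
        [ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(sizes))]
    )

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(tie_counts**3 - tie_counts))
    tie_correction = 1.0 - tie_sum / (N**3 - N)
    m = n_comparisons if n_comparisons is not None else len(names) * (len(names) - 1) // 2

    if tie_correction == 0.0:  # every pooled value identical
        comp = GroupComparison(metric, names, sizes, H=0.0, p_value=1.0)
        comp.pairwise = [
            PairwiseComparison(names[i], names[j], 0.0, 1.0, 1.0)
            for i in range(len(names))
            for j in range(i + 1, len(names))
        ]
        return comp

    H = (
        12.0 / (N * (N + 1)) * np.sum(np.array(sizes) * rank_means**2)
        - 3.0 * (N + 1)
    ) / tie_correction
    H = float(max(H, 0.0))
    p_value = float(chi2.sf(H, df=len(names) - 1))

    sigma2 = (N * (N + 1)) / 12.0 - tie_sum / (12.0 * (N - 1))
    pairwise = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            se = np.sqrt(sigma2 * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = float((rank_means[i] - rank_means[j]) / se)
            p_un = float(2.0 * norm.sf(abs(z)))
            p_adj = min(1.0, p_un * m) if adjust else p_un
            pairwise.append(PairwiseComparison(names[i], names[j], z, p_un, p_adj))
    return GroupComparison(metric, names, sizes, H=H, p_value=p_value, pairwise=pairwise)
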