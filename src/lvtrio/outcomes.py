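"""Outcome classification and small statistical utilities.

Maps simulation endpoints to coexistence/exclusion categories via an
extinction threshold, aggregates replicate experiments by majority rule,
applies assay detection limits, and wraps the paired t-test (with
Bonferroni correction) and the 2x2 chi-square test.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dynamics import ROLES, CommunityState, Trajectory

#: Classification threshold (cells/mL): populations at or below this after
#: a 24-h batch are deemed extinct.  Rationale: the ~1000x daily dilution
#: combined with strong competition drives such populations to zero within
#: one or two further cycles.
EXTINCTION_THRESHOLD = 1e4

CATEGORIES = (
    "coexist",
    "competitor_extinct",
    "ecoli_extinct",
    "yeast_extinct",
    "multiple_extinct",
)

_SINGLE = {
    frozenset(): "coexist",
    frozenset({"B"}): "competitor_extinct",
    frozenset({"E"}): "ecoli_extinct",
    frozenset({"Y"}): "yeast_extinct",
}


@dataclass(frozen=True)
class OutcomeLabel:
    """Coexistence/exclusion category of a community endpoint."""

    category: str
    extinct_set: frozenset[str]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        expected = _SINGLE.get(self.extinct_set, "multiple_extinct")
        if self.category != expected:
            raise ValueError(
                f"category {self.category!r} inconsistent with extinct set "
                f"{set(self.extinct_set)}"
            )


@dataclass(frozen=True)
class ReplicateOutcomes:
    """Per-replicate coexist/extirpated labels for one condition."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) < 1:
            raise ValueError("need at least one replicate")
        bad = set(self.labels) - {"coexist", "extirpated"}
        if bad:
            raise ValueError(f"unknown replicate labels: {bad}")

    @property
    def n_replicates(self) -> int:
        return len(self.labels)


def classify_simulation(
    end_state: CommunityState, extinction_threshold: float = EXTINCTION_THRESHOLD
) -> OutcomeLabel:
    """Label a simulation endpoint.

    Every species whose density is at or below ``extinction_threshold``
    (default 1e4 cells/mL) is extinct; the category is coexist /
    competitor_extinct / ecoli_extinct / yeast_extinct for zero or one
    extinction, multiple_extinct otherwise.
    """
    pops = dict(zip(ROLES, end_state.as_array()))
    extinct = frozenset(s for s, n in pops.items() if n <= extinction_threshold)
    return OutcomeLabel(
        category=_SINGLE.get(extinct, "multiple_extinct"), extinct_set=extinct
    )


def classify_trajectory(
    traj: Trajectory,
    extinction_threshold: float = EXTINCTION_THRESHOLD,
    at_any_time: bool = False,
) -> OutcomeLabel:
    """Label a trajectory: by default at its endpoint, optionally if any
    time point dips to or below the threshold."""
    if not at_any_time:
        return classify_simulation(traj.end_state, extinction_threshold)
    minima = traj.populations.min(axis=0)
    extinct = frozenset(
        s for s, n in zip(ROLES, minima) if n <= extinction_threshold
    )
    return OutcomeLabel(
        category=_SINGLE.get(extinct, "multiple_extinct"), extinct_set=extinct
    )


def classify_replicates(outcomes: ReplicateOutcomes) -> str:
    """Strict-majority label over replicates; ties raise ValueError."""
    counts = Counter(outcomes.labels)
    top = counts.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        raise ValueError("indeterminate: replicate outcomes are tied")
    return top[0][0]


def detection_limit_check(subpop: float, total: float, method: str) -> str:
    """Whether a subpopulation is observable by the given assay.

    selective_plating resolves down to ~10 cells absolute;
    morphology_screen resolves down to a 0.1% frequency (the conservative
    end of the 0.1-1% screening range).  Returns "detectable" or
    "below_limit"; boundaries count as detectable.
    """
    if total <= 0:
        raise ValueError("total population must be positive")
    if not (0 <= subpop <= total):
        raise ValueError("need 0 <= subpop <= total")
    if method == "selective_plating":
        return "below_limit" if subpop < 10 else "detectable"
    if method == "morphology_screen":
        return "below_limit" if subpop / total < 1e-3 else "detectable"
    raise ValueError(f"unknown method {method!r}")


def extinction_projection(
    n: float = 1e4,
    daily_dilution: float = 1000.0,
    suppressed_regrowth: float = 10.0,
) -> float:
    """Population after one daily cycle under strong competition.

    The extinction-threshold rationale: cultures are diluted ~1000x daily,
    and an interaction coefficient of 1 or more holds regrowth to roughly
    tenfold, so a population of 10,000 falls to 100 after one cycle and to
    effectively zero after the next.
    """
    if n < 0 or daily_dilution <= 0 or suppressed_regrowth <= 0:
        raise ValueError("n must be >= 0; factors must be positive")
    return n / daily_dilution * suppressed_regrowth


# ---------------------------------------------------------------------------
# Statistical utilities
# ---------------------------------------------------------------------------

def chi_square_2x2(
    table: np.ndarray | list[list[int]], correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 contingency table (df = 1).

    No continuity correction by default; set ``correction=True`` for
    Yates.  Raises on negative counts or a zero marginal.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("all row and column marginals must be positive")
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


def paired_t_and_bonferroni(
    x: np.ndarray | list[float],
    y: np.ndarray | list[float],
    m: int = 1,
) -> tuple[float, int, float, float]:
    """Paired t-test with Bonferroni adjustment over ``m`` comparisons.

    Returns ``(t, df, p_raw, p_adjusted)`` with df = n - 1 and
    p_adjusted = min(1, m * p_raw).  Raises on mismatched lengths, n < 2,
    or zero variance of the paired differences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    if m < 1:
        raise ValueError("m must be >= 1")
    d = x - y
    if float(np.std(d, ddof=1)) == 0.0:
        if np.allclose(d, 0.0):
            # identical vectors: t is exactly 0 by convention
            return 0.0, n - 1, 1.0, 1.0
        raise ValueError("paired differences have zero variance")
    res = stats.ttest_rel(x, y)
    t = float(res.statistic)
    p_raw = float(res.pvalue)
    return t, n - 1, p_raw, min(1.0, m * p_raw)
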