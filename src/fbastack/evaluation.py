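"""Paired-comparison statistics: forced-choice counts, exact sign test, summaries.

Each comparison is a forced choice between a focus-stacked image (arm A) and
its single-frame baseline (arm B), so ties are structurally excluded.  Win
counts are tested against a fair coin with the exact two-sided sign test
(binomial tail summation, no normal approximation).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import binom

from .focus_measures import compare_pair, laplacian_energy
from .image_io import GrayImage

__all__ = [
    "PairedComparison",
    "SignTestResult",
    "EvaluationSummary",
    "sign_test",
    "win_percentage",
    "evaluate_objective",
]


@dataclass
class PairedComparison:
    """Forced-choice win counts for merged (A) versus baseline (B)."""

    wins_a: int
    wins_b: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.wins_a < 0 or self.wins_b < 0:
            raise ValueError("win counts must be nonnegative")
        if self.wins_a + self.wins_b < 1:
            raise ValueError("at least one comparison is required")

    @property
    def n(self) -> int:
        return self.wins_a + self.wins_b


@dataclass
class SignTestResult:
    """Exact two-sided sign-test outcome on n Bernoulli(1/2) trials."""

    p_two_sided: float
    n: int
    k: int


def sign_test(wins_a: int, wins_b: int) -> SignTestResult:
    """Exact two-sided sign test: ``p = min(1, 2 P[X >= k])``, X ~ Bin(n, 1/2).

    ``k`` is the larger of the two win counts; the tail is an exact binomial
    sum, never a normal approximation.
    """
    if wins_a < 0 or wins_b < 0:
        raise ValueError("win counts must be nonnegative")
    n = wins_a + wins_b
    if n < 1:
        raise ValueError("at least one comparison is required")
    k = max(wins_a, wins_b)
    tail = float(binom.sf(k - 1, n, 0.5))  # P[X >= k], exact summation
    return SignTestResult(p_two_sided=min(1.0, 2.0 * tail), n=n, k=k)


def win_percentage(wins_a: int, n: int) -> float:
    """``100 * wins_a / n`` rounded to one decimal place."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= wins_a <= n:
        raise ValueError("wins_a must lie in [0, n]")
    return round(100.0 * wins_a / n, 1)


@dataclass
class EvaluationSummary:
    """Objective-arm summary row: counts, percentage, p-value, energy stats."""

    comparison: PairedComparison
    test: SignTestResult
    percentage_a: float
    energy_mean_a: float
    energy_sd_a: float
    energy_mean_b: float
    energy_sd_b: float

    def as_dict(self) -> dict:
        return {
            "label": self.comparison.label,
            "wins_a": self.comparison.wins_a,
            "wins_b": self.comparison.wins_b,
            "n": self.comparison.n,
            "percentage_a": self.percentage_a,
            "p_two_sided": self.test.p_two_sided,
            "energy_mean_a": self.energy_mean_a,
            "energy_sd_a": self.energy_sd_a,
            "energy_mean_b": self.energy_mean_b,
            "energy_sd_b": self.energy_sd_b,
        }


def _mean_sd(values: list[float]) -> tuple[float, float]:
    n = len(values)
    mean = sum(values) / n
    if n < 2:
        return mean, 0.0
    var = sum((v - mean) ** 2 for v in values) / (n - 1)  # sample SD
    return mean, var**0.5


def evaluate_objective(
    pairs: list[tuple[GrayImage, GrayImage]],
    label: str = "energy_of_laplacian",
) -> EvaluationSummary:
    """Forced-choice Laplacian-energy comparison over (merged, baseline) pairs.

    Applies :func:`~fbastack.focus_measures.compare_pair` to every pair,
    aggregates the win counts, runs the exact sign test, and reports each
    arm's energy mean and sample SD (n-1 denominator).
    """
    if not pairs:
        raise ValueError("pairs must be nonempty")
    wins_a = 0
    energies_a: list[float] = []
    energies_b: list[float] = []
    for merged, baseline in pairs:
        if compare_pair(merged, baseline) == "A":
            wins_a += 1
        energies_a.append(laplacian_energy(merged))
        energies_b.append(laplacian_energy(baseline))
    n = len(pairs)
    comparison = PairedComparison(wins_a=wins_a, wins_b=n - wins_a, label=label)
    mean_a, sd_a = _mean_sd(energies_a)
    mean_b, sd_b = _mean_sd(energies_b)
    return EvaluationSummary(
        comparison=comparison,
        test=sign_test(comparison.wins_a, comparison.wins_b),
        percentage_a=win_percentage(wins_a, n),
        energy_mean_a=mean_a,
        energy_sd_a=sd_a,
        energy_mean_b=mean_b,
        energy_sd_b=sd_b,
    )
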