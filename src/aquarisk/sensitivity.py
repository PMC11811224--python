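"""Contribution-to-variance sensitivity analysis over Monte Carlo trials.

Each varied input's influence on the simulated hazard quotient is scored by
its Spearman rank correlation with the output across trials; the contribution
percentage is the squared correlation normalised over all inputs,

    contribution_i = 100 * rho_i**2 / sum_j rho_j**2 .

Rank-based scoring makes the result invariant to any monotone rescaling of an
input.  Body weight enters the intake equation inversely, so its signed
correlation is expected to be negative; the sign is reported alongside the
(unsigned) contribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, ValidationError
from .montecarlo import ScenarioSpec, simulate_hq

__all__ = [
    "SensitivityReport",
    "rank_correlation",
    "contribution_to_variance",
    "sensitivity_report",
    "largest_remainder_round",
]


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman coefficient: Pearson correlation of mid-ranks, average-tied.

    A zero-variance vector on either side yields 0.0 (the degenerate-input
    convention; :func:`contribution_to_variance` additionally flags it).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValidationError("rank_correlation requires two equal-length 1-D vectors")
    if xa.size < 3:
        raise ValidationError(f"rank_correlation requires length >= 3, got {xa.size}")
    if np.ptp(xa) == 0.0 or np.ptp(ya) == 0.0:
        return 0.0
    rho = stats.spearmanr(xa, ya).statistic
    return float(rho)


def largest_remainder_round(
    values: Mapping[str, float], ndigits: int = 1, total: float = 100.0
) -> dict[str, float]:
    """Round percentages so they still sum exactly to ``total``.

    Standard largest-remainder apportionment at a quantum of 10**-ndigits:
    floor everything, then hand out the leftover quanta to the largest
    fractional remainders (ties broken by input order).
    """
    quantum = 10.0**-ndigits
    scaled = {k: v / quantum for k, v in values.items()}
    floored = {k: np.floor(s) for k, s in scaled.items()}
    leftover = int(round(total / quantum - sum(floored.values())))
    remainders = sorted(scaled, key=lambda k: scaled[k] - floored[k], reverse=True)
    for k in remainders[:leftover]:
        floored[k] += 1
    return {k: round(float(floored[k]) * quantum, ndigits) for k in values}


@dataclass(frozen=True)
class SensitivityReport:
    """Ranked contribution-to-variance result for one simulated output.

    ``contributions`` are unrounded percentages summing to 100 (to floating
    precision); ``correlations`` carries the signed Spearman coefficients;
    ``ranking`` lists input names by descending contribution; ``degenerate``
    lists zero-variance inputs (contribution fixed at 0).
    """

    contributions: Mapping[str, float]
    correlations: Mapping[str, float]
    ranking: tuple[str, ...]
    degenerate: tuple[str, ...] = ()
    group: str | None = None
    contaminant: str | None = None

    def rounded(self, ndigits: int = 1) -> dict[str, float]:
        """Display percentages reconciled to sum exactly to 100."""
        return largest_remainder_round(self.contributions, ndigits=ndigits)

    @property
    def top(self) -> str:
        return self.ranking[0]

    def pie_data(self, ndigits: int = 1) -> list[tuple[str, float]]:
        """(label, percentage) pairs in ranked order, chart-ready."""
        rounded = self.rounded(ndigits)
        return [(name, rounded[name]) for name in self.ranking]


def contribution_to_variance(
    inputs: Mapping[str, Sequence[float]],
    output: Sequence[float],
    group: str | None = None,
    contaminant: str | None = None,
) -> SensitivityReport:
    """Score each input's contribution to the output's rank variance.

    All vectors must share the output's length; zero-variance inputs are
    flagged and contribute 0.  Raises :class:`DegenerateInputError` when no
    input varies (or none correlates at all, leaving nothing to apportion).
    """
    if not inputs:
        raise DegenerateInputError("contribution_to_variance requires at least one input")
    out = np.asarray(output, dtype=float)
    rhos: dict[str, float] = {}
    degenerate: list[str] = []
    for name, vec in inputs.items():
        arr = np.asarray(vec, dtype=float)
        if arr.shape != out.shape:
            raise ValidationError(
                f"input {name!r} has length {arr.size}, output has {out.size}"
            )
        if np.ptp(arr) == 0.0:
            degenerate.append(name)
            rhos[name] = 0.0
        else:
            rhos[name] = rank_correlation(arr, out)
    if len(degenerate) == len(inputs):
        raise DegenerateInputError("all sensitivity inputs have zero variance")
    denom = sum(r * r for r in rhos.values())
    if denom == 0.0:
        raise DegenerateInputError("no input shows any rank association with the output")
    contributions = {name: 100.0 * r * r / denom for name, r in rhos.items()}
    ranking = tuple(sorted(contributions, key=lambda k: (-contributions[k], list(inputs).index(k))))
    return SensitivityReport(
        contributions=contributions,
        correlations=rhos,
        ranking=ranking,
        degenerate=tuple(degenerate),
        group=group,
        contaminant=contaminant,
    )


def sensitivity_report(scenario: ScenarioSpec) -> SensitivityReport:
    """Run the scenario's HQ simulation and apportion its variance.

    Only inputs with a non-point distribution enter the analysis; an
    all-point scenario raises :class:`DegenerateInputError`.  Fixed seed in,
    identical report out.
    """
    varied = scenario.varied_inputs
    if not varied:
        raise DegenerateInputError(
            f"scenario {scenario.contaminant.name}/{scenario.group}: every input is a point "
            "distribution; nothing to analyse"
        )
    result = simulate_hq(scenario, capture_inputs=True)
    assert result.inputs is not None
    inputs = {name: result.inputs[name] for name in varied}
    return contribution_to_variance(
        inputs, result.trials, group=scenario.group, contaminant=scenario.contaminant.name
    )
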