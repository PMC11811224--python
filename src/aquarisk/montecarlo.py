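"""Monte Carlo uncertainty propagation for hazard quotients and indices.

Per trial, concentration C, ingestion rate IR and body weight BW are drawn
from their marginal distributions (EF, ED, AT and RfD stay fixed points) and
pushed through the intake chain, yielding the full HQ distribution instead of
a single point estimate.  For a hazard index, the IR and BW draws are shared
across contaminants within a trial — each trial represents one person — while
concentration draws are independent per contaminant.

Reproducibility contract: every scenario carries one root seed; the three
per-variable random streams are spawned deterministically from it, so an
identical scenario yields a bitwise-identical trial vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data_model import BrandPanel, ContaminantSpec, ExposureProfile
from .deterministic import _edi_expr
from .errors import (
    ConfigurationError,
    EmptyInputError,
    FittingError,
    SamplingError,
    ValidationError,
)

__all__ = [
    "DistributionSpec",
    "LognormalFit",
    "ScenarioSpec",
    "SimulationResult",
    "HiSimulation",
    "fit_lognormal",
    "sample",
    "simulate_hq",
    "simulate_hi",
    "percentile",
    "default_scenario",
    "histogram",
    "DEFAULT_FLOOR",
    "DEFAULT_IR_LOG_SD",
    "DEFAULT_BW_CV",
    "DEFAULT_TRIALS",
]

#: Detection floor substituted for near-zero concentrations before log fitting, mg/L.
DEFAULT_FLOOR = 0.005
#: Default log-scale SD of the ingestion-rate lognormal (median = profile IR).
DEFAULT_IR_LOG_SD = 0.25
#: Default coefficient of variation of the body-weight normal (mean = profile BW).
DEFAULT_BW_CV = 0.15
#: Default number of Monte Carlo trials.
DEFAULT_TRIALS = 10_000
#: Default summary percentiles (percent).
DEFAULT_PERCENTILES = (5.0, 50.0, 95.0)

# Rejection sampling gives up when, after at least this many proposals, the
# acceptance rate is below the threshold: the truncation region holds
# negligible probability mass.
_REJECTION_PROBE = 10_000
_MIN_ACCEPT_RATE = 1e-4


@dataclass(frozen=True)
class DistributionSpec:
    """A named marginal distribution with optional inclusive truncation bounds.

    ``kind`` is one of ``lognormal`` (p1 = log-mean, p2 = log-SD), ``normal``
    (p1 = mean, p2 = SD) or ``point`` (p1 = the value, p2 = 0).  Truncation is
    applied by redrawing out-of-bounds values; bounds are inclusive.
    """

    kind: str
    p1: float
    p2: float = 0.0
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("lognormal", "normal", "point"):
            raise ConfigurationError(f"unknown distribution kind {self.kind!r}")
        if self.p2 < 0 or not math.isfinite(self.p2):
            raise ConfigurationError(f"scale parameter p2 must be >= 0, got {self.p2!r}")
        if self.lower is not None and self.upper is not None and not (self.lower < self.upper):
            raise ConfigurationError(
                f"truncation interval must satisfy lower < upper, got [{self.lower}, {self.upper}]"
            )

    @classmethod
    def point(cls, value: float) -> "DistributionSpec":
        return cls(kind="point", p1=value, p2=0.0)

    @classmethod
    def normal(
        cls, mean: float, sd: float, lower: float | None = None, upper: float | None = None
    ) -> "DistributionSpec":
        return cls(kind="normal", p1=mean, p2=sd, lower=lower, upper=upper)

    @classmethod
    def lognormal(
        cls, log_mean: float, log_sd: float, lower: float | None = None, upper: float | None = None
    ) -> "DistributionSpec":
        return cls(kind="lognormal", p1=log_mean, p2=log_sd, lower=lower, upper=upper)

    @property
    def is_point(self) -> bool:
        return self.kind == "point" or self.p2 == 0.0

    def analytic_mean(self) -> float:
        """Closed-form mean, ignoring truncation (exact when untruncated)."""
        if self.kind == "point":
            return self.p1
        if self.kind == "normal":
            return self.p1
        return math.exp(self.p1 + self.p2**2 / 2.0)


@dataclass(frozen=True)
class LognormalFit:
    """Result of log-moment fitting: the spec plus detection-floor bookkeeping."""

    spec: DistributionSpec
    n_clamped: int
    floor: float

    @property
    def p1(self) -> float:
        return self.spec.p1

    @property
    def p2(self) -> float:
        return self.spec.p2


def fit_lognormal(values: Sequence[float], floor: float = DEFAULT_FLOOR) -> LognormalFit:
    """Fit a lognormal by log-moments: p1 = mean(ln x), p2 = sample SD(ln x).

    Values at or below ``floor`` (detection-limit semantics) are clamped to
    the floor before logging; the count of clamped values is reported so a
    caller can judge how much the floor shaped the fit.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise FittingError("fit_lognormal requires at least 2 values")
    if not (floor > 0):
        raise ConfigurationError(f"floor must be > 0, got {floor!r}")
    if np.any(~np.isfinite(arr)):
        raise FittingError("fit_lognormal requires finite values")
    clamped = int(np.sum(arr <= floor))
    logs = np.log(np.maximum(arr, floor))
    p1 = float(np.mean(logs))
    p2 = float(np.std(logs, ddof=1))
    return LognormalFit(
        spec=DistributionSpec.lognormal(p1, p2), n_clamped=clamped, floor=floor
    )


def _draw(spec: DistributionSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.kind == "point":
        return np.full(n, spec.p1, dtype=float)
    if spec.kind == "normal":
        return rng.normal(spec.p1, spec.p2, size=n)
    return rng.lognormal(spec.p1, spec.p2, size=n)


def sample(spec: DistributionSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` values, applying truncation by rejection (inclusive bounds).

    Raises :class:`SamplingError` when the acceptance rate over a probe of
    proposals falls below a negligible-mass threshold.
    """
    if n < 1:
        raise ValidationError(f"sample size must be >= 1, got {n}")
    draws = _draw(spec, n, rng)
    lo = -math.inf if spec.lower is None else spec.lower
    hi = math.inf if spec.upper is None else spec.upper
    if spec.lower is None and spec.upper is None:
        return draws
    if spec.kind == "point":
        if not (lo <= spec.p1 <= hi):
            raise SamplingError(
                f"point value {spec.p1} lies outside truncation bounds [{lo}, {hi}]"
            )
        return draws

    accepted_total = 0
    proposed_total = n
    out = np.empty(n, dtype=float)
    mask = (draws >= lo) & (draws <= hi)
    k = int(mask.sum())
    out[:k] = draws[mask]
    accepted_total = k
    while accepted_total < n:
        if proposed_total >= _REJECTION_PROBE and accepted_total / proposed_total < _MIN_ACCEPT_RATE:
            raise SamplingError(
                f"truncation interval [{lo}, {hi}] for {spec.kind} distribution has "
                f"negligible mass (acceptance {accepted_total}/{proposed_total})"
            )
        batch = max(n - accepted_total, 1000)
        draws = _draw(spec, batch, rng)
        proposed_total += batch
        good = draws[(draws >= lo) & (draws <= hi)]
        take = min(good.size, n - accepted_total)
        out[accepted_total : accepted_total + take] = good[:take]
        accepted_total += take
    return out


@dataclass(frozen=True)
class ScenarioSpec:
    """Everything needed to simulate one contaminant x group hazard quotient."""

    contaminant: ContaminantSpec
    group: str
    c_dist: DistributionSpec
    ir_dist: DistributionSpec
    bw_dist: DistributionSpec
    ef: float
    ed: float
    at: float
    n_trials: int = DEFAULT_TRIALS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValidationError(f"n_trials must be >= 1, got {self.n_trials}")
        for name in ("ef", "ed", "at"):
            if not (getattr(self, name) > 0):
                raise ValidationError(f"{name} must be strictly positive")

    @property
    def varied_inputs(self) -> tuple[str, ...]:
        """Names of inputs with a non-degenerate distribution, in (C, IR, BW) order."""
        out = []
        for name, dist in (("C", self.c_dist), ("IR", self.ir_dist), ("BW", self.bw_dist)):
            if not dist.is_point:
                out.append(name)
        return tuple(out)


@dataclass(frozen=True)
class SimulationResult:
    """Trial-level output with moment and percentile summaries.

    ``percentiles`` maps the percent level (e.g. 95.0) to the value at that
    level; ``sd`` uses the n-1 denominator.  ``inputs`` optionally carries the
    per-variable trial vectors (populated when a simulation is asked to
    capture them, e.g. for sensitivity analysis).
    """

    trials: np.ndarray
    mean: float
    sd: float
    percentiles: Mapping[float, float]
    inputs: Mapping[str, np.ndarray] | None = None

    @property
    def n_trials(self) -> int:
        return int(self.trials.size)

    def summary(self, ndigits: int | None = None) -> dict[str, object]:
        def _r(x: float) -> float:
            return x if ndigits is None else round(x, ndigits)

        return {
            "n_trials": self.n_trials,
            "mean": _r(self.mean),
            "sd": _r(self.sd),
            "min": _r(float(self.trials.min())),
            "max": _r(float(self.trials.max())),
            "percentiles": {f"p{level:g}": _r(v) for level, v in self.percentiles.items()},
        }


def percentile(result: "SimulationResult | np.ndarray", q: float) -> float:
    """Value at probability ``q`` in (0, 1), by linear interpolation between
    adjacent order statistics at rank 1 + (n-1) q."""
    if not (0.0 < q < 1.0):
        raise ValidationError(f"percentile probability must lie in (0, 1), got {q!r}")
    trials = result.trials if isinstance(result, SimulationResult) else np.asarray(result, dtype=float)
    if trials.size == 0:
        raise EmptyInputError("percentile requires a non-empty trial vector")
    return float(np.quantile(trials, q))  # numpy's default 'linear' method matches the rank rule


def _summarize(
    trials: np.ndarray,
    percentiles: Sequence[float],
    inputs: Mapping[str, np.ndarray] | None,
) -> SimulationResult:
    pct = {float(p): percentile(trials, p / 100.0) for p in percentiles}
    if np.all(trials == trials[0]):
        # Constant (degenerate) trial vector: report the constant exactly
        # rather than letting summation round-off leak into mean/sd.
        mean, sd = float(trials[0]), 0.0
    else:
        mean = float(np.mean(trials))
        sd = float(np.std(trials, ddof=1)) if trials.size > 1 else 0.0
    return SimulationResult(trials=trials, mean=mean, sd=sd, percentiles=pct, inputs=inputs)


def _hq_trials(
    scenario: ScenarioSpec,
    c: np.ndarray,
    ir: np.ndarray,
    bw: np.ndarray,
) -> np.ndarray:
    edi_t = _edi_expr(c, ir, scenario.ef, scenario.ed, bw, scenario.at)
    return edi_t / scenario.contaminant.rfd


def simulate_hq(
    scenario: ScenarioSpec,
    percentiles: Sequence[float] = DEFAULT_PERCENTILES,
    capture_inputs: bool = False,
) -> SimulationResult:
    """Simulate the hazard quotient distribution for one scenario.

    C, IR and BW are drawn independently from streams spawned off the
    scenario seed; per trial, HQ = C*IR*EF*ED / (BW*AT*RfD).
    """
    ss = np.random.SeedSequence(scenario.seed)
    c_rng, ir_rng, bw_rng = (np.random.default_rng(s) for s in ss.spawn(3))
    c = sample(scenario.c_dist, scenario.n_trials, c_rng)
    ir = sample(scenario.ir_dist, scenario.n_trials, ir_rng)
    bw = sample(scenario.bw_dist, scenario.n_trials, bw_rng)
    trials = _hq_trials(scenario, c, ir, bw)
    inputs = {"C": c, "IR": ir, "BW": bw} if capture_inputs else None
    return _summarize(trials, percentiles, inputs)


@dataclass(frozen=True)
class HiSimulation:
    """Hazard-index simulation output plus its per-contaminant components.

    ``hi.trials`` equals the elementwise sum of the per-contaminant HQ trial
    vectors by construction.
    """

    hi: SimulationResult
    per_contaminant: Mapping[str, SimulationResult]


def simulate_hi(
    scenarios: Sequence[ScenarioSpec],
    percentiles: Sequence[float] = DEFAULT_PERCENTILES,
    capture_inputs: bool = False,
) -> HiSimulation:
    """Simulate a hazard index across contaminants for one receptor group.

    Each trial is one person: the IR and BW draws are shared across
    contaminants while concentration draws are independent per contaminant.
    All scenarios must agree on group, trial count and seed.
    """
    if not scenarios:
        raise EmptyInputError("simulate_hi requires at least one scenario")
    first = scenarios[0]
    for s in scenarios[1:]:
        if s.group != first.group:
            raise ValidationError(
                f"scenarios must share a group: {first.group!r} != {s.group!r}"
            )
        if s.n_trials != first.n_trials or s.seed != first.seed:
            raise ValidationError("scenarios must share n_trials and seed")
    names = [s.contaminant.name for s in scenarios]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate contaminants in HI scenarios: {names}")

    ss = np.random.SeedSequence(first.seed)
    children = ss.spawn(2 + len(scenarios))
    ir_rng = np.random.default_rng(children[0])
    bw_rng = np.random.default_rng(children[1])
    # IR/BW marginals must describe the same receptor; take them from the
    # first scenario (validated implicitly by the shared-group contract).
    ir = sample(first.ir_dist, first.n_trials, ir_rng)
    bw = sample(first.bw_dist, first.n_trials, bw_rng)

    per: dict[str, SimulationResult] = {}
    hi_trials = np.zeros(first.n_trials, dtype=float)
    for scenario, child in zip(scenarios, children[2:]):
        c = sample(scenario.c_dist, scenario.n_trials, np.random.default_rng(child))
        trials = _hq_trials(scenario, c, ir, bw)
        inputs = {"C": c, "IR": ir, "BW": bw} if capture_inputs else None
        per[scenario.contaminant.name] = _summarize(trials, percentiles, inputs)
        hi_trials = hi_trials + trials
    return HiSimulation(hi=_summarize(hi_trials, percentiles, None), per_contaminant=per)


def default_scenario(
    panel: BrandPanel,
    profile: ExposureProfile,
    floor: float = DEFAULT_FLOOR,
    ir_log_sd: float = DEFAULT_IR_LOG_SD,
    bw_cv: float = DEFAULT_BW_CV,
    n_trials: int = DEFAULT_TRIALS,
    seed: int = 0,
) -> ScenarioSpec:
    """Build the package's default probabilistic scenario for a panel and group.

    Concentration: lognormal fitted to the panel's measured values by
    log-moments (detection floor applied).  Ingestion rate: lognormal with
    median equal to the profile IR and log-SD ``ir_log_sd``.  Body weight:
    normal with mean equal to the profile BW, SD ``bw_cv * BW``, truncated
    below at 20% of the mean to keep weights physical.  EF, ED and AT stay
    fixed at the profile values.
    """
    fit = fit_lognormal(panel.measured, floor=floor)
    return ScenarioSpec(
        contaminant=panel.contaminant,
        group=profile.group,
        c_dist=fit.spec,
        ir_dist=DistributionSpec.lognormal(math.log(profile.ir), ir_log_sd),
        bw_dist=DistributionSpec.normal(profile.bw, bw_cv * profile.bw, lower=0.2 * profile.bw),
        ef=profile.ef,
        ed=profile.ed,
        at=profile.at,
        n_trials=n_trials,
        seed=seed,
    )


def histogram(result: SimulationResult, bins: int = 50) -> dict[str, list[float]]:
    """Bin edges and counts for chart-ready output (no plotting here)."""
    counts, edges = np.histogram(result.trials, bins=bins)
    return {"bin_edges": [float(e) for e in edges], "counts": [int(c) for c in counts]}
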