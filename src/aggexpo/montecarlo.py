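"""Generic Monte-Carlo aggregate exposure engine (Tier-2 output structure).

Higher-tier consumer exposure models refine the deterministic SED skeleton
by drawing habits-and-practices inputs (amount applied, use frequency,
retention, body weight) from distributions and reporting per-pair sample
populations summarised as P05 / mean / P95.  This engine reproduces that
output structure for arbitrary distributional inputs; it makes no claim to
the proprietary habits-and-practices databases of the production tools.

Sampling conventions: one seed per run, a single generator stream, draws
ordered product-major then iteration, so sample vectors are
bit-reproducible for a given scenario and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .study_io import (
    IngredientParams,
    PredictionSet,
    ProductParams,
    TableValidationError,
    UseProfile,
)

__all__ = [
    "DistributionSpec",
    "StochasticScenario",
    "simulate_population",
    "summarize_samples",
]


@dataclass(frozen=True)
class DistributionSpec:
    """A non-negative input distribution.

    Families:
      point      — {"value": v}
      lognormal  — {"mean": m, "gsd": g}, arithmetic mean m and geometric SD g
      uniform    — {"low": a, "high": b}
      empirical  — {"values": [...]}, resampled with replacement

    Optional truncation ``bounds=(lo, hi)`` clips draws into [lo, hi].
    """

    family: str
    parameters: Mapping[str, object]
    bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        p = self.parameters
        if self.family == "point":
            if "value" not in p or float(p["value"]) < 0:
                raise TableValidationError("point family needs a non-negative 'value'")
        elif self.family == "lognormal":
            if float(p.get("mean", -1)) <= 0 or float(p.get("gsd", 0)) < 1:
                raise TableValidationError(
                    "lognormal family needs mean > 0 and gsd >= 1"
                )
        elif self.family == "uniform":
            low, high = float(p.get("low", -1)), float(p.get("high", -1))
            if not 0 <= low <= high:
                raise TableValidationError("uniform family needs 0 <= low <= high")
        elif self.family == "empirical":
            values = np.asarray(p.get("values", ()), dtype=float)
            if values.size == 0 or (values < 0).any():
                raise TableValidationError(
                    "empirical family needs non-empty, non-negative 'values'"
                )
        else:
            raise TableValidationError(f"unknown distribution family {self.family!r}")
        if self.bounds is not None:
            lo, hi = self.bounds
            if not 0 <= lo <= hi:
                raise TableValidationError("bounds must satisfy 0 <= lo <= hi")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        p = self.parameters
        if self.family == "point":
            out = np.full(n, float(p["value"]))
        elif self.family == "lognormal":
            # arithmetic mean m, geometric SD g:  mu = ln m - sigma^2/2
            sigma = np.log(float(p["gsd"]))
            mu = np.log(float(p["mean"])) - 0.5 * sigma**2
            out = rng.lognormal(mean=mu, sigma=sigma, size=n)
        elif self.family == "uniform":
            out = rng.uniform(float(p["low"]), float(p["high"]), size=n)
        else:  # empirical
            values = np.asarray(p["values"], dtype=float)
            out = rng.choice(values, size=n, replace=True)
        if self.bounds is not None:
            out = np.clip(out, *self.bounds)
        return out

    @classmethod
    def point(cls, value: float) -> "DistributionSpec":
        return cls("point", {"value": value})

    @classmethod
    def lognormal(
        cls, mean: float, gsd: float, bounds: tuple[float, float] | None = None
    ) -> "DistributionSpec":
        return cls("lognormal", {"mean": mean, "gsd": gsd}, bounds)


@dataclass(frozen=True)
class StochasticScenario:
    """Distributional analogue of a deterministic exposure scenario.

    Per-product specs for amount (g/d), daily use frequency (events/day,
    default point mass 1 — per-day averaging, not a one-day draw-or-skip
    model) and retention; fixed ingredient concentration and per-product
    absorption; a body-weight spec; iteration count and seed.
    """

    label: str
    amount: Mapping[str, DistributionSpec]
    retention: Mapping[str, DistributionSpec]
    body_weight: DistributionSpec
    concentration: float
    n_iterations: int
    seed: int
    frequency: Mapping[str, DistributionSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise TableValidationError("n_iterations must be >= 1")
        if not 0 < self.concentration < 1:
            raise TableValidationError("concentration must be in (0, 1)")


def _frequency_spec(
    scenario: StochasticScenario, product: str
) -> DistributionSpec:
    return scenario.frequency.get(product, DistributionSpec.point(1.0))


def simulate_population(
    scenario: StochasticScenario,
    profile: UseProfile,
    ingredient: IngredientParams,
    products: dict[str, ProductParams],
) -> PredictionSet:
    """Draw n_iterations aggregate SED samples for one relevant pair.

    Each iteration sums per-product SED with independently sampled amount,
    frequency, retention and body weight.  Oral-route products use the
    sampled amount x ingested fraction x oral absorption.  Degenerate
    (point-mass) specs collapse the engine to the deterministic value.
    """
    used = profile.products_for(ingredient.name)
    if not used:
        raise TableValidationError(
            f"pair ({profile.participant_id}, {ingredient.name}) is not relevant"
        )
    for prod in used:
        if prod not in scenario.amount or prod not in scenario.retention:
            raise TableValidationError(
                f"scenario {scenario.label!r} lacks specs for product {prod!r}"
            )

    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_iterations
    bw = scenario.body_weight.sample(rng, n)
    if (bw <= 0).any():
        raise TableValidationError("sampled body weights must be > 0")

    total = np.zeros(n)
    for prod in used:  # product-major draw order
        amount = scenario.amount[prod].sample(rng, n)
        freq = _frequency_spec(scenario, prod).sample(rng, n)
        retention = scenario.retention[prod].sample(rng, n)
        pp = products[prod]
        daily_g = amount * freq
        if pp.route == "oral_incidental":
            dose_ug = daily_g * pp.ingested_fraction * scenario.concentration \
                * pp.oral_absorption * 1e6
        else:
            d = ingredient.dermal_absorption(prod)
            dose_ug = daily_g * retention * scenario.concentration * d * 1e6
        total += dose_ug / bw

    return PredictionSet(
        model=scenario.label,
        participant_id=profile.participant_id,
        ingredient=ingredient.name,
        kind="samples",
        value=tuple(float(v) for v in total),
        concentration_scenario=format(scenario.concentration, "g"),
    )


def summarize_samples(samples) -> dict[str, float]:
    """P05 / mean / P95 of a sample population.

    Percentiles use linear interpolation between order statistics (the
    "type 7" convention); the mean is arithmetic.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.size == 0:
        raise TableValidationError("cannot summarise empty samples")
    p05, p95 = np.percentile(arr, [5, 95], method="linear")
    return {"P05": float(p05), "mean": float(arr.mean()), "P95": float(p95)}
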