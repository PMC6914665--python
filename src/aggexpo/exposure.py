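"""Deterministic Tier-1 aggregate exposure engine.

All screening models for personal-care-product exposure share one
algorithmic skeleton, the systemic exposure dose per product:

    SED = A * R * C * D      [μg/kg-d]

where A is the daily application rate normalised to body weight, R the
retention factor (share of product staying in contact with skin), C the
mass fraction of the ingredient in the product, and D the dermal
absorption fraction.  Toothpaste goes through an incidental-ingestion
route instead: swallowed grams/day x C x oral absorption.  A participant's
aggregate exposure to one ingredient is the sum of per-product SEDs over
exactly the products they used containing that ingredient.  Inter-model
differences are represented purely as parameter sources (per-product
amounts, retention conventions), not as separate algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass

from .study_io import (
    IngredientParams,
    Participant,
    PredictionSet,
    ProductParams,
    TableValidationError,
    UseProfile,
)

__all__ = [
    "NoExposureError",
    "AggregateScenario",
    "sed_dermal",
    "sed_dermal_normalized",
    "sed_oral_incidental",
    "product_sed",
    "predict_participant",
    "sccs_aggregate",
    "build_aggregate_scenario",
    "rescale_concentration",
]

_G_PER_DAY_TO_UG = 1e6  # grams/day -> μg/day


class NoExposureError(LookupError):
    """Raised when a (participant, ingredient) pair has no product in the diary.

    An irrelevant pair is an explicit "no exposure" outcome, distinct from
    a model legitimately predicting zero.
    """


def _check_fraction(name: str, value: float, upper_inclusive: bool = True) -> None:
    ok = 0 < value <= 1 if upper_inclusive else 0 < value < 1
    if not ok:
        raise TableValidationError(f"{name} must be in (0, 1{']' if upper_inclusive else ')'}, got {value}")


def sed_dermal(
    amount_g_d: float,
    retention: float,
    concentration: float,
    absorption: float,
    body_weight_kg: float,
) -> float:
    """Dermal-route SED (μg/kg-d) from an application rate in g/d."""
    if amount_g_d <= 0:
        raise TableValidationError(f"amount must be > 0, got {amount_g_d}")
    if body_weight_kg <= 0:
        raise TableValidationError(f"body weight must be > 0, got {body_weight_kg}")
    _check_fraction("retention", retention)
    _check_fraction("concentration", concentration, upper_inclusive=False)
    _check_fraction("absorption", absorption)
    a_norm = amount_g_d * _G_PER_DAY_TO_UG / body_weight_kg
    return sed_dermal_normalized(a_norm, retention, concentration, absorption)


def sed_dermal_normalized(
    a_ug_kg_d: float, retention: float, concentration: float, absorption: float
) -> float:
    """Dermal-route SED with A already normalised to μg of product/kg-d."""
    if a_ug_kg_d <= 0:
        raise TableValidationError("normalised application rate must be > 0")
    return a_ug_kg_d * retention * concentration * absorption


def sed_oral_incidental(
    concentration: float,
    body_weight_kg: float,
    amount_g_d: float | None = None,
    ingested_fraction: float | None = None,
    fixed_ingested_g: float | None = None,
    oral_absorption: float = 1.0,
) -> float:
    """Incidental-ingestion SED (μg/kg-d), e.g. swallowed toothpaste.

    Exactly one ingestion spec is allowed: either ``ingested_fraction`` of
    ``amount_g_d``, or a ``fixed_ingested_g`` mass per day.
    """
    if body_weight_kg <= 0:
        raise TableValidationError("body weight must be > 0")
    _check_fraction("concentration", concentration, upper_inclusive=False)
    _check_fraction("oral absorption", oral_absorption)
    has_fraction = ingested_fraction is not None
    has_fixed = fixed_ingested_g is not None
    if has_fraction == has_fixed:
        raise TableValidationError(
            "give exactly one of ingested_fraction / fixed_ingested_g"
        )
    if has_fraction:
        if amount_g_d is None or amount_g_d <= 0:
            raise TableValidationError("ingested_fraction needs a positive amount_g_d")
        _check_fraction("ingested fraction", ingested_fraction)
        ingested_g = amount_g_d * ingested_fraction
    else:
        if fixed_ingested_g <= 0:
            raise TableValidationError("fixed ingested mass must be > 0")
        ingested_g = fixed_ingested_g
    return ingested_g * concentration * oral_absorption * _G_PER_DAY_TO_UG / body_weight_kg


def product_sed(
    product: ProductParams,
    ingredient: IngredientParams,
    source: str,
    concentration: float,
    body_weight_kg: float,
    absorption_override: float | None = None,
) -> float:
    """SED for one product/ingredient pair under one parameter source."""
    if product.route == "oral_incidental":
        if source == "consexpo":
            # ConsExpo parameterises ingestion as a fixed swallowed mass.
            from .study_io import load_defaults

            fixed = float(load_defaults()["consexpo_fixed_ingested_g"])
            return sed_oral_incidental(
                concentration,
                body_weight_kg,
                fixed_ingested_g=fixed,
                oral_absorption=product.oral_absorption,
            )
        return sed_oral_incidental(
            concentration,
            body_weight_kg,
            amount_g_d=product.amount(source),
            ingested_fraction=product.ingested_fraction,
            oral_absorption=product.oral_absorption,
        )
    absorption = (
        absorption_override
        if absorption_override is not None
        else ingredient.dermal_absorption(product.name)
    )
    return sed_dermal(
        product.amount(source),
        product.retention_factor,
        concentration,
        absorption,
        body_weight_kg,
    )


def predict_participant(
    profile: UseProfile,
    participant: Participant,
    ingredient: IngredientParams,
    products: dict[str, ProductParams],
    source: str = "sccs",
    concentration: str | float = "max",
    absorption_overrides: dict[str, float] | None = None,
) -> PredictionSet:
    """Aggregate deterministic prediction for one (participant, ingredient).

    Sums per-product SEDs over exactly the products the participant used
    containing the ingredient; raises :class:`NoExposureError` for an
    irrelevant pair rather than silently returning zero.
    """
    if not profile.is_relevant(ingredient.name):
        raise NoExposureError(
            f"participant {profile.participant_id} used no product containing "
            f"{ingredient.name}"
        )
    c = ingredient.concentration(concentration)
    overrides = absorption_overrides or {}
    total = 0.0
    for prod_name in profile.products_for(ingredient.name):
        total += product_sed(
            products[prod_name],
            ingredient,
            source,
            c,
            participant.body_weight_kg,
            absorption_override=overrides.get(prod_name),
        )
    label = concentration if isinstance(concentration, str) else format(c, "g")
    return PredictionSet(
        model=source,
        participant_id=profile.participant_id,
        ingredient=ingredient.name,
        kind="point",
        value=total,
        concentration_scenario=label,
    )


@dataclass(frozen=True)
class AggregateScenario:
    """Default aggregate preservative scenario.

    A fixed basket of personal care products, all assumed to contain the
    preservative at the same mass fraction — a deliberately conservative
    regulatory construct.  ``product_table`` rows are
    ``(name, amount_g_d, retention_factor)``; toothpaste-like oral items are
    represented through their retention factor (swallowed share).
    """

    label: str
    product_table: tuple[tuple[str, float, float], ...]
    concentration: float
    dermal_d: float
    body_weight_kg: float

    def __post_init__(self) -> None:
        if not self.product_table:
            raise TableValidationError("aggregate scenario has no products")
        for name, amount, retention in self.product_table:
            if amount <= 0:
                raise TableValidationError(f"amount for {name} must be > 0")
            _check_fraction(f"retention for {name}", retention)
        _check_fraction("concentration", self.concentration, upper_inclusive=False)
        _check_fraction("dermal D", self.dermal_d)
        if self.body_weight_kg <= 0:
            raise TableValidationError("body weight must be > 0")


def sccs_aggregate(scenario: AggregateScenario) -> float:
    """Aggregate SED (μg/kg-d) over the full default product basket.

    Participant-independent apart from body weight: every individual at a
    given body weight receives the same prediction for a given ingredient.
    """
    return sum(
        sed_dermal(
            amount,
            retention,
            scenario.concentration,
            scenario.dermal_d,
            scenario.body_weight_kg,
        )
        for _, amount, retention in scenario.product_table
    )


def build_aggregate_scenario(
    ingredient: IngredientParams,
    config: dict,
    concentration: str | float = "max",
    body_weight_kg: float = 60.0,
) -> AggregateScenario:
    """Build the shipped default aggregate basket for one ingredient."""
    rows = tuple(
        (p["name"], float(p["amount_g_d"]), float(p["retention_factor"]))
        for p in config["aggregate_scenario"]["products"]
    )
    return AggregateScenario(
        label=f"aggregate-default/{ingredient.name}",
        product_table=rows,
        concentration=ingredient.concentration(concentration),
        dermal_d=ingredient.dermal_d.get("default", next(iter(ingredient.dermal_d.values()))),
        body_weight_kg=body_weight_kg,
    )


def rescale_concentration(
    pred: PredictionSet, from_c: float, to_c: float
) -> PredictionSet:
    """Linearly rescale a prediction to an alternative ingredient concentration.

    Absorbed dose is linear in C for every model, so a prediction made at
    mass fraction ``from_c`` maps to ``to_c`` by the ratio ``to_c/from_c``.
    """
    if from_c <= 0:
        raise TableValidationError(f"from_c must be > 0, got {from_c}")
    if to_c < 0:
        raise TableValidationError(f"to_c must be >= 0, got {to_c}")
    ratio = to_c / from_c
    value = (
        pred.value * ratio
        if pred.kind == "point"
        else tuple(v * ratio for v in pred.samples)
    )
    return PredictionSet(
        model=pred.model,
        participant_id=pred.participant_id,
        ingredient=pred.ingredient,
        kind=pred.kind,
        value=value,
        concentration_scenario=format(to_c, "g"),
    )
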