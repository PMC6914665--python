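"""Synthetic observational-study generator with known ground truth.

Emulates the study design end to end: a multi-day observation window with
product-use days and intervention (non-use) days, one absorbed-dose bolus
per product application, first-order urinary elimination of the parent
compound with an F_UE mass partition (the remainder is metabolised or
otherwise lost), complete void-level urine collection, and LOD censoring.
Because every absorbed dose is recorded as ground truth, the dose
reconstruction and evaluation layers can be tested against known answers.

Kinetic model: an application at time t_e contributes, by time t,

    F_UE * dose * (1 - exp(-k_elim * (t - lag - t_e)))        [μg]

to cumulative urinary parent-compound excretion (zero before the lag).
Absorption is an instantaneous bolus after a fixed lag; this deliberately
simple model has a closed form, which is what makes oracle testing of the
reconstruction possible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .study_io import (
    IngredientParams,
    Participant,
    ProductParams,
    TableValidationError,
    UseProfile,
    VoidTable,
)
from . import exposure, reconstruction

__all__ = [
    "KineticsParams",
    "StudyDesign",
    "GroundTruth",
    "default_dose_model",
    "generate_events",
    "cumulative_excreted",
    "sample_voids",
    "end_to_end_recovery",
]


@dataclass(frozen=True)
class KineticsParams:
    """First-order elimination constants for one analyte."""

    half_life_h: float
    f_ue: float
    absorption_lag_h: float = 1.0

    def __post_init__(self) -> None:
        if self.half_life_h <= 0:
            raise TableValidationError("half-life must be > 0")
        if not 0 < self.f_ue <= 1:
            raise TableValidationError("F_UE must be in (0, 1]")
        if self.absorption_lag_h < 0:
            raise TableValidationError("absorption lag must be >= 0")

    @property
    def k_elim(self) -> float:
        """Elimination rate constant (1/h), ln 2 / half-life."""
        return math.log(2.0) / self.half_life_h


@dataclass(frozen=True)
class StudyDesign:
    """Observation schedule, void sampling scheme and censoring.

    Hours run from t = 0 at the first observation midnight; day d covers
    [24(d-1), 24d).  ``use_day_indices`` are 1-based; the default places a
    two-day intervention (non-use) period mid-study.  ``collection_fraction``
    below 1 simulates missed voids.
    """

    n_observation_days: int = 6
    use_day_indices: tuple[int, ...] = (1, 2, 5, 6)
    voids_per_day: int = 6
    void_volume_range: tuple[float, float] = (0.1, 0.4)
    lod_ug_L: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0
    collection_fraction: float = 1.0
    application_hour: float = 8.0
    dose_noise_gsd: float = 1.0  # 1.0 = no jitter

    def __post_init__(self) -> None:
        if self.n_observation_days < 1:
            raise TableValidationError("need at least one observation day")
        if not self.use_day_indices:
            object.__setattr__(self, "use_day_indices", ())
        for d in self.use_day_indices:
            if not 1 <= d <= self.n_observation_days:
                raise TableValidationError(
                    f"use day {d} outside the observation window"
                )
        if self.voids_per_day < 1:
            raise TableValidationError("need at least one void per day")
        lo, hi = self.void_volume_range
        if not 0 < lo <= hi:
            raise TableValidationError("void volumes must satisfy 0 < lo <= hi")
        for analyte, lod in self.lod_ug_L.items():
            if lod < 0:
                raise TableValidationError(f"LOD for {analyte} must be >= 0")
        if not 0 < self.collection_fraction <= 1:
            raise TableValidationError("collection fraction must be in (0, 1]")
        if not 0 <= self.application_hour < 24:
            raise TableValidationError("application hour must be in [0, 24)")
        if self.dose_noise_gsd < 1:
            raise TableValidationError("dose noise GSD must be >= 1")

    @property
    def end_h(self) -> float:
        return 24.0 * self.n_observation_days


@dataclass
class GroundTruth:
    """Everything the generator knows that the reconstruction must not.

    events: (participant, analyte) -> tuple of (time_h, dose_ug) boluses
    total_absorbed_ug: (participant, analyte) -> summed bolus mass
    uncensored: tidy void table with true (pre-LOD) concentrations,
        populated by :func:`sample_voids`
    """

    events: dict[tuple[str, str], tuple[tuple[float, float], ...]]
    total_absorbed_ug: dict[tuple[str, str], float]
    uncensored: pd.DataFrame | None = None

    def excreted_parent_ug(
        self, participant_id: str, analyte: str, kinetics: KineticsParams, t: float
    ) -> float:
        """Closed-form cumulative excreted parent mass at time t (μg)."""
        return cumulative_excreted(
            self.events.get((participant_id, analyte), ()), kinetics, t
        )


def default_dose_model(
    participants: Mapping[str, Participant],
    ingredients: Mapping[str, IngredientParams],
    products: Mapping[str, ProductParams],
    source: str = "sccs",
    concentration: str | float = "max",
) -> Callable[[str, str, str], float]:
    """Per-application dose hook backed by the deterministic engine.

    Returns dose_fn(participant_id, ingredient, product) -> μg absorbed per
    application day (the per-product SED in μg/kg-d times body weight).
    """

    def dose_fn(pid: str, ingredient: str, product: str) -> float:
        ing = ingredients[ingredient]
        sed = exposure.product_sed(
            products[product],
            ing,
            source,
            ing.concentration(concentration),
            participants[pid].body_weight_kg,
        )
        return sed * participants[pid].body_weight_kg

    return dose_fn


def generate_events(
    design: StudyDesign,
    profiles: Mapping[str, UseProfile],
    participants: Mapping[str, Participant],
    dose_fn: Callable[[str, str, str], float],
) -> GroundTruth:
    """Lay down one absorbed-dose bolus per product application per use day.

    Bolus magnitudes come from the deterministic engine hook, optionally
    jittered by multiplicative lognormal noise (``design.dose_noise_gsd``).
    Deterministic for a fixed design seed.
    """
    if not profiles:
        raise TableValidationError("no use profiles given")
    rng = np.random.default_rng([int(design.seed), 0])
    events: dict[tuple[str, str], list[tuple[float, float]]] = {}
    totals: dict[tuple[str, str], float] = {}
    for pid in sorted(profiles):
        profile = profiles[pid]
        if pid not in participants:
            raise TableValidationError(f"no participant record for {pid!r}")
        for ingredient in profile.ingredients:
            key = (pid, ingredient)
            events.setdefault(key, [])
            totals.setdefault(key, 0.0)
            for day in design.use_day_indices:
                t_apply = 24.0 * (day - 1) + design.application_hour
                for product in profile.products_for(ingredient):
                    dose = dose_fn(pid, ingredient, product)
                    if design.dose_noise_gsd > 1.0:
                        sigma = math.log(design.dose_noise_gsd)
                        dose *= float(
                            rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma)
                        )
                    events[key].append((t_apply, dose))
                    totals[key] += dose
    return GroundTruth(
        events={k: tuple(v) for k, v in events.items()},
        total_absorbed_ug=totals,
    )


def cumulative_excreted(
    events: Sequence[tuple[float, float]], kinetics: KineticsParams, t: float
) -> float:
    """Cumulative parent mass (μg) excreted in urine by time t.

    Monotone non-decreasing in t; approaches F_UE x total dose as
    t -> infinity.
    """
    if t < 0:
        raise TableValidationError("time must be >= 0")
    k = kinetics.k_elim
    total = 0.0
    for t_event, dose in events:
        elapsed = t - kinetics.absorption_lag_h - t_event
        if elapsed > 0:
            total += kinetics.f_ue * dose * (1.0 - math.exp(-k * elapsed))
    return total


def _void_schedule(design: StudyDesign, rng: np.random.Generator) -> np.ndarray:
    """Sorted void times over the whole observation window."""
    times = []
    for day in range(design.n_observation_days):
        times.append(rng.uniform(24.0 * day, 24.0 * (day + 1), design.voids_per_day))
    out = np.sort(np.concatenate(times))
    if out.size == 0:
        raise TableValidationError("void schedule produced zero voids")
    return out


def sample_voids(
    ground_truth: GroundTruth,
    kinetics: Mapping[str, KineticsParams],
    design: StudyDesign,
) -> VoidTable:
    """Simulate complete void-level urine collection.

    The mass of analyte in each void is the increment of cumulative
    excretion between consecutive voids, so summed C·V over all voids
    equals cumulative excretion at the last void time exactly (mass
    conservation; urine produced after the final void is not collected).
    Concentrations below the analyte LOD are released as non-detects with
    value 0; the true concentrations are retained in
    ``ground_truth.uncensored`` only.
    """
    rng = np.random.default_rng([int(design.seed), 1])
    pids = sorted({pid for pid, _ in ground_truth.events})
    if not pids:
        raise TableValidationError("ground truth contains no participants")

    # every analyte is assayed in every sample, as in the study protocol;
    # pairs without events simply yield zero-mass (non-detect) measurements
    analytes = sorted({a for _, a in ground_truth.events})
    released, uncensored = [], []
    for pid in pids:
        times = _void_schedule(design, rng)
        volumes = rng.uniform(*design.void_volume_range, size=times.size)
        if design.collection_fraction < 1.0:
            collected = rng.random(times.size) < design.collection_fraction
        else:
            collected = np.ones(times.size, dtype=bool)
        for analyte in analytes:
            kin = kinetics[analyte]
            events = ground_truth.events.get((pid, analyte), ())
            lod = float(design.lod_ug_L.get(analyte, 0.0))
            prev_cum = 0.0
            for t, vol, keep in zip(times, volumes, collected):
                cum = cumulative_excreted(events, kin, t)
                mass = cum - prev_cum
                prev_cum = cum
                if not keep:
                    continue  # missed void: its urine (and mass) is lost
                conc = mass / vol
                detected = conc >= lod and conc > 0.0
                uncensored.append(
                    dict(
                        participant_id=pid,
                        time_h=float(t),
                        volume_L=float(vol),
                        analyte=analyte,
                        conc_ug_L=float(conc),
                        detected=bool(detected),
                    )
                )
                released.append(
                    dict(
                        participant_id=pid,
                        time_h=float(t),
                        volume_L=float(vol),
                        analyte=analyte,
                        conc_ug_L=float(conc) if detected else 0.0,
                        detected=bool(detected),
                    )
                )
    ground_truth.uncensored = pd.DataFrame(uncensored, columns=list(VoidTable.COLUMNS))
    return VoidTable(pd.DataFrame(released, columns=list(VoidTable.COLUMNS)))


def end_to_end_recovery(
    design: StudyDesign,
    profiles: Mapping[str, UseProfile],
    participants: Mapping[str, Participant],
    ingredients: Mapping[str, IngredientParams],
    products: Mapping[str, ProductParams],
    source: str = "sccs",
    concentration: str | float = "max",
) -> pd.DataFrame:
    """Generate -> sample -> reconstruct, reporting per-pair recovery.

    The recovery ratio compares the reconstructed minimum dose with its
    theoretical complete-collection value F_UE x true dose / (BW x
    n_use_days); under zero LOD and a collection tail much longer than the
    half-life it approaches 1 from below (tail bound exp(-k x tail)).
    """
    dose_fn = default_dose_model(participants, ingredients, products, source, concentration)
    truth = generate_events(design, profiles, participants, dose_fn)
    kinetics = {
        name: KineticsParams(half_life_h=ing.half_life_h, f_ue=ing.f_ue)
        for name, ing in ingredients.items()
    }
    voids = sample_voids(truth, kinetics, design)

    rows = []
    for (pid, analyte), true_dose in sorted(truth.total_absorbed_ug.items()):
        part = participants[pid]
        mass = reconstruction.excreted_mass(voids, pid, analyte)
        d_min = reconstruction.min_absorbed_dose(
            mass, part.body_weight_kg, part.n_use_days
        )
        ideal = (
            ingredients[analyte].f_ue
            * true_dose
            / (part.body_weight_kg * part.n_use_days)
        )
        rows.append(
            dict(
                participant_id=pid,
                ingredient=analyte,
                true_dose_ug=true_dose,
                excreted_mass_ug=mass,
                d_min=d_min,
                ideal_d_min=ideal,
                recovery_ratio=d_min / ideal if ideal > 0 else float("nan"),
            )
        )
    return pd.DataFrame(rows)
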