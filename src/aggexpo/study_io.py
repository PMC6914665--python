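"""Domain types, tabular I/O, and packaged study fixtures.

The package revolves around a small observational design: eight volunteers,
six observation days of complete urine collection, four days of personal
care product use, and four preservative analytes (methyl-, ethyl- and
n-propylparaben and triclosan, abbreviated MP, EP, PP, TCS).  This module
holds the data containers shared by the reconstruction, exposure-modelling
and evaluation layers, CSV readers/writers for them, and the packaged
fixture tables (use profiles, per-participant excretion, model predictions,
product amounts, and the default parameter set).

The product-level entries of the use-profile fixture are a reconstruction:
the relevance pattern (which participant/ingredient pairs exist and how many
products back each pair) is exact, but the identity of the products within a
few pairs is not publicly documented and was filled in consistently with the
narrative constraints of the study.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "TableValidationError",
    "VoidRecord",
    "VoidTable",
    "Participant",
    "UseProfile",
    "IngredientParams",
    "ProductParams",
    "DoseEstimate",
    "PredictionSet",
    "StudyFixtures",
    "ANALYTES",
    "PRODUCTS",
    "ND_SENTINEL",
    "read_void_table",
    "write_void_table",
    "read_use_profiles",
    "load_defaults",
    "load_study_fixtures",
    "write_report_table",
]

#: Canonical analyte order used throughout.
ANALYTES = ("MP", "EP", "PP", "TCS")

#: Controlled vocabulary of diary products (extensible via config).
PRODUCTS = (
    "toothpaste",
    "shampoo",
    "shower_gel",
    "deodorant",
    "shaving_cream",
    "day_cream",
    "body_lotion",
)

#: Sentinel marking a non-detect concentration cell in void CSV files.
ND_SENTINEL = "ND"


class FormatError(ValueError):
    """A file does not match the expected tabular layout."""


class TableValidationError(ValueError):
    """Parsed values violate a domain invariant (e.g. negative volume)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VoidRecord:
    """One urine void.

    ``concentrations`` maps analyte name to ``(value_ug_L, detected)``.
    Non-detected values are retained as given; zero-imputation is a
    downstream policy, never an I/O side effect.
    """

    participant_id: str
    time_h: float
    volume_L: float
    concentrations: Mapping[str, tuple[float, bool]]

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise TableValidationError(f"void time must be >= 0, got {self.time_h}")
        if self.volume_L <= 0:
            raise TableValidationError(f"void volume must be > 0, got {self.volume_L}")
        for analyte, (value, _) in self.concentrations.items():
            if value < 0:
                raise TableValidationError(
                    f"concentration of {analyte} must be >= 0, got {value}"
                )


class VoidTable:
    """Collection of voids, held as a tidy DataFrame.

    Columns: ``participant_id, time_h, volume_L, analyte, conc_ug_L,
    detected``.  Rows are sorted by participant then time.
    """

    COLUMNS = ("participant_id", "time_h", "volume_L", "analyte", "conc_ug_L", "detected")

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"void table missing columns: {sorted(missing)}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        if (df["volume_L"] <= 0).any():
            bad = df.index[df["volume_L"] <= 0][0]
            raise TableValidationError(f"non-positive void volume at row {bad}")
        if (df["conc_ug_L"] < 0).any():
            bad = df.index[df["conc_ug_L"] < 0][0]
            raise TableValidationError(f"negative concentration at row {bad}")
        self.df = df.sort_values(
            ["participant_id", "time_h"], kind="stable"
        ).reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[VoidRecord]) -> "VoidTable":
        rows = []
        for rec in records:
            for analyte, (value, detected) in rec.concentrations.items():
                rows.append(
                    dict(
                        participant_id=rec.participant_id,
                        time_h=rec.time_h,
                        volume_L=rec.volume_L,
                        analyte=analyte,
                        conc_ug_L=value,
                        detected=bool(detected),
                    )
                )
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))

    @property
    def participants(self) -> list[str]:
        return sorted(self.df["participant_id"].unique())

    @property
    def analytes(self) -> list[str]:
        return sorted(self.df["analyte"].unique())

    def for_participant(self, participant_id: str) -> pd.DataFrame:
        sub = self.df[self.df["participant_id"] == participant_id]
        if sub.empty:
            raise KeyError(f"unknown participant: {participant_id!r}")
        return sub

    def n_voids(self, participant_id: str) -> int:
        sub = self.for_participant(participant_id)
        return sub[["time_h", "volume_L"]].drop_duplicates().shape[0]

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VoidTable):
            return NotImplemented
        return self.df.equals(other.df)


@dataclass(frozen=True)
class Participant:
    """Study participant with body weight and design counts.

    The excreted mass is averaged over the days of product use
    (default 4), not the full observation window (default 6): collection on
    non-use days captures carryover from earlier applications.
    """

    participant_id: str
    body_weight_kg: float
    n_use_days: int = 4
    n_observation_days: int = 6

    def __post_init__(self) -> None:
        if self.body_weight_kg <= 0:
            raise TableValidationError("body weight must be > 0")
        if not 0 < self.n_use_days <= self.n_observation_days:
            raise TableValidationError(
                "need 0 < n_use_days <= n_observation_days, got "
                f"{self.n_use_days} / {self.n_observation_days}"
            )


@dataclass(frozen=True)
class UseProfile:
    """Set of (ingredient, product) pairs a participant actually used."""

    participant_id: str
    entries: frozenset[tuple[str, str]]

    def is_relevant(self, ingredient: str) -> bool:
        """True iff at least one used product contains the ingredient."""
        return any(ing == ingredient for ing, _ in self.entries)

    def products_for(self, ingredient: str) -> tuple[str, ...]:
        return tuple(sorted(p for ing, p in self.entries if ing == ingredient))

    @property
    def ingredients(self) -> tuple[str, ...]:
        return tuple(sorted({ing for ing, _ in self.entries}))


@dataclass(frozen=True)
class IngredientParams:
    """Per-ingredient constants.

    f_ue: urinary excretion fraction of a systemically absorbed dose
    recovered in urine as parent compound (free + conjugated), in (0, 1].
    dermal_d: product -> dermal absorption fraction; a ``default`` key
    covers products without a specific value.
    conc_scenarios: scenario label -> mass fraction of ingredient in product.
    """

    name: str
    f_ue: float
    dermal_d: Mapping[str, float]
    conc_scenarios: Mapping[str, float]
    half_life_h: float

    def __post_init__(self) -> None:
        if not 0 < self.f_ue <= 1:
            raise TableValidationError(f"F_UE must be in (0, 1], got {self.f_ue}")
        for prod, d in self.dermal_d.items():
            if not 0 < d <= 1:
                raise TableValidationError(f"dermal D for {prod} must be in (0, 1]")
        for label, c in self.conc_scenarios.items():
            if not 0 < c < 1:
                raise TableValidationError(
                    f"concentration scenario {label!r} must be in (0, 1)"
                )
        if self.half_life_h <= 0:
            raise TableValidationError("half-life must be > 0")

    def dermal_absorption(self, product: str) -> float:
        try:
            return self.dermal_d.get(product, self.dermal_d["default"])
        except KeyError:
            raise KeyError(
                f"no dermal absorption fraction for {self.name}/{product} and no default"
            ) from None

    def concentration(self, scenario: str | float) -> float:
        """Resolve a scenario label, or accept a literal mass fraction."""
        if isinstance(scenario, str):
            try:
                return float(self.conc_scenarios[scenario])
            except KeyError:
                raise KeyError(
                    f"unknown concentration scenario {scenario!r} for {self.name}"
                ) from None
        c = float(scenario)
        if not 0 < c < 1:
            raise TableValidationError(f"mass fraction must be in (0, 1), got {c}")
        return c


@dataclass(frozen=True)
class ProductParams:
    """Per-product usage and route constants.

    ``daily_amount_g`` maps a parameter source (``sccs``, ``consexpo``,
    ``sheds``, ``creme``, ``raidar``, ``observed``) to grams of product per
    day, so engines can be parameterised by source.  The oral-incidental
    route carries exactly one of ``ingested_fraction`` (share of the amount
    used that is swallowed) or ``fixed_ingested_g`` (fixed swallowed mass).
    """

    name: str
    daily_amount_g: Mapping[str, float]
    retention_factor: float
    route: str  # "dermal" | "oral_incidental"
    ingested_fraction: float | None = None
    fixed_ingested_g: float | None = None
    oral_absorption: float = 1.0

    def __post_init__(self) -> None:
        if self.route not in ("dermal", "oral_incidental"):
            raise TableValidationError(f"unknown route {self.route!r}")
        if not 0 < self.retention_factor <= 1:
            raise TableValidationError("retention factor must be in (0, 1]")
        if self.route == "oral_incidental":
            specs = (self.ingested_fraction is not None) + (
                self.fixed_ingested_g is not None
            )
            if specs != 1:
                raise TableValidationError(
                    "oral route needs exactly one of ingested_fraction / fixed_ingested_g"
                )
            if self.ingested_fraction is not None and not 0 < self.ingested_fraction <= 1:
                raise TableValidationError("ingested fraction must be in (0, 1]")
            if not 0 < self.oral_absorption <= 1:
                raise TableValidationError("oral absorption must be in (0, 1]")

    def amount(self, source: str) -> float:
        try:
            a = self.daily_amount_g[source]
        except KeyError:
            raise KeyError(
                f"no daily amount for product {self.name!r} from source {source!r}"
            ) from None
        if a is None or (isinstance(a, float) and pd.isna(a)):
            raise KeyError(
                f"source {source!r} does not parameterise product {self.name!r}"
            )
        return float(a)


@dataclass(frozen=True)
class DoseEstimate:
    """Reconstructed minimum/maximum absorbed dose for one pair (μg/kg-d)."""

    participant_id: str
    ingredient: str
    d_min: float
    d_max: float
    user_flag: bool

    def __post_init__(self) -> None:
        if self.d_min < 0:
            raise TableValidationError("d_min must be >= 0")
        if self.d_max < self.d_min:
            raise TableValidationError("d_max must be >= d_min")


@dataclass(frozen=True)
class PredictionSet:
    """Model output for one (participant, ingredient) pair.

    ``kind`` is ``point`` (a single μg/kg-d value) or ``samples`` (an
    ordered collection of μg/kg-d draws from a probabilistic engine).
    """

    model: str
    participant_id: str
    ingredient: str
    kind: str
    value: float | tuple[float, ...]
    concentration_scenario: str = "max"

    def __post_init__(self) -> None:
        if self.kind not in ("point", "samples"):
            raise TableValidationError(f"unknown prediction kind {self.kind!r}")
        if self.kind == "point":
            if float(self.value) < 0:
                raise TableValidationError("prediction must be >= 0")
        else:
            vals = tuple(float(v) for v in self.value)
            if not vals:
                raise TableValidationError("sample predictions must be non-empty")
            if any(v < 0 for v in vals):
                raise TableValidationError("sample predictions must be >= 0")
            object.__setattr__(self, "value", vals)

    @property
    def samples(self) -> tuple[float, ...]:
        if self.kind != "samples":
            raise TableValidationError("not a sample-kind prediction")
        return self.value  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_void_table(path: str | Path) -> VoidTable:
    """Parse a wide void CSV into a :class:`VoidTable`.

    Expected header: ``participant_id,time_h,volume_L,<analyte>,...`` with
    one column per analyte.  A concentration cell equal to ``ND`` marks a
    non-detect (stored with value 0.0 and ``detected=False``); any other
    cell must be a non-negative number.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str)
    required = ["participant_id", "time_h", "volume_L"]
    for col in required:
        if col not in raw.columns:
            raise FormatError(f"void file {path.name} missing column {col!r}")
    analytes = [c for c in raw.columns if c not in required]
    if not analytes:
        raise FormatError(f"void file {path.name} has no analyte columns")

    rows = []
    for idx, row in raw.iterrows():
        try:
            time_h = float(row["time_h"])
            volume = float(row["volume_L"])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"row {idx}: non-numeric time or volume") from exc
        if volume <= 0:
            raise TableValidationError(f"row {idx}: non-positive volume {volume}")
        if time_h < 0:
            raise TableValidationError(f"row {idx}: negative time {time_h}")
        for analyte in analytes:
            cell = row[analyte]
            if pd.isna(cell):
                raise FormatError(
                    f"row {idx}: blank {analyte} cell; non-detects must be "
                    f"marked {ND_SENTINEL!r}"
                )
            if isinstance(cell, str) and cell.strip().upper() == ND_SENTINEL:
                value, detected = 0.0, False
            else:
                try:
                    value = float(cell)
                except (TypeError, ValueError) as exc:
                    raise FormatError(
                        f"row {idx}: cannot parse {analyte} cell {cell!r}"
                    ) from exc
                if value < 0:
                    raise TableValidationError(
                        f"row {idx}: negative concentration {value} for {analyte}"
                    )
                detected = True
            rows.append(
                dict(
                    participant_id=str(row["participant_id"]),
                    time_h=time_h,
                    volume_L=volume,
                    analyte=analyte,
                    conc_ug_L=value,
                    detected=detected,
                )
            )
    return VoidTable(pd.DataFrame(rows, columns=list(VoidTable.COLUMNS)))


def write_void_table(table: VoidTable, path: str | Path) -> None:
    """Write a void table back to the wide CSV layout of read_void_table."""
    wide_rows: dict[tuple[str, float, float], dict] = {}
    analytes = table.analytes
    for _, r in table.df.iterrows():
        key = (r["participant_id"], r["time_h"], r["volume_L"])
        rec = wide_rows.setdefault(
            key,
            {"participant_id": key[0], "time_h": key[1], "volume_L": key[2]},
        )
        rec[r["analyte"]] = (
            ND_SENTINEL if not r["detected"] else format(r["conc_ug_L"], ".6g")
        )
    df = pd.DataFrame(list(wide_rows.values()))
    df = df[["participant_id", "time_h", "volume_L", *analytes]]
    write_report_table(df, path)


def read_use_profiles(path: str | Path) -> dict[str, UseProfile]:
    """Read a long-format diary CSV (participant_id, ingredient, product)."""
    df = pd.read_csv(path, dtype=str)
    for col in ("participant_id", "ingredient", "product"):
        if col not in df.columns:
            raise FormatError(f"use-profile file missing column {col!r}")
    profiles: dict[str, UseProfile] = {}
    for pid, sub in df.groupby("participant_id", sort=True):
        entries = frozenset(zip(sub["ingredient"], sub["product"]))
        profiles[str(pid)] = UseProfile(participant_id=str(pid), entries=entries)
    return profiles


def write_report_table(
    df: pd.DataFrame, path: str | Path, float_format: str = "%.4f"
) -> None:
    """Write a report CSV deterministically.

    Fixed column order (as given), fixed decimal formatting, RFC-4180
    dialect, UTF-8, trailing newline; two writes of the same rows are
    byte-identical.
    """
    path = Path(path)
    try:
        df.to_csv(
            path,
            index=False,
            float_format=float_format,
            lineterminator="\n",
            encoding="utf-8",
        )
    except OSError as exc:
        raise OSError(f"cannot write report table to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("aggexpo").joinpath("data", name))


def load_defaults() -> dict:
    """Load the packaged default parameter set (YAML) as a dict."""
    with open(_data_path("defaults.yaml"), "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


@dataclass
class StudyFixtures:
    """All packaged study tables in domain form.

    observed:   per-participant daily excretion (μg/kg-d) with user flags
    predictions: observed min/max doses plus every model column
    spearman:   the published rank-correlation summary rows
    amounts:    per-product daily application amounts by parameter source
    """

    participants: dict[str, Participant]
    profiles: dict[str, UseProfile]
    ingredients: dict[str, IngredientParams]
    products: dict[str, ProductParams]
    observed: pd.DataFrame
    predictions: pd.DataFrame
    spearman: pd.DataFrame
    amounts: pd.DataFrame
    config: dict = field(repr=False, default_factory=dict)

    @property
    def relevant_pairs(self) -> list[tuple[str, str]]:
        out = []
        for pid in sorted(self.profiles, key=lambda p: (len(p), p)):
            for ing in ANALYTES:
                if self.profiles[pid].is_relevant(ing):
                    out.append((pid, ing))
        return out


def load_study_fixtures() -> StudyFixtures:
    """Load the packaged study tables.

    Returns the eight participants with their body weights, the
    use-profile relevance matrix (25 relevant participant/ingredient
    pairs), ingredient and product parameter sets, the per-participant
    excretion table, and the model-prediction / rank-correlation matrices.
    """
    config = load_defaults()

    observed = pd.read_csv(_data_path("observed_excretion.csv"), dtype={"participant_id": str})
    observed["user"] = observed["user"].astype(bool)

    participants = {
        str(pid): Participant(
            participant_id=str(pid),
            body_weight_kg=float(sub["body_weight_kg"].iloc[0]),
            n_use_days=int(config["study_defaults"]["n_use_days"]),
            n_observation_days=int(config["study_defaults"]["n_observation_days"]),
        )
        for pid, sub in observed.groupby("participant_id")
    }

    profiles = read_use_profiles(_data_path("use_profiles.csv"))

    ingredients = {
        name: IngredientParams(
            name=name,
            f_ue=float(spec["f_ue"]),
            dermal_d={k: float(v) for k, v in spec["dermal_absorption"].items()},
            conc_scenarios={k: float(v) for k, v in spec["conc_scenarios"].items()},
            half_life_h=float(spec["half_life_h"]),
        )
        for name, spec in config["ingredients"].items()
    }

    amounts = pd.read_csv(_data_path("product_amounts.csv"))
    amount_by_product: dict[str, dict[str, float]] = {}
    for _, row in amounts.iterrows():
        for product in amounts.columns[1:]:
            amount_by_product.setdefault(product, {})[row["source"]] = (
                float(row[product]) if pd.notna(row[product]) else float("nan")
            )

    products = {}
    for name, spec in config["products"].items():
        kwargs = dict(
            name=name,
            daily_amount_g=amount_by_product.get(name, {}),
            retention_factor=float(spec["retention_factor"]),
            route=spec["route"],
        )
        if spec["route"] == "oral_incidental":
            kwargs["ingested_fraction"] = float(spec["ingested_fraction"])
            kwargs["oral_absorption"] = float(spec["oral_absorption"])
        products[name] = ProductParams(**kwargs)

    predictions = pd.read_csv(
        _data_path("model_predictions.csv"), dtype={"participant_id": str}
    )
    spearman = pd.read_csv(_data_path("rank_correlations.csv"))

    return StudyFixtures(
        participants=participants,
        profiles=profiles,
        ingredients=ingredients,
        products=products,
        observed=observed,
        predictions=predictions,
        spearman=spearman,
        amounts=amounts,
        config=config,
    )
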