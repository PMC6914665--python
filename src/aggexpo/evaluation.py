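"""Model-vs-observation evaluation statistics.

Three complementary views of model performance against biomonitoring-derived
dose estimates:

* tie-aware Spearman rank correlation (Pearson correlation of average
  ranks) between predictions and observed minimum/maximum absorbed doses;
* factor-of-k agreement: the share of predictions within a factor of
  k_inner (default 3) and k_outer (default 10) of the observation, split
  into over- and under-predictions;
* percentile placement: where an observed dose falls inside a
  probabilistic model's sample population for that pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .study_io import TableValidationError

__all__ = [
    "SpearmanResult",
    "AgreementBreakdown",
    "PercentilePlacement",
    "spearman_rho",
    "factor_agreement",
    "percentile_of_observation",
    "evaluation_report",
]


@dataclass(frozen=True)
class SpearmanResult:
    """Rank correlation with an explicit undefined state.

    Constant input vectors have no rank ordering; the coefficient is then
    reported as undefined with a reason, never coerced to 0.
    """

    rho: float
    n: int
    defined: bool = True
    reason: str | None = None


@dataclass(frozen=True)
class AgreementBreakdown:
    """Factor-of-k agreement fractions over included pairs.

    A pair with ratio r = pred/obs is within factor k iff 1/k <= r <= k
    (boundaries inclusive); it is an over-prediction iff r > 1 (r == 1 is
    counted as within-inner-over by convention).  The six fractions sum to
    one over the included pairs; pairs with non-positive pred or obs are
    excluded and counted in n_excluded.
    """

    k_inner: float
    k_outer: float
    within_inner_over: float
    within_inner_under: float
    inner_to_outer_over: float
    inner_to_outer_under: float
    beyond_outer_over: float
    beyond_outer_under: float
    n_pairs: int
    n_excluded: int

    @property
    def within_inner(self) -> float:
        return self.within_inner_over + self.within_inner_under

    @property
    def within_outer(self) -> float:
        return self.within_inner + self.inner_to_outer_over + self.inner_to_outer_under

    @property
    def fractions(self) -> dict[str, float]:
        return {
            "within_inner_over": self.within_inner_over,
            "within_inner_under": self.within_inner_under,
            "inner_to_outer_over": self.inner_to_outer_over,
            "inner_to_outer_under": self.inner_to_outer_under,
            "beyond_outer_over": self.beyond_outer_over,
            "beyond_outer_under": self.beyond_outer_under,
        }


@dataclass(frozen=True)
class PercentilePlacement:
    """Placement of an observation inside a predicted sample population."""

    participant_id: str
    ingredient: str
    percentile: float
    bin_label: str


def spearman_rho(x, y) -> SpearmanResult:
    """Tie-aware Spearman rank correlation.

    Computed as the Pearson correlation of average ranks (tied values
    receive the mean of the ranks they span).  Needs equal-length inputs
    with at least 3 pairs and no missing values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise TableValidationError(
            f"inputs must be equal-length 1-d vectors, got {x.shape} vs {y.shape}"
        )
    if x.size < 3:
        raise TableValidationError("need at least 3 pairs")
    if np.isnan(x).any() or np.isnan(y).any():
        raise TableValidationError("missing values are not allowed")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return SpearmanResult(
            rho=float("nan"), n=x.size, defined=False, reason="constant input vector"
        )
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    return SpearmanResult(rho=rho, n=x.size)


def factor_agreement(
    pred, obs, k_inner: float = 3.0, k_outer: float = 10.0
) -> AgreementBreakdown:
    """Classify prediction/observation ratios into factor-of-k bands."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise TableValidationError("pred and obs must have equal length")
    if not 1 < k_inner <= k_outer:
        raise TableValidationError("need 1 < k_inner <= k_outer")

    valid = (pred > 0) & (obs > 0)
    n_excluded = int((~valid).sum())
    r = pred[valid] / obs[valid]
    n = r.size
    counts = dict.fromkeys(
        (
            "within_inner_over",
            "within_inner_under",
            "inner_to_outer_over",
            "inner_to_outer_under",
            "beyond_outer_over",
            "beyond_outer_under",
        ),
        0,
    )
    for ratio in r:
        over = ratio >= 1.0  # r == 1 counted on the over side by convention
        if 1.0 / k_inner <= ratio <= k_inner:
            band = "within_inner"
        elif 1.0 / k_outer <= ratio <= k_outer:
            band = "inner_to_outer"
        else:
            band = "beyond_outer"
        counts[f"{band}_{'over' if over else 'under'}"] += 1
    fractions = {k: (v / n if n else 0.0) for k, v in counts.items()}
    return AgreementBreakdown(
        k_inner=k_inner,
        k_outer=k_outer,
        n_pairs=n,
        n_excluded=n_excluded,
        **fractions,
    )


def _bin_label(percentile: float) -> str:
    if percentile < 5:
        return "<5"
    if percentile > 99:
        return ">99"
    if 90 < percentile <= 95:
        return "90-95"
    return str(int(round(percentile)))


def percentile_of_observation(
    samples, observed: float, participant_id: str = "", ingredient: str = ""
) -> PercentilePlacement:
    """Percentile of an observed dose within a predicted sample population.

    Uses the midpoint rule for ties: percentile = 100 x (#samples below +
    half the #samples equal) / n, avoiding 0/100 artefacts from exact ties.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.size == 0:
        raise TableValidationError("empty sample population")
    if observed < 0:
        raise TableValidationError("observed dose must be >= 0")
    below = int((arr < observed).sum())
    equal = int((arr == observed).sum())
    percentile = 100.0 * (below + 0.5 * equal) / arr.size
    return PercentilePlacement(
        participant_id=participant_id,
        ingredient=ingredient,
        percentile=percentile,
        bin_label=_bin_label(percentile),
    )


def evaluation_report(
    predictions: pd.DataFrame,
    estimates: pd.DataFrame,
    k_inner: float = 3.0,
    k_outer: float = 10.0,
) -> pd.DataFrame:
    """Integrated per-model evaluation against reconstructed doses.

    ``predictions`` needs columns ``model, participant_id, ingredient``
    plus either ``value`` (point predictions) or ``samples`` (tuple/list
    cells); ``estimates`` needs ``participant_id, ingredient, d_min,
    d_max``.  The two tables must cover identical (participant,
    ingredient) keys; orphans on either side raise a reconciliation error
    listing them.

    Returns one row per model with Spearman rho vs d_min and d_max, the
    factor-of-k agreement fractions vs d_min, and (for sample-kind
    predictions) the mean observed-dose percentile.
    """
    key = ["participant_id", "ingredient"]
    est_keys = set(map(tuple, estimates[key].itertuples(index=False)))
    rows = []
    for model, sub in predictions.groupby("model", sort=True):
        pred_keys = set(map(tuple, sub[key].itertuples(index=False)))
        if pred_keys != est_keys:
            orphans = sorted(pred_keys ^ est_keys)
            raise TableValidationError(
                f"key mismatch for model {model!r}; orphan pairs: {orphans}"
            )
        merged = sub.merge(estimates, on=key, validate="one_to_one")
        if "samples" in merged.columns and merged["samples"].notna().all():
            point = np.array([float(np.mean(s)) for s in merged["samples"]])
            percentiles = [
                percentile_of_observation(s, o, p, i).percentile
                for s, o, p, i in zip(
                    merged["samples"],
                    merged["d_min"],
                    merged["participant_id"],
                    merged["ingredient"],
                )
            ]
            mean_percentile = float(np.mean(percentiles))
        else:
            point = merged["value"].to_numpy(dtype=float)
            mean_percentile = float("nan")

        rho_min = spearman_rho(point, merged["d_min"].to_numpy())
        rho_max = spearman_rho(point, merged["d_max"].to_numpy())
        agreement = factor_agreement(point, merged["d_min"].to_numpy(), k_inner, k_outer)
        rows.append(
            dict(
                model=model,
                n_pairs=agreement.n_pairs,
                rho_vs_dmin=rho_min.rho if rho_min.defined else float("nan"),
                rho_vs_dmin_defined=rho_min.defined,
                rho_vs_dmax=rho_max.rho if rho_max.defined else float("nan"),
                rho_vs_dmax_defined=rho_max.defined,
                within_inner=agreement.within_inner,
                within_outer=agreement.within_outer,
                **agreement.fractions,
                mean_obs_percentile=mean_percentile,
            )
        )
    return pd.DataFrame(rows)
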