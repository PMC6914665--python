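# aggexpo

Aggregate exposure modelling and reverse dosimetry for preservatives in
personal care products (methyl-, ethyl- and n-propylparaben and triclosan:
MP, EP, PP, TCS).

Consumer-exposure models are routinely used in safety assessment, but
opportunities to check their predictions against observed absorbed doses
are rare. `aggexpo` implements the full computational chain for one such
evaluation, built around a small observational design: eight volunteers,
six days of complete urine collection (every void timed and measured),
four days of product use separated by a two-day intervention period with
preservative-free replacement products.

The package provides, for researchers in exposure science and
biomonitoring:

* **Reverse dosimetry** (`aggexpo.reconstruction`): the average daily
  minimum absorbed dose from void-level urine data,

  `D_min = Σᵢ Cᵢ·Vᵢ / (BW · n_use_days)`   [μg/kg-d]

  with non-detects imputed as zero, and the upper bound
  `D_max = D_min / F_UE` from urinary excretion fractions
  (F_UE = 17.4 %, 13.7 %, 9.7 % and 54 % for MP, EP, PP, TCS).
* **A deterministic Tier-1 engine** (`aggexpo.exposure`): per-product
  systemic exposure dose `SED = A·R·C·D` (application rate × retention ×
  ingredient mass fraction × absorption fraction), an incidental-ingestion
  route for toothpaste, participant-level aggregation over the products
  actually used, a conservative 17-product default aggregate scenario, and
  linear concentration rescaling. Screening models are represented as
  parameter sources (per-product amounts and conventions), not separate
  algorithms.
* **A Monte-Carlo Tier-2 engine** (`aggexpo.montecarlo`): distributional
  habits-and-practices inputs, per-pair sample populations, P05/mean/P95
  summaries, bit-reproducible by seed.
* **Evaluation statistics** (`aggexpo.evaluation`): tie-aware Spearman
  rank correlation, factor-of-3/10 agreement with over/under-prediction
  decomposition, and percentile placement of observations inside
  probabilistic prediction distributions.
* **A synthetic-study generator** (`aggexpo.synthetic`): absorbed-dose
  boluses on use days, first-order urinary elimination with an F_UE mass
  partition, complete void-level collection and LOD censoring — with full
  ground truth, so the whole chain is testable without any external data.
* **Packaged study tables** (`aggexpo.study_io.load_study_fixtures`):
  product/ingredient use profiles, body weights, per-participant daily
  excretion, model-prediction matrices and per-product usage amounts.

## Worked example

```python
from aggexpo import load_study_fixtures, reconstruction, exposure, evaluation

fx = load_study_fixtures()

# participant 1, triclosan: observed minimum dose -> upper bound
d_min = 35.09                                     # μg/kg-d, from urine
d_max = reconstruction.max_absorbed_dose(d_min, fx.ingredients["TCS"].f_ue)
print(f"D_max = {d_max:.2f} μg/kg-d")             # D_max = 64.98 μg/kg-d

# deterministic aggregate prediction for participant 1 / methylparaben
pred = exposure.predict_participant(
    fx.profiles["1"], fx.participants["1"], fx.ingredients["MP"],
    fx.products, source="sccs", concentration="max",
)
print(f"predicted SED = {pred.value:.2f} μg/kg-d")  # predicted SED = 24.63 μg/kg-d

# how well does the default aggregate scenario rank the 25 observed doses?
rho = evaluation.spearman_rho(
    fx.predictions["min_abs_dose"], fx.predictions["sccs_default"])
print(f"Spearman rho = {rho.rho:.3f} (n = {rho.n})")  # Spearman rho = 0.701 (n = 25)
```

The first number turns the urinary recovery of participant 1's triclosan
into an upper bound on systemic absorption (the oral excretion fraction
over-corrects for dermal exposure, so the true dose lies between 35.09 and
64.98 μg/kg-d). The second is the engine's aggregate prediction for that
participant's four MP-containing products at the regulatory maximum
concentration. The third says the conservative aggregate screen still
ranks individuals' exposures moderately well.

A CLI wraps the same functionality:

```sh
aggexpo synthesize --seed 42 --out-dir synth/   # synthetic study with ground truth
aggexpo reconstruct --voids synth/voids.csv --participants participants.csv \
    --profiles synth/diary.csv --out estimates.csv
aggexpo predict --param-source sccs --concentration 0.1% --out predictions.csv
aggexpo evaluate --predictions predictions.csv --estimates estimates.csv --out report.csv
aggexpo reproduce-study --out reproduction_report.csv   # 68/68 checks passed
```

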