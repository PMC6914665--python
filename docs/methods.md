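# Methods

This note documents the models, parameter defaults, numerical conventions
and deliberate design choices behind `aggexpo`. It states nothing the test
suite or `scripts/acceptance.py` does not itself compute.

## Study design and reverse dosimetry

The package is organised around a small observational design: eight
participants, a 6-day window of complete urine collection (every void
timed, its volume measured, all four analytes assayed), 4 days of
personal-care-product use, and a 2-day mid-study intervention with
preservative-free replacement products. The minimum absorbed dose of an
analyte is

    D_min = Σᵢ Cᵢ·Vᵢ / (BW · n_use_days)        [μg/kg-d]

summing concentration × volume over *all* observation days. Mass excreted
on non-use days is carryover from earlier applications, which is why the
divisor is the number of use days (default 4), not observation days
(default 6); both counts are per-participant parameters. Non-detects are
imputed as zero — a policy of the reconstruction, deliberately not of the
I/O layer (void files must mark non-detects explicitly with an `ND`
sentinel; blank cells are a format error).

`D_min` bounds absorption from below because the urinary assay measures
parent compound (free + conjugated) only, missing hydrolysis and
oxidative metabolites. Dividing by the urinary excretion fraction
observed after controlled **oral** dosing gives `D_max = D_min / F_UE`,
an upper bound that over-corrects for dermally dominated exposure (no
first-pass metabolism). Defaults: F_UE = 0.174 (MP), 0.137 (EP),
0.097 (PP), 0.54 (TCS).

Group summaries (users / non-users / all, per ingredient) use the
arithmetic mean and the sample SD (n − 1 denominator); SD is undefined
(NaN) for single-member groups. A participant is a "user" for an
ingredient iff at least one diary product contains it.

## Deterministic exposure engine

Every screening model shares the per-product systemic exposure dose

    SED = A · R · C · D        [μg/kg-d]

with A the application rate normalised to body weight (internally the
engine takes grams of product per day and converts via 10⁶/BW; an
alternative entry point accepts A already normalised), R the retention
factor, C the ingredient mass fraction, and D the dermal absorption
fraction. Toothpaste goes through incidental ingestion instead:
swallowed grams/day × C × oral absorption (100 % by default), with the
swallowed amount specified either as a fraction of product used (5 %
default) or as a fixed mass (0.08 g, the ConsExpo convention; selected
automatically for the `consexpo` parameter source). A participant's
aggregate exposure to an ingredient sums per-product SEDs over exactly
the products they used containing it; a pair with no such product raises
an explicit no-exposure error rather than returning a silent zero.

Inter-model differences are represented purely as *parameter sources* —
per-product daily amounts keyed by source (`sccs`, `consexpo`, `sheds`,
`creme`, `raidar`, `observed`) plus route/retention conventions — not as
separate algorithms, since the tools differ mainly in default values.

Parameter defaults, with provenance:

| parameter | default | status |
|---|---|---|
| dermal D, parabens (all products) | 0.037 | regulatory review value |
| dermal D, TCS deodorant / shower gel / toothpaste | 0.077 / 0.072 / 0.113 | regulatory review values |
| C, maximum scenario (MP, EP / PP / TCS) | 0.004 / 0.0019 / 0.003 | EU regulatory maxima |
| C, typical scenario | 0.001 | literature-typical |
| retention, leave-on products | 1.0 | assumption (convention) |
| retention, rinse-off products | 0.01 | assumption (convention) |
| toothpaste ingested fraction / fixed mass | 0.05 / 0.08 g | model conventions |

Retention factors are not published per product; the leave-on/rinse-off
defaults are conventional values, clearly flagged in the config and
overridable. Absorbed dose is linear in C for every model, so predictions
rescale between concentration scenarios by the ratio `to_C/from_C`;
rescaling is exactly consistent with direct computation (tested).

The **default aggregate preservative scenario** assumes exposure to the
preservative in a full basket of 17 personal care products, making the
prediction identical for every individual at a given body weight. The
published parameterisation behind the corresponding prediction column is
not public; the shipped basket uses regulatory-guidance-style amounts and
retention factors and is a configurable assumption. The published
aggregate-scenario predictions are therefore carried as *fixture data*
for evaluation, never as an engine target.

## Monte-Carlo engine

The Tier-2 engine draws amount, use frequency, retention and body weight
from per-product `DistributionSpec`s (point, lognormal parameterised by
arithmetic mean and geometric SD, uniform, or empirical resampling;
optional truncation), sums per-product SED per iteration, and summarises
sample populations as P05/mean/P95. Conventions:

* quantiles by linear interpolation between order statistics ("type 7") —
  the percentile estimator of the production tools is not documented, so
  one was fixed and stated;
* one seed per run, a single generator stream, draws ordered
  product-major then iteration — sample vectors are bit-reproducible;
* frequency defaults to a point mass of 1/day and exposure is a per-day
  average (no draw-or-skip days), matching how one-day models are run
  with fixed frequency;
* with all inputs degenerate the engine reproduces the deterministic
  value exactly (tested to 10⁻⁹ μg/kg-d).

Default GSD where a spread must be assumed: 2.0, flagged as a non-study
assumption (habits-and-practices data are conventionally right-skewed).

## Evaluation statistics

* **Spearman rank correlation**: Pearson correlation of average ranks
  (ties get the mean of the ranks they span). Constant vectors yield an
  explicitly *undefined* result with a reason code, never a coerced 0.
  The implementation is assembled from rank transforms and checked in the
  tests against an independent library implementation.
* **Factor-of-k agreement** (k_inner = 3, k_outer = 10): a pair with
  ratio r = pred/obs is within factor k iff 1/k ≤ r ≤ k. Boundaries are
  inclusive ("within a factor of k" is read inclusively; the convention
  is stated because it is not standardised). r > 1 is an over-prediction;
  r = 1 counts as within-inner-over. Pairs with non-positive prediction
  or observation are excluded and counted. The six over/under × band
  fractions sum to 1 and the within-k fraction is monotone in k (tested).
* **Percentile placement**: percentile = 100·(#below + ½·#equal)/n — the
  midpoint rule avoids 0/100 artefacts from exact ties. Bin labels follow
  the reporting convention `<5`, numeric interior bins, `90-95`, `>99`.
  Calibration: for observations drawn from the sample distribution the
  placement is uniform (probability integral transform; KS distance
  < 0.03 at n = 5000, tested).
* p-values for rank correlations are not emitted; the published analysis
  reports significance stars only, and reproducing them is out of scope.

## Synthetic-study generator

The generator emulates the observational design with known ground truth:

* one absorbed-dose bolus per product application per use day (default
  use days 1, 2, 5, 6 of a 6-day window — a mid-study two-day
  intervention), magnitudes from the deterministic engine, optional
  multiplicative lognormal jitter;
* absorption as an instantaneous bolus with a fixed lag (default 1 h)
  rather than a first-order absorption phase — the reconstruction needs
  only excreted-mass bookkeeping, and the bolus model has a closed form
  usable as an independent oracle: cumulative excretion of an event of
  size `d` at `t_e` is `F_UE·d·(1 − e^(−k(t − lag − t_e)))` with
  `k = ln 2 / t_half`;
* default half-lives 8 h for all parabens, 11 h for triclosan;
* complete urine collection by default: void times drawn per day (default
  6/day, volumes uniform 0.1–0.4 L — void frequency and volumes are not
  published for the study, so these are stated assumptions), the mass in
  each void being the increment of cumulative excretion since the
  previous void. Summed C·V therefore equals cumulative excretion at the
  last void time *exactly*, for every seed (tested). A
  `collection_fraction` knob simulates missed voids (their mass is lost,
  not deferred);
* every analyte is assayed in every void, as in the study protocol;
  concentrations below the analyte LOD are released as non-detects with
  value 0, the true values retained only in the ground-truth object;
* day d covers hours [24(d−1), 24d); applications default to 08:00.

What passing synthetic tests show — and what they do not: the generator
shares the reconstruction's kinetic assumptions (single first-order
compartment, no circadian urine flow, no metabolite kinetics beyond the
F_UE partition, no inter-product correlation), so recovery tests validate
the *bookkeeping* of the chain, not the physiological realism of the
model. With zero LOD, complete collection and a ≥ 48 h tail after the
last application, the recovered dose satisfies
`recovery ≥ 1 − e^(−k·48 h) > 0.98` at an 8 h half-life, and the bias is
one-sided (reconstruction never exceeds the F_UE-scaled truth); raising
the LOD degrades recovery monotonically. The default problem size for
these checks (8 participants × 25 pairs, 36 voids each) runs in well
under a second.

## Reproduction tolerances

`aggexpo reproduce-study` recomputes the published summary surface from
the packaged per-participant tables and compares at printed precision.
Three classes of cell need documented tolerances:

* **Group means/SDs**: one unit in the last printed digit. Two cells
  (PP users' SD, printed 1.70 vs 1.705 computed; TCS non-users' mean,
  printed 0.01 vs 0.005 computed) indicate the published table averaged
  unrounded per-participant values; both sit within one printed ULP.
* **Maximum doses**: the published column divides *unrounded* minimum
  doses by F_UE, while the packaged inputs are the printed (2 d.p.)
  minimums. The comparison therefore uses the exact rounding-propagation
  bound |calc − printed| ≤ 0.005/F_UE + 0.005, which every one of the 25
  cells satisfies; cells where that bound is tighter than half a printed
  unit reproduce exactly at 2 d.p.
* **Rank correlations**: seven of eleven published coefficients reproduce
  within ±0.01 from the printed prediction columns (including the two
  headline values, 0.701 and 0.649). Four (the QSAR-absorption screening
  column, the probabilistic P05 columns and one probabilistic mean) do
  not — recomputing from printed values gives e.g. 0.473 where 0.378 was
  published — indicating those coefficients were computed on unrounded
  model outputs that are not public. They are checked loosely (±0.05 to
  ±0.10) and noted here rather than silently matched.

Whether the published Spearman row used rounded or unrounded model
outputs is unknowable from the printed record; the ±0.01 tolerance on the
reproducible columns absorbs that ambiguity.

## Known limitations

* The use-profile fixture's product-level entries are partially
  reconstructed: the relevance pattern (which pairs, how many products
  each) is exact, but the identity of the products within a few pairs is
  inferred from narrative constraints (e.g. which pairs are
  toothpaste-only, who used deodorant).
* No creatinine or specific-gravity adjustment of urine concentrations;
  no deconvolution of individual exposure events from concentration–time
  profiles.
* No QSAR-based skin permeability, inhalation route, or spray scenarios;
  the proprietary habits-and-practices databases of the production
  probabilistic tools are not modelled, so comparisons to their published
  percentile columns are qualitative.
* The synthetic generator is not a PBPK model; it partitions absorbed
  mass by F_UE and eliminates first-order, nothing more.
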