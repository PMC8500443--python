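# Methods

## The problem

Crop growth models such as WOFOST simulate winter-wheat development and
yield from daily weather, but their parameter values drift with cultivar,
planting density and fertilisation, so a single regionally "localized"
parameter set misrepresents individual plots. Low-altitude UAV imagery
supplies plot-level leaf area index (LAI) a handful of times per season.
This package implements the assimilation of such LAI observations into a
crop model by parameter optimization: the five parameters to which
simulated LAI is most sensitive — the specific-leaf-area table values
SLATB0, SLATB0.5, SLATB2 (at development stages 0, 0.5 and 2) and the
maximum gross CO₂-assimilation table values AMAXTB1, AMAXTB1.3 (at stages
1 and 1.3) — are re-estimated per plot by bounded least squares against
the observed LAI, and the re-parameterised model is validated on LAI and
yield against the localized baseline.

Because the underlying field campaign data are not public, the package
ships a synthetic twin of the campaign; every claim the tests make is
about this synthetic system.

## Reduced crop model

The simulator is a deliberately reduced WOFOST-style model: daily explicit
Euler integration, state floors at zero, potential production (no water or
nutrient limitation), and the WOFOST state conventions (DVS 0→1→2 =
emergence→anthesis→maturity; organ dry masses in kg ha⁻¹; LAI
dimensionless).

Phenology. Effective temperature `max(0, T − T_base)` with `T_base = 0 °C`
accumulates toward TSUMEM (110 °C·d) before emergence, then DVS advances
at `eff/TSUM1` (680 °C·d) up to anthesis and `eff/TSUM2` (900 °C·d) to
maturity, capped at 2. The rate in force is the one for the current DVS
(no within-day carry-over at the anthesis crossing); at a one-day step the
error is below the model's own resolution. No vernalization or
photoperiod response is modelled.

Carbon budget, per day after emergence while DVS < 2:

* gross assimilation `A = AMAX(DVS) · f_day · (1 − exp(−k·LAI)) · min(1, R/R_ref)`
  in kg CO₂ ha⁻¹ d⁻¹, with `f_day = 12 h` of effective assimilating
  daylight, Beer-law extinction `k = 0.6`, and a light limitation that
  saturates at `R_ref = 10 MJ m⁻² d⁻¹` of global radiation;
* conversion to CH₂O by the molar ratio 30/44; maintenance respiration
  `Q10^((T−25)/10) · Σ c_o · W_o` with coefficients 0.030/0.015/0.010/0.010
  kg CH₂O per kg DM per day for leaf/stem/storage/root and `Q10 = 2`;
* structural growth `CVS · max(0, A_CH₂O − maintenance)` with
  `CVS = 0.70`, partitioned over root/leaf/stem/storage by DVS-indexed
  tables sharing one knot grid (so the fractions sum to one at every DVS);
  leaf investment ends at anthesis, storage fill dominates after it;
* leaf area growth `ΔLAI = SLA(DVS) · ΔW_leaf` (SLA in ha kg⁻¹ against
  mass in kg ha⁻¹, hence dimensionless LAI), and post-anthesis senescence
  at relative rate `rdr_base · max(0, DVS − 1)` with `rdr_base =
  0.025 d⁻¹`, applied to both leaf area and leaf mass;
* stem-reserve remobilisation: after anthesis a fraction
  `stem_trans_rate = 0.012 d⁻¹` of the stem pool transfers to the storage
  organ each day — over a ~50-day grain fill roughly half the anthesis
  stem mass. This mass-conserving flux represents the water-soluble
  carbohydrate reserves that source a substantial share of wheat grain
  fill, and it ties yield to the pre-anthesis canopy that the LAI
  observations actually constrain.

Parameter tables use the AFGEN convention: piecewise-linear in DVS,
clamped to the end values outside the knot range. SLATB has knots at DVS
{0, 0.5, 2} and AMAXTB at {1, 1.3}, exactly the stages named by the five
sensitive parameters; AMAXTB's clamping means AMAXTB1 governs the whole
pre-anthesis canopy. Yield is the storage mass on the maturity date
(kg hm⁻²); the simulation continues to the end of the forcing so that
late observation dates remain inside the trajectory.

The non-sensitive constants live in a versioned default configuration
(`src/cropassim/data/winter_wheat.yaml`), chosen once for realism of the
default season: emergence ~12 days after early-November sowing, anthesis
late March to mid-April, maturity in the second half of May, peak LAI
4–5.5 reached 145–165 days after sowing at DVS ≈ 1, and yields of
6–9 t ha⁻¹. Because dead leaves leave the above-ground bookkeeping, the
apparent harvest index computed against maturity-date biomass is higher
than a field harvest index; this is a bookkeeping artefact of the reduced
model, not a claim about wheat.

## Synthetic twin of the field campaign

Two seasons are emulated with the real campaign calendars: sowing
2015-11-02 with observations on 2016-01-07/03-07/03-27/04-12/05-30, and
sowing 2016-11-14 with observations on 2017-01-06/02-28/03-14/04-24/05-19
— five LAI dates per season, the number assimilated per optimization.
Each season crosses 3 sowing densities (150/225/300 plants m⁻²) with 4
nitrogen doses (0/180/240/300 kg ha⁻¹), 12 treatments.

Weather is a seeded annual sinusoid for a lower-Yangtze climate (mean
15 °C, amplitude 12.5 °C, coldest mid-January) with AR(1) temperature
noise (sd 2 °C, lag-1 correlation 0.7), and seasonal clear-sky radiation
(6.5–19.5 MJ m⁻² d⁻¹) damped by uniform cloudiness up to 60%.

Treatment truth parameters derive from the localized set: nitrogen scales
both AMAXTB knots by a saturating response `0.85 + 0.25·N/(N+120)`
(unfertilised plots assimilate ~15% less; the response flattens above
240 kg ha⁻¹), density scales the emergence LAI proportionally
(reference 225 m⁻²), and the five sensitive parameters get a 4%-CV
log-normal jitter, all clipped into the optimization bounds. These
functional forms are this package's own modelling choices; they are meant
to produce realistic between-treatment spread, not to reproduce any
particular agronomic response curve.

The UAV retrieval step is represented by multiplicative Gaussian noise:
`LAI_UAV = LAI_true · (1 + ε)`, `ε ~ N(0, cv)` with `cv = 0.10` by
default, floored at zero; measured yields carry 5% CV noise. What passing
tests show is therefore that the assimilation machinery works when the
observation operator is unbiased with ~10% noise; real UAV LAI retrievals
can be biased, heteroscedastic and spatially correlated, and none of that
is emulated.

## Assimilation

The cost is the sum of squared differences between simulated and observed
LAI at the observation dates, `F = Σᵢ (LAI_M,i − LAI_UAV,i)²`, minimised
over the five sensitive parameters with all other parameters held at
their localized values, one optimization per treatment and season.

Bounds per parameter are the union of the published initial and optimized
ranges: SLATB0 0.001–0.00212, SLATB0.5 0.0011–0.00215, SLATB2
0.0007–0.0012 ha kg⁻¹, AMAXTB1 35–45 and AMAXTB1.3 30–60 kg CO₂ ha⁻¹ h⁻¹.
Start points are sampled uniformly from the initial-value ranges
(AMAXTB1's single initial value 38.83 is a degenerate range), after a
first cycle warm-started at the localized values — which guarantees the
assimilated cost never exceeds the localized cost. Each cycle runs a
trust-region-reflective bounded least-squares refinement
(`scipy.optimize.least_squares`, finite-difference Jacobian with relative
step 1e−4, variables scaled by bound width, at most 60 trust-region
iterations per cycle).

Search-level bookkeeping and termination are implemented here. A restart
displaces the incumbent only when it improves the cost by at least the
relative tolerance (1e−6, i.e. 0.0001%); the best-so-far cost sequence is
therefore nonincreasing. The search ends when the first of three
conditions fires: (1) no 0.0001% relative improvement over five
consecutive cycles, (2) more than 10 000 cumulative forward-model
evaluations, or (3) all five parameters within 1e−9 of a bound. A hard
cap of `n_restarts` cycles (default 12 in the pipeline) backs these up
and reports as patience convergence.

Tie-break toward the localized values: after the search, each parameter is
returned, one at a time, to its localized value whenever that leaves the
cost unchanged within the same relative tolerance. Five noisy
observations cannot constrain all five parameters everywhere — in
particular, post-anthesis LAI is insensitive to AMAXTB1.3 in this reduced
model — and among (near-)equal-cost optima the solution closest to the
localized prior is the defensible choice. Without this tie-break,
unidentified parameters inherit whatever value the winning restart
happened to sample, which is catastrophic for yield prediction while
invisible in the LAI fit.

A shape check flags (never silently modifies) solutions violating the
agronomic ordering SLATB2 ≤ SLATB0.5 and SLATB2 ≤ SLATB0; policy `warn`
(default) or `reject`.

## Validation statistics

For paired simulated (Y) and measured (X) series: R² about the 1:1 line,
`1 − Σ(Y−X)²/Σ(X−X̄)²`, which measures agreement with the measurements
directly and may be negative (a separate regression-R² helper exists for
scatter plots but is not the headline statistic); CRM `(ΣY−ΣX)/ΣX`,
positive for overestimation; RMSE; and NRMSE `= RMSE/X̄·100%` with
accuracy classes ≤10% extremely high, ≤20% high, ≤30% medium, >30% low
(boundaries belong to the better class). Undefined cases (constant
measured series, non-positive measured mean, zero measured sum) raise
rather than return sentinels.

## Pipeline and problem sizes

The end-to-end synthetic experiment runs two seasons × 12 treatments:
localized simulation, per-treatment assimilation (12 restart cycles),
re-simulation, then pooled validation of LAI (all observation points,
n = 120) and yield (n = 24) for both model variants. One full run takes
about a minute on a single CPU; these sizes were chosen so the whole
experiment, its tests and its reproduction scripts run comfortably at
desk scale while still covering the full factorial twice.

With the default seed the run reproduces the qualitative headline:
assimilation lowers pooled LAI NRMSE from ~28% to ~9% (R² 0.76 → 0.97,
LAI error reduced in 24/24 treatments) and yield NRMSE from ~16% to ~10%
(R² −0.09 → 0.56). The magnitudes differ from a real campaign — the
synthetic observation noise is unbiased and the truth lies inside the
model class, both of which flatter the assimilation — but the structure
of the result (large LAI gain, smaller but consistent yield gain,
localized yield R² near zero because a single parameter set cannot rank
treatments) is the phenomenon of interest.

## Numerical choices and degenerate inputs

* Explicit Euler, one-day step, state floors at zero (death limited to the
  available pool; growth only from positive net assimilate).
* AFGEN lookups clamp outside the knot range; tables require strictly
  ascending DVS knots and non-negative values.
* Weather gaps, non-monotone observation dates, empty observation files,
  out-of-range extraction dates and constant measured series all raise
  typed errors naming the offending input.
* A forcing that ends before maturity raises an incomplete-season error
  carrying the partial trajectory.
* Observation CSVs store floats via shortest round-trip repr and are read
  back with round-trip parsing, so write→read is exact.

## Known limitations

* The crop model is reduced: no photoperiod, vernalization, water or
  nutrient dynamics, sub-daily radiation integration, or CO₂ response.
  Treatment effects exist only through the parameter vector.
* AMAXTB1.3 is structurally unidentifiable from LAI here; its assimilated
  value equals the localized value unless the observations say otherwise.
  Yield improvement from assimilation is correspondingly driven by the
  pre-anthesis parameters and the reserve-remobilisation pathway.
* SLATB and AMAXTB1 are partially confounded in the LAI signal (both
  scale canopy growth); parameter recovery is therefore checked through
  the trajectory, not parameter-by-parameter, at the campaign's n = 5.
* The synthetic twin shares its model class with the assimilation engine;
  real-data performance additionally depends on structural model error
  and retrieval bias that these experiments cannot probe.
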