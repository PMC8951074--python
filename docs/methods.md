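# Methods

`milletswb` is a daily-timestep mechanistic crop growth and soil water
balance model in the SWB (Soil Water Balance) family of generic crop
models, parameterised for three pearl millet (*Pennisetum glaucum*)
varieties, plus the growth-analysis pipeline that derives those
parameters from field observations and a synthetic data generator that
lets everything be tested against known truth. This note documents the
model equations, the assumptions and defaults, the numerical choices and
the limits of what the test suite demonstrates.

## Atmospheric drivers

For each day the model derives three quantities from the raw weather
record (Tmax, Tmin, RHmax, RHmin, Rs, u, P):

- **Reference evapotranspiration (ETo, mm d⁻¹)** — the FAO-56
  Penman–Monteith daily formulation for a grass reference surface:
  albedo 0.23, zero daily soil heat flux, psychrometric constant from
  site-altitude pressure, net longwave from the Stefan–Boltzmann law
  with humidity (0.34 − 0.14·√ea) and cloudiness (1.35·Rs/Rso − 0.35)
  corrections. Rs/Rso is clipped to [0.3, 1.0]; wind measured off the
  standard 2 m is height-adjusted with the FAO log-profile factor; the
  result is clamped at ≥ 0. The implementation is cross-checked in the
  test suite against an independently coded step-by-step FAO-56
  computation on randomized days (agreement to ±0.05 mm d⁻¹).
- **Vapour pressure deficit (VPD, Pa)** — saturation vapour pressure is
  the Tetens form es(T) = 0.611·exp(17.27·T/(T + 237.3)) kPa; daily mean
  es is the arithmetic mean at the temperature extremes; actual vapour
  pressure pairs each extreme with the opposite humidity extreme,
  ea = (es(Tmin)·RHmax + es(Tmax)·RHmin)/200. VPD = es̄ − ea, clamped
  at ≥ 0, reported in Pa (the water-productivity parameter DWR is in
  Pa). The ETo pathway uses the FAO-56 coefficient 0.6108 internally;
  the two constants differ by < 0.05%.
- **Thermal time (GDD, °C d)** — daily mean temperature capped at the
  cutoff (45 °C) minus the base (10 °C); a mean at or below base
  contributes zero. The optimum temperature (33 °C) is stored with each
  variety but does not enter thermal time: the model uses a linear
  base/cutoff response, not a triangular one.

## Soil water: a cascading bucket profile

The profile is an ordered stack of layers (default: five 0.20 m layers
of a sandy clay loam to 1.0 m — the measurement grid of the source
trials). Field capacity 0.27 and wilting point 0.13 m³ m⁻³ are package
defaults chosen as representative of the site's sandy clay loam (the
source reports bulk density 1152–1506 kg m⁻³ but prints no FC/PWP);
every layer is configurable.

Daily order of operations: irrigation is decided from the morning
deficit; rain + irrigation infiltrate the cascade (each layer fills to
field capacity, the excess spills down, water past the bottom layer is
drainage — there is no drainage-rate constant, the profile free-drains
within the day); canopy cover splits ETo into potential soil evaporation
(1 − FI)·ETo and potential transpiration FI·ETo; evaporation is removed
from the top layer only, limited by its plant-available water (no staged
surface-drying curve — a documented simplification); transpiration
demand (capped at the crop maximum, 9 mm d⁻¹) is reduced by the
root-zone supply factor and removed from root-zone layers in proportion
to each layer's available water. The supply factor is
min(1, f/0.30) where f is the root-zone plant-available water fraction:
the tabulated "stress index 0.30" is read as the available-water
fraction below which transpiration falls off linearly, which yields the
conventional stress index SI = 1 − T_act/T_pot ranging 0 (ample) to 1
(maximum stress). Evaporation is taken before transpiration; at daily
resolution the ordering matters only when the top layer nears wilting.

Runoff is carried as an explicit always-zero ledger column (flat,
bunded plots under drip irrigation). The ledger closes
P + I − R − D − E − T = ΔS to 1 × 10⁻⁹ mm every day by construction,
and the state never leaves [PWP, FC] after the cascade-and-extraction
step. Storage change is defined as ΔS = Q_end − Q_start; the packaged
observed weekly table prints the column with the opposite sign, and is
stored as printed.

Irrigation modes: `weekly_refill` and `fortnightly_refill` refill the
assumed 1.0 m root zone to field capacity on their schedule (first
application one interval after sowing by default), `rainfed` never
irrigates, and `daily_refill` is the idealised well-watered treatment
used when generating growth-analysis trials.

## Crop growth

Phenology is thermal-time driven with variety thresholds (°C d from
sowing): emergence (60–64), transition to reproductive allocation
(655–780), flowering (832–1058) and maturity (1480–2124). "Transition"
is interpreted as the vegetative→reproductive partitioning switch
preceding flowering; flowering itself anchors the end of root-fraction
decline and root-depth growth. A stress slow-down of thermal time is
plumbed in but ships disabled (coefficient 0) because no value is
reported for it. Stage transitions are irreversible.

Daily dry-matter production is the minimum of two limits:

- radiation-limited: ΔDM = RUE · FI_RAD · Rs (kg m⁻² d⁻¹), with
  FI_RAD = 1 − exp(−Ks·LAI);
- transpiration-limited: ΔDM = DWR · T_act / max(VPD, 100 Pa), the
  daily form of the VPD-normalised water productivity relation. The
  100 Pa floor prevents blow-up on near-saturated days and only binds
  when VPD is far below the climate the parameters were derived in.

A root share of each increment — root_fraction_initial (default 0.25)
at emergence, declining linearly to zero at flowering — goes below
ground. The tabulated DWR values were already adjusted upward to account
for unmeasured root mass, so root dry matter is tracked but excluded
from all above-ground outputs. During the vegetative phase the shoot
share enters the canopy pool CDM, which is re-split as
LDM = CDM/(1 + p·CDM), SDM = CDM − LDM; during the reproductive phase
it goes to grain (HDM). Whether grain receives the whole post-transition
shoot share or a fraction is not specified in the source; the model
allocates all of it, which makes HDM an upper bound under the given
parameters. LAI = SLA·LDM is restored after every partition step, and
the pools conserve mass exactly: final LDM+SDM+HDM+RDM equals the
emergence mass plus the summed daily increments to 1 × 10⁻⁹ kg m⁻².

At the emergence crossing the seed-reserve mass (0.0019 kg m⁻²) appears
as shoot mass and is split leaf/stem by the same rule. Root depth grows
linearly from 0.05 m at emergence to the 1.0 m maximum at flowering.
Leaf senescence is not modelled: LAI freezes at maturity, so simulated
late-season LAI overstates a real senescing canopy. Plant height,
tillering, nitrogen and frost damage are out of scope.

## Canopy optics

Interception follows the Beer–Bouguer law. Ceptometer measurements give
the PAR coefficient K_PAR; the total-solar coefficient Ks used for both
growth and ET partitioning follows the Campbell–van Evert conversion
K_bd = K_PAR/√a_p, a_s = √(a_p·a_n), Ks = K_bd·√a_s, with leaf
absorptances a_p = 0.8 (PAR) and a_n = 0.2 (NIR), which collapses to
Ks = K_PAR·√0.5. This reproduces the tabulated landrace (0.40 → 0.28)
and improved (0.42 → 0.30) values at two decimals; for the hybrid,
0.43·√0.5 = 0.304 rounds to 0.30 while the table prints 0.31 — the
conversion is kept and the one-digit discrepancy documented rather than
fitted. The published equations print without operators; the form above
is the only reading consistent with "geometric mean of the
absorptances" and with the tabulated values.

## Parameter derivation

All regressions are forced through the origin with the closed form
slope = Σxy/Σx²; the no-intercept coefficient of determination is
r² = 1 − SS_res/Σy² (stated explicitly because r² conventions differ
without an intercept).

- **RUE**: slope of above-ground dry matter on cumulative FI·Rs. The
  known emergence seed mass can be passed as a constant offset and is
  subtracted from the response first; otherwise it acts as a small
  intercept that biases a forced-origin slope.
- **K_PAR**: slope of −ln(1 − FI_PAR) on LAI (the log-linearised
  Beer–Bouguer law); a nonlinear refit is deliberately out of scope.
- **p**: slope of (SLA·CDM/LAI) − 1 on CDM, which the partitioning law
  reduces to p·CDM exactly.
- **SLA**: unweighted seasonal mean of per-sampling leaf-area/leaf-mass
  ratios; zero-mass samplings are skipped with a warning.
- **DWR lower limit**: AGDM·V̄PD/ET at maturity — a lower bound because
  ET exceeds transpiration and AGDM excludes roots. The upward
  calibration of DWR is exposed as `dwr_sweep`, a scalar sweep that
  re-simulates the season per candidate and scores the root-zone
  deficit trace with the Willmott index; it is a sweep, not an
  optimiser.
- **Stage GDD** evaluates cumulative thermal time from sowing at each
  phenology date; **WUE** is yield over ET expressed in kg m⁻³.

## Synthetic data

The weather generator emulates the semi-arid summer season the
parameters come from: daily mean temperature sliding linearly from 26 to
18 °C with ±1.2 °C noise (clipped to the band), a 12 °C diurnal range
compressed 30% on cloudy days, clear-sky radiation 28 MJ m⁻² d⁻¹ scaled
by U(0.75, 1) on clear and U(0.3, 0.7) on cloudy days (cloud probability
0.35), humidity spanning ≈50–93%, and Gamma-distributed wind with mean
2 m s⁻¹. These defaults put the seasonal mean VPD at ≈0.8 kPa, matching
the reported 0.78–0.83 kPa. Rain falls on Bernoulli(0.28) days; the
season total is drawn from U(350, 600) mm and distributed over rain days
with Gamma(0.8) weights — conditioning on the total is standard
weather-generator practice and keeps every season inside a realistic
300–700 mm band, emulating the observed 334–542 mm (without/with the
extreme event). A ~208 mm three-day storm can be injected on demand
(`big_event_day`) on top of the conditioned total. Generators are pure
functions of (spec, seed).

Growth trials run the forward model under `daily_refill` (ample water,
so growth stays radiation-limited as in the well-watered calibration
plots), sample the state fortnightly, and perturb masses and areas with
independent multiplicative lognormal factors of unit mean (destructive-
harvest errors scale with magnitude); FI_PAR is perturbed on the logit
scale and clamped to (0, 1); CDM is the sum of the noised leaf and stem
masses so the additivity invariant survives noising. Trial truths
default to shoot-only allocation (root fraction 0) because the derived
parameters are defined on above-ground mass. What passing tests show:
the pipeline inverts the forward model exactly without noise and stays
within a few percent at 5% noise. What they do not show: robustness to
the structure of real measurement error (serial correlation, sampling-
area heterogeneity, senescent-leaf loss), which no synthetic trial here
emulates.

## Numerical choices and degenerate inputs

Tolerances: water closure and dry-matter conservation are asserted at
1 × 10⁻⁹ (mm, kg m⁻²); interception is capped at the largest double
below 1 to keep FI ∈ [0, 1) under exponent underflow; a negative ET
from the measured balance is returned with a warning (instrument noise),
whereas impossible inputs (humidity outside [0, 100], below-canopy PAR
above the reference, dates with gaps) raise typed errors; a below-canopy
reading above the reference can instead be clamped explicitly. The
Willmott index returns 1 by convention when both series are identical
constants; the MAE is normalised by the observed mean and reported in
percent (the other plausible reading — absolute mm — is not used).
Missing weather fields fail loudly; there is no imputation.

Default problem sizes are one 130-day season (the observed season is
~122 days; the late landrace needs ≈180–210 days of the default climate
to reach its 2124 °C d maturity and tests use a 210-day season for
that), fortnightly sampling (9–10 samplings per trial), and 200
Monte-Carlo replicates for noisy-recovery checks; a full season
simulates in well under a second.

## Known limitations

No Richards-equation flow, capillary rise, water table or salinity; no
runoff generation; no canopy senescence, tillering, nitrogen, frost or
photoperiod response; single seasonal SLA (the source itself notes a
declining SLA through the season); evaporation from the top layer
without a two-stage drying curve; irrigation decisions only by calendar
refill-to-capacity. The printed seasonal water-input totals for the
improved and hybrid varieties are not fully consistent with their weekly
ledgers in the source; the seasonal table is taken as authoritative for
fixtures, and only the landrace season closes exactly by construction.
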