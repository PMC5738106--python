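# Methods

`midasim` is a computational twin of a dynamic infant *in vitro* digestion
protocol: a 45-ml liquid feed passes an oral hold, a fed-batch gastric phase
and a pulse-fed intestinal phase, with 21 analytical samples withdrawn along
the way.  This note records the model, its parameters, the calibration of
the shipped presets, the numerical choices, and what the synthetic data can
and cannot say about real measurements.

## Protocol model

**50:50 mixing and volume bookkeeping.**  Each compartment's simulated fluid
(SSF, SGF, SIF) is prepared to match the volume arriving from the previous
compartment *after* sampling withdrawals (`protocol.plan_fluid_volumes`).
For the standard plan — one 10-ml oral bolus frozen for analysis, eight
10-ml gastric samples — a 45-ml portion needs 45 ml SSF, 80 ml SGF and 80 ml
SIF, ending in 160 ml of chyle.  Without sampling, the stream doubles at
each stage (2·V into the stomach, 4·V of gastric content, 8·V of chyle).

**Timeline.**  t = 0–2 min: the portion is mixed 50:50 with SSF and held at
37 °C (nine 10-ml boluses in the physical rig).  t = 2–16 min: every 2 min
one 10-ml bolus plus 10 ml of SGF enters the stomach (eight feeds).  Gastric
phase ends at t = 122 min, with samples every 15 min (t = 17 … 122).  From
t = 122 the pylorus delivers chyme per the emptying schedule, each pulse
matched by an equal SIF volume; intestinal samples every 15 min
(t = 137 … 242) and three drain samples (t = 244, 246, 248).  Events at
equal timestamps execute inflows before withdrawals.

**Fluid recipes and enzyme doses.**  The electrolyte-stock compositions and
per-food fluid make-ups are versioned JSON data fixtures
(`midasim/data/*.json`), not code, so other INFOGEST-style recipes can be
swapped in.  pH-adjustment volumes (HCl/NaHCO₃) are tabulated per food class
because they come from pre-digestion titration tests, not buffer chemistry.
Target enzyme activities are defined per ml of *final compartment content*
(twice the fluid volume under 50:50 mixing); `protocol.enzyme_stock_amount`
converts them to stock amounts using the stock activities (α-amylase
10 000 U/ml; pepsin 3 850 U/mg, the midpoint of the 3 200–4 500 U/mg stock
specification; glucoamylase 1 300 U/g; pancrelipase 10 000 lipase U per
150-mg capsule).  Pancrelipase is dosed at 1 000 lipase U/kg per meal with
amylase and protease scaled by the capsule ratio; for the reference 7.695-kg
infant this gives 7 695 lipase U, 6 156 amylase U and 461.7 protease U.  The
original protocol prints 770 protease U, which contradicts its own capsule
composition (600 : 10 000); both numbers are exposed
(`REPORTED_PROTEASE_UNITS`) and the capsule ratio is always applied.

## Gastric emptying

The fraction of chyme remaining follows the power-exponential curve
`y(t) = 2^−(t/T½)^β`; y(0) = 1 and y(T½) = ½ for any shape β.  Defaults:
β = 1.5 (infant feeds), T½ = 2.14 min (rice-starch feeds) or 3.17 min
(rice-cream feeds), emptying horizons 20 and 28 min.  The half-time can in
principle be estimated from portion volume and caloric density via a linear
form `T½ = a·V₀ − b·K` (a = 0.1797, b = 0.1670), but the published
correlation this parameterizes is typographically ambiguous in its source
and does not reproduce the published half-times; the named constants (or a
directly measured half-time) are therefore preferred.

The curve is discretized at 4 pulses/min into piecewise-constant per-pulse
volumes over the published interval grid: each interval's per-pulse volume
is its average emptied volume, and the remainder the curve would leave past
the horizon, `V·y(horizon)`, is folded into the final interval so the
schedule total equals the gastric volume exactly.  The published per-pulse
tables are also shipped verbatim (`load_schedule_fixture`); they are **not**
reproduced by the model with the published half-times (first-interval
fraction ≈ 0.62 tabulated vs ≈ 0.47 modelled), an inconsistency internal to
the source protocol.  The two schedule sources are therefore never asserted
equal; the model-derived schedule is the default (it conserves exactly the
80 ml available after gastric sampling, whereas the rice-cream fixture
totals 80.256 ml and is clipped at the available volume when used).

## Digestion kinetics

Starch hydrolysis is first order per compartment:

    dS/dt = −k_c · S,      dG/dt = +(1/0.9) · k_c · S

with `k_oral`, `k_gastric` (default 0) and `k_intestinal` in min⁻¹.  The
1/0.9 yield is the water gained on hydrolysis (0.9 g of anhydroglucose per
gram of free glucose).  Salivary amylase acts only during the 2-min oral
hold: queued boluses are modelled as identical to the sampled one, and
amylase is inactivated by gastric acid on entry, which with `k_gastric = 0`
makes the gastric starch trend exactly flat.  Fermented foods carry a
non-starch glucogenic pool (maltodextrins etc.) that converts to glucose in
the intestinal compartment at `glucogenic_rate` (default: equal to
`k_intestinal`); this is what lets %SH exceed 100 %.

Because the kinetics are linear, the state between events has a closed form
and the simulator is exact — no ODE integrator, no step-size error.  An
independent fixed-step RK4 integrator (0.01-min step) exists in the test
suite as an oracle; the event-driven simulator is required to agree with it
to 0.1 % on random parameter draws.

Compartments are well mixed; withdrawals remove concentration-proportional
mass.  Records carry the withdrawn 10-ml aliquot's masses by default;
`simulate(..., sample_basis="compartment")` switches to whole-compartment
masses.

## Preset calibration

The four presets carry their measured t = 0 masses per 10-ml aliquot of
prepared food (basic rice cream: 1.309 g starch, 0.004 g glucose; premium:
0.411 g and 0.009 g; classical/HTST rice starch glucose: 0.036/0.007 g).
The rice-starch baselines (0.112 g classical, 0.136 g HTST) are inferred
from the reported oral masses and conversions, since they were not reported
directly.  The kinetic constants are **calibrated, not measured**:

* `k_oral` solves the oral-conversion endpoint analytically,
  `k = ln(0.5·S₀/m_oral)/2` for the 50:50 bolus held 2 min — endpoints
  75.78 % (basic), 50.85 % (premium), 71.43 % (classical), 87.5 % (HTST);
* `k_intestinal` is root-found on the full simulate→metrics loop
  (`synthetic.calibrate_intestinal_rate`) against one intestinal conversion
  endpoint per food: 98.29 % at t = 137 for the premium food and 99.69 % at
  t = 248 for the basic food.  The rice-starch feeds have no reported
  intestinal conversion; their 0.10 min⁻¹ default gives near-complete
  digestion by ~170 min, matching the reported completion window.

One endpoint per rate is used because a single first-order intestinal rate
cannot satisfy two independent intestinal endpoints, and because the
reported intestinal *masses* are larger than strict dilution bookkeeping
allows for a 10-ml aliquot (two further 50:50 dilutions after the oral
sample bound the aliquot mass from above).  For the same reason the reported
glucose trajectories are wet-lab outcomes that the mass balance does not
reproduce and are not calibration targets.  The premium glucogenic pool is
set to 0.898 g — the food's t = 0 starch deficit relative to the unfermented
food, i.e. the starch the fermentation converted to soluble saccharides —
rather than fitted.

## Synthetic data

`generate_experiment` runs the deterministic simulator once and applies
independent multiplicative log-normal noise per record and replicate
(default CV = 0.10, a stand-in: the source experiments report scatter only
graphically), truncating values below the detection floor (default 0.001 g;
applied only when CV > 0 so that CV = 0 is a bit-identical passthrough).
Replicate streams are spawned from a single seed via `numpy`
`SeedSequence.spawn`, so a (design, seed) pair fully determines the output.

The generator emulates the measurement *structure* of the real experiments —
21 samples per run, triplicates, flat gastric trend, oral and intestinal
decay, positive masses spanning two orders of magnitude.  It does not
emulate assay chemistry (GOPOD absorbances, dilution series, ethanol
precipitation), inter-day drift, pH dynamics, enzyme-activity decay, or the
aliquot-basis inconsistencies of real reported masses discussed above.
Passing tests on synthetic data therefore validate the bookkeeping, the
kinetic model and the estimators — not the wet-lab accuracy of any
particular published mass.

## Numerical and interface choices

* Time is continuous minutes; schedule intervals are half-open [start, end).
* Group comparisons use the two-sided equal-variance Student t-test on
  replicate values (Welch behind `equal_var=False`); degenerate
  zero-variance groups are flagged, with identical groups reporting
  t = 0, p = 1 and separated ones p at the machine-eps floor.
* Negative released glucose and conversions outside [0, 100] are preserved
  with warnings, never clipped — they diagnose assay noise, and >100 % %SH
  is a real phenomenon for fermented foods.
* Initial-starch conventions are explicit (`at_dissolution` — the t = 0
  baseline record, the convention for cream-based foods; `pre_treatment` /
  `explicit` — a supplied value, the convention for plain starch foods
  measured before sterilization).
* Rate fitting (`fit_first_order_kinetics`) is a least-squares line through
  log starch concentration vs time; for intestinal data pass a window
  starting after pyloric inflow ends (t ≥ 150 for rice-cream runs) so the
  decay is purely first order.  Confidence intervals are percentile
  bootstraps over replicates.
* CSV artifacts are UTF-8, dot-decimal; readers normalize comma-decimal
  text columns on ingest.  Pipeline manifests carry SHA-256 hashes of every
  artifact, so hashes change exactly when an input or seed changes.
* Problem sizes throughout tests and examples are the protocol's own: 45-ml
  portions, 21 samples, triplicates; Monte-Carlo checks use 100 noise
  repetitions (rate recovery) and 10 000 null pairs (t-test calibration).

## Known limitations

* No pH dynamics, enzyme-activity-vs-pH curves, protein/lipid digestion
  state, absorption, or fluid mechanics; pepsin and pancrelipase affect
  recipes only, not the simulated state.
* The glucogenic pool converts only intestinally; oral glucose release of
  fermented foods is therefore under-predicted relative to measurements,
  where fermentation saccharides evidently release glucose already in the
  oral phase.
* The emptying horizons (20/28 min) are configuration constants; no stopping
  rule derives them from the curve.
* `half_time_from_food` implements a linear form whose published source is
  corrupted; treat it as a convenience with named-constant override, not a
  validated correlation.
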