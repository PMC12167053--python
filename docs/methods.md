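# Methods

This note documents the models implemented in `aavprocess`, their
assumptions, the defaults that matter, and what the synthetic generators do
and do not emulate.

## Cost-of-goods and scheduling model

The engine is a deterministic, spreadsheet-style model. Its scope is a
single fixed facility producing one batch of a requested post-downstream
output; there is no demand uncertainty, contamination-loss modelling,
currency handling, amortization or NPV.

**Unit sizing.** `required_units(T, y, r) = min{n : n·y·r ≥ T}` with
per-unit crude yield `y` and a single compounded downstream recovery `r`
applied end to end (default 0.30 from harvested lysate to formulated drug
product). Recovery is deliberately not decomposed per unit operation in the
cost engine; the mass-balance module handles per-step recoveries where data
exist.

**Packing.** A production is a set of units run concurrently; a batch is a
sequence of productions run back-to-back, so calendar days multiply with
the production count. Each production must satisfy, simultaneously:

- *area*: `n·footprint + MSCs·msc_footprint + incubators·incubator_footprint
  + operators·2.0 m² ≤ 60 m²` (all defaults configurable);
- *MSC throughput*: flask platforms occupy `ceil(n/6)` cabinets, capped at
  3. A closed system (`units_per_msc_session = 0`) occupies one cabinet for
  sterile preparation regardless of unit count;
- *staffing*: 2 operators per occupied MSC, or — for platforms operated as
  crewed systems — one 2-operator crew per `systems_per_operator_pair`
  units (default 10 for the hollow-fiber system).

Every resource requirement is non-decreasing in `n`, so feasibility is
monotone and the greedy rule "take the largest feasible unit count each
production" provably minimizes the production count (verified against an
exhaustive dynamic-programming oracle for all scenarios up to 30 units in
the test suite). With the reference scenario these rules bind as follows:
flask productions cap at 18 units (MSC-bound), hollow-fiber productions at
55 systems (area-bound), so the whole 10¹⁴–10¹⁵ vg sweep fits in one
hollow-fiber production.

**Costing.** Materials with a `per_unit` basis scale with the total unit
count; `per_batch` items are incurred once per production (a zero-unit
plan still pays its batch-level terms once). Labor is step duration ×
step operators × rate per production, with no idle-time discounting.
Facility cost is calendar days × day rate. QC samples pool batch-wide and
pay whole plates (ceiling division — a partial plate costs a full plate).
Open steps count per-unit manipulations × units plus per-batch
manipulations per production; closed-system welds count zero, so the
counts live entirely in the scenario file.

**Fold changes.** All comparisons divide a platform's metric by the
reference platform's at the same target. Ratios cancel any global price
rescaling, which is why the shipped catalog can be (and is) a fixture:
the original price inputs behind absolute cost magnitudes are not public.
Only orderings and the reference-vs-reference ≡ 1 identity are asserted.
"Production time" is reported as calendar days (headline) with operator
hours alongside, and facility usage as peak concurrent area.

## Reference scenario

Platform yields (6.81 × 10¹³ / 1.26 × 10¹⁴ / 2.45 × 10¹³ vg per unit),
the 30% downstream recovery, the 60 m² facility, 2.0 m² per operator,
6 flask units per MSC with at most 3 cabinets, one flask unit per 168 L
incubator, and the 10-systems-per-2-operators/1-MSC hollow-fiber setup are
the study's stated operating assumptions. Everything priced — the catalog,
step-level material quantities, labor hours, MSC and incubator footprints
(2.5 and 0.7 m²), the operator rate (150/h) and facility day rate (800/day)
— is a FIXTURE chosen once as round, realistic-looking values in which
labor and facility dominate materials, the qualitative regime consistent
with a persistent flask penalty across the sweep. The flask schedule spans
14 days (expansion train, stack seeding, feeds, transfection, harvest);
the hollow-fiber schedule spans 8 days (seed, 3-day expansion,
transfection, 3-day production, harvest + in situ lysis). One stated
staffing inconsistency in the source assumptions (5 operators for a 6-unit
flask batch vs 2 GMP operators per MSC) is resolved in favour of the
per-MSC scheduling rule.

## Mass balance

All operations are closed-form arithmetic. Reporting mirrors field
convention: integer percent for particle ratios and clearances, one
decimal for fold equivalences; raw values are always retained. Recoveries
above 100% are flagged, not rejected — assay noise produces them (the
observed clarification range extends to 104%). Impurity increases return a
flagged negative clearance. Vendor-nominal flask surface areas
(CS10 6,360 cm²; HS36 18,000 cm²) ship as constants marked as manufacturer
data. Note that the two engineering-run DNA clearances compute to 88.9%
and 88.3%; the integer reporting variant therefore returns 89 and 88.

## Lysis DoE and response surfaces

A face-centred central composite design over `k` factors has `2^k`
factorial rows at ±1, `2k` axial rows on the cube faces, and `n_center`
center replicates (default 3 — replication in the original study is not
reported, so this is an explicit package default). Fitting is ordinary
least squares on the full quadratic (1 + 2k + k(k−1)/2 terms) in coded
units for conditioning; statsmodels supplies the OLS machinery and the
model F-test. Dilution factors multiply responses before fitting
(per-row factors supported, as assay dilution varies with cell density).
Constant responses yield a flat model reported with R² = 0 and p = 1.
Rank-deficient designs raise an error naming the unestimable terms.

The bounded optimizer is exact, not iterative: the maximizer of a
quadratic on `[-1, 1]^k` lies at an interior stationary point or on a
face, so all `3^k` pin patterns (each coordinate at −1, +1 or free) are
enumerated and each restricted stationary system solved directly. The
test suite checks it against an exhaustive 0.001-resolution grid
(k = 2; 4 × 10⁶ points) and a coarser k = 3 grid. Maximization is the
default objective since the response is recovered titer.

## Perfusion growth estimation

The bioreactor is modelled as one well-mixed volume `V` (default 1.5 L)
with perfusion rate `Q(t)` and feed concentration `C_feed`:

    V dC/dt = N(t)·q − Q(t)·(C − C_feed)

per analyte, with constant specific rates `q` (pmol/cell/day): glucose −3,
lactate +4, glutamine −0.35, ammonium +0.3 — literature-typical HEK293
values shipped as overridable defaults, not study data. Feed levels default
to 25 mM glucose, 2 mM glutamine, 0 lactate/ammonium. The simulator
integrates this balance as an explicit daily difference equation with
non-negativity clamping, then adds Gaussian measurement noise last.

The cell estimator inverts the lactate balance per sampling interval:
`N_i = [V·ΔC/Δt + Q_i·(C_i − C_feed)] / q_lac`, floored at zero. Forward
(interval) differences are the default because they are the exact inverse
of the simulator's explicit step, making the noise-free round trip exact
at any sampling rate; centered differences are available but leak washout
error of several percent at daily sampling with realistic perfusion, so
they are not the default. The estimator is linear in `1/q_lac`, so an
incorrect assumed rate rescales, never reshapes, the curve. Missing days
simply lengthen an interval (the difference quotient spans it). This
reconstruction is a package modelling choice — the bioreactor vendor's
proprietary prediction tool has an unpublished functional form, so
absolute agreement with it cannot be claimed beyond the plateau property.

The synthetic growth generator uses a logistic curve (seed 4 × 10⁷ cells,
plateau 5 × 10⁹, rate 1.2/day) whose inflection falls at day 4, echoing
the described mid-run acceleration of glucose uptake; perfusion ramps
300 → 1200 mL/day and then holds, which keeps late-run lactate and
ammonium monotone as observed. The generator does not emulate assay
dropouts, intracapillary/extracapillary compartment gradients, or
substrate-limited growth feedback.

## Numerical choices

- `required_units` guards its ceiling against float round-up so exact
  multiples `n·y·r` return exactly `n`.
- Same-day schedule steps keep insertion order (stable sort) for
  reproducible reports.
- All randomness flows through `numpy.random.default_rng(seed)`; every
  stochastic generator requires a seed.
- Scientific notation in machine outputs is `%.6g`; human-facing tables
  round to 3 significant figures.

## Problem sizes

The shipped tests and the acceptance script run at the study's own scale:
5-point output sweeps over 10¹⁴–10¹⁵ vg, 17-row three-factor designs,
50-seed noise ladders, 20-quadratic optimizer checks, 9-day growth runs,
and exhaustive packing checks to 30 units.

## Known limitations

- Absolute cost magnitudes are fixture-dependent by construction; only
  fold-change structure is meaningful.
- Productions are strictly sequential; parallel suites or overlapping
  schedules are out of scope.
- No depth-filter or TFF hydraulics (pressure/flux curves are handled as
  data, not models), and no assay error models.
- The growth balance assumes a single homogeneous compartment and
  constant specific rates; metabolic shifts would bias the estimate.
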