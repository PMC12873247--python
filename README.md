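# paleochron

Bayesian radiocarbon chronologies for fossil collection units: calibrate
geochronological dates against an IntCal-style curve, fit a uniform
phase/sequence model per collection unit by MCMC, extract the two chronology
types ("event" and "bounds"), infer age ranges for undated analysis units
from stratigraphic relationships, and write Neotoma-schema chronology tables.

All ages are in cal BP (calendar years before 1950 CE); quantiles follow the
*from-old* convention (the q-quantile has probability mass q on its old
side), which is what makes `agelimitolder >= age >= agelimityounger` hold in
every output row.

## Layout

| module | purpose |
| --- | --- |
| `paleochron.calibration` | `.14c` curve parsing, two-piece-Gaussian calibration, calendar-date densities, quantiles, chron-control summaries |
| `paleochron.phase_model` | phase/sequence model, Gibbs sampler, split R-hat / ESS diagnostics |
| `paleochron.chronology_builder` | event/bounds sample ages, collection age bounds, time-interval bins |
| `paleochron.strat_inference` | rules a-f for undated analysis units |
| `paleochron.neotoma_io` | collection fixtures (JSON/CSV), optional API client, date filters, chronology-table writers, OxCal script emission |
| `paleochron.synthetic_data` | synthetic curves and collections with known ground truth |
| `paleochron.pipeline` | end-to-end `build_collection_chronologies` |

Bundled data: `data/intcal20.14c` (IntCal20 Northern Hemisphere curve,
Reimer et al. 2020) and `data/selby_cu4417.json`, a worked-example fixture
(Neotoma collection unit 4417, site "Selby"; raw 14C ages reconstructed by
inverting the published calibrated control quantiles against IntCal20 —
SI-2877 matches its published 11,710 +/- 150 14C BP).

## Model

Each dated analysis unit is a phase: its events are i.i.d. uniform between
unknown boundaries (beta, alpha), giving likelihood `(alpha - beta)^-n`; a
configurable span-prior exponent `e` adds `(alpha - beta)^+e` (default
`e = n - 1`, a uniform implied span prior; values `<= -1` are rejected as
improper). Collections with a clear stratigraphic order (declared order or
distinct depths) become an ordered sequence with per-draw boundary
monotonicity; otherwise phases are independent. An optional
`overall_span_exponent` couples phases through a
`(max alpha - min beta)^-kappa` factor. Sampling is Metropolis-within-Gibbs:
inverse-CDF draws for events on the restricted calibration grid, analytic
truncated power-law conditionals for boundaries, and a uniform predictive
("new event") draw per kept iteration that underlies the event chronology.

The reference implementation this emulates (OxCal v4.4) does not document
its exact phase-span prior; the worked example is reproduced approximately
(hundreds of years on boundary medians), and the acceptance suite records
the deviations explicitly rather than hiding them.

## CLI

```sh
# calibrate one date (bundled IntCal20 or any .14c file)
paleochron calibrate --curve intcal20 --age 11710 --error 150

# fit a collection (JSON/CSV fixture or neotoma:<siteid>) and write tables
paleochron model --input cu.json --curve intcal20 --seed 1 --iters 25000 --out tables/

# simulate a synthetic collection with known truth
paleochron simulate --out sim.json --truth-out truth.json --seed 1
```

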