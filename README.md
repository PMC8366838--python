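# fjordtrace

Movement ecology and trophic niche analysis for sympatric Atlantic cod
(*Gadus morhua*) ecotypes in an instrumented fjord — and a synthetic-study
generator that makes the whole chain testable without any field data.

Coastal Skagerrak fjords hold two genetically distinct cod ecotypes: a
resident **Fjord** form and an oceanic **North Sea** form. Telling their
ecologies apart requires stitching together three data streams on the same
individuals: SNP-based ecotype assignment, acoustic telemetry from a
receiver array, and stable-isotope chemistry of muscle tissue. This package
implements that full chain for researchers working with such designs:

* **Genetics** — GENEPOP I/O and Bayesian individual assignment
  (Rannala–Mountain posterior-predictive likelihoods with a symmetric
  Dirichlet(1/k) prior), with the field-standard >80% score and ≥20-loci
  filters.
* **Telemetry** — detection-count-weighted 30-min position averages
  (Position_i = Σ_r count_r·coords_r / Σ_r count_r), along-axis distance to
  the fjord outlet, per-fish fate classification from the outer receiver
  gate (resident / short excursion / prolonged departure with return /
  permanent departure / lost), and gate-order QC.
* **Home ranges** — 95% minimum convex polygons (centroid peeling, monotone
  chain hull, shoelace area in hectares).
* **Isotope lab** — linear drift correction of δ15N/δ13C run sheets against
  interleaved Gel-A standards (5.4‰ / −21.8‰), duplicate averaging.
* **Niche metrics** — distance-residualized bivariate niches: standard
  ellipse areas SEA = π√det(S) and SEAc = SEA·(n−1)/(n−2), convex hull
  total areas, and SEAc-ellipse overlaps in ‰².
* **Models** — Gaussian GLMs with interaction dropping, VIF, Pearson tests,
  and a gamma random-intercept GLMM with log link fitted by Laplace maximum
  likelihood (statsmodels-style `Model.fit() → Results.summary()`).
* **Simulator** — mean-reverting movement tracks, logistic distance-decay
  detections from 30–90 s transmissions, Hardy–Weinberg genotypes with a
  configurable allele-frequency differential, and drifting isotope run
  sheets, all seeded and bit-reproducible.

See `docs/methods.md` for the models, their assumptions, and the defaults.

## Worked example

Simulate a compact study (24 fish, March–December, array deployed
May–November) and run the full pipeline:

```python
import datetime as dt
from fjordtrace import RunConfig, SimulationConfig
from fjordtrace.pipeline import run_pipeline

UTC = dt.timezone.utc
sim = SimulationConfig(
    n_fish=24, seed=11,
    transmit_interval_s=(240.0, 720.0),
    study_start=dt.datetime(2017, 3, 1, tzinfo=UTC),
    study_end=dt.datetime(2017, 12, 1, tzinfo=UTC),
    array_start=dt.datetime(2017, 5, 1, tzinfo=UTC),
    array_end=dt.datetime(2017, 11, 30, tzinfo=UTC),
)
outputs = run_pipeline(RunConfig(out_dir="demo", simulation=sim, seed=11))
```

The run directory then holds assignments, positions, fates, home ranges,
corrected isotopes, niche metrics, and model tables. The summaries print:

```
ecotype  n  departed  departed_pct  departed_permanent  departed_permanent_pct  ...
     FJ 15         0             0                   0                       0
     NS  9         3            33                   2                      22

 n  mean_ha  sd_ha  median_ha  min_ha  max_ha
23     4.96   6.67       1.28     0.0   21.43

 group  n   sea  seac  hull_area  pooled_ta_ratio
    FJ 15 0.920 0.991      2.615             1.08
    NS  8 0.651 0.760      1.176             2.40
pooled 23 0.995 1.043      2.825             1.00
```

Reading this: 3 of the 9 North Sea fish left the fjord (two permanently,
one returning after a prolonged absence) while no Fjord fish did — the
simulated ecotype-specific emigration showing through the detection and
classification chain. Home ranges are hectare-scale and right-skewed
(median 1.3 ha, max 21.4 ha), with zero-area entries for fish pinned to a
single receiver. The isotopic niche table gives standard ellipse areas near
1 ‰² per ecotype, a pooled hull 1.08–2.40× the group hulls, and an
FJ–NS ellipse overlap of 0.129 ‰² (in `overlap.csv`) — the two ecotypes
occupy mostly distinct regions of isotope space even after removing the
shared along-fjord baseline gradient.

The same stages are scriptable from a shell:

```bash
fjordtrace simulate --out inputs/ --seed 11
fjordtrace assign --genepop inputs/genotypes.gen --out assignments.csv
fjordtrace telemetry --detections inputs/detections.csv \
                     --receivers inputs/receivers.csv --out telemetry/
fjordtrace run --config run.toml
```

## Fitting the residence model directly

```python
from fjordtrace.models import GammaRandomInterceptModel

model = GammaRandomInterceptModel.from_dataframe(
    daily, response="distance_km",
    terms=["is_ns", "time_days", "is_ns:time_days"], group="tag_id",
)
print(model.fit().summary())
```

gives estimates, Wald z tests, the gamma shape, and the random-intercept
standard deviation for daily distance-to-outlet trajectories.

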