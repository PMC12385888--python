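# dietrisk

Deterministic and probabilistic dietary risk assessment of pesticide
residues in food, built around the chlorpyrifos (CPF) exposure
assessment for tomato and cucumber consumers in Armenia.

The package is aimed at food-safety and exposure-assessment scientists
who need the full chain from raw monitoring data to risk
characterisation as tested, scriptable code: summarising left-censored
residue surveys, turning food-frequency-questionnaire (FFQ) answers
into chronic and acute intakes, computing the point-estimate risk
metrics, and propagating input variability by Monte Carlo simulation
with a sensitivity ranking of the inputs.

## The model

For a residue concentration *C*<sub>content</sub> (mg/kg), a
consumption *C*<sub>food</sub> (kg/day for chronic, kg/occasion for
acute) and body weight *BW* (kg):

- **EDI** = *C*<sub>content</sub> × *C*<sub>food</sub> / *BW* — estimated
  daily intake, mg/kg bw/day;
- **MOE** = HBGV / EDI — chronic margin of exposure against a
  health-based guidance value (here the developmental-neurotoxicity
  LOAEL of 0.3 mg/kg bw/day); MOE < 300 flags a potential concern,
  300–1000 a possible concern;
- **HQ** = EDI / ARfD — acute hazard quotient against the acute
  reference dose (the artificially low 1 × 10⁻⁴ mg/kg bw/day adopted in
  2020; the pre-2020 value 0.005 is available as a scenario);
  HQ < 1 means no acute concern;
- **HI** = ΣHQ and **ΣMOE** = HBGV / ΣEDI for cumulative risk over
  commodities.

Samples below the limit of detection are handled by substitution
(lower/middle/upper bound: 0, LOD/2, LOD), with the default summary
taken over detected values only. The Monte Carlo engine samples
consumption and residue inputs from bounded fitted distributions
(triangular, Beta-PERT, beta-general, point), computes the metric per
iteration, and summarises the output distribution (mean, median,
half-sample mode, 90% CI of the mean, P50/P75/P90/P95, min, max, SD);
Spearman rank correlations of inputs with the output give the
sensitivity ranking.

Because the individual-level survey data are not public, the
`dietrisk.synthetic` module generates residue surveys and FFQ
populations calibrated to the published marginals (survey sizes,
detection rates, detected concentration range, and the consumption
levels implied by the published mean EDIs), so the whole pipeline runs
and is testable end to end.

## Worked example

```python
import dietrisk as dr

scenario = dr.paper_like_scenario(seed=1)
samples = [s for i, com in enumerate(sorted(scenario.commodities))
           for s in dr.generate_residue_survey(scenario, com, seed=i)]
records = dr.generate_ffq_population(scenario)
result = dr.assess(samples, records)

print(result.residue_table[["commodity", "n_samples", "nd_fraction", "mean", "max"]])
print(f"cumulative chronic MOE: {result.cumulative_moe():,.0f}")
print(f"hazard index (acute):   {result.hazard_index():.2f}")

sim = dr.simulate(result, samples)
print(f"simulated HI: mean {sim.results['hi'].summary.mean:.2f}, "
      f"p95 {sim.results['hi'].summary.p95:.2f}")
print("top HI sensitivity:", sim.sensitivities["hi"][0])
```

prints

```
  commodity  n_samples  nd_fraction   mean    max
0  cucumber         14     0.714286  0.003  0.005
1    tomato         20     0.850000  0.003  0.003
cumulative chronic MOE: 15,371
hazard index (acute):   0.24
simulated HI: mean 0.24, p95 0.39
top HI sensitivity: ('tomato consumption', 0.83827899851479)
```

Reading the numbers: chlorpyrifos was detected in 15% of tomato and
28.6% of cucumber samples at a detected mean of 0.003 mg/kg. The
cumulative chronic margin of exposure of ~1.5 × 10⁴ is far above the
concern level of 300, and the acute hazard index of 0.24 is well below
1 — no health concern for the average adult consumer, although the
combined consumption of the two vegetables already uses about a quarter
of the acute safety margin. The sensitivity ranking shows the risk
estimates are driven by consumption rates rather than residue levels.

The same run is available from the shell:

```bash
dietrisk generate --out data --seed 1
dietrisk report --residue data/residue.csv --consumption data/consumption.csv \
                --out results --seed 1
```

## Documentation

`docs/methods.md` describes the model assumptions, the calibration of
the synthetic generator, numerical choices and known limitations.
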