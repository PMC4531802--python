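# hibafish

High-throughput break-apart FISH analysis: detection of rare interphase
chromosome breaks and translocations from three-color FISH image stacks,
with a synthetic-imaging simulator that makes every stage testable against
exact ground truth.

## The problem

Balanced chromosome translocations are hallmark lesions of many cancers.
Break-apart FISH marks a candidate breakpoint with two probes (Green and
Red) flanking it and a third probe (FarRed) on a putative translocation
partner: an intact allele shows Red and Green together; a break separates
them; a translocation additionally places the separated Red signal next to
a FarRed signal. Scoring such events by eye caps practical sample sizes at
a few hundred cells, far too few to quantify events that occur in ~1 cell
in 100 (breaks) or ~1 in 300 (translocations). `hibafish` automates the
whole chain for thousands of nuclei per condition: maximum projection,
DAPI nucleus segmentation with morphology filters, ROI-constrained spot
detection, distance-thresholded event calling, and population statistics.

## The statistic at the core

For every Red signal in a QC-passing nucleus (≥2 signals per FISH channel,
equal Green and Red counts), compute the per-signal minima over all 2D
center-to-center distances,

    RG_min  = min_j ||red − green_j||,    RFR_min = min_k ||red − farred_k||,

in pixels on the maximum projection. With proximity threshold t
(default 4 px = 1.28 µm at 320 nm/px):

* **breakage** event: RG_min > t
* **translocation** event: RG_min > t and RFR_min ≤ t
* intact otherwise (a distance of exactly t counts as proximal)

A nucleus is positive for a class if ≥1 of its Red signals qualifies. The
positive fraction x/n per condition is reported with the modified Wald
(Agresti–Coull) 95% CI — p̃ = (x+2)/(n+4), half-width 1.96·√(p̃(1−p̃)/(n+4)),
clipped to [0,1] — and conditions are compared with two-sided Fisher exact
tests. The threshold itself can be calibrated from a negative-control
condition as the smallest integer pixel radius covering 99.8% of RG_min.

## Worked example

Simulate an untreated and a "damaged" condition (10% of cells with ≥1
break, 2% with a translocation), then run the full pipeline:

```python
import hibafish as hf
from hibafish import simulate as sim
from hibafish.config import CellModel, RunConfig
from hibafish.pipeline import run_pipeline

conds = [
    sim.Condition("UN", hf.negative_cell_model(), 150, cell_line="M2A"),
    sim.Condition("IR", CellModel.from_cell_rates(0.10, 0.02, name="irr",
                                                  n_alleles_A=3, n_alleles_B=2),
                  150, cell_line="M2A"),
]
sim.simulate_experiment(conds, seed=1, out_dir="demo")
res = run_pipeline(RunConfig(input_dir="demo", output_dir="demo_results"))
print(res.condition_summary.to_string(index=False))
print(res.comparisons.to_string(index=False))
```

Output:

```
 condition   event_class  n_nuclei_analyzed  n_positive  proportion   ci_low  ci_high percent
M2A/IR/ALK      breakage                150          13    0.086667 0.050573 0.144232   8.67%
M2A/IR/ALK translocation                150           4    0.026667 0.008400 0.069522   2.67%
M2A/UN/ALK      breakage                150           0    0.000000 0.000000 0.030869   0.00%
M2A/UN/ALK translocation                150           0    0.000000 0.000000 0.030869   0.00%

  event_class condition_a condition_b  p_value  fold_change
     breakage  M2A/IR/ALK  M2A/UN/ALK 0.000186          0.0
translocation  M2A/IR/ALK  M2A/UN/ALK 0.122496          0.0
```

13 of 150 analyzed nuclei in the damaged condition carry at least one
breakage event (8.67%, 95% CI 5.1–14.4%) versus 0 of 150 untreated
(CI upper bound 3.1%); the breakage difference is significant by Fisher's
exact test (p = 1.9e-4) while 4 translocation-positive nuclei are not yet
distinguishable from zero at this sample size — rare-event quantification
is exactly why the method scales to thousands of nuclei. (The example's
event rates are deliberately high so that 150 cells, about a minute of
simulation and analysis, show non-trivial counts.)

The same workflow is available from the shell:

```sh
hibafish simulate --out demo --seed 1 --cells 150
hibafish run --input demo --out demo_results
hibafish report --results demo_results --out demo_figs
```

`analyze` (images → spot tables), `call` (tables → events) and `stats`
(events → summaries) expose the individual pipeline seams; spot tables
from any source can enter mid-way via `call`.

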