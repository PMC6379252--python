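# gradedif

Item-level psychometrics for polytomous depression scales: graded-response-model
(GRM) calibration, latent-trait scoring, classical reliability statistics, and
hybrid ordinal-logistic-regression detection of differential item functioning
(DIF), packaged with a synthetic-data generator driven by a published
calibration of the 21-item Beck Depression Inventory-II (BDI-II).

## Who it is for

Researchers validating ordinal symptom scales who want, in one importable
library: Samejima's graded response model fitted by marginal maximum
likelihood, EAP severity scores, Cronbach's α and item-total diagnostics,
and a lordif-style DIF scan that conditions on IRT trait scores instead of
raw sum scores — plus a generator that produces realistic BDI-II-like data
for power studies and pipeline testing without access to any survey data.

## The model

Each item has four ordered response categories scored 0–3. The probability
of responding in category *k* or above is logistic in the latent severity θ,

P\*ₖ(θ) = 1 / (1 + exp(−a(θ − bₖ))),  b₁ < b₂ < b₃,

so the category probabilities are the telescoping differences
Pₖ = P\*ₖ − P\*ₖ₊₁. Discrimination *a* is the slope of the boundary curves;
threshold bₖ is the severity at which the k-th boundary is crossed with
probability ½. The metric is logistic **without** the 1.702 scaling constant;
the packaged bank reproduces the calibration sample's observed response
proportions only under this convention. Calibration integrates θ out over a
61-node quadrature grid with a N(0,1) prior (EM algorithm); scoring is EAP.

DIF detection fits, per item, four nested proportional-odds models of the
item response — intercepts only; + θ; + θ and group; + θ×group interaction —
and flags an item when the pseudo-R² change between the θ-only and the full
model exceeds 0.02 (McFadden by default). A 1-vs-2 change above threshold is
uniform DIF, a 2-vs-3 change non-uniform DIF. Flagged items get group-specific
parameters in a recalibration anchored by the clean items, trait scores are
re-estimated, and the scan repeats until the flagged set stabilizes.

## Worked example

```python
from gradedif import (DIFInjection, SimulationSpec, dif_analysis,
                      load_bdi2_bank, simulate_responses)

bank = load_bdi2_bank()          # published 21-item BDI-II calibration
data = simulate_responses(SimulationSpec(
    n_persons=12_677, item_bank=bank, seed=11,
    dif_spec=(DIFInjection(item_index=10, focal_group="F",
                           threshold_shift=0.75),),
))
report = dif_analysis(data, grouping="gender")
print(report.flagged_items)                  # [10]
print(report.results[9].dif_type)            # 'uniform'
print(round(report.results[9].delta("1v3"), 4))  # 0.0303
```

The scan flags exactly the item whose thresholds were shifted for women,
classifies the effect as uniform (constant across severity), and reports a
McFadden ΔR² of 0.030 for the 1-vs-3 model comparison — above the 0.02
flagging rule. The scripts in `examples/` walk through each capability
(implied population quantities, calibration recovery, reliability,
DIF scanning, characteristic curves) and print the numbers they compute.

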