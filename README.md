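# hicreprog

Hi-C analysis of chromatin-architecture reprogramming trajectories, built
for the somatic-cell-nuclear-transfer (SCNT) embryo setting: a donor
nucleus whose interphase chromatin (compartments, TADs) dissolves into a
metaphase-like state after transfer and is progressively re-established
through cleavage stages.  The package provides the complete per-stage
analysis battery plus a synthetic Hi-C generator with planted ground truth
so every stage is testable without the original sequencing data.

## What it computes

- **Contact matrices** — validPairs ingestion, binning (40 kb–1 Mb), ICE
  balancing (iterative correction of bin marginals), scaling to a common
  depth of 10⁸ contacts.
- **Distance decay / state calls** — P(s) in 0.05 log₁₀ bins, the
  s⁻¹-normalized curve, least-squares decay exponents, fall-off detection,
  and classification into interphase (P(s) ~ s⁻¹, fractal globule),
  mitotic metaphase (s⁻⁰·⁵ with a ~10 Mb fall-off) or MII metaphase
  (~4 Mb fall-off).
- **A/B compartments** — PC1 of the correlation of observed/expected,
  oriented by an activity track; compartment switches (sign change and
  |ΔPC1| > 1); distance-matched A–B segregation ratio; K-means (K = 10)
  PC1 trajectory clustering.
- **TADs** — insulation score (1 Mb square, 200 kb delta window, 0.25
  noise threshold), boundary and TAD calling, directionality index,
  rescaled aggregate TAD heatmaps (1.2 Mb convention with half-length
  flanks), and the **relative TAD intensity** RTI = median over distance
  rows of median(I_in)/median(I_out), used to classify reprogrammed vs
  unreprogrammed and H3K9me3-marked vs unmarked TADs.
- **Interactions** — binomial/Benjamini–Hochberg significant-interaction
  calling at 100 kb (q < 0.01) against a smoothed empirical distance
  expectation, ROSE-style super-enhancer calling (stitching + hockey-stick
  cutoff), SE–promoter / promoter–promoter classification with fragment
  interaction regions (500 bp minimum) and TSS ± 1 kb promoters, and
  virtual-4C anchor profiles.
- **Synthetic data** — Poisson maps with configurable decay exponent α,
  metaphase fall-off scale d_c, planted TADs (boost β), compartment plaid
  (strength γ), focal loops, trans fraction, plus matched ChIP tracks and
  annotations — all with serializable ground truth.

## Worked example

Run the six-stage demo trajectory (donor cell → mitotic metaphase → MII
metaphase → three maturing interphase stages), entirely from synthetic
data:

```sh
hicreprog demo --seed 0
```

which prints (abridged columns):

```
stage             state  exponent   falloff_bp  n_boundaries  segregation_ratio  pc1_truth_corr  mean_rti
   CC        interphase -2.402353          NaN            37           0.339647        0.982250  4.791811
 1hpi mitotic_metaphase -0.502945 9.440609e+06             0           1.090518        0.052036  1.004334
 1hpa     MII_metaphase -0.504738 3.758374e+06             0           0.874256        0.025788  0.996007
early        interphase -1.568569          NaN            36           0.608840        0.973172  1.946126
  mid        interphase -1.899736          NaN            37           0.485021        0.978452  2.892401
  ICM        interphase -2.399730          NaN            37           0.336507        0.980534  4.885417
```

Reading the table: the two post-transfer stages are called metaphase-like
(fitted exponent ≈ −0.5 with fall-offs detected at ≈ 9.4 and ≈ 3.8 Mb —
the mitotic ~10 Mb vs meiotic ~4 Mb signature), their insulation boundary
counts drop to zero and their PC1 no longer correlates with the planted
compartments.  Across the three post-activation stages the mean RTI of the
reference TADs rises (1.95 → 2.89 → 4.89) and the A–B segregation ratio
falls (0.61 → 0.49 → 0.34): TADs and compartments mature.  The steep
interphase exponents reflect the planted TAD/plaid structure on top of the
s⁻¹ background.

The same battery runs on files via `hicreprog run config.yml`, and the
individual steps are exposed as `hicreprog bin | ice | scale | ps |
classify-state | compartments | tads | rti | loops | v4c | simulate`.

Library use:

```python
from hicreprog import sim, decay

params = sim.SimParams(n_bins=2000, bin_size=100_000,
                       decay_exponent=-0.5, cutoff_distance=1e7,
                       depth=1e6, seed=1)
matrix, truth = sim.simulate_contact_map(params)
call = decay.classify_chromatin_state(decay.contact_probability(matrix))
print(call.label, round(call.exponent, 3), round(call.falloff / 1e6, 2))
# mitotic_metaphase -0.501 9.44
```

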