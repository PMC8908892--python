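# raylife

Life-history and trophic analysis for batoids (rays), built around the kind of
small-sample field study used to assess data-deficient coastal elasmobranchs:
aged specimens (vertebral band counts), staged gonads, and stomach contents.
`raylife` estimates growth, median size-at-maturity and diet composition, and
tests for ontogenetic diet shifts. It was developed for the pearl whipray
(*Fontitrygon margaritella*), a small, fast-growing West African stingray, but
every stage is generic over the input tables.

## What it computes

**Growth.** Disc width at age is fitted under three families sharing the
parameters (DW∞, DW_birth, k):

- logistic: DW(t) = DW∞ / (1 + ((DW∞ − DW_birth)/DW_birth) e^(−kt))
- Gompertz: DW(t) = DW_birth · exp(ln(DW∞/DW_birth)(1 − e^(−kt)))
- von Bertalanffy: DW(t) = DW_birth + (DW∞ − DW_birth)(1 − e^(−kt))

with i.i.d. Gaussian observation error (s.d. σ). Posteriors come from a seeded
adaptive random-walk Metropolis sampler (4 chains × 3,500 iterations, 1,000
warm-up; split R-hat and ESS diagnostics), and families are compared by
PSIS-LOO cross-validation on the LOOIC scale (LOOIC = −2·elpd_loo); fits
within 2 LOOIC units are flagged as indistinguishable.

**Maturity.** A Bayesian logistic ogive P(mature | DW) = 1/(1 + e^(−(a+b·DW)))
per sex and combined, with DW50 = −a/b computed draw-wise so its credible
interval carries the (a, b) posterior correlation. Age-at-maturity follows by
inverting the selected growth curve.

**Diet.** Stomach contents over six prey groups (crustaceans, polychaetes,
bivalves, other molluscs, teleosts, unidentified) are summarised by the Index
of Importance, IOI_a = 100·(%F_a + %W_a)/Σ(%F + %W), per life stage (YOY,
juvenile, adult). Composition differences are tested by PERMANOVA on
Bray–Curtis dissimilarities of per-stomach mass proportions, with seeded
permutations and Holm-adjusted pairwise tests.

**Synthetic data.** A seeded generator produces specimen and stomach tables
with known ground truth (growth family, ogive coefficients, stage-specific
diet profiles), so the whole pipeline is testable end to end.

## Worked example

```python
from raylife.synthetic import SimulationScenario, gen_size_at_age
from raylife.growth import GrowthFamily, fit_growth
from raylife.inference import MCMCConfig
from raylife.model_selection import psis_loo, compare

obs = gen_size_at_age(SimulationScenario(seed=42))   # 71 aged specimens
loos = {}
for j, fam in enumerate(GrowthFamily):
    fit = fit_growth(obs, fam, config=MCMCConfig(seed=42 + j))
    loos[fam.value] = psis_loo(fit.pointwise_loglik)
res = compare(loos)
print(res.table.round(2)); print("indistinguishable:", res.indistinguishable)
```

prints

```
                  n   looic     se  delta_looic
von_bertalanffy  71  252.28  15.22         0.00
gompertz         71  252.54  14.45         0.26
logistic         71  253.00  14.11         0.72
indistinguishable: True
```

The data were simulated from a logistic truth (DW∞ = 34.5 cm, DW_birth =
14.0 cm, k = 0.3 yr⁻¹, σ = 1.5 cm), yet all three families land within one
LOOIC unit of each other — over the sampled age range 0–7 years the three
curves are nearly coincident, so the comparison correctly declines to pick a
winner. The logistic fit's posterior medians (33.5, 13.8, 0.32, σ = 1.41)
recover the truth within their 95% credible intervals.

The same analysis runs from the shell:

```sh
raylife simulate --seed 42 --out data/
raylife compare data/specimens.csv --seed 42
raylife fit-maturity data/specimens.csv --seed 42
raylife run-all --config config.yaml     # full pipeline, CSV outputs + run log
```

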