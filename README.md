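# selenospec

Bayesian quantification of selenium speciation from LC‒ICP-MS
chromatograms, and of selenium-methyltransferase kinetics from
saturation assays.

## The problem

Methyltransferases such as INMT detoxify selenium by successive
methylation; the reaction products — selenite and its glutathione adduct
GSSeSG (the non-methylated fraction M₀), methaneseleninic acid (MSA, M₁)
and dimethylselenoxide (DMSeO, M₂) — are separated by liquid
chromatography and detected element-specifically as ⁸²Se counts per
second. Peaks overlap and tail, so "how much of the selenium is still
non-methylated?" is a deconvolution problem, and enzyme-activity
comparisons additionally require Michaelis–Menten parameters from noisy
saturation curves. `selenospec` implements the full inferential chain:

1. **Calibration** — each standard compound's peak is modeled as an
   exponentially modified Gaussian (EMG),

   EMG(x; μ, σ, λ) = (λ/2)·exp[(λ/2)(2μ + λσ² − 2x)]·erfc[(μ + λσ² − x)/(√2 σ)],

   with uniform priors on (μ, σ, λ) and MCMC posterior sampling. The
   posterior means form a *standard library* of fixed peak shapes.
2. **Deconvolution** — a reaction mixture's elution profile, converted
   to a probability distribution over time bins, is modeled as
   p(x | ω) = Σₖ ωₖ·EMG(x; μₖ, σₖ, λₖ) with a Dirichlet(1,1,1,1) prior
   on the weight simplex ω. The posterior over ω gives each species'
   share of the Se signal, and M₀ = ω_GSSeSG + ω_selenite per draw.
   Replicate M₀ values are compared between groups with Student's or
   Welch's *t* test.
3. **Kinetics** — initial rates v₀ at substrate concentrations S₀
   follow v = V_max·S₀/(K_M + S₀) with Gaussian noise. A deterministic
   least-squares initializer (multi-start minimization of
   Σᵢ(v₀ᵢ − V_max·S₀ᵢ/(K_M+S₀ᵢ))²) centers Gaussian priors on K_M and
   V_max; gamma priors sit on the three precisions. Fits report
   mean ± SD, and a Michaelis constant the data cannot identify is
   reported as **N.D.** by an explicit rule rather than as a meaningless
   number.

A seeded synthetic-data module generates chromatograms (EMG mixtures
with multinomial or Poisson count noise) and kinetics tables with
exactly the statistical structure the models assume, so every stage is
verified by parameter recovery without instrument data.

## Worked example

```python
import numpy as np
from selenospec import (
    EMGParams, SamplerConfig, DeconvolutionConfig, ChromSimSpec,
    simulate_mixture_chromatogram, to_elution_distribution, deconvolve,
)
from selenospec.calibration import SE_PANEL, StandardLibrary

# calibrated peak shapes for the four-species Se panel (minutes, 1/min)
lib = StandardLibrary(SE_PANEL, {
    "GSSeSG":   EMGParams(13.6, 0.12, 6.0),
    "MSA":      EMGParams(9.0,  0.10, 4.0),
    "selenite": EMGParams(16.0, 0.10, 5.0),
    "DMSeO":    EMGParams(19.0, 0.15, 3.0),
})

# a reaction mixture: 40% GSSeSG, 30% MSA, 20% selenite, 10% DMSeO
spec = ChromSimSpec(
    components=tuple(lib[c] for c in SE_PANEL),
    weights=(0.4, 0.3, 0.2, 0.1), total_counts=5000, seed=7,
)
dist = to_elution_distribution(simulate_mixture_chromatogram(spec))
res = deconvolve(dist, lib, DeconvolutionConfig(sampler=SamplerConfig(seed=8)))
for c in res.panel:
    print(f"{c:9s} {res.weight_mean[c]:.3f} ± {res.weight_sd[c]:.3f}")
print(f"M0        {res.m0_mean:.3f} ± {res.m0_sd:.3f}")
```

prints

```
GSSeSG    0.394 ± 0.007
MSA       0.314 ± 0.006
selenite  0.193 ± 0.005
DMSeO     0.098 ± 0.004
M0        0.588 ± 0.007
```

i.e. the posterior recovers the generating mixture within ±0.01 and
reports that 58.8 ± 0.7% of the selenium is still non-methylated.

The same stages are available from the shell:

```bash
selenospec simulate kinetics --spec kin_spec.json --out kin.csv
selenospec kinetics --data kin.csv --seed 3 --out fit.json
selenospec calibrate --standards standards/ --seed 1 --out library.json
selenospec deconvolve --sample mix.csv --library library.json --seed 2 --out result.json
selenospec compare --a 0.61,0.63,0.60 --b 0.35,0.38,0.33 --policy welch
```

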