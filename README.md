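# mcrkin

Curve resolution and milling kinetics for time-resolved *in situ* powder
X-ray diffraction (PXRD) of mechanochemical reactions.

Ball-mill syntheses — here the liquid-assisted co-crystallisation that turns
two reagents into a product polymorph through a cascade of crystalline
intermediates — are monitored by collecting a diffractogram every fraction of
a minute while the mill runs.  The resulting frames × 2θ matrix **D** mixes
every phase present at every instant.  This package implements the workflow
that turns such a matrix into quantitative kinetics, for researchers doing
mechanochemistry, pharmaceutical solid-form screening, or chemometrics on
diffraction data:

1. **MCR-ALS** — bilinear decomposition D ≈ C·Sᵀ into concentration profiles
   C and pure patterns S by alternating non-negativity-constrained least
   squares, seeded by **SIMPLISMA** purest-variable selection
   (purity = σ/(μ+δ), determinant-weighted across rounds), with SVD rank
   diagnostics for the rank deficiency that merged phases cause.
2. **Kinetic soft-hard constraint** — a reaction network (first-order,
   Finke–Watzky autocatalytic `D + P → 2P`, and lag-activated steps) is fitted
   inside the ALS loop and regenerates model-consistent concentration
   columns, returning optimised rate constants k_i and lag times τ.
3. **Per-impact (CLC) kinetics** — a phenomenological model of milling in
   which only the powder fraction κ under critical loading conditions reacts
   per impact: dα/dn = κ·ν(α) with n = f·t impacts, including the product
   fraction α_P,start formed at the first effective impact.
4. **Synthetic study conditions** — a generator producing the three
   liquid-additive scenarios ("30uL", "60uL", "90uL") as noisy bilinear PXRD
   series with known ground truth, so the entire chain is testable without
   any external data.

See `docs/methods.md` for the models, assumptions, defaults and limitations.

## Worked example

Resolve a synthetic 30 µL experiment and extract its rate constants:

```python
import numpy as np
from mcrkin import (make_scenario, estimate_rank, simplisma, als_fit,
                    match_components, preset_network, integrate,
                    KineticConstraintConfig, mcr_kinetic_fit)

bundle = make_scenario("30uL", noise_sd=0.02, seed=7)
rank = estimate_rank(bundle.series)
sel = simplisma(bundle.series, 5)
soft = als_fit(bundle.series, sel.initial_estimate, max_iter=400)

net = preset_network("30uL")
Y0 = integrate(net, np.concatenate([[0.0], bundle.series.times]))[1:]
perm, _ = match_components(soft.C, Y0)
mapping = {int(perm[j]): net.species[j] for j in range(5)}
kin = mcr_kinetic_fit(
    bundle.series,
    KineticConstraintConfig(network=net, component_to_species=mapping),
    sel.initial_estimate)
```

Output:

```
phases: ('R', 'A', 'B', 'D', 'P')
frames x channels: (161, 1500)
estimated rank (elbow): 5
purest frames at t = [72.5, 15.0, 0.5, 26.5, 2.5] min
soft MCR-ALS: LOF = 13.56% after 400 iterations
kinetic MCR:  LOF = 13.60%
  k_AB       = 0.2736
  k_BD       = 0.1560
  k_DP       = 0.0073
  k_DPP      = 0.2047
  k_RA       = 0.4902
  tau_k_BD   = 15.0694
matched cosine similarity vs truth: [0.9991 0.9999 1.     1.     1.    ]
```

Reading it: the rank estimate finds all five phases resolvable (at 60/90 µL
it drops below the number of generating phases — the merged-component rank
deficiency).  SIMPLISMA picks one purest frame per phase (t = 0.5 min is the
reagent-dominated frame, t = 72.5 min pure product).  The soft resolution
explains the data to a 13.6% lack of fit (the floor set by 2% detector
noise); the kinetic constraint costs only 0.04 LOF points while pinning the
concentration profiles to an integrable reaction network.  The fitted rate
constants sit within ~10% of the generator's true values (k_RA = 0.45,
k_AB = 0.30, k_BD = 0.15, k_DP = 0.008, k_DPP = 0.20, τ = 15 min), and the
resolved concentration profiles match the ground truth to cosine ≥ 0.999.

The same flow is available from the shell:

```sh
mcrkin simulate --scenario 30uL --seed 7 --out sim/
mcrkin mcr --input sim/series.csv --components 5 --out soft/
mcrkin mcr-kinetic --input sim/series.csv --scenario 30uL --out kin/
mcrkin clc-fit --profiles kin/C.csv --scenario 30uL --phases R,A,B,D,P --out clc/
mcrkin pipeline --scenario all --seed 1 --out bench/
```

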