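# nucleoquant

Quantitative image- and signal-analysis tools for studying how DNA-binding
protein complexes assemble into higher-order nucleoprotein structures. The
package was built around the measurements used to characterize a minimal
trimeric Rec114–Mei4 DNA-binding domain — a meiotic double-strand-break
factor that compacts DNA, bridges coaligned duplexes, and forms
condensates — but every stage is generic:

- **AFM tracing and volume stoichiometry** (`nucleoquant.afm`) — segment
  DNA molecules in calibrated height maps, thin them to skeletons,
  decompose at branch points, and measure contour lengths with weighted
  chain-code steps (rx, ry, √(rx²+ry²)). Molecular volume is
  V = rx·ry·Σ(h_p − h_b) over the molecule footprint; comparing mean
  volumes of protein-bound vs bare DNA against the single-complex
  reference volume V_p = M/(ρ·N_A) gives the average number of complexes
  per binding site, n = V_d/(V_p·N_p).
- **Condensate morphometry** (`nucleoquant.condensate`) — core radius from
  thresholded area (A = πr²) and halo thickness by casting 36 rays at 10°
  steps from the core center in two-channel confocal images.
- **Dissociation kinetics** (`nucleoquant.kinetics`) — ROI mean photon
  counts, first-frame normalization, single-exponential fits
  I(t) = A·e^(−kt), and threshold-with-persistence waiting times.
- **EMSA binding curves** (`nucleoquant.emsa`) — fraction bound, C₅₀ by
  linear interpolation at the first 50%-bound crossing, and replicate
  aggregation (mean ± half-range for two replicates, mean ± SD for three
  or more).
- **Synthetic scenes** (`nucleoquant.synthetic`) — seeded generators with
  ground-truth manifests: 2D worm-like-chain DNA (closed-form
  ⟨R²⟩ = 2ξL − 2ξ²(1−e^(−L/ξ)), ξ = 2l_p) rendered into height maps with
  Gaussian tip broadening, core/halo condensates, exponential decay
  traces, and sigmoidal binding tables.
- **Pipeline + CLI** (`nucleoquant.pipeline`, console script
  `nucleoquant`) — configured, seeded simulate → analyze runs producing
  byte-identical tables for identical config + seed.

## Worked example

```python
import numpy as np
from nucleoquant import afm, synthetic as syn

# a seeded synthetic AFM scene: 9 worm-like chains (383 nm each, l_p = 50 nm,
# 1 nm/pixel) decorated with ~2.2 particles per molecule
hm, truth = syn.simulate_afm_scene(n_chains=9, seed=3)
traces, particles, volumes, h_b = afm.analyze_height_map(hm)
print(len(traces), sum(len(p) for p in particles))
# -> 9 14           (all chains and all 14 rendered particles recovered)
print(round(np.median([t.total_contour_length for t in traces]), 1))
# -> 413.0          (chain-code tracing carries a known ~+6% digitization bias)

# volume-ratio stoichiometry with the published inputs:
print(round(afm.bound_trimer_count(v_d=303, v_p=20.7, n_p=2.2), 2))
# -> 6.65           (~6.7 complexes per binding site)
print(round(afm.protein_reference_volume(mass_da=17970, density=1.44), 1))
# -> 20.7           (single-complex volume in nm^3)
```

Or from a shell:

```sh
nucleoquant run --seed 11 --out-dir run_out     # full simulate -> analyze run
nucleoquant report run_out                      # combined summary table
```

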