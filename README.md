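# rotorlab

Virtual radiofrequency-ablation (RFA) planning on a synthetic fibrotic
left atrium (LA).

Persistent atrial fibrillation (pAF) is driven by reentrant spiral waves
("rotors") whose phase singularities (PSs) can be mapped, targeted and —
in principle — ablated.  `rotorlab` is a desk-scale in-silico test bed
for that workflow, aimed at computational electrophysiologists: it
simulates fibrillation on a synthetic left-atrial surface with a
pAF-remodeled human atrial ionic model, maps rotor phase singularities,
applies virtual RFA lesion sets, and quantifies outcomes.

The pipeline, module by module:

| module | what it does |
|---|---|
| `rotorlab.geometry` | synthetic LA surface: triangulated sheet with four PV ostia, mitral rim, fiber field with ~90° rotation at PV bases, LGE-likelihood map, eight analysis subdivisions |
| `rotorlab.fibrosis` | stochastic interstitial fibrosis: edge selection with weight α(4cos²θ + sin²θ)·L, calibration of α to a 670 µm median cluster length, no-flux edge splitting |
| `rotorlab.ionic` | Courtemanche–Ramirez–Nattel atrial myocyte with pAF remodeling (gNa×2, gK1×0.8, Ito×0.5, IKur×0.5, ICaL×0.3) and PV/appendage variants |
| `rotorlab.monodomain` | anisotropic monodomain reaction–diffusion on the (split) surface: P1 finite elements, Rush–Larsen + explicit splitting, lesions at 0.001 S/m, −40 mV activation maps |
| `rotorlab.protocols` | sinus pacing (86 bpm), PV burst initiation (5 beats, CL 160 ms, CI 240/400 ms), sustainment detection, experiment orchestration |
| `rotorlab.phase` | Hilbert phase, PS detection by topological charge, tracking, the 120 ms rotor rule, density maps, regional statistics |
| `rotorlab.ablation` | lesion geometry: PVI rings, roof/mitral lines, PS-guided circles / perforated circles / lines / crosses (0.5–1.5 cm), activation-sequence streamlining lines |
| `rotorlab.outcomes` | post-RFA classification (sinus / AT / pAF), Pearson correlation tables of outcome vs PS and fibrosis density |
| `rotorlab.scenarios` | reusable experiments, e.g. cross-field S1–S2 reentry induction on a remodeled sheet |

The core statistic relating substrate to rotor behaviour is the Pearson
product-moment correlation between per-subdivision normalized densities
(each vector scaled by its maximum across the eight LA subdivisions):

    r = Σ(xᵢ−x̄)(yᵢ−ȳ) / √(Σ(xᵢ−x̄)² Σ(yᵢ−ȳ)²),   p from t(n−2)

and the operational rotor definition is a tracked phase singularity
(±2π winding of Hilbert phase around a mesh element) persisting > 120 ms.

See `docs/methods.md` for the full model description, parameter tables,
numerical choices and limitations.

## Worked example

Build the synthetic atrium, calibrate fibrosis, and correlate the
printed density vectors:

```python
import numpy as np
from rotorlab import geometry, fibrosis, outcomes

mesh = geometry.build_la_surface()              # 50×50 mm, 0.5 mm edges
lge = geometry.build_lge_map(mesh, seed=0)      # matches density targets
alpha, median_um = fibrosis.calibrate_alpha(mesh, lge)
print(f"alpha = {alpha:.3f}, median cluster = {median_um:.0f} um")

fib_density = (0.84, 0.28, 1.0, 0.57, 0.42, 0.35, 0.25, 0.20)
ps_density = (0.0, 0.08, 1.0, 0.0, 0.42, 0.14, 0.65, 0.0)
print(outcomes.pearson(fib_density, ps_density))
```

prints (the calibration is stochastic over 20 fixed seeds):

```
alpha = 0.339, median cluster = 650 um
r=0.38, p=0.35
```

i.e. the weighting constant that reproduces the observed ~670 µm median
interstitial-fibrosis cluster length, and the weak, non-significant
spatial correlation between fibrosis density and where rotors actually
live — the quantitative form of "fibrosis maps are not enough to target
rotors".

Inducing and measuring a rotor (several minutes of compute):

```python
from rotorlab import scenarios
sc = scenarios.induce_spiral(seed=1)            # cross-field S1–S2
cl = scenarios.mean_reentry_cl(sc.recording, sc.mesh, t_min=sc.t_s2 + 400)
print(f"rotor cycle length {cl:.0f} ms")        # ~190 ms
```

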