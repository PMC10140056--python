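# rodcone

Estimate the proportional survival of rod and cone photoreceptors from
the thickness of the outer nuclear layer (ONL) on clinical OCT.

Commercial OCT cannot resolve single photoreceptors, but the ONL — here
always the combined Henle fiber layer + ONL + myoid zone — is the layer
their nuclei occupy, and its thinning tracks photoreceptor death.
`rodcone` turns regional ONL thickness into separate rod and cone
survival estimates by exploiting the stereotyped topography of the two
cell classes: cones dominate the fovea, rods dominate the periphery.
The intended users are retina researchers quantifying degeneration
(e.g. Stargardt disease, retinitis pigmentosa) from routine macular
volume scans.

## The model

A density-registered **reference model** of a healthy eye pairs every
A-scan position with its normal ONL thickness `T_normal` and expected
rod proportion `P_rods` (histologic rod/cone densities, projected from
spherical retinal coordinates, registered through the fovea and
optic-nerve landmarks, and interpolated at every A-scan;
`P_cones = 1 − P_rods`). Assuming rods and cones contribute equally to
ONL thickness, survival fractions `S_cones, S_rods ∈ [0, 1]` thin the
layer linearly:

```
P_simulated = (1 − P_rods)·S_cones + P_rods·S_rods
T_simulated = T_normal · P_simulated
```

Averaged over an ETDRS region, the simulated mean thickness is affine
in `(S_cones, S_rods)` with coefficients
`a_cones = ⟨T_normal·(1 − P_rods)⟩` and `a_rods = ⟨T_normal·P_rods⟩`.
One region cannot identify two unknowns, but the cone-dominated ETDRS
center subfield (1 mm) together with the rod-dominated outer ring
(3–6 mm annulus, treated as one unit so the statistic is rotation
invariant) gives a well-conditioned 2×2 linear system:

```
[t_center]   [a_cones_c  a_rods_c] [S_cones]
[t_outer ] = [a_cones_o  a_rods_o] [S_rods ]
```

Solutions outside the physical box `[0,1]²` are replaced by the
box-constrained least-squares fit, flagged, and reported with their
thickness residual. The fitted pair can be fed back through the forward
model to render simulated thickness maps and — by seeded random voxel
removal with vitreous compensation — simulated B-scan volumes.

## Worked example

```python
from rodcone import SurvivalModel, SynthConfig

cfg = SynthConfig(seed=0, n_rows=65, n_cols=65, dx_mm=0.1, dy_mm=0.1,
                  fovea_rc=(32.0, 32.0), nerve_rc=(30.0, 78.0))
model = SurvivalModel.from_synthetic(cfg)      # synthetic healthy reference
t_center, t_outer = model.design @ [0.30, 0.80]  # an eye with 30% cones, 80% rods
res = model.fit(t_center, t_outer)
print(res.summary())
```

prints

```
            Photoreceptor Survival Estimate
========================================================
Method:            linear
Condition number:  1.758
--------------------------------------------------------
param     estimate   clamped
S_cones     0.3000   False
S_rods      0.8000   False
--------------------------------------------------------
region    observed(µm)  fitted(µm)  residual(µm)  a_cones  a_rods
center          37.82      37.82            0    93.57    12.18
outer           46.89      46.89            0     5.79    56.44
========================================================
```

The healthy regional means here are 105.8 µm (center) and 62.2 µm
(outer ring). An eye retaining 30 % of its cones and 80 % of its rods
thins the cone-dominated center to 37.8 µm and the rod-dominated outer
ring to 46.9 µm; inverting the two-region system recovers the survival
pair exactly (zero residual, no clamping). `res.simulate_thickness()`
renders the corresponding en face map and
`res.simulate_volume(volume, seed)` the corresponding B-scan volume.

The same workflow is available from the shell:

```
rodcone synth --config cfg.json --out fixtures/
rodcone build-ref --thickness fixtures/healthy_thickness.tiff \
        --densities fixtures/densities.csv --out ref.h5
rodcone estimate --ref ref.h5 --measurements fixtures/cohort.csv --out est.csv
rodcone bscan-sim --ref ref.h5 --volume fixtures/healthy_volume.h5 \
        --s-cones 0.3 --s-rods 0.8 --seed 1 --out sim.h5
```

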