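# qusatten

Quantitative-ultrasound tissue characterization: a reference-free
plane-wave-imaging (PWI) estimator of the attenuation-coefficient slope,
the two classical reference-phantom comparators (spectral difference, SDM,
and spectral log difference, SLDM), a multi-echo proton-density-fat-fraction
(PDFF) estimator for the companion quantitative-MRI arm, and the statistics
used to compare them — all exercisable end-to-end on synthetic RF and MR
data generated in-repo.

## Who this is for

Researchers in quantitative ultrasound and tissue characterization who want
a reproducible, hardware-free sandbox for attenuation estimation: simulate
speckle from a virtual phantom with known attenuation, beamform it, run the
estimators, and check recovery against ground truth.

## The science in brief

A single zero-angle plane wave insonifies a medium of sub-wavelength
scatterers with frequency-linear attenuation α(f) = α₀·f (α₀ in
Np/(cm·MHz)). Under single scattering and dense in-phase backscatter, the
ensemble backscattered intensity decays as

    I_r(z, f) = A² · exp(−4 α(f) z),

so the attenuation follows from the data alone, with no reference medium:

    α_PWI(f) = −¼ · ∂ ln I_r(z, f) / ∂z,      α₀ = α_PWI / f.

Beamforming uses Stolt's f–k migration of the plane-wave data (a
delay-and-sum beamformer is included as a cross-check). Local α₀ maps are
built by exponential regression of windowed, laterally averaged intensity
(square windows of 8.5λ/17λ/25λ, 95% overlap, depths 2–5.7 cm by default);
each window's slope is normalized by the spectral centroid measured in that
window, which removes the depth-downshift bias of broadband pulses.

The comparators need a calibrated reference medium (known α_ref, matched
sound speed):

    α_SDM(f)  = α_ref(f) − ¼ · ∂/∂z ln [S_s(f,z) / S_ref(f,z)],
    α_SLDM(f) = α_ref(f) − [ln R(f, z_d) − ln R(f, z_p)] / [4 (z_d − z_p)],

with S the depth-resolved power spectra and R their ratio at a proximal and
a distal window.

The MR arm models the voxel signal as water plus an 8-peak triglyceride
spectrum, shared R2\* and a field-map phase, and fits it by variable
projection; PDFF = 100·ρ_f/(ρ_f + ρ_w). Group comparisons use unpaired
t-tests with Bonferroni-adjusted tiers (0.05, 0.01, 0.001)/n_tests and
Cohen's d = (X̄_a − X̄_b)/√((σ_a² + σ_b²)/2); fat–attenuation coupling is
quantified by the Pearson correlation of log(PDFF) against α₀.

## Worked example

```python
import numpy as np
from qusatten import (build_phantom, sample_scatterers,
                      simulate_channel_data_fast, fk_migrate,
                      map_local_ac, roi_average_ac, ProbeGeometry)

probe = ProbeGeometry()                      # 128 el, 5.2 MHz, 20.8 MHz fs
phantom = build_phantom("cirs_two_zone")     # 0.079 | 0.107 Np/(cm.MHz)
field = sample_scatterers(phantom, seed=11)
data = simulate_channel_data_fast(field, phantom, probe)
image = fk_migrate(data)
acmap = map_local_ac(image)                  # 17-wavelength pixels, 95% overlap

left = np.outer(acmap.x_centers_cm < -0.8, np.ones(acmap.z_centers_cm.size, bool))
right = np.outer(acmap.x_centers_cm > 0.8, np.ones(acmap.z_centers_cm.size, bool))
print("weak zone :", roi_average_ac(acmap, left))
print("strong zone:", roi_average_ac(acmap, right))
```

Output (seed 11):

```
weak zone : GroupSummary(mean=0.0821749510222658, std=0.0486753507869553, n=3596, label='')
strong zone: GroupSummary(mean=0.10638720296623787, std=0.059084958992370484, n=3596, label='')
```

The weak-zone mean sits near the true 0.079 Np/(cm·MHz) and the strong zone
near 0.107. The large per-pixel std is single-realization speckle noise of
the 17λ local estimates — averaging 3596 highly overlapping pixels leaves a
zone-mean uncertainty of a few times 10⁻³, and the seeded multi-realization
experiments in `qusatten.study` (e.g. `two_zone_recovery`) show the
between-realization spread of the zone means themselves is ≈ 0.002–0.003.

There is also a CLI for the same pipeline plus a one-command virtual study:

```bash
qusatten simulate --phantom cirs_two_zone --seed 1 --out cd.h5
qusatten beamform --in cd.h5 --out bf.h5
qusatten estimate-ac --in bf.h5 --pixel-lambda 17 --out acmap.csv
qusatten simulate-mri --pdff 3.7 --snr 50 --seed 1 --n-voxels 100 --out mri.h5
qusatten fit-pdff --in mri.h5 --out pdff.csv
qusatten study --seed 1 --outdir study_out
```

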