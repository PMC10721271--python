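# myorod

Quantitative analysis tools for myosin rod (light meromyosin, LMM)
mutations and their functional consequences in skeletal muscle.

Mutations in the coiled-coil tail of the myosin heavy chains MYH7 and MYH2
cause myosinopathies. Characterising them requires a chain of quantitative
methods that spans scales: geometric modelling of the two-chain coiled coil
itself, geometry metrics on simulation trajectories of mutant fragments,
circular-dichroism measures of helicity and thermal stability, Mant-ATP
chase assays that partition myosin heads into the disordered-relaxed (DRX)
and super-relaxed (SRX) states, single-fiber force–pCa mechanics, sarcomere
fluorescence line profiles, and cohort statistics. `myorod` implements this
whole analysis chain as a tested Python library with a thin CLI, together
with synthetic-data generators that emulate every input class so the
pipeline can be exercised end to end without experimental material.

## What is inside

| module | purpose |
| --- | --- |
| `cc_builder` | ab initio two-chain coiled-coil Cα models from Crick parameters, with canonical 7-residue motifs, 29-residue skip motifs and 27-residue deletion motifs |
| `traj_geometry` | D_com, heptad length, interheptad angle, dihedral helicity on multi-model PDB trajectories, with burn-in and multi-run aggregation |
| `rod_register` | heptad-register assignment with skip residues, rolling charge profiles, mutation-density profiles |
| `mant_atp` | normalisation and unconstrained double-exponential fitting of Mant-ATP chase decays (P1/T1 fast-DRX, P2/T2 slow-SRX) |
| `spectroscopy` | mean residue ellipticity, percent helicity (36,000 full-helix reference at 222 nm), sigmoid melt fitting for T_m |
| `fiber_mech` | elliptical cross-sectional area, specific force, 4-parameter Hill fits (pCa50, nH) |
| `sarcomere_profile` | alignment/normalisation of sarcomere line profiles and peak-to-peak distance across the M-band |
| `srx_model` | steady-state three-state SRX ⇌ DRX ⇌ force-generating surrogate model |
| `cohort_stats` | pooled controls, one-way ANOVA, Dunnett many-to-one post hoc |
| `synthetic_data` | seeded generators for every input class above |

## The core models

**Coiled-coil geometry.** Each chain's Cα trace is a minor helix of radius
r ≈ 2.3 Å about a local axis that winds as a left-handed superhelix of
radius R = 4.9 Å about the central axis, rising 1.495 Å per residue with a
laboratory-frame periodicity of 3.617 residues/turn. The supercoil rate per
residue follows from the mismatch with the motif's frame periodicity
(residues per turn in the rotating frame):

    ω₀ = 360 (1/3.617 − 1/p_frame)  deg/residue

with p_frame = 3.5 for a canonical heptad (ω₀ ≈ −3.33°/residue), 29/8 for a
skip motif (locally unwound) and 27/8 for a deletion motif (locally
overwound). The winding profile is Gaussian-smoothed with width
b × chain length (default b = 0.03). The second chain is the first rotated
210° about the central axis.

**Mant-ATP chase.** Normalised fluorescence is fit to

    y(t) = 1 − P1 (1 − e^(−t/T1)) − P2 (1 − e^(−t/T2)),  T1 < T2,

P1 approximating the DRX head fraction and P2 the SRX fraction.

**Force–pCa.** F(pCa) = F_min + (F_max − F_min) / (1 + 10^{nH (pCa − pCa50)}).

## Worked example

```python
import numpy as np
from myorod import cc_builder, traj_geometry, validation

params = cc_builder.CrickParameters()          # 3.617 r/t, 1.495 Å, R=4.9 Å, 210°
wt = cc_builder.build(params, cc_builder.make_pattern(91))
mut = cc_builder.build(params, cc_builder.make_pattern(91, deletion_sites=(46,)))

print(round(validation.recover_rise(wt), 4))          # 1.495
print(round(validation.recover_periodicity(wt), 4))   # 3.617
print(round(validation.recover_major_radius(wt), 3))  # 4.867
print(round(validation.recover_interchain_rotation(wt), 1))  # 210.0

traj = traj_geometry.CoiledCoilTrajectory(mut.coords[None], mut.residue_numbers)
profile = traj_geometry.heptad_length_profile(traj)
peak = profile.residue_numbers[np.argmax(np.abs(profile.mean - 10.69))]
print(peak)                                # 39 — inside the deletion span (29-55)
```

The recovered rise, periodicity and interchain rotation round-trip the
builder's generating constants; the recovered radius (4.867 Å vs 4.9 Å,
−0.7 %) reflects the slight chord shrinkage of 7-Cα window centroids on a
curved axis. The heptad-length deviation of the deletion mutant peaks
inside the 27-residue noncanonical span — the local kink that brings the
coil back into register.

Fitting a synthetic Mant-ATP cohort:

```python
from myorod import mant_atp, synthetic_data

spec = synthetic_data.CohortSpec(n_control=5, n_patient=5, drx_shift=0.15,
                                 noise_sd=0.0, seed=0)
base = mant_atp.RelaxFit(p1=0.25, t1=20.0, p2=0.55, t2=200.0)
fits = mant_atp.fit_traces(synthetic_data.make_decay_cohort(spec, base))
print(fits.groupby("group")["p1"].mean().round(4))
# control    0.2500
# patient    0.2875     <- 15 % DRX shift recovered exactly at zero noise
```

A CLI mirrors the main entry points, e.g.
`myorod build --length 91 --deletion 46 --out model.pdb`,
`myorod fit-mant traces.csv --out fits.csv`, `myorod fit-cd melt.csv ...`,
`myorod stats dunnett values.csv ...`.

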