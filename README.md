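# isodose

A radiobiological dose engine for comparing and combining **boron neutron
capture therapy (BNCT)** and **carbon-ion radiotherapy (CIRT)** plans on a
common photon-equivalent scale, with tumour control probability (TCP) as the
figure of merit.

BNCT deposits dose through a mixed radiation field — boron-capture
alpha/lithium products, nitrogen-capture protons, hydrogen-recoil fast dose
and photons — whose biological weight differs per component and per tissue.
To compare such a plan with a carbon-ion plan (already expressed in
photon-equivalent Gy (IsoE; C12)), this package implements the *photon
isoeffective dose* formalism: the dose of a reference photon irradiation
producing the same biological effect as the mixed field, solved per voxel.
Fractionated plans are mapped to single-fraction equivalents through the
linear-quadratic **biologically effective dose**,

    BED = n·d·(1 + d/(α/β)),      D_SF = (α/β)/2·(−1 + √(1 + 4·BED/(α/β))),

and plans delivered sequentially are summed voxelwise in BED space.  Tumour
control is evaluated with a head-and-neck TCP model with an explicit volume
effect,

    TCP(v, D) = exp(−c1·v^c2·S(D)),        S(D) = exp(−αD − βD²),

extended to non-uniform dose by the equivalent-subvolume model: the survival
entering the formula is the generalized mean of exponent 1/c2 of the
per-voxel survivals (computed in log space; c2 → 0 is the cold-spot limit).
Defaults carry the published fit c1 = 2.4 [1.1, 3.7], c2 = 0.12 [0, 0.26],
α = 0.022 [0.016, 0.028] Gy⁻¹; 68% confidence intervals on TCP are
propagated by Monte Carlo over these bounds.

The clinical voxel data this kind of analysis runs on are not public, so the
package ships a seeded synthetic phantom generator (nested GTV / PTV-HD /
PTV-LD targets with realistic volumes, brain, optic nerves, a recurrence
region, a mucosa compartment) plus CIRT- and BNCT-like dose generators, and a
scenario pipeline reproducing the structure of a published clinical analysis:
primary-tumour comparison, recurrence re-treatment, and combined
CIRT + BNCT plans.  Who is it for: medical-physics researchers exploring
multi-modality dose bookkeeping and TCP-based plan comparison.

## Worked example

```bash
isodose run-primary --seed 0 --outdir demo_out
```

prints

```
[primary] report hash c8f964c4eae682fcb4d29789e7378fb13ee51eb082c0c81ef0c1e8e1e4837e48
modality    roi       hi
    CIRT PTV-HD 0.121607
    CIRT    GTV 0.093965
    BNCT PTV-HD 0.503730
    BNCT    GTV 0.300097
TCP_GTV_BNCT: 0.665 [0.516, 0.778]
TCP_GTV_CIRT: 0.340 [0.171, 0.526]
TCP_GTV_fixed_RBE: 1.000 [0.999, 1.000]
```

Reading this: the carbon-ion plan is far more uniform in the gross tumour
volume (homogeneity index (D2 − D98)/Dmean ≈ 0.09 vs ≈ 0.30 for BNCT — an
epithermal neutron field inevitably attenuates with depth), yet BNCT's
boron-mediated dose escalation yields the higher tumour control probability
(0.665 vs 0.340, with 68% CIs from the TCP-parameter uncertainty).  The last
row is the traditional fixed-RBE/CBE comparator: multiplying the four
absorbed components by fixed factors drives the nominal TCP to ≈ 1.0,
the kind of unrealistically certain prediction the isoeffective formalism
avoids.  Each BNCT application is scaled so the maximum mucosa absorbed dose
is exactly 6 Gy (here ≈ 24 min of irradiation per session).

`demo_out/` then contains the per-ROI D98/mean/D2 tables, DVH CSVs, all dose
grids in a portable JSON-header + raw-payload format, and a manifest with the
config hash; `isodose run-recurrence` and `isodose run-combined` cover the
other two scenarios, `isodose generate` dumps the raw phantom and plan
grids, and `--config config.yaml` overrides any parameter block
(see `examples/config.yaml`).

Everything is importable as a library too:

```python
from isodose import tcp_nonuniform, TCPParameters
tcp_nonuniform([22.0, 26.0, 31.0], voxel_volume=1.0, params=TCPParameters())
```

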