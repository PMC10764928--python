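# Example configuration: every block is optional and overrides the defaults
# documented in docs/methods.md.

phantom:
  seed: 0
  # volumes in cm^3; lattice is 24x24x24 voxels of 1 cm^3 by default

cirt:
  ld_prescription: 38.7   # Gy (IsoE;C12), 9 fractions to PTV-LD
  hd_prescription: 30.1   # Gy (IsoE;C12), 7 fractions to PTV-HD
  noise_sigma: 0.035

bnct:
  ports: ["+z", "+y"]
  boron_ppm: {tumour: 52.5, mucosa: 30.0, skin: 22.5, other: 15.0}

radiobiology:
  alpha_R: 0.022          # reference photon LQ terms
  beta_R: 0.0022
  a_boron: 0.04           # healthy-tissue boron effect coefficient [/Gy]
  boron_by_tissue: {tumour: 0.12}

constraints:
  mucosa_limit: 6.0       # absorbed Gy per BNCT application
  sessions: 2

tcp_model:
  c1: 2.4
  c2: 0.12
  alpha: 0.022

pipeline:
  n_tcp_samples: 10000
  nerve_tolerance: 12.0   # Gy (IsoE) per application, placeholder
  seed: 0
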