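# nemaflow

Modelling and quantification toolkit for endothelial-monolayer flow
adaptation, built around the analogy with a dual-frequency nematic liquid
crystal:

- **`nemaflow.dielectric`** — frequency-dependent permittivities of a
  dual-frequency nematic (single-relaxation law for the long axis), the
  anisotropy zero-crossing and a Freedericksz-threshold check.
- **`nemaflow.simulator`** — Landau–de Gennes Q-tensor gradient flow on a 2D
  lattice under a constant-amplitude field whose coupling is the
  frequency-dependent anisotropy. Supports rod-like (B = −1) and disk-like
  "senescent" (B = +1) mixtures, full or species-decoupled elastic bonds,
  frequency-switch protocols (`fig3a`, `fig3b`, `fig4a`, `fig4b`), order
  heat-maps, free-energy traces and senescent-fraction sweeps.
- **`nemaflow.monolayer`** — moment-equivalent ellipse fits of segmented
  cell outlines, aspect ratio, orientation angles folded to [0°, 90°], and
  the experimental order parameter S = ⟨cos²θ⟩ − 1/3.
- **`nemaflow.pcp`** — planar-cell-polarity index: Voronoi (nearest-nucleus)
  assignment of Golgi detections, distance-weighted Golgi positions, and the
  nucleus→Golgi angle φ versus flow with index cos φ (upstream polarity ⇒
  index → −1).
- **`nemaflow.flowfield`** — velocity magnitude, drift subtraction,
  isotropically binned spatial velocity correlation with an exponential fit
  for the correlation length, the 10 µm h⁻¹ migration threshold, and Butler
  strain energy of traction/displacement pairs.
- **`nemaflow.synth`** — seeded generators for every input format with known
  ground truth: monolayers at a target order S*, nucleus/Golgi sets at a
  target polarization bias, Gaussian random fields with prescribed
  exponential correlation length, and traction/displacement pairs with
  closed-form strain energy.

## CLI

One entry point with per-task subcommands:

```bash
nemaflow simulate --protocol fig3a --config sim.yaml --out run/
nemaflow senescence-sweep --fractions 0,0.3,0.7,1.0 --replicates 3 --out sweep/
nemaflow synth monolayer --spec spec.yaml --out data/
nemaflow metrics --outlines data/cells.geojson --reference-deg 0 --out metrics/
nemaflow pcp --points detections.csv --flow-deg 0 --out pcp/
nemaflow flowfield --field vel.npz --max-r 200 --out flow/
nemaflow energy --traction t.npz --displacement d.npz --out energy.csv
```

Every run writes a config echo, the RNG seed and a `manifest.json` with
sha256 checksums of all outputs; reruns with identical configuration are
byte-for-byte reproducible. Simulation configs and synthesis specs are YAML
files whose keys mirror the `SimulationConfig` / spec dataclasses; unknown
keys are rejected.

## Conventions

- Frequencies are angular (s⁻¹); no 2π factors anywhere.
- Orientation angles are measured counterclockwise from the reference axis
  and folded to [0°, 90°]; nematic directors are sign-free (n ≡ −n).
- The per-site scalar order is the signed uniaxial fit S = (3/2)·λ of the
  largest-magnitude eigenvalue of Q: prolate (rod-ordered) sites report
  S > 0, oblate (disk-like) sites report S < 0.
- Strain energy is reported in joules (tractions in Pa, displacements and
  grid spacings in µm); the ½ prefactor can be disabled per call.
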