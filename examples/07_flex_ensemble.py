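"""Rigid-body flexibility of a dimer: ensemble simulation + PCA.

One monomer rocks as a rigid body about the interface pivot, with
rotations bounded at 13 degrees.  Two read-outs characterise the motion:
the distance distribution of the cross-monomer chlorophyll pair, and the
PCA eigenvalue spectrum of the moving-group coordinates (rigid rotations
about a point span a three-mode manifold).
"""

from pathlib import Path

from photosys import (EnsembleSpec, SyntheticSpec, estimate_max_angle,
                      pair_distance_series, parse_structure, pca_modes,
                      simulate_ensemble)
from photosys.synth import generate_dimer

out = Path("scratch_examples")
out.mkdir(exist_ok=True)
path, manifest = generate_dimer(SyntheticSpec(seed=0), out / "dimer.cif")
model = parse_structure(path)

moving = {c for c, g in manifest["grouping"].items() if g == "M2"}
spec = EnsembleSpec(moving_chains=moving, n_conformers=1000,
                    max_angle=13.0, seed=0)
ens = simulate_ensemble(model, spec)

summary = pair_distance_series(ens, [(("P", 888), ("P2", 888))])
s = summary.series[0]
print(f"cross-pair distance over {spec.n_conformers} conformers: "
      f"min {s.min:.1f}, mean {s.mean:.1f}, max {s.max:.1f} A")
centers, counts = s.histogram()
print("histogram (0.5 A bins):",
      ", ".join(f"{c:.2f}:{n}" for c, n in zip(centers, counts) if n))

modes = pca_modes(ens)
print(f"top-3 PCA variance fraction: {modes.top_k_variance:.3f}")
print(f"recovered angular bound: {estimate_max_angle(ens):.2f} deg "
      f"(simulated: {spec.max_angle} deg)")
print("\nThe ~20% spread of the pair distance shows why a fixed-geometry "
      "reading of any single cross-monomer distance overstates certainty: "
      "rigid-body rocking moves the pair by several Angstroms.")
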