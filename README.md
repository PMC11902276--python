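# ensdyn

Ensemble dynamics analysis for proteins and protein–DNA complexes: the
post-simulation toolchain used to dissect how a local chemical change (a
posttranslational modification, a mutation, a stiffened contact) reshapes the
collective dynamics and allosteric wiring of a complex such as DNA
polymerase β bound to gapped DNA.

The package operates on coordinate ensembles over coarse analysis nodes —
one Cα per protein residue, one backbone phosphorus per nucleotide — and
provides, for each labelled state and against a designated reference state:

* **Structural metrics** — RMSD after Kabsch superposition, per-node RMSF,
  radius of gyration, centre-of-mass distances, geometric hydrogen-bond
  detection (d(D···A) ≤ 3.5 Å, ∠H-D-A ≤ 30°) and salt-bridge detection
  (min N···O ≤ 4 Å) with exact per-frame occupancy counting.
* **Essential dynamics** — the Cartesian covariance
  M = ⟨(r − ⟨r⟩)(r − ⟨r⟩)ᵀ⟩ of the superposed trajectory, its
  eigendecomposition, cosine-content screening of the leading components
  (only PCs with cosine content ≤ 0.1 enter landscapes), and free-energy
  surfaces G = −kT ln(P/P_max) over two principal components.
* **LMI cross-correlation** — the generalized correlation
  C_ij = (1 − e^(−2 I_ij / 3))^(1/2) with I_ij = H_i + H_j − H_ij, the mutual
  information of two 3-D node fluctuation vectors under a Gaussian model;
  unlike the Pearson cross-correlation map it does not miss correlated
  motion in orthogonal directions. C is 0 for independent motion, 1 for an
  exact copy, and equals |ρ| for isotropic per-axis correlation ρ.
* **Correlation networks** — contact-filtered graphs with edge weight
  −ln C_ij, Brandes weighted betweenness centrality
  BC_i = Σ_ab n_ab(i)/g_ab normalized by (N−1)(N−2)/2, and ΔBC maps against
  the reference with the conventional ±0.1 flagging band.
* **ANM / PRS** — anisotropic-network-model Hessians (12 Å spring cutoff),
  slow-mode truncated covariances (default 20 non-zero modes), and
  perturbation response scanning ΔR = H⁻¹F with exact isotropic-force
  averaging, yielding effector (influence) and sensor (sensitivity)
  profiles averaged over representative frames.

Because real microsecond trajectories are neither shippable nor analytically
characterized, the package ships a synthetic-ensemble generator
(`ensdyn.synth`) that draws frames from the Gaussian implied by a toy
complex's own ANM — so the true covariance, true LMI matrix and true
fluctuations are known in closed form and every stage is validated against
ground truth.

## Worked example

```python
import numpy as np
from ensdyn import synth, metrics, lmi, network, anm

spec = synth.ToyComplexSpec(n_protein_nodes=60, n_dna_nodes=8)
model = synth.build_toy_complex(spec)
sel = synth.toy_selection(spec)
ens, truth = synth.sample_anm_ensemble(
    model, n_frames=2000, temperature_scale=0.5, seed=1, selection=sel)

rmsd = metrics.rmsd_series(ens, model.coordinates,
                           measure_selection=range(sel.n_protein))
print("protein RMSD:", metrics.mean_sd_string(rmsd), "A")

C = lmi.lmi_matrix(ens).C
print("max |C - ground truth|: %.3f" % np.abs(C - truth.true_lmi_correlation).max())

graph = network.build_graph(C, ensemble=ens)
bc = network.betweenness(graph)
print("most central node:", int(bc.bc_normalized.argmax()),
      "(normalized BC %.3f)" % bc.bc_normalized.max())

prs = anm.prs_scan(anm.build_anm(model.coordinates))
print("top effector node:", int(prs.effector_profile.argmax()))
```

prints

```
protein RMSD: 2.30 (0.80) A
max |C - ground truth|: 0.037
most central node: 25 (normalized BC 0.332)
top effector node: 48
```

Protein RMSD is reported in the field's `mean (sd)` convention. The sampled
LMI matrix sits within 0.04 of the analytic matrix of the generating
covariance at 2,000 frames. The most central node bridges a third of all
shortest correlation paths; the top effector is the node whose perturbation
displaces the rest of the network most, relative to its self-response.

## Command line

```bash
ensdyn demo --seed 42 --out demo        # synthetic reference+perturbed fixture set
ensdyn run --config demo/config.yaml    # all stages, per-state and delta reports
ensdyn lmi --config demo/config.yaml    # one stage (dependencies run implicitly)
```

Outputs are tidy CSV tables and plain-text matrices plus a JSON manifest
with a config hash and per-file checksums; identical configs yield
bit-identical deterministic outputs.

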