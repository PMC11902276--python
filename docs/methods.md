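# Methods

This note records the models implemented in `ensdyn`, the estimators and
numerical conventions behind them, what the synthetic generator does and
does not emulate, and the design choices made where practice varies.

## Analysis nodes and units

All coordinates are ångströms internally (PDB native); nm inputs must be
converted at the boundary. The analysis operates on coarse nodes: one Cα
pseudo-atom per protein residue and one backbone P atom per nucleotide,
ordered protein-first by (chain, resid). Residues lacking the node atom
(e.g. a 5′-terminal nucleotide without a phosphate) are skipped with a
warning rather than an error — the node set is defined by the atoms present.
Residue numbers are 1-based as in PDB files; node indices are 0-based and
reports always print resids. Trajectories travel as multi-model PDB or a
plain whitespace frame table; binary MD formats are deliberately out of
scope so the package is testable without simulation infrastructure.

## Superposition, RMSD, RMSF

Rigid fits are least-squares Kabsch transforms with proper rotations
(det +1). The scalar path uses SciPy's `align_vectors` with optional
per-node weights; whole-ensemble fits use a batched 3×3-SVD implementation
that is bit-compatible with the scalar path and ~50× faster at large frame
counts. RMSD series fit on the measured selection by default (the behaviour
of the standard single-group tools); fit and measure selections are
independently configurable. RMSF superposes every frame onto the iteratively
converged ensemble mean (tolerance 1e-6 Å on the mean).

The converged mean's orientation is a gauge: it is only pinned when an
external `reference` structure anchors the first fit. Covariance and RMSF
therefore accept a reference (the pipeline passes the starting structure),
which makes both invariant under a global rigid transform of the input
trajectory; without a reference the covariance is defined up to an
orthogonal conjugation (its spectrum, RMSF and LMI are unaffected).

## Interaction criteria and occupancies

Hydrogen bond: donor–acceptor distance ≤ 3.5 Å and, when a hydrogen
position is supplied, hydrogen–donor–acceptor angle ≤ 30°; with no hydrogen
the distance decides alone. This is the gmx hbond convention; descriptions
of the angle as measured ">30°" between donor and acceptor circulate in the
literature but contradict the tool they cite, and the tool's convention is
implemented. Salt bridge: minimum distance over the listed side-chain
nitrogen (Arg NH1/NH2/NE, Lys NZ) and oxygen (Glu OE1/OE2, Asp OD1/OD2)
atoms ≤ 4.0 Å — no cutoff is universal in the literature; 4 Å is the
conventional choice and is configurable. Every threshold in the package is
inclusive (≤ / ≥). Occupancies are exact integer counts n_true/n_frames;
the percent rendering trims trailing zeros but keeps one decimal
("73.0", "73.04"), matching the common table style.

## Essential dynamics

The covariance uses the population divisor F (matching the ensemble-average
definition) and no mass weighting — node masses are near-uniform for Cα and
the choice is configurable. Eigenvectors carry a reproducible sign
convention (largest-magnitude component positive). Projections are computed
from frames re-fitted onto the covariance's mean, so the variance of
projection k equals eigenvalue k to round-off.

Cosine content of a projection p_t, t = 0..F−1, is
c = (2/F)(Σ_t p_t cos(πt/F))² / Σ_t p_t² — the squared overlap with the
first half-period cosine. Diffusion-like, unconverged sampling gives c near
1; components used for landscapes must pass c ≤ 0.1, and landscape PCs are
the two highest-variance passing components among the first 20. Fewer than
two passing components is an error whose remedy is longer sampling, not a
silent fallback.

The free-energy landscape is the histogram estimate G = −kT ln(P/P_max)
over a 32×32 grid by default, in kT units (kT = 1, since only relative
basin depths are meaningful here). Empty bins are masked, never zero; the
occupied minimum is exactly 0.

## Linear mutual information

Entropies are Gaussian differential entropies in nats,
H = ½ ln[(2πe)^k det Σ], with Σ the 3×3 marginal (k = 3) or 6×6 joint
(k = 6) sample-covariance block — the Gaussian plug-in estimator is what
makes the measure *linear*. I_ij = H_i + H_j − H_ij, clipped at 0 against
round-off, and C_ij = (1 − e^(−2I/3))^(1/2) with d = 3 Cartesian dimensions
per node. Block diagonals are regularized by ε·trace(M)/3N with ε = 1e-8
before determinants, which perturbs C by ≲1e-7 on unit-scale data.

Degeneracy: when one node is an exact linear copy of another the joint
block is singular and the mutual information diverges. The singularity is
detected on the *unregularized* joint determinant (ratio ≤ 1e-12 against
the marginals' product), mapped to an infinite-information sentinel, and
C = 1 exactly — so the fully-correlated limit is exact rather than
1 − O(ε). Self-correlation C_ii = 1 by the same convention (continuous
self-information diverges; documented, not computed). Only the Gaussian
estimator is provided; k-NN or histogram mutual-information estimators and
time-lagged correlation are out of scope.

## Correlation networks and betweenness

Edges require physical contact — node–node distance ≤ 10 Å in ≥ 75 % of
frames (both configurable, recorded in the graph metadata) — which prevents
the complete graph on which betweenness degenerates; sequence adjacency
alone never creates an edge. Edge weight is −ln C_ij with C clipped to
[1e-6, 1−1e-6], the standard dynamical-network transform making strongly
correlated pairs short hops. Betweenness is Brandes' weighted algorithm
(via NetworkX), endpoints excluded, equal-weight shortest paths split
fractionally; it is validated against exhaustive all-simple-paths
enumeration. Normalization divides by (N−1)(N−2)/2, and ΔBC (state −
reference, on normalized values) flags nodes beyond ±0.1. A disconnected
graph is a warning, with betweenness computed per component. Exact
floating-point weight equality decides path ties; with continuous sampled
correlations exact ties are measure-zero, and the enumeration oracle uses a
1e-9 relative band.

## ANM and perturbation response scanning

The ANM Hessian uses uniform springs γ = 1 (all reported quantities are
normalized and γ-invariant) within a 12 Å cutoff: off-diagonal super-element
−γ/|d_ij|² · d_ij d_ijᵀ, diagonal blocks minus the row sums. Connectivity is
checked on the spring adjacency graph; a connected, non-collinear node set
has exactly six near-zero modes (≤ 1e-8 × λ_max), asserted as a tested
property. (Collinear chains are admitted for closed-form tests; they carry
additional transverse zero modes, which is why connectivity is not defined
by mode counting.)

The PRS covariance truncates the pseudo-inverse to the slowest 20 non-zero
modes by default — the energetically dominant collective motions; with all
modes it equals the Moore–Penrose pseudo-inverse. The response of node j to
a unit force at node i, averaged over isotropic force directions, is
evaluated in closed form, ⟨|ΔR_j|²⟩ = (1/3)‖C_ji‖²_F (for a uniformly
distributed unit force E[ffᵀ] = I/3); Monte-Carlo direction sampling is
retained for validation and agrees within 2 % at 10⁴ directions. Rows are
normalized by the self-response, making the map independent of γ and of the
force magnitude; effector and sensor profiles are off-diagonal row and
column means. Ensemble-averaged PRS builds one ANM per representative frame
(100 evenly spaced by default) and averages the normalized maps,
skipping — with a warning — frames whose network is disconnected.

## Synthetic ensembles and what passing tests show

`build_toy_complex` places protein nodes on a helix whose per-residue turn
angle is solved from (radius 2.3 Å, pitch 5.5 Å, consecutive spacing
3.8 Å), and DNA P nodes on a parallel line 9.5 Å from the axis at 7.0 Å
steps (the B-DNA P–P rise); geometry is rejected if any two nodes fall
within 1 Å. `sample_anm_ensemble` draws i.i.d. frames from the zero-mean
Gaussian with covariance = scale × pseudo-inverse of the complex's own ANM
Hessian, sampled in internal-mode space so rigid-body modes carry exactly
zero variance; the returned ground truth holds that covariance and the
closed-form LMI matrix derived from it. Designed binary event series
realize prescribed H-bond/salt-bridge occupancies exactly, either packed
("block") or i.i.d. ("bernoulli"); correlated node pairs realize a chosen
per-axis Gaussian correlation whose closed-form LMI correlation is |ρ|.

The default generator conditions used throughout the validation suite are a
scaled-down 60 Cα + 8 P complex at temperature scale 0.5 Å² (sub-ångström
node fluctuations, comparable to a stable fold); convergence checks use
50,000 frames, qualitative checks 2,000. The full-size 326 + 28 = 354-node
selection is exercised where only counting matters. Every stochastic
operation takes an explicit integer seed; there is no global RNG state.

What the generator does *not* emulate: force-field energetics, anharmonic
and multi-basin dynamics, solvent and ions, temporal autocorrelation
(frames are i.i.d., so cosine-content screening trivially passes), and the
chemistry of the modification itself — a perturbed state is modelled as
locally rescaled spring stiffnesses. Passing tests therefore demonstrate
correctness of the estimators and transforms against known statistical
structure, not fidelity of any particular biomolecular interpretation;
headline values from real trajectory studies (specific RMSDs, occupancy
percentages, variance fractions) are trajectory-specific and are used here
only as reporting-format templates.

## Pipeline and reproducibility

Stages run in dependency order (metrics → pca → lmi → network → prs);
requesting a stage pulls in what it needs (network implies lmi) and the
manifest records what actually ran, all output checksums, a config hash and
every warning raised (skipped atoms, disconnected frames, unconverged PCs).
All randomness flows from the single config seed. The demo fixture pairs a
reference ensemble with a perturbed one whose springs around two designated
nodes are stiffened 5×, mirroring a two-site local-modification comparison
design.

## Known limitations

* The Gaussian LMI estimator is exact only for Gaussian fluctuations; on
  strongly anharmonic data it is a lower-bound-style approximation.
* Contact filtering uses node–node (not heavy-atom) distances, a coarser
  notion of contact than all-atom definitions.
* Betweenness on near-complete contact graphs concentrates on few nodes;
  interpretation should always accompany the edge-count metadata.
* No altloc handling beyond the first conformer, and no chemistry-aware
  donor/acceptor perception — monitored pairs are declared explicitly.
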