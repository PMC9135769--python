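# Methods

This note records the models implemented by topofold, the defaults and
numerical choices behind them, and what the synthetic generators do and do
not emulate.

## Geometry substrate

Structures are read from PDB files through gemmi into lightweight
chain → residue → atom containers addressed by author residue numbers
(no renumbering). Alternate locations keep the highest-occupancy atom, ties
resolved toward the lexicographically smallest altloc identifier;
hydrogens are dropped unless requested. "Backbone" throughout means the
N, CA, C atom triplet — the minimal conventional set; O is excluded. Any
selection that touches a missing atom raises rather than silently dropping
it, because silent loss changes the meaning of every RMSD downstream.

Superposition is the closed-form Kabsch solution (SVD of the
cross-covariance with a determinant correction, so the rotation is always
proper). Fewer than 3 points or a collinear point set is rejected; the
independent cross-check in the test suite is scipy's `Rotation.align_vectors`
plus a random-rotation search confirming no sampled rotation beats the
analytic optimum.

## Rewiring and junction geometry

N segments admit N·(N−1)! = N! orderings; circular permutations are already
contained in that count and segments are never direction-reversed.
Enumeration is lexicographic over segment labels for determinism.

A junction gap is the Euclidean distance between the backbone **C** atom of
the preceding segment's last residue and the backbone **N** atom of the
following segment's first residue, measured on the unmoved template (it is
an N–C distance, not Cα–Cα). The suggested loop length is
⌈gap / 3.5 Å⌉ floored at 1. The 3.5 Å per-residue span sits just below the
fully extended 3.8 Å Cα–Cα spacing — a loop residue cannot quite bridge its
extended length once bond geometry is paid for — and maps a 10 Å gap to 3
residues and a 13 Å gap to 4.

## Loop alphabets, ranking, splicing

The built-in alphabets are the 9-letter {G, D, P, S, L, N, T, E, K} for
3-residue loops and the 8-letter {G, D, P, S, L, N, T, K} for 4-residue
loops (E is omitted at length 4 to shrink the space). G, D, P, S, T carry
high loop propensity, L is common in helix–helix turns, and E, D, K are
helix-cappers. Enumeration is the full Cartesian power, sorted
lexicographically.

Scoring is pluggable: the intended scorer computes S_h on a per-candidate
conformational ensemble supplied by the caller (ensembles in, ranking out —
no simulation engine is embedded). "Most stable" means lowest S_h. Ties at
the top-k cutoff break lexicographically by sequence so selection is
reproducible. Splicing is the exact Cartesian product of the two junctions'
shortlists, outer loop on junction 1.

## Conformational homogeneity S_h

S_h = Σ_{i≠j} S_RMSD(i,j) / N² over an ensemble's N frames, where
S_RMSD(i,j) is the Kabsch-superposed RMSD between frames i and j over the
chosen selection (default: all backbone atoms). The denominator N² is used
literally even though only N² − N ordered pairs contribute; a
`denominator="pairs"` flag provides the plain mean over pairs (÷ N(N−1))
for callers who want an unbiased average — the two differ by the factor
(N−1)/N. Superposition uses the whole selection, not loop atoms only.

## Radial distribution function and ruggedness

g(r) is the pairwise-distance histogram of the selected atoms normalised by
the uniform-density expectation ρ·4πr²Δr, with ρ = n/V. Two choices were
genuinely open and are fixed as follows:

* **Reference volume** — the convex hull of the selection by default
  (rotation invariant, no box assumption), overridable via `volume=` when
  the enclosing volume is known. The hull of a sparse sample underestimates
  its generating volume by a few percent, biasing g slightly upward; pass
  the true volume when you have it.
* **Boundary correction** — the fraction of a radius-r shell falling inside
  an equal-volume sphere, 1 − 3r/(4R) + r³/(16R³). This keeps g ≈ 1 for
  finite uniform clouds without introducing a rotation-dependent bounding
  shape.

Default selection for packing analysis: side-chain heavy atoms of buried
residues, with burial proxied by CA neighbour count ≥ 16 within 10 Å
(configurable). Ruggedness is the total variation Σ|g_{i+1} − g_i| over the
bins spanning 0–4 Å with 0.1 Å bins — over a histogram this is exactly the
discretisation of ∫₀⁴ |dg/dr| dr.

## Epitope RMSD and ensemble deviation

Epitope RMSD superposes on the epitope atoms only (local alignment) and
reports the RMSD over those same atoms; backbone mode uses N/CA/C, all-atom
mode all heavy atoms with residue-identity checking. The default epitope is
the site II residue set (16, 19, 20, 22, 23, 27, 109, 112 on chain A).

Ensemble deviation superposes all frames onto frame 1, averages
coordinates, and reports the mean plain RMSD of each superposed frame to
that average. A two-pass option re-superposes onto the evolving mean; the
single pass is the default because it is deterministic and the two differ
negligibly for compact ensembles.

## SPR kinetics

The association phase under a 1:1 interaction model is
Γ(t) = Γ_GG(1 − e^(−k_obs t)), fit as Γ(t) = c + a·e^(−b·t) by Nelder–Mead
minimisation of the reduced chi-square χ² = Σ(Γ_fit − Γ_obs)²/(n − p),
p = 3, at tolerance 10⁻¹² and up to 10⁶ iterations, within the open bounds
a ∈ (−700, 0) RU, b ∈ (10⁻⁴, 10⁻¹) s⁻¹, c ∈ (0, 700) RU. Bounds are
enforced by projecting proposals onto the interval interior with a 10⁻⁹
margin. Initialisation is scale-aware and deterministic: c₀ = final
observed response, a₀ = −c₀, b₀ = 1/t₆₃ (time to 63% of the final
response), each clamped into bounds. Non-convergence returns the
best-so-far parameters flagged `converged=False`.

k_obs = b is then regressed on concentration by ordinary least squares
(slope k_a, intercept k_d), K_d = k_d/k_a exactly, and dispersions come
from N leave-one-concentration-out refits of the line:
s = √(Σ(xᵢ − x̄)²/(N − 1)) for each of k_a, k_d, K_d. A negative intercept
(unphysical k_d) is flagged, never clamped. Reported K_d values are rounded
to 2 significant figures. Only association-phase data are modelled;
dissociation-phase points and instrument-side double-referencing are
expected to be handled upstream (a simple reference-subtraction helper is
included).

## Synthetic generators

The generators exist so every pipeline is exercised end-to-end without
external data, and their defaults are the study conditions used by the
tests and the acceptance script:

* **Helices/bundles** — textbook ideal α-helix geometry (1.5 Å rise, 100°
  twist, 2.3 Å Cα radius), with N and C atoms placed at standard bond
  lengths (CA–C 1.52 Å, N–CA 1.46 Å, peptide C–N ≈ 1.33 Å) by a symmetric
  tilt off the Cα–Cα line. Bundles place helices on parallel axes (default
  spacing 10 Å) alternating up/down. Not emulated: supercoiling, side
  chains, sequence-dependent geometry.
* **Ensembles** — i.i.d. Gaussian coordinate noise per frame, amplitude =
  per-coordinate standard deviation in Å. This exercises the ordering
  behaviour of S_h and deviation metrics; it has none of the correlated,
  anisotropic motion of real conformational ensembles, so passing tests
  show metric correctness, not realism of dynamics.
* **Titrations** — exact 1:1 association curves with optional Gaussian
  read noise; defaults mirror a multi-cycle acquisition (180 s window,
  900 points per curve, five 2-fold steps from 5 nM). Mass transport,
  drift, regeneration artefacts and 2:2 binding are not simulated, which is
  why noise-free recovery of the generating rates is exact rather than
  approximate.

All generators are deterministic under a fixed seed.

## Problem sizes

Tests and the acceptance script run the full published-scale problems where
they are cheap (729/4096-sequence enumerations, 2500-pair splices, 24-plan
rewirings, 900-point five-curve titrations) and compact ensembles (≤ 20
frames of ≤ 76 residues) for the geometry metrics, which exercise the same
code paths as larger ensembles at identical numerical behaviour.

## Known limitations

* Loop candidates are ranked, not built: no loop backbone coordinates are
  generated, and sequence design/refinement around a rewired scaffold is
  out of scope.
* The RDF normalisation is a declared convention (hull volume +
  equal-volume-sphere edge correction); absolute g values depend on it,
  though the ruggedness comparison between structures of similar size is
  insensitive to the choice.
* The SPR module fits association only and assumes pre-referenced data;
  K_d values for avid, bivalent, or transport-limited interactions are
  apparent constants.
* mmCIF writing, ligand chemistry and symmetry expansion are unsupported.
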