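# Methods

## Model

The protein is coarse-grained to one node per residue at its Cα
position. Nodes closer than a cutoff r_c are joined by identical
harmonic springs (spring constant γ), giving the Kirchhoff matrix Γ —
the graph Laplacian of the contact graph. We use the standard
positive-semidefinite convention (positive diagonal equal to the
contact count times γ, off-diagonal −γ for contacts); the equivalent
global negation, with the diagonal written as the negative row sum,
changes no fluctuation quantity because only λ⁻¹ u uᵀ of the spectrum
enters. The contact test is a strict inequality on the Euclidean
distance; a residue at exactly r_c is not in contact.

Within the harmonic (Gaussian) approximation, cross-correlations of
residue fluctuations are

    ⟨ΔR_i · ΔR_j⟩ = (kT/γ) Σ_k λ_k⁻¹ u_ki u_kj

summed over non-rigid modes; over all of them this is kT/γ times the
Moore–Penrose pseudo-inverse of Γ. Rigid-body modes (one zero
eigenvalue per connected component) carry no fluctuation content and
selecting them is an error, not a silent zero.

The analysis here deliberately keeps only the largest-eigenvalue mode.
Two properties justify this: the fast mode is spatially localized on
the most tightly packed residues, and the top eigenvalue of a graph
Laplacian is the most sensitive to perturbations of the graph, so the
fast mode is where energetic coupling concentrates. The spring-length
fluctuation of a contact, C_ii + C_jj − 2C_ij ≥ 0, measures the share
of exchanged energy stored in that contact; it is large only for
anti-correlated pairs (for the rank-1 fast-mode correlation,
sign(C_ij) = sign(u_i u_j) exactly). The importance statistic

    D_i = (kT/γ) Σ_{j in contact with i} (u_i − u_j)² / λ_max

sums these over residue i's contacts. Note that the plain row sum of
the rank-1 fast-mode correlation matrix is identically zero (every
non-rigid eigenvector is orthogonal to the constant zero mode), so the
contact-restricted sum is the only self-consistent reading of "sum of
the distance fluctuations of the bonds the residue makes". An
`all_pairs` variant extends the sum over all j ≠ i; by orthonormality
it equals (kT/γ)(n u_i² + 1)/λ_max, so it ranks residues exactly like
u_i² and is mostly useful as an analytic cross-check.

Gate/hub classification uses contact degree as a surface proxy: the
model is Cα-only, so no solvent-accessible surface is computed. A
top-k residue whose degree is strictly below the configurable quantile
(default median) of the degree distribution is labelled a gate
(loosely packed, exposed), otherwise a hub (buried). These labels are
heuristics for interpretation, not calibrated predictions.

Interaction pathways are the connected components (size ≥ 2) of the
contact subgraph induced on the top-k residues, ordered by
breadth-first traversal from the lowest-numbered tip (degree ≤ 1)
node. Cyclic components have no tips; their traversal starts at the
lowest-numbered member and their endpoints are the traversal's first
and last nodes.

## Perturbation response

Stiffening the contacts of residue i by a fraction δ multiplies the
nonzero off-diagonal entries of row and column i of Γ by (1 + δ). The
diagonal is then rebuilt so each row sums to zero again: stiffer
springs still form a consistent Laplacian, and without the rebuild the
rigid-body mode is destroyed and D jumps discontinuously at δ → 0.
(The alternative, leaving the diagonal fixed, is available as
a sensitivity study by perturbing the matrix directly, but is not a
supported default.) The response Δ_i D_j is the finite difference of D
computed by a full re-analysis of the perturbed network — no
first-order shortcut — so the linearity of the response is an
empirical property to be checked, not an assumption. `linearity_check`
reports ‖response(δ)‖ normalized by the smallest-δ response and flags
deviations beyond 10%.

Paired structures are compared by subtracting response profiles
residue-by-residue, matched on (chain, author number, insertion code).
This presumes consistently numbered structures, e.g. allele pairs of
the same protein; sequence alignment is out of scope, and unmatched
residues are reported rather than dropped.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `cutoff` | 7.0 Å | contact radius; ≈ first coordination shell of Cα atoms |
| `gamma` | 1 | spring constant; all outputs are in kT/γ units, so only ratios matter |
| `kT` | 1 | thermal energy scale, same remark |
| `variant` | `contact_sum` | D restricted to contacts (the method's definition) |
| `top_k` | 10 | residues labelled/used for pathway extraction |
| `delta` | 0.01 | perturbation fraction; 1% sits in the linear regime for well-separated fast modes |
| `surface_degree_quantile` | 0.5 | degree quantile below which a top residue counts as surface |

## Numerical choices

- Eigendecomposition is dense (`numpy.linalg.eigh`); structures of a
  few hundred residues decompose in milliseconds, so no sparse or
  partial solver is warranted.
- Zero modes are eigenvalues below 1e-9 × λ_max (scale-free cutoff);
  spring fluctuations may round off slightly negative and are clamped
  to zero only within −1e-12.
- If the top eigenvalue is degenerate within a relative gap of 1e-6,
  the "max" selection sums the whole degenerate subspace and logs a
  warning: rankings computed from one arbitrary member of a degenerate
  pair are meaningless. Perturbation responses computed near a
  degeneracy carry a flag.
- Ranking ties are broken by ascending author residue number, after
  quantizing D at 1e-9 relative resolution so that symmetry-equivalent
  residues (equal up to round-off) count as tied. All orderings are
  deterministic.
- The Laplacian row-sum invariant holds exactly in the sense that the
  diagonal is the exact floating-point negation of the off-diagonal
  row sum; re-summing a full row in a different order shows rounding
  of order 1e-16.

## Synthetic structures

The generator produces three geometries: collinear chains (contact
topology forced by spacing), rings (circulant contact graphs with the
closed-form Laplacian spectrum 2γ(1 − cos 2πk/n), used as an exact
spectral oracle), and packed clusters — seeded rejection sampling in a
sphere with a minimum pairwise distance of 3.8 Å (the Cα virtual bond
length) and a radius sized for 25% sphere packing, which reproduces
the mean contact degree of folded proteins at the 7 Å cutoff (≈ 6–7).
Identical arguments always give bit-identical coordinates.

What the clusters do not emulate: chain connectivity (no backbone
path), secondary structure, the anisotropic shape of real domains, and
— importantly — the spectral structure of folded proteins. Random
clusters have fast-mode spectral gaps of only a few percent of λ_max.
Consequences: tests passing on clusters validate the algebra and the
contracts, not the biological discrimination of the method; and the
1%-perturbation response on clusters is *not* uniformly in the linear
regime. The second-order error of the response grows like
δ·‖ΔΓ‖/(λ_max − λ_{n−1}), so residues that load the fast mode of a
small-gap network show 1%→2% doubling ratios deviating by 10% or more,
with occasional top-mode crossings producing larger excursions. The
ratio converges to 2 as δ → 0 (at δ = 0.001→0.002 it is within ~1%),
which is what the test suite asserts quantitatively; on the real HLA
structures the fast mode is set by the specific packing around the
disulfide-bonded core, and the doubling is cleaner for the pathway
residues one actually perturbs.

## Problem sizes

The default test and reproduction runs use clusters of n = 30–50 (20
clusters for the linearity study), 50 random contact graphs of n ≤ 50
for the pseudo-inverse identity, and rings of n = 6–24 for the exact
spectra; the real-structure analysis uses the ~276-residue HLA heavy
chain A. These sizes make every quantity reproducible in seconds while
leaving the conclusions unchanged at larger n.

## Known limitations

- Isotropic GNM only: no 3n × 3n Hessian, no directional fluctuations,
  no distance-dependent spring constants.
- Single conformer: first model of a multi-model file, altloc 'A' or
  blank only.
- The surface/buried call is a degree heuristic; residues at domain
  interfaces can be mislabelled.
- Pair comparison requires shared author numbering; no alignment.
- The ten-structure HLA-B27 reference set is downloaded on demand
  (public PDB entries), not bundled.
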