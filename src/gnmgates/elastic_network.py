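"""Kirchhoff matrix construction and spectral analysis.

The Gaussian network model treats the protein as an elastic network:
each pair of alpha carbons closer than a cutoff (7 Å by default, the
radius of the first coordination shell) is joined by a harmonic spring
of force constant γ. The resulting connectivity (Kirchhoff) matrix Γ is
the graph Laplacian of the contact graph, written here in the standard
positive-semidefinite convention:

    Γ_ij = -γ           if ‖R_i - R_j‖ < cutoff, i ≠ j
    Γ_ij = 0            otherwise (i ≠ j)
    Γ_ii = γ × (number of contacts of i)

so that every row sums to zero and Γ has exactly one zero eigenvalue
per connected component. Cross-correlations of residue fluctuations are
⟨ΔR_i·ΔR_j⟩ ∝ (Γ⁻¹)_ij restricted to the non-rigid modes; restricting
further to the largest-eigenvalue mode gives the localized, perturbation-
sensitive fluctuations used for residue-importance analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .exceptions import NumericalError, ValidationError
from .structure_io import CoarseGrainedStructure, ResidueRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ContactNetwork",
    "ModeSpectrum",
    "build_kirchhoff",
    "eigendecompose",
    "mode_correlation",
    "spring_fluctuation",
]

#: relative gap below which the top eigenvalue is treated as degenerate
DEGENERACY_RTOL = 1e-6

#: zero-mode threshold as a fraction of the largest eigenvalue
ZERO_MODE_RTOL = 1e-9


@dataclass
class ContactNetwork:
    """Kirchhoff matrix of a residue contact graph.

    Attributes
    ----------
    matrix : numpy.ndarray
        Symmetric ``(n, n)`` Laplacian; rows sum to zero.
    cutoff : float
        Contact cutoff in Å (strict inequality on Euclidean distance).
    gamma : float
        Spring constant (dimensionless; all fluctuations are reported
        in kT/γ units).
    index_map : list of ResidueRecord
        Internal index -> residue identity, in structure order.
    """

    matrix: np.ndarray
    cutoff: float
    gamma: float
    index_map: list[ResidueRecord] = field(repr=False)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        """Contact count of each residue."""
        return np.count_nonzero(self.matrix, axis=1) - (np.diag(self.matrix) != 0)

    @property
    def adjacency(self) -> np.ndarray:
        """Boolean contact map (off-diagonal sparsity pattern)."""
        adj = self.matrix != 0
        np.fill_diagonal(adj, False)
        return adj

    def contacts_of(self, i: int) -> np.ndarray:
        """Indices of residues in contact with residue ``i``."""
        return np.flatnonzero(self.adjacency[i])

    def index_of(self, residue) -> int:
        """Internal index from an identity tuple, author number or record."""
        if isinstance(residue, ResidueRecord):
            residue = residue.identity
        if isinstance(residue, tuple):
            for i, rec in enumerate(self.index_map):
                if rec.identity == residue:
                    return i
            raise ValidationError(f"residue {residue} not in network")
        for i, rec in enumerate(self.index_map):
            if rec.author_seq_number == int(residue):
                return i
        raise ValidationError(f"no residue with author number {residue}")

    def validate(self, atol: float = 1e-10) -> None:
        """Assert the Laplacian invariants (symmetry, zero row sums)."""
        if not np.allclose(self.matrix, self.matrix.T, atol=atol):
            raise ValidationError("Kirchhoff matrix is not symmetric")
        if not np.allclose(self.matrix.sum(axis=1), 0.0, atol=atol):
            raise ValidationError("Kirchhoff rows do not sum to zero")


@dataclass
class ModeSpectrum:
    """Eigenvalues and eigenvectors of a Kirchhoff matrix.

    Eigenvalues are ascending and nonnegative; column ``k`` of
    ``eigenvectors`` is the orthonormal mode paired with
    ``eigenvalues[k]``. The first ``zero_mode_count`` modes are the
    rigid-body (constant-per-component) modes and carry no fluctuation
    content.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray = field(repr=False)
    zero_mode_count: int
    kT: float = 1.0
    gamma: float = 1.0

    @property
    def n(self) -> int:
        return self.eigenvalues.shape[0]

    @property
    def lambda_max(self) -> float:
        return float(self.eigenvalues[-1])

    def top_mode_indices(self) -> list[int]:
        """Index of the largest-eigenvalue mode, expanded to the whole
        near-degenerate subspace when the top gap is below
        ``DEGENERACY_RTOL`` (rankings from one member of a degenerate
        pair are arbitrary)."""
        lam = self.eigenvalues
        top = lam[-1]
        idx = [self.n - 1]
        k = self.n - 2
        while k >= 0 and (top - lam[k]) / top < DEGENERACY_RTOL:
            idx.append(k)
            k -= 1
        if len(idx) > 1:
            logger.warning(
                "top eigenvalue is %d-fold near-degenerate; using the whole subspace",
                len(idx),
            )
        return sorted(idx)

    @property
    def top_mode_degenerate(self) -> bool:
        lam = self.eigenvalues
        return self.n >= 2 and (lam[-1] - lam[-2]) / lam[-1] < DEGENERACY_RTOL


def build_kirchhoff(
    structure: CoarseGrainedStructure,
    cutoff: float = 7.0,
    gamma: float = 1.0,
) -> ContactNetwork:
    """Build the Kirchhoff (connectivity) matrix of a structure.

    Two residues are in contact when their alpha carbons are separated
    by strictly less than ``cutoff`` Å.
    """
    n = len(structure)
    if n < 2:
        raise ValidationError(f"need at least 2 residues, got {n}")
    if cutoff <= 0:
        raise ValidationError(f"cutoff must be positive, got {cutoff}")
    if gamma <= 0:
        raise ValidationError(f"gamma must be positive, got {gamma}")

    dist = squareform(pdist(structure.positions))
    adj = dist < cutoff
    np.fill_diagonal(adj, False)

    matrix = -gamma * adj.astype(float)
    np.fill_diagonal(matrix, gamma * adj.sum(axis=1))

    isolated = np.flatnonzero(adj.sum(axis=1) == 0)
    for i in isolated:
        logger.warning(
            "residue %s has no contacts under cutoff %.2f Å (isolated node)",
            structure.records[i], cutoff,
        )
    return ContactNetwork(
        matrix=matrix, cutoff=cutoff, gamma=gamma, index_map=list(structure.records)
    )


def eigendecompose(network: ContactNetwork, kT: float = 1.0) -> ModeSpectrum:
    """Full eigendecomposition of the Kirchhoff matrix.

    Modes are returned ascending; eigenvalues below
    ``ZERO_MODE_RTOL × λ_max`` are counted as zero (rigid-body) modes —
    one per connected component of the contact graph.
    """
    if not np.allclose(network.matrix, network.matrix.T, atol=1e-10):
        raise ValidationError("Kirchhoff matrix is not symmetric")
    lam, vec = np.linalg.eigh(network.matrix)
    lam = np.where(np.abs(lam) < max(lam.max(), 1.0) * 1e-12, 0.0, lam)
    if lam[-1] <= 0:
        raise NumericalError("network has no nonzero modes (empty contact graph)")
    tol = ZERO_MODE_RTOL * lam[-1]
    zero_count = int(np.count_nonzero(lam < tol))
    lam[:zero_count] = np.maximum(lam[:zero_count], 0.0)
    return ModeSpectrum(
        eigenvalues=lam,
        eigenvectors=vec,
        zero_mode_count=zero_count,
        kT=kT,
        gamma=network.gamma,
    )


def _resolve_selection(spectrum: ModeSpectrum, mode_selection) -> list[int]:
    if mode_selection == "max":
        return spectrum.top_mode_indices()
    if mode_selection == "all_nonzero":
        return list(range(spectrum.zero_mode_count, spectrum.n))
    if isinstance(mode_selection, (int, np.integer)):
        k = int(mode_selection)
        if not 0 <= k < spectrum.n:
            raise ValidationError(f"mode index {k} out of range [0, {spectrum.n})")
        if k < spectrum.zero_mode_count:
            raise ValidationError(
                f"mode {k} is a rigid-body mode and has no fluctuation content"
            )
        return [k]
    raise ValidationError(
        f"mode_selection must be an int, 'max' or 'all_nonzero', got {mode_selection!r}"
    )


def mode_correlation(spectrum: ModeSpectrum, mode_selection="max") -> np.ndarray:
    """Residue cross-correlation matrix from a mode selection.

    Returns ``C = kT/γ × Σ_k λ_k⁻¹ u_k u_kᵀ`` over the selected nonzero
    modes. With ``"all_nonzero"`` this is kT/γ times the pseudo-inverse
    of Γ; with ``"max"`` it is the rank-1 (or degenerate-subspace)
    fast-mode correlation used for importance analysis.
    """
    selection = _resolve_selection(spectrum, mode_selection)
    lam = spectrum.eigenvalues[selection]
    U = spectrum.eigenvectors[:, selection]
    scale = spectrum.kT / spectrum.gamma
    return scale * (U / lam) @ U.T


def spring_fluctuation(correlation: np.ndarray, i: int, j: int) -> float:
    """Mean-square fluctuation of the spring length between residues i, j.

    ``⟨(ΔR_i - ΔR_j)²⟩ = C_ii + C_jj - 2 C_ij``; this is the share of
    the energy exchanged with the surroundings that is stored in the
    i–j contact, and is nonnegative (tiny negative round-off is clamped
    to zero).
    """
    value = correlation[i, i] + correlation[j, j] - 2.0 * correlation[i, j]
    if value < -1e-12:
        raise NumericalError(
            f"spring fluctuation ({i},{j}) = {value} is negative beyond round-off"
        )
    return max(value, 0.0)
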