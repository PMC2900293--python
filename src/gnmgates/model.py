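"""Model/results front end for the Gaussian network analysis.

:class:`GaussianNetworkModel` is constructed from a coarse-grained
structure (or directly from a PDB file); :meth:`~GaussianNetworkModel.fit`
builds the Kirchhoff matrix, eigendecomposes it and computes the
importance profile, returning a :class:`GNMResults` that carries the
estimates, the gate/hub classification, the extracted pathways, a
``summary()`` table, and methods for perturbation-response analysis.

Example
-------
>>> from gnmgates import GaussianNetworkModel, generate_synthetic_structure
>>> structure = generate_synthetic_structure("cluster", n=40, seed=3)
>>> results = GaussianNetworkModel(structure).fit()
>>> top = results.top_residues(3)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import elastic_network, importance, perturbation, structure_io
from .elastic_network import ContactNetwork, ModeSpectrum
from .exceptions import ValidationError
from .importance import ImportanceProfile, InteractionPath
from .perturbation import PerturbationResponse, ResponseDifference
from .structure_io import CoarseGrainedStructure

__all__ = ["GaussianNetworkModel", "GNMResults"]


class GaussianNetworkModel:
    """Elastic-network model of a protein built from Cα coordinates.

    Parameters
    ----------
    structure : CoarseGrainedStructure
        Ordered Cα records (see :mod:`gnmgates.structure_io`).
    cutoff : float
        Contact cutoff in Å; residues strictly closer than this are
        joined by a spring (default 7.0, the first coordination shell).
    gamma : float
        Spring constant (default 1; results are in kT/γ units).
    kT : float
        Thermal energy scale (default 1).
    """

    def __init__(
        self,
        structure: CoarseGrainedStructure,
        cutoff: float = 7.0,
        gamma: float = 1.0,
        kT: float = 1.0,
    ):
        if len(structure) < 2:
            raise ValidationError("structure must have at least 2 residues")
        self.structure = structure
        self.cutoff = float(cutoff)
        self.gamma = float(gamma)
        self.kT = float(kT)

    @classmethod
    def from_pdb(
        cls,
        path,
        chains=None,
        model_index: int = 0,
        cutoff: float = 7.0,
        gamma: float = 1.0,
        kT: float = 1.0,
    ) -> "GaussianNetworkModel":
        """Build the model straight from a PDB file (Cα atoms only)."""
        structure = structure_io.read_pdb_calpha(path, chains=chains,
                                                 model_index=model_index)
        return cls(structure, cutoff=cutoff, gamma=gamma, kT=kT)

    def fit(
        self,
        variant: str = "contact_sum",
        top_k: int = 10,
        surface_degree_quantile: float = 0.5,
    ) -> "GNMResults":
        """Run the full analysis and return the results object.

        Builds Γ, computes the full spectrum, the fast-mode importance
        profile D, the gate/hub labels for the top-k residues, and the
        interaction pathways they form.
        """
        network = elastic_network.build_kirchhoff(
            self.structure, cutoff=self.cutoff, gamma=self.gamma
        )
        spectrum = elastic_network.eigendecompose(network, kT=self.kT)
        profile = importance.residue_importance(network, spectrum, variant=variant)
        top_k = min(top_k, len(self.structure))
        importance.classify_gates_hubs(
            network, profile, top_k=top_k,
            surface_degree_quantile=surface_degree_quantile,
        )
        paths = (
            importance.extract_paths(network, profile, top_k=top_k)
            if top_k >= 2 else []
        )
        return GNMResults(
            model=self,
            network=network,
            spectrum=spectrum,
            profile=profile,
            paths=paths,
            top_k=top_k,
        )


@dataclass
class GNMResults:
    """Results of a fitted Gaussian network model."""

    model: GaussianNetworkModel
    network: ContactNetwork
    spectrum: ModeSpectrum
    profile: ImportanceProfile
    paths: list[InteractionPath]
    top_k: int = 10
    _responses: dict = field(default_factory=dict, repr=False)

    @property
    def structure(self) -> CoarseGrainedStructure:
        return self.model.structure

    @property
    def lambda_max(self) -> float:
        return self.spectrum.lambda_max

    def top_residues(self, top_k: int | None = None):
        """Top residues by descending D (ties: ascending author number)."""
        return importance.rank_residues(self.profile, top_k or self.top_k)

    def to_frame(self) -> pd.DataFrame:
        """Per-residue table: identity, D, rank, label."""
        order = {idx: r for r, idx in enumerate(self.profile.ranking)}
        recs = self.profile.records
        return pd.DataFrame(
            {
                "chain": [r.chain_id for r in recs],
                "author_number": [r.author_seq_number for r in recs],
                "insertion_code": [r.insertion_code for r in recs],
                "residue_name": [r.residue_name for r in recs],
                "D": self.profile.values,
                "rank": [order[i] + 1 for i in range(len(recs))],
                "label": list(self.profile.labels),
            }
        )

    def perturb(self, residue, delta: float = 0.01) -> PerturbationResponse:
        """Response of every residue's D to perturbing one residue's
        contacts by the fraction ``delta`` (cached per (residue, delta))."""
        key = (self.network.index_of(residue), float(delta))
        if key not in self._responses:
            resp = perturbation.response_profile(
                self.network, self.network.index_map[key[0]].identity, delta=delta,
                variant=self.profile.normalization_variant, kT=self.model.kT,
            )
            resp.structure_label = self.structure.label
            self._responses[key] = resp
        return self._responses[key]

    def linearity(self, residue, deltas=(0.01, 0.02)) -> list[dict]:
        """Linear-response diagnostics for a set of perturbation sizes."""
        return perturbation.linearity_check(
            self.network, residue, deltas,
            variant=self.profile.normalization_variant,
        )

    def compare_response(
        self, other: "GNMResults", residue, delta: float = 0.01
    ) -> ResponseDifference:
        """Difference of perturbation responses between two structures
        (self minus other), matched by residue identity."""
        return perturbation.compare_pairs(
            self.perturb(residue, delta), other.perturb(residue, delta)
        )

    def summary(self) -> str:
        """Human-readable summary of the fit."""
        lines = [
            "Gaussian network model results",
            "=" * 46,
            f"structure:        {self.structure.label or '(unlabeled)'}",
            f"residues:         {len(self.structure)}",
            f"cutoff:           {self.model.cutoff:g} A",
            f"gamma, kT:        {self.model.gamma:g}, {self.model.kT:g}",
            f"contacts:         {int(self.network.adjacency.sum() // 2)}",
            f"lambda_max:       {self.lambda_max:.6g}",
            f"zero modes:       {self.spectrum.zero_mode_count}"
            + ("" if self.spectrum.zero_mode_count == 1
               else "  (disconnected contact graph)"),
            f"D variant:        {self.profile.normalization_variant}",
            "",
            f"top {self.top_k} residues by D (kT/gamma units):",
            f"{'residue':>12s} {'D':>12s} {'degree':>7s} {'label':>6s}",
        ]
        degrees = self.network.degrees
        for idx in self.profile.ranking[: self.top_k]:
            rec = self.profile.records[idx]
            lines.append(
                f"{str(rec):>12s} {self.profile.values[idx]:12.6f} "
                f"{degrees[idx]:7d} {self.profile.labels[idx]:>6s}"
            )
        if self.paths:
            lines.append("")
            lines.append("interaction pathways:")
            for p in self.paths:
                lines.append(f"  {p}")
        return "\n".join(lines)
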