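"""Graph perturbation and linear response of the importance profile.

Binding at residue i stiffens that residue's contacts. In the network
picture this is a multiplicative perturbation of the Kirchhoff matrix:
every nonzero off-diagonal entry in row i and column i is scaled by
(1 + δ) — δ = 0.01 by default, i.e. a 1% increase of the contact
strengths — and the diagonal is rebuilt so each row again sums to zero
(stiffer springs still form a consistent Laplacian). The response of
residue j is the change Δ_i D_j of its importance statistic, computed
by a full re-analysis of the perturbed network. Perturbations up to a
few percent sit in the linear-response regime (doubling δ doubles the
response); large δ leaves it.

Paired structures — e.g. two alleles of the same protein with the same
author numbering — are compared by subtracting their response profiles
residue by residue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .elastic_network import (
    ContactNetwork,
    eigendecompose,
)
from .exceptions import ValidationError
from .importance import residue_importance
from .structure_io import ResidueRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PerturbationResponse",
    "ResponseDifference",
    "perturb_residue",
    "response_profile",
    "linearity_check",
    "compare_pairs",
]


@dataclass
class PerturbationResponse:
    """Per-residue change of D after perturbing one residue's contacts.

    ``response[j] = D_j(perturbed) - D_j(original)`` in kT/γ units, one
    entry per residue in network order.
    """

    perturbed_residue: ResidueRecord
    delta: float
    response: np.ndarray
    variant: str
    records: list[ResidueRecord] = field(repr=False, default_factory=list)
    degenerate_top_mode: bool = False
    structure_label: str = ""

    def value_of(self, author_number: int, chain_id: str | None = None) -> float:
        for j, rec in enumerate(self.records):
            if rec.author_seq_number == author_number and (
                chain_id is None or rec.chain_id == chain_id
            ):
                return float(self.response[j])
        raise ValidationError(f"no residue with author number {author_number}")


@dataclass
class ResponseDifference:
    """Difference of two response profiles on their shared residues.

    Residues are matched by (chain, author number, insertion code);
    ``difference = response_X - response_Y`` per matched residue.
    Unmatched residues of either structure are listed, never silently
    dropped.
    """

    pair_labels: tuple[str, str]
    matched_residues: list[tuple[ResidueRecord, ResidueRecord]]
    difference: np.ndarray
    unmatched_x: list[ResidueRecord] = field(default_factory=list)
    unmatched_y: list[ResidueRecord] = field(default_factory=list)

    def value_of(self, author_number: int) -> float:
        for k, (rx, _) in enumerate(self.matched_residues):
            if rx.author_seq_number == author_number:
                return float(self.difference[k])
        raise ValidationError(f"no matched residue with author number {author_number}")


def perturb_residue(
    network: ContactNetwork, residue, delta: float = 0.01
) -> ContactNetwork:
    """Scale the contact strengths of one residue by (1 + delta).

    Every nonzero off-diagonal entry of row i and column i is multiplied
    by (1 + delta); the whole diagonal is then rebuilt from the
    off-diagonal entries so every row sums to zero again. The result is
    symmetric and positive semidefinite like the input.
    """
    if delta <= -1.0:
        raise ValidationError(f"delta must be > -1, got {delta}")
    i = network.index_of(residue)
    if len(network.contacts_of(i)) == 0:
        raise ValidationError(
            f"residue {network.index_map[i]} has no contacts; "
            "perturbation has no effect"
        )
    M = network.matrix.copy()
    diag = np.diag(M).copy()
    np.fill_diagonal(M, 0.0)
    # with the diagonal zeroed, the two passes touch disjoint entries
    # (row i and column i), so each contact of i is scaled exactly once
    M[i, :] *= 1.0 + delta
    M[:, i] *= 1.0 + delta
    np.fill_diagonal(M, -M.sum(axis=1))
    if delta == 0.0:
        np.fill_diagonal(M, diag)
    return ContactNetwork(
        matrix=M,
        cutoff=network.cutoff,
        gamma=network.gamma,
        index_map=list(network.index_map),
    )


def response_profile(
    network: ContactNetwork,
    residue,
    delta: float = 0.01,
    variant: str = "contact_sum",
    kT: float = 1.0,
) -> PerturbationResponse:
    """Response of every residue's D to perturbing one residue.

    The perturbed network is re-analysed from scratch (eigendecomposition
    and importance profile); the response is the per-residue difference
    of D after minus before. A near-degenerate top mode in either
    network is flagged on the result, since response magnitudes from a
    degenerate subspace are not individually meaningful.
    """
    i = network.index_of(residue)
    base_spec = eigendecompose(network, kT=kT)
    base = residue_importance(network, base_spec, variant=variant)
    perturbed = perturb_residue(network, network.index_map[i].identity, delta)
    pert_spec = eigendecompose(perturbed, kT=kT)
    pert = residue_importance(perturbed, pert_spec, variant=variant)
    degenerate = base_spec.top_mode_degenerate or pert_spec.top_mode_degenerate
    if degenerate:
        logger.warning(
            "top mode is near-degenerate; response magnitudes may be unreliable"
        )
    return PerturbationResponse(
        perturbed_residue=network.index_map[i],
        delta=delta,
        response=pert.values - base.values,
        variant=variant,
        records=list(network.index_map),
        degenerate_top_mode=degenerate,
    )


def linearity_check(
    network: ContactNetwork,
    residue,
    deltas,
    variant: str = "contact_sum",
    flag_tolerance: float = 0.10,
) -> list[dict]:
    """Check that the response scales linearly with the perturbation.

    For each delta the report contains the ratio
    ``‖response(δ)‖ / (δ · ‖response(δ_min)‖ / δ_min)`` — 1 in the
    perfectly linear regime — and a flag where it deviates from 1 by
    more than ``flag_tolerance``. Zero deltas are excluded with a
    warning (a zero perturbation has an identically zero response).
    """
    deltas = [float(d) for d in deltas]
    nonzero = [d for d in deltas if d != 0.0]
    if len(nonzero) < len(deltas):
        logger.warning("excluding delta = 0 from linearity check")
    positive = [d for d in nonzero if d > 0]
    if len(positive) < 2:
        raise ValidationError("need at least 2 positive deltas")
    d_min = min(positive)
    ref_norm = float(np.linalg.norm(
        response_profile(network, residue, d_min, variant).response
    ))
    report = []
    for d in positive:
        norm = float(np.linalg.norm(
            response_profile(network, residue, d, variant).response
        ))
        ratio = norm / (d * ref_norm / d_min)
        report.append(
            {
                "delta": d,
                "response_norm": norm,
                "ratio": ratio,
                "nonlinear": abs(ratio - 1.0) > flag_tolerance,
            }
        )
    return report


def compare_pairs(
    response_x: PerturbationResponse,
    response_y: PerturbationResponse,
) -> ResponseDifference:
    """Subtract two response profiles over their shared residues.

    Both responses must perturb the same author residue number with the
    same delta and variant. Matching is by (chain, author number,
    insertion code); this presumes consistently numbered structures
    (e.g. allele pairs), not a sequence alignment.
    """
    if response_x.delta != response_y.delta:
        raise ValidationError(
            f"delta mismatch: {response_x.delta} vs {response_y.delta}"
        )
    if response_x.variant != response_y.variant:
        raise ValidationError(
            f"variant mismatch: {response_x.variant} vs {response_y.variant}"
        )
    px, py = response_x.perturbed_residue, response_y.perturbed_residue
    if px.author_seq_number != py.author_seq_number:
        raise ValidationError(
            f"perturbed residues differ: {px} vs {py}"
        )
    index_y = {rec.identity: j for j, rec in enumerate(response_y.records)}
    matched: list[tuple[ResidueRecord, ResidueRecord]] = []
    diffs: list[float] = []
    unmatched_x: list[ResidueRecord] = []
    seen_y: set = set()
    for jx, rx in enumerate(response_x.records):
        jy = index_y.get(rx.identity)
        if jy is None:
            unmatched_x.append(rx)
            continue
        seen_y.add(rx.identity)
        matched.append((rx, response_y.records[jy]))
        diffs.append(float(response_x.response[jx] - response_y.response[jy]))
    unmatched_y = [r for r in response_y.records if r.identity not in seen_y]
    return ResponseDifference(
        pair_labels=(response_x.structure_label, response_y.structure_label),
        matched_residues=matched,
        difference=np.asarray(diffs, dtype=float),
        unmatched_x=unmatched_x,
        unmatched_y=unmatched_y,
    )
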