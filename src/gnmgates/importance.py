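"""Per-residue energy-coupling statistic, gates, hubs and pathways.

The importance statistic D_i of residue i is the sum of the fast-mode
spring-length fluctuations of the contacts that residue makes:

    D_i = (kT/γ) Σ_{j in contact with i} (u_i - u_j)² / λ_max

with u the largest-eigenvalue eigenvector of Γ. Because the fast mode
is localized and most sensitive to graph perturbation, a large D_i
marks a residue through which the protein exchanges energy: a surface
residue with large D_i is an "energy gate" (candidate ligand-binding
site), a buried one is a "hub" relaying interactions between gates.
Spatially contiguous high-D residues form an interaction pathway.

The ``all_pairs`` variant extends the sum over every other residue;
by orthonormality of the eigenvector it equals
``(kT/γ)(n u_i² + 1)/λ_max``, so its ranking is the u_i² ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .elastic_network import ContactNetwork, ModeSpectrum, mode_correlation
from .exceptions import NumericalError, ValidationError
from .structure_io import ResidueRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ImportanceProfile",
    "InteractionPath",
    "residue_importance",
    "rank_residues",
    "classify_gates_hubs",
    "extract_paths",
    "spring_energy_fractions",
]


def _tie_break_order(values: np.ndarray, records: list[ResidueRecord]) -> list[int]:
    """Indices sorted by descending value; ties by ascending author number.

    Values are quantized at 1e-9 relative resolution first, so that
    differences at round-off level (e.g. symmetry-equivalent residues)
    count as ties and the ordering stays deterministic.
    """
    scale = float(np.max(values)) or 1.0
    quantized = np.round(values / scale, 9)
    keys = [
        (-quantized[i], records[i].author_seq_number, records[i].insertion_code,
         records[i].chain_id)
        for i in range(len(records))
    ]
    return sorted(range(len(records)), key=keys.__getitem__)


@dataclass
class ImportanceProfile:
    """Per-residue D values with ranking and gate/hub labels.

    ``values[i]`` is D of the residue at internal index i, in kT/γ
    units. ``ranking`` lists internal indices by descending D (ties
    broken by ascending author residue number). ``labels`` holds
    ``"gate"``, ``"hub"`` or ``"unlabeled"`` per residue and is filled
    by :func:`classify_gates_hubs`.
    """

    values: np.ndarray
    records: list[ResidueRecord] = field(repr=False)
    mode_used: str = "max"
    normalization_variant: str = "contact_sum"
    ranking: list[int] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValidationError("D values must be nonnegative")
        if not self.ranking:
            self.ranking = _tie_break_order(self.values, self.records)
        if not self.labels:
            self.labels = ["unlabeled"] * len(self.records)

    @property
    def n(self) -> int:
        return len(self.records)

    def value_of(self, author_number: int, chain_id: str | None = None) -> float:
        for i, rec in enumerate(self.records):
            if rec.author_seq_number == author_number and (
                chain_id is None or rec.chain_id == chain_id
            ):
                return float(self.values[i])
        raise ValidationError(f"no residue with author number {author_number}")


@dataclass
class InteractionPath:
    """One spatially contiguous component of the top-D residues.

    ``members`` are internal indices in breadth-first order; consecutive
    members are in contact in the source network. ``endpoints`` are the
    members of degree <= 1 within the induced subgraph.
    """

    members: list[int]
    endpoints: tuple[int, int]
    component_id: int
    records: list[ResidueRecord] = field(repr=False, default_factory=list)

    @property
    def member_residues(self) -> list[ResidueRecord]:
        return [self.records[i] for i in self.members]

    def __str__(self) -> str:
        names = " - ".join(str(self.records[i]) for i in self.members)
        return f"path[{self.component_id}]: {names}"


def residue_importance(
    network: ContactNetwork,
    spectrum: ModeSpectrum,
    variant: str = "contact_sum",
) -> ImportanceProfile:
    """Compute the fast-mode importance statistic D_i for every residue.

    Parameters
    ----------
    network, spectrum
        The Kirchhoff matrix and its eigendecomposition.
    variant : {"contact_sum", "all_pairs"}
        ``contact_sum`` (default) sums spring fluctuations over the
        residues in contact with i; ``all_pairs`` sums over all j ≠ i.
    """
    if variant not in ("contact_sum", "all_pairs"):
        raise ValidationError(f"unknown variant {variant!r}")
    if spectrum.zero_mode_count >= spectrum.n:
        raise ValidationError("spectrum has no nonzero mode")
    C = mode_correlation(spectrum, "max")
    diag = np.diag(C)
    # pairwise spring fluctuations C_ii + C_jj - 2 C_ij, clamped at 0
    fluct = np.maximum(diag[:, None] + diag[None, :] - 2.0 * C, 0.0)
    if variant == "contact_sum":
        mask = network.adjacency
        values = (fluct * mask).sum(axis=1)
        for i in np.flatnonzero(~mask.any(axis=1)):
            logger.warning(
                "residue %s has no contacts; D set to 0", network.index_map[i]
            )
    else:
        np.fill_diagonal(fluct, 0.0)
        values = fluct.sum(axis=1)
    return ImportanceProfile(
        values=values,
        records=list(network.index_map),
        mode_used="max",
        normalization_variant=variant,
    )


def rank_residues(profile: ImportanceProfile, top_k: int = 10) -> list[ResidueRecord]:
    """Top-k residues by descending D (ties: ascending author number)."""
    if top_k < 1:
        raise ValidationError(f"top_k must be >= 1, got {top_k}")
    if top_k > profile.n:
        raise ValidationError(f"top_k {top_k} exceeds structure size {profile.n}")
    return [profile.records[i] for i in profile.ranking[:top_k]]


def classify_gates_hubs(
    network: ContactNetwork,
    profile: ImportanceProfile,
    top_k: int = 10,
    surface_degree_quantile: float = 0.5,
) -> list[str]:
    """Label the top-k residues as energy gates or hubs.

    Contact degree is used as a surface proxy (the model is CA-only, so
    no solvent accessibility is available): a top-k residue whose degree
    is below the given quantile of the degree distribution is loosely
    packed, hence exposed — a "gate"; otherwise buried — a "hub". The
    labels are heuristic and are also written back into
    ``profile.labels``.
    """
    if not 0.0 < surface_degree_quantile < 1.0:
        raise ValidationError("surface_degree_quantile must be in (0, 1)")
    degrees = network.degrees
    threshold = np.quantile(degrees, surface_degree_quantile)
    labels = ["unlabeled"] * profile.n
    for i in profile.ranking[:top_k]:
        labels[i] = "gate" if degrees[i] < threshold else "hub"
    profile.labels = labels
    return labels


def extract_paths(
    network: ContactNetwork,
    profile: ImportanceProfile,
    top_k: int = 10,
) -> list[InteractionPath]:
    """Interaction pathways among the top-k residues.

    The contact subgraph induced on the top-k residues is split into
    connected components; each component of size >= 2 becomes one path.
    Members are ordered by breadth-first traversal from the
    lowest-author-number node of degree <= 1 (or the lowest author
    number overall if the component has no such node, e.g. a cycle);
    endpoints are the two lowest-numbered degree <= 1 nodes.
    """
    if top_k < 2:
        raise ValidationError(f"top_k must be >= 2 for path extraction, got {top_k}")
    top = profile.ranking[:top_k]
    adj = network.adjacency
    G = nx.Graph()
    G.add_nodes_from(top)
    G.add_edges_from(
        (a, b) for ai, a in enumerate(top) for b in top[ai + 1:] if adj[a, b]
    )

    def author_key(i: int):
        rec = network.index_map[i]
        return (rec.author_seq_number, rec.insertion_code, rec.chain_id)

    paths: list[InteractionPath] = []
    components = sorted(
        (sorted(c, key=author_key) for c in nx.connected_components(G)),
        key=lambda c: author_key(c[0]),
    )
    cid = 0
    for comp in components:
        if len(comp) < 2:
            continue
        tips = [i for i in comp if G.degree(i) <= 1]
        start = tips[0] if tips else comp[0]
        order = []
        seen = {start}
        queue = [start]
        while queue:
            node = queue.pop(0)
            order.append(node)
            for nb in sorted(G.neighbors(node), key=author_key):
                if nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
        if len(tips) >= 2:
            endpoints = (tips[0], tips[1])
        elif len(tips) == 1:
            endpoints = (tips[0], order[-1])
        else:
            endpoints = (order[0], order[-1])
        paths.append(
            InteractionPath(
                members=order,
                endpoints=endpoints,
                component_id=cid,
                records=list(network.index_map),
            )
        )
        cid += 1
    if not paths:
        logger.warning("no contact component of size >= 2 among the top-%d residues",
                       top_k)
    return paths


def spring_energy_fractions(
    network: ContactNetwork,
    spectrum: ModeSpectrum,
) -> dict[tuple[int, int], float]:
    """Fraction of the exchanged energy absorbed by each contact.

    For every contact (i, j) the fast-mode spring fluctuation is divided
    by the sum over all contacts, so the fractions are nonnegative and
    sum to one.
    """
    adj = network.adjacency
    pairs = [(i, j) for i in range(network.n) for j in range(i + 1, network.n)
             if adj[i, j]]
    if not pairs:
        raise ValidationError("network has no contacts")
    C = mode_correlation(spectrum, "max")
    diag = np.diag(C)
    raw = {
        (i, j): max(diag[i] + diag[j] - 2.0 * C[i, j], 0.0) for i, j in pairs
    }
    total = sum(raw.values())
    if total <= 0.0:
        raise NumericalError("all spring fluctuations vanish; cannot normalize")
    return {pair: value / total for pair, value in raw.items()}
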