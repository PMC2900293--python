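"""Tabular and JSON export of result objects.

All result files are plain text: TSV with a header line, or JSON
mirrors of the same content. Logs never go into result files.
"""

from __future__ import annotations

import json
from pathlib import Path

from .importance import ImportanceProfile, InteractionPath
from .perturbation import PerturbationResponse, ResponseDifference
from .structure_io import CoarseGrainedStructure, ResidueRecord

__all__ = [
    "profile_tsv", "profile_json", "paths_json",
    "response_tsv", "response_json", "difference_tsv", "difference_json",
    "structure_tsv", "write_text",
]


def _ident(rec: ResidueRecord) -> dict:
    return {
        "chain": rec.chain_id,
        "author_number": rec.author_seq_number,
        "insertion_code": rec.insertion_code,
        "residue_name": rec.residue_name,
    }


def write_text(text: str, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(text)
    return path


def structure_tsv(structure: CoarseGrainedStructure) -> str:
    lines = ["chain\tauthor_number\tinsertion_code\tresidue_name\tx\ty\tz"]
    for r in structure.records:
        x, y, z = r.position
        lines.append(
            f"{r.chain_id}\t{r.author_seq_number}\t{r.insertion_code}\t"
            f"{r.residue_name}\t{x:.3f}\t{y:.3f}\t{z:.3f}"
        )
    return "\n".join(lines) + "\n"


def profile_tsv(profile: ImportanceProfile) -> str:
    order = {idx: r + 1 for r, idx in enumerate(profile.ranking)}
    lines = ["chain\tauthor_number\tinsertion_code\tresidue_name\tD\trank\tlabel"]
    for i, rec in enumerate(profile.records):
        lines.append(
            f"{rec.chain_id}\t{rec.author_seq_number}\t{rec.insertion_code}\t"
            f"{rec.residue_name}\t{profile.values[i]:.12g}\t{order[i]}\t"
            f"{profile.labels[i]}"
        )
    return "\n".join(lines) + "\n"


def profile_json(profile: ImportanceProfile) -> str:
    order = {idx: r + 1 for r, idx in enumerate(profile.ranking)}
    payload = {
        "mode_used": profile.mode_used,
        "normalization_variant": profile.normalization_variant,
        "residues": [
            {**_ident(rec), "D": float(profile.values[i]),
             "rank": order[i], "label": profile.labels[i]}
            for i, rec in enumerate(profile.records)
        ],
    }
    return json.dumps(payload, indent=1) + "\n"


def paths_json(paths: list[InteractionPath]) -> str:
    payload = [
        {
            "component_id": p.component_id,
            "members": [_ident(r) for r in p.member_residues],
            "endpoints": [_ident(p.records[e]) for e in p.endpoints],
        }
        for p in paths
    ]
    return json.dumps(payload, indent=1) + "\n"


def response_tsv(resp: PerturbationResponse) -> str:
    lines = [
        "chain\tauthor_number\tinsertion_code\tresidue_name\tdelta_D",
    ]
    for j, rec in enumerate(resp.records):
        lines.append(
            f"{rec.chain_id}\t{rec.author_seq_number}\t{rec.insertion_code}\t"
            f"{rec.residue_name}\t{resp.response[j]:.12g}"
        )
    return "\n".join(lines) + "\n"


def response_json(resp: PerturbationResponse) -> str:
    payload = {
        "perturbed_residue": _ident(resp.perturbed_residue),
        "delta": resp.delta,
        "variant": resp.variant,
        "degenerate_top_mode": bool(resp.degenerate_top_mode),
        "structure_label": resp.structure_label,
        "response": [
            {**_ident(rec), "delta_D": float(resp.response[j])}
            for j, rec in enumerate(resp.records)
        ],
    }
    return json.dumps(payload, indent=1) + "\n"


def difference_tsv(diff: ResponseDifference) -> str:
    lines = ["chain\tauthor_number\tinsertion_code\tresidue_name\tdifference"]
    for k, (rx, _) in enumerate(diff.matched_residues):
        lines.append(
            f"{rx.chain_id}\t{rx.author_seq_number}\t{rx.insertion_code}\t"
            f"{rx.residue_name}\t{diff.difference[k]:.12g}"
        )
    return "\n".join(lines) + "\n"


def difference_json(diff: ResponseDifference) -> str:
    payload = {
        "pair_labels": list(diff.pair_labels),
        "matched": [
            {**_ident(rx), "difference": float(diff.difference[k])}
            for k, (rx, _) in enumerate(diff.matched_residues)
        ],
        "unmatched_x": [_ident(r) for r in diff.unmatched_x],
        "unmatched_y": [_ident(r) for r in diff.unmatched_y],
    }
    return json.dumps(payload, indent=1) + "\n"
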