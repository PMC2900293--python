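"""The HLA-B27 study set and a PDB fetcher.

The reference application of this package is a set of ten HLA class I
(HLA-B27) crystal structures: five of the disease-associated B*2705
allele and five of the properly functioning B*2709 allele, paired so
that both members of a pair carry the same peptide. Analysis is run on
the heavy chain A. The structures are public PDB entries and are not
bundled; :func:`fetch_hla_structures` downloads them once into a cache
directory, and :func:`find_hla_structures` locates previously
downloaded copies.
"""

from __future__ import annotations

import urllib.error
import urllib.request
from pathlib import Path

from .exceptions import InputError

__all__ = [
    "HLA_PAIRS",
    "HLA_PDB_IDS",
    "fetch_hla_structures",
    "find_hla_structures",
]

#: (B*2709 member, B*2705 member) pairs sharing the same bound peptide
HLA_PAIRS: tuple[tuple[str, str], ...] = (
    ("1OF2", "1OGT"),
    ("1UXW", "1UXS"),
    ("1W0W", "1W0V"),
    ("1K5N", "1JGE"),
    ("3BP7", "3BP4"),
)

HLA_PDB_IDS: tuple[str, ...] = tuple(p for pair in HLA_PAIRS for p in pair)

_RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"

#: default on-disk location searched by find_hla_structures, relative to
#: the current working directory
DEFAULT_DATA_DIR = Path("data") / "pdb"


def fetch_hla_structures(
    directory=DEFAULT_DATA_DIR,
    pdb_ids=HLA_PDB_IDS,
    timeout: float = 30.0,
) -> dict[str, Path]:
    """Download the study structures from RCSB into ``directory``.

    Files already present are kept. Returns a mapping PDB id -> path.

    Raises
    ------
    InputError
        If a structure can neither be found locally nor downloaded
        (e.g. no network access).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for pdb_id in pdb_ids:
        dest = directory / f"{pdb_id}.pdb"
        if not dest.exists():
            url = _RCSB_URL.format(pdb_id=pdb_id)
            try:
                with urllib.request.urlopen(url, timeout=timeout) as response:
                    data = response.read()
            except (urllib.error.URLError, OSError, TimeoutError) as exc:
                raise InputError(
                    f"could not download {pdb_id} from {url} ({exc}); "
                    f"place {pdb_id}.pdb in {directory} manually or enable "
                    f"network access"
                ) from exc
            dest.write_bytes(data)
        paths[pdb_id] = dest
    return paths


def find_hla_structures(
    directory=DEFAULT_DATA_DIR,
    pdb_ids=HLA_PDB_IDS,
) -> dict[str, Path] | None:
    """Return id -> path if every study structure is present, else None."""
    directory = Path(directory)
    paths = {pdb_id: directory / f"{pdb_id}.pdb" for pdb_id in pdb_ids}
    if all(p.exists() for p in paths.values()):
        return paths
    return None
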