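"""Retrieval of reference crystal structures from the RCSB PDB.

The package does not bundle crystal-structure coordinate files; analyses
of the real peroxidase structures (HRP, PDB 1H5A; soybean APX, PDB
1OAG) download them on demand and cache them locally.
"""

from __future__ import annotations

import urllib.request
from pathlib import Path

__all__ = ["fetch_pdb", "StructureUnavailableError"]

_RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"


class StructureUnavailableError(RuntimeError):
    """The requested PDB entry could not be retrieved."""


def fetch_pdb(pdb_id: str, cache_dir: str | Path | None = None, timeout: float = 20.0) -> Path:
    """Download a PDB entry (cached) and return the local file path."""
    pdb_id = pdb_id.upper()
    cache = Path(cache_dir) if cache_dir is not None else Path.home() / ".cache" / "splitperox"
    cache.mkdir(parents=True, exist_ok=True)
    target = cache / f"{pdb_id.lower()}.pdb"
    if target.exists() and target.stat().st_size > 0:
        return target
    url = _RCSB_URL.format(pdb_id=pdb_id)
    try:
        with urllib.request.urlopen(url, timeout=timeout) as response:
            data = response.read()
    except Exception as exc:
        raise StructureUnavailableError(
            f"could not retrieve PDB entry {pdb_id} from {url}: {exc}"
        ) from exc
    target.write_bytes(data)
    return target
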