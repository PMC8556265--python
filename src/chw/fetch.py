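"""Retrieval of deposited structures from the PDB (with a local cache).

Deposition-anchored analyses (entity census, NPA spacing, pore profile,
RMSD comparisons against other aquaporin structures) need the deposited
mmCIF files; this helper downloads them once into a cache directory and
reuses the cached copy afterwards, so the analyses also run in offline
settings where the files were staged beforehand.
"""

from __future__ import annotations

import urllib.error
import urllib.request
from pathlib import Path

RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.cif"


class FetchError(RuntimeError):
    """The deposition could not be retrieved (offline, or bad id)."""


def fetch_pdb(pdb_id: str, cache_dir: str | Path = "data/depositions",
              timeout: float = 20.0) -> Path:
    """Return a local path to the mmCIF file for ``pdb_id``.

    Looks for ``<cache_dir>/<id>.cif`` first; otherwise downloads from the
    RCSB and caches it.  Raises :class:`FetchError` when neither works.
    """
    pdb_id = pdb_id.upper()
    cache_dir = Path(cache_dir)
    target = cache_dir / f"{pdb_id}.cif"
    if target.exists():
        return target
    cache_dir.mkdir(parents=True, exist_ok=True)
    url = RCSB_URL.format(pdb_id=pdb_id)
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            data = resp.read()
    except (urllib.error.URLError, OSError, TimeoutError) as exc:
        raise FetchError(
            f"cannot retrieve {pdb_id}: {exc}. Stage the file at {target} "
            "to run deposition-anchored analyses offline."
        ) from exc
    target.write_bytes(data)
    return target
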