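"""Opt-in retrieval of deposited PDB entries.

Core commands never touch the network; this helper exists so the
deposited-entry comparisons can be (re)run where a network is available.
Files are cached under ``data/pdb/<id>.pdb`` relative to a chosen root.
"""

from __future__ import annotations

import urllib.error
import urllib.request
from pathlib import Path

__all__ = ["entry_path", "load_entry", "fetch_entry", "EntryUnavailable"]

RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"


class EntryUnavailable(RuntimeError):
    """The entry is neither cached locally nor fetchable."""


def entry_path(pdb_id: str, data_dir: str | Path = "data/pdb") -> Path:
    return Path(data_dir) / f"{pdb_id.lower()}.pdb"


def fetch_entry(pdb_id: str, data_dir: str | Path = "data/pdb",
                timeout: float = 20.0) -> Path:
    """Download one entry from RCSB into the cache directory."""
    path = entry_path(pdb_id, data_dir)
    path.parent.mkdir(parents=True, exist_ok=True)
    url = RCSB_URL.format(pdb_id=pdb_id.upper())
    try:
        with urllib.request.urlopen(url, timeout=timeout) as response:
            path.write_bytes(response.read())
    except (urllib.error.URLError, OSError, TimeoutError) as exc:
        raise EntryUnavailable(f"cannot fetch {pdb_id}: {exc}") from exc
    return path


def load_entry(pdb_id: str, data_dir: str | Path = "data/pdb",
               allow_fetch: bool = True, timeout: float = 20.0) -> Path:
    """Path of a cached entry, fetching it first if permitted and needed."""
    path = entry_path(pdb_id, data_dir)
    if path.exists():
        return path
    if not allow_fetch:
        raise EntryUnavailable(f"{path} not present and fetching disabled")
    return fetch_entry(pdb_id, data_dir, timeout=timeout)
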