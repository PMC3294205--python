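"""Small shared I/O helpers: gzip-aware file opening and read-pair naming."""

from __future__ import annotations

import gzip
import io
import re
from pathlib import Path

# Mate designators found in the wild: "name/1", "name/2", and the Casava 1.8+
# "name 1:N:0:..." whitespace-tag dialect. FASTQ naming is not standardized.
_MATE_SUFFIX = re.compile(r"/[12]$")


def xopen(path, mode: str = "rt"):
    """Open *path* transparently, gunzipping if the name ends in .gz.

    Gzip members are written with ``mtime=0`` so that regenerating a file with
    identical content yields identical bytes.
    """
    path = Path(path)
    if path.suffix == ".gz":
        if "w" in mode:
            raw = gzip.GzipFile(filename=str(path), mode="wb", mtime=0)
            if "b" in mode:
                return raw
            return io.TextIOWrapper(raw)
        return gzip.open(path, mode)
    return open(path, mode)


def pair_id(read_id: str) -> str:
    """Normalize a read ID to its pair ID: drop any whitespace tag, then a /1 or /2 suffix."""
    base = read_id.split()[0] if read_id else read_id
    return _MATE_SUFFIX.sub("", base)
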