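"""Small shared utilities: atomic file writes and seed derivation."""

from __future__ import annotations

import contextlib
import os
import tempfile
from pathlib import Path

import numpy as np


@contextlib.contextmanager
def atomic_write(path: str | Path, mode: str = "w"):
    """Write to a temp file in the target directory, then rename into place.

    Interrupted runs never leave truncated files at the final path.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        with contextlib.suppress(OSError):
            os.unlink(tmp)
        raise


def child_seed(seed: int, stream: str) -> np.random.Generator:
    """Derive an independent, reproducible RNG stream from one master seed."""
    import hashlib

    digest = hashlib.sha256(stream.encode()).digest()
    salt = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([seed, salt]))
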