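"""Run manifests: reproducibility metadata written next to every output."""

from __future__ import annotations

import hashlib
import json
import sys
from datetime import datetime, timezone
from pathlib import Path

from .config import ModelConfig

__all__ = ["write_manifest"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_path: str | Path,
    config: ModelConfig,
    seed: int | None,
    outputs: list[str | Path],
    extra: dict | None = None,
) -> Path:
    """Write a JSON manifest recording everything needed to re-run.

    Contains the fully resolved flat config snapshot, the master seed, the
    package version, the command line, and a sha256 checksum per output
    file.  Re-running with the same config and seed reproduces the outputs
    byte for byte.
    """
    from . import __version__

    out_path = Path(out_path)
    doc = {
        "package": "hybridcycle",
        "version": __version__,
        "created": datetime.now(timezone.utc).isoformat(),
        "command": sys.argv,
        "seed": seed,
        "config": config.flat_dict(),
        "outputs": {str(p): _sha256(Path(p)) for p in outputs},
    }
    if extra:
        doc.update(extra)
    out_path.write_text(json.dumps(doc, indent=2, default=str) + "\n")
    return out_path
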