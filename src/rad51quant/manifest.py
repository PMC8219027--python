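"""Run manifests: enough provenance to reproduce a run byte-identically.

A manifest records the configuration snapshot, SHA-256 hashes of every
input file, all seeds, the per-stage logs, and the package version. Because
every random draw in the package flows through a recorded seed and every
threshold is echoed from the configuration, re-running from a manifest
reproduces all numeric outputs exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from . import __version__

__all__ = ["file_sha256", "build_manifest", "write_manifest", "read_manifest"]


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def build_manifest(
    config: dict,
    inputs: dict[str, str | Path] | None = None,
    seeds: dict[str, int] | None = None,
    stage_logs: dict | None = None,
) -> dict:
    return {
        "package": "rad51quant",
        "version": __version__,
        "config": config,
        "input_hashes": {
            name: file_sha256(p) for name, p in (inputs or {}).items()
        },
        "seeds": dict(seeds or {}),
        "stage_logs": dict(stage_logs or {}),
    }


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
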