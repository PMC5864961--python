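"""Run manifests: every CLI invocation records how to re-run itself."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

from . import __version__

__all__ = ["RunManifest", "write_manifest"]


@dataclass(frozen=True)
class RunManifest:
    command: str
    parameters: dict
    seed: int | None
    package_version: str
    timestamp: str


def write_manifest(
    out_dir: str | Path,
    command: str,
    parameters: dict,
    seed: int | None = None,
    name: str = "manifest.json",
) -> RunManifest:
    """Write a manifest JSON alongside the outputs of one command."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        command=command,
        parameters={k: _jsonable(v) for k, v in parameters.items()},
        seed=seed,
        package_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )
    (out_dir / name).write_text(json.dumps(asdict(manifest), indent=2) + "\n")
    return manifest


def _jsonable(v):
    if isinstance(v, Path):
        return str(v)
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    return v
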