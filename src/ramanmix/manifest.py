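"""Reproducibility manifests for CLI runs.

Every CLI invocation writes exactly one manifest next to its primary
output: the command, the full parameter set, the root seed and the named
child-stream seeds derived from it, library versions, SHA-256 digests of
input and output files, and the wall time.  Manifests are JSON, which is
both human-readable and machine-verifiable.
"""

from __future__ import annotations

import hashlib
import json
import platform
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import scipy

__all__ = ["RunManifest", "file_digest", "child_seeds"]


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def child_seeds(root_seed: Optional[int], names: tuple[str, ...]) -> dict[str, int]:
    """Expand a root seed into named, independently usable child seeds."""
    ss = np.random.SeedSequence(root_seed)
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


@dataclass
class RunManifest:
    command: str
    parameters: dict[str, Any]
    root_seed: Optional[int]
    child_stream_seeds: dict[str, int] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    outputs: dict[str, str] = field(default_factory=dict)
    wall_time_seconds: Optional[float] = None
    versions: dict[str, str] = field(default_factory=dict)
    started_at: float = field(default_factory=time.time)

    def __post_init__(self) -> None:
        if not self.versions:
            self.versions = {
                "python": sys.version.split()[0],
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
                "platform": platform.platform(),
            }

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = file_digest(path)

    def add_output(self, path: str | Path) -> None:
        self.outputs[str(path)] = file_digest(path)

    def finalize(self) -> None:
        self.wall_time_seconds = time.time() - self.started_at

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "command": self.command,
            "parameters": self.parameters,
            "root_seed": self.root_seed,
            "child_stream_seeds": self.child_stream_seeds,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "wall_time_seconds": self.wall_time_seconds,
            "versions": self.versions,
        }
        path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
        return path

    @staticmethod
    def read(path: str | Path) -> dict[str, Any]:
        return json.loads(Path(path).read_text())

    def verify_digests(self) -> list[str]:
        """Re-hash recorded files; returns a list of mismatch descriptions."""
        bad = []
        for group in (self.inputs, self.outputs):
            for path, digest in group.items():
                if not Path(path).exists():
                    bad.append(f"{path}: missing")
                elif file_digest(path) != digest:
                    bad.append(f"{path}: digest mismatch")
        return bad
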