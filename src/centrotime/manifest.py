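"""Run manifests: the provenance record every CLI command writes."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Config snapshot, input digests, seeds and record counts for one run.

    Contains no timestamps, so a rerun with identical inputs produces a
    byte-identical manifest.
    """

    command: str
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)    # path -> sha256
    seeds: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    version: str = ""

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = file_digest(path)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))
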