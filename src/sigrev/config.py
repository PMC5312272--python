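"""Pipeline configuration: defaults, file round-trip, provenance hash."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, fields
from pathlib import Path


@dataclass
class PipelineConfig:
    """Tunable parameters and input/output paths of the full workflow.

    ``s`` is the extreme-set size used by the transcriptional distance
    (top/bottom features of each ranking); ``tau`` the inclusive neighbor
    threshold on the [0, 2] distance scale; ``alpha`` the raw-p significance
    level of the community enrichment; ``k_extreme`` the cutoff for
    candidate target-gene shortlists.  Path fields may stay empty when the
    corresponding stage is not run.
    """

    s: int = 250
    tau: float = 0.86
    alpha: float = 0.05
    k_extreme: int = 100
    seed: int = 0
    signatures: str = ""
    prls: str = ""
    annotations: str = ""
    communities: str = ""
    outdir: str = "sigrev-out"

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        known = {f.name: f.type for f in fields(cls)}
        kwargs: dict[str, object] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            kwargs[key] = raw
        cfg = cls()
        for key, raw in kwargs.items():
            current = getattr(cfg, key)
            if isinstance(current, bool):
                value: object = raw.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                value = int(raw)
            elif isinstance(current, float):
                value = float(raw)
            else:
                value = raw
            setattr(cfg, key, value)
        return cfg

    def digest(self) -> str:
        """Short hash of the effective configuration, for provenance logs."""
        text = "\n".join(f"{f.name}={getattr(self, f.name)}" for f in fields(self))
        return hashlib.sha256(text.encode()).hexdigest()[:12]
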