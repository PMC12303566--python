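"""Dataset directory layout and the stage-completion manifest.

A *dataset* is a directory holding everything derived from one source
video: the config, the chunk table, per-chunk masks and point tracks,
masterframes, chunk alignments, the cleanqueen, and the exported CSV
series.  Each stage records a checksum of its configuration section
and of its upstream stage in ``manifest.json``, so completed stages are
skipped on re-run (idempotence) and stale downstream artifacts are
detected when an upstream stage or its config changed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

from .config import PipelineConfig

log = logging.getLogger("chromatrack.dataset")

STAGE_ORDER = ["chunk", "segment", "register", "stitch", "area", "slice", "analyse"]

#: config sections each stage depends on
_STAGE_SECTIONS = {
    "chunk": ["video", "chunking"],
    "segment": ["video", "segmentation"],
    "register": ["video", "registration"],
    "stitch": ["video", "stitching"],
    "area": ["video", "territories"],
    "slice": ["video", "anisotropy"],
    "analyse": ["motor_units"],
}

_PREREQ = {
    "chunk": [],
    "segment": ["chunk"],
    "register": ["chunk", "segment"],
    "stitch": ["register"],
    "area": ["register", "stitch"],
    "slice": ["area"],
    "analyse": ["slice"],
}


class StageError(RuntimeError):
    pass


class MissingPrerequisite(StageError):
    def __init__(self, stage: str, missing: str):
        super().__init__(
            f"stage '{stage}' requires '{missing}' to be run first "
            f"(chromatrack {missing} <dataset>)"
        )
        self.missing = missing


class Dataset:
    def __init__(self, root: str | Path):
        self.root = Path(root)
        if not self.root.exists():
            raise FileNotFoundError(self.root)
        self.config = (
            PipelineConfig.from_yaml(self.root / "config.yaml")
            if (self.root / "config.yaml").exists()
            else PipelineConfig()
        )

    # -- creation --------------------------------------------------------
    @classmethod
    def create(
        cls,
        root: str | Path,
        video_source: str | Path,
        config: PipelineConfig | None = None,
    ) -> "Dataset":
        root = Path(root)
        root.mkdir(parents=True, exist_ok=True)
        cfg = config or PipelineConfig()
        cfg.to_yaml(root / "config.yaml")
        manifest = {"video_source": str(video_source), "stages": {}}
        (root / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return cls(root)

    # -- paths -----------------------------------------------------------
    def path(self, *parts: str) -> Path:
        p = self.root.joinpath(*parts)
        p.parent.mkdir(parents=True, exist_ok=True)
        return p

    @property
    def video_source(self) -> Path:
        return Path(self.manifest()["video_source"])

    # -- manifest --------------------------------------------------------
    def manifest(self) -> dict:
        f = self.root / "manifest.json"
        return json.loads(f.read_text()) if f.exists() else {"stages": {}}

    def _write_manifest(self, m: dict) -> None:
        (self.root / "manifest.json").write_text(json.dumps(m, indent=2))

    def stage_hash(self, stage: str) -> str:
        """Checksum covering this stage's config sections and the hashes
        of its prerequisite stages."""
        cfg = self.config.model_dump(mode="json")
        payload = {s: cfg[s] for s in _STAGE_SECTIONS[stage]}
        payload["seed"] = cfg["seed"]
        parents = {}
        m = self.manifest()
        for pre in _PREREQ[stage]:
            parents[pre] = m["stages"].get(pre, {}).get("hash", "missing")
        blob = json.dumps({"cfg": payload, "parents": parents}, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def is_current(self, stage: str) -> bool:
        rec = self.manifest()["stages"].get(stage)
        return rec is not None and rec.get("hash") == self.stage_hash(stage)

    def check_prerequisites(self, stage: str) -> None:
        for pre in _PREREQ[stage]:
            if stage in _PREREQ and not self.is_current(pre):
                raise MissingPrerequisite(stage, pre)

    def mark_done(self, stage: str, **extra) -> None:
        m = self.manifest()
        m["stages"][stage] = {"hash": self.stage_hash(stage), **extra}
        self._write_manifest(m)

    def stale_stages(self) -> list[str]:
        m = self.manifest()["stages"]
        return [s for s in STAGE_ORDER if s in m and not self.is_current(s)]
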