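"""Pipeline configuration: YAML schema, validation and per-module hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .model import MarkerMetadata, SampleRecord, validate_markers

CANONICAL_ORDER = (
    "selectROIs",
    "artifactDetect",
    "dnaIntensity",
    "areaFilter",
    "cycleCorrelation",
    "pruneOutliers",
    "metaQC",
    "clustering",
    "setContrast",
    "curateThumbnails",
)


@dataclass
class QCConfig:
    """Ordered module list with per-module parameters and a global seed.

    The enabled modules must appear in their canonical relative order (any
    subset may be disabled). Each module's parameters hash independently so a
    checkpoint stays valid when only downstream parameters change.
    """

    modules: list[str]
    samples: list[SampleRecord]
    markers: list[MarkerMetadata]
    params: dict[str, dict] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        unknown = [m for m in self.modules if m not in CANONICAL_ORDER]
        if unknown:
            raise ConfigError(f"unknown modules: {unknown}")
        if len(set(self.modules)) != len(self.modules):
            raise ConfigError("duplicate modules in order")
        positions = [CANONICAL_ORDER.index(m) for m in self.modules]
        if positions != sorted(positions):
            raise ConfigError(
                f"module order must follow the canonical order {CANONICAL_ORDER}"
            )
        validate_markers(self.markers)

    def module_params(self, module: str) -> dict:
        return dict(self.params.get(module, {}))

    def module_hash(self, module: str) -> str:
        payload = {
            "module": module,
            "params": self.params.get(module, {}),
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def module_hashes(self) -> dict[str, str]:
        return {m: self.module_hash(m) for m in self.modules}

    def module_seed(self, module: str) -> int:
        """Stable per-module sub-seed derived from the global seed."""
        blob = f"{self.seed}:{module}".encode()
        return int.from_bytes(hashlib.sha256(blob).digest()[:4], "big") % (2**31)

    # -- YAML --------------------------------------------------------------

    @classmethod
    def from_yaml(cls, path: Path | str) -> "QCConfig":
        path = Path(path)
        try:
            raw = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
        return cls.from_dict(raw, base_dir=path.parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None) -> "QCConfig":
        base = Path(base_dir) if base_dir else Path(".")
        for key in ("modules", "samples", "markers"):
            if key not in raw:
                raise ConfigError(f"config missing required key: {key}")

        def resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        samples = []
        for s in raw["samples"]:
            try:
                samples.append(
                    SampleRecord(
                        sample_id=str(s["sample_id"]),
                        image_path=resolve(s["image"]),
                        mask_path=resolve(s["mask"]),
                        table_path=resolve(s["table"]),
                        outline_path=resolve(s["outline"]) if s.get("outline") else None,
                        pixel_size=float(s.get("pixel_size", 0.65)),
                    )
                )
            except KeyError as exc:
                raise ConfigError(f"sample entry missing key: {exc}") from exc
        markers = [
            MarkerMetadata(
                channel_index=i,
                marker_name=str(m["name"]),
                cycle_number=int(m["cycle"]),
                is_counterstain=bool(m.get("counterstain", False)),
            )
            for i, m in enumerate(raw["markers"])
        ]
        params = {
            m: dict(raw.get(m, {}) or {})
            for m in CANONICAL_ORDER
            if isinstance(raw.get(m), dict)
        }
        return cls(
            modules=list(raw["modules"]),
            samples=samples,
            markers=markers,
            params=params,
            seed=int(raw.get("seed", 0)),
        )
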