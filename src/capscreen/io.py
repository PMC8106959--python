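"""Plate manifests and run configuration.

The plate manifest emulates the CSV emitted by the automated imaging
platform: one row per embryo with its well, compound, concentration,
orientation and acquisition time.  ``RunConfig`` is the single declarative
file from which a whole pipeline run is reproducible.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

__all__ = ["REQUIRED_MANIFEST_COLUMNS", "read_manifest", "write_manifest",
           "RunConfig"]

REQUIRED_MANIFEST_COLUMNS = ("embryo_id", "well", "compound_id",
                             "concentration_uM", "orientation",
                             "acquisition_time")

_WELL_96 = re.compile(r"^[A-H](?:[1-9]|1[0-2])$")
_WELL_24 = re.compile(r"^[A-D][1-6]$")


def _valid_well(label: str) -> bool:
    """Accept 24-well (A1-D6) and 96-well (A1-H12) labels."""
    return bool(_WELL_96.match(label) or _WELL_24.match(label))


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a plate manifest CSV.

    Raises on missing required columns (naming them), duplicate embryo ids,
    or malformed well labels (reported with 1-based data line numbers).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path.name} missing required "
                         f"column(s): {', '.join(missing)}")
    dupes = df["embryo_id"][df["embryo_id"].duplicated()]
    if not dupes.empty:
        raise ValueError(f"duplicate embryo_id(s): "
                         f"{', '.join(map(str, dupes.unique()[:5]))}")
    bad = [(i + 2, w) for i, w in enumerate(df["well"].astype(str))
           if not _valid_well(w)]
    if bad:
        lines = "; ".join(f"line {ln}: {w!r}" for ln, w in bad[:5])
        raise ValueError(f"malformed well label(s): {lines}")
    df["acquisition_time"] = pd.to_datetime(df["acquisition_time"])
    if "image_path" in df.columns:
        df["image_path"] = df["image_path"].fillna("").astype(str)
    return df


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(path, index=False)
    return path


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run.

    All thresholds carry their pipeline defaults; a run is fully
    reproducible from this object alone (every stochastic stage is driven
    by ``seed``).
    """

    seed: int = 0
    output_dir: str = "capscreen-out"
    pixel_size: float = 1.0
    hm_margin_um: float = 2.0
    binarize_fraction: float = 0.30
    min_punctum_px: int = 2
    ri_threshold: float = 2.5
    alpha: float = 0.05
    score_only: bool = True
    n_compounds: int = 20
    n_active: int = 2
    toxic_split: tuple[int, int, int] = (1, 1, 0)
    active_effect: float = 3.4
    control_preset: str = "chodl-DMSO"
    preset_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.binarize_fraction < 1.0:
            raise ValueError("binarize_fraction must be in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.ri_threshold <= 0 or self.hm_margin_um < 0:
            raise ValueError("thresholds out of range")
        if self.min_punctum_px < 1 or self.n_compounds < 1:
            raise ValueError("min_punctum_px and n_compounds must be >= 1")
        self.toxic_split = tuple(self.toxic_split)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["toxic_split"] = list(self.toxic_split)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
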