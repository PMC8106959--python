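"""Ground-truth sidecar records emitted by the synthetic-embryo generator.

Every generated image carries a serializable record of the true axon paths,
branch geometry, puncta and toxicity state, so that the measurement modules
can be validated against known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .geometry import EmbryoGeometry

TOXICITY_STATES = ("none", "death", "delayed", "malformed")


@dataclass
class BranchSpec:
    """One side branch of a CaP axon.

    ``lateral_extent_um`` is the realized maximal column displacement of the
    branch from the main-axon path at the same row (the quantity the 8-um
    offset-line counting rule responds to).  ``side`` is 'anterior' or
    'posterior'.
    """

    attach_index: int
    lateral_extent_um: float
    side: str
    crosses_offset_um: float | None = None  # offset the branch verifiably exceeds


@dataclass
class AxonTruth:
    """True state of one CaP axon."""

    present: bool
    true_length_um: float
    crossed_hm: bool
    abnormal: bool
    tip: tuple[int, int] | None = None
    exit_col: int = 0
    branches: list[BranchSpec] = field(default_factory=list)

    def n_branches_beyond(self, offset_um: float) -> int:
        return sum(1 for b in self.branches if b.lateral_extent_um > offset_um)


@dataclass
class PunctaChannelTruth:
    """True puncta of one label channel, pooled over hemisegment ROIs."""

    centers: list[tuple[float, float]] = field(default_factory=list)
    sigmas_um: list[float] = field(default_factory=list)
    amplitudes: list[float] = field(default_factory=list)


@dataclass
class PunctaTruth:
    pre: PunctaChannelTruth = field(default_factory=PunctaChannelTruth)
    post: PunctaChannelTruth = field(default_factory=PunctaChannelTruth)
    # nominal group-effect multipliers relative to the wild-type control preset
    area_ratio_pre: float = 1.0
    count_ratio_pre: float = 1.0
    intensity_ratio_pre: float = 1.0
    area_ratio_post: float = 1.0
    count_ratio_post: float = 1.0
    intensity_ratio_post: float = 1.0


@dataclass
class GroundTruth:
    """Full sidecar for one synthetic embryo."""

    preset: str
    seed: int
    geometry: EmbryoGeometry
    axons: list[AxonTruth]
    puncta: PunctaTruth
    toxicity: str = "none"

    def __post_init__(self) -> None:
        if self.toxicity not in TOXICITY_STATES:
            raise ValueError(f"unknown toxicity state {self.toxicity!r}")

    # -- derived summaries -------------------------------------------------
    @property
    def n_crossed(self) -> int:
        return sum(a.crossed_hm for a in self.axons)

    @property
    def n_scored(self) -> int:
        return len(self.axons)

    @property
    def abnormal_fraction(self) -> float:
        return sum(a.abnormal for a in self.axons) / len(self.axons)

    def mean_true_length_um(self, stalled_only: bool = False) -> float:
        lens = [a.true_length_um for a in self.axons
                if a.present and (not stalled_only or not a.crossed_hm)]
        return float(sum(lens) / len(lens)) if lens else 0.0

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["geometry"] = self.geometry.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        axons = [
            AxonTruth(
                present=a["present"],
                true_length_um=a["true_length_um"],
                crossed_hm=a["crossed_hm"],
                abnormal=a["abnormal"],
                tip=tuple(a["tip"]) if a.get("tip") is not None else None,
                exit_col=a.get("exit_col", 0),
                branches=[BranchSpec(**b) for b in a.get("branches", [])],
            )
            for a in d["axons"]
        ]
        pt = d["puncta"]

        def _chan(c: dict) -> PunctaChannelTruth:
            return PunctaChannelTruth(
                centers=[tuple(x) for x in c["centers"]],
                sigmas_um=list(c["sigmas_um"]),
                amplitudes=list(c["amplitudes"]),
            )

        puncta = PunctaTruth(
            pre=_chan(pt["pre"]), post=_chan(pt["post"]),
            **{k: pt[k] for k in pt if k.endswith(("_pre", "_post"))},
        )
        return cls(
            preset=d["preset"], seed=int(d["seed"]),
            geometry=EmbryoGeometry.from_dict(d["geometry"]),
            axons=axons, puncta=puncta, toxicity=d.get("toxicity", "none"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))
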