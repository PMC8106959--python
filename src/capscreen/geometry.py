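"""Embryo coordinate frame and landmark geometry.

The lateral-view frame is: rows increase dorsal -> ventral, columns increase
anterior -> posterior, 0-based indices.  "Beyond the horizontal myoseptum
(HM)" means tip row strictly greater than ``hm_row``.  All landmark indices
are stored in pixels; ``pixel_size`` converts to micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass(frozen=True)
class EmbryoGeometry:
    """Landmarks of one lateral-view trunk image.

    Parameters
    ----------
    pixel_size : float
        Micrometres per pixel (isotropic).
    exit_row : int
        Row of the spinal-cord ventral edge, where motor axons exit.
    hm_row : int
        Row of the horizontal myoseptum, the intermediate synaptic target.
    ventral_extent_row : int
        Most ventral myotome row an axon may reach.
    exit_cols : tuple of int
        Eight column indices, one per scoreable hemisegment (somites 7-14),
        strictly increasing.
    shape : tuple of int
        Image shape ``(rows, cols)``.
    """

    pixel_size: float = 1.0
    exit_row: int = 30
    hm_row: int = 55
    ventral_extent_row: int = 120
    exit_cols: tuple[int, ...] = (29, 55, 81, 107, 133, 159, 185, 211)
    shape: tuple[int, int] = (144, 240)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not (0 <= self.exit_row < self.hm_row < self.ventral_extent_row
                < self.shape[0]):
            raise ValueError(
                "landmark rows must satisfy exit_row < hm_row < "
                "ventral_extent_row and lie inside the image")
        if len(self.exit_cols) != 8:
            raise ValueError("exactly 8 exit columns (somites 7-14) required")
        cols = list(self.exit_cols)
        if cols != sorted(set(cols)):
            raise ValueError("exit_cols must be strictly increasing")
        if cols[0] < 0 or cols[-1] >= self.shape[1]:
            raise ValueError("exit_cols must lie inside the image")

    @property
    def n_hemisegments(self) -> int:
        return len(self.exit_cols)

    @property
    def hemisegment_halfwidth(self) -> int:
        """Half the inter-hemisegment spacing, in pixels."""
        spacing = min(b - a for a, b in zip(self.exit_cols, self.exit_cols[1:]))
        return spacing // 2

    def um_to_px(self, um: float) -> float:
        return um / self.pixel_size

    def px_to_um(self, px: float) -> float:
        return px * self.pixel_size

    def to_dict(self) -> dict:
        d = asdict(self)
        d["exit_cols"] = list(self.exit_cols)
        d["shape"] = list(self.shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EmbryoGeometry":
        return cls(
            pixel_size=float(d["pixel_size"]),
            exit_row=int(d["exit_row"]),
            hm_row=int(d["hm_row"]),
            ventral_extent_row=int(d["ventral_extent_row"]),
            exit_cols=tuple(int(c) for c in d["exit_cols"]),
            shape=tuple(int(s) for s in d["shape"]),
        )
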