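"""Reproducible group-level measurement protocols on synthetic embryos.

These routines regenerate a synthetic group from a preset and a seed, run
the measurement pipeline on every embryo, and return the per-embryo
summaries used for effect-size recovery checks.  All randomness derives
from ``base_seed``; per-embryo seeds are consecutive.
"""

from __future__ import annotations

import numpy as np

from .axon import (measure_embryo_axons, score_abnormal, AbnormalityRules)
from .simulate import generate_embryo
from .synapse import measure_embryo, MeasureParams

__all__ = ["grand_mean_length", "embryo_mean_lengths", "presynaptic_stats",
           "percent_abnormal_group"]


def _seed(base_seed: int, i: int) -> int:
    return int((base_seed + i) % (2 ** 31))


def grand_mean_length(preset: str, base_seed: int, n: int) -> float:
    """Grand mean of traced CaP axon lengths (um) over ``n`` embryos."""
    lengths: list[float] = []
    for i in range(n):
        image, truth = generate_embryo(preset, _seed(base_seed, i))
        traces = measure_embryo_axons(image[0], truth.geometry)
        lengths += [t.length_um for t in traces if t.present]
    return float(np.mean(lengths))


def embryo_mean_lengths(preset: str, base_seed: int, n: int) -> list[float]:
    """Per-embryo mean traced axon length (um) for ``n`` embryos."""
    out: list[float] = []
    for i in range(n):
        image, truth = generate_embryo(preset, _seed(base_seed, i))
        traces = measure_embryo_axons(image[0], truth.geometry)
        out.append(float(np.mean([t.length_um for t in traces
                                  if t.present])))
    return out


def presynaptic_stats(preset: str, base_seed: int, n: int,
                      params: MeasureParams | None = None) -> dict:
    """Per-embryo presynaptic puncta area, count and intensity summaries."""
    out = {"area": [], "count": [], "intensity": []}
    for i in range(n):
        image, truth = generate_embryo(preset, _seed(base_seed, i))
        m = measure_embryo(image, truth.geometry, params)
        if not m.usable:
            continue
        out["area"].append(m.pre.total_area_um2)
        out["count"].append(m.pre.puncta_count)
        out["intensity"].append(m.pre.mean_intensity)
    return out


def percent_abnormal_group(preset: str, base_seed: int, n: int) -> list[float]:
    """Per-embryo percent of axons scored morphologically abnormal."""
    out: list[float] = []
    for i in range(n):
        image, truth = generate_embryo(preset, _seed(base_seed, i))
        rules = AbnormalityRules.for_geometry(truth.geometry)
        traces = measure_embryo_axons(image[0], truth.geometry,
                                      rules=rules)
        _, pct = score_abnormal(traces, rules)
        out.append(pct)
    return out
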