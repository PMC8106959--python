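"""Low-level rendering primitives for the synthetic embryo generator.

Axons are constructed directly as 8-connected pixel chains; the recorded
true length of an axon is the Euclidean chain length (1 per axial step,
sqrt(2) per diagonal step) times the pixel size.  A sinusoidal lateral
meander, whose amplitude is solved by bisection, gives each chain the arc
length drawn from the preset's length distribution while placing the tip at
the required row (at the horizontal myoseptum for stalled axons, beyond it
for crossed ones).  Tracing a noise-free rendering therefore recovers the
truth up to skeletonization effects at the chain ends.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy import stats, optimize

SQRT2 = math.sqrt(2.0)


# ---------------------------------------------------------------------------
# calibrated truncated normal
# ---------------------------------------------------------------------------

@lru_cache(maxsize=256)
def _truncnorm_loc(mean: float, sd: float, low: float, high: float) -> float:
    """Location parameter so the *truncated* normal has the nominal mean.

    Truncation to [low, high] shifts the mean of a normal away from its
    location parameter; solving for the location keeps group calibration
    exact in expectation despite feasibility bounds.
    """
    if not low < mean < high:
        raise ValueError(f"nominal mean {mean} outside truncation "
                         f"interval ({low}, {high})")

    def truncated_mean(loc: float) -> float:
        a, b = (low - loc) / sd, (high - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd)

    lo, hi = mean - 8.0 * sd, mean + 12.0 * sd
    return float(optimize.brentq(lambda m: truncated_mean(m) - mean, lo, hi,
                                 xtol=1e-8))


def sample_calibrated_length(rng: np.random.Generator, mean: float, sd: float,
                             low: float, high: float = np.inf,
                             size: int | None = None):
    """Draw lengths from a truncated normal whose mean equals ``mean``."""
    hi_key = float(high) if np.isfinite(high) else math.inf
    loc = _truncnorm_loc(round(mean, 6), round(sd, 6), round(low, 6), hi_key)
    a, b = (low - loc) / sd, (high - loc) / sd
    u = rng.random(size)
    return stats.truncnorm.ppf(u, a, b, loc=loc, scale=sd)


def stochastic_round(rng: np.random.Generator, x: float) -> int:
    """Round to floor(x) or ceil(x) with probabilities preserving the mean."""
    base = math.floor(x)
    frac = x - base
    return base + (1 if rng.random() < frac else 0)


# ---------------------------------------------------------------------------
# axon chains
# ---------------------------------------------------------------------------

def chain_length(path: list[tuple[int, int]]) -> float:
    """Euclidean length of an 8-connected pixel chain, in pixels."""
    total = 0.0
    for (r0, c0), (r1, c1) in zip(path, path[1:]):
        total += SQRT2 if (r0 != r1 and c0 != c1) else 1.0
    return total


def build_axon_chain(rng: np.random.Generator, exit_rc: tuple[int, int],
                     drop: int, target_len_px: float,
                     max_amplitude: float) -> list[tuple[int, int]]:
    """Chain of ``drop`` row-advances whose length matches ``target_len_px``.

    Only axial and diagonal steps are used (the local slope never exceeds
    one column per row), so the chain is the digitization of a smooth
    ventrally growing curve: re-skeletonizing a rendered tube reproduces
    the same step mix and hence the same Euclidean chain length.  The
    fraction of diagonal steps is chosen so the realized length matches the
    target to within half a diagonal step; the lateral excursion drifts
    between ``+-max_amplitude`` columns, flipping direction at the bounds.
    Requires ``drop <= target_len_px <= sqrt(2) * drop``.
    """
    r0, c0 = exit_rc
    surplus = max(0.0, target_len_px - drop)
    k = min(drop, int(round(surplus / (SQRT2 - 1.0))))
    direction0 = 1 if rng.random() < 0.5 else -1
    phase = rng.random()

    def make(k_diag: int) -> list[tuple[int, int]]:
        slope = k_diag / drop if drop else 0.0
        direction, err, pos = direction0, phase, 0
        path = [(r0, c0)]
        for i in range(1, drop + 1):
            err += slope
            if err >= 1.0 - 1e-9:
                err -= 1.0
                if abs(pos + direction) > max_amplitude:
                    direction = -direction
                    # brief axial plateau at the turn: a sharp V-corner
                    # would be rounded (shortened) by tube skeletonization
                    err -= 1.5
                else:
                    pos += direction
            path.append((r0 + i, c0 + pos))
        return path

    # turns consume diagonal budget; top the budget up until the realized
    # chain length matches the target (within half a diagonal step)
    path = make(k)
    for _ in range(4):
        deficit = target_len_px - chain_length(path)
        if deficit <= 0.5 * SQRT2 or k >= drop:
            break
        k = min(drop, k + int(math.ceil(deficit / (SQRT2 - 1.0))))
        path = make(k)
    return path


def build_branch_chain(rng: np.random.Generator, attach_rc: tuple[int, int],
                       main_cols_by_row: dict[int, list[int]],
                       extent_px: float, direction: int,
                       shape: tuple[int, int],
                       descent_prob: float = 0.4) -> list[tuple[int, int]]:
    """Side-branch chain walked outward until its maximal column displacement
    from the main-axon path (at the same row) reaches ``extent_px``.

    Tracking displacement against the live main-path columns makes the
    recorded lateral extent exactly the quantity the offset-line branch
    counting rule measures, independent of the main axon's meander.
    """
    r, c = attach_rc
    path = [(r, c)]
    guard = 0
    while guard < 200:
        guard += 1
        step_down = 1 if rng.random() < descent_prob else 0
        nr, nc = r + step_down, c + direction
        if not (0 <= nr < shape[0] and 0 <= nc < shape[1]):
            break
        r, c = nr, nc
        path.append((r, c))
        ref_cols = main_cols_by_row.get(r)
        if ref_cols is None:
            # below the axon tip: measure against the deepest path row
            ref_cols = main_cols_by_row[max(main_cols_by_row)]
        disp = min(abs(c - rc) for rc in ref_cols)
        if disp >= extent_px:
            break
    return path


def lateral_extent(path: list[tuple[int, int]],
                   main_cols_by_row: dict[int, list[int]]) -> float:
    """Maximal column displacement of a branch from the main path, pixels."""
    worst = 0.0
    deepest = max(main_cols_by_row)
    for r, c in path:
        ref = main_cols_by_row.get(r, main_cols_by_row[deepest])
        worst = max(worst, min(abs(c - rc) for rc in ref))
    return worst


# ---------------------------------------------------------------------------
# stamping and puncta
# ---------------------------------------------------------------------------

def stamp_chain(img: np.ndarray, path: list[tuple[int, int]],
                amplitude: float, edge_fraction: float = 0.45,
                tip_blob: bool = False) -> None:
    """Stamp a pixel chain at full amplitude with anti-aliased 4-neighbours.

    With ``tip_blob`` the last pixel gets a bright 3x3 cap (a growth cone),
    which keeps skeletonization from retracting the free end.
    """
    rows, cols = img.shape
    rr = np.array([p[0] for p in path])
    cc = np.array([p[1] for p in path])
    for dr, dc, frac in ((0, 0, 1.0), (-1, 0, edge_fraction),
                         (1, 0, edge_fraction), (0, -1, edge_fraction),
                         (0, 1, edge_fraction)):
        r2, c2 = rr + dr, cc + dc
        ok = (r2 >= 0) & (r2 < rows) & (c2 >= 0) & (c2 < cols)
        np.maximum.at(img, (r2[ok], c2[ok]), amplitude * frac)
    if tip_blob and len(path):
        tr, tc = path[-1]
        r_lo, r_hi = max(0, tr - 1), min(rows, tr + 2)
        c_lo, c_hi = max(0, tc - 1), min(cols, tc + 2)
        np.maximum(img[r_lo:r_hi, c_lo:c_hi], amplitude,
                   out=img[r_lo:r_hi, c_lo:c_hi])


def stamp_gaussian_spot(img: np.ndarray, center: tuple[float, float],
                        sigma_px: float, amplitude: float) -> None:
    """Add one Gaussian punctum (additive, truncated at 4 sigma)."""
    r0, c0 = center
    rad = int(math.ceil(4.0 * sigma_px))
    r_lo, r_hi = max(0, int(r0) - rad), min(img.shape[0], int(r0) + rad + 1)
    c_lo, c_hi = max(0, int(c0) - rad), min(img.shape[1], int(c0) + rad + 1)
    if r_lo >= r_hi or c_lo >= c_hi:
        return
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    d2 = (rr - r0) ** 2 + (cc - c0) ** 2
    img[r_lo:r_hi, c_lo:c_hi] += amplitude * np.exp(-d2 / (2.0 * sigma_px ** 2))


def place_puncta(rng: np.random.Generator, n: int,
                 region: tuple[float, float, float, float],
                 min_separation: float,
                 n_candidates: int = 40) -> list[tuple[float, float]]:
    """Well-spread placement of ``n`` centers inside a (r0,r1,c0,c1) box.

    Greedy farthest-point (maximin) selection: each center is the uniform
    candidate maximizing its distance to the centers already placed, with
    candidates at ``min_separation`` or more accepted immediately.  This
    keeps puncta from overlapping into single thresholded components while
    never failing on crowded boxes.
    """
    r0, r1, c0, c1 = region
    pts: list[tuple[float, float]] = []
    for _ in range(n):
        best, best_d = None, -1.0
        for _ in range(n_candidates):
            cand = (rng.uniform(r0, r1), rng.uniform(c0, c1))
            d = min(((cand[0] - p[0]) ** 2 + (cand[1] - p[1]) ** 2) ** 0.5
                    for p in pts) if pts else math.inf
            if d >= min_separation:
                best = cand
                break
            if d > best_d:
                best, best_d = cand, d
        pts.append(best)
    return pts
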