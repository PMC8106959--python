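"""Synthetic lateral-view embryo images, plate-structured screens, ground truth.

The generator emulates the output of an automated embryo-imaging platform:
one multi-channel 2-D frame per embryo (channel 0 motor-neuron reporter,
channel 1 presynaptic label, channel 2 postsynaptic label), a JSON ground
truth sidecar, and a CSV plate manifest.  Each preset encodes one
experimental group (see :mod:`capscreen.presets`); identical
``(preset, seed)`` pairs regenerate bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .geometry import EmbryoGeometry
from .presets import (Preset, get_preset, AXON_AMP, BACKGROUND_FRACTION)
from .render import (sample_calibrated_length, stochastic_round,
                     build_axon_chain, build_branch_chain, lateral_extent,
                     chain_length, stamp_chain, stamp_gaussian_spot,
                     place_puncta)
from .truth import (GroundTruth, AxonTruth, BranchSpec, PunctaTruth,
                    PunctaChannelTruth, TOXICITY_STATES)

__all__ = ["generate_embryo", "sample_embryo_truth", "generate_screen",
           "ScreenDesign", "CompoundClass", "write_embryo",
           "DEFAULT_GEOMETRY"]

DEFAULT_GEOMETRY = EmbryoGeometry(
    pixel_size=1.0, exit_row=22, hm_row=55, ventral_extent_row=120,
    exit_cols=(30, 82, 134, 186, 238, 290, 342, 394), shape=(144, 424),
)

# feasibility margins, in micrometres
_MIN_CROSS_EXTENSION = 5.0    # a crossed tip sits at least this far past the HM
_MAX_CROSS_EXTENSION = 18.0
_MEANDER_AMPLITUDE_UM = 8.0
_MIN_STALLED_LENGTH = 10.0
# branch lateral-extent classes (um): filopodia are never counted at the 8 um
# offset lines, developmental branches are, and only ectopic branches exceed
# the 14 um abnormality offset.
_FILOPODIUM_EXTENT = (3.0, 5.0)
_DEV_BRANCH_EXTENT = (9.0, 10.0)
_ECTOPIC_EXTENT = (16.5, 18.5)


# ---------------------------------------------------------------------------
# axon truth construction
# ---------------------------------------------------------------------------

def _span_um(geometry: EmbryoGeometry) -> float:
    return geometry.px_to_um(geometry.hm_row - geometry.exit_row)


def _length_bounds(preset: Preset, geometry: EmbryoGeometry):
    """Feasible length intervals and conditional means for crossed/stalled.

    A crossed axon must be long enough to descend past the HM with a slope
    at most one column per row (chain length <= sqrt(2) x row drop), a
    stalled axon short enough to fit the exit-to-HM span at that slope.
    Conditional means are solved so the grand mean over crossing states
    equals the preset mean exactly, with crossed axons nominally 8 um
    longer than stalled ones (clamped into the feasible intervals).
    """
    span = _span_um(geometry)
    lo_c = span + _MIN_CROSS_EXTENSION + 1.0
    hi_c = 1.41 * (span + _MAX_CROSS_EXTENSION) - 1.0
    lo_s = _MIN_STALLED_LENGTH
    hi_s = 1.38 * span
    if preset.abnormal_count_mean > 0:
        # normal axons in abnormality-scored groups stay clearly longer
        # than the short-axon criterion (exit->HM + 10 um)
        lo_c = max(lo_c, span + 14.0)
    p, mean, delta = preset.p_cross, preset.length_mean_um, 8.0
    s = preset.sd_um
    # margins proportional to the spread keep the calibrated truncated
    # normals solvable (a mean too close to a bound cannot be realized)
    m_c = mean + delta * (1.0 - p)
    m_s = mean - delta * p
    m_s = min(max(m_s, lo_s + 0.3 * s), hi_s - 0.75 * s)
    if p > 0:
        m_c = (mean - (1.0 - p) * m_s) / p
    m_c = min(max(m_c, lo_c + 0.3 * s), hi_c - 0.3 * s)
    if p < 1:
        m_s = (mean - p * m_c) / (1.0 - p)
        if not lo_s < m_s < hi_s:
            raise ValueError(f"preset {preset.name!r}: mean length "
                             f"{mean} um infeasible for this geometry")
    return dict(crossed=(lo_c, hi_c, m_c), stalled=(lo_s, hi_s, m_s))


def _sample_axon_plan(rng: np.random.Generator, preset: Preset,
                      geometry: EmbryoGeometry) -> list[dict]:
    """Per-axon generative decisions: mechanism, crossing, nominal length."""
    n_axons = geometry.n_hemisegments
    k_abn = min(stochastic_round(rng, preset.abnormal_count_mean), n_axons)
    abn_idx = set(rng.choice(n_axons, size=k_abn, replace=False).tolist()) \
        if k_abn else set()
    mech_w = np.asarray(preset.abnormal_mechanisms, dtype=float)
    mech_w = mech_w / mech_w.sum() if mech_w.sum() > 0 else np.array([0, 0, 1.0])
    bounds = _length_bounds(preset, geometry)

    plans = []
    for i in range(n_axons):
        plan: dict = {"mechanism": None}
        if i in abn_idx:
            mech = ("missing", "truncated", "ectopic")[
                int(rng.choice(3, p=mech_w))]
            plan["mechanism"] = mech
            if mech == "missing":
                plans.append(plan)
                continue
            if mech == "truncated":
                plan["crossed"] = False
                plan["length_um"] = float(rng.uniform(12.0, 26.0))
                plans.append(plan)
                continue
            # ectopic: a normally grown axon carrying an aberrant branch
        crossed = bool(rng.random() < preset.p_cross) \
            if plan["mechanism"] is None else True
        plan["crossed"] = crossed
        lo, hi, m = bounds["crossed" if crossed else "stalled"]
        plan["length_um"] = float(sample_calibrated_length(
            rng, m, preset.sd_um, lo, hi))
        plans.append(plan)
    return plans


def _build_axons(rng: np.random.Generator, preset: Preset,
                 geometry: EmbryoGeometry):
    """Realize axon chains and truth records from the per-axon plans."""
    px = geometry.pixel_size
    span = _span_um(geometry)
    span_px = geometry.hm_row - geometry.exit_row
    max_amp_px = max(2.0, _MEANDER_AMPLITUDE_UM / px)
    ventral_cap = geometry.px_to_um(geometry.ventral_extent_row
                                    - geometry.hm_row) - 2.0

    truths: list[AxonTruth] = []
    chains: list[list[tuple[int, int]] | None] = []
    branch_chains: list[list[list[tuple[int, int]]]] = []

    for i, plan in enumerate(_sample_axon_plan(rng, preset, geometry)):
        col = geometry.exit_cols[i]
        if plan["mechanism"] == "missing":
            truths.append(AxonTruth(present=False, true_length_um=0.0,
                                    crossed_hm=False, abnormal=True,
                                    tip=None, exit_col=col))
            chains.append(None)
            branch_chains.append([])
            continue

        length_um = plan["length_um"]
        len_px = length_um / px
        if plan["crossed"]:
            # feasible tip extension past the HM at slope <= 1
            e_lo = max(_MIN_CROSS_EXTENSION, length_um / 1.41 - span + 0.5)
            e_hi = min(_MAX_CROSS_EXTENSION, length_um - span - 1.0,
                       ventral_cap)
            ext = float(rng.uniform(e_lo, max(e_lo, e_hi)))
            drop = int(round((span + ext) / px))
        else:
            jitter = int(rng.integers(0, 3))
            drop = min(int(0.97 * len_px), span_px - jitter)
            drop = max(drop, 3, int(math.ceil(len_px / 1.41)))
            drop = min(drop, span_px)
        chain = build_axon_chain(rng, (geometry.exit_row, col), drop,
                                 len_px, max_amp_px)
        realized_um = geometry.px_to_um(chain_length(chain))

        # main-path columns per row, for branch displacement bookkeeping
        cols_by_row: dict[int, list[int]] = {}
        for r, c in chain:
            cols_by_row.setdefault(r, []).append(c)

        branches: list[BranchSpec] = []
        bchains: list[list[tuple[int, int]]] = []
        long_used: list[tuple[int, int]] = []   # (direction, attach idx)

        def _add_branch(extent_range: tuple[float, float],
                        force: bool = False) -> None:
            long = extent_range[0] >= 8.0
            lo_i = int(0.20 * len(chain))
            # forced (ectopic) branches attach dorsally so they can never
            # out-measure the remaining main axon
            hi_i = max(lo_i + 1, int((0.30 if force else 0.45) * len(chain)))
            idx = int(rng.integers(lo_i, hi_i))
            direction = 1 if rng.random() < 0.5 else -1
            if long:
                # keep countable branches apart so they cannot merge into
                # one skeleton component
                for d in (direction, -direction):
                    if all(d != ud or abs(idx - ui) >= 10
                           for ud, ui in long_used):
                        direction = d
                        break
                else:
                    if not force:
                        return
                long_used.append((direction, idx))
            extent_um = float(rng.uniform(*extent_range))
            # skip branches that would out-measure the remaining main axon,
            # so the geodesic tip selection stays unambiguous (short stalled
            # axons carry proportionally fewer branches)
            attach_len = chain_length(chain[:idx + 1])
            est_branch = 1.25 * extent_um / px + 2.0
            if not force and \
                    attach_len + est_branch >= 0.95 * chain_length(chain):
                return
            bc = build_branch_chain(rng, chain[idx], cols_by_row,
                                    extent_um / px, direction, geometry.shape)
            ext_um = geometry.px_to_um(lateral_extent(bc, cols_by_row))
            branches.append(BranchSpec(
                attach_index=idx, lateral_extent_um=ext_um,
                side="posterior" if direction > 0 else "anterior"))
            bchains.append(bc)

        if plan["mechanism"] == "ectopic":
            _add_branch(_ECTOPIC_EXTENT, force=True)
        for _ in range(rng.poisson(preset.filopodia_per_axon)):
            _add_branch(_FILOPODIUM_EXTENT)
        for _ in range(rng.poisson(preset.branches_per_axon)):
            _add_branch(_DEV_BRANCH_EXTENT)

        truths.append(AxonTruth(
            present=True, true_length_um=realized_um,
            crossed_hm=bool(plan["crossed"]),
            abnormal=plan["mechanism"] is not None,
            tip=chain[-1], exit_col=col, branches=branches))
        chains.append(chain)
        branch_chains.append(bchains)
    return truths, chains, branch_chains


# ---------------------------------------------------------------------------
# puncta truth construction
# ---------------------------------------------------------------------------

def _sample_puncta(rng: np.random.Generator, preset: Preset,
                   geometry: EmbryoGeometry) -> PunctaTruth:
    px = geometry.pixel_size
    params = preset.puncta.realized_params()
    roi_half = geometry.um_to_px(10.0)

    channels: dict[str, PunctaChannelTruth] = {}
    pre_centers_by_hemi: list[list[tuple[float, float]]] = []
    for chan in ("pre", "post"):
        p = params[chan]
        sigma_px = p["sigma_um"] / px
        margin = math.ceil(2.2 * sigma_px) + 1
        sep = 7.0 * sigma_px
        truth = PunctaChannelTruth()
        for h, ccol in enumerate(geometry.exit_cols):
            n = stochastic_round(rng, p["count_mean"])
            region = (geometry.hm_row - roi_half + margin,
                      geometry.hm_row + roi_half - margin,
                      ccol - roi_half + margin, ccol + roi_half - margin)
            if chan == "pre":
                centers = place_puncta(rng, n, region, sep)
                pre_centers_by_hemi.append(centers)
            else:
                # postsynaptic puncta apposed to presynaptic ones with jitter
                pre_c = pre_centers_by_hemi[h]
                centers = []
                for k in range(n):
                    if k < len(pre_c):
                        r = pre_c[k][0] + rng.normal(0.0, 0.8)
                        c = pre_c[k][1] + rng.normal(0.0, 0.8)
                        r = min(max(r, region[0]), region[1])
                        c = min(max(c, region[2]), region[3])
                        centers.append((r, c))
                    else:
                        centers.extend(place_puncta(rng, 1, region, sep))
            for (r, c) in centers:
                truth.centers.append((float(r), float(c)))
                truth.sigmas_um.append(
                    float(p["sigma_um"] * math.exp(rng.normal(0.0, 0.08))))
                truth.amplitudes.append(
                    float(p["amplitude"] * math.exp(rng.normal(0.0, 0.03))))
        channels[chan] = truth

    e = preset.puncta
    return PunctaTruth(
        pre=channels["pre"], post=channels["post"],
        area_ratio_pre=e.area_ratio_pre, count_ratio_pre=e.count_ratio_pre,
        intensity_ratio_pre=e.intensity_ratio_pre,
        area_ratio_post=e.area_ratio_post, count_ratio_post=e.count_ratio_post,
        intensity_ratio_post=e.intensity_ratio_post,
    )


# ---------------------------------------------------------------------------
# public generator API
# ---------------------------------------------------------------------------

def sample_embryo_truth(preset: str | Preset, seed: int,
                        geometry: EmbryoGeometry | None = None):
    """Ground truth plus render plans, without producing an image.

    Returns ``(truth, chains, branch_chains)``; :func:`generate_embryo`
    consumes the same draws, so the truth is identical in both modes.
    """
    preset = get_preset(preset) if isinstance(preset, str) else preset
    geometry = geometry or DEFAULT_GEOMETRY
    rng = np.random.default_rng(seed)
    axons, chains, bchains = _build_axons(rng, preset, geometry)
    puncta = _sample_puncta(rng, preset, geometry)
    truth = GroundTruth(preset=preset.name, seed=int(seed), geometry=geometry,
                        axons=axons, puncta=puncta)
    return truth, chains, bchains


def generate_embryo(preset: str | Preset, seed: int,
                    geometry: EmbryoGeometry | None = None,
                    noise: bool = True):
    """Render one synthetic embryo.

    Parameters
    ----------
    preset : str or Preset
        Registered preset name (see :func:`capscreen.presets.list_presets`)
        or a preset object.
    seed : int
        Reproducibility seed; identical ``(preset, seed)`` give identical
        bytes.
    noise : bool
        If False, the additive Gaussian noise stage is skipped (background
        offset is still applied), for noise-free oracle checks.

    Returns
    -------
    image : (3, rows, cols) float32 ndarray
        Channel 0 motor-neuron reporter, 1 presynaptic, 2 postsynaptic.
    truth : GroundTruth
    """
    preset = get_preset(preset) if isinstance(preset, str) else preset
    geometry = geometry or DEFAULT_GEOMETRY
    truth, chains, bchains = sample_embryo_truth(preset, seed, geometry)
    rng = np.random.default_rng((int(seed) + 1) * 7919 % (2 ** 31))  # noise stream

    img = np.zeros((3,) + tuple(geometry.shape), dtype=np.float64)
    for chain, bcs in zip(chains, bchains):
        if chain is None:
            continue
        stamp_chain(img[0], chain, AXON_AMP)
        for bc in bcs:
            stamp_chain(img[0], bc, AXON_AMP * 0.9)

    px = geometry.pixel_size
    for ci, chan in ((1, truth.puncta.pre), (2, truth.puncta.post)):
        for center, s_um, amp in zip(chan.centers, chan.sigmas_um,
                                     chan.amplitudes):
            stamp_gaussian_spot(img[ci], center, s_um / px, amp)

    params = preset.puncta.realized_params()
    amps = (AXON_AMP, params["pre"]["amplitude"], params["post"]["amplitude"])
    for ci, amp in enumerate(amps):
        img[ci] += BACKGROUND_FRACTION * amp
        if noise and preset.snr:
            img[ci] += rng.normal(0.0, amp / preset.snr, size=img[ci].shape)
    np.clip(img, 0.0, None, out=img)
    return img.astype(np.float32), truth


def write_embryo(image: np.ndarray, truth: GroundTruth, out_dir: str | Path,
                 embryo_id: str) -> tuple[Path, Path]:
    """Write one embryo as multi-channel TIFF plus JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tiff_path = out_dir / f"{embryo_id}.tiff"
    json_path = out_dir / f"{embryo_id}.truth.json"
    tifffile.imwrite(tiff_path, image, photometric="minisblack")
    truth.save(json_path)
    return tiff_path, json_path


# ---------------------------------------------------------------------------
# plate-structured screens
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompoundClass:
    """True effect class of one library compound."""

    kind: str = "inactive"            # inactive | active | toxic
    effect: float = 1.0               # rescue-index multiple for actives
    toxicity: str = "none"            # death | delayed | malformed for toxic

    def __post_init__(self) -> None:
        if self.kind not in ("inactive", "active", "toxic"):
            raise ValueError(f"unknown compound class {self.kind!r}")
        if self.kind == "toxic" and self.toxicity not in TOXICITY_STATES[1:]:
            raise ValueError("toxic compounds need a toxicity state")


@dataclass
class ScreenDesign:
    """Layout and truth structure of a simulated compound screen.

    Defaults mirror the study design: six embryos per compound at 10 uM,
    eight scoreable axons per embryo, 20 compounds per 96-well plate (three
    embryos per well) with one internal DMSO-mutant control group per plate
    placed in the first two wells, four random mid-plate wells and the last
    two wells.
    """

    n_compounds: int
    embryos_per_compound: int = 6
    axons_per_embryo: int = 8
    compounds_per_plate: int = 20
    embryos_per_well: int = 3
    control_preset: str = "chodl-DMSO"
    concentration_uM: float = 10.0
    classes: list[CompoundClass] = field(default_factory=list)
    active_effect: float = 3.4        # true rescue-index multiple of actives
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")
        if self.embryos_per_compound < 1:
            raise ValueError("embryos_per_compound must be >= 1")
        if not self.classes:
            self.classes = [CompoundClass()] * self.n_compounds
        if len(self.classes) != self.n_compounds:
            raise ValueError("classes must have one entry per compound")

    @classmethod
    def replicate_study(cls, seed: int = 0, n_compounds: int = 982,
                        n_active: int = 12,
                        toxic_split: tuple[int, int, int] = (47, 22, 13),
                        active_effect: float = 3.4, **kw) -> "ScreenDesign":
        """Design with the screen's truth structure: 982 compounds, 12 true
        actives, 82 toxic compounds split 47 death / 22 delayed / 13
        malformed, positions shuffled by ``seed``."""
        classes = [CompoundClass("active", effect=active_effect)
                   for _ in range(n_active)]
        for state, n in zip(("death", "delayed", "malformed"), toxic_split):
            classes += [CompoundClass("toxic", toxicity=state)
                        for _ in range(n)]
        classes += [CompoundClass()] * (n_compounds - len(classes))
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(classes))
        classes = [classes[i] for i in order]
        return cls(n_compounds=n_compounds, classes=classes,
                   active_effect=active_effect, seed=seed, **kw)


_ROWS = "ABCDEFGH"


def well_label(index: int, n_cols: int = 12) -> str:
    return f"{_ROWS[index // n_cols]}{index % n_cols + 1}"


def _control_well_indices(rng: np.random.Generator, n_wells: int = 96):
    """First two wells, four random mid-plate wells, last two wells."""
    middle = rng.choice(np.arange(n_wells // 4, 3 * n_wells // 4), size=4,
                        replace=False)
    return [0, 1] + sorted(int(i) for i in middle) + [n_wells - 2, n_wells - 1]


def generate_screen(design: ScreenDesign,
                    geometry: EmbryoGeometry | None = None,
                    render: bool = False, out_dir: str | Path | None = None):
    """Simulate a plate-structured screen.

    In the default score-only mode the per-embryo number of axons beyond the
    HM is drawn as binomial(axons_per_embryo, p) with p = p_control for
    inactive compounds and p = min(effect x p_control, 0.95) for actives;
    toxic compounds' embryos carry their toxicity state and no scores.  With
    ``render=True`` every non-toxic embryo is also rendered and written to
    ``out_dir``.

    Returns
    -------
    records : DataFrame
        One row per compound x embryo (and per control embryo) with columns
        plate, well, embryo_id, compound_id, true_class, true_effect,
        toxicity, n_scored, n_crossed.
    manifest : DataFrame
        Plate manifest (embryo_id, well, compound_id, concentration_uM,
        orientation, acquisition_time, image_path).
    """
    geometry = geometry or DEFAULT_GEOMETRY
    rng = np.random.default_rng(design.seed)
    control = get_preset(design.control_preset)
    p_control = control.p_cross
    wells_per_compound = math.ceil(design.embryos_per_compound
                                   / design.embryos_per_well)
    n_plates = math.ceil(design.n_compounds / design.compounds_per_plate)
    n_control_wells = 8

    rec_rows: list[dict] = []
    man_rows: list[dict] = []
    t_step = 0

    def _emit(plate, well_idx, embryo_id, compound_id, klass: CompoundClass,
              conc, preset_for_render: Preset | None):
        nonlocal t_step
        toxic = klass.kind == "toxic"
        if toxic:
            n_crossed = np.nan
        else:
            p = p_control if klass.kind == "inactive" \
                else min(klass.effect * p_control, 0.95)
            if compound_id == "DMSO-control":
                p = p_control
            n_crossed = int(rng.binomial(design.axons_per_embryo, p))
        image_path = ""
        if render and not toxic and out_dir is not None:
            pr = preset_for_render or control
            img, tr = generate_embryo(pr, int(rng.integers(0, 2 ** 31)),
                                      geometry)
            tiff, _ = write_embryo(img, tr, out_dir, embryo_id)
            image_path = str(tiff)
            n_crossed = tr.n_crossed
        rec_rows.append(dict(
            plate=plate, well=well_label(well_idx), embryo_id=embryo_id,
            compound_id=compound_id, true_class=klass.kind,
            true_effect=klass.effect if klass.kind == "active" else 1.0,
            toxicity=klass.toxicity,
            n_scored=design.axons_per_embryo,
            n_crossed=n_crossed))
        man_rows.append(dict(
            embryo_id=embryo_id, well=well_label(well_idx),
            compound_id=compound_id, concentration_uM=conc,
            orientation="lateral",
            acquisition_time=pd.Timestamp("2021-01-04 09:00:00")
            + pd.Timedelta(seconds=100 * t_step),
            image_path=image_path))
        t_step += 1

    ctrl_class = CompoundClass()
    compound_idx = 0
    for plate in range(1, n_plates + 1):
        ctrl_wells = _control_well_indices(rng)
        free_wells = [w for w in range(96) if w not in ctrl_wells]
        # internal control embryos
        for w in ctrl_wells:
            for e in range(design.embryos_per_well):
                _emit(plate, w, f"P{plate:02d}-{well_label(w)}-{e + 1}",
                      "DMSO-control", ctrl_class, 0.0, control)
        # compounds, two consecutive free wells each
        on_plate = min(design.compounds_per_plate,
                       design.n_compounds - compound_idx)
        for k in range(on_plate):
            cid = f"C{compound_idx + 1:04d}"
            klass = design.classes[compound_idx]
            wells = free_wells[k * wells_per_compound:
                               (k + 1) * wells_per_compound]
            if klass.kind == "active":
                from dataclasses import replace as _replace
                render_preset = _replace(
                    control, name=f"{control.name}+{cid}",
                    p_cross=min(klass.effect * p_control, 0.95))
            else:
                render_preset = control
            emitted = 0
            for w in wells:
                for e in range(design.embryos_per_well):
                    if emitted >= design.embryos_per_compound:
                        break
                    _emit(plate, w, f"P{plate:02d}-{well_label(w)}-{e + 1}",
                          cid, klass, design.concentration_uM, render_preset)
                    emitted += 1
            compound_idx += 1

    records = pd.DataFrame(rec_rows)
    manifest = pd.DataFrame(man_rows)
    return records, manifest
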