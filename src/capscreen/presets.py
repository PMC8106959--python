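"""Preset registry: the group conditions the synthetic generator emulates.

Each preset encodes one experimental group of the chodl-mutant screening
study as generative parameters: the per-axon probability of growing beyond
the horizontal myoseptum (HM), the mean total CaP axon length, neuromuscular
puncta effect multipliers relative to the DMSO wild-type control, and the
expected number of morphologically abnormal axons per embryo.

Means are reported study values; spreads (sd, branch rates, the wild-type
length itself) are the generator's own choices and are flagged as such in
the preset ``note``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

# Wild-type-control base rendering parameters shared by all presets.
BASE_PUNCTA_COUNT = 5.0          # mean puncta per 400 um^2 HM ROI
BASE_PUNCTA_SIGMA_UM = 0.9       # Gaussian radius of one punctum
BASE_AMP_PRE = 120.0             # presynaptic (synaptotagmin-2) peak intensity
BASE_AMP_POST = 100.0            # postsynaptic (AChR) peak intensity
AXON_AMP = 150.0                 # motor-neuron reporter line intensity
# diffuse background (autofluorescence) as a fraction of channel amplitude;
# keeping it proportional makes every channel scale-invariant under the
# relative 30%-of-max threshold
BACKGROUND_FRACTION = 0.30


@dataclass(frozen=True)
class PunctaEffects:
    """Nominal multipliers relative to the wild-type DMSO preset."""

    area_ratio_pre: float = 1.0
    count_ratio_pre: float = 1.0
    intensity_ratio_pre: float = 1.0
    area_ratio_post: float = 1.0
    count_ratio_post: float = 1.0
    intensity_ratio_post: float = 1.0

    def realized_params(self) -> dict:
        """Per-channel rendering parameters achieving the nominal ratios.

        Under a relative threshold at fraction f of the ROI peak, the
        measured area of a Gaussian punctum of radius sigma is
        2*pi*sigma^2 * ln(peak/threshold).  On a pixel grid the sampled peak
        is attenuated by about exp(-1/(12 sigma^2)) (mean subpixel offset of
        the brightest pixel), which makes the area affine in sigma^2:
        area(sigma) ~= c0 sigma^2 + pi/6 with c0 = 2 pi ln(1/f).  The mutant
        sigma is obtained by inverting this relation, so the nominal
        area-per-count ratio is what the measurement pipeline realizes, not
        just the idealized sigma^2 law.
        """
        import math

        f = 0.30                      # documented pipeline threshold fraction
        c0 = 2.0 * math.pi * math.log(1.0 / f)
        c1 = math.pi / 6.0
        base_area = c0 * BASE_PUNCTA_SIGMA_UM ** 2 + c1
        out = {}
        for chan, amp0 in (("pre", BASE_AMP_PRE), ("post", BASE_AMP_POST)):
            a = getattr(self, f"area_ratio_{chan}")
            c = getattr(self, f"count_ratio_{chan}")
            i = getattr(self, f"intensity_ratio_{chan}")
            target_area = (a / c) * base_area
            sigma = math.sqrt(max(target_area - c1, 1e-6) / c0)
            out[chan] = {
                "count_mean": BASE_PUNCTA_COUNT * c,
                "sigma_um": sigma,
                "amplitude": amp0 * i,
            }
        return out


@dataclass(frozen=True)
class Preset:
    """One synthetic experimental group."""

    name: str
    note: str
    p_cross: float                     # per-axon P(grow beyond the HM)
    length_mean_um: float              # nominal mean total CaP length
    length_sd_um: float | None = None  # default: 20 % of the mean
    abnormal_count_mean: float = 1.0   # expected abnormal axons of 8 scored
    # mechanism mix for abnormal axons: (missing, truncated, ectopic-branch)
    abnormal_mechanisms: tuple[float, float, float] = (0.0, 0.0, 1.0)
    # expected side branches per axon by class (normal axons only)
    filopodia_per_axon: float = 0.7    # lateral extent < 8 um, never counted
    branches_per_axon: float = 0.8     # extent ~9.5-11 um, counted at 8 um lines
    puncta: PunctaEffects = field(default_factory=PunctaEffects)
    snr: float = 15.0                  # peak amplitude / noise sd; None = noise-free

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_cross <= 1.0:
            raise ValueError("p_cross must be in [0, 1]")
        if self.length_mean_um <= 0:
            raise ValueError("length_mean_um must be positive")

    @property
    def sd_um(self) -> float:
        return self.length_sd_um if self.length_sd_um is not None \
            else 0.2 * self.length_mean_um

    def to_dict(self) -> dict:
        d = asdict(self)
        d["abnormal_mechanisms"] = list(self.abnormal_mechanisms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Preset":
        d = dict(d)
        d["abnormal_mechanisms"] = tuple(d["abnormal_mechanisms"])
        d["puncta"] = PunctaEffects(**d["puncta"])
        return cls(**d)


# Reported chodl-mutant synapse phenotype at the HM, relative to wild type:
# 58 % larger presynaptic area, 83 % brighter presynaptic label, fewer
# discernible puncta (postsynaptic count down 37 %; presynaptic count
# reduction not printed, set to 0.60 as the generator's choice).
_CHODL_PUNCTA = PunctaEffects(
    area_ratio_pre=1.58, count_ratio_pre=0.60, intensity_ratio_pre=1.83,
    area_ratio_post=1.0, count_ratio_post=0.63, intensity_ratio_post=1.0,
)

_UBA1_MIX = (0.25, 0.45, 0.30)   # missing / truncated / ectopic-branch

_PRESETS: dict[str, Preset] = {}


def _register(p: Preset) -> Preset:
    _PRESETS[p.name] = p
    return p


_register(Preset(
    name="wild-type-DMSO",
    note=("DMSO-treated wild-type control: all 8 CaP axons grown beyond the "
          "HM; mean length 50 um is the generator's choice (not a reported "
          "value); baseline one abnormal (ectopically branched) axon of 8."),
    p_cross=1.0, length_mean_um=50.0, length_sd_um=10.0,
    abnormal_count_mean=1.0, abnormal_mechanisms=(0.0, 0.0, 1.0),
))

_register(Preset(
    name="chodl-DMSO",
    note=("chodl -/- mutant internal control: reported mean total CaP length "
          "35.06 um; typically 2 of 8 axons beyond the HM (p = 0.25); "
          "reported synapse multipliers: presynaptic area x1.58, presynaptic "
          "intensity x1.83, postsynaptic count x0.63."),
    p_cross=0.25, length_mean_um=35.06,
    abnormal_count_mean=0.0,
    filopodia_per_axon=0.3, branches_per_axon=0.3,
    puncta=_CHODL_PUNCTA,
))

# Concentration series for the three top hits; length ratios are reported
# percent-of-control values applied to the 35.06 um mutant control mean.
for _name, _ratio, _p, _note_extra, _puncta in [
    ("dipyridamole-10uM", 1.35, 0.65,
     "presynaptic area fully rescued; puncta count and intensity not rescued",
     replace(_CHODL_PUNCTA, area_ratio_pre=1.0)),
    ("dipyridamole-30uM", 1.33, 0.65, "",
     replace(_CHODL_PUNCTA, area_ratio_pre=1.0)),
    ("iox1-10uM", 1.39, 0.60,
     "all presynaptic defects rescued",
     PunctaEffects(count_ratio_post=0.63)),
    ("iox1-50uM", 1.58, 0.70,
     "presynapse rescued; postsynaptic area reduced by 32 %",
     PunctaEffects(count_ratio_post=0.63, area_ratio_post=0.68)),
    ("mg132-10uM", 1.18, 0.55, "", _CHODL_PUNCTA),
]:
    _register(Preset(
        name=_name,
        note=(f"chodl mutant treated with {_name.replace('-', ' at ')}: "
              f"reported mean CaP length {100 * _ratio:.0f} % of the "
              f"DMSO-chodl control. " + _note_extra).strip(),
        p_cross=_p, length_mean_um=round(_ratio * 35.06, 3),
        abnormal_count_mean=0.0,
        filopodia_per_axon=0.4, branches_per_axon=0.4,
        puncta=_puncta,
    ))

_register(Preset(
    name="uba1",
    note=("UBEI-41-treated (UBA1-inhibition) SMA model: reported 117 % "
          "increase in abnormal axons over the DMSO control baseline "
          "(expected abnormal count 1.0 x 2.17 of 8 scored axons); abnormal "
          "axons are missing, truncated or ectopically branched."),
    p_cross=1.0, length_mean_um=50.0, length_sd_um=10.0,
    abnormal_count_mean=2.17, abnormal_mechanisms=_UBA1_MIX,
))

_register(Preset(
    name="uba1+dipyridamole",
    note=("UBEI-41 plus 10 uM dipyridamole: reported 31 % decrease in the "
          "abnormal-axon fraction relative to UBEI-41 alone "
          "(expected abnormal count 2.17 x 0.69)."),
    p_cross=1.0, length_mean_um=50.0, length_sd_um=10.0,
    abnormal_count_mean=round(2.17 * 0.69, 4), abnormal_mechanisms=_UBA1_MIX,
))

_register(Preset(
    name="uba1+quercetin",
    note=("UBEI-41 plus 50 uM quercetin (positive rescue control): abnormal "
          "fraction restored to the DMSO control baseline."),
    p_cross=1.0, length_mean_um=50.0, length_sd_um=10.0,
    abnormal_count_mean=1.0, abnormal_mechanisms=_UBA1_MIX,
))


def list_presets() -> dict[str, Preset]:
    """Return the registry (name -> :class:`Preset`), a shallow copy."""
    return dict(_PRESETS)


def get_preset(name: str) -> Preset:
    """Look up a preset; unknown names raise with the available names."""
    try:
        return _PRESETS[name]
    except KeyError:
        avail = ", ".join(sorted(_PRESETS))
        raise ValueError(f"unknown preset {name!r}; available: {avail}") from None
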