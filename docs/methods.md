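# Methods

This note documents the models, parameter choices and numerical decisions
behind `capscreen`: what the synthetic-embryo generator emulates, how the
measurement pipeline is defined, and what passing the test suite does and
does not establish about real screen data.

## Coordinate frame and geometry

Lateral-view images use 0-based pixel indices with rows increasing
dorsal → ventral and columns increasing anterior → posterior.  "Beyond the
horizontal myoseptum (HM)" means the axon tip row is strictly ventral of
`hm_row`; the HM-crossing classifier adds a 2 µm margin to make the visual
scoring rule reproducible at pixel resolution.  The default geometry places
the spinal exit row 33 µm dorsal of the HM, eight hemisegment exit columns
52 µm apart (somites 7–14), and a ventral myotome limit 65 µm below the HM,
at 1 µm/pixel (configurable).  All thresholds scale with `pixel_size`.

## Synthetic axons

Axons are constructed directly as 8-connected pixel chains, and the chain's
Euclidean length (1 per axial step, √2 per diagonal step) times the pixel
size **is** the recorded true length.  Chains use only axial and diagonal
steps — the local slope never exceeds one column per row — so a chain is the
digitization of a smooth ventrally growing curve; re-skeletonizing a
rendered tube reproduces the same step mix and hence the same length.  The
lateral meander drifts between ±8 µm with a short axial plateau at each
turn (a sharp V-corner would be rounded, i.e. shortened, by
skeletonization).  The number of diagonal steps is iterated until the
realized chain length matches the sampled target within half a diagonal
step.

Per-axon lengths are drawn from truncated normal distributions whose
*truncated* mean is solved by root-finding on the location parameter, so
group calibration is exact in expectation despite feasibility bounds (a
crossed axon must be long enough to pass the HM at slope ≤ 1, a stalled
axon short enough to fit the exit→HM span).  Crossing states are Bernoulli
with the preset's `p_cross`; conditional crossed/stalled means are solved
so the grand mean equals the preset mean, with crossed axons nominally 8 µm
longer and sd-proportional clamping at the feasibility bounds.  For presets
whose nominal mean approaches the geometric ceiling (the 158 %
percent-of-control group) the realized mean saturates ~3 % low; the
acceptance-relevant presets calibrate within 1 %.

Branches are walked outward from an attachment point on the main chain
until their maximal column displacement *from the main path at the same
row* — exactly the quantity the offset-line counting rule measures —
reaches the sampled extent.  Extent classes keep the truth unambiguous
against both counting thresholds: filopodia 3–5 µm (never reach the 8 µm
lines), developmental branches 9–10 µm (counted at 8 µm, never at the
14 µm abnormality offset), ectopic branches 16.5–18.5 µm.  Long branches
on the same side are kept ≥ 10 rows apart so they cannot merge into one
skeleton component, and branches that would out-measure the remaining main
axon are skipped so the geodesic tip selection stays unambiguous (short
stalled axons therefore carry proportionally fewer branches).

## Abnormal axons and dispersion

An abnormal axon is missing, truncated (uniform 12–26 µm), or ectopically
branched; the mechanism mix for the UBA1-inhibition presets is 25/45/30 %.
The DMSO wild-type baseline is one abnormal (ectopically branched) axon of
eight; the UBA1 preset multiplies the expected abnormal count by 2.17 and
the dipyridamole co-treatment preset by a further 0.69.  Per-embryo
abnormal counts (and per-ROI puncta counts) are drawn by **stochastic
rounding** of the expectation — floor or ceiling with probabilities that
preserve the mean — rather than as independent Bernoulli draws.  This is a
deliberate low-dispersion design: the generator's purpose is effect-size
calibration, and with only 7–8 axons per embryo and 30–50 embryos per
group, binomial axon-level noise alone would swamp a ±10-point check on a
117 % ratio.  Real embryo-to-embryo variability is wider; recovery of these
ratios on synthetic groups therefore demonstrates measurement fidelity, not
the statistical power of a real screen at those group sizes.  Per-embryo
HM⁺ counts in score-only screen mode remain binomial(8, p), which is the
dispersion that matters for hit-calling behaviour.

## Rendering and noise

Chains are stamped at full amplitude with 4-neighbour anti-aliased edges
(0.45×); puncta are additive 2-D Gaussians.  Each channel receives a
diffuse background of 0.30× its peak amplitude and white Gaussian noise of
amplitude/SNR, default SNR 15.  Two properties of this model are
load-bearing:

- the background and the noise scale with each channel's amplitude, so the
  relative 30 %-of-max puncta threshold sees geometrically identical images
  in every group and mutant/control ratios are unbiased (an absolute
  background or noise floor would shift the effective threshold differently
  for channels of different brightness);
- at SNR 15 the noise tail stays clear of the 30 % threshold, so puncta
  segmentation — not denoising — is what the tests exercise.

## Synthetic puncta

Per hemisegment ROI the wild-type presynaptic channel holds 5 puncta of
radius σ = 0.9 µm; counts scale by the preset count ratio, peak amplitudes
by the intensity ratio.  Under a threshold at fraction f of the ROI peak,
the measured area of one punctum is 2πσ²·ln(peak/threshold), and on a pixel
grid the sampled peak is attenuated by ≈ exp(−1/(12σ²)), making the area
affine in σ²: area(σ) ≈ c₀σ² + π/6 with c₀ = 2π·ln(1/f).  The generator
inverts this relation (not the naive σ² law) to choose the mutant σ, so the
nominal area ratio is what the measurement pipeline actually realizes.
The π/6 term is a pixel-level correction and is exact at the default
1 µm/pixel; at other pixel sizes the realized area ratio shifts by a
percent-scale amount.  Puncta centers are placed by greedy farthest-point
(maximin) selection with a separation target of 7σ, which keeps thresholded
puncta from merging into single components; postsynaptic puncta are placed
apposed to presynaptic ones with 0.8 px jitter, so pre/post overlap is
structural, as at a synapse.  Occasional merging of the large mutant puncta
still loses ~5–8 % of their count (area is conserved); puncta-count ratios
are therefore recovered more coarsely than area and intensity ratios.

## Axon measurement

Tracing binarizes a hemisegment window by iterated Otsu: if a threshold
pass marks more than 15 % of the window as foreground — impossible for one
axon, the signature of Otsu splitting the background noise — the threshold
is re-estimated on the upper class (≤ 3 passes).  A contrast gate
(foreground–background separation ≥ 3 background sd) plus a 5 µm capture
radius around the exit point rejects windows with no credible axon.  The
skeleton (8-connected) component nearest the exit point is traversed by
Dijkstra from the skeleton pixel nearest the exit; the main axon is the
geodesic path to the endpoint of maximal geodesic distance, ties within
half a pixel broken toward the more ventral endpoint (the growth
direction).  The exit point is prepended to the path, which compensates the
dorsal skeleton retraction.  Length is the Euclidean chain sum × pixel
size.  On noise-free renderings presence, HM status and branch counts equal
ground truth on every axon and lengths agree within ~1 % (worst axons
~4 %); at SNR 15 the per-axon length error is ≈ 0 ± 3 %.

Branch counting re-segments the window, removes the main path from the
skeleton, keeps components 8-adjacent to the path, and counts a component
once per side on which its maximal same-row column displacement reaches the
offset (8 µm for branch counts, 14 µm for the ectopic-branch abnormality
rule).  Displacement-based crossing is equivalent to intersecting the
offset guide lines for attached branches but robust to ±1 px skeleton
shifts.

## Synapse measurement

Per hemisegment: a 20 µm square ROI centred on (HM row, hemisegment
centre); top-hat background subtraction with a 10 µm disk (a rolling-ball
analogue), clipped at zero; threshold at 30 % of the ROI maximum (the
documented reading of a "30 % threshold" — percent of display range or a
fixed grey level would be alternative readings); 8-connected components of
≥ 2 px are puncta.  Mean punctum intensity is measured on the
background-subtracted image by default (`intensity_on="raw"` selects raw
pixels).  The overlap compartment is the conjunction of the pre and post
masks.  Embryo values average hemisegments 2–6 (five ROIs; at least four
valid ROIs required, otherwise the embryo is flagged unusable).

## Screen statistics

The rescue index pools crossed/scored counts over embryos by default
(`method="per-embryo"` averages per-embryo fractions instead; with six
embryos of eight axons the pooled form is the more stable of the two).
Hit calling is inclusive at RI ≥ 2.5 — the canonical worked example (5/8
vs 2/8) lands exactly on the threshold and is a hit.  Compounds with any
toxicity state (death, delayed development, severe malformation) are
excluded before hit calling and reported as counts and percent of all
compounds tested.

Group comparisons gate on per-group Shapiro–Wilk normality at α = 0.05
("as appropriate" made operational): all groups normal → t-test (two
groups) or one-way ANOVA with Dunnett's (vs-control) or Tukey's
(all-pairs) post hoc; otherwise Mann–Whitney U or Kruskal–Wallis with
Dunn's post hoc.  Dunn's test is implemented directly (rank-based z with
tie correction; two-sided normal p times the number of comparisons, capped
at 1 — the procedure's built-in adjustment, with no additional correction
on top).  Post-hoc power uses the observed effect size: Cohen's d with the
pooled SD through the noncentral t (two groups) or Cohen's f through the
noncentral F (more groups), via `statsmodels`; it is reported as
observed-effect power, a design diagnostic rather than evidence.

## Plate simulation

Screens follow the study layout: compounds at 10 µM, six embryos per
compound, three embryos per well in 96-well plates, 20 compounds per
plate, and one internal DMSO-mutant control group per plate in the first
two wells, four random mid-plate wells and the last two wells (a
first-vs-last-wells Mann–Whitney drift check is reported, non-blocking).
Score-only mode draws per-embryo HM⁺ counts directly (binomial) for fast
statistics testing; render mode writes TIFF + ground-truth sidecars and
re-measures them with the tracing pipeline.  True actives multiply the
control crossing probability by their rescue-index effect (default 3.4,
capped at 0.95); toxic compounds' embryos carry their state and are never
scoreable.

## Known limitations

- The generator renders single 2-D frames: no z-stacks, projection
  artefacts, pigmentation, or stitching seams; secondary motor axons and
  neighbouring-structure clutter are absent.  Tracing accuracy on real
  projections will be worse than the synthetic figures above.
- Preset spreads (length sd = 20 % of the mean unless stated, branch
  rates, the 50 µm wild-type mean length, the presynaptic count ratio
  0.60, the wild-type abnormal baseline of 1/8) are generator choices where
  the study reports means or directions only; each is flagged in the
  preset's `note`.
- Percent-of-control presets near the geometric ceiling (≥ 1.5× the
  control mean) saturate a few percent low.
- The subpixel area-inversion constant assumes the default threshold
  fraction (0.30) and is exact at 1 µm/pixel.
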