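# capscreen

Automated analysis for in vivo small-molecule screens that read out zebrafish
CaP motor-axon growth and neuromuscular-synapse morphology.

In the *chodl⁻/⁻* (chondrolectin) mutant, CaP motor axons stall at the
horizontal myoseptum (HM), the intermediate synaptic target, because the
en-passant synapses formed there do not mature.  Axon growth beyond the HM is
therefore a fast, quantifiable proxy for synapse stabilisation, and a
plate-based screen can score thousands of compounds by how many axons they
push past the HM.  `capscreen` implements the complete analysis side of such
a screen:

- **axon quantification** — trace each CaP axon from its spinal exit point
  to its tip in the motor-neuron reporter channel (Otsu binarisation,
  skeletonisation, geodesic path selection), measure total path length,
  classify each axon as stalled at or grown beyond the HM, count side
  branches crossing guide lines 8 µm anterior/posterior of the axon, and
  score axons normal/abnormal (missing, truncated, or ectopically branched)
  for the UBA1-inhibition SMA model;
- **synapse quantification** — in a square 400 µm² ROI at the HM, subtract
  background (morphological top-hat), threshold at 30 % of the ROI maximum,
  and count/measure pre- and postsynaptic puncta and their overlap,
  averaged over 4–5 hemisegments per embryo;
- **screen statistics** — toxicity exclusion, the rescue index
  RI = (crossing fraction, treated) / (crossing fraction, DMSO-mutant
  internal control), hit calling at RI ≥ 2.5, percent-of-control axon
  length, and normality-gated group comparison (Shapiro–Wilk gate; t-test /
  one-way ANOVA with Dunnett or Tukey vs Mann–Whitney / Kruskal–Wallis with
  Dunn) with post-hoc power from the noncentral t/F distributions;
- **synthetic embryos** — a calibrated generator that renders lateral-view
  multi-channel embryo images (reporter, presynaptic, postsynaptic
  channels), plate-structured screens with internal-control wells and
  toxicity states, and JSON ground-truth sidecars, so every stage of the
  pipeline can be validated against known truth.

The central screening statistic is the rescue index

    RI = (Σ crossed_treated / Σ scored_treated) /
         (Σ crossed_control / Σ scored_control)

pooled over embryos (eight scoreable axons per embryo, somites 7–14), with
compounds reaching RI ≥ 2.5 called first-stage hits and re-examined by total
axon length in a second stage.

## Worked example

The worked RI example: five of eight axons beyond the HM against two of
eight in the internal control,

```python
>>> from capscreen import rescue_index
>>> rescue_index([(5, 8)], [(2, 8)])
2.5
```

which sits exactly at the (inclusive) hit threshold.  From the shell, a
synthetic embryo pair and its measurements:

```
$ capscreen simulate --preset chodl-DMSO --seed 7 --n 2 --out embryos
wrote embryos/chodl-DMSO-s7.tiff
wrote embryos/chodl-DMSO-s8.tiff
$ capscreen quantify-axons embryos --out axons.csv
chodl-DMSO-s7: 1/8 crossed, 88% abnormal
chodl-DMSO-s8: 1/8 crossed, 100% abnormal
```

One or two of eight axons beyond the HM is exactly the stalled mutant
phenotype the screen is built on.  The per-axon table starts:

```
embryo_id,axon_id,present,length_um,hm_status,branch_count,ectopic_branch_count,abnormal
chodl-DMSO-s7,0,True,37.627,stalled,0,0,True
chodl-DMSO-s7,1,True,39.657,crossed,0,0,True
```

(the `abnormal` column applies the UBA1-model scoring rules, under which
stalled mutant axons are short — it is not used for the chodl screen
itself).  A small score-only screen, end to end:

```
$ capscreen screen --seed 2 --out run
20 compounds, 2 hits (10.00%), 2 toxic (10.00%)
```

`run/` then holds the plate manifest, per-embryo records, per-compound
rescue indices with hit flags, and a JSON summary embedding the config hash
and seed; rerunning with the same configuration reproduces every file
byte-identically.

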