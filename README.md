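# drdtrial

Statistical analysis stack for **paired-eye diagnostic-accuracy
non-inferiority trials** of autonomous AI systems that screen for diabetic
retinal disease (DRD) in primary care. It is written for biostatisticians and
trial methodologists who need the complete chain from case definitions to
equity metrics as tested, reusable code:

- **Case definitions** on the ETDRS severity scale: referable DRD
  (ETDRS ≥ 35 or diabetic macular edema), vision-threatening DRD
  (ETDRS ≥ 53 or DME), center-involved DME (OCT central subfield > 300 µm),
  with worst-eye aggregation to the participant level.
- **Accuracy engine**: eye- and participant-level confusion tables against a
  Level I prognostic standard or a Level II reading-center standard,
  sensitivity/specificity/PPV/NPV/likelihood ratios, diagnosability, and
  worst-case imputation of insufficient-quality results.
- **Clustered inference**: participant-clustered bootstrap (eyes never
  separated from their cluster), disease-spectrum expansion of ETDRS ≥ 53
  eyes to a target fraction of positives, one-sided 97.5% lower confidence
  bounds, non-inferiority p-values, fixed-sequence hierarchical testing, and
  design power simulation.
- **Screening equity**: Population Achieved Sensitivity (PAS) and the
  break-even adoption ratio between two screening systems, with Monte-Carlo
  uncertainty and a literature-derived clinical-risk lookup.
- **Bias audit**: subgroup and intersectional sensitivity/specificity
  comparisons (sex, Black vs non-Black, Hispanic vs non-Hispanic) with
  clustered-bootstrap p-values and a total suppression rule for subgroups
  under 10 participants.
- **Synthetic trials + reference fixture**: a seeded generator whose defaults
  reproduce the published trial's marginals, and a 1073-eye reference dataset
  reconstructed exactly from published counts
  (`src/drdtrial/data/paper_eyes.csv`).

## The model in brief

For a unit (eye or participant) with true disease status per the reference
standard, the AI emits `detected`, `not_detected`, or `insufficient_quality`.
Diagnosable units form a 2×2 table; sensitivity p̂ = TP/(TP+FN) and
specificity = TN/(TN+FP). Non-inferiority tests

    H0: p < p0   vs.   HA: p ≥ p0,   p0 = 0.75 (sens), 0.775 (spec)

one-sided at α = 0.025 via the participant-clustered bootstrap: replicates
resample whole participants, the one-sided 97.5% lower bound is the empirical
2.5th percentile, and the NI p-value is the smoothed tail probability
(1 + #{p̂\* ≤ p0})/(B + 1). Study success requires both rejections.

Population Achieved Sensitivity for a system with sensitivity s_c,
diagnosability d_c, access c, and prevalences p_c / p̂_nc:

    PAS = s_c · c · p_c · d_c / (c·p_c + (1−c)·p̂_nc)  ≅  s_c · c · d_c

The break-even ratio PAS_ref/PAS_new eliminates c and gives the adoption
multiple above which the more-adoptable system finds more true cases.

## Worked example

```bash
python examples/03_accuracy_worst_case.py
```

prints

```
observed sensitivity:   79.7%  (220/276)
observed specificity:   88.4%  (696/787)
worst-case sensitivity: 64.5%  (220/341)
worst-case specificity: 83.9%  (696/830)
```

— the observed operating point among diagnosable eyes, then the lower bound
obtained by counting every insufficient-quality diseased eye as a miss and
every insufficient-quality healthy eye as a false alarm. And

```bash
python examples/05_pas_break_even.py
```

prints

```
break-even adoption ratio: 1.07x  (95% MC interval 0.99-1.16)
```

meaning a handheld-camera system with 81.5% participant-level sensitivity
identifies more true DRD cases than an 87.2%-sensitivity desktop system once
its adoption exceeds 1.07× — the quantitative case that easier adoption can
outweigh a small sensitivity deficit. The other `examples/` scripts cover
case definitions, the synthetic generator, the clustered bootstrap, and the
bias audit; a thin CLI (`drdtrial simulate|analyze|infer|pas|audit|pipeline`)
wraps the same functions for shell use.

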