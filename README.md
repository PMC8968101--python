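# myoecv

Cardiac-MRI **extracellular volume fraction (ECV)** versus histological
**cardiomyocyte breadth (CmyB)** — a tested, reusable re-implementation of the
quantitative chain used to show that, in healthy myocardium, larger
cardiomyocytes go with a *smaller* ECV.

## The problem

ECV is widely read as a fibrosis index, but it is a ratio of volumes: anything
that grows the cells shrinks the extracellular fraction even when nothing
fibrotic is happening. Quantifying that under physiological conditions needs
the full measurement chain:

1. **MOLLI T1 relaxometry** — magnitude inversion-recovery signals are fitted
   to the three-parameter model `S(TI) = |A − B·exp(−TI/T1*)|` with the
   Look-Locker correction `T1 = T1*·(B/A − 1)`, after restoring the signal
   polarity lost by magnitude reconstruction.
2. **Partition-coefficient regression** — per animal, myocardial
   `R1 = 1000/T1` is regressed on blood-pool R1 over the pre-contrast point
   plus every post-contrast point inside the detected contrast-equilibrium
   window (never earlier than 5 min post-injection). The slope is the
   gadolinium partition coefficient λ, and

   `ECV = λ · (1 − hematocrit)`.

3. **H&E morphometry** — in each 356 × 266 µm field, cell cross-sections are
   segmented (color deconvolution → Otsu → distance-transform watershed),
   fitted with second-moment ellipses, filtered by the study's inclusion rules
   (intact outline, approximately oval, centered nucleus), and the minor-axis
   length is recorded as the breadth. The *shorter* diameter is used because
   out-of-plane tilt of the fiber axis elongates only the long diameter.
4. **Cohort statistics** — Shapiro–Wilk screening, Pearson correlation with a
   Fisher-z confidence interval, and Cohen's κ for reader agreement.

The package ships the published 16-animal table as a first-class fixture and a
synthetic-cohort generator (contrast kinetics, MOLLI signal stacks, T1-map
phantoms, H&E-like histology fields) with exact ground truth, so every stage
can be validated by recovery rather than by eye.

## Worked example

Replicate the published per-animal table:

```
$ myoecv table1
cohort: 16 animals, 14 analyzed
ECV: 0.253 ± 0.043 (n = 14)
CmyB: 10.02 ± 0.84 μm (n = 14)
body weight: 24.3 ± 3.9 kg (n = 16)
ECV vs CmyB: r = -0.728, p = 0.003, n = 14, 95% CI [-0.908, -0.322]
```

Two animals contribute no endpoints (one death, one failed enhanced scan), so
ECV/CmyB statistics pool 14 animals while covariates cover all 16. The
correlation is strongly negative: animals with broader cardiomyocytes have a
lower extracellular fraction. (Recomputing r from the printed 3-decimal values
gives −0.7284; the published −0.729 was computed from unrounded data.)

The same chain runs end-to-end on synthetic pigs with known truth:

```sh
myoecv run --out scratch/demo --n-animals 14 --corr=-0.73 --seed 0 \
    --n-fields 2 --um-per-px 1.0 --t1-measurement ideal
```

which prints the pipeline-estimated cross-animal correlation with its
confidence interval and writes per-animal λ, equilibrium window start, ECV and
CmyB to `results.csv`. `myoecv simulate` writes a cohort to disk (histology
PNGs, truth CSVs, manifest with checksums), `myoecv measure-cmyb` re-measures
saved fields, and `myoecv fit-t1` / `myoecv estimate-ecv` expose the two core
fits on plain CSV inputs.

As a library:

```python
from myoecv.cohort import load_table1, analyzable_subset
from myoecv.stats import pearson

sub = analyzable_subset(load_table1())
print(pearson([r.ecv for r in sub], [r.cmyb_mean for r in sub]))
```

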