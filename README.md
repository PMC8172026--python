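# castrop — IOL power calculation with the Castrop vergence formula

`castrop` is a scientific Python package for intraocular lens (IOL) power
calculation in cataract surgery. Its core is the **Castrop formula**, a
paraxial vergence model of the pseudophakic eye with four refracting
surfaces (front and back corneal surface, thin IOL, spectacle correction)
and three lens-specific constants. Around it the package provides:

- five classical comparator formulae — SRK/T, Hoffer Q (with published
  errata), Holladay 1, and Haigis in single-constant and triplet mode;
- constant optimization for every formula by a damped (Levenberg–Marquardt)
  least-squares scheme with box constraints, minimizing the root mean
  squared prediction error (rmsPE) of the spherical equivalent;
- a cross-validated evaluation protocol (train/test split, prediction-error
  statistics, within-limit fractions, a composite formula performance
  index, paired Wilcoxon signed-rank comparisons with Bonferroni
  correction);
- a calibrated synthetic biometry generator for method development and
  validation when clinical data cannot be shared;
- CSV/XLSX import with schema mapping and a `castrop` command-line
  interface.

The intended audience is researchers in ophthalmic optics and biostatistics
who want a transparent, testable reference implementation of modern
vergence-based IOL power calculation.

## The model

All distances are in mm, powers and vergences in dioptres (dpt). The
axially measured quantities are axial length `AL`, anterior chamber depth
`ACD` (epithelium to lens), lens thickness `LT`, and the mean corneal front
radius `RCA`. The effective lens plane is predicted from the phakic
anatomy with two of the three constants:

```
ELP = ACD + C·LT + H
```

Light from a spectacle-plane target refraction is propagated through the
system: translation over the vertex distance (default 12 mm, air),
refraction at the corneal front surface `P_CA = (n_C − 1)/R_CA` with
`n_C = 1.376`, translation through the cornea (thickness `d_C`, default
0.5 mm), refraction at the back surface `P_CP = (n − n_C)/R_CP` with
aqueous index `n = 1.336`, and translation to the lens plane. The IOL
power is the difference between the vergence required to focus on the
retina, `n/(AL − ELP)`, and the arriving vergence. When the posterior
radius is not measured it is derived from the fixed Gullstrand ratio
`R_CP = R_CA · 6.4/7.77`. The third constant `R` is an additive offset on
the predicted spherical-equivalent refraction that absorbs systematic
refraction bias. Forward (power for a target) and inverse (predicted
refraction for an implanted power) directions are exact algebraic inverses
of each other; the test suite verifies the round trip to 1e-9 dpt and
checks the closed forms against an independent surface-by-surface paraxial
ray trace.

## Worked example

All formulae are scikit-learn-style estimators: constructor arguments are
the lens constants, `fit(X, y)` optimizes them against observed
refractions, `predict` returns the predicted spherical equivalent.

```python
import pandas as pd
from castrop import CastropFormula
from castrop.simulate import GeneratorSpec, generate_dataset
from castrop.evaluation import evaluate_formulas

# Population-mean eye, constants typical of a one-piece acrylic IOL
eye = pd.DataFrame({"AL": [23.497], "ACD": [3.099], "LT": [4.608], "RCA": [7.668]})
f = CastropFormula(c=0.424, h=-0.312, r=0.077)

print(f.iol_power(eye, target_se=-0.5))            # [21.43622449]
print(f.predict_refraction(eye.assign(PIOL=21.5))) # [-0.54656718]

# Full benchmark on a synthetic cohort of 1452 eyes
df = generate_dataset(GeneratorSpec(n=1452, seed=1))
table, reports = evaluate_formulas(df, seed=1)
print(table[["formula", "rmsPE", "absPE_median", "within_0.5", "FPI"]].round(4))
```

Output of the last statement:

```
  formula  rmsPE  absPE_median  within_0.5     FPI
     srkt 0.7271        0.4725      0.5241  0.7235
  hofferq 0.6424        0.4082      0.5632  0.9017
holladay1 0.6687        0.4180      0.5770  0.8071
   haigis 0.5583        0.3834      0.6345  1.0208
  haigis3 0.5171        0.3567      0.6552  1.0814
  castrop 0.4699        0.3212      0.7057  1.1802
```

Each formula's constants are optimized on a 70 % training split and
evaluated on the held-out 30 % (1017 / 435 eyes at n = 1452); with the
generator's defaults the Castrop formula's rmsPE on the test split
recovers the injected refraction noise (0.45 dpt) plus the power-rounding
contribution.

## Command line

```sh
castrop simulate --n 300 --seed 7 --out cohort.csv
castrop optimize --data cohort.csv --formula castrop --out constants.json
castrop predict  --data cohort.csv --formula castrop \
    --constants 0.424,-0.312,0.077 --mode power --target-se -0.5 --out powers.csv
castrop evaluate --data cohort.csv --seed 1 --out report.csv --plot-dir figs/
```

The `optimize` run above prints, for seed 7:

```json
{
  "formula": "castrop",
  "constants": {"c": 0.4358, "h": -0.4813, "r": 0.2078},
  "iterations": 7,
  "converged_by": "ftol",
  "rmsPE": 0.4727
}
```

together with the (monotonically non-increasing) SSE trajectory and a hash
of the effective configuration; every artifact records its seed so runs
are reproducible byte-for-byte.

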