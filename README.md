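# petsim

Simulation study of how errors in MR-based attenuation correction (MRAC) of
brain FDG-PET propagate into an automated Alzheimer's-disease discrimination
statistic, run entirely on synthetic phantoms — no patient data required.

PET quantification on PET/MR scanners depends on attenuation maps derived
from MR (zero-echo-time bone imaging, or registration of a CT atlas) instead
of a measured CT. The resulting voxelwise bias is multiplicative, so it can
be encoded as an *error map* — the ratio of an MRAC-corrected PET volume to
its CT-corrected counterpart — and imposed on any normalized PET volume by
voxelwise multiplication. This package builds such error fields in two
regimes (low-variance "ZTE-like", high-variance "atlas-like"), crosses them
with a cohort of uptake phantoms, and measures the effect on the automated
AD score:

- per-voxel Student t of a subject against a voxelwise age-regression normal
  database, t_v = (a_v + b_v·age − u_v) / (s_v·sqrt(1 + 1/n + (age − ā)²/S_xx)),
  after 12 mm Gaussian smoothing and intensity normalization to a
  preserved-uptake mask;
- AD t-sum = Σ t_v over an AD-pattern voxel set;
- PET score = log2(AD t-sum / 11089 + 1), so score 1 marks the published 95%
  prediction limit of the AD t-sum.

Audience: PET/MR methods researchers and developers of automated dementia
classifiers who want a fully reproducible, downloadable-data-free testbed for
attenuation-correction error propagation. See `docs/methods.md` for the
model details and limitations.

## Worked example

The numbered drivers under `analysis/` run the study end to end on a 32³
template grid (48 NC + 59 AD phantoms, 27 error maps per regime, hence
107 × 27 = 2889 simulated scores per regime):

```
python analysis/01_simulate_inputs.py --seed 7
python analysis/02_fit_normal_database.py
python analysis/03_inject_errors_and_score.py --seed 7
python analysis/04_diagnostic_accuracy.py --seed 7
```

which prints (seed 7):

```
PET-score differences vs original (per regime):
  Atlas_like  signed   mean -0.0790  SD 0.2762  range [-0.9334, +0.4535]  (n=2889)
  Atlas_like  absolute mean +0.2153  SD 0.1901  range [+0.0042, +0.9334]  (n=2889)
  ZTE_like    signed   mean -0.0274  SD 0.0940  range [-0.2930, +0.1565]  (n=2889)
  ZTE_like    absolute mean +0.0779  SD 0.0593  range [+0.0030, +0.2930]  (n=2889)
paired t-test of |error| (Atlas_like vs ZTE_like): t = 42.38, p = 1.39e-305
Atlas_like: y = 1.1206x + -0.1064, R^2 = 0.999; bias -0.0790, LOA [-0.130, -0.028]
ZTE_like: y = 1.0342x + -0.0351, R^2 = 1.000; bias -0.0274, LOA [-0.042, -0.013]
```

Reading: both regimes underestimate the PET score slightly on average
(skull-concentrated −2% bias survives intensity normalization only through
its spatial structure), while the low-variance ZTE-like regime shows a ~3×
smaller mean absolute score error and tighter limits of agreement — the
variability of the attenuation error, not its mean, is what degrades the
score. Spatially *uniform* bias cancels exactly in the normalization; the
test suite asserts this. Score tables land in `results/score_table.csv`,
metrics in `results/metrics.json`, figures in `results/figures/`; binary
NIfTI intermediates go to `scratch/`.

The same workflow is available as a CLI (`petsim run-all --seed 7 --outdir
results/study`) with subcommands `simulate-data`, `build-db`, `score`,
`simulate-study`, `evaluate` for running stages against files on disk.

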