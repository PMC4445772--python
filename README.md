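# bgmrsi

Proton MR spectroscopic imaging (MRSI) of the basal ganglia, end to end:
from a 24 × 24 phase-encode k-space acquisition to pure grey-matter and
white-matter metabolite levels in institutional units (IU), with a
synthetic brain-phantom cohort generator standing in for scanner data.

## Who this is for

MRS methodologists and neuroimaging analysts who need a tested, fully
reproducible reference implementation of the classic single-slab MRSI
analysis chain used in ageing studies at 1.5 T: cosine-apodised spatial
Fourier reconstruction, residual-water self-referencing (zero-order phase,
eddy-current and frequency correction), HLSVD water removal, AMARES-style
prior-knowledge time-domain fitting, a strict ordered voxel-rejection
cascade, T1/T2- and proton-normalised quantification, tissue-fraction
overlay, and random-intercept mixed-effects extrapolation to pure tissue.

## The model

Each voxel FID is modelled as Gaussian-damped resonances

```
s(t) = Σ_k a_k e^{iφ_k} exp(2πi f_k t − β_k t²) + water + noise
```

with three in-phase singlets (Cho 3.20, Cre 3.03, NAA 2.02 ppm) and an
inverted lactate doublet (1.31 ppm, 7.3 Hz split). Fitted areas are
converted to institutional units by

```
IU = area / (exp(−TE/T2) · (1 − exp(−TR/T1)) · n_protons)
```

(3 protons for NAA and creatine, 9 for choline). Valid voxels enter a
random-intercept linear mixed model

```
y_ij = β0 + β1·x_ij + u_i + ε_ij,     x = (%WM − %GM)/(%WM + %GM)
```

so that pure-WM and pure-GM levels are `β0 ± β1`. Per-voxel metabolite
ratios are modelled the same way.

## Worked example

```
bgmrsi simulate --seed 1 --n-subjects 10 --out cohort/
bgmrsi process  --in cohort/ --out proc/
bgmrsi stats    --in proc/  --out stats/
```

`stats/table1.txt` from this exact run:

```
      response       WM       GM p (GM vs WM)
Metabolites (IU)
           NAA    75.34    69.47            0
           Cho    13.21    10.25            0
           Cre    42.71    56.02            0
Metabolite ratios (IU)
       naa_cho     5.70     6.71            0
       naa_cre     1.76     1.20            0
       cho_cre     0.31     0.17            0
Spectral peak area ratios
  area_naa_cho     1.74     2.05            0
  area_naa_cre     2.54     1.73            0
  area_cho_cre     1.45     0.81            0
```

(p-values below double-precision underflow print as 0.)

Reading it: creatine extrapolates higher in grey matter (56 vs 43 IU)
while choline and NAA are higher in white matter — the expected tissue
contrasts — and the estimates recover the generator's ground-truth preset
(GM/WM creatine 57/44, choline 10/13, NAA 70/76 IU) to within a few
percent through the complete measurement chain. `proc/attrition.json`
accounts for every rejected voxel by cascade stage (background, CSF, NAA
fit, visual proxy, Cho/Cre fit), and `stats/cohort_stats.json` adds
subject-level correlations (including percent-valid-voxels against mean
NAA linewidth, which comes out negative — r = −0.56 in this run: poorer
shim, fewer usable voxels).

Note that the mixed-model estimates for per-voxel IU *ratios* are not
quotients of the level estimates: a ratio is a convex function of the
tissue contrast, so its linear extrapolation is a distinct quantity. Both
are reported.

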