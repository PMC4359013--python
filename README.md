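# linrelax

General linear relaxometry of brain R1 from multi-parameter mapping (MPM)
data, with a synthetic brain-phantom / multi-echo FLASH simulator so every
stage of the analysis can be verified without scanner data.

## The scientific problem

The longitudinal relaxation rate R1 = 1/T1 measured in vivo reflects the
local tissue microenvironment: free water, macromolecular content, and
paramagnetic iron. Under fast exchange between water pools, the observed R1
is a pool-fraction-weighted sum of pool relaxation rates. Replacing the
unobservable pool fractions with two imaging surrogates — the MT-saturation
map (macromolecules) and the R2\* map (iron) — gives a voxelwise linear
model with a single set of global coefficients per subject:

```
R1(r) = β0 + β1·MT(r) + β2·R2*(r) + ε(r)
```

* β0 (s⁻¹) is the relaxation rate of free water, so 1/β0 is the free-water T1;
* β1 (s⁻¹/p.u.) carries the macromolecular bound-fraction × relaxivity product;
* β2 (dimensionless) is the iron contribution;
* ε(r) is the spatially specific residual.

For each subject a model matrix **M** with columns (1, MT, R2\*) is built
over all pooled brain voxels (gray or white matter probability > 50%, CSF
probability < 50%), β is the least-squares solution of R1 = **M**β, a
synthetic R1 map is **M**β, and the Pearson coefficient between synthetic
and measured R1 quantifies the fit.

The package is aimed at quantitative-MRI researchers who want to (a) fit
and evaluate this model on their own R1 / MT / R2\* / tissue-probability
maps (NIfTI-1), or (b) study its estimation properties — coefficient
stability, iron-term ablation, the MTR-vs-MT-saturation surrogate choice —
on fully controlled synthetic data.

## What is in the box

| module | contents |
| --- | --- |
| `linrelax.phantom` | four-class digital brain phantom (WM, cortical GM, iron-rich deep GM, CSF) with ground-truth R1/PD/MT/R2\*, tissue-probability maps, and a smooth relative-B1⁺ field |
| `linrelax.flash` | steady-state multi-echo FLASH signal (Ernst equation), MT-saturated steady state, and the three-weighting MPM acquisition simulator |
| `linrelax.maps` | map estimation: R2\* log-linear fit, echo averaging (effective TE 8.45 ms on the default grid), dual-angle rational R1/PD, MT saturation, empirical B1 correction, MTR |
| `linrelax.model` | mask rule, design matrix, QR least-squares fit, synthetic R1, residual/Pearson evaluation, free-water T1, macromolecular relaxivity |
| `linrelax.cohort` | synthetic cohorts, coefficient-of-variation summaries, model-variant comparison (full / no-iron / MTR-surrogate), voxel-level coefficient-recovery experiments |
| `linrelax.io`, `linrelax.pipeline`, `linrelax.cli` | NIfTI-1 and YAML config I/O, the end-to-end pipeline with provenance sidecars, and a thin `linrelax` command-line wrapper |

## Worked example

`examples/03_linear_relaxometry_fit.py` runs the full pipeline on a 32³
phantom whose true R1 is *generated by* the linear model with the reference
coefficients, simulates the three FLASH weightings noiselessly, estimates
all maps, and refits the model:

```
generating coefficients : (0.2677, 0.3971, 0.0025)
fitted coefficients     : (0.2591, 0.4061, 0.00247)
Pearson (synthetic vs measured R1): 0.999996
voxels pooled into the fit        : 29688
free-water T1 from the intercept  : 3.859 s
free-water T1 at the reference b0 : 3.736 s
```

The fitted coefficients recover the generating ones to within a few percent
— the residual bias of the rational dual-angle map estimators, not of the
least-squares fit itself — and the synthetic R1 map is essentially
indistinguishable from the measured one (Pearson ≈ 1). The intercept's
reciprocal is the free-water T1 in seconds.

The other examples each exercise one capability: `01` the FLASH/MT signal
model and Ernst angle, `02` quantitative-map recovery accuracy, `04`
coefficient stability across a 20-subject synthetic cohort (the iron
coefficient β2 shows a far larger coefficient of variation than β0 and β1),
and `05` the iron-term ablation (mean |residual| in iron-rich deep gray
matter drops from 0.056 to 0.012 s⁻¹ when the R2\* term is included) and
the MTR-surrogate comparison (MTR residuals carry transmit-field structure;
MT-saturation residuals do not).

A shell workflow is available through the thin CLI:

```sh
linrelax simulate phantom --seed 1 --out phantom/
linrelax simulate mpm --phantom phantom/ --noise 0.5 --seed 1 --out series/
linrelax fit-maps --pdw series/pdw.nii --t1w series/t1w.nii \
    --mtw series/mtw.nii --b1 series/b1_rel.nii --out qmaps/
linrelax fit-model --r1 qmaps/r1.nii --mt qmaps/mt_sat.nii --r2s qmaps/r2s.nii \
    --gm phantom/prob_cortical_gm.nii --wm phantom/prob_wm.nii \
    --csf phantom/prob_csf.nii --out fit/
```

## Documentation

`docs/methods.md` describes the model, the signal equations, the estimator
chain and its approximations, the synthetic-data generator and its
limitations, and the numerical design choices.
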