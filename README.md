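# ivimfield

Analysis tools for the **field-strength dependence of Intravoxel Incoherent
Motion (IVIM) parameters in skeletal muscle**: segmented IVIM fitting of
diffusion-weighted ROI signal curves, and a three-compartment relaxation
model that explains why the measured perfusion fraction changes with the
main magnetic field B0 and how to remove that dependence.

## The problem

IVIM diffusion MRI models the signal of a perfused voxel biexponentially,

    S(b)/S0 = f · exp(−b·D*) + (1 − f) · exp(−b·D),

with tissue diffusion coefficient *D*, pseudo-diffusion coefficient *D\**
and perfusion fraction *f*. In a spin-echo acquisition, each compartment's
proton density is scaled by its relaxation weight

    w = exp(−TE/T2) · (1 − exp(−TR/T1)),

and because the T1/T2 of muscle, arterial blood and venous blood diverge
differently with B0, the *measured* f is field dependent even though the
underlying blood volume fraction f0 is not. With non-exchanging muscle (m),
arterial (a) and venous (v) pools and f0 = f0,a + f0,v:

    f = (f0,a·wa + f0,v·wv) / (f0,a·wa + f0,v·wv + (1 − f0)·wm)

This package provides the forward map f0 → f, its closed-form inverse at a
fixed venous:arterial volume ratio fv/fa, a grid scan for the fv/fa that
reconciles measurements at two field strengths, cross-field prediction of
f, sensitivity scans over relaxation-time uncertainty, quadratic
interpolation of blood R2 rates over B0, Rayleigh/Rician SNR machinery, a
seeded synthetic-study generator with ground truth, and normality-gated
paired statistics. Literature relaxation times for calf muscle at 0.55 T
and 7 T (TE 56 ms, TR 2800 ms, b = 0/50/100/500/600 s/mm²) and for liver
at 1.5/3 T ship as YAML fixtures.

For quantitative-MRI researchers comparing IVIM results across scanners,
and for anyone needing relaxation-compensated perfusion fractions.

## Worked example

Invert the cohort-mean perfusion fractions measured in the gastrocnemius
medialis at 0.55 T (7.59 % at rest, 14.03 % after muscle activation) to
proton-density-weighted fractions, assuming fv/fa = 4:

```python
from ivimfield import (SequenceProtocol, invert_perfusion_fraction,
                       load_relaxation_set)

weights = load_relaxation_set("calf_0.55T").weights(SequenceProtocol.study_default())
for f in (0.0759, 0.1403):
    print(f"f = {100*f:.2f} %  ->  f0 = {100*invert_perfusion_fraction(f, 4.0, weights):.2f} %")
```

```
f = 7.59 %  ->  f0 = 3.39 %
f = 14.03 %  ->  f0 = 6.52 %
```

So roughly half of the measured perfusion fraction at 0.55 T is relaxation
weighting, not blood volume. Scanning for the venous:arterial ratio that
makes the 0.55 T and 7 T measurements agree on a single f0:

```sh
$ ivimfield reproduce ratio-scan
{
 "f0_high_percent": 3.1766983438541896,
 "f0_low_percent": 3.17642042308864,
 "ratio_v_a": 6.1600000000000055
}
```

i.e. a venous-to-arterial volume ratio of about six brings both field
strengths to a common f0 ≈ 3.2 % — venous-dominated blood, consistent with
7 T IVIM being arterial-weighted (venous blood T2 ≈ 20 ms is nearly
invisible at TE 56 ms) while 0.55 T IVIM weights both pools about equally.

A full synthetic pipeline (simulate → fit → compare) runs from the shell:

```sh
ivimfield simulate --seed 1 --out study/
ivimfield fit --input study/signals.tsv --out study/fits.tsv
ivimfield compare --fits study/fits.tsv --out study/comparisons.tsv
```

## Layout

- `src/ivimfield/relaxation.py` — three-compartment model: weights,
  forward/inverse perfusion fraction, ratio scan, cross-field prediction,
  sensitivity curves
- `src/ivimfield/ivim.py` — signal normalization, segmented and
  biexponential fits
- `src/ivimfield/interp.py` — quadratic R2(B0) interpolation of blood T2
- `src/ivimfield/noise.py` — Rayleigh SNR estimators, ROI-SNR scaling,
  Rician sampler
- `src/ivimfield/simulate.py` — seeded study-shaped synthetic data with
  ground truth
- `src/ivimfield/stats.py` — Shapiro–Wilk-gated paired t / Wilcoxon tests
- `src/ivimfield/cli.py` — `ivimfield` command-line interface
- `docs/methods.md` — model assumptions, parameter choices, limitations
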