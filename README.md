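# mibiquant

Semi-quantitative analysis of dual-time-point [99mTc]Tc-sestamibi breast
imaging: prone SPECT/CT volumes and planar Molecular Breast Imaging (MBI)
views, with a synthetic digital breast phantom for end-to-end validation.

## Who this is for

Sestamibi is a transport substrate of P-glycoprotein, the efflux pump behind
multidrug resistance, so how strongly a breast tumor takes the tracer up —
and how quickly it washes it out between an early (5 min p.i.) and a delayed
(90 min p.i.) acquisition — is a candidate marker of chemoresistance in
locally advanced breast cancer. This package implements the measurement side
of that idea for researchers in quantitative nuclear medicine: reproducible
volume-of-interest delineation, SUV-family parameters, wash-out rate, and
intra-tumor heterogeneity indices, on both the volumetric (SPECT) and planar
(MBI) modality, plus the cohort-level statistics to compare them.

Because no patient data ship with the package, a first-class phantom module
generates paired early/delayed activity volumes with known ground truth
(tumor volume, contrast, heterogeneity, wash-out) and forward-projects them
into the three planar views, so every stage of the pipeline is verifiable at
desk scale.

## The parameters

With SUV the body-weight standardized uptake value (tissue concentration
divided by decay-corrected injected activity per gram), the tumor VOI
delineated by a 42% iso-contour around the hottest voxel, and background
sampled in a ~3 cm sphere in the contralateral breast:

- FTV — functional tumor volume of the delineated VOI (mL)
- TLMU — total lesion mitochondrial uptake, `FTV x SUV_mean` (g)
- TBR_max = `SUV_max,tumor / SUV_mean,background`, TBR_mean analogous
- WOR — wash-out rate, `100 x (TBR_early - TBR_late) / TBR_early` (%),
  positive when the tumor loses tracer, negative when it keeps accumulating
- COV — `100 x SD / SUV_mean` inside the tumor (%), a heterogeneity proxy

On the planar side (3.20 mm pixels, views CC / MLO / LAT, no attenuation or
scatter correction): ellipsoid FTV from three perpendicular diameters
`pi/6 * a * b * c`, mean tumor counts over the three views, two TBR variants
(overall-max vs view-averaged) and three COV variants (COV_max, COV_ave and
the counts-unit COV_norm).

## Worked example

```python
from mibiquant import (
    AcquisitionMeta, TumorPhantomSpec, activity_to_suv,
    background_voi_sphere, compute_spect_params, compute_wor,
    generate_phantom_pair, segment_tumor_iso42,
)

spec = TumorPhantomSpec(tbr_true=6.0, cov_true=10.0, washout_fraction=0.30, seed=17)
early, delayed, truth = generate_phantom_pair(spec)

meta = AcquisitionMeta(injected_activity_MBq=600, injection_time_h=0.0,
                       scan_start_time_h=5/60, body_weight_kg=70)
suv = activity_to_suv(early, meta)
tumor = segment_tumor_iso42(suv, truth.tumor_mask.mask)
bg = background_voi_sphere(suv, truth.background_center_mm)
p = compute_spect_params(suv, tumor, bg)
print(f"SUV_mean {p.suv_mean:.3f}  SUV_max {p.suv_max:.3f}  FTV {p.ftv_mL:.2f} mL")
print(f"TLMU {p.tlmu:.2f} g  TBR_mean {p.tbr_mean:.2f}  TBR_max {p.tbr_max:.2f}  COV {p.cov_pct:.1f} %")
```

prints

```
SUV_mean 0.707  SUV_max 0.897  FTV 7.92 mL
TLMU 5.60 g  TBR_mean 6.00  TBR_max 7.61  COV 10.0 %
```

The phantom was generated at contrast 6 and 10% heterogeneity — both are
recovered exactly — and its true ellipsoid volume is 7.85 mL against the
delineated 7.92 mL. Quantifying the delayed volume the same way and calling
`compute_wor(p_early, p_delayed)` returns `WOR 30.0 %`, the generating
wash-out fraction.

A full synthetic cohort (simulate → quantify SPECT early/delayed → project
and quantify MBI → compare modalities) runs from the shell:

```bash
mibiquant run --out results/cohort18 --seed 1 --n 18
```

writing `cohort.csv` (one row per subject; columns documented in
`docs/data_dictionary.md`), `comparisons.csv`/`.json` (normality-gated
paired tests, Spearman correlations, a spread test), box-plot and scatter
figures, and a provenance record. `mibiquant simulate`, `quant-spect`,
`quant-mbi` and `compare` expose the individual stages.

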