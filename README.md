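# flico

Quantitative image analysis for two-channel confocal studies of
*Drosophila* Filamin (Cheerio) and the kinase Drak: control-calibrated
fluorescence colocalization, actomyosin-ring circularity dynamics during
cellularization, cortical/depth intensity profiling, and gamma mixed models
for muscle attachment-site length. Each pipeline can be exercised end to end
on synthetic microscopy data with known ground truth, so every estimator is
testable against analytic truth.

## Who it is for

Labs quantifying pixel-level co-distribution of two fluorophores and
time-lapse morphology in fly embryos/muscle — or anyone who needs a tested,
scriptable reimplementation of the common ImageJ-macro workflow
(Otsu/MaxEntropy/Huang auto-thresholds, rolling-ball background, mean
filters, Fourier-descriptor shape smoothing) with the statistics done in one
place.

## The statistics at the core

With per-channel global thresholds `t_A`, `t_B` estimated from
single-fluorophore controls as the pooled pixel mean + 3 SD, and an ROI that
keeps the cell-boundary network while excluding nuclei and bright
autofluorescent spots:

- **M1** = Σ A·[A>t_A ∧ B>t_B] / Σ A·[A>t_A]  (M2 symmetric) — thresholded
  Manders co-occurrence;
- **tPCC** — Pearson correlation over pixels above threshold in both
  channels;
- images → samples by informative-pixel-count weighting; samples →
  population by one-sample t inference, Fisher-z transformed for tPCC;
- **circularity** = 4πA/P² of the Fourier-smoothed inner-edge contour of the
  segmented ring, with a penalized-spline + random-intercept trend over time;
- **attachment length** ~ Gamma(α), log-link mean exp(Xβ + u_sample +
  u_image), Laplace-fitted, with Wald z contrasts including the epistasis
  combination β_double − β_closed − β_ko (Bonferroni, m = 3).

## Worked example

```python
import numpy as np
from flico import synthetic_data as sd, roi, coloc
from flico.image_io import Mask

spec = sd.ColocFieldSpec(seed=11, coloc_fraction=1.0, background_sd=2.0)
a, b, truth = sd.gen_coloc_field(spec)           # two registered channels

full = Mask(np.ones(spec.image_shape, bool))
t_a = coloc.estimate_threshold([(sd.gen_control_field(spec, "a").plane(), full)])
t_b = coloc.estimate_threshold([(sd.gen_control_field(spec, "b").plane(), full)])

res = roi.build_embryo_roi(b.plane(), spot_channels=[a.plane(), b.plane()],
                           background_value=spec.background_mean)
r = coloc.compute_coloc(coloc.ChannelPair(a.plane(), b.plane(), res.roi, t_a, t_b))
print(f"M1={r.m1:.3f} M2={r.m2:.3f} tPCC={r.tpcc:.3f} "
      f"(n_a={r.n_a}, n_b={r.n_b}, n_ab={r.n_ab})")
```

prints

```
M1=0.980 M2=1.000 tPCC=0.987 (n_a=5612, n_b=5392, n_ab=5392)
```

M1 ≈ M2 ≈ 1 says nearly all above-threshold signal in each channel overlaps
the other (the planted structures co-occur), and tPCC ≈ 0.98 says the
intensities covary pixel-for-pixel — as they must at a planted colocalized
fraction of 1. Lowering `coloc_fraction` leaves M1/M2 high but drives tPCC
toward 0, the signature that distinguishes co-occurrence from correlation.

The same pipelines are available from the shell:

```sh
flico simulate coloc --seed 7 --out sim/
flico roi --filamin sim/channel_b.tif --channels sim/channel_a.tif \
      --channels sim/channel_b.tif --background 20 --out roi/
flico coloc --pairs pairs.csv --controls-a ctlA/ --controls-b ctlB/ --out results/
flico rings --stack movie.tif --interval-min 3 --out traj.csv
flico attachment-stats --table lengths.csv --out contrasts.csv
```

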