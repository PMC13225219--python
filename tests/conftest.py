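import numpy as np
import pytest

from flico import coloc, image_io, roi, synthetic_data as sd


@pytest.fixture(scope="session")
def coloc_field():
    """One default two-channel field with truth (f=1, mild noise)."""
    spec = sd.ColocFieldSpec(seed=11, background_sd=2.0)
    a, b, truth = sd.gen_coloc_field(spec)
    return spec, a, b, truth


@pytest.fixture(scope="session")
def coloc_roi(coloc_field):
    """ROI built from the Filamin-like channel of the session field."""
    spec, a, b, truth = coloc_field
    return roi.build_embryo_roi(b.plane(),
                                spot_channels=[a.plane(), b.plane()],
                                background_value=spec.background_mean)


@pytest.fixture(scope="session")
def control_thresholds(coloc_field):
    spec = coloc_field[0]
    full = image_io.Mask(np.ones(spec.image_shape, dtype=bool))
    t_a = coloc.estimate_threshold(
        [(sd.gen_control_field(spec, "a").plane(), full)])
    t_b = coloc.estimate_threshold(
        [(sd.gen_control_field(spec, "b").plane(), full)])
    return t_a, t_b


def brute_force_coloc(a, b, roi_mask, t_a, t_b):
    """Independent evaluation of the colocalization definitions by explicit
    per-pixel loops and textbook formulas (no shared code with the package)."""
    num1 = den1 = num2 = den2 = 0.0
    xs, ys = [], []
    n_a = n_b = n_ab = 0
    H, W = len(a), len(a[0])
    for i in range(H):
        for j in range(W):
            if not roi_mask[i][j]:
                continue
            av, bv = float(a[i][j]), float(b[i][j])
            aa, bb = av > t_a, bv > t_b
            if aa:
                n_a += 1
                den1 += av
                if bb:
                    num1 += av
            if bb:
                n_b += 1
                den2 += bv
                if aa:
                    num2 += bv
            if aa and bb:
                n_ab += 1
                xs.append(av)
                ys.append(bv)
    m1 = num1 / den1 if n_a else None
    m2 = num2 / den2 if n_b else None
    tpcc = None
    if n_ab >= 2:
        mx = sum(xs) / n_ab
        my = sum(ys) / n_ab
        sxx = sum((x - mx) ** 2 for x in xs)
        syy = sum((y - my) ** 2 for y in ys)
        sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
        if sxx > 0 and syy > 0:
            tpcc = sxy / (sxx * syy) ** 0.5
    return m1, m2, tpcc, n_a, n_b, n_ab
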