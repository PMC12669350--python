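import numpy as np
import pytest

import osteomat as om


@pytest.fixture(scope="session")
def curve():
    return om.default_curve()


@pytest.fixture(scope="session")
def ols_phantom(curve):
    """Rendered OLS benchmark phantom: (CaImage, PhantomTruth)."""
    spec = om.synth.ols_benchmark_spec(seed=7)
    image, truth = om.render_phantom(spec, curve)
    return om.apply_calibration(image, curve), truth


def make_ca_image(values, pixel_size=1.8, threshold=5.2):
    """CaImage from a raw array, fully inside one cancellous compartment."""
    values = np.asarray(values, dtype=float)
    mask = np.full(values.shape, om.CANCELLOUS, dtype=np.uint8)
    return om.CaImage(ca=values, pixel_size=pixel_size, compartment_mask=mask,
                      mineralization_threshold=threshold)


@pytest.fixture(scope="session")
def reference_cohort(curve):
    """25 healthy-reference subjects: (list of BMDD curves, subject Ca means)."""
    rng = np.random.default_rng(42)
    means = rng.normal(22.0, 0.55, size=25)
    curves = []
    for i, mu in enumerate(means):
        spec = om.PhantomSpec(shape=(80, 80), pixel_size=1.8, ca_mean=float(mu),
                              ca_sd=1.5, margin=2, seed=500 + i)
        image, _ = om.render_phantom(spec, curve)
        ca = om.apply_calibration(image, curve)
        curves.append(om.compute_bmdd(ca, om.CANCELLOUS))
    return curves, means
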