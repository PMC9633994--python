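import numpy as np
import pytest

from nlseg import (
    LabelMask,
    LongitudinalCase,
    PhantomSpec,
    Volume,
    generate_case,
    generate_cohort,
)


@pytest.fixture(scope="session")
def easy_spec() -> PhantomSpec:
    """Small isotropic phantom with bright, well-separated lesions."""
    return PhantomSpec(
        shape=(32, 32, 32),
        spacing=(1.0, 1.0, 1.0),
        n_new_lesions=2,
        n_existing_lesions=1,
        lesion_radius_range_mm=(2.0, 4.0),
        lesion_contrast=1.0,
        growth_fraction=0.3,
        noise_sigma=0.02,
        seed=11,
    )


@pytest.fixture(scope="session")
def easy_case(easy_spec) -> LongitudinalCase:
    return generate_case(easy_spec, case_id="easy")


@pytest.fixture(scope="session")
def small_cohort(easy_spec) -> list[LongitudinalCase]:
    return generate_cohort(easy_spec, n_cases=6, fraction_no_new=0.0, seed=5)


def random_mask(rng: np.random.Generator, shape=(16, 16, 16), p=0.08,
                spacing=(1.0, 1.0, 1.0)) -> LabelMask:
    return LabelMask((rng.uniform(size=shape) < p).astype(np.uint8), spacing)


def cube_mask(shape, corner, size, spacing=(1.0, 1.0, 1.0)) -> LabelMask:
    data = np.zeros(shape, dtype=np.uint8)
    sl = tuple(slice(c, c + s) for c, s in zip(corner, (size,) * 3))
    data[sl] = 1
    return LabelMask(data, spacing)


def constant_case(shape=(16, 16, 16), spacing=(1.0, 1.0, 1.0), value=1.0,
                  label_corner=None, label_size=3, case_id="c") -> LongitudinalCase:
    base = Volume(np.full(shape, value, dtype=np.float32), spacing)
    follow = Volume(np.full(shape, value, dtype=np.float32), spacing)
    label = np.zeros(shape, dtype=np.uint8)
    if label_corner is not None:
        sl = tuple(slice(c, c + label_size) for c in label_corner)
        label[sl] = 1
    return LongitudinalCase(base, follow, LabelMask(label, spacing), case_id=case_id)
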