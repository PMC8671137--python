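import numpy as np
import pytest

from noisypath.patching import AnnotationSet, SlideImage
from noisypath.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec(width_px=256, height_px=256, n_tumor_regions=2)


@pytest.fixture(scope="session")
def phantom_slide(small_spec):
    return generate_phantom(small_spec, seed=42)


@pytest.fixture(scope="session")
def phantom_as_slide(phantom_slide):
    return SlideImage(phantom_slide.image, base_magnification=20.0, slide_id="ph0")


@pytest.fixture(scope="session")
def phantom_annotations(phantom_slide):
    return (
        AnnotationSet(phantom_slide.rough_annotation, "rough"),
        AnnotationSet(phantom_slide.elaborate_annotation, "elaborate"),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
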