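import numpy as np
import pytest

from ctseg.io import Case, CTVolume, LabelVolume
from ctseg.phantom import PhantomConfig, generate_cohort, generate_phantom


@pytest.fixture(scope="session")
def tiny_config() -> PhantomConfig:
    """Small phantom geometry used throughout the suite (fast to generate)."""
    return PhantomConfig(
        in_plane_size=32,
        slice_count_range=(10, 28),
        organ_radius_range=(5.0, 9.0),
        tumour_radius_range=(2.0, 4.0),
        noise_sigma=3.0,
    )


@pytest.fixture(scope="session")
def clean_config() -> PhantomConfig:
    """Zero-noise, zero-spread palette: every voxel equals its class mean."""
    return PhantomConfig(
        in_plane_size=32,
        slice_count_range=(10, 20),
        organ_radius_range=(5.0, 9.0),
        tumour_radius_range=(2.0, 4.0),
        tissue_palette={
            "background": (-1000.0, 0.0),
            "body": (40.0, 0.0),
            "organ": (60.0, 0.0),
            "tumour": (100.0, 0.0),
        },
        noise_sigma=0.0,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(8, tiny_config, seed=11)


@pytest.fixture(scope="session")
def clean_case(clean_config):
    return generate_phantom(clean_config, seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_case(image: np.ndarray, labels: np.ndarray | None = None,
              spacing=(1.0, 1.0, 1.0), identifier="synthetic") -> Case:
    """Hand-built case for oracle tests."""
    lv = None if labels is None else LabelVolume(np.asarray(labels))
    return Case(image=CTVolume(np.asarray(image), spacing=spacing), labels=lv,
                identifier=identifier)
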