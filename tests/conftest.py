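import numpy as np
import pytest

from nailfold import detect, phantom


@pytest.fixture(scope="session")
def clean_row_phantom():
    """Noise-free row of 8 hairpins with its rendered mosaic and ridge maps."""
    spec = phantom.PhantomSpec(
        n_capillaries=8, spacing_um=100.0, frame_shape=(420, 1000),
        noise_sd=0.0, seed=3, tortuosity=0.1, derangement_spread=0.2,
    )
    truth = phantom.generate_truth(spec)
    image = phantom.render_mosaic(spec, truth)
    ridge = detect.ridge_map(image, (8, 12, 16), spec.pixel_scale_um)
    return spec, truth, image, ridge


@pytest.fixture(scope="session")
def single_tube_phantom():
    """One noise-free straight vertical hairpin (limbs exactly vertical)."""
    spec = phantom.PhantomSpec(
        n_capillaries=1, frame_shape=(420, 300), noise_sd=0.0, seed=1,
        tortuosity=0.0, derangement_spread=0.0, apex_y_jitter_um=0.0,
        margin_um=150.0, width_um=12.0,
    )
    truth = phantom.generate_truth(spec)
    image = phantom.render_mosaic(spec, truth)
    ridge = detect.ridge_map(image, (8, 12, 16), spec.pixel_scale_um)
    return spec, truth, image, ridge


def truth_path_to_capillary(cap, pixel_scale_um=1.0):
    """Wrap a ground-truth centerline as a CapillaryPath (bypassing imaging)."""
    n = len(cap.points)
    return detect.CapillaryPath(
        apex_xy=cap.apex_xy / pixel_scale_um,
        points=cap.points / pixel_scale_um,
        orientations=cap.orientations.copy(),
        widths=cap.widths.copy(),
        width_valid=np.ones(n, dtype=bool),
        apex_index=cap.apex_index,
        limb_arc_lengths_um=(100.0, 100.0),
        detection_score=1.0,
        pixel_scale_um=pixel_scale_um,
    )
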