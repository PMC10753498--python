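import numpy as np
import pytest

from focipipe.synthetic_scenes import SceneParams, render_timelapse
from focipipe.workbench import PlateLayout


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def single_nucleus_scene():
    """One large nucleus, no foci, no noise — segmentation oracle."""
    params = SceneParams(
        image_shape=(160, 160),
        n_cells=1,
        n_frames=1,
        nucleus_radius_mean=25.0,
        nucleus_radius_sd=0.0,
        late_s_fraction=0.0,
        noise_sd=0.0,
        seed=7,
    )
    return render_timelapse(params)


@pytest.fixture(scope="session")
def foci_scene():
    """Five nuclei with exactly 3 planted foci each (primary-profile scale)."""
    params = SceneParams(
        image_shape=(256, 256),
        n_cells=5,
        n_frames=1,
        nucleus_radius_mean=22.0,
        late_s_fraction=1.0,
        foci_count_fixed=3,
        focus_amplitude=0.05,
        focus_radius=2.0,
        noise_sd=0.0,
        seed=3,
    )
    return render_timelapse(params)


@pytest.fixture()
def small_layout():
    layout = PlateLayout(plate_id="t")
    layout.add("A01", "LIB1", gene="G1", role="library")
    layout.add("A02", "LIB1", gene="G1", role="library")
    for w in ("H01", "H02", "H03", "H04"):
        layout.add(w, "sNEG1", role="sNEG1")
    return layout
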