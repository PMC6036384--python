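import numpy as np
import pytest

from fidseg import SegmentationConfig, Volume3D, build_template


@pytest.fixture(scope="session")
def template():
    return build_template()


@pytest.fixture(scope="session")
def seg_cfg(template):
    return SegmentationConfig.from_template(template)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_volume(data, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0), meta=None):
    """Axis-aligned LPS volume with the given spacing and origin."""
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = origin
    return Volume3D(np.asarray(data, dtype=np.int32), affine, meta or {})


@pytest.fixture(scope="session")
def small_marker_volume(template):
    """A tiny noiseless scene: four markers rasterized at 1.5 mm isotropic
    resolution with no background, for fast end-to-end checks."""
    from fidseg import AcquisitionSpec, ScenePose, rasterize_scene

    pose = ScenePose(body_center=None, blobs=[])
    spec = AcquisitionSpec(
        name="tiny",
        in_plane_mm=(1.5, 1.5),
        slice_thickness_mm=1.5,
        slice_gap_mm=0.0,
        fov_mm=(130.0, 60.0, 80.0),
        fov_center_mm=(0.0, -3.0, 5.0),
        noise_sigma=0.0,
        seed=0,
    )
    return rasterize_scene(template, pose, spec), pose, spec
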