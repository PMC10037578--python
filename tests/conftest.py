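import numpy as np
import pytest

from orbitarea import PhantomSpec, rasterize_phantom


@pytest.fixture(scope="session")
def flat_phantom():
    """Noiseless flat floor with a 10 mm circular defect (truth: pi*100)."""
    spec = PhantomSpec()
    volume, truth = rasterize_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def tilted45_phantom():
    spec = PhantomSpec(floor_kind="tilted_plane", tilt_deg=45.0)
    volume, truth = rasterize_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def cap_phantom():
    """Spherical-cap floor R=20 mm, base radius 10 mm (truth: 2*pi*R*h = 336.70)."""
    spec = PhantomSpec(floor_kind="spherical_cap", cap_radius_mm=20.0)
    volume, truth = rasterize_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def intact_phantom():
    """Shell with a defect too far from the centre hint: locally intact floor."""
    spec = PhantomSpec(semi_axis_a_mm=4.0, semi_axis_b_mm=4.0)
    volume, truth = rasterize_phantom(spec)
    # rebuild a defect-free volume by filling the defect channel with bone
    values = volume.values.copy()
    values[values == spec.tissue_hu] = np.where(
        _near_floor(spec, values.shape, volume.spacing)[values == spec.tissue_hu],
        spec.bone_hu,
        spec.tissue_hu,
    )
    from orbitarea import VoxelVolume

    return spec, VoxelVolume(values=values, spacing=volume.spacing), truth


def _near_floor(spec, shape, spacing):
    nx, ny, nz = shape
    dx, dy, dz = spacing
    x = (np.arange(nx) * dx)[:, None, None]
    y = (np.arange(ny) * dy)[None, :, None]
    z = (np.arange(nz) * dz)[None, None, :]
    from orbitarea.phantom import _signed_distance_and_regions

    d, _defect, support = _signed_distance_and_regions(spec, x, y, z)
    t = spec.shell_thickness_mm
    return np.broadcast_to((d >= -t) & (d <= 0.0) & support, shape)
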