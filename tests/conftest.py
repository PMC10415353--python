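import numpy as np
import pytest

from bifusion.angio_centerline import Centerline3D, ProjectionGeometry
from bifusion.contour_io import Contour
from bifusion.frame_geometry import FramePlacement
from bifusion.phantom_sim import PhantomSpec, RadiusProfile, make_phantom
from bifusion.surface_builder import PlacedContour, loft_surface


def circle_points(n: int = 128, r: float = 1.0, center=(0.0, 0.0)) -> np.ndarray:
    phi = 2 * np.pi * np.arange(n) / n
    return np.stack(
        [center[0] + r * np.cos(phi), center[1] + r * np.sin(phi)], axis=1
    )


def ellipse_points(n: int = 128, a: float = 2.0, b: float = 1.0) -> np.ndarray:
    phi = 2 * np.pi * np.arange(n) / n
    return np.stack([a * np.cos(phi), b * np.sin(phi)], axis=1)


def star_points(rng: np.random.Generator, n: int = 180, base: float = 1.5) -> np.ndarray:
    """Random star-shaped (about the origin) polygon."""
    phi = 2 * np.pi * np.arange(n) / n
    k1, k2 = rng.integers(2, 7, size=2)
    a1, a2 = rng.uniform(0.05, 0.25, size=2) * base
    p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
    r = base + a1 * np.cos(k1 * phi + p1) + a2 * np.sin(k2 * phi + p2)
    return np.stack([r * np.cos(phi), r * np.sin(phi)], axis=1)


def straight_placements(n: int, spacing: float, axis=None) -> list[FramePlacement]:
    triad = np.eye(3) if axis is None else np.asarray(axis, dtype=float)
    return [
        FramePlacement(
            frame_index=i, origin=triad[0] * (i * spacing), triad=triad, s=i * spacing
        )
        for i in range(n)
    ]


def tube_mesh(radii, spacing: float, n_theta: int = 256, axis=None, label="lumen"):
    """Capped tube from circular rings along a straight axis."""
    pls = straight_placements(len(radii), spacing, axis=axis)
    pcs = [
        PlacedContour(
            contour=Contour(frame_index=i, label=label, points=circle_points(128, r)),
            placement=pl,
        )
        for i, (r, pl) in enumerate(zip(radii, pls))
    ]
    return loft_surface(pcs, n_theta=n_theta, label=label)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def stenosed_spec(seed: int = 1, scale: float = 1.0) -> PhantomSpec:
    return PhantomSpec(
        mv_radius=RadiusProfile(
            base=1.5 * scale, stenosis_center=8.0, stenosis_depth=0.35, stenosis_width=2.5
        ),
        sb_radius=RadiusProfile(
            base=1.2 * scale, stenosis_center=5.0, stenosis_depth=0.25, stenosis_width=2.0
        ),
        murray=True,
        seed=seed,
    )


@pytest.fixture(scope="session")
def phantom_session():
    """One full (meshed) stenosed phantom shared across the suite."""
    return make_phantom(stenosed_spec())


@pytest.fixture(scope="session")
def phantom_light():
    """Phantom without meshes: centerlines, implicit tubes, carina only."""
    return make_phantom(stenosed_spec(), with_meshes=False)


@pytest.fixture(scope="session")
def biplane_geoms():
    return (
        ProjectionGeometry(rao_lao_angle=30.0, cran_caud_angle=0.0),
        ProjectionGeometry(rao_lao_angle=-40.0, cran_caud_angle=20.0),
    )


@pytest.fixture(scope="session")
def reconstructed_session(phantom_session, biplane_geoms):
    """Noiseless end-to-end reconstruction of the session phantom."""
    import warnings

    from bifusion.angio_centerline import triangulate_centerlines
    from bifusion.phantom_sim import simulate_biplane, simulate_pullback
    from bifusion.pipeline_cli import RunConfig, run_reconstruction

    ga, gb = biplane_geoms
    curves = simulate_biplane(phantom_session, ga, gb)
    mv_pb, _ = simulate_pullback(phantom_session, "MV", seed=2)
    sb_pb, _ = simulate_pullback(phantom_session, "SB", seed=3)
    mv_cl = triangulate_centerlines(curves["MV"][0], ga, curves["MV"][1], gb)
    sb_cl = triangulate_centerlines(curves["SB"][0], ga, curves["SB"][1], gb)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_reconstruction(mv_pb, mv_cl, sb_pb, sb_cl, RunConfig())
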