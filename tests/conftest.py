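import numpy as np
import pytest

from eyemorph import EyeCast, EyeGenParams, generate_eye_cast


def hex_lattice(spacing: float, n_cols: int, n_rows: int) -> np.ndarray:
    """Uniform hexagonal lattice (row-offset axial layout), centered at origin."""
    dy = spacing * np.sqrt(3.0) / 2.0
    pts = []
    for r in range(n_rows):
        offset = 0.5 * spacing if r % 2 else 0.0
        for c in range(n_cols):
            pts.append((c * spacing + offset, r * dy))
    pts = np.asarray(pts, dtype=float)
    return pts - pts.mean(axis=0)


def square_outline(half: float) -> np.ndarray:
    return np.array([[-half, -half], [half, -half], [half, half], [-half, half]])


@pytest.fixture
def hexagon_cast() -> EyeCast:
    """Seven points: a regular hexagon of side 0.03 mm around a center facet."""
    s = 0.03
    ang = np.arange(6) * np.pi / 3.0
    centers = np.vstack([[0.0, 0.0], np.column_stack([s * np.cos(ang), s * np.sin(ang)])])
    return EyeCast("hex7", "female", centers, square_outline(0.05))


@pytest.fixture
def uniform_cast() -> EyeCast:
    """Noiseless 20x20 uniform lattice at 0.03 mm spacing."""
    pts = hex_lattice(0.03, 20, 20)
    return EyeCast("uniform", "female", pts, square_outline(0.4))


@pytest.fixture(scope="session")
def hotspot_cast():
    """Synthetic acute-zone cast shared across tests (modest size for speed)."""
    params = EyeGenParams(
        lattice_spacing=0.029, n_target=3000, hotspot_center=(0.4, 0.3),
        hotspot_amplitude=1.6, gradient_scale=0.5, jitter_sd=0.001,
        outline_shape=(3.2, 2.4), seed=42,
    )
    cast, true_diam = generate_eye_cast(params)
    return params, cast, true_diam
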