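"""Synthetic eye casts and specimen datasets.

Real inputs to this pipeline are coordinate tables picked by hand from
flattened corneal casts, plus per-specimen morphometric tables.  Neither can
be regenerated from a publication, so this module produces synthetic stand-ins
with the statistical structure the downstream analyses assume:

* :func:`generate_eye_cast` — a jittered hexagonal facet lattice clipped to an
  oval outline, with a dorsofrontal "acute zone" of enlarged facets imposed by
  a Gaussian-radial diameter gradient and recorded as per-facet ground truth.
* :func:`generate_allometry_dataset` — (x, y) specimen tables whose OLS refit
  recovers, in expectation, a chosen slope/intercept at a chosen R².

All randomness flows through one integer seed per call.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .types import DegenerateInputError, EyeCast

DEFAULT_SEED = 20180501


@dataclass
class EyeGenParams:
    """Parameters of the synthetic eye-cast generator.

    ``lattice_spacing`` is the baseline center-to-center distance (mm) far
    from the hotspot; the facet diameter equals this local spacing, so the
    default 0.029 mm produces ~29 um facets.  ``hotspot_amplitude`` multiplies
    spacing/diameter at the hotspot center, decaying as a Gaussian with scale
    ``gradient_scale``.  When ``n_target`` is set, the oval outline is scaled
    (preserving aspect) so the clipped cast contains ~n_target facets.
    """

    lattice_spacing: float = 0.029
    n_target: Optional[int] = 11000
    hotspot_center: Tuple[float, float] = (0.9, 0.7)
    hotspot_amplitude: float = 1.6
    gradient_scale: float = 0.5
    jitter_sd: float = 0.001
    outline_shape: Tuple[float, float] = (4.4, 2.8)  # full oval axes, mm
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if not self.lattice_spacing > 0:
            raise ValueError("lattice_spacing must be > 0")
        if self.n_target is not None and self.n_target < 7:
            raise ValueError("n_target must be >= 7")
        if self.hotspot_amplitude < 1:
            raise ValueError("hotspot_amplitude must be >= 1")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if not self.gradient_scale > 0:
            raise ValueError("gradient_scale must be > 0")
        if not (self.outline_shape[0] > 0 and self.outline_shape[1] > 0):
            raise ValueError("outline axes must be > 0")


def diameter_gradient(points: np.ndarray, params: EyeGenParams) -> np.ndarray:
    """Dimensionless spacing multiplier g(p) >= 1 at each point.

    g(p) = 1 + (A - 1) * exp(-|p - c|^2 / (2 * scale^2)) with A the hotspot
    amplitude and c the hotspot center.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d2 = ((pts - np.asarray(params.hotspot_center)) ** 2).sum(axis=1)
    g = 1.0 + (params.hotspot_amplitude - 1.0) * np.exp(
        -d2 / (2.0 * params.gradient_scale**2)
    )
    return g if np.ndim(points) == 2 else float(g[0])


def _hex_lattice(spacing: float, half_w: float, half_h: float) -> np.ndarray:
    """Uniform hexagonal lattice covering [-half_w, half_w] x [-half_h, half_h]."""
    dy = spacing * np.sqrt(3.0) / 2.0
    n_rows = int(np.ceil(2 * half_h / dy)) + 3
    n_cols = int(np.ceil(2 * half_w / spacing)) + 3
    rows = []
    for r in range(n_rows):
        offset = 0.5 * spacing if r % 2 else 0.0
        x = np.arange(n_cols) * spacing + offset - half_w - spacing
        y = np.full(n_cols, r * dy - half_h - dy)
        rows.append(np.column_stack([x, y]))
    return np.vstack(rows)


def _radial_warp(points: np.ndarray, params: EyeGenParams) -> np.ndarray:
    """Map a uniform lattice so local area scale at the image equals g^2.

    Solves r(R)^2 = 2 * int_0^R u / g(u)^2 du for the reference radius r as a
    function of mapped radius R (monotone; inverted by interpolation).  Both
    principal stretches average to g, so mean center-to-center spacing at a
    mapped point tracks spacing * g(point).
    """
    if params.hotspot_amplitude == 1.0:
        return points.copy()
    center = np.asarray(params.hotspot_center, dtype=float)
    rel = points - center
    r_ref = np.hypot(rel[:, 0], rel[:, 1])
    r_max = float(r_ref.max()) * params.hotspot_amplitude + 1.0
    R_grid = np.linspace(0.0, r_max, 20001)
    g_grid = 1.0 + (params.hotspot_amplitude - 1.0) * np.exp(
        -(R_grid**2) / (2.0 * params.gradient_scale**2)
    )
    ref_sq = 2.0 * cumulative_trapezoid(R_grid / g_grid**2, R_grid, initial=0.0)
    ref_grid = np.sqrt(ref_sq)
    R_mapped = np.interp(r_ref, ref_grid, R_grid)
    with np.errstate(invalid="ignore", divide="ignore"):
        factor = np.where(r_ref > 0, R_mapped / r_ref, params.hotspot_amplitude)
    return center + rel * factor[:, None]


def _inside_oval(points: np.ndarray, axes: Tuple[float, float], scale: float = 1.0) -> np.ndarray:
    a = 0.5 * axes[0] * scale
    b = 0.5 * axes[1] * scale
    return (points[:, 0] / a) ** 2 + (points[:, 1] / b) ** 2 <= 1.0


def _oval_polygon(axes: Tuple[float, float], scale: float, n_vertices: int = 256) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    return np.column_stack(
        [0.5 * axes[0] * scale * np.cos(theta), 0.5 * axes[1] * scale * np.sin(theta)]
    )


def generate_eye_cast(
    params: EyeGenParams, specimen_id: str = "synthetic", group: str = "small_male"
) -> tuple[EyeCast, np.ndarray]:
    """Generate one synthetic eye cast.

    Returns the :class:`EyeCast` (centers + oval outline, mm) and the
    ground-truth per-facet diameter array (um), defined as
    ``1000 * lattice_spacing * g(center)`` at each facet's pre-jitter position.

    Raises :class:`DegenerateInputError` if the outline holds < 7 facets.
    """
    rng = np.random.default_rng(params.seed)
    axes = params.outline_shape
    s, A, sig = params.lattice_spacing, params.hotspot_amplitude, params.gradient_scale
    density = 2.0 / (np.sqrt(3.0) * s**2)  # facets per mm^2 at baseline spacing
    oval_area = np.pi * axes[0] * axes[1] / 4.0
    if params.n_target is None:
        max_scale = 1.0
    else:
        # area needed at baseline density, plus the worst-case hotspot deficit
        area_needed = params.n_target / density + 2.0 * np.pi * sig**2 * A**2
        max_scale = 1.35 * np.sqrt(area_needed / oval_area) + 0.05
    # Reference lattice covering the scaled outline with room for warp expansion.
    margin = (A - 1.0) * sig * np.sqrt(np.pi / 2.0) + 4.0 * s
    half_w = 0.5 * axes[0] * max_scale + abs(params.hotspot_center[0]) + margin
    half_h = 0.5 * axes[1] * max_scale + abs(params.hotspot_center[1]) + margin
    lattice = _hex_lattice(s, half_w, half_h)
    warped = _radial_warp(lattice, params)
    jittered = warped
    if params.jitter_sd > 0:
        jittered = warped + rng.normal(0.0, params.jitter_sd, size=warped.shape)

    if params.n_target is None:
        scale = 1.0
    else:
        lo, hi = 1e-3, max_scale
        if int(_inside_oval(jittered, axes, hi).sum()) < params.n_target:
            raise DegenerateInputError(
                "outline scale bound too small for requested n_target"
            )
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if int(_inside_oval(jittered, axes, mid).sum()) < params.n_target:
                lo = mid
            else:
                hi = mid
        scale = hi

    keep = _inside_oval(jittered, axes, scale)
    if int(keep.sum()) < 7:
        raise DegenerateInputError(
            f"outline contains only {int(keep.sum())} lattice points (< 7)"
        )
    centers = jittered[keep]
    true_diam_um = 1000.0 * params.lattice_spacing * diameter_gradient(warped[keep], params)
    outline = _oval_polygon(axes, scale)
    cast = EyeCast(
        specimen_id=specimen_id,
        group=group,
        centers=centers,
        outline=outline,
        scale_provenance=f"synthetic (seed={params.seed})",
    )
    return cast, true_diam_um


@dataclass
class AllometryGenParams:
    """Parameters of the synthetic regression-dataset generator.

    ``slope``/``intercept`` act on the log10 scale when ``log_log``; the noise
    SD is chosen analytically so the expected sample R² matches
    ``r_squared_target``.
    """

    slope: float
    intercept: float
    r_squared_target: float
    x_range: Tuple[float, float]
    n: int
    log_log: bool = False
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if not (0.0 < self.r_squared_target < 1.0):
            raise ValueError("r_squared_target must lie in (0, 1)")
        if self.n < 3:
            raise ValueError("n must be >= 3")
        if not self.x_range[0] < self.x_range[1]:
            raise ValueError("x_range must satisfy min < max")
        if self.log_log and self.x_range[0] <= 0:
            raise ValueError("log-log generation needs a positive x_range")


def _predictor_variance(params: AllometryGenParams) -> float:
    """Population variance of the (possibly log10-transformed) predictor."""
    a, b = params.x_range
    if not params.log_log:
        return (b - a) ** 2 / 12.0
    # Var(log10 U(a,b)) via the closed-form moments of ln U.
    ln = np.log
    e1 = (b * ln(b) - a * ln(a)) / (b - a) - 1.0
    e2 = (b * ln(b) ** 2 - a * ln(a) ** 2) / (b - a) - 2.0 * e1
    var_ln = e2 - e1**2
    return var_ln / ln(10.0) ** 2


def noise_sd(params: AllometryGenParams) -> float:
    """Residual SD giving expected sample R² ~= the target.

    From R² = signal/(signal+noise) with signal = slope² Var(x):
    sigma² = slope² Var(x) (1 - R²) / R².
    """
    var_x = _predictor_variance(params)
    r2 = params.r_squared_target
    return float(abs(params.slope) * np.sqrt(var_x * (1.0 - r2) / r2))


def generate_allometry_dataset(params: AllometryGenParams) -> pd.DataFrame:
    """Draw one synthetic specimen table with columns ``x`` and ``y``.

    x ~ Uniform(x_range); y = slope*x + intercept + eps on the raw scale, or
    log10 y = slope*log10 x + intercept + eps when ``log_log`` (y returned on
    the original scale).  eps is Gaussian with SD from :func:`noise_sd`.
    """
    rng = np.random.default_rng(params.seed)
    x = rng.uniform(params.x_range[0], params.x_range[1], size=params.n)
    eps = rng.normal(0.0, noise_sd(params), size=params.n)
    if params.log_log:
        log_y = params.slope * np.log10(x) + params.intercept + eps
        y = 10.0**log_y
    else:
        y = params.slope * x + params.intercept + eps
    return pd.DataFrame({"x": x, "y": y})


def generate_specimen_cohort(
    n_per_group: int = 10, seed: int = DEFAULT_SEED
) -> pd.DataFrame:
    """Synthesize a morphometric cohort across the three groups.

    Group-level head-width ranges and the scaling relations tying eye height,
    intertegular span, ommatidia number and local inter-ommatidial angles to
    head width follow the study system's reported morphology: small males
    4.53-5.27 mm head width with hyperallometric eyes (b = 1.10), large males
    5.34-6.02 mm with hypoallometric eyes (b = 0.61), females 4.85-5.97 mm
    (b = 0.83).
    """
    rng = np.random.default_rng(seed)
    configs = {
        "small_male": dict(hw=(4.53, 5.27), b=1.10, r2=0.90, mass=(0.11, 0.21)),
        "large_male": dict(hw=(5.34, 6.02), b=0.61, r2=0.67, mass=(0.25, 0.35)),
        "female": dict(hw=(4.85, 5.97), b=0.83, r2=0.84, mass=(0.16, 0.35)),
    }
    rows = []
    for group, cfg in configs.items():
        hw = rng.uniform(*cfg["hw"], size=n_per_group)
        # eye height ~ 0.72 * head width at the midpoint, scaled by exponent b
        hw_mid = 0.5 * (cfg["hw"][0] + cfg["hw"][1])
        c = np.log10(0.72 * hw_mid) - cfg["b"] * np.log10(hw_mid)
        sd = abs(cfg["b"]) * np.std(np.log10(hw)) * np.sqrt((1 - cfg["r2"]) / cfg["r2"])
        eye_h = 10 ** (cfg["b"] * np.log10(hw) + c + rng.normal(0, sd, n_per_group))
        head_h = hw * rng.normal(0.92, 0.02, n_per_group)
        it = 0.75 * hw + rng.normal(1.1, 0.05, n_per_group)
        mass = rng.uniform(*cfg["mass"], size=n_per_group)
        n_omm = np.round(1095 * hw + 5198 + rng.normal(0, 300, n_per_group)).astype(int)
        if group == "female":
            # female local angles show no body-size relationship
            dphi_x = np.clip(rng.normal(1.72, 0.26, n_per_group), 0.3, None)
            dphi_y = np.clip(rng.normal(0.80, 0.16, n_per_group), 0.2, None)
        else:
            dphi_x = np.clip(-0.93 * hw + 6.84 + rng.normal(0, 0.25, n_per_group), 0.3, None)
            dphi_y = np.clip(-0.58 * hw + 4.18 + rng.normal(0, 0.16, n_per_group), 0.2, None)
        for i in range(n_per_group):
            rows.append(
                dict(
                    specimen_id=f"{group}_{i + 1:02d}",
                    group=group,
                    head_width_mm=hw[i],
                    head_height_mm=head_h[i],
                    eye_height_mm=eye_h[i],
                    it_span_mm=it[i],
                    mass_g=mass[i],
                    n_ommatidia=n_omm[i],
                    dphi_x_deg=dphi_x[i],
                    dphi_y_deg=dphi_y[i],
                )
            )
    return pd.DataFrame(rows)
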