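"""Seeded synthetic-data generators with serialized ground truth.

Every analysis stage in this package gets a generator that emulates the
statistical structure its inputs are assumed to have:

* fiber images — anti-aliased line segments whose axial orientations are
  drawn from a von Mises distribution on doubled angles (mean direction
  and concentration kappa controllable; kappa=0 is isotropic);
* FRAP sequences — a Gaussian-profile bleached spot advected at a known
  velocity over a uniform fluorophore field, recovering by the closed-form
  2-D diffusing-Gaussian amplitude decay;
* cyst masks — polar boundaries r(phi) = ellipse + Gaussian protrusion
  bumps + band-limited ruffle noise with independently controllable
  top/bottom amplitude;
* gradient scenes — solver concentration stacks rendered to noisy
  intensity frames.

Noise model throughout: Poisson shot noise (via a photon-scale parameter)
plus additive Gaussian read noise.  Identical ``(seed, parameters)`` give
bit-identical output; truths are returned as plain dicts and can be saved
as JSON sidecars next to the TIFFs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import tifffile
from skimage.draw import line_aa, polygon

from .frap import FrapSequence
from .transport import ConcentrationField

__all__ = [
    "GeneratorSpec",
    "gen_fiber_image",
    "gen_frap_sequence",
    "frap_spot_amplitude",
    "gen_cyst_mask",
    "render_mask_image",
    "gen_gradient_scene",
    "sample_axial_von_mises",
    "save_tiff_with_truth",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Common generator settings: seed, raster geometry and noise model.

    ``poisson_scale`` is the photon count corresponding to intensity 1.0
    (0 disables shot noise); ``read_noise`` is the additive Gaussian sigma
    in intensity units.
    """

    seed: int = 0
    image_size: tuple[int, int] = (256, 256)  # (rows, cols)
    pixel_size: float = 1.0                   # um / px
    poisson_scale: float = 50.0
    read_noise: float = 2.0


def _apply_noise(rng: np.random.Generator, img: np.ndarray,
                 spec: GeneratorSpec) -> np.ndarray:
    out = np.asarray(img, dtype=float)
    if spec.poisson_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) * spec.poisson_scale) / spec.poisson_scale
    if spec.read_noise > 0:
        out = out + rng.normal(0.0, spec.read_noise, size=out.shape)
    return out


def sample_axial_von_mises(
    rng: np.random.Generator,
    n: int,
    mean_angle: float,
    kappa: float,
) -> np.ndarray:
    """Axial angles (degrees in [0, 180)) from a von Mises on doubled angles.

    ``kappa`` is the concentration of the doubled-angle distribution;
    kappa=0 gives the uniform axial distribution, ``numpy.inf`` a point
    mass at ``mean_angle``.
    """
    if np.isinf(kappa):
        return np.full(n, mean_angle % 180.0)
    if kappa == 0:
        return rng.uniform(0.0, 180.0, size=n)
    doubled = rng.vonmises(np.deg2rad(2.0 * mean_angle), kappa, size=n)
    return (np.rad2deg(doubled) / 2.0) % 180.0


# ---------------------------------------------------------------------------
# fibers
# ---------------------------------------------------------------------------


def gen_fiber_image(
    spec: GeneratorSpec,
    n_fibers: int = 400,
    mean_angle: float = 90.0,
    kappa: float = 8.0,
    length_range: tuple[float, float] = (30.0, 60.0),
    amplitude: float = 60.0,
    background: float = 10.0,
) -> tuple[np.ndarray, dict]:
    """Synthetic reflectance-style fiber image with known orientations.

    Fibers are anti-aliased segments of random length (px) centered at
    uniform positions; angles follow the axial von Mises law.  Returns
    ``(image, truth)`` where truth carries the drawn angle list.
    """
    if n_fibers < 1:
        raise ValueError("n_fibers must be >= 1")
    rng = np.random.default_rng(spec.seed)
    ny, nx = spec.image_size
    canvas = np.zeros((ny, nx))
    angles = sample_axial_von_mises(rng, n_fibers, mean_angle, kappa)
    lengths = rng.uniform(*length_range, size=n_fibers)
    r0 = rng.uniform(0, ny, size=n_fibers)
    c0 = rng.uniform(0, nx, size=n_fibers)
    for ang, L, rc, cc in zip(angles, lengths, r0, c0):
        th = np.deg2rad(ang)
        # math y-up -> image row-down
        dr, dc = -np.sin(th) * L / 2, np.cos(th) * L / 2
        r1, c1 = int(round(rc - dr)), int(round(cc - dc))
        r2, c2 = int(round(rc + dr)), int(round(cc + dc))
        r1 = np.clip(r1, 0, ny - 1); r2 = np.clip(r2, 0, ny - 1)
        c1 = np.clip(c1, 0, nx - 1); c2 = np.clip(c2, 0, nx - 1)
        if (r1, c1) == (r2, c2):
            continue
        rr, cc2, val = line_aa(r1, c1, r2, c2)
        canvas[rr, cc2] += amplitude * val
    img = _apply_noise(rng, background + canvas, spec)
    truth = {
        "angles_deg": angles.tolist(),
        "mean_angle": mean_angle,
        "kappa": kappa,
        "n_fibers": n_fibers,
    }
    return img, truth


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------


def frap_spot_amplitude(t: float, bleach_depth: float, sigma0: float,
                        diffusivity: float) -> float:
    """Closed-form amplitude of a 2-D diffusing Gaussian bleach profile.

    depth(t) = depth0 * sigma0^2 / (sigma0^2 + 2 D t).
    """
    return bleach_depth * sigma0**2 / (sigma0**2 + 2.0 * diffusivity * t)


def gen_frap_sequence(
    spec: GeneratorSpec,
    velocity: tuple[float, float] = (10.0, 0.0),  # um/s, math coords
    dye_diffusivity: float = 10.0,                # um^2/s
    bleach_depth: float = 0.85,
    bleach_diameter: float = 30.0,                # um
    frame_interval: float = 0.5,
    n_frames: int = 31,
    baseline: float = 100.0,
    image_size: tuple[int, int] | None = None,
    start: tuple[float, float] | None = None,
) -> tuple[FrapSequence, dict]:
    """FRAP sequence of a bleached spot advected at a known velocity.

    The bleach profile is Gaussian with sigma0 = bleach_diameter/4; its
    center moves at ``velocity`` and its depth decays by the analytic 2-D
    diffusing-Gaussian law, so the noise-free spot is an exact solution of
    the advection-diffusion equation.  When no ``image_size`` is given the
    frame is sized so the whole track keeps a margin from the edges.
    """
    vx, vy = (float(velocity[0]), float(velocity[1]))
    if not (np.isfinite(vx) and np.isfinite(vy)):
        raise ValueError("velocity must be finite")
    rng = np.random.default_rng(spec.seed)
    px = spec.pixel_size
    sigma0 = bleach_diameter / 4.0
    total_t = (n_frames - 1) * frame_interval
    margin = 1.5 * bleach_diameter

    if image_size is None:
        span_x = abs(vx) * total_t + 2 * margin
        span_y = abs(vy) * total_t + 2 * margin
        image_size = (int(np.ceil(span_y / px)), int(np.ceil(span_x / px)))
    ny, nx = image_size

    if start is None:
        x0 = margin if vx >= 0 else nx * px - margin
        y0 = margin if vy >= 0 else ny * px - margin
    else:
        x0, y0 = start

    cols = (np.arange(nx) + 0.5) * px
    rows_y = ((ny - 1) - np.arange(ny) + 0.5) * px  # y-up coordinate per row

    frames = np.empty((n_frames, ny, nx))
    centers = []
    for k in range(n_frames):
        t = k * frame_interval
        cx_t = x0 + vx * t
        cy_t = y0 + vy * t
        sig2 = sigma0**2 + 2.0 * dye_diffusivity * t
        depth = bleach_depth * sigma0**2 / sig2
        g = np.exp(
            -((cols[None, :] - cx_t) ** 2 + (rows_y[:, None] - cy_t) ** 2)
            / (2.0 * sig2)
        )
        frames[k] = _apply_noise(rng, baseline * (1.0 - depth * g), spec)
        centers.append((cx_t, cy_t))

    seq = FrapSequence(frames=frames, frame_interval=frame_interval,
                       pixel_size=px, bleach_diameter=bleach_diameter)
    truth = {
        "velocity_um_s": [vx, vy],
        "speed_um_s": float(np.hypot(vx, vy)),
        "direction_deg": float(np.rad2deg(np.arctan2(vy, vx)) % 360.0),
        "centers_um": centers,
        "sigma0_um": sigma0,
        "dye_diffusivity_um2_s": dye_diffusivity,
        "bleach_depth": bleach_depth,
    }
    return seq, truth


# ---------------------------------------------------------------------------
# cysts
# ---------------------------------------------------------------------------


def gen_cyst_mask(
    spec: GeneratorSpec,
    axes: tuple[float, float] = (60.0, 45.0),   # semi-axes, um
    orientation: float = 0.0,                   # degrees CCW
    protrusions: list[tuple[float, float, float]] = (),  # (dir deg, prominence um, width deg)
    ruffle_amplitude_top: float = 0.0,          # um (RMS)
    ruffle_amplitude_bottom: float = 0.0,
    ruffle_band: tuple[int, int] = (8, 16),     # angular harmonics
    n_phi: int = 2048,
) -> tuple[np.ndarray, dict]:
    """Binary cyst mask from a polar boundary with known perturbations.

    r(phi) = ellipse radius + Gaussian bumps at the protrusion directions
    + band-limited random ruffles whose RMS amplitude blends smoothly from
    the bottom to the top half.  Truth records the folded protrusion
    angles, axes, orientation and ruffle settings.
    """
    a, b = axes
    if any(p[1] >= min(a, b) for p in protrusions):
        raise ValueError("protrusion prominence must stay below the minor semi-axis")
    rng = np.random.default_rng(spec.seed)
    px = spec.pixel_size
    ny, nx = spec.image_size
    cx = nx * px / 2.0
    cy = ny * px / 2.0

    phi = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
    d = phi - np.deg2rad(orientation)
    r = a * b / np.sqrt((b * np.cos(d)) ** 2 + (a * np.sin(d)) ** 2)

    for ang_deg, prom, width_deg in protrusions:
        dphi = np.angle(np.exp(1j * (phi - np.deg2rad(ang_deg))))
        r = r + prom * np.exp(-0.5 * (dphi / np.deg2rad(width_deg)) ** 2)

    if ruffle_amplitude_top > 0 or ruffle_amplitude_bottom > 0:
        m_lo, m_hi = ruffle_band
        field = np.zeros_like(phi)
        for m in range(m_lo, m_hi + 1):
            field += rng.normal() * np.cos(m * phi) + rng.normal() * np.sin(m * phi)
        field /= max(np.std(field), 1e-12)
        blend = 0.5 * (1.0 + np.tanh(np.sin(phi) / 0.2))  # 1 on top, 0 on bottom
        amp = ruffle_amplitude_bottom + (ruffle_amplitude_top - ruffle_amplitude_bottom) * blend
        r = r + amp * field

    r = np.clip(r, 2 * px, None)
    xs = cx + r * np.cos(phi)
    ys = cy + r * np.sin(phi)
    rows = (ny - 1) - ys / px
    cols = xs / px
    mask = np.zeros((ny, nx), dtype=bool)
    rr, cc = polygon(rows, cols, shape=(ny, nx))
    mask[rr, cc] = True

    truth = {
        "axes_um": [a, b],
        "orientation_deg": orientation % 180.0,
        "center_um": [cx, cy],
        "protrusion_angles_deg": sorted(
            (ang % 360.0 if ang % 360.0 <= 180.0 else ang % 360.0 - 180.0)
            for ang, _, _ in protrusions
        ),
        "protrusion_directions_deg": [ang % 360.0 for ang, _, _ in protrusions],
        "protrusion_prominences_um": [p for _, p, _ in protrusions],
        "ruffle_amplitude_top_um": ruffle_amplitude_top,
        "ruffle_amplitude_bottom_um": ruffle_amplitude_bottom,
        "ruffle_band": list(ruffle_band),
    }
    return mask, truth


def render_mask_image(
    mask: np.ndarray,
    spec: GeneratorSpec,
    foreground: float = 200.0,
    background: float = 20.0,
) -> np.ndarray:
    """Render a binary mask as a noisy fluorescence-like intensity image."""
    rng = np.random.default_rng(spec.seed + 1)
    img = np.where(mask, foreground, background).astype(float)
    return _apply_noise(rng, img, spec)


# ---------------------------------------------------------------------------
# gradient scenes
# ---------------------------------------------------------------------------


def gen_gradient_scene(
    spec: GeneratorSpec,
    conc: ConcentrationField,
    intensity_scale: float = 150.0,
    background: float = 10.0,
) -> tuple[np.ndarray, dict]:
    """Render a solved concentration stack to noisy dextran-like images.

    Frame rows run from the dosed line (top) down to the plain line, so
    the rendered frames look like the microscope's field of view.  Truth
    carries the underlying concentration stack and times.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    for c in conc.concentration:
        img = background + intensity_scale * np.flipud(c)
        frames.append(_apply_noise(rng, img, spec))
    truth = {
        "times_s": conc.times.tolist(),
        "profile": conc.profile().tolist(),
        "intensity_scale": intensity_scale,
        "background": background,
    }
    return np.array(frames), truth


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_tiff_with_truth(path: str | Path, data: np.ndarray, truth: dict,
                         spec: GeneratorSpec | None = None) -> Path:
    """Write data as float32 TIFF with a JSON truth sidecar next to it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(data, dtype=np.float32)
    tifffile.imwrite(path, arr, photometric="minisblack")
    sidecar = path.with_suffix(".truth.json")
    payload = dict(truth)
    if spec is not None:
        payload["generator_spec"] = asdict(spec)
    sidecar.write_text(json.dumps(payload, indent=2))
    return sidecar
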