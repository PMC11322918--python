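"""Canned study-level experiments over the analysis stages.

Each function runs one of the package's validation or characterization
studies end to end — generating synthetic inputs where needed, executing
the corresponding stage, and returning measured quantities as plain dicts
or DataFrames.  They carry no expected values: oracles and thresholds live
with the callers (tests, the acceptance script, the analysis drivers).

Study conditions follow the source assays: 2-20 mm H2O heads, a 5 mm x
250 um chamber, 70 kDa dextran diffusivity 7e-11 m^2/s, 30 um bleach spot
imaged every 0.5 s for 15 s, physiological speeds 2-20 um/s.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import cysts as cy
from . import fibers as fb
from . import frap as fr
from . import synth
from . import transport as tr

__all__ = [
    "slab_darcy_velocity",
    "velocity_linearity",
    "transport_transient_profiles",
    "gradient_formation_study",
    "laminarity",
    "frap_speed_sweep",
    "frap_zero_flow",
    "alignment_concentration_sweep",
    "fiber_image_separation",
    "morphometric_closed_forms",
    "protrusion_recovery",
    "ruffling_ratio_study",
]


# ---------------------------------------------------------------------------
# transport
# ---------------------------------------------------------------------------


def slab_darcy_velocity(n_cells: int = 50) -> dict:
    """Solver vs analytic Darcy velocity on the 1-D slab limit.

    Slab: flow path 1 mm, transparent interface, dP = 9.80665 Pa
    (1 mm H2O), k = 2e-13 m^2, mu = 1 cP; v = k dP / (mu L).
    """
    length = 1e-3
    geom = tr.DeviceGeometry(chamber_length=0.2e-3, chamber_width=length,
                             grid_spacing=length / n_cells,
                             pore_conductance=np.inf)
    props = tr.PorousMediumProps()
    bc = tr.PressureBoundary(inlet_head=1.0, outlet_head=0.0)
    flow = tr.solve_darcy(geom, props, bc)
    dp = tr.head_to_pressure(1.0, props)
    v_analytic = props.permeability * dp / (props.viscosity * length)
    v_solver = float(np.abs(flow.velocity_y).max())
    return {
        "v_solver_m_s": v_solver,
        "v_analytic_m_s": v_analytic,
        "rel_err": abs(v_solver - v_analytic) / v_analytic,
        "max_rel_divergence": flow.max_relative_divergence(),
    }


def velocity_linearity(heads_mm=(2.0, 5.0, 10.0, 20.0)) -> dict:
    """Proportionality of chamber speed to the applied head (2-20 mm H2O)."""
    geom = tr.aligned_preset(grid_spacing=25e-6, pore_conductance=1e-6)
    props = tr.PorousMediumProps()
    vmax = [tr.solve_darcy(geom, props, tr.PressureBoundary(h, 0.0)).speed.max()
            for h in heads_mm]
    slopes = np.array(vmax) / np.array(heads_mm)
    return {
        "heads_mm": list(heads_mm),
        "vmax_m_s": [float(v) for v in vmax],
        "max_slope_deviation": float(np.ptp(slopes) / slopes[0]),
    }


def transport_transient_profiles(n_cells: int = 50, n_times: int = 24):
    """Pure-diffusion gradient formation across the 250 um chamber width.

    Returns ``(times, y, profiles)``: solver profiles on [0, 3 L^2/D] for
    comparison against the eigenfunction-series solution.
    """
    length, diff = 250e-6, 7e-11
    geom = tr.DeviceGeometry(chamber_length=100e-6, chamber_width=length,
                             grid_spacing=length / n_cells)
    total = 3 * length**2 / diff
    params = tr.TransportParams(diffusivity=diff, time_step=2.0, total_time=total)
    times = np.linspace(0, total, n_times + 1)[1:]
    conc = tr.solve_transport(tr.zero_flow(geom), geom, params,
                              output_times=times)
    y = (np.arange(geom.shape[0]) + 0.5) * geom.grid_spacing
    return conc.times, y, conc.profile()


def gradient_formation_study(preset: str = "aligned", tolerance: float = 0.1,
                             window_h: float = 24.0) -> dict:
    """Zero-flow gradient formation and maintenance in a device preset."""
    geom = (tr.aligned_preset(grid_spacing=25e-6) if preset == "aligned"
            else tr.random_preset())
    props = tr.PorousMediumProps()
    params = tr.TransportParams(time_step=60.0, total_time=window_h * 3600.0)
    flow = tr.zero_flow(geom)
    times = np.arange(0, window_h * 3600.0 + 1, 900.0)
    conc = tr.solve_transport(flow, geom, params, porosity=props.porosity,
                              output_times=times)
    steady = tr.solve_steady_transport(flow, geom, params,
                                       porosity=props.porosity)
    gm = tr.gradient_metrics(conc, steady.mean(axis=1), tolerance=tolerance,
                             maintenance_window=window_h * 3600.0)
    return {
        "preset": preset,
        "formation_time_s": gm.formation_time,
        "formation_time_h": (None if gm.formation_time is None
                             else gm.formation_time / 3600.0),
        "maintained_24h": bool(gm.maintained_24h),
        "tolerance": tolerance,
    }


def laminarity(target_speed: float = 20e-6, head_mm: float = 20.0) -> dict:
    """Reynolds/Peclet numbers with the pore interface calibrated so the
    chamber peaks at the physiological maximum speed (20 um/s default)."""
    geom = tr.aligned_preset(grid_spacing=25e-6)
    props = tr.PorousMediumProps()
    g = tr.calibrate_pore_conductance(geom, props, target_speed, head_mm)
    flow = tr.solve_darcy(replace(geom, pore_conductance=g), props,
                          tr.PressureBoundary(head_mm, 0.0))
    rp = tr.reynolds_peclet(flow, geom, props, diffusivity=7e-11)
    return {
        "pore_conductance": g,
        "max_speed_m_s": float(flow.speed.max()),
        "Re_max": rp["Re_max"],
        "Pe": rp["Pe"],
    }


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------


def frap_speed_sweep(speeds=(2.0, 5.0, 10.0, 20.0), n_seeds: int = 200,
                     base_seed: int = 0) -> pd.DataFrame:
    """Recover known convective speeds from seeded FRAP sequences.

    Study conditions: 31 frames at 0.5 s, 30 um spot, shot + read noise,
    diffusive recovery on.  One row per (speed, seed).
    """
    rows = []
    for i, speed in enumerate(speeds):
        for s in range(n_seeds):
            spec = synth.GeneratorSpec(seed=base_seed + 1000 * (i + 1) + s,
                                       pixel_size=2.0)
            seq, truth = synth.gen_frap_sequence(spec, velocity=(speed, 0.0))
            est = fr.estimate_velocity(fr.track_centroid(seq))
            dir_err = abs((est.direction - truth["direction_deg"] + 180) % 360 - 180)
            rows.append({
                "true_speed_um_s": speed,
                "seed": spec.seed,
                "speed_um_s": est.speed,
                "rel_speed_err": abs(est.speed - speed) / speed,
                "direction_err_deg": dir_err,
                "fit_r2": est.fit_r2,
            })
    return pd.DataFrame(rows)


def frap_zero_flow(n_seeds: int = 200, base_seed: int = 0) -> pd.DataFrame:
    """Velocity components recovered from zero-flow (pure recovery) sequences."""
    rows = []
    for s in range(n_seeds):
        spec = synth.GeneratorSpec(seed=base_seed + 9_000_000 + s, pixel_size=2.0)
        seq, _ = synth.gen_frap_sequence(spec, velocity=(0.0, 0.0))
        est = fr.estimate_velocity(fr.track_centroid(seq))
        rows.append({"seed": spec.seed, "vx_um_s": est.vx, "vy_um_s": est.vy,
                     "speed_um_s": est.speed})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fibers
# ---------------------------------------------------------------------------


def alignment_concentration_sweep(kappas=(0.0, 0.5, 1.0, 2.0, 4.0, 8.0),
                                  n: int = 10**4, seed: int = 11) -> list[float]:
    """Alignment coefficient of von Mises angle samples across kappa levels."""
    rng = np.random.default_rng(seed)
    out = []
    for kappa in kappas:
        ang = synth.sample_axial_von_mises(rng, n, 90.0, kappa)
        sample = fb.OrientationSample(ang, np.ones_like(ang))
        out.append(fb.alignment_coefficient(sample).coefficient)
    return out


def fiber_image_separation(seed: int = 0, n_rep: int = 3) -> dict:
    """End-to-end image-pipeline contrast: highly aligned vs isotropic fibers."""
    hi, lo = [], []
    for r in range(n_rep):
        spec = synth.GeneratorSpec(seed=seed + r, image_size=(384, 384))
        img, _ = synth.gen_fiber_image(spec, kappa=12.0, mean_angle=90.0)
        hi.append(fb.alignment_coefficient(fb.estimate_orientations(img)).coefficient)
        spec = synth.GeneratorSpec(seed=seed + 100 + r, image_size=(384, 384))
        img, _ = synth.gen_fiber_image(spec, kappa=0.0)
        lo.append(fb.alignment_coefficient(fb.estimate_orientations(img)).coefficient)
    return {
        "aligned_coefficients": hi,
        "uniform_coefficients": lo,
        "aligned_min": float(min(hi)),
        "uniform_max": float(max(lo)),
    }


# ---------------------------------------------------------------------------
# cysts
# ---------------------------------------------------------------------------


def morphometric_closed_forms() -> dict:
    """Shape metrics of rasterized reference shapes with known geometry."""
    spec = synth.GeneratorSpec(seed=0, image_size=(160, 160))
    mask, _ = synth.gen_cyst_mask(spec, axes=(50.0, 50.0))
    circ = cy.shape_metrics(cy.CystShape.from_mask(mask, 1.0))
    prof = cy.contour_curvature(cy.CystShape.from_mask(mask, 1.0).contour,
                                closed=True)
    spec = synth.GeneratorSpec(seed=0, image_size=(280, 280))
    mask, _ = synth.gen_cyst_mask(spec, axes=(100.0, 50.0))
    ell = cy.shape_metrics(cy.CystShape.from_mask(mask, 1.0))
    return {
        "circle_aspect_ratio": circ.aspect_ratio,
        "circle_roundness": circ.roundness,
        "circle_shape_factor": circ.shape_factor,
        "circle_mean_curvature_per_um": prof.mean,
        "ellipse_aspect_ratio": ell.aspect_ratio,
        "ellipse_roundness": ell.roundness,
    }


def _circ_dist(a: float, b: float) -> float:
    return abs((a - b + 180.0) % 360.0 - 180.0)


def protrusion_recovery(n_cysts: int = 200, base_seed: int = 42,
                        detect_prominence: float = 8.0,
                        match_tol_deg: float = 20.0) -> dict:
    """Detect known protrusions on seeded cysts; angle error and F1.

    Each cyst carries 1-3 protrusions of 12-18 um prominence at directions
    at least 40 degrees apart; the detector threshold (8 um) sits between
    the residual/ruffle floor and the smallest true protrusion.
    """
    rng = np.random.default_rng(base_seed)
    errs, tp, fp, fn = [], 0, 0, 0
    for s in range(n_cysts):
        n_p = int(rng.integers(1, 4))
        dirs: list[float] = []
        while len(dirs) < n_p:
            cand = float(rng.uniform(0, 360))
            if all(_circ_dist(cand, d) > 40 for d in dirs):
                dirs.append(cand)
        prot = [(d, float(rng.uniform(12, 18)), float(rng.uniform(7, 10)))
                for d in dirs]
        spec = synth.GeneratorSpec(seed=base_seed + 100_000 + s,
                                   image_size=(256, 256))
        mask, _ = synth.gen_cyst_mask(spec, axes=(55.0, 45.0), protrusions=prot)
        shape = cy.CystShape.from_mask(mask, 1.0)
        det = cy.detect_protrusions(shape, prominence=detect_prominence)
        cx, cyy = shape.centroid
        det_dirs = [float(np.degrees(np.arctan2(p.tip[1] - cyy,
                                                p.tip[0] - cx)) % 360)
                    for p in det]
        used: set[int] = set()
        for d in dirs:
            best, bd = None, np.inf
            for i, dd in enumerate(det_dirs):
                if i not in used and _circ_dist(d, dd) < bd:
                    best, bd = i, _circ_dist(d, dd)
            if best is not None and bd <= match_tol_deg:
                used.add(best)
                tp += 1
                errs.append(bd)
            else:
                fn += 1
        fp += len(det_dirs) - len(used)
    precision = tp / max(tp + fp, 1)
    recall = tp / max(tp + fn, 1)
    f1 = (0.0 if precision + recall == 0
          else 2 * precision * recall / (precision + recall))
    return {
        "n_cysts": n_cysts,
        "median_angle_err_deg": float(np.median(errs)),
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }


def ruffling_ratio_study(n_directional: int = 100, n_symmetric: int = 50,
                         base_seed: int = 0) -> dict:
    """Curvature ratios of top-ruffled vs symmetric cyst populations.

    Top-only ruffling (8 um RMS) should drive the ratio above 1 in nearly
    every seed; equal top/bottom ruffling (5 um) should leave the
    population mean near 1.
    """
    def ratio(seed: int, amp_top: float, amp_bot: float) -> float:
        spec = synth.GeneratorSpec(seed=seed, image_size=(256, 256))
        mask, _ = synth.gen_cyst_mask(spec, axes=(60.0, 50.0),
                                      ruffle_amplitude_top=amp_top,
                                      ruffle_amplitude_bottom=amp_bot)
        shape = cy.CystShape.from_mask(mask, 1.0)
        t, b = cy.split_top_bottom(shape)
        return cy.curvature_ratio(cy.half_curvature(t), cy.half_curvature(b))

    top = [ratio(base_seed + 200_000 + s, 8.0, 0.0) for s in range(n_directional)]
    sym = [ratio(base_seed + 300_000 + s, 5.0, 5.0) for s in range(n_symmetric)]
    top_arr = np.asarray(top)
    return {
        "n_directional": n_directional,
        "n_symmetric": n_symmetric,
        "frac_directional_gt1": float(np.mean(top_arr > 1.0)),
        "directional_median_ratio": float(np.median(top_arr)),
        "symmetric_mean_ratio": float(np.mean(sym)),
        "symmetric_sd_ratio": float(np.std(sym, ddof=1)),
    }
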