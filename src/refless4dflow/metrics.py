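"""Agreement analyses between two velocity/TKE reconstructions.

Implements the comparisons used to validate a referenceless reconstruction
against the conventional 4-point one: voxel-wise linear regression and
Bland-Altman statistics (per timeframe and direction), per-beat flow volumes
through vessel cross-sections (Qp/Qs), peak-systole region summaries of
velocity and turbulent kinetic energy, and complex-image error measures.

Sign convention: differences are test - reference, so a negative bias means
the test (referenceless) arm underestimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .recon import DIRECTIONS, VelocityField, TurbulenceMaps

REGIONS = ("RA", "RV", "LA", "LV", "aorta", "pulmonary")


# ---------------------------------------------------------------------------
# voxel-wise agreement
# ---------------------------------------------------------------------------

def _regress(x: np.ndarray, y: np.ndarray) -> dict:
    if np.ptp(x) == 0:
        return {"slope": np.nan, "intercept": np.nan, "pearson_r": np.nan,
                "rmse": float(np.sqrt(np.mean((y - x) ** 2)))}
    res = stats.linregress(x, y)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "pearson_r": float(res.rvalue),
            "rmse": float(np.sqrt(np.mean((y - x) ** 2)))}


def bland_altman(v_ref: np.ndarray, v_test: np.ndarray,
                 mask: np.ndarray | None = None) -> tuple[float, float]:
    """Bias and 1.96*SD limits-of-agreement half-width of test - reference."""
    v_ref = np.asarray(v_ref, dtype=float)
    v_test = np.asarray(v_test, dtype=float)
    if mask is not None:
        v_ref, v_test = v_ref[..., mask], v_test[..., mask]
    d = (v_test - v_ref).ravel()
    if d.size < 2:
        raise ValueError("need at least 2 paired values for Bland-Altman")
    return float(d.mean()), float(1.96 * d.std(ddof=0))


def voxelwise_regression(v_ref: VelocityField | np.ndarray,
                         v_test: VelocityField | np.ndarray,
                         mask: np.ndarray, per_timeframe: bool = True
                         ) -> pd.DataFrame:
    """OLS of test on reference over masked voxels, per direction.

    Returns a tidy frame with one row per (timeframe x) direction carrying
    slope, intercept, Pearson r, RMSE, bias and the limits-of-agreement
    half-width.  With ``per_timeframe=False`` all timeframes are pooled.
    """
    a = v_ref.v if isinstance(v_ref, VelocityField) else np.asarray(v_ref)
    b = v_test.v if isinstance(v_test, VelocityField) else np.asarray(v_test)
    if a.shape != b.shape:
        raise ValueError("velocity grids disagree")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    rows = []
    frames = range(a.shape[1]) if per_timeframe else [None]
    for t in frames:
        for d, name in enumerate(DIRECTIONS):
            x = a[d, t][mask].ravel() if t is not None else a[d][:, mask].ravel()
            y = b[d, t][mask].ravel() if t is not None else b[d][:, mask].ravel()
            row = {"timeframe": t if t is not None else -1, "direction": name}
            row.update(_regress(x, y))
            bias, loa = bland_altman(x, y)
            row.update({"bias": bias, "loa_halfwidth": loa})
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_agreement(df: pd.DataFrame) -> pd.DataFrame:
    """Median and interquartile range over timeframes, per direction."""
    stats_cols = ["slope", "intercept", "bias", "loa_halfwidth"]
    out = []
    for name, grp in df.groupby("direction"):
        row = {"direction": name}
        for c in stats_cols:
            vals = grp[c].dropna()
            row[f"{c}_median"] = float(vals.median())
            row[f"{c}_iqr"] = float(vals.quantile(0.75) - vals.quantile(0.25))
        out.append(row)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# region summaries
# ---------------------------------------------------------------------------

def flow_volume(vf: VelocityField, plane_mask: np.ndarray,
                normal_direction: int | str, dt_s: float | None = None) -> float:
    """Per-beat flow volume (mL) through a one-voxel-thick cross-section.

    Q = sum_t sum_vox v_normal * A_voxel * dt, with the through-plane
    direction given as an index into (AP, RL, FH) or its name.
    """
    plane_mask = np.asarray(plane_mask, dtype=bool)
    if not plane_mask.any():
        raise ValueError("plane mask is empty")
    if isinstance(normal_direction, str):
        normal_direction = DIRECTIONS.index(normal_direction)
    dt = vf.dt_s if dt_s is None else dt_s
    vx, vy, vz = vf.voxel_size_mm
    in_plane = {0: (vy, vz), 1: (vx, vz), 2: (vx, vy)}[normal_direction]
    area_m2 = in_plane[0] * in_plane[1] * 1e-6
    q_m3 = vf.v[normal_direction][:, plane_mask].sum() * area_m2 * dt
    return float(q_m3 * 1e6)    # m^3 -> mL


def systolic_frames(n_timeframes: int, fraction: float = 0.4) -> np.ndarray:
    """Default systolic window: the first 40% of the cycle."""
    return np.arange(max(1, int(np.ceil(fraction * n_timeframes))))


def peak_systole_summary(vf: VelocityField, tke: TurbulenceMaps | None,
                         region_masks: dict[str, np.ndarray], window: int = 4,
                         aorta_key: str = "aorta") -> pd.DataFrame:
    """Region summaries of velocity and TKE averaged around peak systole.

    The peak frame is the systolic frame maximizing mean speed in the aorta
    mask; fields are averaged over ``window`` consecutive frames centred on
    it before computing region mean/max speed and total (volume-integrated,
    mJ) and maximum (J/m^3) TKE.
    """
    T = vf.v.shape[1]
    if window > T:
        raise ValueError("averaging window exceeds the cardiac cycle")
    sys_frames = systolic_frames(T)
    aorta = np.asarray(region_masks[aorta_key], dtype=bool)
    speed = np.sqrt((vf.v ** 2).sum(axis=0))        # (T, X, Y, Z)
    mean_speed = speed[:, aorta].mean(axis=1)
    peak = int(sys_frames[np.argmax(mean_speed[sys_frames])])
    lo = max(0, peak - (window - 1) // 2)
    hi = min(T, lo + window)
    lo = max(0, hi - window)
    speed_avg = speed[lo:hi].mean(axis=0)
    tke_avg = tke.tke[lo:hi].mean(axis=0) if tke is not None else None
    vx, vy, vz = vf.voxel_size_mm
    voxel_m3 = vx * vy * vz * 1e-9
    rows = []
    for name, m in region_masks.items():
        m = np.asarray(m, dtype=bool)
        if not m.any():
            continue
        row = {"region": name, "peak_systole_frame": peak,
               "mean_velocity_m_s": float(speed_avg[m].mean()),
               "max_velocity_m_s": float(speed_avg[m].max())}
        if tke_avg is not None:
            row["total_tke_mJ"] = float(tke_avg[m].sum() * voxel_m3 * 1e3)
            row["max_tke_J_m3"] = float(tke_avg[m].max())
        rows.append(row)
    return pd.DataFrame(rows)


def image_error(pred_ref: np.ndarray, true_ref: np.ndarray) -> tuple[float, float]:
    """MAE and MSE over all voxels, timeframes and both (real, imag) channels."""
    pred_ref = np.asarray(pred_ref, dtype=float)
    true_ref = np.asarray(true_ref, dtype=float)
    if pred_ref.shape != true_ref.shape:
        raise ValueError("image shapes disagree")
    d = pred_ref - true_ref
    return float(np.abs(d).mean()), float((d ** 2).mean())
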