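"""Synthetic whole-heart 4D flow phantom with exact ground truth.

The phantom emulates the salient features of a whole-heart phase-contrast
acquisition: two tube-like vessels (aorta, pulmonary artery) carrying
pulsatile parabolic flow along the feet-head axis, a chamber with slower
three-directional swirling flow, static tissue, a noise-dominated low-signal
lung region, a jet region with per-direction intravoxel velocity dispersion,
and a spatially smooth, temporally varying background phase offset shared by
all encodings.  The forward signal model is the exact inverse of the
reconstruction equations in :mod:`refless4dflow.recon`, so noise-free round
trips recover the ground truth to machine precision.

Signal model (VENC in m/s, magnitude M, background phase phi_b):

    S_0 = M * exp(i * phi_b)
    S_e = M * exp(-sigma_e^2 (pi/VENC)^2) * exp(i * (phi_b + pi v_e / VENC))

with independent complex Gaussian noise added to every encoding.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .recon import EncodingSet, polynomial_basis, normalized_coords

#: index order of velocity components and of motion encodings 1..3
COMPONENTS = ("ap", "rl", "fh")


@dataclass(frozen=True)
class PhantomConfig:
    """Stated world of the synthetic acquisition.

    Defaults follow the emulated protocol where one exists (VENC 1.2 m/s,
    40 reconstructed timeframes, ~2.8 mm isotropic voxels, 4th-order
    background field) and desk-scale choices elsewhere (32^3 grid; a ~12 mm
    vessel radius, i.e. aorta-like at this field of view).
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: tuple[float, float, float] = (2.8, 2.8, 2.8)
    n_timeframes: int = 40
    rr_interval_s: float = 1.0
    venc_m_s: float = 1.2
    vessel_radius_mm: float = 12.0
    peak_velocity_m_s: float = 1.0
    chamber_velocity_scale: float = 0.3
    jet_sigma_m_s: float = 0.3
    background_poly_order: int = 4
    background_amplitude_rad: float = 0.3
    noise_sd: float = 0.02
    seed: int = 0
    sigma_factor: str = "direct"     # magnitude-damping convention, see recon
    allow_wrap: bool = False

    def __post_init__(self) -> None:
        if any(n < 16 for n in self.grid_shape):
            raise ValueError("all spatial dims must be >= 16")
        if self.n_timeframes < 2:
            raise ValueError("n_timeframes must be >= 2")
        if self.venc_m_s <= 0 or self.rr_interval_s <= 0:
            raise ValueError("venc_m_s and rr_interval_s must be positive")
        if self.peak_velocity_m_s > self.venc_m_s and not self.allow_wrap:
            raise ValueError(
                "peak_velocity_m_s exceeds venc_m_s; set allow_wrap=True for "
                "wrap testing")
        fov_x = self.grid_shape[0] * self.voxel_size_mm[0]
        if self.vessel_radius_mm > fov_x / 4:
            raise ValueError(
                f"grid too small for vessel radius {self.vessel_radius_mm} mm "
                f"(field of view {fov_x:.0f} mm)")

    @property
    def dt_s(self) -> float:
        return self.rr_interval_s / self.n_timeframes


@dataclass
class PhantomGroundTruth:
    """Exact ground truth of one synthetic subject."""

    velocity: np.ndarray          # (3, T, X, Y, Z) m/s
    sigma: np.ndarray             # (3, X, Y, Z) m/s, zero outside the jet
    magnitude: np.ndarray         # (X, Y, Z) in [0, 1]
    background_phase: np.ndarray  # (T, X, Y, Z) rad, polynomial in space
    masks: dict[str, np.ndarray]  # named boolean fields
    waveform: np.ndarray          # (T,) systolic/diastolic modulation, max 1
    peak_frame: int
    config: PhantomConfig = field(repr=False, default=None)

    @property
    def blood_mask(self) -> np.ndarray:
        return self.masks["vessel"] | self.masks["chamber"]


def _waveform(config: PhantomConfig) -> np.ndarray:
    """Raised-cosine systolic pulse over the first 40% of the cycle plus
    low-amplitude E/A diastolic bumps; normalized so the maximum is exactly 1."""
    t = np.arange(config.n_timeframes) * config.dt_s
    rr = config.rr_interval_s
    ts = 0.4 * rr
    w = np.where(t < ts, 0.5 * (1.0 - np.cos(2.0 * np.pi * t / ts)), 0.0)
    w = w + 0.25 * np.exp(-0.5 * ((t - 0.55 * rr) / (0.05 * rr)) ** 2)   # E wave
    w = w + 0.15 * np.exp(-0.5 * ((t - 0.85 * rr) / (0.04 * rr)) ** 2)   # A wave
    return w / w.max()


def generate_phantom(config: PhantomConfig) -> PhantomGroundTruth:
    """Build the deterministic ground truth for one subject."""
    nx, ny, nz = config.grid_shape
    vx, vy, vz = config.voxel_size_mm
    rng = np.random.default_rng([config.seed, 0])

    ix = np.arange(nx)[:, None, None] * np.ones((1, ny, nz))
    iy = np.arange(ny)[None, :, None] * np.ones((nx, 1, nz))
    iz = np.arange(nz)[None, None, :] * np.ones((nx, ny, 1))

    # vessels: tubes along the FH (z) axis with axes on voxel centres
    r_vox = config.vessel_radius_mm / vx
    cx_a, cy_a = nx // 2 + int(round(r_vox)) + 1, ny // 2
    cx_p, cy_p = nx // 2 - int(round(r_vox)) - 1, ny // 2
    r2_a = ((ix - cx_a) * vx) ** 2 + ((iy - cy_a) * vy) ** 2
    r2_p = ((ix - cx_p) * vx) ** 2 + ((iy - cy_p) * vy) ** 2
    R2 = config.vessel_radius_mm ** 2
    aorta = r2_a < R2
    pulmonary = (r2_p < R2) & ~aorta
    vessel = aorta | pulmonary

    # chamber: sphere in the anterior half
    cc = np.array([nx * 0.5, ny * 0.22, nz * 0.5])
    rad_ch = 0.16 * min(nx * vx, ny * vy, nz * vz)
    d2 = ((ix - cc[0]) * vx) ** 2 + ((iy - cc[1]) * vy) ** 2 + ((iz - cc[2]) * vz) ** 2
    chamber = (d2 < rad_ch ** 2) & ~vessel

    # lung: posterior slab, excluding vessels and chamber
    lung = (iy > 0.8 * ny) & ~vessel & ~chamber
    static = ~(vessel | chamber | lung)

    # jet: core of the aorta over the central third in z
    jet = aorta & (r2_a < (0.5 * config.vessel_radius_mm) ** 2) \
        & (iz > nz / 3) & (iz < 2 * nz / 3)

    # one-voxel-thick analysis planes through each vessel
    z_pl = nz // 2
    plane_aorta = aorta & (iz == z_pl)
    plane_pulmonary = pulmonary & (iz == z_pl)

    w = _waveform(config)
    peak_frame = int(np.argmax(w))

    # velocity: parabolic axial profile in the tubes; the aorta axis passes
    # through a voxel centre so the spatial profile attains exactly 1 there
    prof_a = np.where(aorta, 1.0 - r2_a / R2, 0.0)
    prof_p = np.where(pulmonary, 1.0 - r2_p / R2, 0.0)
    T = config.n_timeframes
    velocity = np.zeros((3, T) + config.grid_shape)
    vpk = config.peak_velocity_m_s
    for t in range(T):
        velocity[2, t] = vpk * w[t] * (prof_a + 0.9 * prof_p)
    # chamber: smooth rigid-body-like swirl, all three components
    if chamber.any():
        dxc = (ix - cc[0]) * vx
        dyc = (iy - cc[1]) * vy
        dzc = (iz - cc[2]) * vz
        sw = np.stack([dyc - 0.5 * dzc, dzc - dxc, dxc - 0.5 * dyc])
        speed = np.sqrt((sw ** 2).sum(axis=0))
        smax = speed[chamber].max()
        if smax > 0:
            sw *= config.chamber_velocity_scale * vpk / smax
        taper = np.clip(1.0 - d2 / rad_ch ** 2, 0.0, None)
        for t in range(T):
            velocity[:, t] += np.where(chamber, sw * taper, 0.0) * w[t]

    # intravoxel SD: jet only, per-direction amplitudes, smooth radial profile
    sigma = np.zeros((3,) + config.grid_shape)
    if jet.any():
        prof_jet = np.clip(1.0 - r2_a / (0.5 * config.vessel_radius_mm) ** 2, 0.0, None)
        for d, amp in enumerate((0.8, 0.9, 1.0)):
            sigma[d] = np.where(jet, amp * config.jet_sigma_m_s * prof_jet, 0.0)

    # magnitude: bright blood, dimmer tissue, near-zero lung
    magnitude = np.where(vessel | chamber, 1.0, np.where(lung, 0.03, 0.7))

    # background phase: random polynomial in normalized coords, smooth in time
    background = np.zeros((T,) + config.grid_shape)
    if config.background_amplitude_rad > 0:
        basis = polynomial_basis(config.grid_shape, config.background_poly_order)
        nterms = basis.shape[1]
        c0 = rng.standard_normal(nterms)
        c1 = rng.standard_normal(nterms)
        psi = rng.uniform(0, 2 * np.pi)
        tt = np.arange(T) / T
        raw = np.empty((T,) + config.grid_shape)
        for t in range(T):
            c = c0 + 0.35 * c1 * np.sin(2 * np.pi * tt[t] + psi)
            raw[t] = (basis @ c).reshape(config.grid_shape)
        background = raw * (config.background_amplitude_rad / np.abs(raw).max())

    masks = {
        "vessel": vessel, "aorta": aorta, "pulmonary": pulmonary,
        "chamber": chamber, "static_tissue": static, "lung": lung, "jet": jet,
        "plane_aorta": plane_aorta, "plane_pulmonary": plane_pulmonary,
    }
    return PhantomGroundTruth(velocity=velocity, sigma=sigma, magnitude=magnitude,
                              background_phase=background, masks=masks,
                              waveform=w, peak_frame=peak_frame, config=config)


def simulate_encodings(gt: PhantomGroundTruth, config: PhantomConfig | None = None
                       ) -> EncodingSet:
    """Forward signal model: ground truth -> four complex encodings."""
    config = config or gt.config
    if gt.velocity.shape[2:] != tuple(config.grid_shape):
        raise ValueError("ground truth and config grids disagree")
    T = config.n_timeframes
    venc = config.venc_m_s
    f = 1.0 if config.sigma_factor == "direct" else 2.0
    damp = np.exp(-f * gt.sigma ** 2 * (np.pi / venc) ** 2)
    real = np.empty((4, T) + tuple(config.grid_shape))
    imag = np.empty_like(real)
    for t in range(T):
        phi0 = gt.background_phase[t]
        s0 = gt.magnitude * np.exp(1j * phi0)
        real[0, t], imag[0, t] = s0.real, s0.imag
        for e in range(3):
            phase = phi0 + np.pi * gt.velocity[e, t] / venc
            se = gt.magnitude * damp[e] * np.exp(1j * phase)
            real[e + 1, t], imag[e + 1, t] = se.real, se.imag
    if config.noise_sd > 0:
        rng = np.random.default_rng([config.seed, 1])
        real += rng.normal(0.0, config.noise_sd, real.shape)
        imag += rng.normal(0.0, config.noise_sd, imag.shape)
    return EncodingSet(real=real, imag=imag, venc_m_s=venc,
                       voxel_size_mm=tuple(config.voxel_size_mm),
                       dt_s=config.dt_s)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def subject_seeds(master_seed: int, n: int) -> list[int]:
    """Disjoint, deterministic per-subject seeds below 2^31."""
    ss = np.random.SeedSequence(master_seed)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]


def make_dataset(n_subjects: int, config_template: PhantomConfig, out_dir: str | Path,
                 train_frac: float = 0.9, master_seed: int | None = None) -> dict:
    """Write ``n_subjects`` phantom acquisitions as NIfTI + JSON to ``out_dir``.

    Returns (and writes) a manifest with per-subject file paths, metadata and
    train/test splits.  Per-subject seeds derive from ``master_seed``
    (default: the template's seed).
    """
    import nibabel as nib

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    master = config_template.seed if master_seed is None else master_seed
    seeds = subject_seeds(master, n_subjects)

    def save(path: Path, arr: np.ndarray, zooms: tuple) -> None:
        img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine=np.diag(
            list(zooms[:3]) + [1.0]))
        z = tuple(zooms) + (1.0,) * max(0, arr.ndim - len(zooms))
        img.header.set_zooms(z[: arr.ndim])
        nib.save(img, str(path))

    subjects = []
    for i, seed in enumerate(seeds):
        sid = f"sub{i:03d}"
        cfg = PhantomConfig(**{**asdict(config_template), "seed": seed})
        gt = generate_phantom(cfg)
        es = simulate_encodings(gt, cfg)
        zooms3 = tuple(cfg.voxel_size_mm)
        zooms4 = zooms3 + (cfg.dt_s,)
        files: dict[str, str] = {}
        for e in range(4):
            for comp, arr in (("real", es.real[e]), ("imag", es.imag[e])):
                name = f"{sid}_enc{e}_{comp}.nii.gz"
                # (T, X, Y, Z) -> (X, Y, Z, T) spatial-first for NIfTI
                save(out_dir / name, np.moveaxis(arr, 0, -1), zooms4)
                files[f"enc{e}_{comp}"] = name
        gt_files = {
            "gt_velocity": f"{sid}_gt_vel.nii.gz",
            "gt_sigma": f"{sid}_gt_sigma.nii.gz",
            "gt_magnitude": f"{sid}_gt_mag.nii.gz",
            "gt_background": f"{sid}_gt_bg.nii.gz",
            "gt_masks": f"{sid}_gt_masks.nii.gz",
        }
        save(out_dir / gt_files["gt_velocity"],
             np.moveaxis(gt.velocity, (0, 1), (-1, -2)), zooms3)      # (X,Y,Z,T,3)
        save(out_dir / gt_files["gt_sigma"], np.moveaxis(gt.sigma, 0, -1), zooms3)
        save(out_dir / gt_files["gt_magnitude"], gt.magnitude, zooms3)
        save(out_dir / gt_files["gt_background"],
             np.moveaxis(gt.background_phase, 0, -1), zooms4)
        mask_names = sorted(gt.masks)
        save(out_dir / gt_files["gt_masks"],
             np.stack([gt.masks[m] for m in mask_names], axis=-1).astype(np.float32),
             zooms3)
        meta = {
            "subject_id": sid, "seed": seed, "venc_m_s": cfg.venc_m_s,
            "rr_interval_s": cfg.rr_interval_s, "dt_s": cfg.dt_s,
            "n_timeframes": cfg.n_timeframes,
            "voxel_size_mm": list(cfg.voxel_size_mm),
            "grid_shape": list(cfg.grid_shape),
            "mask_names": mask_names, "peak_frame": gt.peak_frame,
            "files": files, "ground_truth": gt_files,
        }
        meta_name = f"{sid}_meta.json"
        (out_dir / meta_name).write_text(json.dumps(meta, indent=1, sort_keys=True))
        subjects.append({"subject_id": sid, "seed": seed, "meta": meta_name})

    n_train = int(round(train_frac * n_subjects))
    manifest = {
        "master_seed": master, "subjects": subjects,
        "splits": {"train": [s["subject_id"] for s in subjects[:n_train]],
                   "test": [s["subject_id"] for s in subjects[n_train:]]},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {**manifest, "out_dir": str(out_dir)}


def dataset_checksum(out_dir: str | Path) -> str:
    """SHA256 over the decoded array contents and JSON files of a dataset."""
    import gzip

    h = hashlib.sha256()
    for p in sorted(Path(out_dir).iterdir()):
        h.update(p.name.encode())
        if p.suffix == ".gz":
            h.update(gzip.decompress(p.read_bytes()))
        else:
            h.update(p.read_bytes())
    return h.hexdigest()
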