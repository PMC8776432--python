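"""Synthetic H&E scenes and survival cohorts with known ground truth.

The image generator produces a two-stain Beer-Lambert forward model of
clear-cell-like tissue: elliptical hematoxylin-rich nuclei, a perinuclear
cytoplasm band whose staining is heterogeneous (gamma-distributed organelle
texture), and clear lipid vacuoles punched into that band.  The vacuole
fraction is the dial that controls the excess kurtosis of the cytoplasmic
hematoxylin distribution: a vacuole-rich ("clear cell") band is a sharp
near-zero spike plus a diffuse stained remainder, i.e. leptokurtic, and the
kurtosis grows with the vacuole fraction over the 0.1-0.6 range used here.

The survival simulator draws event times from an exponential
proportional-hazards model with independent exponential censoring, so the
true log hazard ratio of any covariate is known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse

from .errors import PlacementError

__all__ = [
    "SceneSpec",
    "GroundTruthScene",
    "RGBTile",
    "SurvivalSimSpec",
    "DEFAULT_STAIN_BASIS",
    "generate_scene",
    "render_he",
    "simulate_survival",
    "save_scene",
    "generate_cohort",
]

# Classic H&E optical-density vectors (rows: hematoxylin, eosin), unit norm.
_H = np.array([0.65, 0.70, 0.29])
_E = np.array([0.07, 0.99, 0.11])
DEFAULT_STAIN_BASIS = np.stack([_H / np.linalg.norm(_H), _E / np.linalg.norm(_E)])


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic tissue tile.

    Lengths are in microns; ``mpp`` (microns per pixel) converts to pixels.
    ``vacuole_fraction`` is the fraction of the cytoplasm-band area occupied
    by clear lipid vacuoles.  ``cyto_texture_rel_sd`` is the relative
    standard deviation of the gamma-distributed staining texture of the
    non-vacuole cytoplasm (0 gives a uniform band).
    """

    image_height_px: int = 256
    image_width_px: int = 256
    mpp: float = 0.5
    n_nuclei: int = 25
    nucleus_radius_um: tuple[float, float] = (3.0, 5.0)
    vacuole_fraction: float = 0.3
    nucleus_h_conc: float = 1.0
    cyto_base_conc: tuple[float, float] = (0.18, 0.25)
    cyto_width_um: float = 6.0
    cyto_texture_rel_sd: float = 0.9
    cyto_texture_cap: float = 3.0
    vacuole_radius_um: tuple[float, float] = (0.8, 2.0)
    noise_sd: float = 0.02
    min_separation_um: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.vacuole_fraction <= 1.0):
            raise ValueError("vacuole_fraction must be in [0, 1]")
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")
        if self.nucleus_h_conc < 0 or min(self.cyto_base_conc) < 0:
            raise ValueError("stain concentrations must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class RGBTile:
    """8-bit RGB pixel grid with physical scale (microns per pixel)."""

    pixels: np.ndarray  # (H, W, 3) uint8
    mpp: float


@dataclass(frozen=True)
class GroundTruthScene:
    """A rendered-ready scene with known labels, concentrations and stains."""

    nuclei_labels: np.ndarray       # (H, W) int32, 0 = background
    true_concentrations: np.ndarray  # (H, W, 2) float64, [h, e]
    cytoplasm_band: np.ndarray      # (H, W) bool, the true perinuclear band
    stain_basis: np.ndarray         # (2, 3) rows h, e; unit norm
    spec: SceneSpec


@dataclass(frozen=True)
class SurvivalSimSpec:
    """Exponential proportional-hazards simulation parameters.

    The hazard for covariate value z is ``baseline_hazard * exp(beta * z)``;
    censoring is an independent Exponential(censor_rate) clock.
    """

    n_patients: int = 200
    beta: float = 0.0
    baseline_hazard: float = 1.0
    censor_rate: float = 0.3
    covariate_model: str = "binary"  # "binary" | "continuous-standardized"
    seed: int = 0

    def __post_init__(self):
        if self.baseline_hazard <= 0 or self.censor_rate <= 0:
            raise ValueError("baseline_hazard and censor_rate must be positive")
        if self.covariate_model not in ("binary", "continuous-standardized"):
            raise ValueError(f"unknown covariate_model {self.covariate_model!r}")


def _place_nuclei(spec: SceneSpec, rng: np.random.Generator):
    """Sample non-overlapping ellipse parameters (centers, axes, angles)."""
    h_px, w_px = spec.image_height_px, spec.image_width_px
    r_lo, r_hi = spec.nucleus_radius_um
    margin = r_hi / spec.mpp + 1
    if h_px - 2 * margin <= 0 or w_px - 2 * margin <= 0:
        raise PlacementError(
            "image too small to place nuclei of radius "
            f"{r_hi} um at mpp {spec.mpp}"
        )
    centers, radii, angles = [], [], []
    max_attempts = 500 * max(spec.n_nuclei, 1)
    attempts = 0
    while len(centers) < spec.n_nuclei:
        if attempts >= max_attempts:
            raise PlacementError(
                f"placed {len(centers)}/{spec.n_nuclei} nuclei after "
                f"{max_attempts} attempts; constraint: min_separation_um="
                f"{spec.min_separation_um} within "
                f"{h_px}x{w_px} px at mpp {spec.mpp}"
            )
        attempts += 1
        cy = rng.uniform(margin, h_px - margin)
        cx = rng.uniform(margin, w_px - margin)
        a = rng.uniform(r_lo, r_hi)  # semi-axes, um
        b = rng.uniform(r_lo, r_hi)
        ang = rng.uniform(0, np.pi)
        r_out = max(a, b)
        ok = True
        if spec.min_separation_um > 0:
            for (py, px), (pa, pb) in zip(centers, radii):
                d_um = np.hypot(cy - py, cx - px) * spec.mpp
                if d_um < r_out + max(pa, pb) + spec.min_separation_um:
                    ok = False
                    break
        if ok:
            centers.append((cy, cx))
            radii.append((a, b))
            angles.append(ang)
    return centers, radii, angles


def generate_scene(spec: SceneSpec) -> GroundTruthScene:
    """Generate one scene with ground-truth labels and concentrations.

    Deterministic for a fixed ``spec`` (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    h_px, w_px = spec.image_height_px, spec.image_width_px
    labels = np.zeros((h_px, w_px), dtype=np.int32)
    conc = np.zeros((h_px, w_px, 2), dtype=np.float64)

    if spec.n_nuclei > 0:
        centers, radii, angles = _place_nuclei(spec, rng)
        for k, ((cy, cx), (a, b), ang) in enumerate(
            zip(centers, radii, angles), start=1
        ):
            rr, cc = draw_ellipse(
                cy, cx, a / spec.mpp, b / spec.mpp,
                shape=labels.shape, rotation=ang,
            )
            labels[rr, cc] = k

    nucleus = labels > 0
    conc[nucleus, 0] = spec.nucleus_h_conc
    conc[nucleus, 1] = 0.5 * spec.cyto_base_conc[1]

    # Perinuclear cytoplasm band: within cyto_width_um of a nucleus edge.
    if nucleus.any() and spec.cyto_width_um > 0:
        dist_um = ndi.distance_transform_edt(~nucleus, sampling=spec.mpp)
        band = (~nucleus) & (dist_um <= spec.cyto_width_um)
    else:
        band = np.zeros_like(nucleus)

    n_band = int(band.sum())
    if n_band > 0:
        # Independent gamma staining textures per channel (mean 1, relative
        # SD cyto_texture_rel_sd): basophilic and eosinophilic content vary
        # independently, which also lets the OD cloud span h- to e-dominant
        # directions as real tissue does.
        if spec.cyto_texture_rel_sd > 0:
            shape_k = 1.0 / spec.cyto_texture_rel_sd**2
            g_h = rng.gamma(shape_k, 1.0 / shape_k, size=n_band)
            g_e = rng.gamma(shape_k, 1.0 / shape_k, size=n_band)
            # Staining saturates: truncate the texture tail so rendered
            # optical densities stay within the 8-bit-recoverable range.
            np.minimum(g_h, spec.cyto_texture_cap, out=g_h)
            np.minimum(g_e, spec.cyto_texture_cap, out=g_e)
        else:
            g_h = g_e = np.ones(n_band)
        conc[band, 0] = spec.cyto_base_conc[0] * g_h
        conc[band, 1] = spec.cyto_base_conc[1] * g_e

        # Punch clear circular vacuoles (both channels ~0) into the band only
        # -- never inside nuclei -- until the target area fraction is clear.
        if spec.vacuole_fraction > 0:
            target = spec.vacuole_fraction * n_band
            vac = np.zeros_like(band)
            band_idx = np.flatnonzero(band.ravel())
            v_lo, v_hi = spec.vacuole_radius_um
            yy, xx = np.indices(labels.shape, sparse=True)
            cleared = 0
            for _ in range(200_000):
                if cleared >= target:
                    break
                flat = band_idx[rng.integers(len(band_idx))]
                cy, cx = divmod(flat, w_px)
                r_px = rng.uniform(v_lo, v_hi) / spec.mpp
                disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
                new = disk & band & ~vac
                vac |= new
                cleared += int(new.sum())
            conc[vac] = 0.0

    if spec.noise_sd > 0:
        conc = conc + rng.normal(0.0, spec.noise_sd, size=conc.shape)
        np.clip(conc, 0.0, None, out=conc)

    return GroundTruthScene(
        nuclei_labels=labels,
        true_concentrations=conc,
        cytoplasm_band=band,
        stain_basis=DEFAULT_STAIN_BASIS.copy(),
        spec=spec,
    )


def render_he(scene: GroundTruthScene, background_intensity: float = 255.0) -> RGBTile:
    """Render a scene to 8-bit RGB via the Beer-Lambert forward model.

    Per pixel, ``I = background * 10**-(c_h * v_h + c_e * v_e)`` rounded and
    clipped to [0, background].
    """
    basis = np.asarray(scene.stain_basis, dtype=float)
    conc = scene.true_concentrations
    if basis.shape != (2, 3) or conc.shape[-1] != 2:
        raise ValueError(
            f"concentration/basis shape mismatch: {conc.shape} vs {basis.shape}"
        )
    od = conc @ basis  # (H, W, 3)
    img = np.rint(background_intensity * np.power(10.0, -od))
    img = np.clip(img, 0, min(255.0, background_intensity)).astype(np.uint8)
    return RGBTile(pixels=img, mpp=scene.spec.mpp)


def simulate_survival(
    covariates: np.ndarray | None,
    spec: SurvivalSimSpec,
) -> pd.DataFrame:
    """Simulate a survival table under proportional hazards.

    Parameters
    ----------
    covariates
        One value per patient, or None to draw them from
        ``spec.covariate_model`` (Bernoulli(0.5) or standard normal).

    Returns
    -------
    DataFrame with columns ``patient_id, time, event, covariate``; ``event``
    is 1 when the event time precedes the censoring time.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    if covariates is None:
        if spec.covariate_model == "binary":
            z = rng.integers(0, 2, size=n).astype(float)
        else:
            z = rng.standard_normal(n)
    else:
        z = np.asarray(covariates, dtype=float)
        if z.shape != (n,):
            raise ValueError(
                f"expected {n} covariate values, got shape {z.shape}"
            )
    rate = spec.baseline_hazard * np.exp(spec.beta * z)
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.exponential(1.0 / spec.censor_rate, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "time": time,
            "event": event,
            "covariate": z,
        }
    )


def save_scene(scene: GroundTruthScene, out_dir: str | Path, stem: str = "scene") -> dict:
    """Write tile PNG, 16-bit label TIFF and a YAML sidecar of the spec."""
    import imageio.v3 as iio
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tile = render_he(scene)
    paths = {
        "tile": out / f"{stem}.png",
        "labels": out / f"{stem}_labels.tiff",
        "spec": out / f"{stem}_spec.yaml",
    }
    iio.imwrite(paths["tile"], tile.pixels)
    tifffile.imwrite(paths["labels"], scene.nuclei_labels.astype(np.uint16))
    meta = asdict(scene.spec)
    meta["nucleus_radius_um"] = list(meta["nucleus_radius_um"])
    meta["cyto_base_conc"] = list(meta["cyto_base_conc"])
    meta["vacuole_radius_um"] = list(meta["vacuole_radius_um"])
    paths["spec"].write_text(yaml.safe_dump(meta, sort_keys=False))
    return {k: str(v) for k, v in paths.items()}


def generate_cohort(
    out_dir: str | Path,
    n_patients: int = 20,
    tiles_per_patient: int = 4,
    vacuole_fraction_low: float = 0.15,
    vacuole_fraction_high: float = 0.55,
    beta: float = -1.2,
    baseline_hazard: float = 0.4,
    censor_rate: float = 0.05,
    seed: int = 0,
    scene_overrides: dict | None = None,
) -> dict:
    """Write a full synthetic cohort: tiles, manifest and survival table.

    Half the patients get vacuole-poor tumors, half vacuole-rich.  The
    survival covariate is each patient's true cytoplasm-band hematoxylin
    excess kurtosis (pooled over their tiles, cohort-standardized), so with
    ``beta < 0`` low kurtosis is wired to a higher hazard -- the structure
    the downstream survival stage should detect.

    Returns paths to ``manifest.csv`` and ``survival.csv`` plus the true
    per-patient kurtosis values.
    """
    from scipy.stats import kurtosis as _kurtosis

    import imageio.v3 as iio
    import tifffile

    out = Path(out_dir)
    tiles_dir = out / "tiles"
    tiles_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    overrides = dict(scene_overrides or {})
    overrides.setdefault("n_nuclei", 28)
    overrides.setdefault("min_separation_um", 3.0)

    manifest_rows = []
    true_kurt = np.empty(n_patients)
    for i in range(n_patients):
        pid = f"P{i:04d}"
        vac = vacuole_fraction_low if i < n_patients // 2 else vacuole_fraction_high
        band_vals = []
        for j in range(tiles_per_patient):
            spec = SceneSpec(
                vacuole_fraction=vac,
                seed=int(rng.integers(2**31)),
                **overrides,
            )
            scene = generate_scene(spec)
            tile = render_he(scene)
            path = tiles_dir / f"{pid}_t{j}.png"
            iio.imwrite(path, tile.pixels)
            # Whole synthetic scenes are tumor; say so via a mask so patch
            # selection cannot bias against vacuole-rich (OD-sparse) tiles.
            mask_path = tiles_dir / f"{pid}_t{j}_mask.tiff"
            tifffile.imwrite(
                mask_path,
                np.ones(scene.nuclei_labels.shape, dtype=np.uint8),
            )
            manifest_rows.append(
                {"patient_id": pid, "slide_id": pid, "path": str(path),
                 "mask_path": str(mask_path)}
            )
            band_vals.append(scene.true_concentrations[scene.cytoplasm_band, 0])
        true_kurt[i] = _kurtosis(np.concatenate(band_vals), fisher=True, bias=True)

    z = (true_kurt - true_kurt.mean()) / true_kurt.std()
    surv_spec = SurvivalSimSpec(
        n_patients=n_patients,
        beta=beta,
        baseline_hazard=baseline_hazard,
        censor_rate=censor_rate,
        covariate_model="continuous-standardized",
        seed=int(rng.integers(2**31)),
    )
    surv = simulate_survival(z, surv_spec)
    surv["age"] = rng.integers(40, 80, size=n_patients)
    surv["gender"] = rng.choice(["F", "M"], size=n_patients)
    surv["stage"] = rng.integers(1, 5, size=n_patients)

    manifest_path = out / "manifest.csv"
    survival_path = out / "survival.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, index=False)
    surv.to_csv(survival_path, index=False)
    return {
        "manifest": str(manifest_path),
        "survival": str(survival_path),
        "true_kurtosis": true_kurt,
        "covariate": z,
    }
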