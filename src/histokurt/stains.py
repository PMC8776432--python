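"""Stain separation: optical density, Macenko vectors, deconvolution, normalization.

Beer-Lambert with log base 10: for 8-bit intensity I and blank-field
intensity I0, the optical density is ``od = -log10(max(I, 1) / I0)`` per RGB
channel, and stain contributions add linearly in OD.  The Macenko estimator
finds the two extreme directions of the OD point cloud inside its leading
principal plane; deconvolution solves the per-pixel least-squares mixture
and clips negatives; normalization rescales each concentration channel so a
high percentile over tissue pixels hits a common target, making channels
comparable across slides.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .errors import DegenerateStainError, InsufficientTissueError, BlankChannelError
from .synthetic import RGBTile

__all__ = [
    "ODImage",
    "StainBasis",
    "ConcentrationPair",
    "NormalizationReference",
    "rgb_to_od",
    "od_to_rgb",
    "estimate_stain_vectors_macenko",
    "deconvolve",
    "tissue_mask",
    "fit_normalization",
    "fit_normalization_cohort",
    "apply_normalization",
]

MIN_TISSUE_PIXELS = 100
_COLLINEAR_DEG = 1.0


@dataclass(frozen=True)
class ODImage:
    od: np.ndarray  # (H, W, 3) nonnegative optical densities
    mpp: float


@dataclass(frozen=True)
class StainBasis:
    """Unit OD vectors for hematoxylin and eosin.

    ``h_vec`` is the vector with the larger blue-channel component
    (hematoxylin stains blue); vectors must not be collinear.
    """

    h_vec: np.ndarray
    e_vec: np.ndarray

    def __post_init__(self):
        for v in (self.h_vec, self.e_vec):
            if not np.isclose(np.linalg.norm(v), 1.0, atol=1e-6):
                raise ValueError("stain vectors must be unit-norm")
            if np.any(np.asarray(v) < -1e-9):
                raise ValueError("stain vector components must be nonnegative")
        ang = self.angle_between()
        if ang < _COLLINEAR_DEG:
            raise DegenerateStainError(
                f"stain vectors collinear ({ang:.3f} deg apart)"
            )

    def angle_between(self) -> float:
        c = float(np.clip(np.dot(self.h_vec, self.e_vec), -1.0, 1.0))
        return float(np.degrees(np.arccos(c)))

    @property
    def matrix(self) -> np.ndarray:
        """(2, 3) row-stacked [h; e] matrix."""
        return np.stack([self.h_vec, self.e_vec])


@dataclass(frozen=True)
class ConcentrationPair:
    c_h: np.ndarray  # (H, W) nonnegative hematoxylin concentration
    c_e: np.ndarray  # (H, W) nonnegative eosin concentration
    mpp: float
    normalized: bool = False


@dataclass(frozen=True)
class NormalizationReference:
    """Per-slide channel scales: percentile values mapped onto a target."""

    h_scale_percentile_value: float
    e_scale_percentile_value: float
    percentile: float = 99.0
    target: float = 1.0

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "NormalizationReference":
        return cls(**yaml.safe_load(Path(path).read_text()))


def rgb_to_od(tile: RGBTile, background_intensity: float = 255.0) -> ODImage:
    """Convert an 8-bit RGB tile to optical density (log10 convention).

    Intensities are floored at 1 so fully black pixels stay finite.
    """
    px = np.asarray(tile.pixels)
    if px.ndim != 3 or px.shape[-1] != 3:
        raise ValueError(f"expected (H, W, 3) RGB input, got shape {px.shape}")
    i = np.maximum(px.astype(np.float64), 1.0)
    od = -np.log10(i / background_intensity)
    return ODImage(od=np.maximum(od, 0.0), mpp=tile.mpp)


def od_to_rgb(od: ODImage, background_intensity: float = 255.0) -> RGBTile:
    arr = np.asarray(od.od, dtype=float)
    if np.any(arr < 0):
        raise ValueError("optical densities must be nonnegative")
    img = np.rint(background_intensity * np.power(10.0, -arr))
    return RGBTile(pixels=np.clip(img, 0, 255).astype(np.uint8), mpp=od.mpp)


def tissue_mask(od: ODImage, od_threshold: float = 0.15) -> np.ndarray:
    """Boolean mask of pixels whose OD Euclidean norm exceeds the threshold."""
    return np.linalg.norm(od.od, axis=-1) > od_threshold


def estimate_stain_vectors_macenko(
    od: ODImage,
    od_threshold: float = 0.15,
    angle_percentile: float = 1.0,
) -> StainBasis:
    """Macenko stain-vector estimation from the OD point cloud.

    Pixels with OD norm below ``od_threshold`` are discarded; the rest are
    projected onto the top-2 principal plane, and the directions at the
    ``angle_percentile``-th and (100 - angle_percentile)-th percentiles of
    the in-plane angle become the stain vectors.  Invariant to pixel order
    and to uniform pixel duplication (percentiles use the inverted-CDF
    convention; covariance is the biased estimator).
    """
    pts = od.od.reshape(-1, 3)
    pts = pts[np.linalg.norm(pts, axis=1) > od_threshold]
    if pts.shape[0] < MIN_TISSUE_PIXELS:
        raise InsufficientTissueError(
            f"only {pts.shape[0]} tissue pixels above OD {od_threshold} "
            f"(need >= {MIN_TISSUE_PIXELS})"
        )
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / pts.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    if evals[-2] < 1e-8 * max(evals[-1], 1e-30):
        raise DegenerateStainError(
            "OD cloud is effectively rank-1; cannot separate two stains"
        )
    plane = evecs[:, [-1, -2]]  # (3, 2), leading principal plane
    # Orient plane axes so projections of the (all-nonnegative) OD cloud
    # land consistently regardless of eigenvector sign.
    for j in range(2):
        if plane[:, j].sum() < 0:
            plane[:, j] = -plane[:, j]
    proj = pts @ plane
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo = np.percentile(phi, angle_percentile, method="inverted_cdf")
    hi = np.percentile(phi, 100.0 - angle_percentile, method="inverted_cdf")
    vecs = []
    for ang in (lo, hi):
        v = plane @ np.array([np.cos(ang), np.sin(ang)])
        if v.sum() < 0:
            v = -v
        v = np.clip(v, 0.0, None)
        n = np.linalg.norm(v)
        if n == 0:
            raise DegenerateStainError("degenerate extreme direction")
        vecs.append(v / n)
    # Hematoxylin has the larger blue (index 2) OD component.
    vecs.sort(key=lambda v: -v[2])
    return StainBasis(h_vec=vecs[0], e_vec=vecs[1])


def deconvolve(
    od: ODImage,
    basis: StainBasis,
    nonnegative_ls: bool = False,
) -> ConcentrationPair:
    """Unmix OD into (hematoxylin, eosin) concentrations.

    Default is the pseudoinverse least-squares solution clipped at zero;
    ``nonnegative_ls=True`` runs per-pixel NNLS instead (slow, for
    validation of near-background pixels).
    """
    m = basis.matrix  # (2, 3)
    if nonnegative_ls:
        from scipy.optimize import nnls

        flat = od.od.reshape(-1, 3)
        out = np.empty((flat.shape[0], 2))
        a = m.T
        for i, row in enumerate(flat):
            out[i], _ = nnls(a, row)
        conc = out.reshape(od.od.shape[:2] + (2,))
    else:
        pinv = np.linalg.pinv(m)  # (3, 2)
        conc = np.clip(od.od @ pinv, 0.0, None)
    return ConcentrationPair(
        c_h=conc[..., 0], c_e=conc[..., 1], mpp=od.mpp, normalized=False
    )


def fit_normalization(
    pair: ConcentrationPair,
    tissue: np.ndarray,
    percentile: float = 99.0,
    target: float = 1.0,
) -> NormalizationReference:
    """Measure one slide's per-channel percentile over tissue pixels."""
    if tissue.sum() == 0:
        raise BlankChannelError("no tissue pixels to fit normalization on")
    scales = []
    for name, chan in (("hematoxylin", pair.c_h), ("eosin", pair.c_e)):
        val = float(np.percentile(chan[tissue], percentile))
        if val <= 0:
            raise BlankChannelError(
                f"{name} channel percentile {percentile} is zero; blank channel"
            )
        scales.append(val)
    return NormalizationReference(
        h_scale_percentile_value=scales[0],
        e_scale_percentile_value=scales[1],
        percentile=percentile,
        target=target,
    )


def fit_normalization_cohort(
    pairs: list[ConcentrationPair],
    tissues: list[np.ndarray],
    percentile: float = 99.0,
    target: float = 1.0,
) -> list[NormalizationReference]:
    """Per-slide normalization references for a cohort of slides."""
    return [
        fit_normalization(p, t, percentile=percentile, target=target)
        for p, t in zip(pairs, tissues)
    ]


def apply_normalization(
    pair: ConcentrationPair, ref: NormalizationReference
) -> ConcentrationPair:
    """Scale channels so the slide's fitted percentile equals the target."""
    return ConcentrationPair(
        c_h=pair.c_h * (ref.target / ref.h_scale_percentile_value),
        c_e=pair.c_e * (ref.target / ref.e_scale_percentile_value),
        mpp=pair.mpp,
        normalized=True,
    )
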