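"""End-to-end pipeline: tiles -> concentrations -> cells -> survival reports.

Stage order mirrors the analysis this package implements: region selection,
per-slide stain-vector estimation (Macenko over pooled tumor-patch pixels),
color deconvolution, cross-slide intensity normalization, nuclei
segmentation, perinuclear expansion, feature extraction, patient-level
aggregation by medians, then the survival stage (univariate Cox screen,
maximally selected cutpoint on the configured feature, Kaplan-Meier +
log-rank, stepwise multivariate Cox with clinicopathologic covariates).

Every stage is deterministic, all outputs are plain CSV/YAML/JSON/TIFF, and
drop counts reconcile (cells detected = cells kept + cells dropped).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import segment as seg
from . import stains
from .errors import PipelineStageError, SurvivalModelError
from .segment import SegmentationParams
from .survival import fit_cox, km_curve, logrank_test, maxstat_cutpoint, stepwise_cox
from .synthetic import RGBTile

__all__ = [
    "PipelineConfig",
    "PatchDecision",
    "tile_image",
    "select_regions",
    "run_pipeline",
    "load_tile",
]

logger = logging.getLogger(__name__)

CLINICAL_COLUMNS = ("age", "gender", "stage")


@dataclass(frozen=True)
class PatchDecision:
    """One patch of the raster grid: 0-based half-open pixel coordinates."""

    patch_id: str
    x: int
    y: int
    width: int
    height: int
    keep: bool = True
    reason: str = ""


@dataclass
class StainConfig:
    background_intensity: float = 255.0
    od_threshold: float = 0.15
    angle_percentile: float = 1.0
    normalization_percentile: float = 99.0
    normalization_target: float = 1.0
    nonnegative_ls: bool = False


@dataclass
class FeatureConfig:
    expansion_um: float = 4.0
    n_bins: int = 32
    bin_range: tuple[float, float] = (0.0, 2.0)
    min_cells_per_patient: int = 100
    heatmap_quantile: float = 0.10
    heatmap_bandwidth_um: float = 50.0


@dataclass
class SurvivalConfig:
    cutpoint_feature: str = "kurtosis_hC"
    minprop: float = 0.1
    screen_alpha: float = 0.05
    # stepwise starts from a full model; cap its size so small cohorts with
    # many univariately significant (collinear) features stay fittable
    max_stepwise_candidates: int = 10


@dataclass
class TissueFilterConfig:
    min_tissue_fraction: float = 0.5
    min_mask_coverage: float = 0.5


@dataclass
class PipelineConfig:
    """All pipeline parameters; every field has a default.

    The effective config is echoed verbatim into the output directory.
    """

    tiles_manifest: str = "manifest.csv"
    survival_table: str = "survival.csv"
    output_dir: str = "histokurt_out"
    mpp: float = 0.5
    patch_size_px: int = 512
    stride_px: int | None = None  # None -> patch_size_px (non-overlapping)
    stain: StainConfig = field(default_factory=StainConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    tissue_filter: TissueFilterConfig = field(default_factory=TissueFilterConfig)
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        for key, sub in (
            ("stain", StainConfig), ("segmentation", SegmentationParams),
            ("features", FeatureConfig), ("survival", SurvivalConfig),
            ("tissue_filter", TissueFilterConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                block = kwargs[key]
                if key == "features" and "bin_range" in block:
                    block["bin_range"] = tuple(block["bin_range"])
                kwargs[key] = sub(**block)
        return cls(**kwargs)


def load_tile(path: str | Path, mpp: float) -> RGBTile:
    """Read a PNG/TIFF RGB tile from disk."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3 and arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"{path}: expected an RGB image, got shape {arr.shape}")
    return RGBTile(pixels=arr.astype(np.uint8), mpp=mpp)


def tile_image(
    shape: tuple[int, int],
    patch_size_px: int,
    stride_px: int | None = None,
    id_prefix: str = "patch",
) -> list[PatchDecision]:
    """Raster-order patch grid over an image; partial edge patches dropped."""
    if patch_size_px < 64:
        raise ValueError("patch_size_px must be >= 64")
    stride = stride_px if stride_px is not None else patch_size_px
    if stride <= 0:
        raise ValueError("stride_px must be positive")
    h, w = shape[:2]
    if h < patch_size_px or w < patch_size_px:
        raise ValueError(
            f"image {h}x{w} smaller than one {patch_size_px}px patch"
        )
    out = []
    idx = 0
    for y in range(0, h - patch_size_px + 1, stride):
        for x in range(0, w - patch_size_px + 1, stride):
            out.append(
                PatchDecision(
                    patch_id=f"{id_prefix}_{idx:04d}",
                    x=x, y=y, width=patch_size_px, height=patch_size_px,
                )
            )
            idx += 1
    return out


def select_regions(
    tile: RGBTile,
    patches: list[PatchDecision],
    tumor_mask: np.ndarray | None = None,
    tissue_params: TissueFilterConfig = TissueFilterConfig(),
    od_threshold: float = 0.15,
    background_intensity: float = 255.0,
    external_verdicts: pd.DataFrame | None = None,
) -> list[PatchDecision]:
    """Keep tumor/tissue patches; record a reason for every decision.

    Priority: external classifier verdicts (CSV hook with columns
    patch_id, keep) > user tumor mask coverage > tissue-fraction heuristic
    (fraction of pixels with OD norm above threshold).
    """
    if tumor_mask is not None and tumor_mask.shape[:2] != tile.pixels.shape[:2]:
        raise ValueError(
            f"tumor mask shape {tumor_mask.shape[:2]} misaligned with "
            f"tile {tile.pixels.shape[:2]}"
        )
    verdicts = None
    if external_verdicts is not None:
        verdicts = dict(
            zip(external_verdicts["patch_id"], external_verdicts["keep"])
        )
    od = stains.rgb_to_od(tile, background_intensity)
    tissue = stains.tissue_mask(od, od_threshold)
    out = []
    for p in patches:
        sl = (slice(p.y, p.y + p.height), slice(p.x, p.x + p.width))
        if verdicts is not None and p.patch_id in verdicts:
            keep = bool(verdicts[p.patch_id])
            reason = "external" if keep else "rejected_external"
        elif tumor_mask is not None:
            cov = float(np.asarray(tumor_mask[sl], dtype=bool).mean())
            keep = cov >= tissue_params.min_mask_coverage
            reason = "tumor_mask" if keep else "rejected_masked"
        else:
            frac = float(tissue[sl].mean())
            keep = frac >= tissue_params.min_tissue_fraction
            reason = "tissue_heuristic" if keep else "rejected_background"
        out.append(dataclasses.replace(p, keep=keep, reason=reason))
    return out


def _encode_clinical(table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Numeric-encode age/gender/stage where present.

    Gender becomes a 0/1 indicator (alphabetical first level = 0); stage is
    coerced to ordered numeric 1-4 when given as I-IV strings.
    """
    table = table.copy()
    used = []
    roman = {"I": 1, "II": 2, "III": 3, "IV": 4}
    for col in CLINICAL_COLUMNS:
        if col not in table.columns:
            continue
        if col == "gender" and not pd.api.types.is_numeric_dtype(table[col]):
            levels = sorted(table[col].astype(str).unique())
            table[col] = table[col].astype(str).map(
                {lv: i for i, lv in enumerate(levels)}
            )
        elif col == "stage" and not pd.api.types.is_numeric_dtype(table[col]):
            table[col] = (
                table[col].astype(str).str.upper().str.replace("STAGE ", "")
                .map(roman)
            )
        table[col] = pd.to_numeric(table[col], errors="coerce")
        if table[col].notna().all() and table[col].nunique() > 1:
            used.append(col)
    return table, used


def _percentile_reference(
    values_h: np.ndarray, values_e: np.ndarray, cfg: StainConfig
) -> stains.NormalizationReference:
    ph = float(np.percentile(values_h, cfg.normalization_percentile))
    pe = float(np.percentile(values_e, cfg.normalization_percentile))
    if ph <= 0 or pe <= 0:
        raise PipelineStageError("normalize", "blank concentration channel")
    return stains.NormalizationReference(
        h_scale_percentile_value=ph,
        e_scale_percentile_value=pe,
        percentile=cfg.normalization_percentile,
        target=cfg.normalization_target,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; return a dict of output paths.

    Inputs: a tiles manifest CSV (patient_id, slide_id, path[, mask_path])
    and a survival CSV (patient_id, time, event[, age, gender, stage]).
    Rerunning with the same config and inputs is bit-identical.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("histokurt")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    paths: dict[str, str] = {"log": str(log_path)}
    try:
        config.to_yaml(out_dir / "config.yaml")
        paths["config"] = str(out_dir / "config.yaml")

        t0 = _time.perf_counter()
        manifest = pd.read_csv(config.tiles_manifest, dtype=str)
        for col in ("patient_id", "slide_id", "path"):
            if col not in manifest.columns:
                raise PipelineStageError("ingest", f"manifest missing column {col!r}")
        manifest = manifest.sort_values(
            ["patient_id", "slide_id", "path"]
        ).reset_index(drop=True)

        cell_frames: list[pd.DataFrame] = []
        drop_frames: list[pd.DataFrame] = []
        decisions_rows: list[dict] = []
        import tifffile

        for slide_id, slide_rows in manifest.groupby("slide_id", sort=True):
            # --- region selection + pooled OD for per-slide stain vectors
            kept: list[tuple[str, RGBTile, PatchDecision]] = []
            od_pool: list[np.ndarray] = []
            for _, row in slide_rows.iterrows():
                tile = load_tile(row["path"], config.mpp)
                mask = None
                if "mask_path" in row and isinstance(row.get("mask_path"), str) and row["mask_path"]:
                    mask = np.asarray(tifffile.imread(row["mask_path"])) > 0
                grid = tile_image(
                    tile.pixels.shape[:2], config.patch_size_px,
                    config.stride_px, id_prefix=Path(row["path"]).stem,
                )
                decided = select_regions(
                    tile, grid, tumor_mask=mask,
                    tissue_params=config.tissue_filter,
                    od_threshold=config.stain.od_threshold,
                    background_intensity=config.stain.background_intensity,
                )
                for p in decided:
                    decisions_rows.append(
                        {"slide_id": slide_id, "tile": row["path"],
                         **dataclasses.asdict(p)}
                    )
                    if not p.keep:
                        continue
                    sub = RGBTile(
                        pixels=tile.pixels[p.y:p.y + p.height, p.x:p.x + p.width],
                        mpp=config.mpp,
                    )
                    kept.append((row["patient_id"], sub, p))
                    od = stains.rgb_to_od(sub, config.stain.background_intensity)
                    pts = od.od.reshape(-1, 3)
                    od_pool.append(
                        pts[np.linalg.norm(pts, axis=1) > config.stain.od_threshold]
                    )
            if not kept:
                logger.warning("slide %s: no patches kept", slide_id)
                continue

            pooled = np.concatenate(od_pool, axis=0)
            basis = stains.estimate_stain_vectors_macenko(
                stains.ODImage(od=pooled.reshape(-1, 1, 3), mpp=config.mpp),
                od_threshold=config.stain.od_threshold,
                angle_percentile=config.stain.angle_percentile,
            )

            # --- deconvolve all kept patches, then per-slide normalization
            pairs = []
            tissue_h, tissue_e = [], []
            for patient_id, sub, p in kept:
                od = stains.rgb_to_od(sub, config.stain.background_intensity)
                pair = stains.deconvolve(
                    od, basis, nonnegative_ls=config.stain.nonnegative_ls
                )
                tis = stains.tissue_mask(od, config.stain.od_threshold)
                pairs.append((patient_id, pair, tis, p))
                tissue_h.append(pair.c_h[tis])
                tissue_e.append(pair.c_e[tis])
            ref = _percentile_reference(
                np.concatenate(tissue_h), np.concatenate(tissue_e), config.stain
            )
            ref.save(out_dir / f"normalization_{slide_id}.yaml")

            # --- segmentation + features per patch
            slide_cells: list[feat.CellRecord] = []
            shape_px = None
            for patient_id, pair, _tis, p in pairs:
                norm_pair = stains.apply_normalization(pair, ref)
                nuclei = seg.segment_nuclei(
                    norm_pair.c_h, config.mpp, config.segmentation
                )
                cyto = seg.expand_perinuclear(nuclei, config.features.expansion_um)
                cells, drops = feat.extract_cell_features(
                    norm_pair, nuclei, cyto,
                    patient_id=patient_id, slide_id=str(slide_id),
                    patch_id=p.patch_id,
                    n_bins=config.features.n_bins,
                    bin_range=config.features.bin_range,
                )
                # shift centroids to slide coordinates for the heatmap
                shifted = [
                    dataclasses.replace(
                        c, centroid=(c.centroid[0] + p.y, c.centroid[1] + p.x)
                    )
                    for c in cells
                ]
                slide_cells.extend(shifted)
                if shifted:
                    cell_frames.append(feat.cells_to_frame(shifted))
                if not drops.empty:
                    drops = drops.assign(slide_id=slide_id, patch_id=p.patch_id)
                    drop_frames.append(drops)
                shape_px = (
                    max(shape_px[0] if shape_px else 0, p.y + p.height),
                    max(shape_px[1] if shape_px else 0, p.x + p.width),
                )

            if len(slide_cells) >= 10:
                d_all, d_low, thr = feat.kurtosis_density_heatmap(
                    slide_cells, config.mpp, shape_px,
                    quantile=config.features.heatmap_quantile,
                    bandwidth_um=config.features.heatmap_bandwidth_um,
                )
                tifffile.imwrite(
                    out_dir / f"heatmap_all_{slide_id}.tiff",
                    d_all.astype(np.float32),
                )
                tifffile.imwrite(
                    out_dir / f"heatmap_lowkurt_{slide_id}.tiff",
                    d_low.astype(np.float32),
                )
                from matplotlib.image import imsave

                imsave(out_dir / f"heatmap_all_{slide_id}.png", d_all,
                       cmap="magma")
                imsave(out_dir / f"heatmap_lowkurt_{slide_id}.png", d_low,
                       cmap="magma")
            logger.info("slide %s done (%.1fs)", slide_id, _time.perf_counter() - t0)

        pd.DataFrame(decisions_rows).to_csv(out_dir / "patch_decisions.csv", index=False)
        paths["patch_decisions"] = str(out_dir / "patch_decisions.csv")
        if not cell_frames:
            raise PipelineStageError("features", "no cells extracted from any slide")
        cells_df = pd.concat(cell_frames, ignore_index=True)
        cells_df.to_csv(out_dir / "cells.csv", index=False)
        paths["cells"] = str(out_dir / "cells.csv")
        drops_df = (
            pd.concat(drop_frames, ignore_index=True)
            if drop_frames
            else pd.DataFrame(columns=["cell_label", "reason", "slide_id", "patch_id"])
        )
        drops_df.to_csv(out_dir / "drop_log.csv", index=False)
        paths["drop_log"] = str(out_dir / "drop_log.csv")

        patients_df = feat.aggregate_patients(
            cells_df, min_cells=config.features.min_cells_per_patient
        )
        patients_df.to_csv(out_dir / "patients.csv", index=False)
        paths["patients"] = str(out_dir / "patients.csv")
    except Exception:
        root.removeHandler(handler)
        handler.close()
        raise
    root.removeHandler(handler)
    handler.close()

    paths.update(_survival_stage(config, patients_df, out_dir))
    return paths


def _survival_stage(
    config: PipelineConfig, patients_df: pd.DataFrame, out_dir: Path
) -> dict:
    """Univariate screen, cutpoint + KM + log-rank, stepwise multivariate."""
    surv = pd.read_csv(config.survival_table)
    if surv.empty:
        raise PipelineStageError("survival", "empty survival table")
    surv["patient_id"] = surv["patient_id"].astype(str)
    merged = patients_df.merge(surv, on="patient_id", how="inner")
    if merged.empty:
        raise PipelineStageError(
            "survival", "no patients shared between feature table and survival table"
        )
    merged, clinical = _encode_clinical(merged)
    paths: dict[str, str] = {}

    # Cox fits (screen + stepwise) run on cohort-standardized features:
    # identical p-values, but scale-free coefficients keep Newton stable for
    # features whose raw variance is tiny.  Cutpoint/KM use raw values.
    screened = [
        c for c in feat.feature_columns()
        if c in merged.columns and merged[c].nunique() > 1
    ]
    z_table = merged.copy()
    for c in screened:
        z_table[c] = (merged[c] - merged[c].mean()) / merged[c].std()

    rows = []
    significant = []
    import warnings as _warnings

    from lifelines.exceptions import ConvergenceWarning as _CW

    for col in screened:
        try:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", _CW)
                fit = fit_cox(z_table, [col])
        except SurvivalModelError as exc:
            logger.warning("univariate Cox failed for %s: %s", col, exc)
            continue
        r = fit.summary.loc[col]
        rows.append(
            {"feature": col, "coef": r["coef"], "hazard_ratio": r["hazard_ratio"],
             "ci_lo": r["ci_lo"], "ci_hi": r["ci_hi"], "p": r["p"]}
        )
        if r["p"] < config.survival.screen_alpha:
            significant.append((float(r["p"]), col))
    uni = pd.DataFrame(rows)
    uni.to_csv(out_dir / "univariate_cox.csv", index=False)
    paths["univariate"] = str(out_dir / "univariate_cox.csv")

    feature = config.survival.cutpoint_feature
    if feature not in merged.columns:
        raise PipelineStageError("survival", f"cutpoint feature {feature!r} missing")
    cut = maxstat_cutpoint(merged, feature, minprop=config.survival.minprop)
    merged["group"] = np.where(
        merged[feature] > cut.cutpoint, "high", "low"
    )
    chi2, logrank_p = logrank_test(merged, "group")
    group_fit = fit_cox(
        merged.assign(high=(merged["group"] == "high").astype(float)), ["high"]
    )
    hr_high = float(group_fit.summary.loc["high", "hazard_ratio"])
    report = {
        "feature": feature,
        "cutpoint": cut.cutpoint,
        "max_statistic": cut.max_statistic,
        "adjusted_p": cut.adjusted_p,
        "minprop": cut.minprop,
        "logrank_chi2": chi2,
        "logrank_p": logrank_p,
        "hazard_ratio_high_vs_low": hr_high,
        "n_high": int((merged["group"] == "high").sum()),
        "n_low": int((merged["group"] == "low").sum()),
    }
    (out_dir / "cutpoint.json").write_text(json.dumps(report, indent=2))
    paths["cutpoint"] = str(out_dir / "cutpoint.json")

    km = km_curve(merged, "group")
    km_rows = []
    for g, curve in km.items():
        for t, s, r in zip(curve.times, curve.survival, curve.at_risk):
            km_rows.append({"group": g, "time": t, "survival": s, "at_risk": r})
    pd.DataFrame(km_rows).to_csv(out_dir / "km_coordinates.csv", index=False)
    paths["km"] = str(out_dir / "km_coordinates.csv")

    top_features = [c for _, c in sorted(significant)]
    cap = config.survival.max_stepwise_candidates
    while top_features or clinical:
        candidates = top_features[:cap] + clinical
        if not candidates:
            break
        try:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", _CW)
                final, trace = stepwise_cox(z_table, candidates)
            trace.to_csv(out_dir / "stepwise_trace.csv", index=False)
            final.summary.to_csv(out_dir / "stepwise_final_model.csv")
            paths["stepwise_trace"] = str(out_dir / "stepwise_trace.csv")
            paths["stepwise_final"] = str(out_dir / "stepwise_final_model.csv")
            break
        except SurvivalModelError as exc:
            logger.warning(
                "stepwise Cox with %d candidates failed (%s); retrying smaller",
                len(candidates), exc,
            )
            if cap > 1:
                cap -= 2
            elif top_features:
                top_features = []
            else:
                logger.warning("stepwise Cox skipped entirely")
                break
    return paths
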