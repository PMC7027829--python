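"""End-to-end workflow: preprocess → PCA features → community partition.

:func:`run_pipeline` chains the standard steps on a reflectance cube and
writes the result tables and maps to an output directory:

* ``summary.csv`` — SS_γ/β/α, β and α percentage shares, SD_γ, SD_β, SD̄_α
* ``fcsd.csv`` — per-feature contributions to γ and β
* ``fcsd_alpha.csv`` — feature × community contributions to α
* ``lcsd_beta.csv`` / ``lcsd_beta.tif`` — per-community contribution to β
* ``sd_alpha.csv`` / ``sd_alpha.tif`` — per-community α-diversity
* ``lcsd_gamma.tif`` — per-pixel contribution to γ
* ``config.yaml`` — the exact configuration used, for provenance
* ``run.log`` — per-stage pixel counts and settings

Rarefaction is engaged automatically when masking leaves unequal valid-pixel
counts across plots. Everything is deterministic given the config + seed.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import preprocess as pp
from .cube import SpectralCube
from .errors import SpecvarError, ValidationError
from .features import FeatureMatrix, pca_features
from .io import read_envi, read_tiff_cube, write_tiff
from .partition import (
    SpectralPartition,
    make_community_grid,
    partition_all,
    rarefied_partition,
    scaled_diversity_summary,
)

logger = logging.getLogger("specvar")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    input_path: Optional[str] = None  # .hdr (ENVI) or .tif; None = in-memory
    output_dir: str = "specvar_out"
    plot_size_px: int = 40
    # preprocessing
    drop_windows: Sequence[Tuple[float, float]] = pp.DEFAULT_DROP_WINDOWS
    keep_range: Tuple[float, float] = pp.DEFAULT_KEEP_RANGE
    sg_order: int = pp.DEFAULT_SG_ORDER
    sg_window: int = pp.DEFAULT_SG_WINDOW
    ndvi_threshold: float = pp.DEFAULT_NDVI_THRESHOLD
    red_wl: float = pp.DEFAULT_RED_WL
    nir_wl: float = pp.DEFAULT_NIR_WL
    shade_mask_enabled: bool = False
    shade_mask_quantile: float = 0.2
    # features
    n_components: Optional[int] = None
    variance_target: Optional[float] = None
    # partition / rarefaction
    rarefaction_repeats: int = 30
    rarefaction_aggregation: str = "mean"
    min_fraction: Optional[float] = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        # normalize sequences (YAML round-trips lists) to tuples
        self.drop_windows = tuple(tuple(w) for w in self.drop_windows)
        self.keep_range = tuple(self.keep_range)

    def validate(self) -> None:
        if self.plot_size_px < 1:
            raise ValidationError("plot_size_px must be >= 1")
        if self.n_components is not None and self.variance_target is not None:
            raise ValidationError(
                "n_components and variance_target are mutually exclusive"
            )
        if self.rarefaction_aggregation not in ("mean", "median"):
            raise ValidationError("aggregation must be 'mean' or 'median'")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: Union[str, Path]) -> None:
        d = asdict(self)
        d["drop_windows"] = [list(w) for w in self.drop_windows]
        d["keep_range"] = list(self.keep_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


@dataclass
class PipelineResult:
    """Bundle returned by :func:`run_pipeline`."""

    partition: SpectralPartition
    features: FeatureMatrix
    cube: SpectralCube
    output_dir: Path
    rarefied: bool
    m_min: Optional[int] = None


def _load_cube(config: RunConfig) -> SpectralCube:
    path = Path(config.input_path)
    if path.suffix.lower() == ".hdr":
        return read_envi(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return read_tiff_cube(path)
    raise ValidationError(f"unrecognized cube format: {path}")


def _write_float_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def run_pipeline(
    config: RunConfig, cube: Optional[SpectralCube] = None
) -> PipelineResult:
    """Execute the full workflow and write tables/maps to the output dir.

    ``cube`` may be supplied in-memory; otherwise ``config.input_path`` is
    read. Partial outputs are removed if any stage fails.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    log_lines: List[str] = []

    def log(stage: str, msg: str) -> None:
        line = f"[{stage}] {msg}"
        logger.info(line)
        log_lines.append(line)

    try:
        stage = "load"
        if cube is None:
            cube = _load_cube(config)
        log(stage, f"cube {cube.spatial_shape} x {cube.n_bands} bands, "
                   f"{cube.n_valid} valid pixels")

        stage = "preprocess"
        cube = pp.trim_bands(cube, config.drop_windows, config.keep_range)
        log(stage, f"bands after trim: {cube.n_bands}")
        cube = pp.savgol_smooth(cube, config.sg_order, config.sg_window)
        ndvi_map = pp.ndvi(cube, config.red_wl, config.nir_wl)
        cube = pp.mask_vegetation(cube, ndvi_map, config.ndvi_threshold)
        log(stage, f"valid after NDVI >= {config.ndvi_threshold}: {cube.n_valid}")
        if config.shade_mask_enabled:
            cube = pp.shade_mask(cube, config.nir_wl, config.shade_mask_quantile)
            log(stage, f"valid after shade mask: {cube.n_valid}")
        cube = pp.brightness_normalize(cube)

        stage = "features"
        bands = FeatureMatrix.from_cube(cube)
        scores, model = pca_features(
            bands,
            n_components=config.n_components,
            variance_target=config.variance_target,
        )
        log(stage, f"PCA: kept {scores.p} of {model.n_components} components "
                   f"({model.relative_eigenvalues[:scores.p].sum():.4f} of variance)")

        stage = "partition"
        grid, kept, counts = make_community_grid(
            scores.pixel_index, config.plot_size_px, cube.spatial_shape
        )
        dropped = int((~kept).sum())
        if dropped:
            log(stage, f"discarded {dropped} pixels outside complete "
                       f"{config.plot_size_px}x{config.plot_size_px} plots")
        nonempty = counts[counts > 0]
        log(stage, f"{grid.q} plots; valid pixels per plot min={nonempty.min()} "
                   f"max={nonempty.max()}")
        Y = FeatureMatrix(
            values=scores.values[kept],
            feature_labels=scores.feature_labels,
            pixel_index=scores.pixel_index[kept],
        )
        rarefied = False
        m_min = None
        lcsd_gamma_map = np.full(cube.spatial_shape, np.nan)
        if grid.is_balanced:
            part = partition_all(Y, grid)
            if part.lcsd_gamma_i is not None:
                lcsd_gamma_map[Y.pixel_index[:, 0], Y.pixel_index[:, 1]] = (
                    part.lcsd_gamma_i
                )
            log(stage, f"equal plot sizes (m={part.m}); exact partition")
        else:
            rarefied = True
            res = rarefied_partition(
                Y, grid.assignment,
                repeats=config.rarefaction_repeats,
                seed=config.seed,
                aggregation=config.rarefaction_aggregation,
                min_fraction=config.min_fraction,
            )
            part = res.aggregate
            m_min = res.m_min
            lcsd_gamma_map[Y.pixel_index[:, 0], Y.pixel_index[:, 1]] = (
                res.lcsd_gamma_full
            )
            log(stage, f"unequal plot sizes; rarefied to m_min={m_min}, "
                       f"{res.repeats} repeats, {res.aggregation} aggregate")

        stage = "write"
        _write_outputs(part, Y, grid, cube, config, out, lcsd_gamma_map)
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        config.to_yaml(out / "config.yaml")
        return PipelineResult(
            partition=part, features=Y, cube=cube, output_dir=out,
            rarefied=rarefied, m_min=m_min,
        )
    except SpecvarError as exc:
        for f in out.glob("*"):
            if f.is_file():
                f.unlink()
        raise SpecvarError(f"stage {stage!r} failed: {exc}") from exc


def _plot_shape(grid, image_shape) -> Tuple[int, int]:
    size = grid.plot_size_px
    return (image_shape[0] // size, image_shape[1] // size)


def _write_outputs(
    part: SpectralPartition,
    Y: FeatureMatrix,
    grid,
    cube: SpectralCube,
    config: RunConfig,
    out: Path,
    lcsd_gamma_map: np.ndarray,
) -> None:
    summary = scaled_diversity_summary(
        part.ss_gamma, part.ss_beta, part.ss_alpha, part.n, part.q, part.m
    )
    _write_float_csv(
        pd.DataFrame(
            [{
                "ss_gamma": part.ss_gamma,
                "ss_beta": part.ss_beta,
                "ss_alpha": part.ss_alpha,
                "beta_pct_of_ss_gamma": summary["beta_pct"],
                "alpha_pct_of_ss_gamma": summary["alpha_pct"],
                "sd_gamma": part.sd_gamma,
                "sd_beta": part.sd_beta,
                "sd_alpha_mean": part.sd_alpha_mean,
                "n": part.n, "p": part.p, "q": part.q, "m": part.m,
            }]
        ),
        out / "summary.csv",
    )
    nanarr = lambda a, size: np.full(size, np.nan) if a is None else a
    _write_float_csv(
        pd.DataFrame({
            "feature": Y.feature_labels,
            "fcsd_gamma": nanarr(part.fcsd_gamma_j, part.p),
            "fcsd_beta": nanarr(part.fcsd_beta_j, part.p),
        }),
        out / "fcsd.csv",
    )
    fa = nanarr(part.fcsd_alpha_jk, (part.q, part.p))
    _write_float_csv(
        pd.DataFrame(fa, columns=Y.feature_labels).assign(
            community=np.arange(part.q)
        )[["community", *Y.feature_labels]],
        out / "fcsd_alpha.csv",
    )
    _write_float_csv(
        pd.DataFrame({
            "community": np.arange(part.q),
            "lcsd_beta": nanarr(part.lcsd_beta_k, part.q),
        }),
        out / "lcsd_beta.csv",
    )
    _write_float_csv(
        pd.DataFrame({
            "community": np.arange(part.q),
            "sd_alpha": part.sd_alpha_k,
        }),
        out / "sd_alpha.csv",
    )
    # plot-level maps (one value per plot polygon) and the per-pixel gamma map
    qr, qc = _plot_shape(grid, cube.spatial_shape)
    if qr * qc == part.q:
        write_tiff(
            nanarr(part.lcsd_beta_k, part.q).reshape(qr, qc),
            out / "lcsd_beta.tif",
        )
        write_tiff(part.sd_alpha_k.reshape(qr, qc), out / "sd_alpha.tif")
    write_tiff(lcsd_gamma_map, out / "lcsd_gamma.tif")
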