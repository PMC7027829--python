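"""Additive partitioning of spectral variance into γ, β and α components.

Spectral γ-diversity of a region is the total variance of the pixel ×
spectral-feature matrix **Y**:

    SD_γ = Var(Y) = SS_γ / (n − 1),   SS_γ = Σ_i Σ_j (y_ij − ȳ_j)²

With pixels grouped into q communities of m pixels each (n = q·m), the
classical ANOVA identity splits the total sum of squares into an
among-community (β) and a within-community (α) part:

    SS_γ = SS_β + SS_α
    SS_β = Σ_k Σ_j m (ŷ_kj − ȳ_j)²        (community centroids vs. grand mean)
    SS_α = Σ_k Σ_i Σ_j (y_ijk − ŷ_kj)²    (pixels vs. their community centroid)

from which the diversities are SD_β = SS_β/(n−1) and, per community,
SD_α,k = SS_α,k/(m−1). Contribution indices are shares of the corresponding
sum of squares: a pixel's local contribution LCSD_γ,i = SS_γ,i/SS_γ, a
community's LCSD_β,k = SS_β,k/SS_β, and a feature's FCSD_γ,j = SS_γ,j/SS_γ
(analogously for β and per-community α). Each family of shares sums to 1.

The exact decomposition assumes equal m across communities; when valid-pixel
counts differ (masking leaves holes in real imagery), the rarefaction wrapper
repeatedly subsamples m_min pixels per community and aggregates.

Deviations are computed against explicitly materialized column means
(two-pass), never via E[x²]−E[x]² shortcuts, which keeps the additivity
identity stable in floating point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import (
    InternalConsistencyError,
    NoValidPixelsError,
    ParameterError,
    ValidationError,
)
from .features import FeatureMatrix

#: Relative tolerance for the SS_γ = SS_β + SS_α identity check.
ADDITIVITY_RTOL = 1e-9


# ---------------------------------------------------------------------------
# community grid
# ---------------------------------------------------------------------------

@dataclass
class CommunityGrid:
    """Assignment of pixels (rows of Y) to communities.

    ``assignment`` holds a community label in 0..q−1 for every row of the
    feature matrix it accompanies. ``m`` is the common community size when
    all communities are equal-sized (required for the exact partition),
    otherwise None — use :func:`rarefied_partition` then.
    """

    assignment: np.ndarray
    q: int
    m: Optional[int] = None
    plot_size_px: Optional[int] = None
    origin: Tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.assignment.ndim != 1:
            raise ValidationError("assignment must be 1-D (one label per pixel)")
        if self.q < 1:
            raise ValidationError("q must be >= 1")
        if self.assignment.size and (
            self.assignment.min() < 0 or self.assignment.max() >= self.q
        ):
            raise ValidationError("community labels must lie in 0..q-1")

    @property
    def n(self) -> int:
        return self.assignment.size

    def counts(self) -> np.ndarray:
        """Pixels per community, length q."""
        return np.bincount(self.assignment, minlength=self.q)

    @property
    def is_balanced(self) -> bool:
        c = self.counts()
        return bool(c.size and (c == c[0]).all())


def make_community_grid(
    valid_pixels: np.ndarray,
    plot_size_px: int,
    image_shape: Tuple[int, int],
    origin: Tuple[int, int] = (0, 0),
) -> Tuple[CommunityGrid, np.ndarray, np.ndarray]:
    """Tile an image into square plots and assign valid pixels to them.

    Plots are non-overlapping ``plot_size_px`` × ``plot_size_px`` squares,
    numbered row-major from ``origin`` (top-left, 0-based); each plot covers
    the half-open pixel range [r, r+plot) × [c, c+plot). Plots not fully
    inside the image are discarded, and pixels falling outside any complete
    plot are dropped.

    Parameters
    ----------
    valid_pixels
        (n, 2) array of (row, col) coordinates of usable pixels.
    plot_size_px
        Side length of the square community, in pixels.
    image_shape
        (rows, cols) of the source image.

    Returns
    -------
    grid
        CommunityGrid over the retained pixels.
    kept
        Boolean array over the input pixels: True where the pixel fell in a
        complete plot (use it to subset the feature matrix rows).
    counts
        Valid pixels per community, length q.
    """
    if plot_size_px < 1:
        raise ParameterError(f"plot_size_px must be >= 1; got {plot_size_px}")
    rows, cols = image_shape
    r0, c0 = origin
    q_rows = (rows - r0) // plot_size_px
    q_cols = (cols - c0) // plot_size_px
    if q_rows < 1 or q_cols < 1:
        raise ValidationError(
            f"image {image_shape} holds no complete {plot_size_px}x"
            f"{plot_size_px} plot from origin {origin}"
        )
    q = q_rows * q_cols
    valid_pixels = np.asarray(valid_pixels, dtype=int)
    pr = (valid_pixels[:, 0] - r0) // plot_size_px
    pc = (valid_pixels[:, 1] - c0) // plot_size_px
    kept = (
        (valid_pixels[:, 0] >= r0)
        & (valid_pixels[:, 1] >= c0)
        & (pr < q_rows)
        & (pc < q_cols)
    )
    labels = (pr[kept] * q_cols + pc[kept]).astype(int)
    counts = np.bincount(labels, minlength=q)
    m = int(counts[0]) if counts.size and (counts == counts[0]).all() else None
    grid = CommunityGrid(
        assignment=labels, q=q, m=m, plot_size_px=plot_size_px, origin=origin
    )
    return grid, kept, counts


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class CommunityCentroids:
    """Per-community feature means ŷ_kj, a (q, p) matrix."""

    means: np.ndarray


@dataclass
class SpectralPartition:
    """Complete γ/β/α variance partition of one pixel × feature matrix.

    Contribution indices whose denominator sum of squares is zero are
    undefined and stored as None (scalars per community appear as NaN in the
    per-community arrays).
    """

    n: int
    p: int
    q: int
    m: int
    ss_gamma: float
    sd_gamma: float
    ss_beta: float
    sd_beta: float
    ss_alpha: float
    ss_beta_k: np.ndarray  # (q,)
    ss_alpha_k: np.ndarray  # (q,)
    sd_alpha_k: np.ndarray  # (q,)
    sd_alpha_mean: float
    lcsd_gamma_i: Optional[np.ndarray]  # (n,) or None if SS_γ = 0
    lcsd_beta_k: Optional[np.ndarray]  # (q,) or None if SS_β = 0
    fcsd_gamma_j: Optional[np.ndarray]  # (p,)
    fcsd_beta_j: Optional[np.ndarray]  # (p,)
    fcsd_alpha_jk: Optional[np.ndarray]  # (q, p); NaN rows where SS_α,k = 0
    centroids: Optional[CommunityCentroids] = None

    @property
    def beta_fraction(self) -> float:
        """SS_β as a fraction of SS_γ."""
        return self.ss_beta / self.ss_gamma if self.ss_gamma > 0 else np.nan

    @property
    def alpha_fraction(self) -> float:
        """SS_α as a fraction of SS_γ."""
        return self.ss_alpha / self.ss_gamma if self.ss_gamma > 0 else np.nan


# ---------------------------------------------------------------------------
# the three partitions
# ---------------------------------------------------------------------------

def _values(Y: Union[FeatureMatrix, np.ndarray]) -> np.ndarray:
    v = Y.values if isinstance(Y, FeatureMatrix) else np.asarray(Y, dtype=float)
    if v.ndim != 2:
        raise ValidationError("Y must be 2-D (n pixels x p features)")
    return v


def gamma_partition(Y: Union[FeatureMatrix, np.ndarray]):
    """Total (γ) spectral variation of the region.

    Returns ``(ss_gamma, sd_gamma, lcsd_gamma_i, fcsd_gamma_j, ss_gamma_j,
    ss_gamma_i)``. If SS_γ = 0 (all pixels identical) the SS/SD are 0 and the
    contribution indices are None.
    """
    v = _values(Y)
    n, p = v.shape
    if n < 2:
        raise ValidationError(f"gamma_partition needs n >= 2 pixels; got {n}")
    # exactly-rounded column sums (math.fsum) make the totals invariant
    # under any permutation of the pixels, as the math says they must be
    col_means = np.array([math.fsum(v[:, j]) for j in range(p)]) / n
    dev2 = (v - col_means) ** 2  # s_ij
    ss_gamma_j = np.array([math.fsum(dev2[:, j]) for j in range(p)])
    ss_gamma_i = dev2.sum(axis=1)
    ss_gamma = math.fsum(ss_gamma_j)
    sd_gamma = ss_gamma / (n - 1)
    if ss_gamma > 0:
        fcsd = ss_gamma_j / ss_gamma
        lcsd = ss_gamma_i / ss_gamma
    else:
        fcsd = lcsd = None
    return ss_gamma, sd_gamma, lcsd, fcsd, ss_gamma_j, ss_gamma_i


def beta_partition(
    Y: Union[FeatureMatrix, np.ndarray], grid: CommunityGrid
):
    """Among-community (β) spectral variation.

    Returns ``(ss_beta, sd_beta, ss_beta_k, lcsd_beta_k, fcsd_beta_j,
    centroids)``. Requires equal community sizes; unequal counts raise with
    an instruction to rarefy first.
    """
    v = _values(Y)
    n, p = v.shape
    if grid.n != n:
        raise ValidationError(
            f"grid covers {grid.n} pixels but Y has {n} rows"
        )
    counts = grid.counts()
    if (counts == 0).any():
        raise ValidationError(
            f"communities with no pixels: {np.nonzero(counts == 0)[0].tolist()}"
        )
    if not (counts == counts[0]).all():
        raise ValidationError(
            "communities have unequal pixel counts "
            f"(min {counts.min()}, max {counts.max()}); the exact partition "
            "requires equal m — use rarefied_partition"
        )
    m = int(counts[0])
    grand_mean = np.array([math.fsum(v[:, j]) for j in range(p)]) / n
    # centroids computed relative to a per-community reference pixel:
    # communities of identical pixels then get an exactly-equal centroid,
    # so their within-community deviations vanish exactly
    order = np.argsort(grid.assignment, kind="stable")
    bounds = np.searchsorted(grid.assignment[order], np.arange(grid.q + 1))
    centroids = np.empty((grid.q, p))
    for k in range(grid.q):
        seg = v[order[bounds[k]:bounds[k + 1]]]
        centroids[k] = seg[0] + (seg - seg[0]).mean(axis=0)  # ŷ_kj
    dev2 = (centroids - grand_mean) ** 2  # s_kj
    ss_beta_k = m * dev2.sum(axis=1)
    ss_beta_j = m * dev2.sum(axis=0)
    ss_beta = float(ss_beta_k.sum())
    sd_beta = ss_beta / (n - 1)
    if grid.q >= 2 and ss_beta > 0:
        lcsd_beta_k = ss_beta_k / ss_beta
        fcsd_beta_j = ss_beta_j / ss_beta
    else:
        lcsd_beta_k = fcsd_beta_j = None
    return ss_beta, sd_beta, ss_beta_k, lcsd_beta_k, fcsd_beta_j, (
        CommunityCentroids(means=centroids)
    )


def alpha_partition(
    Y: Union[FeatureMatrix, np.ndarray],
    grid: CommunityGrid,
    centroids: CommunityCentroids,
    allow_singleton: bool = False,
):
    """Within-community (α) spectral variation.

    Returns ``(ss_alpha, ss_alpha_k, sd_alpha_k, sd_alpha_mean,
    fcsd_alpha_jk)``. SD_α,k needs m ≥ 2; with m = 1 an error is raised
    unless ``allow_singleton`` requests SS-only output (SD_α,k = NaN).
    """
    v = _values(Y)
    counts = grid.counts()
    m = int(counts[0])
    if m < 2 and not allow_singleton:
        raise ValidationError(
            "SD_alpha,k is undefined for single-pixel communities (m=1); "
            "pass allow_singleton=True for SS-only output"
        )
    dev2 = (v - centroids.means[grid.assignment]) ** 2  # s_ijk
    ss_alpha_jk = np.zeros((grid.q, v.shape[1]))
    np.add.at(ss_alpha_jk, grid.assignment, dev2)
    ss_alpha_k = ss_alpha_jk.sum(axis=1)
    ss_alpha = float(ss_alpha_k.sum())
    sd_alpha_k = ss_alpha_k / (m - 1) if m >= 2 else np.full(grid.q, np.nan)
    sd_alpha_mean = float(np.mean(sd_alpha_k))
    with np.errstate(divide="ignore", invalid="ignore"):
        fcsd_alpha_jk = np.where(
            ss_alpha_k[:, None] > 0, ss_alpha_jk / ss_alpha_k[:, None], np.nan
        )
    return ss_alpha, ss_alpha_k, sd_alpha_k, sd_alpha_mean, fcsd_alpha_jk


def partition_all(
    Y: Union[FeatureMatrix, np.ndarray],
    grid: CommunityGrid,
    allow_singleton: bool = False,
) -> SpectralPartition:
    """Full γ → β + α partition with the additivity identity enforced.

    Raises :class:`InternalConsistencyError` if SS_γ and SS_β + SS_α disagree
    beyond relative tolerance 1e−9 — this is an internal invariant, never a
    property of the data, so a violation indicates a numerical defect.
    """
    v = _values(Y)
    ss_g, sd_g, lcsd_g, fcsd_g, _, _ = gamma_partition(v)
    ss_b, sd_b, ss_beta_k, lcsd_b, fcsd_b, centroids = beta_partition(v, grid)
    ss_a, ss_alpha_k, sd_alpha_k, sd_alpha_mean, fcsd_a = alpha_partition(
        v, grid, centroids, allow_singleton=allow_singleton
    )
    scale = max(ss_g, 1.0)
    if abs(ss_g - (ss_b + ss_a)) > ADDITIVITY_RTOL * scale:
        raise InternalConsistencyError(
            f"additivity violated: SS_gamma={ss_g!r} but SS_beta+SS_alpha="
            f"{ss_b + ss_a!r}"
        )
    m = int(grid.counts()[0])
    return SpectralPartition(
        n=v.shape[0], p=v.shape[1], q=grid.q, m=m,
        ss_gamma=ss_g, sd_gamma=sd_g,
        ss_beta=ss_b, sd_beta=sd_b,
        ss_alpha=ss_a,
        ss_beta_k=ss_beta_k, ss_alpha_k=ss_alpha_k,
        sd_alpha_k=sd_alpha_k, sd_alpha_mean=sd_alpha_mean,
        lcsd_gamma_i=lcsd_g, lcsd_beta_k=lcsd_b,
        fcsd_gamma_j=fcsd_g, fcsd_beta_j=fcsd_b,
        fcsd_alpha_jk=fcsd_a,
        centroids=centroids,
    )


# ---------------------------------------------------------------------------
# rarefaction over unequal community sizes
# ---------------------------------------------------------------------------

@dataclass
class RarefactionResult:
    """Partition aggregated over repeated equal-m subsamples.

    Each repeat draws ``m_min`` pixels per community without replacement;
    the aggregate is the elementwise mean (or median) over repeats. Per-pixel
    LCSD_γ is aggregated only over the repeats in which the pixel was drawn;
    pixels never drawn have NaN. ``aggregate`` reuses the SpectralPartition
    shape; its per-pixel field refers to the original row order of Y.
    """

    m_min: int
    repeats: int
    seed: int
    aggregation: str
    kept_communities: np.ndarray  # original community labels retained
    per_repeat: List[SpectralPartition]
    aggregate: SpectralPartition
    lcsd_gamma_full: np.ndarray  # (n_original,), NaN where never drawn


def _substream(seed: int, repeat: int, community: int) -> np.random.Generator:
    # counter-scheme substreams: reproducible regardless of iteration order
    return np.random.default_rng(np.random.SeedSequence([seed, repeat, community]))


def rarefied_partition(
    Y: Union[FeatureMatrix, np.ndarray],
    labels: np.ndarray,
    repeats: int = 30,
    seed: int = 0,
    aggregation: str = "mean",
    min_fraction: Optional[float] = None,
) -> RarefactionResult:
    """Equal-m partition of unequal communities via repeated subsampling.

    ``labels`` assigns each row of Y a community label (any non-negative
    ints; communities are the distinct labels). ``m_min`` is the smallest
    valid-pixel count over retained communities; every repeat draws m_min
    pixels per community without replacement from an independent substream
    of the master seed, runs :func:`partition_all`, and the aggregate is the
    elementwise mean (default) or median over repeats.

    ``min_fraction`` optionally drops communities whose count is below that
    fraction of the largest count *before* computing m_min (off by default).
    """
    v = _values(Y)
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (v.shape[0],):
        raise ValidationError("labels must have one entry per row of Y")
    if repeats < 1:
        raise ParameterError(f"repeats must be >= 1; got {repeats}")
    if aggregation not in ("mean", "median"):
        raise ParameterError(f"aggregation must be mean or median; got {aggregation!r}")

    uniq, inv = np.unique(labels, return_inverse=True)
    counts = np.bincount(inv)
    keep = np.ones(uniq.size, dtype=bool)
    if min_fraction is not None:
        keep = counts >= min_fraction * counts.max()
    if keep.sum() < 1:
        raise NoValidPixelsError("no communities retained after floor filtering")
    too_small = uniq[keep & (counts < 2)]
    if too_small.size:
        raise ValidationError(
            f"communities with < 2 valid pixels: {too_small.tolist()}"
        )
    m_min = int(counts[keep].min())
    kept_labels = uniq[keep]
    # per-community row indices, in original order
    comm_rows = [np.nonzero(labels == lab)[0] for lab in kept_labels]
    q = len(kept_labels)

    n_orig = v.shape[0]
    lcsd_sum = np.zeros(n_orig)
    lcsd_cnt = np.zeros(n_orig, dtype=int)
    per_repeat: List[SpectralPartition] = []
    for r in range(repeats):
        rows = []
        for k in range(q):
            idx = comm_rows[k]
            if idx.size == m_min:
                chosen = idx
            else:
                rng = _substream(seed, r, k)
                chosen = idx[rng.choice(idx.size, size=m_min, replace=False)]
            rows.append(np.sort(chosen))
        rows = np.concatenate(rows)
        sub_labels = np.repeat(np.arange(q), m_min)
        grid = CommunityGrid(assignment=sub_labels, q=q, m=m_min)
        part = partition_all(v[rows], grid)
        per_repeat.append(part)
        if part.lcsd_gamma_i is not None:
            lcsd_sum[rows] += part.lcsd_gamma_i
            lcsd_cnt[rows] += 1

    aggregate = _aggregate_partitions(per_repeat, aggregation)
    with np.errstate(invalid="ignore", divide="ignore"):
        lcsd_full = np.where(lcsd_cnt > 0, lcsd_sum / lcsd_cnt, np.nan)
    return RarefactionResult(
        m_min=m_min, repeats=repeats, seed=seed, aggregation=aggregation,
        kept_communities=kept_labels, per_repeat=per_repeat,
        aggregate=aggregate, lcsd_gamma_full=lcsd_full,
    )


def _aggregate_partitions(
    parts: Sequence[SpectralPartition], aggregation: str
) -> SpectralPartition:
    agg = np.mean if aggregation == "mean" else np.median

    def scalar(name):
        return float(agg([getattr(p, name) for p in parts]))

    def array(name):
        vals = [getattr(p, name) for p in parts]
        if any(x is None for x in vals):
            return None
        return agg(np.stack(vals), axis=0)

    first = parts[0]
    return SpectralPartition(
        n=first.n, p=first.p, q=first.q, m=first.m,
        ss_gamma=scalar("ss_gamma"), sd_gamma=scalar("sd_gamma"),
        ss_beta=scalar("ss_beta"), sd_beta=scalar("sd_beta"),
        ss_alpha=scalar("ss_alpha"),
        ss_beta_k=array("ss_beta_k"), ss_alpha_k=array("ss_alpha_k"),
        sd_alpha_k=array("sd_alpha_k"), sd_alpha_mean=scalar("sd_alpha_mean"),
        lcsd_gamma_i=None,  # aggregated separately over drawn repeats
        lcsd_beta_k=array("lcsd_beta_k"),
        fcsd_gamma_j=array("fcsd_gamma_j"),
        fcsd_beta_j=array("fcsd_beta_j"),
        fcsd_alpha_jk=array("fcsd_alpha_jk"),
        centroids=None,
    )


# ---------------------------------------------------------------------------
# region merging and analytic scaling
# ---------------------------------------------------------------------------

def merge_regions(
    partitions: Sequence[Union[SpectralPartition, Tuple[float, int]]],
) -> Tuple[float, float]:
    """Joint (SS_γ, SD_γ) of adjacent regions sharing one feature space.

    Total sums of squares are additive across regions, so the joint SS is the
    plain sum and the joint SD divides by the total pixel count minus one.
    Caveat: this is exact only when every region's deviations are taken from
    the joint (common) mean; regions centered on their own means understate
    the joint SS. The caller asserts the common-centering convention.
    """
    parts = list(partitions)
    if not parts:
        raise ValidationError("merge_regions: empty region list")
    ps = {p.p for p in parts if isinstance(p, SpectralPartition)}
    if len(ps) > 1:
        raise ValidationError(
            f"regions have differing feature counts p: {sorted(ps)}"
        )
    ss = 0.0
    n = 0
    for part in parts:
        if isinstance(part, SpectralPartition):
            ss += part.ss_gamma
            n += part.n
        else:
            s, cnt = part
            ss += float(s)
            n += int(cnt)
    if n < 2:
        raise ValidationError("merged regions must total n >= 2 pixels")
    return ss, ss / (n - 1)


def scaled_diversity_summary(
    ss_gamma: float,
    ss_beta: float,
    ss_alpha: float,
    n: int,
    q: int,
    m: int,
) -> dict:
    """Diversities and percentage shares from sums of squares and counts.

    Applies the scaling definitions SD_γ = SS_γ/(n−1), SD_β = SS_β/(n−1) and
    SD̄_α = SS_α/(q·(m−1)) (the mean per-community α-diversity under equal m),
    plus the β and α percentage shares of SS_γ. Useful for re-deriving every
    per-region summary quantity from reported SS values and pixel counts.
    """
    if n < 2 or m < 2 or q < 1:
        raise ParameterError("need n >= 2, m >= 2, q >= 1")
    return {
        "sd_gamma": ss_gamma / (n - 1),
        "sd_beta": ss_beta / (n - 1),
        "sd_alpha_mean": ss_alpha / (q * (m - 1)),
        "beta_pct": 100.0 * ss_beta / ss_gamma if ss_gamma > 0 else np.nan,
        "alpha_pct": 100.0 * ss_alpha / ss_gamma if ss_gamma > 0 else np.nan,
    }
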