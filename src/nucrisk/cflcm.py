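"""Cell-feature-level co-occurrence (CFLCM) ROI heterogeneity features.

Classical co-occurrence texture works at the pixel level.  Here each nucleus
is collapsed to a single "pixel": nuclei are rasterized onto a coarse grid by
centroid, each nuclear feature is quantized to G levels, and a co-occurrence
matrix is accumulated over occupied neighbouring grid cells.  Haralick-type
statistics of that matrix quantify how heterogeneously a nuclear feature is
arranged in space across the ROI — e.g. whether strongly and weakly oriented
nuclei are intermixed or spatially segregated.

The 960-entry ROI vector is: for each of the 90 nuclear features the mean,
variance and 8 co-occurrence heterogeneity statistics (900), plus 60
ROI-global spatial descriptors (density, nearest-neighbour spacing, quadrat
dispersion, orientation alignment, ...).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError, cKDTree
from sklearn.base import BaseEstimator, TransformerMixin

from .morphometry import cooccurrence_stats, masked_glcm
from .registry import (
    CIRCULAR_FEATURES,
    GLCM_OFFSETS,
    HARALICK_STATS,
    NUCLEUS_FEATURE_NAMES,
    ROI_FEATURE_NAMES,
    SPATIAL_FEATURES,
)

__all__ = ["CFLCMConfig", "ROIFeaturizer", "rasterize", "cflcm_matrix", "roi_vector"]


@dataclass
class CFLCMConfig:
    """Settings for cell-level co-occurrence aggregation.

    ``pitch`` is the raster cell size in pixels, or "auto" for the median
    nearest-neighbour centroid distance of the ROI.  ``roi_size_px`` fixes
    the physical scale: 2048 px corresponds to 1 mm on a side.
    """

    levels: int = 8
    pitch: float | str = "auto"
    offsets: tuple[tuple[int, int], ...] = GLCM_OFFSETS
    min_nuclei: int = 10
    roi_size_px: int = 2048
    circular_features: frozenset[str] = field(default_factory=lambda: CIRCULAR_FEATURES)

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if not self.offsets:
            raise ValueError("offsets must be non-empty")


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def rasterize(
    centroids: np.ndarray, pitch: float | str = "auto"
) -> tuple[np.ndarray, tuple[int, int], float, int]:
    """Map nuclei to grid cells, one nucleus per cell.

    The grid is anchored at the centroid bounding box, so the occupancy
    pattern is invariant to global translation.  When two nuclei land in the
    same cell, nuclei are processed in lexicographic (row, col, y, x) order
    and the displaced one moved to the nearest free cell found by a
    deterministic ring search; the mapping is therefore invertible and
    independent of table row order.

    Returns ``(cells, (rows, cols), pitch, n_collisions)`` where ``cells`` is
    an (n, 2) integer array of (row, col) per nucleus.
    """
    centroids = np.asarray(centroids, dtype=float)
    n = len(centroids)
    if n == 0:
        raise ValueError("cannot rasterize an empty nucleus set")
    if pitch == "auto":
        pitch = auto_pitch(centroids)
    pitch = float(pitch)
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    x = centroids[:, 0] - centroids[:, 0].min()
    y = centroids[:, 1] - centroids[:, 1].min()
    col = np.floor(x / pitch).astype(np.intp)
    row = np.floor(y / pitch).astype(np.intp)
    rows = int(row.max()) + 1
    cols = int(col.max()) + 1
    cells = np.column_stack([row, col])
    flat = row * cols + col
    if len(np.unique(flat)) == n:  # collision-free fast path
        return cells, (rows, cols), pitch, 0
    # canonical processing order derived from positions alone, so the
    # resolution is independent of table row order
    order = np.lexsort((x, y, col, row))
    occupied: set[tuple[int, int]] = set()
    n_collisions = 0
    for i in order:
        c = (int(row[i]), int(col[i]))
        if c in occupied:
            n_collisions += 1
            c = _nearest_free(c, occupied)
            rows = max(rows, c[0] + 1)
            cols = max(cols, c[1] + 1)
        occupied.add(c)
        cells[i] = c
    return cells, (rows, cols), pitch, n_collisions


def auto_pitch(centroids: np.ndarray) -> float:
    """Median nearest-neighbour centroid distance (1.0 for a single nucleus)."""
    if len(centroids) < 2:
        return 1.0
    tree = cKDTree(centroids)
    d, _ = tree.query(centroids, k=2)
    return float(np.median(d[:, 1]))


def _nearest_free(cell: tuple[int, int], occupied: set[tuple[int, int]]) -> tuple[int, int]:
    r0, c0 = cell
    for radius in range(1, 10_000):
        best = None
        for dr in range(-radius, radius + 1):
            for dc in range(-radius, radius + 1):
                if max(abs(dr), abs(dc)) != radius:
                    continue
                cand = (r0 + dr, c0 + dc)
                if cand[0] < 0 or cand[1] < 0 or cand in occupied:
                    continue
                d2 = dr * dr + dc * dc
                key = (d2, cand[0], cand[1])
                if best is None or key < best[0]:
                    best = (key, cand)
        if best is not None:
            return best[1]
    raise RuntimeError("no free grid cell found")  # pragma: no cover


def _neighbor_pairs(
    cells: np.ndarray, shape: tuple[int, int], offsets
) -> np.ndarray:
    """Index pairs (i, j) of nuclei occupying neighbouring cells."""
    rows, cols = shape
    grid = np.full((rows, cols), -1, dtype=np.intp)
    grid[cells[:, 0], cells[:, 1]] = np.arange(len(cells))
    pairs = []
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(rows, rows - dr)
        c0, c1 = max(0, -dc), min(cols, cols - dc)
        a = grid[r0:r1, c0:c1]
        b = grid[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        ok = (a >= 0) & (b >= 0)
        if ok.any():
            pairs.append(np.column_stack([a[ok], b[ok]]))
    if not pairs:
        return np.empty((0, 2), dtype=np.intp)
    return np.concatenate(pairs, axis=0)


# ---------------------------------------------------------------------------
# quantization and matrices
# ---------------------------------------------------------------------------

def quantize_equal_frequency(
    values: np.ndarray, levels: int, ids: np.ndarray | None = None
) -> np.ndarray:
    """Equal-frequency levels 0..G-1.

    Ranking is deterministic (ties ordered by value then nucleus id), but
    equal values always share the level of their lowest-ranked member, so a
    constant feature maps to a single level and can never manufacture
    spurious heterogeneity.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if ids is None:
        ids = np.arange(n)
    order = np.lexsort((ids, values))
    ranks = np.empty(n, dtype=np.intp)
    ranks[order] = np.arange(n)
    lv = (ranks * levels) // n
    return _merge_tied_levels(values, order, lv)


def _merge_tied_levels(values: np.ndarray, order: np.ndarray, lv: np.ndarray) -> np.ndarray:
    """Force equal values to share the level of their first occurrence."""
    v_sorted = values[order]
    lv_sorted = lv[order]
    new_group = np.ones(len(values), dtype=bool)
    new_group[1:] = v_sorted[1:] != v_sorted[:-1]
    group_id = np.cumsum(new_group) - 1
    first_level = lv_sorted[new_group]
    merged = np.empty_like(lv)
    merged[order] = first_level[group_id]
    return merged


def quantize_circular(values_deg: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width bins of the doubled angle (axial data on [0, 180))."""
    doubled = (2.0 * np.asarray(values_deg, dtype=float)) % 360.0
    return np.minimum((doubled / 360.0 * levels).astype(np.intp), levels - 1)


def _quantize_all(
    feat: np.ndarray, ids: np.ndarray, G: int, circular: frozenset[str]
) -> np.ndarray:
    """Quantize every registry column at once (single lexsort over all features)."""
    n, F = feat.shape
    feat_idx = np.repeat(np.arange(F), n)
    v = feat.T.ravel()
    ids_t = np.tile(np.asarray(ids), F)
    order = np.lexsort((ids_t, v, feat_idx))
    ranks = np.empty(n * F, dtype=np.intp)
    ranks[order] = np.arange(n * F) % n
    lv = (ranks * G) // n
    # tie merging respects feature blocks: the lexsort keeps each feature's
    # block contiguous, and a group boundary is forced wherever the feature
    # index changes
    v_sorted = v[order]
    f_sorted = feat_idx[order]
    lv_sorted = lv[order]
    new_group = np.ones(n * F, dtype=bool)
    new_group[1:] = (v_sorted[1:] != v_sorted[:-1]) | (f_sorted[1:] != f_sorted[:-1])
    group_id = np.cumsum(new_group) - 1
    first_level = lv_sorted[new_group]
    merged = np.empty_like(lv)
    merged[order] = first_level[group_id]
    levels_nf = merged.reshape(F, n).T
    for f, name in enumerate(NUCLEUS_FEATURE_NAMES[:F]):
        if name in circular:
            levels_nf[:, f] = quantize_circular(feat[:, f], G)
    return levels_nf


def cflcm_matrix(
    cells: np.ndarray,
    shape: tuple[int, int],
    feature_values: np.ndarray,
    config: CFLCMConfig,
    circular: bool = False,
    ids: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    """Normalized symmetric G x G cell-level co-occurrence matrix.

    Returns ``(matrix, degenerate)``; ``degenerate`` flags an ROI with no
    neighbouring occupied cell pair, for which the matrix carries the level
    distribution on its diagonal.
    """
    feature_values = np.asarray(feature_values, dtype=float)
    if not np.isfinite(feature_values).all():
        raise ValueError("feature values must be finite")
    if len(cells) == 0:
        raise ValueError("empty grid")
    G = config.levels
    if circular:
        lv = quantize_circular(feature_values, G)
    else:
        lv = quantize_equal_frequency(feature_values, G, ids)
    pairs = _neighbor_pairs(np.asarray(cells, dtype=np.intp), shape, config.offsets)
    P = np.zeros((G, G), dtype=float)
    if len(pairs) == 0:
        counts = np.bincount(lv, minlength=G).astype(float)
        np.fill_diagonal(P, counts / counts.sum())
        return P, True
    np.add.at(P, (lv[pairs[:, 0]], lv[pairs[:, 1]]), 1.0)
    P = P + P.T
    return P / P.sum(), False


def _stack_matrices(
    levels_nf: np.ndarray, pairs: np.ndarray, G: int
) -> np.ndarray:
    """All-feature co-occurrence stack (F, G, G) from one shared pair list."""
    n, F = levels_nf.shape
    out = np.zeros((F, G, G), dtype=float)
    if len(pairs) == 0:
        counts = np.zeros((F, G))
        for f in range(F):
            counts[f] = np.bincount(levels_nf[:, f], minlength=G)
        counts /= counts.sum(axis=1, keepdims=True)
        idx = np.arange(G)
        out[:, idx, idx] = counts
        return out
    a = levels_nf[pairs[:, 0], :]  # (m, F)
    b = levels_nf[pairs[:, 1], :]
    f_idx = np.broadcast_to(np.arange(F), a.shape)
    flat = (f_idx * G + a) * G + b
    binc = np.bincount(flat.ravel(), minlength=F * G * G).astype(float)
    out = binc.reshape(F, G, G)
    out = out + out.transpose(0, 2, 1)
    return out / out.sum(axis=(1, 2), keepdims=True)


def _stack_stats(P: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorized Haralick statistics over a (F, G, G) matrix stack."""
    F, G, _ = P.shape
    i, j = np.indices((G, G))
    d = i - j
    asm = np.einsum("fij,fij->f", P, P)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(P > 0, np.log2(np.where(P > 0, P, 1.0)), 0.0)
    entropy = -np.einsum("fij,fij->f", P, logs)
    contrast = np.einsum("fij,ij->f", P, (d * d).astype(float))
    dissim = np.einsum("fij,ij->f", P, np.abs(d).astype(float))
    homog = np.einsum("fij,ij->f", P, 1.0 / (1.0 + d * d))
    pm = P.sum(axis=2)  # (F, G) marginal
    levels = np.arange(G, dtype=float)
    mu = pm @ levels
    var = np.einsum("fg,fg->f", pm, (levels[None, :] - mu[:, None]) ** 2)
    di = i[None] - mu[:, None, None]
    dj = j[None] - mu[:, None, None]
    cov = np.einsum("fij,fij->f", P, di * dj)
    corr = np.where(var > 0, cov / np.where(var > 0, var, 1.0), 1.0)
    return {
        "asm": asm,
        "contrast": contrast,
        "correlation": corr,
        "variance": var,
        "homogeneity": homog,
        "entropy": entropy,
        "dissimilarity": dissim,
        "energy": np.sqrt(asm),
    }


# ---------------------------------------------------------------------------
# full ROI vector
# ---------------------------------------------------------------------------

_AREA_IDX = NUCLEUS_FEATURE_NAMES.index("area")
_ORIENT_IDX = NUCLEUS_FEATURE_NAMES.index("orientation")


def roi_vector(nuclei: pd.DataFrame, config: CFLCMConfig | None = None) -> pd.Series:
    """The 960-entry feature vector for one ROI's nucleus table."""
    config = config or CFLCMConfig()
    nuclei = nuclei.sort_values("nucleus_id", kind="mergesort")
    ids = nuclei["nucleus_id"].to_numpy()
    centroids = nuclei[["centroid_x", "centroid_y"]].to_numpy(dtype=float)
    feat = nuclei[list(NUCLEUS_FEATURE_NAMES)].to_numpy(dtype=float)
    values = _roi_vector_core(ids, centroids, feat, config)
    vec = pd.Series(values)
    assert len(vec) == 960 and tuple(vec.index) == ROI_FEATURE_NAMES
    return vec


def _roi_vector_core(
    ids: np.ndarray, centroids: np.ndarray, feat: np.ndarray, config: CFLCMConfig
) -> dict[str, float]:
    """Array-level ROI vector (dict in registry order)."""
    if len(ids) < config.min_nuclei:
        raise ValueError(
            f"ROI has {len(ids)} nuclei, fewer than min_nuclei={config.min_nuclei}"
        )
    cells, shape, pitch, n_coll = rasterize(centroids, config.pitch)
    pairs = _neighbor_pairs(cells, shape, config.offsets)
    G = config.levels
    levels_nf = _quantize_all(feat, ids, G, config.circular_features)
    stack = _stack_matrices(levels_nf, pairs, G)
    het = _stack_stats(stack)

    means = feat.mean(axis=0)
    variances = feat.var(axis=0)
    for f, name in enumerate(NUCLEUS_FEATURE_NAMES):
        if name in config.circular_features:
            # circular mean / variance on doubled angles
            ang = np.deg2rad(2.0 * feat[:, f])
            C, S = np.cos(ang).mean(), np.sin(ang).mean()
            means[f] = (np.degrees(np.arctan2(S, C)) % 360.0) / 2.0
            variances[f] = 1.0 - np.hypot(C, S)
    # per-feature block: mean, var, 8 heterogeneity stats — registry order
    per_feature = np.column_stack(
        [means, variances] + [het[s] for s in HARALICK_STATS]
    )
    values: dict[str, float] = dict(
        zip(ROI_FEATURE_NAMES[: per_feature.size], per_feature.ravel())
    )

    values.update(
        _spatial_block(
            centroids,
            feat[:, _AREA_IDX],
            feat[:, _ORIENT_IDX],
            cells,
            shape,
            pitch,
            n_coll,
            len(pairs),
            config,
        )
    )
    return values


def _spatial_block(
    xy: np.ndarray,
    areas: np.ndarray,
    orientations: np.ndarray,
    cells: np.ndarray,
    shape: tuple[int, int],
    pitch: float,
    n_collisions: int,
    n_pairs: int,
    config: CFLCMConfig,
) -> dict[str, float]:
    n = len(xy)
    roi_px = float(config.roi_size_px)
    roi_area_px2 = roi_px * roi_px
    mm2 = (roi_px / 2048.0) ** 2

    out: dict[str, float] = {
        "n_nuclei": float(n),
        "density_per_mm2": n / mm2,
        "nucleus_area_fraction": float(areas.sum()) / roi_area_px2,
        "grid_pitch": pitch,
        "grid_rows": float(shape[0]),
        "grid_cols": float(shape[1]),
        "grid_occupied_fraction": n / float(shape[0] * shape[1]),
        "grid_collision_count": float(n_collisions),
        "n_neighbor_pairs": float(n_pairs),
    }

    tree = cKDTree(xy)
    k = min(4, n)
    d, nn_idx = tree.query(xy, k=k)
    nn = d[:, 1] if n > 1 else np.zeros(1)
    p10, p25, med, p75, p90 = np.percentile(nn, [10, 25, 50, 75, 90])
    nn_mean, nn_std = float(nn.mean()), float(nn.std())
    out.update(
        nn_dist_mean=nn_mean,
        nn_dist_std=nn_std,
        nn_dist_var=nn_std**2,
        nn_dist_min=float(nn.min()),
        nn_dist_max=float(nn.max()),
        nn_dist_median=float(med),
        nn_dist_p10=float(p10),
        nn_dist_p25=float(p25),
        nn_dist_p75=float(p75),
        nn_dist_p90=float(p90),
        nn_dist_iqr=float(p75 - p25),
        nn_dist_cv=nn_std / nn_mean if nn_mean > 0 else 0.0,
    )
    knn = d[:, 1:k].mean(axis=1) if k > 1 else np.zeros(n)
    km, ks = float(knn.mean()), float(knn.std())
    out.update(
        knn3_dist_mean=km,
        knn3_dist_std=ks,
        knn3_dist_median=float(np.median(knn)),
        knn3_dist_cv=ks / km if km > 0 else 0.0,
    )

    # every positional statistic is taken relative to the centroid cloud, so
    # the whole vector is invariant to global translation of the ROI
    cx = xy[:, 0] - xy[:, 0].min()
    cy = xy[:, 1] - xy[:, 1].min()
    cxm, cym = float(cx.mean()), float(cy.mean())
    disp = np.hypot(cx - cxm, cy - cym)
    cdist = np.hypot(cx - np.median(cx), cy - np.median(cy))
    w = float(cx.max())
    h = float(cy.max())
    out.update(
        centroid_x_mean=cxm,
        centroid_x_std=float(cx.std()),
        centroid_y_mean=cym,
        centroid_y_std=float(cy.std()),
        centroid_cov_xy=float(np.mean((cx - cxm) * (cy - cym))),
        dispersion_mean=float(disp.mean()),
        dispersion_std=float(disp.std()),
        dispersion_max=float(disp.max()),
        center_dist_mean=float(cdist.mean()),
        center_dist_std=float(cdist.std()),
        center_dist_median=float(np.median(cdist)),
        centroid_bbox_width=w,
        centroid_bbox_height=h,
        centroid_bbox_area=w * h,
        centroid_bbox_aspect=max(w, h) / max(min(w, h), 1e-12),
    )

    try:
        hull = ConvexHull(xy)
        hull_area = float(hull.volume)  # 2-D: volume is area
        hull_perim = float(hull.area)
    except (QhullError, ValueError):
        hull_area = hull_perim = 0.0
    out.update(
        hull_area=hull_area,
        hull_perimeter=hull_perim,
        hull_density=n / hull_area if hull_area > 0 else 0.0,
    )

    qx = np.minimum((cx / max(w, 1e-12) * 4).astype(int), 3)
    qy = np.minimum((cy / max(h, 1e-12) * 4).astype(int), 3)
    counts = np.bincount(qy * 4 + qx, minlength=16).astype(float)
    qmean = counts.mean()
    qvar = counts.var()
    p = counts[counts > 0] / counts.sum()
    out.update(
        quadrat_mean=float(qmean),
        quadrat_var=float(qvar),
        quadrat_vmr=float(qvar / qmean) if qmean > 0 else 0.0,
        quadrat_max=float(counts.max()),
        quadrat_min=float(counts.min()),
        quadrat_entropy=float(-np.sum(p * np.log2(p))),
    )
    lam = n / roi_area_px2
    out["clark_evans_index"] = nn_mean / (0.5 / np.sqrt(lam)) if lam > 0 else 0.0

    theta2 = np.deg2rad(2.0 * orientations)
    C, S = np.cos(theta2).mean(), np.sin(theta2).mean()
    R = float(np.hypot(C, S))
    out.update(
        orientation_resultant_length=R,
        orientation_circ_var=1.0 - R,
        orientation_circ_std=float(np.sqrt(max(-2.0 * np.log(max(R, 1e-300)), 0.0))),
    )

    occ = np.zeros(shape, dtype=np.intp)
    occ[cells[:, 0], cells[:, 1]] = 1
    occ_stats = [
        cooccurrence_stats(masked_glcm(occ, np.ones(shape, dtype=bool), 2, off))
        for off in config.offsets
    ]
    out.update(
        occupancy_asm=float(np.mean([s["asm"] for s in occ_stats])),
        occupancy_contrast=float(np.mean([s["contrast"] for s in occ_stats])),
        occupancy_entropy=float(np.mean([s["entropy"] for s in occ_stats])),
        occupancy_homogeneity=float(np.mean([s["homogeneity"] for s in occ_stats])),
    )

    if n > 1:
        theta = np.deg2rad(orientations)
        align = np.cos(2.0 * (theta - theta[nn_idx[:, 1]]))
        out.update(nn_alignment_mean=float(align.mean()), nn_alignment_std=float(align.std()))
    else:
        out.update(nn_alignment_mean=1.0, nn_alignment_std=0.0)

    expected_nn = 0.5 / np.sqrt(n / hull_area) if hull_area > 0 else 0.0
    out["spacing_ratio"] = nn_mean / expected_nn if expected_nn > 0 else 0.0

    assert len(out) == len(SPATIAL_FEATURES)
    return out


# ---------------------------------------------------------------------------
# sklearn-style transformer
# ---------------------------------------------------------------------------

class ROIFeaturizer(TransformerMixin, BaseEstimator):
    """Transform per-nucleus tables into 960-entry ROI heterogeneity vectors.

    A stateless transformer (``fit`` only validates parameters), so it can sit
    at the head of an sklearn ``Pipeline``.  ``transform`` accepts a long
    nucleus table carrying ``case_id`` and ``roi_id`` columns and returns one
    row per ROI with the 960 registry columns plus ``case_id``, ``roi_id``
    and ``n_nuclei``.  ROIs with fewer than ``min_nuclei`` nuclei are skipped
    with a warning, mirroring quality-control of sparse tumour regions.
    """

    def __init__(
        self,
        levels: int = 8,
        pitch: float | str = "auto",
        min_nuclei: int = 10,
        roi_size_px: int = 2048,
    ) -> None:
        self.levels = levels
        self.pitch = pitch
        self.min_nuclei = min_nuclei
        self.roi_size_px = roi_size_px

    def _config(self) -> CFLCMConfig:
        return CFLCMConfig(
            levels=self.levels,
            pitch=self.pitch,
            min_nuclei=self.min_nuclei,
            roi_size_px=self.roi_size_px,
        )

    def fit(self, X=None, y=None) -> "ROIFeaturizer":
        self._config()  # parameter validation
        self.n_features_out_ = len(ROI_FEATURE_NAMES)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        config = self._config()
        X = X.sort_values(["case_id", "roi_id", "nucleus_id"], kind="mergesort")
        ids_all = X["nucleus_id"].to_numpy()
        xy_all = X[["centroid_x", "centroid_y"]].to_numpy(dtype=float)
        feat_all = X[list(NUCLEUS_FEATURE_NAMES)].to_numpy(dtype=float)
        rows = []
        group_idx = X.groupby(["case_id", "roi_id"], sort=True).indices
        for (case_id, roi_id) in sorted(group_idx):
            idx = group_idx[(case_id, roi_id)]
            try:
                values = _roi_vector_core(
                    ids_all[idx], xy_all[idx], feat_all[idx], config
                )
            except ValueError as exc:
                warnings.warn(f"skipping ROI {case_id}/{roi_id}: {exc}", stacklevel=2)
                continue
            rec = {"case_id": case_id, "roi_id": roi_id}
            rec.update(values)  # n_nuclei is part of the registry block
            rows.append(rec)
        cols = ["case_id", "roi_id"] + list(ROI_FEATURE_NAMES)
        if not rows:
            return pd.DataFrame(columns=cols)
        return pd.DataFrame(rows)[cols]

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(ROI_FEATURE_NAMES, dtype=object)
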