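"""Per-nucleus morphometry from label masks.

Computes the 90-entry feature vector (24 shape + 66 chromatin-texture
descriptors) for every labelled nucleus in a segmentation mask, given the
matching grayscale (or RGB, converted) intensity image.  The gray-level
co-occurrence matrix is accumulated strictly over pixel pairs that both lie
inside the nucleus mask, so surrounding background never contaminates the
texture statistics — the reason an off-the-shelf whole-patch GLCM cannot be
used here.

Coordinate conventions (fixed; the cell-level co-occurrence step depends on
them): pixel centres, 0-based, ``x`` rightward (column), ``y`` downward
(row); orientation measured from the +x axis, axial range [0, 180) degrees.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.measure import regionprops

from .registry import (
    GLCM_OFFSETS,
    HARALICK_STATS,
    NUCLEUS_FEATURE_NAMES,
)

__all__ = [
    "haralick_features",
    "glcm_texture",
    "extract_nuclei",
    "validate_nucleus_table",
]

META_COLUMNS = ["nucleus_id", "centroid_x", "centroid_y"]


# ---------------------------------------------------------------------------
# co-occurrence statistics
# ---------------------------------------------------------------------------

def cooccurrence_stats(P: np.ndarray) -> dict[str, float]:
    """Haralick-type statistics of one normalized symmetric G x G matrix.

    Entropy is in bits.  For a degenerate matrix (all mass on one level)
    ASM = 1, entropy = 0 and correlation is defined as 1.
    """
    P = np.asarray(P, dtype=float)
    G = P.shape[0]
    i, j = np.indices((G, G))
    d = i - j
    asm = float(np.sum(P * P))
    nz = P[P > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    contrast = float(np.sum(P * d * d))
    dissimilarity = float(np.sum(P * np.abs(d)))
    homogeneity = float(np.sum(P / (1.0 + d * d)))
    pm = P.sum(axis=1)  # marginal (symmetric)
    levels = np.arange(G)
    mu = float(levels @ pm)
    var = float(((levels - mu) ** 2) @ pm)
    if var > 0:
        correlation = float(np.sum((i - mu) * (j - mu) * P) / var)
    else:
        correlation = 1.0
    return {
        "asm": asm,
        "contrast": contrast,
        "correlation": correlation,
        "variance": var,
        "homogeneity": homogeneity,
        "entropy": entropy,
        "dissimilarity": dissimilarity,
        "energy": float(np.sqrt(asm)),
    }


# kept under the name tests and users expect
haralick_features = cooccurrence_stats


def _quantize_minmax(values: np.ndarray, levels: int) -> np.ndarray:
    """Min-max scale to integer levels 0..levels-1; constant input -> level 0."""
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        return np.zeros(values.shape, dtype=np.intp)
    q = ((values - lo) / (hi - lo) * levels).astype(np.intp)
    return np.minimum(q, levels - 1)


def masked_glcm(
    quantized: np.ndarray,
    mask: np.ndarray,
    levels: int,
    offset: tuple[int, int],
) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix over in-mask pixel pairs.

    If the offset yields no valid pair the matrix degenerates to all mass on
    the (modal level, modal level) diagonal cell, which downstream statistics
    treat as perfectly homogeneous.
    """
    dr, dc = offset
    h, w = mask.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a_mask = mask[r0:r1, c0:c1]
    b_mask = mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = a_mask & b_mask
    P = np.zeros((levels, levels), dtype=float)
    if not valid.any():
        inmask = quantized[mask]
        lv = int(np.bincount(inmask).argmax()) if inmask.size else 0
        P[lv, lv] = 1.0
        return P
    a = quantized[r0:r1, c0:c1][valid]
    b = quantized[r0 + dr : r1 + dr, c0 + dc : c1 + dc][valid]
    np.add.at(P, (a, b), 1.0)
    P = P + P.T
    return P / P.sum()


def glcm_texture(
    pixels: np.ndarray,
    mask: np.ndarray,
    levels: int = 8,
    offsets: tuple[tuple[int, int], ...] = GLCM_OFFSETS,
) -> dict[str, float]:
    """The 66-entry texture block for one nucleus.

    Per-direction statistics at distance 1, their isotropic means, isotropic
    means at distance 2, and first-order intensity statistics of the masked
    pixels.
    """
    pixels = np.asarray(pixels, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if pixels.shape != mask.shape:
        raise ValueError("pixels and mask dimensions differ")
    if int(mask.sum()) < 2:
        raise ValueError("need at least 2 masked pixels for texture")
    if levels < 2:
        raise ValueError("levels must be >= 2")

    vals = pixels[mask]
    q = np.zeros(pixels.shape, dtype=np.intp)
    q[mask] = _quantize_minmax(vals, levels)

    out: dict[str, float] = {}
    angles = (0, 45, 90, 135)
    per_dir = []
    for (dr, dc), ang in zip(offsets, angles):
        stats = cooccurrence_stats(masked_glcm(q, mask, levels, (dr, dc)))
        per_dir.append(stats)
        for s in HARALICK_STATS:
            out[f"glcm_{s}_a{ang}"] = stats[s]
    for s in HARALICK_STATS:
        out[f"glcm_{s}_mean"] = float(np.mean([d[s] for d in per_dir]))
    d2 = [
        cooccurrence_stats(masked_glcm(q, mask, levels, (2 * dr, 2 * dc)))
        for dr, dc in offsets
    ]
    for s in HARALICK_STATS:
        out[f"glcm_{s}_d2_mean"] = float(np.mean([d[s] for d in d2]))

    out.update(_intensity_stats(vals))
    return out


def _intensity_stats(vals: np.ndarray) -> dict[str, float]:
    mean = float(vals.mean())
    std = float(vals.std())
    p10, p25, med, p75, p90 = (float(v) for v in np.percentile(vals, [10, 25, 50, 75, 90]))
    if std > 0:
        centered = (vals - mean) / std
        skew = float(np.mean(centered**3))
        kurt = float(np.mean(centered**4) - 3.0)
    else:
        skew = kurt = 0.0
    lo, hi = float(vals.min()), float(vals.max())
    if hi > lo:
        hist, _ = np.histogram(vals, bins=8, range=(lo, hi))
        p = hist[hist > 0] / hist.sum()
        ent = float(-np.sum(p * np.log2(p)))
    else:
        ent = 0.0
    return {
        "int_mean": mean,
        "int_std": std,
        "int_var": std * std,
        "int_skew": skew,
        "int_kurtosis": kurt,
        "int_min": lo,
        "int_max": hi,
        "int_range": hi - lo,
        "int_median": med,
        "int_p10": p10,
        "int_p25": p25,
        "int_p75": p75,
        "int_p90": p90,
        "int_iqr": p75 - p25,
        "int_mad": float(np.median(np.abs(vals - med))),
        "int_cv": std / mean if mean != 0 else 0.0,
        "int_entropy": ent,
        "int_integrated": float(vals.sum()),
    }


# ---------------------------------------------------------------------------
# shape block
# ---------------------------------------------------------------------------

def _axial_orientation_deg(coords_rc: np.ndarray) -> float:
    """Principal-axis angle from +x, axial [0, 180), x=col / y=row."""
    x = coords_rc[:, 1].astype(float)
    y = coords_rc[:, 0].astype(float)
    x = x - x.mean()
    y = y - y.mean()
    mu20 = np.mean(x * x)
    mu02 = np.mean(y * y)
    mu11 = np.mean(x * y)
    theta = 0.5 * np.arctan2(2.0 * mu11, mu20 - mu02)
    return float(np.degrees(theta) % 180.0)


def _shape_block(prop) -> dict[str, float]:
    area = float(prop.area)
    # Crofton estimator: nearly unbiased for smooth boundaries, so the form
    # factor of a digital disk stays close to 1
    perim = float(prop.perimeter_crofton) if prop.perimeter_crofton > 0 else 1.0
    major = float(prop.axis_major_length)
    minor = float(prop.axis_minor_length)
    coords = prop.coords
    cy, cx = prop.centroid
    d = np.hypot(coords[:, 1] - cx, coords[:, 0] - cy)
    minr, minc, maxr, maxc = prop.bbox
    bh, bw = maxr - minr, maxc - minc
    hu = prop.moments_hu
    form_factor = min(4.0 * np.pi * area / perim**2, 1.0)
    return {
        "area": area,
        "perimeter": perim,
        "form_factor": form_factor,
        "eccentricity": float(prop.eccentricity),
        "solidity": float(prop.solidity),
        "extent": float(prop.extent),
        "major_axis": major,
        "minor_axis": minor,
        "aspect_ratio": major / minor if minor > 0 else 1.0,
        "equivalent_diameter": float(prop.equivalent_diameter_area),
        "convex_area": float(prop.area_convex),
        "max_radius": float(d.max()),
        "mean_radius": float(d.mean()),
        "median_radius": float(np.median(d)),
        "compactness": perim**2 / area,
        "roundness": min(4.0 * area / (np.pi * major**2), 1.0) if major > 0 else 1.0,
        "bbox_area": float(bh * bw),
        "bbox_aspect": float(max(bh, bw) / max(min(bh, bw), 1)),
        "feret_diameter_max": float(prop.feret_diameter_max),
        "orientation": _axial_orientation_deg(coords),
        "hu_moment_1": float(hu[0]),
        "hu_moment_2": float(hu[1]),
        "hu_moment_3": float(hu[2]),
        "hu_moment_4": float(hu[3]),
    }


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def extract_nuclei(
    mask: np.ndarray,
    intensity: np.ndarray,
    levels: int = 8,
    exclude_border: bool = True,
) -> pd.DataFrame:
    """One 90-feature record per labelled nucleus.

    Parameters
    ----------
    mask
        Integer label image; 0 is background.
    intensity
        Grayscale image of the same shape (RGB is converted by luminance
        averaging).
    levels
        Gray levels for the per-nucleus co-occurrence quantization.
    exclude_border
        Drop nuclei touching the image border (truncated shapes bias the
        size features).

    Returns a DataFrame with ``nucleus_id``, ``centroid_x``, ``centroid_y``
    and the 90 registry columns; empty mask yields an empty, well-typed
    table.
    """
    mask = np.asarray(mask)
    intensity = np.asarray(intensity)
    if intensity.ndim == 3:
        intensity = intensity[..., :3].mean(axis=2)
    if mask.shape != intensity.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match intensity shape {intensity.shape}"
        )
    if mask.min() < 0:
        raise ValueError("labels must be non-negative integers")

    records: list[dict[str, float]] = []
    h, w = mask.shape
    for prop in regionprops(mask, intensity_image=intensity):
        minr, minc, maxr, maxc = prop.bbox
        if exclude_border and (minr == 0 or minc == 0 or maxr == h or maxc == w):
            continue
        sub_mask = prop.image
        sub_int = intensity[minr:maxr, minc:maxc]
        rec: dict[str, float] = {
            "nucleus_id": float(prop.label),
            "centroid_x": float(prop.centroid[1]),
            "centroid_y": float(prop.centroid[0]),
        }
        rec.update(_shape_block(prop))
        if int(sub_mask.sum()) >= 2:
            rec.update(glcm_texture(sub_int, sub_mask, levels=levels))
        else:  # single-pixel nucleus: flat texture
            flat = {f"glcm_{s}_a{a}": (1.0 if s in ("asm", "energy", "correlation", "homogeneity") else 0.0)
                    for s in HARALICK_STATS for a in (0, 45, 90, 135)}
            rec.update(flat)
            for s in HARALICK_STATS:
                v = 1.0 if s in ("asm", "energy", "correlation", "homogeneity") else 0.0
                rec[f"glcm_{s}_mean"] = v
                rec[f"glcm_{s}_d2_mean"] = v
            rec.update(_intensity_stats(sub_int[sub_mask]))
        records.append(rec)

    columns = META_COLUMNS + list(NUCLEUS_FEATURE_NAMES)
    if not records:
        return pd.DataFrame(columns=columns).astype(float)
    df = pd.DataFrame.from_records(records)[columns]
    validate_nucleus_table(df)
    return df


def validate_nucleus_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check a nucleus table against the registry invariants.

    Raises ``ValueError`` on missing columns, NaNs, or out-of-range values
    (area <= 0, eccentricity outside [0, 1), solidity or form factor outside
    (0, 1]).  Returns the table unchanged for call chaining.
    """
    missing = [c for c in NUCLEUS_FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"nucleus table missing {len(missing)} features: {missing[:5]}")
    feat = df[list(NUCLEUS_FEATURE_NAMES)]
    if not np.isfinite(feat.to_numpy(dtype=float)).all():
        raise ValueError("nucleus table contains non-finite feature values")
    if len(df):
        if (df["area"] <= 0).any():
            raise ValueError("area must be positive")
        if ((df["eccentricity"] < 0) | (df["eccentricity"] >= 1)).any():
            raise ValueError("eccentricity must lie in [0, 1)")
        for col in ("solidity", "form_factor"):
            if ((df[col] <= 0) | (df[col] > 1)).any():
                raise ValueError(f"{col} must lie in (0, 1]")
        if ((df["orientation"] < 0) | (df["orientation"] >= 180)).any():
            raise ValueError("orientation must lie in [0, 180)")
    return df


def relabel_sequential_mask(mask: np.ndarray) -> np.ndarray:
    """Utility: compress arbitrary positive labels to 1..n (order preserved)."""
    labels = np.unique(mask)
    labels = labels[labels > 0]
    lut = np.zeros(int(mask.max()) + 1, dtype=mask.dtype)
    lut[labels] = np.arange(1, labels.size + 1, dtype=mask.dtype)
    return lut[mask]
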