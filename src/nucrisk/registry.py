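"""Frozen feature registries.

The per-nucleus vocabulary has exactly 90 entries (24 shape + 66 chromatin
texture descriptors); the per-ROI vocabulary has exactly 960 entries
(mean + variance + 8 cell-level co-occurrence heterogeneity statistics for
each nuclear feature, plus 60 ROI-global spatial descriptors).  Downstream
code treats both lists as a stable, ordered contract: models, CSV schemas
and importance breakdowns all key on these names.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

#: Haralick-type co-occurrence statistics used throughout (nuclear GLCM and
#: cell-level co-occurrence alike), in a fixed order.
HARALICK_STATS = (
    "asm",
    "contrast",
    "correlation",
    "variance",
    "homogeneity",
    "entropy",
    "dissimilarity",
    "energy",
)

#: Pixel offsets (row, col) at distance 1: 0, 45, 90 and 135 degrees.
GLCM_OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1))
GLCM_ANGLES = (0, 45, 90, 135)


@dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    block: str  # "shape" | "texture" | "spatial"
    circular: bool = False


def _shape_descriptors() -> list[FeatureDescriptor]:
    names = [
        "area",
        "perimeter",
        "form_factor",
        "eccentricity",
        "solidity",
        "extent",
        "major_axis",
        "minor_axis",
        "aspect_ratio",
        "equivalent_diameter",
        "convex_area",
        "max_radius",
        "mean_radius",
        "median_radius",
        "compactness",
        "roundness",
        "bbox_area",
        "bbox_aspect",
        "feret_diameter_max",
        "orientation",
        "hu_moment_1",
        "hu_moment_2",
        "hu_moment_3",
        "hu_moment_4",
    ]
    return [
        FeatureDescriptor(n, "shape", circular=(n == "orientation")) for n in names
    ]


def _texture_descriptors() -> list[FeatureDescriptor]:
    out: list[FeatureDescriptor] = []
    # 8 statistics x 4 directions at distance 1
    for stat in HARALICK_STATS:
        for ang in GLCM_ANGLES:
            out.append(FeatureDescriptor(f"glcm_{stat}_a{ang}", "texture"))
    # isotropic (direction-averaged) statistics at distances 1 and 2
    for stat in HARALICK_STATS:
        out.append(FeatureDescriptor(f"glcm_{stat}_mean", "texture"))
    for stat in HARALICK_STATS:
        out.append(FeatureDescriptor(f"glcm_{stat}_d2_mean", "texture"))
    # first-order intensity statistics of the masked nucleus pixels
    intensity = [
        "int_mean",
        "int_std",
        "int_var",
        "int_skew",
        "int_kurtosis",
        "int_min",
        "int_max",
        "int_range",
        "int_median",
        "int_p10",
        "int_p25",
        "int_p75",
        "int_p90",
        "int_iqr",
        "int_mad",
        "int_cv",
        "int_entropy",
        "int_integrated",
    ]
    out.extend(FeatureDescriptor(n, "texture") for n in intensity)
    return out


#: The 90-entry per-nucleus registry.
NUCLEUS_FEATURES: tuple[FeatureDescriptor, ...] = tuple(
    _shape_descriptors() + _texture_descriptors()
)
NUCLEUS_FEATURE_NAMES: tuple[str, ...] = tuple(d.name for d in NUCLEUS_FEATURES)
CIRCULAR_FEATURES: frozenset[str] = frozenset(
    d.name for d in NUCLEUS_FEATURES if d.circular
)

assert len(NUCLEUS_FEATURES) == 90, "nuclear registry must hold exactly 90 features"
assert len(set(NUCLEUS_FEATURE_NAMES)) == 90


#: Per-nuclear-feature ROI summaries: mean, variance and the 8 heterogeneity
#: statistics of the cell-level co-occurrence matrix.
ROI_SUMMARY_SUFFIXES = ("mean", "var") + tuple(f"het_{s}" for s in HARALICK_STATS)


def _spatial_descriptors() -> list[FeatureDescriptor]:
    names = [
        # counts / occupancy
        "n_nuclei",
        "density_per_mm2",
        "nucleus_area_fraction",
        "grid_pitch",
        "grid_rows",
        "grid_cols",
        "grid_occupied_fraction",
        "grid_collision_count",
        "n_neighbor_pairs",
        # nearest-neighbour centroid distances
        "nn_dist_mean",
        "nn_dist_std",
        "nn_dist_var",
        "nn_dist_min",
        "nn_dist_max",
        "nn_dist_median",
        "nn_dist_p10",
        "nn_dist_p25",
        "nn_dist_p75",
        "nn_dist_p90",
        "nn_dist_iqr",
        "nn_dist_cv",
        # mean distance to the 3 nearest neighbours
        "knn3_dist_mean",
        "knn3_dist_std",
        "knn3_dist_median",
        "knn3_dist_cv",
        # centroid cloud geometry
        "centroid_x_mean",
        "centroid_x_std",
        "centroid_y_mean",
        "centroid_y_std",
        "centroid_cov_xy",
        "dispersion_mean",
        "dispersion_std",
        "dispersion_max",
        "center_dist_mean",
        "center_dist_std",
        "center_dist_median",
        "centroid_bbox_width",
        "centroid_bbox_height",
        "centroid_bbox_area",
        "centroid_bbox_aspect",
        "hull_area",
        "hull_perimeter",
        "hull_density",
        # quadrat (4x4) dispersion
        "quadrat_mean",
        "quadrat_var",
        "quadrat_vmr",
        "quadrat_max",
        "quadrat_min",
        "quadrat_entropy",
        "clark_evans_index",
        # circular statistics of nuclear orientations (axial)
        "orientation_resultant_length",
        "orientation_circ_var",
        "orientation_circ_std",
        # co-occurrence texture of the binary occupancy grid
        "occupancy_asm",
        "occupancy_contrast",
        "occupancy_entropy",
        "occupancy_homogeneity",
        # orientation alignment between nearest neighbours
        "nn_alignment_mean",
        "nn_alignment_std",
        # observed / expected spacing under complete spatial randomness
        "spacing_ratio",
    ]
    return [FeatureDescriptor(n, "spatial") for n in names]


SPATIAL_FEATURES: tuple[FeatureDescriptor, ...] = tuple(_spatial_descriptors())
assert len(SPATIAL_FEATURES) == 60, "spatial block must hold exactly 60 features"


def roi_feature_descriptors() -> tuple[FeatureDescriptor, ...]:
    """The frozen 960-entry ROI registry.

    Each nuclear feature contributes ``<name>_mean``, ``<name>_var`` and
    ``<name>_het_<stat>`` for the 8 co-occurrence statistics; they inherit the
    parent's block.  The 60 spatial globals close the vector.
    """
    out: list[FeatureDescriptor] = []
    for desc in NUCLEUS_FEATURES:
        for suffix in ROI_SUMMARY_SUFFIXES:
            out.append(
                FeatureDescriptor(f"{desc.name}_{suffix}", desc.block, desc.circular)
            )
    out.extend(SPATIAL_FEATURES)
    return tuple(out)


ROI_FEATURES: tuple[FeatureDescriptor, ...] = roi_feature_descriptors()
ROI_FEATURE_NAMES: tuple[str, ...] = tuple(d.name for d in ROI_FEATURES)
assert len(ROI_FEATURES) == 960, "ROI registry must hold exactly 960 features"
assert len(set(ROI_FEATURE_NAMES)) == 960


def nucleus_feature_blocks() -> dict[str, str]:
    return {d.name: d.block for d in NUCLEUS_FEATURES}


def roi_feature_blocks() -> dict[str, str]:
    return {d.name: d.block for d in ROI_FEATURES}


def export_registry(path: str | Path) -> None:
    """Write both registries to a JSON file (the versioned on-disk form)."""
    payload = {
        "version": 1,
        "nucleus_features": [
            {"name": d.name, "block": d.block, "circular": d.circular}
            for d in NUCLEUS_FEATURES
        ],
        "roi_features": [
            {"name": d.name, "block": d.block, "circular": d.circular}
            for d in ROI_FEATURES
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))
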