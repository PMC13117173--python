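import numpy as np
import pandas as pd
import pytest

from nucrisk.cflcm import (
    CFLCMConfig,
    ROIFeaturizer,
    auto_pitch,
    cflcm_matrix,
    quantize_equal_frequency,
    rasterize,
    roi_vector,
)
from nucrisk.morphometry import cooccurrence_stats
from nucrisk.registry import GLCM_OFFSETS, ROI_FEATURE_NAMES
from nucrisk.synth import CohortParams, generate_cohort

from conftest import make_nucleus_table


def brute_force_cflcm(cells, levels, G, offsets):
    """Independent oracle: enumerate every (i, j) nucleus pair for every offset."""
    cells = np.asarray(cells)
    levels = np.asarray(levels)
    n = len(cells)
    dr_all = cells[None, :, 0] - cells[:, None, 0]  # cells[j] - cells[i]
    dc_all = cells[None, :, 1] - cells[:, None, 1]
    P = np.zeros((G, G))
    for dr, dc in offsets:
        ii, jj = np.nonzero((dr_all == dr) & (dc_all == dc))
        for i, j in zip(ii, jj):
            P[levels[i], levels[j]] += 1
    P = P + P.T
    total = P.sum()
    return P / total if total > 0 else P


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def test_rasterize_square_corners():
    """4 nuclei on a square of side 2*pitch occupy the corners of a 3x3 grid."""
    pitch = 10.0
    xy = np.array([[0, 0], [20, 0], [0, 20], [20, 20]], dtype=float) + 0.5
    cells, shape, used_pitch, n_coll = rasterize(xy, pitch)
    assert shape == (3, 3)
    assert n_coll == 0
    assert {tuple(c) for c in cells} == {(0, 0), (0, 2), (2, 0), (2, 2)}


def test_rasterize_translation_invariance():
    xy = np.array([[3.0, 4.0], [18.0, 4.0], [3.0, 19.0], [33.0, 34.0]])
    c1, s1, _, _ = rasterize(xy, 10.0)
    c2, s2, _, _ = rasterize(xy + 500.0, 10.0)
    assert s1 == s2
    assert np.array_equal(c1, c2)


def test_rasterize_collision_resolution_deterministic():
    xy = np.array([[1.0, 1.0], [1.5, 1.2], [30.0, 30.0]])
    c1, _, _, n1 = rasterize(xy, 10.0)
    c2, _, _, n2 = rasterize(xy, 10.0)
    assert n1 == n2 == 1
    assert np.array_equal(c1, c2)
    assert len({tuple(c) for c in c1}) == 3  # invertible: one nucleus per cell


def test_auto_pitch_invertible_on_generated_rois():
    """Auto pitch keeps the nucleus -> cell map one-to-one on every default ROI.

    The occupied-cell count always equals the nucleus count (displaced
    nuclei are moved to free cells), and raw grid collisions stay a small
    fraction of the population.
    """
    cohort = generate_cohort(
        CohortParams(n_cases=10, rois_per_case=10, nuclei_per_roi=150, seed=21)
    )
    groups = list(cohort.nuclei.groupby(["case_id", "roi_id"]))
    coll_fractions = []
    for _, grp in groups:
        xy = grp[["centroid_x", "centroid_y"]].to_numpy(dtype=float)
        cells, _, _, n_coll = rasterize(xy, "auto")
        assert len({tuple(c) for c in cells}) == len(xy)
        coll_fractions.append(n_coll / len(xy))
    assert np.mean(coll_fractions) < 0.10


# ---------------------------------------------------------------------------
# co-occurrence matrices
# ---------------------------------------------------------------------------

def test_homogeneous_roi_matrix():
    """All nuclei share one value: no off-diagonal mass, contrast 0, ASM 1."""
    xy = np.array([[0.0, 0.0], [10.0, 0.0], [20.0, 0.0], [30.0, 0.0]])
    cells, shape, _, _ = rasterize(xy, 10.0)
    cfg = CFLCMConfig(levels=2, min_nuclei=1)
    P, degen = cflcm_matrix(cells, shape, np.ones(4), cfg)
    assert not degen
    assert cooccurrence_stats(P)["contrast"] == 0.0
    assert cooccurrence_stats(P)["asm"] == 1.0


def test_alternating_line_matrix():
    """4 nuclei in a line with alternating levels: matrix [[0,.5],[.5,0]], contrast 1."""
    xy = np.array([[0.0, 0.0], [10.0, 0.0], [20.0, 0.0], [30.0, 0.0]])
    cells, shape, _, _ = rasterize(xy, 10.0)
    cfg = CFLCMConfig(levels=2, offsets=((0, 1),), min_nuclei=1)
    P, _ = cflcm_matrix(cells, shape, np.array([0.0, 1.0, 0.0, 1.0]), cfg)
    assert np.allclose(P, [[0.0, 0.5], [0.5, 0.0]])
    assert cooccurrence_stats(P)["contrast"] == pytest.approx(1.0)


def test_matrix_position_permutation_invariance():
    """The matrix depends on positions + values, not on table row order."""
    rng = np.random.default_rng(4)
    xy = rng.uniform(0, 200, size=(30, 2))
    vals = rng.normal(size=30)
    cfg = CFLCMConfig(levels=4, min_nuclei=1)
    cells, shape, _, _ = rasterize(xy, 25.0)
    P1, _ = cflcm_matrix(cells, shape, vals, cfg, ids=np.arange(30))
    perm = rng.permutation(30)
    cells2, shape2, _, _ = rasterize(xy[perm], 25.0)
    P2, _ = cflcm_matrix(cells2, shape2, vals[perm], cfg, ids=perm)
    assert shape == shape2
    assert np.allclose(P1, P2)


def test_degenerate_no_neighbors_flagged():
    """Nuclei too far apart for any neighbour pair: flagged diagonal matrix."""
    xy = np.array([[0.0, 0.0], [500.0, 500.0], [900.0, 100.0]])
    cells, shape, _, _ = rasterize(xy, 10.0)
    cfg = CFLCMConfig(levels=3, min_nuclei=1)
    P, degen = cflcm_matrix(cells, shape, np.array([0.0, 1.0, 2.0]), cfg)
    assert degen
    assert P.sum() == pytest.approx(1.0)
    assert np.allclose(P, np.diag(np.diag(P)))


def test_matrix_matches_brute_force_randomized():
    """Implementation equals exhaustive pair enumeration on small random grids."""
    rng = np.random.default_rng(99)
    cfg_offsets = GLCM_OFFSETS
    for _ in range(50):
        rows, cols = rng.integers(2, 8, size=2)
        n = int(rng.integers(2, rows * cols + 1))
        flat = rng.choice(rows * cols, size=n, replace=False)
        cells = np.column_stack(np.divmod(flat, cols)).astype(np.intp)
        G = int(rng.integers(2, 5))
        levels = rng.integers(0, G, size=n)
        from nucrisk.cflcm import _neighbor_pairs, _stack_matrices

        pairs = _neighbor_pairs(cells, (rows, cols), cfg_offsets)
        P = _stack_matrices(levels.reshape(-1, 1), pairs, G)[0]
        ref = brute_force_cflcm([tuple(c) for c in cells], levels, G, cfg_offsets)
        if ref.sum() == 0:  # no neighbouring pair: implementation uses diagonal form
            continue
        assert np.allclose(P, ref, atol=1e-12)


def test_quantization_equal_frequency_and_ties():
    lv = quantize_equal_frequency(np.array([5.0, 1.0, 3.0, 9.0]), 2)
    assert list(lv) == [1, 0, 0, 1]
    # equal values must share a level: a constant feature is homogeneous
    lv2 = quantize_equal_frequency(np.array([1.0, 1.0, 1.0, 1.0]), 2, ids=np.array([4, 3, 2, 1]))
    assert list(lv2) == [0, 0, 0, 0]
    # partial ties collapse onto the tied group's first level
    lv3 = quantize_equal_frequency(np.array([2.0, 2.0, 1.0, 3.0]), 4)
    assert lv3[0] == lv3[1]


# ---------------------------------------------------------------------------
# full ROI vector
# ---------------------------------------------------------------------------

def test_roi_vector_length_and_order():
    df = make_nucleus_table(50, seed=2)
    vec = roi_vector(df)
    assert len(vec) == 960
    assert tuple(vec.index) == ROI_FEATURE_NAMES
    assert np.isfinite(vec.to_numpy()).all()


def test_identical_nuclei_on_lattice_zero_heterogeneity():
    """Identical nuclei: every variance and heterogeneity-contrast entry is 0."""
    n = 36
    side = 6
    xy = np.stack(np.meshgrid(np.arange(side), np.arange(side)), -1).reshape(-1, 2) * 30.0
    df = make_nucleus_table(n, seed=0)
    df["centroid_x"], df["centroid_y"] = xy[:, 0], xy[:, 1]
    from nucrisk.registry import NUCLEUS_FEATURE_NAMES

    for name in NUCLEUS_FEATURE_NAMES:
        df[name] = 0.5 if name != "orientation" else 45.0
    df["area"] = 300.0
    vec = roi_vector(df)
    var_cols = [f"{n}_var" for n in NUCLEUS_FEATURE_NAMES]
    het_contrast = [c for c in vec.index if c.endswith("_het_contrast")]
    assert all(vec[c] == pytest.approx(0.0, abs=1e-12) for c in var_cols)
    assert all(vec[c] == pytest.approx(0.0, abs=1e-12) for c in het_contrast)


def test_roi_vector_row_order_and_translation_invariance():
    df = make_nucleus_table(40, seed=6)
    v1 = roi_vector(df)
    shuffled = df.sample(frac=1.0, random_state=1)
    v2 = roi_vector(shuffled)
    translated = df.copy()
    translated["centroid_x"] += 500.0
    translated["centroid_y"] += 500.0
    v3 = roi_vector(translated)
    pd.testing.assert_series_equal(v1, v2)
    assert np.allclose(v1.to_numpy(), v3.to_numpy(), atol=1e-9)


def test_min_nuclei_enforced_and_skipped(recwarn):
    df = make_nucleus_table(5, seed=3)
    with pytest.raises(ValueError, match="min_nuclei"):
        roi_vector(df)
    out = ROIFeaturizer().fit().transform(df)
    assert len(out) == 0
    assert any("skipping ROI" in str(w.message) for w in recwarn.list)


def test_monotone_interleaving_contrast():
    """Mixing two level populations more finely never lowers heterogeneity contrast.

    On an 8-cell 1-D lattice, arrangements from fully segregated (aaaabbbb)
    to fully interleaved (abababab) give non-decreasing co-occurrence
    contrast.
    """
    xy = np.column_stack([np.arange(8) * 10.0, np.zeros(8)])
    cells, shape, _, _ = rasterize(xy, 10.0)
    cfg = CFLCMConfig(levels=2, offsets=((0, 1),), min_nuclei=1)
    arrangements = [
        [0, 0, 0, 0, 1, 1, 1, 1],  # 1 boundary
        [0, 0, 1, 1, 0, 0, 1, 1],  # 3 boundaries
        [0, 1, 0, 1, 0, 1, 0, 1],  # 7 boundaries
    ]
    contrasts = []
    for arr in arrangements:
        P, _ = cflcm_matrix(cells, shape, np.array(arr, dtype=float), cfg)
        contrasts.append(cooccurrence_stats(P)["contrast"])
    assert contrasts == sorted(contrasts)


def test_orientation_heterogeneity_separates_kappa():
    """Disordered ROIs (kappa=0) show higher orientation co-occurrence entropy
    than aligned ROIs (kappa -> inf) in >= 95 of 100 seeded pairs."""
    from nucrisk.cflcm import _neighbor_pairs, _stack_matrices, _stack_stats
    from nucrisk.cflcm import quantize_circular
    from nucrisk.synth import sample_centroids

    cfg = CFLCMConfig()
    wins = 0
    for seed in range(100):
        rng = np.random.default_rng(1000 + seed)
        xy = sample_centroids(200, 2048, rng)
        cells, shape, _, _ = rasterize(xy, "auto")
        pairs = _neighbor_pairs(cells, shape, cfg.offsets)
        uniform = rng.uniform(0, 180, size=200)
        mu = rng.uniform(0, 180)
        aligned = np.full(200, mu) + rng.normal(0, 0.5, size=200)
        ent = {}
        for name, theta in (("k0", uniform), ("kinf", aligned % 180.0)):
            lv = quantize_circular(theta, cfg.levels)
            P = _stack_matrices(lv.reshape(-1, 1), pairs, cfg.levels)
            ent[name] = _stack_stats(P)["entropy"][0]
        wins += ent["k0"] > ent["kinf"]
    assert wins >= 95
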