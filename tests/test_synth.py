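import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nucrisk.morphometry import validate_nucleus_table
from nucrisk.synth import (
    CohortParams,
    PlacementError,
    assign_category,
    generate_cohort,
    render_roi,
    sample_case_table,
    sample_centroids,
)


def circular_variance(theta_deg):
    ang = np.deg2rad(2.0 * np.asarray(theta_deg))
    return 1.0 - np.hypot(np.cos(ang).mean(), np.sin(ang).mean())


# ---------------------------------------------------------------------------
# parameters and categories
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "field,value",
    [
        ("n_cases", 0),
        ("baseline_hazard", 0.0),
        ("censor_rate", -1.0),
        ("effect_orientation", float("nan")),
        ("stage_probs", (0.5, 0.5, 0.5)),
    ],
)
def test_invalid_params_rejected_naming_field(field, value):
    with pytest.raises(ValueError, match=field.split("_")[0]):
        CohortParams(**{field: value})


def test_assign_category_bins():
    assert assign_category(True, 10.0) == 1
    assert assign_category(True, 24.0) == 2
    assert assign_category(True, 40.0) == 3
    assert assign_category(True, 80.0) == 4
    assert assign_category(False, 30.0) == 5
    assert assign_category(False, 50.0) == 6
    assert assign_category(False, 70.0) == 7
    assert assign_category(False, 100.0) == 8


def test_short_followup_nonrecurrent_excluded():
    with pytest.raises(ValueError, match="24 months"):
        assign_category(False, 20.0)


def test_categories_partition_generated_cohort(small_cohort):
    cats = small_cohort.cases["category"]
    assert cats.between(1, 8).all()
    rec = small_cohort.cases["event"]
    assert cats[rec].between(1, 4).all()
    assert cats[~rec].between(5, 8).all()


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def test_seed_reproducibility_byte_identical(tmp_path):
    p = CohortParams(n_cases=12, rois_per_case=2, nuclei_per_roi=30, seed=77)
    a = generate_cohort(p)
    b = generate_cohort(CohortParams(n_cases=12, rois_per_case=2, nuclei_per_roi=30, seed=77))
    a.write(tmp_path / "a")
    b.write(tmp_path / "b")
    for f in sorted((tmp_path / "a").iterdir()):
        assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()


def test_different_seed_differs():
    p1 = generate_cohort(CohortParams(n_cases=8, rois_per_case=1, nuclei_per_roi=20, seed=1))
    p2 = generate_cohort(CohortParams(n_cases=8, rois_per_case=1, nuclei_per_roi=20, seed=2))
    assert not p1.cases["time_months"].equals(p2.cases["time_months"])


def test_generated_tables_satisfy_registry_invariants(small_cohort):
    validate_nucleus_table(small_cohort.nuclei)
    assert small_cohort.cases["time_months"].gt(0).all()
    # inclusion rule: non-recurrent cases followed at least 24 months
    nonrec = small_cohort.cases[~small_cohort.cases["event"]]
    assert nonrec["time_months"].ge(24.0).all()


def test_null_effects_match_stage_only_model():
    """With zero morphology effects, event times depend on stage alone.

    Oracle: an independent stage-only exponential simulation with the same
    baseline hazard, stage increment and censoring; per-stage event times
    must be indistinguishable (two-sample KS p > 0.01).
    """
    params = CohortParams(
        n_cases=2000, effect_orientation=0.0, effect_texture=0.0, seed=31
    )
    cases = sample_case_table(params)
    rng = np.random.default_rng(123456)
    for stage_idx, stage in enumerate(("I", "II", "III")):
        obs = cases.loc[cases["stage"] == stage, "time_months"].to_numpy()
        lam = params.baseline_hazard * np.exp(params.stage_effect * stage_idx)
        m = 4000
        T = rng.exponential(1.0 / lam, size=m)
        C = np.minimum(rng.exponential(1.0 / params.censor_rate, size=m),
                       params.max_followup_months)
        t_ref = np.minimum(T, C)
        t_ref = np.maximum(t_ref, 0.5)
        keep = (T <= C) | (t_ref >= 24.0)
        _, p = stats.ks_2samp(obs, t_ref[keep])
        assert p > 0.01, f"stage {stage}"


def test_aggressiveness_correlates_with_orientation_heterogeneity():
    """Latent aggressiveness shows Spearman > 0.5 with observed ROI
    orientation disorder when the hazard link is strong."""
    params = CohortParams(
        n_cases=400, rois_per_case=2, nuclei_per_roi=60,
        effect_orientation=1.5, seed=41,
    )
    cohort = generate_cohort(params)
    per_roi = (
        cohort.nuclei.groupby(["case_id", "roi_id"])["orientation"]
        .apply(circular_variance)
    )
    obs = per_roi.groupby("case_id").mean().rename("circ_var")
    merged = cohort.cases.set_index("case_id").join(obs)
    rho, _ = stats.spearmanr(merged["aggressiveness"], merged["circ_var"])
    assert rho > 0.5


def test_monotone_latent_links():
    """The generator contract: aggressiveness lowers orientation concentration
    and raises texture contrast at the population level."""
    cases = sample_case_table(CohortParams(n_cases=1500, seed=9))
    r_kappa, _ = stats.spearmanr(cases["aggressiveness"], cases["orientation_concentration"])
    r_tex, _ = stats.spearmanr(cases["aggressiveness"], cases["texture_contrast_mean"])
    assert r_kappa < -0.4
    assert r_tex > 0.4


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def one_nucleus_table(area, ecc, theta, cx=100.0, cy=100.0):
    from conftest import make_nucleus_table

    df = make_nucleus_table(1, seed=0)
    df["centroid_x"], df["centroid_y"] = cx, cy
    df["area"], df["eccentricity"], df["orientation"] = area, ecc, theta
    return df


def test_render_single_circle_area():
    """One circular nucleus of radius 20: one label, area within 5% of pi r^2."""
    df = one_nucleus_table(np.pi * 20**2, 0.0, 0.0)
    _, mask, _ = render_roi(df, canvas_px=200)
    labels, counts = np.unique(mask[mask > 0], return_counts=True)
    assert len(labels) == 1
    assert abs(counts[0] - np.pi * 400) / (np.pi * 400) < 0.05


def test_render_mask_table_centroid_consistency():
    from conftest import make_nucleus_table
    from nucrisk.morphometry import extract_nuclei

    df = make_nucleus_table(30, seed=8, canvas=900.0)
    rgb, mask, table = render_roi(df, canvas_px=900, seed=3)
    ext = extract_nuclei(mask, rgb, exclude_border=False)
    merged = ext.merge(table, on="nucleus_id", suffixes=("_e", "_g"))
    assert len(merged) == 30
    assert (np.abs(merged["centroid_x_e"] - merged["centroid_x_g"]) < 2.0).all()
    assert (np.abs(merged["centroid_y_e"] - merged["centroid_y_g"]) < 2.0).all()


def test_render_aligned_orientations_low_circular_variance():
    """Fully aligned nuclei render to orientations with circular variance < 0.01."""
    from conftest import make_nucleus_table
    from nucrisk.morphometry import extract_nuclei

    df = make_nucleus_table(50, seed=10, orientation=np.full(50, 37.0), canvas=1200.0)
    df["eccentricity"] = 0.85
    df["area"] = 500.0
    rgb, mask, _ = render_roi(df, canvas_px=1200, seed=4)
    ext = extract_nuclei(mask, rgb, exclude_border=False)
    assert circular_variance(ext["orientation"]) < 0.01


def test_render_uniform_orientations_match_monte_carlo_interval():
    """kappa = 0 orientations: circular variance inside the uniform-draw
    reference interval (1000 Monte-Carlo draws of n = 50)."""
    from conftest import make_nucleus_table
    from nucrisk.morphometry import extract_nuclei

    mc_rng = np.random.default_rng(2024)
    ref = np.array([
        circular_variance(mc_rng.uniform(0, 180, size=50)) for _ in range(1000)
    ])
    lo, hi = np.quantile(ref, [0.005, 0.995])
    gen_rng = np.random.default_rng(15)
    theta = 0.5 * np.degrees(gen_rng.vonmises(0.0, 0.0, size=50)) % 180.0
    df = make_nucleus_table(50, seed=16, orientation=theta, canvas=1200.0)
    df["eccentricity"] = 0.85
    df["area"] = 500.0
    rgb, mask, _ = render_roi(df, canvas_px=1200, seed=5)
    ext = extract_nuclei(mask, rgb, exclude_border=False)
    assert lo <= circular_variance(ext["orientation"]) <= hi


def test_table_path_matches_image_path():
    """Extracting a rendered ROI recovers the generator's shape parameters:
    area within 5%; orientation within 3° for clearly elongated nuclei."""
    from nucrisk.morphometry import extract_nuclei

    co = generate_cohort(CohortParams(n_cases=1, rois_per_case=1, nuclei_per_roi=40, seed=7))
    rgb, mask, table = render_roi(co.nuclei, canvas_px=2048, seed=1)
    ext = extract_nuclei(mask, rgb, exclude_border=False)
    m = ext.merge(table, on="nucleus_id", suffixes=("_e", "_g"))
    assert len(m) == 40
    rel = np.abs(m["area_e"] - m["area_g"]) / m["area_g"]
    assert (rel < 0.05).all()
    do = np.abs(m["orientation_e"] - m["orientation_g"])
    do = np.minimum(do, 180 - do)
    elongated = m["eccentricity_g"] > 0.55
    assert elongated.sum() >= 10
    assert (do[elongated] < 3.0).all()


def test_render_overlap_exhaustion_reports_achieved():
    df = pd.concat(
        [one_nucleus_table(2000.0, 0.3, 10.0, cx=50.0, cy=50.0) for _ in range(3)],
        ignore_index=True,
    )
    df["nucleus_id"] = [1, 2, 3]
    with pytest.raises(PlacementError, match="1 of 3"):
        render_roi(df, canvas_px=100)


def test_sample_centroids_min_separation():
    rng = np.random.default_rng(0)
    xy = sample_centroids(150, 2048, rng)
    from scipy.spatial import cKDTree

    d, _ = cKDTree(xy).query(xy, k=2)
    assert d[:, 1].min() > 30.0  # well separated at default density
    assert (xy >= 0).all() and (xy <= 2048).all()
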