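"""Gradient profiles, Center of Mass, aspect and intratumoral densities."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_half_plane_map
from immunogradient.config import PipelineConfig
from immunogradient.hexgrid import (
    STROMA,
    TUMOR,
    TissueMap,
    assign_cells,
    build_hex_grid,
    compute_area_fractions,
)
from immunogradient.indicators import (
    INDICATOR_COLUMNS,
    GradientProfile,
    aspect_densities,
    center_of_mass,
    compute_indicator_set,
    gradient_profile,
    intratumoral_density,
)
from immunogradient.interface import (
    classify_hexagons,
    detect_tumor_edge,
    extract_interface_zone,
    rank_hexagons,
)


def profile(q_values, ranks=(-1, 0, 1)):
    return GradientProfile(
        marker="CD8", ranks=np.array(ranks), q=np.array(q_values, float),
        n_hex=np.ones(len(ranks), int),
    )


@pytest.mark.parametrize(
    "q,expected",
    [
        ((1, 1, 1), 0.0),  # symmetric profile
        ((0, 0, 5), 1.0),  # all mass at the tumor aspect
        ((5, 0, 0), -1.0),  # all mass at the stroma aspect
        ((2, 1, 1), -0.25),  # (-2 + 0 + 1) / 4
    ],
)
def test_center_of_mass_values(q, expected):
    assert center_of_mass(profile(q)) == pytest.approx(expected)


def test_center_of_mass_undefined_on_zero_profile():
    assert center_of_mass(profile((0, 0, 0))) is None
    assert center_of_mass(GradientProfile("CD8", np.array([]), np.array([]), np.array([]))) is None


@given(
    q=st.tuples(*[st.floats(0, 1e6, allow_nan=False) for _ in range(3)]),
    scale=st.floats(1e-3, 1e3),
)
@settings(max_examples=200, deadline=None)
def test_cm_range_and_scale_invariance(q, scale):
    cm = center_of_mass(profile(q))
    if cm is None:
        assert sum(q) == 0
    else:
        assert -1 - 1e-9 <= cm <= 1 + 1e-9
        cm_scaled = center_of_mass(profile(tuple(scale * v for v in q)))
        assert cm_scaled == pytest.approx(cm, abs=1e-9)


def test_cm_monotone_in_mass_transfer():
    """Moving cell mass from the S aspect to the T aspect increases CM."""
    rng = np.random.default_rng(7)
    for _ in range(100):
        q = rng.uniform(0.5, 10, 3)
        delta = rng.uniform(0.01, 0.4) * q[0]
        shifted = q + np.array([-delta, 0.0, delta])
        assert center_of_mass(profile(shifted)) > center_of_mass(profile(q))


def test_iz3_closed_form_matches_general_formula():
    rng = np.random.default_rng(42)
    for _ in range(1000):
        q = rng.uniform(0, 100, 3)
        if q.sum() == 0:
            continue
        closed = (q[2] - q[0]) / q.sum()
        assert center_of_mass(profile(q)) == pytest.approx(closed, rel=1e-12)


def _iz_with_counts(counts_by_rank, hex_side_um=40.0):
    """Half-plane fixture with per-rank counts injected directly."""
    tmap = make_half_plane_map()
    grid = compute_area_fractions(build_hex_grid(tmap, hex_side_um), tmap)
    assign_cells(grid, pd.DataFrame(columns=["marker", "x_um", "y_um"]), tmap)
    ranked = rank_hexagons(detect_tumor_edge(classify_hexagons(grid)))
    iz = extract_interface_zone(ranked, 3)
    for rank, c in counts_by_rank.items():
        iz.table.loc[iz.table["rank"] == rank, "n_cd8"] = c
    return iz


def test_gradient_profile_definition_and_groupby_oracle(rng):
    iz = _iz_with_counts({})
    iz.table["n_cd8"] = rng.integers(0, 30, len(iz.table))
    prof = gradient_profile(iz, "CD8")
    # independent flat re-computation
    area = iz.table["area_tumor_mm2"] + iz.table["area_stroma_mm2"]
    dens = iz.table["n_cd8"] / area
    usable = area >= 1e-3
    for r, qv, n in zip(prof.ranks, prof.q, prof.n_hex):
        sel = usable & (iz.table["rank"] == r)
        assert n == sel.sum()
        assert qv == pytest.approx(dens[sel].mean())


def test_identical_hexagons_give_constant_profile():
    iz = _iz_with_counts({-1: 4, 0: 4, 1: 4})
    # restrict to interior hexagons of equal area
    areas = iz.table["area_tumor_mm2"] + iz.table["area_stroma_mm2"]
    mode = areas.round(9).mode()[0]
    sub = iz.table[areas.round(9) == mode]
    prof_dens = sub["n_cd8"] / mode
    assert prof_dens.nunique() == 1


def test_counts_2_4_8_profile_proportional():
    iz = _iz_with_counts({-1: 2, 0: 4, 1: 8})
    # equal-area fixture: force a common analyzed-tissue area
    iz.table["area_tumor_mm2"] = 0.004
    iz.table["area_stroma_mm2"] = 0.0
    prof = gradient_profile(iz, "CD8")
    q = dict(zip(prof.ranks, prof.q))
    assert q[0] == pytest.approx(2 * q[-1]) and q[1] == pytest.approx(4 * q[-1])


def test_aspect_densities_equal_profile_values(rng):
    iz = _iz_with_counts({})
    iz.table["n_cd8"] = rng.integers(0, 20, len(iz.table))
    prof = gradient_profile(iz, "CD8")
    d_s, d_te, d_t = aspect_densities(iz, "CD8")
    q = dict(zip(prof.ranks, prof.q))
    assert (d_s, d_te, d_t) == (
        pytest.approx(q[-1]), pytest.approx(q[0]), pytest.approx(q[1])
    )


def test_zero_cells_everywhere():
    iz = _iz_with_counts({})
    assert aspect_densities(iz, "CD8") == (0.0, 0.0, 0.0)
    assert center_of_mass(gradient_profile(iz, "CD8")) is None


def test_intratumoral_density_uniform_poisson(rng):
    """Uniform intensity over tumor recovers the configured rate."""
    tmap = make_half_plane_map(n=400, pixel_size_um=4.0)  # tumor = 1.28 mm2
    lam = 5000.0  # cells/mm2
    area = tmap.class_area_mm2(TUMOR)
    n = rng.poisson(lam * area)
    x = rng.uniform(0, 800.0, n)  # tumor half: x in [0, 800)
    y = rng.uniform(0, 1600.0, n)
    cells = pd.DataFrame({"marker": "CD8", "x_um": x, "y_um": y})
    est = intratumoral_density(tmap, cells, "CD8")
    assert est == pytest.approx(lam, abs=3 * np.sqrt(lam / area))


def test_intratumoral_density_ignores_stromal_cells():
    tmap = make_half_plane_map()
    cells = pd.DataFrame({"marker": ["CD8"] * 5, "x_um": [500.0] * 5, "y_um": [100.0] * 5})
    assert intratumoral_density(tmap, cells, "CD8") == 0.0
    assert intratumoral_density(tmap, cells.iloc[:0], "CD8") == 0.0


def test_indicator_set_complete_and_deterministic(rng):
    tmap = make_half_plane_map(n=300, pixel_size_um=4.0)
    cells = pd.DataFrame(
        {
            "marker": rng.choice(["CD8", "CD20", "CD68"], 600),
            "x_um": rng.uniform(0, 1200, 600),
            "y_um": rng.uniform(0, 1200, 600),
        }
    )
    cfg = PipelineConfig(min_tumor_area_mm2=0.5)
    res1 = compute_indicator_set(tmap, cells, cfg)
    res2 = compute_indicator_set(tmap, cells, cfg)
    assert set(res1.indicators) == set(INDICATOR_COLUMNS)
    assert all(np.isfinite(v) for v in res1.indicators.values())
    assert not res1.flags
    assert res1.indicators == res2.indicators


def test_all_tumor_case_flags_interface_but_keeps_intratumoral():
    tmap = TissueMap(labels=np.full((200, 200), TUMOR, dtype=np.uint8), pixel_size_um=4.0)
    cells = pd.DataFrame({"marker": ["CD8"] * 10, "x_um": np.linspace(10, 700, 10), "y_um": np.full(10, 400.0)})
    res = compute_indicator_set(tmap, cells, PipelineConfig(min_tumor_area_mm2=0.1))
    assert res.flags["CD8_CM"] == "no_interface"
    assert np.isnan(res.indicators["CD8_CM"])
    assert res.indicators["INT_CD8"] == pytest.approx(10 / tmap.class_area_mm2(TUMOR))


def test_simulated_doubling_gradient(rng):
    """Cells drawn with intensity doubling per rank give d_T ~ 2 d_TE ~ 4 d_S."""
    tmap = make_half_plane_map(n=500, pixel_size_um=4.0)  # boundary at x=1000
    side = 40.0
    grid = compute_area_fractions(build_hex_grid(tmap, side), tmap)
    ranked = rank_hexagons(detect_tumor_edge(classify_hexagons(grid)))
    iz = extract_interface_zone(ranked, 3)
    # paint counts per hexagon from Poisson with rank-dependent intensity
    lam = {-1: 20000.0, 0: 40000.0, 1: 80000.0}
    areas = (iz.table["area_tumor_mm2"] + iz.table["area_stroma_mm2"]).to_numpy()
    counts = np.zeros(len(iz.table), int)
    for i, (r, a) in enumerate(zip(iz.table["rank"], areas)):
        counts[i] = rng.poisson(lam[int(r)] * a)
    iz.table["n_cd8"] = counts
    d_s, d_te, d_t = aspect_densities(iz, "CD8")
    assert d_te / d_s == pytest.approx(2.0, rel=0.25)
    assert d_t / d_te == pytest.approx(2.0, rel=0.25)
    cm = center_of_mass(gradient_profile(iz, "CD8"))
    assert cm == pytest.approx((800 - 200) / 1400, abs=0.05)
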