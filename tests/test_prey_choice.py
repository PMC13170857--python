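"""PERR, habitat classes, the two correlation models, and energetics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from zooarch.assemblage import table_from_records
from zooarch.prey_choice import (
    build_prey_profiles,
    classify_habitat,
    compute_perr,
    energy_by_slice,
    habitat_shares,
    model_a,
    model_b,
    pcm_site_report,
)


def _site(rows, site_id="A"):
    base = dict(site_id=site_id, site_name=site_id, tax_class="mammal", tax_family="f", mni=1)
    return table_from_records([dict(base, tax_group=r["taxon"], **r) for r in rows])


def _nutrition(entries):
    return pd.DataFrame(
        [{"taxon": t, "e_kcal": e, "h_minutes": h} for t, e, h in entries]
    )


# -- PERR ---------------------------------------------------------------


def test_perr_reference_and_scaling():
    assert compute_perr(60, 60) == 60.0
    assert compute_perr(1000, 30) == 2000.0
    assert compute_perr(2000, 30) == 2 * compute_perr(1000, 30)
    assert compute_perr(1000, 60) == compute_perr(1000, 30) / 2
    with pytest.raises(ValueError):
        compute_perr(0, 10)
    with pytest.raises(ValueError):
        compute_perr(10, -1)


# -- habitat ------------------------------------------------------------


@pytest.mark.parametrize(
    "biome,expected",
    [
        ("Marine", "marine"),
        ("Mixed water", "marine"),
        ("Mixed saltwater", "marine"),
        ("Coastal", "coastal"),
        ("Freshwater", "coastal"),
        ("Wetland", "coastal"),
        ("Forest", "terrestrial"),
        ("Mixed Land", "terrestrial"),
        ("Land", "terrestrial"),
    ],
)
def test_habitat_mapping(biome, expected):
    assert classify_habitat(biome) == expected


def test_unknown_biome_warns_and_classes_unknown():
    with pytest.warns(UserWarning, match="not in the controlled vocabulary"):
        assert classify_habitat("Lunar") == "unknown"


def test_habitat_shares_sum_to_one():
    table = _site(
        [
            dict(taxon="cattle", nisp=50, biome="Land"),
            dict(taxon="eel", nisp=30, biome="Mixed water"),
            dict(taxon="duck", nisp=20, biome="Wetland"),
        ]
    )
    nut = _nutrition([("cattle", 290000, 420), ("eel", 900, 10), ("duck", 1200, 15)])
    prof = build_prey_profiles(table, nut)
    shares = habitat_shares(prof)
    assert sum(shares.values()) == pytest.approx(1.0)
    assert shares["terrestrial"] == pytest.approx(0.5)


# -- profiles -----------------------------------------------------------


def test_profiles_join_and_ranks():
    table = _site(
        [
            dict(taxon="cattle", nisp=60, biome="Land"),
            dict(taxon="eel", nisp=30, biome="Mixed water"),
            dict(taxon="duck", nisp=10, biome="Wetland"),
        ]
    )
    nut = _nutrition([("cattle", 290000, 420), ("eel", 900, 10), ("duck", 1200, 15)])
    prof = build_prey_profiles(table, nut)
    assert prof["pct_nisp"].sum() == pytest.approx(1.0)
    by = prof.set_index("taxon")
    assert by.loc["cattle", "perr"] == pytest.approx(290000 / 420 * 60)
    assert by.loc["cattle", "nisp_rank"] == 3.0  # most abundant
    assert sorted(prof["perr_rank"]) == [1.0, 2.0, 3.0]


def test_missing_nutrition_listed_and_total_miss_raises():
    table = _site([dict(taxon="cattle", nisp=60, biome="Land"), dict(taxon="sphinx", nisp=5, biome="Land")])
    nut = _nutrition([("cattle", 290000, 420)])
    prof = build_prey_profiles(table, nut)
    assert prof.attrs["missing_nutrition"] == ["sphinx"]
    with pytest.raises(ValueError, match="sphinx"):
        build_prey_profiles(table, _nutrition([("unicorn", 1, 1)]))


# -- models -------------------------------------------------------------


def _prof(perr, nisp):
    n = len(perr)
    return pd.DataFrame(
        {
            "perr": perr,
            "nisp": nisp,
            "pct_nisp": np.asarray(nisp) / np.sum(nisp),
        }
    )


def test_model_a_perfect_proportionality_and_oracle(rng):
    perr = np.array([10.0, 20.0, 40.0, 80.0])
    assert model_a(_prof(perr, perr * 3)).correlation == pytest.approx(1.0)
    x = rng.uniform(1, 100, 12)
    y = rng.integers(1, 500, 12)
    res = model_a(_prof(x, y))
    xc, yc = x - x.mean(), y / y.sum() - (y / y.sum()).mean()
    r = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
    assert res.correlation == pytest.approx(r, abs=1e-12)


def test_model_a_degenerate_flagged():
    res = model_a(_prof([5.0, 5.0, 5.0], [1, 2, 3]))
    assert res.undefined and np.isnan(res.correlation)


def test_model_b_identical_and_reversed_orders():
    perr = [1.0, 2.0, 3.0, 4.0, 5.0]
    assert model_b(_prof(perr, [10, 20, 30, 40, 50])).correlation == pytest.approx(1.0)
    assert model_b(_prof(perr, [50, 40, 30, 20, 10])).correlation == pytest.approx(-1.0)


def test_model_b_invariant_to_monotone_transform_model_a_not(rng):
    perr = rng.uniform(1, 100, 10)
    nisp = rng.integers(1, 300, 10)
    b1 = model_b(_prof(perr, nisp)).correlation
    b2 = model_b(_prof(np.exp(perr / 50), nisp)).correlation
    assert b1 == pytest.approx(b2, abs=1e-12)
    a1 = model_a(_prof(perr, nisp)).correlation
    a2 = model_a(_prof(np.exp(perr / 50), nisp)).correlation
    assert abs(a1 - a2) > 1e-6


def test_model_b_matches_scipy_spearman(rng):
    perr = rng.uniform(1, 100, 15)
    nisp = rng.integers(1, 50, 15)  # ties likely
    res = model_b(_prof(perr, nisp))
    rho, p = stats.spearmanr(perr, nisp)
    assert res.correlation == pytest.approx(rho) and res.p_value == pytest.approx(p)


def test_models_need_three_taxa():
    with pytest.raises(ValueError):
        model_a(_prof([1.0, 2.0], [1, 2]))


# -- site report --------------------------------------------------------


def test_constructed_rank_agreement_gives_rho_one():
    rows = [dict(taxon=f"t{i}", nisp=10 * (i + 1), biome="Land") for i in range(6)]
    table = _site(rows)
    nut = _nutrition([(f"t{i}", 1000.0 * (i + 1), 10.0) for i in range(6)])
    rep = pcm_site_report(table, nut)
    assert rep["model_b"].correlation == pytest.approx(1.0)
    assert rep["model_b"].p_value < 0.01
    assert 0 <= rep["d_group"] <= 1


def test_noise_degrades_rank_correlation_on_average(rng):
    """Injecting abundance noise weakens the PERR-abundance coupling."""
    perr = np.arange(1.0, 13.0)
    mean_rho = []
    for noise in (0.0, 2.0, 6.0):
        rhos = []
        for _ in range(40):
            nisp = np.argsort(np.argsort(perr + rng.normal(0, noise, 12))) * 10 + 10
            rhos.append(model_b(_prof(perr, nisp)).correlation)
        mean_rho.append(np.mean(rhos))
    assert mean_rho[0] == pytest.approx(1.0)
    assert mean_rho[0] > mean_rho[1] > mean_rho[2]


# -- energetics ---------------------------------------------------------


def _two_slice_table(e_by_slice):
    rows = []
    for sl, (site, taxa) in e_by_slice.items():
        for i, taxon in enumerate(taxa):
            rows.append(
                dict(site_id=site, site_name=site, taxon=taxon, tax_class="fish",
                     tax_family="f", tax_group=taxon, nisp=20, mni=1, biome="Marine")
            )
    return table_from_records(rows)


def test_identical_composition_gives_p_one():
    table = _two_slice_table(
        {"Early Neolithic": ("S1", ["eel", "cod", "perch"]), "Bronze Age": ("S2", ["eel", "cod", "perch"])}
    )
    nut = _nutrition([("eel", 900, 10), ("cod", 1300, 15), ("perch", 200, 6)])
    out = energy_by_slice(table, nut, {"S1": "Early Neolithic", "S2": "Bronze Age"})
    res = out["pairwise_tests"]["Early Neolithic vs Bronze Age"]
    assert res.p_value == pytest.approx(1.0)


def test_missing_top_energy_taxon_lowers_mean():
    table = _two_slice_table(
        {"Early Neolithic": ("S1", ["eel", "cod", "perch"]), "Bronze Age": ("S2", ["cod", "perch"])}
    )
    nut = _nutrition([("eel", 9000, 10), ("cod", 1300, 15), ("perch", 200, 6)])
    out = energy_by_slice(table, nut, {"S1": "Early Neolithic", "S2": "Bronze Age"})
    s = out["summaries"]
    assert s["Bronze Age"]["mean_kcal"] < s["Early Neolithic"]["mean_kcal"]


def test_small_slice_skipped_with_flag():
    table = _two_slice_table({"Early Neolithic": ("S1", ["eel", "cod", "perch"]), "Bronze Age": ("S2", ["cod"])})
    nut = _nutrition([("eel", 900, 10), ("cod", 1300, 15), ("perch", 200, 6)])
    out = energy_by_slice(table, nut, {"S1": "Early Neolithic", "S2": "Bronze Age"})
    assert "skipped" in out["pairwise_tests"]["Early Neolithic vs Bronze Age"]


def test_two_slice_welch_matches_hand_computation():
    table = _two_slice_table(
        {"Early Neolithic": ("S1", ["a", "b", "c"]), "Bronze Age": ("S2", ["d", "e", "f"])}
    )
    nut = _nutrition([("a", 100, 1), ("b", 200, 1), ("c", 300, 1), ("d", 400, 1), ("e", 600, 1), ("f", 800, 1)])
    out = energy_by_slice(table, nut, {"S1": "Early Neolithic", "S2": "Bronze Age"})
    res = out["pairwise_tests"]["Early Neolithic vs Bronze Age"]
    expect = stats.ttest_ind([100, 200, 300], [400, 600, 800], equal_var=False)
    assert res.statistic == pytest.approx(expect.statistic)
    assert res.p_value == pytest.approx(expect.pvalue)
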