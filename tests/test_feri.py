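"""Trait matrices and correspondence analysis for habitat reconstruction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import random_assemblage
from zooarch.assemblage import table_from_records
from zooarch.feri import (
    BinaryTraitMatrix,
    TraitMap,
    build_trait_matrix,
    correspondence_analysis,
    detrend,
    feri_report,
)
from zooarch.synthetic import simulate_gradient_matrix


def _table(rows):
    base = dict(site_name="s", tax_family="f", tax_group="g", mni=1, biome="Marine")
    return table_from_records([dict(base, **r) for r in rows])


def _traits(mapping):
    tm = TraitMap()
    for taxon, cats in mapping.items():
        tm.salinity[taxon.casefold()] = frozenset(cats)
    return tm


# -- trait matrix -------------------------------------------------------


def test_fish_nisp_threshold_is_strict_above_14():
    table = _table(
        [
            dict(site_id="low", taxon="eel", tax_class="fish", nisp=14),
            dict(site_id="ok", taxon="eel", tax_class="fish", nisp=15),
        ]
    )
    m = build_trait_matrix(table, _traits({"eel": {"freshwater"}}), "salinity")
    assert list(m.values.index) == ["ok"]


def test_single_site_single_category():
    table = _table([dict(site_id="A", taxon="cod", tax_class="fish", nisp=20)])
    m = build_trait_matrix(table, _traits({"cod": {"marine"}}), "salinity")
    assert m.values.shape == (1, 1) and m.values.iloc[0, 0] == 1


def test_uncovered_taxa_listed_not_silently_dropped():
    table = _table(
        [
            dict(site_id="A", taxon="cod", tax_class="fish", nisp=20),
            dict(site_id="A", taxon="mystery fish", tax_class="fish", nisp=5),
        ]
    )
    m = build_trait_matrix(table, _traits({"cod": {"marine"}}), "salinity")
    assert m.excluded_taxa == ["mystery fish"]


def test_no_qualifying_assemblage_is_an_error():
    table = _table([dict(site_id="A", taxon="eel", tax_class="fish", nisp=3)])
    with pytest.raises(ValueError, match="fish NISP"):
        build_trait_matrix(table, _traits({"eel": {"freshwater"}}), "salinity")


def test_matrix_matches_double_loop_oracle(rng):
    table = random_assemblage(rng, n_sites=6, n_taxa=10, max_count=40)
    fish_taxa = sorted(set(table.records[table.records["tax_class"] == "fish"]["taxon"]))
    cats = ["marine", "brackish", "freshwater"]
    tm = _traits({t: {cats[i % 3], cats[(i + 1) % 3]} for i, t in enumerate(fish_taxa)})
    m = build_trait_matrix(table, tm, "salinity", min_fish_nisp=1)
    for site in m.values.index:
        sub = table.records[(table.records["site_id"] == site) & (table.records["tax_class"] == "fish")]
        for cat in m.values.columns:
            expect = int(
                any(cat in tm.categories(t, "salinity") for t in sub[sub["nisp"] > 0]["taxon"])
            )
            assert m.values.loc[site, cat] == expect


def test_combined_axis_concatenates_prefixed_columns():
    tm = TraitMap(
        salinity={"cod": frozenset({"marine"})},
        sediment={"cod": frozenset({"rock"}), "eel": frozenset({"mud"})},
    )
    table = _table(
        [
            dict(site_id="A", taxon="cod", tax_class="fish", nisp=20),
            dict(site_id="B", taxon="eel", tax_class="fish", nisp=20),
        ]
    )
    m = build_trait_matrix(table, tm, "combined")
    assert set(m.values.columns) == {"salinity:marine", "sediment:rock", "sediment:mud"}


# -- correspondence analysis --------------------------------------------


def _ca_eigen_oracle(M):
    """Independent route: eigenvalues of S Sᵀ for the chi-square residual."""
    N = np.asarray(M, dtype=float)
    n = N.sum()
    P = N / n
    r, c = P.sum(1), P.sum(0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    ev = np.linalg.eigvalsh(S @ S.T)[::-1]
    return ev[ev > 1e-10][: min(N.shape) - 1]


def test_block_diagonal_gives_unit_first_eigenvalue():
    M = pd.DataFrame(
        [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]],
        index=list("abcd"),
        columns=list("wxyz"),
    )
    res = correspondence_analysis(M)
    assert res.eigenvalues[0] == pytest.approx(1.0)


def test_uniform_matrix_has_no_structure():
    M = pd.DataFrame(np.ones((4, 5)), index=list("abcd"))
    res = correspondence_analysis(M)
    assert len(res.eigenvalues) == 0 and res.total_inertia == pytest.approx(0.0, abs=1e-12)


def _random_binary(rng, shape):
    while True:
        M = (rng.random(shape) < 0.4).astype(int)
        if M.sum(axis=0).min() > 0 and M.sum(axis=1).min() > 0:
            return pd.DataFrame(M)


def test_eigenvalues_match_independent_oracle(rng):
    for _ in range(30):
        M = _random_binary(rng, (int(rng.integers(4, 10)), int(rng.integers(3, 8))))
        res = correspondence_analysis(M)
        expect = _ca_eigen_oracle(M)
        assert np.allclose(res.eigenvalues, expect, atol=1e-9)
        assert (res.eigenvalues >= -1e-12).all() and (res.eigenvalues <= 1 + 1e-9).all()
        assert (np.diff(res.eigenvalues) <= 1e-12).all()


def test_eigenvalues_match_skbio_cross_check(rng):
    skbio_ord = pytest.importorskip("skbio.stats.ordination")
    M = _random_binary(rng, (8, 6))
    res = correspondence_analysis(M)
    other = skbio_ord.ca(M.astype(float))
    assert np.allclose(res.eigenvalues, other.eigvals.to_numpy()[: len(res.eigenvalues)], atol=1e-8)


def test_total_inertia_is_chisq_over_n(rng):
    M = _random_binary(rng, (7, 5))
    res = correspondence_analysis(M)
    chi2 = stats.chi2_contingency(M.to_numpy(), correction=False).statistic
    assert res.total_inertia == pytest.approx(chi2 / M.to_numpy().sum(), abs=1e-9)
    assert res.eigenvalues.sum() == pytest.approx(res.total_inertia, abs=1e-9)


def test_eigenvalues_invariant_to_permutation_and_duplication(rng):
    M = _random_binary(rng, (6, 5))
    res = correspondence_analysis(M)
    perm = M.iloc[rng.permutation(6), rng.permutation(5)]
    res_p = correspondence_analysis(perm)
    assert np.allclose(res.eigenvalues, res_p.eigenvalues, atol=1e-9)
    # duplicating a row of well-separated gradient data keeps the ordering
    # of the original rows (margins shift, but not enough to swap ranks)
    G, _ = simulate_gradient_matrix(n_sites=12, n_categories=8, seed=9)
    res_g = correspondence_analysis(G)
    res_d = correspondence_analysis(pd.concat([G, G.iloc[[0]].set_axis(["dup"])]))
    order_before = np.argsort(res_g.row_scores["CA1"].to_numpy()).tolist()
    order_after = np.argsort(res_d.row_scores["CA1"].to_numpy()[:12]).tolist()
    assert order_before in (order_after, order_after[::-1])


def test_degenerate_inputs_rejected():
    with pytest.raises(ValueError):
        correspondence_analysis(pd.DataFrame([[1, 0], [0, 0]]))  # zero row
    with pytest.raises(ValueError):
        correspondence_analysis(pd.DataFrame([[1], [1]]))  # single column


# -- detrending ---------------------------------------------------------


def test_detrend_requires_two_axes_and_segments():
    M = pd.DataFrame([[1, 1, 0], [0, 1, 1], [1, 0, 1], [1, 1, 1]])
    res = correspondence_analysis(M)
    with pytest.raises(ValueError):
        detrend(res, segments=1)


def test_detrend_no_arch_leaves_scores_unchanged():
    """A balanced two-factor design has no arch: axis-2 means vanish
    within every axis-1 segment, so detrending is a no-op."""
    blocks = pd.DataFrame(
        [
            [1, 0, 1, 0],
            [1, 0, 0, 1],
            [0, 1, 1, 0],
            [0, 1, 0, 1],
        ],
        index=list("abcd"),
    )
    res = correspondence_analysis(blocks)
    det = detrend(res, segments=2)
    delta = np.abs(det.row_scores.to_numpy() - res.row_scores.to_numpy()).max()
    assert delta < 1e-6


def test_detrend_reduces_arch_on_single_gradient():
    M, _ = simulate_gradient_matrix(n_sites=120, n_categories=15, seed=5)
    ca = correspondence_analysis(M)
    a1 = ca.row_scores["CA1"].to_numpy()
    a2 = ca.row_scores["CA2"].to_numpy()
    det = detrend(ca)
    b2 = det.row_scores["CA2"].to_numpy()
    arch_before = abs(np.corrcoef(a1, a2**2)[0, 1])
    arch_after = abs(np.corrcoef(a1, b2**2)[0, 1])
    assert arch_after < arch_before
    # the sharper quadratic-signature check
    assert abs(np.corrcoef(a1**2, b2)[0, 1]) < abs(np.corrcoef(a1**2, a2)[0, 1]) / 3
    assert np.allclose(det.eigenvalues, ca.eigenvalues)  # axis-1 inertia untouched


def test_axis1_recovers_planted_gradient():
    for seed in range(5):
        M, pos = simulate_gradient_matrix(n_sites=25, n_categories=12, seed=seed)
        res = correspondence_analysis(M)
        rho = stats.spearmanr(res.row_scores["CA1"].to_numpy(), pos).statistic
        assert abs(rho) >= 0.9


# -- report -------------------------------------------------------------


def test_report_serializes_eigenvalues_and_scores():
    M, pos = simulate_gradient_matrix(n_sites=10, n_categories=6, seed=1)
    res = correspondence_analysis(M)
    rep = feri_report({"salinity": res}, context={M.index[0]: "fjord"})
    ax = rep["axes"]["salinity"]
    assert ax["method"] == "CA"
    assert len(ax["eigenvalues"]) == len(res.eigenvalues)
    assert ax["site_scores"][M.index[0]]["context"] == "fjord"


def test_report_two_axis_run_reports_both_eigenvalue_sets():
    Ms, _ = simulate_gradient_matrix(n_sites=12, n_categories=6, seed=2)
    Md, _ = simulate_gradient_matrix(n_sites=12, n_categories=7, seed=3)
    rep = feri_report(
        {"salinity": correspondence_analysis(Ms), "sediment": correspondence_analysis(Md)}
    )
    assert set(rep["axes"]) == {"salinity", "sediment"}
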