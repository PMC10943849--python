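"""OHRB screening, diversity, Bray-Curtis/PCoA, networks, NST, ANOVA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pcbdechlor.ecology import (
    AbundanceTable,
    EcologyError,
    alpha_diversity,
    bray_curtis,
    build_network,
    compare_groups,
    nst,
    ohrb_screen,
    pcoa,
    prevalence_filter,
    topology,
)
from pcbdechlor.simulate import CommunitySimConfig, simulate_communities


def _table(data: dict, mode="counts", groups=None, taxonomy=None):
    df = pd.DataFrame(data).T  # rows = taxa
    return AbundanceTable(
        data=df,
        taxonomy=None if taxonomy is None else pd.Series(taxonomy),
        groups=None if groups is None else pd.Series(groups), mode=mode)


# --- OHRB screening -----------------------------------------------------

def test_any_listed_taxon_counts_as_present():
    t = _table({"Dehalobacter": [1, 0], "Genus_A": [9999, 100]})
    t.data.columns = ["s1", "s2"]
    screen = ohrb_screen(t)
    assert bool(screen.loc["s1", "present"]) is True
    assert bool(screen.loc["s2", "present"]) is False
    assert screen.loc["s1", "ohrb_relabund"] == pytest.approx(1 / 10000)


def test_planted_prevalence_recovered_exactly():
    cfg = CommunitySimConfig(n_taxa=40, samples_per_group=20, depth=2000,
                             ohrb_prevalence=0.5, seed=11)
    table, truth = simulate_communities(cfg)
    screen = ohrb_screen(table)
    assert screen.attrs["occurrence_frequency"] == pytest.approx(0.5)
    assert (screen["present"].values == truth["ohrb_present"].values).all()


def test_no_listed_taxa_gives_zero_frequency():
    t = _table({"Genus_A": [5, 5], "Genus_B": [1, 2]})
    assert ohrb_screen(t).attrs["occurrence_frequency"] == 0.0


# --- alpha diversity ----------------------------------------------------

def test_uniform_shannon_is_log_richness():
    richness, h, j = alpha_diversity([10] * 10)
    assert richness == 10
    assert h == pytest.approx(math.log(10), abs=1e-12)
    assert j == pytest.approx(1.0, abs=1e-12)


def test_single_taxon_zero_entropy():
    richness, h, j = alpha_diversity([0, 42, 0])
    assert (richness, h) == (1, 0.0)
    assert math.isnan(j)


def test_shannon_direct_evaluation():
    _, h, _ = alpha_diversity([4, 3, 2, 1])
    assert h == pytest.approx(1.27985, abs=1e-4)


def test_alpha_diversity_rejects_zero_total():
    with pytest.raises(EcologyError):
        alpha_diversity([0, 0])


# --- Bray-Curtis --------------------------------------------------------

@pytest.mark.parametrize("x,y,expected", [
    ([1, 2, 3], [1, 2, 3], 0.0),
    ([1, 1, 0, 0], [0, 0, 2, 5], 1.0),
    ([2, 1, 0], [0, 1, 2], 4 / 6),
])
def test_bray_curtis_formula(x, y, expected):
    assert bray_curtis(x, y) == pytest.approx(expected, abs=1e-12)


def test_bray_curtis_undefined_for_double_zero():
    with pytest.raises(EcologyError):
        bray_curtis([0, 0], [0, 0])


# --- PCoA ---------------------------------------------------------------

def test_pcoa_reconstructs_euclidean_distances():
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(7, 2))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    res = pcoa(d, k=2)
    rec = np.linalg.norm(res.coordinates[:, None] - res.coordinates[None, :],
                         axis=-1)
    assert np.allclose(rec, d, atol=1e-8)


def test_pcoa_equilateral_degenerate_eigenvalues():
    d = np.ones((3, 3)) - np.eye(3)
    res = pcoa(d, k=2)
    pos = res.eigenvalues[res.eigenvalues > 1e-12]
    assert len(pos) == 2
    assert pos[0] == pytest.approx(pos[1], rel=1e-10)


def test_pcoa_matches_independent_eigensolver():
    """Axis eigenvalues agree with scikit-bio's PCoA on a random
    Bray-Curtis matrix (independent implementation)."""
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(5)
    counts = rng.integers(0, 50, size=(6, 12))
    from scipy.spatial.distance import pdist, squareform
    d = squareform(pdist(counts, metric="braycurtis"))
    res = pcoa(d, k=3)
    ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d))
    ref_eigs = np.sort(np.asarray(ref.eigvals))[::-1]
    mine = np.sort(res.eigenvalues)[::-1]
    assert np.allclose(mine[:3], ref_eigs[:3], atol=1e-8)


def test_pcoa_rejects_asymmetric_input():
    d = np.array([[0.0, 1.0], [0.5, 0.0]])
    with pytest.raises(EcologyError):
        pcoa(d)


# --- prevalence filter --------------------------------------------------

def test_prevalence_boundary_strict_at_half():
    n = 21
    data = {
        "ten_of_21": [3] * 10 + [0] * 11,    # 47.6% -> removed
        "eleven_of_21": [3] * 11 + [0] * 10,  # 52.4% -> kept
        "singleton": [1] + [0] * 20,          # total count 1 -> removed
        "common": [5] * 21,
    }
    t = _table(data)
    kept = prevalence_filter(t).taxa
    assert "eleven_of_21" in kept and "common" in kept
    assert "ten_of_21" not in kept and "singleton" not in kept


# --- networks -----------------------------------------------------------

def _planted_table(n=21, seed=0):
    rng = np.random.default_rng(seed)
    base = rng.lognormal(3, 1, size=(n, 30))
    z = rng.standard_normal(n)
    base[:, 0] = 200 * np.exp(1.0 * z)
    base[:, 1] = 200 * np.exp(1.0 * (0.95 * z
                                     + math.sqrt(1 - 0.95 ** 2)
                                     * rng.standard_normal(n)))
    counts = np.rint(base).astype(int)
    df = pd.DataFrame(counts.T, index=[f"g{i}" for i in range(30)],
                      columns=[f"s{j}" for j in range(n)])
    return AbundanceTable(data=df)


def test_planted_pair_recovered_as_edge():
    net = build_network(_planted_table())
    assert net.graph.has_edge("g0", "g1")
    for u, v, d in net.graph.edges(data=True):
        assert abs(d["rho"]) > 0.6 and d["p_adj"] < 0.01


def test_bh_monotonicity_edge_counts():
    net = build_network(_planted_table(seed=4))
    raw = ((net.edges["rho"].abs() > net.rho_cutoff)
           & (net.edges["p_raw"] < net.alpha)).sum()
    assert net.n_edges <= raw


def test_constant_genus_excluded_with_warning():
    t = _table({"g1": [1, 2, 3, 4, 5], "g2": [5, 4, 3, 2, 1],
                "g3": [2, 2, 2, 2, 2]})
    with pytest.warns(UserWarning, match="constant"):
        net = build_network(t)
    assert "g3" not in net.tested_taxa


def test_exact_permutation_p_for_perfect_monotone():
    """At n = 6 a perfect rank correlation has exact two-sided permutation
    p = 2/6! (identity and reversal only)."""
    # constant sample totals so relative abundances keep the count ranks
    g1 = [1, 2, 3, 4, 6, 8]
    g2 = [2, 3, 5, 8, 9, 11]
    filler = [30 - a - b for a, b in zip(g1, g2)]
    t = _table({"g1": g1, "g2": g2, "g3": filler})
    net = build_network(t, rho_cutoff=0.5, alpha=0.5)
    row = net.edges.set_index(["source", "target"]).loc[("g1", "g2")]
    assert row["p_raw"] == pytest.approx(2 / math.factorial(6), rel=1e-9)


def test_topology_triangle_and_empty():
    net = build_network(_planted_table())
    n, L, k = topology(net)
    assert (n, L) == (net.graph.number_of_nodes(), net.graph.number_of_edges())
    assert k == pytest.approx(2 * L / n if n else 0.0)
    # independent recount from the emitted edge table
    sig = net.edges[net.edges["edge"]]
    assert L == len(sig)
    assert n == len(set(sig["source"]) | set(sig["target"]))


# --- NST ----------------------------------------------------------------

def test_nst_bounded_and_reproducible():
    cfg = CommunitySimConfig(n_taxa=50, samples_per_group=8, depth=1000,
                             seed=2)
    table, _ = simulate_communities(cfg)
    a = nst(table, B=200, seed=5)
    b = nst(table, B=200, seed=5)
    assert 0.0 <= a.nst <= 100.0
    assert a.nst == b.nst
    assert (a.pairs["ratio"].values == b.pairs["ratio"].values).all()


def test_nst_invariant_to_taxon_renaming():
    cfg = CommunitySimConfig(n_taxa=30, samples_per_group=6, depth=500, seed=3)
    table, _ = simulate_communities(cfg)
    renamed = AbundanceTable(
        data=table.data.set_axis([f"x{i}" for i in range(len(table.taxa))]),
        mode="counts")
    assert nst(table, B=100, seed=1).nst == nst(renamed, B=100, seed=1).nst


def test_nst_requires_integer_counts():
    df = pd.DataFrame(np.full((3, 4), 1.5), index=list("abc"),
                      columns=list("wxyz"))
    with pytest.raises(EcologyError):
        nst(AbundanceTable(data=df, mode="counts"), B=100)


def test_nst_low_b_warns():
    cfg = CommunitySimConfig(n_taxa=20, samples_per_group=4, depth=500, seed=9)
    table, _ = simulate_communities(cfg)
    with pytest.warns(UserWarning, match="randomizations"):
        nst(table, B=50, seed=0)


# --- ANOVA --------------------------------------------------------------

def test_anova_null_case():
    rng = np.random.default_rng(0)
    v = rng.normal(0, 1, 40)
    f, p = compare_groups(v, np.repeat(["a", "b"], 20))
    assert p > 0.05


def test_anova_separated_groups():
    rng = np.random.default_rng(1)
    v = np.concatenate([rng.normal(0, 1, 20), rng.normal(5, 1, 20)])
    _, p = compare_groups(v, np.repeat(["a", "b"], 20))
    assert p < 1e-3


def test_anova_matches_textbook_formula():
    values = np.array([3.0, 4.0, 5.0, 6.0, 8.0, 10.0])
    labels = np.array(["a", "a", "a", "b", "b", "b"])
    groups = [values[labels == g] for g in ("a", "b")]
    grand = values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    f_hand = (ss_between / 1) / (ss_within / 4)
    f, _ = compare_groups(values, labels)
    assert f == pytest.approx(f_hand, rel=1e-12)


def test_anova_rejects_degenerate_groups():
    with pytest.raises(EcologyError):
        compare_groups([1.0, 2.0, 3.0], ["a", "a", "b"])
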