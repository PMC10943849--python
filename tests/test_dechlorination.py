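"""Cl/PCB statistics, activity calling, lag, preference, pathway fluxes."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcbdechlor.congeners import BIPHENYL
from pcbdechlor.dechlorination import (
    CongenerProfile,
    DechlorError,
    MicrocosmSeries,
    attribute_fluxes,
    build_pathway_graph,
    call_activity,
    cl_per_pcb,
    delta_cl,
    lag_time,
    positional_cl_per_pcb,
    preference_class,
)


def profile(day, values, sample="S"):
    return CongenerProfile(sample_id=sample, day=day, values=values)


def series(*profiles, microcosm="M", control=None):
    return MicrocosmSeries(microcosm_id=microcosm, profiles=tuple(profiles),
                           control=control)


# --- Cl/PCB -------------------------------------------------------------

@pytest.mark.parametrize("values,expected", [
    ({"23456-23456": 1.0}, 10.0),
    ({"245-25": 0.5, "25-25": 0.5}, 4.5),
    ({"2345-245": 2.0, "245-245": 1.0, "25-25": 1.0}, 6.0),  # (14+6+4)/4
])
def test_cl_per_pcb_weighted_mean(values, expected):
    assert cl_per_pcb(profile(0, values)) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("values,expected", [
    ({"23456-23456": 1.0}, (4, 4, 2)),
    ({"25-25": 1.0}, (2, 2, 0)),
    ({"2345-245": 1.0, "25-25": 1.0}, (2.0, 2.5, 1.0)),
])
def test_positional_cl_per_pcb(values, expected):
    assert positional_cl_per_pcb(profile(0, values)) == \
        pytest.approx(expected, abs=1e-12)


def test_cl_per_pcb_scale_invariant():
    values = {"2345-245": 2.0, "245-245": 1.0, "25-25": 1.0}
    scaled = {k: 7.3 * v for k, v in values.items()}
    assert cl_per_pcb(profile(0, values)) == \
        pytest.approx(cl_per_pcb(profile(0, scaled)), rel=1e-12)


def test_all_zero_profile_undefined():
    with pytest.raises(DechlorError):
        cl_per_pcb(profile(0, {"25-25": 0.0}))


def test_biphenyl_counts_zero_chlorines():
    p = profile(0, {"25-25": 1.0, BIPHENYL: 1.0})
    assert cl_per_pcb(p) == pytest.approx(2.0)


congener_labels = st.sampled_from(
    ["2345-245", "245-245", "234-245", "25-25", "245-25", "236-25",
     "2345-2356", "4-0", "23456-23456"])
profiles_strategy = st.dictionaries(
    congener_labels, st.floats(0.01, 100.0), min_size=1, max_size=6)


@given(v0=profiles_strategy, v1=profiles_strategy)
@settings(max_examples=100, deadline=None)
def test_delta_equals_sum_of_positional_deltas(v0, v1):
    s = series(profile(0, v0), profile(10, v1))
    d = delta_cl(s, 10)
    assert d["total"] == pytest.approx(d["ortho"] + d["meta"] + d["para"],
                                       abs=1e-9)


def test_delta_zero_for_identical_profiles():
    v = {"2345-245": 1.0, "25-25": 2.0}
    s = series(profile(0, v), profile(30, v), profile(60, v))
    for day in (30, 60):
        assert delta_cl(s, day)["total"] == pytest.approx(0.0, abs=1e-12)


def test_single_meta_removal_delta():
    s = series(profile(0, {"2345-245": 1.0}),
               profile(180, {"245-245": 1.0}))
    d = delta_cl(s, 180)
    assert d["total"] == pytest.approx(1.0, abs=1e-12)
    assert (d["ortho"], d["meta"], d["para"]) == \
        pytest.approx((0.0, 1.0, 0.0), abs=1e-12)


def test_delta_requires_sampled_day():
    s = series(profile(0, {"25-25": 1.0}), profile(30, {"25-25": 1.0}))
    with pytest.raises(DechlorError):
        delta_cl(s, 15)


# --- activity and lag ---------------------------------------------------

def _mixture_with_delta(target_delta):
    """day-180 profile whose dCl/PCB from pure '2345-245' equals target."""
    # fraction f converted to the 6-Cl daughter gives delta == f
    return {"2345-245": 1.0 - target_delta, "245-245": target_delta}


@pytest.mark.parametrize("delta,expected", [
    (0.04, False), (0.05, True), (0.36, True)])
def test_activity_threshold_inclusive(delta, expected):
    s = series(profile(0, {"2345-245": 1.0}),
               profile(180, _mixture_with_delta(delta)))
    assert call_activity(s) is expected


def test_linked_control_replaces_threshold():
    ctrl = series(profile(0, {"2345-245": 1.0}, sample="C"),
                  profile(180, _mixture_with_delta(0.08), sample="C"),
                  microcosm="CTRL")
    s = series(profile(0, {"2345-245": 1.0}),
               profile(180, _mixture_with_delta(0.06)), control=ctrl)
    assert call_activity(s) is False  # 0.06 < control max 0.08
    s2 = series(profile(0, {"2345-245": 1.0}),
                profile(180, _mixture_with_delta(0.09)), control=ctrl)
    assert call_activity(s2) is True


def test_lag_interval_reflects_sampling_resolution():
    profs = [profile(d, _mixture_with_delta(x)) for d, x in
             [(0, 0.0), (30, 0.01), (60, 0.07), (90, 0.2)]]
    lag = lag_time(series(*profs))
    assert (lag.prev_day, lag.onset_day) == (30, 60)


def test_lag_at_first_sample():
    s = series(profile(0, {"2345-245": 1.0}),
               profile(30, _mixture_with_delta(0.2)))
    lag = lag_time(s)
    assert (lag.prev_day, lag.onset_day) == (0, 30)


def test_lag_undefined_when_inactive():
    s = series(profile(0, {"2345-245": 1.0}),
               profile(180, _mixture_with_delta(0.01)))
    with pytest.raises(DechlorError):
        lag_time(s)


# --- preference ---------------------------------------------------------

def _replicate(meta_frac, para_frac, rid):
    # start pure hepta; convert fractions to meta- and para-removal daughters
    rest = 1.0 - meta_frac - para_frac
    return MicrocosmSeries(
        microcosm_id="M", replicate_id=rid,
        profiles=(profile(0, {"2345-245": 1.0}, sample=rid),
                  profile(180, {"2345-245": rest, "245-245": meta_frac,
                                "235-245": para_frac}, sample=rid)))


def test_identical_para_meta_removal_is_comparable():
    reps = [_replicate(0.2, 0.2, f"r{i}") for i in range(3)]
    assert preference_class(reps) == "comparable"


def test_meta_only_removal_is_meta_preferential():
    reps = [_replicate(0.3 + 0.01 * i, 0.0, f"r{i}") for i in range(3)]
    assert preference_class(reps) == "meta-preferential"


def test_para_dominant_removal_is_para_preferential():
    rng = np.random.default_rng(0)
    reps = [_replicate(0.1 + 0.01 * rng.standard_normal(),
                       0.3 + 0.01 * rng.standard_normal(), f"r{i}")
            for i in range(8)]
    assert preference_class(reps) == "para-preferential"


def test_preference_requires_replication():
    with pytest.raises(DechlorError):
        preference_class([_replicate(0.0, 0.3, "r1")])
    assert preference_class([_replicate(0.0, 0.3, "r1")],
                            effect_size_fallback=True) == "para-preferential"


def test_inactive_replicates_labeled_inactive():
    reps = [_replicate(0.01, 0.01, f"r{i}") for i in range(3)]
    assert preference_class(reps) == "inactive"


# --- pathway graph ------------------------------------------------------

def test_pathway_edge_annotated():
    s = series(profile(0, {"2345-245": 1.0, "245-245": 0.0}),
               profile(60, {"2345-245": 0.7, "245-245": 0.3}))
    g = build_pathway_graph(s)
    assert g.has_edge("2345-245", "245-245")
    e = g.edges["2345-245", "245-245"]
    assert (e["position"], e["flank"]) == ("meta", "doubly-flanked")


def test_no_edge_across_two_chlorine_difference():
    s = series(profile(0, {"2345-245": 1.0}),
               profile(60, {"2345-245": 0.5, "25-25": 0.5}))
    g = build_pathway_graph(s)
    assert g.number_of_edges() == 0


def test_orphan_daughter_flagged():
    # "24-25" (4 Cl) appears without any observed 5-Cl parent
    s = series(profile(0, {"2345-245": 1.0}),
               profile(60, {"2345-245": 0.8, "24-25": 0.2}))
    g = build_pathway_graph(s)
    assert g.nodes["24-25"]["orphan"] is True
    assert g.nodes["2345-245"]["orphan"] is False


def test_every_pathway_edge_decrements_one_position():
    from pcbdechlor.congeners import parse_congener, positional_counts
    s = series(profile(0, {"2345-245": 1.0, "245-245": 0.1, "245-25": 0.0,
                           "235-245": 0.05, "25-25": 0.01}),
               profile(60, {"245-245": 0.5, "245-25": 0.2, "25-25": 0.1}))
    g = build_pathway_graph(s)
    assert g.number_of_edges() > 0
    for u, v in g.edges:
        du = positional_counts(parse_congener(u))
        dv = positional_counts(parse_congener(v))
        diff = [a - b for a, b in zip(du, dv)]
        assert sum(diff) == 1 and max(diff) == 1 and min(diff) == 0


# --- flux attribution ---------------------------------------------------

def test_linear_chain_flux_unique():
    s = series(profile(0, {"2345-245": 2.0, "245-245": 0.0}),
               profile(60, {"2345-245": 1.0, "245-245": 1.0}))
    g = attribute_fluxes(build_pathway_graph(s), s)
    assert g.edges["2345-245", "245-245"]["flux"] == pytest.approx(1.0, abs=1e-6)


def test_two_parents_one_daughter_flux_split():
    # "235-245" (para removal) and "2345-24" (meta removal) both feed "235-24"
    s = series(
        profile(0, {"235-245": 1.0, "2345-24": 1.0, "235-24": 0.0}),
        profile(60, {"235-245": 0.4, "2345-24": 0.6, "235-24": 1.0}))
    g = build_pathway_graph(s)
    assert set(g.edges) == {("235-245", "235-24"), ("2345-24", "235-24")}
    g = attribute_fluxes(g, s)
    assert g.edges["235-245", "235-24"]["flux"] == pytest.approx(0.6, abs=1e-4)
    assert g.edges["2345-24", "235-24"]["flux"] == pytest.approx(0.4, abs=1e-4)


def test_infeasible_mass_balance_warns_not_fails():
    # daughter gain with no possible inflow (parent constant)
    s = series(profile(0, {"2345-245": 1.0, "245-245": 0.0}),
               profile(60, {"2345-245": 1.0, "245-245": 0.5}))
    g = build_pathway_graph(s)
    with pytest.warns(UserWarning, match="residual"):
        g = attribute_fluxes(g, s)
    assert g.graph["flux_residuals"][0] > 0
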