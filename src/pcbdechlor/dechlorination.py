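"""Dechlorination statistics over congener concentration time series.

The central activity statistic is the average number of chlorines per
biphenyl, Cl/PCB = sum_i x_i * n_i, where x_i is the mole fraction of
congener i in the mixture and n_i its chlorine count.  Microbial reductive
dechlorination replaces chlorines with hydrogen one at a time, so Cl/PCB
decreases over incubation; its drop from day 0, dCl/PCB, quantifies
activity, and decomposing it over ortho/meta/para positions reveals which
ring positions are attacked.

A microcosm is called *active* when dCl/PCB ever reaches the abiotic-control
threshold (default 0.05 chlorines per biphenyl).  The lag time is the
sampling interval in which the threshold is first crossed.  Replicated
microcosms are classified as para-preferential, meta-preferential or
comparable by one-way ANOVA on the final para vs meta positional removals.

Because each dechlorination step removes exactly one chlorine, the observed
congeners form a directed pathway graph whose edges are single-chlorine
parent->daughter relations; non-negative least squares on interval-wise
mass balance attributes reaction fluxes to those edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import optimize, stats

from .congeners import (
    BIPHENYL,
    Congener,
    parse_congener,
    single_dechlorination_products,
)

__all__ = [
    "CongenerProfile",
    "DechlorError",
    "DechlorResult",
    "LagInterval",
    "MicrocosmSeries",
    "attribute_fluxes",
    "build_pathway_graph",
    "call_activity",
    "cl_per_pcb",
    "delta_cl",
    "lag_time",
    "positional_cl_per_pcb",
    "preference_class",
]

ACTIVITY_THRESHOLD = 0.05  # dCl/PCB of the abiotic controls


class DechlorError(ValueError):
    """Invalid series/profile or undefined dechlorination statistic."""


@dataclass(frozen=True)
class CongenerProfile:
    """Congener concentrations (uM) or mole fractions at one timepoint.

    Keys of ``values`` are canonical ring-notation labels (canonicalized at
    construction); ``BIPHENYL`` is accepted as a terminal pseudo-species and
    contributes zero chlorines to Cl/PCB.
    """

    sample_id: str
    day: float
    values: dict[str, float]

    def __post_init__(self) -> None:
        canon: dict[str, float] = {}
        for label, v in self.values.items():
            if not np.isfinite(v) or v < 0:
                raise DechlorError(
                    f"negative or non-finite abundance {v!r} for {label!r} "
                    f"(sample {self.sample_id}, day {self.day})")
            key = BIPHENYL if label == BIPHENYL else parse_congener(label).label
            canon[key] = canon.get(key, 0.0) + float(v)
        object.__setattr__(self, "values", canon)

    def total(self) -> float:
        return float(sum(self.values.values()))


@dataclass(frozen=True)
class MicrocosmSeries:
    """Ordered congener profiles of one microcosm (first timepoint day 0),
    with optional linked abiotic-control series."""

    microcosm_id: str
    profiles: tuple[CongenerProfile, ...]
    replicate_id: str = "1"
    control: "MicrocosmSeries | None" = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "profiles", tuple(self.profiles))
        days = [p.day for p in self.profiles]
        if not days:
            raise DechlorError(f"microcosm {self.microcosm_id}: empty series")
        if days[0] != 0:
            raise DechlorError(
                f"microcosm {self.microcosm_id}: first timestamp must be day 0")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise DechlorError(
                f"microcosm {self.microcosm_id}: timestamps must strictly increase")

    @property
    def days(self) -> tuple[float, ...]:
        return tuple(p.day for p in self.profiles)

    def profile_at(self, day: float) -> CongenerProfile:
        for p in self.profiles:
            if p.day == day:
                return p
        raise DechlorError(
            f"day {day} not sampled in microcosm {self.microcosm_id} "
            f"(sampled: {self.days}); no interpolation is performed")


@dataclass(frozen=True)
class LagInterval:
    """Onset interval (prev_day, onset_day] of dechlorination activity."""

    prev_day: float
    onset_day: float


@dataclass(frozen=True)
class DechlorResult:
    """Summary dechlorination statistics of one microcosm."""

    microcosm_id: str
    delta_cl_total: float
    delta_cl_ortho: float
    delta_cl_meta: float
    delta_cl_para: float
    active: bool
    lag: LagInterval | None
    preference: str  # para-preferential / meta-preferential / comparable / inactive


def _chlorine_weights(profile: CongenerProfile) -> tuple[np.ndarray, np.ndarray]:
    """(mole fractions, per-congener (n_o, n_m, n_p)) over detected species."""
    labels = list(profile.values)
    conc = np.array([profile.values[k] for k in labels], dtype=float)
    total = conc.sum()
    if total <= 0:
        raise DechlorError(
            f"all-zero profile (sample {profile.sample_id}, day {profile.day}): "
            "Cl/PCB undefined")
    counts = np.array(
        [(0, 0, 0) if k == BIPHENYL else
         (lambda c: (c.n_ortho, c.n_meta, c.n_para))(parse_congener(k))
         for k in labels], dtype=float)
    return conc / total, counts


def cl_per_pcb(profile: CongenerProfile) -> float:
    """Average chlorines per biphenyl, sum_i x_i * n_i over mole fractions."""
    x, counts = _chlorine_weights(profile)
    return float(x @ counts.sum(axis=1))


def positional_cl_per_pcb(profile: CongenerProfile) -> tuple[float, float, float]:
    """(ortho, meta, para) chlorines per biphenyl; sums to Cl/PCB."""
    x, counts = _chlorine_weights(profile)
    o, m, p = x @ counts
    return float(o), float(m), float(p)


def delta_cl(series: MicrocosmSeries, day: float) -> dict[str, float]:
    """dCl/PCB(day) = Cl/PCB(day 0) - Cl/PCB(day), total and per position.

    Returns keys ``total``, ``ortho``, ``meta``, ``para``; total equals the
    positional sum by construction.  ``day`` must be a sampled timestamp.
    """
    p0 = series.profiles[0]
    pt = series.profile_at(day)
    o0, m0, pa0 = positional_cl_per_pcb(p0)
    ot, mt, pat = positional_cl_per_pcb(pt)
    return {"total": (o0 + m0 + pa0) - (ot + mt + pat),
            "ortho": o0 - ot, "meta": m0 - mt, "para": pa0 - pat}


def _effective_threshold(series: MicrocosmSeries, threshold: float) -> float:
    if series.control is not None:
        return max(delta_cl(series.control, d)["total"]
                   for d in series.control.days[1:])
    return threshold


def call_activity(series: MicrocosmSeries,
                  threshold: float = ACTIVITY_THRESHOLD) -> bool:
    """Whether dCl/PCB ever reaches the activity threshold (inclusive).

    When a linked abiotic-control series is present, its maximum dCl/PCB
    replaces the default threshold.
    """
    if len(series.profiles) < 2:
        raise DechlorError(
            f"microcosm {series.microcosm_id}: need >= 2 timepoints")
    thr = _effective_threshold(series, threshold)
    return any(delta_cl(series, d)["total"] >= thr for d in series.days[1:])


def lag_time(series: MicrocosmSeries,
             threshold: float = ACTIVITY_THRESHOLD) -> LagInterval:
    """Onset interval (previous sample, first sample with dCl/PCB >= threshold].

    Reported as an interval because activity between samplings is
    unobserved.  Raises for inactive series.
    """
    thr = _effective_threshold(series, threshold)
    prev = series.days[0]
    for d in series.days[1:]:
        if delta_cl(series, d)["total"] >= thr:
            return LagInterval(prev_day=prev, onset_day=d)
        prev = d
    raise DechlorError(
        f"microcosm {series.microcosm_id}: threshold {thr} never reached; "
        "lag time undefined for inactive series")


def preference_class(replicates: list[MicrocosmSeries], alpha: float = 0.05,
                     threshold: float = ACTIVITY_THRESHOLD,
                     effect_size_fallback: bool = False) -> str:
    """Positional-preference label from replicate final para vs meta removals.

    One-way ANOVA compares the final-timepoint para deltas against the meta
    deltas across replicates; a significant difference at `alpha` yields
    ``para-preferential`` or ``meta-preferential`` by the larger mean,
    otherwise ``comparable``.  All replicates must be active; with a single
    replicate an error is raised unless ``effect_size_fallback`` requests
    classification by sign of the (untested) difference.
    """
    if not replicates:
        raise DechlorError("no replicate series given")
    if not all(call_activity(s, threshold) for s in replicates):
        return "inactive"
    para = np.array([delta_cl(s, s.days[-1])["para"] for s in replicates])
    meta = np.array([delta_cl(s, s.days[-1])["meta"] for s in replicates])
    if len(replicates) < 2:
        if not effect_size_fallback:
            raise DechlorError(
                "preference classification needs >= 2 replicates "
                "(pass effect_size_fallback=True to classify by effect size)")
        if para[0] == meta[0]:
            return "comparable"
        return "para-preferential" if para[0] > meta[0] else "meta-preferential"
    if np.allclose(para, meta):
        return "comparable"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero within-group variance -> F=inf
        f, p = stats.f_oneway(para, meta)
    if np.isnan(p):
        return "comparable"
    if p < alpha:
        return ("para-preferential" if para.mean() > meta.mean()
                else "meta-preferential")
    return "comparable"


def summarize(series: MicrocosmSeries, replicates: list[MicrocosmSeries] | None = None,
              threshold: float = ACTIVITY_THRESHOLD, alpha: float = 0.05) -> DechlorResult:
    """Full dechlorination summary for one microcosm at its final timepoint."""
    final = series.days[-1]
    d = delta_cl(series, final)
    active = call_activity(series, threshold)
    lag = lag_time(series, threshold) if active else None
    if not active:
        pref = "inactive"
    elif replicates and len(replicates) >= 2:
        pref = preference_class(replicates, alpha=alpha, threshold=threshold)
    else:
        pref = preference_class([series], threshold=threshold,
                                effect_size_fallback=True)
    return DechlorResult(
        microcosm_id=series.microcosm_id, delta_cl_total=d["total"],
        delta_cl_ortho=d["ortho"], delta_cl_meta=d["meta"],
        delta_cl_para=d["para"], active=active, lag=lag, preference=pref)


# ---------------------------------------------------------------------------
# Pathway graph and flux attribution
# ---------------------------------------------------------------------------

def build_pathway_graph(series: MicrocosmSeries,
                        detection_limit: float = 0.0) -> nx.DiGraph:
    """Directed single-dechlorination graph over the observed congeners.

    Nodes are congeners whose concentration ever exceeds ``detection_limit``
    (plus the terminal biphenyl if reported); a directed edge parent ->
    daughter exists for every symmetry-distinct single-chlorine removal
    connecting two observed nodes, annotated with the removed-position
    class, flanking context and channel multiplicity.  Observed daughters
    that were absent at day 0 and have no observed parent are flagged
    ``orphan`` (their precursor fell below detection).
    """
    if len(series.profiles) < 2:
        raise DechlorError(
            f"microcosm {series.microcosm_id}: need >= 2 timepoints")
    if detection_limit < 0:
        raise DechlorError("detection_limit must be >= 0")
    observed: set[str] = set()
    for p in series.profiles:
        observed |= {k for k, v in p.values.items() if v > detection_limit}
    g = nx.DiGraph(microcosm_id=series.microcosm_id,
                   detection_limit=detection_limit)
    for label in sorted(observed):
        g.add_node(label)
    for label in sorted(observed - {BIPHENYL}):
        for ch in single_dechlorination_products(parse_congener(label)):
            if ch.product_label in observed:
                g.add_edge(label, ch.product_label,
                           position=ch.position_class, flank=ch.flank,
                           multiplicity=ch.multiplicity)
    at_day0 = {k for k, v in series.profiles[0].values.items()
               if v > detection_limit}
    for label in g.nodes:
        g.nodes[label]["orphan"] = (g.in_degree(label) == 0
                                    and label not in at_day0)
    return g


def _interval_fluxes(incidence: np.ndarray, dconc: np.ndarray,
                     l1_weight: float) -> np.ndarray:
    """Non-negative LSQ flux assignment for one interval.

    Minimizes ||A f - dc||^2 + l1_weight * sum(f) over f >= 0; the tiny L1
    term breaks degeneracy toward fewer active edges.
    """
    f0, _ = optimize.nnls(incidence, dconc)

    def obj(f: np.ndarray) -> tuple[float, np.ndarray]:
        r = incidence @ f - dconc
        return float(r @ r + l1_weight * f.sum()), 2 * incidence.T @ r + l1_weight

    res = optimize.minimize(obj, f0, jac=True, method="L-BFGS-B",
                            bounds=[(0, None)] * len(f0),
                            options={"maxiter": 500, "ftol": 1e-14,
                                     "gtol": 1e-12})
    return np.maximum(res.x, 0.0)


def attribute_fluxes(graph: nx.DiGraph, series: MicrocosmSeries,
                     l1_weight: float = 1e-6,
                     residual_tol: float = 1e-3) -> nx.DiGraph:
    """Attribute cumulative reaction fluxes (uM) to pathway-graph edges.

    For each consecutive timepoint pair the per-node concentration changes
    are explained by non-negative fluxes on the graph edges (daughter gain =
    inflow - outflow), solved by least squares; cumulative fluxes are the
    interval sums, stored on each edge as ``flux``.  Biphenyl-skeleton mass
    is conserved by the incidence structure.  A mass-balance residual beyond
    ``residual_tol`` (uM, per interval) triggers a warning, not a failure;
    the per-interval residual norms are stored as graph attribute
    ``flux_residuals``.
    """
    g = graph.copy()
    nodes = sorted(g.nodes)
    edges = sorted(g.edges)
    if not edges:
        g.graph["flux_residuals"] = []
        return g
    idx = {n: i for i, n in enumerate(nodes)}
    incidence = np.zeros((len(nodes), len(edges)))
    for j, (u, v) in enumerate(edges):
        incidence[idx[u], j] = -1.0
        incidence[idx[v], j] = 1.0
    total = np.zeros(len(edges))
    residuals: list[float] = []
    for p0, p1 in zip(series.profiles, series.profiles[1:]):
        dconc = np.array([p1.values.get(n, 0.0) - p0.values.get(n, 0.0)
                          for n in nodes])
        f = _interval_fluxes(incidence, dconc, l1_weight)
        total += f
        residuals.append(float(np.linalg.norm(incidence @ f - dconc)))
    if max(residuals) > residual_tol:
        warnings.warn(
            f"microcosm {series.microcosm_id}: mass-balance residuals exceed "
            f"{residual_tol} uM in {sum(r > residual_tol for r in residuals)} "
            f"interval(s); max residual {max(residuals):.3g} uM. Fluxes on "
            "unobserved intermediates or non-dechlorination losses are not "
            "modeled.", stacklevel=2)
    for j, (u, v) in enumerate(edges):
        g.edges[u, v]["flux"] = float(total[j])
    g.graph["flux_residuals"] = residuals
    return g
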