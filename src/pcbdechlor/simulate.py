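"""Seeded synthetic-data generators for every pipeline stage.

Three forward models emulate the statistical structure of a PCB
microcosm study so the whole analysis chain is testable without
laboratory data:

* **Dechlorination kinetics** -- first-order sequential dechlorination of a
  congener mixture.  Every chlorine of every congener is removed at a rate
  set by its position class (ortho/meta/para) and flanking context, scaled
  by channel multiplicity; products are routed along the single-
  dechlorination graph.  The system is linear in concentrations, so it is
  propagated exactly with matrix exponentials (augmented with concentration
  integrals that yield exact per-edge cumulative fluxes).  Rates are zero
  before a configurable lag phase; measurements carry multiplicative
  lognormal noise.  Biphenyl-skeleton molarity is conserved in the ground
  truth.
* **qPCR** -- Cq = intercept + slope * log10(copies) + Gaussian noise, for
  a plasmid dilution series (standards) and unknown samples.
* **Communities** -- genus count tables assembled either stochastically
  (multinomial draws from a regional pool, the same process the NST null
  model assumes) or deterministically (fixed group templates with small
  multiplicative noise), with designated OHRB taxa whose abundance tracks
  an assigned dechlorination activity, and optional planted rank
  correlations between taxon pairs for network tests.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .congeners import BIPHENYL, parse_congener, single_dechlorination_products
from .dechlorination import CongenerProfile, MicrocosmSeries
from .ecology import AbundanceTable
from .qpcr import DilutionSeries

__all__ = [
    "CommunitySimConfig",
    "DEFAULT_MIXTURE",
    "DEFAULT_RATES",
    "KineticConfig",
    "SimulatedMicrocosm",
    "simulate_communities",
    "simulate_microcosm",
    "simulate_qpcr",
]

#: Synthetic hexa/hepta-dominated congener mixture (mole fractions) standing
#: in for a highly chlorinated commercial PCB formulation.  The major
#: congeners and their weights are a plausible composition for such a
#: mixture (Cl/PCB ~ 6.2), not a measured formulation table.
DEFAULT_MIXTURE: dict[str, float] = {
    "2345-245": 0.12,   # hepta
    "234-245": 0.14,    # hexa
    "245-245": 0.12,    # hexa
    "2345-234": 0.06,   # hepta
    "2356-245": 0.08,   # hepta
    "234-236": 0.08,    # hexa
    "2345-236": 0.06,   # hepta
    "236-245": 0.07,    # hexa
    "2345-2356": 0.05,  # octa
    "245-25": 0.08,     # penta
    "234-25": 0.06,     # penta
    "2356-236": 0.08,   # hexa
}

#: First-order removal rate constants (per chlorine channel, per day) by
#: (position class, flanking context).  Flanked para and meta chlorines are
#: the preferred microbial targets; ortho and unflanked removal is rare.
#: Magnitudes give dCl/PCB of roughly 0.3-0.4 over 180 days, the activity
#: scale typical of sludge microcosms.
DEFAULT_RATES: dict[tuple[str, str], float] = {
    ("para", "doubly-flanked"): 1.2e-3,
    ("para", "singly-flanked"): 6.5e-4,
    ("meta", "doubly-flanked"): 1.0e-3,
    ("meta", "singly-flanked"): 5.5e-4,
    ("meta", "unflanked"): 5.0e-5,
    ("ortho", "singly-flanked"): 5.0e-5,
    ("ortho", "unflanked"): 2.5e-5,
}

DEFAULT_SAMPLING_DAYS = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0)


@dataclass(frozen=True)
class KineticConfig:
    """Configuration of one simulated microcosm experiment."""

    mixture: tuple[tuple[str, float], ...] = tuple(sorted(DEFAULT_MIXTURE.items()))
    rates: tuple[tuple[tuple[str, str], float], ...] = tuple(
        sorted(DEFAULT_RATES.items()))
    lag_days: float = 30.0
    noise_cv: float = 0.05
    sampling_days: tuple[float, ...] = DEFAULT_SAMPLING_DAYS
    replicates: int = 3
    total_conc_um: float = 10.0  # total biphenyl-skeleton molarity (uM)
    microcosm_id: str = "SIM1"
    seed: int | None = None

    def __post_init__(self) -> None:
        mix = tuple(sorted((parse_congener(l).label, float(f))
                           for l, f in dict(self.mixture).items()))
        object.__setattr__(self, "mixture", mix)
        object.__setattr__(self, "rates", tuple(sorted(
            ((c, fl), float(k)) for (c, fl), k in dict(self.rates).items())))
        fracs = np.array([f for _, f in self.mixture])
        if (fracs < 0).any() or not np.isclose(fracs.sum(), 1.0):
            raise ValueError("initial mole fractions must be >= 0 and sum to 1")
        if any(k < 0 for _, k in self.rates):
            raise ValueError("rate constants must be >= 0")
        if self.sampling_days[0] != 0:
            raise ValueError("sampling days must start at 0")
        if self.lag_days < 0 or self.noise_cv < 0 or self.replicates < 1:
            raise ValueError("invalid lag/noise/replicates")

    @classmethod
    def from_dicts(cls, mixture: dict[str, float] | None = None,
                   rates: dict[tuple[str, str], float] | None = None,
                   **kwargs) -> "KineticConfig":
        return cls(
            mixture=tuple(sorted((mixture or DEFAULT_MIXTURE).items())),
            rates=tuple(sorted((rates if rates is not None
                                else DEFAULT_RATES).items())),
            **kwargs)


@dataclass(frozen=True)
class SimulatedMicrocosm:
    """Simulator output: noisy observations, noise-free truth, true fluxes."""

    observed: tuple[MicrocosmSeries, ...]
    truth: MicrocosmSeries
    fluxes: dict[tuple[str, str], float]  # cumulative uM per pathway edge
    config: KineticConfig


def _reaction_network(cfg: KineticConfig):
    """Closure of the mixture under nonzero-rate dechlorination channels.

    Returns (state labels incl. biphenyl, A rate matrix, edge list
    [(parent, child, k_total)]).
    """
    rates = dict(cfg.rates)
    labels: list[str] = []
    edge_rates: dict[tuple[str, str], float] = {}
    stack = [l for l, f in cfg.mixture]
    seen: set[str] = set()
    while stack:
        lab = stack.pop()
        if lab in seen:
            continue
        seen.add(lab)
        labels.append(lab)
        if lab == BIPHENYL:
            continue
        for ch in single_dechlorination_products(parse_congener(lab)):
            k = rates.get((ch.position_class, ch.flank), 0.0) * ch.multiplicity
            if k <= 0:
                continue
            key = (lab, ch.product_label)
            edge_rates[key] = edge_rates.get(key, 0.0) + k
            if ch.product_label not in seen:
                stack.append(ch.product_label)
    labels = sorted(seen - {BIPHENYL}) + ([BIPHENYL] if BIPHENYL in seen else [])
    idx = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    a = np.zeros((n, n))
    for (parent, child), k in edge_rates.items():
        a[idx[child], idx[parent]] += k
        a[idx[parent], idx[parent]] -= k
    edges = sorted((p, c, k) for (p, c), k in edge_rates.items())
    return labels, a, edges


_TRUTH_CACHE: dict = {}


def _simulate_truth(cfg: KineticConfig):
    """Noise-free concentrations at sampling days plus cumulative fluxes.

    The augmented linear system [c; integral(c)] is propagated with matrix
    exponentials, giving exact concentrations and exact per-edge cumulative
    fluxes k_e * integral(c_parent).  Cached per kinetic configuration
    (noise and seed do not enter).
    """
    key = (cfg.mixture, cfg.rates, cfg.lag_days, cfg.sampling_days,
           cfg.total_conc_um)
    if key in _TRUTH_CACHE:
        return _TRUTH_CACHE[key]
    labels, a, edges = _reaction_network(cfg)
    idx = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    c = np.zeros(n)
    for lab, frac in cfg.mixture:
        c[idx[lab]] = frac * cfg.total_conc_um
    m = np.zeros((2 * n, 2 * n))
    m[:n, :n] = a
    m[n:, :n] = np.eye(n)
    # reaction time elapsed at each sampling day (zero before the lag phase)
    taus = [max(0.0, d - cfg.lag_days) for d in cfg.sampling_days]
    prop_cache: dict[float, np.ndarray] = {}
    conc = [c.copy()]
    cum_flux = {(p, ch): 0.0 for p, ch, _ in edges}
    for t0, t1 in zip(taus, taus[1:]):
        dt = t1 - t0
        if dt > 0:
            if dt not in prop_cache:
                prop_cache[dt] = expm(m * dt)
            aug = prop_cache[dt] @ np.concatenate([c, np.zeros(n)])
            c, integral = aug[:n], aug[n:]
            for p, ch, k in edges:
                cum_flux[(p, ch)] += k * integral[idx[p]]
        conc.append(c.copy())
    result = (labels, np.array(conc), cum_flux)
    _TRUTH_CACHE[key] = result
    return result


def simulate_microcosm(cfg: KineticConfig) -> SimulatedMicrocosm:
    """Simulate one microcosm: noise-free truth plus noisy replicates.

    Observed series exclude the terminal biphenyl (not quantified by the
    congener-specific chemistry the tables emulate) and carry per-congener,
    per-timepoint multiplicative lognormal noise of coefficient of
    variation ``noise_cv`` (mean 1).
    """
    labels, conc, cum_flux = _simulate_truth(cfg)
    truth_profiles = [
        CongenerProfile(sample_id=cfg.microcosm_id, day=d,
                        values={lab: float(conc[t, i])
                                for i, lab in enumerate(labels)
                                if conc[t, i] > 0})
        for t, d in enumerate(cfg.sampling_days)]
    truth = MicrocosmSeries(microcosm_id=cfg.microcosm_id,
                            profiles=tuple(truth_profiles), replicate_id="truth")
    rng = np.random.default_rng(cfg.seed)
    obs_labels = [l for l in labels if l != BIPHENYL]
    obs_idx = [labels.index(l) for l in obs_labels]
    sigma = float(np.sqrt(np.log1p(cfg.noise_cv ** 2)))
    observed = []
    for rep in range(cfg.replicates):
        factors = (np.exp(sigma * rng.standard_normal(
            (len(cfg.sampling_days), len(obs_labels))) - sigma ** 2 / 2)
            if sigma > 0 else np.ones((len(cfg.sampling_days), len(obs_labels))))
        profiles = [
            CongenerProfile(
                sample_id=f"{cfg.microcosm_id}.r{rep + 1}", day=d,
                values={lab: float(conc[t, i] * factors[t, j])
                        for j, (lab, i) in enumerate(zip(obs_labels, obs_idx))
                        if conc[t, i] > 0})
            for t, d in enumerate(cfg.sampling_days)]
        observed.append(MicrocosmSeries(
            microcosm_id=cfg.microcosm_id, profiles=tuple(profiles),
            replicate_id=str(rep + 1)))
    return SimulatedMicrocosm(observed=tuple(observed), truth=truth,
                              fluxes=dict(cum_flux), config=cfg)


# ---------------------------------------------------------------------------
# qPCR forward model
# ---------------------------------------------------------------------------

def simulate_qpcr(truth_copies_per_ml: dict[str, float], target: str = "target",
                  slope: float = -3.3219, intercept: float = 38.0,
                  sigma_cq: float = 0.0, seed: int | None = None,
                  standard_levels: tuple[float, ...] = tuple(
                      10.0 ** e for e in range(2, 9)),
                  template_volume_ml: float = 0.002,
                  ) -> tuple[DilutionSeries, pd.DataFrame]:
    """Forward qPCR model: standards dilution series plus unknown-sample Cqs.

    Cq = intercept + slope * log10(copies/mL) + N(0, sigma_cq); samples with
    non-positive true copies are emitted as non-detects (NaN Cq).
    """
    if sigma_cq < 0:
        raise ValueError("sigma_cq must be >= 0")
    if slope >= 0:
        raise ValueError("slope must be negative")
    rng = np.random.default_rng(seed)
    std_points = tuple(
        (lvl, intercept + slope * np.log10(lvl)
         + (rng.normal(0.0, sigma_cq) if sigma_cq > 0 else 0.0))
        for lvl in standard_levels)
    standards = DilutionSeries(target=target, points=std_points,
                               template_volume_ml=template_volume_ml)
    rows = []
    for sample, copies in truth_copies_per_ml.items():
        if copies <= 0:
            cq = float("nan")  # non-detect
        else:
            cq = intercept + slope * np.log10(copies) + (
                rng.normal(0.0, sigma_cq) if sigma_cq > 0 else 0.0)
        rows.append({"sample": sample, "target": target, "cq": cq,
                     "dilution_factor": 1.0, "true_copies_per_ml": copies})
    return standards, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Community tables
# ---------------------------------------------------------------------------

DEFAULT_OHRB_TAXON_NAMES = (
    "Dehalococcoides", "Dehalogenimonas", "Dehalobacter",
    "Dehalococcoidia_S085", "Dehalococcoidia_vadinBA26",
    "Dehalococcoidia_GIF9", "Dehalococcoidia_DscP2", "Dehalococcoidia_t0.6.f",
)


@dataclass(frozen=True)
class CommunitySimConfig:
    """Configuration of a simulated genus count table.

    ``mode="stochastic"`` assembles every sample by a multinomial draw from
    the regional pool (exactly the NST null-model process);
    ``mode="deterministic"`` assigns each group two fixed, strongly distinct
    template compositions and builds samples from them with only small
    multiplicative noise.  Designated OHRB taxa are scaled per sample by
    ``1 + activity_coupling * activity`` and may be planted in only a
    fraction of samples; ``planted_pairs`` adds latent Gaussian-copula rank
    correlations between named taxa for co-occurrence tests.
    """

    n_taxa: int = 120
    samples_per_group: int = 21
    n_groups: int = 1
    depth: int = 20000
    mode: str = "stochastic"
    ohrb_taxa: tuple[str, ...] = DEFAULT_OHRB_TAXON_NAMES
    ohrb_prevalence: float = 1.0
    activity_coupling: float = 0.0
    activities: tuple[float, ...] | None = None
    planted_pairs: tuple[tuple[str, str, float], ...] = ()
    overdispersion: float = 0.0  # lognormal sigma of per-sample taxon factors
    noise_cv: float = 0.02       # deterministic-mode template noise
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("stochastic", "deterministic"):
            raise ValueError(f"unknown assembly mode {self.mode!r}")
        if self.depth < 100:
            raise ValueError("sample depth must be >= 100")
        if not 0 <= self.ohrb_prevalence <= 1:
            raise ValueError("ohrb_prevalence must be in [0, 1]")


def simulate_communities(cfg: CommunitySimConfig
                         ) -> tuple[AbundanceTable, dict]:
    """Simulate a genus x sample count table plus planted ground truth."""
    rng = np.random.default_rng(cfg.seed)
    n_ohrb = len(cfg.ohrb_taxa)
    if cfg.n_taxa <= n_ohrb:
        raise ValueError("n_taxa must exceed the number of OHRB taxa")
    taxa = list(cfg.ohrb_taxa) + [
        f"Genus_{i:03d}" for i in range(1, cfg.n_taxa - n_ohrb + 1)]
    # Regional pool: lognormal abundance spectrum; OHRB kept moderately rare.
    pool = np.exp(rng.normal(0.0, 1.2, size=cfg.n_taxa))
    pool[:n_ohrb] *= 0.15
    pool /= pool.sum()
    if cfg.planted_pairs:
        # planted-correlation taxa are kept common, so the planted rank
        # signal is identifiable above counting noise
        floor = float(np.quantile(pool, 0.75))
        for ti, tj, _ in cfg.planted_pairs:
            for t in (ti, tj):
                i = (list(cfg.ohrb_taxa) + [
                    f"Genus_{k:03d}" for k in range(1, cfg.n_taxa - n_ohrb + 1)
                ]).index(t)
                pool[i] = max(pool[i], floor)
        pool /= pool.sum()

    n_samples = cfg.samples_per_group * cfg.n_groups
    sample_ids = [f"G{g + 1}S{s + 1:02d}" for g in range(cfg.n_groups)
                  for s in range(cfg.samples_per_group)]
    group_of = {sid: f"G{g + 1}" for g in range(cfg.n_groups)
                for s, sid in [(s, f"G{g + 1}S{s + 1:02d}")
                               for s in range(cfg.samples_per_group)]}
    activities = (np.asarray(cfg.activities, dtype=float)
                  if cfg.activities is not None
                  else rng.uniform(0.0, 0.6, size=n_samples))
    if len(activities) != n_samples:
        raise ValueError("activities length must equal total sample count")
    n_with_ohrb = int(round(cfg.ohrb_prevalence * n_samples))
    ohrb_present = np.zeros(n_samples, dtype=bool)
    ohrb_present[rng.choice(n_samples, size=n_with_ohrb, replace=False)] = True

    name_idx = {t: i for i, t in enumerate(taxa)}
    counts = np.zeros((n_samples, cfg.n_taxa), dtype=np.int64)
    templates: dict[str, np.ndarray] = {}
    if cfg.mode == "deterministic":
        for g in range(cfg.n_groups):
            for tmpl in ("A", "B"):
                w = pool * np.exp(rng.normal(0.0, 2.0, size=cfg.n_taxa))
                templates[f"G{g + 1}{tmpl}"] = w / w.sum()
    sigma_noise = float(np.sqrt(np.log1p(cfg.noise_cv ** 2)))
    template_of: list[str] = []
    for s in range(n_samples):
        g = s // cfg.samples_per_group
        if cfg.mode == "deterministic":
            tmpl = f"G{g + 1}{'A' if (s % cfg.samples_per_group) % 2 == 0 else 'B'}"
            template_of.append(tmpl)
            p = templates[tmpl].copy()
        else:
            template_of.append("pool")
            p = pool.copy()
        if cfg.overdispersion > 0:
            z = rng.standard_normal(cfg.n_taxa)
            for ti, tj, rho in cfg.planted_pairs:
                i, j = name_idx[ti], name_idx[tj]
                # Greiner inverse: latent Pearson that yields the requested
                # Spearman rho under a Gaussian copula
                rho_lat = 2.0 * np.sin(np.pi * rho / 6.0)
                z[j] = (rho_lat * z[i]
                        + np.sqrt(1 - rho_lat ** 2) * rng.standard_normal())
            p = p * np.exp(cfg.overdispersion * z)
        if cfg.activity_coupling != 0:
            p[:n_ohrb] *= 1.0 + cfg.activity_coupling * activities[s]
        if not ohrb_present[s]:
            p[:n_ohrb] = 0.0
        p /= p.sum()
        if cfg.mode == "deterministic":
            noisy = p * (np.exp(sigma_noise * rng.standard_normal(cfg.n_taxa)
                                - sigma_noise ** 2 / 2)
                         if sigma_noise > 0 else 1.0)
            counts[s] = np.rint(noisy / noisy.sum() * cfg.depth).astype(np.int64)
        else:
            counts[s] = rng.multinomial(cfg.depth, p)

    data = pd.DataFrame(counts.T, index=taxa, columns=sample_ids)
    table = AbundanceTable(
        data=data,
        taxonomy=pd.Series(taxa, index=taxa, dtype=object),
        groups=pd.Series([group_of[s] for s in sample_ids], index=sample_ids),
        mode="counts")
    truth = {
        "mode": cfg.mode,
        "pool": pd.Series(pool, index=taxa),
        "activities": pd.Series(activities, index=sample_ids),
        "ohrb_present": pd.Series(ohrb_present, index=sample_ids),
        "ohrb_taxa": list(cfg.ohrb_taxa),
        "templates": templates,
        "template_of": pd.Series(template_of, index=sample_ids),
        "planted_pairs": list(cfg.planted_pairs),
        "seed": cfg.seed,
    }
    return table, truth


# ---------------------------------------------------------------------------
# Miniature fixture study
# ---------------------------------------------------------------------------

def write_fixture_study(out_dir, seed: int = 0):
    """Write a complete miniature synthetic study to ``out_dir``.

    Eight microcosms x two replicates (rate constants scaled per microcosm,
    one microcosm left without dechlorination activity) plus an abiotic
    control, a six-target qPCR table (standards + unknowns coupled to the
    true activity), a two-group community count table with OHRB-activity
    coupling, and the sample metadata and study configuration needed to run
    the full pipeline.  Returns the :class:`~pcbdechlor.pipeline.StudyConfig`.
    """
    from pathlib import Path

    from . import io as pio
    from .dechlorination import delta_cl
    from .pipeline import StudyConfig

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    series: dict[str, MicrocosmSeries] = {}
    meta_rows: list[dict] = []
    activities: dict[str, float] = {}
    for i in range(1, 9):
        scale = 0.0 if i == 8 else float(rng.uniform(0.5, 1.6))
        rates = {k: v * scale for k, v in DEFAULT_RATES.items()}
        lag = float(rng.choice([0.0, 30.0, 60.0]))
        cfg = KineticConfig.from_dicts(
            rates=rates, lag_days=lag, noise_cv=0.05, replicates=2,
            microcosm_id=f"M{i}", seed=int(rng.integers(2 ** 31)))
        sim = simulate_microcosm(cfg)
        final = cfg.sampling_days[-1]
        activities[f"M{i}"] = float(delta_cl(sim.truth, final)["total"])
        for s in sim.observed:
            sid = s.profiles[0].sample_id
            series[sid] = MicrocosmSeries(microcosm_id=sid,
                                          profiles=s.profiles,
                                          replicate_id=s.replicate_id)
            meta_rows.append({"sample": sid, "microcosm": f"M{i}",
                              "replicate": s.replicate_id, "role": "microcosm",
                              "activity": activities[f"M{i}"]})
    ctrl_cfg = KineticConfig.from_dicts(
        rates={k: 0.0 for k in DEFAULT_RATES}, lag_days=0.0, noise_cv=0.02,
        replicates=1, microcosm_id="CTRL", seed=int(rng.integers(2 ** 31)))
    ctrl = simulate_microcosm(ctrl_cfg).observed[0]
    sid = ctrl.profiles[0].sample_id
    series[sid] = MicrocosmSeries(microcosm_id=sid, profiles=ctrl.profiles)
    meta_rows.append({"sample": sid, "microcosm": "CTRL", "replicate": "1",
                      "role": "abiotic-control", "activity": 0.0})
    pio.write_congener_table(series, out / "congeners.csv")
    pd.DataFrame(meta_rows).to_csv(out / "metadata.csv", index=False)

    # qPCR: per-target standard curves plus unknowns coupled to activity.
    from .qpcr import OHRB_GENERA, RDASE_GENES
    standards: dict[str, DilutionSeries] = {}
    unknown_rows: list[pd.DataFrame] = []
    base_log10 = {"Dehalococcoides": 3.7, "Dehalogenimonas": 3.9,
                  "Dehalobacter": 3.0, "pcbA1": 2.3, "pcbA4": 3.5,
                  "pcbA5": 3.6}
    for target in (*OHRB_GENERA, *RDASE_GENES):
        slope = float(rng.uniform(-3.45, -3.25))
        intercept = float(rng.uniform(36.0, 40.0))
        truth = {
            mid: float(10 ** (base_log10[target] + 4.0 * act
                              + rng.normal(0.0, 0.3)))
            for mid, act in activities.items()}
        std, unknowns = simulate_qpcr(
            truth, target=target, slope=slope, intercept=intercept,
            sigma_cq=0.15, seed=int(rng.integers(2 ** 31)))
        standards[target] = std
        unknown_rows.append(unknowns.drop(columns=["true_copies_per_ml"]))
    pio.write_qpcr_table(standards, pd.concat(unknown_rows, ignore_index=True),
                         out / "qpcr.csv")

    # Communities: two groups of ten samples, activity-coupled OHRB.
    act_values = tuple(float(v) for v in rng.uniform(0.0, 0.6, size=20))
    ccfg = CommunitySimConfig(
        n_taxa=60, samples_per_group=10, n_groups=2, depth=5000,
        mode="stochastic", activity_coupling=6.0, activities=act_values,
        overdispersion=0.4, seed=int(rng.integers(2 ** 31)))
    table, truth_c = simulate_communities(ccfg)
    pio.write_abundance_table(table, out / "abundance.tsv")
    pd.DataFrame({
        "sample": table.samples,
        "group": [table.groups[s] for s in table.samples],
        "activity": [truth_c["activities"][s] for s in table.samples],
    }).to_csv(out / "community_metadata.csv", index=False)

    cfg = StudyConfig(
        congener_table=str(out / "congeners.csv"),
        qpcr_table=str(out / "qpcr.csv"),
        abundance_table=str(out / "abundance.tsv"),
        metadata=str(out / "metadata.csv"),
        community_metadata=str(out / "community_metadata.csv"),
        out_dir=str(out / "results"), seed=seed)
    cfg.to_yaml(out / "config.yaml")
    return cfg
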