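"""Study configuration and end-to-end orchestration.

``StudyConfig`` gathers the input paths and every analysis threshold
(activity 0.05 dCl/PCB, co-occurrence cutoffs |rho| > 0.6 and BH-adjusted
p < 0.01, > 50% prevalence, NST boundary 50% with 1000 randomizations,
> 90% dominance, 10x / 0.1 RDase/OHRB ratio bands, qPCR acceptability
bounds and LOD) with the study defaults; it round-trips through YAML.

``run_pipeline`` executes the stages in the order a dechlorination study is
analyzed -- congener statistics, qPCR quantification with ratio and
dominance calls, then community ecology (OHRB screening, diversity,
networks per activity group, NST, abundance-activity correlations) -- and
writes CSV/TSV/JSON outputs plus a run manifest recording package and
library versions, the seed, all thresholds, input checksums, and the count
surviving every filter decision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .dechlorination import DechlorResult, preference_class, summarize
from .ecology import (
    DEFAULT_OHRB_TAXA,
    alpha_diversity,
    build_network,
    nst,
    ohrb_screen,
    prevalence_filter,
)
from .qpcr import (
    OHRB_GENERA,
    RDASE_GENES,
    correlate_abundance_activity,
    dominance,
    fit_standard_curve,
    quantify,
    rdase_ohrb_ratio,
)

__all__ = ["StudyConfig", "run_pipeline"]

logger = logging.getLogger("pcbdechlor")


@dataclass
class StudyConfig:
    """Input paths, thresholds and options of one study analysis."""

    # input tables (paths; any may be None to skip that stage)
    congener_table: str | None = None
    qpcr_table: str | None = None
    abundance_table: str | None = None
    metadata: str | None = None
    community_metadata: str | None = None
    out_dir: str = "results"
    seed: int | None = 0
    # dechlorination
    activity_threshold: float = 0.05
    preference_alpha: float = 0.05
    detection_limit: float = 0.0
    # qPCR
    efficiency_bounds: tuple[float, float] = (0.90, 1.10)
    r2_min: float = 0.99
    lod_copies_per_reaction: float = 6.0
    dominance_frac: float = 0.90
    ratio_upper: float = 10.0
    ratio_lower: float = 0.1
    # ecology
    rho_cutoff: float = 0.6
    network_alpha: float = 0.01
    prevalence_min_frac: float = 0.5
    nst_randomizations: int = 1000
    nst_boundary: float = 50.0
    n_activity_groups: int = 4
    ohrb_taxa: tuple[str, ...] = DEFAULT_OHRB_TAXA

    def __post_init__(self) -> None:
        self.efficiency_bounds = tuple(self.efficiency_bounds)  # type: ignore
        self.ohrb_taxa = tuple(self.ohrb_taxa)  # type: ignore
        if not 0 <= self.activity_threshold <= 10:
            raise ValueError("activity_threshold out of range")
        if not 0 < self.rho_cutoff < 1 or not 0 < self.network_alpha < 1:
            raise ValueError("network cutoffs out of range")
        if not 0 <= self.prevalence_min_frac < 1:
            raise ValueError("prevalence_min_frac out of range")
        if not 0 < self.nst_boundary < 100 or self.nst_randomizations < 1:
            raise ValueError("NST settings out of range")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["efficiency_bounds"] = list(self.efficiency_bounds)
        d["ohrb_taxa"] = list(self.ohrb_taxa)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**d)


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _thresholds(cfg: StudyConfig) -> dict:
    d = dataclasses.asdict(cfg)
    for k in ("congener_table", "qpcr_table", "abundance_table", "metadata",
              "community_metadata", "out_dir"):
        d.pop(k)
    d["efficiency_bounds"] = list(cfg.efficiency_bounds)
    d["ohrb_taxa"] = list(cfg.ohrb_taxa)
    return d


def _dechlor_stage(cfg: StudyConfig, out: Path, meta: pd.DataFrame | None,
                   manifest: dict) -> pd.DataFrame | None:
    series_by_sample = pio.read_congener_table(cfg.congener_table)
    logger.info("read %d congener series", len(series_by_sample))
    # Replicate linkage: metadata column `microcosm` groups sample series.
    groups: dict[str, list] = {}
    for sid, s in series_by_sample.items():
        mid = sid
        if meta is not None and sid in meta.index and "microcosm" in meta.columns:
            mid = str(meta.loc[sid, "microcosm"])
        groups.setdefault(mid, []).append(s)
    results: list[DechlorResult] = []
    for mid in sorted(groups):
        reps = groups[mid]
        per_rep = [summarize(s, threshold=cfg.activity_threshold)
                   for s in reps]
        # replicate aggregation: statistics averaged over replicates
        active = any(r.active for r in per_rep)
        lag = next((r.lag for r in per_rep if r.lag is not None), None)
        if active and len([r for r in per_rep if r.active]) >= 2:
            pref = preference_class(
                [s for s, r in zip(reps, per_rep) if r.active],
                alpha=cfg.preference_alpha, threshold=cfg.activity_threshold)
        else:
            pref = per_rep[0].preference
        results.append(DechlorResult(
            microcosm_id=mid,
            delta_cl_total=float(np.mean([r.delta_cl_total for r in per_rep])),
            delta_cl_ortho=float(np.mean([r.delta_cl_ortho for r in per_rep])),
            delta_cl_meta=float(np.mean([r.delta_cl_meta for r in per_rep])),
            delta_cl_para=float(np.mean([r.delta_cl_para for r in per_rep])),
            active=active, lag=lag, preference=pref))
    pio.write_dechlor_results(results, out / "dechlorination.csv")
    n_active = sum(r.active for r in results)
    manifest["filters"]["microcosms_total"] = len(results)
    manifest["filters"]["microcosms_active"] = n_active
    logger.info("dechlorination: %d/%d microcosms active",
                n_active, len(results))
    return pd.read_csv(out / "dechlorination.csv")


def _qpcr_stage(cfg: StudyConfig, out: Path, manifest: dict) -> pd.DataFrame:
    standards, unknowns = pio.read_qpcr_table(cfg.qpcr_table)
    curves = {t: fit_standard_curve(s, efficiency_bounds=cfg.efficiency_bounds,
                                    r2_min=cfg.r2_min)
              for t, s in sorted(standards.items())}
    pio.write_curve_report(list(curves.values()), out / "standard_curves.csv")
    quants = []
    for row in unknowns.itertuples():
        if row.target not in curves or not np.isfinite(row.cq):
            continue  # non-detect or target without a curve
        quants.append(quantify(
            str(row.sample), float(row.cq), curves[str(row.target)],
            dilution_factor=float(row.dilution_factor),
            lod_copies_per_reaction=cfg.lod_copies_per_reaction,
            require_acceptable=False))
    per_sample: dict[str, dict[str, float]] = {}
    for q in quants:
        per_sample.setdefault(q.sample_id, {})[q.target] = q.copies_per_ml
    ratios, dom = [], {}
    for sid in sorted(per_sample):
        panel = per_sample[sid]
        ratios.append(rdase_ohrb_ratio(panel, sample_id=sid))
        dom[sid] = dominance({g: panel.get(g, 0.0) for g in OHRB_GENERA},
                             frac=cfg.dominance_frac)
    pio.write_quant_results(quants, ratios, dom, out / "gene_quants.csv",
                            out / "rdase_ohrb_ratios.csv")
    manifest["filters"]["qpcr_curves_acceptable"] = sum(
        c.acceptable for c in curves.values())
    manifest["filters"]["qpcr_samples_quantified"] = len(per_sample)
    manifest["filters"]["qpcr_below_lod"] = sum(q.below_lod for q in quants)
    logger.info("qPCR: %d curves (%d acceptable), %d samples",
                len(curves), sum(c.acceptable for c in curves.values()),
                len(per_sample))
    return pd.read_csv(out / "rdase_ohrb_ratios.csv")


def _ecology_stage(cfg: StudyConfig, out: Path, manifest: dict) -> dict:
    cmeta = (pio.read_metadata(cfg.community_metadata)
             if cfg.community_metadata else None)
    table = pio.read_abundance_table(cfg.abundance_table, metadata=cmeta)
    logger.info("abundance table: %d taxa x %d samples",
                len(table.taxa), len(table.samples))
    report: dict = {}

    screen = ohrb_screen(table, ohrb_taxa=cfg.ohrb_taxa)
    screen.to_csv(out / "ohrb_screen.csv")
    report["ohrb_occurrence_frequency"] = screen.attrs["occurrence_frequency"]
    manifest["filters"]["ohrb_positive_samples"] = int(screen["present"].sum())

    alpha = pd.DataFrame(
        [alpha_diversity(table.data[s]) for s in table.samples],
        index=table.samples, columns=["richness", "shannon", "pielou"])
    alpha.to_csv(out / "alpha_diversity.csv")

    # Activity-based grouping: quartiles of the metadata activity column
    # ("divided into four groups ... according to dehalogenation activity"),
    # unless explicit groups are given.
    activity = None
    if cmeta is not None and "activity" in cmeta.columns:
        activity = cmeta["activity"].reindex(table.samples).astype(float)
    if table.groups is None:
        if activity is not None and activity.notna().all():
            q = pd.qcut(activity.rank(method="first"),
                        min(cfg.n_activity_groups, len(activity)),
                        labels=False)
            table.groups = pd.Series(
                [f"Q{int(v) + 1}" for v in q], index=table.samples)
        else:
            table.groups = pd.Series("all", index=table.samples)

    report["groups"] = {}
    rng_seed = cfg.seed
    for gi, group in enumerate(sorted(table.groups.unique())):
        filtered = prevalence_filter(table, group=group,
                                     min_frac=cfg.prevalence_min_frac)
        manifest["filters"][f"genera_after_prevalence_{group}"] = len(
            filtered.taxa)
        net = build_network(filtered, rho_cutoff=cfg.rho_cutoff,
                            alpha=cfg.network_alpha)
        pio.write_network(net, out / f"network_{group}_edges.tsv",
                          out / f"network_{group}.graphml")
        seed_g = None if rng_seed is None else rng_seed + gi
        nst_res = nst(table, group=group, B=cfg.nst_randomizations,
                      seed=seed_g, boundary=cfg.nst_boundary)
        pio.write_nst(nst_res, out / f"nst_{group}.json",
                      out / f"nst_{group}_pairs.csv")
        report["groups"][group] = {
            "n_samples": len(table.group_samples(group)),
            "genera_tested": len(net.tested_taxa),
            "network": {"n_nodes": net.n_nodes, "n_edges": net.n_edges,
                        "average_degree": net.average_degree},
            "nst_percent": nst_res.nst, "assembly": nst_res.label,
        }
        logger.info("group %s: network n=%d L=%d <k>=%.2f, NST=%.1f%% (%s)",
                    group, net.n_nodes, net.n_edges, net.average_degree,
                    nst_res.nst, nst_res.label)

    if activity is not None and activity.notna().all() and np.ptp(activity) > 0:
        r, p = correlate_abundance_activity(
            screen["ohrb_relabund"].reindex(table.samples), activity)
        report["ohrb_activity_correlation"] = {"r": r, "p": p}
        rs, ps = correlate_abundance_activity(
            alpha["shannon"], activity)
        report["diversity_activity_correlation"] = {"r": rs, "p": ps}
    return report


def run_pipeline(cfg: StudyConfig) -> dict:
    """Run all configured stages; returns the report dict (also written as
    ``report.json`` beside the stage outputs and the run ``manifest.json``)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    import networkx
    import scipy

    from . import __version__
    manifest: dict = {
        "versions": {"pcbdechlor": __version__, "numpy": np.__version__,
                     "scipy": scipy.__version__, "pandas": pd.__version__,
                     "networkx": networkx.__version__},
        "seed": cfg.seed,
        "thresholds": _thresholds(cfg),
        "inputs": {},
        "filters": {},
    }
    for name in ("congener_table", "qpcr_table", "abundance_table",
                 "metadata", "community_metadata"):
        path = getattr(cfg, name)
        if path:
            manifest["inputs"][name] = {"path": str(path),
                                        "sha256": _sha256(path)}
    report: dict = {}
    meta = pio.read_metadata(cfg.metadata) if cfg.metadata else None
    if cfg.congener_table:
        dechlor = _dechlor_stage(cfg, out, meta, manifest)
        report["dechlorination"] = {
            "n_microcosms": int(len(dechlor)),
            "n_active": int(dechlor["active"].sum()),
            "mean_delta_cl_active": float(
                dechlor.loc[dechlor["active"], "delta_cl_total"].mean())
            if dechlor["active"].any() else float("nan"),
        }
    if cfg.qpcr_table:
        ratios = _qpcr_stage(cfg, out, manifest)
        report["qpcr"] = {
            "n_samples": int(len(ratios)),
            "band_counts": ratios["band"].value_counts().to_dict(),
            "dominance_counts": ratios["dominance"].value_counts().to_dict(),
        }
    if cfg.abundance_table:
        report["ecology"] = _ecology_stage(cfg, out, manifest)
    (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return report
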