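"""Readers and writers for the pipeline's table dialects.

All formats are plain text: congener concentration tables (CSV, long or
wide), qPCR result tables (CSV with a ``role`` column separating standards
from unknowns), genus abundance tables (TSV, taxa rows x sample columns
with an optional ``taxonomy`` column), sample metadata (CSV), dechlorination
result tables (CSV), network edge lists (TSV) plus GraphML, and NST records
(JSON + per-pair CSV).  Every writer's output is re-readable by the
matching reader.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .congeners import BIPHENYL, congener_table, parse_congener
from .dechlorination import CongenerProfile, DechlorResult, MicrocosmSeries
from .ecology import AbundanceTable, NetworkResult, NSTResult
from .qpcr import DilutionSeries, GeneQuant, RatioResult, StandardCurve

__all__ = [
    "export_congener_list",
    "read_abundance_table",
    "read_congener_table",
    "read_metadata",
    "read_qpcr_table",
    "write_abundance_table",
    "write_congener_table",
    "write_dechlor_results",
    "write_network",
    "write_nst",
    "write_qpcr_table",
]

LONG_COLUMNS = ("sample", "day", "congener", "value")


class TableFormatError(ValueError):
    """Malformed input table."""


def _validate_label(label: str, context: str) -> str:
    if label == BIPHENYL:
        return BIPHENYL
    try:
        return parse_congener(str(label)).label
    except ValueError as exc:
        raise TableFormatError(f"{context}: {exc}") from exc


def read_congener_table(path, sample_id: str | None = None
                        ) -> dict[str, MicrocosmSeries]:
    """Read congener concentration series (long or wide CSV).

    Long format has columns ``sample, day, congener, value`` (one row per
    measurement); wide format has congener labels in the first column and
    day numbers as the remaining column names, describing a single sample
    (id from ``sample_id`` or the file stem).  Labels are validated and
    canonicalized; duplicates and negative values are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if set(LONG_COLUMNS) <= set(df.columns):
        long = df[list(LONG_COLUMNS)].copy()
    else:
        first = df.columns[0]
        try:
            days = [float(c) for c in df.columns[1:]]
        except ValueError as exc:
            raise TableFormatError(
                f"{path}: wide-format day columns must be numeric "
                f"(got {list(df.columns[1:])})") from exc
        sid = sample_id or path.stem
        long = df.melt(id_vars=[first], var_name="day", value_name="value")
        long = long.rename(columns={first: "congener"})
        long["day"] = long["day"].astype(float)
        long["sample"] = sid
        del days
    long["congener"] = [
        _validate_label(lab, f"{path} row {i}")
        for i, lab in zip(long.index, long["congener"])]
    long["day"] = long["day"].astype(float)
    long["value"] = long["value"].astype(float)
    if (long["value"] < 0).any():
        bad = long[long["value"] < 0].iloc[0]
        raise TableFormatError(
            f"{path}: negative value {bad['value']} "
            f"(sample {bad['sample']}, day {bad['day']}, {bad['congener']})")
    dup = long.duplicated(subset=["sample", "day", "congener"])
    if dup.any():
        bad = long[dup].iloc[0]
        raise TableFormatError(
            f"{path}: duplicate entry (sample {bad['sample']}, "
            f"day {bad['day']}, {bad['congener']})")
    out: dict[str, MicrocosmSeries] = {}
    for sid, sdf in long.groupby("sample", sort=True):
        profiles = []
        for day, ddf in sorted(sdf.groupby("day"), key=lambda kv: kv[0]):
            profiles.append(CongenerProfile(
                sample_id=str(sid), day=float(day),
                values=dict(zip(ddf["congener"], ddf["value"]))))
        out[str(sid)] = MicrocosmSeries(microcosm_id=str(sid),
                                        profiles=tuple(profiles))
    return out


def write_congener_table(series: dict[str, MicrocosmSeries] | MicrocosmSeries,
                         path) -> None:
    """Write series as a long-format CSV (sample, day, congener, value)."""
    if isinstance(series, MicrocosmSeries):
        series = {series.microcosm_id: series}
    rows = [
        {"sample": p.sample_id, "day": p.day, "congener": lab, "value": v}
        for s in series.values() for p in s.profiles
        for lab, v in sorted(p.values.items())]
    pd.DataFrame(rows, columns=list(LONG_COLUMNS)).to_csv(path, index=False)


def read_qpcr_table(path) -> tuple[dict[str, DilutionSeries], pd.DataFrame]:
    """Read a qPCR result CSV into standards and unknowns.

    Required columns: ``sample, target, cq, dilution_factor, role``; rows
    with role ``standard`` additionally need ``nominal_copies_per_ml`` and
    form one dilution series per target; the remaining (role ``unknown``)
    rows are returned as a DataFrame.
    """
    df = pd.read_csv(path)
    required = {"sample", "target", "cq", "dilution_factor", "role"}
    if not required <= set(df.columns):
        raise TableFormatError(
            f"{path}: missing columns {sorted(required - set(df.columns))}")
    std = df[df["role"] == "standard"]
    if len(std) and "nominal_copies_per_ml" not in df.columns:
        raise TableFormatError(
            f"{path}: standards need a nominal_copies_per_ml column")
    series = {
        str(target): DilutionSeries(
            target=str(target),
            points=tuple(zip(tdf["nominal_copies_per_ml"].astype(float),
                             tdf["cq"].astype(float))))
        for target, tdf in std.groupby("target")}
    unknowns = df[df["role"] != "standard"].reset_index(drop=True)
    return series, unknowns


def write_qpcr_table(standards: dict[str, DilutionSeries],
                     unknowns: pd.DataFrame, path) -> None:
    rows = [
        {"sample": f"std_{t}_{i}", "target": t, "cq": q,
         "dilution_factor": 1.0, "role": "standard",
         "nominal_copies_per_ml": c}
        for t, s in sorted(standards.items())
        for i, (c, q) in enumerate(s.points)]
    df = pd.DataFrame(rows)
    unk = unknowns.copy()
    unk["role"] = "unknown"
    if "nominal_copies_per_ml" not in unk.columns:
        unk["nominal_copies_per_ml"] = float("nan")
    cols = ["sample", "target", "cq", "dilution_factor", "role",
            "nominal_copies_per_ml"]
    pd.concat([df[cols], unk[cols]], ignore_index=True).to_csv(path, index=False)


def read_abundance_table(path, mode: str = "counts",
                         metadata: pd.DataFrame | None = None,
                         group_column: str = "group") -> AbundanceTable:
    """Read a taxa x samples TSV (first column taxon id, optional
    ``taxonomy`` column, remaining columns samples)."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    taxonomy = None
    if "taxonomy" in df.columns:
        taxonomy = df["taxonomy"].astype(str)
        df = df.drop(columns=["taxonomy"])
    groups = None
    if metadata is not None and group_column in metadata.columns:
        groups = metadata[group_column].astype(str)
    return AbundanceTable(data=df.astype(float), taxonomy=taxonomy,
                          groups=groups, mode=mode)


def write_abundance_table(table: AbundanceTable, path) -> None:
    df = table.data.copy()
    df.insert(0, "taxonomy", table.taxonomy)
    df.index.name = "taxon_id"
    df.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    """Sample metadata CSV, indexed by its first column (sample id)."""
    df = pd.read_csv(path)
    return df.set_index(df.columns[0])


def write_dechlor_results(results: list[DechlorResult], path) -> None:
    """One CSV row per microcosm with activity, deltas, lag and preference."""
    rows = []
    for r in results:
        d = dataclasses.asdict(r)
        lag = d.pop("lag")
        d["lag_prev_day"] = lag["prev_day"] if lag else float("nan")
        d["lag_onset_day"] = lag["onset_day"] if lag else float("nan")
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_pathway_graph(graph: nx.DiGraph, edges_path, graphml_path=None) -> None:
    """Tab-delimited edge list (+ optional GraphML) of a pathway graph."""
    rows = [
        {"parent": u, "daughter": v, "position": d.get("position", ""),
         "flank": d.get("flank", ""), "multiplicity": d.get("multiplicity", 1),
         "flux": d.get("flux", float("nan"))}
        for u, v, d in graph.edges(data=True)]
    pd.DataFrame(rows, columns=["parent", "daughter", "position", "flank",
                                "multiplicity", "flux"]).to_csv(
        edges_path, sep="\t", index=False)
    if graphml_path is not None:
        g = graph.copy()
        g.graph.pop("flux_residuals", None)  # lists are not GraphML scalars
        nx.write_graphml(g, graphml_path)


def write_network(net: NetworkResult, edges_path, graphml_path=None) -> None:
    """Tested-pair table as TSV and the thresholded graph as GraphML."""
    net.edges.to_csv(edges_path, sep="\t", index=False)
    if graphml_path is not None:
        nx.write_graphml(net.graph, graphml_path)


def write_nst(result: NSTResult, json_path, pairs_path=None) -> None:
    record = {
        "group": result.group, "nst_percent": result.nst,
        "label": result.label, "n_randomizations": result.n_randomizations,
        "seed": result.seed,
    }
    Path(json_path).write_text(json.dumps(record, indent=2) + "\n")
    if pairs_path is not None:
        result.pairs.to_csv(pairs_path, index=False)


def write_curve_report(curves: list[StandardCurve], path) -> None:
    rows = [{
        "target": c.target, "slope": c.slope, "intercept": c.intercept,
        "r_squared": c.r_squared, "efficiency_percent": 100 * c.efficiency,
        "acceptable": c.acceptable, "flags": "; ".join(c.flags),
    } for c in curves]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_quant_results(quants: list[GeneQuant], ratios: list[RatioResult],
                        dominance_labels: dict[str, str], quants_path,
                        ratios_path) -> None:
    pd.DataFrame([dataclasses.asdict(q) for q in quants]).to_csv(
        quants_path, index=False)
    rows = []
    for r in ratios:
        d = dataclasses.asdict(r)
        d["dominance"] = dominance_labels.get(r.sample_id, "")
        rows.append(d)
    pd.DataFrame(rows).to_csv(ratios_path, index=False)


def export_congener_list(path) -> None:
    """Write the 209-congener structural table as CSV."""
    congener_table().to_csv(path, index=False)
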