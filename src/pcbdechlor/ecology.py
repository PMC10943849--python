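"""Community ecology of dechlorinating microbiomes from abundance tables.

Works on genus-level taxon x sample tables (counts or relative abundance):

* screening for known and putative organohalide-respiring bacteria (OHRB),
  including uncultivated Dehalococcoidia lineages, with per-sample presence
  and group occurrence frequencies;
* alpha diversity (richness, Shannon H, Pielou evenness) and Bray-Curtis /
  principal-coordinate (classical MDS) ordination;
* prevalence-filtered Spearman co-occurrence networks with
  Benjamini-Hochberg false-discovery control and topology metrics;
* the normalized stochasticity ratio (NST): a null-model statistic in
  [0, 100]% comparing observed Bray-Curtis dissimilarities with those of
  communities assembled by random multinomial draws from the group's
  regional species pool.  NST > 50% is read as stochastic-dominated
  assembly, < 50% as deterministic-dominated.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import braycurtis as _braycurtis, pdist, squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AbundanceTable",
    "DEFAULT_OHRB_TAXA",
    "EcologyError",
    "NSTResult",
    "NetworkResult",
    "PCoAResult",
    "alpha_diversity",
    "bray_curtis",
    "build_network",
    "compare_groups",
    "nst",
    "ohrb_screen",
    "pcoa",
    "prevalence_filter",
    "topology",
]

#: Known OHRB genera plus uncultivated Dehalococcoidia lineages implicated
#: in organohalide respiration.  Matched as case-insensitive substrings of
#: the taxonomy labels.
DEFAULT_OHRB_TAXA = (
    "Dehalococcoides", "Dehalogenimonas", "Dehalobacter",
    "S085", "vadinBA26", "GIF9", "DscP2", "t0.6.f",
)


class EcologyError(ValueError):
    """Invalid abundance table or ecology-statistic input."""


@dataclass
class AbundanceTable:
    """Taxon x sample abundance matrix with taxonomy and group metadata.

    ``data`` has taxa as rows and samples as columns; ``taxonomy`` maps
    taxon id to a genus-level label (defaults to the taxon id itself);
    ``groups`` optionally maps sample id to a group label; ``mode`` is
    ``"counts"`` (non-negative integers) or ``"relative"`` (columns sum
    to 1).
    """

    data: pd.DataFrame
    taxonomy: pd.Series | None = None
    groups: pd.Series | None = None
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise EcologyError("duplicate taxon ids")
        if self.data.columns.duplicated().any():
            raise EcologyError("duplicate sample ids")
        if (self.data.values < 0).any():
            raise EcologyError("negative abundances")
        if self.mode not in ("counts", "relative"):
            raise EcologyError(f"unknown mode {self.mode!r}")
        if self.mode == "relative":
            sums = self.data.sum(axis=0)
            if not np.allclose(sums[sums > 0], 1.0, atol=1e-6):
                raise EcologyError("relative-abundance columns must sum to 1")
        if self.taxonomy is None:
            self.taxonomy = pd.Series(self.data.index, index=self.data.index,
                                      dtype=object)
        else:
            self.taxonomy = self.taxonomy.reindex(self.data.index)
            if self.taxonomy.isna().any():
                raise EcologyError("taxonomy labels missing for some taxa")

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    def relative(self) -> pd.DataFrame:
        """Column-normalized relative abundances."""
        totals = self.data.sum(axis=0)
        if (totals == 0).any():
            empty = list(totals.index[totals == 0])
            raise EcologyError(f"samples with zero total abundance: {empty}")
        return self.data / totals

    def group_samples(self, group: str) -> list[str]:
        if self.groups is None:
            raise EcologyError("table has no group assignments")
        return [s for s in self.samples if self.groups.get(s) == group]


def ohrb_screen(table: AbundanceTable,
                ohrb_taxa: tuple[str, ...] = DEFAULT_OHRB_TAXA) -> pd.DataFrame:
    """Per-sample OHRB summed relative abundance and presence.

    A taxon is OHRB when its taxonomy label contains any entry of
    ``ohrb_taxa`` (case-insensitive).  Returns a DataFrame indexed by
    sample with columns ``ohrb_relabund`` and ``present``; overall
    occurrence frequency (fraction of samples with presence) is attached
    as ``df.attrs["occurrence_frequency"]``.
    """
    labels = table.taxonomy.astype(str)
    if (labels.str.strip() == "").all():
        raise EcologyError("empty taxonomy: cannot screen for OHRB")
    needles = [t.lower() for t in ohrb_taxa]
    is_ohrb = labels.str.lower().map(
        lambda s: any(n in s for n in needles)).astype(bool)
    rel = table.relative() if table.mode == "counts" else table.data
    summed = rel.loc[is_ohrb.values].sum(axis=0)
    out = pd.DataFrame({"ohrb_relabund": summed, "present": summed > 0})
    out.attrs["occurrence_frequency"] = float(out["present"].mean())
    out.attrs["ohrb_taxa"] = [t for t, f in zip(table.taxa, is_ohrb) if f]
    return out


def alpha_diversity(counts) -> tuple[int, float, float]:
    """(richness, Shannon H in nats, Pielou evenness) of one sample.

    H = -sum p_i ln p_i over detected taxa; Pielou J = H / ln(richness),
    NaN when richness <= 1.
    """
    x = np.asarray(counts, dtype=float)
    if (x < 0).any() or x.sum() <= 0:
        raise EcologyError("counts must be non-negative with positive total")
    p = x[x > 0] / x.sum()
    richness = int(len(p))
    shannon = float(-(p * np.log(p)).sum())
    pielou = shannon / math.log(richness) if richness > 1 else float("nan")
    return richness, shannon, pielou


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise EcologyError("vectors must be 1-d and equal length")
    if (xa < 0).any() or (ya < 0).any():
        raise EcologyError("negative abundances")
    if xa.sum() + ya.sum() == 0:
        raise EcologyError("Bray-Curtis undefined for two all-zero vectors")
    return float(_braycurtis(xa, ya))


@dataclass(frozen=True)
class PCoAResult:
    """Classical-scaling ordination of a dissimilarity matrix."""

    coordinates: np.ndarray        # n_samples x k
    explained: np.ndarray          # fraction of positive eigenvalue mass, per axis
    eigenvalues: np.ndarray        # all eigenvalues, descending (negatives kept)
    sample_ids: tuple[str, ...] = ()


def pcoa(d, k: int = 2, sample_ids: tuple[str, ...] = ()) -> PCoAResult:
    """Principal coordinate analysis (classical metric MDS).

    Double-centers -D^2/2 and eigendecomposes; coordinates are returned for
    the top ``k`` positive eigenvalues and explained fractions are relative
    to the positive eigenvalue total.  Negative eigenvalues (non-Euclidean
    dissimilarities such as Bray-Curtis) are reported, not corrected.
    """
    dm = np.asarray(d, dtype=float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise EcologyError("dissimilarity matrix must be square")
    if not np.allclose(dm, dm.T, atol=1e-12):
        raise EcologyError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(dm), 0.0, atol=1e-12):
        raise EcologyError("dissimilarity matrix must have a zero diagonal")
    n = dm.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-12, 1e-10 * abs(evals[0])) if n > 1 else evals > 0
    k_eff = min(k, int(pos.sum()))
    coords = evecs[:, :k_eff] * np.sqrt(evals[:k_eff])
    explained = evals[:k_eff] / evals[pos].sum() if k_eff else np.empty(0)
    return PCoAResult(coordinates=coords, explained=explained,
                      eigenvalues=evals, sample_ids=tuple(sample_ids))


def prevalence_filter(table: AbundanceTable, group: str | None = None,
                      min_frac: float = 0.5) -> AbundanceTable:
    """Keep taxa detected in strictly more than ``min_frac`` of the group's
    samples; drop singletons (total count 1 across the group, counts mode).

    ``group=None`` filters over all samples.  Detection means any count
    (or relative abundance) > 0.
    """
    samples = table.samples if group is None else table.group_samples(group)
    if len(samples) < 2:
        raise EcologyError("prevalence filter needs a group with >= 2 samples")
    sub = table.data[samples]
    prevalence = (sub > 0).sum(axis=1) / len(samples)
    keep = prevalence > min_frac
    if table.mode == "counts":
        keep &= sub.sum(axis=1) > 1  # exclude singletons
    return AbundanceTable(
        data=sub.loc[keep], taxonomy=table.taxonomy.loc[keep],
        groups=None if table.groups is None else table.groups[samples],
        mode=table.mode)


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray,
                      perms: np.ndarray) -> float:
    """Two-sided exact permutation p for Spearman's rho at small n (< 10).

    ``perms`` holds all n! index permutations; the permutation distribution
    of the centered rank cross-product is compared with its observed value.
    """
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    obs = abs(float(rxc @ ryc))
    stat = np.abs(ryc[perms] @ rxc)
    return float((stat >= obs - 1e-12).mean())


def _spearman_matrix(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Spearman rho and two-sided p over columns of ``mat``.

    p-values use the t approximation for n >= 10 samples and exact rank
    permutation below that.
    """
    n, m = mat.shape
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(mat)
    if m == 2:  # scipy returns scalars for a single pair
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    if n < 10:
        ranks = np.apply_along_axis(stats.rankdata, 0, mat)
        perms = np.array(list(itertools.permutations(range(n))))
        for i in range(m):
            for j in range(i + 1, m):
                p[i, j] = p[j, i] = _spearman_exact_p(
                    ranks[:, i], ranks[:, j], perms)
    return rho, p


@dataclass(frozen=True)
class NetworkResult:
    """Co-occurrence network: graph over genera plus the tested-edge table."""

    graph: nx.Graph
    edges: pd.DataFrame      # source, target, rho, p_raw, p_adj, sign
    tested_taxa: tuple[str, ...]
    rho_cutoff: float
    alpha: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def average_degree(self) -> float:
        n = self.n_nodes
        return 2.0 * self.n_edges / n if n else 0.0


def build_network(table: AbundanceTable, rho_cutoff: float = 0.6,
                  alpha: float = 0.01) -> NetworkResult:
    """Spearman co-occurrence network with Benjamini-Hochberg control.

    All pairs of (non-constant) genera are tested on relative abundances;
    p-values are BH-adjusted over all tested pairs; an edge requires both
    |rho| > ``rho_cutoff`` and adjusted p < ``alpha``.  Nodes of the
    resulting graph are the genera incident to at least one edge.
    """
    rel = table.relative() if table.mode == "counts" else table.data
    if rel.shape[1] < 4:
        raise EcologyError("network inference needs >= 4 samples")
    mat = rel.values.T  # samples x genera
    taxa = np.array(table.taxa)
    const = np.ptp(mat, axis=0) == 0
    if const.any():
        warnings.warn(
            f"excluding {int(const.sum())} constant genus vector(s) from "
            f"correlation testing: {list(taxa[const])}", stacklevel=2)
        mat, taxa = mat[:, ~const], taxa[~const]
    if mat.shape[1] < 2:
        raise EcologyError("network inference needs >= 2 non-constant genera")
    rho, p = _spearman_matrix(mat)
    iu, ju = np.triu_indices(len(taxa), k=1)
    p_raw = p[iu, ju]
    _, p_adj, _, _ = multipletests(p_raw, method="fdr_bh")
    edges = pd.DataFrame({
        "source": taxa[iu], "target": taxa[ju],
        "rho": rho[iu, ju], "p_raw": p_raw, "p_adj": p_adj,
    })
    edges["sign"] = np.where(edges["rho"] >= 0, "positive", "negative")
    edges["edge"] = (edges["rho"].abs() > rho_cutoff) & (edges["p_adj"] < alpha)
    g = nx.Graph()
    for row in edges[edges["edge"]].itertuples():
        g.add_edge(row.source, row.target, rho=float(row.rho),
                   p_raw=float(row.p_raw), p_adj=float(row.p_adj),
                   sign=row.sign)
    return NetworkResult(graph=g, edges=edges, tested_taxa=tuple(taxa),
                         rho_cutoff=rho_cutoff, alpha=alpha)


def topology(net: NetworkResult) -> tuple[int, int, float]:
    """(n nodes, L edges, average degree 2L/n; 0 for the empty graph)."""
    return net.n_nodes, net.n_edges, net.average_degree


@dataclass(frozen=True)
class NSTResult:
    """Normalized stochasticity ratio for one sample group."""

    group: str
    nst: float               # percent, in [0, 100]
    label: str               # stochastic-dominated / deterministic-dominated
    pairs: pd.DataFrame      # sample_i, sample_j, d_obs, e_null, ratio
    n_randomizations: int
    seed: int | None


def nst(table: AbundanceTable, group: str | None = None, B: int = 1000,
        seed: int | None = None, boundary: float = 50.0) -> NSTResult:
    """Normalized stochasticity ratio of a sample group's assembly.

    The group's regional pool assigns each taxon a probability proportional
    to its summed abundance across the group; ``B`` null communities per
    sample are drawn multinomially at the sample's observed depth.  For
    each sample pair the observed Bray-Curtis dissimilarity D_obs is
    compared with the null-mean E_null through the magnitude ratio
    min(D_obs, E_null) / max(D_obs, E_null); NST is the group mean of that
    ratio x 100%.  Communities indistinguishable from their own null model
    score near 100%; strongly structured (deterministic) groups score low.
    NST > ``boundary`` (50%) is labeled stochastic-dominated.
    """
    if table.mode != "counts":
        raise EcologyError("NST requires a counts-mode table")
    samples = table.samples if group is None else table.group_samples(group)
    if len(samples) < 3:
        raise EcologyError("NST needs a group with >= 3 samples")
    if B < 100:
        warnings.warn(f"B={B} randomizations is low; null means will be "
                      "noisy (>= 1000 recommended)", stacklevel=2)
    counts = table.data[samples].values.T.astype(float)  # samples x taxa
    if not np.allclose(counts, np.round(counts)):
        raise EcologyError("NST counts mode requires integer counts")
    counts = np.round(counts).astype(np.int64)
    depths = counts.sum(axis=1)
    if (depths == 0).any():
        raise EcologyError("samples with zero total count")
    pool = counts.sum(axis=0) / counts.sum()
    rng = np.random.default_rng(seed)
    d_obs = pdist(counts, metric="braycurtis")
    null_sum = np.zeros_like(d_obs)
    for _ in range(B):
        null = rng.multinomial(depths, pool)  # samples x taxa
        null_sum += pdist(null, metric="braycurtis")
    e_null = null_sum / B
    hi = np.maximum(d_obs, e_null)
    ratio = np.where(hi > 0, np.minimum(d_obs, e_null) / np.where(hi > 0, hi, 1.0), 1.0)
    value = float(100.0 * ratio.mean())
    iu, ju = np.triu_indices(len(samples), k=1)
    pairs = pd.DataFrame({
        "sample_i": np.array(samples)[iu], "sample_j": np.array(samples)[ju],
        "d_obs": d_obs, "e_null": e_null, "ratio": ratio,
    })
    label = ("stochastic-dominated" if value > boundary
             else "deterministic-dominated")
    return NSTResult(group=group if group is not None else "all", nst=value,
                     label=label, pairs=pairs, n_randomizations=B, seed=seed)


def compare_groups(values, labels) -> tuple[float, float]:
    """One-way ANOVA (F, p) of ``values`` across the groups in ``labels``."""
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    if v.shape != lab.shape:
        raise EcologyError("values and labels must align")
    groups = [v[lab == g] for g in pd.unique(lab)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise EcologyError("need >= 2 groups with >= 2 values each")
    if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        raise EcologyError("all values identical; ANOVA degenerate")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)
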