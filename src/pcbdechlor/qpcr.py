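"""qPCR calibration and quantification of OHRB genera and PCB-RDase genes.

Real-time PCR quantification cycle Cq is linear in log10 template copies
over the calibrated range: Cq = intercept + slope * log10(copies), with
slope < 0 and amplification efficiency E = 10^(-1/slope) - 1 (E = 1 for the
ideal slope of -log2(10) ~ -3.3219).  A standard curve is fitted by
ordinary least squares on a plasmid dilution series and inverted to
quantify unknowns; per-reaction copies below the limit of detection (LOD)
are flagged.

Downstream analyses mirror how organohalide-respiring bacteria (OHRB:
Dehalococcoides, Dehalogenimonas, Dehalobacter; 16S-based, reported as
cells/mL) and PCB reductive-dehalogenase genes (pcbA1, pcbA4, pcbA5;
copies/mL) are compared: the summed RDase/OHRB ratio with a 10-fold
quantification-uncertainty band (ratio > 10 suggests quantification bias,
ratio < 0.1 suggests RDases not captured by the assayed genes), a > 90%
single-genus dominance call, and abundance-activity correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DilutionSeries",
    "GeneQuant",
    "OHRB_GENERA",
    "QpcrError",
    "RDASE_GENES",
    "RatioResult",
    "StandardCurve",
    "correlate_abundance_activity",
    "dominance",
    "fit_standard_curve",
    "quantify",
    "rdase_ohrb_ratio",
]

OHRB_GENERA = ("Dehalococcoides", "Dehalogenimonas", "Dehalobacter")
RDASE_GENES = ("pcbA1", "pcbA4", "pcbA5")

#: Conservative end of the assay's printed 6-9 copies/reaction LOD band.
DEFAULT_LOD_COPIES_PER_REACTION = 6.0
#: Template volume per reaction (mL); 2 uL of template in a 20 uL reaction.
DEFAULT_TEMPLATE_VOLUME_ML = 0.002


class QpcrError(ValueError):
    """Invalid dilution series, curve, or quantification input."""


@dataclass(frozen=True)
class DilutionSeries:
    """Standard-curve input: (nominal copies/mL, Cq) pairs for one target."""

    target: str
    points: tuple[tuple[float, float], ...]  # (copies_per_ml, cq)
    template_volume_ml: float = DEFAULT_TEMPLATE_VOLUME_ML

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(
            (float(c), float(q)) for c, q in self.points))
        for c, q in self.points:
            if c <= 0:
                raise QpcrError(f"{self.target}: nominal copies must be > 0, got {c}")
            if not np.isfinite(q) or q <= 0:
                raise QpcrError(f"{self.target}: Cq must be finite and positive, got {q}")


@dataclass(frozen=True)
class StandardCurve:
    """Fitted log-linear qPCR calibration for one target."""

    target: str
    slope: float       # Cq per log10 copies, < 0
    intercept: float   # Cq at 1 copy/mL
    r_squared: float
    efficiency: float  # fraction: 1.0 == 100%
    acceptable: bool
    flags: tuple[str, ...] = ()
    template_volume_ml: float = DEFAULT_TEMPLATE_VOLUME_ML


@dataclass(frozen=True)
class GeneQuant:
    """Quantified target in one sample (copies/mL, or cells/mL for
    16S-based genus targets)."""

    sample_id: str
    target: str
    copies_per_ml: float
    below_lod: bool
    lod_copies_per_reaction: float


@dataclass(frozen=True)
class RatioResult:
    """Summed RDase-gene to summed OHRB-cell ratio with uncertainty band."""

    sample_id: str
    ratio: float  # nan when the OHRB denominator is zero
    band: str     # within-band / above-10x / below-0.1 / undefined
    rdase_copies_per_ml: float
    ohrb_cells_per_ml: float


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency E = 10^(-1/slope) - 1 (fraction)."""
    if slope >= 0:
        raise QpcrError(f"standard-curve slope must be negative, got {slope}")
    return 10.0 ** (-1.0 / slope) - 1.0


def fit_standard_curve(series: DilutionSeries,
                       efficiency_bounds: tuple[float, float] = (0.90, 1.10),
                       r2_min: float = 0.99) -> StandardCurve:
    """OLS fit of Cq on log10(nominal copies/mL).

    Acceptability requires r^2 >= ``r2_min`` and efficiency within
    ``efficiency_bounds`` (fractions); out-of-bound curves are returned
    with ``acceptable=False`` and explanatory flags rather than rejected.
    """
    log_copies = np.log10([c for c, _ in series.points])
    cq = np.array([q for _, q in series.points])
    if len(set(log_copies)) < 3:
        raise QpcrError(
            f"{series.target}: need >= 3 distinct dilution levels, "
            f"got {len(set(log_copies))}")
    fit = stats.linregress(log_copies, cq)
    if fit.slope >= 0:
        raise QpcrError(
            f"{series.target}: non-negative slope {fit.slope:.3g}; Cq must "
            "decrease with template amount")
    eff = efficiency_from_slope(fit.slope)
    flags = []
    if fit.rvalue ** 2 < r2_min:
        flags.append(f"r_squared {fit.rvalue**2:.4f} < {r2_min}")
    if not efficiency_bounds[0] <= eff <= efficiency_bounds[1]:
        flags.append(
            f"efficiency {100*eff:.1f}% outside "
            f"[{100*efficiency_bounds[0]:.1f}%, {100*efficiency_bounds[1]:.1f}%]")
    return StandardCurve(
        target=series.target, slope=float(fit.slope),
        intercept=float(fit.intercept), r_squared=float(fit.rvalue ** 2),
        efficiency=float(eff), acceptable=not flags, flags=tuple(flags),
        template_volume_ml=series.template_volume_ml)


def quantify(sample_id: str, cq: float, curve: StandardCurve,
             dilution_factor: float = 1.0,
             lod_copies_per_reaction: float = DEFAULT_LOD_COPIES_PER_REACTION,
             require_acceptable: bool = True) -> GeneQuant:
    """Invert the standard curve: copies/mL = dilution * 10^((Cq - b)/m).

    The below-LOD flag compares copies present in the reaction itself
    (undiluted-template copies/mL x template volume) against
    ``lod_copies_per_reaction``.
    """
    if not np.isfinite(cq):
        raise QpcrError(f"{sample_id}/{curve.target}: non-finite Cq {cq!r}")
    if require_acceptable and not curve.acceptable:
        raise QpcrError(
            f"{sample_id}/{curve.target}: curve flagged unacceptable "
            f"({'; '.join(curve.flags)}); pass require_acceptable=False to override")
    raw_copies_per_ml = 10.0 ** ((cq - curve.intercept) / curve.slope)
    copies_per_reaction = raw_copies_per_ml * curve.template_volume_ml
    return GeneQuant(
        sample_id=sample_id, target=curve.target,
        copies_per_ml=float(dilution_factor * raw_copies_per_ml),
        below_lod=bool(copies_per_reaction < lod_copies_per_reaction),
        lod_copies_per_reaction=lod_copies_per_reaction)


def rdase_ohrb_ratio(quants: dict[str, float], sample_id: str = "",
                     rdase_genes: tuple[str, ...] = RDASE_GENES,
                     ohrb_genera: tuple[str, ...] = OHRB_GENERA) -> RatioResult:
    """(pcbA1+pcbA4+pcbA5 copies/mL) / (Dhc+Dhg+Dhb cells/mL) with band flag.

    ``quants`` maps target name to abundance; missing targets count as 0
    with a warning.  Band flags are strict: ``above-10x`` for ratio > 10,
    ``below-0.1`` for ratio < 0.1 (suggesting RDases beyond the assayed
    genes), ``within-band`` otherwise; a zero OHRB denominator yields an
    ``undefined`` flag (low-abundance quantification bias).
    """
    missing = [t for t in (*rdase_genes, *ohrb_genera) if t not in quants]
    if missing:
        warnings.warn(
            f"sample {sample_id!r}: targets {missing} not quantified; "
            "treated as 0", stacklevel=2)
    rdase = sum(float(quants.get(t, 0.0)) for t in rdase_genes)
    ohrb = sum(float(quants.get(t, 0.0)) for t in ohrb_genera)
    if rdase < 0 or ohrb < 0:
        raise QpcrError(f"sample {sample_id!r}: negative abundances")
    if ohrb == 0:
        return RatioResult(sample_id, float("nan"), "undefined", rdase, ohrb)
    ratio = rdase / ohrb
    band = "above-10x" if ratio > 10 else "below-0.1" if ratio < 0.1 else "within-band"
    return RatioResult(sample_id, float(ratio), band, rdase, ohrb)


def dominance(genus_quants: dict[str, float],
              frac: float = 0.90) -> str:
    """OHRB dominance label from per-genus cell densities.

    ``solely-dominated:<genus>`` when one genus strictly exceeds ``frac``
    of the summed OHRB abundance, ``codominated`` otherwise, ``undetected``
    for an all-zero panel.
    """
    if any(v < 0 for v in genus_quants.values()):
        raise QpcrError("negative genus abundance")
    total = sum(genus_quants.values())
    if total == 0:
        return "undetected"
    top_genus = max(genus_quants, key=lambda g: genus_quants[g])
    if genus_quants[top_genus] > frac * total:
        return f"solely-dominated:{top_genus}"
    return "codominated"


def correlate_abundance_activity(abundance, activity, method: str = "pearson",
                                 log10_abundance: bool = False) -> tuple[float, float]:
    """Correlation (r, p) between target abundance and dCl/PCB activity."""
    x = np.asarray(abundance, dtype=float)
    y = np.asarray(activity, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise QpcrError("need paired 1-d vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise QpcrError("non-finite values in correlation input")
    if log10_abundance:
        if (x <= 0).any():
            raise QpcrError("log10 transform requires positive abundances")
        x = np.log10(x)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise QpcrError("zero variance in correlation input")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise QpcrError(f"unknown method {method!r}; use pearson or spearman")
    return float(r), float(p)
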