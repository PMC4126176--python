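"""Absolute quantification by qPCR and 16S copy-number normalisation.

Standard curves Cq = slope * log10(copies) + intercept are fitted by
ordinary least squares over 10-fold dilution series (10^2-10^7 copies for
gene assays, 10^3-10^8 for total 16S); amplification efficiency is
10^(-1/slope) - 1.  Sample Cq replicates are back-transformed to the
copies scale first and then averaged, with the half-range kept as the
error bar.  Copies below the 10^2 detection limit are reported as 0 with
a below-detection flag.

Percent-of-community values put all assays on a common genome basis: the
target genes are single copy while gut bacteria average five 16S rRNA
operons, so functional-gene copies are multiplied by five before division
by total 16S copies; 16S-targeted assays are first divided by their
taxon's own copy number and then scaled to the same five-copy basis.
The same normalisation screens 16S taxon count tables for butyrate-
producer candidates attributed to the *but* and/or *buk* pathways.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "QpcrMeasurement",
    "CopyNumberTable",
    "QuantResult",
    "InvalidCurveError",
    "DETECTION_LIMIT",
    "COMMUNITY_AVG_16S_COPIES",
    "fit_standard_curve",
    "quantify",
    "percent_of_community",
    "screen_taxa",
]

DETECTION_LIMIT = 1e2  # target copies
COMMUNITY_AVG_16S_COPIES = 5.0  # average 16S rRNA operons per gut genome


class InvalidCurveError(ValueError):
    pass


@dataclass(frozen=True)
class StandardCurve:
    assay: str
    slope: float
    intercept: float
    r_squared: float
    log10_span: tuple[float, float]

    @property
    def efficiency(self) -> float:
        """Amplification efficiency, 1.0 = perfect doubling per cycle."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def copies_from_cq(self, cq: float) -> float:
        return 10.0 ** ((cq - self.intercept) / self.slope)


@dataclass(frozen=True)
class QpcrMeasurement:
    sample: str
    assay: str
    cq_replicates: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.cq_replicates:
            raise ValueError("at least one Cq replicate required")


@dataclass(frozen=True)
class CopyNumberTable:
    """Per-taxon mean 16S copy numbers with a logged default fallback."""

    copies: dict[str, float]
    default_copies: float = COMMUNITY_AVG_16S_COPIES

    def lookup(self, taxon: str) -> float:
        if taxon in self.copies:
            return self.copies[taxon]
        warnings.warn(
            f"no 16S copy number for {taxon!r}; using default {self.default_copies}",
            stacklevel=2,
        )
        return self.default_copies


@dataclass(frozen=True)
class QuantResult:
    sample: str
    assay: str
    copies: float
    copies_half_range: float
    percent_of_community: float | None
    below_detection: bool


def fit_standard_curve(
    points: Sequence[tuple[float, float]], assay: str = ""
) -> StandardCurve:
    """OLS fit of Cq against log10 copies over a dilution series.

    `points` are (log10 copies, Cq) pairs; at least four dilution levels
    are required and the slope must be negative.
    """
    if len(points) < 4:
        raise InvalidCurveError(f"{assay}: need >=4 dilution points, got {len(points)}")
    logc = np.asarray([p[0] for p in points], dtype=float)
    cq = np.asarray([p[1] for p in points], dtype=float)
    fit = stats.linregress(logc, cq)
    if fit.slope >= 0:
        raise InvalidCurveError(f"{assay}: non-negative slope {fit.slope:.3f}")
    return StandardCurve(
        assay=assay,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        log10_span=(float(logc.min()), float(logc.max())),
    )


def quantify(
    m: QpcrMeasurement,
    curve: StandardCurve,
    detection_limit: float = DETECTION_LIMIT,
) -> QuantResult:
    """Back-transform Cq replicates to copies, then average.

    Averaging happens on the copies scale (not on Cq), and the half-range
    over replicates is kept as the error bar.  Cq values outside the
    fitted dilution span trigger an extrapolation warning.  Below the
    detection limit, copies propagate as 0 with the flag set.
    """
    per_rep = np.array([curve.copies_from_cq(cq) for cq in m.cq_replicates])
    lo, hi = curve.log10_span
    if np.any((np.log10(per_rep) < lo - 1e-9) | (np.log10(per_rep) > hi + 1e-9)):
        warnings.warn(
            f"{m.sample}/{m.assay}: Cq outside the standard-curve span; extrapolating",
            stacklevel=2,
        )
    copies = float(per_rep.mean())
    half_range = float((per_rep.max() - per_rep.min()) / 2.0)
    # relative epsilon so a measurement at exactly the limit is not flagged
    below = copies < detection_limit * (1.0 - 1e-9)
    if below:
        copies, half_range = 0.0, 0.0
    return QuantResult(
        sample=m.sample,
        assay=m.assay,
        copies=copies,
        copies_half_range=half_range,
        percent_of_community=None,
        below_detection=below,
    )


def percent_of_community(
    target_copies: float,
    total_16s_copies: float,
    functional_gene: bool = True,
    taxon_16s_copies: float | None = None,
    community_avg_copies: float = COMMUNITY_AVG_16S_COPIES,
) -> float:
    """Express target copies as percent of the total bacterial community.

    Functional genes (single copy per genome) are multiplied by the
    community-average 16S copy number (five); 16S-targeted assays are
    divided by their own taxon's copy number and then put on the same
    five-copy basis.
    """
    if total_16s_copies <= 0:
        raise ValueError("total 16S copies must be positive")
    if functional_gene:
        genome_equivalents = target_copies
    else:
        if taxon_16s_copies is None or taxon_16s_copies <= 0:
            raise ValueError("16S-targeted assays need the taxon's copy number")
        genome_equivalents = target_copies / taxon_16s_copies
    return 100.0 * community_avg_copies * genome_equivalents / total_16s_copies


def screen_taxa(
    taxon_counts: pd.DataFrame,
    candidates: Mapping[str, str],
    copy_table: CopyNumberTable,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen a sample x taxon 16S count table for butyrate producers.

    `candidates` maps taxon -> pathway in {"but", "buk", "both"}.  Each
    candidate's counts are divided by its 16S copy number (genome
    equivalents), rescaled to the five-copy community basis, and expressed
    as percent of the sample's total counts; "both" taxa contribute to
    both pathways.

    Returns (genome_equivalents, pathway_percent): the former is
    sample x candidate-taxon, the latter sample x {but, buk}.
    """
    bad = {pw for pw in candidates.values()} - {"but", "buk", "both"}
    if bad:
        raise ValueError(f"unknown pathway labels: {sorted(bad)}")
    present = [t for t in candidates if t in taxon_counts.columns]
    totals = taxon_counts.sum(axis=1).astype(float)

    ge = pd.DataFrame(index=taxon_counts.index, columns=present, dtype=float)
    for taxon in present:
        ge[taxon] = taxon_counts[taxon].astype(float) / copy_table.lookup(taxon)

    pct = pd.DataFrame(0.0, index=taxon_counts.index, columns=["but", "buk"])
    for taxon in present:
        share = 100.0 * COMMUNITY_AVG_16S_COPIES * ge[taxon] / totals.replace(0, np.nan)
        share = share.fillna(0.0)
        pw = candidates[taxon]
        if pw in ("but", "both"):
            pct["but"] += share
        if pw in ("buk", "both"):
            pct["buk"] += share
    ge.index.name = pct.index.name = "sample"
    return ge, pct
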