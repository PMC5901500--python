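"""Assay-corrected allelic log-ratios for differential allelic expression.

For a heterozygous SNP the raw statistic is the natural log of the ratio of
the two allele peak heights, r = ln(h_ref / h_alt).  Reverse-strand reads
report complementary bases and are re-oriented onto the forward strand so
every ratio has the designated reference allele in the numerator.  Genomic
DNA from the same heterozygous individuals carries a true 1:1 allele ratio,
so the mean gDNA log-ratio per sequencing direction estimates the assay/dye
bias of that direction; subtracting it yields the corrected ratio

    rho = r_oriented - mean(r_gDNA, same direction).

Corrected gDNA ratios therefore average exactly zero per direction, and any
additive direction-specific bias cancels.  Forward and reverse measurements
of a sample are combined by averaging the corrected log-ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .trace_io import COMPLEMENT, PeakPair

__all__ = [
    "AllelicMeasurement",
    "DAEStudy",
    "UndefinedRatioError",
    "AlleleMismatchError",
    "CenteringError",
    "log_allelic_ratio",
    "measurement_from_pair",
    "orient_measurement",
    "center_by_gdna",
    "combine_directions",
    "summarize_snp",
    "measurements_frame",
]

GROUP_FAMILY = "affected_family"
GROUP_CONTROL = "control"


class UndefinedRatioError(ValueError):
    """A peak pair with a zero height has no log-ratio."""


class AlleleMismatchError(ValueError):
    """Observed alleles are inconsistent with the SNP's allele pair."""


class CenteringError(ValueError):
    """A sequencing direction has no usable gDNA measurement to center on."""


@dataclass
class AllelicMeasurement:
    """One oriented ln allele-height ratio with its design labels."""

    sample_id: str
    snp_id: str
    group: str  # "affected_family" or "control" (free-form strata allowed)
    template: str  # "cDNA" or "gDNA"
    direction: str  # "F" or "R"
    r: float
    oriented: bool = False
    rho: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.r):
            raise ValueError("raw log-ratio must be finite")
        if self.template not in ("cDNA", "gDNA"):
            raise ValueError(f"template must be 'cDNA' or 'gDNA', got {self.template!r}")
        if self.direction not in ("F", "R"):
            raise ValueError(f"direction must be 'F' or 'R', got {self.direction!r}")


@dataclass
class DAEStudy:
    """All measurements of one SNP plus its forward-strand allele pair.

    ``gdna_means`` (direction -> mean oriented gDNA r) is filled by
    :func:`center_by_gdna`; ``combined`` (per sample x template mean of the
    corrected ratios over directions) by :func:`combine_directions`.
    """

    snp_id: str
    reference_allele: str
    alternate_allele: str
    measurements: list[AllelicMeasurement] = field(default_factory=list)
    gdna_means: dict[str, float] = field(default_factory=dict)
    combined: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.reference_allele = self.reference_allele.upper()
        self.alternate_allele = self.alternate_allele.upper()
        if self.reference_allele == self.alternate_allele:
            raise ValueError("reference and alternate allele must differ")


def log_allelic_ratio(pair: PeakPair) -> float:
    """Natural log of the allele peak-height ratio, ln(height1 / height2)."""
    if pair.height1 <= 0 or pair.height2 <= 0:
        raise UndefinedRatioError(
            f"{pair.snp_id}/{pair.sample_id}: zero peak height, ratio undefined"
        )
    return math.log(pair.height1 / pair.height2)


def measurement_from_pair(pair: PeakPair, group: str) -> AllelicMeasurement:
    """Build an (unoriented) measurement from a peak pair and its group label."""
    return AllelicMeasurement(
        sample_id=pair.sample_id,
        snp_id=pair.snp_id,
        group=group,
        template=pair.template,
        direction=pair.direction,
        r=log_allelic_ratio(pair),
    )


def orient_measurement(
    m: AllelicMeasurement,
    reference_allele: str,
    alternate_allele: str,
    observed_allele1: str,
    observed_allele2: str,
) -> AllelicMeasurement:
    """Map a measurement onto the forward strand with the reference allele first.

    Reverse-direction alleles are complemented to forward-strand bases; if the
    numerator allele then differs from ``reference_allele`` the log-ratio is
    negated.  Orienting an already-oriented measurement is the identity.
    """
    if m.oriented:
        return m
    ref, alt = reference_allele.upper(), alternate_allele.upper()
    a1, a2 = observed_allele1.upper(), observed_allele2.upper()
    if m.direction == "R":
        try:
            a1, a2 = COMPLEMENT[a1], COMPLEMENT[a2]
        except KeyError as exc:
            raise AlleleMismatchError(f"cannot complement allele {exc}") from exc
    if {a1, a2} != {ref, alt}:
        raise AlleleMismatchError(
            f"{m.snp_id}/{m.sample_id}: observed alleles {a1}/{a2} (forward strand) "
            f"do not match SNP alleles {ref}/{alt}"
        )
    r = m.r if a1 == ref else -m.r
    return replace(m, r=r, oriented=True)


def center_by_gdna(study: DAEStudy) -> DAEStudy:
    """Center all log-ratios by the per-direction mean gDNA log-ratio.

    The gDNA reference group pools every oriented gDNA measurement of the
    study (family and controls alike).  Every measurement of direction d —
    cDNA and gDNA — receives ``rho = r - mean_d``; the corrected gDNA mean per
    direction is zero by construction.
    """
    for m in study.measurements:
        if not m.oriented:
            raise ValueError("center_by_gdna requires oriented measurements")
    directions = sorted({m.direction for m in study.measurements})
    means: dict[str, float] = {}
    for d in directions:
        gdna = [m.r for m in study.measurements if m.direction == d and m.template == "gDNA"]
        if not gdna:
            raise CenteringError(
                f"{study.snp_id}: no gDNA measurement for direction {d}; cannot center"
            )
        means[d] = float(np.mean(gdna))
    centered = [replace(m, rho=m.r - means[m.direction]) for m in study.measurements]
    return replace(study, measurements=centered, gdna_means=means, combined=None)


def combine_directions(study: DAEStudy) -> pd.DataFrame:
    """Average corrected log-ratios over available directions per sample x template.

    Samples with only one passing direction contribute that single value.
    Returns a frame (sample_id, group, template, rho, analysis_set="F&R") and
    stores it on ``study.combined``.
    """
    rows = [
        (m.sample_id, m.group, m.template, m.rho)
        for m in study.measurements
        if m.rho is not None
    ]
    if not rows:
        raise ValueError("combine_directions requires corrected measurements; center first")
    frame = pd.DataFrame(rows, columns=["sample_id", "group", "template", "rho"])
    combined = (
        frame.groupby(["sample_id", "group", "template"], sort=True)["rho"]
        .mean()
        .reset_index()
    )
    combined["analysis_set"] = "F&R"
    study.combined = combined
    return combined


def _analysis_values(study: DAEStudy, analysis_set: str) -> pd.DataFrame:
    """Corrected values for one analysis set as (group, template, rho) rows."""
    if analysis_set in ("F", "R"):
        rows = [
            (m.group, m.template, m.rho)
            for m in study.measurements
            if m.direction == analysis_set and m.rho is not None
        ]
        return pd.DataFrame(rows, columns=["group", "template", "rho"])
    if analysis_set == "F&R":
        combined = study.combined if study.combined is not None else combine_directions(study)
        return combined[["group", "template", "rho"]].copy()
    raise ValueError(f"unknown analysis set {analysis_set!r}")


def summarize_snp(study: DAEStudy, analysis_set: str = "F&R") -> dict[str, dict]:
    """Group means and sample SDs of corrected ratios for one analysis set.

    Returns a mapping with keys ``gDNA`` (pooled over groups), ``cDNA_control``
    and ``cDNA_family``, each holding mean, sd (ddof=1, NaN for n<2) and n;
    empty groups carry mean/sd NaN and n 0, never silent zeros.
    """
    frame = _analysis_values(study, analysis_set)
    out: dict[str, dict] = {}
    selections = {
        "gDNA": frame["template"] == "gDNA",
        "cDNA_control": (frame["template"] == "cDNA") & (frame["group"] == GROUP_CONTROL),
        "cDNA_family": (frame["template"] == "cDNA") & (frame["group"] == GROUP_FAMILY),
    }
    for label, sel in selections.items():
        values = frame.loc[sel, "rho"].to_numpy()
        out[label] = {
            "mean": float(np.mean(values)) if len(values) else float("nan"),
            "sd": float(np.std(values, ddof=1)) if len(values) > 1 else float("nan"),
            "n": int(len(values)),
        }
    return out


def measurements_frame(study: DAEStudy, include_combined: bool = True) -> pd.DataFrame:
    """Tidy measurement table: per-direction rows plus optional combined rows."""
    rows = [
        {
            "sample_id": m.sample_id,
            "snp_id": m.snp_id,
            "group": m.group,
            "template": m.template,
            "direction": m.direction,
            "r": m.r,
            "rho": m.rho,
            "analysis_set": m.direction,
        }
        for m in study.measurements
    ]
    frame = pd.DataFrame(rows)
    if include_combined and study.combined is not None:
        comb = study.combined.copy()
        comb["snp_id"] = study.snp_id
        comb["direction"] = "F&R"
        comb["r"] = np.nan
        frame = pd.concat(
            [frame, comb[["sample_id", "snp_id", "group", "template", "direction", "r", "rho", "analysis_set"]]],
            ignore_index=True,
        )
    return frame
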