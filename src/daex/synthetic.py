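"""Synthetic data with known ground truth for every pipeline stage.

Emulates the study design end to end: heterozygous peak-height pairs with
group-specific allelic imbalance, multiplicative (log-normal) intensity noise
and additive direction-specific assay bias; full four-channel chromatograms
with Gaussian peaks; and genotype tables where controls follow Hardy-Weinberg
proportions and the affected family arises by gene-dropping through a fixed
three-generation, ten-member pedigree template.

The height model for one sample/template/direction is

    t  = theta_group(template) + bias_direction          (true ln allele ratio)
    p  = exp(t) / (1 + exp(t))
    h1 = L * p * exp(eps1),   h2 = L * (1 - p) * exp(eps2)

with eps ~ Normal(0, sigma^2) independent, so the measured ln(h1/h2) is
t + Normal(0, 2 sigma^2).  Every stochastic draw flows from a named substream
of the root seed, so adding a new draw never perturbs existing streams and a
fixed config reproduces its output exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .dae_core import GROUP_CONTROL, GROUP_FAMILY
from .snp_screen import GenotypeTable
from .trace_io import CHANNEL_ORDER, COMPLEMENT, Chromatogram, write_trace_table

__all__ = [
    "SnpSpec",
    "SimulationConfig",
    "TruthRecord",
    "simulate_peak_table",
    "simulate_trace",
    "simulate_genotype_table",
    "simulate_null_study",
    "substream",
]

PEAK_TABLE_COLUMNS = [
    "sample_id",
    "group",
    "template",
    "direction",
    "snp_id",
    "allele1",
    "allele2",
    "height1",
    "height2",
    "qc_flags",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream of a root seed."""
    key = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass(frozen=True)
class SnpSpec:
    """Forward-strand allele pair and flanking sequence of one simulated SNP."""

    snp_id: str
    reference_allele: str
    alternate_allele: str
    flank5: str = "ACGTACGT"
    flank3: str = "TGCATGCA"


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the peak-height simulator.

    Defaults mirror the assayed design: six heterozygous family and seven
    heterozygous control cell lines, cDNA allelic log fold changes +0.42
    (family) and -0.34 (controls) on the natural-log scale, balanced gDNA,
    small opposite dye biases per sequencing direction, and log-normal
    intensity noise chosen so corrected gDNA ratios scatter with SD ~0.1.
    """

    n_family: int = 6
    n_control: int = 7
    theta_family: float = 0.42
    theta_control: float = -0.34
    theta_gdna: float = 0.0
    bias_f: float = 0.1
    bias_r: float = -0.1
    noise_sd: float = 0.07
    base_intensity: float = 1000.0
    missing_direction_rate: float = 0.1
    qc_artifact_rate: float = 0.0
    seed: int = 0
    snp_panel: tuple[SnpSpec, ...] = (SnpSpec("rs600753", "C", "T"),)

    def __post_init__(self) -> None:
        if self.n_family < 0 or self.n_control < 0:
            raise ValueError("sample counts must be >= 0")
        if self.noise_sd < 0 or self.base_intensity <= 0:
            raise ValueError("noise_sd >= 0 and base_intensity > 0 required")
        for rate in (self.missing_direction_rate, self.qc_artifact_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must be in [0, 1]")
        if not self.snp_panel:
            raise ValueError("snp_panel must name at least one SNP")


@dataclass
class TruthRecord:
    """Ground truth of one simulated peak table.

    ``true_log_ratio`` maps (snp_id, sample_id, template, direction) to the
    noise-free oriented ln allele ratio (group effect plus direction bias);
    ``group_means`` holds the configured per-group cDNA/gDNA effects per SNP.
    """

    true_log_ratio: dict[tuple[str, str, str, str], float] = field(default_factory=dict)
    group_means: dict[str, dict[str, float]] = field(default_factory=dict)


def _theta(config: SimulationConfig, group: str, template: str) -> float:
    if template == "gDNA":
        return config.theta_gdna
    return config.theta_family if group == GROUP_FAMILY else config.theta_control


def simulate_peak_table(config: SimulationConfig) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate a peak-height table in the trace_io peak-table dialect.

    Reverse-direction rows report the complemented allele pair, numerator
    first, exactly as a reverse Sanger read would; forward rows report
    reference/alternate.  Directions drop out independently at
    ``missing_direction_rate``; ``qc_artifact_rate`` rows get a collapsed
    minor peak plus a pre-set ``low_signal`` flag.
    """
    samples = [(f"fam{i:02d}", GROUP_FAMILY) for i in range(1, config.n_family + 1)] + [
        (f"ctrl{i:02d}", GROUP_CONTROL) for i in range(1, config.n_control + 1)
    ]
    noise_rng = substream(config.seed, "peak_noise")
    drop_rng = substream(config.seed, "direction_dropout")
    artifact_rng = substream(config.seed, "qc_artifacts")

    truth = TruthRecord()
    rows = []
    for spec in config.snp_panel:
        truth.group_means[spec.snp_id] = {
            "family": config.theta_family,
            "control": config.theta_control,
            "gdna": config.theta_gdna,
        }
        for sample_id, group in samples:
            for template in ("cDNA", "gDNA"):
                for direction, bias in (("F", config.bias_f), ("R", config.bias_r)):
                    if drop_rng.random() < config.missing_direction_rate:
                        continue
                    t = _theta(config, group, template) + bias
                    truth.true_log_ratio[(spec.snp_id, sample_id, template, direction)] = t
                    p = 1.0 / (1.0 + np.exp(-t))
                    eps1, eps2 = noise_rng.normal(0.0, config.noise_sd, size=2)
                    h1 = config.base_intensity * p * np.exp(eps1)
                    h2 = config.base_intensity * (1.0 - p) * np.exp(eps2)
                    if direction == "F":
                        a1, a2 = spec.reference_allele, spec.alternate_allele
                    else:
                        a1 = COMPLEMENT[spec.reference_allele]
                        a2 = COMPLEMENT[spec.alternate_allele]
                    flags = ""
                    if (
                        config.qc_artifact_rate
                        and artifact_rng.random() < config.qc_artifact_rate
                    ):
                        h2 *= 0.01
                        flags = "low_signal"
                    rows.append(
                        (sample_id, group, template, direction, spec.snp_id, a1, a2, h1, h2, flags)
                    )
    table = pd.DataFrame(rows, columns=PEAK_TABLE_COLUMNS)
    return table, truth


def simulate_trace(
    sequence: str,
    variant_index: int,
    allele_heights: dict[str, float],
    *,
    base_amplitude: float = 300.0,
    peak_spacing: int = 12,
    peak_sd: float = 2.5,
    noise_floor: float = 0.0,
    seed: int = 0,
    sample_id: str = "sim",
    direction: str = "F",
    out_path: str | Path | None = None,
) -> Chromatogram:
    """Simulate a four-channel chromatogram with one Gaussian peak per base.

    At ``variant_index`` the two channels named in ``allele_heights`` carry the
    configured amplitudes (a heterozygous double peak); every other basecall
    gets a single peak of ``base_amplitude`` in its base's channel.  Additive
    non-negative baseline noise is uniform on [0, noise_floor].  Peaks wider
    than the spacing (peak_sd > peak_spacing) trigger a warning but are still
    generated.  If ``out_path`` is given the trace is also written in the
    tabular dialect.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if not 0 <= variant_index < len(sequence):
        raise ValueError("variant_index out of range")
    for base in allele_heights:
        if base.upper() not in CHANNEL_ORDER:
            raise ValueError(f"allele {base!r} is not one of A/C/G/T")
    if peak_sd > peak_spacing:
        import warnings

        warnings.warn(
            f"peak_sd {peak_sd} exceeds peak_spacing {peak_spacing}; peaks overlap",
            stacklevel=2,
        )

    n = len(sequence)
    length = peak_spacing * (n + 1)
    x = np.arange(length, dtype=float)
    centers = peak_spacing * (np.arange(n) + 1)
    trace = np.zeros((4, length))
    index_of = {b: i for i, b in enumerate(CHANNEL_ORDER)}

    def add_peak(base: str, center: float, amplitude: float) -> None:
        trace[index_of[base.upper()]] += amplitude * np.exp(
            -((x - center) ** 2) / (2.0 * peak_sd**2)
        )

    for i, base in enumerate(sequence):
        if i == variant_index:
            for allele, amp in allele_heights.items():
                add_peak(allele, centers[i], amp)
        elif base.upper() in index_of:
            add_peak(base, centers[i], base_amplitude)

    if noise_floor > 0:
        rng = substream(seed, "trace_noise")
        trace += rng.uniform(0.0, noise_floor, size=trace.shape)

    chrom = Chromatogram(
        trace=trace,
        basecall_positions=centers.astype(int),
        called_sequence=sequence,
        sample_id=sample_id,
        direction=direction,
    )
    if out_path is not None:
        write_trace_table(chrom, out_path)
    return chrom


# fixed 3-generation, 10-member pedigree template: founder grandparents, two
# children who married in founder spouses, four grandchildren
_PEDIGREE = {
    "gp1": None,
    "gp2": None,
    "c1": ("gp1", "gp2"),
    "s1": None,
    "g1": ("c1", "s1"),
    "g2": ("c1", "s1"),
    "c2": ("gp1", "gp2"),
    "s2": None,
    "g3": ("c2", "s2"),
    "g4": ("c2", "s2"),
}


def simulate_genotype_table(
    n_snps: int,
    n_family: int = 10,
    n_control: int = 18,
    maf_range: tuple[float, float] = (0.1, 0.5),
    hwe_disequilibrium: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Simulate a genotype table: HWE controls plus a gene-dropped family.

    Controls are drawn per SNP from genotype frequencies p^2 + F p q,
    2 p q (1 - F), q^2 + F p q where F is the ``hwe_disequilibrium``
    (fixation-index-style) parameter.  Family genotypes gene-drop through the
    fixed pedigree template (founders from population allele frequencies,
    offspring by Mendelian transmission); with more than 10 family samples the
    template repeats.  Missingness is applied uniformly.  Returns the table
    and a per-SNP truth frame (maf, disequilibrium).
    """
    if n_snps <= 0:
        raise ValueError("n_snps must be positive")
    if not 0 <= missing_rate <= 1:
        raise ValueError("missing_rate must be in [0, 1]")
    lo, hi = maf_range
    if not 0 <= lo <= hi <= 0.5:
        raise ValueError("maf_range must satisfy 0 <= lo <= hi <= 0.5")

    maf_rng = substream(seed, "maf")
    geno_rng = substream(seed, "genotypes")
    miss_rng = substream(seed, "missingness")

    family_ids = [f"fam{i:02d}" for i in range(1, n_family + 1)]
    control_ids = [f"ctrl{i:02d}" for i in range(1, n_control + 1)]
    members = list(_PEDIGREE)

    rows = {}
    truth_rows = []
    for k in range(n_snps):
        snp_id = f"snp{k + 1:03d}"
        maf = float(maf_rng.uniform(lo, hi)) if hi > lo else lo
        q, p = maf, 1.0 - maf
        f = hwe_disequilibrium
        probs = np.array([p * p + f * p * q, 2 * p * q * (1 - f), q * q + f * p * q])
        if np.any(probs < -1e-12):
            raise ValueError(f"hwe_disequilibrium {f} invalid for maf {maf:.3f}")
        probs = np.clip(probs, 0.0, None)
        probs /= probs.sum()

        # gene-drop the family: alleles 0 (major) / 1 (minor); the pedigree
        # lists parents before their children, so offspring can always draw
        # one allele from each parent's stored genome
        calls: list[str] = []
        genomes: dict[str, tuple[int, int]] = {}
        for i in range(n_family):
            member = members[i % len(members)]
            if i % len(members) == 0:
                genomes = {}  # template repeats: start an unrelated pedigree
            parents = _PEDIGREE[member]
            if parents is None:
                pair = (int(geno_rng.random() < maf), int(geno_rng.random() < maf))
            else:
                mother, father = parents
                pair = (
                    genomes[mother][int(geno_rng.integers(2))],
                    genomes[father][int(geno_rng.integers(2))],
                )
            genomes[member] = pair
            calls.append({0: "AA", 1: "AB", 2: "BB"}[sum(pair)])

        dosages = geno_rng.choice(3, size=n_control, p=probs)
        calls += [{0: "AA", 1: "AB", 2: "BB"}[int(d)] for d in dosages]

        if missing_rate > 0:
            mask = miss_rng.random(len(calls)) < missing_rate
            calls = [np.nan if m else c for c, m in zip(calls, mask)]
        rows[snp_id] = calls
        truth_rows.append({"snp_id": snp_id, "maf": maf, "hwe_disequilibrium": f})

    calls_df = pd.DataFrame.from_dict(rows, orient="index", columns=family_ids + control_ids)
    groups = pd.Series(
        {s: GROUP_FAMILY for s in family_ids} | {s: GROUP_CONTROL for s in control_ids},
        name="group",
    )
    return (
        GenotypeTable(calls=calls_df, groups=groups),
        pd.DataFrame(truth_rows).set_index("snp_id"),
    )


def simulate_null_study(
    config: SimulationConfig, n_studies: int = 1
) -> list[tuple[pd.DataFrame, TruthRecord]]:
    """Independent replicate studies under the global null (all effects equal).

    Requires theta_family == theta_control == theta_gdna; each replicate uses
    its own seed substream of the root seed.
    """
    if not (config.theta_family == config.theta_control == config.theta_gdna):
        raise ValueError("null studies require all group effects equal")
    seed_rng = substream(config.seed, "null_study_seeds")
    studies = []
    for _ in range(n_studies):
        rep_seed = int(seed_rng.integers(0, 2**31 - 1))
        studies.append(simulate_peak_table(replace(config, seed=rep_seed)))
    return studies
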