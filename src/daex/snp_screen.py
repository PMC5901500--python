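"""SNP eligibility screen: genotype QC and heterozygote-count filtering.

A SNP enters differential allelic expression analysis only if it

1. passes genotyping QC — Hardy-Weinberg equilibrium (exact test, Bonferroni
   adjusted across the tested SNPs, adjusted p > 0.05), SNP-wise call rate
   > 0.97 and minor allele frequency > 0.05;
2. is heterozygous in at least ``min_het_per_group`` cell lines in BOTH the
   affected family and the control group (only heterozygotes are informative
   for within-sample allelic comparison);
3. has its transcript expressed in the assayed cells — a wet-lab fact that is
   supplied as external flags, never inferred here.

The HWE test is the Levene-Haldane exact test (the conditional distribution
of the heterozygote count given the allele counts), the standard choice at
cohort sizes of a few dozen where the chi-square approximation is unreliable;
a chi-square variant is available via ``hwe_test="chisq"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .dae_core import GROUP_CONTROL, GROUP_FAMILY

__all__ = [
    "GenotypeTable",
    "ScreenConfig",
    "hwe_exact_p",
    "hwe_chisq_p",
    "genotype_qc",
    "eligibility_filter",
    "expression_gate",
    "read_genotype_tsv",
    "read_genotype_vcf",
]

VALID_CALLS = {"AA", "AB", "BB"}
VALID_GROUPS = {GROUP_FAMILY, GROUP_CONTROL}


@dataclass
class GenotypeTable:
    """SNP x sample genotype calls with group labels.

    ``calls`` is a DataFrame (rows = SNP ids, columns = sample ids) holding
    "AA" / "AB" / "BB" / NaN (missing); ``groups`` maps sample id -> group
    label; ``alleles`` optionally maps SNP id -> (allele A, allele B) as
    forward-strand bases.
    """

    calls: pd.DataFrame
    groups: pd.Series
    alleles: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.groups.unique()) - VALID_GROUPS
        if unknown:
            raise ValueError(f"unknown group label(s): {sorted(unknown)}")
        missing = [s for s in self.calls.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        bad = set(self.calls.stack().unique()) - VALID_CALLS
        if bad:
            raise ValueError(f"invalid genotype call(s): {sorted(bad)}")

    @property
    def snp_ids(self) -> list[str]:
        return list(self.calls.index)

    def genotype_counts(self, snp_id: str) -> tuple[int, int, int]:
        """(nAA, nAB, nBB) among called genotypes for one SNP."""
        row = self.calls.loc[snp_id]
        return (
            int((row == "AA").sum()),
            int((row == "AB").sum()),
            int((row == "BB").sum()),
        )


@dataclass
class ScreenConfig:
    """Thresholds of the eligibility screen (defaults per the study design)."""

    hwe_alpha: float = 0.05
    hwe_bonferroni: bool = True
    min_call_rate: float = 0.97
    min_maf: float = 0.05
    min_het_per_group: int = 3
    hwe_test: str = "exact"  # exact | chisq

    def __post_init__(self) -> None:
        if not 0 < self.hwe_alpha < 1:
            raise ValueError("hwe_alpha must be in (0, 1)")
        if not 0 <= self.min_call_rate <= 1 or not 0 <= self.min_maf <= 0.5:
            raise ValueError("min_call_rate in [0,1], min_maf in [0,0.5]")
        if self.min_het_per_group < 0:
            raise ValueError("min_het_per_group must be >= 0")
        if self.hwe_test not in ("exact", "chisq"):
            raise ValueError(f"unknown hwe_test {self.hwe_test!r}")


def _log_het_prob(n: int, n_a: int, nab: int) -> float:
    """log P(heterozygote count = nab | allele counts), Levene-Haldane."""
    naa = (n_a - nab) // 2
    nbb = n - naa - nab
    return (
        gammaln(n + 1)
        - gammaln(naa + 1)
        - gammaln(nab + 1)
        - gammaln(nbb + 1)
        + nab * np.log(2.0)
        + gammaln(n_a + 1)
        + gammaln(2 * n - n_a + 1)
        - gammaln(2 * n + 1)
    )


def hwe_exact_p(nAA: int, nAB: int, nBB: int) -> float:
    """Levene-Haldane exact Hardy-Weinberg p-value.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts no more probable than the observed one.  A monomorphic
    SNP has a single possible configuration, hence p = 1.
    """
    if min(nAA, nAB, nBB) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = nAA + nAB + nBB
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = 2 * nAA + nAB
    n_minor = min(n_a, 2 * n - n_a)
    # heterozygote counts share the parity of the minor allele count
    nab_values = np.arange(n_minor % 2, n_minor + 1, 2)
    if len(nab_values) == 0:
        return 1.0
    log_probs = np.array([_log_het_prob(n, n_a, int(k)) for k in nab_values])
    probs = np.exp(log_probs - log_probs.max())
    probs /= probs.sum()
    p_obs = probs[nab_values == nAB][0]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def hwe_chisq_p(nAA: int, nAB: int, nBB: int) -> float:
    """One-df chi-square Hardy-Weinberg p-value (no continuity correction)."""
    n = nAA + nAB + nBB
    if n == 0:
        raise ValueError("all genotype counts are zero")
    p = (2 * nAA + nAB) / (2 * n)
    q = 1 - p
    if p == 0 or q == 0:
        return 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([nAA, nAB, nBB], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    from scipy.stats import chi2 as chi2_dist

    return float(chi2_dist.sf(chi2, df=1))


def genotype_qc(table: GenotypeTable, config: ScreenConfig | None = None) -> pd.DataFrame:
    """Per-SNP QC report: call rate, MAF, HWE p (raw and Bonferroni-adjusted).

    ``qc_pass`` requires adjusted HWE p > hwe_alpha, call rate > min_call_rate
    and MAF > min_maf.  The Bonferroni multiplier is the number of SNPs
    entering QC.  Never raises on failing SNPs — this is a report.
    """
    config = config or ScreenConfig()
    hwe_fn = hwe_exact_p if config.hwe_test == "exact" else hwe_chisq_p
    n_samples = table.calls.shape[1]
    m = len(table.snp_ids)
    rows = []
    for snp in table.snp_ids:
        naa, nab, nbb = table.genotype_counts(snp)
        called = naa + nab + nbb
        call_rate = called / n_samples if n_samples else 0.0
        if called:
            freq_a = (2 * naa + nab) / (2 * called)
            maf = min(freq_a, 1 - freq_a)
            hwe_p = hwe_fn(naa, nab, nbb)
        else:
            maf = 0.0
            hwe_p = float("nan")
        hwe_p_adj = min(1.0, m * hwe_p) if config.hwe_bonferroni else hwe_p
        rows.append(
            {
                "snp_id": snp,
                "call_rate": call_rate,
                "maf": maf,
                "hwe_p": hwe_p,
                "hwe_p_adj": hwe_p_adj,
                "hwe_pass": bool(hwe_p_adj > config.hwe_alpha),
                "call_rate_pass": bool(call_rate > config.min_call_rate),
                "maf_pass": bool(maf > config.min_maf),
            }
        )
    report = pd.DataFrame(rows).set_index("snp_id")
    report["qc_pass"] = report["hwe_pass"] & report["call_rate_pass"] & report["maf_pass"]
    return report


def eligibility_filter(
    table: GenotypeTable, config: ScreenConfig | None = None
) -> pd.DataFrame:
    """Per-SNP heterozygote counts per group and the eligibility call.

    A SNP is eligible iff it has >= ``min_het_per_group`` heterozygous samples
    in the affected family AND in the controls.
    """
    config = config or ScreenConfig()
    family = [s for s in table.calls.columns if table.groups[s] == GROUP_FAMILY]
    control = [s for s in table.calls.columns if table.groups[s] == GROUP_CONTROL]
    het = table.calls == "AB"
    report = pd.DataFrame(
        {
            "het_family": het[family].sum(axis=1).astype(int),
            "het_control": het[control].sum(axis=1).astype(int),
        }
    )
    report["eligible"] = (report["het_family"] >= config.min_het_per_group) & (
        report["het_control"] >= config.min_het_per_group
    )
    report.index.name = "snp_id"
    return report


def expression_gate(snp_ids: list[str], expressed_flags: dict[str, bool]) -> list[str]:
    """Intersect eligible SNPs with externally supplied expression flags.

    Expression in the assayed cell type is a wet-lab determination; a missing
    flag for an eligible SNP is an error, flags for unknown SNPs only warn.
    """
    missing = [s for s in snp_ids if s not in expressed_flags]
    if missing:
        raise KeyError(f"no expression flag for eligible SNP(s): {missing}")
    extra = set(expressed_flags) - set(snp_ids)
    if extra:
        warnings.warn(
            f"expression flags for SNPs not in the eligible list ignored: {sorted(extra)}",
            stacklevel=2,
        )
    return [s for s in snp_ids if expressed_flags[s]]


def read_genotype_tsv(path, groups: pd.Series) -> GenotypeTable:
    """Read a SNP x sample genotype matrix (TSV, calls AA/AB/BB, blank=missing)."""
    calls = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return GenotypeTable(calls=calls, groups=groups)


def read_genotype_vcf(path, groups: pd.Series) -> GenotypeTable:
    """Read diploid, biallelic genotypes from an (uncompressed) VCF.

    GT fields are mapped to AA (hom ref), AB (het), BB (hom alt); missing or
    half-called genotypes become missing calls.  Allele annotations carry the
    VCF REF/ALT bases.
    """
    sample_ids: list[str] = []
    rows: dict[str, list] = {}
    alleles: dict[str, tuple[str, str]] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                sample_ids = fields[9:]
                continue
            snp_id = fields[2] if fields[2] != "." else f"{fields[0]}:{fields[1]}"
            ref, alt = fields[3], fields[4]
            if "," in alt:
                warnings.warn(f"skipping multi-allelic record {snp_id}", stacklevel=2)
                continue
            fmt = fields[8].split(":")
            gt_idx = fmt.index("GT")
            calls = []
            for entry in fields[9:]:
                gt = entry.split(":")[gt_idx].replace("|", "/")
                parts = gt.split("/")
                if len(parts) != 2 or "." in parts:
                    calls.append(np.nan)
                    continue
                dose = sum(int(p) for p in parts)
                calls.append({0: "AA", 1: "AB", 2: "BB"}[dose])
            rows[snp_id] = calls
            alleles[snp_id] = (ref, alt)
    calls_df = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)
    return GenotypeTable(calls=calls_df, groups=groups, alleles=alleles)
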