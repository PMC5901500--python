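"""The 12-SNP dyslexia candidate panel used by the eligibility screen.

Twelve exonic/UTR SNPs previously associated with dyslexia-related phenotypes
were genotyped in 28 EBV-immortalised B-cell lines (10 from a three-generation
family affected by dyslexia, 18 controls).  Six SNPs reached at least three
heterozygous cell lines in both groups, and transcripts of four of those were
expressed in B-cells — the per-group heterozygote counts and expression flags
encoded here are the published ones.

The full genotype matrix behind those counts was never published: the
individual genotype assignments in :func:`candidate_panel_genotypes` are a
SYNTHETIC reconstruction that reproduces the published per-group heterozygote
counts exactly and fills the remaining calls with homozygotes deterministically.
Use it for screening-cascade logic, not as real genotype data.
"""

from __future__ import annotations

import pandas as pd

from .dae_core import GROUP_CONTROL, GROUP_FAMILY
from .snp_screen import GenotypeTable

__all__ = [
    "CANDIDATE_SNPS",
    "EXPRESSED_IN_B_CELLS",
    "panel_groups",
    "candidate_panel_genotypes",
]

# snp_id -> (gene, heterozygotes in family of 10, heterozygotes in 18 controls)
CANDIDATE_SNPS: dict[str, tuple[str, int, int]] = {
    "rs10046": ("CYP19A1", 6, 11),
    "rs934634": ("CYP19A1", 4, 9),
    "rs555879": ("MYO5B", 7, 14),
    "rs3743205": ("DYX1C1", 1, 2),
    "rs2038137": ("KIAA0319", 3, 2),
    "rs3178": ("NRSN1", 2, 4),
    "rs600753": ("DYX1C1", 7, 10),
    "rs17819126": ("DYX1C1", 2, 2),
    "rs9467075": ("DCDC2", 5, 8),
    "rs3734972": ("FLNC", 0, 2),
    "rs4504469": ("KIAA0319", 2, 6),
    "rs2143340": ("TDP2", 4, 7),
}

# transcript detectable in the immortalised B-cells (wet-lab determination,
# recorded for the six heterozygote-eligible SNPs)
EXPRESSED_IN_B_CELLS: dict[str, bool] = {
    "rs10046": True,
    "rs934634": True,
    "rs600753": True,
    "rs9467075": True,
    "rs555879": False,
    "rs2143340": False,
}

FAMILY_SAMPLES = [f"fam{i:02d}" for i in range(1, 11)]
CONTROL_SAMPLES = [f"ctrl{i:02d}" for i in range(1, 19)]


def panel_groups() -> pd.Series:
    """Sample -> group labels of the 28-cell-line design."""
    return pd.Series(
        {s: GROUP_FAMILY for s in FAMILY_SAMPLES} | {s: GROUP_CONTROL for s in CONTROL_SAMPLES},
        name="group",
    )


def candidate_panel_genotypes() -> GenotypeTable:
    """Synthetic genotype matrix matching the published heterozygote counts.

    For each SNP the first ``het_family`` family samples and the first
    ``het_control`` control samples are heterozygous; one further sample per
    group (when available) is the alternate homozygote, the rest are reference
    homozygotes.  Deterministic, no randomness.
    """
    samples = FAMILY_SAMPLES + CONTROL_SAMPLES
    rows = {}
    for snp_id, (_gene, het_fam, het_ctrl) in CANDIDATE_SNPS.items():
        calls = []
        for cohort, n_het in ((FAMILY_SAMPLES, het_fam), (CONTROL_SAMPLES, het_ctrl)):
            for i, _sample in enumerate(cohort):
                if i < n_het:
                    calls.append("AB")
                elif i == n_het and n_het + 1 < len(cohort):
                    calls.append("BB")
                else:
                    calls.append("AA")
        rows[snp_id] = calls
    calls_df = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    return GenotypeTable(calls=calls_df, groups=panel_groups())
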