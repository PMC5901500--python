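"""Rank-based group comparison of corrected allelic log-ratios.

The global test across the three groups (cDNA of the affected family, cDNA of
controls, pooled gDNA) is the Kruskal-Wallis test; pairwise Wilcoxon rank-sum
tests serve as post-hocs.  Multiplicity is controlled by the closed testing
procedure: with exactly three groups every intersection hypothesis that
contains two pairwise nulls equals the global null, so the closure collapses
to the rule "a pair is significant iff its own p < alpha AND the global
p < alpha".  Pairwise p-values are reported raw; the closure lives in the
decisions.

Exact p-values use full enumeration (midranks for ties): label permutations
for Kruskal-Wallis, subset rank-sum distributions (a numpy dynamic program
over doubled midranks) for Wilcoxon.  Two-sided exact p doubles the smaller
tail, capped at 1.  Asymptotic fallbacks are the chi-square reference and the
tie-corrected normal approximation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GroupComparison",
    "ClosedTestResult",
    "UnsupportedDesignError",
    "kruskal_wallis_p",
    "wilcoxon_ranksum_p",
    "closed_test_decisions",
    "closed_test_posthoc",
    "dae_association_table",
]

# above this many distinct label assignments, "exact" switches to complete
# Monte-Carlo enumeration of random permutations
EXACT_ENUM_CAP = 500_000
MC_RESAMPLES = 20_000
AUTO_EXACT_KW_N = 12
AUTO_EXACT_RANKSUM_N = 20
_TOL = 1e-9


class UnsupportedDesignError(ValueError):
    """The closed-test shortcut is only valid for the three-group design."""


@dataclass
class GroupComparison:
    """Corrected log-ratios per group plus testing configuration."""

    groups: dict[str, list[float]]
    alpha: float = 0.05
    method: str = "auto"  # exact | asymptotic | auto

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        for label, values in self.groups.items():
            if len(values) == 0:
                raise ValueError(f"group {label!r} is empty")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.method not in ("exact", "asymptotic", "auto"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class ClosedTestResult:
    """Global p, raw pairwise p-values, and closed-test significance calls."""

    global_p: float
    posthoc_p: dict[tuple[str, str], float]
    posthoc_significant: dict[tuple[str, str], bool]
    alpha: float


def _rank_sum_statistic(rank_sums: np.ndarray, sizes: np.ndarray) -> float:
    # monotone transform of the Kruskal-Wallis H: sum R_g^2 / n_g
    return float(np.sum(rank_sums**2 / sizes))


def _kw_exact(groups: list[np.ndarray], rng: np.random.Generator | None) -> float:
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    sizes = np.array([len(g) for g in groups])
    n = len(pooled)
    bounds = np.cumsum(sizes)
    s_obs = _rank_sum_statistic(
        np.array([ranks[b - s : b].sum() for s, b in zip(sizes, bounds)]), sizes
    )

    n_assignments = math.factorial(n)
    for s in sizes:
        n_assignments //= math.factorial(s)
    if n_assignments > EXACT_ENUM_CAP:
        rng = rng or np.random.default_rng(0)
        hits = 0
        for _ in range(MC_RESAMPLES):
            perm = rng.permutation(ranks)
            sums = np.array([perm[b - s : b].sum() for s, b in zip(sizes, bounds)])
            if _rank_sum_statistic(sums, sizes) >= s_obs - _TOL:
                hits += 1
        return (hits + 1) / (MC_RESAMPLES + 1)

    # full enumeration: recursively choose index sets for each group
    total_rank = ranks.sum()
    hits = 0
    count = 0

    def recurse(available: tuple[int, ...], gi: int, sums: list[float]) -> None:
        nonlocal hits, count
        if gi == len(sizes) - 1:
            last = total_rank - sum(sums)
            s_val = _rank_sum_statistic(np.array(sums + [last]), sizes)
            count += 1
            if s_val >= s_obs - _TOL:
                hits += 1
            return
        for chosen in itertools.combinations(available, int(sizes[gi])):
            rest = tuple(i for i in available if i not in set(chosen))
            recurse(rest, gi + 1, sums + [float(ranks[list(chosen)].sum())])

    recurse(tuple(range(n)), 0, [])
    assert count == n_assignments
    return hits / count


def kruskal_wallis_p(
    groups: dict[str, list[float]] | list,
    method: str = "auto",
    *,
    rng: np.random.Generator | None = None,
) -> float:
    """Kruskal-Wallis p-value across >=2 groups (midranks, tie-corrected).

    ``method="exact"`` enumerates all distinct group-label assignments of the
    pooled ranks (complete Monte-Carlo above ``EXACT_ENUM_CAP`` assignments)
    and reports the proportion with H >= H_observed; ``"asymptotic"`` uses the
    chi-square reference with k-1 df; ``"auto"`` is exact for total n <= 12.
    """
    if isinstance(groups, dict):
        arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        arrays = [np.asarray(v, dtype=float) for v in groups]
    if len(arrays) < 2 or any(len(a) == 0 for a in arrays):
        raise ValueError("need >=2 non-empty groups")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 1.0  # H = 0, every assignment ties the observed statistic
    n = len(pooled)
    if method == "auto":
        method = "exact" if n <= AUTO_EXACT_KW_N else "asymptotic"
    if method == "exact":
        return _kw_exact(arrays, rng)
    if method == "asymptotic":
        return float(stats.kruskal(*arrays).pvalue)
    raise ValueError(f"unknown method {method!r}")


def _ranksum_exact(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided rank-sum p via the subset-sum distribution of midranks.

    Doubled midranks are integers, so the number of size-n_a subsets attaining
    each rank sum follows from a dynamic program; this equals full enumeration
    of C(n_a + n_b, n_a) assignments.
    """
    pooled = np.concatenate([a, b])
    ranks2 = np.rint(2 * stats.rankdata(pooled)).astype(int)
    na = len(a)
    w_obs = int(ranks2[:na].sum())
    max_sum = int(ranks2.sum())
    # dp[k, s] = number of k-subsets of the processed ranks summing to s
    dp = np.zeros((na + 1, max_sum + 1))
    dp[0, 0] = 1.0
    for v in ranks2:
        dp[1 : na + 1, v:] += dp[0:na, 0 : max_sum + 1 - v]
    counts = dp[na]
    total = counts.sum()
    p_le = counts[: w_obs + 1].sum() / total
    p_ge = counts[w_obs:].sum() / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_ranksum_p(a, b, method: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum p-value (midranks for ties).

    ``method="exact"``: enumeration-equivalent distribution of the rank-sum
    statistic, two-sided by doubling the smaller tail (capped at 1);
    ``"asymptotic"``: normal approximation with tie-corrected variance;
    ``"auto"``: exact when n_a + n_b <= 20.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    if method == "auto":
        method = "exact" if len(pooled) <= AUTO_EXACT_RANKSUM_N else "asymptotic"
    if method == "exact":
        return _ranksum_exact(a, b)
    if method == "asymptotic":
        return float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )
    raise ValueError(f"unknown method {method!r}")


def closed_test_decisions(
    global_p: float, posthoc_p: dict[tuple[str, str], float], alpha: float = 0.05
) -> dict[tuple[str, str], bool]:
    """Closed-test significance calls for the three-group design.

    A pair is declared significant iff its own p < alpha and the global
    p < alpha.  For three groups this IS the closed testing procedure: every
    intersection of two pairwise nulls forces all three distributions equal,
    i.e. the global null.
    """
    if len(posthoc_p) != 3:
        raise UnsupportedDesignError(
            f"closed-test shortcut requires exactly 3 pairwise hypotheses, got {len(posthoc_p)}"
        )
    gate = global_p < alpha
    return {pair: bool(gate and p < alpha) for pair, p in posthoc_p.items()}


def closed_test_posthoc(
    groups: dict[str, list[float]],
    alpha: float = 0.05,
    method: str = "auto",
    *,
    rng: np.random.Generator | None = None,
) -> ClosedTestResult:
    """Global Kruskal-Wallis plus closed-test-gated pairwise Wilcoxon tests.

    Requires exactly three groups (the design this closure shortcut is valid
    for); raises :class:`UnsupportedDesignError` otherwise.  Pairwise p-values
    are raw; ``posthoc_significant`` carries the closure decisions.
    """
    comparison = GroupComparison(groups=groups, alpha=alpha, method=method)
    if len(groups) != 3:
        raise UnsupportedDesignError(
            f"closed testing is implemented for exactly 3 groups, got {len(groups)}"
        )
    global_p = kruskal_wallis_p(comparison.groups, method=method, rng=rng)
    labels = list(groups)
    posthoc_p = {
        (la, lb): wilcoxon_ranksum_p(groups[la], groups[lb], method=method)
        for la, lb in itertools.combinations(labels, 2)
    }
    significant = closed_test_decisions(global_p, posthoc_p, alpha)
    return ClosedTestResult(
        global_p=global_p, posthoc_p=posthoc_p, posthoc_significant=significant, alpha=alpha
    )


def _direction_allele_label(study, analysis_set: str) -> str:
    from .trace_io import COMPLEMENT

    ref, alt = study.reference_allele, study.alternate_allele
    if analysis_set == "F":
        return f"F ({ref}/{alt})"
    if analysis_set == "R":
        return f"R ({COMPLEMENT[ref]}/{COMPLEMENT[alt]})"
    return "F&R"


def dae_association_table(
    studies,
    alpha: float = 0.05,
    method: str = "auto",
    analysis_sets: tuple[str, ...] = ("F", "R", "F&R"),
    *,
    rng: np.random.Generator | None = None,
):
    """Per-SNP association rows: group summaries, global p, post-hoc p's.

    One row per SNP x analysis set with data in all three groups; rows where a
    group is empty carry NaN p-values.  Column pairs map as control_vs_family,
    family_vs_gdna, control_vs_gdna; ``sig_*`` columns hold the closed-test
    decisions (a flagged pair always implies a flagged global test).
    """
    import pandas as pd

    from .dae_core import _analysis_values, summarize_snp

    rows = []
    for study in studies:
        for aset in analysis_sets:
            frame = _analysis_values(study, aset)
            if frame.empty:
                continue
            summary = summarize_snp(study, aset)
            row = {
                "snp_id": study.snp_id,
                "analysis_set": _direction_allele_label(study, aset),
            }
            for label, stats_ in summary.items():
                key = {"gDNA": "gdna", "cDNA_control": "control", "cDNA_family": "family"}[label]
                row[f"mean_{key}"] = stats_["mean"]
                row[f"sd_{key}"] = stats_["sd"]
                row[f"n_{key}"] = stats_["n"]
            groups = {
                "control": frame.loc[
                    (frame["template"] == "cDNA") & (frame["group"] == "control"), "rho"
                ].tolist(),
                "family": frame.loc[
                    (frame["template"] == "cDNA") & (frame["group"] == "affected_family"), "rho"
                ].tolist(),
                "gdna": frame.loc[frame["template"] == "gDNA", "rho"].tolist(),
            }
            pair_cols = {
                ("control", "family"): "control_vs_family",
                ("family", "gdna"): "family_vs_gdna",
                ("control", "gdna"): "control_vs_gdna",
            }
            if all(len(v) for v in groups.values()):
                result = closed_test_posthoc(groups, alpha=alpha, method=method, rng=rng)
                row["global_p"] = result.global_p
                for pair, col in pair_cols.items():
                    row[f"p_{col}"] = result.posthoc_p[pair]
                    row[f"sig_{col}"] = result.posthoc_significant[pair]
                row["global_significant"] = result.global_p < alpha
            else:
                row["global_p"] = float("nan")
                for col in pair_cols.values():
                    row[f"p_{col}"] = float("nan")
                    row[f"sig_{col}"] = False
                row["global_significant"] = False
            rows.append(row)
    return pd.DataFrame(rows)
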