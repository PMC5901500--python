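"""Pipeline orchestration: screen -> quantify -> center -> combine -> test -> report.

`run_pipeline` drives the whole analysis from a single config mapping (loaded
from YAML by the CLI): genotype screening (optional), peak-height input —
simulated or from a table — quantification into assay-corrected allelic
log-ratios, and the rank-based group tests for the F, R and combined F&R
analysis sets.  Every run emits a manifest with the config snapshot, input
digests, seed and per-stage counts so that any reported number is traceable
and a rerun with identical inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dae_core import (
    DAEStudy,
    UndefinedRatioError,
    center_by_gdna,
    combine_directions,
    measurement_from_pair,
    measurements_frame,
    orient_measurement,
)
from .group_stats import dae_association_table
from .snp_screen import (
    GenotypeTable,
    ScreenConfig,
    eligibility_filter,
    expression_gate,
    genotype_qc,
    read_genotype_tsv,
    read_genotype_vcf,
)
from .synthetic import SimulationConfig, SnpSpec, simulate_peak_table
from .trace_io import COMPLEMENT, PeakPair

__all__ = [
    "PipelineError",
    "RunBundle",
    "quantify_peak_table",
    "analyze_peak_table",
    "closed_test_error_rate",
    "run_pipeline",
    "render_report",
]

logger = logging.getLogger("daex")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class RunBundle:
    """Everything one pipeline run produced."""

    association: pd.DataFrame
    measurements: pd.DataFrame
    manifest: dict
    studies: dict[str, DAEStudy] = field(default_factory=dict)
    screen_report: pd.DataFrame | None = None


def _infer_alleles(rows: pd.DataFrame) -> tuple[str, str]:
    """Forward-strand allele pair of one SNP from its peak-table rows."""
    forward = rows[rows["direction"] == "F"]
    if len(forward):
        first = forward.iloc[0]
        return str(first["allele1"]), str(first["allele2"])
    first = rows.iloc[0]
    return COMPLEMENT[str(first["allele1"])], COMPLEMENT[str(first["allele2"])]


def quantify_peak_table(
    peaks: pd.DataFrame,
    snp_alleles: dict[str, tuple[str, str]] | None = None,
    *,
    drop_flagged: bool = True,
) -> tuple[dict[str, DAEStudy], dict[str, int]]:
    """Peak-height table -> centered, direction-combined studies per SNP.

    Rows with QC flags (unless ``drop_flagged=False``) or with a zero height
    are excluded and counted.  The forward-strand reference/alternate alleles
    are taken from ``snp_alleles`` when given, otherwise inferred from the
    table's forward rows.  Returns (studies, exclusion counts).
    """
    counts = {"rows": int(len(peaks)), "qc_excluded": 0, "undefined_ratio": 0}
    studies: dict[str, DAEStudy] = {}
    for snp_id, rows in peaks.groupby("snp_id", sort=True):
        ref, alt = (snp_alleles or {}).get(snp_id) or _infer_alleles(rows)
        study = DAEStudy(snp_id=str(snp_id), reference_allele=ref, alternate_allele=alt)
        for row in rows.itertuples(index=False):
            flags = str(row.qc_flags) if pd.notna(row.qc_flags) else ""
            if drop_flagged and flags.strip():
                counts["qc_excluded"] += 1
                continue
            pair = PeakPair(
                snp_id=str(row.snp_id),
                allele1=str(row.allele1),
                allele2=str(row.allele2),
                height1=float(row.height1),
                height2=float(row.height2),
                template=str(row.template),
                direction=str(row.direction),
                sample_id=str(row.sample_id),
            )
            try:
                m = measurement_from_pair(pair, group=str(row.group))
            except UndefinedRatioError:
                counts["undefined_ratio"] += 1
                logger.warning("excluding %s/%s: zero peak height", row.snp_id, row.sample_id)
                continue
            m = orient_measurement(m, ref, alt, pair.allele1, pair.allele2)
            study.measurements.append(m)
        study = center_by_gdna(study)
        combine_directions(study)
        studies[str(snp_id)] = study
    return studies, counts


def analyze_peak_table(
    peaks: pd.DataFrame,
    alpha: float = 0.05,
    method: str = "auto",
    snp_alleles: dict[str, tuple[str, str]] | None = None,
) -> tuple[dict[str, DAEStudy], pd.DataFrame]:
    """Quantify a peak table and compute the per-SNP association rows."""
    studies, _ = quantify_peak_table(peaks, snp_alleles)
    table = dae_association_table(studies.values(), alpha=alpha, method=method)
    return studies, table


def closed_test_error_rate(
    config: SimulationConfig,
    n_studies: int,
    alpha: float = 0.05,
    method: str = "asymptotic",
    analysis_set: str = "F&R",
) -> tuple[float, int]:
    """Empirical family-wise error of the closed procedure under the null.

    Simulates ``n_studies`` independent studies with all group effects equal,
    runs the full pipeline on each, and counts studies where any pairwise
    comparison of the chosen analysis set is declared significant.
    """
    from .synthetic import simulate_null_study

    sig_cols = ["sig_control_vs_family", "sig_family_vs_gdna", "sig_control_vs_gdna"]
    errors = 0
    for peaks, _truth in simulate_null_study(config, n_studies):
        _studies, table = analyze_peak_table(peaks, alpha=alpha, method=method)
        rows = table[table["analysis_set"].str.startswith(analysis_set)]
        if rows[sig_cols].to_numpy().any():
            errors += 1
    return errors / n_studies, n_studies


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def _load_groups(path: str | Path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return frame.set_index("sample_id")["group"]


def run_pipeline(config: dict, outdir: str | Path | None = None) -> RunBundle:
    """Execute the full pipeline from a config mapping.

    Config keys: ``seed``, ``alpha``, ``method``; a ``simulate`` block
    (SimulationConfig fields) or an ``inputs`` block with ``peaks`` (TSV) and
    optionally ``genotypes`` (TSV matrix or VCF) + ``groups`` (TSV);
    ``expressed`` (snp -> bool) enables the expression gate; ``screen``
    overrides ScreenConfig fields.  Writes report files into ``outdir`` when
    given.  Raises :class:`PipelineError` naming the failed stage.
    """
    alpha = float(config.get("alpha", 0.05))
    method = str(config.get("method", "auto"))
    seed = int(config.get("seed", 0))
    manifest: dict = {
        "tool": "daex",
        "version": __version__,
        "seed": seed,
        "config": config,
        "inputs": {},
        "stage_counts": {},
    }
    counts = manifest["stage_counts"]
    inputs = config.get("inputs", {})

    # ---- stage: screen (optional) -------------------------------------
    screen_report = None
    analyzable: list[str] | None = None
    if "genotypes" in inputs or config.get("use_candidate_panel"):
        screen_cfg = ScreenConfig(**config.get("screen", {}))
        try:
            if config.get("use_candidate_panel"):
                from .panel import EXPRESSED_IN_B_CELLS, candidate_panel_genotypes

                table = candidate_panel_genotypes()
                expressed = dict(config.get("expressed") or EXPRESSED_IN_B_CELLS)
            else:
                geno_path = Path(inputs["genotypes"])
                groups = _load_groups(inputs["groups"])
                manifest["inputs"]["genotypes"] = _sha256(geno_path)
                reader = (
                    read_genotype_vcf if geno_path.suffix.lower() == ".vcf" else read_genotype_tsv
                )
                table = reader(geno_path, groups)
                expressed = config.get("expressed")
            qc = genotype_qc(table, screen_cfg)
            elig = eligibility_filter(table, screen_cfg)
            screen_report = qc.join(elig)
            eligible = [s for s in screen_report.index if screen_report.loc[s, "eligible"]]
            if expressed is not None:
                analyzable = expression_gate(eligible, expressed)
                screen_report["expressed"] = [
                    bool(expressed.get(s, False)) for s in screen_report.index
                ]
            else:
                analyzable = eligible
            screen_report["analyzable"] = [s in analyzable for s in screen_report.index]
            counts["candidates"] = int(len(screen_report))
            counts["eligible"] = int(len(eligible))
            counts["analyzable"] = int(len(analyzable))
            logger.info(
                "screen: %d candidates -> %d eligible -> %d analyzable",
                counts["candidates"], counts["eligible"], counts["analyzable"],
            )
        except (KeyError, ValueError, OSError) as exc:
            raise PipelineError("screen", str(exc)) from exc

    # ---- stage: peaks --------------------------------------------------
    try:
        if "simulate" in config:
            sim_kwargs = dict(config["simulate"])
            panel = sim_kwargs.pop("snp_panel", None)
            if panel is not None:
                sim_kwargs["snp_panel"] = tuple(
                    SnpSpec(**spec) if isinstance(spec, dict) else spec for spec in panel
                )
            sim = SimulationConfig(seed=seed, **sim_kwargs)
            peaks, _truth = simulate_peak_table(sim)
        elif "peaks" in inputs:
            peaks_path = Path(inputs["peaks"])
            manifest["inputs"]["peaks"] = _sha256(peaks_path)
            peaks = pd.read_csv(peaks_path, sep="\t", dtype={"qc_flags": str})
        else:
            raise ValueError("config needs a 'simulate' block or inputs.peaks")
    except (ValueError, OSError, TypeError) as exc:
        raise PipelineError("peaks", str(exc)) from exc
    counts["peak_rows"] = int(len(peaks))

    if analyzable is not None:
        peaks = peaks[peaks["snp_id"].isin(analyzable)]
        if peaks.empty:
            raise PipelineError("quantify", "no peak data for any analyzable SNP")

    # ---- stage: quantify (orient, center, combine) ---------------------
    try:
        studies, qcounts = quantify_peak_table(peaks)
    except Exception as exc:
        raise PipelineError("center", str(exc)) from exc
    counts.update(qcounts)
    counts["snps_quantified"] = len(studies)

    measurements = (
        pd.concat([measurements_frame(s) for s in studies.values()], ignore_index=True)
        if studies
        else pd.DataFrame()
    )

    # ---- stage: test ----------------------------------------------------
    try:
        rng = np.random.default_rng(seed)
        association = dae_association_table(studies.values(), alpha=alpha, method=method, rng=rng)
    except Exception as exc:
        raise PipelineError("test", str(exc)) from exc
    counts["association_rows"] = int(len(association))

    bundle = RunBundle(
        association=association,
        measurements=measurements,
        manifest=manifest,
        studies=studies,
        screen_report=screen_report,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if screen_report is not None:
            screen_report.to_csv(outdir / "screen_report.tsv", sep="\t")
        measurements.to_csv(outdir / "measurements.tsv", sep="\t", index=False)
        association.to_csv(outdir / "association.tsv", sep="\t", index=False)
        (outdir / "report.txt").write_text(render_report(association, "text"))
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return bundle


_REPORT_COLUMNS = [
    "snp_id",
    "analysis_set",
    "mean_gdna",
    "sd_gdna",
    "n_gdna",
    "mean_control",
    "sd_control",
    "n_control",
    "mean_family",
    "sd_family",
    "n_family",
    "global_p",
    "p_control_vs_family",
    "p_family_vs_gdna",
    "p_control_vs_gdna",
    "sig_control_vs_family",
    "sig_family_vs_gdna",
    "sig_control_vs_gdna",
    "global_significant",
]


def render_report(association: pd.DataFrame, fmt: str = "text") -> str:
    """Render the association table as ``tsv``, human-readable ``text`` or ``json``.

    The text layout mirrors the published table: per-group "mean (SD)"
    columns, the global Kruskal-Wallis p, and the three post-hoc p's with a
    significance asterisk; post-hoc cells are left blank when the global test
    does not reject (the closed procedure never examines them).
    """
    if association.empty:
        raise ValueError("association table is empty")
    cols = [c for c in _REPORT_COLUMNS if c in association.columns]
    table = association[cols]
    if fmt == "tsv":
        return table.to_csv(sep="\t", index=False)
    if fmt == "json":

        def clean(value):
            if isinstance(value, (np.floating, np.integer, np.bool_)):
                value = value.item()
            if isinstance(value, float) and np.isnan(value):
                return None
            return value

        records = [
            {key: clean(value) for key, value in row.items()}
            for row in table.to_dict(orient="records")
        ]
        return json.dumps(records, indent=2) + "\n"
    if fmt == "text":
        lines = []
        header = (
            f"{'SNP':<12} {'Set':<10} {'gDNA':>14} {'cDNA controls':>16} "
            f"{'cDNA family':>16} {'Global p':>10} {'ctrl-vs-fam':>12} "
            f"{'fam-vs-gDNA':>12} {'ctrl-vs-gDNA':>13}"
        )
        lines.append(header)
        lines.append("-" * len(header))

        def cell(mean, sd, n):
            if n == 0 or pd.isna(mean):
                return "-"
            sd_txt = f"{sd:.2f}" if pd.notna(sd) else "NA"
            return f"{mean:.2f} ({sd_txt}) n={n}"

        def pcell(p, sig):
            if pd.isna(p):
                return ""
            return f"{p:.4g}{'*' if sig else ''}"

        for row in table.itertuples(index=False):
            gate = bool(getattr(row, "global_significant", False))
            posthocs = (
                [
                    pcell(row.p_control_vs_family, row.sig_control_vs_family),
                    pcell(row.p_family_vs_gdna, row.sig_family_vs_gdna),
                    pcell(row.p_control_vs_gdna, row.sig_control_vs_gdna),
                ]
                if gate
                else ["", "", ""]
            )
            global_txt = "" if pd.isna(row.global_p) else f"{row.global_p:.4g}{'*' if gate else ''}"
            lines.append(
                f"{row.snp_id:<12} {row.analysis_set:<10} "
                f"{cell(row.mean_gdna, row.sd_gdna, row.n_gdna):>14} "
                f"{cell(row.mean_control, row.sd_control, row.n_control):>16} "
                f"{cell(row.mean_family, row.sd_family, row.n_family):>16} "
                f"{global_txt:>10} {posthocs[0]:>12} {posthocs[1]:>12} {posthocs[2]:>13}"
            )
        lines.append("")
        lines.append("* p < alpha under the closed testing procedure")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format {fmt!r}")
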