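"""Chromatogram reading and allele peak-height extraction.

Supports two on-disk representations of a four-channel Sanger trace:

* ABIF/AB1 binary files, parsed through :mod:`Bio.SeqIO` (read-only);
* a plain-text tabular trace dialect used as the exchange format with the
  synthetic-trace generator (see :func:`read_trace_table` for the layout).

Peak heights for the two alleles of a heterozygous SNP are taken as the
channel maxima inside a window around the basecall position; the window is
half the local inter-peak spacing by default so that neighbouring peaks are
never captured.  A point-intensity mode (intensity exactly at the call
position) is available via ``peak_mode="point"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO

__all__ = [
    "Chromatogram",
    "PeakPair",
    "QCConfig",
    "TraceFormatError",
    "VariantNotFoundError",
    "AmbiguousFlankError",
    "ExtractionError",
    "read_ab1",
    "read_trace_table",
    "write_trace_table",
    "locate_variant_index",
    "extract_peak_pair",
    "qc_assess",
]

CHANNEL_ORDER = "ACGT"
_CHANNEL_INDEX = {b: i for i, b in enumerate(CHANNEL_ORDER)}

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class TraceFormatError(ValueError):
    """A trace file is unreadable or missing a required record."""


class VariantNotFoundError(LookupError):
    """The flanking sequences match nowhere in the called sequence."""


class AmbiguousFlankError(LookupError):
    """The flanking sequences match more than one basecall position."""


class ExtractionError(ValueError):
    """The extraction window around a basecall contains no trace points."""


@dataclass
class Chromatogram:
    """A four-channel Sanger trace with basecalls.

    ``trace`` has shape (4, n_points) with channels ordered A, C, G, T
    regardless of the instrument's dye order.  ``basecall_positions`` are
    0-based indices into the trace, strictly increasing, one per called base.
    """

    trace: np.ndarray
    basecall_positions: np.ndarray
    called_sequence: str
    sample_id: str = ""
    direction: str = "F"

    def __post_init__(self) -> None:
        self.trace = np.asarray(self.trace, dtype=float)
        self.basecall_positions = np.asarray(self.basecall_positions, dtype=int)
        if self.trace.ndim != 2 or self.trace.shape[0] != 4:
            raise ValueError("trace must have shape (4, n_points)")
        if self.trace.shape[1] == 0:
            raise ValueError("trace has zero length")
        if np.any(self.trace < 0):
            raise ValueError("trace intensities must be non-negative")
        if len(self.called_sequence) != len(self.basecall_positions):
            raise ValueError("called_sequence and basecall_positions differ in length")
        if len(self.basecall_positions):
            if np.any(np.diff(self.basecall_positions) <= 0):
                raise ValueError("basecall_positions must be strictly increasing")
            if self.basecall_positions[0] < 0 or self.basecall_positions[-1] >= self.trace.shape[1]:
                raise ValueError("basecall_positions outside trace")
        if self.direction not in ("F", "R"):
            raise ValueError(f"direction must be 'F' or 'R', got {self.direction!r}")

    def channel(self, base: str) -> np.ndarray:
        return self.trace[_CHANNEL_INDEX[base.upper()]]


@dataclass
class PeakPair:
    """Peak heights of the two alleles of one SNP in one sample/template/direction.

    Alleles are recorded as read on the sequenced strand; reverse reads carry
    the complement of the forward-strand bases and are reconciled downstream.
    """

    snp_id: str
    allele1: str
    allele2: str
    height1: float
    height2: float
    template: str  # "cDNA" or "gDNA"
    direction: str  # "F" or "R"
    sample_id: str
    qc_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.allele1 == self.allele2:
            raise ValueError("alleles of a peak pair must differ")
        if self.height1 < 0 or self.height2 < 0:
            raise ValueError("peak heights must be non-negative")
        if self.template not in ("cDNA", "gDNA"):
            raise ValueError(f"template must be 'cDNA' or 'gDNA', got {self.template!r}")
        if self.direction not in ("F", "R"):
            raise ValueError(f"direction must be 'F' or 'R', got {self.direction!r}")


@dataclass
class QCConfig:
    """Thresholds for heterozygous-call quality control.

    min_signal
        each allele peak must exceed ``min_signal`` times the median flanking
        baseline of its own channel.
    max_offtarget
        a third base's peak inside the variant window must stay below
        ``max_offtarget`` times the smaller allele height.
    min_purity
        mean fraction of total signal carried by the called base over the
        flanking basecalls (a sharpness/quality proxy).
    """

    min_signal: float = 5.0
    max_offtarget: float = 0.5
    min_purity: float = 0.5
    flank_calls: int = 5
    window_fraction: float = 0.5


def read_ab1(path: str | Path, direction: str = "F") -> Chromatogram:
    """Read an ABIF (.ab1) chromatogram into a :class:`Chromatogram`.

    The processed trace channels (DATA9-12) are mapped to bases via the
    file's dye-order record (FWO_1); basecall positions come from PLOC2
    (falling back to PLOC1) and the called sequence from PBAS2 (PBAS1).
    """
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "abi")
    except Exception as exc:  # Biopython raises ValueError/struct.error on bad containers
        raise TraceFormatError(f"{path}: not a readable ABIF file ({exc})") from exc
    raw = record.annotations.get("abif_raw", {})

    order_rec = raw.get("FWO_1")
    if order_rec is None:
        raise TraceFormatError(f"{path}: missing ABIF record FWO_1 (dye order)")
    dye_order = order_rec.decode() if isinstance(order_rec, bytes) else str(order_rec)

    channels = {}
    for k, base in enumerate(dye_order):
        rec = raw.get(f"DATA{9 + k}")
        if rec is None:
            raise TraceFormatError(f"{path}: missing ABIF record DATA{9 + k}")
        channels[base.upper()] = np.asarray(rec, dtype=float)
    missing = [b for b in CHANNEL_ORDER if b not in channels]
    if missing:
        raise TraceFormatError(f"{path}: dye order {dye_order!r} lacks channel(s) {missing}")

    ploc = raw.get("PLOC2", raw.get("PLOC1"))
    if ploc is None:
        raise TraceFormatError(f"{path}: missing ABIF record PLOC2/PLOC1 (basecall positions)")
    pbas = raw.get("PBAS2", raw.get("PBAS1"))
    if pbas is None:
        raise TraceFormatError(f"{path}: missing ABIF record PBAS2/PBAS1 (called sequence)")
    sequence = pbas.decode() if isinstance(pbas, bytes) else str(pbas)

    trace = np.vstack([channels[b] for b in CHANNEL_ORDER])
    if trace.shape[1] == 0:
        raise TraceFormatError(f"{path}: zero-length trace data")
    sample_id = record.id if record.id not in ("", "<unknown id>") else path.stem
    try:
        return Chromatogram(
            trace=trace,
            basecall_positions=np.asarray(ploc if not np.isscalar(ploc) else [ploc]),
            called_sequence=sequence,
            sample_id=sample_id,
            direction=direction,
        )
    except ValueError as exc:
        raise TraceFormatError(f"{path}: inconsistent ABIF records ({exc})") from exc


def read_trace_table(path: str | Path) -> Chromatogram:
    """Read the tabular trace dialect.

    Layout: header lines ``#sample=``, ``#direction=``, ``#basecalls=`` (comma
    separated trace indices), ``#sequence=``, followed by one line per trace
    point with four tab-separated intensities ordered A, C, G, T.
    """
    path = Path(path)
    headers: dict[str, str] = {}
    rows: list[list[float]] = []
    try:
        text = path.read_text()
    except OSError as exc:
        raise TraceFormatError(f"{path}: unreadable ({exc})") from exc
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            headers[key.strip()] = value.strip()
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise TraceFormatError(
                f"{path}:{lineno}: expected 4 channel columns (A,C,G,T), got {len(fields)}"
            )
        try:
            rows.append([float(v) for v in fields])
        except ValueError as exc:
            raise TraceFormatError(f"{path}:{lineno}: non-numeric intensity") from exc
    for key in ("sample", "direction", "basecalls", "sequence"):
        if key not in headers:
            raise TraceFormatError(f"{path}: missing header line '#{key}='")
    if not rows:
        raise TraceFormatError(f"{path}: no trace data lines")
    basecalls = (
        [int(v) for v in headers["basecalls"].split(",") if v.strip() != ""]
        if headers["basecalls"]
        else []
    )
    return Chromatogram(
        trace=np.asarray(rows, dtype=float).T,
        basecall_positions=np.asarray(basecalls, dtype=int),
        called_sequence=headers["sequence"],
        sample_id=headers["sample"],
        direction=headers["direction"],
    )


def write_trace_table(chrom: Chromatogram, path: str | Path) -> None:
    """Write a :class:`Chromatogram` in the tabular trace dialect (lossless)."""
    path = Path(path)
    lines = [
        f"#sample={chrom.sample_id}",
        f"#direction={chrom.direction}",
        "#basecalls=" + ",".join(str(int(p)) for p in chrom.basecall_positions),
        f"#sequence={chrom.called_sequence}",
    ]
    for col in chrom.trace.T:
        lines.append("\t".join(format(v, ".17g") for v in col))
    path.write_text("\n".join(lines) + "\n")


def locate_variant_index(chrom: Chromatogram, flank5: str, flank3: str) -> int:
    """Locate the unique basecall flanked by ``flank5``/``flank3``.

    Matching is exact on the called sequence; the base at the variant position
    itself is unconstrained (it may be an ambiguity code).  Returns the 0-based
    basecall index.  Raises :class:`VariantNotFoundError` on zero matches and
    :class:`AmbiguousFlankError` on several — extend the flanks to narrow down.
    """
    if not flank5 or not flank3:
        raise ValueError("flanks must be non-empty")
    seq = chrom.called_sequence.upper()
    f5, f3 = flank5.upper(), flank3.upper()
    hits = [
        i
        for i in range(len(f5), len(seq) - len(f3))
        if seq[i - len(f5) : i] == f5 and seq[i + 1 : i + 1 + len(f3)] == f3
    ]
    if not hits:
        raise VariantNotFoundError(
            f"flanks {flank5}/{flank3} not found in trace {chrom.sample_id!r}"
        )
    if len(hits) > 1:
        raise AmbiguousFlankError(
            f"flanks {flank5}/{flank3} match {len(hits)} positions in trace "
            f"{chrom.sample_id!r}; extend the flanks"
        )
    return hits[0]


def _local_window(chrom: Chromatogram, index: int, window_fraction: float) -> tuple[int, int]:
    positions = chrom.basecall_positions
    if index < 0 or index >= len(positions):
        raise IndexError(f"basecall index {index} out of range")
    pos = int(positions[index])
    spacings = []
    if index > 0:
        spacings.append(pos - int(positions[index - 1]))
    if index < len(positions) - 1:
        spacings.append(int(positions[index + 1]) - pos)
    # single-basecall trace: fall back to the full trace extent
    spacing = float(np.mean(spacings)) if spacings else float(chrom.trace.shape[1])
    half = window_fraction * spacing
    lo = max(0, math.ceil(pos - half))
    hi = min(chrom.trace.shape[1] - 1, math.floor(pos + half))
    if lo > hi:
        raise ExtractionError(f"empty extraction window at basecall {index}")
    return lo, hi


def extract_peak_pair(
    chrom: Chromatogram,
    index: int,
    allele1: str,
    allele2: str,
    window_fraction: float = 0.5,
    *,
    snp_id: str = "",
    template: str = "cDNA",
    peak_mode: str = "max",
) -> PeakPair:
    """Extract the two allele peak heights at a basecall position.

    Each height is the maximum intensity of that allele's channel inside a
    window of ±``window_fraction`` × local inter-peak spacing around the
    basecall position (``peak_mode="point"`` uses the intensity exactly at the
    call position instead).  Alleles are on the sequenced strand.
    """
    allele1, allele2 = allele1.upper(), allele2.upper()
    for a in (allele1, allele2):
        if a not in _CHANNEL_INDEX:
            raise ValueError(f"allele {a!r} is not one of A/C/G/T")
    if allele1 == allele2:
        raise ValueError("alleles must be distinct")
    if peak_mode not in ("max", "point"):
        raise ValueError(f"unknown peak_mode {peak_mode!r}")
    lo, hi = _local_window(chrom, index, window_fraction)
    if peak_mode == "point":
        pos = int(chrom.basecall_positions[index])
        h1 = float(chrom.channel(allele1)[pos])
        h2 = float(chrom.channel(allele2)[pos])
    else:
        h1 = float(chrom.channel(allele1)[lo : hi + 1].max())
        h2 = float(chrom.channel(allele2)[lo : hi + 1].max())
    return PeakPair(
        snp_id=snp_id,
        allele1=allele1,
        allele2=allele2,
        height1=h1,
        height2=h2,
        template=template,
        direction=chrom.direction,
        sample_id=chrom.sample_id,
    )


def qc_assess(
    pair: PeakPair, chrom: Chromatogram, index: int, config: QCConfig | None = None
) -> PeakPair:
    """Return a copy of ``pair`` with quality-control flags attached.

    Flags (never raises):

    * ``low_signal`` — an allele peak at or below ``min_signal`` × the median
      flanking baseline of its channel (zero-height peaks always flag);
    * ``offtarget_peak`` — a third base's peak in the variant window exceeds
      ``max_offtarget`` × the smaller allele height;
    * ``low_quality`` — mean signal purity of the flanking basecalls (called
      channel over total) below ``min_purity``.
    """
    config = config or QCConfig()
    flags: list[str] = []
    lo, hi = _local_window(chrom, index, config.window_fraction)

    # flanking span: basecalls within ±flank_calls, excluding the variant window
    n = len(chrom.basecall_positions)
    j0 = max(0, index - config.flank_calls)
    j1 = min(n - 1, index + config.flank_calls)
    span_lo = int(chrom.basecall_positions[j0])
    span_hi = int(chrom.basecall_positions[j1])
    mask = np.ones(chrom.trace.shape[1], dtype=bool)
    mask[: span_lo] = False
    mask[span_hi + 1 :] = False
    mask[lo : hi + 1] = False

    for allele, height in ((pair.allele1, pair.height1), (pair.allele2, pair.height2)):
        channel = chrom.channel(allele)
        baseline = float(np.median(channel[mask])) if mask.any() else 0.0
        if height == 0 or height < config.min_signal * baseline:
            if "low_signal" not in flags:
                flags.append("low_signal")

    others = [b for b in CHANNEL_ORDER if b not in (pair.allele1, pair.allele2)]
    off = max(float(chrom.channel(b)[lo : hi + 1].max()) for b in others)
    if off > config.max_offtarget * min(pair.height1, pair.height2):
        flags.append("offtarget_peak")

    purities = []
    for j in range(j0, j1 + 1):
        if j == index:
            continue
        base = chrom.called_sequence[j].upper()
        if base not in _CHANNEL_INDEX:
            continue
        pos = int(chrom.basecall_positions[j])
        total = float(chrom.trace[:, pos].sum())
        if total > 0:
            purities.append(float(chrom.channel(base)[pos]) / total)
    if purities and float(np.mean(purities)) < config.min_purity:
        flags.append("low_quality")

    return replace(pair, qc_flags=flags)
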