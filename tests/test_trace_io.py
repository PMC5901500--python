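"""Chromatogram parsing, variant location and peak extraction."""

import math

import numpy as np
import pytest

from daex.synthetic import simulate_trace
from daex.trace_io import (
    AmbiguousFlankError,
    Chromatogram,
    QCConfig,
    TraceFormatError,
    VariantNotFoundError,
    extract_peak_pair,
    locate_variant_index,
    qc_assess,
    read_ab1,
    read_trace_table,
    write_trace_table,
)

SEQ = "ACGTYGCA"


def _toy_channels(n_points=96):
    """One clean peak per base of SEQ at positions 6, 18, 30, ..."""
    positions = [6 + 12 * i for i in range(len(SEQ))]
    channels = {b: [0] * n_points for b in "ACGT"}
    for base, pos in zip(SEQ, positions):
        targets = {"Y": ("C", "T")}.get(base, (base,))
        for k, b in enumerate(targets):
            channels[b][pos] = 200 - 100 * k  # het site: 200/100
    return channels, positions


class TestReadAb1:
    def test_round_trip(self, tmp_path, abif_writer):
        channels, positions = _toy_channels()
        path = tmp_path / "toy.ab1"
        abif_writer(path, SEQ, channels, positions)
        chrom = read_ab1(path)
        assert chrom.called_sequence == SEQ
        assert chrom.sample_id == "specimen"
        assert list(chrom.basecall_positions) == positions
        assert chrom.channel("C")[positions[4]] == 200  # Y site major peak

    def test_dye_order_remapped(self, tmp_path, abif_writer):
        channels, positions = _toy_channels()
        p1, p2 = tmp_path / "gatc.ab1", tmp_path / "acgt.ab1"
        abif_writer(p1, SEQ, channels, positions, dye_order="GATC")
        abif_writer(p2, SEQ, channels, positions, dye_order="ACGT")
        c1, c2 = read_ab1(p1), read_ab1(p2)
        np.testing.assert_array_equal(c1.trace, c2.trace)

    @pytest.mark.parametrize("missing", ["FWO_1", "PLOC2", "PBAS2", "DATA10"])
    def test_missing_record_named(self, tmp_path, abif_writer, missing):
        channels, positions = _toy_channels()
        path = tmp_path / "broken.ab1"
        abif_writer(path, SEQ, channels, positions, omit={missing})
        with pytest.raises(TraceFormatError) as err:
            read_ab1(path)
        assert missing[:4] in str(err.value)

    def test_zero_length_trace(self, tmp_path, abif_writer):
        channels = {b: [] for b in "ACGT"}
        path = tmp_path / "empty.ab1"
        abif_writer(path, "", channels, [])
        with pytest.raises(TraceFormatError):
            read_ab1(path)

    def test_not_abif(self, tmp_path):
        path = tmp_path / "junk.ab1"
        path.write_bytes(b"not an abif file")
        with pytest.raises(TraceFormatError):
            read_ab1(path)


class TestTraceTable:
    def test_generator_round_trip(self, tmp_path):
        chrom = simulate_trace("ACGT", 1, {"C": 150.0, "T": 90.0}, noise_floor=2.0, seed=4)
        path = tmp_path / "trace.txt"
        write_trace_table(chrom, path)
        back = read_trace_table(path)
        np.testing.assert_array_equal(back.trace, chrom.trace)
        np.testing.assert_array_equal(back.basecall_positions, chrom.basecall_positions)
        assert back.called_sequence == chrom.called_sequence
        assert (back.sample_id, back.direction) == (chrom.sample_id, chrom.direction)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.txt"
        path.write_text("")
        with pytest.raises(TraceFormatError):
            read_trace_table(path)

    def test_missing_channel_column(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text(
            "#sample=s\n#direction=F\n#basecalls=0\n#sequence=A\n1.0\t2.0\t3.0\n"
        )
        with pytest.raises(TraceFormatError, match="4 channel columns"):
            read_trace_table(path)

    def test_single_basecall(self, tmp_path):
        path = tmp_path / "one.txt"
        path.write_text(
            "#sample=s\n#direction=F\n#basecalls=1\n#sequence=G\n"
            "0\t0\t5\t0\n0\t0\t9\t0\n0\t0\t5\t0\n"
        )
        chrom = read_trace_table(path)
        assert chrom.called_sequence == "G"
        assert chrom.channel("G")[1] == 9


class TestLocateVariant:
    def _chrom(self, seq):
        n = 12 * (len(seq) + 1)
        return Chromatogram(
            trace=np.zeros((4, n)),
            basecall_positions=[12 * (i + 1) for i in range(len(seq))],
            called_sequence=seq,
            sample_id="s",
        )

    def test_unique_match(self):
        assert locate_variant_index(self._chrom("ACGTYGCA"), "ACGT", "GCA") == 4

    def test_double_match_is_ambiguous(self):
        # AA?GG occurs at basecalls 2 and 8
        with pytest.raises(AmbiguousFlankError):
            locate_variant_index(self._chrom("AACGGTAATGG"), "AA", "GG")

    def test_not_found(self):
        with pytest.raises(VariantNotFoundError):
            locate_variant_index(self._chrom("ACGTACGT"), "TTT", "GGG")

    def test_strand_consistency(self):
        """The reverse-complement read locates the same physical base."""
        seq = "AACGTYGGCTA"
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "Y": "R"}
        rc = "".join(comp[b] for b in reversed(seq))
        i_fwd = locate_variant_index(self._chrom(seq), "AACGT", "GGCTA")
        i_rev = locate_variant_index(self._chrom(rc), "TAGCC", "ACGTT")
        assert i_rev == len(seq) - 1 - i_fwd
        assert comp[seq[i_fwd]] == rc[i_rev]


class TestExtractPeakPair:
    def test_recovers_gaussian_amplitudes(self):
        chrom = simulate_trace("ACGTACGTYTGCATGCA", 8, {"C": 200.0, "T": 100.0}, peak_sd=2.5)
        pair = extract_peak_pair(chrom, 8, "C", "T", snp_id="x")
        assert pair.height1 == pytest.approx(200.0, rel=0.02)
        assert pair.height2 == pytest.approx(100.0, rel=0.02)

    def test_homozygous_flat_channel(self):
        # T appears nowhere in the sequence, so its channel is exactly flat
        chrom = simulate_trace("ACGCA", 2, {"G": 180.0})
        pair = extract_peak_pair(chrom, 2, "G", "T")
        assert pair.height1 > 0
        assert pair.height2 == 0.0

    def test_linearity_under_scaling(self):
        chrom = simulate_trace("ACGTYACGT", 4, {"C": 150.0, "T": 70.0}, peak_sd=2.0)
        doubled = Chromatogram(
            trace=2.0 * chrom.trace,
            basecall_positions=chrom.basecall_positions,
            called_sequence=chrom.called_sequence,
            sample_id=chrom.sample_id,
        )
        p1 = extract_peak_pair(chrom, 4, "C", "T")
        p2 = extract_peak_pair(doubled, 4, "C", "T")
        assert p2.height1 == pytest.approx(2 * p1.height1)
        assert p2.height2 == pytest.approx(2 * p1.height2)
        assert math.log(p2.height1 / p2.height2) == pytest.approx(
            math.log(p1.height1 / p1.height2)
        )

    def test_point_mode(self):
        chrom = simulate_trace("ACGTYACGT", 4, {"C": 150.0, "T": 70.0}, peak_sd=2.0)
        pair = extract_peak_pair(chrom, 4, "C", "T", peak_mode="point")
        pos = chrom.basecall_positions[4]
        assert pair.height1 == chrom.channel("C")[pos]


class TestQcAssess:
    def _het_trace(self, minor=100.0, noise=0.0, seed=0):
        return simulate_trace(
            "ACGTACGTYTGCATGCA", 8, {"C": 200.0, "T": minor},
            peak_sd=2.5, noise_floor=noise, seed=seed,
        )

    def test_clean_heterozygote_no_flags(self):
        chrom = self._het_trace(noise=1.0)
        pair = extract_peak_pair(chrom, 8, "C", "T")
        assert qc_assess(pair, chrom, 8).qc_flags == []

    def test_low_signal_flag(self):
        # minor-allele channel appears only at the variant, collapsed into the
        # noise floor (T occurs nowhere else, so no neighbouring-peak leakage)
        chrom = simulate_trace(
            "ACGAACGAYAGCAAGCA", 8, {"C": 200.0, "T": 1.0},
            peak_sd=2.5, noise_floor=2.0, seed=1,
        )
        pair = extract_peak_pair(chrom, 8, "C", "T")
        assert "low_signal" in qc_assess(pair, chrom, 8).qc_flags

    def test_offtarget_peak_flag(self):
        chrom = self._het_trace()
        pos = int(chrom.basecall_positions[8])
        trace = chrom.trace.copy()
        trace[2, pos] += 90.0  # G artifact at 0.9 x minor height
        dirty = Chromatogram(
            trace=trace,
            basecall_positions=chrom.basecall_positions,
            called_sequence=chrom.called_sequence,
            sample_id=chrom.sample_id,
        )
        pair = extract_peak_pair(dirty, 8, "C", "T")
        flags = qc_assess(pair, dirty, 8, QCConfig(max_offtarget=0.5)).qc_flags
        assert "offtarget_peak" in flags
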