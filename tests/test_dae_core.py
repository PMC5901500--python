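"""Allelic log-ratios: orientation, gDNA centering, direction combination."""

import math

import numpy as np
import pytest

from daex.dae_core import (
    AllelicMeasurement,
    CenteringError,
    DAEStudy,
    AlleleMismatchError,
    UndefinedRatioError,
    center_by_gdna,
    combine_directions,
    log_allelic_ratio,
    orient_measurement,
    summarize_snp,
)
from daex.trace_io import PeakPair


def _pair(h1, h2, direction="F"):
    return PeakPair(
        snp_id="rs600753", allele1="C", allele2="T", height1=h1, height2=h2,
        template="cDNA", direction=direction, sample_id="s1",
    )


def _meas(r, direction="F", template="cDNA", group="control", sample="s1", oriented=False):
    return AllelicMeasurement(
        sample_id=sample, snp_id="rs600753", group=group, template=template,
        direction=direction, r=r, oriented=oriented,
    )


class TestLogRatio:
    def test_equal_peaks_zero(self):
        assert log_allelic_ratio(_pair(150.0, 150.0)) == 0.0

    def test_two_to_one(self):
        assert log_allelic_ratio(_pair(200.0, 100.0)) == pytest.approx(math.log(2))

    def test_swap_negates(self):
        assert log_allelic_ratio(_pair(173.0, 91.0)) == -log_allelic_ratio(_pair(91.0, 173.0))

    def test_zero_height_rejected(self):
        with pytest.raises(UndefinedRatioError):
            log_allelic_ratio(_pair(100.0, 0.0))


class TestOrientation:
    def test_reverse_read_complement_keeps_sign(self):
        # reverse read of a C/T SNP reports G/A; complement(G)=C is reference
        m = orient_measurement(_meas(0.3, direction="R"), "C", "T", "G", "A")
        assert m.oriented and m.r == 0.3

    def test_forward_reference_first_identity(self):
        m = orient_measurement(_meas(0.3), "C", "T", "C", "T")
        assert m.r == 0.3

    def test_reverse_read_alternate_first_negates(self):
        # reverse read (A, G) complements to (T, C); reference C must lead
        m = orient_measurement(_meas(0.3, direction="R"), "C", "T", "A", "G")
        assert m.r == -0.3

    def test_orienting_twice_is_identity(self):
        m1 = orient_measurement(_meas(0.3), "C", "T", "T", "C")
        m2 = orient_measurement(m1, "C", "T", "T", "C")
        assert m2 == m1

    def test_mismatched_alleles_rejected(self):
        with pytest.raises(AlleleMismatchError):
            orient_measurement(_meas(0.3), "C", "T", "A", "G")


def _study(measurements):
    return DAEStudy(
        snp_id="rs600753", reference_allele="C", alternate_allele="T",
        measurements=measurements,
    )


class TestCentering:
    def test_zero_mean_gdna_leaves_cdna(self):
        ms = [
            _meas(0.2, template="gDNA", sample="g1", oriented=True),
            _meas(-0.2, template="gDNA", sample="g2", oriented=True),
            _meas(0.0, template="gDNA", sample="g3", oriented=True),
            _meas(0.5, sample="c1", oriented=True),
        ]
        study = center_by_gdna(_study(ms))
        assert study.gdna_means["F"] == 0.0
        assert [m.rho for m in study.measurements] == [0.2, -0.2, 0.0, 0.5]

    def test_constant_gdna_bias_subtracted(self):
        ms = [
            _meas(0.1, template="gDNA", sample=f"g{i}", oriented=True) for i in range(3)
        ] + [_meas(0.5, sample="c1", oriented=True)]
        study = center_by_gdna(_study(ms))
        assert [m.rho for m in study.measurements[:3]] == pytest.approx([0.0, 0.0, 0.0])
        assert study.measurements[3].rho == pytest.approx(0.4)

    def test_corrected_gdna_mean_is_zero(self, rng):
        ms = [
            _meas(rng.normal(0.2, 0.3), template="gDNA", direction=d, sample=f"g{i}{d}",
                  oriented=True)
            for i in range(9)
            for d in ("F", "R")
        ]
        study = center_by_gdna(_study(ms))
        for d in ("F", "R"):
            vals = [m.rho for m in study.measurements if m.direction == d]
            assert abs(np.mean(vals)) < 1e-12

    def test_direction_without_gdna_rejected(self):
        ms = [
            _meas(0.1, template="gDNA", direction="F", oriented=True),
            _meas(0.4, direction="R", oriented=True),
        ]
        with pytest.raises(CenteringError, match="direction R"):
            center_by_gdna(_study(ms))

    def test_unoriented_measurements_rejected(self):
        with pytest.raises(ValueError, match="oriented"):
            center_by_gdna(_study([_meas(0.1, template="gDNA")]))

    def test_shift_invariance_of_direction_bias(self, rng):
        """Adding a constant to every r of one direction changes no rho."""
        base = [
            _meas(rng.normal(0, 0.4), template=t, direction=d, sample=f"s{i}", oriented=True)
            for i in range(6)
            for t in ("cDNA", "gDNA")
            for d in ("F", "R")
        ]
        shifted = [
            AllelicMeasurement(
                sample_id=m.sample_id, snp_id=m.snp_id, group=m.group, template=m.template,
                direction=m.direction, r=m.r + (0.7 if m.direction == "F" else 0.0),
                oriented=True,
            )
            for m in base
        ]
        rho1 = [m.rho for m in center_by_gdna(_study(base)).measurements]
        rho2 = [m.rho for m in center_by_gdna(_study(shifted)).measurements]
        assert rho1 == pytest.approx(rho2, abs=1e-12)


class TestCombineAndSummarize:
    def _centered(self, rows):
        study = _study([_meas(r, direction=d, template=t, group=g, sample=s, oriented=True)
                        for (r, d, t, g, s) in rows])
        return center_by_gdna(study)

    def test_average_of_directions(self):
        study = self._centered(
            [(0.0, "F", "gDNA", "control", "g1"), (0.0, "R", "gDNA", "control", "g1"),
             (0.4, "F", "cDNA", "control", "c1"), (0.6, "R", "cDNA", "control", "c1")]
        )
        combined = combine_directions(study)
        c1 = combined[(combined.sample_id == "c1") & (combined.template == "cDNA")]
        assert c1.rho.iloc[0] == pytest.approx(0.5)
        assert (combined.analysis_set == "F&R").all()

    def test_single_direction_fallback(self):
        study = self._centered(
            [(0.0, "F", "gDNA", "control", "g1"), (0.4, "F", "cDNA", "control", "c1")]
        )
        combined = combine_directions(study)
        assert combined[combined.sample_id == "c1"].rho.iloc[0] == pytest.approx(0.4)

    def test_equal_directions_idempotent(self):
        study = self._centered(
            [(0.0, "F", "gDNA", "control", "g1"), (0.0, "R", "gDNA", "control", "g1"),
             (0.7, "F", "cDNA", "control", "c1"), (0.7, "R", "cDNA", "control", "c1")]
        )
        combined = combine_directions(study)
        assert combined[combined.sample_id == "c1"].rho.iloc[0] == pytest.approx(0.7)

    def test_constant_group_summary(self):
        study = self._centered(
            [(0.0, "F", "gDNA", "control", "g1"), (0.0, "F", "gDNA", "control", "g2"),
             (0.3, "F", "cDNA", "affected_family", "f1"),
             (0.3, "F", "cDNA", "affected_family", "f2")]
        )
        summary = summarize_snp(study, "F")
        assert summary["cDNA_family"]["mean"] == pytest.approx(0.3)
        assert summary["cDNA_family"]["sd"] == pytest.approx(0.0)
        assert summary["gDNA"]["mean"] == pytest.approx(0.0, abs=1e-15)

    def test_empty_group_marked_not_zeroed(self):
        study = self._centered(
            [(0.0, "F", "gDNA", "control", "g1"),
             (0.2, "F", "cDNA", "affected_family", "f1")]
        )
        summary = summarize_snp(study, "F")
        assert summary["cDNA_control"]["n"] == 0
        assert math.isnan(summary["cDNA_control"]["mean"])


def test_allele_swap_antisymmetry(rng):
    """Swapping reference/alternate globally negates every corrected value."""
    rows = [
        (rng.normal(0.1, 0.5), d, t, g, f"s{i}{t}")
        for i in range(5)
        for d in ("F", "R")
        for t, g in (("cDNA", "affected_family"), ("gDNA", "control"))
    ]

    def build(ref, alt):
        ms = []
        for r, d, t, g, s in rows:
            raw = _meas(r, direction=d, template=t, group=g, sample=s)
            observed = ("C", "T")
            if d == "R":
                observed = tuple({"C": "G", "T": "A"}[b] for b in observed)
            ms.append(orient_measurement(raw, ref, alt, *observed))
        return center_by_gdna(
            DAEStudy(snp_id="x", reference_allele=ref, alternate_allele=alt, measurements=ms)
        )

    study_ct = build("C", "T")
    study_tc = build("T", "C")
    rho_ct = np.array([m.rho for m in study_ct.measurements])
    rho_tc = np.array([m.rho for m in study_tc.measurements])
    np.testing.assert_allclose(rho_tc, -rho_ct, atol=1e-12)
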