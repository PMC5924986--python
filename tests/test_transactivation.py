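"""Plate QC, percent activation, cytotoxicity flagging, hit calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pparscreen.transactivation import (
    activation_fold,
    call_hits,
    confirm_hits,
    flag_cytotoxicity,
    percent_activation,
    plate_qc,
)

from conftest import build_plate


def two_point_group(mu, sigma):
    """Two values with exact sample mean mu and sample SD sigma."""
    d = sigma / np.sqrt(2)
    return [mu - d, mu + d]


class TestPlateQC:
    def test_z_prime_formula(self):
        # mu_p=100 sd_p=5, mu_n=1 sd_n=0.1 -> Z' = 1 - 3*5.1/99
        plate = build_plate(two_point_group(1.0, 0.1), two_point_group(100.0, 5.0))
        qc = plate_qc(plate)
        assert qc.mu_pos == pytest.approx(100.0)
        assert qc.sigma_pos == pytest.approx(5.0)
        assert qc.z_prime == pytest.approx(1 - 3 * 5.1 / 99)
        assert qc.z_prime == pytest.approx(0.84545, abs=1e-4)
        assert qc.signal_to_background == pytest.approx(100.0)

    def test_zero_variance_gives_z_prime_one(self):
        plate = build_plate([1.0, 1.0, 1.0], [50.0, 50.0, 50.0])
        assert plate_qc(plate).z_prime == pytest.approx(1.0)

    def test_equal_means_undefined(self):
        plate = build_plate([1.0, 1.2], [1.2, 1.0])
        qc = plate_qc(plate)
        assert qc.z_prime is None
        assert not qc.passes_gate()

    def test_too_few_controls_rejected(self):
        plate = build_plate([1.0], [50.0, 51.0])
        with pytest.raises(ValueError, match="negative"):
            plate_qc(plate)

    def test_low_z_prime_fails_reliability_gate(self):
        # wide control spread -> Z' ~ 0.21-like failure
        plate = build_plate(two_point_group(1.0, 2.0), two_point_group(20.0, 3.0))
        qc = plate_qc(plate)
        assert qc.z_prime < 0.5
        assert not qc.passes_gate(0.5)

    def test_matches_brute_force_on_random_plates(self, rng):
        for _ in range(20):
            neg = rng.normal(1.0, 0.1, 8)
            pos = rng.normal(60.0, 5.0, 8)
            qc = plate_qc(build_plate(neg, pos))
            expected = 1 - 3 * (np.std(pos, ddof=1) + np.std(neg, ddof=1)) / abs(
                pos.mean() - neg.mean()
            )
            assert qc.z_prime == pytest.approx(expected)

    @given(
        a=st.floats(0.1, 50.0),
        b=st.floats(-5.0, 5.0),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_z_prime_affine_invariant(self, a, b):
        neg = np.array([0.9, 1.0, 1.1, 1.05])
        pos = np.array([48.0, 50.0, 52.0, 49.0])
        z0 = plate_qc(build_plate(neg, pos)).z_prime
        z1 = plate_qc(build_plate(a * neg + b, a * pos + b)).z_prime
        assert z1 == pytest.approx(z0, rel=1e-9)


class TestPercentActivation:
    def test_anchors_and_midpoint(self):
        plate = build_plate(
            [0.9, 1.1],
            [99.0, 101.0],
            sample_ratios={"at_neg": 1.0, "at_pos": 100.0, "mid": 50.5},
        )
        pct = percent_activation(plate)
        addr = {w.sample_id: str(w.address) for w in plate.samples()}
        assert pct[addr["at_neg"]] == pytest.approx(0.0)
        assert pct[addr["at_pos"]] == pytest.approx(100.0)
        assert pct[addr["mid"]] == pytest.approx(50.0)

    def test_affine_invariance(self):
        neg, pos = [0.9, 1.1], [99.0, 101.0]
        samples = {"s1": 30.0, "s2": 75.0}
        p0 = percent_activation(build_plate(neg, pos, dict(samples)))
        scaled = {k: 3.0 * v + 2.0 for k, v in samples.items()}
        p1 = percent_activation(
            build_plate([3 * x + 2 for x in neg], [3 * x + 2 for x in pos], scaled)
        )
        for k in p0:
            assert p1[k] == pytest.approx(p0[k])

    def test_degenerate_anchor_rejected(self):
        plate = build_plate([1.0, 1.2], [1.2, 1.0], {"s": 1.1})
        with pytest.raises(ValueError, match="anchor"):
            percent_activation(plate)


class TestCytotoxicity:
    @staticmethod
    def _plate_with_control_renilla(mu, sigma, sample_renilla):
        """8 control wells with exact Renilla sample mean mu and SD sigma."""
        plate = build_plate(
            [1.0] * 4,
            [50.0] * 4,
            sample_ratios={sid: 1.0 for sid in sample_renilla},
            sample_renilla=sample_renilla,
        )
        n = 8
        d = sigma * np.sqrt((n - 1) / n)  # alternating +-d has sample SD sigma
        for i, w in enumerate(plate.controls()):
            w.renilla = mu + (d if i % 2 == 0 else -d)
        ctrl = [w.renilla for w in plate.controls()]
        assert np.mean(ctrl) == pytest.approx(mu)
        assert np.std(ctrl, ddof=1) == pytest.approx(sigma)
        return plate

    def test_five_sd_cutoff(self):
        # control renilla mean 10000, SD 500 -> cutoff 7500
        plate = self._plate_with_control_renilla(
            10000.0, 500.0, {"dead": 7400.0, "alive": 9000.0}
        )
        flags = flag_cytotoxicity(plate, tox_k=5.0)
        assert {f.sample_id for f in flags} == {"dead"}
        assert flags[0].cutoff == pytest.approx(7500.0)

    def test_boundary_is_strictly_below(self):
        # zero-variance controls make the cutoff exact: wells at the cutoff stay
        plate = build_plate(
            [1.0] * 4,
            [50.0] * 4,
            sample_ratios={"at": 1.0, "below": 1.0},
            sample_renilla={"at": 10000.0, "below": 9999.0},
        )
        flags = flag_cytotoxicity(plate, tox_k=5.0)  # cutoff = 10000 exactly
        assert {f.sample_id for f in flags} == {"below"}

    def test_all_equal_renilla_flags_none(self):
        plate = build_plate(
            [1.0, 1.0], [50.0, 50.0], sample_ratios={"s": 1.0}
        )
        assert flag_cytotoxicity(plate) == []


class TestCallHits:
    def test_threshold_mu_plus_7_sigma(self):
        # mu_n=1.0 sd_n=0.1 -> threshold 1.7 (inclusive boundary is covered
        # exactly by the zero-variance case below)
        plate = build_plate(
            two_point_group(1.0, 0.1),
            two_point_group(100.0, 1.0),
            sample_ratios={"hi": 1.71, "lo": 1.69},
        )
        calls = {c.sample_id: c for c in call_hits(plate)}
        assert calls["hi"].is_hit
        assert not calls["lo"].is_hit
        assert calls["hi"].threshold == pytest.approx(1.7)

    def test_zero_sd_degenerate_threshold(self):
        plate = build_plate(
            [1.0, 1.0, 1.0],
            [100.0, 100.0, 100.0],
            sample_ratios={"above": 1.001, "at": 1.0, "below": 0.999},
        )
        calls = {c.sample_id: c for c in call_hits(plate)}
        assert calls["above"].is_hit
        assert calls["at"].is_hit
        assert not calls["below"].is_hit

    def test_cytotoxic_well_cannot_be_hit(self):
        plate = build_plate(
            two_point_group(1.0, 0.1),
            two_point_group(100.0, 1.0),
            sample_ratios={"dead_high": 5.0, "alive_high": 5.0},
            sample_renilla={"dead_high": 100.0},
        )
        calls = {c.sample_id: c for c in call_hits(plate)}
        assert calls["dead_high"].is_cytotoxic and not calls["dead_high"].is_hit
        assert calls["alive_high"].is_hit and not calls["alive_high"].is_cytotoxic

    def test_monotone_in_ratio(self):
        base = {"s": 1.5}
        plate_lo = build_plate(
            two_point_group(1.0, 0.1), two_point_group(100.0, 1.0), dict(base)
        )
        lo_hit = call_hits(plate_lo)[0].is_hit
        plate_hi = build_plate(
            two_point_group(1.0, 0.1), two_point_group(100.0, 1.0), {"s": 2.5}
        )
        hi_hit = call_hits(plate_hi)[0].is_hit
        assert (not lo_hit) or hi_hit  # raising ratio never un-calls

    def test_matches_brute_force_enumeration(self, rng):
        neg = rng.normal(1.0, 0.05, 8)
        pos = rng.normal(60.0, 3.0, 8)
        ratios = {f"s{i}": float(r) for i, r in enumerate(rng.uniform(0.8, 2.2, 40))}
        plate = build_plate(neg, pos, ratios)
        thr = neg.mean() + 7 * np.std(neg, ddof=1)
        expected = {sid for sid, r in ratios.items() if r >= thr}
        called = {c.sample_id for c in call_hits(plate) if c.is_hit}
        assert called == expected


class TestConfirmHits:
    def _plate(self, ratios, plate_id):
        return build_plate(
            two_point_group(1.0, 0.1),
            two_point_group(100.0, 1.0),
            ratios,
            plate_id=plate_id,
        )

    def test_two_of_three_quorum(self):
        hot, cold = 2.5, 1.0
        p1 = self._plate({"a": hot, "b": hot, "c": cold}, "R1")
        p2 = self._plate({"a": cold, "b": hot, "c": cold}, "R2")
        p3 = self._plate({"a": hot, "b": cold, "c": cold}, "R3")
        assert confirm_hits([p1, p2, p3]) == ["a", "b"]

    def test_single_pass_not_confirmed(self):
        hot, cold = 2.5, 1.0
        plates = [
            self._plate({"x": hot}, "R1"),
            self._plate({"x": cold}, "R2"),
            self._plate({"x": cold}, "R3"),
        ]
        assert confirm_hits(plates) == []

    def test_all_pass_is_identity(self):
        plates = [self._plate({"x": 2.5, "y": 3.0}, f"R{i}") for i in range(3)]
        assert confirm_hits(plates) == ["x", "y"]

    def test_missing_candidate_names_plate(self):
        p1 = self._plate({"a": 2.0, "b": 2.0}, "R1")
        p2 = self._plate({"a": 2.0}, "R2")
        p3 = self._plate({"a": 2.0, "b": 2.0}, "R3")
        with pytest.raises(ValueError, match="R2"):
            confirm_hits([p1, p2, p3])


class TestActivationFold:
    def test_199_fold(self):
        plate = build_plate([1.0, 1.0], [199.0, 199.0])
        assert activation_fold(plate) == pytest.approx(199.0)

    def test_no_activation_is_fold_one(self):
        assert activation_fold(treated=[1.1, 0.9], vehicle=[0.9, 1.1]) == pytest.approx(1.0)

    def test_scale_invariance(self):
        f0 = activation_fold(treated=[5.0, 6.0], vehicle=[1.0, 1.2])
        f1 = activation_fold(treated=[10.0, 12.0], vehicle=[2.0, 2.4])
        assert f0 == pytest.approx(f1)

    def test_nonpositive_vehicle_rejected(self):
        with pytest.raises(ValueError):
            activation_fold(treated=[1.0], vehicle=[0.0])
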