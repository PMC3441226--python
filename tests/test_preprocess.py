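import hashlib
import zlib

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hgca import fixtures
from hgca.errors import ValidationError
from hgca.matrix_io import ExpressionMatrix
from hgca.preprocess import (
    IntensityVector,
    balanced_selection,
    deduplicate,
    drop_control_probesets,
    intensity_signature,
    normalize_matrix,
    qc_intensity_range,
    round_to_half,
    scaling_factor,
    serialize_intensities,
    trimmed_mean,
)


class TestQc:
    def test_boundaries_pass(self):
        ok, bad = qc_intensity_range(IntensityVector("s", [0, 65535, 123.5]))
        assert ok and bad == []

    def test_below_range(self):
        ok, bad = qc_intensity_range(IntensityVector("s", [-1, 10]))
        assert not ok and bad == [0]

    def test_above_range(self):
        ok, bad = qc_intensity_range(IntensityVector("s", [10, 65536]))
        assert not ok and bad == [1]

    def test_empty_vector(self):
        with pytest.raises(ValidationError):
            qc_intensity_range(IntensityVector("s", []))


class TestSignature:
    def test_md5_component_of_empty_serialization(self):
        # RFC 1321 test vector for the empty message
        sig = intensity_signature(IntensityVector("s", []))
        assert sig[:32] == "d41d8cd98f00b204e9800998ecf8427e"
        assert len(sig) == 80

    def test_matches_independent_hashing(self):
        # integers render without ".0", fractions with their shortest decimal
        assert serialize_intensities([1, 2.5, 300.0]) == "12.5300"
        data = b"12.5300"
        expected = (
            hashlib.md5(data).hexdigest()
            + hashlib.sha1(data).hexdigest()
            + format(zlib.crc32(data) & 0xFFFFFFFF, "08x")
        )
        assert intensity_signature(IntensityVector("s", [1, 2.5, 300.0])) == expected

    def test_deterministic(self):
        v = IntensityVector("s", [1.5, 2, 3])
        w = IntensityVector("other", [1.5, 2, 3])
        assert intensity_signature(v) == intensity_signature(w)

    def test_single_value_perturbations_change_signature(self, rng):
        base = rng.uniform(0, 65535, size=32).round(1)
        reference = intensity_signature(IntensityVector("s", base))
        for _ in range(100):
            idx = int(rng.integers(0, base.size))
            perturbed = base.copy()
            perturbed[idx] += float(rng.uniform(0.5, 10.0))
            assert intensity_signature(IntensityVector("s", perturbed)) != reference


class TestDeduplicate:
    def test_pair_collapsed(self):
        samples = [
            IntensityVector("GSM2", [1, 2, 3]),
            IntensityVector("GSM1", [1, 2, 3]),
            IntensityVector("GSM3", [4, 5, 6]),
        ]
        unique, report = deduplicate(samples)
        assert [s.sample_id for s in unique] == ["GSM1", "GSM3"]
        assert sorted(len(v) for v in report.values()) == [1, 2]

    def test_all_distinct_retained(self):
        samples = [IntensityVector(f"GSM{i}", [i, i + 1]) for i in range(5)]
        unique, report = deduplicate(samples)
        assert len(unique) == 5
        assert all(len(v) == 1 for v in report.values())

    def test_planted_duplicates_removed_exactly(self):
        spec = fixtures.FixtureSpec(
            n_probes=5, n_samples=3, duplicates=280, seed=3,
            tissues=(fixtures.TissueSpec("liver", (500, 500)),),
        )
        samples = fixtures.make_intensity_set(spec)
        assert len(samples) == 1280
        unique, _ = deduplicate(samples)
        assert len(samples) - len(unique) == 280

    def test_never_removes_without_partner(self, rng):
        samples = [
            IntensityVector(f"GSM{i}", rng.uniform(0, 100, size=8)) for i in range(20)
        ]
        unique, report = deduplicate(samples)
        removed = {s.sample_id for s in samples} - {s.sample_id for s in unique}
        for sid in removed:
            group = next(g for g in report.values() if sid in g)
            assert len(group) >= 2


class TestBalancedSelection:
    @staticmethod
    def _samples(layout):
        # layout: {tissue: {series: count}}
        out = []
        i = 0
        for tissue, by_series in layout.items():
            for series, count in by_series.items():
                for _ in range(count):
                    out.append(
                        IntensityVector(f"GSM{i:04d}", [0.0], tissue=tissue, series=series)
                    )
                    i += 1
        return out

    def test_even_split(self):
        samples = self._samples({"liver": {"g1": 10}, "brain": {"g1": 10}})
        picked = balanced_selection(samples, 10)
        counts = {t: 0 for t in ("liver", "brain")}
        by_id = {s.sample_id: s for s in samples}
        for sid in picked:
            counts[by_id[sid].tissue] += 1
        assert counts == {"liver": 5, "brain": 5}

    def test_target_exceeds_total(self):
        samples = self._samples({"liver": {"g1": 3}})
        assert len(balanced_selection(samples, 99)) == 3

    def test_exhausted_tissue(self):
        # hand-simulated round robin over tissue sizes (2, 10, 10), target 12
        samples = self._samples({"t1": {"g": 2}, "t2": {"g": 10}, "t3": {"g": 10}})
        picked = balanced_selection(samples, 12)
        by_id = {s.sample_id: s for s in samples}
        counts = {}
        for sid in picked:
            counts[by_id[sid].tissue] = counts.get(by_id[sid].tissue, 0) + 1
        assert counts == {"t1": 2, "t2": 5, "t3": 5}

    def test_series_balance_within_tissue(self):
        samples = self._samples({"liver": {"g1": 8, "g2": 8, "g3": 8}})
        picked = set(balanced_selection(samples, 9))
        by_id = {s.sample_id: s for s in samples}
        counts = {}
        for sid in picked:
            counts[by_id[sid].series] = counts.get(by_id[sid].series, 0) + 1
        assert counts == {"g1": 3, "g2": 3, "g3": 3}

    def test_input_order_invariance(self, rng):
        samples = self._samples({"a": {"g1": 4, "g2": 6}, "b": {"g1": 7}})
        shuffled = list(samples)
        rng.shuffle(shuffled)
        assert balanced_selection(samples, 9) == balanced_selection(shuffled, 9)

    def test_invalid_target(self):
        with pytest.raises(ValidationError):
            balanced_selection(self._samples({"a": {"g": 1}}), 0)


class TestDropControls:
    def test_drops_affx(self):
        m = ExpressionMatrix(
            ["AFFX-1_at", "200725_x_at"], ["s1"], np.array([[1.0], [2.0]])
        )
        out = drop_control_probesets(m)
        assert out.probe_ids == ["200725_x_at"]
        assert out.values.tolist() == [[2.0]]

    def test_identity_without_controls(self):
        m = ExpressionMatrix(["a_at", "b_at"], ["s1"], np.array([[1.0], [2.0]]))
        assert drop_control_probesets(m) is m

    def test_all_controls_error(self):
        m = ExpressionMatrix(["AFFX-1", "AFFX-2"], ["s1"], np.ones((2, 1)))
        with pytest.raises(ValidationError):
            drop_control_probesets(m)


class TestScalingFactor:
    def test_constant_vector(self):
        assert scaling_factor([250.0] * 100) == pytest.approx(2.0)

    def test_identity_when_already_at_target(self):
        values = [400.0, 500.0, 600.0] * 40
        assert scaling_factor(values) == pytest.approx(500.0 / trimmed_mean(values))
        assert scaling_factor([500.0] * 50) == pytest.approx(1.0)

    def test_lognormal_recomputation_oracle(self):
        gen = np.random.default_rng(1234)
        values = gen.lognormal(mean=5.0, sigma=1.0, size=1000)
        factor = scaling_factor(values)
        scaled = values * factor
        # independent recomputation: sort, drop 20 from each end, average
        s = np.sort(scaled)
        assert s[20:-20].mean() == pytest.approx(500.0, rel=1e-9)

    def test_trim_count_uses_floor(self):
        # N=120 -> floor(0.02*120)=2 removed per end
        values = np.array([1e6, 1e6] + [500.0] * 116 + [0.0, 0.0])
        assert scaling_factor(values) == pytest.approx(1.0)

    def test_all_zero_trimmed_segment(self):
        with pytest.raises(ValidationError, match="zero"):
            scaling_factor([0.0] * 50)

    def test_too_few_values(self):
        with pytest.raises(ValidationError):
            scaling_factor([1.0, 2.0])


class TestRoundToHalf:
    @pytest.mark.parametrize(
        "x,expected",
        [(123.2, 123.0), (123.26, 123.5), (0.75, 1.0), (0.25, 0.5), (0.0, 0.0),
         (1.24, 1.0), (-0.75, -1.0)],
    )
    def test_examples(self, x, expected):
        assert round_to_half(x) == expected

    @given(st.floats(min_value=-1e6, max_value=1e6))
    def test_nearest_multiple(self, x):
        r = round_to_half(x)
        assert (r * 2) == int(r * 2)  # multiple of 0.5
        assert abs(r - x) <= 0.25 + 1e-9

    def test_non_finite(self):
        with pytest.raises(ValidationError):
            round_to_half(float("nan"))


class TestNormalizeMatrix:
    def test_constant_column(self):
        m = ExpressionMatrix(
            [f"p{i}_at" for i in range(5)], ["s1"], np.full((5, 1), 250.0)
        )
        out = normalize_matrix(m)
        assert np.all(out.values == 500.0)

    def test_already_normalized_column(self):
        values = np.array([[400.0], [500.0], [600.0], [450.0], [550.0]])
        m = ExpressionMatrix([f"p{i}_at" for i in range(5)], ["s1"], values)
        out = normalize_matrix(m)
        np.testing.assert_array_equal(out.values, values)

    def test_columns_hit_target(self, rng):
        values = rng.uniform(10, 900, size=(50, 10))
        m = ExpressionMatrix(
            [f"p{i}_at" for i in range(50)], [f"s{j}" for j in range(10)], values
        )
        out = normalize_matrix(m)
        for j in range(10):
            col = np.sort(out.values[:, j])
            k = int(np.floor(0.02 * 50))
            assert col[k : 50 - k].mean() == pytest.approx(500.0, abs=0.5)

    def test_idempotent_up_to_rounding(self, rng):
        values = rng.uniform(10, 900, size=(60, 4))
        m = ExpressionMatrix(
            [f"p{i}_at" for i in range(60)], [f"s{j}" for j in range(4)], values
        )
        once = normalize_matrix(m)
        twice = normalize_matrix(once)
        # the re-scaling factor is ~1, so values move by at most one grid step
        assert np.max(np.abs(twice.values - once.values)) <= 0.5
        assert np.mean(twice.values != once.values) < 0.05
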