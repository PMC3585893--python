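"""Feature encodings, train-derived scaling, and tabular round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lignoclass as lc
from lignoclass import features as ft
from lignoclass.annotation import AnnotationProfile


def profile(sample, **counts):
    return AnnotationProfile(sample, counts)


class TestBuildMatrix:
    def test_frequency_divides_by_sample_total(self):
        m = ft.build_matrix([profile("s1", A=2, B=3, C=5)], ft.FREQUENCY)
        assert m.X[0].tolist() == [0.2, 0.3, 0.5]

    def test_binary_marks_presence(self):
        m = ft.build_matrix([profile("s1", B=7, C=1)], ft.BINARY)
        assert m.family_ids == ["B", "C"] and m.X[0].tolist() == [1.0, 1.0]

    def test_disjoint_families_give_complementary_zeros(self):
        m = ft.build_matrix([profile("s1", A=1), profile("s2", B=4)], ft.BINARY)
        assert m.family_ids == ["A", "B"]
        assert m.X.tolist() == [[1.0, 0.0], [0.0, 1.0]]

    def test_family_universe_is_sorted_union(self):
        m = ft.build_matrix([profile("s1", Z=1, A=1), profile("s2", M=1)], ft.BINARY)
        assert m.family_ids == ["A", "M", "Z"]

    def test_empty_profile_list_rejected(self):
        with pytest.raises(ValueError):
            ft.build_matrix([], ft.BINARY)

    def test_zero_total_under_frequency_names_the_sample(self):
        with pytest.raises(ValueError, match="empty_one"):
            ft.build_matrix([profile("s1", A=1), profile("empty_one")], ft.FREQUENCY)

    def test_missing_label_names_the_sample(self):
        with pytest.raises(ValueError, match="s2"):
            ft.build_matrix([profile("s1", A=1), profile("s2", A=1)],
                            ft.BINARY, labels={"s1": 1})

    def test_labels_attached_in_sample_order(self):
        m = ft.build_matrix([profile("s1", A=1), profile("s2", B=1)],
                            ft.BINARY, labels={"s1": 1, "s2": -1})
        assert m.labels.tolist() == [1, -1]

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(min_value=2, max_value=50))
    def test_binary_encoding_invariant_to_count_scaling(self, factor):
        base = [profile("s1", A=2, B=5), profile("s2", B=1, C=7)]
        scaled = [
            AnnotationProfile(p.sample_id, {f: c * factor for f, c in p.counts.items()})
            for p in base
        ]
        m1 = ft.build_matrix(base, ft.BINARY)
        m2 = ft.build_matrix(scaled, ft.BINARY)
        assert np.array_equal(m1.X, m2.X)

    def test_frequency_rows_sum_to_one_over_full_universe(self):
        m = ft.build_matrix(
            [profile("s1", A=2, B=3), profile("s2", B=1, C=9)], ft.FREQUENCY
        )
        assert np.allclose(m.X.sum(axis=1), 1.0)


class TestScaler:
    def test_minmax_maps_training_column_to_unit_interval(self):
        m = lc.FeatureMatrix(["a", "b", "c"], ["f"], np.array([[0.1], [0.2], [0.3]]),
                             encoding=ft.FREQUENCY)
        scaled = ft.apply_scaler(ft.fit_scaler(m), m)
        assert scaled.X.ravel() == pytest.approx([0.0, 0.5, 1.0])

    def test_constant_training_column_maps_to_zero(self):
        m = lc.FeatureMatrix(["a", "b"], ["f"], np.array([[0.4], [0.4]]),
                             encoding=ft.FREQUENCY)
        scaled = ft.apply_scaler(ft.fit_scaler(m), m)
        assert scaled.X.ravel().tolist() == [0.0, 0.0]

    def test_held_out_values_are_not_clipped(self):
        train = lc.FeatureMatrix(["a", "b"], ["f"], np.array([[0.1], [0.3]]),
                                 encoding=ft.FREQUENCY)
        scaler = ft.fit_scaler(train)
        test = lc.FeatureMatrix(["t"], ["f"], np.array([[0.5]]), encoding=ft.FREQUENCY)
        assert ft.apply_scaler(scaler, test).X.item() == pytest.approx(2.0)

    def test_unknown_families_listed_in_error(self):
        train = lc.FeatureMatrix(["a"], ["f"], np.array([[0.1]]), encoding=ft.FREQUENCY)
        scaler = ft.fit_scaler(train)
        other = lc.FeatureMatrix(["a"], ["g"], np.array([[0.1]]), encoding=ft.FREQUENCY)
        with pytest.raises(ValueError, match="g"):
            ft.apply_scaler(scaler, other)

    def test_training_matrix_scales_into_unit_interval(self):
        rng = np.random.default_rng(5)
        m = lc.FeatureMatrix(
            [f"s{i}" for i in range(8)],
            [f"f{j}" for j in range(6)],
            rng.uniform(0, 0.3, size=(8, 6)),
            encoding=ft.FREQUENCY,
        )
        scaled, scaler = ft.scale_training(m)
        assert scaler is not None
        assert scaled.X.min() >= 0.0 and scaled.X.max() <= 1.0

    def test_binary_matrices_pass_through_unscaled(self):
        m = ft.build_matrix([profile("s1", A=1), profile("s2", B=1)], ft.BINARY)
        scaled, scaler = ft.scale_training(m)
        assert scaler is None and scaled is m


class TestEncodeProfile:
    def test_projection_onto_universe_ignores_unseen(self, caplog):
        x = ft.encode_profile(profile("s1", A=1, NEW=5), ["A", "B"], ft.BINARY)
        assert x.tolist() == [1.0, 0.0]

    def test_frequency_denominator_includes_unseen_families(self):
        x = ft.encode_profile(profile("s1", A=1, NEW=3), ["A", "B"], ft.FREQUENCY)
        assert x.tolist() == [0.25, 0.0]

    def test_empty_profile_under_frequency_rejected(self):
        with pytest.raises(ValueError, match="s1"):
            ft.encode_profile(profile("s1"), ["A"], ft.FREQUENCY)


class TestExportAndIO:
    def test_rescaled_frequency_export_subsets_columns(self):
        m = ft.build_matrix([profile("s1", A=2, B=3, C=5)], ft.FREQUENCY)
        table = ft.export_rescaled_frequencies(m, ["C", "A"])
        assert table.columns.tolist() == ["C", "A"]
        assert table.loc["s1"].tolist() == [0.5, 0.2]

    def test_rescaled_frequency_export_rejects_unknown_family(self):
        m = ft.build_matrix([profile("s1", A=1)], ft.FREQUENCY)
        with pytest.raises(ValueError, match="NOPE"):
            ft.export_rescaled_frequencies(m, ["NOPE"])

    def test_rescaled_frequency_export_requires_frequency_encoding(self):
        m = ft.build_matrix([profile("s1", A=1)], ft.BINARY)
        with pytest.raises(ValueError):
            ft.export_rescaled_frequencies(m, ["A"])

    def test_matrix_tsv_round_trip_preserves_labels(self, tmp_path):
        m = ft.build_matrix([profile("s1", A=2), profile("s2", B=3)],
                            ft.FREQUENCY, labels={"s1": 1, "s2": -1})
        path = tmp_path / "matrix.tsv"
        m.to_tsv(path)
        back = lc.FeatureMatrix.from_tsv(path, encoding=ft.FREQUENCY)
        assert back.sample_ids == m.sample_ids
        assert back.family_ids == m.family_ids
        assert np.allclose(back.X, m.X)
        assert back.labels.tolist() == [1, -1]

    def test_label_tsv_round_trip(self, tmp_path):
        labels = {"b": -1, "a": 1}
        path = tmp_path / "labels.tsv"
        ft.write_labels(labels, path)
        assert ft.read_labels(path) == labels

    def test_label_tsv_rejects_other_values(self, tmp_path):
        path = tmp_path / "labels.tsv"
        path.write_text("sample_id\tlabel\ns1\t2\n")
        with pytest.raises(ValueError):
            ft.read_labels(path)

    def test_matrix_rejects_bad_labels(self):
        with pytest.raises(ValueError):
            lc.FeatureMatrix(["s"], ["f"], np.array([[1.0]]), labels=np.array([0]))
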