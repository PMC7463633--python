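"""Feature-table parsing, filters, normalization and ion-mode merging."""

import numpy as np
import pandas as pd
import pytest

from fusemet.feature_io import (
    FeatureTableError,
    filter_cv,
    filter_missingness,
    impute_minimum,
    log2_transform,
    merge_ion_modes,
    normalize_and_impute,
    read_feature_table,
    tic_normalize,
    write_feature_table,
)

from conftest import make_matrix


# --------------------------------------------------------------------- #
# reading / writing
# --------------------------------------------------------------------- #

def _write_toy_table(tmp_path, rows, header="feature_id\ts1\ts2\ts3"):
    table = tmp_path / "t.tsv"
    table.write_text("\n".join([header] + rows) + "\n")
    meta = tmp_path / "m.tsv"
    meta.write_text(
        "sample_id\tcell_line\tmdm2_status\ttreatment\treplicate\tion_mode"
        "\tnormalization_factor\n"
        "s1\tA\thigh\tuntreated\t1\tnone\t1.0\n"
        "s2\tA\thigh\tuntreated\t2\tnone\t1.0\n"
        "s3\tB\tlow\tuntreated\t1\tnone\t1.0\n"
    )
    return table, meta


def test_read_parses_values_and_flags_na(tmp_path):
    table, meta = _write_toy_table(tmp_path, ["f1\t1.5\tNA\t3", "f2\t2\t4\t8"])
    m = read_feature_table(table, meta)
    assert m.values.shape == (2, 3)
    assert m.missing_mask.loc["f1", "s2"]
    assert int(m.missing_mask.to_numpy().sum()) == 1
    assert m.values.loc["f2", "s3"] == 8


def test_read_rejects_duplicate_feature_id(tmp_path):
    table, meta = _write_toy_table(tmp_path, ["M001\t1\t2\t3", "M001\t4\t5\t6"])
    with pytest.raises(FeatureTableError, match="duplicate feature id"):
        read_feature_table(table, meta)


def test_read_rejects_unknown_sample_and_bad_cell(tmp_path):
    table, meta = _write_toy_table(
        tmp_path, ["f1\t1\t2\t3"], header="feature_id\ts1\ts2\tsX")
    with pytest.raises(FeatureTableError, match="without metadata"):
        read_feature_table(table, meta)
    table2, meta2 = _write_toy_table(tmp_path, ["f1\t1\toops\t3"])
    with pytest.raises(FeatureTableError, match="non-numeric"):
        read_feature_table(table2, meta2)


def test_round_trip_is_bit_exact(tmp_path):
    rng = np.random.default_rng(5)
    vals = {f"f{i}": rng.lognormal(1, 1, 6) for i in range(8)}
    m = make_matrix(vals)
    m.values.iloc[2, 3] = np.nan
    m.missing_mask.iloc[2, 3] = True
    write_feature_table(m, tmp_path / "x.tsv", tmp_path / "xm.tsv")
    back = read_feature_table(tmp_path / "x.tsv", tmp_path / "xm.tsv")
    assert back.values.equals(m.values)
    assert back.missing_mask.equals(m.missing_mask)
    pd.testing.assert_frame_equal(
        back.samples[["cell_line", "treatment"]],
        m.samples[["cell_line", "treatment"]])


# --------------------------------------------------------------------- #
# filters
# --------------------------------------------------------------------- #

def test_missingness_boundary_is_inclusive():
    m = make_matrix({
        "half": [1, np.nan, 1, np.nan],      # exactly 50% -> removed
        "quarter": [1, 1, 1, np.nan],        # 25% -> retained
        "full": [1, 2, 3, 4],
    })
    out, report = filter_missingness(m, 0.5)
    assert report.removed_feature_ids == ["half"]
    assert list(out.values.index) == ["quarter", "full"]
    assert report.removed.loc["half", "statistic"] == 0.5


def test_filter_conservation_and_idempotence():
    rng = np.random.default_rng(0)
    vals = {f"f{i}": np.where(rng.random(8) < 0.4, np.nan, rng.lognormal(0, 1, 8))
            for i in range(40)}
    m = make_matrix(vals)
    out, report = filter_missingness(m, 0.5)
    assert out.n_features + len(report.removed) == m.n_features
    again, report2 = filter_missingness(out, 0.5)
    assert list(again.values.index) == list(out.values.index)
    assert len(report2.removed) == 0


def test_cv_filter_hand_computed_cases():
    # within-group values {1,1,1,1} -> CV 0 retained; {0,0,0,4}: mean 1, sd 2
    # -> CV 200 > 150 removed (hand computation of 100*sd/mean)
    m = make_matrix({
        "flat": [1, 1, 1, 1, 5, 5],
        "wild": [0, 0, 0, 4, 1, 1],
        "calm": [2, 2.1, 1.9, 2, 4, 4],
    }, cell_lines=["A", "A", "A", "A", "B", "B"])
    out, report = filter_cv(m, 150)
    assert report.removed_feature_ids == ["wild"]
    assert report.removed.loc["wild", "statistic"] == pytest.approx(200.0)
    assert set(out.values.index) == {"flat", "calm"}


def test_cv_constant_matrix_removes_nothing():
    m = make_matrix({"a": [2, 2, 2, 2], "b": [7, 7, 7, 7]})
    _, report = filter_cv(m, 150)
    assert len(report.removed) == 0


def test_cv_zero_mean_group_counts_as_infinite():
    # a group with no signal at all (all zeros) is treated as infinite CV
    m = make_matrix({"z": [0, 0, 0, 1, 1, 1]},
                    cell_lines=["A", "A", "A", "B", "B", "B"])
    out, rep = filter_cv(m, 150)
    assert rep.removed_feature_ids == ["z"]
    assert np.isinf(rep.removed.loc["z", "statistic"])


# --------------------------------------------------------------------- #
# normalization and transforms
# --------------------------------------------------------------------- #

def test_median_scaling_hand_case():
    m = make_matrix({"f": [2, 4, 8]}, cell_lines=["A", "A", "B"])
    out = normalize_and_impute(m)
    assert list(out.values.loc["f"]) == [0.5, 1.0, 2.0]
    assert out.scale == "normalized"


def test_imputation_fills_row_minimum_and_keeps_mask():
    m = make_matrix({"f": [2, 4, np.nan, 8]})
    out = normalize_and_impute(m)
    # median of observed {2,4,8} = 4 -> scaled {0.5,1,2}; min = 0.5
    assert out.values.loc["f"].tolist() == [0.5, 1.0, 0.5, 2.0]
    assert out.missing_mask.loc["f"].tolist() == [False, False, True, False]


def test_normalization_identity_case():
    m = make_matrix({"f": [0.5, 1, 2], "g": [1, 1, 1]},
                    cell_lines=["A", "A", "B"])
    out = normalize_and_impute(m)
    assert np.allclose(out.values.to_numpy(), m.values.to_numpy())


def test_normalization_divides_by_sample_factor():
    m = make_matrix({"f": [2, 4, 8]}, factors=[2.0, 1.0, 1.0],
                    cell_lines=["A", "A", "B"])
    out = normalize_and_impute(m)
    # after factor division: {1,4,8}, median 4 -> {0.25,1,2}
    assert out.values.loc["f"].tolist() == [0.25, 1.0, 2.0]


def test_all_missing_feature_is_an_error():
    m = make_matrix({"f": [np.nan, np.nan, np.nan], "g": [1, 2, 3]})
    with pytest.raises(FeatureTableError, match="missing in all samples"):
        normalize_and_impute(m)


def test_tic_normalization_equalizes_within_mode_only():
    m = make_matrix(
        {"f": [2, 4, 10, 1], "g": [8, 16, 10, 3]},
        ion_modes=["positive", "positive", "negative", "negative"],
        cell_lines=["A", "A", "B", "B"],
    )
    out = tic_normalize(m)
    sums = out.values.sum(axis=0)
    assert sums["s1"] == pytest.approx(sums["s2"])
    assert sums["s3"] == pytest.approx(sums["s4"])
    # altering a negative-mode sample leaves positive-mode output unchanged
    m2 = make_matrix(
        {"f": [2, 4, 10, 99], "g": [8, 16, 10, 99]},
        ion_modes=["positive", "positive", "negative", "negative"],
        cell_lines=["A", "A", "B", "B"],
    )
    out2 = tic_normalize(m2)
    assert np.allclose(out.values[["s1", "s2"]].to_numpy(),
                       out2.values[["s1", "s2"]].to_numpy())


def test_tic_zero_signal_sample_raises():
    m = make_matrix({"f": [0, 4], "g": [0, 1]},
                    ion_modes=["positive", "positive"],
                    cell_lines=["A", "A"])
    with pytest.raises(FeatureTableError, match="s1"):
        tic_normalize(m)


def test_log2_exact_values_and_error_on_zero():
    m = make_matrix({"f": [8, 1, 2]}, scale="normalized")
    out = log2_transform(m)
    assert out.values.loc["f"].tolist() == [3.0, 0.0, 1.0]
    assert out.scale == "log2"
    bad = make_matrix({"f": [0, 1, 2]}, scale="normalized")
    with pytest.raises(FeatureTableError, match="non-positive"):
        log2_transform(bad)


# --------------------------------------------------------------------- #
# ion-mode merging
# --------------------------------------------------------------------- #

def _mode_matrix(mode, rows):
    n = 4
    ids = [r[0] for r in rows]
    m = make_matrix(
        {fid: vals for fid, _, _, vals, *_ in rows},
        scale="log2", ion_modes=[mode] * n,
        cell_lines=["A", "A", "B", "B"],
        feature_meta={
            fid: {"display_name": name, "adduct": adduct,
                  "ms_level_identified": (rest[0] if rest else 2)}
            for fid, name, adduct, vals, *rest in rows
        },
    )
    return m


def test_merge_prefers_negative_and_highest_abundance_and_na_rules():
    pos = _mode_matrix("positive", [
        ("p1", "SM(d18:1/24:1)", "[M+H]+", [5, 5, 5, 5]),
        ("p2", "PC(16:0_18:1)", "[M+H]+", [10, 10, 10, 10]),
        ("p3", "PC(16:0_18:1)", "[M+NH4]+", [12, 12, 12, 12]),
        ("p4", "TG(54:2)", "[M+Na]+", [8, 8, 8, 8]),
        ("p5", "DG(36:1)", "[M+Na]+", [9, 9, 9, 9]),
        ("p6", "DG(36:1)", "[M+H]+", [4, 4, 4, 4]),
        ("p7", "unconfirmed", "[M+H]+", [3, 3, 3, 3], 1),
    ])
    neg = _mode_matrix("negative", [
        ("n1", "SM(d18:1/24:1)", "[M-H]-", [6, 6, 6, 6]),
        ("n2", "PE(34:1)", "[M-H]-", [7, 7, 7, 7]),
    ])
    merged = merge_ion_modes(pos, neg)
    feats = merged.features
    # negative adduct preferred over positive for the shared sphingomyelin
    assert feats.loc["SM(d18:1/24:1)", "source_feature_id"] == "n1"
    # duplicate identification within a mode -> highest mean abundance
    assert feats.loc["PC(16:0_18:1)", "source_feature_id"] == "p3"
    # sodium kept only as last resort
    assert feats.loc["TG(54:2)", "source_feature_id"] == "p4"
    assert feats.loc["DG(36:1)", "source_feature_id"] == "p6"
    # MS1-only identifications dropped; output identifications unique
    assert "unconfirmed" not in feats.index
    assert feats.index.is_unique
    # provenance: each output row traces to exactly one input row
    assert feats["source_feature_id"].is_unique


def test_merge_requires_alignable_samples():
    pos = _mode_matrix("positive", [("p1", "X", "[M+H]+", [1, 2, 3, 4])])
    neg = _mode_matrix("negative", [("n1", "X", "[M-H]-", [1, 2, 3, 4])])
    neg.samples.loc["s4", "replicate"] = 9
    with pytest.raises(FeatureTableError, match="not alignable"):
        merge_ion_modes(pos, neg)


def test_impute_minimum_standalone():
    m = make_matrix({"f": [3, np.nan, 6]}, scale="normalized")
    out = impute_minimum(m)
    assert out.values.loc["f"].tolist() == [3.0, 3.0, 6.0]
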