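import numpy as np
import pandas as pd
import pytest

from dysregdir import (
    PairedExpressionStudy,
    compute_differences,
    expression_filter,
    load_study,
    write_study,
)
from dysregdir.core import StudyValidationError


def test_round_trip(tmp_path, tiny_study):
    ep, mp = tmp_path / "expr.tsv", tmp_path / "meta.tsv"
    write_study(tiny_study, ep, mp)
    back = load_study(ep, mp)
    assert back.features == tiny_study.features
    assert back.subjects == tiny_study.subjects
    np.testing.assert_array_equal(back.tumor_signal, tiny_study.tumor_signal)
    np.testing.assert_array_equal(back.normal_signal, tiny_study.normal_signal)
    assert list(back.site) == list(tiny_study.site)
    pd.testing.assert_frame_equal(back.factors, tiny_study.factors,
                                  check_names=False)


def test_load_shape_and_factor_count(tmp_path, tiny_study):
    ep, mp = tmp_path / "e.tsv", tmp_path / "m.tsv"
    write_study(tiny_study, ep, mp)
    study = load_study(ep, mp)
    assert study.tumor_signal.shape == (2, 3)
    assert study.factor_names == ["F1"]


def test_load_mismatched_subjects(tmp_path, tiny_study):
    ep, mp = tmp_path / "e.tsv", tmp_path / "m.tsv"
    write_study(tiny_study, ep, mp)
    meta = pd.read_csv(mp, sep="\t", index_col=0)
    meta = meta.rename(index={"s3": "s4"})
    meta.to_csv(mp, sep="\t")
    with pytest.raises(StudyValidationError, match="s3|s4"):
        load_study(ep, mp)


def test_load_bad_factor_value(tmp_path, tiny_study):
    ep, mp = tmp_path / "e.tsv", tmp_path / "m.tsv"
    write_study(tiny_study, ep, mp)
    meta = pd.read_csv(mp, sep="\t", index_col=0)
    meta.loc["s1", "F1"] = 2
    meta.to_csv(mp, sep="\t")
    with pytest.raises(StudyValidationError, match="F1"):
        load_study(ep, mp)


def test_load_non_numeric_factor(tmp_path, tiny_study):
    ep, mp = tmp_path / "e.tsv", tmp_path / "m.tsv"
    write_study(tiny_study, ep, mp)
    meta = pd.read_csv(mp, sep="\t", index_col=0)
    meta["F1"] = meta["F1"].astype(object)
    meta.loc["s1", "F1"] = "x"
    meta.to_csv(mp, sep="\t")
    with pytest.raises(StudyValidationError, match="non-numeric"):
        load_study(ep, mp)


def test_load_unknown_site(tmp_path, tiny_study):
    ep, mp = tmp_path / "e.tsv", tmp_path / "m.tsv"
    write_study(tiny_study, ep, mp)
    meta = pd.read_csv(mp, sep="\t", index_col=0)
    meta.loc["s1", "site"] = "elbow"
    meta.to_csv(mp, sep="\t")
    with pytest.raises(StudyValidationError, match="elbow"):
        load_study(ep, mp)


def test_negative_signal_rejected(tiny_study):
    with pytest.raises(StudyValidationError, match="negative"):
        tiny_study.with_signals(-tiny_study.tumor_signal, tiny_study.normal_signal)


def test_differences_log2p1_example(tiny_study):
    dm = compute_differences(tiny_study, "proximal", transform="log2p1")
    # tumor=8, normal=2 -> log2(9) - log2(3)
    assert dm.diffs[0, 0] == pytest.approx(np.log2(9) - np.log2(3))
    assert dm.diffs[0, 0] == pytest.approx(1.585, abs=1e-3)


def test_differences_zero_pair_is_exact_zero(tiny_study):
    for transform in ("identity", "log2p1"):
        dm = compute_differences(tiny_study, "proximal", transform=transform)
        assert dm.diffs[0, 1] == 0.0  # tumor=normal=0


def test_differences_identical_signals(tiny_study):
    dm = compute_differences(tiny_study, "distal", transform="identity")
    assert dm.diffs[0, 0] == 0.0  # tumor=normal=5


def test_differences_empty_site(tiny_study):
    with pytest.raises(StudyValidationError):
        compute_differences(tiny_study, "rectal")


def test_differences_unknown_transform(tiny_study):
    with pytest.raises(ValueError):
        compute_differences(tiny_study, "proximal", transform="sqrt")


def test_differences_antisymmetric(rng):
    tumor = rng.gamma(2.0, 10.0, (5, 8))
    normal = rng.gamma(2.0, 10.0, (5, 8))
    study = PairedExpressionStudy(
        features=[f"f{i}" for i in range(5)],
        subjects=[f"s{j}" for j in range(8)],
        tumor_signal=tumor, normal_signal=normal,
        site=np.array(["rectal"] * 8, dtype=object),
        factors=pd.DataFrame(index=[f"s{j}" for j in range(8)]),
    )
    swapped = study.with_signals(normal, tumor)
    for transform in ("identity", "log2p1"):
        d1 = compute_differences(study, "rectal", transform=transform).diffs
        d2 = compute_differences(swapped, "rectal", transform=transform).diffs
        np.testing.assert_allclose(d1, -d2, atol=1e-12)


def test_zero_count_matches_joint_zero_pairs(rng):
    tumor = rng.gamma(2.0, 10.0, (6, 20))
    normal = rng.gamma(2.0, 10.0, (6, 20))
    both_zero = rng.random((6, 20)) < 0.3
    tumor[both_zero] = 0.0
    normal[both_zero] = 0.0
    study = PairedExpressionStudy(
        features=[f"f{i}" for i in range(6)],
        subjects=[f"s{j}" for j in range(20)],
        tumor_signal=tumor, normal_signal=normal,
        site=np.array(["distal"] * 20, dtype=object),
        factors=pd.DataFrame(index=[f"s{j}" for j in range(20)]),
    )
    for transform in ("identity", "log2p1"):
        d = compute_differences(study, "distal", transform=transform).diffs
        assert (d == 0).sum() == both_zero.sum()


def test_expression_filter_thresholds():
    tumor = np.zeros((2, 10))
    normal = np.zeros((2, 10))
    tumor[0, :3] = 1.0   # nonzero in 3/10
    normal[1, :5] = 1.0  # nonzero in 5/10
    study = PairedExpressionStudy(
        features=["low", "mid"],
        subjects=[f"s{j}" for j in range(10)],
        tumor_signal=tumor, normal_signal=normal,
        site=np.array(["proximal"] * 10, dtype=object),
        factors=pd.DataFrame(index=[f"s{j}" for j in range(10)]),
    )
    assert expression_filter(study, 0.0) == ["low", "mid"]
    assert expression_filter(study, 0.5) == ["mid"]  # 0.5 boundary inclusive
    with pytest.raises(ValueError):
        expression_filter(study, 1.5)
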