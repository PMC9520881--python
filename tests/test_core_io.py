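"""Data model, CSV IO, and inclusion rules."""

import numpy as np
import pandas as pd
import pytest

from sclpipe.core_io import (
    MISSING,
    ColumnSchema,
    GroupedDataset,
    apply_completeness_filter,
    load_grouped_responses,
    validate_item_set,
)

LABELS = ["rarely or never", "about every month", "about every week",
          "more than once a week", "about every day"]
CAT_MAP = {lab: i for i, lab in enumerate(LABELS)}


def _write_csv(tmp_path, df, name="data.csv"):
    path = tmp_path / name
    df.to_csv(path, index=False)
    return path


def test_label_recoding_and_roundtrip(tmp_path):
    rng = np.random.default_rng(0)
    codes = rng.integers(0, 5, size=(20, 3))
    df = pd.DataFrame({f"it{j}": [LABELS[c] for c in codes[:, j]] for j in range(3)})
    df.insert(0, "group", ["A"] * 10 + ["B"] * 10)
    path = _write_csv(tmp_path, df)
    ds = load_grouped_responses(path, ColumnSchema(item_cols=["it0", "it1", "it2"],
                                                   category_map=CAT_MAP))
    assert np.array_equal(ds.responses, codes)
    assert ds.category_labels[0] == "rarely or never"
    # numeric round trip: write then read reproduces everything
    out = tmp_path / "roundtrip.csv"
    ds.to_csv(out)
    ds2 = load_grouped_responses(out, ColumnSchema(item_cols=ds.item_names))
    assert np.array_equal(ds.responses, ds2.responses)
    assert np.array_equal(ds.group, ds2.group)


def test_zero_matrix_identity(tmp_path):
    df = pd.DataFrame(np.zeros((3, 8), dtype=int),
                      columns=[f"i{j}" for j in range(8)])
    df.insert(0, "group", "G")
    ds = load_grouped_responses(_write_csv(tmp_path, df))
    assert ds.responses.shape == (3, 8)
    assert (ds.responses == 0).all()


@pytest.mark.parametrize("case", ["empty", "non_integer", "bad_group", "out_of_range"])
def test_loader_errors(tmp_path, case):
    if case == "empty":
        path = tmp_path / "empty.csv"
        path.write_text("group,i1\n")
        with pytest.raises(ValueError, match="no records"):
            load_grouped_responses(path)
    elif case == "non_integer":
        df = pd.DataFrame({"group": ["A"], "i1": ["sometimes"]})
        with pytest.raises(ValueError, match="non-integer.*i1"):
            load_grouped_responses(_write_csv(tmp_path, df))
    elif case == "bad_group":
        df = pd.DataFrame({"country": ["A"], "i1": [0]})
        with pytest.raises(ValueError, match="group column"):
            load_grouped_responses(_write_csv(tmp_path, df))
    else:
        df = pd.DataFrame({"group": ["A"], "i1": [7]})
        with pytest.raises(ValueError, match="out-of-range"):
            load_grouped_responses(_write_csv(tmp_path, df),
                                   ColumnSchema(n_categories=5))


def _dataset(responses, groups=None, weights=None):
    responses = np.asarray(responses)
    n = responses.shape[0]
    return GroupedDataset(
        responses=responses,
        item_names=[f"i{j}" for j in range(responses.shape[1])],
        group=np.asarray(groups if groups is not None else ["G"] * n),
        weights=weights,
    )


def test_completeness_filter_counts_and_idempotence():
    rng = np.random.default_rng(3)
    x = rng.integers(0, 5, size=(100, 4))
    x[:4, 2] = MISSING
    ds = _dataset(x)
    filtered, report = apply_completeness_filter(ds)
    assert filtered.n_persons == 96
    assert report.exclusion_percentage("G") == pytest.approx(4.0)
    again, rep2 = apply_completeness_filter(filtered)
    assert again.n_persons == 96 and rep2.exclusion_percentage("G") == 0.0


def test_completeness_filter_no_missing_identity():
    x = np.ones((10, 3), dtype=int)
    filtered, report = apply_completeness_filter(_dataset(x))
    assert np.array_equal(filtered.responses, x)
    assert not report.excluded_groups


def test_completeness_filter_drops_empty_group():
    x = np.ones((25, 4), dtype=int)
    x[:, 3] = MISSING
    filtered, report = apply_completeness_filter(_dataset(x))
    assert filtered.n_persons == 0
    assert "G" in report.excluded_groups


def test_validate_item_set_rules():
    x = np.ones((40, 3), dtype=int)
    groups = np.array(["A"] * 20 + ["B"] * 20)
    x[20:, 2] = MISSING                      # item never administered in B
    x[:10, 1] = MISSING                      # 50% nonresponse in A: retained
    report = validate_item_set(_dataset(x, groups), ["i0", "i1", "i2"])
    assert "B" in report.excluded_groups
    assert "i2" in report.excluded_groups["B"]
    assert report.after["A"] == 20           # nonresponse is not exclusion
    clean = validate_item_set(_dataset(np.ones((10, 3), dtype=int)), ["i0"])
    assert not clean.excluded_groups
    with pytest.raises(ValueError):
        validate_item_set(_dataset(x, groups), [])


def test_dataset_invariants():
    with pytest.raises(ValueError):
        GroupedDataset(responses=np.array([[0, 6]]), item_names=["a", "b"],
                       group=np.array(["G"]), n_categories=5)
    with pytest.raises(ValueError):
        GroupedDataset(responses=np.array([[0, 1]]), item_names=["a", "b"],
                       group=np.array(["G"]), weights=np.array([-1.0]))
    ds = _dataset([[0, 4], [1, 2]], weights=np.array([2.0, 1.0]))
    assert ds.n_categories == 5
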