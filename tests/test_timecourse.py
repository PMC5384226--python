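import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ufba.errors import DataError
from ufba.timecourse import (
    MetabolicStateWindow,
    RateEstimate,
    TimeCourseDataset,
    apply_pool_splits,
    discretize_states,
    estimate_rates,
    impute_missing,
)

from conftest import linear_dataset, long_df


# ------------------------------------------------------------- ingestion


def test_from_csv_day_conversion(tmp_path):
    rows = [("x", "c", t, 0, 10.0 + t) for t in range(3)]
    path = tmp_path / "tc.csv"
    long_df(rows).to_csv(path, index=False)
    ds_h = TimeCourseDataset.from_csv(path, time_unit="h")
    ds_d = TimeCourseDataset.from_csv(path, time_unit="day")
    assert list(ds_h.times) == [0.0, 1.0, 2.0]
    assert list(ds_d.times) == [0.0, 24.0, 48.0]
    with pytest.raises(DataError, match="unknown time unit"):
        TimeCourseDataset.from_csv(path, time_unit="fortnight")


def test_from_csv_missing_column(tmp_path):
    path = tmp_path / "tc.csv"
    pd.DataFrame({"metabolite_id": ["x"], "time": [0.0]}).to_csv(path, index=False)
    with pytest.raises(DataError, match="missing columns"):
        TimeCourseDataset.from_csv(path)


def test_dataset_invariants():
    with pytest.raises(DataError, match="duplicate"):
        TimeCourseDataset(data=long_df([("x", "c", 0.0, 0, 1.0), ("x", "c", 0.0, 0, 2.0),
                                        ("x", "c", 1.0, 0, 2.0)]))
    with pytest.raises(DataError, match="negative time"):
        TimeCourseDataset(data=long_df([("x", "c", -1.0, 0, 1.0), ("x", "c", 1.0, 0, 1.0)]))
    with pytest.raises(DataError, match="non-finite"):
        TimeCourseDataset(data=long_df([("x", "c", 0.0, 0, np.inf), ("x", "c", 1.0, 0, 1.0)]))


def test_pool_splits():
    ds = linear_dataset({"pool": 1.0}, times=[0, 1, 2])
    out = apply_pool_splits(ds, {"pool": {"a": 0.25, "b": 0.75}})
    assert set(out.metabolites) == {"a", "b"}
    a = out.data[out.data["metabolite_id"] == "a"]["concentration"].to_numpy()
    b = out.data[out.data["metabolite_id"] == "b"]["concentration"].to_numpy()
    assert np.allclose(a / 0.25, b / 0.75)
    with pytest.raises(DataError, match="sum to"):
        apply_pool_splits(ds, {"pool": {"a": 0.5, "b": 0.6}})


# ------------------------------------------------------------ imputation


def _knn_oracle(wide: pd.DataFrame, k: int) -> pd.DataFrame:
    """Direct distance-weighted kNN, written independently of sklearn."""
    X = wide.to_numpy()
    out = X.copy()
    for i in range(X.shape[0]):
        for j in range(X.shape[1]):
            if not np.isnan(X[i, j]):
                continue
            dists = []
            for other in range(X.shape[0]):
                if other == i or np.isnan(X[other, j]):
                    continue
                both = ~np.isnan(X[i]) & ~np.isnan(X[other])
                if not both.any():
                    continue
                # sklearn's nan-euclidean rescales by column count
                d = np.sqrt(np.sum((X[i, both] - X[other, both]) ** 2)
                            * X.shape[1] / both.sum())
                dists.append((d, X[other, j]))
            dists.sort(key=lambda p: p[0])
            near = dists[:k]
            if any(d == 0 for d, _ in near):
                vals = [v for d, v in near if d == 0]
                out[i, j] = np.mean(vals)
            else:
                w = np.array([1.0 / d for d, _ in near])
                out[i, j] = np.sum(w * [v for _, v in near]) / w.sum()
    return pd.DataFrame(out, index=wide.index, columns=wide.columns)


def test_impute_matches_direct_knn():
    rng = np.random.default_rng(5)
    rows = []
    for m in range(8):
        for t in range(6):
            rows.append((f"m{m}", "c", float(t), 0, float(rng.uniform(1, 20))))
    df = long_df(rows)
    holes = rng.choice(len(df), size=6, replace=False)
    df.loc[holes, "concentration"] = np.nan
    ds = TimeCourseDataset(data=df)
    filled = impute_missing(ds, k=3)
    expected = _knn_oracle(ds.wide(), k=3)
    got = filled.wide()
    assert np.allclose(got.to_numpy(), expected.loc[got.index, got.columns].to_numpy())
    # non-missing entries untouched
    obs = ~df["concentration"].isna()
    assert np.array_equal(filled.data.loc[obs, "concentration"], df.loc[obs, "concentration"])


def test_impute_errors():
    ds = linear_dataset({"a": 1.0, "b": 2.0}, times=[0, 1, 2])
    with pytest.raises(DataError, match="k must be"):
        impute_missing(ds, k=0)
    df = ds.data.copy()
    df.loc[df["metabolite_id"] == "a", "concentration"] = np.nan
    with pytest.raises(DataError, match="zero non-missing"):
        impute_missing(TimeCourseDataset(data=df))


def test_impute_noop_without_missing():
    ds = linear_dataset({"a": 1.0}, times=[0, 1, 2])
    assert impute_missing(ds) is ds


# --------------------------------------------------------- discretization


def test_discretize_flat_data_single_window():
    ds = linear_dataset({"a": 0.0, "b": 0.0})
    windows = discretize_states(ds)
    assert len(windows) == 1
    assert windows[0].times == tuple(np.arange(10.0))


def test_discretize_noiseless_two_state_exact_boundary():
    times = np.arange(20.0)
    rows = []
    for t in times:
        y = 10.0 + t if t < 10 else 20.0 - (t - 10.0)
        rows.append(("a", "c", float(t), 0, y))
        rows.append(("b", "c", float(t), 0, 2 * y))
    ds = TimeCourseDataset(data=long_df(rows))
    windows = discretize_states(ds)
    assert len(windows) == 2
    assert windows[1].t_start in (9.0, 10.0)


def test_discretize_pinned_state_count_and_limits():
    ds = linear_dataset({"a": 1.0})
    assert len(discretize_states(ds, n_states=2)) == 2
    with pytest.raises(DataError, match="cannot support"):
        discretize_states(ds, n_states=4)
    few = linear_dataset({"a": 1.0}, times=[0, 1])
    with pytest.raises(DataError, match="at least 3"):
        discretize_states(few)


def test_discretize_requires_imputed_data():
    df = linear_dataset({"a": 1.0, "b": 2.0}).data
    df.loc[(df["metabolite_id"] == "a") & (df["time"] == 3.0), "concentration"] = np.nan
    with pytest.raises(DataError, match="impute"):
        discretize_states(TimeCourseDataset(data=df))


def test_discretize_translation_invariance():
    base = linear_dataset({"a": 1.0, "b": -0.5}, noise=0.1, seed=3)
    shifted = base.data.copy()
    shifted["time"] += 7.0
    w0 = discretize_states(base)
    w1 = discretize_states(TimeCourseDataset(data=shifted))
    assert [len(w.times) for w in w0] == [len(w.times) for w in w1]


def test_windows_partition_time_axis():
    sc_times = np.arange(20.0)
    rows = [("a", "c", float(t), 0, (10 + t if t < 10 else 20 - (t - 10)) + 0.01 * (t % 3))
            for t in sc_times]
    ds = TimeCourseDataset(data=long_df(rows))
    windows = discretize_states(ds)
    covered = [t for w in windows for t in w.times]
    assert covered == sorted(sc_times)
    assert all(len(w.times) >= 3 for w in windows)
    assert [w.index for w in windows] == list(range(1, len(windows) + 1))


# ------------------------------------------------------- rate estimation


def test_noiseless_rates_exact():
    ds = linear_dataset({"up": 0.7, "down": -1.2, "flat": 0.0})
    window = discretize_states(ds)[0]
    rates = {r.metabolite_id: r for r in estimate_rates(ds, window)}
    assert rates["up"].slope == pytest.approx(0.7)
    assert rates["up"].b1 == pytest.approx(0.7, abs=1e-9)
    assert rates["up"].significant
    assert rates["down"].slope == pytest.approx(-1.2)
    assert rates["down"].significant
    assert not rates["flat"].significant


def test_rates_match_linregress():
    ds = linear_dataset({"x": 0.5}, noise=0.4, replicates=3, seed=9)
    window = discretize_states(ds)[0]
    est = estimate_rates(ds, window)[0]
    sub = ds.data
    ref = stats.linregress(sub["time"], sub["concentration"])
    half = stats.t.ppf(0.975, len(sub) - 2) * ref.stderr
    assert est.slope == pytest.approx(ref.slope)
    assert est.b1 == pytest.approx(ref.slope - half)
    assert est.b2 == pytest.approx(ref.slope + half)


def test_rates_alpha_widens_interval():
    ds = linear_dataset({"x": 0.5}, noise=0.4, seed=2)
    window = discretize_states(ds)[0]
    narrow = estimate_rates(ds, window, alpha=0.32)[0]
    wide = estimate_rates(ds, window, alpha=0.01)[0]
    assert wide.b2 - wide.b1 > narrow.b2 - narrow.b1
    with pytest.raises(DataError, match="alpha"):
        estimate_rates(ds, window, alpha=1.5)


def test_rates_errors():
    ds = linear_dataset({"x": 1.0}, times=[0, 1, 2])
    window = MetabolicStateWindow(index=1, t_start=0, t_end=2, times=(0.0, 1.0, 2.0))
    df = ds.data.copy()
    df.loc[2, "concentration"] = np.nan
    with pytest.raises(DataError, match="fewer than 3"):
        estimate_rates(TimeCourseDataset(data=df), window)


def test_rate_estimate_invariant():
    with pytest.raises(DataError, match="outside CI"):
        RateEstimate(metabolite_id="x", state_index=1, slope=2.0, b1=0.0, b2=1.0,
                     significant=True)
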