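"""Cohort summaries, KS / chi-squared statistics, weekly tracks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ecogprop import chi2_association, ks_two_sample, percent_reduction, summarize_cohort
from ecogprop.cohort import ZeroMarginError, cluster_fraction_table, weekly_track


# ---------------------------------------------------------------------------
# percent reduction


def test_percent_reduction_examples():
    assert round(percent_reduction(52, 7)) == 87
    assert percent_reduction(41.6, 1.4) == pytest.approx(96.635, abs=0.01)
    assert percent_reduction(3.3, 3.3) == 0.0
    with pytest.raises(ValueError):
        percent_reduction(0.0, 1.0)


# ---------------------------------------------------------------------------
# Kolmogorov–Smirnov


def brute_ks(a, b):
    """Sup |ECDF_a - ECDF_b| over all pooled points, plus asymptotic p
    via the Kolmogorov distribution at the effective sample size."""
    a, b = np.sort(a), np.sort(b)
    xs = np.r_[a, b]
    Fa = np.searchsorted(a, xs, side="right") / len(a)
    Fb = np.searchsorted(b, xs, side="right") / len(b)
    D = float(np.abs(Fa - Fb).max())
    en = len(a) * len(b) / (len(a) + len(b))
    return D, float(sps.kstwo.sf(D, int(round(en))))


def test_ks_identical_samples():
    x = np.array([0.1, 0.4, 0.7])
    D, p = ks_two_sample(x, x)
    assert D == 0.0 and p == pytest.approx(1.0)


def test_ks_disjoint_supports():
    D, _ = ks_two_sample([1.0, 2.0, 3.0], [10.0, 11.0])
    assert D == 1.0


def test_ks_worked_example_third():
    D, p = ks_two_sample([1, 2, 3], [1.5, 2.5, 3.5])
    bD, bp = brute_ks(np.array([1.0, 2, 3]), np.array([1.5, 2.5, 3.5]))
    assert D == pytest.approx(1 / 3, abs=1e-12)
    assert D == pytest.approx(bD, abs=1e-12)
    assert p == pytest.approx(bp, abs=1e-6)


def test_ks_matches_bruteforce_on_random_instances():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        a = rng.normal(size=rng.integers(3, 15))
        b = rng.normal(rng.uniform(0, 1), size=rng.integers(3, 15))
        D, p = ks_two_sample(a, b)
        bD, bp = brute_ks(a, b)
        assert D == pytest.approx(bD, abs=1e-9)
        assert p == pytest.approx(bp, abs=1e-6)


def test_ks_empty_sample_raises():
    with pytest.raises(ValueError):
        ks_two_sample([], [1.0])


# ---------------------------------------------------------------------------
# chi-squared association


def brute_chi2(T):
    T = np.asarray(T, dtype=float)
    n = T.sum()
    rows, cols = T.sum(axis=1), T.sum(axis=0)
    x2 = 0.0
    for i in range(T.shape[0]):
        for j in range(T.shape[1]):
            e = rows[i] * cols[j] / n
            x2 += (T[i, j] - e) ** 2 / e
    dof = (T.shape[0] - 1) * (T.shape[1] - 1)
    return x2, dof, float(sps.chi2.sf(x2, dof))


def test_chi2_identical_rows_is_zero():
    x2, dof, p = chi2_association([[10, 20, 30], [10, 20, 30]])
    assert x2 == pytest.approx(0.0, abs=1e-12)
    assert dof == 2
    assert p == pytest.approx(1.0)


def test_chi2_worked_table_against_oracle():
    T = [[160, 14, 26], [10, 120, 70]]
    x2, dof, p = chi2_association(T)
    bx2, bdof, bp = brute_chi2(T)
    assert x2 == pytest.approx(bx2, abs=1e-9)
    assert dof == bdof == 2
    assert p == pytest.approx(bp, abs=1e-6)


def test_chi2_matches_bruteforce_on_random_instances():
    rng = np.random.default_rng(1)
    for _ in range(1000):
        shape = (rng.integers(2, 4), rng.integers(2, 5))
        T = rng.integers(1, 50, size=shape)
        x2, dof, p = chi2_association(T)
        bx2, bdof, bp = brute_chi2(T)
        assert x2 == pytest.approx(bx2, abs=1e-9)
        assert dof == bdof
        assert p == pytest.approx(bp, abs=1e-6)


def test_chi2_zero_margin_raises():
    with pytest.raises(ZeroMarginError):
        chi2_association([[0, 5], [0, 3]])


# ---------------------------------------------------------------------------
# summaries


def _toy_events():
    rows = []
    eid = 0
    # animal a: 2 weeks; animal b: 1 week, different group
    layout = [
        ("a", "epilepsy_control", 0, [("seizure", "propagated")] * 8 + [("seizure", "attenuated")] * 2),
        ("a", "epilepsy_control", 1, [("seizure", "propagated")] * 3 + [("seizure", "nonpropagated")] * 1
         + [("polyspike", "propagated")] * 5),
        ("b", "epilepsy_laser_cut_single", 0, [("seizure", "nonpropagated")] * 9
         + [("seizure", "propagated")] * 1 + [("interictal_spike", "attenuated")] * 4),
    ]
    for animal, group, week, evs in layout:
        for etype, lab in evs:
            rows.append(
                {"event_id": eid, "animal_id": animal, "group": group, "week": week,
                 "type": etype, "cluster_label": lab}
            )
            eid += 1
    return pd.DataFrame(rows)


def test_daily_summary_counts_and_percentages():
    out = summarize_cohort(_toy_events(), session_days=1.0)
    daily = out["daily"].set_index(["animal_id", "week"])
    assert daily.loc[("a", 0), "n_seizure"] == 10
    assert daily.loc[("a", 0), "percent_propagated"] == pytest.approx(80.0)
    assert daily.loc[("a", 1), "percent_propagated"] == pytest.approx(75.0)
    assert daily.loc[("b", 0), "percent_propagated"] == pytest.approx(10.0)
    assert daily.loc[("b", 0), "propagated_per_day"] == 1.0


def test_per_animal_averages_session_percentages():
    out = summarize_cohort(_toy_events())
    pa = out["per_animal"].set_index("animal_id")
    # mean of 80% and 75%, not the pooled 11/14
    assert pa.loc["a", "percent_propagated"] == pytest.approx(77.5)


def test_count_conservation():
    ev = _toy_events()
    daily = summarize_cohort(ev)["daily"]
    for etype in ("seizure", "polyspike", "interictal_spike"):
        assert daily[f"n_{etype}"].sum() == (ev["type"] == etype).sum()


def test_cluster_fraction_rows_sum_to_100():
    cf = cluster_fraction_table(_toy_events())
    pct = cf[["pct_propagated", "pct_attenuated", "pct_nonpropagated"]].sum(axis=1)
    assert np.allclose(pct, 100.0)


def test_empty_input_gives_empty_summaries():
    out = summarize_cohort(pd.DataFrame())
    assert all(len(v) == 0 for v in out.values())


# ---------------------------------------------------------------------------
# weekly tracks


def _week_profiles(counts, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for week, n in enumerate(counts):
        for _ in range(n):
            rows.append(
                {"week": week, "r_1mm": rng.normal(0.7, 0.05), "r_2mm": rng.normal(0.6, 0.05)}
            )
    return pd.DataFrame(rows)


def test_sparse_week_excluded():
    pts = weekly_track(_week_profiles([9, 10, 25]), min_seizures=10)
    assert [p.included for p in pts] == [False, True, True]
    assert [p.week for p in pts] == [0, 1, 2]


def test_single_week_track():
    pts = weekly_track(_week_profiles([12]))
    assert len(pts) == 1 and pts[0].included
    assert pts[0].n_seizures == 12


def test_stationary_weeks_have_stable_centroids():
    """Six weeks drawn from one distribution: centroids agree within
    sampling error of the common mean."""
    pts = weekly_track(_week_profiles([60] * 6, seed=3))
    meds = np.array([[p.median_r1, p.median_r2] for p in pts])
    spread = np.linalg.norm(meds - meds.mean(axis=0), axis=1)
    assert spread.max() < 3 * 0.05 / np.sqrt(60) * 2  # ~3 SE with slack
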