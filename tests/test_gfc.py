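"""gFC statistics, the change screen, FDR control, fixed-set validation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rsgfc.connectivity import ConnectivityMatrix
from rsgfc.gfc import (
    critical_t,
    delta_gfc,
    fdr_adjust,
    fixed_positive_set,
    gfc_change_screen,
    gfc_table,
    gfc_values,
    one_sample_t,
    restricted_delta_gfc,
    split_sessions,
    t_from_summary,
)
from rsgfc.pipeline import connectivity_from_dataset
from rsgfc.synthetic import generate_dataset

from conftest import random_connectivity


def conn_from_z(z, subject="s1", session="rest1"):
    z = np.asarray(z, dtype=float)
    np.fill_diagonal(z, np.nan)
    ids = [f"p{i:03d}" for i in range(z.shape[0])]
    return ConnectivityMatrix(z=z, parcel_ids=ids, subject=subject, session=session)


class TestGfcValues:
    def test_three_parcel_arithmetic(self):
        z = np.array([[0.0, 0.5, -0.2], [0.5, 0.0, 0.1], [-0.2, 0.1, 0.0]])
        df = gfc_values(conn_from_z(z)).set_index("parcel")
        row = df.loc["p000"]
        assert row["gfc"] == pytest.approx(0.3)
        assert row["gfc_pos"] == pytest.approx(0.5)
        assert row["gfc_neg"] == pytest.approx(-0.2)

    def test_all_zero_matrix(self):
        df = gfc_values(conn_from_z(np.zeros((4, 4))))
        assert (df[["gfc", "gfc_pos", "gfc_neg"]].to_numpy() == 0).all()

    def test_matches_loop_oracle(self, rng):
        conn = random_connectivity(rng, n_parcels=20)
        df = gfc_values(conn)
        for k, pid in enumerate(conn.parcel_ids):
            tot = pos = neg = 0.0
            for j in range(20):
                if j == k:
                    continue
                v = conn.z[k, j]
                tot += v
                pos += v if v > 0 else 0.0
                neg += v if v < 0 else 0.0
            row = df[df["parcel"] == pid].iloc[0]
            assert row["gfc"] == pytest.approx(tot, abs=1e-12)
            assert row["gfc_pos"] == pytest.approx(pos, abs=1e-12)
            assert row["gfc_neg"] == pytest.approx(neg, abs=1e-12)

    def test_decomposition_exact(self, small_conns):
        table = gfc_table(small_conns)
        assert (table["gfc"] == table["gfc_pos"] + table["gfc_neg"]).all()


class TestDeltaGfc:
    def test_reported_session_means_difference(self):
        # session-mean gFC+ of one parcel: 53.70 -> 62.91 gives a 9.21 change
        assert 62.91 - 53.70 == pytest.approx(9.21, abs=1e-10)

    def test_identical_sessions_give_zero(self, small_conns):
        t1, _ = split_sessions(gfc_table(small_conns))
        d = delta_gfc(t1, t1.copy())
        assert np.allclose(d[["dgfc", "dgfc_pos", "dgfc_neg"]], 0.0)

    def test_session_swap_negates_deltas(self, small_conns):
        t1, t2 = split_sessions(gfc_table(small_conns))
        d = delta_gfc(t1, t2)
        d_swapped = delta_gfc(t2, t1)
        assert np.allclose(
            d[["dgfc", "dgfc_pos", "dgfc_neg"]],
            -d_swapped[["dgfc", "dgfc_pos", "dgfc_neg"]],
        )

    def test_mismatched_subjects_fail(self, small_conns):
        t1, t2 = split_sessions(gfc_table(small_conns))
        with pytest.raises(ValueError):
            delta_gfc(t1, t2[t2["subject"] != "sub-01"])


class TestOneSampleT:
    def test_reported_summaries(self):
        assert t_from_summary(9.21, 14.51, 44).t == pytest.approx(4.21, abs=0.005)
        assert t_from_summary(5.73, 9.79, 44).t == pytest.approx(3.88, abs=0.005)

    def test_zero_mean(self, rng):
        x = rng.normal(size=20)
        res = one_sample_t(x - x.mean())
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_scipy(self, rng):
        from scipy import stats

        x = rng.normal(0.3, 1.0, 25)
        res = one_sample_t(x)
        ref = stats.ttest_1samp(x, 0.0)
        assert res.t == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)
        assert res.df == 24

    def test_degenerate_sample_fails(self):
        with pytest.raises(ValueError):
            one_sample_t([2.0, 2.0, 2.0])


class TestCriticalT:
    @pytest.mark.parametrize(
        "df,alpha,expected,tol",
        [(43, 0.05, 2.017, 1e-3), (10**6, 0.05, 1.960, 1e-3), (1, 0.05, 12.706, 1e-3)],
    )
    def test_values(self, df, alpha, expected, tol):
        assert critical_t(df, alpha) == pytest.approx(expected, abs=tol)


def by_oracle(p, q):
    """Hand step-up: reject the largest k with p_(k) <= k*q/(m*c(m))."""
    p = np.asarray(p, float)
    m = p.size
    c = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p)
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / (m * c):
            k_max = rank
    reject = np.zeros(m, bool)
    reject[order[:k_max]] = True
    return reject


class TestFdr:
    def test_hand_executed_by_fixture(self):
        p = [0.001, 0.02, 0.04, 0.5]
        # c(4) = 25/12, thresholds 0.006, 0.012, 0.018, 0.024
        q_adj, reject = fdr_adjust(p, q=0.05, method="by")
        assert reject.tolist() == [True, False, False, False]
        assert np.array_equal(reject, by_oracle(p, 0.05))

    def test_all_zero_p_all_rejected(self):
        _, reject = fdr_adjust([0.0] * 5, q=0.05, method="by")
        assert reject.all()

    def test_single_p_reduces_to_plain_threshold(self):
        _, reject = fdr_adjust([0.049], q=0.05, method="by")
        assert reject.all()

    def test_adjusted_values_monotone_in_rank(self, rng):
        p = rng.uniform(size=50)
        for method in ("by", "bh"):
            q_adj, _ = fdr_adjust(p, method=method)
            order = np.argsort(p)
            assert (np.diff(q_adj[order]) >= -1e-12).all()

    @given(st.integers(0, 10_000))
    def test_by_matches_hand_oracle_and_is_subset_of_bh(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 40))
        p = rng.uniform(size=m) ** rng.uniform(0.5, 3)
        _, by = fdr_adjust(p, q=0.05, method="by")
        _, bh = fdr_adjust(p, q=0.05, method="bh")
        assert np.array_equal(by, by_oracle(p, 0.05))
        assert not np.any(by & ~bh)  # BY rejections are a subset of BH's


class TestScreen:
    def test_screen_matches_loop_oracle(self, small_conns):
        from scipy import stats

        deltas = delta_gfc(*split_sessions(gfc_table(small_conns)))
        table, _ = gfc_change_screen(deltas, q=0.05, method="by")
        for row in table.itertuples(index=False):
            vals = deltas[deltas["parcel"] == row.parcel][f"d{row.measure}"].to_numpy()
            t_ref, p_ref = stats.ttest_1samp(vals, 0.0)
            assert row.t == pytest.approx(t_ref, abs=1e-10)
            assert row.p == pytest.approx(p_ref, abs=1e-10)

    def test_two_parcel_degenerate_family_runs(self, rng):
        conns = []
        for s in range(6):
            for session in ("rest1", "rest2"):
                z = np.full((2, 2), rng.normal(0.3, 0.1))
                conns.append(conn_from_z(z, subject=f"s{s}", session=session))
        deltas = delta_gfc(*split_sessions(gfc_table(conns)))
        table, _ = gfc_change_screen(deltas)
        assert len(table) == 6  # 2 parcels x 3 measures
        # all-positive edges: the gfc_neg family is degenerate but not fatal
        neg = table[table["measure"] == "gfc_neg"]
        assert neg["t"].isna().all() and not neg["significant"].any()

    def test_session_label_permutation_destroys_detection(self, small_spec):
        """Sign-flipping subjects' deltas removes the planted-effect signal."""
        rng = np.random.default_rng(123)
        spec = dataclasses.replace(small_spec, n_subjects=12, delta_z=0.4)
        detections = 0
        reps = 20
        for rep in range(reps):
            ds = generate_dataset(dataclasses.replace(spec, rng_seed=rep))
            conns = connectivity_from_dataset(ds)
            # per-subject coin flip swaps both of the subject's session labels
            by_subj = {}
            for c in conns:
                by_subj.setdefault(c.subject, []).append(c)
            flipped = []
            for subj, pair in by_subj.items():
                swap = rng.random() < 0.5
                for c in pair:
                    session = ({"rest1": "rest2", "rest2": "rest1"}[c.session] if swap else c.session)
                    flipped.append(
                        ConnectivityMatrix(
                            z=c.z, parcel_ids=c.parcel_ids, subject=c.subject, session=session
                        )
                    )
            deltas = delta_gfc(*split_sessions(gfc_table(flipped)))
            _, detected = gfc_change_screen(deltas)
            seed_id = spec.parcel_ids[spec.seed_node]
            detections += (seed_id, "gfc_pos") in detected
        assert detections / reps <= 0.15


class TestFixedPositiveSet:
    def test_zero_mean_parcel_not_member(self, rng):
        conns = []
        for s in range(10):
            for session in ("rest1", "rest2"):
                z = np.zeros((3, 3))
                z[0, 1] = z[1, 0] = 0.5 + rng.normal(0, 0.01)
                z[0, 2] = z[2, 0] = rng.normal(0, 0.3)  # mean-zero edge
                z[1, 2] = z[2, 1] = 0.1
                conns.append(conn_from_z(z, subject=f"s{s}", session=session))
        fps = fixed_positive_set("p000", conns)
        assert "p001" in fps.members
        assert "p002" not in fps.members

    def test_community_members_recovered(self, small_spec):
        # parcels in the seed's community share r=0.4: near-certain members
        ds = generate_dataset(dataclasses.replace(small_spec, n_subjects=20))
        conns = connectivity_from_dataset(ds)
        fps = fixed_positive_set(small_spec.parcel_ids[small_spec.seed_node], conns)
        community = [
            pid
            for i, pid in enumerate(small_spec.parcel_ids)
            if i % small_spec.community_count == small_spec.seed_node % small_spec.community_count
            and i != small_spec.seed_node
        ]
        assert set(community) <= set(fps.members)

    def test_vacuous_alpha_admits_all_positive(self, small_conns, small_spec):
        seed_id = small_spec.parcel_ids[small_spec.seed_node]
        fps = fixed_positive_set(seed_id, small_conns, alpha=1.0)
        means = fps.stats.groupby("parcel")["mean_z"].min()
        all_pos = set(means[means > 0].index)
        assert set(fps.members) == all_pos


class TestRestrictedDelta:
    def test_reported_restricted_means(self):
        assert 33.11 - 27.37 == pytest.approx(5.74, abs=1e-10)
        assert abs((33.11 - 27.37) - 5.73) <= 0.02  # rounding of printed values

    def test_singleton_set_equals_edge_delta(self, small_conns, small_spec):
        seed_id = small_spec.parcel_ids[small_spec.seed_node]
        other = small_spec.parcel_ids[3]
        sums, res = restricted_delta_gfc(seed_id, [other], small_conns)
        by_key = {(c.subject, c.session): c for c in small_conns}
        s, o = small_spec.seed_node, 3
        for subject in sums.index:
            dz = by_key[(subject, "rest2")].z[s, o] - by_key[(subject, "rest1")].z[s, o]
            assert sums.loc[subject, "delta"] == pytest.approx(dz, abs=1e-12)

    def test_all_positive_members_equal_gfc_pos(self, rng):
        conns = []
        for s in range(5):
            for session in ("rest1", "rest2"):
                z = np.abs(rng.normal(0.3, 0.1, (4, 4)))
                z = (z + z.T) / 2
                conns.append(conn_from_z(z, subject=f"s{s}", session=session))
        members = ["p001", "p002", "p003"]
        sums, _ = restricted_delta_gfc("p000", members, conns)
        table = gfc_table(conns)
        seed_rows = table[table["parcel"] == "p000"]
        for row in seed_rows.itertuples(index=False):
            assert sums.loc[row.subject, row.session] == pytest.approx(
                row.gfc_pos, abs=1e-12
            )

    def test_empty_member_set_fails(self, small_conns):
        with pytest.raises(ValueError):
            restricted_delta_gfc("p000", [], small_conns)
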