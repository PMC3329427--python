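"""Turnover unit bookkeeping, matrix assembly and clustering."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet

from cleavekit import (
    AMINO_ACIDS,
    ArgumentError,
    SpentMediumSample,
    TurnoverMatrix,
    build_matrix,
    cluster_turnover,
    compute_turnover,
    profile_correlation,
    read_media_csv,
    simulate_spent_media,
    total_turnover,
)
from cleavekit.aaflux import linkage_to_newick


def make_sample(sample_id, conc, n_embryos=10, hours=17.5, volume=5.0,
                group="NT", window="0-24", control_id=None):
    return SpentMediumSample(
        sample_id=sample_id, group=group, stage_window=window,
        n_embryos=n_embryos, hours=hours, drop_volume=volume,
        concentrations=dict(conc), control_id=control_id,
    )


class TestComputeTurnover:
    def test_unit_bookkeeping_worked_example(self):
        control = make_sample("c", {"alanine": 100.0}, n_embryos=0)
        sample = make_sample("s", {"alanine": 90.0}, n_embryos=10, hours=17.5)
        rate = compute_turnover(sample, control)["alanine"]
        # (100-90) umol/L * 5 uL / (10 embryos * 17.5 h)
        assert rate == pytest.approx(10 * 5 / (10 * 17.5))
        assert rate == pytest.approx(0.2857, abs=1e-4)

    def test_sample_equal_to_control_gives_zero(self):
        control = make_sample("c", {"glycine": 120.0}, n_embryos=0)
        sample = make_sample("s", {"glycine": 120.0})
        assert compute_turnover(sample, control)["glycine"] == 0.0

    def test_release_is_negative(self):
        control = make_sample("c", {"glutamine": 100.0}, n_embryos=0)
        sample = make_sample("s", {"glutamine": 130.0})
        assert compute_turnover(sample, control)["glutamine"] < 0

    def test_linearity_and_volume_scaling(self):
        control = make_sample("c", {"serine": 100.0}, n_embryos=0)
        r1 = compute_turnover(make_sample("s", {"serine": 90.0}), control)["serine"]
        r2 = compute_turnover(make_sample("s", {"serine": 80.0}), control)["serine"]
        assert r2 == pytest.approx(2 * r1)
        big = make_sample("s", {"serine": 90.0}, volume=10.0)
        assert compute_turnover(big, control)["serine"] == pytest.approx(2 * r1)
        many = make_sample("s", {"serine": 90.0}, n_embryos=20)
        assert compute_turnover(many, control)["serine"] == pytest.approx(r1 / 2)

    def test_dilution_correction(self):
        control = make_sample("c", {"valine": 8.0}, n_embryos=0)
        sample = make_sample("s", {"valine": 7.2})
        raw = compute_turnover(sample, control)["valine"]
        corrected = compute_turnover(sample, control, dilution=12.5)["valine"]
        assert corrected == pytest.approx(12.5 * raw)

    def test_missing_amino_acid_in_control_named(self):
        control = make_sample("c", {"alanine": 100.0}, n_embryos=0)
        sample = make_sample("s", {"alanine": 90.0, "leucine": 50.0})
        with pytest.raises(ArgumentError, match="leucine"):
            compute_turnover(sample, control)

    def test_control_as_sample_rejected(self):
        control = make_sample("c", {"alanine": 100.0}, n_embryos=0)
        with pytest.raises(ArgumentError, match="n_embryos"):
            compute_turnover(control, control)

    def test_stage_mismatch_rejected(self):
        control = make_sample("c", {"alanine": 100.0}, n_embryos=0, window="24-48")
        sample = make_sample("s", {"alanine": 90.0}, window="0-24")
        with pytest.raises(ArgumentError, match="stage window"):
            compute_turnover(sample, control)


class TestTotalTurnover:
    @pytest.mark.parametrize(
        "rates,expected",
        [({"a": 0.2, "b": -0.3}, 0.5), ({"a": 0.0, "b": 0.0}, 0.0),
         ({"a": -1.2}, 1.2)],
    )
    def test_sum_of_absolute_rates(self, rates, expected):
        assert total_turnover(rates) == pytest.approx(expected)

    def test_empty_mapping_rejected(self):
        with pytest.raises(ArgumentError):
            total_turnover({})


class TestBuildMatrix:
    def _replicates(self, concs, group="NT", window="0-24"):
        samples, controls = [], []
        for i, c in enumerate(concs):
            cid = f"ctrl{i}"
            controls.append(make_sample(cid, {"alanine": 100.0}, n_embryos=0,
                                        group=group, window=window))
            samples.append(make_sample(f"s{i}", {"alanine": c}, group=group,
                                       window=window, control_id=cid))
        return samples, controls

    def test_identical_replicates_zero_sem(self):
        samples, controls = self._replicates([90.0, 90.0, 90.0])
        m = build_matrix(samples, controls)
        assert m.values.iloc[0, 0] == pytest.approx(0.2857, abs=1e-4)
        assert m.sem.iloc[0, 0] == 0.0
        assert m.n.iloc[0, 0] == 3

    def test_sem_hand_computed(self):
        # rates 0.2, 0.3, 0.4 -> mean 0.3, SEM = sd/sqrt(3) = 0.0577
        concs = [100.0 - r * 10 * 17.5 / 5 for r in (0.2, 0.3, 0.4)]
        samples, controls = self._replicates(concs)
        m = build_matrix(samples, controls)
        assert m.values.iloc[0, 0] == pytest.approx(0.3)
        assert m.sem.iloc[0, 0] == pytest.approx(0.1 / math.sqrt(3), abs=1e-4)

    def test_missing_stage_column_absent_with_warning(self, caplog):
        samples, controls = self._replicates([90.0, 92.0])
        with caplog.at_level("WARNING"):
            m = build_matrix(samples, controls)
        assert list(m.values.columns) == [("NT", "0-24")]
        assert any("stage window" in r.message for r in caplog.records)

    def test_unmatched_control_rejected(self):
        samples, controls = self._replicates([90.0])
        samples[0].control_id = "nope"
        with pytest.raises(ArgumentError, match="unmatched control"):
            build_matrix(samples, controls)


def lance_williams_trace(dist, method, sizes=None):
    """Agglomerative clustering by the Lance-Williams recurrence.

    Independent of scipy: returns [(members_a, members_b, height)] merge
    steps.  Supports 'complete' and the Ward criterion on Euclidean
    distances.
    """
    clusters = {i: frozenset([i]) for i in range(len(dist))}
    d = {
        frozenset((i, j)): float(dist[i][j])
        for i in range(len(dist))
        for j in range(i + 1, len(dist))
    }
    size = {i: 1 for i in clusters}
    trace = []
    next_id = len(dist)
    while len(clusters) > 1:
        pair, h = min(d.items(), key=lambda kv: kv[1])
        i, j = sorted(pair)
        trace.append((clusters[i], clusters[j], h))
        new = next_id
        next_id += 1
        for k in list(clusters):
            if k in (i, j):
                continue
            dik, djk = d[frozenset((i, k))], d[frozenset((j, k))]
            if method == "complete":
                dnew = max(dik, djk)
            else:  # ward on Euclidean distances
                ni, nj, nk = size[i], size[j], size[k]
                dnew = math.sqrt(
                    ((ni + nk) * dik**2 + (nj + nk) * djk**2 - nk * h**2)
                    / (ni + nj + nk)
                )
            d[frozenset((new, k))] = dnew
        d = {key: v for key, v in d.items() if i not in key and j not in key}
        clusters[new] = clusters[i] | clusters[j]
        size[new] = size[i] + size[j]
        del clusters[i], clusters[j], size[i], size[j]
    return trace


def scipy_trace(linkage, n):
    """Convert a scipy linkage matrix to the same member-set trace."""
    members = {i: frozenset([i]) for i in range(n)}
    trace = []
    for row_idx, (a, b, h, _) in enumerate(linkage):
        sa, sb = members[int(a)], members[int(b)]
        trace.append((sa, sb, float(h)))
        members[n + row_idx] = sa | sb
    return trace


class TestClustering:
    def _matrix(self, values, rows=None, cols=None):
        rows = rows or [f"aa{i}" for i in range(len(values))]
        cols = cols or [("NT", w) for w in ("0-24", "24-48", "48-72", "72-96")][
            : len(values[0])
        ]
        vals = pd.DataFrame(values, index=rows,
                            columns=pd.MultiIndex.from_tuples(cols))
        zeros = vals.copy() * 0.0
        return TurnoverMatrix(vals, zeros, zeros.astype(int) + 1)

    def test_identical_rows_merge_first_at_zero(self):
        m = self._matrix([[1, 2, 3, 4], [1, 2, 3, 4], [4, 3, 2, 1]])
        res = cluster_turnover(m)
        first = res.row_linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0)

    def test_reversed_ranks_distance_two(self):
        m = self._matrix([[1, 2, 3, 4], [4, 3, 2, 1]])
        res = cluster_turnover(m)
        assert res.row_linkage[0][2] == pytest.approx(2.0)

    def test_constant_row_gets_max_distance_with_warning(self, caplog):
        m = self._matrix([[1, 2, 3, 4], [5, 5, 5, 5], [2, 3, 4, 5]])
        with caplog.at_level("WARNING"):
            res = cluster_turnover(m)
        # the constant row joins last, at distance 2
        assert res.row_linkage[-1][2] == pytest.approx(2.0)

    def test_complete_linkage_matches_manual_lance_williams_trace(self):
        # 4 profiles whose rank patterns give a hand-checkable 1-Spearman
        # distance matrix; complete linkage merges (0,1) at 0, then (2,3),
        # then the two pairs at the largest pairwise distance
        m = self._matrix(
            [[1, 2, 3, 4], [2, 3, 4, 5], [4, 3, 2, 1], [8, 6, 4, 2]]
        )
        res = cluster_turnover(m)
        link = res.row_linkage
        # rows 0,1 share ranks (rho=1, d=0); rows 2,3 share ranks (d=0);
        # across the two pairs rho=-1 so complete-linkage height is 2
        assert {int(link[0][0]), int(link[0][1])} == {0, 1}
        assert link[0][2] == pytest.approx(0.0)
        assert {int(link[1][0]), int(link[1][1])} == {2, 3}
        assert link[1][2] == pytest.approx(0.0)
        assert link[2][2] == pytest.approx(2.0)

    def test_ward_column_merge_heights_hand_checked(self):
        # three columns: two identical, one far away; Ward merges the
        # identical pair at height 0, then joins the far column at the
        # Lance-Williams height sqrt(4/3)*|delta| for the (2,1) merge
        vals = np.array([[0.0, 0.0, 3.0], [0.0, 0.0, 4.0]])
        m = self._matrix(vals, rows=["a", "b"],
                         cols=[("G", "0-24"), ("G", "24-48"), ("G", "48-72")])
        res = cluster_turnover(m)
        link = res.col_linkage
        assert link[0][2] == pytest.approx(0.0)
        delta = math.hypot(3.0, 4.0)
        assert link[1][2] == pytest.approx(math.sqrt(4.0 / 3.0) * delta)

    # 4 rows x 5 columns of integer ranks chosen so all pairwise Spearman
    # distances are distinct (no merge-order ties): 0.1, 0.2, 0.4, 1.8,
    # 1.9 and 2.0
    TIE_FREE = [
        [1.0, 2.0, 3.0, 4.0, 5.0],
        [2.0, 1.0, 3.0, 4.0, 5.0],
        [1.0, 3.0, 2.0, 5.0, 4.0],
        [5.0, 4.0, 3.0, 2.0, 1.0],
    ]
    FIVE_COLS = [("NT", "0-24"), ("NT", "24-48"), ("NT", "48-72"),
                 ("NT", "72-96"), ("ICSI", "0-24")]

    def test_full_trace_matches_manual_lance_williams(self):
        # rows clustered on 1 - Spearman rho with complete linkage, columns
        # on Euclidean distance with Ward's criterion
        vals = np.array(self.TIE_FREE)
        m = self._matrix(vals.tolist(), cols=self.FIVE_COLS)
        res = cluster_turnover(m)

        from scipy.stats import spearmanr

        rho = spearmanr(vals, axis=1).statistic
        row_dist = 1.0 - rho
        np.fill_diagonal(row_dist, 0.0)
        manual_rows = lance_williams_trace(row_dist, "complete")
        assert scipy_trace(res.row_linkage, 4) == [
            (a, b, pytest.approx(h)) for a, b, h in manual_rows
        ]

        n_cols = vals.shape[1]
        col_dist = np.array(
            [[np.linalg.norm(vals[:, i] - vals[:, j]) for j in range(n_cols)]
             for i in range(n_cols)]
        )
        manual_cols = lance_williams_trace(col_dist, "ward")
        assert scipy_trace(res.col_linkage, n_cols) == [
            (a, b, pytest.approx(h)) for a, b, h in manual_cols
        ]

    def test_permutation_invariance_up_to_relabeling(self):
        vals = self.TIE_FREE
        m = self._matrix(vals, cols=self.FIVE_COLS)
        res = cluster_turnover(m)
        perm = [2, 0, 3, 1]
        m2 = self._matrix([vals[i] for i in perm],
                          rows=[f"aa{i}" for i in perm], cols=self.FIVE_COLS)
        res2 = cluster_turnover(m2)
        assert sorted(res.ordered.index) == sorted(res2.ordered.index)
        coph1 = dict(zip_pairs(res.row_order_input, res.row_linkage))
        coph2 = dict(zip_pairs(res2.row_order_input, res2.row_linkage))
        assert all(abs(coph1[k] - coph2[k]) < 1e-9 for k in coph1)

    def test_single_row_rejected(self):
        m = self._matrix([[1, 2, 3, 4]])
        with pytest.raises(ArgumentError):
            cluster_turnover(m)

    def test_newick_export_is_parsable(self):
        import dendropy

        m = self._matrix([[1, 2, 3, 4], [2, 1, 4, 3], [4, 3, 2, 1]])
        res = cluster_turnover(m)
        tree = dendropy.Tree.get(data=res.row_newick(), schema="newick")
        assert len(tree.leaf_nodes()) == 3


def zip_pairs(labels, linkage):
    """Cophenetic distances keyed by frozenset label pairs."""
    from scipy.spatial.distance import squareform

    coph = squareform(cophenet(linkage))
    out = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            out[frozenset((labels[i], labels[j]))] = coph[i, j]
    return out.items()


class TestProfileCorrelation:
    def _simulated_matrix(self, noise=1.0, seed=2):
        table = simulate_spent_media(seed=seed, noise_sd=noise)
        path_free = table  # long-format frame accepted via samples
        import io

        buf = io.StringIO()
        table.to_csv(buf, index=False)
        buf.seek(0)
        samples = read_media_csv(buf)
        return build_matrix(samples)

    def test_column_against_itself_is_unity(self):
        m = self._simulated_matrix()
        res = profile_correlation(m, ("NT", "0-24"), ("NT", "0-24"))
        assert res.estimate == pytest.approx(1.0)

    def test_sign_invariance_with_signed_r_reported(self):
        m = self._simulated_matrix()
        col = m.values[("NT", "0-24")]
        neg = m.values.copy()
        neg[("NT", "24-48")] = -col
        m2 = TurnoverMatrix(neg, m.sem, m.n)
        res = profile_correlation(m2, ("NT", "0-24"), ("NT", "24-48"))
        assert res.estimate == pytest.approx(1.0)
        assert res.extra["r"] == pytest.approx(-1.0)

    def test_metabolic_lag_correlation(self):
        m = self._simulated_matrix(seed=2)
        res = profile_correlation(m, ("NT", "24-48"), ("ICSI", "0-24"))
        assert res.estimate > 0.7


class TestMediaSimulation:
    def test_noise_free_lag_is_exact(self):
        import io

        table = simulate_spent_media(seed=0, noise_sd=0.0)
        buf = io.StringIO()
        table.to_csv(buf, index=False)
        buf.seek(0)
        m = build_matrix(read_media_csv(buf))
        nt_lag = m.values[("NT", "24-48")]
        icsi_first = m.values[("ICSI", "0-24")]
        assert np.allclose(nt_lag.to_numpy(), icsi_first.to_numpy())

    def test_arginine_scaling_pattern(self):
        import io

        table = simulate_spent_media(seed=0, noise_sd=0.0)
        buf = io.StringIO()
        table.to_csv(buf, index=False)
        buf.seek(0)
        m = build_matrix(read_media_csv(buf))
        arg = m.values.loc["arginine"]
        # cloned embryos consume less arginine before the morula stage and
        # more at the morula/blastocyst stage
        for window in ("0-24", "24-48", "48-72"):
            assert arg[("NT", window)] < arg[("ICSI", window)]
        assert arg[("NT", "72-96")] > arg[("ICSI", "72-96")]

    def test_clustering_places_lagged_nt_with_early_stages(self):
        import io

        table = simulate_spent_media(seed=2)
        buf = io.StringIO()
        table.to_csv(buf, index=False)
        buf.seek(0)
        m = build_matrix(read_media_csv(buf))
        res = cluster_turnover(m)
        coph = dict(zip_pairs(res.col_order_input, res.col_linkage))
        lag_pair = frozenset(("NT|24-48", "ICSI|0-24"))
        same_window = frozenset(("NT|24-48", "ICSI|24-48"))
        assert coph[lag_pair] < coph[same_window]

    def test_all_panel_amino_acids_present(self):
        table = simulate_spent_media(seed=1, n_replicates=2)
        assert set(table["amino_acid"]) == set(AMINO_ACIDS)
        assert (table.groupby("sample_id").size() == 18).all()
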