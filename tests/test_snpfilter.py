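"""Filter cascade stages, Mann-Whitney z, ledger conservation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

import gbsconcord as gc
from conftest import make_snp_table


def _uniform_table(n_sites, n_ind, rd=2, ad=2, **kw):
    return make_snp_table(
        [f"i{k}" for k in range(n_ind)],
        [f"c{s}" for s in range(n_sites)],
        list(range(n_sites)),
        np.full((n_sites, n_ind), rd),
        np.full((n_sites, n_ind), ad),
        **kw,
    )


class TestPresence:
    @pytest.mark.parametrize("present,kept", [(11, False), (12, True), (14, True)])
    def test_ceiling_boundary_n14(self, present, kept):
        rd = np.zeros((1, 14), dtype=int)
        rd[0, :present] = 3
        t = make_snp_table([f"i{k}" for k in range(14)], ["c"], [0], rd, np.zeros((1, 14), int))
        out, stage = gc.presence_filter(t)
        assert (out.n_sites == 1) is kept
        assert stage.sites_in == 1


class TestDepthFloor:
    @pytest.mark.parametrize("total,kept", [(28, True), (27, False), (0, False)])
    def test_inclusive_2n_boundary(self, total, kept):
        rd = np.zeros((1, 14), dtype=int)
        for k in range(total):  # spread `total` reads over individuals
            rd[0, k % 14] += 1
        t = make_snp_table([f"i{k}" for k in range(14)], ["c"], [0], rd, np.zeros((1, 14), int))
        out, _ = gc.depth_floor_filter(t)
        assert (out.n_sites == 1) is kept


class TestParalogDepth:
    def test_equal_depths_none_removed(self):
        t = _uniform_table(6, 4)
        out, _ = gc.paralog_depth_filter(t)
        assert out.n_sites == 6  # sd = 0, strict >

    def test_single_outlier_removed(self):
        """10 sites at mean depth 3, one at 50: exactly the outlier goes."""
        n_ind = 4
        rd = np.full((11, n_ind), 3)
        rd[10] = 50
        t = make_snp_table([f"i{k}" for k in range(n_ind)], [f"c{s}" for s in range(11)],
                           range(11), rd, np.zeros((11, n_ind), int))
        means = rd.mean(axis=1)
        cutoff = means.mean() + 2 * means.std()  # direct computation
        assert (means > cutoff).sum() == 1
        out, stage = gc.paralog_depth_filter(t)
        assert stage.sites_removed == 1
        assert "c10" not in out.contig_ids

    def test_two_sites_pair_rule(self):
        rd = np.array([[3, 3], [30, 30]])
        t = make_snp_table(["i0", "i1"], ["c0", "c1"], [0, 1], rd, np.zeros((2, 2), int))
        out, _ = gc.paralog_depth_filter(t)
        # mean 16.5, sd 13.5 -> cutoff 43.5: neither exceeds
        assert out.n_sites == 2

    def test_single_site_passthrough_with_warning(self):
        t = _uniform_table(1, 3)
        with pytest.warns(UserWarning):
            out, _ = gc.paralog_depth_filter(t)
        assert out.n_sites == 1


class TestMappingQuality:
    @pytest.mark.parametrize("mq,kept", [(60.0, True), (30.0, True), (29.0, False)])
    def test_minimum_score_30(self, mq, kept):
        t = _uniform_table(1, 3, site_mq=[mq])
        out, _ = gc.mapping_quality_filter(t)
        assert (out.n_sites == 1) is kept


def mw_enumeration_oracle(x, y):
    """Exact permutation mean/variance of U with midranks; z = (U - m)/sd."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)
    ranks = rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        us.append(ranks[list(comb)].sum() - n1 * (n1 + 1) / 2)
    us = np.array(us)
    sd = us.std(ddof=0)
    if sd == 0:
        return 0.0
    return (u_obs - us.mean()) / sd


class TestMannWhitney:
    def test_identical_groups_zero(self):
        assert gc.mann_whitney_z([5, 5, 5], [5, 5, 5]) == 0.0

    def test_separated_groups_matches_enumeration(self):
        z = gc.mann_whitney_z([1, 2, 3], [4, 5, 6])
        assert z == pytest.approx(-4.5 / np.sqrt(5.25))
        assert z == pytest.approx(mw_enumeration_oracle([1, 2, 3], [4, 5, 6]))
        assert abs(z) > 1.96  # the site would be removed

    def test_tied_2v2_matches_enumeration(self):
        x, y = [1.0, 2.0], [2.0, 3.0]
        assert gc.mann_whitney_z(x, y) == pytest.approx(mw_enumeration_oracle(x, y))

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 6), min_size=1, max_size=6),
        st.lists(st.integers(0, 6), min_size=1, max_size=6),
    )
    def test_matches_enumeration_oracle_small_groups(self, x, y):
        assert gc.mann_whitney_z(x, y) == pytest.approx(
            mw_enumeration_oracle(x, y), abs=1e-10
        )

    def test_empty_group_rejected(self):
        with pytest.raises(gc.InputError):
            gc.mann_whitney_z([], [1])


class TestMAF:
    def _table_with_freq(self, f):
        t = _uniform_table(1, 4)
        t.allele_freq = np.array([f])
        return t

    @pytest.mark.parametrize("f,kept", [(0.5, True), (0.05, True), (0.049, False), (0.96, False)])
    def test_boundary(self, f, kept):
        out, _ = gc.maf_filter(self._table_with_freq(f))
        assert (out.n_sites == 1) is kept


class TestThinning:
    def _multi(self):
        return make_snp_table(
            ["i0", "i1"],
            ["c0", "c1", "c1", "c2", "c2", "c2", "c2", "c2"],
            [0, 3, 9, 1, 2, 3, 4, 5],
            np.full((8, 2), 3),
            np.full((8, 2), 3),
        )

    def test_one_survivor_per_contig(self):
        out, stage = gc.thin_one_per_contig(self._multi(), seed=0)
        assert out.n_sites == 3
        assert sorted(out.contig_ids) == ["c0", "c1", "c2"]
        assert stage.sites_removed == 5

    def test_seeded_determinism_and_reorder_stability(self):
        t = self._multi()
        out1, _ = gc.thin_one_per_contig(t, seed=7)
        out2, _ = gc.thin_one_per_contig(t, seed=7)
        assert (out1.positions == out2.positions).all()
        # reordering sites leaves per-contig survivorship unchanged
        perm = np.array([4, 2, 7, 0, 3, 6, 1, 5])
        out3, _ = gc.thin_one_per_contig(t.subset(perm), seed=7)
        assert sorted(zip(out1.contig_ids, out1.positions)) == sorted(
            zip(out3.contig_ids, out3.positions)
        )


class TestCascade:
    def build_staged_fixture(self):
        """One site engineered to fall at each stage, plus a clean survivor.

        n = 5 individuals: presence needs ceil(0.8*5) = 4, depth floor 10.
        """
        ids = [f"i{k}" for k in range(5)]
        full = np.full(5, 2)
        z = np.zeros(5, dtype=int)
        rows = {
            # name: (contig, biallelic, rd, ad, site_mq, bq_alt_override)
            "triallelic": ("c_tri", False, full * 2, full, 60.0, None),
            "absent": ("c_abs", True, np.array([4, 4, 4, 0, 0]), np.array([2, 2, 2, 0, 0]), 60.0, None),
            "shallow": ("c_sha", True, np.array([1, 1, 1, 1, 1]), np.array([1, 1, 1, 0, 0]), 60.0, None),
            "paralog": ("c_par", True, np.full(5, 40), np.full(5, 40), 60.0, None),
            "badmap": ("c_map", True, full, full, 29.0, None),
            "lowqualalt": ("c_mwu", True, full, full, 60.0, 10),
            "rare": ("c_maf", True, full * 2, z, 60.0, None),
            "clean": ("c_ok", True, full, full, 60.0, None),
            "clean_sib": ("c_ok", True, full, full, 60.0, None),
        }
        names = list(rows)
        rd = np.stack([rows[n][2] for n in names])
        ad = np.stack([rows[n][3] for n in names])
        bq_alt = []
        for n in names:
            override = rows[n][5]
            val = override if override is not None else 38
            bq_alt.append(np.full(int(rows[n][3].sum()), val, dtype=np.int64))
        t = make_snp_table(
            ids,
            [rows[n][0] for n in names],
            list(range(len(names))),
            rd,
            ad,
            site_mq=[rows[n][4] for n in names],
            biallelic=[rows[n][1] for n in names],
            bq_alt=bq_alt,
        )
        return t, names

    def test_each_removal_attributed_to_intended_stage(self):
        t, names = self.build_staged_fixture()
        out, ledger = gc.apply_cascade(t, gc.FilterParams(thin_seed=1))
        frame = ledger.to_frame().set_index("stage")
        assert frame.loc["biallelic", "sites_removed"] == 1
        assert frame.loc["presence", "sites_removed"] == 1
        assert frame.loc["depth_floor", "sites_removed"] == 1
        assert frame.loc["paralog_depth", "sites_removed"] == 1
        assert frame.loc["mapping_quality", "sites_removed"] == 1
        assert frame.loc["allele_quality_mw", "sites_removed"] == 1
        assert frame.loc["maf", "sites_removed"] == 1
        assert frame.loc["thin_one_per_contig", "sites_removed"] == 1
        assert out.n_sites == 1
        assert out.contig_ids[0] == "c_ok"

    def test_ledger_conservation_chain(self):
        t, _ = self.build_staged_fixture()
        _, ledger = gc.apply_cascade(t)
        stages = ledger.stages
        for st_ in stages:
            assert st_.sites_in == st_.sites_removed + st_.sites_out
        for a, b in zip(stages, stages[1:]):
            assert a.sites_out == b.sites_in
        assert stages[0].sites_in == t.n_sites

    def test_all_passing_table_thins_to_one_per_contig(self):
        t = make_snp_table(
            [f"i{k}" for k in range(5)],
            ["cA", "cA", "cB"],
            [0, 5, 2],
            np.full((3, 5), 2),
            np.full((3, 5), 2),
        )
        out, _ = gc.apply_cascade(t)
        assert out.n_sites == 2

    def test_empty_table_ledger_of_zeros(self):
        t = make_snp_table([f"i{k}" for k in range(3)], [], [], np.zeros((0, 3), int), np.zeros((0, 3), int))
        out, ledger = gc.apply_cascade(t)
        assert out.n_sites == 0
        assert (ledger.to_frame()["sites_removed"] == 0).all()

    def test_conservation_on_simulated_data(self, tiny_snp_table):
        out, ledger = gc.apply_cascade(tiny_snp_table)
        frame = ledger.to_frame()
        assert frame.iloc[0]["sites_in"] == tiny_snp_table.n_sites
        assert frame.iloc[-1]["sites_out"] == out.n_sites
        assert (frame["sites_in"] == frame["sites_removed"] + frame["sites_out"]).all()
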