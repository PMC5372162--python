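"""Richness profiles, co-occurrence counts and the stratum-level report."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from coralguild.community import ColonyRecord, IncidenceMatrix, Stratum
from coralguild.datasets import ANALYSIS_STRATA, KEY_TAXA
from coralguild.guildstats import (
    pairwise_cooccurrence,
    richness_profile,
    run_guild_analysis,
    solitary_count,
)
from coralguild.nullmodels import NullModelConfig

binary_matrices = arrays(
    np.int8,
    st.tuples(st.integers(1, 8), st.just(5)),
    elements=st.integers(0, 1),
)


class TestRichnessProfile:
    @pytest.mark.parametrize(
        "stratum,k,expected",
        [
            ("RI-adult", 1, 37),
            ("NC-adult-alpha", 2, 34),
            ("NC-adult-alpha", 1, 12),
            ("NC-juvenile-alpha", 1, 21),
            ("RI-juvenile", 1, 31),
        ],
    )
    def test_published_richness_counts(self, stratum_matrices, stratum, k, expected):
        assert richness_profile(stratum_matrices[stratum]).n_k[k] == expected

    def test_zero_matrix_all_in_k0(self):
        p = richness_profile(np.zeros((9, 5), dtype=np.int8))
        assert p.n_k[0] == 9 and p.n_k[1:].sum() == 0

    def test_wrong_column_count_rejected(self):
        with pytest.raises(ValueError, match="key-species columns"):
            richness_profile(np.zeros((3, 4), dtype=np.int8))

    @given(binary_matrices)
    @settings(max_examples=200, deadline=None)
    def test_counts_partition_colonies(self, a):
        p = richness_profile(a)
        assert p.n_k.sum() == a.shape[0]
        # presence-mass conservation: sum_k k*n_k == sum_s f_s
        assert (np.arange(6) * p.n_k).sum() == a.sum()


class TestPairwiseCooccurrence:
    def test_guttata_with_lottini_l1_at_reunion(self, stratum_matrices):
        m = stratum_matrices["RI-adult"]
        t = pairwise_cooccurrence(m)
        i, j = t.taxon_ids.index("Tgut"), t.taxon_ids.index("AlotL1")
        assert t.c[i, j] == 15

    def test_guttata_never_with_speciosa_at_reunion(self, stratum_matrices):
        t = pairwise_cooccurrence(stratum_matrices["RI-adult"])
        i, j = t.taxon_ids.index("Tgut"), t.taxon_ids.index("Tspe")
        assert t.c[i, j] == 0

    @given(binary_matrices)
    @settings(max_examples=200, deadline=None)
    def test_diagonal_is_prevalence_and_table_symmetric(self, a):
        t = pairwise_cooccurrence(a)
        assert (np.diag(t.c) == a.sum(axis=0)).all()
        assert (t.c == t.c.T).all()
        assert (t.c <= np.minimum.outer(np.diag(t.c), np.diag(t.c))).all()
        assert (t.s <= np.diag(t.c)).all()

    @given(binary_matrices)
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_per_row_loop_oracle(self, a):
        t = pairwise_cooccurrence(a)
        for i in range(5):
            for j in range(5):
                brute = sum(1 for row in a if row[i] and row[j])
                assert t.c[i, j] == brute
            brute_solo = sum(1 for row in a if row[i] and row.sum() == 1)
            assert t.s[i] == brute_solo


class TestSolitaryCount:
    def test_speciosa_mostly_alone_at_reunion(self, stratum_matrices):
        assert solitary_count(stratum_matrices["RI-adult"], "Tspe") == 24

    def test_always_cooccurring_taxon_has_zero(self):
        a = np.zeros((4, 5), dtype=np.int8)
        a[:, 0] = a[:, 1] = 1
        m = IncidenceMatrix([f"c{i}" for i in range(4)], KEY_TAXA, a)
        assert solitary_count(m, "AlotL1") == 0

    def test_non_key_taxon_rejected(self, stratum_matrices):
        with pytest.raises(KeyError):
            solitary_count(stratum_matrices["RI-adult"], "Tcymo")

    def test_matches_row_scan_on_hand_matrix(self, rng):
        a = rng.integers(0, 2, size=(6, 5)).astype(np.int8)
        m = IncidenceMatrix([f"c{i}" for i in range(6)], KEY_TAXA, a)
        for j, tid in enumerate(KEY_TAXA):
            brute = sum(1 for row in a if row[j] == 1 and row.sum() == 1)
            assert solitary_count(m, tid) == brute


@pytest.fixture(scope="module")
def ri_report(survey_records):
    return run_guild_analysis(
        survey_records,
        KEY_TAXA,
        ANALYSIS_STRATA["RI-adult"],
        config=NullModelConfig(reps=2000, seed=11),
    )


class TestRunGuildAnalysis:
    def test_speciosa_lottini_pair_underrepresented_under_m2(self, ri_report):
        row = ri_report[
            (ri_report.statistic_id == "pair_AlotL1_Tspe") & (ri_report.model == "M2")
        ].iloc[0]
        assert row.observed == 3
        assert row.flag == "below"

    def test_guttata_lottini_pair_overrepresented_under_m2(self, ri_report):
        row = ri_report[
            (ri_report.statistic_id == "pair_AlotL1_Tgut") & (ri_report.model == "M2")
        ].iloc[0]
        assert row.observed == 15
        assert row.flag == "above"

    def test_nc_alpha_lineage_pair_observed_once(self, survey_records):
        rep = run_guild_analysis(
            survey_records,
            KEY_TAXA,
            ANALYSIS_STRATA["NC-adult-alpha"],
            models=("M2",),
            config=NullModelConfig(reps=200, seed=2),
        )
        row = rep[rep.statistic_id == "pair_AlotL1_AlotL2"].iloc[0]
        assert row.observed == 1

    def test_richness_reported_under_m1_m2_only(self, ri_report):
        models = set(ri_report[ri_report.family == "richness"].model)
        assert models == {"M1", "M2"}
        assert set(ri_report[ri_report.family == "pairwise"].model) == {"M1", "M2", "M3"}

    def test_k0_class_marked_informational(self, ri_report):
        info = ri_report[ri_report.informational]
        assert set(info.statistic_id) == {"richness_k0"}

    def test_report_counts(self, ri_report):
        # 6 richness classes x 2 models + (10 pairs + 5 solitary) x 3 models
        assert len(ri_report) == 6 * 2 + 15 * 3

    def test_empty_stratum_rejected(self, survey_records):
        with pytest.raises(ValueError, match="no colonies"):
            run_guild_analysis(
                survey_records, KEY_TAXA, Stratum(region="RI", host_type="alpha")
            )

    def test_degenerate_all_empty_stratum(self):
        recs = [
            ColonyRecord(f"e{i}", "RI", "LI", "adult", "beta") for i in range(5)
        ]
        rep = run_guild_analysis(
            recs, KEY_TAXA, Stratum(region="RI"), config=NullModelConfig(reps=50, seed=0)
        )
        assert (rep[rep.family != "richness"].observed == 0).all()
        assert set(rep.flag) <= {"inside", "below"}
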