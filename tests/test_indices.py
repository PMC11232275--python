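"""Citation, consensus and fidelity indices, rounding, and summaries."""

import math

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ethnosurvey as es
from ethnosurvey.indices import BoundaryWarning

# Published per-category aggregates: (category, Nt, Nur, printed ICF).
TABLE3_CATEGORIES = [
    ("OTHA-A", 13, 398, 0.97),
    ("GAS-D", 40, 114, 0.65),
    ("CAR-K", 2, 73, 0.99),
    ("Blood-B", 4, 117, 0.97),
    ("SKE-L", 3, 122, 0.98),
    ("NER-N", 1, 26, 1.00),
    ("RES-R", 17, 479, 0.97),
    ("DER-S", 19, 549, 0.97),
    ("URO-U", 5, 119, 0.97),
    ("CAN-C", 1, 26, 1.00),
    ("PRE-W", 1, 26, 1.00),
    ("OTH", 19, 431, 0.96),
]

# Published highest-fidelity exemplar per category: (species, Iu, Ip, printed FL%).
TABLE3_FIDELITY = [
    ("Ajuga integrifolia", 14, 11, 78.57),
    ("Mentha longifolia", 14, 13, 92.86),
    ("Ziziphus jujuba", 13, 10, 76.92),
    ("Plocama brevifolia", 15, 7, 46.67),
    ("Datisca cannabina", 14, 8, 57.14),
    ("Indigofera tinctoria", 12, 5, 41.67),
    ("Lepidium sativum", 14, 9, 64.29),
    ("Myrtus communis", 18, 17, 94.44),
    ("Clematis grata", 12, 8, 66.67),
    ("Pteridium esculentum", 12, 5, 41.67),
    ("Verbascum thapsus", 12, 7, 58.33),
    ("Ambrosia artemisiifolia", 14, 9, 64.29),
]


# ---------------------------------------------------------------------------
# Scalar index functions
# ---------------------------------------------------------------------------


class TestRFC:
    def test_published_example(self):
        # the most-cited species: 18 of 281 respondents
        assert es.round_index(es.compute_rfc(18, 281), 2) == 0.06

    def test_boundaries_warn_but_return(self):
        with pytest.warns(BoundaryWarning):
            assert es.compute_rfc(0, 281) == 0.0
        with pytest.warns(BoundaryWarning):
            assert es.compute_rfc(50, 50) == 1.0

    @pytest.mark.parametrize("fc,n", [(5, 4), (-1, 10), (3, 0)])
    def test_domain_errors(self, fc, n):
        with pytest.raises(ValueError):
            es.compute_rfc(fc, n)

    @given(st.integers(1, 500), st.integers(0, 499))
    def test_strictly_increasing_in_fc(self, n, fc):
        fc = min(fc, n - 1)
        if fc < 0:
            return
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", BoundaryWarning)
            assert es.compute_rfc(fc + 1, n) > es.compute_rfc(fc, n)


class TestICF:
    @pytest.mark.parametrize("code,nt,nur,printed", TABLE3_CATEGORIES)
    def test_published_category_values(self, code, nt, nur, printed):
        assert es.round_index(es.compute_icf(nur, nt), 2) == printed

    def test_single_taxon_category_has_full_consensus(self):
        assert es.compute_icf(26, 1) == 1.0

    @pytest.mark.parametrize("k", [2, 5, 17])
    def test_no_consensus_when_every_report_cites_a_new_taxon(self, k):
        assert es.compute_icf(k, k) == 0.0

    def test_undefined_at_single_report(self):
        assert es.compute_icf(1, 1) is None

    @pytest.mark.parametrize("nur,nt", [(5, 6), (5, 0), (0, 1)])
    def test_domain_errors(self, nur, nt):
        with pytest.raises(ValueError):
            es.compute_icf(nur, nt)

    @given(st.integers(2, 1000), st.integers(1, 999))
    def test_strictly_decreasing_in_nt(self, nur, nt):
        nt = min(nt, nur - 1)
        assert es.compute_icf(nur, nt + 1) < es.compute_icf(nur, nt)


class TestFL:
    @pytest.mark.parametrize("species,iu,ip,printed", TABLE3_FIDELITY)
    def test_published_fidelity_values(self, species, iu, ip, printed):
        assert es.round_index(es.compute_fl(ip, iu), 2) == printed

    def test_single_purpose_species_is_100_percent(self):
        assert es.compute_fl(7, 7) == 100.0

    @pytest.mark.parametrize("ip,iu", [(5, 4), (-1, 10), (0, 0)])
    def test_domain_errors(self, ip, iu):
        with pytest.raises(ValueError):
            es.compute_fl(ip, iu)

    @given(st.integers(1, 500), st.integers(0, 499))
    def test_strictly_increasing_in_ip(self, iu, ip):
        ip = min(ip, iu - 1)
        if ip < 0:
            return
        assert es.compute_fl(ip + 1, iu) > es.compute_fl(ip, iu)


class TestRounding:
    @pytest.mark.parametrize(
        "x,places,expected",
        [
            (0.96715, 2, 0.97),  # 530/548
            (0.005, 2, 0.01),  # half-up, not half-even
            (0.6548672566, 2, 0.65),
            (94.44444, 2, 94.44),
            (92.857142, 2, 92.86),
            (71.875, 1, 71.9),
            (3.0, 0, 3.0),
        ],
    )
    def test_half_up(self, x, places, expected):
        assert es.round_index(x, places) == expected

    def test_negative_places_rejected(self):
        with pytest.raises(ValueError):
            es.round_index(1.0, -1)


# ---------------------------------------------------------------------------
# Fixture-level index table
# ---------------------------------------------------------------------------


class TestKohistanIndexTable:
    def test_all_twelve_category_icf_values_reproduce(self, kohistan_index):
        rounded = kohistan_index.rounded(2).per_category.set_index("category")
        for code, _, _, printed in TABLE3_CATEGORIES:
            assert rounded.loc[code, "icf"] == printed, code

    def test_all_twelve_fidelity_values_reproduce(self, kohistan_index):
        rounded = kohistan_index.rounded(2).per_fidelity
        got = dict(zip(rounded["species"], rounded["fl"]))
        for species, _, _, printed in TABLE3_FIDELITY:
            assert got[species] == printed, species

    def test_fidelity_ranking_tops_out_at_myrtus(self, kohistan_index):
        ranked = es.rank_species(kohistan_index, metric="fl")
        assert ranked.iloc[0]["species"] == "Myrtus communis"
        assert es.round_index(ranked.iloc[0]["fl"], 2) == 94.44

    def test_rfc_is_fc_over_n_before_rounding(self, kohistan_index):
        df = kohistan_index.per_species
        assert all(
            math.isclose(r, f / kohistan_index.n)
            for r, f in zip(df["rfc"], df["fc"])
        )


# ---------------------------------------------------------------------------
# Categorization and frequency summaries
# ---------------------------------------------------------------------------


class TestCategorize:
    def test_single_species_single_ailment(self):
        informants = [es.Informant("i1", "V", "G1", "M", 30)]
        sp = es.SpeciesRecord(
            species_id="s1",
            scientific_name="Genus alba",
            family="Fam",
            local_names=(),
            habit="herb",
            parts_used=frozenset({"leaves"}),
            preparations=frozenset({"powder"}),
            routes=frozenset({"oral"}),
            ailments=("fever",),
            fc=1,
        )
        vocab = es.Vocabulary(
            categories={
                "C1": es.DiseaseCategory("C1", "one", frozenset({"fever"})),
                "C2": es.DiseaseCategory("C2", "two", frozenset({"cough"})),
            }
        )
        ds = es.SurveyDataset(
            informants, [sp], [es.UseReport("i1", "s1", "fever")], [], mode="raw"
        )
        out = es.categorize_ailments(ds, vocab).set_index("category")
        assert out.loc["C1", "nt"] == 1 and out.loc["C1", "nur"] == 1
        assert "C2" not in out.index

    def test_multi_category_species_counts_once_per_category(self, kohistan):
        # aggregate mode: nt from ailment listings through the vocabulary
        out = es.categorize_ailments(kohistan).set_index("category")
        multi = [
            s
            for s in kohistan.species
            if len(
                {
                    kohistan.vocabulary.category_of(a)
                    for a in s.ailments
                }
            )
            > 1
        ]
        assert multi  # the survey has multi-category species
        total_nt = out["nt"].sum()
        assert total_nt > len(kohistan.species)

    def test_unmapped_term_raises_in_strict_mode(self):
        informants = [es.Informant("i1", "V", "G1", "M", 30)]
        sp = es.SpeciesRecord(
            species_id="s1",
            scientific_name="Genus alba",
            family="Fam",
            local_names=(),
            habit="herb",
            parts_used=frozenset(),
            preparations=frozenset(),
            routes=frozenset(),
            ailments=("weird mystery illness",),
            fc=0,
        )
        vocab = es.Vocabulary(
            categories={"C1": es.DiseaseCategory("C1", "one", frozenset({"fever"}))}
        )
        ds = es.SurveyDataset(informants, [sp], [], [], mode="aggregate")
        from ethnosurvey.data_model import VocabularyError

        with pytest.raises(VocabularyError, match="weird mystery illness"):
            es.categorize_ailments(ds, vocab, strict=True)
        with pytest.warns(UserWarning, match="OTH"):
            out = es.categorize_ailments(ds, vocab).set_index("category")
        assert out.loc["OTH", "nt"] == 1


class TestFrequencySummary:
    def test_family_count_matches_polygonaceae(self, kohistan):
        ft = es.frequency_summary(kohistan, "family")
        row = ft.table.set_index("term").loc["Polygonaceae"]
        assert row["count"] == 11
        assert ft.denominator == 96

    def test_habit_shares_close_to_published_percentages(self, kohistan):
        # printed life-form shares (71.8 herbs / 16.6 trees / 10.4 shrubs)
        # are not exactly consistent with the printed species table, so the
        # recount is checked within 3 percentage points
        ft = es.frequency_summary(kohistan, "habit").table.set_index("term")
        assert abs(ft.loc["herb", "percent"] - 71.8) <= 3.0
        assert abs(ft.loc["tree", "percent"] - 16.6) <= 3.0
        assert abs(ft.loc["shrub", "percent"] - 10.4) <= 3.0

    def test_exclusive_dimension_percents_sum_to_100(self, kohistan):
        for dim in ("habit", "family"):
            ft = es.frequency_summary(kohistan, dim)
            assert ft.table["count"].sum() == ft.denominator
            assert abs(ft.table["percent"].sum() - 100.0) <= 0.1 + 0.05 * len(ft.table)

    def test_single_species_dataset_is_all_one_habit(self):
        informants = [es.Informant("i1", "V", "G1", "M", 30)]
        sp = es.SpeciesRecord(
            species_id="s1",
            scientific_name="Genus alba",
            family="Fam",
            local_names=(),
            habit="shrub",
            parts_used=frozenset({"leaves", "roots"}),
            preparations=frozenset({"powder"}),
            routes=frozenset({"oral"}),
            ailments=("fever",),
            fc=1,
        )
        ds = es.SurveyDataset(informants, [sp], [], [], mode="aggregate")
        ft = es.frequency_summary(ds, "habit")
        assert ft.table.iloc[0]["term"] == "shrub"
        assert ft.table.iloc[0]["percent"] == 100.0
        # incidence dimension counts both parts
        fp = es.frequency_summary(ds, "part")
        assert fp.denominator == 2

    def test_unknown_dimension_rejected(self, kohistan):
        with pytest.raises(ValueError, match="dimension"):
            es.frequency_summary(kohistan, "constellation")


class TestRanking:
    def test_default_tie_break_is_alphabetical(self):
        tbl = es.IndexTable(
            per_species=pd.DataFrame(
                {
                    "species_id": ["a", "b", "c"],
                    "scientific_name": ["Zed spec", "Alpha spec", "Mid spec"],
                    "fc": [5, 5, 9],
                    "rfc": [0.05, 0.05, 0.09],
                }
            ),
            per_category=pd.DataFrame(),
            per_fidelity=pd.DataFrame(),
            n=100,
        )
        ranked = es.rank_species(tbl, metric="fc")
        assert list(ranked["scientific_name"]) == ["Mid spec", "Alpha spec", "Zed spec"]
        assert list(ranked["tied"]) == [False, True, True]

    def test_stable_rule_preserves_input_order(self):
        tbl = es.IndexTable(
            per_species=pd.DataFrame(
                {
                    "species_id": ["a", "b"],
                    "scientific_name": ["Zed spec", "Alpha spec"],
                    "fc": [5, 5],
                    "rfc": [0.05, 0.05],
                }
            ),
            per_category=pd.DataFrame(),
            per_fidelity=pd.DataFrame(),
            n=100,
        )
        ranked = es.rank_species(tbl, metric="fc", tie_rule="stable")
        assert list(ranked["scientific_name"]) == ["Zed spec", "Alpha spec"]


# ---------------------------------------------------------------------------
# Raw / aggregate equivalence
# ---------------------------------------------------------------------------


class TestModeEquivalence:
    def test_indices_agree_between_raw_and_aggregated(self, small_raw):
        ds, _ = small_raw
        agg = es.aggregate_survey(ds)
        t_raw = es.build_index_table(ds)
        t_agg = es.build_index_table(agg)
        pd.testing.assert_frame_equal(t_raw.per_species, t_agg.per_species)
        pd.testing.assert_frame_equal(
            t_raw.per_category.reset_index(drop=True),
            t_agg.per_category.reset_index(drop=True),
        )
        raw_f = (
            t_raw.per_fidelity.set_index("species")[["ip", "iu", "fl"]].sort_index()
        )
        agg_f = (
            t_agg.per_fidelity.set_index("species")[["ip", "iu", "fl"]].sort_index()
        )
        pd.testing.assert_frame_equal(raw_f, agg_f)

    def test_aggregated_dataset_validates(self, small_raw):
        ds, _ = small_raw
        agg = es.aggregate_survey(ds)
        assert agg.mode == "aggregate"
        assert es.validate_dataset(agg).ok
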