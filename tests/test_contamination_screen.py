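"""Contamination screen: fragmentation, hit-width metrics, classification and
the per-family symbiont summary."""

import pytest
from hypothesis import given, strategies as st

from conftest import brute_union_length
from miridscreen.formats_io import Hit, ScaffoldRecord
from miridscreen.contamination_screen import (
    ContamMetrics,
    ScreenParams,
    add_totals_row,
    classify_contaminants,
    family_summary,
    fragment_scaffold,
    scaffold_metrics,
    screen_assembly,
    toy_search,
    union_length,
)
from miridscreen.synthetic_data import (
    SimParams,
    build_truth_assembly,
    fabricate_hit_table,
)


def bact(scaffold, start, end, subject="sp1", family="FamA", bitscore=200.0):
    return Hit(scaffold, start, end, subject, family, bitscore, "bacterial",
               fragment_index=start // 1000)


class TestFragmentation:
    @pytest.mark.parametrize(
        "length,expected",
        [
            (2500, [(0, (0, 1000)), (1, (1000, 2000)), (2, (2000, 2500))]),
            (1000, [(0, (0, 1000))]),
            (999, [(0, (0, 999))]),
        ],
    )
    def test_fragments_tile_the_scaffold(self, length, expected):
        assert fragment_scaffold(length, 1000) == expected

    def test_bad_fragment_length_rejected(self):
        with pytest.raises(ValueError):
            fragment_scaffold(100, 0)


class TestScaffoldMetrics:
    def test_union_and_width_of_overlapping_hits(self):
        hits = [bact("s", 100, 600), bact("s", 400, 900)]
        m = scaffold_metrics(hits, "s", 1000)
        assert (m.n_matches, m.covered_bp) == (2, 800)
        assert m.covered_prop == pytest.approx(0.8)
        assert m.hit_width_prop == pytest.approx(0.8)

    def test_bitscore_exactly_at_threshold_is_discarded(self):
        m = scaffold_metrics([bact("s", 0, 500, bitscore=50.0)], "s", 1000)
        assert m.n_matches == 0 and m.covered_bp == 0 and m.hit_width_bp == 0

    def test_top_taxon_tie_breaks_lexicographically(self):
        hits = [
            bact("s", 900, 950, subject="B"), bact("s", 950, 1000, subject="B"),
            bact("s", 0, 50, subject="A"), bact("s", 50, 100, subject="A"),
        ]
        m = scaffold_metrics(hits, "s", 1000)
        assert m.hit_width_prop == pytest.approx(1.0)
        assert m.covered_prop == pytest.approx(0.2)
        assert m.top_taxon == "A" and m.top_taxon_tie

    def test_hit_outside_scaffold_raises(self):
        with pytest.raises(ValueError, match="outside"):
            scaffold_metrics([bact("s", 900, 1200)], "s", 1000)

    @given(
        st.lists(
            st.tuples(st.integers(0, 990), st.integers(1, 200)),
            min_size=1, max_size=20,
        )
    )
    def test_union_matches_per_base_oracle_and_width_bound(self, raw):
        """Interval-union coverage equals brute-force per-base marking, and
        covered proportion never exceeds hit-width proportion."""
        intervals = [(s, min(s + l, 1000)) for s, l in raw]
        hits = [bact("s", s, e) for s, e in intervals]
        m = scaffold_metrics(hits, "s", 1000)
        assert m.covered_bp == brute_union_length(intervals, 1000)
        assert m.covered_prop <= m.hit_width_prop <= 1.0


class TestClassification:
    @pytest.mark.parametrize(
        "width,call", [(0.40, "contaminant"), (0.399, "clean"), (0.0, "clean")]
    )
    def test_width_cutoff_is_inclusive(self, width, call):
        m = ContamMetrics("s", 1000, hit_width_prop=width,
                          n_matches=1 if width else 0)
        out, removal = classify_contaminants([m])
        assert out[0].call == call
        assert ("s" in removal) == (call == "contaminant")

    @given(
        st.lists(st.tuples(st.integers(0, 900), st.integers(60, 500)),
                 min_size=0, max_size=8)
    )
    def test_adding_a_qualifying_hit_never_unflags(self, raw):
        """Classification is monotone in the hit set."""
        hits = [bact("s", s, min(s + 100, 1000), bitscore=b) for s, b in raw]
        call0 = classify_contaminants([scaffold_metrics(hits, "s", 1000)])[0][0].call
        hits.append(bact("s", 0, 100))
        call1 = classify_contaminants([scaffold_metrics(hits, "s", 1000)])[0][0].call
        assert not (call0 == "contaminant" and call1 == "clean")


class TestFamilySummary:
    def test_single_hit_single_family(self):
        df = family_summary([bact("s", 0, 500)])
        assert df.iloc[0].tolist() == ["FamA", 500, 1]
        assert df.iloc[-1].tolist() == ["Total", 500, 1]

    def test_scaffold_with_two_families_counts_once_per_family(self):
        hits = [bact("s", 0, 300, family="FamA"),
                bact("s", 500, 800, family="FamB")]
        df = family_summary(hits)
        body = df[df.family != "Total"]
        assert body.n_scaffolds_affected.tolist() == [1, 1]
        assert int(df[df.family == "Total"].n_scaffolds_affected.iloc[0]) == 2

    def test_empty_family_binned_as_others(self):
        df = family_summary([bact("s", 0, 100, family="")])
        assert df.iloc[0].family == "Others"

    @given(
        st.lists(
            st.tuples(st.integers(0, 3), st.integers(0, 2), st.integers(0, 900)),
            min_size=1, max_size=25,
        )
    )
    def test_totals_row_equals_column_sums(self, raw):
        hits = [
            bact(f"s{sc}", p, p + 100, family=f"Fam{fam}")
            for fam, sc, p in raw
        ]
        df = family_summary(hits)
        body = df[df.family != "Total"]
        total = df[df.family == "Total"].iloc[0]
        assert total.total_bp == body.total_bp.sum()
        assert total.n_scaffolds_affected == body.n_scaffolds_affected.sum()


class TestPlantedRecovery:
    def test_noise_free_screen_recovers_exactly_the_planted_contaminants(self):
        p = SimParams(
            seed=21, n_host=12,
            contaminants={"Erwiniaceae": 4, "Rickettsiaceae": 3, "Yersiniaceae": 2},
            contaminant_truth_fraction=0.9,
        )
        recs, *_rest, truth = build_truth_assembly(p)
        hits = fabricate_hit_table(recs, truth, noise=(0.0, 50.0), seed=21)
        _metrics, removal = screen_assembly(recs, hits)
        assert set(removal) == truth.contaminant_ids()

    def test_subthreshold_noise_does_not_create_false_positives(self):
        p = SimParams(seed=22, n_host=10, contaminants={"Erwiniaceae": 2})
        recs, *_rest, truth = build_truth_assembly(p)
        hits = fabricate_hit_table(recs, truth, noise=(2.0, 50.0), seed=22)
        _metrics, removal = screen_assembly(recs, hits)
        assert set(removal) == truth.contaminant_ids()


class TestToySearch:
    def test_planted_exact_copy_is_found(self):
        subject = ScaffoldRecord("subj", "ATGCCGTAGGCTA" * 20)
        query = ScaffoldRecord(
            "q", "TTTT" * 30 + subject.seq[:200] + "GGGG" * 30
        )
        hits = toy_search([query], [(subject, "FamX", "bacterial")])
        assert hits and max(h.end - h.start for h in hits) >= 200

    def test_no_shared_word_no_hit(self):
        subject = ScaffoldRecord("subj", "A" * 300)
        query = ScaffoldRecord("q", "CG" * 150)
        assert toy_search([query], [(subject, "FamX", "bacterial")]) == []

    def test_top_taxon_family_matches_planted_family(self):
        p = SimParams(seed=23, n_host=1, host_length=(3000, 4000),
                      contaminants={"Erwiniaceae": 1},
                      contaminant_length=(1500, 2000))
        recs, *_rest, truth = build_truth_assembly(p)
        contam = next(r for r in recs if r.id in truth.contaminant_ids())
        # subject pool: a slice of the contaminant's own family pool vs an
        # unrelated family pool
        subjects = [
            (ScaffoldRecord("erw_ref", contam.seq[:800]), "Erwiniaceae", "bacterial"),
            (ScaffoldRecord("other_ref", recs[0].seq[:800]), "Other", "bacterial"),
        ]
        hits = toy_search([contam], subjects)
        best = max(hits, key=lambda h: h.bitscore)
        assert best.family == "Erwiniaceae"
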