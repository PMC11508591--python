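"""Column classification, site collapsing, artifact filtering, full screen."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from resistkit.align import TripleAlignment, build_triple
from resistkit.core import ContigContext, ProteinRecord, StrainProteome, TransferAttributes
from resistkit.screen import (
    CALLS,
    MutationReport,
    ScreenConfig,
    classify_columns,
    collapse_sites,
    filter_artifacts,
    find_mismatched_transcripts,
    screen_transcripts,
    site_count_histogram,
)
from resistkit.simulate import (
    apply_truncation_artifacts,
    generate_ancestral_proteome,
    plant_mutations,
)


def triple(sus, res, ref, present=True, tid="g1.t1"):
    return TripleAlignment(
        transcript_id=tid, susceptible=sus, resistant=res, reference=ref,
        reference_present=present,
    )


def _proteome(strain, **seqs):
    p = StrainProteome(strain=strain)
    for tid, seq in seqs.items():
        p.add(ProteinRecord(tid, tid, strain, seq))
    return p


class TestFindMismatched:
    def test_identical_proteomes_give_empty_list(self):
        a = _proteome("susceptible", t1="MKVLA")
        b = _proteome("resistant", t1="MKVLA")
        assert find_mismatched_transcripts(a, b) == []

    def test_planted_differences_found_exactly(self, small_triple_proteomes):
        sus, res, _, truth = small_triple_proteomes
        expected = sorted(
            {
                s.transcript_id
                for s in truth.sites
                if s.site_class != "reference_specific"  # those leave sus == res
            }
        )
        assert find_mismatched_transcripts(sus, res) == expected

    def test_attribute_flag_is_authoritative_over_sequence(self):
        a = _proteome("susceptible", t1="MKVLA")
        b = _proteome("resistant", t1="MKVLA")
        attrs = [TransferAttributes("t1", matches_ref_protein=False)]
        assert find_mismatched_transcripts(a, b, attrs) == ["t1"]

    def test_no_shared_ids_is_an_error(self):
        a = _proteome("susceptible", t1="MKVLA")
        b = _proteome("resistant", t2="MKVLA")
        with pytest.raises(ValueError, match="share no transcript"):
            find_mismatched_transcripts(a, b)


class TestClassifyColumns:
    @pytest.mark.parametrize(
        "col,expected",
        [
            (("L", "I", "L"), "resistant_specific_sub"),  # the kdr-style L-to-I change
            (("A", "A", "A"), "conserved"),
            (("A", "W", "G"), "triallelic"),
            (("A", "-", "A"), "resistant_specific_gap"),
            (("-", "A", "-"), "resistant_specific_gap"),  # insertion polarity
            (("G", "A", "A"), "susceptible_specific"),
            (("-", "A", "A"), "susceptible_specific"),
            (("A", "A", "G"), "reference_specific"),
            (("A", "A", "-"), "reference_specific"),
            (("X", "A", "A"), "unclassified"),
            (("A", "X", "A"), "unclassified"),
            (("A", "-", "G"), "triallelic"),
        ],
    )
    def test_single_column_rules(self, col, expected):
        s, r, f = col
        calls = classify_columns(triple(s, r, f))
        assert [c.call for c in calls] == [expected]

    def test_every_column_gets_exactly_one_valid_call(self):
        t = build_triple("MKVLAXDGH", "MKILADGH", "MKVLAXDGG")
        calls = classify_columns(t)
        assert len(calls) == t.n_columns
        assert all(c.call in CALLS for c in calls)
        assert [c.column for c in calls] == list(range(1, t.n_columns + 1))

    def test_two_way_calls_downgrade_without_reference(self):
        t = build_triple("MKVLA", "MKILA", None)
        calls = classify_columns(t)
        assert [c.call for c in calls if c.call != "conserved"] == ["unclassified"]

    def test_two_way_calls_kept_when_allowed(self):
        t = build_triple("MKVLA", "MKILA", None)
        calls = classify_columns(t, allow_two_way=True)
        assert [c.call for c in calls][2] == "resistant_specific_sub"

    @given(
        cols=st.lists(
            st.tuples(
                st.sampled_from("ACDG-"), st.sampled_from("ACDG-"), st.sampled_from("ACDG-")
            ).filter(lambda c: c != ("-", "-", "-")),
            min_size=1,
            max_size=20,
        )
    )
    def test_swapping_strains_mirrors_specific_calls(self, cols):
        sus = "".join(c[0] for c in cols)
        res = "".join(c[1] for c in cols)
        ref = "".join(c[2] for c in cols)
        fwd = classify_columns(triple(sus, res, ref))
        rev = classify_columns(triple(res, sus, ref))
        mirror = {
            "resistant_specific_sub": {"susceptible_specific"},
            "resistant_specific_gap": {"susceptible_specific"},
            "susceptible_specific": {"resistant_specific_sub", "resistant_specific_gap"},
        }
        for f, r in zip(fwd, rev):
            if f.call in mirror:
                assert r.call in mirror[f.call]
            else:
                assert r.call == f.call


class TestCollapseSites:
    def test_two_isolated_substitutions_are_two_sites(self):
        t = triple("MKVLAKDGH", "MKILAKDGW", "MKVLAKDGH")
        sites = collapse_sites(classify_columns(t), "g1.t1")
        assert [(s.start, s.kind) for s in sites] == [
            (3, "substitution"),
            (9, "substitution"),
        ]

    def test_gap_run_collapses_to_one_indel(self):
        t = triple("MKVLADGH", "MKV---GH", "MKVLADGH")
        sites = collapse_sites(classify_columns(t), "g1.t1")
        assert [(s.start, s.end, s.kind) for s in sites] == [(4, 6, "indel")]
        assert sites[0].resistant == "---" and sites[0].susceptible == "LAD"

    def test_adjacent_sub_and_gap_run_stay_separate(self):
        t = triple("MKVLADGH", "MKW--DGH", "MKVLADGH")
        sites = collapse_sites(classify_columns(t), "g1.t1")
        assert [(s.kind) for s in sites] == ["substitution", "indel"]

    def test_per_column_mode_splits_runs(self):
        t = triple("MKVLADGH", "MKV---GH", "MKVLADGH")
        sites = collapse_sites(classify_columns(t), "g1.t1", indel_counting="per_column")
        assert len(sites) == 3 and all(s.kind == "indel" for s in sites)

    def test_nonresistant_calls_yield_no_sites(self):
        t = triple("MAVLA", "MKVLG", "MKVLW")  # sus-specific + triallelic
        assert collapse_sites(classify_columns(t), "g1.t1") == []


def _context(near_start=True, length=1_000_000, gene_bp=300):
    if near_start:
        return ContigContext("c", length, 200, 200 + gene_bp)
    return ContigContext("c", length, length - 200 - gene_bp, length - 200)


class TestFilterArtifacts:
    def _report_for(self, sus, res, tid="g1.t1"):
        t = build_triple(sus, res, sus, transcript_id=tid)
        sites = collapse_sites(classify_columns(t), tid)
        rep = MutationReport(
            transcript_id=tid, gene_id="g1", sites=sites,
            included=bool(sites), n_columns=t.n_columns,
        )
        return rep, t

    def test_intact_record_passes_unchanged(self):
        sus = "MKVLADGHWKL"
        res = "MKILADGHWKL"
        rep, t = self._report_for(sus, res)
        rec = ProteinRecord("g1.t1", "g1", "resistant", res)
        out = filter_artifacts(rep, rec, triple=t)
        assert out.artifact_flags == set() and out.included and out.n_sites == 1

    def test_terminal_gap_only_truncation_is_excluded(self):
        sus = "MKVLADGHWKL"
        res = sus[4:]  # prefix-truncated: leading gap run only
        rep, t = self._report_for(sus, res)
        rec = ProteinRecord("g1.t1", "g1", "resistant", res, cds_complete=False)
        out = filter_artifacts(rep, rec, context=_context(near_start=True), triple=t)
        assert {"missing_start", "contig_end"} <= out.artifact_flags
        assert out.n_sites == 0 and not out.included

    def test_internal_site_survives_terminal_artifact(self):
        sus = "MKVLADGHWKLAADDE"
        res = sus[4:10] + "W" + sus[11:]  # truncated prefix + internal sub
        rep, t = self._report_for(sus, res)
        rec = ProteinRecord("g1.t1", "g1", "resistant", res, cds_complete=False)
        out = filter_artifacts(rep, rec, context=_context(near_start=True), triple=t)
        assert out.included and out.n_sites == 1
        assert out.sites[0].kind == "substitution"

    def test_truncation_far_from_contig_end_keeps_sites(self):
        sus = "MKVLADGHWKL"
        res = sus[4:]
        rep, t = self._report_for(sus, res)
        rec = ProteinRecord("g1.t1", "g1", "resistant", res, cds_complete=False)
        ctx = ContigContext("c", 1_000_000, 500_000, 500_300)
        out = filter_artifacts(rep, rec, context=ctx, triple=t)
        # no fragmentation evidence: the terminal deletion counts as real
        assert "contig_end" not in out.artifact_flags
        assert out.n_sites == 1 and out.included

    def test_suffix_truncation_near_contig_end_is_excluded(self):
        sus = "MKVLADGHWKL"
        res = sus[:-4]
        rep, t = self._report_for(sus, res)
        rec = ProteinRecord("g1.t1", "g1", "resistant", res, cds_complete=False)
        out = filter_artifacts(rep, rec, context=_context(near_start=False), triple=t)
        assert {"missing_stop", "contig_end"} <= out.artifact_flags
        assert out.n_sites == 0 and not out.included


class TestScreenTranscripts:
    def test_null_planting_includes_nothing(self):
        anc = generate_ancestral_proteome(10, (30, 40), seed=31)
        sus, res, ref, _ = plant_mutations(anc, {}, seed=32)
        reports = screen_transcripts(sus, res, ref)
        assert reports == []

    def test_planted_recovery_with_exact_site_totals(self):
        anc = generate_ancestral_proteome(60, (40, 60), seed=33)
        sus, res, ref, truth = plant_mutations(
            anc, {"resistant_specific_sub": 10, "susceptible_specific": 7}, seed=34
        )
        reports = screen_transcripts(sus, res, ref)
        included = [r for r in reports if r.included]
        assert {r.transcript_id for r in included} == truth.resistant_transcripts()
        assert sum(r.n_sites for r in included) == 10
        for rep in reports:
            for site in rep.sites:
                assert site.kind == "substitution"

    def test_mixed_classes_report_only_resistant_sites(self, small_triple_proteomes):
        sus, res, ref, truth = small_triple_proteomes
        reports = screen_transcripts(sus, res, ref)
        assert {r.transcript_id for r in reports if r.included} == truth.resistant_transcripts()

    def test_truncation_artifacts_are_filtered(self):
        anc = generate_ancestral_proteome(40, (40, 60), seed=35)
        sus, res, ref, truth = plant_mutations(
            anc, {"resistant_specific_sub": 8}, seed=36
        )
        res2, trunc = apply_truncation_artifacts(res, fraction=0.5, max_cut=5, seed=37)
        # attributes list only covers truncated transcripts, so mismatch
        # discovery runs on sequence comparison; contexts drive the filter
        reports = screen_transcripts(sus, res2, ref, contexts=trunc.contexts)
        included = {r.transcript_id for r in reports if r.included}
        # truncated transcripts with no planted site must not be included
        artifact_only = set(trunc.truncated) - truth.resistant_transcripts()
        assert included & artifact_only == set()
        # planted sites survive truncation of the same transcript
        assert truth.resistant_transcripts() <= included | set()

    def test_missing_reference_transcript_flagged_and_excluded(self):
        sus = _proteome("susceptible", t1="MKVLADGHWKL")
        res = _proteome("resistant", t1="MKILADGHWKL")
        ref = StrainProteome(strain="reference")
        reports = screen_transcripts(sus, res, ref)
        assert reports[0].artifact_flags == {"no_reference"}
        assert not reports[0].included

    def test_best_hit_ortholog_mode(self):
        sus = _proteome("susceptible", t1="MKVLADGHWKLMKVLADGH")
        res = _proteome("resistant", t1="MKILADGHWKLMKVLADGH")
        ref = _proteome(
            "reference",
            r1="MKVLADGHWKLMKVLADGH",
            r2="WWWWADGHAAAAKVLAAAA",
        )
        reports = screen_transcripts(
            sus, res, ref, config=ScreenConfig(ortholog="best_hit")
        )
        assert reports[0].included and reports[0].n_sites == 1


class TestSiteCountHistogram:
    def test_empty_when_nothing_included(self):
        assert site_count_histogram([]) == {}

    def test_counts_and_conservation(self):
        reps = [
            MutationReport("a", "a", sites=[], included=False),
            MutationReport(
                "b", "b",
                sites=[_site("b", 3)], included=True,
            ),
            MutationReport(
                "c", "c",
                sites=[_site("c", 3), _site("c", 7)], included=True,
            ),
            MutationReport(
                "d", "d",
                sites=[_site("d", 4)], included=True,
            ),
        ]
        hist = site_count_histogram(reps)
        assert hist == {1: 2, 2: 1}
        assert sum(hist.values()) == sum(1 for r in reps if r.included)


def _site(tid, col):
    from resistkit.screen import MutationSite

    return MutationSite(tid, col, col, "substitution", "L", "I", "L")
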