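"""Annotation loading, variant assignment, summaries, prediction scoring."""

import numpy as np
import pytest

from promoterpath.errors import AmbiguousWindowError, InputError
from promoterpath.observed_data import (
    NON_PROMOTER,
    NO_LANDSCAPE_CAVEAT,
    VariantObservation,
    assign_variant_to_promoter,
    compare_to_prediction,
    load_promoter_annotation,
    load_promoter_annotation_gff3,
    load_variant_table,
    resolve_promoters,
    summarize_observations,
    write_promoter_annotation,
    write_variant_table,
)
from promoterpath.passage_sim import PromoterLocus
from promoterpath.synthetic_data import (
    make_annotation_fixture,
    make_observed_fixture,
)

SRC, DST = "GAC", "CGG"


# ---------------------------------------------------------------------------
# Annotation fixtures and I/O
# ---------------------------------------------------------------------------

def test_deletion_variant_annotation_has_16_promoters(loci_delta1):
    assert len(loci_delta1) == 16


def test_wildtype_annotation_17_promoters_15_with_consensus(loci_wildtype):
    assert len(loci_wildtype) == 17
    assert sum(l.ancestral_triplet == SRC for l in loci_wildtype) == 15
    assert sum(l.ancestral_triplet == "AAC" for l in loci_wildtype) == 2


def test_deletion_removes_exactly_the_first_promoter(loci_delta1, loci_wildtype):
    diff = {l.name for l in loci_wildtype} - {l.name for l in loci_delta1}
    assert diff == {"phi1.1A"}


def test_annotation_tsv_round_trip(tmp_path, loci_delta1):
    path = tmp_path / "annotation.tsv"
    write_promoter_annotation(loci_delta1, path, header_comment="fixture")
    assert load_promoter_annotation(path) == loci_delta1


def test_annotation_duplicate_name_reports_line_number(tmp_path):
    path = tmp_path / "dup.tsv"
    path.write_text(
        "name\tgenome_start\tstrand\tancestral_triplet\tweight\n"
        "pA\t100\t+\tGAC\t1\n"
        "pA\t500\t+\tGAC\t1\n"
    )
    with pytest.raises(InputError, match=r"dup\.tsv:3"):
        load_promoter_annotation(path)


def test_annotation_malformed_row_reports_line_number(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text(
        "name\tgenome_start\tstrand\tancestral_triplet\tweight\n"
        "pA\tnot_a_number\t+\tGAC\t1\n"
    )
    with pytest.raises(InputError, match=r"bad\.tsv:2"):
        load_promoter_annotation(path)


def test_empty_annotation_warns_and_returns_empty(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text("# nothing here\n")
    with pytest.warns(UserWarning):
        assert load_promoter_annotation(path) == []


def test_gff3_annotation_reader(tmp_path):
    path = tmp_path / "promoters.gff3"
    path.write_text(
        "##gff-version 3\n"
        "genome\tfixture\tpromoter\t7761\t7783\t.\t+\t.\t"
        "ID=p1;Name=phi1.5;triplet=GAC;weight=1.0\n"
        "genome\tfixture\tgene\t100\t900\t.\t+\t.\tID=g1\n"
        "genome\tfixture\tpromoter\t9090\t9112\t.\t+\t.\t"
        "ID=p2;Name=phi2.5;triplet=GAC;weight=2.0\n"
    )
    loci = load_promoter_annotation_gff3(path)
    assert [l.name for l in loci] == ["phi1.5", "phi2.5"]
    assert loci[0].genome_start == 7761
    assert loci[1].weight == 2.0


# ---------------------------------------------------------------------------
# Variant -> promoter assignment
# ---------------------------------------------------------------------------

def test_assignment_window_arithmetic(loci_delta1):
    # phi1.5 starts at 7761; the specificity triplet occupies offsets 6..8
    # of the 23-nt promoter, i.e. genome positions 7767-7769.
    for pos in (7767, 7768, 7769):
        assert assign_variant_to_promoter(pos, loci_delta1) == "phi1.5"
    assert assign_variant_to_promoter(7766, loci_delta1) == NON_PROMOTER
    assert assign_variant_to_promoter(7770, loci_delta1) == NON_PROMOTER


def test_assignment_far_upstream_is_non_promoter(loci_delta1):
    assert assign_variant_to_promoter(1, loci_delta1) == NON_PROMOTER


def test_assignment_minus_strand_window_mirrors():
    locus = PromoterLocus("pRev", 1000, "-", SRC)
    # promoter spans 1000..1022; motif at offsets 6..8 from the 3' end
    assert locus.motif_window() == (1014, 1016)
    assert assign_variant_to_promoter(1015, [locus]) == "pRev"


def test_assignment_overlapping_windows_is_ambiguous():
    loci = [
        PromoterLocus("pA", 100, "+", SRC),
        PromoterLocus("pB", 101, "+", SRC),
    ]
    with pytest.raises(AmbiguousWindowError):
        assign_variant_to_promoter(107, loci)


def test_resolve_promoters_accepts_positions_and_rejects_unknown(loci_delta1):
    obs = [VariantObservation("line1", 50, "7768", "GAG", 50.0)]
    resolved = resolve_promoters(obs, loci_delta1)
    assert resolved[0].promoter == "phi1.5"
    with pytest.raises(InputError):
        resolve_promoters(
            [VariantObservation("line1", 50, "phiXX", "GAG", 50.0)], loci_delta1
        )


# ---------------------------------------------------------------------------
# Summaries of the in-record observation fixture
# ---------------------------------------------------------------------------

def test_fixture_yields_five_evolved_promoters(observed_fixture, loci_delta1):
    summary = summarize_observations(observed_fixture, loci_delta1)
    assert summary.n_evolved_promoters == 5
    assert summary.evolved_promoters == [
        "phi1.5", "phi2.5", "phi6.5", "phiOL", "phiOR"
    ]
    assert summary.n_promoters == 16


def test_fixture_phi15_fixed_at_gag_in_all_four_lines(observed_fixture, loci_delta1):
    summary = summarize_observations(observed_fixture, loci_delta1)
    assert summary.fixed_lines_by_promoter["phi1.5"]["GAG"] == [
        "line1", "line2", "line3", "line4"
    ]


def test_fixture_phi25_gag_does_not_fix(observed_fixture, loci_delta1):
    summary = summarize_observations(observed_fixture, loci_delta1)
    assert "phi2.5" not in summary.fixed_lines_by_promoter


def test_fixture_duplications_recorded(observed_fixture, loci_delta1):
    summary = summarize_observations(observed_fixture, loci_delta1)
    assert summary.duplicated_promoters == ["phi6.5", "phiOL"]


def test_empty_observation_table_gives_zero_counts(loci_delta1):
    summary = summarize_observations([], loci_delta1)
    assert summary.n_evolved_promoters == 0
    assert summary.evolved_promoters == []


# ---------------------------------------------------------------------------
# Prediction comparison
# ---------------------------------------------------------------------------

def test_comparison_finds_three_unanticipated_triplets(
    observed_fixture, loci_delta1, noiseless_landscape
):
    report = compare_to_prediction(
        observed_fixture, loci_delta1, noiseless_landscape, SRC, DST
    )
    assert report.unanticipated_triplets == ["AAG", "CCC", "GCC"]
    assert report.counts["unanticipated"] == 3


def test_comparison_label_partition_is_consistent(
    observed_fixture, loci_delta1, noiseless_landscape
):
    report = compare_to_prediction(
        observed_fixture, loci_delta1, noiseless_landscape, SRC, DST
    )
    c = report.counts
    assert (
        c["predicted"] + c["unanticipated"] + c["ancestral"] + c["target"]
        == c["distinct_triplets"]
    )


def test_comparison_flags_unmeasured_background(
    observed_fixture, loci_delta1, noiseless_landscape
):
    report = compare_to_prediction(
        observed_fixture, loci_delta1, noiseless_landscape, SRC, DST
    )
    ol_rows = report.labels[report.labels.promoter == "phiOL"]
    assert (ol_rows.caveat == NO_LANDSCAPE_CAVEAT).all()
    assert (ol_rows.background == "AAC").all()
    main_rows = report.labels[report.labels.background == SRC]
    assert (main_rows.caveat == "").all()


def test_comparison_classifies_alt_background_against_own_ancestor(
    observed_fixture, loci_delta1, noiseless_landscape
):
    report = compare_to_prediction(
        observed_fixture, loci_delta1, noiseless_landscape, SRC, DST
    )
    agc = report.labels[
        (report.labels.promoter == "phiOL")
        & (report.labels.observed_triplet == "AGC")
    ]
    # AGC is one step from AAC on the AAC -> CGG sub-cube
    assert (agc.label == "predicted_single").all()


def test_comparison_invariant_to_row_order(
    observed_fixture, loci_delta1, noiseless_landscape
):
    rng = np.random.default_rng(31)
    shuffled = list(observed_fixture)
    rng.shuffle(shuffled)
    a = compare_to_prediction(observed_fixture, loci_delta1, noiseless_landscape, SRC, DST)
    b = compare_to_prediction(shuffled, loci_delta1, noiseless_landscape, SRC, DST)
    assert a.labels.equals(b.labels)
    assert a.counts == b.counts
    assert a.text_summary() == b.text_summary()


def test_ancestral_observations_do_not_count_as_evolution(loci_delta1):
    obs = [VariantObservation("line1", 50, "phi6.5", SRC, 40.0)]
    summary = summarize_observations(obs, loci_delta1)
    assert summary.n_evolved_promoters == 0


# ---------------------------------------------------------------------------
# Table round trips
# ---------------------------------------------------------------------------

def test_variant_table_round_trip_preserves_summaries(
    tmp_path, observed_fixture, loci_delta1
):
    path = tmp_path / "observations.tsv"
    write_variant_table(observed_fixture, path, header_comment="fixture")
    back = load_variant_table(path)
    assert back == observed_fixture
    a = summarize_observations(observed_fixture, loci_delta1)
    b = summarize_observations(back, loci_delta1)
    assert a == b


def test_variant_table_reporting_floor(tmp_path):
    obs = [
        VariantObservation("line1", 50, "pA", "GAG", 1.0),
        VariantObservation("line1", 50, "pA", "GGG", 50.0),
    ]
    path = tmp_path / "obs.tsv"
    write_variant_table(obs, path)
    kept = load_variant_table(path, reporting_floor_pct=2.0)
    assert [o.observed_triplet for o in kept] == ["GGG"]


def test_variant_observation_validates_frequency():
    with pytest.raises(InputError):
        VariantObservation("line1", 50, "pA", "GAG", 101.0)
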