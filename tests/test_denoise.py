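"""Tag families, single-indel merging, the 2-read-bin histogram, the
smoothed 90% threshold and the monitoring estimators."""

import numpy as np
import pytest

from noirseq import denoise
from noirseq.denoise import (
    TagFamily,
    TagHistogram,
    build_histogram,
    estimate_bdhv_errors,
    estimate_removed_error_free,
    find_threshold,
    group_and_merge,
    remove_erroneous,
    single_deletions,
    single_insertions,
    smooth_proportions,
)


def _fam(tag, n):
    return TagFamily(tag, member_read_ids=[f"{tag}:{i}" for i in range(n)])


# grouping and merging -------------------------------------------------------

def test_single_indel_variants_merge_into_12bp_family():
    """An 11-bp single-deletion variant and a 13-bp single-insertion
    variant both join their parent 12-bp family."""
    canonical = "TGCATGATTACG"
    reads = (
        [(f"c{i}", canonical) for i in range(5)]
        + [("d0", "TGCATGATACG")]       # one T deleted
        + [("i0", "TGCATGGATTACG")]     # one G inserted
    )
    fams = group_and_merge(reads)
    assert len(fams) == 1
    assert fams[0].canonical_tag == canonical
    assert fams[0].n_reads == 7
    assert sorted(fams[0].merged_from) == ["TGCATGATACG", "TGCATGGATTACG"]


def test_tags_shorter_than_9bp_discarded():
    fams = group_and_merge([("a", "ACGTACGT"), ("b", "ACGTACGTA")])
    assert [f.canonical_tag for f in fams] == ["ACGTACGTA"]


def test_12bp_tags_never_merge_with_each_other():
    t1, t2 = "A" * 12, "A" * 11 + "C"
    fams = group_and_merge([("a", t1), ("b", t2)])
    assert len(fams) == 2


def test_ambiguous_variant_goes_to_largest_family():
    """A variant with several candidate parents joins the parent with the
    most reads (brute-force insertion enumeration finds the candidates)."""
    variant = "ACGTACGTACG"  # 11 bp
    parents = sorted(p for p in single_insertions(variant) if len(p) == 12)
    p_small, p_big = parents[0], parents[-1]
    reads = (
        [(f"b{i}", p_big) for i in range(5)]
        + [(f"s{i}", p_small) for i in range(2)]
        + [("v0", variant)]
    )
    fams = group_and_merge(reads)
    by_tag = {f.canonical_tag: f for f in fams}
    assert by_tag[p_big].n_reads == 6
    assert by_tag[p_small].n_reads == 2
    # tie on reads -> lexicographically smaller canonical wins
    reads_tie = [("a", p_big), ("b", p_small), ("v", variant)]
    by_tag = {f.canonical_tag: f for f in group_and_merge(reads_tie)}
    assert by_tag[min(p_small, p_big)].n_reads == 2


def test_single_deletion_enumeration_is_exhaustive():
    tag = "ACGT"
    assert single_deletions(tag) == {"CGT", "AGT", "ACT", "ACG"}
    assert all(len(t) == 5 for t in single_insertions(tag))
    # every deletion of every insertion recovers the original
    assert all(tag in single_deletions(t) for t in single_insertions(tag))


# histogram ------------------------------------------------------------------

def test_two_read_bins():
    assert [TagHistogram.bin_of(n) for n in (1, 2, 3, 4, 5)] == [1, 1, 2, 2, 3]
    fams = [_fam("A" * 12, n) for n in (1, 2, 3, 4)]
    hist = build_histogram(fams, 12)
    assert list(hist.totals) == [2, 2]


def test_all_correct_families_give_unit_proportions():
    fams = [_fam("C" * 12, 1), _fam("A" * 12, 5)]
    hist = build_histogram(fams, 12)
    nonempty = hist.totals > 0
    assert np.all(hist.raw_proportion[nonempty] == 1.0)


def test_mixed_bin_proportion():
    fams = [_fam("A" * 12, 1), _fam("C" * 12, 2), _fam("G" * 10, 1)]
    hist = build_histogram(fams, 12)
    assert hist.totals[0] == 3
    assert hist.raw_proportion[0] == pytest.approx(2 / 3)


def test_empty_bins_are_missing_not_zero():
    fams = [_fam("A" * 12, 1), _fam("C" * 12, 9)]
    hist = build_histogram(fams, 12)
    assert np.isnan(hist.raw_proportion[2])


# smoothing ------------------------------------------------------------------

def test_smoothing_preserves_constant_proportion():
    fams = [_fam("ACGTACGTACG" + "ACGT"[i % 4], 2 * k + 1)
            for k in range(30) for i in (0,)]
    hist = build_histogram(fams, 12)
    smooth_proportions(hist)
    nonempty = ~np.isnan(hist.raw_proportion)
    assert np.allclose(hist.smoothed_proportion[nonempty], 1.0)


def test_smoothing_of_step_function():
    """Step 0 -> 1 at bin 50 smooths to 6/11 at the step bin."""
    hist = TagHistogram(
        totals=np.ones(100, dtype=np.int64),
        correct=np.array([0] * 49 + [1] * 51, dtype=np.int64),
        raw_proportion=np.array([0.0] * 49 + [1.0] * 51),
    )
    smooth_proportions(hist)
    assert hist.smoothed_proportion[49] == pytest.approx(6 / 11)
    assert hist.smoothed_proportion[0] == 0.0
    assert hist.smoothed_proportion[99] == 1.0


def test_single_nonempty_bin_smooths_to_itself():
    raw = np.full(20, np.nan)
    raw[7] = 0.4
    hist = TagHistogram(np.zeros(20, np.int64), np.zeros(20, np.int64), raw)
    smooth_proportions(hist)
    assert hist.smoothed_proportion[7] == pytest.approx(0.4)


# threshold ------------------------------------------------------------------

def test_threshold_is_lower_bound_of_first_qualifying_bin():
    n = 40
    hist = TagHistogram(np.ones(n, np.int64), np.ones(n, np.int64),
                        np.full(n, np.nan))
    hist.smoothed_proportion = np.array([0.2] * 20 + [0.95] * 20)
    assert find_threshold(hist) == 41  # bin 21 -> 2*21 - 1


def test_threshold_when_all_bins_qualify_is_one():
    hist = TagHistogram(np.ones(5, np.int64), np.ones(5, np.int64),
                        np.full(5, np.nan))
    hist.smoothed_proportion = np.full(5, 0.95)
    assert find_threshold(hist) == 1


def test_no_qualifying_bin_raises():
    hist = TagHistogram(np.ones(5, np.int64), np.zeros(5, np.int64),
                        np.full(5, np.nan))
    hist.smoothed_proportion = np.full(5, 0.5)
    with pytest.raises(denoise.ThresholdNotFound):
        find_threshold(hist)


def test_strict_mode_skips_non_persistent_bins():
    hist = TagHistogram(np.ones(6, np.int64), np.ones(6, np.int64),
                        np.full(6, np.nan))
    hist.smoothed_proportion = np.array([0.95, 0.5, 0.95, 0.95, 0.95, 0.95])
    assert find_threshold(hist) == 1
    assert find_threshold(hist, strict=True) == 5  # bin 3


# removal and estimators -----------------------------------------------------

def test_removal_at_threshold_boundary():
    fams = [_fam("A" * 12, 10), _fam("C" * 12, 11), _fam("G" * 12, 50)]
    accepted, removed = remove_erroneous(fams, 11)
    assert [f.n_reads for f in removed] == [10]
    assert sorted(f.n_reads for f in accepted) == [11, 50]
    accepted, removed = remove_erroneous(fams, 1)
    assert not removed and len(accepted) == 3


def test_conservation_accepted_plus_removed(ion_run):
    assert len(ion_run.accepted) + len(ion_run.removed) == len(ion_run.families)


def test_thresholding_does_not_reduce_precision(ion_run):
    true_barcodes = {rec.barcode for rec in ion_run.truth}
    raw = np.mean([f.canonical_tag in true_barcodes for f in ion_run.families])
    acc = np.mean([f.canonical_tag in true_barcodes for f in ion_run.accepted])
    assert acc >= raw


def test_threshold_separates_error_and_true_tag_populations(ion_run):
    """M falls between the erroneous-tag peak (singletons) and the
    true-tag read-count distribution known from the truth table."""
    true_barcodes = {rec.barcode for rec in ion_run.truth}
    true_counts = [f.n_reads for f in ion_run.families
                   if f.canonical_tag in true_barcodes]
    err_counts = [f.n_reads for f in ion_run.families
                  if f.canonical_tag not in true_barcodes]
    assert np.median(err_counts) < ion_run.threshold_M <= np.percentile(true_counts, 5)


def test_removed_error_free_bound_counts_correct_families_in_M_2M():
    fams = [_fam("A" * 12, 12), _fam("C" * 12, 15), _fam("G" * 10, 14),
            _fam("T" * 12, 22), _fam("AC" * 6, 3)]
    bound, frac = estimate_removed_error_free(fams, 11)
    assert bound == 2  # the 12- and 15-read 12-bp families; 22 >= 2M
    assert frac == pytest.approx(2 / 4)
    assert estimate_removed_error_free([_fam("A" * 12, 30)], 11)[0] == 0


# BDHV scheme ----------------------------------------------------------------

def test_bdhv_banned_base_flags_tag():
    clean = "CGTACGTACGTACGT"  # allowed at every BDHV position
    assert denoise.is_bdhv_clean(clean)
    flagged = "A" + clean[1:]  # A at a B position certifies an error
    assert denoise.bdhv_flagged(flagged)
    assert not denoise.is_bdhv_clean(flagged)


def test_bdhv_estimate_is_three_times_flagged():
    clean = "CGTACGTACGTACGT"
    flagged_b = "A" + clean[1:]            # banned A at a B position
    flagged_d = clean[0] + "C" + clean[2:]  # banned C at a D position
    fams = [_fam(clean, 5), _fam(flagged_b, 1), _fam(flagged_d, 1)]
    assert estimate_bdhv_errors(fams) == 6
    assert estimate_bdhv_errors([_fam(clean, 5)]) == 0
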