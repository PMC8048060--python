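import numpy as np
import pytest

from barcodegap.distances import DistanceMatrix, distance_matrix
from barcodegap.errors import DataError
from barcodegap.summary import (
    BetweenRange,
    WithinRange,
    between_species_ranges,
    estimate_cutoff,
    summarize,
    within_species_ranges,
)

from conftest import make_alignment, make_labels


def dm_from(ids, dists):
    """Build a DistanceMatrix from a dict of unordered pairs -> distance."""
    n = len(ids)
    d = np.zeros((n, n))
    ns = np.full((n, n), 100, dtype=np.int64)
    for (a, b), v in dists.items():
        i, j = ids.index(a), ids.index(b)
        d[i, j] = d[j, i] = v
        if np.isnan(v):
            ns[i, j] = ns[j, i] = 0
    return DistanceMatrix(tuple(ids), d, ns)


class TestWithinRanges:
    def test_single_pair_species(self):
        dm = dm_from(["a", "b"], {("a", "b"): 0.012})
        within, singles = within_species_ranges(dm, make_labels({"a": ("X",), "b": ("X",)}))
        assert within["X"] == WithinRange("X", 0.012, 0.012, 1)
        assert singles == ()

    def test_singleton_excluded(self):
        dm = dm_from(["a", "b", "c"], {("a", "b"): 0.01, ("a", "c"): 0.05, ("b", "c"): 0.05})
        labels = make_labels({"a": ("X",), "b": ("X",), "c": ("Y",)})
        within, singles = within_species_ranges(dm, labels)
        assert "Y" not in within
        assert singles == ("Y",)

    def test_identical_members_zero_range(self):
        aln = make_alignment({"a": "ACGT", "b": "ACGT", "c": "ACGT"})
        labels = make_labels({k: ("X",) for k in "abc"})
        within, _ = within_species_ranges(distance_matrix(aln), labels)
        assert within["X"] == WithinRange("X", 0.0, 0.0, 3)

    def test_undefined_pairs_skipped(self):
        dm = dm_from(["a", "b", "c"], {("a", "b"): np.nan, ("a", "c"): 0.02, ("b", "c"): 0.03})
        within, _ = within_species_ranges(dm, make_labels({k: ("X",) for k in "abc"}))
        assert within["X"].n_pairs == 2
        assert within["X"].min == 0.02


class TestBetweenRanges:
    def test_single_cross_pair(self):
        dm = dm_from(["a", "b"], {("a", "b"): 0.03})
        labels = make_labels({"a": ("X",), "b": ("Y",)})
        between, no_data = between_species_ranges(dm, labels)
        assert between[("X", "Y")] == BetweenRange("X", "Y", 0.03, 0.03, 1)
        assert no_data == ()

    def test_zero_between_reported_not_hidden(self):
        dm = dm_from(["a", "b"], {("a", "b"): 0.0})
        between, _ = between_species_ranges(dm, make_labels({"a": ("X",), "b": ("Y",)}))
        assert between[("X", "Y")].min == 0.0

    def test_three_species_three_pairs(self):
        dm = dm_from(
            ["a", "b", "c"],
            {("a", "b"): 0.02, ("a", "c"): 0.03, ("b", "c"): 0.04},
        )
        labels = make_labels({"a": ("X",), "b": ("Y",), "c": ("Z",)})
        between, _ = between_species_ranges(dm, labels)
        assert len(between) == 3

    def test_fewer_than_two_species_rejected(self):
        dm = dm_from(["a", "b"], {("a", "b"): 0.01})
        with pytest.raises(DataError):
            between_species_ranges(dm, make_labels({"a": ("X",), "b": ("X",)}))


class TestEstimateCutoff:
    WITHIN = {
        "A": WithinRange("A", 0.0, 0.011, 3),
        "B": WithinRange("B", 0.0, 0.013, 3),
    }

    def test_gap_present(self):
        between = {("A", "B"): BetweenRange("A", "B", 0.020, 0.04, 9)}
        cutoff, gap_ok, exceptions = estimate_cutoff(self.WITHIN, between)
        assert cutoff == 0.013
        assert gap_ok is True
        assert exceptions == ()

    def test_overlapping_pair_reported_as_exception(self):
        between = {
            ("A", "B"): BetweenRange("A", "B", 0.010, 0.04, 9),
            ("A", "C"): BetweenRange("A", "C", 0.030, 0.05, 9),
        }
        cutoff, gap_ok, exceptions = estimate_cutoff(self.WITHIN, between)
        assert gap_ok is False
        assert exceptions == (("A", "B"),)

    def test_excluding_high_variance_species_lowers_cutoff(self):
        within = dict(self.WITHIN, C=WithinRange("C", 0.0, 0.05, 3))
        between = {("A", "B"): BetweenRange("A", "B", 0.02, 0.04, 9)}
        cutoff, _, _ = estimate_cutoff(within, between, exclude_species=("C",))
        assert cutoff == 0.013

    def test_all_excluded_is_error(self):
        with pytest.raises(DataError, match="no within-species data"):
            estimate_cutoff(self.WITHIN, {}, exclude_species=("A", "B"))


class TestSummarize:
    def _dataset(self):
        aln = make_alignment(
            {
                "a1": "ACGTACGTAC",
                "a2": "ACGTACGTAT",
                "b1": "TGCATGCAAC",
                "b2": "TGCATGCAAT",
                "c1": "AAAATTTTCC",
            }
        )
        labels = make_labels(
            {"a1": ("A",), "a2": ("A",), "b1": ("B",), "b2": ("B",), "c1": ("C",)}
        )
        return aln, labels

    def test_full_summary(self):
        aln, labels = self._dataset()
        summ = summarize(distance_matrix(aln), labels)
        assert summ.excluded_singletons == ("C",)
        assert summ.cutoff == 0.1  # one mismatch in ten columns
        assert summ.gap_ok is True

    def test_invariant_under_sequence_permutation(self):
        aln, labels = self._dataset()
        base = summarize(distance_matrix(aln), labels)
        perm = ["c1", "b2", "a1", "b1", "a2"]
        aln2 = aln.subset(perm)
        labels2 = make_labels({i: (labels.species_of(i),) for i in perm})
        other = summarize(distance_matrix(aln2), labels2)
        assert other.within == base.within
        assert {frozenset(k) for k in other.between} == {frozenset(k) for k in base.between}
        assert other.cutoff == base.cutoff
        assert other.gap_ok == base.gap_ok

    def test_tsv_and_json_outputs(self, tmp_path):
        aln, labels = self._dataset()
        summ = summarize(distance_matrix(aln), labels)
        tsv = tmp_path / "summary.tsv"
        summ.write_tsv(tsv)
        text = tsv.read_text()
        assert "# within species" in text and "# between species" in text
        assert "10.00" in text  # percent with 2 decimals
        js = tmp_path / "summary.json"
        summ.write_json(js)
        assert '"gap_ok": true' in js.read_text()
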