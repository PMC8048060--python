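import numpy as np
import pytest

from barcodegap.alphabet import IUPAC_SETS
from barcodegap.diagnostics import (
    assemble_fragments,
    column_profiles,
    diagnostic_columns,
    find_diagnostic_fragments,
    species_consensus,
)
from barcodegap.errors import DataError

from conftest import make_alignment, make_labels


def set_profiles(alignment, labels):
    """Independent residue-set oracle built with plain Python sets."""
    groups = labels.ids_by_species()
    out = {}
    for sp, ids in groups.items():
        per_col = []
        for c in range(alignment.n_columns):
            s = set()
            for sid in ids:
                ch = alignment.row(sid)[c]
                if ch != "-":
                    s |= set(IUPAC_SETS[ch])
            per_col.append(frozenset(s))
        out[sp] = per_col
    return out


def oracle_diagnostic_columns(alignment, labels, target):
    """Brute-force disjointness check per column (1-based)."""
    profiles = set_profiles(alignment, labels)
    others = [p for sp, p in profiles.items() if sp != target]
    cols = []
    for c in range(alignment.n_columns):
        mine = profiles[target][c]
        union = set().union(*(p[c] for p in others))
        if mine and not (mine & union):
            cols.append(c + 1)
    return cols


def oracle_fragments(diag_cols, min_diag, merge_gap):
    """Exhaustive window enumeration: all (start, end) with diagnostic ends,
    internal merge gaps <= merge_gap, >= min_diag diagnostic columns, maximal.
    Returns (start, end, n_diag) tuples."""
    cols = sorted(diag_cols)
    valid = []
    for i in range(len(cols)):
        for j in range(i, len(cols)):
            window = cols[i : j + 1]
            if len(window) < min_diag:
                continue
            if all(b - a - 1 <= merge_gap for a, b in zip(window, window[1:])):
                valid.append((window[0], window[-1], len(window)))
    maximal = [
        w for w in valid
        if not any(
            v != w and v[0] <= w[0] and w[1] <= v[1] for v in valid
        )
    ]
    return sorted(maximal)


def two_species(diag_cols, L, members=2):
    """Alignment where species S carries C exactly at diag_cols, T carries A
    everywhere, so S's diagnostic columns are exactly diag_cols."""
    s_row = "".join("C" if c + 1 in diag_cols else "A" for c in range(L))
    rows = {f"s{i}": s_row for i in range(members)}
    rows.update({f"t{i}": "A" * L for i in range(members)})
    labels = make_labels(
        {**{f"s{i}": ("S",) for i in range(members)},
         **{f"t{i}": ("T",) for i in range(members)}}
    )
    return make_alignment(rows), labels


class TestColumnProfiles:
    def test_residue_union_and_gaps(self):
        aln = make_alignment({"x1": "AA", "x2": "A-", "x3": "TA"})
        labels = make_labels({k: ("X",) for k in ("x1", "x2", "x3")})
        prof = column_profiles(aln, labels)
        assert prof.residue_set("X", 1) == {"A", "T"}
        assert prof.residue_set("X", 2) == {"A"}
        assert prof.gap_counts["X"][1] == 1

    def test_ambiguity_expansion(self):
        aln = make_alignment({"x1": "W"})
        prof = column_profiles(aln, make_labels({"x1": ("X",)}))
        assert prof.residue_set("X", 1) == {"A", "T"}

    def test_species_without_members_rejected(self):
        aln = make_alignment({"x1": "A"})
        with pytest.raises(DataError):
            column_profiles(aln, make_labels({"x1": ("X",)}), species_set=["Y"])


class TestSpeciesConsensus:
    @pytest.mark.parametrize(
        "rows, expected",
        [
            (("A", "A"), "A"),
            (("A", "T"), "W"),
            (("A", "C", "G", "T"), "N"),
            (("-", "-"), "-"),
            (("A", "-"), "A"),
        ],
    )
    def test_minimal_iupac_code(self, rows, expected):
        aln = make_alignment({f"x{i}": r for i, r in enumerate(rows)})
        labels = make_labels({f"x{i}": ("X",) for i in range(len(rows))})
        prof = column_profiles(aln, labels)
        assert species_consensus(prof, "X", 1) == expected


class TestDiagnosticColumns:
    def test_disjoint_residue_is_diagnostic(self):
        aln = make_alignment({"s": "A", "t": "C", "u": "G"})
        labels = make_labels({"s": ("S",), "t": ("T",), "u": ("U",)})
        prof = column_profiles(aln, labels)
        assert diagnostic_columns(prof, "S") == [1]

    def test_shared_base_inside_ambiguity_not_diagnostic(self):
        # S's set {A,T} (coded W) overlaps the other species' {A}
        aln = make_alignment({"s1": "A", "s2": "T", "t1": "A"})
        labels = make_labels({"s1": ("S",), "s2": ("S",), "t1": ("T",)})
        prof = column_profiles(aln, labels)
        assert diagnostic_columns(prof, "S") == []

    def test_all_others_gapped_is_diagnostic(self):
        aln = make_alignment({"s": "C", "t": "-", "u": "-"})
        labels = make_labels({"s": ("S",), "t": ("T",), "u": ("U",)})
        prof = column_profiles(aln, labels)
        assert diagnostic_columns(prof, "S") == [1]
        # the gapped species has an empty set there: not diagnostic for it
        assert diagnostic_columns(prof, "T") == []

    def test_matches_set_oracle_on_random_alignments(self):
        rng = np.random.default_rng(19)
        pool = np.array(list("ACGTACGT-WN"))
        for _ in range(20):
            n_sp = int(rng.integers(2, 5))
            members = int(rng.integers(1, 4))
            L = int(rng.integers(5, 40))
            rows, spec = {}, {}
            for s in range(n_sp):
                for m in range(members):
                    sid = f"sp{s}_m{m}"
                    rows[sid] = "".join(rng.choice(pool, L))
                    spec[sid] = (f"sp{s}",)
            aln, labels = make_alignment(rows), make_labels(spec)
            prof = column_profiles(aln, labels)
            for s in range(n_sp):
                assert diagnostic_columns(prof, f"sp{s}") == oracle_diagnostic_columns(
                    aln, labels, f"sp{s}"
                )


class TestAssembleFragments:
    def test_adjacent_columns_merge(self):
        aln, labels = two_species({10, 11}, L=20)
        prof = column_profiles(aln, labels)
        frags = assemble_fragments([10, 11], prof, "S", min_diag=2, merge_gap=4)
        assert len(frags) == 1
        assert (frags[0].start, frags[0].end, frags[0].n_diagnostic) == (10, 11, 2)
        assert frags[0].sequence == "CC"

    def test_isolated_columns_dropped(self):
        aln, labels = two_species({10, 20}, L=25)
        prof = column_profiles(aln, labels)
        assert assemble_fragments([10, 20], prof, "S", min_diag=2, merge_gap=4) == []

    def test_interleaved_nondiagnostic_columns_join_span(self):
        aln, labels = two_species({10, 12, 14}, L=20)
        prof = column_profiles(aln, labels)
        frags = assemble_fragments([10, 12, 14], prof, "S", min_diag=2, merge_gap=4)
        assert len(frags) == 1
        f = frags[0]
        assert (f.start, f.end, f.n_diagnostic) == (10, 14, 3)
        assert f.sequence == "CACAC"  # consensus bases fill the gaps in the run

    def test_span_may_exceed_sequence_length(self):
        # S carries a gap inside the span: 5-column span, 4-base sequence
        rows = {
            "s1": "AAACC-CCAA",
            "s2": "AAACC-CCAA",
            "t1": "AAAAAAAAAA",
        }
        labels = make_labels({"s1": ("S",), "s2": ("S",), "t1": ("T",)})
        aln = make_alignment(rows)
        prof = column_profiles(aln, labels)
        cols = diagnostic_columns(prof, "S")
        assert cols == [4, 5, 7, 8]
        frags = assemble_fragments(cols, prof, "S", min_diag=2, merge_gap=4)
        assert len(frags) == 1
        f = frags[0]
        assert (f.start, f.end) == (4, 8)
        assert f.sequence == "CCCC"
        assert f.span == 5 and len(f.sequence) == 4

    def test_matches_window_enumeration_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            L = int(rng.integers(10, 80))
            k = int(rng.integers(0, min(12, L)))
            diag = set(int(c) + 1 for c in rng.choice(L, size=k, replace=False))
            merge_gap = int(rng.integers(0, 7))
            aln, labels = two_species(diag, L)
            prof = column_profiles(aln, labels)
            got = assemble_fragments(sorted(diag), prof, "S", 2, merge_gap)
            want = oracle_fragments(diag, 2, merge_gap)
            assert [(f.start, f.end, f.n_diagnostic) for f in got] == want


class TestFindDiagnosticFragments:
    def test_fragments_sorted_and_nonoverlapping_per_species(self):
        rng = np.random.default_rng(5)
        pool = np.array(list("ACGT-"))
        rows, spec = {}, {}
        for s in range(4):
            root = rng.choice(pool, 60)
            for m in range(3):
                sid = f"sp{s}_m{m}"
                rows[sid] = "".join(root)
                spec[sid] = (f"sp{s}",)
        aln, labels = make_alignment(rows), make_labels(spec)
        frags = find_diagnostic_fragments(aln, labels)
        starts = [f.start for f in frags]
        assert starts == sorted(starts)
        by_species = {}
        for f in frags:
            by_species.setdefault(f.species, []).append(f)
        for fl in by_species.values():
            for a, b in zip(fl, fl[1:]):
                assert a.end < b.start
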