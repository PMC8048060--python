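"""Species-diagnostic column detection and fragment assembly.

For each species and alignment column the *residue set* is the union of the
concrete bases observed among that species' members, with IUPAC ambiguity
codes expanded to their base sets (W contributes {A, T}, etc.) and gaps
recorded separately.  A column is diagnostic for a species when its residue
set is non-empty and disjoint from the union of every other species' residue
set at that column — including the case where all other species are gapped,
so that presence/absence at an indel region is itself diagnostic.

Diagnostic columns are assembled into fragments by a greedy left-to-right
merge: consecutive diagnostic columns join one fragment when separated by at
most ``merge_gap`` intervening columns; fragments keep diagnostic columns at
both ends and need at least ``min_diag`` diagnostic columns to be reported.
The fragment sequence is the species' IUPAC consensus over the span's
non-gap columns, so a span may be longer than its sequence.  These fragments
are the candidate targets for probe-based assays (e.g. hyperbranched
rolling circle amplification) that discriminate few-nucleotide differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce
from typing import Iterable, Sequence

import numpy as np

from .alphabet import GAP, MASK_TO_CODE, mask_to_set
from .errors import ConfigError, DataError
from .io import MultipleAlignment, SpeciesLabelMap


@dataclass(frozen=True)
class ColumnProfiles:
    """Per-species residue-set bit masks and gap counts per alignment column.

    ``masks[species]`` is a uint8 array of length ``n_columns`` whose bits
    encode the species' residue set at each column (0 = all members gapped);
    ``gap_counts[species]`` counts gapped members per column.
    """

    masks: dict[str, np.ndarray]
    gap_counts: dict[str, np.ndarray]
    member_counts: dict[str, int]
    n_columns: int

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.masks)

    def residue_set(self, species: str, column: int) -> frozenset[str]:
        """Base set of one species at one 1-based column."""
        return mask_to_set(int(self.masks[species][column - 1]))

    def others_mask(self, target: str) -> np.ndarray:
        """Columnwise union of residue sets over all species except target."""
        others = [m for s, m in self.masks.items() if s != target]
        if not others:
            raise DataError("profiles hold no species other than the target")
        return reduce(np.bitwise_or, others)


@dataclass(frozen=True)
class DiagnosticFragment:
    """A candidate species-diagnostic region of the alignment.

    ``start``/``end`` are 1-based inclusive alignment columns; both end
    columns are diagnostic.  ``sequence`` is the species consensus over the
    span's non-gap columns, so ``end - start + 1 >= len(sequence)``.
    """

    species: str
    sequence: str
    start: int
    end: int
    n_diagnostic: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DataError("fragment start exceeds end")
        if self.n_diagnostic < 2:
            raise DataError("diagnostic fragments need at least 2 diagnostic columns")
        if self.end - self.start + 1 < len(self.sequence):
            raise DataError("fragment span shorter than its sequence")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def column_profiles(
    alignment: MultipleAlignment,
    labels: SpeciesLabelMap,
    species_set: Sequence[str] | None = None,
) -> ColumnProfiles:
    """Build residue-set profiles for the given species (default: all)."""
    groups = labels.ids_by_species()
    species = list(species_set) if species_set is not None else list(groups)
    masks: dict[str, np.ndarray] = {}
    gaps: dict[str, np.ndarray] = {}
    members: dict[str, int] = {}
    mask_matrix = alignment.mask_matrix()
    index = {sid: k for k, sid in enumerate(alignment.ids)}
    for sp in species:
        ids = groups.get(sp, [])
        if not ids:
            raise DataError(f"species {sp!r} has no members")
        rows = mask_matrix[[index[i] for i in ids]]
        masks[sp] = np.bitwise_or.reduce(rows, axis=0)
        gaps[sp] = (rows == 0).sum(axis=0)
        members[sp] = len(ids)
    return ColumnProfiles(masks, gaps, members, alignment.n_columns)


def species_consensus(profiles: ColumnProfiles, species: str, column: int) -> str:
    """Minimal IUPAC code for the species' residue set at a 1-based column.

    Returns ``-`` when every member is gapped; columns where only some
    members are gapped still yield the residue-set code (gap presence is
    recorded in ``gap_counts``, not in the consensus symbol).
    """
    return MASK_TO_CODE[int(profiles.masks[species][column - 1])]


def consensus_sequence(
    profiles: ColumnProfiles, species: str, start: int, end: int
) -> str:
    """Species consensus over a 1-based inclusive span, non-gap columns only."""
    codes = (species_consensus(profiles, species, c) for c in range(start, end + 1))
    return "".join(c for c in codes if c != GAP)


def diagnostic_columns(profiles: ColumnProfiles, target_species: str) -> list[int]:
    """1-based columns whose target residue set is disjoint from all others.

    A column where every other species is fully gapped is diagnostic: the
    empty union intersects nothing, and presence/absence is informative.
    """
    if target_species not in profiles.masks:
        raise DataError(f"species {target_species!r} not profiled")
    if len(profiles.masks) < 2:
        raise DataError("diagnostic columns need at least 2 profiled species")
    t = profiles.masks[target_species]
    others = profiles.others_mask(target_species)
    diag = (t != 0) & ((t & others) == 0)
    return [int(c) + 1 for c in np.nonzero(diag)[0]]


def assemble_fragments(
    diag_cols: Sequence[int],
    profiles: ColumnProfiles,
    target_species: str,
    min_diag: int = 2,
    merge_gap: int = 5,
) -> list[DiagnosticFragment]:
    """Greedy left-to-right merge of diagnostic columns into fragments.

    Two consecutive diagnostic columns join the same fragment when at most
    ``merge_gap`` non-diagnostic columns lie between them.  Fragments are
    trimmed to diagnostic end columns by construction and discarded when
    they carry fewer than ``min_diag`` diagnostic columns.
    """
    if min_diag < 2:
        raise ConfigError("min_diag must be >= 2")
    if merge_gap < 0:
        raise ConfigError("merge_gap must be >= 0")
    cols = sorted(diag_cols)
    fragments: list[DiagnosticFragment] = []
    runs: list[list[int]] = []
    for c in cols:
        if runs and c - runs[-1][-1] - 1 <= merge_gap:
            runs[-1].append(c)
        else:
            runs.append([c])
    for run in runs:
        if len(run) < min_diag:
            continue
        start, end = run[0], run[-1]
        fragments.append(
            DiagnosticFragment(
                species=target_species,
                sequence=consensus_sequence(profiles, target_species, start, end),
                start=start,
                end=end,
                n_diagnostic=len(run),
            )
        )
    return fragments


def find_diagnostic_fragments(
    alignment: MultipleAlignment,
    labels: SpeciesLabelMap,
    species_set: Sequence[str] | None = None,
    min_diag: int = 2,
    merge_gap: int = 5,
) -> list[DiagnosticFragment]:
    """Diagnostic fragments for every species in ``species_set`` (default all).

    Fragments from all species are returned jointly, sorted by start column;
    a downstream table writer labels them A, B, C, ... in this order.
    """
    profiles = column_profiles(alignment, labels, species_set)
    fragments: list[DiagnosticFragment] = []
    for sp in profiles.species:
        cols = diagnostic_columns(profiles, sp)
        fragments.extend(
            assemble_fragments(cols, profiles, sp, min_diag=min_diag, merge_gap=merge_gap)
        )
    return sorted(fragments, key=lambda f: (f.start, f.end, f.species))
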