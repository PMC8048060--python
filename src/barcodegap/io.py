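"""Reading, validating and writing the pipeline's file formats.

This module fixes the coordinate and alphabet conventions for everything
downstream: alignment columns are 1-based inclusive at every interface, all
residues are uppercase IUPAC DNA (``U`` is normalised to ``T``), and species
metadata travels as a tab-separated table with the header
``id  accession  species  material  reliable  [host  origin]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import ALPHABET, encode_bases, encode_masks
from .errors import AlphabetError, DataError, RaggedAlignmentError

logger = logging.getLogger(__name__)

MATERIALS = ("specimen", "strain")

LABEL_COLUMNS = ("id", "accession", "species", "material", "reliable", "host", "origin")


@dataclass(frozen=True)
class MultipleAlignment:
    """An in-memory multiple sequence alignment over the IUPAC DNA alphabet.

    ``ids`` are unique and ordered; every row has length ``n_columns``.
    Column coordinates exposed anywhere by this package are 1-based inclusive.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise DataError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise DataError(f"duplicate sequence ids: {', '.join(dupes)}")
        if not self.rows:
            raise DataError("empty alignment")
        width = len(self.rows[0])
        for sid, row in zip(self.ids, self.rows):
            if len(row) != width:
                raise RaggedAlignmentError(
                    f"ragged alignment: sequence {sid!r} has length "
                    f"{len(row)}, expected {width}"
                )
            bad = set(row) - ALPHABET
            if bad:
                col = next(i for i, ch in enumerate(row) if ch in bad) + 1
                raise AlphabetError(
                    f"illegal character {row[col - 1]!r} in sequence {sid!r} "
                    f"at column {col}"
                )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def row(self, sid: str) -> str:
        return self.rows[self.index(sid)]

    def index(self, sid: str) -> int:
        try:
            return self.ids.index(sid)
        except ValueError:
            raise KeyError(f"unknown sequence id {sid!r}") from None

    def base_matrix(self) -> np.ndarray:
        """(n_rows, n_columns) uint8 matrix: 0..3 = A/C/G/T, 255 = missing."""
        return np.vstack([encode_bases(r) for r in self.rows])

    def mask_matrix(self) -> np.ndarray:
        """(n_rows, n_columns) uint8 matrix of IUPAC bit masks (gap = 0)."""
        return np.vstack([encode_masks(r) for r in self.rows])

    def subset(self, ids: Sequence[str]) -> "MultipleAlignment":
        return MultipleAlignment(tuple(ids), tuple(self.row(i) for i in ids))


@dataclass(frozen=True)
class SpeciesRecord:
    """One row of the species-label table (a Table-1-style record)."""

    id: str
    species: str
    material: str
    reliable: bool
    accession: str | None = None
    host: str | None = None
    origin: str | None = None

    def __post_init__(self) -> None:
        if not self.species:
            raise DataError(f"empty species label for id {self.id!r}")
        if self.material not in MATERIALS:
            raise DataError(
                f"invalid material {self.material!r} for id {self.id!r}; "
                f"expected one of {MATERIALS}"
            )


@dataclass(frozen=True)
class SpeciesLabelMap:
    """id -> species label, material type and reliability flag."""

    records: Mapping[str, SpeciesRecord]

    def __post_init__(self) -> None:
        for rid, rec in self.records.items():
            if rid != rec.id:
                raise DataError(f"record keyed {rid!r} carries id {rec.id!r}")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self.records)

    def species_of(self, sid: str) -> str:
        return self.records[sid].species

    def species(self) -> tuple[str, ...]:
        """Distinct species labels in first-appearance order."""
        seen: dict[str, None] = {}
        for rec in self.records.values():
            seen.setdefault(rec.species, None)
        return tuple(seen)

    def ids_by_species(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for rec in self.records.values():
            out.setdefault(rec.species, []).append(rec.id)
        return out

    def relabel(self, new_species: Mapping[str, str]) -> "SpeciesLabelMap":
        """Return a copy with some ids' species labels replaced."""
        recs = {
            rid: (replace(rec, species=new_species[rid]) if rid in new_species else rec)
            for rid, rec in self.records.items()
        }
        return SpeciesLabelMap(recs)


@dataclass(frozen=True)
class ReferenceDesignation:
    """species -> ids designated as that species' reliable reference sequences."""

    by_species: Mapping[str, tuple[str, ...]]

    def validate(self, labels: SpeciesLabelMap) -> None:
        for species, ids in self.by_species.items():
            if not ids:
                raise DataError(f"species {species!r} designates no reference ids")
            for sid in ids:
                if sid not in labels.records:
                    raise DataError(
                        f"designated reference {sid!r} for {species!r} is not "
                        "in the label table"
                    )
                if not labels.records[sid].reliable:
                    raise DataError(
                        f"designated reference {sid!r} for {species!r} is not "
                        "flagged reliable"
                    )

    @property
    def reference_ids(self) -> frozenset[str]:
        return frozenset(i for ids in self.by_species.values() for i in ids)


def _normalise_row(row: str) -> str:
    return row.upper().replace("U", "T")


def read_alignment(path: str | Path) -> MultipleAlignment:
    """Read an aligned FASTA file, normalising case and ``U``->``T``.

    Raises :class:`RaggedAlignmentError` (naming the offending id) if rows
    differ in length, and :class:`AlphabetError` (naming id and column) on
    residues outside the IUPAC DNA alphabet plus gap.
    """
    path = Path(path)
    ids: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(_normalise_row(str(rec.seq)))
    if not ids:
        raise DataError(f"no FASTA records in {path}")
    return MultipleAlignment(tuple(ids), tuple(rows))


def write_alignment(alignment: MultipleAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(alignment.ids, alignment.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


_TRUE = {"true", "1", "yes", "t", "y"}
_FALSE = {"false", "0", "no", "f", "n"}


def _parse_bool(value: object, sid: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise DataError(f"cannot parse reliable flag {value!r} for id {sid!r}")


def read_labels(
    path: str | Path,
    alignment: MultipleAlignment,
    strict: bool = True,
) -> SpeciesLabelMap:
    """Read the species-label TSV and reconcile it against the alignment.

    In strict mode (default) the table and the alignment must carry exactly
    the same id set; with ``strict=False`` rows absent from the alignment are
    dropped with a warning.  Alignment ids missing from the table are an
    error in either mode.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"id", "species", "material", "reliable"} - set(df.columns)
    if missing:
        raise DataError(f"label table lacks required columns: {sorted(missing)}")

    if df["id"].duplicated().any():
        dupes = sorted(df.loc[df["id"].duplicated(), "id"].unique())
        raise DataError(f"duplicate ids in label table: {', '.join(dupes)}")

    aln_ids = set(alignment.ids)
    extra = [i for i in df["id"] if i not in aln_ids]
    if extra:
        if strict:
            raise DataError(
                "label table ids absent from alignment (strict mode): "
                + ", ".join(extra)
            )
        logger.warning("dropping %d label rows absent from alignment", len(extra))
        df = df[df["id"].isin(aln_ids)]

    records: dict[str, SpeciesRecord] = {}
    for row in df.itertuples(index=False):
        rec = SpeciesRecord(
            id=row.id,
            species=row.species,
            material=row.material,
            reliable=_parse_bool(row.reliable, row.id),
            accession=getattr(row, "accession", None) or None,
            host=getattr(row, "host", None) or None,
            origin=getattr(row, "origin", None) or None,
        )
        records[rec.id] = rec

    absent = [i for i in alignment.ids if i not in records]
    if absent:
        raise DataError(
            "alignment ids missing from label table: " + ", ".join(absent)
        )
    # preserve alignment order
    records = {i: records[i] for i in alignment.ids}
    return SpeciesLabelMap(records)


def write_labels(labels: SpeciesLabelMap, path: str | Path) -> None:
    rows = [
        {
            "id": r.id,
            "accession": r.accession or "",
            "species": r.species,
            "material": r.material,
            "reliable": str(r.reliable).lower(),
            "host": r.host or "",
            "origin": r.origin or "",
        }
        for r in labels.records.values()
    ]
    pd.DataFrame(rows, columns=list(LABEL_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_references(path: str | Path, labels: SpeciesLabelMap) -> ReferenceDesignation:
    """Read a two-column TSV ``species<TAB>id`` of reference designations."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"species", "id"} <= set(df.columns):
        raise DataError("reference table needs columns: species, id")
    by_species: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        by_species.setdefault(row.species, []).append(row.id)
    desig = ReferenceDesignation({s: tuple(i) for s, i in by_species.items()})
    desig.validate(labels)
    return desig


def write_references(designations: ReferenceDesignation, path: str | Path) -> None:
    rows = [
        {"species": s, "id": i}
        for s, ids in designations.by_species.items()
        for i in ids
    ]
    pd.DataFrame(rows, columns=["species", "id"]).to_csv(path, sep="\t", index=False)


def fragment_label(index: int) -> str:
    """Spreadsheet-style fragment label: A..Z, AA, AB, ... for index 0, 1, ..."""
    label = ""
    index += 1
    while index > 0:
        index, rem = divmod(index - 1, 26)
        label = chr(ord("A") + rem) + label
    return label


def write_fragments_table(fragments: Iterable, path: str | Path) -> None:
    """Write diagnostic fragments as TSV, labelled A, B, C, ... by start column.

    Fragments from all species are labelled jointly in alignment order
    (start column, then end, then species), matching how probe-candidate
    tables interleave species.
    """
    frags = sorted(fragments, key=lambda f: (f.start, f.end, f.species))
    rows = [
        {
            "label": fragment_label(i),
            "species": f.species,
            "sequence": f.sequence,
            "start": f.start,
            "end": f.end,
            "n_diagnostic": f.n_diagnostic,
        }
        for i, f in enumerate(frags)
    ]
    cols = ["label", "species", "sequence", "start", "end", "n_diagnostic"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
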