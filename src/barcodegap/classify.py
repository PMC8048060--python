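"""Distance-based species assignment against designated reference sequences.

Each query is assigned to the species of its nearest reliable reference
(p-distance, pairwise deletion).  A query farther than ``genus_cutoff`` from
every reference is gated out as not belonging to the genus — mirroring how
outlier sequences are dropped from barcode datasets on similarity grounds.
Queries whose two best references from different species tie within
``tie_epsilon`` are reported ambiguous, never silently broken.  A nearest-
reference classifier is a deliberately simple stand-in for clade membership
in a phylogenetic tree; it behaves identically when species clusters are
well separated but carries no support values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import pairwise_p_distance
from .errors import DataError
from .io import MultipleAlignment, ReferenceDesignation, SpeciesLabelMap

logger = logging.getLogger(__name__)

STATUSES = ("concordant", "mislabeled", "not_in_genus", "ambiguous")

#: default genus gate: 5% distance, the complement of a 95% similarity screen
DEFAULT_GENUS_CUTOFF = 0.05


@dataclass(frozen=True)
class ReferenceEntry:
    species: str
    id: str
    row: str


@dataclass(frozen=True)
class ReferencePanel:
    entries: tuple[ReferenceEntry, ...]

    @property
    def species(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.species, None)
        return tuple(seen)

    @property
    def ids(self) -> frozenset[str]:
        return frozenset(e.id for e in self.entries)


@dataclass(frozen=True)
class ClassificationResult:
    query_id: str
    given_label: str
    assigned_species: str | None
    d_min: float
    status: str
    runner_up: tuple[str, float] | None = None


def build_reference_set(
    alignment: MultipleAlignment,
    labels: SpeciesLabelMap,
    designations: ReferenceDesignation,
) -> ReferencePanel:
    """Assemble the reference panel from the designated reliable sequences.

    Every designated id must exist in the alignment and be flagged reliable;
    a species designating no usable reference is an error.
    """
    designations.validate(labels)
    entries = []
    for species, ids in designations.by_species.items():
        if not ids:
            raise DataError(f"species {species!r} has zero designated references")
        for sid in ids:
            entries.append(ReferenceEntry(species, sid, alignment.row(sid)))
    return ReferencePanel(tuple(entries))


def classify_query(
    query_row: str,
    panel: ReferencePanel,
    given_label: str,
    query_id: str = "",
    genus_cutoff: float = DEFAULT_GENUS_CUTOFF,
    tie_epsilon: float = 0.0,
) -> ClassificationResult:
    """Classify one aligned query against the reference panel.

    Status logic, in order: ``not_in_genus`` when the nearest reference is
    farther than ``genus_cutoff``; ``ambiguous`` when references from two
    species tie for nearest within ``tie_epsilon``; otherwise ``concordant``
    or ``mislabeled`` by comparison with the given label.
    """
    best_by_species: dict[str, float] = {}
    any_defined = False
    for entry in panel.entries:
        d, n = pairwise_p_distance(query_row, entry.row)
        if n == 0:
            continue
        any_defined = True
        cur = best_by_species.get(entry.species)
        if cur is None or d < cur:
            best_by_species[entry.species] = d
    if not any_defined:
        raise DataError(f"no comparable sites between query {query_id!r} and panel")

    ranked = sorted(best_by_species.items(), key=lambda t: (t[1], t[0]))
    best_species, d_min = ranked[0]
    runner_up = ranked[1] if len(ranked) > 1 else None

    if d_min > genus_cutoff:
        return ClassificationResult(
            query_id, given_label, None, d_min, "not_in_genus", runner_up
        )
    if runner_up is not None and runner_up[1] - d_min <= tie_epsilon:
        return ClassificationResult(
            query_id, given_label, None, d_min, "ambiguous", runner_up
        )
    status = "concordant" if best_species == given_label else "mislabeled"
    return ClassificationResult(
        query_id, given_label, best_species, d_min, status, runner_up
    )


def classify_all(
    alignment: MultipleAlignment,
    labels: SpeciesLabelMap,
    panel: ReferencePanel,
    genus_cutoff: float = DEFAULT_GENUS_CUTOFF,
    tie_epsilon: float = 0.0,
) -> list[ClassificationResult]:
    """Classify every sequence in the alignment, panel members included.

    A panel member classifies against itself at distance zero; membership in
    the panel is metadata, not exclusion.
    """
    return [
        classify_query(
            alignment.row(sid),
            panel,
            given_label=labels.species_of(sid),
            query_id=sid,
            genus_cutoff=genus_cutoff,
            tie_epsilon=tie_epsilon,
        )
        for sid in alignment.ids
    ]


def mislabel_report(
    results: list[ClassificationResult], labels: SpeciesLabelMap
) -> dict:
    """Status counts split by material type, plus a per-query correction table."""
    counts = {
        material: {status: 0 for status in STATUSES}
        for material in ("specimen", "strain")
    }
    corrections = []
    for res in results:
        material = labels.records[res.query_id].material
        counts[material][res.status] += 1
        if res.status == "mislabeled":
            corrections.append(
                {
                    "id": res.query_id,
                    "given": res.given_label,
                    "assigned": res.assigned_species,
                }
            )
    totals = {
        status: sum(counts[m][status] for m in counts) for status in STATUSES
    }
    return {
        "n_queries": len(results),
        "by_material": counts,
        "totals": totals,
        "corrections": corrections,
    }


def results_to_frame(
    results: list[ClassificationResult], percent: bool = True
) -> pd.DataFrame:
    scale = 100.0 if percent else 1.0
    rows = []
    for r in results:
        rows.append(
            {
                "id": r.query_id,
                "given": r.given_label,
                "assigned": r.assigned_species or "",
                "d_min": r.d_min * scale,
                "status": r.status,
                "runner_up": r.runner_up[0] if r.runner_up else "",
                "runner_up_d": r.runner_up[1] * scale if r.runner_up else np.nan,
            }
        )
    cols = ["id", "given", "assigned", "d_min", "status", "runner_up", "runner_up_d"]
    return pd.DataFrame(rows, columns=cols)


def write_classification_tsv(results, path, percent: bool = True) -> None:
    results_to_frame(results, percent=percent).to_csv(
        path, sep="\t", index=False, float_format="%.4f", na_rep="NA"
    )


def write_report_json(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
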