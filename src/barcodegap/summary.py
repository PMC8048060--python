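"""Within/between-species distance ranges and the barcoding-gap cut-off.

Collapses a pairwise distance matrix by species labels into per-species
within ranges and per-species-pair between ranges, then estimates an
identification cut-off as the largest within-species distance (optionally
after setting aside named high-variance species).  The *barcoding gap* holds
when every between-species minimum exceeds that cut-off; species pairs that
violate it are reported as exceptions rather than hidden.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .errors import DataError
from .io import SpeciesLabelMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WithinRange:
    species: str
    min: float
    max: float
    n_pairs: int


@dataclass(frozen=True)
class BetweenRange:
    species_i: str
    species_j: str
    min: float
    max: float
    n_pairs: int

    @property
    def pair(self) -> tuple[str, str]:
        return (self.species_i, self.species_j)


@dataclass(frozen=True)
class SpeciesDistanceSummary:
    """Within/between ranges plus the estimated cut-off and gap verdict."""

    within: dict[str, WithinRange]
    between: dict[tuple[str, str], BetweenRange]
    excluded_singletons: tuple[str, ...]
    no_data_pairs: tuple[tuple[str, str], ...]
    cutoff: float
    gap_ok: bool
    exceptions: tuple[tuple[str, str], ...]
    exclude_species: tuple[str, ...] = ()

    def to_frames(self, percent: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
        scale = 100.0 if percent else 1.0
        w = pd.DataFrame(
            [
                {
                    "species": r.species,
                    "min": r.min * scale,
                    "max": r.max * scale,
                    "n_pairs": r.n_pairs,
                }
                for r in self.within.values()
            ],
            columns=["species", "min", "max", "n_pairs"],
        )
        b = pd.DataFrame(
            [
                {
                    "species_i": r.species_i,
                    "species_j": r.species_j,
                    "min": r.min * scale,
                    "max": r.max * scale,
                    "n_pairs": r.n_pairs,
                }
                for r in self.between.values()
            ],
            columns=["species_i", "species_j", "min", "max", "n_pairs"],
        )
        return w, b

    def write_tsv(self, path, percent: bool = True) -> None:
        """Two-block TSV: within ranges, a blank line, then between ranges."""
        w, b = self.to_frames(percent=percent)
        with open(path, "w") as fh:
            fh.write("# within species\n")
            w.to_csv(fh, sep="\t", index=False, float_format="%.2f")
            fh.write("\n# between species\n")
            b.to_csv(fh, sep="\t", index=False, float_format="%.2f")

    def to_json_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "cutoff_percent": round(self.cutoff * 100, 2),
            "gap_ok": self.gap_ok,
            "exceptions": [list(p) for p in self.exceptions],
            "excluded_singletons": list(self.excluded_singletons),
            "exclude_species": list(self.exclude_species),
            "no_data_pairs": [list(p) for p in self.no_data_pairs],
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)
            fh.write("\n")


def _defined_pair_values(matrix: DistanceMatrix, ids_a, ids_b, same: bool):
    """Defined distances over cross (or intra, if same) pairs of two id lists."""
    idx = {sid: k for k, sid in enumerate(matrix.ids)}
    values = []
    skipped = 0
    if same:
        pairs = itertools.combinations(ids_a, 2)
    else:
        pairs = itertools.product(ids_a, ids_b)
    for a, b in pairs:
        v = matrix.d[idx[a], idx[b]]
        if np.isnan(v):
            skipped += 1
        else:
            values.append(float(v))
    return values, skipped


def within_species_ranges(
    matrix: DistanceMatrix, labels: SpeciesLabelMap
) -> tuple[dict[str, WithinRange], tuple[str, ...]]:
    """Per-species (min, max) over intra-species defined pairs.

    Species represented by a single sequence carry no within range and are
    returned separately as excluded singletons.
    """
    ranges: dict[str, WithinRange] = {}
    singletons: list[str] = []
    skipped_total = 0
    for species, ids in labels.ids_by_species().items():
        if len(ids) < 2:
            singletons.append(species)
            continue
        values, skipped = _defined_pair_values(matrix, ids, ids, same=True)
        skipped_total += skipped
        if values:
            ranges[species] = WithinRange(species, min(values), max(values), len(values))
        else:
            singletons.append(species)  # all pairs undefined: no usable range
    if skipped_total:
        logger.info("skipped %d undefined within-species pairs", skipped_total)
    return ranges, tuple(singletons)


def between_species_ranges(
    matrix: DistanceMatrix, labels: SpeciesLabelMap
) -> tuple[dict[tuple[str, str], BetweenRange], tuple[tuple[str, str], ...]]:
    """Per unordered species pair (min, max) over defined cross distances.

    Pairs with no defined cross distance are reported in the second return
    value as "no data" rather than silently dropped.
    """
    groups = labels.ids_by_species()
    species = list(groups)
    if len(species) < 2:
        raise DataError("between-species ranges need at least 2 species")
    ranges: dict[tuple[str, str], BetweenRange] = {}
    no_data: list[tuple[str, str]] = []
    skipped_total = 0
    for sp_i, sp_j in itertools.combinations(species, 2):
        values, skipped = _defined_pair_values(
            matrix, groups[sp_i], groups[sp_j], same=False
        )
        skipped_total += skipped
        if values:
            ranges[(sp_i, sp_j)] = BetweenRange(
                sp_i, sp_j, min(values), max(values), len(values)
            )
        else:
            no_data.append((sp_i, sp_j))
    if skipped_total:
        logger.info("skipped %d undefined between-species pairs", skipped_total)
    return ranges, tuple(no_data)


def estimate_cutoff(
    within: dict[str, WithinRange],
    between: dict[tuple[str, str], BetweenRange],
    exclude_species: tuple[str, ...] = (),
) -> tuple[float, bool, tuple[tuple[str, str], ...]]:
    """Barcoding-gap cut-off: the largest within-species maximum.

    ``exclude_species`` names species whose (high) within-species variation
    should not set the cut-off; the default is to exclude none.  Returns
    ``(cutoff, gap_ok, exceptions)`` where ``gap_ok`` is true when every
    between-species minimum exceeds the cut-off and ``exceptions`` lists the
    species pairs whose between minimum falls below it.
    """
    pool = {s: r for s, r in within.items() if s not in exclude_species}
    if not pool:
        raise DataError("no within-species data after exclusions")
    cutoff_species, cutoff = max(
        ((s, r.max) for s, r in pool.items()), key=lambda t: t[1]
    )
    logger.info("cutoff %.4f set by species %s", cutoff, cutoff_species)
    exceptions = tuple(
        sorted(pair for pair, r in between.items() if r.min < cutoff)
    )
    gap_ok = bool(between) and min(r.min for r in between.values()) > cutoff
    return cutoff, gap_ok, exceptions


def summarize(
    matrix: DistanceMatrix,
    labels: SpeciesLabelMap,
    exclude_species: tuple[str, ...] = (),
) -> SpeciesDistanceSummary:
    """Full species-level summary: ranges, cut-off, gap verdict, exceptions."""
    within, singletons = within_species_ranges(matrix, labels)
    between, no_data = between_species_ranges(matrix, labels)
    cutoff, gap_ok, exceptions = estimate_cutoff(within, between, exclude_species)
    return SpeciesDistanceSummary(
        within=within,
        between=between,
        excluded_singletons=singletons,
        no_data_pairs=no_data,
        cutoff=cutoff,
        gap_ok=gap_ok,
        exceptions=exceptions,
        exclude_species=tuple(exclude_species),
    )
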