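"""Synthetic species-structured alignments with known ground truth.

The generator emulates a curated barcode dataset: a genus ancestor sequence
is drawn uniformly over {A, C, G, T}; each species root mutates the ancestor
independently per site with probability ``p_inter`` (new base uniform over
the other three, Jukes-Cantor-like); each member mutates its species root
likewise with ``p_intra``.  Optional extras exercise the downstream stages:
gap blocks (indel regions) knocked into single species, planted
species-unique fragments whose columns are guaranteed diagnostic, and a
known fraction of swapped species labels.  Everything is reproducible from
the mandatory seed.

Under this model the expected p-distance between two members of one species
is ``2p(1-p) + (2/3)p^2`` with ``p = p_intra`` — the probability that two
independent per-site mutants of a common root disagree at a site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import BASES, GAP
from .errors import ConfigError, DataError
from .io import (
    MultipleAlignment,
    ReferenceDesignation,
    SpeciesLabelMap,
    SpeciesRecord,
)


@dataclass(frozen=True)
class PlantedFragment:
    """A species-unique run of bases planted at fixed alignment columns."""

    species: str
    start: int  # 1-based inclusive
    bases: str

    @property
    def columns(self) -> range:
        """0-based column range."""
        return range(self.start - 1, self.start - 1 + len(self.bases))


@dataclass(frozen=True)
class SyntheticConfig:
    n_species: int
    members_per_species: int
    n_columns: int
    p_intra: float
    p_inter: float
    seed: int
    indel_block_rate: float = 0.0
    planted_fragments: tuple[PlantedFragment, ...] = ()
    mislabel_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.n_species < 1 or self.members_per_species < 1 or self.n_columns < 1:
            raise ConfigError("n_species, members_per_species, n_columns must be >= 1")
        for name in ("p_intra", "p_inter", "indel_block_rate", "mislabel_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for pf in self.planted_fragments:
            if pf.start < 1 or pf.start - 1 + len(pf.bases) > self.n_columns:
                raise ConfigError(
                    f"planted fragment for {pf.species!r} at {pf.start} "
                    "falls outside the alignment"
                )
            if any(b not in BASES for b in pf.bases):
                raise ConfigError("planted fragment bases must be concrete A/C/G/T")

    def species_names(self) -> tuple[str, ...]:
        width = max(2, len(str(self.n_species)))
        return tuple(f"sp{k + 1:0{width}d}" for k in range(self.n_species))


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth accompanying a generated dataset."""

    true_species: dict[str, str]
    swapped: tuple[str, ...]
    ancestor: str
    roots: dict[str, str]
    planted: tuple[PlantedFragment, ...]
    designations: ReferenceDesignation


def expected_within_distance(p_intra: float) -> float:
    """Closed-form expected within-species p-distance of the generator."""
    p = p_intra
    return 2 * p * (1 - p) + p * p * (2.0 / 3.0)


def _mutate(rng: np.random.Generator, template: np.ndarray, p: float) -> np.ndarray:
    """Per-site substitution: with prob p replace by a uniform other base."""
    out = template.copy()
    hit = rng.random(template.size) < p
    # offset 1..3 mod 4 is uniform over the three other bases
    out[hit] = (template[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return out


def _indel_blocks(
    rng: np.random.Generator, config: SyntheticConfig, species: tuple[str, ...]
) -> list[tuple[str, int, int]]:
    """Draw (species, start0, length) gap blocks; block starts are per-column
    Bernoulli(indel_block_rate), lengths uniform on 3..8 columns."""
    blocks = []
    starts = np.nonzero(rng.random(config.n_columns) < config.indel_block_rate)[0]
    for s in starts:
        length = int(rng.integers(3, 9))
        sp = species[int(rng.integers(0, len(species)))]
        blocks.append((sp, int(s), min(length, config.n_columns - int(s))))
    return blocks


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[MultipleAlignment, SpeciesLabelMap, SyntheticTruth]:
    """Generate an alignment, a (possibly mislabeled) label table and truth.

    The first member of each species is flagged reliable and designated as
    that species' reference; label swaps never touch designated references.
    Raises :class:`DataError` if a drawn indel block overlaps a planted
    fragment of the same (target) species.
    """
    rng = np.random.default_rng(config.seed)
    species = config.species_names()
    for pf in config.planted_fragments:
        if pf.species not in species:
            raise ConfigError(f"planted fragment names unknown species {pf.species!r}")

    L = config.n_columns
    ancestor = rng.integers(0, 4, size=L)
    roots = {sp: _mutate(rng, ancestor, config.p_inter) for sp in species}

    ids: list[str] = []
    rows_idx: list[np.ndarray] = []
    gapped: list[np.ndarray] = []  # boolean gap masks per row
    owner: dict[str, list[int]] = {sp: [] for sp in species}
    for sp in species:
        for m in range(config.members_per_species):
            owner[sp].append(len(ids))
            ids.append(f"{sp}_m{m + 1:02d}")
            rows_idx.append(_mutate(rng, roots[sp], config.p_intra))
            gapped.append(np.zeros(L, dtype=bool))

    for sp, start0, length in _indel_blocks(rng, config, species):
        block = range(start0, start0 + length)
        for pf in config.planted_fragments:
            if pf.species == sp and set(block) & set(pf.columns):
                raise DataError(
                    f"indel block at columns {start0 + 1}-{start0 + length} "
                    f"collides with the planted fragment of {sp!r}"
                )
        for r in owner[sp]:
            gapped[r][start0 : start0 + length] = True

    base_index = {b: i for i, b in enumerate(BASES)}
    for pf in config.planted_fragments:
        for offset, base in enumerate(pf.bases):
            col = pf.start - 1 + offset
            b = base_index[base]
            for r in owner[pf.species]:
                rows_idx[r][col] = b
                gapped[r][col] = False
            # force every other species to a single different base, erasing
            # any gap, so the column is unambiguously diagnostic
            for other in species:
                if other == pf.species:
                    continue
                alt = (b + int(rng.integers(1, 4))) % 4
                for r in owner[other]:
                    rows_idx[r][col] = alt
                    gapped[r][col] = False

    base_arr = np.frombuffer(BASES.encode(), dtype=np.uint8)
    rows = []
    for idx_row, gap_row in zip(rows_idx, gapped):
        chars = base_arr[idx_row].copy()
        chars[gap_row] = ord(GAP)
        rows.append(chars.tobytes().decode("ascii"))
    alignment = MultipleAlignment(tuple(ids), tuple(rows))

    records = {}
    for sp in species:
        for m, r in enumerate(owner[sp]):
            sid = ids[r]
            records[sid] = SpeciesRecord(
                id=sid,
                species=sp,
                material="specimen" if m == 0 else ("strain" if rng.random() < 0.5 else "specimen"),
                reliable=(m == 0),
            )
    true_labels = SpeciesLabelMap(records)
    designations = ReferenceDesignation(
        {sp: (f"{sp}_m01",) for sp in species}
    )

    mislabel_seed = int(rng.integers(0, 2**31 - 1))
    labels, swapped = inject_mislabels(
        true_labels,
        config.mislabel_fraction,
        seed=mislabel_seed,
        protect=designations.reference_ids,
    )

    truth = SyntheticTruth(
        true_species={sid: rec.species for sid, rec in true_labels.records.items()},
        swapped=swapped,
        ancestor="".join(BASES[i] for i in ancestor),
        roots={sp: "".join(BASES[i] for i in roots[sp]) for sp in species},
        planted=config.planted_fragments,
        designations=designations,
    )
    return alignment, labels, truth


def inject_mislabels(
    labels: SpeciesLabelMap,
    fraction: float,
    seed: int,
    protect: frozenset[str] = frozenset(),
) -> tuple[SpeciesLabelMap, tuple[str, ...]]:
    """Swap round(fraction * n) ids to a uniformly chosen *different* species.

    ``protect`` shields ids (designated references) from swapping; the swap
    count is still computed over all n sequences and must fit in the
    unprotected pool.  Returns the relabeled map and the swapped ids.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ConfigError(f"mislabel fraction must be in [0, 1], got {fraction}")
    species = labels.species()
    if len(species) < 2:
        raise DataError("mislabel injection needs at least 2 species")
    n = len(labels.records)
    k = round(fraction * n)
    if k == 0:
        return labels, ()
    eligible = [i for i in labels.ids if i not in protect]
    if k > len(eligible):
        raise DataError(
            f"cannot swap {k} labels with only {len(eligible)} unprotected ids"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(eligible), size=k, replace=False)
    new_species: dict[str, str] = {}
    for ci in sorted(int(c) for c in chosen):
        sid = eligible[ci]
        current = labels.species_of(sid)
        others = [s for s in species if s != current]
        new_species[sid] = others[int(rng.integers(0, len(others)))]
    return labels.relabel(new_species), tuple(new_species)
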