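import numpy as np
import pytest

from barcodegap.io import MultipleAlignment, SpeciesLabelMap, SpeciesRecord

#: residue pool used by random-alignment generators in tests: mostly concrete
#: bases, with gaps and a few ambiguity codes to exercise pairwise deletion
RANDOM_ALPHABET = list("ACGTACGTACGT-NRYW")


def make_alignment(rows: dict[str, str]) -> MultipleAlignment:
    return MultipleAlignment(tuple(rows), tuple(rows.values()))


def make_labels(table: dict[str, tuple]) -> SpeciesLabelMap:
    """table: id -> (species,) or (species, material) or (species, material, reliable)."""
    records = {}
    for sid, fields in table.items():
        species = fields[0]
        material = fields[1] if len(fields) > 1 else "specimen"
        reliable = fields[2] if len(fields) > 2 else True
        records[sid] = SpeciesRecord(sid, species, material, reliable)
    return SpeciesLabelMap(records)


def random_alignment(rng: np.random.Generator, n_rows: int, n_cols: int) -> MultipleAlignment:
    pool = np.array(RANDOM_ALPHABET)
    rows = {
        f"s{i}": "".join(rng.choice(pool, size=n_cols))
        for i in range(n_rows)
    }
    return make_alignment(rows)


@pytest.fixture
def toy_alignment() -> MultipleAlignment:
    return make_alignment(
        {
            "a1": "ACGTACGT",
            "a2": "ACGTACGA",
            "b1": "TGCAACGT",
            "b2": "TGCAACGA",
        }
    )


@pytest.fixture
def toy_labels(toy_alignment) -> SpeciesLabelMap:
    return make_labels(
        {
            "a1": ("A", "specimen", True),
            "a2": ("A", "strain", False),
            "b1": ("B", "specimen", True),
            "b2": ("B", "strain", False),
        }
    )
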