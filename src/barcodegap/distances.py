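"""Pairwise p-distance engine with pairwise deletion of gaps and missing data.

The p-distance between two aligned sequences is the proportion of differing
sites among the sites compared; transitions and transversions count equally
and no multiple-hit correction is applied.  Under *pairwise deletion* the
compared sites for a pair are exactly the columns where both residues are
concrete bases (A, C, G or T): gaps and IUPAC ambiguity codes are treated as
missing data and excluded per pair, never globally.  A pair with no
comparable sites has an *undefined* distance, represented as NaN and carried
through (never silently zero).

Variance is estimated by site bootstrap: alignment columns are resampled
with replacement, the distance is recomputed per replicate (pairwise
deletion applied within each replicate), and the standard deviation of the
replicate distances is reported as the standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabet import encode_bases
from .errors import DataError
from .io import MultipleAlignment

_MISSING = 255


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise p-distances with per-pair compared-site counts.

    ``d`` holds proportions in [0, 1]; undefined entries (no comparable
    sites) are NaN and correspond exactly to ``n_sites == 0``.  ``se`` is an
    optional matrix of bootstrap standard errors with the same NaN pattern.
    """

    ids: tuple[str, ...]
    d: np.ndarray
    n_sites: np.ndarray
    se: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n) or self.n_sites.shape != (n, n):
            raise DataError("distance matrix shape does not match ids")

    def index(self, sid: str) -> int:
        try:
            return self.ids.index(sid)
        except ValueError:
            raise KeyError(f"unknown id {sid!r}") from None

    def get(self, id_i: str, id_j: str) -> float:
        """Distance between two ids (NaN if undefined)."""
        return float(self.d[self.index(id_i), self.index(id_j)])

    @property
    def n_undefined_pairs(self) -> int:
        iu = np.triu_indices(len(self.ids), k=1)
        return int(np.isnan(self.d[iu]).sum())

    def to_long_frame(self, percent: bool = False) -> pd.DataFrame:
        """Long-format table (upper triangle): id_i, id_j, distance, n_sites, se."""
        scale = 100.0 if percent else 1.0
        rows = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append(
                    {
                        "id_i": self.ids[i],
                        "id_j": self.ids[j],
                        "distance": self.d[i, j] * scale,
                        "n_sites": int(self.n_sites[i, j]),
                        "se": (self.se[i, j] * scale) if self.se is not None else np.nan,
                    }
                )
        return pd.DataFrame(rows, columns=["id_i", "id_j", "distance", "n_sites", "se"])

    def write_long_tsv(self, path, percent: bool = False) -> None:
        self.to_long_frame(percent=percent).to_csv(
            path, sep="\t", index=False, float_format="%.6g", na_rep="NA"
        )

    def write_square_tsv(self, path, percent: bool = False) -> None:
        scale = 100.0 if percent else 1.0
        df = pd.DataFrame(self.d * scale, index=list(self.ids), columns=list(self.ids))
        df.to_csv(path, sep="\t", float_format="%.6g", na_rep="NA", index_label="id")


def pairwise_p_distance(row_i: str, row_j: str) -> tuple[float, int]:
    """p-distance between two aligned rows under pairwise deletion.

    Returns ``(distance, n_sites)``; the distance is NaN when no column has
    a concrete base in both rows.
    """
    if len(row_i) != len(row_j):
        raise DataError("rows differ in length")
    a = encode_bases(row_i)
    b = encode_bases(row_j)
    compared = (a != _MISSING) & (b != _MISSING)
    n_sites = int(compared.sum())
    if n_sites == 0:
        return float("nan"), 0
    mismatches = int(((a != b) & compared).sum())
    return mismatches / n_sites, n_sites


def distance_matrix(alignment: MultipleAlignment) -> DistanceMatrix:
    """All-pairs p-distance matrix with pairwise deletion.

    Requires at least two rows.  Symmetry and a zero diagonal hold by
    construction; undefined pairs are NaN with ``n_sites == 0``.
    """
    n = alignment.n_rows
    if n < 2:
        raise DataError("distance matrix needs at least 2 sequences")
    enc = alignment.base_matrix()
    valid = enc != _MISSING
    d = np.zeros((n, n), dtype=float)
    n_sites = np.zeros((n, n), dtype=np.int64)
    np.fill_diagonal(n_sites, int(valid[0].size))
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        ns = both.sum(axis=1)
        mism = ((enc[i] != enc[i + 1 :]) & both).sum(axis=1)
        with np.errstate(invalid="ignore"):
            row_d = np.where(ns > 0, mism / np.maximum(ns, 1), np.nan)
        d[i, i + 1 :] = row_d
        d[i + 1 :, i] = row_d
        n_sites[i, i + 1 :] = ns
        n_sites[i + 1 :, i] = ns
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        n_sites[i, i] = int(valid[i].sum())
    return DistanceMatrix(alignment.ids, d, n_sites)


def bootstrap_se(
    alignment: MultipleAlignment,
    pair: tuple[str, str],
    replicates: int = 1000,
    seed: int | None = None,
    _chunk: int = 2048,
) -> float:
    """Site-bootstrap standard error of one pair's p-distance.

    Columns of the full alignment are resampled with replacement
    ``replicates`` times; pairwise deletion is applied within each replicate
    and the standard deviation of the replicate distances is returned.
    Replicates with no comparable sites are dropped.  Returns NaN when the
    pair itself has no comparable sites.  Seeded runs are reproducible.
    """
    if replicates < 1:
        raise DataError("replicates must be >= 1")
    a = encode_bases(alignment.row(pair[0]))
    b = encode_bases(alignment.row(pair[1]))
    if not ((a != _MISSING) & (b != _MISSING)).any():
        return float("nan")
    rng = np.random.default_rng(seed)
    L = a.size
    dists: list[np.ndarray] = []
    done = 0
    while done < replicates:
        k = min(_chunk, replicates - done)
        idx = rng.integers(0, L, size=(k, L))
        ra, rb = a[idx], b[idx]
        compared = (ra != _MISSING) & (rb != _MISSING)
        ns = compared.sum(axis=1)
        mism = ((ra != rb) & compared).sum(axis=1)
        with np.errstate(invalid="ignore"):
            dists.append(np.where(ns > 0, mism / np.maximum(ns, 1), np.nan))
        done += k
    reps = np.concatenate(dists)
    reps = reps[~np.isnan(reps)]
    if reps.size < 2:
        return 0.0
    return float(np.std(reps, ddof=1))


def bootstrap_se_matrix(
    alignment: MultipleAlignment,
    replicates: int = 1000,
    seed: int | None = None,
) -> np.ndarray:
    """Bootstrap SEs for every pair; one seed stream, pair order fixed by ids."""
    rng = np.random.default_rng(seed)
    n = alignment.n_rows
    se = np.full((n, n), np.nan)
    np.fill_diagonal(se, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            val = bootstrap_se(
                alignment, (alignment.ids[i], alignment.ids[j]), replicates, sub_seed
            )
            se[i, j] = se[j, i] = val
    return se
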