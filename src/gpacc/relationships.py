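"""Pedigree and genomic relationship matrices.

Builds the additive (numerator) relationship matrix ``A`` from a pedigree by
the tabular method, genomic relationship matrices ``G`` from marker dosages
(VanRaden methods 1 and 2), the reciprocal-variance estimator of the
effective number of chromosome segments from ``G - A``, and the
decomposition of GEBV into a pedigree-trackable part and a genomic deviation
(``g_A* = A G^-1 g_G``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "RelationshipMatrix",
    "build_A",
    "build_G",
    "me_from_relationship_variance",
    "decompose_gebv",
    "read_pedigree",
    "write_pedigree",
    "read_dosages",
    "write_dosages",
]

UNKNOWN_PARENT = 0  # sentinel in pedigree files; empty fields map to it too


@dataclass
class Pedigree:
    """Ordered pedigree records (id, sire, dam, generation).

    Unknown parents are encoded as 0.  Individuals must appear after both of
    their parents; ids must be unique and positive.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"id", "sire", "dam"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"pedigree table is missing columns {sorted(missing)}")
        if "generation" not in self.table.columns:
            self.table = self.table.assign(generation=0)
        ids = self.table["id"].to_numpy()
        if len(ids) != len(set(ids)):
            raise ValueError("pedigree ids are not unique")
        if (ids <= 0).any():
            raise ValueError("pedigree ids must be positive integers")
        seen: set[int] = set()
        for rec in self.table.itertuples(index=False):
            for parent in (rec.sire, rec.dam):
                if parent != UNKNOWN_PARENT and parent not in seen:
                    raise ValueError(
                        f"individual {rec.id} precedes its parent {parent} "
                        "(pedigree must be sorted, parents before offspring, "
                        "and acyclic)"
                    )
            seen.add(rec.id)

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class RelationshipMatrix:
    """Symmetric relationship matrix with its id ordering and provenance."""

    values: np.ndarray
    ids: np.ndarray
    kind: Literal["A", "G_method1", "G_method2", "G_minus_A"] = "A"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = np.asarray(self.ids)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )

    def subset(self, ids: Sequence[int]) -> "RelationshipMatrix":
        """Restriction to the given ids (in the given order)."""
        pos = {int(i): j for j, i in enumerate(self.ids)}
        idx = np.array([pos[int(i)] for i in ids])
        return RelationshipMatrix(
            self.values[np.ix_(idx, idx)], np.asarray(ids), self.kind
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Additive relationship matrix by the tabular method.

    ``A[i, j] = 0.5 * (A[s_i, j] + A[d_i, j])`` for j processed before i, and
    ``A[i, i] = 1 + 0.5 * A[s_i, d_i]`` (1 + inbreeding coefficient).
    Founders with unknown parents are treated as unrelated and non-inbred.
    """
    ids = ped.ids
    n = len(ids)
    pos = {int(i): j for j, i in enumerate(ids)}
    sire_idx = np.array(
        [pos[int(s)] if s != UNKNOWN_PARENT else -1 for s in ped.table["sire"]]
    )
    dam_idx = np.array(
        [pos[int(d)] if d != UNKNOWN_PARENT else -1 for d in ped.table["dam"]]
    )
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire_idx[i], dam_idx[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return RelationshipMatrix(A, ids, "A")


def build_G(
    dosages: np.ndarray,
    ids: Sequence[int],
    method: Literal[1, 2] = 2,
    freqs: Optional[np.ndarray] = None,
) -> RelationshipMatrix:
    """Genomic relationship matrix from 0/1/2 dosages.

    Method 1 scales the centered cross-product by ``2 * sum_j p_j (1 - p_j)``;
    method 2 averages locus-wise cross-products each scaled by
    ``2 * p_j * (1 - p_j)`` (monomorphic loci are excluded from the average).
    Allele frequencies default to those observed in ``dosages``; base
    population frequencies may be supplied instead.
    """
    X = np.asarray(dosages, dtype=float)
    if X.ndim != 2:
        raise ValueError("dosages must be a 2-D (individuals x loci) matrix")
    if np.isnan(X).any():
        raise ValueError("missing dosages are not supported")
    if X.min() < 0 or X.max() > 2:
        raise ValueError("dosages must lie in [0, 2]")
    n, m = X.shape
    if freqs is None:
        p = X.mean(axis=0) / 2.0
    else:
        p = np.asarray(freqs, dtype=float)
        if p.shape != (m,):
            raise ValueError("freqs must have one entry per locus")
    het = 2.0 * p * (1.0 - p)
    poly = het > 0
    if not poly.any():
        raise ValueError("all loci are monomorphic; G is undefined")
    Z = X - 2.0 * p
    if method == 1:
        G = (Z @ Z.T) / het.sum()
        kind = "G_method1"
    elif method == 2:
        if m < 2:
            raise ValueError("method 2 requires at least 2 loci")
        Zp = Z[:, poly] / np.sqrt(het[poly])
        G = (Zp @ Zp.T) / poly.sum()
        kind = "G_method2"
    else:
        raise ValueError(f"method must be 1 or 2, got {method}")
    return RelationshipMatrix(G, np.asarray(ids), kind)


def me_from_relationship_variance(
    G: RelationshipMatrix, A: RelationshipMatrix
) -> float:
    """``Me`` as the reciprocal of var(G - A) over all pairs of individuals.

    Uses the unbiased variance of the off-diagonal (unordered-pair) elements
    of ``G - A`` over a common id set.
    """
    if not np.array_equal(G.ids, A.ids):
        A = A.subset(G.ids)
    n = len(G.ids)
    if n < 2:
        raise ValueError("at least 2 individuals are required")
    D = G.values - A.values
    iu = np.triu_indices(n, k=1)
    var = float(np.var(D[iu], ddof=1))
    if var == 0.0:
        raise ValueError("zero relationship variance: G equals A off-diagonal")
    return 1.0 / var


def decompose_gebv(
    gebv: np.ndarray,
    A: RelationshipMatrix,
    G: RelationshipMatrix,
    ridge: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Split GEBV into a pedigree-trackable part and a genomic deviation.

    ``g_A* = A G^-1 g_G`` and ``g_D = g_G - g_A*``; the two parts sum back to
    the input exactly.  A small diagonal ridge (e.g. 1e-6) may be supplied for
    a near-singular ``G``.
    """
    gebv = np.asarray(gebv, dtype=float)
    if not np.array_equal(A.ids, G.ids):
        A = A.subset(G.ids)
    Gv = G.values
    if ridge is not None:
        Gv = Gv + ridge * np.eye(len(G.ids))
    try:
        sol = np.linalg.solve(Gv, gebv)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "G is singular; pass ridge=1e-6 (or similar) to regularize"
        ) from exc
    g_A_star = A.values @ sol
    return g_A_star, gebv - g_A_star


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------


def read_pedigree(path) -> Pedigree:
    """Read a pedigree CSV with columns id, sire, dam[, generation].

    Empty or 0 parent fields mean unknown.
    """
    table = pd.read_csv(path)
    for col in ("sire", "dam"):
        table[col] = table[col].fillna(UNKNOWN_PARENT).astype(int)
    table["id"] = table["id"].astype(int)
    return Pedigree(table)


def write_pedigree(ped: Pedigree, path) -> None:
    ped.table.to_csv(path, index=False)


def read_dosages(path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read a whitespace-delimited dosage table.

    First column is the individual id, the header row names the loci; values
    are 0/1/2 dosages.  Returns (dosages, ids, locus names).
    """
    table = pd.read_csv(path, sep=r"\s+")
    ids = table.iloc[:, 0].to_numpy()
    X = table.iloc[:, 1:].to_numpy(dtype=float)
    return X, ids, list(table.columns[1:])


def write_dosages(
    path, dosages: np.ndarray, ids: Sequence[int], loci: Optional[Sequence[str]] = None
) -> None:
    X = np.asarray(dosages)
    if loci is None:
        loci = [f"snp{j + 1}" for j in range(X.shape[1])]
    table = pd.DataFrame(X, columns=list(loci))
    table.insert(0, "id", list(ids))
    table.to_csv(path, sep="\t", index=False)
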