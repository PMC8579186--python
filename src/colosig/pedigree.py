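"""Pedigree container and numerator relationship matrix.

The additive (numerator) relationship matrix ``A`` encodes expected
identity-by-descent between animals: ``A[i, j]`` is twice the kinship
coefficient, and the diagonal is ``1 + F_i`` where ``F_i`` is the
inbreeding coefficient.  It is built by the tabular method, the classical
recursion over a parent-before-offspring ordered pedigree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN = 0


class PedigreeError(ValueError):
    """Raised for cyclic, duplicated or otherwise malformed pedigrees."""


@dataclass
class Pedigree:
    """Ordered pedigree records.

    Parameters
    ----------
    records : pandas.DataFrame
        Columns ``animal``, ``sire``, ``dam`` (integer ids; ``0`` means
        unknown parent).  Additional columns (sex, generation, birth
        order) are preserved but ignored by the relationship machinery.
    """

    records: pd.DataFrame
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        df = self.records
        for col in ("animal", "sire", "dam"):
            if col not in df.columns:
                raise PedigreeError(f"pedigree is missing column {col!r}")
        animals = df["animal"].to_numpy()
        if len(set(animals)) != len(animals):
            raise PedigreeError("duplicate animal ids in pedigree")
        if (animals == UNKNOWN).any():
            raise PedigreeError("animal id 0 is reserved for unknown parents")
        self.records = df.reset_index(drop=True)
        self._index = {a: i for i, a in enumerate(self.records["animal"])}
        self._validate_order()

    def _validate_order(self) -> None:
        seen: set[int] = set()
        for row in self.records.itertuples(index=False):
            for parent in (row.sire, row.dam):
                if parent != UNKNOWN and parent not in self._index:
                    raise PedigreeError(
                        f"parent {parent} of animal {row.animal} has no record"
                    )
                if parent != UNKNOWN and parent not in seen:
                    # not yet seen: pedigree unordered; caller should sort
                    raise PedigreeError(
                        "pedigree not ordered parents-before-offspring; "
                        "use Pedigree.from_unordered()"
                    )
            seen.add(row.animal)

    @classmethod
    def from_unordered(cls, records: pd.DataFrame) -> "Pedigree":
        """Topologically sort records (parents before offspring) and build."""
        df = records.reset_index(drop=True)
        ids = list(df["animal"])
        sire = dict(zip(df["animal"], df["sire"]))
        dam = dict(zip(df["animal"], df["dam"]))
        order: list[int] = []
        state: dict[int, int] = {}  # 0 unvisited, 1 in stack, 2 done

        def visit(a: int) -> None:
            stack = [(a, False)]
            while stack:
                node, processed = stack.pop()
                if processed:
                    state[node] = 2
                    order.append(node)
                    continue
                if state.get(node) == 2:
                    continue
                if state.get(node) == 1:
                    raise PedigreeError(f"pedigree cycle involving animal {node}")
                state[node] = 1
                stack.append((node, True))
                for p in (sire.get(node, UNKNOWN), dam.get(node, UNKNOWN)):
                    if p != UNKNOWN and state.get(p) != 2:
                        if p not in sire:
                            raise PedigreeError(f"parent {p} has no record")
                        stack.append((p, False))

        for a in ids:
            if state.get(a) != 2:
                visit(a)
        pos = {a: i for i, a in enumerate(order)}
        df = df.iloc[np.argsort([pos[a] for a in ids])].reset_index(drop=True)
        return cls(df)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def animals(self) -> np.ndarray:
        return self.records["animal"].to_numpy()

    def index_of(self, animal_ids) -> np.ndarray:
        """Row/column positions of the given animals in the A matrix."""
        return np.asarray([self._index[a] for a in np.asarray(animal_ids)])

    def to_csv(self, path) -> None:
        self.records[["animal", "sire", "dam"]].to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "Pedigree":
        df = pd.read_csv(path)
        return cls.from_unordered(df)


def build_a_matrix(pedigree: Pedigree) -> np.ndarray:
    """Numerator relationship matrix by the tabular method.

    ``A[i, i] = 1 + 0.5 * A[sire_i, dam_i]`` and for j earlier than i,
    ``A[i, j] = 0.5 * (A[j, sire_i] + A[j, dam_i])``; an unknown parent
    contributes zero.  Returns a dense symmetric matrix in pedigree order.
    """
    n = len(pedigree)
    df = pedigree.records
    sires = np.array([pedigree._index.get(s, -1) for s in df["sire"]])
    dams = np.array([pedigree._index.get(d, -1) for d in df["dam"]])
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sires[i], dams[i]
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        if i == 0:
            continue
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
    return A


def inbreeding(pedigree: Pedigree) -> np.ndarray:
    """Inbreeding coefficients ``F_i = A[i, i] - 1`` in pedigree order."""
    return np.diag(build_a_matrix(pedigree)) - 1.0


def relationship_gene_flow(pedigree: Pedigree) -> np.ndarray:
    """Independent oracle for the relationship matrix via A = T D T'.

    Henderson's decomposition: ``T`` is the lower-triangular gene-flow
    matrix (``T[i, i] = 1``, ``T[i, k] = 0.5 * (T[s, k] + T[d, k])``,
    the expected path contribution of every ancestor ``k`` to ``i``) and
    ``D`` is the diagonal of Mendelian-sampling variances
    ``D_i = 0.5 - 0.25 * (F_s + F_d)`` (with 0.25 added back per unknown
    parent).  Inbreeding coefficients of parents are read off the
    partially accumulated product, so no tabular recursion is used.
    Quadratic time and memory; intended for cross-checks in tests.
    """
    n = len(pedigree)
    df = pedigree.records
    sires = np.array([pedigree._index.get(s, -1) for s in df["sire"]])
    dams = np.array([pedigree._index.get(d, -1) for d in df["dam"]])
    T = np.zeros((n, n))
    D = np.zeros(n)
    diag = np.zeros(n)  # accumulated A_ii = sum_k T[i,k]^2 D_k
    for i in range(n):
        s, d = sires[i], dams[i]
        T[i, i] = 1.0
        if s >= 0:
            T[i, :i] += 0.5 * T[s, :i]
        if d >= 0:
            T[i, :i] += 0.5 * T[d, :i]
        D[i] = 1.0
        if s >= 0:
            F_s = diag[s] - 1.0
            D[i] -= 0.25 * (1.0 + F_s)
        if d >= 0:
            F_d = diag[d] - 1.0
            D[i] -= 0.25 * (1.0 + F_d)
        diag[i] = np.sum(T[i, : i + 1] ** 2 * D[: i + 1])
    return (T * D) @ T.T
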