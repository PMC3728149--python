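"""Species-level divergence matrices and Mantel / partial Mantel tests.

CHC divergence between two species is the Euclidean distance between their
per-component median vectors; genetic divergence can be supplied as a
precomputed matrix or derived from an alignment as an uncorrected
p-distance.  Mantel statistics correlate the lower triangles of two labeled
distance (or similarity) matrices, with significance from simultaneous
row/column permutation of one matrix; the partial Mantel test removes a
third matrix by the standard first-order partial-correlation formula, with
the same permutation scheme applied to the first matrix (Smouse-Long-Sokal).

The mating-propensity matrix enters these tests directly as a similarity
(higher = more mating), so the expected sign of its correlation with a
divergence matrix is negative.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

from .chc_io import CompositionTable, LogContrastTable
from .errors import InvalidInputError

_GAP_OR_AMBIG = set("-.?NRYSWKMBDHVX")


@dataclass
class DistanceMatrix:
    """Square symmetric labeled matrix with a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise InvalidInputError("duplicate labels in distance matrix")
        if self.values.shape != (n, n):
            raise InvalidInputError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise InvalidInputError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise InvalidInputError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def triangle(self) -> np.ndarray:
        """Condensed lower-triangle entries (row-major, i > j)."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels=list(labels),
                              values=self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DistanceMatrix":
        return cls(labels=list(df.index), values=df.to_numpy(dtype=float))

    @classmethod
    def read(cls, path, sep: str = "\t") -> "DistanceMatrix":
        return cls.from_dataframe(pd.read_csv(path, sep=sep, index_col=0,
                                              comment="#"))

    def write(self, path, sep: str = "\t",
              header_comment: str | None = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            self.to_dataframe().to_csv(fh, sep=sep)


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    tail: str
    partial: bool = False


def _median_table(data, species=None) -> pd.DataFrame:
    if isinstance(data, CompositionTable):
        values, labels = data.proportions, data.meta["species"]
    elif isinstance(data, LogContrastTable):
        values, labels = data.values, data.meta["species"]
    elif isinstance(data, pd.DataFrame):
        if species is None:
            raise InvalidInputError("species labels required for a raw DataFrame")
        values, labels = data, pd.Series(list(species), index=data.index)
    else:
        raise InvalidInputError(f"unsupported data type {type(data)!r}")
    if species is not None and not isinstance(data, pd.DataFrame):
        labels = pd.Series(list(species), index=values.index)
    return values.groupby(labels.to_numpy()).median()


def species_median_distance(data, species=None) -> DistanceMatrix:
    """Euclidean distance between per-species component medians.

    Each component is an axis; a species is the cloud of its specimens and
    is summarized by the median on each axis; the distance between two
    species is the distance between those median points.
    """
    med = _median_table(data, species)
    if med.isna().to_numpy().any():
        raise InvalidInputError("species with no specimens in median table")
    arr = med.to_numpy(dtype=float)
    diff = arr[:, None, :] - arr[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=list(med.index), values=d)


def per_component_difference(data, component: str, species=None) -> DistanceMatrix:
    """|median_A - median_B| for one named component."""
    med = _median_table(data, species)
    if component not in med.columns:
        raise InvalidInputError(
            f"unknown component {component!r}; have {list(med.columns)}"
        )
    v = med[component].to_numpy(dtype=float)
    d = np.abs(v[:, None] - v[None, :])
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=list(med.index), values=d)


def p_distance(sequences: dict[str, str] | None = None,
               fasta_path=None) -> DistanceMatrix:
    """Uncorrected p-distance: mismatches / compared sites.

    Sites with a gap or ambiguity code in either sequence are skipped.
    """
    if sequences is None:
        if fasta_path is None:
            raise InvalidInputError("provide sequences or a FASTA path")
        sequences = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")
        }
    labels = list(sequences)
    if len(labels) < 2:
        raise InvalidInputError("need at least 2 sequences")
    seqs = [sequences[l].upper() for l in labels]
    L = len(seqs[0])
    for l, s in zip(labels, seqs):
        if len(s) != L:
            raise InvalidInputError(
                f"sequence {l!r} length {len(s)} != {L}; alignment required"
            )
    arrs = [np.frombuffer(s.encode(), dtype="S1") for s in seqs]
    valid = [~np.isin(a, [g.encode() for g in _GAP_OR_AMBIG]) for a in arrs]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = valid[i] & valid[j]
            m = int(ok.sum())
            if m == 0:
                raise InvalidInputError(
                    f"no comparable sites between {labels[i]!r} and {labels[j]!r}"
                )
            d[i, j] = d[j, i] = float((arrs[i][ok] != arrs[j][ok]).sum()) / m
    return DistanceMatrix(labels=labels, values=d)


def _check_aligned(*mats: DistanceMatrix) -> None:
    labels = mats[0].labels
    for m in mats[1:]:
        if m.labels != labels:
            raise InvalidInputError("distance matrices have different labels")


def _triangle_r(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def _tail_p(r_obs: float, r_perm: np.ndarray, tail: str,
            exact: bool) -> float:
    tol = 1e-12
    if tail == "two-sided":
        exceed = np.sum(np.abs(r_perm) >= abs(r_obs) - tol)
    elif tail == "upper":
        exceed = np.sum(r_perm >= r_obs - tol)
    elif tail == "lower":
        exceed = np.sum(r_perm <= r_obs + tol)
    else:
        raise InvalidInputError(f"unknown tail {tail!r}")
    if exact:
        return float(exceed) / len(r_perm)
    return (int(exceed) + 1) / (len(r_perm) + 1)


def mantel(
    A: DistanceMatrix,
    B: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    tail: str = "two-sided",
    exact: bool = False,
) -> MantelResult:
    """Mantel matrix correlation with a row/column permutation null.

    r is the Pearson correlation of the lower triangles; the null permutes
    the labels of A (rows and columns simultaneously).  ``exact=True``
    enumerates all n! label permutations (identity included) instead of
    sampling, and p = #(as extreme) / n!.
    """
    _check_aligned(A, B)
    n = A.n
    if n < 3:
        raise InvalidInputError("Mantel test needs at least 3 labels")
    a_tri, b_tri = A.triangle(), B.triangle()
    if np.std(a_tri) == 0 or np.std(b_tri) == 0:
        raise InvalidInputError("zero variance in a distance triangle")
    r_obs = _triangle_r(a_tri, b_tri)
    tri_i, tri_j = np.tril_indices(n, k=-1)

    def r_for(perm: np.ndarray) -> float:
        av = A.values[np.ix_(perm, perm)][tri_i, tri_j]
        return _triangle_r(av, b_tri)

    if exact:
        perms = list(itertools.permutations(range(n)))
        r_perm = np.array([r_for(np.array(p)) for p in perms])
        p = _tail_p(r_obs, r_perm, tail, exact=True)
        return MantelResult(r=r_obs, p=p, n_perm=len(perms), tail=tail)
    if seed is None:
        raise InvalidInputError("seed is required for sampled permutations")
    rng = np.random.default_rng(seed)
    r_perm = np.array([r_for(rng.permutation(n)) for _ in range(n_perm)])
    p = _tail_p(r_obs, r_perm, tail, exact=False)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm, tail=tail)


def _partial_r(rab: float, rac: float, rbc: float) -> float:
    if min(1 - rac * rac, 1 - rbc * rbc) < 1e-12:
        raise InvalidInputError(
            "degenerate partialling: a control correlation is +/-1"
        )
    return (rab - rac * rbc) / math.sqrt((1 - rac * rac) * (1 - rbc * rbc))


def partial_mantel(
    A: DistanceMatrix,
    B: DistanceMatrix,
    C: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    tail: str = "two-sided",
    exact: bool = False,
) -> MantelResult:
    """Partial Mantel correlation r_{AB.C} with permutation of A only."""
    _check_aligned(A, B, C)
    n = A.n
    if n < 4:
        raise InvalidInputError("partial Mantel needs at least 4 labels")
    a_tri, b_tri, c_tri = A.triangle(), B.triangle(), C.triangle()
    for name, tri in (("A", a_tri), ("B", b_tri), ("C", c_tri)):
        if np.std(tri) == 0:
            raise InvalidInputError(f"zero variance in triangle of {name}")
    rbc = _triangle_r(b_tri, c_tri)
    r_obs = _partial_r(_triangle_r(a_tri, b_tri), _triangle_r(a_tri, c_tri), rbc)
    tri_i, tri_j = np.tril_indices(n, k=-1)

    def r_for(perm: np.ndarray) -> float:
        av = A.values[np.ix_(perm, perm)][tri_i, tri_j]
        return _partial_r(_triangle_r(av, b_tri), _triangle_r(av, c_tri), rbc)

    if exact:
        perms = list(itertools.permutations(range(n)))
        r_perm = np.array([r_for(np.array(p)) for p in perms])
        p = _tail_p(r_obs, r_perm, tail, exact=True)
        return MantelResult(r=r_obs, p=p, n_perm=len(perms), tail=tail,
                            partial=True)
    if seed is None:
        raise InvalidInputError("seed is required for sampled permutations")
    rng = np.random.default_rng(seed)
    r_perm = np.array([r_for(rng.permutation(n)) for _ in range(n_perm)])
    p = _tail_p(r_obs, r_perm, tail, exact=False)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm, tail=tail, partial=True)
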