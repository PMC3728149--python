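"""Distance-based permutation MANOVA, Wilks MANOVA, and discriminant analysis.

The permutation MANOVA partitions squared Euclidean distances on (typically
log-contrast) coordinates into a nested decomposition: an outer factor
(species, or host plant), inner units nested within it (populations), and a
residual.  For Euclidean distance this equals the classical nested ANOVA
trace partition, which is what is computed here.

Two permutation schemes mirror the nested design: the outer effect is tested
by randomizing whole inner units (populations) between outer levels; the
inner effect by randomizing individuals among inner units within each outer
level.  The outer pseudo-F is tested against the nested mean square, the
inner pseudo-F against the residual.  p-values use the
(exceedances + 1)/(n_perm + 1) convention so that p is never exactly zero.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .chc_io import LogContrastTable
from .errors import InvalidInputError, NumericalError

_EPS = 1e-12


@dataclass
class NestedDesign:
    """Outer (species/host) and inner (population) labels per specimen.

    Every inner level must map to exactly one outer level.  If the inner
    labels coincide with the outer labels the nested term is absent and the
    outer effect is tested directly against the residual.
    """

    outer: np.ndarray
    inner: np.ndarray
    specimens: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.outer = np.asarray(self.outer, dtype=object)
        self.inner = np.asarray(self.inner, dtype=object)
        if self.outer.shape != self.inner.shape:
            raise InvalidInputError("outer and inner label arrays differ in length")
        if len(np.unique(self.outer)) < 2:
            raise InvalidInputError("need at least 2 outer levels")
        # an inner unit is the (outer, inner) pair; check inner labels are
        # not reused across outer levels under the same name with different
        # meaning — we key units by the pair, so this is always consistent.
        pairs = {}
        for o, i in zip(self.outer, self.inner):
            if i in pairs and pairs[i] != o and not _inner_equals_outer(self):
                raise InvalidInputError(
                    f"inner level {i!r} appears under outer levels "
                    f"{pairs[i]!r} and {o!r}"
                )
            pairs.setdefault(i, o)

    @property
    def n(self) -> int:
        return len(self.outer)


def _inner_equals_outer(design: NestedDesign) -> bool:
    return bool(np.all(design.outer == design.inner))


@dataclass
class PermManovaResult:
    F_outer: float
    p_outer: float
    F_inner: float | None
    p_inner: float | None
    ss: dict[str, float]
    df: dict[str, int]
    n_perm: int
    degenerate: bool = False


@dataclass
class WilksResult:
    lambda_: float
    approx_F: float
    df1: float
    df2: float
    p: float


@dataclass
class DiscriminantResult:
    loadings: pd.DataFrame          # functions x variables
    pct_between_variance: np.ndarray
    scores: pd.DataFrame            # specimens x functions
    eigenvalues: np.ndarray


def _as_matrix(data) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(data, LogContrastTable):
        return (
            data.values.to_numpy(dtype=float),
            list(data.values.index),
            list(data.values.columns),
        )
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), list(data.index), list(data.columns)
    arr = np.atleast_2d(np.asarray(data, dtype=float))
    if arr.shape[0] == 1 and arr.size > 1:
        arr = arr.T
    return arr, [str(i) for i in range(arr.shape[0])], []


def _unit_codes(design: NestedDesign) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Integer codes for outer levels and (outer, inner) units."""
    outer_codes, _ = pd.factorize(design.outer)
    # NB: avoid NUL as separator — pandas' hashing truncates at NUL bytes
    pair = np.array(
        [f"{o}\x1f{i}" for o, i in zip(design.outer, design.inner)], dtype=object
    )
    unit_codes, _ = pd.factorize(pair)
    return outer_codes, unit_codes, outer_codes.max() + 1, unit_codes.max() + 1


def _group_ss(X: np.ndarray, codes: np.ndarray, k: int) -> float:
    """Sum over groups of ||group sum||^2 / group size."""
    p = X.shape[1]
    sums = np.zeros((k, p))
    np.add.at(sums, codes, X)
    counts = np.bincount(codes, minlength=k).astype(float)
    return float(((sums ** 2).sum(axis=1) / counts).sum())


def ss_partition(X: np.ndarray, design: NestedDesign) -> tuple[dict, dict]:
    """Nested sums-of-squares partition and degrees of freedom."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n != design.n:
        raise InvalidInputError("data rows do not match design length")
    outer_codes, unit_codes, a, b = _unit_codes(design)
    total_sq = float((X ** 2).sum())
    grand = float((X.sum(axis=0) ** 2).sum()) / n
    s_outer = _group_ss(X, outer_codes, a)
    s_unit = _group_ss(X, unit_codes, b)
    ss = {
        "outer": s_outer - grand,
        "inner": s_unit - s_outer,
        "residual": total_sq - s_unit,
        "total": total_sq - grand,
    }
    df = {"outer": a - 1, "inner": b - a, "residual": n - b}
    return ss, df


def _f_ratios(ss: dict, df: dict) -> tuple[float, float | None]:
    """(F_outer, F_inner); the outer F tests against the nested mean square
    when an inner term exists, else against the residual."""
    ms_outer = ss["outer"] / df["outer"] if df["outer"] > 0 else np.nan
    has_inner = df["inner"] > 0
    ms_inner = ss["inner"] / df["inner"] if has_inner else np.nan
    ms_resid = ss["residual"] / df["residual"] if df["residual"] > 0 else np.nan
    if has_inner:
        F_outer = ms_outer / ms_inner if ms_inner > _EPS else np.nan
        F_inner = ms_inner / ms_resid if ms_resid > _EPS else np.nan
    else:
        F_outer = ms_outer / ms_resid if ms_resid > _EPS else np.nan
        F_inner = None
    return F_outer, F_inner


def _perm_pvalue(obs: float, perm: np.ndarray, n_perm: int) -> float:
    exceed = int(np.sum(perm >= obs - 1e-12))
    return (exceed + 1) / (n_perm + 1)


def nested_perm_manova(
    data,
    design: NestedDesign,
    n_perm: int = 1000,
    seed: int | None = None,
    exact: bool = False,
) -> PermManovaResult:
    """Nested permutation MANOVA on Euclidean distances.

    With ``exact=True`` all distinct permutations are enumerated (feasible
    only for small designs) and p = #(F_perm >= F_obs) / #permutations,
    the identity permutation included.
    """
    X, _, _ = _as_matrix(data)
    ss, df = ss_partition(X, design)
    F_outer, F_inner = _f_ratios(ss, df)
    if not np.isfinite(F_outer) and (F_inner is None or not np.isfinite(F_inner)):
        return PermManovaResult(
            F_outer=0.0, p_outer=float("nan"), F_inner=None, p_inner=None,
            ss=ss, df=df, n_perm=0, degenerate=True,
        )
    if seed is None and not exact:
        raise InvalidInputError("seed is required for sampled permutations")
    rng = np.random.default_rng(seed)

    outer_codes, unit_codes, a, b = _unit_codes(design)
    has_inner = df["inner"] > 0
    n = X.shape[0]

    # population-level summaries for the outer test
    p_dim = X.shape[1]
    unit_sums = np.zeros((b, p_dim))
    np.add.at(unit_sums, unit_codes, X)
    unit_counts = np.bincount(unit_codes, minlength=b).astype(float)
    unit_outer = np.empty(b, dtype=int)
    unit_outer[unit_codes] = outer_codes
    grand = float((X.sum(axis=0) ** 2).sum()) / n
    A_units = float(((unit_sums ** 2).sum(axis=1) / unit_counts).sum())
    total_sq = float((X ** 2).sum())

    def outer_F_for_assignment(assign: np.ndarray) -> float:
        sums = np.zeros((a, p_dim))
        np.add.at(sums, assign, unit_sums)
        counts = np.bincount(assign, weights=unit_counts, minlength=a)
        S = float(((sums ** 2).sum(axis=1) / counts).sum())
        ss_o = S - grand
        if has_inner:
            ss_i = A_units - S
            if ss_i <= _EPS:
                return np.inf
            return (ss_o / df["outer"]) / (ss_i / df["inner"])
        ss_r = total_sq - S
        if ss_r <= _EPS:
            return np.inf
        return (ss_o / df["outer"]) / (ss_r / df["residual"])

    def inner_ss_for_unit_codes(codes: np.ndarray) -> float:
        sums = np.zeros((b, p_dim))
        np.add.at(sums, codes, X)
        return float(((sums ** 2).sum(axis=1) / unit_counts).sum())

    # ---- outer test -------------------------------------------------------
    if has_inner:
        # randomize whole inner units (populations) between outer levels
        if b < 2:
            raise InvalidInputError("no exchangeable inner units for outer test")
        if exact:
            perms = sorted(set(itertools.permutations(unit_outer.tolist())))
            Fs = np.array(
                [outer_F_for_assignment(np.array(p, dtype=int)) for p in perms]
            )
            p_outer = float(np.mean(Fs >= F_outer - 1e-12))
            n_perm_outer = len(perms)
        else:
            Fs = np.empty(n_perm)
            for k in range(n_perm):
                Fs[k] = outer_F_for_assignment(rng.permutation(unit_outer))
            p_outer = _perm_pvalue(F_outer, Fs, n_perm)
            n_perm_outer = n_perm
    else:
        # no nested term: randomize individuals among outer groups
        if exact:
            perms = sorted(set(itertools.permutations(outer_codes.tolist())))
            Fs = []
            for p in perms:
                ss_p, df_p = ss_partition(
                    X,
                    NestedDesign(
                        outer=np.array(p, dtype=object),
                        inner=np.array(p, dtype=object),
                    ),
                )
                Fs.append(_f_ratios(ss_p, df_p)[0])
            Fs = np.array(Fs)
            p_outer = float(np.mean(Fs >= F_outer - 1e-12))
            n_perm_outer = len(perms)
        else:
            Fs = np.empty(n_perm)
            for k in range(n_perm):
                idx = rng.permutation(n)
                codes = outer_codes[idx]
                sums = np.zeros((a, p_dim))
                np.add.at(sums, codes, X)
                counts = np.bincount(codes, minlength=a).astype(float)
                S = float(((sums ** 2).sum(axis=1) / counts).sum())
                ss_r = total_sq - S
                Fs[k] = (
                    np.inf if ss_r <= _EPS
                    else ((S - grand) / df["outer"]) / (ss_r / df["residual"])
                )
            p_outer = _perm_pvalue(F_outer, Fs, n_perm)
            n_perm_outer = n_perm

    # ---- inner test -------------------------------------------------------
    p_inner = None
    if has_inner and F_inner is not None and np.isfinite(F_inner):
        s_outer_fixed = _group_ss(X, outer_codes, a)

        def inner_F(codes: np.ndarray) -> float:
            s_unit = inner_ss_for_unit_codes(codes)
            ss_i = s_unit - s_outer_fixed
            ss_r = total_sq - s_unit
            if ss_r <= _EPS:
                return np.inf
            return (ss_i / df["inner"]) / (ss_r / df["residual"])

        # randomize individuals among inner units within each outer level
        by_outer = [np.flatnonzero(outer_codes == g) for g in range(a)]
        if exact:
            per_group = []
            for idx in by_outer:
                labs = tuple(unit_codes[idx].tolist())
                per_group.append(sorted(set(itertools.permutations(labs))))
            Fs = []
            for combo in itertools.product(*per_group):
                codes = unit_codes.copy()
                for idx, labs in zip(by_outer, combo):
                    codes[idx] = labs
                Fs.append(inner_F(codes))
            Fs = np.array(Fs)
            p_inner = float(np.mean(Fs >= F_inner - 1e-12))
        else:
            Fs = np.empty(n_perm)
            codes = unit_codes.copy()
            for k in range(n_perm):
                for idx in by_outer:
                    codes[idx] = unit_codes[idx][rng.permutation(len(idx))]
                Fs[k] = inner_F(codes)
            p_inner = _perm_pvalue(F_inner, Fs, n_perm)

    return PermManovaResult(
        F_outer=float(F_outer), p_outer=float(p_outer),
        F_inner=None if F_inner is None else float(F_inner),
        p_inner=None if p_inner is None else float(p_inner),
        ss=ss, df=df, n_perm=n_perm_outer, degenerate=False,
    )


def _scatter_matrices(X: np.ndarray, groups: np.ndarray):
    codes, levels = pd.factorize(groups)
    g = len(levels)
    if g < 2:
        raise InvalidInputError("need at least 2 groups")
    n, p = X.shape
    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for k in range(g):
        Xk = X[codes == k]
        mk = Xk.mean(axis=0)
        d = Xk - mk
        W += d.T @ d
        B += len(Xk) * np.outer(mk - grand, mk - grand)
    return W, B, g, n, p


def wilks_manova(data, groups) -> WilksResult:
    """Parametric MANOVA via Wilks' lambda with Rao's F approximation.

    lambda = det(W) / det(W + B); small values indicate group separation.
    """
    X, _, _ = _as_matrix(data)
    groups = np.asarray(groups, dtype=object)
    W, B, g, n, p = _scatter_matrices(X, groups)
    sign, logdet_w = np.linalg.slogdet(W)
    if sign <= 0 or not np.isfinite(logdet_w):
        raise NumericalError(
            "within-group scatter matrix is singular; reduce the number of "
            "variables or add specimens per group"
        )
    sign_t, logdet_t = np.linalg.slogdet(W + B)
    lam = math.exp(logdet_w - logdet_t)
    q = g - 1
    v = n - g
    denom = p * p + q * q - 5
    t = math.sqrt((p * p * q * q - 4) / denom) if denom > 0 else 1.0
    w = v + q - (p + q + 1) / 2
    df1 = p * q
    df2 = w * t - (p * q) / 2 + 1
    lam_t = lam ** (1 / t)
    F = (1 - lam_t) / lam_t * df2 / df1
    pval = float(stats.f.sf(F, df1, df2))
    return WilksResult(lambda_=lam, approx_F=float(F), df1=df1, df2=df2, p=pval)


def discriminant_analysis(data, groups) -> DiscriminantResult:
    """Canonical discriminant functions: eigenvectors of W^{-1} B.

    Functions are ordered by eigenvalue; the j-th fraction of between-group
    variance is lambda_j / sum(lambda).
    """
    X, row_labels, col_labels = _as_matrix(data)
    groups = np.asarray(groups, dtype=object)
    W, B, g, n, p = _scatter_matrices(X, groups)
    try:
        evals, evecs = linalg.eigh(B, W)
    except linalg.LinAlgError as exc:  # pragma: no cover - scipy raises rarely
        raise NumericalError(f"singular within-group matrix: {exc}") from exc
    if not np.all(np.isfinite(evals)):
        raise NumericalError("singular within-group matrix in DFA")
    order = np.argsort(evals)[::-1]
    n_func = min(g - 1, p)
    evals = np.clip(evals[order][:n_func], 0.0, None)
    evecs = evecs[:, order][:, :n_func]
    # sign convention: dominant loading of each function is positive
    for j in range(n_func):
        if evecs[np.argmax(np.abs(evecs[:, j])), j] < 0:
            evecs[:, j] = -evecs[:, j]
    total = evals.sum()
    pct = evals / total if total > 0 else np.zeros_like(evals)
    func_names = [f"DF{j + 1}" for j in range(n_func)]
    if not col_labels:
        col_labels = [f"x{j}" for j in range(p)]
    loadings = pd.DataFrame(evecs.T, index=func_names, columns=col_labels)
    scores = pd.DataFrame(
        (X - X.mean(axis=0)) @ evecs, index=row_labels, columns=func_names
    )
    return DiscriminantResult(
        loadings=loadings, pct_between_variance=pct, scores=scores,
        eigenvalues=evals,
    )


def variance_partition(data, design: NestedDesign) -> dict[str, float]:
    """Fractions of total SS attributable to each stratum (sum to 1)."""
    X, _, _ = _as_matrix(data)
    ss, _ = ss_partition(X, design)
    total = ss["total"]
    if total <= _EPS:
        return {"outer": float("nan"), "inner": float("nan"),
                "residual": float("nan"), "degenerate": True}
    return {
        "outer": ss["outer"] / total,
        "inner": ss["inner"] / total,
        "residual": ss["residual"] / total,
        "degenerate": False,
    }
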