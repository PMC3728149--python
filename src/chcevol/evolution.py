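"""Maximum-likelihood models of continuous-trait change on a phylogeny.

Nine models form a 3 x 3 design: a phylogenetic class (pure-phylogenetic,
nonphylogenetic/star, punctuated) crossed with a tempo of change (distance —
change proportional to branch length; equal — every branch length 1; free —
branch lengths are free parameters).  All nine share the Brownian-motion
likelihood: tip values are multivariate normal with mean mu (the root state)
and covariance sigma^2 * C, where C_ij is the shared root-to-MRCA path
length on the *transformed* tree.

Fitting conventions:

* distance/equal tempo: mu by generalized least squares, sigma^2 in closed
  form (residual quadratic / number of informative tips), one counted
  parameter (mu is profiled and uncounted, matching the AIC bookkeeping of
  the 3 x 3 framework);
* punctuated classes: the likelihood is additionally maximized over the
  2^(n-1) assignments of which daughter changes at each bifurcation
  (exhaustive up to 15 internal nodes, hill-climbing beyond);
* free tempo: sigma^2 is fixed at 1 and branch lengths are optimized,
  bounded below by eps because the likelihood is unbounded as a branch
  length shrinks onto a fitted tip; such fits are flagged "boundary".

Tips whose root path on the transformed tree has zero length are exact
observations of mu (point masses): they constrain mu and contribute nothing
to the log-likelihood; discordant point masses give lnL = -inf.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .errors import InvalidInputError, NumericalError
from .trees import Node, Phylogeny, transform_tree, _len

LOG2PI = math.log(2.0 * math.pi)
_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class ModelSpec:
    """One of the nine trait-change models."""

    phylo_class: str  # pure_phylogenetic | nonphylogenetic | punctuated
    tempo: str        # distance | equal | free

    def __post_init__(self) -> None:
        if self.phylo_class not in (
            "pure_phylogenetic", "nonphylogenetic", "punctuated"
        ):
            raise InvalidInputError(
                f"unknown phylogenetic class {self.phylo_class!r}"
            )
        if self.tempo not in ("distance", "equal", "free"):
            raise InvalidInputError(f"unknown tempo {self.tempo!r}")

    @property
    def name(self) -> str:
        short = {
            "pure_phylogenetic": "pure",
            "nonphylogenetic": "nonphylo",
            "punctuated": "punct",
        }
        return f"{short[self.phylo_class]}/{self.tempo}"


ALL_MODELS: tuple[ModelSpec, ...] = tuple(
    ModelSpec(pc, t)
    for pc in ("pure_phylogenetic", "nonphylogenetic", "punctuated")
    for t in ("distance", "equal", "free")
)


def n_params(spec: ModelSpec, n_tips: int) -> int:
    """Counted parameters P: 1 for single-rate models; for free tempo the
    number of optimized branch lengths (2n-2, n, n-1)."""
    if spec.tempo != "free":
        return 1
    return {
        "pure_phylogenetic": 2 * n_tips - 2,
        "nonphylogenetic": n_tips,
        "punctuated": n_tips - 1,
    }[spec.phylo_class]


@dataclass
class ModelFit:
    spec: ModelSpec
    lnL: float
    rate: float
    root_state: float
    n_params: int
    aic: float
    branch_params: np.ndarray | None = None
    punct_assignment: tuple[int, ...] | None = None
    boundary: bool = False
    message: str = ""


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _tip_values(tree: Phylogeny, tips) -> np.ndarray:
    labels = tree.tip_labels
    if isinstance(tips, dict):
        missing = [l for l in labels if l not in tips]
        if missing:
            raise InvalidInputError(f"tip values missing for {missing}")
        return np.array([float(tips[l]) for l in labels])
    arr = np.asarray(tips, dtype=float)
    if arr.shape != (len(labels),):
        raise InvalidInputError(
            f"expected {len(labels)} tip values, got shape {arr.shape}"
        )
    return arr


def bm_loglik(
    tree: Phylogeny,
    tips,
    rate: float,
    root_state: float,
    method: str = "pruning",
) -> float:
    """Brownian-motion log-likelihood of tip values.

    ``method='pruning'`` uses Felsenstein's contrast-style post-order pass;
    ``method='direct'`` evaluates the multivariate normal density from the
    covariance matrix.  Both handle zero-length root paths by exact
    conditioning on the root state.
    """
    if rate <= 0:
        raise InvalidInputError("rate must be > 0")
    x = _tip_values(tree, tips)
    if method == "pruning":
        return _loglik_pruning(tree, x, rate, root_state)
    if method == "direct":
        return _loglik_direct(tree.covariance() * rate, x, root_state)
    raise InvalidInputError(f"unknown method {method!r}")


def _loglik_pruning(tree: Phylogeny, x: np.ndarray, rate: float,
                    root_state: float) -> float:
    flat = tree._flatten()
    tip_index = flat["tip_index"]

    def prune(node: Node) -> tuple[float, float, float]:
        if node.is_tip:
            return x[tip_index[id(node)]], 0.0, 0.0
        mean = var = lnl = 0.0
        first = True
        for ch in node.children:
            m_c, v_c, l_c = prune(ch)
            v_c += rate * _len(ch)
            if first:
                mean, var, lnl = m_c, v_c, l_c
                first = False
                continue
            lnl += l_c
            s = var + v_c
            if s <= _ZERO_TOL:
                if abs(mean - m_c) > 1e-9:
                    lnl = -math.inf
                continue
            d = mean - m_c
            lnl += -0.5 * (LOG2PI + math.log(s)) - d * d / (2.0 * s)
            mean = (mean * v_c + m_c * var) / s
            var = var * v_c / s
        return mean, var, lnl

    mean, var, lnl = prune(tree.root)
    if not math.isfinite(lnl):
        return -math.inf
    if var <= _ZERO_TOL:
        if abs(mean - root_state) > 1e-9:
            return -math.inf
        return lnl
    d = mean - root_state
    return lnl - 0.5 * (LOG2PI + math.log(var)) - d * d / (2.0 * var)


def _loglik_direct(C: np.ndarray, x: np.ndarray, root_state: float,
                   jitter: float | None = None) -> float:
    d = np.diag(C)
    zero = d <= _ZERO_TOL
    if zero.any():
        if np.any(np.abs(x[zero] - root_state) > 1e-9):
            return -math.inf
    S = ~zero
    m = int(S.sum())
    if m == 0:
        return 0.0
    Css = C[np.ix_(S, S)]
    if jitter:
        Css = Css + jitter * np.eye(m)
    r = x[S] - root_state
    try:
        cho = linalg.cho_factor(Css, lower=True)
    except linalg.LinAlgError as exc:
        raise NumericalError(
            "singular tip covariance; pass a jitter to regularize"
        ) from exc
    logdet = 2.0 * float(np.log(np.diag(cho[0])).sum())
    q = float(r @ linalg.cho_solve(cho, r))
    return -0.5 * (m * LOG2PI + logdet + q)


# ---------------------------------------------------------------------------
# closed-form single-rate fits
# ---------------------------------------------------------------------------

def _gls_scaled_fit(C: np.ndarray, x: np.ndarray):
    """Profile (mu, sigma^2) for covariance sigma^2 * C.

    Returns (lnL, sigma2, mu) or (-inf, nan, nan) when point-mass tips are
    discordant or C is numerically singular.
    """
    n = len(x)
    d = np.diag(C)
    zero = d <= _ZERO_TOL
    if zero.any():
        zvals = x[zero]
        if np.ptp(zvals) > 1e-9:
            return -math.inf, math.nan, math.nan
        mu = float(zvals[0])
        S = ~zero
        m = int(S.sum())
        if m == 0:
            return -math.inf, math.nan, mu
        Css = C[np.ix_(S, S)]
        try:
            cho = linalg.cho_factor(Css, lower=True)
        except linalg.LinAlgError:
            return -math.inf, math.nan, math.nan
        r = x[S] - mu
        q = float(r @ linalg.cho_solve(cho, r))
    else:
        m = n
        try:
            cho = linalg.cho_factor(C, lower=True)
        except linalg.LinAlgError:
            return -math.inf, math.nan, math.nan
        ones = np.ones(n)
        Ci_one = linalg.cho_solve(cho, ones)
        mu = float(Ci_one @ x) / float(Ci_one @ ones)
        r = x - mu
        q = float(r @ linalg.cho_solve(cho, r))
    logdet = 2.0 * float(np.log(np.diag(cho[0])).sum())
    sigma2 = max(q / m, 1e-300)
    lnL = -0.5 * m * (LOG2PI + math.log(sigma2)) - 0.5 * logdet - 0.5 * m
    return lnL, sigma2, mu


def _edge_masks(tree: Phylogeny):
    """Tip-membership mask and original length per non-root preorder edge."""
    flat = tree._flatten()
    edges = [n for n in flat["preorder"] if n is not tree.root]
    member = flat["member"]
    tip_index = flat["tip_index"]
    n = len(flat["tips"])
    masks = np.zeros((len(edges), n), dtype=float)
    lengths = np.zeros(len(edges))
    for k, e in enumerate(edges):
        if e.is_tip:
            masks[k, tip_index[id(e)]] = 1.0
        else:
            masks[k] = member[id(e)].astype(float)
        lengths[k] = _len(e)
    return masks, lengths


def _punct_node_info(tree: Phylogeny):
    """Per internal node (preorder): per-child tip masks and edge lengths."""
    flat = tree._flatten()
    member = flat["member"]
    tip_index = flat["tip_index"]
    n = len(flat["tips"])
    info = []
    for node in flat["internals"]:
        entry = []
        for ch in node.children:
            if ch.is_tip:
                mask = np.zeros(n, dtype=float)
                mask[tip_index[id(ch)]] = 1.0
            else:
                mask = member[id(ch)].astype(float)
            entry.append((mask, _len(ch)))
        info.append(entry)
    return info


def _punct_cov(info, bits, tempo: str) -> np.ndarray:
    n = len(info[0][0][0])
    C = np.zeros((n, n))
    for k, entry in enumerate(info):
        mask, length = entry[bits[k]]
        t = length if tempo == "distance" else 1.0
        C += t * np.outer(mask, mask)
    return C


def _punct_rep_values(tree: Phylogeny, x: np.ndarray, bits):
    """Root state and per-node change magnitudes implied by an assignment.

    Following retained (zero-length) daughters from any node reaches the tip
    whose value equals that node's ancestral state; the change on internal
    node k's changing branch is the difference between the representative
    values of the changing daughter and of the node itself.
    """
    flat = tree._flatten()
    tip_index = flat["tip_index"]
    internals = flat["internals"]
    node_bit = {id(node): bits[k] for k, node in enumerate(internals)}

    rep_cache: dict[int, float] = {}

    def rep(node: Node) -> float:
        key = id(node)
        if key in rep_cache:
            return rep_cache[key]
        if node.is_tip:
            v = x[tip_index[key]]
        else:
            retained = node.children[1 - node_bit[key]]
            v = rep(retained)
        rep_cache[key] = v
        return v

    mu = rep(tree.root)
    z = np.array(
        [rep(node.children[node_bit[id(node)]]) - rep(node)
         for node in internals]
    )
    return mu, z


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def fit_model(
    tree: Phylogeny,
    tips,
    spec: ModelSpec,
    eps: float = 1e-6,
    n_starts: int = 10,
    seed: int = 0,
    max_internal_exhaustive: int = 15,
    punct_assignment: str | tuple = "max",
) -> ModelFit:
    """Fit one of the nine models by maximum likelihood and report its AIC.

    ``punct_assignment`` controls the punctuated daughter assignment:
    "max" profiles over all 2^(n-1) assignments (exhaustive up to
    ``max_internal_exhaustive`` internal nodes, hill-climbing beyond);
    "fixed" uses the canonical data-independent assignment (the first
    daughter at every node changes); an explicit 0/1 tuple fixes it.
    Model *comparison* across classes should use a fixed assignment — the
    profile maximum is not an honest 1-parameter fit (see aic_model_table).
    """
    x = _tip_values(tree, tips)
    n = len(x)
    if np.ptp(x) <= 0:
        raise NumericalError(
            "zero trait variance: likelihood unbounded under punctuated models"
        )
    P = n_params(spec, n)

    if spec.phylo_class == "punctuated":
        fit = _fit_punctuated(tree, x, spec, eps, seed, max_internal_exhaustive,
                              punct_assignment)
    elif spec.tempo == "free":
        if spec.phylo_class == "nonphylogenetic":
            fit = _fit_nonphylo_free(tree, x, eps)
        else:
            fit = _fit_pure_free(tree, x, eps, n_starts, seed)
    else:
        t = transform_tree(tree, spec.phylo_class, spec.tempo)
        lnL, sigma2, mu = _gls_scaled_fit(t.covariance(), x)
        if not math.isfinite(lnL):
            raise NumericalError(f"degenerate fit for {spec.name}")
        fit = ModelFit(spec=spec, lnL=lnL, rate=sigma2, root_state=mu,
                       n_params=P, aic=math.nan)
    fit.n_params = P
    fit.aic = -2.0 * fit.lnL + 2.0 * P
    return fit


def _fit_punctuated(tree, x, spec, eps, seed, max_exhaustive,
                    assignment="max") -> ModelFit:
    info = _punct_node_info(tree)
    n_int = len(info)
    if isinstance(assignment, (tuple, list)):
        if len(assignment) != n_int:
            raise InvalidInputError(
                f"assignment length {len(assignment)} != {n_int} internal nodes"
            )
        bits = tuple(int(b) for b in assignment)
        best = _punct_eval(tree, x, spec, info, bits, eps) + (bits,)
    elif assignment == "fixed":
        bits = (0,) * n_int
        best = _punct_eval(tree, x, spec, info, bits, eps) + (bits,)
    elif assignment == "max":
        if n_int <= max_exhaustive:
            candidates = itertools.product((0, 1), repeat=n_int)
            best = None
            for bits in candidates:
                cand = _punct_eval(tree, x, spec, info, bits, eps)
                if best is None or cand[0] > best[0]:
                    best = cand + (bits,)
        else:
            best = _punct_hillclimb(tree, x, spec, info, eps, seed)
    else:
        raise InvalidInputError(f"unknown punct_assignment {assignment!r}")
    lnL, sigma2, mu, bparams, boundary, bits = best
    if not math.isfinite(lnL):
        raise NumericalError(f"degenerate punctuated fit ({spec.name})")
    return ModelFit(
        spec=spec, lnL=lnL, rate=sigma2, root_state=mu,
        n_params=0, aic=math.nan, branch_params=bparams,
        punct_assignment=tuple(bits), boundary=boundary,
    )


def _punct_eval(tree, x, spec, info, bits, eps):
    """(lnL, sigma2, mu, branch_params, boundary) for one assignment."""
    if spec.tempo == "free":
        mu, z = _punct_rep_values(tree, x, bits)
        b = np.maximum(z * z, eps)
        lnL = float(np.sum(-0.5 * (LOG2PI + np.log(b)) - z * z / (2.0 * b)))
        return lnL, 1.0, mu, b, bool(np.any(z * z < eps))
    C = _punct_cov(info, bits, spec.tempo)
    lnL, sigma2, mu = _gls_scaled_fit(C, x)
    return lnL, sigma2, mu, None, False


def _punct_hillclimb(tree, x, spec, info, eps, seed, n_restarts: int = 5):
    rng = np.random.default_rng(seed)
    n_int = len(info)
    best = None
    for _ in range(n_restarts):
        bits = list(rng.integers(0, 2, size=n_int))
        cur = _punct_eval(tree, x, spec, info, tuple(bits), eps)
        improved = True
        while improved:
            improved = False
            for k in range(n_int):
                bits[k] ^= 1
                cand = _punct_eval(tree, x, spec, info, tuple(bits), eps)
                if cand[0] > cur[0] + 1e-12:
                    cur = cand
                    improved = True
                else:
                    bits[k] ^= 1
        if best is None or cur[0] > best[0]:
            best = cur + (tuple(bits),)
    return best


def _fit_nonphylo_free(tree, x, eps) -> ModelFit:
    """Star tree, free tip variances, sigma^2 = 1, mu profiled.

    Given mu, the optimal variance for tip i is max(eps, (x_i - mu)^2); the
    profile likelihood diverges as mu approaches a tip value, so the
    eps floor is always active and the fit is flagged as a boundary fit.
    """
    def profile_lnl(mu: float) -> float:
        z2 = (x - mu) ** 2
        b = np.maximum(z2, eps)
        return float(np.sum(-0.5 * (LOG2PI + np.log(b)) - z2 / (2.0 * b)))

    candidates = list(x) + [float(np.mean(x))]
    vals = [profile_lnl(m) for m in candidates]
    k = int(np.argmax(vals))
    mu0, best = candidates[k], vals[k]
    span = max(np.ptp(x), 1.0)
    res = optimize.minimize_scalar(
        lambda m: -profile_lnl(m),
        bounds=(mu0 - 0.1 * span, mu0 + 0.1 * span),
        method="bounded",
        options={"xatol": 1e-10},
    )
    mu = float(res.x) if -res.fun > best else mu0
    lnL = profile_lnl(mu)
    b = np.maximum((x - mu) ** 2, eps)
    return ModelFit(
        spec=ModelSpec("nonphylogenetic", "free"), lnL=lnL, rate=1.0,
        root_state=mu, n_params=0, aic=math.nan, branch_params=b,
        boundary=bool(np.any((x - mu) ** 2 <= eps)),
        message="profile optimum at the branch-length floor",
    )


def _fit_pure_free(tree, x, eps, n_starts, seed) -> ModelFit:
    """All 2n-2 branch lengths free, sigma^2 = 1, mu profiled by GLS."""
    masks, lengths = _edge_masks(tree)
    n_edges = masks.shape[0]
    upper = max(np.ptp(x) ** 2, 1.0) * 1e4

    def neg_lnl(logb: np.ndarray) -> float:
        b = np.exp(logb)
        C = (masks * b[:, None]).T @ masks
        lnL, _, _ = _gls_fixed_rate(C, x)
        return 1e10 if not math.isfinite(lnL) else -lnL

    starts = []
    for tempo in ("distance", "equal"):
        try:
            t = transform_tree(tree, "pure_phylogenetic", tempo)
            _, sigma2, _ = _gls_scaled_fit(t.covariance(), x)
            base = lengths if tempo == "distance" else np.ones(n_edges)
            starts.append(np.clip(sigma2 * base, eps, upper))
        except (InvalidInputError, NumericalError):
            pass
    rng = np.random.default_rng(seed)
    scale = max(np.var(x), eps)
    while len(starts) < n_starts:
        starts.append(
            np.clip(scale * rng.lognormal(0.0, 1.0, size=n_edges), eps, upper)
        )

    bounds = [(math.log(eps), math.log(upper))] * n_edges
    best_logb, best_val = None, math.inf
    for s in starts:
        s0 = np.log(np.clip(s, eps, upper))
        v0 = neg_lnl(s0)
        if v0 < best_val:
            best_logb, best_val = s0, v0
        res = optimize.minimize(
            neg_lnl, s0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 300, "ftol": 1e-12},
        )
        if res.fun < best_val:
            best_logb, best_val = res.x, res.fun
    b = np.exp(best_logb)
    C = (masks * b[:, None]).T @ masks
    lnL, mu, _ = _gls_fixed_rate(C, x)
    boundary = bool(np.any(b <= eps * 1.001) or np.any(b >= upper * 0.999))
    return ModelFit(
        spec=ModelSpec("pure_phylogenetic", "free"), lnL=float(lnL), rate=1.0,
        root_state=float(mu), n_params=0, aic=math.nan, branch_params=b,
        boundary=boundary,
        message="branch lengths at the optimization bounds" if boundary else "",
    )


def _gls_fixed_rate(C: np.ndarray, x: np.ndarray):
    """lnL with sigma^2 fixed at 1 and mu profiled by GLS."""
    n = len(x)
    try:
        cho = linalg.cho_factor(C, lower=True)
    except linalg.LinAlgError:
        return -math.inf, math.nan, math.nan
    ones = np.ones(n)
    Ci_one = linalg.cho_solve(cho, ones)
    mu = float(Ci_one @ x) / float(Ci_one @ ones)
    r = x - mu
    q = float(r @ linalg.cho_solve(cho, r))
    logdet = 2.0 * float(np.log(np.diag(cho[0])).sum())
    return -0.5 * (n * LOG2PI + logdet + q), mu, q


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

@dataclass
class AicTable:
    delta_aic: pd.DataFrame          # traits x models; NaN = not comparable
    best_model: pd.Series            # per trait
    indistinguishable: dict[str, list[str]]  # models within 2 AIC of best
    boundary: pd.DataFrame | None = None     # traits x models, bool
    fits: dict[str, dict[str, ModelFit]] = field(default_factory=dict)
    errors: dict[str, dict[str, str]] = field(default_factory=dict)


def aic_model_table(
    tree: Phylogeny,
    trait_table: pd.DataFrame,
    specs: tuple[ModelSpec, ...] = ALL_MODELS,
    eps: float = 1e-6,
    seed: int = 0,
    n_starts: int = 10,
    punct_mode: str | tuple = "fixed",
) -> AicTable:
    """Fit every model to every trait row and tabulate AIC differences.

    ``trait_table`` rows are traits, columns are species matching the tree's
    tips.  Per-trait fit failures are recorded, not fatal for other cells.

    For an honest cross-model comparison punctuated fits use a fixed,
    data-independent daughter assignment by default (profiling over the
    2^(n-1) assignments is an uncounted discrete maximization that biases
    AIC toward punctuated models); pass ``punct_mode='max'`` for the
    profiled variant.  Free-tempo fits whose likelihood sits at the
    branch-length floor (boundary fits: the MLE does not exist) are flagged
    and excluded from the Delta-AIC ranking; their cells are NaN.
    """
    labels = tree.tip_labels
    missing = [l for l in labels if l not in trait_table.columns]
    if missing:
        raise InvalidInputError(f"trait table misses species {missing}")
    names = [s.name for s in specs]
    rows, best, indist = {}, {}, {}
    bnd_rows = {}
    fits: dict[str, dict[str, ModelFit]] = {}
    errors: dict[str, dict[str, str]] = {}
    for trait, row in trait_table.iterrows():
        tips = {l: float(row[l]) for l in labels}
        aics, bnd = {}, {}
        fits[trait] = {}
        errors[trait] = {}
        for s in specs:
            bnd[s.name] = False
            try:
                fit = fit_model(tree, tips, s, eps=eps, seed=seed,
                                n_starts=n_starts, punct_assignment=punct_mode)
                fits[trait][s.name] = fit
                bnd[s.name] = fit.boundary
                aics[s.name] = math.nan if fit.boundary else fit.aic
            except (NumericalError, InvalidInputError) as exc:
                errors[trait][s.name] = str(exc)
                aics[s.name] = math.nan
        arr = pd.Series(aics, dtype=float)
        if arr.notna().any():
            mn = arr.min()
            delta = arr - mn
            best[trait] = delta.idxmin()
            indist[trait] = sorted(delta.index[delta < 2.0])
        else:
            delta = arr
            best[trait] = None
            indist[trait] = []
        rows[trait] = delta
        bnd_rows[trait] = bnd
    table = pd.DataFrame(rows).T.loc[:, names]
    bnd_table = pd.DataFrame(bnd_rows).T.loc[:, names]
    return AicTable(
        delta_aic=table,
        best_model=pd.Series(best),
        indistinguishable=indist,
        boundary=bnd_table,
        fits=fits,
        errors=errors,
    )
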