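"""Mating-trial bookkeeping and the quasibinomial mating-propensity model.

A no-choice trial pairs one male with one female; mating propensity for a
female-species x male-species cell is the fraction of trials ending in
copulation.  The interspecific model regresses per-cell propensity on the
male-species factor (baseline "eagerness"), genetic divergence, and CHC
profile divergence via a logit-link binomial GLM weighted by trial counts,
with a Pearson-based dispersion (quasibinomial) inflating standard errors.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .errors import InvalidInputError


@dataclass
class MatingTrialMatrix:
    """Female-species x male-species trial and success counts."""

    trials: pd.DataFrame
    successes: pd.DataFrame

    def __post_init__(self) -> None:
        t, s = self.trials, self.successes
        if list(t.index) != list(t.columns):
            raise InvalidInputError("trial matrix row/column labels differ")
        if list(t.index) != list(s.index) or list(t.columns) != list(s.columns):
            raise InvalidInputError("trials and successes labels differ")
        if (t.to_numpy() < 0).any() or (s.to_numpy() < 0).any():
            raise InvalidInputError("negative counts")
        if (s.to_numpy() > t.to_numpy()).any():
            raise InvalidInputError("successes exceed trials in some cell")

    @property
    def species(self) -> list[str]:
        return list(self.trials.index)

    @property
    def total_trials(self) -> int:
        return int(self.trials.to_numpy().sum())

    @property
    def n_combinations(self) -> int:
        return int(self.trials.size)


@dataclass
class GlmFit:
    terms: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    dispersion: float
    df_residual: int
    n_cells: int
    n_dropped: int
    converged: bool
    separation_flag: bool

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.coefficients,
                "se": self.standard_errors,
                "t": self.t_values,
                "p": self.p_values,
            },
            index=self.terms,
        )


def packaged_trial_counts() -> pd.DataFrame:
    """Trial counts of the 9x9 no-choice design shipped with the package."""
    ref = importlib.resources.files("chcevol.data") / "trial_counts.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index.name = "female_species"
    return df.astype(int)


def packaged_sampling_locations() -> pd.DataFrame:
    """Sampling-location design table (species, population, host, study)."""
    ref = importlib.resources.files("chcevol.data") / "sampling_locations.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def read_trial_matrix(trials_path, successes_path, sep: str = "\t") -> MatingTrialMatrix:
    trials = pd.read_csv(trials_path, sep=sep, index_col=0, comment="#")
    succ = pd.read_csv(successes_path, sep=sep, index_col=0, comment="#")
    return MatingTrialMatrix(trials=trials, successes=succ)


def mating_proportions(m: MatingTrialMatrix) -> pd.DataFrame:
    """p_ij = successes / trials; zero-trial cells become NaN (missing)."""
    t = m.trials.to_numpy(dtype=float)
    s = m.successes.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(t > 0, s / np.where(t > 0, t, 1.0), np.nan)
    return pd.DataFrame(p, index=m.trials.index, columns=m.trials.columns)


def reciprocal_pair_means(p: pd.DataFrame) -> pd.DataFrame:
    """Symmetric matrix of unweighted means of the two reciprocal cells.

    If one direction is missing the other is used alone; if both are missing
    the pair stays missing.  The diagonal is set to NaN (conspecific cells
    are not a species *pair*).
    """
    if list(p.index) != list(p.columns):
        raise InvalidInputError("proportion matrix must be square and labeled")
    arr = p.to_numpy(dtype=float)
    n = arr.shape[0]
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            vals = [v for v in (arr[i, j], arr[j, i]) if np.isfinite(v)]
            if vals:
                out[i, j] = out[j, i] = float(np.mean(vals))
    return pd.DataFrame(out, index=p.index, columns=p.columns)


def pearson_correlation(x, y) -> tuple[float, float, int, float]:
    """Pearson r with its t statistic: t = r sqrt(df / (1 - r^2)), df = n-2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise InvalidInputError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InvalidInputError("zero variance in correlation input")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    if abs(r) >= 1.0:
        t = math_inf_sign(r)
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r * r))
        p = float(2 * stats.t.sf(abs(t), df))
    return r, float(t), df, p


def math_inf_sign(r: float) -> float:
    return float("inf") if r > 0 else float("-inf")


def proportion_heterogeneity_chi2(successes, trials) -> tuple[float, int, float]:
    """Pearson chi-square for heterogeneity of proportions across groups.

    Builds the 2 x k success/failure contingency table; df = k - 1.
    """
    s = np.asarray(successes, dtype=float)
    t = np.asarray(trials, dtype=float)
    if len(s) < 2:
        raise InvalidInputError("need at least 2 groups")
    if (t <= 0).any():
        raise InvalidInputError("every group needs at least one trial")
    table = np.vstack([s, t - s])
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def quasibinomial_glm(
    m: MatingTrialMatrix,
    genetic_div: pd.DataFrame | None = None,
    chc_div: pd.DataFrame | None = None,
    include_diagonal: bool = False,
) -> GlmFit:
    """Quasibinomial GLM of per-cell mating propensity.

    Design matrix: intercept, male-species treatment dummies (first species
    alphabetically as reference) first, then the genetic and CHC divergence
    covariates.  Cells with zero trials are dropped (count reported);
    conspecific (diagonal) cells are excluded unless ``include_diagonal``.
    Dispersion is the Pearson X^2 / df_residual; standard errors are scaled
    by its square root.
    """
    species = m.species
    for name, mat in (("genetic_div", genetic_div), ("chc_div", chc_div)):
        if mat is not None and (
            list(mat.index) != species or list(mat.columns) != species
        ):
            raise InvalidInputError(f"{name} labels do not match trial matrix")
    rows = []
    n_dropped = 0
    for i, fem in enumerate(species):
        for j, mal in enumerate(species):
            if i == j and not include_diagonal:
                continue
            t = float(m.trials.iloc[i, j])
            if t <= 0:
                n_dropped += 1
                continue
            row = {"female": fem, "male": mal, "trials": t,
                   "prop": float(m.successes.iloc[i, j]) / t}
            if genetic_div is not None:
                row["genetic_div"] = float(genetic_div.iloc[i, j])
            if chc_div is not None:
                row["chc_div"] = float(chc_div.iloc[i, j])
            rows.append(row)
    data = pd.DataFrame(rows)
    if data.empty:
        raise InvalidInputError("no usable cells for the GLM")

    male_levels = sorted(data["male"].unique())
    if len(male_levels) < 2:
        raise InvalidInputError("need at least 2 male species levels")
    terms = ["intercept"]
    cols = [np.ones(len(data))]
    for lev in male_levels[1:]:
        terms.append(f"male[{lev}]")
        cols.append((data["male"] == lev).to_numpy(dtype=float))
    for cov in ("genetic_div", "chc_div"):
        if cov in data.columns:
            terms.append(cov)
            cols.append(data[cov].to_numpy(dtype=float))
    Xfull = np.column_stack(cols)

    # drop rank-deficient columns (e.g. an identically-zero covariate),
    # keeping earlier terms in preference
    keep: list[int] = []
    for k in range(Xfull.shape[1]):
        trial_cols = keep + [k]
        if np.linalg.matrix_rank(Xfull[:, trial_cols]) == len(trial_cols):
            keep.append(k)
    dropped_terms = [terms[k] for k in range(Xfull.shape[1]) if k not in keep]
    X = Xfull[:, keep]
    kept_terms = [terms[k] for k in keep]

    model = sm.GLM(
        data["prop"].to_numpy(),
        X,
        family=sm.families.Binomial(),
        var_weights=data["trials"].to_numpy(),
    )
    # point estimates equal the phi = 1 binomial fit; the quasibinomial
    # dispersion phi = Pearson X^2 / df_resid only rescales the SEs.
    # Saturated designs (df_resid 0) make statsmodels warn while computing
    # its own scale; separation is re-detected below from the coefficients.
    import warnings
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        res = model.fit(maxiter=100)
    if not res.converged:
        raise NumericalError(
            f"GLM did not converge; last deviance {res.deviance:.6g}"
        )
    coefs = np.asarray(res.params, dtype=float)
    df_resid_val = int(res.df_resid)
    phi = (
        float(res.pearson_chi2) / df_resid_val if df_resid_val > 0
        else float("nan")
    )
    ses = np.asarray(res.bse, dtype=float) * np.sqrt(phi)
    separation = bool(np.any(np.abs(coefs) > 15))

    full_terms = kept_terms + [f"{t} (dropped: rank)" for t in dropped_terms]
    coefs_full = np.concatenate([coefs, np.full(len(dropped_terms), np.nan)])
    ses_full = np.concatenate([ses, np.full(len(dropped_terms), np.nan)])
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = coefs_full / ses_full
    pvals = (
        2 * stats.t.sf(np.abs(tvals), df_resid_val) if df_resid_val > 0
        else np.full_like(tvals, np.nan)
    )
    return GlmFit(
        terms=full_terms,
        coefficients=coefs_full,
        standard_errors=ses_full,
        t_values=tvals,
        p_values=pvals,
        dispersion=phi,
        df_residual=df_resid_val,
        n_cells=len(data),
        n_dropped=n_dropped,
        converged=bool(res.converged),
        separation_flag=separation,
    )
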