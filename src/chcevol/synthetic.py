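"""Synthetic study generator: every input the pipeline consumes.

The generator emulates the design of a nine-species CHC study: five
hydrocarbon components per female, one or two populations per species
(one species has a single sampling location), three to six females per
location, an unbalanced 9 x 9 no-choice trial-count matrix (the packaged
design counts), binomial mating outcomes whose propensity declines with CHC
and genetic distance on a logit scale plus a male-species "eagerness"
intercept, and tip traits simulated under any of the nine trait-change
models.

Species/population structure is generated in log-contrast space (which
guarantees valid compositions after the inverse logistic transform): a
species mean vector (optionally evolved by Brownian motion along the tree),
a population-level offset, and individual noise.  Default scales put about
78% of coordinate variance between species, 7.5% between populations within
species, and the rest within populations.  Amounts are the compositions
scaled by a random body-size factor, so analyses must be invariant to
per-specimen rescaling.

All generators are deterministic given a seed; child streams are spawned
from the master seed so stages are independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .chc_io import (
    ComponentSet,
    CompositionTable,
    INTERSPECIFIC_COMPONENTS,
    SpecimenTable,
    log_contrast,
    to_proportions,
)
from .distances import DistanceMatrix, species_median_distance
from .errors import ConfigError, InvalidInputError
from .mating import MatingTrialMatrix, packaged_trial_counts
from .trees import Phylogeny, simulate_trait, yule_tree


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic data generator."""

    species: tuple[str, ...] | None = None   # None -> packaged 9 species
    populations_per_species: int = 2
    single_population_species: str | None = "T_boharti"
    females_per_location: tuple[int, int] = (3, 6)
    components: tuple[str, ...] = INTERSPECIFIC_COMPONENTS
    divisor: str = "13Me27"
    # log-contrast space scales (sd per coordinate)
    species_scale: float = 0.9
    population_scale: float = 0.28
    within_scale: float = 0.39
    species_means_mode: str = "bm"           # "bm" on the tree, or "iid"
    composition_mode: str = "logistic_normal"  # or "dirichlet"
    dirichlet_concentration: float = 200.0
    # tree
    birth_rate: float = 1.0
    tree_depth: float = 1.0
    ultrametric: bool = True
    # mating model (logit scale)
    alpha_mean: float = 1.2
    alpha_sd: float = 1.0
    beta_chc: float = -1.0
    beta_gen: float = -1.0
    trial_counts: pd.DataFrame | None = None  # None -> packaged design
    # body size factor (lognormal sd), total amount scale in ng
    body_size_sd: float = 0.35
    total_amount_ng: float = 500.0
    seed: int = 0

    def resolved_species(self) -> list[str]:
        if self.species is not None:
            return list(self.species)
        return list(packaged_trial_counts().index)

    def resolved_trials(self) -> pd.DataFrame:
        if self.trial_counts is not None:
            return self.trial_counts
        counts = packaged_trial_counts()
        sp = self.resolved_species()
        if list(counts.index) == sp:
            return counts
        raise ConfigError(
            "custom species labels need an explicit trial_counts matrix"
        )

    def config_hash(self) -> str:
        payload = {
            k: (v if not isinstance(v, pd.DataFrame) else v.to_dict())
            for k, v in asdict(self).items()
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def gen_tree(cfg: SimulationConfig) -> Phylogeny:
    """Random ultrametric Yule tree over the configured species.

    This fixture tree stands in for a real species phylogeny; it is a random
    topology, not an inferred one.
    """
    sp = cfg.resolved_species()
    rng, = _spawn(cfg.seed, 1)
    return yule_tree(
        len(sp), birth_rate=cfg.birth_rate, rng=rng,
        ultrametric=cfg.ultrametric, labels=sp,
        depth=cfg.tree_depth if cfg.ultrametric else None,
    )


def _species_mean_coords(cfg: SimulationConfig, tree: Phylogeny | None,
                         rng: np.random.Generator) -> pd.DataFrame:
    sp = cfg.resolved_species()
    k = len(cfg.components) - 1
    if cfg.species_means_mode == "bm" and tree is not None:
        cols = {}
        for j in range(k):
            vals = simulate_trait(
                tree, "pure_phylogenetic", "distance",
                rate=cfg.species_scale ** 2 / max(cfg.tree_depth, 1e-12),
                root_state=0.0, rng=rng,
            )
            cols[j] = [vals[s] for s in tree.tip_labels]
        df = pd.DataFrame(cols, index=tree.tip_labels)
        return df.loc[sp]
    means = rng.normal(0.0, cfg.species_scale, size=(len(sp), k))
    return pd.DataFrame(means, index=sp)


def gen_chc_specimens(
    cfg: SimulationConfig, tree: Phylogeny | None = None
) -> SpecimenTable:
    """Simulate the specimen-level CHC amount table."""
    rng_means, rng_pop, rng_ind = _spawn(cfg.seed + 1, 3)
    sp = cfg.resolved_species()
    comp_set = ComponentSet(names=tuple(cfg.components), divisor=cfg.divisor)
    k = len(cfg.components) - 1
    mean_coords = _species_mean_coords(cfg, tree, rng_means)

    lo, hi = cfg.females_per_location
    meta_rows, coords = [], []
    for s in sp:
        n_pop = (
            1 if s == cfg.single_population_species
            else cfg.populations_per_species
        )
        for p in range(n_pop):
            pop = f"{s}_P{p + 1}"
            offset = rng_pop.normal(0.0, cfg.population_scale, size=k)
            n_fem = int(rng_pop.integers(lo, hi + 1))
            for f in range(n_fem):
                noise = rng_ind.normal(0.0, cfg.within_scale, size=k)
                coords.append(mean_coords.loc[s].to_numpy() + offset + noise)
                meta_rows.append(
                    {"specimen_id": f"{pop}_F{f + 1}", "species": s,
                     "population": pop, "host": f"host{(p % 2) + 1}"}
                )
    coords = np.asarray(coords)
    if cfg.composition_mode == "logistic_normal":
        props = _inverse_log_contrast(coords, cfg)
    elif cfg.composition_mode == "dirichlet":
        base = _inverse_log_contrast(coords, cfg)
        props = np.vstack([
            rng_ind.dirichlet(row * cfg.dirichlet_concentration)
            for row in base
        ])
    else:
        raise ConfigError(f"unknown composition_mode {cfg.composition_mode!r}")
    body = cfg.total_amount_ng * rng_ind.lognormal(
        0.0, cfg.body_size_sd, size=len(props)
    )
    amounts = props * body[:, None]
    meta = pd.DataFrame(meta_rows).set_index("specimen_id")
    amount_df = pd.DataFrame(
        amounts, index=meta.index, columns=list(cfg.components)
    )
    return SpecimenTable(meta=meta, amounts=amount_df, components=comp_set)


def _inverse_log_contrast(coords: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Map (k-1)-dim log-contrast coordinates back to compositions."""
    cols = list(cfg.components)
    d_idx = cols.index(cfg.divisor)
    n = coords.shape[0]
    full = np.zeros((n, len(cols)))
    j = 0
    for i in range(len(cols)):
        if i == d_idx:
            continue
        full[:, i] = coords[:, j]
        j += 1
    expd = np.exp(full - full.max(axis=1, keepdims=True))
    return expd / expd.sum(axis=1, keepdims=True)


def logistic(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


def gen_mating_trials(
    cfg: SimulationConfig,
    chc_dist: DistanceMatrix,
    gen_dist: DistanceMatrix,
    alpha: dict[str, float] | None = None,
) -> tuple[MatingTrialMatrix, dict[str, float]]:
    """Binomial mating outcomes from the logistic propensity model.

    success_ij ~ Binomial(trials_ij,
        logistic(alpha_male(j) + beta_chc * chc_ij + beta_gen * gen_ij)),
    where i is the female species and j the male species.
    """
    sp = cfg.resolved_species()
    if chc_dist.labels != sp:
        chc_dist = chc_dist.reorder(sp)
    if gen_dist.labels != sp:
        gen_dist = gen_dist.reorder(sp)
    trials = cfg.resolved_trials()
    if list(trials.index) != sp or list(trials.columns) != sp:
        raise InvalidInputError("trial counts labels do not match species")
    rng_alpha, rng_out = _spawn(cfg.seed + 2, 2)
    if alpha is None:
        alpha = {
            s: float(rng_alpha.normal(cfg.alpha_mean, cfg.alpha_sd)) for s in sp
        }
    t = trials.to_numpy(dtype=int)
    eta = (
        np.array([alpha[s] for s in sp])[None, :]
        + cfg.beta_chc * chc_dist.values
        + cfg.beta_gen * gen_dist.values
    )
    p = logistic(eta)
    succ = rng_out.binomial(t, p)
    m = MatingTrialMatrix(
        trials=pd.DataFrame(t, index=sp, columns=sp),
        successes=pd.DataFrame(succ, index=sp, columns=sp),
    )
    return m, alpha


def gen_trait_panel(
    tree: Phylogeny,
    specs,
    rates,
    seed: int = 0,
    root_state: float = 0.0,
) -> tuple[pd.DataFrame, dict]:
    """One simulated trait row per model spec; generating spec in metadata."""
    if len(specs) != len(rates):
        raise InvalidInputError("specs and rates differ in length")
    rngs = _spawn(seed, len(specs))
    rows, meta = {}, {}
    for k, (spec, rate, rng) in enumerate(zip(specs, rates, rngs)):
        name = f"trait{k + 1}"
        vals = simulate_trait(
            tree, spec.phylo_class, spec.tempo, rate=rate,
            root_state=root_state, rng=rng,
        )
        rows[name] = vals
        meta[name] = {
            "phylo_class": spec.phylo_class, "tempo": spec.tempo,
            "rate": rate, "root_state": root_state, "seed": seed,
        }
    table = pd.DataFrame(rows).T
    return table, meta


@dataclass
class SyntheticStudy:
    """All inputs of one synthetic study, plus the generating truth."""

    config: SimulationConfig
    tree: Phylogeny
    specimens: SpecimenTable
    composition: CompositionTable
    chc_dist: DistanceMatrix
    genetic_dist: DistanceMatrix
    trials: MatingTrialMatrix
    alpha: dict[str, float] = field(default_factory=dict)


def run_synthetic_study(cfg: SimulationConfig) -> SyntheticStudy:
    """Generate tree, specimens, distance matrices, and mating trials."""
    tree = gen_tree(cfg)
    specimens = gen_chc_specimens(cfg, tree)
    comp = to_proportions(specimens)
    lct = log_contrast(comp)
    chc_dist = species_median_distance(lct)
    sp = cfg.resolved_species()
    gen_dist = DistanceMatrix(
        labels=tree.tip_labels, values=tree.patristic_distances()
    ).reorder(sp)
    chc_dist = chc_dist.reorder(sp)
    trials, alpha = gen_mating_trials(cfg, chc_dist, gen_dist)
    return SyntheticStudy(
        config=cfg, tree=tree, specimens=specimens, composition=comp,
        chc_dist=chc_dist, genetic_dist=gen_dist, trials=trials, alpha=alpha,
    )
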