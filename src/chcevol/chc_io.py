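"""Specimen-level cuticular hydrocarbon (CHC) tables.

Reads delimited specimen tables, converts raw GC peak areas to nanogram
amounts against an internal standard, closes each specimen's profile to a
composition (proportions summing to 1), and maps compositions to additive
log-ratio ("log-contrast") coordinates for multivariate analysis.

The default component set is the five methyl-branched heptacosanes used for
between-species comparisons (3Me27, 5Me27, 7Me27, 9/11Me27 pooled, 13Me27);
a field/intraspecific set pools 11Me27 with 13Me27 instead.  Log-contrasts
divide every component's proportion by a designated divisor component
(default 13Me27) and take logarithms, removing the unit-sum constraint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidInputError

#: Component names for the interspecific analyses (9Me27 and 11Me27 pooled).
INTERSPECIFIC_COMPONENTS: tuple[str, ...] = (
    "3Me27", "5Me27", "7Me27", "9_11Me27", "13Me27",
)

#: Field-sample set: 11Me27 pooled with 13Me27 instead of with 9Me27.
FIELD_COMPONENTS: tuple[str, ...] = (
    "3Me27", "5Me27", "7Me27", "9Me27", "11_13Me27",
)

DEFAULT_DIVISOR = "13Me27"
DEFAULT_IS_MASS_NG = 200.0

META_COLUMNS = ("specimen_id", "species", "population", "host")


@dataclass(frozen=True)
class ComponentSet:
    """An ordered set of hydrocarbon components with a log-contrast divisor."""

    names: tuple[str, ...] = INTERSPECIFIC_COMPONENTS
    divisor: str = DEFAULT_DIVISOR

    def __post_init__(self) -> None:
        if len(self.names) < 2:
            raise ConfigError("component set needs at least 2 members")
        if len(set(self.names)) != len(self.names):
            raise ConfigError("component names must be unique")
        if self.divisor not in self.names:
            raise ConfigError(
                f"divisor {self.divisor!r} not in component set {self.names}"
            )

    @property
    def non_divisor(self) -> tuple[str, ...]:
        return tuple(c for c in self.names if c != self.divisor)


@dataclass
class SpecimenTable:
    """Per-specimen component amounts (ng) with species/population labels.

    ``meta`` is indexed by specimen_id with columns species, population, host;
    ``amounts`` shares the index and has one column per component.
    """

    meta: pd.DataFrame
    amounts: pd.DataFrame
    components: ComponentSet = field(default_factory=ComponentSet)

    def __post_init__(self) -> None:
        if not self.meta.index.equals(self.amounts.index):
            raise InvalidInputError("meta and amounts indices differ")
        if not self.meta.index.is_unique:
            dupes = self.meta.index[self.meta.index.duplicated()].tolist()
            raise InvalidInputError(f"duplicate specimen ids: {dupes}")
        missing = [c for c in self.components.names if c not in self.amounts.columns]
        if missing:
            raise InvalidInputError(f"missing component columns: {missing}")
        self.amounts = self.amounts.loc[:, list(self.components.names)].astype(float)
        if (self.amounts.to_numpy() < 0).any():
            raise InvalidInputError("negative component amounts")
        zero = self.amounts.sum(axis=1) <= 0
        if zero.any():
            raise InvalidInputError(
                f"all-zero amount rows for specimens: {list(self.meta.index[zero])}"
            )

    @property
    def specimen_ids(self) -> list[str]:
        return list(self.meta.index)


@dataclass
class CompositionTable:
    """Row-normalized proportions per specimen (each row sums to 1)."""

    meta: pd.DataFrame
    proportions: pd.DataFrame
    components: ComponentSet = field(default_factory=ComponentSet)

    def __post_init__(self) -> None:
        rows = self.proportions.sum(axis=1).to_numpy()
        if not np.allclose(rows, 1.0, atol=1e-10):
            raise InvalidInputError("composition rows must sum to 1")

    @property
    def specimen_ids(self) -> list[str]:
        return list(self.meta.index)


@dataclass
class LogContrastTable:
    """(k-1)-dimensional log-ratio coordinates per specimen."""

    meta: pd.DataFrame
    values: pd.DataFrame  # columns: LC_<component> for non-divisor components
    divisor: str

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise InvalidInputError("non-finite log-contrast values")

    @property
    def specimen_ids(self) -> list[str]:
        return list(self.meta.index)


def quantify_components(
    peak_areas: Mapping[str, float],
    is_area: float,
    is_mass: float = DEFAULT_IS_MASS_NG,
    specimen_id: str = "<unknown>",
) -> dict[str, float]:
    """Convert chromatographic peak areas to nanogram amounts.

    amount_c = area_c * is_mass / is_area, scaling every peak by the known
    mass of the co-injected internal standard.
    """
    if not is_area > 0:
        raise InvalidInputError(
            f"specimen {specimen_id}: internal-standard area must be > 0"
        )
    if not is_mass > 0:
        raise InvalidInputError(
            f"specimen {specimen_id}: internal-standard mass must be > 0"
        )
    out: dict[str, float] = {}
    for comp, area in peak_areas.items():
        if area < 0:
            raise InvalidInputError(
                f"specimen {specimen_id}: negative area for {comp}"
            )
        out[comp] = area * is_mass / is_area
    return out


def to_proportions(table: SpecimenTable) -> CompositionTable:
    """Close each specimen's amounts to a composition (rows sum to 1)."""
    totals = table.amounts.sum(axis=1)
    zero = totals <= 0
    if zero.any():
        raise InvalidInputError(
            f"zero total amount for specimens: {list(table.meta.index[zero])}"
        )
    props = table.amounts.div(totals, axis=0)
    return CompositionTable(
        meta=table.meta.copy(), proportions=props, components=table.components
    )


def log_contrast(
    comp: CompositionTable,
    divisor: str | None = None,
    log_base: float | None = None,
    zero_policy: str = "error",
    pseudocount_frac: float = 1e-6,
) -> LogContrastTable:
    """Additive log-ratio transform of a composition table.

    value_{ic} = log(p_{ic} / p_{i,divisor}) for each non-divisor component c.
    The result is invariant to rescaling a specimen's raw amounts.

    Parameters
    ----------
    divisor : reference component; defaults to the component set's divisor.
    log_base : base of the logarithm; ``None`` means natural log.  The base
        only rescales coordinates by a constant and leaves permutation
        F-ratios, Mantel r, and discriminant variance fractions unchanged.
    zero_policy : "error" (default) or "pseudocount" — replace zero
        proportions by ``pseudocount_frac`` of the row total and re-close.
    """
    cs = comp.components
    divisor = divisor or cs.divisor
    if divisor not in cs.names:
        raise ConfigError(f"divisor {divisor!r} not a component")
    props = comp.proportions.to_numpy(dtype=float).copy()
    if (props <= 0).any():
        if zero_policy == "error":
            rows, cols = np.nonzero(props <= 0)
            sid = comp.proportions.index[rows[0]]
            cname = comp.proportions.columns[cols[0]]
            raise InvalidInputError(
                f"zero proportion for specimen {sid!r}, component {cname!r}; "
                "set zero_policy='pseudocount' to impute"
            )
        elif zero_policy == "pseudocount":
            props = np.where(props <= 0, pseudocount_frac, props)
            props /= props.sum(axis=1, keepdims=True)
        else:
            raise ConfigError(f"unknown zero_policy {zero_policy!r}")
    cols = list(cs.names)
    d_idx = cols.index(divisor)
    logp = np.log(props)
    values = logp - logp[:, [d_idx]]
    keep = [i for i, c in enumerate(cols) if c != divisor]
    values = values[:, keep]
    if log_base is not None:
        values = values / math.log(log_base)
    out_cols = [f"LC_{cols[i]}" for i in keep]
    df = pd.DataFrame(values, index=comp.proportions.index, columns=out_cols)
    return LogContrastTable(meta=comp.meta.copy(), values=df, divisor=divisor)


def pool_components(
    table: SpecimenTable,
    pooling_map: Mapping[str, str],
    pooled_set: ComponentSet | None = None,
) -> SpecimenTable:
    """Sum raw components into pooled ones (e.g. 9Me27 + 11Me27 -> 9_11Me27).

    ``pooling_map`` must cover every raw component; total mass is conserved.
    """
    raw = list(table.amounts.columns)
    missing = [c for c in raw if c not in pooling_map]
    if missing:
        raise InvalidInputError(f"pooling map misses raw components: {missing}")
    pooled_names: list[str] = []
    for c in raw:
        tgt = pooling_map[c]
        if tgt not in pooled_names:
            pooled_names.append(tgt)
    pooled = pd.DataFrame(0.0, index=table.amounts.index, columns=pooled_names)
    for c in raw:
        pooled[pooling_map[c]] += table.amounts[c]
    if pooled_set is None:
        divisor = table.components.divisor
        divisor = pooling_map.get(divisor, divisor)
        if divisor not in pooled_names:
            divisor = pooled_names[-1]
        pooled_set = ComponentSet(names=tuple(pooled_names), divisor=divisor)
    return SpecimenTable(meta=table.meta.copy(), amounts=pooled, components=pooled_set)


def read_specimen_table(
    path,
    components: ComponentSet | None = None,
    mode: str = "amounts",
    is_mass: float = DEFAULT_IS_MASS_NG,
    sep: str | None = None,
) -> SpecimenTable:
    """Read a delimited specimen table (comma or tab separated, UTF-8).

    Header must contain specimen_id, species, population, optionally host,
    then one column per component.  With ``mode='areas'`` an ``is_area``
    column is required and amounts are computed against the internal
    standard of mass ``is_mass`` ng.
    """
    df = pd.read_csv(path, sep=sep, engine="python", comment="#")
    required = {"specimen_id", "species", "population"}
    if not required.issubset(df.columns):
        raise InvalidInputError(
            f"specimen table must have columns {sorted(required)}; "
            f"got {list(df.columns)}"
        )
    components = components or ComponentSet()
    if "host" not in df.columns:
        df["host"] = ""
    meta = df.set_index("specimen_id")[["species", "population", "host"]]
    if mode == "amounts":
        amounts = df.set_index("specimen_id")[list(components.names)]
    elif mode == "areas":
        if "is_area" not in df.columns:
            raise InvalidInputError("mode='areas' requires an is_area column")
        rows = []
        for sid, row in df.set_index("specimen_id").iterrows():
            rows.append(
                quantify_components(
                    {c: float(row[c]) for c in components.names},
                    is_area=float(row["is_area"]),
                    is_mass=is_mass,
                    specimen_id=str(sid),
                )
            )
        amounts = pd.DataFrame(rows, index=meta.index)
    else:
        raise ConfigError(f"unknown mode {mode!r}")
    return SpecimenTable(meta=meta, amounts=amounts, components=components)


def write_specimen_table(table: SpecimenTable, path, sep: str = "\t",
                         header_comment: str | None = None) -> None:
    """Write a specimen table back to delimited text."""
    out = pd.concat([table.meta, table.amounts], axis=1)
    out.index.name = "specimen_id"
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        out.to_csv(fh, sep=sep)
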