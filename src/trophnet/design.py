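"""Model specifications and fixed/random design construction.

The fixed-effect term language is deliberately small, mirroring the analysis
it serves: group size (continuous, optionally as a second-degree polynomial),
food type (carbohydrate vs protein), food availability (limited vs unlimited),
one of five interaction structures, and optional extra numeric covariates
(e.g. mean frame rate for trial-level responses).

Factors are indicator-coded against configurable reference levels.  The
defaults are ``food_type="protein"`` and ``food_availability="limited"``, so
the interaction coefficient measures the availability effect specific to the
carbohydrate diet — the contrast the analysis reports.

Each fixed term records which model variables it involves; the strict-superset
relation between those sets defines the marginality ordering used by the
type II Wald tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MissingColumnError, RankDeficientDesignError

FOOD_TYPE_LEVELS = ("carbohydrate", "protein")
AVAILABILITY_LEVELS = ("limited", "unlimited")

INTERACTION_STRUCTURES = (
    "none", "type_availability", "size_type", "size_availability", "three_way",
)

DEFAULT_REFERENCE_LEVELS = {"food_type": "protein", "food_availability": "limited"}


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one candidate mixed model."""

    response: str
    interaction: str = "none"
    poly_group_size: bool = False
    covariates: tuple[str, ...] = ()
    random_effects: tuple[str, ...] = ("group_id",)
    family: str = "gaussian"           # "gaussian" (identity) or "gamma" (log)

    def __post_init__(self):
        if self.interaction not in INTERACTION_STRUCTURES:
            raise ValueError(f"unknown interaction structure {self.interaction!r}")
        if self.family not in ("gaussian", "gamma"):
            raise ValueError(f"unknown family {self.family!r}")

    def label(self) -> str:
        bits = [self.response, self.interaction]
        if self.poly_group_size:
            bits.append("poly2")
        return "~".join(bits)


def candidate_specs(
    response: str,
    random_effects: Sequence[str] = ("group_id",),
    family: str = "gaussian",
    covariates: Sequence[str] = (),
    include_polynomial: bool = False,
) -> list[ModelSpec]:
    """The five candidate fixed-effect structures (plus optional polynomial).

    All candidates share the three main effects; they differ in interaction
    structure: none, each single two-way, and the full factorial three-way.
    """
    specs = [
        ModelSpec(response=response, interaction=s, covariates=tuple(covariates),
                  random_effects=tuple(random_effects), family=family)
        for s in INTERACTION_STRUCTURES
    ]
    if include_polynomial:
        specs.append(ModelSpec(
            response=response, interaction="none", poly_group_size=True,
            covariates=tuple(covariates), random_effects=tuple(random_effects),
            family=family,
        ))
    return specs


@dataclass(frozen=True)
class Term:
    name: str
    factors: frozenset
    columns: tuple[int, ...]

    @property
    def order(self) -> int:
        return len(self.factors)


@dataclass
class Design:
    """Fixed design matrix with term metadata and a reference-grid builder."""

    X: np.ndarray
    column_names: list[str]
    terms: list[Term]
    spec: ModelSpec
    reference_levels: dict[str, str]
    group_size_center: float
    covariate_means: dict[str, float]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def term(self, name: str) -> Term:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def relatives(self, term: Term) -> list[Term]:
        """Higher-order relatives: terms whose variable set strictly contains."""
        return [t for t in self.terms
                if t.factors > term.factors and t.name != term.name]

    def make_row(self, group_size: float, food_type: str, food_availability: str,
                 covariates: Mapping[str, float] | None = None) -> np.ndarray:
        """Design row for an arbitrary point of the reference grid."""
        covs = dict(self.covariate_means)
        if covariates:
            covs.update(covariates)
        vars_ = _encode(
            np.array([group_size], float),
            np.array([food_type == _nonref(self.reference_levels, "food_type")]).astype(float),
            np.array([food_availability == _nonref(self.reference_levels, "food_availability")]).astype(float),
            {k: np.array([v], float) for k, v in covs.items()},
            self.group_size_center,
        )
        cols = _column_funcs(self.spec, self.reference_levels)
        return np.column_stack([f(vars_) for _, _, f in cols])[0]


def _nonref(ref: Mapping[str, str], factor: str) -> str:
    levels = FOOD_TYPE_LEVELS if factor == "food_type" else AVAILABILITY_LEVELS
    other = [l for l in levels if l != ref[factor]]
    return other[0]


def _encode(gs, carb, unlim, covs, gs_center):
    return {"gs": gs, "gs_c": gs - gs_center, "carb": carb, "unlim": unlim, **covs}


def _column_funcs(spec: ModelSpec, ref: Mapping[str, str] = DEFAULT_REFERENCE_LEVELS,
                  ) -> list[tuple[str, tuple[str, frozenset], Callable]]:
    """(column name, (term name, term factors), row function) for each column."""
    ft_level = _nonref(ref, "food_type")
    fa_level = _nonref(ref, "food_availability")
    cols: list[tuple[str, tuple[str, frozenset], Callable]] = [
        ("Intercept", ("Intercept", frozenset()), lambda v: np.ones_like(v["gs"])),
    ]
    if spec.poly_group_size:
        cols.append(("group_size", ("poly(group_size,2)", frozenset({"group_size"})),
                     lambda v: v["gs_c"]))
        cols.append(("group_size^2", ("poly(group_size,2)", frozenset({"group_size"})),
                     lambda v: v["gs_c"] ** 2))
    else:
        cols.append(("group_size", ("group_size", frozenset({"group_size"})),
                     lambda v: v["gs"]))
    cols.append((f"food_type[{ft_level}]",
                 ("food_type", frozenset({"food_type"})), lambda v: v["carb"]))
    cols.append((f"food_availability[{fa_level}]",
                 ("food_availability", frozenset({"food_availability"})),
                 lambda v: v["unlim"]))

    def two_way(name, factors, f):
        cols.append((name, (name, frozenset(factors)), f))

    if spec.interaction in ("type_availability", "three_way"):
        two_way("food_type:food_availability", {"food_type", "food_availability"},
                lambda v: v["carb"] * v["unlim"])
    if spec.interaction in ("size_type", "three_way"):
        two_way("group_size:food_type", {"group_size", "food_type"},
                lambda v: v["gs"] * v["carb"])
    if spec.interaction in ("size_availability", "three_way"):
        two_way("group_size:food_availability", {"group_size", "food_availability"},
                lambda v: v["gs"] * v["unlim"])
    if spec.interaction == "three_way":
        cols.append(("group_size:food_type:food_availability",
                     ("group_size:food_type:food_availability",
                      frozenset({"group_size", "food_type", "food_availability"})),
                     lambda v: v["gs"] * v["carb"] * v["unlim"]))
    for c in spec.covariates:
        cols.append((c, (c, frozenset({c})), lambda v, _c=c: v[_c]))
    return cols


def build_design(
    spec: ModelSpec,
    data: pd.DataFrame,
    reference_levels: Mapping[str, str] | None = None,
) -> Design:
    """Build the fixed-effect design matrix for ``spec`` from ``data``."""
    ref = dict(DEFAULT_REFERENCE_LEVELS)
    if reference_levels:
        ref.update(reference_levels)
    needed = ["group_size", "food_type", "food_availability", *spec.covariates]
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise MissingColumnError(f"data lacks column(s) {missing}")
    bad_ft = set(data["food_type"].unique()) - set(FOOD_TYPE_LEVELS)
    bad_fa = set(data["food_availability"].unique()) - set(AVAILABILITY_LEVELS)
    if bad_ft or bad_fa:
        raise ValueError(f"unexpected factor levels: {bad_ft | bad_fa}")

    gs = data["group_size"].to_numpy(float)
    gs_center = float(gs.mean()) if spec.poly_group_size else 0.0
    carb = (data["food_type"] == _nonref(ref, "food_type")).to_numpy(float)
    unlim = (data["food_availability"] == _nonref(ref, "food_availability")).to_numpy(float)
    covs = {c: data[c].to_numpy(float) for c in spec.covariates}
    vars_ = _encode(gs, carb, unlim, covs, gs_center)

    cols = _column_funcs(spec, ref)
    X = np.column_stack([f(vars_) for _, _, f in cols])
    names = [name for name, _, _ in cols]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficientDesignError(
            "fixed-effect design is rank deficient (a factor may have a single "
            "observed level)"
        )
    terms: dict[str, list[int]] = {}
    factors: dict[str, frozenset] = {}
    for j, (_, (tname, tfac), _f) in enumerate(cols):
        terms.setdefault(tname, []).append(j)
        factors[tname] = tfac
    term_objs = [Term(name=t, factors=factors[t], columns=tuple(ix))
                 for t, ix in terms.items()]
    return Design(
        X=X, column_names=names, terms=term_objs, spec=spec,
        reference_levels=ref, group_size_center=gs_center,
        covariate_means={c: float(np.mean(v)) for c, v in covs.items()},
    )


DEFAULT_FRAME_RATE_BIN_WIDTH = 0.1


def random_effect_codes(
    data: pd.DataFrame,
    random_effects: Sequence[str],
    frame_rate_bin_width: float = DEFAULT_FRAME_RATE_BIN_WIDTH,
) -> tuple[list[np.ndarray], list[int], list[str]]:
    """Integer level codes for each random-intercept grouping factor.

    ``frame_rate`` (or ``frame_rate_bin``) is a grouping factor formed by
    binning the continuous trial-mean rate to ``frame_rate_bin_width``
    images/s.  Factors with a single observed level are dropped with a
    warning (their variance is not identifiable and is fixed at zero).
    """
    import warnings

    codes, sizes, names = [], [], []
    for factor in random_effects:
        if factor in data.columns:
            values = data[factor]
        elif factor in ("frame_rate", "frame_rate_bin") and "mean_frame_rate_ips" in data.columns:
            values = (data["mean_frame_rate_ips"] / frame_rate_bin_width).round() * frame_rate_bin_width
            values = values.round(6)
        else:
            raise MissingColumnError(f"random-effect column {factor!r} not in data")
        c, levels = pd.factorize(values, sort=True)
        if len(levels) < 2:
            warnings.warn(
                f"random factor {factor!r} has a single level; variance fixed at 0",
                stacklevel=2,
            )
            continue
        codes.append(np.asarray(c, dtype=int))
        sizes.append(int(len(levels)))
        names.append(factor)
    return codes, sizes, names
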