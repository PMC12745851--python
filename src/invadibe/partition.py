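"""Hierarchical deviance partitioning of pairwise F_ST variation.

The full additive model's predictors are grouped into three components
(genetic cluster identity, spatial structure, environmental gradients).
Seven models are fitted — full, three "reduced" (one component removed) and
three "simple" (one component alone) — and the percent deviance explained is
decomposed into unique and pairwise-shared contributions:

    unique_i   = D_full - D_reduced(-i)
    shared_ij  = D_simple(i) + D_simple(j) - D_reduced(-k)    (k != i, j)

with the three-way shared term taken as the closure so that the unique,
pairwise-shared and three-way terms sum to D_full. Component significance is
assessed by jointly permuting the component's predictor columns across pair
rows and recomputing its unique contribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .scam import SMOOTH_KINDS, ScamRegressor, TermSpec

COMPONENT_NAMES = ("genetic", "spatial", "environmental")


@dataclass(frozen=True)
class PartitionResult:
    d_full: float                         # % deviance explained, full model
    d_simple: dict                        # component -> % D of its simple model
    d_reduced: dict                       # component -> % D with it removed
    unique: dict                          # component -> unique %
    shared: dict                          # frozenset pair -> shared %
    shared3: float                        # three-way closure term
    residual: float                       # 100 - d_full
    perm_p: dict | None = None            # component -> permutation p-value

    def identity_gap(self) -> float:
        """| sum(unique) + sum(shared) + shared3 - d_full | (algebraic check)."""
        total = sum(self.unique.values()) + sum(self.shared.values()) + self.shared3
        return abs(total - self.d_full)


def default_components(columns: Sequence[str]) -> dict[str, list[str]]:
    """Standard 3-component grouping of pair-table predictors."""
    spatial = [c for c in ("dist_geo_km", "delta_dist_km_CT", "delta_dist_km_SB")
               if c in columns]
    env = [c for c in columns if c.startswith("delta_") and c not in spatial]
    comp = {"genetic": [c for c in ("clus_type",) if c in columns],
            "spatial": spatial, "environmental": env}
    return comp


class DeviancePartitioner(BaseEstimator):
    """Fit the 7 component models and decompose percent deviance explained.

    Parameters
    ----------
    terms : sequence of TermSpec
        The full-model terms.
    components : mapping component name -> list of term names
        Disjoint groups whose union is the full term set.
    family : model family passed through to :class:`ScamRegressor`.
    n_permutations, seed : permutation-test controls (0 disables the test).
    permute : {"rows", "samples"}
        "rows" jointly shuffles the component's predictor columns across pair
        rows (mirrors the row-wise description of the original analysis;
        ignores the non-independence of pairs sharing a sample).
        "samples" applies a Mantel-style permutation: sample identities are
        shuffled and pair rows are re-indexed accordingly (requires id_a/id_b
        columns).

    Attributes (after ``fit``)
    --------------------------
    result_ : :class:`PartitionResult`; ``fits_`` the 7 fitted models keyed
    "full", "reduced:<c>", "simple:<c>".
    """

    def __init__(self, terms: Sequence[TermSpec] = (),
                 components: Mapping[str, Sequence[str]] | None = None,
                 family: str = "quasibinomial", n_permutations: int = 0,
                 seed: int = 0, permute: str = "rows", **fit_kwargs):
        self.terms = terms
        self.components = components
        self.family = family
        self.n_permutations = n_permutations
        self.seed = seed
        self.permute = permute
        self.fit_kwargs = fit_kwargs

    def _check_components(self):
        comp = {k: list(v) for k, v in self.components.items()}
        names = [t.name for t in self.terms]
        all_members = [m for v in comp.values() for m in v]
        if len(all_members) != len(set(all_members)):
            raise ValueError("components overlap")
        if set(all_members) != set(names):
            raise ValueError("components must jointly cover the full term set; "
                             f"mismatch: {set(names) ^ set(all_members)}")
        return comp

    def fit(self, X: pd.DataFrame, y=None):
        if y is None:
            y = np.asarray(X["fst"], float)
        else:
            y = np.asarray(y, float)
        self.terms = list(self.terms)
        if self.components is None:
            self.components = default_components([t.name for t in self.terms])
        comp = self._check_components()
        full = ScamRegressor(terms=self.terms, family=self.family,
                             **self.fit_kwargs).fit(X, y)
        if not full.converged_:
            raise RuntimeError("full model failed to converge; partition aborted")
        lam_full = dict(full.lambda_)
        self.fits_ = {"full": full}

        def submodel(term_names):
            terms = [t for t in self.terms if t.name in term_names]
            lam = {t.name: lam_full[t.name] for t in terms
                   if t.kind in SMOOTH_KINDS}
            m = ScamRegressor(terms=terms, family=self.family,
                              select_lambda=False, **self.fit_kwargs)
            m = _fit_with_lambda(m, X, y, lam)
            if not m.converged_:
                raise RuntimeError("component submodel failed to converge")
            return m

        names = list(comp)
        d_simple, d_reduced = {}, {}
        for c in names:
            self.fits_[f"simple:{c}"] = m = submodel(comp[c])
            d_simple[c] = m.deviance_explained_
            others = [t for c2 in names if c2 != c for t in comp[c2]]
            self.fits_[f"reduced:{c}"] = m = submodel(others)
            d_reduced[c] = m.deviance_explained_
        d_full = full.deviance_explained_
        unique = {c: d_full - d_reduced[c] for c in names}
        shared = {}
        for i, j in combinations(names, 2):
            # deviance of the model containing exactly components i and j:
            # with three components this is the reduced model of the third,
            # with two it is the full model
            rest = [c for c in names if c not in (i, j)]
            d_pair = d_reduced[rest[0]] if rest else d_full
            shared[frozenset((i, j))] = d_simple[i] + d_simple[j] - d_pair
        shared3 = d_full - sum(unique.values()) - sum(shared.values())
        perm_p = None
        if self.n_permutations > 0:
            perm_p = {c: self._permute_component(X, y, comp, c, d_full,
                                                 d_reduced[c], lam_full)
                      for c in names}
        self.result_ = PartitionResult(d_full, d_simple, d_reduced, unique,
                                       shared, shared3, 100.0 - d_full, perm_p)
        return self

    def _permute_component(self, X, y, comp, component, d_full_obs,
                           d_reduced_obs, lam_full):
        B = self.n_permutations
        if B < 99:
            warnings.warn(f"B={B} gives low permutation resolution")
        rng = np.random.default_rng(self.seed)
        cols = comp[component]
        unique_obs = d_full_obs - d_reduced_obs
        X = X.reset_index(drop=True)
        count = 0
        for _ in range(B):
            Xp = X.copy()
            if self.permute == "rows":
                perm = rng.permutation(len(X))
                Xp[cols] = X[cols].to_numpy()[perm]
            elif self.permute == "samples":
                Xp = _permute_samples(X, cols, rng)
            else:
                raise ValueError(f"unknown permute mode {self.permute!r}")
            m = ScamRegressor(terms=self.terms, family=self.family,
                              select_lambda=False, fixed_lambda=lam_full,
                              **self.fit_kwargs)
            m.fit(Xp, y)
            unique_perm = m.deviance_explained_ - d_reduced_obs
            if unique_perm >= unique_obs:
                count += 1
        return (1 + count) / (B + 1)


def _fit_with_lambda(model: ScamRegressor, X, y, lam: Mapping[str, float]):
    """Fit with fixed, pre-selected smoothing parameters."""
    model.select_lambda = False
    model.fixed_lambda = dict(lam)
    model.fit(X, y)
    return model


def _permute_samples(X: pd.DataFrame, cols, rng):
    """Mantel-style permutation: shuffle sample identities, re-index pair rows."""
    ids = sorted(set(X["id_a"]) | set(X["id_b"]))
    perm = dict(zip(ids, rng.permutation(ids)))
    key = {}
    for r in X.itertuples(index=False):
        key[frozenset((r.id_a, r.id_b))] = tuple(
            getattr(r, c) for c in cols)
    Xp = X.copy()
    vals = [key[frozenset((perm[a], perm[b]))]
            for a, b in zip(X["id_a"], X["id_b"])]
    Xp[list(cols)] = pd.DataFrame(vals, columns=list(cols), index=X.index)
    return Xp


def fit_component_models(table: pd.DataFrame, full_spec: Sequence[TermSpec],
                         components: Mapping[str, Sequence[str]] | None = None,
                         family: str = "quasibinomial", **kwargs):
    """Functional wrapper returning the dict of 7 fitted models."""
    part = DeviancePartitioner(terms=list(full_spec), components=components,
                               family=family, **kwargs).fit(table)
    return part.fits_, part.result_


def partition_deviance(table: pd.DataFrame, full_spec: Sequence[TermSpec],
                       components: Mapping[str, Sequence[str]] | None = None,
                       family: str = "quasibinomial", n_permutations: int = 0,
                       seed: int = 0, **kwargs) -> PartitionResult:
    """Fit and decompose; returns the :class:`PartitionResult`."""
    part = DeviancePartitioner(terms=list(full_spec), components=components,
                               family=family, n_permutations=n_permutations,
                               seed=seed, **kwargs).fit(table)
    return part.result_
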