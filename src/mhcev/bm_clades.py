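"""Brownian-motion clade models on a two-clade ultrametric tree.

Four models — shared vs clade-specific trait means crossed with shared vs
clade-specific Brownian rates — are fit by maximum likelihood and compared by
AIC.  The tree's root must be the split between the two clades (outgroup
removed), which makes the tip covariance block-diagonal across clades: the
covariance of two tips is the rate-weighted length of their shared root path,
where every edge inside clade A (including its stem branch) carries clade A's
relative rate.  Because the stem carries A's rate and contributes shared
variance to all A tips, scaling the stem branch changes the likelihood — the
basis of the stem-length sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from scipy import optimize

import mhcev.phylo as phylo
from mhcev.errors import FitError, LabelingError, ShapeError

MODELS = (
    "same_mean_same_rate",
    "diff_mean_same_rate",
    "same_mean_diff_rate",
    "diff_mean_diff_rate",
)
_N_PARAMS = {
    "same_mean_same_rate": 2,
    "diff_mean_same_rate": 3,
    "same_mean_diff_rate": 3,
    "diff_mean_diff_rate": 4,
}


@dataclass(frozen=True)
class CladeSplit:
    clade_a_tips: frozenset[str]
    clade_b_tips: frozenset[str]

    def __post_init__(self) -> None:
        if self.clade_a_tips & self.clade_b_tips:
            raise ValueError("clade tip sets must be disjoint")

    @classmethod
    def from_iterables(cls, a: Iterable[str], b: Iterable[str]) -> "CladeSplit":
        return cls(frozenset(a), frozenset(b))


@dataclass(frozen=True)
class BMFit:
    model: str
    mu: tuple[float, ...]  # (shared,) or (mu_a, mu_b)
    sigma2: float
    rel_rate_a: float
    lnl: float
    n_params: int

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.lnl


def _check_split(tree: dendropy.Tree, split: CladeSplit) -> None:
    tips = set(phylo.tip_labels(tree))
    if tips != split.clade_a_tips | split.clade_b_tips:
        raise LabelingError("clade tip sets do not cover the tree's tips exactly")
    root_kids = tree.seed_node.child_nodes()
    if len(root_kids) != 2:
        raise ShapeError("tree root must be the bifurcating A/B split")
    sides = [
        {l.taxon.label for l in kid.leaf_iter()} for kid in root_kids
    ]
    if not (
        (sides[0] == split.clade_a_tips and sides[1] == split.clade_b_tips)
        or (sides[0] == split.clade_b_tips and sides[1] == split.clade_a_tips)
    ):
        raise ShapeError("root does not separate clade A from clade B")


def _check_clade_ultrametric(tree: dendropy.Tree, split: CladeSplit, rel_tol: float = 1e-6) -> None:
    """Tips within each clade must be equidistant from the root (the stem may
    have been rescaled, so clades may sit at different depths)."""
    depths = phylo.node_depths(tree)
    tip_depth = {l.taxon.label: depths[l] for l in tree.leaf_node_iter()}
    overall = max(tip_depth.values())
    for tips in (split.clade_a_tips, split.clade_b_tips):
        vals = [tip_depth[t] for t in tips]
        if max(vals) - min(vals) > rel_tol * max(overall, 1e-300):
            raise ShapeError("tree is not ultrametric within a clade")


def bm_covariance(
    tree: dendropy.Tree, split: CladeSplit, rel_rate_a: float = 1.0
) -> tuple[list[str], np.ndarray]:
    """Unit-variance BM covariance of the tips (multiply by sigma2 for use).

    Entry (i, j) is the rate-weighted shared root-path length; edges inside
    clade A, including A's stem branch, are weighted by `rel_rate_a`.
    """
    if rel_rate_a <= 0.0:
        raise ValueError("rel_rate_a must be positive")
    _check_split(tree, split)
    labels = sorted(phylo.tip_labels(tree))
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    cov = np.zeros((n, n))

    # rate-weighted depth of every node
    rdepth: dict[dendropy.Node, float] = {}
    in_a: dict[dendropy.Node, bool] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            rdepth[node] = 0.0
            in_a[node] = False
            continue
        if node.parent_node is tree.seed_node:
            side = {l.taxon.label for l in node.leaf_iter()}
            in_a[node] = side == split.clade_a_tips
        else:
            in_a[node] = in_a[node.parent_node]
        rate = rel_rate_a if in_a[node] else 1.0
        rdepth[node] = rdepth[node.parent_node] + rate * (node.edge.length or 0.0)

    below: dict[dendropy.Node, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            below[node] = [i]
            cov[i, i] = rdepth[node]
            continue
        kids = node.child_nodes()
        h = rdepth[node]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                for i in below[kids[a]]:
                    for j in below[kids[b]]:
                        cov[i, j] = cov[j, i] = h
        below[node] = [i for kid in kids for i in below[kid]]
    return labels, cov


def _values_vector(labels: Sequence[str], values: Mapping[str, float]) -> np.ndarray:
    try:
        return np.array([float(values[l]) for l in labels])
    except KeyError as exc:
        raise LabelingError(f"tip {exc.args[0]!r} has no trait value") from exc


def _design(labels: Sequence[str], split: CladeSplit, diff_mean: bool) -> np.ndarray:
    if not diff_mean:
        return np.ones((len(labels), 1))
    x = np.zeros((len(labels), 2))
    for i, lab in enumerate(labels):
        x[i, 0 if lab in split.clade_a_tips else 1] = 1.0
    return x


def bm_loglik(
    tree: dendropy.Tree,
    values: Mapping[str, float],
    split: CladeSplit,
    mu: float | Sequence[float],
    sigma2: float,
    rel_rate_a: float = 1.0,
    _check_shape: bool = True,
) -> float:
    """Log-likelihood of tip values under the two-clade BM model."""
    if sigma2 <= 0.0:
        raise ValueError("sigma2 must be positive")
    if _check_shape:
        _check_clade_ultrametric(tree, split)
    labels, cov = bm_covariance(tree, split, rel_rate_a)
    y = _values_vector(labels, values)
    mus = (mu,) if np.isscalar(mu) else tuple(mu)
    if len(mus) == 1:
        mean = np.full(len(labels), float(mus[0]))
    else:
        mean = np.array(
            [float(mus[0]) if l in split.clade_a_tips else float(mus[1]) for l in labels]
        )
    v = sigma2 * cov
    sign, logdet = np.linalg.slogdet(v)
    if sign <= 0:
        raise FitError("singular BM covariance matrix")
    resid = y - mean
    quad = resid @ np.linalg.solve(v, resid)
    n = len(labels)
    return float(-0.5 * (n * math.log(2.0 * math.pi) + logdet + quad))


def _profile_fit(
    cov: np.ndarray,
    y: np.ndarray,
    x: np.ndarray,
) -> tuple[np.ndarray, float, float]:
    """GLS means, ML sigma2 and profiled lnL for fixed unit-rate covariance."""
    n = len(y)
    cinv_x = np.linalg.solve(cov, x)
    cinv_y = np.linalg.solve(cov, y)
    xtcx = x.T @ cinv_x
    beta = np.linalg.solve(xtcx, x.T @ cinv_y)
    resid = y - x @ beta
    quad = float(resid @ np.linalg.solve(cov, resid))
    sigma2 = quad / n
    if sigma2 <= 0.0:
        raise FitError("degenerate trait data: zero residual variance")
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise FitError("singular BM covariance matrix")
    lnl = -0.5 * (n * math.log(2.0 * math.pi) + n * math.log(sigma2) + logdet + n)
    return beta, sigma2, lnl


def bm_fit(
    tree: dendropy.Tree,
    values: Mapping[str, float],
    split: CladeSplit,
    model: str,
) -> BMFit:
    """ML fit of one of the four clade models.

    Means are solved by GLS and sigma2 in closed form at each candidate rate
    ratio; for the different-rate models the single rate ratio is profiled on
    a log scale.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    _check_clade_ultrametric(tree, split)
    diff_mean = model.startswith("diff_mean")
    diff_rate = model.endswith("diff_rate")
    labels, _ = bm_covariance(tree, split, 1.0)
    y = _values_vector(labels, values)
    x = _design(labels, split, diff_mean)

    def fit_at(log_r: float) -> tuple[np.ndarray, float, float]:
        _, cov = bm_covariance(tree, split, math.exp(log_r))
        return _profile_fit(cov, y, x)

    if not diff_rate:
        beta, sigma2, lnl = fit_at(0.0)
        rate = 1.0
    else:
        result = optimize.minimize_scalar(
            lambda lr: -fit_at(lr)[2],
            bounds=(-8.0, 8.0),
            method="bounded",
            options={"xatol": 1e-9},
        )
        if not result.success:
            raise FitError(f"rate-ratio optimization failed: {result.message}")
        rate = float(math.exp(result.x))
        beta, sigma2, lnl = fit_at(result.x)

    return BMFit(
        model=model,
        mu=tuple(float(b) for b in beta),
        sigma2=float(sigma2),
        rel_rate_a=rate,
        lnl=float(lnl),
        n_params=_N_PARAMS[model],
    )


def clade_model_table(
    tree: dendropy.Tree,
    values: Mapping[str, float],
    split: CladeSplit,
    stem_factors: Sequence[float] = (1.0, 0.5),
) -> list[dict]:
    """All four model fits for each stem-scaling factor.

    For each factor, clade A's stem branch is multiplied by the factor and all
    four models refit; the AIC-minimal model per factor is flagged.
    Returns a list of dicts (model, stem_factor, fit, best).
    """
    _check_clade_ultrametric(tree, split)
    rows: list[dict] = []
    for factor in stem_factors:
        scaled = (
            tree
            if factor == 1.0
            else phylo.scale_clade_stem(tree, split.clade_a_tips, factor)
        )
        fits = [bm_fit(scaled, values, split, model) for model in MODELS]
        best = min(range(len(fits)), key=lambda i: fits[i].aic)
        for i, fit in enumerate(fits):
            rows.append(
                {
                    "model": fit.model,
                    "stem_factor": factor,
                    "fit": fit,
                    "best": i == best,
                }
            )
    return rows


def clade_model_frame(rows: list[dict]):
    """Flatten clade_model_table output into a pandas DataFrame."""
    import pandas as pd

    records = []
    for row in rows:
        fit: BMFit = row["fit"]
        records.append(
            {
                "model": fit.model,
                "stem_factor": row["stem_factor"],
                "AIC": fit.aic,
                "lnL": fit.lnl,
                "brownian_variance": fit.sigma2,
                "brownian_variance_clade_a": fit.sigma2 * fit.rel_rate_a,
                "rel_rate_a": fit.rel_rate_a,
                "mean_a": fit.mu[0],
                "mean_b": fit.mu[-1],
                "n_params": fit.n_params,
                "best": row["best"],
            }
        )
    return pd.DataFrame(records)
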