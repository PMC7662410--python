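"""Partial least squares path modeling with reflective (Mode A) blocks.

Implements the classical iterative composite algorithm: manifest variables
are standardized, outer weights are updated against inner latent estimates
until convergence, latent scores are weighted composites, and structural
coefficients are ordinary least-squares weights between latent scores.
Includes sign alignment of reflective blocks, bootstrap significance for
path coefficients, and a permutation test for group differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PathModelSpec",
    "PLSPMFit",
    "GroupComparison",
    "default_model",
    "align_indicator_signs",
    "fit_plspm",
    "goodness_of_fit",
    "bootstrap_paths",
    "permutation_group_test",
]

INNER_SCHEMES = ("path", "centroid", "factorial")


@dataclass(frozen=True)
class PathModelSpec:
    """Measurement blocks plus an acyclic latent adjacency.

    ``blocks`` maps each latent variable to its ordered manifest variables
    (all blocks reflective); ``edges`` lists directed structural links as
    ``(source, target)`` pairs.
    """

    blocks: Mapping[str, tuple[str, ...]]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks",
                           {lv: tuple(mvs) for lv, mvs in self.blocks.items()})
        object.__setattr__(self, "edges", tuple(map(tuple, self.edges)))
        seen: set[str] = set()
        for lv, mvs in self.blocks.items():
            if not mvs:
                raise ValueError(f"block {lv!r} has no manifest variables")
            for mv in mvs:
                if mv in seen:
                    raise ValueError(f"MV {mv!r} appears in more than one block")
                seen.add(mv)
        for s, t in self.edges:
            if s not in self.blocks or t not in self.blocks:
                raise ValueError(f"edge ({s!r}, {t!r}) references unknown LV")
        self.topological_order()  # raises on cycles
        connected = {v for e in self.edges for v in e}
        for lv in self.blocks:
            if lv not in connected:
                raise ValueError(f"LV {lv!r} is not part of the structural model")

    def topological_order(self) -> tuple[str, ...]:
        indeg = {lv: 0 for lv in self.blocks}
        for _, t in self.edges:
            indeg[t] += 1
        order, ready = [], [lv for lv in self.blocks if indeg[lv] == 0]
        while ready:
            lv = ready.pop(0)
            order.append(lv)
            for s, t in self.edges:
                if s == lv:
                    indeg[t] -= 1
                    if indeg[t] == 0:
                        ready.append(t)
        if len(order) != len(self.blocks):
            raise ValueError("structural model contains a cycle")
        return tuple(order)

    def predecessors(self, lv: str) -> tuple[str, ...]:
        return tuple(s for s, t in self.edges if t == lv)

    def successors(self, lv: str) -> tuple[str, ...]:
        return tuple(t for s, t in self.edges if s == lv)

    @property
    def endogenous(self) -> tuple[str, ...]:
        return tuple(lv for lv in self.blocks if self.predecessors(lv))

    def all_mvs(self) -> tuple[str, ...]:
        return tuple(mv for mvs in self.blocks.values() for mv in mvs)

    def block_of(self, mv: str) -> str:
        for lv, mvs in self.blocks.items():
            if mv in mvs:
                return lv
        raise KeyError(mv)

    def to_jsonable(self) -> dict:
        return {"blocks": {lv: list(mvs) for lv, mvs in self.blocks.items()},
                "edges": [list(e) for e in self.edges]}

    @classmethod
    def from_jsonable(cls, d: Mapping) -> "PathModelSpec":
        return cls(blocks={lv: tuple(mvs) for lv, mvs in d["blocks"].items()},
                   edges=tuple((s, t) for s, t in d["edges"]))


def default_model() -> PathModelSpec:
    """Four-construct model: Sympathetic and Vagal drive ANS, ANS drives Recall."""
    return PathModelSpec(
        blocks={
            "Sympathetic": ("lf", "sdnn", "ns_scr", "mean_scl"),
            "Vagal": ("hf", "pnn50", "rmssd"),
            "ANS": ("lf_hf", "avnn"),
            "Recall": ("recall_score",),
        },
        edges=(("Sympathetic", "ANS"), ("Vagal", "ANS"), ("ANS", "Recall")),
    )


# ---------------------------------------------------------------------------
# Sign alignment
# ---------------------------------------------------------------------------

def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        raise ValueError("zero-variance manifest variable")
    return (x - x.mean(axis=0)) / sd


def align_indicator_signs(table: pd.DataFrame, spec: PathModelSpec
                          ) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Negate manifest variables so each reflective block is sign-consistent.

    Within every multi-MV block an MV is flipped when it correlates
    negatively with the block's first principal component.  The component
    orientation is chosen to minimize the number of flips; exact ties are
    broken by a sign-antisymmetric statistic of the candidate aligned
    columns (sum of third moments), so the aligned block is a deterministic
    function of the data up to the signs the caller happened to supply.
    Single-MV blocks are left untouched.  Returns the adjusted table and a
    per-MV flip log.
    """
    out = table.copy()
    flips: dict[str, bool] = {mv: False for mv in spec.all_mvs()}
    for lv, mvs in spec.blocks.items():
        x = table[list(mvs)].to_numpy(dtype=float)
        if np.any(x.std(axis=0, ddof=1) <= 0):
            raise ValueError(f"zero-variance MV in block {lv!r}")
        if len(mvs) < 2:
            continue
        xs = _standardize(x)
        # corr(x_j, first PC) shares its sign with the leading eigenvector
        # of the block correlation matrix; eigh beats a data-matrix SVD here
        C = xs.T @ xs / (len(xs) - 1)
        eigvals, eigvecs = np.linalg.eigh(C)
        corr = eigvecs[:, -1] * np.sqrt(max(eigvals[-1], 0.0))
        n_neg = int(np.sum(corr < 0))
        if 2 * n_neg < len(mvs):
            signs = np.where(corr < 0, -1.0, 1.0)
        elif 2 * n_neg > len(mvs):
            signs = np.where(corr < 0, 1.0, -1.0)
        else:
            signs = np.where(corr < 0, -1.0, 1.0)
            skew_sum = float(np.sum((xs * signs) ** 3))
            if skew_sum < 0:
                signs = -signs
        for j, mv in enumerate(mvs):
            if signs[j] < 0:
                out[mv] = -out[mv]
                flips[mv] = True
    flipped = [mv for mv, f in flips.items() if f]
    if flipped:
        logger.info("sign-aligned MVs flipped: %s", ", ".join(flipped))
    return out, flips


# ---------------------------------------------------------------------------
# Core fit
# ---------------------------------------------------------------------------

@dataclass
class PLSPMFit:
    spec: PathModelSpec
    outer_weights: dict[str, float]
    loadings: dict[str, float]
    lv_scores: pd.DataFrame
    path_coefficients: dict[tuple[str, str], float]
    r_squared: dict[str, float]
    communalities: dict[str, float]
    gof: float
    n_iterations: int
    converged: bool
    n_rows: int
    scheme: str = "path"
    flips: dict[str, bool] = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "outer_weights": self.outer_weights,
            "loadings": self.loadings,
            "path_coefficients": {f"{s}->{t}": b for (s, t), b
                                  in self.path_coefficients.items()},
            "r_squared": self.r_squared,
            "communalities": self.communalities,
            "gof": self.gof,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "n_rows": self.n_rows,
            "scheme": self.scheme,
            "flips": {mv: bool(f) for mv, f in self.flips.items()},
        }


def _inner_weights(Y: np.ndarray, lvs: Sequence[str], spec: PathModelSpec,
                   scheme: str) -> np.ndarray:
    """Inner weighting matrix E: column j weights LV j's neighbours."""
    k = len(lvs)
    idx = {lv: i for i, lv in enumerate(lvs)}
    n = Y.shape[0]
    C = Y.T @ Y / (n - 1)
    E = np.zeros((k, k))
    for lv in lvs:
        j = idx[lv]
        preds = [idx[p] for p in spec.predecessors(lv)]
        succs = [idx[s] for s in spec.successors(lv)]
        if scheme == "centroid":
            for i in preds + succs:
                E[i, j] = np.sign(C[i, j])
        elif scheme == "factorial":
            for i in preds + succs:
                E[i, j] = C[i, j]
        else:  # path scheme
            if preds:
                Cpp = C[np.ix_(preds, preds)]
                b = np.linalg.solve(Cpp, C[preds, j])
                for i, bi in zip(preds, b):
                    E[i, j] = bi
            for i in succs:
                E[i, j] = C[i, j]
    return E


def fit_plspm(table: pd.DataFrame, spec: PathModelSpec, scheme: str = "path",
              tol: float = 1e-7, max_iter: int = 300) -> PLSPMFit:
    """Fit the path model on an indicator table.

    Manifest variables are standardized; Mode A outer weights iterate until
    the largest absolute weight change drops below ``tol``.  Latent scores
    are re-standardized composites; path coefficients come from per-equation
    ordinary least squares on the latent scores.
    """
    if scheme not in INNER_SCHEMES:
        raise ValueError(f"scheme must be one of {INNER_SCHEMES}")
    lvs = list(spec.blocks)
    mvs = list(spec.all_mvs())
    missing = [mv for mv in mvs if mv not in table.columns]
    if missing:
        raise ValueError(f"table lacks MV columns: {missing}")
    X = table[mvs].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("indicator table contains missing values")
    n = X.shape[0]
    max_preds = max((len(spec.predecessors(lv)) for lv in lvs), default=0)
    if n < max_preds + 2:
        raise ValueError(f"need at least {max_preds + 2} rows, got {n}")
    Xs = _standardize(X)

    block_idx = {lv: [mvs.index(mv) for mv in spec.blocks[lv]] for lv in lvs}
    w = {lv: np.ones(len(block_idx[lv])) for lv in lvs}

    def scores(weights: dict[str, np.ndarray]) -> np.ndarray:
        Y = np.empty((n, len(lvs)))
        for j, lv in enumerate(lvs):
            y = Xs[:, block_idx[lv]] @ weights[lv]
            Y[:, j] = y / y.std(ddof=1)
        return Y

    def normalized(weights: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        out = {}
        for lv in lvs:
            y = Xs[:, block_idx[lv]] @ weights[lv]
            out[lv] = weights[lv] / y.std(ddof=1)
        return out

    w = normalized(w)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Y = scores(w)
        E = _inner_weights(Y, lvs, spec, scheme)
        w_new: dict[str, np.ndarray] = {}
        for j, lv in enumerate(lvs):
            z = Y @ E[:, j]
            # Mode A: weight proportional to covariance of MV with inner estimate
            w_new[lv] = Xs[:, block_idx[lv]].T @ z / (n - 1)
        w_new = normalized(w_new)
        delta = max(np.max(np.abs(w_new[lv] - w[lv])) for lv in lvs)
        w = w_new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("PLS-PM outer estimation did not converge in %d "
                       "iterations", max_iter)

    Y = scores(w)
    lv_scores = pd.DataFrame(Y, columns=lvs, index=table.index)

    loadings = {}
    communalities = {}
    outer_weights = {}
    for j, lv in enumerate(lvs):
        for pos, mv in enumerate(spec.blocks[lv]):
            lo = float(Xs[:, mvs.index(mv)] @ Y[:, j] / (n - 1))
            loadings[mv] = lo
            communalities[mv] = lo * lo
            outer_weights[mv] = float(w[lv][pos])

    path_coefficients: dict[tuple[str, str], float] = {}
    r_squared: dict[str, float] = {}
    for lv in spec.endogenous:
        preds = spec.predecessors(lv)
        j = lvs.index(lv)
        P = Y[:, [lvs.index(p) for p in preds]]
        try:
            beta, *_ = np.linalg.lstsq(P, Y[:, j], rcond=None)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise ValueError("singular predictor matrix") from exc
        resid = Y[:, j] - P @ beta
        r2 = 1.0 - float(resid @ resid) / float(Y[:, j] @ Y[:, j])
        for p, b in zip(preds, beta):
            path_coefficients[(p, lv)] = float(b)
        r_squared[lv] = r2

    mean_comm = float(np.mean(list(communalities.values())))
    mean_r2 = float(np.mean(list(r_squared.values()))) if r_squared else 0.0
    gof = float(np.sqrt(mean_comm * mean_r2))

    return PLSPMFit(spec=spec, outer_weights=outer_weights, loadings=loadings,
                    lv_scores=lv_scores, path_coefficients=path_coefficients,
                    r_squared=r_squared, communalities=communalities, gof=gof,
                    n_iterations=it, converged=converged, n_rows=n,
                    scheme=scheme)


def goodness_of_fit(fit: PLSPMFit) -> float:
    """Geometric mean of average communality and average R-squared."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    if not fit.r_squared:
        raise ValueError("model has no endogenous latent variable")
    mean_comm = float(np.mean(list(fit.communalities.values())))
    mean_r2 = float(np.mean(list(fit.r_squared.values())))
    return float(np.sqrt(mean_comm * mean_r2))


# ---------------------------------------------------------------------------
# Resampling inference
# ---------------------------------------------------------------------------

def _orient_like(reference: PLSPMFit, fit: PLSPMFit) -> dict[tuple[str, str], float]:
    """Path coefficients of ``fit`` after matching LV orientations to ``reference``.

    A resample can legitimately converge with a whole block's orientation
    flipped; comparing raw coefficients across resamples would then mix
    signs.  A latent variable is flipped when its loading vector points
    against the reference's.
    """
    flip = {}
    for lv, mvs in fit.spec.blocks.items():
        dot = sum(fit.loadings[mv] * reference.loadings[mv] for mv in mvs)
        flip[lv] = -1.0 if dot < 0 else 1.0
    return {(s, t): b * flip[s] * flip[t]
            for (s, t), b in fit.path_coefficients.items()}


def bootstrap_paths(table: pd.DataFrame, spec: PathModelSpec,
                    n_boot: int = 500, seed: int = 0, alpha: float = 0.05,
                    scheme: str = "path", tol: float = 1e-7,
                    max_iter: int = 300) -> dict:
    """Row-resampling bootstrap for path coefficients.

    Each resample is sign-aligned and refit; an edge is flagged significant
    when the two-sided percentile interval excludes zero.  Resamples that
    produce a zero-variance MV are redrawn (count reported).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    aligned, _ = align_indicator_signs(table, spec)
    reference = fit_plspm(aligned, spec, scheme=scheme, tol=tol,
                          max_iter=max_iter)
    edges = list(reference.path_coefficients)
    draws = {e: np.empty(n_boot) for e in edges}
    n = len(table)
    redraws = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            sample = table.iloc[idx].reset_index(drop=True)
            try:
                s_aligned, _ = align_indicator_signs(sample, spec)
                fit = fit_plspm(s_aligned, spec, scheme=scheme, tol=tol,
                                max_iter=max_iter)
            except ValueError:
                redraws += 1
                continue
            break
        oriented = _orient_like(reference, fit)
        for e in edges:
            draws[e][b] = oriented[e]

    lo_q, hi_q = 100 * alpha / 2, 100 * (1 - alpha / 2)
    result = {"n_boot": n_boot, "seed": seed, "alpha": alpha,
              "n_redraws": redraws, "edges": {}}
    for e in edges:
        d = draws[e]
        ci = (float(np.percentile(d, lo_q)), float(np.percentile(d, hi_q)))
        p = 2.0 * min(float(np.mean(d <= 0)), float(np.mean(d >= 0)))
        result["edges"][e] = {
            "beta": reference.path_coefficients[e],
            "se": float(d.std(ddof=1)),
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p_value": float(min(max(p, 1.0 / n_boot), 1.0)),
            "significant": bool(ci[0] > 0 or ci[1] < 0),
        }
    return result


@dataclass
class GroupComparison:
    edges: dict[tuple[str, str], dict]
    n_permutations: int
    seed: int

    def to_jsonable(self) -> dict:
        return {"n_permutations": self.n_permutations, "seed": self.seed,
                "edges": {f"{s}->{t}": v for (s, t), v in self.edges.items()}}


def permutation_group_test(table: pd.DataFrame, spec: PathModelSpec,
                           group_labels: Sequence, n_perm: int = 199,
                           seed: int = 0, scheme: str = "path",
                           tol: float = 1e-7, max_iter: int = 300
                           ) -> GroupComparison:
    """Permutation test for group differences in path coefficients.

    The observed statistic per edge is the difference of group-wise
    coefficients; the null distribution refits under random label shuffles.
    The p-value is ``(1 + #{|perm diff| >= |obs diff|}) / (1 + n_perm)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    labels = np.asarray(group_labels)
    if len(labels) != len(table):
        raise ValueError("group_labels length must match table rows")
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    counts = {u: int(np.sum(labels == u)) for u in uniq}
    if min(counts.values()) < 3:
        raise ValueError("each group needs at least 3 rows")

    aligned, _ = align_indicator_signs(table, spec)
    pooled = fit_plspm(aligned, spec, scheme=scheme, tol=tol,
                       max_iter=max_iter)

    def group_betas(lab: np.ndarray) -> dict[tuple[str, str], tuple[float, float]]:
        out = {}
        fits = {}
        for u in uniq:
            sub = aligned.loc[lab == u]
            fits[u] = fit_plspm(sub, spec, scheme=scheme, tol=tol,
                                max_iter=max_iter)
        a = _orient_like(pooled, fits[uniq[0]])
        b = _orient_like(pooled, fits[uniq[1]])
        for e in pooled.path_coefficients:
            out[e] = (a[e], b[e])
        return out

    try:
        observed = group_betas(labels)
    except ValueError as exc:
        raise ValueError(f"a group is too small or degenerate to fit: {exc}")
    edges = list(pooled.path_coefficients)
    exceed = {e: 0 for e in edges}
    rng = np.random.default_rng(seed)
    for _ in range(n_perm):
        # a shuffle can concentrate identical values into one group and
        # make an MV constant there; redraw such degenerate permutations
        for _attempt in range(100):
            perm = rng.permutation(labels)
            try:
                perm_betas = group_betas(perm)
            except ValueError:
                continue
            break
        else:
            raise ValueError("could not find a non-degenerate permutation")
        for e in edges:
            pa, pb = perm_betas[e]
            oa, ob = observed[e]
            if abs(pa - pb) >= abs(oa - ob):
                exceed[e] += 1

    result_edges = {}
    for e in edges:
        oa, ob = observed[e]
        result_edges[e] = {
            f"beta_{uniq[0]}": oa,
            f"beta_{uniq[1]}": ob,
            "observed_diff": oa - ob,
            "p_value": (1 + exceed[e]) / (1 + n_perm),
        }
    return GroupComparison(edges=result_edges, n_permutations=n_perm,
                           seed=seed)
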