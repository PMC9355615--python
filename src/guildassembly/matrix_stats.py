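"""Permutation-based inference on distance matrices.

All statistics operate on the canonical lower-triangle vectorization of
labelled square matrices (scipy ``squareform`` order), so reordering sample
labels consistently leaves every statistic unchanged.

Permutation convention: simultaneous row/column permutation of one matrix
(the response for MRM/PERMANOVA, the first matrix for Mantel), predictors
held fixed; p-values use (count + 1) / (n_perm + 1) smoothing. ``method=
"exact"`` enumerates all n! permutations instead (identity included, no
smoothing), feasible for small n.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateStatisticError, ValidationError
from .tabular_io import DistanceMatrix

__all__ = [
    "MantelResult", "MrmResult", "VpaResult", "PermanovaResult",
    "NmdsResult", "ContrastResult",
    "mantel", "partial_mantel", "mrm", "forward_select_mrm",
    "variation_partitioning", "permanova", "nmds", "category_contrast",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# plumbing


def _check_aligned(*dms: DistanceMatrix) -> tuple[str, ...]:
    labels = dms[0].labels
    for dm in dms[1:]:
        if dm.labels != labels:
            raise ValidationError(
                "distance matrices have mismatched sample labels; "
                "reorder them to a common label order first")
    return labels


def _condensed(dm: DistanceMatrix) -> np.ndarray:
    return dm.condensed()


def _permuted_condensed(values: np.ndarray, perm: np.ndarray,
                        iu: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    return values[np.ix_(perm, perm)][iu]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0:
        raise DegenerateStatisticError("zero variance in a distance triangle")
    return float(xc @ yc) / denom


def _zscore(v: np.ndarray, what: str) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise DegenerateStatisticError(f"zero variance in {what}")
    return (v - v.mean()) / sd


def _perm_iterator(n: int, n_perm: int, seed, method: str):
    """Yield permutations; returns (iterator, n_total, exact)."""
    if method == "exact":
        return (np.array(p) for p in itertools.permutations(range(n))), \
            math.factorial(n), True
    if method != "permutation":
        raise ValidationError(f"method must be 'permutation' or 'exact', "
                              f"got {method!r}")
    rng = np.random.default_rng(seed)
    return (rng.permutation(n) for _ in range(n_perm)), n_perm, False


def _perm_pvalue(count_ge: int, n_total: int, exact: bool) -> float:
    if exact:
        return count_ge / n_total
    return (count_ge + 1) / (n_total + 1)


# ---------------------------------------------------------------------------
# Mantel and partial Mantel


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    alternative: str = "two-sided"
    controlled: str | None = None
    method: str = "permutation"


def mantel(dx: DistanceMatrix, dy: DistanceMatrix, n_perm: int = 999,
           seed: int | None = 0, alternative: str = "two-sided",
           method: str = "permutation") -> MantelResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the lower triangles; significance comes
    from simultaneous row/column permutations of ``dx``.
    """
    labels = _check_aligned(dx, dy)
    n = len(labels)
    if method == "permutation" and n_perm < 99:
        raise ValidationError("n_perm must be >= 99 for Monte-Carlo inference")
    if alternative not in ("two-sided", "greater"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    iu = np.triu_indices(n, k=1)
    x = dx.values[iu]
    y = dy.values[iu]
    r_obs = _pearson(x, y)
    perms, n_total, exact = _perm_iterator(n, n_perm, seed, method)
    count = 0
    for perm in perms:
        xp = _permuted_condensed(dx.values, perm, iu)
        r_p = _pearson(xp, y)
        if alternative == "greater":
            count += r_p >= r_obs - _EPS
        else:
            count += abs(r_p) >= abs(r_obs) - _EPS
    return MantelResult(r=r_obs, p=_perm_pvalue(count, n_total, exact),
                        n_perm=n_total, alternative=alternative,
                        method=method)


def _partial_r(r_xy: float, r_xz: float, r_yz: float) -> float:
    denom = math.sqrt((1 - r_xz ** 2) * (1 - r_yz ** 2))
    if denom == 0:
        raise DegenerateStatisticError(
            "perfect correlation with the controlled matrix; "
            "partial correlation undefined")
    return (r_xy - r_xz * r_yz) / denom


def partial_mantel(dx: DistanceMatrix, dy: DistanceMatrix, dz: DistanceMatrix,
                   n_perm: int = 999, seed: int | None = 0,
                   alternative: str = "two-sided",
                   method: str = "permutation",
                   controlled_label: str | None = None) -> MantelResult:
    """Partial Mantel: correlation of dx and dy controlling for dz.

    Permutes dx and recomputes the full partial statistic each round.
    """
    labels = _check_aligned(dx, dy, dz)
    n = len(labels)
    if alternative not in ("two-sided", "greater"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    iu = np.triu_indices(n, k=1)
    x, y, z = dx.values[iu], dy.values[iu], dz.values[iu]
    r_yz = _pearson(y, z)
    r_obs = _partial_r(_pearson(x, y), _pearson(x, z), r_yz)
    perms, n_total, exact = _perm_iterator(n, n_perm, seed, method)
    count = 0
    for perm in perms:
        xp = _permuted_condensed(dx.values, perm, iu)
        try:
            r_p = _partial_r(_pearson(xp, y), _pearson(xp, z), r_yz)
        except DegenerateStatisticError:
            continue
        if alternative == "greater":
            count += r_p >= r_obs - _EPS
        else:
            count += abs(r_p) >= abs(r_obs) - _EPS
    return MantelResult(r=r_obs, p=_perm_pvalue(count, n_total, exact),
                        n_perm=n_total, alternative=alternative,
                        controlled=controlled_label, method=method)


# ---------------------------------------------------------------------------
# MRM


@dataclass(frozen=True)
class MrmResult:
    selected: tuple[str, ...]
    coefficients: dict[str, float]
    r_squared: float
    p_per_predictor: dict[str, float]
    p_model: float
    n_perm: int
    alpha: float | None = None
    selection_path: tuple[dict, ...] = ()


def _design_matrix(dy: DistanceMatrix,
                   predictors: Mapping[str, DistanceMatrix],
                   standardize: bool,
                   check_collinearity: bool = True
                   ) -> tuple[np.ndarray, np.ndarray, list]:
    if not predictors:
        raise ValidationError("MRM needs at least one predictor")
    _check_aligned(dy, *predictors.values())
    n = dy.n
    iu = np.triu_indices(n, k=1)
    names = list(predictors)
    y = dy.values[iu]
    cols = []
    for name in names:
        v = predictors[name].values[iu]
        cols.append(_zscore(v, f"predictor {name!r}") if standardize else v)
    X = np.column_stack([np.ones(y.size)] + cols)
    # collinearity guard on the predictor block
    if check_collinearity and len(names) > 1:
        corr = np.corrcoef(np.column_stack(cols), rowvar=False)
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                if abs(corr[a, b]) > 1 - 1e-10:
                    raise ValidationError(
                        f"collinear predictors: {names[a]!r} and {names[b]!r}")
    if standardize:
        y = _zscore(y, "response triangle")
    return y, X, names


def _ols(X: np.ndarray, y: np.ndarray, xtx_inv: np.ndarray
         ) -> tuple[np.ndarray, float, np.ndarray]:
    """Return (beta, R2, t-values) for the design X (intercept first)."""
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    yc = y - y.mean()
    tss = float(yc @ yc)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    df = y.size - X.shape[1]
    sigma2 = rss / df if df > 0 else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.diagonal(xtx_inv) * sigma2)
        t = np.where(se > 0, beta / se, np.sign(beta) * np.inf)
    return beta, r2, t


def mrm(dy: DistanceMatrix, predictors: Mapping[str, DistanceMatrix],
        n_perm: int = 999, seed: int | None = 0, standardize: bool = True,
        method: str = "permutation") -> MrmResult:
    """Multiple regression of dy's triangle on predictor triangles.

    Predictors (and the response) are z-scored by default, so coefficients
    are standardized betas. Only dy is permuted for inference.
    """
    y, X, names = _design_matrix(dy, predictors, standardize)
    n = dy.n
    iu = np.triu_indices(n, k=1)
    xtx_inv = np.linalg.pinv(X.T @ X)
    beta_obs, r2_obs, t_obs = _ols(X, y, xtx_inv)
    perms, n_total, exact = _perm_iterator(n, n_perm, seed, method)
    count_t = np.zeros(len(names), dtype=int)
    count_r2 = 0
    yvals = dy.values
    for perm in perms:
        yp = _permuted_condensed(yvals, perm, iu)
        if standardize:
            yp = _zscore(yp, "response triangle")
        _, r2_p, t_p = _ols(X, yp, xtx_inv)
        count_t += np.abs(t_p[1:]) >= np.abs(t_obs[1:]) - _EPS
        count_r2 += r2_p >= r2_obs - _EPS
    p_pred = {name: _perm_pvalue(int(c), n_total, exact)
              for name, c in zip(names, count_t)}
    return MrmResult(
        selected=tuple(names),
        coefficients={name: float(b) for name, b in zip(names, beta_obs[1:])},
        r_squared=float(r2_obs),
        p_per_predictor=p_pred,
        p_model=_perm_pvalue(count_r2, n_total, exact),
        n_perm=n_total)


def forward_select_mrm(dy: DistanceMatrix,
                       candidates: Mapping[str, DistanceMatrix],
                       alpha: float = 0.05, n_perm: int = 999,
                       seed: int | None = 0,
                       method: str = "permutation") -> MrmResult:
    """Forward selection over candidate matrices until no addition has p < alpha.

    Each round fits the model with every remaining candidate added to the
    already-selected terms; the candidate with the largest R-squared gain
    whose marginal permutation p is below alpha enters (R-squared ties broken
    by candidate name order). Returns the final fitted model; an empty
    selection yields R-squared 0.
    """
    if not (0 < alpha <= 1):
        raise ValidationError("alpha must lie in (0, 1]")
    ss = np.random.SeedSequence(seed)
    selected: list[str] = []
    remaining = sorted(candidates)
    path: list[dict] = []
    current_r2 = 0.0
    while remaining:
        best: tuple[float, str, MrmResult] | None = None
        round_seeds = ss.spawn(len(remaining))
        for cand, cand_seed in zip(remaining, round_seeds):
            model_preds = {name: candidates[name] for name in selected + [cand]}
            fit = mrm(dy, model_preds, n_perm=n_perm, seed=cand_seed,
                      method=method)
            if fit.p_per_predictor[cand] >= alpha:
                continue
            gain = fit.r_squared - current_r2
            # ties on R2 gain broken by name order (candidates iterated sorted)
            if best is None or gain > best[0] + _EPS:
                best = (gain, cand, fit)
        if best is None:
            break
        gain, cand, fit = best
        selected.append(cand)
        remaining.remove(cand)
        current_r2 = fit.r_squared
        path.append({"added": cand, "r_squared": fit.r_squared,
                     "p": fit.p_per_predictor[cand]})
    if not selected:
        return MrmResult(selected=(), coefficients={}, r_squared=0.0,
                         p_per_predictor={}, p_model=1.0, n_perm=n_perm,
                         alpha=alpha, selection_path=())
    final = mrm(dy, {name: candidates[name] for name in selected},
                n_perm=n_perm, seed=ss.spawn(1)[0], method=method)
    return MrmResult(selected=final.selected, coefficients=final.coefficients,
                     r_squared=final.r_squared,
                     p_per_predictor=final.p_per_predictor,
                     p_model=final.p_model, n_perm=final.n_perm, alpha=alpha,
                     selection_path=tuple(path))


# ---------------------------------------------------------------------------
# Variation partitioning


@dataclass(frozen=True)
class VpaResult:
    pure_env: float
    pure_space: float
    shared: float
    unexplained: float
    r2_full: float
    r2_env: float
    r2_space: float
    adjusted: bool = False

    def fractions(self) -> dict[str, float]:
        return {"pure_env": self.pure_env, "pure_space": self.pure_space,
                "shared": self.shared, "unexplained": self.unexplained}


def _r2_only(dy: DistanceMatrix, predictors: Mapping[str, DistanceMatrix],
             adjusted: bool) -> float:
    # VPA tolerates shared/duplicated predictors across groups; pinv handles
    # the singular design, so no collinearity guard here
    y, X, _ = _design_matrix(dy, predictors, standardize=True,
                             check_collinearity=False)
    xtx_inv = np.linalg.pinv(X.T @ X)
    _, r2, _ = _ols(X, y, xtx_inv)
    if adjusted:
        m, k = y.size, X.shape[1] - 1
        r2 = 1 - (1 - r2) * (m - 1) / (m - k - 1)
    return float(r2)


def variation_partitioning(dy: DistanceMatrix,
                           env: Mapping[str, DistanceMatrix],
                           space: Mapping[str, DistanceMatrix],
                           adjusted: bool = False) -> VpaResult:
    """Partition dy's explained variance into pure env / pure space / shared.

    Pure environmental fractions index selection; pure spatial fractions
    index dispersal limitation. Fractions sum to 1 exactly.
    """
    if not env or not space:
        raise ValidationError("both predictor groups must be non-empty")
    overlap = set(env) & set(space)
    if overlap:
        raise ValidationError(f"predictors in both groups: {sorted(overlap)}")
    r2_full = _r2_only(dy, {**env, **space}, adjusted)
    r2_env = _r2_only(dy, env, adjusted)
    r2_space = _r2_only(dy, space, adjusted)
    pure_env = r2_full - r2_space
    pure_space = r2_full - r2_env
    shared = r2_env + r2_space - r2_full
    return VpaResult(pure_env=pure_env, pure_space=pure_space, shared=shared,
                     unexplained=1.0 - r2_full, r2_full=r2_full,
                     r2_env=r2_env, r2_space=r2_space, adjusted=adjusted)


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p: float
    n_perm: int
    n_groups: int


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        members = np.flatnonzero(codes == g)
        sub = d2[np.ix_(members, members)]
        ss_within += sub[np.triu_indices(len(members), k=1)].sum() / len(members)
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    return (ss_among / df_among) / (ss_within / df_within)


def permanova(d: DistanceMatrix, groups: Sequence[str], n_perm: int = 999,
              seed: int | None = 0, method: str = "permutation"
              ) -> PermanovaResult:
    """One-way PERMANOVA (pseudo-F) with label-permutation significance."""
    n = d.n
    if len(groups) != n:
        raise ValidationError("one group label per sample required")
    labels, codes = np.unique(np.asarray(groups), return_inverse=True)
    if len(labels) < 2:
        raise ValidationError("PERMANOVA needs >= 2 groups")
    sizes = np.bincount(codes)
    if sizes.min() < 2:
        small = labels[int(np.argmin(sizes))]
        raise ValidationError(f"group {small!r} has fewer than 2 members")
    d2 = d.values ** 2
    f_obs = _pseudo_f(d2, codes, len(labels))
    perms, n_total, exact = _perm_iterator(n, n_perm, seed, method)
    count = 0
    for perm in perms:
        count += _pseudo_f(d2, codes[perm], len(labels)) >= f_obs - _EPS
    return PermanovaResult(pseudo_f=float(f_obs),
                           p=_perm_pvalue(count, n_total, exact),
                           n_perm=n_total, n_groups=len(labels))


# ---------------------------------------------------------------------------
# NMDS


@dataclass(frozen=True)
class NmdsResult:
    coords: pd.DataFrame  # samples x k
    stress: float
    k: int


def nmds(d: DistanceMatrix, k: int = 2, n_starts: int = 20,
         seed: int | None = 0) -> NmdsResult:
    """Non-metric MDS minimizing Kruskal stress-1 over random starts."""
    from sklearn.manifold import MDS

    if k < 1:
        raise ValidationError("k must be >= 1")
    if k >= d.n:
        raise ValidationError(f"k={k} must be below the number of samples ({d.n})")
    model = MDS(n_components=k, metric="precomputed", metric_mds=False,
                n_init=n_starts, max_iter=500, eps=1e-6, init="random",
                random_state=np.random.RandomState(seed),
                normalized_stress=True)
    coords = model.fit_transform(d.values)
    df = pd.DataFrame(coords, index=list(d.labels),
                      columns=[f"NMDS{i + 1}" for i in range(k)])
    df.index.name = "sample_id"
    return NmdsResult(coords=df, stress=float(model.stress_), k=k)


# ---------------------------------------------------------------------------
# Category contrasts


@dataclass(frozen=True)
class ContrastResult:
    bin_labels: tuple[str, ...]       # included bins, low-to-high order
    bin_stats: dict[str, dict]        # per included bin: n_pairs/mean/median
    pairwise_p: dict[tuple[str, str], float]
    letters: dict[str, str]           # compact letter display
    excluded: tuple[str, ...]         # bins with too few within-bin pairs
    bin_of_sample: dict[str, str]


_BIN_NAMES = {2: ("low", "high"), 3: ("low", "medium", "high")}


def _compact_letters(bins: Sequence[str],
                     different: set[tuple[str, str]]) -> dict[str, str]:
    """Letters via maximal cliques of the not-significantly-different graph."""
    n = len(bins)
    adj = {b: set() for b in bins}
    for a in bins:
        for b in bins:
            if a != b and (a, b) not in different and (b, a) not in different:
                adj[a].add(b)
    cliques: list[frozenset] = []
    for r in range(n, 0, -1):
        for combo in itertools.combinations(bins, r):
            s = frozenset(combo)
            if any(s <= c for c in cliques):
                continue
            if all(b in adj[a] for a, b in itertools.combinations(combo, 2)):
                cliques.append(s)
    cliques.sort(key=lambda c: min(bins.index(b) for b in c))
    letters = {b: "" for b in bins}
    for i, clique in enumerate(cliques):
        ch = chr(ord("a") + i)
        for b in bins:
            if b in clique:
                letters[b] += ch
    return letters


def category_contrast(deviations: DistanceMatrix, attribute: pd.Series,
                      n_bins: int = 3, alpha: float = 0.05,
                      min_pairs: int = 2) -> ContrastResult:
    """Within-bin deviation summaries and pairwise Wilcoxon rank-sum tests.

    Samples are binned by quantiles of ``attribute`` (terciles for 3 bins,
    median split for 2); a pairwise deviation belongs to a bin only if both
    of its samples do. Bins with fewer than ``min_pairs`` within-bin pairs
    are flagged and excluded from testing.
    """
    if n_bins not in _BIN_NAMES:
        raise ValidationError("n_bins must be 2 or 3")
    labels = deviations.labels
    missing = [s for s in labels if s not in attribute.index]
    if missing:
        raise ValidationError(f"attribute missing for samples {missing[:5]}")
    vals = attribute.loc[list(labels)].to_numpy(dtype=float)
    qs = np.quantile(vals, np.linspace(0, 1, n_bins + 1))
    # digitize against interior edges; right-closed top bin
    codes = np.clip(np.searchsorted(qs[1:-1], vals, side="right"), 0, n_bins - 1)
    names = _BIN_NAMES[n_bins]
    bin_of_sample = {s: names[c] for s, c in zip(labels, codes)}
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    dev = deviations.values[iu]
    pair_bins = np.where(codes[iu[0]] == codes[iu[1]], codes[iu[0]], -1)
    per_bin_values: dict[str, np.ndarray] = {}
    for c, name in enumerate(names):
        v = dev[pair_bins == c]
        per_bin_values[name] = v[~np.isnan(v)]
    included = [b for b in names if per_bin_values[b].size >= min_pairs]
    excluded = tuple(b for b in names if b not in included)
    bin_stats = {b: {"n_pairs": int(per_bin_values[b].size),
                     "mean": float(per_bin_values[b].mean()),
                     "median": float(np.median(per_bin_values[b]))}
                 for b in included}
    pairwise_p: dict[tuple[str, str], float] = {}
    different: set[tuple[str, str]] = set()
    for a, b in itertools.combinations(included, 2):
        va, vb = per_bin_values[a], per_bin_values[b]
        if np.all(va[0] == np.concatenate([va, vb])):
            p = 1.0  # all values identical: no evidence of difference
        else:
            p = float(stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue)
        pairwise_p[(a, b)] = p
        if p < alpha:
            different.add((a, b))
    letters = _compact_letters(included, different)
    return ContrastResult(bin_labels=tuple(included), bin_stats=bin_stats,
                          pairwise_p=pairwise_p, letters=letters,
                          excluded=excluded, bin_of_sample=bin_of_sample)
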