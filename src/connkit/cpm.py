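"""Connectome-based Predictive Modeling (CPM).

Within each cross-validation fold, edges whose Fisher-z values correlate
with the behavioural score beyond a selection threshold (p < 0.005 by
default, two-tailed t-transform of r) are split into a positive and a
negative network. A subject's "network strength" is the sum of their
edge values over a network, and simple linear models (plus a combined
two-predictor GLM) map strength to behaviour. Out-of-fold predictions
are scored by Pearson correlation with the observed scores; significance
comes from re-running the whole pipeline on behaviour-permuted data.

The reported networks are the intersection of the per-fold selections
("consensus" networks), so an edge must survive selection in every fold
to be reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import reduce

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold

from .fc import edge_index

__all__ = [
    "CpmConfig",
    "CpmResults",
    "CPM",
    "select_edges",
    "network_strength",
    "degree_table",
    "high_degree_followup",
    "groupwise_evaluation",
    "partial_correlation",
]

_MODELS = ("positive", "negative", "combined")


@dataclass
class CpmConfig:
    select_alpha: float = 0.005
    cv: str = "loocv"  # "loocv" | "kfold"
    n_folds: int = 10
    n_permutations: int = 1000
    negative_r_to_zero: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.select_alpha < 1.0:
            raise ValueError("select_alpha must lie in (0, 1)")
        if self.cv not in ("loocv", "kfold"):
            raise ValueError("cv must be 'loocv' or 'kfold'")


def _edge_behavior_r(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r between each edge column and the behaviour vector."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r[sx == 0] = np.nan  # constant edges carry no information
    return r


_R_CRIT_CACHE: dict[tuple[float, int], float] = {}


def _r_critical(alpha: float, df: int) -> float:
    """|r| above which the two-tailed t-transform p-value falls below alpha."""
    key = (alpha, df)
    if key not in _R_CRIT_CACHE:
        t_crit = stats.t.isf(alpha / 2.0, df)
        _R_CRIT_CACHE[key] = t_crit / np.sqrt(df + t_crit**2)
    return _R_CRIT_CACHE[key]


def select_edges(
    X: np.ndarray, y: np.ndarray, alpha: float = 0.005
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split edges into positive/negative behaviour-correlated sets.

    p-values come from the exact t-transform of r with n-2 degrees of
    freedom, two-tailed; the sign of r decides set membership. (The
    threshold is applied on the equivalent critical |r|, which avoids
    computing every p explicitly.)

    Returns
    -------
    positive, negative, r
        Sorted edge-index arrays and the per-edge correlation vector
        (NaN for constant edges, which are excluded with a warning).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 subjects for edge selection")
    if np.std(y) == 0:
        raise ValueError("behaviour has zero variance")
    r = _edge_behavior_r(X, y)
    if np.any(np.isnan(r)):
        warnings.warn("constant edge column(s) excluded from selection", stacklevel=2)
    r_crit = _r_critical(alpha, n - 2)
    pos = np.flatnonzero(r > r_crit)
    neg = np.flatnonzero(r < -r_crit)
    return pos, neg, r


def network_strength(edge_values: np.ndarray, edge_set: np.ndarray) -> np.ndarray:
    """Sum of edge z-values over an edge set (the network "strength").

    Accepts a single edge vector or a subjects x edges matrix; an empty
    set yields strength 0.
    """
    edge_values = np.asarray(edge_values, float)
    edge_set = np.asarray(edge_set, int)
    if edge_set.size == 0:
        return np.zeros(edge_values.shape[:-1])
    return edge_values[..., edge_set].sum(axis=-1)


def _fit_simple(s: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(slope, intercept) of y ~ strength; constant strength -> mean model."""
    sm, ym = s.mean(), y.mean()
    ss = float(((s - sm) ** 2).sum())
    if ss == 0:
        return 0.0, float(ym)
    slope = float(((s - sm) * (y - ym)).sum() / ss)
    return slope, float(ym - slope * sm)


def _fit_combined(sp, sn, y) -> np.ndarray:
    A = np.column_stack([np.ones_like(y), sp, sn])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return coef


class CpmResults:
    """Fitted CPM: consensus networks, out-of-fold predictions, scores."""

    def __init__(
        self,
        fold_positive: list[np.ndarray],
        fold_negative: list[np.ndarray],
        consensus_positive: np.ndarray,
        consensus_negative: np.ndarray,
        fold_coefficients: list[dict],
        predictions: pd.DataFrame,
        behavior: np.ndarray,
        config: CpmConfig,
        n_regions: int | None = None,
    ):
        self.fold_positive = fold_positive
        self.fold_negative = fold_negative
        self.consensus_positive = consensus_positive
        self.consensus_negative = consensus_negative
        self.fold_coefficients = fold_coefficients
        #: out-of-fold predicted scores, one column per model
        self.predictions = predictions
        self.behavior = behavior
        self.config = config
        self.n_regions = n_regions
        self.permutation_p: dict[str, float] | None = None

    def performance(self, model: str = "combined", raw: bool = False) -> float:
        """Pearson r between out-of-fold predictions and observed scores.

        Negative correlations are reported as 0 unless ``raw=True`` or
        the config disables the truncation.
        """
        pred = self.predictions[model].to_numpy()
        if np.std(pred) == 0 or np.std(self.behavior) == 0:
            return np.nan
        r = float(np.corrcoef(pred, self.behavior)[0, 1])
        if not raw and self.config.negative_r_to_zero:
            r = max(r, 0.0)
        return r

    def summary(self) -> str:
        lines = [
            "Connectome-based Predictive Modeling",
            f"  subjects: {len(self.behavior)}, cv: {self.config.cv}, "
            f"selection p < {self.config.select_alpha:g}",
            f"  consensus positive network: {len(self.consensus_positive)} edges",
            f"  consensus negative network: {len(self.consensus_negative)} edges",
        ]
        for m in _MODELS:
            line = f"  {m} model r = {self.performance(m):.3f}"
            if self.permutation_p is not None and m in self.permutation_p:
                line += f", permutation p = {self.permutation_p[m]:.4f}"
            lines.append(line)
        return "\n".join(lines)


class CPM:
    """Connectome-based Predictive Modeling of a behavioural score.

    Parameters
    ----------
    edge_matrix
        Subjects x edges Fisher-z matrix (upper-triangle convention).
    behavior
        Per-subject behavioural score (e.g. a Wechsler composite).
    config
        :class:`CpmConfig`. LOOCV is the default; k-fold assignment is
        shuffled (stratified by ``groups`` when given) under the seed.
    groups
        Optional per-subject labels used to stratify k-fold splits.
    n_regions
        Optional region count; required only for node-level summaries.
    """

    def __init__(
        self,
        edge_matrix: np.ndarray,
        behavior: np.ndarray,
        config: CpmConfig | None = None,
        groups=None,
        n_regions: int | None = None,
    ):
        self.X = np.asarray(edge_matrix, float)
        self.y = np.asarray(behavior, float)
        if self.X.ndim != 2 or len(self.y) != self.X.shape[0]:
            raise ValueError("edge_matrix must be subjects x edges, matching behavior")
        if len(self.y) < 10:
            raise ValueError("need at least 10 subjects for cross-validated CPM")
        self.config = config or CpmConfig()
        self.groups = None if groups is None else np.asarray(groups)
        self.n_regions = n_regions

    def _folds(self) -> list[np.ndarray]:
        n = len(self.y)
        if self.config.cv == "loocv":
            return [np.array([i]) for i in range(n)]
        if self.groups is not None:
            kf = StratifiedKFold(
                n_splits=self.config.n_folds, shuffle=True,
                random_state=self.config.seed,
            )
            return [test for _, test in kf.split(self.X, self.groups)]
        kf = KFold(
            n_splits=self.config.n_folds, shuffle=True, random_state=self.config.seed
        )
        return [test for _, test in kf.split(self.X)]

    def fit(self, _y: np.ndarray | None = None, _warn: bool = True) -> CpmResults:
        y = self.y if _y is None else np.asarray(_y, float)
        X = self.X
        n = len(y)
        folds = self._folds()
        pred = {m: np.full(n, np.nan) for m in _MODELS}
        fold_pos, fold_neg, fold_coef = [], [], []
        for test in folds:
            mask = np.ones(n, bool)
            mask[test] = False
            train = np.flatnonzero(mask)
            pos, neg, _ = select_edges(X[train], y[train], self.config.select_alpha)
            fold_pos.append(pos)
            fold_neg.append(neg)
            if pos.size == 0 and neg.size == 0 and _warn:
                warnings.warn(
                    "a fold selected no edges; predicting the training mean",
                    stacklevel=2,
                )
            sp_tr = network_strength(X[train], pos)
            sn_tr = network_strength(X[train], neg)
            sp_te = network_strength(X[test], pos)
            sn_te = network_strength(X[test], neg)
            coef = {
                "positive": _fit_simple(sp_tr, y[train]),
                "negative": _fit_simple(sn_tr, y[train]),
                "combined": _fit_combined(sp_tr, sn_tr, y[train]),
            }
            fold_coef.append(coef)
            pred["positive"][test] = coef["positive"][0] * sp_te + coef["positive"][1]
            pred["negative"][test] = coef["negative"][0] * sn_te + coef["negative"][1]
            b = coef["combined"]
            pred["combined"][test] = b[0] + b[1] * sp_te + b[2] * sn_te
        consensus_pos = reduce(np.intersect1d, fold_pos)
        consensus_neg = reduce(np.intersect1d, fold_neg)
        return CpmResults(
            fold_pos, fold_neg, consensus_pos, consensus_neg, fold_coef,
            pd.DataFrame(pred), y, self.config, self.n_regions,
        )

    def permutation_test(
        self,
        results: CpmResults | None = None,
        n_permutations: int | None = None,
        seed: int | None = None,
    ) -> dict[str, float]:
        """One-tailed permutation p-value of the out-of-fold performance.

        Behaviour is shuffled against the connectivity matrices and the
        full cross-validated pipeline re-run each time;
        ``p = (1 + #{null r >= observed r}) / (n_perm + 1)``.
        The p-values are stored on ``results.permutation_p``.
        """
        if results is None:
            results = self.fit()
        n_perm = n_permutations or self.config.n_permutations
        rng = np.random.default_rng(self.config.seed if seed is None else seed)
        obs = {m: results.performance(m, raw=True) for m in _MODELS}
        exceed = {m: 0 for m in _MODELS}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(n_perm):
                y_perm = rng.permutation(self.y)
                null_res = self.fit(_y=y_perm, _warn=False)
                for m in _MODELS:
                    r_null = null_res.performance(m, raw=True)
                    if np.isnan(obs[m]) or (
                        not np.isnan(r_null) and r_null >= obs[m]
                    ):
                        exceed[m] += 1
        pvals = {}
        for m in _MODELS:
            if np.isnan(obs[m]):
                warnings.warn(
                    f"{m} model performance undefined (constant predictions); p = 1",
                    stacklevel=2,
                )
                pvals[m] = 1.0
            else:
                pvals[m] = (1.0 + exceed[m]) / (n_perm + 1.0)
        results.permutation_p = pvals
        return pvals


# ---------------------------------------------------------------------------
# network localisation and follow-up

def degree_table(
    edge_set: np.ndarray, n_regions: int, atlas: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-node degree within an edge set, with atlas annotation.

    Degree is the number of selected edges incident to the node, so the
    degrees sum to twice the edge count.
    """
    iu, ju = edge_index(n_regions)
    edge_set = np.asarray(edge_set, int)
    deg = np.bincount(
        np.concatenate([iu[edge_set], ju[edge_set]]), minlength=n_regions
    )
    df = pd.DataFrame({"region_id": np.arange(n_regions), "degree": deg})
    if atlas is not None:
        df = df.merge(
            atlas[["region_id", "name", "lobe", "canonical_network"]],
            on="region_id", how="left",
        )
    return df.sort_values("degree", ascending=False, ignore_index=True)


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Pearson correlation of x and y after residualising both on covariates.

    Returns (r, two-tailed p) with n - 2 - k degrees of freedom.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    k = 0
    if covariates is not None and np.size(covariates) > 0:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        k = C.shape[1]
        design = np.column_stack([np.ones(n), C])
        x = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
        y = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    df = n - 2 - k
    if df <= 0 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan
    r = float(np.corrcoef(x, y)[0, 1])
    rr = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    t = rr * np.sqrt(df / (1.0 - rr**2))
    return r, float(2.0 * stats.t.sf(abs(t), df))


def high_degree_followup(
    edge_matrix: np.ndarray,
    behavior: np.ndarray,
    results: CpmResults,
    k: int = 4,
    covariates: np.ndarray | None = None,
    network: str = "positive",
    atlas: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Predictive power of each top-k hub's incident sub-network.

    For each of the k highest-degree nodes of the consensus network, the
    network is restricted to edges incident to that node, per-subject
    strength is recomputed, and its (partial, if covariates are given)
    correlation with behaviour is tested; p-values are BH-adjusted
    across the k nodes.
    """
    from .mediation import fdr_adjust

    if results.n_regions is None:
        raise ValueError("results lack n_regions; pass n_regions to CPM")
    edges = (
        results.consensus_positive if network == "positive"
        else results.consensus_negative
    )
    n_regions = results.n_regions
    iu, ju = edge_index(n_regions)
    deg = degree_table(edges, n_regions, atlas)
    top = deg.head(k)
    rows = []
    for _, node_row in top.iterrows():
        node = int(node_row["region_id"])
        incident = edges[(iu[edges] == node) | (ju[edges] == node)]
        if incident.size == 0:
            warnings.warn(f"node {node} has no incident edges; skipped", stacklevel=2)
            continue
        s = network_strength(np.asarray(edge_matrix, float), incident)
        r, p = partial_correlation(s, behavior, covariates)
        row = {"region_id": node, "degree": int(node_row["degree"]),
               "n_edges": int(incident.size), "r": r, "p": p}
        if "name" in node_row:
            row["name"] = node_row["name"]
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out["p_fdr"] = fdr_adjust(out["p"].to_numpy())
    return out


def groupwise_evaluation(
    strengths: np.ndarray, behavior: np.ndarray, groups
) -> pd.DataFrame:
    """Within-group correlation of network strength with behaviour.

    Groups with fewer than 4 subjects are excluded with a warning.
    """
    strengths = np.asarray(strengths, float)
    behavior = np.asarray(behavior, float)
    groups = np.asarray(groups)
    rows = []
    for g in pd.unique(groups):
        mask = groups == g
        if mask.sum() < 4:
            warnings.warn(f"group {g!r} has fewer than 4 subjects; excluded",
                          stacklevel=2)
            continue
        r, p = partial_correlation(strengths[mask], behavior[mask])
        rows.append({"group": g, "n": int(mask.sum()), "r": r, "p": p})
    return pd.DataFrame(rows)
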