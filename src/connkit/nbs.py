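"""Network-Based Statistics: permutation FWER control on component size.

Edges are first screened for being significantly nonzero within at least
one group (Bonferroni one-sample t-tests), then tested edge-wise with a
two-sample t-test at a strict primary threshold (p < 1e-4 by default).
Suprathreshold edges form a graph whose connected components are the
units of inference; the family-wise-corrected p-value of a component of
M edges is the permutation-null exceedance probability of the maximal
component size, estimated as ``(1 + #{null >= M}) / (n_perm + 1)``.

The screening mask is computed once on the observed grouping and reused
across permutations; only the group labels are shuffled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse import csgraph

from .fc import edge_index, n_edges

__all__ = [
    "NbsConfig",
    "NbsResults",
    "NBS",
    "prefilter_edges",
    "edge_tstats",
    "connected_components",
]

_TAILS = ("less", "greater", "two-sided")


@dataclass
class NbsConfig:
    """Settings for an NBS run.

    ``tail='less'`` tests for lower connectivity in the first (patient)
    group, the usual direction for a disease cohort.
    """

    primary_alpha: float = 1e-4
    tail: str = "less"
    n_permutations: int = 10_000
    prefilter_alpha: float = 0.05
    prefilter_bonferroni: bool = True
    welch: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.primary_alpha < 1.0:
            raise ValueError("primary_alpha must lie in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")
        if self.tail not in _TAILS:
            raise ValueError(f"tail must be one of {_TAILS}")


def prefilter_edges(
    z_patients: np.ndarray,
    z_controls: np.ndarray,
    alpha: float = 0.05,
    bonferroni: bool = True,
) -> np.ndarray:
    """Mask of edges significantly nonzero in at least one group.

    One-sample two-tailed t-test of the Fisher-z values against zero,
    within each group; an edge is retained if it passes in either group
    at ``alpha`` divided by the edge count (Bonferroni) across edges.
    """
    z_patients = np.atleast_2d(np.asarray(z_patients, float))
    z_controls = np.atleast_2d(np.asarray(z_controls, float))
    if z_patients.shape[0] < 2 or z_controls.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    E = z_patients.shape[1]
    thresh = alpha / E if bonferroni else alpha
    pmin = np.ones(E)
    any_degenerate = False
    for grp in (z_patients, z_controls):
        n = grp.shape[0]
        mean = grp.mean(axis=0)
        sd = grp.std(axis=0, ddof=1)
        ok = sd > 0
        any_degenerate |= bool(np.any(~ok))
        t = np.zeros(E)
        t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
        p = np.ones(E)
        p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=n - 1)
        pmin = np.minimum(pmin, p)
    if any_degenerate:
        warnings.warn("zero-variance edge(s) treated as non-significant", stacklevel=2)
    return pmin < thresh


def _pooled_t(s1, q1, n1, tot, tot2, n2):
    """Pooled-variance two-sample t from group-1 sums/sumsquares."""
    m1 = s1 / n1
    m2 = (tot - s1) / n2
    ss1 = q1 - s1**2 / n1
    ss2 = (tot2 - q1) - (tot - s1) ** 2 / n2
    df = n1 + n2 - 2
    pooled = (ss1 + ss2) / df
    se = np.sqrt(np.clip(pooled, 0.0, None) * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (m1 - m2) / se, 0.0)
    return t


def edge_tstats(
    z_patients: np.ndarray,
    z_controls: np.ndarray,
    tail: str = "less",
    welch: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sample t statistic and p-value per edge (patients vs controls).

    Pooled-variance (Student) t by default, matching the classic NBS
    formulation; ``welch=True`` uses Welch's unequal-variance test.
    """
    if tail not in _TAILS:
        raise ValueError(f"tail must be one of {_TAILS}")
    zp = np.atleast_2d(np.asarray(z_patients, float))
    zc = np.atleast_2d(np.asarray(z_controls, float))
    n1, n2 = zp.shape[0], zc.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 subjects per group")
    if welch:
        res = stats.ttest_ind(zp, zc, axis=0, equal_var=False, alternative=tail)
        return np.asarray(res.statistic), np.asarray(res.pvalue)
    both = np.vstack([zp, zc])
    t = _pooled_t(
        zp.sum(axis=0), (zp**2).sum(axis=0), n1,
        both.sum(axis=0), (both**2).sum(axis=0), n2,
    )
    df = n1 + n2 - 2
    if tail == "less":
        p = stats.t.cdf(t, df)
    elif tail == "greater":
        p = stats.t.sf(t, df)
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p


def _edge_component_labels(i_arr, j_arr, n_nodes):
    adj = sparse.coo_matrix(
        (np.ones(len(i_arr)), (i_arr, j_arr)), shape=(n_nodes, n_nodes)
    )
    _, node_labels = csgraph.connected_components(adj, directed=False)
    return node_labels[i_arr]


def connected_components(
    edges, n_nodes: int
) -> tuple[list[np.ndarray], np.ndarray]:
    """Components of the graph formed by an edge list.

    Parameters
    ----------
    edges
        Sequence of (i, j) node pairs, or a pair of index arrays.
    n_nodes
        Size of the node set.

    Returns
    -------
    components, sizes
        ``components[k]`` holds the positions (into the input edge list)
        of the edges in component k; ``sizes[k]`` is its edge count.
        Components are ordered by decreasing size. Singleton nodes never
        appear (a component needs at least one edge).
    """
    edges = np.asarray(list(zip(*edges)) if isinstance(edges, tuple) else edges, int)
    if edges.size == 0:
        return [], np.zeros(0, int)
    i_arr, j_arr = edges[:, 0], edges[:, 1]
    labels = _edge_component_labels(i_arr, j_arr, n_nodes)
    comps = [np.flatnonzero(labels == lab) for lab in np.unique(labels)]
    comps.sort(key=len, reverse=True)
    return comps, np.array([len(c) for c in comps], int)


def _max_component_size(i_arr, j_arr, n_nodes) -> int:
    if len(i_arr) == 0:
        return 0
    labels = _edge_component_labels(i_arr, j_arr, n_nodes)
    return int(np.bincount(labels).max())


class NbsResults:
    """Container for an NBS fit; see :class:`NBS`."""

    def __init__(
        self,
        components: list[np.ndarray],
        sizes: np.ndarray,
        corrected_p: np.ndarray,
        null_max_sizes: np.ndarray,
        tstats: np.ndarray,
        pvals: np.ndarray,
        retained_edges: np.ndarray,
        n_regions: int,
        config: NbsConfig,
    ):
        #: list of edge-index arrays (global upper-triangle indices), largest first
        self.components = components
        self.sizes = sizes
        self.corrected_p = corrected_p
        self.null_max_sizes = null_max_sizes
        self.tstats = tstats
        self.pvals = pvals
        self.retained_edges = retained_edges
        self.n_regions = n_regions
        self.config = config

    @property
    def n_significant(self) -> int:
        return int(np.sum(self.corrected_p < 0.05))

    def component_table(self, atlas: pd.DataFrame | None = None) -> pd.DataFrame:
        """One row per suprathreshold edge, annotated with its component."""
        iu, ju = edge_index(self.n_regions)
        rows = []
        names = None
        if atlas is not None:
            names = atlas.set_index("region_id")["name"]
        for k, comp in enumerate(self.components):
            for e in comp:
                row = {
                    "component": k,
                    "edge": int(e),
                    "i": int(iu[e]),
                    "j": int(ju[e]),
                    "t": self.tstats[e],
                    "corrected_p": self.corrected_p[k],
                }
                if names is not None:
                    row["region_i"] = names.get(iu[e], str(iu[e]))
                    row["region_j"] = names.get(ju[e], str(ju[e]))
                rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Network-Based Statistics",
            f"  regions: {self.n_regions}, edges retained by screen: "
            f"{int(self.retained_edges.sum())}/{self.retained_edges.size}",
            f"  primary threshold p < {self.config.primary_alpha:g} "
            f"({self.config.tail}), {self.config.n_permutations} permutations",
            f"  components: {len(self.components)}",
        ]
        for k, (m, p) in enumerate(zip(self.sizes, self.corrected_p)):
            lines.append(f"    component {k}: {m} edges, corrected p = {p:.4f}")
        return "\n".join(lines)


class NBS:
    """Network-Based Statistics group comparison.

    Parameters
    ----------
    edge_matrix
        Subjects x edges matrix of Fisher-z values (upper-triangle order).
    groups
        Per-subject group label.
    n_regions
        Number of atlas regions (defines the edge -> node-pair map).
    config
        :class:`NbsConfig`; defaults match the conventional setup
        (primary p < 1e-4, one-tailed patients-below-controls, 10,000
        permutations).
    patient_label
        Which label is the patient group. Required unless one of the two
        labels is literally ``"patient"``.
    """

    def __init__(
        self,
        edge_matrix: np.ndarray,
        groups,
        n_regions: int,
        config: NbsConfig | None = None,
        patient_label=None,
    ):
        self.X = np.asarray(edge_matrix, float)
        self.groups = np.asarray(groups)
        self.n_regions = int(n_regions)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.groups):
            raise ValueError("edge_matrix must be subjects x edges, matching groups")
        if self.X.shape[1] != n_edges(self.n_regions):
            raise ValueError(
                f"expected {n_edges(self.n_regions)} edges for {self.n_regions} regions"
            )
        labels = pd.unique(self.groups)
        if len(labels) != 2:
            raise ValueError("exactly two groups required")
        if patient_label is None:
            if "patient" in labels:
                patient_label = "patient"
            else:
                raise ValueError(
                    f"patient_label must be given explicitly for labels {list(labels)}"
                )
        self.patient_label = patient_label
        self.config = config or NbsConfig()
        self._is_patient = self.groups == patient_label
        if self._is_patient.sum() < 2 or (~self._is_patient).sum() < 2:
            raise ValueError("need at least 2 subjects per group")

    def fit(self) -> NbsResults:
        cfg = self.config
        X = self.X
        S, E = X.shape
        is_pat = self._is_patient
        n1 = int(is_pat.sum())
        n2 = S - n1

        retained = prefilter_edges(
            X[is_pat], X[~is_pat], cfg.prefilter_alpha, cfg.prefilter_bonferroni
        )
        iu, ju = edge_index(self.n_regions)
        ridx = np.flatnonzero(retained)

        tstats = np.full(E, np.nan)
        pvals = np.full(E, np.nan)
        if ridx.size == 0:
            warnings.warn("screening removed all edges; no components", stacklevel=2)
            return NbsResults(
                [], np.zeros(0, int), np.zeros(0), np.zeros(cfg.n_permutations, int),
                tstats, pvals, retained, self.n_regions, cfg,
            )

        Xr = X[:, ridx]
        t_obs, p_obs = edge_tstats(Xr[is_pat], Xr[~is_pat], cfg.tail, cfg.welch)
        tstats[ridx] = t_obs
        pvals[ridx] = p_obs

        supra_local = np.flatnonzero(p_obs < cfg.primary_alpha)
        supra = ridx[supra_local]
        comps_local, sizes = connected_components(
            np.column_stack([iu[supra], ju[supra]]), self.n_regions
        )
        components = [supra[c] for c in comps_local]

        null_max = self._null_max_sizes(Xr, iu[ridx], ju[ridx], n1, n2)
        corrected = np.array(
            [(1.0 + np.sum(null_max >= m)) / (cfg.n_permutations + 1.0) for m in sizes]
        )
        return NbsResults(
            components, sizes, corrected, null_max,
            tstats, pvals, retained, self.n_regions, cfg,
        )

    # -- permutation machinery -------------------------------------------

    def _null_max_sizes(self, Xr, iu_r, ju_r, n1, n2):
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        S, Er = Xr.shape
        df = n1 + n2 - 2
        if cfg.tail == "less":
            t_crit_lo, t_crit_hi = stats.t.ppf(cfg.primary_alpha, df), np.inf
        elif cfg.tail == "greater":
            t_crit_lo, t_crit_hi = -np.inf, stats.t.isf(cfg.primary_alpha, df)
        else:
            c = stats.t.isf(cfg.primary_alpha / 2.0, df)
            t_crit_lo, t_crit_hi = -c, c

        tot = Xr.sum(axis=0)
        tot2 = (Xr**2).sum(axis=0)
        Xr2 = Xr**2
        null_max = np.zeros(cfg.n_permutations, int)
        chunk = max(1, min(cfg.n_permutations, 20_000_000 // max(Er, 1)))
        done = 0
        while done < cfg.n_permutations:
            b = min(chunk, cfg.n_permutations - done)
            ind = np.zeros((b, S))
            for r in range(b):
                ind[r, rng.choice(S, size=n1, replace=False)] = 1.0
            s1 = ind @ Xr
            q1 = ind @ Xr2
            t = _pooled_t(s1, q1, n1, tot, tot2, n2)
            if cfg.welch:
                # recompute exceedance by exact Welch p for flagged candidates
                supra_rows = [
                    np.flatnonzero(
                        stats.ttest_ind(
                            Xr[ind[r].astype(bool)], Xr[~ind[r].astype(bool)],
                            axis=0, equal_var=False, alternative=cfg.tail,
                        ).pvalue
                        < cfg.primary_alpha
                    )
                    for r in range(b)
                ]
            else:
                supra_rows = [
                    np.flatnonzero((t[r] < t_crit_lo) | (t[r] > t_crit_hi))
                    for r in range(b)
                ]
            for r, sup in enumerate(supra_rows):
                null_max[done + r] = _max_component_size(
                    iu_r[sup], ju_r[sup], self.n_regions
                )
            done += b
        return null_max
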