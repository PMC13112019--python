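"""Single-mediator path analysis with bootstrap confidence intervals.

The classic observed-variable mediation layout (PROCESS "Model 4"):

    M = i_1 + a*X            + g_1'C + e_1
    Y = i_2 + c'*X + b*M     + g_2'C + e_2
    Y = i_3 + c*X            + g_3'C + e_3

fitted by OLS with covariates C entering every equation. The indirect
effect is a*b, its 95% CI is a percentile bootstrap over subjects
(bias-corrected-and-accelerated optional), and the OLS identity
``c = c' + a*b`` holds exactly when the covariate set is shared.
Continuous variables are mean-centered before fitting.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["Mediation", "MediationResults", "fdr_adjust"]


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p_values, float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class MediationResults:
    """Path coefficients, bootstrap CI and the full-mediation flag."""

    def __init__(self, paths: pd.DataFrame, indirect: float,
                 ci: tuple[float, float], boot_draws: np.ndarray,
                 n: int, n_redrawn: int, conf_level: float):
        #: rows a, b, c_prime, total_c with estimate/se/t/p
        self.paths = paths
        self.indirect = indirect
        self.ci = ci
        self.boot_draws = boot_draws
        self.n = n
        self.n_redrawn = n_redrawn
        self.conf_level = conf_level

    def __getattr__(self, name):
        paths = self.__dict__.get("paths")
        if paths is not None and name in paths.index:
            return float(paths.loc[name, "estimate"])
        raise AttributeError(name)

    @property
    def full_mediation(self) -> bool:
        """Indirect CI excludes zero while the direct path is nonsignificant."""
        lo, hi = self.ci
        return bool((lo > 0 or hi < 0) and self.paths.loc["c_prime", "p"] >= 0.05)

    @property
    def identity_gap(self) -> float:
        """total_c - (c_prime + a*b); zero (to FP error) for shared-covariate OLS."""
        return float(
            self.paths.loc["total_c", "estimate"]
            - self.paths.loc["c_prime", "estimate"]
            - self.indirect
        )

    def summary(self) -> str:
        lines = [f"Mediation (Model 4), n = {self.n}"]
        for name, row in self.paths.iterrows():
            lines.append(
                f"  {name:8s} = {row['estimate']:+.4f} (SE {row['se']:.4f}, "
                f"p = {row['p']:.4g})"
            )
        lo, hi = self.ci
        lines.append(
            f"  indirect a*b = {self.indirect:+.4f}, "
            f"{100 * self.conf_level:.0f}% bootstrap CI [{lo:+.4f}, {hi:+.4f}]"
        )
        lines.append(f"  full mediation: {self.full_mediation}")
        return "\n".join(lines)


class Mediation:
    """Simple mediation X -> M -> Y with covariates and bootstrap CI.

    Parameters
    ----------
    x, m, y
        Exposure (e.g. hemoglobin), mediator (e.g. mean CPM-network
        connectivity) and outcome (e.g. a cognitive composite).
    covariates
        Optional n x k matrix (e.g. age, sex, brain volume), entering
        every path equation.
    n_boot
        Bootstrap resamples for the indirect-effect CI (default 1000).
    center
        Mean-center continuous variables before fitting (default True);
        binary 0/1 columns are left as they are.
    """

    def __init__(self, x, m, y, covariates=None, n_boot: int = 1000,
                 seed: int | None = None, center: bool = True,
                 conf_level: float = 0.95, method: str = "percentile"):
        x, m, y = (np.asarray(v, float) for v in (x, m, y))
        if not len(x) == len(m) == len(y):
            raise ValueError("x, m, y must have equal length")
        C = None
        if covariates is not None and np.size(covariates) > 0:
            C = np.asarray(covariates, float)
            if C.ndim == 1:
                C = C[:, None]
            if C.shape[0] != len(x):
                raise ValueError("covariates must have one row per subject")
        keep = np.isfinite(x) & np.isfinite(m) & np.isfinite(y)
        if C is not None:
            keep &= np.all(np.isfinite(C), axis=1)
        if keep.sum() < len(x):
            warnings.warn(f"listwise deletion dropped {len(x) - keep.sum()} row(s)",
                          stacklevel=2)
        self.x, self.m, self.y = x[keep], m[keep], y[keep]
        self.C = C[keep] if C is not None else None
        k = 0 if self.C is None else self.C.shape[1]
        if len(self.x) <= k + 3:
            raise ValueError("too few observations for the requested design")
        if method not in ("percentile", "bca"):
            raise ValueError("method must be 'percentile' or 'bca'")
        self.n_boot = int(n_boot)
        self.seed = seed
        self.center = center
        self.conf_level = conf_level
        self.method = method

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _center(v: np.ndarray) -> np.ndarray:
        vals = np.unique(v)
        if vals.size <= 2 and np.isin(vals, (0.0, 1.0)).all():
            return v  # leave binary indicators alone
        return v - v.mean()

    def _designs(self):
        x = self._center(self.x) if self.center else self.x
        m = self._center(self.m) if self.center else self.m
        y = self._center(self.y) if self.center else self.y
        if self.C is not None:
            C = (np.column_stack([self._center(c) for c in self.C.T])
                 if self.center else self.C)
        else:
            C = np.empty((len(x), 0))
        n = len(x)
        ones = np.ones(n)
        Zm = np.column_stack([ones, x, C])          # M ~ X + C
        Zy = np.column_stack([ones, x, m, C])       # Y ~ X + M + C
        Zt = Zm                                     # Y ~ X + C
        for name, Z in (("M ~ X + C", Zm), ("Y ~ X + M + C", Zy)):
            if np.linalg.matrix_rank(Z) < Z.shape[1]:
                raise ValueError(f"collinear design in {name}")
        return x, m, y, Zm, Zy, Zt

    @staticmethod
    def _ols(Z, v, coef_names):
        fit = sm.OLS(v, Z).fit()
        rows = {}
        for idx, nm in coef_names.items():
            rows[nm] = {
                "estimate": fit.params[idx],
                "se": fit.bse[idx],
                "t": fit.tvalues[idx],
                "p": fit.pvalues[idx],
            }
        return rows

    # -- estimation --------------------------------------------------------

    def fit(self) -> MediationResults:
        x, m, y, Zm, Zy, Zt = self._designs()
        rows = {}
        rows.update(self._ols(Zm, m, {1: "a"}))
        rows.update(self._ols(Zy, y, {2: "b", 1: "c_prime"}))
        out = self._ols(Zt, y, {1: "total_c"})
        rows.update(out)
        paths = pd.DataFrame(rows).T[["estimate", "se", "t", "p"]]
        indirect = float(paths.loc["a", "estimate"] * paths.loc["b", "estimate"])

        draws, n_redrawn = self._bootstrap(x, m, y, Zm, Zy)
        alpha = 1.0 - self.conf_level
        if self.method == "bca":
            ci = self._bca_ci(draws, indirect, x, m, y, Zm, Zy, alpha)
        else:
            ci = tuple(np.quantile(draws, [alpha / 2, 1 - alpha / 2]))
        return MediationResults(paths, indirect, ci, draws, len(x),
                                n_redrawn, self.conf_level)

    @staticmethod
    def _ab_batch(idx, x_dummy, m, y, Zm, Zy):
        """Indirect-effect draws for a batch of resample index rows."""
        Zm_b = Zm[idx]                      # B x n x km
        Zy_b = Zy[idx]
        m_b = m[idx]
        y_b = y[idx]
        # pinv-based batched OLS: tolerant of resamples where a covariate
        # happens to be constant (minimum-norm solution)
        a = np.einsum("bkn,bn->bk", np.linalg.pinv(Zm_b), m_b)[:, 1]
        b = np.einsum("bkn,bn->bk", np.linalg.pinv(Zy_b), y_b)[:, 2]
        return a * b

    def _bootstrap(self, x, m, y, Zm, Zy):
        rng = np.random.default_rng(self.seed)
        n = len(x)
        draws = np.empty(self.n_boot)
        filled = 0
        n_redrawn = 0
        while filled < self.n_boot:
            B = self.n_boot - filled
            idx = rng.integers(0, n, size=(B, n))
            # degenerate resamples (constant exposure or mediator) are redrawn
            ok = (np.ptp(x[idx], axis=1) > 0) & (np.ptp(m[idx], axis=1) > 0)
            n_redrawn += int(np.sum(~ok))
            idx = idx[ok]
            if len(idx) == 0:
                continue
            draws[filled:filled + len(idx)] = self._ab_batch(idx, x, m, y, Zm, Zy)
            filled += len(idx)
        if n_redrawn > 0.01 * self.n_boot:
            warnings.warn(
                f"{n_redrawn} degenerate bootstrap resamples were redrawn",
                stacklevel=2,
            )
        return draws, n_redrawn

    def _bca_ci(self, draws, est, x, m, y, Zm, Zy, alpha):
        n = len(x)
        # jackknife for the acceleration constant
        jack = np.empty(n)
        all_idx = np.arange(n)
        for i in range(n):
            idx = np.delete(all_idx, i)[None, :]
            jack[i] = self._ab_batch(idx, x, m, y, Zm, Zy)[0]
        jm = jack.mean()
        num = ((jm - jack) ** 3).sum()
        den = 6.0 * (((jm - jack) ** 2).sum()) ** 1.5
        a_acc = num / den if den > 0 else 0.0
        z0 = stats.norm.ppf(np.clip(np.mean(draws < est), 1e-6, 1 - 1e-6))
        zlo, zhi = stats.norm.ppf([alpha / 2, 1 - alpha / 2])
        lo = stats.norm.cdf(z0 + (z0 + zlo) / (1 - a_acc * (z0 + zlo)))
        hi = stats.norm.cdf(z0 + (z0 + zhi) / (1 - a_acc * (z0 + zhi)))
        return tuple(np.quantile(draws, [lo, hi]))
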