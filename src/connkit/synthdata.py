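"""Synthetic connectome cohorts with recorded ground truth.

Generates a two-group cohort (patients / controls) whose statistical
structure matches what the downstream analyses assume, with every
planted effect recorded so recovery can be tested:

* a control connectivity profile with edge-wise Fisher-z means around
  0.3 (sd 0.15), built from a low-rank factor model so implied
  correlation matrices are positive semidefinite by construction;
* a *disrupted component*: a set of edges whose patient-group mean is
  lowered by a fixed z-delta (the target for group comparison);
* a *behaviour network*: a set of edges sharing a per-subject network
  integrity factor; the behavioural score is linear in the summed
  strength of these edges (the target for predictive modeling);
* patient-only haematology (hemoglobin, red-cell distribution width)
  whose effect on behaviour is routed through the behaviour network
  (the target for mediation analysis).

Two routes are provided: a direct z-matrix route (fast; used for large
simulation studies) and a time-series route producing BOLD-like AR(1)
regional series so that detrending/filtering has realistic input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fc
from .fc import edge_index, n_edges

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "UnsupportedOperationError",
    "generate_matrix_cohort",
    "generate_timeseries_cohort",
    "generate_behavior",
    "generate_hematology",
    "generate_cohort",
    "planted_component",
]

# Patient haematology moments (g/L for hemoglobin; RDW units carried as
# metadata only, the source tabulations disagree on them).
HEMOGLOBIN_MEAN, HEMOGLOBIN_SD = 104.28, 13.31
RDW_MEAN, RDW_SD = 42.06, 9.21
#: correlation between hemoglobin and RDW in patients (anaemia severity axis)
_HB_RDW_RHO = -0.8
#: z-space tolerance for planted edge edits after PSD projection
_EDIT_TOL = 0.1


class UnsupportedOperationError(RuntimeError):
    """Raised when an operation is requested for a group it is not defined on."""


@dataclass
class CohortSpec:
    """Ground-truth parameters of a synthetic cohort.

    Effect parameters (``disruption_delta``, ``behavior_slope``, the
    mediation paths) are in z-units, score units per z-unit, and
    standardised path units respectively. ``mediation_c_prime = 0``
    plants full mediation.
    """

    n_patients: int = 25
    n_controls: int = 35
    n_regions: int = 116
    n_timepoints: int = 120
    disrupted_edges: tuple[int, ...] = ()
    disruption_delta: float = 0.6
    behavior_edges: tuple[int, ...] = ()
    behavior_slope: float = 2.0
    behavior_intercept: float = 90.0
    noise_sd_behavior: float = 5.0
    mediation_a: float = 0.85
    mediation_b: float = 0.9
    mediation_c_prime: float = 0.0
    seed: int = 0
    # generator conventions (see docs/methods.md)
    control_mean_z: float = 0.3
    control_sd_z: float = 0.15
    subject_sd: float = 0.2
    network_factor_sd: float = 0.2
    ar_rho: float = 0.3

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_controls", "n_regions", "n_timepoints"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd_behavior < 0:
            raise ValueError("noise_sd_behavior must be non-negative")
        E = n_edges(self.n_regions)
        self.disrupted_edges = tuple(sorted(int(e) for e in self.disrupted_edges))
        self.behavior_edges = tuple(sorted(int(e) for e in self.behavior_edges))
        for name in ("disrupted_edges", "behavior_edges"):
            edges = getattr(self, name)
            if edges and (min(edges) < 0 or max(edges) >= E):
                raise ValueError(f"{name} must lie in [0, {E})")

    @property
    def n_subjects(self) -> int:
        return self.n_patients + self.n_controls

    @property
    def n_edges(self) -> int:
        return n_edges(self.n_regions)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["disrupted_edges"] = list(d["disrupted_edges"])
        d["behavior_edges"] = list(d["behavior_edges"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "CohortSpec":
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class SyntheticCohort:
    """A generated cohort: data, manifest and the spec that produced it."""

    manifest: pd.DataFrame
    ground_truth: CohortSpec
    z_matrices: np.ndarray | None = None      # S x N x N
    timeseries: np.ndarray | None = None      # S x T x N
    edge_means: dict = field(default_factory=dict)  # group -> E-vector (matrix route)
    base_R: dict = field(default_factory=dict)      # group -> N x N (time-series route)
    factors: np.ndarray | None = None
    _rng: np.random.Generator | None = field(default=None, repr=False)
    _edge_cache: np.ndarray | None = field(default=None, repr=False)

    @property
    def groups(self) -> np.ndarray:
        return self.manifest["group"].to_numpy()

    @property
    def is_patient(self) -> np.ndarray:
        return self.groups == "patient"

    def rng(self, seed: int | None = None) -> np.random.Generator:
        """The cohort's RNG stream (or a fresh one for an explicit seed)."""
        if seed is not None:
            return np.random.default_rng(seed)
        if self._rng is None:
            self._rng = np.random.default_rng(self.ground_truth.seed)
        return self._rng

    def edge_matrix(self, refresh: bool = False) -> np.ndarray:
        """Subjects x edges Fisher-z matrix (computed from series if needed)."""
        if self._edge_cache is not None and not refresh:
            return self._edge_cache
        iu, ju = edge_index(self.ground_truth.n_regions)
        if self.z_matrices is not None:
            X = self.z_matrices[:, iu, ju]
        elif self.timeseries is not None:
            mats = [
                fc.correlation_matrix(fc.RoiTimeSeries(ts)).z
                for ts in self.timeseries
            ]
            X = np.stack(mats)[:, iu, ju]
        else:
            raise ValueError("cohort holds neither matrices nor time series")
        self._edge_cache = X
        return X

    # -- persistence -------------------------------------------------------

    def save(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.manifest.to_csv(out / "manifest.csv", index=False)
        (out / "ground_truth.yaml").write_text(self.ground_truth.to_yaml())
        if self.z_matrices is not None:
            mdir = out / "matrices"
            mdir.mkdir(exist_ok=True)
            for sid, z in zip(self.manifest["subject_id"], self.z_matrices):
                np.savetxt(mdir / f"{sid}.tsv", z, delimiter="\t")
        if self.timeseries is not None:
            tdir = out / "timeseries"
            tdir.mkdir(exist_ok=True)
            for sid, ts in zip(self.manifest["subject_id"], self.timeseries):
                np.savetxt(tdir / f"{sid}.tsv", ts, delimiter="\t")
        return out

    @classmethod
    def load(cls, in_dir) -> "SyntheticCohort":
        src = Path(in_dir)
        manifest = pd.read_csv(src / "manifest.csv")
        spec = CohortSpec.from_yaml((src / "ground_truth.yaml").read_text())
        z = ts = None
        if (src / "matrices").is_dir():
            z = np.stack([
                np.loadtxt(src / "matrices" / f"{sid}.tsv", delimiter="\t")
                for sid in manifest["subject_id"]
            ])
        if (src / "timeseries").is_dir():
            ts = np.stack([
                np.loadtxt(src / "timeseries" / f"{sid}.tsv", delimiter="\t")
                for sid in manifest["subject_id"]
            ])
        return cls(manifest, spec, z_matrices=z, timeseries=ts)


# ---------------------------------------------------------------------------
# helpers

def planted_component(
    n_regions: int, n_component_edges: int, offset: int = 0
) -> tuple[int, ...]:
    """Edge indices of a connected planted component.

    Builds a chain over consecutive nodes plus chords until the requested
    edge count is reached; useful for seeding ``disrupted_edges``.
    """
    iu, ju = edge_index(n_regions)
    lut = {(int(a), int(b)): e for e, (a, b) in enumerate(zip(iu, ju))}
    edges: list[int] = []
    nodes = list(range(offset, n_regions))
    span = 2
    while len(edges) < n_component_edges:
        added = False
        for i in nodes:
            j = i + span - 1
            if j >= n_regions:
                break
            edges.append(lut[(i, j)])
            added = True
            if len(edges) == n_component_edges:
                break
        span += 1
        if not added:
            raise ValueError("component larger than the graph allows")
    return tuple(sorted(edges))


def _manifest(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    S = spec.n_subjects
    groups = ["patient"] * spec.n_patients + ["control"] * spec.n_controls
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i:03d}" for i in range(S)],
            "group": groups,
            "wis": np.nan,
            "age": rng.uniform(6.3, 15.1, S).round(2),
            "sex": rng.integers(0, 2, S),
            "brain_volume": rng.normal(0.0, 1.0, S).round(4),
            "hemoglobin": np.nan,
            "rdw": np.nan,
        }
    )


def _edges_to_matrices(spec: CohortSpec, X: np.ndarray) -> np.ndarray:
    iu, ju = edge_index(spec.n_regions)
    S = X.shape[0]
    Z = np.zeros((S, spec.n_regions, spec.n_regions))
    Z[:, iu, ju] = X
    Z += np.transpose(Z, (0, 2, 1))
    return Z


def _subject_edges(
    spec: CohortSpec, mean_vec: np.ndarray, f: float, rng: np.random.Generator
) -> np.ndarray:
    z = mean_vec + rng.normal(0.0, spec.subject_sd, spec.n_edges)
    if spec.behavior_edges:
        z[list(spec.behavior_edges)] += spec.network_factor_sd * f
    return z


# ---------------------------------------------------------------------------
# matrix route

def generate_matrix_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate per-subject Fisher-z matrices directly.

    Each subject's edge vector is the group mean profile plus iid edge
    noise plus (on behaviour edges) a shared network-integrity factor.
    Matrices are exactly symmetric with zero diagonal.
    """
    rng = np.random.default_rng(spec.seed)
    manifest = _manifest(spec, rng)
    z0 = rng.normal(spec.control_mean_z, spec.control_sd_z, spec.n_edges)
    zp = z0.copy()
    if spec.disrupted_edges:
        zp[list(spec.disrupted_edges)] -= spec.disruption_delta
    factors = rng.normal(0.0, 1.0, spec.n_subjects)
    X = np.empty((spec.n_subjects, spec.n_edges))
    for s in range(spec.n_subjects):
        mean_vec = zp if s < spec.n_patients else z0
        X[s] = _subject_edges(spec, mean_vec, factors[s], rng)
    cohort = SyntheticCohort(
        manifest, spec,
        z_matrices=_edges_to_matrices(spec, X),
        edge_means={"patient": zp, "control": z0},
        factors=factors,
        _rng=rng,
    )
    cohort._edge_cache = X
    return cohort


# ---------------------------------------------------------------------------
# time-series route

def _nearest_psd_corr(R: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Higham-style projection: clip eigenvalues, restore unit diagonal."""
    w, V = np.linalg.eigh((R + R.T) / 2.0)
    w = np.clip(w, floor, None)
    A = (V * w) @ V.T
    d = np.sqrt(np.diag(A))
    A = A / np.outer(d, d)
    np.fill_diagonal(A, 1.0)
    return (A + A.T) / 2.0


def _factor_base_corr(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """PSD control correlation matrix with edge z-values ~ (mean 0.3, sd 0.15).

    Low-rank loading construction: every region loads on a shared
    direction (setting the mean correlation) plus random factors
    (setting the spread); loading norms are capped so |r| < 1.
    """
    k = 6
    alpha = np.sqrt(np.tanh(spec.control_mean_z))
    s = 0.177 * (spec.control_sd_z / 0.15)
    B = rng.normal(0.0, s, size=(spec.n_regions, k))
    B[:, 0] += alpha
    nrm = np.linalg.norm(B, axis=1)
    B *= np.minimum(1.0, 0.85 / nrm)[:, None]
    R = B @ B.T
    np.fill_diagonal(R, 1.0)
    return R


def _apply_edge_edits(
    R: np.ndarray, edit_edges: np.ndarray, target_r: np.ndarray,
    n_iter: int = 100, tol: float = _EDIT_TOL,
) -> np.ndarray:
    """Plant correlation targets on selected edges, staying PSD.

    Alternating projection between the PSD cone and the affine set fixing
    the edited entries; the final matrix is PSD and a fidelity check
    rejects edits the cone cannot accommodate.
    """
    iu, ju = edge_index(R.shape[0])
    ei, ej = iu[edit_edges], ju[edit_edges]
    out = R.copy()
    out[ei, ej] = out[ej, ei] = target_r
    for _ in range(n_iter):
        out = _nearest_psd_corr(out)
        out[ei, ej] = out[ej, ei] = target_r
    out = _nearest_psd_corr(out)
    achieved = np.arctanh(np.clip(out[ei, ej], -0.999999, 0.999999))
    requested = np.arctanh(np.clip(target_r, -0.999999, 0.999999))
    dev = np.abs(achieved - requested)
    if np.max(dev) > tol:
        worst = np.argsort(dev)[::-1][:5]
        pairs = [(int(ei[w]), int(ej[w]), float(dev[w])) for w in worst]
        raise ValueError(
            "requested edge edits are infeasible for a positive semidefinite "
            f"correlation matrix; worst offending edges (i, j, |z error|): {pairs}"
        )
    return out


def _sample_ar1(
    R: np.ndarray, T: int, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) series (T x N) with cross-correlation R."""
    L = np.linalg.cholesky(R + 1e-10 * np.eye(len(R)))
    N = len(R)
    u = np.empty((T, N))
    u[0] = rng.normal(size=N)
    innov_sd = np.sqrt(1.0 - rho**2)
    eps = rng.normal(size=(T - 1, N)) * innov_sd
    for t in range(1, T):
        u[t] = rho * u[t - 1] + eps[t - 1]
    return u @ L.T


def generate_timeseries_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate BOLD-like regional time series per subject.

    Group-level target correlation matrices are built from a PSD factor
    model; planted disruptions are imposed by alternating projection
    (infeasible edits raise, naming the offending edges). Each subject's
    series is a stationary AR(1) process (temporal autocorrelation 0.3)
    with the subject's target cross-correlation, so that the implied
    Fisher-z difference on disrupted edges approximates the planted
    delta.
    """
    rng = np.random.default_rng(spec.seed)
    manifest = _manifest(spec, rng)
    iu, ju = edge_index(spec.n_regions)

    R_control = _nearest_psd_corr(_factor_base_corr(spec, rng))
    z_control = np.arctanh(np.clip(R_control[iu, ju], -0.999999, 0.999999))
    if spec.disrupted_edges:
        edit = np.asarray(spec.disrupted_edges, int)
        target = np.tanh(z_control[edit] - spec.disruption_delta)
        R_patient = _apply_edge_edits(R_control, edit, target)
    else:
        R_patient = R_control
    factors = rng.normal(0.0, 1.0, spec.n_subjects)
    series = np.empty((spec.n_subjects, spec.n_timepoints, spec.n_regions))
    for s in range(spec.n_subjects):
        R = R_patient if s < spec.n_patients else R_control
        if spec.behavior_edges:
            be = np.asarray(spec.behavior_edges, int)
            z = np.arctanh(np.clip(R[iu, ju], -0.999999, 0.999999))
            z[be] = z[be] + spec.network_factor_sd * factors[s]
            Rs = np.eye(spec.n_regions)
            Rs[iu, ju] = np.tanh(z)
            Rs += Rs.T
            np.fill_diagonal(Rs, 1.0)
            R = _nearest_psd_corr(Rs)
        series[s] = _sample_ar1(R, spec.n_timepoints, spec.ar_rho, rng)
    return SyntheticCohort(
        manifest, spec,
        timeseries=series,
        base_R={"patient": R_patient, "control": R_control},
        factors=factors,
        _rng=rng,
    )


# ---------------------------------------------------------------------------
# behaviour and haematology

def generate_behavior(
    spec: CohortSpec, cohort: SyntheticCohort, seed: int | None = None
) -> SyntheticCohort:
    """Attach a behavioural score linear in behaviour-network strength.

    ``wis = intercept + slope * sum(z over behavior_edges) + noise``.
    With an empty behaviour-edge set the score is pure noise around the
    intercept (the null design).
    """
    rng = cohort.rng(seed)
    X = cohort.edge_matrix()
    strength = (
        X[:, list(spec.behavior_edges)].sum(axis=1)
        if spec.behavior_edges
        else np.zeros(len(X))
    )
    noise = (
        rng.normal(0.0, spec.noise_sd_behavior, len(X))
        if spec.noise_sd_behavior > 0
        else 0.0
    )
    cohort.manifest["wis"] = (
        spec.behavior_intercept + spec.behavior_slope * strength + noise
    )
    return cohort


def generate_hematology(
    spec: CohortSpec,
    cohort: SyntheticCohort,
    seed: int | None = None,
    group: str = "patient",
) -> SyntheticCohort:
    """Attach patient haematology and plant the mediation pathway.

    Hemoglobin is drawn near the reference patient moments
    (104.28 +/- 13.31 g/L); RDW is strongly anti-correlated with it.
    The patients' network-integrity factor is regenerated as
    ``a * hb_std + sqrt(1 - a^2) * noise``, behaviour-network edges are
    refreshed accordingly, and the patients' behavioural score becomes
    ``b * strength_std + c' * hb_std + noise`` (re-expressed on the
    score scale), so with ``c' = 0`` the haematology -> cognition effect
    is fully mediated by connectivity.

    Haematology is defined for patients only; asking for controls raises
    :class:`UnsupportedOperationError`.
    """
    if group != "patient":
        raise UnsupportedOperationError(
            "haematological metrics are measured in patients only"
        )
    if not spec.behavior_edges:
        raise ValueError("mediation pathway needs a non-empty behaviour-edge set")
    if cohort.manifest["wis"].isna().all():
        raise ValueError("generate_behavior must run before generate_hematology")
    rng = cohort.rng(seed)
    is_pat = cohort.is_patient
    n_pat = int(is_pat.sum())
    be = np.asarray(spec.behavior_edges, int)

    hb = rng.normal(HEMOGLOBIN_MEAN, HEMOGLOBIN_SD, n_pat)
    hb_std = (hb - hb.mean()) / hb.std()
    rdw_std = _HB_RDW_RHO * hb_std + np.sqrt(1 - _HB_RDW_RHO**2) * rng.normal(
        size=n_pat
    )
    rdw = RDW_MEAN + RDW_SD * rdw_std

    a = spec.mediation_a
    f_new = a * hb_std + np.sqrt(max(0.0, 1.0 - a**2)) * rng.normal(size=n_pat)

    # refresh patients' behaviour-network edges under the new factor
    X = cohort.edge_matrix()
    pat_idx = np.flatnonzero(is_pat)
    if cohort.edge_means:
        mean_be = cohort.edge_means["patient"][be]
    elif cohort.base_R:
        iu, ju = edge_index(spec.n_regions)
        zfull = np.arctanh(
            np.clip(cohort.base_R["patient"][iu, ju], -0.999999, 0.999999)
        )
        mean_be = zfull[be]
    else:
        mean_be = X[pat_idx][:, be].mean(axis=0)
    for s, f in zip(pat_idx, f_new):
        X[s, be] = (
            mean_be
            + spec.network_factor_sd * f
            + rng.normal(0.0, spec.subject_sd, len(be))
        )
    if cohort.factors is not None:
        cohort.factors[pat_idx] = f_new
    if cohort.z_matrices is not None:
        cohort.z_matrices = _edges_to_matrices(spec, X)
    elif cohort.timeseries is not None:
        # redraw patient series under the regenerated factor
        iu, ju = edge_index(spec.n_regions)
        for s, f in zip(pat_idx, f_new):
            z = np.arctanh(
                np.clip(cohort.base_R["patient"][iu, ju], -0.999999, 0.999999)
            )
            z[be] = z[be] + spec.network_factor_sd * f
            Rs = np.eye(spec.n_regions)
            Rs[iu, ju] = np.tanh(z)
            Rs += Rs.T
            np.fill_diagonal(Rs, 1.0)
            cohort.timeseries[s] = _sample_ar1(
                _nearest_psd_corr(Rs), spec.n_timepoints, spec.ar_rho, rng
            )
        cohort.edge_matrix(refresh=True)
        X = cohort.edge_matrix()
    cohort._edge_cache = X

    # rebuild the patients' behavioural score on standardised paths
    strength = X[pat_idx][:, be].mean(axis=1)
    m_std = (strength - strength.mean()) / strength.std()
    b, cp = spec.mediation_b, spec.mediation_c_prime
    resid_sd = np.sqrt(max(0.05, 1.0 - b**2 - cp**2 - 2 * a * b * cp))
    y_std = b * m_std + cp * hb_std + resid_sd * rng.normal(size=n_pat)
    wis = cohort.manifest["wis"].to_numpy(float)
    wis[pat_idx] = 71.57 + 16.25 * y_std
    cohort.manifest["wis"] = wis
    cohort.manifest.loc[pat_idx, "hemoglobin"] = np.round(hb, 2)
    cohort.manifest.loc[pat_idx, "rdw"] = np.round(rdw, 2)
    return cohort


def generate_cohort(
    spec: CohortSpec, route: str = "matrix", hematology: bool = True
) -> SyntheticCohort:
    """Convenience wrapper: cohort + behaviour (+ haematology) in one call."""
    if route == "matrix":
        cohort = generate_matrix_cohort(spec)
    elif route == "timeseries":
        cohort = generate_timeseries_cohort(spec)
    else:
        raise ValueError("route must be 'matrix' or 'timeseries'")
    generate_behavior(spec, cohort)
    if hematology and spec.behavior_edges:
        generate_hematology(spec, cohort)
    return cohort
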