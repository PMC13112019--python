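"""End-to-end orchestration: cohort -> FC -> NBS -> CPM -> mediation.

`run_all` executes the stages in order against either a synthetic cohort
(generated from the config's cohort block) or user-supplied data, writes
flat per-stage outputs (TSV/CSV/JSON) into the run directory, and records
a machine-readable run manifest (package version, seeds, config hash) so
a rerun with the same seed is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .atlas import load_atlas
from .cpm import CPM, CpmConfig, degree_table, groupwise_evaluation, network_strength
from .fc import RoiTimeSeries, clean_timeseries, correlation_matrix, edge_index
from .mediation import Mediation, fdr_adjust
from .nbs import NBS, NbsConfig
from .synthdata import CohortSpec, SyntheticCohort, generate_cohort

__all__ = [
    "RunConfig",
    "group_compare_behavior",
    "group_compare_from_stats",
    "run_all",
]

_REQUIRED_MANIFEST = ("subject_id", "group", "wis")


@dataclass
class RunConfig:
    """Configuration for an end-to-end run (YAML-loadable)."""

    out_dir: str = "connkit_run"
    seed: int = 0
    cohort: dict = field(default_factory=dict)     # CohortSpec kwargs or {"path": dir}
    route: str = "matrix"                          # "matrix" | "timeseries"
    band: tuple[float, float] = (0.01, 0.08)
    nbs: dict = field(default_factory=dict)        # NbsConfig kwargs
    cpm: dict = field(default_factory=dict)        # CpmConfig kwargs
    mediation: dict = field(default_factory=dict)  # n_boot, exposures

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if "path" in cfg.cohort and not Path(cfg.cohort["path"]).exists():
            raise FileNotFoundError(f"cohort path {cfg.cohort['path']} does not exist")
        return cfg

    def to_dict(self) -> dict:
        return {
            "out_dir": self.out_dir,
            "seed": self.seed,
            "cohort": self.cohort,
            "route": self.route,
            "band": list(self.band),
            "nbs": self.nbs,
            "cpm": self.cpm,
            "mediation": self.mediation,
        }

    def config_hash(self) -> str:
        # identity of the analysis, not of the output location
        d = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def group_compare_behavior(
    manifest: pd.DataFrame,
    behavior_col: str = "wis",
    group_col: str = "group",
) -> dict:
    """Welch two-sample t-test of the behavioural score between groups."""
    if behavior_col not in manifest.columns:
        raise ValueError(f"manifest lacks a {behavior_col!r} column")
    labels = pd.unique(manifest[group_col])
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    a = manifest.loc[manifest[group_col] == labels[0], behavior_col].dropna()
    b = manifest.loc[manifest[group_col] == labels[1], behavior_col].dropna()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 subjects per group")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {
        "t": float(t),
        "p": float(p),
        "groups": {
            str(labels[0]): {"n": len(a), "mean": float(a.mean()), "sd": float(a.std())},
            str(labels[1]): {"n": len(b), "mean": float(b.mean()), "sd": float(b.std())},
        },
    }


def group_compare_from_stats(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float
) -> tuple[float, float]:
    """Welch t-test from published summary statistics alone.

    Lets printed group tables (n, mean, sd) be audited without raw data.
    """
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=False
    )
    return float(res.statistic), float(res.pvalue)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]


def _validate_manifest(manifest: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED_MANIFEST if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest is missing required column(s): {missing}")


def run_all(config: RunConfig) -> Path:
    """Execute every stage and return the run directory.

    Stages: cohort (load or generate) -> connectivity -> behavioural
    group comparison -> NBS -> CPM (+ degree table, group-wise
    evaluation) -> mediation (patients only, one model per exposure).
    Any stage failure propagates with the stage name in the message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 4)
    stage = "cohort"
    try:
        if "path" in config.cohort:
            cohort = SyntheticCohort.load(config.cohort["path"])
        else:
            spec_kwargs = dict(config.cohort)
            spec_kwargs.setdefault("seed", seeds[0])
            spec = CohortSpec(**spec_kwargs)
            cohort = generate_cohort(spec, route=config.route)
        _validate_manifest(cohort.manifest)
        cohort.manifest.to_csv(out / "manifest.csv", index=False)

        stage = "connectivity"
        spec = cohort.ground_truth
        if cohort.timeseries is not None:
            mats = []
            for ts in cohort.timeseries:
                cleaned = clean_timeseries(RoiTimeSeries(ts), band=config.band)
                mats.append(correlation_matrix(cleaned).z)
            iu, ju = edge_index(spec.n_regions)
            X = np.stack(mats)[:, iu, ju]
        else:
            X = cohort.edge_matrix()
        np.savetxt(out / "edge_matrix.tsv", X, delimiter="\t")

        stage = "group comparison"
        behav = group_compare_behavior(cohort.manifest)
        (out / "behavior_summary.json").write_text(json.dumps(behav, indent=2))

        stage = "nbs"
        nbs_cfg = NbsConfig(**{"seed": seeds[1], **config.nbs})
        nbs_res = NBS(X, cohort.groups, spec.n_regions, nbs_cfg).fit()
        atlas = load_atlas() if spec.n_regions == 116 else None
        nbs_res.component_table(atlas).to_csv(out / "nbs_components.tsv",
                                              sep="\t", index=False)
        np.savetxt(out / "nbs_null_max_sizes.tsv", nbs_res.null_max_sizes, fmt="%d")
        (out / "nbs_summary.json").write_text(json.dumps({
            "sizes": nbs_res.sizes.tolist(),
            "corrected_p": nbs_res.corrected_p.tolist(),
            "n_retained_edges": int(nbs_res.retained_edges.sum()),
            "config": {**nbs_cfg.__dict__},
        }, indent=2))

        stage = "cpm"
        y = cohort.manifest["wis"].to_numpy(float)
        cpm_cfg = CpmConfig(**{"seed": seeds[2], **config.cpm})
        model = CPM(X, y, cpm_cfg, groups=cohort.groups, n_regions=spec.n_regions)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cpm_res = model.fit()
            perm_p = model.permutation_test(cpm_res)
        deg = degree_table(cpm_res.consensus_positive, spec.n_regions, atlas)
        deg.to_csv(out / "cpm_degree_table.csv", index=False)
        preds = cpm_res.predictions.copy()
        preds.insert(0, "subject_id", cohort.manifest["subject_id"])
        preds["observed"] = y
        preds.to_csv(out / "cpm_predictions.csv", index=False)
        strengths = network_strength(X, cpm_res.consensus_positive)
        gw = groupwise_evaluation(strengths, y, cohort.groups)
        (out / "cpm_summary.json").write_text(json.dumps({
            "consensus_positive_edges": cpm_res.consensus_positive.tolist(),
            "consensus_negative_edges": cpm_res.consensus_negative.tolist(),
            "r": {m: cpm_res.performance(m) for m in ("positive", "negative", "combined")},
            "permutation_p": perm_p,
            "groupwise": gw.to_dict(orient="records"),
            "config": {**cpm_cfg.__dict__},
        }, indent=2))

        stage = "mediation"
        med_summary = {}
        pat = cohort.manifest[cohort.is_patient]
        if (
            pat["hemoglobin"].notna().any()
            and len(cpm_res.consensus_positive) > 0
        ):
            m_vals = X[cohort.is_patient][:, cpm_res.consensus_positive].mean(axis=1)
            covs = pat[["age", "sex", "brain_volume"]].to_numpy(float)
            n_boot = int(config.mediation.get("n_boot", 1000))
            exposures = config.mediation.get("exposures", ["hemoglobin", "rdw"])
            rows = []
            for i, exp_col in enumerate(exposures):
                med = Mediation(
                    pat[exp_col].to_numpy(float), m_vals,
                    pat["wis"].to_numpy(float), covariates=covs,
                    n_boot=n_boot, seed=seeds[3] + i,
                ).fit()
                med_summary[exp_col] = {
                    "paths": med.paths.to_dict(orient="index"),
                    "indirect": med.indirect,
                    "ci": list(med.ci),
                    "full_mediation": med.full_mediation,
                }
                rows.append({"exposure": exp_col,
                             "p_indirect_proxy": med.paths.loc["a", "p"]})
            fam = pd.DataFrame(rows)
            fam["p_fdr"] = fdr_adjust(fam["p_indirect_proxy"].to_numpy())
            med_summary["fdr_family"] = fam.to_dict(orient="records")
        (out / "mediation_summary.json").write_text(json.dumps(med_summary, indent=2))

        stage = "manifest"
        (out / "run_manifest.json").write_text(json.dumps({
            "package_version": __version__,
            "seed": config.seed,
            "stage_seeds": seeds,
            "config_hash": config.config_hash(),
            "config": config.to_dict(),
        }, indent=2))
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    return out
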