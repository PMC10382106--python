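"""End-to-end orchestration: simulate/load -> fit -> score -> analyse.

`run_full_analysis` reproduces the full analysis flow on one configuration:
normative curves are fitted to the normative cohort, every surgical scan is
scored against them, pre/post scores become Z-slope trajectories, extreme
deviations are counted at the configured thresholds, and the clinical
association battery is run family-by-family with BH FDR correction inside
each 13-region family.  Identical configuration and seed give byte-identical
output bundles.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigurationError
from .io import read_covariate_table, read_scan_table
from .normative import NormativeAtlas
from .regions import MODELLED_REGIONS
from .simulate import simulate_chd, simulate_normative
from .stats import bh_fdr, spearman
from .trajectories import DEFAULT_THRESHOLDS, build_trajectories, census, scan_census
from .stats import run_region_family

__all__ = ["RunConfig", "ReportBundle", "run_full_analysis", "write_bundle", "bundle_digest"]


@dataclass
class RunConfig:
    """Configuration of one reproducible analysis run."""

    seed: int = 0
    n_normative: int = 219
    n_chd: int = 36
    thresholds: tuple = DEFAULT_THRESHOLDS
    fdr_alpha: float = 0.05
    regions: tuple = MODELLED_REGIONS
    n_restarts: int = 4
    strict_range: bool = False
    normative_path: str | None = None
    chd_path: str | None = None
    covariate_path: str | None = None

    def __post_init__(self):
        taus = tuple(self.thresholds)
        if any(t <= 0 for t in taus) or list(taus) != sorted(taus):
            raise ConfigurationError("thresholds must be positive and ascending")
        if not 0 < self.fdr_alpha < 1:
            raise ConfigurationError("fdr_alpha must lie in (0, 1)")
        self.thresholds = taus
        self.regions = tuple(self.regions)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class ReportBundle:
    """All artifacts of one run, each traceable through the provenance block."""

    normative_scans: pd.DataFrame
    chd_scans: pd.DataFrame
    covariates: pd.DataFrame
    scores: pd.DataFrame
    trajectories: pd.DataFrame
    census: dict
    scan_flags: dict
    families: dict = field(default_factory=dict)
    model_summary: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def _table_hash(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()


def _somatic_family(cov):
    """Scalar somatic cross-checks: change in weight / head-circumference Z
    against the main clinical exposures, BH-adjusted as one family."""
    rows = []
    exposures = ("surgery_age_days", "bypass_min", "arrest_min", "picu_days")
    for somatic in ("weight_z_delta", "hc_z_delta"):
        for exposure in exposures:
            merged = cov.dropna(subset=[somatic, exposure])
            res = spearman(
                merged[exposure].to_numpy(dtype=float),
                merged[somatic].to_numpy(dtype=float),
            )
            rows.append(
                {
                    "region": f"{somatic}~{exposure}",
                    "test_name": res.test_name,
                    "family": "somatic_clinical",
                    "statistic": res.statistic,
                    "effect": res.effect,
                    "p_raw": res.p_raw,
                    "n_used": res.n_used,
                    "note": res.note,
                }
            )
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_fdr(out["p_raw"].to_numpy())
    return out


def run_full_analysis(config: RunConfig) -> ReportBundle:
    """Execute the full pipeline for one configuration.

    Inputs are simulated at the configured sizes unless file paths are
    given.  Returns the in-memory bundle; use :func:`write_bundle` to
    persist it.
    """
    if config.normative_path:
        normative = read_scan_table(config.normative_path)
    else:
        normative = simulate_normative(n=config.n_normative, seed=config.seed)
    if config.chd_path:
        chd_scans = read_scan_table(config.chd_path)
        covariates = read_covariate_table(config.covariate_path)
    else:
        chd_scans, covariates, _truth = simulate_chd(
            n=config.n_chd, seed=config.seed + 1
        )

    atlas = NormativeAtlas(
        regions=config.regions,
        n_restarts=config.n_restarts,
        random_state=config.seed,
        strict_range=config.strict_range,
    ).fit(normative)

    scores = atlas.score_scans(chd_scans)
    pre = scores[scores["timepoint"] == "pre"]
    post = scores[scores["timepoint"] == "post"]
    traj = build_trajectories(pre, post, thresholds=config.thresholds)

    cov = covariates.set_index("subject_id")
    categories = cov["chd_category"]
    census_out = census(traj, thresholds=config.thresholds, categories=categories)
    scan_flags = scan_census(scores, threshold=max(config.thresholds))

    fam = {}
    fam["wilcoxon_pre_post"] = run_region_family(
        traj, "wilcoxon_pre_post", "wilcoxon_pre_post", regions=config.regions
    )
    fam["kruskal_chd_category"] = run_region_family(
        traj, "kruskal", "kruskal_chd_category", groups=categories,
        regions=config.regions,
    )
    for name, col in (
        ("spearman_age_at_surgery", "surgery_age_days"),
        ("spearman_surgery_to_postmri", "surgery_to_postmri_days"),
        ("spearman_interscan_interval", "interscan_days"),
        ("spearman_ventilation_days", "ventilation_days"),
        ("spearman_inotrope_days", "inotrope_days"),
        ("spearman_weight_z_delta", "weight_z_delta"),
        ("spearman_hc_z_delta", "hc_z_delta"),
    ):
        fam[name] = run_region_family(
            traj, "spearman", name, covariate=cov[col], regions=config.regions
        )
    for name, col, adj in (
        ("partial_picu_given_age", "picu_days", "surgery_age_days"),
        ("partial_bypass_given_picu", "bypass_min", "picu_days"),
        ("partial_arrest_given_picu", "arrest_min", "picu_days"),
        ("partial_creatinine_given_age", "creatinine_umol_l", "creatinine_age_days"),
    ):
        fam[name] = run_region_family(
            traj,
            "partial_spearman",
            name,
            covariate=cov[col],
            adjust_for=cov[adj],
            regions=config.regions,
        )
    for name, col in (("mw_rrt", "rrt"), ("mw_nec", "nec")):
        fam[name] = run_region_family(
            traj, "mann_whitney", name, covariate=cov[col], regions=config.regions
        )
    fam["somatic_clinical"] = _somatic_family(covariates)

    model_summary = {
        region: {
            "n_train": model.n_train_,
            "pma_range": list(model.pma_range_),
            "log_marginal_likelihood": float(
                model.gp_.log_marginal_likelihood_value_
            ),
            "kernel": str(model.gp_.kernel_),
        }
        for region, model in atlas.models_.items()
    }
    provenance = {
        "package_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_sha256": config.digest(),
        "input_hashes": {
            "normative_scans": _table_hash(normative),
            "chd_scans": _table_hash(chd_scans),
            "covariates": _table_hash(covariates),
        },
    }
    bundle = ReportBundle(
        normative_scans=normative,
        chd_scans=chd_scans,
        covariates=covariates,
        scores=scores,
        trajectories=traj,
        census=census_out,
        scan_flags=scan_flags,
        families=fam,
        model_summary=model_summary,
        provenance=provenance,
    )
    bundle.atlas_ = atlas
    return bundle


def _bundle_parts(bundle: ReportBundle):
    parts = {
        "normative_scans.csv": bundle.normative_scans.to_csv(index=False),
        "chd_scans.csv": bundle.chd_scans.to_csv(index=False),
        "covariates.csv": bundle.covariates.to_csv(index=False),
        "scores.csv": bundle.scores.to_csv(index=False),
        "trajectories.csv": bundle.trajectories.to_csv(index=False),
        "census.json": json.dumps(bundle.census, indent=2, sort_keys=True),
        "report.json": json.dumps(
            {
                "census": bundle.census,
                "scan_flags": bundle.scan_flags,
                "model_summary": bundle.model_summary,
                "provenance": bundle.provenance,
            },
            indent=2,
            sort_keys=True,
            default=str,
        ),
    }
    for name in sorted(bundle.families):
        parts[f"family_{name}.csv"] = bundle.families[name].to_csv(index=False)
    return parts


def write_bundle(bundle: ReportBundle, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, text in _bundle_parts(bundle).items():
        (outdir / name).write_text(text)
    return outdir


def bundle_digest(bundle: ReportBundle) -> str:
    """Stable digest of every serialized artifact; equal configs+seeds give
    equal digests."""
    h = hashlib.sha256()
    for name, text in sorted(_bundle_parts(bundle).items()):
        h.update(name.encode())
        h.update(text.encode())
    return h.hexdigest()
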