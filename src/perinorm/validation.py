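"""Reusable validation experiments for the normative pipeline.

These functions re-run the package's own statistical guarantees from
scratch: held-out Z calibration of the normative models, false-discovery
control of a 13-region family under the global null, and recovery of an
injected clinical effect through the full simulate-fit-score-test chain.
They are used by the test suite and the reproduction script; problem sizes
are arguments so both can choose their scale.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .normative import NormativeAtlas
from .regions import MODELLED_REGIONS
from .simulate import EffectSpec, simulate_chd, simulate_normative
from .stats import run_region_family
from .trajectories import build_trajectories, normal_tail

__all__ = [
    "fit_reference_atlas",
    "calibration_experiment",
    "fdr_null_experiment",
    "effect_recovery_experiment",
    "RECOVERY_REGIONS",
]

#: Regions carrying the injected effect in the recovery experiment: the two
#: CSF compartments plus four deep nuclei, chosen so the sigma-weighted
#: leakage into the total-tissue sum stays far below its slope noise.
RECOVERY_REGIONS = (
    "csf",
    "ventricles",
    "caudate_l",
    "caudate_r",
    "thalamus_l",
    "thalamus_r",
)


def fit_reference_atlas(seed: int, n_train: int = 219, n_restarts: int = 4):
    """Fit the 13-region atlas on a fresh normative cohort."""
    train = simulate_normative(n=n_train, seed=seed)
    return NormativeAtlas(n_restarts=n_restarts, random_state=seed).fit(train)


def calibration_experiment(
    atlas: NormativeAtlas,
    seed: int,
    n_heldout: int = 2000,
    threshold: float = 2.6,
) -> dict:
    """Score held-out normative scans and summarise Z calibration.

    Returns per-region mean and SD of the deviation scores, the pooled
    two-tailed flag rate at ``threshold`` with its Monte-Carlo standard
    error, and the standard-normal expectation.
    """
    held = simulate_normative(n=n_heldout, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = atlas.score_scans(held)
    per_region = scores.groupby("region")["z"].agg(["mean", "std"])
    flags = (scores["z"].abs() > threshold).to_numpy()
    expected = 2 * normal_tail(threshold)
    n_scores = int(len(scores))
    return {
        "per_region": per_region,
        "max_abs_mean": float(per_region["mean"].abs().max()),
        "sd_min": float(per_region["std"].min()),
        "sd_max": float(per_region["std"].max()),
        "flag_rate": float(flags.mean()),
        "expected_rate": float(expected),
        "mc_se": float(np.sqrt(expected * (1 - expected) / n_scores)),
        "n_scores": n_scores,
    }


def _null_trajectories(rng, n_subjects: int) -> pd.DataFrame:
    subjects = [f"s{i:03d}" for i in range(n_subjects)]
    rows = []
    for region in MODELLED_REGIONS:
        z_pre = rng.standard_normal(n_subjects)
        z_post = rng.standard_normal(n_subjects)
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": subjects,
                    "region": region,
                    "z_pre": z_pre,
                    "z_post": z_post,
                    "delta_z": z_post - z_pre,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def fdr_null_experiment(
    seed: int, n_reps: int = 500, n_subjects: int = 36, alpha: float = 0.05
) -> dict:
    """Global-null replicates of the paired 13-region Wilcoxon family.

    Returns the fraction of replicates with at least one BH-adjusted
    p below ``alpha`` (the family-level false-positive rate, which BH
    bounds by ``alpha`` under the global null).
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        traj = _null_trajectories(rng, n_subjects)
        fam = run_region_family(traj, "wilcoxon_pre_post", "null")
        hits += bool((fam["p_fdr"] < alpha).any())
    frac = hits / n_reps
    return {
        "any_discovery_rate": frac,
        "alpha": alpha,
        "mc_se": float(np.sqrt(alpha * (1 - alpha) / n_reps)),
        "n_reps": n_reps,
    }


def effect_recovery_experiment(
    atlas: NormativeAtlas,
    seed: int,
    n_reps: int = 100,
    n_subjects: int = 200,
    picu_beta: float = -0.12,
    alpha: float = 0.05,
) -> dict:
    """Recovery of an injected PICU-days effect through the full pipeline.

    Each replicate simulates a surgical cohort in which six regions
    (:data:`RECOVERY_REGIONS`) receive a negative PICU-days coefficient on
    their Z-slope change on top of cohort-wide slope noise, scores it with
    ``atlas``, and runs the partial-Spearman family (PICU days given age at
    surgery).  A replicate "recovers the sign" when every injected region's
    partial rho is negative; an effect-free region is "falsely flagged"
    when its adjusted p falls below ``alpha``.
    """
    effects = [
        EffectSpec(name="baseline", baseline_dev=-0.8, noise_sd=0.3),
        EffectSpec(
            name="picu",
            beta={"picu_days": picu_beta},
            noise_sd=0.3,
            regions=RECOVERY_REGIONS,
        ),
    ]
    free_regions = [r for r in MODELLED_REGIONS if r not in RECOVERY_REGIONS]
    sign_ok = 0
    false_flags = {r: 0 for r in free_regions}
    for rep in range(n_reps):
        scans, cov, _ = simulate_chd(
            effects=effects, n=n_subjects, seed=seed + 7919 * rep
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores = atlas.score_scans(scans)
        traj = build_trajectories(
            scores[scores["timepoint"] == "pre"],
            scores[scores["timepoint"] == "post"],
        )
        covi = cov.set_index("subject_id")
        fam = run_region_family(
            traj,
            "partial_spearman",
            "picu_given_age",
            covariate=covi["picu_days"],
            adjust_for=covi["surgery_age_days"],
        ).set_index("region")
        sign_ok += bool((fam.loc[list(RECOVERY_REGIONS), "effect"] < 0).all())
        for r in free_regions:
            false_flags[r] += bool(fam.loc[r, "p_fdr"] < alpha)
    return {
        "sign_recovery_rate": sign_ok / n_reps,
        "false_flag_rates": {r: c / n_reps for r, c in false_flags.items()},
        "max_false_flag_rate": max(false_flags.values()) / n_reps,
        "n_reps": n_reps,
        "injected_regions": list(RECOVERY_REGIONS),
    }
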