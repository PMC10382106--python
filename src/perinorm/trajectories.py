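"""Pre/post deviation trajectories, extreme-deviation flags and the census.

The growth trajectory of one region in one infant is summarised by the
Z-slope change ``delta_z = z_post - z_pre``: negative values mean growth
slowed relative to typically developing peers between the two scans.
Extreme deviations are flagged at fixed thresholds (1.65, 2.3 and 2.6 by
default, the two-tailed 5%, 1% and 0.5% points of the standard normal),
using strict inequalities, so a value exactly at the threshold is not
flagged.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataIntegrityError

__all__ = [
    "DEFAULT_THRESHOLDS",
    "normal_tail",
    "flag_extremes",
    "build_trajectories",
    "census",
    "scan_census",
]

DEFAULT_THRESHOLDS = (1.65, 2.3, 2.6)


def normal_tail(z):
    """Standard-normal upper-tail probability P(Z > z)."""
    return stats.norm.sf(z)


def flag_extremes(z, threshold):
    """Classify values against a symmetric threshold.

    Returns ``"negative"`` where ``z < -threshold``, ``"positive"`` where
    ``z > threshold`` (strict comparisons), ``"none"`` otherwise and missing
    for non-finite input.  Works on scalars and arrays.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    z_arr = np.asarray(z, dtype=float)
    out = np.full(z_arr.shape, "none", dtype=object)
    out[z_arr < -threshold] = "negative"
    out[z_arr > threshold] = "positive"
    out[~np.isfinite(z_arr)] = None
    if np.isscalar(z) or z_arr.ndim == 0:
        return out.item() if out.shape == () else out[0]
    return out


def build_trajectories(
    scores_pre: pd.DataFrame,
    scores_post: pd.DataFrame,
    thresholds=DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Join per-scan deviation scores into subject x region trajectories.

    Inputs are long score tables with columns ``subject_id``, ``region`` and
    ``z`` (extra columns ignored).  A missing Z at either timepoint (for
    example a region excluded because injury corrupted its segmentation)
    yields a missing ``delta_z`` for that region only; the subject's other
    regions are unaffected.
    """
    frames = []
    for name, tab in (("pre", scores_pre), ("post", scores_post)):
        dup = tab.duplicated(subset=["subject_id", "region"])
        if dup.any():
            rows = tab.loc[dup, ["subject_id", "region"]].drop_duplicates()
            raise DataIntegrityError(
                f"duplicate {name} score rows for: "
                + "; ".join(f"{r.subject_id}/{r.region}" for r in rows.itertuples())
            )
        frames.append(
            tab[["subject_id", "region", "z"]].rename(columns={"z": f"z_{name}"})
        )
    traj = frames[0].merge(frames[1], on=["subject_id", "region"], how="outer")
    traj["delta_z"] = traj["z_post"] - traj["z_pre"]
    for tau in thresholds:
        traj[f"flag_{tau:g}"] = flag_extremes(traj["delta_z"].to_numpy(), tau)
    return traj.sort_values(["subject_id", "region"], ignore_index=True)


def census(
    trajectories: pd.DataFrame,
    thresholds=DEFAULT_THRESHOLDS,
    categories: dict | pd.Series | None = None,
) -> dict:
    """Count subjects with at least one extreme Z-slope change per threshold.

    A subject is counted once per threshold no matter how many regions are
    flagged.  The denominator is the number of subjects with at least one
    non-missing ``delta_z`` and is recorded alongside each percentage.
    Subjects absent from ``categories`` are labelled ``"unknown"`` with a
    warning.
    """
    if categories is None:
        categories = {}
    elif isinstance(categories, pd.Series):
        categories = categories.to_dict()
    valid = trajectories.dropna(subset=["delta_z"])
    subjects = valid["subject_id"].unique()
    unknown = [s for s in subjects if s not in categories] if categories else []
    if categories and unknown:
        warnings.warn(
            f"{len(unknown)} subject(s) missing from category map; "
            "labelled 'unknown'"
        )
    denom = len(subjects)
    out = {"denominator": denom, "thresholds": {}}
    for tau in thresholds:
        extreme = valid.loc[np.abs(valid["delta_z"]) > tau, "subject_id"].unique()
        by_cat: dict[str, int] = {}
        for s in extreme:
            cat = categories.get(s, "unknown") if categories else "unknown"
            by_cat[cat] = by_cat.get(cat, 0) + 1
        out["thresholds"][f"{tau:g}"] = {
            "count": int(len(extreme)),
            "percent": 100.0 * len(extreme) / denom if denom else 0.0,
            "by_category": dict(sorted(by_cat.items())),
        }
    return out


def scan_census(scores: pd.DataFrame, threshold: float = 2.6) -> dict:
    """Per-scan extreme single-timepoint deviations at one threshold."""
    valid = scores.dropna(subset=["z"])
    flagged = valid[np.abs(valid["z"]) > threshold]
    n_scores = int(len(valid))
    return {
        "threshold": threshold,
        "n_scores": n_scores,
        "n_flagged_scores": int(len(flagged)),
        "flag_rate": len(flagged) / n_scores if n_scores else 0.0,
        "subjects_flagged": sorted(flagged["subject_id"].unique().tolist()),
    }
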