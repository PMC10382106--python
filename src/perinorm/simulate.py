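"""Synthetic normative and surgical (CHD) cohorts with known ground truth.

The generator emulates two cohorts:

* a normative cohort of healthy term infants, one scan each, acquired between
  37 and 45 weeks postmenstrual age (PMA), used to fit the normative curves;
* a congenital-heart-disease (CHD) cohort with paired pre-/post-operative
  scans, clinical covariates calibrated to published cohort demographics, and
  configurable covariate effects injected into the per-region growth
  deviations.

Each regional volume follows a quadratic mean curve in PMA with a sex offset
and a linear postnatal-days term, plus heteroscedastic Gaussian noise whose
SD grows linearly with PMA.  Total tissue volume is never drawn: it is the
exact sum of its component volumes in every generated row, so the summation
rule used on real segmentations holds in the synthetic tables too.

For the CHD cohort the post-operative volume is constructed as
``mu(x_post) + (z_pre + dz) * sigma(x_post)``, so the generative model and
the scoring model agree by construction and the injected deviation ``dz`` is
recoverable by any well-calibrated normative model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ParameterError
from .regions import (
    CHD_CATEGORIES,
    MODELLED_REGIONS,
    PRIMITIVE_REGIONS,
    TOTAL_TISSUE,
    TOTAL_TISSUE_COMPONENTS,
)

__all__ = [
    "GrowthCurveParams",
    "EffectSpec",
    "GroundTruth",
    "default_curve_params",
    "default_chd_effects",
    "total_tissue_params",
    "simulate_normative",
    "simulate_chd",
    "true_deviation_z",
    "SCAN_META_COLUMNS",
    "NUMERIC_COVARIATES",
]

#: Metadata columns of a scan table, in canonical order.
SCAN_META_COLUMNS = (
    "subject_id",
    "group",
    "sex",
    "ga_birth_weeks",
    "pma_scan_weeks",
    "postnatal_days",
    "timepoint",
)

#: Numeric clinical covariates an :class:`EffectSpec` may reference.
NUMERIC_COVARIATES = (
    "ga_birth_weeks",
    "surgery_age_days",
    "pre_scan_age_days",
    "post_scan_age_days",
    "bypass_min",
    "arrest_min",
    "picu_days",
    "ventilation_days",
    "inotrope_days",
    "rrt",
    "nec",
    "creatinine_umol_l",
    "creatinine_age_days",
    "interscan_days",
    "surgery_to_postmri_days",
    "weight_z_delta",
    "hc_z_delta",
)

_PMA_GRID = np.arange(37.0, 45.01, 0.25)


@dataclass(frozen=True)
class GrowthCurveParams:
    """Parameters of one region's generative growth curve.

    The mean volume at PMA ``t`` (weeks), postnatal age ``pnd`` (days) and
    sex is ``a + b*(t-40) + c*(t-40)**2 + s*male + d*pnd`` (mL) and the
    residual SD is ``sigma0 * (1 + kappa*(t-40))``.
    """

    region: str
    a: float
    b: float
    c: float = 0.0
    s: float = 0.0
    d: float = 0.0
    sigma0: float = 1.0
    kappa: float = 0.05

    def mean(self, pma, postnatal_days, male):
        t = np.asarray(pma, dtype=float) - 40.0
        return (
            self.a
            + self.b * t
            + self.c * t**2
            + self.s * np.asarray(male, dtype=float)
            + self.d * np.asarray(postnatal_days, dtype=float)
        )

    def sd(self, pma):
        t = np.asarray(pma, dtype=float) - 40.0
        return self.sigma0 * (1.0 + self.kappa * t)

    def validate(self, pma_lo: float = 37.0, pma_hi: float = 45.0) -> None:
        if self.sigma0 <= 0:
            raise ParameterError(f"{self.region}: sigma0 must be > 0")
        grid = _PMA_GRID[(_PMA_GRID >= pma_lo) & (_PMA_GRID <= pma_hi)]
        if np.any(self.sd(grid) <= 0):
            raise ParameterError(
                f"{self.region}: residual SD non-positive within "
                f"PMA [{pma_lo}, {pma_hi}] (kappa={self.kappa})"
            )
        # mean positivity over the supported covariate envelope
        for male in (0.0, 1.0):
            pnd_max = 7.0 * (grid - pma_lo)  # earliest possible birth
            for pnd in (np.zeros_like(grid), pnd_max):
                if np.any(self.mean(grid, pnd, male) <= 0):
                    raise ParameterError(
                        f"{self.region}: mean volume non-positive somewhere on "
                        f"the covariate grid"
                    )


def default_curve_params() -> dict[str, GrowthCurveParams]:
    """Invented but anatomically plausible neonatal growth curves (mL).

    These are configuration constants, not published values; they place the
    total tissue volume near 400 mL at 40 weeks with realistic relative
    region sizes and noise levels.  All regions share ``kappa`` so the
    total-tissue SD keeps the same linear-in-PMA form as its components.
    """
    specs = {
        #            a      b     c      s     d       sigma0
        "cortical_gm": (170.0, 12.0, 0.30, 8.0, -0.10, 15.0),
        "white_matter": (160.0, 6.0, 0.10, 8.0, -0.05, 12.0),
        "cerebellum": (22.0, 1.80, 0.05, 1.0, 0.01, 2.5),
        "brainstem": (6.5, 0.35, 0.00, 0.3, 0.00, 0.6),
        "hippocampus_amygdala": (4.2, 0.25, 0.00, 0.2, 0.00, 0.5),
        "caudate_l": (3.2, 0.15, 0.00, 0.15, 0.00, 0.35),
        "caudate_r": (3.2, 0.15, 0.00, 0.15, 0.00, 0.35),
        "lentiform_l": (4.6, 0.20, 0.00, 0.20, 0.00, 0.45),
        "lentiform_r": (4.6, 0.20, 0.00, 0.20, 0.00, 0.45),
        "thalamus_l": (4.8, 0.28, 0.00, 0.20, 0.00, 0.50),
        "thalamus_r": (4.8, 0.28, 0.00, 0.20, 0.00, 0.50),
        "csf": (45.0, 2.50, 0.20, 2.0, 0.05, 8.0),
        "ventricles": (7.0, 0.40, 0.00, 0.5, 0.01, 2.0),
    }
    return {
        region: GrowthCurveParams(region, a, b, c, s, d, sigma0)
        for region, (a, b, c, s, d, sigma0) in specs.items()
    }


def total_tissue_params(params: dict[str, GrowthCurveParams]) -> GrowthCurveParams:
    """Derived curve for total tissue volume (the sum of its components).

    Mean coefficients add; with independent component noise and a shared
    ``kappa``, the summed SD is ``sqrt(sum sigma0_i**2) * (1 + kappa*(t-40))``.
    """
    comps = [params[r] for r in TOTAL_TISSUE_COMPONENTS]
    kappas = {p.kappa for p in comps}
    if len(kappas) != 1:
        raise ParameterError(
            "total-tissue SD is only closed-form when all component regions "
            "share kappa; got " + repr(sorted(kappas))
        )
    return GrowthCurveParams(
        region=TOTAL_TISSUE,
        a=sum(p.a for p in comps),
        b=sum(p.b for p in comps),
        c=sum(p.c for p in comps),
        s=sum(p.s for p in comps),
        d=sum(p.d for p in comps),
        sigma0=float(np.sqrt(sum(p.sigma0**2 for p in comps))),
        kappa=kappas.pop(),
    )


def _check_params(params: dict[str, GrowthCurveParams]) -> None:
    missing = [r for r in PRIMITIVE_REGIONS if r not in params]
    if missing:
        raise ConfigurationError(
            "missing growth-curve parameters for region(s): " + ", ".join(missing)
        )
    for region in PRIMITIVE_REGIONS:
        params[region].validate()


@dataclass(frozen=True)
class EffectSpec:
    """One injected clinical effect on per-region growth deviations.

    ``baseline_dev`` displaces the mean pre-operative Z; ``beta`` maps a
    clinical covariate name to its linear coefficient on the Z-slope change
    (Z units per covariate unit, applied to the raw covariate value);
    ``noise_sd`` is the SD of an independent per-subject, per-region residual
    added to the slope change; ``regions`` restricts the effect to a subset
    of primitive regions (``None`` means all).  Total tissue volume cannot be
    targeted directly — it inherits effects through its components.
    """

    name: str = "effect"
    baseline_dev: float = 0.0
    beta: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0
    regions: tuple[str, ...] | None = None

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError(f"effect {self.name!r}: noise_sd must be >= 0")
        unknown = sorted(set(self.beta) - set(NUMERIC_COVARIATES))
        if unknown:
            raise ConfigurationError(
                f"effect {self.name!r}: unknown covariate(s) in beta: "
                + ", ".join(unknown)
            )
        if self.regions is not None:
            bad = sorted(set(self.regions) - set(PRIMITIVE_REGIONS))
            if bad:
                raise ConfigurationError(
                    f"effect {self.name!r}: unknown or non-primitive region(s): "
                    + ", ".join(bad)
                )

    def region_set(self) -> set[str]:
        return set(PRIMITIVE_REGIONS if self.regions is None else self.regions)


def default_chd_effects() -> list[EffectSpec]:
    """Default perioperative effect: global growth slowing driven by a longer
    intensive-care stay and longer bypass, on top of a negative pre-operative
    baseline displacement."""
    return [
        EffectSpec(
            name="perioperative_slowing",
            baseline_dev=-0.8,
            beta={"picu_days": -0.08, "bypass_min": -0.002},
            noise_sd=0.35,
        )
    ]


@dataclass
class GroundTruth:
    """True per-subject deviations and the generating curves.

    ``zscores`` has one row per subject x modelled region with columns
    ``z_pre``, ``z_post``, ``delta_z`` (``delta_z == z_post - z_pre``
    exactly); ``curve_params`` includes the derived total-tissue curve.
    """

    zscores: pd.DataFrame
    curve_params: dict[str, GrowthCurveParams]
    effects: list[EffectSpec]


def _volume_columns(df: pd.DataFrame, params: dict[str, GrowthCurveParams]):
    ordered = [r for r in MODELLED_REGIONS if r != TOTAL_TISSUE]
    ordered += [r for r in PRIMITIVE_REGIONS if r not in ordered]
    return ordered


def simulate_normative(
    params: dict[str, GrowthCurveParams] | None = None,
    n: int = 219,
    seed: int = 0,
    pnd_mean_days: float = 10.0,
) -> pd.DataFrame:
    """Generate a single-scan normative cohort of ``n`` term infants.

    Gestational age at birth is truncated-normal around 40.1 weeks within
    [37, 42].  Scan timing mixes early postnatal scans (exponential delay
    after birth) with scans spread uniformly across the remaining window, so
    the cohort covers the whole 37-45 week PMA range the normative curves
    are meant to support; postnatal days are whole days and exactly
    consistent with GA and PMA.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    params = default_curve_params() if params is None else params
    _check_params(params)
    rng = np.random.default_rng(seed)

    ga = np.round(np.clip(rng.normal(40.1, 1.3, size=n), 37.0, 42.0), 2)
    pnd_cap = np.floor(7.0 * (45.0 - ga)).astype(int)
    early = rng.random(n) < 0.6
    pnd_draw = np.where(
        early,
        rng.exponential(pnd_mean_days, size=n),
        rng.uniform(0.0, 7.0 * (45.0 - ga)),
    )
    pnd = np.minimum(np.rint(pnd_draw), pnd_cap).astype(int)
    pma = ga + pnd / 7.0
    male = rng.random(n) < 0.5

    df = pd.DataFrame(
        {
            "subject_id": [f"norm{i:04d}" for i in range(n)],
            "group": "normative",
            "sex": np.where(male, "M", "F"),
            "ga_birth_weeks": ga,
            "pma_scan_weeks": ga + pnd / 7.0,
            "postnatal_days": pnd,
            "timepoint": "single",
        }
    )
    male_f = male.astype(float)
    for region in _volume_columns(df, params):
        p = params[region]
        mu = np.asarray(p.mean(df["pma_scan_weeks"], pnd, male_f))
        sd = np.asarray(p.sd(df["pma_scan_weeks"]))
        vol = mu + sd * rng.standard_normal(n)
        # volumes are physical: redraw the rare noise excursion below zero
        # (truncation point is beyond -3.5 SD for every default region)
        bad = np.flatnonzero(vol <= 0)
        while bad.size:
            vol[bad] = mu[bad] + sd[bad] * rng.standard_normal(bad.size)
            bad = bad[vol[bad] <= 0]
        df[region] = vol
    df[TOTAL_TISSUE] = sum(df[r] for r in TOTAL_TISSUE_COMPONENTS)
    cols = list(SCAN_META_COLUMNS) + list(MODELLED_REGIONS) + [
        r for r in PRIMITIVE_REGIONS if r not in MODELLED_REGIONS
    ]
    return df[cols]


def _lognormal(rng, median, sigma, size):
    return np.exp(rng.normal(np.log(median), sigma, size=size))


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Clinical covariates calibrated to the cohort's published medians/IQRs.

    Durations are log-normal (right-skewed); flags are Bernoulli with the
    cohort's observed frequencies; the CHD category follows the 20/12/4
    streaming/left/right split.
    """
    ga = np.round(np.clip(rng.normal(38.5, 0.8, size=n), 37.0, 41.0), 2)
    male = rng.random(n) < 19 / 36

    surgery = np.clip(np.rint(_lognormal(rng, 12.0, 0.50, n)), 4, 40).astype(int)
    pre_day = np.clip(
        np.rint(surgery * rng.uniform(0.25, 0.75, size=n)), 1, surgery - 1
    ).astype(int)
    post_gap = np.clip(np.rint(_lognormal(rng, 8.0, 0.35, n)), 3, 25).astype(int)
    post_day = surgery + post_gap
    # keep the post-operative scan inside the modelled PMA window (< 46 wk)
    post_cap = np.floor(7.0 * (45.5 - ga)).astype(int)
    post_day = np.minimum(post_day, post_cap)

    has_bypass = rng.random(n) < 31 / 36
    bypass = np.where(has_bypass, _lognormal(rng, 150.0, 0.18, n), 0.0)
    has_arrest = has_bypass & (rng.random(n) < 0.3)
    arrest = np.where(has_arrest, _lognormal(rng, 12.0, 0.5, n), 0.0)

    picu = _lognormal(rng, 4.0, 0.38, n)
    vent = _lognormal(rng, 3.0, 0.35, n)
    inotrope = _lognormal(rng, 3.0, 0.35, n)
    rrt = (rng.random(n) < 6 / 36).astype(int)
    nec = (rng.random(n) < 4 / 36).astype(int)
    creat = _lognormal(rng, 45.0, 0.30, n)
    creat_age = np.maximum(surgery - rng.integers(0, 4, size=n), 0)

    category = rng.choice(CHD_CATEGORIES, size=n, p=[20 / 36, 12 / 36, 4 / 36])
    injury = (rng.random(n) < 2 / 36).astype(int)

    w_pre = rng.normal(0.1, 1.0, size=n)
    w_post = w_pre + rng.normal(-1.0, 0.8, size=n)
    hc_pre = rng.normal(0.2, 0.9, size=n)
    hc_post = hc_pre + rng.normal(-0.8, 0.7, size=n)

    return pd.DataFrame(
        {
            "subject_id": [f"chd{i:03d}" for i in range(n)],
            "sex": np.where(male, "M", "F"),
            "chd_category": category,
            "ga_birth_weeks": np.round(ga, 2),
            "surgery_age_days": surgery,
            "pre_scan_age_days": pre_day,
            "post_scan_age_days": post_day,
            "bypass_min": np.round(bypass, 1),
            "arrest_min": np.round(arrest, 1),
            "picu_days": np.round(picu, 1),
            "ventilation_days": np.round(vent, 1),
            "inotrope_days": np.round(inotrope, 1),
            "rrt": rrt,
            "nec": nec,
            "creatinine_umol_l": np.round(creat, 1),
            "creatinine_age_days": creat_age,
            "interscan_days": post_day - pre_day,
            "surgery_to_postmri_days": post_day - surgery,
            "weight_z_pre": np.round(w_pre, 2),
            "weight_z_post": np.round(w_post, 2),
            "weight_z_delta": np.round(w_post - w_pre, 2),
            "hc_z_pre": np.round(hc_pre, 2),
            "hc_z_post": np.round(hc_post, 2),
            "hc_z_delta": np.round(hc_post - hc_pre, 2),
            "brain_injury": injury,
        }
    )


def simulate_chd(
    params: dict[str, GrowthCurveParams] | None = None,
    effects: list[EffectSpec] | None = None,
    n: int = 36,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a paired pre/post surgical cohort with injected effects.

    Returns the scan table (two rows per infant), the per-subject covariate
    table, and the :class:`GroundTruth` deviations used to construct the
    volumes.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    params = default_curve_params() if params is None else params
    _check_params(params)
    effects = default_chd_effects() if effects is None else list(effects)
    for eff in effects:
        eff.validate()

    rng = np.random.default_rng(seed)
    cov = _draw_covariates(rng, n)

    pma_pre = cov["ga_birth_weeks"].to_numpy() + cov["pre_scan_age_days"].to_numpy() / 7.0
    pma_post = (
        cov["ga_birth_weeks"].to_numpy() + cov["post_scan_age_days"].to_numpy() / 7.0
    )
    male = (cov["sex"] == "M").to_numpy(dtype=float)

    prim = list(PRIMITIVE_REGIONS)
    baseline = {r: 0.0 for r in prim}
    z_pre = pd.DataFrame(
        rng.standard_normal((n, len(prim))), columns=prim, index=cov.index
    )
    delta = pd.DataFrame(0.0, columns=prim, index=cov.index)
    for eff in effects:
        mask = [r for r in prim if r in eff.region_set()]
        shift = np.zeros(n)
        for name, coef in eff.beta.items():
            shift = shift + coef * cov[name].to_numpy(dtype=float)
        for r in mask:
            baseline[r] += eff.baseline_dev
            delta[r] += shift + eff.noise_sd * rng.standard_normal(n)
    for r in prim:
        z_pre[r] += baseline[r]
    z_post = z_pre + delta

    pnd_pre = cov["pre_scan_age_days"].to_numpy(dtype=float)
    pnd_post = cov["post_scan_age_days"].to_numpy(dtype=float)
    for r in prim:
        # keep volumes physical: redraw the rare pre-scan Z whose implied
        # pre or post volume would be non-positive (delta_z is untouched,
        # so the ground-truth identity is preserved)
        p = params[r]
        lo = np.maximum(
            -p.mean(pma_pre, pnd_pre, male) / p.sd(pma_pre),
            -p.mean(pma_post, pnd_post, male) / p.sd(pma_post)
            - delta[r].to_numpy(),
        )
        z = z_pre[r].to_numpy()
        bad = np.flatnonzero(z <= lo)
        while bad.size:
            z[bad] = baseline[r] + rng.standard_normal(bad.size)
            bad = bad[z[bad] <= lo[bad]]
        z_pre[r] = z
    z_post = z_pre + delta

    def _scan_rows(timepoint, pma, pnd, z_table):
        rows = pd.DataFrame(
            {
                "subject_id": cov["subject_id"],
                "group": "chd",
                "sex": cov["sex"],
                "ga_birth_weeks": cov["ga_birth_weeks"],
                "pma_scan_weeks": pma,
                "postnatal_days": pnd,
                "timepoint": timepoint,
            }
        )
        for r in prim:
            p = params[r]
            rows[r] = p.mean(pma, pnd, male) + z_table[r].to_numpy() * p.sd(pma)
        rows[TOTAL_TISSUE] = sum(rows[r] for r in TOTAL_TISSUE_COMPONENTS)
        return rows

    pre_rows = _scan_rows("pre", pma_pre, cov["pre_scan_age_days"].to_numpy(), z_pre)
    post_rows = _scan_rows(
        "post", pma_post, cov["post_scan_age_days"].to_numpy(), z_post
    )
    scans = pd.concat([pre_rows, post_rows], ignore_index=True)
    cols = list(SCAN_META_COLUMNS) + list(MODELLED_REGIONS) + [
        r for r in PRIMITIVE_REGIONS if r not in MODELLED_REGIONS
    ]
    scans = scans[cols]

    # ground truth for the 13 modelled regions; total tissue is the
    # sigma-weighted combination of its components (exact under shared kappa)
    full_params = dict(params)
    full_params[TOTAL_TISSUE] = total_tissue_params(params)
    weights = {
        r: params[r].sigma0 / full_params[TOTAL_TISSUE].sigma0
        for r in TOTAL_TISSUE_COMPONENTS
    }
    records = []
    for i, sid in enumerate(cov["subject_id"]):
        for region in MODELLED_REGIONS:
            if region == TOTAL_TISSUE:
                zp = sum(weights[r] * z_pre[r].iat[i] for r in TOTAL_TISSUE_COMPONENTS)
                zq = sum(weights[r] * z_post[r].iat[i] for r in TOTAL_TISSUE_COMPONENTS)
            else:
                zp = z_pre[region].iat[i]
                zq = z_post[region].iat[i]
            records.append(
                {
                    "subject_id": sid,
                    "region": region,
                    "z_pre": zp,
                    "z_post": zq,
                    "delta_z": zq - zp,
                }
            )
    truth = GroundTruth(
        zscores=pd.DataFrame.from_records(records),
        curve_params=full_params,
        effects=effects,
    )
    return scans, cov, truth


def true_deviation_z(
    params: dict[str, GrowthCurveParams], scans: pd.DataFrame
) -> pd.DataFrame:
    """Score scans against the *generating* curves (the simulator's oracle).

    Returns a long table (subject_id, timepoint, region, z).  ``params``
    should include the derived total-tissue entry (see
    :func:`total_tissue_params`).
    """
    male = (scans["sex"] == "M").to_numpy(dtype=float)
    pma = scans["pma_scan_weeks"].to_numpy(dtype=float)
    pnd = scans["postnatal_days"].to_numpy(dtype=float)
    out = []
    for region, p in params.items():
        if region not in scans.columns:
            continue
        z = (scans[region].to_numpy(dtype=float) - p.mean(pma, pnd, male)) / p.sd(pma)
        out.append(
            pd.DataFrame(
                {
                    "subject_id": scans["subject_id"],
                    "timepoint": scans["timepoint"],
                    "region": region,
                    "z": z,
                }
            )
        )
    return pd.concat(out, ignore_index=True)
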