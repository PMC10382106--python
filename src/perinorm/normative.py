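"""Gaussian-process normative curves and deviation Z-scores.

One GP per region is fitted to the normative cohort with postmenstrual age
at scan (weeks), postnatal days and sex as covariates.  The predictive
distribution of a *new observation* (latent mean plus learned observation
noise) defines the normative range, and the deviation Z-score of a scan is

    z = (observed - mu_pred) / sigma_pred

which is approximately standard normal for typical infants.  Including the
observation-noise variance in ``sigma_pred`` is what makes the fixed tail
thresholds (|z| > 2.6 for the extreme 1%) interpretable as population
percentiles.

Estimators follow scikit-learn conventions (``fit``/``predict``,
``get_params``, fitted attributes with trailing underscores) and accept
either scan-table DataFrames or plain ``(n, 3)`` arrays of
``[pma_weeks, postnatal_days, male]``.
"""

from __future__ import annotations

import hashlib
import json
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import (
    RBF,
    ConstantKernel,
    DotProduct,
    WhiteKernel,
)

from .exceptions import (
    ConfigurationError,
    ConvergenceError,
    InsufficientDataError,
    RangeError,
)
from .regions import MODELLED_REGIONS

__all__ = [
    "RegionNormativeGP",
    "NormativeAtlas",
    "fit_region_model",
    "fit_all_regions",
    "predict",
    "deviation_z",
    "default_kernel",
]

#: Minimum complete training rows per region.
MIN_TRAIN_ROWS = 30


def default_kernel():
    """Smooth growth plus a polynomial trend and irreducible noise.

    Anisotropic RBF over the four model features (PMA, PMA curvature,
    postnatal weeks, sex) captures smooth departures from trend; the
    DotProduct term is a Bayesian linear fit in the same features, so the
    family contains linear-plus-quadratic growth with additive sex and
    postnatal-age offsets exactly; WhiteKernel carries the observation
    noise that widens the normative band.  Length-scale floors keep the
    smooth part smooth — volumetric growth has no sub-fortnight structure —
    and steer the curvature, postnatal and sex dimensions toward their
    linear (DotProduct) pathway, which guards against absorbing noise into
    region-specific wiggles at normative-cohort sample sizes."""
    rbf = ConstantKernel(1.0, (1e-3, 1e3)) * RBF(
        length_scale=[3.0, 50.0, 50.0, 10.0],
        length_scale_bounds=[(2.0, 1e3), (30.0, 1e3), (30.0, 1e3), (5.0, 1e3)],
    )
    linear = ConstantKernel(0.1, (1e-6, 1e3)) * DotProduct(
        sigma_0=0.0, sigma_0_bounds="fixed"
    )
    return rbf + linear + WhiteKernel(0.1, (1e-8, 1e2))


def _design_matrix(X) -> np.ndarray:
    """Map covariates to model features [(pma-40), pnd/7, male]."""
    if isinstance(X, pd.DataFrame):
        pma = X["pma_scan_weeks"].to_numpy(dtype=float)
        pnd = X["postnatal_days"].to_numpy(dtype=float)
        sex = X["sex"]
        if sex.dtype == object:
            male = sex.map({"F": 0.0, "M": 1.0})
            if male.isna().any():
                bad = sorted(set(sex[male.isna()]))
                raise ConfigurationError(f"unknown sex code(s): {bad}")
            male = male.to_numpy()
        else:
            male = sex.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr.reshape(1, -1)
        if arr.shape[1] != 3:
            raise ConfigurationError(
                "array covariates must have 3 columns: pma_weeks, "
                "postnatal_days, male"
            )
        pma, pnd, male = arr[:, 0], arr[:, 1], arr[:, 2]
    t = pma - 40.0
    feats = np.column_stack([t, t**2 / 5.0, pnd / 7.0, male])
    if not np.all(np.isfinite(feats)):
        raise ConfigurationError("covariates must be finite")
    return feats


class RegionNormativeGP(RegressorMixin, BaseEstimator):
    """Normative GP for a single region's volume.

    Parameters
    ----------
    region : str or None
        Region label carried through results; optional.
    kernel : sklearn kernel or None
        ``None`` uses :func:`default_kernel`.
    n_restarts : int
        Additional seeded restarts of the marginal-likelihood optimiser.
    optimizer : str or None
        ``"fmin_l_bfgs_b"`` (default) or ``None`` to keep the kernel's
        hyperparameters fixed (closed-form posterior with no fitting of
        hyperparameters).
    range_margin : float
        PMA weeks beyond the training range still accepted at predict time.
    strict_range : bool
        Raise instead of warn for out-of-range predictions.
    """

    def __init__(
        self,
        region=None,
        kernel=None,
        n_restarts=4,
        optimizer="fmin_l_bfgs_b",
        random_state=0,
        normalize_y=True,
        range_margin=0.5,
        strict_range=False,
        min_train=MIN_TRAIN_ROWS,
    ):
        self.region = region
        self.kernel = kernel
        self.n_restarts = n_restarts
        self.optimizer = optimizer
        self.random_state = random_state
        self.normalize_y = normalize_y
        self.range_margin = range_margin
        self.strict_range = strict_range
        self.min_train = min_train

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        feats = _design_matrix(X)
        keep = np.isfinite(y)
        feats, y = feats[keep], y[keep]
        if len(y) < self.min_train:
            raise InsufficientDataError(
                f"region {self.region!r}: {len(y)} complete rows "
                f"(< {self.min_train})"
            )
        kernel = self.kernel if self.kernel is not None else default_kernel()
        gp = GaussianProcessRegressor(
            kernel=kernel,
            optimizer=self.optimizer,
            n_restarts_optimizer=self.n_restarts if self.optimizer else 0,
            random_state=self.random_state,
            normalize_y=self.normalize_y,
            alpha=1e-10,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gp.fit(feats, y)
        except Exception as exc:  # pragma: no cover - optimiser failure path
            raise ConvergenceError(
                f"region {self.region!r}: hyperparameter optimisation failed",
                diagnostics={"kernel": str(kernel), "error": str(exc)},
            ) from exc
        self.gp_ = gp
        self.n_train_ = int(len(y))
        self.pma_range_ = (
            float(feats[:, 0].min() + 40.0),
            float(feats[:, 0].max() + 40.0),
        )
        self.X_train_raw_ = np.column_stack(
            [feats[:, 0] + 40.0, feats[:, 2] * 7.0, feats[:, 3]]
        )
        self.y_train_ = y.copy()
        return self

    @property
    def kernel_hyperparams_(self) -> dict:
        """Fitted kernel hyperparameters by name (positive scale)."""
        k = self.gp_.kernel_
        return {h.name: np.exp(t) for h, t in zip(k.hyperparameters, k.theta)}

    def _check_range(self, feats):
        lo = self.pma_range_[0] - self.range_margin
        hi = self.pma_range_[1] + self.range_margin
        pma = feats[:, 0] + 40.0
        out = (pma < lo) | (pma > hi)
        if out.any():
            msg = (
                f"region {self.region!r}: {int(out.sum())} prediction(s) at PMA "
                f"outside training range [{lo:.2f}, {hi:.2f}] weeks"
            )
            if self.strict_range:
                raise RangeError(msg)
            warnings.warn(msg, stacklevel=3)

    def predict(self, X, return_std=False):
        feats = _design_matrix(X)
        self._check_range(feats)
        return self.gp_.predict(feats, return_std=return_std)

    def deviation(self, X, y):
        """Deviation Z-scores for observed volumes ``y`` at covariates ``X``.

        Missing observations yield missing Z-scores."""
        y = np.asarray(y, dtype=float)
        mu, sd = self.predict(X, return_std=True)
        return (y - mu) / sd


class NormativeAtlas(BaseEstimator):
    """Bank of per-region normative GPs fitted from one scan table."""

    def __init__(
        self,
        regions=None,
        kernel=None,
        n_restarts=4,
        optimizer="fmin_l_bfgs_b",
        random_state=0,
        normalize_y=True,
        range_margin=0.5,
        strict_range=False,
        min_train=MIN_TRAIN_ROWS,
    ):
        self.regions = regions
        self.kernel = kernel
        self.n_restarts = n_restarts
        self.optimizer = optimizer
        self.random_state = random_state
        self.normalize_y = normalize_y
        self.range_margin = range_margin
        self.strict_range = strict_range
        self.min_train = min_train

    def _region_list(self):
        return list(MODELLED_REGIONS if self.regions is None else self.regions)

    def _make_model(self, region):
        return RegionNormativeGP(
            region=region,
            kernel=self.kernel,
            n_restarts=self.n_restarts,
            optimizer=self.optimizer,
            random_state=self.random_state,
            normalize_y=self.normalize_y,
            range_margin=self.range_margin,
            strict_range=self.strict_range,
            min_train=self.min_train,
        )

    def fit(self, scans: pd.DataFrame):
        regions = self._region_list()
        missing = [r for r in regions if r not in scans.columns]
        if missing:
            raise ConfigurationError(
                "scan table lacks region column(s): " + ", ".join(missing)
            )
        models, failures = {}, {}
        for region in regions:
            try:
                models[region] = self._make_model(region).fit(
                    scans, scans[region].to_numpy(dtype=float)
                )
            except Exception as exc:
                failures[region] = exc
        if failures:
            lines = [f"  {r}: {e}" for r, e in failures.items()]
            raise ConfigurationError(
                f"{len(failures)} region model(s) failed:\n" + "\n".join(lines)
            )
        self.models_ = models
        self.n_scans_ = int(len(scans))
        return self

    def score_scans(self, scans: pd.DataFrame) -> pd.DataFrame:
        """Deviation scores for every scan x fitted region (long format).

        Scans missing a region's volume keep a row with missing ``z``; other
        regions of the same scan are unaffected."""
        out = []
        mu_sd = {
            region: model.predict(scans, return_std=True)
            for region, model in self.models_.items()
        }
        for region, (mu, sd) in mu_sd.items():
            obs = (
                scans[region].to_numpy(dtype=float)
                if region in scans.columns
                else np.full(len(scans), np.nan)
            )
            out.append(
                pd.DataFrame(
                    {
                        "subject_id": scans["subject_id"].to_numpy(),
                        "timepoint": scans["timepoint"].to_numpy(),
                        "region": region,
                        "observed": obs,
                        "mu_pred": mu,
                        "sigma_pred": sd,
                        "z": (obs - mu) / sd,
                    }
                )
            )
        return pd.concat(out, ignore_index=True)

    def centile_table(
        self,
        region: str,
        pma_grid=None,
        sex: str = "F",
        postnatal_days=None,
        sd_multiples=(1.0, 2.0, 3.0),
    ) -> pd.DataFrame:
        """Exportable normative curve (mean and +/- k*SD bands) for one sex.

        By default postnatal days track a term birth at 40 weeks
        (``7*(pma-40)`` clipped at zero), giving a representative
        cross-section of the covariate space for display."""
        model = self.models_[region]
        if pma_grid is None:
            lo, hi = model.pma_range_
            pma_grid = np.linspace(lo, hi, 81)
        pma_grid = np.asarray(pma_grid, dtype=float)
        if postnatal_days is None:
            pnd = np.clip(7.0 * (pma_grid - 40.0), 0.0, None)
        else:
            pnd = np.full_like(pma_grid, float(postnatal_days))
        male = np.full_like(pma_grid, 1.0 if sex == "M" else 0.0)
        mu, sd = model.predict(np.column_stack([pma_grid, pnd, male]), return_std=True)
        tab = pd.DataFrame(
            {
                "region": region,
                "sex": sex,
                "pma_weeks": pma_grid,
                "postnatal_days": pnd,
                "mean": mu,
                "sd": sd,
            }
        )
        for k in sd_multiples:
            tab[f"lo{k:g}"] = mu - k * sd
            tab[f"hi{k:g}"] = mu + k * sd
        return tab

    # -- serialization ----------------------------------------------------

    def to_json(self, path) -> None:
        """Persist fitted models: hyperparameters plus training data (the
        solve artifacts are re-derived on load)."""
        payload = {"regions": {}, "params": {
            k: v for k, v in self.get_params().items() if k != "kernel"
        }}
        for region, model in self.models_.items():
            X, y = model.X_train_raw_, model.y_train_
            digest = hashlib.sha256(
                X.tobytes() + y.tobytes()
            ).hexdigest()
            payload["regions"][region] = {
                "theta": model.gp_.kernel_.theta.tolist(),
                "X_train": X.tolist(),
                "y_train": y.tolist(),
                "pma_range": list(model.pma_range_),
                "n_train": model.n_train_,
                "data_sha256": digest,
            }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path, kernel=None) -> "NormativeAtlas":
        with open(path) as fh:
            payload = json.load(fh)
        params = payload["params"]
        params["regions"] = list(payload["regions"])
        atlas = cls(**params)
        atlas.models_ = {}
        for region, blob in payload["regions"].items():
            base = kernel if kernel is not None else default_kernel()
            fixed = base.clone_with_theta(np.asarray(blob["theta"], dtype=float))
            model = atlas._make_model(region)
            model.kernel = fixed
            model.optimizer = None
            model.n_restarts = 0
            model.fit(
                np.asarray(blob["X_train"], dtype=float),
                np.asarray(blob["y_train"], dtype=float),
            )
            atlas.models_[region] = model
        atlas.n_scans_ = None
        return atlas


# -- thin functional wrappers ---------------------------------------------


def fit_region_model(train: pd.DataFrame, region: str, **config) -> RegionNormativeGP:
    if region not in train.columns:
        raise ConfigurationError(f"scan table lacks region column: {region}")
    return RegionNormativeGP(region=region, **config).fit(
        train, train[region].to_numpy(dtype=float)
    )


def fit_all_regions(train: pd.DataFrame, **config) -> NormativeAtlas:
    return NormativeAtlas(**config).fit(train)


def predict(model: RegionNormativeGP, covariates, return_std=True):
    return model.predict(covariates, return_std=return_std)


def deviation_z(model: RegionNormativeGP, covariates, observed):
    return model.deviation(covariates, observed)
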