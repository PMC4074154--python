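"""Simulation-study pipeline: parameter grids, splits, estimator evaluation.

Reproduces the simulated-data experiment design: build the mechanism
parameter grid (rate constants crossed with a dense series of diffusion
coefficients), simulate every voltammogram, split 50/50 into training and
test halves, reduce dimensionality (PCA, downsampling or manual peak
features, fitted on the training half only), train a regressor mapping the
reduced signal to D, and summarize absolute test errors overall and per
rate-constant group with bootstrap confidence intervals.

All stochastic steps (split, CV folds, multistarts, bootstrap) are seeded
hierarchically from one experiment seed, so a run is reproducible
end-to-end.
"""

from __future__ import annotations

import enum
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import classical, gpr, preprocess, svr
from .conditions import (
    ExperimentConditions,
    Mechanism,
    MechanismSpec,
    NumericsConfig,
    Voltammogram,
    potential_waveform,
)
from .cvsim import simulate_cv
from .errors import InvalidInputError

__all__ = [
    "D_SCALE",
    "DEFAULT_SEED",
    "Preprocessing",
    "Estimator",
    "GridSpec",
    "ErrorSummary",
    "ExperimentResult",
    "standard_conditions",
    "d_series",
    "build_grid",
    "simulate_grid",
    "split_dataset",
    "bootstrap_ci",
    "run_mechanism_experiment",
    "ReducerState",
    "fit_reducer",
    "TrainedPipeline",
    "train_estimator",
]

D_SCALE = 1e-5
"""Diffusion coefficients are regressed in units of 1e-5 cm^2/s for conditioning."""

DEFAULT_SEED = 1400

_EC_K1 = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)
_EQR_KS = (0.001, 0.005, 0.01, 0.02, 0.03, 0.04, 0.05,
           0.06, 0.07, 0.08, 0.09, 0.1, 0.5, 1.0)
_WINDOWS = {  # mechanism -> (E0, E_reverse)
    Mechanism.EC: (0.3, 0.7),
    Mechanism.E_QR: (0.2108, 0.5),
    Mechanism.E_QR_C: (0.2775, 0.6),
}


class Preprocessing(enum.Enum):
    PCA = "pca"
    DOWNSAMPLE = "downsample"
    MANUAL = "manual"


class Estimator(enum.Enum):
    NS = "ns"
    SVR_LIN = "svr_lin"
    SVR_RBF = "svr_rbf"
    GPR_LIN = "gpr_lin"
    GPR_SQEXP = "gpr_sqexp"


def standard_conditions(e_reverse: float, scan_rate: float = 0.2,
                        bulk_concentration: float = 4e-7) -> ExperimentConditions:
    """The common simulation conditions: 0.2 V/s, 293.15 K, 0.064 cm^2,
    0.4 mmol/L (= 4e-7 mol/cm^3), one electron, 1 mV steps, window from 0 V."""
    return ExperimentConditions(
        scan_rate=scan_rate,
        temperature=293.15,
        electrode_area=0.064,
        bulk_concentration=bulk_concentration,
        n_electrons=1,
        e_start=0.0,
        e_reverse=e_reverse,
        e_step=1e-3,
    )


def d_series(stride: int = 1) -> np.ndarray:
    """The diffusion-coefficient series 1e-6, 1.5e-6, ..., 5e-5 plus 5.05e-5.

    ``stride`` keeps every ``stride``-th value (scaled-down studies).
    """
    base = np.arange(2, 101) * 5e-7  # 1.0e-6 .. 5.0e-5 in 5e-7 steps
    series = np.concatenate([base, [5.05e-5]])
    return series[::stride] if stride > 1 else series


@dataclass(frozen=True)
class GridSpec:
    """A mechanism parameter grid (Cartesian product) plus shared conditions."""

    kind: Mechanism
    k1_values: tuple
    ks_values: tuple
    d_values: tuple
    e0: float
    conditions: ExperimentConditions

    @property
    def size(self) -> int:
        return (
            max(len(self.k1_values), 1)
            * max(len(self.ks_values), 1)
            * len(self.d_values)
        )

    def specs(self) -> list[MechanismSpec]:
        """All mechanism specifications in deterministic (k1, ks, D) order."""
        out = []
        for k1 in self.k1_values or (None,):
            for ks in self.ks_values or (None,):
                for d in self.d_values:
                    out.append(
                        MechanismSpec(kind=self.kind, e0=self.e0, D=float(d),
                                      ks=ks, k1=k1)
                    )
        return out


def build_grid(kind: Mechanism, d_stride: int = 1,
               ks_subset: Optional[Sequence[float]] = None) -> GridSpec:
    """Build the standard parameter grid for a mechanism.

    EC crosses 7 follow-up rates k1 with 100 diffusion coefficients (700
    combinations); the quasi-reversible mechanism crosses 14 heterogeneous
    rates ks with the same D series (1400); the quasi-reversible mechanism
    with follow-up crosses k1 x ks x D (9800 by default; ``ks_subset``
    restricts the ks list).  ``d_stride`` thins the D series for
    scaled-down runs.
    """
    if kind not in _WINDOWS:
        raise InvalidInputError(f"unsupported grid mechanism: {kind}")
    e0, e_rev = _WINDOWS[kind]
    ds = tuple(d_series(d_stride))
    cond = standard_conditions(e_rev)
    if kind is Mechanism.EC:
        return GridSpec(kind, _EC_K1, (), ds, e0, cond)
    if kind is Mechanism.E_QR:
        return GridSpec(kind, (), _EQR_KS, ds, e0, cond)
    ks = tuple(ks_subset) if ks_subset is not None else _EQR_KS
    return GridSpec(kind, _EC_K1, ks, ds, e0, cond)


_memory_cache: dict[str, np.ndarray] = {}


def _grid_key(grid: GridSpec, num: NumericsConfig) -> str:
    payload = json.dumps(
        {
            "kind": grid.kind.value,
            "k1": grid.k1_values,
            "ks": grid.ks_values,
            "d": grid.d_values,
            "e0": grid.e0,
            "cond": [
                grid.conditions.scan_rate,
                grid.conditions.temperature,
                grid.conditions.electrode_area,
                grid.conditions.bulk_concentration,
                grid.conditions.n_electrons,
                grid.conditions.e_start,
                grid.conditions.e_reverse,
                grid.conditions.e_step,
            ],
            "num": [num.n_space_nodes, num.grid_expansion,
                    num.domain_factor, num.time_substeps],
        },
        sort_keys=True,
    )
    return hashlib.sha1(payload.encode()).hexdigest()[:16]


def simulate_grid(
    grid: GridSpec,
    numerics: Optional[NumericsConfig] = None,
    cache_dir: Optional[str] = None,
    progress: bool = False,
) -> np.ndarray:
    """Simulate every grid point; returns the (size, n_points) current matrix.

    Results are cached (in memory, and on disk when ``cache_dir`` is given)
    keyed by a hash of all grid, condition and solver parameters, so
    repeated experiments never re-simulate an unchanged grid.
    """
    num = numerics or NumericsConfig()
    key = f"grid_{grid.kind.value}_{_grid_key(grid, num)}"
    if key in _memory_cache:
        return _memory_cache[key]
    path = os.path.join(cache_dir, key + ".npz") if cache_dir else None
    if path and os.path.exists(path):
        X = np.load(path)["X"]
        _memory_cache[key] = X
        return X
    specs = grid.specs()
    X = np.empty((len(specs), grid.conditions.n_points))
    iterator = enumerate(specs)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(list(iterator), desc=f"simulating {grid.kind.value} grid")
    for i, spec in iterator:
        X[i] = simulate_cv(spec, grid.conditions, num).currents
    _memory_cache[key] = X
    if path:
        os.makedirs(cache_dir, exist_ok=True)
        np.savez_compressed(path, X=X)
    return X


def split_dataset(n_items: int, fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint, exhaustive partition of range(n_items); seeded."""
    if not 0.0 < fraction < 1.0:
        raise InvalidInputError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_items)
    n_train = int(round(n_items * fraction))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def bootstrap_ci(errors, n_boot: int = 1000, level: float = 0.95,
                 seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the mean of ``errors``."""
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise InvalidInputError("errors must be nonempty")
    if n_boot < 100:
        raise InvalidInputError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, errors.size, size=(n_boot, errors.size))
    means = errors[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclass
class ErrorSummary:
    """Mean absolute error of one rate-constant group with a bootstrap CI."""

    group: tuple
    n: int
    mean_abs_error: float
    ci_low: float
    ci_high: float


@dataclass
class ExperimentResult:
    """Outcome of one mechanism x preprocessing x estimator experiment."""

    mechanism: Mechanism
    preprocessing: Optional[Preprocessing]
    estimator: Estimator
    n_train: int
    n_test: int
    items: pd.DataFrame  # per-test-item: rate constants, D_true, D_est, abs_error
    mean_abs_error: float
    ci_low: float
    ci_high: float
    per_group: list[ErrorSummary] = field(default_factory=list)

    def summary(self) -> dict:
        """The summary in plain-JSON form."""
        return {
            "mechanism": self.mechanism.value,
            "preprocessing": self.preprocessing.value if self.preprocessing else None,
            "estimator": self.estimator.value,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "mean_abs_error": self.mean_abs_error,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "per_group": [
                {
                    "group": list(g.group),
                    "n": g.n,
                    "mean_abs_error": g.mean_abs_error,
                    "ci_low": g.ci_low,
                    "ci_high": g.ci_high,
                }
                for g in self.per_group
            ],
        }


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def _group_columns(kind: Mechanism) -> list[str]:
    if kind is Mechanism.EC:
        return ["k1"]
    if kind is Mechanism.E_QR:
        return ["ks"]
    return ["k1", "ks"]


@dataclass
class ReducerState:
    """Training-derived state of a dimensionality-reduction route.

    Test (and later, experimental) voltammograms are reduced with the
    statistics of the training half only: the PCA mean/loadings, the global
    amplitude scale, or the per-column feature standardization.
    """

    preprocessing: Preprocessing
    pca: Optional[preprocess.PCAModel] = None
    scale: float = 1.0
    feature_mean: Optional[np.ndarray] = None
    feature_std: Optional[np.ndarray] = None
    downsample_factor: int = 20

    def apply(self, X: np.ndarray, cond: ExperimentConditions) -> np.ndarray:
        if self.preprocessing is Preprocessing.PCA:
            return preprocess.pca_transform(self.pca, X) / self.scale
        if self.preprocessing is Preprocessing.DOWNSAMPLE:
            return np.atleast_2d(X)[:, :: self.downsample_factor] / self.scale
        E = potential_waveform(cond)
        rows = [
            preprocess.extract_peak_features(
                Voltammogram(E, currents, cond)
            ).as_vector()
            for currents in np.atleast_2d(X)
        ]
        return (np.asarray(rows) - self.feature_mean) / self.feature_std


def fit_reducer(
    prep: Preprocessing,
    X_train: np.ndarray,
    cond: ExperimentConditions,
    downsample_factor: int = 20,
    n_components: int = 5,
) -> ReducerState:
    """Fit a reduction route on the training half.

    Outputs are rescaled to O(1) magnitude using training statistics only
    (a single amplitude scale for PCA/downsampling; per-column
    standardization for the mixed-unit manual features)."""
    if prep is Preprocessing.PCA:
        model = preprocess.pca_fit(X_train, n_components)
        scale = float(np.std(preprocess.pca_transform(model, X_train))) or 1.0
        return ReducerState(prep, pca=model, scale=scale)
    if prep is Preprocessing.DOWNSAMPLE:
        scale = float(np.std(X_train[:, ::downsample_factor])) or 1.0
        return ReducerState(prep, scale=scale, downsample_factor=downsample_factor)
    state = ReducerState(prep, feature_mean=np.zeros(7), feature_std=np.ones(7))
    Z = state.apply(X_train, cond)
    sd = Z.std(axis=0)
    sd[sd == 0] = 1.0
    return ReducerState(prep, feature_mean=Z.mean(axis=0), feature_std=sd)


# Coarsened selection grids used inside experiments (full grids are the
# select_hyperparameters defaults; these keep a whole experiment matrix
# affordable on one CPU without changing the selection protocol).
_SVR_C_GRID = tuple(np.logspace(-1.0, 3.0, 5))
_SVR_EPS_FACTORS = (0.0, 1e-3, 1e-2)
_SVR_GAMMA_GRID = tuple(np.logspace(-2.0, 2.0, 5))


def run_mechanism_experiment(
    kind: Mechanism,
    preprocessing: Optional[Preprocessing],
    estimator: Estimator,
    seed: int = DEFAULT_SEED,
    d_stride: int = 1,
    ks_subset: Optional[Sequence[float]] = None,
    numerics: Optional[NumericsConfig] = None,
    cache_dir: Optional[str] = None,
    n_boot: int = 1000,
    progress: bool = False,
) -> ExperimentResult:
    """Run one mechanism x preprocessing x estimator experiment.

    Simulates (or loads from cache) the parameter grid, splits it 50/50,
    fits the preprocessing and the estimator on the training half, predicts
    D on the test half and reports absolute errors in cm^2/s, grouped by
    rate constant with bootstrap confidence intervals.  The classical
    peak-current estimator ignores ``preprocessing``: it reads each test
    voltammogram directly.
    """
    grid = build_grid(kind, d_stride=d_stride, ks_subset=ks_subset)
    specs = grid.specs()
    X = simulate_grid(grid, numerics=numerics, cache_dir=cache_dir, progress=progress)
    y_true = np.array([s.D for s in specs])

    ss = np.random.SeedSequence(seed)
    s_split, s_folds, s_gpr, s_boot = (_child_seed(c) for c in ss.spawn(4))
    train_idx, test_idx = split_dataset(len(specs), 0.5, s_split)

    gcols = _group_columns(kind)
    meta = pd.DataFrame(
        {
            "k1": [s.k1 for s in specs],
            "ks": [s.ks for s in specs],
            "D_true": y_true,
        }
    )

    if estimator is Estimator.NS:
        E = potential_waveform(grid.conditions)
        d_est = np.empty(len(test_idx))
        for j, i in enumerate(test_idx):
            cv = Voltammogram(E, X[i], grid.conditions)
            try:
                d_est[j] = classical.estimate_D_nicholson_shain(cv)
            except Exception:
                d_est[j] = np.nan
    else:
        if preprocessing is None:
            raise InvalidInputError(f"{estimator.value} requires a preprocessing route")
        reducer = fit_reducer(preprocessing, X[train_idx], grid.conditions)
        Z_tr = reducer.apply(X[train_idx], grid.conditions)
        Z_te = reducer.apply(X[test_idx], grid.conditions)
        y_tr = y_true[train_idx] / D_SCALE
        if estimator in (Estimator.SVR_LIN, Estimator.SVR_RBF):
            kernel = svr.Kernel.RBF if estimator is Estimator.SVR_RBF else svr.Kernel.LINEAR
            d = Z_tr.shape[1]
            C, eps, gamma = svr.select_hyperparameters(
                Z_tr,
                y_tr,
                kernel,
                C_grid=_SVR_C_GRID,
                epsilon_grid=np.array(_SVR_EPS_FACTORS) * (np.std(y_tr) or 1.0),
                gamma_grid=np.array(_SVR_GAMMA_GRID) / d if kernel is svr.Kernel.RBF else None,
                seed=s_folds,
            )
            model = svr.svr_train(Z_tr, y_tr, svr.KernelSpec(kernel, gamma), C, eps)
            d_est = svr.svr_predict(model, Z_te) * D_SCALE
        else:
            cov_kind = (
                gpr.Covariance.SQEXP
                if estimator is Estimator.GPR_SQEXP
                else gpr.Covariance.LINEAR
            )
            model = gpr.gpr_train(Z_tr, y_tr, cov_kind, seed=s_gpr)
            d_est = gpr.gpr_predict(model, Z_te)[0] * D_SCALE

    items = meta.iloc[test_idx].reset_index(drop=True)
    items["D_est"] = d_est
    items["abs_error"] = np.abs(items["D_est"] - items["D_true"])

    valid = items["abs_error"].dropna().to_numpy()
    lo, hi = bootstrap_ci(valid, n_boot=n_boot, seed=s_boot)
    per_group = []
    boot_rng = np.random.SeedSequence(s_boot).spawn(items.groupby(gcols).ngroups)
    for (gkey, sub), gss in zip(items.groupby(gcols, sort=True), boot_rng):
        errs = sub["abs_error"].dropna().to_numpy()
        glo, ghi = bootstrap_ci(errs, n_boot=n_boot, seed=_child_seed(gss))
        gkey = gkey if isinstance(gkey, tuple) else (gkey,)
        per_group.append(
            ErrorSummary(
                group=gkey,
                n=len(errs),
                mean_abs_error=float(errs.mean()),
                ci_low=glo,
                ci_high=ghi,
            )
        )
    return ExperimentResult(
        mechanism=kind,
        preprocessing=None if estimator is Estimator.NS else preprocessing,
        estimator=estimator,
        n_train=len(train_idx),
        n_test=len(test_idx),
        items=items,
        mean_abs_error=float(valid.mean()),
        ci_low=lo,
        ci_high=hi,
        per_group=per_group,
    )


@dataclass
class TrainedPipeline:
    """A reduction route plus a trained regressor, ready to estimate D.

    ``normalized`` records whether currents were divided by (c0 * v) before
    reduction; prediction applies the same transformation, which makes the
    pipeline applicable to voltammograms recorded at other concentrations
    and scan rates.
    """

    mechanism: Mechanism
    preprocessing: Preprocessing
    estimator: Estimator
    reducer: ReducerState
    model: object
    conditions: ExperimentConditions
    normalized: bool = False

    def predict(self, cvs: Sequence[Voltammogram]) -> np.ndarray:
        """Estimate D (cm^2/s) for each voltammogram."""
        rows = []
        for cv in cvs:
            x = preprocess.normalize_current(cv) if self.normalized else cv.currents
            rows.append(x)
        Z = self.reducer.apply(np.asarray(rows), cvs[0].conditions)
        if self.estimator in (Estimator.SVR_LIN, Estimator.SVR_RBF):
            return svr.svr_predict(self.model, Z) * D_SCALE
        return gpr.gpr_predict(self.model, Z)[0] * D_SCALE


def train_estimator(
    kind: Mechanism,
    preprocessing: Preprocessing,
    estimator: Estimator,
    seed: int = DEFAULT_SEED,
    d_stride: int = 1,
    ks_subset: Optional[Sequence[float]] = None,
    numerics: Optional[NumericsConfig] = None,
    cache_dir: Optional[str] = None,
    normalize: bool = False,
    progress: bool = False,
) -> TrainedPipeline:
    """Train an estimation pipeline on the full simulated grid of a mechanism.

    Unlike :func:`run_mechanism_experiment` (which holds out a test half to
    measure errors), this uses every grid point for training, the setting
    in which a pipeline is applied to voltammograms from the bench.
    """
    if estimator is Estimator.NS:
        raise InvalidInputError("the peak-current inversion needs no training")
    grid = build_grid(kind, d_stride=d_stride, ks_subset=ks_subset)
    specs = grid.specs()
    X = simulate_grid(grid, numerics=numerics, cache_dir=cache_dir, progress=progress)
    if normalize:
        X = X / (grid.conditions.bulk_concentration * grid.conditions.scan_rate)
    y = np.array([s.D for s in specs]) / D_SCALE

    ss = np.random.SeedSequence(seed)
    s_folds, s_gpr = (_child_seed(c) for c in ss.spawn(2))
    reducer = fit_reducer(preprocessing, X, grid.conditions)
    Z = reducer.apply(X, grid.conditions)
    if estimator in (Estimator.SVR_LIN, Estimator.SVR_RBF):
        kernel = svr.Kernel.RBF if estimator is Estimator.SVR_RBF else svr.Kernel.LINEAR
        d = Z.shape[1]
        C, eps, gamma = svr.select_hyperparameters(
            Z,
            y,
            kernel,
            C_grid=_SVR_C_GRID,
            epsilon_grid=np.array(_SVR_EPS_FACTORS) * (np.std(y) or 1.0),
            gamma_grid=np.array(_SVR_GAMMA_GRID) / d if kernel is svr.Kernel.RBF else None,
            seed=s_folds,
        )
        model = svr.svr_train(Z, y, svr.KernelSpec(kernel, gamma), C, eps)
    else:
        cov_kind = (
            gpr.Covariance.SQEXP if estimator is Estimator.GPR_SQEXP else gpr.Covariance.LINEAR
        )
        model = gpr.gpr_train(Z, y, cov_kind, seed=s_gpr)
    return TrainedPipeline(
        mechanism=kind,
        preprocessing=preprocessing,
        estimator=estimator,
        reducer=reducer,
        model=model,
        conditions=grid.conditions,
        normalized=normalize,
    )
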