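"""Portable JSON serialization for trained SVR and GP models.

One versioned, schema-checked JSON document per model; arrays are stored as
nested lists at full double precision, so save/load round-trips reproduce
predictions exactly.
"""

from __future__ import annotations

import json
import os
from typing import Union

import numpy as np

from .errors import InvalidInputError
from .gpr import Covariance, CovarianceSpec, GPModel
from .svr import Kernel, KernelSpec, SVRModel

__all__ = ["save_model", "load_model", "save_pipeline", "load_pipeline"]

_FORMAT_VERSION = 1


def _arr(a: np.ndarray) -> list:
    return np.asarray(a).tolist()


def _model_doc(model: Union[SVRModel, GPModel]) -> dict:
    if isinstance(model, SVRModel):
        doc = {
            "format_version": _FORMAT_VERSION,
            "model_type": "svr",
            "kernel": {"kind": model.kernel.kind.value, "gamma": model.kernel.gamma},
            "beta": _arr(model.beta),
            "bias": model.bias,
            "training_inputs": _arr(model.training_inputs),
            "C": model.C,
            "epsilon": model.epsilon,
            "converged": model.converged,
        }
    elif isinstance(model, GPModel):
        doc = {
            "format_version": _FORMAT_VERSION,
            "model_type": "gpr",
            "covariance": {
                "kind": model.cov.kind.value,
                "signal_variance": model.cov.signal_variance,
                "length_scale": model.cov.length_scale,
                "noise_variance": model.cov.noise_variance,
            },
            "training_inputs": _arr(model.training_inputs),
            "target_mean": model.target_mean,
            "centered_targets": _arr(model.centered_targets),
            "chol": _arr(model.chol),
            "alpha_vec": _arr(model.alpha_vec),
            "log_marginal": model.log_marginal,
        }
    else:
        raise InvalidInputError(f"cannot serialize object of type {type(model)!r}")
    return doc


def save_model(model: Union[SVRModel, GPModel], path: Union[str, os.PathLike]) -> None:
    """Serialize a trained model to a JSON file."""
    with open(path, "w") as fh:
        json.dump(_model_doc(model), fh)


def _model_from_doc(doc: dict) -> Union[SVRModel, GPModel]:
    version = doc.get("format_version")
    if version != _FORMAT_VERSION:
        raise InvalidInputError(f"unsupported model format version: {version}")
    mtype = doc.get("model_type")
    if mtype == "svr":
        required = {"kernel", "beta", "bias", "training_inputs", "C", "epsilon"}
        missing = required - doc.keys()
        if missing:
            raise InvalidInputError(f"SVR model file missing fields: {sorted(missing)}")
        return SVRModel(
            beta=np.asarray(doc["beta"], dtype=float),
            bias=float(doc["bias"]),
            kernel=KernelSpec(Kernel(doc["kernel"]["kind"]), doc["kernel"]["gamma"]),
            training_inputs=np.asarray(doc["training_inputs"], dtype=float),
            C=float(doc["C"]),
            epsilon=float(doc["epsilon"]),
            converged=bool(doc.get("converged", True)),
        )
    if mtype == "gpr":
        required = {"covariance", "training_inputs", "target_mean",
                    "centered_targets", "chol", "alpha_vec"}
        missing = required - doc.keys()
        if missing:
            raise InvalidInputError(f"GP model file missing fields: {sorted(missing)}")
        cov = doc["covariance"]
        return GPModel(
            cov=CovarianceSpec(
                Covariance(cov["kind"]),
                float(cov["signal_variance"]),
                cov["length_scale"],
                float(cov["noise_variance"]),
            ),
            training_inputs=np.asarray(doc["training_inputs"], dtype=float),
            target_mean=float(doc["target_mean"]),
            centered_targets=np.asarray(doc["centered_targets"], dtype=float),
            chol=np.asarray(doc["chol"], dtype=float),
            alpha_vec=np.asarray(doc["alpha_vec"], dtype=float),
            log_marginal=float(doc.get("log_marginal", np.nan)),
        )
    raise InvalidInputError(f"unknown model_type: {mtype!r}")


def load_model(path: Union[str, os.PathLike]) -> Union[SVRModel, GPModel]:
    """Load a model written by :func:`save_model`, validating the schema."""
    with open(path) as fh:
        doc = json.load(fh)
    return _model_from_doc(doc)


def save_pipeline(pipe, path: Union[str, os.PathLike]) -> None:
    """Serialize a trained estimation pipeline (reducer state + model)."""
    from .pipeline import Preprocessing, TrainedPipeline  # local: avoid cycle

    if not isinstance(pipe, TrainedPipeline):
        raise InvalidInputError(f"cannot serialize object of type {type(pipe)!r}")
    red = pipe.reducer
    reducer_doc = {
        "preprocessing": red.preprocessing.value,
        "scale": red.scale,
        "downsample_factor": red.downsample_factor,
        "feature_mean": None if red.feature_mean is None else _arr(red.feature_mean),
        "feature_std": None if red.feature_std is None else _arr(red.feature_std),
        "pca": None
        if red.pca is None
        else {
            "mean": _arr(red.pca.mean),
            "loadings": _arr(red.pca.loadings),
            "eigenvalues": _arr(red.pca.eigenvalues),
            "explained_variance_ratio": red.pca.explained_variance_ratio,
            "total_variance": red.pca.total_variance,
        },
    }
    cond = pipe.conditions
    doc = {
        "format_version": _FORMAT_VERSION,
        "model_type": "pipeline",
        "mechanism": pipe.mechanism.value,
        "preprocessing": pipe.preprocessing.value,
        "estimator": pipe.estimator.value,
        "normalized": pipe.normalized,
        "conditions": {
            "scan_rate": cond.scan_rate,
            "temperature": cond.temperature,
            "electrode_area": cond.electrode_area,
            "bulk_concentration": cond.bulk_concentration,
            "n_electrons": cond.n_electrons,
            "e_start": cond.e_start,
            "e_reverse": cond.e_reverse,
            "e_step": cond.e_step,
        },
        "reducer": reducer_doc,
        "model": _model_doc(pipe.model),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_pipeline(path: Union[str, os.PathLike]):
    """Load a pipeline written by :func:`save_pipeline`."""
    from .conditions import ExperimentConditions, Mechanism
    from .pipeline import Estimator, Preprocessing, ReducerState, TrainedPipeline
    from .preprocess import PCAModel

    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format_version") != _FORMAT_VERSION or doc.get("model_type") != "pipeline":
        raise InvalidInputError("not a voltdiff pipeline file")
    red = doc["reducer"]
    pca = None
    if red.get("pca") is not None:
        p = red["pca"]
        pca = PCAModel(
            mean=np.asarray(p["mean"], dtype=float),
            loadings=np.asarray(p["loadings"], dtype=float),
            eigenvalues=np.asarray(p["eigenvalues"], dtype=float),
            explained_variance_ratio=float(p["explained_variance_ratio"]),
            total_variance=float(p["total_variance"]),
        )
    reducer = ReducerState(
        preprocessing=Preprocessing(red["preprocessing"]),
        pca=pca,
        scale=float(red["scale"]),
        feature_mean=None if red["feature_mean"] is None
        else np.asarray(red["feature_mean"], dtype=float),
        feature_std=None if red["feature_std"] is None
        else np.asarray(red["feature_std"], dtype=float),
        downsample_factor=int(red["downsample_factor"]),
    )
    return TrainedPipeline(
        mechanism=Mechanism(doc["mechanism"]),
        preprocessing=Preprocessing(doc["preprocessing"]),
        estimator=Estimator(doc["estimator"]),
        reducer=reducer,
        model=_model_from_doc(doc["model"]),
        conditions=ExperimentConditions(**doc["conditions"]),
        normalized=bool(doc["normalized"]),
    )
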