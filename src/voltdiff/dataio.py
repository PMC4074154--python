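"""Reading and writing voltammograms and feature matrices as CSV.

A voltammogram file consists of ``#key=value`` header lines carrying the
experiment conditions (and, when known, the mechanism parameters used to
simulate the trace), followed by a ``potential_V,current_A`` table.  Values
are written with full ``repr`` precision so a write/read cycle is lossless.
"""

from __future__ import annotations

import io
import os
from typing import Optional, TextIO, Union

import numpy as np
import pandas as pd

from .conditions import (
    ExperimentConditions,
    Mechanism,
    MechanismSpec,
    Voltammogram,
)
from .errors import InvalidConditionsError

__all__ = ["write_voltammogram_csv", "read_voltammogram_csv",
           "write_feature_matrix", "read_feature_matrix"]

_COND_KEYS = (
    "scan_rate",
    "temperature",
    "electrode_area",
    "bulk_concentration",
    "n_electrons",
    "e_start",
    "e_reverse",
    "e_step",
)
_MECH_KEYS = ("kind", "e0", "D", "ks", "alpha", "k1")


def write_voltammogram_csv(cv: Voltammogram, path_or_file: Union[str, os.PathLike, TextIO]) -> None:
    """Write a voltammogram to CSV with a ``#key=value`` metadata header."""
    own = isinstance(path_or_file, (str, os.PathLike))
    fh = open(path_or_file, "w") if own else path_or_file
    try:
        cond = cv.conditions
        for key in _COND_KEYS:
            value = getattr(cond, key)
            value = int(value) if key == "n_electrons" else float(value)
            fh.write(f"#{key}={value!r}\n")
        if cv.provenance is not None:
            mech = cv.provenance
            fh.write(f"#kind={mech.kind.value}\n")
            for key in _MECH_KEYS[1:]:
                value = getattr(mech, key)
                if value is not None:
                    fh.write(f"#{key}={float(value)!r}\n")
        fh.write("potential_V,current_A\n")
        for e, i in zip(cv.potentials, cv.currents):
            fh.write(f"{float(e)!r},{float(i)!r}\n")
    finally:
        if own:
            fh.close()


def read_voltammogram_csv(path_or_file: Union[str, os.PathLike, TextIO]) -> Voltammogram:
    """Read a voltammogram written by :func:`write_voltammogram_csv`.

    Validates the triangular-sweep invariants of :class:`Voltammogram`.
    """
    own = isinstance(path_or_file, (str, os.PathLike))
    fh = open(path_or_file, "r") if own else path_or_file
    try:
        meta: dict[str, str] = {}
        data_lines = []
        header_seen = False
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                meta[key.strip()] = value.strip()
            elif not header_seen:
                if line.replace(" ", "") != "potential_V,current_A":
                    raise InvalidConditionsError(f"unexpected column header: {line}")
                header_seen = True
            else:
                data_lines.append(line)
    finally:
        if own:
            fh.close()
    missing = [k for k in _COND_KEYS if k not in meta]
    if missing:
        raise InvalidConditionsError(f"missing condition keys in header: {missing}")
    cond = ExperimentConditions(
        scan_rate=float(meta["scan_rate"]),
        temperature=float(meta["temperature"]),
        electrode_area=float(meta["electrode_area"]),
        bulk_concentration=float(meta["bulk_concentration"]),
        n_electrons=int(meta["n_electrons"]),
        e_start=float(meta["e_start"]),
        e_reverse=float(meta["e_reverse"]),
        e_step=float(meta["e_step"]),
    )
    mech: Optional[MechanismSpec] = None
    if "kind" in meta:
        mech = MechanismSpec(
            kind=Mechanism(meta["kind"]),
            e0=float(meta["e0"]),
            D=float(meta["D"]),
            ks=float(meta["ks"]) if "ks" in meta else None,
            alpha=float(meta.get("alpha", 0.5)),
            k1=float(meta["k1"]) if "k1" in meta else None,
        )
    arr = np.loadtxt(io.StringIO("\n".join(data_lines)), delimiter=",")
    arr = np.atleast_2d(arr)
    return Voltammogram(arr[:, 0], arr[:, 1], cond, provenance=mech)


def write_feature_matrix(path, X, column_names, manifest: Optional[pd.DataFrame] = None) -> None:
    """Persist a feature matrix as CSV with named columns.

    When ``manifest`` is given (one row per matrix row: mechanism parameters
    and the true D), it is prepended column-wise so each CSV row is
    self-describing.
    """
    df = pd.DataFrame(np.asarray(X), columns=list(column_names))
    if manifest is not None:
        if len(manifest) != len(df):
            raise InvalidConditionsError("manifest length does not match matrix rows")
        df = pd.concat([manifest.reset_index(drop=True), df], axis=1)
    df.to_csv(path, index=False)


def read_feature_matrix(path, feature_columns=None) -> tuple[np.ndarray, pd.DataFrame]:
    """Read a feature matrix written by :func:`write_feature_matrix`.

    Returns ``(X, manifest)`` where ``X`` holds the ``feature_columns``
    (default: every column) and ``manifest`` the remaining columns.
    """
    df = pd.read_csv(path)
    if feature_columns is None:
        return df.to_numpy(dtype=float), df.iloc[:, :0]
    X = df[list(feature_columns)].to_numpy(dtype=float)
    manifest = df.drop(columns=list(feature_columns))
    return X, manifest
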