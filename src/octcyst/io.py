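"""Manifest, image and model persistence.

A manifest is a CSV with columns patient_id, scan_index, path and
(optionally) label, one row per B-scan.  Scan indices must be contiguous
and ascending within each patient because decoding consumes ordered
sequences.  Labels use the canonical encoding 1 = cystic, 2 = non-cystic.

Models serialise to JSON with full double precision, so a save/load
round-trip reproduces A, B and pi bit-exactly.
"""

from __future__ import annotations

import json
import os

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import ManifestError
from .hmm import HmmParams

__all__ = ["read_manifest", "load_image", "save_model", "load_model"]

_REQUIRED = ("patient_id", "scan_index", "path")


def read_manifest(path, require_labels: bool = False, check_files: bool = True) -> pd.DataFrame:
    """Load and validate a manifest CSV, sorted by (patient_id, scan_index)."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest missing required column(s): {missing}")
    if require_labels and "label" not in df.columns:
        raise ManifestError("manifest has no label column but labels are required")
    if "label" in df.columns and not df["label"].isin([1, 2]).all():
        raise ManifestError("labels must take values in {1, 2}")
    df = df.sort_values(["patient_id", "scan_index"]).reset_index(drop=True)
    for pid, grp in df.groupby("patient_id"):
        idx = grp["scan_index"].to_numpy()
        if not np.array_equal(np.diff(idx), np.ones(len(idx) - 1, dtype=idx.dtype)):
            raise ManifestError(f"scan_index not contiguous ascending for patient {pid!r}")
    if check_files:
        for p in df["path"]:
            if not os.path.exists(p):
                raise ManifestError(f"image file not found: {p}")
    return df


def load_image(path) -> np.ndarray:
    """Read a TIFF/PNG as a grayscale float array in [0, 1].

    Integer images are rescaled by their dtype maximum; multi-channel inputs
    are reduced by the channel mean.
    """
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2:
        raise ManifestError(f"cannot interpret {path} as a 2-D image")
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / np.iinfo(arr.dtype).max
    arr = arr.astype(float)
    if arr.max() > 1.0:  # float TIFFs stored on an integer scale
        arr = arr / arr.max()
    return arr


def save_model(params: HmmParams, path) -> None:
    params.validate()
    payload = {
        "A": params.A.tolist(),
        "B": params.B.tolist(),
        "pi": params.pi.tolist(),
        "K": params.K,
        "feature_name": params.feature_name,
        "emission_mode": params.emission_mode,
        "emission_mass": params.emission_mass,
        "emission_log_offset": list(params.emission_log_offset),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> HmmParams:
    """Load a model JSON; stochasticity invariants are re-checked on load."""
    with open(path) as fh:
        payload = json.load(fh)
    try:
        params = HmmParams(
            A=np.array(payload["A"], dtype=float),
            B=np.array(payload["B"], dtype=float),
            pi=np.array(payload["pi"], dtype=float),
            feature_name=payload.get("feature_name"),
            emission_mode=payload.get("emission_mode", "dot"),
            emission_mass=payload.get("emission_mass"),
            emission_log_offset=tuple(payload.get("emission_log_offset", (0.0, 0.0))),
        )
    except KeyError as exc:
        raise ManifestError(f"model file missing field {exc}") from exc
    params.validate()
    if params.K != payload.get("K", params.K):
        raise ManifestError("stored K inconsistent with emission matrix width")
    return params
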