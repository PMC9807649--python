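"""Synthetic OCT phantoms and simulated patient-level observation sequences.

Two generators make every downstream stage testable without any dataset
download:

* :func:`generate_phantom_bscan` draws a layered retinal phantom — bright
  horizontal bands on a dark background, optionally containing dark
  elliptical cysts — and corrupts it with multiplicative speckle, the
  dominant noise process in OCT.
* :func:`generate_patient_sequences` samples per-patient sequences of
  non-negative feature vectors driven by a known two-state Markov chain
  (state 1 = cystic scan, state 2 = non-cystic scan), so that the
  supervised HMM estimator can be checked for parameter recovery against
  known ground truth.

Observation vectors are multinomial counts drawn from the active state's
emission profile; normalising summed absolute observations is then a
consistent estimator of the emission matrix.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import ParameterError

__all__ = [
    "PhantomSpec",
    "SequenceSimSpec",
    "generate_phantom_bscan",
    "generate_patient_sequences",
    "simulate_phantom_patients",
    "write_phantom_dataset",
    "write_sequences",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise parameters of a phantom B-scan.

    Defaults mirror a typical SD-OCT B-scan frame (496 rows x 512 columns).
    """

    height: int = 496
    width: int = 512
    n_layers: int = 5
    n_cysts: int = 2
    cyst_axes_range: tuple[int, int] = (4, 20)
    speckle_sigma: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ParameterError("phantom height and width must be positive")
        if self.n_layers <= 0:
            raise ParameterError("n_layers must be positive")
        if self.n_cysts < 0:
            raise ParameterError("n_cysts must be non-negative")
        lo, hi = self.cyst_axes_range
        if lo <= 0 or lo > hi:
            raise ParameterError("cyst_axes_range must satisfy 0 < min <= max")
        if self.speckle_sigma < 0:
            raise ParameterError("speckle_sigma must be non-negative")


@dataclass(frozen=True)
class SequenceSimSpec:
    """Ground-truth chain and emission profiles for sequence simulation.

    ``obs_total`` is the count mass of each simulated observation vector
    (multinomial draws per scan).  ``sign_flip_frac`` optionally negates a
    random fraction of entries, exercising the absolute-value step of the
    training rule.
    """

    A_true: np.ndarray
    pi_true: np.ndarray
    B_true: np.ndarray
    T: int = 31
    n_patients: int = 200
    obs_total: int = 500
    sign_flip_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "A_true", np.asarray(self.A_true, dtype=float))
        object.__setattr__(self, "pi_true", np.asarray(self.pi_true, dtype=float))
        object.__setattr__(self, "B_true", np.asarray(self.B_true, dtype=float))

    def validate(self) -> None:
        A, pi, B = self.A_true, self.pi_true, self.B_true
        if A.shape != (2, 2):
            raise ParameterError("A_true must be 2x2")
        if pi.shape != (2,):
            raise ParameterError("pi_true must have length 2")
        if B.ndim != 2 or B.shape[0] != 2:
            raise ParameterError("B_true must be 2xK")
        for name, M in (("A_true", A), ("B_true", B)):
            if np.any(M < 0) or not np.allclose(M.sum(axis=1), 1.0, atol=1e-12):
                raise ParameterError(f"rows of {name} must be non-negative and sum to 1")
        if np.any(pi < 0) or not np.isclose(pi.sum(), 1.0, atol=1e-12):
            raise ParameterError("pi_true must be a probability vector")
        if self.T < 1:
            raise ParameterError("T must be >= 1")
        if self.n_patients < 1:
            raise ParameterError("n_patients must be >= 1")
        if self.obs_total <= 0:
            raise ParameterError("obs_total must be positive")
        if not 0.0 <= self.sign_flip_frac <= 1.0:
            raise ParameterError("sign_flip_frac must lie in [0, 1]")


def _draw_bands(spec: PhantomSpec, rng: np.random.Generator):
    """Place ``n_layers`` bright bands in the central half of the frame.

    Returns (image, list of (row_start, row_stop, intensity)).
    """
    img = np.full((spec.height, spec.width), 0.05, dtype=float)
    top = int(0.2 * spec.height)
    bottom = int(0.8 * spec.height)
    span = bottom - top
    slot = max(span // spec.n_layers, 2)
    thickness = max(slot // 2, 1)
    bands = []
    for i in range(spec.n_layers):
        r0 = top + i * slot
        r1 = min(r0 + thickness, spec.height)
        if r0 >= spec.height:
            break
        intensity = rng.uniform(0.55, 0.85)
        img[r0:r1, :] = intensity
        bands.append((r0, r1, intensity))
    return img, bands


def generate_phantom_bscan(spec: PhantomSpec):
    """Draw one phantom B-scan.

    Returns
    -------
    image : (height, width) float array in [0, 1]
        Layered phantom with multiplicative speckle.
    cyst_mask : (height, width) bool array
        True inside drawn cysts.
    label : int
        1 (cystic) iff the mask is non-empty, else 2 (non-cystic).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    img, bands = _draw_bands(spec, rng)
    mask = np.zeros(img.shape, dtype=bool)

    lo, hi = spec.cyst_axes_range
    rows, cols = np.ogrid[: spec.height, : spec.width]
    for _ in range(spec.n_cysts):
        r0, r1, _band_int = bands[rng.integers(len(bands))]
        a_r = int(rng.integers(lo, hi + 1))  # vertical semi-axis
        a_c = int(rng.integers(lo, hi + 1))  # horizontal semi-axis
        cr = int(rng.integers(r0, r1))
        cc = int(rng.integers(0, spec.width))
        ellipse = ((rows - cr) / a_r) ** 2 + ((cols - cc) / a_c) ** 2 <= 1.0
        img[ellipse] = 0.10  # cyst fluid: darker than any band
        mask |= ellipse

    if spec.speckle_sigma > 0:
        img = img * (1.0 + spec.speckle_sigma * rng.standard_normal(img.shape))
        img = np.clip(img, 0.0, 1.0)
    label = 1 if mask.any() else 2
    return img, mask, label


def generate_patient_sequences(spec: SequenceSimSpec):
    """Simulate ``n_patients`` hidden-state sequences with observations.

    Each patient contributes a length-``T`` state path over {1, 2} sampled
    from (``pi_true``, ``A_true``) and, per scan, a multinomial count vector
    with ``obs_total`` draws from the active state's row of ``B_true``.

    Returns a list of ``(states, observations)`` pairs where ``states`` is an
    int array over {1, 2} and ``observations`` is a (T, K) float array.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.n_patients):
        states = np.empty(spec.T, dtype=int)
        states[0] = rng.choice(2, p=spec.pi_true) + 1
        for t in range(1, spec.T):
            states[t] = rng.choice(2, p=spec.A_true[states[t - 1] - 1]) + 1
        obs = np.empty((spec.T, spec.B_true.shape[1]), dtype=float)
        for t in range(spec.T):
            obs[t] = rng.multinomial(spec.obs_total, spec.B_true[states[t] - 1])
        if spec.sign_flip_frac > 0:
            flips = rng.random(obs.shape) < spec.sign_flip_frac
            obs[flips] *= -1.0
        out.append((states, obs))
    return out


def simulate_phantom_patients(
    n_patients: int,
    T: int,
    A: np.ndarray,
    pi: np.ndarray,
    phantom: PhantomSpec,
    seed: int = 0,
):
    """Markov-chain-driven phantom sequences: the full study design in miniature.

    The cystic/non-cystic status of consecutive scans follows the chain
    (``pi``, ``A``); cystic scans are phantoms with cysts drawn, non-cystic
    scans have none.  Yields ``(patient_id, images, labels)`` with labels in
    {1, 2}.
    """
    rng = np.random.default_rng(seed)
    A = np.asarray(A, dtype=float)
    pi = np.asarray(pi, dtype=float)
    for p in range(n_patients):
        states = np.empty(T, dtype=int)
        states[0] = rng.choice(2, p=pi) + 1
        for t in range(1, T):
            states[t] = rng.choice(2, p=A[states[t - 1] - 1]) + 1
        images = []
        for t in range(T):
            n_cysts = phantom.n_cysts if states[t] == 1 else 0
            sub = PhantomSpec(
                height=phantom.height,
                width=phantom.width,
                n_layers=phantom.n_layers,
                n_cysts=max(n_cysts, 1) if states[t] == 1 else 0,
                cyst_axes_range=phantom.cyst_axes_range,
                speckle_sigma=phantom.speckle_sigma,
                seed=int(rng.integers(2**31 - 1)),
            )
            img, _mask, _label = generate_phantom_bscan(sub)
            images.append(img)
        yield f"P{p:03d}", images, states.copy()


def write_phantom_dataset(
    out_dir: str,
    n_patients: int,
    T: int,
    A: np.ndarray,
    pi: np.ndarray,
    phantom: PhantomSpec,
    seed: int = 0,
    fmt: str = "tiff",
) -> pd.DataFrame:
    """Write a phantom dataset to disk and return its manifest.

    Images are 8-bit grayscale TIFF (or PNG); the manifest CSV has columns
    patient_id, scan_index, path, label with label 1=cystic, 2=non-cystic.
    """
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for pid, images, labels in simulate_phantom_patients(n_patients, T, A, pi, phantom, seed):
        for t, (img, lab) in enumerate(zip(images, labels)):
            arr = np.round(img * 255).astype(np.uint8)
            fname = f"{pid}_{t:03d}.{ 'tif' if fmt == 'tiff' else 'png' }"
            path = os.path.join(out_dir, fname)
            if fmt == "tiff":
                tifffile.imwrite(path, arr)
            else:
                iio.imwrite(path, arr)
            rows.append({"patient_id": pid, "scan_index": t, "path": path, "label": int(lab)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest


def write_sequences(out_dir: str, sequences, prefix: str = "patient") -> None:
    """Write simulated sequences: one observation matrix CSV per patient plus
    a combined states CSV."""
    os.makedirs(out_dir, exist_ok=True)
    state_rows = []
    for i, (states, obs) in enumerate(sequences):
        pid = f"{prefix}{i:03d}"
        np.savetxt(os.path.join(out_dir, f"{pid}_obs.csv"), obs, delimiter=",")
        for t, s in enumerate(states):
            state_rows.append({"patient_id": pid, "scan_index": t, "state": int(s)})
    pd.DataFrame(state_rows).to_csv(os.path.join(out_dir, "states.csv"), index=False)
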