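"""Supervised two-state hidden Markov model over ordered B-scan sequences.

The hidden state of scan ``t`` is its cystic status: state 1 = cystic,
state 2 = non-cystic.  Because the presence of a cyst in one B-scan strongly
predicts its presence in the next, an ergodic two-state chain with
per-state emission profiles over the components of a non-negative feature
vector is a natural model.  Estimation is fully supervised — no
Baum-Welch — and proceeds per patient, then averages:

* ``pi_i`` is the one-hot indicator of the first scan's label,
* the transition matrix ``A_i`` contains the empirical transition
  frequencies between consecutive labels,
* emission row j of ``B_i`` is the normalised sum of the absolute feature
  vectors of the scans with label j (absolute values are taken first
  because raw embeddings can be negative, while probabilities cannot),
* the final parameters are the element-wise means of the per-patient
  estimates, which keeps every row stochastic.

Decoding uses the Viterbi algorithm (implemented in the log domain for
numerical stability):

    delta_1(i) = pi_i * b_i(o_1)
    delta_t(j) = max_i(delta_{t-1}(i) * a_ij) * b_j(o_t)
    phi_t(j)   = argmax_i(delta_{t-1}(i) * a_ij)

with the terminal state the argmax of the last delta column and the path
recovered by backtracking through phi.  All argmax ties break toward
state 1 (the lowest index), deterministically.

The per-vector emission score ``b_j(o)`` reduces a whole observation vector
to a scalar.  The default is the inner product of the emission row with the
normalised absolute observation — the expected emission probability under
the observation's own weight profile, consistent with how B is estimated.
A multinomial log-likelihood reduction is available via
``emission_mode="multinomial"``.

The statsmodels-style surface is :class:`CystHMM` (model, holds the
training sequences) and :class:`CystHMMResults` (fitted parameters,
diagnostics, ``summary()``, ``decode``/``posterior``/``simulate``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DecodingError, DegenerateError, DimensionError, ParameterError

__all__ = [
    "HmmParams",
    "PatientEstimate",
    "ViterbiTrellis",
    "estimate_patient_params",
    "train",
    "emission_score",
    "viterbi",
    "posterior_scores",
    "CystHMM",
    "CystHMMResults",
]

_STOCH_ATOL = 1e-9


@dataclass
class HmmParams:
    """lambda = (A, B, pi).  State 1 = cystic, state 2 = non-cystic."""

    A: np.ndarray  # (2, 2) row-stochastic transition matrix
    B: np.ndarray  # (2, K) row-stochastic emission profiles
    pi: np.ndarray  # (2,) initial distribution
    feature_name: str | None = None
    emission_mode: str = "dot"
    # multinomial mode only: rescale each |o| to this total mass so scans
    # with large raw feature magnitudes are not treated as more informative
    emission_mass: float | None = None
    # balanced scaled-likelihood calibration: constants subtracted from the
    # per-state log emission scores so that the class-conditional
    # log-likelihood ratio is centred on the training scans (estimated by
    # fit() when calibration is requested; zero means uncalibrated)
    emission_log_offset: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)

    @property
    def K(self) -> int:
        return self.B.shape[1]

    def validate(self) -> None:
        if self.A.shape != (2, 2) or self.B.ndim != 2 or self.B.shape[0] != 2 or self.pi.shape != (2,):
            raise DimensionError("A must be 2x2, B 2xK, pi length 2")
        for name, M in (("A", self.A), ("B", self.B)):
            if np.any(M < 0) or np.any(M > 1):
                raise ParameterError(f"entries of {name} must lie in [0, 1]")
            if not np.allclose(M.sum(axis=1), 1.0, atol=_STOCH_ATOL):
                raise ParameterError(f"rows of {name} must sum to 1")
        if np.any(self.pi < 0) or not np.isclose(self.pi.sum(), 1.0, atol=_STOCH_ATOL):
            raise ParameterError("pi must be a probability vector")


@dataclass
class PatientEstimate:
    """Per-patient parameter estimate plus fallback diagnostics.

    ``fallback_A`` / ``fallback_B`` list the states (1-based) whose
    transition or emission row could not be estimated from this patient
    (no transitions out of the state / no scans with that label) and was
    set to uniform.
    """

    A: np.ndarray
    B: np.ndarray
    pi: np.ndarray
    fallback_A: tuple[int, ...] = ()
    fallback_B: tuple[int, ...] = ()


@dataclass
class ViterbiTrellis:
    delta: np.ndarray  # (2, T) log-domain path scores
    phi: np.ndarray  # (2, T) backpointers (0 in the first column)
    qP: np.ndarray  # (T,) decoded states over {1, 2}


def _check_sequence(labels, observations):
    labels = np.asarray(labels, dtype=int)
    observations = np.asarray(observations, dtype=float)
    if labels.ndim != 1 or labels.size == 0:
        raise DegenerateError("empty label sequence")
    if not np.isin(labels, (1, 2)).all():
        raise ParameterError("labels must take values in {1, 2}")
    if observations.ndim != 2 or observations.shape[0] != labels.size:
        raise DimensionError("observations must be (T, K) aligned with labels")
    return labels, observations


def estimate_patient_params(labels, observations) -> PatientEstimate:
    """Supervised per-patient estimate of (A_i, B_i, pi_i).

    Transition probabilities are counting ratios: a_jk = (# transitions
    j -> k) / (# transitions out of j).  Emission row j is the normalised
    element-wise sum of |o_t| over scans with label j.  A state with no
    outgoing transitions (or no scans) gets a uniform row, recorded in the
    fallback fields.
    """
    labels, observations = _check_sequence(labels, observations)
    T, K = observations.shape

    pi = np.array([1.0, 0.0]) if labels[0] == 1 else np.array([0.0, 1.0])

    counts = np.zeros((2, 2))
    for t in range(T - 1):
        counts[labels[t] - 1, labels[t + 1] - 1] += 1.0
    A = np.empty((2, 2))
    fallback_A = []
    for j in range(2):
        row_sum = counts[j].sum()
        if row_sum > 0:
            A[j] = counts[j] / row_sum
        else:
            A[j] = 0.5
            fallback_A.append(j + 1)

    B = np.empty((2, K))
    fallback_B = []
    abs_obs = np.abs(observations)
    for j in range(2):
        sel = labels == j + 1
        if sel.any():
            summed = abs_obs[sel].sum(axis=0)
            total = summed.sum()
            if total == 0:
                raise DegenerateError(
                    f"all-zero summed |o| for state {j + 1}: emission row undefined"
                )
            B[j] = summed / total
        else:
            B[j] = 1.0 / K
            fallback_B.append(j + 1)
    return PatientEstimate(A=A, B=B, pi=pi, fallback_A=tuple(fallback_A), fallback_B=tuple(fallback_B))


def train(
    patient_data,
    feature_name: str | None = None,
    emission_mode: str = "dot",
    emission_mass: float | None = None,
    exclude_fallback_rows: bool = False,
) -> HmmParams:
    """Average per-patient estimates into the final model parameters.

    ``patient_data`` is a list of ``(labels, observations)`` pairs (or
    :class:`PatientEstimate` objects).  With ``exclude_fallback_rows`` the
    averages for each row skip patients whose row was a uniform fallback;
    a row with no informative patient at all stays uniform.
    """
    if len(patient_data) == 0:
        raise DegenerateError("need at least one patient")
    ests = [
        p if isinstance(p, PatientEstimate) else estimate_patient_params(*p)
        for p in patient_data
    ]
    Ks = {e.B.shape[1] for e in ests}
    if len(Ks) != 1:
        raise DimensionError(f"inconsistent observation lengths across patients: {sorted(Ks)}")
    N = len(ests)
    if not exclude_fallback_rows:
        A = sum(e.A for e in ests) / N
        B = sum(e.B for e in ests) / N
    else:
        A = np.empty((2, 2))
        B = np.empty((2, Ks.pop()))
        for j in range(2):
            a_rows = [e.A[j] for e in ests if (j + 1) not in e.fallback_A]
            b_rows = [e.B[j] for e in ests if (j + 1) not in e.fallback_B]
            A[j] = np.mean(a_rows, axis=0) if a_rows else 0.5
            B[j] = np.mean(b_rows, axis=0) if b_rows else 1.0 / B.shape[1]
    pi = sum(e.pi for e in ests) / N
    params = HmmParams(A=A, B=B, pi=pi, feature_name=feature_name,
                       emission_mode=emission_mode, emission_mass=emission_mass)
    params.validate()
    return params


def emission_score(B_row, o) -> float:
    """Default per-vector emission probability: <B_row, |o| / sum|o|>.

    Lies in (0, 1] for a stochastic ``B_row``; equals B_row[k] for a one-hot
    observation at index k and 1/K for a uniform emission row.
    """
    B_row = np.asarray(B_row, dtype=float)
    o = np.asarray(o, dtype=float)
    if B_row.shape != o.shape:
        raise DimensionError("B_row and o must have equal length")
    w = np.abs(o)
    total = w.sum()
    if total == 0:
        raise DegenerateError("all-zero observation vector has no emission score")
    return float(B_row @ (w / total))


def _log_emissions(params: HmmParams, observations: np.ndarray, eps: float = 1e-300) -> np.ndarray:
    """(2, T) log emission scores under the configured reduction."""
    observations = np.asarray(observations, dtype=float)
    if observations.ndim != 2 or observations.shape[1] != params.K:
        raise DimensionError(f"observations must be (T, {params.K})")
    w = np.abs(observations)
    totals = w.sum(axis=1)
    if np.any(totals == 0):
        raise DegenerateError("observation vector(s) with zero mass cannot be scored")
    if params.emission_mode == "dot":
        scores = params.B @ (w / totals[None].T).T  # (2, T)
        with np.errstate(divide="ignore"):
            return np.log(np.maximum(scores, 0.0))
    if params.emission_mode == "multinomial":
        # sum_k |o_k| log B[j, k]; eps-smoothed zeros so a single unseen
        # component does not annihilate the state
        logB = np.log(np.maximum(params.B, eps))
        if params.emission_mass is not None:
            w = w / totals[:, None] * params.emission_mass
        logb = logB @ w.T
        off = np.asarray(params.emission_log_offset, dtype=float)
        return logb - off[:, None]
    raise ParameterError(f"unknown emission mode {params.emission_mode!r}")


def viterbi(params: HmmParams, observations) -> ViterbiTrellis:
    """Most probable hidden-state path, log-domain, ties toward state 1."""
    params.validate()
    logb = _log_emissions(params, observations)
    T = logb.shape[1]
    with np.errstate(divide="ignore"):
        logA = np.log(params.A)
        logpi = np.log(params.pi)
    delta = np.full((2, T), -np.inf)
    phi = np.zeros((2, T), dtype=int)
    delta[:, 0] = logpi + logb[:, 0]
    for t in range(1, T):
        # cand[i, j] = delta_{t-1}(i) + log a_ij
        cand = delta[:, t - 1][:, None] + logA
        phi[:, t] = np.argmax(cand, axis=0)  # first max index = state 1 on ties
        delta[:, t] = cand[phi[:, t], [0, 1]] + logb[:, t]
    if np.all(np.isinf(delta[:, -1])):
        raise DecodingError("all paths have zero probability; decoding failed")
    qP = np.empty(T, dtype=int)
    qP[-1] = int(np.argmax(delta[:, -1]))
    for t in range(T - 2, -1, -1):
        qP[t] = phi[qP[t + 1], t + 1]
    return ViterbiTrellis(delta=delta, phi=phi, qP=qP + 1)


def posterior_scores(params: HmmParams, observations) -> np.ndarray:
    """Forward-backward smoothing probability of the cystic state per scan.

    Uses the same emission reduction as :func:`viterbi`; the returned values
    lie in [0, 1] and serve as continuous per-scan scores for ROC analysis.
    """
    params.validate()
    logb = _log_emissions(params, observations)
    b = np.exp(logb - logb.max(axis=0, keepdims=True))  # column-rescaled, safe
    T = b.shape[1]
    A = params.A
    alpha = np.empty((2, T))
    c = np.empty(T)
    alpha[:, 0] = params.pi * b[:, 0]
    c[0] = alpha[:, 0].sum()
    if c[0] == 0:
        raise DecodingError("zero forward mass at t=0")
    alpha[:, 0] /= c[0]
    for t in range(1, T):
        alpha[:, t] = (A.T @ alpha[:, t - 1]) * b[:, t]
        c[t] = alpha[:, t].sum()
        if c[t] == 0:
            raise DecodingError(f"zero forward mass at t={t}")
        alpha[:, t] /= c[t]
    beta = np.empty((2, T))
    beta[:, -1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[:, t] = A @ (b[:, t + 1] * beta[:, t + 1]) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=0, keepdims=True)
    return gamma[0]


# ---------------------------------------------------------------------------
# statsmodels-style surface


class CystHMM:
    """Supervised cyst-identification HMM over per-patient scan sequences.

    Parameters
    ----------
    patient_data : list of (labels, observations)
        One entry per training patient; ``labels`` is the ordered cystic
        status sequence over {1, 2} and ``observations`` the matching (T, K)
        feature matrix.
    feature_name : str, optional
        Name of the feature backend the observations came from.
    emission_mode : {"dot", "multinomial"}
        Per-vector emission reduction used at decode time.
    exclude_fallback_rows : bool
        Skip uninformative per-patient rows when averaging.
    """

    def __init__(
        self,
        patient_data,
        feature_name: str | None = None,
        emission_mode: str = "dot",
        emission_mass: float | None = None,
        calibrate_emissions: bool = False,
        exclude_fallback_rows: bool = False,
    ):
        self.patient_data = [( np.asarray(l, dtype=int), np.asarray(o, dtype=float)) for l, o in patient_data]
        self.feature_name = feature_name
        self.emission_mode = emission_mode
        self.emission_mass = emission_mass
        self.calibrate_emissions = calibrate_emissions
        self.exclude_fallback_rows = exclude_fallback_rows

    @classmethod
    def from_dataframe(cls, df, feature_columns, label_column="label",
                       patient_column="patient_id", order_column="scan_index", **kwargs):
        """Build the model from a long-format DataFrame (one row per scan)."""
        data = []
        for _pid, grp in df.groupby(patient_column, sort=True):
            grp = grp.sort_values(order_column)
            data.append((grp[label_column].to_numpy(int), grp[feature_columns].to_numpy(float)))
        return cls(data, **kwargs)

    def fit(self) -> "CystHMMResults":
        estimates = [estimate_patient_params(l, o) for l, o in self.patient_data]
        params = train(
            estimates,
            feature_name=self.feature_name,
            emission_mode=self.emission_mode,
            emission_mass=self.emission_mass,
            exclude_fallback_rows=self.exclude_fallback_rows,
        )
        if self.calibrate_emissions:
            if self.emission_mode != "multinomial":
                raise ParameterError(
                    "emission calibration applies to the multinomial reduction only"
                )
            params.emission_log_offset = self._calibration_offsets(params)
        return CystHMMResults(self, params, estimates)

    def _calibration_offsets(self, params: HmmParams) -> tuple[float, float]:
        """Balanced scaled-likelihood offsets.

        The generative emission rows can carry a common bias (one row scoring
        higher than the other on every scan) when the two per-state profiles
        overlap strongly.  The offsets centre the class-conditional
        log-likelihood ratio on the training scans, leaving its separation
        untouched: c = (E[LLR | cystic] + E[LLR | non-cystic]) / 2 is split
        evenly between the two states.
        """
        llr_by_state = {1: [], 2: []}
        for labels, obs in self.patient_data:
            logb = _log_emissions(params, obs)
            llr = logb[0] - logb[1]
            for j in (1, 2):
                llr_by_state[j].extend(llr[labels == j])
        means = [np.mean(llr_by_state[j]) if llr_by_state[j] else 0.0 for j in (1, 2)]
        c = float(np.mean(means))
        return (c / 2.0, -c / 2.0)


class CystHMMResults:
    """Fitted parameters plus decoding, simulation and reporting."""

    def __init__(self, model: CystHMM, params: HmmParams, patient_estimates):
        self.model = model
        self.params = params
        self.patient_estimates = list(patient_estimates)

    # --- estimates -------------------------------------------------------
    @property
    def transition_matrix(self) -> np.ndarray:
        return self.params.A

    @property
    def emission_matrix(self) -> np.ndarray:
        return self.params.B

    @property
    def initial_probs(self) -> np.ndarray:
        return self.params.pi

    @property
    def n_patients(self) -> int:
        return len(self.patient_estimates)

    @property
    def n_scans(self) -> int:
        return sum(len(l) for l, _ in self.model.patient_data)

    @property
    def fallback_fraction(self) -> float:
        """Fraction of patients needing any uniform fallback row."""
        if not self.patient_estimates:
            return 0.0
        flagged = sum(1 for e in self.patient_estimates if e.fallback_A or e.fallback_B)
        return flagged / len(self.patient_estimates)

    def transition_se(self) -> np.ndarray:
        """Between-patient standard error of each transition probability."""
        As = np.stack([e.A for e in self.patient_estimates])
        n = As.shape[0]
        if n < 2:
            return np.full((2, 2), np.nan)
        return As.std(axis=0, ddof=1) / np.sqrt(n)

    # --- inference -------------------------------------------------------
    def decode(self, observations) -> np.ndarray:
        """Viterbi path over {1, 2} for one patient's observation matrix."""
        return viterbi(self.params, observations).qP

    def posterior(self, observations) -> np.ndarray:
        """Smoothed per-scan probability of the cystic state."""
        return posterior_scores(self.params, observations)

    def simulate(self, T: int, n_patients: int = 1, obs_total: int = 500, seed: int = 0):
        """Sample synthetic patients from the fitted model."""
        from .synthetic import SequenceSimSpec, generate_patient_sequences

        spec = SequenceSimSpec(
            A_true=self.params.A, pi_true=self.params.pi, B_true=self.params.B,
            T=T, n_patients=n_patients, obs_total=obs_total, seed=seed,
        )
        return generate_patient_sequences(spec)

    def plot_posterior(self, observations, truth=None, ax=None):
        """Plot the per-scan cystic posterior for one patient."""
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots(figsize=(6, 2.5))
        post = self.posterior(observations)
        ax.plot(np.arange(1, len(post) + 1), post, marker="o", label="P(cystic)")
        if truth is not None:
            truth = np.asarray(truth)
            ax.step(np.arange(1, len(truth) + 1), (truth == 1).astype(float),
                    where="mid", alpha=0.5, label="truth")
        ax.set_xlabel("scan index")
        ax.set_ylabel("posterior")
        ax.set_ylim(-0.05, 1.05)
        ax.legend()
        return ax

    def save(self, path) -> None:
        from .io import save_model

        save_model(self.params, path)

    def summary(self) -> str:
        p = self.params
        se = self.transition_se()
        lines = [
            "        Cyst-identification HMM (supervised)        ",
            "=" * 50,
            f"Patients: {self.n_patients}    Scans: {self.n_scans}    K: {p.K}",
            f"Feature: {p.feature_name or '-'}    Emission mode: {p.emission_mode}",
            f"Patients with fallback rows: {self.fallback_fraction:.1%}",
            "-" * 50,
            "Transition matrix A (rows: from cystic, from non-cystic)",
            f"  a11={p.A[0,0]:.4f} (se {se[0,0]:.4f})   a12={p.A[0,1]:.4f} (se {se[0,1]:.4f})",
            f"  a21={p.A[1,0]:.4f} (se {se[1,0]:.4f})   a22={p.A[1,1]:.4f} (se {se[1,1]:.4f})",
            f"Initial probabilities pi: [{p.pi[0]:.4f}, {p.pi[1]:.4f}]",
            "-" * 50,
            f"Emission rows: stochastic over {p.K} components;",
            f"  max|B1-B2| component gap: {np.abs(p.B[0] - p.B[1]).max():.4e}",
            "=" * 50,
        ]
        return "\n".join(lines)
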