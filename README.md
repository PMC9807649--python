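# octcyst

Identification of cyst-containing B-scans in retinal optical coherence
tomography (OCT) volumes with a supervised two-state hidden Markov model.

In diseases such as diabetic macular edema and age-related macular
degeneration, fluid-filled cysts form between and inside the retinal
layers.  An OCT acquisition yields tens of consecutive cross-sectional
B-scans per eye, and an ophthalmologist's first task is simply finding the
scans that contain cysts.  Because consecutive B-scans sample adjacent
tissue slices, the cystic status of one scan strongly predicts the status
of the next — which makes per-scan classification wasteful and a Markov
chain over the scan sequence natural.

## Model

The hidden state of scan *t* is q₁ (cystic) or q₂ (non-cystic); the
observation is a per-scan feature vector **o**ₜ with K non-negative (after
|·|) components.  The model is an ergodic HMM λ = (A, B, π) with

* A — 2×2 transition matrix (a₁₁ = probability a cystic scan follows a
  cystic scan, …), rows stochastic;
* B — 2×K emission matrix, row *j* a probability profile over the feature
  components for state *j*;
* π — initial state distribution.

Training is fully supervised, per patient *i* and then averaged:
πᵢ one-hot in the first scan's label; Aᵢ from transition counts between
consecutive labels; row *j* of Bᵢ the normalised sum of |**o**ₜ| over scans
labelled *j*; finally A = Σᵢ Aᵢ / N (same for B, π).  Decoding runs the
Viterbi recursion δₜ(j) = maxᵢ(δₜ₋₁(i)·aᵢⱼ)·bⱼ(**o**ₜ) in the log domain
per test patient; smoothed per-scan posteriors P(q₁ | **o**₁…**o**_T) from
the forward–backward recursions provide continuous scores for ROC
analysis.

Around the model, the package implements the full pipeline: margin
cropping and a colorize-and-resize transform (227×227×3) for deep-feature
backends; local feature extraction (Sobel gradient field, HOG, Harris,
Min-Eigen, FAST, determinant-of-Hessian) with grid pooling of keypoints
into fixed-length vectors and a plug-in contract for pretrained
embeddings; an SVM/KNN feature-ranking harness on patient-level 80/20
splits; confusion metrics, ROC/AUC and DeLong's paired AUC test; and a
synthetic module that generates layered speckle phantoms and
Markov-driven feature sequences so everything is testable without data
downloads.

## Worked example

Fit the model to a simulated 200-patient cohort (31 scans per patient,
K = 20, persistent cystic state with a₁₁ = a₂₂ = 0.9) and decode a
held-in patient:

```python
import numpy as np
from octcyst import CystHMM, SequenceSimSpec, generate_patient_sequences

rng = np.random.default_rng(0)
spec = SequenceSimSpec(
    A_true=np.array([[0.9, 0.1], [0.1, 0.9]]),
    pi_true=np.array([0.5, 0.5]),
    B_true=rng.dirichlet(np.ones(20), size=2),
    T=31, n_patients=200, obs_total=500, seed=0,
)
cohort = generate_patient_sequences(spec)
results = CystHMM(cohort, feature_name="simulated",
                  emission_mode="multinomial").fit()
print(results.summary())
states, obs = cohort[0]
decoded = results.decode(obs)
print("agreement: %.3f" % (decoded == states).mean())
```

prints

```
        Cyst-identification HMM (supervised)
==================================================
Patients: 200    Scans: 6200    K: 20
Feature: simulated    Emission mode: multinomial
Patients with fallback rows: 4.5%
--------------------------------------------------
Transition matrix A (rows: from cystic, from non-cystic)
  a11=0.8453 (se 0.0113)   a12=0.1547 (se 0.0113)
  a21=0.1639 (se 0.0137)   a22=0.8361 (se 0.0137)
Initial probabilities pi: [0.4800, 0.5200]
--------------------------------------------------
Emission rows: stochastic over 20 components;
  max|B1-B2| component gap: 2.0086e-01
==================================================
agreement: 1.000
```

The estimated a₁₁ ≈ 0.85 recovers the generator's cyst persistence (0.9,
less the short-sequence bias of per-patient ratio averaging discussed in
`docs/methods.md`); the decoded state sequence of the first patient
matches the simulated truth exactly.

A command-line surface mirrors the pipeline end to end:

```bash
octcyst simulate --out-dir data --n-patients 10 -T 12 --seed 0
octcyst extract --manifest data/manifest.csv --method hog --out feats.csv
octcyst train-hmm --features feats.csv --out model.json
octcyst decode --model model.json --features feats.csv --out states.csv
octcyst evaluate --pred states.csv --truth data/manifest.csv
```

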