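"""Cognitive-state classification of EEG epochs with an RBF-feature network.

Architecture: a spatial-transform stage that maps each raw epoch to a small
gain-invariant feature vector (alpha power, beta power, log alpha/beta ratio,
spectral entropy computed after per-epoch amplitude standardisation), a bank
of radial-basis prototype units whose centers come from seeded k-means, and a
one-hidden-layer MLP head on the RBF activations.  An optional exponential
smoothing of per-epoch class scores across consecutive epochs exploits the
fact that cognitive states evolve as sequences rather than isolated windows.

All randomness (k-means initialisation, MLP weights) is isolated behind a
single seed, so refitting with the same seed reproduces the parameters
exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from . import spectral
from .synth import ALPHA_BAND, BETA_BAND, EEG_STATE_PRESETS, EegStateSpec, gen_eeg
from .trace import SignalTrace

COGNITIVE_STATES = (
    "relaxation",
    "stress",
    "emotion",
    "distraction",
    "drowsiness",
    "attention",
)

FEATURE_NAMES = ("alpha_power", "beta_power", "log_ab_ratio", "spectral_entropy")


def spatial_transform(
    epochs: Sequence[np.ndarray] | Sequence[SignalTrace],
    fs: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Map raw epochs to gain-invariant band-feature vectors.

    Each epoch is standardised to unit variance (so a per-epoch gain change
    produces an identical vector), then summarised by Welch band powers in
    the alpha and beta bands, their log ratio, and the spectral entropy of
    the normalised 1-45 Hz spectrum. Zero-variance epochs are excluded.

    Returns (features, kept_indices).
    """
    feats: list[np.ndarray] = []
    kept: list[int] = []
    for i, ep in enumerate(epochs):
        if isinstance(ep, SignalTrace):
            x, fs_i = ep.samples, ep.fs
        else:
            x, fs_i = np.asarray(ep, dtype=float), fs
        sd = np.std(x)
        if sd == 0 or x.size == 0:
            warnings.warn(f"epoch {i} has zero variance; excluded")
            continue
        z = (x - np.mean(x)) / sd
        spec = spectral.WelchSpec.for_trace(
            SignalTrace(z, fs_i), segment_s=min(2.0, x.size / fs_i)
        )
        psd = spectral.welch_psd(z, spec)
        a = spectral.band_power(psd, *ALPHA_BAND)
        b = spectral.band_power(psd, *BETA_BAND)
        eps = 1e-12
        mask = (psd.freqs >= 1.0) & (psd.freqs <= 45.0)
        p = psd.power[mask]
        p = p / (p.sum() + eps)
        entropy = float(-(p * np.log(p + eps)).sum())
        feats.append(np.array([a, b, np.log((a + eps) / (b + eps)), entropy]))
        kept.append(i)
    if not feats:
        return np.empty((0, len(FEATURE_NAMES))), np.array([], dtype=int)
    return np.stack(feats), np.array(kept, dtype=int)


@dataclass
class EpochDataset:
    """Fixed-length feature vectors with labels and a train/test split."""

    features: np.ndarray
    labels: np.ndarray  # strings from COGNITIVE_STATES
    train_idx: np.ndarray
    test_idx: np.ndarray

    def __post_init__(self) -> None:
        unknown = set(self.labels) - set(COGNITIVE_STATES)
        if unknown:
            raise ValueError(f"unknown cognitive states: {sorted(unknown)}")
        if set(self.train_idx) & set(self.test_idx):
            raise ValueError("train and test indices must be disjoint")


@dataclass
class RbfModParams:
    """Fitted model: standardisation stats, RBF prototypes, MLP head."""

    scaler: StandardScaler
    centers: np.ndarray  # (K, n_features) in standardised space
    gamma: float
    mlp: MLPClassifier
    classes: tuple[str, ...]
    seed: int

    def rbf_activations(self, x_std: np.ndarray) -> np.ndarray:
        d2 = ((x_std[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-self.gamma * d2)

    def save(self, path: str | Path) -> None:
        """Persist as a versioned JSON file."""
        blob = {
            "format": "rbfmod-params",
            "version": 1,
            "seed": self.seed,
            "gamma": self.gamma,
            "classes": list(self.classes),
            "scaler_mean": self.scaler.mean_.tolist(),
            "scaler_scale": self.scaler.scale_.tolist(),
            "centers": self.centers.tolist(),
            "mlp": {
                "coefs": [c.tolist() for c in self.mlp.coefs_],
                "intercepts": [c.tolist() for c in self.mlp.intercepts_],
                "hidden_layer_sizes": list(self.mlp.hidden_layer_sizes),
                "classes": self.mlp.classes_.tolist(),
                "activation": self.mlp.activation,
                "out_activation": self.mlp.out_activation_,
                "n_layers": self.mlp.n_layers_,
                "n_outputs": self.mlp.n_outputs_,
            },
        }
        Path(path).write_text(json.dumps(blob, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "RbfModParams":
        blob = json.loads(Path(path).read_text())
        if blob.get("format") != "rbfmod-params" or blob.get("version") != 1:
            raise ValueError("unrecognised model file")
        scaler = StandardScaler()
        scaler.mean_ = np.array(blob["scaler_mean"])
        scaler.scale_ = np.array(blob["scaler_scale"])
        scaler.var_ = scaler.scale_**2
        scaler.n_features_in_ = scaler.mean_.size
        m = blob["mlp"]
        mlp = MLPClassifier(hidden_layer_sizes=tuple(m["hidden_layer_sizes"]))
        mlp.coefs_ = [np.array(c) for c in m["coefs"]]
        mlp.intercepts_ = [np.array(c) for c in m["intercepts"]]
        mlp.classes_ = np.array(m["classes"])
        mlp.activation = m["activation"]
        mlp.out_activation_ = m["out_activation"]
        mlp.n_layers_ = m["n_layers"]
        mlp.n_outputs_ = m["n_outputs"]
        mlp.n_features_in_ = mlp.coefs_[0].shape[0]
        mlp._label_binarizer = None  # predict_proba does not need it
        return cls(
            scaler=scaler,
            centers=np.array(blob["centers"]),
            gamma=blob["gamma"],
            mlp=mlp,
            classes=tuple(blob["classes"]),
            seed=blob["seed"],
        )


def fit(
    dataset: EpochDataset,
    k: int = 12,
    gamma: float = 1.0,
    seed: int = 0,
    hidden: int = 16,
) -> RbfModParams:
    """Fit prototypes (seeded k-means) and the MLP head.

    ``gamma`` is the RBF width exp(-gamma * ||x - c||^2) in standardised
    feature space. Deterministic given ``seed``.
    """
    x = dataset.features[dataset.train_idx]
    y = dataset.labels[dataset.train_idx]
    if k > x.shape[0]:
        raise ValueError(f"K={k} prototypes exceed {x.shape[0]} training epochs")
    classes = tuple(sorted(set(y)))
    if k < len(classes):
        raise ValueError("need at least one prototype per class")
    scaler = StandardScaler().fit(x)
    xs = scaler.transform(x)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(xs)
    params = RbfModParams(
        scaler=scaler,
        centers=km.cluster_centers_,
        gamma=gamma,
        mlp=MLPClassifier(
            hidden_layer_sizes=(hidden,),
            solver="lbfgs",
            max_iter=2000,
            random_state=seed,
        ),
        classes=classes,
        seed=seed,
    )
    params.mlp.fit(params.rbf_activations(xs), y)
    return params


def predict(
    params: RbfModParams,
    features: np.ndarray,
    smooth: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Labels and per-class scores for feature vectors.

    Scores sum to one per epoch. With ``smooth`` in (0, 1), scores are
    recursively blended with the previous epoch's scores
    (s_t = (1-smooth) p_t + smooth s_{t-1}), treating the input as a
    consecutive epoch sequence. Ties break towards the earlier class in
    ``params.mlp.classes_`` order.
    """
    features = np.atleast_2d(features)
    if features.shape[1] != params.scaler.mean_.size:
        raise ValueError("feature dimensionality mismatch")
    xs = params.scaler.transform(features)
    proba = params.mlp.predict_proba(params.rbf_activations(xs))
    if smooth > 0:
        out = np.empty_like(proba)
        carry = proba[0]
        out[0] = carry
        for t in range(1, len(proba)):
            carry = (1.0 - smooth) * proba[t] + smooth * carry
            out[t] = carry
        proba = out / out.sum(axis=1, keepdims=True)
    labels = params.mlp.classes_[np.argmax(proba, axis=1)]
    return labels, proba


# ---------------------------------------------------------------------------
# Synthetic cognitive benchmark
# ---------------------------------------------------------------------------

#: Band-amplitude signatures (alpha, beta, broadband noise in uV) per class
#: for the 4-class benchmark; distinct enough that band features separate the
#: classes, jittered per epoch so the problem is not degenerate.
BENCHMARK_SIGNATURES: dict[str, tuple[float, float, float]] = {
    "relaxation": (40.0, 10.0, 5.0),
    "stress": (8.0, 35.0, 5.0),
    "emotion": (25.0, 18.0, 5.0),
    "distraction": (12.0, 15.0, 25.0),
}


def make_cognitive_benchmark(
    n_per_class: int = 30,
    epoch_s: float = 8.0,
    fs: float = 250.0,
    seed: int = 0,
    test_fraction: float = 0.3,
) -> EpochDataset:
    """Generate the 4-class synthetic cognitive benchmark.

    Each epoch is one synthetic EEG window with class-specific alpha/beta
    amplitudes jittered by +/-15%. The split is stratified and seeded.
    """
    rng = np.random.default_rng(seed)
    epochs: list[SignalTrace] = []
    labels: list[str] = []
    for ci, (state, (a, b, nz)) in enumerate(sorted(BENCHMARK_SIGNATURES.items())):
        for j in range(n_per_class):
            jit = rng.uniform(0.85, 1.15, 3)
            spec = EegStateSpec(state, a * jit[0], b * jit[1], nz * jit[2])
            epochs.append(
                gen_eeg(spec, epoch_s, fs, seed=int(rng.integers(0, 2**31)))
            )
            labels.append(state)
    features, kept = spatial_transform(epochs, fs=fs)
    labels_arr = np.array(labels)[kept]
    n = len(labels_arr)
    test_idx: list[int] = []
    for state in BENCHMARK_SIGNATURES:
        cls_idx = np.nonzero(labels_arr == state)[0]
        n_test = max(1, int(round(test_fraction * cls_idx.size)))
        test_idx.extend(rng.permutation(cls_idx)[:n_test].tolist())
    test = np.array(sorted(test_idx), dtype=int)
    train = np.setdiff1d(np.arange(n), test)
    return EpochDataset(features, labels_arr, train, test)
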