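"""Learning-based nonperfusion segmentation.

The model is a fully convolutional per-pixel classifier over the paired
angiographic + structural en face images.  A fixed multiscale Gaussian
pyramid encodes each channel into hypercolumn features (the raw value plus
its smoothed value at each configured scale), and a small multilayer
perceptron head maps each pixel's hypercolumn to an NPA probability.  A pixel
counts as NPA when its probability is strictly greater than 0.5.

Because the structural channel enters the feature stack, the model can learn
the artifact cue that distinguishes true nonperfusion (low angiographic but
high structural signal) from shadow artifact (both channels low); the
``use_structure=False`` ablation removes that cue for controlled comparisons.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from sklearn.neural_network import MLPClassifier

from .config import SegmenterConfig
from .types import EnFaceScan, GroundTruth, Method, NPAMask

__all__ = ["ProbabilityMap", "NPASegmenter", "train_segmenter", "segment_npa_ai"]


@dataclass
class ProbabilityMap:
    """Per-pixel NPA probability with the binarization convention attached."""

    probs: np.ndarray
    threshold: float = 0.5

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, float)
        if p.min() < -1e-9 or p.max() > 1 + 1e-9:
            raise ValueError("probabilities must lie in [0, 1]")
        self.probs = np.clip(p, 0.0, 1.0)

    def binarize(self, threshold: float | None = None) -> np.ndarray:
        """Strict ``probs > threshold`` (a uniform 0.5 map yields no NPA)."""
        t = self.threshold if threshold is None else threshold
        return self.probs > t


def _feature_stack(scan: EnFaceScan, config: SegmenterConfig) -> np.ndarray:
    """(H, W, F) hypercolumn features: raw + Gaussian pyramid per channel."""
    channels = [scan.angio]
    if config.use_structure:
        channels.append(scan.structure)
    feats = []
    for ch in channels:
        feats.append(ch)
        for sigma in config.feature_scales_px:
            feats.append(ndimage.gaussian_filter(ch, sigma))
    return np.stack(feats, axis=-1)


class NPASegmenter:
    """Trainable two-channel NPA segmenter (see module docstring)."""

    def __init__(self, config: SegmenterConfig):
        config.validate()
        self.config = config
        self._mlp: MLPClassifier | None = None
        self.loss_curve_: list[float] = []

    # -- training -----------------------------------------------------------

    def _sample_pixels(
        self,
        scan: EnFaceScan,
        truth: GroundTruth,
        rng: np.random.Generator,
    ) -> tuple[np.ndarray, np.ndarray]:
        feats = _feature_stack(scan, self.config)
        flat = feats.reshape(-1, feats.shape[-1])
        labels = truth.npa_mask.ravel()
        n = self.config.pixels_per_image
        pos = np.flatnonzero(labels)
        neg = np.flatnonzero(~labels)
        # Stratified draw: up to half the budget from NPA pixels.
        n_pos = min(n // 2, pos.size)
        n_neg = min(n - n_pos, neg.size)
        idx = np.concatenate(
            [
                rng.choice(pos, n_pos, replace=False) if n_pos else np.empty(0, int),
                rng.choice(neg, n_neg, replace=False) if n_neg else np.empty(0, int),
            ]
        )
        return flat[idx], labels[idx]

    def fit(self, train_set: list[tuple[EnFaceScan, GroundTruth]]) -> "NPASegmenter":
        if not train_set:
            raise ValueError("training set is empty")
        n_feat = _feature_stack(train_set[0][0], self.config).shape[-1]
        rng = np.random.default_rng(self.config.seed)
        xs, ys = [], []
        for scan, truth in train_set:
            feats = _feature_stack(scan, self.config)
            if feats.shape[-1] != n_feat:
                raise ValueError("inconsistent channel contract across training scans")
            x, y = self._sample_pixels(scan, truth, rng)
            xs.append(x)
            ys.append(y)
        X = np.concatenate(xs)
        y = np.concatenate(ys)
        self._mlp = MLPClassifier(
            hidden_layer_sizes=tuple(self.config.hidden_layers),
            activation="relu",
            solver="adam",
            learning_rate_init=self.config.learning_rate,
            batch_size=min(self.config.batch_size, X.shape[0]),
            max_iter=self.config.max_iter,
            random_state=self.config.seed,
            early_stopping=False,
        )
        import warnings

        from sklearn.exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            # fixed-epoch training: hitting max_iter is the intended stop
            warnings.simplefilter("ignore", ConvergenceWarning)
            self._mlp.fit(X, y)
        self.loss_curve_ = list(self._mlp.loss_curve_)
        return self

    # -- inference ----------------------------------------------------------

    @property
    def is_trained(self) -> bool:
        return self._mlp is not None

    def predict_proba_map(self, scan: EnFaceScan) -> ProbabilityMap:
        if self._mlp is None:
            raise RuntimeError("segmenter has not been trained")
        feats = _feature_stack(scan, self.config)
        flat = feats.reshape(-1, feats.shape[-1])
        probs = self._mlp.predict_proba(flat)[:, 1].reshape(scan.shape)
        return ProbabilityMap(probs=probs, threshold=self.config.threshold)

    def segment(self, scan: EnFaceScan) -> tuple[ProbabilityMap, NPAMask]:
        pmap = self.predict_proba_map(scan)
        mask = NPAMask(
            mask=pmap.binarize(),
            pixel_pitch_mm=scan.pixel_pitch_mm,
            method=Method.AI,
        )
        return pmap, mask

    # -- persistence / identity --------------------------------------------

    def signature(self) -> tuple:
        """Model graph identity implied by the config (pre-training)."""
        c = self.config
        n_channels = 2 if c.use_structure else 1
        n_features = n_channels * (1 + len(c.feature_scales_px))
        return (n_features, tuple(c.hidden_layers), 1, c.threshold)

    def save(self, path: str | Path) -> None:
        Path(path).write_bytes(pickle.dumps(self))

    @staticmethod
    def load(path: str | Path) -> "NPASegmenter":
        model = pickle.loads(Path(path).read_bytes())
        if not isinstance(model, NPASegmenter):
            raise TypeError(f"{path} does not contain an NPASegmenter")
        return model


def train_segmenter(
    train_set: list[tuple[EnFaceScan, GroundTruth]], config: SegmenterConfig
) -> NPASegmenter:
    """Train a fresh segmenter; reproducible given ``config.seed``."""
    return NPASegmenter(config).fit(train_set)


def segment_npa_ai(model: NPASegmenter, scan: EnFaceScan) -> tuple[ProbabilityMap, NPAMask]:
    """Probability map and strict >0.5 binarized NPA mask for one scan."""
    return model.segment(scan)
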