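"""Scikit-learn-style estimator surface over the restoration pipeline.

These classes follow the sklearn conventions (constructor stores
hyperparameters verbatim, ``fit`` learns and sets trailing-underscore
attributes, ``transform``/``predict`` applies, ``get_params`` /
``set_params`` work for model selection).  Samples are images rather
than feature rows: X is a sequence of 2-D arrays or of image pairs, so
only the parameter-handling contract — not the 2-D feature-matrix
contract — is inherited.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ._constants import DEFAULT_EXTINCTION, ExtinctionTable
from .degrade import AcquisitionPair
from .metrics import evaluate_pairs
from .mtrdn import MTRDN
from .so2 import apply_mask, unmix_so2
from .train import build_patch_set, reconstruct, train_model
from .vesselness import VesselnessParams, make_ground_truth3

__all__ = ["FrangiVesselness", "MTRDNRestorer", "SO2Unmixer"]


class FrangiVesselness(BaseEstimator, TransformerMixin):
    """Stateless multiscale vesselness enhancement as a transformer.

    ``transform`` maps each image to its normalized Frangi response
    (the "ground truth 3" operator).
    """

    def __init__(self, scales=(1.0, 2.0, 3.0, 4.0), beta: float = 0.5, c="auto", bright_on_dark: bool = True):
        self.scales = scales
        self.beta = beta
        self.c = c
        self.bright_on_dark = bright_on_dark

    def _params(self) -> VesselnessParams:
        return VesselnessParams(
            scales=tuple(self.scales), beta=self.beta, c=self.c, bright_on_dark=self.bright_on_dark
        )

    def fit(self, X=None, y=None):
        self._params()  # validate
        self.n_features_in_ = 0
        return self

    def transform(self, X):
        params = self._params()
        if isinstance(X, np.ndarray) and X.ndim == 2:
            return make_ground_truth3(X, params)
        return [make_ground_truth3(np.asarray(img), params) for img in X]


class MTRDNRestorer(BaseEstimator):
    """Multitask residual dense network restorer with a fit/predict surface.

    fit(X, y): X is a sequence of AcquisitionPair (or (input1, input2)
    image pairs at low resolution), y the matching sequence of
    (gt1, gt2, gt3) full-resolution target triples.  predict(X) returns
    one (recon1, recon2, recon3) triple per sample.
    """

    def __init__(
        self,
        scale: int = 2,
        n_blocks: int = 4,
        convs_per_block: int = 4,
        growth: int = 16,
        base_channels: int = 32,
        loss_weights: tuple[float, float, float] = (0.25, 0.25, 0.5),
        patch: int = 16,
        stride: int | None = None,
        steps: int = 500,
        lr: float = 1e-3,
        batch: int = 4,
        seed: int = 0,
    ):
        self.scale = scale
        self.n_blocks = n_blocks
        self.convs_per_block = convs_per_block
        self.growth = growth
        self.base_channels = base_channels
        self.loss_weights = loss_weights
        self.patch = patch
        self.stride = stride
        self.steps = steps
        self.lr = lr
        self.batch = batch
        self.seed = seed

    def _as_pairs(self, X) -> list[AcquisitionPair]:
        from .degrade import DegradationSpec

        pairs = []
        for item in X:
            if isinstance(item, AcquisitionPair):
                pairs.append(item)
            else:
                i1, i2 = item
                pairs.append(
                    AcquisitionPair(
                        np.asarray(i1, float),
                        np.asarray(i2, float),
                        DegradationSpec(undersample_factor=self.scale, noise_sigma=0.0),
                    )
                )
        return pairs

    def fit(self, X, y):
        pairs = self._as_pairs(X)
        triples = [tuple(np.asarray(img, float) for img in t) for t in y]
        patches = build_patch_set(pairs, triples, patch=self.patch, stride=self.stride)
        model = MTRDN(
            scale=self.scale,
            n_blocks=self.n_blocks,
            convs_per_block=self.convs_per_block,
            growth=self.growth,
            base_channels=self.base_channels,
            loss_weights=self.loss_weights,
            seed=self.seed,
        )
        state = train_model(
            patches, model, steps=self.steps, lr=self.lr, batch=self.batch, seed=self.seed
        )
        self.model_ = state.model
        self.loss_history_ = state.loss_history
        self.n_parameters_ = state.model.n_parameters()
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return [
            reconstruct(self.model_, p.input1, p.input2, patch=self.patch, stride=self.stride)
            for p in self._as_pairs(X)
        ]

    def score(self, X, y):
        """Mean PSNR (dB) of the fused output against gt3 over the samples."""
        recons = self.predict(X)
        report = evaluate_pairs([t[2] for t in y], [r[2] for r in recons])
        return float(np.mean(report.psnr_values))


class SO2Unmixer(BaseEstimator, TransformerMixin):
    """Two-wavelength linear sO2 unmixing (+ optional mask thresholding)."""

    def __init__(self, extinction: ExtinctionTable = DEFAULT_EXTINCTION, threshold: float | None = None):
        self.extinction = extinction
        self.threshold = threshold

    def fit(self, X=None, y=None):
        self.n_features_in_ = 0
        return self

    def transform(self, X):
        """X: sequence of (pa532, pa560) or (pa532, pa560, mask_image) tuples."""
        out = []
        for item in X:
            pa532, pa560 = item[0], item[1]
            so2 = unmix_so2(pa532, pa560, self.extinction)
            if len(item) > 2 and self.threshold is not None:
                out.append(apply_mask(so2, item[2], self.threshold))
            else:
                out.append(so2)
        return out
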