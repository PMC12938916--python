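"""scikit-learn-style front door for the multimodal lesion classifier.

`LesionClassifier` wraps the full pipeline — convolutional backbone,
metadata-conditioned channel recalibration, FiLM modulation +
cross-attention fusion, uncertainty-weighted focal-loss training — behind
fit / predict / predict_proba with get_params/set_params, so it composes
with sklearn model selection.  X is the pair (images, metadata):
images (n, 3, S, S) normalised arrays, metadata (n, 81) encoded vectors.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .amcr import AmcrConfig
from .backbone import BackboneConfig
from .datamodel import Sample
from .network import ImageOnlyNet, LesionNet, predict_proba
from .train import FocalLossConfig, TrainConfig, samples_to_arrays, train

__all__ = ["LesionClassifier", "split_X"]


def split_X(X) -> tuple[np.ndarray, np.ndarray]:
    """Accept (images, metadata) tuples or lists of Sample objects."""
    if isinstance(X, (tuple, list)) and len(X) and isinstance(X[0], Sample):
        I, M, _ = samples_to_arrays(list(X))
        return I, M
    I, M = X
    return np.asarray(I, dtype=float), np.asarray(M, dtype=float)


class LesionClassifier(ClassifierMixin, BaseEstimator):
    """Multimodal image+metadata classifier.

    Parameters mirror the training recipe: the full-scale profile is
    architecture="resnet50", image_size=224, embed_dim=512, hidden_dim=256,
    mc_passes=10, epochs=150; the default construction is the tiny profile
    (32-pixel images, small embedding, T=3, 5 epochs) meant for
    desk-scale experiments and tests.
    """

    def __init__(self, architecture: str = "tiny", image_size: int = 32,
                 embed_dim: int = 32, hidden_dim: int = 16, dropout: float = 0.5,
                 mc_passes: int = 3, lam: float = 0.1, gamma_focal: float = 2.0,
                 static_alpha: tuple = (1.0, 1.0, 2.0, 1.0, 2.0, 1.0),
                 use_uncertainty: bool = True, use_fusion: bool = True,
                 image_only: bool = False, epochs: int = 5, batch_size: int = 8,
                 lr0: float = 0.001, momentum: float = 0.9,
                 weight_decay: float = 0.001, t_max: int | None = None,
                 metadata_dim: int = 81, seed: int = 0):
        self.architecture = architecture
        self.image_size = image_size
        self.embed_dim = embed_dim
        self.hidden_dim = hidden_dim
        self.dropout = dropout
        self.mc_passes = mc_passes
        self.lam = lam
        self.gamma_focal = gamma_focal
        self.static_alpha = static_alpha
        self.use_uncertainty = use_uncertainty
        self.use_fusion = use_fusion
        self.image_only = image_only
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr0 = lr0
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.t_max = t_max
        self.metadata_dim = metadata_dim
        self.seed = seed

    # -- config assembly -----------------------------------------------------
    def _backbone_config(self) -> BackboneConfig:
        return BackboneConfig(architecture=self.architecture,
                              input_size=self.image_size, seed=self.seed)

    def _amcr_config(self) -> AmcrConfig:
        return AmcrConfig(metadata_dim=self.metadata_dim, embed_dim=self.embed_dim,
                          hidden_dim=self.hidden_dim, dropout=self.dropout,
                          mc_passes=self.mc_passes, lam=self.lam)

    def _train_config(self) -> TrainConfig:
        focal = FocalLossConfig(gamma=self.gamma_focal,
                                static_alpha=tuple(self.static_alpha),
                                lam=self.lam, use_uncertainty=self.use_uncertainty)
        return TrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                           lr0=self.lr0, momentum=self.momentum,
                           weight_decay=self.weight_decay,
                           t_max=self.t_max, mc_passes=self.mc_passes,
                           seed=self.seed, focal=focal)

    def build_network(self):
        if self.image_only:
            return ImageOnlyNet(self._backbone_config(), head_dropout=self.dropout,
                                seed=self.seed)
        return LesionNet(self._backbone_config(), self._amcr_config(),
                         head_dropout=self.dropout, use_fusion=self.use_fusion,
                         seed=self.seed)

    # -- sklearn API ---------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None, artifact_dir=None):
        """Train on (images, metadata) and integer labels.

        Without explicit validation data the training data doubles as the
        per-epoch monitoring set (checkpoint selection is then in-sample).
        """
        I, M = split_X(X)
        y = np.asarray(y, dtype=np.int64)
        if len(I) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        from .datamodel import LesionImage, Sample as S
        from .schema import MetadataSchema

        schema = MetadataSchema.default()

        def wrap(Ia, Ma, ya):
            out = []
            for i in range(len(ya)):
                img = LesionImage(Ia[i], sample_id=f"fit_{i}")
                vec_values = Ma[i]
                from .schema import MetadataVector
                vec = MetadataVector(vec_values, dict(schema.attribute_map),
                                     {k: False for k in schema.by_name}) \
                    if Ma.shape[1] == schema.dim else None
                if vec is None:
                    raise ValueError(f"metadata must have {schema.dim} dims")
                out.append(S(image=img, metadata=vec, label=int(ya[i])))
            return out

        train_samples = wrap(I, M, y)
        if X_val is not None:
            Iv, Mv = split_X(X_val)
            val_samples = wrap(Iv, Mv, np.asarray(y_val, dtype=np.int64))
        else:
            val_samples = train_samples
        self.network_ = self.build_network()
        result = train(self.network_, train_samples, val_samples,
                       self._train_config(), artifact_dir=artifact_dir)
        self.history_ = result["history"]
        self.best_epoch_ = result["best_epoch"]
        self.best_val_bacc_ = result["best_bacc"]
        return self

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        I, M = split_X(X)
        return predict_proba(self.network_, I, M)

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def _check_fitted(self):
        if not hasattr(self, "network_"):
            raise RuntimeError("LesionClassifier is not fitted; call fit() first")

    # tags for sklearn compatibility checks: X is a (images, metadata) pair
    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.two_d_array = False
        return tags
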