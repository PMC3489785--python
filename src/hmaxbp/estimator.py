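"""Scikit-learn estimator wrapping the full train/categorise pipeline."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .bp_core import ApproximationConfig
from .gabor import GaborBank
from .inference import feedforward
from .learning import LearningConfig, train_network
from .network_arch import ArchitectureParams, build_network

__all__ = ["HmaxBayesClassifier"]


class HmaxBayesClassifier(ClassifierMixin, BaseEstimator):
    """One-shot silhouette classifier based on the hierarchical
    Bayesian network with loopy belief propagation.

    Fitting takes exactly one image per category (weight sharing makes
    one exemplar sufficient) and learns all conditional tables layer by
    layer; prediction runs the feedforward schedule and returns the
    category with the highest top-node belief.

    Parameters mirror the architecture (receptive-field sizes/strides
    and state counts), the belief-propagation approximations and the
    table learners; defaults are the reference configuration. Smaller
    ``K_S2``/``K_C2group`` give a lighter network for experimentation.

    Attributes (after ``fit``)
    --------------------------
    classes_ : ndarray of the category labels.
    network_ : the trained :class:`~hmaxbp.network_arch.NetworkModel`.

    Examples
    --------
    >>> from hmaxbp.synthetic import make_silhouettes
    >>> data = make_silhouettes(3, seed=0)
    >>> clf = HmaxBayesClassifier(K_S2=40, K_C2group=4)
    >>> clf.fit(np.stack(data.images), data.labels).score(
    ...     np.stack(data.images), data.labels)
    1.0
    """

    def __init__(self, *, N_C1=10, step_C1=5, K_C1group=10,
                 N_S2=4, step_S2=1, K_S2=250, N_C2=6, step_C2=3,
                 K_C2group=10, N_S3=6, eps_min=1e-12, m_pi=16, m_states=10,
                 patch_threshold=0.3, dmin_step_frac=0.05,
                 invert_images=False, random_state=0):
        self.N_C1 = N_C1
        self.step_C1 = step_C1
        self.K_C1group = K_C1group
        self.N_S2 = N_S2
        self.step_S2 = step_S2
        self.K_S2 = K_S2
        self.N_C2 = N_C2
        self.step_C2 = step_C2
        self.K_C2group = K_C2group
        self.N_S3 = N_S3
        self.eps_min = eps_min
        self.m_pi = m_pi
        self.m_states = m_states
        self.patch_threshold = patch_threshold
        self.dmin_step_frac = dmin_step_frac
        self.invert_images = invert_images
        self.random_state = random_state

    def _configs(self, n_classes: int):
        params = ArchitectureParams(
            N_C1=self.N_C1, step_C1=self.step_C1,
            K_C1=4 * self.K_C1group, K_C1group=self.K_C1group,
            N_S2=self.N_S2, step_S2=self.step_S2, K_S2=self.K_S2,
            N_C2=self.N_C2, step_C2=self.step_C2,
            K_C2=self.K_S2 * self.K_C2group, K_C2group=self.K_C2group,
            K_S3=n_classes, N_S3=self.N_S3,
        )
        approx = ApproximationConfig(eps_min=self.eps_min, m_pi=self.m_pi,
                                     m_states=self.m_states)
        learn = LearningConfig(patch_threshold=self.patch_threshold,
                               dmin_step_frac=self.dmin_step_frac,
                               rng_seed=self.random_state or 0)
        return params, approx, learn

    @staticmethod
    def _as_images(X) -> list:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3:
            raise ValueError(f"X must be (n_images, H, W); got {X.shape}")
        return list(X)

    def fit(self, X, y):
        """Learn the network from one image per category.

        ``X``: array of shape (n_categories, H, W); ``y``: unique
        category labels, one per image.
        """
        images = self._as_images(X)
        y = np.asarray(y)
        if len(y) != len(images):
            raise ValueError("X and y length mismatch")
        if len(np.unique(y)) != len(y):
            raise ValueError("one-shot fit requires unique labels")
        self.classes_ = np.unique(y)
        order = np.argsort(y)  # classes_ order
        params, approx, learn = self._configs(len(images))
        self.bank_ = GaborBank()
        network = build_network(params)
        train_network(network, [images[i] for i in order],
                      list(self.classes_), learn_cfg=learn,
                      approx_cfg=approx, bank=self.bank_,
                      invert=self.invert_images)
        self.network_ = network
        self.approx_cfg_ = approx
        return self

    def predict_proba(self, X):
        """Top-node belief over the categories for each image."""
        check_is_fitted(self, "network_")
        out = np.empty((len(self._as_images(X)), len(self.classes_)))
        for i, img in enumerate(self._as_images(X)):
            state = feedforward(self.network_, img, self.approx_cfg_,
                                bank=self.bank_, invert=self.invert_images)
            out[i] = state.bel[self.network_.layers[-1].name][0, 0]
        return out

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]
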