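"""Factory for the four gesture-classification pipelines.

* ``td``       — time-domain feature vector -> standardize -> one-vs-rest
                 L2 logistic regression;
* ``cov``      — OAS covariance -> tangent space at the training Fréchet
                 mean -> logistic regression;
* ``xdawncov`` — xDAWN augmentation -> OAS covariance -> tangent space ->
                 logistic regression;
* ``cnn``      — the compact convolutional network.

All are scikit-learn estimators operating on (N, E, S) epoch arrays, so
they clone cleanly inside cross-validation.
"""

from __future__ import annotations

from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .features import TimeDomainFeatures
from .neuralnet import EmgCnnClassifier
from .riemann import Covariances, LinearGestureClassifier, TangentSpace, XdawnAugment

PIPELINE_NAMES = ("td", "cov", "xdawncov", "cnn")


def make_pipeline(name: str, n_xdawn_filters: int = 4, **kwargs):
    """Build one of the named pipelines; kwargs go to the final estimator."""
    if name == "td":
        return Pipeline(
            [
                ("features", TimeDomainFeatures()),
                ("scale", StandardScaler()),
                ("clf", LinearGestureClassifier(**kwargs)),
            ]
        )
    if name == "cov":
        return Pipeline(
            [
                ("cov", Covariances()),
                ("tangent", TangentSpace()),
                ("clf", LinearGestureClassifier(**kwargs)),
            ]
        )
    if name == "xdawncov":
        return Pipeline(
            [
                ("xdawn", XdawnAugment(n_filters=n_xdawn_filters)),
                ("cov", Covariances()),
                ("tangent", TangentSpace()),
                ("clf", LinearGestureClassifier(**kwargs)),
            ]
        )
    if name == "cnn":
        return EmgCnnClassifier(**kwargs)
    raise ValueError(f"unknown pipeline {name!r}; choose from {PIPELINE_NAMES}")
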