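"""Model/Results front end for path classification.

`PathClassificationModel` bundles the two labeled training path sets, the
known class-1 mixing probability, and (optionally) the SDE-induced NIW
priors; `fit` performs the conjugate update and returns a
`PathClassificationResults` holding the trained discriminant, the posterior
hyperparameters, and diagnostics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classifiers import BinaryClassifier, build_obc, build_qda_from_data
from .exceptions import InvalidInputError
from .paths import ObservationGrid, PathSet
from .priors import NIWParams, posterior_update


class PathClassificationModel:
    """Binary classification of Gaussian-process sample paths.

    Parameters
    ----------
    train0, train1 : PathSet
        Labeled training sample paths of each class on a common grid.
    alpha1 : float
        Known class-1 mixing probability (separate sampling: never
        estimated from the data).
    prior0, prior1 : NIWParams, optional
        SDE-induced normal-inverse-Wishart priors; required for
        ``fit(method="obc")``.

    Examples
    --------
    >>> from sdebayes import datasets, sde, priors
    >>> fx = datasets.make_fixture("ou_beta010")
    >>> tr0 = sde.simulate_paths(fx.spec0, fx.grid, 100, seed=1, label=0)
    >>> tr1 = sde.simulate_paths(fx.spec1, fx.grid, 100, seed=2, label=1)
    >>> pri0 = priors.prior_from_sde(fx.spec0, fx.grid, nu=530, kappa=530)
    >>> pri1 = priors.prior_from_sde(fx.spec1, fx.grid, nu=530, kappa=530)
    >>> res = PathClassificationModel(tr0, tr1, prior0=pri0, prior1=pri1).fit()
    >>> labels = res.predict(tr0)
    """

    def __init__(
        self,
        train0: PathSet,
        train1: PathSet,
        *,
        alpha1: float = 0.5,
        prior0: NIWParams | None = None,
        prior1: NIWParams | None = None,
    ) -> None:
        if train0.grid != train1.grid:
            raise InvalidInputError("training sets must share one observation grid")
        if (prior0 is None) != (prior1 is None):
            raise InvalidInputError("provide priors for both classes or neither")
        if prior0 is not None and prior0.dim != train0.grid.dim:
            raise InvalidInputError("prior dimension does not match the grid")
        self.train0 = train0
        self.train1 = train1
        self.alpha1 = float(alpha1)
        self.prior0 = prior0
        self.prior1 = prior1
        self.grid: ObservationGrid = train0.grid

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        *,
        alpha1: float = 0.5,
        prior0: NIWParams | None = None,
        prior1: NIWParams | None = None,
    ) -> "PathClassificationModel":
        """Build from a long-format table (path_id, label, time,
        coordinate_index, value); labels must be exactly {0, 1}."""
        from .io import pathset_from_dataframe

        labels = sorted(df["label"].unique())
        if labels != [0, 1]:
            raise InvalidInputError(
                f"training table must contain labels 0 and 1, found {labels}"
            )
        tr0 = pathset_from_dataframe(df[df["label"] == 0])
        tr1 = pathset_from_dataframe(df[df["label"] == 1])
        return cls(tr0, tr1, alpha1=alpha1, prior0=prior0, prior1=prior1)

    def fit(self, method: str = "obc") -> "PathClassificationResults":
        """Train the requested discriminant.

        ``method="obc"`` performs the conjugate NIW update of both priors
        and builds the optimal Bayesian classifier; ``method="qda"`` builds
        the stochastic QDA from the empirical training moments (requires
        more paths per class than the stacked dimension).
        """
        if method == "obc":
            if self.prior0 is None:
                raise InvalidInputError("fit(method='obc') requires class priors")
            post0 = posterior_update(self.prior0, self.train0)
            post1 = posterior_update(self.prior1, self.train1)
            clf = build_obc(post0, post1, self.alpha1)
        elif method == "qda":
            post0 = post1 = None
            clf = build_qda_from_data(self.train0, self.train1, self.alpha1)
        else:
            raise InvalidInputError(f"method must be 'obc' or 'qda', got {method!r}")
        return PathClassificationResults(self, method, clf, post0, post1)


class PathClassificationResults:
    """Fitted discriminant plus posterior parameters and diagnostics."""

    def __init__(
        self,
        model: PathClassificationModel,
        method: str,
        classifier: BinaryClassifier,
        posterior0: NIWParams | None,
        posterior1: NIWParams | None,
    ) -> None:
        self.model = model
        self.method = method
        self.classifier = classifier
        self.posterior0 = posterior0
        self.posterior1 = posterior1
        self.nobs = (model.train0.n, model.train1.n)

    def predict(self, x) -> np.ndarray:
        """Class labels for stacked vectors, an (n, Np) matrix, or a PathSet."""
        return self.classifier.classify(x)

    def log_odds(self, x) -> np.ndarray:
        """Discriminant values; positive favors class 0."""
        return self.classifier.discriminant(x)

    def error_rate(self, test0: PathSet, test1: PathSet) -> float:
        """Mixing-weighted misclassification rate on labeled test sets."""
        from .evaluation import true_error

        return true_error(self.classifier, test0, test1, self.model.alpha1)

    @property
    def apparent_error(self) -> float:
        """Training-set (resubstitution) error; optimistic, for diagnostics."""
        e0 = float(np.mean(self.predict(self.model.train0) != 0))
        e1 = float(np.mean(self.predict(self.model.train1) != 1))
        a1 = self.model.alpha1
        return (1 - a1) * e0 + a1 * e1

    def _condition_numbers(self) -> tuple[float, float]:
        out = []
        for cp in (self.classifier.class0, self.classifier.class1):
            sv = np.linalg.svd(cp.chol, compute_uv=False)
            out.append(float((sv.max() / sv.min()) ** 2))
        return tuple(out)

    def summary(self) -> str:
        """Plain-text summary of the fit."""
        g = self.model.grid
        c0, c1 = self._condition_numbers()
        lines = [
            "Path classification results",
            "=" * 46,
            f"method:            {self.method.upper()}",
            f"observation grid:  N={g.N}, p={g.p}, Np={g.dim}",
            f"training paths:    n0={self.nobs[0]}, n1={self.nobs[1]}",
            f"alpha1 (known):    {self.model.alpha1:.4g}",
            f"apparent error:    {self.apparent_error:.4f}",
            f"cond(cov) class 0: {c0:.3e}",
            f"cond(cov) class 1: {c1:.3e}",
        ]
        if self.method == "obc":
            lines += [
                f"posterior nu*:     {self.posterior0.nu:.6g} / {self.posterior1.nu:.6g}",
                f"posterior kappa*:  {self.posterior0.kappa:.6g} / {self.posterior1.kappa:.6g}",
                f"effective dof k:   {self.classifier.class0.k:.6g} / {self.classifier.class1.k:.6g}",
            ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<PathClassificationResults method={self.method!r} "
            f"nobs={self.nobs} dim={self.classifier.dim}>"
        )
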