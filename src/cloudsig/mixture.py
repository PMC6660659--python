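"""Multinomial mixture model (MMM) over signature states.

The MMM treats every mutation as an independent draw: a signature k is chosen
with marginal probability g_k, then a category is emitted from the fixed
signature (emission) matrix E. It serves both as the stand-alone baseline and
as the generator of "sky" mutations inside the composite sky/cloud model.

EM here is exact and cheap: responsibilities depend on a mutation only through
its category, so the E- and M-steps operate on the 96-bin category histogram.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .catalog import N_CATEGORIES, SignatureMatrix


@dataclass
class MmmParams:
    """Learned mixture weights over a fixed signature matrix."""

    g: np.ndarray
    signatures: SignatureMatrix

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        if self.g.shape != (self.signatures.K,):
            raise ValueError("g must have one entry per signature")
        if np.any(self.g < 0) or abs(self.g.sum() - 1.0) > 1e-10:
            raise ValueError("g must be a probability vector (sum 1 within 1e-10)")

    def to_json(self) -> str:
        return json.dumps(
            {"signatures": self.signatures.names, "g": self.g.tolist()}, indent=2
        )


def mmm_loglik(params: MmmParams, categories) -> float:
    """Total log-likelihood sum_t log sum_k g_k E[k, O_t] (log space)."""
    categories = np.asarray(categories, dtype=np.int64)
    if len(categories) == 0:
        return 0.0
    with np.errstate(divide="ignore"):
        log_g = np.log(params.g)
    comp = log_g[:, None] + params.signatures.log_E[:, categories]
    return float(logsumexp(comp, axis=0).sum())


class SignatureMixture(BaseEstimator):
    """Multinomial mixture of fixed signatures, fit by EM.

    Parameters
    ----------
    signatures : SignatureMatrix
        Fixed emission matrix; only the mixture weights are learned.
    tol : float
        Relative log-likelihood change declaring convergence.
    max_iter : int
        EM iteration cap; reaching it sets ``converged_ = False`` and warns.
    random_state : int or numpy Generator, optional
        Seeds the symmetric Dirichlet(1) initialization when ``init`` is None.
    init : array-like, optional
        Explicit initial weights (overrides the random draw).

    Attributes
    ----------
    weights_ : ndarray of shape (K,)
        Fitted signature marginal probabilities g.
    loglik_trace_ : list of float
        Log-likelihood at each EM iteration (non-decreasing).
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, signatures=None, tol=1e-6, max_iter=1000,
                 random_state=None, init=None):
        self.signatures = signatures
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state
        self.init = init

    def fit(self, X, y=None):
        categories = np.asarray(X, dtype=np.int64).ravel()
        if len(categories) == 0:
            raise ValueError("cannot fit a mixture on an empty sequence")
        sig = self.signatures
        if sig is None:
            raise ValueError("signatures must be provided")
        K = sig.K
        counts = np.bincount(categories, minlength=N_CATEGORIES).astype(float)
        log_E = sig.log_E  # K x 96

        if self.init is not None:
            g = np.asarray(self.init, dtype=float)
            g = g / g.sum()
        else:
            rng = np.random.default_rng(self.random_state)
            g = rng.dirichlet(np.ones(K))

        trace: list[float] = []
        T = counts.sum()
        converged = False
        for _ in range(self.max_iter):
            with np.errstate(divide="ignore"):
                comp = np.log(g)[:, None] + log_E  # K x 96
            per_cat = logsumexp(comp, axis=0)
            ll = float(per_cat @ counts)
            trace.append(ll)
            # responsibilities per category, weighted by category counts
            gamma = np.exp(comp - per_cat[None, :])
            g = (gamma @ counts) / T
            if len(trace) > 1:
                prev = trace[-2]
                if abs(ll - prev) <= self.tol * max(abs(prev), 1.0):
                    converged = True
                    break
        if not converged:
            warnings.warn(
                f"mixture EM did not converge in {self.max_iter} iterations",
                RuntimeWarning,
            )
        self.weights_ = g
        self.loglik_trace_ = trace
        self.n_iter_ = len(trace)
        self.converged_ = converged
        self.params_ = MmmParams(g / g.sum(), sig)
        return self

    def score(self, X, y=None) -> float:
        """Total log-likelihood of a category sequence under the fit."""
        return mmm_loglik(self.params_, X)

    def predict_proba(self, X) -> np.ndarray:
        """Per-mutation posterior responsibilities, shape (T, K)."""
        categories = np.asarray(X, dtype=np.int64).ravel()
        with np.errstate(divide="ignore"):
            comp = np.log(self.weights_)[:, None] + \
                self.signatures.log_E[:, categories]
        return np.exp(comp - logsumexp(comp, axis=0)[None, :]).T

    def predict(self, X) -> np.ndarray:
        """Most probable signature index per mutation."""
        return np.argmax(self.predict_proba(X), axis=1)


def mmm_em_fit(categories, E: SignatureMatrix, init=None, tol=1e-6,
               max_iter=1000, random_state=None):
    """Functional wrapper: fit the MMM, returning (MmmParams, loglik trace)."""
    est = SignatureMixture(signatures=E, tol=tol, max_iter=max_iter,
                           random_state=random_state, init=init).fit(categories)
    return est.params_, est.loglik_trace_
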