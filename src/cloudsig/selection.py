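"""Meta-parameter selection and restart robustness.

The distance threshold separating sky from clouds is chosen by
leave-one-chromosome-out cross-validation: for each candidate threshold and
each fold, the model is trained on all other chromosomes and scored on the
held-out one; per-restart fold sums are summarized by their median across
restarts, and the threshold maximizing that median wins. Folds x restarts are
independent work units with seeds spawned deterministically from the root
seed, so serial and concurrent execution give identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .catalog import SampleSequence, SignatureMatrix
from .mixture import SignatureMixture, mmm_loglik
from .model import (
    CloudSignatureModel,
    DecodedPath,
    conditional_loglik,
    forward_loglik,
)
from .partition import label_sky_cloud

DEFAULT_THRESHOLD_GRID = (250, 500, 1000, 2000, 4000, 8000, 16000)


@dataclass
class CvResult:
    """Cross-validation outcome for one threshold.

    ``heldout`` and ``train`` have shape (restarts, folds); ``conditional``
    holds the category-predictive held-out score (comparable to the mixture
    baseline, which carries no indicator chain).
    """

    threshold: int
    chromosomes: list[str]
    heldout: np.ndarray
    train: np.ndarray
    conditional: np.ndarray
    model: str = "full"

    @property
    def per_restart_heldout(self) -> np.ndarray:
        return self.heldout.sum(axis=1)

    @property
    def median_heldout(self) -> float:
        """Median across restarts of the fold-summed held-out log-likelihood."""
        return float(np.median(self.per_restart_heldout))

    @property
    def median_conditional(self) -> float:
        return float(np.median(self.conditional.sum(axis=1)))


def _one_fold(sequences, signatures, threshold, fold, chroms, seed_key,
              model, cloud_signatures, tol, max_iter):
    seed = np.random.SeedSequence(seed_key)
    train_keys = [c for c in chroms if c != fold]
    if model == "mmm":
        train_cats = np.concatenate([sequences[c][1] for c in train_keys])
        rng = np.random.default_rng(seed)
        est = SignatureMixture(signatures=signatures, tol=tol,
                               max_iter=max_iter, random_state=rng).fit(train_cats)
        held_cats = sequences[fold][1]
        held = est.score(held_cats)
        return held, est.score(train_cats), held
    parts = {
        c: label_sky_cloud(sequences[c][0], threshold, sequences[c][1],
                           chromosome=str(c))
        for c in chroms
    }
    rng = np.random.default_rng(seed)
    est = CloudSignatureModel(
        signatures=signatures, threshold=threshold, variant=model,
        cloud_signatures=cloud_signatures, n_restarts=1, tol=tol,
        max_iter=max_iter, random_state=int(rng.integers(2 ** 31)),
    ).fit([parts[c] for c in train_keys])
    held = forward_loglik(est.params_, parts[fold])
    cond = conditional_loglik(est.params_, parts[fold])
    return held, est.loglik_, cond


def _as_sequence_dict(sequences) -> dict:
    """Normalize input to {chromosome: (positions, categories)} for one sample."""
    if isinstance(sequences, pd.DataFrame):
        from .catalog import build_sample_sequences

        seqs = build_sample_sequences(sequences)
        samples = {s for s, _ in seqs}
        if len(samples) > 1:
            raise ValueError("cross-validation operates on a single sample")
        return {c: (s.positions, s.categories) for (_, c), s in seqs.items()}
    out = {}
    for key, val in sequences.items():
        if isinstance(val, SampleSequence):
            out[key] = (val.positions, val.categories)
        else:
            out[key] = (np.asarray(val[0]), np.asarray(val[1]))
    return out


def loco_cv(
    sequences,
    signatures: SignatureMatrix,
    thresholds=DEFAULT_THRESHOLD_GRID,
    restarts: int = 5,
    seed: int = 0,
    model: str = "full",
    cloud_signatures=None,
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_jobs: int = 1,
) -> list[CvResult]:
    """Leave-one-chromosome-out CV over a threshold grid for one sample.

    Parameters
    ----------
    sequences : dict or DataFrame
        One sample's mutations: {chrom: (positions, categories)} or a table.
    model : {"full", "single", "restricted", "mmm"}
        The model family to evaluate; ``"mmm"`` fits the mixture baseline,
        whose score does not depend on the threshold.
    """
    seqs = _as_sequence_dict(sequences)
    chroms = sorted(c for c in seqs if len(seqs[c][0]) > 0)
    if len(chroms) < 2:
        raise ValueError(
            "cross-validation needs >= 2 chromosomes with mutations; "
            "use a manual train/test split for single-chromosome samples"
        )
    thresholds = list(thresholds)
    jobs = [
        (ti, thr, ri, fi, fold)
        for ti, thr in enumerate(thresholds)
        for ri in range(restarts)
        for fi, fold in enumerate(chroms)
    ]
    # the init seed is shared across folds of one restart, so folds differ
    # only by their training data (two identical chromosomes score equally)
    results = Parallel(n_jobs=n_jobs)(
        delayed(_one_fold)(
            seqs, signatures, thr, fold, chroms,
            (seed, ti, ri), model, cloud_signatures, tol, max_iter,
        )
        for ti, thr, ri, fi, fold in jobs
    )
    out = []
    for ti, thr in enumerate(thresholds):
        held = np.empty((restarts, len(chroms)))
        train = np.empty((restarts, len(chroms)))
        cond = np.empty((restarts, len(chroms)))
        for (tj, _, ri, fi, _), (h, tr, c) in zip(jobs, results):
            if tj == ti:
                held[ri, fi], train[ri, fi], cond[ri, fi] = h, tr, c
        out.append(CvResult(int(thr), [str(c) for c in chroms],
                            held, train, cond, model=model))
    return out


def choose_threshold(results: list[CvResult]) -> int:
    """Threshold with the highest median held-out log-likelihood."""
    best = max(results, key=lambda r: r.median_heldout)
    return best.threshold


def cv_report(results: list[CvResult]) -> pd.DataFrame:
    """Tidy per-(threshold, restart, fold) report plus summary rows."""
    rows = []
    for res in results:
        for ri in range(res.heldout.shape[0]):
            for fi, chrom in enumerate(res.chromosomes):
                rows.append({
                    "threshold": res.threshold, "fold": chrom, "restart": ri,
                    "train_loglik": res.train[ri, fi],
                    "heldout_loglik": res.heldout[ri, fi],
                    "heldout_conditional": res.conditional[ri, fi],
                    "summary": False,
                })
        rows.append({
            "threshold": res.threshold, "fold": "all", "restart": -1,
            "train_loglik": np.nan,
            "heldout_loglik": res.median_heldout,
            "heldout_conditional": res.median_conditional,
            "summary": True,
        })
    return pd.DataFrame(rows)


def majority_assignment(paths):
    """Per-mutation modal signature over restarts, plus agreement.

    Parameters
    ----------
    paths : list of DecodedPath or list/array of per-restart signature arrays
        All restarts must cover the same mutation list.

    Returns
    -------
    consensus : ndarray
        Modal signature per mutation (ties broken toward the lower index).
    agreement : float
        Mean over restarts of the fraction of mutations matching the consensus.
    """
    arrays = []
    for p in paths:
        arrays.append(p.signatures if isinstance(p, DecodedPath) else np.asarray(p))
    if not arrays:
        raise ValueError("need at least one decoded path")
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("restart paths cover different mutation lists")
    stack = np.stack(arrays)  # R x N
    kmax = int(stack.max()) + 1 if n else 1
    consensus = np.empty(n, dtype=int)
    for j in range(n):
        consensus[j] = np.argmax(np.bincount(stack[:, j], minlength=kmax))
    agreement = float((stack == consensus[None, :]).mean()) if n else 1.0
    return consensus, agreement
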