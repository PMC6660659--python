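"""Downstream statistics on decoded signature assignments.

Covers per-sample signature exposures split by sky/cloud compartment,
transition counting within chain-generated cloud runs pooled across samples,
enrichment of transitions via Pearson residuals (with an option to correct
for the dominant self-transitions), and a context-preserving permutation null
that shuffles signature labels only among mutations of the same 96-channel
category within each sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

COMPARTMENTS = ("all", "sky", "cloud")


def _signature_names(decoded: pd.DataFrame, signature_names):
    if signature_names is not None:
        return list(signature_names)
    return sorted(decoded["signature"].unique())


def _compartment_mask(decoded: pd.DataFrame, compartment: str) -> np.ndarray:
    if compartment == "all":
        return np.ones(len(decoded), dtype=bool)
    if compartment == "sky":
        return (decoded["sky_flag"] == 1).to_numpy()
    if compartment == "cloud":
        return (decoded["sky_flag"] == 0).to_numpy()
    raise ValueError(f"compartment must be one of {COMPARTMENTS}; got {compartment}")


def compute_exposures(
    decoded: pd.DataFrame,
    compartment: str = "all",
    signature_names=None,
) -> pd.DataFrame:
    """Per-sample signature frequencies within a compartment.

    Rows are samples, columns signatures; each non-empty row sums to 1. A
    sample with no mutations in the compartment gets a NaN row (flagged with a
    warning).
    """
    names = _signature_names(decoded, signature_names)
    sub = decoded[_compartment_mask(decoded, compartment)]
    samples = sorted(decoded["sample"].unique())
    out = pd.DataFrame(np.nan, index=pd.Index(samples, name="sample"),
                       columns=names)
    empty = []
    for sample in samples:
        grp = sub[sub["sample"] == sample]
        if len(grp) == 0:
            empty.append(sample)
            continue
        counts = grp["signature"].value_counts()
        out.loc[sample] = [counts.get(n, 0) / len(grp) for n in names]
    if empty:
        warnings.warn(
            f"compartment {compartment!r} empty for sample(s) {empty}; "
            "exposures undefined there", RuntimeWarning,
        )
    return out


def exposure_log2_fold_change(decoded: pd.DataFrame,
                              signature_names=None) -> pd.Series:
    """log2(cloud exposure / sky exposure) per signature, pooled over samples.

    Zero exposures propagate to +/-inf or NaN; interpret alongside counts.
    """
    names = _signature_names(decoded, signature_names)
    cloud = decoded[_compartment_mask(decoded, "cloud")]
    sky = decoded[_compartment_mask(decoded, "sky")]
    out = {}
    for n in names:
        c = (cloud["signature"] == n).mean() if len(cloud) else np.nan
        s = (sky["signature"] == n).mean() if len(sky) else np.nan
        with np.errstate(divide="ignore", invalid="ignore"):
            out[n] = float(np.log2(c / s))
    return pd.Series(out, name="log2_cloud_vs_sky")


@dataclass
class TransitionTable:
    """K x K counts of consecutive signature pairs in chain-generated runs."""

    counts: np.ndarray
    names: list[str]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.names, columns=self.names)


def transition_counts(decoded: pd.DataFrame,
                      signature_names=None) -> TransitionTable:
    """Count signature transitions inside chain-generated cloud runs.

    A pair (Q_{t-1}, Q_t) is counted when the two mutations are adjacent in
    their (sample, chromosome) sequence, both are decoded chain-generated
    (indicator 0), and both lie in the same cloud. Counts are pooled across
    all samples; runs of length 1 contribute nothing.
    """
    names = _signature_names(decoded, signature_names)
    index = {n: i for i, n in enumerate(names)}
    K = len(names)
    counts = np.zeros((K, K), dtype=np.int64)
    for _, grp in decoded.groupby(["sample", "chrom"], sort=False):
        grp = grp.sort_values("pos", kind="stable")
        ind = grp["indicator"].to_numpy()
        cloud = grp["cloud_id"].to_numpy()
        sig = grp["signature"].map(index).to_numpy()
        ok = (ind[:-1] == 0) & (ind[1:] == 0) & \
            (cloud[:-1] >= 0) & (cloud[:-1] == cloud[1:])
        for a, b in zip(sig[:-1][ok], sig[1:][ok]):
            counts[a, b] += 1
    return TransitionTable(counts, names)


def pearson_residuals(table: TransitionTable,
                      exclude_diagonal: bool = False) -> np.ndarray:
    """Pearson residuals (obs - exp) / sqrt(exp) under row/column independence.

    With ``exclude_diagonal`` the margins and the total are computed from the
    off-diagonal cells only, correcting for the dominant self-transitions, and
    the diagonal residuals are returned as NaN. Cells with zero expected count
    are NaN with a warning.
    """
    obs = np.asarray(table.counts, dtype=float)
    K = obs.shape[0]
    if exclude_diagonal:
        off = obs.copy()
        np.fill_diagonal(off, 0.0)
        row, col, total = off.sum(axis=1), off.sum(axis=0), off.sum()
    else:
        row, col, total = obs.sum(axis=1), obs.sum(axis=0), obs.sum()
    if total <= 0:
        raise ValueError("transition table total must be positive")
    expected = np.outer(row, col) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        resid = (obs - expected) / np.sqrt(expected)
    if exclude_diagonal:
        np.fill_diagonal(resid, np.nan)
    zero_exp = (expected == 0)
    if exclude_diagonal:
        np.fill_diagonal(zero_exp, False)
    if zero_exp.any():
        warnings.warn(
            f"{int(zero_exp.sum())} cell(s) have zero expected count; "
            "their residuals are undefined (NaN)", RuntimeWarning,
        )
        resid[zero_exp] = np.nan
    return resid


def enriched_transition_pairs(residuals: np.ndarray, names,
                              min_residual: float = 10.0):
    """Signature pairs with residuals above a threshold in both directions.

    The default threshold of 10 is the conventional report filter for calling
    a pair of signatures mutually enriched.
    """
    pairs = []
    K = len(names)
    for i in range(K):
        for j in range(i + 1, K):
            if (np.isfinite(residuals[i, j]) and np.isfinite(residuals[j, i])
                    and residuals[i, j] > min_residual
                    and residuals[j, i] > min_residual):
                pairs.append((names[i], names[j]))
    return pairs


def signature_cooccurrence(exposures: pd.DataFrame,
                           min_exposure: float = 0.01) -> pd.DataFrame:
    """Boolean presence table: a signature is present in a sample when its
    exposure is at least ``min_exposure``."""
    return exposures.ge(min_exposure)


def iter_context_preserving_permutations(decoded: pd.DataFrame, n_perm: int,
                                         seed=None):
    """Yield permuted signature-index arrays preserving context composition.

    Within each sample and each of the 96 categories, the observed signature
    labels are shuffled among that block's mutations, so per-sample
    per-category signature totals are invariant under every permutation.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    labels = decoded["signature_index"].to_numpy()
    blocks = [
        idx.to_numpy()
        for _, idx in decoded.groupby(["sample", "category"],
                                      sort=True).groups.items()
    ]
    # positional indices, robust to non-range DataFrame indexes
    pos = {lab: i for i, lab in enumerate(decoded.index)}
    blocks = [np.array([pos[l] for l in b]) for b in blocks]
    for _ in range(n_perm):
        out = labels.copy()
        for b in blocks:
            if len(b) > 1:
                out[b] = labels[b][rng.permutation(len(b))]
        yield out


def context_preserving_permutation(decoded: pd.DataFrame, n_perm: int,
                                   seed=None) -> np.ndarray:
    """Materialized permutation null: array of shape (n_perm, n_mutations)."""
    return np.stack(
        list(iter_context_preserving_permutations(decoded, n_perm, seed))
    )
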