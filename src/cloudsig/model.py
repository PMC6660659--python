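"""The composite sky/cloud signature model: likelihood, training, decoding.

The model explains an ordered sequence of mutation categories O_1..O_T on one
chromosome with two hidden variables per mutation: the signature Q_t that
emitted it, and a binary generator indicator I_t selecting *chain* generation
(I_t = 0, an HMM step) or *mixture* generation (I_t = 1, an independent draw,
as in the stand-alone multinomial mixture). The joint distribution factorizes
as

    Pr(O, Q, I) = Pr(Q_1) Pr(I_1)
                  * prod_{t>=2} Pr(Q_t | Q_{t-1}, I_{t-1}, I_t) Pr(I_t | I_{t-1})
                  * prod_t Pr(O_t | Q_t)

with conditional distributions

    Pr(Q_1 = j)               = pi_j
    Pr(I_1 = i)               = rho_i
    Pr(Q_t = j | Q_{t-1} = i,
       I_{t-1} = f, I_t = g)  = A_ij  if f = 0 and g = 0, else pi_j
    Pr(I_t = g | I_{t-1} = f) = B_fg
    Pr(O_t = o | Q_t = k)     = E_ko

so mixture-generated mutations are always independent draws from pi, and the
signature transition matrix A only acts along uninterrupted chain runs. The
spatial sky/cloud partition enters as *clamping*: at sky positions (nearest
flanking mutations farther than the distance threshold) the indicator is
clamped to 1; at cloud positions it is free in {0, 1}. The likelihood is the
sum over all admissible (Q, I) paths; indicator-chain factors at clamped
positions are retained, so train/held-out comparisons between parameterized
variants stay coherent.

The emission matrix E is fixed throughout; a model for K signatures learns
(K - 1) + K(K - 1) + 2 + 1 = K^2 + 2 free parameters (146 for K = 12).

All recursions run in log space over the 2K joint states (k, f), laid out as
s = f*K + k (chain block first), with log-sum-exp for stability.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .catalog import CATEGORY_LABELS, SampleSequence, SignatureMatrix
from .partition import PartitionedSequence, label_sky_cloud

CHAIN, MIXTURE = 0, 1  # indicator values: 0 = chain-generated, 1 = mixture


def count_free_parameters(K: int) -> int:
    """Number of free parameters learned for K signatures: K^2 + 2.

    pi contributes K - 1, A contributes K(K - 1), B contributes 2 and rho
    contributes 1; the emission matrix is fixed and not counted.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1; got {K}")
    return K * K + 2


def _check_stochastic(name: str, v: np.ndarray, axis=None) -> None:
    if np.any(v < 0):
        raise ValueError(f"{name} must be non-negative")
    sums = v.sum(axis=axis) if axis is not None else v.sum()
    if np.any(np.abs(sums - 1.0) > 1e-10):
        raise ValueError(f"{name} must sum to 1 within 1e-10")


@dataclass
class CloudSignatureParams:
    """Per-sample learned parameters of the sky/cloud model.

    Attributes
    ----------
    pi : ndarray (K,)
        Signature starting/restart distribution; also the mixture marginal.
    A : ndarray (K, K)
        Signature transition matrix along chain runs.
    rho : ndarray (2,)
        Starting distribution of the generator indicator (chain, mixture).
    B : ndarray (2, 2)
        Indicator transition matrix between chain and mixture generation.
    signatures : SignatureMatrix
        The fixed emission matrix E and signature names.
    threshold : int
        Sky/cloud distance threshold in bp.
    chain_allowed : ndarray of bool (K,), optional
        Signatures permitted in chain-generated states (restricted variant);
        None means all.
    """

    pi: np.ndarray
    A: np.ndarray
    rho: np.ndarray
    B: np.ndarray
    signatures: SignatureMatrix
    threshold: int = 2000
    chain_allowed: np.ndarray | None = None

    def __post_init__(self) -> None:
        K = self.signatures.K
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if self.pi.shape != (K,) or self.A.shape != (K, K):
            raise ValueError("pi/A shapes must match the signature count")
        if self.rho.shape != (2,) or self.B.shape != (2, 2):
            raise ValueError("rho must be length 2 and B 2x2")
        _check_stochastic("pi", self.pi)
        _check_stochastic("A rows", self.A, axis=1)
        _check_stochastic("rho", self.rho)
        _check_stochastic("B rows", self.B, axis=1)
        if self.chain_allowed is not None:
            self.chain_allowed = np.asarray(self.chain_allowed, dtype=bool)
            if self.chain_allowed.shape != (K,):
                raise ValueError("chain_allowed must have one flag per signature")

    @property
    def K(self) -> int:
        return self.signatures.K

    def to_json(self, **extra) -> str:
        doc = {
            "signatures": self.signatures.names,
            "pi": self.pi.tolist(),
            "A": self.A.tolist(),
            "rho": self.rho.tolist(),
            "B": self.B.tolist(),
            "threshold": self.threshold,
            "chain_allowed": None if self.chain_allowed is None
            else self.chain_allowed.tolist(),
        }
        doc.update(extra)
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str, signatures: SignatureMatrix) -> "CloudSignatureParams":
        doc = json.loads(text)
        if doc["signatures"] != signatures.names:
            raise ValueError("signature names do not match the provided matrix")
        return cls(
            pi=np.array(doc["pi"]), A=np.array(doc["A"]),
            rho=np.array(doc["rho"]), B=np.array(doc["B"]),
            signatures=signatures, threshold=int(doc["threshold"]),
            chain_allowed=None if doc.get("chain_allowed") is None
            else np.array(doc["chain_allowed"], dtype=bool),
        )


@dataclass
class Variant:
    """A constrained-model specification produced by :func:`constrain_variant`."""

    kind: str  # "full" | "single" | "restricted"
    chain_allowed: np.ndarray | None = None  # bool (K,) or None
    fix_identity_A: bool = False


def constrain_variant(
    variant: str,
    signatures: SignatureMatrix,
    cloud_signatures: list[str] | None = None,
) -> Variant:
    """Build a model-variant specification.

    - ``"full"``: unconstrained.
    - ``"single"`` (single signature per cloud run): A is clamped to the
      identity, so chain-generated runs cannot switch signature.
    - ``"restricted"``: chain-generated states are limited to the signatures
      named in ``cloud_signatures`` (mixture-generated states, including all
      sky mutations, remain unrestricted).
    """
    if variant in ("full", None):
        return Variant("full")
    if variant in ("single", "single-signature-per-cloud"):
        return Variant("single", fix_identity_A=True)
    if variant in ("restricted", "restricted-cloud-signatures"):
        if not cloud_signatures:
            raise ValueError("restricted variant needs a non-empty signature set")
        unknown = [n for n in cloud_signatures if n not in signatures.names]
        if unknown:
            raise ValueError(f"restricted set contains unknown signature(s): {unknown}")
        mask = np.array([n in cloud_signatures for n in signatures.names])
        return Variant("restricted", chain_allowed=mask)
    raise ValueError(f"unknown variant {variant!r}")


def transition_cpd(params: CloudSignatureParams, prev_signature: int,
                   prev_indicator: int, cur_indicator: int) -> np.ndarray:
    """Distribution of the current signature given the previous joint state.

    Returns row ``prev_signature`` of A when both the previous and the current
    mutation are chain-generated; otherwise (either side mixture-generated)
    returns pi, so mixture draws are independent.
    """
    if prev_indicator == CHAIN and cur_indicator == CHAIN:
        return params.A[prev_signature].copy()
    return params.pi.copy()


# ---------------------------------------------------------------------------
# Lattice construction: log transition matrix, initial vector, per-position
# admissibility masks over the 2K joint states s = f*K + k.
# ---------------------------------------------------------------------------

def _log(v):
    with np.errstate(divide="ignore"):
        return np.log(v)


def _state_logs(params: CloudSignatureParams):
    K = params.K
    log_pi, log_A = _log(params.pi), _log(params.A)
    log_B, log_rho = _log(params.B), _log(params.rho)
    S = 2 * K
    logT = np.empty((S, S))
    logT[:K, :K] = log_B[0, 0] + log_A
    logT[:K, K:] = log_B[0, 1] + log_pi[None, :]
    logT[K:, :K] = log_B[1, 0] + log_pi[None, :]
    logT[K:, K:] = log_B[1, 1] + log_pi[None, :]
    loginit = np.concatenate([log_rho[0] + log_pi, log_rho[1] + log_pi])
    return logT, loginit


def _position_masks(params: CloudSignatureParams, part: PartitionedSequence) -> np.ndarray:
    """Additive log-mask (T, 2K): -inf on inadmissible joint states."""
    K, T = params.K, len(part)
    mask = np.zeros((T, 2 * K))
    sky = part.sky_flag.astype(bool)
    mask[sky, :K] = -np.inf  # indicator clamped to mixture at sky positions
    if params.chain_allowed is not None:
        mask[:, :K][:, ~params.chain_allowed] = -np.inf
    return mask


def _log_emissions(params: CloudSignatureParams, categories: np.ndarray) -> np.ndarray:
    emit_k = params.signatures.log_E[:, categories].T  # T x K
    return np.concatenate([emit_k, emit_k], axis=1)  # T x 2K


def _prepare(params: CloudSignatureParams, part: PartitionedSequence):
    logT, loginit = _state_logs(params)
    em = _log_emissions(params, part.categories) + _position_masks(params, part)
    return logT, loginit, em


def _forward(logT, loginit, em):
    # log-domain recursion; each step shifts by the running max so the
    # matrix product runs in scaled linear space without under/overflow
    T, S = em.shape
    alpha = np.empty((T, S))
    alpha[0] = loginit + em[0]
    Tlin = np.exp(logT)
    with np.errstate(divide="ignore"):
        for t in range(1, T):
            m = alpha[t - 1].max()
            alpha[t] = np.log(np.exp(alpha[t - 1] - m) @ Tlin) + m + em[t]
    return alpha, float(logsumexp(alpha[-1]))


def _backward(logT, em):
    T, S = em.shape
    beta = np.zeros((T, S))
    Tlin = np.exp(logT)
    with np.errstate(divide="ignore"):
        for t in range(T - 1, 0, -1):
            v = em[t] + beta[t]
            m = v.max()
            beta[t - 1] = np.log(Tlin @ np.exp(v - m)) + m
    return beta


def _as_part_list(parts) -> list[PartitionedSequence]:
    if isinstance(parts, PartitionedSequence):
        return [parts]
    if isinstance(parts, dict):
        return list(parts.values())
    return list(parts)


def forward_loglik(params: CloudSignatureParams, parts) -> float:
    """Log-likelihood of one or more partitioned sequences (forward recursion).

    Sums log Pr(O, I admissible) over the given sequences: every chromosome is
    an independent observation sequence sharing the sample's parameters, with
    rho applying at each chromosome start.
    """
    total = 0.0
    for part in _as_part_list(parts):
        if len(part) == 0:
            continue
        logT, loginit, em = _prepare(params, part)
        _, ll = _forward(logT, loginit, em)
        total += ll
    return total


def indicator_loglik(params: CloudSignatureParams, parts) -> float:
    """Log-probability mass of the admissible indicator set alone.

    A 2-state forward over the indicator chain (rho, B) with the same sky
    clamping but no emissions; subtracting it from :func:`forward_loglik`
    yields a category-predictive score comparable across model families.
    """
    log_B, log_rho = _log(params.B), _log(params.rho)
    total = 0.0
    for part in _as_part_list(parts):
        T = len(part)
        if T == 0:
            continue
        mask = np.zeros((T, 2))
        mask[part.sky_flag.astype(bool), CHAIN] = -np.inf
        a = log_rho + mask[0]
        with np.errstate(invalid="ignore"):
            for t in range(1, T):
                a = logsumexp(a[:, None] + log_B, axis=0) + mask[t]
        total += float(logsumexp(a))
    return total


def conditional_loglik(params: CloudSignatureParams, parts) -> float:
    """Category-predictive log score: forward minus indicator-chain mass."""
    return forward_loglik(params, parts) - indicator_loglik(params, parts)


def joint_logprob(params: CloudSignatureParams, part: PartitionedSequence,
                  indicators, signatures) -> float:
    """Log-probability of one fully specified (Q, I) path (direct product).

    Returns -inf for inadmissible paths (chain indicator at a sky-clamped
    position, or a chain state outside a restricted signature set).
    """
    indicators = np.asarray(indicators, dtype=int)
    sigs = np.asarray(signatures, dtype=int)
    T = len(part)
    if len(indicators) != T or len(sigs) != T:
        raise ValueError("indicators and signatures must match the sequence length")
    if T == 0:
        return 0.0
    sky = part.sky_flag.astype(bool)
    if np.any(indicators[sky] == CHAIN):
        return -np.inf
    if params.chain_allowed is not None and np.any(
        (indicators == CHAIN) & ~params.chain_allowed[sigs]
    ):
        return -np.inf
    log_pi, log_A = _log(params.pi), _log(params.A)
    log_B, log_rho = _log(params.B), _log(params.rho)
    log_E = params.signatures.log_E
    lp = log_rho[indicators[0]] + log_pi[sigs[0]] + log_E[sigs[0], part.categories[0]]
    for t in range(1, T):
        lp += log_B[indicators[t - 1], indicators[t]]
        if indicators[t - 1] == CHAIN and indicators[t] == CHAIN:
            lp += log_A[sigs[t - 1], sigs[t]]
        else:
            lp += log_pi[sigs[t]]
        lp += log_E[sigs[t], part.categories[t]]
    return float(lp)


# ---------------------------------------------------------------------------
# Exhaustive-enumeration oracle (small instances only).
# ---------------------------------------------------------------------------

def _iter_admissible_indicators(sky_flag: np.ndarray):
    T = len(sky_flag)
    cloud_idx = np.where(sky_flag == 0)[0]
    for bits in itertools.product((0, 1), repeat=len(cloud_idx)):
        I = np.ones(T, dtype=int)
        I[cloud_idx] = bits
        yield I


def _enumeration_size(params: CloudSignatureParams, part: PartitionedSequence) -> int:
    n_cloud = int((part.sky_flag == 0).sum())
    return params.K ** len(part) * 2 ** n_cloud


def _enumerate(params: CloudSignatureParams, part: PartitionedSequence,
               max_paths: int = 4_000_000):
    """Yield (I, per-path log-probs, paths T x K^T) over all admissible paths."""
    T, K = len(part), params.K
    if _enumeration_size(params, part) > max_paths:
        raise ValueError(
            "instance too large for exhaustive enumeration "
            f"({_enumeration_size(params, part)} > {max_paths} paths)"
        )
    log_pi, log_A = _log(params.pi), _log(params.A)
    log_B, log_rho = _log(params.B), _log(params.rho)
    log_E = params.signatures.log_E
    chain_mask = np.zeros(K)
    if params.chain_allowed is not None:
        chain_mask[~params.chain_allowed] = -np.inf
    paths = np.array(list(itertools.product(range(K), repeat=T)), dtype=int).T
    O = part.categories
    for I in _iter_admissible_indicators(part.sky_flag):
        lp = log_rho[I[0]] + log_pi[paths[0]] + log_E[paths[0], O[0]]
        if I[0] == CHAIN:
            lp = lp + chain_mask[paths[0]]
        for t in range(1, T):
            lp = lp + log_B[I[t - 1], I[t]] + log_E[paths[t], O[t]]
            if I[t - 1] == CHAIN and I[t] == CHAIN:
                lp = lp + log_A[paths[t - 1], paths[t]]
            else:
                lp = lp + log_pi[paths[t]]
            if I[t] == CHAIN:
                lp = lp + chain_mask[paths[t]]
        yield I, lp, paths


def brute_force_loglik(params: CloudSignatureParams, part: PartitionedSequence,
                       max_paths: int = 4_000_000) -> float:
    """Exhaustive log-sum over all admissible (Q, I) paths (test oracle).

    Refuses instances whose admissible path count K^T * 2^(#cloud) exceeds
    ``max_paths``. Agrees with :func:`forward_loglik` to ~1e-9 relative.
    """
    pieces = [logsumexp(lp) for _, lp, _ in _enumerate(params, part, max_paths)]
    return float(logsumexp(pieces))


def brute_force_decode(params: CloudSignatureParams, part: PartitionedSequence,
                       max_paths: int = 4_000_000):
    """Exhaustive argmax over admissible paths: (signatures, indicators, logp).

    When several paths tie for the maximum (ties are structural: indicator
    rearrangements with identical factor products), an arbitrary maximizer is
    returned; compare by log-probability, or gate exact-path comparisons on
    :func:`brute_force_path_logprobs` showing a unique argmax.
    """
    best = (-np.inf, None, None)
    for I, lp, paths in _enumerate(params, part, max_paths):
        j = int(np.argmax(lp))
        if lp[j] > best[0]:
            best = (float(lp[j]), paths[:, j].copy(), I.copy())
    return best[1], best[2], best[0]


def brute_force_path_logprobs(params: CloudSignatureParams, part: PartitionedSequence,
                              max_paths: int = 4_000_000) -> np.ndarray:
    """Log-probabilities of every admissible (Q, I) path, unsorted."""
    return np.concatenate(
        [lp for _, lp, _ in _enumerate(params, part, max_paths)]
    )


# ---------------------------------------------------------------------------
# Viterbi decoding.
# ---------------------------------------------------------------------------

@dataclass
class DecodedPath:
    """Viterbi assignment for one partitioned sequence.

    ``signatures`` holds per-mutation signature indices; ``indicators`` is 0
    where the mutation is chain-generated (sequence-dependent) and 1 where it
    is mixture-generated. The indicator is 1 at every sky position.
    """

    part: PartitionedSequence
    signatures: np.ndarray
    indicators: np.ndarray
    logprob: float

    def to_frame(self, signature_names: list[str]) -> pd.DataFrame:
        p = self.part
        return pd.DataFrame(
            {
                "sample": p.sample_id,
                "chrom": p.chromosome,
                "pos": p.positions,
                "category": [CATEGORY_LABELS[c] for c in p.categories],
                "signature_index": self.signatures,
                "signature": [signature_names[k] for k in self.signatures],
                "indicator": self.indicators,
                "sky_flag": p.sky_flag,
                "cloud_id": p.cloud_id,
            }
        )


def _preference_order(K: int) -> np.ndarray:
    # tie-break: lower signature index first, then indicator 1 (mixture)
    order = []
    for k in range(K):
        order.extend([K + k, k])
    return np.array(order, dtype=int)


def viterbi_decode(params: CloudSignatureParams, part: PartitionedSequence) -> DecodedPath:
    """Most probable admissible (Q, I) path by dynamic programming.

    Ties are broken toward the lower signature index, then toward the mixture
    indicator, both for the terminal state and for each backpointer.
    """
    T, K = len(part), params.K
    if T == 0:
        return DecodedPath(part, np.empty(0, int), np.empty(0, int), 0.0)
    logT, loginit, em = _prepare(params, part)
    S = 2 * K
    pref = _preference_order(K)
    delta = loginit + em[0]
    psi = np.empty((T, S), dtype=int)
    with np.errstate(invalid="ignore"):
        for t in range(1, T):
            scores = delta[:, None] + logT  # from x to
            sub = scores[pref, :]
            am = np.argmax(sub, axis=0)
            psi[t] = pref[am]
            delta = sub[am, np.arange(S)] + em[t]
    final_vals = delta[pref]
    state = int(pref[np.argmax(final_vals)])
    logp = float(delta[state])
    states = np.empty(T, dtype=int)
    states[-1] = state
    for t in range(T - 1, 0, -1):
        states[t - 1] = psi[t, states[t]]
    indicators, signatures = np.divmod(states, K)
    return DecodedPath(part, signatures, indicators, logp)


def decode_sample(params: CloudSignatureParams, parts) -> list[DecodedPath]:
    """Viterbi-decode every chromosome sequence of one sample."""
    return [viterbi_decode(params, p) for p in _as_part_list(parts)]


def assignments_frame(decoded, signature_names: list[str]) -> pd.DataFrame:
    """Concatenate decoded paths into one tidy assignment table."""
    frames = [d.to_frame(signature_names) for d in _as_part_list(decoded)]
    if not frames:
        return pd.DataFrame(
            columns=["sample", "chrom", "pos", "category", "signature_index",
                     "signature", "indicator", "sky_flag", "cloud_id"]
        )
    return pd.concat(frames, ignore_index=True)


def sequence_dependent_fraction(decoded) -> float:
    """Fraction of cloud mutations whose Viterbi indicator is chain (0).

    Accepts decoded paths or an assignment table. Returns NaN (with a warning)
    when there are no cloud mutations.
    """
    if isinstance(decoded, pd.DataFrame):
        cloud = decoded[decoded["cloud_id"] >= 0]
        n_cloud = len(cloud)
        n_chain = int((cloud["indicator"] == CHAIN).sum())
    else:
        n_cloud = n_chain = 0
        for d in _as_part_list(decoded):
            in_cloud = d.part.cloud_id >= 0
            n_cloud += int(in_cloud.sum())
            n_chain += int((d.indicators[in_cloud] == CHAIN).sum())
    if n_cloud == 0:
        warnings.warn("no cloud mutations; sequence-dependent fraction undefined",
                      RuntimeWarning)
        return float("nan")
    return n_chain / n_cloud


# ---------------------------------------------------------------------------
# Baum-Welch training.
# ---------------------------------------------------------------------------

def _layout_init_B_rho(parts: list[PartitionedSequence]):
    """Initial B and rho from the observed sky/cloud run structure.

    The spatial labels (sky=1, cloud=0) are used as a proxy indicator path;
    counts are smoothed by +1 so both rows stay stochastic.
    """
    trans = np.ones((2, 2))
    first = np.ones(2)
    for part in parts:
        lab = part.sky_flag.astype(int)
        if len(lab) == 0:
            continue
        first[lab[0]] += 1
        for f, g in zip(lab[:-1], lab[1:]):
            trans[f, g] += 1
    return trans / trans.sum(axis=1, keepdims=True), first / first.sum()


def _random_init(rng: np.random.Generator, K: int, variant: Variant):
    pi = rng.dirichlet(np.ones(K))
    if variant.fix_identity_A:
        A = np.eye(K)
    elif variant.chain_allowed is not None:
        A = np.zeros((K, K))
        allowed = np.where(variant.chain_allowed)[0]
        A[:, allowed] = rng.dirichlet(np.ones(len(allowed)), size=K)
    else:
        A = rng.dirichlet(np.ones(K), size=K)
    return pi, A


def _baum_welch_single(
    parts: list[PartitionedSequence],
    signatures: SignatureMatrix,
    threshold: int,
    pi0: np.ndarray,
    A0: np.ndarray,
    B0: np.ndarray,
    rho0: np.ndarray,
    variant: Variant,
    tol: float,
    max_iter: int,
    update_B: bool,
):
    """One EM run from a given initialization. Returns (params, trace, converged)."""
    K = signatures.K
    params = CloudSignatureParams(pi0, A0, rho0, B0, signatures, threshold,
                         chain_allowed=variant.chain_allowed)
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        logT, loginit = _state_logs(params)
        xi = np.zeros((2 * K, 2 * K))
        gamma_init = np.zeros(2 * K)
        total_ll = 0.0
        for part in parts:
            if len(part) == 0:
                continue
            em = _log_emissions(params, part.categories) + \
                _position_masks(params, part)
            alpha, ll = _forward(logT, loginit, em)
            beta = _backward(logT, em)
            total_ll += ll
            gamma_init += np.exp(alpha[0] + beta[0] - ll)
            embm = em + beta  # T x S
            T_len = len(part)
            with np.errstate(invalid="ignore"):
                for lo in range(1, T_len, 512):  # chunked pairwise posteriors
                    hi = min(lo + 512, T_len)
                    block = (alpha[lo - 1:hi - 1, :, None]
                             + embm[lo:hi, None, :] + logT[None] - ll)
                    xi += np.exp(block).sum(axis=0)
        trace.append(total_ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= \
                tol * max(abs(trace[-2]), 1.0):
            converged = True
            break

        # M-step: expected-count updates, E fixed.
        pi_counts = (
            gamma_init[:K] + gamma_init[K:]          # initial positions
            + xi[:, K:].sum(axis=0).reshape(-1)      # targets (j, mixture)
            + xi[K:, :K].sum(axis=0)                 # mixture -> chain entries
        )
        new_pi = pi_counts / pi_counts.sum()
        if variant.fix_identity_A:
            new_A = params.A
        else:
            A_counts = xi[:K, :K]
            row_tot = A_counts.sum(axis=1)
            new_A = params.A.copy()
            nonzero = row_tot > 0
            new_A[nonzero] = A_counts[nonzero] / row_tot[nonzero, None]
        if update_B:
            B_counts = np.array(
                [[xi[:K, :K].sum(), xi[:K, K:].sum()],
                 [xi[K:, :K].sum(), xi[K:, K:].sum()]]
            )
            rho_counts = np.array([gamma_init[:K].sum(), gamma_init[K:].sum()])
            B_tot = B_counts.sum(axis=1)
            new_B = params.B.copy()
            nz = B_tot > 0
            new_B[nz] = B_counts[nz] / B_tot[nz, None]
            new_rho = rho_counts / rho_counts.sum()
        else:
            new_B, new_rho = params.B, params.rho
        params = CloudSignatureParams(new_pi, new_A, new_rho, new_B, signatures,
                             threshold, chain_allowed=variant.chain_allowed)
    return params, trace, converged


def _coerce_parts(X, threshold: int) -> list[PartitionedSequence]:
    """Accept partitioned sequences, raw (positions, categories) material, or a
    single-sample mutation table, and return per-chromosome partitions."""
    if isinstance(X, PartitionedSequence):
        return [X]
    if isinstance(X, pd.DataFrame):
        from .catalog import build_sample_sequences

        seqs = build_sample_sequences(X)
        samples = {s for s, _ in seqs}
        if len(samples) > 1:
            raise ValueError(
                f"a model is trained per sample; table has {len(samples)} samples"
            )
        return [
            label_sky_cloud(s.positions, threshold, s.categories,
                            sample_id=s.sample_id, chromosome=s.chromosome)
            for s in seqs.values()
        ]
    items = list(X.values()) if isinstance(X, dict) else list(X)
    out = []
    for item in items:
        if isinstance(item, PartitionedSequence):
            out.append(item)
        elif isinstance(item, SampleSequence):
            out.append(
                label_sky_cloud(item.positions, threshold, item.categories,
                                sample_id=item.sample_id,
                                chromosome=item.chromosome)
            )
        else:
            positions, categories = item
            out.append(label_sky_cloud(positions, threshold, categories))
    return out


class CloudSignatureModel(BaseEstimator):
    """Sky/cloud signature-assignment model for one sample, fit by Baum-Welch.

    Parameters
    ----------
    signatures : SignatureMatrix
        Fixed emission matrix (K signatures x 96 categories).
    threshold : int, default 2000
        Sky/cloud distance threshold in bp.
    variant : {"full", "single", "restricted"}, default "full"
        Model variant; see :func:`constrain_variant`.
    cloud_signatures : list of str, optional
        Allowed chain signatures for the restricted variant.
    n_restarts : int, default 10
        Independent random initializations; the best final log-likelihood wins.
    tol : float, default 1e-6
        Relative log-likelihood change declaring convergence.
    max_iter : int, default 1000
        EM iteration cap per restart.
    update_B : bool, default True
        Re-estimate the indicator transition matrix B and rho inside EM; when
        False they stay at their direct estimate from the observed sky/cloud
        run structure.
    random_state : int, optional
        Root seed; restart seeds are spawned from it by counter.
    init : dict, optional
        Explicit initial values (keys among pi, A, B, rho); overrides the
        random draw and forces a single restart.

    Attributes
    ----------
    params_ : CloudSignatureParams
    pi_, A_, B_, rho_ : ndarray views of the fitted parameters
    loglik_ : float, final training log-likelihood of the best restart
    loglik_trace_ : list of float (best restart, non-decreasing)
    restart_logliks_ : list of float
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, signatures=None, threshold=2000, variant="full",
                 cloud_signatures=None, n_restarts=10, tol=1e-6, max_iter=1000,
                 update_B=True, random_state=None, init=None):
        self.signatures = signatures
        self.threshold = threshold
        self.variant = variant
        self.cloud_signatures = cloud_signatures
        self.n_restarts = n_restarts
        self.tol = tol
        self.max_iter = max_iter
        self.update_B = update_B
        self.random_state = random_state
        self.init = init

    def _parts(self, X) -> list[PartitionedSequence]:
        parts = _coerce_parts(X, self.threshold)
        if sum(len(p) for p in parts) == 0:
            raise ValueError("cannot fit on a sample with no mutations")
        return parts

    def fit(self, X, y=None):
        sig = self.signatures
        if sig is None:
            raise ValueError("signatures must be provided")
        parts = self._parts(X)
        var = constrain_variant(self.variant, sig, self.cloud_signatures)
        B0, rho0 = _layout_init_B_rho(parts)
        if all(p.n_cloud == 0 for p in parts):
            warnings.warn(
                "sample has no cloud mutations; the transition matrix A stays "
                "at its initialization (no evidence)", RuntimeWarning,
            )

        if self.init is not None:
            inits = [(
                np.asarray(self.init.get("pi",
                                         np.full(sig.K, 1.0 / sig.K)), float),
                np.eye(sig.K) if var.fix_identity_A
                else np.asarray(self.init.get(
                    "A", np.full((sig.K, sig.K), 1.0 / sig.K)), float),
                np.asarray(self.init.get("B", B0), float),
                np.asarray(self.init.get("rho", rho0), float),
            )]
        else:
            root = np.random.SeedSequence(self.random_state)
            inits = []
            for child in root.spawn(self.n_restarts):
                rng = np.random.default_rng(child)
                pi0, A0 = _random_init(rng, sig.K, var)
                inits.append((pi0, A0, B0, rho0))

        best = None
        restart_lls = []
        for pi0, A0, b0, r0 in inits:
            params, trace, conv = _baum_welch_single(
                parts, sig, self.threshold, pi0, A0, b0, r0, var,
                self.tol, self.max_iter, self.update_B,
            )
            restart_lls.append(trace[-1])
            if best is None or trace[-1] > best[1][-1]:
                best = (params, trace, conv)
        params, trace, conv = best
        if not conv:
            warnings.warn(
                f"Baum-Welch did not converge in {self.max_iter} iterations",
                RuntimeWarning,
            )
        self.params_ = params
        self.pi_, self.A_ = params.pi, params.A
        self.B_, self.rho_ = params.B, params.rho
        self.loglik_trace_ = trace
        self.loglik_ = trace[-1]
        self.restart_logliks_ = restart_lls
        self.n_iter_ = len(trace)
        self.converged_ = conv
        self.variant_ = var
        return self

    def score(self, X, y=None) -> float:
        """Forward log-likelihood of (possibly held-out) sequences."""
        return forward_loglik(self.params_, self._parts(X))

    def conditional_score(self, X) -> float:
        """Category-predictive score (forward minus indicator-chain mass)."""
        return conditional_loglik(self.params_, self._parts(X))

    def decode(self, X) -> list[DecodedPath]:
        """Viterbi paths for each chromosome sequence."""
        return decode_sample(self.params_, self._parts(X))

    def predict(self, X) -> pd.DataFrame:
        """Viterbi assignment table (one row per mutation)."""
        return assignments_frame(self.decode(X), self.signatures.names)


def baum_welch_fit(sequences, E: SignatureMatrix, threshold: int = 2000,
                   init: dict | None = None, tol: float = 1e-6,
                   max_iter: int = 1000, seed=None, n_restarts: int = 1,
                   variant: str = "full", cloud_signatures=None,
                   update_B: bool = True):
    """Functional wrapper around :class:`CloudSignatureModel`.

    Returns (CloudSignatureParams, log-likelihood trace of the winning restart).
    """
    est = CloudSignatureModel(
        signatures=E, threshold=threshold, variant=variant,
        cloud_signatures=cloud_signatures, n_restarts=n_restarts, tol=tol,
        max_iter=max_iter, update_B=update_B, random_state=seed, init=init,
    ).fit(sequences)
    return est.params_, est.loglik_trace_


def fit_cohort(table: pd.DataFrame, signatures: SignatureMatrix,
               **model_kwargs) -> dict[str, CloudSignatureModel]:
    """Train one model per sample from a cohort mutation table."""
    models = {}
    for sample, grp in table.groupby("sample", sort=True):
        models[str(sample)] = CloudSignatureModel(
            signatures=signatures, **model_kwargs
        ).fit(grp)
    return models
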