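import numpy as np

import cloudsig as cs


def diagonal_params(signatures, diag, B, pi=None, threshold=2000):
    """Planted parameters with a diagonally dominant transition matrix."""
    K = signatures.K
    if pi is None:
        pi = np.arange(K, 0, -1, dtype=float)
        pi = pi / pi.sum()
    A = np.full((K, K), (1 - diag) / (K - 1))
    np.fill_diagonal(A, diag)
    return cs.CloudSignatureParams(pi, A, np.array([0.5, 0.5]),
                                   np.asarray(B, float), signatures, threshold)


def structured_params(signatures, diag, partner, B, threshold=2000):
    """Planted transitions with a preferred partner signature per signature
    (cyclic), the structure that distinguishes the full chain model from the
    single-signature-per-cloud variant."""
    K = signatures.K
    pi = np.arange(K, 0, -1, dtype=float)
    pi = pi / pi.sum()
    rest = (1 - diag - partner) / (K - 2)
    A = np.full((K, K), rest)
    np.fill_diagonal(A, diag)
    for i in range(K):
        A[i, (i + 1) % K] = partner
    return cs.CloudSignatureParams(pi, A, np.array([0.5, 0.5]),
                                   np.asarray(B, float), signatures, threshold)
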