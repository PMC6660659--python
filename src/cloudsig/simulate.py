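"""Generative sampler for the sky/cloud signature model.

Produces cohorts with the model's own statistical structure — genomic layout
(alternating isolated mutations and dense clouds), hidden indicator and
signature chains, and emitted 96-channel categories — together with full
ground truth, serving as the oracle for every recovery test in the package.

The layout generator plants the partition exactly: intra-cloud gaps are drawn
at or below the distance threshold and gaps between separate units strictly
above it, so re-partitioning the sampled positions reproduces the planted
sky/cloud labels. Default geometry mirrors a whole-genome regime in which
clouds hold ~2.33 mutations on average and ~8% of all mutations (wgs-like
preset); the small preset is cloud-enriched for fast, well-conditioned tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import (
    CATEGORY_LABELS,
    N_CATEGORIES,
    SignatureMatrix,
    write_signature_matrix,
)
from .model import CHAIN, MIXTURE, CloudSignatureParams
from .partition import label_sky_cloud


@dataclass
class LayoutSpec:
    """Genomic geometry of a simulated sample.

    Each chromosome carries ``sky_per_chromosome`` isolated mutations and
    ``clouds_per_chromosome`` clouds whose sizes are 2 + Geometric, with mean
    ``cloud_size_mean`` (>= 2). Intra-cloud gaps are uniform on
    [1, threshold]; gaps between units are uniform on
    (threshold, max_sky_gap].
    """

    n_chromosomes: int = 4
    sky_per_chromosome: int = 100
    clouds_per_chromosome: int = 10
    cloud_size_mean: float = 2.33
    threshold: int = 2000
    max_sky_gap: int = 200_000

    def __post_init__(self) -> None:
        if self.cloud_size_mean <= 2:
            raise ValueError("cloud_size_mean must exceed 2")
        if self.max_sky_gap <= self.threshold:
            raise ValueError("max_sky_gap must exceed the threshold")
        if self.threshold < 1:
            raise ValueError("threshold must be positive")

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def expected_cloud_fraction(self) -> float:
        cloud = self.clouds_per_chromosome * self.cloud_size_mean
        return cloud / (cloud + self.sky_per_chromosome)


@dataclass
class GroundTruth:
    """Planted parameters and per-mutation hidden states of a cohort."""

    params: CloudSignatureParams
    spec: LayoutSpec
    truth: pd.DataFrame  # sample, chrom, pos, category, signature, indicator,
    #                      sky_flag, cloud_id

    @property
    def sequence_dependent_fraction(self) -> float:
        cloud = self.truth[self.truth["cloud_id"] >= 0]
        return float((cloud["indicator"] == CHAIN).mean())


def synthetic_signatures(K: int, separation: float = 0.9, seed=0,
                         names=None) -> SignatureMatrix:
    """Synthetic, well-separated signature matrix (stand-in for a real
    catalogue; not derived from any published signature data).

    Signature k concentrates ``separation`` of its mass on its own block of
    96/K categories, with Dirichlet noise spread over the rest, so emissions
    are informative and mixtures are identifiable.
    """
    if not 0 < separation < 1:
        raise ValueError("separation must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if names is None:
        names = [f"Signature {k + 1}" for k in range(K)]
    edges = np.linspace(0, N_CATEGORIES, K + 1).astype(int)
    E = np.empty((K, N_CATEGORIES))
    for k in range(K):
        block = slice(edges[k], edges[k + 1])
        width = block.stop - block.start
        row = rng.dirichlet(np.ones(N_CATEGORIES)) * (1 - separation)
        inner = rng.dirichlet(np.ones(width) * 5.0) * separation
        row[block] += inner
        E[k] = row / row.sum()
    return SignatureMatrix(list(names), E)


def _sample_layout(spec: LayoutSpec, rng: np.random.Generator):
    """Positions and planted labels for one chromosome."""
    p_geo = 1.0 / (spec.cloud_size_mean - 1.0)
    units = ["S"] * spec.sky_per_chromosome + ["C"] * spec.clouds_per_chromosome
    rng.shuffle(units)
    positions: list[int] = []
    sky_flag: list[int] = []
    cloud_id: list[int] = []
    pos = 0
    cid = -1
    for unit in units:
        pos += int(rng.integers(spec.threshold + 1, spec.max_sky_gap + 1))
        if unit == "S":
            positions.append(pos)
            sky_flag.append(1)
            cloud_id.append(-1)
        else:
            cid += 1
            size = 2 + int(rng.geometric(p_geo)) - 1
            for m in range(size):
                if m > 0:
                    pos += int(rng.integers(1, spec.threshold + 1))
                positions.append(pos)
                sky_flag.append(0)
                cloud_id.append(cid)
    return (np.array(positions, dtype=np.int64),
            np.array(sky_flag, dtype=np.int8),
            np.array(cloud_id, dtype=np.int64))


def _sample_hidden(params: CloudSignatureParams, sky_flag: np.ndarray,
                   rng: np.random.Generator):
    """Indicator and signature chains along one chromosome.

    The indicator follows rho/B but is forced to mixture at sky positions;
    the signature follows A only across uninterrupted chain steps.
    """
    T = len(sky_flag)
    I = np.empty(T, dtype=np.int8)
    Q = np.empty(T, dtype=np.int64)
    K = params.K
    for t in range(T):
        if sky_flag[t]:
            I[t] = MIXTURE
        else:
            row = params.rho if t == 0 else params.B[I[t - 1]]
            I[t] = rng.choice(2, p=row)
        if t == 0 or I[t - 1] == MIXTURE or I[t] == MIXTURE:
            Q[t] = rng.choice(K, p=params.pi)
        else:
            Q[t] = rng.choice(K, p=params.A[Q[t - 1]])
    return I, Q


def sample_cohort(spec: LayoutSpec, params: CloudSignatureParams, n_samples: int,
                  seed=0):
    """Sample a cohort mutation table plus ground truth.

    Returns
    -------
    table : DataFrame
        Columns sample, chrom, pos, category (labels like ``A[C>T]G``) — the
        same dialect :func:`cloudsig.catalog.read_mutation_table` reads.
    truth : GroundTruth
        Planted parameters and per-mutation signature/indicator states.
    """
    if params.threshold != spec.threshold:
        raise ValueError("params.threshold must equal spec.threshold")
    root = np.random.SeedSequence(seed)
    rows = []
    for i, sample_ss in enumerate(root.spawn(n_samples)):
        rng = np.random.default_rng(sample_ss)
        sample_id = f"S{i + 1:03d}"
        for chrom in spec.chromosomes:
            positions, sky_flag, cloud_id = _sample_layout(spec, rng)
            I, Q = _sample_hidden(params, sky_flag, rng)
            cats = np.array(
                [rng.choice(N_CATEGORIES, p=params.signatures.E[q]) for q in Q]
            )
            for t in range(len(positions)):
                rows.append({
                    "sample": sample_id, "chrom": chrom,
                    "pos": int(positions[t]),
                    "category": int(cats[t]), "signature": int(Q[t]),
                    "indicator": int(I[t]), "sky_flag": int(sky_flag[t]),
                    "cloud_id": int(cloud_id[t]),
                })
    truth_df = pd.DataFrame(rows)
    table = truth_df[["sample", "chrom", "pos", "category"]].copy()
    table["category"] = table["category"].map(lambda c: CATEGORY_LABELS[c])
    return table, GroundTruth(params=params, spec=spec, truth=truth_df)


def default_params(signatures: SignatureMatrix,
                   threshold: int = 2000) -> CloudSignatureParams:
    """Planted parameters for the presets: a strong-diagonal transition matrix
    (processes persist along chain runs), a persistent indicator chain giving
    roughly 70% chain generation inside clouds, and a mildly skewed pi."""
    K = signatures.K
    weights = np.arange(K, 0, -1, dtype=float)
    pi = weights / weights.sum()
    A = np.full((K, K), 0.1 / max(K - 1, 1))
    np.fill_diagonal(A, 0.9)
    B = np.array([[0.90, 0.10], [0.70, 0.30]])
    rho = np.array([0.5, 0.5])
    return CloudSignatureParams(pi, A, rho, B, signatures, threshold)


PRESETS = {
    # a few hundred mutations, cloud-enriched: quick demonstrations
    "tiny": dict(
        n_samples=2,
        spec=LayoutSpec(n_chromosomes=3, sky_per_chromosome=40,
                        clouds_per_chromosome=20, cloud_size_mean=3.0),
        K=3,
    ),
    # ~2,000 mutations per sample, cloud-enriched for well-conditioned fits
    "small": dict(
        n_samples=10,
        spec=LayoutSpec(n_chromosomes=4, sky_per_chromosome=375,
                        clouds_per_chromosome=54),
        K=4,
    ),
    # geometry echoing a whole-genome cohort at reduced scale: ~8% of
    # mutations in clouds, mean cloud size ~2.33
    "wgs-like": dict(
        n_samples=5,
        spec=LayoutSpec(n_chromosomes=4, sky_per_chromosome=215,
                        clouds_per_chromosome=8),
        K=4,
    ),
}


def benchmark_suite(preset: str, outdir, seed=0) -> dict[str, Path]:
    """Write a deterministic fixture cohort for a named preset.

    Emits ``cohort.tsv`` (mutation table), ``signatures.tsv`` (synthetic
    signature matrix in the standard text layout), ``truth.tsv`` (per-mutation
    hidden states) and ``params.json`` (planted parameters). Regenerating with
    the same seed is byte-identical.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {list(PRESETS)}")
    cfg = PRESETS[preset]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sig = synthetic_signatures(cfg["K"], seed=seed)
    params = default_params(sig, threshold=cfg["spec"].threshold)
    table, truth = sample_cohort(cfg["spec"], params, cfg["n_samples"],
                                 seed=seed)
    paths = {
        "cohort": outdir / "cohort.tsv",
        "signatures": outdir / "signatures.tsv",
        "truth": outdir / "truth.tsv",
        "params": outdir / "params.json",
    }
    table.to_csv(paths["cohort"], sep="\t", index=False)
    write_signature_matrix(sig, paths["signatures"])
    truth.truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["params"].write_text(
        params.to_json(preset=preset, seed=seed,
                       layout=asdict(cfg["spec"])) + "\n"
    )
    return paths


def verify_layout(truth: GroundTruth) -> bool:
    """Check that re-partitioning recovers the planted labels exactly."""
    for (_, _), grp in truth.truth.groupby(["sample", "chrom"], sort=False):
        grp = grp.sort_values("pos", kind="stable")
        part = label_sky_cloud(grp["pos"].to_numpy(), truth.spec.threshold)
        if not np.array_equal(part.sky_flag, grp["sky_flag"].to_numpy()):
            return False
        if not np.array_equal(part.cloud_id, grp["cloud_id"].to_numpy()):
            return False
    return True
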