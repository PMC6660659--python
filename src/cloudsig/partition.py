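"""Sky/cloud partitioning of mutation sequences by inter-mutation distance.

A mutation whose flanking mutations on the same chromosome (if any) are more
than ``threshold`` bp away is *sky*; otherwise it lies in a *cloud*. Clouds are
maximal runs of mutations in which every consecutive gap is <= threshold, and
by construction contain at least two mutations. The threshold itself is
cloud-joining: a gap of exactly ``threshold`` keeps two mutations together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PartitionedSequence:
    """One chromosome's mutations with sky/cloud labels.

    ``sky_flag[t]`` is 1 for sky mutations; ``cloud_id[t]`` numbers maximal
    cloud runs from 0 in positional order and is -1 at sky positions.
    """

    positions: np.ndarray
    categories: np.ndarray
    sky_flag: np.ndarray
    cloud_id: np.ndarray
    threshold: int
    sample_id: str = ""
    chromosome: str = ""

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_sky(self) -> int:
        return int(self.sky_flag.sum())

    @property
    def n_cloud(self) -> int:
        return int((1 - self.sky_flag).sum())

    @property
    def n_clouds(self) -> int:
        return int(self.cloud_id.max() + 1) if len(self) else 0

    def cloud_slices(self) -> list[slice]:
        """Index slices of the maximal cloud runs, in positional order."""
        out = []
        for cid in range(self.n_clouds):
            idx = np.where(self.cloud_id == cid)[0]
            out.append(slice(int(idx[0]), int(idx[-1]) + 1))
        return out


def label_sky_cloud(
    positions,
    threshold: int,
    categories=None,
    sample_id: str = "",
    chromosome: str = "",
) -> PartitionedSequence:
    """Partition one chromosome's sorted positions into sky and clouds.

    Parameters
    ----------
    positions : array-like of int
        Strictly increasing mutation positions (1-based).
    threshold : int
        Distance threshold in bp; a gap <= threshold joins a cloud.
    categories : array-like of int, optional
        96-channel category per mutation; stored alongside (zeros if omitted).
    """
    positions = np.asarray(positions, dtype=np.int64)
    if threshold <= 0:
        raise ValueError(f"threshold must be positive; got {threshold}")
    if len(positions) > 1 and np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    if categories is None:
        categories = np.zeros(len(positions), dtype=np.int64)
    else:
        categories = np.asarray(categories, dtype=np.int64)
        if categories.shape != positions.shape:
            raise ValueError("categories must align with positions")

    n = len(positions)
    sky = np.ones(n, dtype=np.int8)
    cloud_id = np.full(n, -1, dtype=np.int64)
    if n > 1:
        gaps = np.diff(positions)
        near_prev = np.concatenate([[False], gaps <= threshold])
        near_next = np.concatenate([gaps <= threshold, [False]])
        sky = (~(near_prev | near_next)).astype(np.int8)
        # maximal runs: a new cloud starts at a cloud position not joined to
        # its predecessor by a within-threshold gap
        current = -1
        for t in range(n):
            if sky[t]:
                continue
            if not near_prev[t]:
                current += 1
            cloud_id[t] = current
    return PartitionedSequence(
        positions=positions,
        categories=categories,
        sky_flag=sky,
        cloud_id=cloud_id,
        threshold=int(threshold),
        sample_id=sample_id,
        chromosome=chromosome,
    )


def partition_sequences(
    sequences: dict, threshold: int
) -> dict[tuple[str, str], PartitionedSequence]:
    """Partition every (sample, chromosome) sequence at one threshold."""
    return {
        key: label_sky_cloud(
            seq.positions, threshold, seq.categories,
            sample_id=seq.sample_id, chromosome=seq.chromosome,
        )
        for key, seq in sequences.items()
    }


@dataclass
class CloudSummary:
    """Cloud geometry statistics over a set of partitioned sequences."""

    n_clouds: int
    n_cloud_mutations: int
    n_sky_mutations: int
    mean_cloud_size: float  # 0.0 when there are no clouds (see has_clouds)
    median_intra_cloud_gap: float
    has_clouds: bool

    @property
    def n_mutations(self) -> int:
        return self.n_cloud_mutations + self.n_sky_mutations

    @property
    def cloud_fraction(self) -> float:
        return self.n_cloud_mutations / self.n_mutations if self.n_mutations else 0.0


def cloud_summary(parts) -> CloudSummary:
    """Summarize cloud counts, sizes and gaps over one or many sequences."""
    if isinstance(parts, PartitionedSequence):
        parts = [parts]
    elif isinstance(parts, dict):
        parts = list(parts.values())
    n_clouds = n_cloud = n_sky = 0
    sizes: list[int] = []
    gaps: list[np.ndarray] = []
    for part in parts:
        n_sky += part.n_sky
        n_cloud += part.n_cloud
        n_clouds += part.n_clouds
        for sl in part.cloud_slices():
            sizes.append(sl.stop - sl.start)
            gaps.append(np.diff(part.positions[sl]))
    has = n_clouds > 0
    return CloudSummary(
        n_clouds=n_clouds,
        n_cloud_mutations=n_cloud,
        n_sky_mutations=n_sky,
        mean_cloud_size=float(np.mean(sizes)) if has else 0.0,
        median_intra_cloud_gap=float(np.median(np.concatenate(gaps))) if has else 0.0,
        has_clouds=has,
    )


def clouds_to_bed(parts) -> pd.DataFrame:
    """Export cloud intervals as 0-based half-open BED-like records."""
    if isinstance(parts, PartitionedSequence):
        parts = [parts]
    elif isinstance(parts, dict):
        parts = list(parts.values())
    rows = []
    for part in parts:
        for cid, sl in enumerate(part.cloud_slices()):
            rows.append(
                {
                    "chrom": part.chromosome,
                    "start": int(part.positions[sl.start]) - 1,
                    "end": int(part.positions[sl.stop - 1]),
                    "name": f"{part.sample_id}_cloud{cid}",
                    "size": sl.stop - sl.start,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "size"])
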