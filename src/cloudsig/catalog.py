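"""The 96-channel single-base-substitution catalog and signature-matrix I/O.

Somatic single-base substitutions are classified into 96 categories by their
pyrimidine-normalized substitution type (C>A, C>G, C>T, T>A, T>C, T>G) and the
two flanking bases. Mutations reported with a purine reference (A or G) are
reverse-complemented, which also flips and swaps the flanks, so every mutation
has a unique pyrimidine representation. The category ordering is frozen to the
COSMIC v2 convention: substitution-major (alphabetical), then left flank
A,C,G,T, then right flank A,C,G,T.

Signature ("emission") matrices are read from the COSMIC v2 tab-separated text
layout: one row per category, one column per signature, plus context columns
identifying the category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
N_CATEGORIES = 96


class FormatError(ValueError):
    """Raised when an input file does not conform to its documented layout."""


def _check_base(name: str, value: str) -> str:
    if not isinstance(value, str) or value.upper() not in _COMPLEMENT:
        raise ValueError(f"{name} must be one of A, C, G, T; got {value!r}")
    return value.upper()


def map_to_category(ref: str, alt: str, left: str, right: str) -> int:
    """Map a substitution with flanking context to its category index in [0, 96).

    Purine-reference mutations are reverse-complemented to their pyrimidine
    representation: ref/alt are complemented and the flanks are complemented
    and swapped. The mapping is strand-symmetric:
    ``map_to_category(ref, alt, left, right)`` equals the category of the
    reverse-complement strand's description of the same event.

    Parameters
    ----------
    ref, alt : str
        Reference and alternate base; ``alt`` must differ from ``ref``.
    left, right : str
        The 5' and 3' flanking reference bases.

    Returns
    -------
    int
        Index into the frozen COSMIC v2 category ordering.
    """
    ref = _check_base("ref", ref)
    alt = _check_base("alt", alt)
    left = _check_base("left", left)
    right = _check_base("right", right)
    if ref == alt:
        raise ValueError(f"alt must differ from ref; both are {ref!r}")
    if ref in "AG":  # pyrimidine normalization
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        left, right = _COMPLEMENT[right], _COMPLEMENT[left]
    sub = SUBSTITUTIONS.index(f"{ref}>{alt}")
    return sub * 16 + BASES.index(left) * 4 + BASES.index(right)


def category_label(index: int) -> str:
    """Return the standard label, e.g. ``"A[C>T]G"``, for a category index."""
    if not 0 <= index < N_CATEGORIES:
        raise ValueError(f"category index must be in [0, 96); got {index}")
    sub, ctx = divmod(index, 16)
    left, right = divmod(ctx, 4)
    ref, alt = SUBSTITUTIONS[sub].split(">")
    return f"{BASES[left]}[{ref}>{alt}]{BASES[right]}"


def parse_category_label(label: str) -> int:
    """Parse a label like ``"A[C>T]G"`` back to its category index."""
    try:
        left, rest = label[0], label[2:]
        ref, alt, right = rest[0], rest[2], rest[4]
        if label[1] != "[" or rest[1] != ">" or rest[3] != "]":
            raise IndexError
    except (IndexError, TypeError):
        raise FormatError(f"malformed category label {label!r}") from None
    return map_to_category(ref, alt, left, right)


CATEGORY_LABELS = tuple(category_label(i) for i in range(N_CATEGORIES))

#: Floor applied to emission probabilities so log-space decoding is finite.
EMISSION_FLOOR = 1e-10


@dataclass
class SignatureMatrix:
    """A fixed set of K mutational signatures over the 96 categories.

    Attributes
    ----------
    names : list of str
        Signature labels, e.g. ``"Signature 2"``.
    E : ndarray of shape (K, 96)
        Emission probabilities; each row sums to 1. Zero entries are floored
        at :data:`EMISSION_FLOOR` and rows renormalized on construction.
    """

    names: list[str]
    E: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        if self.E.shape != (len(self.names), N_CATEGORIES):
            raise ValueError(
                f"E must have shape ({len(self.names)}, {N_CATEGORIES}); "
                f"got {self.E.shape}"
            )
        if np.any(self.E < 0):
            raise ValueError("emission probabilities must be non-negative")
        sums = self.E.sum(axis=1)
        bad = np.abs(sums - 1.0) > 1e-3
        if np.any(bad):
            raise FormatError(
                "signature rows must sum to 1 within 1e-3: "
                + ", ".join(f"{self.names[i]} sums to {sums[i]:.6f}"
                            for i in np.where(bad)[0])
            )
        self.E = np.maximum(self.E, EMISSION_FLOOR)
        self.E /= self.E.sum(axis=1, keepdims=True)

    @property
    def K(self) -> int:
        return len(self.names)

    def subset(self, names: list[str]) -> "SignatureMatrix":
        """Restrict to the named signatures, preserving the given order."""
        missing = [n for n in names if n not in self.names]
        if missing:
            raise FormatError(f"unknown signature label(s): {missing}")
        idx = [self.names.index(n) for n in names]
        return SignatureMatrix(list(names), self.E[idx].copy())

    @property
    def log_E(self) -> np.ndarray:
        return np.log(self.E)


def _normalize_columns(columns: list[str]) -> dict[str, str]:
    return {c.strip().lower(): c for c in columns}


def read_signature_matrix(path, subset: list[str] | None = None) -> SignatureMatrix:
    """Read a signature matrix from a COSMIC v2 tab-separated file.

    The file must contain 96 data rows, one per category, identified either by
    a ``Somatic Mutation Type`` column (labels like ``A[C>A]A``) or by
    ``Substitution Type`` + ``Trinucleotide`` columns. All remaining numeric
    columns are taken as signatures. Rows may appear in any order; they are
    reordered to the canonical category order. Each signature column must sum
    to 1 within 1e-3.

    Parameters
    ----------
    path : str or file-like
        The signature file.
    subset : list of str, optional
        Restrict to these signature labels (order preserved).
    """
    df = pd.read_csv(path, sep="\t")
    cols = _normalize_columns(list(df.columns))
    if "somatic mutation type" in cols:
        labels = df[cols["somatic mutation type"]].astype(str)
    elif "substitution type" in cols and "trinucleotide" in cols:
        subs = df[cols["substitution type"]].astype(str)
        tris = df[cols["trinucleotide"]].astype(str)
        labels = pd.Series(
            [f"{t[0]}[{s}]{t[2]}" for s, t in zip(subs, tris)], index=df.index
        )
    else:
        raise FormatError(
            "signature file must contain a 'Somatic Mutation Type' column or "
            "'Substitution Type' and 'Trinucleotide' columns"
        )
    try:
        indices = labels.map(parse_category_label)
    except FormatError as exc:
        raise FormatError(f"bad category row in signature file: {exc}") from None
    if sorted(indices) != list(range(N_CATEGORIES)):
        missing = sorted(set(range(N_CATEGORIES)) - set(indices))
        raise FormatError(
            f"signature file must contain all 96 categories exactly once; "
            f"missing/duplicated (first few): {missing[:5]}"
        )

    context_cols = {
        cols.get("somatic mutation type"),
        cols.get("substitution type"),
        cols.get("trinucleotide"),
    } - {None}
    sig_cols = []
    for c in df.columns:
        if c in context_cols:
            continue
        values = pd.to_numeric(df[c], errors="coerce")
        if values.notna().all():
            sig_cols.append(c)
    if not sig_cols:
        raise FormatError("no numeric signature columns found")

    order = np.argsort(indices.to_numpy())
    E = df.iloc[order][sig_cols].to_numpy(dtype=float).T  # K x 96
    sig = SignatureMatrix([str(c) for c in sig_cols], E)
    if subset is not None:
        sig = sig.subset(list(subset))
    return sig


def write_signature_matrix(sig: SignatureMatrix, path) -> None:
    """Write a signature matrix in the COSMIC v2 tab-separated layout."""
    rows = {
        "Substitution Type": [lab[2:5] for lab in CATEGORY_LABELS],
        "Trinucleotide": [lab[0] + lab[2] + lab[6] for lab in CATEGORY_LABELS],
        "Somatic Mutation Type": list(CATEGORY_LABELS),
    }
    df = pd.DataFrame(rows)
    for k, name in enumerate(sig.names):
        df[name] = sig.E[k]
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


@dataclass
class SampleSequence:
    """Position-sorted mutation categories for one (sample, chromosome)."""

    sample_id: str
    chromosome: str
    positions: np.ndarray
    categories: np.ndarray

    def __len__(self) -> int:
        return len(self.positions)


_REQUIRED_COLUMNS = ("sample", "chrom", "pos")


def read_mutation_table(path, fasta: str | None = None) -> pd.DataFrame:
    """Read a tab-separated mutation table and attach category indices.

    Required columns: ``sample``, ``chrom``, ``pos`` (1-based), plus either a
    ``category`` column (labels like ``A[C>T]G`` or integer indices) or
    ``ref``/``alt`` with flanking context from ``left``/``right`` columns or,
    as a convenience, from a reference FASTA (requires pyfaidx).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"mutation table is missing column(s): {missing}")
    if (df["pos"] < 1).any():
        bad = df.index[df["pos"] < 1][0]
        raise FormatError(f"positions must be >= 1 (1-based); bad row {bad}")

    if "category" in df.columns:
        first = df["category"].iloc[0] if len(df) else 0
        if isinstance(first, str):
            df["category"] = df["category"].map(parse_category_label)
        else:
            cats = df["category"].to_numpy()
            if len(df) and (cats.min() < 0 or cats.max() >= N_CATEGORIES):
                raise FormatError("integer categories must lie in [0, 96)")
    elif {"ref", "alt"} <= set(df.columns):
        if {"left", "right"} <= set(df.columns):
            left, right = df["left"], df["right"]
        elif fasta is not None:
            left, right = _context_from_fasta(df, fasta)
        else:
            raise FormatError(
                "mutation table needs 'left'/'right' flank columns or a "
                "reference FASTA to derive context"
            )
        df["category"] = [
            map_to_category(r, a, l, g)
            for r, a, l, g in zip(df["ref"], df["alt"], left, right)
        ]
    else:
        raise FormatError(
            "mutation table needs a 'category' column or 'ref'/'alt' columns"
        )
    return df


def _context_from_fasta(df: pd.DataFrame, fasta: str):
    try:
        from pyfaidx import Fasta
    except ImportError as exc:  # pragma: no cover
        raise FormatError("deriving context from FASTA requires pyfaidx") from exc
    ref = Fasta(fasta)
    left, right = [], []
    for chrom, pos in zip(df["chrom"], df["pos"]):
        seq = ref[str(chrom)][pos - 2 : pos + 1].seq.upper()
        left.append(seq[0])
        right.append(seq[2])
    return left, right


def build_sample_sequences(
    records: pd.DataFrame,
) -> dict[tuple[str, str], SampleSequence]:
    """Group mutations into position-sorted per-(sample, chromosome) sequences.

    Duplicate (sample, chromosome, position) entries are collapsed to the first
    occurrence with a logged warning; chromosomes are independent, so no
    adjacency is ever formed across a chromosome boundary.
    """
    out: dict[tuple[str, str], SampleSequence] = {}
    if len(records) == 0:
        return out
    if "category" not in records.columns:
        raise FormatError("records need a 'category' column (label or index)")
    if records["category"].dtype == object:
        records = records.assign(
            category=records["category"].map(parse_category_label)
        )
    for (sample, chrom), grp in records.groupby(["sample", "chrom"], sort=True):
        grp = grp.sort_values("pos", kind="stable")
        dup = grp["pos"].duplicated()
        if dup.any():
            logger.warning(
                "sample %s chrom %s: dropped %d duplicate position(s)",
                sample, chrom, int(dup.sum()),
            )
            grp = grp[~dup]
        out[(str(sample), str(chrom))] = SampleSequence(
            sample_id=str(sample),
            chromosome=str(chrom),
            positions=grp["pos"].to_numpy(dtype=np.int64),
            categories=grp["category"].to_numpy(dtype=np.int64),
        )
    return out
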