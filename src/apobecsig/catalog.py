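"""Trinucleotide-context mutation catalogs.

Somatic single-base substitutions are summarized in the standard 96-channel
representation: six pyrimidine-normalized substitution classes (C>A, C>G, C>T,
T>A, T>C, T>G) crossed with the 4x4 flanking-base contexts, ordered
alphabetically within each class (A[C>A]A, A[C>A]C, ... T[T>G]T).  Mutations
whose reference base is a purine are reverse-complemented onto the pyrimidine
strand before classification.

The module also provides the APOBEC3-context classifier -- a substitution is
APOBEC3-context when it is a C>T, C>G or C>A change at a TpC dinucleotide
(pyrimidine-normalized context TCA, TCC, TCG or TCT), the joint footprint of
signatures SBS2 and SBS13 -- and tumor mutational burden (TMB) arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = "ACGT"
PYRIMIDINES = frozenset("CT")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: The 96 channel labels in canonical (COSMIC-style) order.
CHANNEL_LABELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)

_CHANNEL_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(CHANNEL_LABELS)}

#: Channels diagnostic of APOBEC3 activity: C>A/C>G/C>T at TC dinucleotides.
APOBEC3_SUBSTITUTIONS = frozenset({"C>A", "C>G", "C>T"})


class ContextError(ValueError):
    """Raised when a trinucleotide context cannot be resolved."""


class BoundaryError(ContextError):
    """Position at a contig end: no flanking base to resolve the context."""


@dataclass(frozen=True)
class Channel:
    """One of the 96 pyrimidine-normalized substitution channels."""

    substitution: str
    five_prime: str
    three_prime: str

    def __post_init__(self) -> None:
        if self.substitution not in SUBSTITUTIONS:
            raise ContextError(f"unknown substitution {self.substitution!r}")
        if self.five_prime not in BASES or self.three_prime not in BASES:
            raise ContextError(
                f"invalid flanks {self.five_prime!r}/{self.three_prime!r}"
            )

    @property
    def label(self) -> str:
        return f"{self.five_prime}[{self.substitution}]{self.three_prime}"

    @property
    def index(self) -> int:
        return _CHANNEL_INDEX[self.label]

    @property
    def context(self) -> str:
        """Pyrimidine-normalized trinucleotide context, e.g. 'TCA'."""
        return self.five_prime + self.substitution[0] + self.three_prime

    @classmethod
    def from_label(cls, label: str) -> "Channel":
        if len(label) != 7 or label[1] != "[" or label[5] != "]":
            raise ContextError(f"unrecognized channel label {label!r}")
        return cls(substitution=label[2:5], five_prime=label[0], three_prime=label[6])


def reverse_complement(seq: str) -> str:
    try:
        return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise ContextError(f"non-ACGTN base in {seq!r}") from exc


def normalize_substitution(ref: str, alt: str, five: str, three: str) -> Channel:
    """Build the pyrimidine-normalized channel for a substitution with flanks.

    If ``ref`` is a purine the substitution and both flanks are
    reverse-complemented so the mutated base is reported as a pyrimidine.
    """
    ref, alt = ref.upper(), alt.upper()
    five, three = five.upper(), three.upper()
    if ref not in BASES or alt not in BASES or ref == alt:
        raise ContextError(f"not a substitution: {ref}>{alt}")
    if ref not in PYRIMIDINES:
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        five, three = COMPLEMENT[three], COMPLEMENT[five]
    if five not in BASES or three not in BASES:
        raise ContextError(f"ambiguous flanking bases {five!r}/{three!r}")
    return Channel(substitution=f"{ref}>{alt}", five_prime=five, three_prime=three)


def extract_context(reference: Mapping[str, str], chrom: str, pos: int,
                    ref: str, alt: str) -> Channel:
    """Resolve the 96-channel class of a substitution from the reference.

    Parameters
    ----------
    reference : mapping of contig name to sequence (e.g. a `pyfaidx.Fasta`).
    pos : 1-based position; the reference base there must equal ``ref``.

    Raises
    ------
    BoundaryError
        If ``pos`` sits at a contig end (no flanking base).
    ContextError
        If the reference base disagrees with ``ref``.
    """
    seq = reference[chrom]
    n = len(seq)
    if pos < 1 or pos > n:
        raise ContextError(f"{chrom}:{pos} outside contig of length {n}")
    if pos == 1 or pos == n:
        raise BoundaryError(f"{chrom}:{pos} at contig boundary")
    triplet = str(seq[pos - 2:pos + 1]).upper()
    if triplet[1] != ref.upper():
        raise ContextError(
            f"reference mismatch at {chrom}:{pos}: expected {ref!r}, "
            f"reference has {triplet[1]!r}"
        )
    return normalize_substitution(ref, alt, triplet[0], triplet[2])


def is_apobec3_context(channel: Channel | str) -> bool:
    """True for the 12 channels in the SBS2/SBS13 footprint (TpC C>D)."""
    if isinstance(channel, str):
        channel = Channel.from_label(channel)
    return channel.five_prime == "T" and channel.substitution in APOBEC3_SUBSTITUTIONS


#: Boolean mask over the canonical channel order (exactly 12 True).
APOBEC3_CHANNEL_MASK: np.ndarray = np.array(
    [is_apobec3_context(lab) for lab in CHANNEL_LABELS], dtype=bool
)


def tcn_mask() -> np.ndarray:
    """Mask of all C>* channels with a 5' T (the TCN motif, 24 channels)."""
    out = np.zeros(96, dtype=bool)
    for i, lab in enumerate(CHANNEL_LABELS):
        ch = Channel.from_label(lab)
        out[i] = ch.five_prime == "T" and ch.substitution.startswith("C")
    return out


@dataclass
class CatalogMatrix:
    """Per-sample 96-channel SNV count matrix in canonical channel order."""

    counts: pd.DataFrame  # samples x 96, columns = CHANNEL_LABELS
    side_tally: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(self.counts.columns) != CHANNEL_LABELS:
            self.counts = self.counts.reindex(columns=list(CHANNEL_LABELS),
                                              fill_value=0)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_snv(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def row(self, sample_id: str) -> np.ndarray:
        return self.counts.loc[sample_id].to_numpy()

    def to_tsv(self, path) -> None:
        # channels x samples, the orientation public catalogs use
        self.counts.T.to_csv(path, sep="\t", index_label="MutationType")

    @classmethod
    def read_tsv(cls, path) -> "CatalogMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(counts=df.T.astype(int))


def build_catalog(mutations: Iterable, reference: Mapping[str, str]) -> CatalogMatrix:
    """Aggregate mutation records into a sample x 96 catalog.

    Indels, non-ACGT alleles and boundary-position SNVs are excluded from the
    96 channels but reported in a per-sample side tally.
    """
    rows: dict[str, np.ndarray] = {}
    tally: dict[str, dict[str, int]] = {}

    def _bump(sample: str, key: str) -> None:
        tally.setdefault(sample, {})[key] = tally.setdefault(sample, {}).get(key, 0) + 1

    for rec in mutations:
        sample = rec.sample_id
        rows.setdefault(sample, np.zeros(96, dtype=np.int64))
        if rec.vclass != "SNV":
            _bump(sample, rec.vclass)
            continue
        try:
            ch = extract_context(reference, rec.chrom, rec.pos, rec.ref, rec.alt)
        except BoundaryError:
            logger.warning("skipping %s:%d (%s>%s): contig boundary",
                           rec.chrom, rec.pos, rec.ref, rec.alt)
            _bump(sample, "boundary_skipped")
            continue
        rows[sample][ch.index] += 1

    counts = pd.DataFrame.from_dict(rows, orient="index", columns=list(CHANNEL_LABELS))
    if counts.empty:
        counts = pd.DataFrame(np.zeros((0, 96), dtype=np.int64),
                              columns=list(CHANNEL_LABELS))
    return CatalogMatrix(counts=counts.astype(np.int64), side_tally=tally)


def apobec3_context_fraction(row: np.ndarray | pd.Series) -> float:
    """Fraction of a catalog row falling in the 12 APOBEC3-context channels.

    Returns NaN when the sample has no context-resolvable SNVs.
    """
    arr = np.asarray(row, dtype=float)
    if arr.shape != (96,):
        raise ValueError("catalog row must have 96 channels")
    total = arr.sum()
    if total == 0:
        return float("nan")
    return float(arr[APOBEC3_CHANNEL_MASK].sum() / total)


def tmb(n_mutations: int, footprint, high_threshold: float = 10.0) -> tuple[float, bool]:
    """Tumor mutational burden in mutations per megabase.

    ``high`` is flagged at >= ``high_threshold`` (default ten mutations per
    megabase, the tumor-agnostic immunotherapy cutoff).  Whether indels are
    included in ``n_mutations`` is the caller's choice (SNVs + indels by
    default upstream).
    """
    total_bases = getattr(footprint, "total_bases", footprint)
    if total_bases <= 0:
        raise ValueError("footprint has zero length; TMB undefined")
    value = n_mutations / (total_bases / 1e6)
    return value, value >= high_threshold
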