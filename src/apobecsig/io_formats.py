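"""Readers and writers for the formats the pipeline touches.

Conventions
-----------
* Mutation tables (MAF-like TSV) and VCF are 1-based; BED is 0-based
  half-open.  A 1-based position ``p`` lies in a BED interval ``(start, end)``
  iff ``start < p <= end``.
* Samples with tumor purity exactly at the threshold are retained (the
  exclusion rule is strictly "< min_purity"); samples with no purity estimate
  are retained by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import BASES

logger = logging.getLogger(__name__)

MAF_COLUMNS = [
    "sample_id", "patient_id", "chrom", "pos", "ref", "alt", "gene",
    "vclass", "alt_reads", "total_reads", "oncogenic_flag",
]


class FormatError(ValueError):
    """Malformed input file."""


def classify_variant(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1 and ref in BASES and alt in BASES:
        return "SNV"
    if len(alt) > len(ref):
        return "INS"
    if len(alt) < len(ref):
        return "DEL"
    # equal-length multi-base substitution: treat as neither INS nor DEL
    return "MNV"


@dataclass
class MutationRecord:
    """One somatic variant call."""

    sample_id: str
    patient_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str = ""
    vclass: str = ""
    alt_reads: Optional[int] = None
    total_reads: Optional[int] = None
    oncogenic: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise FormatError(
                f"ref equals alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if not self.vclass:
            self.vclass = classify_variant(self.ref, self.alt)

    @property
    def site(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class SampleMeta:
    """Clinical/sample-level metadata used for cohort QC and pairing."""

    sample_id: str
    patient_id: str
    sample_type: str = "primary"  # {primary, metastatic}
    receptor_status: str = ""
    purity: Optional[float] = None
    collection_date: Optional[int] = None  # ordinal; larger = later

    def __post_init__(self) -> None:
        if self.purity is not None and not (0.0 <= self.purity <= 1.0):
            raise FormatError(f"purity {self.purity} outside [0, 1]")


@dataclass
class PanelFootprint:
    """Merged genomic intervals covered by a sequencing panel.

    Intervals are 0-based half-open and non-overlapping after construction.
    """

    intervals: list[tuple[str, int, int]]
    total_bases: int = field(init=False)
    _starts: dict[str, np.ndarray] = field(init=False, repr=False)
    _ends: dict[str, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.intervals = merge_intervals(self.intervals)
        self.total_bases = sum(e - s for _, s, e in self.intervals)
        self._starts, self._ends = {}, {}
        for chrom in {c for c, _, _ in self.intervals}:
            ivs = [(s, e) for c, s, e in self.intervals if c == chrom]
            self._starts[chrom] = np.array([s for s, _ in ivs])
            self._ends[chrom] = np.array([e for _, e in ivs])

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position: start < pos <= end."""
        starts = self._starts.get(chrom)
        if starts is None:
            return False
        i = int(np.searchsorted(starts, pos)) - 1  # last interval with start < pos
        return i >= 0 and pos <= self._ends[chrom][i]


def merge_intervals(intervals: Iterable[tuple[str, int, int]]
                    ) -> list[tuple[str, int, int]]:
    """Merge overlapping/adjacent half-open intervals; order-independent."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        if start >= end:
            raise FormatError(f"invalid interval {chrom}:{start}-{end}")
        by_chrom.setdefault(chrom, []).append((int(start), int(end)))
    merged: list[tuple[str, int, int]] = []
    for chrom in sorted(by_chrom):
        cur_s = cur_e = None
        for s, e in sorted(by_chrom[chrom]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            merged.append((chrom, cur_s, cur_e))
    return merged


# ---------------------------------------------------------------------------
# mutation tables


def read_mutations(path, format: str = "maf_tsv",
                   sample_id: Optional[str] = None) -> list[MutationRecord]:
    """Read somatic variants from a MAF-like TSV or a minimal VCF.

    VCF rows carry the sample in the ``SAMPLE`` INFO key when present;
    otherwise ``sample_id`` (or the file stem) is used.  Multi-allelic VCF
    rows are split into one record per ALT.
    """
    if format == "maf_tsv":
        return _read_maf_tsv(path)
    if format == "vcf":
        return _read_vcf(path, sample_id=sample_id)
    raise ValueError(f"unknown mutation format {format!r}")


def _read_maf_tsv(path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = {"sample_id", "chrom", "pos", "ref", "alt"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        d = row._asdict()
        try:
            onco = d.get("oncogenic_flag")
            records.append(MutationRecord(
                sample_id=d["sample_id"],
                patient_id=d.get("patient_id") or d["sample_id"],
                chrom=d["chrom"],
                pos=int(d["pos"]),
                ref=d["ref"],
                alt=d["alt"],
                gene=(d.get("gene") or "") if pd.notna(d.get("gene")) else "",
                vclass=(d.get("vclass") or "") if pd.notna(d.get("vclass")) else "",
                alt_reads=_opt_int(d.get("alt_reads")),
                total_reads=_opt_int(d.get("total_reads")),
                oncogenic=_opt_bool(onco),
            ))
        except (FormatError, ValueError, TypeError, KeyError) as exc:
            raise FormatError(f"{path}: malformed row at line {i}: {exc}") from exc
    return records


def _opt_int(v) -> Optional[int]:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v in ("", "NA", "nan"):
        return None
    return int(v)


def _opt_bool(v) -> Optional[bool]:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v in ("", "NA", "nan"):
        return None
    return str(v).strip().lower() in ("1", "true", "yes", "oncogenic")


def _read_vcf(path, sample_id: Optional[str] = None) -> list[MutationRecord]:
    from cyvcf2 import VCF

    default_sample = sample_id or Path(path).stem
    records = []
    vcf = VCF(str(path))
    try:
        for var in vcf:
            sid = var.INFO.get("SAMPLE") or default_sample
            pid = var.INFO.get("PATIENT") or sid
            gene = var.INFO.get("GENE") or ""
            for alt in var.ALT:
                records.append(MutationRecord(
                    sample_id=str(sid), patient_id=str(pid),
                    chrom=var.CHROM, pos=var.POS, ref=var.REF, alt=alt,
                    gene=str(gene)))
    finally:
        vcf.close()
    return records


def write_mutations(records: Sequence[MutationRecord], path) -> None:
    df = pd.DataFrame([{
        "sample_id": r.sample_id, "patient_id": r.patient_id,
        "chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
        "gene": r.gene, "vclass": r.vclass,
        "alt_reads": "" if r.alt_reads is None else r.alt_reads,
        "total_reads": "" if r.total_reads is None else r.total_reads,
        "oncogenic_flag": "" if r.oncogenic is None else int(r.oncogenic),
    } for r in records], columns=MAF_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED / FASTA / signatures / segments / clinical


def read_panel_bed(path) -> PanelFootprint:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start {start} >= end {end}")
            intervals.append((chrom, start, end))
    return PanelFootprint(intervals=intervals)


def write_panel_bed(footprint: PanelFootprint, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in footprint.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_fasta(path) -> Mapping[str, str]:
    """Open a FASTA as a mapping of contig -> sequence (via pyfaidx)."""
    from pyfaidx import Fasta

    return Fasta(str(path), as_raw=False, sequence_always_upper=True)


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_signature_matrix(path, tol: float = 1e-6) -> pd.DataFrame:
    """Read a COSMIC-style 96-channel signature TSV.

    Rows are reordered to the canonical channel order; each column must sum
    to 1 within ``tol`` and is renormalized exactly.
    """
    from .catalog import CHANNEL_LABELS

    df = pd.read_csv(path, sep="\t", index_col=0)
    return validate_signature_matrix(df, tol=tol)


def validate_signature_matrix(df: pd.DataFrame, tol: float = 1e-6) -> pd.DataFrame:
    from .catalog import CHANNEL_LABELS

    missing = [lab for lab in CHANNEL_LABELS if lab not in df.index]
    if missing:
        raise FormatError(
            f"signature matrix missing {len(missing)} channels: "
            f"{missing[:5]}{'...' if len(missing) > 5 else ''}")
    df = df.loc[list(CHANNEL_LABELS)].astype(float)
    sums = df.sum(axis=0)
    bad = sums[(sums - 1.0).abs() > tol]
    if len(bad):
        raise FormatError(
            "signature columns do not sum to 1: "
            + ", ".join(f"{k}={v:.4g}" for k, v in bad.items()))
    return df / sums


def write_signature_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="MutationType")


@dataclass
class CNSegment:
    """Allele-specific copy-number segment (0-based half-open)."""

    chrom: str
    start: int
    end: int
    major_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(f"segment end {self.end} <= start {self.start}")
        if self.major_cn < self.minor_cn:
            raise FormatError("major_cn must be >= minor_cn")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def total_cn(self) -> int:
        return self.major_cn + self.minor_cn


def read_cn_segments(path) -> list[CNSegment]:
    df = pd.read_csv(path, sep="\t")
    return [CNSegment(chrom=str(r.chrom), start=int(r.start), end=int(r.end),
                      major_cn=int(r.major_cn), minor_cn=int(r.minor_cn))
            for r in df.itertuples(index=False)]


def write_cn_segments(segments: Sequence[CNSegment], path) -> None:
    pd.DataFrame([{
        "chrom": s.chrom, "start": s.start, "end": s.end,
        "major_cn": s.major_cn, "minor_cn": s.minor_cn,
    } for s in segments]).to_csv(path, sep="\t", index=False)


def read_clinical(path) -> pd.DataFrame:
    """Clinical outcome table: sample_id, group, time_months, event, strata."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "group", "time_months", "event"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing clinical columns {sorted(missing)}")
    if (df["time_months"] <= 0).any():
        raise FormatError("time_months must be positive")
    return df


# ---------------------------------------------------------------------------
# cohort QC


def qc_filter_cohort(samples: Sequence[SampleMeta], min_purity: float = 0.2,
                     drop_missing_purity: bool = False
                     ) -> tuple[list[SampleMeta], dict[str, int]]:
    """Apply the purity exclusion: drop samples with purity < ``min_purity``.

    Purity exactly at the threshold is retained.  Samples without a purity
    estimate are retained unless ``drop_missing_purity``.
    """
    retained: list[SampleMeta] = []
    report = {"retained": 0, "low_purity": 0, "missing_purity": 0}
    for s in samples:
        if s.purity is None:
            if drop_missing_purity:
                report["missing_purity"] += 1
                continue
        elif s.purity < min_purity:
            report["low_purity"] += 1
            continue
        retained.append(s)
        report["retained"] += 1
    return retained, report
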