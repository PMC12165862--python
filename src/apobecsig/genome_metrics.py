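"""Copy-number-derived genome-instability metrics.

Whole-genome doubling (WGD) is called when the length-weighted fraction of
profiled bases with major allele copy number greater than one exceeds 50%
(strictly).  Fraction of genome altered (FGA) is the length-weighted
fraction of profiled bases whose copy state deviates from the diploid
baseline: total copy number different from 2, or loss of heterozygosity
(minor copy number 0 with nonzero total).  An alternative total-copy-ratio
threshold mode is available for pipelines that define "altered" on log
ratios.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .io_formats import CNSegment

SEX_CHROMS = frozenset({"X", "Y", "chrX", "chrY"})


def _profiled(segments: Sequence[CNSegment], exclude_sex: bool
              ) -> list[CNSegment]:
    segs = [s for s in segments
            if not (exclude_sex and s.chrom in SEX_CHROMS)]
    if not segs:
        raise ValueError("no autosomal segments; metrics undefined")
    return segs


def wgd_call(segments: Sequence[CNSegment],
             exclude_sex: bool = True) -> tuple[bool, float]:
    """Whole-genome doubling flag and the doubled-genome fraction.

    WGD iff the fraction of profiled bases with major_cn > 1 is > 0.5
    (strict: exactly half the genome doubled is not WGD).
    """
    segs = _profiled(segments, exclude_sex)
    total = sum(s.length for s in segs)
    doubled = sum(s.length for s in segs if s.major_cn > 1)
    fraction = doubled / total
    return fraction > 0.5, fraction


def fga(segments: Sequence[CNSegment], baseline_ploidy: int = 2,
        exclude_sex: bool = True, mode: str = "copy_state",
        log_ratio_threshold: float = 0.2) -> float:
    """Fraction of the profiled genome altered by copy-number changes.

    ``copy_state`` (default): a segment is altered when total copy number
    differs from ``baseline_ploidy`` or shows LOH (minor 0 with total > 0).
    ``log_ratio``: altered when |log2(total / baseline)| exceeds the
    threshold (segments with total 0 always count).
    """
    segs = _profiled(segments, exclude_sex)
    total = sum(s.length for s in segs)
    altered = 0
    for s in segs:
        tc = s.total_cn
        if mode == "copy_state":
            is_alt = tc != baseline_ploidy or (s.minor_cn == 0 and tc > 0)
        elif mode == "log_ratio":
            is_alt = (tc == 0 or
                      abs(np.log2(tc / baseline_ploidy)) > log_ratio_threshold)
        else:
            raise ValueError(f"unknown FGA mode {mode!r}")
        if is_alt:
            altered += s.length
    return altered / total
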