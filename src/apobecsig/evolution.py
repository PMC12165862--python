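"""Paired early/late sample analysis.

For patients with several tumor samples over time, each later sample is
compared to the earliest one.  A late mutation is *shared* when it was
called in the early sample or when tumor-informed genotyping finds at least
two supporting reads for it there; otherwise it is *acquired*.  Pairs whose
mutation sets are complete mismatches (zero shared) are treated as probable
sample mix-ups and excluded.

Downstream summaries: the APOBEC3-context composition of acquired versus
shared mutations (Fisher's exact test on the pooled 2x2 table), transitions
of the dominant mutational process from early to late, and the APOBEC3
exposure of early samples whose late counterpart is APOBEC3-dominant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import extract_context, is_apobec3_context, ContextError
from .enrichment import fisher_exact
from .io_formats import MutationRecord
from .signatures import NOT_EVALUABLE

logger = logging.getLogger(__name__)

MIN_SUPPORT_READS_DEFAULT = 2

TRANSITION_LABELS = ("APOBEC3", "Clock", "HRD", "other", NOT_EVALUABLE)


@dataclass
class PairedPatient:
    """An (early, late) sample pair with per-mutation sharing status."""

    patient_id: str
    early_id: str
    late_id: str
    status: pd.DataFrame  # columns: site..., status in {shared, acquired}
    n_shared: int
    n_acquired: int
    n_early_only: int
    valid: bool
    exclusion_reason: str = ""


def classify_shared_acquired(early_records: Sequence[MutationRecord],
                             late_records: Sequence[MutationRecord],
                             genotype: Optional[Mapping[tuple, int]] = None,
                             min_support_reads: int = MIN_SUPPORT_READS_DEFAULT,
                             ) -> pd.DataFrame:
    """Status of each late mutation: shared with the early sample or acquired.

    A late mutation is shared when its site is in the early call set, or
    when ``genotype`` (site -> supporting read count in the early sample)
    reports at least ``min_support_reads`` reads.  Without genotype data the
    classification falls back to call-set membership alone (logged).
    """
    early_sites = {m.site for m in early_records}
    if genotype is None:
        logger.info("no genotyping read support supplied; using call-set "
                    "membership only")
    rows = []
    for m in late_records:
        shared = m.site in early_sites
        if not shared and genotype is not None:
            shared = genotype.get(m.site, 0) >= min_support_reads
        rows.append({"chrom": m.chrom, "pos": m.pos, "ref": m.ref,
                     "alt": m.alt, "vclass": m.vclass,
                     "status": "shared" if shared else "acquired"})
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                       "vclass", "status"])


def pair_and_validate(samples_by_patient: Mapping[str, Sequence[tuple]],
                      genotypes: Optional[Mapping[str, Mapping[tuple, int]]] = None,
                      min_support_reads: int = MIN_SUPPORT_READS_DEFAULT,
                      pairing: str = "earliest") -> list[PairedPatient]:
    """Build validated pairs per patient.

    ``samples_by_patient`` maps patient id to an ordered sequence of
    (sample_id, collection_date, records); samples are sorted by date and
    each later sample is paired with the earliest (default) or with its
    predecessor (``pairing="consecutive"``).  Pairs sharing zero mutations
    are excluded as complete somatic mismatches.
    """
    if pairing not in ("earliest", "consecutive"):
        raise ValueError("pairing must be 'earliest' or 'consecutive'")
    pairs: list[PairedPatient] = []
    for pid, samples in samples_by_patient.items():
        ordered = sorted(samples, key=lambda s: s[1])
        if len(ordered) < 2:
            continue
        for k in range(1, len(ordered)):
            ref_idx = 0 if pairing == "earliest" else k - 1
            early_id, _, early_recs = ordered[ref_idx]
            late_id, _, late_recs = ordered[k]
            genotype = (genotypes or {}).get(pid)
            status = classify_shared_acquired(
                early_recs, late_recs, genotype=genotype,
                min_support_reads=min_support_reads)
            n_shared = int((status["status"] == "shared").sum()) if len(status) else 0
            n_acq = len(status) - n_shared
            late_sites = {m.site for m in late_recs}
            n_early_only = sum(1 for m in early_recs if m.site not in late_sites)
            valid = n_shared > 0
            pairs.append(PairedPatient(
                patient_id=pid, early_id=early_id, late_id=late_id,
                status=status, n_shared=n_shared, n_acquired=n_acq,
                n_early_only=n_early_only, valid=valid,
                exclusion_reason="" if valid else "complete_somatic_mismatch"))
            if not valid:
                logger.warning("excluding pair %s/%s: complete somatic mismatch",
                               early_id, late_id)
    return pairs


def acquired_context_test(pairs: Sequence[PairedPatient],
                          reference: Mapping[str, str]) -> dict:
    """APOBEC3-context composition of shared vs acquired SNVs, pooled.

    Builds the 2x2 table {shared, acquired} x {APOBEC3-context, other} over
    all valid pairs and tests it with the two-sided Fisher's exact test.
    Non-SNVs and boundary positions are skipped.
    """
    table = np.zeros((2, 2), dtype=int)  # rows: shared, acquired
    for pair in pairs:
        if not pair.valid:
            continue
        for row in pair.status.itertuples(index=False):
            if row.vclass != "SNV":
                continue
            try:
                ch = extract_context(reference, row.chrom, row.pos,
                                     row.ref, row.alt)
            except ContextError:
                continue
            i = 0 if row.status == "shared" else 1
            j = 0 if is_apobec3_context(ch) else 1
            table[i, j] += 1
    totals = table.sum(axis=1)
    props = np.divide(table[:, 0], totals, out=np.full(2, np.nan),
                      where=totals > 0)
    if (totals > 0).all():
        p, odds = fisher_exact(table)
    else:
        p, odds = float("nan"), float("nan")
    return {"table": table, "shared_apobec_fraction": float(props[0]),
            "acquired_apobec_fraction": float(props[1]),
            "fisher_p": p, "odds_ratio": odds,
            "n_shared": int(totals[0]), "n_acquired": int(totals[1])}


def dominant_transitions(pairs: Sequence[PairedPatient],
                         dominant_by_sample: Mapping[str, str],
                         labels: Sequence[str] = TRANSITION_LABELS
                         ) -> pd.DataFrame:
    """Early -> late dominant-process transition counts over valid pairs.

    Individual signatures outside the named groups are pooled as "other".
    """
    def _norm(lab: str) -> str:
        return lab if lab in labels else "other"

    table = pd.DataFrame(0, index=list(labels), columns=list(labels))
    for pair in pairs:
        if not pair.valid:
            continue
        e = _norm(dominant_by_sample.get(pair.early_id, NOT_EVALUABLE))
        l = _norm(dominant_by_sample.get(pair.late_id, NOT_EVALUABLE))
        table.loc[e, l] += 1
    return table


def earlier_exposure_summary(early_apobec_pct: Sequence[float],
                             early_dominant: Sequence[bool]) -> dict:
    """Summary of early-sample APOBEC3 exposure (for late-dominant pairs).

    Quartiles use linear interpolation.
    """
    x = np.asarray(early_apobec_pct, dtype=float)
    dom = np.asarray(early_dominant, dtype=bool)
    if len(x) == 0:
        return {"n": 0, "median": float("nan"), "iqr": (float("nan"),) * 2,
                "fraction_dominant": float("nan")}
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {"n": len(x), "median": float(med),
            "iqr": (float(q1), float(q3)),
            "fraction_dominant": float(dom.mean())}
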