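"""Panel-downsampling validation of dominant-signature calling.

Rich (WGS/WES-scale) mutation sets are reduced to the positions a targeted
panel covers, dominant signatures are re-called on the downsampled catalogs,
and agreement with the full-data truth is scored.  Samples retaining fewer
than five SNVs inside the panel are excluded from the performance metrics
(the sparse-sample gate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import CatalogMatrix, build_catalog
from .io_formats import MutationRecord, PanelFootprint
from .signatures import (DominantSignatureCaller, MIN_SNV_DEFAULT,
                         group_exposures)


def intersect_panel(mutations: Sequence[MutationRecord],
                    footprint: PanelFootprint) -> list[MutationRecord]:
    """Keep mutations whose 1-based position lies inside the footprint."""
    return [m for m in mutations if footprint.contains(m.chrom, m.pos)]


def evaluable_gate(panel_catalog: CatalogMatrix,
                   min_snv: int = MIN_SNV_DEFAULT
                   ) -> tuple[pd.Index, float]:
    """Samples with >= ``min_snv`` panel SNVs, plus the excluded fraction."""
    n = panel_catalog.n_snv
    keep = n.index[n >= min_snv]
    excluded = 1.0 - len(keep) / len(n) if len(n) else 0.0
    return keep, excluded


def classification_metrics(truth: Sequence[str], predicted: Sequence[str],
                           positive: str = "APOBEC3") -> dict[str, float]:
    """Confusion-matrix metrics for detecting the positive dominant label.

    Undefined ratios (zero denominators) are reported as NaN.
    """
    t = np.asarray([lab == positive for lab in truth])
    p = np.asarray([lab == positive for lab in predicted])
    if t.shape != p.shape:
        raise ValueError("truth and prediction lengths differ")
    tp = int(np.sum(t & p))
    tn = int(np.sum(~t & ~p))
    fp = int(np.sum(~t & p))
    fn = int(np.sum(t & ~p))

    def _ratio(num, den):
        return num / den if den else float("nan")

    return {
        "n": len(t), "tp": tp, "tn": tn, "fp": fp, "fn": fn,
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "accuracy": _ratio(tp + tn, len(t)) if len(t) else float("nan"),
        "ppv": _ratio(tp, tp + fp),
        "npv": _ratio(tn, tn + fn),
    }


def exposure_correlation(full_exposures: Sequence[float],
                         panel_exposures: Sequence[float]) -> float:
    """Pearson r between full-data and panel APOBEC3 exposures."""
    x = np.asarray(full_exposures, dtype=float)
    y = np.asarray(panel_exposures, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired vectors must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired samples")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance in exposure vector; correlation undefined")
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class ValidationReport:
    """Panel-validation summary for APOBEC3-dominant detection."""

    n_total: int
    n_evaluable: int
    excluded_fraction: float
    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float
    pearson_r: float

    def to_dict(self) -> dict:
        return asdict(self)


def validate_panel(mutations: Sequence[MutationRecord],
                   footprint: PanelFootprint,
                   reference: Mapping[str, str],
                   signatures: Optional[pd.DataFrame] = None,
                   truth_labels: Optional[Mapping[str, str]] = None,
                   truth_apobec_pct: Optional[Mapping[str, float]] = None,
                   min_snv: int = MIN_SNV_DEFAULT,
                   positive: str = "APOBEC3") -> ValidationReport:
    """Downsample to the panel, re-call dominant signatures, score agreement.

    ``truth_labels`` gives the per-sample ground-truth dominant label.  On
    synthetic cohorts the generating mixture's grouped argmax is the natural
    truth; alternatively pass labels from a full-data refit.  When
    ``truth_labels`` is None a full-data refit is used as truth.
    """
    full_catalog = build_catalog(mutations, reference)
    caller = DominantSignatureCaller(signatures=signatures,
                                     min_snv=min_snv).fit()
    if truth_labels is None or truth_apobec_pct is None:
        full_frame = caller.predict_frame(full_catalog)
        if truth_labels is None:
            truth_labels = full_frame["dominant"].to_dict()
        if truth_apobec_pct is None:
            truth_apobec_pct = full_frame.get(
                "group_APOBEC3",
                pd.Series(0.0, index=full_frame.index)).to_dict()

    panel_muts = intersect_panel(mutations, footprint)
    panel_catalog = build_catalog(panel_muts, reference)
    # samples losing every panel mutation still count toward the gate
    panel_catalog.counts = panel_catalog.counts.reindex(
        full_catalog.counts.index, fill_value=0)
    evaluable, excluded = evaluable_gate(panel_catalog, min_snv=min_snv)

    panel_frame = caller.predict_frame(
        CatalogMatrix(panel_catalog.counts.loc[evaluable]))
    truth_vec = [truth_labels[s] for s in evaluable]
    pred_vec = panel_frame["dominant"].tolist()
    metrics = classification_metrics(truth_vec, pred_vec, positive=positive)

    if len(evaluable) >= 3:
        full_pct = [truth_apobec_pct[s] for s in evaluable]
        panel_pct = panel_frame.get(
            "group_APOBEC3", pd.Series(0.0, index=panel_frame.index)).tolist()
        try:
            r = exposure_correlation(full_pct, panel_pct)
        except ValueError:
            r = float("nan")
    else:
        r = float("nan")

    return ValidationReport(
        n_total=len(full_catalog.counts), n_evaluable=len(evaluable),
        excluded_fraction=excluded,
        sensitivity=metrics["sensitivity"],
        specificity=metrics["specificity"], accuracy=metrics["accuracy"],
        ppv=metrics["ppv"], npv=metrics["npv"], pearson_r=r)


def truth_from_mixtures(truth: pd.DataFrame,
                        signature_names: Sequence[str]) -> dict[str, str]:
    """Grouped argmax of the generating mixtures (synthetic ground truth)."""
    labels = {}
    for sid, row in truth.iterrows():
        pct = {s: 100.0 * float(row[s]) for s in signature_names}
        grouped = group_exposures(pct)
        labels[str(sid)] = max(sorted(grouped), key=lambda g: grouped[g])
    return labels
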