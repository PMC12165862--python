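"""Signature refitting and dominant-process calling.

A sample's 96-channel catalog row ``m`` is decomposed against a fixed
reference signature matrix ``S`` (96 x k, column-stochastic) by non-negative
least squares:

    e = argmin_{e >= 0} || m - S e ||_2

Raw exposures are on the mutation-count scale; for cross-sample comparison
they are expressed as percentages of the total.  Percentages are grouped
into biological processes -- Clock (SBS1 + SBS5), APOBEC3 (SBS2 + SBS13),
HRD (SBS3 + SBS8) -- with every other fitted signature kept as its own
group, and the group with the highest percentage is called dominant.
Samples with fewer than five context-resolvable SNVs are too sparse for a
reliable call and are labelled ``not_evaluable``.

A likelihood-based scorer for sparse panels is also provided: candidate
mixtures are ranked by multinomial log-likelihood of the observed catalog
(with a small probability floor), alongside cosine similarity.

The estimator classes follow the scikit-learn fit/transform/predict
contract and compose with sklearn pipelines and model selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _scipy_nnls
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .catalog import CatalogMatrix
from .io_formats import validate_signature_matrix

DEFAULT_SIGNATURE_SET = ("SBS1", "SBS2", "SBS3", "SBS5", "SBS8", "SBS13",
                         "SBS17", "SBS18")

#: Grouping of individual signatures into mutational processes.
SIGNATURE_GROUPS: dict[str, tuple[str, ...]] = {
    "Clock": ("SBS1", "SBS5"),
    "APOBEC3": ("SBS2", "SBS13"),
    "HRD": ("SBS3", "SBS8"),
}

NOT_EVALUABLE = "not_evaluable"
MIN_SNV_DEFAULT = 5


def nnls_refit(catalog_row: Sequence[float], signatures: pd.DataFrame
               ) -> tuple[np.ndarray, float]:
    """Non-negative least-squares exposures for one catalog row.

    Returns (exposures, residual) where residual is ||m - S e||_2.
    Deterministic; scale-equivariant (refitting k*m gives k*e).
    """
    m = np.asarray(catalog_row, dtype=float)
    if m.shape != (signatures.shape[0],):
        raise ValueError(
            f"catalog row has {m.shape[0]} channels, signatures have "
            f"{signatures.shape[0]}")
    if not m.any():
        raise ValueError("all-zero catalog row: nothing to refit")
    e, residual = _scipy_nnls(signatures.to_numpy(), m)
    return e, float(residual)


def exposures_to_percentages(exposures: Sequence[float]) -> np.ndarray:
    e = np.asarray(exposures, dtype=float)
    total = e.sum()
    if total <= 0:
        return np.zeros_like(e)
    return 100.0 * e / total


def group_exposures(percentages: Mapping[str, float]) -> dict[str, float]:
    """Sum signature percentages into process groups.

    Clock = SBS1+SBS5, APOBEC3 = SBS2+SBS13, HRD = SBS3+SBS8; any other
    signature keeps its own name as a group.
    """
    member_of: dict[str, str] = {}
    for group, members in SIGNATURE_GROUPS.items():
        for m in members:
            member_of[m] = group
    grouped: dict[str, float] = {}
    for sig, pct in percentages.items():
        group = member_of.get(sig, sig)
        grouped[group] = grouped.get(group, 0.0) + float(pct)
    return grouped


@dataclass
class DominantCall:
    """Dominant mutational process for one sample."""

    sample_id: str
    label: str
    percentage: float
    pass_gate: bool
    tie: bool = False


def dominant_call(grouped: Mapping[str, float], n_snv: int,
                  sample_id: str = "", min_snv: int = MIN_SNV_DEFAULT
                  ) -> DominantCall:
    """Argmax process group, gated on a minimum SNV count.

    Samples with fewer than ``min_snv`` SNVs are ``not_evaluable``.  Exact
    ties are broken lexicographically on the group name, with a flag set.
    """
    if n_snv < min_snv:
        return DominantCall(sample_id=sample_id, label=NOT_EVALUABLE,
                            percentage=float("nan"), pass_gate=False)
    if not grouped:
        return DominantCall(sample_id=sample_id, label=NOT_EVALUABLE,
                            percentage=float("nan"), pass_gate=False)
    best = max(grouped.values())
    winners = sorted(g for g, v in grouped.items() if v == best)
    return DominantCall(sample_id=sample_id, label=winners[0],
                        percentage=float(best), pass_gate=True,
                        tie=len(winners) > 1)


def sparse_likelihood_scores(catalog_row: Sequence[float],
                             candidates: pd.DataFrame,
                             eps: float = 1e-6) -> pd.DataFrame:
    """Score candidate channel mixtures against a sparse catalog row.

    Each candidate column must be a point on the 96-simplex.  The score is
    the multinomial log-likelihood sum_c m_c log(q_c) with q floored at
    ``eps`` and renormalized, plus the cosine similarity of the raw vectors.
    Candidates are returned ranked by log-likelihood.
    """
    m = np.asarray(catalog_row, dtype=float)
    q = candidates.to_numpy(dtype=float)
    if eps < 0:
        raise ValueError("eps must be >= 0")
    if eps == 0 and np.any((q == 0) & (m[:, None] > 0)):
        raise ValueError(
            "candidate has zero probability where the catalog has counts; "
            "use eps > 0")
    qf = np.maximum(q, eps)
    qf = qf / qf.sum(axis=0)
    loglik = m @ np.log(qf)
    mnorm = np.linalg.norm(m)
    qnorm = np.linalg.norm(q, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosine = (m @ q) / (mnorm * qnorm)
    out = pd.DataFrame({"log_likelihood": loglik, "cosine": cosine},
                       index=candidates.columns)
    return out.sort_values("log_likelihood", ascending=False)


def cosine_similarity(a: Sequence[float], b: Sequence[float]) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return float("nan")
    return float(a @ b / (na * nb))


# ---------------------------------------------------------------------------
# estimators


class SignatureRefitter(TransformerMixin, BaseEstimator):
    """NNLS refit of 96-channel catalogs against reference signatures.

    Parameters
    ----------
    signatures : DataFrame (96 x k), column-stochastic reference spectra.
        Validated and reordered to the canonical channel order at ``fit``.
    scale : {"counts", "percent"}
        Output scale of ``transform``: raw mutation-count exposures or
        percentages summing to 100 per sample.

    Attributes
    ----------
    signatures_ : validated signature matrix used for refitting.
    signature_names_ : list of fitted signature names.
    """

    def __init__(self, signatures: Optional[pd.DataFrame] = None,
                 scale: str = "counts"):
        self.signatures = signatures
        self.scale = scale

    def fit(self, X=None, y=None) -> "SignatureRefitter":
        if self.signatures is None:
            from .synthetic import synthetic_signature_matrix
            sigs = synthetic_signature_matrix()[list(DEFAULT_SIGNATURE_SET)]
        else:
            sigs = self.signatures
        if self.scale not in ("counts", "percent"):
            raise ValueError(f"unknown scale {self.scale!r}")
        self.signatures_ = validate_signature_matrix(sigs)
        self.signature_names_ = list(self.signatures_.columns)
        return self

    def transform(self, X) -> pd.DataFrame:
        """Refit each catalog row; rows with zero counts get zero exposures."""
        check_is_fitted(self, "signatures_")
        counts, index = _as_counts(X)
        out = np.zeros((counts.shape[0], len(self.signature_names_)))
        resid = np.zeros(counts.shape[0])
        for i in range(counts.shape[0]):
            if counts[i].any():
                out[i], resid[i] = nnls_refit(counts[i], self.signatures_)
        if self.scale == "percent":
            out = np.vstack([exposures_to_percentages(row) for row in out])
        df = pd.DataFrame(out, columns=self.signature_names_, index=index)
        self.residuals_ = pd.Series(resid, index=index)
        return df

    def reconstruction_cosine(self, X) -> pd.Series:
        """Cosine similarity between each catalog row and its reconstruction."""
        check_is_fitted(self, "signatures_")
        counts, index = _as_counts(X)
        expo = self.transform(X).to_numpy()
        recon = expo @ self.signatures_.to_numpy().T
        return pd.Series([cosine_similarity(counts[i], recon[i])
                          for i in range(len(index))], index=index)


class DominantSignatureCaller(BaseEstimator):
    """Call the dominant mutational process per sample.

    Refits catalogs (via :class:`SignatureRefitter`), groups exposure
    percentages into processes and returns the argmax group, applying the
    sparse-sample gate: samples with fewer than ``min_snv`` SNVs are
    ``not_evaluable``.
    """

    def __init__(self, signatures: Optional[pd.DataFrame] = None,
                 min_snv: int = MIN_SNV_DEFAULT):
        self.signatures = signatures
        self.min_snv = min_snv

    def fit(self, X=None, y=None) -> "DominantSignatureCaller":
        self.refitter_ = SignatureRefitter(signatures=self.signatures,
                                           scale="percent").fit()
        return self

    def predict(self, X) -> np.ndarray:
        return self.predict_frame(X)["dominant"].to_numpy()

    def predict_frame(self, X) -> pd.DataFrame:
        """Full per-sample table: n_snv, signature and group percentages,
        dominant label, gate and tie flags."""
        check_is_fitted(self, "refitter_")
        counts, index = _as_counts(X)
        pct = self.refitter_.transform(counts)
        pct.index = index
        rows = []
        for i, sid in enumerate(index):
            n_snv = int(counts[i].sum())
            grouped = group_exposures(pct.iloc[i].to_dict())
            call = dominant_call(grouped, n_snv, sample_id=str(sid),
                                 min_snv=self.min_snv)
            row = {"sample_id": str(sid), "n_snv": n_snv,
                   "dominant": call.label,
                   "dominant_pct": call.percentage,
                   "pass_gate": call.pass_gate, "tie": call.tie}
            row.update({f"pct_{k}": v for k, v in pct.iloc[i].items()})
            row.update({f"group_{k}": v for k, v in grouped.items()})
            rows.append(row)
        return pd.DataFrame(rows, index=index)


def _as_counts(X) -> tuple[np.ndarray, pd.Index]:
    if isinstance(X, CatalogMatrix):
        return X.counts.to_numpy(dtype=float), X.counts.index
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), X.index
    arr = np.atleast_2d(np.asarray(X, dtype=float))
    return arr, pd.RangeIndex(arr.shape[0])


def exposure_table(catalog: CatalogMatrix,
                   signatures: Optional[pd.DataFrame] = None,
                   min_snv: int = MIN_SNV_DEFAULT) -> pd.DataFrame:
    """One-call exposure + dominant-label table for a catalog."""
    caller = DominantSignatureCaller(signatures=signatures,
                                     min_snv=min_snv).fit()
    return caller.predict_frame(catalog)
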