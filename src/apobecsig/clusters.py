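"""Clustered-mutation detection from inter-mutation distances.

Somatic hypermutation foci are flagged from runs of same-chromosome
mutations whose adjacent inter-mutation distances (IMD) all fall at or
below a threshold (1 kb by default).  Runs of 2-3 mutations are classed as
omikli, runs of 6 or more as kataegis, and sizes 4-5 as intermediate; all
cutoffs are configurable.  An optional sample-adaptive threshold is derived
by simulating uniform mutation placement at the sample's burden and taking
a low quantile of the resulting IMDs.

The APOBEC3 character of a cluster is summarized as the fraction of member
SNVs at TCN motifs (pyrimidine-normalized 5' T with a mutated C), with the
strict APOBEC3-context subset (C>T/C>G/C>A at TpC) reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .catalog import (Channel, ContextError, extract_context,
                      is_apobec3_context)
from .io_formats import MutationRecord
from .synthetic import as_rng

IMD_THRESHOLD_DEFAULT = 1000
KATAEGIS_MIN_SIZE = 6
OMIKLI_MAX_SIZE = 3


@dataclass
class MutationCluster:
    """A maximal run of closely spaced mutations on one chromosome."""

    sample_id: str
    chrom: str
    positions: tuple[int, ...]
    classification: str  # {omikli, intermediate, kataegis}
    max_adjacent_imd: int
    tcn_fraction: float = float("nan")
    apobec3_fraction: float = float("nan")

    @property
    def size(self) -> int:
        return len(self.positions)

    @property
    def span(self) -> tuple[int, int]:
        return self.positions[0], self.positions[-1]


def intermutation_distances(mutations: Sequence[MutationRecord]
                            ) -> dict[str, np.ndarray]:
    """Adjacent distances between sorted positions, per chromosome."""
    by_chrom: dict[str, list[int]] = {}
    for m in mutations:
        by_chrom.setdefault(m.chrom, []).append(m.pos)
    return {c: np.diff(np.sort(np.asarray(p)))
            for c, p in by_chrom.items() if len(p) >= 2}


def _classify_size(size: int, kataegis_min: int, omikli_max: int) -> str:
    if size >= kataegis_min:
        return "kataegis"
    if size <= omikli_max:
        return "omikli"
    return "intermediate"


def detect_clusters(mutations: Sequence[MutationRecord],
                    imd_threshold: int = IMD_THRESHOLD_DEFAULT,
                    kataegis_min: int = KATAEGIS_MIN_SIZE,
                    omikli_max: int = OMIKLI_MAX_SIZE,
                    reference: Optional[Mapping[str, str]] = None,
                    ) -> list[MutationCluster]:
    """Maximal runs of mutations with every adjacent IMD <= threshold.

    Clusters are disjoint; every mutation participating in a qualifying run
    belongs to exactly one cluster.  When a reference is supplied, member
    contexts are resolved and the TCN / APOBEC3-context fractions filled in.
    """
    clusters: list[MutationCluster] = []
    by_key: dict[tuple[str, str], list[MutationRecord]] = {}
    for m in mutations:
        by_key.setdefault((m.sample_id, m.chrom), []).append(m)
    for (sample_id, chrom), muts in by_key.items():
        muts = sorted(muts, key=lambda m: m.pos)
        run: list[MutationRecord] = [muts[0]]
        for prev, cur in zip(muts, muts[1:]):
            if cur.pos - prev.pos <= imd_threshold:
                run.append(cur)
            else:
                if len(run) >= 2:
                    clusters.append(_make_cluster(
                        sample_id, chrom, run, kataegis_min, omikli_max,
                        reference))
                run = [cur]
        if len(run) >= 2:
            clusters.append(_make_cluster(sample_id, chrom, run,
                                          kataegis_min, omikli_max, reference))
    return clusters


def _make_cluster(sample_id: str, chrom: str,
                  members: Sequence[MutationRecord], kataegis_min: int,
                  omikli_max: int, reference) -> MutationCluster:
    positions = tuple(m.pos for m in members)
    imds = np.diff(positions)
    cluster = MutationCluster(
        sample_id=sample_id, chrom=chrom, positions=positions,
        classification=_classify_size(len(members), kataegis_min, omikli_max),
        max_adjacent_imd=int(imds.max()))
    if reference is not None:
        channels = []
        for m in members:
            if m.vclass != "SNV":
                continue
            try:
                channels.append(extract_context(reference, m.chrom, m.pos,
                                                m.ref, m.alt))
            except ContextError:
                continue
        cluster.tcn_fraction = cluster_tcn_fraction(channels)
        cluster.apobec3_fraction = (
            float(np.mean([is_apobec3_context(c) for c in channels]))
            if channels else float("nan"))
    return cluster


def cluster_tcn_fraction(channels: Sequence[Channel]) -> float:
    """Fraction of member SNVs at TCN motifs (5' T, mutated C; any C>N)."""
    if not channels:
        return float("nan")
    hits = [c.five_prime == "T" and c.substitution.startswith("C")
            for c in channels]
    return float(np.mean(hits))


def adaptive_imd_threshold(n_mutations: int, genome_length: int,
                           quantile: float = 0.01, n_sim: int = 100,
                           rng=None) -> float:
    """Sample-adaptive IMD cutoff from uniform-placement simulations.

    Simulates ``n_sim`` uniform placements of the sample's burden on the
    genome and returns the requested quantile of the pooled IMDs.
    """
    if n_mutations < 2:
        raise ValueError("need at least 2 mutations")
    rng = as_rng(rng)
    imds = []
    for _ in range(n_sim):
        pos = np.sort(rng.integers(1, genome_length + 1, size=n_mutations))
        imds.append(np.diff(pos))
    return float(np.quantile(np.concatenate(imds), quantile))
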