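"""Seeded synthetic-cohort generators.

Every input the analysis pipeline consumes can be generated here with the
statistical structure the analyses assume: a toy reference genome with gene
and panel intervals, per-sample mutation sets drawn from known signature
mixtures at negative-binomial burdens, binary gene x sample matrices with an
injectable exposure-mutation association, paired early/late samples with
controlled shared/acquired composition, survival times with group-dependent
hazards, and allele-specific copy-number segments with or without genome
doubling.

All generators are driven by `numpy.random.Generator`; identical seeds give
identical outputs.

Signature spectra
-----------------
Two bundled signature matrices are provided, both synthetic:

* :func:`toy_signature_matrix` -- orthogonal indicator-like spectra, useful
  for unit tests where identifiability must not be a confounder.
* :func:`synthetic_signature_matrix` -- richer stand-ins for the breast
  cancer SBS repertoire (SBS1, 2, 3, 5, 8, 13, 17, 18) with peaked profiles
  at the motifs each process is known for (SBS2: C>T at TpC; SBS13: C>G/C>A
  at TpC; SBS1: C>T at CpG; SBS17: T>G at TpT; SBS18: C>A) over smooth
  backgrounds.  They reproduce the qualitative channel structure of the
  public references, not their exact values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import (BASES, CHANNEL_LABELS, COMPLEMENT, APOBEC3_CHANNEL_MASK,
                      Channel)
from .io_formats import CNSegment, MutationRecord, PanelFootprint, SampleMeta

#: pyrimidine-normalized trinucleotide contexts, in channel-compatible order
CONTEXTS: tuple[str, ...] = tuple(
    f + c + t for c in "CT" for f in BASES for t in BASES
)
_CONTEXT_ID = {ctx: i for i, ctx in enumerate(CONTEXTS)}

_BASE_CODE = {b: i for i, b in enumerate(BASES)}


def as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _channel_context_and_alt(index: int) -> tuple[str, str]:
    """Map a channel index to (pyrimidine context, pyrimidine-strand alt)."""
    ch = Channel.from_label(CHANNEL_LABELS[index])
    return ch.context, ch.substitution[2]


_CHANNEL_CONTEXT = [_channel_context_and_alt(i)[0] for i in range(96)]
_CHANNEL_ALT = [_channel_context_and_alt(i)[1] for i in range(96)]


# ---------------------------------------------------------------------------
# signature matrices


def toy_signature_matrix(names: Sequence[str] = ("SIG_A", "SIG_B", "SIG_C")
                         ) -> pd.DataFrame:
    """Orthogonal indicator-like spectra on disjoint channel blocks."""
    k = len(names)
    if k > 6:
        raise ValueError("at most 6 orthogonal toy signatures")
    mat = np.zeros((96, k))
    for j in range(k):
        block = slice(16 * j, 16 * (j + 1))
        mat[block, j] = 1.0 / 16
    return pd.DataFrame(mat, index=list(CHANNEL_LABELS), columns=list(names))


def _peak_profile(peaks: Mapping[str, float], background: float) -> np.ndarray:
    """96-vector: named channel peaks over a uniform background; sums to 1."""
    v = np.full(96, background / 96.0)
    for label, w in peaks.items():
        v[CHANNEL_LABELS.index(label)] += w
    return v / v.sum()


def synthetic_signature_matrix() -> pd.DataFrame:
    """Synthetic stand-ins for the breast cancer SBS reference signatures."""
    tc_contexts = [f"T[C>{alt}]{t}" for alt in "TGA" for t in BASES]
    sigs: dict[str, np.ndarray] = {}
    # SBS1: clock-like C>T at CpG sites
    sigs["SBS1"] = _peak_profile(
        {f"{f}[C>T]G": 0.20 for f in BASES}, background=0.20)
    # SBS2: APOBEC3 C>T at TpC
    sigs["SBS2"] = _peak_profile(
        {f"T[C>T]{t}": 0.23 for t in BASES}, background=0.08)
    # SBS13: APOBEC3 C>G (major) and C>A (minor) at TpC
    peaks13 = {f"T[C>G]{t}": 0.17 for t in BASES}
    peaks13.update({f"T[C>A]{t}": 0.055 for t in BASES})
    sigs["SBS13"] = _peak_profile(peaks13, background=0.10)
    # SBS3: HRD-associated, near-featureless flat spectrum
    sigs["SBS3"] = np.full(96, 1.0 / 96)
    # SBS5: clock-like, broad with C>T and T>C elevation
    v5 = np.ones(96)
    v5[32:48] = 3.0   # C>T block
    v5[64:80] = 2.5   # T>C block
    sigs["SBS5"] = v5 / v5.sum()
    # SBS8: HRD-associated, C>A weighted broad spectrum
    v8 = np.ones(96)
    v8[0:16] = 4.0    # C>A block
    v8[48:64] = 1.5   # T>A block
    sigs["SBS8"] = v8 / v8.sum()
    # SBS17: T>G at TpT (and some T>C)
    peaks17 = {f"T[T>G]{t}": 0.17 for t in BASES}
    peaks17.update({f"T[T>C]{t}": 0.05 for t in BASES})
    sigs["SBS17"] = _peak_profile(peaks17, background=0.12)
    # SBS18: reactive-oxygen C>A peaks
    sigs["SBS18"] = _peak_profile(
        {f"{f}[C>A]A": 0.14 for f in BASES} | {f"{f}[C>A]T": 0.08 for f in BASES},
        background=0.12)
    order = ["SBS1", "SBS2", "SBS3", "SBS5", "SBS8", "SBS13", "SBS17", "SBS18"]
    df = pd.DataFrame(sigs, index=list(CHANNEL_LABELS))[order]
    return df / df.sum(axis=0)


# ---------------------------------------------------------------------------
# reference genome, genes and panel


class SiteIndex:
    """Per-context site lists for rejection-free mutation placement.

    For every pyrimidine-normalized trinucleotide context, stores the
    (contig, 1-based position) of every interior reference site whose
    context matches, together with whether the reference base there is the
    purine partner (in which case emitted ref/alt are complemented).
    """

    def __init__(self, reference: Mapping[str, str]):
        self.contigs = list(reference.keys())
        pos_lists: list[list[np.ndarray]] = [[] for _ in CONTEXTS]
        contig_lists: list[list[np.ndarray]] = [[] for _ in CONTEXTS]
        flip_lists: list[list[np.ndarray]] = [[] for _ in CONTEXTS]
        lut = self._triplet_lut()
        for ci, name in enumerate(self.contigs):
            seq = str(reference[name]).upper()
            codes = np.frombuffer(seq.encode(), dtype=np.uint8)
            code_map = np.full(256, -1, dtype=np.int8)
            for b, v in _BASE_CODE.items():
                code_map[ord(b)] = v
            b = code_map[codes]
            if len(b) < 3:
                continue
            tri = b[:-2] * 16 + b[1:-1] * 4 + b[2:]
            valid = (b[:-2] >= 0) & (b[1:-1] >= 0) & (b[2:] >= 0)
            ctx_id = np.where(valid, lut[0][np.clip(tri, 0, 63)], -1)
            flipped = np.where(valid, lut[1][np.clip(tri, 0, 63)], False)
            for k in range(32):
                sel = np.nonzero(ctx_id == k)[0]
                if len(sel):
                    pos_lists[k].append(sel + 2)  # center, 1-based
                    contig_lists[k].append(np.full(len(sel), ci, dtype=np.int32))
                    flip_lists[k].append(flipped[sel])
        self.positions = [np.concatenate(p) if p else np.empty(0, dtype=int)
                          for p in pos_lists]
        self.contig_idx = [np.concatenate(c) if c else np.empty(0, dtype=np.int32)
                           for c in contig_lists]
        self.flipped = [np.concatenate(f) if f else np.empty(0, dtype=bool)
                        for f in flip_lists]

    @staticmethod
    def _triplet_lut() -> tuple[np.ndarray, np.ndarray]:
        ctx = np.full(64, -1, dtype=np.int8)
        flip = np.zeros(64, dtype=bool)
        for f in BASES:
            for c in BASES:
                for t in BASES:
                    code = _BASE_CODE[f] * 16 + _BASE_CODE[c] * 4 + _BASE_CODE[t]
                    if c in "CT":
                        key = f + c + t
                        flip[code] = False
                    else:
                        key = COMPLEMENT[t] + COMPLEMENT[c] + COMPLEMENT[f]
                        flip[code] = True
                    ctx[code] = _CONTEXT_ID[key]
        return ctx, flip

    def n_sites(self, context: str) -> int:
        return len(self.positions[_CONTEXT_ID[context]])


def make_reference(genome_length: int = 1_000_000, gc_fraction: float = 0.41,
                   n_genes: int = 60, gene_length: int = 10_000,
                   panel_fraction: float = 1.0, seed=0,
                   contig: str = "chr1"
                   ) -> tuple[dict[str, str], pd.DataFrame, PanelFootprint]:
    """Generate a toy reference, non-overlapping genes and a panel footprint.

    The panel is a random subset of the gene intervals covering approximately
    ``panel_fraction`` of the total gene bases (the last selected gene is
    truncated to land on the target).
    """
    rng = as_rng(seed)
    total_gene = n_genes * gene_length
    if total_gene > genome_length:
        raise ValueError(
            f"{n_genes} genes of {gene_length} bp do not fit in "
            f"{genome_length} bp")
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                  gc_fraction / 2, (1 - gc_fraction) / 2])
    seq = "".join(np.array(list(BASES))[rng.choice(4, size=genome_length, p=p)])
    reference = {contig: seq}

    # distribute slack space as random gaps between genes
    slack = genome_length - total_gene
    gaps = rng.multinomial(slack, np.ones(n_genes + 1) / (n_genes + 1))
    starts, cursor = [], 0
    for g in range(n_genes):
        cursor += gaps[g]
        starts.append(cursor)
        cursor += gene_length
    genes = pd.DataFrame({
        "chrom": contig,
        "start": starts,
        "end": [s + gene_length for s in starts],
        "gene": [f"GENE{g:03d}" for g in range(n_genes)],
    })

    target = int(round(panel_fraction * total_gene))
    order = rng.permutation(n_genes)
    panel_intervals: list[tuple[str, int, int]] = []
    covered = 0
    for g in order:
        if covered >= target:
            break
        s, e = int(genes.start[g]), int(genes.end[g])
        take = min(e - s, target - covered)
        panel_intervals.append((contig, s, s + take))
        covered += take
    footprint = PanelFootprint(intervals=panel_intervals)
    return reference, genes, footprint


def annotate_genes(records: Sequence[MutationRecord], genes: pd.DataFrame) -> None:
    """Set ``gene`` on each record from interval overlap (in place)."""
    by_chrom = {c: g.sort_values("start") for c, g in genes.groupby("chrom")}
    for rec in records:
        g = by_chrom.get(rec.chrom)
        if g is None:
            continue
        i = int(np.searchsorted(g["start"].to_numpy(), rec.pos)) - 1
        if i >= 0 and rec.pos <= g["end"].iloc[i]:  # 0-based half-open
            rec.gene = g["gene"].iloc[i]


# ---------------------------------------------------------------------------
# mutation simulation


def simulate_sample_mutations(exposure: Sequence[float], n_mut: int,
                              signatures: pd.DataFrame,
                              site_index: SiteIndex, seed,
                              sample_id: str = "S1", patient_id: str = "",
                              ) -> list[MutationRecord]:
    """Draw ``n_mut`` SNVs whose channels follow the signature mixture.

    Channels are drawn from ``signatures @ exposure``; each mutation is then
    placed uniformly at a reference site whose pyrimidine-normalized context
    matches, without replacement within the sample.
    """
    rng = as_rng(seed)
    e = np.asarray(exposure, dtype=float)
    if e.shape != (signatures.shape[1],):
        raise ValueError("exposure length must match signature count")
    if not np.isclose(e.sum(), 1.0):
        raise ValueError("exposure must sum to 1")
    q = signatures.to_numpy() @ e
    q = q / q.sum()
    counts = rng.multinomial(n_mut, q)
    return _place_channel_counts(counts, site_index, rng, sample_id,
                                 patient_id or sample_id)


def _place_channel_counts(counts: np.ndarray, site_index: SiteIndex,
                          rng: np.random.Generator, sample_id: str,
                          patient_id: str) -> list[MutationRecord]:
    records: list[MutationRecord] = []
    by_context: dict[int, list[tuple[int, int]]] = {}
    for ch_idx in np.nonzero(counts)[0]:
        cid = _CONTEXT_ID[_CHANNEL_CONTEXT[ch_idx]]
        by_context.setdefault(cid, []).append((int(ch_idx), int(counts[ch_idx])))
    for cid, channels in by_context.items():
        need = sum(n for _, n in channels)
        pool = site_index.positions[cid]
        if len(pool) == 0:
            raise ValueError(
                f"context {CONTEXTS[cid]} absent from reference")
        if need > len(pool):
            raise ValueError(
                f"context {CONTEXTS[cid]}: need {need} sites, "
                f"reference has {len(pool)}")
        pick = rng.choice(len(pool), size=need, replace=False)
        offset = 0
        center = CONTEXTS[cid][1]
        for ch_idx, n in channels:
            alt_pyr = _CHANNEL_ALT[ch_idx]
            for j in pick[offset:offset + n]:
                flipped = bool(site_index.flipped[cid][j])
                ref = COMPLEMENT[center] if flipped else center
                alt = COMPLEMENT[alt_pyr] if flipped else alt_pyr
                records.append(MutationRecord(
                    sample_id=sample_id, patient_id=patient_id,
                    chrom=site_index.contigs[site_index.contig_idx[cid][j]],
                    pos=int(site_index.positions[cid][j]),
                    ref=ref, alt=alt, vclass="SNV"))
            offset += n
    return records


# ---------------------------------------------------------------------------
# cohort-level configuration and simulation


def default_group_means(signature_names: Sequence[str]) -> dict[str, np.ndarray]:
    """Mean signature mixtures for APOBEC3-, clock- and HRD-dominant groups."""
    base = {
        "APOBEC3": {"SBS1": 0.10, "SBS2": 0.32, "SBS3": 0.05, "SBS5": 0.12,
                    "SBS8": 0.04, "SBS13": 0.28, "SBS17": 0.04, "SBS18": 0.05},
        "Clock": {"SBS1": 0.28, "SBS2": 0.05, "SBS3": 0.08, "SBS5": 0.34,
                  "SBS8": 0.07, "SBS13": 0.04, "SBS17": 0.07, "SBS18": 0.07},
        "HRD": {"SBS1": 0.08, "SBS2": 0.05, "SBS3": 0.34, "SBS5": 0.10,
                "SBS8": 0.26, "SBS13": 0.04, "SBS17": 0.06, "SBS18": 0.07},
    }
    out = {}
    for group, d in base.items():
        v = np.array([d.get(name, 0.0) for name in signature_names])
        out[group] = v / v.sum()
    return out


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate a WGS-scale breast cancer cohort: per-sample burdens of
    ~2,000 SNVs (negative binomial), three dominant-process groups with
    clearly separated mean mixtures, a 1 Mb toy genome with 60 x 10 kb genes.
    """

    n_samples: int = 300
    signature_names: tuple[str, ...] = (
        "SBS1", "SBS2", "SBS3", "SBS5", "SBS8", "SBS13", "SBS17", "SBS18")
    group_weights: dict[str, float] = field(default_factory=lambda: {
        "APOBEC3": 0.40, "Clock": 0.40, "HRD": 0.20})
    dirichlet_concentration: float = 60.0
    burden_mean: float = 2000.0
    burden_dispersion: float = 5.0
    genome_length: int = 1_000_000
    gc_fraction: float = 0.41
    n_genes: int = 60
    gene_length: int = 10_000
    panel_fraction: float = 1.0
    # gene-matrix association
    n_matrix_genes: int = 50
    baseline_rate: float = 0.10
    # paired cohort
    paired_fraction: float = 0.3
    shared_fraction: float = 0.6
    shared_apobec_fraction: float = 0.32
    acquired_apobec_fraction: float = 0.52
    # survival
    survival_rates: dict[str, float] = field(default_factory=lambda: {
        "APOBEC3": 1 / 12.0, "other": 1 / 18.0})
    censor_window: float = 60.0
    wgd_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.panel_fraction, self.paired_fraction,
                  self.shared_fraction, self.shared_apobec_fraction,
                  self.acquired_apobec_fraction, self.wgd_fraction,
                  self.gc_fraction):
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"fraction {f} outside [0, 1]")
        if self.dirichlet_concentration <= 0:
            raise ValueError("Dirichlet concentration must be > 0")


def draw_burdens(n: int, mean: float, dispersion: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial SNV burdens with the given mean and dispersion."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=n)


def simulate_exposures(config: CohortConfig, rng: np.random.Generator
                       ) -> pd.DataFrame:
    """Per-sample true signature mixtures, with group assignment.

    Each sample belongs to a dominant-process group; its mixture is a
    Dirichlet draw around the group mean (concentration scales the mean).
    """
    names = list(config.signature_names)
    means = default_group_means(names)
    groups = list(config.group_weights)
    w = np.array([config.group_weights[g] for g in groups], dtype=float)
    w = w / w.sum()
    assignment = rng.choice(len(groups), size=config.n_samples, p=w)
    rows = []
    for i in range(config.n_samples):
        g = groups[assignment[i]]
        alpha = means[g] * config.dirichlet_concentration
        rows.append(rng.dirichlet(np.maximum(alpha, 1e-3)))
    df = pd.DataFrame(rows, columns=names,
                      index=[f"S{i:04d}" for i in range(config.n_samples)])
    df.insert(0, "group", [groups[a] for a in assignment])
    return df


def simulate_catalog_cohort(config: CohortConfig,
                            signatures: Optional[pd.DataFrame] = None,
                            site_index: Optional[SiteIndex] = None,
                            reference: Optional[Mapping[str, str]] = None,
                            ) -> dict:
    """Simulate a full cohort: reference, mutations, truth table.

    Returns a dict with keys ``reference``, ``genes``, ``footprint``,
    ``site_index``, ``signatures``, ``truth`` (per-sample group, mixture and
    burden) and ``mutations`` (flat list of records).
    """
    rng = as_rng(config.seed)
    if signatures is None:
        signatures = synthetic_signature_matrix()[list(config.signature_names)]
    if site_index is None:
        if reference is None:
            reference, genes, footprint = make_reference(
                genome_length=config.genome_length,
                gc_fraction=config.gc_fraction, n_genes=config.n_genes,
                gene_length=config.gene_length,
                panel_fraction=config.panel_fraction,
                seed=rng.integers(2**31))
        else:
            genes, footprint = None, None
        site_index = SiteIndex(reference)
    else:
        genes, footprint = None, None

    truth = simulate_exposures(config, rng)
    burdens = draw_burdens(config.n_samples, config.burden_mean,
                           config.burden_dispersion, rng)
    truth["n_mut"] = burdens
    mutations: list[MutationRecord] = []
    names = list(config.signature_names)
    for i, sid in enumerate(truth.index):
        mutations.extend(simulate_sample_mutations(
            truth.loc[sid, names].to_numpy(dtype=float), int(burdens[i]),
            signatures, site_index, rng, sample_id=sid, patient_id=f"P{i:04d}"))
    if genes is not None:
        annotate_genes(mutations, genes)
    return {"reference": reference, "genes": genes, "footprint": footprint,
            "site_index": site_index, "signatures": signatures,
            "truth": truth, "mutations": mutations}


# ---------------------------------------------------------------------------
# gene x sample association matrix


def simulate_gene_matrix(exposures: Sequence[float], seed,
                         n_genes: int = 50, baseline_rate: float = 0.10,
                         betas: Optional[Mapping[int, float]] = None,
                         gene_names: Optional[Sequence[str]] = None,
                         sample_ids: Optional[Sequence[str]] = None,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binary gene x sample matrix with a logistic exposure association.

    P(gene g mutated in sample i) = logistic(alpha_g + beta_g * exposure_i),
    with alpha_g = logit(baseline_rate) and beta_g = 0 except for the genes
    listed in ``betas`` (gene index -> log-odds effect).  Returns the matrix
    and a ground-truth table of (alpha, beta) per gene.
    """
    rng = as_rng(seed)
    x = np.asarray(exposures, dtype=float)
    alpha = np.log(baseline_rate / (1 - baseline_rate))
    beta = np.zeros(n_genes)
    for g, b in (betas or {}).items():
        beta[g] = b
    logits = alpha + beta[:, None] * x[None, :]
    p = 1.0 / (1.0 + np.exp(-logits))
    mat = (rng.random(p.shape) < p).astype(np.int8)
    genes = list(gene_names) if gene_names is not None else [
        f"GENE{g:03d}" for g in range(n_genes)]
    samples = list(sample_ids) if sample_ids is not None else [
        f"S{i:04d}" for i in range(len(x))]
    matrix = pd.DataFrame(mat, index=genes, columns=samples)
    truth = pd.DataFrame({"gene": genes, "alpha": alpha, "beta": beta})
    return matrix, truth


# ---------------------------------------------------------------------------
# paired early/late samples


def _context_controlled_counts(n_mut: int, apobec_fraction: float,
                               rng: np.random.Generator) -> np.ndarray:
    """Channel counts with a fixed expected APOBEC3-context fraction.

    Mutations are APOBEC3-context with probability ``apobec_fraction``
    (uniform over the 12 TpC C>D channels), otherwise uniform over the
    remaining 84 channels.
    """
    is_apo = rng.random(n_mut) < apobec_fraction
    counts = np.zeros(96, dtype=int)
    apo_idx = np.nonzero(APOBEC3_CHANNEL_MASK)[0]
    other_idx = np.nonzero(~APOBEC3_CHANNEL_MASK)[0]
    n_apo = int(is_apo.sum())
    np.add.at(counts, rng.choice(apo_idx, size=n_apo), 1)
    np.add.at(counts, rng.choice(other_idx, size=n_mut - n_apo), 1)
    return counts


def simulate_paired_cohort(site_index: SiteIndex, seed,
                           n_patients: int = 30, n_early: int = 40,
                           shared_fraction: float = 0.6,
                           n_acquired: int = 30,
                           shared_apobec_fraction: float = 0.32,
                           acquired_apobec_fraction: float = 0.52,
                           genotype_depth: float = 30.0) -> dict:
    """Paired early/late samples with controlled shared/acquired structure.

    Each patient has an early sample of ``n_early`` SNVs; the late sample
    carries a random ``shared_fraction`` of them (same sites) plus
    ``n_acquired`` newly acquired SNVs.  APOBEC3-context composition is
    controlled separately for the early/shared pool
    (``shared_apobec_fraction``) and the acquired pool
    (``acquired_apobec_fraction``).  Early-sample genotyping read support is
    emitted for every late mutation: Poisson(``genotype_depth``) alt reads at
    shared sites, zero at acquired sites.

    Returns per-patient early/late record lists, genotype maps
    (site -> early alt reads) and per-late-mutation truth labels.
    """
    rng = as_rng(seed)
    patients = {}
    truth_rows = []
    for pi in range(n_patients):
        pid = f"P{pi:03d}"
        early_id, late_id = f"{pid}_early", f"{pid}_late"
        counts = _context_controlled_counts(n_early, shared_apobec_fraction, rng)
        early = _place_channel_counts(counts, site_index, rng, early_id, pid)
        n_shared = int(round(shared_fraction * n_early))
        keep = rng.choice(n_early, size=n_shared, replace=False)
        late: list[MutationRecord] = []
        genotype: dict[tuple, int] = {}
        for j in keep:
            src = early[j]
            late.append(MutationRecord(
                sample_id=late_id, patient_id=pid, chrom=src.chrom,
                pos=src.pos, ref=src.ref, alt=src.alt, vclass="SNV"))
            genotype[src.site] = max(2, int(rng.poisson(genotype_depth)))
            truth_rows.append({"patient_id": pid, "site": src.site,
                               "truth": "shared"})
        acq_counts = _context_controlled_counts(
            n_acquired, acquired_apobec_fraction, rng)
        early_sites = {m.site[:2] for m in early}
        acquired = [m for m in _place_channel_counts(
            acq_counts, site_index, rng, late_id, pid)
            if m.site[:2] not in early_sites]
        for m in acquired:
            genotype[m.site] = 0
            truth_rows.append({"patient_id": pid, "site": m.site,
                               "truth": "acquired"})
        late.extend(acquired)
        patients[pid] = {"early_id": early_id, "late_id": late_id,
                         "early": early, "late": late, "genotype": genotype}
    return {"patients": patients, "truth": pd.DataFrame(truth_rows)}


# ---------------------------------------------------------------------------
# survival and copy number


def simulate_survival(groups: Mapping[str, int], rates: Mapping[str, float],
                      censor_window: float, seed) -> pd.DataFrame:
    """Exponential event times per group with uniform censoring.

    ``groups`` maps group label -> arm size; ``rates`` maps label -> hazard
    (events per month).  Censoring times are uniform on (0, censor_window);
    the event flag is 1 when the event time does not exceed the censoring
    time.
    """
    rng = as_rng(seed)
    rows = []
    for g, n in groups.items():
        t_event = rng.exponential(1.0 / rates[g], size=n)
        if np.isfinite(censor_window):
            t_cens = rng.uniform(0, censor_window, size=n)
        else:
            t_cens = np.full(n, np.inf)
        t = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        for i in range(n):
            rows.append({"sample_id": f"{g}_{i:04d}", "group": g,
                         "time_months": max(float(t[i]), 1e-9),
                         "event": int(event[i])})
    return pd.DataFrame(rows)


def simulate_cn_segments(wgd: bool, genome_length: int = 1_000_000,
                         seed=0, n_segments: int = 20,
                         doubled_fraction: Optional[float] = None,
                         ) -> list[CNSegment]:
    """Allele-specific segments with or without whole-genome doubling.

    With ``wgd`` the fraction of bases at major copy number >= 2 is ~0.75
    (always > 0.5); without, ~0.25 (always <= 0.5).  Pass
    ``doubled_fraction`` to force an exact fraction (e.g. 0.5 for the
    boundary case).
    """
    rng = as_rng(seed)
    if doubled_fraction is None:
        doubled_fraction = 0.75 if wgd else 0.25
    cuts = np.sort(rng.choice(
        np.arange(1, genome_length), size=n_segments - 1, replace=False))
    bounds = np.concatenate([[0], cuts, [genome_length]])
    target = doubled_fraction * genome_length
    segments: list[CNSegment] = []
    doubled_bases = 0
    for s, e in zip(bounds[:-1], bounds[1:]):
        length = int(e - s)
        if doubled_bases < target:
            take = min(length, int(round(target)) - doubled_bases)
            if take > 0:
                major = int(rng.choice([2, 2, 3]))
                minor = int(rng.integers(0, min(major, 2) + 1))
                segments.append(CNSegment("chr1", int(s), int(s) + take,
                                          major, min(minor, major)))
                doubled_bases += take
            if take < length:
                segments.append(CNSegment("chr1", int(s) + take, int(e), 1,
                                          int(rng.integers(0, 2))))
        else:
            segments.append(CNSegment("chr1", int(s), int(e), 1,
                                      int(rng.integers(0, 2))))
    return segments
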