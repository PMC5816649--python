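"""K-mer representation bias between basecalled reads and their reference.

Neural-network nanopore basecallers call overlapping 5-mers, so systematic
miscalls surface as specific k-mers being over- or under-represented in the
read data relative to the genomic regions the reads actually map to.  This
module quantifies that bias three ways:

1. **Coverage-normalized ratio** — the frequency of each k-mer among mapped
   read bases divided by its frequency in the covered reference regions
   (pseudocounted so a k-mer absent from one side stays finite).
2. **Z-score outliers** — log2 ratios standardized against their own
   distribution; |z| above a threshold flags gross outliers.
3. **Negative-binomial regression** — per k-mer, a two-group NB GLM with a
   log link compares replicate read counts against the single reference
   count, with log(total k-mer count) as offset:

       log mu = beta0 + beta1 * source,   source = 1 for read tables

   The dispersion is estimated per k-mer by profile maximum likelihood with
   a floor at 1e-8 (the Poisson limit), beta1 is tested with a two-sided
   Wald test, and p-values are Benjamini-Hochberg adjusted across all 4^k
   k-mers.

Reads mapped to the minus strand are reverse-complemented into reference
orientation before tallying so read and reference k-mers share a frame, and
reference tallies cover only regions reached by at least one read.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io_formats import AlignmentRecord, ReadRecord, SequenceRecord, reverse_complement

BASES = "ACGT"
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_INDEX[ord(_b)] = _i

DISPERSION_FLOOR = 1e-8
_DISPERSION_CEIL = 1e6


@lru_cache(maxsize=8)
def kmer_strings(k: int) -> tuple[str, ...]:
    """All 4^k k-mers in alphabetical order (AAAAA ... TTTTT for k=5)."""
    return tuple("".join(p) for p in itertools.product(BASES, repeat=k))


def kmer_gc(k: int) -> np.ndarray:
    """GC fraction of every k-mer, in alphabetical order."""
    return np.array([(s.count("G") + s.count("C")) / k for s in kmer_strings(k)])


@dataclass
class KmerTable:
    """Counts of all 4^k k-mers for one sequence collection.

    ``counts`` is a dense, zero-filled vector aligned with
    :func:`kmer_strings`; ``total`` is its sum.
    """

    k: int
    counts: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != 4**self.k:
            raise ValueError(f"expected {4**self.k} counts for k={self.k}")
        if np.any(self.counts < 0):
            raise ValueError("k-mer counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(kmer_strings(self.k)), name=self.source_label)


def count_kmers(
    sequences: Iterable[str | SequenceRecord], k: int = 5, source_label: str = ""
) -> KmerTable:
    """Tally all overlapping k-mers (step 1) across a sequence collection.

    Windows containing N are skipped; sequences shorter than k contribute
    nothing.  The table is zero-filled over all 4^k keys.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = np.zeros(4**k, dtype=np.int64)
    for seq in sequences:
        s = seq.sequence if isinstance(seq, SequenceRecord) else seq
        codes = _BASE_INDEX[np.frombuffer(s.upper().encode("ascii"), dtype=np.uint8)]
        n_win = len(codes) - k + 1
        if n_win < 1:
            continue
        safe = np.where(codes < 0, 0, codes).astype(np.int64)
        w = np.zeros(n_win, dtype=np.int64)
        for j in range(k):
            w = w * 4 + safe[j : j + n_win]
        invalid = (codes < 0).astype(np.int64)
        if invalid.any():
            bad = np.convolve(invalid, np.ones(k, dtype=np.int64), mode="valid") > 0
            w = w[~bad]
        counts += np.bincount(w, minlength=4**k)
    return KmerTable(k=k, counts=counts, source_label=source_label)


# ---------------------------------------------------------------------------
# Restricting tallies to mapped material
# ---------------------------------------------------------------------------

def aligned_read_portion(read: ReadRecord, aln: AlignmentRecord) -> str:
    """The aligned (non-clipped) part of a read, in reference orientation.

    Minus-strand reads are reverse-complemented first, so the returned string
    runs along the forward reference strand; soft-clipped bases are dropped
    (hard-clipped bases are never in the stored sequence).
    """
    if not aln.is_mapped:
        raise ValueError(f"read {aln.read_id!r} is unmapped")
    seq = reverse_complement(read.sequence) if aln.strand == "-" else read.sequence
    lead = 0
    for op, n in aln.cigar:
        if op == "H":
            continue
        if op == "S":
            lead = n
        break
    trail = 0
    for op, n in reversed(aln.cigar):
        if op == "H":
            continue
        if op == "S":
            trail = n
        break
    return seq[lead : len(seq) - trail] if trail else seq[lead:]


def merged_covered_intervals(
    alignments: Iterable[AlignmentRecord],
) -> dict[str, list[tuple[int, int]]]:
    """Union of reference intervals covered by >= 1 mapped alignment."""
    by_ref: dict[str, list[tuple[int, int]]] = {}
    for aln in alignments:
        if not aln.is_mapped:
            continue
        by_ref.setdefault(aln.ref_name, []).append((aln.ref_start, aln.ref_end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for ref, ivals in by_ref.items():
        ivals.sort()
        out = [list(ivals[0])]
        for start, end in ivals[1:]:
            if start <= out[-1][1]:
                out[-1][1] = max(out[-1][1], end)
            else:
                out.append([start, end])
        merged[ref] = [(s, e) for s, e in out]
    return merged


def mapped_kmer_tables(
    replicate_sets: Sequence[tuple[Sequence[ReadRecord], Sequence[AlignmentRecord]]],
    references: Sequence[SequenceRecord],
    k: int = 5,
) -> tuple[list[KmerTable], KmerTable]:
    """Per-replicate read k-mer tables plus the matched reference table.

    Read tables tally the aligned portions of mapped reads (reference
    orientation); the reference table tallies only regions covered by at
    least one read in any replicate, so both sides describe the same genomic
    material.
    """
    ref_by_name = {r.id: r for r in references}
    read_tables: list[KmerTable] = []
    all_alignments: list[AlignmentRecord] = []
    for i, (reads, alignments) in enumerate(replicate_sets):
        aln_by_id = {a.read_id: a for a in alignments if a.is_mapped}
        pieces = []
        for read in reads:
            aln = aln_by_id.get(read.qualified_id)
            if aln is not None:
                pieces.append(aligned_read_portion(read, aln))
                all_alignments.append(aln)
        read_tables.append(count_kmers(pieces, k=k, source_label=f"replicate_{i + 1}"))
    covered = merged_covered_intervals(all_alignments)
    ref_pieces = [
        ref_by_name[name].sequence[s:e]
        for name, ivals in covered.items()
        for s, e in ivals
        if name in ref_by_name
    ]
    ref_table = count_kmers(ref_pieces, k=k, source_label="reference")
    return read_tables, ref_table


# ---------------------------------------------------------------------------
# Ratio and Z-score screens
# ---------------------------------------------------------------------------

def normalized_ratio(
    reads_table: KmerTable, ref_table: KmerTable, pseudocount: float = 0.5
) -> pd.Series:
    """Coverage-normalized read/reference frequency ratio per k-mer.

    Both tables are converted to pseudocounted frequencies
    ``(c + pc) / (total + 4^k * pc)`` before dividing, so the ratio is
    finite and positive even for k-mers absent on one side.
    """
    if reads_table.k != ref_table.k:
        raise ValueError("tables have different k")
    if reads_table.total == 0 or ref_table.total == 0:
        raise ValueError("cannot form ratios from an empty k-mer table")
    n = 4**reads_table.k
    f_read = (reads_table.counts + pseudocount) / (reads_table.total + n * pseudocount)
    f_ref = (ref_table.counts + pseudocount) / (ref_table.total + n * pseudocount)
    return pd.Series(f_read / f_ref, index=list(kmer_strings(reads_table.k)), name="ratio")


def zscore_outliers(ratios: pd.Series, z_threshold: float = 3.0) -> pd.DataFrame:
    """Standardize log2 ratios; |z| > threshold flags an outlier.

    A zero-variance ratio set yields all-zero z-scores and no outliers.
    """
    if len(ratios) < 2:
        raise ValueError("need at least 2 ratios for a Z-score")
    log2r = np.log2(np.asarray(ratios, dtype=float))
    sd = log2r.std(ddof=1)
    z = np.zeros_like(log2r) if sd == 0 else (log2r - log2r.mean()) / sd
    return pd.DataFrame(
        {"zscore": z, "outlier": np.abs(z) > z_threshold}, index=ratios.index
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Negative-binomial regression
# ---------------------------------------------------------------------------

def _solve_group_rate(Y: np.ndarray, T: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """MLE of the common rate m for counts Y ~ NB(m * T, disp), vectorized
    over rows.  Solved by Newton iteration on log m."""
    u = np.log(Y.sum(axis=1) / T.sum())
    a = disp[:, None]
    for _ in range(40):
        mu = np.exp(u)[:, None] * T
        denom = 1.0 + a * mu
        f = ((Y - mu) / denom).sum(axis=1)
        fp = -(mu * (1.0 + a * Y) / denom**2).sum(axis=1)
        step = np.clip(f / fp, -5.0, 5.0)
        u = u - step
        if np.max(np.abs(f)) < 1e-10 * max(1.0, float(Y.sum())):
            break
    return np.exp(u)


def _profile_dispersion(
    y_ref: np.ndarray, t_ref: float, Y: np.ndarray, T: np.ndarray
) -> np.ndarray:
    """Per-row profile-ML NB dispersion with a floor at the Poisson limit.

    The group rates are re-solved at each candidate dispersion; by the
    envelope theorem the profile-likelihood gradient in the dispersion equals
    the partial derivative at the refitted rates, so a sign-based bisection
    on that gradient finds the profile maximum.
    """

    def grad(a: np.ndarray) -> np.ndarray:
        m = _solve_group_rate(Y, T, a)
        mu_reads = m[:, None] * T
        g = _disp_score_rows(Y, mu_reads, a)
        g += _disp_score_rows(y_ref[:, None], y_ref[:, None].astype(float), a)
        return g

    lo = np.full(len(y_ref), DISPERSION_FLOOR)
    g_lo = grad(lo)
    if g_lo.max() <= 0:
        return lo
    hi = np.ones_like(lo)
    active = g_lo > 0
    # expand the bracket where the gradient is still positive at hi
    for _ in range(25):
        g_hi = grad(hi)
        need = active & (g_hi > 0) & (hi < _DISPERSION_CEIL)
        if not need.any():
            break
        hi[need] *= 4.0
    a_lo = np.where(active, lo, lo)
    a_hi = np.where(active, np.minimum(hi, _DISPERSION_CEIL), lo)
    for _ in range(45):
        mid = np.sqrt(a_lo * a_hi)  # bisection in log space
        g_mid = grad(mid)
        go_up = g_mid > 0
        a_lo = np.where(active & go_up, mid, a_lo)
        a_hi = np.where(active & ~go_up, mid, a_hi)
    out = np.where(active, np.sqrt(a_lo * a_hi), lo)
    return np.maximum(out, DISPERSION_FLOOR)


def _disp_score_rows(y: np.ndarray, mu: np.ndarray, a: np.ndarray) -> np.ndarray:
    inv_a = 1.0 / a
    t1 = inv_a**2 * (
        np.log1p(a[:, None] * mu).sum(axis=1)
        + (special.digamma(inv_a)[:, None] - special.digamma(y + inv_a[:, None])).sum(axis=1)
    )
    t2 = ((y - mu) / (a[:, None] * (1.0 + a[:, None] * mu))).sum(axis=1)
    return t1 + t2


def nb_regression(
    read_tables: Sequence[KmerTable],
    ref_table: KmerTable,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-k-mer two-group negative-binomial GLM of reads versus reference.

    For each k-mer the replicate read counts and the single reference count
    are modeled as NB with ``log mu = beta0 + beta1*source + log(total)``
    (source = 1 for read tables).  ``log2_fold_change`` is beta1/ln 2; the
    p-value is a two-sided Wald test on beta1 with the per-k-mer dispersion
    profiled out (floored at 1e-8); ``p_adjusted`` is BH over all 4^k
    k-mers and ``significant`` means ``p_adjusted < alpha``.

    K-mers with zero counts everywhere get p = 1 by convention; k-mers where
    one whole group is zero are Haldane-adjusted (0.5 added to every cell of
    that k-mer's row) and flagged ``zero_adjusted``.
    """
    if len(read_tables) < 2:
        raise ValueError("need >= 2 read replicates for the NB regression")
    k = ref_table.k
    if any(t.k != k for t in read_tables):
        raise ValueError("all tables must share the same k")
    n = 4**k
    Y = np.stack([t.counts for t in read_tables], axis=1).astype(float)  # (n, R)
    T = np.array([t.total for t in read_tables], dtype=float)
    y_ref = ref_table.counts.astype(float)
    t_ref = float(ref_table.total)
    if t_ref == 0 or np.any(T == 0):
        raise ValueError("cannot regress against an empty k-mer table")

    all_zero = (Y.sum(axis=1) == 0) & (y_ref == 0)
    zero_adjusted = ((Y.sum(axis=1) == 0) | (y_ref == 0)) & ~all_zero
    Yw = Y.copy()
    yw_ref = y_ref.copy()
    Yw[zero_adjusted | all_zero] += 0.5
    yw_ref[zero_adjusted | all_zero] += 0.5

    disp = _profile_dispersion(yw_ref, t_ref, Yw, T)
    m = _solve_group_rate(Yw, T, disp)
    r0 = yw_ref / t_ref
    beta1 = np.log(m) - np.log(r0)

    mu_reads = m[:, None] * T
    info_reads = (mu_reads / (1.0 + disp[:, None] * mu_reads)).sum(axis=1)
    info_ref = yw_ref / (1.0 + disp * yw_ref)
    se = np.sqrt(1.0 / info_ref + 1.0 / info_reads)
    z = beta1 / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    p[all_zero] = 1.0
    beta1[all_zero] = 0.0

    p_adj = bh_adjust(p)
    return pd.DataFrame(
        {
            "log2_fold_change": beta1 / np.log(2.0),
            "dispersion": disp,
            "wald_z": z,
            "p_value": p,
            "p_adjusted": p_adj,
            "significant": p_adj < alpha,
            "zero_adjusted": zero_adjusted,
            "all_zero": all_zero,
        },
        index=list(kmer_strings(k)),
    )


def annotate_volcano(result: pd.DataFrame, fc_threshold: float = 2.0) -> pd.DataFrame:
    """Volcano-plot table: effect size, -log10 p, and annotation flags.

    A k-mer is annotated when it is significant and its fold change is at
    least ``fc_threshold`` in either direction.
    """
    k = len(result.index[0])
    out = result.copy()
    out["neg_log10_p"] = -np.log10(out["p_value"])
    out["gc_fraction"] = kmer_gc(k)
    out["annotated"] = out["significant"] & (
        np.abs(out["log2_fold_change"]) >= np.log2(fc_threshold)
    )
    return out


def replicate_concordance(tables: Sequence[KmerTable]) -> float:
    """Mean pairwise Spearman correlation of k-mer counts across replicates.

    Returns NaN when any table has constant counts (correlation undefined).
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 tables")
    rhos = []
    for i in range(len(tables)):
        for j in range(i + 1, len(tables)):
            a, b = tables[i].counts, tables[j].counts
            if np.all(a == a[0]) or np.all(b == b[0]):
                return float("nan")
            rho, _ = stats.spearmanr(a, b)
            rhos.append(rho)
    return float(np.mean(rhos))


def kmer_bias_analysis(
    read_tables: Sequence[KmerTable],
    ref_table: KmerTable,
    alpha: float = 0.05,
    z_threshold: float = 3.0,
    pseudocount: float = 0.5,
    fc_threshold: float = 2.0,
) -> pd.DataFrame:
    """Full per-k-mer bias table combining all three screens.

    Ratios and Z-scores are computed on the pooled read table; the NB
    regression uses the replicate tables individually.
    """
    k = ref_table.k
    pooled = KmerTable(
        k=k,
        counts=np.sum([t.counts for t in read_tables], axis=0),
        source_label="pooled_reads",
    )
    ratios = normalized_ratio(pooled, ref_table, pseudocount)
    zs = zscore_outliers(ratios, z_threshold)
    reg = annotate_volcano(nb_regression(read_tables, ref_table, alpha), fc_threshold)
    out = pd.DataFrame(index=list(kmer_strings(k)))
    out["kmer"] = out.index
    out["gc_fraction"] = kmer_gc(k)
    for i, t in enumerate(read_tables):
        out[f"read_count_{i + 1}"] = t.counts
    out["ref_count"] = ref_table.counts
    out["ratio"] = ratios
    out["zscore"] = zs["zscore"]
    out["z_outlier"] = zs["outlier"]
    for col in (
        "log2_fold_change",
        "dispersion",
        "p_value",
        "p_adjusted",
        "significant",
        "annotated",
        "zero_adjusted",
    ):
        out[col] = reg[col]
    return out
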