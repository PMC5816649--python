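"""Per-read summary metrics and dataset-level length/quality histograms.

Computes the standard per-read diagnostics for a basecalled nanopore run:
mean read Q-score (arithmetic and error-probability-domain), pass/fail
classification, GC content, and CIGAR/NM-based percent identity against a
reference, plus the frequency-normalized 2D histogram of read quality versus
log read length used to visualise whole runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import AlignmentRecord, ReadClass, ReadRecord

#: mean-Q thresholds for pass classification: a 2D consensus read passes at
#: mean Q strictly above 9, any single-strand read strictly above 6.
PASS_Q_1D = 6.0
PASS_Q_2D = 9.0


@dataclass
class ReadSummary:
    """Per-read metric row; ``percent_identity`` is None for unmapped reads."""

    read_id: str
    read_class: ReadClass
    length: int
    mean_q_arith: float
    mean_q_prob: float
    gc_fraction: float
    passed: bool
    percent_identity: float | None = None


@dataclass
class Histogram2D:
    """2D histogram of mean read Q versus log10 read length.

    ``counts[i, j]`` is the number of reads in length bin i and Q bin j;
    ``normalized`` rescales each length column to sum to 1 (all-zero columns
    stay zero), which is the frequency normalization used when comparing runs
    of different depth.
    """

    x_edges: np.ndarray  # log10(length) bin edges
    y_edges: np.ndarray  # mean-Q bin edges
    counts: np.ndarray
    normalized: np.ndarray


def mean_read_qscore(qualities: Sequence[int], method: str = "error_prob") -> float:
    """Mean Q-score of a read.

    ``arithmetic`` is the plain mean of the per-base Phred scores.
    ``error_prob`` converts each score to an error probability, averages, and
    converts back: ``-10*log10(mean(10^(-q/10)))``.  The latter is the
    platform convention for whole-read quality and is always <= the
    arithmetic mean (Jensen's inequality), with equality only when all
    per-base scores agree.
    """
    if len(qualities) == 0:
        raise ValueError("cannot compute mean Q of an empty quality list")
    q = np.asarray(qualities, dtype=float)
    if method == "arithmetic":
        return float(q.mean())
    if method == "error_prob":
        return float(-10.0 * np.log10(np.mean(10.0 ** (-q / 10.0))))
    raise ValueError(f"unknown mean-Q method {method!r}")


def classify_pass(
    read_class: ReadClass,
    mean_q: float,
    threshold_1d: float = PASS_Q_1D,
    threshold_2d: float = PASS_Q_2D,
) -> bool:
    """Pass/fail call: strict ``mean_q > threshold`` with the 2D-consensus
    class held to the higher bar."""
    if read_class is ReadClass.CONSENSUS_2D:
        return mean_q > threshold_2d
    return mean_q > threshold_1d


def gc_fraction(sequence: str) -> float:
    """(G+C) / (A+C+G+T); N bases are excluded from the denominator.

    Returns NaN for an all-N sequence; an empty sequence is a hard error.
    """
    if len(sequence) == 0:
        raise ValueError("cannot compute GC fraction of an empty sequence")
    gc = sequence.count("G") + sequence.count("C")
    acgt = gc + sequence.count("A") + sequence.count("T")
    if acgt == 0:
        return math.nan
    return gc / acgt


def percent_identity(aln: AlignmentRecord) -> float:
    """BLAST-like percent identity from the CIGAR string and NM tag.

    With ``M_len`` the total length of M/=/X ops, ``I``/``D`` the inserted and
    deleted base totals, and ``mismatches = NM - I - D``::

        identity = 100 * (M_len - mismatches) / (M_len + I + D)

    i.e. matched columns over all alignment columns.  Soft/hard clips are
    outside the alignment and do not enter.  Equals a brute-force
    column-by-column comparison of the reconstructed alignment.
    """
    if not aln.is_mapped:
        raise ValueError(f"read {aln.read_id!r} is unmapped; identity undefined")
    if aln.nm is None:
        raise ValueError(f"read {aln.read_id!r} lacks an edit distance (NM)")
    m_len = aln.op_total("M=X")
    ins = aln.op_total("I")
    dele = aln.op_total("D")
    mismatches = aln.nm - ins - dele
    if mismatches < 0:
        raise ValueError(
            f"read {aln.read_id!r}: NM={aln.nm} < I+D={ins + dele}; inconsistent record"
        )
    columns = m_len + ins + dele
    return 100.0 * (m_len - mismatches) / columns


def summarize_reads(
    reads: Iterable[ReadRecord],
    alignments: Iterable[AlignmentRecord] | None = None,
    threshold_1d: float = PASS_Q_1D,
    threshold_2d: float = PASS_Q_2D,
    pass_method: str = "error_prob",
) -> list[ReadSummary]:
    """Build per-read summaries, joining alignments on the qualified read id.

    Both mean-Q conventions are computed; ``pass_method`` selects which one
    the pass/fail call uses.
    """
    aln_by_id: Mapping[str, AlignmentRecord] = {}
    if alignments is not None:
        aln_by_id = {a.read_id: a for a in alignments if a.is_mapped}
    summaries = []
    for read in reads:
        mq_arith = mean_read_qscore(read.qualities, "arithmetic")
        mq_prob = mean_read_qscore(read.qualities, "error_prob")
        mq = mq_prob if pass_method == "error_prob" else mq_arith
        aln = aln_by_id.get(read.qualified_id)
        summaries.append(
            ReadSummary(
                read_id=read.id,
                read_class=read.read_class,
                length=len(read),
                mean_q_arith=mq_arith,
                mean_q_prob=mq_prob,
                gc_fraction=gc_fraction(read.sequence),
                passed=classify_pass(read.read_class, mq, threshold_1d, threshold_2d),
                percent_identity=percent_identity(aln) if aln is not None else None,
            )
        )
    return summaries


def summaries_to_frame(summaries: Sequence[ReadSummary]):
    import pandas as pd

    return pd.DataFrame(
        {
            "read_id": [s.read_id for s in summaries],
            "read_class": [s.read_class.value for s in summaries],
            "length": [s.length for s in summaries],
            "mean_q_arith": [s.mean_q_arith for s in summaries],
            "mean_q_prob": [s.mean_q_prob for s in summaries],
            "gc_fraction": [s.gc_fraction for s in summaries],
            "passed": [s.passed for s in summaries],
            "percent_identity": [s.percent_identity for s in summaries],
        }
    )


def build_length_q_histogram(
    summaries: Sequence[ReadSummary],
    n_length_bins: int = 50,
    n_q_bins: int = 40,
    q_field: str = "mean_q_prob",
) -> Histogram2D:
    """Frequency-normalized 2D histogram of mean read Q versus read length.

    Lengths are binned on a log10 axis spanning the observed range; each
    length column of ``normalized`` sums to 1 (or stays all-zero).
    """
    if n_length_bins < 1 or n_q_bins < 1:
        raise ValueError("bin counts must be positive")
    if len(summaries) == 0:
        raise ValueError("no summaries to bin")
    log_len = np.log10([s.length for s in summaries])
    q = np.array([getattr(s, q_field) for s in summaries], dtype=float)
    # widen degenerate ranges so a single value still lands in a bin
    x_lo, x_hi = log_len.min(), log_len.max()
    y_lo, y_hi = q.min(), q.max()
    if x_lo == x_hi:
        x_lo, x_hi = x_lo - 0.5, x_hi + 0.5
    if y_lo == y_hi:
        y_lo, y_hi = y_lo - 0.5, y_hi + 0.5
    counts, x_edges, y_edges = np.histogram2d(
        log_len, q, bins=[n_length_bins, n_q_bins], range=[[x_lo, x_hi], [y_lo, y_hi]]
    )
    counts = counts.astype(np.int64)
    col_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = np.where(col_sums > 0, counts / np.maximum(col_sums, 1), 0.0)
    return Histogram2D(x_edges=x_edges, y_edges=y_edges, counts=counts, normalized=normalized)
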