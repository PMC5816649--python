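"""Decile-based Markov structure of per-base Q-scores.

Per-base Phred scores of nanopore basecalls are strongly autocorrelated:
the best single predictor of a base's Q-score is the Q-score of the
preceding base.  This module quantifies that structure by discretizing the
pooled Q-score distribution into deciles (bins of near-equal occupancy) and
estimating, as directly observable conditional frequencies,

* the decile-to-decile transition matrix P(next decile | current decile),
  one chain per read (never across read boundaries), and
* the base emission matrix P(called base in {A,C,G,T} | decile), which
  exposes base-specific basecaller bias (low deciles enriched for A/G, high
  deciles for T/C), and
* plain per-base mean Q-scores.

No latent states are fitted: the transition/emission decomposition here is
the observable Markov chain on deciles, which is what the conditional
frequency displays of run diagnostics show.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import ReadRecord

BASES = "ACGT"
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_INDEX[ord(_b)] = _i


class DegenerateBinningError(ValueError):
    """Raised when the Q-score distribution cannot support the requested
    number of equal-occupancy bins (too many ties)."""


@dataclass
class DecileBinning:
    """Equal-occupancy binning of a Q-score distribution.

    ``edges`` are the ``n_bins - 1`` interior cut points (empirical
    nearest-rank quantiles); bins are right-closed, i.e. bin *i* (1-based)
    covers ``(edges[i-2], edges[i-1]]`` with open ends at the extremes.
    Because integer Phred scores are heavily tied, occupancies are only as
    equal as ties permit; the achieved occupancies from the fit are kept in
    ``occupancy``.
    """

    n_bins: int
    edges: np.ndarray
    occupancy: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        if len(self.edges) != self.n_bins - 1:
            raise ValueError(f"expected {self.n_bins - 1} edges, got {len(self.edges)}")
        if np.any(np.diff(self.edges) < 0):
            raise ValueError("edges must be non-decreasing")

    def assign_index(self, q: Sequence[float]) -> np.ndarray:
        """0-based bin index for each value (right-closed bins)."""
        return np.searchsorted(self.edges, np.asarray(q, dtype=float), side="left")

    def assign(self, q: Sequence[float]) -> np.ndarray:
        """1-based decile label for each value, in [1, n_bins]."""
        return self.assign_index(q) + 1


@dataclass
class TransitionMatrix:
    """Decile-to-decile transition counts and row-normalized probabilities."""

    counts: np.ndarray
    probs: np.ndarray
    binning: DecileBinning


@dataclass
class EmissionMatrix:
    """Per-decile base composition: counts and P(base | decile) over A,C,G,T."""

    counts: np.ndarray
    probs: np.ndarray
    binning: DecileBinning
    n_skipped: int = 0  # N bases excluded from the tally


def fit_decile_binning(all_q: Iterable[float], n_bins: int = 10) -> DecileBinning:
    """Fit equal-occupancy bin edges to a pooled Q-score sample.

    Edges are nearest-rank empirical quantiles at k/n_bins.  If ties are so
    heavy that edges coincide (some bin would be empty), a
    :class:`DegenerateBinningError` suggests a smaller ``n_bins``.
    """
    q = np.fromiter(all_q, dtype=float) if not isinstance(all_q, np.ndarray) else np.asarray(all_q, dtype=float)
    if len(q) < n_bins:
        raise ValueError(f"need at least {n_bins} values to fit {n_bins} bins")
    probs = np.arange(1, n_bins) / n_bins
    edges = np.quantile(q, probs, method="inverted_cdf")
    if len(np.unique(edges)) < n_bins - 1:
        raise DegenerateBinningError(
            f"Q-score ties leave fewer than {n_bins} distinct quantile ranks; "
            f"try a smaller n_bins"
        )
    binning = DecileBinning(n_bins=n_bins, edges=edges)
    binning.occupancy = np.bincount(binning.assign_index(q), minlength=n_bins)
    return binning


def _qualities_array(read: ReadRecord) -> np.ndarray:
    return np.asarray(read.qualities, dtype=float)


def transition_matrix(reads: Sequence[ReadRecord], binning: DecileBinning) -> TransitionMatrix:
    """Estimate P(next-base decile | current-base decile).

    Consecutive base pairs are counted within each read only; each read is a
    separate chain and nothing is counted across read boundaries.
    """
    n = binning.n_bins
    counts = np.zeros((n, n), dtype=np.int64)
    any_pair = False
    for read in reads:
        if len(read) < 2:
            continue
        any_pair = True
        d = binning.assign_index(_qualities_array(read))
        np.add.at(counts, (d[:-1], d[1:]), 1)
    if not any_pair:
        raise ValueError("no reads of length >= 2; no transitions to count")
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        probs = np.where(row_sums > 0, counts / np.maximum(row_sums, 1), 0.0)
    return TransitionMatrix(counts=counts, probs=probs, binning=binning)


def emission_matrix(reads: Sequence[ReadRecord], binning: DecileBinning) -> EmissionMatrix:
    """Estimate P(called base | Q-score decile); N bases are skipped and
    counted separately."""
    n = binning.n_bins
    counts = np.zeros((n, 4), dtype=np.int64)
    n_skipped = 0
    for read in reads:
        codes = _BASE_INDEX[np.frombuffer(read.sequence.encode("ascii"), dtype=np.uint8)]
        d = binning.assign_index(_qualities_array(read))
        valid = codes >= 0
        n_skipped += int((~valid).sum())
        np.add.at(counts, (d[valid], codes[valid]), 1)
    if counts.sum() == 0:
        raise ValueError("all bases are N; emission matrix undefined")
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        probs = np.where(row_sums > 0, counts / np.maximum(row_sums, 1), 0.0)
    return EmissionMatrix(counts=counts, probs=probs, binning=binning, n_skipped=n_skipped)


def per_base_mean_q(
    reads: Sequence[ReadRecord],
) -> Mapping[str, Mapping[str, tuple[float, int]]]:
    """Arithmetic mean Q per called base, per read class and pooled.

    Returns ``{class_or_'all': {base: (mean_q, count)}}``; bases with no
    observations are absent from the inner mapping.
    """
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    for read in reads:
        cls = read.read_class.value
        if cls not in sums:
            sums[cls] = np.zeros(4)
            counts[cls] = np.zeros(4, dtype=np.int64)
        codes = _BASE_INDEX[np.frombuffer(read.sequence.encode("ascii"), dtype=np.uint8)]
        q = _qualities_array(read)
        valid = codes >= 0
        np.add.at(sums[cls], codes[valid], q[valid])
        np.add.at(counts[cls], codes[valid], 1)
    if not sums:
        raise ValueError("no reads supplied")
    out: dict[str, dict[str, tuple[float, int]]] = {}
    all_sums = np.zeros(4)
    all_counts = np.zeros(4, dtype=np.int64)
    for cls in sums:
        all_sums += sums[cls]
        all_counts += counts[cls]
        out[cls] = {
            BASES[b]: (sums[cls][b] / counts[cls][b], int(counts[cls][b]))
            for b in range(4)
            if counts[cls][b] > 0
        }
    out["all"] = {
        BASES[b]: (all_sums[b] / all_counts[b], int(all_counts[b]))
        for b in range(4)
        if all_counts[b] > 0
    }
    return out
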