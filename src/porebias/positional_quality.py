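"""Q-score as a function of length-normalized position within reads.

Nanopore basecall quality dips at both ends of a molecule (adapter and
hairpin ends), more sharply for short reads, and the complement strand runs
systematically below the template.  To expose these effects, reads are
grouped into length deciles and the per-base Q-scores of each group are
averaged within bins of relative position (base k of a read of length L
falls into bin ``floor(n_bins * k / L)``).

Means are pooled over bases (every base of every read in the group carries
equal weight); a per-read variant (average the per-read bin means) is
available behind ``per_read=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import ReadClass, ReadRecord


@dataclass
class PositionalProfile:
    """Mean Q per relative-position bin for one read group.

    ``mean_q[b]`` is NaN wherever ``n_obs[b] == 0`` (short reads skip bins).
    """

    mean_q: np.ndarray
    n_obs: np.ndarray
    n_position_bins: int
    read_class: ReadClass | None = None
    length_decile: int | None = None  # 1-based
    length_range: tuple[int, int] | None = None
    n_reads: int = 0


def length_decile_groups(
    reads: Sequence[ReadRecord],
    n_groups: int = 10,
    degenerate: str = "error",
) -> list[tuple[tuple[int, int], list[ReadRecord]]]:
    """Split reads into length deciles at nearest-rank quantile edges.

    Groups are right-closed in length, so reads of identical length always
    share a group and occupancies are equal only up to ties.  All reads of a
    single length raise an error by default (``degenerate="single_group"``
    returns one group instead).
    """
    if len(reads) < n_groups:
        raise ValueError(f"need at least {n_groups} reads to form {n_groups} groups")
    lengths = np.array([len(r) for r in reads])
    if lengths.min() == lengths.max():
        if degenerate == "single_group":
            lo, hi = int(lengths.min()), int(lengths.max())
            return [((lo, hi), list(reads))]
        raise ValueError("all reads have the same length; no decile split exists")
    edges = np.quantile(lengths, np.arange(1, n_groups) / n_groups, method="inverted_cdf")
    group_idx = np.searchsorted(edges, lengths, side="left")
    groups: list[tuple[tuple[int, int], list[ReadRecord]]] = []
    for g in range(n_groups):
        members = [r for r, gi in zip(reads, group_idx) if gi == g]
        if not members:
            continue
        glens = [len(r) for r in members]
        groups.append(((min(glens), max(glens)), members))
    return groups


def positional_profile(
    reads: Sequence[ReadRecord],
    n_position_bins: int = 100,
    per_read: bool = False,
) -> PositionalProfile:
    """Mean Q-score per relative-position bin, pooled over all given reads."""
    if n_position_bins < 2:
        raise ValueError("n_position_bins must be >= 2")
    if len(reads) == 0:
        raise ValueError("no reads supplied")
    if per_read:
        sums = np.zeros(n_position_bins)
        counts = np.zeros(n_position_bins, dtype=np.int64)
        for read in reads:
            bins = (n_position_bins * np.arange(len(read))) // len(read)
            q = np.asarray(read.qualities, dtype=float)
            rsum = np.bincount(bins, weights=q, minlength=n_position_bins)
            rcnt = np.bincount(bins, minlength=n_position_bins)
            seen = rcnt > 0
            sums[seen] += rsum[seen] / rcnt[seen]
            counts[seen] += 1
    else:
        sums = np.zeros(n_position_bins)
        counts = np.zeros(n_position_bins, dtype=np.int64)
        for read in reads:
            bins = (n_position_bins * np.arange(len(read))) // len(read)
            q = np.asarray(read.qualities, dtype=float)
            sums += np.bincount(bins, weights=q, minlength=n_position_bins)
            counts += np.bincount(bins, minlength=n_position_bins)
    with np.errstate(invalid="ignore"):
        mean_q = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return PositionalProfile(
        mean_q=mean_q, n_obs=counts, n_position_bins=n_position_bins, n_reads=len(reads)
    )


def profile_matrix(
    reads: Sequence[ReadRecord],
    n_position_bins: int = 100,
    n_length_deciles: int = 10,
    per_read: bool = False,
) -> list[PositionalProfile]:
    """Positional profiles for every (read class present) x (length decile).

    Length deciles are computed within each read class.  Classes with no
    reads are absent from the output, not zero-filled; a class with too few
    reads or tied lengths for a decile split contributes a single profile
    spanning all its reads (length_decile=None).
    """
    out: list[PositionalProfile] = []
    for cls in ReadClass:
        members = [r for r in reads if r.read_class is cls]
        if not members:
            continue
        try:
            groups = length_decile_groups(members, n_groups=n_length_deciles)
        except ValueError:
            prof = positional_profile(members, n_position_bins, per_read)
            prof.read_class = cls
            lens = [len(r) for r in members]
            prof.length_range = (min(lens), max(lens))
            out.append(prof)
            continue
        for decile, (length_range, group) in enumerate(groups, start=1):
            prof = positional_profile(group, n_position_bins, per_read)
            prof.read_class = cls
            prof.length_decile = decile
            prof.length_range = length_range
            out.append(prof)
    return out


def profiles_to_frame(profiles: Sequence[PositionalProfile]):
    """Long-format table: class, length_decile, bin, mean_q, n_obs."""
    import pandas as pd

    rows = []
    for prof in profiles:
        for b in range(prof.n_position_bins):
            rows.append(
                {
                    "read_class": prof.read_class.value if prof.read_class else "all",
                    "length_decile": prof.length_decile,
                    "length_min": prof.length_range[0] if prof.length_range else None,
                    "length_max": prof.length_range[1] if prof.length_range else None,
                    "bin": b,
                    "mean_q": prof.mean_q[b],
                    "n_obs": int(prof.n_obs[b]),
                }
            )
    return pd.DataFrame(rows)
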