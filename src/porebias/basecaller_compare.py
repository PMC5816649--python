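"""Compare two basecalls of the same sequencing run, read by read.

When one run's raw signal is basecalled by two different algorithms, the
resulting FASTQ sets share read ids (up to tool-specific decoration).  This
module inner-joins the two sets on read id and compares per-read lengths,
mean Q-scores, and read-versus-read sequence identity computed by banded
global (Needleman-Wunsch) alignment with unit scores.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io_formats import ReadRecord
from .read_metrics import mean_read_qscore

_NEG = np.int64(-(10**15))
_PTR_DIAG, _PTR_UP, _PTR_LEFT = 0, 1, 2


@dataclass
class ReadPair:
    """One read basecalled twice: lengths, mean Q, and optional identity."""

    read_id: str
    length_a: int
    length_b: int
    mean_q_a: float
    mean_q_b: float
    pair_identity: float | None = None


def pair_reads(
    set_a: Sequence[ReadRecord],
    set_b: Sequence[ReadRecord],
    id_normalizer: str | Callable[[str], str] | None = None,
) -> tuple[list[ReadPair], list[str], list[str]]:
    """Inner-join two read sets on (normalized) read id.

    ``id_normalizer`` may be a regex whose matches are stripped from ids, or
    a callable.  Duplicate ids within one set are a hard error.  Returns the
    pairs plus the unmatched ids from each side.
    """
    if id_normalizer is None:
        norm = lambda s: s  # noqa: E731
    elif callable(id_normalizer):
        norm = id_normalizer
    else:
        pattern = re.compile(id_normalizer)
        norm = lambda s: pattern.sub("", s)  # noqa: E731

    def index(records: Sequence[ReadRecord], label: str) -> dict[str, ReadRecord]:
        out: dict[str, ReadRecord] = {}
        dupes = []
        for rec in records:
            key = norm(rec.qualified_id)
            if key in out:
                dupes.append(key)
            out[key] = rec
        if dupes:
            raise ValueError(f"duplicate read ids in set {label}: {sorted(set(dupes))}")
        return out

    by_a = index(set_a, "a")
    by_b = index(set_b, "b")
    pairs = []
    for key in by_a:
        if key in by_b:
            ra, rb = by_a[key], by_b[key]
            pairs.append(
                ReadPair(
                    read_id=key,
                    length_a=len(ra),
                    length_b=len(rb),
                    mean_q_a=mean_read_qscore(ra.qualities, "error_prob"),
                    mean_q_b=mean_read_qscore(rb.qualities, "error_prob"),
                )
            )
    unmatched_a = sorted(k for k in by_a if k not in by_b)
    unmatched_b = sorted(k for k in by_b if k not in by_a)
    return pairs, unmatched_a, unmatched_b


def pairwise_identity(seq_a: str, seq_b: str, band: int = 100) -> float:
    """Percent identity from banded global alignment with unit scores.

    Scores: match +1, mismatch -1, gap -1.  The effective band half-width is
    ``band + |len_a - len_b|``, so the band always contains the main
    diagonal corridor; the result is the exact unbanded optimum whenever
    ``band >= max(len_a, len_b)``.  Identity is 100 * matched columns /
    total alignment columns of the optimal-score alignment (ties broken
    diagonal > up > left).
    """
    la, lb = len(seq_a), len(seq_b)
    if la == 0 or lb == 0:
        raise ValueError("sequences must be non-empty")
    band = max(int(band), 0)
    w = band + abs(la - lb)
    w = min(w, max(la, lb))
    a = np.frombuffer(seq_a.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(seq_b.encode("ascii"), dtype=np.uint8)

    width = 2 * w + 2  # +1 slack so the "up" lookup at c+1 stays in range
    score = np.full((la + 1, width), _NEG, dtype=np.int64)
    ptr = np.full((la + 1, width), 3, dtype=np.uint8)

    # row 0: offset o_0 = -w, so column j sits at storage cell j + w
    j_hi0 = min(lb, w)
    score[0, w : w + j_hi0 + 1] = -np.arange(j_hi0 + 1)
    ptr[0, w : w + j_hi0 + 1] = _PTR_LEFT

    for i in range(1, la + 1):
        o = i - w  # reference j of storage cell 0 in this row
        j_lo, j_hi = max(0, o), min(lb, i + w)
        if j_lo > j_hi:
            continue
        j = np.arange(max(1, j_lo), j_hi + 1)
        c = j - o
        prev = score[i - 1]
        match = np.where(a[i - 1] == b[j - 1], 1, -1)
        # previous row's storage offset is one less, so (i-1, j-1) sits at
        # prev[c] and (i-1, j) at prev[c+1]
        diag = prev[c] + match
        up = prev[c + 1] - 1
        best = np.maximum(diag, up)
        bptr = np.where(diag >= up, _PTR_DIAG, _PTR_UP).astype(np.uint8)
        # left moves within the row form a suffix chain: resolve with a
        # running max of (best + j), which equals max over j' <= j of
        # best[j'] - (j - j')
        if j_lo == 0:
            s0 = -i  # gap-only prefix in column 0
            score[i, -o] = s0
            ptr[i, -o] = _PTR_UP
            run = np.maximum.accumulate(np.concatenate(([s0 + 0], best + j)))[1:]
        else:
            run = np.maximum.accumulate(best + j)
        cur = np.maximum(best, run - j)
        cptr = np.where(cur == best, bptr, _PTR_LEFT).astype(np.uint8)
        score[i, c] = cur
        ptr[i, c] = cptr

    # traceback from (la, lb)
    i, j = la, lb
    matches = 0
    columns = 0
    while i > 0 or j > 0:
        if i == 0:
            step = _PTR_LEFT
        elif j == 0:
            step = _PTR_UP
        else:
            step = ptr[i, j - (i - w)]
        columns += 1
        if step == _PTR_DIAG:
            if a[i - 1] == b[j - 1]:
                matches += 1
            i -= 1
            j -= 1
        elif step == _PTR_UP:
            i -= 1
        elif step == _PTR_LEFT:
            j -= 1
        else:  # pragma: no cover - traceback left the band
            raise RuntimeError("traceback escaped the alignment band")
    return 100.0 * matches / columns


def compute_pair_identities(
    pairs: Sequence[ReadPair],
    set_a: Sequence[ReadRecord],
    set_b: Sequence[ReadRecord],
    band: int = 100,
    id_normalizer: str | Callable[[str], str] | None = None,
) -> None:
    """Fill ``pair_identity`` for each pair in place."""
    if id_normalizer is None:
        norm = lambda s: s  # noqa: E731
    elif callable(id_normalizer):
        norm = id_normalizer
    else:
        pattern = re.compile(id_normalizer)
        norm = lambda s: pattern.sub("", s)  # noqa: E731
    by_a = {norm(r.qualified_id): r for r in set_a}
    by_b = {norm(r.qualified_id): r for r in set_b}
    for pair in pairs:
        ra, rb = by_a[pair.read_id], by_b[pair.read_id]
        pair.pair_identity = pairwise_identity(ra.sequence, rb.sequence, band=band)


def compare_summary(
    pairs: Sequence[ReadPair],
    set_a: Sequence[ReadRecord] | None = None,
    set_b: Sequence[ReadRecord] | None = None,
    identity_bin_width: float = 1.0,
) -> dict:
    """Aggregate comparison report over paired reads.

    Returns a dict with the per-pair table, median length difference (b-a),
    median mean-Q difference (b-a), an identity histogram, and — when the
    read sets are supplied — per-base Q-score summaries for each set.
    """
    if len(pairs) == 0:
        raise ValueError("no pairs to summarize")
    table = pd.DataFrame(
        {
            "read_id": [p.read_id for p in pairs],
            "length_a": [p.length_a for p in pairs],
            "length_b": [p.length_b for p in pairs],
            "mean_q_a": [p.mean_q_a for p in pairs],
            "mean_q_b": [p.mean_q_b for p in pairs],
            "pair_identity": [p.pair_identity for p in pairs],
        }
    )
    report: dict = {
        "pairs": table,
        "n_pairs": len(pairs),
        "median_length_diff": float((table.length_b - table.length_a).median()),
        "median_length_ratio": float((table.length_b / table.length_a).median()),
        "median_mean_q_diff": float((table.mean_q_b - table.mean_q_a).median()),
    }
    identities = table.pair_identity.dropna()
    if len(identities):
        edges = np.arange(0.0, 100.0 + identity_bin_width, identity_bin_width)
        counts, _ = np.histogram(identities, bins=edges)
        report["identity_histogram"] = pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
        )
        report["median_identity"] = float(identities.median())
    if set_a is not None and set_b is not None:
        from .qscore_structure import per_base_mean_q

        report["per_base_q_a"] = per_base_mean_q(list(set_a))
        report["per_base_q_b"] = per_base_mean_q(list(set_b))
    return report
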