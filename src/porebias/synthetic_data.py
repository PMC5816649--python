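"""Synthetic nanopore-like reads with known, recoverable statistical structure.

The generator produces a random reference genome and simulated basecalled
reads (FASTQ plus a ground-truth SAM) that embody the statistical features
seen in real MinION runs, each controlled by an explicit parameter so every
analysis stage of this package can be validated by parameter recovery:

* read lengths: truncated log-normal spanning ~100 bp to 100 kb with a
  mode in the 1-2 kb range;
* per-base Q-scores: a first-order Markov chain over a grid of Q levels
  (heavily diagonal transition matrix), reproducing the autocorrelation of
  real per-base scores;
* base-specific quality bias: additive per-base Q offsets (default A/G low,
  T/C high);
* positional effects: a quality dip over both read ends, a penalty for very
  short reads, and a global offset for complement strands;
* alignment errors: i.i.d. substitution/insertion/deletion channel with the
  true placement and CIGAR recorded in a truth SAM;
* k-mer bias: a spike map multiplying local substitution odds where the
  true sequence matches a spiked k-mer, plus a table-level multinomial
  spiker for exact fold-change recovery.

Q-scores are generated independently of the planted alignment errors by
default (quality is a basecaller artifact and is analysed separately from
identity); ``couple_errors_to_q=True`` draws substitutions preferentially at
low-Q positions instead.

Identical configurations produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import (
    AlignmentRecord,
    ReadClass,
    ReadRecord,
    SequenceRecord,
    write_fasta,
    write_fastq,
    write_json,
    write_sam,
)
from .kmer_bias import KmerTable, kmer_strings

BASES = "ACGT"
_BASES_U8 = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_INDEX[ord(_b)] = _i

Q_MAX = 40


def default_transition_matrix(n_bins: int = 10, decay: float = 1.2) -> np.ndarray:
    """Sticky level-transition matrix: P(i -> j) ~ exp(-|i-j|/decay).

    The symmetric kernel is Sinkhorn-balanced into a doubly stochastic
    matrix, so the stationary distribution is uniform over levels and
    empirical decile bins line up with the levels.
    """
    idx = np.arange(n_bins)
    m = np.exp(-np.abs(idx[:, None] - idx[None, :]) / decay)
    for _ in range(10_000):
        m = m / m.sum(axis=1, keepdims=True)
        m = m / m.sum(axis=0, keepdims=True)
        if np.abs(m.sum(axis=1) - 1).max() < 1e-13:
            break
    return m / m.sum(axis=1, keepdims=True)


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(transition.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    v = np.abs(np.real(vecs[:, i]))
    return v / v.sum()


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults emulate a 2D MinION run.

    Rates are per reference base; Q values are Phred units.  The Q-level
    grid carries the Markov chain; per-base offsets, end dips, short-read
    and complement penalties are added afterwards and the result is clamped
    to [0, 40].
    """

    seed: int = 0
    genome_length: int = 1_000_000
    genome_gc: float = 0.5
    n_reads: int = 2000  # molecules; a 2D molecule emits 3 reads
    length_median: float = 1500.0
    length_sigma: float = 0.55
    length_min: int = 100
    length_max: int = 100_000
    q_levels: np.ndarray = field(default_factory=lambda: np.arange(2.0, 21.0, 2.0))
    q_transition_matrix: np.ndarray = field(default_factory=default_transition_matrix)
    base_q_offsets: dict = field(
        default_factory=lambda: {"A": -2.0, "G": -2.0, "C": 2.0, "T": 2.0}
    )
    end_dip_fraction: float = 0.02
    end_dip_delta: float = 3.0
    complement_q_offset: float = -1.0
    short_read_cutoff: int = 200
    short_read_penalty: float = 4.0
    substitution_rate: float = 0.06
    insertion_rate: float = 0.03
    deletion_rate: float = 0.05
    kmer_bias_spikes: dict = field(default_factory=dict)
    spike_k: int = 5
    fraction_2d: float = 0.5
    consensus_q_boost: float = 4.0
    consensus_error_factor: float = 0.25
    couple_errors_to_q: bool = False

    def __post_init__(self) -> None:
        self.q_levels = np.asarray(self.q_levels, dtype=float)
        self.q_transition_matrix = np.asarray(self.q_transition_matrix, dtype=float)
        t = self.q_transition_matrix
        if t.shape != (len(self.q_levels), len(self.q_levels)):
            raise ValueError("q_transition_matrix shape must match q_levels")
        if not np.allclose(t.sum(axis=1), 1.0, atol=1e-9) or np.any(t < 0):
            raise ValueError("q_transition_matrix rows must be non-negative and sum to 1")
        for rate in (self.substitution_rate, self.insertion_rate, self.deletion_rate):
            if not (0 <= rate < 1):
                raise ValueError("error rates must lie in [0, 1)")
        if self.substitution_rate + self.deletion_rate >= 1:
            raise ValueError("substitution_rate + deletion_rate must be < 1")
        if not (0 < self.genome_gc < 1):
            raise ValueError("genome_gc must lie in the open interval (0, 1)")
        if not (0 <= self.fraction_2d <= 1):
            raise ValueError("fraction_2d must lie in [0, 1]")
        for kmer in self.kmer_bias_spikes:
            if len(kmer) != self.spike_k or set(kmer) - set(BASES):
                raise ValueError(f"spiked k-mer {kmer!r} must be a {self.spike_k}-mer over ACGT")

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["q_levels"] = self.q_levels.tolist()
        d["q_transition_matrix"] = self.q_transition_matrix.tolist()
        return d


@dataclass
class TruthRecord:
    """Ground truth for one simulated read (0-based half-open interval)."""

    read_id: str
    ref_name: str
    ref_interval: tuple[int, int]
    strand: str
    cigar: list[tuple[str, int]]
    n_sub: int
    n_ins: int
    n_del: int


@dataclass
class SimulatedDataset:
    """Reads plus matching truth alignments and the generating manifest."""

    reference: SequenceRecord
    reads: list[ReadRecord]
    alignments: list[AlignmentRecord]
    truth: list[TruthRecord]
    manifest: dict

    def write(self, out_prefix: str | Path) -> dict[str, Path]:
        """Write reference FASTA, reads FASTQ, truth SAM, and manifest JSON."""
        prefix = Path(out_prefix)
        paths = {
            "fasta": prefix.parent / (prefix.name + "reference.fasta"),
            "fastq": prefix.parent / (prefix.name + "reads.fastq"),
            "sam": prefix.parent / (prefix.name + "truth.sam"),
            "json": prefix.parent / (prefix.name + "manifest.json"),
        }
        write_fasta([self.reference], paths["fasta"])
        write_fastq(self.reads, paths["fastq"])
        write_sam(zip(self.reads, self.alignments), [self.reference], paths["sam"])
        write_json(self.manifest, paths["json"])
        return paths


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------

def generate_reference(
    length: int, gc: float, seed: int, name: str = "simref"
) -> SequenceRecord:
    """I.i.d. random genome with P(G) = P(C) = gc/2."""
    if not (0 < gc < 1):
        raise ValueError("gc must lie in the open interval (0, 1)")
    if length < 1000:
        raise ValueError("reference length must be >= 1000")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=probs)
    return SequenceRecord(id=name, sequence=_BASES_U8[codes].tobytes().decode("ascii"))


# ---------------------------------------------------------------------------
# Markov chain sampling
# ---------------------------------------------------------------------------

def sample_markov_chains(
    lengths: Sequence[int],
    transition: np.ndarray,
    rng: np.random.Generator,
    init: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Sample one state chain per requested length.

    Chains start from ``init`` (default: the stationary distribution) and
    are advanced column-wise across all still-active chains, so runtime is
    O(total bases) with vectorized steps.
    """
    lengths = np.asarray(lengths, dtype=np.int64)
    n = len(lengths)
    if n == 0:
        return []
    if init is None:
        init = stationary_distribution(transition)
    n_states = transition.shape[0]
    cum_t = np.cumsum(transition, axis=1)
    cum_0 = np.cumsum(init)
    offsets = np.concatenate(([0], np.cumsum(lengths)))
    flat = np.empty(int(lengths.sum()), dtype=np.int8)
    order = np.argsort(-lengths, kind="stable")
    sorted_len = lengths[order]
    off_sorted = offsets[:-1][order]
    neg_sorted = -sorted_len

    u0 = rng.random(n)
    state = np.minimum((cum_0 < u0[:, None]).sum(axis=1), n_states - 1).astype(np.int8)
    flat[off_sorted] = state
    t = 1
    k = int(np.searchsorted(neg_sorted, -t, side="left"))
    while k > 0:
        u = rng.random(k)
        nxt = (cum_t[state[:k]] < u[:, None]).sum(axis=1)
        state[:k] = np.minimum(nxt, n_states - 1)
        flat[off_sorted[:k] + t] = state[:k]
        t += 1
        k = int(np.searchsorted(neg_sorted, -t, side="left"))
    return [flat[offsets[i] : offsets[i + 1]] for i in range(n)]


# ---------------------------------------------------------------------------
# Error channel
# ---------------------------------------------------------------------------

def _spiked_sub_probs(
    seg: np.ndarray, base_rate: float, spikes: dict, k: int
) -> np.ndarray:
    """Per-position substitution probability with spiked-k-mer odds scaling.

    A position's k-mer is the window starting at that position; positions
    whose window matches a spiked key get their substitution odds multiplied
    by the configured fold change.
    """
    sub_p = np.full(len(seg), base_rate)
    if not spikes or len(seg) < k:
        return sub_p
    n_win = len(seg) - k + 1
    w = np.zeros(n_win, dtype=np.int64)
    for j in range(k):
        w = w * 4 + seg[j : j + n_win].astype(np.int64)
    index = {kmer: i for i, kmer in enumerate(kmer_strings(k))}
    for kmer, fold in spikes.items():
        hit = np.flatnonzero(w == index[kmer])
        odds = base_rate / (1 - base_rate) * fold
        sub_p[hit] = odds / (1 + odds)
    return sub_p


def _apply_error_channel(
    seg: np.ndarray,
    rng: np.random.Generator,
    sub_p: np.ndarray,
    ins_rate: float,
    del_rate: float,
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int]], int, int, int]:
    """Plant substitutions, single-base insertions, and deletions.

    Returns (read codes, kept-position index map for Q coupling, CIGAR in
    read orientation, n_sub, n_ins, n_del).  The CIGAR uses M for both match
    and mismatch columns.
    """
    n = len(seg)
    u = rng.random(n)
    del_mask = u < del_rate
    sub_mask = (~del_mask) & (u < del_rate + sub_p)
    ins_mask = rng.random(n) < ins_rate

    keep = ~del_mask
    bases = seg.copy()
    n_sub = int(sub_mask.sum())
    if n_sub:
        bases[sub_mask] = (bases[sub_mask] + rng.integers(1, 4, n_sub)) % 4
    contrib = keep.astype(np.int64) + ins_mask.astype(np.int64)
    total = int(contrib.sum())
    if total == 0:  # pathological: everything deleted; keep one base
        return seg[:1].copy(), np.array([0]), [("M", 1)], 0, 0, 0
    starts = np.concatenate(([0], np.cumsum(contrib)[:-1]))
    read = np.empty(total, dtype=np.int8)
    src = np.empty(total, dtype=np.int64)  # originating segment position
    read[starts[keep]] = bases[keep]
    src[starts[keep]] = np.flatnonzero(keep)
    ins_pos = starts + keep.astype(np.int64)
    n_ins = int(ins_mask.sum())
    if n_ins:
        read[ins_pos[ins_mask]] = rng.integers(0, 4, n_ins)
        src[ins_pos[ins_mask]] = np.flatnonzero(ins_mask)
    n_del = int(del_mask.sum())

    # op stream: per segment position an M or D, then an optional I
    cum_ins = np.concatenate(([0], np.cumsum(ins_mask)[:-1]))
    idx = np.arange(n) + cum_ins
    stream = np.empty(n + n_ins, dtype=np.int8)
    stream[idx] = np.where(del_mask, 2, 0)
    if n_ins:
        stream[idx[ins_mask] + 1] = 1
    change = np.flatnonzero(np.diff(stream))
    bounds = np.concatenate(([0], change + 1, [len(stream)]))
    cigar = [
        ("MID"[stream[b]], int(e - b)) for b, e in zip(bounds[:-1], bounds[1:])
    ]
    return read, src, cigar, n_sub, n_ins, n_del


def _trim_boundary_deletions(
    cigar: list[tuple[str, int]], ref_start: int, nm: int, n_del: int
) -> tuple[list[tuple[str, int]], int, int, int]:
    """Drop D ops at the alignment boundaries (not part of any alignment)."""
    cigar = list(cigar)
    while cigar and cigar[0][0] == "D":
        n = cigar.pop(0)[1]
        ref_start += n
        nm -= n
        n_del -= n
    while cigar and cigar[-1][0] == "D":
        n = cigar.pop()[1]
        nm -= n
        n_del -= n
    return cigar, ref_start, nm, n_del


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _sample_lengths(rng: np.random.Generator, config: SimulationConfig, n: int) -> np.ndarray:
    """Truncated log-normal read lengths (median/sigma parameterization)."""
    hi = min(config.length_max, config.genome_length)
    out = np.empty(n, dtype=np.int64)
    filled = 0
    for _ in range(1000):
        draw = rng.lognormal(np.log(config.length_median), config.length_sigma, n - filled)
        ok = draw[(draw >= config.length_min) & (draw <= hi)]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take].astype(np.int64)
        filled += take
        if filled == n:
            return out
    raise RuntimeError("could not sample read lengths within the configured bounds")


def simulate_reads(config: SimulationConfig, reference: SequenceRecord) -> SimulatedDataset:
    """Simulate a full dataset of reads with truth alignments.

    Each molecule gets a length, start, and strand; with probability
    ``fraction_2d`` it emits template, complement, and 2D-consensus reads
    (the consensus with errors scaled by ``consensus_error_factor`` and Q
    raised by ``consensus_q_boost``), otherwise a single 1D read.
    """
    rng = np.random.default_rng(config.seed)
    ref_codes = _BASE_INDEX[
        np.frombuffer(reference.sequence.encode("ascii"), dtype=np.uint8)
    ].astype(np.int8)
    if np.any(ref_codes < 0):
        raise ValueError("reference must be over ACGT for simulation")
    glen = len(ref_codes)
    n_mol = config.n_reads
    lengths = _sample_lengths(rng, config, n_mol)
    starts = rng.integers(0, glen - lengths + 1)
    strands = np.where(rng.random(n_mol) < 0.5, "+", "-")
    is_2d = rng.random(n_mol) < config.fraction_2d

    offsets_lut = np.array([config.base_q_offsets.get(b, 0.0) for b in BASES])
    specs = []  # (read_id, class, strand, mol_index, error_factor)
    for i in range(n_mol):
        rid = f"read{i:06d}"
        if is_2d[i]:
            flip = {"+": "-", "-": "+"}[strands[i]]
            specs.append((rid, ReadClass.TEMPLATE, strands[i], i, 1.0))
            specs.append((rid, ReadClass.COMPLEMENT, flip, i, 1.0))
            specs.append((rid, ReadClass.CONSENSUS_2D, strands[i], i, config.consensus_error_factor))
        else:
            specs.append((rid, ReadClass.RAW_1D, strands[i], i, 1.0))

    staged = []  # per read: codes, states (if coupled), truth pieces
    for rid, cls, strand, i, err_factor in specs:
        start, length = int(starts[i]), int(lengths[i])
        seg = ref_codes[start : start + length]
        if strand == "-":
            seg = (3 - seg[::-1]).astype(np.int8)
        sub_p = _spiked_sub_probs(
            seg, config.substitution_rate * err_factor, config.kmer_bias_spikes, config.spike_k
        )
        seg_states = None
        if config.couple_errors_to_q:
            # draw the quality chain over the segment first and tilt the
            # substitution probabilities toward low-Q positions
            seg_states = sample_markov_chains([length], config.q_transition_matrix, rng)[0]
            weight = 10.0 ** (-config.q_levels[seg_states] / 10.0)
            sub_p = np.clip(sub_p * weight / weight.mean(), 0.0, 0.9)
        read_codes, src, cigar_read, n_sub, n_ins, n_del = _apply_error_channel(
            seg, rng, sub_p, config.insertion_rate * err_factor, config.deletion_rate * err_factor
        )
        cigar_ref = cigar_read[::-1] if strand == "-" else cigar_read
        nm = n_sub + n_ins + n_del
        cigar_ref, ref_start, nm, n_del = _trim_boundary_deletions(
            cigar_ref, start, nm, n_del
        )
        ref_span = sum(n for op, n in cigar_ref if op in "MD")
        read_states = seg_states[src] if seg_states is not None else None
        staged.append(
            (rid, cls, strand, read_codes, read_states, cigar_ref, ref_start, ref_span, nm, n_sub, n_ins, n_del)
        )

    # Q-score chains for every read, batched for speed (uncoupled mode)
    if config.couple_errors_to_q:
        chains = [s[4] for s in staged]
    else:
        read_lengths = [len(s[3]) for s in staged]
        chains = sample_markov_chains(read_lengths, config.q_transition_matrix, rng)

    reads: list[ReadRecord] = []
    alignments: list[AlignmentRecord] = []
    truth: list[TruthRecord] = []
    for (rid, cls, strand, codes, _states, cigar_ref, ref_start, ref_span, nm, n_sub, n_ins, n_del), states in zip(
        staged, chains
    ):
        length = len(codes)
        q = config.q_levels[states] + offsets_lut[codes.astype(np.int64)]
        edge = np.arange(length) < config.end_dip_fraction * length
        edge |= np.arange(length) >= length - config.end_dip_fraction * length
        q = q - np.where(edge, config.end_dip_delta, 0.0)
        if length <= config.short_read_cutoff:
            q = q - config.short_read_penalty
        if cls is ReadClass.COMPLEMENT:
            q = q + config.complement_q_offset
        elif cls is ReadClass.CONSENSUS_2D:
            q = q + config.consensus_q_boost
        q = np.clip(np.rint(q), 0, Q_MAX).astype(int)
        read = ReadRecord(
            id=rid,
            read_class=cls,
            sequence=_BASES_U8[codes.astype(np.int64)].tobytes().decode("ascii"),
            qualities=q.tolist(),
        )
        aln = AlignmentRecord(
            read_id=read.qualified_id,
            cigar=cigar_ref,
            nm=nm,
            ref_name=reference.id,
            ref_start=ref_start,
            strand=strand,
            is_mapped=True,
        )
        reads.append(read)
        alignments.append(aln)
        truth.append(
            TruthRecord(
                read_id=read.qualified_id,
                ref_name=reference.id,
                ref_interval=(ref_start, ref_start + ref_span),
                strand=strand,
                cigar=cigar_ref,
                n_sub=n_sub,
                n_ins=n_ins,
                n_del=n_del,
            )
        )

    manifest = {
        "config": config.to_manifest(),
        "reference_id": reference.id,
        "reference_length": glen,
        "n_molecules": n_mol,
        "n_reads": len(reads),
        "planted_totals": {
            "substitutions": int(sum(t.n_sub for t in truth)),
            "insertions": int(sum(t.n_ins for t in truth)),
            "deletions": int(sum(t.n_del for t in truth)),
        },
    }
    return SimulatedDataset(
        reference=reference, reads=reads, alignments=alignments, truth=truth, manifest=manifest
    )


def make_replicates(
    config: SimulationConfig, n_replicates: int
) -> tuple[SequenceRecord, list[SimulatedDataset]]:
    """Replicate runs of one genome: same configuration, seeds ``seed + i``.

    The reference is generated once from the base seed; replicate *i* uses
    seed ``seed + i`` (i = 1..n), making runs distinct but exchangeable.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    reference = generate_reference(config.genome_length, config.genome_gc, config.seed)
    datasets = [
        simulate_reads(dataclasses.replace(config, seed=config.seed + i), reference)
        for i in range(1, n_replicates + 1)
    ]
    return reference, datasets


# ---------------------------------------------------------------------------
# Table-level k-mer spiking
# ---------------------------------------------------------------------------

def simulate_read_kmer_tables(
    ref_table: KmerTable,
    n_kmers: int,
    n_replicates: int,
    spikes: dict | None = None,
    seed: int = 0,
) -> list[KmerTable]:
    """Multinomial k-mer tables resampled from a reference composition.

    Each replicate draws ``n_kmers`` k-mer observations from the reference
    frequencies, with spiked k-mers' probabilities multiplied by their fold
    change (then renormalized).  This is the exact generative null/spike
    model for the negative-binomial regression: no spike means the read
    tables differ from the reference by sampling noise only.
    """
    rng = np.random.default_rng(seed)
    p = ref_table.counts.astype(float)
    if p.sum() == 0:
        raise ValueError("reference table is empty")
    if spikes:
        index = {kmer: i for i, kmer in enumerate(kmer_strings(ref_table.k))}
        for kmer, fold in spikes.items():
            p[index[kmer]] *= fold
    p = p / p.sum()
    return [
        KmerTable(
            k=ref_table.k,
            counts=rng.multinomial(n_kmers, p),
            source_label=f"sim_replicate_{i + 1}",
        )
        for i in range(n_replicates)
    ]
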