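import numpy as np
import pytest

import porebias as pb


@pytest.fixture(scope="session")
def small_dataset():
    """A small noisy simulated run shared by read-level tests."""
    cfg = pb.SimulationConfig(
        seed=42,
        genome_length=30_000,
        n_reads=120,
        length_median=400,
        length_sigma=0.4,
        length_max=3000,
    )
    ref = pb.generate_reference(cfg.genome_length, cfg.genome_gc, cfg.seed)
    return pb.simulate_reads(cfg, ref)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def reconstruct_alignment_columns(read_seq, ref_seq, aln):
    """Brute-force column walk of an alignment: (matches, mismatches, columns).

    Independent oracle for CIGAR/NM-based percent identity: reconstructs the
    alignment base by base and compares characters directly.
    """
    from porebias.io_formats import reverse_complement

    q = reverse_complement(read_seq) if aln.strand == "-" else read_seq
    qi, ri = 0, aln.ref_start
    matches = mismatches = columns = 0
    for op, n in aln.cigar:
        if op in "M=X":
            for _ in range(n):
                if q[qi] == ref_seq[ri]:
                    matches += 1
                else:
                    mismatches += 1
                qi += 1
                ri += 1
                columns += 1
        elif op == "I":
            qi += n
            columns += n
        elif op in "DN":
            ri += n
            columns += n
        elif op == "S":
            qi += n
    return matches, mismatches, columns


def full_needleman_wunsch_identity(a, b):
    """Plain unbanded NW with unit scores, tie preference diag > up > left."""
    la, lb = len(a), len(b)
    S = [[0] * (lb + 1) for _ in range(la + 1)]
    P = [[0] * (lb + 1) for _ in range(la + 1)]
    for j in range(1, lb + 1):
        S[0][j] = -j
        P[0][j] = 2
    for i in range(1, la + 1):
        S[i][0] = -i
        P[i][0] = 1
    for i in range(1, la + 1):
        ai = a[i - 1]
        for j in range(1, lb + 1):
            d = S[i - 1][j - 1] + (1 if ai == b[j - 1] else -1)
            u = S[i - 1][j] - 1
            l = S[i][j - 1] - 1
            best = d if d >= u else u
            if l > best:
                best = l
                P[i][j] = 2
            else:
                P[i][j] = 0 if best == d else 1
            S[i][j] = best
    i, j = la, lb
    m = c = 0
    while i > 0 or j > 0:
        p = 2 if i == 0 else (1 if j == 0 else P[i][j])
        c += 1
        if p == 0:
            if a[i - 1] == b[j - 1]:
                m += 1
            i -= 1
            j -= 1
        elif p == 1:
            i -= 1
        else:
            j -= 1
    return 100.0 * m / c


def mutate_sequence(seq, rng, n_edits):
    """Random substitutions/insertions/deletions applied to a sequence."""
    out = list(seq)
    for _ in range(n_edits):
        op = rng.integers(0, 3)
        if op == 0 and out:
            p = int(rng.integers(0, len(out)))
            out[p] = "ACGT"[(("ACGT".index(out[p])) + int(rng.integers(1, 4))) % 4]
        elif op == 1:
            p = int(rng.integers(0, len(out) + 1))
            out.insert(p, "ACGT"[int(rng.integers(0, 4))])
        elif op == 2 and len(out) > 1:
            p = int(rng.integers(0, len(out)))
            out.pop(p)
    return "".join(out)


def random_sequence(rng, length):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
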