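"""Shared fixture builders and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np

from iskit.genome_io import CdsFeature, FlankWindow, TpaseCandidate
from iskit.is_catalog import revcomp

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
BASES = "ACGT"


def rand_dna(n: int, rng: np.random.Generator, gc: float = 0.6) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p).tolist())


def _break_pair(seq: list[str], idx: int, partner: str, rng: np.random.Generator) -> None:
    while seq[idx] == COMP[partner]:
        seq[idx] = BASES[int(rng.integers(4))]


def make_tir_window(
    tir: str,
    stub_len: int = 900,
    flank: int = 50,
    seed: int = 0,
) -> FlankWindow:
    """Window with a planted, guaranteed-maximal TIR arm pair.

    Layout: flank | TIR | stub ("ORF") | rc(TIR) | flank.  The three
    bases on each side of both arms are adjusted so no longer or
    equal-scoring competing arm pair can arise by chance extension.
    """
    rng = np.random.default_rng(seed)
    fl = list(rand_dna(flank, rng))
    stub = list(rand_dna(stub_len, rng))
    fr = list(rand_dna(flank, rng))
    for i in range(3):
        _break_pair(stub, i, stub[-1 - i], rng)          # inward extension
        _break_pair(fr, i, fl[-1 - i], rng)              # outward extension
    seq = "".join(fl) + tir + "".join(stub) + revcomp(tir) + "".join(fr)
    t0 = flank + len(tir) + 1
    cand = TpaseCandidate(
        CdsFeature("TPASE", t0, t0 + stub_len - 1, "+", "transposase"), "transposase"
    )
    return FlankWindow(
        genome_id="fixture",
        tpase=cand,
        window_span=(1, len(seq)),
        sequence=seq,
        tpase_offset=(t0, t0 + stub_len - 1),
    )


def make_event_fixture(
    elem: str,
    position: int,
    dr_seq: str,
    orientation: str,
    wt_len: int = 1000,
    seed: int = 0,
) -> tuple[str, str]:
    """(wt, mut) pair realising a characterised integration event.

    The element ``elem`` (canonical orientation, transposase on '+') is
    inserted after wild-type base ``position`` with target-site
    duplication ``dr_seq`` (written into the wild type just before the
    junction); ``orientation`` flips the element, not the junction.
    Host bases adjacent to the junction are adjusted so the call is
    unambiguous.
    """
    rng = np.random.default_rng(seed)
    k = len(dr_seq)
    wt = list(rand_dna(wt_len, rng))
    wt[position - k : position] = list(dr_seq)
    ins = elem if orientation == "forward" else revcomp(elem)
    # unambiguous junction: no chance extension of prefix, suffix or DR
    _break_pair_eq(wt, position, ins[0], rng)
    _break_pair_eq(wt, position - k - 1, ins[-1], rng)
    wt = "".join(wt)
    assert wt[position - k : position] == dr_seq
    mut = wt[:position] + ins + dr_seq + wt[position:]
    return wt, mut


def _break_pair_eq(seq: list[str], idx: int, avoid: str, rng: np.random.Generator) -> None:
    while seq[idx] == avoid:
        seq[idx] = BASES[int(rng.integers(4))]


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_tir(window: FlankWindow, min_arm=6, max_arm=40, max_mismatch=2,
                    orf_overlap=60, min_score=16):
    """Exhaustive enumeration of all (left start, right end, length) arm
    pairs with the same constraints and tie-breaks as the production search.

    Returns (arm_length, mismatches, left_start0, right_end0) or None.
    """
    seq = window.sequence.upper()
    L = len(seq)
    ts0 = window.tpase_offset[0] - 1
    te0 = window.tpase_offset[1] - 1
    i_max = min(ts0 + orf_overlap, L - 1)
    u_min = max(te0 - orf_overlap, 0)
    best = None
    best_key = None
    for i in range(0, i_max + 1):
        for u in range(max(u_min, i + 2 * min_arm - 1), L):
            hi = min(max_arm, (u - i + 1) // 2)
            mism = 0
            for a in range(1, hi + 1):
                if seq[i + a - 1] != COMP.get(seq[u - a + 1], "?"):
                    mism += 1
                if a < min_arm or mism > max_mismatch:
                    continue
                j = u - a + 1
                if j <= i + a - 1:
                    break
                if a - mism < min_score:
                    continue
                key = (-(a - mism), mism, u - i + 1, i)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (a, mism, i, u)
    return best


def gotoh_score(a: str, b: str, match=1.0, mismatch=0.0, gap_open=-2.0,
                gap_extend=-0.5) -> float:
    """Affine-gap global alignment score by the three-matrix recursion."""
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (vertical)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (horizontal)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend)
    return float(max(M[n, m], X[n, m], Y[n, m]))
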