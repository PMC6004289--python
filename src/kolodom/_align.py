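"""Internal pairwise and progressive alignment machinery.

The multiple-alignment engine is deliberately simple: a guide tree from
3-mer composition distances and profile Needleman-Wunsch merges.  It exists
so the pipeline is self-contained; any external aligner (e.g. mafft) can be
plugged in wherever an ``msa_engine`` callable is accepted — the engine
contract is just ``dict[name, seq] -> dict[name, aligned seq]``.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
_X = 20  # unknown residue
GAP = 21

NT_ALPHABET = "ACGT"
NT_INDEX = {a: i for i, a in enumerate(NT_ALPHABET)}


def _blosum62_array() -> np.ndarray:
    """BLOSUM62 over AA_ALPHABET + X, as float array."""
    mat = substitution_matrices.load("BLOSUM62")
    m = np.zeros((21, 21), dtype=np.float64)
    letters = AA_ALPHABET + "X"
    for i, a in enumerate(letters):
        for j, b in enumerate(letters):
            m[i, j] = mat[a][b]
    return m


BLOSUM62 = _blosum62_array()


def blosum62_score(a: str, b: str) -> float:
    """Single-residue BLOSUM62 score (X for anything outside the 20)."""
    return BLOSUM62[AA_INDEX.get(a, _X), AA_INDEX.get(b, _X)]


def encode_protein(seq: str) -> np.ndarray:
    return np.array([AA_INDEX.get(a, _X) for a in seq], dtype=np.int64)


def encode_nucleotide(seq: str) -> np.ndarray:
    return np.array([NT_INDEX.get(a, 4) for a in seq], dtype=np.int64)


def nt_score_matrix(match: float = 2.0, mismatch: float = -3.0) -> np.ndarray:
    """+2/-3 scoring with N (index 4) neutral-negative."""
    m = np.full((5, 5), mismatch)
    np.fill_diagonal(m, match)
    m[4, :] = m[:, 4] = -1.0
    m[4, 4] = -1.0
    return m


@njit(cache=True)
def _sw_affine(S, gap_open, gap_ext):  # pragma: no cover - numba
    """Local (Smith-Waterman) affine-gap DP on a precomputed score matrix.

    A gap of length k costs gap_open + k * gap_ext (BLAST convention).
    Returns (best score, qstart, qend, tstart, tend) half-open spans.
    """
    n, m = S.shape
    NEG = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(E[i, j - 1] - gap_ext, H[i, j - 1] - gap_open - gap_ext)
            F[i, j] = max(F[i - 1, j] - gap_ext, H[i - 1, j] - gap_open - gap_ext)
            h = H[i - 1, j - 1] + S[i - 1, j - 1]
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0.0:
                h = 0.0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback start by re-walking from (bi, bj)
    i, j = bi, bj
    state = 0  # 0=H
    while i > 0 and j > 0 and H[i, j] > 0.0:
        if state == 0:
            diag = H[i - 1, j - 1] + S[i - 1, j - 1]
            if H[i, j] == diag:
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            if E[i, j] == H[i, j - 1] - gap_open - gap_ext:
                state = 0
            j -= 1
        else:
            if F[i, j] == H[i - 1, j] - gap_open - gap_ext:
                state = 0
            i -= 1
    return best, i, bi, j, bj


@njit(cache=True)
def _nw_affine_trace(S, gap_open, gap_ext, free_ends=True):  # pragma: no cover
    """Global affine-gap DP with traceback.

    With ``free_ends`` (the default) terminal gaps are free on both
    sequences — the semi-global mode appropriate for aligning sequences
    whose 5'/3' extents differ, such as ORFs with excess N-terminal codons.
    Returns (score, path) where path is an (L, 2) array of aligned index
    pairs (-1 marks a gap on that side).
    """
    n, m = S.shape
    NEG = -1e18
    H = np.full((n + 1, m + 1), NEG)
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    H[0, 0] = 0.0
    for j in range(1, m + 1):
        E[0, j] = 0.0 if free_ends else -gap_open - gap_ext * j
        H[0, j] = E[0, j]
    for i in range(1, n + 1):
        F[i, 0] = 0.0 if free_ends else -gap_open - gap_ext * i
        H[i, 0] = F[i, 0]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            eo = 0.0 if (free_ends and i == n) else gap_open + gap_ext
            ee = 0.0 if (free_ends and i == n) else gap_ext
            E[i, j] = max(E[i, j - 1] - ee, H[i, j - 1] - eo)
            fo = 0.0 if (free_ends and j == m) else gap_open + gap_ext
            fe = 0.0 if (free_ends and j == m) else gap_ext
            F[i, j] = max(F[i - 1, j] - fe, H[i - 1, j] - fo)
            h = H[i - 1, j - 1] + S[i - 1, j - 1]
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            H[i, j] = h
    # traceback
    path = np.empty((n + m, 2), dtype=np.int64)
    k = n + m
    i, j = n, m
    state = 0
    if H[n, m] == E[n, m]:
        state = 1
    elif H[n, m] == F[n, m]:
        state = 2
    while i > 0 or j > 0:
        k -= 1
        if state == 0 and i > 0 and j > 0:
            path[k, 0] = i - 1
            path[k, 1] = j - 1
            i -= 1
            j -= 1
            if i > 0 or j > 0:
                if H[i, j] == E[i, j]:
                    state = 1
                elif H[i, j] == F[i, j]:
                    state = 2
        elif state == 1 or i == 0:
            path[k, 0] = -1
            path[k, 1] = j - 1
            eo = 0.0 if (free_ends and i == n) else gap_open + gap_ext
            if E[i, j] == H[i, j - 1] - eo or i == 0:
                state = 0
            j -= 1
            if j == 0 and i > 0:
                state = 2
        else:
            path[k, 0] = i - 1
            path[k, 1] = -1
            fo = 0.0 if (free_ends and j == m) else gap_open + gap_ext
            if F[i, j] == H[i - 1, j] - fo:
                state = 0
            i -= 1
            if i == 0 and j > 0:
                state = 1
        if state == 0 and (i == 0 or j == 0) and (i > 0 or j > 0):
            state = 1 if i == 0 else 2
    return H[n, m], path[k:]


def smith_waterman_protein(a: str, b: str, gap_open: float = 11.0,
                           gap_ext: float = 1.0):
    """Optimal local alignment score/spans of two proteins under BLOSUM62."""
    ea, eb = encode_protein(a), encode_protein(b)
    S = BLOSUM62[ea][:, eb]
    score, qs, qe, ts, te = _sw_affine(S, gap_open, gap_ext)
    return float(score), (int(qs), int(qe)), (int(ts), int(te))


def smith_waterman_nucleotide(a: str, b: str, match: float = 2.0,
                              mismatch: float = -3.0, gap_open: float = 5.0,
                              gap_ext: float = 2.0):
    ea, eb = encode_nucleotide(a), encode_nucleotide(b)
    S = nt_score_matrix(match, mismatch)[ea][:, eb]
    score, qs, qe, ts, te = _sw_affine(S, gap_open, gap_ext)
    return float(score), (int(qs), int(qe)), (int(ts), int(te))


def global_protein_alignment(a: str, b: str, gap_open: float = 11.0,
                             gap_ext: float = 1.0) -> tuple[str, str]:
    """Needleman-Wunsch protein alignment returning gapped strings."""
    ea, eb = encode_protein(a), encode_protein(b)
    S = BLOSUM62[ea][:, eb]
    _, path = _nw_affine_trace(S, gap_open, gap_ext)
    out_a, out_b = [], []
    for i, j in path:
        out_a.append(a[i] if i >= 0 else "-")
        out_b.append(b[j] if j >= 0 else "-")
    return "".join(out_a), "".join(out_b)


# ---------------------------------------------------------------------------
# Progressive MSA

def _profile(seqs: list[str]) -> np.ndarray:
    """Column frequency profile over 22 symbols (20 aa, X, gap)."""
    L = len(seqs[0])
    prof = np.zeros((L, 22))
    for s in seqs:
        for c, ch in enumerate(s):
            prof[c, GAP if ch == "-" else AA_INDEX.get(ch, _X)] += 1
    return prof / len(seqs)


_B22 = np.zeros((22, 22))
_B22[:21, :21] = BLOSUM62


def _align_profiles(sa: list[str], sb: list[str], gap_open: float = 11.0,
                    gap_ext: float = 1.0) -> tuple[list[str], list[str]]:
    pa, pb = _profile(sa), _profile(sb)
    # expected pair score per column pair; gaps inside profiles score 0
    S = pa @ _B22 @ pb.T
    # soften gap cost by the non-gap mass of each profile
    wa = 1.0 - pa[:, GAP].mean()
    wb = 1.0 - pb[:, GAP].mean()
    w = (wa + wb) / 2.0
    _, path = _nw_affine_trace(S, gap_open * w, gap_ext * w)
    out_a = ["" for _ in sa]
    out_b = ["" for _ in sb]
    for i, j in path:
        for k, s in enumerate(sa):
            out_a[k] += s[i] if i >= 0 else "-"
        for k, s in enumerate(sb):
            out_b[k] += s[j] if j >= 0 else "-"
    return out_a, out_b


def progressive_align(sequences: dict[str, str]) -> dict[str, str]:
    """Simple progressive MSA (3-mer guide tree + profile NW merges)."""
    names = list(sequences)
    if len(names) == 1:
        return dict(sequences)
    from scipy.cluster.hierarchy import average
    from scipy.spatial.distance import pdist

    vecs = np.zeros((len(names), 400))
    for r, nm in enumerate(names):
        s = sequences[nm]
        for i in range(len(s) - 2):
            h = (hash(s[i:i + 3]) & 0x7FFFFFFF) % 400
            vecs[r, h] += 1
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1
    d = pdist(vecs / norms, metric="cosine")
    d = np.nan_to_num(d, nan=1.0)
    link = average(d)

    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([nm], [sequences[nm]]) for i, nm in enumerate(names)
    }
    nxt = len(names)
    for a, b, _, _ in link:
        na, sa = clusters.pop(int(a))
        nb, sb = clusters.pop(int(b))
        aa, ab = _align_profiles(sa, sb)
        clusters[nxt] = (na + nb, aa + ab)
        nxt += 1
    (final_names, final_seqs), = clusters.values()
    return {nm: sq for nm, sq in zip(final_names, final_seqs)}


def mafft_align(sequences: dict[str, str], binary: str = "mafft") -> dict[str, str]:
    """External-aligner engine: shells out to mafft if present."""
    if shutil.which(binary) is None:
        raise RuntimeError(f"aligner {binary!r} not on PATH")
    with tempfile.TemporaryDirectory() as td:
        inp = Path(td) / "in.fa"
        with open(inp, "w") as fh:
            for nm, sq in sequences.items():
                fh.write(f">{nm}\n{sq}\n")
        res = subprocess.run([binary, "--auto", "--anysymbol", str(inp)],
                             capture_output=True, text=True, check=True)
    out: dict[str, str] = {}
    name = None
    for line in res.stdout.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            out[name] = ""
        elif name is not None:
            out[name] += line.strip().upper()
    return out
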