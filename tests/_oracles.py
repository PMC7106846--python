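"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results through different code paths than the
package: a regex-free exhaustive ORF scanner, a hand-rolled Gotoh dynamic
program for local alignment, a permutation-based Nei-Gojobori counter built
on Biopython's translate, and exhaustive Mann-Whitney / Benjamini-Hochberg
enumerations.
"""

from __future__ import annotations

import itertools
import math

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}


# --- uORF scanning ----------------------------------------------------------


def uorf_scanner(utr: str) -> list[tuple[int, int]]:
    """Every ATG walked codon-by-codon to its first stop inside the UTR,
    keeping only the longest uORF per shared stop codon."""
    raw = []
    for i in range(len(utr)):
        if utr[i : i + 3] != "ATG":
            continue
        j = i + 3
        while j + 3 <= len(utr):
            codon = utr[j : j + 3]
            if codon in STOPS:
                raw.append((i, j + 3))
                break
            j += 3
    per_stop: dict[int, int] = {}
    for start, end in raw:
        per_stop[end] = min(per_stop.get(end, start), start)
    return sorted((s, e) for e, s in per_stop.items())


def all_complete_orfs(rna: str) -> list[tuple[int, int]]:
    """Every complete forward-frame ATG->nearest-stop ORF in the sequence."""
    out = []
    for i in range(len(rna)):
        if rna[i : i + 3] != "ATG":
            continue
        j = i + 3
        while j + 3 <= len(rna):
            if rna[j : j + 3] in STOPS:
                out.append((i, j + 3))
                break
            j += 3
    return out


# --- local alignment --------------------------------------------------------

_B62 = substitution_matrices.load("BLOSUM62")


def gotoh_local_score(q: str, s: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Smith-Waterman with affine gaps (three-state Gotoh), score only.

    A gap of length k costs ``gap_open + k * gap_extend``.
    """
    n, m = len(q), len(s)
    NEG = -1e9
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in s (consume q)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in q (consume s)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(
                M[i - 1][j] - gap_open - gap_extend, X[i - 1][j] - gap_extend
            )
            Y[i][j] = max(
                M[i][j - 1] - gap_open - gap_extend, Y[i][j - 1] - gap_extend
            )
            sub = _B62[q[i - 1], s[j - 1]]
            M[i][j] = max(
                0.0,
                M[i - 1][j - 1] + sub,
                X[i - 1][j - 1] + sub,
                Y[i - 1][j - 1] + sub,
            )
            best = max(best, M[i][j])
    return best


# --- Nei-Gojobori -----------------------------------------------------------


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def ng86_pair(codons_a: list[str], codons_b: list[str]) -> tuple[float, float]:
    """Nei-Gojobori (1986) Ka and Ks from paired codon lists.

    Site counts: fraction of the three alternative bases per position that
    preserve the amino acid (mutations to stops count as nonsynonymous),
    averaged between the two codons.  Differences: all orderings of the
    differing positions weighted equally, excluding orderings that pass
    through a stop codon unless all do.  Jukes-Cantor corrected.
    """
    S = N = sd = nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        for c in (ca, cb):
            syn = 0.0
            for pos in range(3):
                for b in "ACGT":
                    if b == c[pos]:
                        continue
                    alt = c[:pos] + b + c[pos + 1 :]
                    if alt not in STOPS and _aa(alt) == _aa(c):
                        syn += 1 / 3
            S += syn / 2
            N += (3 - syn) / 2
        positions = [k for k in range(3) if ca[k] != cb[k]]
        if not positions:
            continue
        stats = []
        for order in itertools.permutations(positions):
            cur = ca
            s_steps = n_steps = 0
            through_stop = False
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                if nxt in STOPS and nxt != cb:
                    through_stop = True
                if _aa(nxt) == _aa(cur):
                    s_steps += 1
                else:
                    n_steps += 1
                cur = nxt
            stats.append((through_stop, s_steps, n_steps))
        ok = [t for t in stats if not t[0]] or stats
        sd += sum(t[1] for t in ok) / len(ok)
        nd += sum(t[2] for t in ok) / len(ok)

    def jc(p):
        if p >= 0.75:
            return math.nan
        return 0.0 if p == 0 else -0.75 * math.log(1 - 4 * p / 3)

    ks = (0.0 if sd == 0 else math.nan) if S <= 0 else jc(sd / S)
    ka = (0.0 if nd == 0 else math.nan) if N <= 0 else jc(nd / N)
    return ka, ks


# --- statistics -------------------------------------------------------------


def exact_mannwhitney_less(x: list[float], y: list[float]) -> tuple[float, float]:
    """One-sided (x stochastically smaller) permutation p-value by full
    enumeration of label assignments; U counts pairs with x > y (+0.5 ties)."""

    def u_of(a, b):
        return sum(1.0 if i > j else 0.5 if i == j else 0.0 for i in a for j in b)

    u_obs = u_of(x, y)
    pooled = list(x) + list(y)
    n = len(x)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        sel = set(idx)
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in sel]
        total += 1
        if u_of(a, b) <= u_obs + 1e-9:
            count += 1
    return u_obs, count / total


def bh_direct(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg by the direct formula
    q_i = min over p_(j) >= p_(i) of p_(j) * m / rank(j)."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = math.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        q[i] = running
    return q
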