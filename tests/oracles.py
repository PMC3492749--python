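"""Independent brute-force reference implementations used only by tests.

Everything here is written as plainly as possible (explicit loops,
enumeration, closed forms) and shares no code with the package paths it
checks.
"""

from __future__ import annotations

import itertools
import random

_CODONS = {}
_B = "TCAG"
_A = ("FFLLSSSSYY**CC*W" "LLLLPPPPHHQQRRRR"
      "IIIMTTTTNNKKSSRR" "VVVVAAAADDEEGGGG")
for i, b1 in enumerate(_B):
    for j, b2 in enumerate(_B):
        for k, b3 in enumerate(_B):
            _CODONS[b1 + b2 + b3] = _A[16 * i + 4 * j + k]


def smith_waterman(a: str, b: str, match=1.0, mismatch=-2.0,
                   gap_open=-5.0, gap_extend=-2.0):
    """Quadratic affine-gap local alignment.  Returns (score, identity)
    where identity is matches over all aligned columns (gaps included),
    for one optimal traceback."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in a
    F = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in b
    best, best_ij = 0.0, (0, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best, best_ij = H[i][j], (i, j)
    # traceback
    i, j = best_ij
    matches = columns = 0
    while i > 0 and j > 0 and H[i][j] > 0:
        s = match if a[i - 1] == b[j - 1] else mismatch
        if H[i][j] == H[i - 1][j - 1] + s:
            matches += 1 if a[i - 1] == b[j - 1] else 0
            columns += 1
            i, j = i - 1, j - 1
        elif H[i][j] == E[i][j]:
            # walk the horizontal gap back to its opening
            while j > 0 and H[i][j] == E[i][j]:
                columns += 1
                prev = H[i][j - 1] + gap_open
                j -= 1
                if E[i][j + 1] == prev:
                    break
        elif H[i][j] == F[i][j]:
            while i > 0 and H[i][j] == F[i][j]:
                columns += 1
                prev = H[i - 1][j] + gap_open
                i -= 1
                if F[i + 1][j] == prev:
                    break
        else:
            break
    identity = matches / columns if columns else 0.0
    return best, identity


def p_distance_brute(row_a: str, row_b: str):
    """Per-column scan: exclude any column where either symbol is not a
    plain base."""
    diffs = 0
    sites = 0
    for col in range(len(row_a)):
        x, y = row_a[col].upper(), row_b[col].upper()
        if x not in "ACGT" or y not in "ACGT":
            continue
        sites += 1
        if x != y:
            diffs += 1
    if sites == 0:
        return None, 0
    return diffs / sites, sites


def hgdi_by_pairs(counts: list[int]) -> float:
    """Hunter-Gaston by literal enumeration of all unordered isolate
    pairs."""
    isolates = []
    for type_index, c in enumerate(counts):
        isolates.extend([type_index] * c)
    same = different = 0
    for i in range(len(isolates)):
        for j in range(i + 1, len(isolates)):
            if isolates[i] == isolates[j]:
                same += 1
            else:
                different += 1
    return different / (same + different)


def ng_sites_brute(codon: str):
    """Enumerate all nine single-base mutants; synonymous fraction per
    position, stop-creating mutants nonsynonymous."""
    syn = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1:]
            if _CODONS[mut] != "*" and _CODONS[mut] == _CODONS[codon]:
                syn += 1 / 3
    return syn, 3.0 - syn


def ng_path_brute(c1: str, c2: str):
    """Recursive enumeration of all substitution orderings; paths through
    stops dropped, counts renormalized."""
    results = []

    def walk(current: str, remaining: list[int], sd: float, nd: float):
        if not remaining:
            results.append((sd, nd))
            return
        for pos in remaining:
            nxt = current[:pos] + c2[pos] + current[pos + 1:]
            if _CODONS[nxt] == "*":
                continue
            rest = [p for p in remaining if p != pos]
            if _CODONS[nxt] == _CODONS[current]:
                walk(nxt, rest, sd + 1, nd)
            else:
                walk(nxt, rest, sd, nd + 1)

    diff = [i for i in range(3) if c1[i] != c2[i]]
    walk(c1, diff, 0.0, 0.0)
    if not results:
        return None
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def random_additive_tree(n_taxa: int, rng: random.Random):
    """A random unrooted binary tree with strictly positive branch
    lengths.  Returns (newick, leaf-pair path-length dict, labels); the
    distances are exact path sums over an explicit graph."""
    labels = [f"T{i}" for i in range(n_taxa)]
    graph: dict[str, list[tuple[str, float]]] = {lbl: [] for lbl in labels}
    newicks = {lbl: lbl for lbl in labels}
    active = list(labels)
    counter = itertools.count()
    while len(active) > 3:
        i, j = sorted(rng.sample(range(len(active)), 2), reverse=True)
        a, b = active.pop(i), active.pop(j)
        la, lb = rng.uniform(0.05, 1.0), rng.uniform(0.05, 1.0)
        new = f"_n{next(counter)}"
        graph[new] = [(a, la), (b, lb)]
        graph[a].append((new, la))
        graph[b].append((new, lb))
        newicks[new] = f"({newicks[a]}:{la:.10f},{newicks[b]}:{lb:.10f})"
        active.append(new)
    hub = f"_n{next(counter)}"
    graph[hub] = []
    parts = []
    for a in active:
        la = rng.uniform(0.05, 1.0)
        graph[hub].append((a, la))
        graph[a].append((hub, la))
        parts.append(f"{newicks[a]}:{la:.10f}")
    newick = "(" + ",".join(parts) + ");"

    dists: dict[frozenset, float] = {}
    for start in labels:
        seen = {start: 0.0}
        stack = [start]
        while stack:
            node = stack.pop()
            for nxt, length in graph[node]:
                if nxt not in seen:
                    seen[nxt] = seen[node] + length
                    stack.append(nxt)
        for other in labels:
            if other != start:
                dists[frozenset([start, other])] = seen[other]
    return newick, dists, labels
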