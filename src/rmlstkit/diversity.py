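"""Discriminatory power and codon-level selection statistics.

Implements the Hunter-Gaston discriminatory index, per-locus overall mean
p-distance, and the Nei-Gojobori codon-based test of positive selection
(pathway counting of synonymous/nonsynonymous sites and differences,
Jukes-Cantor correction, bootstrap Z-test of dN > dS).  Genetic code 11
throughout.
"""

from __future__ import annotations

import itertools
import math
import random
from dataclasses import dataclass

from scipy.stats import norm

from .phylo import p_distance
from .seqs import CODON_TABLE

__all__ = ["CodonStats", "hunter_gaston", "codon_sites",
           "codon_path_differences", "nei_gojobori_pair",
           "positive_selection_test", "mean_p_distance"]

_BASES = "ACGT"


def hunter_gaston(type_counts: list[int]) -> float:
    """D = 1 - sum n_j (n_j - 1) / (N (N - 1)): the probability that two
    randomly drawn isolates belong to different types."""
    counts = [c for c in type_counts if c > 0]
    total = sum(counts)
    if total < 2:
        raise ValueError("Hunter-Gaston index needs at least 2 isolates")
    return 1.0 - sum(c * (c - 1) for c in counts) / (total * (total - 1))


def _is_stop(codon: str) -> bool:
    return CODON_TABLE.get(codon) == "*"


def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one sense codon.

    Per position, the synonymous fraction is the share of the three
    possible substitutions that preserve the amino acid; substitutions
    creating a stop codon count as nonsynonymous.  The two values sum to 3.
    """
    codon = codon.upper()
    if codon not in CODON_TABLE or _is_stop(codon):
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = CODON_TABLE[codon]
    syn = 0.0
    for pos in range(3):
        s = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if not _is_stop(mutant) and CODON_TABLE[mutant] == aa:
                s += 1
        syn += s / 3.0
    return syn, 3.0 - syn


# site counts are looked up constantly during pair scans
_SITE_CACHE = {c: None for c in CODON_TABLE}
for _c in CODON_TABLE:
    if not _is_stop(_c):
        _SITE_CACHE[_c] = codon_sites(_c)


def codon_path_differences(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd): synonymous and nonsynonymous difference counts between two
    sense codons, averaged over all orderings of the differing positions;
    pathways passing through a stop codon are excluded and the average
    renormalized over the remainder."""
    c1, c2 = c1.upper(), c2.upper()
    for c in (c1, c2):
        if c not in CODON_TABLE or _is_stop(c):
            raise ValueError(f"not a sense codon: {c!r}")
    diff_positions = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_positions:
        return 0.0, 0.0
    valid = []
    for order in itertools.permutations(diff_positions):
        current = c1
        steps = []
        ok = True
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1:]
            if _is_stop(nxt):
                ok = False
                break
            steps.append(CODON_TABLE[current] == CODON_TABLE[nxt])
            current = nxt
        if ok:
            valid.append(steps)
    if not valid:
        # all pathways hit a stop; fall back to counting through them
        for order in itertools.permutations(diff_positions):
            current = c1
            steps = []
            for pos in order:
                nxt = current[:pos] + c2[pos] + current[pos + 1:]
                steps.append(CODON_TABLE[current] == CODON_TABLE[nxt]
                             and not _is_stop(nxt))
                current = nxt
            valid.append(steps)
    sd = sum(sum(1 for s in steps if s) for steps in valid) / len(valid)
    nd = sum(sum(1 for s in steps if not s) for steps in valid) / len(valid)
    return sd, nd


def _usable(codon_a: str, codon_b: str) -> bool:
    return (set(codon_a) <= set(_BASES) and set(codon_b) <= set(_BASES)
            and not _is_stop(codon_a) and not _is_stop(codon_b))


def _jc_correct(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass(frozen=True)
class CodonStats:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float | None
    pN: float | None
    dS: float | None          # None when pS >= 3/4 (saturated)
    dN: float | None
    codons_compared: int
    Z: float | None = None
    p_one_sided: float | None = None

    @property
    def saturated(self) -> bool:
        return (self.pS is not None and self.dS is None) or \
               (self.pN is not None and self.dN is None)


def _pair_counts(cds1: str, cds2: str,
                 codon_idx: list[int] | None = None
                 ) -> tuple[float, float, float, float, int]:
    """Raw (S, N, Sd, Nd, codons) for one aligned pair; codons containing
    gaps, ambiguity or stops are dropped pairwise.  ``codon_idx`` restricts
    (with multiplicity) which codon columns are used, for bootstrapping."""
    n_codons = len(cds1) // 3
    idx = range(n_codons) if codon_idx is None else codon_idx
    S = N = Sd = Nd = 0.0
    used = 0
    for i in idx:
        a = cds1[3 * i:3 * i + 3]
        b = cds2[3 * i:3 * i + 3]
        if len(a) < 3 or len(b) < 3 or not _usable(a, b):
            continue
        sa, na = _SITE_CACHE[a]
        sb, nb = _SITE_CACHE[b]
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = codon_path_differences(a, b)
        Sd += sd
        Nd += nd
        used += 1
    return S, N, Sd, Nd, used


def _stats_from_counts(S, N, Sd, Nd, used) -> CodonStats:
    pS = Sd / S if S > 0 else None
    pN = Nd / N if N > 0 else None
    dS = _jc_correct(pS) if pS is not None else None
    dN = _jc_correct(pN) if pN is not None else None
    return CodonStats(S, N, Sd, Nd, pS, pN, dS, dN, used)


def nei_gojobori_pair(cds1: str, cds2: str) -> CodonStats:
    """Nei-Gojobori statistics for one pair of equal-length, in-frame
    aligned coding sequences."""
    if len(cds1) != len(cds2):
        raise ValueError("sequences differ in length")
    if len(cds1) % 3:
        raise ValueError("length not a multiple of 3")
    return _stats_from_counts(
        *_pair_counts(cds1.upper(), cds2.upper()))


def positive_selection_test(
    sequences: list[str],
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> CodonStats:
    """Test of strict neutrality (dN = dS) against dN > dS over an aligned
    CDS set: counts averaged over all unordered pairs, the variance of
    dN - dS estimated by codon-position bootstrap (``n_bootstrap``
    replicates, seeded), one-sided p from the normal tail."""
    seqs = [s.upper() for s in sequences]
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    if len({len(s) for s in seqs}) != 1 or len(seqs[0]) % 3:
        raise ValueError("sequences must be aligned, equal length, in frame")
    pairs = list(itertools.combinations(range(len(seqs)), 2))

    def aggregate(codon_idx: list[int] | None) -> tuple[CodonStats, float | None]:
        tot = [0.0, 0.0, 0.0, 0.0, 0]
        for i, j in pairs:
            part = _pair_counts(seqs[i], seqs[j], codon_idx)
            tot = [t + p for t, p in zip(tot, part)]
        avg = [t / len(pairs) for t in tot[:4]] + [tot[4] // len(pairs)]
        stats = _stats_from_counts(*avg)
        if stats.dN is None or stats.dS is None:
            return stats, None
        return stats, stats.dN - stats.dS

    stats, observed = aggregate(None)
    if observed is None:
        return stats
    rng = random.Random(seed)
    n_codons = len(seqs[0]) // 3
    deltas = []
    for _ in range(n_bootstrap):
        idx = [rng.randrange(n_codons) for _ in range(n_codons)]
        _, delta = aggregate(idx)
        if delta is not None:
            deltas.append(delta)
    if len(deltas) > 1:
        mean = sum(deltas) / len(deltas)
        var = sum((d - mean) ** 2 for d in deltas) / (len(deltas) - 1)
        se = math.sqrt(var)
    else:
        se = 0.0
    if se == 0.0:
        z = 0.0 if observed == 0 else math.copysign(math.inf, observed)
    else:
        z = observed / se
    p = float(norm.sf(z))
    return CodonStats(stats.S, stats.N, stats.Sd, stats.Nd, stats.pS,
                      stats.pN, stats.dS, stats.dN, stats.codons_compared,
                      Z=z, p_one_sided=p)


def mean_p_distance(rows: dict[str, str] | list[str]) -> float:
    """Average p-distance (pairwise deletion) over all unordered pairs of
    an aligned set; pairs with no comparable sites are skipped."""
    seqs = list(rows.values()) if isinstance(rows, dict) else list(rows)
    if len(seqs) < 2:
        return 0.0
    dists = []
    for a, b in itertools.combinations(seqs, 2):
        d, _ = p_distance(a, b)
        if d is not None:
            dists.append(d)
    if not dists:
        raise ValueError("no comparable pairs")
    return sum(dists) / len(dists)
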