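"""Codon-aware per-locus multiple alignment, XMFA export/import and
concatenation.

Alignment strategy: translate, align progressively at the protein level
(UPGMA guide tree on shared amino-acid 4-mers, profile-profile
Needleman-Wunsch with affine gaps), then back-translate so every gap is
codon-sized and starts on a codon boundary.  De-gapping any row always
reproduces the input sequence exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqs import translate

__all__ = ["LocusAlignment", "ConcatenatedAlignment", "align_locus",
           "write_xmfa", "read_xmfa", "concatenate", "XmfaError"]

_MATCH, _MISMATCH = 1.0, -2.0
_GAP_OPEN, _GAP_EXTEND = -5.0, -2.0
_NEG_INF = float("-inf")


class XmfaError(ValueError):
    pass


@dataclass
class LocusAlignment:
    locus: str
    rows: dict[str, str] = field(default_factory=dict)  # isolate -> gapped DNA

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.locus}: ragged alignment rows")


# -- guide tree ------------------------------------------------------------

def _kmer_distance(a: str, b: str, k: int = 4) -> float:
    ka = {a[i:i + k] for i in range(len(a) - k + 1)}
    kb = {b[i:i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def _upgma_order(labels: list[str], proteins: dict[str, str]) -> list:
    """Join schedule as a nested tuple tree; deterministic tie-breaks."""
    clusters: dict[tuple, list[str]] = {(lbl,): [lbl] for lbl in labels}
    dist = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            dist[frozenset([(a,), (b,)])] = _kmer_distance(
                proteins[a], proteins[b])
    trees: dict[tuple, object] = {(lbl,): lbl for lbl in labels}
    while len(clusters) > 1:
        best = min(
            ((d, tuple(sorted(pair))) for pair, d in dist.items()),
            key=lambda x: (x[0], x[1]),
        )
        ka, kb = sorted(best[1])
        merged_key = tuple(sorted(ka + kb))
        members = clusters[ka] + clusters[kb]
        new_tree = (trees[ka], trees[kb])
        for key in (ka, kb):
            del clusters[key], trees[key]
        new_dist = {}
        for other in clusters:
            da = dist.get(frozenset([ka, other]))
            db = dist.get(frozenset([kb, other]))
            wa, wb = len(ka), len(kb)
            new_dist[frozenset([merged_key, other])] = (
                (da * wa + db * wb) / (wa + wb))
        dist = {pair: d for pair, d in dist.items()
                if ka not in pair and kb not in pair}
        dist.update(new_dist)
        clusters[merged_key] = members
        trees[merged_key] = new_tree
    return trees[next(iter(trees))]


# -- profile alignment -----------------------------------------------------

def _col_score(col_a: list[str], col_b: list[str]) -> float:
    total = n = 0
    for a in col_a:
        if a == "-":
            continue
        for b in col_b:
            if b == "-":
                continue
            total += _MATCH if a == b else _MISMATCH
            n += 1
    return total / n if n else 0.0


def _align_profiles(rows_a: list[str], rows_b: list[str]
                    ) -> tuple[list[str], list[str]]:
    """Affine-gap global alignment of two aligned blocks; returns the two
    blocks re-gapped to a common length."""
    cols_a = [list(col) for col in zip(*rows_a)] if rows_a[0] else []
    cols_b = [list(col) for col in zip(*rows_b)] if rows_b[0] else []
    n, m = len(cols_a), len(cols_b)
    M = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in B (consume A)
    Y = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in A (consume B)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = _GAP_OPEN + _GAP_EXTEND * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = _GAP_OPEN + _GAP_EXTEND * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _col_score(cols_a[i - 1], cols_b[j - 1])
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] + _GAP_OPEN, X[i - 1][j] + _GAP_EXTEND)
            Y[i][j] = max(M[i][j - 1] + _GAP_OPEN, Y[i][j - 1] + _GAP_EXTEND)
    # traceback (prefer diagonal, then gap-in-B, for determinism)
    out_a: list[list[str]] = [[] for _ in rows_a]
    out_b: list[list[str]] = [[] for _ in rows_b]
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda s: {"M": M, "X": X, "Y": Y}[s][i][j])
    while i > 0 or j > 0:
        if state == "M" and i > 0 and j > 0:
            s = _col_score(cols_a[i - 1], cols_b[j - 1])
            prev = max(("M", "X", "Y"),
                       key=lambda st: {"M": M, "X": X, "Y": Y}[st][i - 1][j - 1])
            for r, row in enumerate(rows_a):
                out_a[r].append(row[i - 1])
            for r, row in enumerate(rows_b):
                out_b[r].append(row[j - 1])
            i, j, state = i - 1, j - 1, prev
        elif state == "X" or (state == "M" and j == 0):
            prev = ("M" if i > 0 and M[i - 1][j] + _GAP_OPEN >= X[i - 1][j] + _GAP_EXTEND
                    else "X")
            for r, row in enumerate(rows_a):
                out_a[r].append(row[i - 1])
            for r in range(len(rows_b)):
                out_b[r].append("-")
            i, state = i - 1, prev
        else:
            prev = ("M" if j > 0 and M[i][j - 1] + _GAP_OPEN >= Y[i][j - 1] + _GAP_EXTEND
                    else "Y")
            for r in range(len(rows_a)):
                out_a[r].append("-")
            for r, row in enumerate(rows_b):
                out_b[r].append(row[j - 1])
            j, state = j - 1, prev
    return (["".join(reversed(r)) for r in out_a],
            ["".join(reversed(r)) for r in out_b])


def _align_tree(tree, proteins: dict[str, str]
                ) -> tuple[list[str], list[str]]:
    if isinstance(tree, str):
        return [tree], [proteins[tree]]
    left, right = tree
    labels_a, rows_a = _align_tree(left, proteins)
    labels_b, rows_b = _align_tree(right, proteins)
    new_a, new_b = _align_profiles(rows_a, rows_b)
    return labels_a + labels_b, new_a + new_b


def align_locus(sequences: dict[str, str], locus: str = "") -> LocusAlignment:
    """Codon-aware multiple alignment of in-frame coding sequences."""
    for iso, seq in sequences.items():
        if len(seq) % 3 != 0:
            raise ValueError(f"{iso}: length {len(seq)} not a multiple of 3")
    if not sequences:
        return LocusAlignment(locus, {})
    proteins = {iso: translate(seq) for iso, seq in sequences.items()}
    labels = sorted(sequences)
    if len(labels) == 1:
        return LocusAlignment(locus, {labels[0]: sequences[labels[0]].upper()})
    if len(set(proteins[l] for l in labels)) == 1 and \
            len({len(sequences[l]) for l in labels}) == 1:
        # common case: equal-length, same protein -> gap-free
        return LocusAlignment(locus, {l: sequences[l].upper() for l in labels})
    tree = _upgma_order(labels, proteins)
    out_labels, aligned_prots = _align_tree(tree, proteins)
    rows = {}
    for iso, prot_row in zip(out_labels, aligned_prots):
        seq = sequences[iso].upper()
        codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
        it = iter(codons)
        rows[iso] = "".join("---" if c == "-" else next(it) for c in prot_row)
    return LocusAlignment(locus, rows)


# -- XMFA ------------------------------------------------------------------

def write_xmfa(alignments: list[LocusAlignment]) -> str:
    """XMFA text: one aligned block per locus, '=' terminated, headers
    '> isolate:start-end +strand locus' with 1-based inclusive coordinates
    over the ungapped sequence."""
    out = []
    for aln in alignments:
        for iso in sorted(aln.rows):
            row = aln.rows[iso]
            ungapped = len(row) - row.count("-")
            out.append(f"> {iso}:1-{ungapped} + {aln.locus}")
            for i in range(0, len(row), 80):
                out.append(row[i:i + 80])
        out.append("=")
    return "\n".join(out) + ("\n" if out else "")


def read_xmfa(text: str) -> list[LocusAlignment]:
    alignments: list[LocusAlignment] = []
    rows: dict[str, list[str]] = {}
    locus = ""
    current: str | None = None
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line == "=":
            if not rows:
                raise XmfaError(f"line {lineno}: block separator with no records")
            alignments.append(LocusAlignment(
                locus, {iso: "".join(parts) for iso, parts in rows.items()}))
            rows, locus, current = {}, "", None
        elif line.startswith(">"):
            fields = line[1:].split()
            if not fields or ":" not in fields[0]:
                raise XmfaError(f"line {lineno}: malformed XMFA header {line!r}")
            iso = fields[0].split(":", 1)[0]
            if len(fields) >= 3:
                locus = fields[2]
            rows[iso] = []
            current = iso
        else:
            if current is None:
                raise XmfaError(f"line {lineno}: sequence outside any record")
            rows[current].append(line)
    if rows:
        raise XmfaError("unterminated final block (missing '=')")
    return alignments


# -- concatenation ---------------------------------------------------------

@dataclass
class ConcatenatedAlignment:
    rows: dict[str, str]
    provenance: list[tuple[str, int]]   # per column: (locus, codon index)

    @property
    def n_columns(self) -> int:
        return len(self.provenance)

    def to_protein(self) -> "ConcatenatedAlignment":
        """Translate codon-aligned rows (gaps are codon-sized by
        construction)."""
        prot_rows = {}
        for iso, row in self.rows.items():
            prot_rows[iso] = "".join(
                "-" if row[i:i + 3] == "---" else translate(row[i:i + 3])
                for i in range(0, len(row), 3))
        prov = [self.provenance[i] for i in range(0, len(self.provenance), 3)]
        return ConcatenatedAlignment(prot_rows, prov)


def concatenate(alignments: list[LocusAlignment],
                isolates: list[str] | None = None,
                locus_order: list[str] | None = None) -> ConcatenatedAlignment:
    """Join per-locus blocks in catalogue order; isolates absent from a
    block are padded with gaps across it."""
    if locus_order is not None:
        order = {name: i for i, name in enumerate(locus_order)}
        alignments = sorted(alignments,
                            key=lambda a: order.get(a.locus, len(order)))
    if isolates is None:
        isolates = sorted({iso for a in alignments for iso in a.rows})
    rows = {iso: [] for iso in isolates}
    provenance: list[tuple[str, int]] = []
    for aln in alignments:
        width = aln.n_columns
        for iso in isolates:
            rows[iso].append(aln.rows.get(iso, "-" * width))
        provenance.extend((aln.locus, c // 3) for c in range(width))
    return ConcatenatedAlignment({iso: "".join(parts)
                                  for iso, parts in rows.items()}, provenance)
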