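"""Seeded local-alignment search of contigs against allele collections.

Two modes: nucleotide (exact DNA word seeds) and translated (both sides in
six reading frames, exact amino-acid word seeds).  Seeding selects candidate
windows; each window is then aligned with an affine-gap local aligner
(match +1, mismatch -2, gap open -5, gap extend -2).  Identity is the
fraction of matching columns over all aligned columns (gap columns
included); coverage is the aligned subject span over the subject length.

Coordinates are 0-based half-open on the contig's forward strand; strand
'-' means the contig's reverse complement aligns to the allele.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from Bio import Align

from .scheme import Allele
from .seqs import reverse_complement, translate

__all__ = ["SearchParams", "Hit", "nucleotide_search", "translated_search"]

_WINDOW_PAD = 60


@dataclass(frozen=True)
class SearchParams:
    min_identity: float = 0.70
    min_coverage: float = 0.50
    word_size: int = 15
    protein_word_size: int = 3

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_identity <= 1.0 and 0.0 <= self.min_coverage <= 1.0):
            raise ValueError("identity/coverage thresholds must lie in [0, 1]")
        if self.word_size < 4 or self.protein_word_size < 3:
            raise ValueError("word size too small")


@dataclass(frozen=True)
class Hit:
    locus: str
    allele_id: int
    contig_id: str
    contig_start: int
    contig_end: int
    allele_start: int
    allele_end: int
    strand: str                 # '+' or '-'
    identity: float
    coverage: float
    alignment_length: int
    score: float
    mode: str = "nt"            # 'nt' or 'aa'

    @property
    def contig_interval(self) -> tuple[int, int]:
        return (self.contig_start, self.contig_end)

    @property
    def allele_interval(self) -> tuple[int, int]:
        return (self.allele_start, self.allele_end)

    def rank_key(self) -> tuple:
        """Ordering used everywhere a single best hit must be chosen."""
        return (-self.score, -self.identity * self.coverage,
                self.allele_id, self.contig_id, self.contig_start)


def _nt_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1.0
    a.mismatch_score = -2.0
    a.open_gap_score = -5.0
    a.extend_gap_score = -2.0
    return a


def _aa_aligner() -> Align.PairwiseAligner:
    # BLOSUM62 with BLAST-style gap costs: match/mismatch scoring cannot
    # extend local alignments through <2/3-identity stretches, which is the
    # whole point of the translated phase
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11.0
    a.extend_gap_score = -1.0
    return a


_NT_ALIGNER = _nt_aligner()
_AA_ALIGNER = _aa_aligner()


def _alignment_stats(aln, target: str, query: str):
    """(matches, columns, t_start, t_end, q_start, q_end) for one local
    alignment, counting gap columns in the total."""
    t_blocks, q_blocks = aln.aligned
    matches = 0
    columns = 0
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if prev_t is not None:
            columns += (ts - prev_t) + (qs - prev_q)
        for a, b in zip(target[ts:te], query[qs:qe]):
            if a == b:
                matches += 1
        columns += te - ts
        prev_t, prev_q = te, qe
    t_start, t_end = int(t_blocks[0][0]), int(t_blocks[-1][1])
    q_start, q_end = int(q_blocks[0][0]), int(q_blocks[-1][1])
    return matches, columns, t_start, t_end, q_start, q_end


def _seed_windows(query: str, contig_index: dict[str, list[int]],
                  word_size: int, query_len: int, contig_len: int) -> list[tuple[int, int]]:
    """Candidate contig windows from exact word seeds, merged when close."""
    diagonals: list[int] = []
    for qpos in range(0, len(query) - word_size + 1):
        for cpos in contig_index.get(query[qpos:qpos + word_size], ()):
            diagonals.append(cpos - qpos)
    if not diagonals:
        return []
    diagonals.sort()
    band = max(20, query_len // 4)
    windows: list[tuple[int, int]] = []
    lo = hi = diagonals[0]
    for d in diagonals[1:]:
        if d - hi <= band:
            hi = d
        else:
            windows.append((lo, hi))
            lo = hi = d
    windows.append((lo, hi))
    spans = []
    for lo, hi in windows:
        start = max(0, lo - _WINDOW_PAD)
        end = min(contig_len, hi + query_len + _WINDOW_PAD)
        # per-diagonal-cluster windows stay separate: tandem copies of the
        # same allele must each get their own alignment; duplicate hits from
        # overlapping windows are removed by overlap suppression later
        if not spans or (start, end) != spans[-1]:
            spans.append((start, end))
    return spans


def _index_words(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i:i + k]].append(i)
    return index


def _suppress_overlaps(hits: list[Hit]) -> list[Hit]:
    """Keep only the best-scoring hit per overlapping contig region
    (ties broken toward the lowest allele id)."""
    kept: list[Hit] = []
    for hit in sorted(hits, key=Hit.rank_key):
        clash = any(
            h.contig_id == hit.contig_id
            and h.contig_start < hit.contig_end
            and hit.contig_start < h.contig_end
            for h in kept
        )
        if not clash:
            kept.append(hit)
    return sorted(kept, key=lambda h: (h.contig_id, h.contig_start, h.allele_id))


def nucleotide_search(
    contigs: dict[str, str],
    alleles: list[Allele],
    params: SearchParams = SearchParams(),
    _indices: dict[str, dict[str, list[int]]] | None = None,
) -> list[Hit]:
    """Search every contig against every allele on both strands.

    Any exact full-length substring occurrence of an allele is guaranteed
    to be reported with identity and coverage 1.0.  Hits below the
    identity or coverage threshold are suppressed, as are hits overlapping
    a better-scoring hit on the same contig region.
    """
    hits: list[Hit] = []
    for contig_id, contig in contigs.items():
        contig = contig.upper()
        if _indices is not None and contig_id in _indices:
            index = _indices[contig_id]
        else:
            index = _index_words(contig, params.word_size)
            if _indices is not None:
                _indices[contig_id] = index
        for allele in alleles:
            n = len(allele.sequence)
            if n < params.word_size:
                continue
            for strand in "+-":
                query = (allele.sequence if strand == "+"
                         else reverse_complement(allele.sequence))
                for w_start, w_end in _seed_windows(
                        query, index, params.word_size, n, len(contig)):
                    window = contig[w_start:w_end]
                    # fast path: exact full-length occurrence
                    pos = window.find(query)
                    if pos >= 0:
                        hits.append(Hit(
                            allele.locus, allele.allele_id, contig_id,
                            w_start + pos, w_start + pos + n, 0, n, strand,
                            1.0, 1.0, n, float(n)))
                        continue
                    alns = _NT_ALIGNER.align(window, query)
                    if not alns or alns.score <= 0:
                        continue
                    aln = alns[0]
                    matches, columns, ts, te, qs, qe = _alignment_stats(
                        aln, window, query)
                    if columns == 0:
                        continue
                    if strand == "+":
                        a_start, a_end = qs, qe
                    else:
                        a_start, a_end = n - qe, n - qs
                    hits.append(Hit(
                        allele.locus, allele.allele_id, contig_id,
                        w_start + ts, w_start + te, a_start, a_end, strand,
                        matches / columns, (qe - qs) / n, columns,
                        float(aln.score)))
    hits = [h for h in hits
            if h.identity >= params.min_identity
            and h.coverage >= params.min_coverage]
    return _suppress_overlaps(hits)


def _frame_peptides(contig: str) -> list[tuple[str, str, int]]:
    """(peptide, strand, frame offset) for all six frames."""
    rc = reverse_complement(contig)
    out = []
    for f in range(3):
        out.append((translate(contig[f:]), "+", f))
    for f in range(3):
        out.append((translate(rc[f:]), "-", f))
    return out


def translated_search(
    contigs: dict[str, str],
    alleles: list[Allele],
    params: SearchParams = SearchParams(),
    _frame_cache: dict[str, tuple] | None = None,
) -> list[Hit]:
    """Six-frame translated search; identity and thresholds apply at the
    amino-acid level, reported coordinates are nucleotide-space."""
    hits: list[Hit] = []
    k = params.protein_word_size
    for contig_id, contig in contigs.items():
        contig = contig.upper()
        clen = len(contig)
        if _frame_cache is not None and contig_id in _frame_cache:
            frames, frame_words = _frame_cache[contig_id]
        else:
            frames = _frame_peptides(contig)
            frame_words = [
                frozenset(pep[i:i + k] for i in range(len(pep) - k + 1))
                for pep, _, _ in frames
            ]
            if _frame_cache is not None:
                _frame_cache[contig_id] = (frames, frame_words)
        for allele in alleles:
            protein = translate(allele.sequence).rstrip("*")
            if len(protein) < k:
                continue
            n_aa = len(protein)
            words = {protein[i:i + k] for i in range(n_aa - k + 1)}
            for (pep, strand, offset), wset in zip(frames, frame_words):
                if not (words & wset):
                    continue
                alns = _AA_ALIGNER.align(pep, protein)
                if not alns or alns.score <= 0:
                    continue
                aln = alns[0]
                matches, columns, ts, te, qs, qe = _alignment_stats(
                    aln, pep, protein)
                if columns == 0:
                    continue
                identity = matches / columns
                coverage = (qe - qs) / n_aa
                if identity < params.min_identity or coverage < params.min_coverage:
                    continue
                if strand == "+":
                    c_start = offset + 3 * ts
                    c_end = offset + 3 * te
                else:
                    c_start = clen - (offset + 3 * te)
                    c_end = clen - (offset + 3 * ts)
                hits.append(Hit(
                    allele.locus, allele.allele_id, contig_id,
                    c_start, c_end, 3 * qs, 3 * qe, strand,
                    identity, coverage, columns, float(aln.score), mode="aa"))
    return _suppress_overlaps(hits)


def hits_to_table(hits: list[Hit]) -> str:
    """Tab-separated export, BLAST outfmt-6-like column order (documented
    in the README)."""
    rows = ["\t".join([
        "locus", "allele_id", "contig", "identity", "aln_length",
        "contig_start", "contig_end", "allele_start", "allele_end",
        "strand", "coverage", "score", "mode"])]
    for h in hits:
        rows.append("\t".join(map(str, [
            h.locus, h.allele_id, h.contig_id, f"{h.identity:.4f}",
            h.alignment_length, h.contig_start, h.contig_end,
            h.allele_start, h.allele_end, h.strand,
            f"{h.coverage:.4f}", f"{h.score:.1f}", h.mode])))
    return "\n".join(rows) + "\n"
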