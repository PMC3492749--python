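"""Iterative stringency-relaxing tagging of loci on genome assemblies.

A tag records, per (isolate, locus), where the locus sits on the contigs
and what state it is in: ``complete`` (a full, in-frame coding sequence),
``partial`` (truncated at a contig end), ``pseudogene`` (full-length but
frameshifted or carrying an internal stop), or ``missing`` (no qualifying
hit in either search phase down to the identity floor).

Discovery scans every genome against the current allele database, defines
new alleles from complete extractions, and rescans until a fixpoint, then
relaxes identity in steps; once the nucleotide phase bottoms out the same
loop runs in six-frame translated mode.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

from .scheme import AlleleDatabase, SchemeError, validate_allele
from .search import Hit, SearchParams, nucleotide_search, translated_search
from .seqs import reverse_complement

__all__ = [
    "TagStatus", "Tag", "StringencySchedule", "RoundLog", "DiscoveryResult",
    "extract_cds", "classify", "scan_isolate", "iterative_discovery",
    "tags_to_table", "read_tags_table",
]


class TagStatus(str, enum.Enum):
    COMPLETE = "complete"
    PARTIAL = "partial"
    MISSING = "missing"
    PSEUDOGENE = "pseudogene"


@dataclass(frozen=True)
class Tag:
    isolate_id: str
    locus: str
    status: TagStatus
    allele_id: int | None = None
    contig_id: str | None = None
    contig_start: int | None = None
    contig_end: int | None = None
    strand: str | None = None
    sequence: str | None = None          # extracted CDS (complete/pseudogene)
    flags: tuple[str, ...] = ()
    identity: float | None = None
    phase: str | None = None             # 'nucleotide' or 'translated'
    level: float | None = None           # identity level at which found

    @property
    def paralogue(self) -> bool:
        return "paralogue" in self.flags


@dataclass(frozen=True)
class StringencySchedule:
    start_identity: float = 0.70
    step: float = 0.05
    floor: float = 0.50
    coverage: float = 0.50
    word_size: int = 15
    max_rounds_per_level: int = 100

    def __post_init__(self) -> None:
        if self.step <= 0 or self.start_identity < self.floor:
            raise ValueError("invalid stringency schedule")

    def levels(self) -> list[float]:
        out, x = [], self.start_identity
        while x >= self.floor - 1e-9:
            out.append(round(x, 10))
            x -= self.step
        return out


@dataclass(frozen=True)
class RoundLog:
    phase: str
    level: float
    round_index: int
    new_alleles: int
    newly_complete: int
    untagged_after: int
    warnings: tuple[str, ...] = ()


@dataclass
class DiscoveryResult:
    db: AlleleDatabase
    tags: dict[str, list[Tag]]           # isolate -> tags (primary + paralogue)
    rounds: list[RoundLog] = field(default_factory=list)


@dataclass(frozen=True)
class Extraction:
    sequence: str
    missing_start: int = 0     # bp of the allele 5' end lost off the contig
    missing_end: int = 0       # bp of the allele 3' end lost off the contig

    @property
    def truncated(self) -> bool:
        return self.missing_start > 0 or self.missing_end > 0


def extract_cds(hit: Hit, contig: str, allele_length: int) -> Extraction:
    """Extend the aligned span to the full allele bounds on the contig and
    return the coding-strand sequence, reporting any truncation at contig
    ends."""
    lead = hit.allele_start                      # allele bp before the span
    trail = allele_length - hit.allele_end       # allele bp after the span
    if hit.strand == "+":
        start = hit.contig_start - lead
        end = hit.contig_end + trail
        missing_start = max(0, -start)
        missing_end = max(0, end - len(contig))
    else:
        start = hit.contig_start - trail
        end = hit.contig_end + lead
        missing_start = max(0, end - len(contig))
        missing_end = max(0, -start)
    seq = contig[max(0, start):min(len(contig), end)].upper()
    if hit.strand == "-":
        seq = reverse_complement(seq)
    return Extraction(seq, missing_start, missing_end)


def classify(hit: Hit | None, extraction: Extraction | None,
             db: AlleleDatabase) -> TagStatus:
    """Status for one candidate call.

    No hit -> missing; truncated extension -> partial; full-length but
    failing the in-frame/no-internal-stop curation rules -> pseudogene;
    otherwise complete.
    """
    if hit is None or extraction is None:
        return TagStatus.MISSING
    if extraction.truncated:
        return TagStatus.PARTIAL
    locus = db.locus(hit.locus)
    if validate_allele(locus, extraction.sequence) is None:
        return TagStatus.COMPLETE
    return TagStatus.PSEUDOGENE


def _primary_key(hit: Hit) -> tuple:
    # best by identity * coverage; ties -> lowest allele id, leftmost
    return (-hit.identity * hit.coverage, hit.allele_id,
            hit.contig_id, hit.contig_start)


def _tag_from_hit(isolate_id: str, hit: Hit, contigs: dict[str, str],
                  db: AlleleDatabase, phase: str, level: float,
                  paralogue: bool = False) -> Tag:
    allele = db.get_allele(hit.locus, hit.allele_id)
    extraction = extract_cds(hit, contigs[hit.contig_id], len(allele.sequence))
    status = classify(hit, extraction, db)
    flags: list[str] = []
    if paralogue:
        flags.append("paralogue")
    allele_id = None
    sequence = None
    if status is TagStatus.COMPLETE:
        sequence = extraction.sequence
        allele_id = db.lookup_exact(hit.locus, sequence)
        if sequence[:3] not in {"ATG", "GTG", "TTG"}:
            flags.append("non-standard-start")
    elif status is TagStatus.PSEUDOGENE:
        sequence = extraction.sequence
    return Tag(
        isolate_id, hit.locus, status, allele_id,
        hit.contig_id, hit.contig_start, hit.contig_end, hit.strand,
        sequence, tuple(flags), hit.identity, phase, level,
    )


def scan_isolate(
    isolate_id: str,
    contigs: dict[str, str],
    db: AlleleDatabase,
    params: SearchParams = SearchParams(),
    loci: list[str] | None = None,
    phase: str = "nucleotide",
    _indices: dict | None = None,
    _frames: dict | None = None,
) -> list[Tag]:
    """One scanning pass: one primary tag per locus (best hit by
    identity x coverage) plus paralogue-flagged secondary tags for other
    non-overlapping qualifying hits."""
    tags: list[Tag] = []
    search = nucleotide_search if phase == "nucleotide" else translated_search
    cache = _indices if phase == "nucleotide" else _frames
    for locus in (loci if loci is not None else sorted(db.loci)):
        alleles = db.alleles(locus)
        hits = search(contigs, alleles, params, cache) if alleles else []
        if not hits:
            tags.append(Tag(isolate_id, locus, TagStatus.MISSING,
                            phase=phase, level=params.min_identity))
            continue
        hits = sorted(hits, key=_primary_key)
        tags.append(_tag_from_hit(isolate_id, hits[0], contigs, db,
                                  phase, params.min_identity))
        for extra in hits[1:]:
            tags.append(_tag_from_hit(isolate_id, extra, contigs, db,
                                      phase, params.min_identity,
                                      paralogue=True))
    return tags


_STATUS_RANK = {TagStatus.COMPLETE: 3, TagStatus.PSEUDOGENE: 2,
                TagStatus.PARTIAL: 2, TagStatus.MISSING: 1}


def _better(new: Tag, old: Tag | None) -> bool:
    """A later complete tag supersedes earlier partial/pseudogene tags;
    within equal rank, the higher-identity call wins."""
    if old is None:
        return True
    if _STATUS_RANK[new.status] != _STATUS_RANK[old.status]:
        return _STATUS_RANK[new.status] > _STATUS_RANK[old.status]
    return (new.identity or 0.0) > (old.identity or 0.0)


def _foreign_locus_warning(db: AlleleDatabase, locus: str, seq: str,
                           k: int = 15) -> str | None:
    """Offline stand-in for the periodic external sanity check: warn when a
    newly defined allele shares more words with another locus than with
    its own."""
    words = {seq[i:i + k] for i in range(len(seq) - k + 1)}
    best_locus, best_shared, own_shared = None, 0, 0
    for name in db.loci:
        shared = 0
        for allele in db.alleles(name):
            if allele.sequence == seq:
                continue
            s = allele.sequence
            shared = max(shared, sum(
                1 for i in range(len(s) - k + 1) if s[i:i + k] in words))
        if name == locus:
            own_shared = shared
        elif shared > best_shared:
            best_locus, best_shared = name, shared
    if best_locus is not None and best_shared > own_shared:
        return (f"new allele at {locus} matches {best_locus} better "
                f"({best_shared} vs {own_shared} shared {k}-mers)")
    return None


def iterative_discovery(
    genomes: dict[str, dict[str, str]],
    db: AlleleDatabase,
    schedule: StringencySchedule = StringencySchedule(),
) -> DiscoveryResult:
    """Grow the allele database to a fixpoint over a genome corpus.

    At each identity level the corpus is rescanned (untagged loci only)
    and every complete, curation-passing extraction is defined as an
    allele, until a pass defines nothing new; then the identity threshold
    drops by ``schedule.step`` down to the floor, first in nucleotide mode
    and then in six-frame translated mode.
    """
    best: dict[tuple[str, str], Tag] = {}
    paralogues: dict[str, list[Tag]] = {iso: [] for iso in genomes}
    seen_paralogues: set[tuple] = set()
    rounds: list[RoundLog] = []
    nt_cache: dict[str, dict] = {iso: {} for iso in genomes}
    aa_cache: dict[str, dict] = {iso: {} for iso in genomes}

    def untagged(iso: str) -> list[str]:
        return [loc for loc in sorted(db.loci)
                if best.get((iso, loc)) is None
                or best[(iso, loc)].status is not TagStatus.COMPLETE
                or best[(iso, loc)].allele_id is None]

    def total_untagged() -> int:
        return sum(len(untagged(iso)) for iso in genomes)

    for phase in ("nucleotide", "translated"):
        for level in schedule.levels():
            params = SearchParams(min_identity=level,
                                  min_coverage=schedule.coverage,
                                  word_size=schedule.word_size)
            for round_index in range(1, schedule.max_rounds_per_level + 1):
                new_alleles = 0
                newly_complete = 0
                warnings: list[str] = []
                for iso in sorted(genomes):
                    todo = untagged(iso)
                    if not todo:
                        continue
                    tags = scan_isolate(
                        iso, genomes[iso], db, params, todo, phase,
                        _indices=nt_cache[iso], _frames=aa_cache[iso])
                    for tag in tags:
                        if tag.paralogue:
                            pkey = (iso, tag.locus, tag.contig_id,
                                    tag.contig_start, tag.contig_end, tag.strand)
                            if pkey not in seen_paralogues:
                                seen_paralogues.add(pkey)
                                paralogues[iso].append(tag)
                            continue
                        if tag.status is TagStatus.MISSING:
                            continue
                        if tag.status is TagStatus.COMPLETE and tag.allele_id is None:
                            before = db.allele_count(tag.locus)
                            try:
                                new_id = db.define_allele(tag.locus, tag.sequence)
                            except SchemeError as exc:
                                warnings.append(str(exc))
                                continue
                            if db.allele_count(tag.locus) > before:
                                new_alleles += 1
                                w = _foreign_locus_warning(db, tag.locus,
                                                           tag.sequence)
                                if w:
                                    warnings.append(w)
                            tag = replace(tag, allele_id=new_id)
                        key = (iso, tag.locus)
                        if _better(tag, best.get(key)):
                            if tag.status is TagStatus.COMPLETE and (
                                    best.get(key) is None
                                    or best[key].status is not TagStatus.COMPLETE):
                                newly_complete += 1
                            best[key] = tag
                rounds.append(RoundLog(phase, level, round_index, new_alleles,
                                       newly_complete, total_untagged(),
                                       tuple(warnings)))
                if new_alleles == 0 and newly_complete == 0:
                    break
            else:
                raise RuntimeError(
                    f"no fixpoint after {schedule.max_rounds_per_level} rounds "
                    f"at {phase} identity {level}")
            if total_untagged() == 0:
                break
        if total_untagged() == 0:
            break

    tags: dict[str, list[Tag]] = {}
    for iso in sorted(genomes):
        out = [best.get((iso, locus)) or Tag(iso, locus, TagStatus.MISSING)
               for locus in sorted(db.loci)]
        out.extend(paralogues[iso])
        tags[iso] = out
    return DiscoveryResult(db, tags, rounds)


def tags_to_table(tags: list[Tag]) -> str:
    """Tab-separated export of a tag list."""
    rows = ["\t".join(["isolate", "locus", "status", "allele_id", "contig",
                       "start", "end", "strand", "flags", "phase", "level"])]
    for t in tags:
        rows.append("\t".join("" if v is None else str(v) for v in [
            t.isolate_id, t.locus, t.status.value, t.allele_id, t.contig_id,
            t.contig_start, t.contig_end, t.strand, ",".join(t.flags),
            t.phase, t.level]))
    return "\n".join(rows) + "\n"


def read_tags_table(text: str) -> list[Tag]:
    """Inverse of :func:`tags_to_table` (extracted sequences are not part
    of the table and come back as None)."""
    lines = [l for l in text.splitlines() if l.strip()]
    if not lines:
        return []
    tags = []
    for line in lines[1:]:
        f = line.split("\t")
        if len(f) != 11:
            raise ValueError(f"malformed tag row: {line!r}")
        tags.append(Tag(
            f[0], f[1], TagStatus(f[2]),
            int(f[3]) if f[3] else None,
            f[4] or None,
            int(f[5]) if f[5] else None,
            int(f[6]) if f[6] else None,
            f[7] or None,
            None,
            tuple(x for x in f[8].split(",") if x),
            None,
            f[9] or None,
            float(f[10]) if f[10] else None,
        ))
    return tags
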