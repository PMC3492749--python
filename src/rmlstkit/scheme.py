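"""Locus catalogue and curated allele reference database.

A scheme is a catalogue of named loci with expected length ranges; the
allele database stores, per locus, every curated coding sequence under a
small-integer allele identifier.  Curation enforces in-frame,
internal-stop-free, unambiguous sequences; the identifier for a given
(locus, sequence) pair is stable for the lifetime of the database.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqs import START_CODONS, has_internal_stop

__all__ = [
    "Locus",
    "Allele",
    "AlleleDatabase",
    "ValidationFailure",
    "SchemeError",
    "validate_allele",
    "load_scheme",
    "default_scheme",
    "load_database",
    "save_database",
]


class SchemeError(ValueError):
    """Raised for malformed scheme/database artefacts or invariant breaches."""


@dataclass(frozen=True)
class Locus:
    name: str
    # permissive fallback bounds, for loci not described by a catalogue
    min_length: int = 6
    max_length: int = 100_000

    def __post_init__(self) -> None:
        if not self.name:
            raise SchemeError("locus name must be non-empty")
        if not (0 < self.min_length <= self.max_length):
            raise SchemeError(
                f"{self.name}: invalid length range "
                f"[{self.min_length}, {self.max_length}]"
            )


@dataclass(frozen=True)
class Allele:
    locus: str
    allele_id: int
    sequence: str

    def __post_init__(self) -> None:
        if self.allele_id < 1:
            raise SchemeError("allele_id must be a positive integer")
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass(frozen=True)
class ValidationFailure:
    """Why a candidate sequence was refused allele status."""

    rule: str       # one of: frameshift/length | ambiguity character |
                    #         internal stop codon | length range
    detail: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.rule}: {self.detail}" if self.detail else self.rule


def validate_allele(locus: Locus, sequence: str) -> ValidationFailure | None:
    """Return None if ``sequence`` qualifies as an allele of ``locus``,
    else the first failed curation rule.

    Rules: length a multiple of 3; alphabet restricted to ACGT; no stop
    codon before the final codon; length within the locus range.  A
    terminal stop codon is allowed (and typical).
    """
    seq = sequence.upper()
    if not seq or len(seq) % 3 != 0:
        return ValidationFailure("frameshift/length",
                                 f"length {len(seq)} not a multiple of 3")
    if set(seq) - set("ACGT"):
        bad = sorted(set(seq) - set("ACGT"))
        return ValidationFailure("ambiguity character", ",".join(bad))
    if has_internal_stop(seq):
        return ValidationFailure("internal stop codon")
    if not (locus.min_length <= len(seq) <= locus.max_length):
        return ValidationFailure(
            "length range",
            f"length {len(seq)} outside [{locus.min_length}, {locus.max_length}]",
        )
    return None


@dataclass
class AlleleDatabase:
    """Per-locus allele collections with sequential id assignment.

    ``lookup_exact`` and id lookup are exact inverses: every stored
    sequence maps to exactly one id and vice versa.
    """

    loci: dict[str, Locus] = field(default_factory=dict)
    _alleles: dict[str, dict[int, Allele]] = field(default_factory=dict)
    _by_seq: dict[str, dict[str, int]] = field(default_factory=dict)

    # -- scheme -----------------------------------------------------------
    def add_locus(self, locus: Locus) -> None:
        if locus.name in self.loci:
            raise SchemeError(f"duplicate locus {locus.name!r}")
        self.loci[locus.name] = locus
        self._alleles.setdefault(locus.name, {})
        self._by_seq.setdefault(locus.name, {})

    def locus(self, name: str) -> Locus:
        try:
            return self.loci[name]
        except KeyError:
            raise SchemeError(f"unknown locus {name!r}") from None

    # -- queries ----------------------------------------------------------
    def alleles(self, locus: str) -> list[Allele]:
        self.locus(locus)
        return [self._alleles[locus][i] for i in sorted(self._alleles[locus])]

    def get_allele(self, locus: str, allele_id: int) -> Allele:
        self.locus(locus)
        try:
            return self._alleles[locus][allele_id]
        except KeyError:
            raise SchemeError(f"{locus}: no allele {allele_id}") from None

    def lookup_exact(self, locus: str, sequence: str) -> int | None:
        """Allele id of the exact (case-insensitive) coding-strand match."""
        self.locus(locus)
        return self._by_seq[locus].get(sequence.upper())

    def allele_count(self, locus: str | None = None) -> int:
        if locus is not None:
            self.locus(locus)
            return len(self._alleles[locus])
        return sum(len(v) for v in self._alleles.values())

    # -- mutation ---------------------------------------------------------
    def define_allele(self, locus: str, sequence: str) -> int:
        """Return the id for ``sequence`` at ``locus``, defining a new
        sequential id if the sequence is unknown.  Idempotent.

        Raises :class:`SchemeError` carrying the failed curation rule if
        the sequence does not validate.
        """
        loc = self.locus(locus)
        seq = sequence.upper()
        existing = self._by_seq[locus].get(seq)
        if existing is not None:
            return existing
        failure = validate_allele(loc, seq)
        if failure is not None:
            raise SchemeError(f"{locus}: sequence rejected ({failure})")
        new_id = max(self._alleles[locus], default=0) + 1
        self._insert(Allele(locus, new_id, seq))
        return new_id

    def _insert(self, allele: Allele) -> None:
        per_id = self._alleles[allele.locus]
        per_seq = self._by_seq[allele.locus]
        if allele.allele_id in per_id:
            if per_id[allele.allele_id].sequence != allele.sequence:
                raise SchemeError(
                    f"{allele.locus}: conflicting sequences for allele "
                    f"{allele.allele_id}"
                )
            return
        if allele.sequence in per_seq:
            raise SchemeError(
                f"{allele.locus}: identical sequence under ids "
                f"{per_seq[allele.sequence]} and {allele.allele_id}"
            )
        per_id[allele.allele_id] = allele
        per_seq[allele.sequence] = allele.allele_id

    def non_standard_starts(self, locus: str) -> list[int]:
        """Ids of alleles not opening with a common start codon (warning
        material only; such alleles are stored regardless)."""
        return [a.allele_id for a in self.alleles(locus)
                if a.sequence[:3] not in START_CODONS]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlleleDatabase):
            return NotImplemented
        return self.loci == other.loci and self._alleles == other._alleles


# -- scheme catalogue ------------------------------------------------------

def load_scheme(path: str | Path) -> list[Locus]:
    """Read a tab-separated catalogue (locus, min_len, max_len); '#' lines
    are comments."""
    loci: list[Locus] = []
    seen: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise SchemeError(f"{path}:{lineno}: expected 3 tab-separated fields")
        name, lo, hi = parts
        if name in seen:
            raise SchemeError(f"{path}:{lineno}: duplicate locus {name!r}")
        seen.add(name)
        loci.append(Locus(name, int(lo), int(hi)))
    return loci


def default_scheme() -> list[Locus]:
    """The bundled 53-locus ribosomal-protein catalogue."""
    ref = importlib.resources.files("rmlstkit.data") / "default_scheme.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_scheme(path)


# -- FASTA persistence -----------------------------------------------------

def _parse_header(header: str, locus: str) -> int:
    prefix = locus + "_"
    if not header.startswith(prefix):
        raise SchemeError(
            f"record {header!r} does not match '<locus>_<id>' for locus {locus!r}"
        )
    try:
        return int(header[len(prefix):])
    except ValueError:
        raise SchemeError(f"record {header!r}: allele id is not an integer") from None


def load_database(
    directory: str | Path,
    scheme: list[Locus] | None = None,
    strict: bool = False,
) -> tuple[AlleleDatabase, list[str]]:
    """Build a database from a directory of per-locus FASTA files.

    Files are named ``<locus>.fas``/``.fasta``; headers are
    ``<locus>_<allele_id>``.  Records failing curation are rejected
    individually and reported in the returned list (or raised when
    ``strict``).  Conflicting duplicate ids are always a hard error.
    """
    directory = Path(directory)
    if scheme is None and (directory / "scheme.tsv").exists():
        scheme = load_scheme(directory / "scheme.tsv")
    db = AlleleDatabase()
    for locus in scheme or []:
        db.add_locus(locus)
    reports: list[str] = []
    files = sorted(p for p in directory.iterdir()
                   if p.suffix.lower() in {".fas", ".fasta", ".fa"})
    for path in files:
        locus_name = path.stem
        if locus_name not in db.loci:
            if scheme is not None:
                reports.append(f"{path.name}: locus not in scheme, skipped")
                continue
            db.add_locus(Locus(locus_name))
        loc = db.loci[locus_name]
        for record in SeqIO.parse(str(path), "fasta"):
            allele_id = _parse_header(record.id, locus_name)
            seq = str(record.seq).upper()
            failure = validate_allele(loc, seq)
            if failure is not None:
                msg = f"{locus_name}_{allele_id}: rejected ({failure})"
                if strict:
                    raise SchemeError(msg)
                reports.append(msg)
                continue
            db._insert(Allele(locus_name, allele_id, seq))
    return db, reports


def save_database(db: AlleleDatabase, directory: str | Path) -> None:
    """Write one ``<locus>.fas`` per locus plus a ``scheme.tsv`` catalogue."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = ["#locus\tmin_len\tmax_len"]
    for name in sorted(db.loci):
        loc = db.loci[name]
        lines.append(f"{loc.name}\t{loc.min_length}\t{loc.max_length}")
        records = [
            SeqRecord(Seq(a.sequence), id=f"{name}_{a.allele_id}", description="")
            for a in db.alleles(name)
        ]
        if records:
            SeqIO.write(records, str(directory / f"{name}.fas"), "fasta")
    (directory / "scheme.tsv").write_text("\n".join(lines) + "\n")
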