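"""Seeded generator of allele schemes, evolved variants and fragmented
genome assemblies with a ground-truth manifest.

Everything is deterministic under the supplied seed.  Generated coding
sequences always open with ATG, close with TAA and contain no internal
stop codon, so they pass allele curation by construction.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .scheme import Locus
from .seqs import CODON_TABLE, SENSE_CODONS, reverse_complement

__all__ = ["ErrorModel", "ManifestEntry", "Corpus", "generate_scheme",
           "evolve_allele", "saturate_synonymous", "build_corpus"]

_SYNONYMS: dict[str, list[str]] = {}
for _c in SENSE_CODONS:
    _SYNONYMS[_c] = [c for c in SENSE_CODONS
                     if c != _c and CODON_TABLE[c] == CODON_TABLE[_c]]


@dataclass(frozen=True)
class ErrorModel:
    """Per-isolate corruption plan applied at corpus build time."""

    substitution_rate: float = 0.0          # uniform per-bp, whole contig
    homopolymer_slip_prob: float = 0.0      # per gene with a run >= 4 bp
    truncated_loci: frozenset = frozenset()   # cut at a contig end -> partial
    missing_loci: frozenset = frozenset()     # not embedded at all
    pseudogene_loci: frozenset = frozenset()  # forced 1-bp slip -> frameshift

    def __post_init__(self) -> None:
        for p in (self.substitution_rate, self.homopolymer_slip_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class ManifestEntry:
    status: str                    # intended TagStatus value
    sequence: str | None = None    # embedded coding-strand sequence
    contig: str | None = None
    start: int | None = None       # 0-based half-open on the contig
    end: int | None = None
    strand: str | None = None


@dataclass
class Corpus:
    scheme: list[Locus]
    ancestors: dict[str, str]
    genomes: dict[str, dict[str, str]]            # isolate -> contig -> seq
    manifest: dict[str, dict[str, ManifestEntry]]  # isolate -> locus -> entry

    def distinct_variants(self, locus: str | None = None) -> int:
        """Number of distinct complete coding sequences embedded, per locus
        or in total (the expected database size after full discovery)."""
        per: dict[str, set[str]] = {}
        for entries in self.manifest.values():
            for loc, e in entries.items():
                if e.status == "complete" and e.sequence:
                    per.setdefault(loc, set()).add(e.sequence)
        if locus is not None:
            return len(per.get(locus, set()))
        return sum(len(v) for v in per.values())

    def write(self, outdir: str | Path) -> None:
        """Per-isolate multi-FASTA plus manifest.json and scheme.tsv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        lines = ["#locus\tmin_len\tmax_len"]
        for loc in self.scheme:
            lines.append(f"{loc.name}\t{loc.min_length}\t{loc.max_length}")
        (outdir / "scheme.tsv").write_text("\n".join(lines) + "\n")
        for iso, contigs in self.genomes.items():
            with open(outdir / f"{iso}.fasta", "w") as fh:
                for cid, seq in contigs.items():
                    fh.write(f">{cid}\n")
                    for i in range(0, len(seq), 70):
                        fh.write(seq[i:i + 70] + "\n")
        payload = {
            iso: {loc: vars(e) for loc, e in entries.items()}
            for iso, entries in self.manifest.items()
        }
        (outdir / "manifest.json").write_text(json.dumps(payload, indent=1))

    @staticmethod
    def read_manifest(path: str | Path) -> dict[str, dict[str, ManifestEntry]]:
        raw = json.loads(Path(path).read_text())
        return {iso: {loc: ManifestEntry(**e) for loc, e in entries.items()}
                for iso, entries in raw.items()}


def _random_cds(rng: random.Random, length: int) -> str:
    """A valid CDS of ``length`` bp (multiple of 3): ATG + sense codons + TAA."""
    if length % 3 or length < 9:
        raise ValueError("CDS length must be a multiple of 3 and >= 9")
    codons = ["ATG"]
    codons += [rng.choice(SENSE_CODONS) for _ in range(length // 3 - 2)]
    codons.append("TAA")
    return "".join(codons)


def generate_scheme(
    n_loci: int,
    length_range: tuple[int, int] = (240, 600),
    seed: int = 0,
    locus_names: list[str] | None = None,
) -> tuple[list[Locus], dict[str, str]]:
    """Ancestral alleles for ``n_loci`` loci; names default to the bundled
    ribosomal-protein symbols (extended generically past 53)."""
    rng = random.Random(seed)
    if locus_names is None:
        from .scheme import default_scheme
        names = [loc.name for loc in default_scheme()]
        locus_names = (names[:n_loci] if n_loci <= len(names)
                       else names + [f"locus{i:03d}"
                                     for i in range(len(names), n_loci)])
    lo, hi = length_range
    scheme: list[Locus] = []
    ancestors: dict[str, str] = {}
    for name in locus_names[:n_loci]:
        length = 3 * rng.randint(max(3, lo // 3), hi // 3)
        seq = _random_cds(rng, length)
        scheme.append(Locus(name, max(9, length - 60), length + 60))
        ancestors[name] = seq
    return scheme, ancestors


def _mutable_positions(seq: str, mode: str) -> list[int]:
    if mode == "any":
        return list(range(len(seq)))
    positions = []
    for i in range(len(seq)):
        codon_start = 3 * (i // 3)
        codon = seq[codon_start:codon_start + 3]
        off = i - codon_start
        for base in "ACGT":
            if base == seq[i]:
                continue
            new = codon[:off] + base + codon[off + 1:]
            if CODON_TABLE.get(new, "*") == "*":
                continue
            same = CODON_TABLE[new] == CODON_TABLE.get(codon, "?")
            if (mode == "synonymous-only") == same:
                positions.append(i)
                break
    return positions


def evolve_allele(sequence: str, n_substitutions: int, mode: str = "any",
                  seed: int | random.Random = 0) -> str:
    """Apply exactly ``n_substitutions`` at distinct positions.

    Modes: ``any`` (no amino-acid constraint beyond avoiding new stops),
    ``synonymous-only`` (protein preserved) and ``nonsynonymous-biased``
    (every substitution changes the amino acid).  The result always passes
    allele validation; identity to the parent is exactly
    ``1 - n/len`` because positions never repeat.
    """
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    if mode not in {"any", "synonymous-only", "nonsynonymous-biased"}:
        raise ValueError(f"unknown mode {mode!r}")
    seq = list(sequence.upper())
    # never touch the terminal stop codon
    candidates = [p for p in _mutable_positions(sequence.upper(), mode)
                  if p < len(seq) - 3]
    if n_substitutions > len(candidates):
        raise ValueError(
            f"cannot place {n_substitutions} substitutions "
            f"({len(candidates)} eligible positions)")
    chosen = rng.sample(candidates, n_substitutions)
    for pos in sorted(chosen):
        codon_start = 3 * (pos // 3)
        off = pos - codon_start
        codon = "".join(seq[codon_start:codon_start + 3])
        options = []
        for base in "ACGT":
            if base == seq[pos]:
                continue
            new = codon[:off] + base + codon[off + 1:]
            if CODON_TABLE[new] == "*":
                continue
            same = CODON_TABLE[new] == CODON_TABLE[codon]
            if mode == "synonymous-only" and not same:
                continue
            if mode == "nonsynonymous-biased" and same:
                continue
            options.append(base)
        if not options:      # codon altered by an earlier pick; fall back
            options = [b for b in "ACGT" if b != seq[pos]
                       and CODON_TABLE[codon[:off] + b + codon[off + 1:]] != "*"]
        seq[pos] = rng.choice(options)
    return "".join(seq)


def saturate_synonymous(sequence: str, seed: int | random.Random = 0) -> str:
    """Replace every codon by a random different synonymous codon where one
    exists: protein identical, nucleotide identity ~2/3, and exact-word
    seeds destroyed."""
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    seq = sequence.upper()
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        alts = _SYNONYMS.get(codon, [])
        out.append(rng.choice(alts) if alts else codon)
    return "".join(out)


def _spacer(rng: random.Random, length: int, gc: float = 0.5) -> str:
    w_at, w_gc = (1 - gc) / 2, gc / 2
    return "".join(rng.choices("ATGC", weights=[w_at, w_at, w_gc, w_gc],
                               k=length))


def _slip(seq: str, rng: random.Random) -> str | None:
    """Delete one base from the longest homopolymer run (>= 2 bp), the
    classic pyrosequencing frameshift; None if no run exists."""
    best_start, best_len = -1, 1
    run_start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[run_start]:
            if i - run_start > best_len:
                best_start, best_len = run_start, i - run_start
            run_start = i
    if best_start < 0:
        return None
    return seq[:best_start] + seq[best_start + 1:]


def build_corpus(
    scheme: list[Locus],
    ancestors: dict[str, str],
    n_isolates: int,
    seed: int = 0,
    divergence: int | dict[str, int] = 0,
    mode: str = "any",
    loci_per_contig: int = 10,
    spacer_range: tuple[int, int] = (80, 200),
    gc: float = 0.5,
    error_models: dict[str, ErrorModel] | None = None,
    isolate_prefix: str = "iso",
) -> Corpus:
    """Assemble ``n_isolates`` genomes with evolved alleles embedded among
    random intergenic spacer, returning genomes plus a truth manifest.

    ``divergence`` gives substitutions per locus, either one count for all
    isolates or per-isolate.  ``mode`` follows :func:`evolve_allele`, plus
    ``mixed`` (three-quarters synonymous, one quarter unconstrained - the
    shape of variation in genes under stabilizing selection).  Contig
    boundaries fall between genes except for planned truncations, which
    place the cut gene at the end of its own contig.
    """
    rng = random.Random(seed)
    error_models = error_models or {}
    genomes: dict[str, dict[str, str]] = {}
    manifest: dict[str, dict[str, ManifestEntry]] = {}
    lo_sp, hi_sp = spacer_range

    for idx in range(1, n_isolates + 1):
        iso = f"{isolate_prefix}{idx:03d}"
        model = error_models.get(iso, ErrorModel())
        n_subs = divergence if isinstance(divergence, int) else divergence.get(iso, 0)
        entries: dict[str, ManifestEntry] = {}
        contigs: dict[str, str] = {}
        contig_idx = 0
        parts: list[str] = []
        placed: list[tuple[str, str, int, int, str, str]] = []
        pos = 0

        def flush() -> None:
            # seal the current contig and fix manifest coordinates on it
            nonlocal contig_idx, parts, placed, pos
            if not parts:
                return
            contig_idx += 1
            cid = f"{iso}_c{contig_idx}"
            contigs[cid] = "".join(parts)
            for locus, status, start, end, strand, seq in placed:
                entries[locus] = ManifestEntry(status, seq, cid, start, end,
                                               strand)
            parts, placed, pos = [], [], 0

        genes_in_contig = 0
        for locus in scheme:
            name = locus.name
            if name in model.missing_loci:
                entries[name] = ManifestEntry("missing")
                continue
            if n_subs == 0:
                variant = ancestors[name]
            elif mode == "mixed":
                # stabilizing-selection flavour: mostly synonymous changes
                n_syn = (3 * n_subs) // 4
                variant = evolve_allele(ancestors[name], n_syn,
                                        "synonymous-only", rng)
                variant = evolve_allele(variant, n_subs - n_syn, "any", rng)
            else:
                variant = evolve_allele(ancestors[name], n_subs, mode, rng)
            if name in model.truncated_loci:
                # own contig, gene running off the right end
                flush()
                keep = min(len(variant) - 3,
                           3 * ((len(variant) * 6 // 10) // 3))
                sp = _spacer(rng, rng.randint(lo_sp, hi_sp), gc)
                contig_idx += 1
                cid = f"{iso}_c{contig_idx}"
                contigs[cid] = sp + variant[:keep]
                entries[name] = ManifestEntry("partial", variant[:keep], cid,
                                              len(sp), len(sp) + keep, "+")
                continue
            embedded, status = variant, "complete"
            slip_wanted = name in model.pseudogene_loci or (
                model.homopolymer_slip_prob
                and _has_long_run(embedded)
                and rng.random() < model.homopolymer_slip_prob)
            if slip_wanted:
                slipped = _slip(embedded, rng)
                if slipped is None:       # no repeated base anywhere
                    slipped = embedded[:-4] + embedded[-3:]
                embedded, status = slipped, "pseudogene"
            strand = rng.choice("+-")
            on_contig = (embedded if strand == "+"
                         else reverse_complement(embedded))
            sp = _spacer(rng, rng.randint(lo_sp, hi_sp), gc)
            parts.append(sp)
            pos += len(sp)
            start = pos
            parts.append(on_contig)
            pos += len(on_contig)
            placed.append((name, status, start, pos, strand, embedded))
            genes_in_contig += 1
            if genes_in_contig >= loci_per_contig:
                parts.append(_spacer(rng, rng.randint(lo_sp, hi_sp), gc))
                flush()
                genes_in_contig = 0
        if parts:
            parts.append(_spacer(rng, rng.randint(lo_sp, hi_sp), gc))
            flush()

        if model.substitution_rate > 0:
            for cid, seq in contigs.items():
                chars = list(seq)
                for i in range(len(chars)):
                    if rng.random() < model.substitution_rate:
                        chars[i] = rng.choice(
                            [b for b in "ACGT" if b != chars[i]])
                contigs[cid] = "".join(chars)

        genomes[iso] = contigs
        manifest[iso] = {k: v for k, v in entries.items() if v is not None}

    return Corpus(list(scheme), dict(ancestors), genomes, manifest)


def _has_long_run(seq: str, min_run: int = 4) -> bool:
    run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        if run >= min_run:
            return True
    return False
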