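"""Typing profiles, rST assignment and corpus-level tagging summaries."""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

from .tagger import Tag, TagStatus

__all__ = ["Profile", "TaggingSummary", "build_profile", "profile_mismatches",
           "assign_rst", "tagging_summary", "profiles_to_table"]


@dataclass(frozen=True)
class Profile:
    """Isolate -> locus -> allele id, with typed absence markers.

    ``calls`` maps each scheme locus to a positive allele id (status
    complete) or to the status string for missing/partial/pseudogene loci.
    """

    isolate_id: str
    calls: dict[str, int | str] = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        return all(isinstance(v, int) for v in self.calls.values())

    def key(self) -> tuple:
        """Hashable identity of a complete profile (locus order fixed)."""
        return tuple(sorted(self.calls.items()))


def build_profile(tags: list[Tag], loci: list[str]) -> Profile:
    """Collapse one isolate's primary tags into a profile.

    Paralogue-flagged secondary tags are excluded; loci without a tag are
    recorded as missing.
    """
    isolates = {t.isolate_id for t in tags}
    if len(isolates) > 1:
        raise ValueError(f"tags span multiple isolates: {sorted(isolates)}")
    isolate_id = isolates.pop() if isolates else ""
    by_locus = {t.locus: t for t in tags if not t.paralogue}
    calls: dict[str, int | str] = {}
    for locus in loci:
        tag = by_locus.get(locus)
        if tag is None:
            calls[locus] = TagStatus.MISSING.value
        elif tag.status is TagStatus.COMPLETE and tag.allele_id is not None:
            calls[locus] = tag.allele_id
        else:
            calls[locus] = tag.status.value
    return Profile(isolate_id, calls)


def profile_mismatches(p1: Profile, p2: Profile) -> tuple[int, int]:
    """(mismatching loci, compared loci) over loci where both profiles
    carry allele ids; loci absent in either are excluded from comparison."""
    mismatches = compared = 0
    for locus in set(p1.calls) & set(p2.calls):
        a, b = p1.calls[locus], p2.calls[locus]
        if isinstance(a, int) and isinstance(b, int):
            compared += 1
            if a != b:
                mismatches += 1
    return mismatches, compared


def assign_rst(profiles: list[Profile]) -> dict[str, int | None]:
    """Sequential rST numbering in first-seen order; identical complete
    profiles share one rST, incomplete profiles get None."""
    seen: dict[tuple, int] = {}
    out: dict[str, int | None] = {}
    for p in profiles:
        if not p.complete:
            out[p.isolate_id] = None
            continue
        key = p.key()
        if key not in seen:
            seen[key] = len(seen) + 1
        out[p.isolate_id] = seen[key]
    return out


@dataclass(frozen=True)
class TaggingSummary:
    n_isolates: int
    n_loci: int
    mean_complete: float
    mode_complete: int
    mean_partial: float
    mode_partial: int
    mean_missing: float
    mode_missing: int
    mean_pseudogene: float
    mode_pseudogene: int
    all_tagged_count: int      # isolates with every locus carrying an allele

    def to_table(self) -> str:
        def fmt(mean: float, mode: int) -> str:
            return f"{round(mean, 3)} ({mode})"
        rows = [
            ("Isolates", str(self.n_isolates)),
            ("Average complete loci per strain", fmt(self.mean_complete, self.mode_complete)),
            ("Average partial loci per strain", fmt(self.mean_partial, self.mode_partial)),
            ("Average missing loci per strain", fmt(self.mean_missing, self.mode_missing)),
            ("Average internal stop codons per strain", fmt(self.mean_pseudogene, self.mode_pseudogene)),
            ("Strains with all loci tagged", str(self.all_tagged_count)),
        ]
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


def tagging_summary(tags_by_isolate: dict[str, list[Tag]],
                    loci: list[str]) -> TaggingSummary:
    """Mean and modal per-strain counts of each tag status (primary tags
    only), plus the count of fully tagged strains."""
    if not tags_by_isolate:
        raise ValueError("empty corpus")
    counts = {s: [] for s in TagStatus}
    all_tagged = 0
    for iso, tags in tags_by_isolate.items():
        primary = {t.locus: t for t in tags if not t.paralogue}
        per = {s: 0 for s in TagStatus}
        for locus in loci:
            tag = primary.get(locus)
            status = tag.status if tag is not None else TagStatus.MISSING
            per[status] += 1
        for s in TagStatus:
            counts[s].append(per[s])
        if per[TagStatus.COMPLETE] == len(loci):
            all_tagged += 1

    def mean(s: TagStatus) -> float:
        return round(statistics.fmean(counts[s]), 3)

    def mode(s: TagStatus) -> int:
        return int(statistics.mode(counts[s]))

    return TaggingSummary(
        n_isolates=len(tags_by_isolate), n_loci=len(loci),
        mean_complete=mean(TagStatus.COMPLETE), mode_complete=mode(TagStatus.COMPLETE),
        mean_partial=mean(TagStatus.PARTIAL), mode_partial=mode(TagStatus.PARTIAL),
        mean_missing=mean(TagStatus.MISSING), mode_missing=mode(TagStatus.MISSING),
        mean_pseudogene=mean(TagStatus.PSEUDOGENE), mode_pseudogene=mode(TagStatus.PSEUDOGENE),
        all_tagged_count=all_tagged,
    )


def profiles_to_table(profiles: list[Profile], loci: list[str],
                      rsts: dict[str, int | None] | None = None) -> str:
    """Profiles as a tab-separated matrix, isolates in rows."""
    header = ["isolate"] + (["rST"] if rsts is not None else []) + list(loci)
    rows = ["\t".join(header)]
    for p in profiles:
        row = [p.isolate_id]
        if rsts is not None:
            rst = rsts.get(p.isolate_id)
            row.append("" if rst is None else str(rst))
        row += [str(p.calls.get(locus, TagStatus.MISSING.value)) for locus in loci]
        rows.append("\t".join(row))
    return "\n".join(rows) + "\n"
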