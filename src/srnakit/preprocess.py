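"""Small-RNA read preprocessing: adapter trimming, quality and length
filtering, collapsing to unique tags, and t/rRNA contaminant removal.

The filter chain is: 3'-adapter trim -> quality filter (no N, at most 6
bases below Q13) -> length filter (16-30 nt) -> collapse identical
sequences with per-library counts -> drop tags contained in a contaminant
sequence (exact substring of either strand).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._seq import normalize, revcomp
from .config import PreprocessConfig

__all__ = [
    "UniqueRead",
    "FilterReport",
    "trim_adapter",
    "quality_filter",
    "collapse_and_filter",
    "preprocess_libraries",
]


@dataclass
class UniqueRead:
    """A collapsed small-RNA tag with its per-library counts.

    ``sequence`` is 5'->3' in the DNA alphabet, 16-30 nt.
    """

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class FilterReport:
    """Per-library read tallies through the filter chain.

    Conservation: raw = adapter_unmatched + quality_failed + length_failed
    + contaminant_removed + clean_total, per library.
    """

    raw: dict[str, int] = field(default_factory=dict)
    adapter_trimmed: dict[str, int] = field(default_factory=dict)
    adapter_unmatched: dict[str, int] = field(default_factory=dict)
    quality_failed: dict[str, int] = field(default_factory=dict)
    length_failed: dict[str, int] = field(default_factory=dict)
    contaminant_removed: dict[str, int] = field(default_factory=dict)
    clean_total: dict[str, int] = field(default_factory=dict)
    unique_total: int = 0

    def to_rows(self) -> list[dict]:
        libs = sorted(self.raw)
        return [
            {
                "library": lib,
                "raw": self.raw.get(lib, 0),
                "adapter_trimmed": self.adapter_trimmed.get(lib, 0),
                "adapter_unmatched": self.adapter_unmatched.get(lib, 0),
                "quality_failed": self.quality_failed.get(lib, 0),
                "length_failed": self.length_failed.get(lib, 0),
                "contaminant_removed": self.contaminant_removed.get(lib, 0),
                "clean_total": self.clean_total.get(lib, 0),
                "unique_total": self.unique_total,
            }
            for lib in libs
        ]


def trim_adapter(read: str, adapter: str, min_overlap: int = 7) -> str | None:
    """Return the insert preceding the leftmost 3'-adapter match, or None.

    The adapter is recognised when a prefix of it (of at least
    ``min_overlap`` bases, up to its full length) matches the read exactly,
    either internally or as a suffix-prefix overlap at the read's 3' end.
    """
    if not adapter:
        raise ValueError("empty adapter")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    read = normalize(read)
    adapter = normalize(adapter)
    n = len(read)
    for i in range(n - min_overlap + 1):
        k = min(len(adapter), n - i)
        if read[i : i + k] == adapter[:k]:
            return read[:i]
    return None


def quality_filter(
    sequence: str,
    quality: str,
    quality_floor: int = 13,
    max_low_quality: int = 6,
) -> bool:
    """True iff the read has no N and at most ``max_low_quality`` bases
    with Phred score below ``quality_floor`` (Phred+33 encoding)."""
    if len(sequence) != len(quality):
        raise ValueError(
            f"sequence/quality length mismatch ({len(sequence)} vs {len(quality)})"
        )
    if "N" in sequence.upper():
        return False
    low = sum(1 for q in quality if ord(q) - 33 < quality_floor)
    return low <= max_low_quality


def load_contaminants(path: str | Path) -> list[str]:
    return [normalize(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def collapse_and_filter(
    reads_per_library: dict[str, list[str]],
    contaminants: list[str] | None = None,
    min_length: int = 16,
    max_length: int = 30,
    report: FilterReport | None = None,
) -> tuple[list[UniqueRead], FilterReport]:
    """Collapse trimmed reads to unique tags and drop contaminants.

    Reads outside [min_length, max_length] are dropped. A unique tag is
    removed when it occurs as an exact substring of any contaminant
    sequence or its reverse complement.
    """
    if report is None:
        report = FilterReport()
    counts: dict[str, dict[str, int]] = {}
    for lib, reads in reads_per_library.items():
        report.raw.setdefault(lib, 0)
        for read in reads:
            seq = normalize(read)
            if not (min_length <= len(seq) <= max_length):
                report.length_failed[lib] = report.length_failed.get(lib, 0) + 1
                continue
            counts.setdefault(seq, {})
            counts[seq][lib] = counts[seq].get(lib, 0) + 1

    haystacks = []
    for c in contaminants or []:
        haystacks.append(c)
        haystacks.append(revcomp(c))

    unique: list[UniqueRead] = []
    for seq in sorted(counts):
        if any(seq in h for h in haystacks):
            for lib, n in counts[seq].items():
                report.contaminant_removed[lib] = (
                    report.contaminant_removed.get(lib, 0) + n
                )
            continue
        unique.append(UniqueRead(sequence=seq, counts=dict(sorted(counts[seq].items()))))

    for ur in unique:
        for lib, n in ur.counts.items():
            report.clean_total[lib] = report.clean_total.get(lib, 0) + n
    report.unique_total = len(unique)
    return unique, report


def preprocess_libraries(
    fastq_paths: dict[str, str | Path],
    cfg: PreprocessConfig,
    contaminants: list[str] | None = None,
) -> tuple[list[UniqueRead], FilterReport]:
    """Run the full filter chain on raw FASTQ libraries.

    ``fastq_paths`` maps library id -> FASTQ path (Phred+33). Reads with no
    detectable adapter are discarded unless ``cfg.keep_untrimmed``.
    """
    report = FilterReport()
    trimmed: dict[str, list[str]] = {}
    for lib in sorted(fastq_paths):
        trimmed[lib] = []
        raw = 0
        for _title, seq, qual in FastqGeneralIterator(str(fastq_paths[lib])):
            raw += 1
            insert = trim_adapter(seq, cfg.adapter, cfg.min_overlap)
            if insert is None:
                if cfg.keep_untrimmed:
                    insert = normalize(seq)
                else:
                    report.adapter_unmatched[lib] = (
                        report.adapter_unmatched.get(lib, 0) + 1
                    )
                    continue
            else:
                report.adapter_trimmed[lib] = report.adapter_trimmed.get(lib, 0) + 1
            if not quality_filter(
                seq, qual, cfg.quality_floor, cfg.max_low_quality
            ):
                report.quality_failed[lib] = report.quality_failed.get(lib, 0) + 1
                continue
            trimmed[lib].append(insert)
        report.raw[lib] = raw
    return collapse_and_filter(
        trimmed,
        contaminants=contaminants,
        min_length=cfg.min_length,
        max_length=cfg.max_length,
        report=report,
    )


def write_collapsed_fasta(unique: list[UniqueRead], path: str | Path) -> None:
    """Write collapsed tags as FASTA with count-annotated headers."""
    with open(path, "w") as fh:
        for i, ur in enumerate(unique, 1):
            tag = "_".join(f"{lib}:{n}" for lib, n in ur.counts.items())
            fh.write(f">read{i}_{tag}\n{ur.sequence}\n")
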