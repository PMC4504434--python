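"""Exact (mismatch-free) short-read mapping to both genome strands.

Reads that do not match the genome perfectly are rejected, as are reads
exceeding the multi-hit cap (default 16 genomic locations). The index is a
k-mer anchor table over both the forward genome and, implicitly, its
reverse complement via read reverse-complement lookup.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from ._seq import normalize, revcomp

__all__ = ["GenomeHit", "GenomeIndex", "map_reads", "load_genome"]


@dataclass(frozen=True)
class GenomeHit:
    """One exact placement of a read.

    Coordinates are 0-based half-open on the forward strand; for strand
    '-', the forward-strand genome slice equals the reverse complement of
    the read.
    """

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'


def load_genome(path: str | Path) -> dict[str, str]:
    genome = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genome[rec.id] = normalize(str(rec.seq))
    if not genome:
        raise ValueError(f"no sequences in genome FASTA {path}")
    return genome


class GenomeIndex:
    """Exact-lookup index over a genome (both strands).

    ``query(seq)`` returns all (chrom, start, end, strand) placements of
    ``seq``; strand '-' means the read matches the reverse complement of
    the forward genome at that interval. N never matches. A read whose
    reverse complement equals itself yields one hit per interval (the '+'
    placement is kept).
    """

    def __init__(self, genome: dict[str, str], k: int = 12):
        if not genome or all(len(s) == 0 for s in genome.values()):
            raise ValueError("empty genome")
        self.genome = {c: normalize(s) for c, s in genome.items()}
        self.k = k
        self._anchors: dict[str, list[tuple[str, int]]] = {}
        for chrom in sorted(self.genome):
            seq = self.genome[chrom]
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                self._anchors.setdefault(kmer, []).append((chrom, i))

    def _forward_hits(self, seq: str) -> list[tuple[str, int]]:
        k = self.k
        if len(seq) < k:
            # rare short-query path: direct scan
            out = []
            for chrom in sorted(self.genome):
                g = self.genome[chrom]
                start = g.find(seq)
                while start != -1:
                    out.append((chrom, start))
                    start = g.find(seq, start + 1)
            return out
        out = []
        for chrom, pos in self._anchors.get(seq[:k], []):
            if self.genome[chrom][pos : pos + len(seq)] == seq:
                out.append((chrom, pos))
        return out

    def query(self, seq: str) -> list[tuple[str, int, int, str]]:
        seq = normalize(seq)
        if not seq or "N" in seq:
            return []
        n = len(seq)
        hits = [(c, p, p + n, "+") for c, p in self._forward_hits(seq)]
        rc = revcomp(seq)
        if rc != seq:
            hits += [(c, p, p + n, "-") for c, p in self._forward_hits(rc)]
        hits.sort()
        return hits


def map_reads(
    sequences: dict[str, str],
    index: GenomeIndex,
    max_hits: int = 16,
) -> tuple[list[GenomeHit], dict[str, list[str]]]:
    """Map unique read sequences; enforce the multi-hit cap.

    ``sequences`` maps read id -> sequence. Returns (hits, rejected) where
    ``rejected`` has keys 'unmapped' and 'multi'.
    """
    hits: list[GenomeHit] = []
    rejected: dict[str, list[str]] = {"unmapped": [], "multi": []}
    for read_id in sorted(sequences):
        placements = index.query(sequences[read_id])
        if not placements:
            rejected["unmapped"].append(read_id)
        elif len(placements) > max_hits:
            rejected["multi"].append(read_id)
        else:
            for chrom, start, end, strand in placements:
                hits.append(GenomeHit(read_id, chrom, start, end, strand))
    return hits, rejected


def write_hits_tsv(hits: list[GenomeHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tstart\tend\tstrand\n")
        for h in hits:
            fh.write(f"{h.read_id}\t{h.chrom}\t{h.start}\t{h.end}\t{h.strand}\n")
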