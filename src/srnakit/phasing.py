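"""Phased siRNA (tasiRNA) locus detection and trigger assignment.

tasiRNA loci shed 21-nt siRNAs whose start positions fall in a fixed
register (mod 21) downstream of a miRNA-guided cleavage site. Detection
slides an 11-cycle (231-nt) window over occupied read starts, scores the
best register with an exact hypergeometric tail, merges overlapping
register-compatible windows, and assigns the phase-initiator miRNA whose
predicted cleavage point (opposite its 10th nucleotide) coincides with the
first phased position (D1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import comb

from ._seq import revcomp
from .config import PhasingConfig, TargetConfig
from .mapping import GenomeHit
from .targets import scan_targets

__all__ = [
    "PhasedCluster",
    "TasiRNA",
    "TriggerAssignment",
    "phasing_pvalue",
    "detect_phased_clusters",
    "merge_overlapping",
    "assign_phase_initiator",
    "name_tasirnas",
]


@dataclass
class PhasedCluster:
    """A phased 21-nt register locus (forward-strand, 0-based half-open).

    ``units`` holds the occupied in-register positions as (projected
    forward start, strand, sequence); minus-strand starts are already
    shifted +2 into the forward register (RNase III 2-nt overhang).
    """

    chrom: str
    start: int
    end: int
    register_offset: int
    m: int
    n: int
    k: int
    pvalue: float
    phase: int = 21
    units: list[tuple[int, str, str]] = field(default_factory=list)
    tas_start: int = 0
    tas_end: int = 0
    tas_id: str = ""

    @property
    def d1_start(self) -> int:
        return min(u[0] for u in self.units)

    @property
    def unit_span(self) -> tuple[int, int]:
        """Interval covered by the observed phased units."""
        return self.d1_start, max(u[0] for u in self.units) + self.phase


@dataclass
class TasiRNA:
    name: str
    sequence: str
    d_index: int
    side: str    # "5'" or "3'"
    strand: str  # '+' or '-'


@dataclass
class TriggerAssignment:
    mirna_id: str
    family: str
    tas_id: str
    site_start: int       # genomic forward coordinates of the trigger site
    site_end: int
    cleavage: int         # genomic forward coordinate of the D1 5' end
    hit_model: str        # 'one_hit' | 'two_hit'
    score: float = 0.0


def phasing_pvalue(m: int, n: int, k: int, phase: int = 21) -> float:
    """Hypergeometric upper tail P(X >= k) for phasing.

    Drawing ``n`` occupied start positions from ``phase * m`` positions of
    which ``m`` are in-register:
    ``sum_{x=k}^{min(n,m)} C(m,x) C((phase-1)m, n-x) / C(phase m, n)``.
    Exact big-integer arithmetic throughout.
    """
    if phase < 3:
        raise ValueError("phase must be >= 3")
    if k < 0 or k > n or k > m:
        raise ValueError(f"k={k} outside [0, min(n={n}, m={m})]")
    if n > phase * m:
        raise ValueError("n exceeds the position population")
    total = comb(phase * m, n)
    num = sum(comb(m, x) * comb((phase - 1) * m, n - x) for x in range(k, min(n, m) + 1))
    return float(Fraction(num, total))


def _projected_starts(
    hits: list[GenomeHit],
    counts: dict[str, int],
    lengths: dict[str, int],
    phase: int,
    min_abundance: int,
) -> dict[str, dict[int, list[tuple[str, str]]]]:
    """Per chrom: projected forward start -> [(strand, read_id)].

    Only reads of exactly ``phase`` nt with total abundance >=
    ``min_abundance`` participate; minus-strand starts shift +2.
    """
    occupied: dict[str, dict[int, list[tuple[str, str]]]] = {}
    for h in hits:
        if lengths.get(h.read_id) != phase:
            continue
        if counts.get(h.read_id, 0) < min_abundance:
            continue
        pos = h.start + 2 if h.strand == "-" else h.start
        occupied.setdefault(h.chrom, {}).setdefault(pos, []).append(
            (h.strand, h.read_id)
        )
    return occupied


def detect_phased_clusters(
    hits: list[GenomeHit],
    counts: dict[str, int],
    sequences: dict[str, str],
    cfg: PhasingConfig | None = None,
) -> list[PhasedCluster]:
    """Find significantly phased windows and merge them into clusters.

    ``counts`` maps read id -> total abundance across libraries;
    ``sequences`` maps read id -> read sequence. A window of
    ``phase * cycles`` nt is anchored at every occupied start; the register
    with maximal in-register occupancy (ties to the smaller offset) is
    scored; windows at p <= threshold are merged when overlapping with a
    compatible register.
    """
    cfg = cfg or PhasingConfig()
    if cfg.phase < 3:
        raise ValueError("phase must be >= 3")
    lengths = {rid: len(seq) for rid, seq in sequences.items()}
    occupied = _projected_starts(hits, counts, lengths, cfg.phase, cfg.min_abundance)
    window_len = cfg.phase * cfg.cycles

    raw: list[PhasedCluster] = []
    for chrom in sorted(occupied):
        starts = sorted(occupied[chrom])
        for anchor in starts:
            in_window = [s for s in starts if anchor <= s < anchor + window_len]
            n = len(in_window)
            by_offset: dict[int, list[int]] = {}
            for s in in_window:
                by_offset.setdefault((s - anchor) % cfg.phase, []).append(s)
            best_off = min(
                by_offset, key=lambda off: (-len(by_offset[off]), off)
            )
            k = len(by_offset[best_off])
            if k > cfg.cycles:
                k = cfg.cycles  # cannot occupy more register slots than exist
            p = phasing_pvalue(cfg.cycles, min(n, cfg.phase * cfg.cycles), k, cfg.phase)
            if p > cfg.p_threshold:
                continue
            units = []
            for s in by_offset[best_off]:
                for strand, rid in occupied[chrom][s]:
                    units.append((s, strand, sequences[rid]))
            raw.append(
                PhasedCluster(
                    chrom=chrom,
                    start=anchor,
                    end=anchor + window_len,
                    register_offset=(anchor + best_off) % cfg.phase,
                    m=cfg.cycles,
                    n=n,
                    k=k,
                    pvalue=p,
                    phase=cfg.phase,
                    units=units,
                )
            )
    merged = merge_overlapping(raw)
    for i, cl in enumerate(merged, 1):
        cl.tas_start = max(0, cl.start - cfg.tas_pad)
        cl.tas_end = cl.end + cfg.tas_pad
        cl.tas_id = f"TAS{i}"
    return merged


def merge_overlapping(clusters: list[PhasedCluster]) -> list[PhasedCluster]:
    """Merge overlapping or book-ended clusters with compatible registers
    (offsets equal mod phase); the merged p-value is the members' minimum,
    duplicate phased units are removed."""
    out: list[PhasedCluster] = []
    for cl in sorted(clusters, key=lambda c: (c.chrom, c.start, c.end)):
        prev = out[-1] if out else None
        if (
            prev is not None
            and prev.chrom == cl.chrom
            and cl.start <= prev.end
            and cl.register_offset == prev.register_offset
        ):
            prev.end = max(prev.end, cl.end)
            if cl.pvalue < prev.pvalue:
                prev.pvalue = cl.pvalue
                prev.m, prev.n, prev.k = cl.m, cl.n, cl.k
            seen = {(s, st) for s, st, _ in prev.units}
            for u in cl.units:
                if (u[0], u[1]) not in seen:
                    prev.units.append(u)
                    seen.add((u[0], u[1]))
            prev.units.sort()
        else:
            out.append(cl)
    return out


def assign_phase_initiator(
    cluster: PhasedCluster,
    candidate_mirnas: dict[str, str],
    tas_seq: str,
    families: dict[str, str] | None = None,
    target_cfg: TargetConfig | None = None,
    seq_start: int | None = None,
) -> TriggerAssignment | None:
    """Assign the miRNA whose cleavage point anchors the register.

    ``tas_seq`` is the forward TAS sequence starting at genomic position
    ``seq_start`` (defaults to ``cluster.tas_start``); it should extend
    upstream of D1 by at least a miRNA length so the trigger site — whose
    3' portion reaches up to 14 nt past the cleavage point — is fully
    contained. For every predicted target site the cleavage position is
    the transcript base paired to miRNA nucleotide 10 (from the miRNA 5'
    end); the assignment requires an exact match to the D1 5' end. The
    hit model is 'two_hit' when a second predicted site of the same
    family cleaves on a register boundary. All reported coordinates are
    genomic (forward strand).
    """
    target_cfg = target_cfg or TargetConfig()
    families = families or {}
    if seq_start is None:
        seq_start = cluster.tas_start
    d1 = cluster.d1_start
    best: TriggerAssignment | None = None
    for mid in sorted(candidate_mirnas):
        mseq = candidate_mirnas[mid]
        sites = scan_targets(mseq, tas_seq, target_cfg)
        cleavages = [
            (seq_start + site.start + (len(mseq) - 10), site) for site in sites
        ]
        anchored = [(c, s) for c, s in cleavages if c == d1]
        if not anchored:
            continue
        cleavage, site = min(anchored, key=lambda t: t[1].score)
        in_register = {
            c for c, _ in cleavages if (c - d1) % cluster.phase == 0
        }
        hit_model = "two_hit" if len(in_register) >= 2 else "one_hit"
        cand = TriggerAssignment(
            mirna_id=mid,
            family=families.get(mid, mid),
            tas_id=cluster.tas_id,
            site_start=seq_start + site.start,
            site_end=seq_start + site.end,
            cleavage=cleavage,
            hit_model=hit_model,
            score=site.score,
        )
        if best is None or cand.score < best.score:
            best = cand
    return best


def name_tasirnas(
    cluster: PhasedCluster,
    trigger: TriggerAssignment | None = None,
) -> list[TasiRNA]:
    """D-register nomenclature for the cluster's observed phased units.

    Registers are numbered D1, D2, ... outward from the cleavage site
    (the D1 5' end when a trigger is assigned, else the first occupied
    register position); a 5'/3' prefix gives the processing direction and
    (+)/(-) the strand. Duplicate sequences are removed.
    """
    if not cluster.units:
        return []
    cleavage = cluster.d1_start
    if trigger is not None:
        cleavage = trigger.cleavage
    if trigger is not None:
        fam = trigger.family
        fam_num = fam[3:] if fam.lower().startswith("mir") else fam
        label = f"{trigger.tas_id}-siR{fam_num}"
    else:
        label = cluster.tas_id or "TAS"

    out: list[TasiRNA] = []
    seen: set[str] = set()
    for start, strand, seq in sorted(cluster.units):
        if len(seq) != cluster.phase:
            continue
        delta = start - cleavage
        if delta % cluster.phase != 0:
            continue
        if delta >= 0:
            side, d = "3'", delta // cluster.phase + 1
        else:
            side, d = "5'", -delta // cluster.phase
        if seq in seen:
            continue
        seen.add(seq)
        out.append(
            TasiRNA(
                name=f"{label}-{side}D{d}({strand})",
                sequence=seq,
                d_index=d,
                side=side,
                strand=strand,
            )
        )
    return out
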