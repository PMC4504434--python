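"""Hairpin-based miRNA discovery from mapped small-RNA reads.

For each mapped read, a 100-nt-flanked genomic window is folded; the
longest unbranched stem-loop containing the read is isolated and refolded;
the miRNA* partner is located through the two-nucleotide 3'-overhang duplex
geometry; and the candidate must pass the annotation filters: hairpin
>= 60 nt, <= 4 duplex mismatches, <= 1 asymmetric bulge of <= 2 nt,
|MFEI| >= 0.85 and a dinucleotide-shuffle randomisation p <= 0.1. Accepted
matures are classified as known / conserved / novel against reference sets
and grouped into families.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from ._seq import gc_fraction, normalize, revcomp
from .config import MirnaConfig
from .fold import fold_rna, pair_table, randfold_pvalue
from .mapping import GenomeHit
from .preprocess import UniqueRead

__all__ = [
    "HairpinCandidate",
    "MiRNAAnnotation",
    "extract_window",
    "trim_hairpin",
    "find_star",
    "check_duplex",
    "compute_mfei",
    "classify_mature",
    "first_nt_bias",
    "call_mirnas",
]


@dataclass
class HairpinCandidate:
    """An isolated stem-loop containing the candidate mature read.

    ``window`` is the trimmed hairpin sequence (5'->3' with the read on it),
    ``structure`` its dot-bracket fold, intervals are 0-based half-open in
    hairpin coordinates. ``chrom``/``start``/``end``/``strand`` locate the
    hairpin on the forward genome strand.
    """

    window: str
    structure: str
    mfe: float
    mature: tuple[int, int]
    star: tuple[int, int] | None = None
    arm: str = ""  # '5p' or '3p'
    chrom: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"


@dataclass
class MiRNAAnnotation:
    mature: str
    star: str | None
    precursor: HairpinCandidate
    amfe: float
    mfei: float
    gc: float
    randfold_p: float
    klass: str = ""       # known | conserved | novel
    family: str = ""
    ref_mismatches: int | None = None
    abundance: int = 0    # max per-library raw count of the mature read
    counts: dict[str, int] = field(default_factory=dict)
    star_counts: dict[str, int] = field(default_factory=dict)
    locus_id: str = ""
    name: str = ""


def extract_window(
    hit: GenomeHit, genome: dict[str, str], flank: int = 100
) -> tuple[str, int, int, int]:
    """Extract the flanked window around a hit.

    Returns (window_seq, win_start, win_end, read_offset). The window is
    reverse-complemented for '-' hits so the read appears 5'->3' at
    ``read_offset`` in window coordinates; win_start/win_end stay on the
    forward strand.
    """
    seq = genome[hit.chrom]
    ws = max(0, hit.start - flank)
    we = min(len(seq), hit.end + flank)
    window = seq[ws:we]
    if hit.strand == "-":
        window = revcomp(window)
        offset = we - hit.end
    else:
        offset = hit.start - ws
    return window, ws, we, offset


def _hairpin_loops(pt: list[int]) -> list[tuple[int, int]]:
    """Closing pairs (i, j) with no paired position strictly between."""
    loops = []
    for i, j in ((i, j) for i, j in enumerate(pt) if j > i):
        if all(pt[x] == -1 for x in range(i + 1, j)):
            loops.append((i, j))
    return loops


def _extend_stem(
    pt: list[int], i: int, j: int, max_bridge: int = 6
) -> tuple[int, int]:
    """Grow the stem around loop-closing pair (i, j) outward while it stays
    unbranched (interior loops and bulges allowed). Extension stops when
    continuing would bridge more than ``max_bridge`` unpaired nt in one
    step — incidental flanking pairs past a large loop are not part of the
    precursor stem."""
    a, b = i, j
    n = len(pt)
    while True:
        p = a - 1
        while p >= 0 and pt[p] == -1:
            p -= 1
        q = b + 1
        while q < n and pt[q] == -1:
            q += 1
        if p >= 0 and q < n and pt[p] == q and (a - p - 1) + (q - b - 1) <= max_bridge:
            a, b = p, q
        else:
            return a, b


def _containing_stemloop(
    structure: str, read_iv: tuple[int, int], loop_tolerance: int = 3
) -> tuple[int, int, str] | None:
    """Find the unbranched stem-loop region containing the read.

    Returns (region_start, region_end, arm) with the region delimited by
    its outermost base pair, or None when the read lies in no stem-loop or
    spans the terminal loop. A read may reach at most ``loop_tolerance``
    nt into the terminal loop (terminal-pair fraying in the MFE structure
    can nudge the loop boundary past a duplex that is otherwise intact).
    """
    pt = pair_table(structure)
    rs, re_ = read_iv
    best = None
    for i, j in _hairpin_loops(pt):
        a, b = _extend_stem(pt, i, j)
        if not (a <= rs and re_ <= b + 1):
            continue
        if rs <= i and re_ <= i + 1 + loop_tolerance:
            arm = "5p"
        elif re_ > j and rs >= j - loop_tolerance:
            arm = "3p"
        else:
            continue  # read inside or spanning the terminal loop
        if best is None or (b - a) > (best[1] - best[0]):
            best = (a, b + 1, arm)
    return best


def trim_hairpin(
    structure: str,
    window: str,
    read_iv: tuple[int, int],
    min_hairpin: int = 60,
) -> HairpinCandidate | None:
    """Isolate and refold the stem-loop around the read.

    The stem-loop is first located in the folded window, then refolded in
    isolation (flanking sequence can distort the fold of the excised
    precursor) and re-validated. Returns None when no unbranched stem-loop
    of >= ``min_hairpin`` nt contains the read on one arm.
    """
    region = _containing_stemloop(structure, read_iv)
    if region is None:
        return None
    a, b, _ = region
    if b - a < min_hairpin:
        return None
    sub = window[a:b]
    sub_struct, sub_mfe = fold_rna(sub)
    sub_read = (read_iv[0] - a, read_iv[1] - a)
    region2 = _containing_stemloop(sub_struct, sub_read)
    if region2 is None:
        return None
    a2, b2, arm = region2
    if b2 - a2 < min_hairpin:
        return None
    # keep the refolded full excision; coordinates refer to `sub`
    return HairpinCandidate(
        window=sub,
        structure=sub_struct,
        mfe=sub_mfe,
        mature=sub_read,
        arm=arm,
    )


def find_star(cand: HairpinCandidate, slide: int = 2) -> tuple[int, int] | None:
    """Locate the miRNA* interval from the duplex 2-nt 3'-overhang geometry.

    The star 5' end pairs with (mature 3' end - 2); the star 3' end is the
    partner of the mature 5' start plus 2. Unpaired anchors may slide up to
    ``slide`` nt to the nearest paired base (compensated on the partner
    side); beyond that the star is undeclared.
    """
    pt = pair_table(cand.structure)
    ms, me = cand.mature
    n = len(cand.window)

    def _partner(pos: int) -> int | None:
        for off in sorted(range(-slide, slide + 1), key=lambda o: (abs(o), o)):
            p = pos + off
            if 0 <= p < n and pt[p] != -1:
                return pt[p] + off  # antiparallel compensation
        return None

    p1 = _partner(me - 3)  # pairs the (3' end - 2) position -> star 5' end
    p2 = _partner(ms)      # pairs the mature 5' start -> star 3' end - 2
    if p1 is None or p2 is None:
        return None
    ss, se = p1, p2 + 3
    ss = max(0, min(ss, n))
    se = max(0, min(se, n))
    if se - ss < 10:
        return None
    if not (se <= ms or ss >= me):  # star must not overlap the mature
        return None
    return ss, se


def check_duplex(
    cand: HairpinCandidate,
    max_mismatches: int = 4,
    max_bulge_count: int = 1,
    max_bulge_size: int = 2,
) -> tuple[bool, list[str], int, list[int]]:
    """Validate the miRNA/miRNA* duplex.

    Mismatches are mature duplex positions (3'-overhang excluded) not
    base-paired to a star position; symmetric interior loops count their
    mature-side length as mismatches. An asymmetric bulge is the length
    excess of one duplex side over the other between consecutive pairs.
    Returns (pass, reasons, n_mismatches, bulge_sizes).
    """
    if cand.star is None:
        raise ValueError("star interval not set")
    pt = pair_table(cand.structure)
    ms, me = cand.mature
    ss, se = cand.star
    duplex_end = me - 2  # the final 2 nt are the 3' overhang
    mismatches = 0
    paired_positions = []
    for p in range(ms, duplex_end):
        q = pt[p]
        if q == -1 or not (ss <= q < se):
            mismatches += 1
        else:
            paired_positions.append((p, q))

    bulges: list[int] = []
    for (p1, q1), (p2, q2) in zip(paired_positions, paired_positions[1:]):
        gap_m = p2 - p1 - 1
        gap_s = abs(q2 - q1) - 1
        if gap_m != gap_s:
            bulges.append(abs(gap_m - gap_s))
        # the symmetric part of an interior loop is already counted above
        # on the mature side; star-only symmetric excess is not re-counted

    reasons = []
    if mismatches > max_mismatches:
        reasons.append(f"mismatches>{max_mismatches}")
    if len(bulges) > max_bulge_count:
        reasons.append(f"bulges>{max_bulge_count}")
    if any(b > max_bulge_size for b in bulges):
        reasons.append(f"bulge>{max_bulge_size}nt")
    return (not reasons), reasons, mismatches, bulges


def compute_mfei(mfe: float, length: int, gc: float) -> tuple[float, float]:
    """Adjusted MFE (kcal/mol per 100 nt) and the MFE index.

    ``amfe = mfe / length * 100``; ``mfei = amfe / (gc * 100)``. The filter
    downstream compares |mfei| >= 0.85 (MFE is negative by convention).
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if gc <= 0 or gc >= 1:
        raise ValueError("MFEI undefined for GC fraction outside (0, 1)")
    amfe = mfe / length * 100.0
    mfei = amfe / (gc * 100.0)
    return amfe, mfei


def load_reference_set(path: str | Path) -> dict[str, str]:
    return {rec.id: normalize(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def _align_distance(a: str, b: str, max_shift: int = 2) -> int:
    """Best ungapped distance between two matures over small offsets,
    counting overhanging positions as mismatches."""
    la, lb = len(a), len(b)
    best = la + lb
    for s in range(-max_shift, max_shift + 1):
        lo = max(0, s)
        hi = min(la, s + lb)
        if hi <= lo:
            continue
        ham = sum(1 for i in range(lo, hi) if a[i] != b[i - s])
        overhang = (la - (hi - lo)) + (lb - (hi - lo))
        best = min(best, ham + overhang)
    return best


_FAMILY_RE = re.compile(r"(miR[A-Za-z]?\d+)", re.IGNORECASE)


def family_of(ref_name: str) -> str:
    m = _FAMILY_RE.search(ref_name)
    return m.group(1) if m else ref_name


def classify_mature(
    mature: str,
    same_species: dict[str, str],
    other_species: dict[str, str],
    max_mismatches: int = 3,
) -> tuple[str, str, int | None]:
    """Classify a mature against reference sets.

    <= ``max_mismatches`` against a same-species entry -> 'known'
    (inheriting its family); else the same bound against another species ->
    'conserved'; else 'novel' (family assigned later by clustering).
    Returns (class, family, mismatches_to_best_reference).
    """
    mature = normalize(mature)

    def _best(refs: dict[str, str]) -> tuple[int, str] | None:
        best = None
        for name in sorted(refs):
            seq = refs[name]
            if abs(len(seq) - len(mature)) > 2:
                continue
            d = _align_distance(mature, seq)
            if best is None or d < best[0]:
                best = (d, name)
        return best

    hit = _best(same_species)
    if hit is not None and hit[0] <= max_mismatches:
        return "known", family_of(hit[1]), hit[0]
    hit = _best(other_species)
    if hit is not None and hit[0] <= max_mismatches:
        return "conserved", family_of(hit[1]), hit[0]
    return "novel", "", None


def assign_novel_families(
    annotations: list[MiRNAAnnotation],
    family_mismatches: int = 2,
    prefix: str = "sbi",
) -> None:
    """Cluster novel matures into families by single linkage at
    <= ``family_mismatches`` mismatches; name ``novel-{prefix}-miR-{n}``
    with letter suffixes distinguishing loci within a family."""
    novel = [a for a in annotations if a.klass == "novel"]
    parent = list(range(len(novel)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(novel)):
        for j in range(i + 1, len(novel)):
            if _align_distance(novel[i].mature, novel[j].mature) <= family_mismatches:
                pi, pj = find(i), find(j)
                if pi != pj:
                    parent[pj] = pi

    cluster_no: dict[int, int] = {}
    members: dict[int, int] = {}
    for i, ann in enumerate(novel):
        root = find(i)
        if root not in cluster_no:
            cluster_no[root] = len(cluster_no) + 1
            members[root] = 0
        fam = f"novel-{prefix}-miR-{cluster_no[root]}"
        ann.family = fam
        suffix = chr(ord("a") + members[root]) if members[root] < 26 else f"-{members[root]+1}"
        size_hint = sum(1 for k in range(len(novel)) if find(k) == root)
        ann.name = fam + (suffix if size_hint > 1 else "")
        members[root] += 1
    for ann in annotations:
        if ann.klass != "novel" and not ann.name:
            ann.name = ann.family


def first_nt_bias(annotations: list[MiRNAAnnotation]) -> dict[str, dict[str, float]]:
    """Fraction of matures starting with each nucleotide (RNA letters),
    per class. Classes with no members are omitted."""
    table: dict[str, dict[str, float]] = {}
    by_class: dict[str, list[str]] = {}
    for ann in annotations:
        by_class.setdefault(ann.klass, []).append(ann.mature)
    for klass in sorted(by_class):
        seqs = by_class[klass]
        counts = {"U": 0, "A": 0, "G": 0, "C": 0}
        for s in seqs:
            first = "U" if s[0] == "T" else s[0]
            counts[first] += 1
        table[klass] = {nt: counts[nt] / len(seqs) for nt in "UAGC"}
    return table


def _locus_seed(seed: int, chrom: str, start: int, strand: str) -> int:
    return (seed ^ zlib.crc32(f"{chrom}:{start}:{strand}".encode())) & 0x7FFFFFFF


def _to_forward(ws: int, we: int, strand: str, iv: tuple[int, int]) -> tuple[int, int]:
    """Window-local interval -> forward-strand genomic interval."""
    if strand == "+":
        return ws + iv[0], ws + iv[1]
    wlen = we - ws
    return ws + (wlen - iv[1]), ws + (wlen - iv[0])


def call_mirnas(
    unique_reads: list[UniqueRead],
    hits: list[GenomeHit],
    genome: dict[str, str],
    cfg: MirnaConfig,
    same_species: dict[str, str] | None = None,
    other_species: dict[str, str] | None = None,
    seed: int = 0,
) -> tuple[list[MiRNAAnnotation], list[dict]]:
    """Full discovery pass: extract -> fold -> trim -> star -> duplex ->
    MFEI -> randfold -> classify.

    Each genomic locus is reported once, seeded by its most abundant read
    (ties broken by sequence); reads falling inside an accepted precursor
    (the miRNA*, isomiRs) do not found new loci. Rejected candidates are
    returned with the first failing rule.
    """
    same_species = same_species or {}
    other_species = other_species or {}
    by_id = {f"read{i}": ur for i, ur in enumerate(unique_reads, 1)}
    seq_to_read = {ur.sequence: ur for ur in unique_reads}
    hits_by_read: dict[str, list[GenomeHit]] = {}
    for h in hits:
        hits_by_read.setdefault(h.read_id, []).append(h)

    order = sorted(
        hits_by_read,
        key=lambda rid: (-max(by_id[rid].counts.values()), by_id[rid].sequence),
    )
    claimed: dict[str, list[tuple[int, int]]] = {}
    annotations: list[MiRNAAnnotation] = []
    rejects: list[dict] = []

    def _claimed(chrom: str, start: int, end: int) -> bool:
        return any(start < e and s < end for s, e in claimed.get(chrom, []))

    for rid in order:
        ur = by_id[rid]
        if max(ur.counts.values()) < cfg.min_abundance:
            continue
        for hit in sorted(hits_by_read[rid], key=lambda h: (h.chrom, h.start, h.strand)):
            if _claimed(hit.chrom, hit.start, hit.end):
                continue

            def _reject(rule: str) -> None:
                rejects.append(
                    {"read_id": rid, "sequence": ur.sequence, "chrom": hit.chrom,
                     "start": hit.start, "strand": hit.strand, "rule": rule}
                )

            window, ws, we, offset = extract_window(hit, genome, cfg.flank)
            structure, _ = fold_rna(window)
            read_iv = (offset, offset + (hit.end - hit.start))
            cand = trim_hairpin(structure, window, read_iv, cfg.min_hairpin)
            if cand is None:
                _reject("no_hairpin")
                continue
            star = find_star(cand)
            if star is None:
                _reject("no_star")
                continue
            cand.star = star
            ok, reasons, _, _ = check_duplex(
                cand, cfg.max_duplex_mismatches, cfg.max_bulge_count, cfg.max_bulge_size
            )
            if not ok:
                _reject(";".join(reasons))
                continue
            gc = gc_fraction(cand.window)
            amfe, mfei = compute_mfei(cand.mfe, len(cand.window), gc)
            if cfg.enable_mfei and abs(mfei) < cfg.min_abs_mfei:
                _reject("mfei")
                continue
            # locate the trimmed hairpin on the forward strand: the trim
            # offset inside the extracted window is recoverable from the
            # mature position (read_iv within window, cand.mature within sub)
            trim_off = read_iv[0] - cand.mature[0]
            hp_iv = (trim_off, trim_off + len(cand.window))
            g_start, g_end = _to_forward(ws, we, hit.strand, hp_iv)
            cand.chrom, cand.start, cand.end, cand.strand = (
                hit.chrom, g_start, g_end, hit.strand,
            )
            if cfg.enable_randfold:
                p = randfold_pvalue(
                    cand.window,
                    cfg.randfold_shuffles,
                    _locus_seed(seed, hit.chrom, g_start, hit.strand),
                )
                if p > cfg.randfold_cutoff:
                    _reject("randfold")
                    continue
            else:
                p = 1.0

            star_seq = cand.window[star[0] : star[1]]
            star_read = seq_to_read.get(star_seq)
            klass, family, ref_mm = classify_mature(
                ur.sequence, same_species, other_species, cfg.max_ref_mismatches
            )
            ann = MiRNAAnnotation(
                mature=ur.sequence,
                star=star_seq if star_read is not None else None,
                precursor=cand,
                amfe=amfe,
                mfei=mfei,
                gc=gc,
                randfold_p=p,
                klass=klass,
                family=family,
                ref_mismatches=ref_mm,
                abundance=max(ur.counts.values()),
                counts=dict(ur.counts),
                star_counts=dict(star_read.counts) if star_read else {},
                locus_id=f"{hit.chrom}:{g_start}-{g_end}({hit.strand})",
            )
            annotations.append(ann)
            claimed.setdefault(hit.chrom, []).append((g_start, g_end))

    assign_novel_families(annotations, cfg.family_mismatches, cfg.novel_prefix)
    return annotations, rejects
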