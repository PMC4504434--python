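"""Synthetic genome and small-RNA library generator with known ground truth.

The generator plants three kinds of loci in a random genome:

* MIR loci — stem-loop precursors whose mature/star duplex obeys the plant
  annotation rules (2-nt 3' overhangs, <= 4 mismatches, at most one small
  bulge), with GC-reinforced stems so the designed fold is the MFE fold;
* TAS loci — a trigger-miRNA target site whose cleavage point (opposite
  trigger nucleotide 10) starts a run of >= 4 consecutive 21-nt phased
  units, optionally with a second in-register site (two-hit configuration);
* contaminant loci — verbatim copies of the shipped synthetic t/rRNA
  fixtures, so the contaminant filter removes their reads.

Four libraries (2 genotypes x control/drought) are simulated with
per-locus Poisson counts; drought multiplies each locus's mean by a
class-specific factor per genotype, defining the expected drought-response
category of every planted miRNA.
"""

from __future__ import annotations

import importlib.resources
import random
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._seq import revcomp

__all__ = [
    "SimConfig",
    "GroundTruth",
    "PlantedMir",
    "PlantedTas",
    "build_genome",
    "simulate_counts",
    "simulate_libraries",
    "simulate_to_dir",
    "LIBRARIES",
    "PlacementError",
]

# library ids: 2 genotypes (G1 tolerant, G2 susceptible) x control/drought
LIBRARIES = ("G1_ctrl", "G1_stress", "G2_ctrl", "G2_stress")

DE_CLASSES = ("up_both", "down_both", "up_T_down_S", "down_T_up_S", "unchanged", "nd")


class PlacementError(ValueError):
    """Genome too short to place the requested loci without overlap."""


def _default_proportions() -> dict[str, float]:
    return {
        "up_both": 0.20,
        "down_both": 0.20,
        "up_T_down_S": 0.15,
        "down_T_up_S": 0.15,
        "unchanged": 0.20,
        "nd": 0.10,
    }


def _default_multipliers() -> dict[str, tuple[float, float]]:
    # stress-library mean multiplier per (G1, G2); 4x gives a 2 log2-fold
    # effect, comfortably past the >= 2-fold reporting threshold
    return {
        "up_both": (4.0, 4.0),
        "down_both": (0.25, 0.25),
        "up_T_down_S": (4.0, 0.25),
        "down_T_up_S": (0.25, 4.0),
        "unchanged": (1.0, 1.0),
        "nd": (0.0, 0.25),  # G1 silent entirely; G2 down-regulated
    }


@dataclass
class SimConfig:
    seed: int = 0
    genome_length: int = 100_000
    n_mir_loci: int = 20
    n_tas_loci: int = 5
    n_contaminant_loci: int = 5
    n_background_fragments: int = 500
    mature_length_range: tuple[int, int] = (20, 24)
    stem_mismatches_range: tuple[int, int] = (0, 4)
    stem_extension_range: tuple[int, int] = (10, 18)
    loop_length_range: tuple[int, int] = (8, 20)
    bulge_probability: float = 0.2   # at most one designed 1-nt star bulge
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    read_length: int = 36
    base_expression_range: tuple[float, float] = (20.0, 100.0)
    star_fraction: float = 0.10      # star read mean as fraction of mature
    bad_read_fraction: float = 0.02  # reads violating N / Q<13 rules
    tas_units_range: tuple[int, int] = (4, 6)
    two_hit_fraction: float = 0.4
    stress_multipliers: dict[str, tuple[float, float]] = field(
        default_factory=_default_multipliers
    )
    de_class_proportions: dict[str, float] = field(
        default_factory=_default_proportions
    )

    def validate(self) -> None:
        total = sum(self.de_class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"de_class_proportions sum to {total}, not 1")
        lo, hi = self.stem_mismatches_range
        if not (0 <= lo <= hi <= 4):
            raise ValueError("stem_mismatches_range must lie within [0, 4]")
        lo, hi = self.mature_length_range
        if not (16 <= lo <= hi <= 30):
            raise ValueError("mature_length_range must lie within [16, 30]")
        if self.loop_length_range[0] < 8:
            raise ValueError("minimum loop length is 8 nt")


@dataclass
class PlantedMir:
    locus_id: str
    chrom: str
    strand: str
    precursor: tuple[int, int]        # forward-strand genomic interval
    mature_seq: str                   # 5'->3' as transcribed
    mature_iv: tuple[int, int]        # forward-strand genomic interval
    star_seq: str
    star_iv: tuple[int, int]
    de_class: str
    expected_means: dict[str, float]  # library -> Poisson mean


@dataclass
class PlantedTas:
    locus_id: str
    chrom: str
    interval: tuple[int, int]
    register_offset: int              # cleavage position mod 21
    cleavage: int                     # genomic forward position of D1 start
    trigger_mirna_id: str
    trigger_seq: str
    n_units: int
    hit_model: str                    # 'one_hit' | 'two_hit'
    unit_starts: list[int]
    unit_seqs: list[str]
    expected_means: dict[str, float]


@dataclass
class BackgroundLocus:
    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str
    seq: str
    expected_means: dict[str, float]


@dataclass
class GroundTruth:
    planted_mirs: list[PlantedMir] = field(default_factory=list)
    planted_tas: list[PlantedTas] = field(default_factory=list)
    contaminants: list[tuple[str, int, int, str]] = field(default_factory=list)
    contaminant_frags: list[BackgroundLocus] = field(default_factory=list)
    background: list[BackgroundLocus] = field(default_factory=list)


def contaminant_fixture_path() -> Path:
    return Path(
        importlib.resources.files("srnakit") / "data" / "contaminants_synthetic.fa"
    )


def reference_fixture_paths() -> tuple[Path, Path]:
    base = importlib.resources.files("srnakit") / "data"
    return (
        Path(base / "mirbase_same_species_synthetic.fa"),
        Path(base / "mirbase_other_species_synthetic.fa"),
    )


def _weighted_seq(rng: random.Random, n: int, gc: float = 0.5) -> str:
    w = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choices("ACGT", weights=w, k=n))


def _expected_means(
    cfg: SimConfig, rng: random.Random, de_class: str
) -> tuple[float, dict[str, float]]:
    lam = rng.uniform(*cfg.base_expression_range)
    m1, m2 = cfg.stress_multipliers[de_class]
    if de_class == "nd":
        means = {
            "G1_ctrl": 0.0,
            "G1_stress": 0.0,
            "G2_ctrl": lam,
            "G2_stress": lam * m2,
        }
    else:
        means = {
            "G1_ctrl": lam,
            "G1_stress": lam * m1,
            "G2_ctrl": lam,
            "G2_stress": lam * m2,
        }
    return lam, means


class _Placer:
    """Non-overlapping interval placement with a guard gap."""

    def __init__(self, length: int, rng: random.Random, gap: int = 250):
        self.length = length
        self.rng = rng
        self.gap = gap
        self.claimed: list[tuple[int, int]] = []

    def place(self, size: int, tries: int = 2000) -> int:
        if size > self.length:
            raise PlacementError(
                f"locus of {size} nt cannot fit in a {self.length} nt genome"
            )
        for _ in range(tries):
            start = self.rng.randrange(0, self.length - size + 1)
            lo, hi = start - self.gap, start + size + self.gap
            if all(hi <= s or e <= lo for s, e in self.claimed):
                self.claimed.append((start, start + size))
                return start
        raise PlacementError(
            f"could not place a {size} nt locus after {tries} tries "
            f"(genome too short or too crowded)"
        )


def _design_hairpin(
    cfg: SimConfig, rng: random.Random
) -> tuple[str, tuple[int, int], tuple[int, int], str, str]:
    """Design one precursor.

    Returns (precursor_seq, mature_iv, star_iv, star_seq, arm) with
    intervals in precursor coordinates (5'->3' of the precursor).

    The stem is GC-biased, the duplex-end pairs are forced to G/C so the
    MFE fold reproduces the designed pairing, designed mismatches are
    identity substitutions (which cannot pair, not even as G:U), and an
    optional single 1-nt bulge is inserted on the star side.
    """
    L = rng.randint(*cfg.mature_length_range)
    ext = rng.randint(*cfg.stem_extension_range)
    loop_len = rng.randint(*cfg.loop_length_range)
    n_mm = rng.randint(*cfg.stem_mismatches_range)

    mature = list(_weighted_seq(rng, L, gc=0.6))
    # first-nucleotide bias toward U, as observed for plant matures
    if rng.random() < 0.6:
        mature[0] = "T"
    # G/C clamps where the duplex geometry is anchored
    for pos in (1, 2, L - 3, L - 2, L - 1):
        mature[pos] = rng.choice("GC")
    mature = "".join(mature)

    mm_positions: list[int] = []
    candidates = list(range(4, L - 5))
    rng.shuffle(candidates)
    for i in candidates:
        if len(mm_positions) == n_mm:
            break
        if all(abs(i - p) >= 4 for p in mm_positions):
            mm_positions.append(i)

    bulge_at = None
    if cfg.bulge_probability > 0 and rng.random() < cfg.bulge_probability:
        bulge_candidates = [
            j for j in range(4, L - 4)
            if all(abs((L - 1 - j) - i) >= 4 for i in mm_positions)
        ]
        if bulge_candidates:
            bulge_at = rng.choice(bulge_candidates)

    # G/C-clamp the pairs flanking every designed defect so the MFE fold
    # keeps the defect as a local 1x1 loop / 1-nt bulge instead of opening
    # the neighbourhood (isolated weak pairs do not close thermodynamically)
    mature = list(mature)
    for i in mm_positions:
        for nb in (i - 1, i + 1):
            if 0 <= nb < L:
                mature[nb] = rng.choice("GC")
    if bulge_at is not None:
        for nb in (L - 1 - bulge_at, L - bulge_at):
            if 0 <= nb < L:
                mature[nb] = rng.choice("GC")
    mature = "".join(mature)

    star = list(revcomp(mature))  # star index j pairs mature index L-1-j
    for i in sorted(mm_positions):
        star[L - 1 - i] = mature[i]  # identity: no WC pair, no wobble
    if bulge_at is not None:
        star.insert(bulge_at, mature[L - 1 - bulge_at])  # unpairable base
    star = "".join(star)
    Ls = len(star)

    ext5 = list(_weighted_seq(rng, ext, gc=0.6))
    for pos in (0, 1, ext - 2, ext - 1):
        ext5[pos] = rng.choice("GC")
    ext5 = "".join(ext5)
    ext3 = revcomp(ext5)
    # loop over {A, C}: cannot pair with itself, keeps the terminal loop open
    loop = "".join(rng.choices("AC", weights=[0.7, 0.3], k=loop_len))

    arm = rng.choice(["5p", "3p"])
    e = len(ext5)
    if arm == "5p":
        prec = ext5 + mature + loop + star + ext3
        mature_iv = (e, e + L)
        star_iv = (e + L + loop_len + 2, e + L + loop_len + Ls + 2)
    else:
        prec = ext5 + star + loop + mature + ext3
        mature_iv = (e + Ls + loop_len, e + Ls + loop_len + L)
        star_iv = (e + 2, e + Ls + 2)
    star_observed = prec[star_iv[0] : star_iv[1]]
    return prec, mature_iv, star_iv, star_observed, arm


def build_genome(cfg: SimConfig) -> tuple[dict[str, str], GroundTruth]:
    """Generate the genome and its ground truth. Deterministic per seed."""
    cfg.validate()
    rng = random.Random(cfg.seed)
    chrom = "chr1"
    genome = list(_weighted_seq(rng, cfg.genome_length, gc=0.5))
    placer = _Placer(cfg.genome_length, rng)
    truth = GroundTruth()

    # --- de_class assignment: deterministic rotation matching proportions
    classes: list[str] = []
    for name in DE_CLASSES:
        classes += [name] * round(cfg.de_class_proportions.get(name, 0.0) * cfg.n_mir_loci)
    while len(classes) < cfg.n_mir_loci:
        classes.append("unchanged")
    classes = classes[: cfg.n_mir_loci]
    rng.shuffle(classes)

    # --- MIR loci
    for i in range(cfg.n_mir_loci):
        prec, m_iv, s_iv, star_seq, arm = _design_hairpin(cfg, rng)
        strand = rng.choice("+-")
        start = placer.place(len(prec))
        placed = prec if strand == "+" else revcomp(prec)
        genome[start : start + len(prec)] = list(placed)
        n = len(prec)
        if strand == "+":
            g_m = (start + m_iv[0], start + m_iv[1])
            g_s = (start + s_iv[0], start + s_iv[1])
        else:
            g_m = (start + n - m_iv[1], start + n - m_iv[0])
            g_s = (start + n - s_iv[1], start + n - s_iv[0])
        de_class = classes[i]
        _, means = _expected_means(cfg, rng, de_class)
        truth.planted_mirs.append(
            PlantedMir(
                locus_id=f"MIR{i+1:03d}",
                chrom=chrom,
                strand=strand,
                precursor=(start, start + n),
                mature_seq=prec[m_iv[0] : m_iv[1]],
                mature_iv=g_m,
                star_seq=star_seq,
                star_iv=g_s,
                de_class=de_class,
                expected_means=means,
            )
        )

    # --- TAS loci (triggered by an always-expressed planted miRNA)
    trigger_pool = [
        m for m in truth.planted_mirs if m.de_class in ("unchanged", "up_both")
    ] or truth.planted_mirs
    if cfg.n_tas_loci > 0 and not trigger_pool:
        raise PlacementError("TAS loci require at least one MIR locus as trigger")
    for i in range(cfg.n_tas_loci):
        trigger = trigger_pool[i % len(trigger_pool)]
        tseq = trigger.mature_seq
        Lt = len(tseq)
        n_units = rng.randint(*cfg.tas_units_range)
        two_hit = rng.random() < cfg.two_hit_fraction
        site = revcomp(tseq)
        pad5, pad3 = 15, 15
        # region layout: pad5 | site | ... phased units ... | (site2) | pad3
        cleave_local = pad5 + (Lt - 10)
        units_end = cleave_local + 21 * n_units
        site2_local = None
        if two_hit:
            site2_local = cleave_local + 21 * (n_units + 1) - (Lt - 10)
            region_len = site2_local + Lt + pad3
        else:
            region_len = units_end + pad3
        region = list(_weighted_seq(rng, region_len, gc=0.5))
        region[pad5 : pad5 + Lt] = list(site)
        if site2_local is not None:
            region[site2_local : site2_local + Lt] = list(site)
        region = "".join(region)
        start = placer.place(len(region))
        genome[start : start + len(region)] = list(region)
        cleavage = start + cleave_local
        unit_starts = [cleavage + 21 * k for k in range(n_units)]
        unit_seqs = [region[s - start : s - start + 21] for s in unit_starts]
        _, means = _expected_means(cfg, rng, "unchanged")
        truth.planted_tas.append(
            PlantedTas(
                locus_id=f"TAS{i+1:02d}",
                chrom=chrom,
                interval=(start, start + len(region)),
                register_offset=cleavage % 21,
                cleavage=cleavage,
                trigger_mirna_id=trigger.locus_id,
                trigger_seq=tseq,
                n_units=n_units,
                hit_model="two_hit" if two_hit else "one_hit",
                unit_starts=unit_starts,
                unit_seqs=unit_seqs,
                expected_means=means,
            )
        )

    # --- contaminant loci: verbatim copies of the fixture sequences
    fixture = [
        str(rec.seq).upper()
        for rec in SeqIO.parse(str(contaminant_fixture_path()), "fasta")
    ]
    for i in range(cfg.n_contaminant_loci):
        cseq = fixture[i % len(fixture)]
        start = placer.place(len(cseq))
        genome[start : start + len(cseq)] = list(cseq)
        truth.contaminants.append((chrom, start, start + len(cseq), "+"))
        # a few expressed fragments per contaminant locus
        for j in range(3):
            flen = rng.randint(18, 26)
            off = rng.randrange(0, len(cseq) - flen + 1)
            _, means = _expected_means(cfg, rng, "unchanged")
            truth.contaminant_frags.append(
                BackgroundLocus(
                    locus_id=f"CONT{i+1:02d}_{j+1}",
                    chrom=chrom,
                    start=start + off,
                    end=start + off + flen,
                    strand="+",
                    seq=cseq[off : off + flen],
                    expected_means=means,
                )
            )

    # --- background fragments: degradation-like reads of 16-30 nt
    genome_str = "".join(genome)
    for i in range(cfg.n_background_fragments):
        flen = rng.randint(16, 30)
        for _ in range(200):
            start = rng.randrange(0, cfg.genome_length - flen + 1)
            lo, hi = start - 5, start + flen + 5
            if all(hi <= s or e <= lo for s, e in placer.claimed):
                break
        else:
            raise PlacementError("no room for background fragments")
        strand = rng.choice("+-")
        seq = genome_str[start : start + flen]
        if strand == "-":
            seq = revcomp(seq)
        _, means = _expected_means(cfg, rng, "unchanged")
        truth.background.append(
            BackgroundLocus(
                locus_id=f"BG{i+1:04d}",
                chrom=chrom,
                start=start,
                end=start + flen,
                strand=strand,
                seq=seq,
                expected_means=means,
            )
        )
    return {chrom: genome_str}, truth


def _emitted_sequences(truth: GroundTruth, cfg: SimConfig):
    """Yield (locus_id, sequence, means) for every expressed sRNA species."""
    for m in truth.planted_mirs:
        yield m.locus_id, m.mature_seq, m.expected_means
        star_means = {
            lib: mu * cfg.star_fraction for lib, mu in m.expected_means.items()
        }
        yield m.locus_id + "*", m.star_seq, star_means
    for t in truth.planted_tas:
        for k, seq in enumerate(t.unit_seqs, 1):
            yield f"{t.locus_id}_D{k}", seq, t.expected_means
    for c in truth.contaminant_frags:
        yield c.locus_id, c.seq, c.expected_means
    for b in truth.background:
        yield b.locus_id, b.seq, b.expected_means


def simulate_counts(
    means: dict[str, float], rng: np.random.Generator
) -> dict[str, int]:
    """Poisson counts per library from per-library means."""
    return {lib: int(rng.poisson(mu)) for lib, mu in sorted(means.items())}


def simulate_libraries(
    truth: GroundTruth, cfg: SimConfig
) -> tuple[dict[str, list[tuple[str, str, str]]], pd.DataFrame]:
    """Simulate 4 FASTQ libraries.

    Returns (reads, expected_counts) where ``reads[lib]`` is a list of
    (read_id, sequence, quality) and ``expected_counts`` records the
    Poisson mean of every locus x library. Each read is the sRNA followed
    by the 3' adapter, truncated to ``cfg.read_length``; a configurable
    fraction carries an injected N or seven sub-Q13 bases to exercise the
    quality filter.
    """
    nrng = np.random.default_rng(cfg.seed + 1)
    brng = random.Random(cfg.seed + 2)
    reads: dict[str, list[tuple[str, str, str]]] = {lib: [] for lib in LIBRARIES}
    rows = []
    for locus_id, seq, means in _emitted_sequences(truth, cfg):
        row = {"locus_id": locus_id, "sequence": seq}
        counts = simulate_counts({lib: means.get(lib, 0.0) for lib in LIBRARIES}, nrng)
        for lib in LIBRARIES:
            row[f"mean_{lib}"] = means.get(lib, 0.0)
            for i in range(counts[lib]):
                full = (seq + cfg.adapter)[: cfg.read_length]
                full = full.ljust(cfg.read_length, "A")
                qual = "I" * len(full)
                if brng.random() < cfg.bad_read_fraction:
                    if brng.random() < 0.5:
                        pos = brng.randrange(0, len(seq))
                        full = full[:pos] + "N" + full[pos + 1 :]
                    else:
                        positions = brng.sample(range(len(full)), 7)
                        q = list(qual)
                        for p in positions:
                            q[p] = "+"  # Phred 10 < 13
                        qual = "".join(q)
                reads[lib].append((f"{locus_id}_{lib}_{i+1}", full, qual))
        rows.append(row)
    expected = pd.DataFrame(rows)
    return reads, expected


# ---------------------------------------------------------------------------
# serialisation


def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_fastq(reads: list[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def save_truth(truth: GroundTruth, cfg: SimConfig, out_dir: str | Path) -> None:
    out = Path(out_dir)
    mir_rows = []
    for m in truth.planted_mirs:
        mir_rows.append(
            {
                "locus_id": m.locus_id, "chrom": m.chrom, "strand": m.strand,
                "prec_start": m.precursor[0], "prec_end": m.precursor[1],
                "mature_seq": m.mature_seq,
                "mature_start": m.mature_iv[0], "mature_end": m.mature_iv[1],
                "star_seq": m.star_seq,
                "star_start": m.star_iv[0], "star_end": m.star_iv[1],
                "de_class": m.de_class,
                **{f"mean_{lib}": m.expected_means.get(lib, 0.0) for lib in LIBRARIES},
            }
        )
    pd.DataFrame(mir_rows).to_csv(out / "truth_mir.tsv", sep="\t", index=False)
    tas_rows = []
    for t in truth.planted_tas:
        tas_rows.append(
            {
                "locus_id": t.locus_id, "chrom": t.chrom,
                "start": t.interval[0], "end": t.interval[1],
                "register_offset": t.register_offset, "cleavage": t.cleavage,
                "trigger_mirna_id": t.trigger_mirna_id,
                "trigger_seq": t.trigger_seq,
                "n_units": t.n_units, "hit_model": t.hit_model,
                "unit_starts": ",".join(map(str, t.unit_starts)),
                "unit_seqs": ",".join(t.unit_seqs),
                **{f"mean_{lib}": t.expected_means.get(lib, 0.0) for lib in LIBRARIES},
            }
        )
    pd.DataFrame(tas_rows).to_csv(out / "truth_tas.tsv", sep="\t", index=False)


def load_truth(out_dir: str | Path) -> GroundTruth:
    out = Path(out_dir)
    truth = GroundTruth()
    mir = pd.read_csv(out / "truth_mir.tsv", sep="\t")
    for _, r in mir.iterrows():
        truth.planted_mirs.append(
            PlantedMir(
                locus_id=r.locus_id, chrom=r.chrom, strand=r.strand,
                precursor=(int(r.prec_start), int(r.prec_end)),
                mature_seq=r.mature_seq,
                mature_iv=(int(r.mature_start), int(r.mature_end)),
                star_seq=r.star_seq,
                star_iv=(int(r.star_start), int(r.star_end)),
                de_class=r.de_class,
                expected_means={lib: float(r[f"mean_{lib}"]) for lib in LIBRARIES},
            )
        )
    tas = pd.read_csv(out / "truth_tas.tsv", sep="\t")
    for _, r in tas.iterrows():
        truth.planted_tas.append(
            PlantedTas(
                locus_id=r.locus_id, chrom=r.chrom,
                interval=(int(r.start), int(r.end)),
                register_offset=int(r.register_offset), cleavage=int(r.cleavage),
                trigger_mirna_id=r.trigger_mirna_id, trigger_seq=r.trigger_seq,
                n_units=int(r.n_units), hit_model=r.hit_model,
                unit_starts=[int(x) for x in str(r.unit_starts).split(",")],
                unit_seqs=str(r.unit_seqs).split(","),
                expected_means={lib: float(r[f"mean_{lib}"]) for lib in LIBRARIES},
            )
        )
    return truth


def write_loci_gff3(truth: GroundTruth, path: str | Path) -> None:
    """Planted loci as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in truth.planted_mirs:
            s, e = m.precursor
            fh.write(
                f"{m.chrom}\tsimkit\tmiRNA_primary_transcript\t{s+1}\t{e}\t.\t"
                f"{m.strand}\t.\tID={m.locus_id};de_class={m.de_class}\n"
            )
            fh.write(
                f"{m.chrom}\tsimkit\tmiRNA\t{m.mature_iv[0]+1}\t{m.mature_iv[1]}\t.\t"
                f"{m.strand}\t.\tID={m.locus_id}.mature;Parent={m.locus_id}\n"
            )
        for t in truth.planted_tas:
            s, e = t.interval
            fh.write(
                f"{t.chrom}\tsimkit\ttasiRNA_locus\t{s+1}\t{e}\t.\t+\t.\t"
                f"ID={t.locus_id};trigger={t.trigger_mirna_id};"
                f"hit_model={t.hit_model}\n"
            )
        for chrom, s, e, strand in truth.contaminants:
            fh.write(
                f"{chrom}\tsimkit\tcontaminant\t{s+1}\t{e}\t.\t{strand}\t.\t.\n"
            )


def _write_transcripts(
    genome: dict[str, str], truth: GroundTruth, cfg: SimConfig, path: Path
) -> None:
    """TAS transcripts (padded locus sequence) plus decoys carrying one
    perfect target site each, for the target-prediction stage."""
    rng = random.Random(cfg.seed + 3)
    with open(path, "w") as fh:
        for t in truth.planted_tas:
            s, e = t.interval
            seq = genome[t.chrom][max(0, s - 20) : e + 20]
            fh.write(f">{t.locus_id}_transcript\n{seq}\n")
        for i, m in enumerate(truth.planted_mirs[: min(10, len(truth.planted_mirs))]):
            body = list(_weighted_seq(rng, 300, gc=0.5))
            pos = rng.randrange(50, 250 - len(m.mature_seq))
            body[pos : pos + len(m.mature_seq)] = list(revcomp(m.mature_seq))
            fh.write(f">target_decoy_{i+1}_{m.locus_id}\n{''.join(body)}\n")


def simulate_to_dir(cfg: SimConfig, out_dir: str | Path) -> GroundTruth:
    """Run the full simulation and write all artefacts.

    Writes genome.fa, lib_{G1,G2}_{ctrl,stress}.fastq, truth_mir.tsv,
    truth_tas.tsv, expected_counts.tsv, loci.gff3 and transcripts.fa.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, truth = build_genome(cfg)
    write_fasta(genome, out / "genome.fa")
    reads, expected = simulate_libraries(truth, cfg)
    for lib in LIBRARIES:
        write_fastq(reads[lib], out / f"lib_{lib}.fastq")
    expected.to_csv(out / "expected_counts.tsv", sep="\t", index=False)
    save_truth(truth, cfg, out)
    write_loci_gff3(truth, out / "loci.gff3")
    _write_transcripts(genome, truth, cfg, out / "transcripts.fa")
    return truth
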