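"""Window extraction, hairpin trimming, duplex validation, MFEI,
classification and the discovery orchestration."""

import pytest

from srnakit._seq import revcomp
from srnakit.config import MirnaConfig
from srnakit.fold import fold_rna
from srnakit.mapping import GenomeHit, GenomeIndex, map_reads
from srnakit.mirna import (
    HairpinCandidate,
    call_mirnas,
    check_duplex,
    classify_mature,
    compute_mfei,
    extract_window,
    find_star,
    first_nt_bias,
    trim_hairpin,
)
from srnakit.preprocess import UniqueRead

STEM26 = "GCAGTCGACCTGGCATGCCAGTCGGC"
HP60 = STEM26 + "AACAACAA" + revcomp(STEM26)   # clean 60-nt hairpin
HP59 = STEM26 + "AACAACA" + revcomp(STEM26)    # 59 nt: below the minimum


class TestExtractWindow:
    def test_plain_arithmetic(self):
        genome = {"c": "A" * 10_000}
        w, ws, we, off = extract_window(GenomeHit("r", "c", 500, 521, "+"), genome, 100)
        assert (ws, we) == (400, 621) and len(w) == 221 and off == 100

    def test_left_clip(self):
        genome = {"c": "A" * 10_000}
        w, ws, we, off = extract_window(GenomeHit("r", "c", 10, 31, "+"), genome, 100)
        assert (ws, we) == (0, 131) and off == 10

    def test_minus_strand_round_trip(self):
        import random

        rng = random.Random(5)
        genome = {"c": "".join(rng.choices("ACGT", k=2000))}
        start, end = 900, 921
        read = revcomp(genome["c"][start:end])
        w, ws, we, off = extract_window(GenomeHit("r", "c", start, end, "-"), genome, 100)
        assert w == revcomp(genome["c"][ws:we])
        assert w[off : off + 21] == read


class TestTrimHairpin:
    def test_clean_hairpin_contains_read_on_5p_arm(self):
        st, _ = fold_rna(HP60)
        cand = trim_hairpin(st, HP60, (3, 24), min_hairpin=60)
        assert cand is not None and cand.arm == "5p" and len(cand.window) >= 60

    def test_hairpin_59_vs_60_boundary(self):
        st60, _ = fold_rna(HP60)
        st59, _ = fold_rna(HP59)
        assert trim_hairpin(st60, HP60, (3, 24), min_hairpin=60) is not None
        assert trim_hairpin(st59, HP59, (3, 24), min_hairpin=60) is None

    def test_read_inside_terminal_loop_rejected(self):
        # long stem so the region passes the length check; read in the loop
        stem = STEM26 + "GCATGCC"  # 33 bp stem, 33*2+12 = 78 nt
        hp = stem + "AACAACAAACAA" + revcomp(stem)
        st, _ = fold_rna(hp)
        loop_read = (len(stem) + 1, len(stem) + 11)
        assert trim_hairpin(st, hp, loop_read, min_hairpin=60) is None

    def test_unstructured_window_rejected(self):
        seq = "ACAACAACAACAA" * 8
        st, _ = fold_rna(seq)
        assert trim_hairpin(st, seq, (10, 30), min_hairpin=60) is None


def perfect_candidate(stem_len=26, loop=8, mature=(3, 24)):
    """Hand-built perfect-stem candidate; no folding involved."""
    window = "G" * stem_len + "A" * loop + "C" * stem_len
    structure = "(" * stem_len + "." * loop + ")" * stem_len
    return HairpinCandidate(
        window=window, structure=structure, mfe=-40.0, mature=mature, arm="5p"
    )


class TestFindStar:
    def test_perfect_stem_geometry(self):
        cand = perfect_candidate()
        star = find_star(cand)
        # partner(me-3)=partner(21)=38; partner(ms)=partner(3)=56 -> +3
        assert star == (38, 59)
        assert star[1] - star[0] == 21

    def test_involution_on_perfect_stem(self):
        cand = perfect_candidate()
        star = find_star(cand)
        cand2 = perfect_candidate(mature=star)
        assert find_star(cand2) == (3, 24)

    def test_mature_ending_in_loop_returns_none(self):
        # mature 3' anchor deep in the terminal loop: no paired base within 2 nt
        cand = perfect_candidate(mature=(10, 31))  # ends at 31, loop = 26..34
        assert find_star(cand) is None


def duplex_candidate(L=21, states=None, star_bulges=None):
    """Synthetic duplex: mature [0, L), loop of 8, star after it.

    ``states[i]`` for duplex positions i in [0, L-2): 'p' paired,
    'm' mismatch (unpaired both sides). ``star_bulges``: {i: size} inserts
    unpaired star nt between the partners of positions i and i+1.
    """
    states = states or {}
    star_bulges = star_bulges or {}
    mature_tokens = []
    star_tokens = []  # in mature-ascending order; reversed for 5'->3'
    for i in range(L - 2):
        s = states.get(i, "p")
        if s == "p":
            mature_tokens.append("(")
            star_tokens.append(")")
        elif s == "m":
            mature_tokens.append(".")
            star_tokens.append(".")
        if i in star_bulges:
            star_tokens.append("." * star_bulges[i])
    mature_struct = "".join(mature_tokens) + ".."  # 2-nt 3' overhang
    star_struct = "".join(reversed(star_tokens)) + ".."
    structure = mature_struct + "." * 8 + star_struct
    window = "A" * len(structure)
    Ls = len(star_struct)
    return HairpinCandidate(
        window=window,
        structure=structure,
        mfe=-30.0,
        mature=(0, L),
        star=(L + 8, L + 8 + Ls),
        arm="5p",
    )


class TestCheckDuplex:
    def test_perfect_duplex(self):
        ok, reasons, mm, bulges = check_duplex(duplex_candidate())
        assert ok and mm == 0 and bulges == []

    def test_mismatch_boundary_four_vs_five(self):
        four = duplex_candidate(states={3: "m", 7: "m", 11: "m", 15: "m"})
        five = duplex_candidate(states={3: "m", 6: "m", 9: "m", 12: "m", 15: "m"})
        ok4, _, mm4, _ = check_duplex(four)
        ok5, reasons5, mm5, _ = check_duplex(five)
        assert ok4 and mm4 == 4
        assert not ok5 and mm5 == 5 and "mismatches>4" in reasons5

    def test_bulge_size_boundary_two_vs_three(self):
        two = duplex_candidate(star_bulges={8: 2})
        three = duplex_candidate(star_bulges={8: 3})
        ok2, _, _, b2 = check_duplex(two)
        ok3, reasons3, _, b3 = check_duplex(three)
        assert ok2 and b2 == [2]
        assert not ok3 and b3 == [3] and "bulge>2nt" in reasons3

    def test_bulge_count_boundary_one_vs_two(self):
        one = duplex_candidate(star_bulges={6: 1})
        two = duplex_candidate(star_bulges={5: 1, 12: 1})
        assert check_duplex(one)[0]
        ok, reasons, _, bulges = check_duplex(two)
        assert not ok and bulges == [1, 1] and "bulges>1" in reasons


class TestComputeMfei:
    @pytest.mark.parametrize(
        "mfe,length,gc,amfe,mfei",
        [
            (-60.0, 100, 0.50, -60.0, -1.20),
            (-40.0, 100, 0.50, -40.0, -0.80),
            (0.0, 80, 0.50, 0.0, 0.0),
        ],
    )
    def test_arithmetic(self, mfe, length, gc, amfe, mfei):
        a, m = compute_mfei(mfe, length, gc)
        assert a == pytest.approx(amfe) and m == pytest.approx(mfei)

    def test_threshold_convention_uses_absolute_value(self):
        _, m = compute_mfei(-42.5, 100, 0.5)
        assert abs(m) >= 0.85
        _, m2 = compute_mfei(-42.4, 100, 0.5)
        assert abs(m2) < 0.85

    def test_degenerate_gc_rejected(self):
        with pytest.raises(ValueError):
            compute_mfei(-10.0, 100, 0.0)


SAME = {"sbi-miR156a": "TGACAGAAGAGAGTGAGCACA"}
OTHER = {"ath-miR390a": "AAGCTCAGGAGGGATAGCGCC"}


def _mutate(seq, positions, to="A"):
    s = list(seq)
    for p in positions:
        s[p] = "C" if s[p] == to else to
    return "".join(s)


class TestClassifyMature:
    def test_exact_reference_is_known(self):
        klass, family, mm = classify_mature(SAME["sbi-miR156a"], SAME, OTHER)
        assert (klass, family, mm) == ("known", "miR156", 0)

    def test_three_vs_four_mismatch_boundary(self):
        ref = SAME["sbi-miR156a"]
        k3, _, mm3 = classify_mature(_mutate(ref, [2, 8, 14]), SAME, OTHER)
        k4, _, _ = classify_mature(_mutate(ref, [2, 8, 14, 19]), SAME, {})
        assert (k3, mm3) == ("known", 3)
        assert k4 == "novel"

    def test_other_species_gives_conserved(self):
        klass, family, _ = classify_mature(OTHER["ath-miR390a"], SAME, OTHER)
        assert (klass, family) == ("conserved", "miR390")

    def test_empty_references_everything_novel(self):
        assert classify_mature("TGACAGAAGAGAGTGAGCACA", {}, {})[0] == "novel"

    def test_u_input_normalised(self):
        rna = SAME["sbi-miR156a"].replace("T", "U")
        assert classify_mature(rna, SAME, OTHER)[0] == "known"


class TestFirstNtBias:
    def test_counting(self):
        from srnakit.mirna import MiRNAAnnotation

        def ann(seq, klass):
            return MiRNAAnnotation(
                mature=seq, star=None, precursor=None, amfe=0, mfei=0,
                gc=0.5, randfold_p=0.01, klass=klass,
            )

        table = first_nt_bias(
            [ann("TGG" + "A" * 18, "novel"), ann("TCC" + "A" * 18, "novel"),
             ann("GGG" + "A" * 18, "novel")]
        )
        assert table["novel"] == {"U": pytest.approx(2 / 3), "A": 0.0,
                                  "G": pytest.approx(1 / 3), "C": 0.0}
        assert "known" not in table  # empty classes omitted
        assert sum(table["novel"].values()) == pytest.approx(1.0)


def _scene_reads_and_hits(genome, truth, max_hits=16):
    unique = []
    for m in truth.planted_mirs:
        unique.append(UniqueRead(m.mature_seq, {"G1_ctrl": 50}))
    index = GenomeIndex(genome)
    ids = {f"read{i}": u.sequence for i, u in enumerate(unique, 1)}
    hits, _ = map_reads(ids, index, max_hits)
    return unique, hits


class TestCallMirnas:
    def test_planted_loci_recovered(self, small_scene):
        genome, truth = small_scene
        unique, hits = _scene_reads_and_hits(genome, truth)
        cfg = MirnaConfig(randfold_shuffles=19)
        anns, _ = call_mirnas(unique, hits, genome, cfg, seed=0)
        called = {a.mature for a in anns}
        assert called == {m.mature_seq for m in truth.planted_mirs}

    def test_mfei_filter_monotonicity(self, small_scene):
        genome, truth = small_scene
        unique, hits = _scene_reads_and_hits(genome, truth)
        strict = MirnaConfig(randfold_shuffles=19)
        loose = MirnaConfig(randfold_shuffles=19, enable_mfei=False)
        called_strict = {a.mature for a in call_mirnas(unique, hits, genome, strict, seed=0)[0]}
        called_loose = {a.mature for a in call_mirnas(unique, hits, genome, loose, seed=0)[0]}
        assert called_strict <= called_loose

    def test_strand_symmetry(self, small_scene):
        """Reverse-complementing the genome yields the same matures
        (the deterministic filter chain; the shuffle test is excluded
        because its per-locus seeds are coordinate-derived)."""
        genome, truth = small_scene
        cfg = MirnaConfig(enable_randfold=False)
        unique, hits = _scene_reads_and_hits(genome, truth)
        anns_fwd, _ = call_mirnas(unique, hits, genome, cfg, seed=0)
        flipped = {c: revcomp(s) for c, s in genome.items()}
        unique2, hits2 = _scene_reads_and_hits(flipped, truth)
        anns_rev, _ = call_mirnas(unique2, hits2, flipped, cfg, seed=0)
        assert {a.mature for a in anns_fwd} == {a.mature for a in anns_rev}
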