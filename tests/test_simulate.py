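"""Generator contracts: determinism, planted-structure round trips,
the Poisson count model, and truth consistency."""

import numpy as np
import pytest

from srnakit._seq import revcomp
from srnakit.fold import fold_rna
from srnakit.mirna import check_duplex, find_star, trim_hairpin
from srnakit.simulate import (
    PlacementError,
    SimConfig,
    build_genome,
    simulate_counts,
    simulate_libraries,
    simulate_to_dir,
)


class TestBuildGenome:
    def test_empty_plan(self):
        cfg = SimConfig(seed=1, genome_length=5000, n_mir_loci=0, n_tas_loci=0,
                        n_contaminant_loci=0, n_background_fragments=0)
        genome, truth = build_genome(cfg)
        assert len(genome["chr1"]) == 5000
        assert truth.planted_mirs == [] and truth.planted_tas == []
        assert truth.contaminants == [] and truth.background == []

    def test_determinism_byte_identical(self, tmp_path):
        cfg = SimConfig(seed=7, genome_length=30_000, n_mir_loci=8, n_tas_loci=2,
                        n_contaminant_loci=2, n_background_fragments=40)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_to_dir(cfg, d1)
        simulate_to_dir(cfg, d2)
        for name in ("genome.fa", "truth_mir.tsv", "truth_tas.tsv",
                     "expected_counts.tsv", "loci.gff3", "lib_G1_ctrl.fastq",
                     "lib_G2_stress.fastq", "transcripts.fa"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name

    def test_genome_too_short_raises_placement_error(self):
        cfg = SimConfig(seed=0, genome_length=800, n_mir_loci=10)
        with pytest.raises(PlacementError):
            build_genome(cfg)

    def test_invalid_proportions_rejected(self):
        cfg = SimConfig(de_class_proportions={"up_both": 0.5, "down_both": 0.4})
        with pytest.raises(ValueError):
            cfg.validate()

    def test_planted_geometry(self, small_scene):
        genome, truth = small_scene
        g = genome["chr1"]
        for m in truth.planted_mirs:
            ps, pe = m.precursor
            assert pe - ps >= 60
            assert 0 <= ps and pe <= len(g)
            # mature/star intervals disjoint and inside the precursor
            assert not (m.mature_iv[0] < m.star_iv[1] and m.star_iv[0] < m.mature_iv[1])
            for iv in (m.mature_iv, m.star_iv):
                assert ps <= iv[0] and iv[1] <= pe
            # sequences match the genome on the recorded strand
            sub = g[m.mature_iv[0] : m.mature_iv[1]]
            assert m.mature_seq == (sub if m.strand == "+" else revcomp(sub))
        for t in truth.planted_tas:
            assert t.n_units >= 4
            assert all((s - t.cleavage) % 21 == 0 for s in t.unit_starts)
            assert t.register_offset == t.cleavage % 21

    def test_planted_precursor_roundtrip_duplex_oracle(self, small_scene):
        """Refolding a planted precursor through the discovery chain
        recovers the designed mature/star duplex and passes every check."""
        genome, truth = small_scene
        g = genome["chr1"]
        for m in truth.planted_mirs:
            ps, pe = m.precursor
            prec = g[ps:pe] if m.strand == "+" else revcomp(g[ps:pe])
            st, _ = fold_rna(prec)
            offset = prec.find(m.mature_seq)
            assert offset >= 0
            cand = trim_hairpin(st, prec, (offset, offset + len(m.mature_seq)), 60)
            assert cand is not None, m.locus_id
            star = find_star(cand)
            assert star is not None, m.locus_id
            cand.star = star
            ok, reasons, mm, bulges = check_duplex(cand)
            assert ok, (m.locus_id, reasons)
            assert cand.window[star[0] : star[1]] == m.star_seq

    def test_trigger_cleavage_opposite_nt10(self, small_scene):
        genome, truth = small_scene
        g = genome["chr1"]
        for t in truth.planted_tas:
            Lt = len(t.trigger_seq)
            site_start = t.cleavage - (Lt - 10)
            assert g[site_start : site_start + Lt] == revcomp(t.trigger_seq)


class TestSimulateLibraries:
    def test_expected_mean_products(self):
        cfg = SimConfig()
        up = cfg.stress_multipliers["up_both"]
        assert up == (4.0, 4.0)  # lambda 50 -> stress mean 200 in both genotypes
        assert 50 * up[0] == 200.0

    def test_nd_class_zero_reads_in_designated_genotype(self):
        cfg = SimConfig(
            seed=5, genome_length=30_000, n_mir_loci=10, n_tas_loci=0,
            n_contaminant_loci=0, n_background_fragments=0,
            de_class_proportions={"nd": 1.0},
        )
        _, truth = build_genome(cfg)
        reads, expected = simulate_libraries(truth, cfg)
        assert all(m.de_class == "nd" for m in truth.planted_mirs)
        for m in truth.planted_mirs:
            assert m.expected_means["G1_ctrl"] == 0.0
            assert m.expected_means["G1_stress"] == 0.0
        matures = {m.mature_seq for m in truth.planted_mirs}
        for lib in ("G1_ctrl", "G1_stress"):
            for _, seq, _ in reads[lib]:
                assert not any(seq.startswith(mat) for mat in matures)

    def test_poisson_clt_sample_mean(self):
        """200 replicate draws at lambda=100: the sample mean lies within
        3 * sqrt(100/200) of 100."""
        rng = np.random.default_rng(99)
        draws = [simulate_counts({"lib": 100.0}, rng)["lib"] for _ in range(200)]
        assert abs(np.mean(draws) - 100) <= 3 * np.sqrt(100 / 200)

    def test_truth_consistency_units_appear_in_reads(self, small_sim_dir):
        """Every planted TAS phased-unit sequence appears verbatim in at
        least one library when its mean is positive."""
        import pandas as pd

        truth_tas = pd.read_csv(small_sim_dir / "truth_tas.tsv", sep="\t")
        inserts = set()
        for lib in ("G1_ctrl", "G1_stress", "G2_ctrl", "G2_stress"):
            with open(small_sim_dir / f"lib_{lib}.fastq") as fh:
                for i, line in enumerate(fh):
                    if i % 4 == 1:
                        inserts.add(line.strip())
        for _, row in truth_tas.iterrows():
            if max(row[f"mean_{lib}"] for lib in
                   ("G1_ctrl", "G1_stress", "G2_ctrl", "G2_stress")) <= 0:
                continue
            for unit in str(row.unit_seqs).split(","):
                assert any(r.startswith(unit) for r in inserts), unit

    def test_bad_read_injection_fraction(self):
        cfg = SimConfig(seed=2, genome_length=20_000, n_mir_loci=5, n_tas_loci=0,
                        n_contaminant_loci=0, n_background_fragments=0,
                        bad_read_fraction=0.5)
        _, truth = build_genome(cfg)
        reads, _ = simulate_libraries(truth, cfg)
        total = bad = 0
        for lib in reads:
            for _, seq, qual in reads[lib]:
                total += 1
                low = sum(1 for q in qual if ord(q) - 33 < 13)
                if "N" in seq or low > 6:
                    bad += 1
        assert total > 100
        assert 0.4 <= bad / total <= 0.6
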