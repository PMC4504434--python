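"""Generate a synthetic small-RNA scene with known ground truth.

Builds a 30-kb genome carrying hairpin (MIR) loci, phased-siRNA (TAS)
loci and t/rRNA contaminant copies, then simulates four sequencing
libraries (two genotypes x control/drought). The printed table shows
what was planted and with which expected expression per library — the
"answer key" the rest of the pipeline is judged against.
"""

from srnakit.simulate import SimConfig, build_genome, simulate_libraries

cfg = SimConfig(
    seed=11,
    genome_length=30_000,
    n_mir_loci=6,
    n_tas_loci=2,
    n_contaminant_loci=2,
    n_background_fragments=60,
)
genome, truth = build_genome(cfg)
reads, expected = simulate_libraries(truth, cfg)

print(f"genome: {len(genome['chr1'])} nt")
print(f"planted MIR loci: {len(truth.planted_mirs)}")
for m in truth.planted_mirs:
    print(
        f"  {m.locus_id} {m.strand} precursor {m.precursor[0]}-{m.precursor[1]} "
        f"class={m.de_class:12s} mature={m.mature_seq}"
    )
print(f"planted TAS loci: {len(truth.planted_tas)}")
for t in truth.planted_tas:
    print(
        f"  {t.locus_id} cleavage@{t.cleavage} units={t.n_units} "
        f"{t.hit_model} trigger={t.trigger_mirna_id}"
    )
for lib in sorted(reads):
    print(f"library {lib}: {len(reads[lib])} reads")
print("\nEach MIR locus emits its mature (and 10% star) reads at a Poisson")
print("mean set by its drought class; TAS loci emit 21-nt phased units.")
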