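"""End-to-end orchestration: preprocess -> map -> miRNA -> DE -> tasiRNA
-> targets, with per-stage reports and an optional ground-truth evaluation.

Every stage writes its own report file into the run directory; nothing is
mutated after being written, and all randomness flows from the single
configured seed, so two runs with the same config produce byte-identical
reports.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from ._seq import normalize
from .config import PipelineConfig
from .evaluate import evaluate_against_truth
from .expression import ExpressionRecord, classify_de
from .mapping import GenomeIndex, load_genome, map_reads, write_hits_tsv
from .mirna import call_mirnas, first_nt_bias, load_reference_set
from .phasing import assign_phase_initiator, detect_phased_clusters, name_tasirnas
from .preprocess import load_contaminants, preprocess_libraries, write_collapsed_fasta
from .simulate import load_truth
from .targets import scan_transcriptome

__all__ = ["run_all"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _library_id(path: str | Path) -> str:
    stem = Path(path).stem
    return stem[4:] if stem.startswith("lib_") else stem


def _genotype_condition(lib: str) -> tuple[str, str]:
    geno, _, cond = lib.rpartition("_")
    if cond not in ("ctrl", "stress") or not geno:
        raise PipelineError(
            "expression", f"library id {lib!r} must look like '<genotype>_<ctrl|stress>'"
        )
    return geno, cond


def run_all(cfg: PipelineConfig, truth_dir: str | Path | None = None) -> Path:
    """Run every stage; returns the run directory.

    ``truth_dir`` (a simulation output directory) enables the evaluation
    stage. Raises PipelineError naming the failing stage.
    """
    out = Path(cfg.paths.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(stage: str, msg: str) -> None:
        log_lines.append(f"[{stage}] {msg}")

    # --- inputs
    for label, p in [("genome", cfg.paths.genome)] + [
        (f"library {i}", lp) for i, lp in enumerate(cfg.paths.libraries, 1)
    ]:
        if not p or not Path(p).exists():
            raise PipelineError("inputs", f"missing input: {label} ({p!r})")
    genome = load_genome(cfg.paths.genome)
    contaminants = (
        load_contaminants(cfg.paths.contaminants) if cfg.paths.contaminants else []
    )
    same_ref = (
        load_reference_set(cfg.paths.same_species_ref)
        if cfg.paths.same_species_ref
        else {}
    )
    other_ref = (
        load_reference_set(cfg.paths.other_species_ref)
        if cfg.paths.other_species_ref
        else {}
    )

    # --- preprocess
    fastqs = {_library_id(p): p for p in cfg.paths.libraries}
    unique, report = preprocess_libraries(fastqs, cfg.preprocess, contaminants)
    pd.DataFrame(report.to_rows()).to_csv(
        out / "filter_report.tsv", sep="\t", index=False
    )
    write_collapsed_fasta(unique, out / "collapsed.fa")
    for lib in sorted(report.raw):
        log(
            "preprocess",
            f"{lib}: raw={report.raw.get(lib, 0)} clean={report.clean_total.get(lib, 0)}",
        )
    log("preprocess", f"unique tags: {len(unique)}")

    # --- mapping
    ids = {f"read{i}": ur.sequence for i, ur in enumerate(unique, 1)}
    index = GenomeIndex(genome)
    hits, rejected = map_reads(ids, index, cfg.mapping.max_hits)
    write_hits_tsv(hits, out / "hits.tsv")
    log(
        "mapping",
        f"hits={len(hits)} unmapped={len(rejected['unmapped'])} "
        f"multi={len(rejected['multi'])}",
    )

    # --- miRNA discovery
    annotations, rejects = call_mirnas(
        unique, hits, genome, cfg.mirna, same_ref, other_ref, seed=cfg.seed
    )
    ann_rows = []
    for a in annotations:
        ann_rows.append(
            {
                "name": a.name or a.locus_id,
                "locus": a.locus_id,
                "class": a.klass,
                "family": a.family,
                "mature": a.mature,
                "star": a.star or "",
                "arm": a.precursor.arm,
                "mfe": round(a.precursor.mfe, 2),
                "amfe": round(a.amfe, 2),
                "mfei": round(a.mfei, 3),
                "gc": round(a.gc, 3),
                "randfold_p": a.randfold_p,
                "ref_mismatches": "" if a.ref_mismatches is None else a.ref_mismatches,
                "abundance": a.abundance,
                **{f"count_{lib}": a.counts.get(lib, 0) for lib in sorted(fastqs)},
            }
        )
    pd.DataFrame(ann_rows).to_csv(out / "mirna_annotations.tsv", sep="\t", index=False)
    pd.DataFrame(rejects).to_csv(out / "mirna_rejected.tsv", sep="\t", index=False)
    with open(out / "hairpins.txt", "w") as fh:
        for a in annotations:
            fh.write(f">{a.name or a.locus_id} {a.locus_id}\n")
            fh.write(a.precursor.window + "\n")
            fh.write(a.precursor.structure + f" ({a.precursor.mfe:.2f})\n")
    with open(out / "mirna.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            p = a.precursor
            fh.write(
                f"{p.chrom}\tsrnakit\tmiRNA_primary_transcript\t{p.start+1}\t{p.end}"
                f"\t.\t{p.strand}\t.\tID={a.name or a.locus_id}\n"
            )
    bias = first_nt_bias(annotations) if annotations else {}
    pd.DataFrame(
        [{"class": k, **v} for k, v in bias.items()]
    ).to_csv(out / "first_nt_bias.tsv", sep="\t", index=False)
    log("mirna", f"calls={len(annotations)} rejected={len(rejects)}")

    # --- differential expression
    libs = sorted(fastqs)
    genotypes = sorted({_genotype_condition(lib)[0] for lib in libs})
    records = []
    for a in annotations:
        for geno in genotypes:
            ctrl_lib, stress_lib = f"{geno}_ctrl", f"{geno}_stress"
            if ctrl_lib not in report.clean_total or stress_lib not in report.clean_total:
                continue
            records.append(
                ExpressionRecord(
                    mirna_id=a.name or a.locus_id,
                    genotype=geno,
                    x_ctrl=a.counts.get(ctrl_lib, 0),
                    y_stress=a.counts.get(stress_lib, 0),
                    n_ctrl=max(1, report.clean_total.get(ctrl_lib, 1)),
                    n_stress=max(1, report.clean_total.get(stress_lib, 1)),
                )
            )
    de_results = classify_de(records, cfg.expression) if records else []
    de_rows = []
    for r in de_results:
        row = {"mirna": r.mirna_id, "category": r.category}
        for geno in genotypes:
            row[f"tpm_ctrl_{geno}"] = round(r.tpm.get(geno, (0, 0))[0], 3)
            row[f"tpm_stress_{geno}"] = round(r.tpm.get(geno, (0, 0))[1], 3)
            fc = r.log2fc.get(geno)
            row[f"log2fc_{geno}"] = "" if fc is None else round(fc, 3)
            p = r.pvalue.get(geno)
            row[f"pvalue_{geno}"] = "" if p is None else p
            row[f"status_{geno}"] = r.status.get(geno, "ND")
        de_rows.append(row)
    pd.DataFrame(de_rows).to_csv(out / "expression_de.tsv", sep="\t", index=False)
    log("expression", f"records={len(de_results)}")

    # --- phased tasiRNA clusters
    counts_total = {rid: sum(ur.counts.values()) for rid, ur in
                    ((f"read{i}", u) for i, u in enumerate(unique, 1))}
    clusters = detect_phased_clusters(hits, counts_total, ids, cfg.phasing)
    cluster_rows = []
    candidate_mirnas = {a.name or a.locus_id: a.mature for a in annotations}
    families = {a.name or a.locus_id: a.family or (a.name or a.locus_id)
                for a in annotations}
    triggers = {}
    tasirnas_all = []
    for cl in clusters:
        # extend the scanned sequence upstream so a trigger site whose 3'
        # half reaches past the cleavage point is fully contained
        search_start = max(0, cl.tas_start - 40)
        tas_seq = genome[cl.chrom][search_start : cl.tas_end]
        trig = assign_phase_initiator(
            cl, candidate_mirnas, tas_seq, families, cfg.targets,
            seq_start=search_start,
        )
        triggers[cl.tas_id] = trig
        tasirnas_all.append((cl, name_tasirnas(cl, trig)))
        cluster_rows.append(
            {
                "tas_id": cl.tas_id, "chrom": cl.chrom,
                "start": cl.start, "end": cl.end,
                "register_offset": cl.register_offset,
                "m": cl.m, "n": cl.n, "k": cl.k, "pvalue": cl.pvalue,
                "tas_start": cl.tas_start, "tas_end": cl.tas_end,
                "trigger": trig.mirna_id if trig else "",
                "hit_model": trig.hit_model if trig else "",
            }
        )
    pd.DataFrame(cluster_rows).to_csv(out / "tas_clusters.tsv", sep="\t", index=False)
    with open(out / "tas_clusters.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for cl in clusters:
            trig = triggers[cl.tas_id]
            attrs = f"ID={cl.tas_id};pvalue={cl.pvalue:.3e}"
            if trig:
                attrs += f";trigger={trig.mirna_id};hit_model={trig.hit_model}"
            fh.write(
                f"{cl.chrom}\tsrnakit\ttasiRNA_locus\t{cl.start+1}\t{cl.end}\t.\t+\t.\t{attrs}\n"
            )
    with open(out / "tasirnas.fa", "w") as fh:
        for cl, tas_list in tasirnas_all:
            for t in tas_list:
                fh.write(f">{t.name}\n{t.sequence}\n")
    log("phasing", f"clusters={len(clusters)}")

    # --- target prediction
    if cfg.paths.transcripts and Path(cfg.paths.transcripts).exists():
        transcripts = {
            rec.id: normalize(str(rec.seq))
            for rec in SeqIO.parse(cfg.paths.transcripts, "fasta")
        }
        predictions = scan_transcriptome(candidate_mirnas, transcripts, cfg.targets)
        pd.DataFrame(
            [
                {
                    "mirna": p.mirna_id, "transcript": p.transcript_id,
                    "start": p.start, "end": p.end, "score": p.score,
                    "inhibition": p.inhibition,
                    "alignment_mirna_3to5": p.alignment[0],
                    "alignment_bonds": p.alignment[1],
                    "alignment_target_5to3": p.alignment[2],
                }
                for p in predictions
            ]
        ).to_csv(out / "targets.tsv", sep="\t", index=False)
        log("targets", f"predictions={len(predictions)}")

    # --- evaluation against simulated truth
    if truth_dir is not None:
        truth = load_truth(truth_dir)
        evaluation = evaluate_against_truth(
            truth, annotations, de_results, clusters, triggers
        )
        evaluation.to_frame().to_csv(out / "evaluation.tsv", sep="\t", index=False)
        for s in evaluation.scores:
            log(
                "evaluate",
                f"{s.task}: tp={s.tp} fp={s.fp} fn={s.fn} "
                f"precision={s.precision:.3f} recall={s.recall:.3f}",
            )

    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return out
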