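"""On-disk fixture bundles: plain-text FASTA/FASTQ/VCF/BED/TSV renditions
of a simulated cohort, plus the truth tables, re-readable into memory."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cohort import SimulatedCohort
from .locus import LocusModel


def _fasta(path: Path, entries: dict[str, str]):
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in entries.items()]
    SeqIO.write(recs, str(path), "fasta")


def _read_fasta(path: Path) -> dict[str, str]:
    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}


def _write_fastq(path: Path, reads: list[tuple[str, str, str]]):
    def gen():
        for name, seq, qual in reads:
            rec = SeqRecord(Seq(seq), id=name, description="")
            rec.letter_annotations["phred_quality"] = [ord(q) - 33 for q in qual]
            yield rec

    SeqIO.write(gen(), str(path), "fastq")


def read_fastq(path) -> list[tuple[str, str, str]]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append((rec.id, str(rec.seq), qual))
    return out


def _write_vcf(path: Path, mutations: pd.DataFrame, contigs: dict[str, str]):
    order = {c: i for i, c in enumerate(contigs)}
    mut = mutations.sort_values(
        ["chrom", "pos", "sample"], key=lambda s: s.map(order) if s.name == "chrom" else s
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=apobec3kit-sim\n")
        for name, seq in contigs.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write('##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample carrying the SNV">\n')
        fh.write('##INFO=<ID=CTX,Number=1,Type=String,Description="Reference trinucleotide context">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in mut.itertuples(index=False):
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t"
                f"SAMPLE={r.sample};CTX={r.context}\n"
            )


def write_fixture_bundle(cohort: SimulatedCohort, outdir) -> Path:
    """Write the whole cohort as plain-text files; returns the directory."""
    out = Path(outdir)
    (out / "reads").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    loc = cohort.locus
    _fasta(out / "genome_nondeleted.fa", loc.contigs["nondeleted"])
    _fasta(out / "genome_deleted.fa", loc.contigs["deleted"])
    _fasta(out / "context_genome.fa", cohort.context_genome)
    _fasta(out / "transcripts.fa", loc.transcript_seqs)
    loc.exons.to_csv(out / "exons.tsv", sep="\t", index=False)
    ds, de = loc.deletion_interval
    with open(out / "deletion.bed", "w") as fh:
        fh.write(f"{LocusModel.MAIN_CONTIG}\t{ds}\t{de}\tA3B_deletion\n")
    with open(out / "exons.bed", "w") as fh:
        for r in loc.exons.itertuples(index=False):
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.transcript_id}_exon{r.exon_index}\n")
    for (sid, tissue), lib in sorted(cohort.reads.items()):
        _write_fastq(out / "reads" / f"{sid}_{tissue}.fastq", lib)
    cohort.depth.drop(columns=["genotype_true"]).to_csv(out / "depths.tsv", sep="\t", index=False)
    cohort.mutations.drop(columns=["class_index"]).to_csv(
        out / "mutations.tsv", sep="\t", index=False
    )
    _write_vcf(out / "mutations.vcf", cohort.mutations, cohort.context_genome)
    cohort.clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    pd.DataFrame({"sample": cohort.sample_ids, "genotype": cohort.genotypes}).to_csv(
        out / "truth" / "genotypes.tsv", sep="\t", index=False
    )
    cohort.truth_catalog.to_csv(out / "truth" / "catalog.tsv", sep="\t")
    cohort.expression_truth.to_csv(out / "truth" / "expression.tsv", sep="\t", index=False)
    cohort.exposures_true.to_csv(out / "truth" / "exposures.tsv", sep="\t")
    cohort.signatures_true.to_csv(out / "truth" / "signatures.tsv", sep="\t")
    cfg = dataclasses.asdict(cohort.config)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(_listify(cfg), fh, sort_keys=True)
    return out


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def read_fixture_bundle(outdir) -> SimpleNamespace:
    """Re-read a bundle written by :func:`write_fixture_bundle`."""
    out = Path(outdir)
    reads = {}
    for fq in sorted((out / "reads").glob("*.fastq")):
        sid, tissue = fq.stem.rsplit("_", 1)
        reads[(sid, tissue)] = read_fastq(fq)
    with open(out / "config.yaml") as fh:
        config = yaml.safe_load(fh)
    dele = pd.read_csv(
        out / "deletion.bed", sep="\t", names=["chrom", "start", "end", "name"]
    )
    return SimpleNamespace(
        genome_nondeleted=_read_fasta(out / "genome_nondeleted.fa"),
        genome_deleted=_read_fasta(out / "genome_deleted.fa"),
        context_genome=_read_fasta(out / "context_genome.fa"),
        transcripts=_read_fasta(out / "transcripts.fa"),
        exons=pd.read_csv(out / "exons.tsv", sep="\t"),
        deletion_bed=dele,
        reads=reads,
        depth=pd.read_csv(out / "depths.tsv", sep="\t"),
        mutations=pd.read_csv(out / "mutations.tsv", sep="\t"),
        clinical=pd.read_csv(out / "clinical.tsv", sep="\t"),
        truth_genotypes=pd.read_csv(out / "truth" / "genotypes.tsv", sep="\t"),
        truth_catalog=pd.read_csv(out / "truth" / "catalog.tsv", sep="\t", index_col=0),
        truth_expression=pd.read_csv(out / "truth" / "expression.tsv", sep="\t"),
        truth_exposures=pd.read_csv(out / "truth" / "exposures.tsv", sep="\t", index_col=0),
        truth_signatures=pd.read_csv(out / "truth" / "signatures.tsv", sep="\t", index_col=0),
        config=config,
    )
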