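"""FASTA / GFF3 / TSV readers and writers shared by the pipeline stages."""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .classify import ORGeneModel
from .synthetic import TruthAnnotation

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_truth_gff3",
    "read_truth_gff3",
    "write_models",
    "read_models",
    "write_manifest",
    "read_manifest",
]


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: dict[str, str], path: str) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()),
        path,
        "fasta",
    )


_GFF_COLS = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]


def write_truth_gff3(annotations: list[TruthAnnotation], path: str) -> None:
    """Truth annotations as GFF3 gene features (1-based closed intervals)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            attrs = (
                f"ID={a.gene_id};true_status={a.true_status};true_class={a.true_class};"
                f"defect={a.defect_mode or 'none'};is_or={int(a.is_or)}"
            )
            fh.write(
                f"{a.contig}\torexpress\tgene\t{a.start}\t{a.end}\t.\t{a.strand}\t.\t{attrs}\n"
            )


def _attr_map(attributes: str) -> dict[str, str]:
    return dict(kv.split("=", 1) for kv in attributes.rstrip(";").split(";") if "=" in kv)


def read_truth_gff3(path: str) -> list[TruthAnnotation]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            attrs = _attr_map(fields[8])
            defect = attrs.get("defect", "none")
            out.append(
                TruthAnnotation(
                    gene_id=attrs["ID"],
                    contig=fields[0],
                    start=int(fields[3]),
                    end=int(fields[4]),
                    strand=fields[6],
                    true_status=attrs.get("true_status", "intact"),
                    true_class=attrs.get("true_class", "none"),
                    defect_mode=None if defect == "none" else defect,
                    is_or=attrs.get("is_or", "0") == "1",
                )
            )
    return out


def write_models(models: list[ORGeneModel], tsv_path: str, gff_path: str | None = None) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [m.gene_id for m in models],
            "contig": [m.contig for m in models],
            "start": [m.start + 1 for m in models],  # 1-based in the table
            "end": [m.end for m in models],
            "strand": [m.strand for m in models],
            "status": [m.status for m in models],
            "or_class": [m.or_class for m in models],
            "defects": [",".join(m.defects) or "none" for m in models],
            "best_query": [m.best_query_id for m in models],
            "name": [m.name or "" for m in models],
            "coding_seq": [m.coding_seq for m in models],
        }
    )
    df.to_csv(tsv_path, sep="\t", index=False)
    if gff_path:
        with open(gff_path, "w") as fh:
            fh.write("##gff-version 3\n")
            for m in models:
                attrs = f"ID={m.gene_id};status={m.status};or_class={m.or_class};defects={','.join(m.defects) or 'none'}"
                fh.write(
                    f"{m.contig}\torexpress\tgene\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\t{attrs}\n"
                )


def read_models(tsv_path: str) -> list[ORGeneModel]:
    df = pd.read_csv(tsv_path, sep="\t", keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        out.append(
            ORGeneModel(
                gene_id=r.gene_id,
                contig=r.contig,
                start=int(r.start) - 1,
                end=int(r.end),
                strand=r.strand,
                coding_seq=r.coding_seq,
                translation="",
                status=r.status,
                or_class=r.or_class,
                class_margin=0.0,
                defects=[] if r.defects == "none" else r.defects.split(","),
                best_query_id=r.best_query,
                name=r["name"] or None,
            )
        )
    return out


def write_manifest(rows: list[dict], path: str) -> None:
    pd.DataFrame(rows, columns=["sample_id", "tissue_label", "fastq1", "fastq2"]).to_csv(
        path, sep="\t", index=False
    )


def read_manifest(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "tissue_label", "fastq1", "fastq2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df
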