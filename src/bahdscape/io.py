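"""Readers and writers for the tabular and sequence formats the pipeline
consumes: FASTA, BLAST tabular (outfmt 6), HMMER tblout/domtblout, id
lists, and the TSV inputs of the co-expression/pathway stages."""

from __future__ import annotations

import io as _io
from typing import Iterable, TextIO

import pandas as pd
from Bio import SearchIO, SeqIO

from .clade_assignment import ReferencePanel, SimilarityHit
from .pathway_prediction import CoexpressionTable, PathwayAnnotation

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_id_list",
    "read_blast6",
    "read_hmmer_tbl",
    "read_domtbl_targets",
    "read_panel",
    "read_orthogroups",
    "read_coexpression_tsv",
    "read_pathway_tsv",
    "read_ortho_calls",
    "read_class_map",
    "read_yn00_pairs",
]

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_fasta(path: str) -> dict[str, str]:
    """FASTA file -> ordered dict of id -> sequence."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_fasta(sequences: dict[str, str], path: str, wrap: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i:i + wrap] + "\n")


def read_id_list(path: str) -> list[str]:
    """One id per line; blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line.split()[0])
    return out


def read_blast6(path: str) -> list[SimilarityHit]:
    """BLAST tabular outfmt 6 -> alignment-engine similarity hits."""
    df = pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS, comment="#",
                     float_precision="round_trip")
    return [
        SimilarityHit(
            query_id=str(r.qseqid), target_id=str(r.sseqid),
            pct_identity=float(r.pident), match_length=int(r.length),
            bit_score=float(r.bitscore), e_value=float(r.evalue),
            engine="alignment",
        )
        for r in df.itertuples()
    ]


def read_hmmer_tbl(path: str) -> list[SimilarityHit]:
    """phmmer/hmmsearch --tblout -> profile-engine similarity hits.

    Full-sequence e-value and score are used; identity and match length
    are not defined for profile hits (set to 0 / full-sequence n/a)."""
    hits = []
    for qresult in SearchIO.parse(path, "hmmer3-tab"):
        for hit in qresult:
            hits.append(SimilarityHit(
                query_id=qresult.id, target_id=hit.id,
                pct_identity=0.0, match_length=0,
                bit_score=float(hit.bitscore),
                e_value=float(hit.evalue), engine="profile",
            ))
    return hits


def read_domtbl_targets(path: str) -> list[str]:
    """Target ids from an hmmsearch --domtblout file (family membership)."""
    seen = dict()
    for qresult in SearchIO.parse(path, "hmmsearch3-domtab"):
        for hit in qresult:
            seen[hit.id] = True
    return list(seen)


def read_panel(fasta_path: str, labels_path: str) -> ReferencePanel:
    """Reference panel from a protein FASTA and a 2-column TSV
    (ref_id <tab> clade_label)."""
    seqs = read_fasta(fasta_path)
    labels = pd.read_csv(labels_path, sep="\t", comment="#",
                         names=["ref_id", "clade"], dtype=str)
    entries = []
    for r in labels.itertuples():
        if r.ref_id not in seqs:
            raise KeyError(f"panel label {r.ref_id!r} has no sequence")
        entries.append((r.ref_id, r.clade, seqs[r.ref_id]))
    return ReferencePanel(entries)


def read_orthogroups(path: str) -> dict[str, set[str]]:
    """Orthogroup TSV (og_id <tab> gene_id) -> og_id -> gene set."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["og_id", "gene_id"], dtype=str)
    out: dict[str, set[str]] = {}
    for r in df.itertuples():
        out.setdefault(r.og_id, set()).add(r.gene_id)
    return out


def read_coexpression_tsv(path: str | TextIO) -> CoexpressionTable:
    """ATTED-style TSV (gene_a <tab> gene_b <tab> z)."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["gene_a", "gene_b", "z"],
                     dtype={"gene_a": str, "gene_b": str, "z": float})
    return CoexpressionTable(
        [(r.gene_a, r.gene_b, float(r.z)) for r in df.itertuples()]
    )


def read_pathway_tsv(path: str | TextIO) -> PathwayAnnotation:
    """PMN-style TSV (gene_id <tab> pathway_id <tab> pathway_name)."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["gene_id", "pathway_id", "pathway_name"],
                     dtype=str)
    gp: dict[str, set[tuple[str, str]]] = {}
    for r in df.itertuples():
        gp.setdefault(r.gene_id, set()).add((r.pathway_id, r.pathway_name))
    return PathwayAnnotation(gp)


def read_ortho_calls(path: str) -> dict[str, str]:
    """Orthology substrate-class TSV (gene_id <tab> substrate_class)."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["gene_id", "substrate_class"], dtype=str)
    return dict(zip(df.gene_id, df.substrate_class))


def read_class_map(path: str) -> dict[str, set[str]]:
    """Pathway-to-substrate-class map TSV
    (pathway_id <tab> substrate_class), possibly many rows per pathway."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["pathway_id", "substrate_class"], dtype=str)
    out: dict[str, set[str]] = {}
    for r in df.itertuples():
        out.setdefault(r.pathway_id, set()).add(r.substrate_class)
    return out


def read_yn00_pairs(path: str) -> pd.DataFrame:
    """Compiled yn00-style pair table (gene_a, gene_b, ka, ks TSV with a
    header) for users who ran PAML externally."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_a", "gene_b", "ka", "ks"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"yn00 table missing columns {sorted(missing)}")
    return df


def fasta_text_to_dict(text: str) -> dict[str, str]:
    """Parse FASTA from an in-memory string (synthetic outputs)."""
    return {rec.id: str(rec.seq)
            for rec in SeqIO.parse(_io.StringIO(text), "fasta")}
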