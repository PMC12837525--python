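"""Readers and writers for the formats the pipeline consumes and emits.

Conventions: all in-memory coordinates are 0-based half-open; GFF3 is
emitted and read as 1-based closed; BED is 0-based half-open with the
region class in column 4.  FASTA goes through Biopython.
"""

from __future__ import annotations

import os
from typing import Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError

ELEMENT_COLUMNS = [
    "element_id", "scaffold", "start", "end", "strand",
    "family", "superfamily", "part", "status",
]


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(scaffolds: dict, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in scaffolds.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_elements_gff3(elements: pd.DataFrame, path, source: str = "ltrscape") -> None:
    """Element part rows as GFF3 (1-based closed coordinates)."""
    type_of = {
        "LTR5": "long_terminal_repeat",
        "LTR3": "long_terminal_repeat",
        "LTR": "long_terminal_repeat",
        "internal": "LTR_retrotransposon_internal_region",
    }
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in elements.itertuples():
            attrs = (
                f"ID={r.element_id}.{r.part};Parent={r.element_id};part={r.part};"
                f"family={r.family};superfamily={r.superfamily};status={r.status}"
            )
            fh.write(
                "\t".join(
                    [
                        r.scaffold, source, type_of.get(r.part, "repeat_region"),
                        str(r.start + 1), str(r.end), ".", r.strand, ".", attrs,
                    ]
                )
                + "\n"
            )


def read_elements_gff3(path) -> pd.DataFrame:
    """Parse the element GFF3 back into 0-based half-open part rows."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise InputError(f"malformed GFF3 line: {line.strip()!r}")
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            rows.append(
                dict(
                    element_id=attrs.get("Parent", attrs.get("ID", "")),
                    scaffold=fields[0],
                    start=int(fields[3]) - 1,
                    end=int(fields[4]),
                    strand=fields[6],
                    family=attrs.get("family", "unknown"),
                    superfamily=attrs.get("superfamily", "unknown"),
                    part=attrs.get("part", fields[2]),
                    status=attrs.get("status", "unassigned"),
                )
            )
    return pd.DataFrame(rows, columns=ELEMENT_COLUMNS)


def read_elements_table(path) -> pd.DataFrame:
    """Tab-separated candidate-element table with the census input columns."""
    df = pd.read_csv(path, sep="\t")
    missing = set(ELEMENT_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise InputError(f"element table missing columns {sorted(missing)}")
    return df


def write_genes_gff3(genes: pd.DataFrame, path, source: str = "ltrscape") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples():
            fh.write(
                "\t".join(
                    [
                        g.scaffold, source, "gene", str(g.start + 1), str(g.end),
                        ".", g.strand, ".", f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )


def read_genes_gff3(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9 or fields[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv)
            rows.append(
                dict(
                    gene_id=attrs.get("ID", ""), scaffold=fields[0],
                    start=int(fields[3]) - 1, end=int(fields[4]), strand=fields[6],
                )
            )
    return pd.DataFrame(rows, columns=["gene_id", "scaffold", "start", "end", "strand"])


def write_bed(df: pd.DataFrame, path, name_column: Optional[str] = "cls") -> None:
    cols = ["scaffold", "start", "end"]
    out = df[cols].copy()
    if name_column and name_column in df.columns:
        out[name_column] = df[name_column]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, name_column: str = "cls") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["scaffold", "start", "end"] + (
        [name_column] if df.shape[1] > 3 else []
    )
    df = df.iloc[:, : len(names)]
    df.columns = names
    return df


def write_bundle(bundle, outdir) -> None:
    """Write a simulated bundle as plain-text files under ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    p = lambda name: os.path.join(outdir, name)  # noqa: E731
    write_fasta(bundle.scaffolds, p("scaffolds.fa"))
    write_elements_gff3(bundle.elements, p("elements.gff3"))
    bundle.elements.to_csv(p("elements.tsv"), sep="\t", index=False)
    write_bed(bundle.regions, p("regions.bed"))
    bundle.truth.elements.to_csv(p("truth_elements.tsv"), sep="\t", index=False)
    if bundle.genes is not None:
        write_genes_gff3(bundle.genes, p("genes.gff3"))
        bundle.genes.to_csv(p("genes.tsv"), sep="\t", index=False)
    if bundle.pairs is not None:
        bundle.pairs.to_csv(p("homolog_pairs.tsv"), sep="\t", index=False)
    if bundle.pseudogenes is not None:
        bundle.pseudogenes.to_csv(p("pseudogene_candidates.tsv"), sep="\t", index=False)
    if bundle.expression is not None:
        bundle.expression.to_csv(p("expression.tsv"), sep="\t", index=False)
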