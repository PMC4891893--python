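"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text: TSV matrices and tables, GMT gene sets, VCF
v4.2 variant lists (written by hand, read back through pysam), a minimal
GFF3 gene-feature reader, SIF and GraphML network exports (Cytoscape
compatible), and YAML provenance/config files.
"""
from __future__ import annotations

import hashlib
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from .core import ExpressionMatrix
from .enrichment import GeneSet, GeneSetCollection

__all__ = [
    "write_expression", "read_expression",
    "write_table", "read_table",
    "write_gmt", "read_gmt",
    "write_vcf", "read_vcf", "read_variant_table",
    "read_gff3_genes",
    "write_sif", "write_graphml",
    "write_yaml", "read_yaml",
    "file_checksum",
]


# -- expression matrices ----------------------------------------------------

def write_expression(matrix: ExpressionMatrix, values_path, meta_path) -> None:
    matrix.values.to_csv(values_path, sep="\t", index_label="gene")
    matrix.samples.to_csv(meta_path, sep="\t", index_label="sample")


def read_expression(values_path, meta_path) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="gene")
    samples = pd.read_csv(meta_path, sep="\t", index_col="sample")
    return ExpressionMatrix(values=values, samples=samples.loc[values.columns])


# -- generic tables ---------------------------------------------------------

def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


# -- GMT gene sets ----------------------------------------------------------

def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            genes = "\t".join(sorted(s.genes))
            fh.write(f"{s.name}\t{s.ontology}\t{genes}\n")


def read_gmt(path, default_ontology: str = "KEGG") -> GeneSetCollection:
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, desc, genes = parts[0], parts[1], parts[2:]
            ontology = desc if desc in ("KEGG", "GO") else default_ontology
            sets.append(GeneSet(name=name, ontology=ontology, genes=frozenset(genes)))
    return GeneSetCollection(sets)


# -- variants ---------------------------------------------------------------

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID={contig},length={length}>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def write_vcf(variants: pd.DataFrame, path, contig: str = "chr1",
              contig_length: int = 10_000_000) -> None:
    """Minimal single-contig VCF v4.2 from a (pos, ref, alt) table."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER.format(contig=contig, length=contig_length))
        for row in variants.sort_values("pos").itertuples(index=False):
            fh.write(f"{contig}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\n")


def read_vcf(path) -> pd.DataFrame:
    """Read a VCF into a (pos, ref, alt) table via pysam."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                rows.append({"pos": rec.pos, "ref": rec.ref, "alt": alt})
    return pd.DataFrame(rows, columns=["pos", "ref", "alt"])


def read_variant_table(path) -> pd.DataFrame:
    """Read variants from either a VCF or a simple TSV with pos/ref/alt."""
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        return read_vcf(path)
    df = read_table(path)
    missing = {"pos", "ref", "alt"} - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    return df[["pos", "ref", "alt"] + [c for c in df.columns if c not in ("pos", "ref", "alt")]]


def read_gff3_genes(path) -> pd.DataFrame:
    """Gene features from a GFF3 file as a (gene, start, end, strand) table."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2].lower() != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene = attrs.get("ID") or attrs.get("Name") or attrs.get("locus_tag")
            rows.append(
                {"gene": gene, "start": int(parts[3]), "end": int(parts[4]),
                 "strand": parts[6]}
            )
    return pd.DataFrame(rows, columns=["gene", "start", "end", "strand"])


# -- networks ---------------------------------------------------------------

def write_sif(graph: nx.Graph, path, relation: str = "co") -> None:
    """Simple interaction format; isolated nodes written as bare names."""
    with open(path, "w") as fh:
        for u, v in sorted(graph.edges()):
            fh.write(f"{u}\t{relation}\t{v}\n")
        for n in sorted(graph.nodes()):
            if graph.degree(n) == 0:
                fh.write(f"{n}\n")


def write_graphml(graph: nx.Graph, path) -> None:
    clean = nx.Graph()
    clean.add_nodes_from(graph.nodes(data=True))
    for u, v, data in graph.edges(data=True):
        clean.add_edge(u, v, **{k: v2 for k, v2 in data.items() if v2 == v2})
    nx.write_graphml(clean, str(path))


# -- provenance -------------------------------------------------------------

def write_yaml(obj, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
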