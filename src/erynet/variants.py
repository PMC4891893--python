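"""Variant-list reconciliation between strains.

Operates downstream of variant calling: given per-strain variant tables
(position, reference allele, alternate allele) it

* flags variants that coincide with RNA-seq-consistent discrepancies in
  the reference assembly (putative reference sequencing errors) and
  removes them from the genuine-mutation set;
* types variants as SNV / MNV / insertion / deletion from allele lengths;
* maps positions onto gene features (ORF, promoter window upstream of the
  start, terminator window downstream of the stop — strand aware);
* computes cross-strain shared/unique sets at the variant and gene level.

Variant identity is the exact tuple (position, ref, alt); coordinates are
1-based and fully closed, VCF style.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "classify_variant_type",
    "flag_reference_errors",
    "map_variant_to_feature",
    "annotate_variants",
    "cross_strain_sets",
    "type_counts",
]

VARIANT_KEY = ["pos", "ref", "alt"]


def classify_variant_type(ref: str, alt: str) -> str:
    """SNV / MNV / insertion / deletion from allele lengths."""
    if not ref or not alt:
        raise ValueError("empty allele")
    if len(ref) == len(alt):
        return "SNV" if len(ref) == 1 else "MNV"
    return "insertion" if len(alt) > len(ref) else "deletion"


def type_counts(variants: pd.DataFrame) -> pd.Series:
    """Counts of SNV / MNV / insertion / deletion in a variant table."""
    types = variants.apply(lambda v: classify_variant_type(v["ref"], v["alt"]), axis=1)
    return (
        types.value_counts()
        .reindex(["SNV", "MNV", "insertion", "deletion"], fill_value=0)
        .rename("count")
    )


def flag_reference_errors(
    strain_variants: pd.DataFrame,
    rnaseq_consistent: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a strain's variants into (flagged errors, genuine mutations).

    A variant is flagged iff its exact (pos, ref, alt) tuple also appears
    among the RNA-seq-consistent reference discrepancies; flagged variants
    are excluded from all downstream mutation sets.
    """
    if rnaseq_consistent.empty:
        return strain_variants.iloc[0:0].copy(), strain_variants.copy()
    error_keys = set(map(tuple, rnaseq_consistent[VARIANT_KEY].itertuples(index=False)))
    is_error = strain_variants[VARIANT_KEY].apply(tuple, axis=1).isin(error_keys)
    return strain_variants[is_error].copy(), strain_variants[~is_error].copy()


def map_variant_to_feature(
    pos: int,
    annotation: pd.DataFrame,
    promoter_bp: int = 300,
    terminator_bp: int = 100,
) -> tuple[str | None, str]:
    """Assign a position to (gene, region) with strand-aware windows.

    Regions: inside the ORF; within ``promoter_bp`` upstream of the start
    (strand aware); within ``terminator_bp`` downstream of the stop;
    otherwise intergenic.  Overlapping windows resolve to the nearest
    feature, ties to the lexicographically lower gene id.
    """
    candidates = []  # (distance, gene, region)
    for row in annotation.itertuples(index=False):
        start, end, strand = row.start, row.end, row.strand
        if start <= pos <= end:
            candidates.append((0, row.gene, "ORF"))
            continue
        if strand == "+":
            upstream = start - pos       # positive when pos is before the gene
            downstream = pos - end
        else:
            upstream = pos - end
            downstream = start - pos
        if 0 < upstream <= promoter_bp:
            candidates.append((upstream, row.gene, "promoter"))
        elif 0 < downstream <= terminator_bp:
            candidates.append((downstream, row.gene, "terminator"))
    if not candidates:
        return None, "intergenic"
    candidates.sort(key=lambda c: (c[0], c[1]))
    _, gene, region = candidates[0]
    return gene, region


def annotate_variants(
    variants: pd.DataFrame,
    annotation: pd.DataFrame,
    promoter_bp: int = 300,
    terminator_bp: int = 100,
) -> pd.DataFrame:
    """Add type / gene / region columns to a variant table."""
    out = variants.copy()
    out["type"] = [classify_variant_type(r, a) for r, a in zip(out["ref"], out["alt"])]
    mapped = [
        map_variant_to_feature(p, annotation, promoter_bp, terminator_bp)
        for p in out["pos"]
    ]
    out["gene"] = [m[0] for m in mapped]
    out["region"] = [m[1] for m in mapped]
    return out


def cross_strain_sets(
    strain_variants: dict[str, pd.DataFrame],
    gene_column: str | None = "gene",
) -> dict:
    """Shared / unique variant and gene sets across strains.

    Returns a dict with ``variant_shared`` (present in every strain),
    ``variant_unique`` (strain -> variants found only there), the
    corresponding counts, and — when the tables carry a gene column —
    gene-level shared/unique sets computed the same way.
    """
    if not strain_variants:
        raise ValueError("no strain variant tables given")
    keys = {
        s: set(map(tuple, df[VARIANT_KEY].itertuples(index=False)))
        for s, df in strain_variants.items()
    }
    strains = list(keys)
    shared = set.intersection(*keys.values())
    unique = {
        s: keys[s] - set.union(set(), *(keys[t] for t in strains if t != s))
        for s in strains
    }
    result = {
        "variant_shared": sorted(shared),
        "variant_unique": {s: sorted(v) for s, v in unique.items()},
        "n_variant_shared": len(shared),
        "n_variant_unique": {s: len(v) for s, v in unique.items()},
    }
    if gene_column and all(gene_column in df.columns for df in strain_variants.values()):
        gsets = {
            s: set(df[gene_column].dropna()) for s, df in strain_variants.items()
        }
        gshared = set.intersection(*gsets.values())
        gunique = {
            s: gsets[s] - set.union(set(), *(gsets[t] for t in strains if t != s))
            for s in strains
        }
        result.update(
            {
                "gene_shared": sorted(gshared),
                "gene_unique": {s: sorted(v) for s, v in gunique.items()},
                "n_gene_shared": len(gshared),
                "n_gene_unique": {s: len(v) for s, v in gunique.items()},
            }
        )
    return result
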