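"""Flat-file IO: GFF3 and TSV annotations, ortholog/interaction tables, matrices.

Every format is plain text. The TSV annotation dialect is
(gene_id, chrom, start, end, strand); ortholog tables are
(anchor_gene, species, comparator_gene, cluster_id); interactions are
(gene_a, gene_b); expression/modification matrices are TSV with a gene-id
row index and condition/mark column headers.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Mapping, Tuple

import gffutils
import pandas as pd

from .errors import InputError
from .genome import GeneRecord, GenomeAnnotation, InteractionSet, OrthologTable

ANNOT_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


# ---------------------------------------------------------------- annotations

def write_annotation_tsv(annotation: GenomeAnnotation, path: str) -> None:
    frame = pd.DataFrame(
        [(r.gene_id, r.chromosome, r.start, r.end, r.strand) for r in annotation.records],
        columns=ANNOT_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path: str, species_id: str, genome_size: int) -> GenomeAnnotation:
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    missing = set(ANNOT_COLUMNS) - set(frame.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    records = [
        GeneRecord(row.gene_id, row.chrom, int(row.start), int(row.end), row.strand)
        for row in frame.itertuples(index=False)
    ]
    return GenomeAnnotation(species_id, records, genome_size)


def write_gff3(annotation: GenomeAnnotation, path: str) -> None:
    """Minimal GFF3: one `gene` feature per record, ID attribute only."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in annotation.records:
            fh.write(
                f"{rec.chromosome}\tcolocpair\tgene\t{rec.start}\t{rec.end}\t.\t"
                f"{rec.strand}\t.\tID={rec.gene_id}\n"
            )


def read_gff3(path: str, species_id: str, genome_size: int) -> GenomeAnnotation:
    """Read gene features from a GFF3 file (in-memory gffutils database)."""
    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="error", sort_attribute_values=False,
    )
    records = []
    for feat in db.features_of_type("gene"):
        ids = feat.attributes.get("ID", [feat.id])
        strand = feat.strand if feat.strand in ("+", "-") else "."
        records.append(GeneRecord(ids[0], feat.seqid, feat.start, feat.end, strand))
    if not records:
        raise InputError(f"{path}: no gene features found")
    return GenomeAnnotation(species_id, records, genome_size)


def read_annotation(path: str, species_id: str, genome_size: int) -> GenomeAnnotation:
    """Dispatch on extension: .gff3/.gff -> GFF3, anything else -> flat TSV."""
    if path.endswith((".gff3", ".gff")):
        return read_gff3(path, species_id, genome_size)
    return read_annotation_tsv(path, species_id, genome_size)


# ------------------------------------------------------------------ orthologs

def write_ortholog_tsv(
    entries: Mapping[str, Mapping[str, Iterable[str]]],
    clusters: Mapping[Tuple[str, str, str], str],
    path: str,
) -> None:
    """Rows (anchor_gene, species, comparator_gene, cluster_id)."""
    rows = []
    for anchor in sorted(entries):
        for sp in sorted(entries[anchor]):
            for comp in sorted(entries[anchor][sp]):
                rows.append((anchor, sp, comp, clusters.get((anchor, sp, comp), "")))
    pd.DataFrame(rows, columns=["anchor_gene", "species", "comparator_gene", "cluster_id"]) \
        .to_csv(path, sep="\t", index=False)


def read_ortholog_tsv(path: str) -> OrthologTable:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"anchor_gene", "species", "comparator_gene"}
    if not needed <= set(frame.columns):
        raise InputError(f"{path}: need columns {sorted(needed)}")
    entries: Dict[str, Dict[str, set]] = {}
    for row in frame.itertuples(index=False):
        entries.setdefault(row.anchor_gene, {}).setdefault(row.species, set()).add(
            row.comparator_gene
        )
    return OrthologTable(entries)


# --------------------------------------------------------------- interactions

def write_interaction_tsv(interactions: InteractionSet, path: str) -> None:
    pd.DataFrame(sorted(interactions.pairs), columns=["gene_a", "gene_b"]) \
        .to_csv(path, sep="\t", index=False)


def read_interaction_tsv(path: str) -> InteractionSet:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_a", "gene_b"} <= set(frame.columns):
        raise InputError(f"{path}: need columns gene_a, gene_b")
    return InteractionSet.from_pairs(
        (row.gene_a, row.gene_b) for row in frame.itertuples(index=False)
    )


# ------------------------------------------------------------------- matrices

def write_matrix_tsv(matrix: pd.DataFrame, path: str) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_matrix_tsv(path: str) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col="gene_id")
    return frame


# -------------------------------------------------------------- species table

def write_species_tsv(rows: List[dict], path: str) -> None:
    """Rows with keys species_id, genome_size_bp, close_set (0/1)."""
    pd.DataFrame(rows, columns=["species_id", "genome_size_bp", "close_set"]) \
        .to_csv(path, sep="\t", index=False)


def read_species_tsv(path: str) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"species_id": str})
    if not {"species_id", "genome_size_bp"} <= set(frame.columns):
        raise InputError(f"{path}: need columns species_id, genome_size_bp")
    return frame


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
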