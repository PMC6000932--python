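"""Core genome containers: gene records, annotations, pairs, ortholog tables.

Coordinates are 1-based inclusive (GFF3 convention). Gene adjacency is a
rank property: per chromosome, genes are totally ordered by
(start, end, gene_id) and "neighboring" means adjacent in that order;
strand and intergenic distance are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Set, Tuple

from .errors import InputError

#: A gene pair in canonical (lexicographic) order.
GenePair = Tuple[str, str]

STATUS_NEIGHBORING = "NEIGHBORING"
STATUS_SEPARATED = "SEPARATED"
STATUS_ABSENT = "ABSENT"
STATUSES = (STATUS_NEIGHBORING, STATUS_SEPARATED, STATUS_ABSENT)


def gene_pair(a: str, b: str) -> GenePair:
    """Canonicalize a pair of gene ids; order of arguments never matters."""
    if a == b:
        raise InputError(f"a gene pair needs two distinct genes, got {a!r} twice")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class GeneRecord:
    """One gene: id, chromosome and a 1-based inclusive interval."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start > self.end:
            raise InputError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise InputError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass
class GenomeAnnotation:
    """Ordered gene records for one species plus its total genome size (bp)."""

    species_id: str
    records: List[GeneRecord]
    genome_size: int

    _by_id: Dict[str, GeneRecord] = field(init=False, repr=False)
    _order: Dict[str, List[str]] = field(init=False, repr=False)

    def __post_init__(self):
        if self.genome_size <= 0:
            raise InputError(f"{self.species_id}: genome_size must be > 0")
        self._by_id = {}
        for rec in self.records:
            if rec.gene_id in self._by_id:
                raise InputError(
                    f"{self.species_id}: duplicate gene id {rec.gene_id!r}"
                )
            self._by_id[rec.gene_id] = rec
        chroms: Dict[str, List[GeneRecord]] = {}
        for rec in self.records:
            chroms.setdefault(rec.chromosome, []).append(rec)
        self._order = {
            chrom: [r.gene_id for r in sorted(recs, key=lambda r: (r.start, r.end, r.gene_id))]
            for chrom, recs in chroms.items()
        }

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def gene(self, gene_id: str) -> GeneRecord:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise InputError(f"{self.species_id}: unknown gene {gene_id!r}") from None

    @property
    def gene_ids(self) -> List[str]:
        return [r.gene_id for r in self.records]

    @property
    def chromosomes(self) -> List[str]:
        return sorted(self._order)

    def ordered_genes(self, chromosome: str) -> List[str]:
        """Gene ids of one chromosome in (start, end, gene_id) rank order."""
        return list(self._order.get(chromosome, []))


def neighboring_pairs(annotation: GenomeAnnotation) -> Set[GenePair]:
    """All rank-adjacent gene pairs, per chromosome.

    The result is independent of the textual order of the input records:
    adjacency is defined on the sorted per-chromosome gene order.
    """
    if len(annotation) == 0:
        raise InputError(f"{annotation.species_id}: empty annotation")
    pairs: Set[GenePair] = set()
    for chrom in annotation.chromosomes:
        order = annotation.ordered_genes(chrom)
        for left, right in zip(order, order[1:]):
            pairs.add(gene_pair(left, right))
    return pairs


def adjacency_index(annotation: GenomeAnnotation) -> Dict[str, Set[str]]:
    """gene_id -> set of rank-adjacent gene ids (both directions)."""
    index: Dict[str, Set[str]] = {g: set() for g in annotation.gene_ids}
    for chrom in annotation.chromosomes:
        order = annotation.ordered_genes(chrom)
        for left, right in zip(order, order[1:]):
            index[left].add(right)
            index[right].add(left)
    return index


@dataclass
class InteractionSet:
    """Same-chromosome (intrachromosomal) interacting gene pairs."""

    pairs: Set[GenePair]

    @classmethod
    def from_pairs(cls, pairs: Iterable[Tuple[str, str]]) -> "InteractionSet":
        return cls({gene_pair(a, b) for a, b in pairs})

    def validate_same_chromosome(self, annotation: GenomeAnnotation) -> None:
        for a, b in self.pairs:
            if annotation.gene(a).chromosome != annotation.gene(b).chromosome:
                raise InputError(
                    f"interaction pair ({a}, {b}) spans chromosomes "
                    f"{annotation.gene(a).chromosome} and {annotation.gene(b).chromosome}"
                )

    def __contains__(self, pair: GenePair) -> bool:
        return pair in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


class OrthologTable:
    """anchor gene id -> comparator species -> set of comparator gene ids.

    Many-to-many maps are allowed: an anchor gene may have several
    co-orthologs in a species (e.g. tandem duplicates sharing a cluster).
    """

    def __init__(self, entries: Mapping[str, Mapping[str, Iterable[str]]]):
        self._map: Dict[str, Dict[str, FrozenSet[str]]] = {
            anchor: {sp: frozenset(genes) for sp, genes in per_sp.items()}
            for anchor, per_sp in entries.items()
        }

    def orthologs(self, anchor_gene: str, species: str) -> FrozenSet[str]:
        return self._map.get(anchor_gene, {}).get(species, frozenset())

    @property
    def species(self) -> List[str]:
        seen: Set[str] = set()
        for per_sp in self._map.values():
            seen.update(per_sp)
        return sorted(seen)

    @property
    def anchor_genes(self) -> List[str]:
        return sorted(self._map)

    def validate_against(self, comparators: Mapping[str, GenomeAnnotation]) -> None:
        """Every referenced comparator gene must exist in its annotation."""
        for anchor, per_sp in self._map.items():
            for sp, genes in per_sp.items():
                ann = comparators.get(sp)
                if ann is None:
                    continue
                for g in genes:
                    if g not in ann:
                        raise InputError(
                            f"ortholog table: {anchor} -> {sp}:{g} but {g!r} "
                            f"is not annotated in {sp}"
                        )
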