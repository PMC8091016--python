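"""Variant filtering and protein-level consequence classification.

Starting from a table of called variants (position, ref/alt, supporting-read
fraction, depth), this module:

* filters out weakly supported calls (by default those supported by fewer
  than 35% of reads or fewer than 10 total reads; boundary values are kept);
* classifies each surviving variant against a genome and CDS gene models as
  synonymous, missense, nonsense (premature stop), frameshift, in-frame
  indel, intergenic, or mobile-element insertion;
* pivots classified calls into a mutation x isolate frequency matrix.

Conventions: coordinates are 1-based inclusive; insertions are anchored to
the base before the inserted sequence; indels are left-aligned before
classification; translation uses the bacterial/plant genetic code (table
11) with alternative initiators reported as the amino acid of the literal
codon; protein changes follow three-letter notation (Gly148Val, Glu115*,
Ala361fs, "-" for synonymous); upstream/downstream is defined relative to
the affected gene's own strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio.Data import CodonTable
from Bio.SeqUtils import seq3

from .io_formats import GeneModel, VariantRecord

__all__ = [
    "Consequence",
    "FilterResult",
    "filter_variants",
    "classify_variant",
    "mutation_frequency_table",
    "ReferenceDiscordanceError",
]

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASES = "ACGT"


class ReferenceDiscordanceError(ValueError):
    """The record's ref allele does not match the genome at its position."""


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _translate_codon(codon: str) -> str:
    """One-letter amino acid, '*' for stop (genetic code table 11)."""
    if codon in _TABLE11.stop_codons:
        return "*"
    return _TABLE11.forward_table[codon]


def _aa3(aa1: str) -> str:
    return "*" if aa1 == "*" else seq3(aa1)


@dataclass
class Consequence:
    """Classified effect of one variant.

    ``notation`` is the protein-level change for coding variants ("-" for
    synonymous); ``distance_bp``/``orientation`` are set for intergenic
    variants, measured to the nearest gene boundary relative to that gene's
    own strand.
    """

    category: str  # missense | nonsense | synonymous | frameshift |
    #               inframe_indel | intergenic | mobile_element_insertion
    gene: str | None = None
    notation: str | None = None
    distance_bp: int | None = None
    orientation: str | None = None  # "upstream" | "downstream"

    @property
    def region_label(self) -> str:
        """Row label in the Table-3-style matrix."""
        if self.distance_bp is not None:
            return f"{self.distance_bp} bp {self.orientation} of {self.gene}"
        return self.gene or "unassigned"


@dataclass
class FilterResult:
    kept: list[VariantRecord]
    removed_low_frequency: int
    removed_low_depth: int

    @property
    def n_removed(self) -> int:
        return self.removed_low_frequency + self.removed_low_depth


def filter_variants(
    records: Sequence[VariantRecord],
    min_frequency: float = 0.35,
    min_depth: int = 10,
    inclusive: bool = True,
) -> FilterResult:
    """Drop weakly supported variants; boundary values are kept by default.

    A record survives when frequency >= min_frequency AND depth >= min_depth
    (strict inequalities when ``inclusive`` is False).  Counts of records
    failing each criterion are returned; a record failing both is counted
    under both.
    """
    kept = []
    low_freq = low_depth = 0
    for rec in records:
        if inclusive:
            freq_ok = rec.frequency >= min_frequency
            depth_ok = rec.depth >= min_depth
        else:
            freq_ok = rec.frequency > min_frequency
            depth_ok = rec.depth > min_depth
        if not freq_ok:
            low_freq += 1
        if not depth_ok:
            low_depth += 1
        if freq_ok and depth_ok:
            kept.append(rec)
    return FilterResult(kept=kept, removed_low_frequency=low_freq,
                        removed_low_depth=low_depth)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def _left_align(seq: str, pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-align a pure indel against the reference sequence.

    ``pos`` is 1-based: the first deleted base for deletions, the anchor
    base before the insertion for insertions.  SNVs pass through unchanged.
    """
    if ref != "-" and alt != "-":
        return pos, ref, alt
    if alt == "-":  # deletion of `ref` starting at pos
        allele = ref
        while pos > 1 and seq[pos - 2] == allele[-1]:
            allele = seq[pos - 2] + allele[:-1]
            pos -= 1
        return pos, allele, "-"
    # insertion of `alt` after pos
    allele = alt
    while pos >= 1 and allele[-1] == seq[pos - 1]:
        allele = seq[pos - 1] + allele[:-1]
        pos -= 1
    return pos, "-", allele


def _containing_gene(genes: Sequence[GeneModel], contig: str, pos: int,
                     is_insertion: bool) -> GeneModel | None:
    for gene in genes:
        if gene.contig != contig:
            continue
        if is_insertion:
            # the inserted sequence sits between pos and pos+1
            if gene.start <= pos < gene.end:
                return gene
        elif gene.start <= pos <= gene.end:
            return gene
    return None


def _nearest_gene(genes: Sequence[GeneModel], contig: str, pos: int):
    """Nearest gene boundary with strand-aware orientation."""
    best = None
    for gene in sorted((g for g in genes if g.contig == contig),
                       key=lambda g: g.start):
        if pos < gene.start:
            dist, side = gene.start - pos, "left"
        elif pos > gene.end:
            dist, side = pos - gene.end, "right"
        else:
            dist, side = 0, "inside"
        if best is None or dist < best[1]:
            best = (gene, dist, side)
    if best is None:
        return None
    gene, dist, side = best
    if gene.strand == "+":
        orientation = "upstream" if side == "left" else "downstream"
    else:
        orientation = "downstream" if side == "left" else "upstream"
    return gene, dist, orientation


def _cds_position(gene: GeneModel, pos: int) -> int:
    """1-based position within the CDS, counted from the initiator codon."""
    if gene.strand == "+":
        return pos - gene.start + 1
    return gene.end - pos + 1


def _gene_sequence(genome_seq: str, gene: GeneModel) -> str:
    region = genome_seq[gene.start - 1 : gene.end]
    return _revcomp(region) if gene.strand == "-" else region


def classify_variant(
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
    v: VariantRecord,
) -> Consequence:
    """Classify one variant's protein-level or intergenic consequence.

    SNVs inside a CDS translate the reference and alternative codons and
    report synonymous ("-"), missense (RefAA Pos AltAA) or nonsense
    (RefAA Pos *).  Indels inside a CDS are frameshifts when their length
    is not divisible by 3 (notation: amino acid at the first affected codon
    + "fs"), otherwise in-frame indels.  Named alt tokens are mobile-element
    insertions.  Everything else is intergenic, annotated with the distance
    and strand-aware orientation to the nearest gene.
    """
    if v.contig not in genome:
        raise ValueError(f"contig {v.contig!r} not in genome")
    seq = genome[v.contig]
    if v.pos > len(seq):
        raise ValueError(f"position {v.pos} beyond contig {v.contig!r} ({len(seq)} bp)")
    if v.ref != "-":
        observed = seq[v.pos - 1 : v.pos - 1 + len(v.ref)]
        if observed != v.ref:
            raise ReferenceDiscordanceError(
                f"reference discordance at {v.contig}:{v.pos}: "
                f"expected {v.ref!r}, genome has {observed!r}"
            )

    if v.is_named_insertion:
        gene = _containing_gene(genes, v.contig, v.pos, is_insertion=True)
        if gene is not None:
            return Consequence(category="mobile_element_insertion",
                               gene=gene.gene, notation=v.alt)
        near = _nearest_gene(genes, v.contig, v.pos)
        if near is None:
            return Consequence(category="mobile_element_insertion", notation=v.alt)
        gene, dist, orientation = near
        return Consequence(category="mobile_element_insertion", gene=gene.gene,
                           notation=v.alt, distance_bp=dist, orientation=orientation)

    pos, ref, alt = _left_align(seq, v.pos, v.ref, v.alt)
    is_insertion = ref == "-"
    gene = _containing_gene(genes, v.contig, pos, is_insertion)

    if gene is None:
        near = _nearest_gene(genes, v.contig, pos)
        if near is None:
            return Consequence(category="intergenic", notation="-")
        ngene, dist, orientation = near
        return Consequence(category="intergenic", gene=ngene.gene, notation="-",
                           distance_bp=dist, orientation=orientation)

    gene_seq = _gene_sequence(seq, gene)

    if ref != "-" and alt != "-":  # SNV
        cds_pos = _cds_position(gene, pos)
        codon_idx = (cds_pos - 1) // 3
        offset = (cds_pos - 1) % 3
        codon = gene_seq[3 * codon_idx : 3 * codon_idx + 3]
        ref_base = ref if gene.strand == "+" else ref.translate(_COMPLEMENT)
        alt_base = alt if gene.strand == "+" else alt.translate(_COMPLEMENT)
        assert codon[offset] == ref_base
        alt_codon = codon[:offset] + alt_base + codon[offset + 1 :]
        ref_aa = _translate_codon(codon)
        alt_aa = _translate_codon(alt_codon)
        residue = codon_idx + 1
        if ref_aa == alt_aa:
            return Consequence(category="synonymous", gene=gene.gene, notation="-")
        if alt_aa == "*":
            return Consequence(category="nonsense", gene=gene.gene,
                               notation=f"{_aa3(ref_aa)}{residue}*")
        return Consequence(category="missense", gene=gene.gene,
                           notation=f"{_aa3(ref_aa)}{residue}{_aa3(alt_aa)}")

    # indel
    length = len(alt) if is_insertion else len(ref)
    if is_insertion:
        # first CDS base shifted by the insertion, in reading direction
        first_pos = pos + 1 if gene.strand == "+" else pos
    else:
        first_pos = pos if gene.strand == "+" else pos + length - 1
    cds_pos = _cds_position(gene, first_pos)
    residue = (cds_pos - 1) // 3 + 1
    codon = gene_seq[3 * (residue - 1) : 3 * residue]
    aa = _aa3(_translate_codon(codon)) if len(codon) == 3 else "?"
    if length % 3 != 0:
        return Consequence(category="frameshift", gene=gene.gene,
                           notation=f"{aa}{residue}fs")
    kind = "ins" if is_insertion else "del"
    return Consequence(category="inframe_indel", gene=gene.gene,
                       notation=f"{aa}{residue}{kind}")


# ---------------------------------------------------------------------------
# Frequency matrix
# ---------------------------------------------------------------------------


def _description(record: VariantRecord, cons: Consequence) -> str:
    if record.is_named_insertion:
        return record.alt
    base = f"{record.ref} → {record.alt}"
    if cons.notation and cons.notation != "-" or cons.category == "synonymous":
        return f"{base}, {cons.notation}"
    return base


def mutation_frequency_table(
    classified: Sequence[tuple[VariantRecord, Consequence]],
):
    """Pivot classified calls into a mutation x isolate frequency matrix.

    Rows are keyed by (gene-or-region, genomic start, description) and
    ordered by genomic position; cells hold the supporting-read frequency
    in each isolate (NaN when the isolate lacks the mutation); the final
    ``n_isolates`` column counts carriers.
    """
    import pandas as pd

    if not classified:
        return pd.DataFrame(columns=["region", "pos", "description", "n_isolates"])
    rows = []
    isolate_order: list[str] = []
    for record, cons in classified:
        if record.isolate not in isolate_order:
            isolate_order.append(record.isolate)
        rows.append(
            {
                "region": cons.region_label,
                "pos": record.pos,
                "description": _description(record, cons),
                "isolate": record.isolate,
                "frequency": record.frequency,
            }
        )
    frame = pd.DataFrame(rows)
    matrix = frame.pivot_table(
        index=["region", "pos", "description"],
        columns="isolate",
        values="frequency",
        aggfunc="max",
    )
    matrix = matrix.reindex(columns=isolate_order)
    matrix["n_isolates"] = matrix.notna().sum(axis=1)
    matrix = matrix.sort_index(level="pos", sort_remaining=False)
    matrix.columns.name = None
    return matrix
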