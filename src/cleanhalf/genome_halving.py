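"""Split a genome into clean and contaminant halves.

Halving removes floor(total/2) nucleotides (or marker genes) from the most
contaminated end of the contig ordering; at most one contig is divided, and
that contig is first oriented so its more contaminated end leads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_formats import ContigSeq, GeneAssignment, TaxonomyString
from .contig_scoring import gene_is_congruent

_COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVN",
    "TGCAAYRSWMKVHDBN",
)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class HalvingResult:
    clean: list[ContigSeq]
    contaminant: list[ContigSeq]
    split_contig_id: str | None
    mode: str  # nucleotide | marker | random
    seed: int | None = None
    clean_marker_ids: list[str] = field(default_factory=list)
    removed_marker_ids: list[str] = field(default_factory=list)

    @property
    def clean_nt(self) -> int:
        return sum(c.length for c in self.clean)

    @property
    def contaminant_nt(self) -> int:
        return sum(c.length for c in self.contaminant)


def orient_contig(
    contig: ContigSeq,
    genes: Sequence[GeneAssignment],
    genome_tax_truncated: TaxonomyString,
) -> tuple[ContigSeq, bool]:
    """Orient a contig so its most contaminated end leads.

    The gene list (in positional order) is split into leading and trailing
    halves; if the trailing half carries strictly more incongruent genes the
    contig is reverse-complemented.  Ties and gene-less contigs keep the
    original orientation.  Returns (oriented contig, was_reversed).
    """
    if not genes:
        return contig, False
    ordered = sorted(genes, key=lambda g: g.gene_index)
    n = len(ordered)
    half = n // 2
    head = ordered[:half]
    tail = ordered[n - half :]
    bad_head = sum(
        not gene_is_congruent(g.hit_taxonomy, genome_tax_truncated) for g in head
    )
    bad_tail = sum(
        not gene_is_congruent(g.hit_taxonomy, genome_tax_truncated) for g in tail
    )
    if bad_tail > bad_head:
        return ContigSeq(contig.contig_id, reverse_complement(contig.sequence)), True
    return contig, False


def split_by_nucleotides(
    contigs_in_order: Sequence[ContigSeq],
    genes_by_contig: Mapping[str, Sequence[GeneAssignment]] | None = None,
    genome_tax_truncated: TaxonomyString | None = None,
    mode: str = "nucleotide",
    seed: int | None = None,
) -> HalvingResult:
    """Remove floor(total nt / 2) from the most contaminated end of the order.

    ``contigs_in_order`` must be pre-ordered most to least contaminated.
    Whole contigs are moved to the contaminant half until the target is
    reached; if a contig must be divided it is oriented (when gene data is
    available) and its most contaminated end pruned to the required length.
    """
    if not contigs_in_order:
        raise ValueError("cannot split an empty genome")
    total = sum(c.length for c in contigs_in_order)
    need = total // 2  # odd totals: clean half keeps the extra base
    contaminant: list[ContigSeq] = []
    clean: list[ContigSeq] = []
    split_id: str | None = None
    for contig in contigs_in_order:
        if need >= contig.length:
            contaminant.append(contig)
            need -= contig.length
        elif need > 0:
            oriented = contig
            if genes_by_contig is not None and genome_tax_truncated is not None:
                oriented, _ = orient_contig(
                    contig,
                    genes_by_contig.get(contig.contig_id, []),
                    genome_tax_truncated,
                )
            contaminant.append(ContigSeq(contig.contig_id, oriented.sequence[:need]))
            clean.append(ContigSeq(contig.contig_id, oriented.sequence[need:]))
            split_id = contig.contig_id
            need = 0
        else:
            clean.append(contig)
    return HalvingResult(
        clean=clean,
        contaminant=contaminant,
        split_contig_id=split_id,
        mode=mode,
        seed=seed,
    )


def split_by_markers(
    contigs_in_order: Sequence[ContigSeq],
    genes_by_contig: Mapping[str, Sequence[GeneAssignment]],
    genome_tax_truncated: TaxonomyString | None = None,
) -> HalvingResult:
    """Remove floor(total markers / 2) marker genes from the contaminated end.

    Markers are walked in the contig contamination order; within a divided
    contig, markers are removed in contaminated-to-clean positional order
    (after orientation).  The divided contig's sequence is cut at a position
    proportional to the number of genes on the removed side, so nucleotide
    totals are conserved.
    """
    if not contigs_in_order:
        raise ValueError("cannot split an empty genome")
    total_markers = sum(
        sum(g.is_marker for g in genes_by_contig.get(c.contig_id, ()))
        for c in contigs_in_order
    )
    if total_markers == 0:
        raise ValueError("genome has no marker genes")
    need = total_markers // 2
    contaminant: list[ContigSeq] = []
    clean: list[ContigSeq] = []
    removed_ids: list[str] = []
    kept_ids: list[str] = []
    split_id: str | None = None
    for contig in contigs_in_order:
        genes = sorted(
            genes_by_contig.get(contig.contig_id, ()), key=lambda g: g.gene_index
        )
        oriented_genes = genes
        oriented_seq = contig
        was_reversed = False
        if genome_tax_truncated is not None and genes:
            oriented_seq, was_reversed = orient_contig(
                contig, genes, genome_tax_truncated
            )
        if was_reversed:
            oriented_genes = genes[::-1]
        markers = [g for g in oriented_genes if g.is_marker]
        if need >= len(markers) and need > 0:
            contaminant.append(contig)
            removed_ids.extend(g.gene_id for g in markers)
            need -= len(markers)
        elif need > 0:
            removed = markers[:need]
            kept = markers[need:]
            removed_ids.extend(g.gene_id for g in removed)
            kept_ids.extend(g.gene_id for g in kept)
            # Cut between the last removed and first kept marker, placing the
            # boundary proportionally along the gene order.
            last_removed_pos = oriented_genes.index(removed[-1])
            cut = round(contig.length * (last_removed_pos + 1) / (len(oriented_genes) + 1))
            cut = min(max(cut, 1), contig.length - 1)
            contaminant.append(ContigSeq(contig.contig_id, oriented_seq.sequence[:cut]))
            clean.append(ContigSeq(contig.contig_id, oriented_seq.sequence[cut:]))
            split_id = contig.contig_id
            need = 0
        else:
            clean.append(contig)
            kept_ids.extend(g.gene_id for g in markers)
    return HalvingResult(
        clean=clean,
        contaminant=contaminant,
        split_contig_id=split_id,
        mode="marker",
        clean_marker_ids=kept_ids,
        removed_marker_ids=removed_ids,
    )


def random_half(contigs: Sequence[ContigSeq], seed: int) -> HalvingResult:
    """Baseline: shuffle the contig order with a seeded PRNG, then split by
    nucleotides on that order (no orientation information is used)."""
    if not contigs:
        raise ValueError("cannot split an empty genome")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(contigs))
    shuffled = [contigs[i] for i in order]
    result = split_by_nucleotides(shuffled, mode="random", seed=seed)
    return result
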