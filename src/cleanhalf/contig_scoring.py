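"""Per-contig contamination scoring.

Derives a genome consensus taxonomy by per-rank majority vote over all gene
assignments, a per-contig taxonomy with tie-rank dropping, truncates both at
the genome's clade-separation rank, and orders contigs from most to least
contaminated.  The ordering key is (divergence depth ascending, congruent
gene fraction ascending, longer contig first, contig id).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import (
    RANK_CODES,
    RANK_INDEX,
    ContigSeq,
    GeneAssignment,
    TaxonomyString,
)


@dataclass(frozen=True)
class ContigScore:
    """Contamination ordering key for one contig.

    divergence_depth: index (0 = domain) of the first rank, scanning from
    domain to the CSS rank, at which the contig taxonomy disagrees with the
    genome taxonomy; css_rank_index + 1 if fully congruent.  Smaller depth
    means more contaminated.
    """

    contig_id: str
    divergence_depth: int
    congruent_fraction: float
    n_genes: int
    length: int = 0

    def sort_key(self) -> tuple:
        # Most contaminated first: shallow divergence, few congruent genes,
        # longer contig, then id for determinism.
        return (
            self.divergence_depth,
            self.congruent_fraction,
            -self.length,
            self.contig_id,
        )


def genome_consensus_taxonomy(
    assignments: Sequence[GeneAssignment],
) -> TaxonomyString:
    """Most commonly inferred taxon at each rank across all genes.

    Each rank is voted independently over the genes that carry a name at
    that rank; ranks with no named hits are left unnamed.  Ties are broken
    lexicographically for determinism.
    """
    if not assignments:
        raise ValueError("need at least one gene assignment")
    ranks = []
    for code in RANK_CODES:
        counts = Counter(
            name
            for g in assignments
            if (name := g.hit_taxonomy.named_at(code)) is not None
        )
        if counts:
            top = max(counts.values())
            winner = min(n for n, c in counts.items() if c == top)
            ranks.append((code, winner))
        else:
            ranks.append((code, ""))
    return TaxonomyString(tuple(ranks))


def contig_taxonomy(genes: Sequence[GeneAssignment]) -> TaxonomyString:
    """Majority vote per rank over a contig's genes; tied ranks are dropped."""
    if not genes:
        raise ValueError("need at least one gene on the contig")
    ranks = []
    for code in RANK_CODES:
        counts = Counter(
            name
            for g in genes
            if (name := g.hit_taxonomy.named_at(code)) is not None
        )
        if not counts:
            continue
        top = max(counts.values())
        winners = [n for n, c in counts.items() if c == top]
        if len(winners) > 1:
            continue  # tied rank not considered
        ranks.append((code, winners[0]))
    return TaxonomyString(tuple(ranks))


def truncate_to_css_rank(tax: TaxonomyString, css_rank: str) -> TaxonomyString:
    if css_rank not in RANK_INDEX:
        raise ValueError(f"css_rank {css_rank!r} not a canonical rank")
    return tax.truncate(css_rank)


def gene_is_congruent(
    gene_tax: TaxonomyString, genome_tax_truncated: TaxonomyString
) -> bool:
    """True iff the gene lineage matches the truncated genome taxonomy at
    every rank the genome taxonomy names."""
    for code, name in genome_tax_truncated.ranks:
        if not name:
            continue  # unnamed consensus rank matches anything
        if gene_tax.named_at(code) != name:
            return False
    return True


def score_contig(
    contig_tax: TaxonomyString,
    genome_tax_truncated: TaxonomyString,
    genes: Sequence[GeneAssignment],
    css_rank: str,
    contig_id: str = "",
    length: int = 0,
) -> ContigScore:
    """Score one contig against the truncated genome taxonomy.

    Ranks dropped from the contig taxonomy by ties, and unnamed ranks on
    either side, are skipped when scanning for the first disagreement.
    """
    css_idx = RANK_INDEX[css_rank]
    depth = css_idx + 1
    for code in RANK_CODES[: css_idx + 1]:
        genome_name = genome_tax_truncated.named_at(code)
        contig_name = contig_tax.named_at(code)
        if genome_name is None or contig_name is None:
            continue
        if genome_name != contig_name:
            depth = RANK_INDEX[code]
            break
    if genes:
        n_congruent = sum(
            gene_is_congruent(g.hit_taxonomy, genome_tax_truncated) for g in genes
        )
        fraction = n_congruent / len(genes)
    else:
        fraction = 1.0
    return ContigScore(
        contig_id=contig_id,
        divergence_depth=depth,
        congruent_fraction=fraction,
        n_genes=len(genes),
        length=length,
    )


def group_genes_by_contig(
    assignments: Iterable[GeneAssignment],
) -> dict[str, list[GeneAssignment]]:
    grouped: dict[str, list[GeneAssignment]] = {}
    for g in assignments:
        grouped.setdefault(g.contig_id, []).append(g)
    for genes in grouped.values():
        genes.sort(key=lambda g: g.gene_index)
    return grouped


def rank_contigs(
    contigs: Sequence[ContigSeq],
    assignments: Sequence[GeneAssignment],
    css_rank: str,
) -> list[ContigScore]:
    """Score every contig of a genome and order them most contaminated first.

    Contigs without any gene assignment are treated as least contaminated
    (no evidence of contamination).
    """
    genome_tax = truncate_to_css_rank(genome_consensus_taxonomy(assignments), css_rank)
    by_contig = group_genes_by_contig(assignments)
    css_idx = RANK_INDEX[css_rank]
    scores = []
    for contig in contigs:
        genes = by_contig.get(contig.contig_id, [])
        if genes:
            ctax = truncate_to_css_rank(contig_taxonomy(genes), css_rank)
            score = score_contig(
                ctax, genome_tax, genes, css_rank, contig.contig_id, contig.length
            )
        else:
            score = ContigScore(
                contig_id=contig.contig_id,
                divergence_depth=css_idx + 1,
                congruent_fraction=1.0,
                n_genes=0,
                length=contig.length,
            )
        scores.append(score)
    scores.sort(key=ContigScore.sort_key)
    return scores


def clade_separation_proxy(
    assignments: Sequence[GeneAssignment],
) -> tuple[dict[str, float], str]:
    """Simplified per-rank clade-separation scores for synthetic inputs.

    score(r) = 1 - fraction of genes congruent with the consensus taxonomy
    through rank r.  Returns the per-rank table and the argmax rank, with
    the shallowest rank winning ties.
    """
    if not assignments:
        raise ValueError("need at least one gene assignment")
    consensus = genome_consensus_taxonomy(assignments)
    table: dict[str, float] = {}
    best_rank = RANK_CODES[0]
    best_score = -1.0
    for code in RANK_CODES:
        trunc = consensus.truncate(code)
        congruent = sum(
            gene_is_congruent(g.hit_taxonomy, trunc) for g in assignments
        )
        score = 1.0 - congruent / len(assignments)
        table[code] = score
        if score > best_score + 1e-12:
            best_score = score
            best_rank = code
    return table, best_rank
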