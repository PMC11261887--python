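"""Shared test helpers: tiny constructors and independent brute-force oracles."""

from __future__ import annotations

from itertools import count

from cleanhalf.io_formats import ContigSeq, GeneAssignment, TaxonomyString

_gene_counter = count()


def tax(text: str) -> TaxonomyString:
    return TaxonomyString.parse(text)


def gene(contig_id: str, gene_index: int, taxonomy: str, marker: bool = False) -> GeneAssignment:
    return GeneAssignment(
        gene_id=f"g{next(_gene_counter)}",
        contig_id=contig_id,
        gene_index=gene_index,
        hit_taxonomy=tax(taxonomy),
        is_marker=marker,
    )


# ---------------------------------------------------------------------------
# Brute-force oracles (kept independent of the implementation paths they check)


def oracle_modal_per_rank(assignments) -> dict[str, str]:
    """Count every (rank, name) pair explicitly; modal name per rank, ties
    broken lexicographically (mirrors the consensus contract)."""
    counts: dict[str, dict[str, int]] = {}
    for g in assignments:
        for code, name in g.hit_taxonomy.ranks:
            if name:
                counts.setdefault(code, {}).setdefault(name, 0)
                counts[code][name] += 1
    out = {}
    for code, names in counts.items():
        top = max(names.values())
        out[code] = min(n for n, c in names.items() if c == top)
    return out


def oracle_order_by_key(scores) -> list[str]:
    """Selection sort on the stated contamination key, checking every
    pairwise order relation explicitly."""
    items = list(scores)
    ordered = []
    while items:
        best = items[0]
        for other in items[1:]:
            if _more_contaminated(other, best):
                best = other
        ordered.append(best.contig_id)
        items.remove(best)
    return ordered


def _more_contaminated(a, b) -> bool:
    if a.divergence_depth != b.divergence_depth:
        return a.divergence_depth < b.divergence_depth
    if a.congruent_fraction != b.congruent_fraction:
        return a.congruent_fraction < b.congruent_fraction
    if a.length != b.length:
        return a.length > b.length
    return a.contig_id < b.contig_id


def oracle_nt_split(contigs: list[ContigSeq]) -> tuple[list[str], str | None, int]:
    """Walk the order accumulating whole contigs into the removed set until
    floor(total/2); return (wholly removed ids, split id, nt taken from it)."""
    total = sum(c.length for c in contigs)
    need = total // 2
    removed, split_id, split_nt = [], None, 0
    for c in contigs:
        if need >= c.length:
            removed.append(c.contig_id)
            need -= c.length
        elif need > 0:
            split_id, split_nt = c.contig_id, need
            need = 0
    return removed, split_id, split_nt


def oracle_kmer_jaccard(a: str, b: str, k: int) -> float:
    """Exhaustive canonical k-mer set Jaccard."""
    sa = _canonical_set(a, k)
    sb = _canonical_set(b, k)
    if not sa and not sb:
        return 0.0
    return len(sa & sb) / len(sa | sb)


_COMP = str.maketrans("ACGT", "TGCA")


def _canonical_set(seq: str, k: int) -> set[str]:
    out = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if set(kmer) - set("ACGT"):
            continue
        rc = kmer.translate(_COMP)[::-1]
        out.add(min(kmer, rc))
    return out
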