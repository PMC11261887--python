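"""Synthetic taxonomy, reference genomes, chimeric queries and noisy
per-gene assignments.

Everything is generated from a seed so the whole pipeline can be exercised
without any downloads.  The sequence model is i.i.d. substitutions on a
random root (no indels by default); divergence accumulates per rank step so
sequence identity decreases with taxonomic distance.  Assignment noise is a
rank-uniform sibling swap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .io_formats import (
    RANK_CODES,
    RANK_INDEX,
    ContigSeq,
    GeneAssignment,
    GenomeSummary,
    TaxonomyString,
    write_fasta,
    write_gene_assignments,
    write_genome_summaries,
    write_rep_metadata,
)
from .contig_scoring import clade_separation_proxy

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 1
    taxa_per_rank: tuple[int, int, int, int, int, int] = (2, 2, 2, 2, 2, 2)
    genome_len: int = 30_000
    n_contigs: int = 10
    genes_per_kb: float = 1.0
    contamination_fraction: float = 0.3
    contamination_rank: str = "f"
    assignment_error: float = 0.05
    divergence_per_rank: float = 0.03
    query_mutation: float = 0.005
    marker_every: int = 10
    indel_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.contamination_fraction <= 0.5:
            raise ValueError("contamination_fraction must be in [0, 0.5]")
        if self.contamination_rank not in RANK_INDEX:
            raise ValueError(f"unknown rank {self.contamination_rank!r}")
        if not 0.0 <= self.assignment_error <= 1.0:
            raise ValueError("assignment_error must be in [0, 1]")
        if len(self.taxa_per_rank) != 6:
            raise ValueError("taxa_per_rank needs 6 fan-outs (p,c,o,f,g,s)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "taxa_per_rank" in data:
            data["taxa_per_rank"] = tuple(data["taxa_per_rank"])
        return cls(**data)


@dataclass(frozen=True)
class SyntheticTruth:
    host_taxon: TaxonomyString
    donor_taxon: TaxonomyString | None
    contaminant_contigs: frozenset[str]
    true_css_rank: str


@dataclass(frozen=True)
class ReferenceSet:
    """Species-representative database: taxonomy plus one sequence each."""

    taxonomy: dict[str, TaxonomyString]
    sequences: dict[str, str]


@dataclass(frozen=True)
class ChimericGenome:
    accession: str
    host_accession: str
    contigs: list[ContigSeq]
    truth: SyntheticTruth


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. substitutions to a uniformly chosen different base."""
    out = seq.copy()
    if rate <= 0.0:
        return out
    hit = rng.random(len(seq)) < rate
    n = int(hit.sum())
    if n:
        out[hit] = (out[hit] + rng.integers(1, 4, size=n).astype(np.uint8)) % 4
    return out


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def generate_taxonomy(config: SimConfig) -> dict[str, TaxonomyString]:
    """Balanced taxonomy over the configured fan-outs; one species
    representative accession per species, deterministic for a given config."""
    prefixes = ("Phy", "Cls", "Ord", "Fam", "Gen", "Spc")
    out: dict[str, TaxonomyString] = {}

    def walk(level: int, path: list[str], digits: list[str]) -> None:
        if level == 6:
            acc = f"R{len(out):05d}"
            ranks = [("d", "Bacteria")] + [
                (RANK_CODES[i + 1], path[i]) for i in range(6)
            ]
            out[acc] = TaxonomyString(tuple(ranks))
            return
        for i in range(config.taxa_per_rank[level]):
            # Encode the path so names are unique across the whole tree.
            name = prefixes[level] + "_".join(digits + [str(i)])
            walk(level + 1, path + [name], digits + [str(i)])

    walk(0, [], [])
    return out


def generate_reference_db(
    taxonomy: Mapping[str, TaxonomyString], config: SimConfig
) -> dict[str, str]:
    """One sequence per species representative.

    Each phylum gets an independent random root; every step down the ranks
    adds ``divergence_per_rank`` substitutions, so identity falls
    monotonically (in expectation) with taxonomic distance.
    """
    rng = np.random.default_rng([config.seed, 101])
    node_seqs: dict[tuple[str, ...], np.ndarray] = {}
    out: dict[str, str] = {}
    for acc, tax in taxonomy.items():
        names = tuple(name for code, name in tax.ranks if code != "d")
        for depth in range(1, len(names) + 1):
            key = names[:depth]
            if key in node_seqs:
                continue
            if depth == 1:
                node_seqs[key] = rng.integers(
                    0, 4, size=config.genome_len, dtype=np.uint8
                )
            else:
                node_seqs[key] = _mutate(
                    node_seqs[key[:-1]], config.divergence_per_rank, rng
                )
        out[acc] = _decode(node_seqs[names])
    return out


def build_reference_set(config: SimConfig) -> ReferenceSet:
    taxonomy = generate_taxonomy(config)
    return ReferenceSet(taxonomy=taxonomy, sequences=generate_reference_db(taxonomy, config))


def _pick_donor(
    host_tax: TaxonomyString,
    taxonomy: Mapping[str, TaxonomyString],
    rank: str,
    rng: np.random.Generator,
) -> str:
    """A species whose lineage first differs from the host at ``rank``."""
    shallower = [c for c in RANK_CODES if RANK_INDEX[c] < RANK_INDEX[rank]]
    candidates = [
        acc
        for acc, tax in taxonomy.items()
        if tax.named_at(rank) != host_tax.named_at(rank)
        and all(tax.named_at(c) == host_tax.named_at(c) for c in shallower)
    ]
    if not candidates:
        raise ValueError(f"no donor available at rank {rank!r}")
    return candidates[int(rng.integers(len(candidates)))]


def _contig_sizes(total: int, n: int) -> list[int]:
    base = total // n
    sizes = [base] * n
    sizes[0] += total - base * n
    return sizes


def make_chimera(
    refs: ReferenceSet,
    config: SimConfig,
    rng: np.random.Generator,
    host_accession: str | None = None,
    accession: str = "CHIMERA",
) -> ChimericGenome:
    """Host contigs from a lightly mutated host representative plus
    contaminant contigs from a donor at the configured rank distance.

    The realised contaminant fraction is within one contig length of the
    configured target; contig order is shuffled so position carries no
    signal.
    """
    accs = sorted(refs.taxonomy)
    if host_accession is None:
        host_accession = accs[int(rng.integers(len(accs)))]
    host_tax = refs.taxonomy[host_accession]
    host_arr = _NT_CODE_ARR(refs.sequences[host_accession])
    host_arr = _mutate(host_arr, config.query_mutation, rng)

    frac = config.contamination_fraction
    n_contam = max(1, round(config.n_contigs * frac)) if frac > 0 else 0
    n_host = config.n_contigs - n_contam
    if n_host < 1:
        raise ValueError("contamination leaves no host contigs")
    contam_nt = round(config.genome_len * frac) if n_contam else 0
    host_nt = config.genome_len - contam_nt

    donor_tax = None
    pieces: list[tuple[np.ndarray, bool]] = []
    pos = 0
    for size in _contig_sizes(host_nt, n_host):
        pieces.append((host_arr[pos : pos + size], False))
        pos += size
    if n_contam:
        donor_acc = _pick_donor(host_tax, refs.taxonomy, config.contamination_rank, rng)
        donor_tax = refs.taxonomy[donor_acc]
        donor_arr = _mutate(
            _NT_CODE_ARR(refs.sequences[donor_acc]), config.query_mutation, rng
        )
        pos = 0
        for size in _contig_sizes(contam_nt, n_contam):
            pieces.append((donor_arr[pos : pos + size], True))
            pos += size

    order = rng.permutation(len(pieces))
    contigs: list[ContigSeq] = []
    contaminant_ids: set[str] = set()
    for i, j in enumerate(order):
        arr, is_contam = pieces[j]
        cid = f"ctg{i:03d}"
        contigs.append(ContigSeq(cid, _decode(arr)))
        if is_contam:
            contaminant_ids.add(cid)
    truth = SyntheticTruth(
        host_taxon=host_tax,
        donor_taxon=donor_tax,
        contaminant_contigs=frozenset(contaminant_ids),
        true_css_rank=config.contamination_rank,
    )
    return ChimericGenome(accession, host_accession, contigs, truth)


_ENC = np.full(256, 0, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


def _NT_CODE_ARR(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _perturb_lineage(
    true_tax: TaxonomyString,
    taxonomy: Mapping[str, TaxonomyString],
    rng: np.random.Generator,
    species_list: Sequence[tuple[str, TaxonomyString]],
) -> TaxonomyString:
    """Swap the lineage to a uniformly chosen sibling at a uniformly chosen
    rank (retrying other ranks if a rank has no sibling)."""
    tried = [RANK_CODES[i] for i in rng.permutation(len(RANK_CODES))]
    for code in tried:
        shallower = [c for c in RANK_CODES if RANK_INDEX[c] < RANK_INDEX[code]]
        sibs = [
            tax
            for _, tax in species_list
            if tax.named_at(code) != true_tax.named_at(code)
            and all(tax.named_at(c) == true_tax.named_at(c) for c in shallower)
        ]
        if sibs:
            return sibs[int(rng.integers(len(sibs)))]
    return true_tax


def emulate_gene_assignments(
    genome: ChimericGenome,
    taxonomy: Mapping[str, TaxonomyString],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[GeneAssignment], GenomeSummary]:
    """Noisy per-gene closest-hit assignments plus a genome summary.

    Genes are placed every 1000/genes_per_kb nt; each gene reports its
    contig's true lineage, replaced by a sibling-swap with probability
    ``assignment_error``.  The summary's CSS rank comes from the
    clade-separation proxy; every ``marker_every``-th gene is flagged as a
    marker.
    """
    step = max(1, int(round(1000.0 / config.genes_per_kb)))
    species_list = sorted(taxonomy.items())
    assignments: list[GeneAssignment] = []
    counter = 0
    for contig in genome.contigs:
        true_tax = (
            genome.truth.donor_taxon
            if contig.contig_id in genome.truth.contaminant_contigs
            else genome.truth.host_taxon
        )
        n_genes = contig.length // step
        for j in range(n_genes):
            tax = true_tax
            if config.assignment_error > 0 and rng.random() < config.assignment_error:
                tax = _perturb_lineage(true_tax, taxonomy, rng, species_list)
            assignments.append(
                GeneAssignment(
                    gene_id=f"{contig.contig_id}_g{j:03d}",
                    contig_id=contig.contig_id,
                    gene_index=j,
                    hit_taxonomy=tax,
                    is_marker=(counter % config.marker_every == 0),
                )
            )
            counter += 1
    if not assignments:
        raise ValueError("genome produced no genes; increase genes_per_kb")
    _, css_rank = clade_separation_proxy(assignments)
    summary = GenomeSummary(
        accession=genome.accession,
        css_rank=css_rank,
        is_failed=bool(genome.truth.contaminant_contigs),
        genome_type="MAG",
    )
    return assignments, summary


def simulate_genome(
    config: SimConfig,
    refs: ReferenceSet | None = None,
    replicate: int = 0,
    host_accession: str | None = None,
) -> tuple[ChimericGenome, list[GeneAssignment], GenomeSummary]:
    """One chimeric genome with assignments, reproducible for a fixed
    (config.seed, replicate) pair."""
    if refs is None:
        refs = build_reference_set(config)
    rng = np.random.default_rng([config.seed, 202, replicate])
    genome = make_chimera(
        refs, config, rng, host_accession=host_accession,
        accession=f"SYN{replicate:04d}",
    )
    assignments, summary = emulate_gene_assignments(genome, refs.taxonomy, config, rng)
    return genome, assignments, summary


def write_simulation(
    outdir: str | Path,
    config: SimConfig,
    n_genomes: int = 1,
) -> None:
    """Write a reference DB plus ``n_genomes`` chimeras in the io dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    refs = build_reference_set(config)
    repdir = outdir / "representatives"
    repdir.mkdir(exist_ok=True)
    for acc, seq in refs.sequences.items():
        write_fasta(repdir / f"{acc}.fasta", [ContigSeq(acc, seq)])
    write_rep_metadata(outdir / "rep_metadata.tsv", refs.taxonomy)
    all_assignments: dict[str, list[GeneAssignment]] = {}
    summaries: list[GenomeSummary] = []
    truths = []
    for rep in range(n_genomes):
        genome, assignments, summary = simulate_genome(config, refs, replicate=rep)
        write_fasta(outdir / f"{genome.accession}.fasta", genome.contigs)
        all_assignments[genome.accession] = assignments
        summaries.append(summary)
        truths.append(
            {
                "accession": genome.accession,
                "host_accession": genome.host_accession,
                "host_taxon": genome.truth.host_taxon.format(),
                "donor_taxon": genome.truth.donor_taxon.format()
                if genome.truth.donor_taxon
                else "",
                "contaminant_contigs": ",".join(
                    sorted(genome.truth.contaminant_contigs)
                ),
                "true_css_rank": genome.truth.true_css_rank,
            }
        )
    write_gene_assignments(outdir / "gene_assignments.tsv", all_assignments)
    write_genome_summaries(outdir / "genome_summaries.tsv", summaries)
    with open(outdir / "truth.tsv", "w") as fh:
        cols = [
            "accession",
            "host_accession",
            "host_taxon",
            "donor_taxon",
            "contaminant_contigs",
            "true_css_rank",
        ]
        fh.write("\t".join(cols) + "\n")
        for row in truths:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
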