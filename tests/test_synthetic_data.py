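import numpy as np
from scipy import stats

from cleanhalf.ani_classify import SpeciesCriteria, classify_genome
from cleanhalf.contig_scoring import rank_contigs
from cleanhalf.io_formats import ContigSeq
from cleanhalf.report_cli import build_sketches
from cleanhalf.synthetic_data import (
    ChimericGenome,
    SimConfig,
    SyntheticTruth,
    build_reference_set,
    emulate_gene_assignments,
    generate_reference_db,
    generate_taxonomy,
    make_chimera,
    simulate_genome,
    write_simulation,
)


def _identity(a: str, b: str) -> float:
    # exhaustive position-wise identity oracle (no-indel sequence model)
    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    return float(np.mean(arr_a == arr_b))


class TestGenerateTaxonomy:
    def test_fanout_product(self):
        cfg = SimConfig(taxa_per_rank=(2, 2, 2, 2, 2, 2))
        assert len(generate_taxonomy(cfg)) == 64

    def test_single_species(self):
        cfg = SimConfig(taxa_per_rank=(1, 1, 1, 1, 1, 1))
        taxa = generate_taxonomy(cfg)
        assert len(taxa) == 1
        (t,) = taxa.values()
        assert len(t) == 7

    def test_deterministic(self):
        cfg = SimConfig(seed=3)
        assert generate_taxonomy(cfg) == generate_taxonomy(cfg)

    def test_names_unique_per_rank(self):
        cfg = SimConfig(taxa_per_rank=(2, 2, 1, 2, 1, 2))
        taxa = generate_taxonomy(cfg)
        for code, expect in zip("pcofgs", (2, 4, 4, 8, 8, 16)):
            names = {t.named_at(code) for t in taxa.values()}
            assert len(names) == expect


class TestGenerateReferenceDb:
    CFG = SimConfig(seed=5, taxa_per_rank=(2, 1, 1, 2, 2, 2), genome_len=5000)

    def test_self_identity(self):
        refs = build_reference_set(self.CFG)
        acc = next(iter(refs.sequences))
        assert _identity(refs.sequences[acc], refs.sequences[acc]) == 1.0

    def test_reproducible(self):
        taxa = generate_taxonomy(self.CFG)
        assert generate_reference_db(taxa, self.CFG) == generate_reference_db(
            taxa, self.CFG
        )

    def test_divergence_monotone_with_rank_distance(self):
        refs = build_reference_set(self.CFG)
        pairs = {"g": [], "f": []}
        accs = sorted(refs.taxonomy)
        for i, a in enumerate(accs):
            for b in accs[i + 1 :]:
                ta, tb = refs.taxonomy[a], refs.taxonomy[b]
                if ta.named_at("g") == tb.named_at("g"):
                    pairs["g"].append((a, b))  # same genus, different species
                elif (
                    ta.named_at("o") == tb.named_at("o")
                    and ta.named_at("f") != tb.named_at("f")
                ):
                    pairs["f"].append((a, b))  # same order, different family
        mean_same_genus = np.mean(
            [_identity(refs.sequences[a], refs.sequences[b]) for a, b in pairs["g"]]
        )
        mean_cross_family = np.mean(
            [_identity(refs.sequences[a], refs.sequences[b]) for a, b in pairs["f"]]
        )
        assert mean_same_genus > mean_cross_family


class TestMakeChimera:
    def test_zero_contamination_empty_truth(self):
        cfg = SimConfig(seed=2, contamination_fraction=0.0, genome_len=10_000,
                        taxa_per_rank=(2, 1, 1, 1, 2, 2))
        refs = build_reference_set(cfg)
        genome = make_chimera(refs, cfg, np.random.default_rng(0))
        assert genome.truth.contaminant_contigs == frozenset()
        assert genome.truth.donor_taxon is None

    def test_inter_phylum_donor_differs_at_phylum(self):
        cfg = SimConfig(seed=2, contamination_rank="p", genome_len=10_000,
                        taxa_per_rank=(2, 1, 1, 1, 2, 2), assignment_error=0.0)
        refs = build_reference_set(cfg)
        genome, assignments, _ = simulate_genome(cfg, refs, replicate=0)
        host_p = genome.truth.host_taxon.named_at("p")
        donor_p = genome.truth.donor_taxon.named_at("p")
        assert donor_p != host_p
        for g in assignments:
            expected = donor_p if g.contig_id in genome.truth.contaminant_contigs else host_p
            assert g.hit_taxonomy.named_at("p") == expected

    def test_realized_fraction_within_one_contig(self):
        cfg = SimConfig(seed=4, contamination_fraction=0.3, genome_len=30_000,
                        n_contigs=10, contamination_rank="g",
                        taxa_per_rank=(2, 1, 1, 1, 2, 2))
        refs = build_reference_set(cfg)
        genome = make_chimera(refs, cfg, np.random.default_rng(1))
        total = sum(c.length for c in genome.contigs)
        contam = sum(
            c.length for c in genome.contigs
            if c.contig_id in genome.truth.contaminant_contigs
        )
        mean_contig = total / cfg.n_contigs
        assert abs(contam - 0.3 * total) <= mean_contig
        assert total == cfg.genome_len

    def test_reproducible(self):
        cfg = SimConfig(seed=6, genome_len=10_000, contamination_rank="g",
                        taxa_per_rank=(2, 1, 1, 1, 2, 2))
        refs = build_reference_set(cfg)
        g1 = make_chimera(refs, cfg, np.random.default_rng(9))
        g2 = make_chimera(refs, cfg, np.random.default_rng(9))
        assert g1.contigs == g2.contigs
        assert g1.truth == g2.truth


class TestEmulateAssignments:
    def _manual_genome(self, cfg, refs, n=1, contig_len=100_000):
        taxa = sorted(refs.taxonomy.items())
        host = taxa[0][1]
        donor = None
        truth = SyntheticTruth(host, donor, frozenset(), cfg.contamination_rank)
        contigs = [ContigSeq(f"c{i}", "A" * contig_len) for i in range(n)]
        return ChimericGenome("M", taxa[0][0], contigs, truth)

    def test_zero_error_all_true(self):
        cfg = SimConfig(seed=7, assignment_error=0.0, genes_per_kb=10.0,
                        taxa_per_rank=(2, 1, 1, 1, 2, 2), genome_len=5000)
        refs = build_reference_set(cfg)
        genome = self._manual_genome(cfg, refs, contig_len=10_000)
        assignments, _ = emulate_gene_assignments(
            genome, refs.taxonomy, cfg, np.random.default_rng(0)
        )
        assert all(g.hit_taxonomy == genome.truth.host_taxon for g in assignments)

    def test_full_error_all_perturbed(self):
        cfg = SimConfig(seed=7, assignment_error=1.0, genes_per_kb=10.0,
                        taxa_per_rank=(2, 1, 1, 1, 2, 2), genome_len=5000)
        refs = build_reference_set(cfg)
        genome = self._manual_genome(cfg, refs, contig_len=10_000)
        assignments, _ = emulate_gene_assignments(
            genome, refs.taxonomy, cfg, np.random.default_rng(0)
        )
        assert all(g.hit_taxonomy != genome.truth.host_taxon for g in assignments)

    def test_error_rate_within_binomial_ci(self):
        rate = 0.1
        cfg = SimConfig(seed=8, assignment_error=rate, genes_per_kb=100.0,
                        taxa_per_rank=(2, 1, 1, 1, 2, 2), genome_len=5000)
        refs = build_reference_set(cfg)
        genome = self._manual_genome(cfg, refs, contig_len=100_000)
        assignments, _ = emulate_gene_assignments(
            genome, refs.taxonomy, cfg, np.random.default_rng(1)
        )
        n = len(assignments)
        assert n == 10_000
        observed = sum(g.hit_taxonomy != genome.truth.host_taxon for g in assignments)
        lo, hi = stats.binom.interval(0.99, n, rate)
        assert lo <= observed <= hi

    def test_marker_flag_spacing(self):
        cfg = SimConfig(seed=9, genes_per_kb=10.0, marker_every=10,
                        taxa_per_rank=(2, 1, 1, 1, 2, 2), genome_len=5000)
        refs = build_reference_set(cfg)
        genome = self._manual_genome(cfg, refs, contig_len=10_000)
        assignments, _ = emulate_gene_assignments(
            genome, refs.taxonomy, cfg, np.random.default_rng(2)
        )
        n_markers = sum(g.is_marker for g in assignments)
        assert n_markers == len(assignments) // 10

    def test_css_rank_from_proxy(self):
        cfg = SimConfig(seed=10, contamination_rank="p", assignment_error=0.0,
                        genome_len=10_000, taxa_per_rank=(2, 1, 1, 1, 2, 2))
        refs = build_reference_set(cfg)
        _, _, summary = simulate_genome(cfg, refs, replicate=0)
        assert summary.css_rank == "p"
        assert summary.is_failed


class TestGrossContaminationPath:
    def test_contaminant_half_classifies_to_donor(self, rng):
        # inter-phylum chimeras: the contaminant half's best reference carries
        # the donor lineage, so clean vs contaminant taxonomy strings differ
        # at the injected rank
        # near-50 % contamination: the contaminant half is almost pure donor
        # (host remnant < one fragment), the regime the gross screen targets
        cfg = SimConfig(seed=11, contamination_rank="p", contamination_fraction=0.48,
                        genome_len=30_000, n_contigs=25, genes_per_kb=5.0,
                        taxa_per_rank=(2, 1, 2, 2, 2, 2), assignment_error=0.05)
        refs = build_reference_set(cfg)
        sketches = build_sketches(refs)
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            genome, assignments, summary = simulate_genome(cfg, refs, replicate=rep)
            scores = rank_contigs(genome.contigs, assignments, summary.css_rank)
            order = {s.contig_id: i for i, s in enumerate(scores)}
            ordered = sorted(genome.contigs, key=lambda c: order[c.contig_id])
            from cleanhalf.genome_halving import split_by_nucleotides

            halving = split_by_nucleotides(ordered)
            contam_pieces = [c.sequence for c in halving.contaminant]
            result = classify_genome(
                query=genome.accession, query_seq=contam_pieces,
                ref_seqs=refs.sequences, ref_sketches=sketches,
                rep_metadata=refs.taxonomy,
                expected_tax=genome.truth.donor_taxon,
                expected_rep=None, criteria=SpeciesCriteria(),
                fragment_len=1000,  # contigs are 1200 nt in this toy
            )
            if result.best_ref is None:
                continue
            best_tax = refs.taxonomy[result.best_ref]
            donor_p = genome.truth.donor_taxon.named_at("p")
            host_p = genome.truth.host_taxon.named_at("p")
            if best_tax.named_at("p") == donor_p != host_p:
                hits += 1
        assert hits >= round(0.95 * n_rep)


class TestWriteSimulation:
    def test_round_trip_files(self, tmp_path):
        from cleanhalf.io_formats import (
            read_fasta,
            read_gene_assignments,
            read_genome_summaries,
            read_rep_metadata,
        )

        cfg = SimConfig(seed=12, genome_len=6000, n_contigs=4, genes_per_kb=2.0,
                        contamination_rank="g", taxa_per_rank=(2, 1, 1, 1, 2, 2))
        write_simulation(tmp_path, cfg, n_genomes=2)
        meta = read_rep_metadata(tmp_path / "rep_metadata.tsv")
        assert len(meta) == 8
        contigs = read_fasta(tmp_path / "SYN0000.fasta")
        assert sum(c.length for c in contigs) == 6000
        assignments = read_gene_assignments(tmp_path / "gene_assignments.tsv")
        assert set(assignments) == {"SYN0000", "SYN0001"}
        summaries = read_genome_summaries(tmp_path / "genome_summaries.tsv")
        assert summaries["SYN0000"].is_failed
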