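import numpy as np
import pytest

from bowstrap.bootstrap import compute_rpkm
from bowstrap.formats import parse_bowtie_output, parse_gene_size_file, write_gene_size_file
from bowstrap.simulate import (
    SimConfig,
    TruthTable,
    align_exact,
    assign_expression,
    simulate_dataset,
    simulate_reads,
    simulate_transcriptome,
    write_bowtie_output,
)

SMALL = dict(n_genes=30, length_range=(300, 600), n_reads=2000, seed=7)


class TestTranscriptome:
    def test_deterministic_under_seed(self):
        cfg = SimConfig(**SMALL, n_families=3)
        a = simulate_transcriptome(cfg)
        b = simulate_transcriptome(cfg)
        assert a.sequences == b.sequences
        assert a.genes == b.genes
        c = simulate_transcriptome(SimConfig(**{**SMALL, "seed": 8}, n_families=3))
        assert c.sequences != a.sequences

    def test_identity_one_gives_exact_duplicates(self):
        cfg = SimConfig(**SMALL, n_families=2, family_size=3, within_family_identity=1.0)
        tx = simulate_transcriptome(cfg)
        assert tx.sequences[0] == tx.sequences[1] == tx.sequences[2]
        assert tx.sequences[3] == tx.sequences[4] == tx.sequences[5]
        assert tx.sequences[0] != tx.sequences[3]

    def test_partial_identity_mutates_at_the_expected_rate(self):
        cfg = SimConfig(
            n_genes=4,
            length_range=(5000, 5000),
            n_families=2,
            family_size=2,
            within_family_identity=0.9,
            seed=1,
        )
        tx = simulate_transcriptome(cfg)
        for a, b in [(0, 1), (2, 3)]:
            diff = sum(x != y for x, y in zip(tx.sequences[a], tx.sequences[b]))
            # binomial(5000, 0.1): 4 sigma around the mean of 500
            assert abs(diff - 500) < 4 * np.sqrt(5000 * 0.1 * 0.9)

    def test_unrelated_genes_share_no_read_length_kmer(self):
        cfg = SimConfig(**SMALL, n_families=0)
        tx = simulate_transcriptome(cfg)
        k = cfg.read_length_bp
        seen: dict[str, int] = {}
        for i, seq in enumerate(tx.sequences):
            for off in range(len(seq) - k + 1):
                kmer = seq[off : off + k]
                assert seen.setdefault(kmer, i) == i
        assert len(tx.genes) == cfg.n_genes

    def test_invalid_configs_are_rejected(self):
        with pytest.raises(ValueError, match="read_length"):
            SimConfig(length_range=(40, 100))
        with pytest.raises(ValueError, match="n_genes"):
            SimConfig(n_genes=10, n_families=10, family_size=2)
        with pytest.raises(ValueError, match="identity"):
            SimConfig(within_family_identity=0.0)


class TestExpressionTruth:
    def test_expressed_count_is_rounded_fraction(self):
        cfg = SimConfig(**SMALL, frac_expressed=0.5)
        tx = simulate_transcriptome(cfg)
        truth = assign_expression(tx.genes, cfg)
        assert int(truth.expressed.sum()) == 15
        assert np.all(truth.expression_weight[~truth.expressed] == 0)
        assert np.all(truth.expression_weight[truth.expressed] > 0)

    def test_full_expression_has_no_zero_weights(self):
        cfg = SimConfig(**SMALL, frac_expressed=1.0)
        tx = simulate_transcriptome(cfg)
        truth = assign_expression(tx.genes, cfg)
        assert np.all(truth.expression_weight > 0)


class TestReadSimulation:
    def test_read_count_and_origin_conservation(self):
        cfg = SimConfig(**SMALL)
        data = simulate_dataset(cfg)
        assert len(data.reads) == cfg.n_reads
        assert data.truth.origin_read_count.sum() == cfg.n_reads

    def test_single_expressed_gene_takes_all_reads(self):
        cfg = SimConfig(
            n_genes=2,
            length_range=(500, 500),
            n_families=0,
            frac_expressed=0.5,
            n_reads=1000,
            seed=3,
        )
        tx = simulate_transcriptome(cfg)
        truth = assign_expression(tx.genes, cfg)
        reads, truth = simulate_reads(tx, truth, cfg)
        (g,) = np.nonzero(truth.expressed)[0]
        assert truth.origin_read_count[g] == 1000
        assert truth.true_rpkm[g] == pytest.approx(compute_rpkm(1000, 500, 1000))
        assert all(r.name.split("|")[1] == truth.genes[g] for r in reads)

    def test_origin_counts_follow_weights(self):
        """Two equal-length genes at weights 2:1 split reads binomially 2:1."""
        cfg = SimConfig(
            n_genes=2, length_range=(800, 800), n_families=0, n_reads=9000, seed=5
        )
        tx = simulate_transcriptome(cfg)
        truth = TruthTable(genes=tx.genes.names, expression_weight=np.array([2.0, 1.0]))
        _, updated = simulate_reads(tx, truth, cfg)
        p = 2.0 / 3.0
        expected = 9000 * p
        sd = np.sqrt(9000 * p * (1 - p))
        assert abs(updated.origin_read_count[0] - expected) < 4 * sd
        assert updated.true_rpkm[0] == pytest.approx(2 * updated.true_rpkm[1])

    def test_reads_are_exact_substrings(self):
        cfg = SimConfig(**SMALL)
        data = simulate_dataset(cfg)
        by_name = dict(zip(data.transcriptome.genes.names, data.transcriptome.sequences))
        for read in data.reads[:50]:
            _, gene, off = read.name.split("|")
            assert by_name[gene][int(off) : int(off) + cfg.read_length_bp] == read.sequence

    def test_all_zero_weights_is_an_error(self):
        cfg = SimConfig(**SMALL)
        tx = simulate_transcriptome(cfg)
        truth = TruthTable(genes=tx.genes.names, expression_weight=np.zeros(cfg.n_genes))
        with pytest.raises(ValueError, match="zero"):
            simulate_reads(tx, truth, cfg)


class TestExactAligner:
    def test_matches_naive_quadratic_scan(self):
        cfg = SimConfig(
            n_genes=20,
            length_range=(300, 500),
            n_families=4,
            family_size=2,
            within_family_identity=0.95,
            n_reads=300,
            seed=13,
        )
        data = simulate_dataset(cfg)
        tx = data.transcriptome
        for ra in data.aligned:
            seq = next(r.sequence for r in data.reads if r.name == ra.read_id)
            naive = set()
            for gene, gseq in zip(tx.genes.names, tx.sequences):
                start = gseq.find(seq)
                while start != -1:
                    naive.add((gene, start))
                    start = gseq.find(seq, start + 1)
            assert {(l.gene, l.offset) for l in ra.locations} == naive

    def test_duplicate_pair_read_aligns_twice(self):
        cfg = SimConfig(
            n_genes=2,
            length_range=(400, 400),
            n_families=1,
            family_size=2,
            within_family_identity=1.0,
            frac_expressed=0.5,
            n_reads=200,
            seed=2,
        )
        data = simulate_dataset(cfg)
        assert all(len(ra.locations) == 2 for ra in data.aligned)

    def test_every_read_hits_its_origin(self):
        data = simulate_dataset(SimConfig(**SMALL, n_families=3))
        for ra in data.aligned:
            _, gene, off = ra.read_id.split("|")
            assert (gene, int(off)) in {(l.gene, l.offset) for l in ra.locations}


class TestBowtieRoundTrip:
    def test_written_alignments_parse_back_identically(self, tmp_path):
        cfg = SimConfig(**SMALL, n_families=3, within_family_identity=1.0)
        data = simulate_dataset(cfg)
        genes_path = tmp_path / "genes.tsv"
        aln_path = tmp_path / "aln.txt"
        write_gene_size_file(data.transcriptome.genes, genes_path)
        write_bowtie_output(data.reads, data.aligned, aln_path)
        reparsed = parse_bowtie_output(aln_path, parse_gene_size_file(genes_path))
        assert len(reparsed) == len(data.aligned)
        original = {
            ra.read_id: {(l.gene, l.offset) for l in ra.locations}
            for ra in data.aligned
        }
        for ra in reparsed:
            assert {(l.gene, l.offset) for l in ra.locations} == original[ra.read_id]


def test_truth_table_roundtrip(tmp_path):
    data = simulate_dataset(SimConfig(**SMALL))
    path = tmp_path / "truth.tsv"
    data.truth.to_tsv(path)
    back = TruthTable.from_tsv(path)
    assert back.genes == data.truth.genes
    assert back.expression_weight == pytest.approx(
        data.truth.expression_weight, rel=1e-5
    )
    assert np.array_equal(back.origin_read_count, data.truth.origin_read_count)
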