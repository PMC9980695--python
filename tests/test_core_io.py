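"""Data model and format round-trips.

All intervals are 0-based half-open; readers and writers must be mutually
inverse on valid files, and parse errors must name the offending line.
"""
import numpy as np
import pytest

from epiconcord.core import BinnedTrack, Gene, Genome, GenomicInterval
from epiconcord import io


class TestModel:
    def test_tss_follows_strand(self):
        plus = Gene("a", "chr1", "+", 100, 500)
        minus = Gene("b", "chr1", "-", 100, 500)
        assert plus.tss == 100
        assert minus.tss == 499

    @pytest.mark.parametrize("start,end", [(-1, 5), (5, 5), (9, 3)])
    def test_invalid_interval_rejected(self, start, end):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", start, end)

    def test_genome_validation(self):
        with pytest.raises(ValueError):
            Genome(("chr1", "chr1"), (100, 100))
        with pytest.raises(ValueError):
            Genome(("chr1",), (0,))

    def test_track_must_tile_genome(self, genome):
        counts = {"chr1": np.zeros(10), "chr2": np.zeros(genome.n_bins("chr2", 50))}
        with pytest.raises(ValueError):
            BinnedTrack.from_counts(genome, 50, counts)


class TestGeneAnnotation:
    def test_bed_strand_conventions(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chr1\t100\t500\tgeneA\t0\t+\nchr1\t100\t500\tgeneB\t0\t-\n")
        genes = io.read_gene_annotation(p)
        by_id = {g.gene_id: g for g in genes}
        assert by_id["geneA"].tss == 100
        assert by_id["geneA"].body.start == 100 and by_id["geneA"].body.end == 500
        assert by_id["geneB"].tss == 499

    def test_gtf_coordinates_converted(self, tmp_path):
        p = tmp_path / "genes.gtf"
        p.write_text(
            'chr1\tsrc\tgene\t101\t500\t.\t+\t.\tgene_id "gA"; gene_biotype "protein_coding";\n'
            'chr1\tsrc\tgene\t601\t900\t.\t-\t.\tgene_id "gB"; gene_biotype "lncRNA";\n'
        )
        genes = io.read_gene_annotation(p)
        assert genes[0].start == 100 and genes[0].end == 500
        assert genes[0].biotype == "coding"
        assert genes[1].biotype == "lncRNA"
        assert genes[1].tss == 899

    def test_roundtrip_identity_many_genes(self, tmp_path, rng, genome):
        genes = []
        for i in range(1000):
            chrom = genome.names[int(rng.integers(2))]
            start = int(rng.integers(0, genome.length_of(chrom) - 25_000))
            end = start + int(rng.integers(1_000, 20_000))
            strand = "+" if rng.random() < 0.5 else "-"
            bt = "lncRNA" if rng.random() < 0.2 else "coding"
            genes.append(Gene(f"g{i:04d}", chrom, strand, start, end, bt))
        p = tmp_path / "g.bed"
        io.write_gene_annotation(genes, p)
        back = io.read_gene_annotation(p)
        assert len(back) == 1000
        assert back == sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))
        io.write_gene_annotation(back, tmp_path / "g2.bed")
        assert (tmp_path / "g2.bed").read_text() == p.read_text()

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t500\tgA\t0\t+\nchr1\tnotanumber\t900\tgB\t0\t-\n")
        with pytest.raises(io.ParseError, match="line 2"):
            io.read_gene_annotation(p)

    def test_duplicate_gene_id_keeps_first_with_warning(self, tmp_path):
        p = tmp_path / "dup.bed"
        p.write_text("chr1\t100\t500\tgA\t0\t+\nchr1\t700\t900\tgA\t0\t+\n")
        with pytest.warns(UserWarning, match="gA"):
            genes = io.read_gene_annotation(p)
        assert len(genes) == 1
        assert genes[0].start == 100


class TestRegionsBed:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert io.read_regions_bed(p) == []

    def test_single_region_field_mapping(self, tmp_path):
        p = tmp_path / "one.bed"
        p.write_text("chr1\t1000\t1400\tr1\t2.5\t.\tgain\t0.001\n")
        (r,) = io.read_regions_bed(p)
        assert (r.chrom, r.start, r.end) == ("chr1", 1000, 1400)
        assert r.fold == 2.5 and r.direction == "gain" and r.p_value == 0.001

    def test_roundtrip_500_random_regions(self, tmp_path, rng, genome,
                                          random_region_factory):
        regions = random_region_factory(rng, genome, 500)
        p = tmp_path / "r.bed"
        io.write_regions_bed(regions, p)
        assert io.read_regions_bed(p) == regions

    def test_inverted_interval_rejected_with_index(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t200\tr0\t2\t.\tgain\t0.01\n"
                     "chr1\t500\t400\tr1\t2\t.\tloss\t0.01\n")
        with pytest.raises(io.ParseError, match="record 1"):
            io.read_regions_bed(p)


class TestCoverage:
    def test_uniform_value_over_chromosome(self, tmp_path):
        g = Genome(("chr1",), (10_000,))
        p = tmp_path / "cov.bedgraph"
        p.write_text("chr1\t0\t10000\t1\n")
        track = io.read_coverage(p, g, 50)
        assert len(track.counts["chr1"]) == 200
        assert (track.counts["chr1"] == 1).all()
        assert track.library_size == 200

    def test_gaps_read_as_zero(self, tmp_path):
        g = Genome(("chr1",), (300,))
        p = tmp_path / "cov.bedgraph"
        p.write_text("chr1\t0\t50\t3\nchr1\t200\t250\t5\n")
        track = io.read_coverage(p, g, 50)
        assert track.counts["chr1"].tolist() == [3, 0, 0, 0, 5, 0]

    def test_rebin_25bp_to_50bp_matches_direct_summation(self, tmp_path, rng):
        g = Genome(("chr1",), (5_000,))
        vals = rng.integers(0, 20, size=200)  # 25-bp native bins
        lines = [f"chr1\t{i * 25}\t{(i + 1) * 25}\t{v}\n"
                 for i, v in enumerate(vals) if v]
        p = tmp_path / "cov.bedgraph"
        p.write_text("".join(lines))
        track = io.read_coverage(p, g, 50)
        expected = vals.reshape(100, 2).sum(axis=1)  # direct summation oracle
        assert track.counts["chr1"].tolist() == expected.tolist()

    def test_overlap_and_negative_rejected(self, tmp_path):
        g = Genome(("chr1",), (1_000,))
        p = tmp_path / "o.bedgraph"
        p.write_text("chr1\t0\t100\t1\nchr1\t50\t150\t1\n")
        with pytest.raises(io.ParseError, match="overlap"):
            io.read_coverage(p, g, 50)
        p.write_text("chr1\t0\t50\t-3\n")
        with pytest.raises(io.ParseError, match="negative"):
            io.read_coverage(p, g, 50)

    def test_roundtrip(self, tmp_path, rng):
        g = Genome(("chr1", "chr2"), (10_000, 7_500))
        counts = {c: rng.poisson(1.5, g.n_bins(c, 50)).astype(np.int64)
                  for c in g.names}
        track = BinnedTrack.from_counts(g, 50, counts)
        p = tmp_path / "t.bedgraph"
        io.write_coverage(track, p)
        back = io.read_coverage(p, g, 50)
        assert back.equals(track)
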