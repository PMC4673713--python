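"""Genome/annotation loading and 3'UTR locus resolution."""

import gzip

import pytest

from utrome import genome_model as gm
from utrome import synthetic_fixtures as fx
from utrome._seq import revcomp

TOY_CONTIG = "chrT"


def _toy_genome(length=3000, stop_at=1000, stop="TAA", strand="+"):
    """Contig of 'A C G T' repeats with a STOP codon planted at stop_at (+ sense)."""
    seq = ("ACGT" * (length // 4 + 1))[:length]
    codon = stop if strand == "+" else revcomp(stop)
    seq = seq[:stop_at] + codon + seq[stop_at + 3 :]
    return {TOY_CONTIG: gm.GenomeSequence(TOY_CONTIG, seq)}


class TestReadGenome:
    def test_loads_record_with_length_and_uppercase(self, tmp_path):
        path = tmp_path / "g.fa"
        path.write_text(">chr_t1\n" + "acgt" * 2500 + "\n")
        genome = gm.read_genome(path)
        assert set(genome) == {"chr_t1"}
        assert genome["chr_t1"].length == 10_000
        assert genome["chr_t1"].sequence.startswith("ACGT")

    def test_duplicate_contig_id_is_an_error(self, tmp_path):
        path = tmp_path / "dup.fa"
        path.write_text(">c1\nACGT\n>c1\nACGT\n")
        with pytest.raises(ValueError, match="duplicate contig"):
            gm.read_genome(path)

    def test_gzip_transparent(self, tmp_path):
        text = ">c1\nACGTACGTNN\n"
        plain = tmp_path / "g.fa"
        plain.write_text(text)
        zipped = tmp_path / "g.fa.gz"
        with gzip.open(zipped, "wt") as fh:
            fh.write(text)
        assert gm.read_genome(plain) == gm.read_genome(zipped)

    def test_non_dna_characters_name_the_record(self, tmp_path):
        path = tmp_path / "bad.fa"
        path.write_text(">ok\nACGT\n>oops\nACXT\n")
        with pytest.raises(ValueError, match="oops"):
            gm.read_genome(path)


GTF_TOY = "\n".join(
    [
        f'{TOY_CONTIG}\ttoy\ttranscript\t901\t1800\t.\t+\t.\tgene_id "gA"; transcript_id "tA";',
        f'{TOY_CONTIG}\ttoy\texon\t901\t1800\t.\t+\t.\tgene_id "gA"; transcript_id "tA";',
        f'{TOY_CONTIG}\ttoy\tCDS\t901\t1000\t.\t+\t.\tgene_id "gA"; transcript_id "tA";',
        f'{TOY_CONTIG}\ttoy\tstop_codon\t1001\t1003\t.\t+\t.\tgene_id "gA"; transcript_id "tA";',
    ]
)

GFF3_TOY = "\n".join(
    [
        "##gff-version 3",
        f"{TOY_CONTIG}\ttoy\tgene\t901\t1800\t.\t+\t.\tID=gA",
        f"{TOY_CONTIG}\ttoy\tmRNA\t901\t1800\t.\t+\t.\tID=tA;Parent=gA",
        f"{TOY_CONTIG}\ttoy\texon\t901\t1800\t.\t+\t.\tParent=tA",
        f"{TOY_CONTIG}\ttoy\tCDS\t901\t1000\t.\t+\t.\tParent=tA",
        f"{TOY_CONTIG}\ttoy\tstop_codon\t1001\t1003\t.\t+\t.\tParent=tA",
    ]
)

# Same locus, STOP folded into the CDS and no stop_codon feature.
GTF_TOY_DERIVED = GTF_TOY.replace("\t901\t1000\t", "\t901\t1003\t").replace(
    f'{TOY_CONTIG}\ttoy\tstop_codon\t1001\t1003\t.\t+\t.\tgene_id "gA"; transcript_id "tA";',
    "",
)


class TestReadAnnotation:
    def test_gtf_coordinates_convert_to_half_open(self):
        genome = _toy_genome()
        models, failures = gm.read_annotation(GTF_TOY, genome, from_string=True)
        assert not failures
        (model,) = models
        assert model.exons == [(900, 1800)]
        assert model.cds_end_genomic == 1003
        assert model.three_prime_end_genomic == 1800
        assert model.stop_codon_interval == (1000, 1003)

    @pytest.mark.parametrize("text", [GFF3_TOY, GTF_TOY_DERIVED],
                             ids=["gff3", "derived-stop"])
    def test_dialects_and_derived_stop_agree_with_explicit_gtf(self, text):
        genome = _toy_genome()
        (reference,), _ = gm.read_annotation(GTF_TOY, genome, from_string=True)
        (model,), failures = gm.read_annotation(text, genome, from_string=True)
        assert not failures
        assert model.cds_end_genomic == reference.cds_end_genomic
        assert model.exons == reference.exons

    def test_unresolvable_stop_is_recorded_not_raised(self):
        genome = _toy_genome()
        text = GTF_TOY_DERIVED.replace("\t901\t1003\t", "\t901\t999\t")
        models, failures = gm.read_annotation(text, genome, from_string=True)
        assert models == []
        assert [f.reason for f in failures] == ["unresolvable stop codon"]

    def test_out_of_bounds_feature_is_hard_error(self):
        genome = _toy_genome(length=1500)
        with pytest.raises(ValueError, match="out of bounds"):
            gm.read_annotation(GTF_TOY, genome, from_string=True)


def _mk_transcript(tid, strand, three_prime, cds_end=1003):
    return gm.TranscriptModel(
        transcript_id=tid, gene_id="g", contig_id=TOY_CONTIG, strand=strand,
        exons=[(900, max(three_prime, 2000)) if strand == "+" else (min(three_prime, 3000), 5000)],
        cds_end_genomic=cds_end, three_prime_end_genomic=three_prime,
    )


class TestSelectLongestTranscript:
    def test_plus_strand_takes_most_distal_end(self):
        t = gm.select_longest_transcript(
            [_mk_transcript("t1", "+", 1800), _mk_transcript("t2", "+", 2200)]
        )
        assert t.transcript_id == "t2"

    def test_minus_strand_distal_is_smaller_coordinate(self):
        t = gm.select_longest_transcript(
            [_mk_transcript("t1", "-", 4000, 4997), _mk_transcript("t2", "-", 3800, 4997)]
        )
        assert t.transcript_id == "t2"

    def test_tie_breaks_on_transcript_id(self):
        t = gm.select_longest_transcript(
            [_mk_transcript("tB", "+", 1800), _mk_transcript("tA", "+", 1800)]
        )
        assert t.transcript_id == "tA"

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            gm.select_longest_transcript([])


class TestResolveUtrLocus:
    def test_plus_strand_arithmetic(self):
        genome = _toy_genome()
        model = gm.TranscriptModel(
            "tA", "gA", TOY_CONTIG, "+", [(900, 1800)], 1003, 1800
        )
        locus = gm.resolve_utr_locus([model], genome)
        assert isinstance(locus, gm.UtrLocus)
        assert locus.insert_interval == (1000, 1950)
        assert locus.insert_length == 950
        assert locus.insert_sequence.startswith("TAA")

    def test_minus_strand_mirror_arithmetic(self):
        genome = _toy_genome(length=6000, stop_at=4997, strand="-")
        model = gm.TranscriptModel(
            "tB", "gB", TOY_CONTIG, "-", [(4000, 5500)], 4997, 4000
        )
        locus = gm.resolve_utr_locus([model], genome)
        assert locus.insert_interval == (3850, 5000)
        assert locus.insert_length == 1150
        expected = revcomp(genome[TOY_CONTIG].sequence[3850:5000])
        assert locus.insert_sequence == expected

    def test_downstream_overflow_is_design_failure(self):
        genome = _toy_genome(length=1840)
        model = gm.TranscriptModel(
            "tA", "gA", TOY_CONTIG, "+", [(900, 1800)], 1003, 1800
        )
        result = gm.resolve_utr_locus([model], genome)
        assert isinstance(result, gm.DesignFailure)
        assert result.reason == "downstream overflow"

    def test_stop_outside_last_exon_is_design_failure(self):
        genome = _toy_genome()
        model = gm.TranscriptModel(
            "tA", "gA", TOY_CONTIG, "+", [(900, 1001), (1100, 1800)], 1003, 1800
        )
        result = gm.resolve_utr_locus([model], genome)
        assert isinstance(result, gm.DesignFailure)
        assert result.reason == "stop not in last exon"


class TestExtractInterval:
    @pytest.mark.parametrize(
        "interval,strand,expected",
        [((2, 5), "+", "GTA"), ((2, 5), "-", "TAC"), ((0, 0), "+", "")],
    )
    def test_slice_and_revcomp(self, interval, strand, expected):
        genome = {"c": gm.GenomeSequence("c", "ACGTACGT")}
        assert gm.extract_interval_sequence(genome, "c", interval, strand) == expected

    def test_out_of_bounds_is_error(self):
        genome = {"c": gm.GenomeSequence("c", "ACGTACGT")}
        with pytest.raises(ValueError):
            gm.extract_interval_sequence(genome, "c", (5, 9), "+")


class TestFixtureContracts:
    def test_roundtrip_matches_generator_truth(self, fixture_loci, fixture_truth):
        """Locus resolution reproduces the generator truth for every gene."""
        assert len(fixture_loci) == len(fixture_truth)
        for locus in fixture_loci:
            truth = fixture_truth[locus.gene_id]
            assert locus.insert_interval == truth.insert_interval
            assert locus.insert_length == truth.insert_length
            assert locus.insert_sequence == truth.insert_sequence
            assert locus.insert_sequence[:3] in {"TAA", "TAG", "TGA"}

    @pytest.mark.parametrize("seed", [1, 2, 3, 11, 23])
    def test_roundtrip_across_seeds(self, seed):
        fix = fx.simulate_genome(n_genes=12, seed=seed)
        models, afail = gm.read_annotation(fix.gtf_text(), fix.genome, from_string=True)
        loci, lfail = gm.resolve_utr_loci(models, fix.genome)
        assert not afail and not lfail
        truth = {t.gene_id: t for t in fix.truth}
        for locus in loci:
            assert locus.insert_sequence == truth[locus.gene_id].insert_sequence

    def test_strand_mirror_yields_identical_insert_sequences(self, fixture_genome, fixture_loci):
        """Reverse-complementing the contig and flipping annotations leaves
        every mRNA-sense insert bitwise unchanged."""
        mirrored = fx.mirror_fixture(fixture_genome)
        models, _ = gm.read_annotation(
            mirrored.gtf_text(), mirrored.genome, from_string=True
        )
        loci, failures = gm.resolve_utr_loci(models, mirrored.genome)
        assert not failures
        original = {l.gene_id: l.insert_sequence for l in fixture_loci}
        assert {l.gene_id: l.insert_sequence for l in loci} == original

    def test_gtf_and_gff3_encodings_agree(self, fixture_genome, fixture_loci):
        models, _ = gm.read_annotation(
            fixture_genome.gff3_text(), fixture_genome.genome, from_string=True
        )
        loci, failures = gm.resolve_utr_loci(models, fixture_genome.genome)
        assert not failures
        original = {l.gene_id: (l.insert_interval, l.insert_sequence) for l in fixture_loci}
        assert {l.gene_id: (l.insert_interval, l.insert_sequence) for l in loci} == original

    def test_writers_emit_one_row_per_locus(self, fixture_loci, tmp_path):
        bed = tmp_path / "loci.bed"
        gm.write_loci_bed(fixture_loci, bed)
        lines = bed.read_text().strip().split("\n")
        assert len(lines) == len(fixture_loci)
        chrom, start, end, name, score, strand = lines[0].split("\t")
        assert int(end) - int(start) == int(score)
        assert strand in "+-"
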