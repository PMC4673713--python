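"""Primer core design, melting temperatures, and Gateway tails."""

import numpy as np
import pytest

from utrome import genome_model as gm
from utrome import panel_design as pdsg
from utrome._seq import revcomp

from .oracles import nn_tm_oracle


class TestMeltingTemperature:
    def test_wallace_rule_hand_value(self):
        # 2(A+T) + 4(G+C) = 2*4 + 4*4
        assert pdsg.melting_temperature("AATTGGCC", model="wallace") == 24.0

    def test_nearest_neighbor_matches_hand_summed_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            length = int(rng.integers(14, 36))
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
            ours = pdsg.melting_temperature(seq, model="nearest_neighbor")
            assert ours == pytest.approx(nn_tm_oracle(seq), abs=0.1)

    def test_appending_gc_does_not_lower_tm(self):
        seq = "ACGTACGTACGTACGTACGT"
        assert pdsg.melting_temperature(seq) <= pdsg.melting_temperature(seq + "GC")

    @pytest.mark.parametrize("bad", ["", "A", "ACGNT"])
    def test_degenerate_input_is_error(self, bad):
        with pytest.raises(ValueError):
            pdsg.melting_temperature(bad)


class TestGatewayTails:
    def test_tail_sequences_are_prepended_verbatim(self):
        pair = _pair("ATGCGTTAA", "TTGACCATTGACCATTGA")
        tailed = pdsg.attach_gateway_tails(pair)
        assert tailed.forward_tailed == "GGGGACAGCTTTCTTGTACAAAGTGGAG" + "ATGCGTTAA"
        assert tailed.reverse_tailed == "GGGGACAACTTTGTATAATAAAGTTG" + "TTGACCATTGACCATTGA"
        assert tailed.forward.sequence_5to3 == "ATGCGTTAA"  # cores unchanged

    def test_double_tailing_is_error(self):
        pair = pdsg.attach_gateway_tails(_pair("ATGCGTTAA", "TTGACCA"))
        with pytest.raises(ValueError, match="double tailing"):
            pdsg.attach_gateway_tails(pair)

    def test_pre_tailed_core_is_rejected(self):
        pair = _pair(pdsg.ATTB2 + "ATGCGTTAA", "TTGACCA")
        with pytest.raises(ValueError, match="tail"):
            pdsg.attach_gateway_tails(pair)


def _pair(fwd, rev):
    return pdsg.PrimerPair(
        gene_id="g", transcript_id="t", contig_id="c", strand="+",
        forward=pdsg.PrimerCore(fwd, (0, len(fwd)), "+", 60.0),
        reverse=pdsg.PrimerCore(rev, (0, len(rev)), "-", 60.0),
        expected_insert_length=500,
    )


def _locus_from_context(cds_context: str, utr: str, stop: str = "TAA"):
    """Build a '+'-strand locus whose last exon is cds_context+stop+utr."""
    lead = "ACGT" * 50
    tail = "TGCA" * 60  # downstream runway
    seq = lead + cds_context + stop + utr + tail
    contig = gm.GenomeSequence("c", seq)
    exon_start = len(lead)
    stop_start = exon_start + len(cds_context)
    three_end = stop_start + 3 + len(utr)
    return (
        gm.UtrLocus(
            gene_id="g", transcript_id="t", contig_id="c", strand="+",
            stop_codon_interval=(stop_start, stop_start + 3),
            last_exon_interval=(exon_start, three_end),
            insert_interval=(stop_start, three_end + 150),
            insert_sequence=seq[stop_start : three_end + 150],
        ),
        {"c": contig},
    )


class TestDesignPrimerCores:
    def test_gc_rich_context_stops_growing_at_min_len(self):
        """First length whose Tm crosses the 60 degC target wins; a GC-rich
        STOP context crosses immediately at the 18-nt minimum."""
        locus, genome = _locus_from_context("GCGCGCGCGCGCGCGCGCGC", "ATCG" * 100)
        pair = pdsg.design_primer_cores(locus, genome)
        assert pair.forward.length == 18
        assert pair.forward.sequence_5to3.endswith("TAA")
        assert pair.forward.tm_celsius >= 60.0

    def test_growth_stops_at_first_tm_crossing_per_oracle(self, fixture_loci, fixture_genome):
        """Forward core length equals the oracle's first 60 degC crossing."""
        config = pdsg.DesignConfig()
        for locus in fixture_loci[:40]:
            pair = pdsg.design_primer_cores(locus, fixture_genome.genome, config)
            if isinstance(pair, gm.DesignFailure):
                continue
            expected = None
            for length in range(config.min_len, config.max_len + 1):
                # re-derive each candidate from the genome to stay independent
                if locus.strand == "+":
                    s = locus.stop_codon_interval[1]
                    candidate = fixture_genome.genome[locus.contig_id].sequence[s - length : s]
                else:
                    s = locus.stop_codon_interval[0]
                    candidate = revcomp(
                        fixture_genome.genome[locus.contig_id].sequence[s : s + length]
                    )
                if nn_tm_oracle(candidate) >= config.target_tm:
                    expected = length
                    break
            cap = min(config.max_len, locus.stop_codon_interval[1] - locus.last_exon_interval[0]
                      if locus.strand == "+"
                      else locus.last_exon_interval[1] - locus.stop_codon_interval[0])
            assert pair.forward.length == (expected if expected is not None else cap)

    def test_at_rich_context_caps_at_max_len_with_flag(self):
        locus, genome = _locus_from_context("ATATATATATATATATATATATATATATATATATAT", "ATCG" * 100, stop="TAA")
        pair = pdsg.design_primer_cores(locus, genome)
        assert pair.forward.length == 35
        assert "low-Tm:F" in pair.flags

    def test_stop_too_close_to_exon_start_fails(self):
        locus, genome = _locus_from_context("GCGCGCGCGC", "ATCG" * 100)  # 10 nt runway
        result = pdsg.design_primer_cores(locus, genome)
        assert isinstance(result, gm.DesignFailure)
        assert result.reason == "stop too close to exon start"

    def test_n_in_mandatory_core_is_failure(self):
        locus, genome = _locus_from_context("GCGCGCGNGCGCGCGCGCGC", "ATCG" * 100)
        result = pdsg.design_primer_cores(locus, genome)
        assert isinstance(result, gm.DesignFailure)
        assert result.reason == "N in primer core"


class TestDesignPanel:
    def test_length_filter_excludes_with_reason(self, fixture_loci, fixture_genome, fixture_panel):
        lo, hi = pdsg.DesignConfig().panel_length_filter
        expected_pass = [l for l in fixture_loci if lo <= l.insert_length <= hi]
        filtered = [f for f in fixture_panel.failures if f.reason == "length filter"]
        assert len(fixture_panel.pairs) + len(filtered) == len(fixture_loci)
        assert {p.gene_id for p in fixture_panel.pairs} <= {l.gene_id for l in expected_pass}

    def test_panel_invariants(self, fixture_panel, fixture_truth):
        assert len(pdsg.ATTB2) == 28 and len(pdsg.ATTB3) == 26
        for pair in fixture_panel.pairs:
            assert pair.forward_tailed.startswith(pdsg.ATTB2)
            assert pair.reverse_tailed.startswith(pdsg.ATTB3)
            assert pair.forward.sequence_5to3[-3:] in {"TAA", "TAG", "TGA"}
            assert pair.expected_insert_length == fixture_truth[pair.gene_id].insert_length

    def test_sheet_is_byte_identical_across_runs(self, fixture_loci, fixture_genome, tmp_path):
        paths = []
        for name in ("a.tsv", "b.tsv"):
            panel = pdsg.design_panel(fixture_loci, fixture_genome.genome)
            path = tmp_path / name
            pdsg.write_primer_sheet(panel, path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_empty_locus_set_is_error(self, fixture_genome):
        with pytest.raises(ValueError):
            pdsg.design_panel([], fixture_genome.genome)

    def test_mirrored_fixture_designs_identical_primers(self, fixture_genome, fixture_panel):
        """Panel design commutes with reverse-complementing the genome."""
        from utrome import synthetic_fixtures as fx

        mirrored = fx.mirror_fixture(fixture_genome)
        models, _ = gm.read_annotation(mirrored.gtf_text(), mirrored.genome, from_string=True)
        loci, _ = gm.resolve_utr_loci(models, mirrored.genome)
        panel_m = pdsg.design_panel(loci, mirrored.genome)
        original = {
            p.gene_id: (p.forward_tailed, p.reverse_tailed) for p in fixture_panel.pairs
        }
        mirrored_primers = {
            p.gene_id: (p.forward_tailed, p.reverse_tailed) for p in panel_m.pairs
        }
        assert mirrored_primers == original
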