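import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exburden import (
    build_background,
    build_genome_exon_mask,
    filter_intergenic,
    parse_gene_annotation,
    project_exons,
)
from exburden.annotation import GtfParseError
from exburden.intervals import interval_positions, total_length

from conftest import make_gene


def gtf(*lines):
    return io.StringIO("\n".join(lines) + "\n")


class TestParseGeneAnnotation:
    def test_coordinates_become_zero_based_half_open(self):
        genes = parse_gene_annotation(gtf(
            'chr1\t.\texon\t101\t200\t.\t+\t.\tgene_id "G"; transcript_id "G.t1";'
        ))
        assert len(genes) == 1
        assert genes[0].transcripts == [("G.t1", [(100, 200)])]

    def test_exons_of_one_transcript_group_into_one_gene(self):
        genes = parse_gene_annotation(gtf(
            'chr1\t.\texon\t101\t200\t.\t+\t.\tgene_id "G"; transcript_id "G.t1";',
            'chr1\t.\texon\t301\t400\t.\t+\t.\tgene_id "G"; transcript_id "G.t1";',
        ))
        assert len(genes) == 1
        (tid, exons), = genes[0].transcripts
        assert tid == "G.t1" and exons == [(100, 200), (300, 400)]

    def test_gene_without_exons_is_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            genes = parse_gene_annotation(gtf(
                'chr1\t.\tgene\t101\t400\t.\t+\t.\tgene_id "EMPTY";',
                'chr1\t.\texon\t101\t200\t.\t+\t.\tgene_id "G"; transcript_id "G.t1";',
            ))
        assert [g.gene_id for g in genes] == ["G"]
        assert "EMPTY" in caplog.text

    def test_exon_missing_transcript_id_gets_synthetic_transcript(self):
        genes = parse_gene_annotation(gtf(
            'chr1\t.\texon\t101\t200\t.\t+\t.\tgene_id "G";'
        ))
        assert genes[0].transcripts[0][0].endswith("synthetic_tx")

    def test_malformed_line_raises_naming_line_number(self):
        with pytest.raises(GtfParseError, match="line 2"):
            parse_gene_annotation(gtf(
                'chr1\t.\texon\t101\t200\t.\t+\t.\tgene_id "G"; transcript_id "t";',
                "chr1\texon\t101",
            ))
        with pytest.raises(GtfParseError, match="line 1"):
            parse_gene_annotation(gtf(
                'chr1\t.\texon\tone\t200\t.\t+\t.\tgene_id "G";'
            ))

    def test_inverted_exon_rejected_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            genes = parse_gene_annotation(gtf(
                'chr1\t.\texon\t200\t100\t.\t+\t.\tgene_id "G"; transcript_id "t";',
                'chr1\t.\texon\t301\t400\t.\t+\t.\tgene_id "G"; transcript_id "t";',
            ))
        assert genes[0].transcripts[0][1] == [(300, 400)]
        assert "end <= start" in caplog.text


class TestProjectExons:
    @pytest.mark.parametrize(
        "exon_lists, expected",
        [
            ([[(100, 200), (150, 250)]], [(100, 250)]),   # overlap union
            ([[(100, 200), (200, 300)]], [(100, 300)]),   # abutting coalesce
            ([[(10, 20), (30, 40)]], [(10, 20), (30, 40)]),  # identity
            ([[(10, 20)], [(15, 25), (40, 50)]], [(10, 25), (40, 50)]),  # across transcripts
        ],
    )
    def test_merged_projection(self, exon_lists, expected):
        gene = make_gene("G", "chr1", "+", exon_lists)
        assert project_exons(gene).tolist() == [list(iv) for iv in expected]

    @given(st.lists(st.tuples(st.integers(0, 300), st.integers(1, 60)), min_size=1, max_size=12))
    @settings(derandomize=True, max_examples=60)
    def test_idempotent_and_order_independent(self, raw):
        # one exon per transcript so per-transcript non-overlap holds by construction
        exons = [(s, s + w) for s, w in raw]
        fwd = project_exons(make_gene("G", "chr1", "+", [[e] for e in exons]))
        rev = project_exons(make_gene("G", "chr1", "+", [[e] for e in exons[::-1]]))
        again = project_exons(make_gene("G", "chr1", "+", [list(map(tuple, fwd))]))
        assert fwd.tolist() == rev.tolist() == again.tolist()
        # covers exactly the union of input positions
        want = sorted({p for s, e in exons for p in range(s, e)})
        assert interval_positions(fwd).tolist() == want


class TestFilterIntergenic:
    def test_opposite_strand_overlap_removed(self):
        lnc = make_gene("L", "chr1", "+", [[(1000, 2000)]])
        pc = make_gene("P", "chr1", "-", [[(1500, 3000)]], biotype="protein_coding")
        assert filter_intergenic([lnc], [pc]) == []

    def test_same_strand_distance_boundary(self):
        """Gap of exactly 10,001 bp retains the gene; 10,000 removes it.

        Cross-checked by a brute-force pairwise distance scan over explicit
        position gaps (pc_start - lnc_end for disjoint half-open spans).
        """
        lnc = make_gene("L", "chr1", "+", [[(1000, 2000)]])
        for pc_start, kept in [(12001, True), (12000, False), (2000, False)]:
            pc = make_gene("P", "chr1", "+", [[(pc_start, pc_start + 1000)]],
                           biotype="protein_coding")
            brute_gap = pc_start - 2000  # closest-point distance, brute force
            assert (brute_gap > 10_000) == kept
            out = filter_intergenic([lnc], [pc])
            assert ([g.gene_id for g in out] == ["L"]) == kept

    def test_opposite_strand_needs_overlap_not_proximity(self):
        lnc = make_gene("L", "chr1", "+", [[(1000, 2000)]])
        pc = make_gene("P", "chr1", "-", [[(3000, 4000)]], biotype="protein_coding")
        assert [g.gene_id for g in filter_intergenic([lnc], [pc])] == ["L"]

    def test_whitelist_overrides_both_rules(self):
        lnc = make_gene("L", "chr1", "+", [[(1000, 2000)]])
        pc = make_gene("P", "chr1", "-", [[(1500, 3000)]], biotype="protein_coding")
        out = filter_intergenic([lnc], [pc], whitelist={"L"})
        assert [g.gene_id for g in out] == ["L"]

    def test_empty_pc_set_is_identity(self):
        lncs = [make_gene(f"L{i}", "chr1", "+", [[(i * 100, i * 100 + 50)]])
                for i in range(1, 4)]
        assert filter_intergenic(lncs, []) == lncs

    def test_unknown_chromosome_retained_with_warning(self, caplog):
        lnc = make_gene("L", "chrZ", "+", [[(1000, 2000)]])
        pc = make_gene("P", "chr1", "+", [[(1000, 2000)]], biotype="protein_coding")
        with caplog.at_level("WARNING"):
            out = filter_intergenic([lnc], [pc])
        assert [g.gene_id for g in out] == ["L"]
        assert "chrZ" in caplog.text


class TestBuildBackground:
    def test_hand_derived_flanks(self):
        """Single-exon gene [5000,6000), no neighbours: background is the
        clipped upstream flank [0,5000) plus downstream [6000,16000)."""
        gene = make_gene("G", "chr1", "+", [[(5000, 6000)]])
        rs = build_background(gene, [], chrom_length=1_000_000, window=10_000)
        assert rs.background.tolist() == [[0, 5000], [6000, 16000]]
        assert rs.background_len_bp == 15_000
        assert rs.exonic.tolist() == [[5000, 6000]]

    def test_neighbour_exon_masked_out(self):
        gene = make_gene("G", "chr1", "+", [[(5000, 6000)]])
        rs = build_background(gene, [(7000, 8000)], chrom_length=1_000_000)
        pos = set(interval_positions(rs.background).tolist())
        assert pos.isdisjoint(range(7000, 8000))
        assert rs.background_len_bp == 14_000

    def test_gene_at_chromosome_start_clips_upstream(self):
        gene = make_gene("G", "chr1", "+", [[(0, 500)]])
        rs = build_background(gene, [], chrom_length=1_000_000)
        assert rs.background.tolist() == [[500, 10_500]]
        assert np.all(rs.background >= 0)

    def test_negative_window_rejected(self):
        gene = make_gene("G", "chr1", "+", [[(5000, 6000)]])
        with pytest.raises(ValueError):
            build_background(gene, [], chrom_length=1_000_000, window=-1)

    def test_position_set_invariants_on_toy_annotation(self):
        """Exonic and background are disjoint and the background avoids every
        exon of every gene — asserted on explicit position sets."""
        genes = [
            make_gene("A", "chr1", "+", [[(1000, 1200), (2000, 2300)]]),
            make_gene("B", "chr1", "-", [[(4000, 4500)], [(4200, 4800)]]),
            make_gene("C", "chr1", "+", [[(30_000, 30_100)]]),
        ]
        mask = build_genome_exon_mask(genes)["chr1"]
        mask_pos = set(interval_positions(mask).tolist())
        for g in genes:
            rs = build_background(g, mask, chrom_length=100_000)
            ex = set(interval_positions(rs.exonic).tolist())
            bg = set(interval_positions(rs.background).tolist())
            assert ex.isdisjoint(bg)
            assert bg.isdisjoint(mask_pos)
            assert rs.exonic_len_bp == len(ex) and rs.background_len_bp == len(bg)
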