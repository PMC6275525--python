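import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from damkit.reference import (
    GATCFragmentMap,
    GenomeError,
    assign_fragments_to_genes,
    load_gene_models,
    load_genome,
    validate_gene_table,
)

from conftest import bruteforce_fragments, random_dna

import pandas as pd


def make_genes(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "symbol", "chrom", "start", "end", "strand"]
    )


class TestFragmentMap:
    def test_worked_example(self):
        # motif starts 2, 9, 15 -> cuts at 4, 11, 17
        fmap = GATCFragmentMap.from_sequences({"c": "TTGATCAAAGATCCCGATCG"})
        assert fmap.starts.tolist() == [0, 4, 11, 17]
        assert fmap.ends.tolist() == [4, 11, 17, 20]
        assert fmap.terminal.tolist() == [True, False, False, True]

    def test_motif_free_chromosome_single_terminal_fragment(self):
        fmap = GATCFragmentMap.from_sequences({"c": "AAAAAAAA"})
        assert fmap.starts.tolist() == [0]
        assert fmap.ends.tolist() == [8]
        assert fmap.terminal.tolist() == [True]

    def test_matches_bruteforce_oracle_on_random_sequences(self, rng):
        for _ in range(20):
            seq = random_dna(rng, 5000)
            fmap = GATCFragmentMap.from_sequences({"c": seq})
            expected = bruteforce_fragments(seq)
            got = list(zip(fmap.starts, fmap.ends, fmap.terminal))
            assert [(int(s), int(e), bool(t)) for s, e, t in got] == expected

    def test_rejects_non_dna_characters(self):
        with pytest.raises(GenomeError):
            GATCFragmentMap.from_sequences({"c": "ACGTXACGT"})

    def test_n_never_matches_inside_motif(self):
        fmap = GATCFragmentMap.from_sequences({"c": "AAGANCAA"})
        assert fmap.n_fragments == 1

    def test_tiling_invariant(self, rng):
        seq = random_dna(rng, 3000)
        fmap = GATCFragmentMap.from_sequences({"c": seq})
        assert fmap.lengths.sum() == len(seq)
        assert (fmap.lengths >= 1).all()

    def test_cut_point_soundness(self, rng):
        seq = random_dna(rng, 4000)
        fmap = GATCFragmentMap.from_sequences({"c": seq})
        for b in fmap.starts[1:]:
            assert seq[b - 2 : b + 2] == "GATC"

    @settings(max_examples=30, deadline=None)
    @given(st.text(alphabet="ACGTN", min_size=1, max_size=400))
    def test_tiling_property(self, seq):
        fmap = GATCFragmentMap.from_sequences({"c": seq})
        assert int(fmap.lengths.sum()) == len(seq)
        # sorted, non-overlapping
        assert (fmap.starts[1:] == fmap.ends[:-1]).all()

    def test_bed_round_trip(self, rng, tmp_path):
        seqs = {"c1": random_dna(rng, 2000), "c2": random_dna(rng, 1500)}
        fmap = GATCFragmentMap.from_sequences(seqs)
        bed = tmp_path / "frags.bed"
        fmap.to_bed(bed)
        back = GATCFragmentMap.from_bed(bed)
        assert back.chrom_names == fmap.chrom_names
        assert np.array_equal(back.starts, fmap.starts)
        assert np.array_equal(back.ends, fmap.ends)
        assert np.array_equal(back.terminal, fmap.terminal)
        assert back.chrom_sizes == fmap.chrom_sizes

    def test_locate_and_overlapping(self):
        fmap = GATCFragmentMap.from_sequences({"c": "TTGATCAAAGATCCCGATCG"})
        assert fmap.locate("c", [0, 4, 10, 11, 19]).tolist() == [0, 1, 1, 2, 3]
        assert fmap.locate("c", [-1, 20]).tolist() == [-1, -1]
        assert fmap.locate("missing", [5]).tolist() == [-1]
        assert fmap.overlapping("c", 3, 12).tolist() == [0, 1, 2]
        assert fmap.overlapping("c", 4, 11).tolist() == [1]
        assert fmap.overlapping("c", 11, 11).tolist() == []


class TestGenomeIO:
    def test_load_genome_wrapped_multirecord(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(">c1\nACGTAC\nGTGATC\n>c2\nttttgatcaa\n")
        genomes = load_genome(fa)
        assert genomes == {"c1": "ACGTACGTGATC", "c2": "TTTTGATCAA"}

    def test_load_genome_rejects_bad_residues(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(">c1\nACGU\n")
        with pytest.raises(GenomeError):
            load_genome(fa)


class TestGeneModels:
    def test_coordinate_conversion(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "c1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1;Name=sym1\n"
        )
        genes = load_gene_models(gff)
        assert genes.loc[0, ["start", "end"]].tolist() == [100, 200]
        assert genes.loc[0, "symbol"] == "sym1"

    def test_transcript_union(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "c1\tsrc\tgene\t101\t300\t.\t+\t.\tID=g1\n"
            "c1\tsrc\tmRNA\t101\t300\t.\t+\t.\tID=t1;Parent=g1\n"
            "c1\tsrc\tmRNA\t251\t900\t.\t+\t.\tID=t2;Parent=g1\n"
        )
        genes = load_gene_models(gff)
        assert genes.loc[0, ["start", "end"]].tolist() == [100, 900]

    def test_malformed_record_skipped_with_warning(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "c1\tsrc\tgene\t60\t50\t.\t+\t.\tID=bad\n"
            "c1\tsrc\tgene\t10\t90\t.\t-\t.\tID=ok\n"
        )
        with pytest.warns(UserWarning, match="end < start"):
            genes = load_gene_models(gff)
        assert genes["gene_id"].tolist() == ["ok"]

    def test_unknown_chromosome_skipped_with_warning(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "cX\tsrc\tgene\t10\t90\t.\t+\t.\tID=g1\n"
            "c1\tsrc\tgene\t10\t90\t.\t+\t.\tID=g2\n"
        )
        with pytest.warns(UserWarning, match="unknown chromosome"):
            genes = load_gene_models(gff, {"c1": 1000})
        assert genes["gene_id"].tolist() == ["g2"]

    def test_validate_rejects_duplicates(self):
        genes = make_genes(
            [("g1", "g1", "c", 0, 10, "+"), ("g1", "g1", "c", 5, 20, "+")]
        )
        with pytest.raises(ValueError, match="duplicate"):
            validate_gene_table(genes)


class TestAssignment:
    @pytest.fixture()
    def fmap(self):
        # internal fragments [90,110), [110,700), [895,950); terminals outside
        seq_len = 1000
        starts = np.array([0, 90, 110, 700, 895, 950])
        ends = np.array([90, 110, 700, 895, 950, 1000])
        terminal = np.array([True, False, False, False, False, True])
        return GATCFragmentMap(
            chrom_names=["c"],
            chrom_sizes={"c": seq_len},
            starts=starts,
            ends=ends,
            terminal=terminal,
            _slices={"c": (0, 6)},
        )

    def test_overlap_rule(self, fmap):
        genes = make_genes([("g1", "g1", "c", 100, 900, "+")])
        assignments, unscorable = assign_fragments_to_genes(fmap, genes)
        assert assignments["g1"].tolist() == [1, 2, 3, 4]
        assert unscorable == []

    def test_half_open_boundary_not_assigned(self, fmap):
        genes = make_genes([("g1", "g1", "c", 700, 895, "+")])
        assignments, _ = assign_fragments_to_genes(fmap, genes)
        # fragment [895, 950) abuts the gene end: no overlap
        assert 4 not in assignments["g1"].tolist()

    def test_terminal_fragments_excluded_by_default(self, fmap):
        genes = make_genes([("g1", "g1", "c", 0, 1000, "+")])
        assignments, _ = assign_fragments_to_genes(fmap, genes)
        assert assignments["g1"].tolist() == [1, 2, 3, 4]
        assignments, _ = assign_fragments_to_genes(fmap, genes, include_terminal=True)
        assert assignments["g1"].tolist() == [0, 1, 2, 3, 4, 5]

    def test_gene_with_no_fragments_is_unscorable(self, fmap):
        genes = make_genes([("g1", "g1", "cX", 0, 100, "+")])
        assignments, unscorable = assign_fragments_to_genes(fmap, genes)
        assert assignments == {}
        assert unscorable == ["g1"]

    def test_strand_invariance(self, fmap):
        plus = make_genes([("g1", "g1", "c", 100, 900, "+")])
        minus = make_genes([("g1", "g1", "c", 100, 900, "-")])
        a_plus, _ = assign_fragments_to_genes(fmap, plus)
        a_minus, _ = assign_fragments_to_genes(fmap, minus)
        assert a_plus["g1"].tolist() == a_minus["g1"].tolist()

    def test_matches_quadratic_oracle_random_layouts(self, rng):
        for _ in range(10):
            seq = random_dna(rng, 8000)
            fmap = GATCFragmentMap.from_sequences({"c": seq})
            genes = make_genes(
                [
                    (f"g{i}", f"g{i}", "c", int(s), int(s) + int(w), "+")
                    for i, (s, w) in enumerate(
                        zip(
                            rng.integers(0, 7500, size=30),
                            rng.integers(1, 500, size=30),
                        )
                    )
                ]
            )
            assignments, unscorable = assign_fragments_to_genes(fmap, genes)
            for g in genes.itertuples(index=False):
                expected = [
                    i
                    for i in range(fmap.n_fragments)
                    if not fmap.terminal[i]
                    and fmap.starts[i] < g.end
                    and fmap.ends[i] > g.start
                ]
                got = assignments.get(g.gene_id, np.empty(0)).tolist()
                assert got == expected
                if not expected:
                    assert g.gene_id in unscorable
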