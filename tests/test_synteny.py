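"""Flank extraction, homology search (vs a quadratic oracle), synteny calls,
set classification and the Circos export."""

import numpy as np
import pandas as pd
import pytest

from polymir.homology import (
    GENE_PARAMS,
    PRECURSOR_PARAMS,
    GenomeIndex,
    HomologyParams,
    homology_search,
)
from polymir.io import GFF_COLUMNS, revcomp
from polymir.synteny import (
    SyntenyRecord,
    PlacementEvidence,
    call_loss_gain,
    call_syntenic,
    classify_sets,
    export_circos,
    extract_flanks,
    subgenome_of,
)
from polymir.homology import HomologyHit


def _random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _annotation(genes):
    rows = [
        (chrom, "test", "gene", s + 1, e, ".", "+", ".", f"ID={gid}")
        for gid, chrom, s, e in genes
    ]
    df = pd.DataFrame(rows, columns=GFF_COLUMNS)
    df["feature_id"] = df["attributes"].str.extract(r"ID=([^;]+)")[0]
    return df


class TestExtractFlanks:
    def test_nearest_five_per_side_in_distance_order(self, rng):
        genome = {"c1": _random_seq(rng, 30_000)}
        genes = [(f"g{i}", "c1", i * 2000, i * 2000 + 500) for i in range(12)]
        ann = _annotation(genes)
        # miRNA between g5 and g6
        ctx = extract_flanks(ann, genome, "m", "c1", 11_000, 11_100)
        assert [f.gene_id for f in ctx.upstream] == ["g5", "g4", "g3", "g2", "g1"]
        assert [f.gene_id for f in ctx.downstream] == ["g6", "g7", "g8", "g9", "g10"]
        assert ctx.upstream[0].sequence == genome["c1"][10_000:10_500]

    def test_chromosome_start_truncates_upstream(self, rng):
        genome = {"c1": _random_seq(rng, 30_000)}
        genes = [(f"g{i}", "c1", i * 2000, i * 2000 + 500) for i in range(8)]
        ctx = extract_flanks(_annotation(genes), genome, "m", "c1", 3_000, 3_100)
        assert [f.gene_id for f in ctx.upstream] == ["g1", "g0"]
        assert len(ctx.downstream) == 5

    def test_overlapping_gene_assigned_by_midpoint(self, rng):
        genome = {"c1": _random_seq(rng, 10_000)}
        # gene spans the miRNA; its midpoint (5250) is left of the miRNA
        # midpoint (5400), so it counts as upstream
        genes = [("gspan", "c1", 5000, 5500), ("gdown", "c1", 6000, 6500)]
        ctx = extract_flanks(_annotation(genes), genome, "m", "c1", 5_350, 5_450)
        assert [f.gene_id for f in ctx.upstream] == ["gspan"]
        assert [f.gene_id for f in ctx.downstream] == ["gdown"]

    def test_missing_chromosome_raises(self, rng):
        genome = {"c1": _random_seq(rng, 1000)}
        with pytest.raises(ValueError):
            extract_flanks(_annotation([("g", "c1", 10, 20)]), genome, "m", "cX", 100, 120)


class TestHomologySearch:
    def test_exact_window_is_top_hit(self, rng):
        genome = {"c1": _random_seq(rng, 5000)}
        q = genome["c1"][1000:1500]
        res = homology_search(q, genome)
        top = res.hits[0]
        assert (top.chrom, top.start, top.strand) == ("c1", 1000, "+")
        assert top.identity == 1.0 and top.coverage == 1.0

    def test_reverse_strand_hit(self, rng):
        genome = {"c1": _random_seq(rng, 5000)}
        q = revcomp(genome["c1"][2000:2400])
        res = homology_search(q, genome)
        assert any(h.start == 2000 and h.strand == "-" for h in res.hits)

    def test_absent_query_has_no_hits(self, rng):
        genome = {"c1": "AC" * 2500}  # shares no 11-mer with a G homopolymer
        res = homology_search("G" * 200, genome)
        assert res.hits == []

    def test_query_shorter_than_k_is_flagged(self, rng):
        res = homology_search("ACGTACG", {"c1": _random_seq(rng, 100)})
        assert res.flagged == "query-shorter-than-k"

    @pytest.mark.parametrize("params", [GENE_PARAMS, PRECURSOR_PARAMS])
    def test_hit_set_matches_quadratic_oracle(self, rng, params):
        genome_seq = _random_seq(rng, 20_000)
        q = _random_seq(rng, 400)
        # plant a diverged copy and an exact copy
        copy = list(q)
        for pos in rng.choice(400, 20, replace=False):
            copy[pos] = "ACGT"[(("ACGT".index(copy[pos])) + 1) % 4]
        genome_seq = genome_seq[:5000] + "".join(copy) + genome_seq[5400:15_000] + q + genome_seq[15_400:]
        genome = {"toy": genome_seq}
        got = {
            (h.chrom, h.start, h.strand, round(h.identity, 9), round(h.coverage, 9))
            for h in homology_search(q, genome, params).hits
        }
        # oracle: evaluate EVERY offset on both strands with the definition
        expected = set()
        g = genome_seq
        for strand in "+-":
            qs = q if strand == "+" else revcomp(q)
            L = len(qs)
            w = int(np.ceil(params.min_coverage * L))
            for d in range(len(g) - L + 1):
                m = [qs[i] == g[d + i] for i in range(L)]
                if sum(m) / L >= params.min_identity:
                    expected.add(("toy", d, strand, round(sum(m) / L, 9), 1.0))
                elif params.min_coverage < 1.0:
                    best = max(sum(m[i : i + w]) for i in range(L - w + 1))
                    if best / w >= params.min_identity:
                        expected.add(("toy", d, strand, round(best / w, 9), round(w / L, 9)))
        assert got == expected


def _hit(chrom, start=0, score=1.0):
    return HomologyHit(chrom, start, "+", score, 1.0)


class TestClassifySets:
    def _rec(self, placements, expected="An"):
        return SyntenyRecord("m", "parent1", "AAAA", "conserved", expected, placements)

    def test_expected_subgenome_with_flanks_is_set1(self):
        rec = self._rec([PlacementEvidence(_hit("An1"), ["g1"], [])])
        assert classify_sets(rec) == "set1"

    def test_opposite_subgenome_only_is_set2(self):
        rec = self._rec([PlacementEvidence(_hit("Cn1"), ["g1"], ["g2"])])
        assert classify_sets(rec) == "set2"

    def test_homology_without_flanks_is_set3(self):
        rec = self._rec([PlacementEvidence(_hit("An1"), [], [])])
        assert classify_sets(rec) == "set3"

    def test_no_homology_is_set4(self):
        assert classify_sets(self._rec([])) == "set4"

    def test_subgenome_prefix_parsing(self):
        assert subgenome_of("An3") == "An"
        assert subgenome_of("Ar12") == "Ar"


class TestCallSyntenic:
    def _toy(self, rng, shuffle_flanks=False):
        """Source locus with two flank genes; target carries a verbatim copy,
        with flanks optionally moved to another chromosome."""
        pre = _random_seq(rng, 120)
        up_gene = _random_seq(rng, 600)
        down_gene = _random_seq(rng, 600)
        filler = lambda n: _random_seq(rng, n)
        target_main = filler(2000)
        if shuffle_flanks:
            target_main += filler(1200) + pre + filler(1200)
            target_other = filler(500) + up_gene + filler(300) + down_gene + filler(500)
        else:
            target_main += up_gene + filler(600) + pre + filler(600) + down_gene
            target_other = filler(2000)
        target = {"An1": target_main, "An2": target_other}
        rows = []
        for chrom, seq in target.items():
            for gid, gene in (("tu", up_gene), ("td", down_gene)):
                pos = seq.find(gene)
                if pos >= 0:
                    rows.append((f"{gid}_{chrom}", chrom, pos, pos + 600))
        ann = _annotation(rows)
        from polymir.synteny import FlankContext, FlankGene

        flanks = FlankContext(
            "m",
            [FlankGene("u", "src1", 0, 600, up_gene)],
            [FlankGene("d", "src1", 0, 600, down_gene)],
        )
        return pre, flanks, GenomeIndex(target), ann

    def test_intact_neighbourhood_is_syntenic(self, rng):
        pre, flanks, index, ann = self._toy(rng)
        rec = call_syntenic("m", pre, flanks, index, ann, expected_subgenome="An")
        assert rec.syntenic
        best = rec.best
        assert best.matched_upstream == ["u"] and best.matched_downstream == ["d"]
        assert classify_sets(rec) == "set1"

    def test_flanks_on_other_chromosome_break_synteny(self, rng):
        pre, flanks, index, ann = self._toy(rng, shuffle_flanks=True)
        rec = call_syntenic("m", pre, flanks, index, ann, expected_subgenome="An")
        assert not rec.syntenic
        assert classify_sets(rec) == "set3"

    def test_absent_precursor_is_set4(self, rng):
        _, flanks, index, ann = self._toy(rng)
        decoy = _random_seq(np.random.default_rng(99), 120)
        rec = call_syntenic("m", decoy, flanks, index, ann)
        assert rec.placements == []
        assert classify_sets(rec) == "set4"


class TestLossGain:
    def _records(self, n_cons, n_nov, label, genome="parent1"):
        out = []
        for i in range(n_cons + n_nov):
            cls = "conserved" if i < n_cons else "novel"
            rec = SyntenyRecord(f"m{i}", genome, f"MAT{i}", cls, "An", [])
            rec.set_label = label
            out.append(rec)
        return out

    def test_printed_lost_split(self):
        events = call_loss_gain(self._records(68, 6, "set4"), [], [])
        assert events["summary"]["lost"] == {"conserved": 68, "novel": 6, "total": 74}

    def test_printed_gained_split(self):
        vs1 = self._records(30, 4, "set4", genome="f1")
        vs2 = self._records(30, 4, "set4", genome="f1")
        events = call_loss_gain([], vs1, vs2)
        assert events["summary"]["gained"] == {"conserved": 30, "novel": 4, "total": 34}

    def test_entity_with_one_syntenic_copy_is_not_lost(self):
        a = self._records(1, 0, "set4")[0]
        b = self._records(1, 0, "set1")[0]
        b.mature = a.mature  # same entity, second copy found in the F1
        events = call_loss_gain([a, b], [], [])
        assert events["lost"] == []


class TestCircos:
    def test_empty_records_give_valid_karyotype_and_no_links(self, rng):
        src = {"An1": "ACGT" * 100}
        tgt = {"Ar1": "ACGT" * 200}
        out = export_circos([], src, tgt, {})
        assert out.links == []
        assert len(out.karyotype) == 2
        assert out.karyotype[0].startswith("chr - src_An1")

    def test_one_link_per_set123_record(self):
        src = {"An1": "A" * 1000}
        tgt = {"An1": "A" * 1000, "Cn1": "A" * 1000}
        coords = {}
        records = []
        for i, label in enumerate(["set1", "set2", "set3", "set4"]):
            rec = SyntenyRecord(f"m{i}", "parent1", f"M{i}", "conserved", "An",
                                [PlacementEvidence(_hit("An1", 100 + i), ["g"], [])])
            rec.set_label = label
            records.append(rec)
            coords[f"m{i}"] = ("An1", 10 * i, 10 * i + 21)
        out = export_circos(records, src, tgt, coords)
        assert len(out.links) == 3  # set4 exports nothing
        assert out.links[0] == "src_An1 0 21 tgt_An1 100 121"
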