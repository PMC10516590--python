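"""Per-gene scan windows, deletion consensus, candidate calling and MSA."""

import numpy as np
import pytest

from condelscan.condel_screen import (
    CondelCandidate,
    call_condels,
    deduplicate_condels,
    extract_condel_msa,
    gene_scan_window,
    outgroup_violation_filter,
    scorable_genes,
    target_deletion_consensus,
)
from condelscan.formats_io import AlignmentChain, GenomicInterval
from condelscan.orthology_filter import (
    GeneModel,
    OrthologyCall,
    Transcript,
)


def iv(s, e, chrom="chr1"):
    return GenomicInterval(chrom, s, e)


def gene_at(tss, strand="+", gene_id="g", length=1000):
    if strand == "+":
        start, end = tss, tss + length
    else:
        start, end = tss - length + 1, tss + 1
    return GeneModel(
        gene_id, "chr1", strand,
        (Transcript("t1", start, end, ((start, end),)),),
    )


class TestScanWindow:
    def test_unclipped_length_is_400001(self):
        w = gene_scan_window(gene_at(500_000), chrom_length=2_000_000)
        assert (w.start, w.end) == (300_000, 700_001)
        assert len(w) == 400_001

    def test_minus_strand_centered_on_tx_end(self):
        g = gene_at(999, strand="-")
        w = gene_scan_window(g, flank=100, chrom_length=10_000)
        assert (w.start, w.end) == (899, 1100)
        assert (w.start + w.end - 1) // 2 == 999

    def test_clipping_at_chromosome_start(self):
        w = gene_scan_window(gene_at(100), chrom_length=1_000_000)
        assert (w.start, w.end) == (0, 200_101)

    def test_tss_outside_chromosome_errors(self):
        with pytest.raises(ValueError, match="outside chromosome"):
            gene_scan_window(gene_at(5_000), chrom_length=1_000)


def call(gene, species, confident=True):
    return OrthologyCall(
        gene, species, "1" if confident else None,
        "confident" if confident else "ambiguous",
    )


class TestScorableGenes:
    ROLES = {f"out{i}": "outgroup" for i in range(20)} | {
        f"tgt{i}": "target" for i in range(7)
    }

    def _calls(self, n_out, n_tgt):
        return [call("g", f"out{i}") for i in range(n_out)] + [
            call("g", f"tgt{i}") for i in range(n_tgt)
        ]

    def test_thresholds_met(self):
        assert scorable_genes(self._calls(17, 5), self.ROLES) == ["g"]

    def test_one_outgroup_short(self):
        assert scorable_genes(self._calls(16, 5), self.ROLES) == []

    @pytest.mark.parametrize("seed", range(3))
    def test_random_tables_match_tally_oracle(self, seed):
        rng = np.random.default_rng(seed)
        calls, expected = [], set()
        for g in ["a", "b", "c", "d"]:
            n_out = int(rng.integers(0, 20))
            n_tgt = int(rng.integers(0, 7))
            calls += [call(g, f"out{i}") for i in range(n_out)]
            calls += [call(g, f"tgt{i}") for i in range(n_tgt)]
            if n_out >= 17 and n_tgt >= 5:
                expected.add(g)
        assert set(scorable_genes(calls, self.ROLES)) == expected


WINDOW = GenomicInterval("chr1", 0, 100_000)


class TestDeletionConsensus:
    def test_ceiling_thresholds(self):
        # clade of 4 needs 3 (ceil(8/3)), clade of 3 needs 2
        clades = {"A": [f"a{i}" for i in range(4)], "B": [f"b{i}" for i in range(3)]}
        tracks = {f"a{i}": [iv(100, 200)] for i in range(3)}
        tracks |= {f"b{i}": [iv(100, 200)] for i in range(2)}
        got = target_deletion_consensus(WINDOW, tracks, clades)
        assert [(g.start, g.end) for g in got] == [(100, 200)]
        # drop one clade-A species below its threshold
        del tracks["a2"]
        assert target_deletion_consensus(WINDOW, tracks, clades) == []

    def test_conjunction_over_clades(self):
        clades = {"A": ["a0", "a1"], "B": ["b0", "b1"]}
        tracks = {"a0": [iv(0, 50)], "a1": [iv(0, 50)]}  # clade B silent
        assert target_deletion_consensus(WINDOW, tracks, clades) == []

    def test_empty_clade_errors(self):
        with pytest.raises(ValueError, match="no configured species"):
            target_deletion_consensus(WINDOW, {}, {"A": []})

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_perbase_oracle(self, seed):
        rng = np.random.default_rng(seed)
        length = 100_000
        clades = {"A": [f"a{i}" for i in range(4)], "B": [f"b{i}" for i in range(3)]}
        tracks = {}
        for sp in clades["A"] + clades["B"]:
            n = rng.integers(0, 15)
            tracks[sp] = [
                iv(int(s), int(s) + int(rng.integers(10, 2000)))
                for s in rng.integers(0, length - 2000, size=n)
            ]
        got = target_deletion_consensus(WINDOW, tracks, clades, frac=2 / 3)
        ok = np.ones(length, dtype=bool)
        for clade, members in clades.items():
            need = int(np.ceil(2 / 3 * len(members)))
            depth = np.zeros(length, dtype=int)
            for sp in members:
                cov = np.zeros(length, dtype=bool)
                for x in tracks.get(sp, ()):
                    cov[x.start : min(x.end, length)] = True
                depth += cov
            ok &= depth >= need
        expect = []
        start = None
        for i, flag in enumerate(ok):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                expect.append((start, i))
                start = None
        if start is not None:
            expect.append((start, length))
        assert [(g.start, g.end) for g in got] == expect


class TestCallCondels:
    def test_size_filters(self):
        raw, final = call_condels(WINDOW, [iv(0, 100)], [iv(30, 55)])
        assert [(r.start, r.end) for r in raw] == [(30, 55)]
        assert final == []  # 25 bp < 50

    def test_merge_then_final(self):
        raw, final = call_condels(WINDOW, [iv(0, 100)], [iv(0, 40), iv(55, 100)])
        assert len(raw) == 2
        assert [(f.start, f.end) for f in final] == [(0, 100)]

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_set_algebra_oracle(self, seed):
        rng = np.random.default_rng(seed)
        length = 100_000
        cons = [
            iv(int(s), int(s) + int(rng.integers(10, 900)))
            for s in rng.integers(0, length - 1000, size=25)
        ]
        dels = [
            iv(int(s), int(s) + int(rng.integers(10, 900)))
            for s in rng.integers(0, length - 1000, size=25)
        ]
        raw, final = call_condels(WINDOW, dels, cons)
        a = np.zeros(length, dtype=bool)
        b = np.zeros(length, dtype=bool)
        for x in dels:
            a[x.start : x.end] = True
        for x in cons:
            b[x.start : x.end] = True
        both = a & b
        pieces, start = [], None
        for i, flag in enumerate(both):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                pieces.append((start, i))
                start = None
        if start is not None:
            pieces.append((start, length))
        expect_raw = [(s, e) for s, e in pieces if e - s >= 20]
        assert [(r.start, r.end) for r in raw] == expect_raw
        # merge raw pieces at <=20 bp, keep >=50 bp
        merged = []
        for s, e in expect_raw:
            if merged and s - merged[-1][1] <= 20:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        assert [(f.start, f.end) for f in final] == [
            (s, e) for s, e in merged if e - s >= 50
        ]


class TestViolationFilter:
    SPANS = {f"o{i}": iv(0, 10_000) for i in range(5)}

    def test_zero_violations_kept(self):
        kept = outgroup_violation_filter([iv(100, 200)], {}, self.SPANS)
        assert kept == [(iv(100, 200), 0)]

    def test_two_violations_dropped(self):
        gaps = {"o0": [iv(120, 180)], "o1": [iv(150, 260)]}
        assert outgroup_violation_filter([iv(100, 200)], gaps, self.SPANS) == []

    def test_nonspanning_outgroup_not_scorable(self):
        spans = dict(self.SPANS, o0=iv(0, 150))  # does not cover candidate
        gaps = {"o0": [iv(120, 180)], "o1": [iv(150, 260)]}
        kept = outgroup_violation_filter([iv(100, 200)], gaps, spans)
        assert kept == [(iv(100, 200), 1)]

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bruteforce_overlap_count(self, seed):
        rng = np.random.default_rng(seed)
        cands = [iv(int(s), int(s) + 100) for s in rng.integers(0, 9000, size=8)]
        spans = {
            f"o{i}": iv(int(rng.integers(0, 3000)), int(rng.integers(6000, 10_000)))
            for i in range(6)
        }
        gaps = {
            f"o{i}": [
                iv(int(s), int(s) + int(rng.integers(5, 400)))
                for s in rng.integers(0, 9000, size=rng.integers(0, 4))
            ]
            for i in range(6)
        }
        kept = outgroup_violation_filter(cands, gaps, spans, max_violations=1)
        for cand in cands:
            v = sum(
                1
                for sp, span in spans.items()
                if span.start <= cand.start and span.end >= cand.end
                and any(
                    g.start < cand.end and cand.start < g.end for g in gaps[sp]
                )
            )
            assert ((cand, v) in kept) == (v <= 1)


class TestDedup:
    def _cand(self, start, end, gene):
        return CondelCandidate("chr1", start, end, {gene}, {}, 17, 0)

    def test_identical_intervals_collapse(self):
        out = deduplicate_condels([self._cand(0, 100, "g1"), self._cand(0, 100, "g2")])
        assert len(out) == 1
        assert out[0].genes == {"g1", "g2"}

    def test_disjoint_preserved(self):
        out = deduplicate_condels([self._cand(0, 100, "g1"), self._cand(500, 600, "g2")])
        assert len(out) == 2

    def test_overlapping_unequal_not_collapsed(self):
        out = deduplicate_condels([self._cand(0, 100, "g1"), self._cand(0, 101, "g2")])
        assert len(out) == 2


class TestMsa:
    def _chain(self, blocks, species_len):
        ref_span = sum(b[0] for b in blocks) + sum(b[1] or 0 for b in blocks)
        q_span = sum(b[0] for b in blocks) + sum(b[2] or 0 for b in blocks)
        return AlignmentChain(
            1, "chr1", 100, "+", 0, ref_span, "q", species_len, "+", 0, q_span,
            "1", list(blocks),
        )

    def test_identical_species(self):
        ref = {"chr1": "ACGTACGTACGTACGTACGTACGTACGTAC"}
        q = {"q": ref["chr1"]}
        chain = self._chain([(30, None, None)], 30)
        msa = extract_condel_msa(iv(5, 25), {"sp": chain}, {"sp": q}, ref)
        assert msa.rows["sp"] == msa.rows["reference"] == ref["chr1"][5:25]

    def test_full_deletion_row_is_gaps(self):
        ref = {"chr1": "ACGTACGTACGTACGTACGTACGTACGTAC"}
        q = {"q": "ACGTA" + "GTACGTACGTAC"}  # 30 - 13 = 17 bases
        chain = self._chain([(5, 13, 0), (12, None, None)], 17)
        msa = extract_condel_msa(iv(5, 18), {"sp": chain}, {"sp": q}, ref)
        assert msa.rows["sp"] == "-" * 13

    def test_three_species_hand_collated(self):
        """30 bp fixture: deletion, insertion side channel, non-spanning chain."""
        ref = {"chr1": "AACCGGTTAACCGGTTAACCGGTTAACCGG"}
        # spA: clean 6 bp deletion at ref [10, 16)
        qa = ref["chr1"][:10] + ref["chr1"][16:]
        chain_a = self._chain([(10, 6, 0), (14, None, None)], 24)
        # spB: 4 bp insertion between ref 19 and 20
        qb = ref["chr1"][:20] + "TTTT" + ref["chr1"][20:]
        chain_b = self._chain([(20, 0, 4), (10, None, None)], 34)
        # spC: chain covers only ref [0, 12) -> cannot span the candidate
        chain_c = self._chain([(12, None, None)], 12)
        qc = ref["chr1"][:12]
        cand = iv(5, 25)
        msa = extract_condel_msa(
            cand,
            {"spA": chain_a, "spB": chain_b, "spC": chain_c},
            {"spA": {"q": qa}, "spB": {"q": qb}, "spC": {"q": qc}},
            ref,
        )
        assert msa.rows["reference"] == ref["chr1"][5:25]
        assert msa.rows["spA"] == ref["chr1"][5:10] + "------" + ref["chr1"][16:25]
        assert msa.rows["spB"] == ref["chr1"][5:25]
        assert msa.insertions["spB"] == [(20, "TTTT")]
        assert msa.missing == ["spC"]
        assert "spC" not in msa.rows
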