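"""Per-gene, per-species selection of the orthology-confident alignment chain.

Every downstream step (gap calling, conservation, the screen itself) indexes
one chain per (gene, species).  A chain is accepted as the confident
ortholog when it wins the gene's overlap score and either dominates the
runner-up by a score ratio, or is supported by synteny: the flanking
reference genes map to the same chain.  Both thresholds default to 10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

from .formats_io import AlignmentChain, merge_intervals, GenomicInterval

CONFIDENT = "confident"
AMBIGUOUS = "ambiguous"
UNMAPPED = "unmapped"


@dataclass(frozen=True)
class Transcript:
    tx_id: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        for s, e in self.exons:
            if s < self.start or e > self.end or s >= e:
                raise ValueError(
                    f"transcript {self.tx_id}: exon ({s},{e}) outside span"
                )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A reference gene with its transcripts; canonical = longest isoform."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[Transcript, ...]

    @property
    def canonical(self) -> Transcript:
        # longest span wins; ties broken by lexicographically smallest id
        return min(self.transcripts, key=lambda t: (-t.length, t.tx_id))

    @property
    def tss(self) -> int:
        tx = self.canonical
        return tx.start if self.strand == "+" else tx.end - 1


@dataclass(frozen=True)
class OrthologyCall:
    gene_id: str
    species: str
    chain_id: str | None
    confidence: str
    best_score: float = 0.0
    second_score: float = 0.0
    synteny_support: int = 0


def score_gene_chain_overlap(gene: GeneModel, chain: AlignmentChain) -> float:
    """Chain score weighted by canonical-exon coverage; 0 without overlap."""
    if gene.chrom != chain.ref_name:
        return 0.0
    exons = merge_intervals(
        [GenomicInterval(gene.chrom, s, e) for s, e in gene.canonical.exons]
    )
    exonic = sum(len(iv) for iv in exons)
    covered = 0
    for bs, be, _, _ in chain.aligned_blocks():
        for iv in exons:
            covered += max(0, min(be, iv.end) - max(bs, iv.start))
    if covered == 0:
        return 0.0
    return chain.score * covered / exonic


def select_orthologous_chain(
    gene: GeneModel,
    chains: Sequence[AlignmentChain],
    species: str = "",
    ratio_thresh: float = 10.0,
    synteny_thresh: int = 10,
    neighbor_best_chains: Sequence[str | None] = (),
    require_both: bool = False,
) -> OrthologyCall:
    """Pick the single orthologous chain of one species for one gene.

    ``neighbor_best_chains`` lists the best-chain ids of the nearest
    flanking reference genes (both sides pooled); synteny support is the
    number of them matching the winning chain.  Confidence is the
    disjunction of the score-ratio and synteny tests unless
    ``require_both`` asks for the conjunction.
    """
    scored = sorted(
        ((score_gene_chain_overlap(gene, c), c) for c in chains),
        key=lambda t: -t[0],
    )
    scored = [(s, c) for s, c in scored if s > 0]
    if not scored:
        return OrthologyCall(gene.gene_id, species, None, UNMAPPED)
    best_score, best = scored[0]
    second_score = scored[1][0] if len(scored) > 1 else 0.0
    ratio = math.inf if second_score == 0 else best_score / second_score
    support = sum(1 for cid in neighbor_best_chains if cid == best.chain_id)
    ratio_ok = ratio >= ratio_thresh
    synteny_ok = support >= synteny_thresh
    ok = (ratio_ok and synteny_ok) if require_both else (ratio_ok or synteny_ok)
    return OrthologyCall(
        gene.gene_id,
        species,
        best.chain_id if ok else None,
        CONFIDENT if ok else AMBIGUOUS,
        best_score,
        second_score,
        support,
    )


def build_orthology_calls(
    genes: Sequence[GeneModel],
    chains: Sequence[AlignmentChain],
    species: str = "",
    ratio_thresh: float = 10.0,
    synteny_thresh: int = 10,
    n_neighbors_per_side: int = 10,
    require_both: bool = False,
) -> list[OrthologyCall]:
    """Call orthologous chains for all genes of one species.

    Two passes: first each gene's best-scoring chain, then the confidence
    call with synteny support drawn from the ``n_neighbors_per_side``
    nearest flanking genes on the same chromosome.
    """
    best_chain: dict[str, str | None] = {}
    for g in genes:
        scored = [(score_gene_chain_overlap(g, c), c) for c in chains]
        scored = [t for t in scored if t[0] > 0]
        best_chain[g.gene_id] = (
            max(scored, key=lambda t: t[0])[1].chain_id if scored else None
        )
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for gl in by_chrom.values():
        gl.sort(key=lambda g: g.tss)
    calls = []
    for g in genes:
        sibs = by_chrom[g.chrom]
        i = sibs.index(g)
        neighbors = (
            sibs[max(0, i - n_neighbors_per_side) : i]
            + sibs[i + 1 : i + 1 + n_neighbors_per_side]
        )
        calls.append(
            select_orthologous_chain(
                g,
                chains,
                species=species,
                ratio_thresh=ratio_thresh,
                synteny_thresh=synteny_thresh,
                neighbor_best_chains=[best_chain[n.gene_id] for n in neighbors],
                require_both=require_both,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Gene-model I/O (BED12-like; name field "gene_id|transcript_id")
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path) -> list[GeneModel]:
    per_gene: dict[str, dict] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5] if len(f) > 5 else "+"
            if len(f) >= 12:
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offs = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = tuple((start + o, start + o + s) for o, s in zip(offs, sizes))
            else:
                exons = ((start, end),)
            gene_id, _, tx_id = name.partition("|")
            tx_id = tx_id or name
            rec = per_gene.setdefault(
                gene_id, {"chrom": chrom, "strand": strand, "txs": []}
            )
            rec["txs"].append(Transcript(tx_id, start, end, exons))
    return [
        GeneModel(gid, rec["chrom"], rec["strand"], tuple(rec["txs"]))
        for gid, rec in per_gene.items()
    ]


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            for tx in g.transcripts:
                sizes = ",".join(str(e - s) for s, e in tx.exons)
                offs = ",".join(str(s - tx.start) for s, e in tx.exons)
                fh.write(
                    "\t".join(
                        [
                            g.chrom, str(tx.start), str(tx.end),
                            f"{g.gene_id}|{tx.tx_id}", "0", g.strand,
                            str(tx.start), str(tx.end), "0",
                            str(len(tx.exons)), sizes, offs,
                        ]
                    )
                    + "\n"
                )


def write_orthology_calls(calls: Iterable[OrthologyCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tspecies\tchain_id\tconfidence\tbest_score\t"
            "second_score\tsynteny_support\n"
        )
        for c in calls:
            fh.write(
                f"{c.gene_id}\t{c.species}\t{c.chain_id or '.'}\t{c.confidence}\t"
                f"{c.best_score:g}\t{c.second_score:g}\t{c.synteny_support}\n"
            )
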