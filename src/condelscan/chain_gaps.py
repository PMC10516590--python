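"""Chain-gap (deletion) calling from pairwise alignment chains.

A chain gap is a reference interval unaligned in the query.  Single-sided
gaps (query advances zero bases) are clean deletion candidates; double-sided
gaps mark mutually unalignable sequence.  Gaps whose query-side context lies
near an assembly N-run are flagged invalid so that incomplete query assembly
is not mistaken for genuinely missing sequence; valid gaps are then merged
per chain into the deletion track the screen consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from collections.abc import Iterable, Sequence

from .formats_io import (
    AlignmentChain,
    GenomicInterval,
    fetch_seq,
    find_n_runs,
    merge_intervals,
)


@dataclass(frozen=True)
class ChainGap:
    """One inter-block reference gap of a chain.

    ``query_start``/``query_end`` give the gap's query-side context in
    forward-strand query coordinates: the insertion point (zero-length
    interval) for single-sided gaps, the unaligned query interval for
    double-sided ones.
    """

    species: str
    chain_id: str
    ref_chrom: str
    ref_start: int
    ref_end: int
    query_chrom: str
    query_start: int
    query_end: int
    sided: str  # "single" | "double"
    valid: bool = True

    @property
    def ref_interval(self) -> GenomicInterval:
        return GenomicInterval(self.ref_chrom, self.ref_start, self.ref_end)


def extract_chain_gaps(chain: AlignmentChain, species: str = "") -> list[ChainGap]:
    """One gap per inter-block junction with dt > 0, in reference order.

    Junctions with dt = 0 (pure query insertions) yield nothing.  Together
    with the blocks, the returned gaps tile [ref_start, ref_end) exactly.
    """
    gaps: list[ChainGap] = []
    t, q = chain.ref_start, chain.query_start
    for size, dt, dq in chain.blocks[:-1]:
        t += size
        q += size
        if dt > 0:
            qs, qe = chain.query_to_forward(q, q + dq)
            gaps.append(
                ChainGap(
                    species=species,
                    chain_id=chain.chain_id,
                    ref_chrom=chain.ref_name,
                    ref_start=t,
                    ref_end=t + dt,
                    query_chrom=chain.query_name,
                    query_start=qs,
                    query_end=qe,
                    sided="single" if dq == 0 else "double",
                )
            )
        t += dt
        q += dq
    return gaps


def _interval_gap(a0: int, a1: int, b0: int, b1: int) -> int:
    """Distance between half-open intervals (0 if they touch or overlap)."""
    return max(a0 - b1, b0 - a1, 0)


def filter_gaps_near_assembly_gaps(
    gaps: Sequence[ChainGap],
    query_genome,
    flank: int = 100,
    n_run_min: int = 6,
) -> list[ChainGap]:
    """Invalidate gaps whose query context is within ``flank`` bp of an N-run.

    N-runs of length >= ``n_run_min`` are located once per query chromosome
    on the forward strand (the frame in which assembly gaps exist).  A
    zero-length context (single-sided junction point) is treated as the
    point between the flanking query bases.
    """
    run_cache: dict[str, list[GenomicInterval]] = {}
    out: list[ChainGap] = []
    for gap in gaps:
        if gap.query_chrom not in run_cache:
            seq = fetch_seq(query_genome, gap.query_chrom)
            run_cache[gap.query_chrom] = find_n_runs(seq, n_run_min, gap.query_chrom)
        invalid = any(
            _interval_gap(gap.query_start, gap.query_end, run.start, run.end) <= flank
            for run in run_cache[gap.query_chrom]
        )
        out.append(replace(gap, valid=not invalid))
    return out


def merged_gap_track(
    gaps: Iterable[ChainGap], max_dist: int = 20
) -> dict[tuple[str, str], list[GenomicInterval]]:
    """Per-(species, chain) flattened reference track of valid gaps.

    Merging happens within a chain only, never across chains; gaps closer
    than ``max_dist`` on the reference collapse into one interval.
    """
    grouped: dict[tuple[str, str], list[GenomicInterval]] = {}
    for gap in gaps:
        if gap.valid:
            grouped.setdefault((gap.species, gap.chain_id), []).append(
                gap.ref_interval
            )
    return {key: merge_intervals(ivs, max_dist) for key, ivs in grouped.items()}
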