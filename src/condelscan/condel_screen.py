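"""The CONDEL association scan.

Around each scorable reference gene (one mapped to enough outgroups and
target species), the screen intersects (i) the per-base consensus of valid
chain-gap deletions across the screened trait-reduced clades with (ii) the
reference footprint conserved in enough trait-complete outgroups, then
applies size, merge, and outgroup-violation filters and deduplicates
candidates discovered via multiple nearby genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence
from pathlib import Path

from .formats_io import (
    AlignmentChain,
    GenomicInterval,
    clip_intervals,
    coverage_count,
    fetch_seq,
    intersect_tracks,
    merge_intervals,
)
from .orthology_filter import CONFIDENT, GeneModel, OrthologyCall

ROLE_REFERENCE = "reference"
ROLE_OUTGROUP = "outgroup"
ROLE_TARGET = "target"


@dataclass(frozen=True)
class SpeciesConfig:
    """One species' role in the screen."""

    species: str
    role: str  # reference | outgroup | target
    clade: str = ""
    screened: bool = False  # clade participates in the deletion consensus
    phenotype: Mapping[str, float] = field(default_factory=dict)
    fasta: str = ""
    chain: str = ""

    def __post_init__(self):
        if self.role not in (ROLE_REFERENCE, ROLE_OUTGROUP, ROLE_TARGET):
            raise ValueError(f"bad role {self.role!r} for {self.species}")


def validate_roster(roster: Sequence[SpeciesConfig]) -> None:
    refs = [s for s in roster if s.role == ROLE_REFERENCE]
    if len(refs) != 1:
        raise ValueError(f"expected exactly one reference species, got {len(refs)}")
    screened = {s.clade for s in roster if s.role == ROLE_TARGET and s.screened}
    if len(screened) < 2:
        raise ValueError(
            f"need at least two screened target clades, got {sorted(screened)}"
        )


def screened_clades(roster: Sequence[SpeciesConfig]) -> dict[str, list[str]]:
    clades: dict[str, list[str]] = {}
    for s in roster:
        if s.role == ROLE_TARGET and s.screened:
            clades.setdefault(s.clade, []).append(s.species)
    return clades


@dataclass
class CondelCandidate:
    """A final screen hit on the reference genome."""

    chrom: str
    start: int
    end: int
    genes: set[str]
    clade_support: dict[str, int]
    conservation_count: int
    violations: int

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Screen operations
# ---------------------------------------------------------------------------

def gene_scan_window(
    gene: GeneModel, flank: int = 200_000, chrom_length: int | None = None
) -> GenomicInterval:
    """The +/- ``flank`` scan interval around the canonical TSS.

    The TSS base itself is included, so the unclipped window length is
    2*flank + 1 (400,001 bp at the default).  The window is clipped to the
    chromosome when its length is known.
    """
    tss = gene.tss
    if tss < 0 or (chrom_length is not None and tss >= chrom_length):
        raise ValueError(
            f"gene {gene.gene_id}: TSS {tss} outside chromosome"
        )
    start = max(0, tss - flank)
    end = tss + flank + 1
    if chrom_length is not None:
        end = min(end, chrom_length)
    return GenomicInterval(gene.chrom, start, end, name=gene.gene_id)


def scorable_genes(
    calls: Sequence[OrthologyCall],
    roles: Mapping[str, str],
    min_outgroups: int = 17,
    min_targets: int = 5,
) -> list[str]:
    """Genes confidently mapped to enough outgroup and target species."""
    tallies: dict[str, dict[str, int]] = {}
    for c in calls:
        if c.confidence != CONFIDENT:
            continue
        role = roles.get(c.species)
        if role in (ROLE_OUTGROUP, ROLE_TARGET):
            tallies.setdefault(c.gene_id, {}).setdefault(role, 0)
            tallies[c.gene_id][role] += 1
    return sorted(
        g
        for g, t in tallies.items()
        if t.get(ROLE_OUTGROUP, 0) >= min_outgroups
        and t.get(ROLE_TARGET, 0) >= min_targets
    )


def clade_min_count(clade_size: int, frac: float) -> int:
    return math.ceil(frac * clade_size)


def target_deletion_consensus(
    window: GenomicInterval,
    gap_tracks: Mapping[str, Sequence[GenomicInterval]],
    clades: Mapping[str, Sequence[str]],
    frac: float = 2.0 / 3.0,
) -> list[GenomicInterval]:
    """Bases deleted in >= ``frac`` of every screened clade, within a window.

    ``gap_tracks`` maps target species to their merged valid-gap intervals
    on the gene's orthologous chain; species absent from the mapping
    contribute no deletion evidence but still count in the clade
    denominator.
    """
    consensus: list[GenomicInterval] | None = None
    for clade, members in clades.items():
        if not members:
            raise ValueError(f"clade {clade!r} has no configured species")
        need = clade_min_count(len(members), frac)
        tracks = [
            clip_intervals(gap_tracks.get(sp, ()), window) for sp in members
        ]
        clade_track = coverage_count(tracks, min_species=need, min_span=1)
        consensus = (
            clade_track
            if consensus is None
            else intersect_tracks(consensus, clade_track)
        )
    return consensus or []


def call_condels(
    window: GenomicInterval,
    deletion_consensus: Sequence[GenomicInterval],
    conserved_track: Sequence[GenomicInterval],
    merge_dist: int = 20,
    min_raw: int = 20,
    min_final: int = 50,
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Intersect deletion consensus with the conserved footprint.

    Raw candidates are intersection pieces of at least ``min_raw`` bp
    (after clipping to the window); raw pieces within ``merge_dist`` merge,
    and merged pieces of at least ``min_final`` bp are the final
    candidates.  Returns ``(raw, final)``.
    """
    pieces = intersect_tracks(
        clip_intervals(deletion_consensus, window),
        clip_intervals(conserved_track, window),
    )
    raw = [iv for iv in pieces if len(iv) >= min_raw]
    if not raw:
        return [], []
    merged = merge_intervals(raw, merge_dist)
    final = [iv for iv in merged if len(iv) >= min_final]
    return raw, final


def outgroup_violation_filter(
    candidates: Sequence[GenomicInterval],
    outgroup_gap_tracks: Mapping[str, Sequence[GenomicInterval]],
    outgroup_chain_spans: Mapping[str, GenomicInterval],
    max_violations: int = 1,
) -> list[tuple[GenomicInterval, int]]:
    """Keep candidates with at most ``max_violations`` outgroup gaps.

    An outgroup is scorable for a candidate when its confident chain span
    covers the candidate entirely; it violates when any of its valid
    merged gaps overlaps the candidate.  Returns kept candidates with
    their violation counts.
    """
    kept = []
    for cand in candidates:
        violations = 0
        for sp, span in outgroup_chain_spans.items():
            if not (
                span.chrom == cand.chrom
                and span.start <= cand.start
                and span.end >= cand.end
            ):
                continue
            if any(g.overlaps(cand) for g in outgroup_gap_tracks.get(sp, ())):
                violations += 1
        if violations <= max_violations:
            kept.append((cand, violations))
    return kept


def conservation_depth(
    candidate: GenomicInterval,
    outgroup_element_tracks: Mapping[str, Sequence[GenomicInterval]],
) -> int:
    """Minimum per-base count of outgroups conserved across the candidate."""
    depth = len(outgroup_element_tracks)
    while depth > 0:
        cov = coverage_count(
            {k: clip_intervals(v, candidate) for k, v in outgroup_element_tracks.items()},
            min_species=depth,
            min_span=1,
        )
        if any(c.start <= candidate.start and c.end >= candidate.end for c in cov):
            return depth
        depth -= 1
    return 0


def deduplicate_condels(candidates: Sequence[CondelCandidate]) -> list[CondelCandidate]:
    """Collapse identical intervals found via different genes.

    Interval identity is exact (chrom, start, end); linked-gene sets are
    unioned.  Overlapping but unequal intervals are kept distinct.
    """
    merged: dict[tuple[str, int, int], CondelCandidate] = {}
    for c in candidates:
        key = (c.chrom, c.start, c.end)
        if key in merged:
            merged[key].genes |= set(c.genes)
            merged[key].violations = max(merged[key].violations, c.violations)
        else:
            merged[key] = CondelCandidate(
                c.chrom, c.start, c.end, set(c.genes), dict(c.clade_support),
                c.conservation_count, c.violations,
            )
    return [merged[k] for k in sorted(merged)]


# ---------------------------------------------------------------------------
# MSA extraction
# ---------------------------------------------------------------------------

@dataclass
class CondelMSA:
    """Reference-anchored gapped alignment of a candidate interval.

    ``rows`` maps species to strings over ACGTN- of the candidate length;
    single-sided deletions appear as '-'.  Query insertions do not fit the
    reference column frame and are reported in ``insertions`` as
    ``(ref_position, sequence)`` pairs; species whose chain does not span
    the interval are listed in ``missing``.
    """

    chrom: str
    start: int
    end: int
    rows: dict[str, str]
    insertions: dict[str, list[tuple[int, str]]]
    missing: list[str]

    def to_fasta(self) -> str:
        out = []
        for name, row in self.rows.items():
            out.append(f">{name}\n{row}")
        return "\n".join(out) + "\n"


def extract_condel_msa(
    candidate: GenomicInterval,
    chains_by_species: Mapping[str, AlignmentChain],
    genomes_by_species: Mapping[str, object],
    ref_genome,
    ref_label: str = "reference",
) -> CondelMSA:
    """Collate each species' orthologous sequence at the candidate."""
    from .conserved_elements import revcomp

    s0, e0 = candidate.start, candidate.end
    rows: dict[str, str] = {
        ref_label: fetch_seq(ref_genome, candidate.chrom, s0, e0)
    }
    insertions: dict[str, list[tuple[int, str]]] = {}
    missing: list[str] = []
    for sp, chain in chains_by_species.items():
        if chain is None or not (
            chain.ref_name == candidate.chrom
            and chain.ref_start <= s0
            and chain.ref_end >= e0
        ):
            missing.append(sp)
            continue
        row = ["-"] * (e0 - s0)
        genome = genomes_by_species[sp]
        t, q = chain.ref_start, chain.query_start
        for size, dt, dq in chain.blocks:
            bs, be = t, t + size
            ov_s, ov_e = max(bs, s0), min(be, e0)
            if ov_s < ov_e:
                q_lo = q + (ov_s - bs)
                q_hi = q + (ov_e - bs)
                fs, fe = chain.query_to_forward(q_lo, q_hi)
                seq = fetch_seq(genome, chain.query_name, fs, fe)
                if chain.query_strand == "-":
                    seq = revcomp(seq)
                row[ov_s - s0 : ov_e - s0] = list(seq)
            t += size
            q += size
            if dt is None:
                break
            if dq and s0 <= t < e0:
                # query insertion anchored at reference position t
                fs, fe = chain.query_to_forward(q, q + dq)
                ins = fetch_seq(genome, chain.query_name, fs, fe)
                if chain.query_strand == "-":
                    ins = revcomp(ins)
                insertions.setdefault(sp, []).append((t, ins))
            t += dt
            q += dq
        rows[sp] = "".join(row)
    return CondelMSA(candidate.chrom, s0, e0, rows, insertions, missing)


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_candidates_tsv(candidates: Sequence[CondelCandidate], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tstart\tend\tlength\tlinked_genes\tclade_support\t"
            "conservation_count\tviolations\n"
        )
        for c in candidates:
            support = ",".join(f"{k}:{v}" for k, v in sorted(c.clade_support.items()))
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.length}\t"
                f"{','.join(sorted(c.genes))}\t{support or '.'}\t"
                f"{c.conservation_count}\t{c.violations}\n"
            )


def candidates_to_bed(candidates: Sequence[CondelCandidate]) -> list[GenomicInterval]:
    return [
        GenomicInterval(
            c.chrom, c.start, c.end,
            name=f"pCONDEL.{i + 1}",
            score=c.conservation_count,
            strand="+",
        )
        for i, c in enumerate(candidates)
    ]
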