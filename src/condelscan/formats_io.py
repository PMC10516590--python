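"""Readers, writers and interval algebra for the on-disk formats the screen touches.

Covers the UCSC pairwise alignment chain format (bit-exact round trip),
soft-masked FASTA, BED3/BED6, Newick trees, JASPAR position frequency
matrices, assembly-gap (N-run) detection, and the genomic-interval
operations (merge, multi-track coverage) every later stage builds on.

All coordinates are 0-based half-open throughout the package; BED output
therefore needs no shifting.
"""

from __future__ import annotations

import io
import re
import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class ChainParseError(ValueError):
    """Raised when a chain file violates the format or its internal sums."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)
    strand: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class AlignmentChain:
    """One UCSC-format pairwise alignment chain.

    ``blocks`` is an ordered list of ``(size, dt, dq)`` tuples; ``dt``/``dq``
    are ``None`` on the last block, mirroring the file format.  Reference
    coordinates are always on '+'; query coordinates follow the chain
    convention (on the reverse-complemented query when ``query_strand`` is
    '-').
    """

    score: float
    ref_name: str
    ref_size: int
    ref_strand: str
    ref_start: int
    ref_end: int
    query_name: str
    query_size: int
    query_strand: str
    query_start: int
    query_end: int
    chain_id: str
    blocks: list[tuple[int, int | None, int | None]]

    def validate(self) -> None:
        if self.score < 0:
            raise ChainParseError(f"chain {self.chain_id}: negative score")
        if self.ref_strand != "+":
            raise ChainParseError(
                f"chain {self.chain_id}: reference strand must be '+'"
            )
        if self.query_strand not in "+-":
            raise ChainParseError(f"chain {self.chain_id}: bad query strand")
        if not self.blocks:
            raise ChainParseError(f"chain {self.chain_id}: no blocks")
        sizes = [b[0] for b in self.blocks]
        dts = [b[1] for b in self.blocks[:-1]]
        dqs = [b[2] for b in self.blocks[:-1]]
        if self.blocks[-1][1] is not None or self.blocks[-1][2] is not None:
            raise ChainParseError(
                f"chain {self.chain_id}: last block must not carry dt/dq"
            )
        if any(s <= 0 for s in sizes):
            raise ChainParseError(f"chain {self.chain_id}: block size <= 0")
        if any(d is None or d < 0 for d in dts) or any(
            d is None or d < 0 for d in dqs
        ):
            raise ChainParseError(f"chain {self.chain_id}: negative/missing dt or dq")
        if sum(sizes) + sum(dts) != self.ref_end - self.ref_start:
            raise ChainParseError(
                f"chain {self.chain_id}: block sums do not match reference span"
            )
        if sum(sizes) + sum(dqs) != self.query_end - self.query_start:
            raise ChainParseError(
                f"chain {self.chain_id}: block sums do not match query span"
            )
        for a, b in ((self.ref_start, self.ref_end), (self.query_start, self.query_end)):
            if a < 0 or a >= b:
                raise ChainParseError(f"chain {self.chain_id}: bad span {a}-{b}")
        if self.ref_end > self.ref_size or self.query_end > self.query_size:
            raise ChainParseError(f"chain {self.chain_id}: span exceeds sequence size")

    def aligned_blocks(self) -> Iterable[tuple[int, int, int, int]]:
        """Yield (ref_start, ref_end, q_start, q_end) per ungapped block.

        Query coordinates are in chain space (reverse-complement frame when
        the query strand is '-').
        """
        t, q = self.ref_start, self.query_start
        for size, dt, dq in self.blocks:
            yield t, t + size, q, q + size
            t += size + (dt or 0)
            q += size + (dq or 0)

    def query_to_forward(self, start: int, end: int) -> tuple[int, int]:
        """Map a chain-space query interval to forward-strand coordinates."""
        if self.query_strand == "+":
            return start, end
        return self.query_size - end, self.query_size - start

    def ref_span(self) -> GenomicInterval:
        return GenomicInterval(self.ref_name, self.ref_start, self.ref_end)


# ---------------------------------------------------------------------------
# Chain format
# ---------------------------------------------------------------------------

_CHAIN_HEADER_FIELDS = 13


def parse_chain(stream: io.TextIOBase | str) -> list[AlignmentChain]:
    """Parse UCSC chain-format text into validated :class:`AlignmentChain`.

    Records are separated by blank lines; record order is preserved.
    Errors report the offending line number.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()
    chains: list[AlignmentChain] = []
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if not line or line.startswith("#"):
            i += 1
            continue
        if not line.startswith("chain"):
            raise ChainParseError(f"line {i + 1}: expected chain header, got {line!r}")
        fields = line.split()
        if len(fields) != _CHAIN_HEADER_FIELDS:
            raise ChainParseError(
                f"line {i + 1}: chain header has {len(fields)} fields, "
                f"expected {_CHAIN_HEADER_FIELDS}"
            )
        try:
            score = float(fields[1])
            ref_name, ref_size = fields[2], int(fields[3])
            ref_strand = fields[4]
            ref_start, ref_end = int(fields[5]), int(fields[6])
            query_name, query_size = fields[7], int(fields[8])
            query_strand = fields[9]
            query_start, query_end = int(fields[10]), int(fields[11])
            chain_id = fields[12]
        except ValueError as exc:
            raise ChainParseError(f"line {i + 1}: bad header field: {exc}") from exc
        i += 1
        blocks: list[tuple[int, int | None, int | None]] = []
        header_line = i  # first block line, for error messages
        while i < n and lines[i].strip():
            parts = lines[i].split()
            try:
                nums = [int(p) for p in parts]
            except ValueError as exc:
                raise ChainParseError(f"line {i + 1}: bad block line: {exc}") from exc
            if len(nums) == 3:
                blocks.append((nums[0], nums[1], nums[2]))
            elif len(nums) == 1:
                blocks.append((nums[0], None, None))
                i += 1
                break
            else:
                raise ChainParseError(
                    f"line {i + 1}: block line must have 1 or 3 fields"
                )
            i += 1
        if not blocks or blocks[-1][1] is not None:
            raise ChainParseError(
                f"line {header_line}: chain {chain_id} lacks a terminal size-only block"
            )
        chain = AlignmentChain(
            score, ref_name, ref_size, ref_strand, ref_start, ref_end,
            query_name, query_size, query_strand, query_start, query_end,
            chain_id, blocks,
        )
        try:
            chain.validate()
        except ChainParseError as exc:
            raise ChainParseError(f"near line {header_line}: {exc}") from exc
        chains.append(chain)
    return chains


def parse_chain_file(path: str | Path) -> list[AlignmentChain]:
    with open(path) as fh:
        return parse_chain(fh)


def _fmt_score(score: float) -> str:
    return str(int(score)) if float(score).is_integer() else repr(score)


def write_chain(chains: Sequence[AlignmentChain]) -> str:
    """Serialize chains to UCSC chain format; round-trips ``parse_chain``."""
    records: list[str] = []
    for c in chains:
        c.validate()
        lines = [
            f"chain {_fmt_score(c.score)} {c.ref_name} {c.ref_size} {c.ref_strand} "
            f"{c.ref_start} {c.ref_end} {c.query_name} {c.query_size} "
            f"{c.query_strand} {c.query_start} {c.query_end} {c.chain_id}"
        ]
        lines += [f"{size} {dt} {dq}" for size, dt, dq in c.blocks[:-1]]
        lines.append(str(c.blocks[-1][0]))
        records.append("\n".join(lines))
    return "\n\n".join(records) + "\n" if records else ""


def write_chain_file(chains: Sequence[AlignmentChain], path: str | Path) -> None:
    Path(path).write_text(write_chain(chains))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def load_genome(source):
    """Return a chrom -> sequence mapping-like object.

    Accepts a path to a FASTA file (indexed lazily via pyfaidx, soft
    masking preserved) or an in-memory mapping of name -> sequence.
    """
    if isinstance(source, (str, Path)):
        import pyfaidx

        return pyfaidx.Fasta(str(source), as_raw=True, sequence_always_upper=False)
    return source


def fetch_seq(genome, chrom: str, start: int | None = None, end: int | None = None) -> str:
    """Fetch a (sub)sequence from any genome object ``load_genome`` returns."""
    try:
        rec = genome[chrom]
    except KeyError:
        raise KeyError(f"sequence {chrom!r} not found in genome") from None
    if start is None:
        return str(rec[:])
    return str(rec[start:end])


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals (track/comment lines skipped)."""
    out = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append(
                GenomicInterval(
                    f[0], int(f[1]), int(f[2]),
                    name=f[3] if len(f) > 3 else None,
                    score=float(f[4]) if len(f) > 4 and f[4] != "." else None,
                    strand=f[5] if len(f) > 5 else None,
                )
            )
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand is not None:
                cols += [
                    iv.name if iv.name is not None else ".",
                    ("%g" % iv.score) if iv.score is not None else "0",
                    iv.strand if iv.strand is not None else "+",
                ]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Newick / JASPAR
# ---------------------------------------------------------------------------

def read_newick(source: str | Path):
    """Load a rooted tree (dendropy.Tree) from a Newick file or string."""
    import dendropy

    text = None
    if isinstance(source, Path) or (
        isinstance(source, str) and "(" not in source and Path(source).exists()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    return dendropy.Tree.get(data=text, schema="newick")


_JASPAR_ROW = re.compile(r"^\s*([ACGT])?\s*\[?\s*([0-9.\s]+?)\s*\]?\s*$")


def read_jaspar_pfms(source: str | Path) -> list[tuple[str, str, np.ndarray]]:
    """Parse JASPAR-format position frequency matrices.

    Accepts both the bracketed dialect (``A  [ 1 2 3 ]``) and the plain
    four-row dialect; rows are in A/C/G/T order either way.  Returns
    ``(matrix_id, name, counts)`` with ``counts`` a 4 x L float array.
    """
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        text = Path(source).read_text()
    else:
        text = str(source)
    motifs: list[tuple[str, str, np.ndarray]] = []
    header: tuple[str, str] | None = None
    rows: list[np.ndarray] = []

    def _flush():
        nonlocal header, rows
        if header is None:
            return
        if len(rows) != 4:
            raise ValueError(
                f"JASPAR matrix {header[0]}: expected 4 rows, got {len(rows)}"
            )
        lens = {len(r) for r in rows}
        if len(lens) != 1:
            raise ValueError(f"JASPAR matrix {header[0]}: ragged rows")
        motifs.append((header[0], header[1], np.vstack(rows).astype(float)))
        header, rows = None, []

    for line in text.splitlines():
        line = line.rstrip()
        if not line:
            continue
        if line.startswith(">"):
            _flush()
            parts = line[1:].split(None, 1)
            header = (parts[0], parts[1] if len(parts) > 1 else parts[0])
            continue
        m = _JASPAR_ROW.match(line)
        if header is None or m is None:
            raise ValueError(f"unparseable JASPAR line: {line!r}")
        rows.append(np.array(m.group(2).split(), dtype=float))
    _flush()
    return motifs


# ---------------------------------------------------------------------------
# N-runs and interval algebra
# ---------------------------------------------------------------------------

_VALID_NT = re.compile(r"[^ACGTNacgtn]")
_N_RUN = re.compile(r"[Nn]+")


def find_n_runs(sequence: str, min_len: int, chrom: str = "seq") -> list[GenomicInterval]:
    """Maximal runs of N/n of length >= ``min_len`` (assembly gaps)."""
    if min_len < 1:
        raise ValueError("min_len must be positive")
    bad = _VALID_NT.search(sequence)
    if bad:
        raise ValueError(
            f"non-IUPAC nucleotide {bad.group()!r} at position {bad.start()}"
        )
    return [
        GenomicInterval(chrom, m.start(), m.end())
        for m in _N_RUN.finditer(sequence)
        if m.end() - m.start() >= min_len
    ]


def _by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    groups: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        groups.setdefault(iv.chrom, []).append(iv)
    return groups


def merge_intervals(
    intervals: Iterable[GenomicInterval], max_dist: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose gap (start_next - end_prev) is <= ``max_dist``.

    Touching intervals (gap 0) always merge.  Output is sorted by
    (chrom, start) and idempotent under repeated application.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be non-negative")
    out: list[GenomicInterval] = []
    for chrom in sorted(_by_chrom(intervals)):
        ivs = sorted(_by_chrom(intervals)[chrom], key=lambda x: (x.start, x.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_e <= max_dist:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def intersect_tracks(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Pieces of the intersection of two (possibly unflattened) tracks."""
    fa, fb = merge_intervals(a), merge_intervals(b)
    out = []
    ga, gb = _by_chrom(fa), _by_chrom(fb)
    for chrom in sorted(set(ga) & set(gb)):
        xs, ys = ga[chrom], gb[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            s = max(xs[i].start, ys[j].start)
            e = min(xs[i].end, ys[j].end)
            if s < e:
                out.append(GenomicInterval(chrom, s, e))
            if xs[i].end < ys[j].end:
                i += 1
            else:
                j += 1
    return out


def clip_intervals(
    intervals: Iterable[GenomicInterval], window: GenomicInterval
) -> list[GenomicInterval]:
    out = []
    for iv in intervals:
        if iv.chrom != window.chrom:
            continue
        s, e = max(iv.start, window.start), min(iv.end, window.end)
        if s < e:
            out.append(GenomicInterval(iv.chrom, s, e))
    return out


def coverage_count(
    tracks,
    min_species: int,
    min_span: int = 1,
) -> list[GenomicInterval]:
    """Maximal intervals covered by >= ``min_species`` distinct tracks.

    ``tracks`` is a mapping (or sequence) of per-species interval lists;
    each species' track is flattened first so a species never counts twice
    at a base.  Resulting intervals shorter than ``min_span`` are dropped.
    Implemented as an event sweep; tested against a per-base counting
    oracle.
    """
    track_list = list(tracks.values()) if isinstance(tracks, Mapping) else list(tracks)
    if min_species > len(track_list):
        warnings.warn(
            f"min_species={min_species} exceeds the number of tracks "
            f"({len(track_list)}); result is empty",
            stacklevel=2,
        )
        return []
    events: dict[str, list[tuple[int, int]]] = {}
    for track in track_list:
        for iv in merge_intervals(track):
            events.setdefault(iv.chrom, []).append((iv.start, +1))
            events[iv.chrom].append((iv.end, -1))
    out: list[GenomicInterval] = []
    for chrom in sorted(events):
        evs = np.array(sorted(events[chrom]), dtype=np.int64)
        pos, delta = evs[:, 0], evs[:, 1]
        # collapse simultaneous events
        upos, idx = np.unique(pos, return_inverse=True)
        net = np.zeros(len(upos), dtype=np.int64)
        np.add.at(net, idx, delta)
        depth = np.cumsum(net)
        above = depth >= min_species
        start = None
        for i, flag in enumerate(above):
            p = int(upos[i])
            if flag and start is None:
                start = p
            elif not flag and start is not None:
                if p - start >= min_span:
                    out.append(GenomicInterval(chrom, start, p))
                start = None
        # depth returns to zero at the final event, so start is always closed
    return out
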