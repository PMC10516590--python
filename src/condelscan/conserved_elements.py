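"""Per-outgroup conserved-element calling from alignment-block identity.

For every ungapped block of a species' orthologous chains, percent identity
to the reference is computed in sliding windows of several sizes (step 1,
windows never span indels).  Windows are then ranked genome-wide by
identity and the top set kept whose merged, flattened footprint reaches a
fixed fraction (default 5%) of the reference; windows tied with the last
admitted score join as a whole class.  Surviving windows merged per chain
are that species' conserved elements.

Window tables are held as pandas DataFrames because a genome scan produces
millions of windows; per-window objects would not scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats_io import AlignmentChain, GenomicInterval, fetch_seq, merge_intervals

DEFAULT_WINDOW_SIZES = (10, 25, 50, 100)

WINDOW_COLUMNS = ["species", "chain_id", "chrom", "start", "end", "window_size", "identity"]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class ConservedElement:
    species: str
    chain_id: str
    chrom: str
    start: int
    end: int
    max_identity: float

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


def _match_array(ref_seq: str, query_seq: str) -> np.ndarray:
    """Boolean per-base identity; case-insensitive; N never matches."""
    r = np.frombuffer(ref_seq.upper().encode(), dtype="S1")
    q = np.frombuffer(query_seq.upper().encode(), dtype="S1")
    return (r == q) & (r != b"N") & (q != b"N")


def score_windows(
    chain: AlignmentChain,
    ref_genome,
    query_genome,
    window_sizes=DEFAULT_WINDOW_SIZES,
    species: str = "",
) -> pd.DataFrame:
    """Identity of every step-1 window inside every ungapped block.

    Returns a DataFrame with columns ``species, chain_id, chrom, start,
    end, window_size, identity``; reference coordinates.
    """
    parts: list[pd.DataFrame] = []
    for bs, be, qs, qe in chain.aligned_blocks():
        size = be - bs
        ref_seq = fetch_seq(ref_genome, chain.ref_name, bs, be)
        fqs, fqe = chain.query_to_forward(qs, qe)
        query_seq = fetch_seq(query_genome, chain.query_name, fqs, fqe)
        if chain.query_strand == "-":
            query_seq = revcomp(query_seq)
        if len(ref_seq) != size or len(query_seq) != size:
            raise ValueError(
                f"chain {chain.chain_id}: sequence shorter than block "
                f"{chain.ref_name}:{bs}-{be}"
            )
        match = _match_array(ref_seq, query_seq)
        csum = np.concatenate(([0], np.cumsum(match)))
        for w in window_sizes:
            if w > size:
                continue
            ident = (csum[w:] - csum[:-w]) / w
            starts = bs + np.arange(size - w + 1)
            parts.append(
                pd.DataFrame(
                    {
                        "species": species,
                        "chain_id": chain.chain_id,
                        "chrom": chain.ref_name,
                        "start": starts,
                        "end": starts + w,
                        "window_size": np.int32(w),
                        "identity": ident.astype(np.float64),
                    }
                )
            )
    if not parts:
        return pd.DataFrame(columns=WINDOW_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def _union_length(starts: np.ndarray, ends: np.ndarray) -> int:
    if len(starts) == 0:
        return 0
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], np.maximum.accumulate(ends[order])
    breaks = np.flatnonzero(s[1:] > e[:-1])
    group_start = np.concatenate(([0], breaks + 1))
    group_end = np.concatenate((breaks, [len(s) - 1]))
    return int(np.sum(e[group_end] - s[group_start]))


def call_conserved_elements(
    windows: pd.DataFrame,
    genome_length: int,
    coverage_frac: float = 0.05,
    merge_dist: int = 20,
    return_windows: bool = False,
) -> list[ConservedElement]:
    """Select top-identity windows up to the coverage quota; merge per chain.

    Windows are admitted in descending identity order as whole tie classes
    until the merged, flattened union of the admitted windows covers
    ``coverage_frac * genome_length`` bases.  If the quota is unreachable,
    all windows are kept with a warning.  With ``return_windows`` the
    selected window table is returned alongside the elements (audit
    output).
    """
    if windows.empty:
        return ([], windows) if return_windows else []
    quota = coverage_frac * genome_length
    ident = windows["identity"].to_numpy()
    # encode (chrom, start/end) into one axis so the union works genome-wide
    chrom_codes, _ = pd.factorize(windows["chrom"], sort=True)
    offset = np.int64(2 * genome_length + 1)
    enc_start = windows["start"].to_numpy(np.int64) + chrom_codes * offset
    enc_end = windows["end"].to_numpy(np.int64) + chrom_codes * offset

    levels = np.unique(ident)[::-1]
    selected_mask = np.zeros(len(windows), dtype=bool)
    covered = 0
    reached = False
    for level in levels:
        cls = ident == level
        selected_mask |= cls
        covered = _union_length(enc_start[selected_mask], enc_end[selected_mask])
        if covered >= quota:
            reached = True
            break
    if not reached:
        warnings.warn(
            f"total window coverage ({covered} bp) below quota "
            f"({quota:.0f} bp); keeping all windows",
            stacklevel=2,
        )
        selected_mask[:] = True

    sel = windows.loc[selected_mask]
    elements: list[ConservedElement] = []
    for (species, chain_id, chrom), grp in sel.groupby(
        ["species", "chain_id", "chrom"], sort=True
    ):
        ivs = merge_intervals(
            [
                GenomicInterval(chrom, int(s), int(e))
                for s, e in zip(grp["start"], grp["end"])
            ],
            merge_dist,
        )
        gs = grp["start"].to_numpy()
        ge = grp["end"].to_numpy()
        gi = grp["identity"].to_numpy()
        for iv in ivs:
            inside = (gs >= iv.start) & (ge <= iv.end)
            elements.append(
                ConservedElement(
                    species, chain_id, chrom, iv.start, iv.end,
                    float(gi[inside].max()) if inside.any() else float(gi.max()),
                )
            )
    if return_windows:
        return elements, sel
    return elements


def elements_to_bed(elements) -> list[GenomicInterval]:
    """BED6 representation (score = identity x 1000, rounded)."""
    return [
        GenomicInterval(
            el.chrom, el.start, el.end,
            name=f"{el.species}.{el.chain_id}",
            score=round(el.max_identity * 1000),
            strand="+",
        )
        for el in elements
    ]
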