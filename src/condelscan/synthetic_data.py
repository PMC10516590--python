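"""Seed-reproducible synthetic screen inputs with planted ground truth.

The generator emits everything the screen consumes — a reference genome,
per-species query genomes and pairwise alignment chains, gene models, a
species/clade roster, a calibrated tree, and a truth table — with planted
conserved elements (mutating at a reduced rate in every non-reference
species) and clade-specific deletions (the CONDELs the screen should
recover).  Chains are emitted directly from the known simulated alignment,
so the screen is exercised in isolation from any aligner's behavior.

Feature coordinates are drawn from a dedicated layout seed, noise
(substitutions, indels, assembly N-gaps) from the run seed: two runs with
different seeds plant identical features under different noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .condel_screen import SpeciesConfig
from .conserved_elements import revcomp
from .formats_io import AlignmentChain, GenomicInterval, write_chain_file, write_fasta
from .orthology_filter import GeneModel, Transcript, write_gene_models

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study-condition defaults: 17 fin-complete outgroups, two screened
    fin-reduced clades of 4 and 3 species, 20 planted CONDELs of 60-300 bp
    overlapping planted conserved elements, neutral substitution rate 0.02
    per site per species and 0.001 within conserved elements."""

    seed: int = 0
    layout_seed: int = 20230917  # planted coordinates; independent of `seed`
    ref_length: int = 120_000
    chrom_name: str = "chr1"
    n_outgroups: int = 17
    clade_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"cladeA": 4, "cladeB": 3}
    )
    n_condels: int = 20
    condel_length_range: tuple[int, int] = (60, 300)
    n_neutral_elements: int = 25
    neutral_length_range: tuple[int, int] = (60, 300)
    background_sub_rate: float = 0.02
    conserved_sub_rate: float = 0.001
    small_indel_rate: float = 1e-4
    indel_length_range: tuple[int, int] = (1, 10)
    n_assembly_gaps: int = 3
    assembly_gap_length_range: tuple[int, int] = (30, 200)
    assembly_gap_near_deletion_frac: float = 0.0
    deletion_jitter: int = 0
    n_genes: int = 6
    gene_length: int = 2000
    n_exons: int = 3
    protected_flank: int = 150
    # condel index -> number of outgroups carrying the same deletion
    violations: Mapping[int, int] = field(default_factory=dict)
    minus_strand_every: int = 5  # every k-th query genome stored reverse-complemented

    def validate(self) -> None:
        for r in (self.background_sub_rate, self.conserved_sub_rate, self.small_indel_rate):
            if not (0 <= r < 1):
                raise ValueError(f"rate {r} outside [0, 1)")
        budget = (
            self.n_condels * (self.condel_length_range[1] + 2 * self.protected_flank)
            + self.n_neutral_elements
            * (self.neutral_length_range[1] + 2 * self.protected_flank)
            + self.n_genes * (self.gene_length + 2 * self.protected_flank)
        )
        if budget >= self.ref_length:
            raise ValueError(
                f"planted features ({budget} bp incl. buffers) overflow the "
                f"reference ({self.ref_length} bp)"
            )
        for idx, k in self.violations.items():
            if not (0 <= idx < self.n_condels):
                raise ValueError(f"violation locus index {idx} out of range")
            if k > self.n_outgroups:
                raise ValueError("more violating outgroups than outgroups")


@dataclass
class SimBundle:
    """Paths and in-memory handles of one simulated dataset."""

    out_dir: Path
    config: SimulationConfig
    ref_fasta: Path
    genes_bed: Path
    species_table: Path
    tree_newick: Path
    truth_table: Path
    screen_config: Path
    roster: list[SpeciesConfig]
    genes: list[GeneModel]
    truth: pd.DataFrame


# ---------------------------------------------------------------------------
# Layout
# ---------------------------------------------------------------------------

def _plan_layout(cfg: SimulationConfig):
    rng = np.random.default_rng(cfg.layout_seed)
    kinds = (
        ["condel"] * cfg.n_condels
        + ["neutral"] * cfg.n_neutral_elements
        + ["gene"] * cfg.n_genes
    )
    lengths = (
        list(rng.integers(*cfg.condel_length_range, endpoint=True, size=cfg.n_condels))
        + list(
            rng.integers(*cfg.neutral_length_range, endpoint=True,
                         size=cfg.n_neutral_elements)
        )
        + [cfg.gene_length] * cfg.n_genes
    )
    order = rng.permutation(len(kinds))
    kinds = [kinds[i] for i in order]
    lengths = [int(lengths[i]) for i in order]
    min_gap = 2 * cfg.protected_flank
    slack = cfg.ref_length - sum(lengths) - min_gap * (len(kinds) + 1)
    extra = rng.multinomial(slack, np.full(len(kinds) + 1, 1 / (len(kinds) + 1)))
    features = []  # (kind, start, end)
    pos = 0
    for kind, length, pad in zip(kinds, lengths, extra[:-1]):
        pos += min_gap + int(pad)
        features.append((kind, pos, pos + length))
        pos += length
    condels = [(s, e) for k, s, e in features if k == "condel"]
    neutrals = [(s, e) for k, s, e in features if k == "neutral"]
    gene_spans = [(s, e) for k, s, e in features if k == "gene"]
    return condels, neutrals, gene_spans


def _make_genes(cfg: SimulationConfig, gene_spans) -> list[GeneModel]:
    genes = []
    for i, (s, e) in enumerate(gene_spans):
        strand = "+" if i % 2 == 0 else "-"
        span = e - s
        exon_len = max(span // (2 * cfg.n_exons), 1)
        exons = tuple(
            (s + j * span // cfg.n_exons,
             s + j * span // cfg.n_exons + exon_len)
            for j in range(cfg.n_exons)
        )
        tx = Transcript(f"tx{i + 1:02d}", s, e, exons)
        genes.append(GeneModel(f"gene{i + 1:02d}", cfg.chrom_name, strand, (tx,)))
    return genes


def _roster(cfg: SimulationConfig) -> list[SpeciesConfig]:
    roster = [
        SpeciesConfig("ref", "reference", phenotype={"pelvic_fins": 2, "caudal_rays": 30})
    ]
    for i in range(cfg.n_outgroups):
        roster.append(
            SpeciesConfig(
                f"out{i + 1:02d}", "outgroup",
                phenotype={"pelvic_fins": 2, "caudal_rays": 26 + i % 5},
            )
        )
    for clade, size in cfg.clade_sizes.items():
        for j in range(size):
            roster.append(
                SpeciesConfig(
                    f"tgt{clade[-1]}{j + 1}", "target", clade=clade, screened=True,
                    phenotype={"pelvic_fins": 0, "caudal_rays": 12 + j % 3},
                )
            )
    return roster


def _newick(roster: Sequence[SpeciesConfig], clades: Mapping[str, int]) -> str:
    outs = ",".join(
        f"{s.species}:0.12" for s in roster if s.role == "outgroup"
    )
    clade_parts = []
    for clade in clades:
        tips = ",".join(
            f"{s.species}:0.05" for s in roster if s.clade == clade
        )
        clade_parts.append(f"({tips}):0.1")
    return f"(ref:0.1,({outs}):0.02,{','.join(clade_parts)});"


# ---------------------------------------------------------------------------
# Per-species genome + chain construction
# ---------------------------------------------------------------------------

def _mutate(ref_arr: np.ndarray, conserved_mask: np.ndarray, cfg, rng) -> np.ndarray:
    rates = np.where(conserved_mask, cfg.conserved_sub_rate, cfg.background_sub_rate)
    hit = rng.random(len(ref_arr)) < rates
    out = ref_arr.copy()
    if hit.any():
        base_idx = np.searchsorted(_BASES, out[hit])
        shift = rng.integers(1, 4, size=hit.sum())
        out[hit] = _BASES[(base_idx + shift) % 4]
    return out


def _species_ops(cfg, species: SpeciesConfig, condels, truth_rows, protected, rng):
    """Alignment edit operations for one species: sorted (pos, dt, dq)."""
    ops = []  # (ref_pos, dt, dq); dt-deletions anchored at pos, insertions between
    for row in truth_rows:
        deleting = (
            species.role == "target" and species.clade in row["clades"].split(",")
        ) or (species.role == "outgroup" and species.species in row["violators"])
        if not deleting:
            continue
        s, e = row["start"], row["end"]
        if cfg.deletion_jitter:
            s = max(1, s + int(rng.integers(-cfg.deletion_jitter, cfg.deletion_jitter + 1)))
            e = min(cfg.ref_length - 1, e + int(rng.integers(-cfg.deletion_jitter,
                                                             cfg.deletion_jitter + 1)))
        ops.append((s, e - s, 0))
    # background small indels, away from planted features
    n_indels = rng.binomial(cfg.ref_length, cfg.small_indel_rate)
    lo, hi = cfg.indel_length_range
    taken = [(p, p + dt) for p, dt, _ in ops]
    for _ in range(n_indels):
        pos = int(rng.integers(1, cfg.ref_length - hi - 1))
        length = int(rng.integers(lo, hi + 1))
        if any(ps - 2 <= pos <= pe + 2 for ps, pe in protected):
            continue
        if any(ps - 2 <= pos <= pe + 2 for ps, pe in taken):
            continue
        if rng.random() < 0.5:
            ops.append((pos, length, 0))  # deletion in query
            taken.append((pos, pos + length))
        else:
            ops.append((pos, 0, length))  # insertion in query
            taken.append((pos, pos))
    ops.sort()
    return ops


def _build_alignment(cfg, query_arr: np.ndarray, ops, rng):
    """Blocks and alignment-frame query sequence from edit operations."""
    blocks: list[tuple[int, int | None, int | None]] = []
    pieces: list[str] = []
    # map from ref coordinate to query (alignment-frame) coordinate of each
    # aligned segment start, needed for assembly-gap placement
    seg_map: list[tuple[int, int, int]] = []  # (ref_s, ref_e, query_s)
    prev = 0
    qpos = 0
    pending: list[tuple[int, int, int]] = [(p, dt, dq) for p, dt, dq in ops]
    for pos, dt, dq in pending:
        size = pos - prev
        if size <= 0:
            raise ValueError("overlapping or touching edit operations")
        seg = "".join(query_arr[prev:pos])
        pieces.append(seg)
        seg_map.append((prev, pos, qpos))
        qpos += size
        if dq:
            ins = "".join(_BASES[rng.integers(0, 4, size=dq)])
            pieces.append(ins)
            qpos += dq
        blocks.append((size, dt, dq))
        prev = pos + dt
    size = cfg.ref_length - prev
    pieces.append("".join(query_arr[prev:]))
    seg_map.append((prev, cfg.ref_length, qpos))
    qpos += size
    blocks.append((size, None, None))
    return blocks, "".join(pieces), seg_map


def _place_assembly_gaps(cfg, aln_seq: str, seg_map, ops, protected, rng,
                         near_deletions: list[int]):
    """Overwrite query bases with N-runs; returns the modified sequence.

    ``near_deletions`` lists query positions just downstream of planted
    deletion junctions where an N-run must land (to exercise the
    assembly-gap exclusion rule)."""
    seq = np.array(list(aln_seq))
    glo, ghi = cfg.assembly_gap_length_range
    placed = 0
    attempts = 0
    def protected_ref(p_ref):
        return any(ps - ghi - 2 <= p_ref <= pe + 2 for ps, pe in protected)
    while placed < cfg.n_assembly_gaps and attempts < 200:
        attempts += 1
        ref_s, ref_e, q_s = seg_map[int(rng.integers(0, len(seg_map)))]
        length = int(rng.integers(glo, ghi + 1))
        if ref_e - ref_s <= length + 2:
            continue
        off = int(rng.integers(1, ref_e - ref_s - length - 1))
        if protected_ref(ref_s + off):
            continue
        seq[q_s + off : q_s + off + length] = "N"
        placed += 1
    for qpos in near_deletions:
        length = int(rng.integers(glo, ghi + 1))
        seq[qpos : qpos + length] = "N"
    return "".join(seq)


def simulate_dataset(cfg: SimulationConfig, out_dir: str | Path) -> SimBundle:
    """Write a complete synthetic screen bundle; deterministic per seed."""
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    condels, neutrals, gene_spans = _plan_layout(cfg)
    genes = _make_genes(cfg, gene_spans)
    roster = _roster(cfg)

    # ground truth
    outgroup_names = [s.species for s in roster if s.role == "outgroup"]
    screened = sorted(cfg.clade_sizes)
    truth_rows = []
    for i, (s, e) in enumerate(condels):
        n_viol = cfg.violations.get(i, 0)
        truth_rows.append(
            {
                "condel_id": f"condel{i + 1:02d}",
                "chrom": cfg.chrom_name,
                "start": s,
                "end": e,
                "length": e - s,
                "clades": ",".join(screened),
                "violators": tuple(outgroup_names[:n_viol]),
                "n_violations": n_viol,
                "expected_recovered": (e - s) >= 50 and n_viol <= 1,
            }
        )

    master = np.random.SeedSequence(cfg.seed)
    ref_rng = np.random.default_rng(master.spawn(1)[0])
    ref_arr = _BASES[ref_rng.integers(0, 4, size=cfg.ref_length)]
    # soft-mask a few segments so case handling is exercised downstream
    for _ in range(5):
        p = int(ref_rng.integers(0, cfg.ref_length - 500))
        ref_arr[p : p + 500] = np.char.lower(ref_arr[p : p + 500])

    conserved_mask = np.zeros(cfg.ref_length, dtype=bool)
    for s, e in condels + neutrals:
        conserved_mask[s:e] = True
    protected = [(s - cfg.protected_flank, e + cfg.protected_flank)
                 for s, e in condels + neutrals + gene_spans]

    ref_fasta = out / "ref.fa"
    write_fasta({cfg.chrom_name: "".join(ref_arr)}, ref_fasta)

    ref_upper = np.char.upper(ref_arr)
    query_species = [s for s in roster if s.role != "reference"]
    sp_seeds = master.spawn(1 + len(query_species))[1:]
    rows = []
    for k, (species, seed_seq) in enumerate(zip(query_species, sp_seeds)):
        rng = np.random.default_rng(seed_seq)
        query_arr = _mutate(ref_upper, conserved_mask, cfg, rng)
        ops = _species_ops(cfg, species, condels, truth_rows, protected, rng)
        blocks, aln_seq, seg_map = _build_alignment(cfg, query_arr, ops, rng)
        near = []
        if cfg.assembly_gap_near_deletion_frac > 0 and species.role == "target":
            del_ops = [(p, dt) for p, dt, dq in ops if dt > 0]
            n_near = int(round(cfg.assembly_gap_near_deletion_frac * len(del_ops)))
            for p, dt in del_ops[:n_near]:
                for ref_s, ref_e, q_s in seg_map:
                    if ref_s <= p + dt <= ref_e:
                        near.append(q_s + (p + dt - ref_s) + 10)
                        break
        aln_seq = _place_assembly_gaps(cfg, aln_seq, seg_map, ops, protected, rng, near)
        qlen = len(aln_seq)
        minus = cfg.minus_strand_every > 0 and (k + 1) % cfg.minus_strand_every == 0
        stored = revcomp(aln_seq) if minus else aln_seq
        chrom = f"{species.species}_chr1"
        chain = AlignmentChain(
            score=float(sum(b[0] for b in blocks)),
            ref_name=cfg.chrom_name, ref_size=cfg.ref_length, ref_strand="+",
            ref_start=0, ref_end=cfg.ref_length,
            query_name=chrom, query_size=qlen,
            query_strand="-" if minus else "+",
            query_start=0, query_end=qlen,
            chain_id="1", blocks=blocks,
        )
        chain.validate()
        fasta_path = out / f"{species.species}.fa"
        chain_path = out / f"{species.species}.chain"
        write_fasta({chrom: stored}, fasta_path)
        write_chain_file([chain], chain_path)
        rows.append(
            SpeciesConfig(
                species.species, species.role, species.clade, species.screened,
                species.phenotype, str(fasta_path.name), str(chain_path.name),
            )
        )
    roster = [
        SpeciesConfig("ref", "reference", phenotype=roster[0].phenotype,
                      fasta=str(ref_fasta.name))
    ] + rows

    genes_bed = out / "genes.bed"
    write_gene_models(genes, genes_bed)
    species_table = out / "species.tsv"
    write_species_table(roster, species_table)
    tree_newick = out / "tree.nwk"
    tree_newick.write_text(_newick(roster, cfg.clade_sizes) + "\n")
    truth = pd.DataFrame(
        [
            {**r, "violators": ",".join(r["violators"]) or "."}
            for r in truth_rows
        ]
    )
    truth_table = out / "truth.tsv"
    truth.to_csv(truth_table, sep="\t", index=False)

    screen_config = out / "screen_config.yaml"
    cfg_doc = {
        "reference": "ref",
        "ref_fasta": str(ref_fasta.name),
        "genes": str(genes_bed.name),
        "species_table": str(species_table.name),
        "tree": str(tree_newick.name),
        "thresholds": {},  # paper-default thresholds
    }
    screen_config.write_text(yaml.safe_dump(cfg_doc, sort_keys=False))

    return SimBundle(
        out, cfg, ref_fasta, genes_bed, species_table, tree_newick,
        truth_table, screen_config, roster, genes, truth,
    )


# ---------------------------------------------------------------------------
# Species table I/O
# ---------------------------------------------------------------------------

def write_species_table(roster: Sequence[SpeciesConfig], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "species\trole\tclade\tscreened\tpelvic_fins\tcaudal_rays\tfasta\tchain\n"
        )
        for s in roster:
            fh.write(
                f"{s.species}\t{s.role}\t{s.clade or '.'}\t"
                f"{int(s.screened)}\t{s.phenotype.get('pelvic_fins', '')}\t"
                f"{s.phenotype.get('caudal_rays', '')}\t{s.fasta or '.'}\t"
                f"{s.chain or '.'}\n"
            )


def read_species_table(path: str | Path) -> list[SpeciesConfig]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    roster = []
    for _, r in df.iterrows():
        pheno = {}
        for key in ("pelvic_fins", "caudal_rays"):
            if key in r and str(r[key]) not in ("", "nan", "."):
                pheno[key] = float(r[key])
        roster.append(
            SpeciesConfig(
                r["species"], r["role"],
                "" if r.get("clade", ".") in (".", None) else r["clade"],
                bool(int(r.get("screened", 0) or 0)),
                pheno,
                "" if r.get("fasta", ".") in (".", None) else r["fasta"],
                "" if r.get("chain", ".") in (".", None) else r["chain"],
            )
        )
    return roster


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryReport:
    precision: float
    recall: float
    matches: tuple[tuple[str, str], ...]  # (condel_id, candidate "chrom:start-end")


def evaluate_recovery(
    candidates: Sequence[GenomicInterval],
    truth: pd.DataFrame,
    slop: int = 0,
) -> RecoveryReport:
    """Overlap-based precision/recall of candidates against planted loci.

    A truth locus counts as recovered when any candidate overlaps it after
    expanding the locus by ``slop`` bp on each side; a candidate is a true
    positive when it overlaps any truth locus likewise.
    """
    matches = []
    recovered = set()
    tp = 0
    for cand in candidates:
        hit = False
        for _, row in truth.iterrows():
            if (
                cand.chrom == row["chrom"]
                and cand.start < row["end"] + slop
                and row["start"] - slop < cand.end
            ):
                hit = True
                recovered.add(row["condel_id"])
                matches.append(
                    (row["condel_id"], f"{cand.chrom}:{cand.start}-{cand.end}")
                )
        tp += hit
    precision = tp / len(candidates) if len(candidates) else 1.0
    recall = len(recovered) / len(truth) if len(truth) else 1.0
    return RecoveryReport(precision, recall, tuple(matches))
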