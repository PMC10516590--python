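"""End-to-end orchestration of the CONDEL screen from a single YAML config.

Stages run in dependency order — orthology calls, chain-gap extraction,
conserved-element calling, the per-gene association scan — and every
threshold of the procedure is a named config key with the screen's
published default.  A manifest with content checksums makes reruns
verifiable: unchanged inputs reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from functools import cached_property
from pathlib import Path

import yaml

from . import __version__
from .chain_gaps import (
    extract_chain_gaps,
    filter_gaps_near_assembly_gaps,
    merged_gap_track,
)
from .condel_screen import (
    CondelCandidate,
    GenomicInterval,
    ROLE_OUTGROUP,
    ROLE_TARGET,
    call_condels,
    candidates_to_bed,
    conservation_depth,
    deduplicate_condels,
    extract_condel_msa,
    gene_scan_window,
    outgroup_violation_filter,
    scorable_genes,
    screened_clades,
    target_deletion_consensus,
    validate_roster,
    write_candidates_tsv,
)
from .conserved_elements import (
    call_conserved_elements,
    elements_to_bed,
    score_windows,
)
from .formats_io import (
    coverage_count,
    load_genome,
    parse_chain_file,
    write_bed,
)
from .orthology_filter import (
    CONFIDENT,
    build_orthology_calls,
    read_gene_models,
    write_orthology_calls,
)
from .synthetic_data import read_species_table

log = logging.getLogger("condelscan")


@dataclass
class ScreenThresholds:
    """Every tunable of the screen, defaulting to the published procedure."""

    min_outgroups: int = 17          # outgroup mappings/conservation required
    min_targets: int = 5             # target mappings required per gene
    clade_frac: float = 2.0 / 3.0    # deletion consensus fraction per clade
    merge_dist: int = 20             # bp; gap/element/candidate merging
    min_raw: int = 20                # bp; raw candidate size floor
    min_final: int = 50              # bp; final candidate size floor
    coverage_frac: float = 0.05      # conserved-window coverage quota
    flank: int = 200_000             # bp around the TSS
    assembly_flank: int = 100        # bp; N-run exclusion distance
    n_run_min: int = 6               # min N-run length counted as assembly gap
    window_sizes: tuple[int, ...] = (10, 25, 50, 100)
    ratio_thresh: float = 10.0       # second-best-chain ratio
    synteny_thresh: int = 10         # gene-in-synteny support
    max_violations: int = 1          # tolerated outgroup gaps per candidate
    conserved_min_span: int = 20     # bp; conserved coverage span floor
    gap_exclusion_mode: str = "drop"  # drop whole gaps near assembly N-runs


@dataclass
class ScreenConfig:
    base_dir: Path
    ref_fasta: Path
    genes: Path
    species_table: Path
    tree: Path | None
    thresholds: ScreenThresholds

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        path = Path(path)
        doc = yaml.safe_load(path.read_text())
        base = path.parent
        missing = [k for k in ("ref_fasta", "genes", "species_table") if k not in doc]
        if missing:
            raise ValueError(f"config {path}: missing keys {missing}")
        th_doc = doc.get("thresholds") or {}
        known = {f for f in ScreenThresholds.__dataclass_fields__}
        bad = set(th_doc) - known
        if bad:
            raise ValueError(f"config {path}: unknown thresholds {sorted(bad)}")
        if "window_sizes" in th_doc:
            th_doc["window_sizes"] = tuple(th_doc["window_sizes"])
        th = ScreenThresholds(**th_doc)
        for name in ("ref_fasta", "genes", "species_table"):
            p = base / doc[name]
            if not p.exists():
                raise FileNotFoundError(f"config {path}: input {p} does not exist")
        tree = base / doc["tree"] if doc.get("tree") else None
        return cls(
            base, base / doc["ref_fasta"], base / doc["genes"],
            base / doc["species_table"], tree, th,
        )


class Screen:
    """Lazy, stage-cached execution of the screen for one config."""

    def __init__(self, config: ScreenConfig) -> None:
        self.config = config
        self.th = config.thresholds

    # -- inputs ------------------------------------------------------------

    @cached_property
    def roster(self):
        roster = read_species_table(self.config.species_table)
        validate_roster(roster)
        return roster

    @cached_property
    def roles(self):
        return {s.species: s.role for s in self.roster}

    @cached_property
    def query_species(self):
        return [s for s in self.roster if s.role != "reference"]

    @cached_property
    def ref_genome(self):
        return load_genome(self.config.ref_fasta)

    @cached_property
    def chrom_lengths(self):
        return {name: len(self.ref_genome[name][:]) for name in self.ref_genome.keys()}

    @cached_property
    def genes(self):
        return read_gene_models(self.config.genes)

    def _species_path(self, rel: str) -> Path:
        # species-table entries are relative to the table's own directory
        return self.config.species_table.parent / rel

    @cached_property
    def chains(self):
        out = {}
        for sp in self.query_species:
            out[sp.species] = parse_chain_file(self._species_path(sp.chain))
        return out

    def query_genome(self, species: str):
        sp = next(s for s in self.query_species if s.species == species)
        return load_genome(self._species_path(sp.fasta))

    # -- stages ------------------------------------------------------------

    @cached_property
    def orthology(self):
        """All orthology calls, and per-(gene, species) confident chains."""
        calls = []
        for sp in self.query_species:
            calls.extend(
                build_orthology_calls(
                    self.genes, self.chains[sp.species], species=sp.species,
                    ratio_thresh=self.th.ratio_thresh,
                    synteny_thresh=self.th.synteny_thresh,
                )
            )
        n_conf = sum(c.confidence == CONFIDENT for c in calls)
        log.info("orthology: %d calls, %d confident", len(calls), n_conf)
        return calls

    @cached_property
    def confident_chain(self):
        """(gene_id, species) -> AlignmentChain of the confident ortholog."""
        by_id = {
            sp.species: {c.chain_id: c for c in self.chains[sp.species]}
            for sp in self.query_species
        }
        out = {}
        for call in self.orthology:
            if call.confidence == CONFIDENT:
                out[(call.gene_id, call.species)] = by_id[call.species][call.chain_id]
        return out

    @cached_property
    def confident_chain_ids(self):
        """species -> set of chain ids confidently mapped to any gene."""
        out: dict[str, set[str]] = {s.species: set() for s in self.query_species}
        for call in self.orthology:
            if call.confidence == CONFIDENT:
                out[call.species].add(call.chain_id)
        return out

    @cached_property
    def gap_tracks(self):
        """species -> chain_id -> merged valid-gap reference intervals."""
        tracks: dict[str, dict[str, list[GenomicInterval]]] = {}
        for sp in self.query_species:
            wanted = self.confident_chain_ids[sp.species]
            gaps = []
            for chain in self.chains[sp.species]:
                if chain.chain_id in wanted:
                    gaps.extend(extract_chain_gaps(chain, species=sp.species))
            genome = self.query_genome(sp.species)
            gaps = filter_gaps_near_assembly_gaps(
                gaps, genome, flank=self.th.assembly_flank,
                n_run_min=self.th.n_run_min,
            )
            merged = merged_gap_track(gaps, max_dist=self.th.merge_dist)
            tracks[sp.species] = {
                chain_id: ivs for (_, chain_id), ivs in merged.items()
            }
            n_valid = sum(g.valid for g in gaps)
            log.info(
                "gaps[%s]: %d extracted, %d valid after assembly-gap filter",
                sp.species, len(gaps), n_valid,
            )
        return tracks

    @cached_property
    def conserved_tracks(self):
        """outgroup species -> flattened conserved-element intervals."""
        genome_length = sum(self.chrom_lengths.values())
        tracks: dict[str, list[GenomicInterval]] = {}
        self.conserved_elements = {}
        for sp in self.query_species:
            if sp.role != ROLE_OUTGROUP:
                continue
            genome = self.query_genome(sp.species)
            import pandas as pd

            window_parts = [
                score_windows(
                    chain, self.ref_genome, genome,
                    window_sizes=self.th.window_sizes, species=sp.species,
                )
                for chain in self.chains[sp.species]
                if chain.chain_id in self.confident_chain_ids[sp.species]
            ]
            windows = (
                pd.concat(window_parts, ignore_index=True)
                if window_parts
                else None
            )
            elements = (
                call_conserved_elements(
                    windows, genome_length,
                    coverage_frac=self.th.coverage_frac,
                    merge_dist=self.th.merge_dist,
                )
                if windows is not None and not windows.empty
                else []
            )
            self.conserved_elements[sp.species] = elements
            tracks[sp.species] = [el.interval for el in elements]
            log.info("conserve[%s]: %d elements", sp.species, len(elements))
        return tracks

    @cached_property
    def conserved_coverage(self):
        """Reference footprint conserved in >= min_outgroups outgroups."""
        track = coverage_count(
            self.conserved_tracks,
            min_species=self.th.min_outgroups,
            min_span=self.th.conserved_min_span,
        )
        log.info(
            "conserve: %d intervals covered by >= %d outgroups (%d bp)",
            len(track), self.th.min_outgroups, sum(len(iv) for iv in track),
        )
        return track

    @cached_property
    def candidates(self):
        """Final deduplicated CONDEL candidates."""
        clades = screened_clades(self.roster)
        genes_by_id = {g.gene_id: g for g in self.genes}
        scorable = scorable_genes(
            self.orthology, self.roles,
            min_outgroups=self.th.min_outgroups,
            min_targets=self.th.min_targets,
        )
        log.info("screen: %d scorable genes", len(scorable))
        per_gene: list[CondelCandidate] = []
        for gene_id in scorable:
            gene = genes_by_id[gene_id]
            window = gene_scan_window(
                gene, flank=self.th.flank,
                chrom_length=self.chrom_lengths.get(gene.chrom),
            )
            target_gaps = {}
            for sp in self.query_species:
                if sp.role != ROLE_TARGET:
                    continue
                chain = self.confident_chain.get((gene_id, sp.species))
                if chain is not None:
                    target_gaps[sp.species] = self.gap_tracks[sp.species].get(
                        chain.chain_id, []
                    )
            consensus = target_deletion_consensus(
                window, target_gaps, clades, frac=self.th.clade_frac
            )
            raw, final = call_condels(
                window, consensus, self.conserved_coverage,
                merge_dist=self.th.merge_dist,
                min_raw=self.th.min_raw,
                min_final=self.th.min_final,
            )
            out_spans = {}
            out_gaps = {}
            for sp in self.query_species:
                if sp.role != ROLE_OUTGROUP:
                    continue
                chain = self.confident_chain.get((gene_id, sp.species))
                if chain is not None:
                    out_spans[sp.species] = chain.ref_span()
                    out_gaps[sp.species] = self.gap_tracks[sp.species].get(
                        chain.chain_id, []
                    )
            kept = outgroup_violation_filter(
                final, out_gaps, out_spans, max_violations=self.th.max_violations
            )
            for cand, violations in kept:
                support = {
                    clade: sum(
                        1
                        for sp in members
                        if any(g.overlaps(cand) for g in target_gaps.get(sp, ()))
                    )
                    for clade, members in clades.items()
                }
                per_gene.append(
                    CondelCandidate(
                        cand.chrom, cand.start, cand.end, {gene_id}, support,
                        conservation_depth(cand, self.conserved_tracks),
                        violations,
                    )
                )
        unique = deduplicate_condels(per_gene)
        log.info(
            "screen: %d per-gene candidates, %d unique", len(per_gene), len(unique)
        )
        return unique

    # -- outputs -----------------------------------------------------------

    def msa(self, interval: GenomicInterval):
        """Candidate MSA using each species' chain spanning the interval."""
        chains = {}
        genomes = {}
        for sp in self.query_species:
            spanning = [
                c
                for c in self.chains[sp.species]
                if c.chain_id in self.confident_chain_ids[sp.species]
                and c.ref_name == interval.chrom
                and c.ref_start <= interval.start
                and c.ref_end >= interval.end
            ]
            chains[sp.species] = spanning[0] if spanning else None
            if spanning:
                genomes[sp.species] = self.query_genome(sp.species)
        return extract_condel_msa(
            interval, chains, genomes, self.ref_genome, ref_label="reference"
        )

    def write_outputs(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        candidates = self.candidates
        paths["candidates_tsv"] = out / "candidates.tsv"
        write_candidates_tsv(candidates, paths["candidates_tsv"])
        paths["candidates_bed"] = out / "candidates.bed"
        write_bed(candidates_to_bed(candidates), paths["candidates_bed"])
        paths["orthology_tsv"] = out / "orthology.tsv"
        write_orthology_calls(self.orthology, paths["orthology_tsv"])
        gaps_dir = out / "gaps"
        gaps_dir.mkdir(exist_ok=True)
        for sp, per_chain in sorted(self.gap_tracks.items()):
            ivs = [
                GenomicInterval(iv.chrom, iv.start, iv.end, name=chain_id,
                                score=len(iv), strand="+")
                for chain_id, track in sorted(per_chain.items())
                for iv in track
            ]
            write_bed(ivs, gaps_dir / f"{sp}.gaps.bed")
            paths[f"gaps_{sp}"] = gaps_dir / f"{sp}.gaps.bed"
        cons_dir = out / "conserved"
        cons_dir.mkdir(exist_ok=True)
        _ = self.conserved_tracks
        for sp, elements in sorted(self.conserved_elements.items()):
            write_bed(elements_to_bed(elements), cons_dir / f"{sp}.elements.bed")
            paths[f"conserved_{sp}"] = cons_dir / f"{sp}.elements.bed"
        return paths


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_screen(config_path: str | Path, out_dir: str | Path) -> Path:
    """Execute every stage and write results plus a checksum manifest."""
    config = ScreenConfig.from_yaml(config_path)
    screen = Screen(config)
    paths = screen.write_outputs(out_dir)
    manifest = {
        "tool": "condelscan",
        "version": __version__,
        "config": _sha256(Path(config_path)),
        "thresholds": {
            k: list(v) if isinstance(v, tuple) else v
            for k, v in asdict(config.thresholds).items()
        },
        "inputs": {
            "ref_fasta": _sha256(config.ref_fasta),
            "genes": _sha256(config.genes),
            "species_table": _sha256(config.species_table),
        },
        "outputs": {name: _sha256(p) for name, p in sorted(paths.items())},
        "n_candidates": len(screen.candidates),
    }
    manifest_path = Path(out_dir) / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest_path
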