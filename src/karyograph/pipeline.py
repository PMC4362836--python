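"""End-to-end orchestration: blocks -> msHSBs -> EBRs -> ancestors -> statistics.

A single :class:`PipelineConfig` drives every stage.  Inputs come either from
files (pairwise synteny tables, karyotype/map/annotation side tables, a
Newick tree) or from the built-in synthetic-evolution generator; each report
is stamped with the configuration hash and seed so a run is reproducible
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import ancestry, breakpoint_stats, enrichment, synteny
from .genome_io import (
    PhyloTree,
    ReportBundle,
    SyntenyBlock,
    packaged_karyotype,
    packaged_tree,
    read_aux_tables,
    read_synteny_table,
    read_tree,
    write_outputs,
)
from .rearrangement import GenomeArrangement
from .simulate import (
    SimulationConfig,
    emit_leaf_tables,
    simulate_annotations,
    simulate_genetic_map,
    simulate_history,
)

log = logging.getLogger("karyograph")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All knobs of the full analysis; defaults follow the study settings
    (300 Kb block resolution, 1 Mb windows, 10,000 randomisation draws,
    alpha and FDR at 0.05)."""

    synteny_paths: Mapping[str, str] | None = None
    convention: str = "one_inclusive"
    tree_path: str | None = None
    karyotype_path: str | None = None
    map_path: str | None = None
    annot_path: str | None = None
    reference: str = "chicken"
    outgroup: str = "ostrich"
    chromosome_groups: Mapping[str, tuple[tuple[str, ...] | None, str]] | None = None
    resolution: int = 300_000
    window_size: int = 1_000_000
    window_rule: str = "midpoint"
    n_iter: int = 10_000
    alpha: float = 0.05
    fdr: float = 0.05
    fdr_scope: str = "per_chromosome"
    y_column: str = "total_interchrom"
    exclude_species: tuple[str, ...] = ()
    direction: str = "greater"
    seed: int = 0
    simulate: bool = False
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, PhyloTree):
                return o.as_newick()
            return str(o)

        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineInputs:
    blocks_by_species: dict[str, list[SyntenyBlock]] | None = None
    tree: PhyloTree | None = None
    karyotype: list | None = None
    markers: list | None = None
    annotations: list | None = None
    truth: object | None = None


def load_inputs(cfg: PipelineConfig) -> PipelineInputs:
    inputs = PipelineInputs()
    if cfg.simulate:
        truth = simulate_history(cfg.sim, seed=cfg.seed)
        inputs.truth = truth
        inputs.tree = truth.tree
        if cfg.reference not in truth.tree.leaves:
            raise StageError("simulate", KeyError(f"reference {cfg.reference!r} not a leaf"))
        inputs.blocks_by_species = emit_leaf_tables(truth, cfg.reference)
        inputs.markers = simulate_genetic_map(truth, cfg.reference)
        annots, _ = simulate_annotations(truth, cfg.reference)
        inputs.annotations = annots
        inputs.karyotype = packaged_karyotype()
        return inputs
    if cfg.synteny_paths:
        inputs.blocks_by_species = {
            sp: read_synteny_table(path, cfg.convention)
            for sp, path in sorted(cfg.synteny_paths.items())
        }
    inputs.tree = read_tree(cfg.tree_path) if cfg.tree_path else packaged_tree()
    if cfg.karyotype_path and cfg.map_path and cfg.annot_path:
        karyo, markers, annots = read_aux_tables(
            cfg.karyotype_path, cfg.map_path, cfg.annot_path
        )
        inputs.karyotype, inputs.markers, inputs.annotations = karyo, markers, annots
    else:
        if cfg.karyotype_path:
            from .genome_io import read_karyotype_table

            inputs.karyotype = read_karyotype_table(cfg.karyotype_path)
        else:
            inputs.karyotype = packaged_karyotype()
        if cfg.map_path:
            from .genome_io import read_genetic_map

            inputs.markers = read_genetic_map(cfg.map_path)
        if cfg.annot_path:
            from .genome_io import read_annotations

            inputs.annotations = read_annotations(cfg.annot_path)
    return inputs


def arrangements_from_mshsbs(
    mshsbs: Sequence[synteny.MsHSB], block_subset: frozenset[int] | None = None
) -> dict[str, GenomeArrangement]:
    """Express each species as signed msHSB orders per target chromosome."""
    if not mshsbs:
        raise ValueError("no msHSBs")
    species = sorted(mshsbs[0].placements)
    out: dict[str, GenomeArrangement] = {}
    for sp in species:
        placed = []
        for hsb in mshsbs:
            if block_subset is not None and hsb.id not in block_subset:
                continue
            tchrom, tlo, thi, strand = hsb.placements[sp]
            placed.append((tchrom, tlo, hsb.id * strand))
        placed.sort()
        chroms: dict[str, list[int]] = {}
        for tchrom, _, signed in placed:
            chroms.setdefault(tchrom, []).append(signed)
        out[sp] = GenomeArrangement.from_lists(sp, [chroms[c] for c in sorted(chroms)])
    return out


def _resolve_groups(
    cfg: PipelineConfig, mshsbs: Sequence[synteny.MsHSB]
) -> dict[str, tuple[frozenset[int], str]]:
    """Map each configured chromosome group to its msHSB-id subset and outgroup."""
    if not cfg.chromosome_groups:
        return {"all": (frozenset(h.id for h in mshsbs), cfg.outgroup)}
    groups = {}
    for label, (chrom_list, outgroup) in cfg.chromosome_groups.items():
        if chrom_list is None:
            ids = frozenset(h.id for h in mshsbs)
        else:
            ids = frozenset(h.id for h in mshsbs if h.ref_chrom in set(chrom_list))
        groups[label] = (ids, outgroup)
    return groups


def run_full_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> ReportBundle:
    """Execute every applicable stage; returns (and optionally writes) the bundle."""
    bundle = ReportBundle()
    bundle.meta = {"seed": cfg.seed, "config_hash": cfg.config_hash()}
    inputs = load_inputs(cfg)

    # --- correlation (always available: packaged karyotype fallback) -----
    try:
        corr = breakpoint_stats.chromnum_correlation(
            inputs.karyotype, exclude=cfg.exclude_species, y_column=cfg.y_column
        )
        bundle.correlation = dataclasses.asdict(corr)
    except Exception as exc:  # noqa: BLE001
        raise StageError("correlation", exc) from exc

    if inputs.annotations:
        try:
            results = enrichment.enrich_all(
                inputs.annotations, cfg.alpha, cfg.fdr, scope=cfg.fdr_scope
            )
            bundle.enrichment = pd.DataFrame([dataclasses.asdict(r) for r in results])
        except Exception as exc:  # noqa: BLE001
            raise StageError("enrichment", exc) from exc

    blocks = inputs.blocks_by_species
    if not blocks:
        log.info("no synteny inputs: correlation/enrichment-only mode")
        if out_dir is not None:
            write_outputs(bundle, out_dir)
        return bundle

    try:
        filtered = {
            sp: synteny.filter_by_resolution(bl, cfg.resolution) for sp, bl in blocks.items()
        }
        mshsbs = synteny.build_mshsbs(filtered, cfg.resolution, cfg.resolution)
        log.info("built %d msHSBs from %d species", len(mshsbs), len(filtered))
    except Exception as exc:  # noqa: BLE001
        raise StageError("mshsb", exc) from exc

    try:
        ebrs = synteny.call_ebrs(filtered, gap_max=cfg.resolution)
        ebrs = synteny.classify_lineage_specificity(ebrs, set(filtered))
    except Exception as exc:  # noqa: BLE001
        raise StageError("ebr", exc) from exc

    event_rows, ancestor_rows = [], []
    reuse_reports = {}
    try:
        groups = _resolve_groups(cfg, mshsbs)
        for label, (ids, outgroup) in sorted(groups.items()):
            if not ids:
                continue
            arrs = arrangements_from_mshsbs(mshsbs, ids)
            recon = ancestry.reconstruct_ancestors(arrs, inputs.tree, outgroup)
            for node, arr in sorted(recon.node_arrangements.items()):
                for car_i, chrom in enumerate(arr.chromosomes):
                    ancestor_rows.append(
                        {
                            "node": node,
                            "car_index": car_i,
                            "signed_blocks": ",".join(f"{s:+d}" for s in chrom),
                            "group": label,
                        }
                    )
            per_branch = ancestry.branch_scenarios(recon)
            for child in sorted(per_branch):
                for ev in per_branch[child]:
                    event_rows.append(
                        {
                            "branch": child,
                            "step": ev.step,
                            "event_type": ev.event_type,
                            "chroms_involved": len(ev.chroms_involved),
                            "broken_ends": ";".join(
                                f"{b}.{s}" for b, s in sorted(ev.broken_ends)
                            ),
                            "group": label,
                        }
                    )
            lineages = ancestry.lineage_scenarios(recon)
            usage = breakpoint_stats.tally_segment_end_usage(lineages, ids)
            reuse_reports[label] = dataclasses.asdict(
                breakpoint_stats.reuse_report(usage, label)
            )
    except Exception as exc:  # noqa: BLE001
        raise StageError("reconstruction", exc) from exc
    bundle.events = pd.DataFrame(event_rows)
    bundle.ancestors = pd.DataFrame(ancestor_rows)
    bundle.reuse = reuse_reports

    if inputs.markers:
        try:
            chrom_lengths: dict[str, int] = {}
            for bl in blocks.values():
                for b in bl:
                    chrom_lengths[b.ref_chrom] = max(
                        chrom_lengths.get(b.ref_chrom, 0), b.ref_end
                    )
            windows = breakpoint_stats.window_recombination_rates(
                inputs.markers, chrom_lengths, cfg.window_size
            )
            windows = breakpoint_stats.flag_ebr_windows(windows, ebrs, cfg.window_rule)
            assoc = breakpoint_stats.association_test(
                windows, cfg.n_iter, cfg.seed, cfg.direction
            )
            bundle.association = dataclasses.asdict(assoc)
        except Exception as exc:  # noqa: BLE001
            raise StageError("association", exc) from exc

    if out_dir is not None:
        write_outputs(bundle, out_dir)
    return bundle
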