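"""Readers and writers for the external tables the pipeline touches.

All genomic intervals are held internally as 0-based half-open ``[start, end)``
on both reference and target coordinates.  Input files may declare either the
internal convention (``zero_half_open``) or the 1-based fully-closed dialect
common to genome browsers (``one_inclusive``, the default); conversion happens
once, at parse time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd

SYNTENY_COLUMNS = [
    "species",
    "ref_chrom",
    "ref_start",
    "ref_end",
    "target_chrom",
    "target_start",
    "target_end",
    "orientation",
]

KARYOTYPE_COLUMNS = ["species", "haploid_n", "total_interchrom", "micro_interchrom", "micro_ids"]
MAP_COLUMNS = ["species", "chrom", "phys_pos", "gen_pos"]
ANNOT_COLUMNS = ["gene_id", "chrom", "family_id", "terms"]


class ParseError(ValueError):
    """A malformed row in an input table."""


class ValidationError(ValueError):
    """Structurally valid input that violates a domain invariant."""


@dataclass(frozen=True, order=True)
class SyntenyBlock:
    """One orthologous segment of a target genome placed on reference coordinates."""

    species: str
    ref_chrom: str
    ref_start: int
    ref_end: int
    target_chrom: str
    target_start: int
    target_end: int
    orientation: int  # +1 forward, -1 inverted relative to the reference

    def __post_init__(self) -> None:
        if not (0 <= self.ref_start < self.ref_end):
            raise ValidationError(
                f"bad reference interval [{self.ref_start}, {self.ref_end}) "
                f"for {self.species}/{self.ref_chrom}"
            )
        if not (0 <= self.target_start < self.target_end):
            raise ValidationError(
                f"bad target interval [{self.target_start}, {self.target_end}) "
                f"for {self.species}/{self.target_chrom}"
            )
        if self.orientation not in (1, -1):
            raise ValidationError(f"orientation must be +-1, got {self.orientation!r}")

    @property
    def ref_len(self) -> int:
        return self.ref_end - self.ref_start


@dataclass(frozen=True)
class KaryotypeInfo:
    """Per-species karyotype facts: haploid count and interchromosomal-change tallies.

    ``haploid_n`` is ``None`` when no chromosome number has been published for
    the species (shown as "?" in the source table).
    """

    species: str
    haploid_n: int | None
    total_interchrom: int = 0
    micro_interchrom: int = 0
    micro_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.haploid_n is not None and self.haploid_n <= 0:
            raise ValidationError(f"haploid_n must be positive for {self.species}")


@dataclass(frozen=True, order=True)
class GeneticMapMarker:
    species: str
    chrom: str
    phys_pos: int
    gen_pos: float


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chrom: str
    family_id: str
    terms: frozenset[str] = frozenset()


class PhyloTree:
    """A rooted, fully branch-length-annotated species tree (lengths in MY)."""

    def __init__(self, tree: dendropy.Tree):
        root = tree.seed_node
        if len(root.child_nodes()) != 2:
            raise ValidationError("tree must be rooted (binary root)")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is root:
                continue
            if edge.length is None:
                raise ValidationError("every branch needs a length (MY)")
        self._tree = tree
        self._label_nodes()

    def _label_nodes(self) -> None:
        i = 0
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                node.label = node.taxon.label
            elif not node.label:
                node.label = f"node{i}"
                i += 1

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        tree.is_rooted = True
        return cls(tree)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaves(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def root_label(self) -> str:
        return self._tree.seed_node.label

    def node(self, label: str) -> dendropy.Node:
        for n in self._tree.preorder_node_iter():
            if n.label == label:
                return n
        raise KeyError(f"no node labelled {label!r}")

    def depth(self, label: str) -> float:
        """Path length in MY from the root to the named node."""
        n, d = self.node(label), 0.0
        while n.parent_node is not None:
            d += n.edge.length
            n = n.parent_node
        return d

    def split_depth(self, a: str, b: str) -> float:
        """Time in MY since the two named leaves diverged."""
        mrca = self._tree.mrca(taxon_labels=[a, b])
        return self.depth(a) - self.depth(mrca.label)

    def branches(self) -> list[tuple[str, str, float]]:
        """(parent label, child label, length MY) for every branch, preorder."""
        out = []
        for node in self._tree.preorder_node_iter():
            if node.parent_node is not None:
                out.append((node.parent_node.label, node.label, float(node.edge.length)))
        return out

    def pruned(self, drop: str) -> "PhyloTree":
        """A copy with one leaf removed (unifurcations suppressed)."""
        clone = self._tree.clone(depth=1)
        taxa = [t for t in clone.taxon_namespace if t.label != drop]
        clone.retain_taxa(taxa)
        clone.purge_taxon_namespace()
        return PhyloTree(clone)

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick").strip()


def _convert(start: int, convention: str) -> int:
    if convention == "one_inclusive":
        return start - 1
    if convention == "zero_half_open":
        return start
    raise ValueError(f"unknown coordinate convention {convention!r}")


def _parse_orientation(raw: str) -> int:
    token = str(raw).strip()
    if token in {"+", "1", "+1"}:
        return 1
    if token in {"-", "−", "-1"}:
        return -1
    raise ParseError(f"cannot parse orientation {raw!r}")


def read_synteny_table(path: str | Path, convention: str = "one_inclusive") -> list[SyntenyBlock]:
    """Read a tab-separated pairwise synteny-block table.

    Returns blocks normalised to 0-based half-open coordinates and sorted by
    (species, ref_chrom, ref_start).  Same-species blocks overlapping on the
    reference raise :class:`ValidationError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in SYNTENY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    blocks: list[SyntenyBlock] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        try:
            blocks.append(
                SyntenyBlock(
                    species=str(row.species),
                    ref_chrom=str(row.ref_chrom),
                    ref_start=_convert(int(row.ref_start), convention),
                    ref_end=int(row.ref_end),
                    target_chrom=str(row.target_chrom),
                    target_start=_convert(int(row.target_start), convention),
                    target_end=int(row.target_end),
                    orientation=_parse_orientation(row.orientation),
                )
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                raise
            raise ParseError(f"{path}: line {idx}: {exc}") from exc
    blocks.sort(key=lambda b: (b.species, b.ref_chrom, b.ref_start))
    _check_reference_overlaps(blocks)
    return blocks


def _check_reference_overlaps(blocks: Sequence[SyntenyBlock]) -> None:
    prev: SyntenyBlock | None = None
    for b in blocks:  # sorted by (species, ref_chrom, ref_start)
        if (
            prev is not None
            and prev.species == b.species
            and prev.ref_chrom == b.ref_chrom
            and b.ref_start < prev.ref_end
        ):
            raise ValidationError(
                f"overlapping blocks for {b.species} on {b.ref_chrom}: "
                f"[{prev.ref_start},{prev.ref_end}) and [{b.ref_start},{b.ref_end})"
            )
        prev = b


def write_synteny_table(
    blocks: Iterable[SyntenyBlock], path: str | Path, convention: str = "one_inclusive"
) -> None:
    shift = 1 if convention == "one_inclusive" else 0
    rows = [
        {
            "species": b.species,
            "ref_chrom": b.ref_chrom,
            "ref_start": b.ref_start + shift,
            "ref_end": b.ref_end,
            "target_chrom": b.target_chrom,
            "target_start": b.target_start + shift,
            "target_end": b.target_end,
            "orientation": "+" if b.orientation > 0 else "-",
        }
        for b in sorted(blocks)
    ]
    pd.DataFrame(rows, columns=SYNTENY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_karyotype_table(path: str | Path) -> list[KaryotypeInfo]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in KARYOTYPE_COLUMNS[:2] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        raw_n = str(row.haploid_n).strip()
        haploid = None if raw_n in {"?", "", "nan", "NA"} else int(raw_n)
        micro_raw = str(getattr(row, "micro_ids", "") or "")
        micro = frozenset(m for m in micro_raw.split(";") if m and micro_raw not in {"nan"})
        out.append(
            KaryotypeInfo(
                species=str(row.species),
                haploid_n=haploid,
                total_interchrom=int(getattr(row, "total_interchrom", 0) or 0),
                micro_interchrom=int(getattr(row, "micro_interchrom", 0) or 0),
                micro_ids=micro,
            )
        )
    return out


def read_genetic_map(path: str | Path) -> list[GeneticMapMarker]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    markers = [
        GeneticMapMarker(str(r.species), str(r.chrom), int(r.phys_pos), float(r.gen_pos))
        for r in df.itertuples(index=False)
    ]
    markers.sort(key=lambda m: (m.species, m.chrom, m.phys_pos))
    return markers


def read_annotations(path: str | Path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in ANNOT_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    out = []
    seen: set[str] = set()
    for r in df.itertuples(index=False):
        gid = str(r.gene_id)
        if gid in seen:
            raise ValidationError(f"duplicate gene_id {gid}")
        seen.add(gid)
        terms_raw = str(getattr(r, "terms", "") or "")
        terms = frozenset(t for t in terms_raw.split(";") if t and terms_raw != "nan")
        out.append(GeneAnnotation(gid, str(r.chrom), str(r.family_id), terms))
    return out


def read_aux_tables(
    karyotype_path: str | Path, map_path: str | Path, annot_path: str | Path
) -> tuple[list[KaryotypeInfo], list[GeneticMapMarker], list[GeneAnnotation]]:
    """Load the karyotype, genetic-map and annotation side tables together."""
    karyo = read_karyotype_table(karyotype_path)
    markers = read_genetic_map(map_path)
    annots = read_annotations(annot_path)
    known = {k.species for k in karyo}
    strays = {m.species for m in markers} - known
    if strays:
        warnings.warn(f"genetic map references species absent from karyotype: {sorted(strays)}")
    return karyo, markers, annots


def read_tree(path: str | Path) -> PhyloTree:
    """Read a rooted Newick tree with branch lengths in million years."""
    return PhyloTree.from_newick(Path(path).read_text())


def packaged_karyotype() -> list[KaryotypeInfo]:
    """The bundled 21-species avian karyotype/interchromosomal-change table."""
    with resources.as_file(resources.files("karyograph.data") / "avian_karyotype.tsv") as p:
        return read_karyotype_table(p)


def packaged_tree() -> PhyloTree:
    """The default six-species avian tree (splits at 100/65/54/30 MY)."""
    text = (resources.files("karyograph.data") / "avian_tree.nwk").read_text()
    return PhyloTree.from_newick(text)


@dataclass
class ReportBundle:
    """Everything the pipeline writes: tables as DataFrames, statistics as dicts."""

    events: pd.DataFrame = field(default_factory=pd.DataFrame)
    ancestors: pd.DataFrame = field(default_factory=pd.DataFrame)
    enrichment: pd.DataFrame = field(default_factory=pd.DataFrame)
    reuse: dict = field(default_factory=dict)
    association: dict = field(default_factory=dict)
    correlation: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


_EVENT_COLS = ["branch", "step", "event_type", "chroms_involved", "broken_ends"]
_ANCESTOR_COLS = ["node", "car_index", "signed_blocks"]
_ENRICH_COLS = ["chrom", "term", "k", "K", "m", "M", "p", "q", "tier"]


def write_outputs(bundle: ReportBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the deterministic report file set; byte-identical for equal bundles."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _tsv(name: str, df: pd.DataFrame, cols: list[str]) -> None:
        frame = df if not df.empty else pd.DataFrame(columns=cols)
        frame.to_csv(out / name, sep="\t", index=False)
        paths[name] = out / name

    def _json(name: str, payload: dict) -> None:
        payload = dict(payload)
        payload.setdefault("meta", bundle.meta)
        (out / name).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        paths[name] = out / name

    _tsv("events.tsv", bundle.events, _EVENT_COLS)
    _tsv("ancestors.tsv", bundle.ancestors, _ANCESTOR_COLS)
    _tsv("enrichment.tsv", bundle.enrichment, _ENRICH_COLS)
    _json("reuse.json", bundle.reuse)
    _json("association.json", bundle.association)
    _json("correlation.json", bundle.correlation)
    return paths
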