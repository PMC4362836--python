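"""Resolution filtering, multispecies HSB intersection and EBR calling.

An msHSB (multispecies homologous synteny block) is a reference interval that
is orthologous, contiguous and consistently oriented in *every* compared
species; msHSBs are the atomic units on which ancestral karyotypes are
reconstructed.  An EBR (evolutionary breakpoint region) is the reference gap
between two blocks of one species that are not contiguous in that species'
genome — intrachromosomal when both flanks map to one target chromosome,
interchromosomal otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .genome_io import SyntenyBlock, ValidationError

DEFAULT_RESOLUTION = 300_000  # bp, minimum block length on the reference


@dataclass(frozen=True)
class MsHSB:
    """A reference interval orthologous in all compared species."""

    id: int
    ref_chrom: str
    ref_start: int
    ref_end: int
    placements: Mapping[str, tuple[str, int, int, int]]  # species -> (chrom, start, end, strand)

    @property
    def ref_len(self) -> int:
        return self.ref_end - self.ref_start


@dataclass(frozen=True)
class EBRecord:
    """A breakpoint interval between two reference-adjacent blocks of a species."""

    species: str
    ref_chrom: str
    start: int
    end: int  # start == end encodes a zero-width breakpoint
    ebr_class: str  # 'intrachromosomal' | 'interchromosomal'
    lineage_specific: bool = False

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


def filter_by_resolution(
    blocks: Sequence[SyntenyBlock], min_len: int = DEFAULT_RESOLUTION
) -> list[SyntenyBlock]:
    """Keep blocks spanning at least ``min_len`` bp on the reference (inclusive)."""
    if min_len <= 0:
        raise ValueError("min_len must be positive")
    return [b for b in blocks if b.ref_len >= min_len]


def _interp_target(block: SyntenyBlock, ref_lo: int, ref_hi: int) -> tuple[str, int, int, int]:
    """Project a reference sub-interval of a block into target coordinates.

    Positions are scaled linearly; a negatively-oriented block maps the start
    of the reference sub-interval to the *end* of the target image.
    """
    scale = (block.target_end - block.target_start) / block.ref_len
    off_lo = round((ref_lo - block.ref_start) * scale)
    off_hi = round((ref_hi - block.ref_start) * scale)
    if block.orientation > 0:
        t_lo = block.target_start + off_lo
        t_hi = block.target_start + off_hi
    else:
        t_lo = block.target_end - off_hi
        t_hi = block.target_end - off_lo
    return (block.target_chrom, t_lo, max(t_hi, t_lo + 1), block.orientation)


def build_mshsbs(
    blocks_by_species: Mapping[str, Sequence[SyntenyBlock]],
    min_len: int = DEFAULT_RESOLUTION,
    merge_gap: int = DEFAULT_RESOLUTION,
) -> list[MsHSB]:
    """Intersect per-species block maps into msHSBs.

    The reference line is cut at the union of all species' block boundaries;
    segments covered in every species survive; adjacent segments whose
    per-species context is identical (same target chromosome, same
    orientation, target-contiguous within ``merge_gap``) are merged; merged
    segments shorter than ``min_len`` are dropped.  Ids are assigned in
    reference order, 1-based.
    """
    species = sorted(blocks_by_species)
    if not species:
        raise ValidationError("no species given")
    for sp in species:
        if not blocks_by_species[sp]:
            raise ValidationError(f"species {sp!r} has no blocks; msHSBs undefined")

    by_chrom: dict[str, dict[str, list[SyntenyBlock]]] = {}
    for sp in species:
        for b in blocks_by_species[sp]:
            by_chrom.setdefault(b.ref_chrom, {}).setdefault(sp, []).append(b)

    segments: list[tuple[str, int, int, dict[str, tuple[str, int, int, int]]]] = []
    for chrom in sorted(by_chrom):
        chrom_blocks = by_chrom[chrom]
        if set(chrom_blocks) != set(species):
            continue  # some species has nothing on this reference chromosome
        cuts = sorted(
            {b.ref_start for bl in chrom_blocks.values() for b in bl}
            | {b.ref_end for bl in chrom_blocks.values() for b in bl}
        )
        for lo, hi in zip(cuts, cuts[1:]):
            placement: dict[str, tuple[str, int, int, int]] = {}
            for sp in species:
                hit = next(
                    (b for b in chrom_blocks[sp] if b.ref_start <= lo and hi <= b.ref_end),
                    None,
                )
                if hit is None:
                    break
                placement[sp] = _interp_target(hit, lo, hi)
            else:
                segments.append((chrom, lo, hi, placement))

    merged: list[tuple[str, int, int, dict[str, tuple[str, int, int, int]]]] = []
    for chrom, lo, hi, placement in segments:
        if merged and _mergeable(merged[-1], (chrom, lo, hi, placement), merge_gap):
            pchrom, plo, _, pplace = merged[-1]
            fused = {
                sp: _fuse_placement(pplace[sp], placement[sp]) for sp in placement
            }
            merged[-1] = (pchrom, plo, hi, fused)
        else:
            merged.append((chrom, lo, hi, placement))

    out = []
    for chrom, lo, hi, placement in merged:
        if hi - lo < min_len:
            continue
        out.append(MsHSB(len(out) + 1, chrom, lo, hi, placement))
    return out


def _mergeable(prev, cur, merge_gap: int) -> bool:
    pchrom, _, phi, pplace = prev
    chrom, lo, _, place = cur
    if chrom != pchrom or lo != phi:
        return False
    for sp, (tchrom, tlo, thi, strand) in place.items():
        ptchrom, ptlo, pthi, pstrand = pplace[sp]
        if tchrom != ptchrom or strand != pstrand:
            return False
        # target contiguity in reading order: + strand continues rightwards
        gap = (tlo - pthi) if strand > 0 else (ptlo - thi)
        if not (-merge_gap <= gap <= merge_gap):
            return False
    return True


def _fuse_placement(prev, cur):
    tchrom, tlo, thi, strand = cur
    _, ptlo, pthi, _ = prev
    return (tchrom, min(ptlo, tlo), max(pthi, thi), strand)


def mshsbs_as_blocks(mshsbs: Sequence[MsHSB]) -> dict[str, list[SyntenyBlock]]:
    """Re-express msHSB placements as per-species synteny blocks (for fixed-point
    checks and downstream EBR calling on the intersected map)."""
    out: dict[str, list[SyntenyBlock]] = {}
    for hsb in mshsbs:
        for sp, (tchrom, tlo, thi, strand) in hsb.placements.items():
            out.setdefault(sp, []).append(
                SyntenyBlock(
                    species=sp,
                    ref_chrom=hsb.ref_chrom,
                    ref_start=hsb.ref_start,
                    ref_end=hsb.ref_end,
                    target_chrom=tchrom,
                    target_start=tlo,
                    target_end=thi,
                    orientation=strand,
                )
            )
    for sp in out:
        out[sp].sort(key=lambda b: (b.ref_chrom, b.ref_start))
    return out


def call_ebrs(
    blocks_by_species: Mapping[str, Sequence[SyntenyBlock]],
    gap_max: int = DEFAULT_RESOLUTION,
) -> list[EBRecord]:
    """Call breakpoint intervals between reference-adjacent blocks per species.

    Adjacent blocks on different target chromosomes delimit an interchromosomal
    EBR; same target chromosome but orientation flip or target-order
    discontinuity (gap beyond ``gap_max`` or order reversal) an intrachromosomal
    one.  The EBR interval is the reference gap between the flanks (zero-width
    allowed).
    """
    out: list[EBRecord] = []
    for sp in sorted(blocks_by_species):
        blocks = sorted(blocks_by_species[sp], key=lambda b: (b.ref_chrom, b.ref_start))
        for a, b in zip(blocks, blocks[1:]):
            if a.ref_chrom != b.ref_chrom:
                continue
            cls = _classify_gap(a, b, gap_max)
            if cls is None:
                continue
            out.append(EBRecord(sp, a.ref_chrom, a.ref_end, b.ref_start, cls))
    return out


def _classify_gap(a: SyntenyBlock, b: SyntenyBlock, gap_max: int) -> str | None:
    if a.target_chrom != b.target_chrom:
        return "interchromosomal"
    if a.orientation != b.orientation:
        return "intrachromosomal"
    # same chromosome, same strand: check reading-order continuity
    gap = (b.target_start - a.target_end) if a.orientation > 0 else (a.target_start - b.target_end)
    if gap < -gap_max or gap > gap_max:
        return "intrachromosomal"
    return None


def classify_lineage_specificity(
    ebrs: Sequence[EBRecord],
    species_set: set[str] | frozenset[str],
    overlap_frac: float = 0.0,
) -> list[EBRecord]:
    """Mark EBRs private to one lineage.

    An EBR is lineage-specific when no EBR of another species reciprocally
    overlaps it on the reference by at least ``overlap_frac`` of each interval
    (the default 0 demands any shared base pair, with zero-width intervals
    treated as points; abutting intervals do not overlap).
    """
    if len(species_set) < 2:
        raise ValidationError("need at least two species to assess specificity")
    out = []
    for e in ebrs:
        specific = True
        for f in ebrs:
            if f.species == e.species or f.ref_chrom != e.ref_chrom:
                continue
            if _reciprocal_overlap(e, f, overlap_frac):
                specific = False
                break
        out.append(replace(e, lineage_specific=specific))
    return out


def _reciprocal_overlap(e: EBRecord, f: EBRecord, frac: float) -> bool:
    lo = max(e.start, f.start)
    hi = min(e.end, f.end)
    if hi < lo:
        return False
    if hi == lo:
        # touching without shared extent: counts only when a zero-width
        # breakpoint lies on/inside the other interval (abutting proper
        # intervals stay distinct)
        return e.start == e.end or f.start == f.end
    if frac <= 0:
        return True
    return (hi - lo) >= frac * (e.end - e.start) and (hi - lo) >= frac * (f.end - f.start)
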