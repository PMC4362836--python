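"""Breakpoint-reuse tallies, EBR-recombination association and karyotype
correlation.

Segment ends are block extremities (two per block).  A segment end is
*involved* when at least one rearrangement breaks it on some lineage's path
from the ancestor; it is *reused* when broken more than once in one lineage or
broken in two or more lineages.

Recombination rates come from a genetic map as cM/Mb in non-overlapping 1 Mb
windows; windows are flagged when an EBR falls in them, and the two classes
are compared by Wilcoxon's rank-sum test with continuity correction plus a
randomisation test that redraws the flagged class size from all windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .genome_io import GeneticMapMarker, KaryotypeInfo, ValidationError
from .rearrangement import EventRecord, Extremity
from .synteny import EBRecord

WINDOW_SIZE = 1_000_000  # bp
DEFAULT_N_ITER = 10_000


@dataclass(frozen=True)
class ReuseReport:
    chromosome_group: str
    total_segment_ends: int
    ends_involved: int
    reused_across_lineages: int
    reused_any: int
    pct_across: float | None
    pct_any: float | None


@dataclass(frozen=True)
class RecombWindow:
    chrom: str
    start: int
    end: int
    rate: float | None
    has_ebr: bool = False


@dataclass(frozen=True)
class AssocResult:
    n_with: int
    n_without: int
    mean_with: float
    sd_with: float
    mean_without: float
    sd_without: float
    wilcoxon_W: float
    wilcoxon_p: float
    perm_diff: float
    perm_p: float
    n_iter: int
    seed: int


@dataclass(frozen=True)
class CorrelationResult:
    n: int
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    excluded: tuple[str, ...]


def tally_segment_end_usage(
    scenarios: Mapping[str, Sequence[EventRecord]],
    block_set: frozenset[int] | set[int],
) -> dict[Extremity, dict[str, int]]:
    """Count, per extremity and lineage, how often it flanks a breakpoint."""
    usage: dict[Extremity, dict[str, int]] = {
        (bid, side): {} for bid in sorted(block_set) for side in ("t", "h")
    }
    for lineage in sorted(scenarios):
        for ev in scenarios[lineage]:
            for ext in ev.broken_ends:
                if ext not in usage:
                    raise ValidationError(f"event references unknown extremity {ext}")
                usage[ext][lineage] = usage[ext].get(lineage, 0) + 1
    return usage


def reuse_report(
    usage: Mapping[Extremity, Mapping[str, int]], group_label: str = "all"
) -> ReuseReport:
    """Summarise segment-end involvement and reuse for one chromosome group."""
    total = len(usage)
    involved = across = any_reuse = 0
    for counts in usage.values():
        tot = sum(counts.values())
        if tot == 0:
            continue
        involved += 1
        multi_lineage = len(counts) >= 2
        if multi_lineage:
            across += 1
        if multi_lineage or max(counts.values()) >= 2:
            any_reuse += 1
    if involved:
        pct_across = round(100 * across / involved, 1)
        pct_any = round(100 * any_reuse / involved, 1)
    else:
        pct_across = pct_any = None
    return ReuseReport(group_label, total, involved, across, any_reuse, pct_across, pct_any)


def reuse_report_from_counts(
    group_label: str, total_ends: int, involved: int, across: int, any_reuse: int
) -> ReuseReport:
    """Build a report directly from published tallies (percentage rule only)."""
    if not (across <= any_reuse <= involved <= total_ends):
        raise ValidationError("reuse counts violate the monotonicity chain")
    pct_across = round(100 * across / involved, 1) if involved else None
    pct_any = round(100 * any_reuse / involved, 1) if involved else None
    return ReuseReport(group_label, total_ends, involved, across, any_reuse, pct_across, pct_any)


def window_recombination_rates(
    markers: Sequence[GeneticMapMarker],
    chrom_lengths: Mapping[str, int],
    window: int = WINDOW_SIZE,
) -> list[RecombWindow]:
    """Per-window cM/Mb rates by linear interpolation of the genetic map.

    Genetic positions at window boundaries are interpolated between flanking
    markers; windows not fully inside the marker span get no rate.  Decreasing
    genetic positions are clamped isotonically (with a warning).
    """
    out: list[RecombWindow] = []
    by_chrom: dict[str, list[GeneticMapMarker]] = {}
    for m in markers:
        by_chrom.setdefault(m.chrom, []).append(m)
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        ms = sorted(by_chrom.get(chrom, []), key=lambda m: m.phys_pos)
        phys = np.array([m.phys_pos for m in ms], dtype=float)
        gen = np.array([m.gen_pos for m in ms], dtype=float)
        if gen.size and np.any(np.diff(gen) < 0):
            warnings.warn(f"non-monotone genetic positions on {chrom}; clamping")
            gen = np.maximum.accumulate(gen)
        starts = np.arange(0, length, window)
        for s in starts:
            e = min(s + window, length)
            if phys.size < 2 or s < phys[0] or e > phys[-1]:
                rate = None
            else:
                g0, g1 = np.interp([s, e], phys, gen)
                rate = float((g1 - g0) / ((e - s) / 1e6))
            out.append(RecombWindow(chrom, int(s), int(e), rate))
    return out


def flag_ebr_windows(
    windows: Sequence[RecombWindow],
    ebrs: Sequence[EBRecord],
    rule: str = "midpoint",
) -> list[RecombWindow]:
    """Flag windows containing EBRs.

    ``midpoint`` (default) flags the window holding an EBR's midpoint under
    the half-open convention; ``any_overlap`` flags every window an EBR
    interval touches (zero-width EBRs flag the window containing their point).
    """
    if rule not in {"midpoint", "any_overlap"}:
        raise ValueError(f"unknown rule {rule!r}")
    flagged_idx: set[int] = set()
    for i, w in enumerate(windows):
        for e in ebrs:
            if e.ref_chrom != w.chrom:
                continue
            if rule == "midpoint":
                if w.start <= e.midpoint < w.end:
                    flagged_idx.add(i)
                    break
            else:
                if e.start < w.end and e.end > w.start or (
                    e.start == e.end and w.start <= e.start < w.end
                ):
                    flagged_idx.add(i)
                    break
    return [replace(w, has_ebr=(i in flagged_idx)) for i, w in enumerate(windows)]


def association_test(
    windows: Sequence[RecombWindow],
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
    direction: str = "greater",
) -> AssocResult:
    """EBR-window vs background recombination comparison.

    Two-sided Wilcoxon rank-sum test with continuity correction, plus a
    randomisation test drawing ``|flagged|`` windows without replacement
    ``n_iter`` times and locating the observed flagged-class mean in the
    resampled means (one-sided, ``direction``-ward).
    """
    rated = [w for w in windows if w.rate is not None]
    with_rates = np.array([w.rate for w in rated if w.has_ebr], dtype=float)
    without_rates = np.array([w.rate for w in rated if not w.has_ebr], dtype=float)
    if with_rates.size == 0:
        raise ValidationError("no rated windows carry an EBR flag")
    if without_rates.size == 0:
        raise ValidationError("no rated windows without an EBR flag")
    # normal approximation with continuity correction (the R wilcox.test path
    # for the window counts this analysis sees)
    wres = stats.mannwhitneyu(
        with_rates,
        without_rates,
        use_continuity=True,
        alternative="two-sided",
        method="asymptotic",
    )
    all_rates = np.concatenate([with_rates, without_rates])
    k = with_rates.size
    rng = np.random.default_rng(seed)
    keys = rng.random((n_iter, all_rates.size))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    sampled_means = all_rates[idx].mean(axis=1)
    obs = float(with_rates.mean())
    if direction == "greater":
        perm_p = float(np.mean(sampled_means >= obs))
    elif direction == "less":
        perm_p = float(np.mean(sampled_means <= obs))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return AssocResult(
        n_with=int(with_rates.size),
        n_without=int(without_rates.size),
        mean_with=obs,
        sd_with=float(with_rates.std(ddof=1)) if with_rates.size > 1 else 0.0,
        mean_without=float(without_rates.mean()),
        sd_without=float(without_rates.std(ddof=1)) if without_rates.size > 1 else 0.0,
        wilcoxon_W=float(wres.statistic),
        wilcoxon_p=float(wres.pvalue),
        perm_diff=obs - float(without_rates.mean()),
        perm_p=perm_p,
        n_iter=n_iter,
        seed=seed,
    )


def chromnum_correlation(
    karyotype: Sequence[KaryotypeInfo],
    changes: Mapping[str, int] | None = None,
    exclude: Sequence[str] = (),
    baseline_n: int = 40,
    y_column: str = "total_interchrom",
) -> CorrelationResult:
    """OLS of interchromosomal-change counts on deviation from ``n = 40``.

    Species without a published haploid number are silently excluded, as are
    the names in ``exclude``.  ``changes`` overrides the change counts carried
    on the karyotype rows; otherwise ``y_column`` selects the total (macro and
    micro) or micro-only column.
    """
    pairs = []
    dropped = set(exclude)
    for k in karyotype:
        if k.species in dropped or k.haploid_n is None:
            continue
        if changes is not None:
            if k.species not in changes:
                continue
            y = changes[k.species]
        else:
            y = getattr(k, y_column)
        pairs.append((abs(k.haploid_n - baseline_n), float(y)))
    if len(pairs) < 3:
        raise ValidationError("need at least three species with published haploid numbers")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    res = stats.linregress(x, y)
    return CorrelationResult(
        n=len(pairs),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        excluded=tuple(sorted(dropped)),
    )
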