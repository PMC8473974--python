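"""Genome binning, pairwise LD, greedy r² grouping and density-balanced
probe selection — the core of the panel design.

The genome is tiled into fixed 100-kb bins (0-based half-open).  Within a
bin, sites are clustered by a greedy tagging pass: the unassigned site
with the highest MAF becomes a representative and captures every
unassigned site whose genotype-dosage r² with it reaches the threshold
(0.65).  The panel then takes, per bin, up to five design-eligible sites,
preferring one per LD group and the highest MAFs, with the per-bin target
raised inside QTL windows and a global 200-bp spacing pass at the end.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .filtering import enforce_min_spacing, minor_allele_frequency
from .io import Genome, GenomeIndex, Interval, ProbeManifest, ProbeRecord, VariantSite

BIN_SIZE = 100_000


@dataclass(frozen=True)
class GenomeBin:
    """One 100-kb genome tile, [start, end) 0-based half-open."""

    chrom: str
    index: int
    start: int
    end: int

    @property
    def bin_id(self) -> str:
        return f"{self.chrom}:{self.index}"


@dataclass
class LDGroup:
    """Sites of one bin mutually tagged by a representative at r² >= t."""

    group_id: str
    bin_id: str
    representative: str
    members: list[str]


@dataclass(frozen=True)
class SelectionParams:
    min_per_bin: int = 1
    max_per_bin: int = 5
    qtl_probes: int = 3
    qtl_window: int = 150_000  # up- and downstream of each QTL interval
    design_score_min: float = 0.6
    ld_threshold: float = 0.65
    bin_size: int = BIN_SIZE
    min_probe_spacing: int = 200


@dataclass
class PanelStats:
    n_probes: int
    per_chromosome: dict[str, int]
    gaps: list[int]
    mean_gap: float
    frac_gaps_gt_100kb: float


def partition_bins(genome: GenomeIndex, bin_size: int = BIN_SIZE) -> list[GenomeBin]:
    """Tile every chromosome with half-open bins; the last may be short."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    bins: list[GenomeBin] = []
    for chrom, length in genome.lengths.items():
        n = -(-length // bin_size)
        for i in range(n):
            bins.append(
                GenomeBin(chrom, i, i * bin_size, min((i + 1) * bin_size, length))
            )
    return bins


def bin_index_of(pos: int, bin_size: int = BIN_SIZE) -> int:
    """Bin index of a 1-based position under the half-open tiling."""
    return (pos - 1) // bin_size


def r_squared(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation of allele dosages over pairwise-complete
    samples — the standard phase-free LD estimate from called genotypes.

    Raises on fewer than two complete pairs or zero variance at either
    site (r² undefined for a monomorphic site).
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2:
        raise ValueError("need >= 2 pairwise-complete samples")
    a, b = a[ok], b[ok]
    va = a.var()
    vb = b.var()
    if va == 0.0 or vb == 0.0:
        raise ValueError("r^2 undefined: zero variance at a site")
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(cov * cov / (va * vb))


def _r_squared_vector(target: np.ndarray, others: np.ndarray) -> np.ndarray:
    """r² of one dosage vector against each row of ``others`` (NaN-aware).

    Pairs with zero variance yield NaN (treated as below any threshold).
    """
    out = np.empty(others.shape[0])
    for i in range(others.shape[0]):
        a, b = target, others[i]
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 2:
            out[i] = np.nan
            continue
        aa, bb = a[ok], b[ok]
        va, vb = aa.var(), bb.var()
        if va == 0.0 or vb == 0.0:
            out[i] = np.nan
            continue
        cov = ((aa - aa.mean()) * (bb - bb.mean())).mean()
        out[i] = cov * cov / (va * vb)
    return out


def greedy_ld_group(
    sites_in_bin: Sequence[VariantSite],
    threshold: float = 0.65,
    bin_id: str = "",
) -> list[LDGroup]:
    """Greedy star partition of one bin's sites.

    Iteratively the unassigned site with the highest MAF (ties to the
    smallest position) becomes a representative; every unassigned site
    with r² >= threshold to it joins the group.  Deterministic, and a
    partition by construction.
    """
    sites = list(sites_in_bin)
    if not sites:
        return []
    dosages = np.array([s.alt_dosage() for s in sites])
    mafs = np.array([minor_allele_frequency(s) for s in sites])
    positions = np.array([s.pos for s in sites])
    unassigned = np.ones(len(sites), dtype=bool)
    groups: list[LDGroup] = []
    order = np.lexsort((positions, -mafs))  # MAF desc, then position asc
    for rep in order:
        if not unassigned[rep]:
            continue
        idx = np.flatnonzero(unassigned)
        r2 = _r_squared_vector(dosages[rep], dosages[idx])
        member_idx = idx[(np.nan_to_num(r2, nan=-1.0) >= threshold) | (idx == rep)]
        unassigned[member_idx] = False
        rep_site = sites[rep]
        groups.append(
            LDGroup(
                group_id=f"{bin_id}:g{len(groups)}",
                bin_id=bin_id,
                representative=site_id(rep_site),
                members=[site_id(sites[i]) for i in member_idx],
            )
        )
    return groups


def site_id(site: VariantSite) -> str:
    return f"{site.chrom}_{site.pos}"


# ---------------------------------------------------------------------------
# design score


_HOMOPOLYMER = re.compile(r"A{6,}|C{6,}|G{6,}|T{6,}")


def design_score_surrogate(flank5: str, snp: str, flank3: str) -> float:
    """Deterministic assay-design heuristic on the probe context, in [0,1].

    Start at 1.0; subtract 0.2 when GC of the context is outside
    [0.30, 0.70]; subtract 0.2 per disjoint 6-bp homopolymer stretch
    (a maximal run of length L counts L // 6 times, so longer runs are
    penalized proportionally); subtract 0.5 when any ambiguity character
    is present; floor at 0.
    """
    seq = (flank5 + snp + flank3).upper()
    score = 1.0
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    if not (0.30 <= gc <= 0.70):
        score -= 0.2
    score -= 0.2 * sum(len(run) // 6 for run in _HOMOPOLYMER.findall(seq))
    if any(c not in "ACGT" for c in seq):
        score -= 0.5
    return max(0.0, score)


# ---------------------------------------------------------------------------
# panel selection


def select_panel(
    candidates: Sequence[VariantSite],
    groups: Sequence[LDGroup],
    bins: Sequence[GenomeBin],
    qtl_intervals: Sequence[Interval] = (),
    params: SelectionParams = SelectionParams(),
    design_scores: dict[str, float] | None = None,
) -> tuple[ProbeManifest, list[str]]:
    """Density-balanced probe selection.

    Per bin the target count is min(max_per_bin, number of eligible LD
    groups), at least min_per_bin, raised to ``qtl_probes`` when the bin
    overlaps a QTL interval widened by ``qtl_window`` on both sides.
    Eligible sites (design score >= threshold) are taken by MAF descending
    (ties to smaller position), at most one per LD group until every
    eligible group in the bin is represented, then recycled.  A final
    global spacing pass (gap > min_probe_spacing, higher MAF wins) is
    applied.  Returns (manifest, ids of bins left uncovered).
    """
    if design_scores is None:
        design_scores = {
            site_id(s): design_score_surrogate(s.flank5 or "", s.ref, s.flank3 or "")
            for s in candidates
        }
    group_of: dict[str, str] = {}
    for g in groups:
        for m in g.members:
            group_of[m] = g.group_id

    by_bin: dict[str, list[VariantSite]] = {}
    for s in candidates:
        b = f"{s.chrom}:{bin_index_of(s.pos, params.bin_size)}"
        by_bin.setdefault(b, []).append(s)

    qtl_bins: set[str] = set()
    for iv in qtl_intervals:
        lo = max(0, iv.start - params.qtl_window)
        hi = iv.end + params.qtl_window
        for b in bins:
            if b.chrom == iv.chrom and b.start < hi and b.end > lo:
                qtl_bins.add(b.bin_id)

    chosen: list[tuple[VariantSite, str, str, str]] = []  # site, group, bin, category
    uncovered: list[str] = []
    for b in bins:
        members = by_bin.get(b.bin_id, [])
        eligible = [
            s for s in members if design_scores.get(site_id(s), 0.0) >= params.design_score_min
        ]
        if not eligible:
            uncovered.append(b.bin_id)
            continue
        eligible.sort(key=lambda s: (-minor_allele_frequency(s), s.pos))
        n_groups = len({group_of.get(site_id(s), site_id(s)) for s in eligible})
        target = min(params.max_per_bin, max(params.min_per_bin, n_groups))
        if b.bin_id in qtl_bins:
            target = max(target, params.qtl_probes)
        target = min(target, len(eligible))
        used_groups: set[str] = set()
        picked: list[VariantSite] = []
        for s in eligible:  # first pass: one per group
            if len(picked) >= target:
                break
            gid = group_of.get(site_id(s), site_id(s))
            if gid in used_groups:
                continue
            used_groups.add(gid)
            picked.append(s)
        if len(picked) < target:  # groups exhausted: recycle by MAF
            rest = [s for s in eligible if s not in picked]
            picked.extend(rest[: target - len(picked)])
        category = "qtl" if b.bin_id in qtl_bins else "background"
        for s in picked:
            chosen.append((s, group_of.get(site_id(s), site_id(s)), b.bin_id, category))

    chosen.sort(key=lambda t: (t[0].chrom, t[0].pos))
    spaced = enforce_min_spacing(
        chosen,
        params.min_probe_spacing,
        priority_key=lambda t: (-minor_allele_frequency(t[0]), t[0].pos),
        chrom_of=lambda t: t[0].chrom,
        pos_of=lambda t: t[0].pos,
    )
    records = [
        ProbeRecord(
            marker_id=site_id(s),
            chrom=s.chrom,
            pos=s.pos,
            ref=s.ref,
            alt=s.alts[0] if s.alts else ".",
            flank5=s.flank5 or "",
            flank3=s.flank3 or "",
            design_score=design_scores.get(site_id(s), 0.0),
            category=category,
            ld_group_id=gid,
            bin_id=bin_id,
        )
        for s, gid, bin_id, category in spaced
    ]
    manifest = ProbeManifest(records, metadata={"bin_size": str(params.bin_size)})
    return manifest, uncovered


def validate_panel(
    manifest: ProbeManifest,
    params: SelectionParams = SelectionParams(),
    groups: Sequence[LDGroup] | None = None,
) -> list[str]:
    """Independent re-check of an emitted manifest.

    Verifies the score threshold, the per-bin cap (max_per_bin, or
    qtl_probes for QTL-boosted bins), pairwise spacing, and — when groups
    are supplied — the one-per-group preference (a group is reused only in
    a bin whose eligible groups are all already represented, which the
    checker approximates as: duplicates allowed only in bins at their
    target count).  Returns a list of violation messages (empty = valid).
    """
    problems: list[str] = []
    per_bin: dict[str, list[ProbeRecord]] = {}
    for r in manifest.records:
        per_bin.setdefault(r.bin_id, []).append(r)
        if r.design_score < params.design_score_min:
            problems.append(f"{r.marker_id}: design score {r.design_score} below minimum")
    for bin_id, recs in per_bin.items():
        cap = max(params.max_per_bin, params.qtl_probes)
        if len(recs) > cap:
            problems.append(f"bin {bin_id}: {len(recs)} probes exceeds cap {cap}")
        if groups is not None:
            gids = [r.ld_group_id for r in recs]
            if len(set(gids)) < len(gids) and len(recs) < cap:
                problems.append(f"bin {bin_id}: LD group reused below the bin cap")
    by_chrom: dict[str, list[int]] = {}
    for r in manifest.records:
        by_chrom.setdefault(r.chrom, []).append(r.pos)
    for chrom, positions in by_chrom.items():
        positions.sort()
        for a, b in zip(positions, positions[1:]):
            if b - a <= params.min_probe_spacing:
                problems.append(f"{chrom}: probes at {a} and {b} violate spacing")
    return problems


def panel_stats(manifest: ProbeManifest, genome: GenomeIndex) -> PanelStats:
    """Adjacent-gap statistics of a manifest (gaps within chromosomes)."""
    per_chrom: dict[str, int] = {c: 0 for c in genome.names}
    gaps: list[int] = []
    by_chrom: dict[str, list[int]] = {}
    for r in manifest.records:
        per_chrom[r.chrom] = per_chrom.get(r.chrom, 0) + 1
        by_chrom.setdefault(r.chrom, []).append(r.pos)
    for positions in by_chrom.values():
        positions.sort()
        gaps.extend(b - a for a, b in zip(positions, positions[1:]))
    mean_gap = float(np.mean(gaps)) if gaps else float("nan")
    frac = float(np.mean([g > 100_000 for g in gaps])) if gaps else 0.0
    return PanelStats(
        n_probes=len(manifest.records),
        per_chromosome=per_chrom,
        gaps=gaps,
        mean_gap=mean_gap,
        frac_gaps_gt_100kb=frac,
    )
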