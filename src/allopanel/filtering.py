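"""The two marker filter cascades: the re-sequencing SNP screen and the
array probe-QC screen, each with a conserved audit trail.

Re-sequencing screen (applied to population variant calls, in order):
(1) biallelic; (2) MAF >= 0.05 and mapping quality >= 30; (3) the second
allele carried by >= 10 samples; (4) no other SNP within 50 bp of the
site; (5) the 101-bp probe context has no other genomic match at >= 85%
identity.

Probe-QC screen (applied to array marker statistics, in order):
(1) call frequency > 0.8 (strict); (2) cluster separation >= 0.15;
(3) MAF > 0.05 (strict, as printed for this screen); (4) unique genomic
match; (5) no two probes within 200 bp (higher-MAF probe kept).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io import Genome, VariantSite, MISSING

PROBE_CONTEXT_LEN = 101  # flank5 (50) + SNP base + flank3 (50)

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of both cascades (defaults as used for the array)."""

    maf_min: float = 0.05
    mq_min: float = 30.0
    min_second_allele_carriers: int = 10
    flank_halfwidth: int = 50
    flank_identity_max: float = 0.85
    min_probe_spacing: int = 200
    call_freq_min: float = 0.8
    cluster_sep_min: float = 0.15
    design_score_min: float = 0.6


@dataclass
class FilterAudit:
    """Ordered per-rule accounting: (rule, n_in, n_removed, n_out)."""

    steps: list[tuple[str, int, int, int]] = field(default_factory=list)

    def add(self, rule: str, n_in: int, n_out: int) -> None:
        self.steps.append((rule, n_in, n_in - n_out, n_out))
        if n_out + (n_in - n_out) != n_in or n_out < 0:
            raise ValueError(f"audit not conserved at rule {rule!r}")

    @property
    def n_survivors(self) -> int:
        return self.steps[-1][3] if self.steps else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["rule", "n_in", "n_removed", "n_out"])


# ---------------------------------------------------------------------------
# per-site statistics


def minor_allele_frequency(site: VariantSite) -> float:
    """MAF over non-missing allele calls (0.0 for a monomorphic site)."""
    alleles = site.genotypes[site.genotypes != MISSING]
    if alleles.size == 0:
        raise ValueError(f"all genotypes missing at {site.chrom}:{site.pos}")
    counts = np.bincount(alleles, minlength=site.n_alleles)
    counts = np.sort(counts[counts.nonzero()])[::-1]
    if len(counts) < 2:
        return 0.0
    return counts[1] / counts.sum()


def second_allele_carriers(site: VariantSite) -> int:
    """Number of samples carrying at least one copy of the second most
    frequent allele ("second allele present in N varieties")."""
    alleles = site.genotypes[site.genotypes != MISSING]
    if alleles.size == 0:
        return 0
    counts = np.bincount(alleles, minlength=site.n_alleles)
    present = np.argsort(counts, kind="stable")[::-1]
    present = [a for a in present if counts[a] > 0]
    if len(present) < 2:
        return 0
    second = present[1]
    return int((site.genotypes == second).any(axis=1).sum())


def call_frequency(n_calls: int, n_no_calls: int) -> float:
    """Call frequency = Calls / (No_Calls + Calls)."""
    total = n_calls + n_no_calls
    if total <= 0:
        raise ValueError("call frequency undefined with no observations")
    return n_calls / total


def flank_is_clean(
    site: VariantSite, all_sites: Sequence[VariantSite], halfwidth: int = 50
) -> bool:
    """True iff no *other* variant lies within ``halfwidth`` bp (inclusive)
    of the site on the same chromosome."""
    for other in all_sites:
        if other is site:
            continue
        if other.chrom == site.chrom and abs(other.pos - site.pos) <= halfwidth:
            return False
    return True


def _clean_flank_mask(sites: Sequence[VariantSite], halfwidth: int) -> np.ndarray:
    """Vectorized flank_is_clean over a (chrom, pos)-sorted site list."""
    mask = np.ones(len(sites), dtype=bool)
    for i, site in enumerate(sites):
        for j in (i - 1, i + 1):
            if 0 <= j < len(sites):
                other = sites[j]
                if other.chrom == site.chrom and abs(other.pos - site.pos) <= halfwidth:
                    mask[i] = False
    return mask


# ---------------------------------------------------------------------------
# probe-context uniqueness


def encode_sequence(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else -> 4, as uint8."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class FlankUniquenessIndex:
    """Seeded search for competing genomic matches of a probe context.

    The criterion is full-length ungapped identity: a competing match is
    any genome offset (other than the probe's own locus) where the 101-bp
    probe context aligns with identity >= ``identity_max``.  Candidate
    offsets come from exact seed hits; on genomes up to ``exact_limit`` bp
    the seed length satisfies the pigeonhole bound (seed <= L // (m+1) for
    m allowed mismatches), making the search exact.  Larger genomes use
    16-bp seeds, a documented heuristic that detects any near-duplicate
    sharing one exact 16-mer with the probe.
    """

    def __init__(
        self,
        genome: Genome,
        identity_max: float = 0.85,
        context_len: int = PROBE_CONTEXT_LEN,
        exact_limit: int = 2_000_000,
    ):
        self.genome = genome
        self.identity_max = identity_max
        self.context_len = context_len
        self.max_mismatches = int(np.floor(context_len * (1.0 - identity_max) + 1e-9))
        if genome.index.total_bp <= exact_limit:
            self.seed_len = max(1, context_len // (self.max_mismatches + 1))
            self.exact = True
        else:
            self.seed_len = 16
            self.exact = False
        self._codes: dict[str, np.ndarray] = {}
        self._hash_sorted: dict[str, np.ndarray] = {}
        self._hash_order: dict[str, np.ndarray] = {}
        for name in genome.index.names:
            codes = encode_sequence(genome.sequence(name))
            self._codes[name] = codes
            hashes = self._window_hashes(codes)
            order = np.argsort(hashes, kind="stable")
            self._hash_sorted[name] = hashes[order]
            self._hash_order[name] = order

    def _window_hashes(self, codes: np.ndarray) -> np.ndarray:
        s = self.seed_len
        n = len(codes) - s + 1
        if n <= 0:
            return np.empty(0, dtype=np.uint64)
        h = np.zeros(n, dtype=np.uint64)
        for j in range(s):
            h |= codes[j : j + n].astype(np.uint64) << np.uint64(3 * j)
        # windows containing a non-ACGT base never match a clean probe seed
        bad = codes > 3
        if bad.any():
            bad_any = np.convolve(bad.astype(np.int32), np.ones(s, dtype=np.int32))
            h[bad_any[s - 1 : s - 1 + n] > 0] = np.uint64(0x7) << np.uint64(61)
        return h

    def has_competing_match(
        self, probe_seq: str, own_chrom: str, own_start: int
    ) -> bool:
        """True iff some offset other than (own_chrom, own_start) matches.

        ``own_start`` is the 1-based position where the probe context
        begins on its own chromosome.
        """
        if len(probe_seq) != self.context_len:
            raise ValueError(
                f"probe context must be {self.context_len} bp, got {len(probe_seq)}"
            )
        probe = encode_sequence(probe_seq)
        s = self.seed_len
        seed_hashes = np.zeros(len(probe) - s + 1, dtype=np.uint64)
        for j in range(s):
            seed_hashes |= (
                probe[j : j + len(seed_hashes)].astype(np.uint64) << np.uint64(3 * j)
            )
        for chrom in self.genome.index.names:
            codes = self._codes[chrom]
            hs = self._hash_sorted[chrom]
            order = self._hash_order[chrom]
            lo = np.searchsorted(hs, seed_hashes, side="left")
            hi = np.searchsorted(hs, seed_hashes, side="right")
            starts: list[np.ndarray] = []
            for off, (a, b) in enumerate(zip(lo, hi)):
                if b > a:
                    starts.append(order[a:b] - off)
            if not starts:
                continue
            cand = np.unique(np.concatenate(starts))
            cand = cand[(cand >= 0) & (cand + self.context_len <= len(codes))]
            if chrom == own_chrom:
                cand = cand[cand != own_start - 1]
            if cand.size == 0:
                continue
            windows = codes[cand[:, None] + np.arange(self.context_len)[None, :]]
            mismatches = (windows != probe[None, :]).sum(axis=1)
            if (mismatches <= self.max_mismatches).any():
                return True
        return False


def probe_context(site: VariantSite, genome: Genome, halfwidth: int = 50) -> str | None:
    """The halfwidth+1+halfwidth reference context around a site, or None
    when the site is too close to a chromosome end (truncated flank)."""
    length = genome.index.lengths[site.chrom]
    start, end = site.pos - halfwidth, site.pos + halfwidth
    if start < 1 or end > length:
        return None
    return genome.subseq(site.chrom, start, end)


def flank_is_unique(
    flank5: str,
    snp_base: str,
    flank3: str,
    genome: Genome,
    own_chrom: str,
    own_pos: int,
    identity_max: float = 0.85,
) -> bool:
    """Convenience one-shot uniqueness test of a probe context.

    ``own_pos`` is the 1-based SNP position.  Builds a fresh index; use
    :class:`FlankUniquenessIndex` directly when screening many sites.
    """
    context = flank5 + snp_base + flank3
    index = FlankUniquenessIndex(genome, identity_max, context_len=len(context))
    return not index.has_competing_match(
        context, own_chrom, own_pos - len(flank5)
    )


# ---------------------------------------------------------------------------
# spacing


def enforce_min_spacing(
    sites_sorted: Sequence,
    min_bp: int,
    priority_key: Callable | None = None,
    chrom_of: Callable = lambda s: s.chrom,
    pos_of: Callable = lambda s: s.pos,
) -> list:
    """Greedy spacing filter: no two kept sites within <= min_bp on a
    chromosome (a gap must be strictly greater than ``min_bp``).

    Sites are considered in priority order (default: MAF descending, then
    position ascending) and kept when they do not conflict with an
    already-kept site.  Returns the kept subset in positional order.
    """
    if priority_key is None:
        priority_key = lambda s: (-minor_allele_frequency(s), pos_of(s))
    order = sorted(range(len(sites_sorted)), key=lambda i: priority_key(sites_sorted[i]))
    kept_pos: dict[str, list[int]] = {}
    kept_idx: list[int] = []
    for i in order:
        site = sites_sorted[i]
        chrom, pos = chrom_of(site), pos_of(site)
        positions = kept_pos.setdefault(chrom, [])
        if any(abs(pos - p) <= min_bp for p in positions):
            continue
        positions.append(pos)
        kept_idx.append(i)
    kept_idx.sort(key=lambda i: (chrom_of(sites_sorted[i]), pos_of(sites_sorted[i])))
    return [sites_sorted[i] for i in kept_idx]


# ---------------------------------------------------------------------------
# cascades


def filter_resequencing_snps(
    sites: Sequence[VariantSite],
    genome: Genome,
    params: FilterParams = FilterParams(),
) -> tuple[list[VariantSite], FilterAudit]:
    """Apply the five re-sequencing screen rules in order with an audit.

    The clean-flank rule uses the *input* site list as the neighbor
    universe (a SNP removed by an earlier rule still disturbs a flank).
    Sites whose flank is truncated by a chromosome end are removed at the
    uniqueness step (reason ``flank_truncated`` folded into that rule).
    Surviving sites get their flanks attached from the reference.
    """
    audit = FilterAudit()
    current = sorted(sites, key=lambda s: (s.chrom, s.pos))

    survivors = [s for s in current if len(s.alts) == 1]
    audit.add("biallelic", len(current), len(survivors))
    current = survivors

    survivors = [
        s for s in current
        if minor_allele_frequency(s) >= params.maf_min
        and (s.mapping_quality is not None and s.mapping_quality >= params.mq_min)
    ]
    audit.add("maf_and_mq", len(current), len(survivors))
    current = survivors

    survivors = [
        s for s in current
        if second_allele_carriers(s) >= params.min_second_allele_carriers
    ]
    audit.add("second_allele_carriers", len(current), len(survivors))
    current = survivors

    all_sorted = sorted(sites, key=lambda s: (s.chrom, s.pos))
    clean_ok = {
        id(s): ok
        for s, ok in zip(all_sorted, _clean_flank_mask(all_sorted, params.flank_halfwidth))
    }
    survivors = [s for s in current if clean_ok[id(s)]]
    audit.add("clean_flanks", len(current), len(survivors))
    current = survivors

    index = FlankUniquenessIndex(
        genome,
        params.flank_identity_max,
        context_len=2 * params.flank_halfwidth + 1,
    )
    survivors = []
    for s in current:
        context = probe_context(s, genome, params.flank_halfwidth)
        if context is None:  # flank_truncated
            continue
        if index.has_competing_match(context, s.chrom, s.pos - params.flank_halfwidth):
            continue
        s.flank5 = context[: params.flank_halfwidth]
        s.flank3 = context[params.flank_halfwidth + 1 :]
        survivors.append(s)
    audit.add("unique_flanks", len(current), len(survivors))
    return survivors, audit


def filter_array_probes(
    marker_stats: pd.DataFrame,
    params: FilterParams = FilterParams(),
) -> tuple[pd.DataFrame, FilterAudit]:
    """Apply the five probe-QC screen rules in order with an audit.

    ``marker_stats`` needs columns: marker_id, chrom, pos, call_freq,
    cluster_sep, maf, unique (bool).  Call frequency and MAF thresholds
    are strict (>) for this screen; cluster separation is >=.
    """
    audit = FilterAudit()
    df = marker_stats

    kept = df[df["call_freq"] > params.call_freq_min]
    audit.add("call_frequency", len(df), len(kept))
    df = kept

    kept = df[df["cluster_sep"] >= params.cluster_sep_min]
    audit.add("cluster_separation", len(df), len(kept))
    df = kept

    kept = df[df["maf"] > params.maf_min]
    audit.add("maf", len(df), len(kept))
    df = kept

    kept = df[df["unique"].astype(bool)]
    audit.add("unique_match", len(df), len(kept))
    df = kept

    rows = list(df.itertuples(index=False))
    kept_rows = enforce_min_spacing(
        sorted(rows, key=lambda r: (r.chrom, r.pos)),
        params.min_probe_spacing,
        priority_key=lambda r: (-r.maf, r.pos),
        chrom_of=lambda r: r.chrom,
        pos_of=lambda r: r.pos,
    )
    out = pd.DataFrame(kept_rows, columns=df.columns)
    audit.add("min_spacing", len(df), len(out))
    return out, audit
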