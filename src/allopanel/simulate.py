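"""Synthetic genomes, populations, crosses, intensities and dilution
series with the statistical structure the pipeline assumes.

Population LD is generated by founder-haplotype mosaics: each chromosome
is cut into blocks, every haplotype copies one of F founder haplotypes
per block, so sites within a block are strongly correlated and sites in
different blocks are near-independent.  Two-channel intensities follow
the cluster geometry of an Infinium-style assay: E[X] tracks the A-allele
dose and E[Y] the B-allele dose (summed over both subgenome loci for
markers with homoeolog interference), with truncated Gaussian channel
noise.  All generators are deterministic under a single seed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .applications import MixtureSeries
from .genotyping import _call_map, theta_of_fraction  # conventions shared with the caller
from .io import Genome, VariantSite

_BASES = np.array(list("ACGT"))

MARKER_TYPES = ("normal", "homoeolog", "no_signal")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic test bed.

    noise_sd is the per-channel Gaussian sd in units of ``signal_mean``;
    the default 0.01 reflects a platform whose fluorescence noise floor
    sits near 1% of full signal, so that a ~3% transgene admixture is
    detectable while a 1% admixture is not.  recomb_rate applies to cross
    simulation only (population LD comes from founder blocks); the
    default is a desk-scale convention — the toy genome is physically
    compressed but keeps the genetic map resolvable at the 1-Mb window
    scale used by the bulk-segregant scan.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    n_samples: int = 96
    snp_rate: float = 1.0 / 1500.0
    maf_beta: tuple[float, float] = (0.8, 2.0)
    n_founders: int = 8
    block_length: int = 20_000
    recomb_rate: float = 2e-6
    homoeolog_fraction: float = 0.30
    no_signal_fraction: float = 0.13
    noise_sd: float = 0.01
    signal_mean: float = 1.0
    background_level: float = 0.05

    def __post_init__(self) -> None:
        if self.chrom_length <= 0 or self.n_chromosomes <= 0 or self.n_samples <= 0:
            raise ValueError("sizes must be positive")
        for p in (self.homoeolog_fraction, self.no_signal_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.noise_sd < 0 or self.signal_mean <= 0 or self.recomb_rate < 0:
            raise ValueError("bad intensity/recombination parameters")
        if self.n_founders < 2 or self.block_length < 1:
            raise ValueError("need >= 2 founders and block_length >= 1")


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config_seed, stream]))


# ---------------------------------------------------------------------------
# population


@dataclass
class PopulationSim:
    """A simulated population: reference genome, sites, phased haplotypes."""

    config: SimConfig
    genome: Genome
    sites: list[VariantSite]
    samples: list[str]
    haplotypes: np.ndarray  # (n_sites, 2 * n_samples) allele indices
    block_ids: np.ndarray  # per-site LD block identifier
    target_maf: np.ndarray

    def dosage(self) -> np.ndarray:
        """(n_sites, n_samples) alt-allele dosage."""
        return (
            self.haplotypes[:, 0::2] + self.haplotypes[:, 1::2]
        ).astype(float)


def simulate_population(config: SimConfig) -> PopulationSim:
    """Generate a reference genome, variant sites and population haplotypes."""
    rng = _rng(config.seed, 1)
    seqs: dict[str, str] = {}
    sites: list[VariantSite] = []
    hap_rows: list[np.ndarray] = []
    block_rows: list[int] = []
    maf_rows: list[float] = []
    n_hap = 2 * config.n_samples
    samples = [f"s{i:03d}" for i in range(config.n_samples)]
    block_counter = 0
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        length = config.chrom_length
        seq_codes = rng.integers(0, 4, size=length)
        n_sites = int(round(length * config.snp_rate))
        positions = np.sort(rng.choice(length, size=n_sites, replace=False)) + 1
        # LD blocks tile the chromosome deterministically; block_length == 1
        # makes every site its own block (the independent-sites limit)
        if config.block_length <= 1:
            site_block = np.arange(n_sites)
        else:
            site_block = (positions - 1) // config.block_length
        n_blocks = int(site_block.max()) + 1 if n_sites else 0
        maf = 0.5 * rng.beta(*config.maf_beta, size=n_sites)
        maf = np.clip(maf, 1.0 / n_hap, 0.5)
        flip = rng.random(n_sites) < 0.5
        p_alt = np.where(flip, maf, 1.0 - maf)
        # Founder alleles share one frequency ranking per block (complete
        # D' structure): a site's alt carriers are the founders whose
        # block rank falls below its allele frequency.  Sites in a block
        # with similar frequencies are then in near-perfect r², sites in
        # different blocks independent, and founder allele frequency
        # still tracks p_alt so the MAF spectrum is preserved.
        n_blocks_tmp = int(site_block.max()) + 1 if n_sites else 0
        block_rank = rng.random((n_blocks_tmp, config.n_founders))
        founder = (
            block_rank[site_block].T < p_alt[None, :]
        ).astype(np.int16)
        choice = rng.integers(0, config.n_founders, size=(n_blocks, n_hap))
        haps = founder[choice[site_block], np.arange(n_sites)[:, None]]
        alt_offsets = rng.integers(1, 4, size=n_sites)
        seq_list = _BASES[seq_codes]
        for i in range(n_sites):
            pos = int(positions[i])
            ref_code = seq_codes[pos - 1]
            alt = _BASES[(ref_code + alt_offsets[i]) % 4]
            gts = np.stack([haps[i, 0::2], haps[i, 1::2]], axis=1)
            sites.append(
                VariantSite(
                    chrom=chrom,
                    pos=pos,
                    ref=str(_BASES[ref_code]),
                    alts=(str(alt),),
                    genotypes=gts.astype(np.int16),
                    mapping_quality=60.0,
                    info="MQ=60",
                )
            )
            block_rows.append(block_counter + int(site_block[i]))
        block_counter += n_blocks
        hap_rows.append(haps)
        maf_rows.extend(maf.tolist())
        seqs[chrom] = "".join(seq_list)
    return PopulationSim(
        config=config,
        genome=Genome(seqs),
        sites=sites,
        samples=samples,
        haplotypes=np.concatenate(hap_rows, axis=0) if hap_rows else np.empty((0, n_hap)),
        block_ids=np.array(block_rows),
        target_maf=np.array(maf_rows),
    )


# ---------------------------------------------------------------------------
# crosses


@dataclass
class MarkerMap:
    """Marker grid for cross simulation: positions (1-based) per chromosome."""

    chrom_lengths: dict[str, int]
    positions: dict[str, np.ndarray]

    @property
    def n_markers(self) -> int:
        return sum(len(p) for p in self.positions.values())

    def marker_ids(self) -> list[str]:
        return [
            f"{chrom}_{pos}"
            for chrom in self.positions
            for pos in self.positions[chrom]
        ]


Individual = dict[str, np.ndarray]  # chrom -> (2, n_markers) allele array


def inbred_parents(marker_map: MarkerMap) -> tuple[Individual, Individual]:
    """Fully homozygous opposite parents (P1 all allele 0, P2 all allele 1)."""
    p1: Individual = {}
    p2: Individual = {}
    for chrom, pos in marker_map.positions.items():
        p1[chrom] = np.zeros((2, len(pos)), dtype=np.int8)
        p2[chrom] = np.ones((2, len(pos)), dtype=np.int8)
    return p1, p2


def _gamete(ind: Individual, marker_map: MarkerMap, recomb_rate: float,
            rng: np.random.Generator) -> Individual:
    out: Individual = {}
    for chrom, pos in marker_map.positions.items():
        length = marker_map.chrom_lengths[chrom]
        n_xo = rng.poisson(recomb_rate * length)
        xo = np.sort(rng.uniform(0, length, size=n_xo))
        start = rng.integers(0, 2)
        phase = (start + np.searchsorted(xo, pos - 0.5)) % 2
        out[chrom] = ind[chrom][phase, np.arange(len(pos))][None, :]
    return out


def _mate(g1: Individual, g2: Individual) -> Individual:
    return {c: np.concatenate([g1[c], g2[c]], axis=0) for c in g1}


_SCHEME_RE = re.compile(r"^(F1|F2|BC(\d+)F1)$")


def simulate_cross(
    p1: Individual,
    p2: Individual,
    scheme: str,
    n_offspring: int,
    marker_map: MarkerMap,
    recomb_rate: float,
    seed: int,
) -> list[Individual]:
    """Simulate offspring under a cross scheme.

    Schemes: ``F1``, ``F2``, ``BC<n>F1`` (n backcrosses of the F1 toward
    P1, the recurrent parent).  Each offspring descends through an
    independent pedigree chain, with Poisson crossovers at ``recomb_rate``
    per bp per meiosis.
    """
    m = _SCHEME_RE.match(scheme)
    if not m:
        raise ValueError(f"unknown cross scheme {scheme!r}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    offspring: list[Individual] = []
    for _ in range(n_offspring):
        f1 = _mate(
            _gamete(p1, marker_map, recomb_rate, rng),
            _gamete(p2, marker_map, recomb_rate, rng),
        )
        if scheme == "F1":
            offspring.append(f1)
            continue
        if scheme == "F2":
            offspring.append(
                _mate(
                    _gamete(f1, marker_map, recomb_rate, rng),
                    _gamete(f1, marker_map, recomb_rate, rng),
                )
            )
            continue
        current = f1
        for _ in range(int(m.group(2))):
            current = _mate(
                _gamete(current, marker_map, recomb_rate, rng),
                _gamete(p1, marker_map, recomb_rate, rng),
            )
        offspring.append(current)
    return offspring


def cross_dosage(offspring: list[Individual], marker_map: MarkerMap) -> np.ndarray:
    """(n_markers, n_offspring) allele-1 dosage in marker-map order."""
    cols = []
    for ind in offspring:
        cols.append(
            np.concatenate([ind[c].sum(axis=0) for c in marker_map.positions])
        )
    return np.array(cols, dtype=float).T


# ---------------------------------------------------------------------------
# intensities


@dataclass
class IntensityTruth:
    """Ground truth behind a simulated intensity table."""

    marker_ids: list[str]
    sample_ids: list[str]
    marker_type: np.ndarray  # "normal" | "homoeolog" | "no_signal" per marker
    dosage: np.ndarray  # target-locus B dose (markers x samples)
    shadow_dosage: np.ndarray  # homoeolog-locus B dose (NaN when absent)
    theta_true: np.ndarray  # noise-free theta (NaN for no-signal markers)
    truth_calls: pd.DataFrame  # expected call codes under the canonical map
    expected_class: list[str]  # ideal noise-free marker classification


def _expected_codes(levels: np.ndarray, theta_row: np.ndarray) -> np.ndarray:
    codes = _call_map(tuple(levels))
    idx = np.searchsorted(levels, theta_row)
    idx = np.clip(idx, 0, len(levels) - 1)
    # snap to nearest level (searchsorted gives right neighbor)
    left = np.clip(idx - 1, 0, len(levels) - 1)
    use_left = np.abs(theta_row - levels[left]) <= np.abs(levels[idx] - theta_row)
    idx = np.where(use_left, left, idx)
    return np.array(codes, dtype=object)[idx]


def simulate_intensities(
    dosage: np.ndarray,
    config: SimConfig,
    marker_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
    marker_type: np.ndarray | None = None,
    shadow_dosage: np.ndarray | None = None,
    stream: int = 2,
) -> tuple[pd.DataFrame, IntensityTruth]:
    """Two-channel intensities for a dosage matrix (markers x samples).

    Marker types are assigned from config fractions unless given.  For a
    normal marker E[X] = signal_mean * (2 - d)/2 and E[Y] = signal_mean *
    d/2 for B dose d; a homoeolog marker adds the shadow locus so total
    dose ranges 0-4 (five theta levels); a no-signal marker emits
    only background.  Channel noise is Gaussian (sd noise_sd), clipped at 0.
    """
    rng = _rng(config.seed, stream)
    dosage = np.asarray(dosage, dtype=float)
    n_markers, n_samples = dosage.shape
    if marker_ids is None:
        marker_ids = [f"m{i:05d}" for i in range(n_markers)]
    if sample_ids is None:
        sample_ids = [f"s{i:03d}" for i in range(n_samples)]
    if marker_type is None:
        u = rng.random(n_markers)
        marker_type = np.where(
            u < config.no_signal_fraction,
            "no_signal",
            np.where(
                u < config.no_signal_fraction + config.homoeolog_fraction,
                "homoeolog",
                "normal",
            ),
        )
    marker_type = np.asarray(marker_type, dtype=object)

    is_hom = marker_type == "homoeolog"
    if shadow_dosage is not None:
        # reuse an earlier draw (e.g. technical replicates share one truth)
        shadow = np.asarray(shadow_dosage, dtype=float).copy()
    else:
        shadow = np.full_like(dosage, np.nan)
        if is_hom.any():
            p_shadow = rng.uniform(0.2, 0.8, size=int(is_hom.sum()))
            shadow[is_hom] = rng.binomial(
                2, p_shadow[:, None], size=(int(is_hom.sum()), n_samples))

    total_b = np.where(is_hom[:, None], dosage + np.nan_to_num(shadow), dosage)
    ploidy = np.where(is_hom, 4.0, 2.0)[:, None]
    theta_true = theta_of_fraction(total_b / ploidy)
    ex = config.signal_mean * (ploidy - total_b) / ploidy
    ey = config.signal_mean * total_b / ploidy
    no_sig = marker_type == "no_signal"
    bg = config.background_level * config.signal_mean / 2.0
    ex[no_sig] = bg
    ey[no_sig] = bg
    theta_true[no_sig] = np.nan

    x = np.clip(ex + rng.normal(0.0, config.noise_sd, size=ex.shape), 0.0, None)
    y = np.clip(ey + rng.normal(0.0, config.noise_sd, size=ey.shape), 0.0, None)

    truth_calls = pd.DataFrame("NC", index=marker_ids, columns=sample_ids, dtype=object)
    truth_calls.index.name = "marker_id"
    expected_class: list[str] = []
    for i in range(n_markers):
        if no_sig[i]:
            expected_class.append("no_signal")
            continue
        levels = np.unique(theta_true[i])
        truth_calls.iloc[i] = _expected_codes(levels, theta_true[i])
        if len(levels) == 1:
            expected_class.append("monomorphic")
        elif len(levels) <= 3:
            expected_class.append("polymorphic_3")
        else:
            expected_class.append("intergenomic_5")

    records = pd.DataFrame(
        {
            "sample_id": np.tile(sample_ids, n_markers),
            "marker_id": np.repeat(marker_ids, n_samples),
            "X": x.ravel(),
            "Y": y.ravel(),
        }
    )
    truth = IntensityTruth(
        marker_ids=list(marker_ids),
        sample_ids=list(sample_ids),
        marker_type=marker_type,
        dosage=dosage,
        shadow_dosage=shadow,
        theta_true=theta_true,
        truth_calls=truth_calls,
        expected_class=expected_class,
    )
    return records, truth


# ---------------------------------------------------------------------------
# GMO dilution series


def simulate_gmo_dilution(
    ratios: list[float],
    n_replicates: int,
    config: SimConfig,
    n_negatives: int = 24,
) -> tuple[MixtureSeries, pd.DataFrame]:
    """Dilution series for a transgene probe.

    A d:1 negative:positive mix carries positive-DNA fraction 1/(1+d), so
    the transgene channel mean is background + (signal_mean - background)
    * 1/(1+d); negative controls have fraction 0.  Returns the series and
    the long intensity table (sample ids encode ratio and replicate).
    """
    if any(d < 0 for d in ratios):
        raise ValueError("dilution ratios must be non-negative")
    rng = _rng(config.seed, 3)
    bg = config.background_level * config.signal_mean
    rows = []
    signals: dict[float, np.ndarray] = {}
    for d in ratios:
        frac = 1.0 / (1.0 + d)
        mean = bg + (config.signal_mean - bg) * frac
        sig = np.clip(rng.normal(mean, config.noise_sd, size=n_replicates), 0.0, None)
        signals[d] = sig
        for i, s in enumerate(sig):
            rows.append((f"d{d:g}_r{i:02d}", "transgene", s, max(0.0, rng.normal(bg, config.noise_sd))))
    negatives = np.clip(rng.normal(bg, config.noise_sd, size=n_negatives), 0.0, None)
    for i, s in enumerate(negatives):
        rows.append((f"neg_r{i:02d}", "transgene", s, max(0.0, rng.normal(bg, config.noise_sd))))
    records = pd.DataFrame(rows, columns=["sample_id", "marker_id", "X", "Y"])
    series = MixtureSeries(ratios=list(ratios), signals=signals, negatives=negatives)
    return series, records
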