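"""Shared fixtures: small synthetic genomes, populations and the
deliberately violated filter-cascade fixture, all built programmatically."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from allopanel.io import Genome, VariantSite
from allopanel.simulate import SimConfig, simulate_population

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

BASES = np.array(list("ACGT"))


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def make_site(chrom, pos, ref="A", alts=("T",), dosages=(0, 1, 2), mq=60.0):
    """VariantSite from per-sample alt dosages (or (a, b) allele pairs)."""
    gts = []
    for d in dosages:
        if isinstance(d, tuple):
            gts.append(d)
        else:
            gts.append({0: (0, 0), 1: (0, 1), 2: (1, 1), -1: (-1, -1)}[d])
    return VariantSite(
        chrom=chrom, pos=pos, ref=ref, alts=tuple(alts),
        genotypes=np.array(gts, dtype=np.int16), mapping_quality=mq,
        info=f"MQ={mq:g}" if mq is not None else ".",
    )


@pytest.fixture(scope="session")
def small_population():
    """One 300-kb chromosome, 96 samples — reused read-only across tests."""
    return simulate_population(
        SimConfig(seed=101, n_chromosomes=1, chrom_length=300_000, n_samples=96)
    )


@pytest.fixture(scope="session")
def toy_genome():
    """A 100-kb single-chromosome random genome."""
    rng = np.random.default_rng(7)
    return Genome({"c1": random_sequence(rng, 100_000)})


@pytest.fixture(scope="session")
def cascade_fixture():
    """20 sites on a 40-kb genome with one deliberate violation per screen
    rule; exactly 15 survive the re-sequencing cascade.

    40 samples.  Violations (one each):
      v1 multi-allelic (pos 2000) — also sits 30 bp from v4's victim so the
         clean-flank rule later removes only that victim;
      v2 MAF below 0.05 (pos 4000);
      v3 minor allele carried by only 5 samples as homozygotes, MAF 10/80
         = 0.125 (pos 6000) -> fails the 10-carrier rule only;
      v4 clean-flank victim at pos 2030 (30 bp from v1);
      v5 duplicated probe context (pos 8000 context copied to 30000).
    """
    rng = np.random.default_rng(11)
    n = 40
    seq = list(random_sequence(rng, 40_000))

    def dosages_with(het_carriers, hom_carriers=0):
        d = [0] * n
        for i in range(het_carriers):
            d[i] = 1
        for i in range(het_carriers, het_carriers + hom_carriers):
            d[i] = 2
        return d

    sites = []
    # 15 clean sites, spaced >=200 bp and >100 bp apart, MAF 12/80 = 0.15
    clean_pos = [1000 + 500 * i for i in range(12)] + [12000, 15000, 20000]
    for p in clean_pos:
        sites.append(make_site("c1", p, ref=seq[p - 1], dosages=dosages_with(12)))
    sites.append(  # v1: multi-allelic
        make_site("c1", 2000 - 250, ref=seq[2000 - 251], alts=("T", "G"),
                  dosages=[(0, 1)] * 12 + [(0, 2)] * 12 + [(0, 0)] * 16)
    )
    sites.append(  # v2: MAF = 3/80 < 0.05 (3 het carriers, passes nothing else)
        make_site("c1", 30500, ref=seq[30499], dosages=dosages_with(3))
    )
    sites.append(  # v3: 5 homozygous carriers -> MAF 10/80 ok, carriers 5 < 10
        make_site("c1", 31500, ref=seq[31499], dosages=dosages_with(0, 5))
    )
    sites.append(  # v4: clean-flank victim, 30 bp from v1
        make_site("c1", 2000 - 250 + 30, ref=seq[2000 - 221], dosages=dosages_with(12))
    )
    sites.append(  # v5: duplicated flank context
        make_site("c1", 8000, ref=seq[7999], dosages=dosages_with(12))
    )
    # fix ref alleles and plant the duplicate of v5's context at 30000
    seq[30000 - 1 : 30000 + 100] = seq[8000 - 51 : 8000 + 50]
    genome = Genome({"c1": "".join(seq)})
    # re-sync every site's ref to the (possibly edited) sequence
    for s in sites:
        s.ref = genome.sequence("c1")[s.pos - 1]
        if s.ref == s.alts[0]:
            s.alts = ("A" if s.ref != "A" else "T",) + s.alts[1:]
    sites.sort(key=lambda s: (s.chrom, s.pos))
    survivors_expected = {s.pos for s in sites} - {1750, 30500, 31500, 1780, 8000}
    return sites, genome, survivors_expected
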