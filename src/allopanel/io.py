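"""Readers and writers for the formats the pipeline consumes and emits.

Coordinate conventions
----------------------
Point variants use 1-based inclusive positions (the VCF convention);
intervals, bins and windows are 0-based half-open (the BED convention).
Every public function states which it uses.

The VCF support is a documented minimal dialect: CHROM/POS/REF/ALT/QUAL/
INFO/FORMAT columns with a GT field, diploid genotypes only, and the MQ
key parsed out of INFO.  Unknown INFO content is carried as opaque text so
that a read/write round trip is lossless.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pyfaidx

MISSING = -1  # missing allele code in genotype arrays

#: legal genotype-call codes in calls matrices (3-genotype + 5-dosage + no-call)
CALL_CODES = ("AA", "AB", "BB", "AAAA", "AAAB", "AABB", "ABBB", "BBBB", "NC")


class FormatError(ValueError):
    """Raised when an input file violates the documented dialect."""


# ---------------------------------------------------------------------------
# genome


@dataclass(frozen=True)
class GenomeIndex:
    """Ordered chromosome names and their lengths in bp."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")

    @property
    def names(self) -> list[str]:
        return list(self.lengths)

    @property
    def total_bp(self) -> int:
        return sum(self.lengths.values())


class Genome:
    """Reference sequence with 1-based inclusive subsequence access.

    Wraps either in-memory strings (synthetic genomes) or a pyfaidx FASTA.
    """

    def __init__(self, sequences: dict[str, str]):
        if len(set(sequences)) != len(sequences):
            raise FormatError("duplicate chromosome names")
        self._seqs = {name: str(seq).upper() for name, seq in sequences.items()}
        self.index = GenomeIndex({name: len(seq) for name, seq in self._seqs.items()})

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]

    def subseq(self, chrom: str, start: int, end: int) -> str:
        """Subsequence at 1-based inclusive coordinates [start, end]."""
        seq = self._seqs[chrom]
        if not (1 <= start <= end <= len(seq)):
            raise IndexError(
                f"range {start}-{end} outside {chrom} (length {len(seq)})"
            )
        return seq[start - 1 : end]


def read_fasta(path: str | Path) -> Genome:
    """Load a FASTA file into a :class:`Genome` (duplicate names are an error)."""
    try:
        fa = pyfaidx.Fasta(str(path), duplicate_action="stop")
    except (ValueError, pyfaidx.FastaIndexingError) as exc:
        raise FormatError(f"bad FASTA {path}: {exc}") from exc
    genome = Genome({name: str(rec[:]) for name, rec in fa.items()})
    fa.close()
    return genome


def write_fasta(genome: Genome, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in genome.index.names:
            fh.write(f">{name}\n")
            seq = genome.sequence(name)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# variants


@dataclass
class VariantSite:
    """One candidate SNP with per-sample diploid genotypes.

    ``pos`` is 1-based.  ``genotypes`` is an (n_samples, 2) int array of
    allele indices (0 = ref, 1.. = alt), :data:`MISSING` for missing.
    ``flank5``/``flank3`` are forward-strand reference flanks when attached.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotypes: np.ndarray
    mapping_quality: float | None = None
    info: str = "."
    flank5: str | None = None
    flank3: str | None = None

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alts)

    def alt_dosage(self) -> np.ndarray:
        """Per-sample count of non-reference alleles (NaN where missing)."""
        gt = self.genotypes
        dose = (gt > 0).sum(axis=1).astype(float)
        dose[(gt == MISSING).any(axis=1)] = np.nan
        return dose

    def __eq__(self, other: object) -> bool:  # arrays defeat dataclass eq
        if not isinstance(other, VariantSite):
            return NotImplemented
        return (
            (self.chrom, self.pos, self.ref, self.alts) ==
            (other.chrom, other.pos, other.ref, other.alts)
            and np.array_equal(self.genotypes, other.genotypes)
            and self.mapping_quality == other.mapping_quality
            and self.info == other.info
        )


def _parse_gt(token: str, line_no: int) -> tuple[int, int]:
    gt = token.split(":", 1)[0]
    sep = "/" if "/" in gt else "|"
    fields = gt.split(sep)
    if len(fields) != 2:
        raise FormatError(f"line {line_no}: GT ploidy is not 2: {gt!r}")
    out = []
    for f in fields:
        out.append(MISSING if f == "." else int(f))
    return out[0], out[1]


def _parse_mq(info: str) -> float | None:
    for kv in info.split(";"):
        if kv.startswith("MQ="):
            try:
                return float(kv[3:])
            except ValueError:
                return None
    return None


def read_vcf_minimal(path: str | Path) -> tuple[list[VariantSite], list[str]]:
    """Parse a minimal VCF.  Returns (sites, sample names).

    Positions are 1-based as in the file.  INFO is kept verbatim; MQ is
    additionally parsed into ``mapping_quality``.
    """
    sites: list[VariantSite] = []
    samples: list[str] | None = None
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if cols[:9] != ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL",
                                "FILTER", "INFO", "FORMAT"]:
                    raise FormatError(f"line {line_no}: malformed #CHROM header")
                samples = cols[9:]
                continue
            if samples is None:
                raise FormatError(f"line {line_no}: data before #CHROM header")
            cols = line.split("\t")
            if len(cols) != 9 + len(samples):
                raise FormatError(f"line {line_no}: wrong number of columns")
            chrom, pos, _id, ref, alt, _qual, _filt, info, fmt = cols[:9]
            if fmt.split(":")[0] != "GT":
                raise FormatError(f"line {line_no}: FORMAT does not start with GT")
            alts = tuple(alt.split(",")) if alt != "." else ()
            gts = np.array(
                [_parse_gt(tok, line_no) for tok in cols[9:]], dtype=np.int16
            ).reshape(len(samples), 2)
            sites.append(
                VariantSite(
                    chrom=chrom,
                    pos=int(pos),
                    ref=ref.upper(),
                    alts=tuple(a.upper() for a in alts),
                    genotypes=gts,
                    mapping_quality=_parse_mq(info),
                    info=info,
                )
            )
    if samples is None:
        raise FormatError("no #CHROM header line found")
    return sites, samples


def write_vcf_minimal(
    sites: Sequence[VariantSite], samples: Sequence[str], path: str | Path
) -> None:
    """Write sites (must be sorted by chrom, pos) as a minimal VCF."""
    order = [(s.chrom, s.pos) for s in sites]
    if order != sorted(order):
        raise ValueError("sites must be sorted by (chrom, pos)")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            "##INFO=<ID=MQ,Number=1,Type=Float,Description=\"Mapping quality\">\n"
        )
        fh.write("##FORMAT=<ID=GT,Number=1,Type=String,Description=\"Genotype\">\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT")
        for s in samples:
            fh.write(f"\t{s}")
        fh.write("\n")
        for site in sites:
            if site.genotypes.shape[0] != len(samples):
                raise ValueError("genotype count does not match sample list")
            alt = ",".join(site.alts) if site.alts else "."
            info = site.info
            if info in (".", "") and site.mapping_quality is not None:
                info = f"MQ={site.mapping_quality:g}"
            gts = "\t".join(
                "/".join("." if a == MISSING else str(a) for a in pair)
                for pair in site.genotypes
            )
            row = f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{alt}\t.\t.\t{info}\tGT"
            fh.write(row + ("\t" + gts if len(samples) else "") + "\n")


# ---------------------------------------------------------------------------
# intervals


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(
                f"interval end <= start: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def read_bed_intervals(path: str | Path) -> list[Interval]:
    """Read a BED4 file (0-based half-open; overlaps preserved, not merged)."""
    out: list[Interval] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            if len(cols) < 3:
                raise FormatError(f"line {line_no}: fewer than 3 BED columns")
            label = cols[3] if len(cols) > 3 else ""
            out.append(Interval(cols[0], int(cols[1]), int(cols[2]), label))
    return out


def write_bed_intervals(intervals: Sequence[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


# ---------------------------------------------------------------------------
# probe manifest


@dataclass
class ProbeRecord:
    """A selected panel marker (positions 1-based, flanks forward strand)."""

    marker_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    flank5: str
    flank3: str
    design_score: float
    category: str  # background | qtl | functional | transgene | cytoplasm
    ld_group_id: str
    bin_id: str


@dataclass
class ProbeManifest:
    records: list[ProbeRecord]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.marker_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate marker ids in manifest")
        order = [(r.chrom, r.pos) for r in self.records]
        if order != sorted(order):
            raise ValueError("manifest records must be sorted by (chrom, pos)")

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


_MANIFEST_COLS = [
    "marker_id", "chrom", "pos", "ref", "alt", "flank5", "flank3",
    "design_score", "category", "ld_group_id", "bin_id",
]


def write_probe_manifest(manifest: ProbeManifest, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for key, val in sorted(manifest.metadata.items()):
            fh.write(f"#{key}={val}\n")
        writer.writerow(_MANIFEST_COLS)
        for r in manifest.records:
            writer.writerow(
                [r.marker_id, r.chrom, r.pos, r.ref, r.alt, r.flank5, r.flank3,
                 f"{r.design_score:.17g}", r.category, r.ld_group_id, r.bin_id]
            )


def read_probe_manifest(path: str | Path) -> ProbeManifest:
    metadata: dict[str, str] = {}
    records: list[ProbeRecord] = []
    with open(path, newline="") as fh:
        rows = []
        for raw in fh:
            if raw.startswith("#"):
                key, _, val = raw[1:].strip().partition("=")
                metadata[key] = val
            else:
                rows.append(raw)
        reader = csv.reader(rows)
        header = next(reader, None)
        if header != _MANIFEST_COLS:
            raise FormatError(f"bad manifest header: {header}")
        for cols in reader:
            records.append(
                ProbeRecord(
                    marker_id=cols[0], chrom=cols[1], pos=int(cols[2]),
                    ref=cols[3], alt=cols[4], flank5=cols[5], flank3=cols[6],
                    design_score=float(cols[7]), category=cols[8],
                    ld_group_id=cols[9], bin_id=cols[10],
                )
            )
    return ProbeManifest(records, metadata)


# ---------------------------------------------------------------------------
# intensities


@dataclass(frozen=True)
class IntensityRecord:
    """Two-channel fluorescence of one sample at one marker (X, Y >= 0)."""

    sample_id: str
    marker_id: str
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise FormatError(
                f"negative intensity for {self.sample_id}/{self.marker_id}"
            )


def write_intensity_matrix(records: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format intensity table (sample_id, marker_id, X, Y)."""
    cols = ["sample_id", "marker_id", "X", "Y"]
    if list(records.columns) != cols:
        records = records[cols]
    if (records["X"] < 0).any() or (records["Y"] < 0).any():
        raise FormatError("negative intensity value")
    records.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_intensity_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "marker_id": str})
    required = {"sample_id", "marker_id", "X", "Y"}
    if not required.issubset(df.columns):
        raise FormatError(f"intensity table missing columns {required - set(df.columns)}")
    if (df["X"] < 0).any() or (df["Y"] < 0).any():
        raise FormatError("negative intensity value")
    return df[["sample_id", "marker_id", "X", "Y"]]


# ---------------------------------------------------------------------------
# genotype-call matrices


def write_calls_matrix(calls: pd.DataFrame, path: str | Path) -> None:
    """Write a markers x samples call matrix (codes from :data:`CALL_CODES`)."""
    bad = set(np.unique(calls.values)) - set(CALL_CODES)
    if bad:
        raise FormatError(f"unknown call codes: {sorted(bad)}")
    calls.to_csv(path, sep="\t", index_label="marker_id")


def read_calls_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="marker_id", dtype=str)
    bad = set(np.unique(df.values)) - set(CALL_CODES)
    if bad:
        raise FormatError(f"unknown call codes: {sorted(bad)}")
    return df


# ---------------------------------------------------------------------------
# cluster files (read/write; the model types live in allopanel.genotyping)


def write_cluster_file(cluster_file, path: str | Path) -> None:
    """Serialize a ClusterFile as TSV, one marker per row, up to 5 clusters."""
    from .genotyping import MAX_CLUSTERS

    cols = ["marker_id", "marker_class", "k", "gentrain", "cluster_sep"]
    for i in range(1, MAX_CLUSTERS + 1):
        cols += [f"theta_mean_{i}", f"theta_sd_{i}", f"r_mean_{i}", f"call_{i}"]
    with open(path, "w") as fh:
        fh.write(f"#background_r={cluster_file.background_r:.17g}\n")
        fh.write(f"#n_input={cluster_file.n_input}\n")
        fh.write(f"#n_no_signal={cluster_file.n_no_signal}\n")
        fh.write(f"#n_poor={cluster_file.n_poor}\n")
        fh.write("\t".join(cols) + "\n")
        for m in cluster_file.models.values():
            row = [m.marker_id, m.marker_class, str(m.k),
                   f"{m.gentrain:.17g}", f"{m.cluster_sep:.17g}"]
            for i in range(MAX_CLUSTERS):
                if i < m.k:
                    row += [f"{m.theta_means[i]:.17g}", f"{m.theta_sds[i]:.17g}",
                            f"{m.r_means[i]:.17g}", m.calls[i]]
                else:
                    row += ["", "", "", ""]
            fh.write("\t".join(row) + "\n")


def read_cluster_file(path: str | Path):
    from .genotyping import ClusterFile, ClusterModel

    meta: dict[str, str] = {}
    models = {}
    with open(path) as fh:
        header: list[str] | None = None
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key] = val
                continue
            cols = line.split("\t")
            if header is None:
                header = cols
                if header[:5] != ["marker_id", "marker_class", "k",
                                  "gentrain", "cluster_sep"]:
                    raise FormatError("bad cluster-file header")
                continue
            marker_id, marker_class, k_s, gentrain_s, sep_s = cols[:5]
            k = int(k_s)
            means, sds, rmeans, calls = [], [], [], []
            for i in range(k):
                base = 5 + 4 * i
                means.append(float(cols[base]))
                sds.append(float(cols[base + 1]))
                rmeans.append(float(cols[base + 2]))
                calls.append(cols[base + 3])
            models[marker_id] = ClusterModel(
                marker_id=marker_id,
                k=k,
                theta_means=tuple(means),
                theta_sds=tuple(sds),
                r_means=tuple(rmeans),
                calls=tuple(calls),
                marker_class=marker_class,
                gentrain=float(gentrain_s),
                cluster_sep=float(sep_s),
            )
    for key in ("background_r", "n_input", "n_no_signal", "n_poor"):
        if key not in meta:
            raise FormatError(f"cluster file missing #{key} metadata")
    return ClusterFile(
        models=models,
        background_r=float(meta["background_r"]),
        n_input=int(meta["n_input"]),
        n_no_signal=int(meta["n_no_signal"]),
        n_poor=int(meta["n_poor"]),
    )
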