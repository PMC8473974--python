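"""Two-channel genotype calling for an allotetraploid.

The Infinium-style assay reports two fluorescence channels per marker and
sample: X tracks the A allele, Y the B allele.  Calling works in polar
coordinates — theta = (2/pi)*arctan(Y/X) encodes the allele ratio, R = X+Y
the total signal.  For a marker assaying a single locus the population
forms up to three theta clusters (AA, AB, BB).  In an allotetraploid the
probe may also hybridize to the homoeologous locus of the other subgenome;
when both loci are polymorphic the summed signal produces up to five
dosage clusters (AAAA, AAAB, AABB, ABBB, BBBB).

Per marker we fit a 1-D Gaussian mixture on theta (k = 1..5, chosen by
BIC), map clusters to genotype codes by nearest canonical theta, classify
the marker (no-signal / monomorphic / 3-genotype polymorphic / 5-dosage
intergenomic / unclassifiable), and retain the usable markers in a cluster
file that is then applied to call new samples.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture

MAX_CLUSTERS = 5


def theta_of_fraction(f):
    """Ideal theta of a B-allele signal fraction f = dose/ploidy.

    With channel means proportional to allele dose, theta =
    (2/pi)*arctan(f/(1-f)); the quarter-dose clusters of a 5-dosage
    marker therefore sit at ~0.205 and ~0.795, not at 0.25/0.75.
    """
    f = np.asarray(f, dtype=float)
    return (2.0 / np.pi) * np.arctan2(f, 1.0 - f)


#: canonical theta positions of the diploid (3-genotype) call map
THETA_GRID_3 = {float(theta_of_fraction(d / 2)): c
                for d, c in enumerate(["AA", "AB", "BB"])}
#: canonical theta positions of the tetraploid (5-dosage) call map
THETA_GRID_5 = {float(theta_of_fraction(d / 4)): c
                for d, c in enumerate(["AAAA", "AAAB", "AABB", "ABBB", "BBBB"])}

NO_CALL = "NC"

MARKER_CLASSES = (
    "no_signal", "monomorphic", "polymorphic_3", "intergenomic_5", "unclassifiable",
)


@dataclass(frozen=True)
class GenotypingParams:
    """Thresholds of the calling engine.

    background_frac: a marker is no-signal when its median R falls below
        this fraction of the panel-wide median R; the same fraction of a
        marker's cluster R defines the per-sample no-call floor.
    abs_background_r: absolute dark floor on the normalized intensity
        scale (full signal ~ 1); keeps an all-dark panel from passing
        the purely relative rule.
    cluster_sep_min / gentrain_min: markers below either are flagged as
        having poor genotyping ability ("unclassifiable").
    max_z: no-call when the nearest cluster is further than this many
        cluster standard deviations in theta.
    """

    background_frac: float = 0.10
    abs_background_r: float = 0.05
    cluster_sep_min: float = 0.15
    gentrain_min: float = 0.5
    max_z: float = 3.0
    max_k: int = MAX_CLUSTERS
    reg_covar: float = 1e-6
    min_cluster_distance: float = 0.1
    # Clipping at the channel floor deflates the empirical theta sd of
    # boundary clusters (point mass at 0/1 plus a folded tail), which
    # would turn genuine cluster members into no-calls under the 3-sd
    # rule; the floor is small against the 0.25 canonical spacing.
    min_theta_sd: float = 0.01


@dataclass
class ThetaR:
    theta: float
    r: float


def theta_r(x, y):
    """Polar transform of channel intensities (vectorized).

    theta = (2/pi) * arctan(Y/X) in [0, 1]; R = X + Y.  X = Y = 0 yields
    theta = NaN (the no-signal sentinel) and R = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("intensities must be non-negative")
    r = x + y
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = (2.0 / np.pi) * np.arctan2(y, x)
    theta = np.where(r > 0, theta, np.nan)
    return theta, r


@dataclass
class ClusterModel:
    """Fitted theta clusters of one marker and its call map."""

    marker_id: str
    k: int
    theta_means: tuple[float, ...]
    theta_sds: tuple[float, ...]
    r_means: tuple[float, ...]
    calls: tuple[str, ...]  # genotype code per cluster, theta-ascending
    marker_class: str
    gentrain: float
    cluster_sep: float

    def __post_init__(self) -> None:
        if self.k != len(self.theta_means):
            raise ValueError("k does not match cluster count")
        if any(b <= a for a, b in zip(self.theta_means, self.theta_means[1:])):
            raise ValueError("cluster theta means must be strictly increasing")


@dataclass
class ClusterFile:
    """Per-marker cluster models retained for calling, with removal audit."""

    models: dict[str, ClusterModel]
    background_r: float
    n_input: int
    n_no_signal: int
    n_poor: int

    def __post_init__(self) -> None:
        if self.n_retained + self.n_no_signal + self.n_poor != self.n_input:
            raise ValueError("cluster-file audit does not conserve marker count")

    @property
    def n_retained(self) -> int:
        return len(self.models)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for m in self.models.values():
            counts[m.marker_class] = counts.get(m.marker_class, 0) + 1
        return counts


def cluster_separation(theta_means, theta_sds) -> float:
    """Separation score: min gap between the +/-2-sd envelopes of adjacent
    clusters, as a fraction of the full theta range (1.0), floored at 0.
    Defined as 1.0 for fewer than two clusters."""
    if len(theta_means) < 2:
        return 1.0
    gaps = []
    for i in range(len(theta_means) - 1):
        lo = theta_means[i] + 2.0 * theta_sds[i]
        hi = theta_means[i + 1] - 2.0 * theta_sds[i + 1]
        gaps.append(hi - lo)
    return max(0.0, min(gaps))


def _call_map(theta_means: tuple[float, ...]) -> tuple[str, ...]:
    """Assign genotype codes to theta-ordered clusters.

    Clusters are matched to an ordered subset of the canonical theta grid
    ({0, .5, 1} for k <= 3, {0, .25, .5, .75, 1} for k in {4, 5}) chosen to
    minimize total |mean - grid| distance; ties take the lower-dosage
    (lower theta) subset.  Guarantees A-dosage non-increasing in theta.
    """
    k = len(theta_means)
    grid = THETA_GRID_3 if k <= 3 else THETA_GRID_5
    points = sorted(grid)
    best: tuple[float, tuple[str, ...]] | None = None
    for subset in itertools.combinations(points, k):
        cost = sum(abs(m - g) for m, g in zip(theta_means, subset))
        if best is None or cost < best[0] - 1e-12:
            best = (cost, tuple(grid[g] for g in subset))
    assert best is not None
    return best[1]


def fit_cluster_model(
    theta: np.ndarray,
    r: np.ndarray,
    marker_id: str = "",
    background_r: float = 0.0,
    params: GenotypingParams = GenotypingParams(),
) -> ClusterModel:
    """Fit the theta-cluster model of one marker.

    Mixtures with k = 1..max_k are fitted on the theta of samples whose R
    clears ``background_r``; for each k both evenly spaced theta-quantile
    initializations and the ordered canonical-grid subsets are tried
    (rare extreme clusters are easy to miss from quantiles alone), and k
    is chosen by BIC (ties to the smaller k).  Components closer than
    ``min_cluster_distance`` in theta are merged afterwards — channel
    clipping puts a point mass at theta 0/1 that would otherwise split a
    boundary cluster — and cluster parameters are recomputed empirically
    from the hard assignments.  Everything is deterministic.  A marker
    whose median R is below background is returned as ``no_signal`` with
    k = 0.
    """
    theta = np.asarray(theta, dtype=float)
    r = np.asarray(r, dtype=float)
    ok = np.isfinite(theta) & (r >= background_r)
    if np.median(r) < background_r or ok.sum() < 2:
        return ClusterModel(marker_id, 0, (), (), (), (),
                            "no_signal", 0.0, 0.0)
    t = theta[ok]
    rr = r[ok]
    X = t.reshape(-1, 1)
    grid5 = sorted(THETA_GRID_5)
    best_bic, best_gm = np.inf, None
    max_k = min(params.max_k, len(np.unique(t)))
    for k in range(1, max_k + 1):
        inits = [np.quantile(t, (2 * np.arange(k) + 1) / (2 * k))]
        inits += [np.array(sub) for sub in itertools.combinations(grid5, k)]
        for means_init in inits:
            gm = GaussianMixture(
                n_components=k,
                covariance_type="spherical",
                means_init=means_init.reshape(-1, 1),
                weights_init=np.full(k, 1.0 / k),
                reg_covar=params.reg_covar,
                random_state=0,
                max_iter=200,
            )
            gm.fit(X)
            bic = gm.bic(X)
            if bic < best_bic - 1e-9:
                best_bic, best_gm = bic, gm
    assert best_gm is not None
    labels = best_gm.predict(X)
    # theta-ordered non-empty components, then merge near-coincident ones
    comp_means = [
        (best_gm.means_[j, 0], j) for j in range(best_gm.n_components)
        if (labels == j).any()
    ]
    comp_means.sort()
    clusters: list[list[int]] = []
    last_mean = None
    for mu, j in comp_means:
        if last_mean is not None and mu - last_mean < params.min_cluster_distance:
            clusters[-1].append(j)
        else:
            clusters.append([j])
        last_mean = mu
    means, sds, rmeans = [], [], []
    hard = np.empty(len(t), dtype=int)
    for rank, members in enumerate(clusters):
        sel = np.isin(labels, members)
        hard[sel] = rank
        mu = float(min(1.0, max(0.0, t[sel].mean())))
        if means and mu <= means[-1]:  # enforce strictly increasing
            mu = np.nextafter(means[-1], 2.0)
        means.append(mu)
        sds.append(max(float(t[sel].std()), params.min_theta_sd))
        rmeans.append(float(rr[sel].mean()))
    k = len(means)
    sep = cluster_separation(means, sds)
    if k >= 2:
        sil = silhouette_score(X, hard)
        gentrain = (sil + 1.0) / 2.0
    else:
        gentrain = 1.0
    model = ClusterModel(
        marker_id=marker_id,
        k=k,
        theta_means=tuple(means),
        theta_sds=tuple(sds),
        r_means=tuple(rmeans),
        calls=_call_map(tuple(means)),
        marker_class="unclassified",
        gentrain=float(gentrain),
        cluster_sep=float(sep),
    )
    model.marker_class = classify_marker(model, params)
    return model


def classify_marker(
    model: ClusterModel, params: GenotypingParams = GenotypingParams()
) -> str:
    """Marker taxonomy from the fitted model.

    no_signal (background rule fired) -> monomorphic (one cluster) ->
    polymorphic_3 (2-3 clusters) or intergenomic_5 (4-5 clusters, homoeolog
    blending); any polymorphic marker whose clusters are too poorly
    separated (cluster_sep or the GenTrain-like score below threshold) is
    unclassifiable — the "software could not genotype correctly" bucket.
    """
    if model.k == 0:
        return "no_signal"
    if model.k == 1:
        return "monomorphic"
    if model.cluster_sep < params.cluster_sep_min or model.gentrain < params.gentrain_min:
        return "unclassifiable"
    return "polymorphic_3" if model.k <= 3 else "intergenomic_5"


def build_cluster_file(
    intensities: pd.DataFrame,
    params: GenotypingParams = GenotypingParams(),
) -> ClusterFile:
    """Fit and classify every marker of a reference panel.

    ``intensities`` is the long table (sample_id, marker_id, X, Y).
    Markers classified no_signal or unclassifiable are removed; the audit
    (input = retained + no_signal + poor) is carried in the result.
    """
    theta, r = theta_r(intensities["X"].values, intensities["Y"].values)
    df = intensities.assign(theta=theta, r=r)
    background_r = max(
        params.background_frac * float(np.median(r)), params.abs_background_r
    )
    models: dict[str, ClusterModel] = {}
    n_no_signal = n_poor = 0
    marker_ids = df["marker_id"].unique()
    for marker_id, grp in df.groupby("marker_id", sort=False):
        model = fit_cluster_model(
            grp["theta"].values, grp["r"].values, str(marker_id),
            background_r, params,
        )
        if model.marker_class == "no_signal":
            n_no_signal += 1
        elif model.marker_class == "unclassifiable":
            n_poor += 1
        else:
            models[str(marker_id)] = model
    return ClusterFile(
        models=models,
        background_r=background_r,
        n_input=len(marker_ids),
        n_no_signal=n_no_signal,
        n_poor=n_poor,
    )


def call_genotypes(
    intensities: pd.DataFrame,
    cluster_file: ClusterFile,
    params: GenotypingParams = GenotypingParams(),
) -> pd.DataFrame:
    """Call genotypes for new samples against a cluster file.

    Returns a markers x samples DataFrame of call codes.  A sample is
    no-call (NC) when its R is below the background floor of the marker's
    clusters or its theta is more than ``max_z`` cluster sd from every
    cluster mean.  Markers absent from the cluster file yield NC columns.
    """
    theta, r = theta_r(intensities["X"].values, intensities["Y"].values)
    df = intensities.assign(theta=theta, r=r)
    samples = list(dict.fromkeys(df["sample_id"]))
    markers = list(dict.fromkeys(df["marker_id"]))
    calls = pd.DataFrame(NO_CALL, index=markers, columns=samples, dtype=object)
    calls.index.name = "marker_id"
    for marker_id, grp in df.groupby("marker_id", sort=False):
        model = cluster_file.models.get(str(marker_id))
        if model is None or model.k == 0:
            continue
        mu = np.array(model.theta_means)
        sd = np.maximum(np.array(model.theta_sds), 1e-9)
        r_floor = params.background_frac * float(np.mean(model.r_means))
        t = grp["theta"].values
        z = np.abs(t[:, None] - mu[None, :]) / sd[None, :]
        nearest = np.argmin(z, axis=1)
        zmin = z[np.arange(len(t)), nearest]
        codes = np.array(model.calls, dtype=object)[nearest]
        bad = (~np.isfinite(t)) | (grp["r"].values < r_floor) | (zmin > params.max_z)
        codes[bad] = NO_CALL
        calls.loc[marker_id, grp["sample_id"].values] = codes
    return calls


def f1_consistency_check(
    parent1_calls: pd.Series, parent2_calls: pd.Series, f1_calls: pd.Series
) -> pd.DataFrame:
    """Mendelian trio check at markers where parents are opposite homozygotes.

    Returns a per-marker verdict frame (column ``ok``) for the informative
    markers (P1 and P2 called AA/BB in either order): ok iff the F1 is AB.
    The summary fraction is ``result['ok'].mean()``.
    """
    shared = parent1_calls.index.intersection(parent2_calls.index).intersection(
        f1_calls.index
    )
    p1, p2, f1 = (s.loc[shared] for s in (parent1_calls, parent2_calls, f1_calls))
    informative = ((p1 == "AA") & (p2 == "BB")) | ((p1 == "BB") & (p2 == "AA"))
    informative &= f1 != NO_CALL
    return pd.DataFrame({"ok": (f1 == "AB")[informative]})


def concordance(
    calls_a: pd.Series | pd.DataFrame,
    calls_b: pd.Series | pd.DataFrame,
    n_total_high_quality: int | None = None,
) -> tuple[int, int, float]:
    """Replicate concordance between two call sets over shared markers.

    Markers no-called in either set are excluded from the comparison.  The
    percent-discordant denominator follows the cluster-file convention:
    the total number of high-quality probes when given, else the number of
    markers compared.  Returns (n_compared, n_discordant, percent).
    """
    if isinstance(calls_a, pd.DataFrame):
        calls_a = calls_a.iloc[:, 0]
    if isinstance(calls_b, pd.DataFrame):
        calls_b = calls_b.iloc[:, 0]
    shared = calls_a.index.intersection(calls_b.index)
    if len(shared) == 0:
        raise ValueError("call sets share no markers")
    a = calls_a.loc[shared]
    b = calls_b.loc[shared]
    called = (a != NO_CALL) & (b != NO_CALL)
    n_compared = int(called.sum())
    n_discordant = int((a[called] != b[called]).sum())
    denom = n_total_high_quality if n_total_high_quality is not None else n_compared
    if denom <= 0:
        raise ValueError("empty comparison")
    return n_compared, n_discordant, 100.0 * n_discordant / denom
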