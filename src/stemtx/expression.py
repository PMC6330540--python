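"""Expression layer: FPKM, BH-FDR differential-expression calls, profile
clustering under Pearson-correlation distance, and 2^-ddCt relative
expression.

The differential-expression engine here is deliberately light: fold change
and Benjamini-Hochberg thresholding are computed in-package on FPKM (with a
pseudocount), while the per-transcript p-value can either come from the
builtin Welch test on log2 FPKM or be supplied from an external DE package
via a statistics table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Counts with replicate design, transcript lengths and library sizes.

    ``counts`` is transcripts x samples; ``design`` maps each sample column
    to its zone and replicate; ``library_sizes`` are total mapped fragments
    per sample (defaults to column sums when not supplied).
    """

    counts: pd.DataFrame
    lengths: pd.Series
    design: pd.DataFrame  # index: sample, columns: zone, replicate
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.lengths.index):
            self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            raise ValueError("lengths missing for some transcripts")
        if (self.lengths <= 0).any():
            raise ValueError("transcript lengths must be positive")
        missing = set(self.counts.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"design missing samples: {sorted(missing)}")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def zones(self) -> list[str]:
        seen: list[str] = []
        for s in self.counts.columns:
            z = self.design.loc[s, "zone"]
            if z not in seen:
                seen.append(z)
        return seen

    def samples_of_zone(self, zone: str) -> list[str]:
        return [s for s in self.counts.columns if self.design.loc[s, "zone"] == zone]

    def fpkm(self) -> pd.DataFrame:
        return compute_fpkm(self.counts, self.lengths, self.library_sizes)

    def zone_mean_fpkm(self) -> pd.DataFrame:
        fpkm = self.fpkm()
        return pd.DataFrame(
            {z: fpkm[self.samples_of_zone(z)].mean(axis=1) for z in self.zones}
        )


def compute_fpkm(
    counts: pd.DataFrame, lengths: pd.Series, library_sizes: pd.Series
) -> pd.DataFrame:
    """Fragments per kilobase of exon per million mapped fragments.

    fpkm[i, s] = counts[i, s] * 1e9 / (library_sizes[s] * lengths[i])
    """
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be positive")
    library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return (
        counts.astype(float)
        .mul(1e9)
        .div(library_sizes, axis=1)
        .div(lengths, axis=0)
    )


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} min(1, m * p_(j) / j), returned in input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def estimate_nb_dispersion(expr: "ExpressionMatrix", min_mean: float = 5.0) -> float:
    """Pooled method-of-moments NB dispersion from within-zone replicates.

    For each (transcript, zone) with mean normalized count >= ``min_mean``,
    alpha_hat = (var - mean) / mean^2; the pooled estimate is the median
    over all such cells, clipped to be non-negative. Pooling across
    transcripts is what makes testing at 2-3 replicates possible at all.
    """
    norm = _normalized_counts(expr)
    alphas = []
    for zone in expr.zones:
        cols = expr.samples_of_zone(zone)
        if len(cols) < 2:
            continue
        m = norm[cols].mean(axis=1).to_numpy()
        v = norm[cols].var(axis=1, ddof=1).to_numpy()
        mask = m >= min_mean
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v[mask] - m[mask]) / m[mask] ** 2
        alphas.append(a)
    if not alphas:
        return 1e-8
    pooled = float(np.median(np.concatenate(alphas)))
    return max(pooled, 1e-8)


def _normalized_counts(expr: "ExpressionMatrix") -> pd.DataFrame:
    """Counts rescaled to a common library size (the mean library)."""
    factors = expr.library_sizes / expr.library_sizes.mean()
    return expr.counts.astype(float).div(factors, axis=1)


def _nb_wald_p(
    mean_a: np.ndarray,
    mean_b: np.ndarray,
    n_a: int,
    n_b: int,
    alpha: float,
    floor: float = 0.5,
) -> np.ndarray:
    """Two-sided Wald p-values on the log ratio of NB means.

    var(log mu_hat) per group ~ (1/mu + alpha) / n under the NB
    mean-variance relation var = mu + alpha mu^2.
    """
    mu_a = np.maximum(mean_a, floor)
    mu_b = np.maximum(mean_b, floor)
    se = np.sqrt((1.0 / mu_a + alpha) / n_a + (1.0 / mu_b + alpha) / n_b)
    z = (np.log(mu_a) - np.log(mu_b)) / se
    return 2.0 * stats.norm.sf(np.abs(z))


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Welch two-sample t-test p-value; 1.0 for degenerate zero-variance ties."""
    if np.allclose(a.var(ddof=1) + b.var(ddof=1), 0.0):
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.ttest_ind(a, b, equal_var=False)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def call_dets(
    expr: ExpressionMatrix,
    contrasts: Sequence[tuple[str, str]] | None = None,
    supplied_p: pd.DataFrame | None = None,
    test: str = "nb_wald",
    fdr: float = 0.01,
    fc: float = 2.0,
    pseudocount: float = 0.1,
) -> pd.DataFrame:
    """Call differentially expressed transcripts per zone contrast.

    Defaults to all adjacent zone pairs. Fold change is the ratio of
    pseudocounted zone-mean FPKM. P-values come from the builtin test —
    ``"nb_wald"`` (default), a Wald test on log normalized-count means with
    a pooled method-of-moments NB dispersion, or ``"welch"`` on
    log2(FPKM + pseudocount) — unless ``supplied_p`` (columns
    transcript_id, zone_a, zone_b, p) plugs in external DE statistics.
    BH adjustment is applied per contrast; a transcript is a DET when
    q <= ``fdr`` and fold change >= ``fc`` in either direction.
    """
    zones = expr.zones
    if contrasts is None:
        contrasts = list(zip(zones, zones[1:]))
    for za, zb in contrasts:
        if za not in zones or zb not in zones:
            raise ValueError(f"contrast ({za}, {zb}) names a zone not in the design")
    if test not in ("nb_wald", "welch"):
        raise ValueError(f"unknown test {test!r}")
    fpkm = expr.fpkm()
    log_fpkm = np.log2(fpkm + pseudocount)

    sup = None
    if supplied_p is not None:
        sup = supplied_p.set_index(["zone_a", "zone_b", "transcript_id"])["p"]
    elif test == "nb_wald":
        alpha = estimate_nb_dispersion(expr)
        norm = _normalized_counts(expr)

    frames = []
    for za, zb in contrasts:
        sa, sb = expr.samples_of_zone(za), expr.samples_of_zone(zb)
        if sup is None and (len(sa) < 2 or len(sb) < 2):
            raise ValueError(
                f"builtin test requires >= 2 replicates per zone ({za} vs {zb})"
            )
        mean_a = fpkm[sa].mean(axis=1) + pseudocount
        mean_b = fpkm[sb].mean(axis=1) + pseudocount
        ratio = mean_a / mean_b
        if sup is not None:
            p = sup.loc[za, zb].reindex(fpkm.index).to_numpy()
            if np.isnan(p).any():
                raise ValueError(f"supplied p-table incomplete for {za} vs {zb}")
        elif test == "nb_wald":
            p = _nb_wald_p(
                norm[sa].mean(axis=1).to_numpy(),
                norm[sb].mean(axis=1).to_numpy(),
                len(sa),
                len(sb),
                alpha,
            )
        else:
            a = log_fpkm[sa].to_numpy()
            b = log_fpkm[sb].to_numpy()
            p = np.array([_welch_p(a[i], b[i]) for i in range(a.shape[0])])
        q = bh_adjust(p)
        fold = np.maximum(ratio, 1.0 / ratio)
        frames.append(
            pd.DataFrame(
                {
                    "transcript_id": fpkm.index,
                    "zone_a": za,
                    "zone_b": zb,
                    "fold_change": ratio.to_numpy(),
                    "log2_fc": np.log2(ratio.to_numpy()),
                    "p": p,
                    "q": q,
                    "is_det": (q <= fdr) & (fold >= fc),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def det_transcripts(calls: pd.DataFrame) -> list[str]:
    """Union of DETs over all contrasts (the set fed to clustering)."""
    return sorted(calls.loc[calls["is_det"], "transcript_id"].unique())


@dataclass
class ClusterAssignment:
    labels: pd.Series  # transcript_id -> cluster index in 1..K
    cluster_profiles: pd.DataFrame  # K x zones, mean standardized profile
    inertia: float
    dropped: list[str] = field(default_factory=list)


def standardize_profiles(profiles: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Row z-scores; rows with zero variance across zones are dropped.

    On z-scored rows of dimension n, squared Euclidean distance equals
    2n(1 - Pearson r), so K-means on the standardized profiles clusters by
    Pearson-correlation distance.
    """
    mu = profiles.mean(axis=1)
    sd = profiles.std(axis=1, ddof=0)
    flat = sd <= 0
    dropped = list(profiles.index[flat])
    if dropped:
        logger.warning("%d flat profiles excluded from clustering", len(dropped))
    kept = profiles.loc[~flat]
    z = kept.sub(mu[~flat], axis=0).div(sd[~flat], axis=0)
    return z, dropped


def kmeans_profiles(
    profiles: pd.DataFrame,
    k: int = 9,
    seed: int = 0,
    n_init: int = 50,
) -> ClusterAssignment:
    """K-means on standardized zone profiles (Pearson-distance clustering).

    ``profiles`` is transcripts x zones (typically zone-mean FPKM of the
    DET set). Clusters are renumbered 1..K by descending size for stable,
    readable output.
    """
    z, dropped = standardize_profiles(profiles)
    if k > len(z):
        raise ValueError(f"k={k} exceeds {len(z)} usable profiles")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(z.to_numpy())
    sizes = pd.Series(raw).value_counts()
    rank = {old: new + 1 for new, old in enumerate(sizes.index)}
    labels = pd.Series([rank[r] for r in raw], index=z.index, name="cluster")
    centers = pd.DataFrame(km.cluster_centers_, columns=profiles.columns)
    centers.index = [rank[i] for i in range(k)]
    centers = centers.sort_index()
    return ClusterAssignment(
        labels=labels,
        cluster_profiles=centers,
        inertia=float(km.inertia_),
        dropped=dropped,
    )


def ddct_relative_expression(
    ct: pd.DataFrame,
    reference_gene: str,
    calibrator_sample: str,
) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    ``ct`` columns: sample, gene, ct. For each target gene,
    dCt = Ct_target - Ct_reference per sample, ddCt = dCt - dCt_calibrator,
    F = 2^-ddCt (so F = 1 in the calibrator sample).
    """
    for col in ("sample", "gene", "ct"):
        if col not in ct.columns:
            raise ValueError(f"Ct table missing column {col!r}")
    wide = ct.pivot_table(index="sample", columns="gene", values="ct")
    if reference_gene not in wide.columns or wide[reference_gene].isna().any():
        raise ValueError(
            f"reference gene {reference_gene!r} Ct missing for some samples"
        )
    if calibrator_sample not in wide.index:
        raise ValueError(f"calibrator sample {calibrator_sample!r} not in Ct table")
    rows = []
    for gene in wide.columns:
        if gene == reference_gene:
            continue
        dct = wide[gene] - wide[reference_gene]
        ddct = dct - dct.loc[calibrator_sample]
        f = np.power(2.0, -ddct)
        for sample in wide.index:
            rows.append(
                {
                    "sample": sample,
                    "gene": gene,
                    "delta_ct": dct.loc[sample],
                    "delta_delta_ct": ddct.loc[sample],
                    "relative_expression": f.loc[sample],
                }
            )
    return pd.DataFrame(rows)
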