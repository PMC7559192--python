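"""Descriptive and inferential statistics on barcode distributions and sizes.

Covers the repertoire-style summaries used to compare treatment arms and
hosts: clonality (1 - normalized Shannon entropy), pairwise barcode
distribution correlations, within- vs between-mouse comparison, per-barcode
ANOVA enrichment screens with Benjamini-Hochberg correction, variance-
equality F tests on relative tumor sizes, and hierarchical clustering of
samples with Kolmogorov-Smirnov distribution comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "clonality",
    "distribution_correlation",
    "within_vs_between_mouse",
    "per_barcode_group_test",
    "variance_equality",
    "hierarchical_cluster_samples",
    "MousePairComparison",
    "SampleClustering",
]


def clonality(freqs) -> float:
    """Unevenness of a clone frequency distribution in [0, 1].

    Defined as 1 - H/ln(R) where H is the Shannon entropy (nats) of the
    nonzero frequencies and R their number: 0 for a uniform distribution,
    1 for a point mass. A single detected clone returns 1 by convention.
    """
    f = np.asarray(freqs, dtype=float)
    if (f < 0).any():
        raise ValueError("frequencies must be non-negative")
    if not np.isclose(f.sum(), 1.0, atol=1e-6):
        raise ValueError(f"frequencies sum to {f.sum()}, not 1")
    f = f[f > 0]
    if f.size == 0:
        raise ValueError("no detected clone")
    if f.size == 1:
        return 1.0
    H = -np.sum(f * np.log(f))
    return float(1.0 - H / np.log(f.size))


def _align_pair(a, b):
    if isinstance(a, pd.Series) and isinstance(b, pd.Series):
        a, b = a.align(b, join="inner")
        return a.to_numpy(float), b.to_numpy(float)
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("frequency vectors must share a barcode universe")
    return a, b


def distribution_correlation(
    a, b, method: str = "pearson_log", read_depth: float = 1e6
) -> float:
    """Correlation of two samples' barcode frequency distributions.

    Computed over barcodes detected in at least one of the two samples.
    ``pearson_log`` takes Pearson correlation of log frequencies, replacing
    zeros by the pseudo-frequency 0.5/read_depth; ``spearman`` ranks the raw
    frequencies.
    """
    x, y = _align_pair(a, b)
    keep = (x > 0) | (y > 0)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(
            f"only {x.size} barcodes detected in either sample (need >= 3)"
        )
    if method == "pearson_log":
        pseudo = 0.5 / read_depth
        r = sps.pearsonr(np.log(np.maximum(x, pseudo)),
                         np.log(np.maximum(y, pseudo))).statistic
    elif method == "spearman":
        r = sps.spearmanr(x, y).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r)


@dataclass
class MousePairComparison:
    """Within- vs between-mouse barcode correlation comparison."""

    within: pd.Series  # (mouse) -> correlation of its two flank tumors
    between: pd.Series  # (sample_a, sample_b) -> correlation, same arm
    statistic: float  # one-sided rank-sum (Mann-Whitney U)
    pvalue: float


def within_vs_between_mouse(
    freqs: pd.DataFrame,
    meta: pd.DataFrame,
    method: str = "pearson_log",
    read_depth: float = 1e6,
) -> MousePairComparison:
    """Compare barcode correlations of flank-tumor pairs within one mouse
    against pairs from different mice.

    Between-mouse pairs are restricted to samples from the same treatment
    arm so that the comparison isolates the host, not the treatment. The
    returned test is a one-sided Mann-Whitney rank-sum of within > between.
    """
    meta = meta.set_index("sample") if "sample" in meta.columns else meta
    within, between = {}, {}
    mice = meta.groupby("mouse").groups
    n_paired = sum(len(s) >= 2 for s in mice.values())
    if n_paired < 2:
        raise ValueError("need at least 2 mice with 2 tumors each")
    for mouse, samp in mice.items():
        samp = list(samp)
        for s1, s2 in combinations(samp, 2):
            within[mouse] = distribution_correlation(
                freqs[s1], freqs[s2], method=method, read_depth=read_depth
            )
    for s1, s2 in combinations(freqs.columns, 2):
        if meta.loc[s1, "mouse"] == meta.loc[s2, "mouse"]:
            continue
        if meta.loc[s1, "arm"] != meta.loc[s2, "arm"]:
            continue
        between[(s1, s2)] = distribution_correlation(
            freqs[s1], freqs[s2], method=method, read_depth=read_depth
        )
    w = pd.Series(within, name="within")
    b = pd.Series(between, name="between")
    stat, p = sps.mannwhitneyu(w, b, alternative="greater")
    return MousePairComparison(within=w, between=b,
                               statistic=float(stat), pvalue=float(p))


def per_barcode_group_test(
    freqs: pd.DataFrame, groups: pd.Series, min_nonzero: int = 2
) -> pd.DataFrame:
    """Screen each barcode for differential abundance across treatment arms.

    One-way ANOVA on log10 frequency per barcode, zero frequencies dropped;
    a barcode is skipped (status ``insufficient``) when any group retains
    fewer than ``min_nonzero`` nonzero samples. Benjamini-Hochberg q-values
    are computed across the tested barcodes.
    """
    groups = groups.reindex(freqs.columns)
    if groups.isna().any():
        raise ValueError("groups must label every sample in freqs")
    labels = groups.unique()
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for bc, row in freqs.iterrows():
        per_group = []
        ok = True
        means = {}
        for g in labels:
            v = row[groups[groups == g].index].to_numpy(float)
            v = np.log10(v[v > 0])
            means[f"mean_log10_{g}"] = v.mean() if v.size else np.nan
            if v.size < min_nonzero:
                ok = False
            per_group.append(v)
        if not ok:
            rows.append({"barcode": bc, "F": np.nan, "p": np.nan,
                         "status": "insufficient", **means})
            continue
        pooled = np.concatenate(per_group)
        if np.allclose(pooled, pooled[0]):
            F, p = 0.0, 1.0  # no variation at all
        else:
            F, p = sps.f_oneway(*per_group)
        rows.append({"barcode": bc, "F": float(F), "p": float(p),
                     "status": "tested", **means})
    out = pd.DataFrame(rows).set_index("barcode")
    tested = out["status"] == "tested"
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = multipletests(
            out.loc[tested, "p"], method="fdr_bh"
        )[1]
    return out


def variance_equality(
    sizes_a, sizes_b, normalize: bool = True, log10: bool = True
) -> tuple[float, float]:
    """F test of equality of variances between two groups of tumor sizes.

    By default each group is first normalized to its median and log10-
    transformed (the relative-size convention); set both flags False to
    test raw values. Returns (F = var_a/var_b, two-sided p).
    """
    a = np.asarray(sizes_a, float)
    b = np.asarray(sizes_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if normalize:
        if (a <= 0).any() or (b <= 0).any():
            raise ValueError("sizes must be positive")
        a = a / np.median(a)
        b = b / np.median(b)
    if log10:
        a = np.log10(a)
        b = np.log10(b)
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if vb == 0:
        raise ValueError("zero variance in denominator group")
    F = va / vb
    dist = sps.f(a.size - 1, b.size - 1)
    p = 2.0 * min(dist.sf(F), dist.cdf(F))
    return float(F), float(min(p, 1.0))


@dataclass
class SampleClustering:
    """Average-linkage clustering of samples on barcode distributions."""

    linkage_matrix: np.ndarray  # scipy hierarchical linkage (average)
    labels: list[str]
    distance: pd.DataFrame  # 1 - Pearson(log frequency)
    ks: pd.DataFrame  # pairwise two-sample KS statistic


def hierarchical_cluster_samples(
    freqs: pd.DataFrame, read_depth: float = 1e6
) -> SampleClustering:
    """Cluster samples by barcode distribution.

    Distance is 1 - Pearson correlation of log frequencies (zeros replaced
    by 0.5/read_depth); linkage is average. Pairwise two-sample Kolmogorov-
    Smirnov statistics on the nonzero frequency distributions are reported
    alongside.
    """
    samples = list(freqs.columns)
    if len(samples) < 3:
        raise ValueError("need at least 3 samples")
    # pairwise correlation under the shared convention: barcodes absent from
    # both samples of a pair are excluded, remaining zeros take the
    # pseudo-frequency
    n = len(samples)
    corr = np.eye(n)
    for i, j in combinations(range(n), 2):
        r = distribution_correlation(
            freqs[samples[i]], freqs[samples[j]],
            method="pearson_log", read_depth=read_depth,
        )
        corr[i, j] = corr[j, i] = r
    D = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    ks = pd.DataFrame(0.0, index=samples, columns=samples)
    nonzero = {s: freqs[s][freqs[s] > 0].to_numpy() for s in samples}
    for s1, s2 in combinations(samples, 2):
        stat = sps.ks_2samp(nonzero[s1], nonzero[s2]).statistic
        ks.loc[s1, s2] = ks.loc[s2, s1] = float(stat)
    return SampleClustering(
        linkage_matrix=Z,
        labels=samples,
        distance=pd.DataFrame(D, index=samples, columns=samples),
        ks=ks,
    )
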