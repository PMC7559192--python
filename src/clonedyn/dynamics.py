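"""Clone fitness inference and growth-pattern clustering.

Fitness advantage
-----------------
A clone k with birth/death rates (b_k, d_k) in a bulk with rates (b_p, d_p)
has fitness advantage x_k defined by 1 + x_k = (b_k - d_k)/(b_p - d_p).
Starting from frequency f_start, its frequency after t days is

    f_end = f_start * e^{(b_k-d_k)t} / (f_start * e^{(b_k-d_k)t}
                                        + (1-f_start) * e^{(b_p-d_p)t}),

and when f_start << 1 this inverts to

    x_k = [ln(f_end/(1-f_end)) + ln(1/f_start)] / ((b_p-d_p) * t).

Growth-pattern clustering
-------------------------
Barcode log frequencies are modeled by a finite mixture of K Gaussian linear
regressions, h(y|x, psi) = sum_k pi_k N(y | x'beta_k, sigma_k^2), in which
all repeated observations of one barcode share a single latent component
(the barcode, not the observation, is the clonal unit). The log likelihood
sum_m sum_n log h(y_mn | x_mn, psi) is maximized by a grouped EM: the
E-step computes per-barcode responsibilities proportional to
pi_k * prod_n N(y_mn | theta_k), and the M-step solves per-component
weighted least squares. Covariates are treatment-arm indicators and the
natural log of tumor size. The number of components is selected by BIC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy import stats as sps
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

__all__ = [
    "logit_frequency",
    "forward_frequency",
    "clone_fitness",
    "fitness_table",
    "build_observations",
    "MixtureFit",
    "fit_mixture",
    "select_K",
    "assign_clusters",
    "cluster_cumulative_frequency",
]

_LOG2PI = math.log(2.0 * math.pi)


def logit_frequency(f: float) -> float:
    """ln(f / (1 - f)), the per-condition fitness surrogate."""
    if not 0.0 < f < 1.0:
        raise ValueError(f"frequency must lie strictly in (0, 1), got {f}")
    return math.log(f / (1.0 - f))


def forward_frequency(f_start: float, x: float, growth_t: float) -> float:
    """Forward selection model: clone frequency after net growth*t days.

    ``growth_t`` is (b_p - d_p) * t for the bulk; the clone grows at
    (1 + x) times the bulk net rate.
    """
    if not 0.0 < f_start < 1.0:
        raise ValueError("f_start must lie strictly in (0, 1)")
    a = f_start * math.exp(x * growth_t)
    return a / (a + (1.0 - f_start))


def clone_fitness(
    f_start: float, f_end: float, net_growth: float, t: float
) -> float:
    """Invert the forward model for the fitness advantage x_k.

    Valid in the f_start << 1 regime; a warning is raised for
    f_start > 0.01 where the approximation degrades.
    """
    if net_growth * t <= 0:
        raise ValueError("net_growth * t must be positive")
    if not 0.0 < f_start < 1.0:
        raise ValueError("f_start must lie strictly in (0, 1)")
    if not 0.0 < f_end < 1.0:
        raise ValueError("f_end must lie strictly in (0, 1): logit undefined")
    if f_start > 0.01:
        warnings.warn(
            f"f_start={f_start:.3g} > 0.01: the small-frequency "
            "approximation degrades",
            stacklevel=2,
        )
    return (logit_frequency(f_end) + math.log(1.0 / f_start)) / (net_growth * t)


def fitness_table(
    freqs: pd.DataFrame,
    meta: pd.DataFrame,
    net_growth: float,
    t: float,
    control_arm: str = "IgG",
    f_start: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-clone fitness advantage x_k for each treatment condition.

    The start frequency of each clone is unobserved; by default it is
    approximated by the clone's mean frequency across control-arm samples,
    where clonal selection is minimal. ``f_end`` is the clone's mean
    frequency across the samples of each treated arm. Clones undetected in
    the controls (or in an arm) are skipped for the affected condition.
    """
    meta = meta.set_index("sample") if "sample" in meta.columns else meta
    arms = meta["arm"].unique()
    if control_arm not in arms:
        raise ValueError(f"control arm {control_arm!r} absent from meta")
    if f_start is None:
        ctrl = meta.index[meta["arm"] == control_arm]
        f_start = freqs[ctrl].mean(axis=1)
    rows = []
    for arm in arms:
        if arm == control_arm:
            continue
        f_end = freqs[meta.index[meta["arm"] == arm]].mean(axis=1)
        for bc in freqs.index:
            fs, fe = f_start.get(bc, 0.0), f_end[bc]
            if not (0.0 < fs < 1.0 and 0.0 < fe < 1.0):
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                x = clone_fitness(fs, fe, net_growth, t)
            rows.append({"barcode": bc, "condition": arm, "x": x,
                         "f_start": fs, "f_end": fe})
    return pd.DataFrame(rows)


def build_observations(
    freqs: pd.DataFrame,
    meta: pd.DataFrame,
    control_arm: str = "IgG",
    size_col: str = "size_end",
) -> pd.DataFrame:
    """Long-format observations for the mixture model.

    One row per (barcode, sample) with nonzero frequency: response
    y = ln(frequency), covariates = indicator(anti-PD-1),
    indicator(anti-CTLA-4) and ln(tumor size). Arms other than the control
    arm each get an indicator column named ``arm_<label>``.
    """
    meta = meta.set_index("sample") if "sample" in meta.columns else meta
    if size_col not in meta.columns:
        raise ValueError(f"meta lacks a {size_col!r} column")
    arms = [a for a in meta["arm"].unique() if a != control_arm]
    records = []
    values = freqs.to_numpy(float)
    barcodes = freqs.index.to_numpy()
    for j, sample in enumerate(freqs.columns):
        arm = meta.loc[sample, "arm"]
        log_size = math.log(float(meta.loc[sample, size_col]))
        col = values[:, j]
        nz = col > 0
        for bc, f in zip(barcodes[nz], col[nz]):
            rec = {"barcode": bc, "sample": sample, "y": math.log(f),
                   "log_size": log_size}
            for a in arms:
                rec[f"arm_{a}"] = 1.0 if arm == a else 0.0
            records.append(rec)
    return pd.DataFrame(records)


@dataclass
class MixtureFit:
    """A fitted grouped mixture of Gaussian linear regressions."""

    K: int
    pi: np.ndarray  # component weights, sum 1
    coef: np.ndarray  # K x p regression coefficients (column 0 = intercept)
    sigma: np.ndarray  # K residual standard deviations
    posteriors: pd.DataFrame  # barcodes x K membership probabilities
    loglik: float
    loglik_trace: np.ndarray  # non-decreasing within the winning EM run
    bic: float
    n_obs: int
    n_iter: int
    converged: bool
    seed: int | None
    design_columns: list[str] = field(default_factory=list)
    warnings_: list[str] = field(default_factory=list)
    bic_by_K: pd.Series | None = None  # filled by select_K


def _em_run(
    y: np.ndarray,
    X: np.ndarray,
    g: np.ndarray,
    M: int,
    R: np.ndarray,
    max_iter: int,
    tol: float,
) -> dict:
    """One EM run from initial responsibilities R (M x K)."""
    N, p = X.shape
    K = R.shape[1]
    trace = []
    prev = -np.inf
    converged = False
    degenerate = False
    coef = np.zeros((K, p))
    sigma = np.ones(K)
    pi = np.full(K, 1.0 / K)
    logdens = np.empty((N, K))
    for it in range(max_iter):
        # M-step from responsibilities
        pi = R.mean(axis=0)
        W = R[g]  # N x K observation weights
        for k in range(K):
            w = W[:, k]
            sw = np.sqrt(w)
            Xw = X * sw[:, None]
            yw = y * sw
            beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
            resid = y - X @ beta
            denom = w.sum()
            if denom <= 0:
                degenerate = True
                denom = 1.0
            s2 = float(np.sum(w * resid**2) / denom)
            coef[k] = beta
            sigma[k] = math.sqrt(max(s2, 1e-12))
            logdens[:, k] = -0.5 * (
                _LOG2PI + 2.0 * math.log(sigma[k]) + (resid / sigma[k]) ** 2
            )
        if (pi < 1.0 / (2.0 * M)).any() or (sigma < 1e-6).any():
            degenerate = True
        # E-step: grouped responsibilities
        S = np.zeros((M, K))
        np.add.at(S, g, logdens)
        A = S + np.log(np.maximum(pi, 1e-300))[None, :]
        lse = logsumexp(A, axis=1)
        R = np.exp(A - lse[:, None])
        ll = float(lse.sum())
        trace.append(ll)
        if np.isfinite(prev) and abs(ll - prev) <= tol * (abs(prev) + 1e-10):
            converged = True
            break
        prev = ll
    return {
        "pi": pi, "coef": coef.copy(), "sigma": sigma.copy(), "R": R,
        "loglik": trace[-1], "trace": np.array(trace),
        "n_iter": len(trace), "converged": converged, "degenerate": degenerate,
    }


def fit_mixture(
    obs: pd.DataFrame,
    K: int,
    n_restarts: int = 10,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
    design_columns: list[str] | None = None,
    short_iter: int = 150,
    short_tol: float = 1e-6,
) -> MixtureFit:
    """Fit a K-component grouped mixture of linear regressions by EM.

    ``obs`` is the long-format table from :func:`build_observations` (or any
    frame with columns ``barcode``, ``y`` and covariates). All observations
    of one barcode share a single latent component. The first restart is
    initialized by k-means on per-barcode mean response, the rest by random
    responsibilities; every restart is run briefly and the best one refined
    to convergence (relative log-likelihood change below ``tol``).
    Degenerate solutions (near-empty component or collapsed variance) are
    re-initialized, and flagged in ``warnings_`` if they persist.
    """
    if design_columns is None:
        design_columns = [
            c for c in obs.columns if c not in ("barcode", "sample", "y")
        ]
    y = obs["y"].to_numpy(float)
    X = np.column_stack(
        [np.ones(len(obs))] + [obs[c].to_numpy(float) for c in design_columns]
    )
    codes, uniques = pd.factorize(obs["barcode"])
    M = len(uniques)
    if K > M:
        raise ValueError(f"K={K} exceeds the number of barcodes ({M})")
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    mean_y = np.bincount(codes, weights=y) / np.bincount(codes)

    def init_R(i_restart: int) -> np.ndarray:
        if i_restart == 0 and K > 1:
            km = KMeans(n_clusters=K, n_init=3,
                        random_state=int(rng.integers(2**31)))
            hard = km.fit_predict(mean_y[:, None])
            R = np.full((M, K), 0.1 / max(K - 1, 1))
            R[np.arange(M), hard] = 0.9
            return R
        R = rng.dirichlet(np.ones(K), size=M)
        return R

    warnings_list: list[str] = []
    runs = []
    n_runs = n_restarts if K > 1 else 1
    for i in range(n_runs):
        run = _em_run(y, X, codes, M, init_R(i), short_iter, short_tol)
        retries = 0
        while run["degenerate"] and retries < 3:
            run = _em_run(y, X, codes, M, rng.dirichlet(np.ones(K), size=M),
                          short_iter, short_tol)
            retries += 1
        runs.append(run)
    # refine the leading short runs to full convergence, keep the best
    leaders = sorted(runs, key=lambda r: r["loglik"], reverse=True)[:3]
    refined = [_em_run(y, X, codes, M, r["R"], max_iter, tol) for r in leaders]
    final = max(refined, key=lambda r: r["loglik"])
    if final["degenerate"]:
        warnings_list.append(
            "degenerate component at convergence (near-empty or collapsed "
            "variance); fit returned as-is"
        )

    p = X.shape[1]
    n_params = (K - 1) + K * (p + 1)
    N = len(y)
    bic = -2.0 * final["loglik"] + n_params * math.log(N)
    posteriors = pd.DataFrame(
        final["R"], index=pd.Index(uniques, name="barcode"),
        columns=[f"cluster_{k + 1}" for k in range(K)],
    )
    return MixtureFit(
        K=K,
        pi=final["pi"],
        coef=final["coef"],
        sigma=final["sigma"],
        posteriors=posteriors,
        loglik=final["loglik"],
        loglik_trace=final["trace"],
        bic=bic,
        n_obs=N,
        n_iter=final["n_iter"],
        converged=final["converged"],
        seed=seed,
        design_columns=["intercept"] + design_columns,
        warnings_=warnings_list,
    )


def select_K(
    obs: pd.DataFrame,
    K_range=range(2, 11),
    n_restarts: int = 10,
    seed: int | None = None,
    **kwargs,
) -> MixtureFit:
    """Fit the mixture over a range of K and return the BIC-minimal fit.

    Ties are broken toward the smaller K. The per-K BIC table is attached
    to the returned fit as ``bic_by_K``.
    """
    K_list = sorted(K_range)
    if not K_list:
        raise ValueError("K_range is empty")
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(K_list))]
    fits, errors = [], []
    for K, ks in zip(K_list, child_seeds):
        try:
            fits.append(fit_mixture(obs, K, n_restarts=n_restarts, seed=ks,
                                    **kwargs))
        except Exception as exc:  # pragma: no cover - defensive
            errors.append(f"K={K}: {exc}")
    if not fits:
        raise RuntimeError("all mixture fits failed: " + "; ".join(errors))
    bics = pd.Series({f.K: f.bic for f in fits}, name="bic")
    best = min(fits, key=lambda f: (round(f.bic, 9), f.K))
    best.bic_by_K = bics
    return best


def assign_clusters(fit: MixtureFit) -> pd.DataFrame:
    """Hard cluster assignment by maximum posterior probability.

    Ties go to the lowest cluster index; the maximum posterior is reported
    as the assignment confidence. Clusters are labeled 1..K.
    """
    P = fit.posteriors.to_numpy()
    idx = P.argmax(axis=1)  # argmax takes the first (lowest) index on ties
    return pd.DataFrame(
        {
            "cluster": idx + 1,
            "confidence": P[np.arange(len(idx)), idx],
        },
        index=fit.posteriors.index,
    )


def cluster_cumulative_frequency(
    assignments: pd.Series | pd.DataFrame,
    freqs: pd.DataFrame,
    labels: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-sample cumulative frequency of each clone cluster.

    ``assignments`` maps barcode -> cluster (or is the frame returned by
    :func:`assign_clusters`). Every barcode present in ``freqs`` must be
    assigned. If ``labels`` maps samples to groups (e.g. responder /
    non-responder), a per-cluster one-way ANOVA across the groups is
    returned with Benjamini-Hochberg correction across clusters.
    """
    if isinstance(assignments, pd.DataFrame):
        assignments = assignments["cluster"]
    missing = freqs.index.difference(assignments.index)
    if len(missing):
        shown = list(missing[:10])
        raise ValueError(f"unassigned barcode(s): {shown}"
                         + ("..." if len(missing) > 10 else ""))
    cum = freqs.groupby(assignments.reindex(freqs.index)).sum().T
    cum.index.name = "sample"
    cum.columns.name = "cluster"
    comparison = None
    if labels is not None:
        labels = labels.reindex(cum.index)
        rows = []
        for cl in cum.columns:
            groups = [cum.loc[labels == g, cl].to_numpy()
                      for g in labels.dropna().unique()]
            groups = [g for g in groups if g.size >= 2]
            if len(groups) < 2:
                rows.append({"cluster": cl, "F": np.nan, "p": np.nan})
                continue
            pooled = np.concatenate(groups)
            if np.allclose(pooled, pooled[0]):
                F, p = 0.0, 1.0
            else:
                F, p = sps.f_oneway(*groups)
            rows.append({"cluster": cl, "F": float(F), "p": float(p)})
        comparison = pd.DataFrame(rows).set_index("cluster")
        ok = comparison["p"].notna()
        comparison["q"] = np.nan
        if ok.any():
            comparison.loc[ok, "q"] = multipletests(
                comparison.loc[ok, "p"], method="fdr_bh"
            )[1]
    return cum, comparison
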