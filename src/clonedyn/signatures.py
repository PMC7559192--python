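"""Expression-signature scoring of bulk tumors.

A resistance (or response) signature is the log2 fold-change profile of a
derived line versus its parental line, restricted to the most regulated
significant genes. A tumor's signature score is the Pearson correlation
between that reference profile and the tumor's mean-centered log2-TPM
(E'_{i,j} = E_{i,j} - mean_j E_{i,.}). Cytolytic activity (CYT) is the
geometric mean of GZMA and PRF1 TPM (+0.01 offset). Score-phenotype
association uses Welch's t test (two response groups) or Pearson
correlation (continuous, e.g. CYT).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "normalize_expression",
    "make_signature",
    "score_samples",
    "cytolytic_score",
    "associate_scores",
    "robustness_grid",
]


def normalize_expression(E: pd.DataFrame) -> pd.DataFrame:
    """Center each gene to zero mean across samples (E' matrix)."""
    if E.shape[1] < 2:
        raise ValueError("need at least 2 samples to mean-center")
    E = E.copy()
    E.index = E.index.str.upper()
    if E.index.duplicated().any():
        raise ValueError("duplicate gene ids after uppercasing")
    return E.sub(E.mean(axis=1), axis=0)


def make_signature(
    de_table: pd.DataFrame,
    top_n: int | None = 200,
    alpha: float = 0.05,
    gene_col: str = "gene",
    lfc_col: str = "log2fc",
    padj_col: str = "padj",
) -> pd.Series:
    """Reference signature: log2 fold changes of the top regulated genes.

    Keeps the ``top_n`` most upregulated and ``top_n`` most downregulated
    genes with adjusted p below ``alpha`` (``top_n=None`` keeps every
    significant gene). Ranking is by log2 fold change with ties broken by
    smaller adjusted p, then gene id.
    """
    de = de_table[[gene_col, lfc_col, padj_col]].copy()
    de[gene_col] = de[gene_col].str.upper()
    sig = de[de[padj_col] < alpha]
    if sig.empty:
        raise ValueError(f"no gene passes the adjusted p < {alpha} filter")
    ranked = sig.sort_values(
        by=[lfc_col, padj_col, gene_col], ascending=[False, True, True]
    )
    if top_n is None:
        chosen = ranked
    else:
        up = ranked.head(top_n)
        down = ranked.tail(top_n)
        chosen = pd.concat([up, down]).drop_duplicates(subset=gene_col)
    out = chosen.set_index(gene_col)[lfc_col].astype(float)
    out.name = "log2fc"
    return out


def score_samples(Eprime: pd.DataFrame, signature: pd.Series) -> pd.Series:
    """Per-sample Pearson correlation between E' and the signature."""
    sig = signature.copy()
    sig.index = sig.index.str.upper()
    genes = Eprime.index.str.upper()
    shared = pd.Index(genes).intersection(sig.index)
    dropped = len(sig) - len(shared)
    if dropped:
        warnings.warn(
            f"{dropped} signature gene(s) absent from the expression matrix",
            stacklevel=2,
        )
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} signature genes shared with the matrix "
            "(need >= 3)"
        )
    sub = Eprime.set_axis(genes, axis=0).loc[shared]
    ref = sig.loc[shared].to_numpy(float)
    scores = {}
    for sample in sub.columns:
        v = sub[sample].to_numpy(float)
        if np.allclose(v, v[0]):
            warnings.warn(
                f"sample {sample!r} has zero variance over signature genes; "
                "score undefined",
                stacklevel=2,
            )
            scores[sample] = np.nan
        else:
            scores[sample] = float(sps.pearsonr(ref, v).statistic)
    return pd.Series(scores, name="signature_score")


def cytolytic_score(E: pd.DataFrame, offset: float = 0.01) -> pd.Series:
    """Cytolytic activity: geometric mean of GZMA and PRF1 TPM + offset.

    ``E`` holds log2-TPM values; TPM is recovered as 2**E.
    """
    genes = E.index.str.upper()
    sub = E.set_axis(genes, axis=0)
    for g in ("GZMA", "PRF1"):
        if g not in sub.index:
            raise KeyError(f"gene {g} missing from the expression matrix")
    tpm = np.power(2.0, sub.loc[["GZMA", "PRF1"]].to_numpy(float))
    cyt = np.sqrt((tpm[0] + offset) * (tpm[1] + offset))
    return pd.Series(cyt, index=E.columns, name="CYT")


def associate_scores(scores: pd.Series, labels_or_values, mode: str) -> dict:
    """Associate signature scores with response labels or a covariate.

    ``two_group_t``: Welch's two-sided t test between exactly two label
    groups. ``pearson``: Pearson correlation with a continuous value per
    sample. Returns statistic, p-value and effect direction.
    """
    other = pd.Series(labels_or_values)
    joined = pd.concat([scores.rename("score"), other.rename("other")],
                       axis=1, join="inner").dropna()
    if mode == "two_group_t":
        groups = joined.groupby("other")["score"]
        if groups.ngroups != 2:
            raise ValueError(f"need exactly 2 groups, got {groups.ngroups}")
        (la, a), (lb, b) = list(groups)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each group needs at least 2 scores")
        pooled = np.concatenate([a.to_numpy(float), b.to_numpy(float)])
        if np.allclose(pooled, pooled[0]):
            t, p = 0.0, 1.0  # zero variance everywhere: no effect
        else:
            t, p = sps.ttest_ind(a, b, equal_var=False)
        direction = f"{la} > {lb}" if t > 0 else (f"{lb} > {la}" if t < 0 else "none")
        return {"statistic": float(t), "pvalue": float(p),
                "direction": direction, "groups": (la, lb)}
    if mode == "pearson":
        if len(joined) < 3:
            raise ValueError("need at least 3 paired values")
        r, p = sps.pearsonr(joined["score"], joined["other"])
        return {"statistic": float(r), "pvalue": float(p),
                "direction": "positive" if r > 0 else "negative"}
    raise ValueError(f"unknown mode {mode!r}")


def robustness_grid(
    de_table: pd.DataFrame,
    Eprime: pd.DataFrame,
    grid=(200, 400, 800, None),
    alpha: float = 0.05,
    **make_kwargs,
) -> tuple[pd.DataFrame, float]:
    """Score samples with signatures of increasing size and report stability.

    For each grid value (``None`` = all significant genes) a signature is
    built and scored; the returned fraction is the share of samples whose
    score keeps a constant sign across the whole grid.
    """
    if not grid:
        raise ValueError("grid is empty")
    cols = {}
    for top_n in grid:
        sig = make_signature(de_table, top_n=top_n, alpha=alpha, **make_kwargs)
        label = "all" if top_n is None else str(top_n)
        cols[label] = score_samples(Eprime, sig)
    scores = pd.DataFrame(cols)
    signs = np.sign(scores.to_numpy())
    consistent = (signs == signs[:, [0]]).all(axis=1)
    return scores, float(consistent.mean())
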