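"""Responder / non-responder classification of treated tumors.

The primary rule compares each treated tumor's end-of-treatment size to the
control cohort: with M the log10 median control size, tumors smaller than
10^(M-0.5) are responders and tumors larger than 10^(M-0.1) non-responders;
everything in between (boundaries included) is intermediate. An alternative
classifier uses the log10 fold change between post- and pre-treatment size.
Both rules are scale-invariant.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["classify_response", "classify_by_fold_change"]

RESPONDER = "responder"
NON_RESPONDER = "non_responder"
INTERMEDIATE = "intermediate"


def _as_series(x, name) -> pd.Series:
    s = pd.Series(x, dtype=float) if not isinstance(x, pd.Series) else x.astype(float)
    s.name = name
    return s


def classify_response(treated_sizes, control_sizes) -> pd.DataFrame:
    """Classify treated tumors against the control cohort's median size.

    ``treated_sizes`` maps sample -> end-of-treatment size; size 0 denotes a
    complete response and is labeled responder before any log transform.
    """
    treated = _as_series(treated_sizes, "size")
    control = np.asarray(list(control_sizes), float)
    if control.size == 0:
        raise ValueError("control cohort is empty")
    if (control <= 0).any():
        raise ValueError("control sizes must be positive")
    if (treated < 0).any():
        raise ValueError("treated sizes must be non-negative")
    M = math.log10(float(np.median(control)))
    lo = 10.0 ** (M - 0.5)
    hi = 10.0 ** (M - 0.1)
    labels = np.where(
        treated < lo, RESPONDER, np.where(treated > hi, NON_RESPONDER, INTERMEDIATE)
    )
    return pd.DataFrame(
        {
            "size": treated,
            "label": labels,
            "M_control": M,
            "threshold_responder": lo,
            "threshold_non_responder": hi,
        }
    )


def classify_by_fold_change(
    pre_sizes, post_sizes, grow_cut: float = 0.2, shrink_cut: float = -0.2
) -> pd.DataFrame:
    """Classify tumors by log10 fold change of post- vs pre-treatment size.

    log10(post/pre) >= ``grow_cut`` gives non-responder, <= ``shrink_cut``
    responder, otherwise intermediate. A post size of 0 (complete response)
    is a responder. Pre and post must be paired by sample id.
    """
    if shrink_cut >= grow_cut:
        raise ValueError("shrink_cut must be below grow_cut")
    pre = _as_series(pre_sizes, "pre_size")
    post = _as_series(post_sizes, "post_size")
    missing = pre.index.symmetric_difference(post.index)
    if len(missing):
        raise ValueError(f"unpaired sample(s): {list(missing)}")
    post = post.reindex(pre.index)
    if (pre <= 0).any():
        raise ValueError("pre-treatment sizes must be positive")
    if (post < 0).any():
        raise ValueError("post-treatment sizes must be non-negative")
    with np.errstate(divide="ignore"):
        lfc = np.log10(post / pre)
    labels = np.where(
        lfc <= shrink_cut,
        RESPONDER,
        np.where(lfc >= grow_cut, NON_RESPONDER, INTERMEDIATE),
    )
    return pd.DataFrame(
        {"pre_size": pre, "post_size": post, "log10_fc": lfc, "label": labels}
    )
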