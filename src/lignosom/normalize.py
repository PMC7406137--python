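"""Low-count masking, median-of-ratios size factors, log2 transform and
fold-change regulation calls.

The chain mirrors standard bulk RNA-seq practice: genes whose mean raw count
within a (species, substrate) replicate group falls strictly below the
low-count threshold are considered not transcribed in that condition and
masked to zero; per-sample size factors are the median across reference
genes of the ratio count / per-gene geometric mean (genes containing a zero
in any sample are excluded from the reference set); expression is then
log2(count / factor + 1), so masked zeros map to exactly 0.

Regulation calls are plain threshold rules on linear fold changes of
size-factor-normalized replicate means versus the control substrate, with a
pseudocount of 1 in numerator and denominator; |FC| >= 4 calls a gene up
(or down, for FC <= 1/4). No dispersion estimation or hypothesis testing is
involved.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def mask_low_counts(counts: pd.DataFrame, sample_info: pd.DataFrame,
                    threshold: float = 5.0) -> pd.DataFrame:
    """Zero out genes not transcribed in a condition.

    For each gene and each (species, substrate) replicate group, if the mean
    raw count across the group's samples is strictly below ``threshold``,
    that group's counts for the gene are set to 0. Idempotent.
    """
    missing = [c for c in counts.columns if c not in sample_info.index]
    if missing:
        raise ValueError(f"samples missing from sample info: {missing}")
    info = sample_info.loc[counts.columns]
    out = counts.copy()
    for (_, _), group in info.groupby(["species", "substrate"], sort=False):
        cols = list(group.index)
        if not cols:
            raise ValueError("condition with zero samples")
        low = counts[cols].mean(axis=1) < threshold
        out.loc[low, cols] = 0
    return out


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    factor_j = median over reference genes g of count_gj / geomean_g, where
    geomean_g is the geometric mean of gene g across samples and the
    reference set holds the genes with geomean > 0 (i.e. no zero anywhere).
    """
    values = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_counts = np.log(values)
    log_geomean = log_counts.mean(axis=1)  # -inf where any zero
    reference = np.isfinite(log_geomean)
    if not reference.any():
        raise ValueError("no reference gene with all-positive counts")
    log_ratios = log_counts[reference] - log_geomean[reference, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_log2(counts: pd.DataFrame, factors: pd.Series,
                   pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(count / size factor + pseudocount), per sample."""
    missing = [c for c in counts.columns if c not in factors.index]
    if missing:
        raise ValueError(f"no size factor for samples: {missing}")
    f = factors.loc[counts.columns]
    if (f <= 0).any():
        raise ValueError("size factors must be strictly positive")
    return np.log2(counts.div(f, axis=1) + pseudocount)


def fold_changes(counts: pd.DataFrame, factors: pd.Series,
                 sample_info: pd.DataFrame, control: str = "maltose",
                 pseudocount: float = 1.0,
                 fc_threshold: float = 4.0) -> pd.DataFrame:
    """Per-gene linear fold changes vs the control substrate, with calls.

    FC = (mean normalized count on substrate + pseudocount) /
         (mean normalized count on control + pseudocount). Direction is
    ``up`` for FC >= fc_threshold, ``down`` for FC <= 1/fc_threshold, else
    ``none``. One row per (gene, non-control substrate).
    """
    info = sample_info.loc[counts.columns]
    if control not in set(info["substrate"]):
        raise ValueError(f"control substrate {control!r} has no samples")
    norm = counts.div(factors.loc[counts.columns], axis=1)
    means = {}
    for sub, group in info.groupby("substrate", sort=False):
        means[sub] = norm[list(group.index)].mean(axis=1)
    ctrl = means[control] + pseudocount
    frames = []
    for sub in means:
        if sub == control:
            continue
        fc = (means[sub] + pseudocount) / ctrl
        direction = np.where(fc >= fc_threshold, "up",
                             np.where(fc <= 1.0 / fc_threshold, "down",
                                      "none"))
        frames.append(pd.DataFrame({
            "gene_id": counts.index, "substrate": sub,
            "fold_change": fc.to_numpy(),
            "log2_fc": np.log2(fc.to_numpy()),
            "direction": direction,
        }))
    calls = pd.concat(frames, ignore_index=True)
    return calls
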