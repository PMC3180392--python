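"""Per-probe batch-effect diagnostics.

For each probe, a one-way ANOVA F statistic compares the between-batch and
within-batch mean squares of that probe's residuals (or normalized log2
values).  Under no batch effect F follows an F(B-1, N-B) distribution, so the
fraction of probes significant at level alpha estimates the extent of batch
effects in a dataset.  Significance is an unadjusted p < alpha by default; a
Benjamini-Hochberg adjusted fraction is reported alongside.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

__all__ = ["BatchEffectReport", "probe_f_statistics"]


@dataclasses.dataclass
class BatchEffectReport:
    f_stat: np.ndarray
    p_value: np.ndarray
    fraction_significant: float
    fraction_significant_bh: float
    alpha: float
    batch_sizes: dict[str, int]
    df_between: int
    df_within: int


def probe_f_statistics(
    values: np.ndarray,
    batch_labels: np.ndarray,
    alpha: float = 0.05,
) -> BatchEffectReport:
    """One-way ANOVA per probe across batches.

    ``values`` is probes x arrays (residuals from the probe-level fit, or a
    normalized log2 matrix).  Batches with fewer than 2 arrays are excluded,
    mirroring training; at least 2 usable batches are required.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be a probes x arrays matrix")
    labels = np.asarray(batch_labels)
    if labels.size != values.shape[1]:
        raise ValueError("one batch label per array is required")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")

    uniq = sorted(set(labels.tolist()))
    groups = [(b, np.flatnonzero(labels == b)) for b in uniq]
    groups = [(b, g) for b, g in groups if g.size >= 2]
    if len(groups) < 2:
        raise ValueError(f"need >= 2 batches with >= 2 arrays; found {len(groups)}")

    cols = np.concatenate([g for _, g in groups])
    x = values[:, cols]
    sizes = np.array([g.size for _, g in groups], dtype=float)
    B, N = len(groups), int(sizes.sum())

    means = np.stack([values[:, g].mean(axis=1) for _, g in groups], axis=1)  # probes x B
    grand = x.mean(axis=1)
    ssb = np.sum(sizes[None, :] * (means - grand[:, None]) ** 2, axis=1)
    sst = np.sum((x - grand[:, None]) ** 2, axis=1)
    ssw = sst - ssb
    df_b, df_w = B - 1, N - B
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_b) / np.maximum(ssw / df_w, np.finfo(float).tiny)
    p = stats.f.sf(f, df_b, df_w)

    p_bh = stats.false_discovery_control(p, method="bh")
    return BatchEffectReport(
        f_stat=f,
        p_value=p,
        fraction_significant=float(np.mean(p < alpha)),
        fraction_significant_bh=float(np.mean(p_bh < alpha)),
        alpha=alpha,
        batch_sizes={str(b): int(g.size) for b, g in groups},
        df_between=df_b,
        df_within=df_w,
    )
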