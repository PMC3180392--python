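"""Apply frozen parameter vectors to new arrays, one at a time or in batches.

A new array is background corrected with its own normexp fit, quantile-mapped
onto the frozen reference distribution, log2 transformed, and summarized per
probeset by a robust precision-weighted mean of probe values minus their
frozen probe effects.  The base precision weight of probe j is
1 / (sigma_j^2 + tau_j^2), so probes known from training to be noisy within a
batch or inconsistent across batches contribute little; Huber weights on
standardized residuals additionally guard against outliers on the new array.

Because every quantity the estimate depends on is frozen, the result for an
array never changes with the composition of the batch it is processed in.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .probe_data import ExpressionResult, FrozenVectors, ModelConfig, ProbeMatrix
from .rma_core import adjust_background, estimate_background, normalize_to_reference

__all__ = ["frma_single", "frma_batch"]


def _huber_weights(std_resid: np.ndarray, c: float) -> np.ndarray:
    a = np.abs(std_resid)
    with np.errstate(divide="ignore"):
        return np.minimum(1.0, np.where(a > 0, c / a, np.inf))


def _summarize_probesets(
    y: np.ndarray,
    fv: FrozenVectors,
    config: ModelConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Robust weighted summarization of a normalized log2 matrix.

    ``y`` is n_probes x n_arrays in the bundle's canonical probe order.
    Returns (theta, se, weights): theta and se are n_probesets x n_arrays,
    weights n_probes x n_arrays.  Columns are independent: each array's IRLS
    stops by its own convergence criterion, so processing an array alone or
    with others gives the same answer.
    """
    n_arrays = y.shape[1]
    var = fv.within_batch_var + fv.between_batch_var
    var = np.maximum(var, np.finfo(float).tiny)
    sd = np.sqrt(var)
    theta_out = np.empty((fv.n_probesets, n_arrays))
    se_out = np.empty((fv.n_probesets, n_arrays))
    w_out = np.empty_like(y)

    for k, (_, sl) in enumerate(fv.probeset_slices()):
        z = y[sl] - fv.probe_effects[sl, None]
        v = var[sl]
        s = sd[sl]
        if z.shape[0] == 1:
            theta_out[k] = z[0]
            se_out[k] = np.sqrt(v[0])
            w_out[sl] = 1.0
            continue
        base_w = (1.0 / v)[:, None]
        theta = np.sum(base_w * z, axis=0) / np.sum(base_w, axis=0)
        active = np.ones(n_arrays, dtype=bool)
        for _ in range(config.max_iter):
            hw = _huber_weights((z - theta) / s[:, None], config.huber_c)
            w = base_w * hw
            theta_new = np.sum(w * z, axis=0) / np.sum(w, axis=0)
            delta = np.abs(theta_new - theta)
            theta = np.where(active, theta_new, theta)
            active &= delta >= 1e-8
            if not active.any():
                break
        # final weights evaluated at the converged estimate
        hw = _huber_weights((z - theta) / s[:, None], config.huber_c)
        w = base_w * hw
        theta_out[k] = theta
        se_out[k] = 1.0 / np.sqrt(np.sum(w, axis=0))
        w_out[sl] = w
    return theta_out, se_out, w_out


def _prepare_column(column: np.ndarray, fv: FrozenVectors, config: ModelConfig) -> np.ndarray:
    """Background-correct one raw array and quantile-map it onto the frozen
    reference; returns the normalized log2 column."""
    column = np.asarray(column, dtype=float)
    if column.size != fv.n_probes:
        raise ValueError(
            f"array has {column.size} probes but the frozen vectors expect {fv.n_probes}"
        )
    if config.background_correct:
        column = adjust_background(column, estimate_background(column))
    return normalize_to_reference(np.log2(column), fv.reference_distribution)


def frma_single(
    column: np.ndarray,
    fv: FrozenVectors,
    config: ModelConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray | None]:
    """Preprocess a single raw array against frozen vectors.

    Returns ``(expression, stderr, probe_weights, quality)`` where expression
    and stderr are per probeset (log2 scale), probe_weights per probe, and
    quality the per-probeset ratio SE / frozen median SE (None when the
    bundle has no median-SE vector).
    """
    config = config or ModelConfig()
    y = _prepare_column(column, fv, config)[:, None]
    theta, se, w = _summarize_probesets(y, fv, config)
    quality = None
    if fv.median_se is not None:
        quality = se[:, 0] / fv.median_se
    return theta[:, 0], se[:, 0], w[:, 0], quality


def frma_batch(
    pm: ProbeMatrix,
    fv: FrozenVectors,
    config: ModelConfig | None = None,
) -> ExpressionResult:
    """Preprocess each array of ``pm`` independently against frozen vectors.

    Column i of the result equals :func:`frma_single` on array i; nothing is
    shared between arrays.
    """
    config = config or ModelConfig()
    if list(pm.probe_ids) != list(fv.probe_ids):
        raise ValueError("probe ids/order of the matrix do not match the frozen vectors")
    y = np.empty_like(pm.intensities)
    for i in range(pm.n_arrays):
        y[:, i] = _prepare_column(pm.intensities[:, i], fv, config)
    theta, se, w = _summarize_probesets(y, fv, config)
    ps_index = pd.Index(fv.probeset_ids, name="probeset")
    quality = None
    if fv.median_se is not None:
        quality = pd.DataFrame(se / fv.median_se[:, None], index=ps_index, columns=pm.array_ids)
    return ExpressionResult(
        expression=pd.DataFrame(theta, index=ps_index, columns=pm.array_ids),
        stderr=pd.DataFrame(se, index=ps_index, columns=pm.array_ids),
        probe_weights=pd.DataFrame(w, index=pd.Index(pm.probe_ids, name="probe"),
                                   columns=pm.array_ids),
        quality=quality,
    )
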