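"""Training of frozen parameter vectors from a batch-labelled probe matrix.

The probe-level model on the normalized log2 scale is

    Y[j, i] = theta_i + phi_j + gamma_{j, k(i)} + eps_{j, i}

with array effect theta, probe effect phi (sum-to-zero within a probeset),
a probe-specific batch shift gamma with variance tau_j^2, and probe noise
eps with variance sigma_j^2.  phi and theta are estimated per probeset by a
robust two-way additive fit (Huber IRLS, MAD scale); the variance components
come from a method-of-moments decomposition of the fit residuals over
batches.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .frma_engine import _huber_weights, _summarize_probesets
from .probe_data import FrozenVectors, ModelConfig, ProbeMatrix, FORMAT_VERSION
from .rma_core import background_correct, build_reference, normalize_to_reference

__all__ = ["ProbeLevelFit", "fit_probe_effects", "estimate_batch_variances", "make_vectors"]


@dataclasses.dataclass
class ProbeLevelFit:
    """Robust two-way additive fit of one probeset's log2 submatrix."""

    probe_effects: np.ndarray  # phi, sum-to-zero
    array_effects: np.ndarray  # theta, one per training array
    residuals: np.ndarray      # probes x arrays, log2 scale
    converged: bool
    n_iterations: int


def fit_probe_effects(Y: np.ndarray, config: ModelConfig | None = None) -> ProbeLevelFit:
    """Fit Y[j,i] ~ theta_i + phi_j by iteratively reweighted least squares
    with Huber weights; the scale is re-estimated each iteration from the
    MAD of the residuals.

    phi is centered to sum to zero; theta absorbs the probeset mean.  A
    single-probe probeset degenerates to phi = 0, theta = Y[0].
    """
    config = config or ModelConfig()
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[0] < 1:
        raise ValueError("Y must be a probes x arrays matrix with >= 1 probe")
    J, I = Y.shape
    if I < 3:
        raise ValueError("need at least 3 arrays to fit probe effects")
    if J == 1:
        return ProbeLevelFit(
            probe_effects=np.zeros(1),
            array_effects=Y[0].copy(),
            residuals=np.zeros_like(Y),
            converged=True,
            n_iterations=0,
        )

    theta = np.median(Y, axis=0)
    phi = np.median(Y - theta[None, :], axis=1)
    shift = phi.mean()
    phi -= shift
    theta = theta + shift

    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        resid = Y - theta[None, :] - phi[:, None]
        med = np.median(resid)
        scale = max(1.4826 * np.median(np.abs(resid - med)), 1e-10)
        w = _huber_weights(resid / scale, config.huber_c)

        theta_new = np.sum(w * (Y - phi[:, None]), axis=0) / np.sum(w, axis=0)
        phi_new = np.sum(w * (Y - theta_new[None, :]), axis=1) / np.sum(w, axis=1)
        shift = phi_new.mean()
        phi_new -= shift
        theta_new = theta_new + shift

        delta = max(np.max(np.abs(theta_new - theta)), np.max(np.abs(phi_new - phi)))
        theta, phi = theta_new, phi_new
        if delta < config.convergence_tol:
            converged = True
            break
    return ProbeLevelFit(
        probe_effects=phi,
        array_effects=theta,
        residuals=Y - theta[None, :] - phi[:, None],
        converged=converged,
        n_iterations=it,
    )


def estimate_batch_variances(
    residuals: np.ndarray,
    batch_labels: np.ndarray,
    config: ModelConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Within- and between-batch variance components per probe.

    sigma^2_j averages the within-batch sample variances of probe j's
    residuals over batches; tau^2_j is the variance of probe j's batch-mean
    residuals minus the sampling contribution sigma^2_j / k~, where k~ is
    the harmonic mean batch size (the textbook balanced-design estimator
    when batch sizes are equal).  Batches with fewer than 2 arrays are
    excluded; both components are floored at ``variance_floor``.
    """
    config = config or ModelConfig()
    residuals = np.asarray(residuals, dtype=float)
    labels = np.asarray(batch_labels)
    if residuals.shape[1] != labels.size:
        raise ValueError("one batch label per array is required")
    uniq = sorted(set(labels.tolist()))
    groups = [np.flatnonzero(labels == b) for b in uniq]
    groups = [g for g in groups if g.size >= 2]
    if len(groups) < 2:
        raise ValueError(
            f"need >= 2 batches with >= 2 arrays; found {len(groups)} usable "
            f"of {len(uniq)} total"
        )
    sizes = np.array([g.size for g in groups], dtype=float)
    k_tilde = len(groups) / np.sum(1.0 / sizes)

    within = np.stack([np.var(residuals[:, g], axis=1, ddof=1) for g in groups])
    means = np.stack([np.mean(residuals[:, g], axis=1) for g in groups])
    sigma2 = np.maximum(within.mean(axis=0), config.variance_floor)
    between = np.var(means, axis=0, ddof=1)
    tau2 = np.maximum(between - sigma2 / k_tilde, config.variance_floor)
    return sigma2, tau2


def make_vectors(pm: ProbeMatrix, config: ModelConfig | None = None) -> FrozenVectors:
    """Train all frozen parameter vectors from a batch-labelled training set.

    Pipeline: normexp background correction per array; reference distribution
    from the mean order statistics of all training arrays; quantile
    normalization of every array to that reference; log2; per probeset a
    robust probe-effect fit followed by the batch variance decomposition.
    The per-probeset average SD is the mean over the probeset's probes of
    sqrt(sigma_j^2 + tau_j^2).  When ``config.compute_median_se`` is set the
    frozen model is applied back to each training array and the per-probeset
    median standard error is stored as the optional sixth vector (the
    denominator of the quality score).
    """
    config = config or ModelConfig()
    if pm.batch_of is None:
        raise ValueError("training requires batch labels")
    labels = np.asarray([pm.batch_of[a] for a in pm.array_ids])

    keep = pm
    dropped: list[str] = []
    for _attempt in range(2):
        corrected = background_correct(keep) if config.background_correct else keep.intensities
        ref_raw = build_reference(corrected)
        y = np.empty_like(corrected)
        for i in range(keep.n_arrays):
            y[:, i] = normalize_to_reference(corrected[:, i], ref_raw)
        y = np.log2(y)

        slices = keep.probeset_slices()
        bad: list[str] = []
        fits: dict[str, tuple[ProbeLevelFit, np.ndarray, np.ndarray]] = {}
        for ps, sl in slices:
            try:
                fit = fit_probe_effects(y[sl], config)
                s2, t2 = estimate_batch_variances(fit.residuals, labels, config)
            except ValueError:
                bad.append(ps)
                continue
            fits[ps] = (fit, s2, t2)
        if not bad:
            break
        dropped.extend(bad)
        keep_rows = ~np.isin(keep.probeset_of.astype(str), np.asarray(bad, dtype=str))
        keep = ProbeMatrix(
            intensities=keep.intensities[keep_rows],
            probe_ids=keep.probe_ids[keep_rows],
            probeset_of=keep.probeset_of[keep_rows],
            array_ids=keep.array_ids,
            batch_of=keep.batch_of,
        )
    if not fits:
        raise ValueError("no probeset could be fitted")

    phi = np.empty(keep.n_probes)
    sigma2 = np.empty(keep.n_probes)
    tau2 = np.empty(keep.n_probes)
    avg_sd = np.empty(len(fits))
    ps_ids = []
    for k, (ps, sl) in enumerate(keep.probeset_slices()):
        fit, s2, t2 = fits[ps]
        phi[sl] = fit.probe_effects
        sigma2[sl] = s2
        tau2[sl] = t2
        avg_sd[k] = np.mean(np.sqrt(s2 + t2))
        ps_ids.append(ps)

    fv = FrozenVectors(
        reference_distribution=np.log2(ref_raw),
        probe_effects=phi,
        within_batch_var=sigma2,
        between_batch_var=tau2,
        probeset_avg_sd=avg_sd,
        probe_ids=keep.probe_ids,
        probeset_of=keep.probeset_of,
        probeset_ids=np.asarray(ps_ids, dtype=object),
        median_se=None,
        metadata={
            "n_training_arrays": int(keep.n_arrays),
            "n_batches": int(len(set(labels.tolist()))),
            "seed": config.seed,
            "format_version": FORMAT_VERSION,
            "dropped_probesets": dropped,
        },
    )

    if config.compute_median_se:
        # self-application: the frozen model summarizes the (already
        # normalized) training arrays, giving each probeset's SE per array
        _, se, _ = _summarize_probesets(y, fv, config)
        fv.median_se = np.median(se, axis=1)
        fv.validate()
    return fv
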