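"""Benchmark metrics for preprocessing methods.

Accuracy is the *signal detection slope*: the least-squares slope of observed
expression on log2 nominal concentration, per spiked probeset, summarized
within low/medium/high concentration strata (1 is ideal: an observed log
fold change equal to the true one).  Precision comes from *null log-ratios*
-- expression differences of non-spiked probesets between comparison arrays:
their SD, and the 99.5th percentile of their absolute values, which exactly
0.5% of null ratios exceed by construction.  SNR = slope / null SD, and POT
is the probability that a probeset with a true log2 fold change of 2 lands
in the top-100 list ranked by observed absolute fold change.

Reproducibility of frozen vectors themselves is measured by the MAD
consistency protocol: train repeatedly on resampled balanced training sets,
preprocess one held-out array with each training, and summarize the
median absolute deviation of each probeset's estimate across trainings.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .frma_engine import frma_single
from .probe_data import ModelConfig, ProbeMatrix, balanced_sample
from .vector_training import make_vectors

__all__ = [
    "ConsistencyReport",
    "StratumMetrics",
    "signal_detect_slope",
    "null_log_ratio_stats",
    "snr_and_pot",
    "consistency_mad",
    "run_consistency_experiment",
    "adjacent_pairs",
    "within_block_pairs",
]

_MAD_SCALE = 1.4826


@dataclasses.dataclass
class StratumMetrics:
    """One expression stratum's row of the benchmark table."""

    stratum: str
    slope: float
    slope_sd: float
    null_sd: float
    null_q995: float
    snr: float
    pot: float


@dataclasses.dataclass
class ConsistencyReport:
    mads: pd.Series
    median_mad: float
    iqr_mad: float
    n_batches: int | None = None
    batch_size: int | None = None
    n_replicates: int | None = None

    def cell(self) -> str:
        """'median (IQR)' formatting of the summary."""
        return f"{self.median_mad:.4f} ({self.iqr_mad:.4f})"


# ---------------------------------------------------------------------------
# Spike-in metrics
# ---------------------------------------------------------------------------


def concentration_strata(concentrations: np.ndarray, n_strata: int = 3) -> list[np.ndarray]:
    """Split the distinct nonzero concentrations into contiguous tertiles
    (or ``n_strata`` chunks): low, medium, high."""
    distinct = np.unique(np.asarray(concentrations, float))
    distinct = distinct[distinct > 0]
    if distinct.size < n_strata:
        raise ValueError("fewer distinct nonzero concentrations than strata")
    return [np.asarray(c) for c in np.array_split(distinct, n_strata)]


def signal_detect_slope(
    expression: pd.DataFrame,
    nominal_concentrations: pd.DataFrame,
    strata: int | Sequence[np.ndarray] = 3,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Per-stratum signal detection slopes.

    For every spiked probeset and stratum, regress its expression on
    log2(concentration) over the arrays whose nominal concentration for that
    probeset falls in the stratum; report the mean and SD of the slopes over
    probesets.  Probesets with fewer than 2 distinct concentrations in a
    stratum are excluded from it.
    """
    nominal = nominal_concentrations
    if isinstance(strata, int):
        strata_list = concentration_strata(nominal.to_numpy().ravel(), strata)
    else:
        strata_list = [np.asarray(s, float) for s in strata]
    names = _stratum_names(len(strata_list))
    cols = [c for c in nominal.columns if c in set(expression.columns)]
    if len(cols) != nominal.shape[1]:
        raise ValueError("expression is missing arrays present in the nominal table")

    slopes: dict[str, list[float]] = {nm: [] for nm in names}
    for ps in nominal.index:
        if ps not in expression.index:
            raise ValueError(f"spiked probeset {ps!r} missing from expression")
        conc = nominal.loc[ps, cols].to_numpy(dtype=float)
        y_all = expression.loc[ps, cols].to_numpy(dtype=float)
        for nm, stratum in zip(names, strata_list):
            mask = np.isin(conc, stratum)
            if np.unique(conc[mask]).size < 2:
                continue
            x = np.log2(conc[mask])
            slopes[nm].append(float(np.polyfit(x, y_all[mask], 1)[0]))
    rows = []
    for nm in names:
        s = np.asarray(slopes[nm], float)
        if s.size == 0:
            raise ValueError(f"no probeset usable in stratum {nm}")
        rows.append({"stratum": nm, "slope": s.mean(),
                     "slope_sd": s.std(ddof=1) if s.size > 1 else 0.0,
                     "n_probesets": s.size})
    return pd.DataFrame(rows).set_index("stratum"), {k: np.asarray(v) for k, v in slopes.items()}


def _stratum_names(n: int) -> list[str]:
    if n == 3:
        return ["low", "medium", "high"]
    return [f"stratum{i}" for i in range(n)]


def adjacent_pairs(array_ids: Sequence[str], batch_of: dict[str, str]) -> list[tuple[str, str]]:
    """Adjacent-array comparison pairs within each replicate block."""
    blocks: dict[str, list[str]] = {}
    for a in array_ids:
        blocks.setdefault(batch_of[a], []).append(a)
    pairs = []
    for b in sorted(blocks):
        arrs = blocks[b]
        pairs.extend((arrs[i], arrs[i + 1]) for i in range(len(arrs) - 1))
    return pairs


def within_block_pairs(array_ids: Sequence[str], batch_of: dict[str, str]) -> list[tuple[str, str]]:
    """All unordered array pairs within each replicate block."""
    blocks: dict[str, list[str]] = {}
    for a in array_ids:
        blocks.setdefault(batch_of[a], []).append(a)
    pairs = []
    for b in sorted(blocks):
        arrs = blocks[b]
        pairs.extend((arrs[i], arrs[j]) for i in range(len(arrs)) for j in range(i + 1, len(arrs)))
    return pairs


def null_log_ratio_stats(
    null_expression: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
) -> tuple[float, float]:
    """SD and 99.5th percentile of null log-ratios.

    Log-ratios are expression differences of non-spiked probesets over the
    comparison pairs.  The 99.5th percentile is the order statistic at rank
    ceil(0.995 n), so with no ties exactly 0.5% of the absolute ratios lie
    strictly above it.
    """
    mat = null_expression.to_numpy(dtype=float)
    col = {a: i for i, a in enumerate(null_expression.columns)}
    ratios = np.concatenate([mat[:, col[a]] - mat[:, col[b]] for a, b in pairs])
    if ratios.size < 200:
        raise ValueError(f"only {ratios.size} null log-ratios; need >= 200")
    sd = float(np.std(ratios, ddof=1))
    abs_sorted = np.sort(np.abs(ratios))
    idx = int(np.ceil(0.995 * ratios.size)) - 1
    return sd, float(abs_sorted[idx])


def snr_and_pot(
    slope: float,
    null_sd: float,
    expression: pd.DataFrame,
    nominal_concentrations: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    list_size: int = 100,
    target_lfc: float = 2.0,
) -> tuple[float, float]:
    """Signal-to-noise ratio and probability-of-top-list.

    snr = slope / null_sd.  POT: over all comparison pairs in which some
    spiked probeset has a true log2 concentration ratio of ``target_lfc``
    (both concentrations nonzero), the fraction of those probesets ranked in
    the top ``list_size`` by observed absolute fold change among all
    probesets.
    """
    if null_sd == 0:
        raise ValueError("null_sd is zero; SNR undefined")
    snr = slope / null_sd
    col = {a: i for i, a in enumerate(expression.columns)}
    mat = expression.to_numpy(dtype=float)
    spiked = [ps for ps in nominal_concentrations.index]
    ps_row = {ps: i for i, ps in enumerate(expression.index)}
    hits = 0
    total = 0
    for a, b in pairs:
        ca = nominal_concentrations[a].to_numpy(dtype=float)
        cb = nominal_concentrations[b].to_numpy(dtype=float)
        ok = (ca > 0) & (cb > 0)
        with np.errstate(divide="ignore"):
            lfc = np.where(ok, np.abs(np.log2(np.where(ok, ca, 1.0) / np.where(ok, cb, 1.0))), np.nan)
        qualifying = [spiked[i] for i in np.flatnonzero(ok & np.isclose(lfc, target_lfc))]
        if not qualifying:
            continue
        fc = np.abs(mat[:, col[a]] - mat[:, col[b]])
        top = set(np.argsort(fc)[::-1][:list_size])
        hits += sum(1 for ps in qualifying if ps_row[ps] in top)
        total += len(qualifying)
    if total == 0:
        raise ValueError(f"no comparison pair carries a true log2 fold change of {target_lfc}")
    return float(snr), hits / total


def spikein_report(
    expression: pd.DataFrame,
    nominal_concentrations: pd.DataFrame,
    batch_of: dict[str, str],
    list_size: int = 100,
    target_lfc: float = 2.0,
    n_strata: int = 3,
) -> list[StratumMetrics]:
    """Full benchmark table for one method on one spike-in dataset."""
    summary, _ = signal_detect_slope(expression, nominal_concentrations, n_strata)
    null_ps = [p for p in expression.index if p not in set(nominal_concentrations.index)]
    pairs_null = adjacent_pairs(list(expression.columns), batch_of)
    null_sd, q995 = null_log_ratio_stats(expression.loc[null_ps], pairs_null)
    pairs_all = within_block_pairs(list(expression.columns), batch_of)
    out = []
    for nm, row in summary.iterrows():
        snr, pot = snr_and_pot(row["slope"], null_sd, expression,
                               nominal_concentrations, pairs_all,
                               list_size=list_size, target_lfc=target_lfc)
        out.append(StratumMetrics(stratum=str(nm), slope=float(row["slope"]),
                                  slope_sd=float(row["slope_sd"]), null_sd=null_sd,
                                  null_q995=q995, snr=snr, pot=pot))
    return out


# ---------------------------------------------------------------------------
# MAD consistency protocol
# ---------------------------------------------------------------------------


def consistency_mad(replicate_expressions: Sequence[pd.Series]) -> ConsistencyReport:
    """Per-probeset MAD of expression across replicate trainings.

    MAD uses the 1.4826 normal-consistency constant.  The report summarizes
    the MADs by their median and inter-quartile range.
    """
    if len(replicate_expressions) < 2:
        raise ValueError("need at least 2 replicates")
    first = replicate_expressions[0].index
    for s in replicate_expressions[1:]:
        if not first.equals(s.index):
            raise ValueError("replicates cover different probeset sets")
    mat = np.column_stack([s.to_numpy(dtype=float) for s in replicate_expressions])
    med = np.median(mat, axis=1)
    mads = _MAD_SCALE * np.median(np.abs(mat - med[:, None]), axis=1)
    series = pd.Series(mads, index=first, name="mad")
    q75, q25 = np.percentile(mads, [75, 25])
    return ConsistencyReport(
        mads=series,
        median_mad=float(np.median(mads)),
        iqr_mad=float(q75 - q25),
        n_replicates=len(replicate_expressions),
    )


def run_consistency_experiment(
    pool: ProbeMatrix,
    designs: Sequence[tuple[int, int]],
    n_replicates: int,
    test_array: np.ndarray,
    seed: int,
    config: ModelConfig | None = None,
) -> list[ConsistencyReport]:
    """Reproducibility of frozen-vector training across resampled trainings.

    For each (n_batches, batch_size) design: draw ``n_replicates`` balanced
    samples from the pool, train frozen vectors on each, preprocess the one
    held-out ``test_array`` with each training, and summarize the spread of
    each probeset's estimate by the MAD protocol.  Training here skips the
    optional median-SE vector, which the consistency measure does not use.
    """
    base = config or ModelConfig()
    config = dataclasses.replace(base, compute_median_se=False)
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=(len(designs), n_replicates))
    reports = []
    for d, (n_batches, batch_size) in enumerate(designs):
        replicates = []
        for r in range(n_replicates):
            train = balanced_sample(pool, n_batches, batch_size, int(sub_seeds[d, r]))
            fv = make_vectors(train, config)
            theta, _, _, _ = frma_single(test_array, fv, config)
            replicates.append(pd.Series(theta, index=fv.probeset_ids))
        rep = consistency_mad(replicates)
        rep.n_batches, rep.batch_size = n_batches, batch_size
        reports.append(rep)
    return reports
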