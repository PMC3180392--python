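"""Synthetic probe-level data with known ground truth.

Two generators share one additive probe-level model on the log2 scale,

    log2 signal[j, i] = level[m(j), i] + phi_j + theta_i + gamma_{j, k(i)} + eps_{j, i}

where level is the probeset's expression level (a constant for null probesets,
a concentration response for spiked ones), phi a probe affinity effect,
theta a small array effect, gamma a probe-specific batch shift redrawn per
batch (SD tau_j), and eps probe noise (SD sigma_j).  The signal is
exponentiated back to the raw scale and optical background noise is added, so
the full pipeline from background correction onward is exercised.

``simulate_spikein`` lays concentrations out as a cyclic latin square --
every concentration appears exactly once per transcript group and once per
array within a replicate block -- and replicates the block across batches,
emulating a spike-in benchmark with probe-specific noise and batch effects.
``simulate_training_set`` produces generic batch-labelled training pools for
parameter-recovery and consistency experiments.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .probe_data import ProbeMatrix

__all__ = [
    "NoiseConfig",
    "SpikeInDesign",
    "SpikeInTruth",
    "make_latin_square",
    "simulate_spikein",
    "simulate_training_set",
]


@dataclasses.dataclass
class NoiseConfig:
    """Distributions of the generator's random components.

    Probe noise SDs sigma_j are drawn from a scaled chi distribution with
    ``chi_df`` degrees of freedom rescaled to mean ``sigma_mean`` (or held
    fixed at ``sigma_mean`` when ``sigma_dispersed`` is off).  Batch-shift
    SDs tau_j are zero for a fraction ``tau_zero_fraction`` of probes (stable
    probes) and otherwise drawn the same way around ``tau_mean``.  Arrays
    carry a small individual brightness effect (``theta_sd``) plus a shared
    batch-level brightness drift (``batch_brightness_sd``), emulating
    scan-date differences in overall intensity.  Optical
    background is additive Normal(bg_mu, bg_sd) on the raw scale, and the
    detector response saturates softly toward the 16-bit scanner ceiling
    (``saturation``; 0 disables).

    A fraction ``off_fraction`` of (non-spiked) probesets is unexpressed:
    their probes measure optical background only, with no signal and hence no
    probe-affinity, noise or batch-shift footprint (their true phi, sigma and
    tau are all zero).  This low-intensity population is what identifies the
    background parameters on real arrays, so the generator reproduces it.
    """

    sigma_mean: float = 0.25
    sigma_dispersed: bool = True
    tau_mean: float = 0.5
    tau_dispersed: bool = True
    tau_zero_fraction: float = 0.6
    chi_df: int = 4
    phi_sd: float = 0.5
    theta_sd: float = 0.2
    batch_brightness_sd: float = 0.1
    baseline_low: float = 8.0
    baseline_high: float = 12.0
    off_fraction: float = 0.3
    bg_mu: float = 40.0
    bg_sd: float = 6.0
    saturation: float = 65535.0

    @classmethod
    def noiseless(cls) -> "NoiseConfig":
        return cls(sigma_mean=0.0, sigma_dispersed=False, tau_mean=0.0,
                   tau_dispersed=False, tau_zero_fraction=1.0,
                   theta_sd=0.0, batch_brightness_sd=0.0, off_fraction=0.0,
                   bg_mu=0.0, bg_sd=0.0, saturation=0.0)


@dataclasses.dataclass
class SpikeInDesign:
    """Cyclic latin-square concentration layout for one replicate block."""

    n_groups: int
    concentrations: np.ndarray          # length n_groups, includes 0, pM
    assignment: np.ndarray              # groups x arrays, concentrations

    def __post_init__(self) -> None:
        n = self.n_groups
        if self.concentrations.shape != (n,) or self.assignment.shape != (n, n):
            raise ValueError("design dimensions inconsistent with n_groups")
        for axis in (0, 1):
            sums = self.assignment.sum(axis=axis)
            if not np.allclose(sums, sums[0]):
                raise ValueError("assignment is not a latin square")


@dataclasses.dataclass
class SpikeInTruth:
    """Everything needed to score recovery without re-simulating."""

    probe_effects: np.ndarray           # phi per probe, canonical order
    probe_sd: np.ndarray                # sigma_j
    batch_sd: np.ndarray                # tau_j
    batch_shifts: np.ndarray            # gamma, probes x batches
    array_effects: np.ndarray           # theta per array
    nominal: pd.DataFrame | None        # spiked probeset x array concentration
    is_off: np.ndarray                  # per probe: unexpressed (background only)
    seed: int


def make_latin_square(n_groups: int, base_conc: float = 0.125,
                      n_doublings: int | None = None) -> SpikeInDesign:
    """Cyclic latin square over a doubling concentration series including 0.

    Concentrations are (0, base, 2*base, ..., base * 2**n_doublings) with
    ``n_doublings = n_groups - 2`` so their count equals ``n_groups``; array i
    uses row 0 rotated by i, so each concentration appears exactly once per
    group and once per array.
    """
    if n_groups < 2:
        raise ValueError("need at least 2 concentration groups")
    if n_doublings is None:
        n_doublings = n_groups - 2
    conc = np.concatenate(([0.0], base_conc * 2.0 ** np.arange(n_doublings + 1)))
    if conc.size != n_groups:
        raise ValueError(
            f"{conc.size} concentrations (0 plus {n_doublings + 1} doublings) "
            f"do not match n_groups={n_groups}"
        )
    idx = (np.arange(n_groups)[:, None] + np.arange(n_groups)[None, :]) % n_groups
    return SpikeInDesign(n_groups=n_groups, concentrations=conc, assignment=conc[idx])


def _draw_sds(rng: np.random.Generator, n: int, mean: float, dispersed: bool,
              df: int) -> np.ndarray:
    if mean == 0.0:
        return np.zeros(n)
    if not dispersed:
        return np.full(n, mean)
    return mean * stats.chi.rvs(df, size=n, random_state=rng) / stats.chi.mean(df)


def _probe_layout(probeset_ids: list[str], probes_per_set: int) -> tuple[np.ndarray, np.ndarray]:
    ps = np.repeat(np.asarray(probeset_ids, dtype=object), probes_per_set)
    probes = np.asarray(
        [f"{p}_p{j:02d}" for p in probeset_ids for j in range(probes_per_set)],
        dtype=object,
    )
    return probes, ps


def _assemble(log2_signal: np.ndarray, is_off: np.ndarray,
              rng: np.random.Generator, cfg: NoiseConfig) -> np.ndarray:
    raw = 2.0 ** log2_signal
    raw[is_off] = 0.0
    if cfg.saturation:
        # soft scanner saturation toward the 16-bit detector ceiling
        raw = raw / (1.0 + raw / cfg.saturation)
    if cfg.bg_mu or cfg.bg_sd:
        raw = raw + rng.normal(cfg.bg_mu, cfg.bg_sd, size=raw.shape)
    return np.maximum(raw, 1e-6)


def simulate_spikein(
    design: SpikeInDesign,
    n_batches: int = 9,
    n_null_probesets: int = 300,
    probes_per_set: int = 4,
    noise_config: NoiseConfig | None = None,
    seed: int = 0,
    probesets_per_group: int = 3,
    spike_floor_log2: float = 6.0,
) -> tuple[ProbeMatrix, SpikeInTruth]:
    """Latin-square spike-in dataset: ``n_batches`` replicate blocks of
    ``design.n_groups`` arrays each, with probe-specific noise and batch
    effects.

    Spiked probesets respond with slope 1 in log2(concentration) above a soft
    floor at 0 pM: level = spike_floor + log2(1 + conc / base), where base is
    the smallest nonzero design concentration.  Null probesets sit at a
    constant level drawn per probeset, so they carry no true fold change
    between any pair of arrays.
    """
    cfg = noise_config or NoiseConfig()
    rng = np.random.default_rng(seed)
    G = design.n_groups
    n_arrays = n_batches * G

    null_ids = [f"nul{m:04d}" for m in range(n_null_probesets)]
    spike_ids = [f"spk{g:02d}r{r}" for g in range(G) for r in range(probesets_per_group)]
    probeset_ids = sorted(null_ids + spike_ids)
    probe_ids, probeset_of = _probe_layout(probeset_ids, probes_per_set)
    n_probes = probe_ids.size

    array_ids = [f"a{b:02d}_{i:02d}" for b in range(n_batches) for i in range(G)]
    batch_of = {a: a.split("_")[0].replace("a", "b") for a in array_ids}
    block_col = np.tile(np.arange(G), n_batches)     # position within the block
    batch_idx = np.repeat(np.arange(n_batches), G)

    base = float(design.concentrations[design.concentrations > 0].min())
    null_levels = dict(zip(null_ids, rng.uniform(cfg.baseline_low, cfg.baseline_high,
                                                 size=n_null_probesets)))
    # per-probeset level matrix
    level = np.empty((len(probeset_ids), n_arrays))
    nominal_rows = {}
    for m, ps in enumerate(probeset_ids):
        if ps.startswith("nul"):
            level[m] = null_levels[ps]
        else:
            g = int(ps[3:5])
            conc = design.assignment[g, block_col]
            level[m] = spike_floor_log2 + np.log2(1.0 + conc / base)
            nominal_rows[ps] = conc
    nominal = pd.DataFrame(nominal_rows, index=array_ids).T
    nominal.index.name = "probeset"

    # unexpressed null probesets measure background only
    off_ps = np.array([ps.startswith("nul") and rng.random() < cfg.off_fraction
                       for ps in probeset_ids])
    is_off = np.repeat(off_ps, probes_per_set)

    phi = rng.normal(0.0, cfg.phi_sd, size=n_probes) if cfg.phi_sd else np.zeros(n_probes)
    # center phi within probesets so truth matches the estimand
    for m in range(len(probeset_ids)):
        sl = slice(m * probes_per_set, (m + 1) * probes_per_set)
        phi[sl] -= phi[sl].mean()
    sigma = _draw_sds(rng, n_probes, cfg.sigma_mean, cfg.sigma_dispersed, cfg.chi_df)
    tau = _draw_sds(rng, n_probes, cfg.tau_mean, cfg.tau_dispersed, cfg.chi_df)
    tau[rng.random(n_probes) < cfg.tau_zero_fraction] = 0.0
    phi[is_off] = 0.0
    sigma[is_off] = 0.0
    tau[is_off] = 0.0
    theta = rng.normal(0.0, cfg.theta_sd, size=n_arrays) if cfg.theta_sd else np.zeros(n_arrays)
    if cfg.batch_brightness_sd:
        theta = theta + rng.normal(0.0, cfg.batch_brightness_sd, size=n_batches)[batch_idx]
    gamma = rng.normal(0.0, 1.0, size=(n_probes, n_batches)) * tau[:, None]
    eps = rng.normal(0.0, 1.0, size=(n_probes, n_arrays)) * sigma[:, None]

    probeset_row = np.repeat(np.arange(len(probeset_ids)), probes_per_set)
    log2_signal = (level[probeset_row] + phi[:, None] + theta[None, :]
                   + gamma[:, batch_idx] + eps)
    pm = ProbeMatrix(
        intensities=_assemble(log2_signal, is_off, rng, cfg),
        probe_ids=probe_ids,
        probeset_of=probeset_of,
        array_ids=np.asarray(array_ids, dtype=object),
        batch_of=batch_of,
    )
    truth = SpikeInTruth(probe_effects=phi, probe_sd=sigma, batch_sd=tau,
                         batch_shifts=gamma, array_effects=theta,
                         nominal=nominal, is_off=is_off, seed=seed)
    return pm, truth


def simulate_training_set(
    n_probesets: int,
    probes_per_set: int,
    n_batches: int,
    batch_size: int,
    effect_config: NoiseConfig | None = None,
    seed: int = 0,
) -> tuple[ProbeMatrix, SpikeInTruth]:
    """Generic batch-labelled training pool from the additive probe model.

    Probeset baselines are uniform on [baseline_low, baseline_high] log2
    units (moderately to highly expressed targets, so background correction
    distorts the signal little and probe effects are an honest estimand).
    """
    if n_batches < 2 or batch_size < 2:
        raise ValueError("need n_batches >= 2 and batch_size >= 2")
    cfg = effect_config or NoiseConfig()
    rng = np.random.default_rng(seed)
    n_arrays = n_batches * batch_size

    probeset_ids = [f"ps{m:04d}" for m in range(n_probesets)]
    probe_ids, probeset_of = _probe_layout(probeset_ids, probes_per_set)
    n_probes = probe_ids.size
    array_ids = [f"a{k:02d}_{i:02d}" for k in range(n_batches) for i in range(batch_size)]
    batch_of = {a: a.split("_")[0].replace("a", "b") for a in array_ids}
    batch_idx = np.repeat(np.arange(n_batches), batch_size)

    baseline = rng.uniform(cfg.baseline_low, cfg.baseline_high, size=n_probesets)
    off_ps = rng.random(n_probesets) < cfg.off_fraction
    is_off = np.repeat(off_ps, probes_per_set)
    phi = rng.normal(0.0, cfg.phi_sd, size=n_probes) if cfg.phi_sd else np.zeros(n_probes)
    for m in range(n_probesets):
        sl = slice(m * probes_per_set, (m + 1) * probes_per_set)
        phi[sl] -= phi[sl].mean()
    sigma = _draw_sds(rng, n_probes, cfg.sigma_mean, cfg.sigma_dispersed, cfg.chi_df)
    tau = _draw_sds(rng, n_probes, cfg.tau_mean, cfg.tau_dispersed, cfg.chi_df)
    tau[rng.random(n_probes) < cfg.tau_zero_fraction] = 0.0
    phi[is_off] = 0.0
    sigma[is_off] = 0.0
    tau[is_off] = 0.0
    theta = rng.normal(0.0, cfg.theta_sd, size=n_arrays) if cfg.theta_sd else np.zeros(n_arrays)
    if cfg.batch_brightness_sd:
        theta = theta + rng.normal(0.0, cfg.batch_brightness_sd, size=n_batches)[batch_idx]
    gamma = rng.normal(0.0, 1.0, size=(n_probes, n_batches)) * tau[:, None]
    eps = rng.normal(0.0, 1.0, size=(n_probes, n_arrays)) * sigma[:, None]

    probeset_row = np.repeat(np.arange(n_probesets), probes_per_set)
    log2_signal = (baseline[probeset_row][:, None] + phi[:, None] + theta[None, :]
                   + gamma[:, batch_idx] + eps)
    pm = ProbeMatrix(
        intensities=_assemble(log2_signal, is_off, rng, cfg),
        probe_ids=probe_ids,
        probeset_of=probeset_of,
        array_ids=np.asarray(array_ids, dtype=object),
        batch_of=batch_of,
    )
    truth = SpikeInTruth(probe_effects=phi, probe_sd=sigma, batch_sd=tau,
                         batch_shifts=gamma, array_effects=theta,
                         nominal=None, is_off=is_off, seed=seed)
    return pm, truth
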