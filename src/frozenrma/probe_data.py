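"""Data model and I/O for probe-level microarray data and frozen parameter bundles.

The package works from three plain-text inputs: a probe-by-array intensity
matrix (TSV, probe ids in the first column, array ids in the header), a
two-column probe-to-probeset annotation table, and an optional two-column
array-to-batch table.  Probe rows are kept in a canonical order -- sorted by
(probeset id, probe id) -- so that positions in every frozen parameter vector
are reproducible across runs and mismatched annotations are detectable.

Frozen parameter bundles are directories holding a JSON metadata file plus one
TSV per vector; they are diffable and lossless at full double precision.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

FORMAT_VERSION = "1"

#: file names inside a frozen-vector bundle directory
_BUNDLE_FILES = {
    "reference_distribution": "reference_distribution.tsv",
    "probe_effects": "probe_effects.tsv",
    "within_batch_var": "within_batch_var.tsv",
    "between_batch_var": "between_batch_var.tsv",
    "probeset_avg_sd": "probeset_avg_sd.tsv",
    "median_se": "median_se.tsv",
}
MANDATORY_VECTORS = (
    "reference_distribution",
    "probe_effects",
    "within_batch_var",
    "between_batch_var",
    "probeset_avg_sd",
)


@dataclasses.dataclass
class ModelConfig:
    """Tuning constants for robust fitting and diagnostics.

    Parameters
    ----------
    huber_c : float
        Huber tuning constant for the M-estimation loops, on the scale of
        standardized residuals.  1.345 gives 95% efficiency under normality.
    max_iter : int
        Iteration cap for the IRLS loops.
    convergence_tol : float
        Convergence tolerance on the maximum absolute parameter change
        (log2 units).
    variance_floor : float
        Lower bound applied to every variance estimate (log2^2 units); keeps
        precision weights finite.
    alpha : float
        Significance level used by the batch-effect diagnostics.
    seed : int or None
        Seed recorded in training metadata.
    compute_median_se : bool
        Whether ``make_vectors`` also produces the optional median
        standard-error vector (needed for quality scores).
    background_correct : bool
        Whether training and application normexp-correct raw intensities.
        Estimating background parameters requires arrays with a genuine
        low-intensity population; switch off for idealized data without one.
    """

    huber_c: float = 1.345
    max_iter: int = 50
    convergence_tol: float = 1e-6
    variance_floor: float = 1e-6
    alpha: float = 0.05
    seed: int | None = None
    compute_median_se: bool = True
    background_correct: bool = True

    def __post_init__(self) -> None:
        if self.huber_c <= 0:
            raise ValueError("huber_c must be > 0")
        if self.variance_floor <= 0:
            raise ValueError("variance_floor must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclasses.dataclass
class ProbeMatrix:
    """Raw probe-level intensities with probe/probeset and batch annotation.

    ``intensities`` has one row per probe (canonical order) and one column per
    array.  ``probeset_of`` is aligned with the rows.  All intensities are
    finite and strictly positive (raw fluorescence scale).
    """

    intensities: np.ndarray
    probe_ids: np.ndarray
    probeset_of: np.ndarray
    array_ids: np.ndarray
    batch_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.probeset_of = np.asarray(self.probeset_of, dtype=object)
        self.array_ids = np.asarray(self.array_ids, dtype=object)
        if self.intensities.shape != (len(self.probe_ids), len(self.array_ids)):
            raise ValueError("intensity matrix shape does not match probe/array ids")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("duplicate probe id")
        if len(set(self.array_ids)) != len(self.array_ids):
            raise ValueError("duplicate array id")
        if not np.all(np.isfinite(self.intensities)):
            bad = np.argwhere(~np.isfinite(self.intensities))[0]
            raise ValueError(
                f"non-finite intensity at probe {self.probe_ids[bad[0]]!r}, "
                f"array {self.array_ids[bad[1]]!r}"
            )
        if np.any(self.intensities <= 0):
            bad = np.argwhere(self.intensities <= 0)[0]
            raise ValueError(
                f"non-positive intensity at probe {self.probe_ids[bad[0]]!r}, "
                f"array {self.array_ids[bad[1]]!r} (raw intensities must be > 0)"
            )
        if self.batch_of is not None:
            missing = [a for a in self.array_ids if a not in self.batch_of]
            if missing:
                raise ValueError(f"arrays without batch label: {missing}")
        self._canonicalize()

    def _canonicalize(self) -> None:
        order = np.lexsort((self.probe_ids.astype(str), self.probeset_of.astype(str)))
        self.intensities = self.intensities[order]
        self.probe_ids = self.probe_ids[order]
        self.probeset_of = self.probeset_of[order]

    # -- convenience accessors -------------------------------------------------

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_arrays(self) -> int:
        return len(self.array_ids)

    @property
    def probeset_ids(self) -> np.ndarray:
        """Unique probeset ids in canonical (sorted) order."""
        seen = pd.unique(self.probeset_of)
        return np.asarray(sorted(seen), dtype=object)

    @property
    def n_probesets(self) -> int:
        return len(self.probeset_ids)

    def probeset_slices(self) -> list[tuple[str, slice]]:
        """(probeset id, row slice) pairs; rows of one probeset are contiguous."""
        ids = self.probeset_of
        out: list[tuple[str, slice]] = []
        start = 0
        for i in range(1, len(ids) + 1):
            if i == len(ids) or ids[i] != ids[start]:
                out.append((ids[start], slice(start, i)))
                start = i
        return out

    def batches(self) -> dict[str, list[str]]:
        """Batch label -> sorted list of array ids."""
        if self.batch_of is None:
            raise ValueError("ProbeMatrix has no batch labels")
        out: dict[str, list[str]] = {}
        for a in self.array_ids:
            out.setdefault(self.batch_of[a], []).append(a)
        return {k: sorted(v) for k, v in sorted(out.items())}

    def subset_arrays(self, array_ids: Sequence[str]) -> "ProbeMatrix":
        idx = {a: i for i, a in enumerate(self.array_ids)}
        cols = [idx[a] for a in array_ids]
        batch = None
        if self.batch_of is not None:
            batch = {a: self.batch_of[a] for a in array_ids}
        return ProbeMatrix(
            intensities=self.intensities[:, cols],
            probe_ids=self.probe_ids.copy(),
            probeset_of=self.probeset_of.copy(),
            array_ids=np.asarray(list(array_ids), dtype=object),
            batch_of=batch,
        )


@dataclasses.dataclass
class FrozenVectors:
    """The frozen parameter vectors that let a single new array be preprocessed.

    Five mandatory vectors: the reference normalization distribution (sorted,
    log2 scale of background-corrected intensities), per-probe effects phi
    (sum-to-zero within each probeset), per-probe within-batch residual
    variance sigma^2, per-probe between-batch residual variance tau^2, and the
    per-probeset average total probe SD.  A sixth, optional vector of median
    standard errors enables quality scoring of new arrays.
    """

    reference_distribution: np.ndarray
    probe_effects: np.ndarray
    within_batch_var: np.ndarray
    between_batch_var: np.ndarray
    probeset_avg_sd: np.ndarray
    probe_ids: np.ndarray
    probeset_of: np.ndarray
    probeset_ids: np.ndarray
    median_se: np.ndarray | None = None
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "reference_distribution",
            "probe_effects",
            "within_batch_var",
            "between_batch_var",
            "probeset_avg_sd",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.median_se is not None:
            self.median_se = np.asarray(self.median_se, dtype=float)
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.probeset_of = np.asarray(self.probeset_of, dtype=object)
        self.probeset_ids = np.asarray(self.probeset_ids, dtype=object)
        self.validate()

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_probesets(self) -> int:
        return len(self.probeset_ids)

    def validate(self) -> None:
        n, m = self.n_probes, self.n_probesets
        for name in ("reference_distribution", "probe_effects", "within_batch_var", "between_batch_var"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} has length {len(getattr(self, name))}, expected n_probes={n}")
        for name in ("probeset_avg_sd",) + (("median_se",) if self.median_se is not None else ()):
            if len(getattr(self, name)) != m:
                raise ValueError(f"{name} has length {len(getattr(self, name))}, expected n_probesets={m}")
        if len(self.probeset_of) != n:
            raise ValueError("probeset_of must align with probe_ids")
        if np.any(np.diff(self.reference_distribution) < 0):
            raise ValueError("reference_distribution must be nondecreasing")
        if np.any(self.within_batch_var < 0) or np.any(self.between_batch_var < 0):
            raise ValueError("variances must be >= 0")
        # phi sums to zero within each probeset
        sums = pd.Series(self.probe_effects).groupby(pd.Series(self.probeset_of.astype(str))).sum()
        if np.any(np.abs(sums.to_numpy()) > 1e-8):
            raise ValueError("probe effects must sum to zero within each probeset")

    def probeset_slices(self) -> list[tuple[str, slice]]:
        ids = self.probeset_of
        out: list[tuple[str, slice]] = []
        start = 0
        for i in range(1, len(ids) + 1):
            if i == len(ids) or ids[i] != ids[start]:
                out.append((ids[start], slice(start, i)))
                start = i
        return out


@dataclasses.dataclass
class ExpressionResult:
    """Probeset-by-array expression estimates with optional uncertainty.

    ``expression`` is on the log2 scale.  ``stderr``, ``probe_weights`` and
    ``quality`` are produced by the frozen-parameter engine; the plain
    multi-array baseline fills them with ``None``.
    """

    expression: pd.DataFrame
    stderr: pd.DataFrame | None = None
    probe_weights: pd.DataFrame | None = None
    quality: pd.DataFrame | None = None

    @property
    def probeset_ids(self) -> np.ndarray:
        return self.expression.index.to_numpy()

    @property
    def array_ids(self) -> np.ndarray:
        return self.expression.columns.to_numpy()


# ---------------------------------------------------------------------------
# Reading delimited inputs
# ---------------------------------------------------------------------------


def read_probe_matrix(
    matrix_path: str | Path,
    annotation_path: str | Path,
    batch_path: str | Path | None = None,
) -> ProbeMatrix:
    """Read a probe-level TSV matrix plus annotation (and batch) tables.

    The matrix file has probe ids in the first column and array ids in the
    header.  The annotation file maps every probe id to its probeset id.  The
    optional batch file maps every array id to a batch label.
    """
    with open(matrix_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dups = sorted({a for a in header if header.count(a) > 1})
        raise ValueError(f"duplicate array id(s) in matrix: {dups}")
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if mat.index.has_duplicates:
        dups = mat.index[mat.index.duplicated()].tolist()
        raise ValueError(f"duplicate probe id(s) in matrix: {dups}")
    values = mat.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        r, c = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"non-numeric intensity at probe {mat.index[r]!r}, array {mat.columns[c]!r}"
        )

    ann = pd.read_csv(annotation_path, sep="\t", header=None, names=["probe", "probeset"], dtype=str)
    mapping = dict(zip(ann["probe"], ann["probeset"]))
    missing = [p for p in mat.index.astype(str) if p not in mapping]
    if missing:
        raise ValueError(f"probe(s) missing from annotation: {missing}")

    batch_of = None
    if batch_path is not None:
        bt = pd.read_csv(batch_path, sep="\t", header=None, names=["array", "batch"], dtype=str)
        batch_of = dict(zip(bt["array"], bt["batch"]))
        uncovered = [a for a in mat.columns.astype(str) if a not in batch_of]
        if uncovered:
            raise ValueError(f"array(s) missing from batch table: {uncovered}")
        batch_of = {a: batch_of[a] for a in mat.columns.astype(str)}

    probe_ids = mat.index.astype(str).to_numpy(dtype=object)
    return ProbeMatrix(
        intensities=values,
        probe_ids=probe_ids,
        probeset_of=np.asarray([mapping[p] for p in probe_ids], dtype=object),
        array_ids=mat.columns.astype(str).to_numpy(dtype=object),
        batch_of=batch_of,
    )


def write_probe_matrix(pm: ProbeMatrix, matrix_path: str | Path,
                       annotation_path: str | Path | None = None,
                       batch_path: str | Path | None = None) -> None:
    """Write a ProbeMatrix back to the TSV formats of :func:`read_probe_matrix`."""
    df = pd.DataFrame(pm.intensities, index=pd.Index(pm.probe_ids, name="probe"),
                      columns=pm.array_ids)
    df.to_csv(matrix_path, sep="\t", float_format="%.17g")
    if annotation_path is not None:
        pd.DataFrame({"probe": pm.probe_ids, "probeset": pm.probeset_of}).to_csv(
            annotation_path, sep="\t", header=False, index=False)
    if batch_path is not None:
        if pm.batch_of is None:
            raise ValueError("ProbeMatrix has no batch labels to write")
        pd.DataFrame({"array": pm.array_ids,
                      "batch": [pm.batch_of[a] for a in pm.array_ids]}).to_csv(
            batch_path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Balanced training-set sampling
# ---------------------------------------------------------------------------


def balanced_sample(pm: ProbeMatrix, n_batches: int, batch_size: int, seed: int) -> ProbeMatrix:
    """Draw a balanced training set: ``batch_size`` arrays from each of
    ``n_batches`` batches, without replacement, deterministically for a seed.

    Batches and arrays are sorted lexicographically before seeded sampling so
    the selection is platform independent.  Batches with fewer than
    ``batch_size`` arrays are ineligible.
    """
    groups = pm.batches()
    eligible = [b for b in sorted(groups) if len(groups[b]) >= batch_size]
    if len(eligible) < n_batches:
        raise ValueError(
            f"only {len(eligible)} batches have >= {batch_size} arrays; "
            f"{n_batches} required"
        )
    rng = np.random.default_rng(seed)
    chosen_batches = [eligible[i] for i in sorted(rng.choice(len(eligible), size=n_batches, replace=False))]
    picked: list[str] = []
    for b in chosen_batches:
        arrays = groups[b]
        idx = sorted(rng.choice(len(arrays), size=batch_size, replace=False))
        picked.extend(arrays[i] for i in idx)
    return pm.subset_arrays(picked)


# ---------------------------------------------------------------------------
# Frozen-vector bundle serialization
# ---------------------------------------------------------------------------


def _write_vector_tsv(path: Path, ids: Sequence, values: np.ndarray) -> None:
    with open(path, "w") as fh:
        for i, v in zip(ids, values):
            fh.write(f"{i}\t{float(v)!r}\n")


def _read_vector_tsv(path: Path) -> tuple[np.ndarray, np.ndarray]:
    ids, values = [], []
    with open(path) as fh:
        for line in fh:
            i, v = line.rstrip("\n").split("\t")
            ids.append(i)
            values.append(float(v))
    return np.asarray(ids, dtype=object), np.asarray(values, dtype=float)


def write_frozen_vectors(fv: FrozenVectors, path: str | Path) -> None:
    """Serialize a frozen-vector bundle to a directory (lossless, diffable)."""
    fv.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = dict(fv.metadata)
    meta.setdefault("format_version", FORMAT_VERSION)
    meta["n_probes"] = int(fv.n_probes)
    meta["n_probesets"] = int(fv.n_probesets)
    meta["has_median_se"] = fv.median_se is not None
    with open(path / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    ranks = [str(r) for r in range(fv.n_probes)]
    _write_vector_tsv(path / _BUNDLE_FILES["reference_distribution"], ranks, fv.reference_distribution)
    _write_vector_tsv(path / _BUNDLE_FILES["probe_effects"], fv.probe_ids, fv.probe_effects)
    _write_vector_tsv(path / _BUNDLE_FILES["within_batch_var"], fv.probe_ids, fv.within_batch_var)
    _write_vector_tsv(path / _BUNDLE_FILES["between_batch_var"], fv.probe_ids, fv.between_batch_var)
    _write_vector_tsv(path / _BUNDLE_FILES["probeset_avg_sd"], fv.probeset_ids, fv.probeset_avg_sd)
    if fv.median_se is not None:
        _write_vector_tsv(path / _BUNDLE_FILES["median_se"], fv.probeset_ids, fv.median_se)
    pd.DataFrame({"probe": fv.probe_ids, "probeset": fv.probeset_of}).to_csv(
        path / "annotation.tsv", sep="\t", header=False, index=False)


def read_frozen_vectors(path: str | Path) -> FrozenVectors:
    """Load a frozen-vector bundle; errors name any missing mandatory vector."""
    path = Path(path)
    with open(path / "metadata.json") as fh:
        meta = json.load(fh)
    for name in MANDATORY_VECTORS:
        if not (path / _BUNDLE_FILES[name]).exists():
            raise ValueError(f"missing mandatory vector: {name}")
    ann = pd.read_csv(path / "annotation.tsv", sep="\t", header=None,
                      names=["probe", "probeset"], dtype=str)
    probe_ids = ann["probe"].to_numpy(dtype=object)
    probeset_of = ann["probeset"].to_numpy(dtype=object)

    _, reference = _read_vector_tsv(path / _BUNDLE_FILES["reference_distribution"])
    pe_ids, probe_effects = _read_vector_tsv(path / _BUNDLE_FILES["probe_effects"])
    if list(pe_ids) != list(probe_ids):
        raise ValueError("probe ids in probe_effects do not match bundle annotation")
    _, within = _read_vector_tsv(path / _BUNDLE_FILES["within_batch_var"])
    _, between = _read_vector_tsv(path / _BUNDLE_FILES["between_batch_var"])
    ps_ids, avg_sd = _read_vector_tsv(path / _BUNDLE_FILES["probeset_avg_sd"])
    median_se = None
    if (path / _BUNDLE_FILES["median_se"]).exists():
        _, median_se = _read_vector_tsv(path / _BUNDLE_FILES["median_se"])

    n_probes = meta.get("n_probes")
    if n_probes is not None and n_probes != len(probe_ids):
        raise ValueError(f"bundle records n_probes={n_probes} but has {len(probe_ids)} probes")
    n_probesets = meta.get("n_probesets")
    if n_probesets is not None and n_probesets != len(ps_ids):
        raise ValueError(f"bundle records n_probesets={n_probesets} but has {len(ps_ids)} probesets")

    return FrozenVectors(
        reference_distribution=reference,
        probe_effects=probe_effects,
        within_batch_var=within,
        between_batch_var=between,
        probeset_avg_sd=avg_sd,
        probe_ids=probe_ids,
        probeset_of=probeset_of,
        probeset_ids=ps_ids,
        median_se=median_se,
        metadata={k: v for k, v in meta.items()
                  if k not in ("n_probes", "n_probesets", "has_median_se")},
    )
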