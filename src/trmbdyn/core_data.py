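"""Core data model and table I/O for perturbation time-course analysis.

The experimental design this package analyses is a two-strain panel
(a parent strain and a regulator-knockout strain) of ~100 genes sampled
on a nonuniform time grid around a nutrient perturbation at t = 0, plus
a single shared transcription-factor binding curve measured by ChIP-qPCR
(fold enrichment of the binding peak over a non-bound control region;
a ratio of 1 means no binding).

Containers
----------
:class:`TimeCourse`
    One gene's expression series in one strain, with replicates.  Missing
    values are stored explicitly as NaN and excluded pairwise from means;
    they are never silently dropped.
:class:`BindingCurve`
    The shared TF promoter fold-enrichment series B(t).
:class:`QpcrMeasurement`
    A (target, reference) Cq pair with per-primer amplification
    efficiencies for efficiency-corrected relative quantification.

Tables are long-format TSV/CSV with columns
``gene, strain, replicate, time_min, value``; binding tables use
``time_min, enrichment``; annotation tables use ``gene, cog_category``.
Floats are serialised with 12 significant digits so a write/read
round-trip is exact for ordinary decimal inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PARENT = "parent"
KNOCKOUT = "knockout"
STRAINS = (PARENT, KNOCKOUT)

#: The 10-point expression sampling design (minutes around the perturbation).
DESIGN_GRID = np.array([-240.0, -60.0, 0.0, 5.0, 10.0, 20.0, 45.0, 90.0, 180.0, 360.0])

#: Extra ChIP sampling times interleaved for higher resolution of binding.
CHIP_EXTRA_TIMES = np.array([2.0, 15.0, 30.0, 60.0, 120.0])

FLOAT_FMT = "%.12g"


class DataError(ValueError):
    """Raised for malformed or contract-violating input data."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class TimeCourse:
    """Expression of one gene in one strain over a nonuniform time grid.

    Parameters
    ----------
    gene_id : str
    strain : {"parent", "knockout"}
    times : array of minutes, strictly increasing (may be negative).
    values : array, shape ``(n_replicates, n_times)``; NaN marks an
        explicitly missing observation.  Values must be >= 0.
    replicate_ids : sequence of replicate labels.
    """

    gene_id: str
    strain: str
    times: np.ndarray
    values: np.ndarray
    replicate_ids: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.strain not in STRAINS:
            raise DataError(f"unknown strain {self.strain!r}; expected one of {STRAINS}")
        if self.times.ndim != 1 or len(self.times) < 1:
            raise DataError("times must be a non-empty 1-D array")
        if np.any(np.diff(self.times) <= 0):
            raise DataError(f"times must be strictly increasing, got {self.times}")
        if self.values.shape[1] != len(self.times):
            raise DataError(
                f"values shape {self.values.shape} does not match {len(self.times)} times"
            )
        with np.errstate(invalid="ignore"):
            if np.any(self.values < 0):
                raise DataError(f"negative expression values for gene {self.gene_id}")
        if not self.replicate_ids:
            self.replicate_ids = [f"rep{i + 1}" for i in range(self.values.shape[0])]
        if len(self.replicate_ids) != self.values.shape[0]:
            raise DataError("replicate_ids length must match number of value rows")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[0]

    def mean_trace(self) -> np.ndarray:
        """Replicate-mean trace; missing values are excluded pairwise.

        A time point missing in every replicate stays NaN (explicitly
        missing) rather than being imputed.
        """
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.values, axis=0)

    def subset_times(self, times: np.ndarray) -> "TimeCourse":
        """Restrict to a subset of the grid (all requested times must exist)."""
        idx = _match_times(self.times, np.asarray(times, dtype=float))
        return TimeCourse(
            self.gene_id, self.strain, self.times[idx], self.values[:, idx],
            list(self.replicate_ids),
        )


@dataclass
class BindingCurve:
    """TF promoter occupancy as fold enrichment over time; 1 = no binding."""

    times: np.ndarray
    enrichment: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.enrichment = np.asarray(self.enrichment, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.enrichment.shape:
            raise DataError("times and enrichment must be matching 1-D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise DataError("binding times must be strictly increasing")
        if np.any(self.enrichment <= 0):
            raise DataError("fold enrichment must be positive (1 = no binding)")

    def at(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation onto arbitrary times, held flat outside the span."""
        return np.interp(np.asarray(t, dtype=float), self.times, self.enrichment)

    @classmethod
    def constant(cls, level: float, times: np.ndarray | None = None) -> "BindingCurve":
        """A flat curve, e.g. the no-binding baseline B(t) = 1 for a knockout."""
        if times is None:
            times = np.array([-240.0, 360.0])
        times = np.asarray(times, dtype=float)
        return cls(times, np.full(len(times), float(level)))


@dataclass(frozen=True)
class QpcrMeasurement:
    """One qPCR observation: target and reference Cq with primer efficiencies.

    Efficiency is the per-cycle amplification factor, 2 = perfect doubling.
    """

    target_cq: float
    reference_cq: float
    target_efficiency: float
    reference_efficiency: float

    def __post_init__(self) -> None:
        for name in ("target_efficiency", "reference_efficiency"):
            e = getattr(self, name)
            if not 1.0 < e <= 2.0:
                raise DataError(f"{name} must be in (1, 2], got {e}")
        for name in ("target_cq", "reference_cq"):
            c = getattr(self, name)
            if not np.isfinite(c) or c <= 0:
                raise DataError(f"{name} must be finite and positive, got {c}")


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

_EXPR_COLUMNS = ["gene", "strain", "replicate", "time_min", "value"]


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def read_timecourse_table(path: str | Path) -> list[TimeCourse]:
    """Read a long-format expression table into TimeCourse objects.

    Expects columns ``gene, strain, replicate, time_min, value`` (``time``
    is accepted as an alias).  Returns one TimeCourse per (gene, strain),
    ordered by gene then strain; row order in the file is irrelevant.
    Duplicated (gene, strain, replicate, time) rows are an error.  An
    empty ``value`` field is stored as an explicit missing observation.
    """
    df = _read_table(path)
    if "time" in df.columns and "time_min" not in df.columns:
        df = df.rename(columns={"time": "time_min"})
    missing_cols = [c for c in _EXPR_COLUMNS if c not in df.columns]
    if missing_cols:
        raise DataError(f"table {path} lacks required columns {missing_cols}")
    key = ["gene", "strain", "replicate", "time_min"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        first = df.loc[dup, key].iloc[0].to_dict()
        raise DataError(f"duplicate measurement rows, e.g. {first}")
    out: list[TimeCourse] = []
    for (gene, strain), sub in sorted(df.groupby(["gene", "strain"], sort=True),
                                      key=lambda kv: (str(kv[0][0]), str(kv[0][1]))):
        wide = sub.pivot(index="replicate", columns="time_min", values="value")
        wide = wide.sort_index(axis=1)
        out.append(TimeCourse(
            gene_id=str(gene),
            strain=str(strain),
            times=wide.columns.to_numpy(dtype=float),
            values=wide.to_numpy(dtype=float),
            replicate_ids=[str(r) for r in wide.index],
        ))
    return out


def write_timecourse_table(panel: Iterable[TimeCourse], path: str | Path) -> None:
    """Write TimeCourses as a long-format table (TSV, or CSV by extension)."""
    rows = []
    for tc in panel:
        for r, rep in enumerate(tc.replicate_ids):
            for j, t in enumerate(tc.times):
                rows.append((tc.gene_id, tc.strain, rep, t, tc.values[r, j]))
    df = pd.DataFrame(rows, columns=_EXPR_COLUMNS)
    sep = "," if Path(path).suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep, index=False, float_format=FLOAT_FMT)


def read_binding_table(path: str | Path) -> BindingCurve:
    """Read a binding table with columns ``time_min, enrichment``."""
    df = _read_table(path)
    if not {"time_min", "enrichment"} <= set(df.columns):
        raise DataError(f"binding table {path} needs columns time_min, enrichment")
    df = df.sort_values("time_min")
    return BindingCurve(df["time_min"].to_numpy(dtype=float),
                        df["enrichment"].to_numpy(dtype=float))


def write_binding_table(curve: BindingCurve, path: str | Path) -> None:
    df = pd.DataFrame({"time_min": curve.times, "enrichment": curve.enrichment})
    sep = "," if Path(path).suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep, index=False, float_format=FLOAT_FMT)


def read_annotation_table(path: str | Path) -> dict[str, str]:
    """Read a gene -> functional-category (COG) map from ``gene, cog_category``."""
    df = _read_table(path)
    if not {"gene", "cog_category"} <= set(df.columns):
        raise DataError(f"annotation table {path} needs columns gene, cog_category")
    return {str(g): str(c) for g, c in zip(df["gene"], df["cog_category"])}


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------

def normalize_total_counts(panel: Sequence[TimeCourse]) -> list[TimeCourse]:
    """Normalise counts by per-sample totals across strains.

    A sample is one (strain, replicate, time point) column of the panel.
    Each sample is rescaled so that its total over genes equals the grand
    mean of all sample totals, which keeps values on the original count
    scale while removing per-sample depth differences.  Within-sample
    proportions (hence gene rank order) are unchanged.

    Raises
    ------
    DataError
        If any sample has zero total, or genes are measured on
        inconsistent grids within a strain.
    """
    if not panel:
        return []
    # totals[(strain, rep, time)] summed over genes
    totals: dict[tuple[str, str, float], float] = {}
    for tc in panel:
        for r, rep in enumerate(tc.replicate_ids):
            for j, t in enumerate(tc.times):
                v = tc.values[r, j]
                if np.isnan(v):
                    continue
                key = (tc.strain, str(rep), float(t))
                totals[key] = totals.get(key, 0.0) + float(v)
    for key, tot in totals.items():
        if tot == 0:
            raise DataError(f"sample {key} has zero total count")
    grand_mean = float(np.mean(list(totals.values())))
    out = []
    for tc in panel:
        scaled = tc.values.copy()
        for r, rep in enumerate(tc.replicate_ids):
            for j, t in enumerate(tc.times):
                key = (tc.strain, str(rep), float(t))
                if key in totals:
                    scaled[r, j] = tc.values[r, j] * grand_mean / totals[key]
        out.append(TimeCourse(tc.gene_id, tc.strain, tc.times.copy(), scaled,
                              list(tc.replicate_ids)))
    return out


def standardize_gene(trace: np.ndarray) -> np.ndarray:
    """Mean-centre a trace and scale it to unit sample standard deviation.

    Uses the n-1 denominator.  Constant traces cannot be standardised and
    raise; callers should exclude such genes from correlation clustering.
    """
    x = np.asarray(trace, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size < 2 or np.all(finite == finite[0]):
        raise DataError("cannot standardize a constant (or near-empty) trace")
    mean = np.nanmean(x)
    sd = np.nanstd(x, ddof=1)
    if sd == 0:
        raise DataError("cannot standardize a constant trace")
    return (x - mean) / sd


# ---------------------------------------------------------------------------
# Efficiency-corrected relative quantification
# ---------------------------------------------------------------------------

def relative_quantification(condition: QpcrMeasurement,
                            calibrator: QpcrMeasurement) -> float:
    """Efficiency-corrected fold change of target vs reference (ratio of ratios).

    Implements the standard efficiency-corrected relative-quantification
    model::

        fold = E_t ** (Cq_t,cal - Cq_t,cond) / E_r ** (Cq_r,cal - Cq_r,cond)

    where ``E_t``/``E_r`` are the per-cycle amplification factors of the
    target and reference primer pairs.  Both measurements must share
    efficiencies (they come from the same primer pairs).
    """
    if not np.isclose(condition.target_efficiency, calibrator.target_efficiency) or \
       not np.isclose(condition.reference_efficiency, calibrator.reference_efficiency):
        raise DataError("condition and calibrator must share primer efficiencies")
    d_target = calibrator.target_cq - condition.target_cq
    d_ref = calibrator.reference_cq - condition.reference_cq
    return (condition.target_efficiency ** d_target
            / condition.reference_efficiency ** d_ref)


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _match_times(grid: np.ndarray, wanted: np.ndarray) -> np.ndarray:
    idx = []
    for t in wanted:
        j = np.flatnonzero(np.isclose(grid, t))
        if j.size == 0:
            raise DataError(f"time {t} not on grid {grid}")
        idx.append(j[0])
    return np.array(idx, dtype=int)


def panel_to_frame(panel: Sequence[TimeCourse],
                   strain: str | None = None) -> pd.DataFrame:
    """Mean traces as a (gene x time) DataFrame for one strain."""
    rows: dict[str, np.ndarray] = {}
    times = None
    for tc in panel:
        if strain is not None and tc.strain != strain:
            continue
        if times is None:
            times = tc.times
        elif not np.array_equal(times, tc.times):
            raise DataError("panel genes are on inconsistent time grids")
        rows[tc.gene_id] = tc.mean_trace()
    if times is None:
        raise DataError(f"no genes for strain {strain!r}")
    return pd.DataFrame.from_dict(rows, orient="index", columns=times)
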