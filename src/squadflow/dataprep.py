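"""Single-cell count normalization into fit-ready measurement series.

Pipeline per gene:

1. drop zero counts at every time point (dropouts are missing measurements,
   not true zeros, and would bias the mean and dispersion downward);
2. divide every remaining value, across all cells and all time points, by
   the gene's global maximum, mapping expression into (0, 1];
3. per time point, summarize the normalized values by their mean (the best
   value fed to fitting) and sample standard deviation (ddof=1); the
   standard error (sd / sqrt(n)) is stored alongside.

The fitting weight defaults to the standard deviation; ``use_sem=True``
writes the standard error instead (the two differ by sqrt(n) — both are in
use as chi-square weights, so the choice is exposed, not hard-coded).
A time point where all cells agree exactly would give sigma = 0 and an
infinite chi-square weight; such sigmas are floored at ``SIGMA_FLOOR``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AllDropoutError, DataError

SIGMA_FLOOR = 1e-3


@dataclass
class CountMatrix:
    """Raw (or log-transformed) counts for one time point, cells x genes."""

    timepoint: float
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise DataError(f"duplicate gene ids in count matrix: {dup}")
        if (self.counts.to_numpy() < 0).any():
            raise DataError("counts must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class MeasurementSeries:
    """Per-gene summary used as fitting input: best value and dispersion."""

    gene: str
    times: np.ndarray
    values: np.ndarray     # best value x~, in [0, 1]
    sd: np.ndarray         # sample standard deviation (ddof=1), floored
    sem: np.ndarray        # standard error sd/sqrt(n)
    n_cells: np.ndarray
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        self.n_cells = np.asarray(self.n_cells, dtype=int)
        if np.any(np.diff(self.times) <= 0):
            raise DataError(f"{self.gene}: time points must be strictly increasing")
        if np.any((self.values < 0) | (self.values > 1)):
            raise DataError(f"{self.gene}: best values must lie in [0, 1]")
        if np.any(self.sd <= 0):
            raise DataError(f"{self.gene}: dispersions must be positive")

    def sigma(self, use_sem: bool = False) -> np.ndarray:
        return self.sem if use_sem else self.sd


def filter_dropouts(values, gene: str = "?", timepoint: float | str = "?") -> np.ndarray:
    """Remove zero entries (dropouts), preserving order.

    Raises :class:`AllDropoutError` if nothing remains.
    """
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise DataError(f"{gene} @ {timepoint}: negative counts")
    kept = arr[arr > 0]
    if kept.size == 0:
        raise AllDropoutError(
            f"gene {gene!r} at timepoint {timepoint}: all values are dropouts")
    return kept


def normalize_gene(per_timepoint: dict[float, np.ndarray]) -> dict[float, np.ndarray]:
    """Divide one gene's values by its maximum over all cells and times.

    Input vectors are assumed dropout-filtered (all positive); the global
    maximum maps to exactly 1.
    """
    if not per_timepoint:
        raise DataError("no time points given")
    divisor = max(float(np.max(v)) for v in per_timepoint.values())
    if divisor <= 0:
        raise DataError("maximum expression is not positive; filter dropouts first")
    return {t: np.asarray(v, dtype=float) / divisor
            for t, v in per_timepoint.items()}


def summarize(normalized: dict[float, np.ndarray], gene: str) -> MeasurementSeries:
    """Mean / sample SD / SEM per time point for one normalized gene.

    A time point with a single retained cell has an undefined sample SD:
    it is excluded from the series and recorded in ``flags``.
    """
    times, means, sds, sems, ns = [], [], [], [], []
    flags: list[str] = []
    for t in sorted(normalized):
        v = np.asarray(normalized[t], dtype=float)
        if v.size < 2:
            flags.append(f"t={t}: n={v.size} cells, dispersion undefined; excluded")
            continue
        sd = float(np.std(v, ddof=1))
        if sd == 0.0:
            flags.append(f"t={t}: zero dispersion floored at {SIGMA_FLOOR}")
            sd = SIGMA_FLOOR
        times.append(t)
        means.append(float(np.mean(v)))
        sds.append(sd)
        sems.append(sd / np.sqrt(v.size))
        ns.append(v.size)
    if not times:
        raise DataError(f"gene {gene!r}: no time point with >= 2 cells")
    return MeasurementSeries(gene, np.array(times), np.array(means),
                             np.array(sds), np.array(sems), np.array(ns), flags)


def prepare(count_matrices: list[CountMatrix],
            genes: list[str] | None = None) -> dict[str, MeasurementSeries]:
    """Full pipeline over a set of per-timepoint count matrices.

    ``genes`` restricts the output (e.g. to topology genes); by default all
    genes present in any matrix are processed.  Genes whose data are all
    dropouts raise; genes missing from a time point are simply unobserved
    there.
    """
    if not count_matrices:
        raise DataError("no count matrices given")
    all_genes: list[str] = []
    for cm in count_matrices:
        for g in cm.genes:
            if g not in all_genes:
                all_genes.append(g)
    wanted = genes if genes is not None else all_genes
    out: dict[str, MeasurementSeries] = {}
    for g in wanted:
        per_tp: dict[float, np.ndarray] = {}
        for cm in count_matrices:
            if g not in cm.counts.columns:
                continue
            try:
                per_tp[cm.timepoint] = filter_dropouts(
                    cm.counts[g].to_numpy(), gene=g, timepoint=cm.timepoint)
            except AllDropoutError:
                # a fully dropped-out time point is unobserved, not fatal
                continue
        if not per_tp:
            raise AllDropoutError(f"gene {g!r}: no usable values at any time point")
        out[g] = summarize(normalize_gene(per_tp), g)
    return out


# ---------------------------------------------------------------------------
# Fit-ready data CSV: columns `time`, then per gene g: `g`, `g_std`
# ---------------------------------------------------------------------------

def series_to_frame(series: dict[str, MeasurementSeries],
                    use_sem: bool = False) -> pd.DataFrame:
    """Wide fit-ready table; missing (gene, time) combinations become NaN."""
    times = sorted({float(t) for s in series.values() for t in s.times})
    data: dict[str, list[float]] = {"time": times}
    for g, s in series.items():
        vals, sigs = [], []
        lookup = {float(t): i for i, t in enumerate(s.times)}
        sigma = s.sigma(use_sem)
        for t in times:
            i = lookup.get(t)
            vals.append(float(s.values[i]) if i is not None else np.nan)
            sigs.append(float(sigma[i]) if i is not None else np.nan)
        data[g] = vals
        data[f"{g}_std"] = sigs
    return pd.DataFrame(data)


def write_data_csv(series: dict[str, MeasurementSeries], path,
                   use_sem: bool = False) -> None:
    series_to_frame(series, use_sem).to_csv(path, index=False)


def read_data_csv(path) -> dict[str, MeasurementSeries]:
    """Read a fit-ready data CSV back into measurement series.

    SD and SEM are not distinguishable from the file; the stored column is
    loaded into both so the chi-square weight is whatever the file carries.
    """
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise DataError(f"data CSV {path} lacks a 'time' column")
    genes = [c for c in df.columns if c != "time" and not c.endswith("_std")]
    out: dict[str, MeasurementSeries] = {}
    for g in genes:
        std_col = f"{g}_std"
        if std_col not in df.columns:
            raise DataError(f"data CSV {path}: missing column {std_col!r}")
        sub = df[["time", g, std_col]].dropna()
        if sub.empty:
            continue
        sub = sub.sort_values("time")
        sigma = sub[std_col].to_numpy(dtype=float)
        if np.any(sigma <= 0):
            raise DataError(f"gene {g!r}: non-positive sigma in {path}")
        out[g] = MeasurementSeries(
            g, sub["time"].to_numpy(dtype=float), sub[g].to_numpy(dtype=float),
            sigma, sigma.copy(), np.zeros(len(sub), dtype=int))
    return out
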