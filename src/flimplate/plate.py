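"""Plate-level assay statistics: plate maps, drift QC, Z', dose response.

Aggregates per-FOV lifetime (or fraction) estimates into per-well and
per-condition summaries and computes the screening-assay quality
metrics: the Z' factor ``1 - 3(sigma_pos + sigma_neg)/|mu_pos - mu_neg|``
(> 0.4 desirable), percent inhibition of a medium dose relative to low
and high anchors, and dose-response tables with an optional Hill fit
for EC50.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "WellSpec",
    "PlateLayout",
    "WellResult",
    "AssayMetrics",
    "DriftSeries",
    "well_name",
    "default_dose_response_layout",
    "well_aggregate",
    "plate_map",
    "drift_check",
    "percent_inhibition",
    "z_prime",
    "dose_response_table",
    "fit_hill_curve",
]

ROLES = ("positive_control", "negative_control", "dose", "excluded", "empty")


def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> plate well id, e.g. (0, 0) -> 'A1'."""
    return f"{string.ascii_uppercase[row]}{col + 1}"


@dataclass(frozen=True)
class WellSpec:
    well_id: str
    row: int
    col: int
    condition: str
    dose_uM: float = float("nan")
    role: str = "dose"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class PlateLayout:
    """Plate geometry plus the condition/dose/role of every well."""

    rows: int = 8
    cols: int = 12
    wells: list = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [w.well_id for w in self.wells]
        if len(ids) != len(set(ids)):
            raise ValueError("well ids must be unique")
        for w in self.wells:
            if not (0 <= w.row < self.rows and 0 <= w.col < self.cols):
                raise ValueError(f"well {w.well_id} outside the {self.rows}x{self.cols} plate")

    def by_id(self) -> dict:
        return {w.well_id: w for w in self.wells}

    def wells_with_role(self, role: str) -> list:
        return [w for w in self.wells if w.role == role]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "well": w.well_id,
                    "row": w.row,
                    "col": w.col,
                    "condition": w.condition,
                    "dose_uM": w.dose_uM,
                    "role": w.role,
                }
                for w in self.wells
            ]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, rows: int = 8, cols: int = 12) -> "PlateLayout":
        wells = [
            WellSpec(
                well_id=str(r.well),
                row=int(r.row),
                col=int(r.col),
                condition=str(r.condition),
                dose_uM=float(r.dose_uM) if np.isfinite(r.dose_uM) else float("nan"),
                role=str(r.role),
            )
            for r in df.itertuples()
        ]
        return cls(rows=rows, cols=cols, wells=wells)


def default_dose_response_layout(
    rows: int = 8,
    cols: int = 12,
    dose_high_uM: float = 10.0,
    dose_low_uM: float = 0.001,
    dose_cols: tuple[int, int] = (1, 9),  # 0-based: plate columns 2..10
    positive_col: int = 0,
    negative_col: int = 10,
    condition: str = "gag",
) -> PlateLayout:
    """The assay's standard plating scheme.

    Column 1 holds positive controls (myristoylation-deficient Gag, no
    membrane binding), columns 2-10 a nine-point dose series from
    ``dose_high_uM`` down to ``dose_low_uM`` in equal logarithmic steps,
    column 11 vehicle-only negative controls, and column 12 is excluded;
    rows are replicates.
    """
    n_dose = dose_cols[1] - dose_cols[0] + 1
    doses = np.geomspace(dose_high_uM, dose_low_uM, n_dose)
    wells = []
    for row in range(rows):
        for col in range(cols):
            wid = well_name(row, col)
            if col == positive_col:
                wells.append(WellSpec(wid, row, col, condition, float("nan"), "positive_control"))
            elif dose_cols[0] <= col <= dose_cols[1]:
                d = float(doses[col - dose_cols[0]])
                wells.append(WellSpec(wid, row, col, condition, d, "dose"))
            elif col == negative_col:
                wells.append(WellSpec(wid, row, col, condition, 0.0, "negative_control"))
            else:
                wells.append(WellSpec(wid, row, col, condition, float("nan"), "excluded"))
    return PlateLayout(rows=rows, cols=cols, wells=wells)


def three_dose_layout(
    dose_low_uM: float,
    dose_med_uM: float,
    dose_high_uM: float,
    rows: int = 8,
    cols: int = 12,
    condition: str = "gag",
) -> PlateLayout:
    """Assay-characterisation plating: low/medium/high doses in repeating
    column triplets (the pattern rotates between plates in practice;
    here columns 1..cols cycle high, medium, low)."""
    doses = (dose_high_uM, dose_med_uM, dose_low_uM)
    names = ("high", "medium", "low")
    wells = []
    for row in range(rows):
        for col in range(cols):
            k = col % 3
            wells.append(
                WellSpec(well_name(row, col), row, col, f"{condition}_{names[k]}",
                         float(doses[k]), "dose")
            )
    return PlateLayout(rows=rows, cols=cols, wells=wells)


# ---------------------------------------------------------------------------
# per-well aggregation
# ---------------------------------------------------------------------------


@dataclass
class WellResult:
    """Aggregated lifetime (or fraction) statistics for one well."""

    well_id: str
    mean_tau: float = float("nan")
    sd_tau: float = float("nan")
    n_values: int = 0
    n_fovs: int = 0
    no_cells_flag: bool = False


def well_aggregate(
    well_id: str,
    fov_values: list,
    method: str = "pixel_pooled",
) -> WellResult:
    """Aggregate per-FOV value collections into one well statistic.

    ``fov_values`` is a list (one entry per FOV) of arrays of per-pixel
    or per-ROI lifetimes.  ``pixel_pooled`` pools all values across
    FOVs; ``fov_mean`` averages the per-FOV means (equal FOV weight).
    FOVs with no values are dropped; a well with no data anywhere is
    returned flagged.
    """
    if method not in ("pixel_pooled", "fov_mean"):
        raise ValueError("method must be 'pixel_pooled' or 'fov_mean'")
    arrays = [np.asarray(v, dtype=float).ravel() for v in fov_values]
    arrays = [a[np.isfinite(a)] for a in arrays]
    arrays = [a for a in arrays if a.size > 0]
    if not arrays:
        return WellResult(well_id, no_cells_flag=True)
    if method == "pixel_pooled":
        pooled = np.concatenate(arrays)
        mean = float(pooled.mean())
        sd = float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0
        n = int(pooled.size)
    else:
        means = np.array([a.mean() for a in arrays])
        mean = float(means.mean())
        sd = float(means.std(ddof=1)) if means.size > 1 else 0.0
        n = int(means.size)
    return WellResult(well_id, mean, sd, n, n_fovs=len(arrays))


def plate_map(well_results: dict, layout: PlateLayout) -> np.ndarray:
    """Row x col grid of well means; NaN for missing/excluded wells."""
    grid = np.full((layout.rows, layout.cols), np.nan)
    for w in layout.wells:
        if w.role in ("excluded", "empty"):
            continue
        res = well_results.get(w.well_id)
        if res is not None and not res.no_cells_flag:
            grid[w.row, w.col] = res.mean_tau
    return grid


# ---------------------------------------------------------------------------
# QC and assay metrics
# ---------------------------------------------------------------------------


@dataclass
class DriftSeries:
    """Ordered well means along one plate axis plus an OLS drift slope."""

    order: list
    means: np.ndarray
    slope: float  # ps per well position; NaN when < 3 wells
    flagged: bool = False


def drift_check(
    well_results: dict,
    layout: PlateLayout,
    condition_role: str = "dose",
    axis: str = "column",
    assay_window: float | None = None,
    flag_fraction: float = 0.5,
) -> DriftSeries:
    """Systematic drift/edge-effect check along columns or rows.

    Orders the wells of one role column-wise (left to right) or
    row-wise (top to bottom), fits an ordinary least-squares line to
    mean lifetime vs position, and flags the series when the fitted
    drift across the span exceeds ``flag_fraction`` of the assay window
    (when a window is supplied).
    """
    if axis not in ("column", "row"):
        raise ValueError("axis must be 'column' or 'row'")
    wells = [w for w in layout.wells if w.role == condition_role]
    key = (lambda w: (w.col, w.row)) if axis == "column" else (lambda w: (w.row, w.col))
    wells = sorted(wells, key=key)
    order, means = [], []
    for w in wells:
        res = well_results.get(w.well_id)
        if res is not None and not res.no_cells_flag:
            order.append(w.well_id)
            means.append(res.mean_tau)
    means = np.asarray(means, dtype=float)
    if means.size < 3:
        return DriftSeries(order, means, float("nan"))
    x = np.arange(means.size, dtype=float)
    slope = float(np.polyfit(x, means, 1)[0])
    flagged = False
    if assay_window is not None and assay_window > 0:
        flagged = abs(slope) * (means.size - 1) > flag_fraction * assay_window
    return DriftSeries(order, means, slope, flagged)


def percent_inhibition(tau_med: float, tau_low: float, tau_high: float) -> tuple[float, bool]:
    """Percent inhibition of the medium dose relative to low/high anchors.

    ``100 * (tau_med - tau_low) / (tau_high - tau_low)``.  Lifetime
    rises with inhibition (less FRET), so the low dose anchors 0% and
    the high dose 100%.  Values outside [0, 100] are reported unclamped
    with the returned range flag set.
    """
    if tau_high == tau_low:
        raise ValueError("tau_high and tau_low must differ")
    pct = 100.0 * (tau_med - tau_low) / (tau_high - tau_low)
    return float(pct), not (0.0 <= pct <= 100.0)


@dataclass
class AssayMetrics:
    """Control-arm statistics and the Z' screening quality factor."""

    mu_pos: float
    sigma_pos: float
    mu_neg: float
    sigma_neg: float
    z_prime: float
    n_pos: int
    n_neg: int


def z_prime(pos_values, neg_values) -> AssayMetrics:
    """Z' factor from positive- and negative-control values.

    ``Z' = 1 - 3 (sigma_pos + sigma_neg) / |mu_pos - mu_neg|`` with
    sample standard deviations.  The arms are typically per-well mean
    lifetimes (replicate wells); per-ROI or per-pixel values may be
    passed instead.  A failed control arm may be substituted by any
    other well group (e.g. a saturating dose column) simply by passing
    its values.
    """
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    pos = pos[np.isfinite(pos)]
    neg = neg[np.isfinite(neg)]
    if pos.size < 2 or neg.size < 2:
        raise ValueError("each control arm needs at least 2 values")
    mu_p, mu_n = float(pos.mean()), float(neg.mean())
    if mu_p == mu_n:
        raise ValueError("control means are equal; Z' is undefined")
    s_p = float(pos.std(ddof=1))
    s_n = float(neg.std(ddof=1))
    z = 1.0 - 3.0 * (s_p + s_n) / abs(mu_p - mu_n)
    return AssayMetrics(mu_p, s_p, mu_n, s_n, float(z), pos.size, neg.size)


# ---------------------------------------------------------------------------
# dose response
# ---------------------------------------------------------------------------


def _hill_rising(log10_dose, bottom, top, log10_ec50, hill):
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log10_ec50 - log10_dose) * hill))


@dataclass
class HillFit:
    bottom: float
    top: float
    ec50_uM: float
    hill: float
    identifiable: bool
    ec50_ci: tuple | None = None


def fit_hill_curve(
    doses_uM: np.ndarray,
    responses: np.ndarray,
    n_bootstrap: int = 0,
    seed: int = 0,
) -> HillFit:
    """4-parameter Hill fit of a rising response vs log dose.

    Returns EC50 in uM; flagged unidentifiable when the fit fails, the
    fitted span is within noise of flat, or EC50 escapes the dosed
    range.  An optional residual bootstrap gives a (2.5, 97.5)% EC50
    interval.
    """
    doses = np.asarray(doses_uM, dtype=float)
    resp = np.asarray(responses, dtype=float)
    good = np.isfinite(doses) & np.isfinite(resp) & (doses > 0)
    doses, resp = doses[good], resp[good]
    if doses.size < 4:
        return HillFit(np.nan, np.nan, np.nan, np.nan, identifiable=False)
    x = np.log10(doses)
    p0 = [resp.min(), resp.max(), float(np.median(x)), 1.0]
    bounds = ([-np.inf, -np.inf, x.min() - 2, 0.1], [np.inf, np.inf, x.max() + 2, 10.0])

    def _fit(xv, yv):
        popt, _ = curve_fit(_hill_rising, xv, yv, p0=p0, bounds=bounds, maxfev=20000)
        return popt

    try:
        popt = _fit(x, resp)
    except Exception:
        return HillFit(np.nan, np.nan, np.nan, np.nan, identifiable=False)
    bottom, top, log_ec50, hill = popt
    span = abs(top - bottom)
    resid = resp - _hill_rising(x, *popt)
    noise = np.std(resid, ddof=1) if resid.size > 4 else 0.0
    identifiable = bool(
        span > 3.0 * noise and x.min() - 1 <= log_ec50 <= x.max() + 1
    )
    ci = None
    if n_bootstrap > 0 and identifiable:
        rng = np.random.default_rng(seed)
        fitted = _hill_rising(x, *popt)
        boot = []
        for _ in range(n_bootstrap):
            y_b = fitted + rng.choice(resid, size=resid.size, replace=True)
            try:
                boot.append(_fit(x, y_b)[2])
            except Exception:
                continue
        if len(boot) >= 10:
            lo, hi = np.percentile(boot, [2.5, 97.5])
            ci = (float(10.0 ** lo), float(10.0 ** hi))
    return HillFit(float(bottom), float(top), float(10.0 ** log_ec50), float(hill),
                   identifiable, ci)


def dose_response_table(
    well_results: dict,
    layout: PlateLayout,
    fit_ec50: bool = True,
    n_bootstrap: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, HillFit | None]:
    """Per-dose mean +/- SD table over repeat wells, plus optional Hill fit.

    One row per dose level, pooling the per-well means of all repeat
    wells at that dose; requires at least 2 dose levels.  When
    ``fit_ec50`` is set (and >= 4 dose levels are present) a 4-parameter
    Hill curve is fitted to mean response vs log dose.
    """
    by_id = layout.by_id()
    records: dict[float, list] = {}
    for wid, res in well_results.items():
        spec = by_id.get(wid)
        if spec is None or spec.role != "dose" or res.no_cells_flag:
            continue
        records.setdefault(spec.dose_uM, []).append(res.mean_tau)
    if len(records) < 2:
        raise ValueError("dose_response_table needs at least 2 dose levels")
    rows = []
    for dose in sorted(records):
        vals = np.asarray(records[dose], dtype=float)
        rows.append(
            {
                "dose_uM": dose,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "n_wells": int(vals.size),
            }
        )
    table = pd.DataFrame(rows)
    hill = None
    if fit_ec50:
        hill = fit_hill_curve(
            table["dose_uM"].to_numpy(), table["mean"].to_numpy(),
            n_bootstrap=n_bootstrap, seed=seed,
        )
    return table, hill
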