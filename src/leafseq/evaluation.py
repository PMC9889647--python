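"""Plan-quality evaluation: gamma analysis, DVH curves, dose metrics.

The gamma index combines a dose-difference criterion with a
distance-to-agreement (DTA) search:

    gamma(r_ref) = min over r_eval of sqrt( (D_eval(r_eval) - D_ref(r_ref))^2
                   / (dd * Dmax)^2  +  |r_eval - r_ref|^2 / dta^2 )

with global normalization to the reference maximum by default, a search
radius of three times the DTA, sub-voxel refinement on a trilinear
interpolation lattice, and voxels below a low-dose threshold excluded.
A deliberately exhaustive brute-force implementation over the identical
search lattice serves as the correctness oracle for the optimized search.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import ndimage

from .core import Dose3D, EvaluationError


@dataclass(frozen=True)
class GammaCriteria:
    """3%/3mm with a 5% low-dose threshold by default."""

    dose_tolerance: float = 0.03       # fraction of the normalization dose
    distance_tolerance: float = 3.0    # mm
    low_dose_threshold: float = 0.05   # fraction of the reference maximum
    normalization: str = "global"      # "global" or "local"
    search_factor: float = 3.0         # search radius in units of the DTA
    subsample: int = 10                # lattice steps per voxel
    max_gamma: float | None = None     # optional cap (>= 1) to bound search

    def __post_init__(self) -> None:
        if min(self.dose_tolerance, self.distance_tolerance,
               self.low_dose_threshold) <= 0:
            raise ValueError("gamma criteria must be strictly positive")
        if self.max_gamma is not None and self.max_gamma < 1.0:
            raise ValueError("max_gamma must be >= 1 to keep pass/fail exact")


@dataclass
class GammaResult:
    pass_rate: float          # percent of evaluated voxels with gamma <= 1
    n_evaluated: int
    gamma_map: np.ndarray     # NaN where below the low-dose threshold

    @property
    def mean_gamma(self) -> float:
        return float(np.nanmean(self.gamma_map))


def _check_same_grid(reference: Dose3D, evaluated: Dose3D) -> None:
    g1, g2 = reference.grid, evaluated.grid
    if (g1.shape != g2.shape or not np.allclose(g1.spacing, g2.spacing)
            or not np.allclose(g1.origin, g2.origin)):
        raise EvaluationError(
            "reference and evaluated doses are on different grids; "
            "resample one onto the other first")


def _search_lattice(spacing, criteria: GammaCriteria):
    """Fractional-voxel offsets within the search sphere, with their
    squared distances (mm^2), sorted by distance."""
    radius = criteria.search_factor * criteria.distance_tolerance
    axes = []
    for sp in spacing:
        nmax = int(np.floor(radius / (sp / criteria.subsample)))
        axes.append(np.arange(-nmax, nmax + 1) / criteria.subsample)
    di, dj, dk = np.meshgrid(*axes, indexing="ij")
    offs = np.stack([di.ravel(), dj.ravel(), dk.ravel()], axis=1)
    d2 = (offs ** 2 * np.asarray(spacing) ** 2).sum(axis=1)
    keep = d2 <= radius ** 2 + 1e-12
    offs, d2 = offs[keep], d2[keep]
    order = np.argsort(d2, kind="stable")
    return offs[order], d2[order]


@njit(cache=True)
def _gamma_search(ref_vals, idx, ev, offs, dist_terms, dd_sq, cap_sq):
    """Per-voxel minimum gamma^2 over the distance-sorted offset lattice.

    Offsets arrive sorted by their spatial term, so the scan for a voxel
    stops as soon as the distance term alone can no longer improve its
    running minimum (or exceeds the cap, beyond which pass/fail is already
    decided).  Trilinear interpolation; positions outside the evaluated
    grid are skipped.
    """
    nx, ny, nz = ev.shape
    m = ref_vals.shape[0]
    out = np.empty(m)
    for v in range(m):
        best = np.inf
        i, j, k = idx[v, 0], idx[v, 1], idx[v, 2]
        rv = ref_vals[v]
        dsq = dd_sq[v]
        for t in range(offs.shape[0]):
            dt = dist_terms[t]
            if dt >= best or dt >= cap_sq:
                break
            x = i + offs[t, 0]
            y = j + offs[t, 1]
            z = k + offs[t, 2]
            if (x < 0.0 or x > nx - 1.0 or y < 0.0 or y > ny - 1.0
                    or z < 0.0 or z > nz - 1.0):
                continue
            x0 = int(np.floor(x)); fx = x - x0
            y0 = int(np.floor(y)); fy = y - y0
            z0 = int(np.floor(z)); fz = z - z0
            x1 = x0 + 1 if fx > 0.0 else x0
            y1 = y0 + 1 if fy > 0.0 else y0
            z1 = z0 + 1 if fz > 0.0 else z0
            c00 = ev[x0, y0, z0] * (1 - fx) + ev[x1, y0, z0] * fx
            c10 = ev[x0, y1, z0] * (1 - fx) + ev[x1, y1, z0] * fx
            c01 = ev[x0, y0, z1] * (1 - fx) + ev[x1, y0, z1] * fx
            c11 = ev[x0, y1, z1] * (1 - fx) + ev[x1, y1, z1] * fx
            val = ((c00 * (1 - fy) + c10 * fy) * (1 - fz)
                   + (c01 * (1 - fy) + c11 * fy) * fz)
            g2 = (val - rv) * (val - rv) / dsq + dt
            if g2 < best:
                best = g2
        out[v] = best
    return out


def gamma_index(reference: Dose3D, evaluated: Dose3D,
                criteria: GammaCriteria = GammaCriteria()) -> GammaResult:
    """Optimized gamma: offsets are visited in order of increasing spatial
    distance with a running per-voxel minimum, and the search stops as soon
    as the distance term alone exceeds the voxel's current minimum (or the
    ``max_gamma`` cap).  Identical to the brute-force search on the same
    lattice wherever gamma is below the cap."""
    _check_same_grid(reference, evaluated)
    ref = reference.values
    ev = np.ascontiguousarray(evaluated.values, dtype=float)
    dmax = float(ref.max())
    if dmax <= 0:
        raise EvaluationError("reference dose is identically zero")
    mask = ref >= criteria.low_dose_threshold * dmax
    idx = np.argwhere(mask)
    ref_vals = ref[mask]
    if criteria.normalization == "global":
        dd_sq = np.full(ref_vals.shape, (criteria.dose_tolerance * dmax) ** 2)
    elif criteria.normalization == "local":
        dd_sq = (criteria.dose_tolerance * ref_vals) ** 2
    else:
        raise ValueError(f"unknown normalization {criteria.normalization!r}")

    offs, d2 = _search_lattice(reference.grid.spacing, criteria)
    dist_terms = d2 / criteria.distance_tolerance ** 2
    cap_sq = np.inf if criteria.max_gamma is None else criteria.max_gamma ** 2
    best = _gamma_search(ref_vals.astype(float), idx.astype(float), ev,
                         offs.astype(float), dist_terms.astype(float),
                         dd_sq.astype(float), cap_sq)
    gamma_map = np.full(ref.shape, np.nan)
    gamma_map[mask] = np.sqrt(best)
    n_eval = int(mask.sum())
    pass_rate = 100.0 * float((np.sqrt(best) <= 1.0).sum()) / n_eval
    return GammaResult(pass_rate=pass_rate, n_evaluated=n_eval,
                       gamma_map=gamma_map)


def gamma_index_brute_force(reference: Dose3D, evaluated: Dose3D,
                            criteria: GammaCriteria = GammaCriteria()
                            ) -> GammaResult:
    """Exhaustive gamma over the identical search lattice — the testing
    oracle.  Every offset is evaluated for every voxel above the
    threshold, with no ordering, early termination or cap."""
    _check_same_grid(reference, evaluated)
    ref = reference.values
    ev = evaluated.values
    dmax = float(ref.max())
    if dmax <= 0:
        raise EvaluationError("reference dose is identically zero")
    mask = ref >= criteria.low_dose_threshold * dmax
    if criteria.normalization == "global":
        dd_sq_m = (criteria.dose_tolerance * dmax) ** 2
    else:
        dd_sq_m = (criteria.dose_tolerance * ref[mask]) ** 2

    offs, d2 = _search_lattice(reference.grid.spacing, criteria)
    dta_sq = criteria.distance_tolerance ** 2
    pts = np.argwhere(mask).astype(float)      # (M, 3)
    shape = np.asarray(ref.shape, dtype=float)
    best = np.full(pts.shape[0], np.inf)
    for d, dist2 in zip(offs, d2):
        coords = pts + d
        valid = np.all((coords >= 0.0) & (coords <= shape - 1.0), axis=1)
        if not np.any(valid):
            continue
        vals = ndimage.map_coordinates(ev, coords[valid].T, order=1,
                                       mode="nearest")
        cand = (vals - ref[mask][valid]) ** 2 / (
            dd_sq_m if np.isscalar(dd_sq_m) else dd_sq_m[valid]) \
            + dist2 / dta_sq
        b = best[valid]
        best[valid] = np.minimum(b, cand)
    gamma_map = np.full(ref.shape, np.nan)
    gamma_map[mask] = np.sqrt(best)
    n_eval = int(mask.sum())
    pass_rate = 100.0 * float((np.sqrt(best) <= 1.0).sum()) / n_eval
    return GammaResult(pass_rate=pass_rate, n_evaluated=n_eval,
                       gamma_map=gamma_map)


# ---------------------------------------------------------------------------
# DVH
# ---------------------------------------------------------------------------

@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram for one ROI."""

    roi: str
    dose_edges: np.ndarray        # cGy, ascending, starts at 0
    volume_fraction: np.ndarray   # percent of ROI volume receiving >= dose
    dmax: float
    dmean: float

    def v(self, dose: float) -> float:
        """Percent of the ROI receiving at least ``dose`` cGy."""
        return float(np.interp(dose, self.dose_edges, self.volume_fraction))


def dvh(dose: Dose3D, roi_mask: np.ndarray, roi: str = "ROI",
        bin_width: float = 1.0) -> DVHCurve:
    """Cumulative DVH over the masked voxels, 1 cGy bins by default."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != dose.values.shape:
        raise EvaluationError("ROI mask and dose are on different grids")
    vals = dose.values[roi_mask]
    if vals.size == 0:
        raise EvaluationError(f"ROI {roi!r} mask is empty")
    dmax = float(vals.max())
    edges = np.arange(0.0, dmax + 2 * bin_width, bin_width)
    counts, _ = np.histogram(vals, bins=edges)
    # volume receiving >= edge e: all voxels in bins at or above e
    above = np.concatenate([np.cumsum(counts[::-1])[::-1], [0]])
    frac = 100.0 * above / vals.size
    return DVHCurve(roi=roi, dose_edges=edges, volume_fraction=frac,
                    dmax=dmax, dmean=float(vals.mean()))


def dose_metric_pct_diff(gt: DVHCurve, pred: DVHCurve,
                         metric: str = "Dmax") -> float:
    """100 x (ground truth - predicted) / ground truth for Dmax or Dmean.

    Negative values mean the predicted plan exceeds the ground truth.
    """
    if gt.roi != pred.roi:
        raise EvaluationError(f"ROI mismatch: {gt.roi!r} vs {pred.roi!r}")
    g = getattr(gt, metric.lower())
    p = getattr(pred, metric.lower())
    if g == 0:
        raise EvaluationError(
            f"{metric} of the ground-truth {gt.roi!r} is zero; "
            "percent difference undefined")
    return 100.0 * (g - p) / g


# ---------------------------------------------------------------------------
# Plan-level reports
# ---------------------------------------------------------------------------

@dataclass
class PlanReport:
    """Evaluation of one predicted plan against its ground truth."""

    gamma: GammaResult
    dvh_table: pd.DataFrame          # one row per ROI
    gt_curves: dict[str, DVHCurve] = field(default_factory=dict)
    pred_curves: dict[str, DVHCurve] = field(default_factory=dict)


def evaluate_predicted_plan(pred_plan, gt_plan, phantom, machine,
                            criteria: GammaCriteria = GammaCriteria(),
                            engine_kwargs: dict | None = None,
                            gt_dose: Dose3D | None = None) -> PlanReport:
    """Recompute the predicted plan's dose with the same engine used for
    the ground truth, then report the gamma pass rate and per-ROI DVH
    metrics with their percent differences."""
    from .simulation import forward_dose_3d

    engine_kwargs = engine_kwargs or {}
    if gt_dose is None:
        gt_dose = forward_dose_3d(gt_plan, phantom, machine, **engine_kwargs)
    pred_dose = forward_dose_3d(pred_plan, phantom, machine, **engine_kwargs)
    gamma = gamma_index(gt_dose, pred_dose, criteria)

    rows = []
    gt_curves, pred_curves = {}, {}
    for roi, mask in phantom.roi_masks().items():
        if not np.any(mask):
            continue
        cg = dvh(gt_dose, mask, roi)
        cp = dvh(pred_dose, mask, roi)
        gt_curves[roi], pred_curves[roi] = cg, cp
        rows.append({
            "roi": roi,
            "dmax_gt": cg.dmax, "dmax_pred": cp.dmax,
            "dmax_pct_diff": dose_metric_pct_diff(cg, cp, "Dmax"),
            "dmean_gt": cg.dmean, "dmean_pred": cp.dmean,
            "dmean_pct_diff": dose_metric_pct_diff(cg, cp, "Dmean"),
        })
    return PlanReport(gamma=gamma, dvh_table=pd.DataFrame(rows),
                      gt_curves=gt_curves, pred_curves=pred_curves)


def gamma_table(reports: dict[int, PlanReport]) -> pd.DataFrame:
    """Per-fraction gamma pass rates plus their average — one test case's
    column of the cross-cohort gamma summary."""
    rows = [{"fraction": fx, "gamma_pass_rate": rep.gamma.pass_rate}
            for fx, rep in sorted(reports.items())]
    df = pd.DataFrame(rows)
    df.loc[len(df)] = {"fraction": "average",
                       "gamma_pass_rate": df["gamma_pass_rate"].mean()}
    return df


def dose_diff_table(reports: dict[int, PlanReport]) -> pd.DataFrame:
    """Max/mean dose percent differences per ROI averaged across the
    evaluated fractions."""
    frames = [rep.dvh_table.assign(fraction=fx)
              for fx, rep in sorted(reports.items())]
    allf = pd.concat(frames, ignore_index=True)
    return (allf.groupby("roi")[["dmax_pct_diff", "dmean_pct_diff"]]
            .mean().reset_index())
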