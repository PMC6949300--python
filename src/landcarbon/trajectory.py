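"""Per-pixel temporal segmentation and land-use typology.

An annual forest-probability series is decomposed into contiguous linear
segments (piecewise-linear fit anchored at observed vertex values, exact
dynamic programme over vertex placements), from which two management
indices (strongest increase / decrease rate), a nine-class dynamics code
and one of eight final land-use types are derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

LANDUSE_CODES = {
    1: "dense_forest",
    2: "forest",
    3: "non_forest",
    4: "recovery",
    5: "afforestation",
    6: "deforestation",
    7: "rotation",
    8: "rotation_L",
}
LANDUSE_NAMES = {v: k for k, v in LANDUSE_CODES.items()}

#: label used for pixels that could not be classified (too many gaps)
MASKED_LABEL = 0

INDEX_CATEGORIES = ("very_low", "low", "intermediate", "high")


@dataclass(frozen=True)
class ProbabilitySeries:
    """One pixel's annual forest-probability trajectory."""

    years: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        years = np.asarray(self.years, dtype=int)
        values = np.asarray(self.values, dtype=float)
        if years.shape != values.shape or years.ndim != 1:
            raise ValueError("years and values must be matching 1-D arrays")
        if np.any(np.diff(years) <= 0):
            raise ValueError("years must be strictly increasing")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.years)


@dataclass(frozen=True)
class Segment:
    """A single linear piece of a fitted trajectory.

    Years are inclusive calendar years; ``duration`` is measured in
    year-to-year steps and is therefore >= 1 for any non-degenerate
    segment.
    """

    start_year: int
    end_year: int
    start_value: float
    end_value: float

    @property
    def duration(self) -> int:
        return self.end_year - self.start_year

    @property
    def magnitude(self) -> float:
        return self.end_value - self.start_value

    @property
    def direction(self) -> int:
        return int(np.sign(self.magnitude))

    @property
    def rate(self) -> float:
        """Absolute change per year; the index contribution of the segment."""
        return abs(self.magnitude) / self.duration


@dataclass
class SegmentationResult:
    segments: list[Segment]
    fitted_values: np.ndarray
    sse: float
    years: np.ndarray = field(default=None)

    @property
    def n_segments(self) -> int:
        return len(self.segments)


@dataclass(frozen=True)
class DisturbanceIndices:
    increase_index: float
    decrease_index: float
    increase_category: str
    decrease_category: str


def _segment_cost_table(values: np.ndarray) -> np.ndarray:
    """SSE of linearly interpolating between anchored endpoints i..j.

    cost[i, j] = sum over interior points of (value - interpolant)^2 where
    the interpolant passes exactly through (i, values[i]) and
    (j, values[j]).  Decomposable per segment, which makes the dynamic
    programme below exact.
    """
    n = len(values)
    cost = np.zeros((n, n))
    idx = np.arange(n, dtype=float)
    for i in range(n):
        for j in range(i + 2, n):
            t = (idx[i + 1 : j] - i) / (j - i)
            interp = values[i] + t * (values[j] - values[i])
            cost[i, j] = float(np.sum((values[i + 1 : j] - interp) ** 2))
    return cost


def _best_partitions(values: np.ndarray, max_segments: int):
    """Exact DP over vertex placements.

    Returns ``(sse_by_k, vertices_by_k)`` where ``sse_by_k[k]`` is the
    minimal anchored-interpolation SSE achievable with exactly ``k``
    segments and ``vertices_by_k[k]`` the corresponding vertex index
    tuple (always including both endpoints).  Ties break toward the
    earliest vertex placement (lexicographically smallest tuple).
    """
    n = len(values)
    kmax = min(max_segments, n - 1)
    cost = _segment_cost_table(values)
    # best[(j, m)] = (sse, vertex tuple ending at j using m segments)
    best = {}
    for j in range(1, n):
        best[(j, 1)] = (cost[0, j], (0, j))
    for m in range(2, kmax + 1):
        for j in range(m, n):
            cand = None
            for i in range(m - 1, j):
                prev = best.get((i, m - 1))
                if prev is None:
                    continue
                sse = prev[0] + cost[i, j]
                verts = prev[1] + (j,)
                if cand is None or sse < cand[0] - 1e-15 or (
                    abs(sse - cand[0]) <= 1e-15 and verts < cand[1]
                ):
                    cand = (sse, verts)
            best[(j, m)] = cand
    sse_by_k = {}
    verts_by_k = {}
    for k in range(1, kmax + 1):
        sse, verts = best[(n - 1, k)]
        sse_by_k[k] = sse
        verts_by_k[k] = verts
    return sse_by_k, verts_by_k


def _select_k(sse_by_k: dict, n: int, alpha: float) -> int:
    """Smallest segment count that no richer fit improves on significantly.

    For candidate k, every k2 > k is compared via an F-test (each extra
    vertex value counts as one parameter, so the k-segment fit has k + 1
    parameters); k is accepted when no comparison is significant at
    ``alpha``.  A one-step-ahead test alone can stall on step-shaped
    series where a single extra vertex helps little but two remove the
    error entirely.
    """
    kmax = max(sse_by_k)
    tol = 1e-12 * max(sse_by_k[1], 1.0)
    for k in range(1, kmax):
        sse_k = sse_by_k[k]
        if sse_k <= tol:
            return k
        improved = False
        for k2 in range(k + 1, kmax + 1):
            sse_k2 = sse_by_k[k2]
            dof = n - (k2 + 1)
            if dof <= 0:
                break
            if sse_k2 <= tol:
                improved = True
                break
            f = ((sse_k - sse_k2) / (k2 - k)) / (sse_k2 / dof)
            if stats.f.sf(f, k2 - k, dof) < alpha:
                improved = True
                break
        if not improved:
            return k
    return kmax


def fill_gaps(values: np.ndarray, max_gap: int = 2) -> np.ndarray:
    """Linearly interpolate interior NaN runs of length <= max_gap.

    Returns None when the series cannot be repaired (leading/trailing
    NaNs or a gap longer than ``max_gap``).
    """
    values = np.asarray(values, dtype=float)
    bad = ~np.isfinite(values)
    if not bad.any():
        return values
    if bad[0] or bad[-1]:
        return None
    # longest run of consecutive NaNs
    run, longest = 0, 0
    for b in bad:
        run = run + 1 if b else 0
        longest = max(longest, run)
    if longest > max_gap:
        return None
    idx = np.arange(len(values))
    out = values.copy()
    out[bad] = np.interp(idx[bad], idx[~bad], values[~bad])
    return out


def segment_series(
    series,
    years=None,
    max_segments: int = 6,
    alpha: float = 0.05,
) -> SegmentationResult:
    """Fit a continuous piecewise-linear trajectory to an annual series.

    The fit is anchored at observed values at the chosen vertices; for a
    fixed segment count the vertex placement minimising the SSE is found
    by an exact dynamic programme, and the segment count is the smallest
    one for which adding a vertex no longer yields a significant F-test
    improvement at level ``alpha``.
    """
    if isinstance(series, ProbabilitySeries):
        values = series.values
        years = series.years
    else:
        values = np.asarray(series, dtype=float)
        years = (
            np.arange(len(values)) if years is None else np.asarray(years, dtype=int)
        )
    n = len(values)
    if n < 4:
        raise ValueError(f"series too short to segment (n={n}, need >= 4)")
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if not np.all(np.isfinite(values)):
        raise ValueError("series contains non-finite values; fill gaps first")
    sse_by_k, verts_by_k = _best_partitions(values, max_segments)
    k = _select_k(sse_by_k, n, alpha)
    verts = verts_by_k[k]
    fitted = np.empty(n)
    segments = []
    for a, b in zip(verts[:-1], verts[1:]):
        t = np.linspace(0.0, 1.0, b - a + 1)
        fitted[a : b + 1] = values[a] + t * (values[b] - values[a])
        segments.append(
            Segment(
                start_year=int(years[a]),
                end_year=int(years[b]),
                start_value=float(values[a]),
                end_value=float(values[b]),
            )
        )
    return SegmentationResult(
        segments=segments, fitted_values=fitted, sse=float(sse_by_k[k]), years=years
    )


def categorize_index(index: float) -> str:
    """Bin an index value: [0,0.2) very_low, [0.2,0.4) low, [0.4,0.6]
    intermediate, (0.6,1] high."""
    if index < 0.2:
        return "very_low"
    if index < 0.4:
        return "low"
    if index <= 0.6:
        return "intermediate"
    return "high"


def disturbance_indices(result: SegmentationResult) -> DisturbanceIndices:
    """Managed-forest increase / decrease indices.

    Each is the strongest signed change rate: max over segments of the
    (positive / negative) magnitude divided by the segment duration,
    zero when no segment of that sign exists.
    """
    if not result.segments:
        raise ValueError("empty segmentation")
    inc = 0.0
    dec = 0.0
    for seg in result.segments:
        if seg.magnitude > 0:
            inc = max(inc, seg.rate)
        elif seg.magnitude < 0:
            dec = max(dec, seg.rate)
    inc = min(inc, 1.0)
    dec = min(dec, 1.0)
    return DisturbanceIndices(
        increase_index=inc,
        decrease_index=dec,
        increase_category=categorize_index(inc),
        decrease_category=categorize_index(dec),
    )


def dynamics_class(
    series,
    result: SegmentationResult,
    theta_dense: float = 0.8,
    theta_forest: float = 0.5,
    seg_mag_tol: float = 0.02,
) -> int:
    """Nine-class trajectory dynamics code.

    1 all years >= theta_dense; 2 all >= theta_forest (not 1); 3 all
    below; 4/5 non-forest -> forest without/with a negative segment;
    6/7 forest -> non-forest without/with a positive segment; 8/9 both
    crossing directions with non-forest / forest endpoints.  A fitted
    segment only counts as positive/negative when its |magnitude|
    exceeds ``seg_mag_tol``, keeping the rule symmetric under time
    reversal.
    """
    values = series.values if isinstance(series, ProbabilitySeries) else np.asarray(
        series, dtype=float
    )
    if np.all(values >= theta_dense):
        return 1
    if np.all(values >= theta_forest):
        return 2
    if np.all(values < theta_forest):
        return 3
    has_pos = any(s.magnitude > seg_mag_tol for s in result.segments)
    has_neg = any(s.magnitude < -seg_mag_tol for s in result.segments)
    start_forest = values[0] >= theta_forest
    end_forest = values[-1] >= theta_forest
    if not start_forest and end_forest:
        return 5 if has_neg else 4
    if start_forest and not end_forest:
        return 7 if has_pos else 6
    if not start_forest and not end_forest:
        return 8
    return 9


def landuse_type(
    indices: DisturbanceIndices,
    dyn: int,
    disturbance_threshold: float = 0.4,
    high_threshold: float = 0.6,
) -> int:
    """Map (increase index, decrease index, dynamics class) to one of the
    eight final land-use types.

    Deterministic, total, priority-ordered rule table.  Residual
    index/dynamics combinations fall through to the documented fallback
    order at the bottom.
    """
    if dyn not in range(1, 10):
        raise ValueError(f"unknown dynamics class {dyn!r}")
    inc, dec = indices.increase_index, indices.decrease_index
    thr = disturbance_threshold
    if dyn == 1:
        return LANDUSE_NAMES["dense_forest"]
    if dyn == 2:
        return LANDUSE_NAMES["forest"]
    if dyn == 3:
        return LANDUSE_NAMES["non_forest"]
    if dyn == 4 and inc < thr:
        return LANDUSE_NAMES["recovery"]
    if dyn in (4, 5) and inc >= thr and dec < thr:
        return LANDUSE_NAMES["afforestation"]
    if dyn == 6:
        return LANDUSE_NAMES["deforestation"]
    if dyn == 7 and dec > high_threshold:
        return LANDUSE_NAMES["rotation_L"]
    if dyn in (5, 7, 8, 9) and inc >= thr and dec >= thr:
        return LANDUSE_NAMES["rotation"]
    # fallback order for residual combinations
    if dyn == 5:  # slow gain with intermediate harvest activity
        return LANDUSE_NAMES["rotation"]
    if dyn == 7:  # net loss with regrowth, harvest below the high band
        return LANDUSE_NAMES["rotation"]
    if dyn == 8:
        if inc >= thr or dec >= thr:
            return LANDUSE_NAMES["rotation"]
        return LANDUSE_NAMES["non_forest"]
    # dyn == 9
    if inc >= thr or dec >= thr:
        return LANDUSE_NAMES["rotation"]
    return LANDUSE_NAMES["forest"]


def classify_series(
    values,
    years=None,
    max_segments: int = 6,
    alpha: float = 0.05,
    theta_dense: float = 0.8,
    theta_forest: float = 0.5,
    disturbance_threshold: float = 0.4,
    high_threshold: float = 0.6,
    seg_mag_tol: float = 0.02,
    max_gap: int = 2,
):
    """Full per-pixel pipeline: gaps -> segmentation -> indices -> type.

    Returns a dict with keys ``label``, ``dynamics``, ``indices``,
    ``segmentation``; ``label`` is MASKED_LABEL when the series has
    unrecoverable gaps.
    """
    values = np.asarray(values, dtype=float)
    filled = fill_gaps(values, max_gap=max_gap)
    if filled is None:
        return {
            "label": MASKED_LABEL,
            "dynamics": None,
            "indices": None,
            "segmentation": None,
        }
    result = segment_series(filled, years=years, max_segments=max_segments, alpha=alpha)
    idx = disturbance_indices(result)
    dyn = dynamics_class(
        filled,
        result,
        theta_dense=theta_dense,
        theta_forest=theta_forest,
        seg_mag_tol=seg_mag_tol,
    )
    label = landuse_type(
        idx, dyn, disturbance_threshold=disturbance_threshold,
        high_threshold=high_threshold,
    )
    return {"label": label, "dynamics": dyn, "indices": idx, "segmentation": result}


def classify_scene(probability: np.ndarray, years=None, **kwargs):
    """Vectorised application of :func:`classify_series` over a scene.

    Parameters
    ----------
    probability : (n_years, n_rows, n_cols) array in [0, 1].
    years : optional calendar-year labels.

    Returns a ``(labels, summary)`` pair: an integer label map (0 where
    masked) and a dict with per-type pixel counts, areal fractions of
    valid pixels, masked-pixel count and per-pixel diagnostics.
    """
    probability = np.asarray(probability, dtype=float)
    if probability.ndim != 3:
        raise ValueError("probability must be (year, row, col)")
    ny, nr, nc = probability.shape
    if ny < 4:
        raise ValueError("need at least 4 annual layers")
    labels = np.zeros((nr, nc), dtype=int)
    diagnostics = []
    for r in range(nr):
        for c in range(nc):
            res = classify_series(probability[:, r, c], years=years, **kwargs)
            labels[r, c] = res["label"]
            diagnostics.append(
                {
                    "row": r,
                    "col": c,
                    "label": res["label"],
                    "dynamics": res["dynamics"],
                    "increase_index": res["indices"].increase_index
                    if res["indices"]
                    else np.nan,
                    "decrease_index": res["indices"].decrease_index
                    if res["indices"]
                    else np.nan,
                    "n_segments": res["segmentation"].n_segments
                    if res["segmentation"]
                    else 0,
                    "sse": res["segmentation"].sse if res["segmentation"] else np.nan,
                }
            )
    valid = labels != MASKED_LABEL
    n_valid = int(valid.sum())
    counts = {
        name: int(np.sum(labels == code)) for code, name in LANDUSE_CODES.items()
    }
    fractions = {
        name: (counts[name] / n_valid if n_valid else 0.0) for name in counts
    }
    summary = {
        "counts": counts,
        "fractions": fractions,
        "n_valid": n_valid,
        "n_masked": int((~valid).sum()),
        "diagnostics": diagnostics,
    }
    return labels, summary
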