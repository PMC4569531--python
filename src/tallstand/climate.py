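"""Climate derivations and the carbon-climate model comparison.

Plot AGC is regressed on candidate climate predictors (MAT, MAP, P:E)
with ordinary least squares and the candidates are ranked by AIC under
the full Gaussian log-likelihood convention,

    AIC = n·(ln 2π + ln(RSS/n) + 1) + 2k,   k = #slopes + intercept + variance,

which matches the convention of mainstream statistical environments and
makes ΔAIC values directly comparable between nested and non-nested
candidates. Candidates within ΔAIC < 2 of the best are flagged as having
equivalent support.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from .errors import DegenerateEnvelopeError, InsufficientDataError, SingularDesignError

#: Predictor names accepted by fit_agc_climate.
PREDICTORS = ("mat", "map", "pe")

#: Default candidate sets: null plus each single climate predictor.
DEFAULT_CANDIDATES = ((), ("mat",), ("map",), ("pe",))

#: Default stand-height classes (m); lower-closed, upper-open.
DEFAULT_HEIGHT_CLASSES = ((25.0, 35.0), (35.0, 45.0), (45.0, float("inf")))


def pe_ratio(map_mm, pan_evap_mm):
    """Precipitation-to-pan-evaporation ratio, an index of water availability."""
    p = np.asarray(map_mm, dtype=float)
    e = np.asarray(pan_evap_mm, dtype=float)
    if np.any(e <= 0):
        raise ValueError("pan evaporation must be positive")
    out = p / e
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ClimateModelFit:
    """One OLS candidate: AGC ~ intercept + predictors."""

    predictors: tuple[str, ...]
    coefficients: dict[str, float]  # includes "intercept"
    n: int
    rss: float
    r2: float
    aic: float
    delta_aic: float = 0.0
    equivalent_support: bool = False

    @property
    def k(self) -> int:
        """AIC parameter count: slopes + intercept + error variance."""
        return len(self.predictors) + 2

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        out = np.full(len(frame), self.coefficients["intercept"])
        for p in self.predictors:
            out = out + self.coefficients[p] * frame[p].to_numpy(dtype=float)
        return out


def gaussian_aic(n: int, rss: float, k: int) -> float:
    """AIC from the maximized Gaussian log-likelihood (constants included)."""
    if rss <= 0:
        # perfect fit: likelihood unbounded; report -inf so the exact model wins
        return float("-inf")
    return n * (np.log(2 * np.pi) + np.log(rss / n) + 1.0) + 2.0 * k


def _fit_one(frame: pd.DataFrame, predictors: tuple[str, ...]) -> ClimateModelFit:
    y = frame["agc"].to_numpy(dtype=float)
    n = len(y)
    X = np.column_stack([np.ones(n)] + [frame[p].to_numpy(dtype=float) for p in predictors])
    if n < X.shape[1] + 2:
        raise InsufficientDataError(
            f"candidate {predictors or ('null',)}: n={n} < parameters + 2"
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError(_collinear(frame, predictors))
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    # an RSS at floating-point rounding level is an exact fit; without this
    # the log-likelihood would rank candidates by numerical noise
    scale = float(np.max(np.abs(y))) or 1.0
    if rss <= n * (1e-10 * scale) ** 2:
        rss = 0.0
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if not predictors else (1.0 - rss / tss if tss > 0 else 0.0)
    coefficients = {"intercept": float(coef[0])}
    coefficients.update({p: float(c) for p, c in zip(predictors, coef[1:])})
    return ClimateModelFit(
        predictors=tuple(predictors),
        coefficients=coefficients,
        n=n,
        rss=rss,
        r2=r2,
        aic=gaussian_aic(n, rss, len(predictors) + 2),
    )


def _collinear(frame: pd.DataFrame, predictors) -> list[str]:
    """Name predictors involved in the rank deficiency."""
    cols = [frame[p].to_numpy(dtype=float) for p in predictors]
    bad = []
    kept: list[np.ndarray] = [np.ones(len(frame))]
    for name, col in zip(predictors, cols):
        trial = np.column_stack(kept + [col])
        if np.linalg.matrix_rank(trial) < trial.shape[1]:
            bad.append(name)
        else:
            kept.append(col)
    return bad or list(predictors)


def fit_agc_climate(plots, candidate_sets=DEFAULT_CANDIDATES) -> list[ClimateModelFit]:
    """Fit and AIC-rank candidate AGC-climate models.

    ``plots`` is a DataFrame with columns ``agc`` (tC/ha) and the needed
    predictors among ``mat`` (°C), ``map`` (mm), ``pe`` (unitless);
    excluded plots must already be removed. Returns fits sorted by AIC
    ascending with ΔAIC to the best; among candidates within ΔAIC < 2 the
    simpler model sorts first and all are flagged ``equivalent_support``.
    """
    frame = pd.DataFrame(plots)
    for cand in candidate_sets:
        for p in cand:
            if p not in PREDICTORS:
                raise ValueError(f"unknown predictor {p!r}")
    fits = [_fit_one(frame, tuple(c)) for c in candidate_sets]
    best = min(f.aic for f in fits)
    # delta is 0 for the best fit even when AIC is -inf (an exact fit)
    deltas = [0.0 if f.aic == best else f.aic - best for f in fits]
    fits = [
        ClimateModelFit(
            predictors=f.predictors,
            coefficients=f.coefficients,
            n=f.n,
            rss=f.rss,
            r2=f.r2,
            aic=f.aic,
            delta_aic=d,
            equivalent_support=d < 2.0,
        )
        for f, d in zip(fits, deltas)
    ]
    # AIC ascending; among near-ties (ΔAIC<2) the simpler candidate first
    fits.sort(key=lambda f: (f.aic if not f.equivalent_support else best, len(f.predictors), f.aic))
    return fits


@dataclass(frozen=True)
class EnvelopePlacement:
    inside: bool
    distance: float  # standardized climate units to the nearest hull edge


def climate_envelope(reference, query) -> EnvelopePlacement:
    """Place a (MAT, MAP) query against the forest estate's climate envelope.

    The envelope is the convex hull of the reference cloud in (MAT, MAP)
    standardized by the reference standard deviations — the
    least-assumption definition of an envelope. Returns whether the query
    falls inside (boundary counts as inside) and the distance to the
    nearest hull edge in standardized units.
    """
    ref = np.asarray(reference, dtype=float)
    if ref.ndim != 2 or ref.shape[1] != 2 or ref.shape[0] < 3:
        raise DegenerateEnvelopeError("need >= 3 (MAT, MAP) reference points")
    sd = ref.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise DegenerateEnvelopeError("reference climate has zero variance in one axis")
    mu = ref.mean(axis=0)
    z = (ref - mu) / sd
    q = (np.asarray(query, dtype=float) - mu) / sd
    try:
        hull = ConvexHull(z)
    except Exception as exc:  # qhull raises on collinear clouds
        raise DegenerateEnvelopeError(f"reference points are degenerate: {exc}") from None
    # hull.equations rows are (a, b, c) with a·x + b·y + c <= 0 inside
    signed = hull.equations[:, :2] @ q + hull.equations[:, 2]
    inside = bool(np.all(signed <= 1e-12))
    verts = z[hull.vertices]
    dist = min(
        _segment_distance(q, verts[i], verts[(i + 1) % len(verts)])
        for i in range(len(verts))
    )
    return EnvelopePlacement(inside=inside, distance=float(dist))


def _segment_distance(p, a, b) -> float:
    ab = b - a
    t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0)
    return float(np.linalg.norm(p - (a + t * ab)))


def classify_height_class(predicted_height: float, classes=DEFAULT_HEIGHT_CLASSES) -> str:
    """Assign a predicted stand height (m) to a height class.

    Classes are lower-closed, upper-open; heights below the lowest class
    are labelled ``below-range``.
    """
    if not predicted_height > 0:
        raise ValueError("predicted_height must be positive")
    for lo, hi in sorted(classes):
        if lo <= predicted_height < hi:
            return _class_label(lo, hi)
    return "below-range"


def _class_label(lo: float, hi: float) -> str:
    if np.isinf(hi):
        return f">{lo:g} m"
    return f"{lo:g}-{hi:g} m"
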