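"""Chemical age estimation from seasonal element cycles.

Otolith Mg:Ca and P:Ca both cycle seasonally (high in the growth season,
low in winter).  Counting shared winter minima along the transect gives the
fish's age; the minima are the annulus boundaries that split the transect
into annual growth zones.  Zones are then labelled with calendar years
(outermost zone = catch year) and per-zone mean ratios are computed for the
proxy table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .transect_processing import ElementTransect, RatioTransect


@dataclass(frozen=True)
class AgeingConfig:
    """Tunables of the extrema-based ageing method.

    smoothing_bandwidth_um
        Gaussian kernel half-width (sigma) for profile smoothing; must stay
        well below the narrowest expected annual increment.
    min_prominence
        Minimum trough prominence as a fraction of the smoothed profile's
        interquartile range for a candidate winter minimum.
    min_increment_fraction
        Boundaries closer than this fraction of the preceding increment are
        merged (deeper minimum kept) — a soft shrinking-increment prior.
    element_weights
        Relative trust in Mg:Ca vs P:Ca candidate positions when averaging
        a matched pair into one boundary.
    match_window_bandwidths
        Candidates from the two elements within this many bandwidths of one
        another count as the same winter; unmatched candidates are accepted
        only at twice the prominence threshold.
    """

    smoothing_bandwidth_um: float = 40.0
    min_prominence: float = 0.10
    min_increment_fraction: float = 0.3
    element_weights: dict = field(default_factory=lambda: {"mg_ca": 1.0, "p_ca": 1.0})
    match_window_bandwidths: float = 0.5

    def __post_init__(self):
        if self.smoothing_bandwidth_um <= 0:
            raise ValueError("bandwidth must be > 0")
        if not (0 < self.min_prominence < 1):
            raise ValueError("min_prominence must be in (0, 1)")
        if not (0 < self.min_increment_fraction <= 1):
            raise ValueError("min_increment_fraction must be in (0, 1]")


@dataclass
class AnnulusSet:
    """Annulus boundaries, age and growth zones for one fish.

    ``age_years`` = number of interior winter minima = completed years.
    Zones are half-open distance intervals [lo, hi) covering the transect
    (the last zone closed at the edge); there are age + 1 of them, the first
    being the Age-0 zone.
    """

    fish_id: str
    boundary_positions_um: np.ndarray
    age_years: int
    zone_spans: list  # list of (lo, hi)
    zone_calendar_years: list | None = None
    low_confidence: bool = False

    def __post_init__(self):
        b = np.asarray(self.boundary_positions_um, dtype=float)
        if not np.all(np.diff(b) > 0):
            raise ValueError("boundaries must be strictly increasing")
        if len(self.zone_spans) != self.age_years + 1:
            raise ValueError("zone count must equal age + 1")
        self.boundary_positions_um = b

    @property
    def zone_ages(self) -> list:
        return list(range(self.age_years + 1))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (lo, hi) in enumerate(self.zone_spans):
            rows.append(
                {
                    "fish_id": self.fish_id,
                    "zone_age": i,
                    "zone_year": None
                    if self.zone_calendar_years is None
                    else self.zone_calendar_years[i],
                    "zone_start_um": lo,
                    "zone_end_um": hi,
                }
            )
        return pd.DataFrame(rows)


def smooth_profile(
    r: RatioTransect, element: str, cfg: AgeingConfig | None = None
) -> np.ndarray:
    """Gaussian-kernel smooth of one ratio series on its own grid.

    Censored and non-finite points are excluded from the kernel average but
    still receive a smoothed estimate from their neighbours.  If the
    bandwidth is below the median sampling step the kernel degenerates; a
    3-point moving average is used instead (with a warning).
    """
    cfg = cfg or AgeingConfig()
    x = r.distance_um
    y = r.series(element)
    good = ~r.censored_mask & np.isfinite(y)
    if good.sum() < 5:
        raise ValueError("need >= 5 uncensored points to smooth")
    step = float(np.median(np.diff(x)))
    bw = cfg.smoothing_bandwidth_um
    if bw < step:
        warnings.warn(
            "smoothing bandwidth below the sampling step; using a 3-point window"
        )
        xv, yv = x[good], y[good]
        sm = np.convolve(np.pad(yv, 1, mode="edge"), np.ones(3) / 3, mode="valid")
        return np.interp(x, xv, sm)
    xg, yg = x[good], y[good]
    # evaluate the Nadaraya-Watson estimate at every grid point
    d = (x[:, None] - xg[None, :]) / bw
    w = np.exp(-0.5 * d * d)
    return (w @ yg) / w.sum(axis=1)


def _candidate_minima(x, s, cfg: AgeingConfig):
    """Local minima of a smoothed series with prominence relative to IQR."""
    iqr = float(np.subtract(*np.percentile(s, [75, 25])))
    scale = iqr if iqr > 0 else (s.max() - s.min() or 1.0)
    prom = cfg.min_prominence * scale
    idx, props = find_peaks(-s, prominence=prom)
    return x[idx], props["prominences"] / scale


def detect_annuli(
    r: RatioTransect, cfg: AgeingConfig | None = None
) -> AnnulusSet:
    """Place annulus boundaries at winter minima shared by Mg:Ca and P:Ca.

    Candidate minima from the two elements are matched within half a
    bandwidth (configurable); a matched pair is averaged with the element
    weights, an unmatched candidate is kept only if its prominence reaches
    twice the threshold.  Boundaries violating the shrinking-increment prior
    are merged, keeping the deeper minimum.  Deterministic.
    """
    cfg = cfg or AgeingConfig()
    x = r.distance_um
    if (~r.censored_mask).sum() < 5:
        raise ValueError("too few points to age")
    s_mg = smooth_profile(r, "mg_ca", cfg)
    s_p = smooth_profile(r, "p_ca", cfg)
    pos_mg, prom_mg = _candidate_minima(x, s_mg, cfg)
    pos_p, prom_p = _candidate_minima(x, s_p, cfg)

    tol = cfg.match_window_bandwidths * cfg.smoothing_bandwidth_um
    w_mg = cfg.element_weights.get("mg_ca", 1.0)
    w_p = cfg.element_weights.get("p_ca", 1.0)

    used_p = np.zeros(pos_p.size, dtype=bool)
    cands = []  # (position, depth score)
    low_confidence = False
    for pm, qm in zip(pos_mg, prom_mg):
        if pos_p.size:
            j = int(np.argmin(np.abs(pos_p - pm)))
        else:
            j = -1
        if j >= 0 and not used_p[j] and abs(pos_p[j] - pm) <= tol:
            used_p[j] = True
            pos = (w_mg * pm + w_p * pos_p[j]) / (w_mg + w_p)
            cands.append((pos, qm + prom_p[j]))
        elif qm >= 2 * cfg.min_prominence:
            cands.append((pm, qm))
            low_confidence = True
    for pp, qp in zip(pos_p[~used_p], prom_p[~used_p]):
        if qp >= 2 * cfg.min_prominence:
            cands.append((pp, qp))
            low_confidence = True

    cands.sort(key=lambda c: c[0])
    end = float(x[-1])
    # keep boundaries strictly interior
    cands = [c for c in cands if 0.0 < c[0] < end]

    # soft shrinking-increment prior: merge implausibly close boundaries
    merged = True
    while merged and len(cands) > 1:
        merged = False
        for i in range(1, len(cands)):
            prev_inc = cands[i - 1][0] - (cands[i - 2][0] if i >= 2 else 0.0)
            if cands[i][0] - cands[i - 1][0] < cfg.min_increment_fraction * prev_inc:
                drop = i if cands[i][1] <= cands[i - 1][1] else i - 1
                del cands[drop]
                merged = True
                break
    # increments never grow with age, so the Age-0 zone is the widest: a
    # first zone much narrower than the next marks a spurious early minimum
    while len(cands) > 1 and cands[0][0] < cfg.min_increment_fraction * (
        cands[1][0] - cands[0][0]
    ):
        del cands[0]

    bounds = np.array([c[0] for c in cands])
    spans = []
    lo = 0.0
    for b in bounds:
        spans.append((lo, float(b)))
        lo = float(b)
    spans.append((lo, end))
    return AnnulusSet(
        fish_id=r.fish_id,
        boundary_positions_um=bounds,
        age_years=len(bounds),
        zone_spans=spans,
        low_confidence=low_confidence,
    )


def assign_calendar_years(a: AnnulusSet, catch_year: int, catch_quarter: int = 4) -> AnnulusSet:
    """Label zones with calendar years: edge zone = catch year, earlier
    zones one year less each; the Age-0 zone gets catch_year - age."""
    if catch_year is None:
        raise ValueError("catch_year is required")
    if not 1 <= int(catch_quarter) <= 4:
        raise ValueError("catch_quarter must be 1..4")
    a.zone_calendar_years = [
        int(catch_year) - a.age_years + i for i in range(a.age_years + 1)
    ]
    return a


def annual_means(
    r: RatioTransect,
    a: AnnulusSet,
    element_transect: ElementTransect | None = None,
    mn_mg_mode: str = "pointwise",
    min_points: int = 3,
) -> pd.DataFrame:
    """Per-zone mean ratios over uncensored points.

    One row per growth zone — emitted with missing values and a flag when a
    zone has fewer than ``min_points`` usable samples, never dropped.  If
    the source ppm transect is supplied, zone-mean Sr ppm is included (for
    the salinity calibration, which works on concentrations).
    """
    x = r.distance_um
    ok = ~r.censored_mask
    rows = []
    for i, (lo, hi) in enumerate(a.zone_spans):
        last = i == len(a.zone_spans) - 1
        inz = (x >= lo) & ((x <= hi) if last else (x < hi))
        sel = inz & ok

        def zmean(v):
            vals = v[sel]
            vals = vals[np.isfinite(vals)]
            return float(vals.mean()) if vals.size else np.nan

        if mn_mg_mode == "pointwise":
            mn_mg = zmean(r.mn_mg)
        else:  # ratio of zone means
            mg = zmean(r.mg_ca)
            mn_mg = (zmean(r.mn_ca) / 1000.0) / mg if mg and np.isfinite(mg) else np.nan
        row = {
            "age": i,
            "calendar_year": None
            if a.zone_calendar_years is None
            else a.zone_calendar_years[i],
            "mn_mg": mn_mg,
            "mg_ca": zmean(r.mg_ca),
            "sr_ca": zmean(r.sr_ca),
            "p_ca": zmean(r.p_ca),
            "outer_boundary_um": hi,
            "n_points": int(sel.sum()),
            "flagged": bool(sel.sum() < min_points),
        }
        if element_transect is not None:
            row["sr_ppm"] = zmean(element_transect.concentrations_ppm["Sr"])
        rows.append(row)
    return pd.DataFrame(rows)
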