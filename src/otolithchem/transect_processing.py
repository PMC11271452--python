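"""Reading and conditioning of LA-ICP-MS otolith line-scan transects.

A transect is a laser line scan from the otolith core to the dorsal (or
proximal) edge, giving element mass fractions (ppm) for Mg, P, Mn, Sr and Ca
at strictly increasing distances from the core.  This module validates raw
transects, applies the Mg polyatomic-interference correction for affected
instrument batches, converts concentrations to molar ratios to Ca, censors
diagenetic Mn spikes by an iterative 3-sd rule, and rescales proximal-axis
scans onto the dorsal axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ELEMENTS = ("Mg", "P", "Mn", "Sr", "Ca")

#: CSV column names for a transect file.
TRANSECT_COLUMNS = ("distance_um",) + tuple(f"{el}_ppm" for el in ELEMENTS)


class TransectSchemaError(ValueError):
    """Raised when a transect file does not conform to the expected schema."""


class TransectValidationError(ValueError):
    """Raised when transect contents violate a structural invariant."""


@dataclass(frozen=True)
class CorrectionConfig:
    """Lab-correction and censoring parameters.

    mg_interference_factor
        Multiplier applied to Mg concentrations from instrument batches that
        suffer the 48Ca2+ polyatomic interference on 24Mg+ (constant
        overestimation; corrected by scaling down).
    affected_lab_tags
        Batch identifiers whose Mg series receives the correction.
    spike_sd_threshold
        Points whose ratio exceeds mean + threshold*sd (iteratively
        re-estimated) are censored as diagenetic outliers.
    """

    mg_interference_factor: float = 0.6
    affected_lab_tags: frozenset = frozenset({"SUNY-ESF"})
    spike_sd_threshold: float = 3.0
    # outlier statistics on the log scale (ratios are strictly positive with
    # multiplicative noise); set False for raw-scale mean/sd
    spike_log_scale: bool = True
    atomic_masses: dict = field(
        default_factory=lambda: {
            "Mg": 24.305,
            "P": 30.974,
            "Mn": 54.938,
            "Sr": 87.62,
            "Ca": 40.078,
        }
    )
    # Zone-mean Mn:Mg: "pointwise" averages the per-sample Mn/Mg ratio,
    # "ratio_of_means" divides zone-mean Mn:Ca by zone-mean Mg:Ca.
    mn_mg_mode: str = "pointwise"

    def __post_init__(self):
        if not (0.0 < self.mg_interference_factor <= 1.0):
            raise ValueError("mg_interference_factor must be in (0, 1]")
        if self.spike_sd_threshold <= 0:
            raise ValueError("spike_sd_threshold must be > 0")


@dataclass
class ElementTransect:
    """One otolith's line scan: distances from core plus ppm series."""

    fish_id: str
    distance_um: np.ndarray
    concentrations_ppm: dict  # element -> np.ndarray
    axis: str = "dorsal"
    lab_tag: str = ""
    mg_correction_applied: bool = False

    def __post_init__(self):
        self.distance_um = np.asarray(self.distance_um, dtype=float)
        self.concentrations_ppm = {
            el: np.asarray(v, dtype=float)
            for el, v in self.concentrations_ppm.items()
        }
        n = self.distance_um.size
        if n < 2:
            raise TransectValidationError("transect needs at least 2 points")
        for el in ELEMENTS:
            if el not in self.concentrations_ppm:
                raise TransectSchemaError(f"missing element series: {el}")
            if self.concentrations_ppm[el].size != n:
                raise TransectValidationError(f"{el} series length mismatch")
        if not np.all(np.diff(self.distance_um) > 0):
            raise TransectValidationError("distances must be strictly increasing")
        for el, v in self.concentrations_ppm.items():
            if np.any(v < 0):
                raise TransectValidationError(f"negative {el} concentration")
        if np.any(self.concentrations_ppm["Ca"] <= 0):
            raise TransectValidationError("Ca must be > 0 everywhere")
        if self.axis not in ("dorsal", "proximal", "dorsal-equivalent"):
            raise TransectValidationError(f"unknown axis {self.axis!r}")

    def __len__(self) -> int:
        return self.distance_um.size

    def to_frame(self) -> pd.DataFrame:
        data = {"distance_um": self.distance_um}
        for el in ELEMENTS:
            data[f"{el}_ppm"] = self.concentrations_ppm[el]
        return pd.DataFrame(data)


@dataclass
class RatioTransect:
    """Molar element:Ca ratios along a transect.

    Units: Mg:Ca, P:Ca, Sr:Ca in mmol/mol; Mn:Ca in umol/mol; Mn:Mg is a
    dimensionless molar ratio.  ``censored_mask`` flags points removed by
    spike censoring; ``mn_mg_undefined`` flags points where Mg = 0 so the
    pointwise Mn:Mg does not exist (NaN, never fabricated).
    """

    fish_id: str
    distance_um: np.ndarray
    mg_ca: np.ndarray  # mmol/mol
    p_ca: np.ndarray  # mmol/mol
    sr_ca: np.ndarray  # mmol/mol
    mn_ca: np.ndarray  # umol/mol
    mn_mg: np.ndarray  # mol/mol, dimensionless
    axis: str = "dorsal"
    censored_mask: np.ndarray | None = None
    mn_mg_undefined: np.ndarray | None = None

    def __post_init__(self):
        self.distance_um = np.asarray(self.distance_um, dtype=float)
        if self.censored_mask is None:
            self.censored_mask = np.zeros(self.distance_um.size, dtype=bool)
        if self.mn_mg_undefined is None:
            self.mn_mg_undefined = np.zeros(self.distance_um.size, dtype=bool)

    def __len__(self) -> int:
        return self.distance_um.size

    def series(self, name: str) -> np.ndarray:
        return {
            "mg_ca": self.mg_ca,
            "p_ca": self.p_ca,
            "sr_ca": self.sr_ca,
            "mn_ca": self.mn_ca,
            "mn_mg": self.mn_mg,
        }[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "distance_um": self.distance_um,
                "mg_ca_mmolmol": self.mg_ca,
                "p_ca_mmolmol": self.p_ca,
                "sr_ca_mmolmol": self.sr_ca,
                "mn_ca_umolmol": self.mn_ca,
                "mn_mg_molmol": self.mn_mg,
                "censored": self.censored_mask.astype(int),
            }
        )


def read_transect(path, fish_id: str | None = None, axis: str = "dorsal",
                  lab_tag: str = "") -> ElementTransect:
    """Read a transect CSV (distance_um, Mg_ppm, ..., Ca_ppm).

    Rows containing non-finite values are dropped with a logged count.
    """
    df = pd.read_csv(path)
    for col in TRANSECT_COLUMNS:
        if col not in df.columns:
            raise TransectSchemaError(f"transect file missing column {col!r}")
    df = df[list(TRANSECT_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    finite = np.isfinite(df.to_numpy()).all(axis=1)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.info("read_transect(%s): dropped %d non-finite row(s)", path, n_dropped)
        df = df.loc[finite]
    if fish_id is None:
        fish_id = str(getattr(path, "stem", path))
    return ElementTransect(
        fish_id=fish_id,
        distance_um=df["distance_um"].to_numpy(),
        concentrations_ppm={el: df[f"{el}_ppm"].to_numpy() for el in ELEMENTS},
        axis=axis,
        lab_tag=lab_tag,
    )


def apply_mg_interference_correction(
    t: ElementTransect, cfg: CorrectionConfig
) -> ElementTransect:
    """Scale Mg by the interference factor iff the lab batch is affected.

    Guarded against double application via ``mg_correction_applied``.
    """
    if t.mg_correction_applied:
        raise ValueError(
            f"Mg interference correction already applied to {t.fish_id}"
        )
    conc = dict(t.concentrations_ppm)
    if t.lab_tag in cfg.affected_lab_tags:
        conc["Mg"] = conc["Mg"] * cfg.mg_interference_factor
    return replace(t, concentrations_ppm=conc, mg_correction_applied=True)


def compute_ratios(t: ElementTransect, cfg: CorrectionConfig | None = None) -> RatioTransect:
    """Convert ppm mass fractions to molar ratios to Ca.

    Me:Ca (mmol/mol) = (Me_ppm / M_Me) / (Ca_ppm / M_Ca) * 1000; Mn:Ca is
    additionally reported in umol/mol; the pointwise Mn:Mg molar ratio is
    NaN-flagged where Mg = 0.
    """
    cfg = cfg or CorrectionConfig()
    m = cfg.atomic_masses
    ca_mol = t.concentrations_ppm["Ca"] / m["Ca"]

    def me_ca(el: str) -> np.ndarray:
        return (t.concentrations_ppm[el] / m[el]) / ca_mol * 1000.0

    mg_mol = t.concentrations_ppm["Mg"] / m["Mg"]
    mn_mol = t.concentrations_ppm["Mn"] / m["Mn"]
    undefined = mg_mol == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        mn_mg = np.where(undefined, np.nan, mn_mol / np.where(undefined, 1.0, mg_mol))
    return RatioTransect(
        fish_id=t.fish_id,
        distance_um=t.distance_um.copy(),
        mg_ca=me_ca("Mg"),
        p_ca=me_ca("P"),
        sr_ca=me_ca("Sr"),
        mn_ca=me_ca("Mn") * 1000.0,  # mmol/mol -> umol/mol
        mn_mg=mn_mg,
        axis=t.axis,
    )


def censor_diagenetic_spikes(
    r: RatioTransect, element: str = "mn_ca", cfg: CorrectionConfig | None = None
) -> RatioTransect:
    """Mask highly elevated outliers of one element ratio (diagenesis).

    Iterative rule: compute mean and sd over the uncensored points, mask
    points above mean + threshold*sd, repeat until no point exceeds.  The
    mask applies to the whole transect row (all ratio series); values are
    never altered, only flagged.
    """
    cfg = cfg or CorrectionConfig()
    series = r.series(element)
    mask = r.censored_mask.copy()
    if (~mask).sum() < 3:
        raise TransectValidationError("need >= 3 uncensored points to censor")
    if cfg.spike_log_scale:
        with np.errstate(divide="ignore", invalid="ignore"):
            work = np.where(series > 0, np.log(np.where(series > 0, series, 1.0)), np.nan)
    else:
        work = series
    while True:
        active = ~mask & np.isfinite(work)
        vals = work[active]
        if vals.size == 0:
            raise TransectValidationError(
                f"censoring removed every point of {r.fish_id}"
            )
        mu, sd = vals.mean(), vals.std(ddof=1) if vals.size > 1 else 0.0
        over = active & (work > mu + cfg.spike_sd_threshold * sd) & (sd > 0)
        if not over.any():
            break
        mask |= over
    if mask.all():
        raise TransectValidationError(f"all points censored for {r.fish_id}")
    out = replace(r)
    out.censored_mask = mask
    n = int(mask.sum() - r.censored_mask.sum())
    if n:
        logger.info("censor_diagenetic_spikes(%s): masked %d point(s)", r.fish_id, n)
    return out


def normalize_proximal_axis(
    r: RatioTransect, dorsal_radius_um: float, proximal_radius_um: float
) -> RatioTransect:
    """Rescale a proximal-axis scan linearly onto the dorsal axis.

    Distances are multiplied by dorsal_radius/proximal_radius; ratios are
    unchanged; the axis is relabelled ``dorsal-equivalent``.
    """
    if dorsal_radius_um <= 0 or proximal_radius_um <= 0:
        raise ValueError("radii must be > 0")
    if r.axis != "proximal":
        raise ValueError("normalize_proximal_axis expects a proximal-axis transect")
    out = replace(r)
    out.distance_um = r.distance_um * (dorsal_radius_um / proximal_radius_um)
    out.axis = "dorsal-equivalent"
    return out
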