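"""Downstream phenotype quantification: exact test, tumor volume,
wound closure, dose conversion, and vessel-area fraction.

These are the small closed-form statistics used to quantify the follow-up
experiments once candidate compounds are in hand: an exact 2×2 test for
phenotype incidence between treatment groups, caliper-based tumor volume,
scratch-assay wound closure, mg/kg ↔ µM-equivalent dose arithmetic, and
thresholded vessel staining area.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .errors import ParameterError

log = logging.getLogger(__name__)

#: Thiabendazole molar mass, g/mol: C10H7N3S from the systematic name
#: 4-(1H-1,3-benzodiazol-2-yl)-1,3-thiazole
#: (10*12.011 + 7*1.008 + 3*14.007 + 32.06 = 201.25).
THIABENDAZOLE_MOLAR_MASS = 201.25

#: Relative tolerance for the "as-or-less-probable" comparison in the exact
#: test; absorbs floating-point noise when two tables tie exactly.
_FISHER_RELTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b) for group 1 and (c, d) for group 2, columns =
    phenotype present / absent."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in counts):
            raise ParameterError("counts must be nonnegative integers")
        if sum(counts) <= 0:
            raise ParameterError("table total must be positive")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_exact_2x2(t: ContingencyTable2x2) -> float:
    """Two-sided exact conditional test on a 2×2 table.

    Conditions on both margins and sums the hypergeometric probability of
    every table as-or-less-probable than the observed one (the standard
    two-sided rule; mid-p is not used). Returns p ∈ (0, 1].
    """
    n = t.total
    r1 = t.a + t.b  # group 1 size
    c1 = t.a + t.c  # phenotype-present column total
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    k = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(k, n, c1, r1)
    p_obs = hypergeom.pmf(t.a, n, c1, r1)
    p = float(pmf[pmf <= p_obs * (1.0 + _FISHER_RELTOL)].sum())
    return min(p, 1.0)


@dataclass(frozen=True)
class TumorMeasurement:
    """Caliper measurement of one tumor, in mm. By convention width is the
    shorter axis; swapped with a logged note if supplied reversed."""

    width: float
    length: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.length <= 0:
            raise ParameterError("tumor dimensions must be positive")
        if self.width > self.length:
            log.info(
                "width %.3g > length %.3g; swapping to keep width <= length",
                self.width,
                self.length,
            )
            w, l = self.width, self.length
            object.__setattr__(self, "width", l)
            object.__setattr__(self, "length", w)


def tumor_volume(tm: TumorMeasurement) -> float:
    """Ellipsoid-style caliper volume in mm³: width² × length / 2."""
    return tm.width**2 * tm.length / 2.0


def wound_closure_ratio(area_0: float, area_t: float) -> float:
    """Scratch-assay closure: (area at 0 h − area at t) / area at 0 h.

    Negative closure (wound grew) is reported as-is with a logged note,
    not clamped.
    """
    if area_0 <= 0:
        raise ParameterError("initial cell-free area must be positive")
    if area_t < 0:
        raise ParameterError("cell-free area cannot be negative")
    if area_t > area_0:
        log.info("area grew (%.3g > %.3g); reporting negative closure", area_t, area_0)
    return (area_0 - area_t) / area_0


@dataclass(frozen=True)
class DoseSpec:
    """One administered dose: ``mass`` mg of compound into a ``body_mass`` g
    animal. ``density_assumption`` (kg/L, default 1) converts µmol/kg into a
    µM-equivalent body concentration."""

    mass: float
    body_mass: float
    molar_mass: float = THIABENDAZOLE_MOLAR_MASS
    density_assumption: float = 1.0

    def __post_init__(self) -> None:
        for name in ("mass", "body_mass", "molar_mass", "density_assumption"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")


def dose_convert(ds: DoseSpec) -> tuple[float, float]:
    """Return (mg/kg, µmol/kg). Under the 1 kg ≈ 1 L density assumption the
    µmol/kg figure doubles as the µM-equivalent whole-body concentration."""
    mg_per_kg = ds.mass / (ds.body_mass / 1000.0)
    umol_per_kg = mg_per_kg / ds.molar_mass * 1000.0 / ds.density_assumption
    return mg_per_kg, umol_per_kg


def vessel_area_fraction(
    image: np.ndarray, threshold: float
) -> tuple[float, int]:
    """Fraction (and count) of pixels strictly above an intensity threshold.

    Quantifies vessel staining (e.g. PECAM-1 immunofluorescence) as the area
    above an arbitrary-units intensity cutoff.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ParameterError("empty image")
    if not np.isfinite(threshold):
        raise ParameterError("threshold must be finite")
    count = int((img > threshold).sum())
    return count / img.size, count
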