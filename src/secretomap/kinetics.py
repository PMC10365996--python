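"""Secretion kinetics: TIC/area curves, onset, plateau, fits, typing.

Two scalar summaries are reduced from each secretion map stack: the total
intensity change (TIC — per-frame sum of the non-zero pixels, a proxy for
the amount of analyte bound near the cell) and the secretion area (non-zero
pixel count times physical pixel area).  The TIC curve shape classifies
each cell:

* **NS** — non-secreting: no onset, or maximum TIC below the noise floor;
* **type I** — linear rise throughout; one linear fit from onset to the
  time the signal reaches 80% of its maximum;
* **type II** — rise then plateau to the end (half sigmoid); same single
  fit;
* **type III** — rise, plateau, second rise; two fits: onset to 80% of the
  plateau mean, and plateau end to 80% of the maximum.

A plateau starts when the signal fails to increase for three successive
frames and ends when it rises for three successive frames.  Secretion
duration is the fitted-interval length (the sum of both for type III); the
plateau itself is never counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import FitError
from .mapping import SecretionMapStack

__all__ = [
    "TICCurve",
    "AreaCurve",
    "PlateauInterval",
    "LinearFit",
    "KineticsRecord",
    "PopulationStats",
    "KineticsConfig",
    "tic_curve",
    "area_curve",
    "detect_onset",
    "detect_plateau",
    "fit_segment",
    "classify_and_fit",
    "population_summary",
]

SECRETION_TYPES = ("NS", "I", "II", "III")


@dataclass
class TICCurve:
    """Total intensity change per frame (a.u.), with times in minutes."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(self.values < 0):
            raise ValueError("TIC values must be >= 0")


@dataclass
class AreaCurve:
    """Secretion area per frame (um^2), with times in minutes."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("areas must be >= 0")


@dataclass
class PlateauInterval:
    start: float  # minutes
    end: float
    plateau_mean: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("plateau start must precede end")


@dataclass
class LinearFit:
    """Least-squares line over a time interval; slope reported per hour."""

    slope_per_h: float
    intercept: float
    r_squared: float
    t_start: float
    t_end: float
    degenerate: bool = False

    @property
    def duration_min(self) -> float:
        return self.t_end - self.t_start


@dataclass
class KineticsRecord:
    """Kinetic summary for one cell."""

    cell_id: str
    secretion_type: str  # NS | I | II | III
    onset_min: float | None
    duration_min: float
    fits: list[LinearFit]
    max_tic: float
    max_area: float = 0.0
    plateau: PlateauInterval | None = None
    apoptosis_onset_min: float | None = None
    diagnostics: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.secretion_type not in SECRETION_TYPES:
            raise ValueError(f"unknown secretion type {self.secretion_type!r}")
        if self.secretion_type == "NS" and self.fits:
            raise ValueError("NS records carry no fits")
        if self.secretion_type == "III" and len(self.fits) != 2:
            raise ValueError("type III requires exactly 2 fits")


@dataclass
class PopulationStats:
    """Per-type counts, percentages and parameter summaries for a population."""

    n_total: int
    counts: dict[str, int]
    percentages: dict[str, float]  # of n_total, 1 decimal
    secreting_fraction_pct: float
    max_tic_mean_sd: dict[str, tuple[float, float]]
    max_area_mean_sd: dict[str, tuple[float, float]]
    rate_mean_sd: dict[str, tuple[float, float]]


@dataclass
class KineticsConfig:
    """Tunables for onset/plateau detection and NS gating.

    ``epsilon`` is the no-increase tolerance as a fraction of the curve
    maximum (0 reproduces the literal "did not increase" rule).  The
    default 0.005 sits between the plateau fluctuation scale and the mean
    per-frame increment of a full-range linear curve (~1.4% of max for 73
    frames), so ramps are not misread as plateaus.
    ``noise_floor`` is an absolute TIC threshold below which a cell is
    called NS (typically derived from the reference-well residual TIC via
    ``noise_floor_mult``).  ``persistence`` (default 3, echoing the
    three-successive-frames motif of the plateau rules) demands a
    sustained crossing: isolated noise excursions above the floor do not
    start a secretion record.
    """

    persistence: int = 3
    epsilon: float = 0.005
    noise_floor: float = 0.0
    noise_floor_mult: float = 5.0
    max_fraction: float = 0.8


def tic_curve(maps: SecretionMapStack) -> TICCurve:
    """Per-frame sum of the non-zero pixels of each secretion map frame.

    With the nonnegativity clamp applied upstream this equals the full
    frame sum.
    """
    values = maps.frames.reshape(len(maps.frames), -1).sum(axis=1)
    return TICCurve(times=maps.times.copy(), values=values)


def area_curve(maps: SecretionMapStack, pixel_area_um2: float) -> AreaCurve:
    """Non-zero pixel count per frame times the physical pixel area."""
    if pixel_area_um2 <= 0:
        raise ValueError("pixel_area_um2 must be > 0")
    counts = (maps.frames > 0).reshape(len(maps.frames), -1).sum(axis=1)
    return AreaCurve(times=maps.times.copy(), values=counts * pixel_area_um2)


def detect_onset(
    curve: TICCurve, persistence: int = 1, floor: float = 0.0
) -> float | None:
    """Earliest time with TIC > ``floor`` sustained for ``persistence`` frames.

    ``persistence=1`` with ``floor=0`` is the literal first-nonzero rule;
    higher values reject single-frame blips, and a positive floor (e.g. the
    reference-well residual TIC level) rejects the residual noise that
    survives the one-sided 3-sigma gate.  Returns ``None`` when never
    sustained.
    """
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    positive = curve.values > floor
    run = 0
    for i, flag in enumerate(positive):
        run = run + 1 if flag else 0
        if run >= persistence:
            return float(curve.times[i - persistence + 1])
    return None


def detect_plateau(
    curve: TICCurve, epsilon: float = 0.005, onset: float | None = None
) -> PlateauInterval | None:
    """Find the first plateau after onset, if any.

    A plateau can only follow a rise ("a plateau after experiencing the
    first increase"): the search starts at the first step after onset that
    increases by more than ``epsilon * max(tic)``.  The plateau starts at
    the first later time from which three successive steps each increase
    by at most that tolerance, and ends at the first subsequent time from
    which three successive steps each increase by more; absent such a rise
    it extends to the curve end.  Requires at least 7 frames after onset.
    """
    if onset is None:
        onset = detect_onset(curve)
    if onset is None:
        return None
    start_idx = int(np.searchsorted(curve.times, onset))
    # need >= 7 frames overall and room for a rise plus a flat triple
    if len(curve.times) < 7 or len(curve.times) - start_idx < 5:
        return None
    tol = epsilon * float(curve.values.max())
    steps = np.diff(curve.values)

    rising_steps = np.nonzero(steps[start_idx:] > tol)[0]
    if len(rising_steps) == 0:
        return None
    first_rise = start_idx + int(rising_steps[0])

    flat = steps <= tol
    s = None
    for i in range(first_rise + 1, len(steps) - 2):
        if flat[i] and flat[i + 1] and flat[i + 2]:
            s = i
            break
    if s is None:
        return None

    rising = steps > tol
    e = None
    for i in range(s + 3, len(steps) - 2):
        if rising[i] and rising[i + 1] and rising[i + 2]:
            e = i
            break
    end_time = float(curve.times[e]) if e is not None else float(curve.times[-1])
    start_time = float(curve.times[s])
    sel = (curve.times >= start_time) & (curve.times <= end_time)
    return PlateauInterval(
        start=start_time, end=end_time, plateau_mean=float(curve.values[sel].mean())
    )


def fit_segment(
    curve: TICCurve | AreaCurve, interval: tuple[float, float]
) -> LinearFit:
    """Least-squares line over ``interval`` (inclusive); slope per hour.

    A constant segment has an undefined R^2: it is reported as 0 with the
    ``degenerate`` flag set.  Fewer than 3 samples raise :class:`FitError`.
    """
    t0, t1 = interval
    sel = (curve.times >= t0) & (curve.times <= t1)
    if sel.sum() < 3:
        raise FitError(
            f"interval [{t0}, {t1}] min contains {int(sel.sum())} samples; need >= 3"
        )
    x = curve.times[sel] / 60.0  # hours
    y = curve.values[sel]
    if np.ptp(y) == 0:
        return LinearFit(
            slope_per_h=0.0,
            intercept=float(y[0]),
            r_squared=0.0,
            t_start=float(curve.times[sel][0]),
            t_end=float(curve.times[sel][-1]),
            degenerate=True,
        )
    result = stats.linregress(x, y)
    return LinearFit(
        slope_per_h=float(result.slope),
        intercept=float(result.intercept),
        r_squared=float(result.rvalue**2),
        t_start=float(curve.times[sel][0]),
        t_end=float(curve.times[sel][-1]),
    )


def _first_time_reaching(curve: TICCurve, level: float, after: float) -> float:
    sel = (curve.times >= after) & (curve.values >= level)
    if not sel.any():
        return float(curve.times[-1])
    return float(curve.times[np.argmax(sel)])


def classify_and_fit(
    curve: TICCurve,
    config: KineticsConfig | None = None,
    cell_id: str = "cell",
    area: AreaCurve | None = None,
    apoptosis_onset_min: float | None = None,
) -> KineticsRecord:
    """Classify the secretion type of a TIC curve and fit its linear parts.

    Degenerate curves never raise; they produce NS records with
    diagnostics.
    """
    cfg = config or KineticsConfig()
    max_tic = float(curve.values.max()) if len(curve.values) else 0.0
    max_area = float(area.values.max()) if area is not None else 0.0
    diagnostics: list[str] = []

    def ns(reason: str) -> KineticsRecord:
        diagnostics.append(reason)
        return KineticsRecord(
            cell_id=cell_id,
            secretion_type="NS",
            onset_min=None,
            duration_min=0.0,
            fits=[],
            max_tic=max_tic,
            max_area=max_area,
            apoptosis_onset_min=apoptosis_onset_min,
            diagnostics=diagnostics,
        )

    onset = detect_onset(curve, persistence=cfg.persistence, floor=cfg.noise_floor)
    if onset is None:
        return ns("no onset: TIC never exceeded the noise floor")
    if cfg.noise_floor > 0 and max_tic <= cfg.noise_floor:
        return ns(f"max TIC {max_tic:.3g} below noise floor {cfg.noise_floor:.3g}")

    plateau = detect_plateau(curve, epsilon=cfg.epsilon, onset=onset)
    ends_at_curve_end = plateau is not None and plateau.end >= float(curve.times[-1])

    try:
        if plateau is not None and not ends_at_curve_end:
            # candidate type III: rise, plateau, second rise
            t80_plateau = _first_time_reaching(
                curve, cfg.max_fraction * plateau.plateau_mean, onset
            )
            t80_max = _first_time_reaching(
                curve, cfg.max_fraction * max_tic, plateau.end
            )
            try:
                second = fit_segment(curve, (plateau.end, t80_max))
                secretion_type = "III"
                fits = [fit_segment(curve, (onset, t80_plateau)), second]
            except FitError:
                # a "further rise" too short to fit is not a rise: the curve
                # was already at its plateau/maximum, i.e. type II
                diagnostics.append(
                    "post-plateau rise unsupportable by a fit; classified II"
                )
                plateau = None
                secretion_type = "II"
                t80 = _first_time_reaching(curve, cfg.max_fraction * max_tic, onset)
                fits = [fit_segment(curve, (onset, t80))]
        else:
            secretion_type = "I" if plateau is None else "II"
            t80 = _first_time_reaching(curve, cfg.max_fraction * max_tic, onset)
            fits = [fit_segment(curve, (onset, t80))]
    except FitError as exc:
        return ns(f"fit failed: {exc}")

    return KineticsRecord(
        cell_id=cell_id,
        secretion_type=secretion_type,
        onset_min=onset,
        duration_min=sum(f.duration_min for f in fits),
        fits=fits,
        max_tic=max_tic,
        max_area=max_area,
        plateau=plateau,
        apoptosis_onset_min=apoptosis_onset_min,
        diagnostics=diagnostics,
    )


def _mean_sd(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    if len(arr) == 0:
        return (float("nan"), float("nan"))
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return (float(arr.mean()), sd)


def population_summary(records: list[KineticsRecord]) -> PopulationStats:
    """Per-type counts, percentages (1 decimal) and mean +/- sd summaries.

    Standard deviations use the sample (n-1) denominator.  The secreting
    fraction counts every non-NS record.
    """
    if not records:
        raise ValueError("need at least one record")
    n = len(records)
    counts = {t: 0 for t in SECRETION_TYPES}
    for rec in records:
        counts[rec.secretion_type] += 1
    percentages = {t: round(100.0 * c / n, 1) for t, c in counts.items()}
    n_secreting = n - counts["NS"]

    tic_by, area_by, rate_by = {}, {}, {}
    for t in ("I", "II", "III"):
        members = [r for r in records if r.secretion_type == t]
        tic_by[t] = _mean_sd([r.max_tic for r in members])
        area_by[t] = _mean_sd([r.max_area for r in members])
        rate_by[t] = _mean_sd([f.slope_per_h for r in members for f in r.fits])

    return PopulationStats(
        n_total=n,
        counts=counts,
        percentages=percentages,
        secreting_fraction_pct=round(100.0 * n_secreting / n, 1),
        max_tic_mean_sd=tic_by,
        max_area_mean_sd=area_by,
        rate_mean_sd=rate_by,
    )
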