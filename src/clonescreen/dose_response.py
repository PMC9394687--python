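"""Dose-response quantification: normalization, log-logistic IC50 fits,
fold-resistance, and dilution-series design.

The fitted model is the normalized variable-slope log-logistic
("log[inhibitor] vs normalized response"):

    response(x) = 100 / (1 + 10^((x - log10 IC50) * h))

with x = log10(concentration), viability in percent of vehicle, top
fixed at 100 and bottom at 0. A 4-parameter variant with free top and
bottom is available behind a flag. Fold-resistance is the IC50 ratio
of two fits of the same compound and is invariant to the concentration
unit as long as both curves share it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DataError, InputError

#: fitted IC50 must stay within this factor of the tested range to count
#: as converged
RANGE_SLACK = 100.0

#: minimum response spread (percent) below which a curve is flagged
#: non-responsive instead of fitted
FLAT_RESPONSE_SPAN = 10.0


@dataclass(frozen=True)
class DoseResponseDataset:
    """Replicated viability readings over a concentration series.

    Concentrations are molar; readings are raw luminescence until
    :func:`normalize_to_vehicle` converts them to percent viability.
    """

    compound: str
    sample: str
    points: tuple[tuple[float, tuple[float, ...]], ...]
    vehicle_readings: tuple[float, ...] = ()
    normalized: bool = False

    def __post_init__(self) -> None:
        for conc, readings in self.points:
            if conc <= 0:
                raise DataError(f"non-positive concentration {conc}")
            if not readings:
                raise DataError(f"no replicate readings at {conc}")

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for c, _ in self.points])

    def flat_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(concentration, reading) pairs with replicates unrolled."""
        conc, vals = [], []
        for c, readings in self.points:
            conc.extend([c] * len(readings))
            vals.extend(readings)
        return np.array(conc), np.array(vals)


@dataclass(frozen=True)
class DoseResponseFit:
    """Normalized log-logistic fit parameters.

    ``log_ic50`` is log10 of molar IC50; ``hill`` > 0 means viability
    decreases with concentration (an inhibitor). ``top``/``bottom``
    are fixed at 100/0 in the default normalized model.
    """

    log_ic50: float
    hill: float
    se_log_ic50: float
    se_hill: float
    converged: bool
    top: float = 100.0
    bottom: float = 0.0
    compound: str = ""
    sample: str = ""

    @property
    def ic50(self) -> float:
        return 10.0 ** self.log_ic50


def loglogistic(x, log_ic50, hill, top=100.0, bottom=0.0):
    """Normalized log-logistic response at x = log10(concentration)."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((x - log_ic50) * hill))


def normalize_to_vehicle(dataset: DoseResponseDataset) -> DoseResponseDataset:
    """Convert readings to percent of the mean vehicle reading.

    The vehicle mean maps to 100; applying the function twice is a
    no-op because normalized vehicle readings average 100.
    """
    if not dataset.vehicle_readings:
        raise DataError("dataset has no vehicle readings")
    vehicle_mean = float(np.mean(dataset.vehicle_readings))
    if vehicle_mean <= 0:
        raise DataError(f"vehicle mean must be positive, got {vehicle_mean}")
    factor = 100.0 / vehicle_mean
    return replace(
        dataset,
        points=tuple(
            (c, tuple(r * factor for r in readings)) for c, readings in dataset.points
        ),
        vehicle_readings=tuple(r * factor for r in dataset.vehicle_readings),
        normalized=True,
    )


def fit_normalized(
    dataset: DoseResponseDataset, free_top_bottom: bool = False
) -> DoseResponseFit:
    """Least-squares fit of the normalized log-logistic model.

    Initialization: log_ic50 at the concentration whose mean response
    is nearest 50%, hill = 1. Standard errors come from the curvature
    (inverse-information) approximation at the optimum. Optimizer
    failure, a non-responsive (flat) curve, a wrong-sign Hill slope, or
    an IC50 far outside the tested range yield ``converged=False``,
    never an exception.
    """
    distinct = {c for c, _ in dataset.points}
    if len(distinct) < 4:
        raise InputError(
            f"need >= 4 distinct concentrations to fit, got {len(distinct)}"
        )
    conc, y = dataset.flat_arrays()
    x = np.log10(conc)

    failed = DoseResponseFit(
        log_ic50=np.nan, hill=np.nan, se_log_ic50=np.nan, se_hill=np.nan,
        converged=False, compound=dataset.compound, sample=dataset.sample,
    )
    if np.ptp(y) < FLAT_RESPONSE_SPAN:
        return failed

    means = np.array([np.mean(r) for _, r in dataset.points])
    x0 = float(np.log10(dataset.concentrations[np.argmin(np.abs(means - 50.0))]))
    try:
        if free_top_bottom:
            p0 = [x0, 1.0, float(means.max()), float(means.min())]
            popt, pcov = curve_fit(loglogistic, x, y, p0=p0, maxfev=20000)
            log_ic50, hill, top, bottom = popt
        else:
            popt, pcov = curve_fit(loglogistic, x, y, p0=[x0, 1.0], maxfev=20000)
            log_ic50, hill = popt
            top, bottom = 100.0, 0.0
    except (RuntimeError, ValueError):
        return failed

    se = np.sqrt(np.abs(np.diag(pcov)))
    fit = DoseResponseFit(
        log_ic50=float(log_ic50), hill=float(hill),
        se_log_ic50=float(se[0]), se_hill=float(se[1]),
        converged=True, top=float(top), bottom=float(bottom),
        compound=dataset.compound, sample=dataset.sample,
    )
    in_range = (
        dataset.concentrations.min() / RANGE_SLACK
        <= fit.ic50
        <= dataset.concentrations.max() * RANGE_SLACK
    )
    if not np.isfinite(fit.hill) or fit.hill <= 0 or not in_range:
        return replace(fit, converged=False)
    return fit


def fold_resistance(mutant: DoseResponseFit, parental: DoseResponseFit) -> float:
    """IC50 ratio mutant / parental (> 1 means resistance)."""
    if not (mutant.converged and parental.converged):
        raise DataError("fold_resistance requires two converged fits")
    return 10.0 ** (mutant.log_ic50 - parental.log_ic50)


def design_dilution_series(
    max_conc: float,
    n_points: int,
    ratio: float | None = None,
    min_conc: float | None = None,
) -> np.ndarray:
    """Geometric dilution series descending from ``max_conc``.

    Exactly one of ``ratio`` (fold step) or ``min_conc`` must be given;
    with ``min_conc`` the step is (max/min)^(1/(n-1)).
    """
    if (ratio is None) == (min_conc is None):
        raise InputError("give exactly one of ratio or min_conc")
    if max_conc <= 0 or n_points < 2:
        raise InputError("max_conc must be > 0 and n_points >= 2")
    if ratio is None:
        if min_conc <= 0 or min_conc >= max_conc:
            raise InputError("min_conc must be in (0, max_conc)")
        ratio = (max_conc / min_conc) ** (1.0 / (n_points - 1))
    if ratio <= 1:
        raise InputError(f"dilution ratio must exceed 1, got {ratio}")
    return max_conc / ratio ** np.arange(n_points)


def screen_concentration_bracket(ic100: float) -> tuple[float, float, float]:
    """Selection concentrations bracketing the 1-week IC100: (/1.25, x1, x1.25)."""
    if ic100 <= 0:
        raise InputError(f"ic100 must be positive, got {ic100}")
    return (ic100 / 1.25, ic100, ic100 * 1.25)


def round_report(value: float, ndigits: int = 2) -> float:
    """Decimal half-even rounding of the printed value (reporting style,
    e.g. micromolar concentrations to 2 decimals: 1.225 -> 1.22)."""
    from decimal import ROUND_HALF_EVEN, Decimal

    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_EVEN))


def round_sig(value: float, digits: int = 2) -> float:
    """Round to significant figures (reporting style for fold values)."""
    if value == 0:
        return 0.0
    from math import floor, log10

    return round(value, -int(floor(log10(abs(value)))) + digits - 1)


VIABILITY_COLUMNS = (
    "compound", "sample", "concentration_molar", "replicate", "reading", "is_vehicle",
)


def read_viability_table(path: str | Path) -> list[DoseResponseDataset]:
    """Read a viability CSV/TSV into one dataset per (compound, sample)."""
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    missing = set(VIABILITY_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"viability table {path} lacks columns {sorted(missing)}")
    datasets = []
    for (compound, sample), group in df.groupby(["compound", "sample"], sort=True):
        vehicle = group[group["is_vehicle"].astype(bool)]
        doses = group[~group["is_vehicle"].astype(bool)]
        points = tuple(
            (float(conc), tuple(sub["reading"].astype(float)))
            for conc, sub in doses.groupby("concentration_molar", sort=True)
        )
        points = tuple(sorted(points, key=lambda p: -p[0]))
        datasets.append(
            DoseResponseDataset(
                compound=str(compound), sample=str(sample), points=points,
                vehicle_readings=tuple(vehicle["reading"].astype(float)),
            )
        )
    return datasets


def write_viability_table(datasets: Sequence[DoseResponseDataset], path: str | Path) -> Path:
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".tab"} else ","
    rows = []
    for ds in datasets:
        for conc, readings in ds.points:
            for i, reading in enumerate(readings, start=1):
                rows.append((ds.compound, ds.sample, conc, i, reading, False))
        for i, reading in enumerate(ds.vehicle_readings, start=1):
            rows.append((ds.compound, ds.sample, 0.0, i, reading, True))
    pd.DataFrame(rows, columns=VIABILITY_COLUMNS).to_csv(path, sep=sep, index=False)
    return path


def fits_table(fits: Sequence[DoseResponseFit], parental_sample: str | None = None) -> pd.DataFrame:
    """Tabulate fits; with a parental sample, add fold-resistance per compound."""
    rows = []
    parental_by_compound = {
        f.compound: f for f in fits if f.sample == parental_sample and f.converged
    }
    for f in fits:
        fold = np.nan
        ref = parental_by_compound.get(f.compound)
        if ref is not None and f.converged and f.sample != parental_sample:
            fold = fold_resistance(f, ref)
        rows.append(
            {
                "compound": f.compound,
                "sample": f.sample,
                "ic50_molar": f.ic50 if f.converged else np.nan,
                "log_ic50": f.log_ic50,
                "hill": f.hill,
                "se_log_ic50": f.se_log_ic50,
                "se_hill": f.se_hill,
                "converged": f.converged,
                "fold_vs_parental": fold,
            }
        )
    return pd.DataFrame(rows)
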