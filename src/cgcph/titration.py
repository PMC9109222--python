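"""pH-sweep driver, equilibration-window selection and Hill-curve fitting.

A titration run produces, at each pH, a time series of per-site
protonation flags.  Analysis follows the time-and-molecule-averaged
convention: the per-frame mean over sites is averaged over an
equilibration window — the earliest contiguous stretch of the requested
effective length whose standard deviation of the mean protonation state
falls below a backend-dependent threshold (0.05 for Ewald runs, 0.1 for
switched-cutoff runs), which excludes the initial, usually poor, guess
at the protonation states.  The windowed mean deprotonated fractions
versus pH are then fit with the Hill equation

    f(pH) = 1 / (1 + 10^{n (pKa - pH)})

yielding the apparent pKa and the Hill coefficient n (n < 1 marks
anticooperative titration).  The fit is exposed statsmodels-style:
``HillCurve(ph, fraction).fit()`` returns a :class:`HillFitResult` with
estimates, standard errors and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .model import CgcphError

#: Default std-of-mean-protonation thresholds per electrostatics backend.
WINDOW_STD_THRESHOLDS = {"pme": 0.05, "switch": 0.1}


class WindowError(CgcphError):
    pass


class FitError(CgcphError):
    pass


@dataclass
class TitrationRecord:
    """Per-cycle protonation time series at one pH.

    ``times`` are effective ns, strictly increasing; ``per_site_series``
    is a (frames, sites) boolean matrix, True = deprotonated.
    """

    ph: float
    times: np.ndarray
    per_site_series: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.per_site_series = np.asarray(self.per_site_series, dtype=bool)
        if len(self.times) != len(self.per_site_series):
            raise ValueError("times and series lengths differ")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def deprotonated_fraction(self) -> np.ndarray:
        """Per-frame mean deprotonated fraction over sites."""
        return self.per_site_series.mean(axis=1)

    def slice(self, start: int, stop: int) -> "TitrationRecord":
        return TitrationRecord(self.ph, self.times[start:stop],
                               self.per_site_series[start:stop])


def ph_grid(low: float, high: float, step: float | None = None) -> list[float]:
    """pH grid for a titration sweep.

    The default follows the standard protocol: a coarse unit step for the
    first interval, then 0.5 increments up to ``high`` — so ``(4, 8)``
    gives ``[4, 5, 5.5, 6, 6.5, 7, 7.5, 8]``.  Passing ``step`` yields a
    uniform grid instead (endpoints included).
    """
    if not low < high:
        raise ValueError("need low < high")
    if step is not None:
        if step <= 0:
            raise ValueError("step must be > 0")
        n = int(round((high - low) / step))
        grid = [low + k * step for k in range(n + 1)]
    else:
        grid = [low, low + 1.0]
        v = low + 1.0
        while v < high - 1e-9:
            v = min(v + 0.5, high)
            grid.append(v)
    return [round(g, 6) for g in grid if g <= high + 1e-9]


def select_window(record: TitrationRecord, std_threshold: float,
                  window_length_ns: float) -> TitrationRecord:
    """Earliest contiguous window of the given effective length whose std
    of the mean protonation state is below the threshold.

    Raises :class:`WindowError` (reporting the best std achieved) when no
    window qualifies.
    """
    t = record.times
    if record.n_frames < 2 or t[-1] - t[0] < window_length_ns:
        raise WindowError(
            f"record spans {t[-1] - t[0] if record.n_frames else 0:.4g} ns, "
            f"shorter than the requested {window_length_ns} ns window")
    frac = record.deprotonated_fraction
    c1 = np.concatenate([[0.0], np.cumsum(frac)])
    c2 = np.concatenate([[0.0], np.cumsum(frac * frac)])
    best = np.inf
    nf = record.n_frames
    ends = np.searchsorted(t, t + window_length_ns, side="left")
    for i in range(nf):
        j = int(ends[i])
        if j >= nf and t[-1] - t[i] < window_length_ns * (1 - 1e-9):
            break  # remaining starts cannot host a full-length window
        j = min(j, nf)
        n = j - i
        mean = (c1[j] - c1[i]) / n
        var = max((c2[j] - c2[i]) / n - mean * mean, 0.0)
        std = np.sqrt(var)
        if std < std_threshold:
            return record.slice(i, j)
        best = min(best, std)
    raise WindowError(
        f"no window of {window_length_ns} ns with std < {std_threshold}; "
        f"best achieved std = {best:.4g}")


# ---------------------------------------------------------------------------
# Hill-curve model

def hill_equation(ph, pka, n):
    """Deprotonated fraction under the Hill model."""
    return 1.0 / (1.0 + 10.0 ** (np.clip(n * (pka - np.asarray(ph, float)),
                                         -300, 300)))


@dataclass
class HillFitResult:
    """Fitted apparent pKa and Hill coefficient with standard errors."""

    pka_apparent: float
    pka_se: float
    hill_n: float
    hill_se: float
    residual_rms: float
    n_points: int

    def __post_init__(self) -> None:
        if self.hill_n <= 0:
            raise ValueError("hill_n must be > 0")

    def predict(self, ph) -> np.ndarray:
        return hill_equation(ph, self.pka_apparent, self.hill_n)

    def summary(self) -> str:
        lines = [
            "Hill titration fit",
            "==================",
            f"points            {self.n_points}",
            f"apparent pKa      {self.pka_apparent:.3f} +/- {self.pka_se:.3f}",
            f"Hill coefficient  {self.hill_n:.3f} +/- {self.hill_se:.3f}",
            f"residual rms      {self.residual_rms:.4g}",
        ]
        return "\n".join(lines)


class HillCurve:
    """Hill-equation model of a titration curve.

    Parameters
    ----------
    ph : array-like
        pH values (>= 3 distinct points).
    fraction : array-like
        Mean deprotonated fraction at each pH, in [0, 1].
    std : array-like, optional
        Standard deviation of each fraction; used as inverse-variance
        weights.  Near-zero entries (variance collapse at the titration
        extremes) trigger an unweighted fit.
    """

    def __init__(self, ph, fraction, std=None):
        self.ph = np.asarray(ph, dtype=float)
        self.fraction = np.asarray(fraction, dtype=float)
        self.std = None if std is None else np.asarray(std, dtype=float)
        if len(self.ph) != len(self.fraction):
            raise ValueError("ph and fraction lengths differ")
        if len(np.unique(self.ph)) < 3:
            raise FitError("need at least 3 distinct pH points")
        if np.all(self.fraction <= 0.0) or np.all(self.fraction >= 1.0):
            raise FitError("degenerate data: all fractions at the same extreme")
        if np.any((self.fraction < 0) | (self.fraction > 1)):
            raise ValueError("fractions must lie in [0, 1]")

    def fit(self) -> HillFitResult:
        p0_pka = float(self.ph[np.argmin(np.abs(self.fraction - 0.5))])
        sigma = None
        if self.std is not None and np.all(self.std > 1e-6):
            sigma = self.std
        try:
            popt, pcov = curve_fit(
                hill_equation, self.ph, self.fraction, p0=(p0_pka, 1.0),
                sigma=sigma, bounds=([-np.inf, 1e-6], [np.inf, np.inf]),
                maxfev=10000)
        except RuntimeError as exc:
            raise FitError(f"Hill fit did not converge: {exc}") from exc
        perr = np.sqrt(np.diag(pcov))
        resid = self.fraction - hill_equation(self.ph, *popt)
        return HillFitResult(
            pka_apparent=float(popt[0]), pka_se=float(perr[0]),
            hill_n=float(popt[1]), hill_se=float(perr[1]),
            residual_rms=float(np.sqrt(np.mean(resid ** 2))),
            n_points=len(self.ph))


def fit_hill(points, std=None) -> HillFitResult:
    """Fit the Hill equation to ``points = [(pH, fraction), ...]``."""
    pts = np.asarray(points, dtype=float)
    return HillCurve(pts[:, 0], pts[:, 1], std=std).fit()


# ---------------------------------------------------------------------------
# sweep driver

def titration_table(records, std_threshold=None, window_length_ns=None,
                    electrostatics: str = "pme") -> pd.DataFrame:
    """Windowed summary of a titration sweep: one row per pH with the mean
    deprotonated fraction, its std over the window, and the frame count."""
    rows = []
    for rec in records:
        if window_length_ns is not None:
            thr = (std_threshold if std_threshold is not None
                   else WINDOW_STD_THRESHOLDS[electrostatics])
            rec = select_window(rec, thr, window_length_ns)
        frac = rec.deprotonated_fraction
        rows.append({"ph": rec.ph, "fraction": float(frac.mean()),
                     "std": float(frac.std()), "n_frames": rec.n_frames})
    return pd.DataFrame(rows).sort_values("ph", ignore_index=True)


def fit_titration(table: pd.DataFrame, weighted: bool = True) -> HillFitResult:
    """Hill fit of a titration table, inverse-variance weighted by the
    windowed standard error where available."""
    std = None
    if weighted:
        se = table["std"].to_numpy() / np.sqrt(table["n_frames"].to_numpy())
        if np.all(se > 1e-6):
            std = se
    return HillCurve(table["ph"].to_numpy(), table["fraction"].to_numpy(),
                     std=std).fit()


def titrate(system_builder, ph_values, params, thermostat, n_cycles: int, *,
            cycle_md_steps: int = 10, protocol=None, neutralize: bool = True,
            electrostatics: str = "pme", seed: int = 0):
    """Run constant-pH simulations over a pH grid with independent seeds.

    ``system_builder`` is either a ``SystemState`` (copied per pH) or a
    callable ``f(ph) -> SystemState``.  Returns a list of
    :class:`TitrationRecord`, one per pH.
    """
    from .cphmd import CpHConfig, run_cphmd  # deferred: avoids import cycle
    from .model import SwitchProtocol, SystemState

    ph_values = list(ph_values)
    if len(ph_values) == 0:
        raise ValueError("no pH points given")
    if protocol is None:
        protocol = SwitchProtocol()
    seed_rng = np.random.default_rng(seed)
    records = []
    for ph in ph_values:
        state = (system_builder(ph) if callable(system_builder)
                 else system_builder.copy())
        if not isinstance(state, SystemState):
            raise TypeError("system_builder must yield a SystemState")
        config = CpHConfig(ph=ph, cycle_md_steps=cycle_md_steps,
                           protocol=protocol, neutralize=neutralize,
                           seed=int(seed_rng.integers(2 ** 31)),
                           electrostatics=electrostatics)
        _, record, _ = run_cphmd(state, config, params, thermostat, n_cycles)
        records.append(record)
    return records
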