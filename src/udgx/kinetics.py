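"""Michaelis–Menten enzyme kinetics estimation.

Workflow mirrored from uracil-excision assays on single-stranded
U-containing DNA: initial rates are ordinary-least-squares slopes of
product (nM) against time (min); (S, v) points are then fitted either by
Lineweaver–Burk double-reciprocal regression (``method="lb"``, the default
used to match published parameter tables) or by direct nonlinear least
squares on v = Vmax S / (Km + S) (``method="mm"``, statistically more
robust, used as a cross-check).  Turnover is kcat = Vmax / [Et] with the
total enzyme concentration [Et] in nM, and catalytic efficiency is
kcat / Km.

The modelling surface follows the Model/Results convention:
``MichaelisMentenModel(data, et=200).fit()`` returns a
:class:`KineticsResults` carrying estimates, delta-method standard errors,
and a ``summary()`` table.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import InsufficientDataError, KineticsFitError

logger = logging.getLogger(__name__)

__all__ = [
    "TimeCourse",
    "RateEstimate",
    "KineticsDataset",
    "MichaelisMentenModel",
    "KineticsResults",
    "FoldChange",
    "initial_rate",
    "kcat",
    "fold_change",
    "substrate_series",
    "REFERENCE_KINETICS",
]


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeCourse:
    """Product formed (nM) at increasing times (min) for one substrate level."""

    times: tuple[float, ...]
    product: tuple[float, ...]
    substrate_nM: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.times) != len(self.product):
            raise ValueError("times and product differ in length")
        t = np.asarray(self.times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.asarray(self.product, dtype=float) < 0):
            raise ValueError("product concentrations must be non-negative")


@dataclass(frozen=True)
class RateEstimate:
    """A reaction rate v (nM min^-1) with its standard error."""

    value: float
    se: float


@dataclass(frozen=True)
class KineticsDataset:
    """(substrate concentration nM, initial rate nM min^-1) pairs."""

    s_nM: tuple[float, ...]
    v: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.s_nM) != len(self.v):
            raise ValueError("s_nM and v differ in length")
        if len(self.s_nM) == 0:
            raise ValueError("empty dataset")
        if np.any(np.asarray(self.s_nM, dtype=float) <= 0):
            raise ValueError("substrate concentrations must be positive")

    @property
    def n(self) -> int:
        return len(self.s_nM)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, s_col: str = "S_nM", v_col: str = "v_nM_per_min"
    ) -> "KineticsDataset":
        return cls(tuple(float(x) for x in df[s_col]), tuple(float(x) for x in df[v_col]))

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "KineticsDataset":
        return cls.from_dataframe(pd.read_csv(path), **kwargs)


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def initial_rate(tc: TimeCourse) -> RateEstimate:
    """OLS slope of product vs time: the initial reaction rate v.

    Requires at least 3 time points; the standard error of the slope is
    reported (0 for an exactly linear course).
    """
    if len(tc.times) < 3:
        raise InsufficientDataError(f"need >= 3 time points, got {len(tc.times)}")
    res = stats.linregress(tc.times, tc.product)
    se = 0.0 if math.isnan(res.stderr) else float(res.stderr)
    return RateEstimate(value=float(res.slope), se=se)


def kcat(vmax: float, et: float) -> float:
    """Turnover number kcat = Vmax / [Et] (min^-1), [Et] in nM."""
    if et <= 0:
        raise ValueError(f"[Et] must be positive, got {et}")
    return vmax / et


@dataclass(frozen=True)
class FoldChange:
    """A ratio a/b with its nearest-integer fold label."""

    ratio: float
    label: str


def fold_change(a: float, b: float) -> FoldChange:
    """Ratio a/b with a human-readable nearest-integer fold label."""
    if b <= 0:
        raise ValueError(f"denominator must be positive, got {b}")
    r = a / b
    return FoldChange(ratio=r, label=f"≈{round(r):d}-fold")


def substrate_series(
    labelled_pmol: float,
    unlabelled_pmols: Sequence[float],
    volume_ul: float,
) -> list[float]:
    """Final substrate concentrations (nM) of a label-dilution series.

    Each reaction holds ``labelled_pmol + u`` pmol of substrate in
    ``volume_ul`` µl; pmol/µl is µM, hence the factor 1000 to nM.
    """
    if volume_ul <= 0:
        raise ValueError(f"volume must be positive, got {volume_ul}")
    if labelled_pmol < 0 or any(u < 0 for u in unlabelled_pmols):
        raise ValueError("substrate amounts must be non-negative")
    return [(labelled_pmol + u) / volume_ul * 1000.0 for u in unlabelled_pmols]


#: label-dilution series of the uracil-excision assay: 0.1 pmol labelled
#: substrate plus 0.5..30 pmol unlabelled in 10 µl -> 60..3010 nM
DEFAULT_UNLABELLED_PMOL = (0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 16.0, 20.0, 25.0, 30.0)
DEFAULT_S_GRID_NM = tuple(substrate_series(0.1, DEFAULT_UNLABELLED_PMOL, 10.0))


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class MichaelisMentenModel:
    """Michaelis–Menten model v = Vmax S / (Km + S) for one enzyme.

    Parameters
    ----------
    data :
        (S, v) observations.
    et :
        Total enzyme concentration [Et] in nM; kcat = Vmax / [Et].

    Examples
    --------
    >>> data = KineticsDataset((60.0, 210.0, 810.0, 3010.0),
    ...                        (6.13, 12.54, 18.89, 21.71))
    >>> res = MichaelisMentenModel(data, et=200.0).fit(method="lb")
    >>> round(res.kcat, 3)  # doctest: +SKIP
    0.115
    """

    def __init__(self, data: KineticsDataset, et: float = 200.0) -> None:
        if et <= 0:
            raise ValueError(f"[Et] must be positive, got {et}")
        self.data = data
        self.et = float(et)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        s_col: str = "S_nM",
        v_col: str = "v_nM_per_min",
        et: float = 200.0,
    ) -> "MichaelisMentenModel":
        return cls(KineticsDataset.from_dataframe(df, s_col=s_col, v_col=v_col), et=et)

    # -- fitting -----------------------------------------------------------
    def fit(self, method: str = "lb") -> "KineticsResults":
        """Fit by ``"lb"`` (double-reciprocal OLS) or ``"mm"`` (nonlinear LS)."""
        if method == "lb":
            return self._fit_lb()
        if method == "mm":
            return self._fit_mm()
        raise ValueError(f"unknown method {method!r}; choose 'lb' or 'mm'")

    def _usable(self) -> tuple[np.ndarray, np.ndarray]:
        s = np.asarray(self.data.s_nM, dtype=float)
        v = np.asarray(self.data.v, dtype=float)
        bad = v <= 0
        if bad.any():
            logger.warning("excluding %d point(s) with non-positive rate", int(bad.sum()))
            s, v = s[~bad], v[~bad]
        return s, v

    def _fit_lb(self) -> "KineticsResults":
        s, v = self._usable()
        if len(np.unique(s)) < 2:
            raise InsufficientDataError("need >= 2 distinct usable substrate levels")
        x, y = 1.0 / s, 1.0 / v
        n = len(x)
        X = np.column_stack([np.ones(n), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        b0, b1 = beta  # intercept = 1/Vmax, slope = Km/Vmax
        resid = y - X @ beta
        saturated = n == 2
        if saturated:
            cov_b = np.zeros((2, 2))
            logger.warning("saturated 2-point fit: standard errors undefined, reported as 0")
        else:
            s2 = float(resid @ resid) / (n - 2)
            cov_b = s2 * np.linalg.inv(X.T @ X)
        if b0 <= 0:
            raise KineticsFitError(
                f"double-reciprocal intercept {b0:.4g} <= 0: Vmax undefined"
            )
        vmax = 1.0 / b0
        km = b1 / b0
        # delta method: (vmax, km) = g(b0, b1), J = dg/db
        J = np.array([[-1.0 / b0**2, 0.0], [-b1 / b0**2, 1.0 / b0]])
        cov_p = J @ cov_b @ J.T
        return KineticsResults(
            vmax=float(vmax), km=float(km), cov_params=cov_p, et=self.et,
            method="lb", nobs=n, model=self, saturated=saturated,
        )

    def _fit_mm(self) -> "KineticsResults":
        s = np.asarray(self.data.s_nM, dtype=float)
        v = np.asarray(self.data.v, dtype=float)
        if len(np.unique(s)) < 3:
            raise InsufficientDataError("need >= 3 distinct substrate levels")
        try:
            lb = self._fit_lb()
            p0 = [lb.vmax, lb.km]
        except (KineticsFitError, InsufficientDataError):
            p0 = [float(v.max()), float(np.median(s))]

        def mm(si, vmax, km):
            return vmax * si / (km + si)

        try:
            popt, pcov = optimize.curve_fit(mm, s, v, p0=p0, maxfev=10000)
        except RuntimeError as exc:
            raise KineticsFitError(f"Michaelis-Menten fit did not converge: {exc}") from exc
        if not np.all(np.isfinite(popt)) or popt[0] <= 0 or popt[1] <= 0:
            raise KineticsFitError(f"non-physical Michaelis-Menten estimates {popt}")
        pcov = np.where(np.isfinite(pcov), pcov, 0.0)
        return KineticsResults(
            vmax=float(popt[0]), km=float(popt[1]), cov_params=pcov, et=self.et,
            method="mm", nobs=len(s), model=self,
        )


@dataclass(frozen=True)
class KineticsResults:
    """Fitted Michaelis–Menten parameters with delta-method uncertainties.

    ``cov_params`` is the 2x2 covariance of (Vmax, Km); kcat and the
    catalytic efficiency kcat/Km are derived from the unrounded estimates.
    """

    vmax: float          # nM min^-1
    km: float            # nM
    cov_params: np.ndarray = field(repr=False)
    et: float            # nM
    method: str
    nobs: int
    model: Optional[MichaelisMentenModel] = field(default=None, repr=False, compare=False)
    saturated: bool = False

    @property
    def vmax_se(self) -> float:
        return float(math.sqrt(max(self.cov_params[0, 0], 0.0)))

    @property
    def km_se(self) -> float:
        return float(math.sqrt(max(self.cov_params[1, 1], 0.0)))

    @property
    def kcat(self) -> float:
        """Turnover number Vmax/[Et] (min^-1)."""
        return self.vmax / self.et

    @property
    def kcat_se(self) -> float:
        return self.vmax_se / self.et

    @property
    def efficiency(self) -> float:
        """Catalytic efficiency kcat/Km (min^-1 nM^-1), from unrounded values."""
        return self.kcat / self.km

    @property
    def efficiency_se(self) -> float:
        # delta method on f(vmax, km) = vmax / (et * km)
        g = np.array([1.0 / (self.et * self.km),
                      -self.vmax / (self.et * self.km**2)])
        var = float(g @ self.cov_params @ g)
        return math.sqrt(max(var, 0.0))

    def predict(self, s_nM: Sequence[float] | np.ndarray) -> np.ndarray:
        """Fitted rate curve v(S) = Vmax S / (Km + S)."""
        s = np.asarray(s_nM, dtype=float)
        return self.vmax * s / (self.km + s)

    def as_row(self, name: str = "") -> dict:
        """Report row matching the published table layout (rounded for display)."""
        return {
            "protein": name,
            "Vmax_nM_per_min": round(self.vmax, 2),
            "Vmax_se": round(self.vmax_se, 2),
            "Km_nM": round(self.km, 2),
            "Km_se": round(self.km_se, 2),
            "kcat_per_min": round(self.kcat, 3),
            "kcat_se": round(self.kcat_se, 3),
            "kcat_over_Km_e-3": round(self.efficiency * 1e3, 3),
            "kcat_over_Km_e-3_se": round(self.efficiency_se * 1e3, 3),
            "method": self.method,
            "n": self.nobs,
        }

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        buf = io.StringIO()
        title = "Michaelis-Menten kinetics" + (
            " (Lineweaver-Burk)" if self.method == "lb" else " (nonlinear LS)"
        )
        buf.write(f"{title}\n{'=' * len(title)}\n")
        buf.write(f"n observations: {self.nobs}    [Et]: {self.et:g} nM\n")
        rows = [
            ("Vmax", self.vmax, self.vmax_se, "nM min^-1"),
            ("Km", self.km, self.km_se, "nM"),
            ("kcat", self.kcat, self.kcat_se, "min^-1"),
            ("kcat/Km", self.efficiency, self.efficiency_se, "min^-1 nM^-1"),
        ]
        buf.write(f"{'param':<10}{'estimate':>14}{'std err':>12}  unit\n")
        for name, est, se, unit in rows:
            buf.write(f"{name:<10}{est:>14.6g}{se:>12.3g}  {unit}\n")
        if self.saturated:
            buf.write("note: saturated 2-point fit; standard errors undefined (0)\n")
        return buf.getvalue()

    # -- plotting ----------------------------------------------------------
    def plot(self, ax=None):
        """Michaelis–Menten curve with the observed (S, v) points."""
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots()
        s = np.asarray(self.model.data.s_nM) if self.model else np.linspace(1, 4 * self.km, 50)
        grid = np.linspace(0, float(np.max(s)) * 1.05, 200)
        ax.plot(grid, self.predict(grid), "-", label="fit")
        if self.model is not None:
            ax.plot(self.model.data.s_nM, self.model.data.v, "o", label="observed")
        ax.set_xlabel("[S] (nM)")
        ax.set_ylabel("v (nM min$^{-1}$)")
        ax.legend()
        return ax

    def plot_double_reciprocal(self, ax=None):
        """Lineweaver–Burk plot: 1/v against 1/[S] with the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots()
        if self.model is not None:
            s = np.asarray(self.model.data.s_nM, dtype=float)
            v = np.asarray(self.model.data.v, dtype=float)
            keep = v > 0
            ax.plot(1.0 / s[keep], 1.0 / v[keep], "o", label="observed")
            grid = np.linspace(0, (1.0 / s[keep]).max() * 1.05, 50)
        else:
            grid = np.linspace(0, 2.0 / self.km, 50)
        ax.plot(grid, (self.km / self.vmax) * grid + 1.0 / self.vmax, "-", label="fit")
        ax.set_xlabel("1/[S] (nM$^{-1}$)")
        ax.set_ylabel("1/v (min nM$^{-1}$)")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# published reference values
# ---------------------------------------------------------------------------

#: Published uracil-excision kinetics of *Msm*UdgX point mutants
#: (Lineweaver-Burk estimates; [Et] = 200 nM).  Columns: Vmax (nM min^-1),
#: Km (nM), kcat (min^-1), kcat/Km (x 10^-3 min^-1 nM^-1), each with its
#: printed error.  Used as fixed inputs for consistency checks and
#: fold-change reports; the wild type forms no Michaelis complex with
#: turnover and has no entry.
REFERENCE_KINETICS = pd.DataFrame(
    [
        ("H109K", 0.67, 0.15, 1002.20, 907.41, 0.003, 0.001, 0.001, 0.000),
        ("H109Q", 7.16, 0.39, 292.10, 14.79, 0.036, 0.002, 0.123, 0.003),
        ("H109G", 22.97, 2.31, 174.76, 29.09, 0.115, 0.012, 0.671, 0.041),
        ("H109S", 11.57, 1.42, 154.92, 21.29, 0.058, 0.007, 0.382, 0.052),
        ("H109C", 12.48, 2.06, 228.11, 50.79, 0.062, 0.010, 0.288, 0.041),
        ("H109A", 4.83, 0.35, 184.50, 13.52, 0.024, 0.002, 0.131, 0.001),
        ("H109S/E52N", 2.21, 0.20, 1063.17, 121.32, 0.006, 0.004, 0.005, 0.001),
        ("H109S/Q53A", 28.27, 2.44, 176.12, 19.25, 0.141, 0.012, 0.806, 0.019),
        ("H109S/R184A", 6.15, 0.31, 308.05, 25.82, 0.031, 0.002, 0.101, 0.011),
    ],
    columns=[
        "protein", "Vmax_nM_per_min", "Vmax_se", "Km_nM", "Km_se",
        "kcat_per_min", "kcat_se", "kcat_over_Km_e-3", "kcat_over_Km_e-3_se",
    ],
).set_index("protein")
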