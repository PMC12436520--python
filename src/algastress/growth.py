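"""Gompertz growth-curve fitting and hormesis comparison for OD750 data.

The modified Gompertz model in the Zwietering parameterisation,

    y(t) = A * exp{ -exp[ (mu_m * e / A) * (lambda - t) + 1 ] },

describes sigmoidal microbial growth through three interpretable
parameters: the asymptote ``A`` (stationary-phase density, OD750 above
baseline), the maximum growth rate ``mu_m`` (1/hr, the slope at the
inflection point) and the lag time ``lambda`` (hr, the time-axis intercept
of the inflection tangent).

Fitting is per replicate: each replicate column of a growth table is fitted
by nonlinear least squares on baseline-subtracted OD, and the condition
estimate is the mean +/- SD of the per-replicate estimates.  Fitting
replicates individually (rather than the mean curve) propagates the large
between-replicate heterogeneity seen near inhibitory Ag+ concentrations
into the reported uncertainty.  Replicates whose OD never rises more than
``no_growth_threshold`` above baseline are flagged and excluded from the
aggregate.

Hormesis comparison: a treated condition is flagged ``hormetic_asymptote``
when its fitted asymptote exceeds the control's by more than the combined
SD of the two estimates, and ``elongated_lag`` analogously for the lag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

DEFAULT_BASELINE = 0.01
NO_GROWTH_THRESHOLD = 0.05


def gompertz(t, A, mu_m, lag):
    """Modified Gompertz curve, y = A exp{-exp[(mu_m e / A)(lag - t) + 1]}.

    Monotone non-decreasing in t; y(lag) = A*exp(-e) ~ 0.066*A; the maximum
    of dy/dt equals mu_m.  Vectorised over t.
    """
    t = np.asarray(t, dtype=float)
    # inner exponent capped: exp(-exp(>40)) underflows to 0 anyway
    inner = np.minimum(mu_m * np.e / A * (lag - t) + 1.0, 40.0)
    return A * np.exp(-np.exp(inner))


@dataclass(frozen=True)
class GompertzFit:
    """Per-replicate Gompertz fit result."""

    A: float
    mu_m: float
    lag: float
    se_A: float
    se_mu: float
    se_lag: float
    converged: bool
    no_growth: bool
    rss: float
    n_points: int

    def as_dict(self) -> dict:
        return {
            "A": self.A,
            "mu_m": self.mu_m,
            "lag": self.lag,
            "se_A": self.se_A,
            "se_mu": self.se_mu,
            "se_lag": self.se_lag,
            "converged": self.converged,
            "no_growth": self.no_growth,
            "rss": self.rss,
            "n_points": self.n_points,
        }


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """A0 = max(y); mu0 = max discrete slope; lag0 = intercept of the
    max-slope tangent with the time axis."""
    a0 = max(float(np.max(y)), 1e-6)
    slopes = np.diff(y) / np.diff(t)
    k = int(np.argmax(slopes))
    mu0 = max(float(slopes[k]), 1e-8)
    t_mid = 0.5 * (t[k] + t[k + 1])
    y_mid = 0.5 * (y[k] + y[k + 1])
    lag0 = float(np.clip(t_mid - y_mid / mu0, 0.0, t[-1]))
    return a0, mu0, lag0


def _fit_single(t: np.ndarray, y: np.ndarray) -> GompertzFit:
    p0 = _initial_guess(t, y)
    bounds = ([1e-9, 1e-12, 0.0], [2.0 * max(np.max(y), 1e-6), np.inf, float(t[-1])])
    p0 = tuple(np.clip(p0, bounds[0], bounds[1]))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                gompertz, t, y, p0=p0, bounds=bounds, maxfev=20000
            )
        ses = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
        resid = y - gompertz(t, *popt)
        return GompertzFit(
            A=float(popt[0]),
            mu_m=float(popt[1]),
            lag=float(popt[2]),
            se_A=float(ses[0]),
            se_mu=float(ses[1]),
            se_lag=float(ses[2]),
            converged=True,
            no_growth=False,
            rss=float(resid @ resid),
            n_points=len(t),
        )
    except RuntimeError:
        return GompertzFit(
            A=np.nan, mu_m=np.nan, lag=np.nan,
            se_A=np.nan, se_mu=np.nan, se_lag=np.nan,
            converged=False, no_growth=False, rss=np.nan, n_points=len(t),
        )


@dataclass
class GompertzResults:
    """Aggregated Gompertz fit of one condition's replicated growth curve.

    Exposes per-replicate fits plus the across-replicate mean +/- SD of
    each parameter (no-growth and non-converged replicates excluded).
    """

    fits: list[GompertzFit]
    condition: float | str | None = None
    params: dict = dc_field(init=False)
    params_sd: dict = dc_field(init=False)

    def __post_init__(self) -> None:
        ok = [f for f in self.fits if f.converged and not f.no_growth]
        if ok:
            self.params = {
                "A": float(np.mean([f.A for f in ok])),
                "mu_m": float(np.mean([f.mu_m for f in ok])),
                "lag": float(np.mean([f.lag for f in ok])),
            }
            self.params_sd = {
                "A": float(np.std([f.A for f in ok], ddof=1)) if len(ok) > 1 else 0.0,
                "mu_m": float(np.std([f.mu_m for f in ok], ddof=1)) if len(ok) > 1 else 0.0,
                "lag": float(np.std([f.lag for f in ok], ddof=1)) if len(ok) > 1 else 0.0,
            }
        else:
            self.params = {"A": np.nan, "mu_m": np.nan, "lag": np.nan}
            self.params_sd = {"A": np.nan, "mu_m": np.nan, "lag": np.nan}

    @property
    def n_replicates(self) -> int:
        return len(self.fits)

    @property
    def n_no_growth(self) -> int:
        return sum(f.no_growth for f in self.fits)

    @property
    def no_growth(self) -> bool:
        """True when every replicate failed to grow."""
        return all(f.no_growth or not f.converged for f in self.fits)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([f.as_dict() for f in self.fits])
        df.insert(0, "replicate", np.arange(1, len(self.fits) + 1))
        if self.condition is not None:
            df.insert(0, "condition", self.condition)
        return df

    def summary(self) -> str:
        lines = ["Gompertz growth fit"]
        if self.condition is not None:
            lines.append(f"condition: {self.condition}")
        lines.append(
            f"replicates: {self.n_replicates} "
            f"(no growth: {self.n_no_growth})"
        )
        for name, unit in (("A", "OD750"), ("mu_m", "1/hr"), ("lag", "hr")):
            lines.append(
                f"  {name:5s} = {self.params[name]:.4g} +/- "
                f"{self.params_sd[name]:.2g} {unit}"
            )
        return "\n".join(lines)

    def plot(self, t=None, od=None, ax=None):
        """Plot replicate data (if given) and the mean fitted curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if t is not None and od is not None:
            od = np.atleast_2d(np.asarray(od, float))
            for col in od:
                ax.plot(t, col, "o", ms=3, alpha=0.5, color="gray")
        if np.isfinite(self.params["A"]):
            tt = np.linspace(0, (max(t) if t is not None else 200), 200)
            ax.plot(
                tt,
                gompertz(tt, self.params["A"], self.params["mu_m"], self.params["lag"]),
                "-",
                label=f"fit (lag={self.params['lag']:.1f} hr)",
            )
            ax.legend()
        ax.set_xlabel("time (hr)")
        ax.set_ylabel("OD750 - baseline")
        return ax


class GompertzModel:
    """Gompertz model of one condition's replicated OD750 growth curve.

    Parameters
    ----------
    t : array of time points, hr
    od : array, shape (n_times,) or (n_times, n_reps)
        Raw OD750 readings (baseline not yet subtracted).
    baseline : float
        Initial OD750 subtracted before fitting (inoculation density).
    no_growth_threshold : float
        Replicates with max(od) - baseline below this are flagged
        no-growth and excluded from aggregation.
    condition : optional label (e.g. Ag+ concentration in uM).
    """

    def __init__(
        self,
        t,
        od,
        baseline: float = DEFAULT_BASELINE,
        no_growth_threshold: float = NO_GROWTH_THRESHOLD,
        condition=None,
    ) -> None:
        self.t = np.asarray(t, dtype=float)
        od = np.asarray(od, dtype=float)
        if od.ndim == 1:
            od = od[:, None]
        if od.shape[0] != len(self.t):
            raise ValueError("od rows must match t")
        if len(self.t) < 5:
            raise ValueError("need at least 5 time points to fit")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        self.od = od
        self.baseline = baseline
        self.no_growth_threshold = no_growth_threshold
        self.condition = condition

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, time_col: str = "time_hr", **kwargs
    ) -> "GompertzModel":
        """Build from a growth table with a time column and replicate columns."""
        if time_col not in df.columns:
            raise ValueError(f"missing column {time_col!r}")
        reps = [c for c in df.columns if c != time_col]
        return cls(df[time_col].to_numpy(), df[reps].to_numpy(), **kwargs)

    def fit(self) -> GompertzResults:
        fits = []
        for j in range(self.od.shape[1]):
            y = self.od[:, j] - self.baseline
            if np.any(~np.isfinite(y)):
                raise ValueError("non-finite OD values")
            if float(np.max(y)) < self.no_growth_threshold:
                fits.append(
                    GompertzFit(
                        A=np.nan, mu_m=np.nan, lag=np.nan,
                        se_A=np.nan, se_mu=np.nan, se_lag=np.nan,
                        converged=True, no_growth=True,
                        rss=float(y @ y), n_points=len(y),
                    )
                )
            else:
                fits.append(_fit_single(self.t, y))
        return GompertzResults(fits=fits, condition=self.condition)


def fit_gompertz(
    curve: pd.DataFrame,
    baseline: float = DEFAULT_BASELINE,
    time_col: str = "time_hr",
    condition=None,
    no_growth_threshold: float = NO_GROWTH_THRESHOLD,
) -> GompertzResults:
    """Fit every replicate column of a growth table; aggregate mean +/- SD."""
    model = GompertzModel.from_dataframe(
        curve,
        time_col=time_col,
        baseline=baseline,
        no_growth_threshold=no_growth_threshold,
        condition=condition,
    )
    return model.fit()


@dataclass(frozen=True)
class ConditionComparison:
    """Flags for one treated condition vs the control."""

    condition: float | str
    A: float
    A_sd: float
    lag: float
    lag_sd: float
    mu_m: float
    mu_m_sd: float
    no_growth: bool
    hormetic_asymptote: bool
    elongated_lag: bool


@dataclass(frozen=True)
class HormesisReport:
    """Condition-by-condition comparison against the untreated control."""

    control: float | str
    control_params: dict
    control_sd: dict
    comparisons: list[ConditionComparison]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "condition": c.condition,
                "A": c.A,
                "A_sd": c.A_sd,
                "mu_m": c.mu_m,
                "mu_m_sd": c.mu_m_sd,
                "lag": c.lag,
                "lag_sd": c.lag_sd,
                "no_growth": c.no_growth,
                "hormetic_asymptote": c.hormetic_asymptote,
                "elongated_lag": c.elongated_lag,
            }
            for c in self.comparisons
        ]
        return pd.DataFrame(rows)


def compare_conditions(
    results: dict, control_id
) -> HormesisReport:
    """Compare fitted conditions against the control for hormesis.

    Parameters
    ----------
    results : mapping condition -> GompertzResults
    control_id : key of the untreated control in ``results``

    A treated condition is ``hormetic_asymptote`` when
    ``A_treated - A_control > sqrt(sd_c^2 + sd_t^2)``, and
    ``elongated_lag`` by the same rule on the lag.  Fully no-growth
    conditions carry NaN parameters and False flags.
    """
    if control_id not in results:
        raise ValueError(f"control condition {control_id!r} not in results")
    ctrl = results[control_id]
    comparisons = []
    for cond, res in results.items():
        if cond == control_id:
            continue
        if res.no_growth or not np.isfinite(res.params["A"]):
            comparisons.append(
                ConditionComparison(
                    condition=cond,
                    A=np.nan, A_sd=np.nan, lag=np.nan, lag_sd=np.nan,
                    mu_m=np.nan, mu_m_sd=np.nan,
                    no_growth=True,
                    hormetic_asymptote=False,
                    elongated_lag=False,
                )
            )
            continue
        comb_sd_A = float(np.hypot(ctrl.params_sd["A"], res.params_sd["A"]))
        comb_sd_lag = float(np.hypot(ctrl.params_sd["lag"], res.params_sd["lag"]))
        comparisons.append(
            ConditionComparison(
                condition=cond,
                A=res.params["A"],
                A_sd=res.params_sd["A"],
                lag=res.params["lag"],
                lag_sd=res.params_sd["lag"],
                mu_m=res.params["mu_m"],
                mu_m_sd=res.params_sd["mu_m"],
                no_growth=False,
                hormetic_asymptote=bool(
                    res.params["A"] - ctrl.params["A"] > comb_sd_A
                ),
                elongated_lag=bool(
                    res.params["lag"] - ctrl.params["lag"] > comb_sd_lag
                ),
            )
        )
    return HormesisReport(
        control=control_id,
        control_params=dict(ctrl.params),
        control_sd=dict(ctrl.params_sd),
        comparisons=comparisons,
    )
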