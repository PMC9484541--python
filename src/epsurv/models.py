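"""Peleg-Fermi survival models for electroporation and their two-step fit.

The survival fraction of a cell population exposed to ``N`` rectangular
pulses of field strength ``E`` (V/cm) follows a Fermi (logistic) dose
response,

    S(E, N) = 1 / (1 + exp((E - Ec(N)) / Ac(N))),

where ``Ec(N)`` is the field at which half the population dies — the
operative threshold for irreversible electroporation — and ``Ac(N)`` sets
the steepness of the sigmoid.  Both parameters decay exponentially with the
pulse number,

    Ec(N) = E0 * exp(-k1 * N),        Ac(N) = A0 * exp(-k2 * N),

so four cell-specific coefficients (E0, k1, A0, k2) summarise the whole
dose-response surface at a given pulse duration.  They are estimated in two
steps: a per-pulse-number logistic fit of viability against field strength
(stage 1), then two separate exponential fits of the stage-1 ``Ec`` and
``Ac`` series against pulse number (stage 2), each with its own R².

A double-exponential variant of the decay laws and a power law linking a
characteristic lethal field to pulse duration are provided as fallbacks for
data the single-exponential model cannot represent.

Estimators follow the scikit-learn protocol (``fit``/``predict``/
``get_params``); the module-level ``fit_*`` functions are thin wrappers
around them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .viability import ViabilityDataset, summarize_replicates

__all__ = [
    "PelegFermiCoefficients",
    "ModifiedPelegFermiCoefficients",
    "PowerLawCoefficients",
    "StageOneFit",
    "InsufficientDesignError",
    "FitFailureError",
    "FermiCurve",
    "PelegFermiModel",
    "ModifiedPelegFermiModel",
    "DurationPowerLaw",
    "survival_probability",
    "ec_of_n",
    "ac_of_n",
    "ec_threshold",
    "fit_stage1",
    "fit_stage2",
    "fit_peleg_fermi",
    "fit_modified_peleg_fermi",
    "fit_power_law",
    "coefficient_table",
    "survival_surface",
]

# parameter bounds shared by all fits: amplitudes positive and bounded,
# decay rates allowed slightly negative (observed in real coefficient sets)
_AMP_BOUNDS = (1e-6, 1e5)
_K_BOUNDS = (-0.1, 0.1)


class InsufficientDesignError(ValueError):
    """The experimental design has too few levels for the requested fit."""


class FitFailureError(RuntimeError):
    """A nonlinear fit failed to converge or the data are degenerate."""


# ---------------------------------------------------------------------------
# coefficient containers


@dataclass(frozen=True)
class StageOneFit:
    """Per-pulse-number logistic fit: the (Ec, Ac) pair at one N."""

    pulse_number: int
    ec_n: float
    ac_n: float
    r2: float
    n_points: int


@dataclass(frozen=True)
class PelegFermiCoefficients:
    """Cell-specific coefficient set for one cell line at one pulse duration."""

    cell_line: str
    organ: str
    pulse_duration_us: float
    e0: float
    k1: float
    a0: float
    k2: float
    r2_e: float = float("nan")
    r2_a: float = float("nan")

    def ec(self, n):
        """Ec(N) = E0 exp(-k1 N); scalar in, scalar out (arrays broadcast)."""
        val = self.e0 * np.exp(-self.k1 * np.asarray(n, dtype=float))
        return val if val.ndim else float(val)

    def ac(self, n):
        """Ac(N) = A0 exp(-k2 N)."""
        val = self.a0 * np.exp(-self.k2 * np.asarray(n, dtype=float))
        return val if val.ndim else float(val)


@dataclass(frozen=True)
class ModifiedPelegFermiCoefficients:
    """Double-exponential decay laws for Ec(N) and Ac(N)."""

    cell_line: str
    organ: str
    pulse_duration_us: float
    e1: float
    e2: float
    k1: float
    k2: float
    a1: float
    a2: float
    k3: float
    k4: float
    r2_e: float = float("nan")
    r2_a: float = float("nan")

    def ec(self, n: float) -> float:
        return float(self.e1 * np.exp(-self.k1 * n) + self.e2 * np.exp(-self.k2 * n))

    def ac(self, n: float) -> float:
        return float(self.a1 * np.exp(-self.k3 * n) + self.a2 * np.exp(-self.k4 * n))


@dataclass(frozen=True)
class PowerLawCoefficients:
    """Lethal-field power law E = a * (tp / t0)^b, reference t0 = 1 ms."""

    a: float
    b: float
    t0_ms: float = 1.0

    def field(self, tp_ms: float | np.ndarray) -> float | np.ndarray:
        return self.a * (np.asarray(tp_ms, dtype=float) / self.t0_ms) ** self.b


# ---------------------------------------------------------------------------
# elementary model evaluations


def survival_probability(efs, ec_n, ac_n):
    """Fermi survival fraction S = 1 / (1 + exp((E - Ec)/Ac)).

    Strictly decreasing in ``efs`` for ``ac_n > 0``; equals 0.5 exactly at
    ``efs == ec_n``.  Accepts scalars or arrays (broadcast).
    """
    ac = np.asarray(ac_n, dtype=float)
    if np.any(ac <= 0):
        raise ValueError("ac_n must be positive")
    z = (np.asarray(efs, dtype=float) - np.asarray(ec_n, dtype=float)) / ac
    # guard the exponential; S saturates at 0/1 well before overflow
    out = 1.0 / (1.0 + np.exp(np.clip(z, -700.0, 700.0)))
    return out if out.ndim else float(out)


def ec_of_n(coeffs: PelegFermiCoefficients, n) -> float | np.ndarray:
    """Half-lethal field Ec(N) = E0 exp(-k1 N), V/cm."""
    val = coeffs.e0 * np.exp(-coeffs.k1 * np.asarray(n, dtype=float))
    return val if val.ndim else float(val)


def ac_of_n(coeffs: PelegFermiCoefficients, n) -> float | np.ndarray:
    """Sigmoid slope constant Ac(N) = A0 exp(-k2 N), V/cm."""
    val = coeffs.a0 * np.exp(-coeffs.k2 * np.asarray(n, dtype=float))
    return val if val.ndim else float(val)


def ec_threshold(coeffs: PelegFermiCoefficients, n: int = 100) -> float:
    """The effective-field threshold used by the injury simulator: Ec(N)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(ec_of_n(coeffs, n))


def survival_surface(coeffs: PelegFermiCoefficients, efs_grid, n_grid) -> np.ndarray:
    """Survival fraction on an (N x EFS) grid; rows indexed by pulse number."""
    efs = np.atleast_1d(np.asarray(efs_grid, dtype=float))
    n = np.atleast_1d(np.asarray(n_grid, dtype=float))
    if efs.size == 0 or n.size == 0:
        raise ValueError("grids must be nonempty")
    ec = coeffs.e0 * np.exp(-coeffs.k1 * n)[:, None]
    ac = coeffs.a0 * np.exp(-coeffs.k2 * n)[:, None]
    return np.asarray(survival_probability(efs[None, :], ec, ac))


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -np.inf
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# estimators


class FermiCurve(BaseEstimator, RegressorMixin):
    """Stage-1 estimator: logistic survival vs field strength at fixed N.

    Parameters
    ----------
    max_starts : int
        Number of perturbed restarts tried before declaring failure.

    Attributes
    ----------
    ec_ : float
        Half-lethal field strength, V/cm.
    ac_ : float
        Slope constant, V/cm.
    r2_ : float
        Coefficient of determination of the fit (may be negative).
    n_points_ : int
        Number of distinct field levels used.
    """

    def __init__(self, max_starts: int = 6):
        self.max_starts = max_starts

    def fit(self, X, y):
        efs = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if efs.shape != y.shape:
            raise ValueError("X and y have mismatched lengths")
        # duplicated field levels are averaged before fitting
        levels, inverse = np.unique(efs, return_inverse=True)
        if levels.size < 3:
            raise InsufficientDesignError(
                f"need >= 3 distinct EFS levels, got {levels.size}"
            )
        means = np.bincount(inverse, weights=y) / np.bincount(inverse)

        if np.allclose(means, means[0]):
            raise FitFailureError("viability constant across EFS; sigmoid unidentifiable")

        span = float(levels.max() - levels.min())
        ec0 = float(levels[np.argmin(np.abs(means - 0.5))])
        ac0 = span / 4.0
        starts = [(ec0, ac0)]
        rng_scales = [0.5, 2.0, 0.25, 4.0, 1.0]
        mids = [ec0, ec0, ec0, ec0, float(levels.mean())]
        starts += [(m, ac0 * s) for m, s in zip(mids, rng_scales)][: self.max_starts - 1]

        def fermi(e, ec, ac):
            return 1.0 / (1.0 + np.exp(np.clip((e - ec) / ac, -700, 700)))

        best = None
        for ec_i, ac_i in starts:
            try:
                popt, _ = curve_fit(
                    fermi,
                    levels,
                    means,
                    p0=[max(ec_i, 1e-6), max(ac_i, 1e-6)],
                    bounds=([_AMP_BOUNDS[0]] * 2, [_AMP_BOUNDS[1]] * 2),
                    maxfev=20000,
                )
            except RuntimeError:
                continue
            ss = float(np.sum((means - fermi(levels, *popt)) ** 2))
            if best is None or ss < best[0]:
                best = (ss, popt)
        if best is None:
            raise FitFailureError("logistic fit did not converge from any start")

        self.ec_, self.ac_ = map(float, best[1])
        self.r2_ = _r_squared(means, fermi(levels, self.ec_, self.ac_))
        self.n_points_ = int(levels.size)
        return self

    def predict(self, X):
        check_is_fitted(self, "ec_")
        efs = np.asarray(X, dtype=float).reshape(-1)
        return np.asarray(survival_probability(efs, self.ec_, self.ac_))

    def to_stage_one(self, pulse_number: int) -> StageOneFit:
        check_is_fitted(self, "ec_")
        return StageOneFit(int(pulse_number), self.ec_, self.ac_, self.r2_, self.n_points_)


def _fit_exponential_decay(n: np.ndarray, values: np.ndarray) -> tuple[float, float, float]:
    """Least-squares fit of values = C * exp(-k n); returns (C, k, r2)."""
    if np.unique(n).size < 3:
        raise InsufficientDesignError("need >= 3 distinct pulse numbers")
    if np.any(values <= 0):
        raise FitFailureError("exponential decay fit requires positive values")

    def model(x, c, k):
        return c * np.exp(-k * x)

    # log-linear regression seeds the nonlinear fit
    slope, intercept = np.polyfit(n, np.log(values), 1)
    starts = [(float(np.exp(intercept)), float(np.clip(-slope, *_K_BOUNDS)))]
    for k_try in (-0.02, -0.01, 0.0, 0.005, 0.01, 0.02, 0.05):
        w = np.exp(-k_try * n)
        c_try = float(np.dot(w, values) / np.dot(w, w))
        if c_try > 0:
            starts.append((c_try, k_try))

    best = None
    for c0, k0 in starts:
        try:
            popt, _ = curve_fit(
                model,
                n,
                values,
                p0=[np.clip(c0, *_AMP_BOUNDS), k0],
                bounds=([_AMP_BOUNDS[0], _K_BOUNDS[0]], [_AMP_BOUNDS[1], _K_BOUNDS[1]]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        ss = float(np.sum((values - model(n, *popt)) ** 2))
        if best is None or ss < best[0]:
            best = (ss, popt)
    if best is None:
        raise FitFailureError("exponential decay fit did not converge")
    c, k = map(float, best[1])
    return c, k, _r_squared(values, model(n, c, k))


class PelegFermiModel(BaseEstimator, RegressorMixin):
    """Two-step Peleg-Fermi fit of survival against (field strength, pulse number).

    ``fit`` expects ``X`` of shape (n_samples, 2) with columns
    ``[efs_v_cm, pulse_number]`` and ``y`` as survival fractions (viability
    percent / 100; values above 1 are permitted and simply fit poorly).
    Stage 1 fits a logistic per pulse number; stage 2 fits the exponential
    decay laws for Ec(N) and Ac(N) separately, each with its own R².

    Attributes
    ----------
    e0_, k1_ : float
        Ec(N) = e0_ * exp(-k1_ * N); ``r2_e_`` is the goodness of that fit.
    a0_, k2_ : float
        Ac(N) = a0_ * exp(-k2_ * N); ``r2_a_`` is its goodness of fit.
    stage1_ : list of StageOneFit
        The per-pulse-number (Ec, Ac) estimates stage 2 consumed.
    failed_pulse_numbers_ : list of int
        Pulse numbers whose stage-1 fit failed (skipped with a warning).
    """

    def __init__(self, max_starts: int = 6, min_pulse_numbers: int = 3):
        self.max_starts = max_starts
        self.min_pulse_numbers = min_pulse_numbers

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_samples, 2): [efs_v_cm, pulse_number]")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have mismatched lengths")

        stage1: list[StageOneFit] = []
        failed: list[int] = []
        for n in np.unique(X[:, 1]):
            mask = X[:, 1] == n
            try:
                curve = FermiCurve(max_starts=self.max_starts).fit(X[mask, 0], y[mask])
            except (InsufficientDesignError, FitFailureError) as exc:
                warnings.warn(f"stage-1 fit failed at N={int(n)}: {exc}", stacklevel=2)
                failed.append(int(n))
                continue
            stage1.append(curve.to_stage_one(int(n)))

        if len(stage1) < self.min_pulse_numbers:
            raise InsufficientDesignError(
                f"only {len(stage1)} successful stage-1 fits; "
                f"need >= {self.min_pulse_numbers} pulse numbers"
            )

        n_arr = np.array([s.pulse_number for s in stage1], dtype=float)
        self.e0_, self.k1_, self.r2_e_ = _fit_exponential_decay(
            n_arr, np.array([s.ec_n for s in stage1])
        )
        self.a0_, self.k2_, self.r2_a_ = _fit_exponential_decay(
            n_arr, np.array([s.ac_n for s in stage1])
        )
        self.stage1_ = stage1
        self.failed_pulse_numbers_ = failed
        return self

    def predict(self, X):
        check_is_fitted(self, "e0_")
        X = np.asarray(X, dtype=float)
        ec = self.e0_ * np.exp(-self.k1_ * X[:, 1])
        ac = self.a0_ * np.exp(-self.k2_ * X[:, 1])
        return np.asarray(survival_probability(X[:, 0], ec, ac))

    def to_coefficients(
        self, cell_line: str = "", organ: str = "", pulse_duration_us: float = float("nan")
    ) -> PelegFermiCoefficients:
        check_is_fitted(self, "e0_")
        return PelegFermiCoefficients(
            cell_line=cell_line,
            organ=organ,
            pulse_duration_us=pulse_duration_us,
            e0=self.e0_,
            k1=self.k1_,
            a0=self.a0_,
            k2=self.k2_,
            r2_e=self.r2_e_,
            r2_a=self.r2_a_,
        )


def _fit_double_exponential(n: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, float]:
    """Fit values = C1 exp(-k1 n) + C2 exp(-k2 n); returns (params, r2)."""

    def model(p, x):
        return p[0] * np.exp(-p[2] * x) + p[1] * np.exp(-p[3] * x)

    c, k, _ = _fit_exponential_decay(n, values)
    starts = [
        (c / 2, c / 2, k, k),
        (0.7 * c, 0.3 * c, min(k + 0.01, 0.1), max(k - 0.01, -0.1)),
        (0.9 * c, 0.1 * c, k, 0.0),
        (0.5 * c, 0.5 * c, 0.05, -0.01),
    ]
    lb = [0.0, 0.0, _K_BOUNDS[0], _K_BOUNDS[0]]
    ub = [_AMP_BOUNDS[1], _AMP_BOUNDS[1], _K_BOUNDS[1], _K_BOUNDS[1]]
    best = None
    for p0 in starts:
        res = least_squares(
            lambda p: model(p, n) - values,
            x0=np.clip(p0, lb, ub),
            bounds=(lb, ub),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=20000,
        )
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success and best.cost > 1e-6:
        raise FitFailureError("double-exponential fit did not converge")
    return best.x, _r_squared(values, model(best.x, n))


class ModifiedPelegFermiModel(BaseEstimator, RegressorMixin):
    """Peleg-Fermi fit with double-exponential Ec(N) and Ac(N) decay laws.

    Fallback for datasets whose stage-1 (Ec, Ac) series a single exponential
    cannot follow.  Requires at least five pulse numbers (four parameters per
    decay curve).  Same ``fit(X, y)`` interface as :class:`PelegFermiModel`.
    The two exponential terms are exchangeable, so individual coefficients
    are identified only up to permutation; predictions are what matter.
    """

    def __init__(self, max_starts: int = 6, min_pulse_numbers: int = 5):
        self.max_starts = max_starts
        self.min_pulse_numbers = min_pulse_numbers

    def fit(self, X, y):
        base = PelegFermiModel(
            max_starts=self.max_starts, min_pulse_numbers=self.min_pulse_numbers
        )
        # reuse stage 1 only; stage 2 is replaced by double-exponential fits
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1)
        stage1 = []
        for n in np.unique(X[:, 1]):
            mask = X[:, 1] == n
            curve = FermiCurve(max_starts=self.max_starts).fit(X[mask, 0], y[mask])
            stage1.append(curve.to_stage_one(int(n)))
        return self.fit_from_stage1(stage1)

    def fit_from_stage1(self, stage1: Sequence[StageOneFit]):
        if len({s.pulse_number for s in stage1}) < self.min_pulse_numbers:
            raise InsufficientDesignError(
                f"need >= {self.min_pulse_numbers} pulse numbers, got {len(stage1)}"
            )
        n = np.array([s.pulse_number for s in stage1], dtype=float)
        pe, self.r2_e_ = _fit_double_exponential(n, np.array([s.ec_n for s in stage1]))
        pa, self.r2_a_ = _fit_double_exponential(n, np.array([s.ac_n for s in stage1]))
        self.e1_, self.e2_, self.k1_, self.k2_ = map(float, pe)
        self.a1_, self.a2_, self.k3_, self.k4_ = map(float, pa)
        self.stage1_ = list(stage1)
        return self

    def predict(self, X):
        check_is_fitted(self, "e1_")
        X = np.asarray(X, dtype=float)
        n = X[:, 1]
        ec = self.e1_ * np.exp(-self.k1_ * n) + self.e2_ * np.exp(-self.k2_ * n)
        ac = self.a1_ * np.exp(-self.k3_ * n) + self.a2_ * np.exp(-self.k4_ * n)
        return np.asarray(survival_probability(X[:, 0], ec, ac))

    def to_coefficients(
        self, cell_line: str = "", organ: str = "", pulse_duration_us: float = float("nan")
    ) -> ModifiedPelegFermiCoefficients:
        check_is_fitted(self, "e1_")
        return ModifiedPelegFermiCoefficients(
            cell_line, organ, pulse_duration_us,
            self.e1_, self.e2_, self.k1_, self.k2_,
            self.a1_, self.a2_, self.k3_, self.k4_,
            self.r2_e_, self.r2_a_,
        )


class DurationPowerLaw(BaseEstimator, RegressorMixin):
    """Power law E = a * (tp/t0)^b between a lethal field and pulse duration.

    Fit by linear regression in log-log coordinates, which is exact for any
    two-point input.  ``X`` is the pulse duration in milliseconds
    (reference t0 = 1 ms), ``y`` the characteristic field in V/cm.
    """

    def __init__(self, t0_ms: float = 1.0):
        self.t0_ms = t0_ms

    def fit(self, X, y):
        tp = np.asarray(X, dtype=float).reshape(-1)
        e = np.asarray(y, dtype=float).reshape(-1)
        if np.unique(tp).size < 2:
            raise InsufficientDesignError("need >= 2 distinct durations")
        if np.any(e <= 0) or np.any(tp <= 0):
            raise ValueError("durations and fields must be positive")
        b, log_a = np.polyfit(np.log(tp / self.t0_ms), np.log(e), 1)
        self.b_ = float(b)
        self.a_ = float(np.exp(log_a))
        return self

    def predict(self, X):
        check_is_fitted(self, "a_")
        tp = np.asarray(X, dtype=float).reshape(-1)
        return self.a_ * (tp / self.t0_ms) ** self.b_


# ---------------------------------------------------------------------------
# functional wrappers over the estimators


def _condition_means(dataset: ViabilityDataset, cell_line: str, duration: float) -> pd.DataFrame:
    summary = summarize_replicates(dataset)
    sel = (summary["cell_line"] == cell_line) & (
        summary["pulse_duration_us"] == duration
    )
    sub = summary.loc[sel]
    if sub.empty:
        raise InsufficientDesignError(
            f"no data for cell line {cell_line!r} at {duration} us"
        )
    return sub


def fit_stage1(
    dataset: ViabilityDataset, cell_line: str, duration: float, n: int
) -> StageOneFit:
    """Logistic fit of mean viability vs EFS at one pulse number."""
    sub = _condition_means(dataset, cell_line, duration)
    sub = sub[sub["pulse_number"] == n]
    if sub.empty:
        raise InsufficientDesignError(f"no data at N={n}")
    curve = FermiCurve().fit(
        sub["efs_v_cm"].to_numpy(), sub["mean_viability_pct"].to_numpy() / 100.0
    )
    return curve.to_stage_one(n)


def fit_stage2(
    stage1_fits: Sequence[StageOneFit],
    cell_line: str = "",
    organ: str = "",
    pulse_duration_us: float = float("nan"),
) -> PelegFermiCoefficients:
    """Exponential decay fits of the stage-1 Ec and Ac series vs pulse number."""
    fits = sorted(stage1_fits, key=lambda s: s.pulse_number)
    n = np.array([s.pulse_number for s in fits], dtype=float)
    e0, k1, r2_e = _fit_exponential_decay(n, np.array([s.ec_n for s in fits]))
    a0, k2, r2_a = _fit_exponential_decay(n, np.array([s.ac_n for s in fits]))
    return PelegFermiCoefficients(
        cell_line, organ, pulse_duration_us, e0, k1, a0, k2, r2_e, r2_a
    )


def fit_peleg_fermi(
    dataset: ViabilityDataset, cell_line: str, duration: float
) -> PelegFermiCoefficients:
    """Full two-step fit for one (cell line, pulse duration)."""
    sub = _condition_means(dataset, cell_line, duration)
    model = PelegFermiModel().fit(
        sub[["efs_v_cm", "pulse_number"]].to_numpy(),
        sub["mean_viability_pct"].to_numpy() / 100.0,
    )
    organ = str(sub["organ"].iloc[0])
    return model.to_coefficients(cell_line, organ, duration)


def fit_modified_peleg_fermi(
    stage1_fits: Sequence[StageOneFit],
    cell_line: str = "",
    organ: str = "",
    pulse_duration_us: float = float("nan"),
) -> ModifiedPelegFermiCoefficients:
    """Double-exponential decay-law fit from stage-1 results."""
    model = ModifiedPelegFermiModel().fit_from_stage1(list(stage1_fits))
    return model.to_coefficients(cell_line, organ, pulse_duration_us)


def fit_power_law(durations_ms: Sequence[float], fields_v_cm: Sequence[float]) -> PowerLawCoefficients:
    """Fit E = a (tp/t0)^b with t0 = 1 ms (log-log least squares)."""
    model = DurationPowerLaw().fit(np.asarray(durations_ms), np.asarray(fields_v_cm))
    return PowerLawCoefficients(a=model.a_, b=model.b_)


def coefficient_table(coeff_sets: Sequence[PelegFermiCoefficients]) -> pd.DataFrame:
    """Render coefficient sets as a database table.

    Columns mirror the published layout: organ, cell line, duration, then
    (E0, k1, R²) for the Ec decay, (A0, k2, R²) for the Ac decay, and the
    derived Ec(100) threshold (always recomputed, never stored).
    """
    rows = [
        {
            "organ": c.organ,
            "cell_line": c.cell_line,
            "pulse_duration_us": c.pulse_duration_us,
            "e0": c.e0,
            "k1": c.k1,
            "r2_e": c.r2_e,
            "a0": c.a0,
            "k2": c.k2,
            "r2_a": c.r2_a,
            "ec100": c.ec(100),
        }
        for c in coeff_sets
    ]
    columns = [
        "organ", "cell_line", "pulse_duration_us",
        "e0", "k1", "r2_e", "a0", "k2", "r2_a", "ec100",
    ]
    return pd.DataFrame(rows, columns=columns)
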