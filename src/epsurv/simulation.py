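"""2D electric-field / bioheat / damage simulation for two-needle ablation.

The treatment geometry is a homogeneous 2D tissue slab with two parallel
needle electrodes (circular cross-sections) held at the pulse voltage and
ground.  Three physics layers are chained:

1. **Electric field** — the quasi-static potential solves Laplace's
   equation ``∇·(σ∇V) = 0`` (σ homogeneous, so σ drops out) with Dirichlet
   values on the electrode cross-sections and zero-flux outer boundaries,
   discretised with a 5-point finite-difference stencil on a regular grid.
2. **Bioheat** — Pennes' equation with Joule heating averaged over the
   pulse duty cycle (pulse duration × repetition frequency, 1e-4 at the
   default 100 μs / 1 Hz protocol):

       ρc ∂T/∂t = k ∇²T + ρ_b c_b ω_b (T_b - T) + ρ q_met + σ|E|² · duty

   The perfusion rate from the tissue table (ml blood / min / kg tissue) is
   converted to a volumetric rate with blood density 1050 kg/m³ and blood
   heat capacity 3617 J/(kg·°C); arterial temperature 37 °C.
3. **Damage** — electrical injury from the Peleg-Fermi survival model
   (P_EI = 1 - S(|E|, N) where |E| exceeds the lethal threshold Ec(N));
   thermal injury from the Arrhenius integral Ω = ∫ζ exp(-Ea/RT) dt with
   P_TI = 1 - exp(-Ω).  A point is irreversibly injured where the
   probability exceeds 0.5, and injury extents are reported as areas
   relative to the tissue domain (electrode interiors excluded).

The needle geometry (40 × 40 mm domain, 1 mm diameter needles 10 mm apart)
is a package default, configurable via :class:`DomainSpec`.  Per-pulse μs
thermal transients are not resolved: at 1 Hz the tissue integrates the
deposited energy, so N pulses correspond to N seconds of averaged heating.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix, identity
from scipy.sparse.linalg import splu

from .database import TissueProperties
from .models import PelegFermiCoefficients, survival_probability

__all__ = [
    "PulseProtocol",
    "DomainSpec",
    "ArrheniusParams",
    "InjuryMap",
    "InjuryAnalysisResult",
    "BLOOD_DENSITY",
    "BLOOD_HEAT_CAPACITY",
    "ARTERIAL_TEMP_C",
    "solve_laplace",
    "solve_potential",
    "field_magnitude",
    "joule_source",
    "BioheatStepper",
    "step_bioheat",
    "arrhenius_integral",
    "thermal_injury_probability",
    "ei_probability",
    "area_ratios",
    "run_injury_analysis",
]

BLOOD_DENSITY = 1050.0  # kg/m^3
BLOOD_HEAT_CAPACITY = 3617.0  # J/(kg.degC)
ARTERIAL_TEMP_C = 37.0


@dataclass(frozen=True)
class PulseProtocol:
    """Pulse train settings: 2 kV, 100 μs, 1 Hz; 100 pulses for the
    electrical-injury analysis and 200 (= 200 s) for the thermal one."""

    voltage: float = 2000.0
    duration_us: float = 100.0
    frequency_hz: float = 1.0
    n_pulses_ei: int = 100
    n_pulses_ti: int = 200

    def __post_init__(self) -> None:
        if min(self.duration_us, self.frequency_hz, self.n_pulses_ei, self.n_pulses_ti) <= 0:
            raise ValueError("protocol settings must be positive")
        if self.voltage < 0:
            raise ValueError("voltage must be >= 0")
        if self.duty_factor > 1:
            raise ValueError("duty factor (duration x frequency) exceeds 1")

    @property
    def duty_factor(self) -> float:
        return self.duration_us * 1e-6 * self.frequency_hz


@dataclass(frozen=True)
class ArrheniusParams:
    """First-order thermal damage kinetics (soft-tissue defaults)."""

    zeta: float = 7.39e39  # frequency factor, 1/s
    ea: float = 2.577e5  # activation energy, J/mol
    r_gas: float = 8.314  # J/(mol.K)

    def __post_init__(self) -> None:
        if self.zeta <= 0 or self.ea <= 0:
            raise ValueError("zeta and ea must be positive")

    def rate(self, temp_c) -> np.ndarray:
        """Damage accumulation rate at temperature(s) in °C (1/s)."""
        t_k = np.asarray(temp_c, dtype=float) + 273.15
        return self.zeta * np.exp(-self.ea / (self.r_gas * t_k))


@dataclass(frozen=True)
class DomainSpec:
    """Regular-grid 2D domain with two circular needle electrodes.

    Physical origin at the lower-left corner; node (iy, ix) sits at
    (x, y) = (ix*spacing, iy*spacing).
    """

    width: float = 0.04  # m
    height: float = 0.04  # m
    spacing: float = 0.25e-3  # m
    electrode_centers: tuple[tuple[float, float], tuple[float, float]] = (
        (0.015, 0.02),
        (0.025, 0.02),
    )
    electrode_radius: float = 0.5e-3  # m

    def __post_init__(self) -> None:
        (x1, y1), (x2, y2) = self.electrode_centers
        r = self.electrode_radius
        for x, y in self.electrode_centers:
            if not (r <= x <= self.width - r and r <= y <= self.height - r):
                raise ValueError("electrode extends outside the domain")
        if np.hypot(x2 - x1, y2 - y1) <= 2 * r:
            raise ValueError("electrodes overlap")
        if 2 * r / self.spacing < 4 - 1e-9:
            raise ValueError("grid spacing too coarse to resolve the electrode diameter")

    @property
    def shape(self) -> tuple[int, int]:
        ny = int(round(self.height / self.spacing)) + 1
        nx = int(round(self.width / self.spacing)) + 1
        return ny, nx

    def coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.shape
        x = np.arange(nx) * self.spacing
        y = np.arange(ny) * self.spacing
        return np.meshgrid(x, y)

    def electrode_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """Boolean node masks of the energised and grounded needles."""
        xx, yy = self.coordinates()
        masks = []
        for cx, cy in self.electrode_centers:
            masks.append((xx - cx) ** 2 + (yy - cy) ** 2 <= self.electrode_radius**2)
        return masks[0], masks[1]

    def electrode_mask(self) -> np.ndarray:
        a, b = self.electrode_masks()
        return a | b


@dataclass(frozen=True)
class InjuryMap:
    """Per-node injury probabilities and the scalar relative-area ratios."""

    p_ei: np.ndarray
    p_ti: np.ndarray
    s_ei_ratio: float
    s_ti_ratio: float
    threshold: float = 0.5


# ---------------------------------------------------------------------------
# electric field


def _laplacian_matrix(shape: tuple[int, int]) -> csr_matrix:
    """5-point graph Laplacian with zero-flux (mirror) outer boundaries.

    Row i holds (sum of existing-neighbour weights) on the diagonal and -1
    per neighbour, i.e. -∇² up to the 1/h² factor.
    """
    ny, nx = shape
    n = ny * nx
    idx = np.arange(n).reshape(shape)
    rows, cols = [], []
    for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        src = idx[max(0, -di): ny - max(0, di), max(0, -dj): nx - max(0, dj)]
        dst = idx[max(0, di): ny - max(0, -di), max(0, dj): nx - max(0, -dj)]
        rows.append(src.ravel())
        cols.append(dst.ravel())
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    data = -np.ones(rows.size)
    off = csr_matrix((data, (rows, cols)), shape=(n, n))
    diag = -np.asarray(off.sum(axis=1)).ravel()
    return (off + csr_matrix((diag, (np.arange(n), np.arange(n))), shape=(n, n))).tocsr()


def solve_laplace(
    shape: tuple[int, int], dirichlet_mask: np.ndarray, dirichlet_values: np.ndarray
) -> np.ndarray:
    """Solve ∇²V = 0 on a regular grid with zero-flux outer boundaries.

    ``dirichlet_mask``/``dirichlet_values`` fix V on arbitrary node sets
    (the electrode rasterisations).  Returns the potential grid.
    """
    if not dirichlet_mask.any():
        raise ValueError("no Dirichlet nodes: the potential is not determined")
    n = shape[0] * shape[1]
    fixed = dirichlet_mask.ravel()
    vals = np.where(fixed, dirichlet_values.ravel(), 0.0)
    lap = _laplacian_matrix(shape)

    # known values move to the RHS of the free equations
    b = -(lap @ vals)
    b[fixed] = vals[fixed]

    # identity rows for fixed nodes, and drop fixed columns from free rows
    free_diag = csr_matrix(
        (np.ones(np.count_nonzero(~fixed)), (np.flatnonzero(~fixed), np.flatnonzero(~fixed))),
        shape=(n, n),
    )
    fixed_diag = identity(n, format="csr") - free_diag
    a = free_diag @ lap @ free_diag + fixed_diag
    v = splu(a.tocsc()).solve(b)
    return v.reshape(shape)


def solve_potential(
    domain: DomainSpec, tissue: TissueProperties, protocol: PulseProtocol
) -> np.ndarray:
    """Potential during a pulse: electrodes at +voltage and ground.

    For a homogeneous conductivity the σ factor cancels from
    ``∇·(σ∇V) = 0``, so the solution is independent of the tissue's σ.
    """
    anode, cathode = domain.electrode_masks()
    mask = anode | cathode
    values = np.where(anode, protocol.voltage, 0.0)
    return solve_laplace(domain.shape, mask, values)


def field_magnitude(potential: np.ndarray, spacing: float) -> np.ndarray:
    """|E| = |∇V| by central differences, returned in V/cm."""
    gy, gx = np.gradient(potential, spacing)
    return np.hypot(gx, gy) / 100.0  # V/m -> V/cm


def joule_source(
    e_mag_v_cm: np.ndarray, sigma: float, protocol: PulseProtocol
) -> np.ndarray:
    """Duty-cycle-averaged volumetric Joule heating q = σ|E|²·duty, W/m³."""
    e_v_m = np.asarray(e_mag_v_cm, dtype=float) * 100.0
    return sigma * e_v_m**2 * protocol.duty_factor


# ---------------------------------------------------------------------------
# bioheat


def _perfusion_coefficient(tissue: TissueProperties) -> float:
    """Pennes sink coefficient ρ_b c_b ω_b in W/(m³·°C).

    ω_b converts the tabulated perfusion (ml blood / min / kg tissue) to a
    volumetric exchange rate: ω_b = w_b · ρ_tissue · 1e-6 / 60  (1/s).
    """
    omega = tissue.w_b * tissue.rho * 1e-6 / 60.0
    return BLOOD_DENSITY * BLOOD_HEAT_CAPACITY * omega


class BioheatStepper:
    """Time-stepper for Pennes' bioheat equation on the domain grid.

    Backward-Euler (implicit, unconditionally stable) by default; the
    sparse operator is factorised once per (domain, tissue, dt).  The outer
    boundary is held at body temperature (37 °C Dirichlet) unless
    ``outer_bc='neumann'`` selects an insulated boundary.
    """

    def __init__(
        self,
        domain: DomainSpec,
        tissue: TissueProperties,
        dt: float,
        scheme: str = "implicit",
        outer_bc: str = "dirichlet",
    ):
        if scheme not in ("implicit", "explicit"):
            raise ValueError("scheme must be 'implicit' or 'explicit'")
        if outer_bc not in ("dirichlet", "neumann"):
            raise ValueError("outer_bc must be 'dirichlet' or 'neumann'")
        self.domain = domain
        self.tissue = tissue
        self.dt = float(dt)
        self.scheme = scheme
        self.outer_bc = outer_bc

        ny, nx = domain.shape
        self._shape = (ny, nx)
        h2 = domain.spacing**2
        rc = tissue.rho * tissue.c
        self._alpha = tissue.k_th / rc  # m^2/s
        self._perf = _perfusion_coefficient(tissue) / rc  # 1/s
        self._rc = rc
        self._lap = _laplacian_matrix(self._shape) / h2  # -laplacian / h^2

        if scheme == "explicit":
            # diffusion + perfusion stability bound for forward Euler
            limit = 1.0 / (4.0 * self._alpha / h2 + self._perf)
            if self.dt > limit:
                raise ValueError(
                    f"explicit step dt={dt} exceeds stability bound {limit:.4g} s"
                )
            self._lu = None
        else:
            n = ny * nx
            a = identity(n, format="csr") + self.dt * (
                self._alpha * self._lap + self._perf * identity(n, format="csr")
            )
            if outer_bc == "dirichlet":
                a = a.tolil()
                border = np.zeros(self._shape, dtype=bool)
                border[0, :] = border[-1, :] = True
                border[:, 0] = border[:, -1] = True
                for i in np.flatnonzero(border.ravel()):
                    a.rows[i] = [i]
                    a.data[i] = [1.0]
                self._border = border
                a = a.tocsr()
            self._lu = splu(a.tocsc())
        if scheme == "explicit" or outer_bc == "neumann":
            border = np.zeros(self._shape, dtype=bool)
            border[0, :] = border[-1, :] = True
            border[:, 0] = border[:, -1] = True
            self._border = border

    def step(self, temp_c: np.ndarray, source: np.ndarray | float = 0.0) -> np.ndarray:
        """Advance one time step; ``source`` is volumetric heating in W/m³."""
        t = np.asarray(temp_c, dtype=float)
        q = np.broadcast_to(np.asarray(source, dtype=float), t.shape)
        forcing = (
            self._perf * ARTERIAL_TEMP_C
            + (q + self.tissue.rho * self.tissue.q_met) / self._rc
        )
        if self.scheme == "explicit":
            flat = t.ravel()
            dtdt = -self._alpha * (self._lap @ flat) - self._perf * flat
            new = flat + self.dt * (dtdt + forcing.ravel())
            new = new.reshape(t.shape)
            if self.outer_bc == "dirichlet":
                new = new.copy()
                new[self._border] = ARTERIAL_TEMP_C
            return new
        rhs = t.ravel() + self.dt * forcing.ravel()
        if self.outer_bc == "dirichlet":
            rhs = rhs.copy()
            rhs[self._border.ravel()] = ARTERIAL_TEMP_C
        return self._lu.solve(rhs).reshape(t.shape)


def step_bioheat(
    temp_c: np.ndarray,
    domain: DomainSpec,
    tissue: TissueProperties,
    source: np.ndarray | float,
    dt: float,
    scheme: str = "explicit",
    outer_bc: str = "neumann",
) -> np.ndarray:
    """One bioheat step (convenience wrapper; see :class:`BioheatStepper`)."""
    return BioheatStepper(domain, tissue, dt, scheme=scheme, outer_bc=outer_bc).step(
        temp_c, source
    )


# ---------------------------------------------------------------------------
# damage


def arrhenius_integral(
    temps_c: np.ndarray, times_s: np.ndarray, params: ArrheniusParams = ArrheniusParams()
) -> np.ndarray:
    """Damage integral Ω = ∫ ζ exp(-Ea/(R·T)) dt by trapezoidal quadrature.

    ``temps_c`` may be a 1D history at a point or an array with time on the
    first axis; ``times_s`` are the matching sample times.  Exact for a
    constant temperature history; additive over shared time partitions.
    """
    temps = np.asarray(temps_c, dtype=float)
    times = np.asarray(times_s, dtype=float)
    if temps.shape[0] != times.shape[0]:
        raise ValueError("temperature history and times have mismatched lengths")
    rates = params.rate(temps)
    return np.trapezoid(rates, times, axis=0)


def thermal_injury_probability(omega) -> np.ndarray:
    """P_TI = 1 - exp(-Ω); Ω = ln 2 maps to exactly 0.5."""
    return -np.expm1(-np.asarray(omega, dtype=float))


def ei_probability(
    e_mag_v_cm: np.ndarray, coeffs: PelegFermiCoefficients, n: int
) -> np.ndarray:
    """Electrical-injury probability map at pulse number ``n``.

    Above the lethal threshold Ec(N) the kill probability is 1 - S(|E|, N)
    from the Peleg-Fermi model; below it, electroporation is reversible and
    the probability is set to zero.
    """
    ec = coeffs.ec(n)
    ac = coeffs.ac(n)
    e = np.asarray(e_mag_v_cm, dtype=float)
    p = 1.0 - np.asarray(survival_probability(e, ec, ac))
    return np.where(e >= ec, p, 0.0)


def area_ratios(
    p_ei: np.ndarray,
    p_ti: np.ndarray,
    electrode_mask: np.ndarray,
    threshold: float = 0.5,
) -> tuple[float, float]:
    """Relative injured-area ratios S_EI/S_total and S_TI/S_total.

    Node counting over the tissue region; electrode interiors are excluded
    from numerator and denominator.  A node counts as injured where its
    probability strictly exceeds the threshold.
    """
    tissue = ~np.asarray(electrode_mask, dtype=bool)
    total = int(tissue.sum())
    s_ei = float(np.count_nonzero((np.asarray(p_ei) > threshold) & tissue)) / total
    s_ti = float(np.count_nonzero((np.asarray(p_ti) > threshold) & tissue)) / total
    return s_ei, s_ti


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class InjuryAnalysisResult:
    """Outputs of a coupled run: ratio time series and final field/maps."""

    series: pd.DataFrame = field(repr=False)
    final_map: InjuryMap = field(repr=False)
    e_mag_v_cm: np.ndarray = field(repr=False)
    temperature_c: np.ndarray = field(repr=False)
    omega: np.ndarray = field(repr=False)


def run_injury_analysis(
    domain: DomainSpec,
    tissue: TissueProperties,
    protocol: PulseProtocol,
    coeffs: PelegFermiCoefficients,
    arrhenius: ArrheniusParams = ArrheniusParams(),
    dt_s: float = 0.1,
    threshold: float = 0.5,
) -> InjuryAnalysisResult:
    """Time-dependent coupled analysis of electrical and thermal injury.

    The field is solved once (static conductivity); the electrical-injury
    map advances with the pulse count N up to ``n_pulses_ei`` and is held
    there for the remainder of the thermal window (``n_pulses_ti`` pulses
    at 1 Hz = as many seconds).  Thermal damage accumulates per bioheat
    step via the Arrhenius integral.
    """
    if protocol.voltage > 0:
        potential = solve_potential(domain, tissue, protocol)
        e_mag = field_magnitude(potential, domain.spacing)
    else:
        e_mag = np.zeros(domain.shape)
    electrode = domain.electrode_mask()
    # no Joule deposition inside the (perfectly conducting) needles
    source = joule_source(e_mag, tissue.sigma, protocol)
    source[electrode] = 0.0

    stepper = BioheatStepper(domain, tissue, dt_s, scheme="implicit")
    temp = np.full(domain.shape, ARTERIAL_TEMP_C)
    omega = np.zeros(domain.shape)
    rate_prev = arrhenius.rate(temp)

    steps_per_pulse = max(int(round(1.0 / (protocol.frequency_hz * dt_s))), 1)
    records = []
    p_ei = np.zeros(domain.shape)
    for pulse in range(1, protocol.n_pulses_ti + 1):
        for _ in range(steps_per_pulse):
            temp = stepper.step(temp, source)
            rate = arrhenius.rate(temp)
            omega += 0.5 * (rate_prev + rate) * dt_s
            rate_prev = rate
        n_ei = min(pulse, protocol.n_pulses_ei)
        if protocol.voltage > 0:
            p_ei = ei_probability(e_mag, coeffs, n_ei)
        p_ti = thermal_injury_probability(omega)
        s_ei, s_ti = area_ratios(p_ei, p_ti, electrode, threshold)
        records.append(
            {
                "pulse_number": pulse,
                "s_ei_ratio": s_ei,
                "s_ti_ratio": s_ti,
                "peak_T_C": float(temp[~electrode].max()),
            }
        )

    p_ti = thermal_injury_probability(omega)
    s_ei, s_ti = area_ratios(p_ei, p_ti, electrode, threshold)
    final = InjuryMap(p_ei=p_ei, p_ti=p_ti, s_ei_ratio=s_ei, s_ti_ratio=s_ti, threshold=threshold)
    return InjuryAnalysisResult(
        series=pd.DataFrame.from_records(records),
        final_map=final,
        e_mag_v_cm=e_mag,
        temperature_c=temp,
        omega=omega,
    )
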