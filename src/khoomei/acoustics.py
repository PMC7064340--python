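"""Lossy transmission-line acoustics of the vocal tract.

The tract is modeled as a chain of short uniform tubes (1-D plane-wave
propagation).  Each tube contributes a two-port chain (ABCD) matrix built
from its per-unit-length series impedance and shunt admittance, which include
the classic loss terms:

* viscous friction (series) and heat conduction (shunt), both of
  boundary-layer form growing as ``sqrt(f)``;
* yielding walls as a mass-resistance-stiffness shunt branch per unit of
  wall surface;
* lip radiation as a piston-in-baffle load (parallel resistance/inertance).

The glottis end is driven by an ideal volume-velocity source, so the default
transfer function is the volume-velocity gain ``U_lips / U_glottis``; its
peaks are the formants F1, F2, ...

On top of the forward model, :func:`compute_sensitivity` gives the classical
energy-based sensitivity of a formant to fractional area perturbations
(kinetic minus potential acoustic energy per section, normalized by total
energy), and :func:`perturb_to_focus` uses two such sensitivity functions to
iteratively deform an area function until two chosen formants merge on a
target frequency — the "focused state" of Sygyt-style overtone singing.

All quantities are in CGS units (cm, g, s, dyn).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

from .geometry import AreaFunction

__all__ = [
    "AcousticConstants",
    "FrequencyResponse",
    "FormantSet",
    "SensitivityFunction",
    "FocusOptions",
    "FocusResult",
    "transfer_function",
    "compute_frequency_response",
    "pick_formants",
    "refine_formant",
    "compute_sensitivity",
    "perturb_to_focus",
    "steer_formant",
]

# air / tissue constants, CGS (body-temperature moist air)
_MU = 1.86e-4  # shear viscosity, poise
_ETA = 1.4  # adiabatic constant
_LAMBDA = 5.5e-5  # heat conduction coefficient, cal/(cm s degC)
_CP = 0.24  # specific heat, cal/(g degC)


@dataclass(frozen=True)
class AcousticConstants:
    """Physical constants and loss toggles for the transmission-line model."""

    c: float = 35000.0  # speed of sound, cm/s
    rho: float = 1.14e-3  # air density, g/cm^3
    wall_resistance: float = 1600.0  # dyn s/cm^3 per unit wall area
    wall_mass: float = 1.5  # g/cm^2 per unit wall area
    wall_compliance: float = 3.0e5  # stiffness, dyn/cm^3 per unit wall area
    include_walls: bool = True
    include_viscous_thermal: bool = True
    include_radiation: bool = True

    def __post_init__(self) -> None:
        if self.c <= 0 or self.rho <= 0:
            raise ValueError("c and rho must be positive")
        if min(self.wall_resistance, self.wall_mass, self.wall_compliance) < 0:
            raise ValueError("wall parameters must be non-negative")

    @classmethod
    def lossless(cls) -> "AcousticConstants":
        """Rigid-walled, loss-free configuration (ideal tube)."""
        return cls(include_walls=False, include_viscous_thermal=False, include_radiation=False)


@dataclass
class FrequencyResponse:
    """Gain (dB) of a tract transfer function on a frequency grid (Hz)."""

    freq: np.ndarray
    gain_db: np.ndarray
    kind: str = "volume_velocity"

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.gain_db = np.asarray(self.gain_db, dtype=float)
        if len(self.freq) != len(self.gain_db):
            raise ValueError("freq and gain_db must have equal length")
        if self.freq[0] <= 0 or np.any(np.diff(self.freq) <= 0):
            raise ValueError("freq must be strictly increasing and positive")
        if not np.all(np.isfinite(self.gain_db)):
            raise ValueError("gain_db must be finite")

    def gain_at(self, f) -> np.ndarray:
        """Interpolated gain (dB) at arbitrary frequencies."""
        return np.interp(np.asarray(f, dtype=float), self.freq, self.gain_db)


@dataclass
class FormantSet:
    """Ordered resonance peaks F1..Fn with levels and merged markers."""

    freqs: np.ndarray
    levels_db: np.ndarray
    merged_flags: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.levels_db = np.asarray(self.levels_db, dtype=float)
        self.merged_flags = np.asarray(self.merged_flags, dtype=bool)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("formant frequencies must be ascending")

    def __len__(self) -> int:
        return len(self.freqs)


@dataclass
class SensitivityFunction:
    """Per-section sensitivity of formant ``formant_index`` to dA/A."""

    formant_index: int
    values: np.ndarray  # same length as the area function


def _section_geometry(af: AreaFunction) -> tuple[np.ndarray, float]:
    """Tube sections between grid points: mean areas and common length."""
    if not af.is_uniform_grid():
        raise ValueError("area function must be resampled to uniform sections")
    areas = 0.5 * (af.A[:-1] + af.A[1:])
    ell = float(af.x[1] - af.x[0])
    return areas, ell


def _line_constants(A: float, omega: np.ndarray, const: AcousticConstants):
    """Per-unit-length series impedance z and shunt admittance y of a tube."""
    S = 2.0 * np.sqrt(np.pi * A)  # circumference of the circular section
    z = 1j * omega * const.rho / A
    y = 1j * omega * A / (const.rho * const.c**2)
    if const.include_viscous_thermal:
        z = z + (S / A**2) * np.sqrt(omega * const.rho * _MU / 2.0)
        y = y + S * (_ETA - 1.0) / (const.rho * const.c**2) * np.sqrt(
            _LAMBDA * omega / (2.0 * _CP * const.rho)
        )
    if const.include_walls:
        zw = (
            const.wall_resistance
            + 1j * omega * const.wall_mass
            + const.wall_compliance / (1j * omega)
        )
        y = y + S / zw
    return z, y


def _sinhc(u: np.ndarray) -> np.ndarray:
    """sinh(u)/u, even in u, stable near 0 (branch-safe for u = sqrt(zy)l)."""
    out = np.ones_like(u)
    nz = np.abs(u) > 1e-12
    out[nz] = np.sinh(u[nz]) / u[nz]
    return out


def _section_matrices(areas: np.ndarray, ell: float, omega: np.ndarray, const: AcousticConstants):
    """Chain matrices for each section, vectorized over frequency."""
    mats = []
    for A in areas:
        z, y = _line_constants(A, omega, const)
        gl = np.sqrt(z * y) * ell
        ch = np.cosh(gl)
        sc = _sinhc(gl)
        mats.append((ch, z * ell * sc, y * ell * sc, ch))  # (a, b, c, d)
    return mats


def radiation_impedance(A_lip: float, omega: np.ndarray, const: AcousticConstants) -> np.ndarray:
    """Piston-in-baffle lip load: parallel radiation resistance and inertance."""
    if not const.include_radiation:
        return np.zeros_like(omega, dtype=complex)
    a = np.sqrt(A_lip / np.pi)
    R = 128.0 * const.rho * const.c / (9.0 * np.pi**2 * A_lip)
    L = 8.0 * const.rho / (3.0 * np.pi**2 * a)
    jwL = 1j * omega * L
    return R * jwL / (R + jwL)


def transfer_function(
    af: AreaFunction,
    const: AcousticConstants,
    freqs: np.ndarray,
    kind: str = "volume_velocity",
) -> np.ndarray:
    """Complex transfer at the given frequencies (Hz).

    ``volume_velocity`` returns ``U_lips/U_glottis``; ``radiated_pressure``
    additionally applies the lip radiation load (adding its characteristic
    high-pass emphasis).
    """
    freqs = np.asarray(freqs, dtype=float)
    omega = 2.0 * np.pi * freqs
    areas, ell = _section_geometry(af)
    mats = _section_matrices(areas, ell, omega, const)

    # cascade glottis -> lips: [P_g; U_g] = T [P_l; U_l]
    Ta = np.ones_like(omega, dtype=complex)
    Tb = np.zeros_like(Ta)
    Tc = np.zeros_like(Ta)
    Td = np.ones_like(Ta)
    for a, b, c, d in mats:
        Ta, Tb, Tc, Td = Ta * a + Tb * c, Ta * b + Tb * d, Tc * a + Td * c, Tc * b + Td * d

    z_rad = radiation_impedance(float(af.A[-1]), omega, const)
    denom = Tc * z_rad + Td
    with np.errstate(divide="ignore"):
        H = 1.0 / denom
    H[~np.isfinite(H)] = 1e12  # lossless poles: finite sentinel for dB math
    if kind == "radiated_pressure":
        H = H * z_rad
    elif kind != "volume_velocity":
        raise ValueError(f"unknown transfer kind {kind!r}")
    return H


def compute_frequency_response(
    af: AreaFunction,
    const: AcousticConstants = AcousticConstants(),
    fmin: float = 10.0,
    fmax: float = 8000.0,
    df: float = 2.0,
    kind: str = "volume_velocity",
) -> FrequencyResponse:
    """Frequency response of an area function on a uniform grid.

    The area function must already be on a uniform grid (use
    :func:`khoomei.geometry.resample_area_function`).
    """
    if not (0 < fmin < fmax) or df <= 0:
        raise ValueError("need 0 < fmin < fmax and df > 0")
    freqs = np.arange(fmin, fmax + 0.5 * df, df)
    H = transfer_function(af, const, freqs, kind=kind)
    gain_db = 20.0 * np.log10(np.maximum(np.abs(H), 1e-30))
    return FrequencyResponse(freq=freqs, gain_db=gain_db, kind=kind)


def _parabolic_peak(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Refine peak i by fitting a parabola through its three samples."""
    if i == 0 or i == len(y) - 1:
        return float(x[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if abs(denom) < 1e-15:
        return float(x[i]), float(y[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    dx = x[i + 1] - x[i] if delta >= 0 else x[i] - x[i - 1]
    return float(x[i] + delta * dx), float(y1 - 0.25 * (y0 - y2) * delta)


def pick_formants(
    fr: FrequencyResponse,
    n_max: int = 5,
    min_prominence_db: float = 1.0,
    min_separation_hz: float = 80.0,
) -> FormantSet:
    """Formants as prominent local maxima of the response.

    Peaks closer together than ``min_separation_hz`` are merged: the taller
    one is kept (ties broken toward lower frequency) and flagged as merged.
    Peak frequencies are refined by parabolic interpolation.
    """
    idx, _ = find_peaks(fr.gain_db, prominence=min_prominence_db)
    if len(idx) == 0:
        warnings.warn("no formant peaks found")
        return FormantSet(np.array([]), np.array([]), np.array([], dtype=bool))

    freqs, levels = zip(*(_parabolic_peak(fr.freq, fr.gain_db, i) for i in idx))
    freqs, levels = list(freqs), list(levels)
    merged = [False] * len(freqs)

    changed = True
    while changed and len(freqs) > 1:
        changed = False
        for i in range(len(freqs) - 1):
            if freqs[i + 1] - freqs[i] < min_separation_hz:
                # keep the taller peak; tie -> lower frequency
                keep = i if levels[i] >= levels[i + 1] else i + 1
                drop = i + 1 if keep == i else i
                merged[keep] = True
                for lst in (freqs, levels, merged):
                    del lst[drop]
                changed = True
                break

    freqs = np.array(freqs[:n_max])
    levels = np.array(levels[: len(freqs)])
    merged = np.array(merged[: len(freqs)], dtype=bool)
    return FormantSet(freqs=freqs, levels_db=levels, merged_flags=merged)


def refine_formant(
    af: AreaFunction,
    const: AcousticConstants,
    f_approx: float,
    half_width: float = 40.0,
    df: float = 0.25,
) -> float:
    """Refine a formant frequency on a fine local grid with parabolic fit."""
    lo = max(f_approx - half_width, 1.0)
    freqs = np.arange(lo, f_approx + half_width, df)
    g = 20.0 * np.log10(np.maximum(np.abs(transfer_function(af, const, freqs)), 1e-30))
    i = int(np.argmax(g))
    return _parabolic_peak(freqs, g, i)[0]


def _interior_state(af: AreaFunction, const: AcousticConstants, f: float):
    """Pressure and volume velocity at every section boundary at frequency f.

    Propagates backward from the lip termination (U_lip = 1, P_lip =
    Z_rad * U_lip) so index 0 is the glottis end.
    """
    omega = np.atleast_1d(2.0 * np.pi * f)
    areas, ell = _section_geometry(af)
    mats = _section_matrices(areas, ell, omega, const)
    z_rad = radiation_impedance(float(af.A[-1]), omega, const)
    P = [z_rad[0]]
    U = [1.0 + 0j]
    for a, b, c, d in reversed(mats):
        P_next, U_next = P[-1], U[-1]
        P.append(a[0] * P_next + b[0] * U_next)
        U.append(c[0] * P_next + d[0] * U_next)
    return np.array(P[::-1]), np.array(U[::-1]), areas, ell


def compute_sensitivity(
    af: AreaFunction,
    const: AcousticConstants = AcousticConstants(),
    formant_index: int = 1,
    formant_freq: float | None = None,
) -> SensitivityFunction:
    """Energy-based sensitivity of formant ``formant_index`` to area changes.

    At the formant frequency the kinetic and potential acoustic energies per
    section are ``KE_n = rho*l/(2*A_n) |U_n|^2`` and ``PE_n = A_n*l/(2*rho*c^2)
    |P_n|^2``; the sensitivity of section n is ``(KE_n - PE_n)`` normalized by
    the total energy, so that ``dF/F ~= sum_n S(n) * dA(n)/A(n)``.  Values are
    mapped back onto the area-function grid points.
    """
    if formant_freq is None:
        fr = compute_frequency_response(af, const)
        fs = pick_formants(fr)
        if len(fs) < formant_index:
            raise ValueError(f"formant {formant_index} not found")
        formant_freq = float(fs.freqs[formant_index - 1])

    P, U, areas, ell = _interior_state(af, const, formant_freq)
    U_mid = 0.5 * (U[:-1] + U[1:])
    P_mid = 0.5 * (P[:-1] + P[1:])
    KE = const.rho * ell / (2.0 * areas) * np.abs(U_mid) ** 2
    PE = areas * ell / (2.0 * const.rho * const.c**2) * np.abs(P_mid) ** 2
    total = np.sum(KE + PE)
    S_sec = (KE - PE) / total

    # section sensitivities -> grid-point sensitivities
    S = np.empty(af.n_sections)
    S[0] = S_sec[0]
    S[-1] = S_sec[-1]
    S[1:-1] = 0.5 * (S_sec[:-1] + S_sec[1:])
    return SensitivityFunction(formant_index=formant_index, values=S)


def steer_formant(
    af0: AreaFunction,
    const: AcousticConstants,
    formant_index: int,
    target_hz: float,
    opts: "FocusOptions" = None,
) -> "FocusResult":
    """Move a single formant onto a target frequency (no merging).

    Same sensitivity-driven minimum-norm iteration as
    :func:`perturb_to_focus` but with one constraint; used e.g. to sharpen
    F4 into a secondary focus near 3-3.5 kHz.
    """
    opts = opts or FocusOptions()
    af = af0.copy()
    fr = compute_frequency_response(af, const, fmax=opts.fmax, df=opts.df)
    fs = pick_formants(fr, n_max=8)
    if len(fs) < formant_index:
        raise ValueError(f"formant {formant_index} not found")
    prev = float(fs.freqs[formant_index - 1])
    trace = []
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        fr = compute_frequency_response(af, const, fmax=opts.fmax, df=opts.df)
        fs = pick_formants(fr, n_max=8)
        if len(fs) == 0:
            break
        k = int(np.argmin(np.abs(fs.freqs - prev)))
        f = float(fs.freqs[k])
        prev = f
        trace.append((it, f, f, False))
        if abs(f - target_hz) <= opts.tol * target_hz:
            converged = True
            break
        S = compute_sensitivity(af, const, formant_index=k + 1, formant_freq=f)
        delta = opts.step * S.values / np.sum(S.values**2) * (target_hz - f) / f
        delta = np.clip(_smooth(delta, opts.smooth_window), -opts.max_delta, opts.max_delta)
        af = AreaFunction(af.x.copy(), np.clip(af.A * (1.0 + delta), opts.area_floor, opts.area_ceiling))
    return FocusResult(af=af, converged=converged, unreachable=False, n_iter=it, trace=trace)


@dataclass(frozen=True)
class FocusOptions:
    """Controls for the iterative formant-merging perturbation."""

    step: float = 0.1
    max_iter: int = 200
    area_floor: float = 0.05  # cm^2
    tol: float = 0.01  # fraction of target
    smooth_window: int = 3
    max_delta: float = 0.15  # per-iteration |dA/A| cap (linear-regime guard)
    area_ceiling: float = 8.0  # cm^2, physiological upper bound
    fmax: float = 8000.0
    df: float = 2.0


@dataclass
class FocusResult:
    """Outcome of :func:`perturb_to_focus` with its per-iteration trace."""

    af: AreaFunction
    converged: bool
    unreachable: bool
    n_iter: int
    trace: list = field(default_factory=list)  # (iter, F_lo, F_hi, merged)

    @property
    def final_formants(self) -> tuple[float, float]:
        _, flo, fhi, _ = self.trace[-1]
        return flo, fhi


def _smooth(v: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return v
    kernel = np.ones(window) / window
    pad = window // 2
    vp = np.pad(v, pad, mode="edge")
    return np.convolve(vp, kernel, mode="valid")[: len(v)]


def perturb_to_focus(
    af0: AreaFunction,
    const: AcousticConstants = AcousticConstants(),
    target_hz: float = 1800.0,
    formant_indices: tuple[int, int] = (2, 3),
    opts: FocusOptions = FocusOptions(),
) -> FocusResult:
    """Deform an area function until two formants merge on a target frequency.

    Each iteration measures the two tracked formants, computes their
    sensitivity functions S_i, S_j, and applies the minimum-norm fractional
    area update that — under the linearized model ``dF/F = sum_n S(n)
    dA(n)/A(n)`` — moves both formants a fraction ``step`` of their remaining
    gap toward the target: ``delta = step * G^+ r`` with G the 2xN matrix of
    sensitivities, r the fractional frequency errors, and G^+ a (ridge-
    regularized) pseudoinverse.  Solving the two constraints jointly keeps
    the update effective when the formants are close and their sensitivity
    functions nearly cancel.  The update is smoothed along the tract,
    capped per iteration, and clipped at ``area_floor``.  The loop stops
    when both formants are within ``tol*target`` of the target, or when the
    picked response shows a single (merged) peak within tolerance.  Failure
    to converge is reported in the result, not raised.
    """
    i, j = formant_indices
    if not (1 <= i < j):
        raise ValueError("formant_indices must be ascending and >= 1")
    af = af0.copy()

    fr = compute_frequency_response(af, const, fmax=opts.fmax, df=opts.df)
    fs = pick_formants(fr)
    if len(fs) < j:
        raise ValueError(f"formant {j} not found on the initial area function")
    unreachable = target_hz < fs.freqs[0]
    prev_lo, prev_hi = float(fs.freqs[i - 1]), float(fs.freqs[j - 1])

    trace = []
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        fr = compute_frequency_response(af, const, fmax=opts.fmax, df=opts.df)
        fs = pick_formants(fr)
        if len(fs) == 0:
            break
        k_lo = int(np.argmin(np.abs(fs.freqs - prev_lo)))
        k_hi = int(np.argmin(np.abs(fs.freqs - prev_hi)))
        merged = k_lo == k_hi

        # the response already shows a single (isolated) peak at the target:
        # treat as converged regardless of the tracked pair (idempotence)
        k_near = int(np.argmin(np.abs(fs.freqs - target_hz)))
        f_near = float(fs.freqs[k_near])
        others = np.delete(fs.freqs, k_near)
        isolated = len(others) == 0 or np.min(np.abs(others - f_near)) > 0.25 * target_hz
        if (
            k_near in (k_lo, k_hi)
            and abs(f_near - target_hz) <= opts.tol * target_hz
            and isolated
        ):
            trace.append((it, f_near, f_near, True))
            converged = True
            break

        if merged:
            fm = float(fs.freqs[k_lo])
            trace.append((it, fm, fm, True))
            prev_lo = prev_hi = fm
            if abs(fm - target_hz) <= opts.tol * target_hz:
                converged = True
                break
            S = compute_sensitivity(af, const, formant_index=k_lo + 1, formant_freq=fm)
            delta = opts.step * S.values / np.sum(S.values**2) * (target_hz - fm) / fm
        else:
            f_lo, f_hi = float(fs.freqs[k_lo]), float(fs.freqs[k_hi])
            trace.append((it, f_lo, f_hi, False))
            prev_lo, prev_hi = f_lo, f_hi
            if (
                abs(f_lo - target_hz) <= opts.tol * target_hz
                and abs(f_hi - target_hz) <= opts.tol * target_hz
            ):
                converged = True
                break
            S_lo = compute_sensitivity(af, const, formant_index=k_lo + 1, formant_freq=f_lo)
            S_hi = compute_sensitivity(af, const, formant_index=k_hi + 1, formant_freq=f_hi)
            G = np.vstack([S_lo.values, S_hi.values])
            r = np.array([(target_hz - f_lo) / f_lo, (target_hz - f_hi) / f_hi])
            gram = G @ G.T + 1e-4 * np.trace(G @ G.T) * np.eye(2)
            delta = opts.step * (G.T @ np.linalg.solve(gram, r))

        delta = _smooth(delta, opts.smooth_window)
        delta = np.clip(delta, -opts.max_delta, opts.max_delta)
        A_new = np.clip(af.A * (1.0 + delta), opts.area_floor, opts.area_ceiling)
        af = AreaFunction(af.x.copy(), A_new)

    return FocusResult(
        af=af, converged=converged, unreachable=unreachable, n_iter=it, trace=trace
    )
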