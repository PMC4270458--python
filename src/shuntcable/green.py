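"""Analytical Green's function of the linearized two-compartment cable.

For an impulse current ``delta(x - y) delta(t)`` applied to the per-area
cable equation, the Laplace-transformed two-point boundary problem

    a G_xx - (g_L + c_m s) G = -delta(x - y),      a = d / (4 r_a)

with a sealed end at ``x = L`` and the lumped-soma condition
``S (c_m s + g_L) G(0) = beta G_x(0)`` (``beta = pi d^2 / (4 r_a)``) is
solved in closed form.  Its poles are simple; writing ``mu^2 =
(g_L + c_m s)/a`` and substituting ``mu = i k`` they sit at

    s_n = -(g_L + a k_n^2) / c_m,

where ``k_0 = 0`` (the spatially uniform mode, which satisfies the soma
condition identically) and ``k_n`` for n >= 1 are the roots of the
transcendental characteristic equation

    sin(k L) + gamma k cos(k L) = 0,        gamma = S / (pi d),

one in each interval ((n - 1/2) pi / L, n pi / L).  The residue theorem
gives the mode amplitudes in closed form, so

    G(x, y, t) = sum_n A_n(x, y) exp(s_n t),    t > 0,

with  A_0 = 1 / (c_m (L + gamma))  and, for n >= 1,

    A_n = 2 [cos(k x<) - gamma k sin(k x<)] cos(k (L - x>))
          / (c_m cos(k L) [(L + gamma) + gamma^2 k^2 L]),

where x< = min(x, y), x> = max(x, y).  The amplitudes are real because the
underlying operator is self-adjoint with respect to the membrane-area
measure pi d dx + S delta(x).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .fd import VoltageTrace
from .model import CableParams

__all__ = [
    "EigenDecomposition",
    "RootSearchError",
    "characteristic_roots",
    "characteristic_residual",
    "residue_coefficients",
    "evaluate_green",
    "convolve_green_source",
    "mode_convolution",
]

#: Default mode truncation; the slowest neglected mode decays within a few
#: hundredths of a millisecond for the default cable.
DEFAULT_N_MODES = 80


class RootSearchError(RuntimeError):
    """Raised when a root bracket fails to show a sign change."""


def characteristic_residual(params: CableParams, k: float) -> float:
    """Value of the characteristic function sin(kL) + gamma k cos(kL)."""
    gamma = params.soma_length
    L = params.length
    return math.sin(k * L) + gamma * k * math.cos(k * L)


def characteristic_roots(params: CableParams, n_modes: int) -> np.ndarray:
    """First ``n_modes`` characteristic spatial frequencies k_n [1/cm].

    Returns [0, k_1, ..., k_{n_modes-1}], strictly increasing; each nonzero
    root is bracketed between consecutive poles of tan(kL) and refined by
    Brent's method, so none are missed or duplicated.  In the limit of a
    vanishing soma (gamma -> 0) the nonzero roots approach the sealed-sealed
    pattern n pi / L; for a dominating soma (gamma -> inf) they approach the
    sealed-clamped pattern (n - 1/2) pi / L.
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    L = params.length
    roots = [0.0]
    eps = 1e-9 * math.pi / L
    for n in range(1, n_modes):
        lo = (n - 0.5) * math.pi / L + eps
        hi = n * math.pi / L - eps
        f_lo = characteristic_residual(params, lo)
        f_hi = characteristic_residual(params, hi)
        if f_lo * f_hi > 0:
            raise RootSearchError(
                f"no sign change in bracket {n}: f({lo})={f_lo}, f({hi})={f_hi}"
            )
        k = brentq(lambda k: characteristic_residual(params, k), lo, hi,
                   xtol=1e-14 * math.pi / L, rtol=8.9e-16)
        roots.append(float(k))
    return np.asarray(roots)


def pole_rates(params: CableParams, roots: np.ndarray) -> np.ndarray:
    """Pole locations s_n = -(g_L + a k_n^2)/c_m [1/ms] (all negative)."""
    return -(params.g_L + params.axial_coef * np.asarray(roots) ** 2) / params.c_m


def residue_coefficients(
    params: CableParams, roots: np.ndarray, x: float, y: float
) -> np.ndarray:
    """Per-mode residue amplitudes A_n(x, y) [mV per unit impulse weight].

    Symmetric in (x, y); linear in the impulse magnitude by construction.
    """
    L, gamma, c_m = params.length, params.soma_length, params.c_m
    for pos, name in ((x, "x"), (y, "y")):
        if not 0.0 <= pos <= L:
            raise ValueError(f"{name}={pos} outside cable [0, {L}]")
    k = np.asarray(roots, dtype=float)
    x_lo, x_hi = (x, y) if x <= y else (y, x)
    amps = np.empty_like(k)
    amps[0] = 1.0 / (c_m * (L + gamma))
    kn = k[1:]
    num = (np.cos(kn * x_lo) - gamma * kn * np.sin(kn * x_lo)) * np.cos(kn * (L - x_hi))
    den = c_m * np.cos(kn * L) * ((L + gamma) + gamma**2 * kn**2 * L) / 2.0
    amps[1:] = num / den
    return amps


@dataclass
class EigenDecomposition:
    """Characteristic roots and pole rates of one cable's Green's function."""

    roots: np.ndarray          # k_n [1/cm], k_0 = 0
    poles: np.ndarray          # s_n [1/ms]
    n_modes: int
    params_digest: str

    @classmethod
    def compute(
        cls, params: CableParams, n_modes: int = DEFAULT_N_MODES
    ) -> "EigenDecomposition":
        roots = characteristic_roots(params, n_modes)
        return cls(
            roots=roots,
            poles=pole_rates(params, roots),
            n_modes=n_modes,
            params_digest=params.digest(),
        )

    def check_params(self, params: CableParams) -> None:
        if params.digest() != self.params_digest:
            raise ValueError(
                "eigendecomposition was computed for different cable parameters"
            )

    def coefficients(self, params: CableParams, x: float, y: float) -> np.ndarray:
        self.check_params(params)
        return residue_coefficients(params, self.roots, x, y)

    # -- JSON cache ---------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "params_digest": self.params_digest,
            "n_modes": self.n_modes,
            "roots_per_cm": list(self.roots),
            "poles_per_ms": list(self.poles),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "EigenDecomposition":
        payload = json.loads(Path(path).read_text())
        return cls(
            roots=np.asarray(payload["roots_per_cm"]),
            poles=np.asarray(payload["poles_per_ms"]),
            n_modes=int(payload["n_modes"]),
            params_digest=str(payload["params_digest"]),
        )


def evaluate_green(
    params: CableParams,
    decomposition: EigenDecomposition,
    x: float,
    y: float,
    t: float | np.ndarray,
) -> float | np.ndarray:
    """Evaluate G(x, y, t) [mV per unit impulse weight] for t > 0.

    The series is dominated at large t by the uniform (slowest) mode, and
    every mode decays, so G -> 0 as t -> infinity.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0.0):
        raise ValueError("Green's function is defined for t > 0")
    decomposition.check_params(params)
    amps = residue_coefficients(params, decomposition.roots, x, y)
    out = np.exp(np.multiply.outer(t_arr, decomposition.poles)) @ amps
    if np.ndim(t) == 0:
        return float(out)
    return out


def convolve_green_source(
    green_slice: np.ndarray, source: np.ndarray, dt: float
) -> np.ndarray:
    """Trapezoidal discrete temporal convolution of two sampled series.

    Both series must share the sampling interval ``dt``; the result has the
    length of ``green_slice`` and is linear in both arguments.
    """
    g = np.asarray(green_slice, dtype=float)
    q = np.asarray(source, dtype=float)
    if g.shape != q.shape:
        raise ValueError("green slice and source must share the sampling grid")
    full = np.convolve(g, q)[: len(g)] * dt
    # trapezoid endpoint correction: halve the two end samples
    full -= 0.5 * dt * (g[0] * q + q[0] * g)
    return full


def mode_convolution(poles: np.ndarray, source: np.ndarray, dt: float) -> np.ndarray:
    """Exact exponential-integrator convolution of each decaying mode with a
    piecewise-linear source.

    Returns C[m, n] = integral_0^{t_m} exp(s_n (t_m - u)) q(u) du for the
    piecewise-linear interpolant of ``source``; the stiff fast modes are
    integrated without step-size restriction, which a plain trapezoid rule
    on the sampled kernel cannot do near t = 0.
    """
    s = np.asarray(poles, dtype=float)
    q = np.asarray(source, dtype=float)
    z = s * dt
    ez = np.exp(z)
    # phi1 = (e^z - 1)/z, phi2 = (e^z - 1 - z)/z^2, with z -> 0 limits
    small = np.abs(z) < 1e-8
    zsafe = np.where(small, 1.0, z)
    phi1 = np.where(small, 1.0 + z / 2.0, (ez - 1.0) / zsafe)
    phi2 = np.where(small, 0.5 + z / 6.0, (ez - 1.0 - z) / zsafe**2)
    n_t = len(q)
    out = np.zeros((n_t, len(s)))
    y = np.zeros(len(s))
    for m in range(n_t - 1):
        y = ez * y + dt * (q[m] * phi1 + (q[m + 1] - q[m]) * phi2)
        out[m + 1] = y
    return out


class ModalResponse:
    """A voltage field assembled from per-mode source convolutions.

    Stores, for each point source location y_src, the mode convolution
    integrals C_n(t); the potential anywhere is then the dot product with
    the residue amplitudes, v(x, t) = sum_src A_n(x, y_src) . C_n(t).
    Storing only these integrals realizes the point-evaluation collapse of
    the spatial integrals for delta-located conductances.
    """

    def __init__(
        self,
        params: CableParams,
        decomposition: EigenDecomposition,
        times: np.ndarray,
        contributions: list[tuple[float, np.ndarray]],
    ) -> None:
        decomposition.check_params(params)
        self.params = params
        self.decomposition = decomposition
        self.times = np.asarray(times, dtype=float)
        self.contributions = contributions   # [(y_src, C[nt, n_modes])]

    def at(self, x: float) -> VoltageTrace:
        """Potential trace at position x [cm]."""
        total = np.zeros(len(self.times))
        for y_src, c in self.contributions:
            amps = residue_coefficients(
                self.params, self.decomposition.roots, x, y_src
            )
            total += c @ amps
        return VoltageTrace(self.times, total)

    def soma(self) -> VoltageTrace:
        return self.at(0.0)

    def scaled(self, a: float) -> "ModalResponse":
        return ModalResponse(
            self.params,
            self.decomposition,
            self.times,
            [(y, a * c) for y, c in self.contributions],
        )

    def __add__(self, other: "ModalResponse") -> "ModalResponse":
        if other.decomposition is not self.decomposition and (
            other.decomposition.params_digest != self.decomposition.params_digest
        ):
            raise ValueError("responses built on different decompositions")
        return ModalResponse(
            self.params,
            self.decomposition,
            self.times,
            self.contributions + other.contributions,
        )
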