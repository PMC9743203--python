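"""Analytic model potential-energy surfaces.

Three surfaces are shipped, each a minimal closed form calibrated so that its
stationary-point structure matches a standard rare-event benchmark scenario:

``double_well_1d``
    A soft trapping harmonic term plus a Gaussian barrier at the origin.
    Two symmetric minima at x = ±3 Å separated by a moderate (1 kT) barrier;
    the spring is soft enough that excursions to |x| ≈ 100 Å cost only a few
    kT, which is what makes the first-passage-time distribution heavy-tailed.

``entropic_two_basin_2d``
    Two isoenergetic basins at (±1.3, 0) Å separated by a ~3 kT barrier at
    the origin.  The basins share their x-width but differ enormously in
    y-width (≈0.5 Å vs ≈50 Å): the particle in the broad right basin spends
    most of its time at |y| values from which it cannot cross, an entropic
    rather than energetic trap.

``modified_wolfe_quapp_2d``
    A three-well surface in the spirit of the modified Wolfe–Quapp benchmark:
    a lower basin (y < 0) split into two near-isoenergetic substates 30 Å
    apart by a ~1.5 kT sub-barrier, and a single upper basin (y > 0) reached
    over ~6.25 kT from the left substate but ~10 kT directly from the right
    one.  The right substate is thus a long-lived, nearly unreactive decoy.

Energies are in internal units (amu·Å²·ps⁻², see :mod:`resetfpt.constants`);
barrier heights are reported in units of k_B·T at a configured temperature.
Parameters are configuration data: the defaults below are derived in closed
form (double well) or fixed by construction (2-D models) from the target
constraints, and ``scripts/calibrate_potentials.py`` re-derives and verifies
them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize

from .constants import DEFAULT_TEMPERATURE, kt

__all__ = [
    "PotentialSpec",
    "StationaryPointReport",
    "ConstraintCheck",
    "ConfigurationError",
    "potential_energy",
    "potential_force",
    "find_minima",
    "barrier_height",
    "slice_barrier",
    "basin_width",
    "verify_constraints",
    "default_spec",
]


class ConfigurationError(ValueError):
    """Unknown potential form or missing/invalid parameter."""


# ---------------------------------------------------------------------------
# Default parameter sets
# ---------------------------------------------------------------------------

def _double_well_defaults(temperature: float = DEFAULT_TEMPERATURE) -> dict:
    """Closed-form calibration of U(x) = ½kx² + A·exp(−x²/2σ²).

    Given the Gaussian width σ, requiring a minimum at x_min and a barrier
    B = U(0) − U(x_min) fixes (k, A) exactly:

        u   = x_min² / (2σ²)
        A   = B / (1 − e^{−u}(1 + u))
        k   = (A/σ²)·e^{−u}

    σ = 0.75 Å keeps the spring soft (U(100 Å) ≈ 3 kT) while the barrier is
    1 kT and the minima sit exactly at ±3 Å.
    """
    sigma = 0.75
    x_min = 3.0
    barrier = 1.0 * kt(temperature)
    u = x_min**2 / (2.0 * sigma**2)
    amp = barrier / (1.0 - math.exp(-u) * (1.0 + u))
    k = amp / sigma**2 * math.exp(-u)
    return {"k": k, "A": amp, "sigma": sigma}


def _entropic_defaults(temperature: float = DEFAULT_TEMPERATURE) -> dict:
    """U(x, y) = a(x² − x_m²)² + ½κ(x)·y², κ log-switched stiff→soft.

    κ interpolates geometrically between κ_stiff (left, y-width 0.5 Å) and
    κ_soft (right, y-width 50 Å) through a tanh of width w; the switch is in
    log κ so that both extreme widths are reproduced to ~1% at x = ∓1.3 Å.
    The x-quartic puts the minima exactly at ±1.3 Å with a 3 kT barrier.
    """
    kbt = kt(temperature)
    x_m = 1.3
    barrier = 3.0 * kbt
    return {
        "a": barrier / x_m**4,
        "x_m": x_m,
        "k_stiff": kbt / 0.5**2,   # y-width 0.5 Å
        "k_soft": kbt / 50.0**2,   # y-width 50 Å
        "w": 0.4,
    }


def _wolfe_quapp_defaults(temperature: float = DEFAULT_TEMPERATURE) -> dict:
    """Three-well surface: lower substate pair + switched single upper well.

    U = Vy(y) + S(y)·Vx(x) + (1 − S(y))·½κ_u x² + Δ·Sx(x)·exp(−y²/2σ_r²)

    with Vx a quartic double well (minima ±15 Å, 1.5 kT sub-barrier),
    Vy a quartic double well in y (minima ∓1.4 Å, 6.25 kT ridge at y = 0),
    S(y) a tanh switch from the substate pair to a single harmonic upper
    well, and a one-sided ridge Δ = 3.75 kT active only at x > 0 that raises
    the direct escape barrier of the right substate to ~10 kT.
    """
    kbt = kt(temperature)
    return {
        "hx": 1.5 * kbt, "sx": 15.0,        # substate pair, 30 Å apart
        "b0": 6.25 * kbt, "ym": 1.4,        # y double well
        "ysw": 0.7, "wy": 0.3,              # lower→upper switch
        "ku": kbt / 5.0**2,                 # upper-well x-stiffness (σ = 5 Å)
        "delta": 3.75 * kbt, "wx": 3.0,     # right-side ridge
        "sr": 0.4,
    }


_DEFAULTS = {
    "harmonic": lambda T: {"k": 2.0},
    "double_well_1d": _double_well_defaults,
    "entropic_two_basin_2d": _entropic_defaults,
    "modified_wolfe_quapp_2d": _wolfe_quapp_defaults,
}

_DIM = {
    "harmonic": None,  # any
    "double_well_1d": 1,
    "entropic_two_basin_2d": 2,
    "modified_wolfe_quapp_2d": 2,
    "custom_expression": None,
}

_DEFAULT_BOX = {
    "double_well_1d": [(-150.0, 150.0)],
    "entropic_two_basin_2d": [(-4.0, 4.0), (-200.0, 200.0)],
    "modified_wolfe_quapp_2d": [(-30.0, 30.0), (-4.0, 4.0)],
    "harmonic": [(-50.0, 50.0)],
}

_REQUIRED = {
    "harmonic": ("k",),
    "double_well_1d": ("k", "A", "sigma"),
    "entropic_two_basin_2d": ("a", "x_m", "k_stiff", "k_soft", "w"),
    "modified_wolfe_quapp_2d": ("hx", "sx", "b0", "ym", "ysw", "wy", "ku",
                                "delta", "wx", "sr"),
    "custom_expression": ("expression",),
}


@dataclass(frozen=True)
class PotentialSpec:
    """A parametrized analytic potential-energy surface.

    Parameters
    ----------
    form : str
        One of ``harmonic``, ``double_well_1d``, ``entropic_two_basin_2d``,
        ``modified_wolfe_quapp_2d``, ``custom_expression``.
    parameters : dict
        Name → value (lengths Å, energies internal units).  For
        ``custom_expression`` the key ``expression`` holds a sympy-parsable
        string in variables ``x`` (and ``y`` for 2-D).
    dimensionality : int
    box : tuple of (lo, hi) per dimension, Å
    temperature : float, K — used for every "in units of kT" report.
    """

    form: str
    parameters: dict = field(default_factory=dict)
    dimensionality: int = 1
    box: tuple = ()
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        if self.form not in _REQUIRED:
            raise ConfigurationError(f"unknown potential form {self.form!r}")
        for name in _REQUIRED[self.form]:
            if name not in self.parameters:
                raise ConfigurationError(
                    f"potential {self.form!r} is missing parameter {name!r}")
        want = _DIM[self.form]
        if want is not None and self.dimensionality != want:
            raise ConfigurationError(
                f"{self.form} is {want}-dimensional, got {self.dimensionality}")
        if not self.box:
            object.__setattr__(
                self, "box",
                tuple(_DEFAULT_BOX.get(self.form, [(-100.0, 100.0)])
                      [: self.dimensionality]
                      if _DIM[self.form] is None
                      else _DEFAULT_BOX[self.form]))
        if self.form == "custom_expression":
            object.__setattr__(self, "_custom", _compile_expression(
                self.parameters["expression"], self.dimensionality))

    @property
    def kbt(self) -> float:
        return kt(self.temperature)


def default_spec(form: str, temperature: float = DEFAULT_TEMPERATURE,
                 dimensionality: int | None = None) -> PotentialSpec:
    """Spec with the shipped calibrated default parameters for `form`."""
    if form not in _DEFAULTS:
        raise ConfigurationError(f"no default parameters for form {form!r}")
    dim = _DIM[form] if _DIM[form] is not None else (dimensionality or 1)
    return PotentialSpec(form=form, parameters=_DEFAULTS[form](temperature),
                         dimensionality=dim, temperature=temperature)


def _compile_expression(expression: str, dim: int):
    import sympy

    symbols = sympy.symbols("x y z"[: 2 * dim - 1].split())
    expr = sympy.sympify(expression)
    extra = expr.free_symbols - set(symbols)
    if extra:
        raise ConfigurationError(
            f"custom expression uses unknown symbols {sorted(map(str, extra))}")
    grads = [sympy.diff(expr, s) for s in symbols]
    f_u = sympy.lambdify(symbols, expr, "numpy")
    f_g = [sympy.lambdify(symbols, g, "numpy") for g in grads]
    return f_u, f_g


# ---------------------------------------------------------------------------
# Energy and force (vectorized: positions with shape (..., dim))
# ---------------------------------------------------------------------------

def _kappa_log_switch(x, k_stiff, k_soft, w):
    s = 0.5 * (1.0 + np.tanh(x / w))
    return np.exp(np.log(k_stiff) + s * (np.log(k_soft) - np.log(k_stiff)))


def _canonical(spec: PotentialSpec, position):
    """Coerce `position` to shape (..., dim).

    Accepts a scalar (1-D only), an array of shape (...,) for 1-D potentials,
    or an array with trailing axis of length `dim`.  Returns the canonical
    array plus the shape the caller's energy output should take.
    """
    x = np.asarray(position, dtype=float)
    dim = spec.dimensionality
    if dim == 1:
        if x.ndim and x.shape[-1] == 1:
            return x, x.shape[:-1]
        return x[..., None], x.shape
    if x.ndim == 0 or x.shape[-1] != dim:
        raise ConfigurationError(
            f"position has trailing dimension "
            f"{x.shape[-1] if x.ndim else 1}, potential expects {dim}")
    return x, x.shape[:-1]


def potential_energy(spec: PotentialSpec, position) -> np.ndarray | float:
    """Potential energy (internal units) at `position` (Å).

    `position` is a length-``dim`` vector or an array of shape ``(..., dim)``;
    for 1-D potentials a bare scalar/array is also accepted.
    """
    x, out_shape = _canonical(spec, position)
    p = spec.parameters
    if spec.form == "harmonic":
        u = 0.5 * p["k"] * np.sum(x**2, axis=-1)
    elif spec.form == "double_well_1d":
        xi = x[..., 0]
        u = (0.5 * p["k"] * xi**2
             + p["A"] * np.exp(-xi**2 / (2.0 * p["sigma"] ** 2)))
    elif spec.form == "entropic_two_basin_2d":
        xc, yc = x[..., 0], x[..., 1]
        kap = _kappa_log_switch(xc, p["k_stiff"], p["k_soft"], p["w"])
        u = p["a"] * (xc**2 - p["x_m"] ** 2) ** 2 + 0.5 * kap * yc**2
    elif spec.form == "modified_wolfe_quapp_2d":
        xc, yc = x[..., 0], x[..., 1]
        vx = p["hx"] * ((xc / p["sx"]) ** 2 - 1.0) ** 2
        vy = p["b0"] * ((yc / p["ym"]) ** 2 - 1.0) ** 2
        s = 0.5 * (1.0 - np.tanh((yc - p["ysw"]) / p["wy"]))
        ridge = (p["delta"] * 0.5 * (1.0 + np.tanh(xc / p["wx"]))
                 * np.exp(-yc**2 / (2.0 * p["sr"] ** 2)))
        u = vy + s * vx + (1.0 - s) * 0.5 * p["ku"] * xc**2 + ridge
    elif spec.form == "custom_expression":
        f_u, _ = spec._custom
        coords = [x[..., i] for i in range(spec.dimensionality)]
        u = np.broadcast_to(np.asarray(f_u(*coords), dtype=float),
                            x.shape[:-1]).astype(float)
    else:  # pragma: no cover
        raise ConfigurationError(f"unknown potential form {spec.form!r}")
    if not np.all(np.isfinite(u)):
        raise ConfigurationError(f"non-finite energy for {spec.form}")
    u = np.asarray(u, dtype=float).reshape(out_shape)
    return float(u) if u.ndim == 0 else u


def potential_force(spec: PotentialSpec, position) -> np.ndarray:
    """Force −∇U (internal units / Å), analytic.

    Output has the canonical shape ``(..., dim)`` except that for 1-D
    potentials called with a bare scalar/array the trailing axis is dropped,
    mirroring the input.
    """
    x, out_shape = _canonical(spec, position)
    p = spec.parameters
    if spec.form == "harmonic":
        f = -p["k"] * x
    elif spec.form == "double_well_1d":
        xi = x[..., 0]
        g = (p["k"] * xi
             - p["A"] * xi / p["sigma"] ** 2
             * np.exp(-xi**2 / (2.0 * p["sigma"] ** 2)))
        f = (-g)[..., None]
    elif spec.form == "entropic_two_basin_2d":
        xc, yc = x[..., 0], x[..., 1]
        kap = _kappa_log_switch(xc, p["k_stiff"], p["k_soft"], p["w"])
        dlnk = ((np.log(p["k_soft"]) - np.log(p["k_stiff"]))
                / (2.0 * p["w"]) / np.cosh(xc / p["w"]) ** 2)
        gx = (4.0 * p["a"] * xc * (xc**2 - p["x_m"] ** 2)
              + 0.5 * kap * dlnk * yc**2)
        gy = kap * yc
        f = -np.stack([gx, gy], axis=-1)
    elif spec.form == "modified_wolfe_quapp_2d":
        xc, yc = x[..., 0], x[..., 1]
        vx = p["hx"] * ((xc / p["sx"]) ** 2 - 1.0) ** 2
        dvx = 4.0 * p["hx"] * xc / p["sx"] ** 2 * ((xc / p["sx"]) ** 2 - 1.0)
        dvy = 4.0 * p["b0"] * yc / p["ym"] ** 2 * ((yc / p["ym"]) ** 2 - 1.0)
        s = 0.5 * (1.0 - np.tanh((yc - p["ysw"]) / p["wy"]))
        ds = -0.5 / p["wy"] / np.cosh((yc - p["ysw"]) / p["wy"]) ** 2
        harm = 0.5 * p["ku"] * xc**2
        gauss = np.exp(-yc**2 / (2.0 * p["sr"] ** 2))
        sx = 0.5 * (1.0 + np.tanh(xc / p["wx"]))
        dsx = 0.5 / p["wx"] / np.cosh(xc / p["wx"]) ** 2
        gx = s * dvx + (1.0 - s) * p["ku"] * xc + p["delta"] * dsx * gauss
        gy = (dvy + ds * vx - ds * harm
              + p["delta"] * sx * gauss * (-yc / p["sr"] ** 2))
        f = -np.stack([gx, gy], axis=-1)
    elif spec.form == "custom_expression":
        _, f_g = spec._custom
        coords = [x[..., i] for i in range(spec.dimensionality)]
        comps = [np.broadcast_to(np.asarray(g(*coords), dtype=float),
                                 x.shape[:-1]).astype(float)
                 for g in f_g]
        f = -np.stack(comps, axis=-1)
    else:  # pragma: no cover
        raise ConfigurationError(f"unknown potential form {spec.form!r}")
    f = np.asarray(f, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ConfigurationError(f"non-finite force for {spec.form}")
    if spec.dimensionality == 1 and out_shape == np.asarray(position).shape:
        return f.reshape(out_shape)
    return f


def _as_points(spec, position):
    """Position (scalar/vector) → shape (dim,) array."""
    a = np.atleast_1d(np.asarray(position, dtype=float))
    if a.shape != (spec.dimensionality,):
        raise ConfigurationError(
            f"expected a {spec.dimensionality}-vector, got shape {a.shape}")
    return a


# ---------------------------------------------------------------------------
# Stationary points and barriers
# ---------------------------------------------------------------------------

def find_minima(spec: PotentialSpec, initial_guesses: Sequence,
                grad_tol: float = 1e-6, merge_tol: float = 1e-3,
                max_iter: int = 500) -> list[np.ndarray]:
    """Locally minimize U from each guess; merge duplicates within 1 mÅ.

    Returned points have gradient norm < `grad_tol` (internal force units).
    """
    found: list[np.ndarray] = []
    for guess in initial_guesses:
        x0 = _as_points(spec, guess)
        res = optimize.minimize(
            lambda v: potential_energy(spec, v),
            x0,
            jac=lambda v: -potential_force(spec, v),
            method="L-BFGS-B",
            options={"maxiter": max_iter, "gtol": 1e-12, "ftol": 1e-15},
        )
        point = np.asarray(res.x, dtype=float)
        g = np.linalg.norm(potential_force(spec, point))
        if g >= 0.1 * grad_tol:
            # Newton polish on the gradient root (finite-difference Jacobian)
            sol = optimize.root(
                lambda v: -np.atleast_1d(potential_force(spec, v)),
                point, method="hybr")
            if np.linalg.norm(potential_force(spec, sol.x)) < g:
                point = np.asarray(sol.x, dtype=float)
                res = optimize.OptimizeResult(x=point)
            g = np.linalg.norm(potential_force(spec, point))
        if g >= grad_tol:
            raise RuntimeError(
                f"minimization from {x0} did not converge "
                f"(|grad| = {g:.2e} after {max_iter} iterations)")
        point = np.asarray(res.x, dtype=float)
        if not any(np.linalg.norm(point - q) < merge_tol for q in found):
            found.append(point)
    return found


def barrier_height(spec: PotentialSpec, min_a, min_b,
                   temperature: float | None = None,
                   grid_points: int = 601) -> tuple[float, bool]:
    """Barrier between two minima, in units of k_B·T.

    1-D: maximum of U on the segment between the minima minus U(min_a).
    2-D: minimax energy over paths between the basins, found by a dense-grid
    sublevel-set connectivity bisection (the lowest energy level at which the
    two minima lie in one connected component).

    Returns ``(barrier_kt, warn_flag)``; the flag is set (and the barrier is
    0) when no interior maximum separates the minima.
    """
    T = temperature if temperature is not None else spec.temperature
    a = _as_points(spec, min_a)
    b = _as_points(spec, min_b)
    u_ref = potential_energy(spec, a)
    if spec.dimensionality == 1:
        xs = np.linspace(a[0], b[0], grid_points)
        us = potential_energy(spec, xs[:, None])
        peak = float(np.max(us))
        interior = float(np.max(us[1:-1])) if grid_points > 2 else peak
        if interior <= max(us[0], us[-1]) + 1e-12:
            return 0.0, True
        return (peak - u_ref) / kt(T), False
    peak = _minimax_level_2d(spec, a, b)
    if peak - u_ref <= 1e-9:
        return 0.0, True
    return (peak - u_ref) / kt(T), False


def _minimax_level_2d(spec, a, b, n_max: int = 601) -> float:
    """Lowest energy level connecting a and b (grid + bisection on level)."""
    (x_lo, x_hi), (y_lo, y_hi) = spec.box
    # margin around the minima keeps the grid focused; box bounds cap it
    pad = 1.2
    x0 = min(a[0], b[0]) - pad * abs(a[0] - b[0]) - 2.0
    x1 = max(a[0], b[0]) + pad * abs(a[0] - b[0]) + 2.0
    y0 = min(a[1], b[1]) - pad * abs(a[1] - b[1]) - 2.0
    y1 = max(a[1], b[1]) + pad * abs(a[1] - b[1]) + 2.0
    x0, x1 = max(x0, x_lo), min(x1, x_hi)
    y0, y1 = max(y0, y_lo), min(y1, y_hi)
    nx = min(n_max, max(201, int((x1 - x0) / 0.05) + 1))
    ny = min(n_max, max(201, int((y1 - y0) / 0.05) + 1))
    xs = np.linspace(x0, x1, nx)
    ys = np.linspace(y0, y1, ny)
    grid = np.stack(np.meshgrid(xs, ys, indexing="ij"), axis=-1)
    u = potential_energy(spec, grid)
    ia = (np.argmin(np.abs(xs - a[0])), np.argmin(np.abs(ys - a[1])))
    ib = (np.argmin(np.abs(xs - b[0])), np.argmin(np.abs(ys - b[1])))
    lo = max(u[ia], u[ib])
    hi = float(np.max(u))

    def connected(level):
        mask = u <= level
        labels, _ = ndimage.label(mask)
        return labels[ia] != 0 and labels[ia] == labels[ib]

    if connected(lo + 1e-12):
        return lo
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if connected(mid):
            hi = mid
        else:
            lo = mid
    return hi


def slice_barrier(spec: PotentialSpec, start, end,
                  temperature: float | None = None,
                  grid_points: int = 2001) -> float:
    """Max of U along the straight segment start→end minus U(start), in kT.

    The direct (straight-path) escape barrier — distinct from the minimax
    barrier, which may detour through intermediate basins.
    """
    T = temperature if temperature is not None else spec.temperature
    a = _as_points(spec, start)
    b = _as_points(spec, end)
    ts = np.linspace(0.0, 1.0, grid_points)[:, None]
    pts = a[None, :] + ts * (b - a)[None, :]
    us = potential_energy(spec, pts)
    return float((np.max(us) - us[0]) / kt(T))


def basin_width(spec: PotentialSpec, minimum, axis: int,
                temperature: float | None = None, h: float = 1e-4) -> float:
    """Harmonic basin width σ = sqrt(kT / U″) along `axis` at a minimum."""
    T = temperature if temperature is not None else spec.temperature
    x = _as_points(spec, minimum)
    e = np.zeros_like(x)
    e[axis] = h
    upp = potential_energy(spec, x + e)
    umm = potential_energy(spec, x - e)
    u0 = potential_energy(spec, x)
    curv = (upp - 2.0 * u0 + umm) / h**2
    if curv <= 0:
        raise ValueError(f"non-positive curvature {curv:.3g} at {x}")
    return math.sqrt(kt(T) / curv)


# ---------------------------------------------------------------------------
# Constraint verification
# ---------------------------------------------------------------------------

@dataclass
class ConstraintCheck:
    kind: str
    target: float
    achieved: float
    tolerance: float
    passed: bool
    detail: str = ""


@dataclass
class StationaryPointReport:
    """Minima, saddle and barrier summary plus per-constraint pass/fail."""

    minima: list          # (position array, energy) pairs
    barrier_kt: float
    checks: list          # ConstraintCheck
    temperature: float

    @property
    def all_passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def __str__(self):
        lines = [f"T = {self.temperature:g} K"]
        for pos, en in self.minima:
            lines.append(
                f"  minimum at ({', '.join(f'{v:.4f}' for v in pos)}) Å, "
                f"U = {en:.4f}")
        lines.append(f"  reference barrier = {self.barrier_kt:.4f} kT")
        for c in self.checks:
            status = "PASS" if c.passed else "FAIL"
            lines.append(
                f"  [{status}] {c.kind} {c.detail}: target {c.target:g}, "
                f"achieved {c.achieved:.4g} (tol {c.tolerance:g})")
        return "\n".join(lines)


def verify_constraints(spec: PotentialSpec, constraints: Sequence) -> StationaryPointReport:
    """Check printed stationary-point facts against the surface.

    Each constraint is ``(kind, value, tolerance, *args)`` with kinds:

    - ``("min_location", x_target, tol, guess)`` — a minimum exists within
      `tol` Å of `x_target` (scalar or vector), refined from `guess`.
    - ``("barrier_kt", value, rel_tol, min_a_guess, min_b_guess)`` — minimax
      barrier between the two minima, kT units.
    - ``("slice_barrier_kt", value, rel_tol, start_guess, end)`` — direct
      straight-path barrier from the minimum near `start_guess` toward `end`.
    - ``("basin_width", value, rel_tol, min_guess, axis)`` — curvature width.
    - ``("width_ratio", value, rel_tol, min_a_guess, min_b_guess, axis)``.
    - ``("min_separation", value, rel_tol, min_a_guess, min_b_guess)``.

    Failures are reported, never raised.
    """
    checks: list[ConstraintCheck] = []
    minima_cache: dict[tuple, np.ndarray] = {}

    def located(guess):
        key = tuple(np.atleast_1d(np.asarray(guess, float)))
        if key not in minima_cache:
            minima_cache[key] = find_minima(spec, [guess])[0]
        return minima_cache[key]

    barrier_ref = 0.0
    for con in constraints:
        kind, value, tol, *args = con
        try:
            if kind == "min_location":
                m = located(args[0] if args else value)
                achieved = float(np.linalg.norm(
                    m - np.atleast_1d(np.asarray(value, float))))
                ok = achieved <= tol
                checks.append(ConstraintCheck(kind, 0.0, achieved, tol, ok,
                                              detail=f"target {value}"))
                continue
            if kind == "barrier_kt":
                m_a, m_b = located(args[0]), located(args[1])
                achieved, warn = barrier_height(spec, m_a, m_b)
                barrier_ref = max(barrier_ref, achieved)
                ok = (not warn) and abs(achieved - value) <= tol * value
            elif kind == "slice_barrier_kt":
                m_a = located(args[0])
                achieved = slice_barrier(spec, m_a, args[1])
                ok = abs(achieved - value) <= tol * value
            elif kind == "basin_width":
                m = located(args[0])
                achieved = basin_width(spec, m, args[1])
                ok = abs(achieved - value) <= tol * value
            elif kind == "width_ratio":
                m_a, m_b = located(args[0]), located(args[1])
                achieved = (basin_width(spec, m_a, args[2])
                            / basin_width(spec, m_b, args[2]))
                ok = abs(achieved - value) <= tol * value
            elif kind == "min_separation":
                m_a, m_b = located(args[0]), located(args[1])
                achieved = float(np.linalg.norm(m_a - m_b))
                ok = abs(achieved - value) <= tol * value
            else:
                checks.append(ConstraintCheck(kind, value, math.nan, tol,
                                              False, detail="unknown kind"))
                continue
        except Exception as exc:  # failures reported, not raised
            checks.append(ConstraintCheck(kind, value, math.nan, tol, False,
                                          detail=f"error: {exc}"))
            continue
        checks.append(ConstraintCheck(kind, value, achieved, tol, ok))

    minima = [(m, potential_energy(spec, m)) for m in minima_cache.values()]
    return StationaryPointReport(minima=minima, barrier_kt=barrier_ref,
                                 checks=checks, temperature=spec.temperature)


def default_constraints(form: str) -> list:
    """The printed stationary-point facts each shipped default must satisfy."""
    if form == "double_well_1d":
        return [
            ("min_location", 3.0, 0.1, 2.5),
            ("min_location", -3.0, 0.1, -2.5),
            ("barrier_kt", 1.0, 0.05, 2.5, -2.5),
        ]
    if form == "entropic_two_basin_2d":
        return [
            ("min_location", (1.3, 0.0), 0.1, (1.0, 0.0)),
            ("min_location", (-1.3, 0.0), 0.1, (-1.0, 0.0)),
            ("barrier_kt", 3.0, 0.05, (1.0, 0.0), (-1.0, 0.0)),
            ("basin_width", 50.0, 0.05, (1.0, 0.0), 1),
            ("basin_width", 0.5, 0.05, (-1.0, 0.0), 1),
            ("width_ratio", 100.0, 0.05, (1.0, 0.0), (-1.0, 0.0), 1),
        ]
    if form == "modified_wolfe_quapp_2d":
        return [
            ("min_separation", 30.0, 0.05, (-15.0, -1.4), (15.0, -1.4)),
            ("barrier_kt", 1.5, 0.07, (-15.0, -1.4), (15.0, -1.4)),
            ("barrier_kt", 6.25, 0.07, (-15.0, -1.4), (0.0, 1.4)),
            ("slice_barrier_kt", 10.0, 0.07, (15.0, -1.4), (15.0, 1.4)),
        ]
    raise ConfigurationError(f"no shipped constraints for form {form!r}")
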