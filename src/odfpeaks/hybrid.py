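"""Derandomized PSO + modified Powell hybrid search for ODF local maxima.

The global stage is a particle swarm whose velocity update keeps only the
inertia and cognitive terms, with no random factors and a zero social
coefficient:

    V' = omega(k) V + c1 (P_id - X),      X' = X + V',

so each particle deterministically contracts onto the best point of its own
trajectory.  When the swarm's mean personal-best improvement drops below the
transfer threshold ``P``, a modified Powell direction-set search is started
from every particle's personal best; converged extrema are merged into an
extreme set with antipodal deduplication.  The swarm is then reinitialized
(fresh seeded draw) and the cycle repeats up to ``m_rounds`` times.  Peaks
below the spherical mean of the ODF or below the normalized threshold ``P``
are discarded at the end.

The search space is the (azimuth, elevation) plane; positions crossing a pole
are reflected.  All randomness is confined to swarm (re)initialization, so
the whole pipeline is a pure function of (objective, params, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .phantom import PhantomConfig, analytic_odf_func
from .recon import SHCoefficients, evaluate_sh
from .sphere import (
    SphereMesh,
    SphericalSamples,
    arc_angle,
    interpolate,
    normalize_angles,
    sph_to_unit,
)

__all__ = [
    "DegenerateObjectiveError",
    "HybridParams",
    "Objective",
    "objective_from",
    "Swarm",
    "inertia",
    "pso_step",
    "pso_run",
    "line_search",
    "powell_search",
    "Peak",
    "PeakSet",
    "canonical_direction",
    "hybrid_find_peaks",
    "filter_peaks",
]


class DegenerateObjectiveError(ValueError):
    """The spherical function is (numerically) constant: no peaks exist."""


@dataclass(frozen=True)
class HybridParams:
    """All constants of the hybrid search.

    Defaults are the reference parameter set: swarm of 100 particles, inertia
    decaying linearly from 0.2 to 0.1, cognitive factor c1 = 0.5, social
    factor c2 = 0, at most 120 PSO iterations per round, transfer/peak
    threshold P = 0.02 (normalized ODF units), at most 20 hybrid rounds.
    """

    n_particles: int = 100
    t_max: int = 120
    m_rounds: int = 20
    epsilon: float = 1e-5          # Powell step tolerance, rad
    transfer_tol: float = 0.02     # P: PSO->Powell transfer and peak threshold
    c1: float = 0.5
    c2: float = 0.0
    omega_max: float = 0.2
    omega_min: float = 0.1
    merge_angle: float = 10.0      # antipodal dedup threshold, degrees
    seed: int = 0
    v0: float = 0.3                # initial velocity half-range, rad/iteration
    early_exit_rounds: int = 3     # stop after this many rounds with no new extremum; 0 = strict
    direction_update: str = "modified"  # Powell retention test: "modified" or "classical"
    line_xtol: float = 1e-6        # line-search refinement tolerance, rad
    max_cycles: int = 100          # Powell cycle cap

    def __post_init__(self):
        if self.omega_min > self.omega_max:
            raise ValueError("omega_min must not exceed omega_max")
        if self.c2 != 0.0:
            raise ValueError("the derandomized update uses c2 = 0")
        for name in ("n_particles", "t_max", "m_rounds", "epsilon",
                     "transfer_tol", "c1", "omega_max", "omega_min",
                     "merge_angle", "line_xtol", "max_cycles"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.direction_update not in ("modified", "classical"):
            raise ValueError("direction_update must be 'modified' or 'classical'")


class Objective:
    """A continuous, min-max-normalized scalar function on the sphere.

    ``func`` maps an ``(..., 2)`` array of (azimuth, elevation) pairs to
    normalized values (0 at the mesh minimum, 1 at the mesh maximum).
    ``samples`` holds the raw (unnormalized) values on the reference mesh,
    used by the mean-value peak filter.
    """

    def __init__(self, raw_func, mesh: SphereMesh, raw_values: np.ndarray,
                 mode: str):
        self.mesh = mesh
        self.mode = mode
        self.samples = SphericalSamples(mesh, raw_values)
        self.vmin = float(raw_values.min())
        self.vmax = float(raw_values.max())
        self.degenerate = (self.vmax - self.vmin) <= 1e-12 * max(1.0, abs(self.vmax))
        self._raw = raw_func

    def __call__(self, angles: np.ndarray) -> np.ndarray:
        angles = np.asarray(angles, dtype=float)
        u = sph_to_unit(angles[..., 0], angles[..., 1])
        raw = self._raw(u)
        if self.degenerate:
            return np.zeros_like(raw)
        return (raw - self.vmin) / (self.vmax - self.vmin)

    def raw_at(self, angles: np.ndarray) -> np.ndarray:
        """Unnormalized value(s) of the underlying spherical function."""
        angles = np.asarray(angles, dtype=float)
        return self._raw(sph_to_unit(angles[..., 0], angles[..., 1]))


def objective_from(source, mode: str | None = None, mesh: SphereMesh | None = None,
                   strict: bool = True) -> Objective:
    """Adapt an ODF representation into a continuous optimizer objective.

    ``source`` may be :class:`~odfpeaks.sphere.SphericalSamples` (modes
    ``nearest`` / ``barycentric``), :class:`~odfpeaks.recon.SHCoefficients`
    (mode ``sh``) or :class:`~odfpeaks.phantom.PhantomConfig` (mode
    ``analytic``).  SH and analytic modes need a reference ``mesh`` for
    normalization; defaults to the samples' mesh where available.

    Nearest-neighbor interpolation makes the objective piecewise constant
    (line searches then snap to sample directions); the continuous ``sh`` and
    ``analytic`` modes, or ``barycentric``, are preferred defaults.
    """
    if isinstance(source, SphericalSamples):
        mode = mode or "barycentric"
        if mode not in ("nearest", "barycentric"):
            raise ValueError("sample objectives support 'nearest' or 'barycentric'")
        mesh = source.mesh
        samples = source

        def raw(u, _s=samples, _m=mode):
            u = np.asarray(u, dtype=float)
            flat = u.reshape(-1, 3)
            vals = np.array([interpolate(_s, q, mode=_m) for q in flat])
            return vals.reshape(u.shape[:-1])

        values = source.values
    elif isinstance(source, SHCoefficients):
        mode = "sh"
        if mesh is None:
            raise ValueError("sh objectives need a reference mesh")

        def raw(u, _c=source):
            u = np.asarray(u, dtype=float)
            flat = u.reshape(-1, 3)
            return evaluate_sh(_c, flat).reshape(u.shape[:-1])

        values = raw(mesh.vertices)
    elif isinstance(source, PhantomConfig):
        mode = "analytic"
        if mesh is None:
            raise ValueError("analytic objectives need a reference mesh")
        raw = analytic_odf_func(source)
        values = raw(mesh.vertices)
    else:
        raise TypeError(f"cannot build an objective from {type(source).__name__}")

    obj = Objective(raw, mesh, np.asarray(values, dtype=float), mode)
    if strict and obj.degenerate:
        raise DegenerateObjectiveError("all samples are (numerically) equal")
    return obj


def inertia(k: int, params: HybridParams) -> float:
    """Linearly decaying inertia weight: omega_max at k=0 down to omega_min at t_max."""
    frac = min(max(k / params.t_max, 0.0), 1.0)
    return params.omega_max - (params.omega_max - params.omega_min) * frac


@dataclass
class Swarm:
    """Particle state: positions/velocities in (azimuth, elevation) space."""

    positions: np.ndarray      # (N, 2)
    velocities: np.ndarray     # (N, 2)
    pbest_positions: np.ndarray
    pbest_fitness: np.ndarray  # (N,)
    k: int = 0

    @property
    def gbest_index(self) -> int:
        return int(np.argmax(self.pbest_fitness))

    @property
    def gbest_position(self) -> np.ndarray:
        return self.pbest_positions[self.gbest_index]

    @property
    def gbest_fitness(self) -> float:
        return float(self.pbest_fitness[self.gbest_index])

    def copy(self) -> "Swarm":
        return Swarm(self.positions.copy(), self.velocities.copy(),
                     self.pbest_positions.copy(), self.pbest_fitness.copy(), self.k)


def _init_swarm(objective: Objective, params: HybridParams,
                rng: np.random.Generator) -> Swarm:
    """Area-uniform positions on the sphere, small uniform random velocities."""
    n = params.n_particles
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    phi = np.arcsin(rng.uniform(-1.0, 1.0, n))
    pos = np.column_stack([theta, phi])
    vel = rng.uniform(-params.v0, params.v0, (n, 2))
    fit = objective(pos)
    return Swarm(pos, vel, pos.copy(), np.asarray(fit, dtype=float))


def pso_step(swarm: Swarm, objective: Objective, params: HybridParams) -> float:
    """One deterministic velocity/position update; returns the mean personal-best gain.

    The update has no random factors: V' = omega(k) V + c1 (P_id - X),
    X' = X + V'.  Positions are wrapped back into the angular domain and
    personal bests updated in place.
    """
    w = inertia(swarm.k, params)
    swarm.velocities = w * swarm.velocities + params.c1 * (
        swarm.pbest_positions - swarm.positions
    )
    pos = swarm.positions + swarm.velocities
    theta, phi = normalize_angles(pos[:, 0], pos[:, 1])
    swarm.positions = np.column_stack([theta, phi])
    fit = np.asarray(objective(swarm.positions), dtype=float)
    improved = fit > swarm.pbest_fitness
    gain = float(np.mean(np.maximum(fit - swarm.pbest_fitness, 0.0)))
    swarm.pbest_positions[improved] = swarm.positions[improved]
    swarm.pbest_fitness[improved] = fit[improved]
    swarm.k += 1
    return gain


def pso_run(objective: Objective, params: HybridParams,
            rng: np.random.Generator | int | None = None):
    """Run the PSO stage until t_max iterations or the transfer tolerance fires.

    Tolerance_PSO after iteration k is the swarm-mean improvement of the
    personal-best fitness during that iteration; the stage ends once it drops
    below ``params.transfer_tol``.  Returns ``(swarm, tolerance_trace)``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(params.seed if rng is None else rng)
    swarm = _init_swarm(objective, params, rng)
    trace = []
    for _ in range(params.t_max):
        gain = pso_step(swarm, objective, params)
        trace.append(gain)
        if gain < params.transfer_tol:
            break
    return swarm, np.array(trace)


_LADDER = 0.05 * 2.0 ** np.arange(8)  # geometric bracketing steps, rad


def _line_max(f, x: np.ndarray, d: np.ndarray, xtol: float, f0=None):
    """Local 1-D maximization of t -> f(x + t d/|d|) over t in [-pi, pi].

    Outward geometric bracketing from t = 0 (stopping at the first decrease,
    so the search stays inside the current local basin — essential for
    multimodal peak extraction) followed by bounded parabolic/golden
    refinement to ``xtol``.  Ties are broken toward t = 0 (a constant
    objective yields alpha = 0).  Returns (alpha, x_new, value).
    """
    nd = np.linalg.norm(d)
    if nd == 0:
        raise ValueError("line-search direction must be nonzero")
    dn = d / nd
    if f0 is None:
        f0 = float(f(x))
    if not np.isfinite(f0):
        raise ValueError("non-finite objective value in line search")
    best_t, best_f = 0.0, f0
    lo, hi = -_LADDER[0], _LADDER[0]
    for sign in (1.0, -1.0):
        ts = np.clip(sign * _LADDER, -np.pi, np.pi)
        vals = np.asarray(f(x[None, :] + ts[:, None] * dn[None, :]), dtype=float)
        prev = f0
        for j, (t, v) in enumerate(zip(ts, vals)):
            if not np.isfinite(v):
                raise ValueError("non-finite objective value in line search")
            if v > best_f:
                best_t, best_f = float(t), float(v)
                lo = float(ts[j - 1]) if j > 0 else -sign * _LADDER[0]
                hi = float(ts[j + 1]) if j + 1 < len(ts) else t
                if sign < 0:
                    lo, hi = hi, lo
            if v < prev:  # left the current basin: stop walking outward
                break
            prev = v
            if abs(t) >= np.pi:
                break
    lo, hi = max(min(lo, hi), -np.pi), min(max(lo, hi), np.pi)
    if hi > lo + xtol:
        res = minimize_scalar(
            lambda t: -float(f(x + t * dn)),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": xtol},
        )
        if np.isfinite(res.fun) and -res.fun > best_f:
            best_t, best_f = float(res.x), float(-res.fun)
    if best_f <= f0:
        return 0.0, x, f0
    return best_t, x + best_t * dn, best_f


def line_search(f, x, d, xtol: float = 1e-6):
    """Derivative-free maximization of f along direction d from x.

    Returns ``(alpha, x_new)`` with ``x_new = x + alpha * d/|d|`` and alpha
    in [-pi, pi].
    """
    alpha, x_new, _ = _line_max(f, np.asarray(x, dtype=float),
                                np.asarray(d, dtype=float), xtol)
    return alpha, x_new


def powell_search(f, x0, epsilon: float = 1e-5, *, max_cycles: int = 100,
                  xtol: float = 1e-6, direction_update: str = "modified",
                  return_trace: bool = False):
    """Modified Powell direction-set maximization in the (azimuth, elevation) plane.

    Each cycle line-searches sequentially along the current direction set
    (initialized to the coordinate axes), then tests the composite step
    ``d_D = x_D - x_0``: below ``epsilon`` it terminates; otherwise a further
    line search along ``d_D`` is taken and the direction-retention inequality
    decides whether the set is kept or the max-drop direction is replaced by
    ``d_D``.  ``direction_update='modified'`` applies the modified-scheme retention
    inequality (on the negated objective, since the direction-set formulas
    minimize); ``'classical'`` uses the standard Numerical-Recipes criterion.
    Returns ``(x_star, f_star)``, or ``(x_star, f_star, trace)`` with the
    per-cycle start values when ``return_trace`` is set; the value at the
    cycle start never decreases.
    """
    ndim = 2
    dirs = [np.array([1.0, 0.0]), np.array([0.0, 1.0])]
    x = np.asarray(x0, dtype=float).copy()
    fx = float(f(x))
    if not np.isfinite(fx):
        raise ValueError("non-finite objective at the Powell start")
    trace = [fx]
    for _ in range(max_cycles):
        xs = [x]
        fs = [fx]
        for i in range(ndim):
            _, xn, fn = _line_max(f, xs[-1], dirs[i], xtol, f0=fs[-1])
            xs.append(xn)
            fs.append(fn)
        d_comp = xs[ndim] - xs[0]
        if np.linalg.norm(d_comp) <= epsilon:
            if return_trace:
                return xs[ndim], fs[ndim], trace + [fs[ndim]]
            return xs[ndim], fs[ndim]
        _, x_next, f_next = _line_max(f, xs[ndim], d_comp, xtol, f0=fs[ndim])
        gains = [fs[i + 1] - fs[i] for i in range(ndim)]  # drops of -f
        tl = int(np.argmax(gains))
        f_ext = float(f(2.0 * xs[ndim] - xs[0]))
        if direction_update == "modified":
            # modified-scheme retention inequality on F = -f:
            # F(x0) - 2 F(xD) + F(2 xD - x0) >= 2 (F(x_tl) - F(x_tl+1))
            keep = (-fs[0] + 2.0 * fs[ndim] - f_ext) >= 2.0 * gains[tl]
        else:
            big_f0, big_fn, big_fe = -fs[0], -fs[ndim], -f_ext
            delta = gains[tl]
            keep = (big_fe >= big_f0) or (
                2.0 * (big_f0 - 2.0 * big_fn + big_fe)
                * (big_f0 - big_fn - delta) ** 2
                >= delta * (big_f0 - big_fe) ** 2
            )
        if not keep:
            dirs.pop(tl)
            dirs.append(d_comp / np.linalg.norm(d_comp))
        x, fx = x_next, f_next
        trace.append(fx)
    if return_trace:
        return x, fx, trace
    return x, fx


@dataclass(frozen=True)
class Peak:
    """One extracted ODF maximum on the canonical hemisphere."""

    direction: np.ndarray
    odf_value: float
    normalized_value: float


@dataclass(frozen=True)
class PeakSet:
    """Extracted maxima, sorted by descending ODF value, pairwise separated."""

    peaks: tuple
    merge_angle: float = 10.0

    def __post_init__(self):
        peaks = tuple(
            sorted(self.peaks, key=lambda p: -p.odf_value)
        )
        for i in range(len(peaks)):
            for j in range(i + 1, len(peaks)):
                sep = arc_angle(peaks[i].direction, peaks[j].direction, antipodal=True)
                if sep < self.merge_angle - 1e-9:
                    raise ValueError("peaks closer than the merge angle")
        object.__setattr__(self, "peaks", peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def directions(self) -> np.ndarray:
        if not self.peaks:
            return np.zeros((0, 3))
        return np.array([p.direction for p in self.peaks])


def canonical_direction(v: np.ndarray) -> np.ndarray:
    """Map a unit vector to the canonical hemisphere.

    Keep v if v_z > 0; on the equator (v_z = 0) keep v_y > 0; on the
    equatorial x-axis keep +x.
    """
    v = np.asarray(v, dtype=float)
    if v[2] < 0 or (v[2] == 0 and (v[1] < 0 or (v[1] == 0 and v[0] < 0))):
        return -v
    return v


def _is_local_max(objective: Objective, x: np.ndarray, value: float,
                  delta_deg: float = 0.5, n_probe: int = 8) -> bool:
    """Cheap verification that x is a spherical local maximum (not a saddle)."""
    u = sph_to_unit(x[0], x[1])
    helper = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    t1 = np.cross(u, helper)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(u, t1)
    gamma = 2.0 * np.pi * np.arange(n_probe) / n_probe
    delta = np.radians(delta_deg)
    probes = (
        np.cos(delta) * u[None, :]
        + np.sin(delta) * (np.cos(gamma)[:, None] * t1 + np.sin(gamma)[:, None] * t2)
    )
    theta = np.mod(np.arctan2(probes[:, 1], probes[:, 0]), 2 * np.pi)
    phi = np.arcsin(np.clip(probes[:, 2], -1, 1))
    vals = objective(np.column_stack([theta, phi]))
    return bool(np.all(vals <= value + 1e-9))


def _merge_extremum(extremes: list, u: np.ndarray, value: float,
                    merge_angle: float) -> bool:
    """Merge (u, value) into the extreme set; returns True if a new entry was added."""
    for idx, (eu, ev) in enumerate(extremes):
        if arc_angle(u, eu, antipodal=True) < merge_angle:
            if value > ev:
                extremes[idx] = (u, value)
            return False
    extremes.append((u, value))
    return True


def hybrid_find_peaks(objective: Objective, params: HybridParams | None = None) -> PeakSet:
    """Full hybrid search: repeated PSO rounds, Powell refinement, dedup, filtering.

    Runs up to ``m_rounds`` rounds.  Each round draws a fresh seeded swarm,
    runs the PSO stage to its transfer condition, then Powell-refines every
    particle's personal best; verified local maxima enter the extreme set
    (antipodal dedup at ``merge_angle`` degrees, higher value wins).  Rounds
    stop early once ``early_exit_rounds`` consecutive rounds add nothing new
    (set to 0 to force all ``m_rounds``).  Finally peaks below the spherical
    mean of the ODF or below the normalized threshold ``P`` are discarded.
    """
    params = params or HybridParams()
    if objective.degenerate:
        warnings.warn("degenerate (constant) objective: returning no peaks")
        return PeakSet((), params.merge_angle)
    seed_seq = np.random.SeedSequence(params.seed)
    extremes: list = []
    rounds_without_new = 0
    for _ in range(params.m_rounds):
        rng = np.random.default_rng(seed_seq.spawn(1)[0])
        swarm, _trace = pso_run(objective, params, rng)
        added_any = False
        for start in swarm.pbest_positions:
            x, fx = powell_search(
                objective, start, params.epsilon,
                max_cycles=params.max_cycles, xtol=params.line_xtol,
                direction_update=params.direction_update,
            )
            if not np.isfinite(fx):
                continue
            if not _is_local_max(objective, x, fx):
                continue
            u = canonical_direction(sph_to_unit(x[0], x[1]))
            if _merge_extremum(extremes, u, float(fx), params.merge_angle):
                added_any = True
        if params.early_exit_rounds > 0:
            rounds_without_new = 0 if added_any else rounds_without_new + 1
            if rounds_without_new >= params.early_exit_rounds:
                break
    span = objective.vmax - objective.vmin
    peaks = tuple(
        Peak(u, objective.vmin + val * span, val) for u, val in extremes
    )
    candidate = PeakSet(peaks, params.merge_angle)
    return filter_peaks(candidate, objective.samples, params.transfer_tol)


def filter_peaks(candidates: PeakSet, samples: SphericalSamples,
                 p_threshold: float = 0.02) -> PeakSet:
    """Discard peaks below the spherical mean or below the normalized threshold.

    A peak survives only if its raw ODF value is at least the mean of the
    mesh samples and its normalized value is at least ``p_threshold``; order
    is preserved.
    """
    mean_val = float(samples.values.mean())
    kept = tuple(
        p for p in candidates.peaks
        if p.odf_value >= mean_val and p.normalized_value >= p_threshold
    )
    return PeakSet(kept, candidates.merge_angle)
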