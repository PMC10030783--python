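"""Two-variable FitzHugh-Nagumo dynamics on the conductive subset of a grid.

The model integrated here is

    du/dt = c1 * u * (u - a) * (1 - u) - c2 * u * v + I + D_u * lap(u)
    dv/dt = b * (u - v)

with explicit Euler stepping (synchronous update from the pre-step fields)
and a five-node Laplacian restricted to conductive nodes.  No-flux
boundaries are realised by mirroring the centre value into any neighbour
that is off-grid or non-conductive.  ``u`` is the trans-membrane potential,
``v`` the slow recovery current; the cubic term has stable fixed points at
``u = 0`` and ``u = 1`` and an excitation threshold at ``u = a``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .templates import ConductiveTemplate

__all__ = [
    "FHNParameters",
    "FieldState",
    "StimulusSpec",
    "SimulationResult",
    "IntegrationBlowUpError",
    "StimulusWarning",
    "masked_laplacian",
    "euler_step",
    "apply_stimulus",
    "disc_offsets",
    "simulate",
    "scan_excitability",
    "ExcitabilityResult",
]


class IntegrationBlowUpError(RuntimeError):
    """Raised when u or v becomes non-finite; carries the first bad iteration."""

    def __init__(self, iteration: int):
        self.iteration = iteration
        super().__init__(f"non-finite field values at iteration {iteration}")


class StimulusWarning(UserWarning):
    """Signals a stimulus disc that contained no conductive node."""


@dataclass(frozen=True)
class FHNParameters:
    """FHN constants and discretisation steps.

    ``c2`` scales the ``u*v`` recovery coupling and acts as the
    excitability dial; the nominal range is 0.015-0.05.  ``d_u`` is the
    diffusive conductance; see :meth:`calibrated` for the value that
    reproduces wave-front speeds of roughly 0.016 nodes per iteration on
    this grid spacing, the regime in which excitation spans insole-scale
    networks.
    """

    d_u: float = 1.0
    a: float = 0.13
    b: float = 0.013
    c1: float = 0.26
    c2: float = 0.05
    i_ext: float = 0.0
    dt: float = 0.015
    dx: float = 2.0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.dx <= 0:
            raise ValueError("dt and dx must be positive")
        if self.d_u < 0:
            raise ValueError("d_u must be non-negative")
        if not 0 < self.a < 1:
            raise ValueError("excitation threshold a must lie in (0, 1)")

    @classmethod
    def calibrated(cls, c2: float = 0.015, **kw) -> "FHNParameters":
        """Conductance calibrated so the Laplacian acts once per iteration.

        With ``d_u = 1/dt`` the per-step diffusion weight is
        ``d_u*dt/dx**2 = 0.25``, giving front speeds of ~0.016 nodes per
        iteration, the regime in which excitation spans a ~1000-node
        network within 50-60 K iterations.  The default ``c2 = 0.015`` is
        the endpoint of the nominal range observed to nucleate waves from
        the smallest stimuli (see docs/methods.md).
        """
        dt = kw.get("dt", 0.015)
        return cls(d_u=1.0 / dt, c2=c2, **kw)


@dataclass
class FieldState:
    """Per-node excitation ``u`` and recovery ``v`` fields plus a step counter."""

    u: np.ndarray
    v: np.ndarray
    t: int = 0

    @classmethod
    def rest(cls, template: ConductiveTemplate) -> "FieldState":
        return cls(np.zeros(template.shape), np.zeros(template.shape), 0)

    def copy(self) -> "FieldState":
        return FieldState(self.u.copy(), self.v.copy(), self.t)


@dataclass(frozen=True)
class StimulusSpec:
    """Localized perturbation: set ``u`` on conductive nodes within a disc.

    ``centres`` are ``(i, j)`` node coordinates (floats allowed); the disc
    contains integer nodes at Euclidean distance < ``radius`` from a
    centre.  The default radius 1.8 covers 9 nodes around an integer
    centre.  Applied at iteration ``at_iteration`` of a simulation.
    """

    centres: tuple
    radius: float = 1.8
    value: float = 1.0
    at_iteration: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "centres", tuple((float(i), float(j)) for i, j in self.centres))
        if self.radius <= 0:
            raise ValueError("stimulus radius must be positive")


def disc_offsets(radius: float) -> np.ndarray:
    """Integer offsets ``(di, dj)`` with ``di**2 + dj**2 < radius**2``."""
    r = int(np.ceil(radius))
    di, dj = np.mgrid[-r : r + 1, -r : r + 1]
    keep = di**2 + dj**2 < radius**2
    return np.stack([di[keep], dj[keep]], axis=1)


def _shifted(arr: np.ndarray, di: int, dj: int, fill) -> np.ndarray:
    """arr shifted so that out[i, j] = arr[i+di, j+dj], edge-filled."""
    out = np.full_like(arr, fill)
    src_i = slice(max(di, 0), arr.shape[0] + min(di, 0))
    dst_i = slice(max(-di, 0), arr.shape[0] + min(-di, 0))
    src_j = slice(max(dj, 0), arr.shape[1] + min(dj, 0))
    dst_j = slice(max(-dj, 0), arr.shape[1] + min(-dj, 0))
    out[dst_i, dst_j] = arr[src_i, src_j]
    return out


def masked_laplacian(u: np.ndarray, template: ConductiveTemplate, dx: float = 2.0) -> np.ndarray:
    """Five-node Laplacian with no-flux (mirror) closure on the mask.

    At each conductive node: ``(sum of the four orthogonal neighbours -
    4*u_centre) / dx**2``, where an off-grid or non-conductive neighbour is
    replaced by the centre value.  Zero at non-conductive nodes.
    """
    u = np.asarray(u, dtype=float)
    if u.shape != template.shape:
        raise ValueError(f"field shape {u.shape} != template shape {template.shape}")
    cond = template.grid
    with np.errstate(over="ignore", invalid="ignore"):
        nb = {}
        for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            nb_u = _shifted(u, di, dj, 0.0)
            nb_c = _shifted(cond, di, dj, False)
            nb[(di, dj)] = np.where(nb_c, nb_u, u)
        # pairwise association (vertical pair + horizontal pair) keeps the
        # sum invariant under the grid's symmetry group in floating point
        acc = (nb[(-1, 0)] + nb[(1, 0)]) + (nb[(0, -1)] + nb[(0, 1)])
        lap = (acc - 4.0 * u) / (dx * dx)
    lap[~cond] = 0.0
    return lap


def euler_step(
    state: FieldState, params: FHNParameters, template: ConductiveTemplate
) -> FieldState:
    """One synchronous explicit Euler step; pre-step fields feed every term."""
    u, v = state.u, state.v
    if u.shape != template.shape or v.shape != template.shape:
        raise ValueError("state fields do not match template shape")
    cond = template.grid
    lap = masked_laplacian(u, template, params.dx)
    with np.errstate(over="ignore", invalid="ignore"):
        du = (
            params.c1 * u * (u - params.a) * (1.0 - u)
            - params.c2 * u * v
            + params.i_ext
            + params.d_u * lap
        )
        un = u + params.dt * du
        vn = v + params.dt * (params.b * (u - v))
    un = np.where(cond, un, 0.0)
    vn = np.where(cond, vn, 0.0)
    t = state.t + 1
    if not (np.isfinite(un).all() and np.isfinite(vn).all()):
        raise IntegrationBlowUpError(t)
    return FieldState(un, vn, t)


def apply_stimulus(
    state: FieldState, stim: StimulusSpec, template: ConductiveTemplate
) -> FieldState:
    """Set ``u`` to ``stim.value`` on conductive nodes inside the stimulus discs."""
    n_i, n_j = template.shape
    u = state.u.copy()
    touched = 0
    for ci, cj in stim.centres:
        # integer nodes at Euclidean distance < radius from the centre;
        # a direct distance test keeps the disc exact for fractional centres
        i_lo = max(0, int(np.ceil(ci - stim.radius)))
        i_hi = min(n_i - 1, int(np.floor(ci + stim.radius)))
        j_lo = max(0, int(np.ceil(cj - stim.radius)))
        j_hi = min(n_j - 1, int(np.floor(cj + stim.radius)))
        if i_lo > i_hi or j_lo > j_hi:
            continue
        ii, jj = np.mgrid[i_lo : i_hi + 1, j_lo : j_hi + 1]
        inside = (ii - ci) ** 2 + (jj - cj) ** 2 < stim.radius**2
        sel = inside & template.grid[i_lo : i_hi + 1, j_lo : j_hi + 1]
        u[i_lo : i_hi + 1, j_lo : j_hi + 1][sel] = stim.value
        touched += int(sel.sum())
    if touched == 0:
        warnings.warn(
            f"stimulus {stim.label or stim.centres} touched no conductive node",
            StimulusWarning,
            stacklevel=2,
        )
    return FieldState(u, state.v.copy(), state.t)


class _FlatStepper:
    """Update restricted to conductive nodes via precomputed neighbour indices.

    Neighbour slots that fall off-grid or on non-conductive nodes point back
    at the centre node, which realises the mirror (no-flux) closure.  The
    arithmetic matches :func:`euler_step` term for term.
    """

    def __init__(self, template: ConductiveTemplate, dx: float):
        cond = template.grid
        n_i, n_j = cond.shape
        idx_grid = np.full(cond.shape, -1, dtype=np.int64)
        self.coords = np.argwhere(cond)
        idx_grid[cond] = np.arange(len(self.coords))
        self.shape = cond.shape
        self.cond = cond
        self.inv_dx2 = 1.0 / (dx * dx)
        self.neighbours = []
        own = idx_grid[cond]
        for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            ii = self.coords[:, 0] + di
            jj = self.coords[:, 1] + dj
            ok = (ii >= 0) & (ii < n_i) & (jj >= 0) & (jj < n_j)
            nb = own.copy()
            flat_ok = idx_grid[ii[ok], jj[ok]]
            valid = flat_ok >= 0
            tmp = nb[ok]
            tmp[valid] = flat_ok[valid]
            nb[ok] = tmp
            self.neighbours.append(nb)

    def laplacian(self, u_flat: np.ndarray) -> np.ndarray:
        n_up, n_dn, n_lt, n_rt = self.neighbours
        # same pairwise association as masked_laplacian (symmetry-safe)
        acc = (u_flat[n_up] + u_flat[n_dn]) + (u_flat[n_lt] + u_flat[n_rt])
        return (acc - 4.0 * u_flat) * self.inv_dx2

    def step(self, u: np.ndarray, v: np.ndarray, p: FHNParameters):
        with np.errstate(over="ignore", invalid="ignore"):
            lap = self.laplacian(u)
            du = p.c1 * u * (u - p.a) * (1.0 - u) - p.c2 * u * v + p.i_ext + p.d_u * lap
            un = u + p.dt * du
            vn = v + p.dt * (p.b * (u - v))
        return un, vn

    def gather(self, field2d: np.ndarray) -> np.ndarray:
        return field2d[self.cond]

    def scatter(self, flat: np.ndarray) -> np.ndarray:
        out = np.zeros(self.shape)
        out[self.cond] = flat
        return out


def _get_stepper(template: ConductiveTemplate, dx: float) -> _FlatStepper:
    key = ("stepper", dx)
    if key not in template._stepper_cache:
        template._stepper_cache[key] = _FlatStepper(template, dx)
    return template._stepper_cache[key]


@dataclass(frozen=True)
class ExcitabilityResult:
    """Outcome of a single-endpoint excitability probe on a uniform grid."""

    c2: float
    excited_count_at_checkpoint: int
    checkpoint: int
    reached_all_edges: bool
    died_at: int | None


def scan_excitability(
    c2_values: Sequence[float] = (0.015, 0.05),
    grid_shape: tuple[int, int] = (100, 100),
    stimulus_radius: float = 1.8,
    stimulus_value: float = 1.0,
    checkpoint: int = 20000,
    n_iter: int = 60000,
    activity_threshold: float = 0.1,
    base_params: FHNParameters | None = None,
) -> list[ExcitabilityResult]:
    """Probe wave nucleation on a uniform fully conductive grid.

    For each ``c2``, a central disc is set to ``stimulus_value`` and the
    system integrated for ``n_iter`` iterations; the probe reports the
    excited-node count (``u > threshold``) at the checkpoint iteration,
    whether the excitation reached all four grid edges, and the iteration
    at which all activity vanished (if it did).  The run stops early once
    the medium is dead.
    """
    base = base_params or FHNParameters()
    n_i, n_j = grid_shape
    template = ConductiveTemplate(np.ones(grid_shape, dtype=bool))
    centre = ((n_i - 1) / 2.0, (n_j - 1) / 2.0)
    results = []
    for c2 in c2_values:
        params = FHNParameters(
            d_u=base.d_u, a=base.a, b=base.b, c1=base.c1, c2=c2,
            i_ext=base.i_ext, dt=base.dt, dx=base.dx,
        )
        stepper = _get_stepper(template, params.dx)
        state = apply_stimulus(
            FieldState.rest(template),
            StimulusSpec(centres=(centre,), radius=stimulus_radius, value=stimulus_value),
            template,
        )
        u = stepper.gather(state.u)
        v = stepper.gather(state.v)
        count_at_checkpoint = 0
        edges = [False] * 4
        died_at = None
        for t in range(1, n_iter + 1):
            u, v = stepper.step(u, v, params)
            if t % 100 == 0 or t == checkpoint:
                field = stepper.scatter(u)
                exc = field > activity_threshold
                edges[0] |= bool(exc[0].any())
                edges[1] |= bool(exc[-1].any())
                edges[2] |= bool(exc[:, 0].any())
                edges[3] |= bool(exc[:, -1].any())
                if t == checkpoint:
                    count_at_checkpoint = int(exc.sum())
                if not exc.any() and float(np.abs(u).max()) < 1e-4:
                    died_at = t
                    break
        results.append(
            ExcitabilityResult(
                c2=c2,
                excited_count_at_checkpoint=count_at_checkpoint,
                checkpoint=checkpoint,
                reached_all_edges=all(edges),
                died_at=died_at,
            )
        )
    return results


@dataclass
class SimulationResult:
    """Final state plus whatever the attached recorders accumulated."""

    final_state: FieldState
    recorders: list


def simulate(
    template: ConductiveTemplate,
    params: FHNParameters,
    stimuli: Sequence[StimulusSpec] = (),
    n_iter: int = 1000,
    recorders: Iterable = (),
) -> SimulationResult:
    """Run the engine for ``n_iter`` iterations.

    Stimuli are applied at their scheduled iterations (before the step that
    advances the counter past them); each recorder's ``record(t, state)``
    is invoked at iteration 0 and then whenever ``t`` is a multiple of its
    ``stride``.  The run is bit-reproducible for identical inputs.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if template.n_conductive == 0:
        raise ValueError("template has no conductive nodes")
    recorders = list(recorders)
    stepper = _get_stepper(template, params.dx)

    by_iter: dict[int, list[StimulusSpec]] = {}
    for s in stimuli:
        by_iter.setdefault(s.at_iteration, []).append(s)

    state = FieldState.rest(template)
    for s in by_iter.get(0, ()):
        state = apply_stimulus(state, s, template)
    u = stepper.gather(state.u)
    v = stepper.gather(state.v)

    def emit(t: int, force: bool = False):
        st = None
        for rec in recorders:
            stride = getattr(rec, "stride", 1)
            if force or t % stride == 0:
                if st is None:
                    st = FieldState(stepper.scatter(u), stepper.scatter(v), t)
                rec.record(t, st)

    emit(0, force=True)
    for t in range(1, n_iter + 1):
        u, v = stepper.step(u, v, params)
        if not np.isfinite(u).all():
            raise IntegrationBlowUpError(t)
        if t in by_iter:
            state_t = FieldState(stepper.scatter(u), stepper.scatter(v), t)
            for s in by_iter[t]:
                state_t = apply_stimulus(state_t, s, template)
            u = stepper.gather(state_t.u)
            v = stepper.gather(state_t.v)
        emit(t)

    final = FieldState(stepper.scatter(u), stepper.scatter(v), n_iter)
    return SimulationResult(final_state=final, recorders=recorders)
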