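"""Kinetic Monte-Carlo simulation of polyprotein pulling experiments.

Constant-velocity mode moves the cantilever base at fixed speed; at every
time step the tip force balances the worm-like-chain tension of the
currently released contour (solved from the force balance
``k_s (z - x) = F_WLC(x)``), and each folded unit's transitions fire with
probability ``1 - exp(-k(F) Δt)``.  Discrete time with a rate-bounded
adaptive sub-step is used instead of an event-driven scheme because the
force, and with it every rate, changes continuously during the ramp.
Competing clamps in one module are sampled jointly per sub-step with
independent Bernoulli draws; in the rare case both fire in the same
sub-step the tie is broken rate-proportionally and the event is logged as
simultaneous.

Force-clamp mode holds the force constant, so transition rates are
constant between events and dwell times are drawn exactly (Gillespie);
each transition adds an extension step of ``ΔLc`` times the fractional WLC
extension x/Lc at the clamp force.

White Gaussian noise is added to the recorded force channel only (and, in
force-clamp mode, to the extension channel scaled by 1/k_s); the event log
always records noise-free ground truth.
"""

from __future__ import annotations

import numpy as np

from cuproforce._version import __version__ as _version
from cuproforce.polymer import PolymerModel, thermal_energy, wlc_extension
from cuproforce.schemes import (
    FOLDED,
    UNFOLDED,
    InstrumentConfig,
    ModuleScheme,
    classify_visited,
)
from cuproforce.traces import ForceClampTrace, ForceExtensionTrace

__all__ = ["simulate_constant_velocity", "simulate_force_clamp"]

_MAX_EXP = 700.0


class _ModuleState:
    __slots__ = ("scheme", "holo", "state", "visited")

    def __init__(self, scheme: ModuleScheme, rng: np.random.Generator):
        self.scheme = scheme
        self.holo = bool(scheme.states) and (rng.random() < scheme.holo_probability)
        self.state = FOLDED
        self.visited = [FOLDED]

    def options(self):
        if self.state == UNFOLDED:
            return []
        if self.holo:
            return self.scheme.states.get(self.state, [])
        if self.state == FOLDED:
            return [(self.scheme.apo_rule, UNFOLDED)]
        return []  # pragma: no cover

    @property
    def done(self) -> bool:
        return self.state == UNFOLDED


def _rate(force: float, rule, kt: float) -> float:
    return rule.k0 * np.exp(min(force * rule.delta_x / kt, _MAX_EXP))


def _solve_balance(z: float, lc: float, spring: float, c: float, x0: float) -> tuple[float, float]:
    """Solve k_s (z - x) = F_WLC(x) for the extension x; returns (x, F)."""
    if z <= 0:
        return 0.0, 0.0
    hi = min(z, lc * (1.0 - 1e-9))
    x = min(max(x0, 0.0), hi)
    for _ in range(60):
        u = x / lc
        f = c * (0.25 / (1.0 - u) ** 2 - 0.25 + u)
        g = f - spring * (z - x)
        if abs(g) < 1e-10 * max(1.0, f):
            return x, f
        df = (c / lc) * (0.5 / (1.0 - u) ** 3 + 1.0) + spring
        x_new = x - g / df
        if not (0.0 <= x_new <= hi):
            break
        x = x_new
    # bisection fallback
    lo_x, hi_x = 0.0, hi
    for _ in range(200):
        x = 0.5 * (lo_x + hi_x)
        u = x / lc
        f = c * (0.25 / (1.0 - u) ** 2 - 0.25 + u)
        if f - spring * (z - x) < 0:
            lo_x = x
        else:
            hi_x = x
    return x, f


def simulate_constant_velocity(
    polyprotein: list[ModuleScheme],
    instrument: InstrumentConfig,
    temperature: float = 298.0,
    persistence_length: float = 0.4,
    tether_contour: float = 20.0,
    extra_pull: float = 15.0,
    max_force: float = 400.0,
    max_rate_dt: float = 0.05,
) -> tuple[ForceExtensionTrace, dict]:
    """Simulate a constant-velocity sawtooth pulling trace.

    Parameters
    ----------
    polyprotein : list of ModuleScheme
        Modules in pulling order (at least one).
    instrument : InstrumentConfig
    temperature : float, K
    persistence_length : float, nm
        WLC persistence length of the unfolded chain.
    tether_contour : float, nm
        Initial contour (handles plus folded-domain spans).
    extra_pull : float, nm
        Distance pulled beyond the last unfolding before stopping.
    max_force : float, pN
        Safety stop (also ends traces with inert modules).
    max_rate_dt : float
        Upper bound on k(F)·Δt per Monte-Carlo sub-step.

    Returns
    -------
    (trace, ground_truth)
        ``ground_truth`` holds the event log (time, force, extension,
        module, rule, states, simultaneous flag), per-module holo status
        and pathway labels, and the configuration echo.
    """
    if not polyprotein:
        raise ValueError("polyprotein must contain at least one module")
    rng = np.random.default_rng(instrument.rng_seed)
    kt = thermal_energy(temperature)
    c = kt / persistence_length
    mods = [_ModuleState(m, rng) for m in polyprotein]

    dt_sample = 1.0 / instrument.sampling_rate
    v = instrument.pulling_velocity
    spring = instrument.spring_constant
    lc = float(tether_contour)
    z = 0.0
    t = 0.0
    x = 0.0
    z_hard_max = tether_contour + sum(m.total_delta_Lc for m in polyprotein) + 200.0

    times, exts, forces = [0.0], [0.0], [0.0]
    events: list[dict] = []
    z_done: float | None = None

    while True:
        # rate-bounded sub-stepping within one recorded sample
        _, f_now = _solve_balance(z + v * dt_sample, lc, spring, c, x)
        rmax = max(
            (_rate(f_now, rule, kt) for m in mods for rule, _ in m.options()),
            default=0.0,
        )
        nsub = int(min(max(np.ceil(rmax * dt_sample / max_rate_dt), 1), 400))
        dt = dt_sample / nsub
        for _ in range(nsub):
            z += v * dt
            t += dt
            x, force = _solve_balance(z, lc, spring, c, x)
            for idx, mod in enumerate(mods):
                options = mod.options()
                if not options:
                    continue
                rates = [_rate(force, rule, kt) for rule, _ in options]
                draws = rng.random(len(options))
                fired = [i for i, (r, d) in enumerate(zip(rates, draws))
                         if d < -np.expm1(-r * dt)]
                if not fired:
                    continue
                if len(fired) == 1:
                    chosen = fired[0]
                    simultaneous = False
                else:
                    w = np.array([rates[i] for i in fired])
                    chosen = fired[int(rng.choice(len(fired), p=w / w.sum()))]
                    simultaneous = True
                rule, nxt = options[chosen]
                events.append(
                    {
                        "time": t,
                        "force": force,
                        "extension": x,
                        "module_index": idx,
                        "module": mod.scheme.name,
                        "rule": rule.name,
                        "from_state": mod.state,
                        "to_state": nxt,
                        "delta_Lc": rule.delta_Lc,
                        "holo": mod.holo,
                        "simultaneous": simultaneous,
                    }
                )
                lc += rule.delta_Lc
                mod.state = nxt
                mod.visited.append(nxt)
        times.append(t)
        exts.append(x)
        forces.append(force)
        if all(m.done for m in mods):
            if z_done is None:
                z_done = z
            if z - z_done >= extra_pull:
                break
        if force > max_force or z > z_hard_max:
            break

    force_arr = np.asarray(forces)
    if instrument.force_noise_sd > 0:
        force_arr = force_arr + rng.normal(0.0, instrument.force_noise_sd, len(force_arr))
    trace = ForceExtensionTrace(
        time=np.asarray(times),
        extension=np.asarray(exts),
        force=force_arr,
        metadata=_metadata(polyprotein, instrument, temperature, persistence_length,
                           tether_contour, mode="constant_velocity"),
    )
    truth = {
        "events": events,
        "modules": [
            {
                "index": i,
                "name": m.scheme.name,
                "holo": m.holo,
                "states_visited": m.visited,
                "pathway": classify_visited(m.visited, m.holo),
            }
            for i, m in enumerate(mods)
        ],
        "seed": instrument.rng_seed,
        "tether_contour_nm": tether_contour,
    }
    return trace, truth


def simulate_force_clamp(
    polyprotein: list[ModuleScheme],
    clamp_force: float,
    duration: float,
    instrument: InstrumentConfig,
    temperature: float = 298.0,
    persistence_length: float = 0.4,
    tether_contour: float = 20.0,
) -> tuple[ForceClampTrace, dict]:
    """Simulate a force-clamp extension staircase.

    Rates are constant at the clamp force, so inter-event dwell times are
    exactly exponential (Gillespie sampling).  Each transition adds
    ``ΔLc · (x/Lc at the clamp force)`` of extension.
    """
    if clamp_force <= 0:
        raise ValueError("clamp_force must be > 0")
    rng = np.random.default_rng(instrument.rng_seed)
    kt = thermal_energy(temperature)
    mods = [_ModuleState(m, rng) for m in polyprotein]
    # fractional WLC extension at the clamp force (independent of Lc)
    u = wlc_extension(clamp_force, PolymerModel(1.0, persistence_length, temperature))

    lc = float(tether_contour)
    t = 0.0
    t_prev = 0.0
    events: list[dict] = []
    lc_times = [0.0]
    lc_values = [lc]
    while True:
        flat = [(mod, idx, rule, nxt) for idx, mod in enumerate(mods)
                for rule, nxt in mod.options()]
        if not flat:
            break
        rates = np.array([_rate(clamp_force, rule, kt) for _, _, rule, _ in flat])
        total = rates.sum()
        t += rng.exponential(1.0 / total)
        if t >= duration:
            break
        mod, idx, rule, nxt = flat[int(rng.choice(len(flat), p=rates / total))]
        events.append(
            {
                "time": t,
                "dwell": t - t_prev,
                "module_index": idx,
                "module": mod.scheme.name,
                "rule": rule.name,
                "from_state": mod.state,
                "to_state": nxt,
                "delta_Lc": rule.delta_Lc,
                "step_extension": rule.delta_Lc * u,
                "holo": mod.holo,
            }
        )
        t_prev = t
        lc += rule.delta_Lc
        mod.state = nxt
        mod.visited.append(nxt)
        lc_times.append(t)
        lc_values.append(lc)

    n = max(int(np.floor(duration * instrument.sampling_rate)), 2)
    times = np.arange(n) / instrument.sampling_rate
    lc_t = np.asarray(lc_values)[np.searchsorted(lc_times, times, side="right") - 1]
    ext = u * lc_t
    if instrument.force_noise_sd > 0:
        ext = ext + rng.normal(0.0, instrument.force_noise_sd / instrument.spring_constant, n)
        force = clamp_force + rng.normal(0.0, instrument.force_noise_sd, n)
    else:
        force = np.full(n, float(clamp_force))
    trace = ForceClampTrace(
        time=times,
        extension=ext,
        force=force,
        metadata=_metadata(polyprotein, instrument, temperature, persistence_length,
                           tether_contour, mode="force_clamp",
                           clamp_force_pN=clamp_force, duration_s=duration),
    )
    truth = {
        "events": events,
        "modules": [
            {
                "index": i,
                "name": m.scheme.name,
                "holo": m.holo,
                "states_visited": m.visited,
                "pathway": classify_visited(m.visited, m.holo),
            }
            for i, m in enumerate(mods)
        ],
        "seed": instrument.rng_seed,
        "extension_ratio": u,
        "tether_contour_nm": tether_contour,
    }
    return trace, truth


def _metadata(polyprotein, instrument, temperature, persistence_length,
              tether_contour, mode, **extra) -> dict:
    md = {
        "construct": "+".join(m.name for m in polyprotein),
        "velocity_nm_s": instrument.pulling_velocity,
        "spring_constant_pN_nm": instrument.spring_constant,
        "sampling_rate_hz": instrument.sampling_rate,
        "force_noise_sd_pN": instrument.force_noise_sd,
        "seed": instrument.rng_seed,
        "temperature_K": temperature,
        "persistence_length_nm": persistence_length,
        "tether_contour_nm": tether_contour,
        "package_version": _version,
    }
    md.update(extra)
    return md
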