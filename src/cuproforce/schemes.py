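"""Polyprotein unfolding schemes: modules, transition rules, instruments.

A :class:`ModuleScheme` describes one protein module of a polyprotein as a
small state graph.  Metal-bearing (holo) cupredoxin modules start in
``folded`` with two competing terminal mechanical clamps; breaking the
C-terminal clamp releases the C segment (chain from the C terminus to the
Cu–S(Cys) bond), breaking the N-terminal clamp releases the N segment (to
the Cu–N(His) bond, shortened by any disulfide shortcut).  From either
intermediate the Cu anchor can rupture, releasing the remainder, or the
other clamp can break first, giving a four-state cascade in which both
segments are released one after the other.  Metal-free (apo) modules unfold
in a single all-or-none step of the full contour length.  Total released
contour length is path-independent by construction.

Transition kinetics follow the Bell-Evans rate law

    k(F) = k0 * exp(F * Δx / kT),

with intrinsic rate ``k0`` (1/s) and distance to the transition state
``Δx`` (nm).  The experiments this package emulates report rupture forces,
not rates, so the default ``k0``/``Δx`` values below are calibration
constants, chosen so that in a simulated (protein-I27)_4 polyprotein
pulled at 400 nm/s with a ~15 pN/nm cantilever the mean rupture forces
approximate the reported ones (azurin main event ~50-55 pN, Cu-anchor
intermediates ~42 pN, plastocyanin ~76 pN, I27 fingerprint ~213 pN) and
the four-state fraction of wt azurin lands near 5%.  Because the first
ruptures in a polyprotein are order statistics over all folded modules,
these k0 values are several-fold smaller than a single-molecule
Evans-Ritchie estimate would suggest; they were set by simulating the
full construct, not barrier by barrier.  Δx = 0.45 nm for the terminal
clamps reproduces the reported ~12 pN spread of unfolding forces; the
I27 Δx is the conventional 0.25 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cuproforce.polymer import thermal_energy

__all__ = [
    "TransitionRule",
    "ModuleScheme",
    "InstrumentConfig",
    "bell_rate",
    "sample_pathway",
    "two_state_module",
    "cupredoxin_module",
    "wt_azurin",
    "azurin_c112a",
    "azurin_c26a",
    "plastocyanin",
    "i27",
    "default_polyprotein",
    "CONSTRUCTS",
]

FOLDED, UNFOLDED = "folded", "unfolded"
INT_C, INT_N, INT_NC = "int_C", "int_N", "int_NC"


@dataclass(frozen=True)
class TransitionRule:
    """One force-activated transition: contour release and Bell parameters."""

    name: str
    delta_Lc: float  # nm released
    k0: float  # intrinsic rate at zero force, 1/s
    delta_x: float  # distance to the transition state, nm

    def __post_init__(self) -> None:
        if self.delta_Lc < 0:
            raise ValueError("delta_Lc must be >= 0")
        if self.k0 <= 0:
            raise ValueError("k0 must be > 0")
        if self.delta_x <= 0:
            raise ValueError("delta_x must be > 0")


def bell_rate(force: float, rule: TransitionRule, temperature: float = 298.0) -> float:
    """Bell-Evans rate k(F) = k0 exp(F Δx / kT); force in pN."""
    if force < 0:
        raise ValueError("force must be >= 0")
    return rule.k0 * np.exp(force * rule.delta_x / thermal_energy(temperature))


@dataclass
class ModuleScheme:
    """State graph of one polyprotein module.

    Parameters
    ----------
    name : str
    states : dict
        state -> list of (TransitionRule, next_state) for the holo form;
        empty for modules without metal-anchored intermediates.
    apo_rule : TransitionRule
        Single all-or-none transition used when the module is apo (or for
        fingerprint modules like I27, which are always "apo" here).
    holo_probability : float
        Fraction of module copies carrying the metal (intermediate-capable).
    """

    name: str
    states: dict[str, list[tuple[TransitionRule, str]]]
    apo_rule: TransitionRule
    holo_probability: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.holo_probability <= 1.0:
            raise ValueError("holo_probability must be in [0, 1]")
        if self.states:
            totals = self._path_totals(FOLDED, 0.0)
            if not totals:
                raise ValueError(f"scheme {self.name}: no path reaches {UNFOLDED!r}")
            if max(totals) - min(totals) > 1e-9:
                raise ValueError(
                    f"scheme {self.name}: released ΔLc is path-dependent: {totals}"
                )
            if abs(totals[0] - self.apo_rule.delta_Lc) > 1e-9:
                raise ValueError(
                    f"scheme {self.name}: apo ΔLc {self.apo_rule.delta_Lc} differs "
                    f"from holo path total {totals[0]}"
                )

    def _path_totals(self, state: str, acc: float, _depth: int = 0) -> list[float]:
        if _depth > 20:
            raise ValueError(f"scheme {self.name}: state graph has a cycle")
        if state == UNFOLDED:
            return [acc]
        options = self.states.get(state, [])
        if not options:
            raise ValueError(
                f"scheme {self.name}: state {state!r} is a dead end"
            )
        out: list[float] = []
        for rule, nxt in options:
            out.extend(self._path_totals(nxt, acc + rule.delta_Lc, _depth + 1))
        return out

    @property
    def total_delta_Lc(self) -> float:
        """Contour released by complete unfolding, any pathway."""
        return self.apo_rule.delta_Lc


@dataclass(frozen=True)
class InstrumentConfig:
    """AFM instrument settings for the simulator."""

    pulling_velocity: float = 400.0  # nm/s
    spring_constant: float = 20.0  # pN/nm, typical calibrated range 12-35
    sampling_rate: float = 10000.0  # Hz
    force_noise_sd: float = 5.0  # pN, white Gaussian on the force channel
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pulling_velocity", "spring_constant", "sampling_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.force_noise_sd < 0:
            raise ValueError("force_noise_sd must be >= 0")


def classify_visited(states_visited: list[str], holo: bool) -> str:
    """Pathway label from the sequence of states a module visited."""
    if not holo:
        return "two-state"
    if INT_NC in states_visited:
        return "four-state"
    if INT_C in states_visited:
        return "C-first"
    if INT_N in states_visited:
        return "N-first"
    return "two-state"


def sample_pathway(
    module: ModuleScheme, rng: np.random.Generator, force: float = 50.0,
    temperature: float = 298.0,
) -> list[str]:
    """Draw one pathway through a module's state graph.

    Holo/apo status is drawn first; competing transitions are then resolved
    by their Bell-rate ratio at the given representative rupture force.
    Returns the sequence of visited states; feed it to
    :func:`classify_visited` for the pathway label.
    """
    holo = rng.random() < module.holo_probability and bool(module.states)
    if not holo:
        return [FOLDED, UNFOLDED]
    visited = [FOLDED]
    state = FOLDED
    guard = 0
    while state != UNFOLDED:
        options = module.states[state]
        rates = np.array([bell_rate(force, r, temperature) for r, _ in options])
        idx = rng.choice(len(options), p=rates / rates.sum())
        state = options[idx][1]
        visited.append(state)
        guard += 1
        if guard > 20:  # pragma: no cover - graphs are validated acyclic
            raise RuntimeError("pathway sampling did not terminate")
    return visited


# ---------------------------------------------------------------------------
# Construct builders and calibrated defaults
# ---------------------------------------------------------------------------

def two_state_module(name: str, delta_Lc: float, k0: float, delta_x: float) -> ModuleScheme:
    """Module that unfolds in a single all-or-none step (e.g. the I27 fingerprint)."""
    return ModuleScheme(
        name=name,
        states={},
        apo_rule=TransitionRule(f"{name}-unfold", delta_Lc, k0, delta_x),
        holo_probability=0.0,
    )


def cupredoxin_module(
    name: str,
    dLc_C: float,
    dLc_N: float,
    dLc_total: float,
    clamp_C: tuple[float, float],
    clamp_N: tuple[float, float],
    cu_anchor: tuple[float, float],
    holo_probability: float,
    cu_anchor_C: tuple[float, float] | None = None,
) -> ModuleScheme:
    """Cupredoxin module with competing N/C clamps and Cu-anchored intermediates.

    ``clamp_*`` and ``cu_anchor`` are (k0, Δx) pairs; ``cu_anchor_C``
    optionally gives the Cu-S(Cys) bond (reached via the C-first pathway)
    kinetics distinct from the Cu-N(His) bond.  The core released on Cu
    rupture is ``dLc_total - dLc_C - dLc_N``.
    """
    if cu_anchor_C is None:
        cu_anchor_C = cu_anchor
    core = dLc_total - dLc_C - dLc_N
    if core < 0:
        raise ValueError("segment releases exceed the total contour length")
    r_C = TransitionRule("C-clamp", dLc_C, *clamp_C)
    r_N = TransitionRule("N-clamp", dLc_N, *clamp_N)
    states = {
        FOLDED: [(r_C, INT_C), (r_N, INT_N)],
        INT_C: [
            (TransitionRule("Cu-S-rupture", dLc_N + core, *cu_anchor_C), UNFOLDED),
            (r_N, INT_NC),
        ],
        INT_N: [
            (TransitionRule("Cu-N-rupture", dLc_C + core, *cu_anchor), UNFOLDED),
            (r_C, INT_NC),
        ],
        INT_NC: [(TransitionRule("Cu-release", core, *cu_anchor), UNFOLDED)],
    }
    # an apo module still has both terminal clamps; either one unfolds it
    apo = TransitionRule("two-state", dLc_total, clamp_C[0] + clamp_N[0],
                         0.5 * (clamp_C[1] + clamp_N[1]))
    return ModuleScheme(name=name, states=states, apo_rule=apo,
                        holo_probability=holo_probability)


# Calibration constants (k0 1/s, Δx nm): see module docstring.
_AZU_CLAMP = (0.05, 0.45)
_AZU_CU = (1.63, 0.40)
_PC_CLAMP_C = (5.1e-3, 0.45)
_PC_CLAMP_N = (6.3e-3, 0.45)  # ~55:45 N:C partition
_PC_CU = (1.7, 0.40)
_PC_CU_S = (7.6, 0.40)
_I27 = (1.0e-4, 0.25)


def wt_azurin() -> ModuleScheme:
    """Wild-type azurin: 38.6 nm total, 6.2/9.4 nm C/N segments, 80% holo."""
    return cupredoxin_module("wt-azurin", 6.2, 9.4, 38.6,
                             _AZU_CLAMP, _AZU_CLAMP, _AZU_CU, 0.8)


def azurin_c112a() -> ModuleScheme:
    """C112A mutant: no Cu-S bond, so the C-clamp pathway is all-or-none."""
    r_N = TransitionRule("N-clamp", 9.4, *_AZU_CLAMP)
    states = {
        FOLDED: [
            (TransitionRule("C-clamp", 38.6, *_AZU_CLAMP), UNFOLDED),
            (r_N, INT_N),
        ],
        INT_N: [(TransitionRule("Cu-N-rupture", 29.2, *_AZU_CU), UNFOLDED)],
    }
    apo = TransitionRule("two-state", 38.6, 2 * _AZU_CLAMP[0], _AZU_CLAMP[1])
    return ModuleScheme(name="AzuC112A", states=states, apo_rule=apo,
                        holo_probability=0.8)


def azurin_c26a() -> ModuleScheme:
    """C26A mutant: no disulfide shortcut; 47.6 nm total, N segment 19.0 nm,
    N pathway favoured ~80:20."""
    return cupredoxin_module("AzuC26A", 6.2, 19.0, 47.6,
                             (0.05, 0.45), (0.20, 0.45), _AZU_CU, 0.8)


def plastocyanin() -> ModuleScheme:
    """Plastocyanin: 36.8 nm total, 5.9/13.8 nm C/N segments, 60% holo."""
    return cupredoxin_module("plastocyanin", 5.9, 13.8, 36.8,
                             _PC_CLAMP_C, _PC_CLAMP_N, _PC_CU, 0.6,
                             cu_anchor_C=_PC_CU_S)


def i27() -> ModuleScheme:
    """Titin I27 fingerprint: 28 nm increment, ~210 pN at 400 nm/s."""
    return two_state_module("I27", 28.0, *_I27)


CONSTRUCTS = {
    "wt-azurin": wt_azurin,
    "AzuC112A": azurin_c112a,
    "AzuC26A": azurin_c26a,
    "plastocyanin": plastocyanin,
    "I27": i27,
}


def default_polyprotein(construct: str = "wt-azurin", n_repeats: int = 4) -> list[ModuleScheme]:
    """(Protein–I27)_n polyprotein: alternating cupredoxin and fingerprint modules."""
    if construct not in CONSTRUCTS:
        raise ValueError(f"unknown construct {construct!r}; known: {sorted(CONSTRUCTS)}")
    mods: list[ModuleScheme] = []
    for _ in range(n_repeats):
        mods.append(CONSTRUCTS[construct]())
        mods.append(i27())
    return mods


# ---------------------------------------------------------------------------
# Scheme (de)serialization
# ---------------------------------------------------------------------------

def scheme_to_dict(scheme: ModuleScheme) -> dict:
    """Plain-dict form of a ModuleScheme (YAML/JSON friendly)."""
    def rule(r: TransitionRule) -> dict:
        return {"name": r.name, "delta_Lc": r.delta_Lc, "k0": r.k0,
                "delta_x": r.delta_x}

    return {
        "name": scheme.name,
        "holo_probability": scheme.holo_probability,
        "apo_rule": rule(scheme.apo_rule),
        "states": {
            state: [{"rule": rule(r), "to": nxt} for r, nxt in options]
            for state, options in scheme.states.items()
        },
    }


def scheme_from_dict(data: dict) -> ModuleScheme:
    """Inverse of :func:`scheme_to_dict`; validates the graph invariants."""
    def rule(d: dict) -> TransitionRule:
        missing = {"name", "delta_Lc", "k0", "delta_x"} - set(d)
        if missing:
            raise ValueError(f"transition rule missing keys: {sorted(missing)}")
        return TransitionRule(d["name"], float(d["delta_Lc"]), float(d["k0"]),
                              float(d["delta_x"]))

    for key in ("name", "apo_rule"):
        if key not in data:
            raise ValueError(f"scheme document missing key: {key!r}")
    states = {
        state: [(rule(opt["rule"]), opt["to"]) for opt in options]
        for state, options in data.get("states", {}).items()
    }
    return ModuleScheme(
        name=data["name"],
        states=states,
        apo_rule=rule(data["apo_rule"]),
        holo_probability=float(data.get("holo_probability", 0.0)),
    )


def save_schemes(schemes: list[ModuleScheme], path) -> None:
    """Write scheme documents (one YAML document per construct)."""
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump_all([scheme_to_dict(s) for s in schemes], fh,
                           sort_keys=False)


def load_schemes(path) -> dict[str, ModuleScheme]:
    """Read a multi-document YAML scheme file; returns name -> scheme."""
    import yaml

    with open(path) as fh:
        docs = list(yaml.safe_load_all(fh))
    out = {}
    for doc in docs:
        if doc is None:
            continue
        scheme = scheme_from_dict(doc)
        out[scheme.name] = scheme
    return out
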