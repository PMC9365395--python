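"""Aggregated continuous-time Markov schemes for single-channel gating.

A channel is modelled as a finite-state Markov chain whose states fall into
two conductance classes, ``open`` and ``shut``.  Only the class is observable:
an event record is the alternating sequence of class sojourns.  This module
holds the scheme representation (states, transitions, rate symbols), builds
concentration-resolved generator (Q) matrices, and derives the exact,
infinite-bandwidth quantities that follow from them: equilibrium occupancies,
dwell-time densities with their exponential-component decomposition, and the
equilibrium constants (priming K', gating Theta_n, binding K_n, block K_B)
conventionally reported alongside fitted rates.

Second-order (ligand-dependent) rate constants are expressed in uM^-1 s^-1
and multiplied by the ligand concentration in uM when the generator is built;
all first-order rates are in s^-1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import scipy.linalg

from .errors import ConfigurationError, SchemeError

OPEN = "open"
SHUT = "shut"


@dataclass(frozen=True)
class State:
    """A kinetic state with its observable conductance class.

    Open-but-blocked states are non-conducting and must be declared ``shut``:
    in a record a blockage is indistinguishable from a brief closure.
    """

    name: str
    conductance: str  # "open" | "shut"
    role: str = ""

    def __post_init__(self) -> None:
        if self.conductance not in (OPEN, SHUT):
            raise SchemeError(
                f"state {self.name!r}: conductance must be 'open' or 'shut', "
                f"got {self.conductance!r}"
            )


@dataclass(frozen=True)
class Transition:
    """A directed transition with a named rate constant.

    ``ligand`` marks a second-order (association) rate: its value is in
    uM^-1 s^-1 and is multiplied by that ligand's concentration (uM) when a
    generator matrix is built.
    """

    source: str
    target: str
    symbol: str
    value: float
    ligand: str | None = None

    def __post_init__(self) -> None:
        if self.value < 0:
            raise SchemeError(f"rate {self.symbol}: negative value {self.value}")


@dataclass(frozen=True)
class KineticScheme:
    """An aggregated Markov scheme: ordered states plus rate-labelled edges."""

    name: str
    states: tuple[State, ...]
    transitions: tuple[Transition, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "transitions", tuple(self.transitions))
        names = [s.name for s in self.states]
        if len(set(names)) != len(names):
            raise SchemeError(f"duplicate state names in scheme {self.name!r}")
        classes = {s.conductance for s in self.states}
        if classes != {OPEN, SHUT}:
            raise SchemeError(
                f"scheme {self.name!r} needs at least one open and one shut state"
            )
        pairs = set()
        for t in self.transitions:
            if t.source not in names or t.target not in names:
                raise SchemeError(
                    f"transition {t.symbol}: unknown state "
                    f"{t.source!r} or {t.target!r}"
                )
            if (t.source, t.target) in pairs:
                raise SchemeError(
                    f"duplicate transition {t.source} -> {t.target}"
                )
            pairs.add((t.source, t.target))
        self._check_connected()

    def _check_connected(self) -> None:
        # strong connectivity by breadth-first search both ways
        names = [s.name for s in self.states]
        fwd: dict[str, set[str]] = {n: set() for n in names}
        bwd: dict[str, set[str]] = {n: set() for n in names}
        for t in self.transitions:
            fwd[t.source].add(t.target)
            bwd[t.target].add(t.source)
        for adj in (fwd, bwd):
            seen = {names[0]}
            stack = [names[0]]
            while stack:
                for nxt in adj[stack.pop()]:
                    if nxt not in seen:
                        seen.add(nxt)
                        stack.append(nxt)
            if seen != set(names):
                missing = sorted(set(names) - seen)
                raise SchemeError(
                    f"scheme {self.name!r} is not strongly connected; "
                    f"unreachable states: {missing}"
                )

    # -- convenience accessors -------------------------------------------
    @property
    def state_names(self) -> list[str]:
        return [s.name for s in self.states]

    def class_indices(self, conductance: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.states) if s.conductance == conductance],
            dtype=int,
        )

    def rates(self) -> dict[str, float]:
        """Current symbol -> value map (shared symbols must agree)."""
        out: dict[str, float] = {}
        for t in self.transitions:
            if t.symbol in out and out[t.symbol] != t.value:
                raise SchemeError(f"symbol {t.symbol} carries conflicting values")
            out[t.symbol] = t.value
        return out

    @property
    def ligands(self) -> set[str]:
        return {t.ligand for t in self.transitions if t.ligand is not None}

    def with_rates(self, new_rates: Mapping[str, float]) -> "KineticScheme":
        """Return a copy with the listed rate symbols replaced."""
        known = {t.symbol for t in self.transitions}
        unknown = set(new_rates) - known
        if unknown:
            raise SchemeError(f"unknown rate symbols: {sorted(unknown)}")
        new_trans = tuple(
            replace(t, value=float(new_rates[t.symbol]))
            if t.symbol in new_rates
            else t
            for t in self.transitions
        )
        return KineticScheme(self.name, self.states, new_trans)

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "states": [
                {"name": s.name, "conductance": s.conductance, "role": s.role}
                for s in self.states
            ],
            "transitions": [
                {
                    "from": t.source,
                    "to": t.target,
                    "symbol": t.symbol,
                    "value": t.value,
                    **({"ligand": t.ligand} if t.ligand else {}),
                }
                for t in self.transitions
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "KineticScheme":
        states = tuple(
            State(s["name"], s["conductance"], s.get("role", ""))
            for s in d["states"]
        )
        transitions = tuple(
            Transition(
                t["from"], t["to"], t["symbol"], float(t["value"]),
                t.get("ligand"),
            )
            for t in d["transitions"]
        )
        return cls(d.get("name", "scheme"), states, transitions)


@dataclass
class GeneratorMatrix:
    """Concentration-resolved generator (Q) matrix of a scheme.

    Off-diagonal q[i, j] is the transition rate i -> j in s^-1 (second-order
    rates already multiplied by ligand concentration); diagonals are negative
    row sums so each row sums to zero.
    """

    q: np.ndarray
    scheme: KineticScheme
    concentrations: dict[str, float] = field(default_factory=dict)

    @property
    def state_order(self) -> list[str]:
        return self.scheme.state_names

    def class_indices(self, conductance: str) -> np.ndarray:
        return self.scheme.class_indices(conductance)

    def sub(self, rows: str, cols: str) -> np.ndarray:
        """Sub-block of Q between two conductance classes ('open'/'shut')."""
        i = self.class_indices(rows)
        j = self.class_indices(cols)
        return self.q[np.ix_(i, j)]


def build_generator(
    scheme: KineticScheme,
    concentrations: Mapping[str, float] | None = None,
) -> GeneratorMatrix:
    """Realize a scheme as a Q matrix at given ligand concentrations (uM)."""
    conc = dict(concentrations or {})
    missing = scheme.ligands - set(conc)
    if missing:
        raise ConfigurationError(
            f"no concentration supplied for ligand(s) {sorted(missing)} "
            f"required by scheme {scheme.name!r}"
        )
    n = len(scheme.states)
    idx = {s.name: i for i, s in enumerate(scheme.states)}
    q = np.zeros((n, n))
    for t in scheme.transitions:
        rate = t.value
        if t.ligand is not None:
            rate *= conc[t.ligand]
        q[idx[t.source], idx[t.target]] = rate
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return GeneratorMatrix(q=q, scheme=scheme, concentrations=conc)


def equilibrium_occupancy(g: GeneratorMatrix) -> np.ndarray:
    """Stationary distribution pi with pi @ Q = 0 and sum(pi) = 1."""
    n = g.q.shape[0]
    a = np.vstack([g.q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    if not np.all(np.isfinite(pi)):
        raise FloatingPointError("singular generator: no stationary solution")
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def class_entry_vector(g: GeneratorMatrix, conductance: str) -> np.ndarray:
    """Steady-state distribution over class states at the moment of entry.

    Proportional to the equilibrium probability flux from the complementary
    class into each state of the requested class.
    """
    other = SHUT if conductance == OPEN else OPEN
    pi = equilibrium_occupancy(g)
    phi = pi[g.class_indices(other)] @ g.sub(other, conductance)
    total = phi.sum()
    if total <= 0:
        raise SchemeError(f"no flux into class {conductance!r}")
    return phi / total


def dwell_components(
    g: GeneratorMatrix, conductance: str
) -> list[tuple[float, float]]:
    """Exponential components (area, tau seconds) of the ideal dwell density.

    The within-class sub-generator Q_aa is diagonalised; each eigenvalue
    contributes a component with tau = -1/eigenvalue.  Areas sum to one.
    Raises LinAlgError for a defective sub-generator (callers may fall back
    to :func:`ideal_dwell_density`, which uses a matrix exponential).
    """
    idx = g.class_indices(conductance)
    if idx.size == 0:
        raise SchemeError(f"class {conductance!r} is empty")
    qaa = g.q[np.ix_(idx, idx)]
    phi = class_entry_vector(g, conductance)
    lam, vec = np.linalg.eig(qaa)
    if np.linalg.cond(vec) > 1e12:
        raise np.linalg.LinAlgError("defective within-class sub-generator")
    vinv = np.linalg.inv(vec)
    exit_rates = -qaa @ np.ones(len(idx))
    comps = []
    for k in range(len(lam)):
        ck = (phi @ vec[:, k]) * (vinv[k, :] @ exit_rates)
        area = float(np.real(-ck / lam[k]))
        tau = float(np.real(-1.0 / lam[k]))
        comps.append((area, tau))
    comps.sort(key=lambda at: at[1])
    return comps


def ideal_dwell_density(
    g: GeneratorMatrix, conductance: str, t: float | np.ndarray
) -> np.ndarray:
    """Ideal (no dead time) dwell-time probability density of one class.

    f(t) = phi @ expm(Q_aa t) @ (-Q_aa) @ 1 with phi the equilibrium
    class-entry vector.  Valid for any (even defective) sub-generator.
    """
    idx = g.class_indices(conductance)
    qaa = g.q[np.ix_(idx, idx)]
    phi = class_entry_vector(g, conductance)
    exit_rates = -qaa @ np.ones(len(idx))
    ts = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(ts < 0):
        raise ValueError("dwell times must be >= 0")
    try:
        comps = dwell_components(g, conductance)
        lam = np.array([-1.0 / tau for _, tau in comps])
        amp = np.array([area * (-lam_k) for (area, _), lam_k in zip(comps, lam)])
        out = (amp[None, :] * np.exp(lam[None, :] * ts[:, None])).sum(axis=1)
    except np.linalg.LinAlgError:
        out = np.array(
            [phi @ scipy.linalg.expm(qaa * tk) @ exit_rates for tk in ts]
        )
    return out if np.ndim(t) else float(out[0])


def mean_dwell(g: GeneratorMatrix, conductance: str) -> float:
    """Closed-form mean class dwell: -phi @ Q_aa^-1 @ 1 (seconds)."""
    idx = g.class_indices(conductance)
    qaa = g.q[np.ix_(idx, idx)]
    phi = class_entry_vector(g, conductance)
    return float(-phi @ np.linalg.solve(qaa, np.ones(len(idx))))


# ---------------------------------------------------------------------------
# Derived equilibrium constants
# ---------------------------------------------------------------------------

@dataclass
class DerivedConstants:
    """Equilibrium constants derived from a rate set.

    ``K_prime[n]`` priming (k_plus_n' / k_minus_n', dimensionless);
    ``Theta[n]`` gating (beta_n / alpha_n, dimensionless);
    ``K[n]`` apparent dissociation (k_minus_n / k_plus_n, uM);
    ``K_B[blocker]`` block dissociation (k_minusB / k_plusB, uM).
    """

    K_prime: dict[int, float] = field(default_factory=dict)
    Theta: dict[int, float] = field(default_factory=dict)
    K: dict[int, float] = field(default_factory=dict)
    K_B: dict[str, float] = field(default_factory=dict)


_PRIME_FWD = re.compile(r"^k_plus(\d+)_prime$")
_BIND_FWD = re.compile(r"^k_plus(\d+)$")
_GATE_FWD = re.compile(r"^beta_(\d+)$")
_BLOCK_FWD = re.compile(r"^k_plusB(?:_(.+))?$")


def _ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        raise SchemeError(f"zero denominator computing {what}")
    return num / den


def derived_constants(
    rates: Mapping[str, float], scheme: KineticScheme | None = None
) -> DerivedConstants:
    """Compute K', Theta_n, K_n and K_B from a symbol -> value rate map.

    Symbols follow the package convention: priming steps ``k_plus<n>_prime``
    / ``k_minus<n>_prime``, binding ``k_plus<n>`` / ``k_minus<n>`` (uM^-1 s^-1
    forward), gating ``beta_<n>`` / ``alpha_<n>``, block ``k_plusB[_<name>]``
    / ``k_minusB[_<name>]``.  Missing partners raise SchemeError.
    """
    out = DerivedConstants()
    for sym, val in rates.items():
        if (m := _PRIME_FWD.match(sym)):
            n = int(m.group(1))
            back = f"k_minus{n}_prime"
            if back not in rates:
                raise SchemeError(f"missing symbol {back} paired with {sym}")
            out.K_prime[n] = _ratio(val, rates[back], f"K'_{n}")
        elif (m := _GATE_FWD.match(sym)):
            n = int(m.group(1))
            back = f"alpha_{n}"
            if back not in rates:
                raise SchemeError(f"missing symbol {back} paired with {sym}")
            out.Theta[n] = _ratio(val, rates[back], f"Theta_{n}")
        elif (m := _BIND_FWD.match(sym)):
            n = int(m.group(1))
            back = f"k_minus{n}"
            if back not in rates:
                raise SchemeError(f"missing symbol {back} paired with {sym}")
            out.K[n] = _ratio(rates[back], val, f"K_{n}")
        elif (m := _BLOCK_FWD.match(sym)):
            label = m.group(1) or ""
            back = f"k_minusB_{label}" if label else "k_minusB"
            if back not in rates:
                raise SchemeError(f"missing symbol {back} paired with {sym}")
            out.K_B[label or "blocker"] = _ratio(rates[back], val, "K_B")
    return out
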