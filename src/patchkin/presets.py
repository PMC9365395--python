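"""Built-in kinetic schemes with published rate constants.

Five named presets cover the schemes used for the ancestral-subunit homomer
and wild-type AChR analyses:

``S1``
    Spontaneous gating of the homopentamer: a linear chain
    C -- C' -- O' (closed, primed-closed, open-primed), agonist-free.
``S2``
    S1 plus a single open-blocked state O'B entered from O' at a rate
    proportional to blocker concentration.  Blocker is acetylcholine
    ("ACh") or the lidocaine derivative QX-222 ("QX-222"); ``variant``
    selects the globally fitted ("free") or core-constrained
    ("constrained") published rate set.
``S3``
    Wild-type muscle AChR activation by ACh with sequential binding
    R -- AR -- A2R, gating from each liganded closed state, and ACh
    open-channel block of the diliganded open state.
``S4``
    S3 plus a QX-222-blocked state off the diliganded open state; the
    published QX rates were estimated at a fixed ACh concentration
    (10 or 30 uM).
``S5``
    Multi-priming spontaneous gating (alternate ancestral subunit):
    shut chain C -- C' -- C'' -- C''' with an open state attached to each
    primed shut state.

All first-order rates are s^-1; association rates (``ligand`` set) are
uM^-1 s^-1 and scale with concentration when a generator is built.
"""

from __future__ import annotations

from .errors import ConfigurationError
from .schemes import OPEN, SHUT, KineticScheme, State, Transition

ACH = "ACh"
QX = "QX-222"

_S1_RATES = {
    "k_plus1_prime": 3900.0,
    "k_minus1_prime": 7600.0,
    "beta_1": 10000.0,
    "alpha_1": 310.0,
}

# (core rates, k_plusB uM^-1 s^-1, k_minusB s^-1) per blocker and variant
_S2_RATES = {
    (ACH, "free"): (
        {"k_plus1_prime": 3500.0, "k_minus1_prime": 5400.0,
         "beta_1": 8000.0, "alpha_1": 330.0},
        170.0, 62000.0,
    ),
    (QX, "free"): (
        {"k_plus1_prime": 4000.0, "k_minus1_prime": 8000.0,
         "beta_1": 10500.0, "alpha_1": 320.0},
        95.0, 1400.0,
    ),
    (ACH, "constrained"): (dict(_S1_RATES), 170.0, 60800.0),
    (QX, "constrained"): (dict(_S1_RATES), 95.0, 1400.0),
}

_S3_RATES = {
    "k_plus1": 650.0,       # uM^-1 s^-1
    "k_minus1": 14400.0,
    "k_plus2": 325.0,       # uM^-1 s^-1
    "k_minus2": 26500.0,
    "beta_1": 33.0,
    "alpha_1": 8750.0,
    "beta_2": 14000.0,
    "alpha_2": 1000.0,
    "k_plusB_ACh": 215.0,   # uM^-1 s^-1
    "k_minusB_ACh": 110000.0,
}

_S4_QX_RATES = {10.0: (100.0, 845.0), 30.0: (110.0, 845.0)}

_S5_RATES = {
    "k_plus1_prime": 2000.0,
    "k_minus1_prime": 2500.0,
    "beta_1": 11500.0,
    "alpha_1": 17000.0,
    "k_plus2_prime": 13650.0,
    "k_minus2_prime": 14800.0,
    "beta_2": 175000.0,
    "alpha_2": 6800.0,
    "k_plus3_prime": 2000.0,
    "k_minus3_prime": 5000.0,
    "beta_3": 40000.0,
    "alpha_3": 500.0,
}


def _s1(name: str = "S1", rates: dict | None = None) -> KineticScheme:
    r = rates or _S1_RATES
    states = (
        State("C", SHUT, role="closed"),
        State("C_prime", SHUT, role="primed-closed"),
        State("O_prime", OPEN, role="open"),
    )
    transitions = (
        Transition("C", "C_prime", "k_plus1_prime", r["k_plus1_prime"]),
        Transition("C_prime", "C", "k_minus1_prime", r["k_minus1_prime"]),
        Transition("C_prime", "O_prime", "beta_1", r["beta_1"]),
        Transition("O_prime", "C_prime", "alpha_1", r["alpha_1"]),
    )
    return KineticScheme(name, states, transitions)


def _s2(blocker: str, variant: str) -> KineticScheme:
    key = (blocker, variant)
    if key not in _S2_RATES:
        raise ConfigurationError(
            f"no published S2 rate set for blocker={blocker!r}, "
            f"variant={variant!r}"
        )
    core, k_on, k_off = _S2_RATES[key]
    base = _s1(f"S2[{blocker},{variant}]", core)
    states = base.states + (State("O_blocked", SHUT, role="open-blocked"),)
    transitions = base.transitions + (
        Transition("O_prime", "O_blocked", "k_plusB", k_on, ligand=blocker),
        Transition("O_blocked", "O_prime", "k_minusB", k_off),
    )
    return KineticScheme(base.name, states, transitions)


def _s3(name: str = "S3", with_ach_block: bool = True) -> KineticScheme:
    r = _S3_RATES
    states = (
        State("R", SHUT, role="closed"),
        State("AR", SHUT, role="monoliganded-closed"),
        State("A2R", SHUT, role="diliganded-closed"),
        State("AR_star", OPEN, role="monoliganded-open"),
        State("A2R_star", OPEN, role="diliganded-open"),
    )
    transitions = [
        Transition("R", "AR", "k_plus1", r["k_plus1"], ligand=ACH),
        Transition("AR", "R", "k_minus1", r["k_minus1"]),
        Transition("AR", "A2R", "k_plus2", r["k_plus2"], ligand=ACH),
        Transition("A2R", "AR", "k_minus2", r["k_minus2"]),
        Transition("AR", "AR_star", "beta_1", r["beta_1"]),
        Transition("AR_star", "AR", "alpha_1", r["alpha_1"]),
        Transition("A2R", "A2R_star", "beta_2", r["beta_2"]),
        Transition("A2R_star", "A2R", "alpha_2", r["alpha_2"]),
    ]
    if with_ach_block:
        states = states + (State("A2R_star_B", SHUT, role="open-blocked"),)
        transitions += [
            Transition("A2R_star", "A2R_star_B", "k_plusB_ACh",
                       r["k_plusB_ACh"], ligand=ACH),
            Transition("A2R_star_B", "A2R_star", "k_minusB_ACh",
                       r["k_minusB_ACh"]),
        ]
    return KineticScheme(name, states, tuple(transitions))


def _s4(ach_concentration_uM: float = 10.0) -> KineticScheme:
    try:
        k_on, k_off = _S4_QX_RATES[float(ach_concentration_uM)]
    except KeyError:
        raise ConfigurationError(
            "published S4 QX-222 rates exist for ACh concentrations of "
            f"10 or 30 uM, not {ach_concentration_uM}"
        ) from None
    base = _s3(f"S4[ACh={ach_concentration_uM:g}uM]")
    states = base.states + (State("A2R_star_QX", SHUT, role="open-blocked"),)
    transitions = base.transitions + (
        Transition("A2R_star", "A2R_star_QX", "k_plusB_QX", k_on, ligand=QX),
        Transition("A2R_star_QX", "A2R_star", "k_minusB_QX", k_off),
    )
    return KineticScheme(base.name, states, transitions)


def _s5() -> KineticScheme:
    r = _S5_RATES
    states = (
        State("C", SHUT, role="closed"),
        State("C_p1", SHUT, role="singly-primed"),
        State("C_p2", SHUT, role="doubly-primed"),
        State("C_p3", SHUT, role="triply-primed"),
        State("O_p1", OPEN, role="open-singly-primed"),
        State("O_p2", OPEN, role="open-doubly-primed"),
        State("O_p3", OPEN, role="open-triply-primed"),
    )
    transitions = (
        Transition("C", "C_p1", "k_plus1_prime", r["k_plus1_prime"]),
        Transition("C_p1", "C", "k_minus1_prime", r["k_minus1_prime"]),
        Transition("C_p1", "C_p2", "k_plus2_prime", r["k_plus2_prime"]),
        Transition("C_p2", "C_p1", "k_minus2_prime", r["k_minus2_prime"]),
        Transition("C_p2", "C_p3", "k_plus3_prime", r["k_plus3_prime"]),
        Transition("C_p3", "C_p2", "k_minus3_prime", r["k_minus3_prime"]),
        Transition("C_p1", "O_p1", "beta_1", r["beta_1"]),
        Transition("O_p1", "C_p1", "alpha_1", r["alpha_1"]),
        Transition("C_p2", "O_p2", "beta_2", r["beta_2"]),
        Transition("O_p2", "C_p2", "alpha_2", r["alpha_2"]),
        Transition("C_p3", "O_p3", "beta_3", r["beta_3"]),
        Transition("O_p3", "C_p3", "alpha_3", r["alpha_3"]),
    )
    return KineticScheme("S5", states, transitions)


def scheme_preset(name: str, **kwargs) -> KineticScheme:
    """Return a built-in scheme by name ("S1" ... "S5").

    Keyword options: S2 takes ``blocker`` ("ACh" | "QX-222") and ``variant``
    ("free" | "constrained"); S4 takes ``ach_concentration_uM`` (10 | 30).
    """
    key = name.upper()
    if key == "S1":
        return _s1()
    if key == "S2":
        return _s2(kwargs.pop("blocker", ACH), kwargs.pop("variant", "free"))
    if key == "S3":
        return _s3()
    if key == "S4":
        return _s4(kwargs.pop("ach_concentration_uM", 10.0))
    if key == "S5":
        return _s5()
    raise ConfigurationError(f"unknown scheme preset {name!r}")


#: Published rate sets, keyed as reported (used by tests and reports).
PUBLISHED_RATES = {
    "S1": dict(_S1_RATES),
    "S2": {
        f"{blocker}:{variant}": {**core, "k_plusB": kon, "k_minusB": koff}
        for (blocker, variant), (core, kon, koff) in _S2_RATES.items()
    },
    "S3": dict(_S3_RATES),
    "S4": {
        conc: {**_S3_RATES, "k_plusB_QX": kon, "k_minusB_QX": koff}
        for conc, (kon, koff) in _S4_QX_RATES.items()
    },
    "S5": dict(_S5_RATES),
}
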