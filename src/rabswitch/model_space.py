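"""Candidate model space for the Rab5-Rab7 conversion switch.

The dynamics of each candidate model follow a fixed two-protein template.
Writing ``r5, r7`` for the passive (GDP-bound) and ``R5, R7`` for the active
(GTP-bound) concentrations of the Rab5 and Rab7 domain proteins::

    dr5/dt = K1 - (k1 + GEF5) * r5 + GAP5 * R5
    dR5/dt = GEF5 * r5 - GAP5 * R5
    dr7/dt = K2 - (k2 + GEF7) * r7 + GAP7 * R7
    dR7/dt = GEF7 * r7 - GAP7 * R7

``K1, K2`` are GDI association fluxes, ``k1, k2`` GDI dissociation rates, and
the four regulatory rate functions GEF5, GAP5, GEF7, GAP7 are functions of the
active-state concentrations ``(R5, R7)``.  A candidate *structure* picks one
kinetic functional form per regulatory slot from the built-in library; GEF7
alternatives may combine a cross-activation component (driven by R5) with an
auto-activation component (driven by R7).  The full library spans
3 * 3 * 7 * 2 = 126 structures.

This module loads the library, enumerates structures, counts process
complexity and compiles a structure into a numerical right-hand-side
evaluator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import yaml

from .errors import InvalidSlotError, MissingParameterError

__all__ = [
    "KineticForm",
    "Library",
    "ModelStructure",
    "CompiledRHS",
    "load_library",
    "enumerate_structures",
    "complexity",
    "compile_rhs",
    "SLOTS",
    "ROOT_PARAMS",
]

#: slot order used for canonical (lexicographic) enumeration
SLOTS = ("gef5", "gap5", "gef7", "gap7")

#: root-template parameters shared by every structure, in packing order
ROOT_PARAMS = ("K1", "k1", "K2", "k2", "r5_0", "R5_0", "r7_0", "R7_0", "K", "td")
N_ROOT = len(ROOT_PARAMS)
IDX_INIT = slice(4, 8)  # r5_0, R5_0, r7_0, R7_0 within a packed vector
IDX_K = 8
IDX_TD = 9

_FORM_CODES = {
    "intrinsic": 0,
    "michaelis_menten": 1,
    "sigmoidal": 2,
    "exchange_inhibition": 3,
    "linear": 4,
}
_REG_CODES = {"R5": 0, "R7": 1, "none": -1}

# component rows in the compiled kinetic table
_COMPONENT_PREFIXES = ("gef5", "gap5", "gef7_cross", "gef7_auto", "gap7")


def _maybe_njit(func):
    try:
        from numba import njit
    except ImportError:  # pragma: no cover - numba is a soft dependency
        return func
    return njit(cache=False)(func)


@_maybe_njit
def _rhs_kernel(y, K1, k1, K2, k2, codes, kin):
    """Evaluate the template derivatives for one state.

    ``codes`` is a (5, 2) int64 array of (form, regulator) codes for the
    components (gef5, gap5, gef7_cross, gef7_auto, gap7); a form code of -1
    marks an absent component.  ``kin`` is the matching (5, 3) float64 array
    of (V-or-k, Km, hill) values.
    """
    rates = np.zeros(5)
    R5 = y[1]
    R7 = y[3]
    for i in range(5):
        form = codes[i, 0]
        if form < 0:
            continue
        reg = codes[i, 1]
        x = 0.0
        if reg == 0:
            x = R5
        elif reg == 1:
            x = R7
        if x < 0.0:
            x = 0.0  # guard against solver micro-undershoot
        V = kin[i, 0]
        Km = kin[i, 1]
        if form == 0:  # intrinsic
            rates[i] = V
        elif form == 1:  # michaelis_menten
            den = Km + x
            rates[i] = V * x / den if den > 0.0 else 0.0
        elif form == 2:  # sigmoidal
            h = kin[i, 2]
            xh = x**h
            den = Km**h + xh
            rates[i] = V * xh / den if den > 0.0 else 0.0
        elif form == 3:  # exchange_inhibition
            den = Km + x
            rates[i] = V * Km / den if den > 0.0 else 0.0
        else:  # linear
            rates[i] = V * x
    gef5 = rates[0]
    gap5 = rates[1]
    gef7 = rates[2] + rates[3]
    gap7 = rates[4]
    out = np.empty(4)
    out[0] = K1 - (k1 + gef5) * y[0] + gap5 * y[1]
    out[1] = gef5 * y[0] - gap5 * y[1]
    out[2] = K2 - (k2 + gef7) * y[2] + gap7 * y[3]
    out[3] = gef7 * y[2] - gap7 * y[3]
    return out


@dataclass(frozen=True)
class KineticForm:
    """One kinetic functional form attached to a regulatory component.

    Parameters
    ----------
    kind
        One of ``intrinsic``, ``michaelis_menten``, ``sigmoidal``,
        ``exchange_inhibition`` or ``linear``.
    regulator
        Which active-state concentration drives the rate: ``R5``, ``R7`` or
        ``none`` (intrinsic forms).
    rate_bounds, km_bounds
        Box bounds for the rate constant (``V`` or ``k``) and, where
        applicable, the half-saturation constant ``Km``.
    hill
        Hill exponent for the sigmoidal form (fixed, not estimated).
    """

    kind: str
    regulator: str
    rate_bounds: tuple[float, float]
    km_bounds: tuple[float, float] | None = None
    hill: float = 3.0

    def __post_init__(self):
        if self.kind not in _FORM_CODES:
            raise ValueError(f"unknown kinetic form kind {self.kind!r}")
        if self.regulator not in _REG_CODES:
            raise ValueError(f"unknown regulator {self.regulator!r}")
        if self.kind == "sigmoidal" and self.hill < 1:
            raise ValueError("sigmoidal form requires a Hill exponent >= 1")
        if self.kind in ("intrinsic", "linear") and self.km_bounds is not None:
            raise ValueError(f"{self.kind} form takes no Km")

    @property
    def has_km(self) -> bool:
        return self.kind in ("michaelis_menten", "sigmoidal", "exchange_inhibition")

    def param_defs(self, prefix: str) -> list[tuple[str, float, float]]:
        """Ordered ``(name, lower, upper)`` entries contributed by this form."""
        rate_name = "V" if self.has_km else "k"
        defs = [(f"{prefix}_{rate_name}", *self.rate_bounds)]
        if self.has_km:
            defs.append((f"{prefix}_Km", *self.km_bounds))
        return defs

    def rate(self, x: float, rate_const: float, km: float | None = None) -> float:
        """Evaluate the form at regulator value ``x``."""
        x = max(float(x), 0.0)
        if self.kind == "intrinsic":
            return rate_const
        if self.kind == "linear":
            return rate_const * x
        if self.kind == "michaelis_menten":
            return rate_const * x / (km + x) if km + x > 0 else 0.0
        if self.kind == "sigmoidal":
            xh = x**self.hill
            den = km**self.hill + xh
            return rate_const * xh / den if den > 0 else 0.0
        den = km + x
        return rate_const * km / den if den > 0 else 0.0  # exchange_inhibition


@dataclass(frozen=True)
class _Alternative:
    """A named slot alternative: one or two kinetic components."""

    name: str
    components: tuple[tuple[str, KineticForm], ...]  # (role, form); role in {main, cross, auto}


@dataclass(frozen=True)
class Library:
    """The declarative collection of slot alternatives and root bounds."""

    slots: Mapping[str, tuple[_Alternative, ...]]
    root_bounds: Mapping[str, tuple[float, float]]
    hill_exponent: float

    def n_alternatives(self, slot: str) -> int:
        return len(self.slots[slot])

    @property
    def n_structures(self) -> int:
        out = 1
        for slot in SLOTS:
            out *= len(self.slots[slot])
        return out

    def complexity_range(self) -> tuple[int, int]:
        """(min, max) process counts over the full library."""
        counts = [complexity(s) for s in enumerate_structures(library=self)]
        return min(counts), max(counts)


def _build_form(node: Mapping, defaults: Mapping, hill: float) -> KineticForm:
    kind = node["form"]
    km = None
    if kind in ("michaelis_menten", "sigmoidal", "exchange_inhibition"):
        km = tuple(node.get("km_bounds", defaults["km_bounds"]))
    return KineticForm(
        kind=kind,
        regulator=node.get("regulator", "none"),
        rate_bounds=tuple(node.get("rate_bounds", defaults["rate_bounds"])),
        km_bounds=km,
        hill=float(node.get("hill_exponent", hill)),
    )


def load_library(path=None, *, bound_overrides: Mapping | None = None) -> Library:
    """Load the built-in library, or a user document with the same schema.

    ``bound_overrides`` may replace any of the default bound entries, e.g.
    ``{"defaults": {"rate_bounds": [0.01, 10]}}`` or
    ``{"root": {"onset_bounds": [0, 50]}}``.
    """
    if path is None:
        text = resources.files(__package__).joinpath("library.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    if bound_overrides:
        for section in ("defaults", "root"):
            doc.setdefault(section, {}).update(bound_overrides.get(section, {}))
    defaults = doc["defaults"]
    hill = float(defaults.get("hill_exponent", 3.0))
    slots: dict[str, tuple[_Alternative, ...]] = {}
    for slot in SLOTS:
        alts = []
        for node in doc["slots"][slot]:
            if "cross" in node or "auto" in node:
                comps = [("cross", _build_form(node["cross"], defaults, hill))]
                if "auto" in node:
                    comps.append(("auto", _build_form(node["auto"], defaults, hill)))
            else:
                comps = [("main", _build_form(node, defaults, hill))]
            alts.append(_Alternative(name=node["name"], components=tuple(comps)))
        slots[slot] = tuple(alts)
    root = doc["root"]
    root_bounds = {
        "K1": tuple(root["flux_bounds"]),
        "k1": tuple(root["flux_bounds"]),
        "K2": tuple(root["flux_bounds"]),
        "k2": tuple(root["flux_bounds"]),
        "r5_0": tuple(root["init_bounds"]),
        "R5_0": tuple(root["init_bounds"]),
        "r7_0": tuple(root["init_bounds"]),
        "R7_0": tuple(root["init_bounds"]),
        "K": tuple(root["scale_bounds"]),
        "td": tuple(root["onset_bounds"]),
    }
    return Library(slots=slots, root_bounds=root_bounds, hill_exponent=hill)


_DEFAULT_LIBRARY: Library | None = None


def default_library() -> Library:
    global _DEFAULT_LIBRARY
    if _DEFAULT_LIBRARY is None:
        _DEFAULT_LIBRARY = load_library()
    return _DEFAULT_LIBRARY


@dataclass(frozen=True)
class ModelStructure:
    """One member of the candidate space: a choice per regulatory slot."""

    gef5: int
    gap5: int
    gef7: int
    gap7: int
    library: Library = field(repr=False, compare=False)

    def __post_init__(self):
        for slot in SLOTS:
            idx = getattr(self, slot)
            n = self.library.n_alternatives(slot)
            if not isinstance(idx, (int, np.integer)) or not 0 <= idx < n:
                raise InvalidSlotError(slot, idx, n)

    @property
    def choices(self) -> tuple[int, int, int, int]:
        return (self.gef5, self.gap5, self.gef7, self.gap7)

    @property
    def index(self) -> int:
        """Canonical index in the full lexicographic enumeration."""
        idx = 0
        for slot, choice in zip(SLOTS, self.choices):
            idx = idx * self.library.n_alternatives(slot) + choice
        return idx

    @property
    def label(self) -> str:
        return f"m{self.index:03d}"

    @property
    def signature(self) -> str:
        """Human-readable slot assignment, e.g. ``gef5=sigmoidal_auto|...``."""
        parts = []
        for slot, choice in zip(SLOTS, self.choices):
            parts.append(f"{slot}={self.library.slots[slot][choice].name}")
        return "|".join(parts)

    def slot_choice_name(self, slot: str) -> str:
        return self.library.slots[slot][getattr(self, slot)].name

    @property
    def components(self) -> tuple[tuple[str, KineticForm], ...]:
        """Kinetic components as ``(prefix, form)`` pairs in packing order."""
        out = []
        for slot in SLOTS:
            alt = self.library.slots[slot][getattr(self, slot)]
            for role, form in alt.components:
                prefix = slot if role == "main" else f"{slot}_{role}"
                out.append((prefix, form))
        return tuple(out)

    @property
    def parameter_space(self) -> tuple[tuple[str, float, float], ...]:
        """Ordered ``(name, lower, upper)`` over root then kinetic parameters."""
        space = [(name, *self.library.root_bounds[name]) for name in ROOT_PARAMS]
        for prefix, form in self.components:
            space.extend(form.param_defs(prefix))
        names = [s[0] for s in space]
        assert len(names) == len(set(names)), "duplicate parameter names"
        return tuple(space)

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.parameter_space)

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_space)


def enumerate_structures(
    constraints: Mapping[str, Iterable[int]] | None = None,
    *,
    library: Library | None = None,
) -> list[ModelStructure]:
    """Enumerate the (optionally constrained) Cartesian product of slot choices.

    ``constraints`` maps a slot name to the allowed alternative indices for
    that slot.  The result is ordered lexicographically by
    ``(gef5, gap5, gef7, gap7)`` indices, which defines the canonical
    structure order used for tie-breaking throughout the package.
    """
    lib = library or default_library()
    constraints = constraints or {}
    for slot in constraints:
        if slot not in SLOTS:
            raise InvalidSlotError(slot, None, 0)
    ranges = []
    for slot in SLOTS:
        n = lib.n_alternatives(slot)
        allowed = constraints.get(slot)
        if allowed is None:
            allowed = range(n)
        else:
            allowed = sorted(set(int(i) for i in allowed))
            for i in allowed:
                if not 0 <= i < n:
                    raise InvalidSlotError(slot, i, n)
        ranges.append(allowed)
    return [
        ModelStructure(*combo, library=lib) for combo in itertools.product(*ranges)
    ]


#: membrane association + dissociation with GDI, per protein: 4 fixed processes
_N_GDI_PROCESSES = 4


def complexity(structure: ModelStructure) -> int:
    """Process count C(m): 4 GDI processes plus one per kinetic component."""
    return _N_GDI_PROCESSES + len(structure.components)


class CompiledRHS:
    """Derivative evaluator for one structure.

    Calling the object with a state and a parameter mapping returns the four
    time-derivatives ``(dr5, dR5, dr7, dR7)``.  For repeated evaluation inside
    an integrator, :meth:`pack` converts a mapping to a flat vector in
    canonical order and :meth:`bind` specialises the evaluator to one vector.
    """

    def __init__(self, structure: ModelStructure):
        self.structure = structure
        space = structure.parameter_space
        self.param_names = tuple(name for name, _, _ in space)
        self.bounds = np.array([[lo, hi] for _, lo, hi in space], dtype=float)
        self._name_to_idx = {name: i for i, name in enumerate(self.param_names)}

        # static (form, regulator) codes and the map from packed-vector
        # positions into the (component, column) cells of the kinetic table
        codes = np.full((5, 2), -1, dtype=np.int64)
        kin_template = np.zeros((5, 3))
        rows, cols, theta_idx = [], [], []
        comp_by_prefix = dict(structure.components)
        pos = N_ROOT
        for row, prefix in enumerate(_COMPONENT_PREFIXES):
            form = comp_by_prefix.get(prefix)
            if form is None:
                continue
            codes[row, 0] = _FORM_CODES[form.kind]
            codes[row, 1] = _REG_CODES[form.regulator]
            kin_template[row, 2] = form.hill
            rows.append(row)
            cols.append(0)
            theta_idx.append(pos)
            pos += 1
            if form.has_km:
                rows.append(row)
                cols.append(1)
                theta_idx.append(pos)
                pos += 1
        assert pos == len(self.param_names)
        self._codes = codes
        self._kin_template = kin_template
        self._kin_rows = np.array(rows, dtype=int)
        self._kin_cols = np.array(cols, dtype=int)
        self._theta_idx = np.array(theta_idx, dtype=int)

    def pack(self, params: Mapping[str, float]) -> np.ndarray:
        """Flatten a parameter mapping into canonical order."""
        missing = [n for n in self.param_names if n not in params]
        if missing:
            raise MissingParameterError(missing)
        return np.array([float(params[n]) for n in self.param_names])

    def unpack(self, theta: Sequence[float]) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.param_names, theta)}

    def bind(self, theta: np.ndarray) -> Callable[[np.ndarray, float], np.ndarray]:
        """Return a fast ``f(y, t)`` closure for a fixed parameter vector."""
        theta = np.asarray(theta, dtype=float)
        K1, k1, K2, k2 = theta[0], theta[1], theta[2], theta[3]
        kin = self._kin_template.copy()
        kin[self._kin_rows, self._kin_cols] = theta[self._theta_idx]
        codes = self._codes

        def rhs(y, t=0.0):
            return _rhs_kernel(y, K1, k1, K2, k2, codes, kin)

        return rhs

    def __call__(self, state, params: Mapping[str, float]) -> np.ndarray:
        y = np.asarray(state, dtype=float)
        return self.bind(self.pack(params))(y)


def compile_rhs(structure: ModelStructure) -> CompiledRHS:
    """Compile a structure into its derivative evaluator."""
    return CompiledRHS(structure)
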