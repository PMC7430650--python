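"""Mass-action reaction schemes for IRES binding to the 40S ribosomal subunit.

The accepted mechanism is a two-step reversible binding reaction with a
conformational partition of the 40S pool:

    40S_in  <-(K'_1/2)->  40S_A
    40S_A + IRES  <-(k1 / k-1)->  [40S-IRES]  <-(k2 / k-2)->  [40S-IRES]*

where 40S_in is a conformation of the small subunit that cannot bind the
IRES, 40S_A is the binding-competent conformation, [40S-IRES] (species C1)
is the initial encounter complex and [40S-IRES]* (species C2) the
conformationally stabilized final complex.  The 40S_in/40S_A partition is
slow on the timescale of a binding experiment and is treated as a static
split fixed at t = 0 by the dimensionless equilibrium constant
K'_1/2 = (fraction 40S_A) / (1 - fraction 40S_A); optional interconversion
rates respecting that ratio can be switched on.

Alternative (rejected) mechanisms are declared in the same framework so
that model comparison can rank them against the two-step scheme:
one-step reversible binding, two-step schemes with one irreversible step,
two parallel reversible binding reactions, and two independent 40S
populations.

Units: concentrations in nM, time in minutes, bimolecular rate constants
in nM^-1 min^-1, first-order rate constants in min^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import odeint

__all__ = [
    "RateConstants",
    "Reaction",
    "ReactionScheme",
    "ExperimentDesign",
    "TimeCourse",
    "SystemState",
    "SCHEME_IDS",
    "build_scheme",
    "scheme_from_params",
    "rates_to_params",
    "simulate",
    "simulate_chase",
    "simulate_states",
    "equilibrium_state",
]

DEFAULT_TEMPERATURE_K = 298.15  # binding reactions performed at 25 C

_RTOL = 1e-8
_ATOL = 1e-12  # nM

# process-wide cache of stoichiometry matrices keyed by scheme topology
_MATRIX_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


@dataclass(frozen=True)
class RateConstants:
    """Rate and equilibrium constants of the two-step binding mechanism.

    Parameters
    ----------
    k1 : float
        Bimolecular association rate constant of step 1, nM^-1 min^-1.
    k_neg1 : float
        Dissociation rate constant of the intermediate complex, min^-1.
    k2 : float
        Forward conformational-conversion rate constant, min^-1.
    k_neg2 : float
        Reverse conversion rate constant, min^-1.
    K_half : float
        Dimensionless equilibrium constant of the 40S_in -> 40S_A
        transition, (fraction 40S_A) / (1 - fraction 40S_A).
    """

    k1: float
    k_neg1: float
    k2: float
    k_neg2: float
    K_half: float

    def __post_init__(self) -> None:
        for name in ("k1", "k_neg1", "k2", "k_neg2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate constant {name} must be finite and >= 0, got {v}")
        if not np.isfinite(self.K_half) or self.K_half <= 0:
            raise ValueError(f"K_half must be finite and > 0, got {self.K_half}")

    @property
    def Kd1(self) -> float:
        """Equilibrium dissociation constant of step 1, k-1/k1, in nM."""
        if self.k1 == 0:
            raise ZeroDivisionError("Kd1 undefined for k1 == 0")
        return self.k_neg1 / self.k1

    @property
    def K2(self) -> float:
        """Equilibrium constant of step 2, k2/k-2 (dimensionless)."""
        if self.k_neg2 == 0:
            raise ZeroDivisionError("K2 undefined for k_neg2 == 0")
        return self.k2 / self.k_neg2

    @property
    def fraction_active(self) -> float:
        """Fraction of 40S in the binding-competent 40S_A conformation."""
        return self.K_half / (1.0 + self.K_half)

    def as_dict(self) -> dict[str, float]:
        return {
            "k1": self.k1,
            "k_neg1": self.k_neg1,
            "k2": self.k2,
            "k_neg2": self.k_neg2,
            "K_half": self.K_half,
        }


@dataclass(frozen=True)
class Reaction:
    """One elementary mass-action reaction.

    Reactants/products are species names repeated by stoichiometric
    multiplicity; ``rate_symbol`` names the governing rate parameter.
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_symbol: str


@dataclass(frozen=True)
class ExperimentDesign:
    """Conditions of one filter-binding experiment."""

    mode: str  # "association" | "chase"
    conc_40S_total: float  # nM
    conc_IRES_labeled: float  # nM
    timepoints: tuple[float, ...]  # min; chase: measured from competitor addition
    preincubation: float | None = None  # min, chase only
    conc_competitor: float | None = None  # nM, chase only
    temperature: float = DEFAULT_TEMPERATURE_K  # K
    experiment_id: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("association", "chase"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.conc_40S_total <= 0 or self.conc_IRES_labeled <= 0:
            raise ValueError("concentrations must be > 0")
        t = np.asarray(self.timepoints, dtype=float)
        if t.size == 0 or np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be non-negative and strictly increasing")
        if self.mode == "chase":
            if self.preincubation is None or self.preincubation <= 0:
                raise ValueError("chase mode requires preincubation > 0")
            if self.conc_competitor is None or self.conc_competitor <= 0:
                raise ValueError("chase mode requires conc_competitor > 0")


@dataclass
class TimeCourse:
    """A (time, fraction-bound) trace for one experiment."""

    design: ExperimentDesign
    times: np.ndarray  # min
    frac_bound: np.ndarray
    sigma: np.ndarray | None = None  # per-point uncertainty of frac_bound

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.frac_bound = np.asarray(self.frac_bound, dtype=float)
        if self.times.shape != self.frac_bound.shape:
            raise ValueError("times and frac_bound must have equal length")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.times.shape:
                raise ValueError("sigma must match times in length")

    @property
    def out_of_range(self) -> np.ndarray:
        """Boolean mask of points outside [0, 1] (possible with noise)."""
        return (self.frac_bound < 0.0) | (self.frac_bound > 1.0)

    def __len__(self) -> int:
        return self.times.size


@dataclass
class SystemState:
    """Species concentrations (nM) at one instant."""

    concentrations: dict[str, float]
    time: float  # min; inf marks an equilibrium state

    def __getitem__(self, species: str) -> float:
        return self.concentrations[species]


@dataclass
class ReactionScheme:
    """A declared mechanism: species, reactions, observable and initial state.

    ``params`` holds every fit parameter (reaction rate constants plus
    partition constants such as K_half); ``pools_40S`` gives the t = 0 split
    of total 40S over its pools as (species, fraction) pairs derived from
    the partition parameters.
    """

    scheme_id: str
    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    params: dict[str, float]
    observable: tuple[str, ...]  # labeled complex species; signal = sum/IRES_total
    param_names: tuple[str, ...]
    association_symbols: frozenset[str]  # bimolecular symbols suppressed in a chase
    pools_40S: tuple[tuple[str, float], ...]
    species_40S: tuple[str, ...]  # all species containing a 40S subunit
    species_ires: tuple[str, ...]  # all species containing labeled IRES
    ires_species: str = "IRES"

    # cached stoichiometry (built lazily)
    _stoich: np.ndarray | None = field(default=None, repr=False, compare=False)
    _orders: np.ndarray | None = field(default=None, repr=False, compare=False)
    _reactant_idx: tuple | None = field(default=None, repr=False, compare=False)

    def rate_vector(self, suppress: frozenset[str] = frozenset()) -> np.ndarray:
        return np.array(
            [0.0 if r.rate_symbol in suppress else self.params[r.rate_symbol]
             for r in self.reactions]
        )

    def matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """Stoichiometry matrix (n_species x n_rxn) and reactant orders.

        The reaction topology is fixed by (scheme_id, species, reactions),
        so the matrices are cached process-wide across rebuilds of the
        same scheme with new parameter values.
        """
        if self._stoich is None:
            key = (self.scheme_id, len(self.species), len(self.reactions))
            cached = _MATRIX_CACHE.get(key)
            if cached is None:
                idx = {s: i for i, s in enumerate(self.species)}
                S = np.zeros((len(self.species), len(self.reactions)))
                orders = np.zeros((len(self.reactions), len(self.species)))
                for j, rxn in enumerate(self.reactions):
                    for r in rxn.reactants:
                        S[idx[r], j] -= 1.0
                        orders[j, idx[r]] += 1.0
                    for p in rxn.products:
                        S[idx[p], j] += 1.0
                reactant_idx = tuple(
                    tuple(i for i in range(orders.shape[1])
                          for _ in range(int(orders[j, i])))
                    for j in range(orders.shape[0])
                )
                cached = (S, orders, reactant_idx)
                _MATRIX_CACHE[key] = cached
            object.__setattr__(self, "_stoich", cached[0])
            object.__setattr__(self, "_orders", cached[1])
            object.__setattr__(self, "_reactant_idx", cached[2])
        return self._stoich, self._orders

    @property
    def reactant_indices(self) -> tuple[tuple[int, ...], ...]:
        self.matrices()
        return self._reactant_idx

    def initial_concentrations(self, conc_40S: float, conc_IRES: float) -> np.ndarray:
        y0 = np.zeros(len(self.species))
        idx = {s: i for i, s in enumerate(self.species)}
        for pool, frac in self.pools_40S:
            y0[idx[pool]] = frac * conc_40S
        y0[idx[self.ires_species]] = conc_IRES
        return y0

    def with_params(self, params: Mapping[str, float]) -> "ReactionScheme":
        """Rebuild this scheme with a new parameter set."""
        return scheme_from_params(self.scheme_id, dict(params))


def _partition(K: float) -> tuple[float, float]:
    """(active, inactive) fractions from a ratio-form equilibrium constant."""
    f = K / (1.0 + K)
    return f, 1.0 - f


def _two_step_reversible(p: Mapping[str, float]) -> ReactionScheme:
    f_a, f_in = _partition(p["K_half"])
    reactions = [
        Reaction(("40S_A", "IRES"), ("C1",), "k1"),
        Reaction(("C1",), ("40S_A", "IRES"), "k_neg1"),
        Reaction(("C1",), ("C2",), "k2"),
        Reaction(("C2",), ("C1",), "k_neg2"),
    ]
    params = dict(p)
    # optional slow 40S_in <-> 40S_A interconversion with ratio K_half
    k_ex = params.get("interconversion_rate", 0.0)
    if k_ex > 0:
        reactions += [
            Reaction(("40S_in",), ("40S_A",), "_k_act"),
            Reaction(("40S_A",), ("40S_in",), "_k_inact"),
        ]
        params["_k_act"] = k_ex * p["K_half"]
        params["_k_inact"] = k_ex
    return ReactionScheme(
        scheme_id="two_step_reversible",
        species=("40S_in", "40S_A", "IRES", "C1", "C2"),
        reactions=tuple(reactions),
        params=params,
        observable=("C1", "C2"),
        param_names=("k1", "k_neg1", "k2", "k_neg2", "K_half"),
        association_symbols=frozenset({"k1"}),
        pools_40S=(("40S_A", f_a), ("40S_in", f_in)),
        species_40S=("40S_in", "40S_A", "C1", "C2"),
        species_ires=("IRES", "C1", "C2"),
    )


def _one_step_reversible(p: Mapping[str, float]) -> ReactionScheme:
    f_a, f_in = _partition(p["K_half"])
    return ReactionScheme(
        scheme_id="one_step_reversible",
        species=("40S_in", "40S_A", "IRES", "C1"),
        reactions=(
            Reaction(("40S_A", "IRES"), ("C1",), "k1"),
            Reaction(("C1",), ("40S_A", "IRES"), "k_neg1"),
        ),
        params=dict(p),
        observable=("C1",),
        param_names=("k1", "k_neg1", "K_half"),
        association_symbols=frozenset({"k1"}),
        pools_40S=(("40S_A", f_a), ("40S_in", f_in)),
        species_40S=("40S_in", "40S_A", "C1"),
        species_ires=("IRES", "C1"),
    )


def _two_step_irrev1(p: Mapping[str, float]) -> ReactionScheme:
    """Two steps, irreversible association (k-1 = 0 by construction)."""
    f_a, f_in = _partition(p["K_half"])
    return ReactionScheme(
        scheme_id="two_step_irrev1",
        species=("40S_in", "40S_A", "IRES", "C1", "C2"),
        reactions=(
            Reaction(("40S_A", "IRES"), ("C1",), "k1"),
            Reaction(("C1",), ("C2",), "k2"),
            Reaction(("C2",), ("C1",), "k_neg2"),
        ),
        params=dict(p),
        observable=("C1", "C2"),
        param_names=("k1", "k2", "k_neg2", "K_half"),
        association_symbols=frozenset({"k1"}),
        pools_40S=(("40S_A", f_a), ("40S_in", f_in)),
        species_40S=("40S_in", "40S_A", "C1", "C2"),
        species_ires=("IRES", "C1", "C2"),
    )


def _two_step_irrev2(p: Mapping[str, float]) -> ReactionScheme:
    """Two steps, irreversible conversion (k-2 = 0 by construction)."""
    f_a, f_in = _partition(p["K_half"])
    return ReactionScheme(
        scheme_id="two_step_irrev2",
        species=("40S_in", "40S_A", "IRES", "C1", "C2"),
        reactions=(
            Reaction(("40S_A", "IRES"), ("C1",), "k1"),
            Reaction(("C1",), ("40S_A", "IRES"), "k_neg1"),
            Reaction(("C1",), ("C2",), "k2"),
        ),
        params=dict(p),
        observable=("C1", "C2"),
        param_names=("k1", "k_neg1", "k2", "K_half"),
        association_symbols=frozenset({"k1"}),
        pools_40S=(("40S_A", f_a), ("40S_in", f_in)),
        species_40S=("40S_in", "40S_A", "C1", "C2"),
        species_ires=("IRES", "C1", "C2"),
    )


def _parallel_reversible(p: Mapping[str, float]) -> ReactionScheme:
    """Two independent reversible complexes formed from one 40S pool."""
    f_a, f_in = _partition(p["K_half"])
    return ReactionScheme(
        scheme_id="parallel_reversible",
        species=("40S_in", "40S_A", "IRES", "Ca", "Cb"),
        reactions=(
            Reaction(("40S_A", "IRES"), ("Ca",), "k1a"),
            Reaction(("Ca",), ("40S_A", "IRES"), "k_neg1a"),
            Reaction(("40S_A", "IRES"), ("Cb",), "k1b"),
            Reaction(("Cb",), ("40S_A", "IRES"), "k_neg1b"),
        ),
        params=dict(p),
        observable=("Ca", "Cb"),
        param_names=("k1a", "k_neg1a", "k1b", "k_neg1b", "K_half"),
        association_symbols=frozenset({"k1a", "k1b"}),
        pools_40S=(("40S_A", f_a), ("40S_in", f_in)),
        species_40S=("40S_in", "40S_A", "Ca", "Cb"),
        species_ires=("IRES", "Ca", "Cb"),
    )


def _two_populations(p: Mapping[str, float]) -> ReactionScheme:
    """Two 40S pools with independent one-step binding; K_mix sets the split."""
    f_a, f_b = _partition(p["K_mix"])
    return ReactionScheme(
        scheme_id="two_populations",
        species=("40S_a", "40S_b", "IRES", "Ca", "Cb"),
        reactions=(
            Reaction(("40S_a", "IRES"), ("Ca",), "k1a"),
            Reaction(("Ca",), ("40S_a", "IRES"), "k_neg1a"),
            Reaction(("40S_b", "IRES"), ("Cb",), "k1b"),
            Reaction(("Cb",), ("40S_b", "IRES"), "k_neg1b"),
        ),
        params=dict(p),
        observable=("Ca", "Cb"),
        param_names=("k1a", "k_neg1a", "k1b", "k_neg1b", "K_mix"),
        association_symbols=frozenset({"k1a", "k1b"}),
        pools_40S=(("40S_a", f_a), ("40S_b", f_b)),
        species_40S=("40S_a", "40S_b", "Ca", "Cb"),
        species_ires=("IRES", "Ca", "Cb"),
    )


_SCHEME_BUILDERS: dict[str, Callable[[Mapping[str, float]], ReactionScheme]] = {
    "two_step_reversible": _two_step_reversible,
    "one_step_reversible": _one_step_reversible,
    "two_step_irrev1": _two_step_irrev1,
    "two_step_irrev2": _two_step_irrev2,
    "parallel_reversible": _parallel_reversible,
    "two_populations": _two_populations,
}

SCHEME_IDS = tuple(_SCHEME_BUILDERS)

# Mapping from the canonical two-step RateConstants onto each alternative
# scheme's parameters.  For the parallel/two-population schemes the pairs
# (k1, k_neg1) and (k2, k_neg2) seed the two binding pathways and K_half
# seeds the pool split; these are starting values for a fit, not mechanistic
# identities.
_RATES_MAP: dict[str, dict[str, str]] = {
    "two_step_reversible": {n: n for n in ("k1", "k_neg1", "k2", "k_neg2", "K_half")},
    "one_step_reversible": {"k1": "k1", "k_neg1": "k_neg1", "K_half": "K_half"},
    "two_step_irrev1": {"k1": "k1", "k2": "k2", "k_neg2": "k_neg2", "K_half": "K_half"},
    "two_step_irrev2": {"k1": "k1", "k_neg1": "k_neg1", "k2": "k2", "K_half": "K_half"},
    "parallel_reversible": {
        "k1a": "k1", "k_neg1a": "k_neg1", "k1b": "k2", "k_neg1b": "k_neg2",
        "K_half": "K_half",
    },
    "two_populations": {
        "k1a": "k1", "k_neg1a": "k_neg1", "k1b": "k2", "k_neg1b": "k_neg2",
        "K_mix": "K_half",
    },
}


def rates_to_params(scheme_id: str, rates: RateConstants) -> dict[str, float]:
    """Map the canonical RateConstants onto a scheme's own parameter names."""
    if scheme_id not in _RATES_MAP:
        raise ValueError(f"unknown scheme_id {scheme_id!r}; known: {sorted(_RATES_MAP)}")
    src = rates.as_dict()
    out = {}
    for name, origin in _RATES_MAP[scheme_id].items():
        v = src[origin]
        if name in ("K_half", "K_mix"):
            v = max(v, 1e-12)
        out[name] = v
    return out


def scheme_from_params(scheme_id: str, params: Mapping[str, float]) -> ReactionScheme:
    """Build a scheme directly from its own parameter dictionary."""
    if scheme_id not in _SCHEME_BUILDERS:
        raise ValueError(f"unknown scheme_id {scheme_id!r}; known: {sorted(_SCHEME_BUILDERS)}")
    for name, v in params.items():
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"parameter {name} must be finite and >= 0, got {v}")
    return _SCHEME_BUILDERS[scheme_id](params)


def build_scheme(
    scheme_id: str,
    rates: RateConstants,
    interconversion_rate: float = 0.0,
) -> ReactionScheme:
    """Declare a mechanism with parameters taken from ``rates``.

    Parameters
    ----------
    scheme_id : str
        One of :data:`SCHEME_IDS`.
    rates : RateConstants
        Canonical two-step constants; mapped onto the scheme's parameters.
    interconversion_rate : float
        Optional 40S_in -> 40S_A exchange rate (min^-1) for the two-step
        scheme; 0 (default) keeps the partition static.
    """
    params = rates_to_params(scheme_id, rates)
    if interconversion_rate:
        if scheme_id != "two_step_reversible":
            raise ValueError("interconversion_rate only applies to two_step_reversible")
        params["interconversion_rate"] = interconversion_rate
    return scheme_from_params(scheme_id, params)


class SimulationError(RuntimeError):
    """Raised when the ODE integrator fails for a given condition."""


def _integrate(
    scheme: ReactionScheme,
    y0: np.ndarray,
    times: np.ndarray,
    suppress: frozenset[str] = frozenset(),
    rtol: float = _RTOL,
    atol: float = _ATOL,
) -> np.ndarray:
    """Integrate the mass-action ODEs; returns concentrations at ``times``.

    ``times`` must start at the initial instant of ``y0``.
    """
    S, orders = scheme.matrices()
    k = scheme.rate_vector(suppress)
    if not np.any(k):
        return np.tile(y0, (times.size, 1))
    # reactant index tuple per reaction, repeated by stoichiometric order
    reactant_idx = scheme.reactant_indices

    n_r = len(reactant_idx)

    def rhs(y: np.ndarray, _t: float) -> np.ndarray:
        yc = np.where(y > 0.0, y, 0.0)
        flux = k.copy()
        for j, idxs in enumerate(reactant_idx):
            for i in idxs:
                flux[j] *= yc[i]
        return S @ flux

    def jac(y: np.ndarray, _t: float) -> np.ndarray:
        yc = np.where(y > 0.0, y, 0.0)
        Jf = np.zeros((n_r, y.size))
        for j, idxs in enumerate(reactant_idx):
            for m, i in enumerate(idxs):
                p = k[j]
                for mm, ii in enumerate(idxs):
                    if mm != m:
                        p *= yc[ii]
                Jf[j, i] += p
        return S @ Jf

    with np.errstate(all="ignore"):
        y, info = odeint(
            rhs, y0, times, Dfun=jac, rtol=rtol, atol=atol,
            mxstep=10000, full_output=True,
        )
    if info["message"] != "Integration successful.":
        raise SimulationError(
            f"ODE integration failed for scheme {scheme.scheme_id}: {info['message']}"
        )
    if not np.all(np.isfinite(y)):
        raise SimulationError(f"non-finite trajectory for scheme {scheme.scheme_id}")
    return y


def _observable(scheme: ReactionScheme, y: np.ndarray, conc_IRES: float) -> np.ndarray:
    idx = {s: i for i, s in enumerate(scheme.species)}
    cols = [idx[s] for s in scheme.observable]
    return y[:, cols].sum(axis=1) / conc_IRES


def _with_zero(times: np.ndarray) -> tuple[np.ndarray, bool]:
    """Prepend t = 0 if absent; odeint requires output from the start."""
    if times[0] == 0.0:
        return times, False
    return np.concatenate(([0.0], times)), True


def simulate(
    scheme: ReactionScheme,
    design: ExperimentDesign,
    rtol: float = _RTOL,
    atol: float = _ATOL,
) -> TimeCourse:
    """Simulate an association experiment and return the fraction bound.

    Starts from free labeled IRES plus the partitioned 40S pools with no
    preformed complex and integrates the scheme's mass-action ODEs to each
    design timepoint.
    """
    if design.mode != "association":
        raise ValueError(f"simulate expects an association design, got {design.mode!r}")
    times = np.asarray(design.timepoints, dtype=float)
    grid, added = _with_zero(times)
    y0 = scheme.initial_concentrations(design.conc_40S_total, design.conc_IRES_labeled)
    y = _integrate(scheme, y0, grid, rtol=rtol, atol=atol)
    frac = _observable(scheme, y, design.conc_IRES_labeled)
    if added:
        frac = frac[1:]
    return TimeCourse(design=design, times=times, frac_bound=frac)


def simulate_chase(
    scheme: ReactionScheme,
    design: ExperimentDesign,
    competitor: str = "flux_zero",
    rtol: float = _RTOL,
    atol: float = _ATOL,
) -> TimeCourse:
    """Simulate a cold-competitor chase experiment.

    Phase 1 associates labeled IRES with 40S for ``design.preincubation``
    minutes.  Phase 2 models the competitor either by zeroing the labeled
    association flux (``competitor="flux_zero"``; the large excess of cold
    IRES captures every free 40S the instant it dissociates) or by adding
    explicit cold species with identical rate constants
    (``competitor="explicit"``).  Returned times run from competitor
    addition.
    """
    if design.mode != "chase":
        raise ValueError(f"simulate_chase expects a chase design, got {design.mode!r}")
    if competitor not in ("flux_zero", "explicit"):
        raise ValueError(f"unknown competitor mode {competitor!r}")
    times = np.asarray(design.timepoints, dtype=float)
    y0 = scheme.initial_concentrations(design.conc_40S_total, design.conc_IRES_labeled)
    pre = _integrate(
        scheme, y0, np.array([0.0, design.preincubation]), rtol=rtol, atol=atol
    )
    y_start = pre[-1]
    grid, added = _with_zero(times)
    if competitor == "flux_zero":
        y = _integrate(
            scheme, y_start, grid, suppress=scheme.association_symbols,
            rtol=rtol, atol=atol,
        )
        frac = _observable(scheme, y, design.conc_IRES_labeled)
    else:
        cold, y0_cold = _cold_extension(scheme, y_start, design.conc_competitor)
        y = _integrate(cold, y0_cold, grid, rtol=rtol, atol=atol)
        frac = _observable(cold, y, design.conc_IRES_labeled)
    if added:
        frac = frac[1:]
    return TimeCourse(design=design, times=times, frac_bound=frac)


def _cold_extension(
    scheme: ReactionScheme, y_start: np.ndarray, conc_competitor: float
) -> tuple[ReactionScheme, np.ndarray]:
    """Extend a scheme with cold-IRES counterparts of every labeled species.

    The competitor is chemically identical to the labeled IRES, so every
    reaction consuming or producing an IRES-containing species is mirrored
    with the same rate symbol.  The observable still tracks labeled
    complexes only.
    """
    labeled = set(scheme.species_ires)
    cold_of = {s: f"{s}_cold" for s in scheme.species_ires}
    species = scheme.species + tuple(cold_of[s] for s in scheme.species_ires)
    reactions = list(scheme.reactions)
    for rxn in scheme.reactions:
        if any(s in labeled for s in rxn.reactants + rxn.products):
            reactions.append(
                Reaction(
                    tuple(cold_of.get(s, s) for s in rxn.reactants),
                    tuple(cold_of.get(s, s) for s in rxn.products),
                    rxn.rate_symbol,
                )
            )
    ext = replace(
        scheme,
        species=species,
        reactions=tuple(reactions),
        species_40S=scheme.species_40S
        + tuple(cold_of[s] for s in scheme.species_ires if s in scheme.species_40S),
        _stoich=None,
        _orders=None,
        _reactant_idx=None,
    )
    y0 = np.zeros(len(species))
    y0[: y_start.size] = y_start
    y0[species.index(cold_of[scheme.ires_species])] = conc_competitor
    return ext, y0


def simulate_states(
    scheme: ReactionScheme,
    design: ExperimentDesign,
    rtol: float = _RTOL,
    atol: float = _ATOL,
) -> list[SystemState]:
    """Full species trajectories of an association run (for diagnostics)."""
    if design.mode != "association":
        raise ValueError("simulate_states expects an association design")
    times = np.asarray(design.timepoints, dtype=float)
    grid, added = _with_zero(times)
    y0 = scheme.initial_concentrations(design.conc_40S_total, design.conc_IRES_labeled)
    y = _integrate(scheme, y0, grid, rtol=rtol, atol=atol)
    if added:
        y, grid = y[1:], grid[1:]
    return [
        SystemState(dict(zip(scheme.species, row)), t) for row, t in zip(y, grid)
    ]


def conservation_error(scheme: ReactionScheme, states: Sequence[SystemState],
                       total_40S: float, total_IRES: float) -> float:
    """Worst absolute deviation of the 40S and IRES conservation sums (nM)."""
    worst = 0.0
    for st in states:
        s40 = sum(st.concentrations[s] for s in scheme.species_40S)
        sir = sum(st.concentrations[s] for s in scheme.species_ires)
        worst = max(worst, abs(s40 - total_40S), abs(sir - total_IRES))
    return worst


def equilibrium_state(
    rates: RateConstants, conc_40S: float, conc_IRES: float
) -> SystemState:
    """Closed-form equilibrium of the two-step mechanism.

    Lumping both complexes gives a single binding equilibrium with an
    effective dissociation constant Kd_eff = Kd1 / (1 + K2); the bound
    amount then follows from the standard quadratic in total bound
    complex, and C1/C2 split according to K2.  Serves as an independent
    oracle for ODE plateaus.
    """
    if rates.k1 <= 0:
        raise ValueError("equilibrium undefined for k1 == 0 (no binding)")
    f_a = rates.fraction_active
    a_tot = f_a * conc_40S
    if conc_IRES == 0 or a_tot == 0:
        return SystemState(
            {"40S_in": (1 - f_a) * conc_40S, "40S_A": a_tot, "IRES": conc_IRES,
             "C1": 0.0, "C2": 0.0},
            np.inf,
        )
    K2 = rates.k2 / rates.k_neg2 if rates.k_neg2 > 0 else 0.0
    if rates.k_neg2 == 0 and rates.k2 > 0:
        # step 2 irreversible: everything bound ends in C2, binding goes to
        # completion of the limiting species
        b = min(a_tot, conc_IRES)
        return SystemState(
            {"40S_in": (1 - f_a) * conc_40S, "40S_A": a_tot - b,
             "IRES": conc_IRES - b, "C1": 0.0, "C2": b},
            np.inf,
        )
    kd_eff = rates.Kd1 / (1.0 + K2)
    s = a_tot + conc_IRES + kd_eff
    bound = (s - np.sqrt(s * s - 4.0 * a_tot * conc_IRES)) / 2.0
    c1 = bound / (1.0 + K2)
    c2 = bound - c1
    return SystemState(
        {
            "40S_in": (1 - f_a) * conc_40S,
            "40S_A": a_tot - bound,
            "IRES": conc_IRES - bound,
            "C1": c1,
            "C2": c2,
        },
        np.inf,
    )
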