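"""State space, parameters and rate laws of the ferritin iron-storage model.

The model describes a population of ferritin nanocages exchanging iron with
the cytosolic labile iron pool (cLIP).  To keep the state space tractable,
iron is lumped into *packages* of ``Fe_pack`` atoms (50 by default), so a
cage holding up to 2,500 atoms is indexed by its core load ``i = 0..N``
packages (``N = 50``).  Three families of species are tracked, all as
per-cell picomole amounts:

* ``Fe`` -- free iron packages, the cLIP;
* ``Fn_i`` -- ferritin cages with ``i`` packages mineralized in the core;
* ``C_i`` -- Michaelis-type complexes of a cage with ``i`` core packages
  plus one reversibly bound package awaiting oxidation.

The elementary processes are mass-action: reversible binding of a free
package to any cage (``k_aso``/``k_dis``), catalytic commitment of the bound
package to the mineral core (``k_cat``, ferroxidase step; full cages cannot
mineralize further), load-dependent first-order release of one package from
the core (Hill-saturating ``k_loss_i``), and proteolytic turnover (``k_d``)
that returns a cage's whole core to the cLIP while synthesis replenishes the
empty-cage pool, keeping total ferritin constant.

Iron and ferritin are conserved exactly by the right-hand side; this is the
primary structural oracle used by the test suite.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ConfigurationError",
    "PackingScheme",
    "ModelParameters",
    "SystemState",
    "make_parameters",
    "k_loss_rate",
    "k_loss_vector",
    "derivatives",
    "total_iron",
    "total_ferritin",
    "initial_state",
    "repack_parameters",
    "equation_count",
]


class ConfigurationError(KeyError):
    """An unknown parameter name was supplied."""


@dataclass(frozen=True)
class PackingScheme:
    """How iron atoms are lumped into packages and how much a cage holds.

    ``n_packages`` (the chain length N) is derived as
    ``effective_capacity_atoms / atoms_per_package`` and must divide evenly.
    The effective capacity (2,500 atoms) is below the theoretical cage
    capacity (4,500 atoms) because ferritin precipitates in vitro beyond
    ~2,500 Fe/cage.
    """

    atoms_per_package: int = 50
    max_capacity_atoms: int = 4500
    effective_capacity_atoms: int = 2500

    def __post_init__(self) -> None:
        for name in (
            "atoms_per_package",
            "max_capacity_atoms",
            "effective_capacity_atoms",
        ):
            value = getattr(self, name)
            if not float(value).is_integer() or value <= 0:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        if self.effective_capacity_atoms > self.max_capacity_atoms:
            raise ValueError(
                "effective_capacity_atoms must not exceed max_capacity_atoms"
            )
        if self.effective_capacity_atoms % self.atoms_per_package != 0:
            raise ValueError(
                "effective_capacity_atoms must be divisible by atoms_per_package "
                f"({self.effective_capacity_atoms} / {self.atoms_per_package})"
            )

    @property
    def n_packages(self) -> int:
        """Maximum number of core packages a cage can store (N)."""
        return self.effective_capacity_atoms // self.atoms_per_package


@dataclass(frozen=True)
class ModelParameters:
    """Kinetic constants, Hill release law and initial amounts.

    Units: first-order rates in hr^-1; ``k_aso`` in
    (pmol-packages cell^-1)^-1 hr^-1; amounts in pmol cell^-1 (iron on the
    packages basis).  Defaults are the published parameter set for Caco-2
    cells / horse-spleen ferritin.
    """

    k_aso: float = 1.6955e15
    k_dis: float = 8.25192e7
    k_cat: float = 7.776e6
    k_d: float = 4.33e-2
    k_loss_base: float = 2.56e7
    hill_n: float = 1.0
    hill_theta: float = 1.0
    hill_kappa: float = 2.4
    fn_total: float = 5.52e-7
    fe_initial: float = 2.7880e-5
    packing: PackingScheme = field(default_factory=PackingScheme)

    def __post_init__(self) -> None:
        for name in (
            "k_aso",
            "k_dis",
            "k_cat",
            "k_d",
            "k_loss_base",
            "hill_kappa",
            "fn_total",
            "fe_initial",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.hill_theta <= 0:
            raise ValueError("hill_theta must be positive")
        if self.hill_n < 1:
            raise ValueError("hill_n must be >= 1")

    @property
    def n_packages(self) -> int:
        return self.packing.n_packages


_PACKING_FIELDS = {f.name for f in dataclasses.fields(PackingScheme)}
_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParameters)} - {"packing"}


def make_parameters(**overrides) -> ModelParameters:
    """Build a :class:`ModelParameters` from the defaults plus overrides.

    Packing fields (``atoms_per_package``, ``max_capacity_atoms``,
    ``effective_capacity_atoms``) may be given flat; N is recomputed.
    Unknown keys raise :class:`ConfigurationError`; invalid values raise
    ``ValueError`` naming the offending field.
    """
    packing = overrides.pop("packing", None)
    pack_kw: dict = {}
    par_kw: dict = {}
    for key, value in overrides.items():
        if key in _PACKING_FIELDS:
            pack_kw[key] = value
        elif key in _PARAM_FIELDS:
            par_kw[key] = value
        else:
            raise ConfigurationError(f"unknown parameter {key!r}")
    if packing is None:
        packing = PackingScheme()
    if pack_kw:
        packing = replace(packing, **pack_kw)
    return ModelParameters(packing=packing, **par_kw)


@dataclass
class SystemState:
    """One point of the 2N+3 dimensional state: cLIP, cages and complexes.

    ``fe`` is the free iron amount (pmol-packages cell^-1); ``fn[i]`` and
    ``c[i]`` are the per-load-class protein amounts (pmol-ferritin cell^-1)
    for i = 0..N.
    """

    fe: float
    fn: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        self.fe = float(self.fe)
        self.fn = np.asarray(self.fn, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.fn.ndim != 1 or self.fn.shape != self.c.shape:
            raise ValueError(
                "fn and c must be 1-d arrays of equal length "
                f"(got {self.fn.shape} and {self.c.shape})"
            )

    @property
    def n_packages(self) -> int:
        return len(self.fn) - 1

    def to_vector(self) -> np.ndarray:
        """Pack into the solver layout [Fe, Fn_0..Fn_N, C_0..C_N]."""
        return np.concatenate(([self.fe], self.fn, self.c))

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "SystemState":
        y = np.asarray(y, dtype=float)
        if y.ndim != 1 or (len(y) - 3) % 2 != 0 or len(y) < 5:
            raise ValueError(f"state vector length must be 2N+3, got {len(y)}")
        n = (len(y) - 3) // 2
        return cls(fe=y[0], fn=y[1 : n + 2].copy(), c=y[n + 2 :].copy())

    def copy(self) -> "SystemState":
        return SystemState(self.fe, self.fn.copy(), self.c.copy())


def k_loss_rate(i, params: ModelParameters):
    """Load-dependent iron-release rate constant (hr^-1).

    Hill form: ``k̃_loss`` for an empty core and
    ``k̃_loss * (1 + κ·i^n / (θ^n + i^n))`` for ``i >= 1`` — release speeds
    up with the exposed mineral surface at small cores and saturates (pore
    availability) at ``(1 + κ)·k̃_loss`` for large ones.

    Accepts a scalar or array of loads; loads outside ``[0, N]`` raise
    ``ValueError``.
    """
    arr = np.asarray(i, dtype=float)
    if np.any(arr < 0) or np.any(arr > params.n_packages):
        raise ValueError(f"load index out of range [0, {params.n_packages}]: {i!r}")
    powered = arr**params.hill_n
    hill = params.hill_kappa * powered / (params.hill_theta**params.hill_n + powered)
    out = params.k_loss_base * (1.0 + hill)
    if np.ndim(i) == 0:
        return float(out)
    return out


def k_loss_vector(params: ModelParameters) -> np.ndarray:
    """``k_loss_rate`` evaluated at every load 0..N (index 0 is unused by
    the rate equations: an empty core has nothing to release)."""
    return np.asarray(k_loss_rate(np.arange(params.n_packages + 1), params))


def _rhs(y: np.ndarray, p: ModelParameters, kloss: np.ndarray) -> np.ndarray:
    """Time derivative of the packed state vector (mass balances)."""
    n = len(kloss) - 1
    fe = y[0]
    fn = y[1 : n + 2]
    c = y[n + 2 :]
    i_arr = np.arange(n + 1)

    dfe = (
        p.k_dis * c.sum()
        + p.k_d * (i_arr * fn).sum()
        + (kloss[1:] * fn[1:]).sum()
        - p.k_aso * fe * fn.sum()
    )

    dfn = np.empty(n + 1)
    # interior and top classes share the loss/degradation/binding terms
    dfn[1:] = (
        p.k_dis * c[1:]
        + p.k_cat * c[:-1]
        - (p.k_d + p.k_aso * fe) * fn[1:]
        - kloss[1:] * fn[1:]
    )
    dfn[1:-1] += kloss[2:] * fn[2:]
    # empty cages: receive degraded cages (synthesis = degradation) and the
    # release flux from singly loaded cages; degradation is a no-op on Fn_0
    dfn[0] = (
        p.k_dis * c[0]
        + p.k_d * fn[1:].sum()
        + kloss[1] * fn[1]
        - p.k_aso * fe * fn[0]
    )

    dc = p.k_aso * fe * fn - (p.k_dis + p.k_cat) * c
    dc[-1] = p.k_aso * fe * fn[-1] - p.k_dis * c[-1]

    out = np.empty_like(y)
    out[0] = dfe
    out[1 : n + 2] = dfn
    out[n + 2 :] = dc
    return out


def _jacobian(y: np.ndarray, p: ModelParameters, kloss: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of :func:`_rhs` (dense (2N+3)^2)."""
    n = len(kloss) - 1
    m = 2 * n + 3
    fe = y[0]
    fn = y[1 : n + 2]
    i_arr = np.arange(n + 1)
    fn_idx = 1 + i_arr
    c_idx = n + 2 + i_arr

    J = np.zeros((m, m))

    # dFe/dt row
    J[0, 0] = -p.k_aso * fn.sum()
    loss_eff = kloss.copy()
    loss_eff[0] = 0.0
    J[0, fn_idx] = p.k_d * i_arr + loss_eff - p.k_aso * fe
    J[0, c_idx] = p.k_dis

    # dFn_0/dt row
    J[1, 0] = -p.k_aso * fn[0]
    J[1, 1] = -p.k_aso * fe
    J[1, fn_idx[1:]] += p.k_d
    J[1, fn_idx[1]] += kloss[1]
    J[1, c_idx[0]] = p.k_dis

    # dFn_i/dt rows, i = 1..N
    rows = fn_idx[1:]
    J[rows, 0] = -p.k_aso * fn[1:]
    J[rows, rows] = -(p.k_d + p.k_aso * fe) - kloss[1:]
    J[rows[:-1], rows[:-1] + 1] += kloss[2:]
    J[rows, c_idx[1:]] += p.k_dis
    J[rows, c_idx[:-1]] += p.k_cat

    # dC_i/dt rows
    J[c_idx, 0] = p.k_aso * fn
    J[c_idx, fn_idx] = p.k_aso * fe
    J[c_idx, c_idx] = -(p.k_dis + p.k_cat)
    J[c_idx[-1], c_idx[-1]] = -p.k_dis
    return J


def derivatives(state: SystemState, params: ModelParameters) -> SystemState:
    """Right-hand side of the ODE system as a state-shaped object."""
    if state.n_packages != params.n_packages:
        raise ValueError(
            f"state has N={state.n_packages} but parameters expect "
            f"N={params.n_packages}"
        )
    dy = _rhs(state.to_vector(), params, k_loss_vector(params))
    return SystemState.from_vector(dy)


def _iron_weights(n: int) -> np.ndarray:
    """Packages of iron carried by each state component."""
    i_arr = np.arange(n + 1, dtype=float)
    return np.concatenate(([1.0], i_arr, i_arr + 1.0))


def total_iron(state: SystemState) -> float:
    """Total iron in the system, pmol-packages cell^-1.

    Counts the cLIP, the mineral cores (i packages per Fn_i) and, for each
    complex, its core plus the one reversibly bound package.
    """
    i_arr = np.arange(state.n_packages + 1)
    return float(state.fe + (i_arr * state.fn).sum() + ((i_arr + 1) * state.c).sum())


def total_ferritin(state: SystemState) -> float:
    """Total protein cages (free + complexed), pmol-ferritin cell^-1."""
    return float(state.fn.sum() + state.c.sum())


def initial_state(params: ModelParameters, total_iron_packages: float) -> SystemState:
    """All cages empty, no complexes, all iron free in the cLIP."""
    if total_iron_packages < 0:
        raise ValueError("total_iron_packages must be non-negative")
    n = params.n_packages
    fn = np.zeros(n + 1)
    fn[0] = params.fn_total
    return SystemState(fe=float(total_iron_packages), fn=fn, c=np.zeros(n + 1))


def repack_parameters(params: ModelParameters, atoms_per_package: int) -> ModelParameters:
    """Re-express a parameter set at a different lumping resolution.

    Lumping iron into packages is a numerical device; changing the package
    size must not change the physics.  Amounts measured in packages scale
    with ``old/new`` (same atoms), the bimolecular association constant
    scales inversely (so the per-cage binding-event rate at a fixed atom
    concentration is unchanged), and the Hill half-saturation point is kept
    at the same number of *atoms*.  Per-event rates (``k_dis``, ``k_cat``,
    ``k̃_loss``, ``k_d``) are unchanged, so the uptake/release balance that
    sets the steady state is preserved; only the discretization resolution
    differs.
    """
    old = params.packing.atoms_per_package
    factor = old / atoms_per_package
    packing = replace(params.packing, atoms_per_package=atoms_per_package)
    return replace(
        params,
        packing=packing,
        k_aso=params.k_aso / factor,
        hill_theta=params.hill_theta * factor,
        fe_initial=params.fe_initial * factor,
    )


def equation_count(n_packages: int) -> int:
    """Number of simultaneous ODEs: Fe plus N+1 cage and N+1 complex classes."""
    if n_packages < 1:
        raise ValueError("n_packages must be >= 1")
    return 2 * n_packages + 3
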