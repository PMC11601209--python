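"""Exact equilibrium of a two-conformation receptor with independent binding-site classes.

The receptor is modeled with two global conformations — a low-affinity "closed"
state and a high-affinity "open" state (the open and desensitized conformations
are merged, since both bind agonists with higher affinity than the closed state
and equilibrium binding cannot distinguish them).  Each receptor carries
``n_ortho`` identical, independent orthosteric (neurotransmitter) sites and
``n_allo`` identical, independent allosteric (transmembrane-domain modulator)
sites.  A ligand is characterized by its dissociation constants from the two
conformations, ``kd_closed`` and ``kd_open``; an agonist binds the open state
more tightly (``kd_closed > kd_open``), an inverse agonist the closed state.

With per-conformation site independence, the grand partition function factorizes,

    W_closed = prod_classes (1 + sum_L [L]/Kd_closed,L) ** n_class
    W_open   = K_gate * prod_classes (1 + sum_L [L]/Kd_open,L) ** n_class

where ``K_gate`` is the gating equilibrium constant of the unliganded receptor.
The gating constant of the receptor with ``m`` orthosteric agonist molecules
bound follows as ``K_gate * (kd_closed/kd_open)**m``.

All concentrations are molar and interpreted as *free* (unbound) concentrations;
unit conversion (nM, uM, ...) happens only in the config I/O layer.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import yaml

from .errors import CapacityError, ComputationError, RoleError

__all__ = [
    "LigandSpec",
    "ReceptorModel",
    "AssayConditions",
    "OccupancyResult",
    "liganded_gating_constant",
    "state_weights",
    "equilibrium_occupancy",
    "enumerate_microstates_oracle",
    "toxin_toxin_occupancy",
    "toxin_half_competition",
    "load_model",
    "dump_model",
]

ORTHOSTERIC = "orthosteric"
ALLOSTERIC = "allosteric"

_MAX_SITES = 8
_MAX_LIGANDS_ORACLE = 4
_LOG_OVERFLOW = 700.0  # exp(700) is near the float64 ceiling


@dataclass(frozen=True)
class LigandSpec:
    """A ligand with conformation-specific dissociation constants (molar).

    ``role`` fixes which site class the ligand occupies; a ligand cannot bind
    both classes.
    """

    name: str
    role: str
    kd_closed: float
    kd_open: float

    def __post_init__(self) -> None:
        if self.role not in (ORTHOSTERIC, ALLOSTERIC):
            raise RoleError(f"role must be 'orthosteric' or 'allosteric', got {self.role!r}")
        if not (self.kd_closed > 0 and math.isfinite(self.kd_closed)):
            raise ValueError(f"kd_closed must be finite and > 0, got {self.kd_closed}")
        if not (self.kd_open > 0 and math.isfinite(self.kd_open)):
            raise ValueError(f"kd_open must be finite and > 0, got {self.kd_open}")
        if not self.name:
            raise ValueError("ligand name must be non-empty")

    @property
    def affinity_ratio(self) -> float:
        """kd_closed / kd_open; the per-site coupling factor of the gating constant."""
        return self.kd_closed / self.kd_open

    def is_agonist(self) -> bool:
        """True when the ligand prefers (stabilizes) the open conformation."""
        return self.kd_closed > self.kd_open

    def is_inverse_agonist(self) -> bool:
        """True when the ligand prefers the closed conformation."""
        return self.kd_closed < self.kd_open

    def is_neutral(self) -> bool:
        """True when binding is conformation-independent (no coupling)."""
        return self.kd_closed == self.kd_open


@dataclass(frozen=True)
class ReceptorModel:
    """Two-conformation receptor with identical, independent site classes."""

    gating_unliganded: float
    ligands: tuple[LigandSpec, ...] = ()
    n_ortho: int = 5
    n_allo: int = 5

    def __post_init__(self) -> None:
        if not (self.gating_unliganded > 0 and math.isfinite(self.gating_unliganded)):
            raise ValueError("gating_unliganded must be finite and > 0")
        if not (isinstance(self.n_ortho, int) and 1 <= self.n_ortho <= _MAX_SITES):
            raise ValueError(f"n_ortho must be an integer in [1, {_MAX_SITES}]")
        if not (isinstance(self.n_allo, int) and 0 <= self.n_allo <= _MAX_SITES):
            raise ValueError(f"n_allo must be an integer in [0, {_MAX_SITES}]")
        object.__setattr__(self, "ligands", tuple(self.ligands))
        names = [lig.name for lig in self.ligands]
        if len(set(names)) != len(names):
            raise ValueError("ligand names must be unique")
        if any(lig.role == ALLOSTERIC for lig in self.ligands) and self.n_allo == 0:
            raise ValueError("model has allosteric ligands but n_allo = 0")

    def ligand(self, name: str) -> LigandSpec:
        for lig in self.ligands:
            if lig.name == name:
                return lig
        raise KeyError(f"no ligand named {name!r} in model")

    def ligands_of(self, role: str) -> tuple[LigandSpec, ...]:
        return tuple(lig for lig in self.ligands if lig.role == role)

    def n_sites(self, role: str) -> int:
        return self.n_ortho if role == ORTHOSTERIC else self.n_allo


@dataclass(frozen=True)
class AssayConditions:
    """Free (unbound) ligand concentrations, molar, keyed by ligand name."""

    free_concentrations: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "free_concentrations", dict(self.free_concentrations))
        for name, conc in self.free_concentrations.items():
            if not (math.isfinite(conc) and conc >= 0):
                raise ValueError(f"concentration of {name!r} must be finite and >= 0, got {conc}")

    def get(self, name: str) -> float:
        return self.free_concentrations.get(name, 0.0)


@dataclass(frozen=True)
class OccupancyResult:
    """Conformational probabilities and expected bound sites per ligand."""

    p_open: float
    p_closed: float
    mean_occupancy: Mapping[str, float] = field(default_factory=dict)


def _check_conditions(model: ReceptorModel, cond: AssayConditions) -> None:
    for name in cond.free_concentrations:
        model.ligand(name)  # KeyError if unknown


def liganded_gating_constant(model: ReceptorModel, ligand: LigandSpec | str, m: int) -> float:
    """Gating equilibrium constant of the receptor with ``m`` orthosteric ligands bound.

    Equals ``gating_unliganded * (kd_closed/kd_open)**m``; ``m = 0`` recovers the
    unliganded constant.
    """
    if isinstance(ligand, str):
        ligand = model.ligand(ligand)
    if ligand.role != ORTHOSTERIC:
        raise RoleError(f"{ligand.name!r} is allosteric; the liganded gating constant "
                        "is defined for orthosteric occupancy")
    if not (isinstance(m, int) and 0 <= m <= model.n_ortho):
        raise ValueError(f"m must be an integer in [0, {model.n_ortho}], got {m}")
    return model.gating_unliganded * ligand.affinity_ratio ** m


def _class_sums(model: ReceptorModel, cond: AssayConditions, role: str) -> tuple[float, float]:
    """(closed, open) per-site binding-polynomial sums for one site class."""
    s_closed = 0.0
    s_open = 0.0
    for lig in model.ligands_of(role):
        c = cond.get(lig.name)
        s_closed += c / lig.kd_closed
        s_open += c / lig.kd_open
    return s_closed, s_open


def _log_state_weights(model: ReceptorModel, cond: AssayConditions) -> tuple[float, float]:
    _check_conditions(model, cond)
    so_c, so_o = _class_sums(model, cond, ORTHOSTERIC)
    sa_c, sa_o = _class_sums(model, cond, ALLOSTERIC)
    log_closed = model.n_ortho * math.log1p(so_c) + model.n_allo * math.log1p(sa_c)
    log_open = (math.log(model.gating_unliganded)
                + model.n_ortho * math.log1p(so_o) + model.n_allo * math.log1p(sa_o))
    if not (math.isfinite(log_closed) and math.isfinite(log_open)):
        raise ComputationError(
            f"non-finite state weight (log closed={log_closed}, log open={log_open}); "
            "check concentrations and dissociation constants")
    return log_closed, log_open


def state_weights(model: ReceptorModel, cond: AssayConditions) -> tuple[float, float]:
    """Statistical weights (closed, open) of the two conformations.

    Weights are evaluated in log space internally; requesting the linear-scale
    weights at absurd concentrations raises :class:`ComputationError` rather
    than returning inf.
    """
    log_closed, log_open = _log_state_weights(model, cond)
    if log_closed > _LOG_OVERFLOW or log_open > _LOG_OVERFLOW:
        raise ComputationError(
            f"state weight overflows float64 (log closed={log_closed:.3g}, "
            f"log open={log_open:.3g}); use equilibrium_occupancy, which works on "
            "weight ratios")
    return math.exp(log_closed), math.exp(log_open)


def equilibrium_occupancy(model: ReceptorModel, cond: AssayConditions) -> OccupancyResult:
    """Conformational probabilities and per-ligand expected site occupancies.

    ``p_open = W_open / (W_closed + W_open)``; the mean number of sites bound by
    ligand L in a class with n sites is the state-probability-weighted single-site
    binding probability times n (sites are identical and independent within each
    conformation).
    """
    log_closed, log_open = _log_state_weights(model, cond)
    # p_open = 1 / (1 + exp(log_closed - log_open)), stable at both extremes
    d = log_closed - log_open
    if d > _LOG_OVERFLOW:
        p_open = 0.0
    elif d < -_LOG_OVERFLOW:
        p_open = 1.0
    else:
        p_open = 1.0 / (1.0 + math.exp(d))
    p_closed = 1.0 - p_open

    sums = {ORTHOSTERIC: _class_sums(model, cond, ORTHOSTERIC),
            ALLOSTERIC: _class_sums(model, cond, ALLOSTERIC)}
    occupancy: dict[str, float] = {}
    for lig in model.ligands:
        c = cond.get(lig.name)
        s_closed, s_open = sums[lig.role]
        f_closed = (c / lig.kd_closed) / (1.0 + s_closed)
        f_open = (c / lig.kd_open) / (1.0 + s_open)
        occupancy[lig.name] = model.n_sites(lig.role) * (p_closed * f_closed + p_open * f_open)
    return OccupancyResult(p_open=p_open, p_closed=p_closed, mean_occupancy=occupancy)


def enumerate_microstates_oracle(model: ReceptorModel, cond: AssayConditions) -> OccupancyResult:
    """Brute-force reference: explicit sum over every conformation x site-assignment.

    Each microstate assigns to every site either "empty" or one ligand of the
    matching class; its weight is the product of per-site factors [L]/Kd(state)
    times the conformational prefactor.  Intended as an independent test oracle
    for :func:`equilibrium_occupancy`; capacity-limited by construction.
    """
    _check_conditions(model, cond)
    if len(model.ligands) > _MAX_LIGANDS_ORACLE:
        raise CapacityError(f"oracle supports at most {_MAX_LIGANDS_ORACLE} ligands")
    ortho = model.ligands_of(ORTHOSTERIC)
    allo = model.ligands_of(ALLOSTERIC)
    n_states = 2 * (len(ortho) + 1) ** model.n_ortho * (len(allo) + 1) ** model.n_allo
    if n_states > 2_000_000:
        raise CapacityError(f"{n_states} microstates exceeds the enumeration limit")

    def assignments(ligs: tuple[LigandSpec, ...], n_sites: int, closed: bool):
        """Yield (weight, counts-per-ligand) over all per-site assignments."""
        choices: list[tuple[float, int | None]] = [(1.0, None)]
        for i, lig in enumerate(ligs):
            kd = lig.kd_closed if closed else lig.kd_open
            choices.append((cond.get(lig.name) / kd, i))
        out = []
        for combo in itertools.product(choices, repeat=n_sites):
            w = 1.0
            counts = [0] * len(ligs)
            for factor, idx in combo:
                w *= factor
                if idx is not None:
                    counts[idx] += 1
            out.append((w, counts))
        return out

    total = {True: 0.0, False: 0.0}  # keyed by "closed"
    occ_sums = {lig.name: 0.0 for lig in model.ligands}
    for closed in (True, False):
        prefactor = 1.0 if closed else model.gating_unliganded
        ortho_states = assignments(ortho, model.n_ortho, closed)
        allo_states = assignments(allo, model.n_allo, closed)
        for w_o, counts_o in ortho_states:
            for w_a, counts_a in allo_states:
                w = prefactor * w_o * w_a
                total[closed] += w
                for lig, k in zip(ortho, counts_o):
                    occ_sums[lig.name] += w * k
                for lig, k in zip(allo, counts_a):
                    occ_sums[lig.name] += w * k
    z = total[True] + total[False]
    if not (z > 0 and math.isfinite(z)):
        raise ComputationError(f"partition function is {z}")
    return OccupancyResult(
        p_open=total[False] / z,
        p_closed=total[True] / z,
        mean_occupancy={name: s / z for name, s in occ_sums.items()},
    )


def toxin_toxin_occupancy(n: int, kd_closed: float, labeled: float, unlabeled: float) -> float:
    """Mean sites bound by labeled toxin competing with unlabeled toxin.

    Closed form for a receptor that stays closed throughout (both toxins are
    inverse agonists):  N = n * [labeled] / (Kd_closed + [labeled] + [unlabeled]).
    """
    if kd_closed <= 0:
        raise ValueError(f"kd_closed must be > 0, got {kd_closed}")
    if labeled < 0 or unlabeled < 0 or n < 0:
        raise ValueError("n, labeled and unlabeled must be >= 0")
    return n * labeled / (kd_closed + labeled + unlabeled)


def toxin_half_competition(kd_closed: float, labeled: float) -> float:
    """Unlabeled-toxin concentration that halves bound labeled toxin.

    Equals ``kd_closed + labeled``: with the label clamped at 1 x Kd_closed this
    is 2 x Kd_closed, which is why the half-competition concentration of an
    inverse agonist directly reads out its closed-state dissociation constant.
    """
    if kd_closed <= 0:
        raise ValueError(f"kd_closed must be > 0, got {kd_closed}")
    if labeled < 0:
        raise ValueError(f"labeled must be >= 0, got {labeled}")
    return kd_closed + labeled


# ---------------------------------------------------------------------------
# Config I/O: flat YAML with a receptor block and per-ligand blocks.
# Dissociation constants may carry a "units" key (M, mM, uM, nM, pM); the
# in-memory model is always molar.

_UNIT_SCALE = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9, "pM": 1e-12}


def _to_molar(value: float, units: str) -> float:
    try:
        return float(value) * _UNIT_SCALE[units]
    except KeyError:
        raise ValueError(f"unknown concentration unit {units!r}; use one of {sorted(_UNIT_SCALE)}")


def load_model(path_or_stream) -> ReceptorModel:
    """Read a receptor model from a YAML config file or stream."""
    if hasattr(path_or_stream, "read"):
        doc = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream) as fh:
            doc = yaml.safe_load(fh)
    rec = doc.get("receptor", {})
    ligands = []
    for name, block in (doc.get("ligands") or {}).items():
        units = block.get("units", "M")
        ligands.append(LigandSpec(
            name=str(name),
            role=block["role"],
            kd_closed=_to_molar(block["kd_closed"], units),
            kd_open=_to_molar(block["kd_open"], units),
        ))
    return ReceptorModel(
        gating_unliganded=float(rec["gating_unliganded"]),
        ligands=tuple(ligands),
        n_ortho=int(rec.get("n_ortho", 5)),
        n_allo=int(rec.get("n_allo", 5)),
    )


def dump_model(model: ReceptorModel, path_or_stream) -> None:
    """Write a receptor model as YAML (molar units)."""
    doc = {
        "receptor": {
            "n_ortho": model.n_ortho,
            "n_allo": model.n_allo,
            "gating_unliganded": model.gating_unliganded,
        },
        "ligands": {
            lig.name: {
                "role": lig.role,
                "kd_closed": lig.kd_closed,
                "kd_open": lig.kd_open,
                "units": "M",
            }
            for lig in model.ligands
        },
    }
    if hasattr(path_or_stream, "write"):
        yaml.safe_dump(doc, path_or_stream, sort_keys=False)
    else:
        with open(path_or_stream, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)
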