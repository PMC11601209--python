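"""Simulation of binding-competition curves and half-competition readouts.

A competition assay clamps the free concentration of a labeled orthosteric
ligand (the toxin) at a chosen multiple of its closed-state Kd and titrates an
unlabeled competitor over a log-spaced grid, optionally in the presence of an
allosteric modulator held at constant free concentration.  The observable is
the mean number of sites bound by label, normalized to its value at zero
competitor ("fraction of control").

The default regime treats all concentrations as free (clamped) — the
experimental design keeps ligand depletion negligible.  An opt-in mass-balance
solver converts total concentrations to free ones when depletion matters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .errors import ConvergenceError, NormalizationError, NotCrossedError
from .model import AssayConditions, ReceptorModel, equilibrium_occupancy

__all__ = [
    "CompetitionCurveSpec",
    "CompetitionCurve",
    "default_grid",
    "simulate_competition_curve",
    "half_competition",
    "modulator_occupancy_profile",
    "solve_free_concentrations",
    "write_curve_tsv",
    "read_curve_tsv",
]


def default_grid(c_min: float, c_max: float, n: int = 17, include_zero: bool = True) -> tuple[float, ...]:
    """Log-spaced titration grid from c_min to c_max, optionally with a leading 0."""
    if not (0 < c_min < c_max):
        raise ValueError("require 0 < c_min < c_max")
    grid = np.logspace(math.log10(c_min), math.log10(c_max), n)
    pts = [0.0] if include_zero else []
    return tuple(pts + list(grid))


@dataclass(frozen=True)
class CompetitionCurveSpec:
    """Design of one simulated competition curve.

    ``label_level`` sets the clamped free label concentration as a multiple of
    the label's kd_closed (1.0 emulates the half-saturating condition of the
    assay).  When ``depletion`` is on, grid/label/modulator concentrations are
    interpreted as totals and converted to free values by mass balance against
    ``receptor_total``.
    """

    label: str
    competitor: str
    competitor_grid: tuple[float, ...]
    label_level: float = 1.0
    modulator: str | None = None
    modulator_concentration: float = 0.0
    depletion: bool = False
    receptor_total: float | None = None

    def __post_init__(self) -> None:
        grid = tuple(float(c) for c in self.competitor_grid)
        object.__setattr__(self, "competitor_grid", grid)
        if len(grid) == 0:
            raise ValueError("competitor_grid must be non-empty")
        if any(c < 0 for c in grid):
            raise ValueError("competitor concentrations must be >= 0")
        positive = grid[1:] if grid[0] == 0.0 else grid
        if any(b <= a for a, b in zip(positive, positive[1:])) or (grid[0] == 0.0 and len(grid) > 1 and grid[1] <= 0):
            raise ValueError("competitor_grid must be strictly increasing after any leading 0")
        if not self.label_level > 0:
            raise ValueError("label_level must be > 0")
        if self.modulator is None and self.modulator_concentration:
            raise ValueError("modulator_concentration given without a modulator")
        if self.modulator_concentration < 0:
            raise ValueError("modulator_concentration must be >= 0")
        if self.depletion and self.receptor_total is None:
            raise ValueError("receptor_total is required when depletion is on")


@dataclass(frozen=True)
class CompetitionCurve:
    """Normalized bound-label signal along a competitor titration."""

    concentrations: tuple[float, ...]
    signal: tuple[float, ...]
    modulator_occupancy: tuple[float, ...] | None = None
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.concentrations) != len(self.signal):
            raise ValueError("concentrations and signal must have equal length")
        if self.modulator_occupancy is not None and len(self.modulator_occupancy) != len(self.signal):
            raise ValueError("modulator_occupancy length mismatch")

    def to_frame(self, curve_id: str = "sim-0") -> pd.DataFrame:
        occ = self.modulator_occupancy
        return pd.DataFrame({
            "concentration_M": self.concentrations,
            "signal": self.signal,
            "modulator_occupancy": occ if occ is not None else [float("nan")] * len(self.signal),
            "curve_id": curve_id,
        })


def _curve_conditions(model: ReceptorModel, spec: CompetitionCurveSpec,
                      competitor_conc: float) -> AssayConditions:
    label = model.ligand(spec.label)
    free = {spec.label: spec.label_level * label.kd_closed,
            spec.competitor: competitor_conc}
    if spec.modulator is not None:
        free[spec.modulator] = spec.modulator_concentration
    return AssayConditions(free)


def _label_occupancy(model: ReceptorModel, spec: CompetitionCurveSpec,
                     competitor_conc: float) -> tuple[float, float | None]:
    cond = _curve_conditions(model, spec, competitor_conc)
    if spec.depletion:
        cond = solve_free_concentrations(model, cond, spec.receptor_total)
    occ = equilibrium_occupancy(model, cond)
    mod_occ = occ.mean_occupancy[spec.modulator] if spec.modulator is not None else None
    return occ.mean_occupancy[spec.label], mod_occ


def simulate_competition_curve(model: ReceptorModel, spec: CompetitionCurveSpec) -> CompetitionCurve:
    """Noiseless competition curve under the model, normalized to zero competitor.

    The normalization anchor is always the zero-competitor occupancy, whether or
    not the grid begins at 0 (this mirrors how fraction-of-control is plotted).
    """
    model.ligand(spec.competitor)  # fail fast on unknown names
    anchor, _ = _label_occupancy(model, spec, 0.0)
    if anchor <= 0:
        raise NormalizationError(
            f"bound label is {anchor} at zero competitor; cannot normalize "
            "(is the label concentration zero?)")
    signal = []
    mod_occ: list[float] = []
    for c in spec.competitor_grid:
        s, m = _label_occupancy(model, spec, c)
        signal.append(s / anchor)
        if m is not None:
            mod_occ.append(m)
    meta = {
        "label": spec.label,
        "label_free_M": spec.label_level * model.ligand(spec.label).kd_closed,
        "competitor": spec.competitor,
        "modulator": spec.modulator,
        "modulator_concentration_M": spec.modulator_concentration if spec.modulator else None,
        "depletion": spec.depletion,
    }
    return CompetitionCurve(
        concentrations=tuple(spec.competitor_grid),
        signal=tuple(signal),
        modulator_occupancy=tuple(mod_occ) if spec.modulator is not None else None,
        meta=meta,
    )


def half_competition(curve: CompetitionCurve, rtol: float = 1e-6) -> float:
    """Competitor concentration at which the interpolated signal equals 0.5.

    Uses shape-preserving (PCHIP) interpolation of signal against
    log-concentration over the positive grid points, then locates the crossing
    by bracketed root-finding.  Requires a monotone non-increasing curve that
    actually crosses 0.5 inside the grid.
    """
    conc = np.asarray(curve.concentrations, dtype=float)
    sig = np.asarray(curve.signal, dtype=float)
    if np.any(np.diff(sig) > 1e-9):
        raise ValueError("signal must be monotone non-increasing along the titration")
    pos = conc > 0
    c_pos, s_pos = conc[pos], sig[pos]
    if len(c_pos) < 2:
        raise ValueError("need at least two positive competitor concentrations")
    if s_pos.min() > 0.5 or sig.max() < 0.5:
        raise NotCrossedError(
            f"signal spans [{sig.min():.4g}, {sig.max():.4g}] and never crosses 0.5")
    if s_pos[0] < 0.5:
        raise NotCrossedError(
            "signal is already below 0.5 at the lowest positive concentration; "
            "extend the grid downward to resolve the crossing")
    x = np.log10(c_pos)
    f = PchipInterpolator(x, s_pos - 0.5)
    # bracket between the last grid point above 0.5 and the first at/below
    idx = int(np.argmax(s_pos <= 0.5))
    root = brentq(f, x[idx - 1], x[idx], rtol=rtol)
    return float(10.0 ** root)


def modulator_occupancy_profile(model: ReceptorModel, spec: CompetitionCurveSpec) -> tuple[float, ...]:
    """Expected allosteric sites bound at each grid point of the titration."""
    if spec.modulator is None:
        raise ValueError("spec does not name a modulator")
    curve = simulate_competition_curve(model, spec)
    assert curve.modulator_occupancy is not None
    return curve.modulator_occupancy


def solve_free_concentrations(model: ReceptorModel, totals: AssayConditions,
                              receptor_total: float, rtol: float = 1e-10,
                              max_iter: int = 1000) -> AssayConditions:
    """Free concentrations satisfying mass balance free + bound(free) = total.

    Bound ligand is ``receptor_total`` times the per-receptor mean occupancy at
    the candidate free concentrations.  Solved by damped fixed-point iteration
    with a per-ligand bisection fallback; the returned solution satisfies every
    balance to ``rtol`` relative.
    """
    if receptor_total < 0:
        raise ValueError("receptor_total must be >= 0")
    names = [n for n in totals.free_concentrations]
    tot = np.array([totals.get(n) for n in names], dtype=float)
    if receptor_total == 0 or len(names) == 0 or tot.sum() == 0:
        return totals

    def bound(free_vec: np.ndarray) -> np.ndarray:
        occ = equilibrium_occupancy(model, AssayConditions(dict(zip(names, free_vec))))
        return receptor_total * np.array([occ.mean_occupancy[n] for n in names])

    scale = np.maximum(tot, tot.max() * 1e-16)

    def residual(free_vec: np.ndarray) -> float:
        return float(np.max(np.abs(free_vec + bound(free_vec) - tot) / scale))

    free = tot.copy()
    damp = 0.5
    for _ in range(max_iter):
        target = np.maximum(tot - bound(free), 0.0)
        new = (1 - damp) * free + damp * target
        if residual(new) < rtol:
            return AssayConditions(dict(zip(names, new)))
        if np.allclose(new, free, rtol=1e-15, atol=0.0):
            break
        free = new

    # fallback: cyclic per-ligand bisection on the monotone single-ligand balance
    for _sweep in range(max_iter):
        for i in range(len(names)):
            def g(fi: float) -> float:
                trial = free.copy()
                trial[i] = fi
                return fi + bound(trial)[i] - tot[i]
            if tot[i] == 0.0:
                free[i] = 0.0
                continue
            # xtol must sit far below the smallest plausible free concentration,
            # or depleted ligands stall at brentq's default absolute tolerance
            free[i] = brentq(g, 0.0, tot[i], rtol=8.9e-16, xtol=tot[i] * 1e-18,
                             maxiter=200)
        if residual(free) < rtol:
            return AssayConditions(dict(zip(names, free)))
    raise ConvergenceError(
        f"mass-balance solver did not reach rtol={rtol}; residual={residual(free):.3g}")


# ---------------------------------------------------------------------------
# Delimited curve format shared with the fitting module

_CURVE_COLUMNS = ["concentration_M", "signal", "modulator_occupancy", "curve_id"]


def write_curve_tsv(curve_or_frame, path, header_lines: Sequence[str] = ()) -> None:
    """Write a curve (or a points DataFrame) as TSV with '#' provenance headers."""
    frame = curve_or_frame.to_frame() if isinstance(curve_or_frame, CompetitionCurve) else curve_or_frame
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_curve_tsv(path) -> pd.DataFrame:
    """Read the delimited curve format, ignoring '#' comment lines."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ("concentration_M", "signal") if c not in frame.columns]
    if missing:
        raise ValueError(f"curve file {path} lacks required columns {missing}")
    if "curve_id" not in frame.columns:
        frame["curve_id"] = "curve-0"
    return frame
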