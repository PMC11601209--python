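"""Global weighted Hill fitting, component selection, and fold shifts.

Replicate competition curves of one condition are fitted jointly with a sum of
Hill components sharing all parameters across curves,

    signal(c) = sum_k a_k / (1 + (c / IC50_k) ** nH_k)

with the lower plateau fixed at 0 (signals are fractions of control) and the
upper plateau equal to the summed amplitudes.  Standard errors come from the
Jacobian covariance scaled by the reduced chi-square of the weighted fit, the
usual practice in weighted nonlinear regression of binding data.  Component
count is chosen with a corrected-AIC improvement rule plus a sanity bound on
the relative parameter errors.  Fold shifts between two single-component fits
carry first-order propagated uncertainty.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .assay import CompetitionCurve, read_curve_tsv
from .errors import ConvergenceError, IdentifiabilityError

__all__ = [
    "AssayDataset",
    "HillFitResult",
    "FoldShift",
    "fit_hill",
    "select_components",
    "fold_shift",
    "weights_from_duplicates",
    "write_fit_report",
    "read_fit_report",
]

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class AssayDataset:
    """Pooled points of replicate competition curves for one condition."""

    points: pd.DataFrame  # columns: curve_id, concentration, signal, weight
    label: str = ""

    def __post_init__(self) -> None:
        df = self.points.copy()
        required = {"curve_id", "concentration", "signal"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"points lack columns {sorted(missing)}")
        if "weight" not in df.columns:
            df["weight"] = 1.0
        if (df["weight"] <= 0).any():
            raise ValueError("weights must be > 0")
        if (df["concentration"] < 0).any():
            raise ValueError("concentrations must be >= 0")
        for cid, grp in df.groupby("curve_id"):
            if grp["concentration"].nunique() < 4:
                raise ValueError(f"curve {cid!r} has fewer than 4 distinct concentrations")
        object.__setattr__(self, "points", df.reset_index(drop=True))

    @classmethod
    def from_curve(cls, curve: CompetitionCurve, curve_id: str = "sim-0",
                   label: str = "") -> "AssayDataset":
        frame = curve.to_frame(curve_id).rename(columns={"concentration_M": "concentration"})
        return cls(frame[["curve_id", "concentration", "signal"]], label=label)

    @classmethod
    def from_tsv(cls, path, label: str = "") -> "AssayDataset":
        frame = read_curve_tsv(path).rename(columns={"concentration_M": "concentration"})
        cols = ["curve_id", "concentration", "signal"] + (
            ["weight"] if "weight" in frame.columns else [])
        return cls(frame[cols], label=label)

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class HillFitResult:
    """Parameters, standard errors and goodness of fit of a global Hill fit.

    Components are sorted by increasing IC50; ``amplitude`` holds the fractional
    amplitudes (summing to 1), ``top`` the shared upper plateau.
    """

    n_components: int
    ic50: tuple[float, ...]
    hill: tuple[float, ...]
    amplitude: tuple[float, ...]
    top: float
    se_ic50: tuple[float, ...]
    se_hill: tuple[float, ...]
    se_amplitude: tuple[float, ...]
    se_top: float
    weighted_rss: float
    reduced_chi2: float
    aicc: float
    n_points: int
    label: str = ""
    selection_trace: tuple[Mapping[str, object], ...] = field(default_factory=tuple)

    @property
    def half_competition(self) -> float:
        """IC50 of a single-component fit."""
        if self.n_components != 1:
            raise ValueError("half_competition is defined for single-component fits")
        return self.ic50[0]

    @property
    def hill_coefficient(self) -> float:
        if self.n_components != 1:
            raise ValueError("hill_coefficient is defined for single-component fits")
        return self.hill[0]

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_components": self.n_components,
            "components": [
                {"ic50_M": i, "se_ic50_M": si, "hill": h, "se_hill": sh,
                 "amplitude_fraction": a, "se_amplitude_fraction": sa}
                for i, si, h, sh, a, sa in zip(
                    self.ic50, self.se_ic50, self.hill, self.se_hill,
                    self.amplitude, self.se_amplitude)
            ],
            "top": self.top,
            "se_top": self.se_top,
            "goodness_of_fit": {
                "weighted_rss": self.weighted_rss,
                "reduced_chi2": self.reduced_chi2,
                "aicc": self.aicc,
                "n_points": self.n_points,
            },
            "selection_trace": [dict(t) for t in self.selection_trace],
        }

    def to_table(self) -> str:
        lines = [f"Hill fit ({self.n_components} component(s), "
                 f"{self.n_points} points){': ' + self.label if self.label else ''}"]
        for k in range(self.n_components):
            lines.append(
                f"  [{k + 1}] IC50 = {self.ic50[k]:.4g} ± {self.se_ic50[k]:.2g} M | "
                f"n_H = {self.hill[k]:.3f} ± {self.se_hill[k]:.3f} | "
                f"amplitude = {self.amplitude[k]:.3f} ± {self.se_amplitude[k]:.3f}")
        lines.append(f"  top = {self.top:.4f} ± {self.se_top:.4f} | "
                     f"reduced chi2 = {self.reduced_chi2:.4g} | AICc = {self.aicc:.4g}")
        return "\n".join(lines)


@dataclass(frozen=True)
class FoldShift:
    """Ratio of two half-competition concentrations with propagated SE."""

    ratio: float
    se: float
    direction: str  # "increase" | "decrease"

    def __post_init__(self) -> None:
        if not self.ratio > 0:
            raise ValueError("ratio must be > 0")
        if self.se < 0:
            raise ValueError("se must be >= 0")


def _hill_model(c: np.ndarray, log_ic50: np.ndarray, nh: np.ndarray,
                amps: np.ndarray) -> np.ndarray:
    """Sum-of-Hill-components signal; c = 0 maps to the full plateau."""
    ic50 = 10.0 ** log_ic50
    with np.errstate(divide="ignore"):
        ratio = (c[:, None] / ic50[None, :]) ** nh[None, :]
    return (amps[None, :] / (1.0 + ratio)).sum(axis=1)


def _starting_values(c: np.ndarray, y: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic start: IC50s at grid points nearest evenly spaced signal levels."""
    top = float(np.clip(y[c == c.min()].mean() if (c == c.min()).any() else y.max(), 1e-6, None))
    pos = c > 0
    cp, yp = c[pos], y[pos]
    order = np.argsort(cp)
    cp, yp = cp[order], yp[order]
    log_ic50 = np.empty(k)
    for j in range(k):
        level = top * (1.0 - (j + 0.5) / k)
        log_ic50[j] = math.log10(cp[int(np.argmin(np.abs(yp - level)))])
    return np.sort(log_ic50), np.ones(k), np.full(k, top / k)


def fit_hill(data: AssayDataset, n_components: int = 1) -> HillFitResult:
    """Weighted least-squares global fit of ``n_components`` Hill components.

    Deterministic given the data (no random restarts).  Raises
    :class:`IdentifiabilityError` when the normal-equations matrix is singular
    or effectively so (e.g. flat data), :class:`ConvergenceError` when the
    optimizer fails.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    df = data.points
    c = df["concentration"].to_numpy(float)
    y = df["signal"].to_numpy(float)
    w = df["weight"].to_numpy(float)
    sw = np.sqrt(w)
    k = n_components
    n_par = 3 * k
    if data.n_points <= n_par:
        raise IdentifiabilityError(
            f"{data.n_points} points cannot identify {n_par} parameters")

    log_ic50_0, nh0, a0 = _starting_values(c, y, k)
    p0 = np.concatenate([log_ic50_0, nh0, a0])
    c_pos = c[c > 0]
    lo_log, hi_log = math.log10(c_pos.min()) - 3.0, math.log10(c_pos.max()) + 3.0
    lower = np.concatenate([np.full(k, lo_log), np.full(k, 0.05), np.zeros(k)])
    upper = np.concatenate([np.full(k, hi_log), np.full(k, 10.0), np.full(k, 2.0)])
    p0 = np.clip(p0, lower + 1e-9, upper - 1e-9)

    def resid(p: np.ndarray) -> np.ndarray:
        return sw * (_hill_model(c, p[:k], p[k:2 * k], p[2 * k:]) - y)

    res = least_squares(resid, p0, bounds=(lower, upper), method="trf", xtol=1e-14,
                        ftol=1e-14, gtol=1e-14)
    if not res.success:
        raise ConvergenceError(f"Hill fit did not converge: {res.message}")

    jac = res.jac
    jtj = jac.T @ jac
    dof = data.n_points - n_par
    if not np.all(np.isfinite(jtj)) or np.linalg.cond(jtj) > 1e10:
        raise IdentifiabilityError(
            "singular or near-singular fit; parameters are not identifiable from "
            "these data (flat or uninformative signal?)")
    chi2 = float(res.fun @ res.fun)
    red_chi2 = chi2 / dof
    # a fitted decline indistinguishable from the residual scatter means the
    # IC50 and Hill slope are not determined by these data
    fitted = _hill_model(c, res.x[:k], res.x[k:2 * k], res.x[2 * k:])
    drop = float(res.x[2 * k:].sum() - _hill_model(
        np.array([c.max()]), res.x[:k], res.x[k:2 * k], res.x[2 * k:])[0])
    rms = float(np.sqrt(np.mean((fitted - y) ** 2)))
    if drop < 2.0 * rms:
        raise IdentifiabilityError(
            f"fitted signal drop ({drop:.3g}) is within the residual noise "
            f"({rms:.3g} rms); the half-competition concentration is unidentifiable")
    cov = np.linalg.inv(jtj) * red_chi2
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    order = np.argsort(res.x[:k])
    log_ic50 = res.x[:k][order]
    nh = res.x[k:2 * k][order]
    amps = res.x[2 * k:][order]
    se_log = se[:k][order]
    se_nh = se[k:2 * k][order]
    se_amp = se[2 * k:][order]

    ic50 = 10.0 ** log_ic50
    se_ic50 = ic50 * _LN10 * se_log
    top = float(amps.sum())
    if top <= 0:
        raise IdentifiabilityError("fitted amplitude collapsed to zero")
    # fractions f_j = a_j / top; delta-method SE using the amplitude covariance block
    amp_idx = np.arange(2 * k, 3 * k)[order]
    cov_a = cov[np.ix_(amp_idx, amp_idx)]
    fracs = amps / top
    se_frac = np.empty(k)
    for j in range(k):
        g = -amps / top ** 2
        g[j] += 1.0 / top
        se_frac[j] = math.sqrt(max(float(g @ cov_a @ g), 0.0))
    se_top = math.sqrt(max(float(np.ones(k) @ cov_a @ np.ones(k)), 0.0))

    n = data.n_points
    aic = n * math.log(chi2 / n) + 2 * n_par
    aicc = aic + (2 * n_par * (n_par + 1) / (n - n_par - 1)) if n - n_par - 1 > 0 else math.inf

    return HillFitResult(
        n_components=k,
        ic50=tuple(ic50), hill=tuple(nh), amplitude=tuple(fracs), top=top,
        se_ic50=tuple(se_ic50), se_hill=tuple(se_nh), se_amplitude=tuple(se_frac),
        se_top=se_top,
        weighted_rss=chi2, reduced_chi2=red_chi2, aicc=aicc,
        n_points=n, label=data.label,
    )


def _relative_errors_ok(fit: HillFitResult, max_rel: float = 0.5) -> bool:
    rel = list(np.array(fit.se_ic50) / np.array(fit.ic50))
    rel += list(np.array(fit.se_hill) / np.array(fit.hill))
    rel += [s / a if a > 0 else math.inf for s, a in zip(fit.se_amplitude, fit.amplitude)]
    return all(r < max_rel for r in rel)


def select_components(data: AssayDataset, max_components: int = 2) -> HillFitResult:
    """Fit 1..max_components and keep the smallest adequate model.

    A larger model replaces the current one only when it improves the corrected
    AIC by more than 2 *and* all its parameter SEs stay below 50% of the
    estimates.  The decision trail is attached as ``selection_trace``.
    """
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    trace: list[dict] = []
    chosen: HillFitResult | None = None
    for k in range(1, max_components + 1):
        try:
            fit = fit_hill(data, k)
        except (IdentifiabilityError, ConvergenceError) as exc:
            trace.append({"n_components": k, "status": type(exc).__name__, "detail": str(exc)})
            if chosen is None and k == 1:
                raise
            continue
        entry = {"n_components": k, "status": "ok", "aicc": fit.aicc,
                 "errors_ok": _relative_errors_ok(fit)}
        if chosen is None:
            entry["selected"] = True
            chosen = fit
        elif fit.aicc < chosen.aicc - 2.0 and entry["errors_ok"]:
            entry["selected"] = True
            chosen = fit
        else:
            entry["selected"] = False
        trace.append(entry)
    assert chosen is not None
    return HillFitResult(**{**chosen.__dict__, "selection_trace": tuple(trace)})


def fold_shift(numerator: HillFitResult, denominator: HillFitResult) -> FoldShift:
    """Ratio of half-competition concentrations with first-order error propagation.

    se = ratio * sqrt((se_num/IC50_num)^2 + (se_den/IC50_den)^2).
    """
    if numerator.n_components != 1 or denominator.n_components != 1:
        raise ValueError("fold shifts are defined between single-component fits")
    r = numerator.half_competition / denominator.half_competition
    rel = math.hypot(numerator.se_ic50[0] / numerator.half_competition,
                     denominator.se_ic50[0] / denominator.half_competition)
    return FoldShift(ratio=r, se=r * rel, direction="increase" if r >= 1.0 else "decrease")


def weights_from_duplicates(points: pd.DataFrame, min_replicates: int = 2) -> pd.DataFrame:
    """Set weights to 1/variance of replicate signals at each (curve, concentration).

    Groups with fewer than ``min_replicates`` members, or zero variance, keep
    weight 1.  Returns a copy.
    """
    df = points.copy()
    df["weight"] = 1.0
    for _, idx in df.groupby(["curve_id", "concentration"]).groups.items():
        vals = df.loc[idx, "signal"]
        if len(vals) >= min_replicates:
            var = float(vals.var(ddof=1))
            if var > 0:
                df.loc[idx, "weight"] = 1.0 / var
    return df


def write_fit_report(fit: HillFitResult, path, provenance: Mapping[str, object] | None = None) -> None:
    """Write a JSON fit report plus an embedded human-readable table."""
    doc = fit.to_dict()
    doc["table"] = fit.to_table()
    if provenance:
        doc["provenance"] = dict(provenance)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def read_fit_report(path) -> HillFitResult:
    """Reload a fit report written by :func:`write_fit_report`."""
    with open(path) as fh:
        doc = json.load(fh)
    comps = doc["components"]
    gof = doc["goodness_of_fit"]
    return HillFitResult(
        n_components=doc["n_components"],
        ic50=tuple(c["ic50_M"] for c in comps),
        hill=tuple(c["hill"] for c in comps),
        amplitude=tuple(c["amplitude_fraction"] for c in comps),
        top=doc["top"],
        se_ic50=tuple(c["se_ic50_M"] for c in comps),
        se_hill=tuple(c["se_hill"] for c in comps),
        se_amplitude=tuple(c["se_amplitude_fraction"] for c in comps),
        se_top=doc["se_top"],
        weighted_rss=gof["weighted_rss"],
        reduced_chi2=gof["reduced_chi2"],
        aicc=gof["aicc"],
        n_points=gof["n_points"],
        label=doc.get("label", ""),
        selection_trace=tuple(doc.get("selection_trace", ())),
    )
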