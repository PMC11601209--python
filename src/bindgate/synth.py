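"""Synthetic competition-assay datasets and toy alignments with known truth.

The assay generator emulates the radioligand design: free labeled toxin clamped
near 1 x its closed-state Kd, a log-spaced unlabeled-ligand titration, each
concentration assayed in duplicate, several independent curves per condition,
counting (Poisson) noise on the measured label, and an additive nonspecific
background that survives the washes.  Every replicate is normalized to the mean
zero-competitor value of its own curve, as fraction-of-control data are.

All randomness flows through one ``numpy.random.default_rng(seed)``; the same
seed reproduces the dataset bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assay import CompetitionCurve, CompetitionCurveSpec, half_competition, simulate_competition_curve
from .errors import DesignError, NotCrossedError
from .hillfit import AssayDataset
from .model import ReceptorModel
from .msa import Alignment

__all__ = [
    "NoiseModel",
    "SyntheticAssayDataset",
    "generate_assay",
    "generate_toy_alignment",
    "AMINO_ACIDS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class NoiseModel:
    """Counting-noise model of the assay readout.

    ``count_scale`` is the expected number of counts at full (uncompeted)
    signal; Poisson statistics then set the relative noise at roughly
    1/sqrt(count_scale).  ``background_fraction`` is the nonspecific fraction of
    the full-signal counts that persists at saturating competitor.
    ``curve_scale_sd`` adds an optional log-normal per-curve scale factor
    (day-to-day variability); it is off by default.
    """

    count_scale: float = 5000.0
    background_fraction: float = 0.05
    n_duplicates: int = 2
    n_curves: int = 3
    seed: int = 0
    curve_scale_sd: float = 0.0

    def __post_init__(self) -> None:
        if not self.count_scale > 0:
            raise ValueError("count_scale must be > 0")
        if not (0 <= self.background_fraction < 1):
            raise ValueError("background_fraction must be in [0, 1)")
        if self.n_duplicates < 1 or self.n_curves < 1:
            raise ValueError("n_duplicates and n_curves must be >= 1")
        if self.curve_scale_sd < 0:
            raise ValueError("curve_scale_sd must be >= 0")


@dataclass(frozen=True)
class SyntheticAssayDataset:
    """Generated dataset plus the ground truth it was drawn from."""

    dataset: AssayDataset
    truth: Mapping[str, object]
    seed: int
    noiseless_curve: CompetitionCurve


def generate_assay(model: ReceptorModel, spec: CompetitionCurveSpec,
                   noise: NoiseModel) -> SyntheticAssayDataset:
    """Draw a noisy replicate dataset around the model's competition curve.

    Expected counts at competitor concentration c are
    ``count_scale * (bg + (1 - bg) * s(c))`` with s the noiseless normalized
    signal.  Each duplicate is an independent Poisson draw divided by
    ``count_scale``; the nominal nonspecific background ``bg`` is then
    subtracted (emulating the mock-transfected control measurement) and the
    specific signal is normalized to the curve's mean zero-competitor value.
    With ``count_scale = inf`` the data equal the model curve exactly.
    """
    curve = simulate_competition_curve(model, spec)
    rng = np.random.default_rng(noise.seed)
    bg = noise.background_fraction
    s = np.asarray(curve.signal, dtype=float)
    mean_signal = bg + (1.0 - bg) * s
    anchor_mean = bg + (1.0 - bg) * 1.0  # s(0) = 1 by normalization

    rows = []
    infinite = math.isinf(noise.count_scale)
    for i in range(noise.n_curves):
        factor = (math.exp(rng.normal(0.0, noise.curve_scale_sd))
                  if noise.curve_scale_sd > 0 else 1.0)
        if infinite:
            anchor = factor * anchor_mean - bg
            raw = np.tile(factor * mean_signal, (noise.n_duplicates, 1)) - bg
        else:
            anchor_counts = rng.poisson(factor * anchor_mean * noise.count_scale,
                                        size=noise.n_duplicates)
            anchor = anchor_counts.mean() / noise.count_scale - bg
            raw = rng.poisson(factor * mean_signal * noise.count_scale,
                              size=(noise.n_duplicates, len(s))) / noise.count_scale - bg
        if anchor <= 0:
            anchor = 1.0 / noise.count_scale  # all-zero anchor draw at tiny count_scale
        for d in range(noise.n_duplicates):
            for j, c in enumerate(curve.concentrations):
                rows.append({"curve_id": f"curve-{i}", "concentration": c,
                             "signal": raw[d, j] / anchor, "weight": 1.0})
    points = pd.DataFrame(rows)

    truth: dict[str, object] = {
        "gating_unliganded": model.gating_unliganded,
        "competitor": spec.competitor,
        "competitor_kd_closed": model.ligand(spec.competitor).kd_closed,
        "competitor_kd_open": model.ligand(spec.competitor).kd_open,
        "label_free_M": spec.label_level * model.ligand(spec.label).kd_closed,
    }
    try:
        truth["half_competition_M"] = half_competition(curve)
    except NotCrossedError:
        truth["half_competition_M"] = None
    return SyntheticAssayDataset(
        dataset=AssayDataset(points, label=f"synthetic:{spec.competitor}"),
        truth=truth, seed=noise.seed, noiseless_curve=curve)


def generate_toy_alignment(n_rows: int, ref_length: int,
                           planted_indels: Sequence[tuple[int, str, int]] = (),
                           seed: int = 0, ref_id: str = "ref") -> Alignment:
    """Toy alignment whose column classification is exactly the planted design.

    ``planted_indels`` holds (reference_position, kind, n_rows_affected)
    triples.  A deletion at position p gaps that column in ``n_rows_affected``
    non-reference rows; an insertion at p adds a column after the reference's
    p-th residue in which only ``n_rows_affected`` non-reference rows carry a
    residue.  Residue letters are random but deterministic under ``seed``.
    """
    if n_rows < 2:
        raise ValueError("need at least 2 rows (reference + 1)")
    if ref_length < 1:
        raise ValueError("ref_length must be >= 1")
    seen: set[tuple[int, str]] = set()
    for pos, kind, affected in planted_indels:
        if kind not in ("deletion", "insertion"):
            raise DesignError(f"unknown indel kind {kind!r}")
        if kind == "deletion" and not (1 <= pos <= ref_length):
            raise DesignError(f"deletion position {pos} outside reference 1..{ref_length}")
        if kind == "insertion" and not (1 <= pos <= ref_length - 1):
            raise DesignError(
                f"insertion position {pos} must lie between residues, 1..{ref_length - 1}")
        if not (1 <= affected <= n_rows - 1):
            raise DesignError(f"n_rows_affected must be in [1, {n_rows - 1}], got {affected}")
        key = (pos, kind)
        if key in seen:
            raise DesignError(f"overlapping planted indels at {key}")
        seen.add(key)

    rng = np.random.default_rng(seed)

    def letters(n: int) -> list[str]:
        return list(rng.choice(list(AMINO_ACIDS), size=n))

    # columns[j][i] = character of row i in column j; row 0 is the reference
    columns: list[list[str]] = [letters(n_rows) for _ in range(ref_length)]

    for pos, kind, affected in planted_indels:
        if kind != "deletion":
            continue
        rows = rng.choice(np.arange(1, n_rows), size=affected, replace=False)
        for i in rows:
            columns[pos - 1][i] = "-"

    insertions = sorted((p for p, k, a in planted_indels if k == "insertion"), reverse=True)
    plant = {(p, k): a for p, k, a in planted_indels}
    for pos in insertions:
        affected = plant[(pos, "insertion")]
        col = ["-"] * n_rows
        rows = rng.choice(np.arange(1, n_rows), size=affected, replace=False)
        chars = letters(affected)
        for i, ch in zip(rows, chars):
            col[i] = ch
        columns.insert(pos, col)

    seqs = ["".join(col[i] for col in columns) for i in range(n_rows)]
    ids = [ref_id] + [f"seq{i:03d}" for i in range(1, n_rows)]
    return Alignment(ids=tuple(ids), seqs=tuple(seqs))
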