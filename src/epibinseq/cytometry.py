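"""Competitive-binding flow-cytometry simulation and gating.

Cells co-express a surface antigen (A copies/cell) and a displayed query
scFv (Q copies/cell), both log-normally distributed across the
population.  A fluorescent reference antibody (rAb) competes with the
displayed qAb for its epitope under single-site mass-action equilibrium;
a second rAb against a distinct epitope binds independently.  The
displayed qAb acts through an effective cis concentration
``C_q = alpha * Q`` (nM), so for an rAb at concentration ``c`` with
dissociation constant ``K_r`` on epitope ``e``, the equilibrium bound
fraction of antigen sites is

    p = (c / K_r) / (1 + sum_{r' on e} c'/K_r' + b_e * C_q / K_q)

with ``b_e = 1`` iff the clone blocks epitope ``e`` (non-binders never
block).  Channel fluorescence is ``gain * A * p`` plus additive Gaussian
background noise, clipped at zero.  Gating below a background-derived
threshold selects the rAb-non-binding, i.e. epitope-blocked, population
that a sorter would collect.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .clones import CloneSpec, RAbSpec

__all__ = [
    "SimConfig",
    "GateResult",
    "KdFit",
    "rab_occupancy_fraction",
    "simulate_cell_events",
    "gate_and_sort",
    "quadrant_percentages",
    "fit_kd",
]


@dataclass(frozen=True)
class SimConfig:
    """Free parameters of the cell-population simulator.

    Expression medians/sds are log10 of molecules per cell; ``alpha`` is
    the effective cis concentration contributed by one displayed qAb
    molecule (nM/molecule); ``gain`` converts rAb-bound antigen copies
    to fluorescence (a.u.); ``noise_sd`` is the additive background sd
    (a.u.); ``q_gate`` is the background quantile that places the auto
    gate.
    """

    n_cells: int = 100_000
    log10_antigen_median: float = 5.0
    log10_antigen_sd: float = 0.5
    log10_qab_median: float = 5.0
    log10_qab_sd: float = 0.5
    alpha: float = 2.5e-4
    gain: float = 0.1124
    noise_sd: float = 30.0
    q_gate: float = 0.995
    antigen_low_fraction: float = 0.04
    antigen_low_factor: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("log10_antigen_sd", "log10_qab_sd", "alpha", "gain"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 < self.q_gate < 1.0:
            raise ValueError("q_gate must lie in (0, 1)")
        if not 0.0 <= self.antigen_low_fraction < 1.0:
            raise ValueError("antigen_low_fraction must lie in [0, 1)")
        if self.antigen_low_factor <= 0:
            raise ValueError("antigen_low_factor must be strictly positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")


def rab_occupancy_fraction(
    clone: CloneSpec,
    rabs: Sequence[RAbSpec],
    qab_copies: float,
    alpha: float,
) -> dict[str, float]:
    """Equilibrium antigen-site occupancy for each rAb on one cell.

    Distinct epitopes are independent sites; rAbs sharing an epitope
    compete with each other, and additionally with the displayed qAb
    when the clone blocks that epitope.
    """
    if qab_copies < 0:
        raise ValueError("qab_copies must be non-negative")
    for r in rabs:
        if r.concentration < 0:
            raise ValueError(f"{r.rab_id}: negative concentration")

    cq_over_kq = 0.0
    if clone.is_binder and clone.blocked_epitope is not None:
        cq_over_kq = alpha * qab_copies / clone.kd_qab

    x = {r.rab_id: r.concentration / r.kd_rab for r in rabs}
    by_epitope: dict[str, float] = {}
    for r in rabs:
        by_epitope[r.epitope_id] = by_epitope.get(r.epitope_id, 0.0) + x[r.rab_id]

    out = {}
    for r in rabs:
        blocked = 1.0 if r.epitope_id == clone.blocked_epitope and clone.is_binder else 0.0
        denom = 1.0 + by_epitope[r.epitope_id] + blocked * cq_over_kq
        out[r.rab_id] = x[r.rab_id] / denom
    return out


def _occupancy_vectorised(
    clone: CloneSpec, rabs: Sequence[RAbSpec], qab_copies: np.ndarray, alpha: float
) -> dict[str, np.ndarray]:
    """Per-cell occupancies for an array of qAb copy numbers (one clone)."""
    cq_over_kq = np.zeros_like(qab_copies, dtype=float)
    if clone.is_binder and clone.blocked_epitope is not None:
        cq_over_kq = alpha * qab_copies / clone.kd_qab
    totals = {r.epitope_id: 0.0 for r in rabs}
    for r in rabs:
        totals[r.epitope_id] += r.concentration / r.kd_rab
    out = {}
    for r in rabs:
        block = cq_over_kq if (clone.is_binder and r.epitope_id == clone.blocked_epitope) else 0.0
        out[r.rab_id] = (r.concentration / r.kd_rab) / (1.0 + totals[r.epitope_id] + block)
    return out


def simulate_cell_events(
    config: SimConfig,
    library: Sequence[CloneSpec],
    rabs: Sequence[RAbSpec],
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw a cell population and its per-channel fluorescence.

    Returns a DataFrame with one row per cell: ``clone_id``, antigen
    copies ``A``, qAb copies ``Q``, and one fluorescence column per rAb
    channel.  Clones are assigned multinomially by library frequency;
    A and Q are independent log-normal per cell.  Reproducible for a
    fixed seed (``config.seed`` unless overridden).
    """
    if config.n_cells > 0 and not library:
        raise ValueError("cannot simulate cells from an empty library")
    channels = sorted({r.channel for r in rabs})
    if config.n_cells == 0:
        return pd.DataFrame(columns=["clone_id", "A", "Q", *channels])

    freqs = np.array([c.library_frequency for c in library], dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError(f"library frequencies sum to {freqs.sum()}, not 1")

    rng = np.random.default_rng(config.seed if seed is None else seed)
    assignment = rng.choice(len(library), size=config.n_cells, p=freqs)

    ln10 = math.log(10.0)
    a = np.exp(rng.normal(config.log10_antigen_median, config.log10_antigen_sd, config.n_cells) * ln10)
    q = np.exp(rng.normal(config.log10_qab_median, config.log10_qab_sd, config.n_cells) * ln10)
    if config.antigen_low_fraction > 0:
        # antigen-silenced subpopulation: dims every stained population
        # and sets the realistic floor of the sort gate
        low = rng.random(config.n_cells) < config.antigen_low_fraction
        a[low] *= config.antigen_low_factor

    fluor = {ch: np.zeros(config.n_cells) for ch in channels}
    for i, clone in enumerate(library):
        mask = assignment == i
        if not mask.any():
            continue
        occ = _occupancy_vectorised(clone, rabs, q[mask], config.alpha)
        for r in rabs:
            fluor[r.channel][mask] += config.gain * a[mask] * occ[r.rab_id]
    for ch in channels:
        if config.noise_sd > 0:
            fluor[ch] += rng.normal(0.0, config.noise_sd, config.n_cells)
        np.clip(fluor[ch], 0.0, None, out=fluor[ch])

    data = {"clone_id": np.array([library[i].clone_id for i in assignment]), "A": a, "Q": q}
    data.update(fluor)
    return pd.DataFrame(data)


def background_threshold(config: SimConfig, channel: str, seed: int | None = None) -> float:
    """Auto gate: the ``q_gate`` quantile of a background-only population.

    Background cells carry no antigen signal (A contributes nothing to
    the channel), leaving only the additive noise floor; the quantile of
    that distribution is a reproducible stand-in for a manually drawn
    negative gate.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = max(config.n_cells, 10_000)
    noise = np.clip(rng.normal(0.0, config.noise_sd, n), 0.0, None) if config.noise_sd > 0 else np.zeros(n)
    return float(np.quantile(noise, config.q_gate))


@dataclass(frozen=True)
class GateResult:
    threshold: float
    percent_negative: float
    sorted_counts: Counter
    n_events: int

    @property
    def n_sorted(self) -> int:
        return sum(self.sorted_counts.values())


def gate_and_sort(
    events: pd.DataFrame,
    channel: str,
    threshold: float | str = "auto",
    config: SimConfig | None = None,
    seed: int | None = None,
) -> GateResult:
    """Gate below ``threshold`` on ``channel`` and collect the negatives.

    An event is rAb(-) iff its channel fluorescence is strictly below
    the threshold.  ``threshold="auto"`` derives the cut from a
    background-only simulation under ``config``.
    """
    if channel not in events.columns:
        raise KeyError(f"unknown fluorescence channel {channel!r}")
    if threshold == "auto":
        if config is None:
            raise ValueError("auto thresholding requires a SimConfig")
        if len(events) == 0:
            raise ValueError("auto thresholding requires a non-empty event list")
        threshold = background_threshold(config, channel, seed=seed)
    threshold = float(threshold)

    negative = events[channel].to_numpy() < threshold
    pct = 100.0 * negative.mean() if len(events) else 0.0
    counts = Counter(events.loc[negative, "clone_id"].tolist())
    return GateResult(threshold, float(pct), counts, len(events))


def quadrant_percentages(
    events: pd.DataFrame,
    channel_x: str,
    channel_y: str,
    thresh_x: float,
    thresh_y: float,
) -> dict[str, float]:
    """Percent of events in each dual-stain quadrant.

    Keys are ``"-/-"``, ``"-/+"``, ``"+/-"``, ``"+/+"`` where the first
    sign is the x channel.  Percentages sum to 100.
    """
    if len(events) == 0:
        raise ValueError("quadrant analysis requires a non-empty event list")
    for ch in (channel_x, channel_y):
        if ch not in events.columns:
            raise KeyError(f"unknown fluorescence channel {ch!r}")
    x_pos = events[channel_x].to_numpy() >= thresh_x
    y_pos = events[channel_y].to_numpy() >= thresh_y
    n = len(events)
    return {
        "-/-": 100.0 * np.sum(~x_pos & ~y_pos) / n,
        "-/+": 100.0 * np.sum(~x_pos & y_pos) / n,
        "+/-": 100.0 * np.sum(x_pos & ~y_pos) / n,
        "+/+": 100.0 * np.sum(x_pos & y_pos) / n,
    }


@dataclass(frozen=True)
class KdFit:
    kd: float
    fmax: float
    baseline: float
    converged: bool


def fit_kd(concentrations: Sequence[float], mfi: Sequence[float]) -> KdFit:
    """One-site saturation-binding fit, MFI(c) = baseline + fmax*c/(KD+c).

    Returns ``converged=False`` (rather than raising) when the response
    is flat, i.e. fmax is not distinguishable from zero — the signature
    of an antigen non-binder.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(mfi, dtype=float)
    if c.shape != y.shape:
        raise ValueError("concentrations and MFI vectors differ in length")
    if len(c) < 4:
        raise ValueError("at least 4 concentration points are required")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    if len(np.unique(c)) != len(c):
        raise ValueError("concentrations must be distinct")

    span = float(y.max() - y.min())
    scale = max(float(np.abs(y).max()), 1.0)
    if span <= 1e-9 * scale:
        return KdFit(math.nan, 0.0, float(y.mean()), False)

    def model(cc, kd, fmax, baseline):
        return baseline + fmax * cc / (kd + cc)

    p0 = (float(np.median(c)), span, float(y.min()))
    try:
        popt, pcov = curve_fit(
            model, c, y, p0=p0,
            bounds=([1e-9, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10_000,
        )
    except RuntimeError:
        return KdFit(math.nan, 0.0, float(y.mean()), False)

    kd, fmax, baseline = map(float, popt)
    # flat response: saturating amplitude indistinguishable from zero
    fmax_sd = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.inf
    if fmax <= 0 or (np.isfinite(fmax_sd) and fmax < 2.0 * fmax_sd and fmax < 0.05 * scale):
        return KdFit(math.nan, fmax, baseline, False)
    return KdFit(kd, fmax, baseline, True)
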