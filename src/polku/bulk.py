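"""Bulk-assay quantification: primer-extension gels and MST titrations.

Gel lanes are quantified from four densitometry boxes (unreacted substrate,
1-5 nucleotides, 6-15 nucleotides, whole lane); species fractions are each
box over the whole lane, and extension time courses summarize lanes as the
mean number of nucleotides incorporated using representative per-box counts
(bin midpoints 0 / 3 / 10.5 by default).

MST titrations are modeled as a 1:1 binding isotherm with ligand depletion:
with target concentration T and total ligand L,

    fb(L) = ((K_D + L + T) - sqrt((K_D + L + T)^2 - 4 L T)) / (2 T)

and the measured response is R = R_free + (R_bound - R_free) * fb, so the fit
is agnostic to the sign of the fluorescence change. Paired synthetic
generators produce lanes and titration curves with known ground truth.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .fitting import FitResult

__all__ = [
    "GelLane",
    "TitrationCurve",
    "quantify_lane",
    "extension_time_course",
    "fraction_bound",
    "fit_isotherm",
    "simulate_titration",
    "simulate_gel_series",
    "default_dilution_series",
]

DEFAULT_BOX_MIDPOINTS = (0.0, 3.0, 10.5)


@dataclasses.dataclass(frozen=True)
class GelLane:
    """Densitometry of one gel lane (arbitrary units)."""

    lane_label: str
    time_point_s: float
    i_0nt: float
    i_1to5: float
    i_6to15: float
    i_lane: float

    def __post_init__(self) -> None:
        boxes = (self.i_0nt, self.i_1to5, self.i_6to15, self.i_lane)
        if any(b < 0 for b in boxes):
            raise ValueError("box intensities must be non-negative")
        if self.i_0nt + self.i_1to5 + self.i_6to15 > self.i_lane * (1 + 1e-9):
            raise ValueError("species boxes exceed the whole-lane intensity")


@dataclasses.dataclass(frozen=True)
class TitrationCurve:
    """Dose-response of a titration: ligand series and normalized response."""

    concentrations: np.ndarray  # molar, descending
    response: np.ndarray
    target_concentration: float  # molar

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        resp = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "response", resp)
        if conc.size != resp.size:
            raise ValueError("concentrations and response differ in length")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.unique(conc).size != conc.size:
            raise ValueError("concentrations must be distinct")
        if self.target_concentration <= 0:
            raise ValueError("target concentration must be > 0")

    @property
    def span_orders(self) -> float:
        return float(np.log10(self.concentrations.max()
                              / self.concentrations.min()))


def quantify_lane(lane: GelLane) -> dict[str, float]:
    """Species fractions of one lane; the unboxed remainder is ``residual``."""
    if lane.i_lane <= 0:
        raise ValueError("whole-lane intensity must be > 0")
    f0 = lane.i_0nt / lane.i_lane
    f1 = lane.i_1to5 / lane.i_lane
    f2 = lane.i_6to15 / lane.i_lane
    return {"f_0nt": f0, "f_1to5": f1, "f_6to15": f2,
            "residual": 1.0 - (f0 + f1 + f2)}


def extension_time_course(
    lanes: Sequence[GelLane],
    midpoints: Sequence[float] = DEFAULT_BOX_MIDPOINTS,
) -> pd.DataFrame:
    """Mean nucleotides incorporated versus time across replicate lanes.

    Each lane's mean uses the representative nucleotide count of each box,
    weighted by the box fractions renormalized over the three boxes.
    """
    if len(midpoints) != 3:
        raise ValueError("midpoints must give one count per species box")
    if not lanes:
        raise ValueError("no lanes supplied")
    rows = []
    for lane in lanes:
        frac = quantify_lane(lane)
        weights = np.array([frac["f_0nt"], frac["f_1to5"], frac["f_6to15"]])
        total = weights.sum()
        if total <= 0:
            raise ValueError(f"lane {lane.lane_label!r} has no boxed signal")
        mean_nt = float(np.dot(weights / total, np.asarray(midpoints, float)))
        rows.append({"time_s": lane.time_point_s, "mean_nt": mean_nt})
    df = pd.DataFrame(rows)
    out = (df.groupby("time_s")["mean_nt"]
             .agg(mean_nt="mean", sd_nt=lambda v: v.std(ddof=1), n_lanes="size")
             .reset_index()
             .sort_values("time_s", ignore_index=True))
    return out


def fraction_bound(ligand_total, k_d: float, target: float):
    """Fraction of target bound at total ligand concentration, with depletion."""
    if k_d <= 0 or target <= 0:
        raise ValueError("K_D and target concentration must be > 0")
    L = np.asarray(ligand_total, dtype=float)
    s = k_d + L + target
    disc = np.maximum(s * s - 4.0 * L * target, 0.0)
    return (s - np.sqrt(disc)) / (2.0 * target)


def fit_isotherm(curve: TitrationCurve, *, min_points: int = 8,
                 min_span_orders: float = 3.0) -> FitResult:
    """Fit K_D, R_free and R_bound to a titration curve by least squares."""
    conc = curve.concentrations
    resp = curve.response
    if conc.size < min_points:
        raise ValueError(f"need at least {min_points} concentrations")
    if curve.span_orders < min_span_orders:
        raise ValueError("concentration series spans too little range for a fit")
    T = curve.target_concentration

    order = np.argsort(conc)
    notes: list[str] = []
    sorted_resp = resp[order]
    direction = np.sign(sorted_resp[-1] - sorted_resp[0]) or 1.0
    span = float(np.ptp(sorted_resp)) + 1e-12
    diffs = direction * np.diff(sorted_resp)
    backtrack = -float(diffs[diffs < 0].sum())
    if backtrack > 0.5 * span:
        notes.append("response is non-monotone beyond noise tolerance")
        warnings.warn("titration response is non-monotone beyond noise "
                      "tolerance", stacklevel=2)

    def model(L, k_d, r_free, r_bound):
        return r_free + (r_bound - r_free) * fraction_bound(L, k_d, T)

    r_free0 = float(sorted_resp[0])
    r_bound0 = float(sorted_resp[-1])
    half = r_free0 + 0.5 * (r_bound0 - r_free0)
    k0 = float(conc[np.argmin(np.abs(resp - half))])
    span = abs(r_bound0 - r_free0) + 1e-9
    lo_k, hi_k = conc.min() * 1e-4, conc.max() * 1e4
    popt, pcov = optimize.curve_fit(
        model, conc, resp, p0=(k0, r_free0, r_bound0),
        bounds=((lo_k, min(resp) - 10 * span, min(resp) - 10 * span),
                (hi_k, max(resp) + 10 * span, max(resp) + 10 * span)),
        maxfev=50000)
    k_d = float(popt[0])
    if k_d <= lo_k * 1.01 or k_d >= hi_k * 0.99:
        raise RuntimeError("isotherm fit did not converge: K_D at bound")
    perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    resid = resp - model(conc, *popt)
    return FitResult(
        model="isotherm",
        params={"k_d": k_d, "r_free": float(popt[1]), "r_bound": float(popt[2])},
        stderr={"k_d": float(perr[0]), "r_free": float(perr[1]),
                "r_bound": float(perr[2])},
        n_observations=int(conc.size),
        goodness=float(np.sum(resid ** 2)),
        notes=tuple(notes),
    )


def default_dilution_series(top: float = 200e-6, n_points: int = 19,
                            factor: float = 2.0) -> np.ndarray:
    """Serial dilution series (molar, descending), 200 uM to ~0.763 nM by default."""
    return top / factor ** np.arange(n_points)


def simulate_titration(
    k_d: float,
    target: float,
    concentrations: np.ndarray | None = None,
    *,
    noise: float = 0.02,
    r_free: float = 1.0,
    r_bound: float = 0.0,
    seed: int | None = None,
) -> TitrationCurve:
    """Forward-model a titration with Gaussian response noise.

    ``noise`` is the noise SD as a fraction of the response span. The default
    response decreases upon binding, as in a fluorescence-quenching readout.
    """
    if k_d <= 0 or target <= 0:
        raise ValueError("K_D and target concentration must be > 0")
    conc = (default_dilution_series() if concentrations is None
            else np.asarray(concentrations, dtype=float))
    fb = fraction_bound(conc, k_d, target)
    response = r_free + (r_bound - r_free) * fb
    if noise > 0:
        rng = np.random.default_rng(seed)
        response = response + rng.normal(
            0.0, noise * abs(r_bound - r_free), size=conc.size)
    return TitrationCurve(conc, response, target)


def simulate_gel_series(
    rate_nt_per_s: float,
    time_points_s: Sequence[float],
    *,
    n_molecules: int = 10_000,
    max_nt: int = 15,
    scale: float = 1000.0,
    noise: float = 0.05,
    unboxed_fraction: float = 0.0,
    seed: int | None = None,
) -> list[GelLane]:
    """Simulate a primer-extension gel time course.

    Per-molecule nucleotide counts follow a Poisson-process extension model
    (``Poisson(rate * t)`` clipped at ``max_nt``), binned into the
    0 / 1-5 / 6-15 boxes and scaled to densitometry units with multiplicative
    lognormal noise. ``unboxed_fraction`` adds lane signal outside the boxes.
    """
    if rate_nt_per_s < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    lanes = []
    for i, t in enumerate(time_points_s):
        counts = np.minimum(rng.poisson(rate_nt_per_s * t, size=n_molecules),
                            max_nt)
        n0 = np.sum(counts == 0)
        n1 = np.sum((counts >= 1) & (counts <= 5))
        n2 = np.sum(counts >= 6)
        boxes = np.array([n0, n1, n2], dtype=float) * scale / n_molecules
        if noise > 0:
            boxes = boxes * rng.lognormal(0.0, noise, size=3)
        lane_total = boxes.sum() * (1.0 + max(unboxed_fraction, 0.0))
        lanes.append(GelLane(
            lane_label=f"t{i}", time_point_s=float(t),
            i_0nt=float(boxes[0]), i_1to5=float(boxes[1]),
            i_6to15=float(boxes[2]), i_lane=float(lane_total)))
    return lanes
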