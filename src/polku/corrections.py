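"""ALEX photophysical corrections: leakage, direct excitation, gamma, bleaching.

Raw three-channel trajectories are converted to per-frame FRET efficiency in
the standard order: the donor leakage and direct-excitation contributions are
subtracted from the recorded acceptor signal, then the gamma factor weights
the donor term in the denominator,

    F_corr = F_DA - l * F_DD - d * F_AA
    E      = F_corr / (F_corr + gamma * F_DD)

Frames at or after a detected single-step photobleach of either dye are
excluded (marked invalid) rather than imputed, as are frames without an
acceptor present (no molecule bound) and frames whose corrected denominator
is non-positive.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .trajectories import Trajectory, TrajectorySet

__all__ = ["CorrectionFactors", "EfretTrace", "estimate_factors",
           "compute_efret", "detect_bleach"]


@dataclasses.dataclass(frozen=True)
class CorrectionFactors:
    """Leakage ``l``, direct excitation ``d`` and gamma imbalance factors."""

    leakage: float
    direct_excitation: float
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.leakage < 1:
            raise ValueError("leakage must be in [0, 1)")
        if not 0 <= self.direct_excitation < 1:
            raise ValueError("direct_excitation must be in [0, 1)")
        if not self.gamma > 0:
            raise ValueError("gamma must be > 0")


@dataclasses.dataclass(frozen=True)
class EfretTrace:
    """Corrected per-frame FRET efficiency with validity flags.

    ``e`` is NaN where the corrected denominator is non-positive. ``valid``
    marks frames usable for event calling: both dyes unbleached, acceptor
    present, and E within the tolerated [-0.2, 1.2] range. ``in_range``
    additionally flags whether E lies in the physical [0, 1] interval.
    """

    molecule_id: int
    time_s: np.ndarray
    e: np.ndarray
    valid: np.ndarray
    in_range: np.ndarray
    frame_interval: float
    donor_bleach_frame: int | None = None
    acceptor_bleach_frame: int | None = None

    @property
    def n_frames(self) -> int:
        return len(self.time_s)


def detect_bleach(intensity, *, background: float = 10.0,
                  min_segment: int = 3) -> int | None:
    """Locate a single-step photobleach in an intensity trace.

    The changepoint maximizing the two-segment mean-shift objective is
    evaluated; it is accepted as a bleach only when the pre-step mean sits
    clearly above background and the post-step mean falls below
    ``background + 2 * sqrt(background)``. Returns the first post-step frame
    index, or ``None`` when no acceptable step exists (including traces
    shorter than twice ``min_segment``).
    """
    x = np.asarray(intensity, dtype=float)
    n = x.size
    if n < 2 * min_segment:
        return None
    c = np.cumsum(x)
    total = c[-1]
    mean = total / n
    k = np.arange(min_segment, n - min_segment + 1)
    m1 = c[k - 1] / k
    m2 = (total - c[k - 1]) / (n - k)
    objective = k * (m1 - mean) ** 2 + (n - k) * (m2 - mean) ** 2
    j = int(np.argmax(objective))
    sigma = np.sqrt(max(background, 1.0))
    ceiling = background + 2.0 * sigma
    if m1[j] > ceiling and m2[j] <= ceiling:
        return int(k[j])
    return None


def compute_efret(traj: Trajectory, factors: CorrectionFactors, *,
                  acceptor_min: float = 50.0,
                  background: float = 10.0) -> EfretTrace:
    """Convert a raw trajectory into a corrected FRET-efficiency trace.

    ``acceptor_min`` is the direct-excitation intensity required to consider
    the acceptor present in a frame (same scale as the colocalization photon
    threshold). ``background`` parameterizes the bleach-step acceptance test.
    """
    for name, value in (("leakage", factors.leakage),
                        ("direct_excitation", factors.direct_excitation),
                        ("gamma", factors.gamma)):
        if not np.isfinite(value):
            raise ValueError(f"{name} must be finite")
    f_corr = (traj.f_da - factors.leakage * traj.f_dd
              - factors.direct_excitation * traj.f_aa)
    denom = f_corr + factors.gamma * traj.f_dd
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(denom > 0, f_corr / np.where(denom > 0, denom, 1.0), np.nan)

    valid = (denom > 0) & (traj.f_aa >= acceptor_min)
    with np.errstate(invalid="ignore"):
        valid &= (e >= -0.2) & (e <= 1.2)
    donor_bleach = detect_bleach(traj.f_dd, background=background)
    acceptor_bleach = detect_bleach(traj.f_aa, background=background)
    if donor_bleach is not None:
        valid[donor_bleach:] = False
    if acceptor_bleach is not None:
        valid[acceptor_bleach:] = False
    with np.errstate(invalid="ignore"):
        in_range = (e >= 0.0) & (e <= 1.0)

    return EfretTrace(
        molecule_id=traj.molecule_id,
        time_s=traj.time_s,
        e=e,
        valid=valid,
        in_range=in_range,
        frame_interval=traj.frame_interval,
        donor_bleach_frame=donor_bleach,
        acceptor_bleach_frame=acceptor_bleach,
    )


def _mean_ratio(num: np.ndarray, den: np.ndarray, background: float,
                min_signal: float) -> float:
    use = (den - background) >= min_signal
    if not np.any(use):
        raise ValueError("no frames with sufficient calibration signal")
    ratios = (num[use] - background) / (den[use] - background)
    return float(np.mean(ratios))


def estimate_factors(
    donor_only: TrajectorySet,
    acceptor_only: TrajectorySet,
    fret_set: TrajectorySet | None = None,
    *,
    background: float = 10.0,
    min_signal: float = 50.0,
    min_transitions: int = 5,
    window: int = 10,
) -> CorrectionFactors:
    """Estimate correction factors from single-species calibration data.

    Leakage is the mean background-subtracted ``F_DA / F_DD`` ratio over
    donor-only molecules; direct excitation is the mean ``F_DA / F_AA`` ratio
    over acceptor-only molecules. Gamma is estimated from intensity changes
    across acceptor photobleach transitions in ``fret_set`` (the ratio of the
    corrected acceptor drop to the donor rise); with fewer than
    ``min_transitions`` usable transitions it falls back to 1.0 with a warning.
    """
    if len(donor_only) == 0 or len(acceptor_only) == 0:
        raise ValueError("calibration sets must not be empty")

    leak_vals, direct_vals = [], []
    for traj in donor_only:
        leak_vals.append(_mean_ratio(traj.f_da, traj.f_dd, background,
                                     min_signal))
    for traj in acceptor_only:
        direct_vals.append(_mean_ratio(traj.f_da, traj.f_aa, background,
                                       min_signal))
    leakage = float(np.mean(leak_vals))
    direct = float(np.mean(direct_vals))
    # shot noise can push the per-molecule means marginally negative
    leakage = min(max(leakage, 0.0), 0.999)
    direct = min(max(direct, 0.0), 0.999)

    gamma = 1.0
    if fret_set is not None:
        ratios = []
        for traj in fret_set:
            ab = detect_bleach(traj.f_aa, background=background)
            if ab is None:
                continue
            db = detect_bleach(traj.f_dd, background=background)
            post_end = min(ab + window, traj.n_frames if db is None else db)
            pre_start = max(ab - window, 0)
            pre = slice(pre_start, ab)
            post = slice(ab, post_end)
            if ab - pre_start < 3 or post_end - ab < 3:
                continue
            f_corr = traj.f_da - leakage * traj.f_dd - direct * traj.f_aa
            # both windows must have the acceptor state expected of a
            # bleach transition (bright donor throughout)
            if np.mean(traj.f_dd[post]) <= np.mean(traj.f_dd[pre]):
                continue
            d_donor = np.mean(traj.f_dd[post]) - np.mean(traj.f_dd[pre])
            d_acceptor = np.mean(f_corr[pre]) - np.mean(f_corr[post])
            if d_donor > 0 and d_acceptor > 0:
                ratios.append(d_acceptor / d_donor)
        if len(ratios) >= min_transitions:
            gamma = float(np.median(ratios))
        else:
            warnings.warn(
                f"only {len(ratios)} usable acceptor-bleach transitions; "
                "falling back to gamma = 1.0", stacklevel=2)
    return CorrectionFactors(leakage=leakage, direct_excitation=direct,
                             gamma=gamma)
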