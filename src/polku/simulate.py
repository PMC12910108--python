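"""Synthetic two-color ALEX trajectory simulators.

Two generators stand in for the raw single-molecule data:

* :func:`simulate_colocalization` renders transient binding of a red-labeled
  polymerase to surface-tethered, green-labeled DNA: exponential first
  arrivals with an unbound molecule fraction, exponential bound dwells,
  rebinding at the same arrival rate, Poisson shot noise, and single-step
  donor photobleaching of the DNA dye.
* :func:`simulate_fret` renders nucleotide incorporation as a FRET staircase:
  on binding the efficiency starts at ``e_start`` and drops by
  ``delta_e_per_nt`` at each incorporation, with per-nucleotide waiting times
  drawn from an exponential of mean ``t_incorporation / n_nucleotides``. The
  recorded acceptor channel carries donor leakage, direct acceptor
  excitation, and a gamma imbalance before Poisson sampling. Each productive
  binding is simulated once per molecule: incorporation consumes the primer
  template, so rebinding at the initial FRET level would not be physical.

State is piecewise constant in continuous time; per-frame photon rates are
obtained by integrating the state over each frame interval, so events that
start or end mid-frame contribute fractional intensity, as on a real camera.
``noiseless=True`` returns the expected rates instead of Poisson counts.
"""

from __future__ import annotations

import numpy as np

from .scenarios import InvalidScenarioError, KineticScenario
from .trajectories import GroundTruthEvent, TrajectorySet

__all__ = [
    "simulate_colocalization",
    "simulate_fret",
    "simulate_calibration",
    "distort_acceptor",
]


def distort_acceptor(f_da_ideal, f_dd, f_aa, leakage: float,
                     direct_excitation: float):
    """Recorded FRET-channel rate: ideal signal plus leakage and direct excitation."""
    return (np.asarray(f_da_ideal, dtype=float)
            + leakage * np.asarray(f_dd, dtype=float)
            + direct_excitation * np.asarray(f_aa, dtype=float))


def _add_interval(rates: np.ndarray, t0: float, t1: float, rate: float,
                  dt: float) -> None:
    """Add ``rate`` over [t0, t1) with fractional frame overlap."""
    n = rates.shape[0]
    t0 = max(float(t0), 0.0)
    t1 = min(float(t1), n * dt)
    if t1 <= t0 or rate == 0.0:
        return
    i0 = int(t0 // dt)
    i1 = min(int(np.ceil(t1 / dt)), n)
    idx = np.arange(i0, i1)
    starts = idx * dt
    frac = (np.minimum(starts + dt, t1) - np.maximum(starts, t0)) / dt
    rates[idx] += rate * frac


def _molecule_rngs(scenario: KineticScenario) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(scenario.seed)
    return [np.random.default_rng(child) for child in ss.spawn(scenario.n_molecules)]


def simulate_colocalization(
    scenario: KineticScenario, *, noiseless: bool = False
) -> tuple[TrajectorySet, list[GroundTruthEvent]]:
    """Simulate transient polymerase-DNA colocalization trajectories.

    The DNA channel (``F_DD``) is constant bright until the donor bleaches;
    the polymerase channel (``F_AA``) is at ``photon_budget`` while a molecule
    is bound and at ``background`` otherwise. ``F_DA`` carries background
    only. Returns the trajectory set and the ground-truth binding events.
    """
    scenario.validate()
    dt = scenario.frame_interval
    n_frames = scenario.n_frames
    if n_frames < 1:
        raise InvalidScenarioError("movie too short for a single frame")
    time_s = np.arange(n_frames) * dt
    T = n_frames * dt
    bg = scenario.background
    budget = scenario.photon_budget

    truth: list[GroundTruthEvent] = []
    fdd_all, fda_all, faa_all, mids = [], [], [], []
    for mid, rng in enumerate(_molecule_rngs(scenario)):
        fdd = np.full(n_frames, bg)
        fda = np.full(n_frames, bg)
        faa = np.full(n_frames, bg)

        donor_bleach = rng.exponential(scenario.bleach_tau_donor)
        _add_interval(fdd, 0.0, donor_bleach, budget - bg, dt)

        if rng.uniform() < scenario.bound_fraction:
            t = rng.exponential(1.0 / scenario.k_bind)
            while t < T:
                dwell = rng.exponential(scenario.tau_dwell)
                t_end = min(t + dwell, T)
                _add_interval(faa, t, t_end, budget - bg, dt)
                truth.append(GroundTruthEvent(mid, "binding", t, t_end))
                t = t + dwell + rng.exponential(1.0 / scenario.k_bind)

        if not noiseless:
            fdd = rng.poisson(fdd).astype(float)
            fda = rng.poisson(fda).astype(float)
            faa = rng.poisson(faa).astype(float)
        mids.append(mid)
        fdd_all.append(fdd)
        fda_all.append(fda)
        faa_all.append(faa)

    trajset = TrajectorySet.from_molecule_arrays(
        mids, time_s, fdd_all, fda_all, faa_all, dt)
    truth.sort(key=lambda ev: (ev.molecule_id, ev.t_start))
    return trajset, truth


def simulate_fret(
    scenario: KineticScenario, *, noiseless: bool = False
) -> tuple[TrajectorySet, list[GroundTruthEvent]]:
    """Simulate FRET staircase trajectories for nucleotide incorporation.

    Ideal channel rates while the donor is alive and the acceptor present:
    ``F_DD = (1 - E) * photon_budget``, ``F_DA_ideal = gamma * E *
    photon_budget``, ``F_AA = photon_budget``; the recorded ``F_DA`` adds
    ``leakage * F_DD + direct_excitation * F_AA`` before Poisson sampling, and
    ``background`` is added to each channel. After the final incorporation
    the molecule remains bound at the final FRET level for an exponential
    residence of mean ``tau_dwell``. Single-step bleaching truncates the
    respective dye (the acceptor clock starts at binding).
    """
    scenario.validate()
    dt = scenario.frame_interval
    n_frames = scenario.n_frames
    if n_frames < 1:
        raise InvalidScenarioError("movie too short for a single frame")
    time_s = np.arange(n_frames) * dt
    T = n_frames * dt
    bg = scenario.background
    budget = scenario.photon_budget
    leak, direct, gamma = (scenario.leakage, scenario.direct_excitation,
                           scenario.gamma)
    n_nt = scenario.n_nucleotides

    truth: list[GroundTruthEvent] = []
    fdd_all, fda_all, faa_all, mids = [], [], [], []
    for mid, rng in enumerate(_molecule_rngs(scenario)):
        donor_bleach = rng.exponential(scenario.bleach_tau_donor)

        t_bind = np.inf
        inc_times = np.empty(0)
        t_off = np.inf
        acceptor_bleach = np.inf
        if rng.uniform() < scenario.bound_fraction:
            t_bind = rng.exponential(1.0 / scenario.k_bind)
            if n_nt > 0:
                waits = rng.exponential(scenario.t_incorporation / n_nt,
                                        size=n_nt)
                inc_times = t_bind + np.cumsum(waits)
            last = inc_times[-1] if n_nt > 0 else t_bind
            t_off = last + rng.exponential(scenario.tau_dwell)
            acceptor_bleach = t_bind + rng.exponential(
                scenario.bleach_tau_acceptor)

        # piecewise-constant state segments over [0, T]
        points = {0.0, T}
        for p in (t_bind, t_off, donor_bleach, acceptor_bleach,
                  *inc_times.tolist()):
            if 0.0 < p < T:
                points.add(float(p))
        bounds = sorted(points)

        fdd = np.full(n_frames, bg)
        fda = np.full(n_frames, bg)
        faa = np.full(n_frames, bg)
        for a, b in zip(bounds[:-1], bounds[1:]):
            m = 0.5 * (a + b)
            bound = t_bind <= m < t_off
            donor_alive = m < donor_bleach
            acceptor_on = bound and m < acceptor_bleach
            n_inc = int(np.searchsorted(inc_times, m, side="right"))
            e = scenario.e_start - n_inc * scenario.delta_e_per_nt
            e_eff = e if (donor_alive and acceptor_on) else 0.0
            s_dd = budget * (1.0 - e_eff) if donor_alive else 0.0
            s_da_ideal = gamma * e_eff * budget if (donor_alive and acceptor_on) else 0.0
            s_aa = budget if acceptor_on else 0.0
            s_da = distort_acceptor(s_da_ideal, s_dd, s_aa, leak, direct)
            _add_interval(fdd, a, b, s_dd, dt)
            _add_interval(fda, a, b, float(s_da), dt)
            _add_interval(faa, a, b, s_aa, dt)

        if t_bind < T:
            bind_end = min(t_off, T)
            truth.append(GroundTruthEvent(mid, "binding", t_bind, bind_end))
            prev = t_bind
            for i, tc in enumerate(inc_times):
                if tc < T:
                    truth.append(GroundTruthEvent(
                        mid, "incorporation-step", prev, float(tc),
                        nt_index=i + 1))
                prev = float(tc)
            if t_bind < donor_bleach < bind_end:
                truth.append(GroundTruthEvent(mid, "bleach-donor",
                                              donor_bleach, bind_end))
            if acceptor_bleach < bind_end:
                truth.append(GroundTruthEvent(mid, "bleach-acceptor",
                                              acceptor_bleach, bind_end))

        if not noiseless:
            fdd = rng.poisson(fdd).astype(float)
            fda = rng.poisson(fda).astype(float)
            faa = rng.poisson(faa).astype(float)
        mids.append(mid)
        fdd_all.append(fdd)
        fda_all.append(fda)
        faa_all.append(faa)

    trajset = TrajectorySet.from_molecule_arrays(
        mids, time_s, fdd_all, fda_all, faa_all, dt)
    truth.sort(key=lambda ev: (ev.molecule_id, ev.t_start))
    return trajset, truth


def simulate_calibration(
    scenario: KineticScenario,
    species: str,
    *,
    n_molecules: int | None = None,
    seed: int | None = None,
    noiseless: bool = False,
) -> TrajectorySet:
    """Simulate single-dye calibration trajectories.

    ``species="donor_only"`` yields molecules carrying only the donor dye
    (``F_DA`` contains leakage only); ``species="acceptor_only"`` yields
    molecules carrying only the acceptor (``F_DA`` contains direct excitation
    only). Each dye is constant bright until its single-step bleach. Used to
    estimate the leakage and direct-excitation correction factors.
    """
    if species not in ("donor_only", "acceptor_only"):
        raise ValueError("species must be 'donor_only' or 'acceptor_only'")
    scenario.validate()
    n_mol = scenario.n_molecules if n_molecules is None else n_molecules
    dt = scenario.frame_interval
    n_frames = scenario.n_frames
    time_s = np.arange(n_frames) * dt
    bg = scenario.background
    budget = scenario.photon_budget
    base_seed = scenario.seed if seed is None else seed
    ss = np.random.SeedSequence((base_seed, 0xCA1))

    fdd_all, fda_all, faa_all, mids = [], [], [], []
    for mid, child in enumerate(ss.spawn(n_mol)):
        rng = np.random.default_rng(child)
        fdd = np.full(n_frames, bg)
        fda = np.full(n_frames, bg)
        faa = np.full(n_frames, bg)
        if species == "donor_only":
            bleach = rng.exponential(scenario.bleach_tau_donor)
            _add_interval(fdd, 0.0, bleach, budget, dt)
            _add_interval(fda, 0.0, bleach, scenario.leakage * budget, dt)
        else:
            bleach = rng.exponential(scenario.bleach_tau_acceptor)
            _add_interval(faa, 0.0, bleach, budget, dt)
            _add_interval(fda, 0.0, bleach,
                          scenario.direct_excitation * budget, dt)
        if not noiseless:
            fdd = rng.poisson(fdd).astype(float)
            fda = rng.poisson(fda).astype(float)
            faa = rng.poisson(faa).astype(float)
        mids.append(mid)
        fdd_all.append(fdd)
        fda_all.append(fda)
        faa_all.append(faa)

    return TrajectorySet.from_molecule_arrays(
        mids, time_s, fdd_all, fda_all, faa_all, dt)
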