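"""Ground-truth kinetic scenarios for simulated single-molecule experiments.

A :class:`KineticScenario` bundles every parameter needed to simulate one
experimental condition: binding kinetics (first-arrival rate, bound fraction,
bound dwell), nucleotide-incorporation kinetics (mean total incorporation time,
number of incorporations, FRET staircase geometry), and photophysics
(photon budget, leakage, direct excitation, gamma, photobleaching lifetimes,
background). Scenarios for the experimental conditions studied with and
without Ku ship as YAML fixtures under ``polku/data`` and are loaded with
:func:`load_condition`.
"""

from __future__ import annotations

import dataclasses
import math
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "InvalidScenarioError",
    "KineticScenario",
    "available_conditions",
    "load_condition",
]


class InvalidScenarioError(ValueError):
    """Raised when a scenario's parameters violate its invariants."""


@dataclasses.dataclass(frozen=True)
class KineticScenario:
    """Parameters of one simulated single-molecule condition.

    Parameters
    ----------
    condition_label:
        Free-text name of the experimental condition.
    k_bind:
        First-arrival binding rate in s^-1; also governs rebinding.
    bound_fraction:
        Fraction of molecules that ever bind (plateau of the cumulative
        fraction-bound curve), in [0, 1].
    tau_dwell:
        Mean bound dwell in seconds. In FRET simulations this is the mean
        residence time after the final incorporation.
    t_incorporation:
        Mean total nucleotide-incorporation time per productive binding, s.
    n_nucleotides:
        Number of incorporations per productive binding event.
    e_start:
        FRET efficiency at the moment of binding.
    delta_e_per_nt:
        FRET efficiency decrease per incorporated nucleotide.
    frame_interval:
        Seconds per alternating-excitation cycle (one cycle = one frame of
        all three ALEX channels).
    movie_length:
        Observation window in seconds.
    photon_budget:
        Mean detected photons per frame from a dye at zero FRET.
    leakage:
        Donor-emission bleed-through fraction into the acceptor channel.
    direct_excitation:
        Fraction of the acceptor-excitation signal appearing in the
        donor-excitation acceptor channel.
    gamma:
        Detection/quantum-yield imbalance factor applied to the acceptor.
    bleach_tau_donor, bleach_tau_acceptor:
        Mean single-step photobleaching lifetimes in seconds. The donor (DNA
        dye) clock starts at frame 0; the acceptor (polymerase dye) clock
        starts when the molecule binds.
    background:
        Mean background photons per frame and channel.
    n_molecules:
        Number of molecules to simulate.
    seed:
        Seed for the simulation's random generator.
    """

    condition_label: str
    k_bind: float
    bound_fraction: float
    tau_dwell: float
    t_incorporation: float
    n_nucleotides: int
    e_start: float = 0.6
    delta_e_per_nt: float = 0.1
    frame_interval: float = 0.2
    movie_length: float = 180.0
    photon_budget: float = 500.0
    leakage: float = 0.1
    direct_excitation: float = 0.05
    gamma: float = 1.2
    bleach_tau_donor: float = 200.0
    bleach_tau_acceptor: float = 100.0
    background: float = 10.0
    n_molecules: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Check all invariants, raising :class:`InvalidScenarioError`."""
        err = []
        if not self.k_bind > 0:
            err.append("k_bind must be > 0")
        if not 0.0 <= self.bound_fraction <= 1.0:
            err.append("bound_fraction must be in [0, 1]")
        for name in ("tau_dwell", "t_incorporation", "bleach_tau_donor",
                     "bleach_tau_acceptor"):
            if not getattr(self, name) > 0:
                err.append(f"{name} must be > 0")
        if not (isinstance(self.n_nucleotides, int) and self.n_nucleotides >= 0):
            err.append("n_nucleotides must be a non-negative integer")
        if not 0 < self.e_start <= 1:
            err.append("e_start must be in (0, 1]")
        if not 0 < self.delta_e_per_nt < 1:
            err.append("delta_e_per_nt must be in (0, 1)")
        if self.n_nucleotides * self.delta_e_per_nt >= self.e_start:
            err.append("n_nucleotides * delta_e_per_nt must stay below e_start")
        if not self.frame_interval > 0:
            err.append("frame_interval must be > 0")
        if not self.movie_length > 0:
            err.append("movie_length must be > 0")
        if not self.photon_budget > 0:
            err.append("photon_budget must be > 0")
        if not 0 <= self.leakage < 1:
            err.append("leakage must be in [0, 1)")
        if not 0 <= self.direct_excitation < 1:
            err.append("direct_excitation must be in [0, 1)")
        if not self.gamma > 0:
            err.append("gamma must be > 0")
        if self.background < 0:
            err.append("background must be >= 0")
        if not (isinstance(self.n_molecules, int) and self.n_molecules >= 1):
            err.append("n_molecules must be a positive integer")
        if err:
            raise InvalidScenarioError("; ".join(err))

    @property
    def n_frames(self) -> int:
        return int(round(self.movie_length / self.frame_interval))

    @property
    def e_final(self) -> float:
        """FRET efficiency after the last incorporation."""
        return self.e_start - self.n_nucleotides * self.delta_e_per_nt

    def replace(self, **changes: Any) -> "KineticScenario":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "KineticScenario":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise InvalidScenarioError(f"unknown scenario fields: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "KineticScenario":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise InvalidScenarioError(f"{path} does not contain a scenario mapping")
        return cls.from_dict(data)


def _data_dir():
    return resources.files("polku") / "data"


def available_conditions() -> list[str]:
    """Names of the condition fixtures shipped with the package."""
    return sorted(p.name[: -len(".yaml")] for p in _data_dir().iterdir()
                  if p.name.endswith(".yaml"))


def load_condition(name: str) -> KineticScenario:
    """Load a shipped condition fixture by name (see :func:`available_conditions`)."""
    path = _data_dir() / f"{name}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise KeyError(
            f"unknown condition {name!r}; available: {available_conditions()}"
        ) from None
    data = yaml.safe_load(text)
    return KineticScenario.from_dict(data)
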