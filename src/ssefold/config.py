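"""Tunable parameters, collected in one place.

Every geometric threshold and optimizer constant used by the pipeline lives
here so that a run is fully described by a :class:`RunConfig`.  The defaults
are the documented stand-ins discussed in ``docs/methods.md``; none of them
is fitted to data.
"""

from __future__ import annotations

import configparser
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class AnnotationParams:
    """Geometric base-pair detection thresholds.

    A candidate pair (i, j), i+1 < j, must satisfy *all* criteria:

    origin_cutoff
        prefilter on the distance between base-ring centroids, Å.
    c1_cutoff
        C1'-C1' distance window, Å.
    plane_angle_deg
        maximum angle between base-plane normals; near anti-parallel
        (>= 180 - plane_angle_deg) also accepted.
    vertical_cutoff
        maximum projection of the centroid displacement onto the mean
        base normal ("rise" between the two bases), Å.
    hbond_cutoff
        at least one polar heavy-atom contact between the two base edges
        must be within this distance, Å.
    """

    origin_cutoff: float = 15.0
    c1_cutoff: float = 10.5
    plane_angle_deg: float = 65.0
    vertical_cutoff: float = 2.5
    hbond_cutoff: float = 3.5


@dataclass
class SanitationParams:
    """Residue/chain filters applied when ingesting deposited structures."""

    min_atoms_per_residue: int = 9   # residues with fewer observed heavy atoms are dropped
    min_chain_length: int = 6        # shorter chains cannot form an SSE and are rejected


@dataclass
class HelixParams:
    """Idealized A-form helix constants used by the fixture generator."""

    twist_deg: float = 32.7
    rise: float = 2.81


@dataclass
class EnergyParams:
    """Built-in geometric scoring/minimization constants.

    The default scorer is a soft-sphere clash term plus harmonic restraints
    that hold SSE junctions together; it is deliberately simple and fully
    pluggable (any ``coords -> float`` callable can replace it).
    """

    contact_distance: float = 2.8      # Å, non-bonded heavy-atom contact
    k_clash: float = 100.0             # score units / Å^2
    k_restraint: float = 10.0          # score units / Å^2
    bond_length_o3p: float = 1.6       # Å, target for inter-residue O3'-P links
    chain_break_cutoff: float = 4.0    # Å; links longer than this at assembly time
                                       # are held at their current length instead
    max_iter: int = 500
    grad_tol: float = 1e-4


@dataclass
class SamcParams:
    """Simulated-annealing Monte Carlo schedule and move amplitudes."""

    t_start: float = 5.0               # score units
    t_end: float = 0.1
    cooling: float = 0.98              # geometric factor
    cool_every: int = 100              # steps between coolings
    max_translation: float = 2.0       # Å
    max_rotation_deg: float = 10.0


@dataclass
class RunConfig:
    """Full configuration of a pipeline run."""

    scheme: str = "lib1"
    seed: int = 0
    verbosity: int = 1
    annotation: AnnotationParams = field(default_factory=AnnotationParams)
    sanitation: SanitationParams = field(default_factory=SanitationParams)
    helix: HelixParams = field(default_factory=HelixParams)
    energy: EnergyParams = field(default_factory=EnergyParams)
    samc: SamcParams = field(default_factory=SamcParams)

    _SECTIONS = ("annotation", "sanitation", "helix", "energy", "samc")

    def to_file(self, path: str | Path) -> None:
        cp = configparser.ConfigParser()
        cp["run"] = {
            "scheme": self.scheme,
            "seed": str(self.seed),
            "verbosity": str(self.verbosity),
        }
        for section in self._SECTIONS:
            obj = getattr(self, section)
            cp[section] = {k: repr(v) for k, v in dataclasses.asdict(obj).items()}
        with open(path, "w") as fh:
            cp.write(fh)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        cp = configparser.ConfigParser()
        with open(path) as fh:
            cp.read_file(fh)
        cfg = cls()
        if cp.has_section("run"):
            cfg.scheme = cp.get("run", "scheme", fallback=cfg.scheme)
            cfg.seed = cp.getint("run", "seed", fallback=cfg.seed)
            cfg.verbosity = cp.getint("run", "verbosity", fallback=cfg.verbosity)
        for section in cls._SECTIONS:
            if not cp.has_section(section):
                continue
            obj = getattr(cfg, section)
            for f in dataclasses.fields(obj):
                if cp.has_option(section, f.name):
                    setattr(obj, f.name, _convert(f, cp.get(section, f.name)))
        return cfg


def _convert(f: dataclasses.Field, raw: str):
    typ = f.type if isinstance(f.type, type) else {"int": int, "float": float}.get(str(f.type), float)
    return typ(raw)
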