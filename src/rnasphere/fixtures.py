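"""Synthetic reference structures and controlled decoys.

The generator builds an idealized helical pseudo-RNA: each residue is a
rigid copy of a seeded atom template, placed on a regular helix (A-form-like
defaults: 2.81 Å rise, 32.7° twist, 9.4 Å backbone radius) and rotated with
the helical frame.  The C1' atom sits exactly on the helix, so consecutive
C1'–C1' distances follow the closed-form helical chord length

    d = sqrt(rise² + 2 R² (1 − cos twist)).

The geometry is deliberately idealized rather than chemically accurate: the
method under test is purely geometric, and what matters for testing is full
determinism (every coordinate is a function of the seed alone), presence of
all four sphere-center atom names in every residue, and realistic length
scales.

:func:`perturb` manufactures decoys with precisely known error structure —
global rigid motions (which any superposition-based score must ignore),
single-residue displacements (localized errors), hinge rotations of a
segment, homogeneous Gaussian coordinate noise, and atom deletions (to
exercise the missing-atom/coverage path).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import Atom, Residue, ResidueKey, Structure

__all__ = [
    "DEFAULT_ATOMS_PER_RESIDUE",
    "HelixParams",
    "PerturbationSpec",
    "generate_helix",
    "perturb",
    "c1_chord_length",
]

#: Backbone + sugar + a minimal base stub; includes all four center atoms.
DEFAULT_ATOMS_PER_RESIDUE: tuple[str, ...] = (
    "P",
    "OP1",
    "OP2",
    "O5'",
    "C5'",
    "C4'",
    "O4'",
    "C3'",
    "O3'",
    "C2'",
    "O2'",
    "C1'",
    "N1",
    "C2",
    "N3",
    "C4",
)

_SEQUENCE_CYCLE = ("A", "C", "G", "U")

_CENTER_CANDIDATES = ("C1'", "P", "O5'", "O3'")


@dataclass(frozen=True)
class HelixParams:
    """Geometry and content of a generated pseudo-RNA helix."""

    n_residues: int = 20
    rise_per_residue: float = 2.81  # Å along the helix axis
    twist_per_residue: float = 32.7  # degrees
    backbone_radius: float = 9.4  # Å from axis to C1'
    atoms_per_residue: tuple[str, ...] = DEFAULT_ATOMS_PER_RESIDUE
    chain_id: str = "A"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.rise_per_residue <= 0 or self.backbone_radius <= 0:
            raise ValueError("rise and backbone radius must be positive")
        missing = [n for n in _CENTER_CANDIDATES if n not in self.atoms_per_residue]
        if missing:
            raise ValueError(f"atoms_per_residue must include center candidates; missing {missing}")
        if len(set(self.atoms_per_residue)) != len(self.atoms_per_residue):
            raise ValueError("atoms_per_residue contains duplicate names")


def c1_chord_length(params: HelixParams) -> float:
    """Closed-form distance between consecutive C1' atoms on the helix."""
    twist = math.radians(params.twist_per_residue)
    return math.sqrt(
        params.rise_per_residue**2
        + 2.0 * params.backbone_radius**2 * (1.0 - math.cos(twist))
    )


def _residue_template(params: HelixParams) -> dict[str, np.ndarray]:
    """Seeded local-frame offsets per atom name; C1' is exactly the origin."""
    rng = np.random.default_rng(params.seed)
    template: dict[str, np.ndarray] = {}
    for name in params.atoms_per_residue:
        if name == "C1'":
            template[name] = np.zeros(3)
            continue
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        # bonded-neighbor length scale: 1.4-3.0 Å from the anchor
        template[name] = direction * rng.uniform(1.4, 3.0)
    return template


def generate_helix(params: HelixParams) -> Structure:
    """Deterministic pseudo-RNA helix; same seed, byte-identical output."""
    template = _residue_template(params)
    twist = math.radians(params.twist_per_residue)
    residues: list[Residue] = []
    serial = 0
    for i in range(params.n_residues):
        theta = i * twist
        cos_t, sin_t = math.cos(theta), math.sin(theta)
        # local frame rotating with the helix: radial, tangential, axial
        frame = np.array(
            [
                [cos_t, -sin_t, 0.0],
                [sin_t, cos_t, 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        anchor = np.array(
            [
                params.backbone_radius * cos_t,
                params.backbone_radius * sin_t,
                i * params.rise_per_residue,
            ]
        )
        residue = Residue(
            chain_id=params.chain_id,
            seq_number=i + 1,
            insertion_code="",
            res_name=_SEQUENCE_CYCLE[i % len(_SEQUENCE_CYCLE)],
        )
        for name in params.atoms_per_residue:
            serial += 1
            coords = anchor + frame @ template[name]
            residue.atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=name[0] if name[0].isalpha() else "C",
                    alt_loc="",
                    occupancy=1.0,
                    coords=coords,
                )
            )
        residues.append(residue)
    return Structure(id=f"helix-n{params.n_residues}-s{params.seed}", residues=residues)


@dataclass(frozen=True)
class PerturbationSpec:
    """A seeded, reproducible structural error to apply to a structure.

    kind:
        ``gaussian_noise`` — i.i.d. N(0, magnitude²) noise on every
        coordinate of the target atoms (magnitude in Å);
        ``residue_displacement`` — translate target residues by magnitude Å
        along one seeded random direction;
        ``segment_rotation`` — rotate the target residues by magnitude
        degrees about a seeded random axis hinged at the first target
        residue's first atom;
        ``rigid_motion`` — one seeded random proper rotation of the whole
        selection plus a translation of length magnitude Å;
        ``atom_deletion`` — remove ``atom_names`` from the target residues
        (magnitude unused).
    target:
        ``None`` means all residues; otherwise a sequence of residue keys.
    """

    kind: str
    magnitude: float = 0.0
    target: tuple[ResidueKey, ...] | None = None
    atom_names: tuple[str, ...] = ("P",)
    seed: int = 0

    _KINDS = (
        "gaussian_noise",
        "residue_displacement",
        "segment_rotation",
        "rigid_motion",
        "atom_deletion",
    )

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.target is not None:
            object.__setattr__(self, "target", tuple(self.target))


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def perturb(structure: Structure, spec: PerturbationSpec) -> Structure:
    """Apply one seeded perturbation, returning a new decoy structure.

    Residue and atom keys are preserved for every kind except
    ``atom_deletion``, which only removes.  An explicitly empty target
    range is an error (nothing to perturb is almost certainly a bug in the
    caller's selection).
    """
    if spec.target is not None and len(spec.target) == 0:
        raise ValueError("empty perturbation target range")
    decoy = copy.deepcopy(structure)
    decoy.id = f"{structure.id}|{spec.kind}-s{spec.seed}"
    if spec.target is None:
        targets = [r for r in decoy.residues]
    else:
        wanted = set(spec.target)
        targets = [r for r in decoy.residues if r.key in wanted]
        if not targets:
            raise ValueError(f"no residues match target keys {spec.target}")
    rng = np.random.default_rng(spec.seed)

    if spec.kind == "gaussian_noise":
        for residue in targets:
            for atom in residue.atoms:
                atom.coords = atom.coords + rng.normal(0.0, spec.magnitude, size=3)
    elif spec.kind == "residue_displacement":
        shift = spec.magnitude * _unit_vector(rng)
        for residue in targets:
            for atom in residue.atoms:
                atom.coords = atom.coords + shift
    elif spec.kind == "segment_rotation":
        hinge = targets[0].atoms[0].coords.copy()
        axis = _unit_vector(rng)
        rotation = Rotation.from_rotvec(axis * math.radians(spec.magnitude)).as_matrix()
        for residue in targets:
            for atom in residue.atoms:
                atom.coords = hinge + rotation @ (atom.coords - hinge)
    elif spec.kind == "rigid_motion":
        rotation = Rotation.random(rng=rng).as_matrix()
        translation = spec.magnitude * _unit_vector(rng)
        for residue in targets:
            for atom in residue.atoms:
                atom.coords = rotation @ atom.coords + translation
    elif spec.kind == "atom_deletion":
        doomed = set(spec.atom_names)
        for residue in targets:
            residue.atoms = [a for a in residue.atoms if a.name not in doomed]
        decoy.residues = [r for r in decoy.residues if r.atoms]
    return decoy
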