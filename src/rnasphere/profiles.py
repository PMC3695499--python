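"""Radii sweeps and their aggregates: profile matrices, averaged and cutoff curves.

A :class:`ProfileMatrix` is the residue × radius grid of sphere RMSD values
for one model — the data behind every plot the tool draws.  Undefined cells
(missing anchor atom, fewer than three paired atoms) are stored as NaN and
tracked with a reason; they are excluded from means and from cutoff
denominators, never interpolated and never treated as infinite.

The default radii vector (3, 8, 20, 38, 300 Å) walks the assessment from
the immediate chemical neighborhood of a nucleotide out to the whole
molecule: at 300 Å every sphere of a typical RNA contains every atom, so
each row of the last column equals the global RMSD.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .sphere_metrics import (
    ALL_ATOMS,
    AtomCorrespondence,
    PairEngine,
    SphereGap,
    SphereSpec,
    match_atoms,
)
from .structure_io import ResidueKey, Structure

__all__ = [
    "DEFAULT_RADII",
    "RadiiVector",
    "ProfileMatrix",
    "AveragedCurve",
    "CutoffCurve",
    "compute_profile",
    "averaged_curve",
    "cutoff_curve",
    "write_profile",
    "read_profile",
]


@dataclass(frozen=True)
class RadiiVector:
    """Strictly increasing vector of positive sphere radii in Å."""

    radii: tuple[float, ...]

    def __post_init__(self) -> None:
        radii = tuple(float(r) for r in self.radii)
        object.__setattr__(self, "radii", radii)
        if not radii:
            raise ValueError("radii vector must be non-empty")
        if any(r <= 0 for r in radii):
            raise ValueError("all radii must be positive")
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValueError("radii must be strictly increasing")

    def __iter__(self):
        return iter(self.radii)

    def __len__(self) -> int:
        return len(self.radii)

    def index_of(self, radius: float, rtol: float = 1e-9) -> int:
        for i, r in enumerate(self.radii):
            if np.isclose(r, radius, rtol=rtol, atol=0.0):
                return i
        raise ValueError(f"radius {radius} not in radii vector {self.radii}")


#: Sweep used throughout unless overridden: local (3 Å) to global (300 Å).
DEFAULT_RADII = RadiiVector((3.0, 8.0, 20.0, 38.0, 300.0))


@dataclass
class ProfileMatrix:
    """Residue × radius grid of sphere RMSD values (Å) for one model.

    ``values`` and ``coverage`` are parallel float grids of shape
    ``(len(residue_order), len(radii))``; NaN marks a gap.  ``gap_reasons``
    maps (row, column) to a reason code for every NaN cell.
    """

    model_id: str
    residue_order: tuple[ResidueKey, ...]
    radii: RadiiVector
    values: np.ndarray
    coverage: np.ndarray
    gap_reasons: dict[tuple[int, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = (len(self.residue_order), len(self.radii))
        if self.values.shape != expected or self.coverage.shape != expected:
            raise ValueError(
                f"grid shape {self.values.shape} does not match "
                f"{len(self.residue_order)} residues x {len(self.radii)} radii"
            )

    @property
    def n_residues(self) -> int:
        return len(self.residue_order)

    def column(self, radius: float) -> np.ndarray:
        return self.values[:, self.radii.index_of(radius)]


@dataclass
class AveragedCurve:
    """Mean sphere RMSD per radius over the residues where it is defined."""

    model_id: str
    radii: RadiiVector
    mean_rmsd: np.ndarray  # NaN where no residue is defined
    n_defined: np.ndarray


@dataclass
class CutoffCurve:
    """Percentage of residues at or below an RMSD threshold, per radius."""

    model_id: str
    threshold: float
    radii: RadiiVector
    percent_below: np.ndarray  # in [0, 100]; NaN where no residue is defined
    n_defined: np.ndarray


def compute_profile(
    reference: Structure,
    model: Structure,
    spec_base: SphereSpec,
    radii: RadiiVector,
    correspondence: AtomCorrespondence | None = None,
    model_id: str | None = None,
) -> ProfileMatrix:
    """Evaluate every (residue, radius) sphere of the reference against the model.

    ``spec_base`` supplies the anchor atom and accuracy mode; its radius, if
    any, is ignored in favor of the swept vector.  Rows follow the
    reference's file order (the X axis of the plots).  Gaps are recorded,
    never interpolated.
    """
    if correspondence is None:
        correspondence = match_atoms(reference, model)
    engine = PairEngine(
        reference, model, correspondence, spec_base.center_atom_name, spec_base.mode
    )
    n_res = len(engine.residue_keys)
    values = np.full((n_res, len(radii)), np.nan)
    coverage = np.full((n_res, len(radii)), np.nan)
    gap_reasons: dict[tuple[int, int], str] = {}
    for j, radius in enumerate(radii):
        for i in range(n_res):
            cell = engine.cell(i, radius)
            if isinstance(cell, SphereGap):
                gap_reasons[(i, j)] = cell.reason
            else:
                values[i, j] = cell.rmsd
                coverage[i, j] = cell.coverage
    return ProfileMatrix(
        model_id=model_id if model_id is not None else model.id,
        residue_order=tuple(engine.residue_keys),
        radii=radii,
        values=values,
        coverage=coverage,
        gap_reasons=gap_reasons,
    )


def averaged_curve(profile: ProfileMatrix) -> AveragedCurve:
    """Unweighted arithmetic mean over residues, per radius.

    Gap cells are excluded from both numerator and denominator; a radius
    with no defined residue at all gets a NaN mean and ``n_defined`` 0.
    """
    defined = ~np.isnan(profile.values)
    n_defined = defined.sum(axis=0)
    with np.errstate(invalid="ignore"):
        sums = np.nansum(profile.values, axis=0)
        mean = np.where(n_defined > 0, sums / np.maximum(n_defined, 1), np.nan)
    return AveragedCurve(
        model_id=profile.model_id,
        radii=profile.radii,
        mean_rmsd=mean,
        n_defined=n_defined,
    )


def cutoff_curve(profile: ProfileMatrix, threshold: float) -> CutoffCurve:
    """Per radius, the percentage of defined residues with RMSD ≤ threshold.

    The comparison is inclusive, so a self-comparison (all zeros) scores
    100% at any positive threshold.
    """
    if not threshold > 0:
        raise ValueError(f"cutoff threshold must be positive, got {threshold}")
    defined = ~np.isnan(profile.values)
    n_defined = defined.sum(axis=0)
    below = ((profile.values <= threshold) & defined).sum(axis=0)
    percent = np.where(n_defined > 0, 100.0 * below / np.maximum(n_defined, 1), np.nan)
    return CutoffCurve(
        model_id=profile.model_id,
        threshold=float(threshold),
        radii=profile.radii,
        percent_below=percent,
        n_defined=n_defined,
    )


_RESIDUE_KEY_RE = re.compile(r"^(?P<chain>[^:]*):(?P<number>-?\d+)(?P<icode>.*)$")


def format_residue_key(key: ResidueKey) -> str:
    chain, number, icode = key
    return f"{chain}:{number}{icode}"


def parse_residue_key(text: str) -> ResidueKey:
    match = _RESIDUE_KEY_RE.match(text)
    if match is None:
        raise ValueError(f"malformed residue key {text!r}")
    return (match.group("chain"), int(match.group("number")), match.group("icode"))


def write_profile(profile: ProfileMatrix, path: str | Path) -> None:
    """Write the profile as UTF-8 CSV.

    Layout: a ``# model=`` comment line, a header row (``residue`` then one
    column per radius labeled with the Å value), one row per residue key
    ``chain:number[icode]``.  Gap cells are empty fields.  Values are
    printed with 17 significant digits, so the matrix round-trips through
    :func:`read_profile` without loss.  Coverage is not persisted.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as handle:
        handle.write(f"# model={profile.model_id}\n")
        writer = csv.writer(handle)
        writer.writerow(["residue"] + [format(r, ".17g") for r in profile.radii])
        for i, key in enumerate(profile.residue_order):
            row = [format_residue_key(key)]
            for j in range(len(profile.radii)):
                v = profile.values[i, j]
                row.append("" if np.isnan(v) else format(v, ".17g"))
            writer.writerow(row)


def read_profile(path: str | Path) -> ProfileMatrix:
    """Inverse of :func:`write_profile`.

    Coverage was not persisted, so the returned matrix carries an all-NaN
    coverage grid; gap cells get the generic reason ``from_file``.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8", newline="") as handle:
        first = handle.readline()
        model_id = ""
        if first.startswith("# model="):
            model_id = first[len("# model=") :].rstrip("\n")
            header_line = handle.readline()
        else:
            header_line = first
        reader = csv.reader([header_line])
        header = next(reader)
        if not header or header[0] != "residue":
            raise ValueError(f"{path}: malformed profile header {header!r}")
        try:
            radii = RadiiVector(tuple(float(h) for h in header[1:]))
        except ValueError as exc:
            raise ValueError(f"{path}: malformed radius labels in header") from exc
        residue_order: list[ResidueKey] = []
        rows: list[list[float]] = []
        gap_reasons: dict[tuple[int, int], str] = {}
        for i, row in enumerate(csv.reader(handle)):
            if not row:
                continue
            if len(row) != len(radii) + 1:
                raise ValueError(f"{path}: row {i} has {len(row)} fields, expected {len(radii) + 1}")
            residue_order.append(parse_residue_key(row[0]))
            parsed: list[float] = []
            for j, cell in enumerate(row[1:]):
                if cell == "":
                    parsed.append(np.nan)
                    gap_reasons[(i, j)] = "from_file"
                else:
                    parsed.append(float(cell))
            rows.append(parsed)
    values = np.asarray(rows, dtype=float).reshape(len(residue_order), len(radii))
    return ProfileMatrix(
        model_id=model_id,
        residue_order=tuple(residue_order),
        radii=radii,
        values=values,
        coverage=np.full_like(values, np.nan),
        gap_reasons=gap_reasons,
    )
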