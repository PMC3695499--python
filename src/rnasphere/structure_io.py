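"""Read, validate and write RNA structures in PDB format.

The parser builds a deliberately small hierarchy (Structure -> Residue ->
Atom) that preserves exactly what the downstream geometry needs: chain and
residue identity as printed in the file, normalized atom names, and
coordinates.  Nothing is renumbered and no chemistry is inferred beyond
element/hydrogen detection.

Normalization rules applied on input:

* legacy atom-name dialect ``*`` is mapped to ``'`` (``C1*`` becomes ``C1'``);
* surrounding whitespace in names is stripped;
* alternate-location (altLoc) conformers are collapsed to the
  highest-occupancy one, ties broken by altLoc letter order;
* hydrogens and HETATM records are dropped by default (both selectable).

Validation never raises: every finding is collected into a
:class:`ValidationReport` with a severity, a machine-readable code and a
locus, so a caller can decide what is fatal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "ValidationIssue",
    "ValidationReport",
    "PDBError",
    "PDBParseError",
    "EmptyStructureError",
    "CENTER_ATOM_NAMES",
    "STANDARD_NUCLEOTIDES",
    "normalize_atom_name",
    "parse_pdb",
    "validate",
    "write_structure",
]

#: Atom names accepted as sphere centers, in the tool's canonical spelling.
CENTER_ATOM_NAMES: tuple[str, ...] = ("C1'", "P", "O5'", "O3'")

#: Unmodified ribonucleotide residue names.
STANDARD_NUCLEOTIDES: frozenset[str] = frozenset({"A", "C", "G", "U"})

#: (chain_id, seq_number, insertion_code)
ResidueKey = tuple[str, int, str]

#: (chain_id, seq_number, insertion_code, atom_name)
AtomKey = tuple[str, int, str, str]


class PDBError(Exception):
    """Base class for structure I/O failures."""


class PDBParseError(PDBError):
    """A record could not be interpreted; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class EmptyStructureError(PDBError):
    """The file (or the requested MODEL block) contains no usable atoms."""


def normalize_atom_name(name: str) -> str:
    """Strip whitespace and map the old prime dialect ``*`` to ``'``."""
    return name.strip().replace("*", "'")


def _infer_element(atom_name: str) -> str:
    # PDB names may lead with digits (e.g. 1H5'); the element is the first
    # alphabetic character.
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return ""


@dataclass
class Atom:
    """A single atom with its PDB identity and Cartesian coordinates (Å)."""

    serial: int
    name: str
    element: str
    alt_loc: str
    occupancy: float
    coords: np.ndarray
    is_hydrogen: bool = False
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coords must be 3 finite values")
        if not self.name:
            raise ValueError("atom name must be non-empty after normalization")


@dataclass
class Residue:
    """One nucleotide (or other residue) identified as printed in the file."""

    chain_id: str
    seq_number: int
    insertion_code: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def get_atom(self, name: str) -> Atom | None:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None


@dataclass
class Structure:
    """An ordered collection of residues read from one MODEL of one file."""

    id: str
    residues: list[Residue] = field(default_factory=list)
    source_path: str = ""
    model_index: int = 0

    def iter_atoms(self) -> Iterator[tuple[Residue, Atom]]:
        """Yield (residue, atom) pairs in file order."""
        for residue in self.residues:
            for atom in residue.atoms:
                yield residue, atom

    def atom_keys(self) -> list[AtomKey]:
        return [res.key + (atom.name,) for res, atom in self.iter_atoms()]

    def atom_table(self) -> dict[AtomKey, Atom]:
        return {res.key + (atom.name,): atom for res, atom in self.iter_atoms()}

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def get_residue(self, key: ResidueKey) -> Residue | None:
        for residue in self.residues:
            if residue.key == key:
                return residue
        return None


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "warning" | "error"
    code: str
    message: str
    locus: str


@dataclass
class ValidationReport:
    """All findings for one structure; empty issues means a clean pass."""

    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    @property
    def has_errors(self) -> bool:
        return any(i.severity == "error" for i in self.issues)

    def format(self) -> str:
        if self.ok:
            return "no issues found\n"
        lines = [
            f"{i.severity.upper()} [{i.code}] {i.locus}: {i.message}"
            for i in self.issues
        ]
        return "\n".join(lines) + "\n"


def _parse_float(text: str, what: str, line_number: int) -> float:
    try:
        value = float(text)
    except ValueError as exc:
        raise PDBParseError(f"malformed {what} field {text.strip()!r}", line_number) from exc
    if not math.isfinite(value):
        raise PDBParseError(f"non-finite {what} field {text.strip()!r}", line_number)
    return value


def _parse_int(text: str, what: str, line_number: int) -> int:
    try:
        return int(text)
    except ValueError as exc:
        raise PDBParseError(f"malformed {what} field {text.strip()!r}", line_number) from exc


def parse_pdb(
    path: str | Path,
    model_index: int = 0,
    include_hydrogens: bool = False,
    include_hetero: bool = False,
    structure_id: str | None = None,
) -> Structure:
    """Parse one MODEL block of a PDB file into a :class:`Structure`.

    Parameters
    ----------
    path:
        PDB file to read.
    model_index:
        Which MODEL block to read, 0-based.  Files without MODEL records
        expose a single block with index 0.
    include_hydrogens, include_hetero:
        Whether to keep hydrogen atoms / HETATM records (both off by
        default: predicted models frequently omit hydrogens, and ions or
        waters have no counterpart in the residue-wise comparison).

    Raises
    ------
    PDBParseError
        On malformed numeric fields (the message names the line).
    EmptyStructureError
        If no ATOM records survive in the requested MODEL block.
    OSError
        If the file cannot be read.
    """
    path = Path(path)
    raw_records: list[tuple[int, str]] = []  # (line_number, line)
    current_model = -1  # becomes 0 at the first MODEL record
    saw_model_record = False
    with open(path, "r", encoding="utf-8", errors="replace") as handle:
        for line_number, line in enumerate(handle, start=1):
            record = line[:6]
            if record == "MODEL ":
                saw_model_record = True
                current_model += 1
                continue
            if record == "ENDMDL":
                continue
            if record not in ("ATOM  ", "HETATM"):
                continue
            block = current_model if saw_model_record else 0
            if block == model_index or (not saw_model_record and model_index == 0):
                raw_records.append((line_number, line))
    if saw_model_record and model_index > current_model:
        raise EmptyStructureError(
            f"{path}: MODEL index {model_index} not present (file has {current_model + 1})"
        )

    residues: list[Residue] = []
    # altLoc conformers per residue, keyed by normalized atom name
    pending: dict[str, list[Atom]] = {}
    current_key: ResidueKey | None = None

    def flush() -> None:
        if current_key is None:
            return
        residue = residues[-1]
        for name in residue_atom_order:
            conformers = pending[name]
            best = min(conformers, key=lambda a: (-a.occupancy, a.alt_loc))
            residue.atoms.append(best)
        pending.clear()
        residue_atom_order.clear()

    residue_atom_order: list[str] = []

    for line_number, line in raw_records:
        line = line.rstrip("\n")
        if len(line) < 54:
            raise PDBParseError("ATOM record shorter than coordinate fields", line_number)
        is_hetero = line.startswith("HETATM")
        serial = _parse_int(line[6:11], "serial", line_number)
        name = normalize_atom_name(line[12:16])
        if not name:
            raise PDBParseError("empty atom name", line_number)
        alt_loc = line[16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21].strip()
        seq_number = _parse_int(line[22:26], "residue number", line_number)
        insertion_code = line[26].strip()
        x = _parse_float(line[30:38], "x coordinate", line_number)
        y = _parse_float(line[38:46], "y coordinate", line_number)
        z = _parse_float(line[46:54], "z coordinate", line_number)
        occ_text = line[54:60].strip() if len(line) >= 60 else ""
        occupancy = _parse_float(occ_text, "occupancy", line_number) if occ_text else 1.0
        element = line[76:78].strip().upper() if len(line) >= 78 else ""
        if not element:
            element = _infer_element(name)
        is_hydrogen = element in ("H", "D")

        if is_hetero and not include_hetero:
            continue
        if is_hydrogen and not include_hydrogens:
            continue

        key = (chain_id, seq_number, insertion_code)
        if key != current_key:
            flush()
            current_key = key
            residues.append(Residue(chain_id, seq_number, insertion_code, res_name))
        if name not in pending:
            pending[name] = []
            residue_atom_order.append(name)
        pending[name].append(
            Atom(
                serial=serial,
                name=name,
                element=element,
                alt_loc=alt_loc,
                occupancy=occupancy,
                coords=np.array([x, y, z], dtype=float),
                is_hydrogen=is_hydrogen,
                is_hetero=is_hetero,
            )
        )
    flush()

    residues = [r for r in residues if r.atoms]
    if not residues:
        raise EmptyStructureError(f"{path}: no ATOM records in MODEL block {model_index}")
    return Structure(
        id=structure_id if structure_id is not None else path.stem,
        residues=residues,
        source_path=str(path),
        model_index=model_index,
    )


def validate(structure: Structure) -> ValidationReport:
    """Check a parsed structure and report every inconsistency found.

    Findings (never raised, always reported):

    * ``duplicate-residue`` (error): two residues share
      (chain, number, insertion code);
    * ``missing-center-candidate`` (warning): a residue lacks one of the
      sphere-center atoms C1'/P/O5'/O3' — spheres anchored there are
      undefined for that name;
    * ``non-nucleotide`` (warning): residue name outside A/C/G/U;
    * ``chain-break`` (warning): non-consecutive numbering inside a chain.
    """
    issues: list[ValidationIssue] = []
    seen: dict[ResidueKey, int] = {}
    for index, residue in enumerate(structure.residues):
        locus = _format_residue_key(residue.key)
        if residue.key in seen:
            issues.append(
                ValidationIssue(
                    "error",
                    "duplicate-residue",
                    f"residue key duplicates residue at position {seen[residue.key]}",
                    locus,
                )
            )
        else:
            seen[residue.key] = index
        present = {atom.name for atom in residue.atoms}
        for name in CENTER_ATOM_NAMES:
            if name not in present:
                issues.append(
                    ValidationIssue(
                        "warning",
                        "missing-center-candidate",
                        f"residue lacks center-atom candidate {name}",
                        locus,
                    )
                )
        if residue.res_name not in STANDARD_NUCLEOTIDES:
            issues.append(
                ValidationIssue(
                    "warning",
                    "non-nucleotide",
                    f"residue name {residue.res_name!r} is not a standard ribonucleotide",
                    locus,
                )
            )
    for prev, curr in zip(structure.residues, structure.residues[1:]):
        if prev.chain_id != curr.chain_id:
            continue
        if prev.insertion_code or curr.insertion_code:
            continue  # insertion codes legitimately repeat numbers
        if curr.seq_number - prev.seq_number != 1:
            issues.append(
                ValidationIssue(
                    "warning",
                    "chain-break",
                    f"numbering jumps from {prev.seq_number} to {curr.seq_number}",
                    _format_residue_key(curr.key),
                )
            )
    return ValidationReport(issues=issues)


def _format_residue_key(key: ResidueKey) -> str:
    chain, number, icode = key
    return f"{chain}:{number}{icode}"


def _format_atom_name(name: str) -> str:
    # Standard PDB alignment: names shorter than 4 characters start in
    # column 14, leaving column 13 for a two-letter element or a digit.
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write the structure as fixed-column PDB ATOM/HETATM records.

    Serial numbers are renumbered sequentially; one TER record closes each
    chain.  Coordinates are emitted at the format's fixed 3-decimal
    precision, so a parse/write/parse round trip preserves residue keys,
    atom names and coordinates to 0.001 Å.
    """
    if not structure.residues:
        raise EmptyStructureError("cannot write a structure with no residues")
    path = Path(path)
    lines: list[str] = []
    serial = 0
    previous_chain: str | None = None
    last_residue: Residue | None = None

    def ter_line(residue: Residue) -> str:
        return (
            f"TER   {serial + 1:5d}      {residue.res_name:>3s} "
            f"{residue.chain_id:1s}{residue.seq_number:4d}{residue.insertion_code:1s}"
        )

    for residue in structure.residues:
        if previous_chain is not None and residue.chain_id != previous_chain:
            lines.append(ter_line(last_residue))
            serial += 1
        for atom in residue.atoms:
            serial += 1
            record = "HETATM" if atom.is_hetero else "ATOM  "
            x, y, z = atom.coords
            lines.append(
                f"{record}{serial:5d} {_format_atom_name(atom.name)}{'':1s}"
                f"{residue.res_name:>3s} {residue.chain_id:1s}"
                f"{residue.seq_number:4d}{residue.insertion_code:1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2s}"
            )
        previous_chain = residue.chain_id
        last_residue = residue
    lines.append(ter_line(last_residue))
    lines.append("END")
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\n".join(lines) + "\n")
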