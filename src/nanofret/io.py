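"""Readers/writers for the package's plain-text formats and core domain types.

All files are UTF-8 CSV with '.' decimals; lines beginning with '#' are
comments. Readers are strict: malformed rows raise :class:`ParseError`
naming the offending line, and nothing is silently coerced. ``write_*``
followed by ``read_*`` is the identity to 1e-12.

Coordinates are ångström internally; wavelengths nm; TCSPC times ns;
transient-absorption times ps; transition energies eV; dipole moments Debye.
"""

from __future__ import annotations

import dataclasses
import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ParseError",
    "Spectrum",
    "TAMap",
    "DecayTrace",
    "ChromophoreSite",
    "DipoleRule",
    "read_spectrum",
    "write_spectrum",
    "read_ta_map",
    "write_ta_map",
    "read_decay",
    "write_decay",
    "parse_chromophore_sites",
]

SPECTRUM_KINDS = ("absorption", "emission", "delta_A")


class ParseError(ValueError):
    """Raised when an input file violates the expected format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Spectrum:
    """A sampled optical spectrum on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths : array, nm, strictly increasing.
    values : array, same length. Absorbance is unitless OD, emission is in
        arbitrary counts, ``delta_A`` is signed.
    kind : one of ``absorption``, ``emission``, ``delta_A``.
    label : free-text description.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "absorption"
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.ndim != 1 or self.values.ndim != 1:
            raise ValueError("wavelengths and values must be 1-D")
        if self.wavelengths.size != self.values.size:
            raise ValueError(
                f"grid/value length mismatch: {self.wavelengths.size} vs {self.values.size}"
            )
        if self.wavelengths.size and np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.kind not in SPECTRUM_KINDS:
            raise ValueError(f"kind must be one of {SPECTRUM_KINDS}, got {self.kind!r}")

    def __len__(self) -> int:
        return self.wavelengths.size

    def interp(self, grid: np.ndarray) -> "Spectrum":
        """Linear interpolation onto ``grid``; extrapolation is forbidden."""
        grid = np.asarray(grid, dtype=float)
        if grid.size and (grid[0] < self.wavelengths[0] - 1e-9 or grid[-1] > self.wavelengths[-1] + 1e-9):
            raise ValueError(
                f"requested grid [{grid[0]}, {grid[-1]}] nm extends beyond the "
                f"measured range [{self.wavelengths[0]}, {self.wavelengths[-1]}] nm"
            )
        return Spectrum(grid, np.interp(grid, self.wavelengths, self.values), self.kind, self.label)

    def scaled(self, factor: float) -> "Spectrum":
        return Spectrum(self.wavelengths, self.values * factor, self.kind, self.label)


@dataclass
class TAMap:
    """A transient-absorption ΔA(time, wavelength) matrix.

    ``times`` are ps, ``wavelengths`` nm (both strictly increasing);
    ``delta_A`` has shape (n_times, n_wavelengths) and is signed.
    """

    times: np.ndarray
    wavelengths: np.ndarray
    delta_A: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.delta_A = np.asarray(self.delta_A, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.delta_A.shape != (self.times.size, self.wavelengths.size):
            raise ValueError(
                f"delta_A shape {self.delta_A.shape} does not match grids "
                f"({self.times.size}, {self.wavelengths.size})"
            )

    def trace(self, wavelength: float) -> np.ndarray:
        """ΔA(t) at the grid wavelength closest to ``wavelength``."""
        j = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        return self.delta_A[:, j]


@dataclass
class DecayTrace:
    """A time-binned photon-count fluorescence decay (times in ns)."""

    times: np.ndarray
    counts: np.ndarray
    irf: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.counts.size != self.times.size:
            raise ValueError("counts length does not match time grid")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.irf is not None:
            self.irf = np.asarray(self.irf, dtype=float)
            if self.irf.size != self.times.size:
                raise ValueError("irf length does not match time grid")
            if np.any(self.irf < 0):
                raise ValueError("irf must be non-negative")


@dataclass
class ChromophoreSite:
    """A point-dipole chromophore used by the Förster engine.

    position is Å, dipole_magnitude Debye, transition centre/fwhm eV.
    ``band`` is ``Qy``, ``Qx`` (chlorophyll) or ``dye``.
    """

    position: np.ndarray
    dipole_unit: np.ndarray
    dipole_magnitude: float
    band: str
    label: str = ""
    transition_center: float = 2.0
    transition_fwhm: float = 0.06

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.dipole_unit = np.asarray(self.dipole_unit, dtype=float).reshape(3)
        norm = float(np.linalg.norm(self.dipole_unit))
        if abs(norm - 1.0) > 1e-6:
            raise ValueError(f"dipole_unit must be unit norm (got |d| = {norm:.3g})")
        self.dipole_unit = self.dipole_unit / norm
        if self.dipole_magnitude <= 0:
            raise ValueError("dipole_magnitude must be positive")
        if self.band not in ("Qy", "Qx", "dye"):
            raise ValueError(f"band must be Qy, Qx or dye, got {self.band!r}")
        if self.transition_fwhm <= 0:
            raise ValueError("transition_fwhm must be positive")


@dataclass(frozen=True)
class DipoleRule:
    """How to turn one residue into a point dipole: atoms A→B plus band data."""

    atom_a: str
    atom_b: str
    magnitude: float  # Debye
    band: str
    center: float  # eV
    fwhm: float  # eV


# ---------------------------------------------------------------------------
# two-column spectra
# ---------------------------------------------------------------------------


def _iter_data_lines(text: str):
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        yield lineno, line


def _parse_row(line: str, lineno: int, n_cols: int | None = None) -> list[float]:
    parts = [p.strip() for p in line.split(",")]
    if n_cols is not None and len(parts) != n_cols:
        raise ParseError(f"line {lineno}: expected {n_cols} columns, got {len(parts)}")
    try:
        return [float(p) for p in parts]
    except ValueError as exc:
        raise ParseError(f"line {lineno}: non-numeric value in {line!r}") from exc


def read_spectrum(path: str | Path, kind: str = "absorption") -> Spectrum:
    """Read a two-column (wavelength nm, intensity) CSV into a Spectrum.

    Rows may appear in any order; the result is sorted ascending. Duplicate
    wavelengths are rejected. '#' lines are comments.
    """
    text = Path(path).read_text()
    wl, vals = [], []
    for lineno, line in _iter_data_lines(text):
        row = _parse_row(line, lineno, 2)
        wl.append(row[0])
        vals.append(row[1])
    if len(wl) < 2:
        raise ParseError(f"{path}: need at least 2 data rows, got {len(wl)}")
    order = np.argsort(wl)
    wl_arr = np.asarray(wl)[order]
    if np.any(np.diff(wl_arr) == 0):
        dup = wl_arr[np.where(np.diff(wl_arr) == 0)[0][0]]
        raise ParseError(f"{path}: duplicate wavelength {dup} nm")
    return Spectrum(wl_arr, np.asarray(vals)[order], kind=kind, label=Path(path).stem)


def write_spectrum(path: str | Path, spectrum: Spectrum) -> None:
    with open(path, "w") as fh:
        fh.write(f"# kind: {spectrum.kind}\n")
        if spectrum.label:
            fh.write(f"# label: {spectrum.label}\n")
        fh.write("# wavelength_nm,value\n")
        for w, v in zip(spectrum.wavelengths, spectrum.values):
            fh.write(f"{w:.12g},{v:.12g}\n")


# ---------------------------------------------------------------------------
# TA maps
# ---------------------------------------------------------------------------


def read_ta_map(path: str | Path) -> TAMap:
    """Read a ΔA matrix CSV: header row of wavelengths, first column times."""
    text = Path(path).read_text()
    rows = list(_iter_data_lines(text))
    if len(rows) < 2:
        raise ParseError(f"{path}: need a header row and at least one data row")
    header_lineno, header = rows[0]
    cells = [c.strip() for c in header.split(",")]
    try:
        wavelengths = [float(c) for c in cells[1:]]
    except ValueError as exc:
        raise ParseError(f"line {header_lineno}: non-numeric wavelength header") from exc
    if not wavelengths:
        raise ParseError(f"line {header_lineno}: header has no wavelength columns")
    times, body = [], []
    for lineno, line in rows[1:]:
        row = _parse_row(line, lineno, len(wavelengths) + 1)
        times.append(row[0])
        body.append(row[1:])
    try:
        return TAMap(np.asarray(times), np.asarray(wavelengths), np.asarray(body))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_ta_map(path: str | Path, ta: TAMap) -> None:
    with open(path, "w") as fh:
        fh.write("time," + ",".join(f"{w:.12g}" for w in ta.wavelengths) + "\n")
        for t, row in zip(ta.times, ta.delta_A):
            fh.write(f"{t:.12g}," + ",".join(f"{v:.12g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# decay traces
# ---------------------------------------------------------------------------


def read_decay(path: str | Path) -> DecayTrace:
    """Read a (time ns, counts[, irf]) CSV into a DecayTrace."""
    text = Path(path).read_text()
    times, counts, irf = [], [], []
    n_cols = None
    for lineno, line in _iter_data_lines(text):
        row = _parse_row(line, lineno)
        if n_cols is None:
            if len(row) not in (2, 3):
                raise ParseError(f"line {lineno}: expected 2 or 3 columns, got {len(row)}")
            n_cols = len(row)
        elif len(row) != n_cols:
            raise ParseError(f"line {lineno}: expected {n_cols} columns, got {len(row)}")
        times.append(row[0])
        counts.append(row[1])
        if n_cols == 3:
            irf.append(row[2])
    if len(times) < 2:
        raise ParseError(f"{path}: need at least 2 data rows")
    try:
        return DecayTrace(np.asarray(times), np.asarray(counts), np.asarray(irf) if irf else None)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_decay(path: str | Path, trace: DecayTrace) -> None:
    with open(path, "w") as fh:
        if trace.irf is not None:
            fh.write("# time_ns,counts,irf\n")
            for t, c, i in zip(trace.times, trace.counts, trace.irf):
                fh.write(f"{t:.12g},{c:.12g},{i:.12g}\n")
        else:
            fh.write("# time_ns,counts\n")
            for t, c in zip(trace.times, trace.counts):
                fh.write(f"{t:.12g},{c:.12g}\n")


# ---------------------------------------------------------------------------
# PDB-subset chromophore sites
# ---------------------------------------------------------------------------


def _as_rules(value) -> list[DipoleRule]:
    if isinstance(value, DipoleRule):
        return [value]
    if isinstance(value, (tuple, list)) and value and not isinstance(value[0], (tuple, list, DipoleRule)):
        return [DipoleRule(*value)]
    return [r if isinstance(r, DipoleRule) else DipoleRule(*r) for r in value]


def parse_chromophore_sites(
    pdb_text: str,
    dipole_rules: Mapping[str, DipoleRule | Sequence],
) -> list[ChromophoreSite]:
    """Extract point-dipole sites from ATOM/HETATM records.

    ``dipole_rules`` maps a residue name to one rule — or a list of rules, so
    a chlorophyll can yield both its Qy and Qx dipoles. For each matching
    residue the site position is the midpoint of atoms A and B and the dipole
    axis is the normalised A→B vector. Fixed PDB columns are used (atom name
    13–16, residue name 18–20, residue seq 23–26, coordinates 31–54); all
    other records are ignored.
    """
    residues: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    order: list[tuple[str, str]] = []
    for lineno, raw in enumerate(pdb_text.splitlines(), start=1):
        if not raw.startswith(("ATOM", "HETATM")):
            continue
        if len(raw) < 54:
            raise ParseError(f"line {lineno}: truncated ATOM/HETATM record")
        resname = raw[17:20].strip()
        if resname not in dipole_rules:
            continue
        atom = raw[12:16].strip()
        resseq = raw[22:26].strip()
        try:
            xyz = np.array([float(raw[30:38]), float(raw[38:46]), float(raw[46:54])])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-numeric coordinates") from exc
        key = (resname, resseq)
        if key not in residues:
            residues[key] = {}
            order.append(key)
        residues[key][atom] = xyz

    sites: list[ChromophoreSite] = []
    for resname, resseq in order:
        atoms = residues[(resname, resseq)]
        for rule in _as_rules(dipole_rules[resname]):
            missing = [a for a in (rule.atom_a, rule.atom_b) if a not in atoms]
            if missing:
                raise ParseError(
                    f"residue {resname} {resseq}: missing atom(s) {', '.join(missing)}"
                )
            a, b = atoms[rule.atom_a], atoms[rule.atom_b]
            axis = b - a
            norm = float(np.linalg.norm(axis))
            if norm < 1e-9:
                raise ParseError(f"residue {resname} {resseq}: zero-length {rule.atom_a}->{rule.atom_b} vector")
            sites.append(
                ChromophoreSite(
                    position=(a + b) / 2.0,
                    dipole_unit=axis / norm,
                    dipole_magnitude=rule.magnitude,
                    band=rule.band,
                    label=f"{resname}{resseq}:{rule.band}",
                    transition_center=rule.center,
                    transition_fwhm=rule.fwhm,
                )
            )
    return sites
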