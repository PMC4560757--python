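"""XYZ molecular geometry reader/writer.

Format: line 1 atom count, line 2 free comment, then ``SYMBOL x y z`` with
coordinates in angstrom.  The writer emits 6 decimal places.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

from .elements import DEFAULT_AMPLITUDES, COVALENT_RADII, ElementSpec, element_dictionary
from .scatter import Molecule


class XYZFormatError(ValueError):
    """Malformed XYZ file; message carries the offending line number."""


def read_xyz(
    path: str | Path,
    radii: Mapping[str, float] | None = None,
    amplitudes: Mapping[str, float] | None = None,
) -> Molecule:
    """Read a molecule from an XYZ file.

    Element symbols absent from the bundled covalent-radius table require a
    radius in ``radii``; unknown symbols raise a missing-radius error.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise XYZFormatError(f"{path}: line 1: empty file")
    try:
        count = int(lines[0].strip())
    except ValueError as exc:
        raise XYZFormatError(f"{path}: line 1: atom count expected, got {lines[0]!r}") from exc
    body = [l for l in lines[2 : 2 + count]]
    if len(body) < count:
        raise XYZFormatError(
            f"{path}: line 1: count line says {count} atoms but body has {len(body)}"
        )
    extra = [l for l in lines[2 + count :] if l.strip()]
    if extra:
        raise XYZFormatError(
            f"{path}: line {3 + count}: count line says {count} atoms but body has more"
        )
    symbols, positions = [], []
    for i, line in enumerate(body, start=3):
        parts = line.split()
        if len(parts) < 4:
            raise XYZFormatError(f"{path}: line {i}: expected 'SYMBOL x y z', got {line!r}")
        symbols.append(parts[0])
        try:
            positions.append([float(v) for v in parts[1:4]])
        except ValueError as exc:
            raise XYZFormatError(f"{path}: line {i}: coordinate parse failure in {line!r}") from exc
    counts: dict[str, int] = {}
    for s in symbols:
        counts[s] = counts.get(s, 0) + 1
        if s not in COVALENT_RADII and (radii is None or s not in radii):
            raise XYZFormatError(
                f"{path}: element {s!r} has no covalent radius in the bundled table; "
                "supply 'radius_angstrom' for it in the config"
            )
    elements = element_dictionary(counts, radii=radii, amplitudes=amplitudes)
    return Molecule.from_arrays(elements, symbols, positions)


def write_xyz(molecule: Molecule, path: str | Path, comment: str = "") -> None:
    lines = [str(len(molecule)), comment.replace("\n", " ")]
    for a in molecule.atoms:
        x, y, z = a.position
        lines.append(f"{a.element.symbol} {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
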