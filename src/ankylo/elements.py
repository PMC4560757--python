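"""Element dictionary: covalent-sphere basis functions and stoichiometry.

Each chemical element is modelled as a uniform ball of its covalent radius;
the per-element stoichiometric atom count is the hard sparsity cap used by
the solver.  Radii are standard published covalent radii; default amplitudes
are proportional to the number of core electrons that scatter X-rays.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

#: Standard covalent radii in angstrom.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "P": 1.07,
    "S": 1.05,
}

#: Default ground-truth amplitudes (effective core-electron charge density),
#: overridable per element in configuration.
DEFAULT_AMPLITUDES: dict[str, float] = {
    "H": 1.0,
    "C": 2.0,
    "N": 2.0,
    "O": 2.0,
    "P": 2.0,
    "S": 2.0,
}

#: Stoichiometry of the bundled 17-atom threonine-like fixture.
THREONINE_STOICHIOMETRY: dict[str, int] = {"C": 4, "N": 1, "O": 3, "H": 9}


@dataclass(frozen=True)
class ElementSpec:
    """One element of the sphere dictionary.

    Parameters
    ----------
    symbol:
        Chemical symbol, unique within a dictionary.
    radius:
        Covalent sphere radius in angstrom, strictly positive.
    count:
        Stoichiometric number of atoms of this element (sparsity cap S_j).
    amplitude:
        Default ground-truth amplitude for atoms of this element.
    """

    symbol: str
    radius: float
    count: int
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"element {self.symbol!r}: radius must be > 0, got {self.radius}")
        if self.count < 0:
            raise ValueError(f"element {self.symbol!r}: count must be >= 0, got {self.count}")

    def with_count(self, count: int) -> "ElementSpec":
        return replace(self, count=count)


def element_dictionary(
    counts: Mapping[str, int],
    radii: Mapping[str, float] | None = None,
    amplitudes: Mapping[str, float] | None = None,
    drop_empty: bool = True,
) -> list[ElementSpec]:
    """Build an element dictionary from a symbol -> atom-count mapping.

    Radii/amplitudes default to the bundled tables; unknown symbols must be
    supplied explicitly.
    """
    out: list[ElementSpec] = []
    for symbol, count in counts.items():
        r = (radii or {}).get(symbol, COVALENT_RADII.get(symbol))
        if r is None:
            raise KeyError(
                f"no covalent radius known for element {symbol!r}; supply one in config"
            )
        a = (amplitudes or {}).get(symbol, DEFAULT_AMPLITUDES.get(symbol, 1.0))
        if count == 0 and drop_empty:
            continue
        out.append(ElementSpec(symbol=symbol, radius=float(r), count=int(count), amplitude=float(a)))
    symbols = [e.symbol for e in out]
    if len(set(symbols)) != len(symbols):
        raise ValueError(f"duplicate element symbols in dictionary: {symbols}")
    return out


def mixed_stoichiometry(total_atoms: int) -> dict[str, int]:
    """Deterministic H/C/N/O composition for a given total atom count.

    Allocates atoms proportionally to the threonine-like ratios (9 H : 4 C :
    3 O : 1 N) by largest remainder, so random benchmark molecules have an
    organic-looking mix at every size.
    """
    if total_atoms < 1:
        raise ValueError("total_atoms must be >= 1")
    ref = THREONINE_STOICHIOMETRY
    ref_total = sum(ref.values())
    shares = {s: total_atoms * c / ref_total for s, c in ref.items()}
    counts = {s: int(v) for s, v in shares.items()}
    remainder = total_atoms - sum(counts.values())
    for s in sorted(ref, key=lambda s: shares[s] - counts[s], reverse=True)[:remainder]:
        counts[s] += 1
    return {s: c for s, c in counts.items() if c > 0}


def total_count(elements: Iterable[ElementSpec]) -> int:
    return sum(e.count for e in elements)


def symbols(elements: Sequence[ElementSpec]) -> list[str]:
    return [e.symbol for e in elements]
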