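"""Molecular geometries and atom-centered basis specifications."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

#: default valence-electron counts for the species used in the toy datasets
DEFAULT_VALENCE = {"H": 1.0, "C": 4.0, "N": 5.0, "O": 6.0, "F": 7.0,
                   "S": 6.0, "Si": 4.0, "X": 1.0}

#: atomic numbers used in cube/XYZ records
ATOMIC_NUMBER = {"H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "Si": 14, "S": 16,
                 "X": 0}
SYMBOL_OF = {v: k for k, v in ATOMIC_NUMBER.items()}


@dataclass
class AtomicSystem:
    """A set of atoms: species labels and positions in Bohr."""

    species: list[str]
    positions: np.ndarray
    valence_charges: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.species = list(self.species)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if len(self.species) != self.positions.shape[0]:
            raise ValueError("species and positions length mismatch")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite atomic positions")
        merged = dict(DEFAULT_VALENCE)
        merged.update(self.valence_charges)
        self.valence_charges = merged

    @property
    def natoms(self) -> int:
        return len(self.species)

    def valence(self, symbol: str) -> float:
        try:
            return float(self.valence_charges[symbol])
        except KeyError:
            raise KeyError(f"no valence charge configured for species "
                           f"{symbol!r}") from None

    @property
    def total_valence(self) -> float:
        return sum(self.valence(s) for s in self.species)

    def translated(self, shift) -> "AtomicSystem":
        return AtomicSystem(list(self.species),
                            self.positions + np.asarray(shift, dtype=float),
                            dict(self.valence_charges))

    def rotated(self, R: np.ndarray, about=(0.0, 0.0, 0.0)) -> "AtomicSystem":
        about = np.asarray(about, dtype=float)
        pos = (self.positions - about) @ np.asarray(R, dtype=float).T + about
        return AtomicSystem(list(self.species), pos, dict(self.valence_charges))


@dataclass(frozen=True)
class SpeciesBasis:
    """Radial/angular sizes and cutoff of one species' atom-centered basis."""

    n_max: int
    l_max: int
    r_o: float

    def __post_init__(self) -> None:
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")
        if self.l_max < 0:
            raise ValueError("l_max must be >= 0")
        if self.r_o <= 0:
            raise ValueError("cutoff radius r_o must be positive")

    @property
    def n_funcs(self) -> int:
        return self.n_max * (self.l_max + 1) ** 2


@dataclass
class BasisSpec:
    """Per-species basis parameters: radial count, angular momentum, cutoff."""

    species: dict[str, SpeciesBasis]

    def __post_init__(self) -> None:
        self.species = {
            k: (v if isinstance(v, SpeciesBasis) else SpeciesBasis(**v))
            for k, v in self.species.items()
        }

    def __getitem__(self, symbol: str) -> SpeciesBasis:
        try:
            return self.species[symbol]
        except KeyError:
            raise KeyError(f"no basis configured for species {symbol!r}") \
                from None

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.species

    @property
    def max_cutoff(self) -> float:
        return max(sb.r_o for sb in self.species.values())

    def content_hash(self) -> str:
        """Stable hash identifying the basis; stored with models/descriptors."""
        items = sorted((k, v.n_max, v.l_max, round(v.r_o, 12))
                       for k, v in self.species.items())
        return hashlib.sha256(repr(items).encode()).hexdigest()[:16]

    @classmethod
    def uniform(cls, species, n_max: int, l_max: int, r_o: float) -> "BasisSpec":
        return cls({s: SpeciesBasis(n_max, l_max, r_o) for s in set(species)})
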