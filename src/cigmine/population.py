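"""In-memory container for a diploid 3D genome structure population.

Coordinates live in nuclear-radius units: after reading, the nucleus is the
unit sphere. Node order within a structure is fixed: domains sorted by
(L1, L2), each contributing copy A then copy B, so node index = 2 * domain + copy.
Copy labels A/B are arbitrary per chromosome per structure and carry no
cross-structure meaning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .domains import DomainTable
from .errors import ValidationError

COPIES = ("A", "B")


@dataclass
class StructurePopulation:
    """K diploid structures of N domains each.

    Attributes
    ----------
    coords : ndarray, shape (K, N, 2, 3)
        Sphere-centre positions; axis 2 is the homolog copy (0=A, 1=B).
    structure_ids : list of str
    nucleus_radius : float
        Always 1.0 after normalization.
    """

    coords: np.ndarray
    structure_ids: list[str] = field(default_factory=list)
    nucleus_radius: float = 1.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 4 or self.coords.shape[2:] != (2, 3):
            raise ValidationError(
                f"coords must have shape (K, N, 2, 3); got {self.coords.shape}"
            )
        if not self.structure_ids:
            self.structure_ids = [f"s{i}" for i in range(self.coords.shape[0])]
        if len(self.structure_ids) != self.coords.shape[0]:
            raise ValidationError("structure_ids length does not match K")

    @property
    def K(self) -> int:
        return self.coords.shape[0]

    @property
    def n_domains(self) -> int:
        return self.coords.shape[1]

    def structure(self, k: int) -> np.ndarray:
        """Flat (2N, 3) node positions of structure k (node = 2*domain + copy)."""
        return self.coords[k].reshape(-1, 3)

    def radial_positions(self, k: int) -> np.ndarray:
        """(N, 2) distance of every node from the nuclear centre."""
        return np.linalg.norm(self.coords[k], axis=-1)

    def check_confinement(self, domains: DomainTable, tol: float = 0.05) -> int:
        """Count nodes whose sphere pokes beyond the nucleus by more than tol.

        Emits a warning (and returns the count) rather than failing: modelled
        populations routinely graze the envelope.
        """
        r = np.linalg.norm(self.coords, axis=-1)  # (K, N, 2)
        excess = r + domains.radii[None, :, None] - self.nucleus_radius
        n_bad = int((excess > tol).sum())
        if n_bad:
            warnings.warn(
                f"{n_bad} node(s) exceed the nuclear envelope by more than tol={tol}",
                stacklevel=2,
            )
        return n_bad
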