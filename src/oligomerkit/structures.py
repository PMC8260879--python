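"""Lightweight in-memory containers for structures and trajectories.

Coordinates follow the PDB convention (Å, 1-based residue numbering
preserved from input); atom metadata lives in a pandas DataFrame with
columns ``chain``, ``res_id``, ``res_name``, ``atom_name``, ``element``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError

ATOM_COLUMNS = ["chain", "res_id", "res_name", "atom_name", "element"]


def make_atom_table(chain, res_id, res_name, atom_name, element) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chain": np.asarray(chain, dtype=object),
            "res_id": np.asarray(res_id, dtype=int),
            "res_name": np.asarray(res_name, dtype=object),
            "atom_name": np.asarray(atom_name, dtype=object),
            "element": np.asarray(element, dtype=object),
        }
    )


@dataclass
class Structure:
    """A single conformation: atom table plus (N, 3) coordinates in Å."""

    atoms: pd.DataFrame
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise InvalidInputError(f"coords must be (N, 3), got {self.coords.shape}")
        if len(self.atoms) != self.coords.shape[0]:
            raise InvalidInputError("atom table and coordinates disagree in length")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def ca_mask(self) -> np.ndarray:
        return (self.atoms["atom_name"] == "CA").to_numpy()

    def backbone_mask(self) -> np.ndarray:
        """Backbone heavy atoms; falls back to all atoms if none are named so."""
        m = self.atoms["atom_name"].isin(["N", "CA", "C", "O"]).to_numpy()
        return m if m.any() else np.ones(self.n_atoms, dtype=bool)

    def select(self, mask) -> "Structure":
        mask = np.asarray(mask)
        return Structure(self.atoms[mask].reset_index(drop=True), self.coords[mask])

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return Structure(self.atoms, np.asarray(coords, dtype=float))


@dataclass
class Trajectory:
    """One coordinate series: (frames, N, 3) over a fixed atom table."""

    atoms: pd.DataFrame
    coords: np.ndarray  # (F, N, 3)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise InvalidInputError(f"trajectory coords must be (F, N, 3), got {self.coords.shape}")
        if len(self.atoms) != self.coords.shape[1]:
            raise InvalidInputError("atom table and trajectory coordinates disagree in length")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> Structure:
        return Structure(self.atoms, self.coords[i])


@dataclass
class TrajectoryBundle:
    """Replicate trajectories sharing one atom table, plus a reference.

    ``frame_interval_ps`` is the sampling interval of the stored frames.
    """

    replicates: list[Trajectory]
    reference: Structure
    frame_interval_ps: float = 50.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.replicates:
            raise InvalidInputError("a trajectory bundle needs at least one replicate")
        n = self.replicates[0].coords.shape[1]
        for t in self.replicates:
            if t.coords.shape[1] != n:
                raise InvalidInputError("replicates disagree in atom count")
        if self.reference.n_atoms != n:
            raise InvalidInputError("reference structure does not match the trajectory atom count")

    @property
    def atoms(self) -> pd.DataFrame:
        return self.replicates[0].atoms

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)
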