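"""Domain containers for residue thermodynamics and proteome profiles.

All energies are held internally in kJ/mol.  A residue's thermodynamic
descriptor (TD) is the 4-vector (dG, dH_apolar, dH_polar, TdS_conf) describing
the local folding equilibrium at that position, computed separately for the
native (locally folded) and denatured (locally unfolded) subensembles.  The
coarse-grained alphabet of eight thermodynamic environments (TEs) per state is
ranked TE1 (least stable, least negative mean dG) through TE8 (most stable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvariantError

#: Gas constant in kJ/(mol K).
GAS_CONSTANT = 0.0083145
#: Standard temperature (25 degrees Celsius) in kelvin.
STANDARD_TEMPERATURE = 298.15
#: Conversion factor from kcal/mol to kJ/mol.
KCAL_TO_KJ = 4.184

#: Order of the four thermodynamic descriptor components.
TD_COMPONENTS = ("dG", "dH_apolar", "dH_polar", "TdS_conf")
#: Number of thermodynamic environments per state.
N_ENVIRONMENTS = 8
#: Per-component multipliers of the native-state assignment metric.  The
#: conformational-entropy term carries a factor of 3.
NATIVE_TERM_WEIGHTS = (1.0, 1.0, 1.0, 3.0)
#: Per-component multipliers of the denatured-state assignment metric.
DENATURED_TERM_WEIGHTS = (1.0, 1.0, 1.0, 1.0)

KINGDOMS = frozenset({"bacteria", "archaea", "eukaryote"})


def _as_td(vec, name: str) -> np.ndarray:
    arr = np.asarray(vec, dtype=float)
    if arr.shape != (4,):
        raise InvariantError(f"{name} must be a 4-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvariantError(f"{name} contains non-finite entries: {arr}")
    return arr


@dataclass(frozen=True)
class ResidueTD:
    """Per-residue thermodynamic descriptors for both states."""

    position: int  # 1-based
    amino_acid: str
    native_td: np.ndarray
    denatured_td: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "native_td", _as_td(self.native_td, "native_td"))
        object.__setattr__(self, "denatured_td", _as_td(self.denatured_td, "denatured_td"))
        if self.position < 1:
            raise InvariantError(f"positions are 1-based, got {self.position}")


class TDTable:
    """Ordered per-residue TD records for one protein.

    Positions must be consecutive 1..L and every energy finite; violations
    raise :class:`InvariantError` at construction.
    """

    def __init__(self, protein_id: str, residues):
        self.protein_id = str(protein_id)
        self.residues = list(residues)
        if not self.residues:
            raise InvariantError(f"{protein_id}: TD table must contain at least one residue")
        for i, r in enumerate(self.residues, start=1):
            if r.position != i:
                raise InvariantError(
                    f"{protein_id}: positions must be consecutive 1..L; "
                    f"expected {i}, got {r.position}"
                )

    @classmethod
    def from_arrays(cls, protein_id, sequence, native, denatured) -> "TDTable":
        native = np.asarray(native, dtype=float)
        denatured = np.asarray(denatured, dtype=float)
        if len(sequence) != len(native) or native.shape != denatured.shape:
            raise InvariantError("sequence and TD arrays must have matching lengths")
        residues = [
            ResidueTD(i + 1, aa, native[i], denatured[i])
            for i, aa in enumerate(sequence)
        ]
        return cls(protein_id, residues)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    @property
    def native_matrix(self) -> np.ndarray:
        """(L, 4) array of native-state descriptors."""
        return np.array([r.native_td for r in self.residues])

    @property
    def denatured_matrix(self) -> np.ndarray:
        """(L, 4) array of denatured-state descriptors."""
        return np.array([r.denatured_td for r in self.residues])


@dataclass(frozen=True)
class OrganismMeta:
    """Organism annotation: kingdom plus optional measured traits."""

    organism_id: str
    kingdom: str
    growth_temp: float | None = None  # degrees Celsius
    disorder_fraction: float | None = None  # unitless, in [0, 1]

    def __post_init__(self):
        if self.kingdom not in KINGDOMS:
            raise InvariantError(
                f"{self.organism_id}: kingdom must be one of {sorted(KINGDOMS)}, "
                f"got {self.kingdom!r}"
            )
        if self.disorder_fraction is not None and not (0.0 <= self.disorder_fraction <= 1.0):
            raise InvariantError(
                f"{self.organism_id}: disorder_fraction must lie in [0, 1], "
                f"got {self.disorder_fraction}"
            )


#: Secondary-structure classes in fixed order.
SS_CLASSES = ("helix", "strand", "turn", "coil")

_DSSP_TO_CLASS = {
    "H": "helix", "G": "helix", "I": "helix",
    "E": "strand", "B": "strand",
    "T": "turn", "S": "turn",
}


def dssp_class(code: str) -> str:
    """Map a single DSSP code to its coarse class.

    H, G, I are helix; E, B are strand; T, S are turn; anything else is coil.
    """
    return _DSSP_TO_CLASS.get(code, "coil")


@dataclass(frozen=True)
class SSAnnotation:
    """Per-residue DSSP codes for one protein, with the derived 4-class track."""

    protein_id: str
    codes: str

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(dssp_class(c) for c in self.codes)

    def __len__(self) -> int:
        return len(self.codes)


class TECenterTable:
    """The 16 cluster centers defining the TE alphabet, plus metric weights.

    Native centers must be ordered so the mean dG is monotone non-increasing
    (TE1 least stable/least negative, TE8 most stable/most negative).
    """

    def __init__(
        self,
        native_centers,
        denatured_centers,
        native_term_weights=NATIVE_TERM_WEIGHTS,
        denatured_term_weights=DENATURED_TERM_WEIGHTS,
    ):
        self.native_centers = np.asarray(native_centers, dtype=float)
        self.denatured_centers = np.asarray(denatured_centers, dtype=float)
        self.native_term_weights = np.asarray(native_term_weights, dtype=float)
        self.denatured_term_weights = np.asarray(denatured_term_weights, dtype=float)
        for name, arr in (("native_centers", self.native_centers),
                          ("denatured_centers", self.denatured_centers)):
            if arr.shape != (N_ENVIRONMENTS, 4):
                raise InvariantError(f"{name} must have shape (8, 4), got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise InvariantError(f"{name} contains non-finite entries")
        for name, w in (("native_term_weights", self.native_term_weights),
                        ("denatured_term_weights", self.denatured_term_weights)):
            if w.shape != (4,):
                raise InvariantError(f"{name} must be a 4-vector")
            if np.any(w < 0) or not np.any(w > 0):
                raise InvariantError(f"{name} must be nonnegative with at least one positive entry")
        dg = self.native_centers[:, 0]
        if np.any(np.diff(dg) > 1e-9):
            raise InvariantError(
                "native center dG means must be monotone non-increasing "
                "(TE1 least stable to TE8 most stable)"
            )


class TESequence:
    """Per-residue native and denatured TE labels for one protein."""

    def __init__(self, protein_id: str, native_labels, denatured_labels):
        self.protein_id = str(protein_id)
        self.native_labels = np.asarray(native_labels, dtype=int)
        self.denatured_labels = np.asarray(denatured_labels, dtype=int)
        if self.native_labels.ndim != 1 or self.native_labels.size < 1:
            raise InvariantError(f"{protein_id}: label lists must be 1-D with L >= 1")
        if self.native_labels.shape != self.denatured_labels.shape:
            raise InvariantError(
                f"{protein_id}: native and denatured label lists must have equal length"
            )
        for name, lab in (("native", self.native_labels), ("denatured", self.denatured_labels)):
            if lab.min() < 1 or lab.max() > N_ENVIRONMENTS:
                raise InvariantError(
                    f"{protein_id}: {name} labels must lie in 1..{N_ENVIRONMENTS}"
                )

    def __len__(self) -> int:
        return self.native_labels.size


class ProteomeProfile:
    """Normalised TE frequency vector for one organism's proteome."""

    def __init__(self, organism_id, native_freq, meta: OrganismMeta,
                 denatured_freq=None, n_proteins: int = 0, n_residues: int = 0):
        self.organism_id = str(organism_id)
        self.native_freq = self._check_freq(np.asarray(native_freq, dtype=float), "native_freq")
        self.denatured_freq = (
            None if denatured_freq is None
            else self._check_freq(np.asarray(denatured_freq, dtype=float), "denatured_freq")
        )
        self.n_proteins = int(n_proteins)
        self.n_residues = int(n_residues)
        self.meta = meta

    def _check_freq(self, f: np.ndarray, name: str) -> np.ndarray:
        if f.shape != (N_ENVIRONMENTS,):
            raise InvariantError(f"{self.organism_id}: {name} must be an 8-vector")
        if np.any(f < 0):
            raise InvariantError(f"{self.organism_id}: {name} entries must be nonnegative")
        if abs(f.sum() - 1.0) > 1e-9:
            raise InvariantError(
                f"{self.organism_id}: {name} must sum to 1 within 1e-9, got {f.sum()!r}"
            )
        return f


class StabilityRecord:
    """TE count features of one protein, with optional experimental stability."""

    def __init__(self, protein_id, native_counts, denatured_counts, length,
                 dG_exp: float | None = None, class_label: str | None = None):
        self.protein_id = str(protein_id)
        self.native_counts = np.asarray(native_counts, dtype=int)
        self.denatured_counts = np.asarray(denatured_counts, dtype=int)
        self.length = int(length)
        self.dG_exp = None if dG_exp is None else float(dG_exp)
        self.class_label = class_label
        if self.native_counts.shape != (N_ENVIRONMENTS,) or \
                self.denatured_counts.shape != (N_ENVIRONMENTS,):
            raise InvariantError(f"{protein_id}: count vectors must be 8-vectors")
        if np.any(self.native_counts < 0) or np.any(self.denatured_counts < 0):
            raise InvariantError(f"{protein_id}: counts must be nonnegative")
        if self.length < 1:
            raise InvariantError(f"{protein_id}: length must be >= 1")
        if self.native_counts.sum() != self.length or self.denatured_counts.sum() != self.length:
            raise InvariantError(
                f"{protein_id}: native and denatured counts must each sum to L={self.length}"
            )
        if class_label is not None and class_label not in ("structured", "disordered"):
            raise InvariantError(
                f"{protein_id}: class_label must be 'structured' or 'disordered'"
            )


@dataclass(frozen=True)
class StabilityParams:
    """Parameters of the additive TE stability expression.

    Predicted global stability (kJ/mol, more negative = more stable) is
    ``sum_i w_native[i] * NTE_i + sum_j w_denatured[j] * DTE_j - L*R*T*ln(Z)``
    where Z is the effective number of unfolded-state conformations per
    residue.
    """

    w_native: np.ndarray
    w_denatured: np.ndarray
    z: float
    temperature: float = STANDARD_TEMPERATURE
    gas_constant: float = GAS_CONSTANT

    def __post_init__(self):
        object.__setattr__(self, "w_native", np.asarray(self.w_native, dtype=float))
        object.__setattr__(self, "w_denatured", np.asarray(self.w_denatured, dtype=float))
        if self.w_native.shape != (N_ENVIRONMENTS,) or self.w_denatured.shape != (N_ENVIRONMENTS,):
            raise InvariantError("weight vectors must have length 8")
        if not self.z > 0:
            raise InvariantError(f"Z must be positive, got {self.z}")
        if not self.temperature > 0:
            raise InvariantError(f"temperature must be positive, got {self.temperature}")

    @property
    def ln_z(self) -> float:
        return float(np.log(self.z))

    @property
    def rt(self) -> float:
        """R*T in kJ/mol."""
        return self.gas_constant * self.temperature

    def to_dict(self) -> dict:
        return {
            "w_native": self.w_native.tolist(),
            "w_denatured": self.w_denatured.tolist(),
            "z": self.z,
            "temperature": self.temperature,
            "gas_constant": self.gas_constant,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StabilityParams":
        return cls(
            w_native=np.asarray(d["w_native"], dtype=float),
            w_denatured=np.asarray(d["w_denatured"], dtype=float),
            z=float(d["z"]),
            temperature=float(d.get("temperature", STANDARD_TEMPERATURE)),
            gas_constant=float(d.get("gas_constant", GAS_CONSTANT)),
        )
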