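"""Structure data model, PDB I/O, residue correspondence and rigid superposition.

All geometry in this package is CA-only: every similarity score used downstream
(GDT-TS, TM-score) is defined on alpha-carbon positions, and model pools for a
single target share one residue numbering, so residue number — not sequence
alignment — is the correspondence key.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Generator",
    "StructureModel",
    "ModelPool",
    "Superposition",
    "read_pdb",
    "write_pdb",
    "correspondence",
    "kabsch",
]


class Generator(str, Enum):
    """Which structure predictor produced a model."""

    AF2 = "AF2"
    AF3 = "AF3"
    ESMFold = "ESMFold"
    other = "other"


@dataclass
class StructureModel:
    """One predicted single-chain model: ordered CA trace plus metadata.

    ``plddt`` is the per-residue predicted-lDDT confidence on the 0-100 scale
    that AlphaFold-family predictors emit; it is optional because not every
    model file carries it.
    """

    model_id: str
    target_id: str
    sequence: str
    residue_numbers: np.ndarray
    ca_coords: np.ndarray
    plddt: np.ndarray | None = None
    generator: Generator = Generator.other

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        self.generator = Generator(self.generator)
        n = len(self.sequence)
        if self.residue_numbers.shape != (n,):
            raise ValueError(
                f"{self.model_id}: sequence length {n} != "
                f"{len(self.residue_numbers)} residue numbers"
            )
        if self.ca_coords.shape != (n, 3):
            raise ValueError(f"{self.model_id}: ca_coords must be ({n}, 3)")
        if n > 1 and not np.all(np.diff(self.residue_numbers) > 0):
            raise ValueError(f"{self.model_id}: residue numbers not strictly increasing")
        if self.plddt is not None:
            self.plddt = np.asarray(self.plddt, dtype=float)
            if self.plddt.shape != (n,):
                raise ValueError(f"{self.model_id}: plddt must have one value per residue")
            if np.any(self.plddt < 0) or np.any(self.plddt > 100):
                raise ValueError(f"{self.model_id}: plddt values must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.sequence)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a copy with coordinates mapped through x -> R x + t."""
        coords = self.ca_coords @ np.asarray(rotation).T + np.asarray(translation)
        return StructureModel(
            model_id=self.model_id,
            target_id=self.target_id,
            sequence=self.sequence,
            residue_numbers=self.residue_numbers.copy(),
            ca_coords=coords,
            plddt=None if self.plddt is None else self.plddt.copy(),
            generator=self.generator,
        )


@dataclass
class ModelPool:
    """All candidate models for one target, sharing the target's numbering."""

    target_id: str
    models: list[StructureModel] = field(default_factory=list)
    reference_length: int = 0

    def __post_init__(self) -> None:
        ids = [m.model_id for m in self.models]
        if len(set(ids)) != len(ids):
            raise ValueError("model_ids in a pool must be unique")
        seqs: dict[int, str] = {}
        for m in self.models:
            if m.target_id != self.target_id:
                raise ValueError(
                    f"model {m.model_id} has target {m.target_id!r}, pool is {self.target_id!r}"
                )
            for num, aa in zip(m.residue_numbers, m.sequence):
                prev = seqs.setdefault(int(num), aa)
                if prev != aa:
                    raise ValueError(
                        f"model {m.model_id}: residue {num} is {aa}, pool has {prev}"
                    )
        if self.reference_length <= 0 and self.models:
            self.reference_length = max(int(m.residue_numbers[-1]) for m in self.models)

    def __len__(self) -> int:
        return len(self.models)

    def __getitem__(self, model_id: str) -> StructureModel:
        for m in self.models:
            if m.model_id == model_id:
                return m
        raise KeyError(model_id)

    @property
    def model_ids(self) -> list[str]:
        return [m.model_id for m in self.models]


@dataclass
class Superposition:
    """Proper rigid-body transform mapping one point set onto another."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        det = np.linalg.det(self.rotation)
        if abs(det - 1.0) > 1e-9:
            raise ValueError(f"rotation determinant {det} is not +1 (reflection?)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


_THREE_TO_ONE_FALLBACK = "X"


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is None:
        return _THREE_TO_ONE_FALLBACK
    code = info.one_letter_code.upper()
    return code if code.isalpha() else _THREE_TO_ONE_FALLBACK


def read_pdb(
    path: str | Path,
    model_id: str,
    generator: Generator | str = Generator.other,
    *,
    chain: str | None = None,
    plddt_from_bfactor: bool = False,
    target_id: str | None = None,
) -> StructureModel:
    """Read a single-chain CA trace from a PDB file.

    Residues are ordered by residue number; for altloc'd CA atoms the first
    occurrence wins. ``plddt_from_bfactor=True`` interprets the B-factor
    column as per-residue plDDT (the AlphaFold convention) — never done
    silently. Insertion codes are rejected.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no CA coordinates (no models)")
    model = st[0]
    chains = [ch.name for ch in model]
    if chain is None:
        if len(chains) > 1:
            raise ValueError(
                f"{path}: multiple chains {chains}; pass an explicit chain selector"
            )
        selected = model[0] if chains else None
    else:
        if chain not in chains:
            raise ValueError(f"{path}: chain {chain!r} not found among {chains}")
        selected = model[chain]

    nums: list[int] = []
    seq: list[str] = []
    coords: list[tuple[float, float, float]] = []
    bfac: list[float] = []
    if selected is not None:
        for res in selected:
            if res.het_flag == "W":
                continue
            if res.seqid.icode not in (" ", "", "\x00"):
                raise ValueError(
                    f"{path}: insertion code {res.seqid.icode!r} at residue "
                    f"{res.seqid.num} not supported"
                )
            ca = None
            for atom in res:
                if atom.name == "CA":
                    ca = atom  # first altloc occurrence wins
                    break
            if ca is None:
                warnings.warn(
                    f"{path}: residue {res.seqid.num} ({res.name}) has no CA atom; skipped"
                )
                continue
            nums.append(res.seqid.num)
            seq.append(_one_letter(res.name))
            coords.append((ca.pos.x, ca.pos.y, ca.pos.z))
            bfac.append(ca.b_iso)
    if not coords:
        raise ValueError(f"{path}: no CA coordinates")

    order = np.argsort(nums, kind="stable")
    nums_a = np.asarray(nums)[order]
    coords_a = np.asarray(coords)[order]
    seq_s = "".join(seq[i] for i in order)
    plddt = np.asarray(bfac)[order] if plddt_from_bfactor else None
    return StructureModel(
        model_id=model_id,
        target_id=target_id if target_id is not None else st.name or path.stem,
        sequence=seq_s,
        residue_numbers=nums_a,
        ca_coords=coords_a,
        plddt=plddt,
        generator=Generator(generator),
    )


_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}


def write_pdb(model: StructureModel, path: str | Path, *, plddt_to_bfactor: bool = True) -> None:
    """Write the CA trace as fixed-format ATOM records on a single chain A."""
    lines = []
    for i, (num, aa, xyz) in enumerate(
        zip(model.residue_numbers, model.sequence, model.ca_coords), start=1
    ):
        b = 0.0
        if plddt_to_bfactor and model.plddt is not None:
            b = float(model.plddt[i - 1])
        res3 = _ONE_TO_THREE.get(aa, "UNK")
        lines.append(
            f"ATOM  {i:5d}  CA  {res3} A{int(num):4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{b:6.2f}"
            f"           C  "
        )
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def correspondence(a: StructureModel, b: StructureModel) -> tuple[np.ndarray, np.ndarray]:
    """Match residues of two models of the same target by residue number.

    Returns (idx_a, idx_b) positional index arrays. Residues present in only
    one model are dropped; a shared residue number with differing amino acids
    is a hard error (models of one target must agree on sequence).
    """
    if a.target_id != b.target_id:
        raise ValueError(f"target mismatch: {a.target_id!r} vs {b.target_id!r}")
    common, ia, ib = np.intersect1d(a.residue_numbers, b.residue_numbers, return_indices=True)
    if common.size == 0:
        raise ValueError(f"no shared residue numbers between {a.model_id} and {b.model_id}")
    seq_a = np.frombuffer(a.sequence.encode(), dtype="S1")[ia]
    seq_b = np.frombuffer(b.sequence.encode(), dtype="S1")[ib]
    bad = np.nonzero(seq_a != seq_b)[0]
    if bad.size:
        num = int(common[bad[0]])
        raise ValueError(
            f"sequence mismatch at residue {num}: {a.model_id} has "
            f"{a.sequence[ia[bad[0]]]}, {b.model_id} has {b.sequence[ib[bad[0]]]}"
        )
    return ia, ib


def _superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares proper rotation R and translation t with R b + t ~= a.

    Tolerant of rank-deficient (collinear/planar) point sets: the SVD solution
    still minimizes RMSD, only uniqueness is lost, which is irrelevant when the
    superposition is used solely to measure distances.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    ca = a.mean(axis=0)
    cb = b.mean(axis=0)
    h = (b - cb).T @ (a - ca)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d == 0:
        d = 1.0
    corr = np.array([1.0, 1.0, d])
    rot = (vt.T * corr) @ u.T
    t = ca - rot @ cb
    diff = b @ rot.T + t - a
    rmsd = float(np.sqrt((diff**2).sum() / len(a)))
    return rot, t, rmsd


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray) -> Superposition:
    """Optimal rigid superposition of point set b onto point set a.

    Requires >= 3 non-collinear points; reflections are suppressed by sign
    correction of the smallest singular vector, so the rotation is always
    proper.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3) with equal n")
    if len(a) < 3:
        raise ValueError("kabsch requires at least 3 points")
    for name, pts in (("a", a), ("b", b)):
        centered = pts - pts.mean(axis=0)
        sv = np.linalg.svd(centered, compute_uv=False)
        if sv[1] <= 1e-8 * max(sv[0], 1e-300):
            raise ValueError(f"point set {name} is collinear/degenerate")
    rot, t, rmsd = _superpose(a, b)
    return Superposition(rotation=rot, translation=t, rmsd=rmsd)
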