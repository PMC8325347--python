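"""Quantitative structure metrics: superposition RMSD, SASA, buried surface, distances.

These are the measurements used to characterise a homodimeric coiled-coil
anti-sigma factor and its sigma/c-di-GMP complex: the Kabsch least-squares
Calpha superposition between dimers, Shrake-Rupley solvent-accessible surface
areas with a 1.4 A probe, buried surface on complex formation
(SASA(A) + SASA(B) - SASA(AB), the two-sided total), and hydrogen-bond
donor/acceptor distances.

Coordinate files (PDB or mmCIF) are read with gemmi; only the first model is
used and alternate locations collapse to the highest-occupancy conformer.
The SASA quadrature is a deterministic Fibonacci spiral on each atom sphere,
so all areas are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegeneracyError, InputError, SelectionError

#: van der Waals radii (A) of the elements that matter for protein SASA
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960


@dataclass(frozen=True)
class Atom:
    chain: str
    res_num: int
    res_name: str
    name: str
    element: str
    x: float
    y: float
    z: float
    het: bool = False


class StructureModel:
    """Chains/residues/atoms with A coordinates, backed by flat numpy arrays."""

    def __init__(self, atoms: Sequence[Atom]):
        if not atoms:
            raise InputError("structure contains no atoms")
        self.atoms = list(atoms)
        self.coords = np.array([[a.x, a.y, a.z] for a in atoms], dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise InputError("non-finite coordinates in structure")

    @classmethod
    def from_file(cls, path: str | Path) -> "StructureModel":
        """Read PDB or mmCIF; first model, highest-occupancy altloc."""
        import gemmi

        st = gemmi.read_structure(str(path))
        st.setup_entities()
        model = st[0]
        atoms: list[Atom] = []
        for chain in model:
            for residue in chain:
                best: dict[str, tuple[float, Atom]] = {}
                for atom in residue:
                    rec = Atom(
                        chain=chain.name,
                        res_num=residue.seqid.num,
                        res_name=residue.name,
                        name=atom.name,
                        element=atom.element.name.upper(),
                        x=atom.pos.x,
                        y=atom.pos.y,
                        z=atom.pos.z,
                        het=residue.het_flag == "H",
                    )
                    prev = best.get(atom.name)
                    if prev is None or atom.occ > prev[0]:
                        best[atom.name] = (atom.occ, rec)
                atoms.extend(rec for _occ, rec in best.values())
        return cls(atoms)

    def radii(self, overrides: dict[str, float] | None = None) -> np.ndarray:
        table = dict(VDW_RADII)
        if overrides:
            table.update({k.upper(): v for k, v in overrides.items()})
        out = np.empty(len(self.atoms))
        for i, a in enumerate(self.atoms):
            r = table.get(a.element)
            if r is None:
                raise InputError(
                    f"no van der Waals radius for element {a.element!r} "
                    f"(atom {a.chain}/{a.res_num}/{a.name}); pass radius_overrides"
                )
            out[i] = r
        return out


@dataclass(frozen=True)
class AtomSelection:
    """Declarative atom filter: chains, residue ranges, atom names, het policy."""

    chains: tuple[str, ...] | None = None
    residue_ranges: tuple[tuple[int, int], ...] | None = None
    atom_names: tuple[str, ...] | None = None
    include_het: bool = False

    def indices(self, model: StructureModel) -> np.ndarray:
        mask = np.ones(len(model.atoms), dtype=bool)
        for i, a in enumerate(model.atoms):
            if self.chains is not None and a.chain not in self.chains:
                mask[i] = False
            elif self.residue_ranges is not None and not any(
                lo <= a.res_num <= hi for lo, hi in self.residue_ranges
            ):
                mask[i] = False
            elif self.atom_names is not None and a.name not in self.atom_names:
                mask[i] = False
            elif a.het and not self.include_het:
                mask[i] = False
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            raise SelectionError(f"selection {self} matches no atoms")
        return idx


#: convenience selection for Calpha-only superpositions
CALPHA = AtomSelection(atom_names=("CA",))


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # (3,3), proper
    translation: np.ndarray  # (3,)
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass(frozen=True)
class SurfaceResult:
    per_atom: np.ndarray  # A^2, one entry per selected atom
    probe: float
    n_points: int
    atom_indices: np.ndarray = field(default=None)  # indices into the model

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


def kabsch_rmsd(reference: np.ndarray, mobile: np.ndarray) -> SuperpositionResult:
    """Optimal rigid (proper-rotation) superposition of paired coordinate sets.

    Classic SVD solution: centre both sets, take the SVD of the covariance,
    and flip the smallest singular direction if needed to keep det(R) = +1.
    Raises on fewer than three points or (near-)collinear sets, where the
    rotation is not determined.
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise InputError(f"paired (n,3) sets required, got {ref.shape} vs {mob.shape}")
    n = ref.shape[0]
    if n < 3:
        raise DegeneracyError(f"need >= 3 atom pairs, got {n}")
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)
    cov = mob_c.T @ ref_c
    scale = max(np.linalg.norm(ref_c), np.linalg.norm(mob_c))
    u, s, vt = np.linalg.svd(cov)
    if np.linalg.matrix_rank(ref_c, tol=1e-8 * max(scale, 1.0)) < 2:
        raise DegeneracyError("reference points are collinear; rotation undetermined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rotation = vt.T @ flip @ u.T
    translation = ref.mean(axis=0) - rotation @ mob.mean(axis=0)
    moved = mob @ rotation.T + translation
    rmsd = float(np.sqrt(((moved - ref) ** 2).sum() / n))
    return SuperpositionResult(
        rotation=rotation, translation=translation, rmsd=rmsd, n_atoms=n
    )


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden-angle spiral)."""
    i = np.arange(n_points)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n_points
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(
    model: StructureModel,
    selection: AtomSelection | None = None,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    radius_overrides: dict[str, float] | None = None,
) -> SurfaceResult:
    """Solvent-accessible surface of the selected atom set, computed in isolation.

    Each atom's sphere (vdW radius + probe) is sampled at ``n_points``
    deterministic spiral points; a point is accessible when it lies outside
    every neighbouring atom's expanded sphere.  Only selected atoms occlude,
    which is exactly the convention the buried-surface difference needs.
    """
    if n_points < 100:
        raise InputError(f"n_points must be >= 100, got {n_points}")
    idx = (
        selection.indices(model)
        if selection is not None
        else np.arange(len(model.atoms))
    )
    coords = model.coords[idx]
    radii = model.radii(radius_overrides)[idx] + probe
    n = len(idx)
    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    per_atom = np.empty(n)
    for i in range(n):
        pts = coords[i] + radii[i] * sphere
        neighbors = [
            j for j in tree.query_ball_point(coords[i], radii[i] + max_r) if j != i
        ]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 > radii[j] ** 2
        per_atom[i] = 4.0 * np.pi * radii[i] ** 2 * accessible.mean()
    return SurfaceResult(
        per_atom=per_atom, probe=probe, n_points=n_points, atom_indices=idx
    )


def buried_surface_area(
    model: StructureModel,
    group_a: AtomSelection,
    group_b: AtomSelection,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    radius_overrides: dict[str, float] | None = None,
) -> float:
    """Total surface buried between two disjoint atom groups (A^2).

    BSA = SASA(A alone) + SASA(B alone) - SASA(A union B): the two-sided sum
    over both partners, not the halved interface area.
    """
    idx_a = group_a.indices(model)
    idx_b = group_b.indices(model)
    if np.intersect1d(idx_a, idx_b).size:
        raise InputError("groups A and B overlap")
    union = np.union1d(idx_a, idx_b)

    def sasa_of(indices: np.ndarray) -> float:
        sub = StructureModel([model.atoms[i] for i in indices])
        return shrake_rupley_sasa(
            sub, probe=probe, n_points=n_points, radius_overrides=radius_overrides
        ).total

    return sasa_of(idx_a) + sasa_of(idx_b) - sasa_of(union)


def atom_pair_distance(
    model: StructureModel, sel1: AtomSelection, sel2: AtomSelection
) -> float:
    """Euclidean distance (A) between two single-atom selections."""

    def single(sel: AtomSelection) -> int:
        idx = sel.indices(model)
        if idx.size != 1:
            cands = [
                f"{model.atoms[i].chain}/{model.atoms[i].res_name}"
                f"{model.atoms[i].res_num}/{model.atoms[i].name}"
                for i in idx
            ]
            raise SelectionError(
                f"selection resolves to {idx.size} atoms, need exactly 1: {cands}"
            )
        return int(idx[0])

    i, j = single(sel1), single(sel2)
    return float(np.linalg.norm(model.coords[i] - model.coords[j]))


def model_from_coords(
    coords: np.ndarray,
    element: str = "C",
    chain: str = "A",
    res_name: str = "ALA",
    atom_name: str = "CA",
    start_res: int = 1,
) -> StructureModel:
    """Wrap a bare (n,3) coordinate array as a single-chain model of one atom type."""
    coords = np.asarray(coords, dtype=float)
    return StructureModel(
        [
            Atom(
                chain=chain,
                res_num=start_res + i,
                res_name=res_name,
                name=atom_name,
                element=element,
                x=float(x),
                y=float(y),
                z=float(z),
            )
            for i, (x, y, z) in enumerate(coords)
        ]
    )


def combine_models(models: Iterable[StructureModel]) -> StructureModel:
    atoms: list[Atom] = []
    for m in models:
        atoms.extend(m.atoms)
    return StructureModel(atoms)
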