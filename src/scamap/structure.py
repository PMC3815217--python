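"""Geometric analysis of protein structures.

Covers the structure side of the sector-mapping workflow: solvent
accessibility and burial, domain-interface area by SASA differencing,
internal-cavity detection on a grid with solvent flood fill, least-squares
superposition and per-residue RMSD between conformers, B-factor and
Ramachandran profiling per domain, and the final sector-on-structure report.

Structures are thin wrappers around a biotite ``AtomArray``; PDB reading and
writing and the Shrake-Rupley SASA sampling are delegated to biotite, while
the cavity grid method, Kabsch superposition and the domain bookkeeping are
implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile
from scipy import ndimage
from scipy.spatial import cKDTree

from .constants import (
    ALPHA_REGION,
    BETA_REGION,
    DEFAULT_BURIAL_THRESHOLD,
    DEFAULT_PROBE_RADIUS,
    DEFAULT_VDW_RADIUS,
    MAX_SASA,
    VDW_RADII,
)

__all__ = [
    "StructureModel",
    "DomainPartition",
    "SASAResult",
    "Cavity",
    "CavitySet",
    "Superposition",
    "RMSDProfile",
    "read_structure",
    "write_structure",
    "vdw_radii_for",
    "compute_sasa",
    "burial_fraction",
    "interface_area",
    "detect_cavities",
    "site_depth",
    "superpose",
    "per_residue_rmsd",
    "bfactor_summary",
    "rama_fractions",
    "annotate_sectors",
    "write_bfactor_annotated",
]

ResidueKey = tuple[str, int, str]  # (chain, author residue number, insertion code)


@dataclass
class StructureModel:
    """A single structural model: atoms with coordinates, identity and
    B-factors.  ``atoms`` is a biotite AtomArray carrying ``b_factor`` and
    ``occupancy`` annotations."""

    atoms: bst.AtomArray
    model_id: int = 1
    name: str = ""

    @property
    def n_atoms(self) -> int:
        return self.atoms.array_length()

    def heavy(self) -> bst.AtomArray:
        """Atoms excluding hydrogen/deuterium (geometry operations default)."""
        el = np.char.upper(self.atoms.element.astype("U4"))
        return self.atoms[(el != "H") & (el != "D")]

    def residue_keys(self, heavy_only: bool = True) -> list[ResidueKey]:
        arr = self.heavy() if heavy_only else self.atoms
        seen: dict[ResidueKey, None] = {}
        ins = arr.ins_code if "ins_code" in arr.get_annotation_categories() else [""] * len(arr)
        for ch, rid, ic in zip(arr.chain_id, arr.res_id, ins):
            seen.setdefault((str(ch), int(rid), str(ic)), None)
        return list(seen)

    def residue_mask(self, residues: Iterable[ResidueKey | tuple[str, int]]) -> np.ndarray:
        """Boolean atom mask for a set of residues (insertion code optional)."""
        want2 = set()
        want3 = set()
        for r in residues:
            if len(r) == 2:
                want2.add((str(r[0]), int(r[1])))
            else:
                want3.add((str(r[0]), int(r[1]), str(r[2])))
        arr = self.atoms
        ins = arr.ins_code if "ins_code" in arr.get_annotation_categories() else [""] * len(arr)
        mask = np.zeros(len(arr), dtype=bool)
        for i, (ch, rid, ic) in enumerate(zip(arr.chain_id, arr.res_id, ins)):
            if (str(ch), int(rid)) in want2 or (str(ch), int(rid), str(ic)) in want3:
                mask[i] = True
        return mask


@dataclass
class DomainPartition:
    """Named residue-range sets: domain -> list of (chain, start, end)
    inclusive intervals.  Ranges must not overlap within the partition."""

    domains: dict[str, list[tuple[str, int, int]]]

    def __post_init__(self):
        seen: set[tuple[str, int]] = set()
        for name, ranges in self.domains.items():
            for chain, start, end in ranges:
                if end < start:
                    raise ValueError(f"domain {name}: range ({start}, {end}) inverted")
                for r in range(start, end + 1):
                    if (chain, r) in seen:
                        raise ValueError(
                            f"domain {name}: residue {chain}/{r} appears in two ranges"
                        )
                    seen.add((chain, r))

    def domain_of(self, chain: str, res_id: int) -> str | None:
        for name, ranges in self.domains.items():
            for ch, start, end in ranges:
                if ch == chain and start <= res_id <= end:
                    return name
        return None

    def residues(self, name: str) -> list[tuple[str, int]]:
        return [
            (ch, r)
            for ch, start, end in self.domains[name]
            for r in range(start, end + 1)
        ]

    @classmethod
    def from_dict(cls, d: dict) -> "DomainPartition":
        domains = {}
        for name, ranges in d.items():
            domains[name] = [(str(c), int(s), int(e)) for c, s, e in ranges]
        return cls(domains)


# ---------------------------------------------------------------------------
# I/O


def read_structure(
    path: str | Path, model: int = 1, altloc_policy: str = "occupancy"
) -> StructureModel:
    """Read a PDB file into a StructureModel.

    The requested model is extracted (first by default) and alternate
    locations resolved by the given policy (highest occupancy by default,
    ties resolving to the first location, normally 'A').  Hydrogens are kept
    in the model; geometry operations ignore them.
    """
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(
            model=model,
            altloc=altloc_policy,
            extra_fields=["b_factor", "occupancy"],
        )
    except Exception as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    if arr.array_length() == 0:
        raise ValueError(f"no atoms in {path}")
    if not np.all(np.isfinite(arr.coord)):
        raise ValueError(f"non-finite coordinates in {path}")
    return StructureModel(arr, model_id=model, name=path.stem)


def write_structure(structure: StructureModel, path: str | Path) -> None:
    pdb = PDBFile()
    pdb.set_structure(structure.atoms)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# SASA


def vdw_radii_for(atoms: bst.AtomArray) -> np.ndarray:
    """Per-atom van der Waals radii from the shipped element table."""
    radii = np.empty(len(atoms))
    unknown: set[str] = set()
    for i, el in enumerate(atoms.element):
        el = str(el).upper().strip()
        r = VDW_RADII.get(el)
        if r is None:
            unknown.add(el)
            r = DEFAULT_VDW_RADIUS
        radii[i] = r
    if unknown:
        warnings.warn(
            f"unknown element(s) {sorted(unknown)}; using default radius "
            f"{DEFAULT_VDW_RADIUS} A"
        )
    return radii


@dataclass
class SASAResult:
    """Per-atom and per-residue solvent accessibility.

    ``per_residue`` is indexed by (chain, res_id, ins_code) with columns
    ``sasa``, ``rel_sasa`` (fraction of the per-residue maximum-exposure
    reference; NaN for residues without a reference value) and ``buried``.
    """

    atom_sasa: np.ndarray
    per_residue: pd.DataFrame
    probe_radius: float
    n_points: int
    burial_threshold: float

    def buried_residues(self) -> list[ResidueKey]:
        return [tuple(k) for k in self.per_residue.index[self.per_residue["buried"]]]


def compute_sasa(
    structure: StructureModel,
    probe: float = DEFAULT_PROBE_RADIUS,
    n_points: int = 960,
    burial_threshold: float = DEFAULT_BURIAL_THRESHOLD,
) -> SASAResult:
    """Shrake-Rupley solvent accessible surface area.

    Sphere sampling is delegated to biotite with the shipped element radii;
    hydrogens are excluded.  Relative SASA divides each residue's total by
    the maximum-exposure reference of its residue type; a residue is buried
    when relative SASA falls below ``burial_threshold``.
    """
    heavy = structure.heavy()
    if len(heavy) == 0:
        raise ValueError("structure has no heavy atoms")
    radii = vdw_radii_for(heavy)
    atom_sasa = bst.sasa(
        heavy,
        probe_radius=probe,
        vdw_radii=radii,
        point_number=n_points,
    )
    ins = (
        heavy.ins_code
        if "ins_code" in heavy.get_annotation_categories()
        else np.array([""] * len(heavy))
    )
    df = pd.DataFrame(
        {
            "chain": heavy.chain_id.astype(str),
            "res_id": heavy.res_id.astype(int),
            "ins_code": np.asarray(ins).astype(str),
            "res_name": heavy.res_name.astype(str),
            "sasa": atom_sasa,
        }
    )
    grouped = (
        df.groupby(["chain", "res_id", "ins_code"], sort=False)
        .agg(sasa=("sasa", "sum"), res_name=("res_name", "first"))
    )
    max_ref = grouped["res_name"].map(MAX_SASA)
    grouped["rel_sasa"] = grouped["sasa"] / max_ref
    grouped["buried"] = grouped["rel_sasa"] < burial_threshold
    grouped.loc[max_ref.isna(), "buried"] = False
    if max_ref.isna().any():
        missing = sorted(grouped.loc[max_ref.isna(), "res_name"].unique())
        warnings.warn(f"no maximum-SASA reference for residue type(s) {missing}")
    return SASAResult(atom_sasa, grouped, probe, n_points, burial_threshold)


def burial_fraction(
    residue_set: Iterable[ResidueKey | tuple[str, int]],
    sasa_result: SASAResult,
) -> float:
    """Fraction of the given residues flagged buried; NaN for an empty set."""
    keys = list(residue_set)
    if not keys:
        warnings.warn("burial fraction undefined for an empty residue set")
        return float("nan")
    table = sasa_result.per_residue
    short = {(c, r): b for (c, r, _ic), b in table["buried"].items()}
    buried = 0
    for k in keys:
        if len(k) == 2:
            flag = short.get((str(k[0]), int(k[1])))
        else:
            flag = (
                table["buried"].get((str(k[0]), int(k[1]), str(k[2])))
                if (str(k[0]), int(k[1]), str(k[2])) in table.index
                else None
            )
        if flag is None:
            raise KeyError(f"residue {k} not in SASA result")
        buried += bool(flag)
    return buried / len(keys)


def interface_area(
    structure: StructureModel,
    set_a: Iterable[tuple[str, int]],
    set_b: Iterable[tuple[str, int]],
    probe: float = DEFAULT_PROBE_RADIUS,
    n_points: int = 960,
) -> dict[str, float]:
    """Buried surface area between two disjoint residue sets.

    Returns ``{"total_buried": SASA(A) + SASA(B) - SASA(A+B), "one_sided":
    total/2}`` in A^2.  ``total_buried`` counts both faces of the interface.
    """
    set_a, set_b = list(set_a), list(set_b)
    mask_a = structure.residue_mask(set_a)
    mask_b = structure.residue_mask(set_b)
    if np.any(mask_a & mask_b):
        raise ValueError("residue sets overlap")

    def total_sasa(mask: np.ndarray) -> float:
        sub = StructureModel(structure.atoms[mask], structure.model_id)
        return float(np.nansum(compute_sasa(sub, probe, n_points).atom_sasa))

    sasa_a = total_sasa(mask_a)
    sasa_b = total_sasa(mask_b)
    sasa_ab = total_sasa(mask_a | mask_b)
    total = sasa_a + sasa_b - sasa_ab
    return {"total_buried": total, "one_sided": total / 2.0}


# ---------------------------------------------------------------------------
# Cavities


@dataclass
class Cavity:
    """An internal void: grid points not reachable by bulk solvent."""

    voxels: np.ndarray  # (m, 3) Cartesian coordinates of member grid points
    volume: float  # A^3 (= m * spacing^3)
    centroid: np.ndarray  # (3,)
    depth: float  # A, centroid to nearest bulk-solvent voxel
    lining_residues: list[ResidueKey]


@dataclass
class CavitySet:
    cavities: list[Cavity]
    grid_spacing: float
    probe_radius: float
    lining_cutoff: float

    def __len__(self):
        return len(self.cavities)

    def __iter__(self):
        return iter(self.cavities)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.cavities, start=1):
            rows.append(
                {
                    "cavity": i,
                    "volume_A3": c.volume,
                    "centroid_x": c.centroid[0],
                    "centroid_y": c.centroid[1],
                    "centroid_z": c.centroid[2],
                    "depth_A": c.depth,
                    "n_lining_residues": len(c.lining_residues),
                    "lining_residues": ";".join(
                        f"{ch}/{r}{ic}" for ch, r, ic in c.lining_residues
                    ),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "cavity", "volume_A3", "centroid_x", "centroid_y", "centroid_z",
                "depth_A", "n_lining_residues", "lining_residues",
            ],
        )


def _sphere_structuring_element(radius_vox: float) -> np.ndarray:
    r = int(np.ceil(radius_vox))
    if r < 1:
        return np.ones((1, 1, 1), dtype=bool)
    zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (xx**2 + yy**2 + zz**2) <= radius_vox**2


def _solvent_grid(
    structure: StructureModel,
    grid: float,
    probe: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Shared grid machinery.

    Returns (origin, empty, bulk, cavity_centers, shape) where ``empty``
    marks voxels outside every vdW sphere, ``bulk`` marks the empty voxels
    reachable by bulk solvent (probe-center flood fill from the box boundary,
    dilated back by the probe radius) and ``cavity_centers`` marks voxels
    where a probe could sit but cannot be reached from the boundary.
    """
    heavy = structure.heavy()
    if len(heavy) == 0:
        raise ValueError("structure has no heavy atoms")
    if grid > probe:
        raise ValueError("grid spacing must not exceed the probe radius")
    coords = heavy.coord
    radii = vdw_radii_for(heavy)
    rmax = radii.max()
    margin = rmax + probe + 2 * grid
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    shape = np.ceil((hi - lo) / grid).astype(int) + 1

    # distance from every voxel to the nearest atom *surface* via KD-tree on
    # atoms, handled per distinct radius to keep it exact
    grids = [np.arange(s) * grid + o for s, o in zip(shape, lo)]
    gx, gy, gz = np.meshgrid(grids[0], grids[1], grids[2], indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    occupied = np.zeros(pts.shape[0], dtype=bool)
    blocked = np.zeros(pts.shape[0], dtype=bool)  # within r+probe of an atom
    tree = cKDTree(pts)
    for r in np.unique(radii):
        sel = coords[radii == r]
        for mark, reach in ((occupied, r), (blocked, r + probe)):
            hits = tree.query_ball_point(sel, reach, workers=-1)
            for h in hits:
                mark[h] = True
    occupied = occupied.reshape(shape)
    blocked = blocked.reshape(shape)
    empty = ~occupied

    probe_space = ~blocked  # voxels where the probe *center* may sit
    labels, n_lab = ndimage.label(probe_space)
    boundary_labels = set()
    for axis in range(3):
        for sl in (0, -1):
            face = np.take(labels, sl, axis=axis)
            boundary_labels.update(np.unique(face[face > 0]))
    bulk_centers = np.isin(labels, sorted(boundary_labels))
    # solvent occupies everything within one probe radius of a reachable center
    selem = _sphere_structuring_element(probe / grid)
    bulk = ndimage.binary_dilation(bulk_centers, structure=selem) & empty
    cavity_centers = probe_space & ~bulk_centers
    return lo, empty, bulk, cavity_centers, shape


def detect_cavities(
    structure: StructureModel,
    grid: float = 0.5,
    probe: float = DEFAULT_PROBE_RADIUS,
    lining_cutoff: float = 4.5,
    min_volume: float = 1.0,
) -> CavitySet:
    """Internal cavity detection by grid flood fill.

    Voxels outside every van der Waals sphere are empty; empty space
    reachable by a probe rolled in from the box boundary is bulk solvent;
    the remaining connected empty components are cavity candidates.  A
    candidate is reported only if it could host the probe (it contains at
    least one voxel farther than vdW + probe from every atom), which
    discards sub-probe surface crevices and lattice interstices.  Each
    cavity reports volume (voxel count x spacing^3), centroid, depth
    (centroid to the nearest bulk-solvent voxel) and lining residues (any
    heavy atom within ``lining_cutoff`` of a cavity voxel).  Components
    smaller than ``min_volume`` A^3 are discarded as grid noise.
    """
    lo, empty, bulk, cavity_centers, shape = _solvent_grid(structure, grid, probe)
    labels, n_lab = ndimage.label(empty & ~bulk)
    # distance (in voxels) to nearest bulk voxel, for depth
    dist_to_bulk = ndimage.distance_transform_edt(~bulk) * grid

    heavy = structure.heavy()
    ins = (
        heavy.ins_code
        if "ins_code" in heavy.get_annotation_categories()
        else np.array([""] * len(heavy))
    )
    atom_tree = cKDTree(heavy.coord)

    cavities = []
    for lab in range(1, n_lab + 1):
        member = labels == lab
        if not np.any(member & cavity_centers):
            continue
        vox_idx = np.argwhere(member)
        volume = len(vox_idx) * grid**3
        if volume < min_volume:
            continue
        # drop components touching the box boundary (open to the outside)
        if (vox_idx == 0).any() or np.any(vox_idx == np.array(shape) - 1):
            continue
        coords = vox_idx * grid + lo
        centroid = coords.mean(axis=0)
        depth = float(dist_to_bulk[tuple(np.round((centroid - lo) / grid).astype(int))])
        lining: dict[ResidueKey, None] = {}
        for hits in atom_tree.query_ball_point(coords, lining_cutoff, workers=-1):
            for a in hits:
                lining.setdefault(
                    (str(heavy.chain_id[a]), int(heavy.res_id[a]), str(ins[a])), None
                )
        if not lining:
            continue
        cavities.append(Cavity(coords, volume, centroid, depth, list(lining)))
    cavities.sort(key=lambda c: -c.volume)
    return CavitySet(cavities, grid, probe, lining_cutoff)


def site_depth(
    structure: StructureModel,
    point: Sequence[float],
    grid: float = 0.5,
    probe: float = DEFAULT_PROBE_RADIUS,
) -> float:
    """Depth of a point: Euclidean distance to the nearest bulk-solvent voxel
    (0 if the point already lies in bulk solvent)."""
    lo, empty, bulk, _cavity_centers, shape = _solvent_grid(structure, grid, probe)
    point = np.asarray(point, dtype=float)
    idx = np.round((point - lo) / grid).astype(int)
    if np.any(idx < 0) or np.any(idx >= shape):
        raise ValueError("point outside the structure bounding box")
    if bulk[tuple(idx)]:
        return 0.0
    dist = ndimage.distance_transform_edt(~bulk) * grid
    return float(dist[tuple(idx)])


# ---------------------------------------------------------------------------
# Superposition / RMSD


@dataclass
class Superposition:
    """Rigid transform mapping mobile coordinates onto the reference:
    ``x_aligned = x @ rotation.T + translation``."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _kabsch(ref: np.ndarray, mob: np.ndarray) -> Superposition:
    cen_r, cen_m = ref.mean(axis=0), mob.mean(axis=0)
    P, Q = mob - cen_m, ref - cen_r
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cen_r - cen_m @ R.T
    aligned = mob @ R.T + t
    rmsd = float(np.sqrt(((aligned - ref) ** 2).sum(axis=1).mean()))
    return Superposition(R, t, rmsd, len(ref))


def _ca_pairing(
    a: StructureModel, b: StructureModel
) -> tuple[np.ndarray, np.ndarray]:
    def ca_map(s: StructureModel) -> dict[ResidueKey, np.ndarray]:
        arr = s.heavy()
        ins = (
            arr.ins_code
            if "ins_code" in arr.get_annotation_categories()
            else np.array([""] * len(arr))
        )
        out = {}
        for i in range(len(arr)):
            if str(arr.atom_name[i]) == "CA":
                out[(str(arr.chain_id[i]), int(arr.res_id[i]), str(ins[i]))] = arr.coord[i]
        return out

    ca_a, ca_b = ca_map(a), ca_map(b)
    shared = [k for k in ca_a if k in ca_b]
    ref = np.array([ca_a[k] for k in shared])
    mob = np.array([ca_b[k] for k in shared])
    return ref, mob


def superpose(
    struct_a: StructureModel,
    struct_b: StructureModel,
    atom_pairing: tuple[np.ndarray, np.ndarray] | None = None,
) -> Superposition:
    """Optimal least-squares rigid superposition (Kabsch) of B onto A.

    Default pairing: C-alpha atoms of residues shared by chain + residue
    number; for non-identical proteins pass ``atom_pairing`` as a pair of
    (n, 3) coordinate arrays from a sequence or structure alignment.
    Reflections are suppressed (det(rotation) = +1).
    """
    if atom_pairing is None:
        ref, mob = _ca_pairing(struct_a, struct_b)
    else:
        ref, mob = (np.asarray(x, dtype=float) for x in atom_pairing)
    if len(ref) != len(mob):
        raise ValueError("pairing arrays must have equal length")
    if len(ref) < 3:
        raise ValueError(f"need at least 3 atom pairs, got {len(ref)}")
    return _kabsch(ref, mob)


@dataclass
class RMSDProfile:
    superposition: Superposition
    global_rmsd: float
    per_residue: pd.Series  # index (chain, res_id, ins_code) -> RMSD (A)

    def to_frame(self) -> pd.DataFrame:
        df = self.per_residue.rename("rmsd_A").reset_index()
        df.columns = ["chain", "res_id", "ins_code", "rmsd_A"]
        return df


def per_residue_rmsd(
    struct_a: StructureModel,
    struct_b: StructureModel,
    superposition: Superposition | None = None,
) -> RMSDProfile:
    """Per-residue all-heavy-atom RMSD after one global superposition.

    Residues are matched by chain + residue number + insertion code; atoms
    by name within the residue.  Residues with no shared atoms are omitted
    with a warning.
    """
    if superposition is None:
        superposition = superpose(struct_a, struct_b)

    def atom_map(s: StructureModel) -> dict[tuple, np.ndarray]:
        arr = s.heavy()
        ins = (
            arr.ins_code
            if "ins_code" in arr.get_annotation_categories()
            else np.array([""] * len(arr))
        )
        return {
            (str(arr.chain_id[i]), int(arr.res_id[i]), str(ins[i]), str(arr.atom_name[i])): arr.coord[i]
            for i in range(len(arr))
        }

    map_a, map_b = atom_map(struct_a), atom_map(struct_b)
    per_res: dict[ResidueKey, list[float]] = {}
    for key, xa in map_a.items():
        if key not in map_b:
            continue
        xb = superposition.apply(map_b[key][None, :])[0]
        per_res.setdefault(key[:3], []).append(float(((xa - xb) ** 2).sum()))
    all_keys_a = {k[:3] for k in map_a}
    missing = all_keys_a - set(per_res)
    if missing:
        warnings.warn(f"{len(missing)} residue(s) had no shared atoms and were omitted")
    if not per_res:
        raise ValueError("no shared atoms between the structures")
    values = {k: float(np.sqrt(np.mean(v))) for k, v in per_res.items()}
    index = pd.MultiIndex.from_tuples(values.keys(), names=["chain", "res_id", "ins_code"])
    series = pd.Series(list(values.values()), index=index).sort_index()
    all_sq = [d for v in per_res.values() for d in v]
    global_rmsd = float(np.sqrt(np.mean(all_sq)))
    return RMSDProfile(superposition, global_rmsd, series)


def anchor_pairing_from_structures(
    struct_a: StructureModel,
    struct_b: StructureModel,
    refmap_a,
    refmap_b,
    max_distance: float = 5.0,
):
    """Derive MSA column anchors from two superposed structures.

    The structures are superposed on their shared C-alpha atoms; residue
    pairs whose C-alphas end up within ``max_distance`` A and that resolve
    through both reference maps become anchored column pairs, thinned to a
    strictly monotonic subsequence.  Returns an
    :class:`scamap.alignment.AnchorPairing`.
    """
    from .alignment import AnchorPairing

    sup = superpose(struct_a, struct_b)
    ref, mob = _ca_pairing(struct_a, struct_b)
    dist = np.linalg.norm(ref - sup.apply(mob), axis=1)

    def ca_keys(s: StructureModel):
        arr = s.heavy()
        ins = (
            arr.ins_code
            if "ins_code" in arr.get_annotation_categories()
            else np.array([""] * len(arr))
        )
        return [
            (str(arr.chain_id[i]), int(arr.res_id[i]), str(ins[i]))
            for i in range(len(arr))
            if str(arr.atom_name[i]) == "CA"
        ]

    keys_a = {k: None for k in ca_keys(struct_a)}
    keys_b = set(ca_keys(struct_b))
    shared = [k for k in keys_a if k in keys_b]
    col_a = refmap_a.resnum_to_col
    col_b = refmap_b.resnum_to_col
    pairs = []
    for k, d in zip(shared, dist):
        resnum = k[1]
        if d <= max_distance and resnum in col_a and resnum in col_b:
            pairs.append((col_a[resnum], col_b[resnum]))
    pairs.sort()
    monotonic: list[tuple[int, int]] = []
    for a, b in pairs:
        if not monotonic or (a > monotonic[-1][0] and b > monotonic[-1][1]):
            monotonic.append((a, b))
    return AnchorPairing(monotonic)


# ---------------------------------------------------------------------------
# Profiling


def _per_residue_table(structure: StructureModel) -> pd.DataFrame:
    heavy = structure.heavy()
    ins = (
        heavy.ins_code
        if "ins_code" in heavy.get_annotation_categories()
        else np.array([""] * len(heavy))
    )
    return pd.DataFrame(
        {
            "chain": heavy.chain_id.astype(str),
            "res_id": heavy.res_id.astype(int),
            "ins_code": np.asarray(ins).astype(str),
            "b_factor": heavy.b_factor
            if "b_factor" in heavy.get_annotation_categories()
            else np.zeros(len(heavy)),
        }
    )


def bfactor_summary(
    structure: StructureModel, partition: DomainPartition
) -> pd.DataFrame:
    """Per-domain B-factor statistics.

    Residue B is the mean over the residue's heavy atoms; domain z-scores
    are relative to the whole-structure per-residue distribution.
    """
    df = _per_residue_table(structure)
    if np.allclose(df["b_factor"], 0.0):
        warnings.warn("all B-factors are zero")
    res = df.groupby(["chain", "res_id", "ins_code"], sort=False)["b_factor"].mean()
    overall_mean, overall_std = float(res.mean()), float(res.std(ddof=0))
    rows = []
    for name in partition.domains:
        wanted = set(partition.residues(name))
        vals = [
            b for (ch, rid, _ic), b in res.items() if (ch, rid) in wanted
        ]
        vals = np.asarray(vals)
        mean = float(vals.mean()) if len(vals) else float("nan")
        rows.append(
            {
                "domain": name,
                "n_residues": len(vals),
                "mean_b": mean,
                "median_b": float(np.median(vals)) if len(vals) else float("nan"),
                "z_score": (mean - overall_mean) / overall_std
                if overall_std > 0 and len(vals)
                else 0.0,
            }
        )
    return pd.DataFrame(rows)


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def backbone_dihedrals(structure: StructureModel) -> pd.DataFrame:
    """phi/psi per residue (degrees); NaN at termini and across chain breaks
    (peptide C-N distance > 1.8 A)."""
    heavy = structure.heavy()
    bb: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    order: list[tuple[str, int]] = []
    for i in range(len(heavy)):
        an = str(heavy.atom_name[i])
        if an in ("N", "CA", "C"):
            key = (str(heavy.chain_id[i]), int(heavy.res_id[i]))
            if key not in bb:
                bb[key] = {}
                order.append(key)
            bb[key][an] = heavy.coord[i]
    rows = []
    for k, key in enumerate(order):
        chain, rid = key
        res = bb[key]
        phi = psi = float("nan")
        prev = order[k - 1] if k > 0 and order[k - 1][0] == chain else None
        nxt = order[k + 1] if k + 1 < len(order) and order[k + 1][0] == chain else None
        if prev and all(a in bb[prev] for a in ("C",)) and all(a in res for a in ("N", "CA", "C")):
            if np.linalg.norm(res["N"] - bb[prev]["C"]) <= 1.8:
                phi = _dihedral(bb[prev]["C"], res["N"], res["CA"], res["C"])
        if nxt and "N" in bb[nxt] and all(a in res for a in ("N", "CA", "C")):
            if np.linalg.norm(bb[nxt]["N"] - res["C"]) <= 1.8:
                psi = _dihedral(res["N"], res["CA"], res["C"], bb[nxt]["N"])
        rows.append({"chain": chain, "res_id": rid, "phi": phi, "psi": psi})
    return pd.DataFrame(rows)


def rama_fractions(
    structure: StructureModel,
    partition: DomainPartition,
    alpha_region: tuple[float, float, float, float] = ALPHA_REGION,
    beta_region: tuple[float, float, float, float] = BETA_REGION,
) -> pd.DataFrame:
    """Fractions of residues in the alpha-helical and beta-strand
    Ramachandran regions, per domain, plus each domain's share of the
    structure's total secondary-structure (alpha+beta) residues."""
    di = backbone_dihedrals(structure)

    def in_region(row, region):
        pmin, pmax, smin, smax = region
        return (
            np.isfinite(row["phi"])
            and np.isfinite(row["psi"])
            and pmin <= row["phi"] <= pmax
            and smin <= row["psi"] <= smax
        )

    di["alpha"] = di.apply(lambda r: in_region(r, alpha_region), axis=1)
    di["beta"] = di.apply(lambda r: in_region(r, beta_region), axis=1)
    di["classifiable"] = np.isfinite(di["phi"]) & np.isfinite(di["psi"])
    di["domain"] = [
        partition.domain_of(c, r) for c, r in zip(di["chain"], di["res_id"])
    ]
    total_ss = int((di["alpha"] | di["beta"]).sum())
    rows = []
    for name in partition.domains:
        sub = di[di["domain"] == name]
        n = int(sub["classifiable"].sum())
        n_a, n_b = int(sub["alpha"].sum()), int(sub["beta"].sum())
        rows.append(
            {
                "domain": name,
                "n_residues": len(sub),
                "n_classifiable": n,
                "alpha_fraction": n_a / n if n else float("nan"),
                "beta_fraction": n_b / n if n else float("nan"),
                "ss_share": (n_a + n_b) / total_ss if total_ss else float("nan"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sector-on-structure report


def annotate_sectors(
    sector_set,
    refmap,
    structure: StructureModel,
    sasa: SASAResult,
    conservation=None,
    cavities: CavitySet | None = None,
    partition: DomainPartition | None = None,
    chain: str = "A",
    conserved_quantile: float = 0.8,
) -> dict:
    """Quantitative sector-on-structure report.

    Sector positions (reference numbering) resolve to structure residues as
    ``(chain, refnum)``.  Per sector: size, burial fraction, conserved
    fraction (conservation above the given quantile of the whole profile),
    per-domain composition, overlap with each cavity's lining residues, and
    pairwise sector overlaps.  Unmappable positions are listed, not dropped.
    """
    from .sca import sector_overlap as _overlap

    known = {(c, r) for c, r, _ in sasa.per_residue.index}
    cons_values = None
    cons_cut = None
    if conservation is not None:
        cons_values = np.asarray(conservation.values)
        cons_cut = float(np.quantile(cons_values, conserved_quantile))
        resnum_to_col = refmap.resnum_to_col if refmap is not None else None
    report: dict = {
        "chain": chain,
        "burial_threshold": sasa.burial_threshold,
        "conserved_quantile": conserved_quantile,
        "sectors": {},
    }
    for s in sector_set:
        mapped = [p for p in s.positions if (chain, p) in known]
        unmapped = [p for p in s.positions if (chain, p) not in known]
        entry: dict = {
            "size": len(s.positions),
            "n_mapped": len(mapped),
            "unmapped_positions": unmapped,
            "burial_fraction": burial_fraction([(chain, p) for p in mapped], sasa)
            if mapped
            else float("nan"),
        }
        if cons_values is not None:
            cols = [
                resnum_to_col[p] if resnum_to_col else p - 1
                for p in s.positions
                if (resnum_to_col is None and 0 <= p - 1 < len(cons_values))
                or (resnum_to_col is not None and p in resnum_to_col)
            ]
            entry["conserved_fraction"] = (
                float(np.mean(cons_values[cols] > cons_cut)) if cols else float("nan")
            )
        if partition is not None:
            comp: dict[str, int] = {}
            for p in mapped:
                d = partition.domain_of(chain, p) or "unassigned"
                comp[d] = comp.get(d, 0) + 1
            entry["domain_composition"] = comp
        if cavities is not None:
            entry["cavity_overlap"] = {}
            for i, cav in enumerate(cavities, start=1):
                lining = {(c, r) for c, r, _ in cav.lining_residues}
                inter = sum(1 for p in s.positions if (chain, p) in lining)
                entry["cavity_overlap"][f"cavity_{i}"] = (
                    inter / len(s.positions) if s.positions else float("nan")
                )
        report["sectors"][s.label] = entry
    report["pairwise_overlap"] = {
        (a.label, b.label): _overlap(a, b)
        for a in sector_set
        for b in sector_set
        if a.label != b.label
    }
    return report


def write_bfactor_annotated(
    structure: StructureModel,
    per_residue_score: dict[tuple[str, int], float],
    path: str | Path,
    default: float = 0.0,
) -> None:
    """Write a PDB with a per-residue score in the B-factor column, for
    visualization of sector loadings / conservation / RMSD on the structure."""
    arr = structure.atoms.copy()
    scores = np.full(len(arr), default)
    for i in range(len(arr)):
        scores[i] = per_residue_score.get(
            (str(arr.chain_id[i]), int(arr.res_id[i])), default
        )
    arr.set_annotation("b_factor", scores)
    out = PDBFile()
    out.set_structure(arr)
    out.write(str(path))
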