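"""Synthetic alignments and toy structures with known ground truth.

Two generator families make every pipeline stage testable without external
data:

* ``gen_sector_msa`` plants co-evolving column groups in an otherwise
  background-composition alignment.  Coupling is modelled as a per-sequence
  hidden state shared by all columns of a sector: each sector column emits
  its state-specific preferred residue with fidelity ``c`` and a background
  draw otherwise.  This is exactly the covariation pattern a coupling
  analysis is built to detect; it makes no claim about how real families
  evolve (no tree, no substitution model — phylogenetic redundancy is
  emulated only as appended near-duplicate rows).

* ``gen_toy_structure`` builds small PDB-writable structures whose geometric
  truths are analytic or computable on a fine grid: a hollow shell with an
  enclosed cavity, two separated mini-domains with zero interface, ideal
  helix/strand backbones with canonical dihedrals, and a packed globule with
  a fully buried core.  Toy structures use alanine-like residues with
  standard radii so the truths are geometry-only.

All generators are deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import biotite.structure as bst

from .alignment import Alignment
from .constants import AA_ALPHABET, BACKGROUND_COMPOSITION, VDW_RADII
from .structure import StructureModel

__all__ = [
    "SectorSpec",
    "SyntheticMSASpec",
    "gen_sector_msa",
    "SyntheticStructureSpec",
    "gen_toy_structure",
    "perturb_conformer",
]


# ---------------------------------------------------------------------------
# Alignments


@dataclass
class SectorSpec:
    """One planted sector: which columns, how many hidden states, and the
    emission fidelity ``c`` (probability a sector column shows its
    state-preferred residue rather than a background draw)."""

    positions: tuple[int, ...]
    n_hidden_states: int = 2
    fidelity: float = 0.9


@dataclass
class SyntheticMSASpec:
    """Defaults: a 400 x 100 alignment with two planted 15-column sectors at
    fidelity 0.9, ten conserved columns, 2% gaps, and 50 appended
    near-duplicate rows emulating phylogenetic redundancy."""

    n_seq: int = 400
    n_pos: int = 100
    sectors: tuple[SectorSpec, ...] = (
        SectorSpec(tuple(range(10, 25))),
        SectorSpec(tuple(range(40, 55))),
    )
    conserved_positions: tuple[int, ...] = tuple(range(70, 80))
    conserved_probability: float = 0.9
    background: np.ndarray = field(default_factory=lambda: BACKGROUND_COMPOSITION.copy())
    gap_rate: float = 0.02
    n_duplicates: int = 50
    duplicate_mutation_rate: float = 0.05
    seed: int = 1

    def __post_init__(self):
        planted: set[int] = set()
        for s in self.sectors:
            if planted & set(s.positions):
                raise ValueError("planted sector position sets overlap")
            planted |= set(s.positions)
        if planted & set(self.conserved_positions):
            raise ValueError("conserved positions overlap a planted sector")
        for s in self.sectors:
            if not 0 < s.fidelity < 1:
                raise ValueError("emission fidelity must be in (0, 1)")
        if not 0 < self.conserved_probability < 1:
            raise ValueError("conserved probability must be in (0, 1)")


@dataclass
class MSAGroundTruth:
    sector_positions: list[tuple[int, ...]]  # 0-based columns per sector
    hidden_states: np.ndarray  # (n_seq_total, n_sectors)
    preferred_residue: list[dict[tuple[int, int], int]]  # sector -> {(state, col): aa}
    conserved_positions: tuple[int, ...]
    dominant_residues: dict[int, int]


def gen_sector_msa(spec: SyntheticMSASpec) -> tuple[Alignment, MSAGroundTruth]:
    """Generate an alignment with planted co-evolving sectors.

    Per sequence and sector a hidden state is drawn uniformly; each sector
    column then emits that state's preferred residue with probability
    ``fidelity`` and a background draw otherwise.  Conserved columns emit a
    dominant residue at ``conserved_probability``; all other columns are iid
    background.  Near-duplicate rows (point mutations at
    ``duplicate_mutation_rate``) are appended last.
    """
    rng = np.random.default_rng(spec.seed)
    q = spec.background / spec.background.sum()
    n, p = spec.n_seq, spec.n_pos

    # state- and column-specific preferred residues, distinct across states
    preferred: list[dict[tuple[int, int], int]] = []
    for s in spec.sectors:
        table: dict[tuple[int, int], int] = {}
        for col in s.positions:
            aas = rng.choice(20, size=s.n_hidden_states, replace=False)
            for state in range(s.n_hidden_states):
                table[(state, col)] = int(aas[state])
        preferred.append(table)
    dominant = {col: int(rng.integers(20)) for col in spec.conserved_positions}

    idx = rng.choice(20, size=(n, p), p=q)
    states = np.column_stack(
        [rng.integers(s.n_hidden_states, size=n) for s in spec.sectors]
    ) if spec.sectors else np.zeros((n, 0), dtype=int)
    for k, s in enumerate(spec.sectors):
        for col in s.positions:
            use_pref = rng.random(n) < s.fidelity
            pref = np.array([preferred[k][(st, col)] for st in states[:, k]])
            idx[use_pref, col] = pref[use_pref]
    for col, aa in dominant.items():
        use_dom = rng.random(n) < spec.conserved_probability
        idx[use_dom, col] = aa

    gaps = rng.random((n, p)) < spec.gap_rate
    code_to_char = np.array(list(AA_ALPHABET) + ["-"])
    idx_full = np.where(gaps, 20, idx)

    # phylogenetic redundancy: near-duplicates of randomly chosen parents
    dup_states = []
    dup_rows = []
    if spec.n_duplicates:
        parents = rng.integers(n, size=spec.n_duplicates)
        for pi in parents:
            row = idx_full[pi].copy()
            mutate = rng.random(p) < spec.duplicate_mutation_rate
            row[mutate] = rng.choice(20, size=mutate.sum(), p=q)
            dup_rows.append(row)
            dup_states.append(states[pi])
    all_rows = np.vstack([idx_full] + [r[None, :] for r in dup_rows]) if dup_rows else idx_full
    all_states = (
        np.vstack([states] + [s[None, :] for s in dup_states]) if dup_rows else states
    )

    ids = [f"seq{i:04d}" for i in range(n)] + [
        f"dup{i:04d}" for i in range(len(dup_rows))
    ]
    rows = ["".join(code_to_char[r]) for r in all_rows]
    truth = MSAGroundTruth(
        [tuple(s.positions) for s in spec.sectors],
        all_states,
        preferred,
        tuple(spec.conserved_positions),
        dominant,
    )
    return Alignment(ids, rows), truth


# ---------------------------------------------------------------------------
# Structures


@dataclass
class SyntheticStructureSpec:
    """Parameters for a toy structure.

    ``kind`` is one of hollow-shell, two-domain, canonical-helix,
    canonical-strand, globule.  Geometric parameters are in Angstrom.
    """

    kind: str = "hollow-shell"
    shell_radius: float = 8.0
    atom_spacing: float = 2.2
    domain_radius: float = 6.0
    separation: float = 20.0
    n_residues: int = 20
    phi: float = -60.0
    psi: float = -45.0
    globule_radius: float = 12.0
    lattice_spacing: float = 1.9
    bfactor: float = 20.0
    seed: int = 1

    def __post_init__(self):
        for v in (self.shell_radius, self.atom_spacing, self.domain_radius,
                  self.separation, self.globule_radius, self.lattice_spacing):
            if v <= 0:
                raise ValueError("geometric parameters must be positive")
        if self.kind not in (
            "hollow-shell", "two-domain", "canonical-helix", "canonical-strand", "globule"
        ):
            raise ValueError(f"unknown structure kind {self.kind!r}")


def _atom_array(
    coords: np.ndarray,
    chain_ids: Sequence[str],
    res_ids: Sequence[int],
    atom_names: Sequence[str],
    elements: Sequence[str],
    res_names: Sequence[str] | None = None,
    bfactors: Sequence[float] | None = None,
) -> bst.AtomArray:
    n = len(coords)
    arr = bst.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id = np.asarray(chain_ids, dtype="U4")
    arr.res_id = np.asarray(res_ids, dtype=int)
    arr.res_name = np.asarray(res_names if res_names is not None else ["ALA"] * n, dtype="U5")
    arr.atom_name = np.asarray(atom_names, dtype="U6")
    arr.element = np.asarray(elements, dtype="U2")
    arr.hetero = np.zeros(n, dtype=bool)
    arr.set_annotation("b_factor", np.asarray(bfactors if bfactors is not None else [20.0] * n, dtype=float))
    arr.set_annotation("occupancy", np.ones(n))
    arr.set_annotation("ins_code", np.array([""] * n, dtype="U1"))
    return arr


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return radius * np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def _carbon_cluster(coords: np.ndarray, chain: str, bfactor: float) -> bst.AtomArray:
    n = len(coords)
    return _atom_array(
        coords,
        [chain] * n,
        list(range(1, n + 1)),
        ["CA"] * n,
        ["C"] * n,
        bfactors=[bfactor] * n,
    )


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          length: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d from the three preceding atoms (natural extension
    reference frame): |cd| = length, angle(b,c,d), dihedral(a,b,c,d)."""
    ang = np.radians(angle_deg)
    tor = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [
            -length * np.cos(ang),
            length * np.sin(ang) * np.cos(tor),
            length * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


# canonical backbone geometry (lengths A, angles deg)
_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7}
_OMEGA = 180.0


def _ideal_backbone(n_res: int, phi: float, psi: float, chain: str,
                    bfactor: float) -> bst.AtomArray:
    """Poly-alanine N/CA/C backbone with uniform (phi, psi)."""
    coords = [
        np.array([0.0, 0.0, 0.0]),  # N1
        np.array([_BOND["N-CA"], 0.0, 0.0]),  # CA1
    ]
    ang = np.radians(_ANGLE["N-CA-C"])
    coords.append(
        coords[1] + _BOND["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    )
    names = ["N", "CA", "C"]
    res_ids = [1, 1, 1]
    for r in range(2, n_res + 1):
        a, b, c = coords[-3], coords[-2], coords[-1]
        n_new = _nerf(a, b, c, _BOND["C-N"], _ANGLE["CA-C-N"], psi)
        ca_new = _nerf(b, c, n_new, _BOND["N-CA"], _ANGLE["C-N-CA"], _OMEGA)
        c_new = _nerf(c, n_new, ca_new, _BOND["CA-C"], _ANGLE["N-CA-C"], phi)
        coords += [n_new, ca_new, c_new]
        names += ["N", "CA", "C"]
        res_ids += [r, r, r]
    elements = ["N" if nm == "N" else "C" for nm in names]
    return _atom_array(
        np.array(coords),
        [chain] * len(coords),
        res_ids,
        names,
        elements,
        bfactors=[bfactor] * len(coords),
    )


def _fine_grid_cavity_volume(
    coords: np.ndarray, radius: float, inner_extent: float, spacing: float = 0.2
) -> float:
    """Oracle volume of the enclosed void of a (closed) shell: grid points
    within ``inner_extent`` of the origin that lie outside every vdW sphere.
    Independent of the flood-fill cavity detector."""
    g = np.arange(-inner_extent, inner_extent + spacing, spacing)
    gx, gy, gz = np.meshgrid(g, g, g, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    inside = np.linalg.norm(pts, axis=1) <= inner_extent
    pts = pts[inside]
    from scipy.spatial import cKDTree

    d, _ = cKDTree(coords).query(pts, workers=-1)
    return float((d > radius).sum() * spacing**3)


def gen_toy_structure(spec: SyntheticStructureSpec) -> tuple[StructureModel, dict]:
    """Build a toy structure and its analytic/oracle truth record."""
    r_c = VDW_RADII["C"]
    if spec.kind == "hollow-shell":
        n_atoms = max(int(np.ceil(4 * np.pi * spec.shell_radius**2 / spec.atom_spacing**2 * 4)), 50)
        coords = _fibonacci_sphere(n_atoms, spec.shell_radius)
        if spec.shell_radius - r_c <= 1.0:
            raise ValueError("shell radius leaves no enclosed void")
        arr = _carbon_cluster(coords, "A", spec.bfactor)
        truth = {
            "cavity_volume_oracle": _fine_grid_cavity_volume(
                coords, r_c, spec.shell_radius, spacing=0.2
            ),
            "wall_center_radius": spec.shell_radius,
            "expected_n_cavities": 1,
        }
    elif spec.kind == "two-domain":
        rng = np.random.default_rng(spec.seed)

        def blob(center):
            g = np.arange(-spec.domain_radius, spec.domain_radius + 1e-9, spec.lattice_spacing)
            gx, gy, gz = np.meshgrid(g, g, g, indexing="ij")
            pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
            pts = pts[np.linalg.norm(pts, axis=1) <= spec.domain_radius]
            return pts + center

        half = spec.separation / 2.0
        a = blob(np.array([-half, 0.0, 0.0]))
        b = blob(np.array([half, 0.0, 0.0]))
        coords = np.vstack([a, b])
        chains = ["A"] * len(a) + ["B"] * len(b)
        arr = _atom_array(
            coords,
            chains,
            list(range(1, len(a) + 1)) + list(range(1, len(b) + 1)),
            ["CA"] * len(coords),
            ["C"] * len(coords),
            bfactors=[spec.bfactor] * len(coords),
        )
        gap = spec.separation - 2 * spec.domain_radius
        truth = {
            "surface_gap": gap,
            "interface_zero": gap > 2 * (r_c + 1.4),
            "chain_a_residues": [("A", i) for i in range(1, len(a) + 1)],
            "chain_b_residues": [("B", i) for i in range(1, len(b) + 1)],
        }
    elif spec.kind in ("canonical-helix", "canonical-strand"):
        if spec.kind == "canonical-helix":
            phi, psi = -60.0, -45.0
        else:
            phi, psi = -120.0, 130.0
        arr = _ideal_backbone(spec.n_residues, phi, psi, "A", spec.bfactor)
        truth = {"phi": phi, "psi": psi}
    elif spec.kind == "globule":
        g = np.arange(-spec.globule_radius, spec.globule_radius + 1e-9, spec.lattice_spacing)
        gx, gy, gz = np.meshgrid(g, g, g, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        r = np.linalg.norm(pts, axis=1)
        pts = pts[r <= spec.globule_radius]
        r = np.linalg.norm(pts, axis=1)
        arr = _carbon_cluster(pts, "A", spec.bfactor)
        core_depth = 4.5
        truth = {
            "core_residues": [
                ("A", i + 1) for i in range(len(pts)) if r[i] < spec.globule_radius - core_depth
            ],
            "expected_n_cavities": 0,
        }
    else:  # pragma: no cover - guarded in __post_init__
        raise ValueError(spec.kind)
    return StructureModel(arr, name=spec.kind), truth


def perturb_conformer(
    structure: StructureModel,
    displacement_map: dict[tuple[str, int], Sequence[float]] | None = None,
    sigma: float = 0.0,
    seed: int = 1,
) -> tuple[StructureModel, "object"]:
    """Create a perturbed conformer with a known per-residue RMSD profile.

    Listed residues are rigidly translated by their vectors; all other atoms
    receive isotropic Gaussian jitter of standard deviation ``sigma`` per
    coordinate.  The truth profile is the exact per-residue RMSD between the
    original and perturbed coordinates (no superposition applied).
    """
    import pandas as pd

    displacement_map = displacement_map or {}
    arr = structure.atoms.copy()
    keys = [(str(c), int(r)) for c, r in zip(arr.chain_id, arr.res_id)]
    present = set(keys)
    for k in displacement_map:
        if (str(k[0]), int(k[1])) not in present:
            raise KeyError(f"residue {k} not in structure")
    rng = np.random.default_rng(seed)
    coords = arr.coord.astype(float).copy()
    displaced_atoms = np.zeros(len(arr), dtype=bool)
    for i, k in enumerate(keys):
        if k in displacement_map:
            coords[i] += np.asarray(displacement_map[k], dtype=float)
            displaced_atoms[i] = True
    if sigma > 0:
        jitter = rng.normal(0.0, sigma, size=coords.shape)
        coords[~displaced_atoms] += jitter[~displaced_atoms]
    new = arr.copy()
    new.coord = coords.astype(np.float32)

    sq = ((coords - structure.atoms.coord.astype(float)) ** 2).sum(axis=1)
    df = pd.DataFrame({"chain": [k[0] for k in keys], "res_id": [k[1] for k in keys], "sq": sq})
    truth = df.groupby(["chain", "res_id"], sort=True)["sq"].mean().pow(0.5)
    return StructureModel(new, name=structure.name + "_perturbed"), truth
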