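"""Coordinate-level analysis of domain-swapped oligomers.

Operations on crystal structures of a swapped antibody-light-chain oligomer:
hydrogen-bond census between protomers and across the dimer-dimer interface,
hydrophobic-cluster identification, Cα RMSD by framework region, detection of
the swapped segment and hinge from interchain contact profiles, and simple
free-energy bookkeeping for assembly steps.

Conventions
-----------
* "Heavy atoms" for hydrogen bonding are N, O and S only (no angle criterion;
  the census is a pure distance cutoff between polar heavy atoms, default
  3.5 Å).  Counts under other definitions will differ; the full bond list is
  always returned so the definition is auditable.
* Waters are parsed and retained but excluded from bond counts by default.
* Residue identifiers honor insertion codes (Kabat numbering, e.g. 27d);
  selection strings are ``chain`` or ``chain:first-last`` with inclusive
  bounds, e.g. ``A:96-107`` or ``B:27d-34``.
* Symmetry mates are never generated; analysis is restricted to the deposited
  asymmetric-unit chains.
* Alternate locations resolve to the highest occupancy, first wins on a tie.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Residue",
    "StructureModel",
    "HydrogenBond",
    "SwapReport",
    "InterfaceReport",
    "read_structure",
    "find_hbonds",
    "interface_report",
    "kabsch_rmsd",
    "detect_swap",
    "framework_rmsd",
    "assembly_free_energy",
    "KABAT_FRAMEWORK_REGIONS",
]

WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}
POLAR_ELEMENTS = {"N", "O", "S"}
HYDROPHOBIC_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP", "TYR"}

# Kabat framework regions of a light-chain variable domain: the three regions
# before the hinge loop (FR1-FR3) and the C-terminal region after it (FR4).
KABAT_FRAMEWORK_REGIONS = {
    "FR1": ("1", "23"),
    "FR2": ("35", "49"),
    "FR3": ("51", "88"),
    "FR4": ("98", "107"),
}


@dataclass(frozen=True)
class AtomRecord:
    chain_id: str
    res_name: str
    res_seq: int
    icode: str  # '' when absent; lowercase-insensitive, stored upper
    atom_name: str
    element: str
    xyz: tuple[float, float, float]
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError(f"atom {self.atom_name} has an empty element symbol")
        if not all(math.isfinite(c) for c in self.xyz):
            raise ValueError(f"non-finite coordinates for atom {self.atom_name}")

    @property
    def res_id(self) -> str:
        return f"{self.res_seq}{self.icode.lower()}"

    @property
    def is_water(self) -> bool:
        return self.res_name.upper() in WATER_NAMES

    def label(self) -> str:
        return f"{self.res_name.capitalize()}{self.res_id}_{self.chain_id}({self.atom_name})"


@dataclass
class Residue:
    chain_id: str
    res_name: str
    res_seq: int
    icode: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def res_id(self) -> str:
        return f"{self.res_seq}{self.icode.lower()}"

    @property
    def is_water(self) -> bool:
        return self.res_name.upper() in WATER_NAMES

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        return None


_RESID_RE = re.compile(r"^(-?\d+)([A-Za-z]?)$")


def parse_res_id(token: str) -> tuple[int, str]:
    """Parse '96' or '27d' into (number, insertion code)."""
    m = _RESID_RE.match(token.strip())
    if not m:
        raise ValueError(f"invalid residue identifier {token!r}")
    return int(m.group(1)), m.group(2).upper()


class StructureModel:
    """Ordered chains of ordered residues with selection support."""

    def __init__(self, chains: dict[str, list[Residue]]):
        if not chains or all(len(v) == 0 for v in chains.values()):
            raise ValueError("empty structure model")
        for cid, residues in chains.items():
            seen = set()
            for r in residues:
                key = (r.res_seq, r.icode)
                if key in seen:
                    raise ValueError(f"duplicate residue {r.res_id} in chain {cid}")
                seen.add(key)
        self.chains = chains

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def protein_chain_ids(self) -> list[str]:
        return [cid for cid, res in self.chains.items() if any(not r.is_water for r in res)]

    def residues(self, chain_id: str, include_waters: bool = True) -> list[Residue]:
        if chain_id not in self.chains:
            raise KeyError(f"no chain {chain_id!r} in model (have {self.chain_ids})")
        res = self.chains[chain_id]
        return res if include_waters else [r for r in res if not r.is_water]

    def select(self, selection: str, include_waters: bool = False) -> list[AtomRecord]:
        """Atoms for ``chain`` or ``chain:first-last`` (inclusive, icode-aware)."""
        sel = selection.strip()
        if ":" in sel:
            chain_id, rng = sel.split(":", 1)
            first_s, last_s = rng.split("-", 1)
            first, last = parse_res_id(first_s), parse_res_id(last_s)
        else:
            chain_id, first, last = sel, None, None
        residues = self.residues(chain_id, include_waters=include_waters)
        if first is not None:
            started = False
            picked: list[Residue] = []
            for r in residues:
                key = (r.res_seq, r.icode)
                if key == first:
                    started = True
                if started:
                    picked.append(r)
                if key == last:
                    break
            residues = picked
        return [a for r in residues for a in r.atoms]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """A copy with xyz -> R·xyz + t (for invariance checks and fixtures)."""
        rot = np.asarray(rotation, dtype=float)
        tr = np.asarray(translation, dtype=float)
        new_chains: dict[str, list[Residue]] = {}
        for cid, residues in self.chains.items():
            out = []
            for r in residues:
                atoms = [
                    AtomRecord(
                        chain_id=a.chain_id,
                        res_name=a.res_name,
                        res_seq=a.res_seq,
                        icode=a.icode,
                        atom_name=a.atom_name,
                        element=a.element,
                        xyz=tuple(rot @ np.asarray(a.xyz) + tr),
                        occupancy=a.occupancy,
                        b_factor=a.b_factor,
                    )
                    for a in r.atoms
                ]
                out.append(Residue(r.chain_id, r.res_name, r.res_seq, r.icode, atoms))
            new_chains[cid] = out
        return StructureModel(new_chains)


@dataclass(frozen=True)
class HydrogenBond:
    """A polar heavy-atom pair under the distance cutoff.

    Without explicit hydrogens the donor/acceptor assignment is not
    determined; ``donor_side`` is the atom from the first selection and
    ``acceptor_side`` the atom from the second.
    """

    donor_side: AtomRecord
    acceptor_side: AtomRecord
    distance: float
    scope: str  # 'interchain' | 'intrachain'

    def label(self) -> str:
        return f"{self.donor_side.label()}-{self.acceptor_side.label()} {self.distance:.2f} A"


@dataclass(frozen=True)
class SwapReport:
    chain_pair: tuple[str, str]
    swapped_segments: dict  # chain -> (first res_id, last res_id) or None
    hinge_segments: dict  # chain -> (first res_id, last res_id) or None
    profiles: dict  # chain -> list of (res_id, smoothed interchain contact fraction)


@dataclass(frozen=True)
class InterfaceReport:
    contacts: tuple  # (atom_a, atom_b, distance) under the contact cutoff
    hydrogen_bonds: tuple  # HydrogenBond list at the H-bond cutoff
    hydrophobic_cluster: tuple  # residue labels 'Tyr36_A' spanning both groups

    @property
    def n_hbonds(self) -> int:
        return len(self.hydrogen_bonds)


# ---------------------------------------------------------------------------
# reading

def read_structure(path: str | Path) -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel.

    All ATOM/HETATM records are parsed; waters are retained but flagged;
    insertion codes are preserved; alternate locations resolve to the highest
    occupancy (first on tie).
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"could not parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: structure contains no models")
    model = st[0]
    chains: dict[str, list[Residue]] = {}
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            icode = res.seqid.icode.strip()
            record = Residue(
                chain_id=chain.name,
                res_name=res.name,
                res_seq=res.seqid.num,
                icode=icode.upper(),
            )
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in best.values():
                record.atoms.append(
                    AtomRecord(
                        chain_id=chain.name,
                        res_name=res.name,
                        res_seq=res.seqid.num,
                        icode=icode.upper(),
                        atom_name=atom.name,
                        element=atom.element.name,
                        xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                        occupancy=atom.occ,
                        b_factor=atom.b_iso,
                    )
                )
            if record.atoms:
                residues.append(record)
        if residues:
            chains.setdefault(chain.name, []).extend(residues)
    if not chains:
        raise ValueError(f"{path}: no atoms found")
    return StructureModel(chains)


# ---------------------------------------------------------------------------
# hydrogen bonds and contacts

def _atom_key(a: AtomRecord) -> tuple:
    return (a.chain_id, a.res_seq, a.icode, a.atom_name)


def _res_key(a: AtomRecord) -> tuple:
    return (a.chain_id, a.res_seq, a.icode)


def _pair_distances(atoms_a: Sequence[AtomRecord], atoms_b: Sequence[AtomRecord]) -> np.ndarray:
    xa = np.array([a.xyz for a in atoms_a])
    xb = np.array([b.xyz for b in atoms_b])
    return np.sqrt(((xa[:, None, :] - xb[None, :, :]) ** 2).sum(axis=2))


def find_hbonds(
    model_or_atoms_a: StructureModel | Sequence[AtomRecord],
    group_a: str | None = None,
    group_b: str | None = None,
    cutoff: float = 3.5,
    include_waters: bool = False,
    atoms_b: Sequence[AtomRecord] | None = None,
) -> list[HydrogenBond]:
    """Polar heavy-atom pairs (N/O/S) between two selections under a cutoff.

    Accepts either (model, selection_a, selection_b) with selection strings,
    or two explicit atom lists.  Pairs within the same residue and
    water-water pairs are excluded; the result is deduplicated and sorted by
    distance.  Overlapping selections are an error.
    """
    if isinstance(model_or_atoms_a, StructureModel):
        if group_a is None or group_b is None:
            raise ValueError("selections group_a and group_b are required with a model")
        sel_a = model_or_atoms_a.select(group_a, include_waters=include_waters)
        sel_b = model_or_atoms_a.select(group_b, include_waters=include_waters)
    else:
        sel_a = list(model_or_atoms_a)
        sel_b = list(atoms_b if atoms_b is not None else [])
    keys_a = {_atom_key(a) for a in sel_a}
    if any(_atom_key(b) in keys_a for b in sel_b):
        raise ValueError("selections overlap; hydrogen-bond groups must be disjoint")

    polar_a = [a for a in sel_a if a.element.upper() in POLAR_ELEMENTS]
    polar_b = [b for b in sel_b if b.element.upper() in POLAR_ELEMENTS]
    if not polar_a or not polar_b:
        return []
    dist = _pair_distances(polar_a, polar_b)
    bonds: dict[tuple, HydrogenBond] = {}
    for i, j in zip(*np.nonzero(dist < cutoff)):
        a, b = polar_a[i], polar_b[j]
        if _res_key(a) == _res_key(b):
            continue
        if a.is_water and b.is_water:
            continue
        pair_key = tuple(sorted((_atom_key(a), _atom_key(b))))
        if pair_key in bonds:
            continue
        scope = "interchain" if a.chain_id != b.chain_id else "intrachain"
        bonds[pair_key] = HydrogenBond(
            donor_side=a, acceptor_side=b, distance=float(dist[i, j]), scope=scope
        )
    return sorted(bonds.values(), key=lambda hb: hb.distance)


def interface_report(
    model: StructureModel,
    group_a: Iterable[str],
    group_b: Iterable[str],
    contact_cutoff: float = 4.5,
    hbond_cutoff: float = 3.5,
    include_waters: bool = False,
) -> InterfaceReport:
    """Contacts, hydrogen bonds and the hydrophobic cluster between chain groups.

    The hydrophobic cluster is the largest connected component of the
    residue-level contact graph restricted to nonpolar/aromatic side chains
    that spans both groups.
    """
    chains_a = list(group_a)
    chains_b = list(group_b)
    if not chains_a or not chains_b:
        raise ValueError("both chain groups must be non-empty")
    if set(chains_a) & set(chains_b):
        raise ValueError("chain groups must be disjoint")

    atoms_a = [a for c in chains_a for a in model.select(c, include_waters=include_waters)]
    atoms_b = [a for c in chains_b for a in model.select(c, include_waters=include_waters)]
    heavy_a = [a for a in atoms_a if a.element.upper() != "H"]
    heavy_b = [a for a in atoms_b if a.element.upper() != "H"]
    contacts = []
    if heavy_a and heavy_b:
        dist = _pair_distances(heavy_a, heavy_b)
        for i, j in zip(*np.nonzero(dist < contact_cutoff)):
            contacts.append((heavy_a[i], heavy_b[j], float(dist[i, j])))
    contacts.sort(key=lambda c: c[2])

    hbonds: list[HydrogenBond] = []
    seen: set = set()
    for ca in chains_a:
        for cb in chains_b:
            for hb in find_hbonds(model, ca, cb, cutoff=hbond_cutoff,
                                  include_waters=include_waters):
                key = tuple(sorted((_atom_key(hb.donor_side), _atom_key(hb.acceptor_side))))
                if key not in seen:
                    seen.add(key)
                    hbonds.append(hb)
    hbonds.sort(key=lambda hb: hb.distance)

    cluster = _hydrophobic_cluster(contacts, set(chains_a), set(chains_b))
    return InterfaceReport(
        contacts=tuple(contacts),
        hydrogen_bonds=tuple(hbonds),
        hydrophobic_cluster=tuple(cluster),
    )


def _hydrophobic_cluster(
    contacts: Sequence[tuple], chains_a: set, chains_b: set
) -> list[str]:
    # residue-level contact graph over hydrophobic residues only
    edges: set[tuple] = set()
    nodes: set[tuple] = set()
    for a, b, _d in contacts:
        if a.res_name.upper() in HYDROPHOBIC_RESIDUES and b.res_name.upper() in HYDROPHOBIC_RESIDUES:
            ka, kb = _res_key(a), _res_key(b)
            nodes.update((ka, kb))
            edges.add(tuple(sorted((ka, kb))))
    if not nodes:
        return []
    adj: dict[tuple, set] = {n: set() for n in nodes}
    for x, y in edges:
        adj[x].add(y)
        adj[y].add(x)
    best: list[tuple] = []
    unvisited = set(nodes)
    while unvisited:
        start = unvisited.pop()
        comp = {start}
        stack = [start]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in comp:
                    comp.add(nb)
                    stack.append(nb)
        unvisited -= comp
        spans = any(k[0] in chains_a for k in comp) and any(k[0] in chains_b for k in comp)
        if spans and len(comp) > len(best):
            best = sorted(comp)
    res_names = {}
    for a, b, _d in contacts:
        res_names[_res_key(a)] = a.res_name
        res_names[_res_key(b)] = b.res_name
    return [
        f"{res_names[k].capitalize()}{k[1]}{k[2].lower()}_{k[0]}" for k in best
    ]


# ---------------------------------------------------------------------------
# superposition

def kabsch_rmsd(coords_a, coords_b) -> float:
    """Cα (or any point-set) RMSD after optimal proper rigid superposition.

    Correspondence is by order.  The rotation is constrained to det = +1
    (no reflection).  Degenerate inputs (< 3 points, or collinear point sets
    with no unique superposition) raise ValueError.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"point sets must both be (n, 3); got {a.shape} and {b.shape}")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for superposition")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    # collinearity check: second singular value of either centered set ~ 0
    for pts, name in ((ac, "first"), (bc, "second")):
        sv = np.linalg.svd(pts, compute_uv=False)
        if sv[1] < 1e-9 * max(sv[0], 1.0):
            raise ValueError(f"{name} point set is (nearly) collinear; superposition is degenerate")
    # covariance H = sum_i bc_i ac_i^T; optimal R = V diag(1,1,d) U^T
    h = bc.T @ ac
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = ac - bc @ rot.T
    return float(np.sqrt((diff**2).sum() / n))


# ---------------------------------------------------------------------------
# swap detection

def _median3(x: np.ndarray) -> np.ndarray:
    if x.size < 3:
        return x.copy()
    out = x.copy()
    out[1:-1] = np.median(np.column_stack([x[:-2], x[1:-1], x[2:]]), axis=1)
    return out


def detect_swap(
    dimer: StructureModel,
    chain_pair: tuple[str, str] | None = None,
    contact_cutoff: float = 4.5,
    min_run: int = 5,
    fraction_threshold: float = 0.5,
    low_threshold: float = 0.25,
) -> SwapReport:
    """Detect an exchanged terminal segment from interchain contact fractions.

    For every residue, the contact fraction is (interchain heavy-atom
    contacts) / (all non-local heavy-atom contacts), where non-local excludes
    sequence neighbors within ±2.  After 3-residue median smoothing, the
    swapped segment is the longest contiguous run of >= ``min_run`` residues
    with fraction > ``fraction_threshold`` that reaches a chain terminus
    (within 2 residues).  The hinge is the stretch between that segment and
    the nearest preceding run of low-fraction (< ``low_threshold``) residues.

    Finding no segment is a valid result (empty swap fields), not an error.
    """
    if chain_pair is None:
        ids = dimer.protein_chain_ids()
        if len(ids) != 2:
            raise ValueError(
                f"chain_pair is required unless the model has exactly two protein chains (have {ids})"
            )
        chain_pair = (ids[0], ids[1])
    ca, cb = chain_pair
    if ca == cb:
        raise ValueError("swap detection needs two distinct chains")

    residues = {c: dimer.residues(c, include_waters=False) for c in (ca, cb)}
    coords = {}
    res_index = {}
    for c in (ca, cb):
        for idx, r in enumerate(residues[c]):
            res_index[(c, r.res_seq, r.icode)] = idx
        atoms = [a for r in residues[c] for a in r.atoms if a.element.upper() != "H"]
        coords[c] = atoms

    # all heavy-atom interchain and intrachain distances
    profiles: dict[str, list] = {}
    swapped: dict[str, tuple | None] = {}
    hinges: dict[str, tuple | None] = {}
    for this, other in ((ca, cb), (cb, ca)):
        own_atoms = coords[this]
        other_atoms = coords[other]
        inter_counts = np.zeros(len(residues[this]), dtype=float)
        intra_counts = np.zeros(len(residues[this]), dtype=float)
        if own_atoms and other_atoms:
            d_inter = _pair_distances(own_atoms, other_atoms)
            for i, j in zip(*np.nonzero(d_inter < contact_cutoff)):
                inter_counts[res_index[_res_key(own_atoms[i])]] += 1
        if own_atoms:
            d_intra = _pair_distances(own_atoms, own_atoms)
            for i, j in zip(*np.nonzero(d_intra < contact_cutoff)):
                if i >= j:
                    continue
                ri = res_index[_res_key(own_atoms[i])]
                rj = res_index[_res_key(own_atoms[j])]
                if abs(ri - rj) <= 2:  # local in sequence, including same residue
                    continue
                intra_counts[ri] += 1
                intra_counts[rj] += 1
        denom = inter_counts + intra_counts
        frac = np.where(denom > 0, inter_counts / np.maximum(denom, 1), 0.0)
        smooth = _median3(frac)
        ids = [r.res_id for r in residues[this]]
        profiles[this] = list(zip(ids, smooth.tolist()))

        seg = _terminal_run(smooth, fraction_threshold, min_run)
        if seg is None:
            swapped[this] = None
            hinges[this] = None
        else:
            i0, i1 = seg
            swapped[this] = (ids[i0], ids[i1])
            hinges[this] = _hinge(smooth, seg, low_threshold, ids)
    return SwapReport(
        chain_pair=(ca, cb),
        swapped_segments=swapped,
        hinge_segments=hinges,
        profiles=profiles,
    )


def _terminal_run(frac: np.ndarray, threshold: float, min_run: int) -> tuple[int, int] | None:
    n = frac.size
    runs = []
    start = None
    for i in range(n + 1):
        if i < n and frac[i] > threshold:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i - 1))
            start = None
    terminal = [
        (s, e) for s, e in runs if (e - s + 1) >= min_run and (s <= 2 or e >= n - 3)
    ]
    if not terminal:
        return None
    return max(terminal, key=lambda r: r[1] - r[0])


def _hinge(
    frac: np.ndarray, segment: tuple[int, int], low_threshold: float, ids: list[str]
) -> tuple[str, str] | None:
    s, e = segment
    n = frac.size
    at_c_terminus = e >= n - 3
    if at_c_terminus:
        # walk back from the segment start to the nearest low-fraction residue
        j = s - 1
        while j >= 0 and frac[j] >= low_threshold:
            j -= 1
        if j + 1 <= s - 1:
            return (ids[j + 1], ids[s - 1])
        return None
    j = e + 1
    while j < n and frac[j] >= low_threshold:
        j += 1
    if e + 1 <= j - 1:
        return (ids[e + 1], ids[j - 1])
    return None


# ---------------------------------------------------------------------------
# framework RMSD and free-energy bookkeeping

def framework_rmsd(
    protomer: StructureModel,
    protomer_chain: str,
    reference: StructureModel,
    reference_chain: str,
    regions: dict[str, tuple[str, str]] | None = None,
) -> dict:
    """Cα RMSD for the pre-hinge framework (FR1+FR2+FR3) and post-hinge FR4.

    Residues present in only one structure are listed under ``missing``, not
    silently dropped; RMSD uses the common residues of each group.
    """
    regions = regions or KABAT_FRAMEWORK_REGIONS
    groups = {
        "FR1+FR2+FR3": [k for k in regions if k != "FR4"],
        "FR4": [k for k in regions if k == "FR4"],
    }
    out: dict = {"rmsd": {}, "missing": {}}
    for group_name, keys in groups.items():
        if not keys:
            continue
        pa, pb, missing = [], [], []
        for key in keys:
            first, last = regions[key]
            sel_p = {
                (a.res_seq, a.icode): a
                for a in protomer.select(f"{protomer_chain}:{first}-{last}")
                if a.atom_name == "CA"
            }
            sel_r = {
                (a.res_seq, a.icode): a
                for a in reference.select(f"{reference_chain}:{first}-{last}")
                if a.atom_name == "CA"
            }
            common = sorted(set(sel_p) & set(sel_r))
            missing += [
                f"{key}:{num}{ic.lower()}" for num, ic in sorted(set(sel_p) ^ set(sel_r))
            ]
            pa += [sel_p[k].xyz for k in common]
            pb += [sel_r[k].xyz for k in common]
        out["missing"][group_name] = missing
        out["rmsd"][group_name] = kabsch_rmsd(pa, pb) if len(pa) >= 3 else float("nan")
    return out


def assembly_free_energy(g_complex: float, g_components: Sequence[float]) -> float:
    """Free energy of assembly: G(complex) - Σ G(components), same units in/out."""
    vals = [g_complex, *g_components]
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("free energies must be finite")
    return g_complex - sum(g_components)
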