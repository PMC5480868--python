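"""Body-bar constraint networks from RNA structures.

Each heavy atom is one body with six degrees of freedom; bonded hydrogens
are absorbed into their parent body. Interactions contribute bars:

========================  ====  =============================================
provenance                bars  source
========================  ====  =============================================
COVALENT_ROTATABLE           5  freely rotating single bonds
COVALENT_LOCKED              6  bonds with hindered rotation (nucleobase
                                rings and their conjugated substituents)
HBOND                        5  hydrogen bonds / salt bridges passing the
                                energy cutoff E_cut
HYDROPHOBIC                  2  C/S contacts inside the vdW threshold
MG_COORD                     5  Mg2+ to first-shell water or to RNA
LIGAND                       6  pairwise bars standing in for a bound ligand
========================  ====  =============================================

Hydrogen bonds are scored with a Mayo-style 12-10 distance term (optimum
donor-acceptor separation 2.8 A, well depth 8 kcal/mol) modulated by the
squared cosine of the donor-hydrogen-acceptor angle; only bonds at or below
``e_cut`` (default -0.6 kcal/mol) contribute bars. Salt-bridge-tagged pairs
get a fixed strong energy so they survive any attractive cutoff. Waters are
kept only inside the first shell (<= 3.5 A) of an Mg2+ ion; Mg-water and
Mg-RNA contacts are covalent-strength bars while shell-water-RNA contacts
enter as hydrogen bonds.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from . import chem
from .model import Structure

PROVENANCES = ("COVALENT_ROTATABLE", "COVALENT_LOCKED", "HBOND",
               "HYDROPHOBIC", "MG_COORD", "LIGAND")

SALT_BRIDGE_ENERGY = -10.0
MAYO_WELL_DEPTH = 8.0       # kcal/mol
MAYO_R0 = 2.8               # A, donor-acceptor optimum
MG_SHELL_CUTOFF = 3.5       # A
SHELL_WATER_HBOND_ENERGY = -3.0


@dataclass(frozen=True)
class HBond:
    donor: int              # atom index of donor heavy atom
    hydrogen: int | None    # atom index, None if geometry-placed on the fly
    acceptor: int           # atom index
    distance_DA: float
    angle_DHA: float
    energy: float
    salt_bridge: bool = False

    def __post_init__(self):
        if not (self.distance_DA > 0 and 0 <= self.angle_DHA <= 180):
            raise ValueError("invalid hydrogen-bond geometry")


@dataclass(frozen=True)
class Bar:
    i: int
    j: int
    multiplicity: int
    provenance: str
    energy: float = 0.0

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("self-edges are not allowed")
        if not 1 <= self.multiplicity <= 6:
            raise ValueError("bar multiplicity must be in 1..6")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def key(self):
        i, j = (self.i, self.j) if self.i < self.j else (self.j, self.i)
        return (i, j, self.provenance, self.multiplicity,
                round(self.energy, 6))


@dataclass
class ConstraintNetwork:
    """Bodies plus multi-bars; the object the pebble game consumes."""

    n_bodies: int
    bars: list[Bar]
    e_cut: float | None = None
    #: per body: (nucleotide_id or None, atom name) - used to locate base
    #: reporter atoms without going back to the structure
    body_labels: list[tuple[int | None, str]] = field(default_factory=list)
    #: atom index -> body (hydrogens map to their parent heavy atom)
    body_of_atom: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        for b in self.bars:
            if not (0 <= b.i < self.n_bodies and 0 <= b.j < self.n_bodies):
                raise ValueError("bar endpoint outside body range")

    def sorted_bars(self) -> list[Bar]:
        return sorted(self.bars, key=lambda b: b.key())

    def total_bar_count(self) -> int:
        return sum(b.multiplicity for b in self.bars)

    def body_for(self, nucleotide_id: int, atom_name: str) -> int:
        for idx, (nid, name) in enumerate(self.body_labels):
            if nid == nucleotide_id and name == atom_name:
                return idx
        raise KeyError(f"no body for nucleotide {nucleotide_id} "
                       f"atom {atom_name!r}")

    def with_bars(self, bars: list[Bar]) -> "ConstraintNetwork":
        return ConstraintNetwork(self.n_bodies, list(bars), self.e_cut,
                                 list(self.body_labels),
                                 dict(self.body_of_atom))

    def bar_key_set(self) -> frozenset:
        return frozenset(b.key() for b in self.bars)

    # -- plain-text serialisation (FIRST-dataset style) ---------------------

    def to_text(self, target=None) -> str | None:
        out = io.StringIO()
        out.write(f"# riborigid constraint network; e_cut={self.e_cut}\n")
        out.write(f"# bodies {self.n_bodies}\n")
        for idx in range(self.n_bodies):
            nid, name = (self.body_labels[idx] if self.body_labels
                         else (None, f"B{idx}"))
            out.write(f"BODY {idx} {nid if nid is not None else '-'} {name}\n")
        for b in self.sorted_bars():
            out.write(f"BAR {b.i} {b.j} {b.multiplicity} {b.provenance} "
                      f"{b.energy:.9g}\n")
        text = out.getvalue()
        if target is None:
            return text
        if hasattr(target, "write"):
            target.write(text)
        else:
            with open(target, "w") as fh:
                fh.write(text)
        return None

    @classmethod
    def from_text(cls, source) -> "ConstraintNetwork":
        if hasattr(source, "read"):
            text = source.read()
        elif "\n" in str(source):
            text = str(source)
        else:
            with open(source) as fh:
                text = fh.read()
        e_cut = None
        labels: list[tuple[int | None, str]] = []
        bars: list[Bar] = []
        for line in text.splitlines():
            line = line.strip()
            if line.startswith("#"):
                if "e_cut=" in line:
                    val = line.split("e_cut=")[1].strip()
                    e_cut = None if val == "None" else float(val)
                continue
            if line.startswith("BODY"):
                _, idx, nid, name = line.split()
                labels.append((None if nid == "-" else int(nid), name))
            elif line.startswith("BAR"):
                _, i, j, m, prov, en = line.split()
                bars.append(Bar(int(i), int(j), int(m), prov, float(en)))
        return cls(len(labels), bars, e_cut, labels)


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def hbond_energy(distance_DA: float, angle_DHA: float,
                 donor_sp2: bool = True, acceptor_sp2: bool = True,
                 salt_bridge: bool = False) -> float:
    """Mayo-style hydrogen-bond energy (kcal/mol).

    E = V0 * [5 (R0/R)^12 - 6 (R0/R)^10] * F(theta) with V0 = 8 kcal/mol and
    R0 = 2.8 A between donor and acceptor heavy atoms. The angular weight is
    cos^2 of the D-H...A angle (1 at 180 deg), squared once more when both
    partners are sp3 to penalise bent sp3-sp3 geometries harder. Salt
    bridges return a fixed strong value so they pass any attractive cutoff.
    """
    if salt_bridge:
        return SALT_BRIDGE_ENERGY
    r = max(float(distance_DA), 2.0)   # clamp: keep energy finite
    ratio = MAYO_R0 / r
    radial = MAYO_WELL_DEPTH * (5.0 * ratio ** 12 - 6.0 * ratio ** 10)
    if angle_DHA <= 90.0:
        return 0.0
    f = math.cos(math.radians(180.0 - angle_DHA)) ** 2
    if not (donor_sp2 or acceptor_sp2):
        f = f * f
    return radial * f


def place_polar_hydrogens(structure: Structure) -> Structure:
    """Return a structure with template-ideal hydrogens on polar donors.

    Crystal structures carry no hydrogens; donors' H positions are
    constructed from the local heavy-atom geometry (in-plane for ring and
    amino nitrogens, anti to the bonded neighbour for hydroxyls). Existing
    hydrogens are kept. Placement is logged via a warning so a reader knows
    the geometry is idealised.
    """
    from .model import Atom, Nucleotide

    neigh: dict[int, list[int]] = {}
    for i, j in structure.bonds:
        neigh.setdefault(i, []).append(j)
        neigh.setdefault(j, []).append(i)

    new_atoms = list(structure.atoms)
    new_coords = [c for c in structure.coords]
    new_bonds = list(structure.bonds)
    placed = 0
    serial = max((a.serial for a in structure.atoms), default=0)
    for nuc in structure.nucleotides:
        donors = chem.donors_of(nuc.base)
        for dname, hnames in donors.items():
            if not structure.has_atom(nuc.nucleotide_id, dname):
                continue
            di = structure.atom_index(nuc.nucleotide_id, dname)
            present = [h for h in hnames
                       if structure.has_atom(nuc.nucleotide_id, h)]
            missing = [h for h in hnames if h not in present]
            if not missing:
                continue
            heavies = [n for n in neigh.get(di, [])
                       if structure.atoms[n].element != "H"]
            if not heavies:
                continue
            positions = _ideal_h_positions(
                structure, di, heavies, len(hnames), neigh)
            for h, pos in zip(missing, positions[len(present):]):
                serial += 1
                da = structure.atoms[di]
                new_atoms.append(Atom(serial, h, "H", da.nucleotide_id,
                                      chem.ATOMIC_MASS["H"], "RNA",
                                      da.resname, da.residue_key))
                new_coords.append(pos)
                new_bonds.append((di, len(new_atoms) - 1))
                placed += 1
    if placed:
        warnings.warn(f"placed {placed} polar hydrogens by ideal geometry",
                      stacklevel=2)
    return Structure(new_atoms, np.array(new_coords), structure.nucleotides,
                     new_bonds)


def _ideal_h_positions(structure, di, heavies, n_h, neigh):
    d = structure.coords[di]
    if len(heavies) >= 2:
        # ring N-H: bisector, in plane
        u = sum((d - structure.coords[n]) /
                np.linalg.norm(d - structure.coords[n]) for n in heavies)
        u = u / np.linalg.norm(u)
        return [d + 1.01 * u]
    c = structure.coords[heavies[0]]
    v = d - c
    v = v / np.linalg.norm(v)
    if n_h == 1:
        return [d + 0.97 * v]
    # amino group: two H in the plane of the parent sp2 carbon, +-60 deg
    others = [n for n in neigh.get(heavies[0], [])
              if n != di and structure.atoms[n].element != "H"]
    if others:
        w = structure.coords[others[0]] - c
        normal = np.cross(v, w)
        nn = np.linalg.norm(normal)
        normal = normal / nn if nn > 1e-9 else np.array([0.0, 0.0, 1.0])
    else:
        normal = np.array([0.0, 0.0, 1.0])
    out = []
    for sign in (1.0, -1.0):
        ang = math.radians(sign * 60.0)
        rot = (v * math.cos(ang)
               + np.cross(normal, v) * math.sin(ang))
        out.append(d + 1.01 * rot)
    return out


def detect_hbonds(structure: Structure, max_distance: float = 3.5,
                  min_angle: float = 120.0,
                  place_hydrogens: bool = True,
                  salt_bridge_pairs: set[tuple[int, int]] | None = None
                  ) -> list[HBond]:
    """Geometric hydrogen-bond detection.

    A bond requires donor-acceptor distance <= ``max_distance`` (default
    3.5 A) and D-H...A angle >= ``min_angle`` (default 120 deg). Donors
    without hydrogens are skipped with a warning unless ``place_hydrogens``
    is set, in which case ideal-geometry hydrogens are constructed first.
    The returned list is sorted by (donor, acceptor).
    """
    work = structure
    if place_hydrogens:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            work = place_polar_hydrogens(structure)

    neigh: dict[int, set[int]] = {}
    for i, j in work.bonds:
        neigh.setdefault(i, set()).add(j)
        neigh.setdefault(j, set()).add(i)

    donors: list[tuple[int, list[int]]] = []   # heavy donor, its hydrogens
    acceptors: list[int] = []
    for nuc in work.nucleotides:
        for dname, hnames in chem.donors_of(nuc.base).items():
            if not work.has_atom(nuc.nucleotide_id, dname):
                continue
            di = work.atom_index(nuc.nucleotide_id, dname)
            hs = [work.atom_index(nuc.nucleotide_id, h) for h in hnames
                  if work.has_atom(nuc.nucleotide_id, h)]
            if not hs:
                warnings.warn(
                    f"donor {dname} of nucleotide {nuc.nucleotide_id} has "
                    "no hydrogen; skipped", stacklevel=2)
                continue
            donors.append((di, hs))
        for aname in chem.acceptors_of(nuc.base):
            if work.has_atom(nuc.nucleotide_id, aname):
                acceptors.append(work.atom_index(nuc.nucleotide_id, aname))
    # waters can both donate and accept
    for i, a in enumerate(work.atoms):
        if a.category == "WATER" and a.element == "O":
            hs = [n for n in neigh.get(i, ())
                  if work.atoms[n].element == "H"]
            if hs:
                donors.append((i, hs))
            acceptors.append(i)

    if not donors or not acceptors:
        return []
    tree = cKDTree(work.coords[acceptors])
    sb = salt_bridge_pairs or set()
    found: list[HBond] = []
    for di, hs in donors:
        for k in tree.query_ball_point(work.coords[di], max_distance):
            ai = acceptors[k]
            if ai == di or ai in neigh.get(di, ()):
                continue
            if neigh.get(di, set()) & neigh.get(ai, set()):
                continue   # 1-3 neighbours
            dist = float(np.linalg.norm(work.coords[di] - work.coords[ai]))
            best = None
            for hi in hs:
                u = work.coords[di] - work.coords[hi]
                v = work.coords[ai] - work.coords[hi]
                cosang = np.dot(u, v) / (np.linalg.norm(u)
                                         * np.linalg.norm(v))
                ang = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
                if best is None or ang > best[0]:
                    best = (ang, hi)
            ang, hi = best
            if ang < min_angle:
                continue
            is_sb = (min(di, ai), max(di, ai)) in sb
            dname = work.atoms[di].name
            aname = work.atoms[ai].name
            energy = hbond_energy(dist, ang,
                                  donor_sp2=dname in chem.SP2_ATOMS,
                                  acceptor_sp2=aname in chem.SP2_ATOMS,
                                  salt_bridge=is_sb)
            hi_orig = hi if hi < structure.n_atoms else None
            found.append(HBond(di, hi_orig, ai, dist, ang, energy, is_sb))
    found.sort(key=lambda h: (h.donor, h.acceptor))
    return found


# ---------------------------------------------------------------------------
# Hydrophobic tethers
# ---------------------------------------------------------------------------

def detect_hydrophobics(structure: Structure,
                        gap_threshold: float = 0.25) -> list[tuple[int, int]]:
    """Carbon/sulfur pairs whose surface separation is within the threshold.

    Surface separation = centre distance minus the summed van der Waals
    radii. Covalently bonded and 1-3 pairs are excluded; the list is sorted.
    """
    neigh: dict[int, set[int]] = {}
    for i, j in structure.bonds:
        neigh.setdefault(i, set()).add(j)
        neigh.setdefault(j, set()).add(i)
    cands = [i for i, a in enumerate(structure.atoms)
             if a.element in ("C", "S") and a.category == "RNA"]
    if not cands:
        return []
    tree = cKDTree(structure.coords[cands])
    rmax = max(chem.VDW_RADIUS["C"], chem.VDW_RADIUS["S"])
    pairs = tree.query_pairs(2 * rmax + gap_threshold)
    out = []
    for a, b in pairs:
        i, j = cands[a], cands[b]
        if j in neigh.get(i, ()) or (neigh.get(i, set()) & neigh.get(j, set())):
            continue
        d = float(np.linalg.norm(structure.coords[i] - structure.coords[j]))
        gap = d - (chem.VDW_RADIUS[structure.atoms[i].element]
                   + chem.VDW_RADIUS[structure.atoms[j].element])
        if gap <= gap_threshold:
            out.append((min(i, j), max(i, j)))
    return sorted(out)


# ---------------------------------------------------------------------------
# Network assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkConfig:
    e_cut: float = -0.6
    hbond_distance: float = 3.5
    hbond_angle: float = 120.0
    hydrophobic_gap: float = 0.25
    mult_rotatable: int = 5
    mult_locked: int = 6
    mult_hbond: int = 5
    mult_hydrophobic: int = 2
    mult_mg: int = 5
    mult_ligand: int = 6


def build_network(structure: Structure, e_cut: float = -0.6,
                  include_mg: bool = True,
                  hbonds: list[HBond] | None = None,
                  hydrophobics: list[tuple[int, int]] | None = None,
                  config: NetworkConfig | None = None) -> ConstraintNetwork:
    """Assemble the body-bar constraint network of one structure.

    Only hydrogen bonds with energy <= ``e_cut`` contribute bars; waters
    outside any Mg2+ first shell are discarded; Mg-water and Mg-RNA
    contacts within 3.5 A become covalent-strength bars.
    """
    if e_cut >= 0:
        raise ValueError("e_cut must be negative (attractive)")
    cfg = config or NetworkConfig()
    if hbonds is None:
        hbonds = detect_hbonds(structure, cfg.hbond_distance, cfg.hbond_angle)
    if hydrophobics is None:
        hydrophobics = detect_hydrophobics(structure, cfg.hydrophobic_gap)

    mg_idx = [i for i, a in enumerate(structure.atoms) if a.category == "MG"]
    water_o = [i for i, a in enumerate(structure.atoms)
               if a.category == "WATER" and a.element == "O"]
    shell_waters: set[int] = set()
    if include_mg and mg_idx and water_o:
        wtree = cKDTree(structure.coords[water_o])
        for mi in mg_idx:
            for k in wtree.query_ball_point(structure.coords[mi],
                                            MG_SHELL_CUTOFF):
                shell_waters.add(water_o[k])

    neigh: dict[int, set[int]] = {}
    for i, j in structure.bonds:
        neigh.setdefault(i, set()).add(j)
        neigh.setdefault(j, set()).add(i)

    def retained(i: int) -> bool:
        a = structure.atoms[i]
        if a.element == "H":
            return False
        if a.category == "RNA" or a.category == "OTHER":
            return True
        if a.category == "MG":
            return include_mg
        if a.category == "WATER":
            o = i if a.element == "O" else next(
                (n for n in neigh.get(i, ()) if
                 structure.atoms[n].element == "O"), None)
            return include_mg and o in shell_waters
        return False

    body_of_atom: dict[int, int] = {}
    body_labels: list[tuple[int | None, str]] = []
    for i, a in enumerate(structure.atoms):
        if a.element == "H":
            continue
        if retained(i):
            body_of_atom[i] = len(body_labels)
            body_labels.append((a.nucleotide_id, a.name))
    # hydrogens absorb into their bonded heavy atom
    for i, a in enumerate(structure.atoms):
        if a.element != "H":
            continue
        parent = next((n for n in neigh.get(i, ())
                       if structure.atoms[n].element != "H"), None)
        if parent is not None and parent in body_of_atom:
            body_of_atom[i] = body_of_atom[parent]

    bars: dict[tuple, Bar] = {}

    def add(i, j, mult, prov, energy=0.0):
        bi, bj = body_of_atom.get(i), body_of_atom.get(j)
        if bi is None or bj is None or bi == bj:
            return
        bar = Bar(min(bi, bj), max(bi, bj), mult, prov, energy)
        bars.setdefault(bar.key(), bar)

    base_by_nid = {n.nucleotide_id: n.base for n in structure.nucleotides}
    for i, j in structure.bonds:
        ai, aj = structure.atoms[i], structure.atoms[j]
        if ai.element == "H" or aj.element == "H":
            continue
        locked = False
        if ai.category == "RNA" and ai.nucleotide_id == aj.nucleotide_id:
            base = base_by_nid.get(ai.nucleotide_id)
            if base is not None:
                locked = chem.is_locked_bond(base, ai.name, aj.name)
        add(i, j, cfg.mult_locked if locked else cfg.mult_rotatable,
            "COVALENT_LOCKED" if locked else "COVALENT_ROTATABLE")

    for hb in hbonds:
        if hb.energy <= e_cut or hb.salt_bridge:
            add(hb.donor, hb.acceptor, cfg.mult_hbond, "HBOND", hb.energy)

    for i, j in hydrophobics:
        add(i, j, cfg.mult_hydrophobic, "HYDROPHOBIC")

    if include_mg and mg_idx:
        rna_polar = [i for i, a in enumerate(structure.atoms)
                     if a.category == "RNA" and a.element in ("O", "N")]
        ptree = cKDTree(structure.coords[rna_polar]) if rna_polar else None
        for mi in mg_idx:
            for wo in shell_waters:
                d = np.linalg.norm(structure.coords[mi]
                                   - structure.coords[wo])
                if d <= MG_SHELL_CUTOFF:
                    add(mi, wo, cfg.mult_mg, "MG_COORD")
            if ptree is not None:
                for k in ptree.query_ball_point(structure.coords[mi],
                                                MG_SHELL_CUTOFF):
                    add(mi, rna_polar[k], cfg.mult_mg, "MG_COORD")
        # first-shell water to RNA: hydrogen bonds; crystal waters carry no
        # hydrogens, so a distance criterion stands in with a strong energy
        covered = {(min(h.donor, h.acceptor), max(h.donor, h.acceptor))
                   for h in hbonds}
        if ptree is not None:
            for wo in shell_waters:
                for k in ptree.query_ball_point(structure.coords[wo],
                                                MG_SHELL_CUTOFF):
                    ri = rna_polar[k]
                    pair = (min(wo, ri), max(wo, ri))
                    if pair in covered:
                        continue
                    add(wo, ri, cfg.mult_hbond, "HBOND",
                        SHELL_WATER_HBOND_ENERGY)

    return ConstraintNetwork(len(body_labels),
                             sorted(bars.values(), key=lambda b: b.key()),
                             e_cut, body_labels, body_of_atom)


def add_ligand_constraints(net: ConstraintNetwork,
                           binding: set[int] = frozenset({47, 51, 74}),
                           config: NetworkConfig | None = None
                           ) -> ConstraintNetwork:
    """Model a bound ligand by pairwise bars between the binding nucleobases.

    Six bars are placed between the base N1 bodies of each pair of binding
    nucleotides, enough to rigidify each (internally rigid) nucleobase pair
    mutually, so the three nucleobases end up in one rigid cluster. The
    input network is not modified; applying twice is idempotent.
    """
    cfg = config or NetworkConfig()
    ids = sorted(binding)
    bodies = []
    for nid in ids:
        try:
            bodies.append(net.body_for(nid, "N1"))
        except KeyError:
            raise ValueError(f"binding nucleotide {nid} missing "
                             "from network") from None
    existing = net.bar_key_set()
    bars = list(net.bars)
    for a in range(len(bodies)):
        for b in range(a + 1, len(bodies)):
            bar = Bar(min(bodies[a], bodies[b]), max(bodies[a], bodies[b]),
                      cfg.mult_ligand, "LIGAND", SALT_BRIDGE_ENERGY)
            if bar.key() not in existing:
                bars.append(bar)
    return net.with_bars(bars)
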