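"""Synthetic inputs with analytically known answers.

Everything the analysis pipeline consumes can be generated here without
any external structure: fixture body-bar networks with known rigidity,
a miniature aptamer (coarse-grained network machine and a full-atom base
stand-in for the loop-loop quadruple), four-condition ensembles whose
largest-rigid-cluster probabilities and cooperativity are known in closed
form, and coordinate trajectories with prescribed fluctuation amplitudes,
two-state hydrogen-bond dynamics and hexahydrated ions.

All generators are seed-deterministic; none of them aims at physical
realism beyond the statistical structure the analyses assume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import chem
from .geom import kabsch
from .model import (Atom, Nucleotide, RegionMap, Structure, Ensemble,
                    assign_regions, default_region_table)
from .network import Bar, ConstraintNetwork


# ---------------------------------------------------------------------------
# Fixture networks with known rigidity
# ---------------------------------------------------------------------------

def _label_bodies(n: int) -> list[tuple[None, str]]:
    return [(None, f"B{i}") for i in range(n)]


def make_fixture_network(kind: str, n: int = 8,
                         seed: int | None = None) -> ConstraintNetwork:
    """Small deterministic networks with documented expected rigidity.

    ``braced_pair``: two bodies, six bars — rigid, no internal modes.
    ``hinge_pair``: two bodies, five bars — one internal mode.
    ``chain``: n bodies linked by 5-bar bonds — n-1 internal modes.
    ``ring``: n bodies in a 5-bar cycle — max(n-6, 0) internal modes.
    ``random``: n bodies (n <= 50), random multiplicities 1-6; its rigidity
    is whatever the rank oracle says.
    """
    if kind == "braced_pair":
        return ConstraintNetwork(2, [Bar(0, 1, 6, "COVALENT_LOCKED")],
                                 body_labels=_label_bodies(2))
    if kind == "hinge_pair":
        return ConstraintNetwork(2, [Bar(0, 1, 5, "COVALENT_ROTATABLE")],
                                 body_labels=_label_bodies(2))
    if kind == "chain":
        bars = [Bar(i, i + 1, 5, "COVALENT_ROTATABLE")
                for i in range(n - 1)]
        return ConstraintNetwork(n, bars, body_labels=_label_bodies(n))
    if kind == "ring":
        bars = [Bar(i, (i + 1) % n, 5, "COVALENT_ROTATABLE")
                for i in range(n)]
        return ConstraintNetwork(n, bars, body_labels=_label_bodies(n))
    if kind == "random":
        if n > 50:
            raise ValueError("random fixtures are limited to 50 bodies "
                             "(rank-oracle scale)")
        if seed is None:
            raise ValueError("random fixture needs a seed")
        rng = np.random.default_rng(seed)
        n_edges = max(int(rng.integers(n, 2 * n + 1)), 1)
        seen = set()
        bars = []
        for _ in range(n_edges):
            i, j = rng.integers(0, n, 2)
            if i == j:
                continue
            key = (min(int(i), int(j)), max(int(i), int(j)))
            if key in seen:
                continue
            seen.add(key)
            bars.append(Bar(key[0], key[1], int(rng.integers(1, 7)),
                            "COVALENT_ROTATABLE"))
        if not bars:
            bars = [Bar(0, 1, 1, "COVALENT_ROTATABLE")]
        return ConstraintNetwork(n, bars, body_labels=_label_bodies(n))
    raise ValueError(f"unknown fixture kind {kind!r}")


# ---------------------------------------------------------------------------
# Idealised nucleobase geometry (full-atom stand-ins)
# ---------------------------------------------------------------------------

_RING_BOND = 1.39
_H_BOND = 1.01
_CH_BOND = 1.08
_EXO_O = 1.23
_EXO_N = 1.35
_GLYCO = 1.47


def _hexagon(names):
    """Regular hexagon, side = ring bond length, counter-clockwise."""
    r = _RING_BOND
    pts = {}
    for k, name in enumerate(names):
        ang = math.radians(60.0 * k - 90.0)
        pts[name] = np.array([r * math.cos(ang), r * math.sin(ang), 0.0])
    return pts


def _radial(pts, center, name, dist):
    u = pts[name] - center
    u = u / np.linalg.norm(u)
    return pts[name] + dist * u


def _amino_hydrogens(n_pos, c_pos):
    v = n_pos - c_pos
    v = v / np.linalg.norm(v)
    out = []
    for sign in (1.0, -1.0):
        a = math.radians(sign * 60.0)
        rot = np.array([v[0] * math.cos(a) - v[1] * math.sin(a),
                        v[0] * math.sin(a) + v[1] * math.cos(a), 0.0])
        out.append(n_pos + _H_BOND * rot)
    return out


def base_geometry(base: str, with_sugar: bool = False
                  ) -> dict[str, np.ndarray]:
    """Planar idealised coordinates (local frame, z = 0) for one base.

    Synthetic geometry: ring bond lengths and substituent directions are
    idealised, not taken from any experimental structure. Good enough for
    the geometric hydrogen-bond criteria, which is all it is used for.
    """
    hexa = _hexagon(["N1", "C2", "N3", "C4", "C5", "C6"])
    center6 = np.mean([hexa[k] for k in hexa], axis=0)
    pts = dict(hexa)
    if base in chem.PURINES:
        c4, c5 = pts["C4"], pts["C5"]
        mid = 0.5 * (c4 + c5)
        out_dir = mid - center6
        out_dir = out_dir / np.linalg.norm(out_dir)
        side = 1.38
        rp = side / (2 * math.sin(math.pi / 5))
        center5 = mid + rp * math.cos(math.pi / 5) * out_dir
        ang4 = math.atan2(*(c4 - center5)[1::-1])
        ang5 = math.atan2(*(c5 - center5)[1::-1])
        # walk the pentagon from C5 away from C4: N7, C8, N9
        step = 2 * math.pi / 5
        direction = 1.0 if ((ang5 - ang4) % (2 * math.pi)) < math.pi else -1.0
        for k, name in enumerate(["N7", "C8", "N9"], start=1):
            a = ang5 + direction * step * k
            pts[name] = center5 + rp * np.array([math.cos(a), math.sin(a),
                                                 0.0])
        pts["C8H"] = None
        pts["H8"] = _radial(pts, center5, "C8", _CH_BOND)
        del pts["C8H"]
        pts["C1'"] = _radial(pts, center5, "N9", _GLYCO)
        if base == "A":
            pts["N6"] = _radial(pts, center6, "C6", _EXO_N)
            pts["H61"], pts["H62"] = _amino_hydrogens(pts["N6"], pts["C6"])
            pts["H2"] = _radial(pts, center6, "C2", _CH_BOND)
        else:  # G
            pts["O6"] = _radial(pts, center6, "C6", _EXO_O)
            pts["N2"] = _radial(pts, center6, "C2", _EXO_N)
            pts["H21"], pts["H22"] = _amino_hydrogens(pts["N2"], pts["C2"])
            pts["H1"] = _radial(pts, center6, "N1", _H_BOND)
    else:
        pts["C1'"] = _radial(pts, center6, "N1", _GLYCO)
        pts["O2"] = _radial(pts, center6, "C2", _EXO_O)
        if base == "C":
            pts["N4"] = _radial(pts, center6, "C4", _EXO_N)
            pts["H41"], pts["H42"] = _amino_hydrogens(pts["N4"], pts["C4"])
            pts["H5"] = _radial(pts, center6, "C5", _CH_BOND)
            pts["H6"] = _radial(pts, center6, "C6", _CH_BOND)
        else:  # U
            pts["O4"] = _radial(pts, center6, "C4", _EXO_O)
            pts["H3"] = _radial(pts, center6, "N3", _H_BOND)
            pts["H5"] = _radial(pts, center6, "C5", _CH_BOND)
            pts["H6"] = _radial(pts, center6, "C6", _CH_BOND)
    if with_sugar:
        # 2'-hydroxyl stub on the glycosidic carbon, toward the minor
        # groove side (O2 for pyrimidines, N3 for purines)
        anchor = pts["C1'"]
        radial = anchor - center6
        radial = radial / np.linalg.norm(radial)
        minor = pts["N3" if base in chem.PURINES else "O2"]
        perp = np.array([-radial[1], radial[0], 0.0])
        if np.dot(perp, minor - anchor) < 0:
            perp = -perp
        u = radial + 0.9 * perp
        u = u / np.linalg.norm(u)
        pts["O2'"] = anchor + 1.43 * u
        pts["HO2'"] = pts["O2'"] + 0.96 * u
    return pts


def _structure_from_bases(placed: dict[int, tuple[str, dict]],
                          serial_start: int = 1) -> Structure:
    """Assemble a base-only Structure from placed base geometries."""
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    nucleotides: list[Nucleotide] = []
    serial = serial_start
    for nid in sorted(placed):
        base, pts = placed[nid]
        nucleotides.append(Nucleotide(nid, base))
        for name in sorted(pts):
            el = "H" if name.startswith("H") else name[0]
            atoms.append(Atom(serial, name, el, nid,
                              chem.ATOMIC_MASS.get(el, 12.0), "RNA", base,
                              ("A", nid, base)))
            coords.append(np.asarray(pts[name], float))
            serial += 1
    # template bonds restricted to atoms actually present
    st = Structure(atoms, np.array(coords), nucleotides, [])
    bonds = []
    for nuc in nucleotides:
        for ni, nj in chem.template_bonds(nuc.base):
            if st.has_atom(nuc.nucleotide_id, ni) and \
                    st.has_atom(nuc.nucleotide_id, nj):
                bonds.append((st.atom_index(nuc.nucleotide_id, ni),
                              st.atom_index(nuc.nucleotide_id, nj)))
    return Structure(atoms, np.array(coords), nucleotides, sorted(bonds))


def _transform3d(pts: dict, rotvec: np.ndarray, tvec: np.ndarray,
                 mirror: bool = False) -> dict:
    from scipy.spatial.transform import Rotation
    R = Rotation.from_rotvec(rotvec).as_matrix()
    M = np.diag([1.0, -1.0, 1.0]) if mirror else np.eye(3)
    return {k: R @ (M @ v) + np.asarray(tvec, float)
            for k, v in pts.items()}


def _transform(pts: dict, theta: float, tx: float, ty: float,
               mirror: bool = False) -> dict:
    c, s = math.cos(theta), math.sin(theta)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    M = np.diag([1.0, -1.0, 1.0]) if mirror else np.eye(3)
    return {k: R @ (M @ v) + np.array([tx, ty, 0.0])
            for k, v in pts.items()}


#: designed hydrogen bonds of the wildtype upper quadruple stand-in:
#: a Watson-Crick 37:61 pair and a Hoogsteen-style 34:65 pair sitting on
#: the minor-groove side of the pair, tied together by the two guanine
#: N2-amino hydrogens (one into C61 O2, one into U34 O2) and by the A65
#: amino donating into C61 O2's second lone pair. Format: (donor
#: nucleotide, donor atom, hydrogen, acceptor nucleotide, acceptor).
#: Bond counts per nucleotide pair: 37-61: 3, 61-65: 1, 34-65: 2,
#: 34-37: 1 — seven in total, the four pairs the occupancy analysis of
#: the loop region tracks.
QUADRUPLE_BONDS_WT = [
    (37, "N1", "H1", 61, "N3"),
    (37, "N2", "H21", 61, "O2"),
    (61, "N4", "H41", 37, "O6"),
    (65, "N6", "H61", 61, "O2"),
    (34, "N3", "H3", 65, "N7"),
    (65, "N6", "H62", 34, "O4"),
    (37, "N2", "H22", 34, "O2"),
]

#: donor/acceptor pairs expected after the G37A/C61U transplant. The two
#: guanine N2-amino bonds disappear (adenine has no N2), so the 34:37
#: pairing is lost entirely; the remaining 37:61 bonds swap polarity
#: (U61 N3-H3 donates to A37 N1, A37 N6-H donates to U61 O4) but persist
#: geometrically. Hydrogen names are None where either amino hydrogen
#: may serve.
QUADRUPLE_BONDS_MUT = [
    (61, "N3", "H3", 37, "N1"),
    (37, "N6", None, 61, "O4"),
    (65, "N6", "H61", 61, "O2"),
    (34, "N3", "H3", 65, "N7"),
    (65, "N6", "H62", 34, "O4"),
]

_HB_LEN = 2.95


def _bond_cost(placed, bonds):
    """Smooth designed-bond cost: donor-acceptor distance pulled to
    2.95 A, best available D-H...A angle pulled toward linear."""
    c = 0.0
    for dn, da, h, an, aa in bonds:
        d = placed[dn][1][da]
        a = placed[an][1][aa]
        dist = np.linalg.norm(d - a)
        c += 4.0 * (dist - _HB_LEN) ** 2
        hs = [h] if h else [n for n in placed[dn][1]
                            if n.startswith("H") and n[1:].startswith(da[1:])]
        best = None
        for hn in hs:
            hh = placed[dn][1][hn]
            u = d - hh
            v = a - hh
            cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
            val = (1.0 + cosang) ** 2
            best = val if best is None else min(best, val)
        c += 2.0 * best
    return c


def _clash_cost(placed, designed, polar, threshold=3.4):
    """Penalty on undesigned cross-base polar contacts that the geometric
    hydrogen-bond criteria could pick up, plus a hard-core term."""
    c = 0.0
    ids = sorted(placed)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            ni, nj = ids[i], ids[j]
            for an in polar[ni]:
                for bn in polar[nj]:
                    pa = placed[ni][1][an]
                    pb = placed[nj][1][bn]
                    dist = np.linalg.norm(pa - pb)
                    if dist < 2.7:      # hard core for any polar pair
                        c += 8.0 * (2.7 - dist) ** 2
                    if (ni, an, nj, bn) in designed:
                        continue
                    if dist >= 4.0:
                        continue
                    # worst-case donor-hydrogen alignment on either side
                    align = 0.0
                    for (dn, dna, acc) in ((ni, an, pb), (nj, bn, pa)):
                        for hn in placed[dn][1]:
                            if not hn.startswith("H"):
                                continue
                            hp = placed[dn][1][hn]
                            dp = placed[dn][1][dna]
                            if np.linalg.norm(hp - dp) > 1.2:
                                continue
                            u = dp - hp
                            v = acc - hp
                            cosang = np.dot(u, v) / (
                                np.linalg.norm(u) * np.linalg.norm(v))
                            ang = math.degrees(math.acos(
                                max(-1.0, min(1.0, cosang))))
                            align = max(align, (ang - 105.0) / 75.0)
                    if align > 0:
                        c += 30.0 * ((4.0 - dist) * align) ** 2
    return c


def _fit_points(local: dict, anchors: list[tuple[str, np.ndarray]],
                tiebreak=None):
    """Best planar rigid placement (grid over mirror/rotation, analytic
    translation, Nelder-Mead refinement) putting named atoms on targets.
    ``tiebreak(pts)`` adds a small secondary score, used to pick between
    the two reflection-equivalent fits."""
    names = [a[0] for a in anchors]
    targets = np.array([a[1] for a in anchors])
    best = None
    for mirror in (False, True):
        for k in range(48):
            th = 2 * math.pi * k / 48
            pts = _transform(local, th, 0.0, 0.0, mirror)
            src = np.array([pts[n] for n in names])
            tr = targets.mean(axis=0) - src.mean(axis=0)

            def cost(x, mirror=mirror):
                p = _transform(local, x[0], x[1], x[2], mirror)
                return float(sum(np.sum((p[n] - t) ** 2)
                                 for n, t in zip(names, targets)))

            res = minimize(cost, np.array([th, tr[0], tr[1]]),
                           method="Nelder-Mead",
                           options={"maxiter": 1500, "xatol": 1e-7,
                                    "fatol": 1e-10})
            score = res.fun
            if tiebreak is not None:
                score += 0.05 * tiebreak(_transform(local, res.x[0],
                                                    res.x[1], res.x[2],
                                                    mirror))
            if best is None or score < best[0]:
                best = (score, res.x, mirror)
    _f, x, mirror = best
    return _transform(local, x[0], x[1], x[2], mirror)


def _refine_pair(fixed: dict, mobile_nid: int, mobile_base: str,
                 mobile_local: dict, bonds, seed_states):
    """Place one mobile base against fixed ones by minimising the designed
    bond cost plus the undesigned-contact penalty, trying seed states."""
    polar = {nid: [n for n in pts if n[0] in "NO"]
             for nid, (_b, pts) in fixed.items()}
    polar[mobile_nid] = [n for n in mobile_local if n[0] in "NO"]
    designed = set()
    for dn, da, _h, an, aa in bonds:
        designed.add((dn, da, an, aa))
        designed.add((an, aa, dn, da))

    def cost(x, mirror):
        pts = _transform(mobile_local, x[0], x[1], x[2], mirror)
        pl = dict(fixed)
        pl[mobile_nid] = (mobile_base, pts)
        return _bond_cost(pl, bonds) + _clash_cost(pl, designed, polar)

    ranked = sorted(seed_states, key=lambda s: cost(s[0], s[1]))
    best = None
    for x0, mirror in ranked[:8]:
        res = minimize(cost, x0, args=(mirror,), method="Nelder-Mead",
                       options={"maxiter": 6000, "xatol": 1e-8,
                                "fatol": 1e-12})
        if best is None or res.fun < best[0]:
            best = (res.fun, res.x, mirror)
    _f, x, mirror = best
    return _transform(mobile_local, x[0], x[1], x[2], mirror)


def _anchor_seeds(local: dict, anchors: list[tuple[str, np.ndarray]]):
    """Grid of (params, mirror) states aligning anchor atoms to targets;
    every grid state is returned so the caller can rank by its own cost."""
    names = [a[0] for a in anchors]
    targets = np.array([a[1] for a in anchors])
    seeds = []
    for mirror in (False, True):
        for k in range(48):
            th = 2 * math.pi * k / 48
            pts = _transform(local, th, 0.0, 0.0, mirror)
            srcpts = np.array([pts[n] for n in names])
            tr = targets.mean(axis=0) - srcpts.mean(axis=0)
            seeds.append((np.array([th, tr[0], tr[1]]), mirror))
    return seeds


def _wc_dimer_au() -> dict[int, tuple[str, dict]]:
    """U34:A65 Hoogsteen-style dimer in the uracil local frame."""
    u = base_geometry("U")
    a_local = base_geometry("A")
    axis = u["H3"] - u["N3"]
    axis = axis / np.linalg.norm(axis)
    anchors = [("N7", u["N3"] + _HB_LEN * axis),
               ("N6", u["O4"] + _HB_LEN * axis)]
    bonds = [b for b in QUADRUPLE_BONDS_WT if {b[0], b[3]} == {34, 65}]
    a_pts = _refine_pair({34: ("U", u)}, 65, "A", a_local, bonds,
                         _anchor_seeds(a_local, anchors))
    return {34: ("U", u), 65: ("A", a_pts)}


def _wc_dimer_gc() -> dict[int, tuple[str, dict]]:
    """G37:C61 Watson-Crick dimer in the guanine local frame."""
    g = base_geometry("G")
    c_local = base_geometry("C")
    axis = g["H1"] - g["N1"]
    axis = axis / np.linalg.norm(axis)
    anchors = [("N3", g["N1"] + _HB_LEN * axis),
               ("O2", g["N2"] + _HB_LEN * axis),
               ("N4", g["O6"] + _HB_LEN * axis)]
    bonds = [b for b in QUADRUPLE_BONDS_WT if {b[0], b[3]} == {37, 61}]
    c_pts = _refine_pair({37: ("G", g)}, 61, "C", c_local, bonds,
                         _anchor_seeds(c_local, anchors))
    return {37: ("G", g), 61: ("C", c_pts)}


def _quadruple_layout() -> dict[int, tuple[str, dict]]:
    """Solve the planar placement of the four tetrad bases.

    Both base pairs (Watson-Crick 37:61, Hoogsteen-style 34:65) are
    constructed exactly as rigid dimers; the 34:65 dimer is then placed
    on the minor-groove side of the pair by a deterministic grid-seeded
    optimisation of the two inter-dimer bonds (G37 N2-H22 to U34 O2,
    A65 N6-H61 to C61 O2) plus a penalty on every undesigned polar
    contact the detection criteria could pick up. A synthetic stand-in
    layout, not a crystal geometry.
    """
    gc = _wc_dimer_gc()
    au = _wc_dimer_au()
    g = gc[37][1]
    c = gc[61][1]

    polar = {nid: [n for n in pts if n[0] in "NO"]
             for nid, (_b, pts) in {**gc, **au}.items()}
    designed = set()
    for dn, da, _h, an, aa in QUADRUPLE_BONDS_WT:
        designed.add((dn, da, an, aa))
        designed.add((an, aa, dn, da))
    link_bonds = [(dn, da, None, an, aa)
                  for dn, da, _h, an, aa in QUADRUPLE_BONDS_WT
                  if {dn, an} not in ({34, 65}, {37, 61})]

    # link-bond targets: along whichever G37 amino hydrogen is not already
    # engaged by C61's O2, and along the free lone pair of C61 O2 (the one
    # not facing G37's N2)
    free_h = max(("H21", "H22"), key=lambda hn: np.linalg.norm(
        g["N2"] + 2.0 * (g[hn] - g["N2"]) / np.linalg.norm(g[hn] - g["N2"])
        - c["O2"]))
    hdir = g[free_h] - g["N2"]
    hdir = hdir / np.linalg.norm(hdir)
    t_o2u = g["N2"] + _HB_LEN * hdir
    co_axis = c["O2"] - c["C2"]
    co_axis = co_axis / np.linalg.norm(co_axis)
    lone_pairs = []
    for sign in (1.0, -1.0):
        ang = math.radians(sign * 60.0)
        lone_pairs.append(np.array([
            co_axis[0] * math.cos(ang) - co_axis[1] * math.sin(ang),
            co_axis[0] * math.sin(ang) + co_axis[1] * math.cos(ang), 0.0]))
    to_n2 = g["N2"] - c["O2"]
    free_lp = min(lone_pairs, key=lambda lp: float(np.dot(lp, to_n2)))
    t_n6 = c["O2"] + _HB_LEN * free_lp

    def place(x, mirror):
        pl = dict(gc)
        for nid, (base, pts) in au.items():
            pl[nid] = (base, _transform3d(pts, x[:3], x[3:6], mirror))
        return pl

    def cost(x, mirror, w=1.0):
        pl = place(x, mirror)
        return (w * _bond_cost(pl, link_bonds)
                + _clash_cost(pl, designed, polar))

    # global search over the dimer's rigid-body pose (the tetrad puckers
    # out of the pair plane; a flat arrangement would clash), followed by
    # a per-base polish that may bend the Hoogsteen pair slightly so the
    # last inter-dimer bond can form. Differential evolution with a fixed
    # seed keeps the search deterministic.
    from scipy.optimize import differential_evolution
    from scipy.spatial.transform import Rotation

    dst_mid = 0.5 * (t_o2u + t_n6)
    bounds = ([(-3.2, 3.2)] * 3
              + [(dst_mid[0] - 8.0, dst_mid[0] + 8.0),
                 (dst_mid[1] - 8.0, dst_mid[1] + 8.0),
                 (-6.0, 6.0)])
    res = differential_evolution(lambda xx: cost(xx, False), bounds,
                                 seed=7, maxiter=150, popsize=24,
                                 tol=1e-10, polish=True, init="sobol")
    placed = place(res.x, False)

    # per-base polish against the full designed-bond set; amino donors use
    # whichever hydrogen serves best
    polish_bonds = [(dn, da, None if da in ("N2", "N4", "N6") else h,
                     an, aa) for dn, da, h, an, aa in QUADRUPLE_BONDS_WT]
    centroids = {nid: np.mean([p for nm, p in placed[nid][1].items()
                               if not nm.startswith("H")], axis=0)
                 for nid in (34, 65)}

    def place_polish(z):
        pl = dict(gc)
        for k, nid in enumerate((34, 65)):
            R = Rotation.from_rotvec(z[6 * k:6 * k + 3]).as_matrix()
            t = z[6 * k + 3:6 * k + 6]
            c0 = centroids[nid]
            pl[nid] = (placed[nid][0],
                       {nm: R @ (p - c0) + c0 + t
                        for nm, p in placed[nid][1].items()})
        return pl

    def polish_cost(z, w=1.0):
        pl = place_polish(z)
        return (w * _bond_cost(pl, polish_bonds)
                + _clash_cost(pl, designed, polar))

    z = np.zeros(12)
    for w in (1.0, 6.0, 1.0):
        res2 = minimize(lambda zz: polish_cost(zz, w), z,
                        method="Nelder-Mead",
                        options={"maxiter": 15000, "xatol": 1e-8,
                                 "fatol": 1e-12})
        z = res2.x
    if polish_cost(z) < polish_cost(np.zeros(12)) - 1e-9:
        return place_polish(z)
    return placed


_QUAD_CACHE: dict[bool, Structure] = {}
_LAYOUT_CACHE: list = []


def make_quadruple(mutant: bool = False) -> Structure:
    """Full-atom (base-only) stand-in for the upper loop-loop quadruple.

    Synthetic geometry: nucleotides 34/37/61/65 as idealised planar bases
    arranged so the seven designed wildtype hydrogen bonds satisfy the
    3.5 A / 120 deg detection criteria. The mutant is produced by actual
    base transplantation (G37A/C61U), which removes two of the seven bonds.
    The (deterministic) layout solve is cached per process.
    """
    if mutant in _QUAD_CACHE:
        return _QUAD_CACHE[mutant].copy()
    if not _LAYOUT_CACHE:
        _LAYOUT_CACHE.append(_quadruple_layout())
    layout = _LAYOUT_CACHE[0]
    if False not in _QUAD_CACHE:
        _QUAD_CACHE[False] = _structure_from_bases(layout)
    if not mutant:
        return _QUAD_CACHE[False].copy()
    from .model import transplant_bases
    donor = _mutant_donor(layout)
    mut = transplant_bases(_QUAD_CACHE[False], donor, {37, 61})
    _QUAD_CACHE[True] = mut.copy()
    return mut


def _mutant_donor(layout) -> Structure:
    """Donor structure carrying A at 37 and U at 61, rings superposed on
    the wildtype G/C placements."""
    placed = {}
    for nid, new_base, old in ((37, "A", "G"), (61, "U", "C")):
        tpts = layout[nid][1]
        local = base_geometry(new_base)
        anchors = [n for n in ("N1", "C2", "N3", "C4", "C5", "C6")
                   if n in local and n in tpts]
        R, t = kabsch(np.array([local[a] for a in anchors]),
                      np.array([tpts[a] for a in anchors]))
        placed[nid] = (new_base, {k: v @ R.T + t for k, v in local.items()})
    for nid in (34, 65):
        placed[nid] = layout[nid]
    return _structure_from_bases(placed)


def make_binding_triplet(separation: float = 7.5) -> Structure:
    """Three pyrimidine bases (U47, U51, C74) around an empty site.

    Synthetic stand-in for the ligand-binding core: the bases face a
    common centre at a separation too large for mutual hydrogen bonds, so
    an empty-site network leaves them in separate rigid clusters.
    """
    placed = {}
    for k, (nid, base) in enumerate(((47, "U"), (51, "U"), (74, "C"))):
        ang = math.radians(120.0 * k)
        pts = _transform(base_geometry(base), ang + math.pi,
                         separation * math.cos(ang),
                         separation * math.sin(ang))
        placed[nid] = (base, pts)
    return _structure_from_bases(placed)


# ---------------------------------------------------------------------------
# Coarse toy aptamer
# ---------------------------------------------------------------------------

#: helix base pairs of the miniature aptamer (same numbering as the real
#: 67-nucleotide domain)
TOY_PAIRS = {
    "P1": [(15 + k, 81 - k) for k in range(7)],
    "P2": [(25 + k, 46 - k) for k in range(8)],
    "P3": [(53 + k, 73 - k) for k in range(7)],
}

#: stochastic tertiary/bridging contacts of the coarse model:
#: name -> (body pair as (nucleotide, nucleotide), bar count,
#:          energy mean by variant {apt, loop}, energy sd)
TOY_CONTACTS = {
    "quad_upper_1": ((34, 65), 5, {"apt": -2.5, "loop": -0.9}, 0.6),
    "quad_upper_2": ((37, 61), 5, {"apt": -2.5, "loop": -0.9}, 0.6),
    "quad_lower_1": ((33, 66), 5, {"apt": -2.0, "loop": -1.6}, 0.7),
    "quad_lower_2": ((38, 60), 5, {"apt": -2.0, "loop": -1.6}, 0.7),
    "triple_P1_a": ((18, 46), 3, {"apt": -0.75, "loop": -0.55}, 0.5),
    "triple_P1_b": ((80, 67), 3, {"apt": -0.75, "loop": -0.55}, 0.5),
    "bind_47": ((47, 43), 3, {"apt": -1.5, "loop": -1.1}, 0.5),
    "bind_51": ((51, 55), 3, {"apt": -1.5, "loop": -1.1}, 0.5),
    # the J3/1 anchor weakens sharply in the loop mutant, mirroring the
    # much higher mobility of nucleotide 74 when the tertiary loop
    # contacts are destabilised
    "bind_74": ((74, 77), 3, {"apt": -1.5, "loop": -0.35}, 0.5),
}


def make_toy_aptamer(mutant: bool = False) -> tuple[Structure, RegionMap]:
    """Coarse miniature of the aptamer: one backbone body (P) and one base
    body (N1) per nucleotide, ids 15-81, with schematic coordinates laying
    the three helical arms out as a junction. The `mutant` flag only
    changes the base identities at 37/61 (the energetic difference lives
    in :func:`toy_snapshot_network`)."""
    table = default_region_table()
    arm_dir = {"P1": np.array([0.0, -1.0, 0.0]),
               "P2": np.array([-0.87, 0.5, 0.0]),
               "P3": np.array([0.87, 0.5, 0.0])}
    pos: dict[int, np.ndarray] = {}
    for helix, pairs in TOY_PAIRS.items():
        d = arm_dir[helix]
        perp = np.array([-d[1], d[0], 0.0])
        for k, (i, j) in enumerate(pairs):
            base = (4.0 + 3.0 * k) * d
            pos[i] = base + 3.0 * perp
            pos[j] = base - 3.0 * perp
    # loops and joining strands: arcs between the helix ends
    remaining = [i for i in range(15, 82) if i not in pos]
    for n, i in enumerate(remaining):
        ang = 2 * math.pi * n / max(len(remaining), 1)
        radius = 26.0 if table[i] in ("L2", "L3") else 2.0
        pos[i] = np.array([radius * math.cos(ang), radius * math.sin(ang),
                           2.0])
    atoms, coords, nucleotides = [], [], []
    serial = 1
    for nid in range(15, 82):
        base = {37: "G" if not mutant else "A",
                61: "C" if not mutant else "U"}.get(nid, "A")
        nucleotides.append(Nucleotide(nid, base))
        for name, el, off in (("P", "P", np.zeros(3)),
                              ("N1", "N", np.array([0.0, 0.0, 1.5]))):
            atoms.append(Atom(serial, name, el, nid,
                              chem.ATOMIC_MASS[el], "RNA", base,
                              ("A", nid, base)))
            coords.append(pos[nid] + off)
            serial += 1
    bonds = []
    st = Structure(atoms, np.array(coords), nucleotides, [])
    for nid in range(15, 82):
        bonds.append((st.atom_index(nid, "P"), st.atom_index(nid, "N1")))
        if nid < 81:
            bonds.append((st.atom_index(nid, "P"),
                          st.atom_index(nid + 1, "P")))
    st = Structure(atoms, np.array(coords), nucleotides, sorted(bonds))
    return st, assign_regions(st)


def toy_snapshot_network(structure: Structure,
                         variant: str = "apt",
                         rng: np.random.Generator | None = None,
                         ) -> ConstraintNetwork:
    """One stochastic snapshot of the coarse aptamer constraint network.

    Deterministic backbone/helix bars plus stochastic tertiary contacts
    whose energies are Gaussian draws; a contact contributes bars only
    after the energy filter (apply :func:`filter_hbond_bars` or build
    profiles at a given e_cut), which is how cutoff sensitivity enters.
    """
    if variant not in ("apt", "loop"):
        raise ValueError("variant must be 'apt' or 'loop'")
    rng = rng or np.random.default_rng(0)
    body_of_atom = {}
    labels = []
    for i, a in enumerate(structure.atoms):
        body_of_atom[i] = len(labels)
        labels.append((a.nucleotide_id, a.name))

    def body(nid, name):
        return body_of_atom[structure.atom_index(nid, name)]

    bars: list[Bar] = []

    def add(b1, b2, mult, prov, energy=0.0):
        bars.append(Bar(min(b1, b2), max(b1, b2), mult, prov, energy))

    for nid in range(15, 82):
        add(body(nid, "P"), body(nid, "N1"), 6, "COVALENT_LOCKED")
        if nid < 81:
            # 3-bar pseudo-bond: one coarse body stands in for the six
            # backbone bodies of a real nucleotide, so the link must
            # transmit fewer constraints than a single covalent bond
            add(body(nid, "P"), body(nid + 1, "P"), 3, "COVALENT_ROTATABLE")
    table = default_region_table()
    for helix, pairs in TOY_PAIRS.items():
        for i, j in pairs:
            add(body(i, "N1"), body(j, "N1"), 6, "HBOND", -6.0)
    # stacking keeps each helix one block and glues L2 to P2, L3 to P3
    strands = [range(15, 22), range(75, 82), range(25, 33), range(33, 39),
               range(39, 47), range(53, 60), range(60, 67), range(67, 74)]
    glue = [(32, 33), (38, 39), (59, 60), (66, 67)]
    for strand in strands:
        ids = list(strand)
        for a, b in zip(ids, ids[1:]):
            add(body(a, "N1"), body(b, "N1"), 6, "HYDROPHOBIC")
    for a, b in glue:
        add(body(a, "N1"), body(b, "N1"), 6, "HYDROPHOBIC")
    # stochastic contacts
    for name in sorted(TOY_CONTACTS):
        (i, j), mult, mu, sd = TOY_CONTACTS[name]
        energy = float(rng.normal(mu[variant], sd))
        add(body(i, "N1"), body(j, "N1"), mult, "HBOND", energy)
    return ConstraintNetwork(len(labels), bars, None, labels, body_of_atom)


def filter_hbond_bars(net: ConstraintNetwork,
                      e_cut: float) -> ConstraintNetwork:
    """Drop HBOND bars weaker than the cutoff (energy > e_cut)."""
    if e_cut >= 0:
        raise ValueError("e_cut must be negative")
    kept = [b for b in net.bars
            if b.provenance != "HBOND" or b.energy <= e_cut]
    out = net.with_bars(kept)
    out.e_cut = e_cut
    return out


def toy_condition_networks(n_snapshots: int, n_trajectories: int = 3,
                           seed: int = 0):
    """Stochastic snapshot networks for the four aptamer conditions.

    Returns (structure, {condition: [trajectory][snapshot] networks})
    where the unfiltered networks carry energies, the apo networks are the
    raw snapshots and the lig networks the same snapshots with ligand
    constraints added — the paired design the ligand-effect profile needs.
    """
    from .network import add_ligand_constraints

    st, _ = make_toy_aptamer()
    out: dict[str, list[list[ConstraintNetwork]]] = {}
    for variant in ("apt", "loop"):
        apo_trajs, lig_trajs = [], []
        for t in range(n_trajectories):
            rng = np.random.default_rng([seed, 7 + t,
                                         0 if variant == "apt" else 1])
            apo, lig = [], []
            for _ in range(n_snapshots):
                net = toy_snapshot_network(st, variant, rng)
                apo.append(net)
                lig.append(add_ligand_constraints(net))
            apo_trajs.append(apo)
            lig_trajs.append(lig)
        out[f"apo_{variant}"] = apo_trajs
        out[f"lig_{variant}"] = lig_trajs
    return st, out


# ---------------------------------------------------------------------------
# Four-condition Bernoulli design with analytic cooperativity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoopDesign:
    """Membership probabilities of the focal base body in the largest
    cluster under the four conditions; the implied cooperativity is
    c = ln[(q_lig_apt * q_apo_loop) / (q_apo_apt * q_lig_loop)]."""

    q_lig_apt: float = 0.9
    q_apo_apt: float = 0.6
    q_lig_loop: float = 0.7
    q_apo_loop: float = 0.5
    n_snapshots: int = 1000
    n_trajectories: int = 3
    seed: int = 0
    focal_nucleotide: int = 15

    def __post_init__(self):
        for q in (self.q_lig_apt, self.q_apo_apt, self.q_lig_loop,
                  self.q_apo_loop):
            if not 0.0 < q < 1.0:
                raise ValueError("membership probabilities must be in (0,1)")

    @property
    def analytic_coop(self) -> float:
        return math.log(self.q_lig_apt * self.q_apo_loop
                        / (self.q_apo_apt * self.q_lig_loop))

    def q_of(self, condition: str) -> float:
        return {"lig_apt": self.q_lig_apt, "apo_apt": self.q_apo_apt,
                "lig_loop": self.q_lig_loop,
                "apo_loop": self.q_apo_loop}[condition]


#: nucleotide ids of the design's minimal topology: five always-rigid core
#: nucleotides, the focal nucleotide, and two always-floppy decoys
_DESIGN_CORE = (16, 17, 18, 19, 20)
_DESIGN_DECOYS = (21, 22)


def _design_network(attached: bool, focal: int) -> ConstraintNetwork:
    ids = [focal, *_DESIGN_CORE, *_DESIGN_DECOYS]
    labels = [(nid, "N1") for nid in sorted(ids)]
    idx = {nid: k for k, (nid, _n) in enumerate(labels)}
    bars = [Bar(idx[a], idx[b], 6, "COVALENT_LOCKED")
            for a, b in zip(_DESIGN_CORE, _DESIGN_CORE[1:])]
    if attached:
        bars.append(Bar(min(idx[focal], idx[_DESIGN_CORE[0]]),
                        max(idx[focal], idx[_DESIGN_CORE[0]]),
                        6, "HBOND", -5.0))
    return ConstraintNetwork(len(labels), bars, None, labels)


def simulate_condition_ensembles(design: CoopDesign
                                 ) -> dict[str, list[list[ConstraintNetwork]]]:
    """Four-condition ensembles with exactly known p_lrc and Coop.

    Per condition and snapshot, the focal nucleotide's base body is tied
    to an always-rigid five-body core with probability q (independent
    Bernoulli draws); the largest rigid cluster is always the core, so
    p_lrc(focal) = q analytically and the pipeline estimate must recover
    ``design.analytic_coop``.
    """
    out = {}
    for c, condition in enumerate(("lig_apt", "apo_apt",
                                   "lig_loop", "apo_loop")):
        q = design.q_of(condition)
        trajs = []
        for t in range(design.n_trajectories):
            rng = np.random.default_rng([design.seed, c, t])
            draws = rng.random(design.n_snapshots) < q
            trajs.append([_design_network(bool(d), design.focal_nucleotide)
                          for d in draws])
        out[condition] = trajs
    return out


def design_nucleotide_ids(design: CoopDesign) -> list[int]:
    return sorted([design.focal_nucleotide, *_DESIGN_CORE, *_DESIGN_DECOYS])


def estimate_coop(design: CoopDesign):
    """Run the full pipeline on a Bernoulli design; returns the
    :class:`~riborigid.stats.CoopResult` restricted to the focal
    nucleotide."""
    from .stats import coop, decompose_ensemble, plrc_profile

    nets = simulate_condition_ensembles(design)
    ids = design_nucleotide_ids(design)
    profiles = {}
    for condition, trajs in nets.items():
        res = [decompose_ensemble(tr) for tr in trajs]
        profiles[condition] = plrc_profile(res, nucleotide_ids=ids,
                                           condition=condition)
    return coop(profiles["lig_apt"], profiles["apo_apt"],
                profiles["lig_loop"], profiles["apo_loop"],
                nucleotides={design.focal_nucleotide}), profiles


# ---------------------------------------------------------------------------
# Coordinate trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TelegraphBond:
    """Two-state donor-acceptor distance process for occupancy tests."""
    donor: tuple[int, str]
    acceptor: tuple[int, str]
    on_fraction: float
    mean_dwell_frames: float = 10.0
    on_distance: float = 2.9
    off_distance: float = 4.5


@dataclass(frozen=True)
class IonSpec:
    center: tuple[float, float, float]
    mode: str = "fixed"            # fixed | diffuse | shed
    shed_frame: int = 0
    step: float = 0.5              # rms displacement per frame (diffuse)


@dataclass
class TrajectorySpec:
    sigma_by_region: dict[str, float] = field(default_factory=dict)
    sigma_default: float = 0.3
    global_motion: bool = True
    hbonds: list[TelegraphBond] = field(default_factory=list)
    ions: list[IonSpec] = field(default_factory=list)
    n_frames: int = 200
    frame_spacing: float = 20.0    # ps


def simulate_trajectory(reference: Structure, spec: TrajectorySpec,
                        seed: int, regions: RegionMap | None = None
                        ) -> Ensemble:
    """Gaussian-fluctuation trajectory around a reference structure.

    Per-atom displacements are isotropic Gaussians with a per-region sigma
    (so RMSF orderings are known by construction); an optional global
    rigid-body tumble checks fitting invariance; listed donor-acceptor
    pairs follow a two-state Markov switch between bonded and broken
    distances; ions carry a six-water octahedral shell and can stay put,
    diffuse, or shed one water at a given frame.
    """
    rng = np.random.default_rng(seed)
    top = reference
    if spec.ions:
        top = _with_ions(reference, spec.ions)
    n = spec.n_frames
    sigma = np.full(top.n_atoms, spec.sigma_default)
    if regions is not None:
        for i, a in enumerate(top.atoms):
            if a.category == "RNA" and a.nucleotide_id in regions.mapping:
                sigma[i] = spec.sigma_by_region.get(
                    regions.mapping[a.nucleotide_id], spec.sigma_default)
    base = top.coords
    frames = np.empty((n, top.n_atoms, 3))
    # telegraph states
    states = {}
    for b in spec.hbonds:
        f = b.on_fraction
        k_off = 1.0 / b.mean_dwell_frames
        k_on = k_off * f / max(1.0 - f, 1e-9)
        s = rng.random() < f
        seq = np.empty(n, bool)
        for k in range(n):
            seq[k] = s
            p = k_off if s else k_on
            if rng.random() < p:
                s = not s
        states[b] = seq
    ion_offsets = {}
    for spec_idx, ion in enumerate(spec.ions):
        if ion.mode == "diffuse":
            steps = rng.normal(0, ion.step / math.sqrt(3), size=(n, 3))
            ion_offsets[spec_idx] = np.cumsum(steps, axis=0)
        else:
            ion_offsets[spec_idx] = np.zeros((n, 3))

    rna = top.category_mask("RNA")
    for k in range(n):
        f = base + rng.normal(0, 1.0, size=base.shape) * sigma[:, None]
        for b, seq in states.items():
            di = top.atom_index(*b.donor)
            ai = top.atom_index(*b.acceptor)
            u = base[ai] - base[di]
            u = u / np.linalg.norm(u)
            d = b.on_distance if seq[k] else b.off_distance
            f[ai] = f[di] + d * u
        # ions and shells ride their offsets
        _apply_ion_motion(top, f, spec.ions, ion_offsets, k)
        if spec.global_motion:
            ang = rng.uniform(0, 2 * math.pi)
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            K = np.array([[0, -axis[2], axis[1]],
                          [axis[2], 0, -axis[0]],
                          [-axis[1], axis[0], 0]])
            R = (np.eye(3) + math.sin(ang) * K
                 + (1 - math.cos(ang)) * (K @ K))
            f = f @ R.T + rng.normal(0, 5.0, size=3)
        frames[k] = f
    times = spec.frame_spacing * (np.arange(n) + 1.0)
    return Ensemble(top, frames, times)


_OCTAHEDRON = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                        [0, -1, 0], [0, 0, 1], [0, 0, -1]], float)


def _with_ions(reference: Structure, ions: list[IonSpec]) -> Structure:
    atoms = list(reference.atoms)
    coords = [c for c in reference.coords]
    bonds = list(reference.bonds)
    serial = max((a.serial for a in atoms), default=0)
    for k, ion in enumerate(ions):
        serial += 1
        atoms.append(Atom(serial, "MG", "MG", None,
                          chem.ATOMIC_MASS["MG"], "MG", "MG",
                          ("M", 1000 + k, "MG")))
        coords.append(np.asarray(ion.center, float))
        for w, v in enumerate(_OCTAHEDRON):
            serial += 1
            atoms.append(Atom(serial, "O", "O", None,
                              chem.ATOMIC_MASS["O"], "WATER", "HOH",
                              ("W", 2000 + 6 * k + w, "HOH")))
            coords.append(np.asarray(ion.center, float) + 2.1 * v)
    return Structure(atoms, np.array(coords), reference.nucleotides, bonds)


def _apply_ion_motion(top, frame, ions, offsets, k):
    mg_idx = [i for i, a in enumerate(top.atoms) if a.category == "MG"]
    wat_idx = [i for i, a in enumerate(top.atoms)
               if a.category == "WATER" and a.element == "O"]
    for s, ion in enumerate(ions):
        mi = mg_idx[s]
        shell = wat_idx[6 * s:6 * s + 6]
        center = np.asarray(ion.center, float) + offsets[s][k]
        frame[mi] = center
        for w, wi in enumerate(shell):
            frame[wi] = center + 2.1 * _OCTAHEDRON[w]
        if ion.mode == "shed" and k >= ion.shed_frame and shell:
            frame[shell[0]] = center + 5.5 * _OCTAHEDRON[0]
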