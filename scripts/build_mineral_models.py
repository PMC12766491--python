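#!/usr/bin/env python
"""Regenerate the vendored mineral model CIFs (whewellite, weddellite, uricite).

The shipped structures carry published unit cells and space-group packings;
their atomic coordinates are synthetic model reconstructions: rigid,
chemically idealized fragments (planar oxalate ions, water, a planar
uric-acid molecule) are packed in the cell and the packing parameters are
fitted by differential evolution so the simulated powder line intensities
approximate each mineral's publicly known experimental line list
(Cu K-alpha d/I values from standard powder-diffraction references). They
are NOT refined experimental atomic coordinates.

All searches are seeded, so a rerun reproduces the shipped files exactly.
Expect ~45 minutes on one CPU for the full rebuild.

Usage:  python scripts/build_mineral_models.py [--only COM|COD|UA] [--quick]
"""

import argparse
import math
from pathlib import Path

import numpy as np
from scipy.optimize import differential_evolution, minimize

from icsxrd.crystal import AtomSite, CrystalStructure, UnitCell, enumerate_reflections
from icsxrd.powder import lorentz_polarization

CU_LAMBDA = 1.5406
DATA_DIR = Path(__file__).resolve().parent.parent / "src" / "icsxrd" / "data"

# ------------------------------------------------------------------ fragments


def rotmat(ang):
    """ZYX Euler rotation."""
    a, b, c = ang
    ca, sa, cb, sb, cc, sc = np.cos(a), np.sin(a), np.cos(b), np.sin(b), np.cos(c), np.sin(c)
    Rz = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
    Ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    Rx = np.array([[1, 0, 0], [0, cc, -sc], [0, sc, cc]])
    return Rz @ Ry @ Rx


def oxalate(twist_deg=0.0):
    """C2O4: C-C 1.56 A, C-O 1.25 A, O-C-O 126 deg; second CO2 twisted about x."""
    cc = 0.78
    co, half = 1.25, math.radians(63.0)
    atoms = [("C", np.array([cc, 0, 0])), ("C", np.array([-cc, 0, 0]))]
    o1 = np.array([cc + co * math.cos(half), co * math.sin(half), 0.0])
    o2 = np.array([cc + co * math.cos(half), -co * math.sin(half), 0.0])
    t = math.radians(twist_deg)
    Rt = np.array([[1, 0, 0], [0, math.cos(t), -math.sin(t)], [0, math.sin(t), math.cos(t)]])
    o3 = Rt @ np.array([-o1[0], -o1[1], 0.0])
    o4 = Rt @ np.array([-o2[0], -o2[1], 0.0])
    atoms += [("O", o1), ("O", o2), ("O", o3), ("O", o4)]
    return atoms


def water():
    return [("O", np.array([0.0, 0.0, 0.0])),
            ("H", np.array([0.76, 0.59, 0.0])),
            ("H", np.array([-0.76, 0.59, 0.0]))]


def uric_acid():
    """Planar idealized 7,9-dihydropurine-2,6,8-trione (z = 0 plane)."""
    R = 1.39
    hexa = {}
    for name, ang in [("C2", 90), ("N3", 30), ("C4", -30), ("C5", -90),
                      ("C6", -150), ("N1", 150)]:
        a = math.radians(ang)
        hexa[name] = np.array([R * math.cos(a), R * math.sin(a), 0.0])
    p4, p5 = hexa["C4"], hexa["C5"]
    mid = 0.5 * (p4 + p5)
    out = mid / np.linalg.norm(mid)
    side = np.linalg.norm(p4 - p5)
    r5 = side / (2 * math.sin(math.pi / 5))
    cen5 = mid + out * (r5 * math.cos(math.pi / 5))
    ang4 = math.atan2(*(p4 - cen5)[[1, 0]])
    penta = {}
    cross_z = (p4 - cen5)[0] * (p5 - cen5)[1] - (p4 - cen5)[1] * (p5 - cen5)[0]
    sign = -1 if cross_z > 0 else 1
    for name, k in [("N9", 1), ("C8", 2), ("N7", 3)]:
        a = ang4 + sign * k * 2 * math.pi / 5
        penta[name] = cen5 + r5 * np.array([math.cos(a), math.sin(a), 0.0])
    atoms = [(n[0], p) for n, p in {**hexa, **penta}.items()]

    def radial(p, center, dist):
        d = p - center
        return p + dist * d / np.linalg.norm(d)

    atoms.append(("O", radial(hexa["C2"], np.zeros(3), 1.23)))
    atoms.append(("O", radial(hexa["C6"], np.zeros(3), 1.23)))
    atoms.append(("O", radial(penta["C8"], cen5, 1.23)))
    atoms.append(("H", radial(hexa["N1"], np.zeros(3), 1.01)))
    atoms.append(("H", radial(hexa["N3"], np.zeros(3), 1.01)))
    atoms.append(("H", radial(penta["N7"], cen5, 1.01)))
    atoms.append(("H", radial(penta["N9"], cen5, 1.01)))
    return atoms


# --------------------------------------------------------------- space groups

P21A = [  # No. 14, b unique, a glide (uricite)
    lambda x, y, z: (x, y, z),
    lambda x, y, z: (-x + 0.5, y + 0.5, -z),
    lambda x, y, z: (-x, -y, -z),
    lambda x, y, z: (x + 0.5, -y + 0.5, z),
]
# No. 14, b unique, n glide (whewellite in the a ~ 9.98 A setting): the
# n glide allows (-1 0 1) at d = 5.93 A — the mineral's strongest observed
# line — and forbids (1 0 0)/(0 0 1); a c glide would extinguish every h0l
# with odd l, including that line
P21N = [
    lambda x, y, z: (x, y, z),
    lambda x, y, z: (-x + 0.5, y + 0.5, -z + 0.5),
    lambda x, y, z: (-x, -y, -z),
    lambda x, y, z: (x + 0.5, -y + 0.5, z + 0.5),
]
I4M = []
for _cen in [(0, 0, 0), (0.5, 0.5, 0.5)]:
    for _op in [
        lambda x, y, z: (x, y, z),
        lambda x, y, z: (-x, -y, z),
        lambda x, y, z: (-y, x, z),
        lambda x, y, z: (y, -x, z),
    ]:
        for _mz in (1, -1):
            I4M.append(
                (lambda op=_op, mz=_mz, cx=_cen[0], cy=_cen[1], cz=_cen[2]:
                 lambda x, y, z: tuple(np.mod([op(x, y, z)[0] + cx,
                                               op(x, y, z)[1] + cy,
                                               mz * op(x, y, z)[2] + cz], 1.0)))()
            )


def expand(cell, frag_sets, ops, dedup_tol=None):
    """Apply symmetry ops to placed Cartesian fragments; return P1 sites.

    dedup_tol (Angstrom) merges special-position duplicates; None skips the
    check for general positions.
    """
    Minv = np.linalg.inv(cell.orthogonalization_matrix)
    M = cell.orthogonalization_matrix
    sites = []
    kept = {}
    for atoms in frag_sets:
        for el, p in atoms:
            f = Minv @ p
            for op in ops:
                q = np.mod(np.array(op(*f)), 1.0)
                if dedup_tol is not None:
                    prev = kept.setdefault(el, [])
                    if prev:
                        d = np.abs(np.array(prev) - q)
                        d = np.minimum(d, 1 - d)
                        if np.linalg.norm(d @ M.T, axis=1).min() < dedup_tol:
                            continue
                    prev.append(q)
                sites.append(AtomSite(el, tuple(q), 1.0, 0.0))
    return sites


def place(frag, centroid_cart, euler):
    R = rotmat(euler)
    return [(el, centroid_cart + R @ p) for el, p in frag]


# ----------------------------------------------------------- intensity model


def line_intensities(struct, d_min=2.25):
    """Grouped (d, I) powder line list at Cu K-alpha, LP-weighted."""
    two_theta_max = 2 * math.degrees(math.asin(min(CU_LAMBDA / (2 * d_min), 1.0)))
    refl = enumerate_reflections(struct, CU_LAMBDA, two_theta_max)
    groups = {}
    for r in refl:
        if r.d < d_min:
            continue
        theta = math.degrees(math.asin(CU_LAMBDA / (2 * r.d)))
        amp = r.f2 * float(lorentz_polarization(theta))
        merged = False
        for k in list(groups):
            if abs(k - r.d) / r.d < 0.008:
                groups[k] += amp
                merged = True
                break
        if not merged:
            groups[round(r.d, 2)] = groups.get(round(r.d, 2), 0.0) + amp
    return sorted(groups.items(), reverse=True)


def min_contact(cell, sites, el_a, el_b):
    fa = np.array([s.frac_xyz for s in sites if s.element == el_a])
    fb = np.array([s.frac_xyz for s in sites if s.element == el_b])
    if len(fa) == 0 or len(fb) == 0:
        return 10.0
    M = cell.orthogonalization_matrix
    best = 10.0
    for sh in ([0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
               [-1, 0, 0], [0, -1, 0], [0, 0, -1]):
        d = fa[:, None, :] - fb[None, :, :] + np.array(sh)
        cart = np.einsum("ij,abj->abi", M, d)
        r = np.linalg.norm(cart, axis=-1)
        r[r < 1e-6] = 10.0
        best = min(best, float(r.min()))
    return best


def clash_penalty(cell, sites):
    pen = 0.0
    limits = [("Ca", "Ca", 3.3), ("Ca", "O", 2.2), ("O", "O", 2.15),
              ("C", "C", 1.4), ("N", "N", 1.25), ("Ca", "C", 2.8)]
    for a, b, lim in limits:
        m = min_contact(cell, sites, a, b)
        if m < lim:
            pen += 4000.0 * (lim - m) ** 2
    return pen


def intensity_loss(struct, targets, match_tol=0.02, extra_weight=0.5,
                   first_line_weight=1.0):
    """Squared mismatch of scaled model line intensities vs the target list,
    plus a penalty on strong model lines where no line is observed."""
    lines = line_intensities(struct)
    if not lines:
        return 1e6
    tvals, matched = [], set()
    for td, _ in targets:
        acc = 0.0
        for d, I in lines:
            if abs(d - td) / td < match_tol:
                acc += I
                matched.add(d)
        tvals.append(acc)
    tvals = np.array(tvals)
    tI = np.array([ti for _, ti in targets], float)
    if tvals.max() <= 0:
        return 1e6
    sc = (tvals @ tI) / (tvals @ tvals)
    w = np.ones_like(tI)
    w[0] = first_line_weight
    resid = float(np.sum(w * (sc * tvals - tI) ** 2))
    extra = sum((sc * I) ** 2 for d, I in lines if d not in matched)
    return resid + extra_weight * extra


# ------------------------------------------------------------------- targets
# approximate experimental powder lines (d in A, relative intensity) of the
# minerals, Cu K-alpha, from standard powder-diffraction references
WHEWELLITE_TARGETS = [(5.93, 100), (5.79, 30), (3.65, 70), (2.966, 45),
                      (2.844, 25), (2.49, 18), (2.354, 30)]
WEDDELLITE_TARGETS = [(6.18, 100), (4.42, 30), (3.91, 14), (3.68, 10),
                      (3.09, 30), (2.99, 12), (2.775, 65), (2.41, 20)]
URICITE_TARGETS = [(6.56, 55), (4.92, 35), (3.85, 25), (3.28, 100),
                   (3.19, 40), (3.08, 30), (2.94, 15)]

# -------------------------------------------------------------------- builds

WHEW_FULL = UnitCell(9.9763, 14.5884, 6.2907, 90, 107.05, 90)
WHEW_SUB = UnitCell(9.9763, 7.2942, 6.2907, 90, 107.05, 90)
# deterministic small displacements breaking the exact b/2 pseudo-translation
_WHEW_JITTER = np.random.default_rng(2024).normal(0.0, 0.004, size=(200, 3))


def build_whewellite(params):
    """Z=4 subcell in P2_1/n, doubled along b with small fixed displacements.

    Whewellite's Z=8 cell is a weak doubling of a Z=4 subcell along b;
    building the model this way reproduces the observed near-extinction of
    k-odd lines and the absence of (0 2 0), and halves the fit's degrees of
    freedom.
    """
    (cax, cay, caz, ox, oy, oz, oa, ob, oc, wx, wy, wz) = params
    M = WHEW_SUB.orthogonalization_matrix
    frags = [
        [("Ca", M @ np.array([cax, cay, caz]))],
        place(oxalate(0.0), M @ np.array([ox, oy, oz]), (oa, ob, oc)),
        place(water(), M @ np.array([wx, wy, wz]), (0, 0, 0)),
    ]
    sub_sites = expand(WHEW_SUB, frags, P21N)
    sites, j = [], 0
    for s in sub_sites:
        x, ys, z = s.frac_xyz
        for shift in (0.0, 0.5):
            dx, dy, dz = _WHEW_JITTER[j % len(_WHEW_JITTER)]
            j += 1
            sites.append(AtomSite(
                s.element,
                ((x + dx) % 1.0, (ys / 2.0 + shift + dy) % 1.0, (z + dz) % 1.0),
            ))
    return CrystalStructure("COM", WHEW_FULL, sites)


def build_weddellite(params):
    cell = UnitCell(12.371, 12.371, 7.357, 90, 90, 90)
    M = cell.orthogonalization_matrix
    cax, cay, oxx, oxy, oxphi, wx, wy, wz = params
    # planar oxalate lying in the z = 0 mirror plane (special position):
    # the 16 operations then generate 8 copies
    frags = [
        [("Ca", M @ np.array([cax, cay, 0.0]))],
        place(oxalate(0.0), M @ np.array([oxx, oxy, 0.0]), (oxphi, 0, 0)),
        place(water(), M @ np.array([wx, wy, wz]), (0, 0, 0)),
    ]
    sites = expand(cell, frags, I4M, dedup_tol=0.05)
    return CrystalStructure("COD", cell, sites)


def build_uricite(params):
    cell = UnitCell(14.464, 7.403, 6.208, 90, 65.10, 90)
    M = cell.orthogonalization_matrix
    cx, cy, cz, ea, eb, ec = params
    frags = [place(uric_acid(), M @ np.array([cx, cy, cz]), (ea, eb, ec))]
    sites = expand(cell, frags, P21A)
    return CrystalStructure("UA", cell, sites)


# ----------------------------------------------------------------- fitting


def _objective(build, targets, **loss_kw):
    def f(p):
        try:
            s = build(p)
        except Exception:
            return 1e7
        return intensity_loss(s, targets, **loss_kw) + clash_penalty(s.cell, s.sites)

    return f


def fit_simple(build, targets, bounds, seed, maxiter, label, **loss_kw):
    f = _objective(build, targets, **loss_kw)
    res = differential_evolution(f, bounds, seed=seed, maxiter=maxiter,
                                 popsize=16, tol=1e-8, mutation=(0.4, 1.0),
                                 recombination=0.8, polish=False)
    print(f"{label}: loss={res.fun:.1f}")
    return res.x


def fit_whewellite(maxiter):
    """Seed sweep + Nelder-Mead polish (the 12-dof search is multimodal)."""
    bounds = [(0, 1)] * 3 + [(0, 1)] * 3 + [(0, math.pi)] * 3 + [(0, 1)] * 3
    f = _objective(build_whewellite, WHEWELLITE_TARGETS,
                   match_tol=0.015, extra_weight=1.0, first_line_weight=2.0)
    best = (1e18, None)
    for seed in (17, 29, 41):
        res = differential_evolution(f, bounds, seed=seed, maxiter=maxiter,
                                     popsize=16, tol=1e-10, mutation=(0.4, 1.0),
                                     recombination=0.8, polish=False)
        pol = minimize(f, res.x, method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8})
        val, x = (pol.fun, pol.x) if pol.fun <= res.fun else (res.fun, res.x)
        print(f"whewellite seed {seed}: DE {res.fun:.1f} -> polished {pol.fun:.1f}")
        if val < best[0]:
            best = (val, x)
    print(f"whewellite: best loss={best[0]:.1f}")
    return best[1]


def write_cif(struct, path, title, spacegroup_note):
    c = struct.cell
    lines = [
        f"# {title}",
        "# Model coordinates (synthetic reconstruction; see",
        "# scripts/build_mineral_models.py): published unit cell and",
        "# space-group packing, rigid idealized molecular fragments, packing",
        "# fitted to the mineral's published powder-diffraction line",
        "# intensities. Not refined experimental atomic coordinates.",
        f"# Underlying space group of the model: {spacegroup_note}; expressed in P1.",
        f"data_{struct.name}",
        f"_cell_length_a {c.a:.4f}",
        f"_cell_length_b {c.b:.4f}",
        f"_cell_length_c {c.c:.4f}",
        f"_cell_angle_alpha {c.alpha:.2f}",
        f"_cell_angle_beta {c.beta:.2f}",
        f"_cell_angle_gamma {c.gamma:.2f}",
        "_symmetry_space_group_name_H-M 'P 1'",
        "loop_",
        "_symmetry_equiv_pos_as_xyz",
        "'x, y, z'",
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
        "_atom_site_occupancy",
    ]
    counts = {}
    for s in struct.sites:
        counts[s.element] = counts.get(s.element, 0) + 1
        x, y, z = s.frac_xyz
        lines.append(
            f"{s.element}{counts[s.element]} {s.element} {x:.5f} {y:.5f} {z:.5f} {s.occupancy:.3f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
    print(f"  wrote {path} ({len(struct.sites)} sites)")


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--only", choices=["COM", "COD", "UA"], default=None)
    ap.add_argument("--quick", action="store_true",
                    help="few DE generations; for smoke testing only")
    args = ap.parse_args()
    m_simple = 40 if args.quick else 400
    m_whew = 40 if args.quick else 350

    if args.only in (None, "UA"):
        bounds = [(0, 0.5), (0, 1), (0, 1)] + [(0, math.pi)] * 3
        x = fit_simple(build_uricite, URICITE_TARGETS, bounds, seed=11,
                       maxiter=m_simple, label="uricite")
        write_cif(build_uricite(x), DATA_DIR / "uricite_model.cif",
                  "Uricite (anhydrous uric acid, C5H4N4O3) structural model",
                  "P2_1/a, b unique, Z=4")
    if args.only in (None, "COM"):
        x = fit_whewellite(m_whew)
        write_cif(build_whewellite(x), DATA_DIR / "whewellite_model.cif",
                  "Whewellite (calcium oxalate monohydrate, CaC2O4.H2O) structural model",
                  "P2_1/n, b unique, Z=8 (b/2 pseudo-translation built in)")
    if args.only in (None, "COD"):
        bounds = [(0, 0.5), (0, 0.5), (0, 0.5), (0, 0.5), (0, 2 * math.pi),
                  (0, 0.5), (0, 0.5), (0, 0.5)]
        x = fit_simple(build_weddellite, WEDDELLITE_TARGETS, bounds, seed=5,
                       maxiter=m_simple, label="weddellite")
        write_cif(build_weddellite(x), DATA_DIR / "weddellite_model.cif",
                  "Weddellite (calcium oxalate dihydrate, CaC2O4.2H2O) structural model",
                  "I4/m, Z=8")


if __name__ == "__main__":
    main()
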