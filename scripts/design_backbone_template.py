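"""One-off design run for the sugar/backbone stub frozen in templates.py.

Optimizes 9 backbone-atom positions (in the uracil standard frame) against:
  * standard ribose bond lengths / valence angles,
  * A-form-like torsions (soft), anti chi (strong),
  * the inter-residue O3'(i)-P(i+1) linkage of a 32 deg / 2.81 A helix,
  * a phosphate radius prior,
  * the calibrated A-form major-groove anchor (min cross-strand P-P = 12 A),
  * a soft steric floor against neighboring residues in the assembled duplex.

Prints achieved geometry and the SUGAR_LOCAL dict to paste into templates.py.
"""
import sys
import numpy as np
from scipy.optimize import least_squares

sys.path.insert(0, str(__import__("pathlib").Path(__file__).resolve().parents[1] / "src"))
from helixbend.geometry import place_atom, dihedral, unit  # noqa: E402
from helixbend.templates import BASE_ATOMS  # noqa: E402

TWIST = 32.0
RISE = 2.81
t = np.radians(TWIST)


def Rz(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])


U = {k: np.array(v) for k, v in BASE_ATOMS["U"].items()}
C1, N1, C2b = U["C1'"], U["N1"], U["C2"]

NAMES = ["O4'", "C2'", "C3'", "C4'", "C5'", "O5'", "O3'", "O2'", "P"]

# ---- initial guess by NeRF chain ----------------------------------------
g = {}
g["O4'"] = place_atom(C2b, N1, C1, 1.414, 108.2, -158.0)
g["C2'"] = place_atom(C2b, N1, C1, 1.528, 113.4, -36.0)
g["C3'"] = place_atom(g["O4'"], C1, g["C2'"], 1.525, 101.5, -25.9)
g["C4'"] = place_atom(C1, g["C2'"], g["C3'"], 1.524, 102.6, 37.1)
g["O3'"] = place_atom(C1, g["C2'"], g["C3'"], 1.423, 110.3, 155.0)
g["O2'"] = place_atom(g["O4'"], C1, g["C2'"], 1.413, 110.7, 95.0)
g["C5'"] = place_atom(g["C2'"], g["C3'"], g["C4'"], 1.510, 116.0, -90.0)
g["O5'"] = place_atom(g["C3'"], g["C4'"], g["C5'"], 1.440, 110.2, 54.0)
g["P"] = place_atom(g["C4'"], g["C5'"], g["O5'"], 1.593, 120.9, 178.0)

x0 = np.concatenate([g[n] for n in NAMES])

BONDS = [
    ("C1'", "O4'", 1.414), ("C1'", "C2'", 1.528), ("C2'", "C3'", 1.525),
    ("C2'", "O2'", 1.413), ("C3'", "C4'", 1.524), ("C3'", "O3'", 1.423),
    ("C4'", "O4'", 1.451), ("C4'", "C5'", 1.510), ("C5'", "O5'", 1.440),
    ("O5'", "P", 1.593),
]
ANGLES = [
    ("N1", "C1'", "O4'", 108.2), ("N1", "C1'", "C2'", 113.4),
    ("O4'", "C1'", "C2'", 106.4), ("C1'", "C2'", "C3'", 101.5),
    ("C1'", "C2'", "O2'", 108.6), ("C3'", "C2'", "O2'", 110.7),
    ("C2'", "C3'", "C4'", 102.6), ("C2'", "C3'", "O3'", 111.0),
    ("C4'", "C3'", "O3'", 110.3), ("C3'", "C4'", "O4'", 104.4),
    ("C1'", "O4'", "C4'", 109.9), ("C3'", "C4'", "C5'", 116.0),
    ("O4'", "C4'", "C5'", 109.8), ("C4'", "C5'", "O5'", 110.2),
    ("C5'", "O5'", "P", 120.9),
]
TORSIONS = [  # (atoms..., target, weight)
    (("O4'", "C1'", "N1", "C2"), -158.0, 0.5),       # chi (anti), firm
    (("O4'", "C1'", "C2'", "C3'"), -25.9, 0.1),      # nu1
    (("C1'", "C2'", "C3'", "C4'"), 37.1, 0.1),       # nu2
    (("C5'", "C4'", "C3'", "O3'"), 81.0, 0.05),      # delta
    (("O5'", "C5'", "C4'", "C3'"), 54.0, 0.05),      # gamma
]


def atom(d, name):
    if name in ("C1'", "N1", "C2"):
        return {"C1'": C1, "N1": N1, "C2": C2b}[name]
    return d[name]


def unpack(x):
    return {n: x[3 * i:3 * i + 3] for i, n in enumerate(NAMES)}


def ang(a, b, c):
    v1, v2 = a - b, c - b
    return np.degrees(np.arccos(np.clip(np.dot(unit(v1), unit(v2)), -1, 1)))


def groove_minima(p):
    """closed-form cross-strand P-P distance vs continuous index offset j"""
    Rp = np.hypot(p[0], p[1])
    psi = np.arctan2(p[1], p[0])
    zp = p[2]
    j = np.linspace(-12, 12, 4801)
    d2 = 2 * Rp ** 2 * (1 - np.cos(2 * psi + j * t)) + (2 * zp + j * RISE) ** 2
    return j, np.sqrt(d2)


def duplex_atoms(d, npairs=12):
    """assembled duplex heavy atoms for steric check (one strand + partner)"""
    tpl = {**{k: v for k, v in U.items()}, **d}
    F = np.diag([1.0, -1.0, -1.0])
    pts_i, pts_ii = [], []
    for i in range(npairs):
        R = Rz(i * t)
        off = np.array([0, 0, i * RISE])
        for v in tpl.values():
            pts_i.append(R @ v + off)
            pts_ii.append(R @ (F @ v) + off)
    return np.array(pts_i), np.array(pts_ii)


MAJOR_WINDOW = None  # set after inspection


def residuals(x, groove_target=None, major_window=None):
    d = unpack(x)
    res = []
    for a, b, l0 in BONDS:
        res.append((np.linalg.norm(atom(d, a) - atom(d, b)) - l0) / 0.01)
    # inter-residue O3'(i) - P(i+1)
    Pn = Rz(t) @ d["P"] + np.array([0, 0, RISE])
    O5n = Rz(t) @ d["O5'"] + np.array([0, 0, RISE])
    C5n = Rz(t) @ d["C5'"] + np.array([0, 0, RISE])
    res.append((np.linalg.norm(d["O3'"] - Pn) - 1.607) / 0.01)
    for a, b, c, a0 in ANGLES:
        res.append((ang(atom(d, a), atom(d, b), atom(d, c)) - a0) / 2.0)
    res.append((ang(d["O3'"], Pn, O5n) - 104.0) / 2.0)
    res.append((ang(d["C3'"], d["O3'"], Pn) - 119.7) / 2.0)
    for atoms, t0, w in TORSIONS:
        dv = dihedral(*(atom(d, a) for a in atoms))
        delta = (dv - t0 + 180.0) % 360.0 - 180.0
        res.append(delta * w)
    # epsilon / zeta soft
    eps = dihedral(d["C4'"], d["C3'"], d["O3'"], Pn)
    res.append(((eps - (-153.0) + 180) % 360 - 180) * 0.05)
    zeta = dihedral(d["C3'"], d["O3'"], Pn, O5n)
    res.append(((zeta - (-71.0) + 180) % 360 - 180) * 0.05)
    beta = dihedral(Pn, O5n, C5n, Rz(t) @ d["C4'"] + np.array([0, 0, RISE]))
    res.append(((beta - 178.0 + 180) % 360 - 180) * 0.05)
    # phosphate radius prior
    res.append((np.hypot(d["P"][0], d["P"][1]) - 9.5) / 0.5)
    # soft steric floor: this residue's atoms vs neighbor residues (both
    # strands, levels -1/0/+1), excluding the O3'-P backbone linkage
    tpl = {**U, **d}
    own = np.array([tpl[n] for n in tpl])
    own_names = list(tpl)
    F = np.diag([1.0, -1.0, -1.0])
    others, other_names = [], []
    for lvl in (-1, 0, 1):
        R = Rz(lvl * t)
        off = np.array([0, 0, lvl * RISE])
        for flip in (False, True):
            if lvl == 0 and not flip:
                continue
            for nm, v in tpl.items():
                others.append(R @ (F @ v if flip else v) + off)
                other_names.append((lvl, flip, nm))
    others = np.array(others)
    dist2 = np.linalg.norm(own[:, None, :] - others[None, :, :], axis=2)
    floor = 2.9
    mask = np.ones_like(dist2, dtype=bool)
    for jj, (lvl, flip, nm2) in enumerate(other_names):
        if not flip and abs(lvl) == 1:
            for ii, nm in enumerate(own_names):
                if {nm, nm2} == {"O3'", "P"}:
                    mask[ii, jj] = False
    pen = np.maximum(0.0, floor - np.where(mask, dist2, np.inf)) / 0.05
    res.extend(pen.ravel())
    if groove_target is not None:
        j, dist = groove_minima(d["P"])
        m = (j >= major_window[0]) & (j <= major_window[1])
        res.append((dist[m].min() - groove_target) / 0.02)
    return np.array(res)


# ---- stage 1: chemistry only ---------------------------------------------
sol1 = least_squares(residuals, x0, xtol=1e-12, ftol=1e-12, max_nfev=20000)
d1 = unpack(sol1.x)
print("stage1 cost:", sol1.cost)
print("P:", d1["P"], "radius", np.hypot(d1["P"][0], d1["P"][1]),
      "azim", np.degrees(np.arctan2(d1["P"][1], d1["P"][0])))
j, dist = groove_minima(d1["P"])
# report local minima
loc = [(j[i], dist[i]) for i in range(1, len(j) - 1)
       if dist[i] < dist[i - 1] and dist[i] < dist[i + 1]]
print("stage1 local minima (j, d):", [(round(a, 2), round(b, 2)) for a, b in loc])

# decide which branch is the major groove: midpoint of the min segment vs
# pair-frame +x direction at the matching z level
for jm, dm in loc:
    # representative pair of P atoms: k=0 on strand I, m chosen via j=k+m-N-1
    # position I at k: azim psi, z zp ; II: azim -psi + (N+1-m)t etc.
    p = d1["P"]
    psi = np.arctan2(p[1], p[0]); Rp = np.hypot(p[0], p[1]); zp = p[2]
    azI, zI = psi, zp
    azII, zII = -psi + (-jm) * 0 + (0 - jm) * 0 - 0, 0  # placeholder
    # direct: P_II at j means azim = -psi - j*t? derive: az_II = -psi+(N+1-m)t,
    # with k=0, j=m-N-1 -> N+1-m = -j  => az_II = -psi - j*t, z_II = -zp - j*RISE
    azII = -psi - jm * t
    zII = -zp - jm * RISE
    mid = 0.5 * (np.array([Rp * np.cos(azI), Rp * np.sin(azI), zI])
                 + np.array([Rp * np.cos(azII), Rp * np.sin(azII), zII]))
    zmid = mid[2]
    q = zmid / RISE  # pair level
    xaxis_az = q * t
    rel = (np.arctan2(mid[1], mid[0]) - xaxis_az + np.pi) % (2 * np.pi) - np.pi
    side = "major(+x)" if abs(rel) < np.pi / 2 else "minor(-x)"
    print(f"  branch j={jm:6.2f} d={dm:6.2f} midpoint side: {side}")

# ---- stage 2: add groove anchor on the major branch ----------------------
# pick the major-branch window around its stage-1 minimum
majors = []
for jm, dm in loc:
    p = d1["P"]; psi = np.arctan2(p[1], p[0]); Rp = np.hypot(p[0], p[1]); zp = p[2]
    azII = -psi - jm * t; zII = -zp - jm * RISE
    mid = 0.5 * (np.array([Rp * np.cos(psi), Rp * np.sin(psi), zp])
                 + np.array([Rp * np.cos(azII), Rp * np.sin(azII), zII]))
    q = mid[2] / RISE
    rel = (np.arctan2(mid[1], mid[0]) - q * t + np.pi) % (2 * np.pi) - np.pi
    if abs(rel) < np.pi / 2:
        majors.append((jm, dm))
print("major-branch minima:", majors)
jm = min(majors, key=lambda ab: ab[1])[0]
win = (jm - 2.5, jm + 2.5)
print("using major window", win)

sol2 = least_squares(residuals, sol1.x, kwargs=dict(groove_target=12.703, major_window=win),
                     xtol=1e-12, ftol=1e-12, max_nfev=40000)
d2 = unpack(sol2.x)
print("stage2 cost:", sol2.cost)

# ---- report --------------------------------------------------------------
print("\nachieved geometry:")
for a, b, l0 in BONDS + [("O3'", "Pnext", 1.607)]:
    if b == "Pnext":
        v = np.linalg.norm(d2["O3'"] - (Rz(t) @ d2["P"] + np.array([0, 0, RISE])))
    else:
        v = np.linalg.norm(atom(d2, a) - atom(d2, b))
    print(f"  bond {a:>4}-{b:<5} {v:6.3f} (target {l0})")
chi = dihedral(d2["O4'"], C1, N1, C2b)
print("  chi:", round(chi, 1))
print("  P radius/azim/z:", round(np.hypot(d2['P'][0], d2['P'][1]), 3),
      round(np.degrees(np.arctan2(d2['P'][1], d2['P'][0])), 2), round(d2['P'][2], 3))
j, dist = groove_minima(d2["P"])
loc = [(round(j[i], 2), round(dist[i], 3)) for i in range(1, len(j) - 1)
       if dist[i] < dist[i - 1] and dist[i] < dist[i + 1]]
print("  groove minima:", loc)

# steric check: nearest non-bonded approach in assembled duplex
tplfull = {**U, **d2}
names = list(tplfull)
F = np.diag([1.0, -1.0, -1.0])
coords = []
ids = []
for i in range(10):
    R = Rz(i * t); off = np.array([0, 0, i * RISE])
    for s, flip in (("I", False), ("II", True)):
        for nm in names:
            v = tplfull[nm]
            coords.append(R @ (F @ v if flip else v) + off)
            ids.append((s, i, nm))
coords = np.array(coords)
from scipy.spatial import cKDTree
tree = cKDTree(coords)
pairs = tree.query_pairs(2.2)
bad = []
for a, b in pairs:
    sa, ia, na = ids[a]; sb, ib, nb = ids[b]
    if sa == sb and ia == ib:
        continue  # intra-residue (bonded) contacts
    if sa == sb and abs(ia - ib) == 1 and {na, nb} == {"O3'", "P"}:
        continue  # backbone linkage
    bad.append((ids[a], ids[b], round(float(np.linalg.norm(coords[a] - coords[b])), 2)))
print("  steric contacts < 2.2 A (excl. bonded):", bad[:12], "n =", len(bad))

# ---- print SUGAR_LOCAL ---------------------------------------------------
ex = unit(C1 - N1)
ez = np.array([0, 0, 1.0])
ey = np.cross(ez, ex); ey /= np.linalg.norm(ey)
Rl = np.column_stack([ex, ey, np.cross(ex, ey)])
print("\nSUGAR_LOCAL = {")
for nm in NAMES:
    loc = Rl.T @ (d2[nm] - C1)
    print(f'    "{nm}": ({loc[0]:.4f}, {loc[1]:.4f}, {loc[2]:.4f}),')
print("}")
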