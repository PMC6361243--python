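"""Structural residue descriptors computed from coordinates.

All descriptors are internal providers: half-sphere exposure and contact
number counted over C-alpha neighbours at 12 Angstrom, an eight-class
hydrogen-bond/dihedral secondary-structure assigner in the Kabsch-Sander
tradition, a rolling-probe (Shrake-Rupley) solvent accessible surface area,
and simple hydrophobicity/protrusion/depth proxies.
"""

from __future__ import annotations

import numpy as np

from .._tables import (
    DEFAULT_VDW_RADIUS,
    KYTE_DOOLITTLE,
    MAX_ASA,
    SASA_PROBE_RADIUS,
    VDW_RADII,
)

#: Secondary-structure classes, one-hot order.
SS_CLASSES = "HGIEBTS-"
SS_INDEX = {c: i for i, c in enumerate(SS_CLASSES)}

HSE_RADIUS = 12.0


def _unit(v: np.ndarray) -> np.ndarray | None:
    n = np.linalg.norm(v)
    if n < 1e-9:
        return None
    return v / n


def half_sphere_exposure(chain, radius: float = HSE_RADIUS):
    """Half-sphere exposure and contact number per residue.

    Neighbours are C-alpha atoms of other residues strictly within
    ``radius``.  The hemisphere axis points from C-alpha towards C-beta
    (pseudo C-beta from the backbone N/C bisector for glycine or when no
    C-beta is present).  Returns ``(hse_up, hse_down, flags)`` integer
    arrays; ``contact_number = hse_up + hse_down``.  Residues without a
    C-alpha are flagged and report zeros.
    """
    n = len(chain)
    up = np.zeros(n, dtype=int)
    down = np.zeros(n, dtype=int)
    flags = np.zeros(n, dtype=bool)
    cas = [res.ca for res in chain]
    for i, res in enumerate(chain):
        ca = cas[i]
        if ca is None:
            flags[i] = True
            continue
        direction = None
        cb = res.atom("CB")
        if cb is not None:
            direction = _unit(cb - ca)
        if direction is None:
            n_at, c_at = res.atom("N"), res.atom("C")
            if n_at is not None and c_at is not None:
                u1, u2 = _unit(n_at - ca), _unit(c_at - ca)
                if u1 is not None and u2 is not None:
                    direction = _unit(-(u1 + u2))
        if direction is None:
            flags[i] = True
        for j, other in enumerate(cas):
            if j == i or other is None:
                continue
            delta = other - ca
            if np.linalg.norm(delta) >= radius:
                continue
            if direction is not None and float(np.dot(delta, direction)) > 0:
                up[i] += 1
            else:
                down[i] += 1
    return up, down, flags


# ---------------------------------------------------------------------------
# Secondary structure (hydrogen-bond based, eight classes)
# ---------------------------------------------------------------------------

_HB_Q1Q2F = 0.084 * 332.0   # electrostatic H-bond energy prefactor (kcal/mol)
_HB_CUTOFF = -0.5


def _backbone(chain):
    """Per-residue backbone coordinates (N, CA, C, O) or None."""
    out = []
    for res in chain:
        atoms = [res.atom(a) for a in ("N", "CA", "C", "O")]
        out.append(None if any(a is None for a in atoms) else atoms)
    return out


def _hbond_matrix(chain) -> np.ndarray:
    """hb[d, a] is True when residue d's amide donates an H-bond to
    residue a's carbonyl (Kabsch-Sander electrostatic criterion)."""
    n = len(chain)
    bb = _backbone(chain)
    hb = np.zeros((n, n), dtype=bool)
    # amide H placed along the previous residue's C=O direction
    h_pos: list[np.ndarray | None] = [None] * n
    for i in range(1, n):
        if bb[i] is None or bb[i - 1] is None or chain[i].aa == "P":
            continue
        c_prev, o_prev = bb[i - 1][2], bb[i - 1][3]
        d = _unit(c_prev - o_prev)
        if d is not None:
            h_pos[i] = bb[i][0] + d
    for d_idx in range(n):
        if h_pos[d_idx] is None or bb[d_idx] is None:
            continue
        n_at = bb[d_idx][0]
        h_at = h_pos[d_idx]
        for a_idx in range(n):
            if abs(d_idx - a_idx) < 2 or bb[a_idx] is None:
                continue
            c_at, o_at = bb[a_idx][2], bb[a_idx][3]
            if np.linalg.norm(bb[d_idx][1] - bb[a_idx][1]) > 9.0:
                continue
            r_on = np.linalg.norm(o_at - n_at)
            r_ch = np.linalg.norm(c_at - h_at)
            r_oh = np.linalg.norm(o_at - h_at)
            r_cn = np.linalg.norm(c_at - n_at)
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue
            energy = _HB_Q1Q2F * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            if energy < _HB_CUTOFF:
                hb[d_idx, a_idx] = True
    return hb


def secondary_structure(chain) -> list[str]:
    """Assign one of eight classes (H, G, I, E, B, T, S, -) per residue.

    Helices (H/G/I) come from consecutive n-turns (n = 4/3/5), strands and
    bridges (E/B) from parallel/antiparallel bridge hydrogen bonding, T
    from isolated turns and S from backbone bends; residues with missing
    backbone atoms get '-'.  Deterministic, priority H > E > B > G > I >
    T > S.
    """
    n = len(chain)
    bb = _backbone(chain)
    hb = _hbond_matrix(chain)

    def turn(i: int, k: int) -> bool:
        return 0 <= i and i + k < n and hb[i + k, i]

    helix = {3: np.zeros(n, bool), 4: np.zeros(n, bool), 5: np.zeros(n, bool)}
    for k in (4, 3, 5):
        for i in range(n - k - 1):
            if turn(i, k) and turn(i + 1, k):
                helix[k][i + 1:i + k + 1] = True

    # bridges
    partners: list[list[int]] = [[] for _ in range(n)]
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (hb[j, i - 1] and hb[i + 1, j]) or (hb[i, j - 1] and hb[j + 1, i])
            anti = (hb[i, j] and hb[j, i]) or (hb[j + 1, i - 1] and hb[i + 1, j - 1])
            if para or anti:
                partners[i].append(j)
                partners[j].append(i)
    bridge = np.array([len(p) > 0 for p in partners])
    extended = np.zeros(n, bool)
    for i in range(n):
        if bridge[i] and (
            (i > 0 and bridge[i - 1] and any(abs(p - q) <= 1 for p in partners[i] for q in partners[i - 1]))
            or (i + 1 < n and bridge[i + 1] and any(abs(p - q) <= 1 for p in partners[i] for q in partners[i + 1]))
        ):
            extended[i] = True

    turn_t = np.zeros(n, bool)
    for k in (3, 4, 5):
        for i in range(n - k):
            if turn(i, k):
                turn_t[i + 1:i + k] = True

    bend = np.zeros(n, bool)
    for i in range(2, n - 2):
        if bb[i] is None or bb[i - 2] is None or bb[i + 2] is None:
            continue
        u1 = _unit(bb[i][1] - bb[i - 2][1])
        u2 = _unit(bb[i + 2][1] - bb[i][1])
        if u1 is None or u2 is None:
            continue
        angle = np.degrees(np.arccos(np.clip(np.dot(u1, u2), -1, 1)))
        if angle > 70.0:
            bend[i] = True

    classes = []
    for i in range(n):
        if bb[i] is None:
            classes.append("-")
        elif helix[4][i]:
            classes.append("H")
        elif extended[i]:
            classes.append("E")
        elif bridge[i]:
            classes.append("B")
        elif helix[3][i]:
            classes.append("G")
        elif helix[5][i]:
            classes.append("I")
        elif turn_t[i]:
            classes.append("T")
        elif bend[i]:
            classes.append("S")
        else:
            classes.append("-")
    return classes


# ---------------------------------------------------------------------------
# Solvent accessible surface area (rolling probe)
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * k
    return np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)],
        axis=1,
    )


def shrake_rupley_sasa(coords: np.ndarray, elements: list[str],
                       probe: float = SASA_PROBE_RADIUS,
                       n_points: int = 120) -> np.ndarray:
    """Per-atom solvent accessible surface area (Angstrom^2).

    Test points on each atom's expanded sphere (vdW + probe radius) are
    counted as accessible when outside every other atom's expanded sphere;
    the per-atom area is the accessible fraction of ``4*pi*(r+probe)^2``.
    """
    coords = np.asarray(coords, dtype=float)
    n_atoms = coords.shape[0]
    radii = np.array(
        [VDW_RADII.get(e.upper(), DEFAULT_VDW_RADIUS) + probe for e in elements]
    )
    sphere = _fibonacci_sphere(n_points)
    areas = np.zeros(n_atoms)
    for i in range(n_atoms):
        pts = coords[i] + radii[i] * sphere
        free = np.ones(n_points, dtype=bool)
        d_atoms = np.linalg.norm(coords - coords[i], axis=1)
        near = np.where((d_atoms < radii + radii[i]) & (np.arange(n_atoms) != i))[0]
        for j in near:
            d = np.linalg.norm(pts - coords[j], axis=1)
            free &= d >= radii[j]
        areas[i] = free.mean() * 4.0 * np.pi * radii[i] ** 2
    return areas


def accessibility(pair, which: str, probe: float = SASA_PROBE_RADIUS,
                  n_points: int = 120):
    """Relative per-residue accessibility of one chain, computed unbound.

    SASA is evaluated on the isolated chain (the partner does not occlude),
    summed per residue and normalised by the residue-type maximum, clipped
    to [0, 1].  Returns ``(values, missing_flags)``; residues without atoms
    get value 0 and a raised flag.
    """
    chain = pair.chain(which)
    coords, elements, owner = [], [], []
    for idx, res in enumerate(chain):
        for name, xyz, el in zip(res.atom_names, res.heavy_atoms, res.elements):
            coords.append(xyz)
            elements.append(el)
            owner.append(idx)
    values = np.zeros(len(chain))
    flags = np.array([not res.resolved for res in chain])
    if coords:
        areas = shrake_rupley_sasa(np.asarray(coords), elements, probe, n_points)
        np.add.at(values, np.asarray(owner), areas)
    rel = np.zeros(len(chain))
    for i, res in enumerate(chain):
        rel[i] = values[i] / MAX_ASA.get(res.aa, MAX_ASA["X"])
    return np.clip(rel, 0.0, 1.0), flags


def geometric_descriptors(chain, hse_up: np.ndarray, hse_down: np.ndarray):
    """Per-residue (hydrophobicity, protrusion proxy, depth proxy).

    Protrusion is the neighbour-count deficit relative to the most buried
    residue of the chain; depth is the normalised proximity of the C-alpha
    to the chain centroid.  Both live in [0, 1].
    """
    n = len(chain)
    kd = np.array([KYTE_DOOLITTLE.get(r.aa, 0.0) for r in chain])
    cn = (hse_up + hse_down).astype(float)
    max_cn = cn.max() if n and cn.max() > 0 else 1.0
    protrusion = 1.0 - cn / max_cn
    cas = np.array([
        r.ca if r.ca is not None else [np.nan] * 3 for r in chain
    ], dtype=float)
    depth = np.zeros(n)
    valid = ~np.isnan(cas).any(axis=1)
    if valid.sum() >= 2:
        centroid = cas[valid].mean(axis=0)
        dist = np.linalg.norm(cas[valid] - centroid, axis=1)
        max_d = dist.max() if dist.max() > 0 else 1.0
        depth[valid] = 1.0 - dist / max_d
    return np.stack([kd, protrusion, depth], axis=1)
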