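"""Independent brute-force reimplementations used as test oracles.

Deliberately coded with different primitives than the package: plane normals
via Newell's polygon method (edge cross-product sum) instead of SVD, angles
via explicit dot/cross arithmetic with the ``math`` module.
"""

import math

import numpy as np


def newell_normal(coords) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    total = np.zeros(3)
    for i in range(n):
        a, b = coords[i], coords[(i + 1) % n]
        total += np.cross(a, b)
    norm = math.sqrt(total[0] ** 2 + total[1] ** 2 + total[2] ** 2)
    return total / norm


def vec_angle_deg(u, v) -> float:
    u, v = np.asarray(u, dtype=float), np.asarray(v, dtype=float)
    cosv = float(np.dot(u, v)) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosv))))


def fold(a: float) -> float:
    a = a % 180.0
    return a if a <= 90.0 else 180.0 - a


def aromatic_descriptors(coords_ref, coords_partner):
    """(D, P, Ttheta1, Ttheta2) from raw ring coordinates."""
    c1 = np.mean(np.asarray(coords_ref, dtype=float), axis=0)
    c2 = np.mean(np.asarray(coords_partner, dtype=float), axis=0)
    n1 = newell_normal(coords_ref)
    n2 = newell_normal(coords_partner)
    d = c2 - c1
    dist = math.sqrt(float(np.dot(d, d)))
    p = fold(vec_angle_deg(n1, n2))
    t1 = math.degrees(math.asin(max(-1.0, min(1.0, abs(float(np.dot(d, n1))) / dist))))
    t2 = math.degrees(math.asin(max(-1.0, min(1.0, abs(float(np.dot(-d, n2))) / dist))))
    return dist, p, t1, t2


def cation_descriptors(ring_coords, cation_pos, cation_plane_coords=None):
    """(D, theta1, theta2-or-None) from raw coordinates."""
    centroid = np.mean(np.asarray(ring_coords, dtype=float), axis=0)
    n = newell_normal(ring_coords)
    d = np.asarray(cation_pos, dtype=float) - centroid
    dist = math.sqrt(float(np.dot(d, d)))
    theta1 = fold(vec_angle_deg(n, d))
    theta2 = None
    if cation_plane_coords is not None:
        m = newell_normal(cation_plane_coords)
        theta2 = fold(vec_angle_deg(m, d))
    return dist, theta1, theta2


# -- naive rule re-evaluation for classifiers ------------------------------

def stacked_rule(D, P, T_theta2, thr) -> bool:
    ok = D <= thr.stack_max_D and P <= thr.stack_max_P
    if ok and thr.stack_min_T_theta2 is not None:
        ok = T_theta2 >= thr.stack_min_T_theta2
    return ok


def cation_pi_rule(D, theta1, thr) -> bool:
    return D <= thr.catpi_max_D and theta1 <= thr.catpi_max_theta1


def ch_pi_rule(c_pos, h_pos, centroid, normal, thr) -> bool:
    c_pos, h_pos = np.asarray(c_pos, dtype=float), np.asarray(h_pos, dtype=float)
    centroid, normal = np.asarray(centroid, dtype=float), np.asarray(normal, dtype=float)
    if math.dist(tuple(c_pos), tuple(centroid)) > thr.chpi_max_C_centroid:
        return False
    off = h_pos - centroid
    proj = off - np.dot(off, normal) * normal
    if math.sqrt(float(np.dot(proj, proj))) > thr.chpi_max_H_projection:
        return False
    return vec_angle_deg(c_pos - h_pos, centroid - h_pos) >= thr.chpi_min_CH_centroid_angle


def h_bond_rule(d_pos, h_pos, a_pos, his_normal, thr) -> bool:
    d_pos, h_pos, a_pos = (np.asarray(p, dtype=float) for p in (d_pos, h_pos, a_pos))
    if math.dist(tuple(d_pos), tuple(a_pos)) > thr.hb_max_DA:
        return False
    if vec_angle_deg(d_pos - h_pos, a_pos - h_pos) < thr.hb_min_DHA_angle:
        return False
    if his_normal is not None:
        v = a_pos - d_pos
        s = abs(float(np.dot(v, his_normal))) / math.sqrt(float(np.dot(v, v)))
        if math.degrees(math.asin(min(1.0, s))) > thr.hb_max_plane_elevation:
            return False
    return True
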