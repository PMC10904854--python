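"""Literal scalar transcription of the energy equations, used as ground truth.

Everything here is written as plain per-atom/per-pair Python loops, directly
off the published closed forms (LJ 12-6, Coulomb, HCT descreening integral,
OBC-I rescaling, Still's GB pair function with Debye salt screening,
Shrake-Rupley point counting), independently of the vectorized engine in
``energy.py``.  The generators store these values next to synthetic systems so
the fast implementation is always checked against an independent route.
"""

from __future__ import annotations

import math

import numpy as np

_KE = 332.0637
_OFFSET = 0.09
_SCREEN = 0.8
_ALPHA, _BETA, _GAMMA = 0.8, 0.0, 2.909125
_KAPPA_FACTOR = 0.73 * 0.32918


def _spiral(n):
    pts = []
    golden = math.pi * (1 + 5**0.5)
    for k in range(n):
        t = k + 0.5
        phi = math.acos(1 - 2 * t / n)
        theta = golden * t
        pts.append(
            (
                math.sin(phi) * math.cos(theta),
                math.sin(phi) * math.sin(theta),
                math.cos(phi),
            )
        )
    return pts


def scalar_sasa(coords, radii, probe=1.4, n_points=960):
    coords = [tuple(map(float, c)) for c in coords]
    aug = [float(r) + probe for r in radii]
    sphere = _spiral(n_points)
    areas = []
    for i, (cx, cy, cz) in enumerate(coords):
        exposed = 0
        for sx, sy, sz in sphere:
            px, py, pz = cx + aug[i] * sx, cy + aug[i] * sy, cz + aug[i] * sz
            buried = False
            for j, (ox, oy, oz) in enumerate(coords):
                if j == i:
                    continue
                if (px - ox) ** 2 + (py - oy) ** 2 + (pz - oz) ** 2 < aug[j] ** 2:
                    buried = True
                    break
            if not buried:
                exposed += 1
        areas.append(4.0 * math.pi * aug[i] ** 2 * exposed / n_points)
    return areas


def scalar_born_radii(coords, gb_radii):
    n = len(coords)
    radii = []
    for i in range(n):
        rho_i = float(gb_radii[i]) - _OFFSET
        integral = 0.0
        for j in range(n):
            if j == i:
                continue
            dx = coords[i][0] - coords[j][0]
            dy = coords[i][1] - coords[j][1]
            dz = coords[i][2] - coords[j][2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            s = _SCREEN * (float(gb_radii[j]) - _OFFSET)
            u = r + s
            if rho_i >= u:
                continue
            lo = max(rho_i, abs(r - s))
            term = 0.5 * (
                1.0 / lo
                - 1.0 / u
                + 0.25 * (r - s * s / r) * (1.0 / (u * u) - 1.0 / (lo * lo))
                + 0.5 / r * math.log(lo / u)
            )
            if rho_i < s - r:
                term += 1.0 / rho_i - 1.0 / lo
            integral += term
        psi = integral * rho_i
        inv_b = 1.0 / rho_i - math.tanh(_ALPHA * psi - _BETA * psi**2 + _GAMMA * psi**3) / float(
            gb_radii[i]
        )
        radii.append(1.0 / inv_b)
    return radii


def scalar_gb_energy(coords, charges, born, eps_in=1.0, eps_out=80.0, salt=0.15):
    kappa = _KAPPA_FACTOR * math.sqrt(salt)
    n = len(coords)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                f = born[i]
            else:
                dx = coords[i][0] - coords[j][0]
                dy = coords[i][1] - coords[j][1]
                dz = coords[i][2] - coords[j][2]
                r2 = dx * dx + dy * dy + dz * dz
                bb = born[i] * born[j]
                f = math.sqrt(r2 + bb * math.exp(-r2 / (4.0 * bb)))
            factor = 1.0 / eps_in - math.exp(-kappa * f) / eps_out
            total += -0.5 * _KE * factor * charges[i] * charges[j] / f
    return total


def scalar_nonbonded(coords, eps, rmin_half, charges, eps_in=1.0):
    n = len(coords)
    e_vdw = e_ele = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            dx = coords[i][0] - coords[j][0]
            dy = coords[i][1] - coords[j][1]
            dz = coords[i][2] - coords[j][2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            e_pair = math.sqrt(eps[i] * eps[j])
            rmin = rmin_half[i] + rmin_half[j]
            ratio6 = (rmin / r) ** 6
            e_vdw += e_pair * (ratio6 * ratio6 - 2.0 * ratio6)
            e_ele += _KE * charges[i] * charges[j] / (eps_in * r)
    return e_vdw, e_ele


def scalar_total(coords, eps, rmin_half, charges, gb_radii, surface_tension=0.0072, salt=0.15):
    e_vdw, e_ele = scalar_nonbonded(coords, eps, rmin_half, charges)
    born = scalar_born_radii(coords, gb_radii)
    e_pol = scalar_gb_energy(coords, charges, born, salt=salt)
    e_npol = surface_tension * sum(scalar_sasa(coords, gb_radii))
    return e_vdw + e_ele + e_pol + e_npol


def binding_oracle(ens, mask_a, surface_tension=0.0072, salt=0.15):
    """Brute-force single-trajectory binding energies for a two-part complex."""
    mask_a = np.asarray(mask_a, dtype=bool)
    idx_a = [i for i in range(ens.n_atoms) if mask_a[i]]
    idx_b = [i for i in range(ens.n_atoms) if not mask_a[i]]
    eps = [a.lj_epsilon for a in ens.atoms]
    rmh = [a.lj_rmin_half for a in ens.atoms]
    q = [a.charge for a in ens.atoms]
    rho = [a.gb_radius for a in ens.atoms]

    def part(values, idx):
        return [values[i] for i in idx]

    per_frame = []
    keys = [(a.chain, a.residue_id, a.residue_name) for a in ens.atoms]
    res_keys = sorted(set(keys))
    res_totals = {k: [] for k in res_keys}
    for f in range(ens.n_frames):
        coords = [tuple(map(float, c)) for c in ens.frames[f]]
        contribs = _per_atom_delta(
            coords, eps, rmh, q, rho, idx_a, idx_b, surface_tension, salt
        )
        per_frame.append(sum(contribs))
        frame_res = {k: 0.0 for k in res_keys}
        for atom_i, k in enumerate(keys):
            frame_res[k] += contribs[atom_i]
        for k in res_keys:
            res_totals[k].append(frame_res[k])
    per_residue = {
        k: (float(np.mean(v)), float(np.std(v))) for k, v in res_totals.items()
    }
    return {
        "per_frame": np.asarray(per_frame),
        "delta_g_mean": float(np.mean(per_frame)),
        "delta_g_sd": float(np.std(per_frame)),
        "per_residue": per_residue,
    }


def _per_atom_delta(coords, eps, rmh, q, rho, idx_a, idx_b, surface_tension, salt):
    n = len(coords)

    def system_per_atom(sub_idx):
        sub = [coords[i] for i in sub_idx]
        sub_eps = [eps[i] for i in sub_idx]
        sub_rmh = [rmh[i] for i in sub_idx]
        sub_q = [q[i] for i in sub_idx]
        sub_rho = [rho[i] for i in sub_idx]
        m = len(sub_idx)
        out = [0.0] * m
        # nonbonded pairs, split half/half
        for i in range(m):
            for j in range(i + 1, m):
                dx = sub[i][0] - sub[j][0]
                dy = sub[i][1] - sub[j][1]
                dz = sub[i][2] - sub[j][2]
                r = math.sqrt(dx * dx + dy * dy + dz * dz)
                e_pair = math.sqrt(sub_eps[i] * sub_eps[j])
                rmin = sub_rmh[i] + sub_rmh[j]
                ratio6 = (rmin / r) ** 6
                v = e_pair * (ratio6 * ratio6 - 2.0 * ratio6) + _KE * sub_q[i] * sub_q[j] / r
                out[i] += 0.5 * v
                out[j] += 0.5 * v
        born = scalar_born_radii(sub, sub_rho)
        kappa = _KAPPA_FACTOR * math.sqrt(salt)
        for i in range(m):
            f = born[i]
            factor = 1.0 - math.exp(-kappa * f) / 80.0
            out[i] += -0.5 * _KE * factor * sub_q[i] * sub_q[i] / f
            for j in range(i + 1, m):
                dx = sub[i][0] - sub[j][0]
                dy = sub[i][1] - sub[j][1]
                dz = sub[i][2] - sub[j][2]
                r2 = dx * dx + dy * dy + dz * dz
                bb = born[i] * born[j]
                f = math.sqrt(r2 + bb * math.exp(-r2 / (4.0 * bb)))
                factor = 1.0 - math.exp(-kappa * f) / 80.0
                term = -_KE * factor * sub_q[i] * sub_q[j] / f
                out[i] += 0.5 * term
                out[j] += 0.5 * term
        areas = scalar_sasa(sub, sub_rho)
        for i in range(m):
            out[i] += surface_tension * areas[i]
        return out

    whole = system_per_atom(list(range(n)))
    part_a = system_per_atom(idx_a)
    part_b = system_per_atom(idx_b)
    delta = list(whole)
    for local, i in enumerate(idx_a):
        delta[i] -= part_a[local]
    for local, i in enumerate(idx_b):
        delta[i] -= part_b[local]
    return delta
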