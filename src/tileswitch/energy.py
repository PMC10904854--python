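"""MM/GBSA energy function, binding energies, and per-residue decomposition.

The total energy of a conformation is

    G = E_bon + E_vdw + E_ele + E_pol + E_npol

with molecular-mechanics bonded and nonbonded terms, a Generalized Born polar
solvation energy built on OBC effective radii (the OBC-I parameterization,
alpha=0.8, beta=0, gamma=2.909125, over HCT pairwise descreening), and a
surface-area nonpolar term E_npol = gamma_surf * SASA + b.  Binding energies
follow the single-trajectory convention

    dG_bind = G(complex) - G(part A) - G(part B)

where parts are extracted from the complex frames, so E_bon cancels
identically.  Per-residue decomposition splits pair terms half/half between
the partner atoms' residues and assigns self/GB-self and SASA terms to the
owning residue; the residue means therefore sum exactly to the total.

Numeric conventions: Coulomb constant 332.0637 kcal·Å/mol/e²; Debye screening
of the GB pair term with kappa scaled by the conventional 0.73 factor; salt
affects only E_pol.  No parity with any MD package is claimed — correctness is
defined against the closed forms and brute-force oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import COULOMB_CONSTANT
from .ensembles import ConformerEnsemble, Selection, select

# OBC-I rescaling coefficients (the "IGB = 2" variant) and the HCT conventions.
OBC_I_COEFFS = (0.8, 0.0, 2.909125)
GB_RADIUS_OFFSET = 0.09  # Å subtracted from intrinsic radii before descreening
HCT_SCREEN = 0.8  # uniform descreening scale for bead/minimal systems
# Debye kappa in 1/Å from ionic strength in mol/L (300 K, water), times the
# conventional GB salt-scaling factor.
KAPPA_PER_SQRT_MOLAR = 0.32918
KAPPA_GB_SCALE = 0.73

# AMBER-convention 1-4 scaling when a bonded topology supplies exclusions.
SCEE = 1.2
SCNB = 2.0


@dataclass(frozen=True)
class GBSettings:
    """Continuum-solvent and surface-area settings."""

    solvent_dielectric: float = 80.0
    solute_dielectric: float = 1.0
    salt_molar: float = 0.15
    surface_tension: float = 0.0072  # kcal/mol/Å²
    sasa_offset_b: float = 0.0  # kcal/mol
    gb_variant: str = "OBC-I"
    sasa_probe_radius: float = 1.4  # Å
    sasa_points: int = 960

    def __post_init__(self):
        if self.solvent_dielectric <= 0 or self.solute_dielectric <= 0:
            raise ValueError("dielectrics must be positive")
        if self.surface_tension < 0:
            raise ValueError("surface tension must be non-negative")

    @property
    def kappa(self) -> float:
        return KAPPA_GB_SCALE * KAPPA_PER_SQRT_MOLAR * np.sqrt(self.salt_molar)


@dataclass(frozen=True)
class EnergyBreakdown:
    """Single-frame energy components in kcal/mol."""

    e_bon: float
    e_vdw: float
    e_ele: float
    e_pol: float
    e_npol: float

    @property
    def g_total(self) -> float:
        return self.e_bon + self.e_vdw + self.e_ele + self.e_pol + self.e_npol


@dataclass(frozen=True)
class BondedTopology:
    """Harmonic bonds/angles and cosine dihedrals; supplies exclusions.

    bonds: (i, j, k_r, r0); angles: (i, j, k, k_theta, theta0_rad);
    dihedrals: (i, j, k, l, k_phi, periodicity, phase_rad).
    """

    bonds: tuple = ()
    angles: tuple = ()
    dihedrals: tuple = ()

    def exclusion_maps(self, n_atoms: int):
        """(excluded, scaled14) symmetric boolean matrices from connectivity."""
        excluded = np.zeros((n_atoms, n_atoms), dtype=bool)
        scaled = np.zeros((n_atoms, n_atoms), dtype=bool)
        for i, j, *_ in self.bonds:
            excluded[i, j] = excluded[j, i] = True
        for i, j, k, *_ in self.angles:
            excluded[i, k] = excluded[k, i] = True
        for i, j, k, l, *_ in self.dihedrals:
            if not excluded[i, l]:
                scaled[i, l] = scaled[l, i] = True
        return excluded, scaled


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (Fibonacci spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def sasa(coords: np.ndarray, radii: np.ndarray, settings: GBSettings = GBSettings()) -> np.ndarray:
    """Shrake-Rupley per-atom solvent-accessible areas in Å².

    Sphere points are a deterministic golden spiral, so results are exactly
    reproducible for a given ``sasa_points``.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if (radii <= 0).any():
        raise ValueError("radii must be positive")
    n = len(coords)
    aug = radii + settings.sasa_probe_radius
    sphere = golden_spiral_points(settings.sasa_points)
    areas = np.empty(n)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    for i in range(n):
        pts = coords[i] + aug[i] * sphere
        neighbors = np.flatnonzero((d[i] < aug[i] + aug) & (np.arange(n) != i))
        if neighbors.size:
            dist2 = ((pts[:, None, :] - coords[neighbors][None, :, :]) ** 2).sum(-1)
            buried = (dist2 < aug[neighbors] ** 2).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * aug[i] ** 2 * frac
    return areas


def born_radii(
    coords: np.ndarray,
    gb_radii: np.ndarray,
    settings: GBSettings = GBSettings(),
    screen: float | np.ndarray = HCT_SCREEN,
) -> np.ndarray:
    """OBC effective Born radii from HCT pairwise descreening integrals."""
    coords = np.asarray(coords, dtype=float)
    rho = np.asarray(gb_radii, dtype=float)
    if (rho <= 0).any():
        raise ValueError("GB radii must be positive")
    alpha, beta, gamma = OBC_I_COEFFS
    rho_t = rho - GB_RADIUS_OFFSET  # reduced radii
    n = len(coords)
    sj = np.broadcast_to(np.asarray(screen, dtype=float) * rho_t, (n,)).astype(float)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    integral = np.zeros(n)
    for i in range(n):
        r = d[i]
        mask = np.arange(n) != i
        r, s = r[mask], sj[mask]
        u = r + s
        active = rho_t[i] < u
        if not active.any():
            continue
        r, s, u = r[active], s[active], u[active]
        lo = np.maximum(rho_t[i], np.abs(r - s))
        term = 0.5 * (
            1.0 / lo
            - 1.0 / u
            + 0.25 * (r - s**2 / r) * (1.0 / u**2 - 1.0 / lo**2)
            + 0.5 / r * np.log(lo / u)
        )
        inside = rho_t[i] < (s - r)
        term = term + np.where(inside, 1.0 / rho_t[i] - 1.0 / lo, 0.0)
        integral[i] = term.sum()
    psi = integral * rho_t
    inv_b = 1.0 / rho_t - np.tanh(alpha * psi - beta * psi**2 + gamma * psi**3) / rho
    return 1.0 / inv_b


def _gb_pair_f(d: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Still's smooth GB interaction distance f_ij (f_ii = B_i)."""
    bb = b[:, None] * b[None, :]
    return np.sqrt(d**2 + bb * np.exp(-(d**2) / (4.0 * bb)))


def gb_polar_energy(
    coords: np.ndarray,
    charges: np.ndarray,
    effective_radii: np.ndarray,
    settings: GBSettings = GBSettings(),
) -> float:
    """Polar solvation energy: the GB pair sum including self terms."""
    return _gb_pair_matrix(coords, charges, effective_radii, settings).sum()


def _gb_pair_matrix(coords, charges, effective_radii, settings) -> np.ndarray:
    """Symmetric matrix whose total is E_pol (off-diagonals hold half-terms)."""
    coords = np.asarray(coords, dtype=float)
    q = np.asarray(charges, dtype=float)
    b = np.asarray(effective_radii, dtype=float)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    f = _gb_pair_f(d, b)
    eps_factor = (
        1.0 / settings.solute_dielectric
        - np.exp(-settings.kappa * f) / settings.solvent_dielectric
    )
    return -0.5 * COULOMB_CONSTANT * eps_factor * np.outer(q, q) / f


def _nonbonded_matrices(coords, lj_eps, lj_rmin_half, charges, settings, topology):
    """Half-split symmetric vdW and electrostatic pair matrices."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    eps = np.sqrt(np.outer(lj_eps, lj_eps))
    rmin = np.add.outer(lj_rmin_half, lj_rmin_half)
    ratio6 = (rmin / d) ** 6
    vdw = eps * (ratio6**2 - 2.0 * ratio6)
    ele = COULOMB_CONSTANT * np.outer(charges, charges) / (settings.solute_dielectric * d)
    if topology is not None:
        excluded, scaled = topology.exclusion_maps(n)
        vdw[excluded] = 0.0
        ele[excluded] = 0.0
        vdw[scaled] /= SCNB
        ele[scaled] /= SCEE
    np.fill_diagonal(vdw, 0.0)
    np.fill_diagonal(ele, 0.0)
    return 0.5 * vdw, 0.5 * ele  # halves: matrix totals equal pair sums


def bonded_energy(coords: np.ndarray, topology: BondedTopology | None) -> float:
    """Harmonic bond/angle plus cosine dihedral energy (0 without topology)."""
    if topology is None:
        return 0.0
    coords = np.asarray(coords, dtype=float)
    e = 0.0
    for i, j, k_r, r0 in topology.bonds:
        e += k_r * (np.linalg.norm(coords[i] - coords[j]) - r0) ** 2
    for i, j, k, k_t, t0 in topology.angles:
        v1, v2 = coords[i] - coords[j], coords[k] - coords[j]
        cos = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        e += k_t * (np.arccos(np.clip(cos, -1, 1)) - t0) ** 2
    for i, j, k, l, k_p, n_per, phase in topology.dihedrals:
        b1, b2, b3 = coords[j] - coords[i], coords[k] - coords[j], coords[l] - coords[k]
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        m1 = np.cross(n1, b2 / np.linalg.norm(b2))
        phi = np.arctan2(np.dot(m1, n2), np.dot(n1, n2))
        e += k_p * (1.0 + np.cos(n_per * phi - phase))
    return float(e)


def mm_terms(
    coords: np.ndarray,
    lj_eps: np.ndarray,
    lj_rmin_half: np.ndarray,
    charges: np.ndarray,
    settings: GBSettings = GBSettings(),
    topology: BondedTopology | None = None,
) -> tuple[float, float, float]:
    """(E_bon, E_vdw, E_ele).  Without a topology all pairs interact and E_bon=0;
    with one, 1-2/1-3 pairs are excluded and 1-4 pairs scaled (1/2.0, 1/1.2)."""
    vdw_m, ele_m = _nonbonded_matrices(coords, lj_eps, lj_rmin_half, charges, settings, topology)
    return bonded_energy(coords, topology), float(vdw_m.sum()), float(ele_m.sum())


def _per_atom_components(ens: ConformerEnsemble, frame_idx: int, settings, topology):
    """Per-atom attributions (vdw, ele, pol, npol) for one frame.

    Pair terms are already half-split in the matrices, so row sums attribute
    half of every pair term to each partner; GB diagonal (self) terms belong
    wholly to the owning atom.
    """
    coords = ens.frames[frame_idx]
    vdw_m, ele_m = _nonbonded_matrices(
        coords, ens.lj_epsilon, ens.lj_rmin_half, ens.charges, settings, topology
    )
    b = born_radii(coords, ens.gb_radius, settings)
    gb_m = _gb_pair_matrix(coords, ens.charges, b, settings)
    # row sums: diagonal (self) term once in full, each pair term half per partner
    gb_atom = gb_m.sum(axis=1)
    areas = sasa(coords, ens.gb_radius, settings)
    return {
        "vdw": vdw_m.sum(axis=1),
        "ele": ele_m.sum(axis=1),
        "pol": gb_atom,
        "npol": settings.surface_tension * areas,
    }


def total_energy(
    ens: ConformerEnsemble,
    frame_idx: int = 0,
    settings: GBSettings = GBSettings(),
    topology: BondedTopology | None = None,
) -> EnergyBreakdown:
    """Full single-frame energy breakdown (the landscape "enthalpic energy")."""
    coords = ens.frames[frame_idx]
    e_bon, e_vdw, e_ele = mm_terms(
        coords, ens.lj_epsilon, ens.lj_rmin_half, ens.charges, settings, topology
    )
    b = born_radii(coords, ens.gb_radius, settings)
    e_pol = float(gb_polar_energy(coords, ens.charges, b, settings))
    e_npol = float(
        settings.surface_tension * sasa(coords, ens.gb_radius, settings).sum()
        + settings.sasa_offset_b
    )
    return EnergyBreakdown(e_bon, e_vdw, e_ele, e_pol, e_npol)


def ensemble_energies(
    ens: ConformerEnsemble,
    settings: GBSettings = GBSettings(),
    topology: BondedTopology | None = None,
    n_frames: int | None = 5000,
) -> pd.DataFrame:
    """Per-frame energy table (evenly subsampled to ``n_frames`` frames)."""
    sub = ens.subsample(n_frames) if n_frames else ens
    rows = []
    for f in range(sub.n_frames):
        bd = total_energy(sub, f, settings, topology)
        rows.append(
            {
                "frame": f,
                "e_bon": bd.e_bon,
                "e_vdw": bd.e_vdw,
                "e_ele": bd.e_ele,
                "e_pol": bd.e_pol,
                "e_npol": bd.e_npol,
                "g_total": bd.g_total,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BindingResult:
    """Mean ± SD binding energy and per-residue contributions over frames."""

    delta_g_mean: float
    delta_g_sd: float
    n_frames: int
    per_residue: dict  # (chain, residue_id, residue_name) -> (mean, sd)
    per_frame: np.ndarray

    def filtered_report(self, threshold: float = -2.0) -> pd.DataFrame:
        """Residues with mean contribution <= threshold (default -2 kcal/mol)."""
        rows = [
            {
                "chain": k[0],
                "residue_id": k[1],
                "residue_name": k[2],
                "mean": v[0],
                "sd": v[1],
                "flag": v[0] <= threshold,
            }
            for k, v in self.per_residue.items()
        ]
        table = pd.DataFrame(rows).sort_values(["chain", "residue_id"], ignore_index=True)
        return table[table["flag"]].reset_index(drop=True)

    def decomposition_table(self) -> pd.DataFrame:
        rows = [
            {"chain": k[0], "residue_id": k[1], "residue_name": k[2], "mean": v[0], "sd": v[1]}
            for k, v in self.per_residue.items()
        ]
        return pd.DataFrame(rows).sort_values(["chain", "residue_id"], ignore_index=True)


def binding_energy(
    complex_ens: ConformerEnsemble,
    sel_a: Selection,
    sel_b: Selection,
    settings: GBSettings = GBSettings(),
    n_frames: int | None = 1000,
) -> BindingResult:
    """Single-trajectory dG_bind with per-residue decomposition.

    ``sel_a`` and ``sel_b`` must partition the complex atoms; parts are scored
    on the complex frames, so bonded terms cancel and the difference reduces to
    cross-interactions plus desolvation (Born radii and SASA changes).
    """
    mask_a = sel_a.mask(complex_ens.atoms)
    mask_b = sel_b.mask(complex_ens.atoms)
    if (mask_a & mask_b).any():
        raise ValueError("partner selections overlap")
    if not (mask_a | mask_b).all():
        raise ValueError("partner selections must partition the complex atoms")
    sub = complex_ens.subsample(n_frames) if n_frames else complex_ens
    part_a = select(sub, sel_a)
    part_b = select(sub, sel_b)
    idx_a = np.flatnonzero(mask_a)
    idx_b = np.flatnonzero(mask_b)

    n_atoms = sub.n_atoms
    per_atom_frames = np.empty((sub.n_frames, n_atoms))
    for f in range(sub.n_frames):
        comp = _per_atom_components(sub, f, settings, topology=None)
        pa = _per_atom_components(part_a, f, settings, topology=None)
        pb = _per_atom_components(part_b, f, settings, topology=None)
        delta = np.zeros(n_atoms)
        for key in ("vdw", "ele", "pol", "npol"):
            delta += comp[key]
            delta[idx_a] -= pa[key]
            delta[idx_b] -= pb[key]
        per_atom_frames[f] = delta

    per_frame = per_atom_frames.sum(axis=1)
    keys = [(a.chain, a.residue_id, a.residue_name) for a in sub.atoms]
    unique_keys = sorted(set(keys))
    res_frames = np.zeros((sub.n_frames, len(unique_keys)))
    key_index = {k: i for i, k in enumerate(unique_keys)}
    for atom_i, k in enumerate(keys):
        res_frames[:, key_index[k]] += per_atom_frames[:, atom_i]
    per_residue = {
        k: (float(res_frames[:, i].mean()), float(res_frames[:, i].std()))
        for k, i in key_index.items()
    }
    return BindingResult(
        delta_g_mean=float(per_frame.mean()),
        delta_g_sd=float(per_frame.std()),
        n_frames=sub.n_frames,
        per_residue=per_residue,
        per_frame=per_frame,
    )


def residue_decomposition(result: BindingResult, threshold: float = -2.0) -> pd.DataFrame:
    """Filtered per-residue report: mean ± SD for residues <= threshold."""
    return result.filtered_report(threshold)
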