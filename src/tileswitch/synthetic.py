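"""Seeded generators emulating the statistical structure of MD ensembles.

The chain model is a deliberate reduction of all-atom peptide simulations: one
bead per residue on 3.8 Å virtual bonds, hard-core excluded volume, a
square-well attraction between designated "sticky" (hydrophobic) beads that
drives hydrophobic collapse, and a bending stiffness that keeps the
non-interacting chain extended.  Ensembles are sampled by pivot Monte Carlo,
whose stationary distribution is exact; a probe- or ligand-induced shift
toward the compact state is emulated by raising the sticky-contact strength.
A 50-residue chain spans mean R_g from above 20 Å (contact strength 0) to
below 12 Å (strong contacts), covering broad/extended and compact regimes.

Everything is reproducible from an integer seed, and every generator emits
its ground truth (frame labels, planted contacts, oracle energies).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numba import njit

from .constants import THREE_LETTER
from .ensembles import AtomRecord, ConformerEnsemble, merge_parameters, read_param_table
from . import _oracle


@dataclass(frozen=True)
class ChainModel:
    """Bead-chain model parameters (energies in units of kT)."""

    n_residues: int
    bond_length: float = 3.8  # Å
    hard_core: float = 4.0  # Å, nonadjacent bead exclusion
    well_range: float = 7.0  # Å, sticky square-well range
    contact_strength: float = 0.0  # well depth epsilon_c, kT; >= 0
    stiffness: float = 2.0  # bending kappa, kT
    kT: float = 1.0
    sticky_positions: frozenset | None = None  # 1-based; None = all beads
    sequence: str | None = None  # one-letter codes; None = poly-A

    def __post_init__(self):
        if self.n_residues < 2:
            raise ValueError("need at least two residues")
        if self.contact_strength < 0:
            raise ValueError("contact strength must be non-negative")

    @property
    def sticky_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_residues, dtype=bool)
        if self.sticky_positions is None:
            mask[:] = True
        else:
            mask[[p - 1 for p in self.sticky_positions]] = True
        return mask


@dataclass(frozen=True)
class MixtureSpec:
    """Two-state compact/extended mixture specification."""

    p_compact: float
    compact: ChainModel
    extended: ChainModel
    n_frames: int
    seed: int

    def __post_init__(self):
        if not 0 <= self.p_compact <= 1:
            raise ValueError("p_compact must lie in [0, 1]")


# Default regimes for 50-residue tiles: the compact model collapses to the
# narrow distributions of switch-hit tiles (mean ~10-12 Å), the extended model
# reproduces the broad sampling (mean > 20 Å, excursions to ~35 Å).
def compact_model(n_residues: int = 50, **kw) -> ChainModel:
    return ChainModel(n_residues, contact_strength=0.5, **kw)


def extended_model(n_residues: int = 50, **kw) -> ChainModel:
    return ChainModel(n_residues, contact_strength=0.0, **kw)


def _chain_topology(model: ChainModel, chain: str = "A", first_res: int = 1):
    seq = model.sequence or "A" * model.n_residues
    atoms = []
    for i, aa in enumerate(seq):
        atoms.append(
            AtomRecord(
                index=i,
                name="CA",
                element="C",
                residue_id=first_res + i,
                residue_name=THREE_LETTER[aa],
                chain=chain,
            )
        )
    return tuple(atoms)


@njit(cache=True)
def _mc_kernel(
    x, sticky, hc2, well2, eps_c, stiffness, kt,
    kinds, pivots, crank_i, crank_j, quats, axes, angles, metro,
    burn_in, stride, frames_out,
):  # pragma: no cover - exercised through sample_chain
    n = x.shape[0]
    n_frames = frames_out.shape[0]
    total = burn_in + stride * n_frames
    rec = 0
    xn = np.empty((n, 3))
    rot = np.empty((3, 3))
    for mv in range(total):
        kind = kinds[mv]
        if kind < 2:  # pivot (uniform or small-angle)
            p = pivots[mv]
            a, b = p + 1, n
            cx, cy, cz = x[p, 0], x[p, 1], x[p, 2]
            j0, j1 = p, -1
        else:  # crankshaft about the chord x[i]..x[j]
            i = crank_i[mv]
            j = crank_j[mv]
            a, b = i + 1, j
            cx, cy, cz = x[i, 0], x[i, 1], x[i, 2]
            j0, j1 = i, j
        if kind == 0:  # uniform rotation from a unit quaternion
            qw, qx, qy, qz = quats[mv]
            rot[0, 0] = 1 - 2 * (qy * qy + qz * qz)
            rot[0, 1] = 2 * (qx * qy - qw * qz)
            rot[0, 2] = 2 * (qx * qz + qw * qy)
            rot[1, 0] = 2 * (qx * qy + qw * qz)
            rot[1, 1] = 1 - 2 * (qx * qx + qz * qz)
            rot[1, 2] = 2 * (qy * qz - qw * qx)
            rot[2, 0] = 2 * (qx * qz - qw * qy)
            rot[2, 1] = 2 * (qy * qz + qw * qx)
            rot[2, 2] = 1 - 2 * (qx * qx + qy * qy)
        else:  # axis-angle; crankshaft uses the chord as axis
            if kind == 1:
                ax, ay, az = axes[mv]
            else:
                ax = x[j1, 0] - x[j0, 0]
                ay = x[j1, 1] - x[j0, 1]
                az = x[j1, 2] - x[j0, 2]
            norm = np.sqrt(ax * ax + ay * ay + az * az)
            ax, ay, az = ax / norm, ay / norm, az / norm
            ang = angles[mv]
            c, s = np.cos(ang), np.sin(ang)
            t = 1 - c
            rot[0, 0] = c + t * ax * ax
            rot[0, 1] = t * ax * ay - s * az
            rot[0, 2] = t * ax * az + s * ay
            rot[1, 0] = t * ax * ay + s * az
            rot[1, 1] = c + t * ay * ay
            rot[1, 2] = t * ay * az - s * ax
            rot[2, 0] = t * ax * az - s * ay
            rot[2, 1] = t * ay * az + s * ax
            rot[2, 2] = c + t * az * az
        for t_i in range(a, b):
            dx, dy, dz = x[t_i, 0] - cx, x[t_i, 1] - cy, x[t_i, 2] - cz
            xn[t_i, 0] = rot[0, 0] * dx + rot[0, 1] * dy + rot[0, 2] * dz + cx
            xn[t_i, 1] = rot[1, 0] * dx + rot[1, 1] * dy + rot[1, 2] * dz + cy
            xn[t_i, 2] = rot[2, 0] * dx + rot[2, 1] * dy + rot[2, 2] * dz + cz
        # hard-core exclusion between the moved block and the rest (|i-j| >= 2)
        overlap = False
        for t_i in range(a, b):
            for r in range(n):
                if a <= r < b:
                    continue
                sep = t_i - r if t_i > r else r - t_i
                if sep < 2:
                    continue
                dx = xn[t_i, 0] - x[r, 0]
                dy = xn[t_i, 1] - x[r, 1]
                dz = xn[t_i, 2] - x[r, 2]
                if dx * dx + dy * dy + dz * dz < hc2:
                    overlap = True
                    break
            if overlap:
                break
        accept = False
        if not overlap:
            de = 0.0
            if stiffness > 0.0:
                for which in range(2):
                    jn = j0 if which == 0 else j1
                    if jn < 1 or jn > n - 2:
                        continue
                    v1x = x[jn - 1, 0] - x[jn, 0]
                    v1y = x[jn - 1, 1] - x[jn, 1]
                    v1z = x[jn - 1, 2] - x[jn, 2]
                    v2x = x[jn + 1, 0] - x[jn, 0]
                    v2y = x[jn + 1, 1] - x[jn, 1]
                    v2z = x[jn + 1, 2] - x[jn, 2]
                    cos_old = (v1x * v2x + v1y * v2y + v1z * v2z) / np.sqrt(
                        (v1x * v1x + v1y * v1y + v1z * v1z)
                        * (v2x * v2x + v2y * v2y + v2z * v2z)
                    )
                    # neighbours of the joint, with moved block substituted
                    w1x = (xn[jn - 1, 0] if a <= jn - 1 < b else x[jn - 1, 0]) - (
                        xn[jn, 0] if a <= jn < b else x[jn, 0]
                    )
                    w1y = (xn[jn - 1, 1] if a <= jn - 1 < b else x[jn - 1, 1]) - (
                        xn[jn, 1] if a <= jn < b else x[jn, 1]
                    )
                    w1z = (xn[jn - 1, 2] if a <= jn - 1 < b else x[jn - 1, 2]) - (
                        xn[jn, 2] if a <= jn < b else x[jn, 2]
                    )
                    w2x = (xn[jn + 1, 0] if a <= jn + 1 < b else x[jn + 1, 0]) - (
                        xn[jn, 0] if a <= jn < b else x[jn, 0]
                    )
                    w2y = (xn[jn + 1, 1] if a <= jn + 1 < b else x[jn + 1, 1]) - (
                        xn[jn, 1] if a <= jn < b else x[jn, 1]
                    )
                    w2z = (xn[jn + 1, 2] if a <= jn + 1 < b else x[jn + 1, 2]) - (
                        xn[jn, 2] if a <= jn < b else x[jn, 2]
                    )
                    cos_new = (w1x * w2x + w1y * w2y + w1z * w2z) / np.sqrt(
                        (w1x * w1x + w1y * w1y + w1z * w1z)
                        * (w2x * w2x + w2y * w2y + w2z * w2z)
                    )
                    # stiffness penalizes deviation from straight (cos -> -1)
                    de += stiffness * (cos_new - cos_old)
            if eps_c > 0.0:
                n_new = 0
                n_old = 0
                for t_i in range(a, b):
                    if not sticky[t_i]:
                        continue
                    for r in range(n):
                        if a <= r < b or not sticky[r]:
                            continue
                        sep = t_i - r if t_i > r else r - t_i
                        if sep < 3:
                            continue
                        dx = xn[t_i, 0] - x[r, 0]
                        dy = xn[t_i, 1] - x[r, 1]
                        dz = xn[t_i, 2] - x[r, 2]
                        if dx * dx + dy * dy + dz * dz < well2:
                            n_new += 1
                        dx = x[t_i, 0] - x[r, 0]
                        dy = x[t_i, 1] - x[r, 1]
                        dz = x[t_i, 2] - x[r, 2]
                        if dx * dx + dy * dy + dz * dz < well2:
                            n_old += 1
                de -= eps_c * (n_new - n_old)
            accept = de <= 0.0 or metro[mv] < np.exp(-de / kt)
        if accept:
            for t_i in range(a, b):
                x[t_i, 0] = xn[t_i, 0]
                x[t_i, 1] = xn[t_i, 1]
                x[t_i, 2] = xn[t_i, 2]
        if mv >= burn_in and (mv - burn_in + 1) % stride == 0:
            for t_i in range(n):
                frames_out[rec, t_i, 0] = x[t_i, 0]
                frames_out[rec, t_i, 1] = x[t_i, 1]
                frames_out[rec, t_i, 2] = x[t_i, 2]
            rec += 1


def sample_chain(
    model: ChainModel,
    n_frames: int,
    seed: int,
    stride: int | None = None,
    burn_in: int | None = None,
) -> ConformerEnsemble:
    """Pivot/crankshaft Monte-Carlo sample, one frame per ``stride`` moves.

    Three move kinds keep the chain ergodic in both regimes: uniform-rotation
    pivots (efficient when extended), small-angle pivots, and crankshaft
    rotations of internal segments about their chord (which relax collapsed
    globules, where large pivots are always rejected).  Frames are recorded
    every 2N attempted moves after a 60N-move burn-in from a straight start
    (long enough to cross the collapse transition at strong sticky contacts).
    All randomness is pre-drawn from one seeded generator, so trajectories are
    exactly reproducible from the seed.
    """
    n = model.n_residues
    stride = stride or 2 * n
    burn_in = burn_in if burn_in is not None else 60 * n
    rng = np.random.default_rng(seed)
    total = burn_in + stride * n_frames
    u = rng.random(total)
    kinds = np.where(u < 0.4, 0, np.where(u < 0.6, 1, 2)).astype(np.int64)
    pivots = rng.integers(1, n - 1, size=total)
    crank_i = rng.integers(0, n - 4, size=total)
    crank_j = np.minimum(crank_i + rng.integers(3, 14, size=total), n - 1)
    quats = rng.normal(size=(total, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    axes = rng.normal(size=(total, 3))
    raw_angles = rng.normal(size=total)
    angles = np.where(kinds == 1, 0.3 * raw_angles, 1.2 * raw_angles)
    metro = rng.random(total)
    x = np.zeros((n, 3))
    x[:, 0] = np.arange(n) * model.bond_length
    frames = np.empty((n_frames, n, 3))
    _mc_kernel(
        x, model.sticky_mask, model.hard_core**2, model.well_range**2,
        model.contact_strength, model.stiffness, model.kT,
        kinds, pivots, crank_i, crank_j, quats, axes, angles, metro,
        burn_in, stride, frames,
    )
    frames -= frames.mean(axis=1, keepdims=True)
    ens = ConformerEnsemble(
        _chain_topology(model), frames, provenance=f"sample_chain(seed={seed})"
    )
    return merge_parameters(ens, read_param_table())


def calibrate_compaction(
    target_mean_rg: float,
    template: ChainModel,
    tolerance: float = 0.75,
    eps_bounds: tuple[float, float] = (0.0, 1.0),
    n_frames: int = 120,
    seed: int = 1234,
    max_iter: int = 12,
) -> tuple[ChainModel, float]:
    """Bisection on the sticky-contact strength to hit a target mean R_g.

    Mean R_g decreases monotonically with contact strength over the bracket;
    a target outside the bracket's achievable range raises with the bracket
    values reported.
    """
    from .metrics import rg_series

    def mean_rg(eps):
        m = replace(template, contact_strength=eps)
        return m, float(rg_series(sample_chain(m, n_frames, seed)).values.mean())

    lo_model, rg_lo = mean_rg(eps_bounds[0])  # weakest contacts: largest Rg
    hi_model, rg_hi = mean_rg(eps_bounds[1])
    if not (rg_hi - tolerance <= target_mean_rg <= rg_lo + tolerance):
        raise ValueError(
            f"target {target_mean_rg:.2f} Å outside achievable bracket "
            f"[{rg_hi:.2f}, {rg_lo:.2f}] Å for eps in {eps_bounds}"
        )
    lo, hi = eps_bounds
    model, achieved = lo_model, rg_lo
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        model, achieved = mean_rg(mid)
        if abs(achieved - target_mean_rg) < tolerance:
            break
        if achieved > target_mean_rg:
            lo = mid  # too extended: strengthen contacts
        else:
            hi = mid
    return model, achieved


def mixture_ensemble(spec: MixtureSpec) -> tuple[ConformerEnsemble, np.ndarray]:
    """Two-state mixture ensemble plus per-frame ground-truth labels."""
    rng = np.random.default_rng(spec.seed)
    labels = np.where(rng.random(spec.n_frames) < spec.p_compact, "compact", "extended")
    n_comp = int((labels == "compact").sum())
    pools = {}
    if n_comp:
        pools["compact"] = sample_chain(spec.compact, n_comp, seed=spec.seed + 1)
    if spec.n_frames - n_comp:
        pools["extended"] = sample_chain(spec.extended, spec.n_frames - n_comp, seed=spec.seed + 2)
    template = pools[labels[0]]
    frames = np.empty((spec.n_frames, template.n_atoms, 3))
    counters = {"compact": 0, "extended": 0}
    for f, lab in enumerate(labels):
        frames[f] = pools[lab].frames[counters[lab]]
        counters[lab] += 1
    ens = ConformerEnsemble(
        template.atoms, frames, provenance=f"mixture(p={spec.p_compact},seed={spec.seed})"
    )
    return ens, labels


def plant_ligand(
    ens: ConformerEnsemble,
    sticky_residues,
    occupancy: float,
    contact_distance: float = 4.0,
    n_ligand_atoms: int = 2,
    seed: int = 0,
) -> tuple[ConformerEnsemble, pd.DataFrame]:
    """Append pseudo-ligand atoms bound to a random sticky residue per frame.

    With probability ``occupancy`` the ligand atoms are placed within
    ``contact_distance`` of a randomly chosen sticky residue; otherwise beyond
    twice that distance from every chain atom.  The returned truth table
    records the per-frame bound state and target residue.
    """
    if not 0 <= occupancy <= 1:
        raise ValueError("occupancy must lie in [0, 1]")
    sticky_residues = list(sticky_residues)
    rng = np.random.default_rng(seed)
    resid_arr = ens.residue_ids
    max_res = int(resid_arr.max())
    lig_atoms = tuple(
        AtomRecord(
            index=ens.n_atoms + k,
            name=f"C{k + 1}",
            element="C",
            residue_id=max_res + 1,
            residue_name="LIG",
            chain="L",
        )
        for k in range(n_ligand_atoms)
    )
    frames = np.empty((ens.n_frames, ens.n_atoms + n_ligand_atoms, 3))
    records = []
    for f in range(ens.n_frames):
        chain_xyz = ens.frames[f]
        bound = rng.random() < occupancy
        if bound:
            target = int(rng.choice(sticky_residues))
            center = chain_xyz[resid_arr == target].mean(axis=0)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            anchor = center + direction * (0.5 * contact_distance)
        else:
            target = -1
            com = chain_xyz.mean(axis=0)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            max_extent = np.linalg.norm(chain_xyz - com, axis=1).max()
            anchor = com + direction * (max_extent + 3.0 * contact_distance)
        lig = anchor + rng.normal(scale=0.3, size=(n_ligand_atoms, 3))
        frames[f, : ens.n_atoms] = chain_xyz
        frames[f, ens.n_atoms:] = lig
        records.append({"frame": f, "bound": bound, "target_residue": target})
    out = ConformerEnsemble(ens.atoms + lig_atoms, frames, ens.provenance + "+ligand")
    out = merge_parameters(out, read_param_table())
    return out, pd.DataFrame(records)


# --- toy two-chain complex with stored brute-force oracle energies ---------

_TOY_SEQ_A = "KAELAD"  # chain A residues 1-6
_TOY_SEQ_B = "EAKAL"  # chain B residues 101-105


def toy_complex(seed: int = 0, n_frames: int = 20, jitter: float = 0.25):
    """Two short bead chains in contact, with oracle binding energies.

    Returns ``(ensemble, oracle)`` where ``oracle`` holds the brute-force
    (scalar-transcription) per-frame binding energies and per-residue means,
    computed independently of the vectorized energy engine.  The facing
    charged pairs (A:K1/B:E101 and A:E3/B:K103) are constructed to contribute
    strongly favorable (< -2 kcal/mol) electrostatics.
    """
    rng = np.random.default_rng(seed)
    atoms_a = _chain_topology(
        ChainModel(len(_TOY_SEQ_A), sequence=_TOY_SEQ_A), chain="A", first_res=1
    )
    atoms_b = tuple(
        replace(a, index=a.index + len(_TOY_SEQ_A))
        for a in _chain_topology(
            ChainModel(len(_TOY_SEQ_B), sequence=_TOY_SEQ_B), chain="B", first_res=101
        )
    )
    base_a = np.column_stack(
        [np.arange(len(_TOY_SEQ_A)) * 3.8, np.zeros(len(_TOY_SEQ_A)), np.zeros(len(_TOY_SEQ_A))]
    )
    base_b = np.column_stack(
        [np.arange(len(_TOY_SEQ_B)) * 3.8, np.full(len(_TOY_SEQ_B), 4.3), np.zeros(len(_TOY_SEQ_B))]
    )
    base = np.vstack([base_a, base_b])
    frames = base[None, :, :] + rng.normal(scale=jitter, size=(n_frames, len(base), 3))
    ens = merge_parameters(
        ConformerEnsemble(atoms_a + atoms_b, frames, provenance=f"toy_complex(seed={seed})"),
        read_param_table(),
    )
    mask_a = np.array([a.chain == "A" for a in ens.atoms])
    oracle = _oracle.binding_oracle(ens, mask_a)
    return ens, oracle


def labels_to_tsv(labels: np.ndarray, path) -> None:
    pd.DataFrame({"frame": range(len(labels)), "label": labels}).to_csv(
        path, sep="\t", index=False
    )
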