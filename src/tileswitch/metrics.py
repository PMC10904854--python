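"""Per-frame geometry statistics, R_g distributions, and the switch decision rule.

A conformational switch is called when a probe/ligand condition compacts an
ensemble relative to water: the interquartile spread shrinks, the extended
tail (R_g above a compact/extended boundary, default 15 Å) empties, and the
two empirical R_g distributions separate by Kolmogorov-Smirnov distance.  All
three must clear their thresholds for a tile to be flagged; the visual analogue
is a broad reference histogram collapsing onto a narrow compact one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .ensembles import ConformerEnsemble, Selection, select

#: Compact/extended boundary in Å: compact tiles sit in narrow distributions
#: around ~15 Å, extended excursions reach ~35 Å.
DEFAULT_TAIL_THRESHOLD = 15.0

#: Default flagging thresholds: spread_reduction >= r*, tail_depletion >= t*,
#: KS distance >= d*.
DEFAULT_SWITCH_RULE = {"spread_reduction": 0.5, "tail_depletion": 0.25, "ks_d": 0.3}


@dataclass(frozen=True)
class RgSeries:
    """Frame-ordered radii of gyration in Å."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.size < 1:
            raise ValueError("empty R_g series")
        if (v < 0).any():
            raise ValueError("R_g values must be non-negative")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class RgDistribution:
    bin_edges: np.ndarray
    frequencies: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        freqs = np.asarray(self.frequencies, dtype=float)
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        if (freqs < 0).any() or abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must be non-negative and sum to 1")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "frequencies", freqs)


@dataclass(frozen=True)
class SwitchScore:
    """Water-vs-probe comparison statistics for one tile."""

    mean_shift: float
    spread_reduction: float
    tail_depletion: float
    ks_d: float
    flagged: bool
    degenerate_reference: bool = False


@dataclass(frozen=True)
class Landscape:
    """(R_g, min-max-normalized energy) points, optionally histogrammed."""

    rg: np.ndarray
    energy_norm: np.ndarray
    domain: str = "separate"

    def __post_init__(self):
        rg = np.asarray(self.rg, dtype=float)
        en = np.asarray(self.energy_norm, dtype=float)
        if rg.shape != en.shape:
            raise ValueError("R_g and energy arrays must align")
        if en.size and (en.min() < -1e-12 or en.max() > 1 + 1e-12):
            raise ValueError("normalized energies must lie in [0, 1]")
        object.__setattr__(self, "rg", rg)
        object.__setattr__(self, "energy_norm", en)

    def histogram2d(self, rg_bins=40, e_bins=20):
        return np.histogram2d(self.rg, self.energy_norm, bins=[rg_bins, e_bins])


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted RMS distance from the mass-weighted centroid, in Å."""
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise ValueError("need at least one atom")
    if (masses <= 0).any():
        raise ValueError("masses must be positive")
    com = np.average(coords, axis=0, weights=masses)
    sq = ((coords - com) ** 2).sum(axis=1)
    return float(np.sqrt(np.average(sq, weights=masses)))


def rg_series(ens: ConformerEnsemble, sel: Selection | None = None) -> RgSeries:
    """Per-frame R_g of the selected atoms."""
    if sel is not None:
        ens = select(ens, sel)
    masses = ens.masses
    return RgSeries(
        np.array([radius_of_gyration(ens.frames[f], masses) for f in range(ens.n_frames)])
    )


def rg_histogram(
    series: RgSeries,
    bin_width: float | None = 1.0,
    bin_count: int | None = None,
    range_: tuple[float, float] | None = (0.0, 40.0),
) -> RgDistribution:
    """Normalized R_g frequency distribution (default 1 Å bins over 0-40 Å)."""
    values = series.values
    lo, hi = range_ if range_ is not None else (values.min(), values.max())
    lo, hi = min(lo, values.min()), max(hi, values.max() + 1e-9)
    if bin_count is not None:
        edges = np.linspace(lo, hi, bin_count + 1)
    else:
        if bin_width is None or bin_width <= 0:
            raise ValueError("bin width must be positive")
        edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    return RgDistribution(edges, counts / counts.sum())


def ks_statistic(a: RgSeries, b: RgSeries) -> float:
    """Two-sample Kolmogorov-Smirnov distance (sup over ECDF differences)."""
    return float(_stats.ks_2samp(a.values, b.values, method="asymp").statistic)


def spread_stats(series: RgSeries, tail_threshold: float = DEFAULT_TAIL_THRESHOLD) -> dict:
    """Order statistics of an R_g series (type-7 percentiles).

    Returns mean, sd (population), IQR, the 5th-95th percentile width, and the
    fraction of frames above ``tail_threshold``.
    """
    v = series.values
    q5, q25, q75, q95 = np.percentile(v, [5, 25, 75, 95])
    return {
        "mean": float(v.mean()),
        "sd": float(v.std()),
        "iqr": float(q75 - q25),
        "p5_p95_width": float(q95 - q5),
        "tail_fraction": float((v > tail_threshold).mean()),
        "tail_threshold": float(tail_threshold),
    }


def switch_statistic(
    reference: RgSeries,
    perturbed: RgSeries,
    rule: dict | None = None,
    tail_threshold: float = DEFAULT_TAIL_THRESHOLD,
) -> SwitchScore:
    """Quantify probe-induced compaction of ``perturbed`` vs ``reference``.

    mean_shift = mean(ref) - mean(pert); spread_reduction = 1 - IQR ratio;
    tail_depletion = P_ref(R_g > T) - P_pert(R_g > T).  Flagged when all three
    of spread_reduction, tail_depletion, and the KS distance clear the rule's
    thresholds.  A zero-IQR reference makes spread_reduction undefined; it is
    reported as 0 with ``degenerate_reference`` set.
    """
    thresholds = dict(DEFAULT_SWITCH_RULE)
    if rule:
        thresholds.update(rule)
    ref_stats = spread_stats(reference, tail_threshold)
    pert_stats = spread_stats(perturbed, tail_threshold)
    degenerate = ref_stats["iqr"] == 0
    spread_reduction = 0.0 if degenerate else 1.0 - pert_stats["iqr"] / ref_stats["iqr"]
    tail_depletion = ref_stats["tail_fraction"] - pert_stats["tail_fraction"]
    ks_d = ks_statistic(reference, perturbed)
    flagged = (
        not degenerate
        and spread_reduction >= thresholds["spread_reduction"]
        and tail_depletion >= thresholds["tail_depletion"]
        and ks_d >= thresholds["ks_d"]
    )
    return SwitchScore(
        mean_shift=ref_stats["mean"] - pert_stats["mean"],
        spread_reduction=spread_reduction,
        tail_depletion=tail_depletion,
        ks_d=ks_d,
        flagged=flagged,
        degenerate_reference=degenerate,
    )


def landscape(
    series: RgSeries,
    energies: np.ndarray,
    domain: str = "separate",
    norm_bounds: tuple[float, float] | None = None,
) -> Landscape:
    """R_g vs min-max-normalized energy points.

    ``norm_bounds`` overrides the normalization domain (pass the pooled min/max
    when comparing two ensembles on a joint scale — the default for paired
    comparisons via :func:`paired_landscapes`).
    """
    energies = np.asarray(energies, dtype=float)
    if energies.shape != series.values.shape:
        raise ValueError("series and energies must have equal length")
    lo, hi = norm_bounds if norm_bounds is not None else (energies.min(), energies.max())
    if hi == lo:
        import warnings

        warnings.warn("all energies identical; normalized landscape is flat at 0")
        norm = np.zeros_like(energies)
    else:
        norm = (energies - lo) / (hi - lo)
    return Landscape(series.values, norm, domain)


def paired_landscapes(
    ref_series: RgSeries,
    ref_energies,
    pert_series: RgSeries,
    pert_energies,
    domain: str = "joint",
) -> tuple[Landscape, Landscape]:
    """Landscapes for two conditions; joint domain pools energies before min-max."""
    ref_energies = np.asarray(ref_energies, dtype=float)
    pert_energies = np.asarray(pert_energies, dtype=float)
    if domain == "joint":
        pooled = np.concatenate([ref_energies, pert_energies])
        bounds = (pooled.min(), pooled.max())
        return (
            landscape(ref_series, ref_energies, "joint", bounds),
            landscape(pert_series, pert_energies, "joint", bounds),
        )
    return (
        landscape(ref_series, ref_energies, "separate"),
        landscape(pert_series, pert_energies, "separate"),
    )


def distribution_to_tsv(dist: RgDistribution, path) -> None:
    import pandas as pd

    centers = 0.5 * (dist.bin_edges[:-1] + dist.bin_edges[1:])
    pd.DataFrame({"rg_bin_center": centers, "frequency": dist.frequencies}).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def plot_rg_comparison(ref: RgDistribution, pert: RgDistribution, path, title="") -> None:
    """Overlay two normalized R_g distributions (black reference, red perturbed)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    for dist, color, label in ((ref, "black", "reference"), (pert, "red", "perturbed")):
        centers = 0.5 * (dist.bin_edges[:-1] + dist.bin_edges[1:])
        ax.plot(centers, dist.frequencies, color=color, label=label)
    ax.set_xlabel("$R_g$ (Å)")
    ax.set_ylabel("normalized frequency")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
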