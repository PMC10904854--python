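"""Sequence tiling, hydropathy/disorder profiling, composition, and mass utilities.

The tiling engine cuts a disordered protein into fixed-length peptides (the
screening unit of the pipeline); profiles report windowed per-residue scores;
the mass helpers support native-MS stoichiometry assignment of peptide
complexes.  Coordinates are 1-based inclusive throughout, matching the
"MYC_101-150" naming convention of the field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from scipy import stats as _stats

from .constants import (
    CTERM_DELTAS,
    HYDROPHOBIC_SET,
    NEGATIVE_RESIDUES,
    NTERM_DELTAS,
    POSITIVE_RESIDUES,
    PROTON_MASS,
    RESIDUE_AVERAGE_MASS,
    STANDARD_AMINO_ACIDS,
    WATER_MASS,
    cmyc_sequence_path,
    load_hydrophobicity_scale,
)

EN_DASH = "–"


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence with 1-based parent numbering.

    ``numbering_offset`` is the parent position of the first residue; it is 1
    for a full-length protein and, e.g., 101 for the coreMYC segment.
    """

    id: str
    residues: str
    numbering_offset: int = 1

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ValueError("sequence must contain at least one residue")
        for i, aa in enumerate(self.residues):
            if aa not in STANDARD_AMINO_ACIDS:
                raise ValueError(
                    f"non-standard residue {aa!r} at position "
                    f"{self.numbering_offset + i} of {self.id}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.numbering_offset, self.numbering_offset + len(self))


@dataclass(frozen=True)
class Tile:
    """A named subsequence with 1-based inclusive parent coordinates."""

    parent_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid tile bounds {self.start}..{self.end}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("tile sequence length does not match its coordinates")

    @property
    def name(self) -> str:
        return f"{self.parent_id}_{self.start}{EN_DASH}{self.end}"

    @property
    def ascii_name(self) -> str:
        """Name with the en-dash normalized to an ASCII hyphen (file outputs)."""
        return f"{self.parent_id}_{self.start}-{self.end}"

    def as_sequence(self) -> ProteinSequence:
        return ProteinSequence(self.ascii_name, self.sequence, numbering_offset=self.start)


@dataclass(frozen=True)
class ResidueProfile:
    """A per-residue score track (positions 1-based, one value each)."""

    positions: np.ndarray
    values: np.ndarray
    scale_name: str
    window: int = 1

    def __post_init__(self):
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=int))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must have the same length")
        if self.window < 1:
            raise ValueError("window must be >= 1")


def read_fasta(path) -> list[ProteinSequence]:
    """Read one or more protein sequences from a FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return [ProteinSequence(r.id.split("|")[0], str(r.seq).upper()) for r in records]


def write_fasta(seqs, path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), 60):
                fh.write(s.residues[i:i + 60] + "\n")


def cmyc_sequence() -> ProteinSequence:
    """The canonical 439-residue human c-MYC sequence shipped with the package."""
    return read_fasta(cmyc_sequence_path())[0]


def tile_sequence(
    seq: ProteinSequence,
    window: int,
    step: int | None = None,
    offset: int = 0,
    keep_partial: bool = True,
) -> list[Tile]:
    """Cut ``seq`` into tiles of ``window`` residues every ``step`` residues.

    ``offset`` shifts the first tile start by that many residues (0-based within
    the sequence).  With ``keep_partial`` a final shorter tile is emitted when
    the window overruns the end; otherwise overrunning tiles are dropped.

    The canonical screen tiles the 439-residue c-MYC with window=step=50 into
    nine peptides (the last 39 residues long), and with offset=24,
    keep_partial=False into the eight frame-shifted 50-mers 25-74 ... 375-424.
    """
    n = len(seq)
    if step is None:
        step = window
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    if not 0 <= offset < n:
        raise ValueError(f"offset must be in [0, {n - 1}]")
    tiles = []
    base = seq.numbering_offset
    for s in range(offset, n, step):
        e = s + window
        if e > n:
            if not keep_partial:
                break
            e = n
        tiles.append(Tile(seq.id, base + s, base + e - 1, seq.residues[s:e]))
        if e == n:
            break
    return tiles


def _windowed_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centered sliding mean, truncated at the termini."""
    n = len(values)
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(values)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def hydropathy_profile(
    seq: ProteinSequence,
    scale: str | dict[str, float] = "miyazawa",
    window: int = 9,
) -> ResidueProfile:
    """Windowed hydropathy profile of ``seq`` on a named or explicit scale.

    The value at position i is the mean raw score over the window centered at
    i, truncated at the termini; window=1 returns the raw per-residue scores.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    name = scale if isinstance(scale, str) else "custom"
    table = load_hydrophobicity_scale(scale) if isinstance(scale, str) else dict(scale)
    missing = STANDARD_AMINO_ACIDS - table.keys()
    if missing:
        raise ValueError(f"scale does not define residues: {sorted(missing)}")
    raw = np.empty(len(seq))
    for i, aa in enumerate(seq.residues):
        if aa not in table:
            raise ValueError(f"unknown residue {aa!r} at position {seq.numbering_offset + i}")
        raw[i] = table[aa]
    return ResidueProfile(seq.positions, _windowed_mean(raw, window), name, window)


def hydrophobic_fraction(
    seq: ProteinSequence, hydrophobic_set=HYDROPHOBIC_SET
) -> float:
    """Fraction of residues in ``hydrophobic_set`` (default {A,C,F,I,L,M,V,W})."""
    hydrophobic_set = frozenset(hydrophobic_set)
    return sum(aa in hydrophobic_set for aa in seq.residues) / len(seq)


# FoldIndex-style foldability: 2.785*<H> - |<q>| - 1.151 with Kyte-Doolittle
# hydropathy rescaled to [0, 1].  The proxy is its negation (higher = more
# disordered); it stands in when external per-residue disorder scores are not
# supplied.
_FOLDINDEX_SLOPE = 2.785
_FOLDINDEX_INTERCEPT = 1.151


def disorder_proxy(seq: ProteinSequence, window: int = 9) -> ResidueProfile:
    """Fold-index-style disorder proxy (positive = predicted disordered)."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    kd = load_hydrophobicity_scale("kyte_doolittle")
    hyd = np.array([(kd[aa] + 4.5) / 9.0 for aa in seq.residues])
    charge = np.array(
        [
            1.0 if aa in POSITIVE_RESIDUES else -1.0 if aa in NEGATIVE_RESIDUES else 0.0
            for aa in seq.residues
        ]
    )
    fold = (
        _FOLDINDEX_SLOPE * _windowed_mean(hyd, window)
        - np.abs(_windowed_mean(charge, window))
        - _FOLDINDEX_INTERCEPT
    )
    return ResidueProfile(seq.positions, -fold, "disorder_proxy", window)


def read_disorder_csv(path) -> ResidueProfile:
    """Read external per-residue disorder scores from a (position,score) CSV."""
    import pandas as pd

    table = pd.read_csv(path, comment="#")
    if table.shape[1] < 2:
        raise ValueError("disorder CSV needs position and score columns")
    return ResidueProfile(
        table.iloc[:, 0].to_numpy(int), table.iloc[:, 1].to_numpy(float), "external", 1
    )


def profile_correlation(a: ResidueProfile, b: ResidueProfile, method: str = "pearson") -> float:
    """Pearson or Spearman correlation of two profiles on identical positions."""
    if len(a.values) != len(b.values) or not np.array_equal(a.positions, b.positions):
        raise ValueError("profiles must be aligned on identical positions")
    if np.ptp(a.values) == 0 or np.ptp(b.values) == 0:
        raise ValueError("correlation undefined for a zero-variance profile")
    if method == "pearson":
        return float(_stats.pearsonr(a.values, b.values).statistic)
    if method == "spearman":
        return float(_stats.spearmanr(a.values, b.values).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def peptide_average_mass(
    seq: ProteinSequence, nterm: str = "free", cterm: str = "free"
) -> float:
    """Average isotopic mass in Da, with optional terminal modifications."""
    if nterm not in NTERM_DELTAS:
        raise ValueError(f"unknown N-terminal modification {nterm!r}")
    if cterm not in CTERM_DELTAS:
        raise ValueError(f"unknown C-terminal modification {cterm!r}")
    mass = sum(RESIDUE_AVERAGE_MASS[aa] for aa in seq.residues) + WATER_MASS
    return mass + NTERM_DELTAS[nterm] + CTERM_DELTAS[cterm]


def mz_series(mass: float, charges) -> list[float]:
    """m/z values for a neutral mass at the given positive charge states."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    out = []
    for z in charges:
        if z < 1:
            raise ValueError(f"charge must be >= 1, got {z}")
        out.append((mass + z * PROTON_MASS) / z)
    return out


def profiles_to_tsv(profiles: dict[str, ResidueProfile], path) -> None:
    """Write aligned profiles as a TSV with one column per track."""
    import pandas as pd

    first = next(iter(profiles.values()))
    data = {"position": first.positions}
    for name, prof in profiles.items():
        if not np.array_equal(prof.positions, first.positions):
            raise ValueError("profiles must share positions for joint export")
        data[name] = prof.values
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.4f")


def tiles_to_tsv(tiles: list[Tile], path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "name": [t.ascii_name for t in tiles],
            "start": [t.start for t in tiles],
            "end": [t.end for t in tiles],
            "length": [len(t.sequence) for t in tiles],
            "sequence": [t.sequence for t in tiles],
        }
    ).to_csv(path, sep="\t", index=False)
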