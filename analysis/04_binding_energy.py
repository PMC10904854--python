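#!/usr/bin/env python
"""MM/GBSA binding energy and per-residue decomposition of the toy complex.

Computes the single-trajectory binding energy of the synthetic two-chain
complex, checks it against the stored brute-force oracle, and writes the
residue decomposition with the <= -2 kcal/mol hotspot report to results/.
Also demonstrates an R_g-energy landscape for a sampled chain.
"""

from pathlib import Path

import numpy as np

import tileswitch as tw
from tileswitch.energy import ensemble_energies
from tileswitch.metrics import paired_landscapes, rg_series

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    ens, oracle = tw.toy_complex(seed=3, n_frames=20)
    res = tw.binding_energy(
        ens, tw.Selection(chains=frozenset("A")), tw.Selection(chains=frozenset("B")),
        n_frames=None,
    )
    print(f"dG_bind = {res.delta_g_mean:.2f} ± {res.delta_g_sd:.2f} kcal/mol "
          f"(n = {res.n_frames} frames; oracle {oracle['delta_g_mean']:.2f}, "
          f"|diff| = {abs(res.delta_g_mean - oracle['delta_g_mean']):.1e})")

    table = res.decomposition_table()
    table["flag"] = table["mean"] <= -2.0
    table.to_csv(RESULTS / "binding_decomposition.tsv", sep="\t", index=False,
                 float_format="%.4f")
    hot = res.filtered_report(-2.0)
    print("\nresidues with contribution <= -2 kcal/mol (mean ± SD):")
    for _, row in hot.iterrows():
        print(f"  {row['chain']}:{row['residue_name']}{row['residue_id']}: "
              f"{row['mean']:.2f} ± {row['sd']:.2f}")

    # R_g-E landscape of compact vs extended chains on a joint 0-1 energy scale
    compact = tw.sample_chain(tw.compact_model(), 60, seed=31)
    extended = tw.sample_chain(tw.extended_model(), 60, seed=32)
    e_comp = ensemble_energies(compact, n_frames=None)["g_total"].to_numpy()
    e_ext = ensemble_energies(extended, n_frames=None)["g_total"].to_numpy()
    l_comp, l_ext = paired_landscapes(rg_series(compact), e_comp,
                                      rg_series(extended), e_ext, "joint")
    np.savetxt(RESULTS / "landscape_compact.tsv",
               np.column_stack([l_comp.rg, l_comp.energy_norm]),
               header="rg\tenergy_norm", delimiter="\t", comments="")
    np.savetxt(RESULTS / "landscape_extended.tsv",
               np.column_stack([l_ext.rg, l_ext.energy_norm]),
               header="rg\tenergy_norm", delimiter="\t", comments="")
    print(f"\nlandscapes: compact mean normalized E = {l_comp.energy_norm.mean():.2f}, "
          f"extended = {l_ext.energy_norm.mean():.2f} (joint 0-1 scale); "
          "the collapsed state sits lower on the shared energy axis")


if __name__ == "__main__":
    main()
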