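#!/usr/bin/env python
"""Predict pairwise adsorption selectivity from the Gibbs energies.

For every absorbent the script computes exp(dG_A/dG_B) for each ordered
pollutant pair, flags pairs with no meaningful selectivity (rounded ratio
<= 2) and highlights the worked cases: chitosan prefers amoxicillin to
tetracycline ~66:1 and to ibuprofen ~10:1; pyrene-based graphene oxide
prefers amoxicillin to ibuprofen ~23:1.

Writes results/selectivity_matrix.tsv.
"""

from pathlib import Path

import pandas as pd

from adsorbscreen.reference import thermo_records
from adsorbscreen.selectivity import selectivity_matrix

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    results = selectivity_matrix(thermo_records())
    frame = pd.DataFrame(
        [
            {
                "absorbent": r.absorbent,
                "pollutant_a": r.pollutant_a,
                "pollutant_b": r.pollutant_b,
                "dg_a": r.dg_a,
                "dg_b": r.dg_b,
                "ratio": round(r.ratio, 2),
                "rounded": r.rounded,
                "no_selectivity": r.no_selectivity,
            }
            for r in results
        ]
    )
    OUT.mkdir(exist_ok=True)
    frame.to_csv(OUT / "selectivity_matrix.tsv", sep="\t", index=False)

    print(f"{len(frame)} ordered pollutant pairs across "
          f"{frame['absorbent'].nunique()} absorbents")
    idx = frame.set_index(["absorbent", "pollutant_a", "pollutant_b"])
    for key, label in [
        (("CS", "AMOX", "Tetracycline"), "chitosan: amoxicillin over tetracycline"),
        (("CS", "AMOX", "IBU"), "chitosan: amoxicillin over ibuprofen"),
        (("GO-1", "AMOX", "IBU"), "pyrene graphene oxide: amoxicillin over ibuprofen"),
        (("CS", "Tetracycline", "Doxycycline"), "chitosan: tetracycline over doxycycline"),
    ]:
        row = idx.loc[key]
        flag = " (no selectivity)" if row["no_selectivity"] else ""
        print(f"  {label}: {row['ratio']:.1f} -> {int(row['rounded'])}:1{flag}")


if __name__ == "__main__":
    main()
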