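"""Binding-energy bookkeeping report.

Converts the reference inhibition constants of the two control drugs to
deltaG in both sign conventions, reports COX-2/COX-1 selectivity ratios
from the bundled docking energies, and tabulates the reference MM-GBSA
binding energies.
"""

from pathlib import Path

import pandas as pd

from coxqsar import delta_g_from_ki, selectivity_ratio
from coxqsar.energetics import (
    KI_REFERENCE,
    KI_REFERENCE_TEMPERATURE,
    load_docking_affinities,
    load_mmgbsa_reference,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for ligand, ki in KI_REFERENCE.items():
        printed = delta_g_from_ki(ki, KI_REFERENCE_TEMPERATURE)
        thermo = delta_g_from_ki(ki, KI_REFERENCE_TEMPERATURE, "thermodynamic")
        rows.append(
            {"ligand": ligand, "ki_M": ki, "T_K": KI_REFERENCE_TEMPERATURE,
             "dG_as_printed": printed, "dG_thermodynamic": thermo}
        )
        print(
            f"{ligand}: Ki={ki:.3g} M at {KI_REFERENCE_TEMPERATURE:g} K -> "
            f"-RT ln Ki = {printed:+.3f} kcal/mol "
            f"(thermodynamic convention: {thermo:+.3f})"
        )

    affinities = {(r.ligand, r.target): r for r in load_docking_affinities()}
    ratio_rows = []
    for ligand in ("Z-627", "Z-964"):
        cox2 = affinities[(ligand, "COX-2")]
        cox1 = affinities[(ligand, "COX-1")]
        r21, r12 = selectivity_ratio(cox2, cox1)
        ratio_rows.append(
            {"ligand": ligand, "dG_cox2": cox2.delta_g, "dG_cox1": cox1.delta_g,
             "cox2_over_cox1": r21, "cox1_over_cox2": r12}
        )
        print(
            f"{ligand}: deltaG COX-2 {cox2.delta_g:+.2f}, COX-1 {cox1.delta_g:+.2f} "
            f"-> ratios COX-2/COX-1 {r21:.3f}, COX-1/COX-2 {r12:.3f}"
        )

    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(RESULTS / "delta_g_from_ki.csv", index=False,
                              float_format="%.4f")
    pd.DataFrame(ratio_rows).to_csv(RESULTS / "selectivity_ratios.csv", index=False,
                                    float_format="%.4f")
    load_mmgbsa_reference().to_csv(RESULTS / "mmgbsa_reference.csv", index=False)
    print(f"wrote energetics tables to {RESULTS}")


if __name__ == "__main__":
    main()
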