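"""Q-FISH telomere quantification on rendered ground-truth images.

Renders synthetic multi-channel fields emulating the four tumor telomere
phenotypes — normal/non-metastatic (reference), TERT-altered (short
telomeres, dim spots), NOP10-overexpressing (intermediate-long), and
ATRX-mutant (heterogeneous, very long, with PML bodies colocalizing at
telomeres) — then quantifies per-nucleus mean telomere intensity and
spot size, classifies each condition against the reference P10/P90
intensity percentiles, and counts ALT-associated PML bodies (APBs).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from telorisk import qfish
from telorisk.render import RenderConfig, render_field

CONDITIONS = {
    # amplitude range encodes the planted telomere-length phenotype
    "normal_reference": dict(spot_amplitude=(400.0, 800.0)),
    "tert_altered": dict(spot_amplitude=(120.0, 300.0)),
    "nop10_overexpressing": dict(spot_amplitude=(600.0, 1400.0)),
    "atrx_mutant": dict(
        spot_amplitude=(300.0, 3000.0), n_pml_per_nucleus=3, pml_colocalized_fraction=0.7
    ),
}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--fields-per-condition", type=int, default=4)
    args = ap.parse_args()

    rng = np.random.default_rng(args.seed)
    per_nucleus, summaries = [], []
    reference_values = None
    for condition, overrides in CONDITIONS.items():
        cfg = RenderConfig(n_nuclei=4, spots_per_nucleus=10, **overrides)
        nuclei_tables, apb_counts, pml_fracs = [], 0, []
        for _ in range(args.fields_per_condition):
            field = render_field(cfg, rng)
            labels = qfish.segment_nuclei(field.dapi)
            spots = qfish.detect_spots(field.telo, labels)
            nuclei = qfish.nucleus_summaries(spots, labels, field.telo)
            nuclei_tables.append(nuclei)
            if field.pml is not None:
                pml_spots = qfish.detect_spots(field.pml, labels)
                per, frac = qfish.apb_colocalization(pml_spots, spots, 3.0, labels)
                apb_counts += int(per["n_apb"].sum())
                pml_fracs.append(frac)
        nuclei = pd.concat(nuclei_tables, ignore_index=True)
        nuclei.insert(0, "condition", condition)
        per_nucleus.append(nuclei)
        values = nuclei["mean_telomere_intensity"].dropna().to_numpy()
        if condition == "normal_reference":
            reference_values = values
        classes = qfish.percentile_classes(values, reference_values)
        summaries.append(
            {
                "condition": condition,
                "n_nuclei": len(values),
                "median_intensity": float(np.median(values)),
                "mean_spot_size_px": float(nuclei["mean_spot_size"].mean()),
                "percent_short": round(classes.percent_short, 1),
                "percent_long": round(classes.percent_long, 1),
                "apb_count": apb_counts,
                "pml_positive_fraction": round(float(np.mean(pml_fracs)), 2) if pml_fracs else 0.0,
            }
        )

    pd.concat(per_nucleus, ignore_index=True).to_csv(
        args.out / "qfish_nuclei.tsv", sep="\t", index=False
    )
    summary = pd.DataFrame(summaries).set_index("condition")
    summary.to_csv(args.out / "qfish_summary.tsv", sep="\t")
    print(summary.to_string())
    print(
        "\nshort (<P10) signals concentrate in the TERT-altered condition, long (>P90) in the "
        "ATRX-mutant one, with NOP10 intermediate; APBs appear only where PML bodies were "
        "rendered at telomeres (ATRX-mutant)."
    )


if __name__ == "__main__":
    main()
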