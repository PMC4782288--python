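#!/usr/bin/env python
"""Histology quantification: PEC density and vessel immaturity per tumor.

Segments the HSV stain bands on each double-stained field, splits
touching Ki67 nuclei by marker-based watershed, counts proliferating
endothelial cells (Ki67+ nuclei inside lectin+ vessels, per mm² of
vessel), and computes the lectin+/α-SMA- immature-vessel area fraction
with the 5-μm distance rule.  Writes results/histology_metrics.csv.
"""

import pandas as pd
from _common import RESULTS, analysis_config, load_bundle

from angioquant import histology as hist

cfg = analysis_config()
bundle = load_bundle(include_spectra=False)
bands = cfg["stain_bands"]

rows = []
for tumor in bundle.tumors:
    masks = hist.segment_stains(tumor.ki67_field, bands)
    labels = hist.separate_nuclei(
        masks.ki67_mask,
        cfg["nucleus_diameter_um"] / tumor.ki67_field.um_per_px)
    pec = hist.pec_density(labels, masks, tumor.ki67_field.um_per_px,
                           rule=cfg["pec_rule"])
    sma_masks = hist.segment_stains(tumor.sma_field, bands)
    mat = hist.immature_vessel_fraction(sma_masks,
                                        tumor.sma_field.um_per_px,
                                        cfg["sma_min_dist_um"])
    rows.append({"tumor_id": tumor.tumor_id, "group": tumor.group,
                 "n_pec": pec.n_pec, "n_ki67": pec.n_ki67_total,
                 "vessel_area_mm2": pec.vessel_area_mm2,
                 "pec_density": pec.pec_density,
                 "immature_fraction": mat.immature_fraction,
                 "true_n_in_vessel":
                     tumor.ki67_gt.nucleus_count_in_vessel,
                 "true_immature_fraction":
                     tumor.sma_gt.immature_fraction})

RESULTS.mkdir(exist_ok=True)
df = pd.DataFrame(rows)
df.to_csv(RESULTS / "histology_metrics.csv", index=False)

print(df.groupby("group")[["pec_density", "immature_fraction"]]
        .median().round(3))
exact = (df.n_pec == df.true_n_in_vessel).mean()
print(f"\nPEC counts equal designed in-vessel nuclei in {exact:.0%} "
      f"of tumors")
print(f"wrote {RESULTS/'histology_metrics.csv'}")
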