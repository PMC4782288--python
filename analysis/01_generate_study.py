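#!/usr/bin/env python
"""Generate the synthetic two-arm imaging study and export sample data.

Writes the study manifest (full ground truth per tumor) and one example
of each raw-data modality — a micro-CT volume (NIfTI), a dynamic series
(4D NIfTI), the two histology fields (PNG) and the spectral cohort (CSV)
— so the downstream drivers and any external tool can inspect what the
phantoms look like.
"""

import json
from _common import RESULTS, STUDY_SEED, load_bundle

from angioquant import io as aio

out = RESULTS / "study"
out.mkdir(parents=True, exist_ok=True)

bundle = load_bundle()
(out / "manifest.json").write_text(bundle.manifest)

example = bundle.tumors[0]
aio.save_volume(example.microct, out / f"{example.tumor_id}_microct.nii")
aio.save_series(example.dce[0], out / f"{example.tumor_id}_dce_day0.nii")
aio.save_field(example.ki67_field, out / f"{example.tumor_id}_ki67.png")
aio.save_field(example.sma_field, out / f"{example.tumor_id}_sma.png")
aio.save_spectra(bundle.spectra, out / "spectra.csv",
                 out / "spectra_labels.csv")

manifest = json.loads(bundle.manifest)
n_ctrl = sum(t["group"] == "control" for t in manifest["tumors"])
n_trt = sum(t["group"] == "treated" for t in manifest["tumors"])
fbv = [t["microct"]["true_fbv"] for t in manifest["tumors"]]
print(f"study seed {STUDY_SEED}: {n_ctrl} control vs {n_trt} treated tumors")
print(f"designed FBV range: {min(fbv):.4f} .. {max(fbv):.4f}")
print(f"wrote manifest and example raw data to {out}")
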