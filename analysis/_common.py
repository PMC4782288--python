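"""Shared configuration for the numbered analysis drivers.

One study seed, one design, one analysis config — every driver
regenerates the identical synthetic study from these, so the scripts can
be run independently and in any order.
"""

from pathlib import Path

from angioquant.config import DEFAULTS
from angioquant.synthetic import StudyDesign, generate_two_group_study

STUDY_SEED = 20160307
RESULTS = Path(__file__).resolve().parent.parent / "results"


def study_design() -> StudyDesign:
    return StudyDesign()


def analysis_config() -> dict:
    cfg = dict(DEFAULTS)
    # scales matched to the 18-36 um phantom vessel radii
    cfg["vesselness_scales_um"] = [9.0, 18.0, 36.0]
    return cfg


def load_bundle(include_spectra: bool = True):
    return generate_two_group_study(study_design(), seed=STUDY_SEED,
                                    include_spectra=include_spectra)
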