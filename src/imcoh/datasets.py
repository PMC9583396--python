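"""Bundled reference tables.

The package ships the published per-subject demographic and clinical table of
the 24-subject chronic-stroke cohort the analysis pipeline was designed
around (age, time since stroke, EmNSA somatosensory score out of 64,
upper-limb Fugl-Meyer sensorimotor score out of 66).  It is the only real
data the package carries and is used to exercise the demographics summary.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_stroke_cohort() -> pd.DataFrame:
    """Per-subject demographics of the 24-subject stroke cohort."""
    with resources.files("imcoh.data").joinpath("stroke_cohort.csv").open() as fh:
        return pd.read_csv(fh)
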