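"""Bundled example data."""

from importlib import resources

import pandas as pd


def load_case_regional() -> pd.DataFrame:
    """Regional per-PLD CBF (ml/100 g/min) and ATT (s) for the example case.

    A unilateral left-ICA stenosis case: per-side values for the
    fronto-temporal and fronto-parietal territories at PLDs 1.0/2.0/3.0 s.
    Long format with columns region, side, cbf_pld1..3, att.
    """
    with resources.files("cafasim.data").joinpath("case_regional.csv").open() as fh:
        return pd.read_csv(fh)
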