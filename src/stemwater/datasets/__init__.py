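"""Bundled reference tables.

``amazon_drydown`` — published per-tree storage statistics from a 163-day
continuous FDR monitoring campaign in an eastern Amazonian terra-firme
forest (2 palms, 5 subcanopy dicot trees, 2023 El Niño dry season): turgid
(99th-percentile) and dry (1st-percentile) volumetric water content, mean ±
sd, CV%, water deficit %, absolute seasonal water loss, maximum diurnal
discharge capacity, and wood density.  Stem geometry (height, DBH, sapwood
depth) is included where reported.  Used as the worked-example input for the
group-contrast statistics and the active-storage calculation.
"""

from importlib import resources

import pandas as pd

__all__ = ["amazon_drydown"]


def amazon_drydown() -> pd.DataFrame:
    """Load the Amazonian dry-down per-tree reference summary."""
    with resources.files(__package__).joinpath("amazon_drydown.csv").open() as fh:
        return pd.read_csv(fh)
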