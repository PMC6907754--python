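"""Bundled reference data.

One small table ships with the package: a published season-long survey
summary of the 19 most abundant entomophilous plant species of a
Mediterranean scrubland (Garraf massif, NE Spain) — per plant, the number of
pollinator species recorded, the mean and SD of flowers visited per
encounter (pooled over pollinators), and the floral display (mean open
flowers per individual at peak bloom). It anchors the display-visits
regression and calibrates the synthetic generator's defaults.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_scrubland_plant_summary"]


def load_scrubland_plant_summary() -> pd.DataFrame:
    """The 19-plant scrubland survey summary.

    Columns: ``code`` (three-letter plant code), ``plant_species``,
    ``n_pollinator_species``, ``mean_visits_per_encounter``,
    ``sd_visits_per_encounter``, ``floral_display``.
    """
    ref = resources.files("pollinet.data").joinpath("scrubland_plant_summary.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)
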