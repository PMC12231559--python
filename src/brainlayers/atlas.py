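"""Region tables for the AAL parcellation.

The packaged table lists the 116 AAL regions in the atlas's standard numeric
order with a hemisphere code (L/R/M for midline vermis) and a cortical flag.
Filtering on the cortical flag yields the 78 cortical regions commonly used as
network nodes in source-space MEG studies (the 38 excluded regions are the six
bilateral subcortical structures — hippocampus, amygdala, caudate, putamen,
pallidum, thalamus — plus the 26 cerebellar/vermis regions).

``cortical_regions`` orders the 78 nodes as a left-hemisphere block (1–39)
followed by a right-hemisphere block (40–78), the axis convention used for
adjacency-matrix displays. Within each block the standard AAL sequence is
preserved. Seed-region defaults are keyed by label (see
:data:`DEFAULT_SEED_LABELS`); any index-based convention from other software
can be reproduced by reordering this table.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Default seed regions for seed-based connectivity comparisons:
#: bilateral supplementary motor area and bilateral precentral gyrus.
DEFAULT_SEED_LABELS: tuple[str, ...] = (
    "Supp_Motor_Area_L",
    "Supp_Motor_Area_R",
    "Precentral_L",
    "Precentral_R",
)


def load_region_list(atlas: str = "AAL116") -> pd.DataFrame:
    """Load the packaged region table for *atlas*.

    Returns a DataFrame with columns ``aal_index`` (1-based standard AAL
    numbering), ``name``, ``hemisphere`` (``L``/``R``/``M``) and ``cortical``
    (bool). Exactly 116 rows for ``"AAL116"``.
    """
    if atlas != "AAL116":
        raise ValueError(f"unknown atlas {atlas!r}; available: 'AAL116'")
    with resources.files("brainlayers.data").joinpath("aal116.csv").open() as fh:
        df = pd.read_csv(fh)
    df["cortical"] = df["cortical"].astype(bool)
    return df


def cortical_regions(atlas: str = "AAL116") -> pd.DataFrame:
    """The 78 cortical network nodes, left block then right block.

    Adds a ``node_index`` column running 1–78 (1–39 left hemisphere,
    40–78 right hemisphere).
    """
    df = load_region_list(atlas)
    cort = df[df["cortical"]]
    left = cort[cort["hemisphere"] == "L"]
    right = cort[cort["hemisphere"] == "R"]
    out = pd.concat([left, right], ignore_index=True)
    out.insert(0, "node_index", range(1, len(out) + 1))
    return out
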