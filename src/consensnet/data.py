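"""Accessors for the small reference tables bundled with the package."""
from __future__ import annotations

from importlib import resources

import pandas as pd

E2_E3_CLASSES = (
    "E2 ubiquitin conjugating enzymes",
    "E3 ubiquitin ligases",
)


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("consensnet").joinpath("data", name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def hwgbmi_intersection_classes() -> pd.DataFrame:
    """Functional category/class/family annotation of the 40 genes shared
    between the mouse weight-gain-prone set and the human weight/BMI set."""
    return _read("hwgbmi_intersection_classes.tsv")


def conserved_aiwg_markers() -> pd.DataFrame:
    """The four blood markers of weight-gain proneness shared between the
    mouse and human studies, with their published fold changes."""
    return _read("conserved_aiwg_markers.tsv")
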