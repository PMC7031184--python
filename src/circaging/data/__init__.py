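"""Bundled reference tables.

``senescence_reference.tsv`` is the published early- vs late-passage
qPCR comparison for the 15-candidate panel across four primary cell
types (median normalized expression per passage group and the ANOVA
p-value; assays undetected in a cell type carry ``expressed=False`` and
no p-value).  It serves as a worked-example input for
:func:`circaging.associate.count_dysregulated`.
"""

from importlib import resources

import pandas as pd

__all__ = ["load_senescence_reference"]


def load_senescence_reference() -> pd.DataFrame:
    """Load the reference senescence comparison table."""
    with resources.files(__package__).joinpath("senescence_reference.tsv").open() as fh:
        frame = pd.read_csv(fh, sep="\t")
    frame["expressed"] = frame["expressed"].map(
        {True: True, False: False, "True": True, "False": False}
    )
    if frame["expressed"].isna().any():
        raise ValueError("unparseable expressed flags in reference table")
    return frame
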