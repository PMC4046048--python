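"""Deregression of progeny-based EBVs into pseudo-phenotypes.

An EBV is a shrunken predictor; regressing it back out against the
pedigree index (PI, the parent-average expectation of the EBV without
progeny information) yields a record suitable for marker models:

    y = PI + (EBV - PI) / r^2

with r^2 the reliability of the EBV from progeny information only. The
record weight assumes markers capture all genetic variance:

    w = (1 - h^2 r^2) / (h^2 (1 - r^2))        ("literal" form)

The printed typography of that numerator is ambiguous (1 - h^2 r^2 versus
(1 - h^2) r^2); both parses are implemented and the Garrick-style
alternative w = r^2 (1 - h^2) / (h^2 (1 - r^2)) is selectable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

WEIGHT_FORMS = ("literal", "garrick")


def deregress(ebv, pi, r2):
    """Deregressed EBV y = PI + (EBV - PI) / r^2; r2 must be in (0, 1]."""
    ebv = np.asarray(ebv, dtype=float)
    pi = np.asarray(pi, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if np.any(r2 <= 0) or np.any(r2 > 1):
        raise ValueError("reliability r2 must lie in (0, 1]")
    return pi + (ebv - pi) / r2


def weight(h2, r2, form: str = "literal"):
    """Record weight; diverges as r2 -> 1 (such records carry no residual)."""
    h2 = np.asarray(h2, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if np.any((h2 <= 0) | (h2 >= 1)):
        raise ValueError("h2 must lie in (0, 1)")
    if np.any((r2 < 0) | (r2 >= 1)):
        raise ValueError("r2 must lie in [0, 1) for a finite weight")
    if form == "literal":
        return (1.0 - h2 * r2) / (h2 * (1.0 - r2))
    if form == "garrick":
        return r2 * (1.0 - h2) / (h2 * (1.0 - r2))
    raise ValueError(f"unknown weight form {form!r}; expected {WEIGHT_FORMS}")


def deregress_table(ebv_table: pd.DataFrame, h2: float, form: str = "literal") -> pd.DataFrame:
    """Apply deregression and weighting to an EBV table.

    Returns columns animal_id, ebv, pi, r2, y, w. Records with r2 == 0
    carry no own information and are dropped.
    """
    df = ebv_table.copy()
    keep = df["r2"] > 0
    df = df.loc[keep].reset_index(drop=True)
    df["y"] = deregress(df["ebv"], df["pi"], df["r2"])
    df["w"] = weight(h2, df["r2"], form=form)
    return df
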