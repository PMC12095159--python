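"""Per-spot fluorescence to autoantibody levels in arbitrary units (AU).

The control-normalized level of one antigen spot is

    AU = (F_antigen - F_neg) / (F_pos - F_neg) * 100

so AU is 0 at the negative-control intensity and 100 at the positive-control
intensity; values may be negative or exceed 100 and are never clipped here.
Per subject, F_neg and F_pos are the medians of that subject's control-spot
intensities (robust to a single bad spot), duplicate antigen spots are
averaged, and the per-subject sum of autoantibody levels (SAL) is the plain
row sum over all antigens, negative AU included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AUMatrix", "DegenerateControlError", "compute_au", "build_au_matrix", "compute_sal"]

REQUIRED_COLUMNS = ("subject_id", "spot_id", "spot_type", "antigen_id", "intensity")
SPOT_TYPES = ("antigen", "pos_control", "neg_control")


class DegenerateControlError(ValueError):
    """Positive-control intensity does not exceed the negative control."""


@dataclass
class AUMatrix:
    """Subjects x antigens matrix of AU values plus per-subject SAL."""

    values: pd.DataFrame  # rows = subjects, columns = antigen ids
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.values.isna().any().any():
            raise ValueError("AUMatrix must have no missing cells")

    @property
    def sal(self) -> pd.Series:
        """Sum of autoantibody levels per subject (row sum, no clipping)."""
        return self.values.sum(axis=1).rename("SAL")

    @property
    def subjects(self) -> list:
        return list(self.values.index)

    @property
    def antigens(self) -> list:
        return list(self.values.columns)

    def subset(self, antigens) -> "AUMatrix":
        return AUMatrix(self.values[list(antigens)].copy(), dict(self.provenance))

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="subject_id")

    def sal_to_csv(self, path) -> None:
        self.sal.to_frame().to_csv(path, index_label="subject_id")

    @classmethod
    def read_csv(cls, path) -> "AUMatrix":
        df = pd.read_csv(path, index_col="subject_id")
        df.index.name = None
        return cls(df, {"source": str(path)})


def compute_au(f_antigen, f_neg, f_pos, subject: str | None = None):
    """Control-normalized autoantibody level; vectorized over ``f_antigen``.

    Raises :class:`DegenerateControlError` (naming the subject when given)
    if the positive control does not exceed the negative control.
    """
    f_neg = float(f_neg)
    f_pos = float(f_pos)
    if not f_pos > f_neg:
        who = f" for subject {subject}" if subject else ""
        raise DegenerateControlError(
            f"positive control ({f_pos}) must exceed negative control ({f_neg}){who}"
        )
    au = (np.asarray(f_antigen, dtype=float) - f_neg) / (f_pos - f_neg) * 100.0
    return float(au) if au.ndim == 0 else au


def build_au_matrix(table: pd.DataFrame) -> AUMatrix:
    """Assemble the AU matrix from a per-spot fluorescence table.

    Per subject the control medians are taken, every antigen spot is mapped
    through :func:`compute_au`, and duplicate spots for one antigen are
    averaged.  Subjects missing either control class raise, listing the
    offenders.
    """
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"fluorescence table missing columns: {missing_cols}")
    bad_types = set(table["spot_type"]) - set(SPOT_TYPES)
    if bad_types:
        raise ValueError(f"unknown spot types: {sorted(bad_types)}")
    if not np.isfinite(table["intensity"].to_numpy(dtype=float)).all():
        raise ValueError("intensities must be finite")

    controls = table[table["spot_type"] != "antigen"]
    counts = controls.groupby(["subject_id", "spot_type"]).size().unstack(fill_value=0)
    subjects = table["subject_id"].unique()
    incomplete = [
        s
        for s in subjects
        if s not in counts.index
        or counts.loc[s].get("pos_control", 0) == 0
        or counts.loc[s].get("neg_control", 0) == 0
    ]
    if incomplete:
        raise ValueError(f"subjects missing a control class: {incomplete}")

    medians = controls.groupby(["subject_id", "spot_type"])["intensity"].median().unstack()
    antigen = table[table["spot_type"] == "antigen"]
    if (antigen["antigen_id"].astype(str).str.len() == 0).any():
        raise ValueError("antigen spots must carry a non-empty antigen_id")

    rows = {}
    for sid, sub in antigen.groupby("subject_id", sort=False):
        f_neg = medians.loc[sid, "neg_control"]
        f_pos = medians.loc[sid, "pos_control"]
        au = compute_au(sub["intensity"].to_numpy(), f_neg, f_pos, subject=str(sid))
        rows[sid] = pd.Series(au, index=sub["antigen_id"].to_numpy()).groupby(level=0).mean()
    values = pd.DataFrame(rows).T
    values = values.loc[[s for s in subjects if s in values.index]]
    values = values[sorted(values.columns)]
    if values.isna().any().any():
        holes = values.columns[values.isna().any()].tolist()
        raise ValueError(f"antigens missing for some subjects: {holes}")
    return AUMatrix(values, {"aggregation": "median controls, mean duplicates"})


def compute_sal(matrix: AUMatrix) -> pd.Series:
    """Per-subject sum of autoantibody levels (negative AU included)."""
    return matrix.sal
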