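"""Differential-elevation screening (volcano selection), Venn arithmetic, PCA.

An antigen is flagged *elevated* in a case group when its Mann-Whitney P
against controls is below ``p_threshold`` AND its fold change (ratio of
group arithmetic means on zero-clipped AU, with an epsilon fallback for
near-zero control means) is at least ``fc_threshold`` with case > control.
Selection is one-directional — only elevation counts — even though the P
value is two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats
from .quantify import AUMatrix

__all__ = ["fold_change", "venn_counts", "pca_embed", "DifferentialScreen", "DifferentialScreenResults"]


def fold_change(case_values, control_values, epsilon: float = 1.0) -> float:
    """Case/control ratio of arithmetic means on zero-clipped AU.

    AU can be negative (below the negative-control intensity); clipping at 0
    before averaging avoids sign pathologies.  When the control mean does
    not exceed ``epsilon`` the denominator falls back to ``epsilon`` so the
    ratio stays finite and non-negative.
    """
    case = np.clip(np.asarray(case_values, dtype=float), 0.0, None)
    ctrl = np.clip(np.asarray(control_values, dtype=float), 0.0, None)
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("both groups must be non-empty")
    denom = ctrl.mean() if ctrl.mean() > epsilon else epsilon
    return float(case.mean() / denom)


def venn_counts(set_ad, set_dlb, shared=None) -> tuple[int, int, int, int]:
    """(n_ad, n_dlb, n_shared, n_union) by inclusion-exclusion.

    Accepts either two id collections, or two set sizes with ``shared``
    given explicitly (the arithmetic form).
    """
    if shared is not None:
        n_ad, n_dlb, n_shared = int(set_ad), int(set_dlb), int(shared)
    else:
        a, b = set(set_ad), set(set_dlb)
        n_ad, n_dlb, n_shared = len(a), len(b), len(a & b)
    return n_ad, n_dlb, n_shared, n_ad + n_dlb - n_shared


def pca_embed(matrix, n_components: int = 2):
    """PCA of subjects on standardized antigen columns.

    Columns are centered and scaled to unit variance; zero-variance columns
    are dropped with a warning.  Scores come from the SVD with a fixed sign
    convention (the largest-magnitude loading of each component is
    positive).  Returns ``(scores, explained_variance_ratio, loadings)``.
    """
    df = matrix.values if isinstance(matrix, AUMatrix) else pd.DataFrame(matrix)
    if df.shape[0] < 2:
        raise ValueError("PCA requires at least 2 subjects")
    if df.shape[1] < 1:
        raise ValueError("PCA requires at least 1 antigen")
    sd = df.std(axis=0, ddof=1)
    dead = sd.index[(sd == 0) | sd.isna()].tolist()
    if dead:
        warnings.warn(f"dropping {len(dead)} zero-variance columns from PCA", stacklevel=2)
        df = df.drop(columns=dead)
        sd = sd.drop(dead)
    if df.shape[1] == 0:
        raise ValueError("all columns have zero variance")
    z = (df - df.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    k = min(n_components, s.size)
    # sign convention: largest-|loading| entry of each component positive
    for j in range(s.size):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    scores = u[:, :k] * s[:k]
    evr = (s**2) / (s**2).sum()
    cols = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(scores, index=df.index, columns=cols),
        evr[:k],
        pd.DataFrame(vt[:k].T, index=df.columns, columns=cols),
    )


@dataclass
class DifferentialScreenResults:
    """Per-antigen screen outcomes for the AD and DLB contrasts vs CNI."""

    table: pd.DataFrame
    p_threshold: float
    fc_threshold: float
    groups: pd.Series = field(repr=False)
    _au: AUMatrix = field(repr=False, default=None)

    def elevated(self, group: str) -> set:
        col = f"elevated_{group.lower()}"
        return set(self.table.index[self.table[col]])

    @property
    def selected_union(self) -> list:
        return sorted(self.elevated("AD") | self.elevated("DLB"))

    def venn(self) -> tuple[int, int, int, int]:
        return venn_counts(self.elevated("AD"), self.elevated("DLB"))

    def volcano(self, group: str) -> pd.DataFrame:
        """log2 fold change and -log10 P coordinates for one contrast."""
        g = group.lower()
        with np.errstate(divide="ignore"):
            return pd.DataFrame(
                {
                    "log2_fc": np.log2(self.table[f"fold_change_{g}"].to_numpy()),
                    "neg_log10_p": -np.log10(self.table[f"p_{g}"].to_numpy()),
                    "elevated": self.table[f"elevated_{g}"].to_numpy(),
                },
                index=self.table.index,
            )

    def pca(self, n_components: int = 2):
        """PCA of subjects restricted to the selected (union) antigens."""
        sel = self.selected_union
        if not sel:
            raise ValueError("no antigens selected; nothing to embed")
        return pca_embed(self._au.subset(sel), n_components)

    def summary(self) -> str:
        n_ad, n_dlb, n_sh, n_un = self.venn()
        lines = [
            "Differential elevation screen (Mann-Whitney + fold change)",
            f"  thresholds: P < {self.p_threshold}, FC >= {self.fc_threshold}",
            f"  antigens tested: {len(self.table)}",
            f"  elevated in AD:  {n_ad}",
            f"  elevated in DLB: {n_dlb}",
            f"  shared:          {n_sh}",
            f"  union:           {n_un}",
        ]
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="antigen_id")


class DifferentialScreen:
    """Volcano screen of an AU matrix: AD vs CNI and DLB vs CNI.

    Parameters
    ----------
    au : AUMatrix
        Subjects x antigens autoantibody levels.
    groups : mapping or Series
        Diagnosis per subject, values in {"AD", "DLB", "CNI"}.
    p_threshold, fc_threshold, epsilon
        Volcano thresholds (defaults P < 0.05, FC >= 2) and the fold-change
        denominator floor.
    """

    def __init__(self, au: AUMatrix, groups, p_threshold: float = 0.05,
                 fc_threshold: float = 2.0, epsilon: float = 1.0):
        self.au = au
        self.groups = pd.Series(groups).reindex(au.subjects)
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()].tolist()
            raise ValueError(f"no diagnosis for subjects: {missing}")
        unknown = set(self.groups) - {"AD", "DLB", "CNI"}
        if unknown:
            raise ValueError(f"unknown diagnoses: {sorted(unknown)}")
        self.p_threshold = p_threshold
        self.fc_threshold = fc_threshold
        self.epsilon = epsilon

    def fit(self) -> DifferentialScreenResults:
        values = self.au.values
        masks = {g: (self.groups == g).to_numpy() for g in ("AD", "DLB", "CNI")}
        for g, m in masks.items():
            if m.sum() < 2:
                raise ValueError(f"group {g} has fewer than 2 subjects")
        rows = {}
        arr = values.to_numpy()
        for j, ag in enumerate(values.columns):
            col = arr[:, j]
            row = {}
            for g in ("AD", "DLB", "CNI"):
                row[f"mean_{g.lower()}"] = float(col[masks[g]].mean())
            for g in ("AD", "DLB"):
                case, ctrl = col[masks[g]], col[masks["CNI"]]
                res = stats.mann_whitney_u(case, ctrl)
                fc = fold_change(case, ctrl, self.epsilon)
                elevated = (res.p_value < self.p_threshold) and (fc >= self.fc_threshold) \
                    and (np.clip(case, 0, None).mean() > np.clip(ctrl, 0, None).mean())
                row[f"fold_change_{g.lower()}"] = fc
                row[f"p_{g.lower()}"] = res.p_value
                row[f"elevated_{g.lower()}"] = bool(elevated)
            rows[ag] = row
        table = pd.DataFrame.from_dict(rows, orient="index")
        table["in_union"] = table["elevated_ad"] | table["elevated_dlb"]
        return DifferentialScreenResults(table, self.p_threshold, self.fc_threshold,
                                         self.groups, self.au)
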