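"""Cross-reactivity screening: antibody correlation then global alignment.

Two autoantibodies whose serum levels correlate strongly across subjects may
reflect one antibody binding two antigens that share sequence.  The screen
computes the pairwise Spearman matrix of the selected autoantibodies, and
for every pair with rho above the threshold (default, strictly > 0.5) runs
a global Needleman-Wunsch alignment of the antigen protein sequences with
identity scoring (match 1, mismatch 0, linear gap -1) and reports percent
identity over the alignment length.  Traceback ties break deterministically
diagonal > up > left.

Percent identity depends on the denominator convention; the default
(alignment length) can be switched to the shorter-sequence length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .simulate import AMINO_ACIDS

__all__ = ["AlignmentResult", "needleman_wunsch", "ab_correlation_matrix",
           "crossreact_screen", "CrossReactivityScreen", "CrossReactReport",
           "read_fasta", "write_fasta"]

_ALPHABET = set(AMINO_ACIDS)


@dataclass(frozen=True)
class AlignmentResult:
    """Global pairwise alignment of two antigen sequences."""

    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float
    length: int
    identities: int
    gaps: int
    denominator: str = "alignment"

    @property
    def pct_identity(self) -> float:
        if self.denominator == "alignment":
            denom = self.length
        else:  # over the shorter ungapped sequence
            denom = min(len(self.aligned_a.replace("-", "")),
                        len(self.aligned_b.replace("-", "")))
        return 100.0 * self.identities / denom


def _check_sequence(seq: str, label: str) -> str:
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    seq = seq.upper()
    for i, c in enumerate(seq):
        if c not in _ALPHABET:
            raise ValueError(f"{label}: non-amino-acid character {c!r} at position {i + 1}")
    return seq


def needleman_wunsch(seq_a: str, seq_b: str, match: float = 1.0, mismatch: float = 0.0,
                     gap: float = -1.0, id_a: str = "a", id_b: str = "b",
                     denominator: str = "alignment") -> AlignmentResult:
    """Optimal global alignment by dynamic programming.

    Ties in the traceback resolve diagonal > up (gap in b) > left (gap in a),
    making the reported alignment deterministic.
    """
    a = _check_sequence(seq_a, id_a)
    b = _check_sequence(seq_b, id_b)
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    score[1:, 0] = gap * np.arange(1, n + 1)
    score[0, 1:] = gap * np.arange(1, m + 1)
    ptr[1:, 0] = 1
    ptr[0, 1:] = 2
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    for i in range(1, n + 1):
        sub = np.where(bb == aa[i - 1], match, mismatch)
        row_prev, row = score[i - 1], score[i]
        for j in range(1, m + 1):
            d = row_prev[j - 1] + sub[j - 1]
            u = row_prev[j] + gap
            l = row[j - 1] + gap
            # priority diagonal > up > left on ties
            if d >= u and d >= l:
                row[j] = d
                ptr[i, j] = 0
            elif u >= l:
                row[j] = u
                ptr[i, j] = 1
            else:
                row[j] = l
                ptr[i, j] = 2
    # traceback
    out_a, out_b = [], []
    i, j = n, m
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif p == 1:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    identities = sum(x == y and x != "-" for x, y in zip(aligned_a, aligned_b))
    gaps = aligned_a.count("-") + aligned_b.count("-")
    return AlignmentResult(id_a, id_b, aligned_a, aligned_b, float(score[n, m]),
                           len(aligned_a), identities, gaps, denominator)


def ab_correlation_matrix(au_subset: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Spearman rho matrix of autoantibody levels across subjects.

    Diagonal is 1; pairs involving a constant column are NaN-flagged.
    """
    df = pd.DataFrame(au_subset)
    if len(df) < 3:
        raise ValueError("correlation matrix requires at least 3 subjects")
    cols = list(df.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            res = stats.spearman(df[a], df[b])
            r = np.nan if res.undefined else res.rho
            out.loc[a, b] = out.loc[b, a] = r
    return out


@dataclass
class CrossReactReport:
    """Correlation matrix plus alignments of the highly correlated pairs."""

    correlations: pd.DataFrame
    pairs: pd.DataFrame  # id_a, id_b, rho, pct_identity, aln_len, gaps, status
    r_threshold: float

    def summary(self) -> str:
        n_pairs = len(self.pairs)
        aligned = self.pairs[self.pairs["status"] == "aligned"]
        lines = [
            f"cross-reactivity screen: {len(self.correlations)} autoantibodies, "
            f"{n_pairs} pairs with rho > {self.r_threshold}",
        ]
        if len(aligned):
            lines.append(f"max percent identity among aligned pairs: "
                         f"{aligned['pct_identity'].max():.1f}%")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)


def crossreact_screen(selected, au, sequences: dict, r_threshold: float = 0.5,
                      denominator: str = "alignment") -> CrossReactReport:
    """Align every pair of selected autoantibodies with Spearman rho strictly
    above ``r_threshold``.  A qualifying pair missing a sequence is reported
    as unresolved rather than failing the screen."""
    values = au.values if hasattr(au, "values") and not isinstance(au, pd.DataFrame) else pd.DataFrame(au)
    sub = values[list(selected)]
    corr = ab_correlation_matrix(sub)
    rows = []
    cols = list(corr.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            rho = corr.loc[a, b]
            if not (rho > r_threshold):  # NaN-safe: skip at/below threshold
                continue
            row = {"id_a": a, "id_b": b, "rho": float(rho)}
            if a in sequences and b in sequences:
                res = needleman_wunsch(str(sequences[a]), str(sequences[b]),
                                       id_a=a, id_b=b, denominator=denominator)
                row.update(pct_identity=res.pct_identity, aln_len=res.length,
                           gaps=res.gaps, status="aligned")
            else:
                row.update(pct_identity=np.nan, aln_len=0, gaps=0, status="unresolved")
            rows.append(row)
    pairs = pd.DataFrame(rows, columns=["id_a", "id_b", "rho", "pct_identity",
                                        "aln_len", "gaps", "status"])
    return CrossReactReport(corr, pairs, r_threshold)


class CrossReactivityScreen:
    """Model object for the correlation-then-alignment screen."""

    def __init__(self, au_subset: pd.DataFrame, sequences: dict,
                 r_threshold: float = 0.5, denominator: str = "alignment"):
        self.au_subset = pd.DataFrame(au_subset)
        self.sequences = {k: str(v) for k, v in sequences.items()}
        self.r_threshold = r_threshold
        self.denominator = denominator

    def fit(self) -> CrossReactReport:
        return crossreact_screen(list(self.au_subset.columns), self.au_subset,
                                 self.sequences, self.r_threshold, self.denominator)


def read_fasta(path) -> dict:
    """FASTA file -> {antigen id: sequence string}."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records, path) -> None:
    from Bio import SeqIO

    SeqIO.write(records, str(path), "fasta")
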