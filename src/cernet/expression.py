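"""Expression-matrix container, quantile normalization, and differential
expression.

The substrate is a features x samples matrix of log2 intensities with a
feature-kind annotation (mRNA | lncRNA | circRNA | miRNA) and a two-group
sample annotation (case | control). Differential expression follows the
classic microarray screen: per-feature log2 fold change (case minus
control) combined with a pooled-variance Student's t-test, a feature being
flagged when |log2FC| exceeds the fold-change threshold AND the raw
two-tailed p falls below the p threshold. Benjamini-Hochberg q-values are
reported alongside for transparency but do not gate the flag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientReplicationError, ValidationError

logger = logging.getLogger(__name__)

FEATURE_KINDS = ("mRNA", "lncRNA", "circRNA", "miRNA")
SAMPLE_GROUPS = ("case", "control")


@dataclass
class ExpressionMatrix:
    """Log2 expression values with feature-kind and sample-group annotations.

    Parameters
    ----------
    values
        DataFrame of log2 intensities, index = feature ids, columns =
        sample ids.
    feature_kinds
        Series mapping each feature id to one of ``FEATURE_KINDS``.
    sample_groups
        Series mapping each sample id to ``"case"`` or ``"control"``.
    """

    values: pd.DataFrame
    feature_kinds: pd.Series
    sample_groups: pd.Series

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.feature_kinds = pd.Series(self.feature_kinds, dtype=object)
        self.sample_groups = pd.Series(self.sample_groups, dtype=object)
        self.validate()

    def validate(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate feature id: {dup!r}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValidationError("expression values must be finite")
        if list(self.feature_kinds.index) != list(self.values.index):
            raise ValidationError("feature_kinds index must match values index")
        if list(self.sample_groups.index) != list(self.values.columns):
            raise ValidationError("sample_groups index must match values columns")
        bad_kind = set(self.feature_kinds) - set(FEATURE_KINDS)
        if bad_kind:
            raise ValidationError(f"unknown feature kind(s): {sorted(bad_kind)}")
        bad_grp = set(self.sample_groups) - set(SAMPLE_GROUPS)
        if bad_grp:
            raise ValidationError(f"unknown sample group(s): {sorted(bad_grp)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s, g in self.sample_groups.items() if g == group]

    def subset_kinds(self, kinds: Iterable[str]) -> "ExpressionMatrix":
        kinds = set(kinds)
        keep = self.feature_kinds[self.feature_kinds.isin(kinds)].index
        return ExpressionMatrix(
            self.values.loc[keep], self.feature_kinds.loc[keep], self.sample_groups
        )

    # ------------------------------------------------------------------ I/O
    # TSV dialect: one comment line "#group<TAB>g1<TAB>g2..." aligned to the
    # sample columns, then a header "feature_id<TAB>kind<TAB>s1<TAB>s2...".

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write("#group\t\t" + "\t".join(self.sample_groups) + "\n")
            fh.write("feature_id\tkind\t" + "\t".join(self.sample_ids) + "\n")
            for fid in self.feature_ids:
                row = "\t".join(f"{v:.10g}" for v in self.values.loc[fid])
                fh.write(f"{fid}\t{self.feature_kinds[fid]}\t{row}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        path = Path(path)
        with path.open() as fh:
            group_line = fh.readline().rstrip("\n")
            if not group_line.startswith("#group\t"):
                raise ValidationError(
                    f"{path}: first line must be a '#group' annotation"
                )
            groups = group_line.split("\t")[2:]
            table = pd.read_csv(fh, sep="\t", index_col=0)
        kinds = table.pop("kind")
        if len(groups) != table.shape[1]:
            raise ValidationError(f"{path}: group annotation/sample count mismatch")
        return cls(table, kinds, pd.Series(groups, index=table.columns))


@dataclass
class DERecord:
    """Per-feature differential-expression result."""

    feature_id: str
    kind: str
    mean_case: float
    mean_control: float
    log2fc: float
    t_stat: float
    p_value: float
    q_value: float = float("nan")
    is_de: bool = False


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to the common distribution of row means over
    sorted columns.

    Each output column holds, at the rank positions of its input, the mean
    across columns of the column-sorted input; every output column therefore
    carries the identical multiset of values. Ties are broken by stable row
    order, which keeps the multiset property exact. Feature and sample order
    are preserved.
    """
    X = matrix.values.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValidationError("quantile_normalize: values must be finite")
    if X.shape[1] == 1:
        return ExpressionMatrix(
            matrix.values.copy(), matrix.feature_kinds, matrix.sample_groups
        )
    order = np.argsort(X, axis=0, kind="stable")
    ref = np.take_along_axis(X, order, axis=0).mean(axis=1)
    out = np.empty_like(X)
    np.put_along_axis(out, order, np.broadcast_to(ref[:, None], X.shape), axis=0)
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values, matrix.feature_kinds, matrix.sample_groups)


def differential_expression(
    matrix: ExpressionMatrix,
    fc_log2_threshold: float = 1.0,
    p_threshold: float = 0.05,
    equal_var: bool = True,
) -> list[DERecord]:
    """Fold-change + Student's t-test screen on log2 expression.

    log2FC = mean(case) - mean(control); t and two-tailed p from the
    pooled-variance Student's t-test (Welch available via ``equal_var=False``).
    A feature is flagged DE when |log2FC| > ``fc_log2_threshold`` (strict)
    and p < ``p_threshold`` (strict). Raw p gates the flag; BH q-values are
    attached for reporting only.

    Degenerate zero-variance features: equal means -> t = 0, p = 1; unequal
    means -> the p -> 0 limit is recorded (t = +/-inf) with a warning.
    """
    case_ids = matrix.samples_in_group("case")
    ctrl_ids = matrix.samples_in_group("control")
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise InsufficientReplicationError(
            f"need >= 2 samples per group for a t-test "
            f"(case={len(case_ids)}, control={len(ctrl_ids)})"
        )
    A = matrix.values[case_ids].to_numpy(dtype=float)
    B = matrix.values[ctrl_ids].to_numpy(dtype=float)
    n1, n0 = A.shape[1], B.shape[1]
    m1, m0 = A.mean(axis=1), B.mean(axis=1)
    log2fc = m1 - m0

    ss1 = ((A - m1[:, None]) ** 2).sum(axis=1)
    ss0 = ((B - m0[:, None]) ** 2).sum(axis=1)
    if equal_var:
        df = n1 + n0 - 2
        pooled = (ss1 + ss0) / df
        se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n0))
        dfs = np.full_like(se, float(df))
    else:
        v1, v0 = ss1 / (n1 - 1) / n1, ss0 / (n0 - 1) / n0
        se = np.sqrt(v1 + v0)
        with np.errstate(divide="ignore", invalid="ignore"):
            dfs = (v1 + v0) ** 2 / (
                v1**2 / (n1 - 1) + v0**2 / (n0 - 1)
            )

    t = np.zeros_like(se)
    p = np.ones_like(se)
    nonzero = se > 0
    t[nonzero] = log2fc[nonzero] / se[nonzero]
    p[nonzero] = 2.0 * stats.t.sf(np.abs(t[nonzero]), dfs[nonzero])
    degenerate = (~nonzero) & (log2fc != 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} feature(s) with zero within-group variance "
            "but unequal means: recording the p -> 0 limit",
            RuntimeWarning,
            stacklevel=2,
        )
        t[degenerate] = np.sign(log2fc[degenerate]) * np.inf
        p[degenerate] = 0.0

    q = multipletests(p, method="fdr_bh")[1]
    is_de = (np.abs(log2fc) > fc_log2_threshold) & (p < p_threshold)

    records = []
    for i, fid in enumerate(matrix.feature_ids):
        records.append(
            DERecord(
                feature_id=fid,
                kind=matrix.feature_kinds[fid],
                mean_case=float(m1[i]),
                mean_control=float(m0[i]),
                log2fc=float(log2fc[i]),
                t_stat=float(t[i]),
                p_value=float(p[i]),
                q_value=float(q[i]),
                is_de=bool(is_de[i]),
            )
        )
    return records


def de_table(records: Sequence[DERecord]) -> pd.DataFrame:
    """DE records as a DataFrame (feature_id, kind, log2fc, t, p, q, is_de)."""
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in records],
            "kind": [r.kind for r in records],
            "log2fc": [r.log2fc for r in records],
            "t": [r.t_stat for r in records],
            "p": [r.p_value for r in records],
            "q": [r.q_value for r in records],
            "is_de": [r.is_de for r in records],
        }
    )


def write_de_table(records: Sequence[DERecord], path: str | Path) -> None:
    de_table(records).to_csv(path, sep="\t", index=False)


def write_volcano_data(records: Sequence[DERecord], path: str | Path) -> None:
    """Export (log2fc, -log10 p) pairs for volcano plotting."""
    with np.errstate(divide="ignore"):
        tab = pd.DataFrame(
            {
                "feature_id": [r.feature_id for r in records],
                "log2fc": [r.log2fc for r in records],
                "neg_log10_p": [
                    -np.log10(r.p_value) if r.p_value > 0 else np.inf
                    for r in records
                ],
            }
        )
    tab.to_csv(path, sep="\t", index=False)
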