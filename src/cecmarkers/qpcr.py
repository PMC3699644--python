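"""Housekeeping-normalized qPCR relative quantification and group statistics.

The quantification is the classic comparative-Ct (2^-ΔΔCt) procedure with a
fixed amplification efficiency of 2 per cycle:

* replicate Ct values of an (assay, sample) pair are averaged first;
* ΔCt(a, s) = mean Ct(a, s) − arithmetic mean over the housekeeping assays
  of their mean Ct in s (an arithmetic mean on the Ct scale is a geometric
  mean on the expression scale);
* relative expression = 100 · 2^−(ΔCt(a,s) − ΔCt(a,ref)), so the reference
  sample reads exactly 100 for every assay.

An undetected assay is carried as "not detected" (relative expression 0 with
a flag), never imputed at a maximal cycle number. Replicate scatter is
propagated to the linear scale with the delta method
(SD_linear ≈ ln 2 · value · SD_Ct) and reported as error bars.

Group comparisons use Welch's two-sample, two-tailed t-test
(unequal variances, Welch–Satterthwaite degrees of freedom), starred
"*" for p < 0.05 and "**" for p < 0.01.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionError
from .normalize import FoldChange, fold_change

#: housekeeping trio of the high-throughput array runs
DEFAULT_HOUSEKEEPING = ("GAPDH", "ATP6V0E1", "H2AFY")


@dataclass
class CtTable:
    """Long-format qPCR threshold cycles plus the housekeeping designation.

    ``data`` columns: ``assay_id``, ``sample_id``, ``replicate``, ``ct``
    (float cycles; NaN = undetected). Every housekeeping assay must be
    measured in every sample and detected Ct values must be positive.
    """

    data: pd.DataFrame
    housekeeping: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        required = {"assay_id", "sample_id", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ExpressionError(f"Ct table missing column(s): {sorted(missing)}")
        self.housekeeping = frozenset(map(str, self.housekeeping))
        if not self.housekeeping:
            raise ExpressionError("housekeeping assay set must be non-empty")
        data = self.data.copy()
        data["ct"] = pd.to_numeric(data["ct"], errors="coerce")
        if ((data["ct"] <= 0) & data["ct"].notna()).any():
            raise ExpressionError("detected Ct values must be positive")
        self.data = data
        samples = set(data["sample_id"])
        for hk in sorted(self.housekeeping):
            measured = set(data.loc[data["assay_id"] == hk, "sample_id"])
            absent = samples - measured
            if absent:
                raise ExpressionError(
                    f"housekeeping assay {hk!r} not measured in sample(s) "
                    f"{sorted(absent)}")

    @property
    def assays(self) -> list[str]:
        return sorted(set(self.data["assay_id"]))

    @property
    def samples(self) -> list[str]:
        return sorted(set(self.data["sample_id"]))


def read_ct_long(path, housekeeping=DEFAULT_HOUSEKEEPING) -> CtTable:
    """Read a long-format TSV (assay_id, sample_id, replicate, ct).

    ``ct`` cells that are empty or read "ND"/"undetected" become NaN.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    table["ct"] = pd.to_numeric(
        table["ct"].replace({"ND": None, "nd": None, "undetected": None, "": None}),
        errors="raise")
    table["replicate"] = pd.to_numeric(table["replicate"]).astype(int)
    return CtTable(table, frozenset(housekeeping))


def read_ct_wide(path, housekeeping=DEFAULT_HOUSEKEEPING) -> CtTable:
    """Read a wide, array-style export: assay rows, one column per sample,
    repeated sample columns meaning replicates (pandas suffixes them
    ``sample``, ``sample.1``, ...)."""
    table = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    rows = []
    seen: dict[str, int] = {}
    for column in table.columns:
        sample = column.split(".")[0] if column.split(".")[-1].isdigit() else column
        seen[sample] = seen.get(sample, 0) + 1
        replicate = seen[sample]
        for assay, cell in table[column].items():
            ct = np.nan if cell in (None, "", "ND", "nd") or pd.isna(cell) \
                else float(cell)
            rows.append({"assay_id": str(assay), "sample_id": sample,
                         "replicate": replicate, "ct": ct})
    return CtTable(pd.DataFrame(rows), frozenset(housekeeping))


def _mean_ct(table: CtTable) -> pd.DataFrame:
    """Replicate-aggregated Ct per (assay, sample): mean, SD, n, detected."""
    def agg(group: pd.Series) -> pd.Series:
        detected = group.dropna()
        return pd.Series({
            "mean_ct": detected.mean() if len(detected) else np.nan,
            "sd_ct": detected.std(ddof=1) if len(detected) > 1 else 0.0,
            "n_replicates": len(group),
            "detected": bool(len(detected)),
        })

    return table.data.groupby(["assay_id", "sample_id"])["ct"].apply(agg).unstack()


def delta_ct(table: CtTable) -> pd.DataFrame:
    """Housekeeping-normalized ΔCt per (assay, sample).

    Returns a frame indexed by (assay_id, sample_id) with columns
    ``delta_ct``, ``sd_ct``, ``n_replicates``, ``detected``. Housekeeping
    assays undetected in any sample abort with an error naming the sample.
    """
    means = _mean_ct(table)
    hk_reference = {}
    for sample in table.samples:
        hk_values = []
        for hk in sorted(table.housekeeping):
            row = means.loc[(hk, sample)]
            if not row["detected"]:
                raise ExpressionError(
                    f"housekeeping assay {hk!r} undetected in sample {sample!r}")
            hk_values.append(row["mean_ct"])
        hk_reference[sample] = float(np.mean(hk_values))

    out = means.copy()
    out["delta_ct"] = [
        row["mean_ct"] - hk_reference[sample] if row["detected"] else np.nan
        for (_assay, sample), row in means.iterrows()]
    return out[["delta_ct", "sd_ct", "n_replicates", "detected"]]


def relative_expression(delta_cts: pd.DataFrame,
                        reference_sample: str) -> pd.DataFrame:
    """Scale ΔCt values so the reference sample reads 100 for every assay.

    value(a, s) = 100 · 2^−(ΔCt(a,s) − ΔCt(a,ref)); undetected assays get
    value 0 with ``detected=False``. A missing or undetected reference
    measurement is an error naming the assay.
    """
    assays = sorted({a for a, _ in delta_cts.index})
    rows = []
    for assay in assays:
        key = (assay, reference_sample)
        if key not in delta_cts.index or not delta_cts.loc[key, "detected"]:
            raise ExpressionError(
                f"assay {assay!r}: no detected measurement in reference sample "
                f"{reference_sample!r}")
        ref = delta_cts.loc[key, "delta_ct"]
        sub = delta_cts.loc[assay]
        for sample, row in sub.iterrows():
            if row["detected"]:
                value = 100.0 * 2.0 ** (-(row["delta_ct"] - ref))
                sd = math.log(2.0) * value * row["sd_ct"]
            else:
                value, sd = 0.0, 0.0
            rows.append({"assay_id": assay, "sample_id": sample,
                         "value": value, "sd": sd,
                         "detected": bool(row["detected"])})
    return pd.DataFrame(rows).set_index(["assay_id", "sample_id"])


@dataclass(frozen=True)
class GroupStats:
    """Welch-test comparison of two groups of relative expressions."""

    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    fold: FoldChange
    t_statistic: float
    df: float
    p_value: float
    stars: str
    degenerate: bool = False


def significance_stars(p_value: float) -> str:
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


def group_stats(values_a, values_b,
                label_a: str = "a", label_b: str = "b") -> GroupStats:
    """Mean ± SD per group, fold a/b, and Welch's two-tailed t-test."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ExpressionError("each group needs at least one value")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    sd_a = float(a.std(ddof=1)) if len(a) > 1 else 0.0
    sd_b = float(b.std(ddof=1)) if len(b) > 1 else 0.0
    fold = fold_change(mean_a, mean_b, label_a, label_b) if mean_a >= 0 and mean_b >= 0 \
        else FoldChange(label_a, label_b, None)

    if len(a) < 2 or len(b) < 2:
        raise ExpressionError("the t-test needs at least two values per group")

    degenerate = sd_a == 0.0 and sd_b == 0.0
    if degenerate:
        # zero variance in both groups: equal means are indistinguishable
        p = 1.0 if mean_a == mean_b else 0.0
        t, df = 0.0 if mean_a == mean_b else math.inf, float(len(a) + len(b) - 2)
    else:
        result = stats.ttest_ind(a, b, equal_var=False)
        t, p = float(result.statistic), float(result.pvalue)
        df = float(result.df)
    return GroupStats(mean_a, sd_a, mean_b, sd_b, fold, t, df, p,
                      significance_stars(p), degenerate)
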