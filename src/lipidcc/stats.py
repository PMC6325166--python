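"""Biomarker-screening statistics over isomer-ratio and subclass tables.

The measured quantities are of two kinds: subclass-level relative
quantitation I/I_IS (species intensity over a spiked internal standard)
and C=C isomer ratios I_ΔA/I_ΔB.  Group differences are tested with a
two-tailed Student's t-test (Welch optional), corrected for multiple
testing by Benjamini–Hochberg, and sample structure is explored by
hierarchical clustering of standardized log-ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from sklearn.metrics import rand_score
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SampleRatioTable",
    "ComparisonResult",
    "HClusterResult",
    "relative_quant",
    "summarize_replicates",
    "group_compare",
    "compare_all",
    "adjust_pvalues",
    "significance_stars",
    "hcluster",
    "rsd_decomposition",
]


@dataclass
class SampleRatioTable:
    """Samples × measurements matrix with group / replicate structure.

    ``data`` rows are observations (one per technical repeat when
    ``individual`` is provided); columns are measurements.  ``kinds``
    maps each column to ``"isomer_ratio"`` or ``"subclass"``.
    """

    data: pd.DataFrame
    groups: pd.Series
    individual: pd.Series | None = None
    kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.groups.index):
            raise ValueError("groups must be indexed like the data rows")
        if self.individual is not None and not self.data.index.equals(
            self.individual.index
        ):
            raise ValueError("individual ids must be indexed like the data rows")
        values = self.data.to_numpy(dtype=float)
        if np.any(values[np.isfinite(values)] <= 0):
            raise ValueError("ratio measurements must be positive (NaN = missing)")

    @property
    def group_names(self) -> list[str]:
        return sorted(self.groups.unique())

    def columns_of_kind(self, kind: str) -> list[str]:
        return [c for c in self.data.columns if self.kinds.get(c, "isomer_ratio") == kind]

    def collapse_technical(self) -> "SampleRatioTable":
        """Average technical repeats, one row per individual."""
        if self.individual is None:
            return self
        grouped = self.data.groupby(self.individual)
        data = grouped.mean()
        groups = self.groups.groupby(self.individual).first()
        return SampleRatioTable(data, groups.loc[data.index], None, dict(self.kinds))

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "group", self.groups)
        if self.individual is not None:
            out.insert(1, "individual", self.individual)
        out.to_csv(path, index_label="sample")

    @classmethod
    def from_csv(cls, path, kinds: Mapping[str, str] | None = None) -> "SampleRatioTable":
        raw = pd.read_csv(path, index_col="sample")
        groups = raw.pop("group")
        individual = raw.pop("individual") if "individual" in raw.columns else None
        return cls(raw, groups, individual, dict(kinds or {}))


def relative_quant(intensity: float, is_intensity: float) -> float:
    """Subclass-level relative quantitation I/I_IS."""
    if is_intensity is None or not np.isfinite(is_intensity) or is_intensity <= 0:
        warnings.warn("internal standard missing; measurement dropped", stacklevel=2)
        return float("nan")
    return intensity / is_intensity


def summarize_replicates(values: Sequence[float]) -> tuple[float, float, float]:
    """(mean, s.d., RSD %) over biological replicates."""
    arr = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if arr.size == 0:
        return float("nan"), float("nan"), float("nan")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return mean, sd, 100.0 * sd / mean if mean else float("nan")


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class ComparisonResult:
    """Two-group comparison of one measurement."""

    measurement: str
    kind: str
    group_names: tuple[str, str]
    means: tuple[float, float]
    sds: tuple[float, float]
    rsds: tuple[float, float]
    p_value: float
    adjusted_p: float | None = None
    welch: bool = False
    degenerate: bool = False

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def group_compare(
    table: SampleRatioTable, measurement: str, welch: bool = False
) -> ComparisonResult:
    """Two-tailed Student's t-test (equal variance; Welch switchable)."""
    names = table.group_names
    if len(names) != 2:
        raise ValueError(f"need exactly 2 groups, found {names}")
    values = table.data[measurement]
    a = values[table.groups == names[0]].dropna().to_numpy(dtype=float)
    b = values[table.groups == names[1]].dropna().to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >=2 values")
    degenerate = a.std(ddof=1) == 0 and b.std(ddof=1) == 0
    if degenerate and np.allclose(a.mean(), b.mean()):
        p = 1.0
        degenerate = False  # identical groups: no evidence of difference
    elif degenerate:
        p = float("nan")
    else:
        p = float(sps.ttest_ind(a, b, equal_var=not welch).pvalue)
    stats_a = summarize_replicates(a)
    stats_b = summarize_replicates(b)
    return ComparisonResult(
        measurement,
        table.kinds.get(measurement, "isomer_ratio"),
        (names[0], names[1]),
        (stats_a[0], stats_b[0]),
        (stats_a[1], stats_b[1]),
        (stats_a[2], stats_b[2]),
        p,
        welch=welch,
        degenerate=degenerate,
    )


def adjust_pvalues(pvals: Sequence[float], method: str = "fdr_bh") -> np.ndarray:
    """Multiple-testing adjustment (Benjamini–Hochberg by default)."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method=method)[1]


def compare_all(
    table: SampleRatioTable, welch: bool = False, method: str = "fdr_bh"
) -> list[ComparisonResult]:
    """Test every measurement and attach adjusted p-values."""
    results = [group_compare(table, m, welch) for m in table.data.columns]
    finite = [r for r in results if np.isfinite(r.p_value)]
    adjusted = adjust_pvalues([r.p_value for r in finite], method)
    for r, q in zip(finite, adjusted):
        r.adjusted_p = float(q)
    return results


# ---------------------------------------------------------------------------
# hierarchical clustering

@dataclass
class HClusterResult:
    linkage: np.ndarray
    samples: list[str]
    flat_labels: np.ndarray | None
    rand_index: float | None
    standardization: str
    distance: str
    method: str

    def newick(self) -> str:
        """Dendrogram as a Newick-like text tree."""
        tree = hierarchy.to_tree(self.linkage)

        def render(node) -> str:
            if node.is_leaf():
                return str(self.samples[node.id])
            left, right = render(node.left), render(node.right)
            return f"({left}:{node.left.dist:.4f},{right}:{node.right.dist:.4f})"

        return render(tree) + ";"


def _standardize(data: pd.DataFrame, how: str) -> np.ndarray:
    x = data.to_numpy(dtype=float)
    if how == "log2-z":
        x = np.log2(x)
    elif how != "z":
        raise ValueError(f"unknown standardization {how!r}")
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def hcluster(
    table: SampleRatioTable,
    k: int | None = None,
    columns: Sequence[str] | None = None,
    standardize: str = "log2-z",
    distance: str = "euclidean",
    method: str = "average",
) -> HClusterResult:
    """Hierarchically cluster samples on standardized (log2, z) ratios.

    With ``k`` given, a flat cut into ``k`` clusters is returned along
    with the Rand index of its agreement with the known group labels.
    """
    collapsed = table.collapse_technical()
    data = collapsed.data[list(columns)] if columns else collapsed.data
    if data.isna().any().any():
        raise ValueError("clustering requires a complete (or imputed) matrix")
    if k is not None and k > len(data):
        raise ValueError(f"k={k} exceeds the {len(data)} samples")
    x = _standardize(data, standardize)
    link = hierarchy.linkage(x, method=method, metric=distance)
    flat = rand = None
    if k is not None:
        flat = hierarchy.fcluster(link, t=k, criterion="maxclust")
        rand = float(rand_score(collapsed.groups.to_numpy(), flat))
    return HClusterResult(
        link, [str(s) for s in data.index], flat, rand, standardize, distance, method
    )


# ---------------------------------------------------------------------------
# RSD decomposition

def rsd_decomposition(table: SampleRatioTable) -> pd.DataFrame:
    """Technical vs inter-individual RSD per measurement.

    Technical RSD is the mean per-individual RSD over nested repeats;
    inter-individual RSD is the RSD of the per-individual means.  Without
    replicate structure only the pooled RSD is reported.
    """
    rows = []
    for col in table.data.columns:
        kind = table.kinds.get(col, "isomer_ratio")
        values = table.data[col]
        if table.individual is None:
            mean, sd, rsd = summarize_replicates(values)
            rows.append(
                {"measurement": col, "kind": kind, "technical_rsd_pct": np.nan,
                 "inter_individual_rsd_pct": np.nan, "pooled_rsd_pct": rsd}
            )
            continue
        per_ind = values.groupby(table.individual)
        tech = []
        means = []
        for _, repeats in per_ind:
            m, sd, rsd = summarize_replicates(repeats)
            means.append(m)
            if len(repeats.dropna()) > 1:
                tech.append(rsd)
        _, _, inter = summarize_replicates(means)
        _, _, pooled = summarize_replicates(values)
        rows.append(
            {
                "measurement": col, "kind": kind,
                "technical_rsd_pct": float(np.mean(tech)) if tech else np.nan,
                "inter_individual_rsd_pct": inter,
                "pooled_rsd_pct": pooled,
            }
        )
    return pd.DataFrame(rows).set_index("measurement")
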