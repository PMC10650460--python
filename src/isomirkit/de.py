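"""Downstream gene-set machinery: BH-FDR, fold-change gene sets, Venn
partitions and 2^−ΔΔCt qPCR quantification.

Gene sets are built from per-gene differential-expression tables with the
inclusive/strict boundary semantics "≥ fold-change threshold" and
"adjusted p < alpha". A simple two-sample count test is provided as plumbing
so synthetic count matrices can be pushed end-to-end; it is a deliberately
plain stand-in (median-of-ratios normalization + Welch t on log counts), not
a negative-binomial GLM.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class DEInputError(ValueError):
    pass


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, returned in input order.

    q_(i) = p_(i)·n/i on the ascending sort, monotonized from the largest
    rank down and capped at 1.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise DEInputError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return [float(q) for q in adjusted]


@dataclass
class DEResultTable:
    """Per-gene DE statistics for one contrast (treatment vs control)."""

    frame: pd.DataFrame  # columns: gene_id, log2fc, pvalue and/or padj
    contrast: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        df = self.frame
        required = {"gene_id", "log2fc"}
        if not required.issubset(df.columns):
            raise DEInputError(f"DE table must have columns {sorted(required)}")
        if df["gene_id"].duplicated().any():
            raise DEInputError("duplicate gene_id in DE table")
        has_p = "pvalue" in df.columns
        has_padj = "padj" in df.columns
        if not has_p and not has_padj:
            raise DEInputError("DE table needs pvalue and/or padj")
        pv = df["pvalue"] if has_p else pd.Series(np.nan, index=df.index)
        pa = df["padj"] if has_padj else pd.Series(np.nan, index=df.index)
        if (pv.isna() & pa.isna()).any():
            raise DEInputError("every row needs at least one of pvalue/padj")

    @property
    def has_padj(self) -> bool:
        return "padj" in self.frame.columns and self.frame["padj"].notna().all()

    def with_padj(self) -> "DEResultTable":
        """Return a table guaranteed to carry padj.

        When padj is already present (e.g. exported from an external DE tool)
        it is kept as-is; otherwise BH adjustment is applied to pvalue.
        """
        if self.has_padj:
            return self
        df = self.frame.copy()
        df["padj"] = bh_adjust(df["pvalue"].tolist())
        return DEResultTable(df, self.contrast, self.condition)

    @classmethod
    def read_tsv(cls, path: str | Path, contrast: str = "", condition: str = "") -> "DEResultTable":
        return cls(pd.read_csv(path, sep="\t"), contrast, condition)

    def write_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def de_sets(
    table: DEResultTable,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    inclusive_alpha: bool = False,
) -> tuple[set[str], set[str]]:
    """Up/down-regulated gene sets at a fold-change and adjusted-p threshold.

    up = {g : padj < alpha and fold change ≥ fc_threshold};
    down = {g : padj < alpha and fold change ≤ 1/fc_threshold}.
    The fold-change comparator is inclusive and the significance comparator
    strict (``inclusive_alpha`` switches to ≤). Comparison happens in log2
    space, which is exact for thresholds expressed as log2 fold changes.
    """
    if fc_threshold <= 1:
        raise DEInputError("fc_threshold must exceed 1")
    df = table.with_padj().frame
    log_thresh = math.log2(fc_threshold)
    padj = df["padj"].to_numpy(dtype=float)
    lfc = df["log2fc"].to_numpy(dtype=float)
    sig = padj <= alpha if inclusive_alpha else padj < alpha
    genes = df["gene_id"].astype(str).to_numpy()
    up = set(genes[sig & (lfc >= log_thresh)])
    down = set(genes[sig & (lfc <= -log_thresh)])
    return up, down


def diff_vs_reference(
    ref_set: set[str], iso_set: set[str]
) -> tuple[set[str], set[str], set[str]]:
    """Three-way partition (shared, iso_only, ref_only) of ref ∪ iso."""
    return ref_set & iso_set, iso_set - ref_set, ref_set - iso_set


@dataclass
class GeneSetPartition:
    """Disjoint Venn regions of 2–3 named gene sets; union == universe."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    universe: set[str] = field(default_factory=set)

    def region_sizes(self) -> dict[str, int]:
        return {label: len(members) for label, members in self.sets.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": label, "size": len(members), "genes": ",".join(sorted(members))}
            for label, members in self.sets.items()
        ]
        return pd.DataFrame(rows, columns=["region", "size", "genes"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def venn_partition(named_sets: Mapping[str, set[str]]) -> GeneSetPartition:
    """Exact Venn region partition of 2 or 3 named sets.

    Region labels are "<name> only" for exclusive regions and "A∩B" /
    "A∩B∩C" for intersections, in the input's name order. Regions are
    pairwise disjoint and their union is the universe.
    """
    names = list(named_sets)
    if len(names) not in (2, 3):
        raise DEInputError("venn_partition supports exactly 2 or 3 sets")
    universe = set().union(*named_sets.values())
    regions: dict[str, set[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set(combo)
            members = {
                g
                for g in universe
                if all(g in named_sets[n] for n in combo)
                and all(g not in named_sets[n] for n in names if n not in inside)
            }
            label = f"{combo[0]} only" if r == 1 else "∩".join(combo)
            regions[label] = members
    return GeneSetPartition(sets=regions, universe=universe)


@dataclass
class CtTable:
    """qPCR Ct values: per-sample target and reference-gene Ct, grouped
    control vs treated."""

    frame: pd.DataFrame  # columns: sample, group, target_ct, ref_ct

    def __post_init__(self) -> None:
        df = self.frame
        required = {"sample", "group", "target_ct", "ref_ct"}
        if not required.issubset(df.columns):
            raise DEInputError(f"Ct table must have columns {sorted(required)}")
        if not set(df["group"]).issubset({"control", "treated"}):
            raise DEInputError("group must be 'control' or 'treated'")
        for col in ("target_ct", "ref_ct"):
            vals = df[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
                raise DEInputError(f"{col} values must be positive and finite")
        for group in ("control", "treated"):
            if not (df["group"] == group).any():
                raise DEInputError(f"Ct table needs at least one {group} row")

    @classmethod
    def read_csv(cls, path: str | Path) -> "CtTable":
        return cls(pd.read_csv(path))


def ddct_fold_change(ct: CtTable) -> float:
    """Relative expression by the 2^−ΔΔCt method.

    ΔCt = target_ct − ref_ct per sample; ΔΔCt = mean ΔCt(treated) − mean
    ΔCt(control); fold change = 2^−ΔΔCt relative to the control group.
    """
    df = ct.frame
    dct = df["target_ct"].to_numpy(dtype=float) - df["ref_ct"].to_numpy(dtype=float)
    treated = dct[(df["group"] == "treated").to_numpy()]
    control = dct[(df["group"] == "control").to_numpy()]
    ddct = treated.mean() - control.mean()
    return float(2.0 ** (-ddct))


def _median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style size factors: median over genes of count/geometric mean,
    restricted to genes with all-positive counts."""
    log_counts = np.log(counts.where(counts > 0))
    log_geomean = log_counts.mean(axis=1)
    usable = np.isfinite(log_geomean)
    if not usable.any():
        return pd.Series(1.0, index=counts.columns)
    log_ratios = log_counts.loc[usable].sub(log_geomean[usable], axis=0)
    sf = np.exp(log_ratios.median(axis=0))
    return sf.fillna(1.0)


def naive_count_test(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    contrast: str = "b_vs_a",
    condition: str = "",
) -> DEResultTable:
    """Plain two-sample DE stand-in on count matrices (genes × replicates).

    Normalizes both matrices jointly by median-of-ratios size factors, then
    reports per-gene log2 fold change of normalized means (group b over
    group a) and a two-sided Welch t-test p-value on log2(normalized + 1)
    counts. Zero within-group variance is resolved exactly: p = 0 when the
    means differ, 1 when they agree. This is plumbing for synthetic
    pipelines; it fits no dispersion model and applies no shrinkage.
    """
    if list(counts_a.index) != list(counts_b.index):
        raise DEInputError("gene indices of the two matrices must match")
    if counts_a.shape[1] < 2 or counts_b.shape[1] < 2:
        raise DEInputError("need >= 2 replicates per group")
    combined = pd.concat([counts_a, counts_b], axis=1)
    sf = _median_of_ratios_size_factors(combined)
    norm = combined.div(sf, axis=1)
    na, nb = counts_a.shape[1], counts_b.shape[1]
    norm_a = norm.iloc[:, :na].to_numpy(dtype=float)
    norm_b = norm.iloc[:, na : na + nb].to_numpy(dtype=float)

    mean_a = norm_a.mean(axis=1)
    mean_b = norm_b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.where(
            (mean_a > 0) & (mean_b > 0),
            np.log2(mean_b) - np.log2(mean_a),
            np.log2(mean_b + 0.5) - np.log2(mean_a + 0.5),
        )

    log_a = np.log2(norm_a + 1.0)
    log_b = np.log2(norm_b + 1.0)
    var_a = log_a.var(axis=1, ddof=1)
    var_b = log_b.var(axis=1, ddof=1)
    # variances this small are float jitter from normalization, not signal
    degenerate = (var_a < 1e-12) & (var_b < 1e-12)
    pvals = np.ones(len(combined))
    if (~degenerate).any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(
                log_a[~degenerate], log_b[~degenerate], axis=1, equal_var=False
            )
        pvals[~degenerate] = res.pvalue
    if degenerate.any():
        same = np.isclose(log_a.mean(axis=1), log_b.mean(axis=1))
        pvals[degenerate] = np.where(same[degenerate], 1.0, 0.0)
    pvals = np.clip(np.nan_to_num(pvals, nan=1.0), 0.0, 1.0)

    frame = pd.DataFrame(
        {
            "gene_id": combined.index.astype(str),
            "log2fc": lfc,
            "pvalue": pvals,
        }
    ).reset_index(drop=True)
    return DEResultTable(frame, contrast=contrast, condition=condition)
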