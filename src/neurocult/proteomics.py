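"""Label-free proteomics post-quantification chain.

Consumes a MaxQuant-style proteinGroups table (protein × sample raw
intensities with contaminant/decoy flags; zeros mean "not detected") and
runs the standard chain: contaminant removal → ≥50% presence filter →
imputation (down-shifted Gaussian by default) → log2 + per-sample median
normalization → Welch-t differential expression under the
">1.5-fold and p < 0.1" rule → PCA / volcano data → a generic
hypergeometric over-representation test with Benjamini–Hochberg
adjustment.

The DE rule is applied to raw p-values (no multiple-testing correction
is part of the call), with ">1.5-fold" read symmetrically as
max(fc, 1/fc) > 1.5 so downregulation is callable.  Both inequalities
are strict: fc = 1.5 or p = 0.1 is not differentially expressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import (
    ConfigurationError,
    DataError,
    DomainError,
    FormatError,
    InsufficientSampleError,
    ValidationError,
)

__all__ = [
    "ProteinTable",
    "OraResult",
    "read_protein_table",
    "filter_contaminants",
    "filter_valid",
    "impute_missing",
    "log2_and_normalize",
    "differential_expression",
    "is_differentially_expressed",
    "pca_scores",
    "volcano_data",
    "overrepresentation",
]

STATES = ("raw", "filtered", "imputed", "log2", "normalized")


@dataclass
class ProteinTable:
    """Protein × sample intensity matrix with flags and group mapping.

    ``intensities`` is indexed by protein id with one column per sample;
    missing measurements are NaN.  ``state`` tracks the processing stage
    (raw → filtered → imputed → log2 → normalized); values are linear
    until the log2 step.
    """

    intensities: pd.DataFrame
    sample_groups: dict[str, str]
    gene_symbols: Optional[pd.Series] = None
    is_contaminant: Optional[pd.Series] = None
    is_decoy: Optional[pd.Series] = None
    state: str = "raw"

    def __post_init__(self):
        if self.state not in STATES:
            raise ValidationError(f"unknown state {self.state!r}")
        if self.intensities.index.has_duplicates:
            dupes = self.intensities.index[
                self.intensities.index.duplicated()].tolist()
            raise FormatError(f"duplicate protein ids: {dupes[:5]}")
        missing = [s for s in self.intensities.columns
                   if s not in self.sample_groups]
        if missing:
            raise ValidationError(
                f"samples without a group assignment: {missing}")
        if self.is_contaminant is None:
            self.is_contaminant = pd.Series(False, index=self.intensities.index)
        if self.is_decoy is None:
            self.is_decoy = pd.Series(False, index=self.intensities.index)

    @property
    def protein_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.sample_groups[s] for s in self.samples))

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.samples if self.sample_groups[s] == group]

    def replace(self, **kw) -> "ProteinTable":
        return dc_replace(self, **kw)

    def _subset(self, keep: pd.Index, state: str) -> "ProteinTable":
        return self.replace(
            intensities=self.intensities.loc[keep],
            gene_symbols=None if self.gene_symbols is None
            else self.gene_symbols.loc[keep],
            is_contaminant=self.is_contaminant.loc[keep],
            is_decoy=self.is_decoy.loc[keep],
            state=state,
        )

    def to_tsv(self, path, intensity_prefix: str = "Intensity ") -> None:
        """Write a proteinGroups-style TSV (missing written as 0)."""
        out = pd.DataFrame(index=self.intensities.index)
        out.index.name = "Protein IDs"
        if self.gene_symbols is not None:
            out["Gene names"] = self.gene_symbols
        out["Potential contaminant"] = np.where(self.is_contaminant, "+", "")
        out["Reverse"] = np.where(self.is_decoy, "+", "")
        for s in self.samples:
            out[f"{intensity_prefix}{s}"] = self.intensities[s].fillna(0.0)
        out.to_csv(path, sep="\t")


def read_protein_table(path, sample_groups: dict[str, str],
                       id_col: str = "Protein IDs",
                       gene_col: str = "Gene names",
                       contaminant_col: str = "Potential contaminant",
                       reverse_col: str = "Reverse",
                       intensity_prefix: str = "Intensity ") -> ProteinTable:
    """Parse a MaxQuant-style proteinGroups TSV.

    Intensity zeros and NA are both treated as missing (the MaxQuant
    convention: 0 means "not detected", not a measurement).
    """
    df = pd.read_csv(path, sep="\t", dtype={id_col: str} if id_col else None)
    if id_col not in df.columns:
        raise FormatError(f"missing id column {id_col!r}")
    if df[id_col].duplicated().any():
        dupes = df.loc[df[id_col].duplicated(), id_col].tolist()
        raise FormatError(f"duplicate protein ids: {dupes[:5]}")
    df = df.set_index(id_col)
    int_cols = [c for c in df.columns if c.startswith(intensity_prefix)]
    if not int_cols:
        raise FormatError(
            f"no intensity columns with prefix {intensity_prefix!r}")
    intens = pd.DataFrame(index=df.index)
    for c in int_cols:
        sample = c[len(intensity_prefix):]
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = vals.isna() & df[c].notna() & (df[c].astype(str).str.strip()
                                             .str.upper() != "NA")
        if bad.any():
            raise FormatError(
                f"non-numeric intensity in column {c!r}, "
                f"row {bad.idxmax()!r}")
        intens[sample] = vals.replace(0.0, np.nan)
    missing = [s for s in intens.columns if s not in sample_groups]
    if missing:
        raise FormatError(f"samples without a group assignment: {missing}")

    def flag(col):
        if col in df.columns:
            return df[col].fillna("").astype(str).str.strip() == "+"
        return pd.Series(False, index=df.index)

    return ProteinTable(
        intensities=intens,
        sample_groups={s: sample_groups[s] for s in intens.columns},
        gene_symbols=df[gene_col] if gene_col in df.columns else None,
        is_contaminant=flag(contaminant_col),
        is_decoy=flag(reverse_col),
        state="raw",
    )


def filter_contaminants(table: ProteinTable) -> ProteinTable:
    """Drop rows flagged as potential contaminants or reverse decoys."""
    keep = table.protein_ids[~(table.is_contaminant | table.is_decoy)]
    return table._subset(keep, state="filtered")


def filter_valid(table: ProteinTable, min_presence: float = 0.5
                 ) -> ProteinTable:
    """Keep proteins present in at least ``min_presence`` of the samples.

    "At least" is inclusive: a protein observed in exactly half of the
    samples passes at the default 0.5.
    """
    if not 0.0 < min_presence <= 1.0:
        raise ConfigurationError("min_presence must lie in (0, 1]")
    frac = table.intensities.notna().mean(axis=1)
    keep = table.protein_ids[frac >= min_presence]
    return table._subset(keep, state="filtered")


def impute_missing(table: ProteinTable, method: str = "downshift",
                   seed: int = 0, shift: float = 1.8, width: float = 0.3
                   ) -> ProteinTable:
    """Fill missing intensities; observed values are untouched.

    ``downshift`` (default): per sample, missing values are drawn from a
    Gaussian on the log2 scale centered ``shift`` standard deviations
    below that sample's observed mean with ``width`` times its standard
    deviation, then back-transformed — the conventional model for
    below-detection-limit missingness.  ``half_min`` substitutes half of
    the sample's observed minimum.  Deterministic under ``seed``.
    """
    intens = table.intensities
    all_missing = intens.isna().all(axis=1)
    if all_missing.any():
        raise DataError(
            f"{int(all_missing.sum())} proteins have no observed values; "
            "apply filter_valid first")
    if not intens.isna().any().any():
        return table.replace(state="imputed")
    out = intens.copy()
    rng = np.random.default_rng(seed)
    for s in table.samples:  # fixed column order keeps the draws deterministic
        col = out[s]
        miss = col.isna()
        if not miss.any():
            continue
        obs = np.log2(col[~miss].to_numpy(dtype=float))
        if method == "downshift":
            mu, sd = float(obs.mean()), float(obs.std(ddof=1))
            draws = rng.normal(mu - shift * sd, width * sd, size=int(miss.sum()))
            out.loc[miss, s] = np.power(2.0, draws)
        elif method == "half_min":
            out.loc[miss, s] = float(np.power(2.0, obs.min())) / 2.0
        else:
            raise ConfigurationError(f"unknown imputation method {method!r}")
    return table.replace(intensities=out, state="imputed")


def log2_and_normalize(table: ProteinTable, method: str = "median"
                       ) -> ProteinTable:
    """log2-transform, then equalize samples.

    ``median`` (default) centers every sample's median on the grand
    median — afterwards all sample medians agree to machine precision.
    ``quantile`` maps each sample onto the mean order-statistic profile.
    """
    intens = table.intensities
    vals = intens.to_numpy(dtype=float)
    if np.nanmin(vals) <= 0:
        raise DomainError("log2 requires strictly positive intensities")
    logd = np.log2(vals)
    if method == "median":
        med = np.nanmedian(logd, axis=0)
        grand = np.median(med)
        logd = logd - med[None, :] + grand
    elif method == "quantile":
        order = np.argsort(logd, axis=0)
        ranks = np.empty_like(order)
        for j in range(logd.shape[1]):
            ranks[order[:, j], j] = np.arange(logd.shape[0])
        mean_profile = np.sort(logd, axis=0).mean(axis=1)
        logd = mean_profile[ranks]
    else:
        raise ConfigurationError(f"unknown normalization method {method!r}")
    out = pd.DataFrame(logd, index=intens.index, columns=intens.columns)
    return table.replace(intensities=out, state="normalized")


def is_differentially_expressed(fold_change: float, p_value: float,
                                fold_threshold: float = 1.5,
                                p_threshold: float = 0.1) -> bool:
    """The DE call: max(fc, 1/fc) > 1.5 AND p < 0.1, both strict."""
    if fold_change <= 0:
        raise DomainError("fold change must be > 0")
    return max(fold_change, 1.0 / fold_change) > fold_threshold \
        and p_value < p_threshold


def differential_expression(table: ProteinTable, group_a: str, group_b: str,
                            fold_threshold: float = 1.5,
                            p_threshold: float = 0.1) -> pd.DataFrame:
    """Per-protein differential expression of ``group_a`` vs ``group_b``.

    On the normalized log2 table: log2 fold change = meanA − meanB,
    p from Welch's two-sample t-test on the log2 values.  Returns one row
    per protein sorted by p, with columns ``protein_id`` (index),
    ``mean_a``, ``mean_b``, ``log2_fc``, ``fold_change``, ``p_value``,
    ``is_de``, ``direction``.
    """
    if table.state != "normalized":
        raise ValidationError(
            f"differential expression expects a normalized table, "
            f"got state {table.state!r}")
    sa = table.samples_in(group_a)
    sb = table.samples_in(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise InsufficientSampleError(
            f"groups need n >= 2 (got {len(sa)} and {len(sb)})")
    a = table.intensities[sa].to_numpy(dtype=float)
    b = table.intensities[sb].to_numpy(dtype=float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    log2_fc = mean_a - mean_b
    p = sps.ttest_ind(a, b, axis=1, equal_var=False).pvalue
    fc = np.power(2.0, log2_fc)
    sym_fc = np.maximum(fc, 1.0 / fc)
    is_de = (sym_fc > fold_threshold) & (p < p_threshold)
    res = pd.DataFrame({
        "mean_a": mean_a,
        "mean_b": mean_b,
        "log2_fc": log2_fc,
        "fold_change": fc,
        "p_value": p,
        "is_de": is_de,
        "direction": np.where(log2_fc >= 0, "up", "down"),
    }, index=table.protein_ids.rename("protein_id"))
    return res.sort_values("p_value", kind="stable")


def pca_scores(table: ProteinTable) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-component scores of the samples.

    The sample × protein matrix is centered per protein and decomposed by
    SVD.  Returns (scores, variance_explained); fractions are
    non-increasing and sum to 1 over all retained components.  Component
    signs are fixed so the largest-magnitude protein loading is positive.
    """
    if len(table.samples) < 2:
        raise InsufficientSampleError("PCA needs at least 2 samples")
    x = table.intensities.to_numpy(dtype=float).T  # samples × proteins
    if np.isnan(x).any():
        raise ValidationError("PCA requires a complete (imputed) table")
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    n_comp = min(x.shape[0] - 1, len(s)) or 1
    u, s, vt = u[:, :n_comp], s[:n_comp], vt[:n_comp]
    for i in range(n_comp):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
            u[:, i] = -u[:, i]
    scores = u * s
    total = float((s ** 2).sum())
    var_frac = (s ** 2) / total if total > 0 else np.zeros_like(s)
    cols = [f"PC{i + 1}" for i in range(n_comp)]
    df = pd.DataFrame(scores, index=pd.Index(table.samples, name="sample"),
                      columns=cols)
    df["group"] = [table.sample_groups[s] for s in table.samples]
    return df, var_frac


def volcano_data(de_results: pd.DataFrame) -> pd.DataFrame:
    """Plain volcano-plot table: log2 fc, −log10 p, DE flag, direction."""
    with np.errstate(divide="ignore"):
        neg = -np.log10(de_results["p_value"].to_numpy(dtype=float))
    return pd.DataFrame({
        "log2_fc": de_results["log2_fc"],
        "neg_log10_p": neg,
        "is_de": de_results["is_de"],
        "direction": de_results["direction"],
    }, index=de_results.index)


@dataclass(frozen=True)
class OraResult:
    """Over-representation of one gene set in a hit list."""

    set_name: str
    overlap: int
    set_size: int
    list_size: int
    background_size: int
    p_value: float
    adjusted_p: float


def overrepresentation(de_ids: Sequence[str], background_ids: Sequence[str],
                       gene_sets: dict[str, Sequence[str]]
                       ) -> list[OraResult]:
    """Hypergeometric upper-tail enrichment per user-supplied gene set.

    For each set: p = P(overlap >= observed) drawing |list| proteins from
    the background, where the set is first intersected with the
    background.  Benjamini–Hochberg adjustment across sets.
    """
    bg = set(background_ids)
    hits = set(de_ids)
    stray = hits - bg
    if stray:
        raise ValidationError(
            f"de ids absent from background: {sorted(stray)[:5]}")
    m = len(bg)
    n = len(hits)
    names, pvals, rows = [], [], []
    for name, members in gene_sets.items():
        kset = set(members) & bg
        overlap = len(kset & hits)
        p = float(sps.hypergeom.sf(overlap - 1, m, len(kset), n))
        names.append(name)
        pvals.append(min(p, 1.0))
        rows.append((name, overlap, len(kset), n, m))
    if not rows:
        return []
    adj = multipletests(pvals, method="fdr_bh")[1]
    return [OraResult(name, ov, ss, ls, bs, p, float(a))
            for (name, ov, ss, ls, bs), p, a in zip(rows, pvals, adj)]
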