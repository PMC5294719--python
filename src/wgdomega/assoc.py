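"""Association statistics between verdict classes and gene properties.

These are the comparisons run downstream of the hypothesis cascade: rank-sum
comparisons of protein abundance, disorder content, and deletion fitness
between rate-change and rate-constant orthogroups (overall and within
functional categories), category enrichment in rate-change or asymmetric
sets, codon adaptation, and the abundance asymmetry of paralog pairs.

Statistical kernels come from scipy.stats; small-sample paths are exact
(full enumeration) so p-values are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .genetics import UNIVERSAL, GeneticCode

#: sample size at or below which the rank-sum test uses exact enumeration
EXACT_WILCOXON_MAX_N = 20


# ---------------------------------------------------------------------------
# Test kernels
# ---------------------------------------------------------------------------


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration of rank splits when both samples have at most
    20 observations (a full permutation enumeration when ties are present);
    otherwise the normal approximation with tie correction.
    Returns ``(U statistic of x, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    small = max(x.size, y.size) <= EXACT_WILCOXON_MAX_N
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if small and not has_ties:
        method = "exact"
    elif small:
        # exact in the presence of ties: enumerate all assignments
        method = scipy.stats.PermutationMethod(n_resamples=np.inf)
    else:
        method = "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Four non-negative counts: rows = group, columns = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        cells = (self.a, self.b, self.c, self.d)
        if any(v < 0 for v in cells):
            raise ValueError("cells must be non-negative")
        if sum(cells) == 0:
            raise ValueError("table total must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test; returns (odds ratio ad/bc, p).

    The odds ratio may be ``inf`` (bc = 0) or 0; the p-value sums
    hypergeometric probabilities no larger than the observed table's.
    """
    arr = table.as_array() if isinstance(table, ContingencyTable2x2) else np.asarray(table)
    if arr.shape != (2, 2) or np.any(arr < 0):
        raise ValueError("need a 2x2 table of non-negative counts")
    odds, p = scipy.stats.fisher_exact(arr, alternative="two-sided")
    return float(odds), float(p)


def chi2_2x2(table, correction: bool = False) -> tuple[float, float]:
    """Chi-square test of independence on a 2x2 table (1 df).

    Continuity correction is off by default so the statistic matches the
    textbook formula sum (O-E)^2 / E.
    """
    arr = table.as_array() if isinstance(table, ContingencyTable2x2) else np.asarray(table)
    chi2, p, _df, _exp = scipy.stats.chi2_contingency(arr, correction=correction)
    return float(chi2), float(p)


def category_enrichment(
    verdicts: pd.DataFrame,
    properties: pd.DataFrame,
    category: str,
    flag: str = "omega_change",
    correction: bool = False,
) -> tuple[float, float, str]:
    """Is a functional category enriched or depleted in flagged orthogroups?

    Builds the 2x2 table (category vs rest) x (flag true vs false) over
    orthogroups and applies the chi-square test; if any expected cell drops
    below 1 the test falls back to Fisher's exact test.  Returns
    ``(statistic, p, "enriched"|"depleted"|"none")``.
    """
    merged = _merge_verdict_categories(verdicts, properties)
    in_cat = merged["category"] == category
    changed = merged[flag].astype(bool)
    a = int((in_cat & changed).sum())
    b = int((in_cat & ~changed).sum())
    c = int((~in_cat & changed).sum())
    d = int((~in_cat & ~changed).sum())
    arr = np.array([[a, b], [c, d]], dtype=float)
    if arr.sum() == 0:
        raise ValueError("no orthogroups to test")
    expected = np.outer(arr.sum(1), arr.sum(0)) / arr.sum()
    if expected.min() < 1:
        stat, p = fisher_exact_2x2(arr.astype(int))
    else:
        stat, p = chi2_2x2(arr.astype(int), correction=correction)
    frac_cat = a / (a + b) if a + b else np.nan
    frac_rest = c / (c + d) if c + d else np.nan
    if np.isnan(frac_cat) or np.isnan(frac_rest) or frac_cat == frac_rest:
        direction = "none"
    else:
        direction = "enriched" if frac_cat > frac_rest else "depleted"
    return stat, p, direction


# ---------------------------------------------------------------------------
# Codon adaptation index
# ---------------------------------------------------------------------------


def compute_cai(
    cds: str,
    reference_weights: Mapping[str, float],
    code: GeneticCode = UNIVERSAL,
) -> float:
    """Codon adaptation index: geometric mean of relative adaptiveness.

    ``reference_weights`` maps codons to weights in (0, 1], 1 for the
    optimal codon of each family.  Codons from single-codon families
    (and stop codons) are excluded, the standard convention.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    aa_family_size: dict[str, int] = {}
    for codon in code.sense_codons:
        aa = code.codon_to_aa[codon]
        aa_family_size[aa] = aa_family_size.get(aa, 0) + 1
    logs = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon not in code.codon_index:
            continue  # gaps/ambiguity/stops are skipped
        if aa_family_size[code.codon_to_aa[codon]] == 1:
            continue
        w = reference_weights.get(codon)
        if w is None:
            continue
        if not (0 < w <= 1):
            raise ValueError(f"weight for {codon} must be in (0, 1]")
        logs.append(np.log(w))
    if not logs:
        raise ValueError("no usable codons for CAI")
    return float(np.exp(np.mean(logs)))


# ---------------------------------------------------------------------------
# Tables over verdicts and properties
# ---------------------------------------------------------------------------


def _merge_verdict_categories(
    verdicts: pd.DataFrame, properties: pd.DataFrame
) -> pd.DataFrame:
    cats = properties.groupby("orthogroup")["category"].first()
    merged = verdicts.merge(cats, on="orthogroup", how="inner")
    return merged


def compare_property_by_verdict(
    verdicts: pd.DataFrame,
    properties: pd.DataFrame,
    property_name: str,
    flag: str = "omega_change",
    stratify_by_category: bool = True,
) -> pd.DataFrame:
    """Compare a gene property between flagged and unflagged orthogroups.

    Returns one overall row plus one row per category present (when
    stratifying): group sample sizes, medians, and the two-sided rank-sum
    p-value (marked unavailable when a group has fewer than 2 genes).
    """
    merged = properties.merge(
        verdicts[["orthogroup", flag]], on="orthogroup", how="inner"
    ).dropna(subset=[property_name])

    def one_row(df: pd.DataFrame, stratum: str) -> dict:
        a = df.loc[df[flag].astype(bool), property_name].to_numpy(dtype=float)
        b = df.loc[~df[flag].astype(bool), property_name].to_numpy(dtype=float)
        row = {
            "stratum": stratum,
            "n_flagged": a.size,
            "n_unflagged": b.size,
            "median_flagged": float(np.median(a)) if a.size else np.nan,
            "median_unflagged": float(np.median(b)) if b.size else np.nan,
            "p": np.nan,
        }
        if a.size >= 2 and b.size >= 2:
            _stat, p = wilcoxon_rank_sum(a, b)
            row["p"] = p
        return row

    rows = [one_row(merged, "all")]
    if stratify_by_category and "category" in merged.columns:
        for cat in sorted(merged["category"].dropna().unique()):
            rows.append(one_row(merged[merged["category"] == cat], cat))
    return pd.DataFrame(rows)


def asymmetry_abundance_report(
    verdicts: pd.DataFrame, properties: pd.DataFrame
) -> pd.DataFrame:
    """Relative abundance of the low-rate paralog in asymmetric pairs.

    For each orthogroup with ``clade_asymmetry`` true and both paralogs'
    abundances present: ``ratio = abundance(low-rate) / abundance(high-rate)``
    (the low-rate paralog is the copy in the clade with the smaller fitted
    omega) plus the absolute CAI difference of the pair.  Pairs with missing
    abundance are skipped and counted in the ``skipped`` attribute.
    """
    asym = verdicts[
        verdicts["clade_asymmetry"].astype(bool) & verdicts["slow_clade"].isin(["A", "B"])
    ]
    rows = []
    skipped = 0
    by_og = properties.groupby("orthogroup")
    for _, v in asym.iterrows():
        og = v["orthogroup"]
        if og not in by_og.groups:
            skipped += 1
            continue
        genes = by_og.get_group(og).set_index("copy")
        if not {"A", "B"} <= set(genes.index):
            skipped += 1
            continue
        slow, fast = (v["slow_clade"], "B" if v["slow_clade"] == "A" else "A")
        ab_slow = genes.loc[slow, "abundance"]
        ab_fast = genes.loc[fast, "abundance"]
        if pd.isna(ab_slow) or pd.isna(ab_fast) or ab_fast <= 0:
            skipped += 1
            continue
        row = {
            "orthogroup": og,
            "slow_copy": slow,
            "abundance_low_rate": float(ab_slow),
            "abundance_high_rate": float(ab_fast),
            "ratio": float(ab_slow / ab_fast),
        }
        if "cai" in genes.columns and genes["cai"].notna().all():
            row["cai_diff"] = float(abs(genes.loc["A", "cai"] - genes.loc["B", "cai"]))
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["skipped"] = skipped
    return out


def abundance_ratio_histogram(
    report: pd.DataFrame, bins: Sequence[float] | None = None
) -> pd.DataFrame:
    """Histogram bins of log2 abundance ratios from the asymmetry report."""
    if bins is None:
        bins = np.linspace(-5, 5, 21)
    ratios = np.log2(report["ratio"].to_numpy(dtype=float))
    counts, edges = np.histogram(ratios, bins=bins)
    return pd.DataFrame(
        {"log2_ratio_left": edges[:-1], "log2_ratio_right": edges[1:], "count": counts}
    )
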