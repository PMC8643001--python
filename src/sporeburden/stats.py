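"""Taxon-category accounting, group log-ratios, gradients, and richness tests.

Spore-category accounting follows the planetary-protection reading of a
community: every genus above a read-total threshold is NSA spore-former
(spore-forming and recoverable by the NASA standard assay's culture
conditions), non-NSA spore-former (spore-forming but invisible to the
assay — anaerobes, thermophiles, slow growers), or non-spore-former.
Log-ratios are natural-log ratios of summed counts of two disjoint
taxon groups — scale-invariant, so sequencing depth cancels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .hsp import HSPResult
from .table import FeatureTable, SampleMetadata, genus_of

#: spore-forming genera recovered by the NASA standard assay in this
#: facility survey; user-overridable everywhere it is consumed.
DEFAULT_NSA_GENERA = (
    "Bacillus", "Brevibacillus", "Cohnella", "Gracilibacillus",
    "Oceanobacillus", "Paenibacillus", "Psychrobacillus",
    "Rummeliibacillus", "Sporosarcina", "Streptomyces",
    "Terribacillus", "Virgibacillus",
)

CATEGORIES = ("nsa_spore", "non_nsa_spore", "non_spore", "excluded")


@dataclass
class CategoryMap:
    categories: pd.Series          # feature -> category
    read_threshold: int

    def included(self) -> pd.Index:
        return self.categories.index[self.categories != "excluded"]


@dataclass
class LogRatioResult:
    values: pd.Series              # sample -> ln(num sum / den sum)
    dropped: list[str]             # samples with a zero group sum
    numerator: list[str]
    denominator: list[str]


def classify_taxa(
    table: FeatureTable,
    spore_former: pd.Series | HSPResult | dict,
    nsa_genera: tuple[str, ...] = DEFAULT_NSA_GENERA,
    read_threshold: int = 100,
    taxonomy: pd.Series | None = None,
) -> CategoryMap:
    """Assign each feature a spore category.

    ``spore_former`` gives the spore-forming call per feature (an HSP
    result's thresholded labels, a curated boolean Series, or a dict).
    Features whose total reads across all samples are <= ``read_threshold``
    are excluded (the threshold is strict: "greater than"). A feature
    with no resolvable genus is categorized from its spore call alone
    (it can never be NSA, which is a genus-level notion).
    """
    if read_threshold < 0:
        raise ValueError("read_threshold must be >= 0")
    if isinstance(spore_former, HSPResult):
        spore = spore_former.labels()
    elif isinstance(spore_former, dict):
        spore = pd.Series(spore_former, dtype=bool)
    else:
        spore = spore_former.astype(bool)
    tax = taxonomy if taxonomy is not None else table.taxonomy
    totals = table.feature_totals()
    nsa_set = set(nsa_genera)
    cats = {}
    for feat in table.feature_ids:
        if totals[feat] <= read_threshold:
            cats[feat] = "excluded"
            continue
        is_spore = bool(spore.get(feat, False))
        genus = genus_of(tax.get(feat)) if tax is not None else None
        if is_spore and genus in nsa_set:
            cats[feat] = "nsa_spore"
        elif is_spore:
            cats[feat] = "non_nsa_spore"
        else:
            cats[feat] = "non_spore"
    return CategoryMap(
        categories=pd.Series(cats).reindex(table.feature_ids),
        read_threshold=read_threshold,
    )


def category_fractions(
    table: FeatureTable,
    categories: CategoryMap,
    metadata: SampleMetadata | None = None,
    group_by: str = "overall",
) -> pd.DataFrame:
    """Read fractions per spore category, overall or per group.

    Fractions are read sums over the included (non-excluded) features,
    normalized within each group; rows sum to 1.
    """
    if group_by not in ("overall", "session", "location"):
        raise ValueError("group_by must be overall, session or location")
    included = categories.included()
    sub = table.counts.loc[included]
    cat_of = categories.categories.loc[included]
    per_sample = sub.groupby(cat_of, observed=True).sum()  # category x sample
    if group_by == "overall":
        sums = per_sample.sum(axis=1).to_frame("overall").T
    else:
        key = "session_index" if group_by == "session" else "location_id"
        if metadata is None:
            raise ValueError(f"metadata required for group_by={group_by!r}")
        metadata.require_samples(table.sample_ids)
        grouping = metadata.data.loc[table.sample_ids, key]
        sums = per_sample.T.groupby(grouping, observed=True).sum()
    totals = sums.sum(axis=1)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"groups with zero included reads: {bad}")
    frac = sums.div(totals, axis=0)
    for cat in ("nsa_spore", "non_nsa_spore", "non_spore"):
        if cat not in frac.columns:
            frac[cat] = 0.0
    return frac[["nsa_spore", "non_nsa_spore", "non_spore"]]


def select_by_lineage(taxonomy: pd.Series, selector: str) -> list[str]:
    """Features whose lineage contains ``rank:name`` (e.g. ``c:Bacilli``).

    Rank letters follow the Greengenes prefixes (k/p/c/o/f/g/s); a bare
    name matches any rank. This is the lowest-common-ancestor style group
    selection: the group is every feature under the named taxon.
    """
    if ":" in selector:
        rank, name = selector.split(":", 1)
        token = f"{rank.lower()}__{name}"
    else:
        token = selector
    hits = [
        feat for feat, lineage in taxonomy.items()
        if any(part.strip().lower() == token.lower()
               or part.strip().split("__")[-1].lower() == selector.lower()
               for part in str(lineage).split(";"))
    ]
    return hits


def group_log_ratio(
    table: FeatureTable,
    numerator: list[str],
    denominator: list[str],
    pseudocount: float = 0.0,
) -> LogRatioResult:
    """Per-sample natural-log ratio of summed counts of two taxon groups.

    Samples where either group sums to zero are dropped and listed
    (default); a pseudocount mode adds the constant to both sums instead.
    """
    num = list(numerator)
    den = list(denominator)
    if not num or not den:
        raise ValueError("numerator and denominator must be nonempty")
    overlap = set(num) & set(den)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")
    num_sum = table.counts.loc[num].sum(axis=0).astype(float) + pseudocount
    den_sum = table.counts.loc[den].sum(axis=0).astype(float) + pseudocount
    ok = (num_sum > 0) & (den_sum > 0)
    dropped = list(num_sum.index[~ok])
    values = np.log(num_sum[ok]) - np.log(den_sum[ok])
    return LogRatioResult(values=values, dropped=dropped,
                          numerator=num, denominator=den)


def compare_log_ratio(
    values: pd.Series,
    grouping: pd.Series,
    n_comparisons: int = 1,
) -> pd.DataFrame:
    """Welch two-sided t tests between groups of log-ratio values.

    With two groups a single test is run; with more, all pairwise tests.
    Bonferroni adjustment: p_adj = min(1, p * n_comparisons).
    """
    grouping = grouping.reindex(values.index)
    levels = sorted(grouping.dropna().unique())
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            a = values[grouping == levels[i]].to_numpy()
            b = values[grouping == levels[j]].to_numpy()
            if len(a) < 2 or len(b) < 2:
                raise ValueError(
                    f"groups {levels[i]!r}/{levels[j]!r} need >= 2 observations"
                )
            if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
                t, p = 0.0, 1.0
            else:
                t, p = sps.ttest_ind(a, b, equal_var=False)
            rows.append((levels[i], levels[j], float(t), float(p),
                         min(1.0, float(p) * n_comparisons)))
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "t", "p", "p_bonferroni"]
    )


def gradient_correlation(
    values: pd.Series,
    metadata: SampleMetadata,
    pma_only: bool = True,
) -> tuple[float, float, pd.DataFrame]:
    """Pearson correlation of per-location mean log-ratio with radius.

    Pools sessions within a location; by default restricted to
    PMA-treated floor samples (the viable community). Returns
    (r, two-sided p, per-location table of mean L and radius).
    """
    meta = metadata.data.loc[values.index.intersection(metadata.data.index)]
    mask = meta["sample_type"] == "floor"
    if pma_only:
        mask &= meta["pma_treated"]
    meta = meta[mask]
    v = values.loc[meta.index]
    per_loc = pd.DataFrame({
        "mean_log_ratio": v.groupby(meta["location_id"], observed=True).mean(),
        "radius": meta.groupby("location_id", observed=True)["radius"].first(),
    })
    per_loc = per_loc.dropna()
    if len(per_loc) < 3:
        raise ValueError("need >= 3 locations with defined mean log-ratio")
    if per_loc["radius"].nunique() < 2 or per_loc["mean_log_ratio"].nunique() < 2:
        raise ValueError("zero variance in radii or location means")
    r, p = sps.pearsonr(per_loc["mean_log_ratio"], per_loc["radius"])
    return float(r), float(p), per_loc


def richness_tests(
    table: FeatureTable,
    metadata: SampleMetadata,
) -> dict:
    """Observed richness per sample with Kruskal-Wallis and post hoc tests.

    Expects a rarefied (equal-depth) table. Groups are sample type x PMA
    status; the omnibus test is Kruskal-Wallis, followed by pairwise
    rank-sum (Mann-Whitney) tests with Benjamini-Hochberg adjustment
    across the pairwise family.
    """
    metadata.require_samples(table.sample_ids)
    richness = (table.counts > 0).sum(axis=0)
    meta = metadata.data.loc[table.sample_ids]
    group = meta["sample_type"].astype(str) + np.where(
        meta["pma_treated"], "+PMA", "-PMA"
    )
    levels = sorted(group.unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 groups for richness comparison")
    arrays = [richness[group == lv].to_numpy() for lv in levels]
    if np.ptp(np.concatenate(arrays)) == 0:
        kw_stat, kw_p = 0.0, 1.0
    else:
        kw_stat, kw_p = sps.kruskal(*arrays)
    pairs, pvals = [], []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            a, b = arrays[i], arrays[j]
            if np.ptp(np.concatenate([a, b])) == 0:
                p = 1.0
            else:
                _, p = sps.mannwhitneyu(a, b, alternative="two-sided")
            pairs.append((levels[i], levels[j]))
            pvals.append(float(p))
    if pvals:
        _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    else:
        p_adj = []
    posthoc = pd.DataFrame(
        [(a, b, p, q) for (a, b), p, q in zip(pairs, pvals, p_adj)],
        columns=["group_a", "group_b", "p", "p_bh"],
    )
    return {
        "richness": richness,
        "groups": group,
        "kruskal_statistic": float(kw_stat),
        "kruskal_p": float(kw_p),
        "posthoc": posthoc,
    }


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    _, adj, _, _ = multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")
    return adj
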