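"""Sample QC, control-based contaminant flagging, and rarefaction.

The contaminant rule is prevalence-and-abundance based: a feature is a
putative reagent/processing contaminant when it occurs in *every*
control sample and its mean raw count over the no-template controls
(extraction and wipe-only negatives) exceeds its mean raw count over
the study samples. Field controls count toward the 100%-prevalence
clause (they share the reagent stream) but not toward the no-template
abundance clause, since they are air-exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .table import (
    CONTROL_TYPES,
    NO_TEMPLATE_TYPES,
    FeatureTable,
    SampleMetadata,
)

DEFAULT_MIN_DEPTH = 5000


@dataclass
class QCReport:
    """Per-sample depth QC outcome."""

    totals: pd.Series                 # per-sample read totals
    passed: pd.Series                 # bool per sample, total >= min_depth
    min_depth: int
    by_group: pd.DataFrame            # survivors tallied by (sample_type, pma)

    @property
    def n_passed(self) -> int:
        return int(self.passed.sum())


@dataclass
class ContaminantReport:
    """Outcome of the control-based contaminant rule."""

    flagged: list[str]
    diagnostics: pd.DataFrame         # per-feature prevalence/mean columns
    control_samples: list[str]        # the 100%-prevalence control set
    no_template_samples: list[str]    # the abundance-clause control set
    aggregator: str


def qc_filter(
    table: FeatureTable,
    metadata: SampleMetadata,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> tuple[FeatureTable, QCReport]:
    """Drop samples with fewer than ``min_depth`` total reads.

    The boundary is inclusive: a sample with exactly ``min_depth`` reads
    passes. Returns the filtered table and a report tallying survivors
    by sample type and PMA status.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if table.counts.size == 0:
        raise ValueError("empty feature table")
    metadata.require_samples(table.sample_ids)
    totals = table.sample_totals()
    passed = totals >= min_depth
    keep = list(totals.index[passed])
    meta = metadata.data.loc[table.sample_ids]
    surv = meta.loc[keep]
    by_group = (
        surv.groupby(["sample_type", "pma_treated"], observed=True)
        .size()
        .rename("n_passed")
        .reset_index()
    )
    report = QCReport(totals=totals, passed=passed, min_depth=min_depth,
                      by_group=by_group)
    return table.select_samples(keep), report


def flag_contaminants(
    table: FeatureTable,
    metadata: SampleMetadata,
    control_types: tuple[str, ...] = CONTROL_TYPES,
    no_template_types: tuple[str, ...] = NO_TEMPLATE_TYPES,
    aggregator: str = "mean",
) -> tuple[FeatureTable, ContaminantReport]:
    """Flag and remove features satisfying the two-clause contaminant rule.

    A feature is flagged iff (1) its raw count is > 0 in every control
    sample, and (2) its aggregated count over no-template controls
    exceeds its aggregated count over study (floor) samples. Flagged
    features are removed from the returned table.
    """
    metadata.require_samples(table.sample_ids)
    meta = metadata.data.loc[table.sample_ids]
    controls = list(meta.index[meta["sample_type"].isin(control_types)])
    no_template = list(meta.index[meta["sample_type"].isin(no_template_types)])
    study = list(meta.index[meta["sample_type"] == "floor"])
    if not controls or not no_template:
        raise ValueError(
            "no control samples present; pass skip_decontam explicitly "
            "instead of running the contaminant rule without controls"
        )
    if not study:
        raise ValueError("no study (floor) samples present")

    agg_funcs = {"mean": lambda df: df.mean(axis=1),
                 "median": lambda df: df.median(axis=1),
                 "max": lambda df: df.max(axis=1)}
    if aggregator not in agg_funcs:
        raise ValueError(f"unknown aggregator {aggregator!r}")
    agg = agg_funcs[aggregator]

    ctrl_counts = table.counts[controls]
    prevalence = (ctrl_counts > 0).mean(axis=1)
    nt_stat = agg(table.counts[no_template])
    study_stat = agg(table.counts[study])
    flagged_mask = (prevalence == 1.0) & (nt_stat > study_stat)
    flagged = list(table.counts.index[flagged_mask])

    diagnostics = pd.DataFrame({
        "control_prevalence": prevalence,
        f"no_template_{aggregator}": nt_stat,
        f"study_{aggregator}": study_stat,
        "flagged": flagged_mask,
    })
    report = ContaminantReport(
        flagged=flagged,
        diagnostics=diagnostics,
        control_samples=controls,
        no_template_samples=no_template,
        aggregator=aggregator,
    )
    return table.drop_features(flagged), report


def control_prevalence_stats(
    table: FeatureTable,
    metadata: SampleMetadata,
    prevalence_cut: float = 0.10,
    control_types: tuple[str, ...] = CONTROL_TYPES,
) -> tuple[int, int]:
    """Diagnostics on control-associated features.

    Returns ``(n_in_controls, n_rare_in_study)``: the number of features
    observed (count > 0) in at least one control sample, and how many of
    those occur in fewer than ``prevalence_cut`` of the study samples.
    Run on a QC-filtered table to restrict to QC-passing controls.
    """
    if not 0.0 < prevalence_cut <= 1.0:
        raise ValueError("prevalence_cut must be in (0, 1]")
    metadata.require_samples(table.sample_ids)
    meta = metadata.data.loc[table.sample_ids]
    controls = list(meta.index[meta["sample_type"].isin(control_types)])
    study = list(meta.index[meta["sample_type"] == "floor"])
    if not controls:
        return (0, 0)
    in_controls = (table.counts[controls] > 0).any(axis=1)
    n_in_controls = int(in_controls.sum())
    if not study or n_in_controls == 0:
        return (n_in_controls, 0)
    study_prev = (table.counts.loc[in_controls, study] > 0).mean(axis=1)
    n_rare = int((study_prev < prevalence_cut).sum())
    return (n_in_controls, n_rare)


def rarefy(table: FeatureTable, depth: int, seed: int) -> FeatureTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped. The draw per
    sample is multivariate hypergeometric (one draw, not an average over
    draws), deterministic under ``seed``.
    """
    if depth <= 0:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = [s for s in table.sample_ids if totals[s] >= depth]
    out = np.zeros((len(table.feature_ids), len(keep)), dtype=np.int64)
    for j, sid in enumerate(keep):
        col = table.counts[sid].to_numpy()
        if totals[sid] == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    tax = table.taxonomy
    return FeatureTable(
        pd.DataFrame(out, index=table.counts.index, columns=keep),
        taxonomy=tax,
    )
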