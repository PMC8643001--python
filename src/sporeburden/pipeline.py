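"""End-to-end orchestration: simulate → QC → decontaminate → rarefy →
trait prediction → category/gradient statistics, with a JSON report.

Every stochastic stage derives its seed deterministically from the
master seed and the stage name, so a run is reproducible from its
serialized config alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sbio
from .bioburden import (
    PlateCountRecord,
    cfu_per_area,
    observed_ratio,
    ssb_viable_estimate,
)
from .hsp import hsp_empirical, loocv_average_precision
from .qc import control_prevalence_stats, flag_contaminants, qc_filter, rarefy
from .simulate import StudyConfig, simulate_cleanroom_study
from .stats import (
    category_fractions,
    classify_taxa,
    gradient_correlation,
    group_log_ratio,
    richness_tests,
)
from .table import FeatureTable, SampleMetadata

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    outdir: str = "sporeburden_run"
    seed: int = 0
    # stage toggles
    do_qc: bool = True
    do_decontam: bool = True
    do_rarefy: bool = True
    do_hsp: bool = True
    do_stats: bool = True
    # thresholds
    min_depth: int = 5000
    read_threshold: int = 100
    prevalence_cut: float = 0.10
    hsp_threshold: float = 0.5
    # synthetic-study settings (used when no input table is given)
    simulate: dict = field(default_factory=dict)
    #: fraction of features whose true trait is treated as known
    trait_known_fraction: float = 0.5
    #: optional plate-count TSV (sample_id, colonies, volume_ml,
    #: concentrate_ml, area_m2[, viable_per_m2]) for the bioburden stage
    plate_counts: str | None = None

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 100_003 + zlib.crc32(stage.encode())) % (2**31)


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages in dependency order and write a JSON report.

    Returns the report dict; artifacts (filtered tables, predictions,
    the echoed config) land in ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}

    # ---- simulate ---------------------------------------------------------
    sim_kwargs = dict(config.simulate)
    sim_kwargs["seed"] = config.stage_seed("simulate")
    study = simulate_cleanroom_study(StudyConfig(**sim_kwargs))
    table, metadata = study.table, study.metadata
    report["simulate"] = {
        "n_features": len(table.feature_ids),
        "n_samples": len(table.sample_ids),
        "n_true_contaminants": len(study.contaminants),
        "n_true_spore_formers": int(study.true_traits.sum()),
    }
    sbio.write_feature_table(table, outdir / "table.tsv")
    sbio.write_metadata(metadata, outdir / "metadata.tsv")
    sbio.write_newick(study.tree, outdir / "tree.nwk")

    # ---- QC ---------------------------------------------------------------
    if config.do_qc:
        table, qc_report = qc_filter(table, metadata, config.min_depth)
        report["qc"] = {
            "min_depth": config.min_depth,
            "n_passed": qc_report.n_passed,
            "n_failed": int((~qc_report.passed).sum()),
            "by_group": {
                f"{r.sample_type}{'+PMA' if r.pma_treated else '-PMA'}":
                    int(r.n_passed)
                for r in qc_report.by_group.itertuples()
            },
        }
    else:
        report["qc"] = "skipped"

    # ---- decontamination --------------------------------------------------
    if config.do_decontam:
        n_ctrl, n_rare = control_prevalence_stats(
            table, metadata, config.prevalence_cut
        )
        table, contam_report = flag_contaminants(table, metadata)
        flagged = contam_report.flagged
        report["decontam"] = {
            "n_flagged": len(flagged),
            "flagged": flagged,
            "n_features_in_controls": n_ctrl,
            "n_rare_control_features": n_rare,
            "prevalence_cut": config.prevalence_cut,
        }
        contam_report.diagnostics.to_csv(
            outdir / "contaminants.tsv", sep="\t", index_label="feature_id"
        )
    else:
        report["decontam"] = "skipped"

    # ---- rarefaction ------------------------------------------------------
    if config.do_rarefy:
        table = rarefy(table, config.min_depth, config.stage_seed("rarefy"))
        report["rarefy"] = {
            "depth": config.min_depth,
            "n_samples": len(table.sample_ids),
        }
        sbio.write_feature_table(table, outdir / "table.rarefied.tsv")
    else:
        report["rarefy"] = "skipped"

    # ---- trait prediction -------------------------------------------------
    spore_calls = study.true_traits
    if config.do_hsp:
        rng = np.random.default_rng(config.stage_seed("hsp"))
        feats = list(study.true_traits.index)
        n_known = max(2, int(round(config.trait_known_fraction * len(feats))))
        known_ids = list(rng.choice(feats, size=n_known, replace=False))
        traits = {f: bool(study.true_traits[f]) for f in known_ids}
        if len(set(traits.values())) < 2:  # degenerate draw on tiny studies
            flip = feats[0] if feats[0] not in traits else feats[1]
            traits[flip] = not next(iter(traits.values()))
        loocv = loocv_average_precision(study.tree, traits)
        result = hsp_empirical(study.tree, traits, config.hsp_threshold)
        spore_calls = pd.Series(
            {**{f: bool(s) for f, s in traits.items()},
             **result.labels().to_dict()}
        ).reindex(feats).astype(bool)
        report["hsp"] = {
            "n_known": len(traits),
            "n_predicted": len(result.predictions),
            "loocv_average_precision": round(loocv.average_precision, 6),
            "threshold": config.hsp_threshold,
        }
        result.predictions.to_csv(
            outdir / "hsp_predictions.tsv", sep="\t", index_label="tip"
        )
    else:
        report["hsp"] = "skipped"

    # ---- community statistics --------------------------------------------
    if config.do_stats:
        cat_map = classify_taxa(
            table, spore_calls.reindex(table.feature_ids).fillna(False),
            read_threshold=config.read_threshold,
        )
        pma_floor = [
            s for s in table.sample_ids
            if metadata.data.loc[s, "sample_type"] == "floor"
            and metadata.data.loc[s, "pma_treated"]
        ]
        frac = category_fractions(table.select_samples(pma_floor), cat_map)
        spore_feats = [
            f for f in cat_map.included()
            if cat_map.categories[f] in ("nsa_spore", "non_nsa_spore")
            and f in table.feature_ids
        ]
        non_spore_feats = [
            f for f in cat_map.included()
            if cat_map.categories[f] == "non_spore" and f in table.feature_ids
        ]
        stats_report: dict = {
            "category_fractions_pma_floor": {
                c: round(float(frac.iloc[0][c]), 6) for c in frac.columns
            },
            "n_excluded_features": int(
                (cat_map.categories == "excluded").sum()
            ),
        }
        if spore_feats and non_spore_feats:
            lr = group_log_ratio(table, spore_feats, non_spore_feats)
            r, p, _ = gradient_correlation(lr.values, metadata)
            stats_report["gradient"] = {
                "orientation": "spore/non_spore",
                "pearson_r": round(r, 6),
                "p": round(p, 6),
                "n_dropped_samples": len(lr.dropped),
            }
        rich = richness_tests(table, metadata)
        stats_report["richness"] = {
            "kruskal_statistic": round(rich["kruskal_statistic"], 6),
            "kruskal_p": float(f"{rich['kruskal_p']:.6g}"),
        }
        report["stats"] = stats_report
    else:
        report["stats"] = "skipped"

    # ---- bioburden --------------------------------------------------------
    if config.plate_counts:
        df = pd.read_csv(config.plate_counts, sep="\t", dtype=str, comment="#")
        rows = []
        for _, row in df.iterrows():
            rec = PlateCountRecord(
                colonies=[int(c) for c in str(row["colonies"]).split(",")],
                volume_per_plate_ml=float(row["volume_ml"]),
                concentrate_volume_ml=float(row["concentrate_ml"]),
                area_m2=float(row["area_m2"]),
            )
            spores = cfu_per_area(rec)
            entry = {"sample_id": row["sample_id"],
                     "spores_per_m2": spores,
                     "ssb_predicted_viable_per_m2": ssb_viable_estimate(spores)}
            viable = row.get("viable_per_m2")
            if viable is not None and not pd.isna(viable):
                est = observed_ratio(float(viable), spores)
                entry["observed_ratio"] = est.observed_ratio
                entry["fraction_of_ssb"] = est.fraction_of_ssb
            rows.append(entry)
        report["bioburden"] = rows
    else:
        report["bioburden"] = "skipped"

    # ---- persist ----------------------------------------------------------
    cfg_dict = dataclasses.asdict(config)
    (outdir / "config.json").write_text(
        json.dumps(cfg_dict, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return report
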