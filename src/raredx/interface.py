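"""Pipeline glue: run configuration, input validation and stage
orchestration.

The pipeline consumes a fixture directory (the format written by
``synthetic.emit_fixture``: OBO ontology, group-mapping TSVs, case table
with a JSON term sidecar, diagnosis table, archive count table, optional
prioritization inputs) and executes the stages in dependency order:
ontology -> group assignment -> yield prediction / prioritization /
cohort statistics.  Every output file records the configuration hash and
seed so results are reproducible from config + seed alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import cohort_stats, yieldpred
from .cohort_stats import diagnoses_from_frame
from .ontology import GroupMap, assign_groups, information_content, load_ontology
from .prioritizer import (
    DescriptorSet,
    causal_rank,
    feature_gene_scores,
    gestalt_gene_scores,
    molecular_gene_scores,
    score_case,
    topk_accuracy,
)

logger = logging.getLogger("raredx")

__all__ = ["RunConfig", "ValidationReport", "validate_inputs", "run_pipeline"]


@dataclass
class RunConfig:
    """Run configuration; unknown keys are rejected on load and every
    threshold is serialized into the output metadata."""

    input_dir: str
    output_dir: str
    seed: int = 1
    autozygosity_threshold: float = 0.02
    af_cutoff: float = 0.01
    path_min_prevalence: float = 0.05
    top_k: tuple[int, ...] = (1, 5, 10, 30, 100)
    cv_folds: int = 10
    n_lambda: int = 60
    verbosity: str = "info"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "top_k" in d:
            d = {**d, "top_k": tuple(int(k) for k in d["top_k"])}
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["top_k"] = list(self.top_k)
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


_REQUIRED_FILES = (
    "ontology.obo",
    "terms_to_subcategory.tsv",
    "subcategory_to_group.tsv",
    "cohort.tsv",
    "cohort_terms.json",
    "diagnoses.tsv",
    "clinvar.tsv",
)


def validate_inputs(input_dir) -> ValidationReport:
    """Schema and invariant checks over a fixture directory.

    Errors block the pipeline (missing files, malformed rows, descriptor
    sets without exactly 12 vectors, invalid MOI categories, autozygosity
    outside [0, 1], solved status inconsistent with the diagnosis table);
    unknown phenotype terms are warnings only, matching the group-
    assignment policy of skipping them.
    """
    report = ValidationReport()
    root = Path(input_dir)
    for name in _REQUIRED_FILES:
        if not (root / name).exists():
            report.errors.append(f"missing required input file: {name}")
    if report.errors:
        return report

    try:
        index = load_ontology(root / "ontology.obo")
    except Exception as exc:  # structural defects are fatal
        report.errors.append(f"ontology.obo: {exc}")
        return report
    try:
        GroupMap.from_tsv(
            root / "terms_to_subcategory.tsv", root / "subcategory_to_group.tsv"
        )
    except Exception as exc:
        report.errors.append(f"group mapping: {exc}")

    cohort = pd.read_csv(root / "cohort.tsv", sep="\t")
    required_cols = {
        "patient_id", "age_class", "sex", "site", "disease_category",
        "autozygosity", "solved",
    }
    missing_cols = required_cols - set(cohort.columns)
    if missing_cols:
        report.errors.append(f"cohort.tsv missing columns {sorted(missing_cols)}")
        return report
    bad = cohort[
        (cohort["autozygosity"] < 0) | (cohort["autozygosity"] > 1)
    ]
    for _, row in bad.iterrows():
        report.errors.append(
            f"cohort.tsv: patient {row['patient_id']} autozygosity "
            f"{row['autozygosity']} outside [0, 1]"
        )
    if cohort["patient_id"].duplicated().any():
        report.errors.append("cohort.tsv: duplicate patient ids")

    with open(root / "cohort_terms.json", "r", encoding="utf-8") as fh:
        term_sets = json.load(fh)
    for pid in cohort["patient_id"]:
        if str(pid) not in term_sets:
            report.errors.append(f"cohort_terms.json: no terms for {pid}")
    unknown = {
        t
        for terms in term_sets.values()
        for t in terms
        if t not in index
    }
    if unknown:
        report.warnings.append(
            f"{len(unknown)} phenotype terms not in the ontology "
            "(will be skipped)"
        )

    diag_frame = pd.read_csv(root / "diagnoses.tsv", sep="\t")
    try:
        diagnoses = diagnoses_from_frame(diag_frame)
    except ValueError as exc:
        report.errors.append(f"diagnoses.tsv: {exc}")
        diagnoses = []
    if diagnoses:
        solved_ids = set(
            cohort.loc[cohort["solved"] == 1, "patient_id"].astype(str)
        )
        diag_ids = {d.patient_id for d in diagnoses}
        orphan = diag_ids - set(cohort["patient_id"].astype(str))
        if orphan:
            report.errors.append(
                f"diagnoses.tsv: {len(orphan)} diagnoses for unknown patients"
            )
        mismatch = solved_ids.symmetric_difference(diag_ids) - orphan
        if mismatch:
            report.errors.append(
                f"solved status inconsistent with diagnoses for "
                f"{len(mismatch)} patients"
            )

    ddir = root / "descriptors"
    if ddir.exists():
        for f in sorted(ddir.glob("*.tsv")):
            mat = np.loadtxt(f, delimiter="\t")
            if mat.ndim != 2 or mat.shape[0] != 12:
                report.errors.append(
                    f"{f.name}: descriptor sets must hold exactly 12 "
                    f"vectors, found shape {mat.shape}"
                )
    return report


def _write_tsv(frame: pd.DataFrame, path: Path, config: RunConfig, **kw) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# config_hash={config.config_hash} seed={config.seed}\n")
        frame.to_csv(fh, sep="\t", **kw)


def _write_json(payload: dict, path: Path, config: RunConfig) -> None:
    payload = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        **payload,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, default=str)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages on a fixture directory and write the result
    bundle to ``config.output_dir``.  Returns the in-memory results."""
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), 20))
    report = validate_inputs(config.input_dir)
    for w in report.warnings:
        logger.warning(w)
    if not report.ok:
        raise RuntimeError(
            "input validation failed:\n" + "\n".join(report.errors)
        )
    root = Path(config.input_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- ontology stage
    index = load_ontology(root / "ontology.obo")
    gm = GroupMap.from_tsv(
        root / "terms_to_subcategory.tsv", root / "subcategory_to_group.tsv"
    )
    cohort = pd.read_csv(root / "cohort.tsv", sep="\t")
    with open(root / "cohort_terms.json", "r", encoding="utf-8") as fh:
        term_sets = {p: set(t) for p, t in json.load(fh).items()}
    logger.info("ontology: %d terms, cohort: %d cases", len(index.terms), len(cohort))

    # information content over the gene/disease annotation corpus if
    # available, else the cohort itself
    ann_path = root / "gene_annotations.tsv"
    gene_annotations: dict[str, set[str]] = {}
    if ann_path.exists():
        ann = pd.read_csv(ann_path, sep="\t")
        gene_annotations = {
            r["gene"]: set(str(r["terms"]).split(";")) for _, r in ann.iterrows()
        }
        corpus = {**gene_annotations, **term_sets}
    else:
        corpus = dict(term_sets)
    information_content(index, corpus)

    # --- group assignment stage
    ids = cohort["patient_id"].astype(str).tolist()
    sub_rows, grp_rows = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for pid in ids:
            sv, gv = assign_groups(term_sets[pid], gm, index)
            sub_rows.append(sv)
            grp_rows.append(gv)
    indicators = pd.DataFrame(sub_rows, index=ids)
    group_ind = pd.DataFrame(grp_rows, index=ids)
    logger.info(
        "group assignment: %d/%d cases mapped to at least one subcategory",
        int((indicators.sum(axis=1) > 0).sum()), len(ids),
    )
    _write_tsv(indicators, out / "subcategory_indicators.tsv", config)

    # --- cohort statistics stage
    diagnoses = diagnoses_from_frame(pd.read_csv(root / "diagnoses.tsv", sep="\t"))
    yt = cohort_stats.yield_table(cohort)
    moi = cohort_stats.moi_distribution(diagnoses)
    strata = cohort_stats.autozygosity_stratify(
        cohort, diagnoses, threshold=config.autozygosity_threshold
    )
    burden = None
    if strata["high"]["moi"] is not None and strata["low"]["moi"] is not None:
        try:
            burden = cohort_stats.denovo_normalized_burden(
                strata["high"]["moi"], strata["low"]["moi"]
            )
        except ValueError:
            logger.warning("burden ratio undefined (zero de novo fraction)")
    rates = cohort_stats.rate_summary(cohort, diagnoses)
    clinvar = pd.read_csv(root / "clinvar.tsv", sep="\t")
    quart = cohort_stats.clinvar_quartiles(clinvar, diagnoses=diagnoses)
    years_cohort = [
        d.year_first_assoc for d in diagnoses if d.year_first_assoc is not None
    ]
    ks_stat, ks_p = cohort_stats.year_comparison(
        years_cohort, clinvar["first_assoc_year"]
    )
    _write_tsv(yt.per_group, out / "yield_by_group.tsv", config, index=False)
    _write_tsv(yt.pairwise, out / "yield_pairwise_fisher.tsv", config, index=False)
    _write_tsv(moi, out / "moi_distribution.tsv", config)
    _write_tsv(rates, out / "rate_summary.tsv", config)
    _write_tsv(quart["summary"], out / "clinvar_quartiles.tsv", config)
    stats_payload = {
        "autozygosity_strata": {
            k: {kk: vv for kk, vv in v.items() if kk != "moi"}
            for k, v in strata.items()
            if isinstance(v, dict)
        },
        "denovo_normalized_burden": burden,
        "year_ks": {"D": ks_stat, "p": ks_p},
    }
    _write_json(stats_payload, out / "cohort_stats.json", config)
    logger.info("cohort stats: yield=%s", rates.loc["diagnostic_yield", "formatted"])

    # --- yield prediction stage
    design = yieldpred.build_design(cohort, indicators.set_axis(ids))
    train_idx, test_idx = yieldpred.split_cohort(design.y, seed=config.seed)
    d_train = yieldpred.DesignMatrix(
        X=design.X.iloc[train_idx],
        y=design.y[train_idx],
        penalty_factors=design.penalty_factors,
        penalized=design.penalized,
        confounders=design.confounders,
        site_levels=design.site_levels,
    )
    model = yieldpred.cv_select(
        d_train, k=config.cv_folds, seed=config.seed, n_lambda=config.n_lambda
    )
    probs = model.predict_proba(design.X.iloc[test_idx].to_numpy())
    auc, ci = yieldpred.roc_auc(probs, design.y[test_idx], seed=config.seed)
    model.to_json(out / "yieldpred_model.json")
    paths = yieldpred.export_paths(model, min_prevalence=config.path_min_prevalence)
    _write_tsv(paths, out / "coefficient_paths.tsv", config, index=False)
    _write_json(
        {
            "test_auc": auc,
            "test_auc_ci": list(ci),
            "lambda_selected": model.lambda_selected,
            "n_nonzero_selected": int(model.n_nonzero[model.selected_index]),
            "n_train": int(len(train_idx)),
            "n_test": int(len(test_idx)),
        },
        out / "yieldpred_summary.json",
        config,
    )
    logger.info("yieldpred: held-out AUC %.3f", auc)

    # --- prioritization stage (optional inputs)
    prio_payload = None
    if (root / "benchmark.tsv").exists():
        bench = pd.read_csv(root / "benchmark.tsv", sep="\t")
        variants = pd.read_csv(root / "variants.tsv", sep="\t")
        gallery = []
        for f in sorted((root / "gallery").glob("*.tsv")):
            gene = f.stem.split("__")[0]
            gallery.append(
                (DescriptorSet(f.stem, np.loadtxt(f, delimiter="\t")), gene)
            )
        ranks = []
        for _, row in bench.iterrows():
            pid = str(row["patient_id"])
            ds = DescriptorSet(
                pid,
                np.loadtxt(root / "descriptors" / f"{pid}.tsv", delimiter="\t"),
            )
            gestalt = gestalt_gene_scores(ds, gallery)
            feature = (
                feature_gene_scores(term_sets[pid], gene_annotations, index)
                if gene_annotations
                else None
            )
            molecular = molecular_gene_scores(
                variants[variants["patient_id"].astype(str) == pid],
                af_cutoff=config.af_cutoff,
            )
            vocab = sorted(set(variants["gene"]))
            table = score_case(
                vocab, gestalt=gestalt, feature=feature, molecular=molecular
            )
            ranks.append(causal_rank(table, str(row["causal_gene"])))
        curve = topk_accuracy(ranks, ks=config.top_k, seed=config.seed)
        _write_tsv(curve.table, out / "topk_accuracy.tsv", config, index=False)
        prio_payload = {
            "n_cases": curve.n_cases,
            "top10": curve.accuracy(10) if 10 in config.top_k else None,
        }
        logger.info("prioritizer: %d benchmark cases", curve.n_cases)

    _write_json(
        {"config": self_config(config), "prioritizer": prio_payload},
        out / "run_metadata.json",
        config,
    )
    return {
        "yield_table": yt,
        "moi": moi,
        "strata": strata,
        "burden": burden,
        "rates": rates,
        "quartiles": quart,
        "year_ks": (ks_stat, ks_p),
        "model": model,
        "test_auc": auc,
        "prioritizer": prio_payload,
        "validation": report,
    }


def self_config(config: RunConfig) -> dict:
    return config.to_dict()
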