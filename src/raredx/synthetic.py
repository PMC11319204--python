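"""Synthetic cohort, ontology and score generator.

Generates complete, statistically structured inputs for every analysis
stage so the whole pipeline is exercisable without external downloads:

* a random single-rooted term DAG carrying the 49 phenotype subcategories
  nested in 12 higher-order groups, plus a catalog of disease genes with
  term annotations;
* a patient cohort whose solved status follows a planted logistic model on
  the subcategory indicators (about five terms per patient, overall yield
  anchored at 32%), with consanguinity, autozygosity and a mode-of-
  inheritance distribution conditional on the autozygosity stratum (the
  recessive-to-de-novo odds are multiplied by a configurable factor,
  default 7, in the high-autozygosity stratum);
* dual diagnoses, parental mosaicism of de novo variants, variant-level
  archive classes and carrier-screening annotations at their anchored
  cohort rates;
* per-case prioritization inputs: disorder-clustered unit-norm facial
  descriptors, variant tables with a planted causal-gene deleteriousness
  boost and controlled common-variant contamination, and gene phenotype
  annotations for the feature channel;
* a long-tailed (Zipf) archive-submission count table with skewed
  first-association years, and a synthetic candidate-gene scoring table.

Every generator is fully determined by its seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_stats import (
    MOI_CATEGORIES,
    Diagnosis,
    Variant,
    diagnoses_to_frame,
)
from .ontology import (
    GroupMap,
    OntologyIndex,
    assign_groups,
    information_content,
    load_ontology,
)
from .prioritizer import (
    DescriptorSet,
    causal_rank,
    feature_gene_scores,
    gestalt_gene_scores,
    molecular_gene_scores,
    score_case,
    topk_accuracy,
)

__all__ = [
    "SimulationParams",
    "SyntheticOntology",
    "SyntheticCohort",
    "ScoreSimulation",
    "CaseInputs",
    "make_ontology",
    "simulate_cohort",
    "simulate_scores",
    "simulate_clinvar",
    "simulate_candidates",
    "run_benchmark",
    "emit_fixture",
]

DISEASE_CATEGORIES = (
    "neurodevelopmental",
    "neurologic_neuromuscular",
    "organ_abnormality",
    "endocrine_metabolic",
    "hematopoiesis_immune",
    "cardiovascular",
)


def _subseed(seed: int, stream: int) -> int:
    """Derive a stream-specific seed below 2**31."""
    return (seed * 1_000_003 + stream * 7919 + 17) % (2**31 - 1)


@dataclass
class SimulationParams:
    """Defaults anchor the generator to the reference cohort: 1,577 cases,
    diagnostic yield 32%, about five phenotype terms per case, 144/1,577
    consanguineous, 224/1,577 with image-analysis consent, dual diagnoses
    in 2% of solved cases, parental mosaicism in 1.3% of de novo
    diagnoses and a sevenfold recessive burden in the high-autozygosity
    stratum."""

    n_patients: int = 1577
    seed: int = 1
    # phenotype
    mean_terms: float = 5.0
    category_prevalences: tuple[float, ...] = (0.45, 0.17, 0.13, 0.10, 0.08, 0.07)
    extra_subcat_prob: float = 0.3
    # planted yield model
    target_yield: float = 0.32
    n_planted: int = 8
    n_planted_negative: int = 3
    planted_effect: float = 1.0
    age_child_effect: float = 0.2
    image_flag_effect: float = 0.3
    autozygosity_effect: float = 0.45
    # cohort structure
    child_fraction: float = 1309 / 1577
    consanguinity_fraction: float = 144 / 1577
    consanguineous_f_scale: float = 0.03
    image_consent_fraction: float = 224 / 1577
    n_sites: int = 5
    # diagnoses
    moi_low: Mapping[str, float] = field(
        default_factory=lambda: {
            "AD": 0.15,
            "AD_de_novo": 0.50,
            "AR_hom": 0.03,
            "AR_comp_het": 0.17,
            "XL": 0.12,
            "MT": 0.03,
        }
    )
    recessive_multiplier: float = 7.0
    hom_share_high: float = 0.9
    dual_rate: float = 11 / 499
    mosaic_rate: float = 3 / 228
    novel_gene_rate: float = 0.12
    treated_rate: float = 5 / 499
    # prioritization channels
    n_genes: int = 816
    descriptor_dim: int = 512
    descriptor_noise: float = 0.1
    molecular_boost: float = 10.0
    gestalt_informative: bool = True
    causal_matched: bool = True
    n_benchmark: int = 94
    gallery_per_gene: int = 3
    n_gallery_background: int = 60
    af_common_fraction: float = 0.3
    # archive counts
    zipf_alpha: float = 1.5
    year_range: tuple[int, int] = (1990, 2020)

    def __post_init__(self) -> None:
        probs = list(self.category_prevalences) + [
            self.target_yield,
            self.child_fraction,
            self.consanguinity_fraction,
            self.image_consent_fraction,
            self.dual_rate,
            self.mosaic_rate,
            self.novel_gene_rate,
            self.treated_rate,
            self.af_common_fraction,
            self.hom_share_high,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all rate parameters must lie in [0, 1]")
        if set(self.moi_low) != set(MOI_CATEGORIES):
            raise ValueError(f"moi_low must cover exactly {MOI_CATEGORIES}")
        if abs(sum(self.moi_low.values()) - 1.0) > 1e-9:
            raise ValueError("moi_low must sum to 1")
        if abs(sum(self.category_prevalences) - 1.0) > 1e-9:
            raise ValueError("category_prevalences must sum to 1")

    def to_json(self, path) -> None:
        d = asdict(self)
        d["moi_low"] = dict(d["moi_low"])
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(d, fh, indent=1)


# ---------------------------------------------------------------------------
# ontology + gene catalog

@dataclass
class SyntheticOntology:
    index: OntologyIndex
    group_map: GroupMap
    gene_annotations: dict[str, set[str]]
    gene_home_subcat: dict[str, str]
    obo_text: str
    genes: list[str]

    @property
    def subcat_terms(self) -> dict[str, list[str]]:
        pools: dict[str, list[str]] = {}
        for term, sub in self.group_map.subcategory_of.items():
            pools.setdefault(sub, []).append(term)
        return {s: sorted(t) for s, t in pools.items()}


def make_ontology(
    n_terms: int = 600,
    branching: int = 5,
    seed: int = 0,
    n_subcats: int = 49,
    n_groups: int = 12,
    n_genes: int = 816,
    extra_parent_prob: float = 0.15,
) -> SyntheticOntology:
    """Random single-rooted DAG hosting the subcategory/group structure.

    The root has ``n_groups`` higher-group anchor children; each group
    anchor hosts at most ``branching`` subcategory anchors (49 in total);
    the remaining terms are attached inside subcategory subtrees, with an
    occasional second parent from the same subtree so the result is a DAG
    rather than a tree.  Every non-anchor term maps to exactly one
    subcategory.  Gene annotation sets are drawn from a home subcategory's
    terms, and term information content is computed with the gene catalog
    as the annotation corpus.
    """
    if n_terms < 60:
        raise ValueError("n_terms must be at least 60")
    if n_groups * branching < n_subcats:
        raise ValueError(
            f"branching {branching} over {n_groups} groups cannot host "
            f"{n_subcats} subcategories"
        )
    n_filler = n_terms - 1 - n_groups - n_subcats
    if n_filler < n_subcats:
        raise ValueError("n_terms too small for one child per subcategory")
    rng = np.random.default_rng(seed)

    counter = [0]

    def _new_id() -> str:
        counter[0] += 1
        return f"HP:{counter[0]:07d}"

    root = _new_id()
    stanzas = [f"[Term]\nid: {root}\nname: phenotypic abnormality\n"]

    group_labels = [f"G{i + 1:02d}" for i in range(n_groups)]
    group_anchor = {}
    for g in group_labels:
        tid = _new_id()
        group_anchor[g] = tid
        stanzas.append(
            f"[Term]\nid: {tid}\nname: higher group {g}\nis_a: {root}\n"
        )

    subcat_labels = [f"S{i + 1:02d}" for i in range(n_subcats)]
    # one subcategory per group first, the rest fill remaining capacity
    assignment = list(group_labels)
    capacity = {g: branching - 1 for g in group_labels}
    for _ in range(n_subcats - n_groups):
        open_groups = [g for g in group_labels if capacity[g] > 0]
        g = open_groups[rng.integers(len(open_groups))]
        capacity[g] -= 1
        assignment.append(g)
    higher_group_of = dict(zip(subcat_labels, assignment))

    subcat_anchor: dict[str, str] = {}
    subcat_nodes: dict[str, list[str]] = {}
    subcategory_of: dict[str, str] = {}
    for s in subcat_labels:
        tid = _new_id()
        subcat_anchor[s] = tid
        subcat_nodes[s] = [tid]
        subcategory_of[tid] = s
        stanzas.append(
            f"[Term]\nid: {tid}\nname: subcategory {s}\n"
            f"is_a: {group_anchor[higher_group_of[s]]}\n"
        )

    for i in range(n_filler):
        s = subcat_labels[i % n_subcats] if i < n_subcats else subcat_labels[
            rng.integers(n_subcats)
        ]
        nodes = subcat_nodes[s]
        parent = nodes[rng.integers(len(nodes))]
        tid = _new_id()
        lines = [f"[Term]", f"id: {tid}", f"name: term {tid[3:]}",
                 f"is_a: {parent}"]
        if len(nodes) > 1 and rng.random() < extra_parent_prob:
            other = nodes[rng.integers(len(nodes))]
            if other != parent:
                lines.append(f"is_a: {other}")
        stanzas.append("\n".join(lines) + "\n")
        subcat_nodes[s].append(tid)
        subcategory_of[tid] = s

    obo_text = "format-version: 1.2\nontology: synthetic-phenotype\n\n" + \
        "\n".join(stanzas)
    index = load_ontology(obo_text)
    group_map = GroupMap(
        subcategory_of=subcategory_of, higher_group_of=higher_group_of
    )

    genes = [f"GENE{i + 1:04d}" for i in range(n_genes)]
    gene_annotations: dict[str, set[str]] = {}
    gene_home: dict[str, str] = {}
    all_terms = sorted(subcategory_of)
    for gene in genes:
        s = subcat_labels[rng.integers(n_subcats)]
        pool = subcat_nodes[s]
        size = int(rng.integers(3, 9))
        ann = set(
            rng.choice(pool, size=min(size, len(pool)), replace=False)
        )
        if rng.random() < 0.3:
            ann.add(all_terms[rng.integers(len(all_terms))])
        gene_annotations[gene] = ann
        gene_home[gene] = s

    information_content(index, gene_annotations)
    return SyntheticOntology(
        index=index,
        group_map=group_map,
        gene_annotations=gene_annotations,
        gene_home_subcat=gene_home,
        obo_text=obo_text,
        genes=genes,
    )


# ---------------------------------------------------------------------------
# cohort

@dataclass
class SyntheticCohort:
    cohort: pd.DataFrame  # one row per patient
    indicators: pd.DataFrame  # patients x 49 subcategory indicators
    group_indicators: pd.DataFrame  # patients x 12 higher groups
    terms: dict[str, set[str]]
    diagnoses: list[Diagnosis]
    planted_coefficients: pd.Series  # the true subcategory effects
    intercept: float
    params: SimulationParams


def moi_probabilities(params: SimulationParams, high: bool) -> dict[str, float]:
    """Stratum-conditional MOI distribution.

    In the high-autozygosity stratum the recessive categories' combined
    odds against every other category are multiplied by
    ``recessive_multiplier`` and the recessive mass is shifted toward
    homozygous diagnoses (``hom_share_high``); the recessive/de-novo odds
    ratio between strata therefore equals the multiplier exactly.
    """
    base = dict(params.moi_low)
    if not high:
        return base
    ar = (base["AR_hom"] + base["AR_comp_het"]) * params.recessive_multiplier
    others = {k: v for k, v in base.items() if not k.startswith("AR_")}
    total = ar + sum(others.values())
    probs = {k: v / total for k, v in others.items()}
    probs["AR_hom"] = ar * params.hom_share_high / total
    probs["AR_comp_het"] = ar * (1.0 - params.hom_share_high) / total
    return probs


def _draw_variant(rng: np.random.Generator) -> Variant:
    cls = rng.choice(["P", "LP", "VUS"], p=[0.5, 0.3, 0.2])
    lof = rng.random() < 0.45
    return Variant(
        clinvar_class=str(cls),
        lof=bool(lof),
        nmd_escape=bool(lof and rng.random() < 0.15),
        af=float(rng.uniform(0.0, 0.005)),
    )


def _draw_year(rng: np.random.Generator, year_range: tuple[int, int]) -> int:
    lo, hi = year_range
    return int(np.clip(hi - rng.exponential(8.0), lo, hi))


def simulate_cohort(
    ont: SyntheticOntology, params: SimulationParams | None = None
) -> SyntheticCohort:
    """Simulate the full case table and diagnosis list.

    Solved status is Bernoulli with logit equal to the planted
    subcategory effects plus small confounder effects; the intercept is
    calibrated by bisection so the expected yield matches
    ``target_yield``.  Diagnoses, dual diagnoses, mosaicism, variants and
    causal genes follow the anchored rates documented on
    :class:`SimulationParams`.
    """
    if params is None:
        params = SimulationParams()
    rng = np.random.default_rng(_subseed(params.seed, 1))
    gm = ont.group_map
    subcats = gm.subcategories
    groups = gm.higher_groups
    pools = ont.subcat_terms
    group_subcats: dict[str, list[str]] = {}
    for s, g in gm.higher_group_of.items():
        group_subcats.setdefault(g, []).append(s)
    # two home higher groups per disease category
    cat_groups = {
        cat: [groups[(2 * i) % len(groups)], groups[(2 * i + 1) % len(groups)]]
        for i, cat in enumerate(DISEASE_CATEGORIES)
    }
    subcat_genes: dict[str, list[str]] = {}
    for gene, s in ont.gene_home_subcat.items():
        subcat_genes.setdefault(s, []).append(gene)

    n = params.n_patients
    ids = [f"P{i + 1:05d}" for i in range(n)]
    rows = []
    term_sets: dict[str, set[str]] = {}
    sub_ind = np.zeros((n, len(subcats)), dtype=int)
    grp_ind = np.zeros((n, len(groups)), dtype=int)
    chosen_subcats: list[list[str]] = []
    sites = [f"site_{chr(ord('A') + i)}" for i in range(params.n_sites)]

    for i, pid in enumerate(ids):
        cat = DISEASE_CATEGORIES[
            rng.choice(len(DISEASE_CATEGORIES), p=params.category_prevalences)
        ]
        home = cat_groups[cat][rng.integers(2)]
        cands = group_subcats[home]
        n_sub = 1 + int(rng.random() < 0.5)
        active = list(
            rng.choice(cands, size=min(n_sub, len(cands)), replace=False)
        )
        if rng.random() < params.extra_subcat_prob:
            active.append(subcats[rng.integers(len(subcats))])
        pool = sorted(set().union(*[pools[s] for s in active]))
        k = max(1, int(rng.poisson(params.mean_terms)))
        terms = set(rng.choice(pool, size=min(k, len(pool)), replace=False))
        term_sets[pid] = terms
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sv, gv = assign_groups(terms, gm, ont.index)
        sub_ind[i] = sv.to_numpy()
        grp_ind[i] = gv.to_numpy()
        chosen_subcats.append([s for s in subcats if sv[s]])

        consang = rng.random() < params.consanguinity_fraction
        if consang:
            autoz = 0.021 + rng.exponential(params.consanguineous_f_scale)
        else:
            autoz = rng.uniform(0.0, 0.015)
        rows.append(
            {
                "patient_id": pid,
                "age_class": "child"
                if rng.random() < params.child_fraction
                else "adult",
                "sex": "m" if rng.random() < 0.5 else "f",
                "site": sites[rng.integers(len(sites))],
                "disease_category": cat,
                "image_flag": int(rng.random() < params.image_consent_fraction),
                "autozygosity": float(min(autoz, 1.0)),
            }
        )

    cohort = pd.DataFrame(rows)
    indicators = pd.DataFrame(sub_ind, index=ids, columns=subcats)
    group_indicators = pd.DataFrame(grp_ind, index=ids, columns=groups)

    # planted logistic model on the subcategory indicators
    planted_idx = rng.choice(len(subcats), size=params.n_planted, replace=False)
    beta = pd.Series(0.0, index=subcats)
    for j, col in enumerate(planted_idx):
        sign = -1.0 if j < params.n_planted_negative else 1.0
        beta.iloc[col] = sign * params.planted_effect
    lp = sub_ind @ beta.to_numpy()
    lp += params.age_child_effect * (cohort["age_class"] == "child").to_numpy()
    lp += params.image_flag_effect * cohort["image_flag"].to_numpy()
    lp += params.autozygosity_effect * (
        cohort["autozygosity"] > 0.02
    ).to_numpy()

    from scipy.special import expit
    from scipy.optimize import brentq

    intercept = float(
        brentq(lambda c: expit(lp + c).mean() - params.target_yield, -20, 20)
    )
    solved = (rng.random(n) < expit(lp + intercept)).astype(int)
    cohort["solved"] = solved

    moi_names = list(MOI_CATEGORIES)
    diagnoses: list[Diagnosis] = []
    treated = np.zeros(n, dtype=int)
    for i, pid in enumerate(ids):
        if not solved[i]:
            continue
        high = cohort.loc[i, "autozygosity"] > 0.02
        n_diag = 1 + int(rng.random() < params.dual_rate)
        used_genes: set[str] = set()
        for _ in range(n_diag):
            probs = moi_probabilities(params, bool(high))
            moi = str(rng.choice(moi_names, p=[probs[m] for m in moi_names]))
            cand_genes = []
            if params.causal_matched:
                for s in chosen_subcats[i]:
                    cand_genes.extend(subcat_genes.get(s, []))
            cand_genes = [g for g in cand_genes if g not in used_genes]
            if not cand_genes:
                cand_genes = [g for g in ont.genes if g not in used_genes]
            gene = cand_genes[rng.integers(len(cand_genes))]
            used_genes.add(gene)
            n_var = 2 if moi == "AR_comp_het" else 1
            diagnoses.append(
                Diagnosis(
                    patient_id=pid,
                    gene=gene,
                    moi=moi,
                    variants=[_draw_variant(rng) for _ in range(n_var)],
                    mosaic=bool(
                        moi == "AD_de_novo"
                        and rng.random() < params.mosaic_rate
                    ),
                    year_first_assoc=_draw_year(rng, params.year_range),
                    novel_gene=bool(rng.random() < params.novel_gene_rate),
                )
            )
        treated[i] = int(rng.random() < params.treated_rate)
    cohort["treated"] = treated

    return SyntheticCohort(
        cohort=cohort,
        indicators=indicators,
        group_indicators=group_indicators,
        terms=term_sets,
        diagnoses=diagnoses,
        planted_coefficients=beta,
        intercept=intercept,
        params=params,
    )


# ---------------------------------------------------------------------------
# prioritization inputs

@dataclass
class CaseInputs:
    patient_id: str
    causal_gene: str
    descriptors: DescriptorSet
    variants: pd.DataFrame  # gene, af, score
    terms: set[str]


@dataclass
class ScoreSimulation:
    gallery: list[tuple[DescriptorSet, str]]
    cases: list[CaseInputs]
    vocabulary: list[str]


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def _descriptors(
    rng: np.random.Generator, center: np.ndarray, noise: float, pid: str
) -> DescriptorSet:
    d = center.shape[0]
    vecs = center[None, :] + noise * rng.standard_normal((12, d))
    return DescriptorSet(patient_id=pid, vectors=_unit(vecs))


def simulate_scores(
    sim: SyntheticCohort,
    ont: SyntheticOntology,
    params: SimulationParams | None = None,
) -> ScoreSimulation:
    """Generate gallery descriptors and per-case prioritization inputs
    for a benchmark of solved cases.

    Each disease gene has a latent unit "disorder center" in descriptor
    space; gallery and (when the gestalt channel is informative) test
    descriptors are Gaussian perturbations of the causal gene's center,
    renormalized to the unit sphere.  The variant table gives every
    vocabulary gene one variant (a controlled fraction with common allele
    frequency, destined for the frequency filter); when
    ``molecular_boost > 0`` the causal gene receives an extra rare variant
    with a boosted deleteriousness score.
    """
    if params is None:
        params = sim.params
    rng = np.random.default_rng(_subseed(params.seed, 2))
    solved = sim.cohort[sim.cohort["solved"] == 1]
    first_diag = {}
    for d in sim.diagnoses:
        first_diag.setdefault(d.patient_id, d.gene)
    preferred = solved.sort_values(
        ["image_flag", "patient_id"], ascending=[False, True]
    )["patient_id"].tolist()
    bench = [p for p in preferred if p in first_diag][: params.n_benchmark]

    centers = {
        g: _unit(rng.standard_normal(params.descriptor_dim))
        for g in ont.genes
    }
    if params.gestalt_informative:
        causal_genes = sorted({first_diag[p] for p in bench})
        background = [g for g in ont.genes if g not in causal_genes]
        bg_pick = list(
            rng.choice(
                background,
                size=min(params.n_gallery_background, len(background)),
                replace=False,
            )
        )
        gallery_genes = sorted(causal_genes + bg_pick)
    else:
        # no-information condition: the gallery must carry no signal,
        # including through its gene composition, so it is drawn without
        # regard to the benchmark's causal genes
        gallery_genes = sorted(
            rng.choice(
                ont.genes,
                size=min(params.n_gallery_background, len(ont.genes)),
                replace=False,
            )
        )
    gallery: list[tuple[DescriptorSet, str]] = []
    for g in gallery_genes:
        for j in range(params.gallery_per_gene):
            gallery.append(
                (
                    _descriptors(
                        rng, centers[g], params.descriptor_noise,
                        f"gallery_{g}_{j}",
                    ),
                    g,
                )
            )

    cases = []
    n_genes = len(ont.genes)
    for pid in bench:
        causal = first_diag[pid]
        if params.gestalt_informative:
            center = centers[causal]
        else:
            center = _unit(rng.standard_normal(params.descriptor_dim))
        descriptors = _descriptors(rng, center, params.descriptor_noise, pid)

        common = rng.random(n_genes) < params.af_common_fraction
        af = np.where(
            common, rng.uniform(0.02, 0.5, n_genes),
            rng.uniform(0.0, 0.005, n_genes),
        )
        score = np.clip(rng.normal(15.0, 5.0, n_genes), 0.0, None)
        variants = pd.DataFrame(
            {"gene": ont.genes, "af": af, "score": score}
        )
        if params.molecular_boost > 0:
            boosted = pd.DataFrame(
                {
                    "gene": [causal],
                    "af": [rng.uniform(0.0, 0.005)],
                    "score": [15.0 + params.molecular_boost + rng.normal(0, 2)],
                }
            )
            variants = pd.concat([variants, boosted], ignore_index=True)
        cases.append(
            CaseInputs(
                patient_id=pid,
                causal_gene=causal,
                descriptors=descriptors,
                variants=variants,
                terms=sim.terms[pid],
            )
        )
    return ScoreSimulation(gallery=gallery, cases=cases, vocabulary=list(ont.genes))


def run_benchmark(
    scores: ScoreSimulation,
    ont: SyntheticOntology,
    channels: Sequence[str] = ("gestalt", "feature", "molecular"),
    af_cutoff: float = 0.01,
    ks: Sequence[int] = (1, 5, 10, 30, 100),
    n_boot: int = 1000,
    seed: int = 1,
):
    """Score every benchmark case with the requested channels, rank genes
    and return the top-k accuracy curve (see the prioritizer module)."""
    ranks = []
    for case in scores.cases:
        gestalt = (
            gestalt_gene_scores(case.descriptors, scores.gallery)
            if "gestalt" in channels
            else None
        )
        feature = (
            feature_gene_scores(case.terms, ont.gene_annotations, ont.index)
            if "feature" in channels
            else None
        )
        molecular = (
            molecular_gene_scores(case.variants, af_cutoff=af_cutoff)
            if "molecular" in channels
            else None
        )
        table = score_case(
            scores.vocabulary, gestalt=gestalt, feature=feature,
            molecular=molecular,
        )
        ranks.append(causal_rank(table, case.causal_gene))
    return topk_accuracy(ranks, ks=ks, n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# archive counts and candidate table

def simulate_clinvar(
    n_genes: int = 1000,
    zipf_alpha: float = 1.5,
    year_range: tuple[int, int] = (1990, 2020),
    seed: int = 0,
    gene_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Long-tailed per-gene P/LP submission counts (Zipf) with recency-
    skewed years of first gene-disease association."""
    if n_genes < 100:
        raise ValueError("n_genes must be at least 100")
    rng = np.random.default_rng(seed)
    counts = rng.zipf(zipf_alpha, size=n_genes)
    years = [_draw_year(rng, year_range) for _ in range(n_genes)]
    if gene_names is None:
        gene_names = [f"GENE{i + 1:04d}" for i in range(n_genes)]
    return pd.DataFrame(
        {
            "gene": list(gene_names)[:n_genes],
            "plp_submissions": counts.astype(int),
            "first_assoc_year": years,
        }
    )


def simulate_candidates(
    n: int = 57,
    n_high: int = 34,
    seed: int = 0,
    weights=None,
) -> pd.DataFrame:
    """Synthetic stand-in for a curated candidate-gene scoring table.

    The real per-candidate criterion table is not distributable; this
    generator produces ``n`` candidates whose criterion indicators imply
    ``n_high`` high-evidence and ``n - n_high`` medium-evidence classes
    under the MOI-specific thresholds, so classifier round-trips can be
    checked against published class counts.
    """
    from .evidence import CriterionWeights, MANDATORY_CRITERIA

    if weights is None:
        weights = CriterionWeights.default()
    rng = np.random.default_rng(seed)
    crits = weights.criteria
    rows = []
    for i in range(n):
        want_high = i < n_high
        moi = "AD" if rng.random() < 0.7 else "AR"
        threshold = 4 if moi == "AD" else 3
        mask = weights.applicable(moi)
        for _ in range(10_000):
            flags = {c: bool(rng.random() < 0.5) for c in crits}
            score = int(
                sum(
                    weights.table.loc[c, "weight"]
                    for c in crits
                    if mask[c] and flags[c]
                )
            )
            if want_high and score >= threshold:
                break
            if not want_high and 1 <= score < threshold:
                break
        row = {"gene": f"CAND{i + 1:03d}", "moi": moi}
        row.update({m: True for m in MANDATORY_CRITERIA})
        row.update(flags)
        rows.append(row)
    frame = pd.DataFrame(rows)
    order = rng.permutation(len(frame))
    return frame.iloc[order].reset_index(drop=True)


# ---------------------------------------------------------------------------
# fixture emission

def emit_fixture(
    directory,
    params: SimulationParams | None = None,
    include_benchmark: bool = True,
    ontology_terms: int = 600,
) -> Path:
    """Write the complete fixture directory consumed by the pipeline:
    ontology.obo, group mapping tables, case table with a JSON sidecar for
    the term lists, diagnosis table, archive count table, prioritization
    inputs and the parameter file."""
    if params is None:
        params = SimulationParams()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ont = make_ontology(
        n_terms=ontology_terms, seed=_subseed(params.seed, 3),
        n_genes=params.n_genes,
    )
    sim = simulate_cohort(ont, params)

    (directory / "ontology.obo").write_text(ont.obo_text, encoding="utf-8")
    terms_frame, groups_frame = ont.group_map.to_frames()
    terms_frame.to_csv(directory / "terms_to_subcategory.tsv", sep="\t", index=False)
    groups_frame.to_csv(directory / "subcategory_to_group.tsv", sep="\t", index=False)

    sim.cohort.to_csv(directory / "cohort.tsv", sep="\t", index=False)
    with open(directory / "cohort_terms.json", "w", encoding="utf-8") as fh:
        json.dump({p: sorted(t) for p, t in sim.terms.items()}, fh)
    diagnoses_to_frame(sim.diagnoses).to_csv(
        directory / "diagnoses.tsv", sep="\t", index=False
    )
    clinvar = simulate_clinvar(
        n_genes=params.n_genes,
        zipf_alpha=params.zipf_alpha,
        year_range=params.year_range,
        seed=_subseed(params.seed, 4),
        gene_names=ont.genes,
    )
    clinvar.to_csv(directory / "clinvar.tsv", sep="\t", index=False)
    ann = pd.DataFrame(
        [
            {"gene": g, "terms": ";".join(sorted(t))}
            for g, t in sorted(ont.gene_annotations.items())
        ]
    )
    ann.to_csv(directory / "gene_annotations.tsv", sep="\t", index=False)
    params.to_json(directory / "params.json")

    if include_benchmark:
        scores = simulate_scores(sim, ont, params)
        ddir = directory / "descriptors"
        gdir = directory / "gallery"
        ddir.mkdir(exist_ok=True)
        gdir.mkdir(exist_ok=True)
        var_frames = []
        bench_rows = []
        for case in scores.cases:
            np.savetxt(
                ddir / f"{case.patient_id}.tsv",
                case.descriptors.vectors,
                delimiter="\t",
                fmt="%.6f",
            )
            v = case.variants.copy()
            v.insert(0, "patient_id", case.patient_id)
            var_frames.append(v)
            bench_rows.append(
                {"patient_id": case.patient_id, "causal_gene": case.causal_gene}
            )
        for j, (ds, gene) in enumerate(scores.gallery):
            np.savetxt(
                gdir / f"{gene}__{j}.tsv", ds.vectors, delimiter="\t",
                fmt="%.6f",
            )
        pd.concat(var_frames, ignore_index=True).to_csv(
            directory / "variants.tsv", sep="\t", index=False
        )
        pd.DataFrame(bench_rows).to_csv(
            directory / "benchmark.tsv", sep="\t", index=False
        )
    return directory
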