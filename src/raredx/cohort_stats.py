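"""Cohort-level genetic-architecture statistics.

Operates on a case table (one row per patient, with solved status and
autozygosity) and a diagnosis list (one entry per molecular diagnosis;
dual diagnoses give a patient two entries).  Covers diagnostic yield by
group with pairwise Fisher tests and Bonferroni correction, the mode-of-
inheritance (MOI) spectrum, autozygosity stratification with a de-novo-
normalized recessive burden ratio, carrier-screening amenability of
recessive diagnoses, headline cohort rates, archive-submission quartiles
of disease genes and the year-of-first-association comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MOI_CATEGORIES",
    "AR_CATEGORIES",
    "DENOVO_CATEGORY",
    "Variant",
    "Diagnosis",
    "YieldTable",
    "yield_table",
    "moi_distribution",
    "autozygosity_stratify",
    "denovo_normalized_burden",
    "carrier_amenable",
    "rate_summary",
    "clinvar_quartiles",
    "year_comparison",
    "year_histogram",
    "format_percent",
    "diagnoses_to_frame",
    "diagnoses_from_frame",
]

#: The six MOI categories of the diagnosis spectrum.
MOI_CATEGORIES = ("AD", "AD_de_novo", "AR_hom", "AR_comp_het", "XL", "MT")
AR_CATEGORIES = ("AR_hom", "AR_comp_het")
DENOVO_CATEGORY = "AD_de_novo"

_PLP = {"P", "LP", "pathogenic", "likely_pathogenic"}


@dataclass(frozen=True)
class Variant:
    """A reported variant with its archive class at the reference date."""

    clinvar_class: str | None  # "P", "LP", "VUS" or None (not submitted)
    lof: bool = False
    nmd_escape: bool = False
    af: float = 0.0

    @property
    def is_plp(self) -> bool:
        return self.clinvar_class in _PLP


@dataclass
class Diagnosis:
    """One molecular diagnosis of one patient."""

    patient_id: str
    gene: str
    moi: str
    variants: list[Variant] = field(default_factory=list)
    mosaic: bool = False  # parental mosaicism of a nominally de novo variant
    year_first_assoc: int | None = None
    novel_gene: bool = False

    def __post_init__(self) -> None:
        if self.moi not in MOI_CATEGORIES:
            raise ValueError(
                f"diagnosis {self.patient_id}/{self.gene}: moi {self.moi!r} "
                f"not in {MOI_CATEGORIES}"
            )
        if self.moi == "AR_comp_het" and len(self.variants) != 2:
            raise ValueError(
                f"compound-heterozygous diagnosis {self.patient_id}/{self.gene} "
                f"must carry exactly 2 variants, has {len(self.variants)}"
            )


# ---------------------------------------------------------------------------
# diagnostic yield

@dataclass
class YieldTable:
    per_group: pd.DataFrame  # group, solved, total, yield
    pairwise: pd.DataFrame  # group_a, group_b, odds_ratio, p, p_adj


def yield_table(
    cohort: pd.DataFrame,
    group_col: str = "disease_category",
    solved_col: str = "solved",
) -> YieldTable:
    """Per-group diagnostic yield with all pairwise two-sided Fisher tests.

    Bonferroni correction runs over the number of pairwise tests
    (adjusted p = min(1, m * p)).  Empty groups are excluded with a
    warning.
    """
    df = cohort[[group_col, solved_col]].copy()
    grouped = df.groupby(group_col)[solved_col].agg(["sum", "count"])
    empty = grouped.index[grouped["count"] == 0]
    if len(empty):
        warnings.warn(f"excluding empty groups: {list(empty)}", stacklevel=2)
        grouped = grouped.drop(index=empty)
    per_group = grouped.rename(columns={"sum": "solved", "count": "total"})
    per_group["yield"] = per_group["solved"] / per_group["total"]
    per_group = per_group.reset_index().rename(columns={group_col: "group"})

    rows = []
    groups = list(per_group["group"])
    lookup = per_group.set_index("group")
    pairs = [
        (a, b) for i, a in enumerate(groups) for b in groups[i + 1:]
    ]
    m = len(pairs)
    for a, b in pairs:
        sa, ta = int(lookup.loc[a, "solved"]), int(lookup.loc[a, "total"])
        sb, tb = int(lookup.loc[b, "solved"]), int(lookup.loc[b, "total"])
        table = [[sa, ta - sa], [sb, tb - sb]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "odds_ratio": odds,
                "p": p,
                "p_adj": min(1.0, m * p),
            }
        )
    pairwise = pd.DataFrame(
        rows, columns=["group_a", "group_b", "odds_ratio", "p", "p_adj"]
    )
    return YieldTable(per_group=per_group, pairwise=pairwise)


# ---------------------------------------------------------------------------
# mode of inheritance

def moi_distribution(diagnoses: Sequence[Diagnosis]) -> pd.DataFrame:
    """Counts and fractions per MOI category over *diagnoses* (dual
    diagnoses count twice, as in the diagnosis-level spectrum)."""
    if not len(diagnoses):
        raise ValueError("diagnosis list is empty")
    counts = pd.Series(0, index=list(MOI_CATEGORIES), dtype=int)
    for d in diagnoses:
        counts[d.moi] += 1
    out = pd.DataFrame({"count": counts})
    out["fraction"] = out["count"] / out["count"].sum()
    return out


def autozygosity_stratify(
    cohort: pd.DataFrame,
    diagnoses: Sequence[Diagnosis],
    threshold: float = 0.02,
) -> dict:
    """Split the cohort at the autozygosity threshold (high is strictly
    greater) and summarize each stratum's yield and MOI composition.

    Cases with missing autozygosity are excluded and flagged.
    """
    df = cohort.copy()
    missing = df["autozygosity"].isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} cases without autozygosity excluded",
            stacklevel=2,
        )
        df = df[~missing]
    high_ids = set(df.loc[df["autozygosity"] > threshold, "patient_id"])
    low_ids = set(df.loc[df["autozygosity"] <= threshold, "patient_id"])
    out = {}
    for name, ids in (("low", low_ids), ("high", high_ids)):
        sub = df[df["patient_id"].isin(ids)]
        diag = [d for d in diagnoses if d.patient_id in ids]
        out[name] = {
            "n": int(len(sub)),
            "solved": int(sub["solved"].sum()),
            "yield": float(sub["solved"].mean()) if len(sub) else float("nan"),
            "n_diagnoses": len(diag),
            "moi": moi_distribution(diag) if diag else None,
        }
    out["threshold"] = threshold
    return out


def denovo_normalized_burden(
    high_composition: Mapping[str, float] | pd.DataFrame,
    low_composition: Mapping[str, float] | pd.DataFrame,
    ar_categories: Sequence[str] = AR_CATEGORIES,
    denovo_category: str = DENOVO_CATEGORY,
) -> float:
    """Recessive burden ratio normalized by the de novo rate.

    R = (AR / de novo)_high / (AR / de novo)_low on MOI fractions.  The de
    novo rate is used as the normalizer because de novo mutation counts
    depend on parental age but not on autozygosity, so the de-novo-
    attributable disease prevalence is comparable between strata.
    """

    def _frac(comp, cat):
        if isinstance(comp, pd.DataFrame):
            return float(comp.loc[cat, "fraction"])
        return float(comp[cat])

    ratios = []
    for comp in (high_composition, low_composition):
        dn = _frac(comp, denovo_category)
        if dn <= 0:
            raise ValueError(
                "de novo fraction must be positive for normalization"
            )
        ar = sum(_frac(comp, c) for c in ar_categories)
        ratios.append(ar / dn)
    return ratios[0] / ratios[1]


# ---------------------------------------------------------------------------
# carrier screening

def carrier_amenable(diagnosis: Diagnosis, strict_comp_het: bool = True) -> bool:
    """Whether a recessive diagnosis would have been detectable by
    expanded carrier screening at the reference date.

    Homozygous: the variant is archive-classified P/LP, or it is a
    predicted loss-of-function variant not predicted to escape nonsense-
    mediated decay.  Compound heterozygous: under the strict default both
    variants must individually be P/LP; with ``strict_comp_het=False`` the
    LoF rule is also accepted per variant.
    """
    if diagnosis.moi not in AR_CATEGORIES:
        raise ValueError(
            f"carrier_amenable applies to AR diagnoses, got {diagnosis.moi}"
        )
    if not diagnosis.variants:
        raise ValueError("diagnosis carries no variant annotations")

    def _lof_rule(v: Variant) -> bool:
        return v.is_plp or (v.lof and not v.nmd_escape)

    if diagnosis.moi == "AR_hom":
        return _lof_rule(diagnosis.variants[0])
    if strict_comp_het:
        return all(v.is_plp for v in diagnosis.variants)
    return all(_lof_rule(v) for v in diagnosis.variants)


# ---------------------------------------------------------------------------
# headline rates

def format_percent(numerator: int, denominator: int) -> str:
    """Cohort-style percent formatting: one decimal below 5%, integer
    otherwise."""
    pct = 100.0 * numerator / denominator
    return f"{pct:.1f}%" if pct < 5 else f"{pct:.0f}%"


def rate_summary(
    cohort: pd.DataFrame, diagnoses: Sequence[Diagnosis]
) -> pd.DataFrame:
    """Named headline rates with their exact denominators.

    dual_diagnosis: patients with >= 2 diagnoses over solved patients;
    parental_mosaicism: mosaic-flagged de novo diagnoses over de novo
    diagnoses; carrier_amenable: amenable recessive diagnoses over
    recessive diagnoses; treated: patients with a targeted therapy
    (``treated`` column, if present) over solved patients.
    """
    solved = int(cohort["solved"].sum())
    per_patient = pd.Series([d.patient_id for d in diagnoses]).value_counts()
    dual = int((per_patient >= 2).sum())
    denovo = [d for d in diagnoses if d.moi == DENOVO_CATEGORY]
    mosaic = sum(1 for d in denovo if d.mosaic)
    ar = [d for d in diagnoses if d.moi in AR_CATEGORIES]
    amen = sum(1 for d in ar if carrier_amenable(d))
    rows = [
        ("diagnostic_yield", solved, int(len(cohort))),
        ("dual_diagnosis", dual, solved),
        ("parental_mosaicism", mosaic, len(denovo)),
        ("carrier_amenable", amen, len(ar)),
    ]
    if "treated" in cohort.columns:
        rows.append(("treated", int(cohort["treated"].sum()), solved))
    out = []
    for name, num, den in rows:
        if den == 0:
            warnings.warn(f"rate {name!r} has zero denominator", stacklevel=2)
            out.append((name, num, den, float("nan"), "undefined"))
        else:
            out.append(
                (name, num, den, 100.0 * num / den, format_percent(num, den))
            )
    return pd.DataFrame(
        out, columns=["rate", "numerator", "denominator", "percent", "formatted"]
    ).set_index("rate")


# ---------------------------------------------------------------------------
# archive-submission quartiles and year-of-association comparison

def clinvar_quartiles(
    counts: pd.DataFrame,
    exclude: Iterable[str] = (),
    diagnoses: Sequence[Diagnosis] | None = None,
) -> dict:
    """Assign disease genes to submission quartiles and tally cohort
    diagnoses per quartile.

    Genes are ranked by descending P/LP submission count (after removing
    the secondary-findings exclusion list); each gene spans an interval of
    the cumulative submission fraction and is assigned to the quartile bin
    containing its interval midpoint.  Cohort genes absent from the count
    table are left unassigned and flagged.
    """
    t = counts.copy()
    if not {"gene", "plp_submissions"} <= set(t.columns):
        raise ValueError("counts needs columns gene, plp_submissions")
    if (t["plp_submissions"] <= 0).any():
        raise ValueError("submission counts must be positive")
    t = t[~t["gene"].isin(set(exclude))]
    t = t.sort_values(
        ["plp_submissions", "gene"], ascending=[False, True]
    ).reset_index(drop=True)
    total = t["plp_submissions"].sum()
    upper = t["plp_submissions"].cumsum() / total
    lower = upper - t["plp_submissions"] / total
    mid = 0.5 * (lower + upper)
    # midpoints exactly on a bin boundary fall to the lower quartile
    t["quartile"] = np.clip(np.ceil(mid * 4).astype(int), 1, 4)
    t["quartile"] = "Q" + t["quartile"].astype(str)
    t["cum_fraction"] = upper

    summary = (
        t.groupby("quartile")
        .agg(
            n_genes=("gene", "size"),
            submission_fraction=("plp_submissions", lambda s: s.sum() / total),
        )
        .reindex([f"Q{i}" for i in range(1, 5)])
    )
    summary["n_genes"] = summary["n_genes"].fillna(0).astype(int)
    summary["submission_fraction"] = summary["submission_fraction"].fillna(0.0)

    unassigned: list[str] = []
    if diagnoses is not None:
        gene_q = dict(zip(t["gene"], t["quartile"]))
        tally = {q: {"variants": 0, "genes": set()} for q in summary.index}
        for d in diagnoses:
            q = gene_q.get(d.gene)
            if q is None:
                unassigned.append(d.gene)
                continue
            tally[q]["variants"] += 1
            tally[q]["genes"].add(d.gene)
        if unassigned:
            warnings.warn(
                f"{len(unassigned)} cohort diagnoses in genes missing from "
                "the count table were left unassigned",
                stacklevel=2,
            )
        summary["cohort_variants"] = [
            tally[q]["variants"] for q in summary.index
        ]
        summary["cohort_genes"] = [
            len(tally[q]["genes"]) for q in summary.index
        ]
    return {"genes": t, "summary": summary, "unassigned": unassigned}


def year_comparison(
    years_a: Sequence[int], years_b: Sequence[int]
) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov test on year-of-first-
    association distributions; returns (D, p)."""
    a = np.asarray(list(years_a), dtype=float)
    b = np.asarray(list(years_b), dtype=float)
    if not len(a) or not len(b):
        raise ValueError("both year samples must be non-empty")
    res = stats.ks_2samp(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def year_histogram(
    years: Sequence[int], start: int = 1970, end: int = 2020, width: int = 10
) -> pd.DataFrame:
    """Decade-style histogram of years of first gene-disease association."""
    edges = list(range(start, end + width, width))
    counts, _ = np.histogram(list(years), bins=edges)
    labels = [f"{lo + 1}-{lo + width}" for lo in edges[:-1]]
    return pd.DataFrame({"interval": labels, "count": counts})


# ---------------------------------------------------------------------------
# tabular IO for diagnoses

_VAR_FIELDS = ("clinvar_class", "lof", "nmd_escape", "af")


def diagnoses_to_frame(diagnoses: Sequence[Diagnosis]) -> pd.DataFrame:
    """Flatten diagnoses (up to two variants each) into a TSV-ready table."""
    rows = []
    for d in diagnoses:
        row = {
            "patient_id": d.patient_id,
            "gene": d.gene,
            "moi": d.moi,
            "mosaic": int(d.mosaic),
            "year_first_assoc": d.year_first_assoc,
            "novel_gene": int(d.novel_gene),
        }
        for i in range(2):
            v = d.variants[i] if i < len(d.variants) else None
            row[f"v{i + 1}_class"] = v.clinvar_class if v else ""
            row[f"v{i + 1}_lof"] = int(v.lof) if v else ""
            row[f"v{i + 1}_nmd_escape"] = int(v.nmd_escape) if v else ""
            row[f"v{i + 1}_af"] = v.af if v else ""
        rows.append(row)
    return pd.DataFrame(rows)


def diagnoses_from_frame(frame: pd.DataFrame) -> list[Diagnosis]:
    out = []
    for _, row in frame.iterrows():
        variants = []
        for i in range(1, 3):
            cls = row.get(f"v{i}_class", "")
            if pd.isna(cls) or cls == "":
                continue
            variants.append(
                Variant(
                    clinvar_class=None if cls == "none" else str(cls),
                    lof=bool(int(row[f"v{i}_lof"])),
                    nmd_escape=bool(int(row[f"v{i}_nmd_escape"])),
                    af=float(row[f"v{i}_af"]),
                )
            )
        year = row.get("year_first_assoc")
        out.append(
            Diagnosis(
                patient_id=str(row["patient_id"]),
                gene=str(row["gene"]),
                moi=str(row["moi"]),
                variants=variants,
                mosaic=bool(int(row["mosaic"])),
                year_first_assoc=None if pd.isna(year) else int(year),
                novel_gene=bool(int(row["novel_gene"])),
            )
        )
    return out
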