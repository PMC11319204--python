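"""Evidence scoring for novel disease-candidate genes.

A candidate gene must first pass four mandatory criteria: (1) no previous
robust association with a human phenotype, (2) no alternative causative
explanation in the case, (3) allele frequency below the cutoff or absent
in controls, (4) inheritance consistent with the family phenotype.
Eligible candidates are then graded with nine weighted criteria; the
maximum attainable score for an autosomal dominant (AD) candidate is 8.
Three of the nine criteria (confirmed de novo status and the two gnomAD
constraint metrics) apply only to AD candidates and contribute nothing
under recessive or X-linked inheritance, which makes the score less
informative there.  Classification thresholds differ by mode of
inheritance: AD candidates score high with >= 4 and medium with 1-3;
recessive (and, by the same mask, X-linked) candidates score high with
>= 3 and medium below.

The per-criterion weights are configuration data, not code; the shipped
default gives the eight actionable criteria weight 1 and records the
animal-model criterion unscored (weight 0) so that the AD maximum is
exactly 8.  Any replacement table with the same columns can be loaded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import pandas as pd

__all__ = [
    "WeightConfigError",
    "IneligibleCandidateError",
    "CriterionWeights",
    "Candidate",
    "MANDATORY_CRITERIA",
    "check_mandatory",
    "evidence_score",
    "classify",
    "score_candidates",
]

AD_MAX_SCORE = 8

MANDATORY_CRITERIA = (
    "no_prior_association",
    "no_alternative_cause",
    "af_below_cutoff",
    "inheritance_consistent",
)

_VALID_MOI = {"AD", "AR", "XL"}


class WeightConfigError(ValueError):
    """The weight configuration cannot produce the required AD maximum."""


class IneligibleCandidateError(ValueError):
    """Scoring was requested for a candidate failing a mandatory criterion."""


@dataclass(frozen=True)
class CriterionWeights:
    """Nine-criterion weight table (criterion id -> weight, AD-only flag)."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        required = {"weight", "ad_only"}
        if not required <= set(t.columns):
            raise WeightConfigError(f"weight table needs columns {required}")
        if len(t) != 9:
            raise WeightConfigError(f"expected 9 criteria, got {len(t)}")
        if (t["weight"] < 0).any() or not (
            t["weight"] == t["weight"].astype(int)
        ).all():
            raise WeightConfigError("weights must be non-negative integers")
        ad_max = int(t["weight"].sum())
        if ad_max != AD_MAX_SCORE:
            raise WeightConfigError(
                f"AD-applicable weights sum to {ad_max}, must equal {AD_MAX_SCORE}"
            )

    @classmethod
    def default(cls) -> "CriterionWeights":
        path = resources.files("raredx").joinpath("data/evidence_weights.tsv")
        with resources.as_file(path) as p:
            return cls.from_tsv(p)

    @classmethod
    def from_tsv(cls, path) -> "CriterionWeights":
        t = pd.read_csv(path, sep="\t", dtype={"criterion": str})
        t = t.set_index("criterion")
        t["weight"] = t["weight"].astype(int)
        t["ad_only"] = t["ad_only"].astype(int).astype(bool)
        return cls(table=t)

    @property
    def criteria(self) -> list[str]:
        return list(self.table.index)

    def applicable(self, moi: str) -> pd.Series:
        """Boolean mask of criteria contributing under the given MOI.

        X-linked candidates are scored with the recessive mask (AD-only
        criteria excluded)."""
        if moi not in _VALID_MOI:
            raise ValueError(f"mode of inheritance must be one of {_VALID_MOI}")
        if moi == "AD":
            return pd.Series(True, index=self.table.index)
        return ~self.table["ad_only"]

    def max_score(self, moi: str) -> int:
        mask = self.applicable(moi)
        return int(self.table.loc[mask, "weight"].sum())


@dataclass
class Candidate:
    """A candidate gene-disease association to be scored."""

    gene: str
    moi: str
    mandatory: Mapping[str, bool]
    criteria: Mapping[str, bool]

    def __post_init__(self) -> None:
        if self.moi not in _VALID_MOI:
            raise ValueError(
                f"candidate {self.gene}: moi must be one of {_VALID_MOI}"
            )


def check_mandatory(candidate: Candidate) -> bool:
    """True iff all four mandatory criteria are supplied and hold."""
    flags = []
    for name in MANDATORY_CRITERIA:
        if name not in candidate.mandatory or candidate.mandatory[name] is None:
            raise ValueError(
                f"candidate {candidate.gene}: mandatory flag {name!r} missing"
            )
        flags.append(bool(candidate.mandatory[name]))
    return all(flags)


def evidence_score(
    candidate: Candidate, weights: CriterionWeights | None = None
) -> int:
    """Weighted sum over the criteria applicable to the candidate's MOI.

    Refuses to score candidates that fail the mandatory gate.
    """
    if weights is None:
        weights = CriterionWeights.default()
    if not check_mandatory(candidate):
        raise IneligibleCandidateError(
            f"candidate {candidate.gene} fails a mandatory criterion"
        )
    mask = weights.applicable(candidate.moi)
    total = 0
    for crit in weights.criteria:
        if mask[crit] and bool(candidate.criteria.get(crit, False)):
            total += int(weights.table.loc[crit, "weight"])
    return total


def classify(score: int, moi: str) -> str:
    """Evidence class from score and mode of inheritance.

    AD: score >= 4 is high, 1-3 medium (0 is flagged and reported medium).
    AR and XL: score >= 3 is high, below medium.
    """
    if moi not in _VALID_MOI:
        raise ValueError(f"mode of inheritance must be one of {_VALID_MOI}")
    if not 0 <= score <= AD_MAX_SCORE:
        raise ValueError(f"score {score} outside [0, {AD_MAX_SCORE}]")
    if moi == "AD":
        if score == 0:
            warnings.warn(
                "AD candidate with score 0: below the defined medium band",
                stacklevel=2,
            )
            return "medium"
        return "high" if score >= 4 else "medium"
    return "high" if score >= 3 else "medium"


def score_candidates(
    frame: pd.DataFrame, weights: CriterionWeights | None = None
) -> pd.DataFrame:
    """Score a candidate table (columns: gene, moi, the four mandatory
    flags, c1..c9) and append ``score`` and ``evidence_class`` columns."""
    if weights is None:
        weights = CriterionWeights.default()
    out = frame.copy()
    scores, classes = [], []
    for _, row in frame.iterrows():
        cand = Candidate(
            gene=row["gene"],
            moi=row["moi"],
            mandatory={k: bool(row[k]) for k in MANDATORY_CRITERIA},
            criteria={c: bool(row[c]) for c in weights.criteria},
        )
        s = evidence_score(cand, weights)
        scores.append(s)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            classes.append(classify(s, cand.moi))
    out["score"] = scores
    out["evidence_class"] = classes
    return out
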