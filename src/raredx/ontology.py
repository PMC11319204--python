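"""Phenotype-ontology machinery: OBO parsing, information content, Resnik
similarity and assignment of patients to phenotype groups.

The ontology is a DAG of phenotype terms (HPO-style identifiers). On top of
it this module provides

* corpus-based information content (IC), ``ic(t) = -ln(n_t / N)`` where
  ``n_t`` counts corpus entities annotated to ``t`` or any descendant;
* Resnik pairwise term similarity (IC of the most informative common
  ancestor, MICA);
* symmetric best-match-average similarity between two term sets, the
  patient-vs-patient (or patient-vs-disease) measure used downstream;
* assignment of patients to clinician-curated phenotype subcategories
  (49 in the reference categorization) and higher-order groups (12), where
  a patient belongs to a group iff at least one of their terms maps to it.
"""

from __future__ import annotations

import io
import math
import os
import warnings
from collections import Counter, deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet
import pandas as pd

__all__ = [
    "OntologyStructureError",
    "OntologyIndex",
    "GroupMap",
    "PatientRecord",
    "load_ontology",
    "information_content",
    "resnik_pair",
    "patient_similarity",
    "assign_groups",
]


class OntologyStructureError(ValueError):
    """The ontology violates a structural requirement (cycle, missing or
    ambiguous root, reference to an undeclared parent term)."""


@dataclass
class OntologyIndex:
    """Parsed ontology with ancestor closure and (optionally) IC.

    ``parents`` maps each term to its direct ``is_a`` parents; ``ancestors``
    is the transitive closure *including the term itself*.  ``ic`` is empty
    until :func:`information_content` has been run against a corpus.
    """

    terms: set[str]
    parents: dict[str, set[str]]
    names: dict[str, str]
    alt_ids: dict[str, str]
    root: str
    ic: dict[str, float] = field(default_factory=dict)
    ic_flagged: set[str] = field(default_factory=set)
    _ancestor_cache: dict[str, frozenset[str]] = field(
        default_factory=dict, repr=False
    )

    def resolve(self, term: str) -> str | None:
        """Map ``term`` (primary or alt id) to its primary id, else None."""
        if term in self.terms:
            return term
        return self.alt_ids.get(term)

    def __contains__(self, term: str) -> bool:
        return self.resolve(term) is not None

    def ancestors(self, term: str) -> frozenset[str]:
        """Transitive ``is_a`` closure of ``term``, including itself."""
        primary = self.resolve(term)
        if primary is None:
            raise KeyError(f"term {term!r} not in ontology")
        cached = self._ancestor_cache.get(primary)
        if cached is not None:
            return cached
        # Iterative DFS with memoization; the graph is acyclic by contract.
        stack = [primary]
        while stack:
            node = stack[-1]
            pending = [
                p for p in self.parents[node] if p not in self._ancestor_cache
            ]
            if pending:
                stack.extend(pending)
                continue
            closure = {node}
            for p in self.parents[node]:
                closure |= self._ancestor_cache[p]
            self._ancestor_cache[node] = frozenset(closure)
            stack.pop()
        return self._ancestor_cache[primary]

    def ancestor_distances(self, term: str) -> dict[str, int]:
        """Ancestors with their minimum upward edge distance (self = 0)."""
        primary = self.resolve(term)
        if primary is None:
            raise KeyError(f"term {term!r} not in ontology")
        dist = {primary: 0}
        queue = deque([primary])
        while queue:
            node = queue.popleft()
            for p in self.parents[node]:
                if p not in dist:
                    dist[p] = dist[node] + 1
                    queue.append(p)
        return dist

    def term_ic(self, term: str) -> float:
        primary = self.resolve(term)
        if primary is None:
            raise KeyError(f"term {term!r} not in ontology")
        if not self.ic:
            raise RuntimeError(
                "information content not computed; run information_content()"
            )
        return self.ic[primary]


def load_ontology(source) -> OntologyIndex:
    """Parse an OBO document into an :class:`OntologyIndex`.

    ``source`` may be a path, an open text handle, or a string containing
    OBO text.  Obsolete stanzas are excluded, ``alt_id`` entries are
    resolved to their primary id, and structural defects (cycles, a parent
    referenced but never declared, zero or multiple roots) raise
    :class:`OntologyStructureError`.
    """
    if isinstance(source, str) and "[Term]" in source:
        handle = io.StringIO(source)
    elif isinstance(source, (str, os.PathLike)):
        handle = open(source, "r", encoding="utf-8")
    else:
        handle = source
    try:
        graph = obonet.read_obo(handle, ignore_obsolete=True)
    finally:
        if isinstance(source, (str, os.PathLike)) and "[Term]" not in str(
            source
        ):
            handle.close()

    undeclared = [n for n, d in graph.nodes(data=True) if "name" not in d]
    if undeclared:
        raise OntologyStructureError(
            f"is_a references to undeclared terms: {sorted(undeclared)}"
        )
    if not nx.is_directed_acyclic_graph(graph):
        raise OntologyStructureError("cycle detected in is_a hierarchy")

    terms = set(graph.nodes)
    # obonet orients edges child -> parent.
    parents = {t: set(graph.successors(t)) for t in terms}
    roots = sorted(t for t in terms if not parents[t])
    if len(roots) != 1:
        raise OntologyStructureError(
            f"expected exactly one root term, found {len(roots)}: {roots}"
        )

    alt_ids: dict[str, str] = {}
    names: dict[str, str] = {}
    for t, data in graph.nodes(data=True):
        names[t] = data.get("name", t)
        for alt in data.get("alt_id", []):
            alt_ids[alt] = t

    return OntologyIndex(
        terms=terms, parents=parents, names=names, alt_ids=alt_ids,
        root=roots[0],
    )


def information_content(
    index: OntologyIndex, corpus: Mapping[str, Iterable[str]]
) -> dict[str, float]:
    """Corpus-based IC in nats, stored on ``index`` and returned.

    Each corpus entity (a disease or a patient) annotates its terms and,
    by propagation, all of their ancestors.  ``ic(t) = -ln(n_t / N)``; the
    root is annotated by every entity and has IC 0.  Terms that annotate no
    entity have undefined IC; they are flagged in ``index.ic_flagged`` and
    assigned the maximum IC observed in the corpus so that similarities
    stay finite.
    """
    if not corpus:
        raise ValueError("corpus must be non-empty")
    n_entities = len(corpus)
    counts: Counter[str] = Counter()
    for entity, terms in corpus.items():
        propagated: set[str] = set()
        for t in terms:
            primary = index.resolve(t)
            if primary is None:
                raise KeyError(
                    f"corpus entity {entity!r} annotated with unknown term {t!r}"
                )
            propagated |= index.ancestors(primary)
        counts.update(propagated)

    ic = {
        t: -math.log(counts[t] / n_entities) for t in index.terms if counts[t]
    }
    max_ic = max(ic.values(), default=0.0)
    flagged = index.terms - ic.keys()
    for t in flagged:
        ic[t] = max_ic
    index.ic = ic
    index.ic_flagged = flagged
    return ic


def resnik_pair(index: OntologyIndex, t1: str, t2: str) -> float:
    """Resnik similarity: IC of the most informative common ancestor.

    The root is a common ancestor of every pair, so the result is >= 0.
    """
    common = index.ancestors(t1) & index.ancestors(t2)
    return max(index.term_ic(a) for a in common)


def patient_similarity(
    index: OntologyIndex, set_a: Iterable[str], set_b: Iterable[str]
) -> float:
    """Symmetric best-match-average Resnik similarity of two term sets.

    For each term in one set the best Resnik match in the other set is
    taken; the two directional means are averaged, which makes the measure
    symmetric by construction.
    """
    a = [index.resolve(t) for t in set_a]
    b = [index.resolve(t) for t in set_b]
    if not a or not b:
        raise ValueError("patient_similarity requires non-empty term sets")
    if any(t is None for t in a) or any(t is None for t in b):
        raise KeyError("term set contains identifiers outside the ontology")
    sims = [[resnik_pair(index, ta, tb) for tb in b] for ta in a]
    forward = sum(max(row) for row in sims) / len(a)
    backward = sum(max(sims[i][j] for i in range(len(a))) for j in range(len(b))) / len(b)
    return 0.5 * (forward + backward)


@dataclass(frozen=True)
class GroupMap:
    """Curated mapping of ontology terms to phenotype subcategories and of
    subcategories to higher-order groups.

    Subcategories are non-overlapping at the term level (each mapped term
    belongs to exactly one subcategory) and every subcategory belongs to
    exactly one higher-order group.
    """

    subcategory_of: Mapping[str, str]
    higher_group_of: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = set(self.subcategory_of.values()) - set(self.higher_group_of)
        if missing:
            raise ValueError(
                f"subcategories without a higher-order group: {sorted(missing)}"
            )

    @property
    def subcategories(self) -> list[str]:
        return sorted(set(self.higher_group_of))

    @property
    def higher_groups(self) -> list[str]:
        return sorted(set(self.higher_group_of.values()))

    @classmethod
    def from_tsv(cls, term_path, group_path) -> "GroupMap":
        """Read the two-column term->subcategory and subcategory->group
        tables (TSV with header columns term_id/subcategory and
        subcategory/higher_group)."""
        terms = pd.read_csv(term_path, sep="\t", dtype=str)
        groups = pd.read_csv(group_path, sep="\t", dtype=str)
        return cls(
            subcategory_of=dict(zip(terms["term_id"], terms["subcategory"])),
            higher_group_of=dict(
                zip(groups["subcategory"], groups["higher_group"])
            ),
        )

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        terms = pd.DataFrame(
            sorted(self.subcategory_of.items()),
            columns=["term_id", "subcategory"],
        )
        groups = pd.DataFrame(
            sorted(self.higher_group_of.items()),
            columns=["subcategory", "higher_group"],
        )
        return terms, groups


@dataclass
class PatientRecord:
    """One study participant.

    ``solved`` must agree with ``diagnoses`` (solved == at least one
    diagnosis); ``autozygosity`` is the genome fraction in runs of
    homozygosity, in [0, 1].
    """

    id: str
    age_class: str
    sex: str
    site: str
    disease_category: str
    hpo_terms: set[str]
    solved: int
    autozygosity: float
    diagnoses: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.autozygosity <= 1.0:
            raise ValueError(
                f"autozygosity {self.autozygosity} outside [0, 1] "
                f"for patient {self.id}"
            )
        if bool(self.solved) != bool(self.diagnoses):
            raise ValueError(
                f"patient {self.id}: solved={self.solved} inconsistent with "
                f"{len(self.diagnoses)} diagnoses"
            )


def assign_groups(
    terms: Iterable[str],
    group_map: GroupMap,
    index: OntologyIndex,
    use_closure: bool = True,
) -> tuple[pd.Series, pd.Series]:
    """Indicator vectors over subcategories and higher-order groups.

    A subcategory indicator is 1 iff at least one patient term maps to it,
    either directly or -- when ``use_closure`` is on -- via its nearest
    mapped ancestor, so that terms newer than the curated table do not drop
    patients.  The higher-group vector is the OR over each group's
    subcategories.  Terms absent from the ontology trigger a warning and
    are skipped.
    """
    if isinstance(terms, PatientRecord):
        terms = terms.hpo_terms
    sub_hit: set[str] = set()
    for t in terms:
        primary = index.resolve(t)
        if primary is None:
            warnings.warn(
                f"term {t!r} not in ontology; skipped in group assignment",
                stacklevel=2,
            )
            continue
        sub = group_map.subcategory_of.get(primary)
        if sub is None and use_closure:
            dist = index.ancestor_distances(primary)
            mapped = [
                (d, anc)
                for anc, d in dist.items()
                if anc in group_map.subcategory_of and d > 0
            ]
            if mapped:
                # nearest listed ancestor; ties broken lexicographically
                _, anc = min(mapped)
                sub = group_map.subcategory_of[anc]
        if sub is not None:
            sub_hit.add(sub)
    if not sub_hit:
        warnings.warn(
            "no term maps to any subcategory; all-zero group assignment",
            stacklevel=2,
        )
    subcats = group_map.subcategories
    groups = group_map.higher_groups
    sub_vec = pd.Series(
        [int(s in sub_hit) for s in subcats], index=subcats, dtype=int
    )
    grp_hit = {group_map.higher_group_of[s] for s in sub_hit}
    grp_vec = pd.Series(
        [int(g in grp_hit) for g in groups], index=groups, dtype=int
    )
    return sub_vec, grp_vec
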