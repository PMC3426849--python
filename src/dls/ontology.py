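"""Ontology DAG handling and training-set derivation.

Parses a minimal OBO-style term file plus GAF-like gene->term annotation
records, propagates annotations upward through the DAG, and derives the
positive / negative training genes for a chosen process term.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

#: relationship types that propagate annotations upward by default
DEFAULT_PROPAGATING_RELATIONS = ("is_a", "part_of")


@dataclass
class OntologyDAG:
    """Directed acyclic graph of terms with child->parent edges."""

    terms: set[str]
    edges: set[tuple[str, str]]
    root: str
    _parents: dict[str, set[str]] = field(init=False, repr=False)
    _ancestor_cache: dict[str, frozenset[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.root not in self.terms:
            raise ValueError(f"root {self.root!r} is not a term")
        self._parents = {t: set() for t in self.terms}
        for child, parent in self.edges:
            if child not in self.terms or parent not in self.terms:
                raise ValueError(f"edge ({child!r}, {parent!r}) references unknown term")
            self._parents[child].add(parent)
        self._ancestor_cache = {}
        self._check_acyclic_and_rooted()

    def _check_acyclic_and_rooted(self) -> None:
        # Kahn's algorithm on child->parent edges; leftovers imply a cycle.
        out_deg = {t: len(self._parents[t]) for t in self.terms}
        children: dict[str, set[str]] = {t: set() for t in self.terms}
        for c, p in self.edges:
            children[p].add(c)
        queue = deque(t for t, d in out_deg.items() if d == 0)
        seen = 0
        while queue:
            t = queue.popleft()
            seen += 1
            for c in children[t]:
                out_deg[c] -= 1
                if out_deg[c] == 0:
                    queue.append(c)
        if seen != len(self.terms):
            raise ValueError("ontology graph contains a cycle")
        for t in self.terms:
            if t != self.root and self.root not in self.ancestors(t):
                raise ValueError(f"term {t!r} does not reach the root")

    def parents(self, term: str) -> set[str]:
        return set(self._parents[term])

    def ancestors(self, term: str) -> frozenset[str]:
        """All terms reachable upward from ``term`` (excluding itself)."""
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        out: set[str] = set()
        stack = list(self._parents[term])
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self._parents[t])
        result = frozenset(out)
        self._ancestor_cache[term] = result
        return result


@dataclass
class AnnotationSet:
    """Direct gene->term annotations plus their upward closure."""

    direct: dict[str, set[str]]
    evidence: dict[tuple[str, str], str] = field(default_factory=dict)
    propagated: dict[str, set[str]] | None = None

    def genes(self) -> list[str]:
        return sorted(self.direct)


@dataclass
class TrainingSet:
    """Positive / negative gene classes for one biological process."""

    process_term: str
    positives: set[str]
    negatives: set[str]
    negative_terms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise ValueError("positives and negatives overlap")
        if not self.positives:
            raise ValueError("positive class is empty")

    def restricted_to(self, gene_ids: list[str] | set[str]) -> "TrainingSet":
        """Drop genes absent from an expression dataset (logged)."""
        universe = set(gene_ids)
        pos = self.positives & universe
        neg = self.negatives & universe
        dropped = (len(self.positives) - len(pos)) + (len(self.negatives) - len(neg))
        if dropped:
            logger.warning("dropped %d training genes absent from the dataset", dropped)
        return TrainingSet(self.process_term, pos, neg, set(self.negative_terms))


def propagate(dag: OntologyDAG, annotations: AnnotationSet, lenient: bool = False) -> AnnotationSet:
    """Fill ``propagated`` with each gene's direct terms plus all their ancestors.

    Unknown terms raise (listing offenders) unless ``lenient``, in which
    case they are skipped with a warning.
    """
    unknown = sorted(
        {t for terms in annotations.direct.values() for t in terms} - dag.terms
    )
    if unknown:
        if not lenient:
            raise ValueError(f"annotations reference unknown terms: {unknown}")
        logger.warning("skipping annotations to unknown terms: %s", unknown)
    propagated: dict[str, set[str]] = {}
    for gene, terms in annotations.direct.items():
        closed: set[str] = set()
        for t in terms:
            if t not in dag.terms:
                continue
            closed.add(t)
            closed |= dag.ancestors(t)
        propagated[gene] = closed
    return AnnotationSet(
        direct={g: set(t) for g, t in annotations.direct.items()},
        evidence=dict(annotations.evidence),
        propagated=propagated,
    )


def _ensure_propagated(dag: OntologyDAG, annotations: AnnotationSet) -> AnnotationSet:
    if annotations.propagated is None:
        return propagate(dag, annotations)
    return annotations


def derive_positive_set(
    dag: OntologyDAG,
    annotations: AnnotationSet,
    term: str,
    evidence_blacklist: frozenset[str] = frozenset(),
) -> set[str]:
    """Genes annotated to ``term`` directly or by inheritance.

    Direct annotations whose evidence code is blacklisted are dropped
    *before* propagation, so a gene reachable only through a blacklisted
    annotation is excluded.
    """
    if term not in dag.terms:
        raise KeyError(f"term {term!r} not in ontology")
    filtered = {
        g: {
            t
            for t in terms
            if annotations.evidence.get((g, t), "") not in evidence_blacklist
        }
        for g, terms in annotations.direct.items()
    }
    filtered = {g: t for g, t in filtered.items() if t}
    prop = propagate(dag, AnnotationSet(direct=filtered, evidence=annotations.evidence))
    positives = {g for g, terms in prop.propagated.items() if term in terms}
    if not positives:
        logger.warning("no genes annotated to %s after filtering", term)
    return positives


def derive_negative_set(
    dag: OntologyDAG,
    annotations: AnnotationSet,
    positives: set[str],
    p_threshold: float = 0.05,
) -> tuple[set[str], set[str]]:
    """Negative genes and the 'negative' terms that license them.

    A term (never the root, which every gene reaches) is *negative* when
    the fraction of positives among its propagated gene set is at most
    ``p_threshold``; terms with no annotated genes are ignored.  A gene is
    negative when it has at least one direct annotation in a negative term
    and no annotation, direct or propagated, in any non-negative term
    (root excluded).
    """
    if not (0 <= p_threshold <= 1):
        raise ValueError("p_threshold must lie in [0, 1]")
    ann = _ensure_propagated(dag, annotations)
    term_genes: dict[str, set[str]] = {}
    for gene, terms in ann.propagated.items():
        for t in terms:
            term_genes.setdefault(t, set()).add(gene)

    negative_terms = {
        t
        for t, genes in term_genes.items()
        if t != dag.root and len(genes & positives) / len(genes) <= p_threshold
    }
    annotated_terms = set(term_genes)
    non_negative = (annotated_terms - negative_terms) - {dag.root}

    negatives: set[str] = set()
    for gene, direct_terms in ann.direct.items():
        if not direct_terms & negative_terms:
            continue
        if ann.propagated[gene] & non_negative:
            continue
        negatives.add(gene)
    negatives -= positives
    if not negatives:
        logger.warning("negative training set is empty at P=%g", p_threshold)
    return negatives, negative_terms


# ---------------------------------------------------------------------------
# readers


def read_obo(path: str) -> OntologyDAG:
    """Minimal OBO reader: ``[Term]`` stanzas with id / is_a / relationship lines.

    The root is the unique term without propagating out-edges.
    """
    terms: set[str] = set()
    edges: set[tuple[str, str]] = set()
    current: str | None = None
    obsolete = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line == "[Term]":
                current = None
                obsolete = False
            elif line.startswith("[") and line.endswith("]"):
                current = None  # non-term stanza
            elif line.startswith("id:") and current is None and not obsolete:
                current = line[3:].strip()
                terms.add(current)
            elif line.startswith("is_obsolete:") and "true" in line and current:
                terms.discard(current)
                obsolete = True
                current = None
            elif line.startswith("is_a:") and current:
                parent = line[5:].strip().split("!")[0].strip()
                edges.add((current, parent))
            elif line.startswith("relationship:") and current:
                parts = line[len("relationship:"):].split("!")[0].split()
                if len(parts) >= 2 and parts[0] in DEFAULT_PROPAGATING_RELATIONS:
                    edges.add((current, parts[1]))
    edges = {(c, p) for c, p in edges if c in terms and p in terms}
    children_only = {c for c, _ in edges}
    roots = sorted(terms - children_only)
    if len(roots) != 1:
        raise ValueError(f"expected exactly one root term, found {roots}")
    return OntologyDAG(terms=terms, edges=edges, root=roots[0])


def read_gaf(path: str) -> AnnotationSet:
    """Tab-delimited (gene, term, evidence) annotation records; '!' lines skipped."""
    direct: dict[str, set[str]] = {}
    evidence: dict[tuple[str, str], str] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("!") or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed annotation line: {line!r}")
            gene, term = parts[0], parts[1]
            code = parts[2] if len(parts) > 2 else ""
            direct.setdefault(gene, set()).add(term)
            evidence[(gene, term)] = code
    return AnnotationSet(direct=direct, evidence=evidence)
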