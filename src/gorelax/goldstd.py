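"""Gold-standard construction from raw GO annotations.

A labelled gold standard is built by three successive filters:

1. drop proteins whose product description contains a banned word
   (case-insensitive substring; e.g. "hypothetical", "predicted",
   "putative");
2. drop terms with no annotation carrying a required evidence code
   (e.g. IPI — inferred from physical interaction — or IGC — inferred from
   genomic context); a per-annotation variant that instead drops individual
   unsupported annotation lines is available behind a flag;
3. drop terms annotating fewer than ``min_count`` or more than
   ``max_count`` proteins.

The surviving ordered term list is the label set L of the predictor; the
surviving proteins are the labelled set used for cross-validation, priors
and clamping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

logger = logging.getLogger(__name__)

DEFAULT_MIN_COUNT = 30
DEFAULT_MAX_COUNT = 400
DEFAULT_EVIDENCE = frozenset({"IPI", "IGC"})
DEFAULT_BANNED_WORDS = ("hypothetical", "predicted", "putative")


@dataclass
class AnnotationSet:
    """Protein -> GO-term labels restricted to a retained label set.

    ``records`` keeps (term, evidence) pairs per protein; ``terms`` is the
    ordered label set L; ``labelled_proteins`` are proteins with at least
    one retained term.
    """

    records: dict[str, set[tuple[str, str]]]
    terms: list[str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._term_set = set(self.terms)
        self._labels: dict[str, set[str]] = {}
        for protein, pairs in self.records.items():
            labels = {t for t, _ in pairs if t in self._term_set}
            if labels:
                self._labels[protein] = labels

    @property
    def labelled_proteins(self) -> set[str]:
        return set(self._labels)

    @property
    def n_labelled(self) -> int:
        return len(self._labels)

    def labels(self, protein: str) -> set[str]:
        """Retained terms annotated to ``protein`` (empty set if none)."""
        return set(self._labels.get(protein, ()))

    def theta(self, protein: str, term: str) -> int:
        """0/1 indicator: does ``protein`` carry retained label ``term``?"""
        if term not in self._term_set:
            raise KeyError(f"term {term!r} is not in the label set")
        return 1 if term in self._labels.get(protein, ()) else 0

    def term_count(self, term: str) -> int:
        if term not in self._term_set:
            raise KeyError(f"term {term!r} is not in the label set")
        return sum(1 for labels in self._labels.values() if term in labels)

    def term_prior(self, term: str) -> float:
        """Fraction of labelled proteins annotated with ``term``."""
        if not self._labels:
            raise ValueError("no labelled proteins: priors undefined")
        return self.term_count(term) / self.n_labelled

    def restricted_to(self, proteins: Iterable[str]) -> "AnnotationSet":
        """Same label set, records limited to the given proteins."""
        keep = set(proteins)
        return AnnotationSet(
            {p: set(pairs) for p, pairs in self.records.items() if p in keep},
            list(self.terms),
            {p: d for p, d in self.descriptions.items() if p in keep},
        )


def build_gold_standard(
    raw: Mapping[str, set[tuple[str, str]]],
    descriptions: Mapping[str, str] | None = None,
    required_evidence: frozenset[str] | set[str] = DEFAULT_EVIDENCE,
    banned_description_words: Iterable[str] = DEFAULT_BANNED_WORDS,
    min_count: int = DEFAULT_MIN_COUNT,
    max_count: int = DEFAULT_MAX_COUNT,
    evidence_per_annotation: bool = False,
) -> AnnotationSet:
    """Apply the description, evidence-code and term-size filters.

    ``raw`` maps protein -> set of (term, evidence-code).  With
    ``evidence_per_annotation=False`` (default) the evidence filter removes
    whole TERMS lacking any required-evidence annotation; with ``True`` it
    removes individual annotation lines instead.  Per-stage attrition is
    logged; an empty result is a warning, not an error.
    """
    descriptions = dict(descriptions or {})
    banned = [w.lower() for w in banned_description_words]
    required = set(required_evidence)

    # stage 1: description filter
    def is_banned(protein: str) -> bool:
        desc = descriptions.get(protein, "").lower()
        return any(w in desc for w in banned)

    records = {
        p: set(pairs) for p, pairs in raw.items() if pairs and not is_banned(p)
    }
    logger.info(
        "description filter: %d of %d proteins retained", len(records), len(raw)
    )

    # stage 2: evidence filter
    if required:
        if evidence_per_annotation:
            records = {
                p: {(t, e) for t, e in pairs if e in required}
                for p, pairs in records.items()
            }
            records = {p: pairs for p, pairs in records.items() if pairs}
            supported = {t for pairs in records.values() for t, _ in pairs}
        else:
            supported = {
                t
                for pairs in records.values()
                for t, e in pairs
                if e in required
            }
    else:
        supported = {t for pairs in records.values() for t, _ in pairs}
    logger.info("evidence filter: %d terms supported", len(supported))

    # stage 3: term-size filter on surviving (protein, term) pairs
    counts: dict[str, int] = {}
    for pairs in records.values():
        for t in {t for t, _ in pairs if t in supported}:
            counts[t] = counts.get(t, 0) + 1
    retained = sorted(t for t, c in counts.items() if min_count <= c <= max_count)
    logger.info("term-size filter: %d of %d terms retained", len(retained), len(counts))
    for t in retained:
        logger.info("retained term %s: %d proteins", t, counts[t])
    if not retained:
        logger.warning("gold standard is empty after filtering")
    return AnnotationSet(records, retained, descriptions)


# -- readers ---------------------------------------------------------------


def read_annotations_tsv(stream: IO[str]) -> dict[str, set[tuple[str, str]]]:
    """Read 3-column TSV: protein, GO id, evidence code ('#' comments)."""
    raw: dict[str, set[tuple[str, str]]] = {}
    seen_data = False
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            if not seen_data:
                continue  # header
            raise ValueError(f"line {lineno}: expected 3 columns")
        protein, term, evidence = (f.strip() for f in fields[:3])
        if not seen_data and term.lower() in ("term", "go_id", "go"):
            continue  # header row
        seen_data = True
        raw.setdefault(protein, set()).add((term, evidence))
    return raw


def read_gaf(stream: IO[str]) -> dict[str, set[tuple[str, str]]]:
    """Read a GAF 2.x file: columns 2, 5, 7 are protein, GO id, evidence."""
    raw: dict[str, set[tuple[str, str]]] = {}
    for lineno, line in enumerate(stream, start=1):
        if not line.strip() or line.startswith("!"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 7:
            raise ValueError(f"line {lineno}: GAF row has {len(fields)} columns, need >= 7")
        protein, term, evidence = fields[1], fields[4], fields[6]
        raw.setdefault(protein, set()).add((term, evidence))
    return raw


def read_descriptions(stream: IO[str]) -> dict[str, str]:
    """Read 2-column TSV: protein, product description."""
    out: dict[str, str] = {}
    for line in stream:
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) >= 2:
            out[fields[0].strip()] = fields[1].strip()
    return out


def write_annotations_tsv(a: AnnotationSet, stream: IO[str]) -> None:
    """Write protein/term/evidence rows for all raw records."""
    stream.write("protein\tterm\tevidence\n")
    for protein in sorted(a.records):
        for term, evidence in sorted(a.records[protein]):
            stream.write(f"{protein}\t{term}\t{evidence}\n")
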