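"""Alignment scoring and alignment-file I/O.

Precision is the fraction of computed correspondences found in the
reference; recall is the fraction of reference correspondences recovered;
the F-measure is their harmonic mean.  Correctness is exact (id1, id2)
membership — no partial credit for near-misses.

Two file formats are supported: the Alignment format used by the OAEI
evaluation campaigns (RDF/XML with Cell/entity1/entity2/measure/relation
elements) and a plain TSV of ``id1, id2, confidence`` rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from lxml import etree

from .ontology import Alignment, Correspondence

__all__ = [
    "EvalResult",
    "score_alignment",
    "read_alignment",
    "write_alignment",
    "AlignmentFormatError",
]

log = logging.getLogger(__name__)

ALIGN_NS = "http://knowledgeweb.semanticweb.org/heterogeneity/alignment"
RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"


class AlignmentFormatError(ValueError):
    """An alignment file could not be parsed."""


@dataclass(frozen=True)
class EvalResult:
    precision: float
    recall: float
    f_measure: float
    n_correct: int
    n_computed: int
    n_reference: int

    def tsv_row(self) -> str:
        return (
            f"{self.precision:.4f}\t{self.recall:.4f}\t{self.f_measure:.4f}"
            f"\t{self.n_correct}\t{self.n_computed}\t{self.n_reference}"
        )


def score_alignment(computed: Alignment, reference: Alignment) -> EvalResult:
    """Exact-pair precision/recall/F against a reference alignment.

    An empty computed alignment scores precision 0 (pessimistic convention,
    keeps F well defined at 0).
    """
    comp = computed.pairs()
    ref = reference.pairs()
    correct = len(comp & ref)
    precision = correct / len(comp) if comp else 0.0
    recall = correct / len(ref) if ref else 0.0
    denom = precision + recall
    f_measure = 2 * precision * recall / denom if denom > 0 else 0.0
    return EvalResult(precision, recall, f_measure, correct, len(comp), len(ref))


def _entity_to_id(iri: str) -> str:
    """Reduce an entity IRI to a class id, mirroring the ontology loaders."""
    if "#" in iri:
        return iri.rsplit("#", 1)[1]
    return iri.rstrip("/").rsplit("/", 1)[-1]


def read_alignment(path: str | Path) -> Alignment:
    """Read OAEI Alignment RDF or native TSV, sniffing by content.

    Only equivalence cells ("=") are kept; cells asserting other relations
    are skipped with a warning.
    """
    path = Path(path)
    head = path.read_text(encoding="utf-8", errors="replace").lstrip()[:200]
    if head.startswith("<"):
        return _read_alignment_rdf(path)
    return _read_alignment_tsv(path)


def _read_alignment_rdf(path: Path) -> Alignment:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise AlignmentFormatError(f"{path}: not well-formed XML: {exc}") from exc
    corrs: set[Correspondence] = set()
    for cell in tree.iter(f"{{{ALIGN_NS}}}Cell"):
        e1 = cell.find(f"{{{ALIGN_NS}}}entity1")
        e2 = cell.find(f"{{{ALIGN_NS}}}entity2")
        if e1 is None or e2 is None:
            raise AlignmentFormatError(f"{path}: Cell missing entity1/entity2")
        iri1 = e1.get(f"{{{RDF_NS}}}resource") or (e1.text or "").strip()
        iri2 = e2.get(f"{{{RDF_NS}}}resource") or (e2.text or "").strip()
        rel_el = cell.find(f"{{{ALIGN_NS}}}relation")
        relation = (rel_el.text or "=").strip() if rel_el is not None else "="
        if relation != "=":
            log.warning("skipping non-equivalence cell (%s) in %s", relation, path)
            continue
        meas_el = cell.find(f"{{{ALIGN_NS}}}measure")
        confidence = float(meas_el.text) if meas_el is not None and meas_el.text else 1.0
        corrs.add(Correspondence(_entity_to_id(iri1), _entity_to_id(iri2), confidence))
    return Alignment(corrs)


def _read_alignment_tsv(path: Path) -> Alignment:
    corrs: set[Correspondence] = set()
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#") or line.lower().startswith("id1\t"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise AlignmentFormatError(f"{path}:{lineno}: need id1<TAB>id2[<TAB>confidence]")
        confidence = 1.0
        if len(fields) >= 3:
            try:
                confidence = float(fields[2])
            except ValueError as exc:
                raise AlignmentFormatError(f"{path}:{lineno}: bad confidence {fields[2]!r}") from exc
        corrs.add(Correspondence(fields[0], fields[1], confidence))
    return Alignment(corrs)


def write_alignment(a: Alignment, path: str | Path, fmt: str = "tsv") -> None:
    """Write TSV (default) or OAEI Alignment RDF; both round-trip losslessly."""
    path = Path(path)
    if fmt == "tsv":
        lines = ["id1\tid2\tconfidence"]
        for c in sorted(a.correspondences):
            lines.append(f"{c.id1}\t{c.id2}\t{c.confidence:.6f}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif fmt == "rdf":
        nsmap = {None: ALIGN_NS, "rdf": RDF_NS}
        root = etree.Element(f"{{{RDF_NS}}}RDF", nsmap=nsmap)
        align = etree.SubElement(root, f"{{{ALIGN_NS}}}Alignment")
        etree.SubElement(align, f"{{{ALIGN_NS}}}type").text = "11"
        for c in sorted(a.correspondences):
            mp = etree.SubElement(align, f"{{{ALIGN_NS}}}map")
            cell = etree.SubElement(mp, f"{{{ALIGN_NS}}}Cell")
            etree.SubElement(cell, f"{{{ALIGN_NS}}}entity1").set(f"{{{RDF_NS}}}resource", c.id1)
            etree.SubElement(cell, f"{{{ALIGN_NS}}}entity2").set(f"{{{RDF_NS}}}resource", c.id2)
            etree.SubElement(cell, f"{{{ALIGN_NS}}}measure").text = f"{c.confidence:.6f}"
            etree.SubElement(cell, f"{{{ALIGN_NS}}}relation").text = "="
        etree.ElementTree(root).write(
            str(path), xml_declaration=True, encoding="utf-8", pretty_print=True
        )
    else:
        raise ValueError(f"unknown alignment format {fmt!r} (use 'tsv' or 'rdf')")
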