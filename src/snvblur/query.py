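"""Local query engine over an aggregated store.

Mirrors the search semantics of a variant-sharing database: lookup by
chromosomal position (``chr1:13272``), dbSNP id (``rs6605067``) or gene
symbol (via a user-supplied BED or GFF3 interval file), plus combined
searches mixing term types. Every hit reports carrier / genotype / allele
frequencies over the whole cohort and, for blurred records, the submitter
contact in place of genotypes.

Conventions: allele frequency counts het carriers once and hom-alt carriers
twice over 2n chromosomes; genotype frequencies use all n samples as the
denominator (carrier counts are reported alongside). BED intervals are
0-based half-open, GFF3 intervals 1-based closed, both handled per standard.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from intervaltree import IntervalTree

from .model import FormatError, SnvKey, UsageError
from .store import AggregatedRecord, AggregatedStore

_POSITION_RE = re.compile(r"^([A-Za-z0-9_.]+):(\d+)$")
_RSID_RE = re.compile(r"^rs\d+$")
_SYMBOL_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_.-]*$")


# ---------------------------------------------------------------------------
# gene intervals


class GeneIndex:
    """Symbol -> intervals and position -> symbols, over BED or GFF3 input.

    Internally everything is 0-based half-open; a 1-based VCF position p is
    inside an interval iff p-1 is.
    """

    def __init__(self) -> None:
        self._by_symbol: Dict[str, List[Tuple[str, int, int]]] = {}
        self._trees: Dict[str, IntervalTree] = {}

    def add(self, symbol: str, chrom: str, start0: int, end0: int) -> None:
        if end0 <= start0:
            return
        self._by_symbol.setdefault(symbol, []).append((chrom, start0, end0))
        self._trees.setdefault(chrom, IntervalTree()).addi(start0, end0, symbol)

    def symbols(self) -> List[str]:
        return sorted(self._by_symbol)

    def intervals(self, symbol: str) -> List[Tuple[str, int, int]]:
        return list(self._by_symbol.get(symbol, []))

    def genes_at(self, chrom: str, pos: int) -> List[str]:
        """Gene symbols overlapping a 1-based position."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.at(pos - 1)})

    def contains(self, symbol: str, chrom: str, pos: int) -> bool:
        return any(
            c == chrom and start <= pos - 1 < end
            for c, start, end in self._by_symbol.get(symbol, [])
        )

    @classmethod
    def from_bed(cls, path: str) -> "GeneIndex":
        index = cls()
        with open(path) as fh:
            for line_no, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise FormatError(
                        f"{path}:{line_no}: BED needs >= 4 columns (chrom start end name)"
                    )
                chrom, start, end, name = fields[:4]
                try:
                    index.add(name, chrom, int(start), int(end))
                except ValueError as exc:
                    raise FormatError(f"{path}:{line_no}: bad coordinates") from exc
        return index

    @classmethod
    def from_gff(cls, path: str, feature_types: Sequence[str] = ("gene",)) -> "GeneIndex":
        index = cls()
        attr_keys = ("Name", "gene_name", "gene_id", "ID")
        with open(path) as fh:
            for line_no, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 9:
                    raise FormatError(f"{path}:{line_no}: GFF needs 9 columns")
                chrom, _src, ftype, start, end, _score, _strand, _frame, attrs = fields
                if feature_types and ftype not in feature_types:
                    continue
                parsed = {}
                for item in attrs.split(";"):
                    item = item.strip()
                    if "=" in item:
                        key, value = item.split("=", 1)
                        parsed[key] = value
                symbol = next((parsed[k] for k in attr_keys if k in parsed), None)
                if symbol is None:
                    continue
                try:
                    # GFF3 is 1-based closed -> half-open
                    index.add(symbol, chrom, int(start) - 1, int(end))
                except ValueError as exc:
                    raise FormatError(f"{path}:{line_no}: bad coordinates") from exc
        return index

    @classmethod
    def from_file(cls, path: str) -> "GeneIndex":
        suffix = Path(path).suffix.lower()
        if suffix in (".gff", ".gff3", ".gtf"):
            return cls.from_gff(path)
        return cls.from_bed(path)


# ---------------------------------------------------------------------------
# user-supplied reference frequencies


def read_ref_freqs(path: str) -> Dict[SnvKey, Dict[str, float]]:
    """TSV keyed ``chrom pos ref alt`` + one column per reference panel."""
    table: Dict[SnvKey, Dict[str, float]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["chrom", "pos", "ref", "alt"]:
            raise FormatError(
                f"{path}: reference-frequency TSV must start with "
                "columns chrom, pos, ref, alt"
            )
        panels = header[4:]
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            key = SnvKey(fields[0], int(fields[1]), fields[2].upper(), fields[3].upper())
            table[key] = {
                panel: float(value)
                for panel, value in zip(panels, fields[4:])
                if value not in ("", ".")
            }
    return table


# ---------------------------------------------------------------------------
# results


@dataclass
class QueryHit:
    key: SnvKey
    rsid: Optional[str]
    blurred: bool
    matched_terms: List[str]
    n_samples: int
    carrier_count: int
    carrier_freq: float
    het_count: Optional[int] = None
    hom_count: Optional[int] = None
    het_freq: Optional[float] = None
    hom_freq: Optional[float] = None
    allele_freq: Optional[float] = None
    within_gene: Optional[bool] = None
    genes: List[str] = field(default_factory=list)
    trait_summary: List[Tuple[str, int]] = field(default_factory=list)
    hpo_present: List[str] = field(default_factory=list)
    hpo_absent: List[str] = field(default_factory=list)
    contact: Optional[str] = None
    ref_freqs: Dict[str, float] = field(default_factory=dict)


@dataclass
class QueryResult:
    hits: List[QueryHit] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)

    def keys(self) -> List[SnvKey]:
        return [h.key for h in self.hits]

    def to_json(self) -> str:
        return json.dumps(
            {
                "warnings": self.warnings,
                "hits": [
                    {
                        "locus": str(h.key),
                        "rsid": h.rsid,
                        "blurred": h.blurred,
                        "matched_terms": h.matched_terms,
                        "n_samples": h.n_samples,
                        "carrier_count": h.carrier_count,
                        "carrier_freq": h.carrier_freq,
                        "het_count": h.het_count,
                        "hom_count": h.hom_count,
                        "het_freq": h.het_freq,
                        "hom_freq": h.hom_freq,
                        "allele_freq": h.allele_freq,
                        "within_gene": h.within_gene,
                        "genes": h.genes,
                        "trait_summary": [[t, n] for t, n in h.trait_summary],
                        "hpo_present": h.hpo_present,
                        "hpo_absent": h.hpo_absent,
                        "contact": h.contact,
                        "ref_freqs": h.ref_freqs,
                    }
                    for h in self.hits
                ],
            },
            indent=2,
        )


def _hit_from_record(
    rec: AggregatedRecord,
    store: AggregatedStore,
    term: str,
    genes: Optional[GeneIndex],
    ref_freqs: Optional[Dict[SnvKey, Dict[str, float]]],
) -> QueryHit:
    n = rec.n_samples
    hit = QueryHit(
        key=rec.key,
        rsid=rec.rsid,
        blurred=rec.blurred,
        matched_terms=[term],
        n_samples=n,
        carrier_count=rec.carrier_count,
        carrier_freq=rec.carrier_count / n if n else 0.0,
        trait_summary=list(rec.trait_summary),
        contact=rec.contact,
        ref_freqs=(ref_freqs or {}).get(rec.key, {}),
    )
    if not rec.blurred:
        hit.het_count = rec.het_count
        hit.hom_count = rec.hom_count
        hit.het_freq = rec.het_count / n
        hit.hom_freq = rec.hom_count / n
        hit.allele_freq = (rec.het_count + 2 * rec.hom_count) / (2 * n)
        class_by_id = {c.class_id: c for c in store.classes}
        present, absent = set(), set()
        for token in rec.class_tokens:
            cls = class_by_id.get(token)
            if cls is not None:
                present |= cls.hpo_present
                absent |= cls.hpo_absent
        hit.hpo_present = sorted(present)
        hit.hpo_absent = sorted(absent)
    if genes is not None:
        hit.genes = genes.genes_at(rec.key.chrom, rec.key.pos)
        hit.within_gene = bool(hit.genes)
    return hit


# ---------------------------------------------------------------------------
# queries


def query_position(
    store: AggregatedStore,
    position: str,
    genes: Optional[GeneIndex] = None,
    ref_freqs: Optional[Dict[SnvKey, Dict[str, float]]] = None,
) -> QueryResult:
    """All alts at ``chrom:pos``; an absent locus is an empty result."""
    match = _POSITION_RE.match(position.strip())
    if not match:
        raise UsageError(f"malformed position {position!r} (expected chrom:pos)")
    chrom, pos = match.group(1), int(match.group(2))
    result = QueryResult()
    for rec in store.records:
        if rec.key.chrom == chrom and rec.key.pos == pos:
            result.hits.append(_hit_from_record(rec, store, position, genes, ref_freqs))
    return result


def query_rsid(
    store: AggregatedStore,
    rsid: str,
    genes: Optional[GeneIndex] = None,
    ref_freqs: Optional[Dict[SnvKey, Dict[str, float]]] = None,
) -> QueryResult:
    """Exact match on the VCF ID column; the "." sentinel never matches."""
    result = QueryResult()
    if rsid == ".":
        return result
    for rec in store.records:
        if rec.rsid == rsid:
            result.hits.append(_hit_from_record(rec, store, rsid, genes, ref_freqs))
    return result


def query_gene(
    store: AggregatedStore,
    symbol: str,
    genes: GeneIndex,
    ref_freqs: Optional[Dict[SnvKey, Dict[str, float]]] = None,
) -> QueryResult:
    """All records whose position falls inside any interval of the symbol."""
    result = QueryResult()
    if symbol not in set(genes.symbols()):
        result.warnings.append(f"unknown gene symbol {symbol!r}")
        return result
    for rec in store.records:
        if genes.contains(symbol, rec.key.chrom, rec.key.pos):
            result.hits.append(_hit_from_record(rec, store, symbol, genes, ref_freqs))
    return result


def classify_term(term: str) -> str:
    term = term.strip()
    if _POSITION_RE.match(term):
        return "position"
    if _RSID_RE.match(term):
        return "rsid"
    if _SYMBOL_RE.match(term):
        return "symbol"
    raise UsageError(f"cannot classify search term {term!r}")


def combined_search(
    store: AggregatedStore,
    terms: Sequence[str],
    genes: Optional[GeneIndex] = None,
    ref_freqs: Optional[Dict[SnvKey, Dict[str, float]]] = None,
) -> QueryResult:
    """Union of per-term results, de-duplicated by SNV key.

    Each hit is annotated with every term that matched it. A gene-symbol
    term without an interval file is a usage error.
    """
    result = QueryResult()
    by_key: Dict[SnvKey, QueryHit] = {}
    for term in terms:
        kind = classify_term(term)
        if kind == "position":
            part = query_position(store, term, genes, ref_freqs)
        elif kind == "rsid":
            part = query_rsid(store, term, genes, ref_freqs)
        else:
            if genes is None:
                raise UsageError(
                    f"gene-symbol term {term!r} requires a BED/GFF interval file"
                )
            part = query_gene(store, term, genes, ref_freqs)
        result.warnings.extend(part.warnings)
        for hit in part.hits:
            existing = by_key.get(hit.key)
            if existing is None:
                by_key[hit.key] = hit
            elif term not in existing.matched_terms:
                existing.matched_terms.append(term)
    result.hits = [by_key[k] for k in sorted(by_key, key=lambda k: (k.chrom, k.pos, k.ref, k.alt))]
    return result


# ---------------------------------------------------------------------------
# optional HPO term names


def hpo_term_names(obo_path: str, term_ids: Sequence[str]) -> Dict[str, str]:
    """Map HPO ids to their names using a local OBO file (parsed by obonet)."""
    import obonet

    graph = obonet.read_obo(obo_path)
    return {
        tid: graph.nodes[tid].get("name", "")
        for tid in term_ids
        if tid in graph.nodes
    }
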