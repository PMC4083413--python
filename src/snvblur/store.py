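"""The shareable aggregated store and its public-facing metadata types.

An :class:`AggregatedStore` is what leaves the submitter's site: per-SNV
records that either carry opaque sub-sample genotypes (common variants) or
have been blurred down to locus + trait + submitter contact (rare variants).
Nothing in it may reference a source sample id — phenotype classes are
published only as (class token, HPO sets, member count).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Tuple

from .model import HET, HOM_ALT, SnvKey, ValidationError, snv_sort_key


def format_contact(contact: Tuple[str, str, str]) -> str:
    """(name, affiliation, email) -> single display string."""
    name, affiliation, email = contact
    return f"{name}, {affiliation} <{email}>"


class ReleasedTuple(NamedTuple):
    """The attribute combination actually released for one sample.

    Suppressed / unset optionals appear as the literal string "unknown".
    """

    trait: str
    hpo_present: frozenset
    hpo_absent: frozenset
    gender: str
    platform: str
    enrichment: str


@dataclass(frozen=True)
class PublicClass:
    """Phenotype class as published: token + shared HPO sets + size only."""

    class_id: str
    hpo_present: frozenset
    hpo_absent: frozenset
    n_members: int


ZYG_CODE = {HET: "H", HOM_ALT: "A"}
CODE_ZYG = {v: k for k, v in ZYG_CODE.items()}


@dataclass
class AggregatedRecord:
    """One SNV in the shareable store.

    Invariant: ``blurred`` implies no sub_calls, no het/hom counts and a
    mandatory contact; unblurred implies ``len(sub_calls) == carrier_count``.
    """

    key: SnvKey
    blurred: bool
    carrier_count: int
    n_samples: int
    trait_summary: List[Tuple[str, int]] = field(default_factory=list)
    sub_calls: List[Tuple[str, str]] = field(default_factory=list)  # (sub_id, zygosity)
    class_tokens: List[str] = field(default_factory=list)  # parallel to sub_calls
    het_count: Optional[int] = None
    hom_count: Optional[int] = None
    contact: Optional[str] = None
    rsid: Optional[str] = None

    def validate(self) -> "AggregatedRecord":
        self.key.validate()
        if self.blurred:
            if self.sub_calls or self.class_tokens:
                raise ValidationError(
                    f"{self.key}: blurred record carries sub-sample linkage"
                )
            if self.het_count is not None or self.hom_count is not None:
                raise ValidationError(f"{self.key}: blurred record keeps genotype counts")
            if not self.contact:
                raise ValidationError(f"{self.key}: blurred record lacks contact")
        else:
            if len(self.sub_calls) != self.carrier_count:
                raise ValidationError(
                    f"{self.key}: {len(self.sub_calls)} sub-calls vs "
                    f"carrier_count {self.carrier_count}"
                )
            if len(self.class_tokens) != len(self.sub_calls):
                raise ValidationError(f"{self.key}: class token / sub-call mismatch")
            n_het = sum(1 for _, z in self.sub_calls if z == HET)
            n_hom = sum(1 for _, z in self.sub_calls if z == HOM_ALT)
            if self.het_count != n_het or self.hom_count != n_hom:
                raise ValidationError(f"{self.key}: het/hom counts disagree with calls")
        if not (1 <= self.carrier_count) or self.carrier_count > self.n_samples:
            raise ValidationError(
                f"{self.key}: carrier_count {self.carrier_count} outside 1..{self.n_samples}"
            )
        return self


@dataclass
class AggregatedStore:
    """The shareable result of aggregation plus its cohort-level metadata."""

    records: List[AggregatedRecord] = field(default_factory=list)
    classes: List[PublicClass] = field(default_factory=list)
    released_tuples: List[ReleasedTuple] = field(default_factory=list)
    n_samples: int = 0
    threshold: float = 0.0
    factor: float = 1.5
    config: Dict[str, object] = field(default_factory=dict)

    def sort(self) -> "AggregatedStore":
        self.records.sort(key=lambda r: snv_sort_key(r.key))
        return self

    def record_map(self) -> Dict[SnvKey, AggregatedRecord]:
        return {r.key: r for r in self.records}

    def validate(self) -> "AggregatedStore":
        seen = set()
        prev = None
        for rec in self.records:
            rec.validate()
            if rec.key in seen:
                raise ValidationError(f"duplicate record key {rec.key}")
            seen.add(rec.key)
            k = snv_sort_key(rec.key)
            if prev is not None and k < prev:
                raise ValidationError(f"records unsorted at {rec.key}")
            prev = k
            if rec.n_samples != self.n_samples:
                raise ValidationError(f"{rec.key}: n_samples differs from store")
        return self
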