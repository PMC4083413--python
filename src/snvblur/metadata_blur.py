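"""Metadata ambiguity inspection and suppression (aggregation step 1).

Samples sharing an identical pair of HPO term sets (present, absent) form a
phenotype class. Before release, the combination of attributes published for
any sample — trait, HPO sets, gender, platform, enrichment — must not be
unique: every released combination has to occur for at least ``k`` samples
(k-anonymity, default k=2). Where a combination is too rare, attributes are
suppressed ("unknown") for all members of the offending group, greedily in
the fixed priority order enrichment -> platform -> gender -> HPO sets, so
that clinically informative HPO terms are kept longest. Trait and
patient/control status are never suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

from .model import SampleMeta, ValidationError
from .store import PublicClass, ReleasedTuple

UNKNOWN = "unknown"

# suppression priority: least informative attributes go first
_PRIORITY = ("enrichment", "platform", "gender", "hpo")


@dataclass(frozen=True)
class PhenotypeClass:
    """Submitter-side phenotype class; member ids never leave the site."""

    class_id: str
    member_ids: Tuple[str, ...]
    hpo_present: frozenset
    hpo_absent: frozenset

    def to_public(self) -> PublicClass:
        return PublicClass(
            class_id=self.class_id,
            hpo_present=self.hpo_present,
            hpo_absent=self.hpo_absent,
            n_members=len(self.member_ids),
        )


def build_phenotype_classes(samples: List[SampleMeta]) -> List[PhenotypeClass]:
    """Partition samples by exact equality of their (present, absent) HPO sets.

    Class ordering (and hence class ids) is deterministic: classes are sorted
    by their sorted member-id tuples.
    """
    groups: Dict[Tuple[frozenset, frozenset], List[str]] = {}
    for sample in samples:
        groups.setdefault((sample.hpo_present, sample.hpo_absent), []).append(
            sample.sample_id
        )
    ordered = sorted(groups.items(), key=lambda item: tuple(sorted(item[1])))
    return [
        PhenotypeClass(
            class_id=f"C{idx}",
            member_ids=tuple(sorted(member_ids)),
            hpo_present=hpo_pair[0],
            hpo_absent=hpo_pair[1],
        )
        for idx, (hpo_pair, member_ids) in enumerate(ordered, start=1)
    ]


def released_tuple(sample: SampleMeta) -> ReleasedTuple:
    """Project a sample onto the attribute combination a third party sees."""
    return ReleasedTuple(
        trait=sample.trait,
        hpo_present=sample.hpo_present,
        hpo_absent=sample.hpo_absent,
        gender=sample.gender if sample.gender is not None else UNKNOWN,
        platform=sample.platform if sample.platform is not None else UNKNOWN,
        enrichment=sample.enrichment if sample.enrichment is not None else UNKNOWN,
    )


def _suppressible(sample: SampleMeta, attribute: str) -> bool:
    if attribute == "hpo":
        return bool(sample.hpo_present or sample.hpo_absent)
    return getattr(sample, attribute) is not None


def _suppress(sample: SampleMeta, attribute: str) -> SampleMeta:
    if attribute == "hpo":
        return sample.copy(hpo_present=frozenset(), hpo_absent=frozenset())
    return sample.copy(**{attribute: None})


def suppress_metadata(
    samples: List[SampleMeta], k: int = 2
) -> Tuple[List[SampleMeta], List[dict]]:
    """Suppress attributes until every released combination occurs >= k times.

    Returns the suppressed copies (input order preserved) and a log of
    deletions, one ``{"sample_id", "attribute", "reason"}`` entry each.

    Raises :class:`ValidationError` when the cohort is smaller than ``k`` or
    when ambiguity cannot be reached because trait labels themselves are
    unique (trait is never suppressed).
    """
    if k < 2:
        raise ValidationError(f"k-anonymity parameter must be >= 2, got {k}")
    if len(samples) < k:
        raise ValidationError(
            f"cohort of {len(samples)} samples cannot be released with k={k}"
        )
    current = [s.copy() for s in samples]
    log: List[dict] = []

    while True:
        counts: Dict[ReleasedTuple, int] = {}
        for sample in current:
            tup = released_tuple(sample)
            counts[tup] = counts.get(tup, 0) + 1
        violating = [
            [s for s in current if released_tuple(s) == tup]
            for tup, n in counts.items()
            if n < k
        ]
        if not violating:
            break
        # smallest violating group; ties broken by sorted member ids
        group = min(
            violating, key=lambda g: (len(g), tuple(sorted(s.sample_id for s in g)))
        )
        attribute = next(
            (a for a in _PRIORITY if any(_suppressible(s, a) for s in group)), None
        )
        group_ids = {s.sample_id for s in group}
        multiplicity = len(group)
        if attribute is None:
            # the group is fully suppressed yet still too small: merge it by
            # pulling down samples sharing its trait (suppress their
            # attributes too, same priority order)
            trait = group[0].trait
            mates = [
                s
                for s in current
                if s.trait == trait and s.sample_id not in group_ids
            ]
            attribute = next(
                (a for a in _PRIORITY if any(_suppressible(s, a) for s in mates)),
                None,
            )
            if attribute is None:
                ids = sorted(group_ids)
                raise ValidationError(
                    "k-anonymity unattainable: the trait label of sample(s) "
                    f"{ids} is carried by fewer than k={k} samples and trait "
                    "is never suppressed"
                )
            group_ids = {s.sample_id for s in mates}
        for idx, sample in enumerate(current):
            if sample.sample_id in group_ids and _suppressible(sample, attribute):
                current[idx] = _suppress(sample, attribute)
                log.append(
                    {
                        "sample_id": sample.sample_id,
                        "attribute": attribute,
                        "reason": (
                            f"released combination shared by only {multiplicity} "
                            f"sample(s), need >= {k}"
                        ),
                    }
                )
    return current, log
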