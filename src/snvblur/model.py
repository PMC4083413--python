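"""Shared domain types and exceptions.

The central identity is :class:`SnvKey`, a normalized single-nucleotide
variant locus ``(chrom, pos, ref, alt)`` with 1-based VCF coordinates.
Everything downstream — occurrence counting, fragmentation, blurring,
querying — keys on it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, List, NamedTuple, Optional, Tuple

# zygosity domain: homozygous-reference calls are never stored
HET = "het"
HOM_ALT = "hom_alt"
ZYGOSITIES = (HET, HOM_ALT)

BASES = frozenset("ACGT")

HPO_PATTERN = re.compile(r"^HP:\d{7}$")


class SnvBlurError(Exception):
    """Base class for all package errors."""


class FormatError(SnvBlurError):
    """A file does not conform to its expected format."""


class ValidationError(SnvBlurError):
    """Input content violates a domain invariant (metadata, cohort size...)."""


class AuthenticationError(SnvBlurError):
    """Linkage-file decryption failed: wrong passphrase or tampered data."""


class UsageError(SnvBlurError):
    """Malformed user-supplied query/argument."""


class SnvKey(NamedTuple):
    """A single-nucleotide variant locus; the identity used everywhere."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str

    def validate(self) -> "SnvKey":
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if self.ref not in BASES or self.alt not in BASES:
            raise ValidationError(
                f"ref/alt must be single uppercase bases, got {self.ref!r}/{self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        return self

    def __str__(self) -> str:  # used in linkage JSON and ref-frequency tables
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def from_string(cls, text: str) -> "SnvKey":
        chrom, pos, ref, alt = text.split(":")
        return cls(chrom, int(pos), ref, alt)


_CHROM_RE = re.compile(r"^(chr)?(\d+|[XYM]T?)$", re.IGNORECASE)


def chrom_sort_key(chrom: str) -> Tuple[int, object]:
    """Natural chromosome ordering: chr1 < chr2 < chr10 < chrX < chrY < chrM.

    Unrecognized names sort after the canonical set, lexicographically.
    """
    m = _CHROM_RE.match(chrom)
    if m:
        body = m.group(2).upper()
        if body.isdigit():
            return (0, int(body))
        return (0, {"X": 23, "Y": 24, "M": 25, "MT": 25}[body])
    return (1, chrom)


def snv_sort_key(key: SnvKey) -> Tuple:
    return (chrom_sort_key(key.chrom), key.pos, key.ref, key.alt)


class GenotypeCall(NamedTuple):
    carrier_id: str
    zygosity: str  # HET or HOM_ALT


@dataclass
class SampleMeta:
    """Per-sample phenotype / technology / contact metadata (INI-sourced)."""

    sample_id: str
    status: str  # "patient" or "control"
    trait: str  # mandatory free-text disease description
    hpo_present: frozenset = frozenset()
    hpo_absent: frozenset = frozenset()
    gender: Optional[str] = None  # "male" / "female"
    platform: Optional[str] = None
    enrichment: Optional[str] = None
    pi: Optional[str] = None
    contact: Optional[Tuple[str, str, str]] = None  # (name, affiliation, email)
    contact_release: bool = False
    vcf: Optional[str] = None  # path to this sample's VCF, if recorded in the INI

    def validate(self) -> "SampleMeta":
        if not self.trait or not self.trait.strip():
            raise ValidationError(f"sample {self.sample_id}: trait is mandatory")
        if self.status not in ("patient", "control"):
            raise ValidationError(
                f"sample {self.sample_id}: status must be 'patient' or 'control', "
                f"got {self.status!r}"
            )
        for hpo_id in sorted(self.hpo_present | self.hpo_absent):
            if not HPO_PATTERN.match(hpo_id):
                raise ValidationError(
                    f"sample {self.sample_id}: malformed HPO ID {hpo_id!r} "
                    "(expected HP: followed by 7 digits)"
                )
        overlap = self.hpo_present & self.hpo_absent
        if overlap:
            raise ValidationError(
                f"sample {self.sample_id}: HPO terms both present and absent: "
                f"{sorted(overlap)}"
            )
        if self.gender is not None and self.gender not in ("male", "female"):
            raise ValidationError(
                f"sample {self.sample_id}: gender must be male/female, got {self.gender!r}"
            )
        if self.contact is None:
            raise ValidationError(f"sample {self.sample_id}: contact is mandatory")
        return self

    def copy(self, **changes) -> "SampleMeta":
        return replace(self, **changes)


@dataclass
class SkipStats:
    """Counts of VCF lines/alleles ignored during parsing."""

    indels: int = 0
    symbolic: int = 0
    malformed: int = 0

    def total(self) -> int:
        return self.indels + self.symbolic + self.malformed


@dataclass
class CohortDataset:
    """In-memory cohort: sample ids, per-site carrier calls, optional metadata.

    ``calls`` maps each SNV to ``{carrier_id: zygosity}``; the dict-of-dicts
    shape makes duplicate (site, carrier) pairs unrepresentable and
    homozygous-reference calls are simply never inserted.
    """

    sample_ids: List[str] = field(default_factory=list)
    calls: Dict[SnvKey, Dict[str, str]] = field(default_factory=dict)
    rsids: Dict[SnvKey, str] = field(default_factory=dict)
    skip_stats: SkipStats = field(default_factory=SkipStats)
    meta: Optional[Dict[str, SampleMeta]] = None

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def validate(self) -> "CohortDataset":
        known = set(self.sample_ids)
        for key, carriers in self.calls.items():
            key.validate()
            for carrier_id, zyg in carriers.items():
                if carrier_id not in known:
                    raise ValidationError(
                        f"carrier {carrier_id!r} at {key} not among cohort samples"
                    )
                if zyg not in ZYGOSITIES:
                    raise ValidationError(f"invalid zygosity {zyg!r} at {key}")
        return self

    def sample_calls(self, sample_id: str) -> Dict[SnvKey, str]:
        """All calls of one sample, as SnvKey -> zygosity."""
        return {
            key: carriers[sample_id]
            for key, carriers in self.calls.items()
            if sample_id in carriers
        }

    def merge(self, other: "CohortDataset") -> "CohortDataset":
        """Union of two cohorts; sample id collisions are an error."""
        dup = set(self.sample_ids) & set(other.sample_ids)
        if dup:
            raise ValidationError(f"duplicate sample ids on merge: {sorted(dup)}")
        merged = CohortDataset(
            sample_ids=list(self.sample_ids) + list(other.sample_ids),
            calls={k: dict(v) for k, v in self.calls.items()},
            rsids=dict(self.rsids),
            skip_stats=SkipStats(
                self.skip_stats.indels + other.skip_stats.indels,
                self.skip_stats.symbolic + other.skip_stats.symbolic,
                self.skip_stats.malformed + other.skip_stats.malformed,
            ),
        )
        for key, carriers in other.calls.items():
            merged.calls.setdefault(key, {}).update(carriers)
        merged.rsids.update(other.rsids)
        if self.meta or other.meta:
            merged.meta = {**(self.meta or {}), **(other.meta or {})}
        return merged

    def attach_metadata(self, samples: List[SampleMeta]) -> "CohortDataset":
        by_id = {s.sample_id: s for s in samples}
        missing = [sid for sid in self.sample_ids if sid not in by_id]
        if missing:
            raise ValidationError(f"no metadata for samples: {missing}")
        self.meta = {sid: by_id[sid] for sid in self.sample_ids}
        return self
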