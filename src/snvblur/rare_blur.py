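"""Median-adaptive rare-variant blurring and pipeline orchestration (step 3).

The occurrence count freq(SNV) of a site is the number of cohort samples
carrying at least one alternate allele there, irrespective of genotype. A
variant is *rare* — and its genotype linkage is blurred away — iff

    freq(SNV) <= factor * median(freq)          (factor defaults to 1.5)

The median is used because the typical exome cohort spectrum has a heavy
singleton excess that would drag any mean-based threshold down. Blurring
replaces the sub-sample genotype list of a rare SNV with the submitting
institution's contact string; locus, alleles and trait summary remain.

:func:`aggregate` wires the three steps — metadata suppression,
fragmentation, blurring — into the shareable :class:`AggregatedStore` plus
the encrypted linkage file; :func:`remove_sample` supports consent
withdrawal using that linkage file.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .fragmentation import (
    FragmentationConfig,
    LinkageRecord,
    SubSample,
    decrypt_linkage,
    encrypt_linkage,
    fragment_sample,
)
from .metadata_blur import (
    PhenotypeClass,
    build_phenotype_classes,
    released_tuple,
    suppress_metadata,
)
from .model import (
    HET,
    HOM_ALT,
    CohortDataset,
    SampleMeta,
    SnvKey,
    ValidationError,
    snv_sort_key,
)
from .store import AggregatedRecord, AggregatedStore, format_contact


@dataclass
class FrequencyTable:
    """Occurrence count per SNV: distinct carrier samples, genotype-blind."""

    counts: Dict[SnvKey, int]
    n_samples: int

    def validate(self) -> "FrequencyTable":
        for key, k in self.counts.items():
            if not 1 <= k <= self.n_samples:
                raise ValidationError(
                    f"{key}: occurrence count {k} outside 1..{self.n_samples}"
                )
        return self


@dataclass
class ThresholdConfig:
    factor: float = 1.5
    strict: bool = False  # rare iff k < threshold instead of k <= threshold

    def validate(self) -> "ThresholdConfig":
        if self.factor <= 0:
            raise ValidationError(f"threshold factor must be > 0, got {self.factor}")
        return self


def occurrence_counts(dataset: CohortDataset) -> FrequencyTable:
    """freq(SNV) for every site: het and hom-alt carriers each count once."""
    if not dataset.sample_ids:
        raise ValidationError("empty cohort")
    return FrequencyTable(
        counts={key: len(carriers) for key, carriers in dataset.calls.items()},
        n_samples=dataset.n_samples,
    )


def threshold_from_counts(counts: Sequence[int], factor: float = 1.5) -> float:
    """factor x median of a count multiset (even length: mean of middle two)."""
    arr = np.asarray(counts)
    if arr.size == 0:
        raise ValidationError("cannot take the median of an empty frequency table")
    return float(factor * np.median(arr))


def rare_threshold(table: FrequencyTable, config: ThresholdConfig = None) -> float:
    config = (config or ThresholdConfig()).validate()
    return threshold_from_counts(list(table.counts.values()), config.factor)


def is_rare(count: int, threshold: float, strict: bool = False) -> bool:
    return count < threshold if strict else count <= threshold


def consequence_rank(label: str) -> int:
    """Damage rank of a coding-consequence label, 1 = most damaging.

    nonsense(1) > readthrough(2) > start-lost(3) > splice site(4) >
    missense(5) > synonymous(6); anything unrecognized ranks 7.
    """
    normalized = " ".join(str(label).lower().replace("-", " ").replace("_", " ").split())
    ranks = {
        "nonsense": 1,
        "readthrough": 2,
        "start lost": 3,
        "splice site": 4,
        "missense": 5,
        "synonymous": 6,
    }
    return ranks.get(normalized, 7)


# ---------------------------------------------------------------------------
# store assembly


def blur_rare(
    dataset: CohortDataset,
    fragments: Dict[str, List[SubSample]],
    classes: List[PhenotypeClass],
    table: FrequencyTable,
    threshold: float,
    contact: str,
    contact_release: bool = False,
    threshold_config: Optional[ThresholdConfig] = None,
) -> AggregatedStore:
    """Assemble the shareable store, blurring every rare SNV.

    For counts k <= threshold the record loses sub-sample linkage and
    genotype counts, keeping locus, trait summary and the contact string;
    otherwise sub-sample genotypes (with phenotype-class tokens) are kept.
    """
    strict = bool(threshold_config and threshold_config.strict)
    meta = dataset.meta or {}
    class_of = {
        member: cls.class_id for cls in classes for member in cls.member_ids
    }
    # key -> [(sub_id, zygosity, class_token)]
    sub_entries: Dict[SnvKey, List[Tuple[str, str, str]]] = {}
    for sample_id, subs in fragments.items():
        token = class_of.get(sample_id, "")
        for sub in subs:
            for key, zyg in sub.calls.items():
                sub_entries.setdefault(key, []).append((sub.sub_id, zyg, token))

    records = []
    for key, carriers in dataset.calls.items():
        k = table.counts[key]
        traits = Counter(
            meta[c].trait if c in meta else "unknown" for c in carriers
        )
        summary = sorted(traits.items())
        rsid = dataset.rsids.get(key)
        if is_rare(k, threshold, strict):
            records.append(
                AggregatedRecord(
                    key=key,
                    blurred=True,
                    carrier_count=k,
                    n_samples=dataset.n_samples,
                    trait_summary=summary,
                    contact=contact,
                    rsid=rsid,
                )
            )
        else:
            entries = sorted(sub_entries.get(key, []))  # sub_id order: unlinkable
            records.append(
                AggregatedRecord(
                    key=key,
                    blurred=False,
                    carrier_count=k,
                    n_samples=dataset.n_samples,
                    trait_summary=summary,
                    sub_calls=[(sid, zyg) for sid, zyg, _ in entries],
                    class_tokens=[token for _, _, token in entries],
                    het_count=sum(1 for z in carriers.values() if z == HET),
                    hom_count=sum(1 for z in carriers.values() if z == HOM_ALT),
                    contact=contact if contact_release else None,
                    rsid=rsid,
                )
            )
    store = AggregatedStore(
        records=records,
        classes=[c.to_public() for c in classes],
        n_samples=dataset.n_samples,
        threshold=threshold,
    )
    return store.sort()


# ---------------------------------------------------------------------------
# end-to-end aggregation


@dataclass
class AggregateConfig:
    """Everything the pipeline needs besides the data itself.

    ``seed`` is mandatory: all randomness (fragment weights, sub-sample ids,
    linkage-file salt/nonce) flows from it, so a published store can be
    reproduced byte-for-byte and audited.
    """

    seed: int
    passphrase: str
    factor: float = 1.5
    strict_threshold: bool = False
    n_subsamples: int = 5
    weight_law: str = "flat-simplex"
    k_anonymity: int = 2

    def validate(self) -> "AggregateConfig":
        if self.seed is None:
            raise ValidationError("an explicit RNG seed is required")
        if not self.passphrase:
            raise ValidationError("a non-empty linkage passphrase is required")
        ThresholdConfig(self.factor, self.strict_threshold).validate()
        FragmentationConfig(self.n_subsamples, self.weight_law).validate()
        return self

    def echo(self) -> dict:
        return {
            "seed": int(self.seed),
            "factor": self.factor,
            "strict_threshold": self.strict_threshold,
            "n_subsamples": self.n_subsamples,
            "weight_law": self.weight_law,
            "k_anonymity": self.k_anonymity,
        }


def _per_sample_calls(dataset: CohortDataset) -> Dict[str, Dict[SnvKey, str]]:
    out: Dict[str, Dict[SnvKey, str]] = {sid: {} for sid in dataset.sample_ids}
    for key, carriers in dataset.calls.items():
        for sample_id, zyg in carriers.items():
            out[sample_id][key] = zyg
    return out


def aggregate_dataset(
    dataset: CohortDataset, config: AggregateConfig
) -> Tuple[AggregatedStore, bytes, List[dict]]:
    """Run steps 1-3 on an in-memory cohort (metadata must be attached).

    Returns (store, encrypted linkage bytes, suppression log). The store
    never references a sample id; the linkage file alone can relink.
    """
    config.validate()
    if dataset.meta is None:
        raise ValidationError("cohort has no metadata attached")
    dataset.validate()
    metas = [dataset.meta[sid] for sid in dataset.sample_ids]

    suppressed, log = suppress_metadata(metas, k=config.k_anonymity)
    classes = build_phenotype_classes(suppressed)
    suppressed_by_id = {s.sample_id: s for s in suppressed}
    dataset = replace(dataset, meta=suppressed_by_id)

    rng = np.random.default_rng(config.seed)
    frag_config = FragmentationConfig(config.n_subsamples, config.weight_law)
    per_sample = _per_sample_calls(dataset)
    fragments: Dict[str, List[SubSample]] = {}
    for sample_id in dataset.sample_ids:
        fragments[sample_id] = fragment_sample(per_sample[sample_id], frag_config, rng)

    table = occurrence_counts(dataset)
    threshold_config = ThresholdConfig(config.factor, config.strict_threshold)
    threshold = rare_threshold(table, threshold_config)

    contact = format_contact(metas[0].contact)
    contact_release = metas[0].contact_release
    store = blur_rare(
        dataset,
        fragments,
        classes,
        table,
        threshold,
        contact,
        contact_release,
        threshold_config,
    )
    store.factor = config.factor
    store.config = config.echo()
    store.released_tuples = sorted(
        (released_tuple(s) for s in suppressed),
        key=lambda t: (t.trait, sorted(t.hpo_present), sorted(t.hpo_absent), t.gender, t.platform, t.enrichment),
    )
    store.validate()

    class_of = {m: c.class_id for c in classes for m in c.member_ids}
    linkage = [
        LinkageRecord(
            sample_id=sid,
            sub_ids=[s.sub_id for s in fragments[sid]],
            calls=per_sample[sid],
            trait=suppressed_by_id[sid].trait,
            class_id=class_of[sid],
            released=tuple(released_tuple(suppressed_by_id[sid])),
        )
        for sid in dataset.sample_ids
    ]
    ciphertext = encrypt_linkage(linkage, config.passphrase, rng=rng)
    return store, ciphertext, log


def aggregate(
    vcf_paths: Iterable[str],
    ini_path: str,
    config: AggregateConfig,
) -> Tuple[AggregatedStore, bytes, List[dict]]:
    """File-level entry point: per-sample VCFs + metadata INI -> store + linkage.

    Each VCF either names its sample in its own column header or, for
    single-sample files listed in the INI's ``vcf`` keys, is matched by path.
    """
    from .vcf_io import read_ini, read_vcf  # deferred: avoids import cycle

    samples = read_ini(ini_path)
    by_vcf = {s.vcf: s.sample_id for s in samples if s.vcf}
    dataset: Optional[CohortDataset] = None
    for path in vcf_paths:
        override = by_vcf.get(str(path))
        part = read_vcf(path, sample_id_override=override)
        dataset = part if dataset is None else dataset.merge(part)
    if dataset is None:
        raise ValidationError("no VCF files supplied")
    dataset.attach_metadata(samples)
    return aggregate_dataset(dataset, config)


# ---------------------------------------------------------------------------
# consent withdrawal


def remove_sample(
    store: AggregatedStore,
    linkage_bytes: bytes,
    passphrase: str,
    sample_id: str,
) -> AggregatedStore:
    """Delete one sample from a store using the submitter's linkage file.

    Carrier / genotype / trait counts are decremented for every site the
    sample carried (blurred records included — the public store alone could
    not do this); records left with zero carriers are dropped. The rare
    threshold is deliberately NOT recomputed: re-thresholding could only
    unblur records whose linkage no longer exists.
    """
    linkage = decrypt_linkage(linkage_bytes, passphrase)
    record = next((r for r in linkage if r.sample_id == sample_id), None)
    if record is None:
        raise ValidationError(f"sample {sample_id!r} not present in linkage file")
    own_subs = set(record.sub_ids)

    new_records = []
    for rec in store.records:
        if rec.key not in record.calls:
            new_records.append(replace(rec, n_samples=rec.n_samples - 1))
            continue
        carrier_count = rec.carrier_count - 1
        if carrier_count == 0:
            continue
        summary = [
            (label, n - 1 if label == record.trait else n)
            for label, n in rec.trait_summary
        ]
        summary = [(label, n) for label, n in summary if n > 0]
        if rec.blurred:
            new_records.append(
                replace(
                    rec,
                    carrier_count=carrier_count,
                    n_samples=rec.n_samples - 1,
                    trait_summary=summary,
                )
            )
        else:
            zyg = record.calls[rec.key]
            kept = [
                (pair, token)
                for pair, token in zip(rec.sub_calls, rec.class_tokens)
                if pair[0] not in own_subs
            ]
            new_records.append(
                replace(
                    rec,
                    carrier_count=carrier_count,
                    n_samples=rec.n_samples - 1,
                    trait_summary=summary,
                    sub_calls=[pair for pair, _ in kept],
                    class_tokens=[token for _, token in kept],
                    het_count=rec.het_count - (1 if zyg == HET else 0),
                    hom_count=rec.hom_count - (1 if zyg == HOM_ALT else 0),
                )
            )

    classes = []
    for cls in store.classes:
        n = cls.n_members - (1 if cls.class_id == record.class_id else 0)
        if n > 0:
            classes.append(replace(cls, n_members=n))
    released = list(store.released_tuples)
    if record.released is not None:
        from .store import ReleasedTuple

        target = ReleasedTuple(*record.released)
        if target in released:
            released.remove(target)

    new_store = AggregatedStore(
        records=new_records,
        classes=classes,
        released_tuples=released,
        n_samples=store.n_samples - 1,
        threshold=store.threshold,  # frozen by design
        factor=store.factor,
        config={**store.config, "withdrawn_samples": int(store.config.get("withdrawn_samples", 0)) + 1},
    )
    return new_store.sort()
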