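"""VCF and INI input, and the aggregated-VCF dialect (write / read / validate).

Input genotypes come from standard VCF 4.x files (plain or bgzipped), parsed
with cyvcf2. Only single-nucleotide substitutions are kept: indels, symbolic
alleles and spanning deletions are skipped and counted, never an error.

The aggregated output is a sites-only VCF 4.2 in which all genotype
information lives in ``GB*`` INFO keys declared in the header:

================  =============================================================
GBBLUR=1          record is blurred (rare variant; no genotype linkage remains)
GBN               total samples in the aggregated set
GBCAR             carrier count (samples with >= 1 alt allele)
GBHET / GBHOM     genotype counts (unblurred records only)
GBSUBS            comma list ``sub_id|H`` (het) / ``sub_id|A`` (hom-alt)
GBCLASS           phenotype-class token per sub-call, parallel to GBSUBS
GBTRAIT           comma list ``label|n`` — trait labels with carrier counts
GBCONTACT         percent-encoded submitter contact string
================  =============================================================

Cohort-level metadata (phenotype classes, released tuples, threshold, config
echo) is carried in a single percent-encoded JSON header line so that
``read_aggregated_vcf(write_aggregated_vcf(s)) == s`` field-exact.
"""

from __future__ import annotations

import configparser
import gzip
import json
import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from cyvcf2 import VCF

from .model import (
    BASES,
    HET,
    HOM_ALT,
    CohortDataset,
    FormatError,
    SampleMeta,
    SkipStats,
    SnvKey,
    ValidationError,
    snv_sort_key,
)
from .store import (
    CODE_ZYG,
    ZYG_CODE,
    AggregatedRecord,
    AggregatedStore,
    PublicClass,
    ReleasedTuple,
)

DIALECT_VERSION = "1.0"
_DIALECT_LINE = "##snvblur_dialect="
_META_LINE = "##snvblur_meta="

_INFO_HEADERS = [
    '##INFO=<ID=GBBLUR,Number=1,Type=Integer,Description="1 if the record is blurred (rare variant; genotype linkage removed)">',
    '##INFO=<ID=GBN,Number=1,Type=Integer,Description="Total number of samples in the aggregated set">',
    '##INFO=<ID=GBCAR,Number=1,Type=Integer,Description="Number of carrier samples (>=1 alt allele, irrespective of genotype)">',
    '##INFO=<ID=GBHET,Number=1,Type=Integer,Description="Heterozygous carrier count">',
    '##INFO=<ID=GBHOM,Number=1,Type=Integer,Description="Homozygous-alt carrier count">',
    '##INFO=<ID=GBSUBS,Number=.,Type=String,Description="Sub-sample genotypes as sub_id|H (het) or sub_id|A (hom-alt)">',
    '##INFO=<ID=GBCLASS,Number=.,Type=String,Description="Phenotype-class token per sub-call, parallel to GBSUBS">',
    '##INFO=<ID=GBTRAIT,Number=.,Type=String,Description="Trait labels with carrier counts, percent-encoded label|n">',
    '##INFO=<ID=GBCONTACT,Number=1,Type=String,Description="Percent-encoded submitter contact">',
]


# ---------------------------------------------------------------------------
# input VCF


def _header_lines(path: str) -> List[str]:
    opener = open
    with open(path, "rb") as fh:
        if fh.read(2) == b"\x1f\x8b":
            opener = gzip.open
    lines = []
    with opener(path, "rt") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            lines.append(line.rstrip("\n"))
    return lines


def read_vcf(path: str, sample_id_override: Optional[str] = None) -> CohortDataset:
    """Parse a VCF into a :class:`CohortDataset` of SNV carrier calls.

    One call is emitted per sample x site with at least one alt allele
    (zygosity ``het`` or ``hom_alt``); multi-allelic lines are split into one
    :class:`SnvKey` per SNV alt; non-SNV alleles are skipped and counted in
    ``skip_stats``. Phased separators are treated as unphased.
    """
    path = str(path)
    if not Path(path).exists():
        raise FormatError(f"no such VCF file: {path}")
    header = _header_lines(path)
    if not any(line.startswith("#CHROM") for line in header):
        raise FormatError(f"{path}: missing #CHROM header line")

    reader = VCF(path, gts012=False)
    samples = list(reader.samples)
    if sample_id_override is not None:
        if len(samples) != 1:
            raise ValidationError(
                "sample_id_override requires exactly one sample column, "
                f"found {len(samples)}"
            )
        samples = [sample_id_override]

    dataset = CohortDataset(sample_ids=samples)
    stats = dataset.skip_stats
    for variant in reader:
        ref = (variant.REF or "").upper()
        alts = [a.upper() for a in (variant.ALT or [])]
        if samples and "GT" not in (variant.FORMAT or []):
            raise FormatError(
                f"{path}: GT absent in FORMAT at {variant.CHROM}:{variant.POS}"
            )
        genotypes = variant.genotypes if samples else []
        for alt_index, alt in enumerate(alts, start=1):
            if alt.startswith("<") or alt == "*":
                stats.symbolic += 1
                continue
            if len(ref) != 1 or len(alt) != 1:
                stats.indels += 1
                continue
            if ref not in BASES or alt not in BASES or ref == alt:
                stats.malformed += 1
                continue
            key = SnvKey(variant.CHROM, int(variant.POS), ref, alt)
            for sample, geno in zip(samples, genotypes):
                alleles = [a for a in geno[:-1] if a >= 0]
                if alt_index not in alleles:
                    continue  # hom-ref, missing, or carries another alt only
                if all(a == alt_index for a in alleles):
                    zygosity = HOM_ALT
                else:
                    zygosity = HET
                dataset.calls.setdefault(key, {})[sample] = zygosity
            rsid = variant.ID
            if rsid and rsid != ".":
                dataset.rsids[key] = rsid
            if key in dataset.calls and not dataset.calls[key]:
                del dataset.calls[key]
    reader.close()
    # sites where no sample carried the alt leave no entry at all
    dataset.calls = {k: v for k, v in dataset.calls.items() if v}
    dataset.rsids = {k: v for k, v in dataset.rsids.items() if k in dataset.calls}
    return dataset


# ---------------------------------------------------------------------------
# INI metadata

_GLOBAL_KEYS = (
    "trait",
    "status",
    "gender",
    "platform",
    "enrichment",
    "pi",
    "contact_name",
    "contact_affiliation",
    "contact_email",
    "contact_release",
)
_SAMPLE_KEYS = _GLOBAL_KEYS + ("vcf", "hpo_present", "hpo_absent")


def _parse_hpo(raw: str) -> frozenset:
    return frozenset(t.strip() for t in raw.split(";") if t.strip())


def read_ini(path: str) -> List[SampleMeta]:
    """Read the sample-metadata INI: a [global] section of defaults plus one
    [sample:<ID>] section per sample; sample keys override globals."""
    parser = configparser.ConfigParser(interpolation=None)
    try:
        with open(path) as fh:
            parser.read_file(fh)
    except OSError as exc:
        raise FormatError(f"cannot read INI {path}: {exc}") from exc
    except configparser.Error as exc:
        raise FormatError(f"malformed INI {path}: {exc}") from exc

    defaults = dict(parser["global"]) if parser.has_section("global") else {}
    samples: List[SampleMeta] = []
    for section in parser.sections():
        if not section.startswith("sample:"):
            continue
        sample_id = section[len("sample:"):]
        merged = {**defaults, **dict(parser[section])}
        contact = None
        if any(merged.get(k) for k in ("contact_name", "contact_affiliation", "contact_email")):
            contact = (
                merged.get("contact_name", ""),
                merged.get("contact_affiliation", ""),
                merged.get("contact_email", ""),
            )
        meta = SampleMeta(
            sample_id=sample_id,
            status=merged.get("status", ""),
            trait=merged.get("trait", ""),
            hpo_present=_parse_hpo(merged.get("hpo_present", "")),
            hpo_absent=_parse_hpo(merged.get("hpo_absent", "")),
            gender=merged.get("gender") or None,
            platform=merged.get("platform") or None,
            enrichment=merged.get("enrichment") or None,
            pi=merged.get("pi") or None,
            contact=contact,
            contact_release=str(merged.get("contact_release", "false")).lower()
            in ("1", "true", "yes"),
            vcf=merged.get("vcf") or None,
        )
        meta.validate()
        samples.append(meta)
    if not samples:
        raise ValidationError(f"{path}: no [sample:<ID>] sections found")
    return samples


def write_ini(samples: List[SampleMeta], path: str) -> None:
    """Write metadata so that ``read_ini(write_ini(x)) == x`` (order kept)."""
    parser = configparser.ConfigParser(interpolation=None)
    parser.add_section("global")
    for meta in samples:
        meta.validate()
        section = f"sample:{meta.sample_id}"
        parser.add_section(section)
        parser.set(section, "status", meta.status)
        parser.set(section, "trait", meta.trait)
        if meta.hpo_present:
            parser.set(section, "hpo_present", ";".join(sorted(meta.hpo_present)))
        if meta.hpo_absent:
            parser.set(section, "hpo_absent", ";".join(sorted(meta.hpo_absent)))
        for attr in ("gender", "platform", "enrichment", "pi", "vcf"):
            value = getattr(meta, attr)
            if value is not None:
                parser.set(section, attr, value)
        name, affiliation, email = meta.contact
        parser.set(section, "contact_name", name)
        parser.set(section, "contact_affiliation", affiliation)
        parser.set(section, "contact_email", email)
        parser.set(section, "contact_release", "true" if meta.contact_release else "false")
    with open(path, "w") as fh:
        parser.write(fh)


# ---------------------------------------------------------------------------
# aggregated-VCF dialect


def _quote(text: str) -> str:
    return urllib.parse.quote(text, safe="")


def _unquote(text: str) -> str:
    return urllib.parse.unquote(text)


def _meta_payload(store: AggregatedStore) -> str:
    payload = {
        "n_samples": store.n_samples,
        "threshold": store.threshold,
        "factor": store.factor,
        "config": store.config,
        "classes": [
            {
                "id": c.class_id,
                "hpo_present": sorted(c.hpo_present),
                "hpo_absent": sorted(c.hpo_absent),
                "n": c.n_members,
            }
            for c in store.classes
        ],
        "released_tuples": [
            [t.trait, sorted(t.hpo_present), sorted(t.hpo_absent), t.gender, t.platform, t.enrichment]
            for t in store.released_tuples
        ],
    }
    return _quote(json.dumps(payload, sort_keys=True))


def _record_info(rec: AggregatedRecord) -> str:
    parts = []
    if rec.blurred:
        parts.append("GBBLUR=1")
    parts.append(f"GBN={rec.n_samples}")
    parts.append(f"GBCAR={rec.carrier_count}")
    if not rec.blurred:
        parts.append(f"GBHET={rec.het_count}")
        parts.append(f"GBHOM={rec.hom_count}")
    if rec.trait_summary:
        parts.append(
            "GBTRAIT=" + ",".join(f"{_quote(label)}|{n}" for label, n in rec.trait_summary)
        )
    if not rec.blurred:
        parts.append(
            "GBSUBS=" + ",".join(f"{sid}|{ZYG_CODE[zyg]}" for sid, zyg in rec.sub_calls)
        )
        if rec.class_tokens:
            parts.append("GBCLASS=" + ",".join(rec.class_tokens))
    if rec.contact is not None:
        parts.append(f"GBCONTACT={_quote(rec.contact)}")
    return ";".join(parts)


def write_aggregated_vcf(store: AggregatedStore, path: str) -> None:
    """Serialize a validated store to the sites-only aggregated-VCF dialect."""
    store.sort().validate()
    lines = [
        "##fileformat=VCFv4.2",
        "##source=snvblur",
        f"{_DIALECT_LINE}{DIALECT_VERSION}",
        f"{_META_LINE}{_meta_payload(store)}",
        *_INFO_HEADERS,
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for rec in store.records:
        lines.append(
            "\t".join(
                [
                    rec.key.chrom,
                    str(rec.key.pos),
                    rec.rsid or ".",
                    rec.key.ref,
                    rec.key.alt,
                    ".",
                    ".",
                    _record_info(rec),
                ]
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_info(info: str) -> Dict[str, str]:
    out = {}
    for token in info.split(";"):
        if not token:
            continue
        if "=" in token:
            key, value = token.split("=", 1)
            out[key] = value
        else:
            out[token] = ""
    return out


def _record_from_line(line: str, line_no: int) -> AggregatedRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 8:
        raise FormatError(f"line {line_no}: expected 8 columns, got {len(fields)}")
    chrom, pos, rsid, ref, alt, _qual, _filt, info_raw = fields
    try:
        key = SnvKey(chrom, int(pos), ref, alt).validate()
    except (ValueError, ValidationError) as exc:
        raise FormatError(f"line {line_no}: bad locus: {exc}") from exc
    info = _parse_info(info_raw)
    blurred = info.get("GBBLUR") == "1"
    try:
        carrier_count = int(info["GBCAR"])
        n_samples = int(info["GBN"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"line {line_no}: missing/invalid GBN or GBCAR") from exc
    trait_summary: List[Tuple[str, int]] = []
    if "GBTRAIT" in info and info["GBTRAIT"]:
        for item in info["GBTRAIT"].split(","):
            label, _, n = item.rpartition("|")
            trait_summary.append((_unquote(label), int(n)))
    sub_calls: List[Tuple[str, str]] = []
    if "GBSUBS" in info and info["GBSUBS"]:
        for item in info["GBSUBS"].split(","):
            sid, _, code = item.rpartition("|")
            if code not in CODE_ZYG:
                raise FormatError(f"line {line_no}: bad zygosity code {code!r}")
            sub_calls.append((sid, CODE_ZYG[code]))
    class_tokens = (
        info["GBCLASS"].split(",") if info.get("GBCLASS") else []
    )
    het = int(info["GBHET"]) if "GBHET" in info else None
    hom = int(info["GBHOM"]) if "GBHOM" in info else None
    contact = _unquote(info["GBCONTACT"]) if "GBCONTACT" in info else None
    return AggregatedRecord(
        key=key,
        blurred=blurred,
        carrier_count=carrier_count,
        n_samples=n_samples,
        trait_summary=trait_summary,
        sub_calls=sub_calls,
        class_tokens=class_tokens,
        het_count=het,
        hom_count=hom,
        contact=contact,
        rsid=None if rsid == "." else rsid,
    )


def read_aggregated_vcf(path: str) -> AggregatedStore:
    """Inverse of :func:`write_aggregated_vcf` (field-exact round trip)."""
    meta_raw = None
    records = []
    seen_dialect = False
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(_DIALECT_LINE):
                seen_dialect = True
                continue
            if line.startswith(_META_LINE):
                meta_raw = line[len(_META_LINE):]
                continue
            if line.startswith("#"):
                continue
            records.append(_record_from_line(line, line_no))
    if not seen_dialect or meta_raw is None:
        raise FormatError(f"{path}: missing aggregated-VCF dialect meta-lines")
    payload = json.loads(_unquote(meta_raw))
    store = AggregatedStore(
        records=records,
        classes=[
            PublicClass(
                class_id=c["id"],
                hpo_present=frozenset(c["hpo_present"]),
                hpo_absent=frozenset(c["hpo_absent"]),
                n_members=c["n"],
            )
            for c in payload["classes"]
        ],
        released_tuples=[
            ReleasedTuple(t[0], frozenset(t[1]), frozenset(t[2]), t[3], t[4], t[5])
            for t in payload["released_tuples"]
        ],
        n_samples=payload["n_samples"],
        threshold=payload["threshold"],
        factor=payload["factor"],
        config=payload["config"],
    )
    return store


# ---------------------------------------------------------------------------
# validation


@dataclass
class Violation:
    line: int  # 0 for file-level problems
    kind: str
    message: str


@dataclass
class ValidationReport:
    path: str
    violations: List[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, line: int, kind: str, message: str) -> None:
        self.violations.append(Violation(line, kind, message))

    def to_json(self) -> str:
        return json.dumps(
            {
                "path": self.path,
                "ok": self.ok,
                "violations": [
                    {"line": v.line, "kind": v.kind, "message": v.message}
                    for v in self.violations
                ],
            },
            indent=2,
        )

    def __str__(self) -> str:
        if self.ok:
            return f"{self.path}: OK (0 violations)"
        lines = [f"{self.path}: {len(self.violations)} violation(s)"]
        lines += [f"  line {v.line}: [{v.kind}] {v.message}" for v in self.violations]
        return "\n".join(lines)


def validate_aggregated_vcf(path: str) -> ValidationReport:
    """Consistency / corruption check of an aggregated VCF.

    All problems are report entries, never exceptions; the report is empty
    iff the file is dialect-conformant.
    """
    report = ValidationReport(path=str(path))
    try:
        with open(path) as fh:
            lines = fh.read().splitlines()
    except OSError as exc:
        report.add(0, "io-error", str(exc))
        return report

    if not any(l.startswith(_DIALECT_LINE) for l in lines):
        report.add(0, "missing-meta", "no dialect version meta-line")
    if not any(l.startswith(_META_LINE) for l in lines):
        report.add(0, "missing-meta", "no cohort metadata meta-line")
    if not any(l.startswith("#CHROM") for l in lines):
        report.add(0, "missing-meta", "no #CHROM column header")

    seen_keys = set()
    prev_key = None
    for line_no, line in enumerate(lines, start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 8:
            report.add(line_no, "malformed-line", f"expected 8 columns, got {len(fields)}")
            continue
        chrom, pos_raw, _rsid, ref, alt, _qual, _filt, info_raw = fields
        try:
            pos = int(pos_raw)
        except ValueError:
            report.add(line_no, "malformed-line", f"non-integer position {pos_raw!r}")
            continue
        if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES or ref == alt:
            report.add(line_no, "malformed-line", f"not an SNV: {ref}>{alt}")
            continue
        key = SnvKey(chrom, pos, ref, alt)
        if key in seen_keys:
            report.add(line_no, "duplicate-key", f"duplicate record for {key}")
        seen_keys.add(key)
        sort_key = snv_sort_key(key)
        if prev_key is not None and sort_key < prev_key:
            report.add(line_no, "unsorted", f"record {key} out of order")
        prev_key = sort_key

        info = _parse_info(info_raw)
        blurred = info.get("GBBLUR") == "1"
        if "GBN" not in info or "GBCAR" not in info:
            report.add(line_no, "malformed-line", "missing GBN or GBCAR")
            continue
        try:
            carriers = int(info["GBCAR"])
        except ValueError:
            report.add(line_no, "malformed-line", f"non-integer GBCAR {info['GBCAR']!r}")
            continue
        subs = [t for t in info.get("GBSUBS", "").split(",") if t]
        classes = [t for t in info.get("GBCLASS", "").split(",") if t]
        if blurred:
            if subs or classes:
                report.add(
                    line_no,
                    "blurred-with-linkage",
                    "blurred record still carries sub-sample identifiers",
                )
            if "GBHET" in info or "GBHOM" in info:
                report.add(
                    line_no,
                    "blurred-with-genotypes",
                    "blurred record still carries genotype counts",
                )
            if "GBCONTACT" not in info:
                report.add(line_no, "missing-contact", "blurred record without GBCONTACT")
        else:
            if len(subs) != carriers:
                report.add(
                    line_no,
                    "count-mismatch",
                    f"GBCAR={carriers} but {len(subs)} genotypes listed",
                )
            if classes and len(classes) != len(subs):
                report.add(
                    line_no,
                    "count-mismatch",
                    f"{len(classes)} class tokens for {len(subs)} sub-calls",
                )
            het = info.get("GBHET")
            hom = info.get("GBHOM")
            if het is None or hom is None:
                report.add(line_no, "count-mismatch", "unblurred record without GBHET/GBHOM")
            else:
                try:
                    if int(het) + int(hom) != carriers:
                        report.add(
                            line_no,
                            "count-mismatch",
                            f"GBHET+GBHOM != GBCAR ({het}+{hom} != {carriers})",
                        )
                except ValueError:
                    report.add(line_no, "malformed-line", "non-integer GBHET/GBHOM")
    return report
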