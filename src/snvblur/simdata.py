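"""Synthetic exome-cohort generator.

Emulates the statistical structure of a resequencing cohort of ~50 exomes
with ~40,000-45,000 SNVs each: the occurrence-count spectrum is a
two-component mixture of a power-law low-frequency component (strong
singleton excess) and a uniform high-frequency "common" component,

    f(k) = (1 - w) * k^-alpha / Z  +  w * U{ceil((1-band)*n) .. n},   k in 1..n

With the defaults (alpha=1, w=0.10, band=0.10) at n=50 this yields
f(1) ~ 0.200 and f(50) ~ 0.0207, i.e. roughly ten singleton sites for every
site shared by the whole cohort, a count-multiset median of 7, and therefore
a default rare threshold of 1.5 x 7 = 10.5 — so the largest count still
classified rare is 10, about 20% of samples.

Carriers per site are exchangeable: chosen uniformly without replacement.
There is no linkage disequilibrium and no per-sample mutation-rate
variation; that realism is unnecessary for any algorithm in this package.
Synthetic phenotype metadata (trait groups, a small HPO vocabulary, genders,
platforms) is attached so the suppression step has real work to do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from .model import CohortDataset, SampleMeta, SnvKey, ValidationError, snv_sort_key

_BASES = np.array(list("ACGT"))

_CONTACT = ("Data Steward", "Synthetic Genomics Unit", "steward@example.org")

# (trait label, base HPO-present set, one optional absent term)
_TRAIT_POOL = [
    ("early-onset epilepsy", ["HP:0001250", "HP:0001263"], "HP:0001249"),
    ("retinal dystrophy", ["HP:0000556", "HP:0000505"], "HP:0000365"),
    ("inflammatory bowel disease", ["HP:0002037", "HP:0004387"], "HP:0002028"),
]
_PLATFORMS = ["Illumina HiSeq 2000", "SOLiD 5500xl"]
_ENRICHMENTS = ["Agilent SureSelect v4", "NimbleGen SeqCap EZ v3"]


@dataclass
class SfsConfig:
    """Parameters of the occurrence-count mixture and cohort layout."""

    n_samples: int = 50
    n_sites: int = 140_000
    alpha: float = 1.0  # power-law exponent of the low-frequency component
    common_weight: float = 0.10  # mixture weight of the common component
    common_band: float = 0.10  # top fraction of counts the common component spans
    p_hom: float = 1.0 / 3.0  # probability a carrier is homozygous-alt
    seed: int = 0
    rsid_fraction: float = 0.2  # fraction of sites given a synthetic dbSNP id

    def validate(self) -> "SfsConfig":
        if self.n_samples < 2:
            raise ValidationError("n_samples must be >= 2")
        if self.n_sites < 1:
            raise ValidationError("n_sites must be >= 1")
        if self.alpha <= 0:
            raise ValidationError("alpha must be > 0")
        if not 0 <= self.common_weight < 1:
            raise ValidationError("common_weight must be in [0, 1)")
        if not 0 < self.common_band <= 1:
            raise ValidationError("common_band must be in (0, 1]")
        if not 0 <= self.p_hom <= 1:
            raise ValidationError("p_hom must be in [0, 1]")
        if self.n_sites * self.n_samples > 500_000_000:
            raise ValidationError(
                "n_sites x n_samples too large for in-memory simulation"
            )
        return self


def site_count_pmf(config: SfsConfig) -> np.ndarray:
    """Analytic mixture pmf over k = 1..n (index 0 corresponds to k=1)."""
    config.validate()
    n = config.n_samples
    k = np.arange(1, n + 1, dtype=float)
    power = k ** (-config.alpha)
    power /= power.sum()
    lo = math.ceil((1.0 - config.common_band) * n)
    lo = max(1, lo)
    uniform = np.zeros(n)
    uniform[lo - 1 :] = 1.0 / (n - lo + 1)
    return (1.0 - config.common_weight) * power + config.common_weight * uniform


def sample_site_counts(
    config: SfsConfig, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Draw one occurrence count per site, i.i.d. from the mixture."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    pmf = site_count_pmf(config)
    return rng.choice(np.arange(1, config.n_samples + 1), size=config.n_sites, p=pmf)


def _synthetic_metadata(
    sample_ids: List[str], rng: np.random.Generator
) -> List[SampleMeta]:
    n = len(sample_ids)
    max_groups = max(1, min(4, n // 2))
    n_groups = int(rng.integers(2, max_groups + 1)) if max_groups >= 2 else 1
    bounds = np.linspace(0, n, n_groups + 1).astype(int)
    metas: List[SampleMeta] = []
    for g in range(n_groups):
        members = sample_ids[bounds[g] : bounds[g + 1]]
        if g == 0 and n_groups > 1:
            trait, status = "healthy control", "control"
            hpo_base, hpo_absent = [], None
        else:
            trait, hpo_base, hpo_absent = _TRAIT_POOL[(g - 1) % len(_TRAIT_POOL)]
            status = "patient"
        for sid in members:
            # most members share the group's exact HPO set; a minority drop
            # the last term, giving the suppression step singleton sets to fix
            present = list(hpo_base)
            if present and rng.random() < 0.2:
                present = present[:-1]
            absent = [hpo_absent] if hpo_absent and rng.random() < 0.5 else []
            metas.append(
                SampleMeta(
                    sample_id=sid,
                    status=status,
                    trait=trait,
                    hpo_present=frozenset(present),
                    hpo_absent=frozenset(absent),
                    gender=str(rng.choice(["male", "female"])),
                    platform=str(rng.choice(_PLATFORMS)),
                    enrichment=str(rng.choice(_ENRICHMENTS)),
                    pi="P. Investigator",
                    contact=_CONTACT,
                    contact_release=False,
                )
            )
    return metas


def simulate_cohort(config: SfsConfig) -> CohortDataset:
    """Generate a full cohort: calls, rsids and metadata, deterministic in seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, n_sites = config.n_samples, config.n_sites
    sample_ids = [f"sample_{i:03d}" for i in range(1, n + 1)]

    ks = sample_site_counts(config, rng)
    # uniform-without-replacement carriers: row-wise random permutations
    order = np.argsort(rng.random((n_sites, n)), axis=1)
    hom_flags = rng.random(int(ks.sum())) < config.p_hom
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    rsid_flags = rng.random(n_sites) < config.rsid_fraction

    dataset = CohortDataset(sample_ids=sample_ids)
    cursor = 0
    for i in range(n_sites):
        chrom = f"chr{(i % 22) + 1}"
        pos = 100_000 + (i // 22) * 17
        key = SnvKey(chrom, pos, str(_BASES[ref_idx[i]]), str(_BASES[alt_idx[i]]))
        k = int(ks[i])
        carriers = {}
        for j in order[i, :k]:
            carriers[sample_ids[j]] = "hom_alt" if hom_flags[cursor] else "het"
            cursor += 1
        dataset.calls[key] = carriers
        if rsid_flags[i]:
            dataset.rsids[key] = f"rs{10_000_000 + i}"

    dataset.attach_metadata(_synthetic_metadata(sample_ids, rng))
    return dataset


# ---------------------------------------------------------------------------
# on-disk fixture set


def write_cohort(dataset: CohortDataset, outdir: str) -> str:
    """Write one VCF per sample plus meta.ini; returns the INI path."""
    from .vcf_io import write_ini  # deferred: avoids import cycle

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    per_sample: Dict[str, Dict[SnvKey, str]] = {sid: {} for sid in dataset.sample_ids}
    for key, carriers in dataset.calls.items():
        for sid, zyg in carriers.items():
            per_sample[sid][key] = zyg

    chroms = sorted(
        {key.chrom for key in dataset.calls}, key=lambda c: snv_sort_key(SnvKey(c, 1, "A", "G"))
    )
    metas = []
    for sid in dataset.sample_ids:
        vcf_path = out / f"{sid}.vcf"
        lines = [
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            *[f"##contig=<ID={c}>" for c in chroms],
            f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sid}",
        ]
        for key in sorted(per_sample[sid], key=snv_sort_key):
            gt = "1/1" if per_sample[sid][key] == "hom_alt" else "0/1"
            rsid = dataset.rsids.get(key, ".")
            lines.append(
                f"{key.chrom}\t{key.pos}\t{rsid}\t{key.ref}\t{key.alt}\t.\tPASS\t.\tGT\t{gt}"
            )
        vcf_path.write_text("\n".join(lines) + "\n")
        # stored INI-relative: meta.ini lives in the same directory
        meta = dataset.meta[sid].copy(vcf=vcf_path.name)
        metas.append(meta)

    ini_path = out / "meta.ini"
    write_ini(metas, str(ini_path))
    return str(ini_path)
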