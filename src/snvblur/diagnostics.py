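"""Privacy / aggregation-quality diagnostics.

Three evaluations:

* ``unblurred_ratio`` — fraction of genotype records (sample-site carrier
  pairs) that keep sub-sample linkage after blurring. The per-site variant
  (fraction of distinct sites unblurred) is reported alongside, since the
  two readings differ: common variants dominate the record-weighted ratio.
* ``ratio_curve`` — the unblurred ratio as a function of cohort size. It
  grows with n and saturates: once the median-adaptive threshold stabilizes
  relative to n, the blurred mass is the fixed low-frequency tail.
* ``overlap_assessment`` — the re-identification experiment: given one
  non-aggregated probe sample, score every released sub-sample by shared
  count, containment and Jaccard against the probe's full SNV set, and ask
  whether the probe's own sub-samples stand out. Own sub-samples have
  containment 1.0 by construction (they are subsets of the probe), so the
  headline metric is Jaccard top-K identification precision, K being the
  number of own sub-samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .fragmentation import decrypt_linkage
from .model import SnvKey, ValidationError
from .rare_blur import (
    AggregateConfig,
    aggregate_dataset,
    occurrence_counts,
    threshold_from_counts,
)
from .simdata import SfsConfig, sample_site_counts, simulate_cohort
from .store import AggregatedStore


def unblurred_ratio(store: AggregatedStore, per_site: bool = False) -> float:
    """Fraction of genotype records retaining sub-sample linkage.

    ``per_site=True`` weights every site equally instead of by carrier count.
    """
    if not store.records:
        raise ValidationError("cannot compute a ratio on an empty store")
    if per_site:
        return sum(1 for r in store.records if not r.blurred) / len(store.records)
    total = sum(r.carrier_count for r in store.records)
    kept = sum(r.carrier_count for r in store.records if not r.blurred)
    return kept / total


def _spectrum_ratios(counts: np.ndarray, factor: float) -> Tuple[float, float]:
    """(record-weighted, site-weighted) unblurred ratio implied by a count
    spectrum under the median-adaptive threshold.

    Identical to aggregating and calling :func:`unblurred_ratio`: a record is
    unblurred iff its count exceeds the threshold, and it then contributes
    its count (or 1, per-site) to the numerator.
    """
    threshold = threshold_from_counts(counts, factor)
    unblurred = counts > threshold
    return (
        float(counts[unblurred].sum() / counts.sum()),
        float(unblurred.sum() / counts.size),
    )


def ratio_curve(
    sizes: Sequence[int],
    config: Optional[SfsConfig] = None,
    replicates: int = 5,
    factor: float = 1.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean +/- sd of the unblurred ratio across simulated cohort sizes.

    Each replicate draws a fresh occurrence-count spectrum from the default
    generator at that n and applies the 1.5 x median rule.
    """
    base = config or SfsConfig()
    rows = []
    rng = np.random.default_rng(seed)
    for n in sizes:
        if n < 2:
            raise ValidationError("cohort sizes must be >= 2")
        record_ratios, site_ratios = [], []
        for _ in range(replicates):
            cfg = SfsConfig(
                n_samples=n,
                n_sites=base.n_sites,
                alpha=base.alpha,
                common_weight=base.common_weight,
                common_band=base.common_band,
                p_hom=base.p_hom,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            counts = sample_site_counts(cfg)
            rec, site = _spectrum_ratios(counts, factor)
            record_ratios.append(rec)
            site_ratios.append(site)
        rows.append(
            {
                "n": n,
                "mean_ratio": float(np.mean(record_ratios)),
                "sd_ratio": float(np.std(record_ratios, ddof=1)) if replicates > 1 else 0.0,
                "mean_site_ratio": float(np.mean(site_ratios)),
                "sd_site_ratio": float(np.std(site_ratios, ddof=1)) if replicates > 1 else 0.0,
                "replicates": replicates,
            }
        )
    return pd.DataFrame(rows)


def sfs_histogram(dataset) -> pd.DataFrame:
    """Exact occurrence-count histogram (site frequency spectrum) of a cohort."""
    table = occurrence_counts(dataset)
    counter: Dict[int, int] = {}
    for k in table.counts.values():
        counter[k] = counter.get(k, 0) + 1
    return pd.DataFrame(
        {"k": sorted(counter), "n_sites": [counter[k] for k in sorted(counter)]}
    )


def singleton_common_ratio(hist: pd.DataFrame, n_samples: int) -> float:
    """Singleton sites per whole-cohort ("common") site."""
    by_k = dict(zip(hist["k"], hist["n_sites"]))
    common = by_k.get(n_samples, 0)
    if common == 0:
        raise ValidationError("no site is carried by all samples")
    return by_k.get(1, 0) / common


# ---------------------------------------------------------------------------
# re-identification overlap experiment


@dataclass
class OverlapEntry:
    sub_id: str
    size: int
    shared: int
    containment: float
    jaccard: float
    is_own: bool


@dataclass
class OverlapReport:
    probe_sample: str
    probe_size: int
    entries: List[OverlapEntry] = field(default_factory=list)
    summary: Dict[str, object] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sub_id": e.sub_id,
                    "size": e.size,
                    "shared": e.shared,
                    "containment": e.containment,
                    "jaccard": e.jaccard,
                    "is_own": e.is_own,
                }
                for e in self.entries
            ]
        )


def _released_sub_contents(store: AggregatedStore) -> Dict[str, Set[SnvKey]]:
    subs: Dict[str, Set[SnvKey]] = {}
    for rec in store.records:
        if rec.blurred:
            continue
        for sub_id, _zyg in rec.sub_calls:
            subs.setdefault(sub_id, set()).add(rec.key)
    return subs


def overlap_assessment(
    store: AggregatedStore,
    linkage_bytes: bytes,
    passphrase: str,
    probe_sample: str,
    probe_calls: Optional[Set[SnvKey]] = None,
) -> OverlapReport:
    """Score every released sub-sample against one probe sample.

    This is an evaluator-side experiment: the linkage file supplies both the
    probe's full (non-aggregated) SNV set and the ground-truth ``is_own``
    flags an attacker would not have. For each metric the summary reports
    the ranks of the probe's own sub-samples and the top-K identification
    precision with K = number of own sub-samples.
    """
    linkage = decrypt_linkage(linkage_bytes, passphrase)
    record = next((r for r in linkage if r.sample_id == probe_sample), None)
    if record is None:
        raise ValidationError(f"probe sample {probe_sample!r} not in linkage file")
    probe = probe_calls if probe_calls is not None else set(record.calls)
    if not probe:
        raise ValidationError("probe sample has no SNVs")
    own = set(record.sub_ids)

    report = OverlapReport(probe_sample=probe_sample, probe_size=len(probe))
    for sub_id, content in sorted(_released_sub_contents(store).items()):
        shared = len(content & probe)
        union = len(content | probe)
        report.entries.append(
            OverlapEntry(
                sub_id=sub_id,
                size=len(content),
                shared=shared,
                containment=shared / len(content),
                jaccard=shared / union if union else 0.0,
                is_own=sub_id in own,
            )
        )

    n_own = sum(1 for e in report.entries if e.is_own)
    summary: Dict[str, object] = {"n_subsamples": len(report.entries), "n_own": n_own}
    for metric in ("shared", "containment", "jaccard"):
        ordered = sorted(
            report.entries, key=lambda e: (-getattr(e, metric), e.sub_id)
        )
        own_ranks = [i + 1 for i, e in enumerate(ordered) if e.is_own]
        top_k = ordered[:n_own]
        precision = (
            sum(1 for e in top_k if e.is_own) / n_own if n_own else float("nan")
        )
        summary[f"{metric}_own_ranks"] = own_ranks
        summary[f"{metric}_topk_precision"] = precision
    report.summary = summary
    return report


def identification_experiment(
    n_samples: int = 10,
    n_sites: int = 20_000,
    seeds: Sequence[int] = tuple(range(20)),
    factor: float = 1.5,
    passphrase: str = "evaluator",
) -> pd.DataFrame:
    """Repeat the probe-identification experiment over fresh cohorts.

    One probe sample per seed (chosen by the seed), full pipeline, Jaccard /
    containment / shared top-K precision recorded per run.
    """
    rows = []
    for seed in seeds:
        cfg = SfsConfig(n_samples=n_samples, n_sites=n_sites, seed=int(seed))
        dataset = simulate_cohort(cfg)
        store, linkage, _log = aggregate_dataset(
            dataset,
            AggregateConfig(seed=int(seed) + 1, passphrase=passphrase, factor=factor),
        )
        probe_idx = int(np.random.default_rng(seed).integers(0, n_samples))
        probe = dataset.sample_ids[probe_idx]
        report = overlap_assessment(store, linkage, passphrase, probe)
        rows.append(
            {
                "seed": int(seed),
                "probe": probe,
                "n_subsamples": report.summary["n_subsamples"],
                "n_own": report.summary["n_own"],
                "jaccard_precision": report.summary["jaccard_topk_precision"],
                "containment_precision": report.summary["containment_topk_precision"],
                "shared_precision": report.summary["shared_topk_precision"],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# optional plots


def plot_ratio_curve(curve: pd.DataFrame, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.errorbar(curve["n"], curve["mean_ratio"], yerr=curve["sd_ratio"], marker="o")
    ax.set_xlabel("aggregated samples (n)")
    ax.set_ylabel("unblurred genotype-record ratio")
    ax.set_ylim(0, 1)
    ax.grid(alpha=0.3)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_sfs(hist: pd.DataFrame, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(hist["k"], hist["n_sites"], width=0.9)
    ax.set_xlabel("occurrence count k (samples carrying the SNV)")
    ax.set_ylabel("number of sites")
    ax.set_yscale("log")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
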