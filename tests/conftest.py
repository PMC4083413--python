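import numpy as np
import pytest

from snvblur import AggregateConfig, SampleMeta, SfsConfig, SnvKey, simulate_cohort

CONTACT = ("A. Submitter", "Example Institute", "submitter@example.org")


def make_meta(sample_id, trait="epilepsy", status="patient", **kwargs):
    kwargs.setdefault("contact", CONTACT)
    return SampleMeta(sample_id=sample_id, status=status, trait=trait, **kwargs)


def fuzz_cohort(rng: np.random.Generator, n_min=4, n_max=12, k=2):
    """Random metadata cohort in which every trait label occurs >= k times."""
    n = int(rng.integers(n_min, n_max + 1))
    traits = ["trait A", "trait B", "trait C"][: int(rng.integers(1, 4))]
    # round-robin assignment guarantees >= k per label (n >= k * len(traits))
    while n < k * len(traits):
        traits.pop()
    hpo_pool = ["HP:0001250", "HP:0001263", "HP:0000556", "HP:0004387"]
    metas = []
    for i in range(n):
        present = frozenset(
            rng.choice(hpo_pool, size=int(rng.integers(0, 3)), replace=False)
        )
        absent_pool = [h for h in hpo_pool if h not in present]
        absent = frozenset(
            rng.choice(absent_pool, size=int(rng.integers(0, 2)), replace=False)
        )
        metas.append(
            make_meta(
                f"fuzzsample_{i:04d}",
                trait=traits[i % len(traits)],
                status="patient" if rng.random() < 0.7 else "control",
                hpo_present=present,
                hpo_absent=absent,
                gender=str(rng.choice(["male", "female"])) if rng.random() < 0.8 else None,
                platform=str(rng.choice(["P1", "P2"])) if rng.random() < 0.7 else None,
                enrichment=str(rng.choice(["E1", "E2"])) if rng.random() < 0.6 else None,
            )
        )
    return metas


@pytest.fixture(scope="session")
def small_cohort():
    """8 samples x 400 sites with metadata; shared read-only across tests."""
    return simulate_cohort(SfsConfig(n_samples=8, n_sites=400, seed=11))


@pytest.fixture()
def agg_config():
    return AggregateConfig(seed=42, passphrase="correct horse")


def toy_calls(n_sites=6, carrier="s1"):
    return {
        SnvKey("chr1", 100 + 10 * i, "A", "G"): ("het" if i % 2 else "hom_alt")
        for i in range(n_sites)
    }
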