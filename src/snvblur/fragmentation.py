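"""Weighted fragmentation of samples into sub-samples (aggregation step 2).

Each sample's SNVs are split into up to ``n_subsamples`` fragments of
deliberately unequal size: per-sample assignment weights are drawn once from
the flat (symmetric, concentration 1) law on the probability simplex, then
every SNV is assigned independently with those weights. Equal-sized
fragments would let an attacker regroup a sample's sub-samples by size, so
non-uniformity is the point — under the flat law the expected coefficient of
variation of fragment sizes is sqrt((m-1)/(m+1)), about 0.82 for m=5.

Sub-sample ids are 128-bit random tokens that carry no information about the
source sample. The secret sample <-> sub-sample map (plus each sample's full
call list, needed for consent withdrawal) lives only in an encrypted,
passphrase-protected linkage file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from ._crypto import decrypt_bytes, encrypt_bytes
from .model import SnvKey, ValidationError, snv_sort_key


@dataclass
class FragmentationConfig:
    n_subsamples: int = 5
    weight_law: str = "flat-simplex"
    seed: Optional[int] = None

    def validate(self) -> "FragmentationConfig":
        if self.n_subsamples < 1:
            raise ValidationError(
                f"n_subsamples must be >= 1, got {self.n_subsamples}"
            )
        if self.weight_law != "flat-simplex":
            raise ValidationError(f"unknown weight law {self.weight_law!r}")
        return self


@dataclass
class SubSample:
    sub_id: str
    calls: Dict[SnvKey, str] = field(default_factory=dict)


@dataclass
class LinkageRecord:
    """Secret record: one sample, its sub-sample ids and full call list.

    Trait and class id ride along so that consent withdrawal can decrement
    blurred-record summaries; the record exists only inside the encrypted
    linkage file.
    """

    sample_id: str
    sub_ids: List[str] = field(default_factory=list)
    calls: Dict[SnvKey, str] = field(default_factory=dict)
    trait: str = ""
    class_id: str = ""
    released: Optional[tuple] = None  # the sample's released attribute tuple


def _new_sub_id(rng: np.random.Generator) -> str:
    return bytes(rng.integers(0, 256, size=16, dtype=np.uint8)).hex()


def fragment_sample(
    calls: Dict[SnvKey, str],
    config: FragmentationConfig,
    rng: np.random.Generator,
) -> List[SubSample]:
    """Partition one sample's calls into unequally weighted sub-samples.

    Deterministic for a fixed RNG state; empty fragments are dropped; the
    union of returned call maps always equals the input exactly.
    """
    config.validate()
    m = config.n_subsamples
    subs = [SubSample(sub_id=_new_sub_id(rng)) for _ in range(m)]
    if not calls:
        return []
    weights = rng.dirichlet(np.ones(m)) if m > 1 else np.ones(1)
    keys = sorted(calls, key=snv_sort_key)
    assignment = rng.choice(m, size=len(keys), p=weights)
    for key, idx in zip(keys, assignment):
        subs[idx].calls[key] = calls[key]
    return [s for s in subs if s.calls]


# ---------------------------------------------------------------------------
# encrypted linkage file


def _records_to_json(records: List[LinkageRecord]) -> bytes:
    payload = [
        {
            "sample_id": r.sample_id,
            "sub_ids": list(r.sub_ids),
            "calls": {str(k): z for k, z in sorted(r.calls.items(), key=lambda kv: snv_sort_key(kv[0]))},
            "trait": r.trait,
            "class_id": r.class_id,
            "released": (
                [
                    r.released[0],
                    sorted(r.released[1]),
                    sorted(r.released[2]),
                    r.released[3],
                    r.released[4],
                    r.released[5],
                ]
                if r.released is not None
                else None
            ),
        }
        for r in records
    ]
    return json.dumps(payload, sort_keys=True).encode("utf-8")


def _records_from_json(blob: bytes) -> List[LinkageRecord]:
    payload = json.loads(blob.decode("utf-8"))
    return [
        LinkageRecord(
            sample_id=r["sample_id"],
            sub_ids=list(r["sub_ids"]),
            calls={SnvKey.from_string(k): z for k, z in r["calls"].items()},
            trait=r.get("trait", ""),
            class_id=r.get("class_id", ""),
            released=(
                (
                    r["released"][0],
                    frozenset(r["released"][1]),
                    frozenset(r["released"][2]),
                    r["released"][3],
                    r["released"][4],
                    r["released"][5],
                )
                if r.get("released") is not None
                else None
            ),
        )
        for r in payload
    ]


def encrypt_linkage(
    records: List[LinkageRecord],
    passphrase: str,
    rng: Optional[np.random.Generator] = None,
) -> bytes:
    """Serialize + encrypt the sample <-> sub-sample map.

    When ``rng`` is given, KDF salt and nonce are drawn from it so that a
    fixed pipeline seed reproduces the file byte-for-byte; otherwise both
    come from the OS entropy pool.
    """
    plaintext = _records_to_json(records)
    if rng is None:
        return encrypt_bytes(plaintext, passphrase)
    salt = bytes(rng.integers(0, 256, size=16, dtype=np.uint8))
    nonce = bytes(rng.integers(0, 256, size=16, dtype=np.uint8))
    return encrypt_bytes(plaintext, passphrase, salt=salt, nonce=nonce)


def decrypt_linkage(ciphertext: bytes, passphrase: str) -> List[LinkageRecord]:
    """Inverse of :func:`encrypt_linkage`; tampering or a wrong passphrase
    raises :class:`~snvblur.model.AuthenticationError` with no partial output."""
    return _records_from_json(decrypt_bytes(ciphertext, passphrase))
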