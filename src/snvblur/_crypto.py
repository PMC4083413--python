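"""Password-based authenticated symmetric encryption for the linkage file.

Construction (stdlib-only, standard components):

* KDF: scrypt (n=2**14, r=8, p=1) over passphrase + random 16-byte salt,
  yielding a 32-byte cipher key and a 32-byte MAC key.
* Cipher: HMAC-SHA256 keystream in counter mode (PRF stream cipher) XORed
  with the plaintext; nonce is 16 random bytes.
* Integrity: encrypt-then-MAC, HMAC-SHA256 over header || nonce || ciphertext;
  verified with a constant-time compare before any byte is decrypted.

The container stores magic bytes, the scheme identifier and the KDF
parameters in a cleartext JSON header, so files remain self-describing.
"""

from __future__ import annotations

import hashlib
import hmac
import json
import os
import struct

from .model import AuthenticationError, ValidationError

MAGIC = b"SNVBLK1\x00"
SCHEME = "scrypt+hmac-sha256-ctr+hmac-sha256"
_BLOCK = 32


def _derive_keys(passphrase: str, salt: bytes, n: int, r: int, p: int) -> tuple:
    raw = hashlib.scrypt(
        passphrase.encode("utf-8"), salt=salt, n=n, r=r, p=p, maxmem=64 * 1024 * 1024,
        dklen=64,
    )
    return raw[:32], raw[32:]


def _keystream_xor(key: bytes, nonce: bytes, data: bytes) -> bytes:
    out = bytearray(len(data))
    for block_idx in range(0, len(data), _BLOCK):
        counter = struct.pack(">Q", block_idx // _BLOCK)
        block = hmac.new(key, nonce + counter, hashlib.sha256).digest()
        chunk = data[block_idx : block_idx + _BLOCK]
        for i, byte in enumerate(chunk):
            out[block_idx + i] = byte ^ block[i]
    return bytes(out)


def encrypt_bytes(
    plaintext: bytes,
    passphrase: str,
    *,
    salt: bytes | None = None,
    nonce: bytes | None = None,
    kdf_n: int = 2 ** 14,
) -> bytes:
    if not passphrase:
        raise ValidationError("passphrase must be non-empty")
    salt = salt if salt is not None else os.urandom(16)
    nonce = nonce if nonce is not None else os.urandom(16)
    header = json.dumps(
        {
            "scheme": SCHEME,
            "kdf": {"name": "scrypt", "n": kdf_n, "r": 8, "p": 1},
            "salt": salt.hex(),
            "nonce": nonce.hex(),
        },
        sort_keys=True,
    ).encode("ascii")
    enc_key, mac_key = _derive_keys(passphrase, salt, kdf_n, 8, 1)
    ciphertext = _keystream_xor(enc_key, nonce, plaintext)
    tag = hmac.new(mac_key, header + nonce + ciphertext, hashlib.sha256).digest()
    return MAGIC + struct.pack(">I", len(header)) + header + ciphertext + tag


def decrypt_bytes(container: bytes, passphrase: str) -> bytes:
    if not passphrase:
        raise ValidationError("passphrase must be non-empty")
    if len(container) < len(MAGIC) + 4 + 32 or not container.startswith(MAGIC):
        raise AuthenticationError("not a linkage container (bad magic)")
    offset = len(MAGIC)
    (header_len,) = struct.unpack(">I", container[offset : offset + 4])
    offset += 4
    header = container[offset : offset + header_len]
    offset += header_len
    body = container[offset:]
    if len(body) < 32:
        raise AuthenticationError("truncated container")
    ciphertext, tag = body[:-32], body[-32:]
    try:
        meta = json.loads(header.decode("ascii"))
        salt = bytes.fromhex(meta["salt"])
        nonce = bytes.fromhex(meta["nonce"])
        kdf = meta["kdf"]
        if meta["scheme"] != SCHEME:
            raise AuthenticationError(f"unsupported scheme {meta['scheme']!r}")
    except (ValueError, KeyError, UnicodeDecodeError) as exc:
        raise AuthenticationError(f"corrupt container header: {exc}") from exc
    enc_key, mac_key = _derive_keys(passphrase, salt, kdf["n"], kdf["r"], kdf["p"])
    expected = hmac.new(mac_key, header + nonce + ciphertext, hashlib.sha256).digest()
    if not hmac.compare_digest(expected, tag):
        raise AuthenticationError(
            "authentication failed: wrong passphrase or tampered file"
        )
    return _keystream_xor(enc_key, nonce, ciphertext)
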