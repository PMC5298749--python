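"""AES-128 payload protection for radio packets.

A self-contained implementation of the AES-128 block cipher (FIPS-197:
SubBytes / ShiftRows / MixColumns / AddRoundKey over 10 rounds) and CTR
mode.  CTR needs only the forward cipher, keeps ciphertext the same length
as plaintext, and tolerates the short, fixed-size frames of a low-power
radio link.  Each encrypted payload carries its 8-byte nonce in front; the
per-message counter block is nonce || 64-bit big-endian block counter.

Key distribution is out of scope: callers hold a static pre-shared 16-byte
key.  Nonce uniqueness is the caller's responsibility (a repeated nonce
under one key leaks the XOR of the plaintexts); the helpers only log a
warning, they cannot see other sessions.
"""

from __future__ import annotations

import logging
import os

logger = logging.getLogger(__name__)

_SBOX = bytes.fromhex(
    "637c777bf26b6fc53001672bfed7ab76"
    "ca82c97dfa5947f0add4a2af9ca472c0"
    "b7fd9326363ff7cc34a5e5f171d83115"
    "04c723c31896059a071280e2eb27b275"
    "09832c1a1b6e5aa0523bd6b329e32f84"
    "53d100ed20fcb15b6acbbe394a4c58cf"
    "d0efaafb434d338545f9027f503c9fa8"
    "51a3408f929d38f5bcb6da2110fff3d2"
    "cd0c13ec5f974417c4a77e3d645d1973"
    "60814fdc222a908846eeb814de5e0bdb"
    "e0323a0a4906245cc2d3ac629195e479"
    "e7c8376d8dd54ea96c56f4ea657aae08"
    "ba78252e1ca6b4c6e8dd741f4bbd8b8a"
    "703eb5664803f60e613557b986c11d9e"
    "e1f8981169d98e949b1e87e9ce5528df"
    "8ca1890dbfe6426841992d0fb054bb16"
)

_RCON = (0x01, 0x02, 0x04, 0x08, 0x10, 0x20, 0x40, 0x80, 0x1B, 0x36)

NONCE_BYTES = 8
BLOCK_BYTES = 16


def _xtime(a: int) -> int:
    a <<= 1
    if a & 0x100:
        a ^= 0x11B
    return a & 0xFF


def expand_key(key: bytes) -> list[bytes]:
    """AES-128 key schedule: 11 round keys of 16 bytes each."""
    if len(key) != 16:
        raise ValueError("AES-128 requires a 16-byte key")
    words = [key[4 * i : 4 * i + 4] for i in range(4)]
    for i in range(4, 44):
        temp = words[i - 1]
        if i % 4 == 0:
            temp = bytes(
                _SBOX[temp[(j + 1) % 4]] ^ (_RCON[i // 4 - 1] if j == 0 else 0)
                for j in range(4)
            )
        words.append(bytes(a ^ b for a, b in zip(words[i - 4], temp)))
    return [b"".join(words[4 * r : 4 * r + 4]) for r in range(11)]


def _encrypt_block(block: bytes, round_keys: list[bytes]) -> bytes:
    # state laid out column-major per FIPS-197: s[r][c] = in[r + 4c]
    s = [[block[r + 4 * c] ^ round_keys[0][r + 4 * c] for c in range(4)] for r in range(4)]
    for rnd in range(1, 11):
        # SubBytes + ShiftRows
        s = [[_SBOX[s[r][(c + r) % 4]] for c in range(4)] for r in range(4)]
        if rnd < 10:
            # MixColumns
            for c in range(4):
                a = [s[r][c] for r in range(4)]
                t = a[0] ^ a[1] ^ a[2] ^ a[3]
                u = a[0]
                s[0][c] = a[0] ^ t ^ _xtime(a[0] ^ a[1])
                s[1][c] = a[1] ^ t ^ _xtime(a[1] ^ a[2])
                s[2][c] = a[2] ^ t ^ _xtime(a[2] ^ a[3])
                s[3][c] = a[3] ^ t ^ _xtime(a[3] ^ u)
        rk = round_keys[rnd]
        for c in range(4):
            for r in range(4):
                s[r][c] ^= rk[r + 4 * c]
    return bytes(s[r][c] for c in range(4) for r in range(4))


def aes128_encrypt_block(block: bytes, key: bytes) -> bytes:
    """Encrypt one 16-byte block (used for known-answer validation)."""
    if len(block) != BLOCK_BYTES:
        raise ValueError("block must be 16 bytes")
    return _encrypt_block(block, expand_key(key))


def aes128_ctr(data: bytes, key: bytes, counter_block: bytes) -> bytes:
    """CTR keystream XOR starting from a full 16-byte counter block.

    The counter block is incremented as a 128-bit big-endian integer per
    block, matching NIST SP 800-38A.  Encryption and decryption are the
    same operation.
    """
    if len(counter_block) != BLOCK_BYTES:
        raise ValueError("counter block must be 16 bytes")
    rk = expand_key(key)
    ctr = int.from_bytes(counter_block, "big")
    out = bytearray()
    for off in range(0, len(data), BLOCK_BYTES):
        ks = _encrypt_block(ctr.to_bytes(BLOCK_BYTES, "big"), rk)
        chunk = data[off : off + BLOCK_BYTES]
        out.extend(a ^ b for a, b in zip(chunk, ks))
        ctr = (ctr + 1) % (1 << 128)
    return bytes(out)


def encrypt_payload(payload: bytes, key: bytes, nonce: bytes | None = None) -> bytes:
    """Encrypt a packet payload; the 8-byte nonce is prepended to the output.

    A fresh random nonce is drawn when none is supplied.  Supplying your own
    nonce is for tests and replay-controlled protocols; reusing one is
    logged as a warning on a best-effort basis (within this process only).
    """
    if nonce is None:
        nonce = os.urandom(NONCE_BYTES)
    if len(nonce) != NONCE_BYTES:
        raise ValueError(f"nonce must be {NONCE_BYTES} bytes")
    if nonce in _seen_nonces:
        logger.warning("nonce reuse detected; CTR keystream repeats")
    _seen_nonces.add(nonce)
    counter0 = nonce + (0).to_bytes(8, "big")
    return nonce + aes128_ctr(payload, key, counter0)


def decrypt_payload(blob: bytes, key: bytes) -> bytes:
    """Inverse of :func:`encrypt_payload`."""
    if len(blob) < NONCE_BYTES:
        raise ValueError("blob shorter than nonce")
    nonce, ct = blob[:NONCE_BYTES], blob[NONCE_BYTES:]
    counter0 = nonce + (0).to_bytes(8, "big")
    return aes128_ctr(ct, key, counter0)


_seen_nonces: set[bytes] = set()
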