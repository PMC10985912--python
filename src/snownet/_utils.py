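"""Small internal helpers."""

from __future__ import annotations

import hashlib


def derive_seed(master_seed: int, *tokens) -> int:
    """Deterministic child seed from a master seed and a token path.

    Hashes ``master_seed`` together with the stringified tokens (stage names,
    condition labels, filter pairs, replicate indices, ...) so every
    (stage, network) combination gets an independent, reproducible stream.
    Result fits in 31 bits.
    """
    h = hashlib.blake2b(digest_size=8)
    h.update(str(int(master_seed)).encode())
    for t in tokens:
        h.update(b"\x00")
        h.update(str(t).encode())
    return int.from_bytes(h.digest(), "big") % (2**31)
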