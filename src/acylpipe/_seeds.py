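"""Deterministic fan-out of one global seed into per-stage child seeds."""

import hashlib


def child_seed(seed: int, stage: str) -> int:
    """Derive a stage-specific 32-bit seed from the global seed.

    The derivation is a stable hash of ``"<seed>:<stage>"`` so each stage is
    independently reproducible from the (seed, stage-name) pair alone.
    """
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")
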